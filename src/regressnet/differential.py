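"""Moderated t-statistics for the responder vs non-responder contrast.

Per-gene pooled variances are shrunk toward a common prior by empirical
Bayes: the gene-wise sample variances s_g^2 (d_g residual df each) are
modelled as scaled F draws around a prior variance s0^2 with d0 prior df, the
hyperparameters are estimated by closed-form method-of-moments on log s_g^2
(digamma/trigamma inversion), and the moderated t uses the posterior variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

with d0 + d_g degrees of freedom.  Benjamini-Hochberg adjustment controls the
false discovery rate, and module-level association summarizes the per-gene
t-statistics module by module.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging
import math

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionDataset

logger = logging.getLogger("regressnet")


@dataclass
class DifferentialResult:
    """Per-gene moderated-t table plus the empirical-Bayes hyperparameters.

    ``table`` is indexed by gene with columns ``logFC`` (mean responder minus
    mean nonresponder, log2 units), ``s2`` (pooled variance), ``df_residual``,
    ``t_mod``, ``p``, ``q``.
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float
    group_a: str = "responder"
    group_b: str = "nonresponder"


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError(f"trigamma inverse needs y > 0, got {y}")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) / x < tol:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the (d0, s0^2) variance prior.

    Works on z = log s^2: after removing the known digamma offset of each
    gene's residual df, the mean of the residuals estimates
    log s0^2 - digamma(d0/2) + log(d0/2) and their excess variance (beyond
    the known trigamma term) estimates trigamma(d0/2).  A non-positive excess
    variance signals no detectable gene-to-gene variance heterogeneity and
    yields d0 = inf.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    if np.any(s2 <= 0):
        raise ValueError("all gene variances must be positive to fit the prior")
    if len(s2) < 2:
        # a single gene carries no pooling information: no shrinkage
        return 0.0, float(s2[0])
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0).mean())
    if evar > 0:
        half_d0 = trigamma_inverse(evar)
        d0 = 2.0 * half_d0
        s0_sq = math.exp(emean + special.digamma(half_d0) - math.log(half_d0))
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    return d0, s0_sq


def moderated_t_test(
    data: ExpressionDataset,
    group_a: str = "responder",
    group_b: str = "nonresponder",
    d0: float | None = None,
    s0_sq: float | None = None,
) -> DifferentialResult:
    """Empirical-Bayes moderated two-sample t-test per gene.

    The prior (d0, s0^2) is estimated from the data unless supplied; d0 = 0
    reduces to the classical pooled-variance t-test, d0 = inf replaces every
    gene's variance by the prior.
    """
    samples_a = data.samples_in_group(group_a)
    samples_b = data.samples_in_group(group_b)
    n_a, n_b = len(samples_a), len(samples_b)
    if n_a < 2 or n_b < 2:
        raise ValueError(
            f"each group needs >= 2 samples; got {group_a}={n_a}, {group_b}={n_b}"
        )
    xa = data.values[samples_a].to_numpy()
    xb = data.values[samples_b].to_numpy()
    logfc = xa.mean(axis=1) - xb.mean(axis=1)
    df_res = float(n_a + n_b - 2)
    s2 = ((n_a - 1) * xa.var(axis=1, ddof=1) + (n_b - 1) * xb.var(axis=1, ddof=1)) / df_res

    if d0 is None or s0_sq is None:
        est_d0, est_s0 = fit_f_dist(s2, np.full(len(s2), df_res))
        d0 = est_d0 if d0 is None else d0
        s0_sq = est_s0 if s0_sq is None else s0_sq

    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = math.inf
    else:
        s2_post = (d0 * s0_sq + df_res * s2) / (d0 + df_res)
        df_total = d0 + df_res
    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    t_mod = logfc / se
    p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    q = bh_adjust(p)
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "s2": s2,
            "df_residual": df_res,
            "t_mod": t_mod,
            "p": p,
            "q": q,
        },
        index=data.gene_ids,
    )
    return DifferentialResult(table, float(d0), float(s0_sq), group_a, group_b)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ModuleAssociation:
    """Per-module response-association summary, ranked by |median t|."""

    table: pd.DataFrame
    alpha: float
    top_up_module: int | None
    top_down_module: int | None


def module_association(
    diff: DifferentialResult, module_of_gene: pd.Series, alpha: float = 0.001
) -> ModuleAssociation:
    """Summarize moderated t per module and rank modules by |median t|.

    For each module the median and mean t, and the fractions of genes
    significant (q < alpha) in each direction, are reported.  The dominant
    direction is the sign of the median t; the top-ranked up- and
    down-modules are flagged (the "immune-like" and "cancer-like" candidates).
    """
    genes = diff.table.index
    labels = module_of_gene.loc[genes]
    rows = []
    for m in sorted(set(labels)):
        sub = diff.table[labels == m]
        if len(sub) == 0:
            logger.warning("module %s is empty; skipped", m)
            continue
        med = float(sub["t_mod"].median())
        sig = sub["q"] < alpha
        rows.append(
            {
                "module": m,
                "n_genes": len(sub),
                "median_t": med,
                "mean_t": float(sub["t_mod"].mean()),
                "frac_sig_up": float((sig & (sub["t_mod"] > 0)).mean()),
                "frac_sig_down": float((sig & (sub["t_mod"] < 0)).mean()),
                "direction": "up" if med > 0 else "down" if med < 0 else "flat",
            }
        )
    table = pd.DataFrame(rows).set_index("module")
    ranked = table.loc[table.index != 0] if 0 in table.index else table
    order = ranked["median_t"].abs().sort_values(ascending=False, kind="stable").index
    rank = pd.Series(range(1, len(order) + 1), index=order, name="rank")
    table = table.join(rank)
    ups = [m for m in order if table.loc[m, "direction"] == "up"]
    downs = [m for m in order if table.loc[m, "direction"] == "down"]
    return ModuleAssociation(
        table=table,
        alpha=alpha,
        top_up_module=int(ups[0]) if ups else None,
        top_down_module=int(downs[0]) if downs else None,
    )
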
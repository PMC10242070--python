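"""Negative-binomial differential expression for two-group contrasts.

A deliberately simple, transparent DE engine: median-of-ratios size
factors, method-of-moments NB dispersion (Var = mu + alpha*mu^2), and a
delta-method Wald test on the log2 ratio of normalized group means, with
Benjamini-Hochberg FDR control and DEG calling at a strict threshold
(default FDR < 0.01).  The pipeline treats this stage as pluggable: any
tool producing the same per-gene table (gene_id, log2fc, se, p, fdr,
is_deg) can stand in for it.

Gene-wise moment dispersions from a handful of replicates are noisy, and
plugging them straight into the Wald statistic is anti-conservative (an
underestimated dispersion shrinks the standard error).  By default the
per-gene estimate is therefore moderated toward the ensemble
(``moderate=True``), in the spirit of the empirical shrinkage used by the
established NB DE tools: estimates below the ensemble median are floored
at it (they are indistinguishable from downward noise and are exactly what
inflates type-I error), and the excess of estimates above the median is
shrunk toward it on the log scale with weight df / (df + prior_df), so
genuinely high-dispersion genes keep an elevated estimate once the data
carry enough replication to support it.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ALPHA_MIN",
    "estimate_size_factors",
    "estimate_dispersion",
    "nb_wald_test",
    "bh_adjust",
    "call_degs",
    "de_table",
]

#: floor on the NB dispersion estimate
ALPHA_MIN = 1e-8

LOG2_SQ = np.log(2.0) ** 2


def estimate_size_factors(counts: pd.DataFrame, pseudocount_fallback: bool = True) -> pd.Series:
    """Median-of-ratios size factors.

    For every gene with strictly positive counts in all samples, the ratio
    of each sample's count to the gene's geometric mean is formed; a
    sample's size factor is the median of those ratios.  If no gene is
    positive everywhere, a pseudocount of 1 is added to every count (logged)
    unless ``pseudocount_fallback`` is disabled, in which case this is an
    error.
    """
    k = counts.to_numpy(dtype=float)
    positive = (k > 0).all(axis=1)
    if not positive.any():
        if not pseudocount_fallback:
            raise ValueError(
                "no gene has all-positive counts; enable the pseudocount fallback"
            )
        logger.warning("no all-positive gene; falling back to pseudocount 1 for size factors")
        k = k + 1.0
        positive = np.ones(len(k), dtype=bool)
    logk = np.log(k[positive])
    log_ratios = logk - logk.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    design_groups: Sequence[Sequence[str]],
    moderate: bool = True,
    prior_df: float = 20.0,
) -> pd.Series:
    """Per-gene NB dispersion by the method of moments on normalized counts.

    alpha_g = max(ALPHA_MIN, (pooled within-group variance - pooled mean) /
    pooled mean^2), pooling variances over all groups with >= 2 replicates
    (weighted by degrees of freedom).  With ``moderate`` the gene-wise value
    is shrunk toward the ensemble median (see module docstring); the median
    itself, and therefore any single-gene call, is left unchanged.
    """
    groups = [list(g) for g in design_groups if len(g) >= 2]
    if not groups:
        raise ValueError("dispersion estimation needs at least one group with >= 2 replicates")
    norm = counts / size_factors
    num = np.zeros(len(counts))
    df_total = 0
    for g in groups:
        sub = norm[g].to_numpy()
        df = sub.shape[1] - 1
        num += df * sub.var(axis=1, ddof=1)
        df_total += df
    pooled_var = num / df_total
    used = [s for g in groups for s in g]
    pooled_mean = norm[used].to_numpy().mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - pooled_mean) / pooled_mean**2
    alpha = np.where(np.isfinite(alpha), alpha, ALPHA_MIN)
    alpha = np.maximum(alpha, ALPHA_MIN)
    if moderate and len(alpha) > 1:
        med = float(np.median(alpha))
        if med > ALPHA_MIN:
            w = df_total / (df_total + prior_df)
            alpha = np.exp(np.log(med) + w * np.maximum(0.0, np.log(alpha) - np.log(med)))
    return pd.Series(alpha, index=counts.index, name="dispersion")


def nb_wald_test(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    dispersions: pd.Series,
    contrast: tuple[Sequence[str], Sequence[str]],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Wald test of group B (treated) over group A (reference).

    log2fc = log2((mu_B + c0)/(mu_A + c0)) on normalized group means with
    pseudocount c0; the delta-method standard error is
    se^2 = [(1/mu_A + alpha)/n_A + (1/mu_B + alpha)/n_B] / ln(2)^2 and the
    p-value is the two-sided normal tail of log2fc/se.  Degenerate genes
    (both group means zero) get log2fc = 0, p = 1.
    """
    group_a, group_b = (list(g) for g in contrast)
    if not group_a or not group_b:
        raise ValueError("both contrast groups must be non-empty")
    norm = counts / size_factors
    mu_a = norm[group_a].to_numpy().mean(axis=1)
    mu_b = norm[group_b].to_numpy().mean(axis=1)
    alpha = dispersions.reindex(counts.index).to_numpy()
    n_a, n_b = len(group_a), len(group_b)

    log2fc = np.log2((mu_b + pseudocount) / (mu_a + pseudocount))
    with np.errstate(divide="ignore"):
        se2 = ((1.0 / mu_a + alpha) / n_a + (1.0 / mu_b + alpha) / n_b) / LOG2_SQ
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(np.isfinite(se) & (se > 0), log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    degenerate = (mu_a == 0) & (mu_b == 0)
    if degenerate.any():
        logger.info("%d genes with zero counts in both groups set to log2fc=0, p=1",
                    int(degenerate.sum()))
        log2fc = np.where(degenerate, 0.0, log2fc)
        p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {"gene_id": counts.index, "log2fc": log2fc, "se": se, "p": p}
    ).reset_index(drop=True)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1), returned
    in the input order.  NaN input is rejected."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(records: pd.DataFrame, threshold: float = 0.01) -> pd.DataFrame:
    """Flag DEGs at strict FDR < threshold."""
    out = records.copy()
    out["is_deg"] = out["fdr"] < threshold
    return out


def de_table(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    dispersions: pd.Series,
    contrast: tuple[Sequence[str], Sequence[str]],
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Full DE record set for one contrast: test, adjust, call."""
    records = nb_wald_test(counts, size_factors, dispersions, contrast)
    records["fdr"] = bh_adjust(records["p"].to_numpy())
    return call_degs(records, fdr_threshold)
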
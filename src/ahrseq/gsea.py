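"""Preranked gene-set enrichment analysis.

Genes are ranked by a signed significance metric combining log2 fold change
and FDR; each gene set is scored with the weighted Kolmogorov-Smirnov
running-sum enrichment score (ES).  Significance comes from a gene-set
permutation null (random member sets of matched size drawn from the ranked
universe): the normalized enrichment score (NES) divides the ES by the mean
same-sign null ES, the nominal p-value is the same-sign null tail, and the
FDR is the NES-based ratio estimator of the original method.  The reporting
filter keeps sets with FDR < 0.25 and NES > 1.5 (optionally symmetric in
|NES| to also admit depleted sets).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as _io

__all__ = [
    "GeneSet",
    "read_gmt",
    "rank_metric",
    "enrichment_score",
    "nes_and_fdr",
    "apply_filter",
]

_FDR_FLOOR = 1e-300


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    description: str = ""


def read_gmt(path) -> list[GeneSet]:
    """Load gene sets from a GMT file (MSigDB dialect)."""
    return [GeneSet(name, frozenset(members), desc) for name, desc, members in _io.read_gmt(path)]


def rank_metric(de_table: pd.DataFrame) -> pd.Series:
    """Signed significance ranking: r_g = sign(log2fc) * -log10(max(fdr, 1e-300)).

    Returns a Series indexed by gene id, sorted descending; ties broken by
    |log2fc| descending, then gene id ascending, giving a strict
    deterministic order.  Duplicate gene ids are an error.
    """
    if de_table["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in DE table")
    lfc = de_table["log2fc"].to_numpy(dtype=float)
    fdr = de_table["fdr"].to_numpy(dtype=float)
    if not (np.isfinite(lfc).all() and np.isfinite(fdr).all()):
        raise ValueError("non-finite log2fc or fdr")
    r = np.sign(lfc) * -np.log10(np.maximum(fdr, _FDR_FLOOR))
    order = pd.DataFrame(
        {"gene_id": de_table["gene_id"].to_numpy(), "r": r, "abs_lfc": np.abs(lfc)}
    ).sort_values(
        by=["r", "abs_lfc", "gene_id"], ascending=[False, False, True], kind="mergesort"
    )
    return pd.Series(order["r"].to_numpy(), index=order["gene_id"].to_numpy(), name="rank_metric")


def _es_from_mask(weights: np.ndarray, mask: np.ndarray) -> tuple[float, np.ndarray]:
    """ES and running profile for a membership mask over the ranked list.

    ``weights`` is |r|^p in ranked order.  P_hit accumulates member weights
    normalized by their total; P_miss accumulates 1/(N - N_S) per
    non-member; the ES is the running deviation of maximal absolute value
    (signed, first maximum on ties).
    """
    n = len(weights)
    n_s = int(mask.sum())
    if n_s == 0 or n_s == n:
        raise ValueError("gene set must be a non-empty proper subset of the ranked universe")
    n_r = float(weights[mask].sum())
    if n_r == 0.0:
        raise ValueError("all member weights are zero; ES undefined")
    step = np.where(mask, weights / n_r, -1.0 / (n - n_s))
    running = np.cumsum(step)
    # signed value at the maximal |deviation|; exact-magnitude ties (and
    # float noise around them) resolve to the earliest position
    dev = np.abs(running)
    i = int(np.argmax(dev >= dev.max() - 1e-12))
    return float(running[i]), running


def enrichment_score(
    ranked: pd.Series, gene_set, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score of a gene set on a ranked list.

    ``ranked`` is the descending rank-metric Series from :func:`rank_metric`;
    ``gene_set`` is a :class:`GeneSet` or any collection of gene ids
    (intersected with the universe before scoring).  With weight p = 0 the
    score reduces to the classical unweighted KS statistic.  Returns
    (ES, running profile).
    """
    members = gene_set.members if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    mask = np.fromiter((g in members for g in ranked.index), dtype=bool, count=len(ranked))
    weights = np.abs(ranked.to_numpy(dtype=float)) ** weight
    return _es_from_mask(weights, mask)


def nes_and_fdr(
    ranked: pd.Series,
    gene_sets,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    fdr_threshold: float = 0.25,
    nes_threshold: float = 1.5,
    symmetric: bool = False,
) -> pd.DataFrame:
    """Score gene sets with ES, NES, nominal p and FDR against a matched-size
    random-set null; reproducible for a fixed seed.

    For each set, ``n_perm`` random member sets of the same size are drawn
    from the ranked universe.  NES = ES / mean(same-sign null ES); nominal
    p is the fraction of same-sign null ES at least as extreme; the FDR is
    the pooled-null NES ratio estimator, capped at 1.  A set with no
    same-sign null ES gets NaN NES and a flag.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    sets = [gs if isinstance(gs, GeneSet) else GeneSet(str(gs[0]), frozenset(gs[1]))
            for gs in gene_sets]
    rng = np.random.default_rng(seed)
    n = len(ranked)
    weights = np.abs(ranked.to_numpy(dtype=float)) ** weight
    universe = list(ranked.index)

    observed, sizes = [], []
    for gs in sets:
        members = gs.members & set(universe)
        es, _ = _es_from_mask(
            weights, np.fromiter((g in members for g in universe), dtype=bool, count=n)
        )
        observed.append(es)
        sizes.append(len(members))

    null_by_size: dict[int, np.ndarray] = {}
    for size in sorted(set(sizes)):
        es_null = np.empty(n_perm)
        for k in range(n_perm):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=size, replace=False)] = True
            es_null[k] = _es_from_mask(weights, mask)[0]
        null_by_size[size] = es_null

    rows = []
    null_nes_pool: list[np.ndarray] = []
    for gs, es, size in zip(sets, observed, sizes):
        null = null_by_size[size]
        pos, neg = null[null > 0], null[null < 0]
        same = pos if es >= 0 else neg
        if len(same) == 0:
            rows.append({"name": gs.name, "size": size, "es": es, "nes": np.nan,
                         "p": np.nan, "undefined_nes": True})
            null_nes_pool.append(np.array([]))
            continue
        mean_pos = pos.mean() if len(pos) else np.nan
        mean_neg = np.abs(neg).mean() if len(neg) else np.nan
        nes = es / mean_pos if es >= 0 else -(abs(es) / mean_neg)
        p = float((np.abs(same) >= abs(es)).sum() / len(same))
        null_nes = np.concatenate([
            pos / mean_pos if len(pos) else np.empty(0),
            -(np.abs(neg) / mean_neg) if len(neg) else np.empty(0),
        ])
        null_nes_pool.append(null_nes)
        rows.append({"name": gs.name, "size": size, "es": es, "nes": nes,
                     "p": p, "undefined_nes": False})
    result = pd.DataFrame(rows)

    pooled = np.concatenate([x for x in null_nes_pool if len(x)]) if null_nes_pool else np.empty(0)
    obs_nes = result["nes"].to_numpy()
    fdrs = []
    for nes in obs_nes:
        if not np.isfinite(nes):
            fdrs.append(np.nan)
            continue
        if nes >= 0:
            num_pool = (pooled >= nes).sum() / max((pooled >= 0).sum(), 1)
            denom = (obs_nes[np.isfinite(obs_nes)] >= nes).sum() / max(
                (obs_nes[np.isfinite(obs_nes)] >= 0).sum(), 1)
        else:
            num_pool = (pooled <= nes).sum() / max((pooled < 0).sum(), 1)
            denom = (obs_nes[np.isfinite(obs_nes)] <= nes).sum() / max(
                (obs_nes[np.isfinite(obs_nes)] < 0).sum(), 1)
        fdrs.append(min(1.0, float(num_pool / denom)) if denom > 0 else 1.0)
    result["fdr"] = fdrs
    return apply_filter(result, fdr_threshold, nes_threshold, symmetric)


def apply_filter(
    result: pd.DataFrame,
    fdr_threshold: float = 0.25,
    nes_threshold: float = 1.5,
    symmetric: bool = False,
) -> pd.DataFrame:
    """Reporting filter: FDR < 0.25 and NES > 1.5 (|NES| if symmetric)."""
    out = result.copy()
    nes = out["nes"]
    magnitude = nes.abs() if symmetric else nes
    out["passes_filter"] = (out["fdr"] < fdr_threshold) & (magnitude > nes_threshold)
    out.loc[~np.isfinite(nes), "passes_filter"] = False
    return out
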
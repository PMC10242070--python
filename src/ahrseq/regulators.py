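"""Upstream-regulator scoring on a user-supplied signed network.

Given regulator->target edges with signs (+1 activating, -1 repressing) and
the observed fold-change directions of AhR-dependent DEGs, each regulator
gets a hypergeometric target-overlap p-value and a consistency activation
z-score z = (n_consistent - n_inconsistent) / sqrt(n_scored); |z| > 2
(strict) calls the regulator activated or inhibited.  A final filter keeps
regulators with at least one AhR-dependent target lacking all AHRE motifs —
the candidates for relaying non-canonical, e.g. interferon-driven, effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "RegulatorCall",
    "read_network",
    "overlap_pvalue",
    "activation_z",
    "score_regulators",
    "filter_to_nonahre",
]


@dataclass(frozen=True)
class RegulatorCall:
    regulator: str
    n_targets_in_degs: int
    overlap_p: float
    z: float
    state: str  # activated | inhibited | undetermined


def read_network(path) -> pd.DataFrame:
    """Read a regulator/target/sign TSV and validate it."""
    net = pd.read_csv(path, sep="\t")
    return validate_network(net)


def validate_network(net: pd.DataFrame) -> pd.DataFrame:
    missing = {"regulator", "target", "sign"} - set(net.columns)
    if missing:
        raise ValueError(f"network lacks columns {sorted(missing)}")
    if net.duplicated(["regulator", "target"]).any():
        raise ValueError("duplicate (regulator, target) edges")
    if not net["sign"].isin([1, -1]).all():
        raise ValueError("edge signs must be +1 or -1")
    return net


def overlap_pvalue(targets, deg_set, universe) -> float:
    """Hypergeometric upper tail P(X >= observed overlap of targets with the
    DEG set) over the gene universe."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    targets = set(targets) & universe
    degs = set(deg_set) & universe
    k = len(targets & degs)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(degs), len(targets)))


def activation_z(edge_signs: pd.Series, observed_lfc: pd.Series) -> tuple[float, int]:
    """Consistency z-score of one regulator.

    ``edge_signs`` maps target -> +/-1; ``observed_lfc`` maps target ->
    log2fc among DEGs.  A target is consistent when sign(log2fc) equals the
    edge sign; zero-fold-change targets are excluded.  Returns (z, number of
    scored targets); z is NaN with a warning when nothing is scorable.
    """
    common = edge_signs.index.intersection(observed_lfc.index)
    lfc = observed_lfc.loc[common]
    scorable = lfc[lfc != 0]
    if len(scorable) == 0:
        logger.warning("regulator has no scorable targets; state undetermined")
        return float("nan"), 0
    agree = np.sign(scorable.to_numpy()) == edge_signs.loc[scorable.index].to_numpy()
    n_con = int(agree.sum())
    n_inc = len(scorable) - n_con
    z = (n_con - n_inc) / np.sqrt(n_con + n_inc)
    return float(z), len(scorable)


def _state(z: float) -> str:
    if np.isfinite(z) and z > 2:
        return "activated"
    if np.isfinite(z) and z < -2:
        return "inhibited"
    return "undetermined"


def score_regulators(
    network: pd.DataFrame,
    de_table: pd.DataFrame,
    dependent_genes,
) -> pd.DataFrame:
    """Score every regulator against the AhR-dependent DEG set.

    ``de_table`` supplies per-gene log2fc (the observed directions);
    ``dependent_genes`` is the DEG set of interest; the universe is the DE
    table's gene universe.  Edges onto genes outside the universe are
    dropped with a warning.
    """
    validate_network(network)
    universe = set(de_table["gene_id"])
    degs = set(dependent_genes) & universe
    lfc = de_table.set_index("gene_id")["log2fc"]
    known = network["target"].isin(universe)
    if (~known).any():
        logger.warning("%d network edges onto genes absent from the universe dropped",
                       int((~known).sum()))
    net = network[known]
    rows = []
    for regulator, edges in net.groupby("regulator", sort=True):
        targets = edges["target"].tolist()
        p = overlap_pvalue(targets, degs, universe)
        signs = edges.set_index("target")["sign"]
        deg_targets = [t for t in targets if t in degs]
        z, n_scored = activation_z(signs.loc[deg_targets], lfc.loc[deg_targets]) \
            if deg_targets else (float("nan"), 0)
        rows.append({"regulator": regulator, "n_targets": len(targets),
                     "n_targets_in_degs": len(deg_targets), "n_scored": n_scored,
                     "overlap_p": p, "z": z, "state": _state(z)})
    return pd.DataFrame(rows)


def filter_to_nonahre(
    calls: pd.DataFrame,
    network: pd.DataFrame,
    motif_profiles,
    dependency_calls: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict regulator calls to those with at least one AhR-dependent,
    AHRE-free target; also returns the regulator -> non-AHRE-target edges
    (the bipartite table behind a circle-plot style report).

    ``motif_profiles`` maps gene id -> :class:`GeneMotifProfile`.
    """
    if len(calls) == 0:
        return calls.copy(), network.iloc[0:0].copy()
    dep_genes = set(
        dependency_calls.loc[dependency_calls["label"] == "ahr_dependent", "gene_id"]
    )
    missing = {t for t in network["target"] if t in dep_genes} - set(motif_profiles)
    if missing:
        raise KeyError(f"motif profiles missing for targets: {sorted(missing)[:5]}")
    nonahre = {g for g in dep_genes if g in motif_profiles and not motif_profiles[g].any_ahre}
    edges = network[network["target"].isin(nonahre)]
    keep = set(edges["regulator"])
    return calls[calls["regulator"].isin(keep)].reset_index(drop=True), edges.reset_index(drop=True)
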
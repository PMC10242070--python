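"""AhR-dependency classification of differentially expressed genes.

A gene's response to an AhR ligand is called AhR-dependent when it is a DEG
in exactly one genotype (wild-type or knockout) for that ligand/time cell,
AhR-independent when it is a DEG in both, and excluded as unspecific when
it is already differentially expressed between the genotypes without any
ligand (the DMSO baseline contrast), which dominates the other rules.
Fold-change-profile correlations across times and ligands, and the Venn
partitions of dependent gene sets, summarize how shared the dependent
response is between conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "LABELS",
    "classify_gene",
    "classify_cell",
    "count_dependent",
    "venn_partition",
    "correlate_profiles",
    "CorrelationResult",
]

LABELS = ("ahr_dependent", "ahr_independent", "unspecific_excluded", "unaffected")


def classify_gene(deg_wt: bool, deg_ko: bool, deg_unspecific: bool,
                  require_wt_only: bool = False) -> str:
    """Map the three DEG flags of one gene in one (ligand, time) cell to its
    dependency label.

    The unspecific flag dominates; otherwise a DEG in exactly one genotype
    is AhR-dependent, in both AhR-independent, in neither unaffected.  With
    ``require_wt_only`` a KO-only DEG is demoted to unaffected instead of
    counting as dependent (the literal either/or reading admits KO-only
    genes; biologically the dependent calls of interest are WT-specific).
    """
    if deg_unspecific:
        return "unspecific_excluded"
    if deg_wt and deg_ko:
        return "ahr_independent"
    if deg_wt:
        return "ahr_dependent"
    if deg_ko:
        return "ahr_dependent" if not require_wt_only else "unaffected"
    return "unaffected"


def classify_cell(
    de_wt: pd.DataFrame,
    de_ko: pd.DataFrame,
    de_unspecific: pd.DataFrame,
    ligand: str,
    time: str,
    require_wt_only: bool = False,
) -> pd.DataFrame:
    """Classify every gene of one (ligand, time) cell from its three DE
    tables (WT ligand-vs-DMSO, KO ligand-vs-DMSO, WT-vs-KO under DMSO).

    The WT and KO tables must cover the same gene universe.  ``direction``
    is the sign of the WT log2fc (KO log2fc for a KO-only dependent call)
    and is ``none`` unless the label is dependent or independent.
    """
    wt = de_wt.set_index("gene_id")
    ko = de_ko.set_index("gene_id")
    uns = de_unspecific.set_index("gene_id")
    if set(wt.index) != set(ko.index):
        raise ValueError("WT and KO DE tables cover different gene universes")
    ko = ko.reindex(wt.index)
    uns = uns.reindex(wt.index)
    ko_only_warned = 0
    rows = []
    for gene_id in wt.index:
        f_wt = bool(wt.at[gene_id, "is_deg"])
        f_ko = bool(ko.at[gene_id, "is_deg"])
        f_uns = bool(uns.at[gene_id, "is_deg"]) if not pd.isna(uns.at[gene_id, "is_deg"]) else False
        label = classify_gene(f_wt, f_ko, f_uns, require_wt_only)
        if label in ("ahr_dependent", "ahr_independent"):
            lfc = wt.at[gene_id, "log2fc"]
            if label == "ahr_dependent" and not f_wt:  # KO-only call
                lfc = ko.at[gene_id, "log2fc"]
                ko_only_warned += 1
            direction = "up" if lfc > 0 else ("down" if lfc < 0 else "none")
        else:
            direction = "none"
        rows.append({"gene_id": gene_id, "ligand": ligand, "time": time,
                     "label": label, "direction": direction})
    if ko_only_warned:
        logger.warning("%s/%s: %d genes called AhR-dependent from the knockout side only",
                       ligand, time, ko_only_warned)
    return pd.DataFrame(rows)


def count_dependent(calls: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Ligand x time table of AhR-dependent DEG counts plus the number of
    unique dependent genes across all cells (deduplicated by gene id)."""
    dep = calls[calls["label"] == "ahr_dependent"]
    ligands = sorted(calls["ligand"].unique())
    times = sorted(calls["time"].unique())
    table = pd.DataFrame(0, index=pd.Index(ligands, name="ligand"),
                         columns=pd.Index(times, name="time"))
    for (ligand, time), cell in dep.groupby(["ligand", "time"]):
        table.loc[ligand, time] = cell["gene_id"].nunique()
    return table, int(dep["gene_id"].nunique())


def venn_partition(set_a, set_b) -> tuple[int, int, int]:
    """Sizes of (A only, B only, A and B); disjoint and summing to |A u B|."""
    a, b = set(set_a), set(set_b)
    both = a & b
    return len(a - both), len(b - both), len(both)


@dataclass(frozen=True)
class CorrelationResult:
    comparison: str
    subset: str
    n: int
    rho: float
    slope: float
    p: float


def correlate_profiles(
    lfc_x: pd.Series,
    lfc_y: pd.Series,
    subset=None,
    comparison: str = "",
    subset_name: str = "all_genes",
) -> CorrelationResult:
    """Pearson correlation and OLS slope between two fold-change profiles.

    Profiles are aligned on their index (gene ids); ``subset`` optionally
    restricts to a collection of gene ids.  The p-value comes from the
    t statistic rho*sqrt((n-2)/(1-rho^2)) with n-2 degrees of freedom,
    two-sided; the slope is least squares of y on x.
    """
    x, y = lfc_x.align(lfc_y, join="inner")
    if subset is not None:
        keep = x.index.intersection(pd.Index(subset))
        x, y = x.loc[keep], y.loc[keep]
    mask = np.isfinite(x.to_numpy()) & np.isfinite(y.to_numpy())
    xv, yv = x.to_numpy()[mask], y.to_numpy()[mask]
    n = len(xv)
    if n < 3:
        raise ValueError("correlation needs at least 3 paired finite values")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("correlation undefined: zero variance in a profile")
    rho = float(np.corrcoef(xv, yv)[0, 1])
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    slope = float(np.polyfit(xv, yv, 1)[0])
    return CorrelationResult(comparison, subset_name, n, rho, slope, p)
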
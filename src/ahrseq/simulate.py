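"""Synthetic dataset generator with known ground truth.

Emulates the study design the downstream stages assume: bone marrow-derived
macrophages from wild-type (WT) and AhR-knockout (KO) mice, exposed to an
AhR ligand (BaP or I3C) or vehicle (DMSO) and activated for 3 h or 20 h,
four replicates per cell — 48 samples.  Counts are negative-binomial with
sample-specific size factors; genes fall into four effect classes:

``ahr_dependent``
    ligand response (log2 effect beta) in WT only — the KO contrast is null;
``ahr_independent``
    the same nonzero ligand response in both genotypes;
``unspecific``
    a genotype effect present already under DMSO (excluded downstream);
``null``
    no effect anywhere.

A toy genome and one-TSS-per-gene annotation are generated alongside, with
AHRE motifs deliberately planted into some promoters and scrubbed out of
others so the canonical/non-canonical partition has an exact truth.
Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import io as _io
from .motifs import (
    BUILTIN_MOTIFS,
    MotifSpec,
    builtin_motifs,
    promoter_interval,
    revcomp,
    scan,
)

__all__ = [
    "Contig",
    "Genome",
    "GeneModel",
    "ScenarioConfig",
    "SyntheticDataset",
    "make_genome",
    "make_annotation",
    "make_design",
    "plant_motif",
    "scrub_motifs",
    "simulate_counts",
    "generate_dataset",
    "true_labels",
]

GENOTYPES = ("WT", "KO")
LIGANDS = ("BaP", "I3C")
TREATMENTS = ("DMSO", "BaP", "I3C")
TIMES = ("3h", "20h")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class Contig:
    id: str
    sequence: str


class Genome:
    """Mutable collection of contigs; behaves as a Mapping[str, str].

    Sequences are held as byte arrays so motif planting and scrubbing are
    cheap in-place edits; string views are cached per contig and invalidated
    on write.
    """

    def __init__(self, contigs: Mapping[str, str] | Iterable[Contig]):
        if isinstance(contigs, Mapping):
            items = contigs.items()
        else:
            items = [(c.id, c.sequence) for c in contigs]
        self._seqs: dict[str, bytearray] = {name: bytearray(seq.encode()) for name, seq in items}
        self._cache: dict[str, str] = {}

    def __getitem__(self, name: str) -> str:
        if name not in self._cache:
            self._cache[name] = self._seqs[name].decode()
        return self._cache[name]

    def __contains__(self, name) -> bool:
        return name in self._seqs

    def __iter__(self):
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def keys(self):
        return self._seqs.keys()

    def items(self):
        return ((name, self[name]) for name in self._seqs)

    def length(self, name: str) -> int:
        return len(self._seqs[name])

    @property
    def contigs(self) -> list[Contig]:
        return [Contig(name, self[name]) for name in self._seqs]

    def write_region(self, contig: str, start0: int, text: str) -> None:
        """Overwrite bases at 0-based offset ``start0``."""
        if start0 < 0 or start0 + len(text) > len(self._seqs[contig]):
            raise ValueError("region outside contig")
        self._seqs[contig][start0 : start0 + len(text)] = text.encode()
        self._cache.pop(contig, None)


@dataclass(frozen=True)
class GeneModel:
    """One gene, one TSS.  ``start``/``end`` are the 1-based closed body
    span; the TSS is the 5' body end on the gene's strand."""

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


def make_genome(n_contigs: int, contig_length: int, gc: float, seed: int) -> Genome:
    """Random genome over A/C/G/T with the requested G+C fraction."""
    if n_contigs < 1 or contig_length < 1:
        raise ValueError("n_contigs and contig_length must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    contigs = {}
    for i in range(n_contigs):
        arr = rng.choice(_BASES, size=contig_length, p=p)
        contigs[f"contig{i + 1}"] = arr.tobytes().decode()
    return Genome(contigs)


def make_annotation(
    genome: Genome,
    n_genes: int,
    promoter_gap: int = 4000,
    body_length: int = 500,
    seed: int = 0,
) -> list[GeneModel]:
    """Place non-overlapping genes so each 3,000-nt upstream window fits.

    Genes are tiled in slots of ``promoter_gap + body_length`` nt across the
    contigs.  Plus-strand genes sit at the slot end (promoter to the left),
    minus-strand genes at the slot start (promoter to the right), so
    promoters never overlap neighbouring genes.  Strands are drawn at random
    with both guaranteed represented.
    """
    if promoter_gap < 3000:
        raise ValueError("promoter_gap must be >= 3000 so promoter windows fit")
    slot = promoter_gap + body_length
    capacity = sum(genome.length(c) // slot for c in genome)
    if capacity < n_genes:
        raise ValueError(f"genome too small: room for {capacity} genes, {n_genes} requested")
    rng = np.random.default_rng(seed)
    strands = rng.choice(np.array(["+", "-"]), size=n_genes)
    if n_genes >= 2:  # both strands represented
        strands[0], strands[1] = "+", "-"
    genes: list[GeneModel] = []
    i = 0
    for contig in genome:
        n_slots = genome.length(contig) // slot
        for k in range(n_slots):
            if i >= n_genes:
                break
            base = k * slot  # 0-based slot origin
            strand = strands[i]
            if strand == "+":
                start = base + promoter_gap + 1
                end = start + body_length - 1
            else:
                start = base + 1
                end = base + body_length
            genes.append(GeneModel(f"gene{i + 1:04d}", contig, strand, start, end))
            i += 1
    return genes


def plant_motif(
    genome: Genome,
    gene: GeneModel,
    motif_id: str,
    offset: int,
    strand: str = "+",
    seed: int = 0,
    window: int = 3000,
) -> str:
    """Write a concrete instance of a motif into a gene's promoter.

    ``offset`` is the 0-based position within the promoter sequence as
    reported by the scanner (5'->3' toward the TSS); ``strand`` is the strand
    of the planted site relative to that reported sequence.  Degenerate
    positions are filled with seeded random concrete bases.  Returns the
    concrete motif text planted (on its strand).
    """
    spec = BUILTIN_MOTIFS.get(motif_id)
    if spec is None:
        raise KeyError(f"unknown motif {motif_id!r}")
    rng = np.random.default_rng(seed)
    concrete = spec.concretize(rng)
    text = concrete if strand == "+" else revcomp(concrete)
    start, end = promoter_interval(gene.tss, gene.strand, genome.length(gene.contig), window)
    avail = end - start + 1
    if not 0 <= offset <= avail - spec.length:
        raise ValueError(
            f"offset {offset} outside promoter window of {gene.gene_id} ({avail} nt available)"
        )
    if gene.strand == "+":
        genome.write_region(gene.contig, (start - 1) + offset, text)
    else:
        # reported sequence is the reverse complement of the genomic slice
        g_end0 = (end - 1) - offset
        genome.write_region(gene.contig, g_end0 - spec.length + 1, revcomp(text))
    return concrete


def scrub_motifs(
    genome: Genome,
    gene: GeneModel,
    motifs: Iterable[MotifSpec] | None = None,
    seed: int = 0,
    window: int = 3000,
) -> int:
    """Remove every perfect motif match from a gene's promoter.

    Iterated single-base substitution inside a remaining hit; a substitution
    is accepted only if the total hit count strictly decreases (so no new
    sites are created and termination is guaranteed).  Returns the number of
    accepted substitutions.
    """
    if motifs is None:
        motifs = builtin_motifs()
    motifs = list(motifs)
    rng = np.random.default_rng(seed)
    start, end = promoter_interval(gene.tss, gene.strand, genome.length(gene.contig), window)
    if end < start:
        return 0
    n_subs = 0
    for _ in range(100_000):
        promoter = genome[gene.contig][start - 1 : end]
        hits = scan(promoter, motifs)
        if not hits:
            return n_subs
        hit = hits[0]
        span = len(hit.matched_text)
        local = bytearray(promoter.encode())
        for _attempt in range(500):
            pos = hit.position + int(rng.integers(span))
            old = chr(local[pos])
            new = str(rng.choice([b for b in "ACGT" if b != old]))
            trial = local.copy()
            trial[pos] = ord(new)
            if len(scan(trial.decode(), motifs)) < len(hits):
                genome.write_region(gene.contig, (start - 1) + pos, new)
                n_subs += 1
                break
        else:  # pragma: no cover - probabilistically unreachable
            raise RuntimeError(f"could not scrub promoter of {gene.gene_id}")
    raise RuntimeError(f"scrubbing of {gene.gene_id} did not terminate")  # pragma: no cover


def make_design(
    replicates: int = 4,
    size_factor_range: tuple[float, float] = (0.5, 2.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Complete crossed design: 2 genotypes x 3 treatments x 2 times x n
    replicates, with true size factors drawn log-uniformly."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for genotype in GENOTYPES:
        for treatment in TREATMENTS:
            for time in TIMES:
                for rep in range(1, replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{genotype}_{treatment}_{time}_r{rep}",
                            "genotype": genotype,
                            "treatment": treatment,
                            "time": time,
                            "replicate": rep,
                        }
                    )
    design = pd.DataFrame(rows)
    lo, hi = size_factor_range
    design["true_size_factor"] = np.exp(rng.uniform(np.log(lo), np.log(hi), len(design)))
    return design


def _beta_columns() -> list[str]:
    return [f"beta_{g}_{l}_{t}" for g in GENOTYPES for l in LIGANDS for t in TIMES]


def _sample_beta(truth: pd.DataFrame, sample: pd.Series) -> np.ndarray:
    """True log2 effect of one sample's condition for every gene."""
    beta = np.zeros(len(truth))
    if sample["treatment"] in LIGANDS:
        beta = beta + truth[f"beta_{sample['genotype']}_{sample['treatment']}_{sample['time']}"].to_numpy()
    if sample["genotype"] == "KO":
        beta = beta + truth["beta_genotype"].to_numpy()
    return beta


def simulate_counts(
    design: pd.DataFrame,
    truth: pd.DataFrame,
    baseline_mean_range: tuple[float, float] | None = None,
    dispersion: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw the count matrix K_gj ~ NB(mean = s_j * q_g * 2^beta, dispersion).

    ``truth`` must carry the per-condition beta columns (see
    :func:`generate_dataset`); baselines q_g come from its ``baseline``
    column or, if absent, are drawn log-uniformly from
    ``baseline_mean_range``.  Var = mu + dispersion * mu^2.
    """
    if len(design) == 0:
        raise ValueError("empty design")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    truth = truth.copy()
    if "baseline" not in truth.columns:
        if baseline_mean_range is None:
            raise ValueError("truth has no baseline column and no range given")
        lo, hi = baseline_mean_range
        truth["baseline"] = np.exp(rng.uniform(np.log(lo), np.log(hi), len(truth)))
    q = truth["baseline"].to_numpy()
    r = 1.0 / dispersion
    counts = np.empty((len(truth), len(design)), dtype=np.int64)
    for j, (_, sample) in enumerate(design.iterrows()):
        mu = sample["true_size_factor"] * q * 2.0 ** _sample_beta(truth, sample)
        counts[:, j] = rng.negative_binomial(r, r / (r + mu))
    return pd.DataFrame(counts, index=pd.Index(truth["gene_id"], name="gene_id"),
                        columns=design["sample_id"].tolist())


@dataclass
class ScenarioConfig:
    """Defaults define the study conditions the pipeline is tested under."""

    n_genes: int = 2000
    n_dependent: int = 300
    n_independent: int = 100
    n_unspecific: int = 50
    replicates: int = 4
    dispersion: float = 0.1
    #: magnitude of log2 effects: drawn uniformly from [effect_low, effect_high]
    #: unless effect_size pins it
    effect_low: float = 1.0
    effect_high: float = 3.0
    effect_size: float | None = None
    baseline_range: tuple[float, float] = (20.0, 500.0)
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    #: fraction of dependent genes with an AHRE planted; the rest are scrubbed
    planted_fraction: float = 0.8
    #: ligand/time assignment of affected genes; the default plants each
    #: gene's effect in every ligand/time cell (one beta per genotype
    #: contrast).  Lowering these shares produces condition-specific genes
    #: (see :func:`condition_specific_scenario`).
    p_both_ligands: float = 1.0
    p_bap_only: float = 0.0
    p_both_times: float = 1.0
    p_late_only: float = 0.0
    gc: float = 0.5
    promoter_gap: int = 4000
    body_length: int = 500
    promoter_window: int = 3000
    n_decoy_sets: int = 10
    decoy_set_size: int = 50
    seed: int = 0


@dataclass
class SyntheticDataset:
    """Everything a pipeline run consumes, plus the ground truth."""

    config: ScenarioConfig
    genome: Genome
    genes: list[GeneModel]
    design: pd.DataFrame
    truth: pd.DataFrame
    counts: pd.DataFrame
    gene_sets: list[tuple[str, str, list[str]]]
    network: pd.DataFrame

    def write(self, outdir) -> dict[str, Path]:
        """Persist the bundle as plain-text files; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "annotation": outdir / "annotation.gff3",
            "counts": outdir / "counts.tsv",
            "samples": outdir / "samples.tsv",
            "truth": outdir / "truth.tsv",
            "gene_sets": outdir / "gene_sets.gmt",
            "network": outdir / "network.tsv",
        }
        _io.write_fasta(dict(self.genome.items()), paths["genome"])
        _io.write_gff3(self.genes, paths["annotation"])
        _io.write_table(self.counts.reset_index(), paths["counts"])
        _io.write_table(self.design, paths["samples"])
        _io.write_table(self.truth, paths["truth"])
        _io.write_gmt(self.gene_sets, paths["gene_sets"])
        _io.write_table(self.network, paths["network"])
        return paths


def _draw_magnitudes(rng, n: int, config: ScenarioConfig) -> np.ndarray:
    if config.effect_size is not None:
        mags = np.full(n, float(config.effect_size))
    else:
        mags = rng.uniform(config.effect_low, config.effect_high, n)
    return mags * rng.choice([-1.0, 1.0], n)


def _draw_cells(rng, config: ScenarioConfig) -> list[tuple[str, str]]:
    """Which (ligand, time) cells a gene's effect occupies."""
    u = rng.random()
    if u < config.p_both_ligands:
        ligands = list(LIGANDS)
    elif u < config.p_both_ligands + config.p_bap_only:
        ligands = ["BaP"]
    else:
        ligands = ["I3C"]
    v = rng.random()
    if v < config.p_both_times:
        times = list(TIMES)
    elif v < config.p_both_times + config.p_late_only:
        times = ["20h"]
    else:
        times = ["3h"]
    return [(l, t) for l in ligands for t in times]


def condition_specific_scenario(**overrides) -> ScenarioConfig:
    """Scenario variant with ligand- and time-specific effects.

    Affected genes are active in a random subset of the four ligand/time
    cells, biased toward the high-affinity ligand (BaP) and the late
    activation time — the condition-specific response structure a real
    ligand-affinity contrast produces.  Power to detect a gene then varies
    per cell, so dependency-call precision is somewhat lower than under the
    default shared-effect scenario.
    """
    defaults = dict(p_both_ligands=0.2, p_bap_only=0.6, p_both_times=0.3, p_late_only=0.55)
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


def generate_dataset(config: ScenarioConfig | None = None, **overrides) -> SyntheticDataset:
    """Build the full synthetic bundle for one scenario.

    Deterministic for a fixed ``config.seed``: genome, annotation, effect
    assignment, motif planting/scrubbing, counts, gene sets and network are
    each driven by an independent child of the master seed sequence.
    """
    if config is None:
        config = ScenarioConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    n_affected = config.n_dependent + config.n_independent + config.n_unspecific
    if n_affected > config.n_genes:
        raise ValueError("effect-class counts exceed n_genes")

    seeds = np.random.SeedSequence(config.seed).spawn(8)
    seed_ints = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]
    (s_genome, s_annot, s_truth, s_motif, s_counts, s_sets, s_net, s_design) = seed_ints

    slot = config.promoter_gap + config.body_length
    contig_length = config.n_genes * slot + slot
    genome = make_genome(1, contig_length, config.gc, s_genome)
    genes = make_annotation(
        genome, config.n_genes, config.promoter_gap, config.body_length, s_annot
    )

    rng = np.random.default_rng(s_truth)
    order = rng.permutation(config.n_genes)
    classes = np.array(["null"] * config.n_genes, dtype=object)
    dep_idx = order[: config.n_dependent]
    ind_idx = order[config.n_dependent : config.n_dependent + config.n_independent]
    uns_idx = order[config.n_dependent + config.n_independent : n_affected]
    classes[dep_idx] = "ahr_dependent"
    classes[ind_idx] = "ahr_independent"
    classes[uns_idx] = "unspecific"

    truth = pd.DataFrame({"gene_id": [g.gene_id for g in genes], "effect_class": classes})
    for col in _beta_columns():
        truth[col] = 0.0
    truth["beta_genotype"] = 0.0

    dep_mags = _draw_magnitudes(rng, config.n_dependent, config)
    for i, mag in zip(dep_idx, dep_mags):
        for ligand, time in _draw_cells(rng, config):
            truth.loc[i, f"beta_WT_{ligand}_{time}"] = mag
    ind_mags = _draw_magnitudes(rng, config.n_independent, config)
    for i, mag in zip(ind_idx, ind_mags):
        for ligand, time in _draw_cells(rng, config):
            truth.loc[i, f"beta_WT_{ligand}_{time}"] = mag
            truth.loc[i, f"beta_KO_{ligand}_{time}"] = mag
    uns_mags = _draw_magnitudes(rng, config.n_unspecific, config)
    truth.loc[uns_idx, "beta_genotype"] = uns_mags

    lo, hi = config.baseline_range
    truth["baseline"] = np.exp(rng.uniform(np.log(lo), np.log(hi), config.n_genes))

    # motif truth: plant into most dependent promoters, scrub the rest clean
    mrng = np.random.default_rng(s_motif)
    truth["motif_truth"] = "ambient"
    n_planted = int(round(config.planted_fraction * config.n_dependent))
    planted_idx = dep_idx[:n_planted]
    scrubbed_idx = dep_idx[n_planted:]
    motif_probs = {"AHRE_I": 0.8, "AHRE_II": 0.2, "RELB": 0.06}
    for i in planted_idx:
        gene = genes[i]
        chosen = [m for m, p in motif_probs.items() if mrng.random() < p] or ["AHRE_I"]
        for motif_id in chosen:
            mlen = BUILTIN_MOTIFS[motif_id].length
            offset = int(mrng.integers(0, config.promoter_window - mlen + 1))
            strand = str(mrng.choice(["+", "-"]))
            plant_motif(genome, gene, motif_id, offset, strand,
                        seed=int(mrng.integers(2**31)), window=config.promoter_window)
        truth.loc[i, "motif_truth"] = "planted:" + "+".join(chosen)
    for i in scrubbed_idx:
        scrub_motifs(genome, genes[i], seed=int(mrng.integers(2**31)),
                     window=config.promoter_window)
        truth.loc[i, "motif_truth"] = "scrubbed"

    design = make_design(config.replicates, config.size_factor_range, s_design)
    counts = simulate_counts(design, truth, dispersion=config.dispersion, seed=s_counts)

    gene_sets = _make_gene_sets(truth, np.random.default_rng(s_sets), config)
    network = _make_network(truth, np.random.default_rng(s_net))

    return SyntheticDataset(config, genome, genes, design, truth, counts, gene_sets, network)


def _make_gene_sets(truth: pd.DataFrame, rng, config: ScenarioConfig):
    """Truth-derived signal sets plus random decoys, GMT-shaped."""
    dep = truth[truth["effect_class"] == "ahr_dependent"]
    wt_cols = [f"beta_WT_{l}_{t}" for l in LIGANDS for t in TIMES]
    dep_sign = dep[wt_cols].sum(axis=1)
    sets = [
        ("AHR_DEPENDENT_UP", "planted AhR-dependent genes, upregulated",
         dep.loc[dep_sign > 0, "gene_id"].tolist()),
        ("AHR_DEPENDENT_DOWN", "planted AhR-dependent genes, downregulated",
         dep.loc[dep_sign < 0, "gene_id"].tolist()),
        ("AHR_INDEPENDENT", "planted AhR-independent genes",
         truth.loc[truth["effect_class"] == "ahr_independent", "gene_id"].tolist()),
    ]
    all_genes = truth["gene_id"].to_numpy()
    # decoys must stay proper subsets of the universe even for tiny scenarios
    decoy_size = min(config.decoy_set_size, max(1, config.n_genes // 4))
    for k in range(config.n_decoy_sets):
        members = rng.choice(all_genes, size=decoy_size, replace=False)
        sets.append((f"DECOY_{k + 1:02d}", "random decoy set", sorted(members.tolist())))
    return [(n, d, m) for n, d, m in sets if m]


def _make_network(truth: pd.DataFrame, rng) -> pd.DataFrame:
    """Toy signed regulator->target network with known truth.

    One regulator drives non-AHRE (scrubbed) dependent genes with
    sign-consistent edges (the interferon-like case the non-canonical filter
    should retain); one drives planted (AHRE) genes; decoys point at nulls.
    """
    wt_cols = [f"beta_WT_{l}_{t}" for l in LIGANDS for t in TIMES]
    sign = np.sign(truth[wt_cols].sum(axis=1))
    edges = []

    scrubbed = truth[truth["motif_truth"] == "scrubbed"]
    for _, row in scrubbed.head(20).iterrows():
        edges.append(("REG_NONCANONICAL", row["gene_id"], int(sign[row.name]) or 1))
    planted = truth[truth["motif_truth"].str.startswith("planted")]
    for _, row in planted.head(20).iterrows():
        edges.append(("REG_CANONICAL", row["gene_id"], int(sign[row.name]) or 1))
    nulls = truth.loc[truth["effect_class"] == "null", "gene_id"].to_numpy()
    for k in range(3):
        for g in rng.choice(nulls, size=15, replace=False):
            edges.append((f"REG_DECOY_{k + 1}", g, int(rng.choice([-1, 1]))))
    return pd.DataFrame(edges, columns=["regulator", "target", "sign"])


def true_labels(truth: pd.DataFrame) -> pd.DataFrame:
    """Classify every gene per (ligand, time) from the TRUE effects.

    Applies the same decision rule as the estimation pipeline but with exact
    knowledge of the planted betas; by construction this reproduces the
    effect-class assignment (the truth-consistency invariant).
    """
    from .classify import classify_gene

    rows = []
    for ligand in LIGANDS:
        for time in TIMES:
            wt = truth[f"beta_WT_{ligand}_{time}"].to_numpy() != 0
            ko = truth[f"beta_KO_{ligand}_{time}"].to_numpy() != 0
            uns = truth["beta_genotype"].to_numpy() != 0
            for g, w, k, u in zip(truth["gene_id"], wt, ko, uns):
                rows.append(
                    {"gene_id": g, "ligand": ligand, "time": time,
                     "label": classify_gene(bool(w), bool(k), bool(u))}
                )
    return pd.DataFrame(rows)
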
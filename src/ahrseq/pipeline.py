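"""End-to-end orchestration: counts -> DE -> dependency classification ->
promoter AHRE scan -> enrichment -> upstream regulators.

In synthetic mode the input bundle is generated with known ground truth; in
user mode it is loaded from files (count matrix + sample sheet, genome
FASTA + GFF3, GMT gene sets, signed network TSV).  Contrasts follow the
study design: each ligand vs DMSO within genotype and time (8 tables) plus
the WT-vs-KO DMSO baseline per time for the unspecific exclusion.  Every
stage's table is persisted as TSV, every number in the report is
recomputable from those intermediates, and a fixed seed reproduces the run
byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import classify as _classify
from . import diffexpr as _de
from . import gsea as _gsea
from . import io as _io
from . import motifs as _motifs
from . import regulators as _reg
from .simulate import (
    GENOTYPES,
    LIGANDS,
    TIMES,
    ScenarioConfig,
    SyntheticDataset,
    generate_dataset,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "validate_inputs"]


@dataclass
class PipelineConfig:
    """Declarative run configuration; defaults are the analysis thresholds
    used throughout (DEG FDR 0.01, GSEA FDR 0.25 / NES 1.5, |z| 2, 3,000-nt
    promoter window)."""

    mode: str = "synthetic"  # synthetic | user
    outdir: str = "ahrseq_run"
    seed: int = 0
    # user-mode inputs
    genome: str | None = None
    annotation: str | None = None
    counts: str | None = None
    samples: str | None = None
    gene_sets: str | None = None
    network: str | None = None
    # thresholds
    deg_fdr: float = 0.01
    gsea_fdr: float = 0.25
    gsea_nes: float = 1.5
    gsea_n_perm: int = 250
    gsea_weight: float = 1.0
    gsea_symmetric: bool = False
    promoter_window: int = 3000
    require_wt_only: bool = False
    #: (ligand, time) cell whose DE profile feeds the regulator analysis
    regulator_cell: tuple[str, str] = ("BaP", "20h")
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)

    def __post_init__(self):
        if isinstance(self.scenario, dict):
            scenario = dict(self.scenario)
            for key in ("baseline_range", "size_factor_range"):
                if key in scenario and scenario[key] is not None:
                    scenario[key] = tuple(scenario[key])
            self.scenario = ScenarioConfig(**scenario)
        self.regulator_cell = tuple(self.regulator_cell)
        for name in ("deg_fdr", "gsea_fdr", "gsea_nes", "promoter_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mode not in ("synthetic", "user"):
            raise ValueError("mode must be 'synthetic' or 'user'")
        # synthetic mode follows the pipeline seed unless a scenario seed was
        # explicitly embedded in a config file
        if self.mode == "synthetic":
            self.scenario = dataclasses.replace(self.scenario, seed=self.seed)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["regulator_cell"] = list(self.regulator_cell)
        return d

    @property
    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (the output location
        does not change what is computed)."""
        d = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Paper-shaped result tables of one pipeline run."""

    dependent_counts: pd.DataFrame      # ligand x time dependent-DEG counts
    unique_dependent_total: int
    venn: pd.DataFrame                  # time and ligand partitions of dependent sets
    correlations: pd.DataFrame
    canonical: pd.DataFrame             # per-cell AHRE proportions
    noncanonical_genes: list[str]
    enrichment: pd.DataFrame
    regulator_calls: pd.DataFrame
    regulator_calls_nonahre: pd.DataFrame
    nonahre_edges: pd.DataFrame
    provenance: dict

    def summary(self) -> dict:
        return {
            "dependent_counts": {
                ligand: {t: int(v) for t, v in row.items()}
                for ligand, row in self.dependent_counts.iterrows()
            },
            "unique_dependent_total": self.unique_dependent_total,
            "n_noncanonical": len(self.noncanonical_genes),
            "n_enriched_sets": int(self.enrichment["passes_filter"].sum())
            if len(self.enrichment) else 0,
            "n_regulators_called": int(
                (self.regulator_calls["state"] != "undetermined").sum()
            ) if len(self.regulator_calls) else 0,
            "provenance": self.provenance,
        }


class _Bundle:
    """Uniform view of the inputs, whether generated or loaded."""

    def __init__(self, genome, genes, design, counts, gene_sets, network, truth=None):
        self.genome = genome
        self.genes = genes
        self.design = design
        self.counts = counts
        self.gene_sets = gene_sets
        self.network = network
        self.truth = truth


def _load_user_bundle(config: PipelineConfig) -> _Bundle:
    genome = _io.read_fasta(config.genome)
    genes = _io.read_gff3(config.annotation)
    counts = _io.read_table(config.counts).set_index("gene_id")
    design = _io.read_table(config.samples)
    gene_sets = _io.read_gmt(config.gene_sets) if config.gene_sets else []
    network = _reg.read_network(config.network) if config.network else pd.DataFrame(
        columns=["regulator", "target", "sign"]
    )
    return _Bundle(genome, genes, design, counts, gene_sets, network)


def _bundle_from_dataset(ds: SyntheticDataset) -> _Bundle:
    return _Bundle(ds.genome, ds.genes, ds.design, ds.counts, ds.gene_sets,
                   ds.network, ds.truth)


def validate_inputs(config: PipelineConfig, bundle: _Bundle | None = None) -> list[tuple[str, str]]:
    """Cross-check the input bundle; returns (level, message) diagnostics.

    Fatal: samples in the sheet missing from the count matrix, annotation
    contigs absent from the genome.  Warnings: count-matrix columns not in
    the sheet, gene sets or network targets without overlap with the count
    matrix (those edges are dropped downstream).
    """
    if bundle is None:
        if config.mode == "user":
            bundle = _load_user_bundle(config)
        else:
            return []  # a freshly generated bundle is consistent by construction
    diags: list[tuple[str, str]] = []
    sheet = set(bundle.design["sample_id"])
    cols = set(bundle.counts.columns)
    missing = sorted(sheet - cols)
    if missing:
        diags.append(("fatal", f"samples in sheet missing from counts: {missing}"))
    extra = sorted(cols - sheet)
    if extra:
        diags.append(("warning", f"count columns not in sample sheet: {extra}"))
    bad_contigs = sorted({g.contig for g in bundle.genes} - set(bundle.genome.keys()))
    if bad_contigs:
        diags.append(("fatal", f"annotation contigs absent from genome: {bad_contigs}"))
    gene_universe = set(bundle.counts.index)
    for name, _desc, members in (
        (gs.name, gs.description, gs.members) if isinstance(gs, _gsea.GeneSet) else gs
        for gs in bundle.gene_sets
    ):
        if not set(members) & gene_universe:
            diags.append(("warning", f"gene set {name!r} has no overlap with the count matrix"))
    if len(bundle.network):
        orphan = sorted(set(bundle.network["target"]) - gene_universe)
        if orphan:
            diags.append(("warning",
                          f"network targets absent from counts (edges dropped): {orphan[:10]}"))
    return diags


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage and persist all intermediates under
    ``config.outdir``.  Stage failures raise with the stage named; outputs
    written before the failure are left in place."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "inputs"
    try:
        if config.mode == "synthetic":
            dataset = generate_dataset(config.scenario)
            dataset.write(outdir / "inputs")
            bundle = _bundle_from_dataset(dataset)
        else:
            bundle = _load_user_bundle(config)
        diags = validate_inputs(config, bundle)
        fatal = [m for lvl, m in diags if lvl == "fatal"]
        for lvl, m in diags:
            (logger.error if lvl == "fatal" else logger.warning)(m)
        if fatal:
            raise ValueError("; ".join(fatal))

        stage = "diffexpr"
        counts = bundle.counts
        design = bundle.design.set_index("sample_id", drop=False)
        size_factors = _de.estimate_size_factors(counts)
        groups = [
            list(g["sample_id"])
            for _, g in bundle.design.groupby(["genotype", "treatment", "time"])
        ]
        dispersions = _de.estimate_dispersion(counts, size_factors, groups)
        _io.write_table(size_factors.rename_axis("sample_id").reset_index(),
                        outdir / "size_factors.tsv")

        def samples_of(genotype, treatment, time):
            m = bundle.design
            return list(
                m.loc[(m.genotype == genotype) & (m.treatment == treatment)
                      & (m.time == time), "sample_id"]
            )

        de_tables: dict[str, pd.DataFrame] = {}
        for genotype in GENOTYPES:
            for ligand in LIGANDS:
                for time in TIMES:
                    key = f"{genotype}_{ligand}_{time}"
                    de_tables[key] = _de.de_table(
                        counts, size_factors, dispersions,
                        (samples_of(genotype, "DMSO", time), samples_of(genotype, ligand, time)),
                        config.deg_fdr,
                    )
        for time in TIMES:
            de_tables[f"baseline_{time}"] = _de.de_table(
                counts, size_factors, dispersions,
                (samples_of("WT", "DMSO", time), samples_of("KO", "DMSO", time)),
                config.deg_fdr,
            )
        de_dir = outdir / "de"
        de_dir.mkdir(exist_ok=True)
        for key, table in de_tables.items():
            _io.write_table(table, de_dir / f"{key}.tsv")

        stage = "dependency_classifier"
        calls = pd.concat(
            [
                _classify.classify_cell(
                    de_tables[f"WT_{ligand}_{time}"], de_tables[f"KO_{ligand}_{time}"],
                    de_tables[f"baseline_{time}"], ligand, time, config.require_wt_only,
                )
                for ligand in LIGANDS
                for time in TIMES
            ],
            ignore_index=True,
        )
        _io.write_table(calls, outdir / "dependency_calls.tsv")
        dep_counts, unique_total = _classify.count_dependent(calls)
        _io.write_table(dep_counts.reset_index(), outdir / "dependent_counts.tsv")

        dep_sets = {
            (ligand, time): set(
                calls.loc[(calls.ligand == ligand) & (calls.time == time)
                          & (calls.label == "ahr_dependent"), "gene_id"]
            )
            for ligand in LIGANDS
            for time in TIMES
        }
        early = dep_sets[("BaP", "3h")] | dep_sets[("I3C", "3h")]
        late = dep_sets[("BaP", "20h")] | dep_sets[("I3C", "20h")]
        bap = dep_sets[("BaP", "3h")] | dep_sets[("BaP", "20h")]
        i3c = dep_sets[("I3C", "3h")] | dep_sets[("I3C", "20h")]
        venn = pd.DataFrame(
            [
                ("3h_vs_20h", *(_classify.venn_partition(early, late))),
                ("I3C_vs_BaP", *(_classify.venn_partition(i3c, bap))),
            ],
            columns=["comparison", "only_a", "only_b", "both"],
        )
        _io.write_table(venn, outdir / "venn.tsv")

        stage = "correlations"
        lfc = {
            (ligand, time): de_tables[f"WT_{ligand}_{time}"].set_index("gene_id")["log2fc"]
            for ligand in LIGANDS
            for time in TIMES
        }
        pairs = [
            ("BaP_3h_vs_20h", ("BaP", "3h"), ("BaP", "20h")),
            ("I3C_3h_vs_20h", ("I3C", "3h"), ("I3C", "20h")),
            ("BaP_vs_I3C_3h", ("BaP", "3h"), ("I3C", "3h")),
            ("BaP_vs_I3C_20h", ("BaP", "20h"), ("I3C", "20h")),
        ]
        corr_rows = []
        for name, cell_x, cell_y in pairs:
            res = _classify.correlate_profiles(lfc[cell_x], lfc[cell_y], comparison=name)
            corr_rows.append(dataclasses.asdict(res))
            dep_union = dep_sets[cell_x] | dep_sets[cell_y]
            if len(dep_union) >= 3:
                res_dep = _classify.correlate_profiles(
                    lfc[cell_x], lfc[cell_y], subset=dep_union,
                    comparison=name, subset_name="ahr_dependent",
                )
                corr_rows.append(dataclasses.asdict(res_dep))
        correlations = pd.DataFrame(corr_rows)
        _io.write_table(correlations, outdir / "correlations.tsv")

        stage = "promoter_motifs"
        promoters = _motifs.extract_promoters(bundle.genes, bundle.genome,
                                              config.promoter_window)
        profiles = _motifs.profile_genes(promoters)
        _io.write_table(_motifs.profiles_to_frame(profiles), outdir / "motif_profiles.tsv")
        canonical, noncanonical = _motifs.canonical_partition(calls, profiles)
        _io.write_table(canonical, outdir / "canonical_partition.tsv")

        stage = "gsea"
        sets = [
            gs if isinstance(gs, _gsea.GeneSet) else _gsea.GeneSet(gs[0], frozenset(gs[2]), gs[1])
            for gs in bundle.gene_sets
        ]
        enrich_frames = []
        for ligand in LIGANDS:
            for time in TIMES:
                ranked = _gsea.rank_metric(de_tables[f"WT_{ligand}_{time}"])
                usable = [gs for gs in sets
                          if 0 < len(gs.members & set(ranked.index)) < len(ranked)]
                if not usable:
                    continue
                res = _gsea.nes_and_fdr(
                    ranked, usable, weight=config.gsea_weight,
                    n_perm=config.gsea_n_perm, seed=config.seed,
                    fdr_threshold=config.gsea_fdr, nes_threshold=config.gsea_nes,
                    symmetric=config.gsea_symmetric,
                )
                res.insert(0, "time", time)
                res.insert(0, "ligand", ligand)
                enrich_frames.append(res)
        enrichment = (
            pd.concat(enrich_frames, ignore_index=True) if enrich_frames
            else pd.DataFrame(columns=["ligand", "time", "name", "size", "es", "nes",
                                       "p", "undefined_nes", "fdr", "passes_filter"])
        )
        _io.write_table(enrichment, outdir / "enrichment.tsv")

        stage = "upstream_regulators"
        reg_ligand, reg_time = config.regulator_cell
        reg_de = de_tables[f"WT_{reg_ligand}_{reg_time}"]
        reg_dep = dep_sets[(reg_ligand, reg_time)]
        if len(bundle.network):
            reg_calls = _reg.score_regulators(bundle.network, reg_de, reg_dep)
            reg_nonahre, edges = _reg.filter_to_nonahre(
                reg_calls, bundle.network, profiles, calls
            )
        else:
            reg_calls = pd.DataFrame(columns=["regulator", "n_targets", "n_targets_in_degs",
                                              "n_scored", "overlap_p", "z", "state"])
            reg_nonahre, edges = reg_calls.copy(), bundle.network.copy()
        _io.write_table(reg_calls, outdir / "regulator_calls.tsv")
        _io.write_table(reg_nonahre, outdir / "regulator_calls_nonahre.tsv")
        _io.write_table(edges, outdir / "nonahre_edges.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    from . import __version__

    provenance = {"seed": config.seed, "config_hash": config.config_hash,
                  "version": __version__, "mode": config.mode}
    report = RunReport(
        dependent_counts=dep_counts,
        unique_dependent_total=unique_total,
        venn=venn,
        correlations=correlations,
        canonical=canonical,
        noncanonical_genes=noncanonical,
        enrichment=enrichment,
        regulator_calls=reg_calls,
        regulator_calls_nonahre=reg_nonahre,
        nonahre_edges=edges,
        provenance=provenance,
    )
    (outdir / "report.json").write_text(json.dumps(report.summary(), indent=2, sort_keys=True))
    return report
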
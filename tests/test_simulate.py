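"""Synthetic genome, annotation, motif planting/scrubbing and NB counts."""

import numpy as np
import pandas as pd
import pytest

from ahrseq import io as aio
from ahrseq.motifs import BUILTIN_MOTIFS, extract_promoters, profile_genes, scan
from ahrseq.simulate import (
    GeneModel,
    Genome,
    ScenarioConfig,
    generate_dataset,
    make_annotation,
    make_design,
    make_genome,
    plant_motif,
    scrub_motifs,
    simulate_counts,
    true_labels,
)


class TestMakeGenome:
    def test_gc_within_binomial_ci(self):
        genome = make_genome(1, 50_000, 0.5, seed=7)
        seq = genome["contig1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.47 <= gc <= 0.53

    def test_gc_zero_means_at_only(self):
        genome = make_genome(1, 10, 0.0, seed=1)
        assert set(genome["contig1"]) <= {"A", "T"}

    def test_deterministic(self):
        a = make_genome(2, 5000, 0.4, seed=7)
        b = make_genome(2, 5000, 0.4, seed=7)
        assert all(a[c] == b[c] for c in a)

    def test_rejects_bad_sizes(self):
        with pytest.raises(ValueError):
            make_genome(0, 100, 0.5, 1)
        with pytest.raises(ValueError):
            make_genome(1, 0, 0.5, 1)


class TestAnnotation:
    def test_placement_constraints(self):
        genome = make_genome(1, 100_000, 0.5, seed=3)
        genes = make_annotation(genome, 20, promoter_gap=4000, seed=3)
        assert len(genes) == 20
        assert len({g.gene_id for g in genes}) == 20
        assert {g.strand for g in genes} == {"+", "-"}
        spans = sorted((g.start, g.end) for g in genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2  # non-overlapping
        # every full 3000-nt window fits inside the contig
        for g in genes:
            if g.strand == "+":
                assert g.tss - 3000 >= 1
            else:
                assert g.tss + 3000 <= genome.length(g.contig)

    def test_genome_too_small(self):
        genome = make_genome(1, 10_000, 0.5, seed=1)
        with pytest.raises(ValueError):
            make_annotation(genome, 50)

    def test_gff3_round_trip(self, tmp_path):
        genome = make_genome(1, 60_000, 0.5, seed=5)
        genes = make_annotation(genome, 10, seed=5)
        path = tmp_path / "ann.gff3"
        aio.write_gff3(genes, path)
        assert aio.read_gff3(path) == genes


class TestPlantMotif:
    def _gene(self, genome):
        return make_annotation(genome, 4, seed=2)

    def test_plant_plus_strand_literal(self):
        genome = make_genome(1, 40_000, 0.5, seed=2)
        gene = next(g for g in self._gene(genome) if g.strand == "+")
        plant_motif(genome, gene, "AHRE_I", offset=100, strand="+", seed=0)
        prom = extract_promoters([gene], genome)[0]
        assert prom.sequence[100:105] == "GCGTG"

    def test_plant_minus_site_is_revcomp_on_reported_sequence(self):
        genome = make_genome(1, 40_000, 0.5, seed=2)
        gene = next(g for g in self._gene(genome) if g.strand == "+")
        plant_motif(genome, gene, "AHRE_I", offset=100, strand="-", seed=0)
        prom = extract_promoters([gene], genome)[0]
        assert prom.sequence[100:105] == "CACGC"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_planting_guarantees_a_scanner_hit(self, strand):
        genome = make_genome(1, 40_000, 0.5, seed=4)
        for gene in self._gene(genome):
            for motif_id in BUILTIN_MOTIFS:
                plant_motif(genome, gene, motif_id, offset=50, strand=strand, seed=9)
                prom = extract_promoters([gene], genome)[0]
                assert any(h.motif_id == motif_id for h in scan(prom.sequence))

    def test_ahre_ii_concretization_matches_pattern(self):
        genome = make_genome(1, 40_000, 0.5, seed=2)
        gene = next(g for g in self._gene(genome) if g.strand == "-")
        planted = plant_motif(genome, gene, "AHRE_II", offset=10, strand="+", seed=3)
        assert len(planted) == 14
        assert planted[:4] == "CATG" and planted[10] == "C" and planted[11] in "AT"
        assert planted[12:] == "TG"
        prom = extract_promoters([gene], genome)[0]
        assert prom.sequence[10:24] == planted

    def test_offset_outside_window_rejected(self):
        genome = make_genome(1, 40_000, 0.5, seed=2)
        gene = self._gene(genome)[0]
        with pytest.raises(ValueError):
            plant_motif(genome, gene, "AHRE_I", offset=2996, strand="+", seed=0)


class TestScrubMotifs:
    def test_scrub_random_promoter_clean(self):
        genome = make_genome(1, 40_000, 0.5, seed=6)
        gene = make_annotation(genome, 2, seed=6)[0]
        scrub_motifs(genome, gene, seed=1)
        prom = extract_promoters([gene], genome)[0]
        assert scan(prom.sequence) == []

    def test_already_clean_promoter_untouched(self):
        genome = Genome({"c1": "AT" * 4000})
        gene = GeneModel("g1", "c1", "+", 4001, 4500)
        before = genome["c1"]
        assert scrub_motifs(genome, gene, seed=1) == 0
        assert genome["c1"] == before

    def test_pathological_tandem_repeat_terminates(self):
        # promoter saturated with overlapping AHRE I sites
        genome = Genome({"c1": "GCGTG" * 600 + "A" * 1000})
        gene = GeneModel("g1", "c1", "+", 3001, 3500)
        scrub_motifs(genome, gene, seed=2)
        prom = extract_promoters([gene], genome)[0]
        assert scan(prom.sequence) == []


class TestSimulateCounts:
    def _null_truth(self, n=1, q=100.0):
        truth = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)]})
        for g in ("WT", "KO"):
            for l in ("BaP", "I3C"):
                for t in ("3h", "20h"):
                    truth[f"beta_{g}_{l}_{t}"] = 0.0
        truth["beta_genotype"] = 0.0
        truth["baseline"] = q
        return truth

    def test_null_gene_mean_within_three_se(self):
        design = make_design(replicates=4, seed=0)
        design["true_size_factor"] = 1.0
        counts = simulate_counts(design, self._null_truth(), dispersion=0.1, seed=1)
        assert 80 <= counts.iloc[0].mean() <= 120

    def test_planted_effect_ratio(self):
        design = make_design(replicates=12, seed=0)
        design["true_size_factor"] = 1.0
        truth = self._null_truth()
        truth["beta_WT_BaP_20h"] = 2.0
        counts = simulate_counts(design, truth, dispersion=0.1, seed=2)
        meta = design.set_index("sample_id")
        treated = [s for s in counts.columns
                   if meta.loc[s, ["genotype", "treatment", "time"]].tolist()
                   == ["WT", "BaP", "20h"]]
        ref = [s for s in counts.columns
               if meta.loc[s, ["genotype", "treatment", "time"]].tolist()
               == ["WT", "DMSO", "20h"]]
        ratio = counts.iloc[0][treated].mean() / counts.iloc[0][ref].mean()
        assert 3.0 <= ratio <= 5.3

    def test_poisson_limit(self):
        design = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(600)], "genotype": "WT",
             "treatment": "DMSO", "time": "3h",
             "replicate": range(1, 601), "true_size_factor": 1.0}
        )
        counts = simulate_counts(design, self._null_truth(), dispersion=1e-5, seed=3)
        row = counts.iloc[0]
        assert 0.8 <= row.var(ddof=1) / row.mean() <= 1.25

    def test_size_factor_scales_means(self):
        design = make_design(replicates=8, seed=1)
        design["true_size_factor"] = np.where(
            design["sample_id"].str.endswith(("r1", "r2", "r3", "r4")), 0.5, 2.0
        )
        counts = simulate_counts(design, self._null_truth(q=400.0), dispersion=0.05, seed=4)
        lo = design.loc[design.true_size_factor == 0.5, "sample_id"]
        hi = design.loc[design.true_size_factor == 2.0, "sample_id"]
        assert counts.iloc[0][hi].mean() / counts.iloc[0][lo].mean() == pytest.approx(4.0, rel=0.25)

    def test_errors(self):
        design = make_design(replicates=2, seed=0)
        with pytest.raises(ValueError):
            simulate_counts(design, self._null_truth(), dispersion=0.0, seed=1)
        with pytest.raises(ValueError):
            simulate_counts(design.iloc[0:0], self._null_truth(), dispersion=0.1, seed=1)

    def test_deterministic(self):
        design = make_design(replicates=2, seed=0)
        a = simulate_counts(design, self._null_truth(5), dispersion=0.1, seed=9)
        b = simulate_counts(design, self._null_truth(5), dispersion=0.1, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestScenario:
    def test_truth_consistency(self, small_dataset):
        """Classifying genes from the TRUE betas reproduces the effect-class
        assignment exactly."""
        truth = small_dataset.truth
        labels = true_labels(truth).set_index(["gene_id", "ligand", "time"])["label"]
        for _, row in truth.iterrows():
            gene_labels = labels.loc[row.gene_id]
            if row.effect_class == "unspecific":
                assert (gene_labels == "unspecific_excluded").all()
            elif row.effect_class == "null":
                assert (gene_labels == "unaffected").all()
            else:
                active = gene_labels[gene_labels != "unaffected"]
                assert len(active) > 0
                assert (active == row.effect_class).all()

    def test_motif_truth_agrees_with_scanner(self, small_dataset):
        """Planted promoters scan positive for each planted motif; scrubbed
        promoters scan negative for all motifs — zero exceptions."""
        ds = small_dataset
        promoters = extract_promoters(ds.genes, ds.genome)
        profiles = profile_genes(promoters)
        for _, row in ds.truth.iterrows():
            if row.motif_truth == "scrubbed":
                assert not profiles[row.gene_id].any_ahre
            elif row.motif_truth.startswith("planted:"):
                for motif_id in row.motif_truth.split(":", 1)[1].split("+"):
                    assert profiles[row.gene_id].present(motif_id)

    def test_design_is_complete_crossed(self, small_dataset):
        design = small_dataset.design
        assert len(design) == 48
        cells = design.groupby(["genotype", "treatment", "time"]).size()
        assert (cells == 4).all() and len(cells) == 12
        assert (design["true_size_factor"] > 0).all()

    def test_dataset_determinism_and_write_round_trip(self, tmp_path):
        cfg = ScenarioConfig(n_genes=60, n_dependent=10, n_independent=4,
                             n_unspecific=2, seed=21)
        a, b = generate_dataset(cfg), generate_dataset(cfg)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        assert a.genome["contig1"] == b.genome["contig1"]
        paths = a.write(tmp_path)
        assert aio.read_fasta(paths["genome"])["contig1"] == a.genome["contig1"]
        assert aio.read_gff3(paths["annotation"]) == a.genes
        counts = aio.read_table(paths["counts"]).set_index("gene_id")
        pd.testing.assert_frame_equal(counts, a.counts, check_names=False)
        sets = aio.read_gmt(paths["gene_sets"])
        assert [s[0] for s in sets] == [s[0] for s in a.gene_sets]

    def test_class_counts_rejected_when_exceeding_genes(self):
        with pytest.raises(ValueError):
            generate_dataset(ScenarioConfig(n_genes=10, n_dependent=20))
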
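# Methods

## The analysis chain

The package models a two-genotype ligand-exposure experiment: bone
marrow-derived macrophages from wild-type and AhR-knockout mice are exposed
to an AhR ligand (BaP or I3C) or vehicle (DMSO), activated with a
multi-PAMP stimulus, and profiled at 3 h and 20 h with four replicates per
cell — a complete 2 × 3 × 2 × 4 design of 48 samples.  Every downstream
claim is built from three families of two-group contrasts at matched time
points: ligand vs DMSO within the wild type, ligand vs DMSO within the
knockout, and wild type vs knockout under DMSO (the "unspecific" baseline).

A gene's per-condition label follows from three DEG flags (FDR < 0.01,
strict): the baseline flag dominates and excludes the gene as unspecific;
otherwise a DEG in exactly one genotype is AhR-dependent, in both
AhR-independent, in neither unaffected.  A KO-only DEG counts as dependent
under the literal either/or rule; because the biologically expected
dependent calls are WT-specific, such calls are logged and a
`require_wt_only` switch demotes them to unaffected.

## Differential expression

The DE stage is deliberately simple and transparent, and the pipeline
treats it as pluggable — any engine emitting the per-gene table
(gene_id, log2fc, se, p, fdr, is_deg) can replace it.

*Normalization.* Median-of-ratios size factors: for every gene with
strictly positive counts in all samples, each sample's count is divided by
the gene's geometric mean across samples; the sample's factor is the median
of these ratios.  If no gene qualifies, a pseudocount of 1 is applied and
logged.  Scaling one sample's library is absorbed into a single global
constant on the normalized matrix, so fold changes are invariant to it.

*Dispersion.* Counts are modeled as negative binomial with
Var = μ + αμ².  The gene-wise estimate is the method of moments on
normalized counts, α̂ = max(10⁻⁸, (v − m)/m²), with the within-group
variance v pooled over all design groups having ≥ 2 replicates (weighted by
degrees of freedom) and m the mean over those samples.  Raw gene-wise
moment estimates at a handful of replicates are far too noisy to plug into
a Wald statistic: genes whose dispersion is underestimated get shrunken
standard errors and inflate the type-I error well above nominal, while
overestimated genes lose power.  The default therefore moderates toward
the ensemble, in the spirit of the empirical shrinkage the established NB
DE tools use: estimates below the ensemble median are floored at it, and
the log-scale excess above the median is multiplied by df/(df + df₀) with
prior weight df₀ = 20.  With few residual degrees of freedom the estimate
is essentially the ensemble median; with many it stays close to the
gene-wise value.  The moderation leaves the ensemble median — and hence any
single-gene estimate — unchanged, and can be disabled
(`moderate=False`) to recover the raw moment estimator.  The test suite
verifies the resulting calibration on all-null NB data (fraction of
p < 0.05 within [0.03, 0.07] at 4 vs 4 replicates, essentially no false
FDR < 0.01 calls) and the recovery of α on simulated data.

*Test.* For contrast B (treated) over A (reference):
log2fc = log2((μ̂_B + ½)/(μ̂_A + ½)) on normalized group means
(pseudocount ½ keeps the fold change bounded and symmetric when a group
mean is zero), the delta-method standard error is
se² = [(1/μ̂_A + α̂)/n_A + (1/μ̂_B + α̂)/n_B]/ln²2, and p is the two-sided
normal tail of log2fc/se.  Genes with zero counts in both groups get
log2fc = 0, p = 1 (logged, never a crash).  FDR control is
Benjamini–Hochberg step-up (via statsmodels; an independent hand-rolled
step-up serves as the test oracle).  Not implemented, by design:
multi-factor GLMs, interaction terms, shrunken fold changes, Cook's
outlier handling, independent filtering.

## Promoter motif scanning

Promoters are the 3,000 nt upstream of the TSS (one TSS per gene; for
multi-transcript annotations the gene's 5′ end), clipped — not dropped — at
contig boundaries, reported 5′→3′ toward the TSS.  The three AHRE variants
are matched exactly (no PWM scoring): AHRE I `GCGTG`, AHRE II
`CATGnnnnnnC(A/T)TG` (8,192 concrete 14-mers), RelB AHRE `GGGTGCAT`.
Reverse-strand matching is defined as matching the reverse complement of
the expansion against the forward sequence, so presence calls are
orientation-invariant.  Overlapping occurrences are all counted and
palindromic sites report once per strand; both choices are irrelevant to
the presence/absence output the partition uses.  Soft-masked bases are
uppercased; other characters never match.  Internally coordinates are
0-based half-open, all I/O is 1-based closed (GFF3 convention).  Ties in
hit ordering resolve by (position, + before −, motif id).

The canonical partition reports, per ligand/time cell, the fraction of
dependent DEGs possessing each motif; the absence of all three motifs
*excludes* canonical AhR–ARNT regulation, which is the informative call —
a random 3-kb window contains the AHRE I pentamer by chance almost surely
(~2 × 2,996 windows at probability 4⁻⁵ each).

## Preranked enrichment

Genes are ranked by r = sign(log2fc)·(−log10 max(fdr, 10⁻³⁰⁰)); the
composite of fold-change direction and significance uses exactly the two
quantities the ranking is defined over, and ties break by |log2fc| then
gene id so the order is strict and deterministic.  The enrichment score is
the weighted KS running sum: member positions add |r|^p normalized by the
members' total (p = 1 default; p = 0 recovers the classical KS statistic),
non-members subtract 1/(N − N_S); the ES is the signed running deviation of
maximal absolute value, earliest position on exact-magnitude ties (with a
10⁻¹² float tolerance).  Significance uses gene-set permutation — random
member sets of matched size — because sample-level data are not part of the
preranked input: NES = ES / mean(|same-sign null ES|), nominal p is the
same-sign null tail, and the FDR is the pooled-null NES ratio estimator
capped at 1.  The reporting filter is FDR < 0.25 and NES > 1.5; the filter
is one-sided as printed, with a `symmetric` switch for |NES| > 1.5 since
depleted sets are equally interpretable.  Sets are intersected with the
ranked universe and must remain non-empty proper subsets.

## Upstream regulators

The network is user-supplied (regulator, target, sign ∈ {±1}); no
biological network is bundled.  Overlap significance is the hypergeometric
upper tail of the regulator's targets within the dependent DEG set over the
DE universe.  The activation z-score is the unweighted consistency
statistic z = (n_consistent − n_inconsistent)/√n over DEG targets with
nonzero fold change (a target is consistent when sign(log2fc) equals the
edge sign); edge-confidence weighting and causal-network corrections of
proprietary tools are intentionally not reproduced.  Thresholding is
strict: z = 2 exactly is undetermined.  The non-canonical filter keeps
regulators with at least one dependent, AHRE-free target and emits the
bipartite regulator → target edge table.

## Assay statistics

*qPCR.* ΔCq = Cq_target − mean(Cq_hk1, Cq_hk2) (arithmetic mean of cycles =
geometric mean of expression); per-replicate relative value 2^(−ΔCq) with
amplification efficiency fixed at 2 (instrument efficiencies are rarely
reported; a Pfaffl-style correction is out of scope); the reported ratio is
mean(treated)/mean(control) and the test is an unpaired two-sided Student
t-test on log2 relative values (Welch by flag).  The statistic is invariant
to shifting all Cq values and swapping groups inverts the ratio leaving p
unchanged.

*ELISA.* ODs are blank-subtracted; the calibration is the 4PL curve
y = d + (a − d)/(1 + (x/c)^b) fitted by Levenberg–Marquardt least squares
from the heuristic start a = min OD, d = max OD, c = concentration nearest
half-maximal OD, b = 1 (tolerances 10⁻¹⁵, ≤ 500 iterations; a fit that
fails to improve on the start is an error carrying the best RSS).  A flat
dose-response is flagged.  Concentrations invert the curve algebraically
and only strictly between the asymptotes — saturated wells are flagged,
never extrapolated.

## Synthetic data: what it emulates, and what it does not

The generator is the package's stand-in for the deposited sequencing data
and defines the conditions the test suite measures under.  Defaults:
2,000 genes (300 AhR-dependent, 100 AhR-independent, 50 unspecific, rest
null), 4 replicates, global NB dispersion α = 0.1 (per-gene dispersion is
deliberately off by default to keep recovery tests interpretable),
baseline means log-uniform on [20, 500] (geometric center ≈ 100, a typical
expressed-gene count at bulk depth), true size factors log-uniform on
[0.5, 2], effect magnitudes uniform on [1, 3] with random sign
(`effect_size` pins the magnitude, e.g. at 2 for recovery runs).
Dependent genes carry their effect in WT only, independent genes in both
genotypes, unspecific genes as a genotype shift present already under
DMSO; classifying from the true effects reproduces the class labels
exactly (a tested invariant).  By default one effect is shared across all
four ligand/time cells, matching the one-effect-per-genotype-contrast
truth model; `condition_specific_scenario()` instead assigns each gene a
BaP- and late-time-biased subset of cells, producing the asymmetric count
tables and partial Venn overlaps of a real affinity contrast.  Under that
variant the knockout contrasts carry fewer true signals, their BH
thresholds are stricter, and dependency-call precision drops measurably —
a real property of the classification rule worth knowing before applying
it at FDR 0.01 to shallow designs.

Promoter truth is planted (80 % of dependent genes receive 1–3 concrete
motif instances at random offsets and strands; AHRE I with probability
0.8, AHRE II 0.2, RelB 0.06, at least one forced) or scrubbed (iterated
single-base substitutions inside remaining hits, each accepted only if the
total hit count strictly decreases, which guarantees termination; chosen
over rejection sampling because AHRE-I-free random 3-kb windows are
essentially nonexistent).  Untouched promoters are labeled "ambient".
Gene sets are truth-derived (up/down dependent, independent) plus random
decoys; the network wires one regulator consistently onto scrubbed
dependent genes (retained by the non-canonical filter), one onto planted
genes (filtered out), and decoys onto nulls.

Not emulated: read-level artifacts (the pipeline starts at counts), gene
length and GC biases, per-gene dispersion trends, isoform structure
(one TSS per gene), correlated genes, batch effects, and chromatin context
for motifs.  Passing tests therefore demonstrate the correctness and
calibration of the statistical machinery under the stated NB model — not
robustness to the full messiness of real libraries.

## Reproducibility and problem sizes

Every stochastic component takes a seed; scenario generation fans a master
seed out to independent child streams (genome, annotation, effects,
motifs, counts, sets, network, design), so a fixed seed reproduces the
whole bundle and a full pipeline run byte-identically (fixed float format
in all TSVs).  Default problem sizes — 2,000 genes × 48 samples, 1,000
scanner-oracle sequences of 200 nt, 250 gene-set permutations in the
pipeline (1,000 standalone) — keep a complete run in the seconds-to-a-
minute range on a single core while leaving every estimate's Monte-Carlo
error well inside the asserted bounds.

## Known limitations

- The DE engine is a two-group Wald test; designs needing covariates or
  interaction terms must substitute their own engine via the table schema.
- The normal reference for the Wald statistic is approximate at n = 4; the
  dispersion moderation compensates on average but individual p-values are
  not exact small-sample quantities.
- The composite GSEA ranking is one reasonable reading of "ranked by fold
  change and FDR"; other monotone composites reorder ties among highly
  significant genes.
- The unspecific exclusion uses the genotype contrast under DMSO at the
  matched time; other baseline definitions (e.g. untreated vs vehicle)
  would need their own contrast tables.
- Motif presence is exact-match only; no PWM affinity, conservation, or
  accessibility weighting.
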
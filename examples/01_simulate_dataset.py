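"""Generate a synthetic macrophage dataset with known ground truth.

Builds a toy genome with a 48-sample design (WT and AhR-knockout, two
ligands plus vehicle, two activation times, four replicates), plants
AhR-dependent, AhR-independent and unspecific expression effects into
negative-binomial counts, and plants or scrubs AHRE motifs in promoters.
"""

from ahrseq.simulate import ScenarioConfig, generate_dataset

dataset = generate_dataset(ScenarioConfig(
    n_genes=400, n_dependent=60, n_independent=20, n_unspecific=10, seed=7,
))

print("samples:", len(dataset.design))
print(dataset.design.head(3).to_string(index=False))
print("\neffect classes:", dataset.truth["effect_class"].value_counts().to_dict())
print("motif truth:", dataset.truth["motif_truth"].str.split(":").str[0]
      .value_counts().to_dict())
print("\ncount matrix:", dataset.counts.shape,
      "| first gene mean count:", round(dataset.counts.iloc[0].mean(), 1))
paths = dataset.write("scratch/example_bundle")
print("\nwrote:", ", ".join(sorted(p.name for p in paths.values())))
# Each gene's class fixes where its log2 effect applies: dependent genes
# respond to ligand in WT only, independent genes in both genotypes,
# unspecific genes differ between genotypes already under DMSO.
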
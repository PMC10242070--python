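"""Scan promoters for AHRE motifs and split dependent genes by eligibility.

The 3,000-nt window upstream of each TSS is scanned on both strands for
perfect matches to AHRE I (GCGTG), AHRE II (CATGnnnnnnC(A/T)TG) and the
RelB AHRE (GGGTGCAT).  A gene without any AHRE cannot be a direct
(canonical) AhR-ARNT target.
"""

from ahrseq.motifs import (
    BUILTIN_MOTIFS, extract_promoters, profile_genes, scan,
)
from ahrseq.simulate import ScenarioConfig, generate_dataset

for motif in BUILTIN_MOTIFS.values():
    print(f"{motif.motif_id:8s} {motif.pattern:20s} "
          f"{motif.cardinality} concrete sequence(s)")

print("\nhits in GCGTGCGTG:", [(h.motif_id, h.position, h.strand)
                               for h in scan("GCGTGCGTG")])

ds = generate_dataset(ScenarioConfig(
    n_genes=300, n_dependent=50, n_independent=15, n_unspecific=5, seed=3,
))
profiles = profile_genes(extract_promoters(ds.genes, ds.genome))
truth = ds.truth.set_index("gene_id")
planted = truth[truth.motif_truth.str.startswith("planted")].index
scrubbed = truth[truth.motif_truth == "scrubbed"].index
print(f"\nplanted promoters with >=1 AHRE: "
      f"{sum(profiles[g].any_ahre for g in planted)}/{len(planted)}")
print(f"scrubbed promoters with 0 AHREs: "
      f"{sum(not profiles[g].any_ahre for g in scrubbed)}/{len(scrubbed)}")
ambient = truth[truth.motif_truth == "ambient"].index
frac = sum(profiles[g].any_ahre for g in ambient) / len(ambient)
print(f"untouched random promoters with an AHRE by chance: {frac:.0%}")
# A 5-mer like GCGTG appears by chance in nearly every random 3-kb window,
# which is why absence of an AHRE is the informative (exclusionary) signal.
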
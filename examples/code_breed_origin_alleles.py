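"""Enumerate ancestry-genotype states and build the w1-w7 design vectors.

Shows the locus-state combinatorics (16 ordered / 10 distinguishable for
two ancestors), assigns breed origin to SNP alleles from haplotype tracks,
and compiles the origin-count and origin-specific dosage vectors with their
per-origin MAF masks.
"""

import numpy as np

from boagwas import simcross, ancestry, origincode

for n in (2, 3):
    t = origincode.enumerate_states(n)
    print(f"{n} ancestors: {t.n_ordered} ordered ancestry-genotype "
          f"combinations, {t.n_distinguishable} distinguishable locus states")

snp_map, freqs = simcross.simulate_ancestral_frequencies(4000, 2, seed=1)
ref = simcross.sample_panel(snp_map, freqs,
                            {"INDICUS": 40, "HF": 50, "JERSEY": 40}, seed=2,
                            ld_founders=30)
founders = simcross.sample_panel(snp_map, freqs,
                                 {"INDICUS": 40, "HF": 40, "JERSEY": 40},
                                 seed=3, ld_founders=30)
cross, truth = simcross.simulate_crossbreds(
    founders, 300, {"INDICUS": 0.36, "HF": 0.49, "JERSEY": 0.15}, 4, seed=4)

partition = ancestry.partition_windows(snp_map, W=400)
model = ancestry.train_window_models(ref, partition,
                                     origins=("INDICUS", "HF", "JERSEY"), K=8)
track = ancestry.infer_ancestry(model, cross)
origins3 = origincode.assign_allele_origins(cross, track)
design3 = origincode.build_design(cross, origins3, mode="three_way")
design2 = origincode.build_design(cross,
                                  origincode.collapse_three_to_two(origins3),
                                  mode="two_way")

dos = cross.dosage()[:, origins3.snp_idx]
assert np.array_equal(design2.w["w2"] + design2.w["w3"], dos)
assert np.all(design3.w["w1"] + design3.w["w6"] + design3.w["w7"] == 2)
print("dosage conservation (w2+w3 = genotype) and origin-count "
      "conservation (w1+w6+w7 = 2) hold exactly")

for origin, mask in design3.masks.items():
    print(f"SNP alleles of {origin:8s} origin with MAF > 1%: {mask.sum():5d} "
          f"({(~mask).sum()} masked)")
# the masks drive the per-SNP model variants: a masked origin's
# within-origin effect is dropped from the association model at that SNP
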
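"""Adjust repeated test-day milk yields and extract per-cow phenotypes.

Simulates ~6 monthly records per cow for 300 cows in herds of ~2, fits the
repeatability model (parity, CDC, year-month, CDC x year-month, Legendre
lactation curves; random animal and herd), and prints the variance
components and the adjusted phenotype y* used by the GWAS.
"""

import numpy as np

from boagwas import simcross, tdadjust

snp_map, freqs = simcross.simulate_ancestral_frequencies(2000, 2, seed=1)
panel = simcross.sample_panel(snp_map, freqs,
                              {"INDICUS": 40, "HF": 40, "JERSEY": 40}, seed=2,
                              ld_founders=30)
cross, truth = simcross.simulate_crossbreds(
    panel, 300, {"INDICUS": 0.36, "HF": 0.49, "JERSEY": 0.15}, 4, seed=3)
truth = simcross.plant_qtl(panel, truth, [], seed=4)
records = simcross.simulate_testday(truth, h2=0.18, repeatability=0.35,
                                    panel=cross, seed=5)
print(f"{len(records)} test-day records on {records['cow_id'].nunique()} cows "
      f"in {records['herd_id'].nunique()} herds")

fit = tdadjust.fit_adjustment(records)
tot = fit.phenotypic_variance
print("variance shares (animal, herd, residual):",
      [round(fit.vc[k] / tot, 3) for k in ("var_animal", "var_herd", "var_e")])
v = truth.variance_components
print("true test-day shares     (a+pe, herd, e):",
      [round((v["var_a_td"] + v["var_pe_td"]) / 4.0, 3),
       round(v["var_h_td"] / 4.0, 3), round(v["var_e_td"] / 4.0, 3)])

ystar = tdadjust.adjusted_phenotypes(fit, records)
r = np.corrcoef(ystar["y_star"], truth.breeding_values)[0, 1]
print(f"correlation of y* with true breeding value: {r:.2f}")
# y* carries the cow's genetic + herd signal with residual noise shrunk by
# the number of records; it is the phenotype every association model uses
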
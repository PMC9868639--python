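"""Shared small simulated fixtures (generated at test time, seeded)."""

import numpy as np
import pytest

from boagwas import simcross

PROPS = {"INDICUS": 0.36, "HF": 0.49, "JERSEY": 0.15}


@pytest.fixture(scope="session")
def small_world():
    """2,000 SNPs on 2 chromosomes; reference, founder and crossbred panels."""
    rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(7).spawn(5)]
    snp_map, freqs = simcross.simulate_ancestral_frequencies(2000, 2, seed=rngs[0])
    ref = simcross.sample_panel(snp_map, freqs,
                                {"INDICUS": 30, "HF": 40, "JERSEY": 30},
                                seed=rngs[1], ld_founders=30)
    founders = simcross.sample_panel(snp_map, freqs,
                                     {"INDICUS": 40, "HF": 40, "JERSEY": 40},
                                     seed=rngs[2], ld_founders=30)
    cross, truth = simcross.simulate_crossbreds(founders, 200, PROPS, 4,
                                                seed=rngs[3])
    return {"snp_map": snp_map, "freqs": freqs, "ref": ref,
            "founders": founders, "cross": cross, "truth": truth,
            "seed_td": rngs[4]}


@pytest.fixture(scope="session")
def small_records(small_world):
    import copy
    truth = copy.deepcopy(small_world["truth"])
    rec = simcross.simulate_testday(truth, panel=small_world["cross"],
                                    seed=np.random.default_rng(99))
    return truth, rec
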
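"""Window partition, PCA classifier, HMM decoding and validation reports."""

import itertools

import numpy as np
import pytest

from boagwas import simcross, ancestry
from boagwas.ancestry import (forward_backward, infer_ancestry,
                              partition_windows, train_window_models,
                              truth_window_labels, validate_assignment,
                              window_loglik, breed_content, AncestryTrack)
from boagwas.simcross import HaplotypePanel


def brute_force_marginals(emissions, log_trans, log_prior):
    """Exhaustive path enumeration oracle for chains of <= 8 windows."""
    T, K = emissions.shape
    marg = np.full((T, K), -np.inf)
    tot = -np.inf
    for path in itertools.product(range(K), repeat=T):
        lp = log_prior[path[0]] + emissions[0, path[0]]
        for t in range(1, T):
            lp += log_trans[path[t - 1], path[t]] + emissions[t, path[t]]
        tot = np.logaddexp(tot, lp)
        for t in range(T):
            marg[t, path[t]] = np.logaddexp(marg[t, path[t]], lp)
    return np.exp(marg - tot), tot


def linear_map(n_snp, n_chrom=1):
    return simcross.uniform_map(n_snp, n_chrom)


class TestPartition:
    def test_trailing_window_dropped_below_80pct(self):
        sm = linear_map(1249)
        part = partition_windows(sm, 500, 0.8)
        assert [(s, e) for _c, s, e in part.windows] == [(0, 500), (500, 1000)]
        assert part.n_dropped_snps == 249

    def test_trailing_window_kept_at_80pct(self):
        sm = linear_map(1400)
        part = partition_windows(sm, 500, 0.8)
        assert [(s, e) for _c, s, e in part.windows] == [
            (0, 500), (500, 1000), (1000, 1400)]

    def test_single_snp_windows(self):
        sm = linear_map(37)
        part = partition_windows(sm, 1, 0.0)
        assert part.n_windows == 37

    def test_short_chromosome_yields_no_windows(self):
        sm = linear_map(300)
        part = partition_windows(sm, 500, 0.8)
        assert part.n_windows == 0
        assert part.n_dropped_snps == 300

    def test_windows_within_chromosomes(self, small_world):
        part = partition_windows(small_world["snp_map"], 300)
        sl = small_world["snp_map"].chromosome_slices()
        for c, s, e in part.windows:
            assert sl[c].start <= s < e <= sl[c].stop


def _two_pop_panel(freq_a, freq_b, n_each=10, seed=0):
    rng = np.random.default_rng(seed)
    m = len(freq_a)
    haps = np.vstack([(rng.random((2 * n_each, m)) < freq_a),
                      (rng.random((2 * n_each, m)) < freq_b)]).astype(np.int8)
    ids = [f"a{i}" for i in range(n_each)] + [f"b{i}" for i in range(n_each)]
    pops = np.array(["REF_INDICUS"] * n_each + ["REF_HF"] * n_each)
    return HaplotypePanel(haps, ids, pops, linear_map(m))


class TestWindowModels:
    def test_fixed_difference_limit_separates_classes(self):
        m = 40
        panel = _two_pop_panel(np.zeros(m), np.ones(m))
        part = partition_windows(panel.snp_map, 40, 0.8)
        model = train_window_models(panel, part, origins=("INDICUS", "HF"), K=2)
        wm = model.window_models[0]
        d = np.linalg.norm(wm.class_means[0] - wm.class_means[1])
        assert d > 1.0
        assert np.all(wm.class_vars <= model.ridge + 1e-12)

    def test_identical_panels_uniform_posteriors(self):
        m = 60
        f = np.full(m, 0.5)
        panel = _two_pop_panel(f, f, n_each=20, seed=1)
        part = partition_windows(panel.snp_map, 60, 0.8)
        model = train_window_models(panel, part, origins=("INDICUS", "HF"), K=2)
        track = infer_ancestry(model, panel)
        assert np.abs(track.posteriors - 0.5).mean() < 0.2

    def test_loglik_matches_gaussian_oracle(self):
        m = 30
        panel = _two_pop_panel(np.full(m, 0.2), np.full(m, 0.8), seed=2)
        part = partition_windows(panel.snp_map, 30, 0.8)
        model = train_window_models(panel, part, origins=("INDICUS", "HF"), K=3)
        wm = model.window_models[0]
        hap = panel.hap_matrix[3]
        ll = window_loglik(model, hap[None, :], 0)[0]
        z = wm.project(hap[None, :].astype(float))[0]
        for o in range(2):
            d = z - wm.class_means[o]
            expect = -0.5 * np.sum(d * d / wm.class_vars[o]
                                   + np.log(2 * np.pi * wm.class_vars[o]))
            assert np.isclose(ll[o], expect)

    def test_missing_origin_errors(self, small_world):
        part = partition_windows(small_world["snp_map"], 200)
        with pytest.raises(ValueError):
            train_window_models(small_world["ref"], part,
                                origins=("INDICUS", "HF", "JERSEY", "GIR"))


class TestForwardBackward:
    @pytest.mark.parametrize("T,K,tau,seed", [
        (4, 2, 0.1, 0), (8, 3, 0.01, 1), (6, 3, 0.3, 2), (5, 2, 0.0, 3)])
    def test_matches_brute_force(self, T, K, tau, seed):
        rng = np.random.default_rng(seed)
        em = rng.normal(0, 2, (1, T, K))
        with np.errstate(divide="ignore"):
            lt = np.full((K, K), np.log(tau / (K - 1)) if tau > 0 else -np.inf)
            np.fill_diagonal(lt, np.log1p(-tau))
            lp = np.log(np.full(K, 1.0 / K))
        post, ll = forward_backward(em, lt, lp)
        oracle_post, oracle_ll = brute_force_marginals(em[0], lt, lp)
        assert abs(ll[0] - oracle_ll) < 1e-6
        np.testing.assert_allclose(post[0], oracle_post, atol=1e-9)

    def test_posteriors_normalized(self, small_world):
        part = partition_windows(small_world["snp_map"], 200)
        model = train_window_models(small_world["ref"], part,
                                    origins=("INDICUS", "HF", "JERSEY"), K=6)
        track = infer_ancestry(model, small_world["cross"])
        np.testing.assert_allclose(track.posteriors.sum(-1), 1.0, atol=1e-9)


class TestInference:
    def test_purebred_haplotypes_recovered(self, small_world):
        sm, freqs = small_world["snp_map"], small_world["freqs"]
        held = simcross.sample_panel(sm, freqs,
                                     {"INDICUS": 10, "HF": 10, "JERSEY": 10},
                                     seed=77, ld_founders=30)
        part = partition_windows(sm, 200)
        model = train_window_models(small_world["ref"], part,
                                    origins=("INDICUS", "HF", "JERSEY"), K=6)
        track = infer_ancestry(model, held)
        truthlab = np.repeat([0] * 20 + [1] * 20 + [2] * 20,
                             part.n_windows).reshape(60, part.n_windows)
        rep = validate_assignment(track, truthlab)
        assert rep["overall_accuracy"] >= 0.99

    def test_f1_content_half_half(self, small_world):
        cross, truth = simcross.simulate_crossbreds(
            small_world["founders"], 30, {"INDICUS": 0.5, "HF": 0.5}, 1,
            mating_scheme="f1", seed=5)
        part = partition_windows(small_world["snp_map"], 200)
        model = train_window_models(small_world["ref"], part,
                                    origins=("INDICUS", "HF"), K=4)
        track = infer_ancestry(model, cross)
        content = breed_content(track)
        np.testing.assert_allclose(content[:, 0], 0.5, atol=0.1)

    def test_tau_zero_single_origin_per_chromosome(self, small_world):
        held = simcross.sample_panel(small_world["snp_map"],
                                     small_world["freqs"], {"INDICUS": 5,
                                                            "HF": 5},
                                     seed=78, ld_founders=30)
        part = partition_windows(small_world["snp_map"], 200)
        model = train_window_models(small_world["ref"], part,
                                    origins=("INDICUS", "HF", "JERSEY"), K=6)
        track = infer_ancestry(model, held, tau=0.0)
        for _c, w0, w1 in part.chrom_window_ranges():
            block = track.labels[:, w0:w1]
            assert np.all(block == block[:, :1])

    def test_crossbred_content_near_target(self, small_world):
        part = partition_windows(small_world["snp_map"], 200)
        model = train_window_models(small_world["ref"], part,
                                    origins=("INDICUS", "HF", "JERSEY"), K=6)
        track = infer_ancestry(model, small_world["cross"])
        content = breed_content(track)
        true_comp = small_world["truth"].composition
        assert abs(content[:, 0].mean() - true_comp[:, 0].mean()) < 0.04

    def test_accuracy_monotone_in_window_size(self, small_world):
        sm, freqs = small_world["snp_map"], small_world["freqs"]
        held = simcross.sample_panel(sm, freqs,
                                     {"INDICUS": 10, "HF": 10, "JERSEY": 10},
                                     seed=79, ld_founders=30)
        truth_of = {25: None, 200: None}
        accs = {}
        for W in (25, 200):
            part = partition_windows(sm, W)
            model = train_window_models(small_world["ref"], part,
                                        origins=("INDICUS", "HF", "JERSEY"),
                                        K=6)
            track = infer_ancestry(model, held)
            tl = np.repeat([0] * 20 + [1] * 20 + [2] * 20,
                           part.n_windows).reshape(60, part.n_windows)
            accs[W] = validate_assignment(track, tl)["overall_accuracy"]
        assert accs[200] >= accs[25] - 1e-9

    def test_label_permutation_equivariance(self, small_world):
        part = partition_windows(small_world["snp_map"], 200)
        m1 = train_window_models(small_world["ref"], part,
                                 origins=("INDICUS", "HF", "JERSEY"), K=6)
        m2 = train_window_models(small_world["ref"], part,
                                 origins=("JERSEY", "INDICUS", "HF"), K=6)
        t1 = infer_ancestry(m1, small_world["cross"])
        t2 = infer_ancestry(m2, small_world["cross"])
        perm = [m2.origins.index(o) for o in m1.origins]
        np.testing.assert_allclose(t1.posteriors,
                                   t2.posteriors[:, :, perm], atol=1e-9)

    def test_map_scaled_transitions_match_constant_on_uniform_map(self,
                                                                  small_world):
        # on an equally spaced map, a per-cM switch rate reproducing the
        # constant per-boundary probability gives identical posteriors
        sm = small_world["snp_map"]
        part = partition_windows(sm, 200)
        model = train_window_models(small_world["ref"], part,
                                    origins=("INDICUS", "HF", "JERSEY"), K=6)
        gaps = np.diff([0.5 * (sm.cm[s] + sm.cm[e - 1])
                        for _c, s, e in part.windows[:part.n_windows // 2]])
        d = gaps[0]
        rate = -np.log(1 - 0.01) / d
        t_const = infer_ancestry(model, small_world["cross"], tau=0.01)
        t_map = infer_ancestry(model, small_world["cross"], tau=rate,
                               transition="map")
        np.testing.assert_allclose(t_const.posteriors, t_map.posteriors,
                                   atol=1e-9)

    def test_bad_tau_and_prior(self, small_world):
        part = partition_windows(small_world["snp_map"], 200)
        model = train_window_models(small_world["ref"], part,
                                    origins=("INDICUS", "HF", "JERSEY"), K=6)
        with pytest.raises(ValueError):
            infer_ancestry(model, small_world["cross"], tau=1.5)
        with pytest.raises(ValueError):
            infer_ancestry(model, small_world["cross"],
                           prior=np.array([0.9, 0.9, 0.2]))


class TestValidationReport:
    def _toy_track(self, labels, origins=("INDICUS", "HF")):
        H, W = labels.shape
        K = len(origins)
        post = np.eye(K)[labels]
        part = partition_windows(linear_map(W), 1, 0.0)
        ids = [f"s{i}" for i in range(H // 2)]
        return AncestryTrack(ids, origins, part, post, labels, 0.01)

    def test_truth_equals_prediction(self):
        labels = np.zeros((4, 10), dtype=np.int8)
        track = self._toy_track(labels)
        rep = validate_assignment(track, labels)
        assert rep["overall_accuracy"] == 1.0
        assert rep["per_origin"]["INDICUS"]["sd"] == 0.0

    def test_random_labels_near_chance(self):
        rng = np.random.default_rng(0)
        pred = rng.integers(0, 2, (40, 50)).astype(np.int8)
        truth = rng.integers(0, 2, (40, 50)).astype(np.int8)
        rep = validate_assignment(self._toy_track(pred), truth)
        assert abs(rep["overall_accuracy"] - 0.5) < 0.06

    def test_shape_mismatch_errors(self):
        labels = np.zeros((4, 10), dtype=np.int8)
        with pytest.raises(ValueError):
            validate_assignment(self._toy_track(labels),
                                np.zeros((4, 9), dtype=np.int8))

    def test_truth_window_labels_majority(self, small_world):
        part = partition_windows(small_world["snp_map"], 200)
        tl = truth_window_labels(small_world["truth"].hap_origin, part)
        h, (_c, s, e) = 0, part.windows[0]
        counts = np.bincount(small_world["truth"].hap_origin[0, s:e],
                             minlength=3)
        assert tl[0, 0] == counts.argmax()


class TestBreedContent:
    def test_all_one_origin(self):
        labels = np.zeros((2, 8), dtype=np.int8)
        post = np.zeros((2, 8, 2))
        post[:, :, 0] = 1.0
        part = partition_windows(linear_map(8), 1, 0.0)
        track = AncestryTrack(["s0"], ("INDICUS", "HF"), part, post, labels,
                              0.01)
        content = breed_content(track)
        np.testing.assert_allclose(content, [[1.0, 0.0]])

    def test_half_half_hard(self):
        labels = np.array([[0] * 4 + [1] * 4, [0] * 4 + [1] * 4],
                          dtype=np.int8)
        post = np.eye(2)[labels]
        part = partition_windows(linear_map(8), 1, 0.0)
        track = AncestryTrack(["s0"], ("INDICUS", "HF"), part, post, labels,
                              0.01)
        content = breed_content(track, method="hard")
        np.testing.assert_allclose(content, [[0.5, 0.5]])
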
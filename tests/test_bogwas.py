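"""GRM, REML, GLS scan, genomic control, FDR, regions and power arithmetic."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg as la
from scipy import stats

from boagwas import simcross, origincode, bogwas
from boagwas.bogwas import (equivalent_n, fdr_tiers, genomic_control,
                            reml_null, rel_power, snp_scan, summarize_regions,
                            vanraden_grm, VarianceComponents)


class TestGrm:
    def test_hand_example(self):
        g = vanraden_grm(np.array([[0.0], [2.0]]), np.array([0.5]))
        np.testing.assert_allclose(g.matrix, [[2, -2], [-2, 2]])

    def test_identical_rows_exchangeable(self):
        dos = np.tile(np.array([0, 1, 2, 1, 0.0]), (4, 1))
        g = vanraden_grm(dos)
        assert np.allclose(g.matrix, g.matrix[0, 0])

    def test_unrelated_panel_diag_one_offdiag_zero(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.9, 5000)
        dos = rng.binomial(2, p, (400, 5000)).astype(float)
        g = vanraden_grm(dos)
        assert abs(np.diag(g.matrix).mean() - 1) < 0.02
        off = g.matrix[np.triu_indices(400, 1)]
        assert abs(off.mean()) < 0.01

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            vanraden_grm(np.zeros((3, 4)))
        with pytest.raises(ValueError):
            vanraden_grm(np.array([[3.0]]))


@pytest.fixture(scope="module")
def structured(small_world):
    """600-cow crossbred set with a structured GRM and herds of ~2."""
    cross, truth = simcross.simulate_crossbreds(
        small_world["founders"], 600,
        {"INDICUS": 0.36, "HF": 0.49, "JERSEY": 0.15}, 4, seed=21)
    grm = vanraden_grm(cross.dosage().astype(float))
    herd = np.repeat(np.arange(300), 2)
    return cross, truth, grm, herd


class TestRemlNull:
    def test_matches_direct_likelihood_oracle(self, structured):
        _c, _t, grm, herd = structured
        n = 600
        G = grm.matrix
        rng = np.random.default_rng(7)
        L = np.linalg.cholesky(G + 1e-8 * np.eye(n))
        Zh = np.zeros((n, 300))
        Zh[np.arange(n), herd] = 1
        y = (L @ rng.normal(size=n) * np.sqrt(0.18)
             + Zh @ rng.normal(size=300) * np.sqrt(0.10)
             + rng.normal(size=n) * np.sqrt(0.72))
        vc = reml_null(y, None, grm, herd)
        X = np.ones((n, 1))

        def negll(logv):
            va, vh, ve = np.exp(logv)
            V = va * G + vh * Zh @ Zh.T + ve * np.eye(n)
            cf = la.cho_factor(V, lower=True)
            Vi_y = la.cho_solve(cf, y)
            Vi_X = la.cho_solve(cf, X)
            XtViX = X.T @ Vi_X
            beta = np.linalg.solve(XtViX, X.T @ Vi_y)
            yPy = y @ Vi_y - (X.T @ Vi_y) @ beta
            return 0.5 * (2 * np.log(np.diag(cf[0])).sum()
                          + np.linalg.slogdet(XtViX)[1] + yPy)

        from scipy.optimize import minimize
        res = minimize(negll, np.log([0.2, 0.1, 0.7]), method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-9,
                                "maxiter": 3000})
        assert vc.converged
        np.testing.assert_allclose(
            [vc.var_a, vc.var_h, vc.var_e], np.exp(res.x), rtol=1e-3)
        assert abs(vc.loglik + res.fun) < 1e-4

    def test_zero_heritability_estimated_small(self, structured):
        _c, _t, grm, herd = structured
        hits = 0
        for s in range(5):
            rng = np.random.default_rng(200 + s)
            y = rng.normal(0, 1, 600)
            vc = reml_null(y, None, grm, herd)
            hits += vc.h2 <= 0.05
        assert hits >= 4

    def test_identity_grm_matches_balanced_anova(self):
        # with G = I the animal and residual variances are confounded; their
        # sum and the herd variance match the balanced one-way ANOVA oracle
        rng = np.random.default_rng(3)
        n_herd, k = 80, 5
        herd = np.repeat(np.arange(n_herd), k)
        y = rng.normal(0, 0.8, n_herd)[herd] + rng.normal(0, 1.1, n_herd * k)
        n = len(y)
        vc = reml_null(y, None, np.eye(n), herd)
        ybar = y.reshape(n_herd, k).mean(axis=1)
        msb = k * np.sum((ybar - y.mean()) ** 2) / (n_herd - 1)
        msw = np.sum((y.reshape(n_herd, k) - ybar[:, None]) ** 2) / (n - n_herd)
        assert abs((vc.var_a + vc.var_e) - msw) < 1e-3
        assert abs(vc.var_h - (msb - msw) / k) < 1e-3

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            reml_null(np.array([1.0, 2.0]), np.ones((2, 3)), np.eye(2))


def _true_origin_design(cross, truth, mode):
    m = cross.snp_map.n_snp
    incl = np.arange(m)
    oa = origincode.OriginAssignment(
        ("INDICUS", "HF", "JERSEY"),
        truth.hap_origin.astype(np.uint8), incl, 0)
    if mode == "two_way":
        oa = origincode.collapse_three_to_two(oa)
    return origincode.build_design(cross, oa, mode)


@pytest.fixture(scope="module")
def scan_world(structured):
    cross, truth, grm, herd = structured
    d2 = _true_origin_design(cross, truth, "two_way")
    d3 = _true_origin_design(cross, truth, "three_way")
    rng = np.random.default_rng(11)
    y = rng.normal(0, 1, 600)
    X = rng.normal(size=(600, 2))
    vc = VarianceComponents(0.2, 0.1, 0.7, 0.0, True, 1)
    return cross, d2, d3, y, X, vc, grm, herd


class TestSnpScan:
    def test_gls_matches_dense_oracle_small(self, small_world):
        founders = small_world["founders"]
        cross, truth = simcross.simulate_crossbreds(
            founders, 40, {"INDICUS": 0.36, "HF": 0.49, "JERSEY": 0.15},
            4, seed=31)
        d2 = _true_origin_design(cross, truth, "two_way")
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, 40)
        X = rng.normal(size=(40, 2))
        herd = np.arange(40) // 2
        grm = vanraden_grm(cross.dosage().astype(float))
        vc = VarianceComponents(0.3, 0.1, 0.6, 0.0, True, 1)
        scan = snp_scan("2", d2, y, X, vc, grm, herd)
        V = bogwas._build_V(vc, grm.matrix, herd)
        Vinv = np.linalg.inv(V)
        full = scan.rows[scan.rows["variant"] == "2"]
        for snp in full["snp"].unique()[:40]:
            j = int(np.where(d2.snp_idx == snp)[0][0])
            D = np.column_stack([np.ones(40), X, d2.w["w1"][:, j],
                                 d2.w["w3"][:, j], d2.w["w2"][:, j]])
            C = D.T @ Vinv @ D
            est = np.linalg.solve(C, D.T @ Vinv @ y)
            se = np.sqrt(np.diag(np.linalg.inv(C)))
            sub = full[full["snp"] == snp].set_index("effect_type")
            for k, eff in enumerate(("g1", "g3", "g2")):
                assert abs(sub.loc[eff, "estimate"] - est[3 + k]) < 1e-8
                assert abs(sub.loc[eff, "se"] - se[3 + k]) < 1e-8

    def test_model34_antisymmetry_and_shared_effects(self, scan_world):
        _c, _d2, d3, y, X, vc, grm, herd = scan_world
        s3 = snp_scan("3", d3, y, X, vc, grm, herd).rows
        s4 = snp_scan("4", d3, y, X, vc, grm, herd).rows
        g6 = s3[s3["effect_type"] == "g6"].set_index("snp")["estimate"]
        g7 = s4[s4["effect_type"] == "g7"].set_index("snp")["estimate"]
        common = g6.index.intersection(g7.index)
        assert len(common) > 100
        assert np.abs(g6[common] + g7[common]).max() < 1e-8
        for eff in ("g2", "g4", "g5"):
            a = s3[s3["effect_type"] == eff].set_index("snp")["estimate"]
            b = s4[s4["effect_type"] == eff].set_index("snp")["estimate"]
            c = a.index.intersection(b.index)
            assert np.abs(a[c] - b[c]).max() < 1e-8

    def test_masked_origin_drops_within_term(self, scan_world):
        _c, d2, _d3, y, X, vc, grm, herd = scan_world
        masked = np.flatnonzero(~d2.masks["INDICUS"])
        if len(masked):
            rows = snp_scan("2", d2, y, X, vc, grm, herd).rows
            snp = d2.snp_idx[masked[0]]
            effs = set(rows[rows["snp"] == snp]["effect_type"])
            assert "g2" not in effs

    def test_chi2_identity(self, scan_world):
        _c, d2, _d3, y, X, vc, grm, herd = scan_world
        rows = snp_scan("2", d2, y, X, vc, grm, herd).rows
        np.testing.assert_allclose(rows["chi2"],
                                   (rows["estimate"] / rows["se"]) ** 2)

    def test_exact_per_snp_reml_close_to_null_v_scan(self, scan_world):
        # re-estimating the variance components per SNP barely moves the
        # estimates relative to the null-REML fixed-V scan on a null trait
        cross, d2, _d3, y, X, _vc, grm, herd = scan_world
        vc_fit = reml_null(y, X, grm, herd, tol=1e-4)
        pick = np.arange(0, 50, 10)
        exact = bogwas.snp_scan_exact("2", d2, y, X, grm, herd, snps=pick,
                                      reml_kwargs={"tol": 1e-4})
        fixed = snp_scan("2", d2, y, X, vc_fit, grm, herd)
        for snp in exact.rows["snp"].unique():
            a = exact.rows[exact.rows["snp"] == snp].set_index("effect_type")
            b = fixed.rows[fixed.rows["snp"] == snp].set_index("effect_type")
            for eff in set(a.index) & set(b.index):
                assert abs(a.loc[eff, "estimate"] - b.loc[eff, "estimate"]) \
                    < 0.5 * b.loc[eff, "se"]

    def test_model1_raw_dosage(self, scan_world):
        cross, d2, _d3, y, X, vc, grm, herd = scan_world
        rows = snp_scan("1", d2, y, X, vc, grm, herd).rows
        assert set(rows["effect_type"]) == {"g"}
        assert len(rows) > 0.9 * d2.n_snp


class TestGenomicControl:
    def test_definitional_lambda_one(self):
        rows = pd.DataFrame({"effect_type": "g1",
                             "chi2": np.full(10, bogwas.CHI2_MEDIAN_1DF),
                             "p": np.full(10, 0.5)})
        out, lam = genomic_control(rows)
        assert np.isclose(lam["g1"], 1.0)
        np.testing.assert_allclose(out["p_gc"], 0.5)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        chi2 = rng.chisquare(1, 1000)
        r1 = pd.DataFrame({"effect_type": "g1", "chi2": chi2,
                           "p": stats.chi2.sf(chi2, 1)})
        r2 = r1.assign(chi2=2 * chi2)
        _o1, l1 = genomic_control(r1)
        o2, l2 = genomic_control(r2)
        assert np.isclose(l2["g1"], 2 * l1["g1"])
        np.testing.assert_allclose(genomic_control(r1)[0]["p_gc"],
                                   o2["p_gc"])

    def test_null_chi2_lambda_near_one(self):
        rng = np.random.default_rng(1)
        chi2 = rng.chisquare(1, 50_000)
        rows = pd.DataFrame({"effect_type": "g1", "chi2": chi2,
                             "p": stats.chi2.sf(chi2, 1)})
        _out, lam = genomic_control(rows)
        assert 0.97 <= lam["g1"] <= 1.03

    def test_deflation_also_applied(self):
        rng = np.random.default_rng(2)
        chi2 = 0.5 * rng.chisquare(1, 20_000)
        rows = pd.DataFrame({"effect_type": "g1", "chi2": chi2,
                             "p": stats.chi2.sf(chi2, 1)})
        out, lam = genomic_control(rows)
        assert lam["g1"] < 1
        adj = out["p_gc"].to_numpy()
        assert abs(np.median(stats.chi2.isf(adj, 1)) -
                   bogwas.CHI2_MEDIAN_1DF) < 0.05


class TestFdr:
    def test_hand_stepup(self):
        rows = pd.DataFrame({"effect_type": "g1",
                             "p_gc": [.01, .02, .03, .04]})
        out = fdr_tiers(rows)
        np.testing.assert_allclose(out["q"], .04)
        assert set(out["tier"]) == {"FDR5"}

    def test_single_p(self):
        out = fdr_tiers(pd.DataFrame({"effect_type": "g1", "p_gc": [0.2]}))
        assert out["q"].iloc[0] == 0.2
        assert out["tier"].iloc[0] == "FDR20"

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(0)
        rows = pd.DataFrame({"effect_type": "g1", "p_gc": rng.random(500)})
        out = fdr_tiers(rows).sort_values("p_gc")
        assert out["q"].is_monotonic_increasing

    def test_per_effect_separation(self):
        rows = pd.DataFrame({"effect_type": ["g1"] * 3 + ["g2"] * 3,
                             "p_gc": [.001, .5, .9, .001, .5, .9]})
        out = fdr_tiers(rows)
        g1 = out[out["effect_type"] == "g1"]["q"].to_numpy()
        g2 = out[out["effect_type"] == "g2"]["q"].to_numpy()
        np.testing.assert_allclose(g1, g2)


class TestRegions:
    def _rows(self, pos, est, q, eff="g1", chrom=5):
        return pd.DataFrame({"effect_type": eff, "chrom": chrom,
                             "pos_bp": pos, "estimate": est, "q": q,
                             "snp": np.arange(len(pos))})

    def test_single_snp_homozygote_difference(self):
        rows = self._rows([44_630_000], [0.425], [0.01])
        reg = summarize_regions(rows, mean_yield=7.22)
        assert len(reg) == 1
        assert np.isclose(reg["hom_diff_mean"].iloc[0], 0.85)
        assert np.isclose(reg["pct_mean_yield"].iloc[0], 11.77, atol=0.01)
        assert reg["favored_origin"].iloc[0] == "INDICUS"

    def test_gap_splits_regions(self):
        rows = self._rows([1_000_000, 9_000_000], [0.3, -0.3], [0.01, 0.01])
        reg = summarize_regions(rows, max_gap_bp=2_000_000)
        assert len(reg) == 2
        assert set(reg["favored_origin"]) == {"INDICUS", "EXOTIC"}

    def test_empty_significant_set(self):
        reg = summarize_regions(self._rows([1], [0.3], [0.5]))
        assert len(reg) == 0


class TestPowerArithmetic:
    def test_values(self):
        assert rel_power(0.5) == 1.0
        assert np.isclose(rel_power(0.36), 0.9216)
        assert np.isclose(rel_power(0.25), 0.75)

    def test_equivalent_sizes(self):
        assert equivalent_n(0.36, 5000) == 1800
        assert equivalent_n(0.64, 5000) == 3200
        assert equivalent_n(0.49, 5000) == 2450
        assert equivalent_n(0.15, 5000) == 750
        assert equivalent_n(1.0, 777, round_to=0) == 777

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            rel_power(0.0)
        with pytest.raises(ValueError):
            rel_power(1.0)
        with pytest.raises(ValueError):
            equivalent_n(1.2, 100)
        with pytest.raises(ValueError):
            equivalent_n(0.5, 0)
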
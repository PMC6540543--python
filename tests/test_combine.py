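"""Oracle checks for the four p-value combination methods, DL pooling and BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from gbmeta.combine import (
    PValueMatrix,
    aw_min_tail,
    bh_fdr,
    combine_aw,
    combine_fisher,
    combine_maxp,
    combine_rop,
    detection_competency,
    meta_table,
    pool_random_effects,
)


def _matrix(pr, pl=None):
    pr = np.atleast_2d(np.asarray(pr, dtype=float))
    if pl is None:
        pl = np.clip(1.0 - pr, 1e-12, 1.0)
    genes = pd.Index([f"G{i}" for i in range(pr.shape[0])])
    return PValueMatrix(genes, list(range(pr.shape[1])), pr, np.atleast_2d(pl))


def _uniform_matrix(G, K, seed=0):
    rng = np.random.default_rng(seed)
    pr = rng.random((G, K))
    return _matrix(pr)


def chi2_sf_4df(x):
    """Independent closed-form chi-square upper tail for 4 df."""
    return np.exp(-x / 2) * (1 + x / 2)


class TestFisher:
    def test_all_ones_give_p_one(self):
        res = combine_fisher(_matrix([[1.0, 1.0]], [[1.0, 1.0]]))
        assert res["statistic"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_hand_example_against_closed_form_chi2(self):
        # K = 2, right-sided p = (0.05, 0.05): S = -2*2*ln 0.05 = 11.983;
        # side p from the closed-form chi2(4) tail; gene p doubles it
        res = combine_fisher(_matrix([[0.05, 0.05]], [[0.95, 0.95]]))
        s = -2 * 2 * np.log(0.05)
        assert res["statistic"].iloc[0] == pytest.approx(s, abs=1e-3)
        assert s == pytest.approx(11.983, abs=1e-3)
        assert res["p_right_comb"].iloc[0] == pytest.approx(chi2_sf_4df(s), rel=1e-10)
        assert res["p"].iloc[0] == pytest.approx(2 * chi2_sf_4df(s), rel=1e-10)
        assert res["direction"].iloc[0] == "up"

    def test_zero_input_p_rejected(self):
        with pytest.raises(ValueError):
            _matrix([[0.0, 0.5]])

    def test_null_tail_calibration(self):
        P = _uniform_matrix(5000, 6, seed=3)
        res = combine_fisher(P)
        frac = (res["p"] < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 5000)

    def test_permutation_reference_agrees_with_chi2(self):
        P = _uniform_matrix(500, 4, seed=5)
        ana = combine_fisher(P, reference="chi2")
        per = combine_fisher(P, reference="permutation", B_null=4000, seed=1)
        # empirical reference converges to the analytic chi2(2K) tail
        mask = ana["p_right_comb"] > 0.01  # inside empirical resolution
        err = np.abs(ana["p_right_comb"][mask] - per["p_right_comb"][mask])
        assert err.median() < 0.02


class TestMaxP:
    def test_statistic_and_p(self):
        res = combine_maxp(_matrix([[0.5, 0.3, 0.2]]))
        assert res["statistic"].iloc[0] == 0.5
        assert res["p_right_comb"].iloc[0] == pytest.approx(0.125)

    def test_all_ones(self):
        res = combine_maxp(_matrix([[1.0, 1.0, 1.0]], [[1.0, 1.0, 1.0]]))
        assert res["p"].iloc[0] == 1.0

    def test_single_study_identity(self):
        res = combine_maxp(_matrix([[0.3]]))
        assert res["p_right_comb"].iloc[0] == pytest.approx(0.3)

    def test_against_monte_carlo_of_max_of_uniforms(self, rng):
        K = 4
        sims = rng.random((200_000, K)).max(axis=1)
        for m in (0.3, 0.6, 0.9):
            res = combine_maxp(_matrix([[m] * K]))
            mc = (sims <= m).mean()
            assert res["p_right_comb"].iloc[0] == pytest.approx(mc, abs=0.005)


class TestRoP:
    def test_reduces_to_maxp_at_r_equals_K(self):
        P = _uniform_matrix(300, 5, seed=9)
        rop = combine_rop(P, r=5)
        maxp = combine_maxp(P)
        pd.testing.assert_frame_equal(rop, maxp)

    def test_beta_symmetry_at_half(self):
        res = combine_rop(_matrix([[0.5, 0.5, 0.5]]), r=2)
        assert res["p_right_comb"].iloc[0] == pytest.approx(0.5)

    def test_r_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            combine_rop(_uniform_matrix(5, 3), r=4)

    def test_against_order_statistic_simulation(self, rng):
        K, r = 5, 2
        sims = np.sort(rng.random((200_000, K)), axis=1)[:, r - 1]
        for m in (0.1, 0.4, 0.7):
            res = combine_rop(_matrix([[m] * K]), r=r)
            mc = (sims <= m).mean()
            assert res["p_right_comb"].iloc[0] == pytest.approx(mc, abs=0.005)


class TestAW:
    def test_single_extreme_study_selected(self):
        pr = [[1e-8, 0.9, 0.8, 0.95]]
        _, w = aw_min_tail(np.array(pr))
        assert w.tolist() == [[1, 0, 0, 0]]

    def test_equal_ps_allow_full_weight(self):
        stat, w = aw_min_tail(np.full((1, 4), 0.01))
        # identical evidence in every study: the full-weight Fisher stat is
        # the strongest prefix
        assert w.sum() == 4
        assert stat[0] == pytest.approx(stats.chi2.sf(-8 * np.log(0.01), 8))

    def test_prefix_reduction_matches_brute_force_over_all_subsets(self, rng):
        K = 4
        p = rng.random((60, K))
        stat, _ = aw_min_tail(p)
        # brute force over all 2^K - 1 nonempty 0/1 weight vectors
        for i in range(p.shape[0]):
            best = np.inf
            for mask in range(1, 2**K):
                idx = [k for k in range(K) if mask >> k & 1]
                s = -2 * np.log(p[i, idx]).sum()
                best = min(best, stats.chi2.sf(s, 2 * len(idx)))
            assert stat[i] == pytest.approx(best, rel=1e-12)

    def test_null_self_calibration(self):
        P = _uniform_matrix(4000, 6, seed=11)
        res = combine_aw(P, B_aw=4000, seed=2)
        d = stats.kstest(res["p_right_comb"], "uniform").statistic
        assert d < 0.05

    def test_invalid_b_rejected(self):
        with pytest.raises(ValueError):
            combine_aw(_uniform_matrix(5, 3), B_aw=0)


class TestPoolRandomEffects:
    def test_homogeneous_studies(self):
        res = pool_random_effects([[0.7] * 4], [[0.2] * 4])
        assert res["Q_het"].iloc[0] == pytest.approx(0.0)
        assert res["tau2"].iloc[0] == 0.0
        assert res["mu"].iloc[0] == pytest.approx(0.7)
        assert res["se"].iloc[0] == pytest.approx(np.sqrt(0.2 / 4))

    def test_hand_evaluated_two_studies(self):
        # g = (0.5, 1.5), v = (0.1, 0.1): Q = 5, tau2 = 0.4, mu = 1, se = 0.5
        res = pool_random_effects([[0.5, 1.5]], [[0.1, 0.1]])
        assert res["Q_het"].iloc[0] == pytest.approx(5.0)
        assert res["tau2"].iloc[0] == pytest.approx(0.4)
        assert res["mu"].iloc[0] == pytest.approx(1.0)
        assert res["se"].iloc[0] == pytest.approx(0.5)
        assert res["z"].iloc[0] == pytest.approx(2.0)

    def test_parameter_recovery(self, rng):
        # true mu = 0.8, tau = 0.2, K = 50: DL recovers both moments
        K, reps = 50, 500
        v = np.full((reps, K), 0.04)
        theta = 0.8 + rng.normal(0, 0.2, size=(reps, K))
        g = theta + rng.normal(0, np.sqrt(0.04), size=(reps, K))
        res = pool_random_effects(g, v)
        assert abs(res["mu"].mean() - 0.8) < 0.05
        assert abs(res["tau2"].mean() - 0.04) < 0.02

    def test_nan_studies_dropped_per_gene(self):
        g = [[0.5, np.nan, 1.5]]
        v = [[0.1, np.nan, 0.1]]
        res = pool_random_effects(g, v)
        assert res["K"].iloc[0] == 2
        assert res["mu"].iloc[0] == pytest.approx(1.0)


class TestBH:
    def test_single_p(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_hand_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_step_up_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(int(rng.integers(1, 40)))
        q = bh_fdr(p)
        # brute-force step-up: q_(i) = min_{j >= i} G * p_(j) / j, capped at 1
        order = np.argsort(p)
        G = len(p)
        q_oracle = np.empty(G)
        running = np.inf
        for rank in range(G, 0, -1):
            running = min(running, G * p[order[rank - 1]] / rank)
            q_oracle[order[rank - 1]] = min(1.0, running)
        assert np.allclose(q, q_oracle)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([])


class TestSymmetryAndCompetency:
    def test_side_flip_reverses_directions_keeps_p(self):
        P = _uniform_matrix(200, 4, seed=13)
        for combiner in (combine_fisher, combine_maxp, lambda m: combine_rop(m, 2)):
            fwd = combiner(P)
            rev = combiner(P.flipped())
            assert np.allclose(fwd["p"], rev["p"])
            flipped = np.where(fwd["direction"] == "up", "down", "up")
            assert (rev["direction"] == flipped).all()

    def test_detection_competency_counts(self, rng):
        results = {}
        for k in range(3):
            genes = pd.Index([f"G{i}" for i in range(200)])
            df = pd.DataFrame(index=genes)
            pr = rng.random(200)
            df["p_right"] = pr
            df["p_left"] = np.clip(1 - pr, 1e-12, 1)
            df["g"] = rng.normal(size=200)
            df["v_g"] = 0.1
            results[f"S{k}"] = df
        meta = meta_table(results, B_aw=200, seed=1)
        grid = [0.0, 0.01, 0.05, 0.2, 1.0]
        comp = detection_competency(meta, grid)
        assert (comp[0.0] == 0).all()
        # counts non-decreasing in the threshold
        assert (comp.to_numpy()[:, 1:] >= comp.to_numpy()[:, :-1]).all()
        # and equal to direct filtering of the table
        for m in ("fisher", "maxp", "rop", "aw"):
            assert comp.loc[m, 0.05] == (meta[f"{m}_q"] < 0.05).sum()
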
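"""Survival, ROC, Kruskal-Wallis and over-representation statistics against
independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from gbmeta.downstream import (
    dichotomize_by_median,
    hypergeometric_ora,
    km_estimate,
    kruskal_wallis,
    logrank_test,
    roc_auc,
    survival_analysis,
)
from gbmeta.io import GeneSetCollection


def km_oracle(times, events):
    """Hand product-limit: multiply (1 - d_i/n_i) over event times."""
    order = np.argsort(times)
    times, events = np.asarray(times, float)[order], np.asarray(events)[order]
    out = {}
    s = 1.0
    at_risk = len(times)
    for t in np.unique(times):
        d = int(((times == t) & (events == 1)).sum())
        c = int(((times == t) & (events == 0)).sum())
        if d:
            s *= 1 - d / at_risk
        out[t] = s
        at_risk -= d + c
    return out


def logrank_oracle(ta, ea, tb, eb):
    """O/E/V tabulation at each distinct event time."""
    ta, tb = np.asarray(ta, float), np.asarray(tb, float)
    ea, eb = np.asarray(ea, int), np.asarray(eb, int)
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    grp = np.concatenate([np.zeros(len(ta)), np.ones(len(tb))])
    O_minus_E = 0.0
    V = 0.0
    for t in np.unique(all_t[all_e == 1]):
        at_risk = all_t >= t
        n = at_risk.sum()
        n1 = (at_risk & (grp == 0)).sum()
        d = ((all_t == t) & (all_e == 1)).sum()
        d1 = ((all_t == t) & (all_e == 1) & (grp == 0)).sum()
        O_minus_E += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return O_minus_E**2 / V


class TestDichotomize:
    def test_even_split(self):
        g = dichotomize_by_median([1, 2, 3, 4])
        assert list(g) == ["low", "low", "high", "high"]

    def test_median_value_goes_low(self):
        g = dichotomize_by_median([1, 2, 3])
        assert list(g) == ["low", "low", "high"]

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_by_median([2, 2, 2, 2])

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(3, 30)))
            g = dichotomize_by_median(x)
            med = np.median(x)
            assert ((x <= med) == (g == "low")).all()


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        surv = dict(zip(km["time"], km["survival"]))
        assert surv[1] == pytest.approx(2 / 3)
        assert surv[2] == pytest.approx(1 / 3)
        assert surv[3] == pytest.approx(0.0)

    def test_all_censored_flat_curve(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert np.allclose(km["survival"], 1.0)

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, size=40)
        km = km_estimate(t, np.ones(40, int))
        for ti, si in zip(km["time"], km["survival"]):
            if ti == 0:
                continue
            assert si == pytest.approx((t > ti).mean())

    def test_matches_oracle_with_censoring(self, rng):
        t = np.round(rng.exponential(5, size=60), 1) + 0.1
        e = (rng.random(60) < 0.7).astype(int)
        km = km_estimate(t, e)
        oracle = km_oracle(t, e)
        for ti, si in zip(km["time"], km["survival"]):
            if ti in oracle:
                assert si == pytest.approx(oracle[ti])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 0, 1]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_oev_oracle(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            ta = np.ceil(r.exponential(5, 25) * 10) / 10
            tb = np.ceil(r.exponential(8, 30) * 10) / 10
            ea = (r.random(25) < 0.8).astype(int)
            eb = (r.random(30) < 0.8).astype(int)
            chi2, _ = logrank_test(ta, ea, tb, eb)
            assert chi2 == pytest.approx(logrank_oracle(ta, ea, tb, eb), rel=1e-6)

    def test_group_relabelling_invariance(self, rng):
        ta, tb = rng.exponential(5, 20), rng.exponential(5, 20)
        ea = eb = np.ones(20, int)
        a = logrank_test(ta, ea, tb, eb)
        b = logrank_test(tb, eb, ta, ea)
        assert a[0] == pytest.approx(b[0])

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [0, 0], [3, 4], [0, 0])

    def test_exclusion_mask_respected(self, rng):
        tab = pd.DataFrame(
            {
                "time": rng.exponential(10, 40),
                "event": np.ones(40, int),
                "expression": rng.normal(size=40),
                "exclude_flag": [True] * 10 + [False] * 30,
            }
        )
        res = survival_analysis(tab, apply_exclusions=True)
        assert res["n_low"] + res["n_high"] == 30


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], list("nnnppp"), positive_label="p")
        assert res.auc == 1.0
        assert res.curve.iloc[0].tolist() == [0.0, 0.0]
        assert res.curve.iloc[-1].tolist() == [1.0, 1.0]

    def test_matches_all_pairs_oracle(self, rng):
        scores = rng.integers(0, 10, size=60).astype(float)  # force ties
        labels = np.where(rng.random(60) < 0.4, "p", "n")
        if len(set(labels)) < 2:
            labels[0], labels[1] = "p", "n"
        res = roc_auc(scores, labels, positive_label="p")
        pos = scores[labels == "p"]
        neg = scores[labels == "n"]
        wins = sum((pi > ni) + 0.5 * (pi == ni) for pi in pos for ni in neg)
        assert res.auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_antisymmetry_under_score_negation(self, rng):
        scores = rng.normal(size=50)
        labels = np.where(rng.random(50) < 0.5, "p", "n")
        a = roc_auc(scores, labels, positive_label="p").auc
        b = roc_auc(-scores, labels, positive_label="p").auc
        assert a == pytest.approx(1 - b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], ["p", "p"], positive_label="p")

    def test_curve_monotone(self, rng):
        scores = rng.normal(size=80)
        labels = np.where(rng.random(80) < 0.5, "p", "n")
        res = roc_auc(scores, labels, positive_label="p")
        assert (np.diff(res.curve["fpr"]) >= 0).all()
        assert (np.diff(res.curve["tpr"]) >= 0).all()


class TestKruskalWallis:
    def test_hand_rank_formula(self):
        # groups (1,2,3) vs (4,5,6): ranks 1..6, H = 12/(6*7)*(36/3+225/3)-21
        h, _ = kruskal_wallis([1, 2, 3], [4, 5, 6])
        assert h == pytest.approx(12 / 42 * (36 / 3 + 225 / 3) - 21)

    def test_null_calibration(self, rng):
        reps, hits = 300, 0
        for _ in range(reps):
            g = [rng.normal(size=12) for _ in range(3)]
            _, p = kruskal_wallis(*g)
            hits += p < 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(hits / reps - 0.05) < 3 * se + 0.01

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 1.0], [1.0, 1.0])


class TestOra:
    def _collection(self, sets):
        return GeneSetCollection(
            sets=sets, descriptions={k: "" for k in sets}
        )

    def test_exact_enumeration_oracle(self):
        # background 20, set 5, query 6, overlap 4
        background = [f"G{i}" for i in range(20)]
        gene_set = set(background[:5])
        query = set(background[:4]) | set(background[10:12])
        coll = self._collection({"S": gene_set})
        res = hypergeometric_ora(query, coll, background)
        p_oracle = sum(
            comb(5, k) * comb(15, 6 - k) for k in range(4, 6)
        ) / comb(20, 6)
        assert res.loc["S", "overlap"] == 4
        assert res.loc["S", "p"] == pytest.approx(p_oracle, rel=1e-10)

    def test_full_overlap_boundary(self):
        bg = [f"G{i}" for i in range(10)]
        coll = self._collection({"S": set(bg)})
        res = hypergeometric_ora(set(bg), coll, bg)
        assert res.loc["S", "p"] == pytest.approx(1.0)

    def test_zero_overlap_near_one(self):
        bg = [f"G{i}" for i in range(100)]
        coll = self._collection({"S": set(bg[:5])})
        res = hypergeometric_ora(set(bg[50:53]), coll, bg)
        assert res.loc["S", "p"] > 0.8

    def test_monotone_in_overlap(self):
        bg = [f"G{i}" for i in range(40)]
        gene_set = set(bg[:10])
        ps = []
        for k in range(1, 6):
            query = set(bg[:k]) | set(bg[20 : 20 + (6 - k)])
            coll = self._collection({"S": gene_set})
            ps.append(hypergeometric_ora(query, coll, bg).loc["S", "p"])
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_ora({"X"}, self._collection({"S": {"A"}}), {"A", "B"})
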
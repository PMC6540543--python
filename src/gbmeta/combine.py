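"""Cross-study evidence combination.

Two complementary meta-analysis routes over K studies:

* p-value combination of one-sided per-study p-values — Fisher's sum of
  logs (-2*sum(ln p) ~ chi2(2K) under the null), maxP (max of K uniforms),
  roP (r-th order statistic, Beta(r, K-r+1)), and the adaptively-weighted
  (AW) statistic: the best chi-square tail value over sorted-prefix subsets
  of studies, calibrated by permutation because a minimum of dependent tail
  values is not uniform;
* random-effects inverse-variance pooling of Hedges' g with the
  DerSimonian-Laird moment estimator of the between-study variance tau^2,
  significance from the z statistic mu/se.

Each combiner works on the right- and left-sided branches separately and
wraps up two-sidedly as p = min(1, 2*min(p_right_combined, p_left_combined))
with the winning side giving the direction (up = over-expressed in cases).
Multiplicity is handled by Benjamini-Hochberg within each comparison's gene
universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

P_COMBINATION_METHODS = ("fisher", "maxp", "rop", "aw")


@dataclass
class PValueMatrix:
    """Genes x studies one-sided p-values on the shared gene universe."""

    genes: pd.Index
    studies: list
    p_right: np.ndarray
    p_left: np.ndarray

    def __post_init__(self) -> None:
        for name, arr in (("p_right", self.p_right), ("p_left", self.p_left)):
            if arr.shape != (len(self.genes), len(self.studies)):
                raise ValueError(f"{name} shape mismatch")
            if np.any(arr <= 0) or np.any(arr > 1):
                raise ValueError(
                    f"{name} must lie in (0, 1]; permutation p-values with the "
                    "add-one correction never reach 0"
                )

    @property
    def K(self) -> int:
        return len(self.studies)

    def flipped(self) -> "PValueMatrix":
        return PValueMatrix(self.genes, self.studies, self.p_left, self.p_right)


def build_pvalue_matrix(results: dict) -> PValueMatrix:
    """Assemble per-study DE results (study_id -> DataFrame) on the
    intersection gene universe."""
    if not results:
        raise ValueError("no study results")
    studies = list(results)
    genes = None
    for df in results.values():
        idx = df.index
        genes = idx if genes is None else genes.intersection(idx)
    genes = genes.sort_values()
    if genes.empty:
        raise ValueError("empty gene intersection across study results")
    p_right = np.column_stack([results[s].loc[genes, "p_right"] for s in studies])
    p_left = np.column_stack([results[s].loc[genes, "p_left"] for s in studies])
    return PValueMatrix(genes, studies, p_right, p_left)


def _wrap_two_sided(
    genes: pd.Index, stat_r, p_r, stat_l, p_l, extra_r=None, extra_l=None
) -> pd.DataFrame:
    right_wins = p_r <= p_l
    out = pd.DataFrame(
        {
            "statistic": np.where(right_wins, stat_r, stat_l),
            "p": np.minimum(1.0, 2.0 * np.minimum(p_r, p_l)),
            "direction": np.where(right_wins, "up", "down"),
            # one-sided combined branches (exactly uniform under the null;
            # the two-sided wrap above is conservative away from the tails)
            "p_right_comb": p_r,
            "p_left_comb": p_l,
        },
        index=genes,
    )
    if extra_r is not None:
        out["weights"] = [
            extra_r[i] if win else extra_l[i] for i, win in enumerate(right_wins)
        ]
    return out


def _fisher_stat(p: np.ndarray) -> np.ndarray:
    return -2.0 * np.log(p).sum(axis=1)


def combine_fisher(
    P: PValueMatrix,
    reference: str = "chi2",
    B_null: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Fisher's sum of logs per side; side p from chi2(2K) (``reference=
    "chi2"``) or from an empirical null of B_null uniform matrices
    (``reference="permutation"``)."""
    s_r, s_l = _fisher_stat(P.p_right), _fisher_stat(P.p_left)
    if reference == "chi2":
        p_r = stats.chi2.sf(s_r, 2 * P.K)
        p_l = stats.chi2.sf(s_l, 2 * P.K)
    elif reference == "permutation":
        rng = np.random.default_rng(seed)
        null = np.sort(_fisher_stat(rng.random((B_null, P.K))))
        p_r = (1.0 + B_null - np.searchsorted(null, s_r, side="right")) / (1.0 + B_null)
        p_l = (1.0 + B_null - np.searchsorted(null, s_l, side="right")) / (1.0 + B_null)
    else:
        raise ValueError(f"unknown Fisher reference {reference!r}")
    return _wrap_two_sided(P.genes, s_r, p_r, s_l, p_l)


def combine_maxp(P: PValueMatrix) -> pd.DataFrame:
    """maxP: statistic = max_k p_k per side; side p = statistic**K."""
    s_r = P.p_right.max(axis=1)
    s_l = P.p_left.max(axis=1)
    return _wrap_two_sided(P.genes, s_r, s_r**P.K, s_l, s_l**P.K)


def combine_rop(P: PValueMatrix, r: int) -> pd.DataFrame:
    """roP: statistic = r-th smallest p per side; side p from Beta(r, K-r+1),
    the null distribution of the r-th order statistic of K uniforms."""
    if not 1 <= r <= P.K:
        raise ValueError(f"order index r={r} outside 1..{P.K}")
    s_r = np.sort(P.p_right, axis=1)[:, r - 1]
    s_l = np.sort(P.p_left, axis=1)[:, r - 1]
    p_r = stats.beta.cdf(s_r, r, P.K - r + 1)
    p_l = stats.beta.cdf(s_l, r, P.K - r + 1)
    return _wrap_two_sided(P.genes, s_r, p_r, s_l, p_l)


def default_rop_order(K: int) -> int:
    return int(np.ceil(K / 2))


def aw_min_tail(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """AW statistic for one side: for each row, the minimum over prefix
    sizes j of the chi2(2j) tail value of the Fisher statistic on the j
    smallest p-values.  Returns (statistic, 0/1 weight matrix) where the
    weight row marks the studies in the minimizing prefix.

    Only sorted prefixes need be searched: among 0/1 weight vectors of a
    fixed size j, the Fisher statistic is maximized (tail value minimized)
    by taking the j smallest p-values.
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    G, K = p.shape
    order = np.argsort(p, axis=1)
    p_sorted = np.take_along_axis(p, order, axis=1)
    s_prefix = -2.0 * np.cumsum(np.log(p_sorted), axis=1)
    tails = stats.chi2.sf(s_prefix, 2 * np.arange(1, K + 1))
    j_star = np.argmin(tails, axis=1)
    stat = tails[np.arange(G), j_star]
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(K)[None, :].repeat(G, axis=0), axis=1)
    weights = (ranks <= j_star[:, None]).astype(int)
    return stat, weights


def combine_aw(P: PValueMatrix, B_aw: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Adaptively-weighted combination with permutation calibration.

    The minimum tail value over prefixes is stochastically smaller than
    uniform, so its p-value is read off an empirical null built from B_aw
    simulated uniform p-matrices of the same K.
    """
    if B_aw < 1:
        raise ValueError("B_aw must be >= 1")
    s_r, w_r = aw_min_tail(P.p_right)
    s_l, w_l = aw_min_tail(P.p_left)
    rng = np.random.default_rng(seed)
    null_stat, _ = aw_min_tail(rng.random((B_aw, P.K)))
    null_sorted = np.sort(null_stat)
    # small statistic = strong evidence; p = fraction of null <= observed
    p_r = (1.0 + np.searchsorted(null_sorted, s_r, side="right")) / (1.0 + B_aw)
    p_l = (1.0 + np.searchsorted(null_sorted, s_l, side="right")) / (1.0 + B_aw)
    return _wrap_two_sided(
        P.genes, s_r, p_r, s_l, p_l, extra_r=list(w_r), extra_l=list(w_l)
    )


def pool_random_effects(g: np.ndarray, v: np.ndarray, genes=None) -> pd.DataFrame:
    """DerSimonian-Laird random-effects pooling of per-study effects.

    Per gene: fixed-effect weights w = 1/v give the heterogeneity statistic
    Q = sum w (g - g_FE)^2; tau2 = max(0, (Q - (K-1)) / (sum w - sum w^2 /
    sum w)); random-effects weights w* = 1/(v + tau2) give mu, se =
    1/sqrt(sum w*), z = mu/se and a two-sided normal p.  Studies with NaN
    effects (zero pooled SD upstream) are dropped per gene; genes with
    fewer than 2 remaining studies get NaN.
    """
    g = np.atleast_2d(np.asarray(g, dtype=float))
    v = np.atleast_2d(np.asarray(v, dtype=float))
    if g.shape != v.shape:
        raise ValueError("g and v shapes differ")
    if np.any(v[~np.isnan(v)] <= 0):
        raise ValueError("all effect variances must be > 0")
    ok = ~(np.isnan(g) | np.isnan(v))
    k_eff = ok.sum(axis=1)
    w = np.where(ok, 1.0 / v, 0.0)
    sw = w.sum(axis=1)
    g0 = np.where(ok, g, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        g_fe = (w * g0).sum(axis=1) / sw
        Q = (w * (g0 - g_fe[:, None]) ** 2 * ok).sum(axis=1)
        denom = sw - (w**2).sum(axis=1) / sw
        tau2 = np.maximum(0.0, (Q - (k_eff - 1)) / denom)
        w_star = np.where(ok, 1.0 / (v + tau2[:, None]), 0.0)
        sw_star = w_star.sum(axis=1)
        mu = (w_star * g0).sum(axis=1) / sw_star
        se = 1.0 / np.sqrt(sw_star)
        z = mu / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {"mu": mu, "se": se, "z": z, "p": p, "tau2": tau2, "Q_het": Q, "K": k_eff},
        index=genes if genes is not None else pd.RangeIndex(g.shape[0]),
    )
    out.loc[k_eff < 2, ["mu", "se", "z", "p", "tau2", "Q_het"]] = np.nan
    return out


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(np.isnan(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def meta_table(
    results: dict,
    methods: tuple = P_COMBINATION_METHODS,
    rop_r: int | None = None,
    B_aw: int = 1000,
    fisher_reference: str = "chi2",
    seed: int = 0,
) -> pd.DataFrame:
    """Full per-gene meta-analysis table over one comparison.

    Columns per p-combination method m: ``{m}_stat``, ``{m}_p``, ``{m}_q``,
    ``{m}_direction`` (plus ``aw_weights``); random-effects columns: mu, se,
    z, p_rem, q_rem, tau2, Q_het, rem_direction.
    """
    P = build_pvalue_matrix(results)
    out = pd.DataFrame(index=P.genes)
    for m in methods:
        if m == "fisher":
            res = combine_fisher(P, reference=fisher_reference, seed=seed)
        elif m == "maxp":
            res = combine_maxp(P)
        elif m == "rop":
            res = combine_rop(P, rop_r if rop_r is not None else default_rop_order(P.K))
        elif m == "aw":
            res = combine_aw(P, B_aw=B_aw, seed=seed)
        else:
            raise ValueError(f"unknown combination method {m!r}")
        out[f"{m}_stat"] = res["statistic"]
        out[f"{m}_p"] = res["p"]
        out[f"{m}_q"] = bh_fdr(res["p"])
        out[f"{m}_direction"] = res["direction"]
        if "weights" in res:
            out[f"{m}_weights"] = [
                ",".join(map(str, w)) for w in res["weights"]
            ]
    g = np.column_stack([results[s].loc[P.genes, "g"] for s in P.studies])
    v = np.column_stack([results[s].loc[P.genes, "v_g"] for s in P.studies])
    rem = pool_random_effects(g, v, genes=P.genes)
    out[["mu", "se", "z", "p_rem", "tau2", "Q_het"]] = rem[
        ["mu", "se", "z", "p", "tau2", "Q_het"]
    ]
    valid = out["p_rem"].notna()
    out["q_rem"] = np.nan
    out.loc[valid, "q_rem"] = bh_fdr(out.loc[valid, "p_rem"])
    out["rem_direction"] = np.where(out["mu"] > 0, "up", "down")
    return out


def detection_competency(
    meta: pd.DataFrame,
    thresholds,
    methods: tuple = P_COMBINATION_METHODS,
) -> pd.DataFrame:
    """DEG counts per combination method over an FDR threshold grid —
    the curves used to compare methods' detection competency."""
    thresholds = np.asarray(sorted(thresholds), dtype=float)
    rows = {}
    for m in methods:
        col = f"{m}_q"
        if col not in meta.columns:
            raise ValueError(f"method {m!r} missing from meta table")
        q = meta[col].to_numpy()
        rows[m] = [(q < t).sum() for t in thresholds]
    return pd.DataFrame(rows, index=pd.Index(thresholds, name="fdr_threshold")).T
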
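"""Downstream validation statistics for selected biomarker genes.

Median-dichotomized Kaplan-Meier survival with the two-group log-rank test,
ROC/AUC for diagnostic discrimination, the Kruskal-Wallis H test for
multi-class expression differences, and a local hypergeometric
over-representation analysis (ORA) against a gene-set collection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from sklearn.metrics import roc_curve

from .combine import bh_fdr
from .io import GeneSetCollection


def dichotomize_by_median(expression) -> np.ndarray:
    """Split patients at the median expression: values <= median -> "low",
    values > median -> "high".  The median-valued patient goes to the low
    group (explicit tie convention)."""
    x = np.asarray(expression, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 patients to dichotomize")
    med = np.median(x)
    groups = np.where(x <= med, "low", "high")
    if (groups == "high").sum() == 0:
        raise ValueError("all values at or below the median; high group empty")
    return groups


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) survival estimate.

    Returns a DataFrame with columns ``time`` and ``survival`` — the step
    function evaluated at the distinct observed times (right-continuous,
    starting from S(0) = 1).  Censored observations (event = 0) leave the
    curve unchanged but shrink the risk set.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if np.any(times <= 0):
        raise ValueError("survival times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
    )


def logrank_test(
    times_a, events_a, times_b, events_b
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p) with p from chi2(1)."""
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea, eb = np.asarray(events_a, int), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group; log-rank undefined")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def survival_analysis(
    table: pd.DataFrame, apply_exclusions: bool = False
) -> dict:
    """Median-dichotomized survival comparison on a SurvivalTable.

    ``table`` needs columns time, event, expression and optionally
    exclude_flag (e.g. G-CIMP-positive patients); with
    ``apply_exclusions=True`` flagged patients are removed first, mirroring
    a sensitivity analysis that drops a better-prognosis molecular subgroup.
    """
    df = table
    if apply_exclusions and "exclude_flag" in df.columns:
        df = df[~df["exclude_flag"].astype(bool)]
    if len(df) < 4:
        raise ValueError("too few patients for a two-group survival comparison")
    groups = dichotomize_by_median(df["expression"])
    low, high = df[groups == "low"], df[groups == "high"]
    chi2, p = logrank_test(low["time"], low["event"], high["time"], high["event"])
    return {
        "n_low": int(len(low)),
        "n_high": int(len(high)),
        "chi2": chi2,
        "p": p,
        "km_low": km_estimate(low["time"], low["event"]),
        "km_high": km_estimate(high["time"], high["event"]),
    }


@dataclass
class ROCResult:
    auc: float
    curve: pd.DataFrame  # columns fpr, tpr
    positive_label: str


def roc_auc(scores, labels, positive_label) -> ROCResult:
    """ROC curve and AUC for a diagnostic score.

    The AUC equals the Mann-Whitney probability that a random positive
    scores above a random negative, ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive_label
    if pos.all() or not pos.any():
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(pos.astype(int), scores)
    # AUC via the rank-sum form (handles ties exactly as probability 1/2)
    n1, n0 = pos.sum(), (~pos).sum()
    ranks = stats.rankdata(scores)
    auc = (ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return ROCResult(auc=float(auc), curve=curve, positive_label=str(positive_label))


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H test across >= 2 groups; returns (H, p)."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        raise ValueError("all values identical; H undefined")
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def hypergeometric_ora(
    query, collection: GeneSetCollection, background
) -> pd.DataFrame:
    """Over-representation of a query gene set in each collection set.

    For each set, p is the upper tail of the hypergeometric distribution
    for the observed overlap given (|background|, |set ∩ background|,
    |query|); q is BH across sets; ``significant`` flags q < 0.05.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background universe")
    query = set(query)
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    rows = []
    N, n = len(background), len(query)
    for name, members in collection:
        in_bg = members & background
        K = len(in_bg)
        k = len(in_bg & query)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "set": name,
                "description": collection.descriptions.get(name, ""),
                "set_size": K,
                "overlap": k,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = bh_fdr(out["p"])
    out["significant"] = out["q"] < 0.05
    return out.sort_values("p")
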
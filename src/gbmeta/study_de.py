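"""Per-study differential expression for one two-class contrast.

Three statistics per gene: a variance-stabilized ("modified") t with a
SAM-style fudge constant in the denominator, one-sided p-values from a
label-permutation null pooled across genes, and Hedges' g with its
sampling variance for downstream effect-size pooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionStudy


@dataclass(frozen=True)
class Contrast:
    """A case/control comparison within one study (e.g. GBM vs NG)."""

    case_class: str
    control_class: str
    case_ids: tuple
    control_ids: tuple

    def __post_init__(self) -> None:
        if len(self.case_ids) < 2 or len(self.control_ids) < 2:
            raise ValueError("need >= 2 samples on each side of the contrast")
        if set(self.case_ids) & set(self.control_ids):
            raise ValueError("case and control samples overlap")

    @property
    def label(self) -> str:
        return f"{self.case_class}_vs_{self.control_class}"

    def swapped(self) -> "Contrast":
        return Contrast(
            self.control_class, self.case_class, self.control_ids, self.case_ids
        )


def from_annotations(ann: pd.DataFrame, study_id: str, case: str, control: str) -> Contrast:
    """Build a contrast from an annotation table for one study."""
    sub = ann[ann["study_id"] == study_id]
    case_ids = tuple(sub.loc[sub["class"] == case, "sample_id"])
    control_ids = tuple(sub.loc[sub["class"] == control, "sample_id"])
    return Contrast(case, control, case_ids, control_ids)


def _group_arrays(study: ExpressionStudy, contrast: Contrast):
    missing = (set(contrast.case_ids) | set(contrast.control_ids)) - set(study.samples)
    if missing:
        raise ValueError(
            f"study {study.study_id}: contrast samples not in study: {sorted(missing)[:3]}"
        )
    x1 = study.values[list(contrast.case_ids)].to_numpy()
    x0 = study.values[list(contrast.control_ids)].to_numpy()
    return x1, x0


def _t_parts(x1: np.ndarray, x0: np.ndarray):
    """Mean difference and unstabilized denominator sp*sqrt(1/n1+1/n0)."""
    n1, n0 = x1.shape[1], x0.shape[1]
    dbar = x1.mean(axis=1) - x0.mean(axis=1)
    ss1 = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss0 = ((x0 - x0.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    sp = np.sqrt((ss1 + ss0) / (n1 + n0 - 2))
    denom = sp * np.sqrt(1.0 / n1 + 1.0 / n0)
    return dbar, sp, denom


def moderated_t(
    study: ExpressionStudy, contrast: Contrast, s0: float | str = "auto"
) -> pd.Series:
    """Fudge-constant t: (mean_case - mean_control) / (sp*sqrt(1/n1+1/n0) + s0).

    With ``s0="auto"`` the constant is the median across genes of the
    unstabilized denominator, which keeps genes with tiny pooled variance
    from dominating the ranking.  ``s0=0`` recovers the classical pooled t.
    """
    x1, x0 = _group_arrays(study, contrast)
    dbar, _, denom = _t_parts(x1, x0)
    s0_val = float(np.median(denom)) if s0 == "auto" else float(s0)
    if s0_val < 0:
        raise ValueError("s0 must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = dbar / (denom + s0_val)
    t = np.where((denom + s0_val) == 0, 0.0, t)
    return pd.Series(t, index=study.genes, name="t_mod")


def permutation_pvalues(
    study: ExpressionStudy,
    contrast: Contrast,
    B: int = 200,
    seed: int = 0,
    s0: float | str = "auto",
) -> pd.DataFrame:
    """One-sided p-values from a pooled permutation null of the modified t.

    Class labels are permuted ``B`` times; the null t statistics of all
    genes in all permutations form one pooled reference of size B*G, giving
    p-value resolution 1/(1 + B*G) with an add-one correction so p > 0:

        p_right = (1 + #{null >= t_obs}) / (1 + B*G)

    and ``p_left`` analogously with <=.  The fudge constant is fixed at its
    observed-data value across permutations.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    x1, x0 = _group_arrays(study, contrast)
    n1, n0 = x1.shape[1], x0.shape[1]
    x = np.concatenate([x1, x0], axis=1)
    g = x.shape[0]

    dbar, _, denom = _t_parts(x1, x0)
    s0_val = float(np.median(denom)) if s0 == "auto" else float(s0)
    t_obs = dbar / (denom + s0_val)

    rng = np.random.default_rng(seed)
    null = np.empty((B, g))
    for b in range(B):
        perm = rng.permutation(n1 + n0)
        p1, p0 = x[:, perm[:n1]], x[:, perm[n1:]]
        d_b, _, den_b = _t_parts(p1, p0)
        null[b] = d_b / (den_b + s0_val)
    pool = np.sort(null.ravel())
    m = pool.size
    # #{null >= t} via searchsorted on the sorted pool
    n_ge = m - np.searchsorted(pool, t_obs, side="left")
    n_le = np.searchsorted(pool, t_obs, side="right")
    p_right = (1.0 + n_ge) / (1.0 + m)
    p_left = (1.0 + n_le) / (1.0 + m)
    min_p = 1.0 / (1.0 + m)
    if min_p > 0.5:
        import warnings

        warnings.warn(
            f"permutation resolution {min_p:.3g} too coarse (B={B}, G={g})",
            stacklevel=2,
        )
    return pd.DataFrame(
        {"p_right": p_right, "p_left": p_left}, index=study.genes
    )


def hedges_g(study: ExpressionStudy, contrast: Contrast) -> pd.DataFrame:
    """Bias-corrected standardized mean difference and its variance.

    g = J * (mean_case - mean_control) / sp with J = 1 - 3/(4*(n1+n0-2) - 1);
    v_g = (n1+n0)/(n1*n0) + g^2 / (2*(n1+n0)).  Genes with zero pooled SD
    get NaN and are excluded downstream.
    """
    x1, x0 = _group_arrays(study, contrast)
    n1, n0 = x1.shape[1], x0.shape[1]
    dbar, sp, _ = _t_parts(x1, x0)
    J = 1.0 - 3.0 / (4.0 * (n1 + n0 - 2) - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = J * dbar / sp
    g = np.where(sp == 0, np.nan, g)
    v_g = (n1 + n0) / (n1 * n0) + g**2 / (2.0 * (n1 + n0))
    return pd.DataFrame({"g": g, "v_g": v_g}, index=study.genes)


def run_study_de(
    study: ExpressionStudy,
    contrast: Contrast,
    B: int = 200,
    seed: int = 0,
    s0: float | str = "auto",
) -> pd.DataFrame:
    """Full per-study result: t_mod, p_right, p_left, g, v_g, dbar, n per side.

    Genes with zero pooled variance are dropped (reported via the index
    difference from the study's gene list).
    """
    study.require_unique_genes()
    x1, x0 = _group_arrays(study, contrast)
    dbar, sp, _ = _t_parts(x1, x0)
    out = pd.DataFrame(index=pd.Index(study.genes, name="gene"))
    out["t_mod"] = moderated_t(study, contrast, s0=s0)
    out[["p_right", "p_left"]] = permutation_pvalues(
        study, contrast, B=B, seed=seed, s0=s0
    )
    out[["g", "v_g"]] = hedges_g(study, contrast)
    out["dbar"] = dbar
    out["n_case"] = x1.shape[1]
    out["n_control"] = x0.shape[1]
    return out[sp > 0]
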
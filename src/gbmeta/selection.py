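"""Directed DEG sets and the biomarker intersection cascade.

The screening logic proceeds: (1) select genes passing an FDR threshold for
a p-combination method and, separately, for the random-effects z test;
(2) intersect the two with direction agreement (dual-method overlap);
(3) confirm in an independent validation cohort (train/validate overlap);
(4) keep only genes also differential versus both other glioma subtypes
(GBM-specificity filter).  Direction agreement is enforced at every
intersection so that "consistently differentially expressed" is operational.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class DEGSet:
    """A directed gene set from one comparison.

    ``members`` maps gene symbol -> direction ("up"/"down").
    """

    comparison: str
    members: dict = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        bad = {d for d in self.members.values()} - {"up", "down"}
        if bad:
            raise ValueError(f"invalid directions {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def counts(self) -> dict:
        up = sum(1 for d in self.members.values() if d == "up")
        return {"up": up, "down": len(self.members) - up, "total": len(self.members)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": list(self.members),
                "direction": list(self.members.values()),
                "comparison": self.comparison,
                "provenance": self.provenance,
            }
        ).set_index("gene")


def select_significant(
    meta: pd.DataFrame,
    method: str,
    fdr_threshold: float,
    comparison: str = "",
) -> DEGSet:
    """Genes with q_method < threshold, direction from the winning branch.

    ``method`` is a p-combination method name ("fisher", "maxp", "rop",
    "aw") or "rem" for the random-effects z-test branch (direction =
    sign of the pooled effect).
    """
    if not 0 < fdr_threshold <= 1:
        raise ValueError("fdr_threshold must lie in (0, 1]")
    if method == "rem":
        q_col, d_col = "q_rem", "rem_direction"
    else:
        q_col, d_col = f"{method}_q", f"{method}_direction"
    if q_col not in meta.columns:
        raise ValueError(f"method {method!r} not present in meta table")
    hits = meta[meta[q_col] < fdr_threshold]
    return DEGSet(
        comparison=comparison,
        members=dict(zip(hits.index, hits[d_col])),
        provenance=f"{method}, FDR<{fdr_threshold:g}",
    )


def _directed_intersection(a: DEGSet, b: DEGSet) -> tuple[dict, list]:
    agree, clash = {}, []
    for gene, d in a.members.items():
        if gene in b.members:
            if b.members[gene] == d:
                agree[gene] = d
            else:
                clash.append(gene)
    return agree, clash


def dual_method_overlap(p_set: DEGSet, es_set: DEGSet) -> DEGSet:
    """Venn overlap of the p-combination and effect-size DEG sets, keeping
    only direction-consistent genes (disagreements are recorded in the
    provenance string)."""
    if p_set.comparison != es_set.comparison:
        raise ValueError(
            f"comparison mismatch: {p_set.comparison!r} vs {es_set.comparison!r}"
        )
    agree, clash = _directed_intersection(p_set, es_set)
    prov = f"overlap[{p_set.provenance} & {es_set.provenance}]"
    if clash:
        prov += f"; direction clashes dropped: {sorted(clash)}"
    return DEGSet(comparison=p_set.comparison, members=agree, provenance=prov)


def train_validate(training: DEGSet, validation: DEGSet) -> DEGSet:
    """Genes confirmed in both the training and validation cohorts with
    agreeing direction."""
    agree, clash = _directed_intersection(training, validation)
    prov = f"train∩validate[{training.comparison} & {validation.comparison}]"
    if clash:
        prov += f"; direction clashes dropped: {sorted(clash)}"
    return DEGSet(comparison=training.comparison, members=agree, provenance=prov)


def specificity_filter(
    gbm_vs_ng: DEGSet, gbm_vs_a: DEGSet, gbm_vs_od: DEGSet
) -> DEGSet:
    """Genes differential in GBM versus non-glioma AND versus both other
    glioma subtypes, with one consistent direction — the GBM-specific
    biomarker set."""
    step, _ = _directed_intersection(gbm_vs_ng, gbm_vs_a)
    tmp = DEGSet(comparison=gbm_vs_ng.comparison, members=step)
    final, _ = _directed_intersection(tmp, gbm_vs_od)
    return DEGSet(
        comparison="GBM_specific",
        members=final,
        provenance=(
            f"{gbm_vs_ng.comparison} ∩ {gbm_vs_a.comparison} ∩ {gbm_vs_od.comparison}"
        ),
    )


def venn_counts(sets: dict) -> dict:
    """Counts for every region of the Venn diagram of 2 or 3 directed sets
    (membership only; direction is ignored here, matching a plotted Venn)."""
    names = list(sets)
    if len(names) not in (2, 3):
        raise ValueError("venn_counts supports 2 or 3 sets")
    universe = set().union(*(set(s.members) for s in sets.values()))
    regions: dict = {}
    for gene in universe:
        key = tuple(sorted(n for n in names if gene in sets[n]))
        regions[key] = regions.get(key, 0) + 1
    return {"&".join(k): v for k, v in sorted(regions.items())}
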
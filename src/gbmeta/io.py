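"""Expression matrices, sample annotations and gene-set collections.

Conventions: expression values are log2-scale, matrices are genes x samples
TSV with a header row of sample IDs and gene/probe identifiers in the first
column.  Gene symbols are upper-cased at load time because symbol casing is
not consistent across platforms.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = ["sample_id", "study_id", "class", "time", "event", "exclude_flag"]
SAMPLE_CLASSES = ("GBM", "A", "OD", "NG")


class ParseError(ValueError):
    """Malformed input file; message carries the offending coordinates."""


@dataclass
class ExpressionStudy:
    """One study's log2 gene-by-sample matrix.

    ``values`` is a pandas DataFrame indexed by gene symbol with sample-ID
    columns.  The frame is the single source of truth; ``genes`` and
    ``samples`` are views of its axes.
    """

    study_id: str
    values: pd.DataFrame
    platform_id: str = ""

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError(f"study {self.study_id}: missing values in matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def require_unique_genes(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(
                f"study {self.study_id}: duplicate gene symbols "
                f"(e.g. {list(dupes[:3])}); collapse probes first"
            )

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. GO terms, KEGG pathways) with descriptions."""

    sets: dict = field(default_factory=dict)  # name -> set of symbols
    descriptions: dict = field(default_factory=dict)  # name -> str

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_expression_matrix(
    path, study_id: str | None = None, platform_id: str = ""
) -> ExpressionStudy:
    """Read a genes x samples TSV into an :class:`ExpressionStudy`.

    Duplicate row identifiers are permitted (probe-level input); call
    :func:`collapse_probes` before analysis.  Raises :class:`ParseError`
    naming the offending line/column for ragged rows, non-numeric cells or
    an empty file.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = [row for row in reader if row]
    if not rows:
        raise ParseError(f"{path}: empty file")
    header = rows[0]
    if len(header) < 2:
        raise ParseError(f"{path}: line 1: header has no sample columns")
    n_cols = len(header)
    samples = header[1:]
    ids: list[str] = []
    data = np.empty((len(rows) - 1, n_cols - 1))
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != n_cols:
            raise ParseError(
                f"{path}: line {i}: expected {n_cols} fields, found {len(row)}"
            )
        ids.append(row[0].strip().upper())
        for j, cell in enumerate(row[1:], start=2):
            try:
                data[i - 2, j - 2] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: line {i}, column {j}: non-numeric cell {cell!r}"
                ) from None
    values = pd.DataFrame(data, index=ids, columns=samples)
    if study_id is None:
        study_id = str(path)
    return ExpressionStudy(study_id=study_id, values=values, platform_id=platform_id)


def collapse_probes(
    matrix: pd.DataFrame, mapping: dict, rule: str = "max_mean"
) -> pd.DataFrame:
    """Collapse a probes x samples matrix to genes x samples.

    Probes absent from ``mapping`` are dropped.  For genes measured by
    several probes, ``max_mean`` (default) keeps the probe with the highest
    mean expression across samples; ``mean`` averages probes;
    ``max_per_sample`` takes the per-sample maximum.
    """
    if not mapping:
        raise ValueError("empty probe-to-gene mapping")
    mapped = matrix.loc[[p for p in matrix.index if p in mapping]]
    genes = pd.Index([str(mapping[p]).upper() for p in mapped.index], name="gene")
    if rule == "max_mean":
        means = mapped.mean(axis=1).to_numpy()
        order = np.argsort(-means, kind="stable")
        best = (
            pd.DataFrame({"gene": genes[order], "pos": order})
            .drop_duplicates("gene")
            .set_index("gene")["pos"]
        )
        out = mapped.iloc[best.to_numpy()]
        out.index = best.index
    elif rule == "mean":
        out = mapped.groupby(genes).mean()
    elif rule == "max_per_sample":
        out = mapped.groupby(genes).max()
    else:
        raise ValueError(f"unknown collapse rule {rule!r}")
    return out.sort_index()


def filter_low_signal(
    study: ExpressionStudy, mean_q: float = 0.10, sd_q: float = 0.10
) -> ExpressionStudy:
    """Drop low-signal genes: bottom ``mean_q`` quantile of per-gene means,
    then the bottom ``sd_q`` quantile of per-gene SDs among the survivors.

    Quantiles use linear interpolation; genes strictly below the cut are
    removed, so ties at the cut survive and the filter never removes more
    than its nominal fraction.
    """
    if not (0 <= mean_q < 1 and 0 <= sd_q < 1):
        raise ValueError("quantile fractions must be in [0, 1)")
    values = study.values
    if mean_q > 0:
        means = values.mean(axis=1)
        values = values.loc[means >= means.quantile(mean_q)]
    if sd_q > 0 and len(values):
        sds = values.std(axis=1, ddof=1)
        values = values.loc[sds >= sds.quantile(sd_q)]
    if values.empty:
        raise ValueError(f"study {study.study_id}: filter removed all genes")
    return ExpressionStudy(
        study_id=study.study_id, values=values, platform_id=study.platform_id
    )


def filter_low_signal_consensus(
    studies: list[ExpressionStudy], mean_q: float = 0.10, sd_q: float = 0.10
) -> list[ExpressionStudy]:
    """Cohort-level low-signal filter on the common gene universe.

    Genes are ranked within each study by per-gene mean (then, among
    survivors, by per-gene SD); the bottom ``mean_q`` (``sd_q``) fraction by
    *average rank across studies* is removed from every study.  Filtering on
    the rank consensus rather than per study keeps the filtered universe
    identical across studies and avoids losing a gene to one study's noise.
    """
    if not (0 <= mean_q < 1 and 0 <= sd_q < 1):
        raise ValueError("quantile fractions must be in [0, 1)")
    genes = pd.Index(common_genes(studies))

    def surviving(index: pd.Index, stat: str, q: float) -> pd.Index:
        if q == 0 or index.empty:
            return index
        ranks = []
        for s in studies:
            vals = (
                s.values.loc[index].mean(axis=1)
                if stat == "mean"
                else s.values.loc[index].std(axis=1, ddof=1)
            )
            ranks.append(vals.rank())
        avg = pd.concat(ranks, axis=1).mean(axis=1)
        return index[(avg >= avg.quantile(q)).to_numpy()]

    keep = surviving(genes, "mean", mean_q)
    keep = surviving(keep, "sd", sd_q)
    if keep.empty:
        raise ValueError("consensus filter removed all genes")
    return [
        ExpressionStudy(
            study_id=s.study_id,
            values=s.values.loc[keep],
            platform_id=s.platform_id,
        )
        for s in studies
    ]


def common_genes(studies: list[ExpressionStudy]) -> list[str]:
    """Lexicographically sorted intersection of the studies' gene sets."""
    if not studies:
        raise ValueError("no studies given")
    genes = set(studies[0].genes)
    for s in studies[1:]:
        genes &= set(s.genes)
    if not genes:
        raise ValueError("empty gene intersection across studies")
    return sorted(genes)


def read_annotations(path) -> pd.DataFrame:
    """Read a sample annotation TSV with the fixed header."""
    ann = pd.read_csv(path, sep="\t")
    missing = [c for c in ("sample_id", "study_id", "class") if c not in ann.columns]
    if missing:
        raise ParseError(f"{path}: missing annotation columns {missing}")
    bad = set(ann["class"]) - set(SAMPLE_CLASSES)
    if bad:
        raise ParseError(f"{path}: unknown class labels {sorted(bad)}")
    if ann["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample_id entries")
    for col in ("time", "event"):
        if col not in ann.columns:
            ann[col] = np.nan
    if "exclude_flag" not in ann.columns:
        ann["exclude_flag"] = False
    has_time = ann["time"].notna()
    if (has_time & ann["event"].isna()).any():
        raise ParseError(f"{path}: time present without event flag")
    return ann[ANNOTATION_COLUMNS]


def write_annotations(ann: pd.DataFrame, path) -> None:
    ann[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name, description, then member symbols per line."""
    sets: dict = {}
    descriptions: dict = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {i}: GMT line with < 3 fields")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ParseError(f"{path}: line {i}: duplicate set name {name!r}")
            members = {f.strip().upper() for f in fields[2:] if f.strip()}
            if not members:
                raise ParseError(f"{path}: line {i}: set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")
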
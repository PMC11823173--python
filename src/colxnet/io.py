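"""Readers and writers for the tabular formats the pipeline consumes.

Canonical formats are TSV (tab-separated, UTF-8, ``.`` decimal) for expression
and clinical tables, and GMT for gene-set collections — the distribution
formats of the upstream sources (GDC expression matrices, MSigDB collections).
Gene identity is by symbol string, case-sensitive, with no alias resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("colxnet")

__all__ = [
    "Unit",
    "ExpressionMatrix",
    "GeneSetCollection",
    "ClinicalTable",
    "FormatError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_sets_gmt",
    "write_gene_sets_gmt",
    "read_clinical_table",
    "write_clinical_table",
]


class FormatError(ValueError):
    """Raised when an input file violates the declared format contract."""


class Unit(str, Enum):
    """Expression measurement scale carried alongside the matrix."""

    RSEM = "rsem"
    LOG_INTENSITY = "log_intensity"
    COUNTS = "counts"
    LOG2 = "log2"


@dataclass
class ExpressionMatrix:
    """Gene × sample numeric matrix with a unit tag and cohort label.

    ``values`` has shape ``(len(gene_ids), len(sample_ids))``. Gene and sample
    ids must be unique; values must be finite; a ``counts`` unit implies
    non-negative integer values.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    unit: Unit = Unit.LOG2
    cohort_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        dup_g = _duplicates(self.gene_ids)
        if dup_g:
            raise FormatError(f"duplicate gene ids: {sorted(dup_g)}")
        dup_s = _duplicates(self.sample_ids)
        if dup_s:
            raise FormatError(f"duplicate sample ids: {sorted(dup_s)}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.unit == Unit.COUNTS:
            if np.any(self.values < 0) or np.any(self.values != np.round(self.values)):
                raise ValueError("counts unit requires non-negative integer values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, unit: Unit, cohort_label: str = "") -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            values=df.to_numpy(dtype=float),
            unit=unit,
            cohort_label=cohort_label,
        )

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:10]}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows, :],
                                self.unit, self.cohort_label)

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), list(samples), self.values[:, cols],
                                self.unit, self.cohort_label)


@dataclass
class GeneSetCollection:
    """Named gene-id sets (e.g. hallmark pathways, TF targets, marker sets)."""

    name: str
    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for sname, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {sname!r} is empty after deduplication")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class ClinicalTable:
    """Per-sample covariates and survival outcomes.

    Stage is binarized as "1-2" vs "3-4" (major stage number; substage letters
    such as IIIa collapse to their major stage). Rows missing one outcome are
    retained for models of the other outcome (complete-case per model).
    """

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("sample_id",)
    OUTCOMES = (("os_time", "os_event"), ("dfi_time", "dfi_event"))

    def __post_init__(self) -> None:
        if "sample_id" not in self.data.columns:
            raise FormatError("clinical table requires a sample_id column")
        self.data = self.data.reset_index(drop=True)
        for tcol, ecol in self.OUTCOMES:
            if tcol in self.data.columns:
                times = self.data[tcol].dropna()
                if (times < 0).any():
                    raise ValueError(f"negative time in column {tcol}")
            if ecol in self.data.columns:
                ev = self.data[ecol].dropna()
                if not ev.isin([0, 1]).all():
                    raise ValueError(f"events in {ecol} must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data["sample_id"]]

    def complete_cases(self, outcome: str, covariates: list[str]) -> pd.DataFrame:
        """Rows with the named outcome and all covariates present."""
        tcol, ecol = f"{outcome}_time", f"{outcome}_event"
        cols = ["sample_id", tcol, ecol] + [c for c in covariates if c in self.data.columns]
        sub = self.data[cols].dropna()
        dropped = sorted(set(self.data["sample_id"]) - set(sub["sample_id"]))
        if dropped:
            logger.info("complete-case for %s: dropped %d samples: %s",
                        outcome, len(dropped), dropped[:10])
        return sub.reset_index(drop=True)


def _duplicates(items) -> set:
    seen, dup = set(), set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def binarize_stage(stage) -> str | float:
    """Collapse a clinical stage (1-4, roman, or with substage letter) to "1-2"/"3-4"."""
    if stage is None or (isinstance(stage, float) and np.isnan(stage)):
        return np.nan
    s = str(stage).strip().upper().removeprefix("STAGE").strip()
    if s in ("1-2", "3-4"):
        return s
    for roman, num in (("IV", 4), ("III", 3), ("II", 2), ("I", 1)):
        if s.startswith(roman):
            s = str(num)
            break
    major = s[0] if s else ""
    if major in ("1", "2"):
        return "1-2"
    if major in ("3", "4"):
        return "3-4"
    raise FormatError(f"unrecognized tumor stage: {stage!r}")


def read_expression_matrix(path: str | Path, unit: Unit | str,
                           cohort_label: str = "") -> ExpressionMatrix:
    """Read a TSV with sample ids in the header row and gene ids in column 1."""
    unit = Unit(unit)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    dup = _duplicates(df.index.tolist())
    if dup:
        raise FormatError(f"{path}: duplicated gene id(s): {sorted(dup)}")
    try:
        vals = df.astype(float)
    except ValueError:
        for j, col in enumerate(df.columns):
            for i, v in enumerate(df[col]):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"{path}: non-numeric cell at gene {df.index[i]!r}, "
                        f"sample {col!r}: {v!r}"
                    ) from None
        raise
    return ExpressionMatrix.from_frame(vals, unit=unit, cohort_label=cohort_label)


def write_expression_matrix(X: ExpressionMatrix, path: str | Path) -> None:
    df = X.to_frame()
    if X.unit == Unit.COUNTS:
        df = df.astype(int)
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_sets_gmt(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, tab-separated members.

    Members are deduplicated preserving order; empty sets are dropped with a
    logged warning; duplicate set names are a format error.
    """
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            sname = fields[0]
            if sname in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {sname!r}")
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            if not members:
                logger.warning("%s:%d: gene set %r is empty; dropped", path, lineno, sname)
                continue
            sets[sname] = members
    return GeneSetCollection(name=name or Path(path).stem, sets=sets, source=str(path))


def write_gene_sets_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sname, members in collection.sets.items():
            fh.write("\t".join([sname, collection.source or "na"] + list(members)) + "\n")


def read_clinical_table(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV; stage (raw 1-4/roman or pre-binarized) is binarized."""
    df = pd.read_csv(path, sep="\t")
    if "stage" in df.columns and "stage_binary" not in df.columns:
        df["stage_binary"] = [binarize_stage(s) for s in df["stage"]]
        df = df.drop(columns=["stage"])
    elif "stage_binary" in df.columns:
        df["stage_binary"] = [binarize_stage(s) for s in df["stage_binary"]]
    return ClinicalTable(df)


def write_clinical_table(table: ClinicalTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)
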
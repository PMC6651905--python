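"""Readers/writers for the tabular formats the pipeline touches, with strict validation.

All on-disk formats are plain text: TSV (UTF-8, ``.`` decimal) for matrices
and clinical tables, GMT or one-symbol-per-line for gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALUE_KINDS = ("activity", "log2_intensity", "fpkm_uq")

#: Columns every clinical table must provide; anything else is a covariate.
CLINICAL_REQUIRED = ("sample_id", "dfs_time", "dfs_event")


class FormatError(ValueError):
    """A file violates the expected dialect or a value-level invariant."""


@dataclass
class ExpressionMatrix:
    """Features x samples numeric table with an identifier axis.

    ``value_kind`` declares the measurement scale: ``activity`` scores live
    in [0, 1], ``log2_intensity`` and ``fpkm_uq`` are unbounded continuous.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    value_kind: str = "log2_intensity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if self.value_kind not in VALUE_KINDS:
            raise FormatError(f"unknown value_kind {self.value_kind!r}")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise FormatError(f"duplicate sample ids: {sorted(dup)}")
        self.feature_ids = _dedupe_features(self.feature_ids)
        if self.values.size and np.isnan(self.values).all(axis=1).any():
            bad = [f for f, row in zip(self.feature_ids, self.values) if np.isnan(row).all()]
            raise FormatError(f"fully-missing feature rows: {bad[:5]}")
        if self.value_kind == "activity":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
                raise FormatError("activity values must lie in [0, 1]")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, feature_id: str) -> pd.Series:
        """One feature as a Series indexed by sample id."""
        try:
            i = self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"feature {feature_id!r} not in matrix") from None
        return pd.Series(self.values[i], index=self.sample_ids, name=feature_id)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            list(self.feature_ids), list(sample_ids), self.values[:, idx], self.value_kind
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class ClinicalTable:
    """Per-sample disease-free survival time, event flag and covariates."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"clinical table missing required columns: {missing}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise FormatError(f"duplicate sample ids in clinical table: {dup[:5]}")
        t = pd.to_numeric(df["dfs_time"], errors="coerce")
        if t.isna().any() or (t < 0).any():
            raise FormatError("dfs_time must be numeric and >= 0")
        e = pd.to_numeric(df["dfs_event"], errors="coerce")
        if not e.isin([0, 1]).all():
            raise FormatError("dfs_event must be 0 (censored) or 1 (event)")
        df = df.copy()
        df["dfs_time"] = t.astype(float)
        df["dfs_event"] = e.astype(int)
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in CLINICAL_REQUIRED]

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        sub = self.table.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return ClinicalTable(sub)


@dataclass
class GeneSet:
    """A named, non-empty list of unique gene symbols."""

    name: str
    members: list[str] = field(default_factory=list)
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"gene set {self.name!r} is empty")
        dup = _duplicates(self.members)
        if dup:
            raise FormatError(f"gene set {self.name!r} has duplicate members: {sorted(dup)}")


def _duplicates(ids: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in ids:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def _dedupe_features(ids: Sequence[str]) -> list[str]:
    """Disambiguate duplicate feature ids with a numeric suffix, keeping all rows."""
    counts: dict[str, int] = {}
    out = []
    for x in ids:
        k = counts.get(x, 0)
        out.append(x if k == 0 else f"{x}.{k}")
        counts[x] = k + 1
    n_dup = sum(1 for x, k in counts.items() if k > 1)
    if n_dup:
        logger.info("disambiguated %d duplicated feature ids by suffix", n_dup)
    return out


def read_expression(path: str | Path, value_kind: str = "log2_intensity") -> ExpressionMatrix:
    """Read a features x samples TSV: header row of sample ids, first column feature ids."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: no sample columns in header")
    dup_cols = _duplicates(header[1:])  # pandas mangles duplicates, so check raw
    if dup_cols:
        raise FormatError(f"{path}: duplicate sample column(s) {sorted(dup_cols)}")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    try:
        values = df.astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from None
    return ExpressionMatrix(
        feature_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        values=values,
        value_kind=value_kind,
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="feature_id")


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.table.to_csv(path, sep="\t", index=False)


def read_geneset(path: str | Path) -> GeneSet:
    """Read a gene set: GMT dialect (name, description, members) or one symbol per line."""
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty gene set file")
    if len(lines) == 1 and "\t" in lines[0]:
        fields = lines[0].split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}: GMT line needs name, description and >= 1 member")
        return GeneSet(name=fields[0], description=fields[1], members=fields[2:])
    if any("\t" in ln for ln in lines):
        raise FormatError(f"{path}: mixed GMT/plain-list content")
    return GeneSet(name=path.stem, members=lines)


def write_geneset(geneset: GeneSet, path: str | Path) -> None:
    line = "\t".join([geneset.name, geneset.description or "na", *geneset.members])
    Path(path).write_text(line + "\n", encoding="utf-8")


def align_cohort(
    expression: ExpressionMatrix, clinical: ClinicalTable
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Intersect expression and clinical tables on sample id.

    Samples lacking survival information (absent from the clinical table, or
    with missing time) are dropped with a logged count.
    """
    expr_ids = set(expression.sample_ids)
    keep = [s for s in clinical.sample_ids if s in expr_ids]
    n_dropped = expression.n_samples - len(keep)
    if n_dropped:
        logger.info("dropped %d samples without survival information", n_dropped)
    if not keep:
        raise FormatError("no samples shared between expression and clinical tables")
    return expression.subset_samples(keep), clinical.subset(keep)


def select_primary_feature(
    matrix: ExpressionMatrix, candidates: Sequence[str], primary: str | None = None
) -> str:
    """Pick the feature row representing a gene.

    When ``primary`` is named and present it wins; otherwise the candidate
    with the highest variance across samples is used and the choice logged.
    """
    present = [c for c in candidates if c in matrix.feature_ids]
    if not present:
        raise KeyError(f"none of {list(candidates)} present in matrix")
    if primary is not None:
        if primary not in matrix.feature_ids:
            raise KeyError(f"primary feature {primary!r} not in matrix")
        return primary
    if len(present) == 1:
        return present[0]
    variances = {c: float(np.nanvar(matrix.row(c).to_numpy())) for c in present}
    choice = max(sorted(variances), key=lambda c: variances[c])
    logger.info("selected highest-variance feature %s among %s", choice, present)
    return choice


def write_report_tables(results: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write named report tables (stratification counts, correlation tables,
    per-gene survival p-values, ...) as TSV files under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in results.items():
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        written.append(path)
    return written
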
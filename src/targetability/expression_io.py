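"""Reading, validating and writing expression matrices and group labels.

Expression values are expected on the UPC (Universal exPression Code)
scale: every entry is a number in ``[0, 1]`` giving, per gene and sample,
the probability-like activity level of the gene.  The fixed region
threshold of 0.5 used downstream is only meaningful on this scale, so
values outside ``[0, 1]`` (beyond a tiny floating-point tolerance) are a
hard load error rather than being clamped -- silently clamping would hide
a normalization mistake upstream.

Two on-disk dialects are supported:

* plain TSV -- first column ``gene``, remaining columns sample ids, one
  row per gene;
* GCT 1.2 -- ``#1.2`` header line, a dimensions line, then a table with
  ``Name``/``Description`` columns (``Description`` is ignored on read
  and written back as the gene id).

Group labels come from a headerless two-column TSV
``sample_id<TAB>group`` with exactly two groups; by default the group
named ``normal`` is taken as the reference side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: values may stray this far outside [0, 1] before loading fails
BOUND_TOLERANCE = 1e-9

#: minimum samples per group, so each of the two regions can in principle
#: hold >=2 samples per group (the minimum for a two-sample test)
MIN_GROUP_SIZE = 4


class ExpressionIOError(ValueError):
    """Malformed or invalid expression / group-label input."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples grid of UPC-scale expression values.

    Parameters
    ----------
    data
        DataFrame indexed by gene symbol with sample ids as columns.
        Validated on construction: unique gene and sample ids, all
        values finite and within ``[0, 1]`` (tolerance
        :data:`BOUND_TOLERANCE`, after which they are clipped exactly
        into the interval).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ExpressionIOError(f"duplicate gene ids: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = sorted(df.columns[df.columns.duplicated()].unique())
            raise ExpressionIOError(f"duplicate sample ids: {dups[:5]}")
        values = df.to_numpy(dtype=float, copy=False)
        _check_bounds(values, df.index, df.columns)
        clipped = pd.DataFrame(
            np.clip(values, 0.0, 1.0),
            index=df.index.astype(str),
            columns=df.columns.astype(str),
        )
        object.__setattr__(self, "data", clipped)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        """Return a new matrix restricted to the given samples (order kept)."""
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        return ExpressionMatrix(self.data[keep])


@dataclass(frozen=True)
class GroupLabels:
    """Sample -> group assignment for a two-group comparison.

    ``reference_group`` is the "normal" side; ``case_group`` the disease
    side.  Exactly those two group names may appear, and each group must
    contain at least :data:`MIN_GROUP_SIZE` samples.
    """

    assignments: dict = field(default_factory=dict)
    reference_group: str = "normal"
    case_group: str = "case"

    def __post_init__(self) -> None:
        groups = set(self.assignments.values())
        expected = {self.reference_group, self.case_group}
        if self.reference_group == self.case_group:
            raise ExpressionIOError("reference and case group names must differ")
        if groups != expected:
            raise ExpressionIOError(
                f"group labels {sorted(groups)} do not match the expected "
                f"two groups {sorted(expected)}"
            )
        for name in (self.reference_group, self.case_group):
            n = sum(1 for g in self.assignments.values() if g == name)
            if n < MIN_GROUP_SIZE:
                raise ExpressionIOError(
                    f"group '{name}' has {n} samples; at least "
                    f"{MIN_GROUP_SIZE} are required"
                )

    @property
    def reference_samples(self) -> list[str]:
        return sorted(s for s, g in self.assignments.items() if g == self.reference_group)

    @property
    def case_samples(self) -> list[str]:
        return sorted(s for s, g in self.assignments.items() if g == self.case_group)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.assignments)

    def swapped(self) -> "GroupLabels":
        """Labels with reference and case roles exchanged (sign checks)."""
        return GroupLabels(
            assignments=dict(self.assignments),
            reference_group=self.case_group,
            case_group=self.reference_group,
        )

    def restrict(self, sample_ids) -> "GroupLabels":
        keep = set(sample_ids)
        return GroupLabels(
            assignments={s: g for s, g in self.assignments.items() if s in keep},
            reference_group=self.reference_group,
            case_group=self.case_group,
        )


def _check_bounds(values: np.ndarray, genes, samples) -> None:
    bad = ~np.isfinite(values)
    bad |= values < -BOUND_TOLERANCE
    bad |= values > 1.0 + BOUND_TOLERANCE
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ExpressionIOError(
            f"value {values[i, j]!r} for gene '{genes[i]}' sample "
            f"'{samples[j]}' is not a finite number in [0, 1]"
        )


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("tsv", "gct"):
            raise ExpressionIOError(f"unknown expression format '{fmt}'")
        return fmt
    return "gct" if path.suffix.lower() == ".gct" else "tsv"


def read_expression(path, fmt: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from TSV or GCT 1.2.

    Duplicate gene rows (probe-to-gene collapse leftovers common in
    microarray exports) are averaged with a logged warning.  Duplicate
    sample ids, non-numeric cells and out-of-``[0,1]`` values are errors
    naming the offending row/column.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "gct":
        df = _read_gct(path)
    else:
        df = _read_tsv(path)
    df = _to_numeric(df, path)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        log.warning(
            "%s: %d duplicate gene rows collapsed by arithmetic mean (e.g. %s)",
            path.name, len(dups), ", ".join(dups[:3]),
        )
        df = df.groupby(level=0, sort=False).mean()
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ExpressionIOError(f"{path}: empty expression matrix")
    return ExpressionMatrix(df)


def _read_header_fields(path: Path, skip: int = 0) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        for _ in range(skip):
            fh.readline()
        line = fh.readline()
    if not line:
        raise ExpressionIOError(f"{path}: missing header line")
    return line.rstrip("\n").split("\t")


def _read_tsv(path: Path) -> pd.DataFrame:
    fields = _read_header_fields(path)
    if len(fields) < 2:
        raise ExpressionIOError(f"{path}: header must have a gene column and >=1 sample")
    samples = fields[1:]
    if len(samples) != len(set(samples)):
        dup = next(s for s in samples if samples.count(s) > 1)
        raise ExpressionIOError(f"{path}: duplicate sample id '{dup}'")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return df


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ExpressionIOError(f"{path}: expected GCT '#1.2' header, got {version!r}")
        dims = fh.readline().split()
    if len(dims) != 2:
        raise ExpressionIOError(f"{path}: malformed GCT dimensions line")
    n_genes, n_samples = (int(d) for d in dims)
    fields = _read_header_fields(path, skip=2)
    if len(fields) < 3 or fields[0] != "Name":
        raise ExpressionIOError(f"{path}: malformed GCT column header")
    samples = fields[2:]
    if len(samples) != len(set(samples)):
        dup = next(s for s in samples if samples.count(s) > 1)
        raise ExpressionIOError(f"{path}: duplicate sample id '{dup}'")
    df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0, dtype=str)
    df = df.drop(columns=df.columns[0])  # Description
    if df.shape != (n_genes, n_samples):
        raise ExpressionIOError(
            f"{path}: dimensions line says {n_genes}x{n_samples} but table "
            f"is {df.shape[0]}x{df.shape[1]}"
        )
    df.index = df.index.astype(str)
    return df


def _to_numeric(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ExpressionIOError(
            f"{path}: non-numeric value {df.iat[i, j]!r} for gene "
            f"'{df.index[i]}' sample '{df.columns[j]}'"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ExpressionIOError(
            f"{path}: missing value for gene '{df.index[i]}' sample '{df.columns[j]}'"
        )
    return numeric.astype(float)


def write_expression(matrix: ExpressionMatrix, path, fmt: str | None = None) -> None:
    """Write a matrix to TSV or GCT 1.2; round-trips through
    :func:`read_expression` to better than 1e-12."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ExpressionIOError("refusing to write an empty expression matrix")
    if fmt == "tsv":
        matrix.data.to_csv(path, sep="\t", index_label="gene")
        return
    n_genes, n_samples = matrix.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#1.2\n")
        fh.write(f"{n_genes}\t{n_samples}\n")
        out = matrix.data.copy()
        out.insert(0, "Description", out.index)
        out.to_csv(fh, sep="\t", index_label="Name")


def read_groups(path, matrix: ExpressionMatrix, reference_group: str | None = None) -> GroupLabels:
    """Read sample group labels and validate them against a matrix.

    Exactly two groups must appear; every matrix sample must be labeled.
    If ``reference_group`` is not given, a group literally named
    ``normal`` is used as the reference; otherwise an explicit choice is
    required.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", header=None, dtype=str).dropna(how="all")
    if table.shape[1] != 2:
        raise ExpressionIOError(f"{path}: expected two columns sample_id<TAB>group")
    assignments: dict[str, str] = {}
    for sample, group in table.itertuples(index=False):
        if sample in assignments and assignments[sample] != group:
            raise ExpressionIOError(f"{path}: sample '{sample}' labeled twice")
        assignments[sample] = group
    groups = sorted(set(assignments.values()))
    if len(groups) != 2:
        raise ExpressionIOError(
            f"{path}: expected exactly 2 groups, found {len(groups)}: {groups}"
        )
    matrix_samples = set(matrix.sample_ids)
    missing = sorted(matrix_samples - set(assignments))
    if missing:
        raise ExpressionIOError(f"{path}: no group label for sample '{missing[0]}'")
    extra = sorted(set(assignments) - matrix_samples)
    if extra:
        log.warning("%s: %d labeled samples absent from the matrix; ignored", path.name, len(extra))
        assignments = {s: g for s, g in assignments.items() if s in matrix_samples}
    if reference_group is None:
        if "normal" in groups:
            reference_group = "normal"
        else:
            raise ExpressionIOError(
                f"{path}: no group named 'normal'; specify the reference group "
                f"explicitly (groups found: {groups})"
            )
    if reference_group not in groups:
        raise ExpressionIOError(
            f"reference group '{reference_group}' not among groups {groups}"
        )
    case_group = next(g for g in groups if g != reference_group)
    return GroupLabels(assignments, reference_group, case_group)


def write_groups(labels: GroupLabels, path) -> None:
    """Write group labels as a headerless two-column TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        for sample in labels.sample_ids:
            fh.write(f"{sample}\t{labels.assignments[sample]}\n")
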
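"""Readers, writers and validated in-memory containers for all tabular inputs.

All tables are UTF-8, tab-delimited, LF line endings, first row header,
first column row key.  Lines starting with ``#`` are treated as provenance
comments and skipped on read; writers can embed such comments so that every
artifact carries its origin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

#: Valid Affymetrix-style detection-call tokens.
DETECTION_CALLS = ("P", "M", "A")

#: Columns required in a design table, in canonical order.
DESIGN_COLUMNS = ("sample_id", "condition_id", "role", "compound", "dose", "timepoint_h")

ROLES = ("control", "treated")


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionBundle:
    """Log2 expression values plus detection calls, probes x samples.

    ``values`` holds log2 intensities; ``calls`` holds one of P/M/A per cell.
    Both frames share identical probe and sample indices.
    """

    values: pd.DataFrame
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        v, c = self.values, self.calls
        if not v.index.is_unique:
            raise ValidationError("duplicate probe IDs in expression values")
        if not v.columns.is_unique:
            raise ValidationError("duplicate sample IDs in expression values")
        if not (v.index.equals(c.index) and v.columns.equals(c.columns)):
            raise ValidationError("values and calls must share identical probe/sample indices")
        arr = v.to_numpy()
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite expression value at probe {v.index[bad[0]]!r}, "
                f"sample {v.columns[bad[1]]!r}"
            )
        tokens = set(np.unique(c.to_numpy().astype(str)))
        unknown = tokens - set(DETECTION_CALLS)
        if unknown:
            raise FormatError(f"unknown detection-call token(s): {sorted(unknown)}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneSetCollection:
    """Ordered mapping of biomarker gene-set name -> probe-ID list.

    Sets may overlap (biomarker collections are not a partition); names are
    unique and no set is empty.
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class DesignTable:
    """Sample-to-condition mapping with control/treated roles."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"design table missing column(s): {missing}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id in design: {dup!r}")
        bad_roles = set(self.table["role"]) - set(ROLES)
        if bad_roles:
            raise FormatError(f"invalid role token(s): {sorted(bad_roles)}; expected {ROLES}")
        for cond, sub in self.table.groupby("condition_id", sort=False):
            roles = set(sub["role"])
            if "control" not in roles:
                raise ValidationError(f"condition {cond!r} has no control samples")
            if "treated" not in roles:
                raise ValidationError(f"condition {cond!r} has no treated samples")

    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.table["condition_id"]))

    def samples(self, condition_id: str, role: str | None = None) -> list[str]:
        sub = self.table[self.table["condition_id"] == condition_id]
        if sub.empty:
            raise ValidationError(f"unknown condition {condition_id!r}")
        if role is not None:
            sub = sub[sub["role"] == role]
        return list(sub["sample_id"])

    def check_against(self, bundle: ExpressionBundle) -> None:
        missing = set(self.table["sample_id"]) - set(bundle.sample_ids)
        if missing:
            raise ValidationError(
                f"design sample(s) absent from expression data: {sorted(missing)}"
            )


@dataclass
class PhenotypeTable:
    """Per-condition changing levels of phenotype endpoints (signed, unitless).

    Missing cells are allowed at read time (NaN); downstream consumers decide
    the missing-data policy.
    """

    table: pd.DataFrame  # conditions x endpoints, float with NaN for missing

    def __post_init__(self) -> None:
        if not self.table.index.is_unique:
            raise ValidationError("duplicate condition IDs in phenotype table")
        if not self.table.columns.is_unique:
            raise ValidationError("duplicate endpoint names in phenotype table")
        arr = self.table.to_numpy()
        if np.isinf(arr).any():
            raise ValidationError("infinite value in phenotype table")


@dataclass
class ScoreTable:
    """Gene set x condition score matrix with its method tag and scale."""

    scores: pd.DataFrame  # sets x conditions
    method: str = "dscore"
    scale: float = 10.0

    def __post_init__(self) -> None:
        if self.method not in ("dscore", "tgp1"):
            raise ValidationError(f"unknown scoring method {self.method!r}")
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValidationError("non-finite score entries")


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, numeric: bool = True) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: cannot parse as TSV: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None   # writers re-attach the row-key label
    df.columns.name = None
    if numeric:
        out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
        for col in df.columns:
            converted = pd.to_numeric(df[col], errors="coerce")
            blank = df[col].isna()  # genuinely empty cell -> missing, not parse error
            bad = converted.isna() & ~blank
            if bad.any():
                row = df.index[bad.argmax()]
                raise FormatError(
                    f"{path}: non-numeric value {df.loc[row, col]!r} "
                    f"at row {row!r}, column {col!r}"
                )
            out[col] = converted
        return out
    return df


def read_expression(path_values: str | Path,
                    path_calls: str | Path | None = None) -> ExpressionBundle:
    """Read a log2 expression matrix and (optionally) its detection calls.

    Without a calls file every call defaults to Present, i.e. full quality
    weight downstream.
    """
    values = _read_tsv(path_values, numeric=True)
    if values.isna().to_numpy().any():
        raise FormatError(f"{path_values}: empty cells are not allowed in expression values")
    if path_calls is None:
        calls = pd.DataFrame("P", index=values.index, columns=values.columns)
    else:
        calls = _read_tsv(path_calls, numeric=False)
        if set(calls.columns) != set(values.columns):
            only_v = sorted(set(values.columns) - set(calls.columns))
            only_c = sorted(set(calls.columns) - set(values.columns))
            raise FormatError(
                "sample headers differ between values and calls files: "
                f"only in values {only_v}, only in calls {only_c}"
            )
        if set(calls.index) != set(values.index):
            raise FormatError("probe IDs differ between values and calls files")
        calls = calls.loc[values.index, values.columns]
    return ExpressionBundle(values=values, calls=calls)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (Broad dialect: name, description, members).

    Duplicate members within a set are de-duplicated (order preserved) with a
    logged warning; duplicate set names and short lines are format errors.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} field(s), need >=3")
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                log.warning("gene set %r: %d duplicate member(s) removed",
                            name, len(members) - len(unique))
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def read_design(path: str | Path) -> DesignTable:
    """Read a sample/condition design table (TSV with fixed columns)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: design table missing column(s): {missing}")
    df = df[list(DESIGN_COLUMNS)]
    try:
        df["timepoint_h"] = pd.to_numeric(df["timepoint_h"])
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric timepoint_h: {exc}") from exc
    return DesignTable(table=df.reset_index(drop=True))


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a condition x endpoint phenotype table; empty cells become NaN."""
    df = _read_tsv(path, numeric=True)
    return PhenotypeTable(table=df)


def read_scores(path: str | Path, method: str = "dscore",
                scale: float = 10.0) -> ScoreTable:
    """Read a score table written by :func:`write_scores`."""
    df = _read_tsv(path, numeric=True)
    if df.isna().to_numpy().any():
        raise FormatError(f"{path}: score table contains empty cells")
    return ScoreTable(scores=df, method=method, scale=scale)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _write_frame(df: pd.DataFrame, path: str | Path, index_label: str,
                 comments: list[str] | None = None,
                 float_format: str | None = "%.17g") -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for c in comments or []:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index_label=index_label,
                  float_format=float_format, lineterminator="\n")


def write_expression(bundle: ExpressionBundle, path_values: str | Path,
                     path_calls: str | Path | None = None,
                     comments: list[str] | None = None) -> None:
    _write_frame(bundle.values, path_values, "probe_id", comments)
    if path_calls is not None:
        _write_frame(bundle.calls, path_calls, "probe_id", comments, float_format=None)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_design(design: DesignTable, path: str | Path,
                 comments: list[str] | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for c in comments or []:
            fh.write(f"# {c}\n")
        design.table.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def write_phenotypes(phenos: PhenotypeTable, path: str | Path,
                     comments: list[str] | None = None) -> None:
    _write_frame(phenos.table, path, "condition_id", comments)


def write_scores(table: ScoreTable, path: str | Path,
                 comments: list[str] | None = None) -> None:
    """Write a score table: gene sets as rows, conditions as columns."""
    _write_frame(table.scores, path, "gene_set", comments)


def log2_transform(values: pd.DataFrame, eps: float = 1.0) -> pd.DataFrame:
    """log2(max(x, eps)) for linear-scale inputs (eps floors non-positive cells)."""
    if eps <= 0 or not math.isfinite(eps):
        raise ValidationError("eps must be a positive finite number")
    return np.log2(values.clip(lower=eps))
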
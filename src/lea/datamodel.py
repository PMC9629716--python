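"""Typed containers, validation and delimited-table I/O.

All on-disk interchange is delimited text (TSV by default, comma
selectable), one header row, UTF-8.  The containers are thin, validated
wrappers around :mod:`numpy` arrays and :mod:`pandas` frames:

``ProbabilityMatrix``
    N x C classifier confidences per cell -- the space LEA operates in.
``CellTable``
    Per-cell metadata and scalar features (donor, well, site, centroid
    position in pixels, normalized intensities, ...).
``DonorMeta``
    Per-donor health covariates (age, gender, blood pressure, ...).
``ExpressionTable``
    Genes x donors normalized abundance matrix (pre-filtered upstream).
``PathwayAnnotation``
    pathway_id -> gene set mapping, read from GMT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "ProbabilityMatrix",
    "CellTable",
    "DonorMeta",
    "ExpressionTable",
    "PathwayAnnotation",
    "read_probability_matrix",
    "write_probability_matrix",
    "read_cell_table",
    "write_cell_table",
    "read_donor_meta",
    "read_expression_table",
    "write_expression_table",
    "read_gmt",
    "write_gmt",
    "filter_high_confidence",
    "subsample_balanced",
]

ROW_SUM_TOL = 1e-6


class FormatError(ValueError):
    """A file could not be parsed as the expected table layout."""


class ValidationError(ValueError):
    """A parsed table violates a container invariant."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class ProbabilityMatrix:
    """Per-cell class probabilities: N cells x C classes, rows on the simplex."""

    cell_ids: np.ndarray
    values: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.class_names = [str(c) for c in self.class_names]
        n, c = self.values.shape
        if n < 1 or c < 2:
            raise ValidationError(f"need N >= 1 and C >= 2, got {n} x {c}")
        if len(self.cell_ids) != n:
            raise ValidationError("cell_ids length does not match matrix rows")
        if len(set(self.class_names)) != c:
            raise ValidationError("class_names must be unique, one per column")
        if len(set(map(str, self.cell_ids))) != n:
            raise ValidationError("cell_ids must be unique")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValidationError("probabilities must lie in [0, 1]")
        bad = np.abs(self.values.sum(axis=1) - 1.0) > ROW_SUM_TOL
        if bad.any():
            ids = list(map(str, self.cell_ids[bad][:10]))
            raise ValidationError(
                f"{bad.sum()} rows do not sum to 1 within {ROW_SUM_TOL:g}: "
                + ", ".join(ids)
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_classes(self) -> int:
        return self.values.shape[1]

    def argmax_class(self) -> np.ndarray:
        """Hard class label per cell (name of the most confident class)."""
        return np.asarray(self.class_names, dtype=object)[self.values.argmax(axis=1)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.class_names)
        df.insert(0, "cell_id", self.cell_ids)
        return df

    def subset(self, cell_ids: Sequence) -> "ProbabilityMatrix":
        """Row subset in the given order."""
        pos = pd.Index(self.cell_ids).get_indexer(cell_ids)
        if (pos < 0).any():
            raise KeyError("unknown cell_ids requested in subset")
        return ProbabilityMatrix(self.cell_ids[pos], self.values[pos], self.class_names)


@dataclass
class CellTable:
    """Per-cell metadata / scalar features; one row per ``cell_id``.

    Recognized columns: ``cell_id`` (required), ``donor_id``, ``condition``,
    ``well_id``, ``site_id``, ``x``, ``y``, ``class_label`` plus arbitrary
    scalar feature columns.  Positions, when present, must be non-negative
    and accompanied by ``site_id`` (pixel coordinate frames are per image
    site and not comparable across sites).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if "cell_id" not in self.df.columns:
            raise ValidationError("CellTable requires a cell_id column")
        if self.df["cell_id"].duplicated().any():
            raise ValidationError("duplicate cell_ids in CellTable")
        self.df = self.df.reset_index(drop=True)
        has_pos = {"x", "y"} <= set(self.df.columns)
        if has_pos:
            if "site_id" not in self.df.columns:
                raise ValidationError("positions present but site_id missing")
            xy = self.df[["x", "y"]].to_numpy(dtype=float)
            ok = np.isnan(xy) | (xy >= 0)
            if not ok.all():
                raise ValidationError("positions must be non-negative")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def cell_ids(self) -> np.ndarray:
        return self.df["cell_id"].to_numpy()

    def column(self, name: str) -> pd.Series:
        if name not in self.df.columns:
            raise KeyError(f"CellTable has no column {name!r}")
        return self.df.set_index("cell_id")[name]

    def aligned_to(self, cell_ids: Sequence) -> pd.DataFrame:
        """Rows reordered to match ``cell_ids`` (e.g. a ProbabilityMatrix)."""
        indexed = self.df.set_index("cell_id")
        missing = pd.Index(cell_ids).difference(indexed.index)
        if len(missing):
            raise ValidationError(f"cells missing from CellTable: {list(missing[:10])}")
        return indexed.loc[cell_ids].reset_index()


@dataclass
class DonorMeta:
    """Per-donor covariates; ``donor_id`` column required and unique.

    Missing continuous values are NaN (empty field on disk); rows with a
    missing value for the tested variable are excluded per-analysis.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if "donor_id" not in self.df.columns:
            raise ValidationError("DonorMeta requires a donor_id column")
        if self.df["donor_id"].duplicated().any():
            raise ValidationError("duplicate donor_ids in DonorMeta")
        self.df = self.df.reset_index(drop=True)

    def variable(self, name: str, donors: Iterable | None = None) -> pd.Series:
        """A covariate as a donor-indexed Series, NaN rows dropped."""
        if name not in self.df.columns:
            raise KeyError(f"DonorMeta has no column {name!r}")
        s = self.df.set_index("donor_id")[name].dropna()
        if donors is not None:
            s = s.loc[s.index.intersection(pd.Index(donors))]
        return s


@dataclass
class ExpressionTable:
    """Genes x donors normalized, non-negative abundance matrix."""

    df: pd.DataFrame  # index: gene_id, columns: donor_id

    def __post_init__(self) -> None:
        if self.df.index.duplicated().any():
            raise ValidationError("duplicate gene_ids in ExpressionTable")
        vals = self.df.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValidationError("expression values must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.df.index

    @property
    def donors(self) -> pd.Index:
        return self.df.columns

    def gene(self, gene_id: str) -> pd.Series:
        if gene_id not in self.df.index:
            raise KeyError(f"gene {gene_id!r} not in ExpressionTable")
        return self.df.loc[gene_id]


@dataclass
class PathwayAnnotation:
    """pathway_id -> gene set; gene ids follow ExpressionTable conventions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for pid, genes in self.sets.items():
            fs = frozenset(map(str, genes))
            if not fs:
                raise ValidationError(f"pathway {pid!r} has an empty gene set")
            clean[str(pid)] = fs
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, pid: str) -> frozenset[str]:
        return self.sets[pid]

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# I/O


def read_probability_matrix(
    path, delimiter: str = "\t", renormalize: bool = False
) -> ProbabilityMatrix:
    """Read a cell x class probability table.

    Layout: header row ``cell_id <class> <class> ...``; one row per cell.
    With ``renormalize=True`` rows are rescaled to sum to one before
    validation (for classifier exports rounded on write); otherwise rows
    outside the 1e-6 sum tolerance raise :class:`ValidationError` listing
    the offending cells.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, header=0)
    except Exception as exc:  # malformed file
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] < 3 or df.columns[0] != "cell_id":
        raise FormatError(
            f"{path}: expected header 'cell_id' followed by >= 2 class columns, "
            f"got {list(df.columns[:4])}"
        )
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    if renormalize:
        sums = values.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            values = np.where(sums > 0, values / sums, values)
    return ProbabilityMatrix(df["cell_id"].to_numpy(), values, list(df.columns[1:]))


def write_probability_matrix(pm: ProbabilityMatrix, path, delimiter: str = "\t") -> None:
    pm.to_frame().to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def read_cell_table(path, delimiter: str = "\t") -> CellTable:
    return CellTable(pd.read_csv(path, sep=delimiter, header=0))


def write_cell_table(ct: CellTable, path, delimiter: str = "\t") -> None:
    ct.df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def read_donor_meta(path, delimiter: str = "\t") -> DonorMeta:
    return DonorMeta(pd.read_csv(path, sep=delimiter, header=0))


def read_expression_table(path, delimiter: str = "\t") -> ExpressionTable:
    df = pd.read_csv(path, sep=delimiter, header=0, index_col=0)
    return ExpressionTable(df)


def write_expression_table(et: ExpressionTable, path, delimiter: str = "\t") -> None:
    et.df.to_csv(path, sep=delimiter, index_label="gene_id", float_format="%.17g")


def read_gmt(path) -> PathwayAnnotation:
    """Read GMT: per line ``pathway_id<TAB>description<TAB>gene1<TAB>...``."""
    sets: dict[str, frozenset[str]] = {}
    desc: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs id, description, genes")
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
            desc[parts[0]] = parts[1]
    return PathwayAnnotation(sets, desc)


def write_gmt(annotation: PathwayAnnotation, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid, genes in annotation.items():
            d = annotation.descriptions.get(pid, "")
            fh.write("\t".join([pid, d, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# selection operations


def filter_high_confidence(
    pm: ProbabilityMatrix, threshold: float = 0.7, inclusive: bool = False
) -> np.ndarray:
    """Cells whose maximum class probability exceeds ``threshold``.

    The comparison is strict (``>``) by default; ``inclusive=True`` switches
    to ``>=``.  Returns the kept cell_ids in input order.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    mx = pm.values.max(axis=1)
    keep = mx >= threshold if inclusive else mx > threshold
    return pm.cell_ids[keep]


def subsample_balanced(
    cells: CellTable | pd.DataFrame,
    group_keys: Sequence[str],
    max_per_group: int,
    seed: int,
) -> np.ndarray:
    """Up to ``max_per_group`` cells per group, sampled without replacement.

    Deterministic given ``seed`` and invariant to input row order: cells are
    canonically sorted by cell_id and groups are visited in sorted key order
    before any random draw.
    """
    df = cells.df if isinstance(cells, CellTable) else cells
    if max_per_group < 1:
        raise ValueError("max_per_group must be >= 1")
    for key in group_keys:
        if key not in df.columns:
            raise KeyError(f"group key {key!r} not in cell table")
    if len(df) == 0:
        warnings.warn("subsample_balanced: empty cell table", stacklevel=2)
        return np.array([], dtype=object)
    ordered = df.sort_values("cell_id", kind="stable")
    rng = np.random.default_rng(seed)
    kept: list[np.ndarray] = []
    for _, grp in ordered.groupby(list(group_keys), sort=True, dropna=False):
        ids = grp["cell_id"].to_numpy()
        if len(ids) <= max_per_group:
            kept.append(ids)
        else:
            kept.append(rng.choice(ids, size=max_per_group, replace=False))
    return np.concatenate(kept) if kept else np.array([], dtype=object)
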
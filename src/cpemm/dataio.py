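"""Tabular dataset container, CSV/ARFF I/O, and preprocessing.

The preprocessing pipeline mirrors common clinical-data practice: drop
features with excessive missingness, impute remaining gaps class-wise
(mean for numeric, mode for nominal), then rescale numeric columns
(z-score by default, min-max for explicitly named columns).

Internally every cell is stored as a float: numeric features hold their
value, nominal features hold the integer code of their category, and
missing cells hold NaN.  This keeps the table a single contiguous array
that the learners can slice cheaply.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING_TOKENS = ("", "?", "NA")

__all__ = [
    "FeatureMeta",
    "Dataset",
    "read_table",
    "write_table",
    "zscore_normalize",
    "minmax_normalize",
    "drop_high_missing",
    "impute_classwise",
    "preprocess",
]


@dataclass(frozen=True)
class FeatureMeta:
    """Per-feature metadata: name, kind, and (for nominal) category order."""

    name: str
    kind: str  # "numeric" | "nominal"
    categories: tuple[str, ...] | None = None
    missing_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "nominal"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "nominal" and not self.categories:
            raise ValueError(f"nominal feature {self.name!r} needs categories")


@dataclass
class Dataset:
    """A feature matrix, label vector and missingness mask.

    ``X`` is an ``(n, d)`` float array; nominal features are stored as
    category codes, missing cells as NaN.  ``classes`` fixes the class
    order used everywhere downstream (confusion matrices, score columns,
    tie-breaks).
    """

    X: np.ndarray
    y: np.ndarray
    classes: tuple[str, ...]
    features: list[FeatureMeta]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=object)
        self.classes = tuple(self.classes)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, d = self.X.shape
        if len(self.y) != n:
            raise ValueError("X and y row counts differ")
        if len(self.features) != d:
            raise ValueError("feature metadata does not match X columns")
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        bad = set(self.y) - set(self.classes)
        if bad:
            raise ValueError(f"labels outside the declared class set: {bad}")
        for j, meta in enumerate(self.features):
            if meta.kind == "nominal":
                col = self.X[:, j]
                codes = col[~np.isnan(col)]
                if codes.size and (codes.min() < 0 or codes.max() >= len(meta.categories)):
                    raise ValueError(f"nominal codes out of range in {meta.name!r}")

    # -- basic views ---------------------------------------------------

    @property
    def n_instances(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.X)

    def column(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"no feature named {name!r}") from None

    def with_columns(self, X: np.ndarray, features: list[FeatureMeta] | None = None) -> "Dataset":
        return Dataset(X=X, y=self.y.copy(), classes=self.classes,
                       features=features if features is not None else list(self.features))

    def refresh_missing_fractions(self) -> "Dataset":
        n = self.n_instances
        feats = [replace(f, missing_fraction=float(np.isnan(self.X[:, j]).sum()) / n)
                 for j, f in enumerate(self.features)]
        return Dataset(X=self.X, y=self.y, classes=self.classes, features=feats)

    def to_frame(self) -> pd.DataFrame:
        """Decode to a human-readable DataFrame (categories as strings)."""
        cols = {}
        for j, meta in enumerate(self.features):
            col = self.X[:, j]
            if meta.kind == "nominal":
                out = np.full(len(col), None, dtype=object)
                ok = ~np.isnan(col)
                out[ok] = [meta.categories[int(c)] for c in col[ok]]
                cols[meta.name] = out
            else:
                cols[meta.name] = col
        cols["class"] = self.y
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------

def _infer_kind(values: pd.Series) -> bool:
    """True if every non-missing value parses as a float."""
    non_missing = values[~values.isna()]
    try:
        non_missing.astype(float)
        return True
    except (ValueError, TypeError):
        return False


def _dataset_from_frame(df: pd.DataFrame, label_column: str,
                        declared: dict[str, tuple[str, ...] | None] | None = None,
                        class_order: Sequence[str] | None = None) -> Dataset:
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} absent")
    if len(df) == 0:
        raise ValueError("dataset has zero instances")
    y_raw = df[label_column]
    if y_raw.isna().any():
        raise ValueError("label column contains missing values")
    y = y_raw.astype(str).to_numpy(dtype=object)
    if class_order is None:
        seen: list[str] = []
        for v in y:
            if v not in seen:
                seen.append(v)
        class_order = sorted(seen)
    feature_cols = [c for c in df.columns if c != label_column]
    n = len(df)
    X = np.empty((n, len(feature_cols)), dtype=float)
    features: list[FeatureMeta] = []
    for j, name in enumerate(feature_cols):
        col = df[name]
        miss = col.isna().to_numpy()
        if declared is not None:
            cats = declared.get(name)
            numeric = cats is None
        else:
            cats = None
            numeric = _infer_kind(col)
        if numeric:
            vals = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
            X[:, j] = vals
            features.append(FeatureMeta(name, "numeric",
                                        missing_fraction=float(miss.sum()) / n))
        else:
            if cats is None:
                cats_list: list[str] = []
                for v in col[~col.isna()].astype(str):
                    if v not in cats_list:
                        cats_list.append(v)
                cats = tuple(cats_list)
            code = {c: i for i, c in enumerate(cats)}
            vals = np.full(n, np.nan)
            for i, v in enumerate(col):
                if not pd.isna(v):
                    v = str(v)
                    if v not in code:
                        raise ValueError(f"value {v!r} outside declared categories of {name!r}")
                    vals[i] = code[v]
            X[:, j] = vals
            features.append(FeatureMeta(name, "nominal", categories=cats,
                                        missing_fraction=float(miss.sum()) / n))
    return Dataset(X=X, y=y, classes=tuple(class_order), features=features)


_ARFF_ATTR = re.compile(r"@attribute\s+('([^']+)'|\"([^\"]+)\"|(\S+))\s+(.+)",
                        re.IGNORECASE)


def _read_arff(path: Path, label_column: str) -> Dataset:
    names: list[str] = []
    declared: dict[str, tuple[str, ...] | None] = {}
    rows: list[list[str | None]] = []
    in_data = False
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        if in_data:
            cells = [c.strip() for c in line.split(",")]
            rows.append([None if c in MISSING_TOKENS else c.strip("'\"") for c in cells])
            continue
        low = line.lower()
        if low.startswith("@relation"):
            continue
        if low.startswith("@attribute"):
            m = _ARFF_ATTR.match(line)
            if not m:
                raise ValueError(f"unparseable @attribute line: {line!r}")
            name = m.group(2) or m.group(3) or m.group(4)
            typ = m.group(5).strip()
            names.append(name)
            if typ.startswith("{"):
                cats = tuple(c.strip().strip("'\"") for c in typ.strip("{} ").split(","))
                declared[name] = cats
            else:
                declared[name] = None  # numeric/real/integer
            continue
        if low.startswith("@data"):
            in_data = True
    if not names:
        raise ValueError("no @attribute declarations found")
    df = pd.DataFrame(rows, columns=names)
    class_order = declared.get(label_column)
    if class_order is None and label_column in declared:
        raise ValueError("label column must be a nominal ARFF attribute")
    return _dataset_from_frame(df, label_column, declared=declared,
                               class_order=class_order)


def read_table(path: str | Path, format: str | None = None, *,
               label_column: str = "class", delimiter: str = ",") -> Dataset:
    """Read a CSV or ARFF table into a :class:`Dataset`.

    Missing cells are empty strings, ``?`` or ``NA`` (CSV) and ``?``
    (ARFF).  CSV column kinds are inferred (numeric if every value
    parses); ARFF kinds come from the ``@attribute`` declarations.
    """
    path = Path(path)
    if format is None:
        format = "arff" if path.suffix.lower() == ".arff" else "csv"
    if format == "arff":
        return _read_arff(path, label_column)
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False,
                     na_values=list(MISSING_TOKENS), skipinitialspace=True)
    if len(df.columns) == 0:
        raise ValueError("empty file")
    return _dataset_from_frame(df, label_column)


def write_table(d: Dataset, path: str | Path, format: str | None = None, *,
                label_column: str = "class") -> None:
    """Write a Dataset to CSV or ARFF (missing cells as ``?``)."""
    path = Path(path)
    if format is None:
        format = "arff" if path.suffix.lower() == ".arff" else "csv"
    df = d.to_frame().rename(columns={"class": label_column})
    if format == "csv":
        out = df.copy()
        for c in out.columns:
            if out[c].dtype == float:
                out[c] = out[c].map(lambda v: "?" if np.isnan(v) else repr(float(v)))
            else:
                out[c] = out[c].map(lambda v: "?" if v is None else v)
        out.to_csv(path, index=False)
        return
    if format != "arff":
        raise ValueError(f"unknown format {format!r}")
    lines = ["@relation dataset", ""]
    for meta in d.features:
        if meta.kind == "numeric":
            lines.append(f"@attribute {meta.name!r} numeric")
        else:
            cats = ",".join(meta.categories)
            lines.append(f"@attribute {meta.name!r} {{{cats}}}")
    lines.append(f"@attribute {label_column!r} {{{','.join(d.classes)}}}")
    lines.append("")
    lines.append("@data")
    for _, row in df.iterrows():
        cells = []
        for c in df.columns[:-1]:
            v = row[c]
            if v is None or (isinstance(v, float) and np.isnan(v)):
                cells.append("?")
            elif isinstance(v, float):
                cells.append(repr(v))
            else:
                cells.append(str(v))
        cells.append(str(row[label_column]))
        lines.append(",".join(cells))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------

def _check_numeric(d: Dataset, columns: Iterable[str]) -> list[int]:
    idx = []
    for name in columns:
        j = d.column(name)
        if d.features[j].kind != "numeric":
            raise ValueError(f"column {name!r} is nominal; cannot rescale")
        idx.append(j)
    return idx


def zscore_normalize(d: Dataset, columns: Sequence[str] | None = None) -> Dataset:
    """Standardise named numeric columns to mean 0, sample sd 1.

    Statistics use non-missing entries only and the n-1 denominator;
    zero-variance columns map to all zeros; missing cells stay missing.
    """
    if columns is None:
        columns = [f.name for f in d.features if f.kind == "numeric"]
    X = d.X.copy()
    for j in _check_numeric(d, columns):
        col = X[:, j]
        ok = ~np.isnan(col)
        if ok.sum() == 0:
            continue
        mu = col[ok].mean()
        sd = col[ok].std(ddof=1) if ok.sum() > 1 else 0.0
        X[ok, j] = 0.0 if sd == 0 else (col[ok] - mu) / sd
    return d.with_columns(X)


def minmax_normalize(d: Dataset, columns: Sequence[str] | None = None) -> Dataset:
    """Rescale named numeric columns to [0, 1]; constant columns map to 0."""
    if columns is None:
        columns = [f.name for f in d.features if f.kind == "numeric"]
    X = d.X.copy()
    for j in _check_numeric(d, columns):
        col = X[:, j]
        ok = ~np.isnan(col)
        if ok.sum() == 0:
            continue
        lo, hi = col[ok].min(), col[ok].max()
        X[ok, j] = 0.0 if hi == lo else (col[ok] - lo) / (hi - lo)
    return d.with_columns(X)


def drop_high_missing(d: Dataset, threshold: float = 0.40) -> Dataset:
    """Remove every feature whose missing fraction strictly exceeds ``threshold``."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    n = d.n_instances
    keep = [j for j in range(d.n_features)
            if np.isnan(d.X[:, j]).sum() / n <= threshold]
    if not keep:
        raise ValueError("all features exceed the missing-data threshold")
    feats = [replace(d.features[j]) for j in keep]
    return d.with_columns(d.X[:, keep].copy(), feats).refresh_missing_fractions()


def impute_classwise(d: Dataset) -> Dataset:
    """Fill missing cells with within-class means (numeric) or modes (nominal).

    A class with no observed value in a column falls back to the global
    mean/mode.  Mode ties break by category declaration order.  A column
    with no observed values at all cannot be imputed.
    """
    X = d.X.copy()
    for j, meta in enumerate(d.features):
        col = X[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        if miss.all():
            raise ValueError(f"column {meta.name!r} is entirely missing")
        if meta.kind == "numeric":
            global_fill = col[~miss].mean()
        else:
            counts = np.bincount(col[~miss].astype(int), minlength=len(meta.categories))
            global_fill = float(np.argmax(counts))  # argmax = first max = declaration order
        for cls in d.classes:
            rows = d.y == cls
            need = rows & miss
            if not need.any():
                continue
            have = rows & ~miss
            if not have.any():
                fill = global_fill
            elif meta.kind == "numeric":
                fill = col[have].mean()
            else:
                counts = np.bincount(col[have].astype(int), minlength=len(meta.categories))
                fill = float(np.argmax(counts))
            X[need, j] = fill
    return d.with_columns(X).refresh_missing_fractions()


def preprocess(d: Dataset, *, missing_threshold: float = 0.40,
               minmax_columns: Sequence[str] = (),
               log: list[str] | None = None) -> Dataset:
    """Full pipeline in fixed order: drop high-missing -> impute -> rescale.

    Numeric columns named in ``minmax_columns`` are scaled to [0, 1];
    every other numeric column is z-scored.
    """
    before = set(d.feature_names)
    d = drop_high_missing(d, missing_threshold)
    dropped = sorted(before - set(d.feature_names))
    if log is not None and dropped:
        log.append(f"dropped >{missing_threshold:.0%}-missing features: {', '.join(dropped)}")
    had_missing = bool(d.missing_mask.any())
    d = impute_classwise(d)
    if log is not None and had_missing:
        log.append("imputed missing cells with class-wise mean/mode")
    mm = [c for c in minmax_columns if c in d.feature_names]
    zs = [f.name for f in d.features if f.kind == "numeric" and f.name not in mm]
    if mm:
        d = minmax_normalize(d, mm)
        if log is not None:
            log.append(f"min-max normalised: {', '.join(mm)}")
    if zs:
        d = zscore_normalize(d, zs)
        if log is not None:
            log.append(f"z-score normalised {len(zs)} numeric columns")
    return d
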
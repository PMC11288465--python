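"""Core data containers and plain-text I/O.

The whole pipeline moves one object around: a :class:`FeatureTable`, an
``n x D`` matrix of real-valued feature activations with one class label per
row.  Feature selection produces a :class:`FeatureMask`, a binary vector over
the ``D`` columns; :func:`apply_mask` restricts a table to the selected
columns.  Tables are stored as CSV with a header row, a ``sample_id`` column
and a ``label`` column; masks as a single line of ``0``/``1`` characters with
a JSON sidecar.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "FeatureMask",
    "SplitSpec",
    "FeatureTableError",
    "MissingLabelColumnError",
    "NonNumericFeatureError",
    "DuplicateFeatureNameError",
    "NonFiniteValueError",
    "EmptyTableError",
    "MaskError",
    "load_feature_table",
    "save_feature_table",
    "save_mask",
    "load_mask",
    "stratified_split",
    "apply_mask",
]

LABEL_COLUMN = "label"
SAMPLE_ID_COLUMN = "sample_id"


class FeatureTableError(ValueError):
    """Base class for feature-table validation failures."""


class MissingLabelColumnError(FeatureTableError):
    """The declared label column is absent from the file header."""


class NonNumericFeatureError(FeatureTableError):
    """A feature cell could not be parsed as a finite number."""


class DuplicateFeatureNameError(FeatureTableError):
    """Two columns in the header share a name."""


class NonFiniteValueError(FeatureTableError):
    """A feature cell is NaN or infinite."""


class EmptyTableError(FeatureTableError):
    """The table has no rows (or no feature columns)."""


class MaskError(ValueError):
    """A feature mask is structurally invalid for the table at hand."""


@dataclass
class FeatureTable:
    """An ``n x D`` matrix of finite real features with per-row class labels.

    Parameters
    ----------
    values : ndarray of shape (n, D)
        Feature activations; must be finite.
    labels : ndarray of shape (n,)
        Class label per row (any hashable label set).
    feature_names : ndarray of shape (D,)
        Unique column identifiers.
    sample_ids : ndarray of shape (n,)
        Unique row identifiers.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: np.ndarray
    sample_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FeatureTableError("values must be a 2-D matrix")
        self.labels = np.asarray(self.labels, dtype=object)
        self.feature_names = np.asarray(self.feature_names, dtype=object)
        n, d = self.values.shape
        if self.sample_ids is None:
            width = max(4, len(str(max(n - 1, 0))))
            self.sample_ids = np.array([f"s{i:0{width}d}" for i in range(n)], dtype=object)
        else:
            self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if d < 1:
            raise EmptyTableError("a feature table needs at least one feature column")
        if len(self.labels) != n or len(self.sample_ids) != n:
            raise FeatureTableError(
                f"row count mismatch: values has {n} rows, "
                f"{len(self.labels)} labels, {len(self.sample_ids)} sample ids"
            )
        if len(self.feature_names) != d:
            raise FeatureTableError(
                f"{len(self.feature_names)} feature names for {d} columns"
            )
        names, counts = np.unique(self.feature_names.astype(str), return_counts=True)
        if (counts > 1).any():
            dup = names[counts > 1][0]
            raise DuplicateFeatureNameError(f"duplicate feature name: {dup!r}")
        ids, counts = np.unique(self.sample_ids.astype(str), return_counts=True)
        if (counts > 1).any():
            raise FeatureTableError(f"duplicate sample id: {ids[counts > 1][0]!r}")
        bad = ~np.isfinite(self.values)
        if bad.any():
            i, j = (int(v) for v in np.argwhere(bad)[0])
            raise NonFiniteValueError(
                f"non-finite value at row {self.sample_ids[i]!r}, "
                f"column {self.feature_names[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        """Sorted unique labels."""
        return np.array(sorted(set(self.labels)), dtype=object)

    def take(self, rows: Sequence[int]) -> "FeatureTable":
        """Return a new table restricted to the given row indices, in order."""
        rows = np.asarray(rows, dtype=int)
        return FeatureTable(
            values=self.values[rows],
            labels=self.labels[rows],
            feature_names=self.feature_names.copy(),
            sample_ids=self.sample_ids[rows],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names.astype(str))
        df.insert(0, SAMPLE_ID_COLUMN, self.sample_ids.astype(str))
        df[LABEL_COLUMN] = self.labels.astype(str)
        return df


@dataclass
class FeatureMask:
    """A binary selection vector over the D feature columns.

    Invalid (all-zero) masks are rejected: every downstream consumer needs at
    least one feature.
    """

    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits)
        if bits.ndim != 1:
            raise MaskError("mask bits must be a 1-D vector")
        if not np.isin(bits, (0, 1)).all():
            raise MaskError("mask bits must be 0 or 1")
        self.bits = bits.astype(np.uint8)
        if self.n_selected < 1:
            raise MaskError("mask selects no features")

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())

    def __len__(self) -> int:
        return len(self.bits)

    def indices(self) -> np.ndarray:
        """Selected column indices in ascending order."""
        return np.flatnonzero(self.bits)


@dataclass
class SplitSpec:
    """How to split a table into train and test portions.

    ``train_fraction`` defaults to 0.8 (the conventional 80/20 train/test
    division); ``stratified`` keeps per-class proportions.
    """

    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(
                f"train_fraction must lie in (0, 1), got {self.train_fraction}"
            )


# ---------------------------------------------------------------------------
# CSV / mask I/O
# ---------------------------------------------------------------------------

def _read_header(path: Path) -> list[str]:
    with open(path, "r", newline="") as fh:
        reader = csv.reader(fh)
        try:
            return next(reader)
        except StopIteration:
            raise EmptyTableError(f"{path}: file is empty") from None


def load_feature_table(path: str | Path, label_column: str = LABEL_COLUMN) -> FeatureTable:
    """Read a delimited feature table from disk and validate it.

    The file must be comma-separated with a header row containing
    ``label_column``; an optional ``sample_id`` column supplies row ids.
    """
    path = Path(path)
    header = _read_header(path)
    seen: set[str] = set()
    for name in header:
        if name in seen:
            raise DuplicateFeatureNameError(f"{path}: duplicate column {name!r} in header")
        seen.add(name)
    if label_column not in header:
        raise MissingLabelColumnError(
            f"{path}: label column {label_column!r} not in header {header}"
        )
    df = pd.read_csv(
        path, dtype={label_column: str}, keep_default_na=False,
        float_precision="round_trip",
    )
    if SAMPLE_ID_COLUMN in df.columns:
        sample_ids = df[SAMPLE_ID_COLUMN].astype(str).to_numpy()
        df = df.drop(columns=[SAMPLE_ID_COLUMN])
    else:
        sample_ids = None
    labels = df[label_column].to_numpy()
    feats = df.drop(columns=[label_column])
    if feats.shape[1] < 1:
        raise EmptyTableError(f"{path}: no feature columns")
    if feats.shape[0] < 1:
        raise EmptyTableError(f"{path}: no data rows")
    values = np.empty(feats.shape, dtype=float)
    for j, col in enumerate(feats.columns):
        try:
            values[:, j] = pd.to_numeric(feats[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(feats[col], errors="coerce")
            row = int(np.flatnonzero(bad.isna().to_numpy())[0])
            cell = feats[col].iloc[row]
            try:
                parses_as_float = True
                float(cell)
            except (ValueError, TypeError):
                parses_as_float = False
            if parses_as_float:  # parses but is NaN/Inf -> a non-finite cell
                raise NonFiniteValueError(
                    f"{path}: non-finite value at data row {row}, column {col!r}: {cell!r}"
                ) from None
            raise NonNumericFeatureError(
                f"{path}: non-numeric cell at data row {row}, column {col!r}: "
                f"{cell!r}"
            ) from None
        finite = np.isfinite(values[:, j])
        if not finite.all():
            row = int(np.flatnonzero(~finite)[0])
            raise NonFiniteValueError(
                f"{path}: non-finite value at data row {row}, column {col!r}"
            )
    return FeatureTable(
        values=values,
        labels=labels,
        feature_names=feats.columns.to_numpy(dtype=object),
        sample_ids=sample_ids,
    )


def save_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a table as CSV with 17-significant-digit floats.

    17 significant digits make binary doubles round-trip exactly, so
    ``load(save(t))`` reproduces ``t.values`` bit for bit and repeated saves
    are byte-identical.
    """
    if table.n_samples == 0:
        raise EmptyTableError("refusing to write a table with no rows")
    path = Path(path)
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(
        [SAMPLE_ID_COLUMN, *table.feature_names.astype(str), LABEL_COLUMN]
    )
    for i in range(table.n_samples):
        row = [str(table.sample_ids[i])]
        row.extend(repr(float(v)) for v in table.values[i])
        row.append(str(table.labels[i]))
        writer.writerow(row)
    path.write_text(buf.getvalue())


def save_mask(mask: FeatureMask, path: str | Path, feature_names: Sequence[str] | None = None) -> None:
    """Write a mask as one line of 0/1 characters plus a ``.json`` sidecar."""
    path = Path(path)
    path.write_text("".join(str(int(b)) for b in mask.bits) + "\n")
    sidecar = {
        "n_features": len(mask),
        "n_selected": mask.n_selected,
        "feature_names": list(map(str, feature_names)) if feature_names is not None else None,
        "selected_features": (
            [str(feature_names[i]) for i in mask.indices()]
            if feature_names is not None
            else None
        ),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_mask(path: str | Path) -> FeatureMask:
    text = Path(path).read_text().strip()
    if not text or set(text) - {"0", "1"}:
        raise MaskError(f"{path}: mask file must be a single line of 0/1 characters")
    return FeatureMask(bits=np.frombuffer(text.encode(), dtype=np.uint8) - ord("0"))


# ---------------------------------------------------------------------------
# Splitting and masking
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(table: FeatureTable, spec: SplitSpec) -> tuple[FeatureTable, FeatureTable]:
    """Partition a table into train and test portions.

    Under stratification each class contributes ``round(train_fraction * n_c)``
    rows to train (round half up), repaired so both sides keep at least one
    row per class; every class therefore needs >= 2 samples.  Row order within
    each side is shuffled by the seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = table.n_samples
    if spec.stratified:
        train_idx: list[int] = []
        test_idx: list[int] = []
        for cls in table.classes:
            rows = np.flatnonzero(table.labels == cls)
            if len(rows) < 2:
                raise ValueError(
                    f"class {cls!r} has {len(rows)} sample(s); stratified splitting "
                    "needs at least 2 per class"
                )
            k = _round_half_up(spec.train_fraction * len(rows))
            k = min(max(k, 1), len(rows) - 1)
            perm = rng.permutation(rows)
            train_idx.extend(perm[:k])
            test_idx.extend(perm[k:])
        train_idx = list(rng.permutation(train_idx))
        test_idx = list(rng.permutation(test_idx))
    else:
        k = min(max(_round_half_up(spec.train_fraction * n), 1), n - 1)
        perm = rng.permutation(n)
        train_idx = list(perm[:k])
        test_idx = list(perm[k:])
    return table.take(train_idx), table.take(test_idx)


def apply_mask(table: FeatureTable, mask: FeatureMask) -> FeatureTable:
    """Restrict a table to the mask's selected columns, order preserved."""
    if len(mask) != table.n_features:
        raise MaskError(
            f"mask length {len(mask)} does not match table width {table.n_features}"
        )
    idx = mask.indices()
    return FeatureTable(
        values=table.values[:, idx],
        labels=table.labels.copy(),
        feature_names=table.feature_names[idx],
        sample_ids=table.sample_ids.copy(),
    )
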
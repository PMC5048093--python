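"""Labeled multichannel time-series records and their on-disk layout.

A dataset lives in a directory holding a ``manifest.csv`` with columns
``id,file,label,rate,channels,samples`` plus one matrix file per record
(rows = channels, columns = samples).  Two matrix dialects are supported,
auto-detected by extension:

* ``.csv`` / ``.txt`` / ``.tsv`` — delimited float text;
* ``.f32`` / ``.bin`` — raw little-endian float32 preceded by a 3-int32
  header ``(channels, samples, reserved)``.

Labels are ``0`` = normal, ``1`` = abnormal (the positive screening
target); an empty label field means "unlabeled", which is accepted only
in prediction contexts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "TimeSeriesRecord",
    "Dataset",
    "SplitSpec",
    "load_dataset",
    "save_dataset",
    "split_dataset",
]

MANIFEST_NAME = "manifest.csv"
_TEXT_EXTS = {".csv", ".txt", ".tsv"}
_BINARY_EXTS = {".f32", ".bin"}


class FormatError(ValueError):
    """An on-disk file disagrees with the manifest or the layout rules."""


@dataclass
class TimeSeriesRecord:
    """One C-channel, F-sample recording with sampling rate and label."""

    id: str
    data: np.ndarray  # shape (C, F)
    rate: float
    label: int | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.data.ndim != 2 or self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError(f"record {self.id!r}: data must be a C x F matrix with C,F >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"record {self.id!r}: data contains non-finite values")
        if self.rate <= 0:
            raise ValueError(f"record {self.id!r}: sampling rate must be positive")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0 (normal) or 1 (abnormal)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray, rate: float | None = None) -> "TimeSeriesRecord":
        """Copy of this record with new sample values (used by view transforms)."""
        return TimeSeriesRecord(self.id, data, self.rate if rate is None else rate, self.label)


@dataclass
class Dataset:
    """Ordered collection of records sharing channel count and rate."""

    records: list[TimeSeriesRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in dataset")
        if self.records:
            c0, r0 = self.records[0].n_channels, self.records[0].rate
            for r in self.records:
                if r.n_channels != c0:
                    raise ValueError(f"record {r.id!r}: channel count {r.n_channels} != {c0}")
                if r.rate != r0:
                    raise ValueError(f"record {r.id!r}: rate {r.rate} != {r0}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Dataset(self.records[i], dict(self.metadata))
        return self.records[i]

    @property
    def n_channels(self) -> int:
        if not self.records:
            raise ValueError("empty dataset has no channel count")
        return self.records[0].n_channels

    @property
    def rate(self) -> float:
        if not self.records:
            raise ValueError("empty dataset has no rate")
        return self.records[0].rate

    def labels(self) -> np.ndarray:
        """Integer label vector; raises if any record is unlabeled."""
        labs = [r.label for r in self.records]
        if any(l is None for l in labs):
            raise ValueError("dataset contains unlabeled records")
        return np.asarray(labs, dtype=int)

    def subset(self, indices) -> "Dataset":
        return Dataset([self.records[i] for i in indices], dict(self.metadata))

    def map(self, fn) -> "Dataset":
        """Apply a record -> record transform to every record."""
        return Dataset([fn(r) for r in self.records], dict(self.metadata))


@dataclass(frozen=True)
class SplitSpec:
    """Sizes of the train/validation/test partition plus the shuffle seed."""

    n_train: int
    n_val: int
    n_test: int
    shuffle_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_train, self.n_val, self.n_test) < 0:
            raise ValueError("split sizes must be nonnegative")


def _matrix_path(root: Path, fname: str) -> Path:
    return root / fname


def _read_matrix(path: Path, rec_id: str) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"matrix file for record {rec_id!r} not found: {path}")
    ext = path.suffix.lower()
    if ext in _TEXT_EXTS:
        delim = "," if ext == ".csv" else None
        return np.atleast_2d(np.loadtxt(path, delimiter=delim, dtype=float))
    if ext in _BINARY_EXTS:
        with open(path, "rb") as fh:
            header = np.fromfile(fh, dtype="<i4", count=3)
            if header.size != 3:
                raise FormatError(f"record {rec_id!r}: truncated binary header in {path.name}")
            c, f = int(header[0]), int(header[1])
            flat = np.fromfile(fh, dtype="<f4", count=c * f)
        if flat.size != c * f:
            raise FormatError(f"record {rec_id!r}: binary payload shorter than header promises")
        return flat.astype(float).reshape(c, f)
    raise FormatError(f"record {rec_id!r}: unknown matrix extension {ext!r}")


def _write_matrix(path: Path, data: np.ndarray) -> None:
    ext = path.suffix.lower()
    if ext in _TEXT_EXTS:
        delim = "," if ext == ".csv" else " "
        np.savetxt(path, data, delimiter=delim, fmt="%.9g")
    elif ext in _BINARY_EXTS:
        c, f = data.shape
        with open(path, "wb") as fh:
            np.asarray([c, f, 0], dtype="<i4").tofile(fh)
            data.astype("<f4").tofile(fh)
    else:
        raise FormatError(f"unknown matrix extension {ext!r}")


def load_dataset(path: str | Path) -> Dataset:
    """Read a manifest directory into a :class:`Dataset` (manifest order kept)."""
    root = Path(path)
    manifest = root / MANIFEST_NAME
    if not manifest.exists():
        raise FileNotFoundError(f"no {MANIFEST_NAME} in {root}")
    table = pd.read_csv(manifest, dtype={"id": str, "file": str})
    records = []
    for row in table.itertuples(index=False):
        data = _read_matrix(_matrix_path(root, row.file), row.id)
        c, f = int(row.channels), int(row.samples)
        if data.shape != (c, f):
            raise FormatError(
                f"record {row.id!r}: matrix shape {data.shape} does not match "
                f"manifest (channels={c}, samples={f})"
            )
        label = None if pd.isna(row.label) else int(row.label)
        records.append(TimeSeriesRecord(str(row.id), data, float(row.rate), label))
    return Dataset(records, {"source": str(root)})


def save_dataset(ds: Dataset, path: str | Path, fmt: str = "csv") -> None:
    """Write a dataset as manifest + one matrix file per record.

    fmt selects the matrix dialect: "csv" (delimited text) or "binary"
    (raw float32).  Validation runs before any file is written.
    """
    if fmt not in ("csv", "binary"):
        raise ValueError(f"fmt must be 'csv' or 'binary', got {fmt!r}")
    ext = ".csv" if fmt == "csv" else ".f32"
    for rec in ds.records:  # invariants re-checked before touching disk
        if not np.all(np.isfinite(rec.data)):
            raise ValueError(f"record {rec.id!r}: non-finite values, refusing to write")
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in ds.records:
        fname = f"{rec.id}{ext}"
        rows.append(
            {
                "id": rec.id,
                "file": fname,
                "label": "" if rec.label is None else rec.label,
                "rate": rec.rate,
                "channels": rec.n_channels,
                "samples": rec.n_samples,
            }
        )
    pd.DataFrame(rows, columns=["id", "file", "label", "rate", "channels", "samples"]).to_csv(
        root / MANIFEST_NAME, index=False
    )
    for rec in ds.records:
        _write_matrix(root / f"{rec.id}{ext}", rec.data)


def split_dataset(
    ds: Dataset, spec: SplitSpec, merge_train_val: bool = False
) -> tuple[Dataset, Dataset, Dataset]:
    """Deterministic shuffled partition into (train, val, test).

    With ``merge_train_val`` the validation slice is folded into the
    training set (the implicit-training convention) and the returned
    validation dataset is empty.
    """
    total = spec.n_train + spec.n_val + spec.n_test
    if total > len(ds):
        raise ValueError(f"split sizes sum to {total} but dataset has {len(ds)} records")
    order = np.random.default_rng(spec.shuffle_seed).permutation(len(ds))
    i1, i2 = spec.n_train, spec.n_train + spec.n_val
    tr = ds.subset(order[:i1])
    va = ds.subset(order[i1:i2])
    te = ds.subset(order[i2 : i2 + spec.n_test])
    if merge_train_val:
        tr = Dataset(tr.records + va.records, dict(ds.metadata))
        va = Dataset([], dict(ds.metadata))
    return tr, va, te
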
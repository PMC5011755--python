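"""Spectrum I/O and in-memory containers.

A :class:`Spectrum` is one sample's paired m/z axis and intensity vector;
a :class:`SpectrumSet` stacks N samples that share a common m/z grid into
an N x d matrix with an optional binary label vector (1 = cancer/positive,
0 = healthy/negative).

On-disk conventions owned here:

* spectrum file -- 2-column delimited text ``(mz, intensity)``, optional
  one-line header, comma/tab/whitespace separated (auto-sniffed);
* sample sheet -- delimited text with columns ``sample_id, path, label``;
* matrix file -- CSV whose header row carries the m/z grid
  (``sample_id,label,<mz_1>,...,<mz_d>``) and whose data rows carry one
  sample each, written with >= 12 significant digits.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectrumSet",
    "MalformedInputError",
    "LABEL_POSITIVE_TOKENS",
    "LABEL_NEGATIVE_TOKENS",
    "canonical_label",
    "read_spectrum",
    "read_sample_sheet",
    "assemble_set",
    "write_matrix",
    "read_matrix",
]


class MalformedInputError(ValueError):
    """Raised when an on-disk file violates the documented layout."""


#: Case-insensitive tokens accepted as the positive (cancer) class.
LABEL_POSITIVE_TOKENS = frozenset({"cancer", "positive", "1"})
#: Case-insensitive tokens accepted as the negative (healthy) class.
LABEL_NEGATIVE_TOKENS = frozenset({"healthy", "negative", "0"})


def canonical_label(token: object) -> int:
    """Map a label token to the canonical binary encoding (1 = cancer)."""
    s = str(token).strip().lower()
    if s in LABEL_POSITIVE_TOKENS:
        return 1
    if s in LABEL_NEGATIVE_TOKENS:
        return 0
    raise ValueError(
        f"unknown label token {token!r}; expected one of "
        f"{sorted(LABEL_POSITIVE_TOKENS | LABEL_NEGATIVE_TOKENS)} (case-insensitive)"
    )


@dataclass
class Spectrum:
    """One sample: m/z axis (strictly increasing) and intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    label: int | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("mz and intensity must be 1-D vectors")
        if self.mz.size != self.intensity.size:
            raise ValueError(
                f"mz length {self.mz.size} != intensity length {self.intensity.size}"
            )
        if self.mz.size < 2:
            raise MalformedInputError("a spectrum needs at least 2 points")
        if not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz must be strictly increasing (no duplicates)")

    def __len__(self) -> int:
        return int(self.mz.size)

    def replace(self, **kw) -> "Spectrum":
        d = dict(mz=self.mz, intensity=self.intensity, label=self.label,
                 sample_id=self.sample_id)
        d.update(kw)
        return Spectrum(**d)


@dataclass
class SpectrumSet:
    """N samples on a shared m/z grid: N x d matrix + labels."""

    grid: np.ndarray
    X: np.ndarray
    labels: np.ndarray | None = None
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if self.X.shape[1] != self.grid.size:
            raise ValueError(
                f"X has {self.X.shape[1]} columns but grid has {self.grid.size} points"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.size != self.X.shape[0]:
                raise ValueError("labels length must equal the number of rows")
        if not self.sample_ids:
            self.sample_ids = [f"sample{i}" for i in range(self.X.shape[0])]
        if len(self.sample_ids) != self.X.shape[0]:
            raise ValueError("sample_ids length must equal the number of rows")

    @property
    def n_samples(self) -> int:
        return int(self.X.shape[0])

    @property
    def n_points(self) -> int:
        return int(self.grid.size)

    def require_labels(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("this operation needs class labels, but the set has none")
        if len(np.unique(self.labels)) != 2:
            raise ValueError("supervised operations need exactly two classes present")
        return self.labels


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_NUMERIC_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _sniff_delimiter(line: str) -> str | None:
    """Return ',' or tab if present, else None (whitespace split)."""
    if "," in line:
        return ","
    if "\t" in line:
        return "\t"
    return None


def read_spectrum(path: str | Path, dialect: str = "mz-intensity") -> Spectrum:
    """Read a 2-column (m/z, intensity) text file into a Spectrum.

    The result is sorted by m/z; duplicated m/z points are averaged and a
    warning is emitted.  ``dialect`` names the column convention; only the
    default ``"mz-intensity"`` order is defined.
    """
    if dialect != "mz-intensity":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            delim = _sniff_delimiter(line)
            parts = [p for p in (line.split(delim) if delim else line.split()) if p.strip()]
            if len(parts) != 2:
                raise MalformedInputError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(parts)}"
                )
            a, b = parts[0].strip(), parts[1].strip()
            if not (_NUMERIC_RE.match(a) and _NUMERIC_RE.match(b)):
                if lineno == 1 and not rows:
                    continue  # one-line header
                raise MalformedInputError(
                    f"{path}: line {lineno}: non-numeric row {line!r}"
                )
            rows.append((float(a), float(b)))
    if len(rows) < 2:
        raise MalformedInputError(f"{path}: fewer than 2 data points")
    arr = np.asarray(rows, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    mz, inv, counts = np.unique(arr[:, 0], return_inverse=True, return_counts=True)
    if mz.size != arr.shape[0]:
        dup = mz[counts > 1]
        warnings.warn(
            f"{path}: {arr.shape[0] - mz.size} duplicate m/z point(s) averaged "
            f"(first at m/z {dup[0]:g})",
            stacklevel=2,
        )
        intensity = np.bincount(inv, weights=arr[:, 1]) / counts
    else:
        intensity = arr[:, 1]
    return Spectrum(mz=mz, intensity=intensity, sample_id=path.stem)


def read_sample_sheet(path: str | Path) -> list[tuple[str, Path, int]]:
    """Read a sample sheet into an ordered list of (sample_id, path, label).

    Columns ``sample_id, path, label`` with or without a header row; label
    tokens are mapped to the canonical binary encoding.  Relative spectrum
    paths are resolved against the sheet's directory.
    """
    path = Path(path)
    out: list[tuple[str, Path, int]] = []
    with open(path, newline="") as fh:
        sample = fh.read()
    delim = _sniff_delimiter(sample.splitlines()[0]) if sample.strip() else ","
    reader = csv.reader(sample.splitlines(), delimiter=delim or "\t")
    for i, row in enumerate(reader):
        row = [c.strip() for c in row if c.strip()]
        if not row:
            continue
        if len(row) != 3:
            raise MalformedInputError(
                f"{path}: row {i + 1}: expected 3 columns, got {len(row)}"
            )
        sid, p, tok = row
        if i == 0 and tok.lower() == "label":
            continue  # header
        label = canonical_label(tok)
        spath = Path(p)
        if not spath.is_absolute():
            spath = path.parent / spath
        if not spath.exists():
            raise FileNotFoundError(f"{path}: sample {sid!r} references missing file {spath}")
        out.append((sid, spath, label))
    return out


def assemble_set(spectra: Sequence[Spectrum]) -> SpectrumSet:
    """Stack spectra that share a bitwise-identical m/z grid into a set."""
    if not spectra:
        raise ValueError("assemble_set needs at least one spectrum")
    grid = spectra[0].mz
    for s in spectra[1:]:
        if s.mz.shape != grid.shape or not np.array_equal(s.mz, grid):
            raise ValueError(
                f"spectrum {s.sample_id!r} is on a different m/z grid; "
                "resample all spectra onto a common grid first"
            )
    X = np.vstack([s.intensity for s in spectra])
    labels_list = [s.label for s in spectra]
    labels = None
    if all(l is not None for l in labels_list):
        labels = np.asarray(labels_list, dtype=int)
    ids = [s.sample_id or f"sample{i}" for i, s in enumerate(spectra)]
    return SpectrumSet(grid=grid, X=X, labels=labels, sample_ids=ids)


def write_matrix(sset: SpectrumSet, path: str | Path) -> Path:
    """Write a SpectrumSet as CSV (header = grid, one sample per row)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "label"] + [f"{v:.12g}" for v in sset.grid])
        for i in range(sset.n_samples):
            lab = "" if sset.labels is None else str(int(sset.labels[i]))
            w.writerow([sset.sample_ids[i], lab] +
                       [f"{v:.12g}" for v in sset.X[i]])
    return path


def read_matrix(path: str | Path) -> SpectrumSet:
    """Read a matrix file written by :func:`write_matrix`."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str}, keep_default_na=False,
                     na_values=[""])
    if df.columns[0] != "sample_id" or df.columns[1] != "label":
        raise MalformedInputError(
            f"{path}: header must start with 'sample_id,label', got {list(df.columns[:2])}"
        )
    try:
        grid = np.asarray([float(c) for c in df.columns[2:]])
    except ValueError as e:
        raise MalformedInputError(f"{path}: non-numeric m/z header entry ({e})") from e
    vals = df.iloc[:, 2:]
    if vals.isna().any().any():
        bad = int(np.where(vals.isna().any(axis=1))[0][0])
        raise MalformedInputError(f"{path}: ragged/short data row at index {bad}")
    X = vals.to_numpy(dtype=float)
    labels = None
    if not df["label"].isna().all():
        if df["label"].isna().any():
            raise MalformedInputError(f"{path}: label column is partially filled")
        labels = df["label"].astype(int).to_numpy()
    return SpectrumSet(grid=grid, X=X, labels=labels,
                       sample_ids=df["sample_id"].tolist())
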
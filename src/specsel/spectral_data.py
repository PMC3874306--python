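"""Labeled spectral sample sets: data model, CSV I/O, role splits, projection.

A sample is one absorbance spectrum (V variables, 1-based indexing at every
interface) with a categorical concentration label and a role tag
(``train`` / ``test`` / ``commercial``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

ROLES = ("train", "test", "commercial")

# 17 significant digits make the text round trip of a float64 exact.
_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class Sample:
    """One spectrum with its class label and partition role."""

    spectrum: np.ndarray
    label: str
    role: str

    def __post_init__(self) -> None:
        spec = np.asarray(self.spectrum, dtype=np.float64)
        if spec.ndim != 1:
            raise DataError("spectrum must be one-dimensional")
        if not np.all(np.isfinite(spec)):
            raise DataError("spectrum contains non-finite absorbance values")
        if self.role not in ROLES:
            raise DataError(
                f"unknown role {self.role!r}; expected one of {ROLES}"
            )
        object.__setattr__(self, "spectrum", spec)


@dataclass(frozen=True)
class SampleSet:
    """An ordered collection of samples over a fixed set of V variables.

    ``class_levels`` is the ordered set of admissible labels; every sample
    label must be a member.  Variables are addressed 1..V at all interfaces.
    """

    samples: tuple[Sample, ...]
    variable_count: int
    class_levels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        samples = tuple(self.samples)
        if self.variable_count <= 0:
            raise DataError("variable_count must be positive")
        levels = tuple(self.class_levels)
        if not levels:
            seen: dict[str, None] = {}
            for s in samples:
                seen.setdefault(s.label, None)
            levels = tuple(seen)
        if len(set(levels)) != len(levels):
            raise DataError("class_levels contains duplicates")
        for i, s in enumerate(samples):
            if s.spectrum.shape[0] != self.variable_count:
                raise DataError(
                    f"sample {i}: spectrum length {s.spectrum.shape[0]} "
                    f"!= variable_count {self.variable_count}"
                )
            if s.label not in levels:
                raise DataError(
                    f"sample {i}: label {s.label!r} not in class_levels"
                )
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "class_levels", levels)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[Sample]:
        return iter(self.samples)

    @property
    def matrix(self) -> np.ndarray:
        """Samples-by-variables absorbance matrix (n, V)."""
        if not self.samples:
            return np.empty((0, self.variable_count))
        return np.vstack([s.spectrum for s in self.samples])

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=object)

    @property
    def roles(self) -> np.ndarray:
        return np.array([s.role for s in self.samples], dtype=object)

    def replace_samples(self, samples: Iterable[Sample]) -> "SampleSet":
        return SampleSet(tuple(samples), self.variable_count, self.class_levels)


def from_arrays(
    matrix: np.ndarray,
    labels: Sequence[str],
    roles: Sequence[str],
    class_levels: Sequence[str] | None = None,
) -> SampleSet:
    """Build a SampleSet from parallel arrays."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2:
        raise DataError("matrix must be 2-dimensional")
    if not (matrix.shape[0] == len(labels) == len(roles)):
        raise DataError("matrix, labels and roles must agree in length")
    samples = tuple(
        Sample(matrix[i], str(labels[i]), str(roles[i]))
        for i in range(matrix.shape[0])
    )
    levels = tuple(str(c) for c in class_levels) if class_levels else ()
    return SampleSet(samples, matrix.shape[1], levels)


def load_spectra(path: str | Path, fmt: str = "csv") -> SampleSet:
    """Read a sample-set CSV (columns ``label,role,v1..vV``).

    V is inferred from the header.  Rows with a missing/invalid label or
    role, or a non-numeric absorbance, raise :class:`DataError` naming the
    offending row or cell.
    """
    if fmt != "csv":
        raise DataError(f"unsupported format {fmt!r}")
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    for col in ("label", "role"):
        if col not in df.columns:
            raise DataError(f"missing required column {col!r} in {path}")
    var_cols = [c for c in df.columns if c not in ("label", "role")]
    expected = [f"v{i}" for i in range(1, len(var_cols) + 1)]
    if var_cols != expected:
        raise DataError(
            f"variable columns must be v1..v{len(var_cols)} in order; got "
            f"{var_cols[:5]}..."
        )
    v = len(var_cols)
    if v == 0:
        raise DataError("no variable columns found")
    samples = []
    for row_i, row in enumerate(df.itertuples(index=False), start=2):
        label = getattr(row, "label")
        role = getattr(row, "role")
        if label is None or (isinstance(label, float) and np.isnan(label)):
            raise DataError(f"row {row_i}: missing label")
        if role not in ROLES:
            raise DataError(
                f"row {row_i}: role {role!r} is not one of {ROLES}"
            )
        values = np.empty(v)
        for j, col in enumerate(var_cols):
            raw = getattr(row, col)
            try:
                values[j] = float(raw)
            except (TypeError, ValueError):
                raise DataError(
                    f"row {row_i}, column {col}: non-numeric absorbance "
                    f"{raw!r}"
                ) from None
        if not np.all(np.isfinite(values)):
            bad = var_cols[int(np.flatnonzero(~np.isfinite(values))[0])]
            raise DataError(f"row {row_i}, column {bad}: non-finite absorbance")
        samples.append(Sample(values, str(label), str(role)))
    return SampleSet(tuple(samples), v)


def save_spectra(sample_set: SampleSet, path: str | Path) -> None:
    """Write a CSV that :func:`load_spectra` reads back identically.

    Absorbances are printed with 17 significant digits so the float64
    round trip is exact.
    """
    path = Path(path)
    v = sample_set.variable_count
    header = ["label", "role"] + [f"v{i}" for i in range(1, v + 1)]
    lines = [",".join(header)]
    for s in sample_set:
        cells = [s.label, s.role] + [_FLOAT_FMT % x for x in s.spectrum]
        lines.append(",".join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def split_by_role(sample_set: SampleSet) -> tuple[SampleSet, SampleSet, SampleSet]:
    """Partition into (train, test, commercial); empty parts are allowed.

    All three parts keep the parent's variable count and class levels.
    """
    parts = []
    for role in ROLES:
        subset = tuple(s for s in sample_set if s.role == role)
        parts.append(
            SampleSet(subset, sample_set.variable_count, sample_set.class_levels)
        )
    return tuple(parts)  # type: ignore[return-value]


def project_variables(sample_set: SampleSet, subset) -> SampleSet:
    """Restrict every spectrum to the 1-based variable indices in ``subset``.

    ``subset`` may be a sequence of indices or anything with a ``genes``
    attribute.  Output column j is input column ``subset[j]``; labels and
    roles are unchanged.
    """
    genes = getattr(subset, "genes", subset)
    indices = [int(g) for g in genes]
    v = sample_set.variable_count
    for g in indices:
        if not 1 <= g <= v:
            raise DataError(f"variable index {g} out of range 1..{v}")
    cols = np.array(indices, dtype=int) - 1
    samples = tuple(
        Sample(s.spectrum[cols], s.label, s.role) for s in sample_set
    )
    return SampleSet(samples, len(indices), sample_set.class_levels)
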
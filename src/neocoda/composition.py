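"""Aitchison-simplex machinery: closure, core-genus selection, zero
replacement, the isometric log-ratio (ilr) transform and its inverse, and
the Aitchison distance.

A D-part composition carries only relative information; the natural sample
space is the simplex and the natural geometry is Aitchison's.  The ilr
transform maps the simplex isometrically onto R^(D-1) through an orthonormal
log-contrast basis, where ordinary multivariate statistics (regression,
MANOVA, Euclidean clustering) are valid.  Every statistic downstream that
matters is invariant to the particular orthonormal basis; the Helmert-type
basis built here is just a convenient default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_tables import AbundanceTable

__all__ = [
    "CompositionMatrix",
    "IlrBasis",
    "IlrCoordinates",
    "closure",
    "from_abundance",
    "select_core",
    "impute_zeros",
    "default_delta",
    "make_ilr_basis",
    "ilr",
    "ilr_inverse",
    "aitchison_distance",
    "group_mean_composition",
]

_SIMPLEX_TOL = 1e-9


@dataclass
class CompositionMatrix:
    """Samples x parts matrix of relative abundances, each row on the simplex."""

    parts: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.parts)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.parts)} parts"
            )
        if np.any(self.values < 0):
            raise ValueError("negative entry in composition matrix")
        bad = np.flatnonzero(np.abs(self.values.sum(axis=1) - 1.0) > _SIMPLEX_TOL)
        if bad.size:
            raise ValueError(
                f"rows not on the simplex (sum != 1): {[self.samples[i] for i in bad]}"
            )

    @property
    def n_parts(self) -> int:
        return len(self.parts)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def row(self, sample_id: str) -> np.ndarray:
        return self.values[self.samples.index(sample_id)]


@dataclass
class IlrBasis:
    """Orthonormal log-contrast basis: a (D-1) x D matrix whose rows are
    orthonormal and orthogonal to the all-ones vector."""

    parts: list[str]
    contrasts: np.ndarray

    def __post_init__(self) -> None:
        self.contrasts = np.asarray(self.contrasts, dtype=float)
        D = len(self.parts)
        if self.contrasts.shape != (D - 1, D):
            raise ValueError(f"contrast matrix must be {(D - 1, D)}")
        gram = self.contrasts @ self.contrasts.T
        if not np.allclose(gram, np.eye(D - 1), atol=1e-10):
            raise ValueError("contrast rows are not orthonormal")
        if not np.allclose(self.contrasts.sum(axis=1), 0.0, atol=1e-10):
            raise ValueError("contrast rows are not orthogonal to the ones vector")


@dataclass
class IlrCoordinates:
    """n x (D-1) real coordinates of compositions under a given basis."""

    samples: list[str]
    basis: IlrBasis
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        D = len(self.basis.parts)
        if self.coords.shape != (len(self.samples), D - 1):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.samples)} samples x {D - 1} coordinates"
            )


def _as_matrix(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    return arr


def closure(values, parts: Sequence[str] | None = None,
            samples: Sequence[str] | None = None) -> CompositionMatrix:
    """Normalise nonnegative rows to unit sum (relative abundances).

    Idempotent; a row of all zeros carries no relative information and is
    rejected by name.
    """
    arr = _as_matrix(values)
    n, D = arr.shape
    parts = list(parts) if parts is not None else [f"part{j + 1}" for j in range(D)]
    samples = list(samples) if samples is not None else [f"s{i + 1}" for i in range(n)]
    if np.any(arr < 0):
        raise ValueError("closure requires nonnegative entries")
    sums = arr.sum(axis=1)
    zero = np.flatnonzero(sums <= 0)
    if zero.size:
        raise ValueError(f"all-zero rows cannot be closed: {[samples[i] for i in zero]}")
    return CompositionMatrix(parts, samples, arr / sums[:, None])


def from_abundance(table: AbundanceTable) -> CompositionMatrix:
    """Close an abundance table (taxa x samples) into samples x parts."""
    return closure(table.counts.T, parts=table.taxa, samples=table.samples)


def select_core(comp: CompositionMatrix, k: int) -> CompositionMatrix:
    """Keep the k genera with the largest mean relative abundance, re-closed.

    Ties at the selection boundary go to the lexicographically smaller
    label so the core is deterministic.
    """
    if not 1 <= k <= comp.n_parts:
        raise ValueError(f"k must be in 1..{comp.n_parts}, got {k}")
    means = comp.values.mean(axis=0)
    # sort by descending mean, then ascending label
    order = sorted(range(comp.n_parts), key=lambda j: (-means[j], comp.parts[j]))
    keep = sorted(order[:k])  # preserve original part order
    sub = comp.values[:, keep]
    sums = sub.sum(axis=1)
    empty = np.flatnonzero(sums <= 0)
    if empty.size:
        raise ValueError(
            "samples with zero total abundance over the selected core: "
            f"{[comp.samples[i] for i in empty]}"
        )
    return CompositionMatrix([comp.parts[j] for j in keep], list(comp.samples),
                             sub / sums[:, None])


def default_delta(comp: CompositionMatrix) -> float:
    """Default zero-replacement value: half the smallest nonzero relative
    abundance in the matrix, capped below 1/D^2."""
    nz = comp.values[comp.values > 0]
    if nz.size == 0:
        raise ValueError("composition matrix has no nonzero entries")
    return float(min(0.5 * nz.min(), 0.5 / comp.n_parts ** 2))


def impute_zeros(comp: CompositionMatrix, delta: float | None = None) -> CompositionMatrix:
    """Multiplicative simple zero replacement.

    Zeros become ``delta``; each nonzero entry x in a row with z zeros is
    scaled to x*(1 - z*delta), so the row still sums to 1 and the ratios
    among nonzero parts are untouched.  Rows without zeros are returned
    unchanged.
    """
    if delta is None:
        delta = default_delta(comp)
    if not 0 < delta < 1 / comp.n_parts:
        raise ValueError(f"delta must be in (0, 1/D); got {delta}")
    vals = comp.values.copy()
    z = (vals == 0).sum(axis=1)
    rows = np.flatnonzero(z)
    for i in rows:
        mask = vals[i] == 0
        vals[i, ~mask] *= 1.0 - z[i] * delta
        vals[i, mask] = delta
    return CompositionMatrix(list(comp.parts), list(comp.samples), vals)


def make_ilr_basis(parts: Sequence[str]) -> IlrBasis:
    """Helmert-type orthonormal basis in the given part order.

    Row j (1-based) contrasts the geometric mean of the first j parts
    against part j+1: entries (1/j, ..., 1/j, -1, 0, ...) scaled by
    sqrt(j/(j+1)).
    """
    D = len(parts)
    if D < 2:
        raise ValueError("need at least 2 parts for an ilr basis")
    V = np.zeros((D - 1, D))
    for j in range(1, D):
        V[j - 1, :j] = 1.0 / j
        V[j - 1, j] = -1.0
        V[j - 1] *= np.sqrt(j / (j + 1.0))
    return IlrBasis(list(parts), V)


def ilr(comp: CompositionMatrix, basis: IlrBasis | None = None) -> IlrCoordinates:
    """Isometric log-ratio transform: coords = ln(values) @ contrasts.T."""
    if basis is None:
        basis = make_ilr_basis(comp.parts)
    if basis.parts != comp.parts:
        raise ValueError("basis parts do not match composition parts")
    if np.any(comp.values <= 0):
        raise ValueError("ilr requires strictly positive entries; run impute_zeros first")
    coords = np.log(comp.values) @ basis.contrasts.T
    return IlrCoordinates(list(comp.samples), basis, coords)


def ilr_inverse(coords, basis: IlrBasis,
                samples: Sequence[str] | None = None) -> CompositionMatrix:
    """Map ilr coordinates back to the simplex (softmax of coords @ contrasts)."""
    if isinstance(coords, IlrCoordinates):
        samples = coords.samples if samples is None else list(samples)
        arr = coords.coords
    else:
        arr = _as_matrix(coords)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite ilr coordinate")
    D = len(basis.parts)
    if arr.shape[1] != D - 1:
        raise ValueError(f"expected {D - 1} coordinates, got {arr.shape[1]}")
    logx = arr @ basis.contrasts
    logx -= logx.max(axis=1, keepdims=True)   # stable softmax
    ex = np.exp(logx)
    vals = ex / ex.sum(axis=1, keepdims=True)
    if samples is None:
        samples = [f"s{i + 1}" for i in range(arr.shape[0])]
    return CompositionMatrix(list(basis.parts), list(samples), vals)


def aitchison_distance(x, y) -> float:
    """Distance between two strictly positive compositions: the Euclidean
    distance of their ilr images.  Basis-independent and scale-invariant."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("compositions must have the same number of parts")
    if np.any(xa <= 0) or np.any(ya <= 0):
        raise ValueError("Aitchison distance requires strictly positive parts")
    lx, ly = np.log(xa), np.log(ya)
    clr_x = lx - lx.mean()
    clr_y = ly - ly.mean()
    return float(np.linalg.norm(clr_x - clr_y))


def group_mean_composition(comp: CompositionMatrix,
                           grouping: Mapping[str, str]) -> CompositionMatrix:
    """Arithmetic mean of relative frequencies per part within each group,
    re-closed (a mean of unit-sum rows already sums to 1)."""
    missing = [s for s in comp.samples if s not in grouping]
    if missing:
        raise KeyError(f"samples without a group: {missing}")
    groups: list[str] = []
    for s in comp.samples:
        g = grouping[s]
        if g not in groups:
            groups.append(g)
    rows = []
    for g in groups:
        idx = [i for i, s in enumerate(comp.samples) if grouping[s] == g]
        if not idx:
            raise ValueError(f"empty group {g!r}")
        rows.append(comp.values[idx].mean(axis=0))
    return closure(np.vstack(rows), parts=comp.parts, samples=groups)
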
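"""Closure and isometric log-ratio (pivot coordinate) geometry for 5-part days.

A day of behaviour is a composition: five strictly positive durations
(sitting, standing, light physical activity, moderate-to-vigorous physical
activity, sleeping) carrying only relative information once closed to a
constant total of 1440 min. All statistics in this package operate on
isometric log-ratio (ilr) coordinates, the orthonormal pivot-coordinate
construction in which the first coordinate contrasts a chosen lead behaviour
against the geometric mean of the remaining four:

    ilr1 = sqrt(4/5) * ln( x1 / (x2 * x3 * x4 * x5)**(1/4) )

and coordinate j contrasts part j against the geometric mean of the parts
after it. Reordering which behaviour leads ("permutation principle") rotates
the coordinates but leaves all distances, fits and predictions unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PARTS",
    "TOTAL_MINUTES",
    "IlrBasis",
    "CANONICAL_BASIS",
    "close",
    "ilr_transform",
    "ilr_inverse",
    "reorder_basis",
    "geometric_mean_composition",
    "as_parts_array",
    "minutes_to_hmm",
]

#: Canonical behaviour order; matches the lead-sitting ilr1 contrast.
PARTS: tuple[str, ...] = ("sitting", "standing", "lpa", "mvpa", "sleeping")

#: Minutes in a day; the closure constant for all compositions.
TOTAL_MINUTES: float = 1440.0

_D = len(PARTS)


class ZeroPartError(ValueError):
    """A behaviour duration is zero or negative; log-ratios are undefined."""


def as_parts_array(parts, *, name: str = "composition") -> np.ndarray:
    """Coerce to a float array with trailing dimension 5, validating positivity.

    Accepts a length-5 sequence, an (n, 5) array, a pandas Series indexed by
    part names, or a DataFrame with the five canonical columns.
    """
    if hasattr(parts, "columns"):  # DataFrame
        missing = [p for p in PARTS if p not in parts.columns]
        if missing:
            raise KeyError(f"missing behaviour columns: {missing}")
        arr = np.asarray(parts.loc[:, list(PARTS)], dtype=float)
    elif hasattr(parts, "to_frame") and set(PARTS) <= set(parts.index):  # Series
        arr = np.asarray([parts[p] for p in PARTS], dtype=float)
    else:
        arr = np.asarray(parts, dtype=float)
    if arr.shape[-1] != _D:
        raise ValueError(f"{name} must have {_D} parts, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    if np.any(arr <= 0):
        bad = np.argwhere(arr <= 0)
        part = PARTS[int(bad[0][-1])]
        raise ZeroPartError(
            f"{name} has non-positive duration for part '{part}' "
            "(log-ratio analysis is undefined on zeros)"
        )
    return arr


def close(parts, total: float = TOTAL_MINUTES) -> np.ndarray:
    """Rescale positive parts proportionally so they sum to ``total``.

    Works row-wise on (n, 5) input. Idempotent; raises :class:`ZeroPartError`
    on non-positive parts.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    arr = as_parts_array(parts)
    s = arr.sum(axis=-1, keepdims=True)
    return arr * (total / s)


@dataclass(frozen=True)
class IlrBasis:
    """Pivot-coordinate ilr basis for the five behaviours.

    ``part_order`` is the permutation used for the sequential contrasts; the
    first entry is the lead behaviour of ilr1. The contrast matrix maps
    log-durations (in canonical column order) to the 4 ilr coordinates.
    """

    part_order: tuple[str, ...] = PARTS

    def __post_init__(self):
        if sorted(self.part_order) != sorted(PARTS):
            raise ValueError(
                f"part_order must be a permutation of {PARTS}, got {self.part_order}"
            )

    @property
    def D(self) -> int:
        return _D

    @property
    def coefficients(self) -> np.ndarray:
        """Normalising constants sqrt((D-j)/(D-j+1)) for j = 1..D-1."""
        j = np.arange(1, _D)
        return np.sqrt((_D - j) / (_D - j + 1.0))

    @property
    def contrast_matrix(self) -> np.ndarray:
        """(5, 4) matrix V with ilr(x) = ln(x) @ V for canonical-order x.

        Columns are orthonormal and orthogonal to the vector of ones, so the
        map is an isometry from the simplex (Aitchison metric) to R^4.
        """
        V = np.zeros((_D, _D - 1))
        order = [PARTS.index(p) for p in self.part_order]
        coef = self.coefficients
        for j in range(_D - 1):  # pivot j+1 contrasts part j vs later parts
            V[order[j], j] = coef[j]
            tail = order[j + 1 :]
            V[tail, j] = -coef[j] / (_D - j - 1)
        return V


CANONICAL_BASIS = IlrBasis(PARTS)


def reorder_basis(basis: IlrBasis, lead_part: str) -> IlrBasis:
    """Return a basis with ``lead_part`` first, remaining parts keeping their
    relative order (the permutation-principle reordering)."""
    if lead_part not in PARTS:
        raise ValueError(f"unknown part {lead_part!r}; expected one of {PARTS}")
    rest = tuple(p for p in basis.part_order if p != lead_part)
    return IlrBasis((lead_part,) + rest)


def ilr_transform(parts, basis: IlrBasis = CANONICAL_BASIS) -> np.ndarray:
    """Map composition(s) to 4 pivot ilr coordinates.

    Scale-invariant: closure before transforming is unnecessary (only ratios
    enter). Input rows are canonical-order durations; output is (..., 4).
    """
    arr = as_parts_array(parts)
    return np.log(arr) @ basis.contrast_matrix


def ilr_inverse(
    coords, basis: IlrBasis = CANONICAL_BASIS, total: float = TOTAL_MINUTES
) -> np.ndarray:
    """Invert ilr coordinates to a composition closed to ``total`` minutes."""
    z = np.asarray(coords, dtype=float)
    if z.shape[-1] != _D - 1:
        raise ValueError(f"expected {_D - 1} ilr coordinates, got shape {z.shape}")
    if not np.all(np.isfinite(z)):
        raise ValueError("ilr coordinates must be finite")
    clr = z @ basis.contrast_matrix.T
    return close(np.exp(clr), total)


def geometric_mean_composition(sample, total: float = TOTAL_MINUTES) -> np.ndarray:
    """Compositional centre: part-wise geometric mean, closed to ``total``.

    This is the reference point from which isotemporal reallocations start.
    """
    arr = as_parts_array(sample, name="sample")
    arr = np.atleast_2d(arr)
    if arr.shape[0] == 0:
        raise ValueError("sample of compositions is empty")
    gm = np.exp(np.log(arr).mean(axis=0))
    return close(gm, total)


def minutes_to_hmm(minutes: float) -> str:
    """Render minutes/day as an ``h:mm`` string, e.g. 400 -> '6:40'."""
    m = int(round(minutes))
    return f"{m // 60}:{m % 60:02d}"
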
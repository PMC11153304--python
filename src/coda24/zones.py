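"""Exhaustive grid search for optimal 24 h compositions.

Candidate days are enumerated on a 10-minute lattice inside the empirical
footprint (the 1st-99th percentile band of each behaviour), keeping only
combinations that sum to exactly 24 h. Each candidate is scored by the
compositional part of a fitted model's linear predictor (covariates shift
every candidate equally and cancel in the ranking); the best ``fraction``
(default top 5%, direction-aware per outcome) forms that outcome's optimal
zone. The cross-outcome overlapping optimal zone is the intersection of the
per-outcome zones, escalating the fraction from 5% towards 10% in 1% steps
until the intersection is non-empty. Zones are summarised by their
compositional centre (geometric mean, rounded to the nearest 10 min — the
rounded parts need not sum to exactly 24 h) and per-behaviour min-max
ranges.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import (
    PARTS,
    TOTAL_MINUTES,
    as_parts_array,
    close,
    geometric_mean_composition,
    ilr_transform,
    minutes_to_hmm,
)
from .regression import ModelFit

__all__ = [
    "GridFootprint",
    "MAASTRICHT_FOOTPRINT",
    "ZoneReport",
    "OptimalZone",
    "compute_footprint",
    "enumerate_grid",
    "rank_and_select",
    "zone_summary",
    "overlap_zone",
    "export_tetrahedron_coords",
]


@dataclass(frozen=True)
class GridFootprint:
    """Per-behaviour inclusive bounds (minutes, multiples of ``step``)."""

    lower: tuple[float, ...]
    upper: tuple[float, ...]
    step: float = 10.0
    total: float = TOTAL_MINUTES

    def __post_init__(self):
        lo, up = np.asarray(self.lower, float), np.asarray(self.upper, float)
        if lo.shape != (len(PARTS),) or up.shape != (len(PARTS),):
            raise ValueError(f"bounds must have {len(PARTS)} entries")
        if np.any(lo > up):
            raise ValueError("lower bound exceeds upper bound for some part")
        if np.any(np.abs(np.round(lo / self.step) * self.step - lo) > 1e-9) or np.any(
            np.abs(np.round(up / self.step) * self.step - up) > 1e-9
        ):
            raise ValueError(f"bounds must be multiples of step={self.step}")
        if lo.sum() > self.total or up.sum() < self.total:
            raise ValueError(
                f"infeasible footprint: lower sum {lo.sum():.0f} / upper sum "
                f"{up.sum():.0f} cannot bracket {self.total:.0f} min"
            )


#: Published cohort footprint (1st-99th percentile band, minutes): sitting
#: 5:40-13:20, standing 1:40-7:50, LPA 0:30-2:20, MVPA 0:10-2:20, sleeping
#: 6:20-10:40. Enumerating this on the 10-min lattice gives 142,938 days.
MAASTRICHT_FOOTPRINT = GridFootprint(
    lower=(340, 100, 30, 10, 380), upper=(800, 470, 140, 140, 640)
)


def compute_footprint(
    sample,
    lower_pct: float = 1.0,
    upper_pct: float = 99.0,
    step: float = 10.0,
    total: float = TOTAL_MINUTES,
) -> GridFootprint:
    """Empirical footprint: per-part percentiles rounded to the nearest step."""
    arr = np.atleast_2d(as_parts_array(sample, name="sample"))
    if arr.shape[0] < 100:
        warnings.warn(
            f"footprint estimated from only {arr.shape[0]} participants; "
            "percentiles will be unstable",
            stacklevel=2,
        )
    lo = np.round(np.percentile(arr, lower_pct, axis=0) / step) * step
    up = np.round(np.percentile(arr, upper_pct, axis=0) / step) * step
    return GridFootprint(tuple(lo), tuple(up), step=step, total=total)


def enumerate_grid(fp: GridFootprint) -> np.ndarray:
    """All lattice compositions inside the footprint summing to the total.

    Returns an (N, 5) float array in lexicographic order of the first four
    parts (the fifth is determined by the total).
    """
    step = fp.step
    axes = [np.arange(fp.lower[i], fp.upper[i] + step / 2, step) for i in range(4)]
    g = np.meshgrid(*axes, indexing="ij")
    first4 = np.stack([a.ravel() for a in g], axis=1)
    fifth = fp.total - first4.sum(axis=1)
    mask = (fifth >= fp.lower[4] - 1e-9) & (fifth <= fp.upper[4] + 1e-9)
    # fifth part lands on the lattice iff total and bounds are step multiples
    on_lattice = np.abs(np.round(fifth / step) * step - fifth) < 1e-6
    mask &= on_lattice
    return np.column_stack([first4[mask], fifth[mask]])


def _score(fit: ModelFit, grid: np.ndarray) -> np.ndarray:
    """Compositional part of the linear predictor for every grid row."""
    return ilr_transform(grid, fit.basis) @ fit.ilr_params


def rank_and_select(
    fit: ModelFit,
    grid: np.ndarray,
    fraction: float = 0.05,
    direction: str = "lower",
) -> np.ndarray:
    """Keep the best ceil(fraction * N) grid compositions for one outcome.

    ``direction='lower'`` keeps the candidates with the lowest predicted
    outcome (adverse markers), ``'higher'`` the highest (insulin
    sensitivity). Ties break by predicted value then lexicographic
    composition, so selection is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if direction not in ("lower", "higher"):
        raise ValueError("direction must be 'lower' or 'higher'")
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    if grid.shape[0] == 0:
        raise ValueError("empty grid")
    pred = _score(fit, grid)
    key = pred if direction == "lower" else -pred
    # np.lexsort: last key is primary
    order = np.lexsort((*[grid[:, c] for c in range(4, -1, -1)], key))
    k = math.ceil(fraction * grid.shape[0])
    return grid[order[:k]]


@dataclass(frozen=True)
class ZoneReport:
    """Summary of one selected set of grid compositions."""

    label: str
    fraction: float
    n_selected: int
    centre: tuple[float, ...]  # geometric mean, closed to 1440
    centre_rounded: tuple[float, ...]  # nearest 10 min; may not sum to 1440
    ranges: tuple[tuple[float, float], ...]  # per-part (min, max)

    def to_row(self) -> dict:
        row = {"label": self.label, "fraction": self.fraction, "n": self.n_selected}
        for i, p in enumerate(PARTS):
            row[f"{p}_centre_min"] = self.centre_rounded[i]
            row[f"{p}_centre_hmm"] = minutes_to_hmm(self.centre_rounded[i])
            row[f"{p}_min"] = self.ranges[i][0]
            row[f"{p}_max"] = self.ranges[i][1]
        return row


def zone_summary(selected: np.ndarray, label: str = "", fraction: float = float("nan"),
                 step: float = 10.0) -> ZoneReport:
    """Compositional centre (geometric mean, rounded per part) and ranges."""
    selected = np.atleast_2d(np.asarray(selected, dtype=float))
    if selected.shape[0] == 0:
        raise ValueError("empty selection")
    centre = geometric_mean_composition(selected)
    rounded = np.round(centre / step) * step
    ranges = tuple((float(selected[:, i].min()), float(selected[:, i].max())) for i in range(5))
    return ZoneReport(
        label=label,
        fraction=fraction,
        n_selected=int(selected.shape[0]),
        centre=tuple(float(c) for c in centre),
        centre_rounded=tuple(float(r) for r in rounded),
        ranges=ranges,
    )


def _rows_as_keys(grid: np.ndarray) -> np.ndarray:
    """Encode 10-min lattice rows as int64 keys for set operations."""
    g = np.round(np.asarray(grid, dtype=float)).astype(np.int64)
    key = g[:, 0]
    for c in range(1, 5):
        key = key * 2048 + g[:, c]
    return key


@dataclass
class OptimalZone:
    """Per-outcome optimal zones and their cross-outcome overlap."""

    per_outcome: dict[str, ZoneReport]
    selected: dict[str, np.ndarray]  # at start_fraction
    overlap_fraction: float | None
    overlap: ZoneReport | None
    overlap_set: np.ndarray | None
    selected_at_overlap: dict[str, np.ndarray]
    pairwise_diagnostics: pd.DataFrame | None = None


def overlap_zone(
    fits: dict[str, ModelFit],
    grid: np.ndarray,
    directions: dict[str, str],
    start_fraction: float = 0.05,
    max_fraction: float = 0.10,
    step: float = 0.01,
) -> OptimalZone:
    """Intersect per-outcome optimal zones, escalating the selection fraction.

    The same fraction applies to every outcome; escalation stops at the first
    non-empty intersection. An empty overlap at ``max_fraction`` is reported
    as a result (with pairwise-overlap diagnostics), not raised.
    """
    if len(fits) < 2:
        raise ValueError("overlap needs at least two outcomes")
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    selected = {
        o: rank_and_select(f, grid, start_fraction, directions[o]) for o, f in fits.items()
    }
    per_outcome = {
        o: zone_summary(s, label=o, fraction=start_fraction) for o, s in selected.items()
    }

    fractions = []
    f = start_fraction
    while f <= max_fraction + 1e-9:
        fractions.append(round(f, 10))
        f += step
    overlap_set = None
    overlap_fraction = None
    sel_at = selected
    for frac in fractions:
        sel_at = {o: rank_and_select(fit, grid, frac, directions[o]) for o, fit in fits.items()}
        keys = None
        for o, s in sel_at.items():
            k = np.sort(_rows_as_keys(s))
            keys = k if keys is None else np.intersect1d(keys, k, assume_unique=True)
        if keys is not None and keys.size > 0:
            mask = np.isin(_rows_as_keys(grid), keys)
            overlap_set = grid[mask]
            overlap_fraction = frac
            break

    diagnostics = None
    if overlap_set is None:
        names = list(fits)
        rows = []
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                ka = _rows_as_keys(sel_at[names[a]])
                kb = _rows_as_keys(sel_at[names[b]])
                rows.append(
                    {
                        "outcome_a": names[a],
                        "outcome_b": names[b],
                        "n_overlap_at_max": int(np.intersect1d(ka, kb).size),
                    }
                )
        diagnostics = pd.DataFrame(rows)
        return OptimalZone(per_outcome, selected, None, None, None, sel_at, diagnostics)

    return OptimalZone(
        per_outcome=per_outcome,
        selected=selected,
        overlap_fraction=overlap_fraction,
        overlap=zone_summary(overlap_set, label="overlap", fraction=overlap_fraction),
        overlap_set=overlap_set,
        selected_at_overlap=sel_at,
    )


#: Regular tetrahedron vertices for the four waking behaviours.
_TETRA_VERTICES = np.array(
    [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
) / np.sqrt(3.0)


def export_tetrahedron_coords(
    sets: dict[str, np.ndarray], sleep_fixed: float = 480.0
) -> pd.DataFrame:
    """Barycentric tetrahedron coordinates of selected grid points.

    Keeps grid points whose sleeping time equals ``sleep_fixed`` (8 h by
    default), renormalises the four waking behaviours to their sum and maps
    them to a regular tetrahedron whose corners are 100% sitting, standing,
    LPA and MVPA; the centroid is equal 25% shares. Columns: the five parts,
    x, y, z and one membership flag per input set.
    """
    if not sets:
        raise ValueError("no selected sets supplied")
    all_rows = np.vstack([np.atleast_2d(s) for s in sets.values()])
    sleep_levels = np.unique(np.round(all_rows[:, 4]))
    if not np.any(np.abs(sleep_levels - sleep_fixed) < 1e-9):
        nearest = float(sleep_levels[np.argmin(np.abs(sleep_levels - sleep_fixed))])
        warnings.warn(
            f"no grid point with sleeping == {sleep_fixed:.0f} min; "
            f"using nearest level {nearest:.0f} min",
            stacklevel=2,
        )
        sleep_fixed = nearest

    keys_per_set = {name: set(_rows_as_keys(np.atleast_2d(s))) for name, s in sets.items()}
    sel = all_rows[np.abs(all_rows[:, 4] - sleep_fixed) < 1e-9]
    uniq_keys, idx = np.unique(_rows_as_keys(sel), return_index=True)
    sel = sel[idx]
    waking = sel[:, :4]
    weights = waking / waking.sum(axis=1, keepdims=True)
    xyz = weights @ _TETRA_VERTICES
    out = pd.DataFrame(sel, columns=list(PARTS))
    out[["x", "y", "z"]] = xyz
    row_keys = _rows_as_keys(sel)
    for name, keys in keys_per_set.items():
        out[f"in_{name}"] = [k in keys for k in row_keys]
    return out
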
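"""End-to-end assembly: outcomes -> fits -> substitutions -> optimal zones.

`analyse` takes a participant table (five behaviour columns, covariates and
the raw marker panel) and produces the full report bundle: per-outcome model
summaries, composition-by-stratum interaction tests, 30-min isotemporal
substitution tables (overall and per stratum), the empirical footprint and
grid, per-outcome optimal zones and the cross-outcome overlapping optimal
zone with tetrahedron export coordinates. All outputs are deterministic
given the input table and options.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import CANONICAL_BASIS, PARTS, geometric_mean_composition, minutes_to_hmm
from .markers import OUTCOME_DIRECTION, OUTCOMES, build_outcomes, classify_glycaemic_status
from .regression import CovariateSpec, ModelFit, fit_compositional_model, fit_stratified, test_interaction
from .substitution import substitution_matrix
from .zones import (
    GridFootprint,
    OptimalZone,
    compute_footprint,
    enumerate_grid,
    export_tetrahedron_coords,
    overlap_zone,
    zone_summary,
)

__all__ = ["PipelineOptions", "AnalysisBundle", "analyse"]

log = logging.getLogger(__name__)


@dataclass
class PipelineOptions:
    """Analysis constants: reallocation size, CI level, grid and selection."""

    delta: float = 30.0  # minutes reallocated in substitutions
    ci_level: float = 0.95
    fraction: float = 0.05  # top fraction defining an optimal zone
    max_fraction: float = 0.10  # escalation ceiling for the overlap
    escalation_step: float = 0.01
    grid_step: float = 10.0
    adjust_waist: bool = False
    t2d_conjunction: str = "or"
    stratum: str = "diabetes_status"
    sleep_fixed: float = 480.0  # tetrahedron slice, minutes
    footprint: GridFootprint | None = None  # inject known bounds; else estimated
    classify_status: bool = True  # derive diabetes_status from the marker panel

    def __post_init__(self):
        for name, v in (("fraction", self.fraction), ("max_fraction", self.max_fraction)):
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if 1440 % self.grid_step:
            raise ValueError("grid_step must divide 1440")


@dataclass
class AnalysisBundle:
    """Everything `analyse` computes, as plain DataFrames plus zone objects."""

    outcomes_z: pd.DataFrame
    model_fits: dict[str, ModelFit]
    stratified_fits: dict[str, dict[str, ModelFit]]
    model_summaries: pd.DataFrame
    interactions: pd.DataFrame
    substitutions: pd.DataFrame
    footprint: GridFootprint
    grid_size: int
    zones: OptimalZone
    zone_table: pd.DataFrame
    tetrahedron: pd.DataFrame
    manifest: dict


def _zone_table(zones: OptimalZone, footprint: GridFootprint, sample_centre) -> pd.DataFrame:
    rows = []
    centre_rounded = np.round(np.asarray(sample_centre) / 10) * 10
    row = {"label": "sample", "fraction": 1.0, "n": None}
    for i, p in enumerate(PARTS):
        row[f"{p}_centre_min"] = centre_rounded[i]
        row[f"{p}_centre_hmm"] = minutes_to_hmm(centre_rounded[i])
        row[f"{p}_min"] = footprint.lower[i]
        row[f"{p}_max"] = footprint.upper[i]
    rows.append(row)
    for o, rep in zones.per_outcome.items():
        rows.append(rep.to_row())
    if zones.overlap is not None:
        rows.append(zones.overlap.to_row())
    return pd.DataFrame(rows)


def analyse(participants: pd.DataFrame, opts: PipelineOptions | None = None) -> AnalysisBundle:
    """Run the complete cross-sectional analysis on a participant table."""
    opts = opts or PipelineOptions()
    data = participants.copy()

    if opts.classify_status:
        data["diabetes_status"] = classify_glycaemic_status(
            data["fpg"], data["two_h_plg"], data["glucose_lowering_med"],
            t2d_conjunction=opts.t2d_conjunction,
        )
    n_strat = data["diabetes_status"].value_counts().to_dict()
    log.info("n per stratum: %s", n_strat)

    z, scaler = build_outcomes(data)
    for o in OUTCOMES:
        data[o] = z[o]

    spec = CovariateSpec(adjust_waist=opts.adjust_waist)
    alpha = 1 - opts.ci_level

    fits: dict[str, ModelFit] = {}
    summaries = []
    for o in OUTCOMES:
        fit = fit_compositional_model(data, o, spec)
        fits[o] = fit
        s = fit.summary_frame(alpha)
        s.insert(0, "outcome", o)
        summaries.append(s)
    model_summaries = pd.concat(summaries, ignore_index=True)

    inter_rows = []
    for o in OUTCOMES:
        for stratum in ("sex", opts.stratum):
            res = test_interaction(data, o, spec, stratum)
            row = {
                "outcome": o,
                "stratum": stratum,
                "f_stat": res.f_stat,
                "p_value": res.p_value,
                "df_num": res.df_num,
                "df_den": res.df_den,
                "significant": res.significant,
            }
            for lv, (b, se) in res.beta1_by_level.items():
                row[f"beta1_{lv}"] = b
                row[f"beta1_se_{lv}"] = se
            inter_rows.append(row)
    interactions = pd.DataFrame(inter_rows)

    strat_fits = {o: fit_stratified(data, o, spec, opts.stratum) for o in OUTCOMES}

    base_all = geometric_mean_composition(data)
    sub_frames = []
    for o in OUTCOMES:
        m = substitution_matrix(fits[o], base_all, opts.delta, alpha)
        m.insert(1, "stratum", "overall")
        sub_frames.append(m)
        for lv, f in strat_fits[o].items():
            base_lv = geometric_mean_composition(data[data[opts.stratum] == lv])
            m = substitution_matrix(f, base_lv, opts.delta, alpha)
            m.insert(1, "stratum", lv)
            sub_frames.append(m)
    substitutions = pd.concat(sub_frames, ignore_index=True)

    fp = opts.footprint or compute_footprint(data, step=opts.grid_step)
    grid = enumerate_grid(fp)
    log.info("grid footprint enumerates %d candidate compositions", grid.shape[0])
    zones = overlap_zone(
        fits, grid, OUTCOME_DIRECTION,
        start_fraction=opts.fraction,
        max_fraction=opts.max_fraction,
        step=opts.escalation_step,
    )
    if zones.overlap_fraction is not None and zones.overlap_fraction > opts.fraction:
        log.info("overlap required escalating to top %.0f%%", 100 * zones.overlap_fraction)

    zone_table = _zone_table(zones, fp, base_all)

    tetra_sets = dict(zones.selected)
    if zones.overlap_set is not None:
        tetra_sets["overlap"] = zones.overlap_set
    tetra = export_tetrahedron_coords(tetra_sets, sleep_fixed=opts.sleep_fixed)

    manifest = {
        "n": int(len(data)),
        "n_per_stratum": {k: int(v) for k, v in n_strat.items()},
        "grid_size": int(grid.shape[0]),
        "overlap_fraction": zones.overlap_fraction,
        "delta_min": opts.delta,
        "ci_level": opts.ci_level,
        "footprint_lower": list(map(float, fp.lower)),
        "footprint_upper": list(map(float, fp.upper)),
    }

    return AnalysisBundle(
        outcomes_z=z,
        model_fits=fits,
        stratified_fits=strat_fits,
        model_summaries=model_summaries,
        interactions=interactions,
        substitutions=substitutions,
        footprint=fp,
        grid_size=int(grid.shape[0]),
        zones=zones,
        zone_table=zone_table,
        tetrahedron=tetra,
        manifest=manifest,
    )
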
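"""Cardiometabolic and glycaemic outcome construction.

Six analysis outcomes are built from the raw marker panel:

* waist circumference (cm),
* fasting plasma glucose FPG, 2 h post-load glucose 2hPLG and HbA1c,
  z-scored after natural-log transformation (their residuals are closer to
  normal on the log scale),
* the Matsuda whole-body insulin sensitivity index (ISI-M), computed from
  fasting and mean OGTT glucose/insulin, z-scored untransformed (higher is
  better),
* a clustered cardiometabolic risk score (CMR): the mean of five standardised
  components — waist, ln FPG, ln triacylglycerol, ln HDL-cholesterol (sign
  flipped) and mean blood pressure — so the sample mean is zero by
  construction.

Glycaemic status (NGM / IGM / T2D) follows the WHO 2006 OGTT cut-points with
a glucose-lowering-medication override.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "OUTCOMES",
    "OUTCOME_DIRECTION",
    "ZScaler",
    "matsuda_index",
    "mean_bp",
    "cmr_score",
    "zscore_outcomes",
    "build_outcomes",
    "classify_glycaemic_status",
    "hba1c_percent_to_mmol_mol",
]

#: Analysis outcomes in reporting order.
OUTCOMES: tuple[str, ...] = ("waist", "fpg", "two_h_plg", "hba1c", "isim", "cmr")

#: Which direction is metabolically favourable for each outcome.
OUTCOME_DIRECTION: dict[str, str] = {
    "waist": "lower",
    "fpg": "lower",
    "two_h_plg": "lower",
    "hba1c": "lower",
    "isim": "higher",
    "cmr": "lower",
}

#: Outcomes z-scored on the natural-log scale.
LOG_SCALE_OUTCOMES = ("fpg", "two_h_plg", "hba1c")


class DegenerateSampleError(ValueError):
    """A marker has zero variance; z-scores are undefined."""


def matsuda_index(fpg, fpi, mean_g, mean_i):
    """ISI-M = 10000 / sqrt(FPG * FPI * meanG * meanI).

    Units follow the inputs; the absolute level is unit-dependent but z-scores
    are invariant to multiplicative unit changes. Vectorised.
    """
    fpg, fpi = np.asarray(fpg, dtype=float), np.asarray(fpi, dtype=float)
    mean_g, mean_i = np.asarray(mean_g, dtype=float), np.asarray(mean_i, dtype=float)
    for name, v in (("fpg", fpg), ("fpi", fpi), ("mean_g", mean_g), ("mean_i", mean_i)):
        if np.any(v <= 0):
            raise ValueError(f"matsuda_index requires positive {name}")
    return 10000.0 / np.sqrt(fpg * fpi * mean_g * mean_i)


def mean_bp(sbp, dbp):
    """Average of systolic and diastolic pressure, mmHg.

    Rows with DBP > SBP are kept but flagged with a warning (likely data
    entry swaps; the average is still well defined).
    """
    sbp, dbp = np.asarray(sbp, dtype=float), np.asarray(dbp, dtype=float)
    if np.any(dbp <= 0) or np.any(sbp <= 0):
        raise ValueError("blood pressures must be positive")
    n_swapped = int(np.sum(dbp > sbp))
    if n_swapped:
        warnings.warn(f"{n_swapped} row(s) have DBP > SBP; kept as-is", stacklevel=2)
    return (sbp + dbp) / 2.0


def _zscore(values: np.ndarray, name: str) -> tuple[np.ndarray, float, float]:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    if not sd > 0:
        raise DegenerateSampleError(f"zero variance in component '{name}'")
    return (values - mean) / sd, mean, sd


def cmr_score(panel: pd.DataFrame) -> pd.Series:
    """Clustered cardiometabolic risk score.

    CMR_i = ( z(waist) + z(ln FPG) + z(ln TG) - z(ln HDL) + z(meanBP) ) / 5
    with sample z-scores (n-1 SD). Requires columns waist, fpg,
    triacylglycerol, hdl and either mean_bp or sbp+dbp.
    """
    if len(panel) < 2:
        raise DegenerateSampleError("CMR needs at least two participants")
    if "mean_bp" in panel.columns:
        bp = np.asarray(panel["mean_bp"], dtype=float)
    else:
        bp = mean_bp(panel["sbp"], panel["dbp"])
    comps = {
        "waist": np.asarray(panel["waist"], dtype=float),
        "ln_fpg": np.log(np.asarray(panel["fpg"], dtype=float)),
        "ln_tg": np.log(np.asarray(panel["triacylglycerol"], dtype=float)),
        "ln_hdl": np.log(np.asarray(panel["hdl"], dtype=float)),
        "mean_bp": bp,
    }
    z = {k: _zscore(v, k)[0] for k, v in comps.items()}
    cmr = (z["waist"] + z["ln_fpg"] + z["ln_tg"] - z["ln_hdl"] + z["mean_bp"]) / 5.0
    return pd.Series(cmr, index=panel.index, name="cmr")


@dataclass
class ZScaler:
    """Per-outcome transform + standardisation parameters, reusable on new data."""

    params: dict[str, tuple[str, float, float]] = field(default_factory=dict)
    # outcome -> (transform tag 'log'|'identity', mean, sd) on the transform scale

    def transform(self, raw: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for name, (tag, mean, sd) in self.params.items():
            v = np.asarray(raw[name], dtype=float)
            if tag == "log":
                if np.any(v <= 0):
                    raise ValueError(f"log-scaled outcome '{name}' must be positive")
                v = np.log(v)
            out[name] = (v - mean) / sd
        return pd.DataFrame(out, index=raw.index)

    def inverse(self, z: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for name, (tag, mean, sd) in self.params.items():
            v = np.asarray(z[name], dtype=float) * sd + mean
            out[name] = np.exp(v) if tag == "log" else v
        return pd.DataFrame(out, index=z.index)

    def to_yaml(self, path):
        payload = {
            k: {"transform": t, "mean": m, "sd": s} for k, (t, m, s) in self.params.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ZScaler":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls({k: (v["transform"], v["mean"], v["sd"]) for k, v in payload.items()})


def zscore_outcomes(
    raw: pd.DataFrame, log_isim: bool = False
) -> tuple[pd.DataFrame, ZScaler]:
    """Standardise the six outcome columns; returns (z-scores, fitted scaler).

    ``raw`` must hold waist, fpg, two_h_plg, hba1c, isim, cmr. FPG, 2hPLG and
    HbA1c are log-transformed first; ISI-M optionally (sensitivity analysis).
    """
    if len(raw) < 2:
        raise DegenerateSampleError("z-scoring needs at least two participants")
    scaler = ZScaler()
    for name in OUTCOMES:
        v = np.asarray(raw[name], dtype=float)
        tag = "log" if name in LOG_SCALE_OUTCOMES or (name == "isim" and log_isim) else "identity"
        if tag == "log":
            if np.any(v <= 0):
                raise ValueError(f"log-scaled outcome '{name}' must be positive")
            v = np.log(v)
        _, mean, sd = _zscore(v, name)
        scaler.params[name] = (tag, mean, sd)
    return scaler.transform(raw), scaler


def build_outcomes(
    panel: pd.DataFrame, rezscore_cmr: bool = True, log_isim: bool = False
) -> tuple[pd.DataFrame, ZScaler]:
    """Derive ISI-M and CMR from the marker panel and z-score all six outcomes.

    CMR is already a standardised score; by default it is re-z-scored (a pure
    rescaling, since its mean is 0) so effect sizes are comparable across
    outcomes. With ``rezscore_cmr=False`` the raw CMR is carried through
    unscaled.
    """
    raw = pd.DataFrame(index=panel.index)
    raw["waist"] = np.asarray(panel["waist"], dtype=float)
    raw["fpg"] = np.asarray(panel["fpg"], dtype=float)
    raw["two_h_plg"] = np.asarray(panel["two_h_plg"], dtype=float)
    raw["hba1c"] = np.asarray(panel["hba1c"], dtype=float)
    raw["isim"] = (
        np.asarray(panel["isim"], dtype=float)
        if "isim" in panel.columns
        else matsuda_index(
            panel["fpg"], panel["fpi"], panel["mean_ogtt_glucose"], panel["mean_ogtt_insulin"]
        )
    )
    raw["cmr"] = cmr_score(panel)
    z, scaler = zscore_outcomes(raw, log_isim=log_isim)
    if not rezscore_cmr:
        z["cmr"] = raw["cmr"]
        scaler.params["cmr"] = ("identity", 0.0, 1.0)
    return z, scaler


def classify_glycaemic_status(fpg, two_h_plg, med_flag, t2d_conjunction: str = "or"):
    """WHO 2006 glycaemic status: NGM / IGM / T2D.

    T2D: glucose-lowering medication, or FPG >= 7.0 / 2hPLG >= 11.1 mmol/l
    combined with ``t2d_conjunction`` ('or' follows the WHO reading, 'and'
    the stricter joint criterion). IGM: impaired glucose tolerance
    (FPG < 7.0 and 7.8 <= 2hPLG < 11.1) and/or impaired fasting glucose
    (6.1 <= FPG < 7.0 and 2hPLG < 7.8). Everything below is NGM. Vectorised;
    scalar inputs return a scalar label.
    """
    if t2d_conjunction not in ("or", "and"):
        raise ValueError("t2d_conjunction must be 'or' or 'and'")
    fpg = np.asarray(fpg, dtype=float)
    plg = np.asarray(two_h_plg, dtype=float)
    med = np.asarray(med_flag, dtype=bool)
    scalar = fpg.ndim == 0
    fpg, plg, med = np.atleast_1d(fpg), np.atleast_1d(plg), np.atleast_1d(med)
    if np.any(fpg <= 0) or np.any(plg <= 0):
        raise ValueError("glucose values must be positive")
    if t2d_conjunction == "or":
        t2d = med | (fpg >= 7.0) | (plg >= 11.1)
    else:
        t2d = med | ((fpg >= 7.0) & (plg >= 11.1))
    igt = (fpg < 7.0) & (plg >= 7.8) & (plg < 11.1)
    # at one-decimal precision the printed 6.1-6.9 band is [6.1, 7.0)
    ifg = (fpg >= 6.1) & (fpg < 7.0) & (plg < 7.8)
    labels = np.where(t2d, "T2D", np.where(igt | ifg, "IGM", "NGM"))
    return labels.item() if scalar else labels


def hba1c_percent_to_mmol_mol(percent):
    """Convert NGSP % HbA1c to IFCC mmol/mol via the standard affine relation."""
    return (np.asarray(percent, dtype=float) - 2.152) / 0.09148
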
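"""Compositional isotemporal substitution.

Starting from a reference composition (by default the sample's compositional
geometric mean), a fixed number of minutes is moved from one behaviour to
another while the other three are held fixed, and the fitted compositional
model predicts the resulting outcome difference:

    estimate = (ilr(new) - ilr(base)) . beta_ilr

Covariate terms cancel in the difference, so the estimate is the same for
every covariate setting. The variance is d' V d with d the ilr difference
and V the ilr-coefficient covariance; confidence limits use the t critical
value on the model's residual degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .composition import PARTS, TOTAL_MINUTES, as_parts_array, ilr_transform
from .regression import ModelFit

__all__ = ["SubstitutionEstimate", "substitute", "substitution_matrix"]


class InfeasibleSubstitutionError(ValueError):
    """The reallocation would drive a behaviour to zero or below."""


@dataclass(frozen=True)
class SubstitutionEstimate:
    """Predicted outcome z-difference for a pairwise time reallocation."""

    outcome: str
    from_part: str
    to_part: str
    delta: float  # minutes moved
    estimate: float
    se: float
    ci_low: float
    ci_high: float


def substitute(
    fit: ModelFit,
    base,
    from_part: str,
    to_part: str,
    delta: float = 30.0,
    alpha: float = 0.05,
) -> SubstitutionEstimate:
    """Estimate the outcome difference when ``delta`` minutes move from one
    behaviour to another, starting at ``base`` (total time conserved)."""
    if from_part not in PARTS or to_part not in PARTS:
        raise ValueError(f"parts must be among {PARTS}")
    if from_part == to_part:
        raise ValueError("from_part and to_part must differ")
    if delta <= 0:
        raise ValueError("delta must be positive")
    base = as_parts_array(base)
    i, j = PARTS.index(from_part), PARTS.index(to_part)
    new = base.copy()
    new[i] -= delta
    new[j] += delta
    if new[i] <= 0:
        raise InfeasibleSubstitutionError(
            f"moving {delta} min out of '{from_part}' leaves "
            f"{new[i]:.1f} min; substitution infeasible"
        )
    d = ilr_transform(new, fit.basis) - ilr_transform(base, fit.basis)
    beta = fit.ilr_params
    est = float(d @ beta)
    var = float(d @ fit.ilr_cov @ d)
    se = np.sqrt(max(var, 0.0))
    crit = scipy.stats.t.ppf(1 - alpha / 2, fit.df_resid)
    return SubstitutionEstimate(
        outcome=fit.outcome,
        from_part=from_part,
        to_part=to_part,
        delta=float(delta),
        estimate=est,
        se=se,
        ci_low=est - crit * se,
        ci_high=est + crit * se,
    )


def substitution_matrix(
    fit: ModelFit, base, delta: float = 30.0, alpha: float = 0.05
) -> pd.DataFrame:
    """All 20 ordered pairwise reallocations of ``delta`` minutes from ``base``.

    Infeasible pairs are reported as a warning and skipped.
    """
    rows = []
    for from_part in PARTS:
        for to_part in PARTS:
            if from_part == to_part:
                continue
            try:
                est = substitute(fit, base, from_part, to_part, delta, alpha)
            except InfeasibleSubstitutionError as e:
                warnings.warn(str(e), stacklevel=2)
                continue
            rows.append(
                {
                    "outcome": est.outcome,
                    "from": est.from_part,
                    "to": est.to_part,
                    "delta_min": est.delta,
                    "estimate": est.estimate,
                    "se": est.se,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                }
            )
    return pd.DataFrame(
        rows, columns=["outcome", "from", "to", "delta_min", "estimate", "se", "ci_low", "ci_high"]
    )
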
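"""Linear regression of outcome z-scores on ilr coordinates plus covariates.

The model is ordinary least squares:

    z_outcome = b0 + b1*ilr1 + b2*ilr2 + b3*ilr3 + b4*ilr4 + covariates + e

where the four ilr coordinates are pivot coordinates of the 24 h behaviour
composition. Because any two pivot bases span the same 4-dimensional log-ratio
space, fitted values, R^2 and all predictions are invariant to which
behaviour leads (permutation principle); only the coordinate-wise
coefficients rotate. The lead coordinate's coefficient (b1) summarises the
lead behaviour relative to the geometric mean of the remaining four.

Covariates: age and diet score (centred), sex, education, smoking and —
outside stratified fits — diabetes status as treatment-coded factors, with
an optional waist-circumference adjustment that is automatically disabled
for the waist and CMR outcomes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .composition import CANONICAL_BASIS, IlrBasis, ilr_transform

__all__ = [
    "CovariateSpec",
    "ModelFit",
    "InteractionResult",
    "build_design",
    "fit_compositional_model",
    "predict",
    "predict_table",
    "test_interaction",
    "fit_stratified",
]

log = logging.getLogger(__name__)

ILR_COLS = ("ilr_1", "ilr_2", "ilr_3", "ilr_4")

#: Allowed levels per factor (reference = first alphabetical, recorded on fit).
CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("F", "M"),
    "education": ("low", "medium", "high"),
    "smoking": ("never", "former", "current"),
    "diabetes_status": ("NGM", "IGM", "T2D"),
}


@dataclass(frozen=True)
class CovariateSpec:
    """Adjustment set for the compositional models."""

    continuous: tuple[str, ...] = ("age", "diet_score")
    categorical: tuple[str, ...] = ("sex", "education", "smoking", "diabetes_status")
    adjust_waist: bool = False

    def without(self, name: str) -> "CovariateSpec":
        return replace(
            self,
            continuous=tuple(c for c in self.continuous if c != name),
            categorical=tuple(c for c in self.categorical if c != name),
        )


@dataclass
class ModelFit:
    """A fitted compositional OLS model plus everything needed to predict."""

    outcome: str
    params: pd.Series
    cov_params: pd.DataFrame
    df_resid: int
    basis: IlrBasis
    spec: CovariateSpec
    n: int
    r_squared: float
    sigma2: float
    centres: dict[str, float]  # continuous covariate means used for centring
    reference_levels: dict[str, str]

    @property
    def ilr_params(self) -> np.ndarray:
        return self.params.loc[list(ILR_COLS)].to_numpy()

    @property
    def ilr_cov(self) -> np.ndarray:
        return self.cov_params.loc[list(ILR_COLS), list(ILR_COLS)].to_numpy()

    def summary_frame(self, alpha: float = 0.05) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov_params.to_numpy()))
        t = self.params.to_numpy() / se
        p = 2 * scipy.stats.t.sf(np.abs(t), self.df_resid)
        crit = scipy.stats.t.ppf(1 - alpha / 2, self.df_resid)
        return pd.DataFrame(
            {
                "term": self.params.index,
                "estimate": self.params.to_numpy(),
                "se": se,
                "t": t,
                "p": p,
                "ci_low": self.params.to_numpy() - crit * se,
                "ci_high": self.params.to_numpy() + crit * se,
            }
        )


def _categorical_columns(data: pd.DataFrame, factor: str) -> tuple[pd.DataFrame, str]:
    levels = CATEGORY_LEVELS.get(factor)
    if levels is None:
        levels = tuple(sorted(pd.unique(data[factor].astype(str))))
    seen = set(map(str, pd.unique(data[factor])))
    unknown = seen - set(levels)
    if unknown:
        raise ValueError(f"unknown level(s) {sorted(unknown)} for factor '{factor}'")
    ref = sorted(levels)[0]
    cols = {}
    for lv in levels:
        if lv == ref:
            continue
        cols[f"{factor}[{lv}]"] = (data[factor].astype(str) == lv).astype(float)
    return pd.DataFrame(cols, index=data.index), ref


def build_design(
    data: pd.DataFrame,
    spec: CovariateSpec,
    basis: IlrBasis = CANONICAL_BASIS,
    centres: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, dict[str, float], dict[str, str]]:
    """Assemble the OLS design matrix (const, ilr block, covariates).

    ``centres`` are the means used to centre continuous covariates; pass the
    values stored in a fit to reproduce its design on new data.
    """
    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    z = ilr_transform(data, basis)
    for j, c in enumerate(ILR_COLS):
        X[c] = z[:, j]
    fitted_centres, refs = {}, {}
    for name in spec.continuous:
        v = np.asarray(data[name], dtype=float)
        mu = float(np.mean(v)) if centres is None else centres[name]
        fitted_centres[name] = mu
        X[name] = v - mu
    for factor in spec.categorical:
        cols, ref = _categorical_columns(data, factor)
        refs[factor] = ref
        X = pd.concat([X, cols], axis=1)
    if spec.adjust_waist:
        v = np.asarray(data["waist"], dtype=float)
        mu = float(np.mean(v)) if centres is None else centres["waist"]
        fitted_centres["waist"] = mu
        X["waist"] = v - mu
    return X, fitted_centres, refs


def _check_rank(X: pd.DataFrame):
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify columns in the span of their predecessors
        bad = []
        for k in range(1, arr.shape[1]):
            sub = arr[:, :k]
            resid = arr[:, k] - sub @ np.linalg.lstsq(sub, arr[:, k], rcond=None)[0]
            if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(arr[:, k])):
                bad.append(X.columns[k])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def _complete_cases(data: pd.DataFrame, outcome: str, spec: CovariateSpec) -> pd.DataFrame:
    from .composition import PARTS

    cols = [outcome, *PARTS, *spec.continuous, *spec.categorical]
    if spec.adjust_waist:
        cols.append("waist")
    cols = list(dict.fromkeys(c for c in cols if c in data.columns))
    missing = [c for c in [outcome, *spec.continuous, *spec.categorical] if c not in data.columns]
    if missing:
        raise KeyError(f"columns missing from data: {missing}")
    kept = data.dropna(subset=cols)
    if len(kept) < len(data):
        log.info("%s: %d of %d rows complete-case", outcome, len(kept), len(data))
    return kept


def fit_compositional_model(
    data: pd.DataFrame,
    outcome: str,
    spec: CovariateSpec = CovariateSpec(),
    basis: IlrBasis = CANONICAL_BASIS,
) -> ModelFit:
    """OLS of a z-scored outcome on the ilr block plus covariates.

    The waist adjustment is dropped automatically when the outcome is waist
    or CMR (waist is a CMR component).
    """
    if spec.adjust_waist and outcome in ("waist", "cmr"):
        spec = replace(spec, adjust_waist=False)
    data = _complete_cases(data, outcome, spec)
    if len(data) == 0:
        raise ValueError("no complete-case rows to fit")
    X, centres, refs = build_design(data, spec, basis)
    if len(data) < X.shape[1] + 1:
        raise ValueError(f"too few rows ({len(data)}) for {X.shape[1]} coefficients")
    _check_rank(X)
    y = np.asarray(data[outcome], dtype=float)
    res = sm.OLS(y, X).fit()
    return ModelFit(
        outcome=outcome,
        params=res.params,
        cov_params=res.cov_params(),
        df_resid=int(res.df_resid),
        basis=basis,
        spec=spec,
        n=len(data),
        r_squared=float(res.rsquared),
        sigma2=float(res.scale),
        centres=centres,
        reference_levels=refs,
    )


def predict_table(fit: ModelFit, data: pd.DataFrame) -> np.ndarray:
    """Vectorised linear predictor for a table of compositions + covariates."""
    for factor in fit.spec.categorical:
        allowed = set(CATEGORY_LEVELS.get(factor, set(map(str, data[factor]))))
        unseen = set(map(str, data[factor])) - allowed
        if unseen:
            raise ValueError(f"unseen level(s) {sorted(unseen)} for factor '{factor}'")
    X, _, _ = build_design(data, fit.spec, fit.basis, centres=fit.centres)
    X = X.reindex(columns=fit.params.index, fill_value=0.0)
    return X.to_numpy() @ fit.params.to_numpy()


def predict(fit: ModelFit, composition, covariates: dict) -> float:
    """Linear predictor at one composition and covariate setting."""
    row = {**covariates}
    from .composition import PARTS, as_parts_array

    comp = as_parts_array(composition)
    for p, v in zip(PARTS, comp):
        row[p] = v
    return float(predict_table(fit, pd.DataFrame([row]))[0])


@dataclass
class InteractionResult:
    """Composition-by-stratum interaction F-test and per-stratum lead effects."""

    stratum: str
    f_stat: float
    p_value: float
    df_num: int
    df_den: int
    beta1_by_level: dict[str, tuple[float, float]]  # level -> (estimate, se)
    significant: bool


def test_interaction(
    data: pd.DataFrame,
    outcome: str,
    spec: CovariateSpec = CovariateSpec(),
    stratum: str = "diabetes_status",
    basis: IlrBasis = CANONICAL_BASIS,
    alpha: float = 0.05,
) -> InteractionResult:
    """F-test of the 4-ilr block interacting with a stratum factor.

    Compares the covariate-adjusted model with a shared ilr block against the
    model with a separate ilr block per stratum level (same span as main
    effects + interactions); reports per-level ilr1 coefficients from the
    cell-means parameterisation.
    """
    if stratum not in spec.categorical:
        spec = replace(spec, categorical=spec.categorical + (stratum,))
    if spec.adjust_waist and outcome in ("waist", "cmr"):
        spec = replace(spec, adjust_waist=False)
    data = _complete_cases(data, outcome, spec)
    levels = [lv for lv in CATEGORY_LEVELS.get(stratum, sorted(data[stratum].unique()))
              if (data[stratum] == lv).any()]
    if len(levels) < 2:
        raise ValueError(f"stratum '{stratum}' has fewer than two levels present")
    y = np.asarray(data[outcome], dtype=float)

    X_r, _, _ = build_design(data, spec, basis)
    _check_rank(X_r)
    res_r = sm.OLS(y, X_r).fit()

    X_f = X_r.drop(columns=list(ILR_COLS))
    z = ilr_transform(data, basis)
    for lv in levels:
        mask = (data[stratum].astype(str) == lv).to_numpy(dtype=float)
        for j, c in enumerate(ILR_COLS):
            X_f[f"{c}:{stratum}[{lv}]"] = z[:, j] * mask
    counts = data[stratum].value_counts()
    if (counts < X_r.shape[1]).any():
        small = counts[counts < X_r.shape[1]]
        raise ValueError(f"stratum level(s) with too few rows: {dict(small)}")
    _check_rank(X_f)
    res_f = sm.OLS(y, X_f).fit()

    q = 4 * (len(levels) - 1)
    df_den = int(res_f.df_resid)
    f_stat = ((res_r.ssr - res_f.ssr) / q) / (res_f.ssr / df_den)
    p = float(scipy.stats.f.sf(f_stat, q, df_den))

    cov_f = res_f.cov_params()
    beta1 = {}
    for lv in levels:
        term = f"ilr_1:{stratum}[{lv}]"
        beta1[lv] = (float(res_f.params[term]), float(np.sqrt(cov_f.loc[term, term])))
    return InteractionResult(
        stratum=stratum,
        f_stat=float(f_stat),
        p_value=p,
        df_num=q,
        df_den=df_den,
        beta1_by_level=beta1,
        significant=p < alpha,
    )


def fit_stratified(
    data: pd.DataFrame,
    outcome: str,
    spec: CovariateSpec = CovariateSpec(),
    stratum: str = "diabetes_status",
    basis: IlrBasis = CANONICAL_BASIS,
) -> dict[str, ModelFit]:
    """Independent fits per stratum level; the stratum leaves the covariates."""
    sub_spec = spec.without(stratum)
    fits: dict[str, ModelFit] = {}
    for lv in CATEGORY_LEVELS.get(stratum, tuple(sorted(data[stratum].dropna().unique()))):
        mask = data[stratum].astype(str) == lv
        if not mask.any():
            warnings.warn(f"stratum level {lv!r} absent; skipped", stacklevel=2)
            continue
        fits[lv] = fit_compositional_model(data[mask], outcome, sub_spec, basis)
    return fits
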
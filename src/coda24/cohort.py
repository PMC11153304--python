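"""Synthetic cohort generator with known ground truth.

The source cohort is not publicly available, so every pipeline stage is
exercised on a fully synthetic stand-in that mimics its structure: a
three-stratum population (normal glucose metabolism, impaired glucose
metabolism, type 2 diabetes; 1341/363/684 participants by default) with

* 24 h behaviour compositions drawn from a logistic-normal model centred on
  the published stratum medians (sitting 9.1/9.6/10.2 h, ...) with a
  plausible (invented) negative sitting-activity covariance;
* covariates (age, diet score, sex, education, smoking, medication) matched
  to the published stratum frequencies;
* eight latent marker responses, each linear in the four ilr coordinates
  plus covariates and a stratum shift with Gaussian noise, back-mapped to
  raw marker units (exponential for log-scaled markers, affine otherwise) so
  that re-standardising the raw markers recovers the latent scale;
* fasting/mean OGTT insulin solved from the target Matsuda index so the
  marker pipeline reproduces the intended insulin-sensitivity latent
  exactly;
* optional day-level wear records (8 days, jittered behaviours, cadence
  epochs) for the aggregation stage.

The truth record stores the generating coefficients and, per analysis
outcome, the coefficient on the standardised (z-score) scale,
``beta_z = beta / SD(latent)``, with the latent SD computed analytically
from the generating mixture. Fitting the pipeline's z-scored outcomes
estimates exactly ``beta_z`` (up to O(1/n) scale-estimation noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .composition import CANONICAL_BASIS, PARTS, TOTAL_MINUTES, close, ilr_transform
from .markers import OUTCOMES

__all__ = [
    "StratumConfig",
    "SyntheticConfig",
    "TruthRecord",
    "default_config",
    "generate_cohort",
    "generate_day_records",
]

STRATA = ("NGM", "IGM", "T2D")


def _norm(freq):
    f = np.asarray(freq, dtype=float)
    return f / f.sum()

#: Latent marker components generated directly (CMR is derived from five of them).
COMPONENTS = ("waist", "fpg", "two_h_plg", "hba1c", "isim", "triacylglycerol", "hdl", "mean_bp")


@dataclass(frozen=True)
class StratumConfig:
    """Per-stratum sample size, composition centre and covariate distributions."""

    n: int
    composition_centre: tuple[float, ...]  # minutes/day, will be closed to 1440
    age_mean: float
    age_sd: float
    diet_mean: float
    diet_sd: float
    sex_m_frac: float
    education_freq: tuple[float, float, float]  # low, medium, high
    smoking_freq: tuple[float, float, float]  # never, former, current
    med_frac: float  # glucose-lowering medication


def _default_strata() -> dict[str, StratumConfig]:
    # centres from the published stratum medians (hours -> minutes)
    return {
        "NGM": StratumConfig(
            n=1341,
            composition_centre=(546, 264, 66, 60, 492),
            age_mean=58.2, age_sd=8.1, diet_mean=85.7, diet_sd=14.4,
            sex_m_frac=0.409,
            education_freq=(0.268, 0.284, 0.448),
            smoking_freq=(0.402, 0.479, 0.119),
            med_frac=0.0,
        ),
        "IGM": StratumConfig(
            n=363,
            composition_centre=(576, 252, 66, 48, 492),
            age_mean=62.1, age_sd=7.2, diet_mean=82.9, diet_sd=14.9,
            sex_m_frac=0.540,
            education_freq=(0.366, 0.264, 0.369),
            smoking_freq=(0.289, 0.603, 0.107),
            med_frac=0.0,
        ),
        "T2D": StratumConfig(
            n=684,
            composition_centre=(612, 222, 54, 36, 498),
            age_mean=62.7, age_sd=7.7, diet_mean=80.5, diet_sd=14.6,
            sex_m_frac=0.702,
            education_freq=(0.453, 0.284, 0.263),
            smoking_freq=(0.297, 0.554, 0.149),
            med_frac=0.797,
        ),
    }


def _default_log_cov() -> np.ndarray:
    """Log-scale behaviour covariance: invented but plausible (sitting trades
    against the active behaviours; sleep is the most stable)."""
    sd = np.array([0.16, 0.28, 0.35, 0.55, 0.09])
    corr = np.eye(5)
    pairs = {
        (0, 1): -0.45,  # sitting vs standing
        (0, 2): -0.30,  # sitting vs LPA
        (0, 3): -0.20,  # sitting vs MVPA
        (0, 4): -0.15,  # sitting vs sleeping
        (1, 2): 0.15,
        (2, 3): 0.25,
    }
    for (i, j), r in pairs.items():
        corr[i, j] = corr[j, i] = r
    return corr * np.outer(sd, sd)


# Latent-scale generating coefficients. beta: effect of the four canonical
# pivot ilr coordinates (lead = sitting). gamma: covariate effects on
# (age - 60), (diet - 84), 1[male], 1[current smoker]. shift: stratum offsets.
_DEFAULT_BETA = {
    "waist": (0.40, -0.15, -0.05, -0.20),
    "fpg": (0.35, -0.10, -0.25, 0.05),
    "two_h_plg": (0.30, 0.05, -0.20, -0.05),
    "hba1c": (0.25, 0.10, -0.15, -0.05),
    "isim": (-0.45, 0.10, 0.15, 0.20),
    "triacylglycerol": (0.25, -0.05, -0.05, -0.10),
    "hdl": (-0.20, 0.05, 0.05, 0.15),
    "mean_bp": (0.15, -0.05, -0.05, -0.05),
}
_DEFAULT_GAMMA = {
    "waist": (0.010, -0.004, 0.50, 0.05),
    "fpg": (0.010, -0.002, 0.10, 0.05),
    "two_h_plg": (0.020, -0.002, 0.05, 0.05),
    "hba1c": (0.020, -0.002, 0.05, 0.10),
    "isim": (-0.010, 0.002, -0.10, -0.05),
    "triacylglycerol": (0.005, -0.002, 0.30, 0.20),
    "hdl": (0.000, 0.002, -0.60, -0.20),
    "mean_bp": (0.030, -0.002, 0.20, 0.05),
}
# Target raw-scale stratum centres (NGM, IGM, T2D); medians for log-scaled
# markers. The generator solves for the latent stratum offsets that hit these
# after the composition and covariate contributions are accounted for.
_DEFAULT_STRATUM_MEDIAN = {
    "waist": (89.3, 97.8, 104.7),
    "fpg": (5.1, 6.0, 7.6),
    "two_h_plg": (5.4, 9.2, 14.5),
    "hba1c": (36.0, 38.0, 50.0),
    "isim": (4.4, 2.6, 1.9),
    "triacylglycerol": (1.2, 1.5, 1.8),
    "hdl": (1.6, 1.4, 1.2),
    "mean_bp": (95.0, 100.0, 103.0),
}
_DEFAULT_RESID_SD = {
    "waist": 0.90,
    "fpg": 0.35,
    "two_h_plg": 0.35,
    "hba1c": 0.35,
    "isim": 0.90,
    "triacylglycerol": 0.90,
    "hdl": 0.90,
    "mean_bp": 0.90,
}
# transform tag, location, scale on the transform scale
_DEFAULT_MARKER_SCALE = {
    "waist": ("identity", 89.3, 9.0),
    "fpg": ("log", float(np.log(5.3)), 0.15),
    "two_h_plg": ("log", float(np.log(5.6)), 0.20),
    "hba1c": ("log", float(np.log(36.0)), 0.10),
    "isim": ("identity", 4.4, 0.60),
    "triacylglycerol": ("log", float(np.log(1.2)), 0.20),
    "hdl": ("log", float(np.log(1.6)), 0.15),
    "mean_bp": ("identity", 97.0, 9.0),
}


@dataclass
class SyntheticConfig:
    """Full generating model for a synthetic cohort."""

    strata: dict[str, StratumConfig] = field(default_factory=_default_strata)
    log_cov: np.ndarray = field(default_factory=_default_log_cov)
    beta: dict[str, tuple] = field(default_factory=lambda: dict(_DEFAULT_BETA))
    gamma: dict[str, tuple] = field(default_factory=lambda: dict(_DEFAULT_GAMMA))
    stratum_median: dict[str, tuple] = field(default_factory=lambda: dict(_DEFAULT_STRATUM_MEDIAN))
    resid_sd: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_RESID_SD))
    marker_scale: dict[str, tuple] = field(default_factory=lambda: dict(_DEFAULT_MARKER_SCALE))
    day_jitter_sd: float = 0.06  # log-scale day-to-day behaviour jitter
    nonclassified_frac: float = 0.02  # waking time the monitor leaves unclassified
    invalid_day_prob: float = 0.03  # chance a mid-week day falls below 14 h waking

    def __post_init__(self):
        cov = np.asarray(self.log_cov, dtype=float)
        if cov.shape != (5, 5) or not np.allclose(cov, cov.T):
            raise ValueError("log_cov must be a symmetric 5x5 matrix")
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as e:
            raise ValueError("log_cov must be positive definite") from e
        self.log_cov = cov

    @property
    def n_total(self) -> int:
        return sum(s.n for s in self.strata.values())

    def to_yaml(self, path):
        payload = {
            "strata": {k: asdict(v) for k, v in self.strata.items()},
            "log_cov": self.log_cov.tolist(),
            "beta": {k: list(v) for k, v in self.beta.items()},
            "gamma": {k: list(v) for k, v in self.gamma.items()},
            "stratum_median": {k: list(v) for k, v in self.stratum_median.items()},
            "resid_sd": dict(self.resid_sd),
            "marker_scale": {k: list(v) for k, v in self.marker_scale.items()},
            "day_jitter_sd": self.day_jitter_sd,
            "nonclassified_frac": self.nonclassified_frac,
            "invalid_day_prob": self.invalid_day_prob,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            p = yaml.safe_load(fh)
        return cls(
            strata={
                k: StratumConfig(**{**v, "composition_centre": tuple(v["composition_centre"]),
                                    "education_freq": tuple(v["education_freq"]),
                                    "smoking_freq": tuple(v["smoking_freq"])})
                for k, v in p["strata"].items()
            },
            log_cov=np.asarray(p["log_cov"], dtype=float),
            beta={k: tuple(v) for k, v in p["beta"].items()},
            gamma={k: tuple(v) for k, v in p["gamma"].items()},
            stratum_median={k: tuple(v) for k, v in p["stratum_median"].items()},
            resid_sd=dict(p["resid_sd"]),
            marker_scale={k: tuple(v) for k, v in p["marker_scale"].items()},
            day_jitter_sd=p["day_jitter_sd"],
            nonclassified_frac=p["nonclassified_frac"],
            invalid_day_prob=p["invalid_day_prob"],
        )


def default_config(**overrides) -> SyntheticConfig:
    """The default study-like configuration, optionally with field overrides."""
    cfg = SyntheticConfig()
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise AttributeError(f"unknown config field {k!r}")
        setattr(cfg, k, v)
    return cfg


@dataclass
class TruthRecord:
    """Generating parameters plus derived standardised-scale truth."""

    seed: int
    beta_latent: dict[str, np.ndarray]
    beta_z: dict[str, np.ndarray]  # per analysis outcome, incl. derived CMR
    sd_latent: dict[str, float]  # SD of each latent component in the mixture
    resid_sd_z: dict[str, float]  # residual SD on the standardised scale
    ilr_mean: dict[str, np.ndarray]  # per-stratum ilr centres
    config: SyntheticConfig

    def to_yaml(self, path):
        payload = {
            "seed": self.seed,
            "beta_latent": {k: np.asarray(v).tolist() for k, v in self.beta_latent.items()},
            "beta_z": {k: np.asarray(v).tolist() for k, v in self.beta_z.items()},
            "sd_latent": {k: float(v) for k, v in self.sd_latent.items()},
            "resid_sd_z": {k: float(v) for k, v in self.resid_sd_z.items()},
            "ilr_mean": {k: np.asarray(v).tolist() for k, v in self.ilr_mean.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def _gamma_mean(cfg: SyntheticConfig, c: str, s: StratumConfig) -> float:
    """Stratum mean of the covariate contribution to component ``c``."""
    g_age, g_diet, g_sex, g_smk = cfg.gamma[c]
    q_cur = _norm(s.smoking_freq)[2]
    return (
        g_age * (s.age_mean - 60.0)
        + g_diet * (s.diet_mean - 84.0)
        + g_sex * s.sex_m_frac
        + g_smk * q_cur
    )


def _stratum_shifts(cfg: SyntheticConfig) -> dict[str, np.ndarray]:
    """Latent offsets per stratum solving for the configured raw centres.

    The target centre maps through the marker transform to a latent mean;
    the composition and covariate mean contributions are subtracted so the
    realised stratum centre lands on target.
    """
    out = {}
    for c in COMPONENTS:
        tag, loc, scale = cfg.marker_scale[c]
        shifts = []
        for si, s in enumerate(cfg.strata.values()):
            target = cfg.stratum_median[c][si]
            t = np.log(target) if tag == "log" else target
            z_target = (t - loc) / scale
            mu_ilr = ilr_transform(close(np.asarray(s.composition_centre, float)))
            beta = np.asarray(cfg.beta[c], float)
            shifts.append(z_target - float(beta @ mu_ilr) - _gamma_mean(cfg, c, s))
        out[c] = np.asarray(shifts)
    return out


def _stratum_moments(cfg: SyntheticConfig):
    """Per-stratum mean and variance of each latent component, analytically."""
    V = CANONICAL_BASIS.contrast_matrix
    sigma_ilr = V.T @ cfg.log_cov @ V
    shifts = _stratum_shifts(cfg)
    weights, means, variances = {}, {}, {}
    n = cfg.n_total
    for si, (sname, s) in enumerate(cfg.strata.items()):
        w = s.n / n
        mu_ilr = ilr_transform(close(np.asarray(s.composition_centre, float)))
        p_m, q_cur = s.sex_m_frac, _norm(s.smoking_freq)[2]
        for c in COMPONENTS:
            beta = np.asarray(cfg.beta[c], float)
            g_age, g_diet, g_sex, g_smk = cfg.gamma[c]
            m = shifts[c][si] + float(beta @ mu_ilr) + _gamma_mean(cfg, c, s)
            v = (
                float(beta @ sigma_ilr @ beta)
                + g_age**2 * s.age_sd**2
                + g_diet**2 * s.diet_sd**2
                + g_sex**2 * p_m * (1 - p_m)
                + g_smk**2 * q_cur * (1 - q_cur)
                + cfg.resid_sd[c] ** 2
            )
            weights.setdefault(c, []).append(w)
            means.setdefault(c, []).append(m)
            variances.setdefault(c, []).append(v)
    return sigma_ilr, weights, means, variances


def _component_sd(cfg: SyntheticConfig) -> dict[str, float]:
    _, weights, means, variances = _stratum_moments(cfg)
    out = {}
    for c in COMPONENTS:
        w = np.asarray(weights[c])
        m = np.asarray(means[c])
        v = np.asarray(variances[c])
        grand = float(w @ m)
        out[c] = float(np.sqrt(w @ v + w @ (m - grand) ** 2))
    return out


def _component_cov(cfg: SyntheticConfig, comps: tuple[str, ...]) -> np.ndarray:
    """Covariance matrix of latent components (residuals independent)."""
    sigma_ilr, weights, means, _ = _stratum_moments(cfg)
    k = len(comps)
    cov = np.zeros((k, k))
    strata = list(cfg.strata.values())
    w = np.array([s.n for s in strata], float) / cfg.n_total
    M = np.array([means[c] for c in comps])  # (k, strata)
    grand = M @ w
    for a in range(k):
        for b in range(k):
            ca, cb = comps[a], comps[b]
            beta_a = np.asarray(cfg.beta[ca], float)
            beta_b = np.asarray(cfg.beta[cb], float)
            within = float(beta_a @ sigma_ilr @ beta_b)
            for si, s in enumerate(strata):
                ga, gb = cfg.gamma[ca], cfg.gamma[cb]
                p_m, q_cur = s.sex_m_frac, s.smoking_freq[2]
                within_s = (
                    ga[0] * gb[0] * s.age_sd**2
                    + ga[1] * gb[1] * s.diet_sd**2
                    + ga[2] * gb[2] * p_m * (1 - p_m)
                    + ga[3] * gb[3] * q_cur * (1 - q_cur)
                )
                cov[a, b] += w[si] * within_s
            cov[a, b] += within
            if ca == cb:
                cov[a, b] += cfg.resid_sd[ca] ** 2
            cov[a, b] += float(w @ ((M[a] - grand[a]) * (M[b] - grand[b])))
    return cov


def standardised_truth(cfg: SyntheticConfig) -> tuple[dict, dict, dict]:
    """True coefficients on the analysis (z-score) scale, analytically.

    For directly generated outcomes beta_z = beta / SD(latent); the derived
    CMR outcome averages its five components' standardised coefficients
    (HDL sign-flipped) and is rescaled by the CMR SD (it is re-z-scored in
    the pipeline).
    """
    sd = _component_sd(cfg)
    beta_z = {}
    resid_sd_z = {}
    for c in ("waist", "fpg", "two_h_plg", "hba1c", "isim"):
        beta_z[c] = np.asarray(cfg.beta[c], float) / sd[c]
        resid_sd_z[c] = cfg.resid_sd[c] / sd[c]
    cmr_comps = ("waist", "fpg", "triacylglycerol", "hdl", "mean_bp")
    signs = np.array([1.0, 1.0, 1.0, -1.0, 1.0])
    beta_cmr = sum(
        sg * np.asarray(cfg.beta[c], float) / sd[c] for sg, c in zip(signs, cmr_comps)
    ) / 5.0
    cov = _component_cov(cfg, cmr_comps)
    d = np.diag(1.0 / np.array([sd[c] for c in cmr_comps]))
    corr = d @ cov @ d  # covariance of the standardised components
    w_vec = signs / 5.0
    sd_cmr = float(np.sqrt(w_vec @ corr @ w_vec))
    beta_z["cmr"] = beta_cmr / sd_cmr
    resid_noise = np.array([cfg.resid_sd[c] / sd[c] for c in cmr_comps])
    resid_sd_z["cmr"] = float(np.sqrt(np.sum((w_vec * resid_noise) ** 2)) / sd_cmr)
    sd["cmr"] = sd_cmr
    return beta_z, sd, resid_sd_z


def generate_cohort(
    cfg: SyntheticConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, TruthRecord]:
    """Draw a full participant table plus its truth record.

    Deterministic given (cfg, seed); behaviour/covariate/marker draws use
    sub-streams spawned from the seed so stages stay reproducible if others
    are added.
    """
    cfg = cfg or default_config()
    ss = np.random.SeedSequence(seed)
    rng_comp, rng_cov, rng_mark = (np.random.default_rng(c) for c in ss.spawn(3))

    chol = np.linalg.cholesky(cfg.log_cov)
    shifts = _stratum_shifts(cfg)
    rows = []
    pid = 0
    ilr_means = {}
    for si, (sname, s) in enumerate(cfg.strata.items()):
        centre = close(np.asarray(s.composition_centre, float))
        ilr_means[sname] = ilr_transform(centre)
        eps = rng_comp.standard_normal((s.n, 5)) @ chol.T
        comp = close(centre * np.exp(eps))

        age = rng_cov.normal(s.age_mean, s.age_sd, s.n)
        diet = np.clip(rng_cov.normal(s.diet_mean, s.diet_sd, s.n), 0.0, 140.0)
        sex = np.where(rng_cov.random(s.n) < s.sex_m_frac, "M", "F")
        edu = rng_cov.choice(["low", "medium", "high"], size=s.n, p=_norm(s.education_freq))
        smoke = rng_cov.choice(["never", "former", "current"], size=s.n, p=_norm(s.smoking_freq))
        med = rng_cov.random(s.n) < s.med_frac

        z = ilr_transform(comp)
        x_eff = {}
        for c in COMPONENTS:
            g_age, g_diet, g_sex, g_smk = cfg.gamma[c]
            lin = (
                shifts[c][si]
                + z @ np.asarray(cfg.beta[c], float)
                + g_age * (age - 60.0)
                + g_diet * (diet - 84.0)
                + g_sex * (sex == "M")
                + g_smk * (smoke == "current")
            )
            x_eff[c] = lin + rng_mark.normal(0.0, cfg.resid_sd[c], s.n)

        raw = {}
        for c in COMPONENTS:
            tag, loc, scale = cfg.marker_scale[c]
            t = loc + scale * x_eff[c]
            raw[c] = np.exp(t) if tag == "log" else t
        raw["waist"] = np.clip(raw["waist"], 55.0, None)
        raw["isim"] = np.clip(raw["isim"], 0.2, None)
        raw["mean_bp"] = np.clip(raw["mean_bp"], 60.0, None)

        mean_g = raw["fpg"] * 1.35 * np.exp(rng_mark.normal(0.0, 0.05, s.n))
        prod = (10000.0 / raw["isim"]) ** 2 / (raw["fpg"] * mean_g)  # FPI * meanI
        fpi = np.sqrt(prod / 4.0)  # mean OGTT insulin set to 4x fasting
        mean_i = 4.0 * fpi

        pp = np.clip(rng_mark.normal(50.0, 8.0, s.n), 20.0, 100.0)
        sbp = raw["mean_bp"] + pp / 2.0
        dbp = raw["mean_bp"] - pp / 2.0

        for i in range(s.n):
            pid += 1
            row = {
                "participant_id": f"P{pid:05d}",
                "stratum_true": sname,
                "diabetes_status": sname,
                **{p: comp[i, k] for k, p in enumerate(PARTS)},
                "age": age[i],
                "diet_score": diet[i],
                "sex": sex[i],
                "education": edu[i],
                "smoking": smoke[i],
                "glucose_lowering_med": bool(med[i]),
                "waist": raw["waist"][i],
                "fpg": raw["fpg"][i],
                "two_h_plg": raw["two_h_plg"][i],
                "hba1c": raw["hba1c"][i],
                "triacylglycerol": raw["triacylglycerol"][i],
                "hdl": raw["hdl"][i],
                "sbp": sbp[i],
                "dbp": dbp[i],
                "fpi": fpi[i],
                "mean_ogtt_glucose": mean_g[i],
                "mean_ogtt_insulin": mean_i[i],
            }
            for c in ("waist", "fpg", "two_h_plg", "hba1c", "isim"):
                row[f"latent_{c}"] = x_eff[c][i]
            rows.append(row)

    table = pd.DataFrame(rows)
    beta_z, sd_latent, resid_sd_z = standardised_truth(cfg)
    truth = TruthRecord(
        seed=seed,
        beta_latent={c: np.asarray(cfg.beta[c], float) for c in COMPONENTS},
        beta_z=beta_z,
        sd_latent=sd_latent,
        resid_sd_z=resid_sd_z,
        ilr_mean=ilr_means,
        config=cfg,
    )
    return table, truth


def generate_day_records(
    cfg: SyntheticConfig, participants: pd.DataFrame, seed: int = 0, n_days: int = 8
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Day-level wear records mimicking an 8-day continuous-wear protocol.

    Returns (days, epochs) tables in the aggregation module's CSV layout.
    Day 1 is the clinic day; the final day's recorded hours are drawn short
    often enough to exercise the last-day rule; occasional short-waking days
    exercise the 14 h validity rule. Per-day behaviours are the participant's
    composition under multiplicative log-normal jitter, with a small
    unclassified-waking remainder.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[3])
    day_rows, epoch_rows = [], []
    for r in participants.itertuples():
        base = np.array([getattr(r, p) for p in PARTS])
        for d in range(1, n_days + 1):
            jit = np.exp(rng.normal(0.0, cfg.day_jitter_sd, 5))
            parts = base * jit
            sleep = min(parts[4], 1200.0)
            waking = TOTAL_MINUTES - sleep
            if d > 1 and rng.random() < cfg.invalid_day_prob:
                waking = rng.uniform(600.0, 835.0)
            classify = waking * (1.0 - cfg.nonclassified_frac)
            w4 = parts[:4] / parts[:4].sum() * classify
            recorded = 24.0 if d < n_days else rng.uniform(6.0, 24.0)
            day_rows.append(
                {
                    "participant_id": r.participant_id,
                    "day_index": d,
                    "recorded_hours": recorded,
                    "waking_minutes": waking,
                    "sitting_minutes": w4[0],
                    "standing_minutes": w4[1],
                    "is_last_day": d == n_days,
                }
            )
            for dur, lo, hi in ((w4[2] / 2, 60, 85), (w4[2] / 2, 85, 100),
                                (w4[3] / 2, 100, 115), (w4[3] / 2, 115, 135)):
                epoch_rows.append(
                    {
                        "participant_id": r.participant_id,
                        "day_index": d,
                        "duration_min": dur,
                        "cadence": rng.uniform(lo, hi),
                    }
                )
    return pd.DataFrame(day_rows), pd.DataFrame(epoch_rows)
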
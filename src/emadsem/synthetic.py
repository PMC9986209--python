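"""Synthetic EMA study generator.

Emulates a two-week smartphone ecological momentary assessment (EMA) design
in which young adults answer four quasi-randomly timed prompts per day
(10:00-22:00) about momentary perceived stress (4 items, sum score 4-20) and
negative affect (7 items, sum score 7-35), with imperfect compliance, and a
single lab wave supplying 9 ADHD trait items and 14 internalising items
(1-5 Likert) plus demographic covariates.

The generative model mirrors the analysis model end to end:

* within person, latent stress/affect deviations follow a bivariate VAR(1)
  on an equidistant 4-hour grid, with person-specific means, autoregressive
  and cross-lagged coefficients (six random effects);
* between persons, the six random effects are linear in a latent ADHD
  factor (plus optional covariates) with independent normal residuals;
* a latent internalising factor is a linear function of the six random
  effects and ADHD;
* both trait factors are measured by ordinal 1-5 items produced by
  discretising continuous linear-factor propensities at fixed thresholds.

Every draw flows through a single :class:`numpy.random.Generator`, so a
fixed seed reproduces the dataset bit for bit on any platform (PCG64).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RE_NAMES",
    "DesignConfig",
    "RandomEffectVector",
    "TrueModel",
    "SyntheticDataset",
    "NonStationaryError",
    "study_truth",
    "sample_schedule",
    "simulate_person_series",
    "simulate_traits",
    "simulate_dataset",
    "stationary_covariance",
]

#: Canonical order of the six person-specific random effects.
RE_NAMES = ("mu_s", "mu_a", "phi_ss", "phi_aa", "phi_as", "phi_sa")

#: Index of the phi-block entries of ``RE_NAMES`` in transition-matrix
#: (row-major) order: stress equation (phi_ss, phi_as), affect equation
#: (phi_sa, phi_aa).
PHI_RE_IDX = np.array([2, 4, 5, 3])

MINUTES_PER_DAY = 1440


class NonStationaryError(ValueError):
    """Raised when a requested VAR(1) transition matrix is non-stationary."""


# ---------------------------------------------------------------------------
# configuration / parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignConfig:
    """Prompt-schedule design of the EMA study.

    Defaults reproduce the emulated study: 262 persons, 14 days, four
    prompts per day in the 10:00-22:00 window, ~67% compliance.
    """

    n_persons: int = 262
    n_days: int = 14
    prompts_per_day: int = 4
    window_start: float = 10.0
    window_end: float = 22.0
    compliance: float = 0.67
    min_gap: float = 30.0  # minutes, enforced between consecutive prompts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 1 or self.n_days < 1 or self.prompts_per_day < 1:
            raise ValueError("n_persons, n_days and prompts_per_day must be positive")
        if not self.window_end > self.window_start:
            raise ValueError("window_end must be later than window_start")
        if not 0.0 <= self.compliance <= 1.0:
            raise ValueError("compliance must be a probability")
        window_min = (self.window_end - self.window_start) * 60.0
        if self.prompts_per_day * self.min_gap > window_min:
            raise ValueError(
                f"window of {window_min:.0f} min cannot hold "
                f"{self.prompts_per_day} prompts with a {self.min_gap:.0f} min gap"
            )

    @property
    def window_minutes(self) -> float:
        return (self.window_end - self.window_start) * 60.0


@dataclass(frozen=True)
class RandomEffectVector:
    """The six person-specific latent dynamics parameters."""

    mu_s: float
    mu_a: float
    phi_ss: float
    phi_aa: float
    phi_as: float  # affect -> stress (stress equation)
    phi_sa: float  # stress -> affect (affect equation)

    @property
    def phi_matrix(self) -> np.ndarray:
        """2x2 VAR(1) transition matrix, rows = (stress, affect) equations."""
        return np.array([[self.phi_ss, self.phi_as], [self.phi_sa, self.phi_aa]])

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in RE_NAMES])

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "RandomEffectVector":
        return cls(**dict(zip(RE_NAMES, np.asarray(a, dtype=float))))


@dataclass
class TrueModel:
    """Full generative parameter set, on the observed sum-score scale.

    ``gamma`` columns follow ``predictors``; rows follow :data:`RE_NAMES`.
    ``beta_int`` follows ``int_predictors`` (the six random effects, then
    ADHD, then any covariates); ``beta_int_const`` centres the latent
    internalising factor at zero under the generating distribution.
    """

    re_means: np.ndarray                      # (6,)
    gamma: np.ndarray                         # (6, n_pred)
    re_resid_sd: np.ndarray                   # (6,)
    sigma_w: np.ndarray                       # (2, 2) innovation covariance
    predictors: tuple = ("adhd",)
    beta_int: np.ndarray = None               # (6 + n_pred,)
    beta_int_const: float = 0.0
    int_resid_sd: float = 1.0
    adhd_var: float = 1.0
    lambda_adhd: np.ndarray = None            # (9,)
    lambda_int: np.ndarray = None             # (14,)
    cross_loading: float = 0.25               # 'restless inside' item on internalising
    cross_item: int = 3                       # 0-based index into the ADHD items
    item_resid_sd_adhd: np.ndarray = None     # (9,)
    item_resid_sd_int: np.ndarray = None      # (14,)
    thresholds: np.ndarray = None             # (4,) shared cut-points

    def __post_init__(self) -> None:
        self.re_means = np.asarray(self.re_means, dtype=float)
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        self.re_resid_sd = np.asarray(self.re_resid_sd, dtype=float)
        self.sigma_w = np.asarray(self.sigma_w, dtype=float)
        if self.lambda_adhd is None:
            self.lambda_adhd = np.full(9, 0.66)
        if self.lambda_int is None:
            self.lambda_int = np.full(14, 0.66)
        self.lambda_adhd = np.asarray(self.lambda_adhd, dtype=float)
        self.lambda_int = np.asarray(self.lambda_int, dtype=float)
        if self.item_resid_sd_adhd is None:
            self.item_resid_sd_adhd = np.sqrt(
                np.clip(1.0 - self.lambda_adhd**2, 0.05, None)
            )
        if self.item_resid_sd_int is None:
            self.item_resid_sd_int = np.sqrt(
                np.clip(1.0 - self.lambda_int**2, 0.05, None)
            )
        if self.thresholds is None:
            self.thresholds = np.array([-1.5, -0.5, 0.5, 1.5])
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.beta_int is None:
            self.beta_int = np.zeros(6 + self.gamma.shape[1])
        self.beta_int = np.asarray(self.beta_int, dtype=float)
        self._validate()

    def _validate(self) -> None:
        if self.re_means.shape != (6,):
            raise ValueError("re_means must have 6 entries")
        if self.gamma.shape[0] != 6:
            raise ValueError("gamma must have one row per random effect")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if np.any(np.linalg.eigvalsh(self.sigma_w) <= 0):
            raise ValueError("sigma_w must be positive definite")
        if np.any(self.re_resid_sd < 0) or self.int_resid_sd < 0:
            raise ValueError("residual SDs must be non-negative")

    @property
    def int_predictors(self) -> tuple:
        return tuple(RE_NAMES) + tuple(self.predictors)


@dataclass
class SyntheticDataset:
    """A simulated study: EMA records, person-level table, and the truth."""

    ema: pd.DataFrame
    persons: pd.DataFrame
    truth: TrueModel
    latents: dict
    config: DesignConfig

    def to_csv(self, ema_path, persons_path) -> None:
        self.ema.to_csv(ema_path, index=False)
        self.persons.to_csv(persons_path, index=False)


# ---------------------------------------------------------------------------
# reference generating truth
# ---------------------------------------------------------------------------

# Standardised generating values for the baseline model: population means of
# the within-person dynamics, effects of latent ADHD on each random effect,
# and the internalising structural equation.  The covariate variant adds
# sex / caregiver-origin / childhood-SES blocks.
_STD_BASE = {
    "phi_mean": {"phi_ss": 0.277, "phi_aa": 0.183, "phi_as": 0.032, "phi_sa": 0.115},
    "gamma_adhd": {
        "mu_s": 0.259, "mu_a": 0.359,
        "phi_ss": 0.392, "phi_aa": -0.245, "phi_as": -0.205, "phi_sa": 0.464,
    },
    "beta_int": {
        "mu_s": 0.102, "mu_a": 0.331,
        "phi_ss": 0.191, "phi_aa": 0.019, "phi_as": 0.019, "phi_sa": 0.019,
        "adhd": 0.426,
    },
}

_STD_COV = {
    "gamma_adhd": {
        "mu_s": 0.324, "mu_a": 0.364,
        "phi_ss": 0.041, "phi_aa": 0.181, "phi_as": 0.150, "phi_sa": 0.088,
    },
    "gamma_sex": {
        "mu_s": 0.158, "mu_a": 0.114,
        "phi_ss": 0.134, "phi_aa": 0.032, "phi_as": -0.112, "phi_sa": -0.004,
    },
    "gamma_origin": {
        "mu_s": -0.091, "mu_a": -0.006,
        "phi_ss": 0.325, "phi_aa": -0.360, "phi_as": -0.300, "phi_sa": 0.313,
    },
    "gamma_ses": {
        "mu_s": 0.151, "mu_a": 0.053,
        "phi_ss": 0.411, "phi_aa": -0.376, "phi_as": -0.356, "phi_sa": 0.335,
    },
    "beta_int": {
        "mu_s": 0.151, "mu_a": 0.270,
        "phi_ss": 0.189, "phi_aa": 0.028, "phi_as": 0.027, "phi_sa": 0.053,
        "adhd": 0.465, "sex": 0.147, "origin": 0.000, "ses": -0.110,
    },
}

# Scale choices for mapping the standardised truth onto the sum-score metric.
# Means and SDs of the person-mean random effects are placed well inside the
# score ranges (4-20 and 7-35) so that floor/ceiling clipping is rare (~2% of
# observations); within-person deviation scales give realistic momentary SDs.
# Random-effect SDs of the dynamics parameters are set to values typical of
# EMA emotion dynamics (0.15-0.22), which also reproduce the order of
# posterior precision the emulated study reports for the trait-moderation
# paths; with much smaller spreads those person-specific coefficients would
# be swamped by their single-person estimation error and the moderation
# paths would be far less precisely estimable than in the study.
_SCALES = {
    "mu_s_mean": 9.5, "mu_s_sd": 1.8,
    "mu_a_mean": 14.0, "mu_a_sd": 2.2,
    "phi_sd": {"phi_ss": 0.22, "phi_aa": 0.22, "phi_as": 0.15, "phi_sa": 0.18},
    "c_s": 1.8,   # within-person stationary SD of stress on the sum scale
    "c_a": 2.6,   # within-person stationary SD of affect on the sum scale
}

# Marginal distributions of the person-level covariates (sample margins of
# the emulated cohort): male share, non-Swiss caregiver share, childhood SES.
COVARIATE_MARGINS = {
    "p_male": 0.387,
    "p_origin_other": 0.375,
    "ses_mean": 49.09,
    "ses_sd": 17.58,
    "ses_range": (16.0, 88.0),
}

#: Variances of the (independent) covariates after coding: sex male=1,
#: origin other=1, SES z-scored.
_COV_VAR = {
    "sex": COVARIATE_MARGINS["p_male"] * (1 - COVARIATE_MARGINS["p_male"]),
    "origin": COVARIATE_MARGINS["p_origin_other"]
    * (1 - COVARIATE_MARGINS["p_origin_other"]),
    "ses": 1.0,
}


def _re_total_sd(name: str) -> float:
    if name == "mu_s":
        return _SCALES["mu_s_sd"]
    if name == "mu_a":
        return _SCALES["mu_a_sd"]
    # phi random effects live on the latent unit-variance within scale; on
    # the observed scale cross-lagged terms pick up the ratio of the two
    # within-person deviation scales.
    sd = _SCALES["phi_sd"][name]
    if name == "phi_as":
        sd *= _SCALES["c_s"] / _SCALES["c_a"]
    elif name == "phi_sa":
        sd *= _SCALES["c_a"] / _SCALES["c_s"]
    return sd


def _phi_obs(name: str, value: float) -> float:
    if name == "phi_as":
        return value * _SCALES["c_s"] / _SCALES["c_a"]
    if name == "phi_sa":
        return value * _SCALES["c_a"] / _SCALES["c_s"]
    return value


def study_truth(covariates: bool = False) -> TrueModel:
    """Reference generating truth for the emulated study.

    Standardised structural coefficients are converted to the raw
    (sum-score) scale using the documented scale choices; standardisation of
    the fitted model therefore recovers the standardised values regardless
    of the raw metric.
    """
    std = _STD_COV if covariates else _STD_BASE
    phi_mean_std = _STD_BASE["phi_mean"]
    preds = ("adhd", "sex", "origin", "ses") if covariates else ("adhd",)

    re_means = np.array(
        [
            _SCALES["mu_s_mean"],
            _SCALES["mu_a_mean"],
            phi_mean_std["phi_ss"],
            phi_mean_std["phi_aa"],
            _phi_obs("phi_as", phi_mean_std["phi_as"]),
            _phi_obs("phi_sa", phi_mean_std["phi_sa"]),
        ]
    )

    pred_sd = {"adhd": 1.0, "sex": np.sqrt(_COV_VAR["sex"]),
               "origin": np.sqrt(_COV_VAR["origin"]), "ses": 1.0}

    gamma = np.zeros((6, len(preds)))
    std_gamma = np.zeros((6, len(preds)))
    for j, p in enumerate(preds):
        block = std[f"gamma_{p}"]
        for k, name in enumerate(RE_NAMES):
            std_gamma[k, j] = block[name]
            gamma[k, j] = block[name] * _re_total_sd(name) / pred_sd[p]

    # residual SDs so that each random effect has the chosen total SD
    # (predictors are mutually independent in the generator)
    re_resid_sd = np.empty(6)
    for k, name in enumerate(RE_NAMES):
        explained = float(np.sum(std_gamma[k] ** 2))
        if explained >= 1.0:
            raise ValueError(f"standardised effects on {name} explain >= 100%")
        re_resid_sd[k] = _re_total_sd(name) * np.sqrt(1.0 - explained)

    # innovation covariance: unit stationary variances at the population-mean
    # transition matrix on the latent scale, then rescaled to the sum metric
    phi_bar = np.array(
        [
            [phi_mean_std["phi_ss"], phi_mean_std["phi_as"]],
            [phi_mean_std["phi_sa"], phi_mean_std["phi_aa"]],
        ]
    )
    sigma_lat = np.eye(2) - phi_bar @ phi_bar.T
    c = np.diag([_SCALES["c_s"], _SCALES["c_a"]])
    sigma_w = c @ sigma_lat @ c

    # internalising equation: raw slopes from standardised targets, residual
    # variance solving for unit total latent variance
    int_names = tuple(RE_NAMES) + preds
    beta_std = np.array([std["beta_int"][n] for n in int_names])
    pred_sds = np.array([_re_total_sd(n) for n in RE_NAMES] + [pred_sd[p] for p in preds])
    beta_raw = beta_std / pred_sds

    # model-implied covariance of (random effects, adhd, covariates)
    n_tot = 6 + len(preds)
    cov = np.zeros((n_tot, n_tot))
    pred_var = np.array([pred_sd[p] ** 2 for p in preds])
    cov[6:, 6:] = np.diag(pred_var)
    cov[:6, :6] = gamma @ np.diag(pred_var) @ gamma.T + np.diag(re_resid_sd**2)
    cov[:6, 6:] = gamma @ np.diag(pred_var)
    cov[6:, :6] = cov[:6, 6:].T
    explained = float(beta_raw @ cov @ beta_raw)
    if explained >= 1.0:
        raise ValueError("internalising equation explains >= 100% of variance")
    int_resid_sd = float(np.sqrt(1.0 - explained))
    means = np.concatenate([re_means, np.zeros(len(preds))])
    beta_const = -float(beta_raw @ means)

    return TrueModel(
        re_means=re_means,
        gamma=gamma,
        re_resid_sd=re_resid_sd,
        sigma_w=sigma_w,
        predictors=preds,
        beta_int=beta_raw,
        beta_int_const=beta_const,
        int_resid_sd=int_resid_sd,
    )


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------


def sample_schedule(cfg: DesignConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a quasi-random prompt schedule with Bernoulli compliance.

    One prompt is drawn uniformly inside each of ``prompts_per_day`` equal
    strata of the daily window (stratified sampling); days violating the
    minimum inter-prompt gap are redrawn.  Returns a long DataFrame with
    columns ``person_id, day, prompt, t_minutes, answered`` where
    ``t_minutes`` counts from midnight of study day 1.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    p, d, k = cfg.n_persons, cfg.n_days, cfg.prompts_per_day
    stratum = cfg.window_minutes / k
    offsets = np.arange(k) * stratum

    times = offsets + rng.uniform(0.0, stratum, size=(p, d, k))
    if k > 1:
        # redraw days whose consecutive prompts are closer than min_gap
        for _ in range(1000):
            bad = (np.diff(times, axis=2) < cfg.min_gap).any(axis=2)
            if not bad.any():
                break
            times[bad] = offsets + rng.uniform(0.0, stratum, size=(int(bad.sum()), k))
        else:  # pragma: no cover - unreachable for sane configs
            raise RuntimeError("could not satisfy the minimum prompt gap")

    day_idx = np.arange(d)
    t_minutes = (
        day_idx[None, :, None] * MINUTES_PER_DAY
        + cfg.window_start * 60.0
        + times
    )
    answered = rng.random(size=(p, d, k)) < cfg.compliance

    out = pd.DataFrame(
        {
            "person_id": np.repeat(np.arange(p), d * k),
            "day": np.tile(np.repeat(day_idx + 1, k), p),
            "prompt": np.tile(np.arange(1, k + 1), p * d),
            "t_minutes": t_minutes.reshape(-1),
            "answered": answered.reshape(-1),
        }
    )
    return out


# ---------------------------------------------------------------------------
# within-person dynamics
# ---------------------------------------------------------------------------


def shift_assign(raw_bins: np.ndarray) -> np.ndarray:
    """Resolve bin collisions by pushing later records to the next free bin.

    ``raw_bins`` must be sorted (records in time order).  This is the
    "approximately equidistant" forcing rule: every record keeps a slot of
    its own.  Shared between the generator and the time-gridder so the two
    agree exactly on which grid state each record observes.
    """
    out = np.empty_like(raw_bins)
    last = -1
    for i, b in enumerate(raw_bins):
        b = max(int(b), last + 1)
        out[i] = b
        last = b
    return out


def stationary_covariance(phi: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Stationary covariance of a VAR(1): solves V = phi V phi' + sigma."""
    phi = np.asarray(phi, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    k = phi.shape[0]
    a = np.eye(k * k) - np.kron(phi, phi)
    v = np.linalg.solve(a, sigma.reshape(-1))
    return v.reshape(k, k)


def simulate_person_series(
    re: RandomEffectVector | np.ndarray,
    sigma_w: np.ndarray,
    n_slots: int,
    rng: np.random.Generator | int | None = None,
    max_radius: float = 0.95,
) -> np.ndarray:
    """Simulate latent (stress, affect) deviations on the equidistant grid.

    The initial state is drawn from the stationary distribution; transition
    matrices with spectral radius >= ``max_radius`` are rejected.
    Returns an ``(n_slots, 2)`` array of mean-zero deviations.
    """
    if not isinstance(re, RandomEffectVector):
        re = RandomEffectVector.from_array(re)
    if n_slots < 2:
        raise ValueError("need at least two grid slots")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    phi = re.phi_matrix
    radius = np.max(np.abs(np.linalg.eigvals(phi)))
    if radius >= max_radius:
        raise NonStationaryError(
            f"transition matrix has spectral radius {radius:.3f} >= {max_radius}"
        )
    v0 = stationary_covariance(phi, sigma_w)
    chol_v0 = np.linalg.cholesky(v0)
    chol_w = np.linalg.cholesky(sigma_w)
    eps = rng.standard_normal((n_slots, 2))
    d = np.empty((n_slots, 2))
    d[0] = chol_v0 @ eps[0]
    for t in range(1, n_slots):
        d[t] = phi @ d[t - 1] + chol_w @ eps[t]
    return d


def _simulate_deviations(
    phi: np.ndarray, sigma_w: np.ndarray, n_slots: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised VAR(1) simulation for all persons at once.

    ``phi`` is ``(n, 2, 2)``; returns ``(n, n_slots, 2)``.
    """
    n = phi.shape[0]
    eye = np.eye(4)
    a = eye[None] - np.einsum("nij,nkl->nikjl", phi, phi).reshape(n, 4, 4)
    v0 = np.linalg.solve(a, np.broadcast_to(sigma_w.reshape(-1), (n, 4))[..., None])
    v0 = v0.reshape(n, 2, 2)
    v0 = 0.5 * (v0 + np.swapaxes(v0, 1, 2))
    chol0 = np.linalg.cholesky(v0)
    chol_w = np.linalg.cholesky(sigma_w)
    eps = rng.standard_normal((n, n_slots, 2))
    d = np.empty((n, n_slots, 2))
    d[:, 0] = np.einsum("nij,nj->ni", chol0, eps[:, 0])
    for t in range(1, n_slots):
        d[:, t] = np.einsum("nij,nj->ni", phi, d[:, t - 1]) + eps[:, t] @ chol_w.T
    return d


# ---------------------------------------------------------------------------
# person-level traits
# ---------------------------------------------------------------------------


def categorize(propensity: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Discretise continuous propensities into 1..k+1 ordinal categories."""
    return 1 + np.searchsorted(np.asarray(thresholds), propensity).astype(np.int64)


def _simulate_items(
    factor: np.ndarray,
    loadings: np.ndarray,
    resid_sd: np.ndarray,
    thresholds: np.ndarray,
    rng: np.random.Generator,
    extra: np.ndarray | None = None,
) -> np.ndarray:
    """Ordinal item responses from a linear factor model.

    ``extra`` is an optional (n_persons, n_items) additive propensity term
    (used for the cross-loading item).
    """
    n = factor.shape[0]
    prop = factor[:, None] * loadings[None, :] + resid_sd[None, :] * rng.standard_normal(
        (n, loadings.size)
    )
    if extra is not None:
        prop = prop + extra
    return categorize(prop, thresholds)


def simulate_traits(
    n_persons: int,
    truth: TrueModel,
    rng: np.random.Generator | int | None = None,
    xi: np.ndarray | None = None,
):
    """Draw latent ADHD, covariates and ADHD item responses.

    ``xi`` (latent internalising) feeds the cross-loading item when the full
    dataset is assembled; standalone calls default it to zero so the ADHD
    items then measure ADHD only.  Returns ``(eta, covariates, adhd_items)``
    where covariates is a DataFrame with columns sex/origin/ses.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    eta = rng.standard_normal(n_persons) * np.sqrt(truth.adhd_var)

    m = COVARIATE_MARGINS
    sex = (rng.random(n_persons) < m["p_male"]).astype(np.int64)
    origin = (rng.random(n_persons) < m["p_origin_other"]).astype(np.int64)
    lo, hi = m["ses_range"]
    from scipy.stats import truncnorm

    a, b = (lo - m["ses_mean"]) / m["ses_sd"], (hi - m["ses_mean"]) / m["ses_sd"]
    ses = truncnorm.rvs(a, b, loc=m["ses_mean"], scale=m["ses_sd"],
                        size=n_persons, random_state=rng)
    covariates = pd.DataFrame({"sex": sex, "origin": origin, "ses": ses})

    if xi is None:
        xi = np.zeros(n_persons)
    extra = np.zeros((n_persons, truth.lambda_adhd.size))
    extra[:, truth.cross_item] = truth.cross_loading * xi
    adhd_items = _simulate_items(
        eta, truth.lambda_adhd, truth.item_resid_sd_adhd, truth.thresholds, rng,
        extra=extra,
    )
    return eta, covariates, adhd_items


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

STRESS_RANGE = (4, 20)
AFFECT_RANGE = (7, 35)


def _split_sum(total: np.ndarray, n_items: int, lo: int = 1, hi: int = 5) -> np.ndarray:
    """Deterministically decompose integer sum scores into valid item scores."""
    base = total // n_items
    rem = total - base * n_items
    items = np.repeat(base[:, None], n_items, axis=1)
    bump = np.arange(n_items)[None, :] < rem[:, None]
    items = items + bump
    return np.clip(items, lo, hi)


def simulate_dataset(
    cfg: DesignConfig,
    truth: TrueModel | None = None,
    seed: int | None = None,
) -> SyntheticDataset:
    """Simulate a complete study: schedule, dynamics, traits, responses.

    Deterministic given ``seed`` (falls back to ``cfg.seed``).
    """
    if truth is None:
        truth = study_truth(covariates=False)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_persons

    schedule = sample_schedule(cfg, rng)
    eta, covariates, _ = simulate_traits(n, truth, rng)  # items drawn again below

    # design matrix for the between-level regressions
    cols = []
    for p in truth.predictors:
        if p == "adhd":
            cols.append(eta)
        elif p == "ses":
            ses = covariates["ses"].to_numpy()
            cols.append((ses - ses.mean()) / ses.std())
        else:
            cols.append(covariates[p].to_numpy().astype(float))
    x = np.column_stack(cols)

    # random effects with stationarity rejection on the phi block
    re = truth.re_means[None, :] + x @ truth.gamma.T
    resid = rng.standard_normal((n, 6)) * truth.re_resid_sd[None, :]
    re = re + resid
    for _ in range(200):
        phi = re[:, PHI_RE_IDX].reshape(n, 2, 2)
        radius = np.max(np.abs(np.linalg.eigvals(phi)), axis=1)
        bad = radius >= 0.95
        if not bad.any():
            break
        nb = int(bad.sum())
        new = (
            truth.re_means[None, 2:]
            + (x[bad] @ truth.gamma.T)[:, 2:]
            + rng.standard_normal((nb, 4)) * truth.re_resid_sd[None, 2:]
        )
        re[bad, 2:] = new
    else:  # pragma: no cover
        raise NonStationaryError("could not draw stationary person dynamics")

    # latent internalising and trait items
    xi = (
        truth.beta_int_const
        + np.column_stack([re, x]) @ truth.beta_int
        + rng.standard_normal(n) * truth.int_resid_sd
    )
    extra = np.zeros((n, truth.lambda_adhd.size))
    extra[:, truth.cross_item] = truth.cross_loading * xi
    adhd_items = _simulate_items(
        eta, truth.lambda_adhd, truth.item_resid_sd_adhd, truth.thresholds, rng,
        extra=extra,
    )
    int_items = _simulate_items(
        xi, truth.lambda_int, truth.item_resid_sd_int, truth.thresholds, rng
    )

    # latent deviations on the full 4-hour grid spanning the study (a few
    # spare slots absorb end-of-study forward shifts)
    slots_per_day = MINUTES_PER_DAY // 240
    n_slots = cfg.n_days * slots_per_day + 4
    phi = re[:, PHI_RE_IDX].reshape(n, 2, 2)
    d = _simulate_deviations(phi, truth.sigma_w, n_slots, rng)

    # observed EMA records: each answered prompt observes the state of the
    # 4-hour grid slot it occupies after the "approximately equidistant"
    # forcing (collisions pushed forward), rounded to integer sum scores and
    # clipped to the scale ranges
    ans = schedule[schedule["answered"]].reset_index(drop=True)
    origin = cfg.window_start * 60.0
    raw_slot = np.floor((ans["t_minutes"].to_numpy() - origin) / 240.0).astype(np.int64)
    pid = ans["person_id"].to_numpy()
    slot = np.empty_like(raw_slot)
    for i in range(n):
        m = pid == i
        slot[m] = shift_assign(raw_slot[m])
    slot = np.clip(slot, 0, n_slots - 1)
    mu = re[:, :2]
    vals = mu[pid] + d[pid, slot]
    stress = np.clip(np.rint(vals[:, 0]), *STRESS_RANGE).astype(np.int64)
    affect = np.clip(np.rint(vals[:, 1]), *AFFECT_RANGE).astype(np.int64)

    s_items = _split_sum(stress, 4)
    a_items = _split_sum(affect, 7)

    start = pd.Timestamp("2021-01-04 00:00:00")
    ema = pd.DataFrame({"person_id": pid})
    ema["timestamp"] = (
        start + pd.to_timedelta(ans["t_minutes"].to_numpy(), unit="m")
    ).strftime("%Y-%m-%dT%H:%M:%S")
    ema["t_minutes"] = ans["t_minutes"].to_numpy()
    for j in range(4):
        ema[f"s{j+1}"] = s_items[:, j]
    for j in range(7):
        ema[f"a{j+1}"] = a_items[:, j]
    ema["stress_sum"] = stress
    ema["affect_sum"] = affect
    ema = ema.sort_values(["person_id", "t_minutes"]).reset_index(drop=True)

    persons = pd.DataFrame({"person_id": np.arange(n)})
    for j in range(9):
        persons[f"adhd{j+1}"] = adhd_items[:, j]
    for j in range(14):
        persons[f"int{j+1}"] = int_items[:, j]
    persons["sex"] = covariates["sex"]
    persons["origin"] = covariates["origin"]
    persons["ses"] = covariates["ses"]

    latents = {"eta": eta, "xi": xi, "re": re, "deviations": d, "schedule": schedule}
    return SyntheticDataset(ema=ema, persons=persons, truth=truth,
                            latents=latents, config=cfg)
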
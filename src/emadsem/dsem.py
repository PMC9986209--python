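"""Two-level Bayesian dynamic structural equation model (DSEM).

The model couples three parts:

1. **Within person** — observed stress/affect sum scores on the equidistant
   grid are decomposed as ``y_it = mu_i + d_it`` where the latent deviation
   ``d_it`` follows a person-specific bivariate VAR(1):
   ``d_it = Phi_i d_{i,t-1} + eps_it``, ``eps ~ N(0, Sigma_w)``.  Latent
   states at missing grid slots are treated as unknowns and sampled from
   their full conditionals.
2. **Between persons** — the six random effects (two means, two
   autoregressive, two cross-lagged coefficients) are linear in a latent
   ADHD factor (plus optional covariates) with independent normal
   residuals; a latent internalising factor is regressed on the six random
   effects and ADHD (plus covariates).
3. **Measurement** — both trait factors are measured by their 1-5 Likert
   items, treated as continuous with one reference loading per factor
   fixed to 1, plus a single configurable cross-loading.

Estimation is a blocked Gibbs sampler in which every update is an exact
conjugate draw (diffuse normal priors on locations, inverse-gamma on
variances, inverse-Wishart on the innovation covariance, a fixed diffuse
normal prior on each person's initial latent state).  Two (or more) chains
run in lock-step; convergence is monitored by the Potential Scale
Reduction (PSR) on the second half of each chain, and on first convergence
the iteration count is doubled before stopping, never exceeding the
iteration cap.  All randomness flows through per-chain PCG64 generators
spawned from one seed, so runs are exactly reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import invwishart
from sklearn.base import BaseEstimator

from .synthetic import RE_NAMES, PHI_RE_IDX, RandomEffectVector, stationary_covariance
from .timegrid import AlignedSeries

__all__ = [
    "MCMCConfig",
    "PosteriorDraws",
    "DynamicSEM",
    "run_mcmc",
    "psr",
    "within_model_loglik",
    "sample_latent_states",
    "sample_random_effects",
    "var_regression_posterior",
]

logger = logging.getLogger(__name__)

# priors (documented in the methods note).  Variances carry the flat
# p(tau^2) proportional to 1 prior (the IG(-1, 0) limit) and the innovation
# covariance the flat improper inverse-Wishart IW(0, -(p+1)); both match the
# default "uninformative" priors of the standard DSEM software and, unlike
# IG(eps, eps), do not pile prior mass at zero for weakly identified
# random-effect variances.  Posteriors are proper once a handful of
# persons/transitions inform each component.
LOC_PREC = 1e-6          # Normal(0, 1e6) on every location parameter
IG_A = -1.0              # flat prior on variances: IG(-1, 0)
IG_B = 0.0
IW_DF = -3               # flat prior on the 2x2 innovation covariance
INIT_STATE_VAR = 100.0   # diffuse N(0, 100 I) prior on each initial state


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings (defaults follow the original estimation recipe)."""

    n_chains: int = 2
    max_iterations: int = 50_000
    min_iterations: int = 0
    thinning: int = 10
    psr_threshold: float = 1.05
    burn_in_fraction: float = 0.5
    check_every: int = 2500
    double_on_first_convergence: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.n_chains < 2:
            raise ValueError("PSR needs at least two chains")
        if not 0 < self.burn_in_fraction < 1:
            raise ValueError("burn_in_fraction must be in (0,1)")


@dataclass
class PosteriorDraws:
    """Retained posterior draws with convergence diagnostics.

    ``params`` is ``(chains, draws, n_params)``; ``random_effects`` (if
    stored) is ``(chains, draws, n_persons, 6)`` in :data:`RE_NAMES` order.
    """

    params: np.ndarray
    names: list
    psr: np.ndarray
    converged: bool
    n_iterations: int
    thinning: int
    seeds: list
    random_effects: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("parameter names must be unique")
        self._idx = {n: i for i, n in enumerate(self.names)}

    @property
    def n_chains(self) -> int:
        return self.params.shape[0]

    @property
    def n_draws(self) -> int:
        return self.params.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (chains, draws)."""
        return self.params[:, :, self._idx[name]]

    def stacked(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def psr_of(self, name: str) -> float:
        return float(self.psr[self._idx[name]])

    def summary(self, point: str = "median") -> pd.DataFrame:
        """Posterior point estimate, SD and 95% equal-tailed interval."""
        flat = self.params.reshape(-1, self.params.shape[2])
        est = np.median(flat, axis=0) if point == "median" else flat.mean(axis=0)
        lo, hi = np.percentile(flat, [2.5, 97.5], axis=0)
        return pd.DataFrame(
            {"estimate": est, "sd": flat.std(axis=0, ddof=1),
             "ci_lower": lo, "ci_upper": hi, "psr": self.psr},
            index=self.names,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long columnar export (chain, draw, parameter columns)."""
        c, d, p = self.params.shape
        df = pd.DataFrame(self.params.reshape(c * d, p), columns=self.names)
        df.insert(0, "draw", np.tile(np.arange(d), c))
        df.insert(0, "chain", np.repeat(np.arange(c), d))
        return df


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def psr(draws: np.ndarray) -> np.ndarray:
    """Gelman-Rubin potential scale reduction, sqrt(((n-1)/n W + B/n)/W).

    ``draws`` is (chains, n) or (chains, n, n_params).  Values are floored
    at 1.0; a degenerate within-chain variance gives 1.0 when the chains
    agree and inf when they do not.
    """
    a = np.asarray(draws, dtype=float)
    if a.ndim == 2:
        a = a[:, :, None]
    m, n = a.shape[0], a.shape[1]
    if m < 2 or n < 2:
        raise ValueError("PSR needs >=2 chains with >=2 draws")
    means = a.mean(axis=1)                      # (m, P)
    w = a.var(axis=1, ddof=1).mean(axis=0)      # (P,)
    b = n * means.var(axis=0, ddof=1)           # (P,)
    out = np.empty(a.shape[2])
    ok = w > 1e-12 * np.maximum(1.0, np.abs(means).max(axis=0)) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        out[ok] = np.sqrt(((n - 1) / n * w[ok] + b[ok] / n) / w[ok])
    degen = ~ok
    out[degen] = np.where(b[degen] <= 1e-12, 1.0, np.inf)
    return np.maximum(out, 1.0) if out.size > 1 else np.maximum(out, 1.0)


# ---------------------------------------------------------------------------
# small building blocks (also used as oracles' counterparts in tests)
# ---------------------------------------------------------------------------


def var_regression_posterior(
    x: np.ndarray,
    y: np.ndarray,
    sigma: np.ndarray,
    prior_mean: np.ndarray,
    prior_cov: np.ndarray,
):
    """Conjugate posterior of VAR coefficients ``B`` in ``y_t = B x_t + e``.

    ``x`` is (T, p), ``y`` is (T, k), ``e ~ N(0, sigma)`` with known
    ``sigma``; the prior is N(prior_mean, prior_cov) on the row-major
    flattening of ``B`` (k*p,).  Returns (mean, cov) of the posterior.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    k, p = sigma.shape[0], x.shape[1]
    w = np.linalg.inv(sigma)
    a = x.T @ x                                   # (p, p)
    c = x.T @ y                                   # (p, k)
    prec_lik = np.kron(w, a)
    h_lik = (w @ c.T).reshape(-1)
    prior_prec = np.linalg.inv(np.atleast_2d(prior_cov))
    prec = prec_lik + prior_prec
    h = h_lik + prior_prec @ np.ravel(prior_mean)
    cov = np.linalg.inv(prec)
    return cov @ h, cov


def within_model_loglik(
    series: AlignedSeries | np.ndarray,
    re: RandomEffectVector | np.ndarray,
    sigma_w: np.ndarray,
) -> float:
    """Log-density of the within-person VAR(1) transitions.

    Deviations are the series values minus the person means in ``re``;
    transitions are counted where both adjacent slots are non-missing
    (latent states at missing slots are model unknowns and contribute
    nothing here).  A series of ``T+1`` complete slots yields ``T``
    transition terms.
    """
    if not isinstance(re, RandomEffectVector):
        re = RandomEffectVector.from_array(re)
    vals = series.values if isinstance(series, AlignedSeries) else np.asarray(series, float)
    sigma_w = np.asarray(sigma_w, dtype=float)
    sign, logdet = np.linalg.slogdet(sigma_w)
    if sign <= 0:
        raise ValueError("sigma_w must be positive definite")
    w = np.linalg.inv(sigma_w)
    d = vals - np.array([re.mu_s, re.mu_a])
    phi = re.phi_matrix
    ok = np.isfinite(d).all(axis=1)
    pair = ok[1:] & ok[:-1]
    r = d[1:][pair] - d[:-1][pair] @ phi.T
    quad = np.einsum("ti,ij,tj->", r, w, r)
    t = int(pair.sum())
    return float(-0.5 * (t * (2 * np.log(2 * np.pi) + logdet) + quad))


def sample_latent_states(
    series: AlignedSeries | np.ndarray,
    re: RandomEffectVector | np.ndarray,
    sigma_w: np.ndarray,
    rng: np.random.Generator | int | None = None,
    n_scans: int = 1,
    init_prior: str = "stationary",
) -> np.ndarray:
    """Gibbs-impute latent deviations at missing slots (exact full
    conditionals per slot, sequential scans).

    Returns the complete (T, 2) deviation array; observed slots are passed
    through unchanged.  ``init_prior`` controls the marginal prior on slot
    0 when it is missing: the stationary VAR distribution (default) or the
    sampler's diffuse normal.
    """
    if not isinstance(re, RandomEffectVector):
        re = RandomEffectVector.from_array(re)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    vals = series.values if isinstance(series, AlignedSeries) else np.asarray(series, float)
    mu = np.array([re.mu_s, re.mu_a])
    d = vals - mu
    obs = np.isfinite(d).all(axis=1)
    if not obs.any():
        raise ValueError("need at least one observed cell")
    t_n = d.shape[0]
    phi = re.phi_matrix
    w = np.linalg.inv(np.asarray(sigma_w, float))
    if init_prior == "stationary":
        p0 = np.linalg.inv(stationary_covariance(phi, sigma_w))
    else:
        p0 = np.eye(2) / INIT_STATE_VAR
    wphi = w @ phi
    ptwp = phi.T @ w @ phi
    ptw = phi.T @ w
    miss = np.flatnonzero(~obs)
    d[miss] = 0.0
    for _ in range(max(1, n_scans)):
        for t in miss:
            prec = (w if t > 0 else p0).copy()
            h = wphi @ d[t - 1] if t > 0 else np.zeros(2)
            if t + 1 < t_n:
                prec = prec + ptwp
                h = h + ptw @ d[t + 1]
            cov = np.linalg.inv(prec)
            d[t] = cov @ h + np.linalg.cholesky(cov) @ rng.standard_normal(2)
    return d


def sample_random_effects(
    series: AlignedSeries | np.ndarray,
    prior_mean: np.ndarray,
    prior_sd: np.ndarray,
    sigma_w: np.ndarray,
    rng: np.random.Generator | int | None = None,
    min_transitions: int = 3,
) -> RandomEffectVector:
    """One conjugate draw of a person's random-effect vector.

    ``prior_mean``/``prior_sd`` are the between-level prior (in
    :data:`RE_NAMES` order), e.g. intercept + gamma * ADHD_i.  The within
    likelihood uses observed-adjacent transitions only; persons with fewer
    than ``min_transitions`` usable transitions fall back to a prior draw
    (logged).  The phi block is drawn given the prior means; the mu block
    given the drawn phi.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    vals = series.values if isinstance(series, AlignedSeries) else np.asarray(series, float)
    prior_mean = np.asarray(prior_mean, float)
    prior_sd = np.asarray(prior_sd, float)
    ok = np.isfinite(vals).all(axis=1)
    pair = ok[1:] & ok[:-1]
    n_tr = int(pair.sum())
    if n_tr < min_transitions:
        logger.info("only %d usable transitions: drawing from the prior", n_tr)
        return RandomEffectVector.from_array(
            prior_mean + prior_sd * rng.standard_normal(6)
        )
    # mu block given data mean, phi block given resulting deviations
    mu_prior_m, mu_prior_sd = prior_mean[:2], prior_sd[:2]
    n_obs = int(ok.sum())
    ybar = vals[ok].mean(axis=0)
    vbar = np.diag(np.asarray(sigma_w, float)) / n_obs  # crude obs precision
    post_var = 1.0 / (1.0 / mu_prior_sd**2 + 1.0 / vbar)
    post_mean = post_var * (mu_prior_m / mu_prior_sd**2 + ybar / vbar)
    mu = post_mean + np.sqrt(post_var) * rng.standard_normal(2)

    d = vals - mu
    x = d[:-1][pair]
    y = d[1:][pair]
    m, cov = var_regression_posterior(
        x, y, sigma_w,
        prior_mean=prior_mean[PHI_RE_IDX],
        prior_cov=np.diag(prior_sd[PHI_RE_IDX] ** 2),
    )
    phi = m + np.linalg.cholesky(cov) @ rng.standard_normal(4)
    re = np.empty(6)
    re[:2] = mu
    re[PHI_RE_IDX] = phi
    return RandomEffectVector.from_array(re)


def param_names(pred_names=("adhd",)) -> list:
    """Monitored-parameter names, in storage order."""
    names = [f"alpha[{n}]" for n in RE_NAMES]
    for p in pred_names:
        names += [f"gamma[{n},{p}]" for n in RE_NAMES]
    names += [f"tau2[{n}]" for n in RE_NAMES]
    names += ["sigma_w[s,s]", "sigma_w[s,a]", "sigma_w[a,a]"]
    names += ["beta_int[const]"]
    names += [f"beta_int[{n}]" for n in RE_NAMES]
    names += [f"beta_int[{p}]" for p in pred_names]
    names += ["psi_adhd", "psi_int_resid"]
    names += [f"lambda_adhd[{j+1}]" for j in range(9)]
    names += ["lambda_cross"]
    names += [f"lambda_int[{j+1}]" for j in range(14)]
    names += [f"theta_adhd[{j+1}]" for j in range(9)]
    names += [f"theta_int[{j+1}]" for j in range(14)]
    return names


# ---------------------------------------------------------------------------
# vectorised chain state
# ---------------------------------------------------------------------------


def _chol2_sample(prec: np.ndarray, h: np.ndarray, z: np.ndarray):
    """Draw from N(prec^-1 h, prec^-1) for batched 2x2 precisions."""
    a, b_, c = prec[..., 0, 0], prec[..., 0, 1], prec[..., 1, 1]
    det = a * c - b_ * b_
    c00, c01, c11 = c / det, -b_ / det, a / det
    m0 = c00 * h[..., 0] + c01 * h[..., 1]
    m1 = c01 * h[..., 0] + c11 * h[..., 1]
    l00 = np.sqrt(c00)
    l10 = c01 / l00
    l11 = np.sqrt(np.maximum(c11 - l10 * l10, 1e-300))
    out = np.empty_like(h)
    out[..., 0] = m0 + l00 * z[..., 0]
    out[..., 1] = m1 + l10 * z[..., 0] + l11 * z[..., 1]
    return out


def _batch_mvn_sample(prec: np.ndarray, h: np.ndarray, z: np.ndarray):
    """Draw from N(prec^-1 h, prec^-1) for batched k x k precisions."""
    l = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, h[..., None])[..., 0]
    lt = np.swapaxes(l, -1, -2)
    return mean + np.linalg.solve(lt, z[..., None])[..., 0]


class _ChainState:
    """All latent quantities and parameters of one MCMC chain."""

    def __init__(self, data: dict, rng: np.random.Generator, jitter: float,
                 sigma_w_diagonal: bool, cut_outcome: bool):
        self.rng = rng
        self.cut = cut_outcome
        self.diag_w = sigma_w_diagonal
        self.y = data["y"]                    # (N, T, 2), NaN-free (0 filled)
        self.obs = data["obs"]                # (N, T)
        self.active = data["active"]          # (N, T)
        self.z = data["z"]                    # (N, 9) ADHD items
        self.w_items = data["w"]              # (N, 14) internalising items
        self.x = data["x"]                    # (N, ncov) or (N, 0)
        self.cross_idx = data["cross_idx"]
        self.n, self.t = self.y.shape[:2]
        self.npred = 1 + self.x.shape[1]      # adhd + covariates
        self.tr = self.active[:, 1:]          # transition mask (N, T-1)
        self.zmask = np.isfinite(self.z)
        self.wmask = np.isfinite(self.w_items)
        self.z0 = np.nan_to_num(self.z)
        self.w0 = np.nan_to_num(self.w_items)

        n = self.n
        r = rng
        j = jitter
        # --- initial values: sample statistics + chain-specific jitter
        ysum = np.where(self.obs[..., None], self.y, 0.0).sum(axis=1)
        nobs = np.maximum(self.obs.sum(axis=1), 1)[:, None]
        self.mu = ysum / nobs + 0.1 * r.standard_normal((n, 2))
        self.phi = np.zeros((n, 4)) + 0.05 * r.standard_normal((n, 4))
        self.d = np.where(self.obs[..., None], self.y - self.mu[:, None, :], 0.0)
        self.sigma_w = np.cov(
            self.d[self.obs], rowvar=False
        ) + 0.1 * np.eye(2)
        zc = np.where(self.zmask, self.z0, np.nan)
        self.eta = np.nanmean(zc, axis=1)
        self.eta = (self.eta - np.nanmean(self.eta)) / max(np.nanstd(self.eta), 1e-6)
        self.eta = np.nan_to_num(self.eta) + 0.1 * r.standard_normal(n)
        wc = np.where(self.wmask, self.w0, np.nan)
        self.xi = np.nanmean(wc, axis=1)
        self.xi = (self.xi - np.nanmean(self.xi)) / max(np.nanstd(self.xi), 1e-6)
        self.xi = np.nan_to_num(self.xi) + 0.1 * r.standard_normal(n)

        self.alpha = np.zeros(6) + j * r.standard_normal(6)
        self.alpha[:2] = self.mu.mean(axis=0) + j * r.standard_normal(2)
        self.gamma = np.zeros((6, self.npred)) + j * 0.2 * r.standard_normal((6, self.npred))
        self.tau2 = np.ones(6)
        self.tau2[2:] = 0.04
        # structural intercept of the internalising equation is fixed at 0
        # (factor-location identification: item intercepts are all free)
        self.beta = np.zeros(6 + self.npred) + j * 0.2 * r.standard_normal(6 + self.npred)
        self.psi_e = 1.0
        self.psi_a = 1.0
        self.nu_z = np.nanmean(zc, axis=0)
        self.lam_z = np.ones(9) + j * 0.2 * r.standard_normal(9)
        self.lam_z[0] = 1.0
        self.lam_cross = 0.0 + j * 0.2 * r.standard_normal()
        self.theta_z = np.ones(9)
        self.nu_w = np.nanmean(wc, axis=0)
        self.lam_w = np.ones(14) + j * 0.2 * r.standard_normal(14)
        self.lam_w[0] = 1.0
        self.theta_w = np.ones(14)
        self.s0inv = np.eye(2) / INIT_STATE_VAR

    # -- assembled views -------------------------------------------------

    @property
    def re(self) -> np.ndarray:
        out = np.empty((self.n, 6))
        out[:, :2] = self.mu
        out[:, PHI_RE_IDX] = self.phi
        return out

    def _pred_matrix(self) -> np.ndarray:
        """(N, npred) matrix [eta, covariates]."""
        return np.column_stack([self.eta, self.x]) if self.x.shape[1] else self.eta[:, None]

    def _re_prior_mean(self) -> np.ndarray:
        return self.alpha[None, :] + self._pred_matrix() @ self.gamma.T

    def _beta_parts(self):
        """Split beta into const (fixed 0), re block, pred block."""
        return 0.0, self.beta[:6], self.beta[6:]

    def _xi_resid_excluding(self, block: str) -> np.ndarray:
        """xi minus all structural terms except the named block."""
        b0, b_re, b_p = self._beta_parts()
        re = self.re
        total = b0 + re @ b_re + self._pred_matrix() @ b_p
        if block == "mu":
            total = total - self.mu @ b_re[:2]
        elif block == "phi":
            total = total - self.phi @ b_re[PHI_RE_IDX]
        elif block == "eta":
            total = total - self.eta * b_p[0]
        return self.xi - total

    # -- Gibbs blocks ----------------------------------------------------

    def update_missing_states(self) -> None:
        w = np.linalg.inv(self.sigma_w)
        phi = self.phi.reshape(self.n, 2, 2)
        wphi = w[None] @ phi
        phit = phi.transpose(0, 2, 1)
        ptw = phit @ w[None]
        ptwp = ptw @ phi
        miss = self.active & ~self.obs
        t_n = self.t
        wphi_t = wphi.transpose(0, 2, 1)
        ptw_t = ptw.transpose(0, 2, 1)
        for parity in (0, 1):
            ts = np.arange(parity, t_n, 2)
            prev_idx = np.maximum(ts - 1, 0)
            next_idx = np.minimum(ts + 1, t_n - 1)
            has_next = (ts + 1 < t_n)[None, :] & self.active[:, next_idx]
            dprev = self.d[:, prev_idx]
            dnext = self.d[:, next_idx]
            prec = has_next[..., None, None] * ptwp[:, None]
            prec += w[None, None]
            h = dprev @ wphi_t
            h += (has_next[..., None] * dnext) @ ptw_t
            if parity == 0:
                # slot 0: the diffuse initial prior replaces the transition
                # from a (non-existent) previous state
                prec[:, 0] += self.s0inv[None] - w[None]
                h[:, 0] -= np.matmul(dprev[:, 0:1], wphi_t)[:, 0]
            z = self.rng.standard_normal(h.shape)
            draw = _chol2_sample(prec, h, z)
            m = miss[:, ts]
            sub = self.d[:, ts]
            sub[m] = draw[m]
            self.d[:, ts] = sub

    def update_phi(self) -> None:
        w = np.linalg.inv(self.sigma_w)
        dprev = self.d[:, :-1]
        dcur = self.d[:, 1:]
        trm = self.tr[..., None]
        dpm = dprev * trm
        dpt = dprev.transpose(0, 2, 1)
        a = dpt @ dpm
        c = dpt @ (dcur * trm)
        prec = np.einsum("rs,ncd->nrcsd", w, a).reshape(self.n, 4, 4)
        h = np.einsum("rs,ncs->nrc", w, c).reshape(self.n, 4)
        pm = self._re_prior_mean()[:, PHI_RE_IDX]
        pv = self.tau2[PHI_RE_IDX]
        prec[:, np.arange(4), np.arange(4)] += 1.0 / pv[None, :]
        h += pm / pv[None, :]
        if not self.cut:
            b_phi = self._beta_parts()[1][PHI_RE_IDX]
            prec += np.outer(b_phi, b_phi)[None] / self.psi_e
            h += b_phi[None, :] * self._xi_resid_excluding("phi")[:, None] / self.psi_e
        z = self.rng.standard_normal((self.n, 4))
        self.phi = _batch_mvn_sample(prec, h, z)

    def update_mu(self) -> None:
        w = np.linalg.inv(self.sigma_w)
        phi = self.phi.reshape(self.n, 2, 2)
        wphi = w[None] @ phi
        phit = phi.transpose(0, 2, 1)
        ptw = phit @ w[None]
        ptwp = ptw @ phi
        aa = np.where(self.obs[..., None], self.y, self.d)
        cc = aa[:, 1:] - aa[:, :-1] @ phi.transpose(0, 2, 1)
        o_cur = self.obs[:, 1:] & self.tr
        o_prev = self.obs[:, :-1] & self.tr
        both = o_cur & o_prev
        n1 = o_cur.sum(axis=1)[:, None, None]
        nb = both.sum(axis=1)[:, None, None]
        n_p = o_prev.sum(axis=1)[:, None, None]
        s1 = (cc * o_cur[..., None]).sum(axis=1)
        s2 = (cc * o_prev[..., None]).sum(axis=1)
        prec = n1 * w[None] - nb * (wphi + ptw) + n_p * ptwp
        h = s1 @ w.T - np.matmul(ptw, s2[..., None])[..., 0]
        o0 = self.obs[:, 0].astype(float)[:, None]
        prec = prec + (o0[..., None] * self.s0inv[None])
        h = h + o0 * (self.y[:, 0] @ self.s0inv.T)
        pm = self._re_prior_mean()[:, :2]
        pv = self.tau2[:2]
        prec[:, np.arange(2), np.arange(2)] += 1.0 / pv[None, :]
        h += pm / pv[None, :]
        if not self.cut:
            b_mu = self._beta_parts()[1][:2]
            prec += np.outer(b_mu, b_mu)[None] / self.psi_e
            h += b_mu[None, :] * self._xi_resid_excluding("mu")[:, None] / self.psi_e
        z = self.rng.standard_normal((self.n, 2))
        self.mu = _chol2_sample(prec, h, z)
        self.d = np.where(self.obs[..., None], self.y - self.mu[:, None, :], self.d)

    def update_sigma_w(self) -> None:
        phi = self.phi.reshape(self.n, 2, 2)
        r = self.d[:, 1:] - self.d[:, :-1] @ phi.transpose(0, 2, 1)
        rm = (r * self.tr[..., None]).reshape(-1, 2)
        scatter = rm.T @ r.reshape(-1, 2)
        ntr = int(self.tr.sum())
        if self.diag_w:
            shape = IG_A + ntr / 2.0
            for k in range(2):
                scale = IG_B + 0.5 * scatter[k, k]
                self.sigma_w[k, k] = scale / self.rng.gamma(shape)
            self.sigma_w[0, 1] = self.sigma_w[1, 0] = 0.0
        else:
            self.sigma_w = invwishart.rvs(
                df=IW_DF + ntr, scale=scatter, random_state=self.rng
            )

    def update_factors(self) -> None:
        """Joint conjugate draw of (eta_i, xi_i) per person.

        The two factors are coupled through the cross-loading item and the
        structural ADHD path; drawing them as a bivariate block mixes the
        direct-versus-mediated direction far better than alternating
        scalar updates.
        """
        lamz, thz = self.lam_z, self.theta_z
        lamw, thw = self.lam_w, self.theta_w
        ci = self.cross_idx
        _, b_re, b_p = self._beta_parts()
        b_a = b_p[0]

        zres = (self.z0 - self.nu_z[None, :]) * self.zmask
        p11 = 1.0 / self.psi_a + (self.zmask * (lamz**2 / thz)[None, :]).sum(axis=1)
        h1 = (zres * (lamz / thz)[None, :]).sum(axis=1)
        g = self.gamma[:, 0]
        rexcl = self.re - self.alpha[None, :]
        if self.x.shape[1]:
            rexcl = rexcl - self.x @ self.gamma[:, 1:].T
        p11 += float(np.sum(g**2 / self.tau2))
        h1 += rexcl @ (g / self.tau2)

        wres = (self.w0 - self.nu_w[None, :]) * self.wmask
        p22 = (self.wmask * (lamw**2 / thw)[None, :]).sum(axis=1)
        h2 = (wres * (lamw / thw)[None, :]).sum(axis=1)
        mci = self.zmask[:, ci].astype(float)
        p22 += mci * self.lam_cross**2 / thz[ci]
        h2 += mci * self.lam_cross * (self.z0[:, ci] - self.nu_z[ci]) / thz[ci]
        p12 = mci * (lamz[ci] * self.lam_cross / thz[ci])

        m_rest = self.re @ b_re
        if self.x.shape[1]:
            m_rest = m_rest + self.x @ b_p[1:]
        p22 += 1.0 / self.psi_e
        if self.cut:
            # debugging mode: the outcome does not inform eta
            h2 += (m_rest + b_a * self.eta) / self.psi_e
        else:
            h2 += m_rest / self.psi_e
            p11 += b_a**2 / self.psi_e
            p12 = p12 - b_a / self.psi_e
            h1 += -b_a * m_rest / self.psi_e

        prec = np.empty((self.n, 2, 2))
        prec[:, 0, 0] = p11
        prec[:, 0, 1] = prec[:, 1, 0] = p12
        prec[:, 1, 1] = p22
        h = np.column_stack([h1, h2])
        draw = _chol2_sample(prec, h, self.rng.standard_normal((self.n, 2)))
        self.eta = draw[:, 0]
        self.xi = draw[:, 1]

    def update_between_regressions(self) -> None:
        u = np.column_stack([np.ones(self.n), self._pred_matrix()])
        utu = u.T @ u
        re = self.re
        p = u.shape[1]
        for k in range(6):
            prec = utu / self.tau2[k] + LOC_PREC * np.eye(p)
            h = u.T @ re[:, k] / self.tau2[k]
            coef = _batch_mvn_sample(prec[None], h[None],
                                     self.rng.standard_normal((1, p)))[0]
            self.alpha[k] = coef[0]
            self.gamma[k] = coef[1:]
            ssr = float(np.sum((re[:, k] - u @ coef) ** 2))
            self.tau2[k] = (IG_B + 0.5 * ssr) / self.rng.gamma(IG_A + self.n / 2.0)

    def update_internalising_regression(self) -> None:
        v = np.column_stack([self.re, self._pred_matrix()])
        q = v.shape[1]
        prec = v.T @ v / self.psi_e + LOC_PREC * np.eye(q)
        h = v.T @ self.xi / self.psi_e
        self.beta = _batch_mvn_sample(prec[None], h[None],
                                      self.rng.standard_normal((1, q)))[0]
        ssr = float(np.sum((self.xi - v @ self.beta) ** 2))
        self.psi_e = (IG_B + 0.5 * ssr) / self.rng.gamma(IG_A + self.n / 2.0)

    def _update_item(self, y, mask, design, theta, prior_prec=None):
        """Conjugate (coefficients, residual variance) update for one item."""
        yv = y[mask]
        x = design[mask]
        p = x.shape[1]
        pp = np.full(p, LOC_PREC) if prior_prec is None else np.asarray(prior_prec)
        prec = x.T @ x / theta + np.diag(pp)
        h = x.T @ yv / theta
        coef = _batch_mvn_sample(prec[None], h[None],
                                 self.rng.standard_normal((1, p)))[0]
        ssr = float(np.sum((yv - x @ coef) ** 2))
        theta_new = (IG_B + 0.5 * ssr) / self.rng.gamma(IG_A + mask.sum() / 2.0)
        return coef, theta_new

    def _update_item_block(self, y, design, theta, pp):
        """Vectorised conjugate updates for items sharing one design."""
        k = y.shape[1]
        p = design.shape[1]
        xtx = design.T @ design
        xty = design.T @ y                       # (p, K)
        prec = xtx[None] / theta[:, None, None] + np.diag(pp)[None]
        h = xty.T / theta[:, None]
        coefs = _batch_mvn_sample(prec, h, self.rng.standard_normal((k, p)))
        resid = y - design @ coefs.T
        ssr = np.einsum("nk,nk->k", resid, resid)
        theta_new = (IG_B + 0.5 * ssr) / self.rng.gamma(IG_A + self.n / 2.0, size=k)
        return coefs, theta_new

    def update_measurement(self) -> None:
        # Working (parameter-expanded) parametrisation: every loading is
        # free, including the reference indicators, under a standard-normal
        # working prior; draws are rescaled to the lambda_ref = 1 metric at
        # recording time.  This removes the scale ridge that traps a Gibbs
        # sampler in the identified parametrisation.
        ones = np.ones(self.n)
        pp2 = np.array([LOC_PREC, 1.0])
        pp3 = np.array([LOC_PREC, 1.0, 1.0])
        if self.zmask.all() and self.wmask.all():
            plain = [j for j in range(9) if j != self.cross_idx]
            design = np.column_stack([ones, self.eta])
            coefs, th = self._update_item_block(
                self.z0[:, plain], design, self.theta_z[plain], pp2
            )
            self.nu_z[plain] = coefs[:, 0]
            self.lam_z[plain] = coefs[:, 1]
            self.theta_z[plain] = th
            design3 = np.column_stack([ones, self.eta, self.xi])
            ci = self.cross_idx
            coefs, th = self._update_item_block(
                self.z0[:, [ci]], design3, self.theta_z[[ci]], pp3
            )
            self.nu_z[ci], self.lam_z[ci], self.lam_cross = coefs[0]
            self.theta_z[ci] = th[0]
            design_w = np.column_stack([ones, self.xi])
            coefs, th = self._update_item_block(
                self.w0, design_w, self.theta_w, pp2
            )
            self.nu_w = coefs[:, 0]
            self.lam_w = coefs[:, 1]
            self.theta_w = th
            self.psi_a = (IG_B + 0.5 * float(np.sum(self.eta**2))) / self.rng.gamma(
                IG_A + self.n / 2.0
            )
            return
        for j in range(9):
            mask = self.zmask[:, j]
            if j == self.cross_idx:
                design = np.column_stack([ones, self.eta, self.xi])
                coef, self.theta_z[j] = self._update_item(
                    self.z0[:, j], mask, design, self.theta_z[j], pp3
                )
                self.nu_z[j], self.lam_z[j], self.lam_cross = coef
            else:
                design = np.column_stack([ones, self.eta])
                coef, self.theta_z[j] = self._update_item(
                    self.z0[:, j], mask, design, self.theta_z[j], pp2
                )
                self.nu_z[j], self.lam_z[j] = coef
        for j in range(14):
            mask = self.wmask[:, j]
            design = np.column_stack([ones, self.xi])
            coef, self.theta_w[j] = self._update_item(
                self.w0[:, j], mask, design, self.theta_w[j], pp2
            )
            self.nu_w[j], self.lam_w[j] = coef
        self.psi_a = (IG_B + 0.5 * float(np.sum(self.eta**2))) / self.rng.gamma(
            IG_A + self.n / 2.0
        )

    def sweep(self) -> None:
        self.update_missing_states()
        self.update_phi()
        self.update_mu()
        self.update_sigma_w()
        self.update_factors()
        self.update_between_regressions()
        self.update_internalising_regression()
        self.update_measurement()

    # -- recording -------------------------------------------------------

    def param_names(self, pred_names) -> list:
        return param_names(pred_names)

    def param_vector(self) -> np.ndarray:
        """Current draw, rescaled to the reference-indicator metric.

        The working factor scales c_a = lambda_adhd[1], c_i = lambda_int[1]
        define the identified factors eta' = c_a eta, xi' = c_i xi; loadings,
        factor variances and structural coefficients transform accordingly,
        so the recorded reference loadings are exactly 1 in every draw.
        """
        c_a = self.lam_z[0]
        c_i = self.lam_w[0]
        gamma = self.gamma.copy()
        gamma[:, 0] /= c_a
        beta = np.concatenate([[0.0], self.beta])  # fixed structural intercept
        beta *= c_i
        beta[7] /= c_a  # coefficient on the ADHD factor
        return np.concatenate(
            [
                self.alpha,
                gamma.T.reshape(-1),
                self.tau2,
                [self.sigma_w[0, 0], self.sigma_w[0, 1], self.sigma_w[1, 1]],
                beta,
                [c_a**2 * self.psi_a, c_i**2 * self.psi_e],
                self.lam_z / c_a,
                [self.lam_cross / c_i],
                self.lam_w / c_i,
                self.theta_z,
                self.theta_w,
            ]
        )


# ---------------------------------------------------------------------------
# data preparation and the estimator
# ---------------------------------------------------------------------------


def _prepare_arrays(series, persons: pd.DataFrame, covariates, cross_item,
                    adhd_items=None, int_items=None) -> dict:
    adhd_items = adhd_items or [f"adhd{j}" for j in range(1, 10)]
    int_items = int_items or [f"int{j}" for j in range(1, 15)]
    if cross_item not in adhd_items:
        raise ValueError("cross_item must be one of the ADHD items")
    cross_idx = adhd_items.index(cross_item)
    if cross_idx == 0:
        raise ValueError("the reference indicator cannot carry the cross-loading")

    series = sorted(series, key=lambda s: s.person_id)
    pers = persons.sort_values("person_id").reset_index(drop=True)
    ids = [s.person_id for s in series]
    if list(pers["person_id"]) != ids:
        pers = pers.set_index("person_id").loc[ids].reset_index()
    t_max = max(s.n_slots for s in series)
    n = len(series)
    y = np.zeros((n, t_max, 2))
    obs = np.zeros((n, t_max), dtype=bool)
    active = np.zeros((n, t_max), dtype=bool)
    for i, s in enumerate(series):
        t_i = s.n_slots
        active[i, :t_i] = True
        ok = np.isfinite(s.values).all(axis=1)
        obs[i, :t_i] = ok
        y[i, :t_i] = np.nan_to_num(s.values)

    z = pers.loc[:, adhd_items].to_numpy(dtype=float)
    w = pers.loc[:, int_items].to_numpy(dtype=float)
    if covariates:
        x = pers.loc[:, list(covariates)].to_numpy(dtype=float).copy()
        if "ses" in covariates:
            k = list(covariates).index("ses")
            x[:, k] = (x[:, k] - x[:, k].mean()) / x[:, k].std()
    else:
        x = np.zeros((n, 0))
    return {
        "y": y, "obs": obs, "active": active, "z": z, "w": w, "x": x,
        "cross_idx": cross_idx, "person_ids": ids,
    }


class DynamicSEM(BaseEstimator):
    """Bayesian two-level DSEM estimator (scikit-learn style).

    Parameters mirror :class:`MCMCConfig` plus model options:

    covariates : None for the baseline model, or a list of person-level
        columns (e.g. ``["sex", "origin", "ses"]``; SES is z-scored).
    sigma_w_diagonal : constrain the within innovation covariance to be
        diagonal (default False: free off-diagonal).
    two_step : debugging mode that cuts the feedback from the internalising
        outcome into the random-effect and factor updates.

    Fitted attributes: ``draws_`` (:class:`PosteriorDraws`), ``psr_``,
    ``converged_``, ``n_iterations_``, ``person_ids_``.
    """

    def __init__(self, n_chains: int = 2, max_iterations: int = 50_000,
                 min_iterations: int = 0, thinning: int = 10,
                 psr_threshold: float = 1.05, check_every: int = 2500,
                 burn_in_fraction: float = 0.5,
                 double_on_first_convergence: bool = True, seed: int = 0,
                 covariates=None, sigma_w_diagonal: bool = False,
                 store_random_effects: bool = True, two_step: bool = False,
                 cross_item: str = "adhd4", init_jitter: float = 0.5):
        self.n_chains = n_chains
        self.max_iterations = max_iterations
        self.min_iterations = min_iterations
        self.thinning = thinning
        self.psr_threshold = psr_threshold
        self.check_every = check_every
        self.burn_in_fraction = burn_in_fraction
        self.double_on_first_convergence = double_on_first_convergence
        self.seed = seed
        self.covariates = covariates
        self.sigma_w_diagonal = sigma_w_diagonal
        self.store_random_effects = store_random_effects
        self.two_step = two_step
        self.cross_item = cross_item
        self.init_jitter = init_jitter

    def fit(self, series, persons: pd.DataFrame):
        cfg = MCMCConfig(
            n_chains=self.n_chains, max_iterations=self.max_iterations,
            min_iterations=self.min_iterations, thinning=self.thinning,
            psr_threshold=self.psr_threshold,
            burn_in_fraction=self.burn_in_fraction,
            check_every=self.check_every,
            double_on_first_convergence=self.double_on_first_convergence,
            seed=self.seed,
        )
        data = _prepare_arrays(series, persons, self.covariates, self.cross_item)
        self.person_ids_ = data["person_ids"]
        pred_names = ("adhd",) + tuple(self.covariates or ())
        self.predictor_names_ = pred_names

        ss = np.random.SeedSequence(cfg.seed)
        child = ss.spawn(cfg.n_chains)
        rngs = [np.random.default_rng(s) for s in child]
        chains = [
            _ChainState(data, rngs[c], self.init_jitter,
                        self.sigma_w_diagonal, self.two_step)
            for c in range(cfg.n_chains)
        ]
        names = chains[0].param_names(pred_names)

        records = [[] for _ in chains]
        re_records = [[] for _ in chains] if self.store_random_effects else None
        it = 0
        target = None
        doubled = False
        final_psr = None
        while True:
            block_end = min(
                it + cfg.check_every,
                target if target is not None else cfg.max_iterations,
            )
            if block_end <= it:
                break
            for c, chain in enumerate(chains):
                for step in range(it + 1, block_end + 1):
                    chain.sweep()
                    if step % cfg.thinning == 0:
                        records[c].append(chain.param_vector())
                        if re_records is not None:
                            re_records[c].append(chain.re.copy())
            it = block_end
            n_rec = len(records[0])
            if n_rec >= 4:
                arr = np.stack([np.stack(r) for r in records])  # (C, n_rec, P)
                half = arr[:, n_rec // 2:, :]
                final_psr = psr(half)
            if target is not None and it >= target:
                break
            if it >= cfg.max_iterations:
                break
            if (
                it >= cfg.min_iterations
                and final_psr is not None
                and np.all(final_psr < cfg.psr_threshold)
            ):
                if cfg.double_on_first_convergence and not doubled:
                    target = min(2 * it, cfg.max_iterations)
                    doubled = True
                    logger.info("first convergence at %d; running to %d", it, target)
                    if target <= it:
                        break
                else:
                    break

        arr = np.stack([np.stack(r) for r in records])
        n_rec = arr.shape[1]
        burn = int(np.floor(n_rec * cfg.burn_in_fraction))
        retained = arr[:, burn:, :]
        final_psr = psr(arr[:, n_rec // 2:, :]) if n_rec >= 4 else np.full(arr.shape[2], np.nan)
        converged = bool(np.all(final_psr < cfg.psr_threshold))
        if not converged:
            logger.warning("PSR above %.3f at %d iterations: non-convergence",
                           cfg.psr_threshold, it)
        re_arr = None
        if re_records is not None:
            re_arr = np.stack([np.stack(r) for r in re_records])[:, burn:]

        self.draws_ = PosteriorDraws(
            params=retained, names=names, psr=final_psr, converged=converged,
            n_iterations=it, thinning=cfg.thinning,
            seeds=[list(s.entropy if isinstance(s.entropy, tuple) else [s.entropy])
                   for s in child],
            random_effects=re_arr,
            meta={
                "predictors": list(pred_names),
                "n_persons": len(self.person_ids_),
                "burn_in_fraction": cfg.burn_in_fraction,
                "doubled": doubled,
            },
        )
        self.psr_ = final_psr
        self.converged_ = converged
        self.n_iterations_ = it
        return self

    def summary(self, point: str = "median") -> pd.DataFrame:
        return self.draws_.summary(point=point)


def run_mcmc(series, persons: pd.DataFrame, config: MCMCConfig | None = None,
             **model_kwargs) -> PosteriorDraws:
    """Functional wrapper around :class:`DynamicSEM`."""
    cfg = config or MCMCConfig()
    est = DynamicSEM(
        n_chains=cfg.n_chains, max_iterations=cfg.max_iterations,
        min_iterations=cfg.min_iterations, thinning=cfg.thinning,
        psr_threshold=cfg.psr_threshold, check_every=cfg.check_every,
        burn_in_fraction=cfg.burn_in_fraction,
        double_on_first_convergence=cfg.double_on_first_convergence,
        seed=cfg.seed, **model_kwargs,
    )
    est.fit(series, persons)
    return est.draws_
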
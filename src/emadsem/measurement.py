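"""Questionnaire scoring and the confirmatory measurement model.

The two trait factors (ADHD, 9 items; internalising, 14 items) are measured
by 1-5 Likert items.  The confirmatory factor analysis treats items as
continuous and maximises the multivariate-normal likelihood; each factor is
identified by fixing the loading of its reference indicator to one.  A
single cross-loading (the 'restless inside' ADHD item on the internalising
factor) is supported, mirroring the modified measurement structure used in
the dynamic model.

Fit indices follow the standard definitions: with F the minimised ML
discrepancy, chi2 = (n-1) F against the saturated model; CFI and TLI
compare against the independence baseline; RMSEA = sqrt(max(chi2-df,0) /
(df (n-1))); SRMR is the root-mean-square standardised residual
(diagonal included); BIC = -2 loglik + k log n.

Missing item responses are handled by full-information ML (casewise
observed-data likelihood, grouped by missingness pattern).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

__all__ = [
    "score_scales",
    "CFASpec",
    "FitIndices",
    "ConfirmatoryFactorAnalysis",
    "fit_cfa",
    "omega",
    "default_trait_spec",
]


def score_scales(items: pd.DataFrame, scale_map: dict[str, list[str]],
                 lo: int = 1, hi: int = 5) -> pd.DataFrame:
    """Sum-score each scale; a sum is missing if any constituent item is.

    Items outside ``[lo, hi]`` raise, guarding against coding slips.
    """
    out = {}
    for scale, cols in scale_map.items():
        block = items.loc[:, cols]
        vals = block.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < lo or finite.max() > hi):
            raise ValueError(f"scale {scale!r} has items outside [{lo}, {hi}]")
        out[scale] = block.sum(axis=1, min_count=len(cols))
    return pd.DataFrame(out, index=items.index)


@dataclass
class CFASpec:
    """Factor -> item lists, plus cross-loadings as (item, factor) pairs.

    The first item of each factor's list is its reference indicator
    (loading fixed to 1).
    """

    factors: dict[str, list[str]]
    cross_loadings: list[tuple[str, str]] = field(default_factory=list)

    @property
    def items(self) -> list[str]:
        seen: list[str] = []
        for cols in self.factors.values():
            for c in cols:
                if c not in seen:
                    seen.append(c)
        return seen

    @classmethod
    def from_yaml(cls, path) -> "CFASpec":
        """Load ``{factors: {name: [items...]}, cross_loadings: [[item, factor]]}``."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cross = [tuple(pair) for pair in raw.get("cross_loadings", [])]
        return cls(factors={k: list(v) for k, v in raw["factors"].items()},
                   cross_loadings=cross)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(
                {"factors": {k: list(v) for k, v in self.factors.items()},
                 "cross_loadings": [list(p) for p in self.cross_loadings]},
                fh,
            )


def default_trait_spec(cross_item: str = "adhd4") -> CFASpec:
    """The two-factor ADHD / internalising model with one cross-loading."""
    return CFASpec(
        factors={
            "adhd": [f"adhd{j}" for j in range(1, 10)],
            "int": [f"int{j}" for j in range(1, 15)],
        },
        cross_loadings=[(cross_item, "int")],
    )


@dataclass
class FitIndices:
    chi2: float
    df: int
    cfi: float
    tli: float
    rmsea: float
    srmr: float
    bic: float
    loglik: float
    n_params: int

    def delta_bic(self, other: "FitIndices") -> float:
        return self.bic - other.bic

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("chi2", "df", "cfi", "tli", "rmsea", "srmr", "bic", "loglik",
                 "n_params")}


class _CFAParams:
    """Index bookkeeping for the free-parameter vector."""

    def __init__(self, spec: CFASpec, items: list[str]):
        self.spec = spec
        self.items = items
        p = len(items)
        m = len(spec.factors)
        self.factor_names = list(spec.factors)
        # (item, factor) -> "fixed" 1 or free-parameter slot
        self.load_entries: list[tuple[int, int]] = []  # free loadings
        self.fixed: list[tuple[int, int]] = []
        for fi, (fac, cols) in enumerate(spec.factors.items()):
            for k, c in enumerate(cols):
                ii = items.index(c)
                if k == 0:
                    self.fixed.append((ii, fi))
                else:
                    self.load_entries.append((ii, fi))
        for item, fac in spec.cross_loadings:
            self.load_entries.append((items.index(item), self.factor_names.index(fac)))
        self.n_load = len(self.load_entries)
        self.n_psi = m * (m + 1) // 2
        self.n_theta = p
        self.n_free = self.n_load + self.n_psi + self.n_theta
        self.p, self.m = p, m

    def unpack(self, x: np.ndarray):
        p, m = self.p, self.m
        lam = np.zeros((p, m))
        for ii, fi in self.fixed:
            lam[ii, fi] = 1.0
        for (ii, fi), v in zip(self.load_entries, x[: self.n_load]):
            lam[ii, fi] += v
        # factor covariance via log-cholesky
        tri = x[self.n_load: self.n_load + self.n_psi]
        chol = np.zeros((m, m))
        idx = np.tril_indices(m)
        chol[idx] = tri
        chol[np.diag_indices(m)] = np.exp(np.diag(chol))
        psi = chol @ chol.T
        theta = np.exp(x[self.n_load + self.n_psi:])
        return lam, psi, theta

    def pack_start(self, s: np.ndarray) -> np.ndarray:
        x = np.zeros(self.n_free)
        sd = np.sqrt(np.diag(s))
        for j, (ii, fi) in enumerate(self.load_entries):
            ref_item = self.items.index(self.spec.factors[self.factor_names[fi]][0])
            x[j] = 0.8 * sd[ii] / max(sd[ref_item], 1e-6)
        # cholesky start: factor SD ~ half the reference-item SD
        tri = np.zeros(self.n_psi)
        k = 0
        for r in range(self.m):
            for c in range(r + 1):
                if r == c:
                    ref_item = self.items.index(
                        self.spec.factors[self.factor_names[r]][0]
                    )
                    tri[k] = np.log(max(0.6 * sd[ref_item], 1e-3))
                k += 1
        x[self.n_load: self.n_load + self.n_psi] = tri
        x[self.n_load + self.n_psi:] = np.log(np.clip(0.5 * np.diag(s), 1e-3, None))
        return x


def _implied_cov(lam, psi, theta):
    return lam @ psi @ lam.T + np.diag(theta)


def _fml(sigma: np.ndarray, s: np.ndarray) -> float:
    p = s.shape[0]
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return 1e10
    _, logdet_s = np.linalg.slogdet(s)
    return float(logdet + np.trace(np.linalg.solve(sigma, s)) - logdet_s - p)


class ConfirmatoryFactorAnalysis(BaseEstimator):
    """ML confirmatory factor analysis for ordinal-as-continuous items.

    Parameters
    ----------
    spec : CFASpec mapping factors to items (first item = reference).
    max_iter : optimiser iteration cap.
    compute_se : numerically differentiate the discrepancy for standard
        errors of the free parameters (Hessian-based).

    Fitted attributes
    -----------------
    loadings_ : DataFrame (items x factors) including fixed references.
    factor_cov_, residual_vars_, fit_indices_, converged_, heywood_ : see
        docstrings; ``se_loadings_`` when ``compute_se``.
    """

    def __init__(self, spec: CFASpec | None = None, max_iter: int = 2000,
                 compute_se: bool = False):
        self.spec = spec
        self.max_iter = max_iter
        self.compute_se = compute_se

    # -- likelihood machinery -------------------------------------------

    def _objective_complete(self, params: _CFAParams, s: np.ndarray):
        def f(x):
            lam, psi, theta = params.unpack(x)
            return _fml(_implied_cov(lam, psi, theta), s)

        return f

    def _objective_fiml(self, params: _CFAParams, patterns, n: int):
        # -2/n * loglik (up to the saturated constant), over missing patterns
        def f(x):
            lam, psi, theta = params.unpack(x)
            sigma = _implied_cov(lam, psi, theta)
            total = 0.0
            for mask, yc, cnt in patterns:
                sub = sigma[np.ix_(mask, mask)]
                sign, logdet = np.linalg.slogdet(sub)
                if sign <= 0:
                    return 1e10
                sol = np.linalg.solve(sub, yc.T)
                quad = np.einsum("ji,ji->", yc.T, sol)
                total += cnt * logdet + quad
            return total / n

        return f

    # -- fitting ----------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None):
        spec = self.spec if self.spec is not None else default_trait_spec()
        items = spec.items
        data = X.loc[:, items].to_numpy(dtype=float)
        n = data.shape[0]
        params = _CFAParams(spec, items)
        if n <= params.n_free:
            raise ValueError("need more observations than free parameters")

        has_missing = np.isnan(data).any()
        col_mean = np.nanmean(data, axis=0)
        centred = data - col_mean
        if not has_missing:
            s = centred.T @ centred / (n - 1)
            obj = self._objective_complete(params, s)
            start_s = s
        else:
            mu_sat, sigma_sat = _em_mvnorm(data)
            centred = data - mu_sat
            groups: dict[tuple, list[int]] = {}
            for i in range(n):
                key = tuple(np.isfinite(data[i]))
                groups.setdefault(key, []).append(i)
            patterns = []
            for key, idx in groups.items():
                mask = np.array(key)
                if not mask.any():
                    continue
                yc = centred[np.ix_(idx, np.flatnonzero(mask))]
                patterns.append((np.flatnonzero(mask), yc, len(idx)))
            obj = self._objective_fiml(params, patterns, n)
            start_s = sigma_sat

        x0 = params.pack_start(start_s)
        res = minimize(obj, x0, method="L-BFGS-B",
                       options={"maxiter": self.max_iter, "maxfun": 10 * self.max_iter})
        lam, psi, theta = params.unpack(res.x)

        self.converged_ = bool(res.success)
        if not self.converged_:
            warnings.warn(f"CFA optimisation did not converge: {res.message}")
        self.heywood_ = bool((theta < 1e-3).any())
        if self.heywood_:
            warnings.warn("Heywood case: near-zero residual variance")

        self.items_ = items
        self.factor_names_ = params.factor_names
        self.loadings_ = pd.DataFrame(lam, index=items, columns=params.factor_names)
        self.factor_cov_ = pd.DataFrame(psi, index=params.factor_names,
                                        columns=params.factor_names)
        self.residual_vars_ = pd.Series(theta, index=items)
        self.means_ = pd.Series(col_mean, index=items)
        self._params = params
        self.n_obs_ = n

        # fit indices (complete-data path; FIML chi2 uses the EM-saturated fit)
        p = len(items)
        if not has_missing:
            fmin = res.fun
            sign, logdet_s = np.linalg.slogdet(s)
            loglik = -0.5 * n * (p * np.log(2 * np.pi) + logdet_s + p + fmin)
            f_base = float(np.sum(np.log(np.diag(s))) - logdet_s)
        else:
            # casewise logliks relative to the saturated EM solution
            sigma_hat = _implied_cov(lam, psi, theta)
            loglik = _fiml_loglik(data, mu_sat, sigma_hat)
            loglik_sat = _fiml_loglik(data, mu_sat, sigma_sat)
            fmin = 2 * (loglik_sat - loglik) / max(n - 1, 1)
            f_base = 2 * (loglik_sat -
                          _fiml_loglik(data, mu_sat, np.diag(np.diag(sigma_sat)))) / max(n - 1, 1)

        df_m = p * (p + 1) // 2 - params.n_free
        df_b = p * (p + 1) // 2 - p
        chi2 = max((n - 1) * fmin, 0.0)
        chi2_b = max((n - 1) * f_base, 0.0)
        num = max(chi2 - df_m, 0.0)
        den = max(chi2_b - df_b, chi2 - df_m, 0.0)
        cfi = 1.0 - (num / den if den > 0 else 0.0)
        if chi2_b > 0 and df_b > 0 and df_m > 0:
            tli = ((chi2_b / df_b) - (chi2 / df_m)) / max((chi2_b / df_b) - 1.0, 1e-12)
            tli = min(tli, 1.0)
        else:
            tli = 1.0
        rmsea = float(np.sqrt(num / (df_m * (n - 1)))) if df_m > 0 else 0.0
        if not has_missing:
            sd = np.sqrt(np.diag(s))
            resid = (s - _implied_cov(lam, psi, theta)) / np.outer(sd, sd)
            iu = np.triu_indices(p)
            srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))
        else:
            sd = np.sqrt(np.diag(sigma_sat))
            resid = (sigma_sat - _implied_cov(lam, psi, theta)) / np.outer(sd, sd)
            iu = np.triu_indices(p)
            srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))
        k_total = params.n_free + p  # free covariance params + item means
        bic = -2.0 * loglik + k_total * np.log(n)
        self.fit_indices_ = FitIndices(
            chi2=float(chi2), df=int(df_m), cfi=float(cfi), tli=float(tli),
            rmsea=rmsea, srmr=srmr, bic=float(bic), loglik=float(loglik),
            n_params=k_total,
        )

        if self.compute_se and not has_missing:
            self.se_ = self._standard_errors(obj, res.x, n)
            se_lam = np.zeros_like(lam)
            for (ii, fi), se in zip(params.load_entries, self.se_[: params.n_load]):
                se_lam[ii, fi] = se
            self.se_loadings_ = pd.DataFrame(se_lam, index=items,
                                             columns=params.factor_names)
        return self

    @staticmethod
    def _standard_errors(obj, x, n, eps: float = 1e-4) -> np.ndarray:
        k = x.size
        h = np.zeros((k, k))
        f0 = obj(x)
        # central finite-difference Hessian of the discrepancy function
        for i in range(k):
            for j in range(i, k):
                xi = x.copy(); xi[i] += eps; xi[j] += eps; fpp = obj(xi)
                xi = x.copy(); xi[i] += eps; xi[j] -= eps; fpm = obj(xi)
                xi = x.copy(); xi[i] -= eps; xi[j] += eps; fmp = obj(xi)
                xi = x.copy(); xi[i] -= eps; xi[j] -= eps; fmm = obj(xi)
                h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
        cov = 2.0 * np.linalg.pinv(h) / (n - 1)
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))

    # -- derived quantities ----------------------------------------------

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Regression-method factor scores."""
        data = X.loc[:, self.items_].to_numpy(dtype=float)
        lam = self.loadings_.to_numpy()
        psi = self.factor_cov_.to_numpy()
        theta = self.residual_vars_.to_numpy()
        sigma = _implied_cov(lam, psi, theta)
        w = psi @ lam.T @ np.linalg.inv(sigma)
        centred = np.where(np.isfinite(data), data - self.means_.to_numpy(), 0.0)
        return pd.DataFrame(centred @ w.T, columns=self.factor_names_, index=X.index)

    def omega(self, factor: str) -> float:
        return omega(self, factor)


def omega(model: ConfirmatoryFactorAnalysis, factor: str) -> float:
    """McDonald's omega: (sum lambda)^2 psi / ((sum lambda)^2 psi + sum theta).

    Uses the factor's primary indicators (cross-loadings excluded), on the
    fitted unstandardised scale — invariant to the choice of reference item.
    """
    spec_items = None
    if model.spec is not None:
        spec_items = model.spec.factors[factor]
    else:
        spec_items = default_trait_spec().factors[factor]
    lam = model.loadings_.loc[spec_items, factor].to_numpy()
    psi = float(model.factor_cov_.loc[factor, factor])
    theta = model.residual_vars_.loc[spec_items].to_numpy()
    num = lam.sum() ** 2 * psi
    return float(num / (num + theta.sum()))


def fit_cfa(X: pd.DataFrame, spec: CFASpec | None = None, **kwargs):
    """Functional wrapper: returns the fitted estimator."""
    return ConfirmatoryFactorAnalysis(spec=spec, **kwargs).fit(X)


# ---------------------------------------------------------------------------
# multivariate-normal EM for the saturated model under missingness
# ---------------------------------------------------------------------------


def _em_mvnorm(data: np.ndarray, max_iter: int = 200, tol: float = 1e-8):
    """EM estimates of (mu, Sigma) for MVN data with missing entries."""
    n, p = data.shape
    mu = np.nanmean(data, axis=0)
    filled = np.where(np.isfinite(data), data, mu)
    sigma = np.cov(filled, rowvar=False, bias=True) + 1e-6 * np.eye(p)
    for _ in range(max_iter):
        ex = np.zeros(p)
        exx = np.zeros((p, p))
        for i in range(n):
            obs = np.isfinite(data[i])
            if obs.all():
                ex += data[i]
                exx += np.outer(data[i], data[i])
                continue
            o = np.flatnonzero(obs)
            m = np.flatnonzero(~obs)
            so = sigma[np.ix_(o, o)]
            som = sigma[np.ix_(o, m)]
            smm = sigma[np.ix_(m, m)]
            sol = np.linalg.solve(so, som)
            cond_mu = data[i, o] @ sol + mu[m] - mu[o] @ sol
            cond_cov = smm - som.T @ sol
            xi = data[i].copy()
            xi[m] = cond_mu
            ex += xi
            outer = np.outer(xi, xi)
            outer[np.ix_(m, m)] += cond_cov
            exx += outer
        mu_new = ex / n
        sigma_new = exx / n - np.outer(mu_new, mu_new)
        if np.max(np.abs(sigma_new - sigma)) < tol and np.max(np.abs(mu_new - mu)) < tol:
            mu, sigma = mu_new, sigma_new
            break
        mu, sigma = mu_new, sigma_new
    return mu, sigma + 1e-9 * np.eye(p)


def _fiml_loglik(data: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    n, p = data.shape
    total = 0.0
    groups: dict[tuple, list[int]] = {}
    for i in range(n):
        groups.setdefault(tuple(np.isfinite(data[i])), []).append(i)
    for key, idx in groups.items():
        mask = np.flatnonzero(np.array(key))
        if mask.size == 0:
            continue
        sub = sigma[np.ix_(mask, mask)]
        sign, logdet = np.linalg.slogdet(sub)
        yc = data[np.ix_(idx, mask)] - mu[mask]
        sol = np.linalg.solve(sub, yc.T)
        quad = np.einsum("ji,ji->", yc.T, sol)
        total += -0.5 * (len(idx) * (mask.size * np.log(2 * np.pi) + logdet) + quad)
    return float(total)
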
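"""Posterior summaries: standardisation, mediation, result tables, pipeline.

Every derived quantity is computed **per posterior draw** and summarised
afterwards (posterior median, SD, equal-tailed 2.5/97.5% credible
interval), so credible intervals propagate exactly; an indirect effect's
interval is never assembled from the intervals of its factors.

Standardisation conventions:

* within-person coefficients are standardised per person and per draw
  using the model-implied stationary SDs of the person's latent VAR(1)
  (an autoregression is scale-free; cross-lagged paths pick up the SD
  ratio), then averaged over persons;
* between-level coefficients use model-implied SDs of predictor and
  outcome (latent factor SDs from the factor variance draws, random-effect
  SDs from gamma and the residual variances);
* a parameter is flagged "significant" exactly when its 95% credible
  interval excludes zero — no p-values anywhere.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dsem import DynamicSEM, PosteriorDraws
from .synthetic import RE_NAMES, PHI_RE_IDX, DesignConfig, simulate_dataset, study_truth
from .timegrid import TimeGridder, missingness_fraction
from .measurement import fit_cfa, default_trait_spec, omega, score_scales

__all__ = [
    "ResultRow",
    "MediationResult",
    "standardize_draws",
    "indirect_effects",
    "make_table",
    "summarise",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

RE_LABELS = {
    "mu_s": "M: Stress",
    "mu_a": "M: Affect",
    "phi_ss": "AR: Stress → Stress",
    "phi_aa": "AR: Affect → Affect",
    "phi_as": "CL: Affect → Stress",
    "phi_sa": "CL: Stress → Affect",
}
PRED_LABELS = {
    "adhd": "ADHD",
    "sex": "Sex",
    "origin": "Primary Caregiver Country of Origin",
    "ses": "SES",
}


@dataclass
class ResultRow:
    block: str
    label: str
    estimate: float
    sd: float
    ci_lower: float
    ci_upper: float
    significant: bool
    scale: str = "standardised"

    def as_dict(self) -> dict:
        return {
            "block": self.block, "label": self.label,
            "estimate": self.estimate, "sd": self.sd,
            "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
            "significant": self.significant, "scale": self.scale,
        }


@dataclass
class MediationResult:
    """Per-draw product of an a-path and b-path (unstandardised)."""

    label: str
    products: np.ndarray  # (chains, draws)
    summary: ResultRow = field(init=False)

    def __post_init__(self) -> None:
        self.summary = _row_from_draws(
            "Indirect effects: ADHD to Internalising", self.label,
            self.products, scale="unstandardised",
        )


def _row_from_draws(block: str, label: str, draws: np.ndarray,
                    scale: str = "standardised", level: float = 0.95) -> ResultRow:
    flat = np.asarray(draws, dtype=float).reshape(-1)
    flat = flat[np.isfinite(flat)]
    if flat.size == 0:
        raise ValueError(f"no finite draws for {label!r}")
    tail = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(flat, [tail, 100.0 - tail])
    return ResultRow(
        block=block, label=label,
        estimate=float(np.median(flat)),
        sd=float(flat.std(ddof=1)),
        ci_lower=float(lo), ci_upper=float(hi),
        significant=bool(lo > 0.0 or hi < 0.0),
        scale=scale,
    )


# ---------------------------------------------------------------------------
# standardisation
# ---------------------------------------------------------------------------


def _within_std(draws: PosteriorDraws) -> dict[str, np.ndarray]:
    """Person-averaged standardised within-person coefficients, per draw."""
    if draws.random_effects is None:
        raise ValueError("within-level standardisation needs stored random effects")
    re = draws.random_effects                       # (C, D, N, 6)
    c, d, n, _ = re.shape
    phi = re[..., PHI_RE_IDX].reshape(c, d, n, 2, 2)
    sw = np.empty((c, d, 2, 2))
    sw[..., 0, 0] = draws.get("sigma_w[s,s]")
    sw[..., 0, 1] = sw[..., 1, 0] = draws.get("sigma_w[s,a]")
    sw[..., 1, 1] = draws.get("sigma_w[a,a]")

    eye = np.eye(4)
    kron = np.einsum("cdnij,cdnkl->cdnikjl", phi, phi).reshape(c, d, n, 4, 4)
    a = eye[None, None, None] - kron
    rhs = np.broadcast_to(sw.reshape(c, d, 1, 4, 1), (c, d, n, 4, 1))
    # guard non-stationary person draws: mask them out of the average
    eig = np.abs(np.linalg.eigvals(phi)).max(axis=-1)
    ok = eig < 0.999
    v = np.full((c, d, n, 4), np.nan)
    if ok.any():
        sol = np.linalg.solve(a[ok], rhs[ok])[..., 0]
        v[ok] = sol
    var_s = v[..., 0]
    var_a = v[..., 3]
    good = ok & (var_s > 0) & (var_a > 0)
    sd_s = np.sqrt(np.where(good, var_s, np.nan))
    sd_a = np.sqrt(np.where(good, var_a, np.nan))

    def avg(x):
        return np.nanmean(np.where(good, x, np.nan), axis=2)

    out = {
        RE_LABELS["phi_ss"]: avg(phi[..., 0, 0]),
        RE_LABELS["phi_aa"]: avg(phi[..., 1, 1]),
        RE_LABELS["phi_as"]: avg(phi[..., 0, 1] * sd_a / sd_s),
        RE_LABELS["phi_sa"]: avg(phi[..., 1, 0] * sd_s / sd_a),
    }
    frac_bad = 1.0 - good.mean()
    if frac_bad > 0.01:
        logger.warning("%.1f%% of person draws non-stationary; excluded from "
                       "within-level standardisation", 100 * frac_bad)
    return out


def _predictor_cov(draws: PosteriorDraws, persons: pd.DataFrame | None):
    """Model-implied covariance of [ADHD factor, covariates], per draw."""
    preds = draws.meta.get("predictors", ["adhd"])
    psi_a = draws.get("psi_adhd")                    # (C, D)
    c, d = psi_a.shape
    p = len(preds)
    cov = np.zeros((c, d, p, p))
    cov[..., 0, 0] = psi_a
    if p > 1:
        if persons is None:
            raise ValueError("covariate standardisation needs the person table")
        x = persons.loc[:, list(preds[1:])].to_numpy(dtype=float).copy()
        if "ses" in preds[1:]:
            k = list(preds[1:]).index("ses")
            x[:, k] = (x[:, k] - x[:, k].mean()) / x[:, k].std()
        s = np.cov(x, rowvar=False)
        s = np.atleast_2d(s)
        cov[..., 1:, 1:] = s[None, None]
    return preds, cov


def _between_std(draws: PosteriorDraws, persons: pd.DataFrame | None):
    """Standardised between-level coefficients and means, per draw."""
    preds, sx = _predictor_cov(draws, persons)       # sx: (C,D,p,p)
    p = len(preds)
    gam = np.stack(
        [np.stack([draws.get(f"gamma[{k},{pr}]") for pr in preds], axis=-1)
         for k in RE_NAMES], axis=-2,
    )                                                # (C, D, 6, p)
    tau2 = np.stack([draws.get(f"tau2[{k}]") for k in RE_NAMES], axis=-1)
    alpha = np.stack([draws.get(f"alpha[{k}]") for k in RE_NAMES], axis=-1)

    gs = np.einsum("cdkp,cdpq->cdkq", gam, sx)       # (C, D, 6, p)
    var_re = np.einsum("cdkp,cdkp->cdk", gs, gam) + tau2
    sd_re = np.sqrt(var_re)
    sd_x = np.sqrt(np.einsum("cdpp->cdp", sx))

    out: dict[str, np.ndarray] = {}
    for k, name in enumerate(RE_NAMES):
        out[RE_LABELS[name]] = alpha[..., k] / sd_re[..., k]
    for j, pr in enumerate(preds):
        for k, name in enumerate(RE_NAMES):
            out[f"Effect of {PRED_LABELS[pr]} on {RE_LABELS[name]}"] = (
                gam[..., k, j] * sd_x[..., j] / sd_re[..., k]
            )

    # internalising equation
    beta_re = np.stack([draws.get(f"beta_int[{k}]") for k in RE_NAMES], axis=-1)
    beta_x = np.stack([draws.get(f"beta_int[{pr}]") for pr in preds], axis=-1)
    psi_e = draws.get("psi_int_resid")
    # full predictor covariance: [re (6), x (p)]
    cov_re = np.einsum("cdkp,cdlp->cdkl", gs, gam)   # (C,D,6,6) via shared x
    idx = np.arange(6)
    cov_re[..., idx, idx] += tau2
    cov_re_x = gs                                    # Cov(re_k, x_p) = (gamma Sx)_kp
    beta_all = np.concatenate([beta_re, beta_x], axis=-1)
    big = np.zeros(cov_re.shape[:2] + (6 + p, 6 + p))
    big[..., :6, :6] = cov_re
    big[..., :6, 6:] = cov_re_x
    big[..., 6:, :6] = np.swapaxes(cov_re_x, -1, -2)
    big[..., 6:, 6:] = sx
    var_xi = np.einsum("cdi,cdij,cdj->cd", beta_all, big, beta_all) + psi_e
    sd_xi = np.sqrt(var_xi)
    block = "Internalising Problems predicted by"
    for k, name in enumerate(RE_NAMES):
        out[f"{block} {RE_LABELS[name]}"] = beta_re[..., k] * sd_re[..., k] / sd_xi
    for j, pr in enumerate(preds):
        out[f"{block} {PRED_LABELS[pr]}"] = beta_x[..., j] * sd_x[..., j] / sd_xi
    return out


def standardize_draws(draws: PosteriorDraws,
                      persons: pd.DataFrame | None = None) -> dict[str, np.ndarray]:
    """Draw-wise standardised coefficients, keyed by report label.

    Returns a mapping label -> (chains, draws) array covering the means,
    autoregressive and cross-lagged blocks (within level), the trait
    effects on each random effect, and the internalising equation.
    """
    out = _between_std(draws, persons)
    out.update(_within_std(draws))
    return out


# ---------------------------------------------------------------------------
# mediation
# ---------------------------------------------------------------------------


def indirect_effects(draws: PosteriorDraws) -> list[MediationResult]:
    """Unstandardised indirect ADHD -> random effect -> internalising paths.

    The product of the two path coefficients is formed inside every draw;
    the direct ADHD path is appended for reference.
    """
    out = []
    for name in RE_NAMES:
        a = draws.get(f"gamma[{name},adhd]")
        b = draws.get(f"beta_int[{name}]")
        out.append(MediationResult(label=f"via {RE_LABELS[name]}", products=a * b))
    out.append(
        MediationResult(label="direct: ADHD", products=draws.get("beta_int[adhd]"))
    )
    return out


# ---------------------------------------------------------------------------
# result table
# ---------------------------------------------------------------------------

_BLOCK_OF = [
    ("Means (M)", ["M: Stress", "M: Affect"]),
    ("Autoregressive effects (AR)",
     ["AR: Stress → Stress", "AR: Affect → Affect"]),
    ("Cross-lagged effects (CL)",
     ["CL: Affect → Stress", "CL: Stress → Affect"]),
]


def make_table(draws: PosteriorDraws,
               std: dict[str, np.ndarray] | None = None,
               persons: pd.DataFrame | None = None,
               level: float = 0.95) -> pd.DataFrame:
    """Result table mirroring the baseline/covariate report layout.

    Standardised rows for the dynamics and the between-level regressions,
    unstandardised rows for the indirect effects.  A ``warning`` column
    flags non-convergence of the source run.
    """
    if draws.params.size == 0:
        raise ValueError("empty draw set")
    if std is None:
        std = standardize_draws(draws, persons)
    preds = draws.meta.get("predictors", ["adhd"])
    rows: list[ResultRow] = []
    for block, labels in _BLOCK_OF:
        for lab in labels:
            rows.append(_row_from_draws(block, lab, std[lab], level=level))
    for pr in preds:
        block = f"Effect of {PRED_LABELS[pr]} on"
        for name in RE_NAMES:
            lab = f"Effect of {PRED_LABELS[pr]} on {RE_LABELS[name]}"
            rows.append(_row_from_draws(block, RE_LABELS[name], std[lab], level=level))
    block = "Internalising Problems predicted by"
    for name in RE_NAMES:
        rows.append(_row_from_draws(block, RE_LABELS[name],
                                    std[f"{block} {RE_LABELS[name]}"], level=level))
    for pr in preds:
        rows.append(_row_from_draws(block, PRED_LABELS[pr],
                                    std[f"{block} {PRED_LABELS[pr]}"], level=level))
    for med in indirect_effects(draws):
        r = med.summary
        if level != 0.95:
            r = _row_from_draws(r.block, r.label, med.products,
                                scale="unstandardised", level=level)
        rows.append(r)

    table = pd.DataFrame([r.as_dict() for r in rows])
    table["warning"] = "" if draws.converged else "non-converged run"
    return table


def summarise(draws: PosteriorDraws, name: str, level: float = 0.95) -> ResultRow:
    """Posterior summary row for one named (unstandardised) parameter."""
    return _row_from_draws("parameters", name, draws.get(name),
                           scale="unstandardised", level=level)


def render_text(table: pd.DataFrame) -> str:
    lines = []
    for block, grp in table.groupby("block", sort=False):
        lines.append(block)
        for _, r in grp.iterrows():
            star = "*" if r["significant"] else " "
            lines.append(
                f"  {r['label']:<45s} {r['estimate']:8.3f} ({r['sd']:.3f}) "
                f"[{r['ci_lower']:.3f}, {r['ci_upper']:.3f}]{star}"
            )
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> dict:
    """Execute simulate/load -> grid -> CFA -> DSEM -> report.

    ``config`` is a dict or path to a YAML file with keys::

        simulate: {n_persons, n_days, ...}    # or
        inputs: {ema: path.csv, persons: path.csv}
        model: baseline | covariates
        mcmc: {max_iterations, thinning, ...}
        seed: int
        output_dir: path

    Returns a dict of artefacts (series, cfa, draws, table, manifest) and,
    when an output directory is configured, writes CSV/JSON outputs plus a
    reproducibility manifest.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = dict(config)
    seed = int(cfg.get("seed", 0))
    out_dir = output_dir or cfg.get("output_dir")

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage tag
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    if "inputs" in cfg:
        ema = _stage("load", pd.read_csv, cfg["inputs"]["ema"])
        persons = _stage("load", pd.read_csv, cfg["inputs"]["persons"])
        if "stress_sum" not in ema or "affect_sum" not in ema:
            sums = _stage(
                "scales", score_scales, ema,
                {"stress_sum": [f"s{j}" for j in range(1, 5)],
                 "affect_sum": [f"a{j}" for j in range(1, 8)]},
            )
            ema = pd.concat([ema, sums], axis=1)
        truth = None
    else:
        sim = cfg.get("simulate", {})
        variant = cfg.get("model", "baseline")
        design = DesignConfig(**{**sim, "seed": seed})
        truth = study_truth(covariates=(variant == "covariates"))
        ds = _stage("simulate", simulate_dataset, design, truth, seed)
        ema, persons = ds.ema, ds.persons

    grid_cfg = cfg.get("grid", {})
    gridder = TimeGridder(**grid_cfg)
    series = _stage("grid", lambda: gridder.fit(ema).transform(ema))
    grid_report = gridder.report(series)

    cfa = _stage("cfa", fit_cfa, persons, default_trait_spec())

    variant = cfg.get("model", "baseline")
    covariates = ["sex", "origin", "ses"] if variant == "covariates" else None
    mcmc = dict(cfg.get("mcmc", {}))
    est = DynamicSEM(seed=seed, covariates=covariates, **mcmc)
    _stage("dsem", est.fit, series, persons)

    std = _stage("report", standardize_draws, est.draws_, persons)
    table = _stage("report", make_table, est.draws_, std, persons)

    manifest = {
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "model": variant,
        "n_persons": int(persons.shape[0]),
        "missingness": grid_report["pooled_missingness"],
        "mcmc_iterations": est.n_iterations_,
        "converged": bool(est.converged_),
        "python": platform.python_version(),
        "numpy": np.__version__,
    }

    artefacts = {
        "series": series, "grid_report": grid_report, "cfa": cfa,
        "draws": est.draws_, "table": table, "manifest": manifest,
    }
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "results_table.csv", index=False)
        (out / "results_table.txt").write_text(render_text(table))
        with open(out / "grid_report.json", "w") as fh:
            json.dump(grid_report, fh, indent=2)
        with open(out / "cfa_fit.json", "w") as fh:
            json.dump(cfa.fit_indices_.as_dict()
                      | {"omega_adhd": omega(cfa, "adhd"),
                         "omega_int": omega(cfa, "int")}, fh, indent=2)
        est.draws_.to_frame().to_csv(out / "posterior_draws.csv", index=False)
        with open(out / "diagnostics.json", "w") as fh:
            json.dump({"psr": dict(zip(est.draws_.names, map(float, est.psr_))),
                       "iterations": est.n_iterations_,
                       "seeds": est.draws_.seeds,
                       "converged": bool(est.converged_)}, fh, indent=2)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return artefacts
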
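"""Standardisation, mediation, table construction, pipeline round-trips."""

import numpy as np
import pandas as pd
import pytest

from emadsem.report import (
    indirect_effects,
    make_table,
    render_text,
    run_pipeline,
    standardize_draws,
    summarise,
    _row_from_draws,
)
from conftest import baseline_re_draws, make_draws


def _unit_variance_draws(extra=None, **kwargs):
    """Draws where every variance is 1 so std == unstandardised."""
    values = {
        "gamma[mu_a,adhd]": 0.35,
        "beta_int[adhd]": 0.4,
        "tau2[mu_a]": 1.0 - 0.35**2,   # total Var(mu_a) = 1
        "psi_adhd": 1.0,
    }
    if extra:
        values.update(extra)
    re = baseline_re_draws(**kwargs)
    return make_draws(values, random_effects=re, **{
        k: v for k, v in kwargs.items() if k in ("n_draws", "n_chains")
    })


class TestStandardise:
    def test_unit_scale_identity(self):
        draws = _unit_variance_draws()
        std = standardize_draws(draws)
        assert np.allclose(std["Effect of ADHD on M: Affect"], 0.35)

    def test_simple_regression_closed_form(self):
        # std = b * SD(x) / SD(y) with SD(x)=sqrt(psi), SD(y) model-implied
        b, psi, tau2 = 0.5, 2.0, 3.0
        draws = make_draws(
            {"gamma[mu_s,adhd]": b, "psi_adhd": psi, "tau2[mu_s]": tau2},
            random_effects=baseline_re_draws(),
        )
        std = standardize_draws(draws)
        sd_y = np.sqrt(b**2 * psi + tau2)
        expected = b * np.sqrt(psi) / sd_y
        assert np.allclose(std["Effect of ADHD on M: Stress"], expected)

    def test_scale_relabelling_invariance(self):
        # multiplying the stress metric by 10 leaves standardised effects alone
        base = {
            "gamma[mu_s,adhd]": 0.5, "psi_adhd": 1.3, "tau2[mu_s]": 2.0,
            "beta_int[mu_s]": 0.3, "psi_int_resid": 0.6,
        }
        rescaled = {
            "gamma[mu_s,adhd]": 5.0, "psi_adhd": 1.3, "tau2[mu_s]": 200.0,
            "beta_int[mu_s]": 0.03, "psi_int_resid": 0.6,
        }
        re1 = baseline_re_draws()
        re2 = re1.copy()
        re2[..., 0] *= 10
        s1 = standardize_draws(make_draws(base, random_effects=re1))
        s2 = standardize_draws(make_draws(rescaled, random_effects=re2))
        for key in ("Effect of ADHD on M: Stress",
                    "Internalising Problems predicted by M: Stress"):
            np.testing.assert_allclose(s1[key], s2[key], rtol=1e-10)

    def test_within_ar_is_scale_free_and_cross_picks_up_sd_ratio(self):
        re = baseline_re_draws(phi=(0.3, 0.2, 0.0, 0.1))
        draws = make_draws({"sigma_w[s,s]": 1.0, "sigma_w[a,a]": 4.0,
                            "sigma_w[s,a]": 0.0}, random_effects=re)
        std = standardize_draws(draws)
        assert np.allclose(std["AR: Stress → Stress"], 0.3, atol=1e-6)
        # phi_sa (stress -> affect) multiplies SD(s)/SD(a)
        from emadsem.synthetic import stationary_covariance

        phi = np.array([[0.3, 0.0], [0.1, 0.2]])
        v = stationary_covariance(phi, np.diag([1.0, 4.0]))
        expected = 0.1 * np.sqrt(v[0, 0] / v[1, 1])
        assert np.allclose(std["CL: Stress → Affect"], expected, atol=1e-9)

    def test_missing_random_effects_raise(self):
        draws = make_draws({})
        with pytest.raises(ValueError, match="random effects"):
            standardize_draws(draws)


class TestIndirect:
    def test_point_mass_product(self):
        draws = make_draws({"gamma[mu_a,adhd]": 0.2, "beta_int[mu_a]": 0.3})
        med = {m.label: m for m in indirect_effects(draws)}
        assert np.allclose(med["via M: Affect"].products, 0.06)
        assert med["via M: Affect"].summary.estimate == pytest.approx(0.06)

    def test_zero_a_path_gives_null_effect(self):
        draws = make_draws({"gamma[mu_s,adhd]": 0.0, "beta_int[mu_s]": 0.5})
        med = {m.label: m for m in indirect_effects(draws)}
        row = med["via M: Stress"].summary
        assert row.estimate == 0.0
        assert not row.significant

    def test_products_formed_within_draws(self, rng):
        # independent normal paths: E(ab) = E(a)E(b); quantiles follow the
        # product distribution, not any combination of marginal CIs
        a = 0.2 + 0.05 * rng.standard_normal((2, 2000))
        b = 0.3 + 0.10 * rng.standard_normal((2, 2000))
        draws = make_draws({"gamma[mu_a,adhd]": a, "beta_int[mu_a]": b},
                           n_draws=2000)
        med = {m.label: m for m in indirect_effects(draws)}
        prod = med["via M: Affect"].products
        np.testing.assert_allclose(prod, a * b)
        assert prod.mean() == pytest.approx(0.06, abs=4 * 0.02 / np.sqrt(4000))
        lo, hi = np.percentile(prod, [2.5, 97.5])
        assert med["via M: Affect"].summary.ci_lower == pytest.approx(lo)
        assert med["via M: Affect"].summary.ci_upper == pytest.approx(hi)


class TestTable:
    def _draws(self, rng):
        re = baseline_re_draws(spread=0.02)
        vals = {
            "gamma[phi_ss,adhd]": 0.4 + 0.05 * rng.standard_normal((2, 400)),
            "gamma[mu_s,adhd]": 0.01 * rng.standard_normal((2, 400)),
        }
        return make_draws(vals, random_effects=re)

    def test_quantile_oracle(self, rng):
        draws = self._draws(rng)
        x = rng.normal(0.5, 0.1, size=(2, 400))
        row = _row_from_draws("blk", "x", x)
        assert row.estimate == pytest.approx(np.median(x))
        lo, hi = np.percentile(x, [2.5, 97.5])
        assert row.ci_lower == pytest.approx(lo)
        assert row.ci_upper == pytest.approx(hi)

    def test_significance_tracks_interval_endpoints(self, rng):
        x = rng.normal(size=(2, 500))
        for shift in (0.0, 5.0, -5.0):
            row = _row_from_draws("blk", "x", x + shift)
            assert row.significant == (row.ci_lower > 0 or row.ci_upper < 0)
        # exactly at the boundary: shifting so the 2.5th percentile is ~0
        lo = np.percentile(x, 2.5)
        row = _row_from_draws("blk", "x", x - lo + 1e-9)
        assert row.significant

    def test_wider_level_widens_every_interval(self, rng):
        draws = self._draws(rng)
        t95 = make_table(draws, level=0.95)
        t99 = make_table(draws, level=0.99)
        assert (t99["ci_lower"].to_numpy() <= t95["ci_lower"].to_numpy() + 1e-12).all()
        assert (t99["ci_upper"].to_numpy() >= t95["ci_upper"].to_numpy() - 1e-12).all()

    def test_csv_round_trip(self, rng, tmp_path):
        draws = self._draws(rng)
        table = make_table(draws)
        path = tmp_path / "table.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path, keep_default_na=False)
        assert list(back["label"]) == list(table["label"])
        np.testing.assert_allclose(back["estimate"], table["estimate"])
        assert (back["significant"].astype(str).str.lower()
                == table["significant"].astype(str).str.lower()).all()

    def test_empty_draws_error(self):
        draws = make_draws({}, n_draws=1)
        draws.params = draws.params[:, :0, :]
        with pytest.raises(ValueError):
            make_table(draws)

    def test_summarise_named_parameter(self, rng):
        draws = self._draws(rng)
        row = summarise(draws, "gamma[phi_ss,adhd]")
        assert row.scale == "unstandardised"
        assert row.ci_lower <= row.estimate <= row.ci_upper

    def test_render_text_marks_significance(self, rng):
        draws = self._draws(rng)
        txt = render_text(make_table(draws))
        assert "AR: Stress → Stress" in txt


class TestPipeline:
    CFG = {
        "simulate": {"n_persons": 80, "n_days": 4},
        "model": "baseline",
        "mcmc": {"max_iterations": 150, "min_iterations": 150,
                 "check_every": 150, "thinning": 5},
        "seed": 5,
    }

    def test_end_to_end_and_reproducible_manifest(self, tmp_path):
        arte1 = run_pipeline(dict(self.CFG), output_dir=tmp_path / "a")
        arte2 = run_pipeline(dict(self.CFG), output_dir=tmp_path / "b")
        assert arte1["manifest"]["config_hash"] == arte2["manifest"]["config_hash"]
        pd.testing.assert_frame_equal(arte1["table"], arte2["table"])
        for f in ("results_table.csv", "grid_report.json", "manifest.json",
                  "cfa_fit.json", "posterior_draws.csv", "diagnostics.json"):
            assert (tmp_path / "a" / f).exists()

    def test_covariate_variant_adds_blocks(self, tmp_path):
        cfg = dict(self.CFG)
        cfg["model"] = "covariates"
        arte = run_pipeline(cfg)
        blocks = set(arte["table"]["block"])
        assert "Effect of SES on" in blocks
        assert "Effect of Sex on" in blocks
        base = run_pipeline(dict(self.CFG))
        assert "Effect of SES on" not in set(base["table"]["block"])

    def test_stage_tagged_failure(self):
        cfg = dict(self.CFG)
        cfg["inputs"] = {"ema": "/nonexistent.csv", "persons": "/nope.csv"}
        with pytest.raises(RuntimeError, match="stage 'load'"):
            run_pipeline(cfg)


class TestPipelineInputs:
    def test_item_only_ema_csv_is_sum_scored(self, tmp_path):
        from emadsem.synthetic import DesignConfig, simulate_dataset

        ds = simulate_dataset(DesignConfig(n_persons=80, n_days=4, seed=5))
        ema_items = ds.ema.drop(columns=["stress_sum", "affect_sum"])
        ema_items.to_csv(tmp_path / "ema.csv", index=False)
        ds.persons.to_csv(tmp_path / "persons.csv", index=False)
        cfg = {
            "inputs": {"ema": str(tmp_path / "ema.csv"),
                       "persons": str(tmp_path / "persons.csv")},
            "mcmc": {"max_iterations": 100, "min_iterations": 100,
                     "check_every": 100, "thinning": 5},
            "seed": 5,
        }
        arte = run_pipeline(cfg)
        assert arte["manifest"]["n_persons"] == 80
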
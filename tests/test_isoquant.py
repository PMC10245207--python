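"""Isoquant production-limit model: closed form, NLS, grid oracle,
parameter recovery."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import noduletrade as nt
from noduletrade.isoquant import IsoquantModel


def random_dataset(rng, n=None):
    n = n or rng.integers(3, 30)
    volumes = rng.uniform(0.1, 3.0, n)
    densities = rng.uniform(0.5, 200.0, n)
    return volumes, densities


class TestClosedForm:
    @pytest.mark.parametrize(
        "volumes, densities, expected_L, expected_sse",
        [
            ([1.0, 2.0], [10.0, 5.0], 10.0, 0.0),  # exact isoquant
            ([1.0, 2.0], [12.0, 5.0], 11.6, None),  # weighted LS
            ([1.0, 1.0], [8.0, 12.0], 10.0, None),  # reduces to mean
        ],
    )
    def test_hand_computable_fits(
        self, volumes, densities, expected_L, expected_sse
    ):
        res = nt.fit_isoquant(volumes, densities)
        assert res.L_hat == pytest.approx(expected_L, abs=1e-9)
        if expected_sse is not None:
            assert res.sse == pytest.approx(expected_sse, abs=1e-12)

    def test_t_stat_is_estimate_over_se(self):
        rng = np.random.default_rng(0)
        res = nt.fit_isoquant(*random_dataset(rng))
        assert res.t_stat == pytest.approx(res.L_hat / res.se_L, rel=1e-12)

    def test_exact_data_any_n_recovers_L(self):
        rng = np.random.default_rng(1)
        for n in (2, 5, 40):
            volumes = rng.uniform(0.2, 2.0, n)
            densities = 17.5 / volumes
            res = nt.fit_isoquant(volumes, densities)
            assert res.L_hat == pytest.approx(17.5, rel=1e-12)
            assert res.sse == pytest.approx(0.0, abs=1e-18)


class TestOracleTriangle:
    def test_nls_closed_form_and_grid_agree(self):
        """Three independent routes to L_hat must coincide."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            volumes, densities = random_dataset(rng)
            model = IsoquantModel(densities, volumes)
            closed = model.fit(method="closed_form").L_hat
            nls = model.fit(method="nls").L_hat
            grid = nt.grid_oracle(volumes, densities, num=10_001)
            step = 2.0 * closed / 10_000
            assert abs(nls - closed) <= 1e-6 * closed
            assert abs(grid - closed) <= step

    def test_sse_is_convex_around_optimum(self):
        rng = np.random.default_rng(3)
        volumes, densities = random_dataset(rng)
        model = IsoquantModel(densities, volumes)
        L = model.closed_form()
        grid = np.linspace(0.0, 2 * L, 501)
        sse = np.array([model.sse(x) for x in grid])
        k = int(np.argmin(sse))
        assert np.all(np.diff(sse[: k + 1]) <= 1e-9)  # decreasing before
        assert np.all(np.diff(sse[k:]) >= -1e-9)  # increasing after

    def test_grid_rejects_empty_grid(self):
        with pytest.raises(ValueError):
            nt.grid_oracle([1.0, 2.0], [10.0, 5.0], grid=np.array([]))


class TestInvariances:
    @given(k=st.floats(0.01, 100.0))
    def test_scale_equivariance(self, k):
        volumes = np.array([0.3, 0.8, 1.5, 2.0])
        densities = np.array([60.0, 30.0, 14.0, 9.0])
        base = nt.fit_isoquant(volumes, densities).L_hat
        dens_scaled = nt.fit_isoquant(volumes, densities * k).L_hat
        vol_scaled = nt.fit_isoquant(volumes * k, densities).L_hat
        assert dens_scaled == pytest.approx(k * base, rel=1e-9)
        assert vol_scaled == pytest.approx(k * base, rel=1e-9)

    def test_alternative_responses_agree_on_exact_data(self):
        volumes = np.array([0.25, 0.5, 1.0, 2.0])
        densities = 25.067 / volumes
        for response in ("density", "volume", "loglog"):
            res = nt.fit_isoquant(volumes, densities, response=response)
            assert res.L_hat == pytest.approx(25.067, rel=1e-9)

    def test_responses_differ_on_noisy_data(self):
        rng = np.random.default_rng(9)
        volumes = rng.uniform(0.2, 2.0, 30)
        densities = 25.0 / volumes * np.exp(rng.normal(0, 0.4, 30))
        fits = {
            r: nt.fit_isoquant(volumes, densities, response=r).L_hat
            for r in ("density", "volume", "loglog")
        }
        assert len({round(v, 6) for v in fits.values()}) == 3


class TestEdgeCases:
    def test_all_zero_densities_degenerate(self):
        res = nt.fit_isoquant([1.0, 2.0], [0.0, 0.0])
        assert res.degenerate
        assert res.L_hat == 0.0
        assert math.isnan(res.se_L)
        assert math.isnan(res.t_stat)

    @pytest.mark.parametrize(
        "volumes, densities, err",
        [
            ([1.0], [10.0], "at least 2"),
            ([1.0, -0.5], [10.0, 5.0], "volumes"),
            ([1.0, 0.0], [10.0, 5.0], "volumes"),
            ([1.0, 2.0], [10.0, -1.0], "densities"),
            ([1.0, 2.0], [10.0, 5.0, 1.0], "equal-length"),
        ],
    )
    def test_invalid_inputs_rejected(self, volumes, densities, err):
        with pytest.raises(ValueError, match=err):
            nt.fit_isoquant(volumes, densities)

    def test_loglog_requires_positive_densities(self):
        with pytest.raises(ValueError):
            nt.fit_isoquant([1.0, 2.0], [10.0, 0.0], response="loglog")


class TestResultsObject:
    def test_from_dataframe_matches_arrays(self, default_traits):
        res_df = IsoquantModel.from_dataframe(default_traits).fit()
        res_arr = nt.fit_isoquant(
            default_traits["volume_mm3"], default_traits["density_per_g"]
        )
        assert res_df.L_hat == res_arr.L_hat
        assert res_df.nobs == 43

    def test_conf_int_brackets_estimate(self, default_traits):
        res = IsoquantModel.from_dataframe(default_traits).fit()
        lo, hi = res.conf_int()
        assert lo < res.L_hat < hi

    def test_summary_and_frame(self, default_traits):
        res = IsoquantModel.from_dataframe(default_traits).fit()
        text = res.summary()
        assert "L_hat" in text and "mm^3/g" in text
        frame = res.to_frame()
        assert frame.loc[0, "L_hat"] == res.L_hat
        assert frame.loc[0, "n"] == 43

    def test_plot_returns_axes(self, default_traits):
        import matplotlib

        matplotlib.use("Agg", force=True)
        res = IsoquantModel.from_dataframe(default_traits).fit()
        ax = res.plot()
        assert ax.get_xlabel().startswith("average nodule volume")


class TestRecovery:
    def test_noise_free_recovery_is_exact_on_true_volumes(self):
        """sigma = 0 and fitting against the clades' true volumes must
        return the generating limit with zero error."""
        cfg = dataclasses.replace(
            nt.default_config(seed=5), density_noise_sigma=0.0
        )
        survey = nt.simulate_survey(cfg)
        res = nt.fit_isoquant(
            survey.true_volumes(), survey.nest_table["density_per_g"]
        )
        assert res.L_hat == pytest.approx(
            cfg.production_limit_L, rel=1e-12
        )
        assert res.sse == pytest.approx(0.0, abs=1e-12)

    def test_recovery_report_fields_and_bias(self):
        cfg = dataclasses.replace(
            nt.default_config(seed=77), density_noise_sigma=0.2
        )
        report = nt.recover_production_limit(cfg, 50, base_seed=200)
        assert report.n_replicates == 50
        assert report.bias_correction_factor == pytest.approx(
            math.exp(0.02), rel=1e-12
        )
        assert abs(report.rel_bias_corrected_pct) < 5.0
        assert report.rmse_corrected > 0

    def test_coverage_calibration_under_multiplicative_noise(self):
        """The homoscedastic se undercovers when residual sd scales with
        1/V; the sandwich se restores near-nominal coverage."""
        cfg = dataclasses.replace(
            nt.default_config(seed=100), density_noise_sigma=0.2
        )
        report = nt.recover_production_limit(cfg, 200)
        assert report.coverage_2se < report.coverage_2se_robust
        assert 0.85 <= report.coverage_2se_robust <= 0.95

    def test_rejects_nonpositive_replicates(self):
        with pytest.raises(ValueError):
            nt.recover_production_limit(nt.default_config(), 0)
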
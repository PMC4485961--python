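import math

import numpy as np
import pytest
from scipy import stats

import samaradisp as sd
from samaradisp.dispersal_lmm import DataError
from samaradisp.kernel_simulation import (
    KernelRequest,
    empirical_summaries,
    kernel_bands,
    kernel_closed_form,
    kernel_grid,
    kernel_monte_carlo,
    write_kernel_csv,
)
from samaradisp.parametric_bootstrap import BootstrapDraws, BootstrapError


class TestClosedForm:
    def test_lognormal_quantiles_at_published_estimates(self, table2_truth):
        k = kernel_closed_form(table2_truth, KernelRequest(iwl=44.60, wind=1.72))
        assert k.quantiles["q50"] == pytest.approx(6.83, abs=0.01)
        assert k.quantiles["q90"] == pytest.approx(
            6.83 * math.exp(1.2816 * 0.558), abs=0.05
        )

    def test_cdf_at_q90_is_090(self, table2_truth):
        req = KernelRequest(iwl=20.0, wind=3.0)
        k = kernel_closed_form(table2_truth, req)
        mu = sd.kernel_simulation.kernel_location(table2_truth, 20.0, 3.0)
        dist = stats.lognorm(s=table2_truth.sigma_resid, scale=math.exp(mu))
        assert dist.cdf(k.quantiles["q90"]) == pytest.approx(0.90, abs=1e-9)

    def test_density_normalizes_on_wide_grid(self, table2_truth):
        k = kernel_closed_form(table2_truth, KernelRequest(iwl=10, wind=2))
        mass = np.trapezoid(k.density, k.grid)
        assert 0.99 <= mass <= 1.001

    def test_species_effect_widens_kernel(self, table2_truth):
        narrow = kernel_closed_form(table2_truth, KernelRequest(iwl=10, wind=2))
        wide = kernel_closed_form(
            table2_truth, KernelRequest(iwl=10, wind=2, include_species_effect=True)
        )
        assert wide.quantiles["q90"] > narrow.quantiles["q90"]
        assert wide.quantiles["q50"] == pytest.approx(narrow.quantiles["q50"], rel=1e-9)

    def test_zero_scale_degenerates_to_point_mass(self, table2_truth):
        import dataclasses

        p = dataclasses.replace(table2_truth, sigma_resid=0.0, sigma_species=0.0)
        k = kernel_closed_form(p, KernelRequest(iwl=10, wind=2))
        assert k.quantiles["q50"] == k.quantiles["q90"]

    def test_negative_request_rejected(self):
        with pytest.raises(DataError):
            KernelRequest(iwl=-1, wind=2)


class TestMonteCarlo:
    def test_converges_to_closed_form(self, table2_truth):
        req = KernelRequest(iwl=20.0, wind=1.72, n_draws=100_000)
        cf = kernel_closed_form(table2_truth, req)
        mc = kernel_monte_carlo(table2_truth, req, rng_seed=0)
        # sup-norm distance between empirical and analytic cdf on the grid
        assert np.max(np.abs(mc.cdf - cf.cdf)) < 0.01
        assert mc.quantiles["q50"] == pytest.approx(cf.quantiles["q50"], rel=0.02)

    def test_determinism(self, table2_truth):
        req = KernelRequest(iwl=5, wind=2, n_draws=2000)
        a = kernel_monte_carlo(table2_truth, req, rng_seed=4)
        b = kernel_monte_carlo(table2_truth, req, rng_seed=4)
        np.testing.assert_array_equal(a.density, b.density)

    def test_median_increases_with_iwl(self, table2_truth):
        lo = kernel_monte_carlo(table2_truth, KernelRequest(iwl=0, wind=5, n_draws=20_000), 1)
        hi = kernel_monte_carlo(table2_truth, KernelRequest(iwl=50, wind=5, n_draws=20_000), 1)
        assert hi.quantiles["q50"] > lo.quantiles["q50"]

    def test_too_few_draws_rejected(self, table2_truth):
        with pytest.raises(DataError):
            kernel_monte_carlo(table2_truth, KernelRequest(iwl=1, wind=1, n_draws=99), 0)


class TestBands:
    def test_degenerate_draws_collapse_bands(self, table2_truth):
        row = [
            table2_truth.beta0, table2_truth.beta1, table2_truth.beta2,
            table2_truth.beta3, table2_truth.sigma_species, table2_truth.sigma_resid,
        ]
        boot = BootstrapDraws(B=50, draws=np.tile(row, (50, 1)), refit_failures=0, base_seed=0)
        k = kernel_bands(boot, KernelRequest(iwl=10, wind=2))
        np.testing.assert_allclose(k.band_lower, k.density, rtol=1e-9)
        np.testing.assert_allclose(k.band_upper, k.density, rtol=1e-9)

    def test_bands_contain_point_kernel_for_all_species(self, small_boot, table2_truth):
        t1 = sd.fixtures.table1()
        for iwl in t1["iwl"]:
            k = kernel_bands(small_boot, KernelRequest(iwl=float(iwl), wind=1.72))
            assert np.all(k.band_lower <= k.density + 1e-12)
            assert np.all(k.density <= k.band_upper + 1e-12)

    def test_band_width_grows_with_iwl(self, small_boot):
        """Mirrors the field observation: higher-IWL kernels have longer
        tails with wider uncertainty, on the absolute scale."""
        low = kernel_bands(small_boot, KernelRequest(iwl=1.97, wind=1.72))
        high = kernel_bands(small_boot, KernelRequest(iwl=44.60, wind=1.72))
        w_low = low.quantile_bands["q90"][1] - low.quantile_bands["q90"][0]
        w_high = high.quantile_bands["q90"][1] - high.quantile_bands["q90"][0]
        assert w_high > w_low

    def test_too_few_draws_for_bands(self, table2_truth):
        boot = BootstrapDraws(
            B=10, draws=np.tile([0.5, 0.2, 0.0, 0.2, 0.1, 0.5], (10, 1)),
            refit_failures=0, base_seed=0,
        )
        with pytest.raises(BootstrapError):
            kernel_bands(boot, KernelRequest(iwl=1, wind=1))


class TestGridAndSummaries:
    def test_grid_medians_monotone_in_iwl_and_wind(self, table2_truth):
        grid = kernel_grid(table2_truth, range(1, 51), range(1, 11))
        assert grid.shape[0] == 500
        for wind, sub in grid.groupby("wind"):
            assert np.all(np.diff(sub.sort_values("iwl")["q50"]) > 0)
        for iwl, sub in grid.groupby("iwl"):
            assert np.all(np.diff(sub.sort_values("wind")["q50"]) > 0)

    def test_tail_ratio_constant_in_iwl(self, table2_truth):
        """q90/q50 is a function of the log-scale SD only, so 'longer tails'
        at high IWL are an absolute-scale, not relative-scale, effect."""
        grid = kernel_grid(table2_truth, [1, 10, 25, 50], [1.72])
        ratios = grid["q90"] / grid["q50"]
        assert np.allclose(ratios, ratios.iloc[0], rtol=1e-9)

    def test_single_cell_grid_matches_closed_form(self, table2_truth):
        grid = kernel_grid(table2_truth, [10.0], [2.0])
        k = kernel_closed_form(table2_truth, KernelRequest(iwl=10.0, wind=2.0))
        assert grid.loc[0, "q50"] == pytest.approx(k.quantiles["q50"], rel=1e-12)

    def test_empirical_summaries_by_hand(self):
        import pandas as pd

        df = pd.DataFrame({"species": ["a"] * 5 + ["b"], "distance_m": [1, 2, 3, 4, 5, 7]})
        per, pooled = empirical_summaries(df)
        a = per.set_index("species").loc["a"]
        assert a["median"] == pytest.approx(3.0)
        assert a["p90"] == pytest.approx(4.6)  # type-7 on {1..5}
        b = per.set_index("species").loc["b"]
        assert b["min"] == b["max"] == b["median"] == b["p90"] == 7
        assert pooled["median"] == pytest.approx(np.quantile([1, 2, 3, 4, 5, 7], 0.5))

    def test_kernel_csv_written(self, table2_truth, tmp_path):
        k = kernel_closed_form(table2_truth, KernelRequest(iwl=10, wind=2))
        path = tmp_path / "k.csv"
        write_kernel_csv(k, path)
        import pandas as pd

        back = pd.read_csv(path)
        assert list(back.columns) == ["distance_m", "density", "cdf"]
        assert back.shape[0] == k.grid.size
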
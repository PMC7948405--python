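"""Cap-isomerization thermodynamics: conversions and the free-energy line."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allokin import (
    CorrelationPoint,
    FreeEnergyCorrelation,
    ThermoContext,
    cap_stabilization_from_ddg,
    ddg_from_kcat_ratio,
    fraction_closed,
    fraction_open,
    free_energy_correlation,
    kcat_from_iso,
    kfold_from_ddg,
    percent_inhibition_paper_convention,
    percent_inhibition_ratio_convention,
)


class TestFractionOpen:
    @pytest.mark.parametrize("k_iso, expected", [(0.0, 1.0), (1.0, 0.5)])
    def test_limits(self, k_iso, expected):
        assert fraction_open(k_iso) == expected

    def test_baseline_equilibrium_matches_rate_pair_oracle(self):
        """K_iso = 13 as an explicit open<->closed rate pair: steady state
        occupancy of the open state equals 1/(1+13)."""
        k_close, k_open = 13.0, 1.0  # ratio 13
        open_ss = k_open / (k_open + k_close)
        assert fraction_open(13.0) == pytest.approx(open_ss, rel=1e-14)
        assert fraction_open(13.0) == pytest.approx(0.0714285714, abs=1e-9)

    def test_negative_k_iso_rejected(self):
        with pytest.raises(ValueError):
            fraction_open(-0.1)

    @given(st.floats(min_value=0.0, max_value=1e6, allow_nan=False))
    @settings(derandomize=True, max_examples=50)
    def test_open_plus_closed_is_one(self, k):
        assert fraction_open(k) + fraction_closed(k) == pytest.approx(1.0, abs=1e-15)

    def test_strictly_decreasing(self):
        ks = np.linspace(0, 100, 200)
        vals = fraction_open(ks)
        assert np.all(np.diff(vals) < 0)


class TestKcat:
    def test_baseline_turnover(self, ctx):
        # k_rel = 2.5 s^-1, K_iso = 13
        assert kcat_from_iso(ctx) == pytest.approx(2.5 / 14.0, rel=1e-12)
        assert kcat_from_iso(ctx) == pytest.approx(0.1786, abs=5e-4)

    def test_all_open_limit(self):
        ctx = ThermoContext(k_rel=1.0, k_iso_baseline=1e-300)
        assert kcat_from_iso(ctx, k_iso=0.0) == 1.0

    @pytest.mark.parametrize("k_iso", [100.0, 130.0, 1e4])
    def test_large_k_iso_approximation(self, ctx, k_iso):
        exact = kcat_from_iso(ctx, k_iso=k_iso)
        approx = ctx.k_rel / k_iso
        assert exact == pytest.approx(approx, rel=0.01)


class TestFreeEnergyConversions:
    def test_equal_rates_give_zero(self, ctx):
        assert ddg_from_kcat_ratio(3.0, 3.0, ctx) == 0.0

    def test_boltzmann_inverse(self, ctx):
        """ddg computed from a ratio exponentiates back to that ratio."""
        ratio = 7.205
        ddg = ddg_from_kcat_ratio(ratio, 1.0, ctx)
        assert ddg == pytest.approx(-1.17, abs=0.005)
        assert math.exp(-ddg / ctx.rt) == pytest.approx(ratio, rel=1e-12)

    def test_antisymmetry(self, ctx):
        assert ddg_from_kcat_ratio(2.0, 5.0, ctx) == pytest.approx(
            -ddg_from_kcat_ratio(5.0, 2.0, ctx), rel=1e-14
        )

    def test_nonpositive_rate_rejected(self, ctx):
        with pytest.raises(ValueError):
            ddg_from_kcat_ratio(0.0, 1.0, ctx)

    @pytest.mark.parametrize(
        "ddg, expected, tol",
        [(0.0, 1.0, 1e-15), (-1.41, 10.80, 0.01), (-1.17, 7.21, 0.01)],
    )
    def test_kfold(self, ctx, ddg, expected, tol):
        assert kfold_from_ddg(ddg, ctx) == pytest.approx(expected, abs=tol)

    def test_kfold_reciprocal_under_sign_flip(self, ctx):
        assert kfold_from_ddg(-0.7, ctx) * kfold_from_ddg(0.7, ctx) == pytest.approx(
            1.0, rel=1e-13
        )

    @given(st.floats(min_value=0.05, max_value=50.0),
           st.floats(min_value=0.05, max_value=50.0))
    @settings(derandomize=True, max_examples=50)
    def test_roundtrip_ratio_identity(self, a, b):
        """exp(-ddg(a,b)/RT) recovers the rate ratio to 1e-10 relative."""
        ctx = ThermoContext()
        ddg = ddg_from_kcat_ratio(a, b, ctx)
        assert kfold_from_ddg(ddg, ctx) == pytest.approx(a / b, rel=1e-10)


class TestPercentInhibition:
    @pytest.mark.parametrize("ddg, expected", [(-1.17, 87.8), (-1.41, 91.5)])
    def test_paper_convention_reproduces_predictions(self, ctx, ddg, expected):
        assert percent_inhibition_paper_convention(ddg, ctx) == pytest.approx(
            expected, abs=0.05
        )

    def test_saturating_stabilization(self, ctx):
        assert percent_inhibition_paper_convention(-50.0, ctx) == pytest.approx(
            100.0, abs=1e-6
        )

    def test_ratio_convention_zero_at_zero(self, ctx):
        assert percent_inhibition_ratio_convention(0.0, ctx) == 0.0

    def test_ratio_convention_twofold(self, ctx):
        """Twofold cap stabilization halves turnover: 50% inhibition."""
        ddg = -ctx.rt * math.log(2.0)
        assert percent_inhibition_ratio_convention(ddg, ctx) == pytest.approx(50.0)

    def test_ratio_convention_strong_stabilizer(self, ctx):
        assert percent_inhibition_ratio_convention(-1.41, ctx) == pytest.approx(
            90.75, abs=0.01
        )

    def test_conventions_converge_for_large_k(self, ctx):
        ddg = -ctx.rt * math.log(250.0)  # K = 250 > 200
        diff = percent_inhibition_paper_convention(ddg, ctx) - \
            percent_inhibition_ratio_convention(ddg, ctx)
        assert abs(diff) < 0.5

    def test_destabilizing_ddg_warns(self, ctx):
        with pytest.warns(UserWarning):
            val = percent_inhibition_paper_convention(0.5, ctx)
        assert val < 50.0

    def test_cap_stabilization_bundle(self, ctx):
        cs = cap_stabilization_from_ddg("CMP13", -1.41, ctx)
        assert cs.k_fold == pytest.approx(10.80, abs=0.01)
        assert round(cs.percent_inhibition_predicted) == 92


class TestFreeEnergyCorrelation:
    def test_identity_line(self):
        pts = [CorrelationPoint(f"c{i}", -0.3 * i, -0.3 * i) for i in range(1, 5)]
        slope, intercept, r = free_energy_correlation(pts)
        assert slope == pytest.approx(1.0, rel=1e-12)
        assert r == pytest.approx(1.0, rel=1e-12)

    def test_constructed_slope(self):
        x = np.array([-0.2, -0.5, -0.8, -1.1, -1.4])
        pts = [CorrelationPoint(f"c{i}", 1.1 * xi, xi) for i, xi in enumerate(x)]
        slope, intercept, _ = free_energy_correlation(pts)
        assert slope == pytest.approx(1.1, rel=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_noisy_series_recovers_generating_slope(self):
        """Slope recovery judged against the sampling SE implied by the
        generating noise (sigma / sqrt(Sxx)), not the realization-dependent
        residual SE."""
        from allokin.synthetic import gen_correlation_points

        sigma = 0.05
        pts = gen_correlation_points(noise_sd=sigma, seed=7)
        fit = FreeEnergyCorrelation().fit(pts)
        x = np.array([p.ddg_exp for p in pts])
        se_gen = sigma / np.sqrt(np.sum((x - x.mean()) ** 2))
        assert abs(fit.slope_ - 1.0) < 3 * se_gen

    def test_too_few_points(self):
        pts = [CorrelationPoint("a", -1.0, -1.0), CorrelationPoint("b", -2.0, -2.0)]
        with pytest.raises(ValueError):
            free_energy_correlation(pts)

    def test_zero_x_variance(self):
        pts = [CorrelationPoint(f"c{i}", -float(i), -1.0) for i in range(4)]
        with pytest.raises(ValueError):
            free_energy_correlation(pts)


def test_context_validation():
    with pytest.raises(ValueError):
        ThermoContext(temperature=0.0)
    with pytest.raises(ValueError):
        ThermoContext(k_rel=-1.0)
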
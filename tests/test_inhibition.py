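"""Tight-binding partial inhibition, ex vivo IC50, quantitation and QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allokin import (
    ExVivoIC50Fit,
    ExVivoParams,
    InhibitionCurveFit,
    InhibitorParams,
    QuantSpec,
    conc_from_absorbance,
    esi_bound,
    exvivo_dps_model,
    fit_exvivo,
    fit_inhibition_curve,
    mass_balance_check,
    percent_inhibition_at_saturation,
    rate_partial_noncompetitive,
)
from allokin.synthetic import NoiseSpec, gen_dose_response


class TestEsiBound:
    def test_no_inhibitor(self):
        assert esi_bound(20.0, 0.0, 11.0) == 0.0

    def test_saturation_bounded_by_enzyme(self):
        esi = esi_bound(20.0, 1e6, 11.0)
        assert esi == pytest.approx(20.0, rel=1e-3)
        assert esi <= 20.0

    def test_matches_bisection_oracle_at_stoichiometric_point(self, bisection_bound):
        assert esi_bound(20.0, 20.0, 11.0) == pytest.approx(
            bisection_bound(20.0, 20.0, 11.0), rel=1e-10
        )

    def test_oracle_equivalence_random_triples(self, bisection_bound, rng):
        """Closed-form root matches mass-action bisection to 1e-10 relative
        over 1000 random valid parameter triples."""
        for _ in range(1000):
            e = 10 ** rng.uniform(-2, 3)
            i = 10 ** rng.uniform(-2, 4)
            k = 10 ** rng.uniform(-2, 4)
            expected = bisection_bound(e, i, k)
            got = esi_bound(e, i, k)
            assert got == pytest.approx(expected, rel=1e-10, abs=1e-12)

    def test_no_cancellation_at_extreme_excess(self):
        # I >> E: complex ~ E * I/(I + K); naive minus-root would lose digits
        esi = esi_bound(1e-3, 1e9, 10.0)
        assert esi == pytest.approx(1e-3 * 1e9 / (1e9 + 10.0), rel=1e-9)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            esi_bound(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            esi_bound(1.0, 1.0, 0.0)


class TestRatePartialNoncompetitive:
    CMP8 = InhibitorParams("CMP8", 34.0, 0.46)

    def test_zero_dose_full_rate(self):
        assert rate_partial_noncompetitive(20.0, 0.0, self.CMP8) == 1.0

    def test_saturation_reaches_alpha(self):
        v = rate_partial_noncompetitive(20.0, 1e7, self.CMP8)
        assert v == pytest.approx(0.46, abs=1e-4)

    def test_non_inhibitor_alpha_one(self):
        p = InhibitorParams("inert", 34.0, 1.0)
        doses = np.geomspace(1, 1e5, 20)
        assert np.allclose(rate_partial_noncompetitive(20.0, doses, p), 1.0)

    def test_monotone_nonincreasing(self):
        doses = np.geomspace(0.1, 1e5, 100)
        v = rate_partial_noncompetitive(20.0, doses, self.CMP8)
        assert np.all(np.diff(v) <= 1e-14)
        assert np.all((v >= 0.46 - 1e-12) & (v <= 1.0 + 1e-12))

    def test_reduces_to_hyperbola_without_depletion(self):
        """At e_total <= K_i/100 the depleting rate law collapses onto
        1 - (1-a) I/(K_i + I) within 0.1%."""
        p = self.CMP8
        e = p.k_i / 100.0
        doses = np.geomspace(0.1, 1e4, 50)
        full = rate_partial_noncompetitive(e, doses, p)
        hyper = 1.0 - (1.0 - p.alpha) * doses / (p.k_i + doses)
        assert np.allclose(full, hyper, rtol=1e-3)


class TestInhibitionFit:
    @pytest.mark.parametrize("k_i, alpha", [(70.0, 0.17), (11.0, 0.02)])
    def test_noiseless_roundtrip_recovers_truth(self, k_i, alpha):
        truth = InhibitorParams("x", k_i, alpha)
        doses = np.concatenate([[0.0], np.geomspace(0.2 * k_i, 20 * k_i, 10)])
        resp = rate_partial_noncompetitive(20.0, doses, truth)
        est = InhibitionCurveFit(e_total=20.0).fit(doses, resp)
        assert est.k_i_ == pytest.approx(k_i, rel=1e-4)
        assert est.alpha_ == pytest.approx(alpha, rel=1e-4)

    def test_normalization_divides_by_zero_dose_mean(self):
        truth = InhibitorParams("x", 34.0, 0.46)
        doses = np.concatenate([[0.0], np.geomspace(7, 700, 9)])
        resp = 3.7 * rate_partial_noncompetitive(20.0, doses, truth)  # raw rates
        est = InhibitionCurveFit(e_total=20.0, normalize=True).fit(doses, resp)
        assert est.k_i_ == pytest.approx(34.0, rel=1e-4)

    def test_noisy_replicates_recover_within_uncertainty(self):
        ds = gen_dose_response("CMP12", noise=NoiseSpec(sigma=0.02, seed=3))
        p = fit_inhibition_curve(ds)
        assert p.k_i == pytest.approx(70.0, rel=0.15)
        assert p.alpha == pytest.approx(0.17, abs=0.05)
        assert p.k_i_sd is not None and p.k_i_sd > 0

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError):
            InhibitionCurveFit().fit([0, 1, 2, 3], [1, 0.9, 0.8, 0.7])

    def test_ill_conditioned_dose_range_warns(self):
        truth = InhibitorParams("x", 1000.0, 0.1)
        doses = np.array([0.0, 1.0, 2.0, 4.0, 8.0, 16.0])  # all << K_i
        resp = rate_partial_noncompetitive(20.0, doses, truth)
        with pytest.warns(UserWarning, match="ill-conditioned"):
            InhibitionCurveFit(e_total=20.0).fit(doses, resp)

    def test_pooled_replicates_supported(self):
        ds = gen_dose_response("CMP13", noise=NoiseSpec(sigma=0.01, seed=5))
        p = fit_inhibition_curve(ds, aggregate="pooled")
        assert p.k_i == pytest.approx(11.0, rel=0.2)

    def test_bootstrap_sds_available(self):
        ds = gen_dose_response("CMP12", noise=NoiseSpec(sigma=0.02, seed=11))
        est = InhibitionCurveFit(e_total=20.0, bootstrap=100, random_state=0)
        est.fit(ds.doses, ds.responses)
        assert est.k_i_sd_boot_ > 0
        # bootstrap and covariance SDs agree in order of magnitude
        assert 0.1 < est.k_i_sd_boot_ / est.k_i_sd_ < 10


class TestPercentInhibition:
    @pytest.mark.parametrize(
        "alpha, expected", [(0.46, 54.0), (1.0, 0.0), (0.02, 98.0)]
    )
    def test_saturation_inhibition(self, alpha, expected):
        p = InhibitorParams("x", 10.0, alpha)
        assert percent_inhibition_at_saturation(p) == pytest.approx(expected)


class TestExVivo:
    PARAMS = ExVivoParams(dps_no_inh=40.0, dps_suppressible=38.0, ic50=12.0)

    def test_zero_dose_is_baseline(self):
        assert exvivo_dps_model(0.0, self.PARAMS) == 40.0

    def test_half_saturation_identity(self):
        assert exvivo_dps_model(12.0, self.PARAMS) == pytest.approx(40.0 - 19.0)

    def test_plateau(self):
        assert exvivo_dps_model(1e12, self.PARAMS) == pytest.approx(2.0, abs=1e-6)
        # exact floor
        i = np.geomspace(1, 1e6, 50)
        assert np.all(exvivo_dps_model(i, self.PARAMS) >= 2.0 - 1e-9)

    @pytest.mark.parametrize(
        "ic50, frac", [(12.0, 0.95), (260.0, 0.84)]
    )
    def test_noiseless_fit_recovers_truth(self, ic50, frac):
        truth = ExVivoParams(40.0, frac * 40.0, ic50)
        doses = np.concatenate([[0.0], np.geomspace(0.2 * ic50, 20 * ic50, 10)])
        dps = exvivo_dps_model(doses, truth)
        est = ExVivoIC50Fit().fit(doses, dps)
        assert est.ic50_ == pytest.approx(ic50, rel=1e-4)
        assert est.pct_inh_sat_ == pytest.approx(100 * frac, rel=1e-4)

    def test_all_zero_doses_rejected(self):
        with pytest.raises(ValueError):
            ExVivoIC50Fit().fit(np.zeros(6), np.full(6, 40.0))

    def test_unresolved_plateau_warns(self):
        truth = ExVivoParams(40.0, 38.0, 500.0)
        doses = np.array([0.0, 50.0, 100.0, 200.0, 400.0, 800.0])
        dps = exvivo_dps_model(doses, truth)
        with pytest.warns(UserWarning, match="plateau"):
            ExVivoIC50Fit().fit(doses, dps)

    def test_fit_exvivo_wrapper(self):
        ds = gen_dose_response("CMP13", kind="ex_vivo",
                               noise=NoiseSpec(sigma=0.0, seed=0))
        p = fit_exvivo(ds)
        assert p.ic50 == pytest.approx(12.0, rel=1e-3)
        assert p.pct_inh_sat == pytest.approx(95.0, rel=1e-3)


class TestQuantitation:
    def test_beer_lambert(self):
        dps = QuantSpec(extinction_coefficient=2.8, wavelength=284.0)
        assert conc_from_absorbance(0.0, dps) == 0.0
        assert conc_from_absorbance(0.28, dps) == pytest.approx(0.1)
        dp = QuantSpec(extinction_coefficient=3.2, wavelength=280.0)
        assert conc_from_absorbance(0.32, dp) == pytest.approx(0.1)

    def test_negative_absorbance_rejected(self):
        with pytest.raises(ValueError):
            conc_from_absorbance(-0.1, QuantSpec(2.8))


class TestMassBalance:
    @pytest.mark.parametrize(
        "dp, dps, added, frac, ok",
        [(60.0, 40.0, 100.0, 1.0, True),
         (50.0, 40.0, 100.0, 0.90, False),
         (95.0, 0.0, 100.0, 0.95, True)],  # boundary inclusive
    )
    def test_recovery(self, dp, dps, added, frac, ok):
        got_frac, got_ok = mass_balance_check(dp, dps, added)
        assert got_frac == pytest.approx(frac)
        assert got_ok is ok

    def test_zero_added_rejected(self):
        with pytest.raises(ValueError):
            mass_balance_check(1.0, 1.0, 0.0)


@given(
    st.floats(min_value=0.1, max_value=100.0),
    st.floats(min_value=0.0, max_value=1.0),
    st.floats(min_value=1.0, max_value=1000.0),
)
@settings(derandomize=True, max_examples=50)
def test_rate_bounded_by_alpha_and_one(k_i, alpha, dose):
    p = InhibitorParams("h", k_i, alpha)
    v = rate_partial_noncompetitive(20.0, dose, p)
    assert alpha - 1e-9 <= v <= 1.0 + 1e-9
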
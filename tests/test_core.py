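"""Core model: saturation ceiling, LET scaling, iso-effect RBE."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protonrbe import (
    DEFAULT_CALIBRATION,
    PROTON,
    Calibration,
    IonSpec,
    LQParams,
    alpha_ceiling,
    iso_effective_photon_dose,
    load_config,
    calibration_from_config,
    prescribe_proton_dose,
    rbe_at_dose,
    rbe_fields,
    rbe_limits,
    scale_radiosensitivity,
)
from conftest import bisect_iso_dose

tissues = st.builds(
    LQParams,
    alpha=st.floats(0.05, 1.0),
    beta=st.floats(0.005, 0.2),
)

# clinically representative range, where the saturation gain in alpha
# outpaces the beta coupling (see docs/methods.md on the alpha/beta trend)
clinical_tissues = st.builds(
    lambda alpha, ratio: LQParams(alpha, alpha / ratio),
    alpha=st.floats(0.05, 0.5),
    ratio=st.floats(1.0, 20.0),
)


class TestAlphaCeiling:
    def test_anchor_identity(self):
        # the calibration is constructed so the V-79 ceiling matches its
        # published fitted line evaluated at the turnover LET
        assert alpha_ceiling(0.12) == pytest.approx(0.12 + 0.02 * 30.5, abs=1e-12)

    @pytest.mark.parametrize(
        "alpha_low, expected",
        [(0.12, 0.73), (1.0, 1.9545558791)],
    )
    def test_frozen_values(self, alpha_low, expected):
        assert alpha_ceiling(alpha_low) == pytest.approx(expected, rel=1e-9)

    def test_through_origin(self):
        assert alpha_ceiling(1e-12) == pytest.approx(0.0, abs=1e-10)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            alpha_ceiling(0.0)
        with pytest.raises(ValueError):
            alpha_ceiling(-0.1)

    def test_monotone_and_concave_in_alpha_low(self):
        grid = np.linspace(0.05, 1.0, 50)
        vals = np.array([alpha_ceiling(a) for a in grid])
        assert np.all(np.diff(vals) > 0)
        assert np.all(np.diff(vals, 2) < 0)
        assert np.all(vals > grid)  # ceiling exceeds the low-LET alpha here


class TestScaling:
    def test_identity_at_zero_let(self, v79):
        s = scale_radiosensitivity(v79, 0.0)
        assert s.alpha_h == v79.alpha
        assert s.beta_h == v79.beta

    def test_v79_alpha_slope_is_published_line(self, v79):
        # (alpha_U - alpha_L)/LET_U reproduces the 0.02 slope by construction
        s = scale_radiosensitivity(v79, 10.0)
        assert s.alpha_h == pytest.approx(0.12 + 0.02 * 10, abs=1e-12)

    def test_beta_law_frozen_value(self, v79):
        s = scale_radiosensitivity(v79, 6.0)
        r_u = 1 + 0.15 * math.sqrt(0.12 / 0.035)
        expected = 0.035 * (1 + (6 / 30.5) * (r_u**2 - 1))
        assert s.beta_h == pytest.approx(expected, rel=1e-12)
        assert s.beta_h == pytest.approx(0.03936, abs=5e-6)

    def test_clamp_beyond_turnover(self, v79):
        at_turnover = scale_radiosensitivity(v79, 30.5)
        beyond = scale_radiosensitivity(v79, 60.0)
        assert beyond.alpha_h == at_turnover.alpha_h
        assert beyond.beta_h == at_turnover.beta_h

    def test_rejects_negative_let(self, v79):
        with pytest.raises(ValueError):
            scale_radiosensitivity(v79, -1.0)

    @settings(max_examples=100, derandomize=True)
    @given(low=clinical_tissues, let=st.floats(0.1, 30.5))
    def test_alpha_beta_ratio_rises_with_let(self, low, let):
        s = scale_radiosensitivity(low, let)
        assert s.alpha_h >= low.alpha
        assert s.beta_h >= low.beta
        assert s.alpha_h / s.beta_h > low.alpha / low.beta

    @settings(max_examples=50, derandomize=True)
    @given(low=tissues)
    def test_alpha_strictly_increasing_below_turnover(self, low):
        lets = np.linspace(0, 30.5, 40)
        alphas = [scale_radiosensitivity(low, l).alpha_h for l in lets]
        assert np.all(np.diff(alphas) > 0)


class TestRBELimits:
    def test_frozen_values_let2(self, v79):
        s = scale_radiosensitivity(v79, 2.0)
        rmax, rmin = rbe_limits(v79, s)
        assert rmax == pytest.approx(0.16 / 0.12, rel=1e-9)
        assert rmin == pytest.approx(1.0205, abs=5e-5)

    def test_unity_at_zero_let(self, v79):
        rmax, rmin = rbe_limits(v79, scale_radiosensitivity(v79, 0.0))
        assert (rmax, rmin) == (1.0, 1.0)

    def test_beta_zero_reports_unity(self):
        low = LQParams(0.2, 0.0)
        s = scale_radiosensitivity(low, 5.0)
        assert s.beta_h == 0.0
        rmax, rmin = rbe_limits(low, s)
        assert rmin == 1.0

    def test_rbemax_inverse_in_alpha_low(self):
        # higher baseline alpha -> smaller RBEmax at fixed LET
        grid = np.linspace(0.05, 1.0, 30)
        rmaxs = [
            rbe_limits(LQParams(a, 0.035), scale_radiosensitivity(LQParams(a, 0.035), 5.0))[0]
            for a in grid
        ]
        assert np.all(np.diff(rmaxs) < 0)

    def test_rbemin_increases_with_sqrt_alpha_beta(self):
        ratios, rmins = [], []
        for a in np.linspace(0.05, 1.0, 30):
            low = LQParams(a, 0.035)
            rmins.append(rbe_limits(low, scale_radiosensitivity(low, 5.0))[1])
            ratios.append(math.sqrt(a / 0.035))
        assert np.all(np.diff(ratios) > 0)
        assert np.all(np.diff(rmins) > 0)


class TestIsoEffectiveDose:
    @pytest.mark.parametrize(
        "low, effect, expected",
        [
            (LQParams(0.12, 0.035), 0.46581, 2.3165),
            (LQParams(0.12, 0.035), 0.0, 0.0),
            (LQParams(0.2, 0.0), 0.5, 2.5),
        ],
    )
    def test_examples(self, low, effect, expected):
        assert iso_effective_photon_dose(low, effect) == pytest.approx(expected, abs=2e-4)

    def test_rejects_negative_effect(self, v79):
        with pytest.raises(ValueError):
            iso_effective_photon_dose(v79, -0.1)

    def test_satisfies_lq_identity(self, v79):
        d = iso_effective_photon_dose(v79, 1.234)
        assert v79.alpha * d + v79.beta * d * d == pytest.approx(1.234, rel=1e-9)

    def test_matches_bisection_oracle_on_random_draws(self):
        rng = np.random.default_rng(20150915)
        for _ in range(1000):
            alpha = rng.uniform(0.05, 1.0)
            beta = rng.uniform(0.001, 0.2)
            effect = rng.uniform(0.0, 10.0)
            closed = iso_effective_photon_dose(LQParams(alpha, beta), effect)
            oracle = bisect_iso_dose(alpha, beta, effect)
            assert closed == pytest.approx(oracle, rel=1e-9, abs=1e-9)


class TestRBEAtDose:
    @pytest.mark.parametrize(
        "let, dose, expected",
        [(2.0, 2.0, 1.1583), (6.0, 1.8, 1.4644)],
    )
    def test_frozen_values(self, v79, let, dose, expected):
        assert rbe_at_dose(v79, let, dose).rbe == pytest.approx(expected, abs=1e-4)

    def test_unity_at_zero_let(self, v79):
        for d in (0.5, 2.0, 10.0):
            assert rbe_at_dose(v79, 0.0, d).rbe == pytest.approx(1.0, abs=1e-12)

    def test_zero_dose_returns_rbe_max(self, v79):
        r = rbe_at_dose(v79, 4.0, 0.0)
        assert r.rbe == r.rbe_max
        assert r.iso_photon_dose == 0.0

    def test_iso_photon_dose_consistent(self, v79):
        r = rbe_at_dose(v79, 2.0, 2.0)
        assert r.iso_photon_dose == pytest.approx(r.rbe * 2.0, rel=1e-12)

    def test_rejects_negative_dose(self, v79):
        with pytest.raises(ValueError):
            rbe_at_dose(v79, 2.0, -1.0)

    @settings(max_examples=100, derandomize=True)
    @given(low=tissues, let=st.floats(0.5, 30.5))
    def test_monotone_decreasing_with_limits(self, low, let):
        # RBE runs monotonically from RBEmax (d -> 0) to RBEmin (d -> inf);
        # decreasing in the usual RBEmax > RBEmin regime, increasing in the
        # reversed regime (very radiosensitive tissues)
        doses = np.geomspace(0.05, 50, 25)
        rbes = [rbe_at_dose(low, let, d).rbe for d in doses]
        r = rbe_at_dose(low, let, 1.0)
        if r.rbe_max > r.rbe_min:
            assert np.all(np.diff(rbes) < 0)
            assert r.rbe_min <= r.rbe <= r.rbe_max
        elif r.rbe_max < r.rbe_min:
            assert np.all(np.diff(rbes) > 0)
            assert r.rbe_max <= r.rbe <= r.rbe_min
        assert rbe_at_dose(low, let, 1e-6).rbe == pytest.approx(r.rbe_max, abs=1e-3)
        assert rbe_at_dose(low, let, 1e6).rbe == pytest.approx(r.rbe_min, abs=1e-3)

    @settings(max_examples=100, derandomize=True)
    @given(low=tissues, let=st.floats(0.0, 40.0), dose=st.floats(0.1, 20.0))
    def test_iso_effect_identity(self, low, let, dose):
        # photon dose RBE*d produces the same log kill as the proton dose d
        r = rbe_at_dose(low, let, dose)
        s = scale_radiosensitivity(low, let)
        proton_effect = s.alpha_h * dose + s.beta_h * dose * dose
        photon_dose = r.rbe * dose
        photon_effect = low.alpha * photon_dose + low.beta * photon_dose**2
        assert photon_effect == pytest.approx(proton_effect, rel=1e-9)

    def test_beta_zero_linear_form(self):
        low = LQParams(0.2, 0.0)
        r = rbe_at_dose(low, 5.0, 2.0)
        s = scale_radiosensitivity(low, 5.0)
        assert r.rbe == pytest.approx(s.alpha_h / 0.2, rel=1e-12)
        assert r.degenerate_beta
        assert r.rbe_min == 1.0


class TestVectorisedFields:
    def test_matches_scalar_path(self, v79):
        rng = np.random.default_rng(7)
        let = rng.uniform(0, 40, 50)
        dose = rng.uniform(0, 10, 50)
        dose[::7] = 0.0
        rbe, iso = rbe_fields(v79, let, dose)
        for i in range(50):
            r = rbe_at_dose(v79, let[i], dose[i])
            assert rbe[i] == pytest.approx(r.rbe, rel=1e-12)
            assert iso[i] == pytest.approx(r.iso_photon_dose, rel=1e-12)


class TestPrescription:
    @pytest.mark.parametrize(
        "photon, rbe, expected",
        [(76.0, 1.1, 69.0909), (76.0, 1.2, 63.3333), (50.0, 1.0, 50.0)],
    )
    def test_division(self, photon, rbe, expected):
        assert prescribe_proton_dose(photon, rbe) == pytest.approx(expected, abs=1e-3)

    def test_rejects_nonpositive_rbe(self):
        with pytest.raises(ValueError):
            prescribe_proton_dose(76.0, 0.0)


class TestConfig:
    def test_roundtrip_and_recalibration(self, tmp_path):
        cfg = tmp_path / "rbe.cfg"
        cfg.write_text(
            "# custom calibration\n"
            "alpha_ceiling = 2.5\n"
            "beta_coupling = 0.0\n"
        )
        calib, ion = calibration_from_config(load_config(cfg))
        assert calib.alpha_ceiling == 2.5
        assert calib.beta_coupling == 0.0
        # anchor identity still holds under the new ceiling
        assert calib.alpha_ceiling * -math.expm1(-calib.alpha_rate * 0.12) == pytest.approx(
            0.73, abs=1e-12
        )
        # beta_coupling 0 leaves beta LET-invariant
        s = scale_radiosensitivity(LQParams(0.12, 0.035), 10.0, ion, calib)
        assert s.beta_h == 0.035

    def test_unknown_key_rejected(self, tmp_path):
        cfg = tmp_path / "bad.cfg"
        cfg.write_text("gamma = 1\n")
        with pytest.raises(ValueError):
            load_config(cfg)

    def test_lqparams_validation(self):
        with pytest.raises(ValueError):
            LQParams(0.0, 0.035)
        with pytest.raises(ValueError):
            LQParams(0.12, -0.01)
        assert LQParams(0.12, 0.035).alpha_beta_ratio == pytest.approx(0.12 / 0.035)
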
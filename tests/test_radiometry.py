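import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermocrop import (
    FIXTURE_PLANCK,
    RadiometricDomainError,
    RadiometricSettings,
    Rect,
    RoiError,
    ThermalFrame,
    correct_reflection,
    estimate_reflected_temperature,
    frame_to_temperature,
    raw_to_temperature,
    temperature_to_raw,
)
from thermocrop.synthetic import generate_panel_frame

# Frozen expectation: Planck forward model at 300 K for the fixture
# constants, evaluated independently with sympy at 30 significant digits.
RAW_300K_FIXTURE = 18714.9232475487487140394567603
# Forward mixing S = 0.96*RAW(303) + 0.04*RAW(293), same oracle.
S_MIXED_FIXTURE = 19221.8681890718484066595861195


def test_forward_model_matches_high_precision_oracle():
    assert temperature_to_raw(300.0, FIXTURE_PLANCK) == pytest.approx(RAW_300K_FIXTURE, abs=1e-6)


def test_forward_model_monotonic_in_temperature():
    assert temperature_to_raw(290.0, FIXTURE_PLANCK) < temperature_to_raw(310.0, FIXTURE_PLANCK)


def test_roundtrip_identity_over_temperature_grid(planck):
    T = np.linspace(250.0, 350.0, 41)
    back = raw_to_temperature(temperature_to_raw(T, planck), planck)
    np.testing.assert_allclose(back, T, atol=1e-9)


def test_inverse_of_frozen_oracle_value_is_300K():
    assert raw_to_temperature(RAW_300K_FIXTURE, FIXTURE_PLANCK) == pytest.approx(300.0, abs=1e-9)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.floats(min_value=250.0, max_value=350.0))
def test_roundtrip_identity_property(T):
    back = raw_to_temperature(temperature_to_raw(T, FIXTURE_PLANCK), FIXTURE_PLANCK)
    assert back == pytest.approx(T, abs=1e-9)


@pytest.mark.parametrize("bad_raw", [-10000.0, 7339.0])
def test_raw_below_log_domain_raises(bad_raw):
    # fixture constants have O = -7340, so raw + O <= 0 for raw <= 7340
    with pytest.raises(RadiometricDomainError):
        raw_to_temperature(bad_raw, FIXTURE_PLANCK)


def test_nonpositive_temperature_raises():
    with pytest.raises(RadiometricDomainError):
        temperature_to_raw(-5.0, FIXTURE_PLANCK)


def test_unit_emissivity_collapses_reflection_correction(planck):
    S = temperature_to_raw(302.0, planck)
    results = {
        correct_reflection(S, RadiometricSettings(emissivity=1.0, T_reflected_K=Tr), planck)
        for Tr in (280.0, 300.0, 320.0)
    }
    assert len(results) == 1  # bit-for-bit independent of T_reflected
    assert results.pop() == raw_to_temperature(S, planck)


@pytest.mark.parametrize("eps", [0.8, 0.96, 1.0])
def test_forward_model_inversion_recovers_true_temperature(planck, eps):
    for T_true in (285.0, 298.0, 312.0):
        for T_refl in (278.0, 293.0, 305.0):
            S = eps * temperature_to_raw(T_true, planck) + (1 - eps) * temperature_to_raw(
                T_refl, planck
            )
            got = correct_reflection(
                S, RadiometricSettings(emissivity=eps, T_reflected_K=T_refl), planck
            )
            assert got == pytest.approx(T_true, abs=1e-9)


def test_frozen_mixed_count_inverts_to_303K():
    got = correct_reflection(
        S_MIXED_FIXTURE,
        RadiometricSettings(emissivity=0.96, T_reflected_K=293.0),
        FIXTURE_PLANCK,
    )
    assert got == pytest.approx(303.0, abs=1e-9)


def test_correct_reflection_decreasing_in_reflected_temperature():
    # warmer surroundings contribute more reflected signal, so the same
    # measured count implies a cooler object
    S = temperature_to_raw(300.0, FIXTURE_PLANCK)
    settings_lo = RadiometricSettings(emissivity=0.96, T_reflected_K=285.0)
    settings_hi = RadiometricSettings(emissivity=0.96, T_reflected_K=305.0)
    assert correct_reflection(S, settings_hi, FIXTURE_PLANCK) < correct_reflection(
        S, settings_lo, FIXTURE_PLANCK
    )


def test_correct_reflection_strictly_increasing_in_count():
    settings = RadiometricSettings(emissivity=0.96, T_reflected_K=293.0)
    S = np.linspace(15000, 25000, 11)
    T = np.array([correct_reflection(s, settings, FIXTURE_PLANCK) for s in S])
    assert np.all(np.diff(T) > 0)


def test_frame_conversion_equals_elementwise_scalar_path():
    rng = np.random.default_rng(0)
    raw = rng.integers(15000, 25000, size=(240, 320), dtype=np.uint16)
    settings = RadiometricSettings(emissivity=0.96, T_reflected_K=293.0)
    tmap = frame_to_temperature(ThermalFrame(raw), settings, FIXTURE_PLANCK)
    scalar = correct_reflection(float(raw[120, 37]), settings, FIXTURE_PLANCK)
    assert tmap.T_object[120, 37] == pytest.approx(scalar, abs=1e-9)
    const = frame_to_temperature(
        ThermalFrame(np.full((240, 320), 20000, np.uint16)), settings, FIXTURE_PLANCK
    )
    assert np.ptp(const.T_object) == 0.0


def test_frame_conversion_names_offending_pixel():
    raw = np.full((240, 320), 20000, np.uint16)
    raw[17, 211] = 100  # raw + O <= 0 after reflection correction
    with pytest.raises(RadiometricDomainError, match=r"x=211, y=17"):
        frame_to_temperature(
            ThermalFrame(raw), RadiometricSettings(emissivity=0.96, T_reflected_K=293.0),
            FIXTURE_PLANCK,
        )


class TestReflectedTemperatureEstimation:
    def test_constant_panel_recovers_apparent_temperature(self):
        frame = generate_panel_frame(295.0, noise_sd=0.0, planck=FIXTURE_PLANCK, seed=0)
        got = estimate_reflected_temperature(frame, FIXTURE_PLANCK, Rect(10, 10, 50, 50))
        assert got == pytest.approx(295.0, abs=0.01)  # count quantization only

    def test_noisy_panel_mean_within_three_sem(self):
        sd = 0.2
        frame = generate_panel_frame(295.0, noise_sd=sd, planck=FIXTURE_PLANCK, seed=42)
        roi = Rect(0, 0, 320, 240)
        got = estimate_reflected_temperature(frame, FIXTURE_PLANCK, roi)
        sem = sd / np.sqrt(roi.width * roi.height)
        assert abs(got - 295.0) < 3 * sem + 0.01

    def test_single_pixel_roi(self):
        raw = np.full((240, 320), 20000, np.uint16)
        frame = ThermalFrame(raw)
        got = estimate_reflected_temperature(frame, FIXTURE_PLANCK, Rect(5, 5, 1, 1))
        assert got == pytest.approx(raw_to_temperature(20000.0, FIXTURE_PLANCK), abs=1e-12)

    @pytest.mark.parametrize("roi", [Rect(300, 0, 40, 10), Rect(0, 0, 0, 5)])
    def test_invalid_roi_rejected(self, roi):
        frame = ThermalFrame(np.full((240, 320), 20000, np.uint16))
        with pytest.raises(RoiError):
            estimate_reflected_temperature(frame, FIXTURE_PLANCK, roi)
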
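"""Spectral processing operators: transform, phasing, baseline, FWQM
integration, and the stack → nLac pipeline."""

import numpy as np
import pytest
from scipy.integrate import quad

from hypermet.hp_mrs import (AcquisitionConfig, NLacPipelineConfig, Spectrum,
                             autophase, baseline_correct, compute_nlac,
                             estimate_noise_sd, fid_to_spectrum,
                             integrate_fwqm)
from hypermet.synthetic_data import (ExchangeParams, simulate_hp_dynamics,
                                     synthesize_fid_stack)


def lorentzian_spectrum(gamma=1.0, center=0.0, span=12.0, step=2e-4):
    ppm = np.arange(-span, span, step) + center
    real = (gamma / np.pi) / ((ppm - center) ** 2 + gamma ** 2)  # unit area
    return Spectrum(ppm, real, np.zeros_like(real))


# ----------------------------------------------------------- fid_to_spectrum

def test_on_resonance_peak_at_center(acq13c):
    t = acq13c.times()
    fid = np.exp(-t / 0.05)
    spec = fid_to_spectrum(fid, acq13c)
    apex = spec.ppm[np.argmax(spec.real)]
    assert apex == pytest.approx(acq13c.center_ppm, abs=0.05)


def test_offset_peak_displacement_matches_hz_to_ppm():
    """+1000 Hz offset at 75.515 MHz displaces the peak by 13.24 ppm."""
    acq = AcquisitionConfig()
    t = acq.times()
    fid = np.exp(2j * np.pi * 1000.0 * t) * np.exp(-t / 0.05)
    spec = fid_to_spectrum(fid, acq)
    apex = spec.ppm[np.argmax(spec.real)]
    assert apex - acq.center_ppm == pytest.approx(1000.0 / 75.515, abs=0.05)


def test_magnitude_integral_invariant_under_zero_fill(acq13c):
    t = acq13c.times()
    fid = np.exp(2j * np.pi * 300.0 * t) * np.exp(-t / 0.03)
    integrals = []
    for zf in (1, 2, 4):
        spec = fid_to_spectrum(fid, acq13c, zero_fill=zf)
        mag = np.hypot(spec.real, spec.imag)
        d = abs(spec.ppm[1] - spec.ppm[0])
        integrals.append(mag.sum() * d)
    assert np.allclose(integrals, integrals[0], rtol=1e-3)


def test_empty_fid_rejected(acq13c):
    with pytest.raises(ValueError):
        fid_to_spectrum(np.array([]), acq13c)


# ------------------------------------------------------------------ autophase

def _clean_two_peak_spectrum(acq):
    dyn = simulate_hp_dynamics(ExchangeParams(kpl=0.05), acq)
    stack = synthesize_fid_stack(dyn)
    return fid_to_spectrum(stack.data[3], acq, zero_fill=2)


def test_autophase_fixed_point(acq13c):
    spec = _clean_two_peak_spectrum(acq13c)
    _, (phi0, phi1) = autophase(spec)
    assert abs(phi0) <= 1.0
    assert abs(phi1) <= 0.1


def test_autophase_recovers_known_corruption(acq13c):
    """phi0 = 40°, phi1 = 10°/ppm corruption is inverted within 2°/0.5°."""
    spec = _clean_two_peak_spectrum(acq13c)
    pivot = 0.5 * (spec.ppm[0] + spec.ppm[-1])
    ramp = np.exp(1j * (np.deg2rad(40.0) +
                        np.deg2rad(10.0) * (spec.ppm - pivot)))
    corrupted = spec.complex * ramp
    bad = Spectrum(spec.ppm, corrupted.real, corrupted.imag)
    _, (phi0, phi1) = autophase(bad)
    assert phi0 == pytest.approx(40.0, abs=2.0)
    assert phi1 == pytest.approx(10.0, abs=0.5)


def test_autophase_resolves_sign_toward_positive_peak(acq13c):
    spec = _clean_two_peak_spectrum(acq13c)
    flipped = Spectrum(spec.ppm, -spec.real, -spec.imag)
    fixed, _ = autophase(flipped)
    assert fixed.real.max() > abs(fixed.real.min())


def test_autophase_all_zero_is_identity(acq13c):
    z = np.zeros(64)
    spec = Spectrum(np.linspace(0, 1, 64), z, z)
    with pytest.warns(UserWarning):
        fixed, (phi0, phi1) = autophase(spec)
    assert phi0 == 0.0 and phi1 == 0.0


# ------------------------------------------------------------------ baseline

def test_constant_offset_removed_exactly(acq13c):
    """Adding a flat offset changes the corrected output not at all: the
    polynomial fit absorbs the constant exactly (operator linearity)."""
    spec = _clean_two_peak_spectrum(acq13c)
    c = 25.0
    windows = [(165.0, 176.0), (178.0, 189.0)]
    ref = baseline_correct(spec, windows)
    shifted = Spectrum(spec.ppm, spec.real + c, spec.imag)
    fixed = baseline_correct(shifted, windows)
    assert np.abs(fixed.real - ref.real).max() <= 1e-9 * c


def test_cubic_drift_removed_areas_within_1pct(acq13c):
    spec = _clean_two_peak_spectrum(acq13c)
    ref_pyr = integrate_fwqm(spec, 171.0, 3.0, noise_sd=0.0)
    x = (spec.ppm - spec.ppm.mean()) / 30.0
    drift = 0.02 * spec.real.max() * (x ** 3 - 0.5 * x + 0.3)
    bad = Spectrum(spec.ppm, spec.real + drift, spec.imag)
    fixed = baseline_correct(bad, [(166.0, 176.0), (178.0, 188.0)])
    got = integrate_fwqm(fixed, 171.0, 3.0, noise_sd=0.0)
    assert got.area == pytest.approx(ref_pyr.area, rel=0.01)


def test_no_corruption_near_noop(acq13c):
    spec = _clean_two_peak_spectrum(acq13c)
    ref = integrate_fwqm(spec, 183.2, 3.0, noise_sd=0.0)
    fixed = baseline_correct(spec, [(166.0, 176.0), (178.0, 188.0)])
    got = integrate_fwqm(fixed, 183.2, 3.0, noise_sd=0.0)
    assert got.area == pytest.approx(ref.area, rel=0.005)


def test_overwide_exclusion_rejected(acq13c):
    spec = _clean_two_peak_spectrum(acq13c)
    with pytest.raises(ValueError):
        baseline_correct(spec, [(spec.ppm[0], spec.ppm[-1])])


# ------------------------------------------------------- FWQM integration

def test_lorentzian_quarter_max_fraction_is_two_thirds():
    """Quarter-max bounds of a Lorentzian sit at ±√3 γ and enclose exactly
    (2/π)·arctan(√3) = 2/3 of the total area."""
    gamma = 1.0
    spec = lorentzian_spectrum(gamma)
    pk = integrate_fwqm(spec, 0.0, 5.0, noise_sd=0.0)
    lo, hi = pk.bounds_ppm
    assert lo == pytest.approx(-np.sqrt(3) * gamma, abs=2e-3)
    assert hi == pytest.approx(np.sqrt(3) * gamma, abs=2e-3)
    assert pk.area == pytest.approx(2.0 / 3.0, abs=1e-6)


def test_gaussian_quarter_max_fraction_matches_quadrature():
    sigma = 1.0
    ppm = np.arange(-10, 10, 2e-4)
    real = np.exp(-ppm ** 2 / (2 * sigma ** 2)) / (sigma * np.sqrt(2 * np.pi))
    spec = Spectrum(ppm, real, np.zeros_like(real))
    pk = integrate_fwqm(spec, 0.0, 5.0, noise_sd=0.0)
    half = sigma * np.sqrt(2.0 * np.log(4.0))
    expected, _ = quad(
        lambda x: np.exp(-x ** 2 / 2) / np.sqrt(2 * np.pi), -half, half)
    assert pk.area == pytest.approx(expected, abs=1e-4)


def test_pure_noise_window_not_detected():
    rng = np.random.default_rng(7)
    ppm = np.linspace(-10, 10, 4096)
    real = rng.standard_normal(ppm.size)
    spec = Spectrum(ppm, real, np.zeros_like(real))
    pk = integrate_fwqm(spec, 0.0, 1.0, noise_floor_k=5.0, noise_sd=1.0)
    assert not pk.detected
    assert pk.area == 0.0


def test_search_window_outside_axis_rejected():
    spec = lorentzian_spectrum()
    with pytest.raises(ValueError):
        integrate_fwqm(spec, 100.0, 1.0)


# ----------------------------------------------------------------- pipeline

def test_noiseless_stack_recovers_truth(dynamics_default):
    stack = synthesize_fid_stack(dynamics_default)
    res = compute_nlac(stack)
    assert res.nlac == pytest.approx(dynamics_default.true_nlac, abs=1e-3)


def test_nlac_invariant_to_global_rescaling(dynamics_default):
    stack = synthesize_fid_stack(dynamics_default)
    res1 = compute_nlac(stack)
    stack.data = stack.data * 37.5
    res2 = compute_nlac(stack)
    assert res2.nlac == pytest.approx(res1.nlac, rel=1e-9)


def test_equal_areas_give_half(acq13c):
    amps = {"pyruvate": np.full(8, 2.0), "lactate": np.full(8, 2.0)}
    stack = synthesize_fid_stack(amps, acq=AcquisitionConfig(n_acq=8))
    res = compute_nlac(stack)
    assert res.nlac == pytest.approx(0.5, abs=0.01)


def test_summed_area_identity(dynamics_default):
    """The reported nLac is exactly the ratio formula applied to the
    per-acquisition bookkeeping."""
    stack = synthesize_fid_stack(dynamics_default)
    res = compute_nlac(stack)
    assert res.ap_total == pytest.approx(res.pyr_areas.sum(), rel=1e-12)
    assert res.nlac == pytest.approx(
        res.al_total / (res.al_total + res.ap_total), rel=1e-12)


def test_all_zero_stack_flagged_undefined(acq13c):
    acq = AcquisitionConfig(n_acq=4)
    amps = {"pyruvate": np.zeros(4), "lactate": np.zeros(4)}
    stack = synthesize_fid_stack(amps, acq=acq)
    res = compute_nlac(stack)
    assert res.undefined
    assert np.isnan(res.nlac)


def test_monotone_in_kpl_noiseless(acq13c):
    grid = [0.0, 0.02, 0.05, 0.1]
    est = []
    for k in grid:
        dyn = simulate_hp_dynamics(ExchangeParams(kpl=k), acq13c)
        est.append(compute_nlac(synthesize_fid_stack(dyn)).nlac)
    assert np.all(np.diff(est) >= 0)


def test_species_outside_window_rejected(acq13c, dynamics_default):
    from hypermet.synthetic_data import LineModel
    bad_lines = (LineModel("pyruvate", 171.0), LineModel("lactate", 300.0))
    with pytest.raises(ValueError, match="lactate"):
        synthesize_fid_stack(dynamics_default, lines=bad_lines)


def test_stack_reproducibility(dynamics_default):
    a = synthesize_fid_stack(dynamics_default, noise_sd=0.05, seed=11)
    b = synthesize_fid_stack(dynamics_default, noise_sd=0.05, seed=11)
    c = synthesize_fid_stack(dynamics_default, noise_sd=0.05, seed=12)
    assert np.array_equal(a.data, b.data)
    assert not np.array_equal(a.data, c.data)
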
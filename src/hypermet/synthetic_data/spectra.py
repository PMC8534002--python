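"""Forward models for synthetic spectra: dynamic ¹³C FID stacks and 1D ¹H
metabolite spectra with known ground truth.

Each spectral line is a complex Lorentzian FID component
``a · exp(i 2π Δf t − t / T2*)`` with ``T2* = 1/(π · hwhm)``; corruption
(zero/first-order phase errors, a polynomial baseline added in the
frequency domain, complex Gaussian noise in the time domain) is applied on
top so the correction operators in the processing modules are genuinely
exercised.  All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.fft import fft, fftshift, ifft, ifftshift

from ..hp_mrs import AcquisitionConfig, FidStack
from ..nmr_metabolomics import (DEFAULT_LIBRARY, DSS_ENTRY, H1_ACQ,
                                MetaboliteEntry)
from .exchange import HpDynamics

__all__ = ["LineModel", "synthesize_fid_stack", "synthesize_1h_spectrum",
           "HP_LINES"]


@dataclass(frozen=True)
class LineModel:
    """Spectral-line and corruption model for one species.

    The corruption fields (``phase0_deg``, ``phase1_deg_per_ppm``,
    ``baseline_coeffs``, ``noise_sd``) describe the *stack-wide* corruption;
    the synthesizer reads them from the first line unless overridden by an
    explicit argument.
    """

    species: str
    shift_ppm: float
    hwhm_hz: float = 8.0
    phase0_deg: float = 0.0
    phase1_deg_per_ppm: float = 0.0
    baseline_coeffs: tuple[float, ...] = ()
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.hwhm_hz <= 0:
            raise ValueError("hwhm_hz must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def t2_star(self) -> float:
        # Lorentzian HWHM gamma = 1/(2 pi T2*)
        return 1.0 / (2.0 * np.pi * self.hwhm_hz)


# Default ¹³C lines: literature-convention shifts for [1-¹³C]pyruvate and
# [1-¹³C]lactate (configurable; the choice only fixes where the peaks sit).
HP_LINES = (LineModel("pyruvate", 171.0), LineModel("lactate", 183.2))


def _corrupt_spectrum_domain(fid: np.ndarray, acq: AcquisitionConfig,
                             phase1_rad_per_ppm: float,
                             baseline_coeffs: tuple[float, ...]) -> np.ndarray:
    """Apply first-order phase and additive polynomial baseline in the
    frequency domain, returning the corrupted FID."""
    n = fid.size
    spec = fftshift(fft(fid))
    ppm = acq.ppm_axis(n)
    pivot = 0.5 * (ppm[0] + ppm[-1])
    if phase1_rad_per_ppm != 0.0:
        spec = spec * np.exp(1j * phase1_rad_per_ppm * (ppm - pivot))
    if baseline_coeffs:
        x = (ppm - pivot) / (abs(ppm[-1] - ppm[0]) / 2.0)
        spec = spec + np.polynomial.polynomial.polyval(x, baseline_coeffs)
    return ifft(ifftshift(spec))


def synthesize_fid_stack(dynamics: HpDynamics | dict[str, np.ndarray],
                         lines: tuple[LineModel, ...] = HP_LINES,
                         acq: AcquisitionConfig | None = None,
                         seed: int = 0,
                         noise_sd: float | None = None,
                         phase0_deg: float | None = None,
                         phase1_deg_per_ppm: float | None = None,
                         baseline_coeffs: tuple[float, ...] | None = None,
                         ) -> FidStack:
    """Render per-pulse species amplitudes into a corrupted FID stack.

    ``dynamics`` is either a :class:`HpDynamics` (species ``pyruvate`` /
    ``lactate`` drawn from ``amp_pyr`` / ``amp_lac``) or a plain mapping
    ``species -> per-acquisition amplitude array``.  Baseline coefficients
    are in units of the mean spectral magnitude so their visual severity is
    scale-free.  Same seed ⇒ bit-identical stack.
    """
    if isinstance(dynamics, HpDynamics):
        acq = dynamics.acq if acq is None else acq
        amp_map = {"pyruvate": dynamics.amp_pyr, "lactate": dynamics.amp_lac}
        truth_nlac = dynamics.true_nlac
    else:
        if acq is None:
            raise ValueError("acq is required when passing raw amplitudes")
        amp_map = {k: np.asarray(v, dtype=float) for k, v in dynamics.items()}
        tot = sum(v.sum() for v in amp_map.values())
        truth_nlac = (amp_map.get("lactate", np.zeros(1)).sum() / tot
                      if tot > 0 else float("nan"))

    ref = lines[0]
    noise_sd = ref.noise_sd if noise_sd is None else noise_sd
    phase0_deg = ref.phase0_deg if phase0_deg is None else phase0_deg
    phase1_deg_per_ppm = (ref.phase1_deg_per_ppm if phase1_deg_per_ppm is None
                          else phase1_deg_per_ppm)
    baseline_coeffs = (ref.baseline_coeffs if baseline_coeffs is None
                       else baseline_coeffs)

    half_sw_ppm = acq.sweep_width / 2.0 / acq.ref_freq
    t = acq.times()
    n_acq = next(iter(amp_map.values())).shape[0]
    rng = np.random.default_rng(seed)
    data = np.zeros((n_acq, acq.n_points), dtype=complex)

    comps = []
    for line in lines:
        if line.species not in amp_map:
            continue
        df = (line.shift_ppm - acq.center_ppm) * acq.ref_freq  # Hz
        if abs(df) > half_sw_ppm * acq.ref_freq:
            raise ValueError(
                f"species '{line.species}' at {line.shift_ppm} ppm falls "
                f"outside the spectral window")
        comps.append((line, amp_map[line.species],
                      np.exp((2j * np.pi * df - 1.0 / line.t2_star) * t)))

    for i in range(n_acq):
        fid = np.zeros(acq.n_points, dtype=complex)
        for line, amps, kernel in comps:
            fid += amps[i] * kernel
        fid *= np.exp(1j * np.deg2rad(phase0_deg))
        if phase1_deg_per_ppm or baseline_coeffs:
            scale = np.abs(fftshift(fft(fid))).mean() if baseline_coeffs else 1.0
            coeffs = tuple(c * scale for c in baseline_coeffs)
            fid = _corrupt_spectrum_domain(
                fid, acq, np.deg2rad(phase1_deg_per_ppm), coeffs)
        if noise_sd > 0:
            fid = fid + noise_sd * (rng.standard_normal(acq.n_points) +
                                    1j * rng.standard_normal(acq.n_points))
        data[i] = fid

    truth = {"nlac": truth_nlac, "amplitudes": amp_map, "lines": lines,
             "noise_sd": noise_sd, "phase0_deg": phase0_deg,
             "phase1_deg_per_ppm": phase1_deg_per_ppm,
             "baseline_coeffs": tuple(baseline_coeffs), "seed": seed}
    return FidStack(data, acq, truth=truth)


def synthesize_1h_spectrum(concentrations: dict[str, float],
                           tissue_mass_mg: float = 1.0,
                           dss_um: float = 500.0,
                           library: dict[str, MetaboliteEntry] = DEFAULT_LIBRARY,
                           noise_sd: float = 0.0,
                           seed: int = 0,
                           acq: AcquisitionConfig = H1_ACQ,
                           hwhm_hz: float = 0.3,
                           water_amp: float = 0.2,
                           phase0_deg: float = 0.0,
                           amp_per_um_proton: float = 1e-4,
                           ) -> tuple[np.ndarray, dict]:
    """Synthesize a 1D ¹H FID for a metabolite mixture plus DSS reference.

    Peak areas are proportional to concentration × proton count; the DSS
    trimethyl singlet (0 ppm, 9 H, ``dss_um`` µM) anchors the concentration
    scale, and a broad residual-water hump sits at the carrier.  Returns the
    FID and a truth record with the designed concentrations and the pool
    sizes (µM/mg) the quantification pipeline should recover.
    """
    unknown = sorted(set(concentrations) - set(library))
    if unknown:
        raise ValueError(
            f"unknown metabolite(s) {unknown}; library contains "
            f"{sorted(library)}")
    t = acq.times()
    fid = np.zeros(acq.n_points, dtype=complex)
    decay = np.exp(-t * 2.0 * np.pi * hwhm_hz)  # HWHM gamma = 1/(2 pi T2*)

    def add_entry(entry: MetaboliteEntry, conc_um: float) -> None:
        nonlocal fid
        for mult in entry.multiplets:
            offs = mult.shift_ppm + mult.component_offsets_ppm(acq.ref_freq)
            weights = mult.component_weights()
            total_amp = amp_per_um_proton * conc_um * mult.n_protons
            for o, w in zip(offs, weights):
                df = (o - acq.center_ppm) * acq.ref_freq
                fid = fid + (total_amp * w) * np.exp(2j * np.pi * df * t) * decay

    add_entry(DSS_ENTRY, dss_um)
    for name, conc in concentrations.items():
        add_entry(library[name], conc)
    # residual water: broad line at the carrier
    if water_amp > 0:
        fid = fid + (water_amp * amp_per_um_proton * dss_um * 9) * \
            np.exp(-t * 2.0 * np.pi * 8.0)
    if phase0_deg:
        fid = fid * np.exp(1j * np.deg2rad(phase0_deg))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fid = fid + noise_sd * (rng.standard_normal(acq.n_points) +
                                1j * rng.standard_normal(acq.n_points))
    truth = {"concentrations_um": dict(concentrations),
             "pool_um_per_mg": {k: v / tissue_mass_mg
                                for k, v in concentrations.items()},
             "tissue_mass_mg": tissue_mass_mg, "dss_um": dss_um,
             "noise_sd": noise_sd, "seed": seed}
    return fid, truth
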
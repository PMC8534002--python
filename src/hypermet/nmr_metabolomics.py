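"""Ex vivo ¹H-NMR metabolite quantification with a DSS internal standard.

A processed 1D ¹H spectrum is referenced to the DSS trimethyl singlet
(0 ppm, 9 protons, known solution concentration), library multiplets are
matched to picked peaks, and each metabolite's quantification multiplet is
integrated (FWQM, component by component).  Concentrations follow from the
proton-normalized area ratio to the internal standard,

    c_met [µM] = c_DSS [µM] · (A_met / N_met) / (A_DSS / 9),

and pool sizes are concentrations divided by the pulverized tissue mass,
reported in µM/mg.  Proton normalization (A/N) is applied explicitly: peak
area is proportional to concentration × number of equivalent protons, and
absolute concentrations are meaningless without dividing it back out.

The shipped library is a compact panel of metabolites prominent in brain
tumor extracts; each entry fixes one well-resolved quantification multiplet
(e.g. the alanine CH₃ doublet) to avoid overlap-prone regions.  The table
schema accepts arbitrary panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .hp_mrs import (AcquisitionConfig, Spectrum, autophase, baseline_correct,
                     estimate_noise_sd, fid_to_spectrum, integrate_fwqm)

__all__ = [
    "Multiplet", "MetaboliteEntry", "DEFAULT_LIBRARY", "H1_ACQ",
    "PoolSizeTable", "Assignment",
    "process_1h", "assign_peaks", "quantify",
]

# Default 1D 1H acquisition: 500 MHz spectrometer, 10240 Hz sweep, 32k
# complex points, carrier on water.  flip/tr/n_acq are immaterial for a
# single averaged spectrum but must satisfy the config invariants.
H1_ACQ = AcquisitionConfig(flip_angle=90.0, tr=7.0, n_acq=1, n_points=32768,
                           sweep_width=10240.0, ref_freq=500.0, center_ppm=4.7)


@dataclass(frozen=True)
class Multiplet:
    """One multiplet: center shift, multiplicity, J coupling, proton count.

    Component positions are ``shift + (k - (m-1)/2) * J / f0`` for
    k = 0..m-1 (J in Hz, f0 the spectrometer frequency in MHz, so J/f0 is
    the ppm spacing); component intensities follow Pascal's triangle.
    """

    shift_ppm: float
    multiplicity: int = 1
    j_hz: float = 0.0
    n_protons: int = 1

    def __post_init__(self) -> None:
        if self.n_protons < 1:
            raise ValueError("n_protons must be >= 1")
        if not 0.0 <= self.shift_ppm <= 10.0:
            raise ValueError("shift must lie within 0-10 ppm")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")

    def component_offsets_ppm(self, ref_freq_mhz: float) -> np.ndarray:
        m = self.multiplicity
        k = np.arange(m) - (m - 1) / 2.0
        return k * self.j_hz / ref_freq_mhz

    def component_weights(self) -> np.ndarray:
        m = self.multiplicity
        w = np.array([float(comb(m - 1, k)) for k in range(m)])
        return w / w.sum()


@dataclass(frozen=True)
class MetaboliteEntry:
    name: str
    multiplets: tuple[Multiplet, ...]
    quantification_multiplet: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.quantification_multiplet < len(self.multiplets):
            raise ValueError("quantification_multiplet index out of range")

    @property
    def quant(self) -> Multiplet:
        return self.multiplets[self.quantification_multiplet]


def _entry(name, multiplets, quant=0):
    return MetaboliteEntry(name, tuple(Multiplet(*m) for m in multiplets), quant)


# Literature chemical shifts (D2O, pH ~7).  Quantification multiplets chosen
# for isolation; upfield methyls for the amino acids, the N-trimethyl
# singlets for the cholines, aromatic H for NAD+.
DEFAULT_LIBRARY: dict[str, MetaboliteEntry] = {e.name: e for e in [
    _entry("alanine", [(1.48, 2, 7.2, 3), (3.78, 4, 7.2, 1)], quant=0),
    _entry("lactate", [(1.33, 2, 7.0, 3), (4.11, 4, 7.0, 1)], quant=0),
    _entry("glycine", [(3.56, 1, 0.0, 2)]),
    _entry("valine", [(0.99, 2, 7.0, 3), (1.04, 2, 7.0, 3)], quant=0),
    _entry("phosphocholine", [(3.221, 1, 0.0, 9)]),
    _entry("glycerophosphocholine", [(3.232, 1, 0.0, 9)]),
    _entry("phosphoethanolamine", [(3.98, 1, 0.0, 2)]),
    _entry("glutathione", [(2.95, 1, 0.0, 2)]),
    _entry("nad+", [(9.33, 1, 0.0, 1)]),
    _entry("creatine", [(3.03, 1, 0.0, 3), (3.93, 1, 0.0, 2)], quant=0),
]}

DSS_ENTRY = _entry("dss", [(0.0, 1, 0.0, 9)])


@dataclass
class Assignment:
    """One library entry matched against the picked peaks of a spectrum."""

    name: str
    entry: MetaboliteEntry
    matched_ppm: tuple[tuple[float, ...], ...]   # per multiplet, per component
    found_fraction: float
    overlap: bool = False


@dataclass
class PoolSizeTable:
    """Quantification result: per-metabolite areas, DSS-normalized areas,
    concentrations (µM) and pool sizes (µM/mg), with reference bookkeeping."""

    table: pd.DataFrame
    dss_area: float
    dss_um: float
    tissue_mass_mg: float

    def pool(self, name: str) -> float:
        return float(self.table.set_index("metabolite")
                     .loc[name, "pool_um_per_mg"])


def process_1h(fid: np.ndarray, acq: AcquisitionConfig = H1_ACQ,
               line_broaden_hz: float = 0.1,
               water_window: tuple[float, float] = (4.5, 5.0),
               dss_search_ppm: float = 0.3,
               zero_fill: int = 4) -> Spectrum:
    """Process a 1D ¹H FID into a referenced absorption spectrum.

    Exponential apodization, zero-filled DFT, automatic phasing and
    polynomial baseline correction (water region excluded from the fit),
    then chemical-shift referencing: the tallest peak within
    ±``dss_search_ppm`` of 0 ppm is taken as the DSS singlet and the axis is
    shifted so its (parabolically interpolated) apex sits at exactly 0 ppm.
    """
    spec = fid_to_spectrum(fid, acq, line_broaden_hz, zero_fill)
    # zero-order phasing only, estimated on the DSS singlet: a pulse-acquire
    # 1H spectrum with a short dead time needs no first-order term, and the
    # reference singlet is isolated by construction — estimating the phase
    # on a multiplet component would inherit its twin's dispersion tail and
    # bias the whole spectrum by several degrees.
    spec, _ = autophase(spec, phi1_span_deg_per_ppm=0.0,
                        peak_windows=[(-dss_search_ppm - 0.05,
                                       dss_search_ppm + 0.05)])
    spec = baseline_correct(spec, [water_window])

    ppm = spec.ppm
    sel = np.where((ppm >= -dss_search_ppm) & (ppm <= dss_search_ppm))[0]
    if sel.size == 0:
        raise ValueError("reference not found: 0 ppm outside spectral window")
    noise = estimate_noise_sd(spec, avoid_ppm=(0.0, 1.3, 3.2))
    i = int(sel[np.argmax(spec.real[sel])])
    # 8 sigma floor: autophasing rotates the largest noise excursion
    # positive, so a pure-noise window can masquerade at ~4-5 sigma
    if noise > 0 and spec.real[i] < 8.0 * noise:
        raise ValueError("reference not found: no peak in DSS search window")
    # parabolic apex refinement
    apex = ppm[i]
    if 0 < i < ppm.size - 1:
        y0, y1, y2 = spec.real[i - 1:i + 2]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            apex = ppm[i] + 0.5 * (y0 - y2) / denom * (ppm[i] - ppm[i - 1])
    out = Spectrum(ppm - apex, spec.real.copy(), spec.imag.copy(),
                   dict(spec.meta))
    out.meta["reference_shift_ppm"] = float(apex)
    return out


def _pick_peaks(spec: Spectrum, snr_min: float) -> np.ndarray:
    """Positions (ppm) of local maxima of the real part above the noise."""
    y = spec.real
    noise = estimate_noise_sd(spec, avoid_ppm=(0.0, 1.3, 3.2))
    # relative floor guards the noiseless case, where numerical ripple
    # would otherwise qualify as peaks everywhere
    floor = max(snr_min * noise, 1e-3 * float(y.max(initial=0.0)))
    idx = np.where((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:]) &
                   (y[1:-1] > floor))[0] + 1
    ppm = spec.ppm
    pos = []
    for i in idx:
        y0, y1, y2 = y[i - 1], y[i], y[i + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        pos.append(ppm[i] + shift * (ppm[i] - ppm[i - 1]))
    return np.asarray(pos)


def assign_peaks(spec: Spectrum,
                 library: dict[str, MetaboliteEntry] = DEFAULT_LIBRARY,
                 tol_ppm: float = 0.02,
                 min_component_fraction: float = 1.0,
                 snr_min: float = 3.0) -> list[Assignment]:
    """Match library multiplets to picked peaks.

    An entry is assigned when at least ``min_component_fraction`` of all its
    expected multiplet components are found within ``tol_ppm`` of a picked
    peak.  Peaks claimed by more than one entry flag the affected
    assignments as overlapping (both are reported).
    """
    acq = spec.meta.get("acq", H1_ACQ)
    f0 = acq.ref_freq
    peaks = _pick_peaks(spec, snr_min)
    claimed: dict[float, list[str]] = {}
    assignments: list[Assignment] = []
    for name, entry in library.items():
        per_mult: list[tuple[float, ...]] = []
        n_expected = 0
        n_found = 0
        used: list[float] = []
        for mult in entry.multiplets:
            comps = mult.shift_ppm + mult.component_offsets_ppm(f0)
            hits = []
            for c in comps:
                n_expected += 1
                if peaks.size:
                    j = int(np.argmin(np.abs(peaks - c)))
                    if abs(peaks[j] - c) <= tol_ppm:
                        hits.append(float(peaks[j]))
                        used.append(float(peaks[j]))
                        n_found += 1
            per_mult.append(tuple(hits))
        frac = n_found / n_expected if n_expected else 0.0
        if frac >= min_component_fraction and n_expected > 0:
            a = Assignment(name, entry, tuple(per_mult), frac)
            assignments.append(a)
            for p in used:
                claimed.setdefault(round(p, 4), []).append(name)
    shared = {p for p, names in claimed.items() if len(names) > 1}
    for a in assignments:
        a.overlap = any(round(p, 4) in shared
                        for mult in a.matched_ppm for p in mult)
    return assignments


def quantify(assignments: list[Assignment], spec: Spectrum,
             dss_um: float = 500.0, tissue_mass_mg: float = 1.0,
             noise_floor_k: float = 3.0) -> PoolSizeTable:
    """Convert assigned multiplet areas into concentrations and pool sizes.

    The DSS singlet at 0 ppm (9 protons) provides the concentration
    reference; each metabolite's quantification multiplet is integrated
    component by component between FWQM crossings (bounds truncated halfway
    toward the neighboring component so resolved multiplet lines do not
    bleed into one another).  Identical FWQM conventions for analyte and
    reference make the captured-area fraction cancel in the ratio.
    """
    if tissue_mass_mg <= 0:
        raise ValueError("tissue_mass_mg must be > 0")
    acq = spec.meta.get("acq", H1_ACQ)
    f0 = acq.ref_freq
    noise = estimate_noise_sd(spec, avoid_ppm=(0.0, 1.3, 3.2))

    dss = integrate_fwqm(spec, 0.0, 0.05, noise_floor_k, noise, "dss")
    if dss.area <= 0:
        raise ValueError("DSS reference area is non-positive")

    rows = []
    for a in assignments:
        if a.name == "dss":
            continue
        mult = a.entry.quant
        comps = mult.shift_ppm + mult.component_offsets_ppm(f0)
        matched = a.matched_ppm[a.entry.quantification_multiplet]
        centers = np.asarray(matched if len(matched) == len(comps) else comps)
        area = 0.0
        spacing = (mult.j_hz / f0) if mult.multiplicity > 1 else None
        # tight apex search window: the component position is already known
        # from assignment, so only sub-linewidth refinement is needed and a
        # wide window would lock onto taller neighbors
        half = 0.005 if spacing is None else min(0.005, spacing / 2.0)
        for c in centers:
            lim = (c - spacing / 2.0, c + spacing / 2.0) \
                if spacing is not None else (None, None)
            pk = integrate_fwqm(spec, float(c), half, noise_floor_k, noise,
                                a.name, lim)
            area += pk.area
        area_norm = (area / mult.n_protons) / (dss.area / 9.0)
        conc_um = dss_um * area_norm
        rows.append({"metabolite": a.name, "area": area,
                     "area_norm": area_norm, "conc_um": conc_um,
                     "pool_um_per_mg": conc_um / tissue_mass_mg})
    table = pd.DataFrame(rows, columns=["metabolite", "area", "area_norm",
                                        "conc_um", "pool_um_per_mg"])
    return PoolSizeTable(table, dss.area, dss_um, tissue_mass_mg)
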
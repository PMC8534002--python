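"""Two-pool pyruvate→lactate exchange under repeated small-flip sampling.

The ground-truth forward model for the dynamic ¹³C experiment: injected
hyperpolarized pyruvate magnetization converts unidirectionally to lactate
at apparent rate ``kpl`` while both pools relax with their own T1.  Between
excitations

    dMp/dt = R(t) - (1/T1p + kpl) Mp
    dMl/dt = kpl Mp - Ml/T1l

with R(t) an optional boxcar infusion (``m0 / bolus_duration`` over
``[0, bolus_duration]``; the default instantaneous bolus puts ``m0`` in the
pyruvate pool at t = 0).  The system is solved in closed form between
pulses.  Each excitation samples ``Mz sin(alpha)`` into the transverse plane
and leaves ``Mz cos(alpha)`` behind; hyperpolarized magnetization is never
re-established, so the readout itself depletes the pools.

The true normalized-lactate value of a simulated experiment is the summed
sampled-amplitude ratio  ΣA_lac / (ΣA_lac + ΣA_pyr) over all acquisitions —
the same functional the spectral pipeline estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..hp_mrs import AcquisitionConfig

__all__ = ["ExchangeParams", "HpDynamics", "simulate_hp_dynamics"]


@dataclass(frozen=True)
class ExchangeParams:
    """Kinetic parameters of the two-pool exchange model.

    kpl             apparent pyruvate→lactate conversion rate (1/s)
    t1_pyr, t1_lac  longitudinal relaxation times (s); defaults are plausible
                    in vivo values for [1-¹³C]pyruvate/lactate at 7 T and are
                    model assumptions, not measured quantities
    m0              initial pyruvate magnetization (arbitrary units)
    bolus_duration  boxcar arrival window (s); 0 = instantaneous bolus
    """

    kpl: float = 0.05
    t1_pyr: float = 43.0
    t1_lac: float = 33.0
    m0: float = 1.0
    bolus_duration: float = 0.0

    def __post_init__(self) -> None:
        if self.kpl < 0:
            raise ValueError("kpl must be >= 0")
        if self.t1_pyr <= 0 or self.t1_lac <= 0:
            raise ValueError("t1_pyr and t1_lac must be > 0")
        if self.m0 <= 0:
            raise ValueError("m0 must be > 0")
        if self.bolus_duration < 0:
            raise ValueError("bolus_duration must be >= 0")


@dataclass
class HpDynamics:
    """Ground-truth magnetization trajectory of one simulated experiment."""

    times: np.ndarray        # pulse times (s)
    mz_pyr: np.ndarray       # longitudinal Mz just before each pulse
    mz_lac: np.ndarray
    amp_pyr: np.ndarray      # sampled transverse amplitudes Mz sin(alpha)
    amp_lac: np.ndarray
    true_nlac: float
    params: ExchangeParams
    acq: AcquisitionConfig

    @property
    def auc_pyr(self) -> float:
        return float(self.amp_pyr.sum())

    @property
    def auc_lac(self) -> float:
        return float(self.amp_lac.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.times,
            "mz_pyr": self.mz_pyr, "mz_lac": self.mz_lac,
            "amp_pyr": self.amp_pyr, "amp_lac": self.amp_lac,
        })


def simulate_hp_dynamics(params: ExchangeParams,
                         acq: AcquisitionConfig) -> HpDynamics:
    """Simulate the sampled two-pool exchange experiment (deterministic).

    Pulses occur at t = 0, TR, 2 TR, …  Magnetization is propagated in
    closed form between pulses (with the boxcar-infusion boundary split into
    its own sub-interval); each pulse records the pre-pulse Mz of both pools,
    emits ``Mz sin(alpha)``, and scales Mz by ``cos(alpha)``.
    """
    kpl = params.kpl
    lam_p = 1.0 / params.t1_pyr + kpl
    lam_l = 1.0 / params.t1_lac
    sin_a = np.sin(np.deg2rad(acq.flip_angle))
    cos_a = np.cos(np.deg2rad(acq.flip_angle))

    def step(mp: float, ml: float, t0: float, t1: float) -> tuple[float, float]:
        """Advance (mp, ml) from t0 to t1, honoring the infusion window."""
        if t1 <= t0:
            return mp, ml
        if params.bolus_duration > 0 and t0 < params.bolus_duration:
            t_mid = min(t1, params.bolus_duration)
            rate = params.m0 / params.bolus_duration
            mp, ml = _closed_form(mp, ml, t_mid - t0, rate, kpl, lam_p, lam_l)
            t0 = t_mid
        if t1 > t0:
            mp, ml = _closed_form(mp, ml, t1 - t0, 0.0, kpl, lam_p, lam_l)
        return mp, ml

    if params.bolus_duration == 0:
        mp, ml = params.m0, 0.0
    else:
        mp, ml = 0.0, 0.0

    n = acq.n_acq
    times = np.arange(n) * acq.tr
    mz_p = np.empty(n)
    mz_l = np.empty(n)
    t_prev = 0.0
    for i, t in enumerate(times):
        mp, ml = step(mp, ml, t_prev, t)
        mz_p[i], mz_l[i] = mp, ml
        mp *= cos_a
        ml *= cos_a
        t_prev = t

    amp_p = mz_p * sin_a
    amp_l = mz_l * sin_a
    total = amp_p.sum() + amp_l.sum()
    true_nlac = float(amp_l.sum() / total) if total > 0 else float("nan")
    return HpDynamics(times, mz_p, mz_l, amp_p, amp_l, true_nlac, params, acq)


def _closed_form(mp0: float, ml0: float, dt: float, rate: float,
                 kpl: float, lam_p: float, lam_l: float) -> tuple[float, float]:
    """Exact solution over ``dt`` with constant infusion ``rate`` into the
    pyruvate pool.  Handles the degenerate lam_p == lam_l case by limit."""
    ep = np.exp(-lam_p * dt)
    el = np.exp(-lam_l * dt)
    mp_inf = rate / lam_p
    mp = mp_inf + (mp0 - mp_inf) * ep
    # lactate: ml' = kpl mp(t) - lam_l ml
    # mp(t) = mp_inf + (mp0 - mp_inf) e^{-lam_p t}
    const_part = kpl * mp_inf / lam_l * (1.0 - el)
    dlam = lam_l - lam_p
    if abs(dlam) > 1e-12 * max(lam_l, lam_p, 1.0):
        trans_part = kpl * (mp0 - mp_inf) * (ep - el) / dlam
    else:
        trans_part = kpl * (mp0 - mp_inf) * dt * ep
    ml = ml0 * el + const_part + trans_part
    return float(mp), float(ml)
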
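"""Synthetic longitudinal cohorts with known ground truth.

The cohort generator emulates the three-arm study design the rest of the
package analyzes: control mice with flat normalized lactate (nLac),
untreated tumor-bearing mice whose mean nLac rises linearly through tumor
development, and irradiated mice whose nLac falls through regression and
then rises again with a development-like slope through recurrence.  Tumor
volumes follow log-linear (piecewise-exponential) trajectories, metabolite
pools piecewise-linear ones.  Per-subject random intercepts and residual
noise are Gaussian; death times come from a per-arm survival rule and are
administratively censored at the study endpoint; measurements after death
are absent.

The default designs encode the study conditions: development slope
0.0069/day anchored at 0.45 on Day 34, flat control mean 0.26, treated
regression to 71% of the post-treatment baseline followed by a 0.0067/day
recurrence slope, Day 94 censoring, and survival arms with median death
times of 34 (untreated) vs 88 (treated) days.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PiecewiseLinear", "LogLinear", "LogNormalSurvival", "ThresholdSurvival",
    "ArmDesign", "CohortDesign", "CohortTable",
    "simulate_cohort", "default_study_design", "default_survival_design",
    "make_ellipsoid_masks",
]


@dataclass(frozen=True)
class PiecewiseLinear:
    """Piecewise-linear mean trajectory through (day, value) knots."""

    knots: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        days = [d for d, _ in self.knots]
        if len(days) < 1 or any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("knot days must be strictly increasing")

    def at(self, day) -> np.ndarray:
        d = np.asarray([k[0] for k in self.knots], dtype=float)
        v = np.asarray([k[1] for k in self.knots], dtype=float)
        return np.interp(np.asarray(day, dtype=float), d, v)


@dataclass(frozen=True)
class LogLinear:
    """Piecewise-exponential trajectory: linear interpolation in log space."""

    knots: tuple[tuple[float, float], ...]

    def at(self, day) -> np.ndarray:
        d = np.asarray([k[0] for k in self.knots], dtype=float)
        v = np.asarray([k[1] for k in self.knots], dtype=float)
        if np.any(v <= 0):
            raise ValueError("log-linear knots require positive values")
        return np.exp(np.interp(np.asarray(day, dtype=float), d, np.log(v)))


@dataclass(frozen=True)
class LogNormalSurvival:
    """Death times log-normal around a designed median (days)."""

    median_days: float
    sigma: float = 0.3

    def draw(self, rng: np.random.Generator, baseline_value: float) -> float:
        return float(self.median_days *
                     np.exp(self.sigma * rng.standard_normal()))


@dataclass(frozen=True)
class ThresholdSurvival:
    """Trajectory-linked rule: a subject whose baseline biomarker exceeds
    ``cutoff`` dies before the endpoint with probability ``p_death_above``
    (``p_death_below`` otherwise), at a uniform time in ``death_window``."""

    cutoff: float = 0.4
    p_death_above: float = 5.0 / 7.0
    p_death_below: float = 0.0
    death_window: tuple[float, float] = (48.0, 93.0)

    def draw(self, rng: np.random.Generator, baseline_value: float) -> float:
        p = self.p_death_above if baseline_value > self.cutoff \
            else self.p_death_below
        if rng.random() < p:
            lo, hi = self.death_window
            return float(rng.uniform(lo, hi))
        return float("inf")


@dataclass(frozen=True)
class ArmDesign:
    label: str
    n_subjects: int
    days: tuple[float, ...]
    nlac: PiecewiseLinear | None = None
    volume: LogLinear | None = None
    pools: dict | None = None            # metabolite -> PiecewiseLinear
    survival: object | None = None       # LogNormalSurvival | ThresholdSurvival

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        d = self.days
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("measurement days must be strictly increasing")


@dataclass(frozen=True)
class CohortDesign:
    arms: tuple[ArmDesign, ...]
    subject_sd: float = 0.0
    residual_sd: float = 0.0
    endpoint_day: float = 94.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subject_sd < 0 or self.residual_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        max_day = max((max(a.days) for a in self.arms if a.days), default=0.0)
        if self.endpoint_day < max_day:
            raise ValueError("endpoint_day must cover all measurement days")


@dataclass
class CohortTable:
    """Tidy long-format measurements plus a per-subject survival table."""

    measurements: pd.DataFrame   # subject, arm, day, nlac, volume, pool_*
    survival: pd.DataFrame       # subject, arm, time, event
    design: CohortDesign


def simulate_cohort(design: CohortDesign) -> CohortTable:
    """Draw one cohort realization.  Same seed ⇒ identical tables; with
    ``subject_sd = residual_sd = 0`` the per-day arm means equal the design
    trajectories exactly."""
    rng = np.random.default_rng(design.seed)
    meas_rows = []
    surv_rows = []
    for arm in design.arms:
        for s in range(arm.n_subjects):
            subject = f"{arm.label}-{s + 1:02d}"
            intercept = design.subject_sd * rng.standard_normal()
            vol_factor = np.exp(design.subject_sd * rng.standard_normal()) \
                if arm.volume is not None else 1.0

            baseline = (float(arm.nlac.at(arm.days[0])) + intercept
                        if arm.nlac is not None and arm.days else 0.0)
            if arm.survival is not None:
                death = arm.survival.draw(rng, baseline)
            else:
                death = float("inf")
            time = min(death, design.endpoint_day)
            event = 1 if death <= design.endpoint_day else 0
            surv_rows.append({"subject": subject, "arm": arm.label,
                              "time": time, "event": event})

            for day in arm.days:
                if day >= death:
                    continue  # no measurements after death
                row = {"subject": subject, "arm": arm.label, "day": day}
                if arm.nlac is not None:
                    row["nlac"] = (float(arm.nlac.at(day)) + intercept +
                                   design.residual_sd * rng.standard_normal())
                if arm.volume is not None:
                    row["volume_mm3"] = (float(arm.volume.at(day)) * vol_factor
                                         * np.exp(design.residual_sd *
                                                  rng.standard_normal()))
                if arm.pools:
                    for met, traj in arm.pools.items():
                        row[f"pool_{met}"] = (float(traj.at(day)) + intercept +
                                              design.residual_sd *
                                              rng.standard_normal())
                meas_rows.append(row)
    measurements = pd.DataFrame(meas_rows)
    survival = pd.DataFrame(surv_rows)
    return CohortTable(measurements, survival, design)


def default_study_design(subject_sd: float = 0.0, residual_sd: float = 0.0,
                         seed: int = 0) -> CohortDesign:
    """The three-arm measurement design with the study's stated trajectory
    parameters (see module docstring)."""
    dev_days = (5.0, 7.0, 10.0, 14.0, 21.0, 28.0, 34.0)
    # development: slope 0.0069/day reaching 0.45 on Day 34
    dev_b = 0.45 - 0.0069 * 34.0
    untreated = ArmDesign(
        "untreated", 5, dev_days,
        nlac=PiecewiseLinear(((0.0, dev_b), (34.0, 0.45))),
        volume=LogLinear(((5.0, 1.4), (34.0, 88.6))),
        pools={"alanine": PiecewiseLinear(((0.0, 1.5), (34.0, 4.8)))})
    control = ArmDesign(
        "control", 3, dev_days,
        nlac=PiecewiseLinear(((0.0, 0.26), (34.0, 0.26))),
        pools={"alanine": PiecewiseLinear(((0.0, 1.5), (34.0, 1.5)))})
    # treated: baseline 0.44 on Day 28, regression to 71% of baseline by
    # Day 48, then recurrence slope 0.0067/day
    base = 0.44
    trough = 0.71 * base
    treated = ArmDesign(
        "treated", 10, (28.0, 34.0, 41.0, 48.0, 55.0, 62.0, 68.0, 72.0),
        nlac=PiecewiseLinear(((28.0, base), (48.0, trough),
                              (72.0, trough + 0.0067 * 24.0))),
        volume=LogLinear(((28.0, 40.0), (34.0, 82.9), (48.0, 57.3),
                          (72.0, 72.3))),
        pools={"alanine": PiecewiseLinear(((28.0, 4.0), (48.0, 2.0)))})
    return CohortDesign((control, untreated, treated),
                        subject_sd=subject_sd, residual_sd=residual_sd,
                        endpoint_day=94.0, seed=seed)


def default_survival_design(seed: int = 0) -> CohortDesign:
    """Survival-only design at the full study scale: 102 untreated vs 59
    treated tumor-bearing mice, log-normal death times, administrative
    censoring at Day 94.

    The medians (34 and 88 days) and the arm spreads are the design
    conditions; the sigmas are calibrated once so the two-arm Kaplan–Meier
    analysis of this family reproduces both the designed medians and a
    logrank O/E hazard ratio near 4.6 — i.e. curve *shapes*, not just
    locations, are part of the design.
    """
    untreated = ArmDesign("untreated", 102, (1.0,),
                          survival=LogNormalSurvival(34.0, 0.58))
    treated = ArmDesign("treated", 59, (1.0,),
                        survival=LogNormalSurvival(88.0, 0.30))
    return CohortDesign((untreated, treated), endpoint_day=94.0, seed=seed)


def make_ellipsoid_masks(semi_axes_mm: tuple[float, float, float],
                         in_plane_spacing_mm: tuple[float, float] = (25.0 / 256,
                                                                     25.0 / 192),
                         slice_thickness_mm: float = 0.75,
                         slice_gap_mm: float = 0.25,
                         margin_mm: float = 2.0):
    """Voxelize one ellipsoid into coronal/sagittal/axial plane stacks.

    Returns a list of three :class:`~hypermet.volumetrics.PlaneMask`
    objects whose plane-averaged volume approximates the analytic
    4/3·π·abc of the ellipsoid.  The slice axis cycles through the three
    anatomical orientations; voxel centers sample the implicit surface.
    """
    from ..volumetrics import PlaneMask

    a, b, c = semi_axes_mm
    dz = slice_thickness_mm + slice_gap_mm
    dr, dc = in_plane_spacing_mm
    masks = []
    # axis order per plane: which semi-axis lies along (slice, row, col)
    orders = {"coronal": (0, 1, 2), "sagittal": (1, 2, 0), "axial": (2, 0, 1)}
    semis = np.array([a, b, c])
    for label, order in orders.items():
        sa = semis[list(order)]
        n_sl = int(np.ceil(2 * (sa[0] + margin_mm) / dz))
        n_r = int(np.ceil(2 * (sa[1] + margin_mm) / dr))
        n_c = int(np.ceil(2 * (sa[2] + margin_mm) / dc))
        z = (np.arange(n_sl) - (n_sl - 1) / 2) * dz
        r = (np.arange(n_r) - (n_r - 1) / 2) * dr
        cc = (np.arange(n_c) - (n_c - 1) / 2) * dc
        zz, rr, ccg = np.meshgrid(z, r, cc, indexing="ij")
        mask = ((zz / sa[0]) ** 2 + (rr / sa[1]) ** 2 +
                (ccg / sa[2]) ** 2) <= 1.0
        masks.append(PlaneMask(mask, (dr, dc), slice_thickness_mm,
                               slice_gap_mm, label))
    return masks
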
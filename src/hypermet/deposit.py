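"""Recompute the headline longitudinal statistics from the study's
deposited measurement tables.

The deposited dataset (tumor volume, nLac, metabolite pool size and protein
expression values per mouse per day) is not redistributed with this
package; point :func:`reproduce_from_deposit` at a local copy exported to
tidy CSV.  Expected layout under ``deposit_dir``:

    nlac.csv     columns: group (control|untreated|treated), day, value[, subject]
    volume.csv   columns: group, day, value[, subject]

The function recomputes, through the package's own statistics layer, the
development-stage nLac slope (untreated, regression on per-day means), the
control-arm mean nLac, the recurrence-stage slope (treated, Days 48–68),
the Day-34 untreated mean nLac, and the exponential growth fit of untreated
tumor volume.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .stats_longitudinal import GroupSeries, exp_growth_fit, slope_fit

__all__ = ["reproduce_from_deposit"]


def reproduce_from_deposit(deposit_dir) -> dict[str, float]:
    deposit_dir = Path(deposit_dir)
    nlac_path = deposit_dir / "nlac.csv"
    if not nlac_path.exists():
        raise FileNotFoundError(
            f"deposited nLac table not found at {nlac_path}; export the "
            "deposited per-mouse values to CSV (columns: group, day, value)")
    nlac = pd.read_csv(nlac_path)
    out: dict[str, float] = {}

    untreated = GroupSeries(nlac[nlac["group"] == "untreated"])
    dev = slope_fit(untreated, day_range=(1.0, 34.0))
    out["development_slope_per_day"] = dev.slope
    out["development_slope_p"] = dev.p

    control = nlac[nlac["group"] == "control"]
    out["control_mean_nlac"] = float(control["value"].mean())

    treated = GroupSeries(nlac[nlac["group"] == "treated"])
    rec = slope_fit(treated, day_range=(48.0, 68.0))
    out["recurrence_slope_per_day"] = rec.slope

    day34 = nlac[(nlac["group"] == "untreated") & (nlac["day"] == 34)]
    if not day34.empty:
        out["untreated_nlac_day34"] = float(day34["value"].mean())

    vol_path = deposit_dir / "volume.csv"
    if vol_path.exists():
        vol = pd.read_csv(vol_path)
        u = vol[vol["group"] == "untreated"]
        means = u.groupby("day")["value"].mean()
        fit = exp_growth_fit(means.index.to_numpy(), means.to_numpy())
        out["volume_growth_rate_per_day"] = fit.rate
        out["volume_growth_r2"] = fit.r2
    return out
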
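"""Simulate dynamic hyperpolarized ¹³C experiments across a grid of
conversion rates and recover nLac through the full spectral pipeline.

Writes results/nlac_grid.csv and results/nlac_dynamics.png.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from hypermet.hp_mrs import AcquisitionConfig, compute_nlac
from hypermet.synthetic_data import (ExchangeParams, simulate_hp_dynamics,
                                     synthesize_fid_stack)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

acq = AcquisitionConfig()
rows = []
fig, axes = plt.subplots(1, 2, figsize=(10, 4))
for kpl in (0.0, 0.01, 0.02, 0.05, 0.1):
    dyn = simulate_hp_dynamics(ExchangeParams(kpl=kpl), acq)
    stack = synthesize_fid_stack(dyn, seed=1)
    res = compute_nlac(stack)
    rows.append({"kpl_per_s": kpl, "true_nlac": dyn.true_nlac,
                 "estimated_nlac": res.nlac,
                 "abs_error": abs(res.nlac - dyn.true_nlac)})
    if kpl == 0.05:
        axes[0].plot(dyn.times, dyn.amp_pyr, label="pyruvate")
        axes[0].plot(dyn.times, dyn.amp_lac, label="lactate")
        axes[0].set(xlabel="time (s)", ylabel="sampled amplitude",
                    title=f"two-pool dynamics, kPL = {kpl}/s")
        axes[0].legend()

table = pd.DataFrame(rows)
table.to_csv(OUT / "nlac_grid.csv", index=False)
axes[1].plot(table.kpl_per_s, table.true_nlac, "o-", label="ground truth")
axes[1].plot(table.kpl_per_s, table.estimated_nlac, "s--",
             label="spectral estimate")
axes[1].set(xlabel="kPL (1/s)", ylabel="nLac", title="estimator fidelity")
axes[1].legend()
fig.tight_layout()
fig.savefig(OUT / "nlac_dynamics.png", dpi=120)

print(table.to_string(index=False))
print(f"\nMax |error| over the grid: {table.abs_error.max():.2e} "
      "(noiseless stacks, 60 spectra each); nLac is monotone in kPL: "
      f"{bool((table.estimated_nlac.diff().dropna() >= 0).all())}")
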
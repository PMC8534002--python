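"""Measure background-subtracted DAB percent area on synthetic H-DAB
scenes with known positive fraction.

Writes results/ihc_recovery.csv and results/ihc_scene.png.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from hypermet.ihc_quant import measure_expression
from hypermet.io import save_image
from hypermet.synthetic_data import IhcScene, synthesize_ihc_image

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rows = []
for pf in (0.0, 0.1, 0.3, 0.5, 1.0):
    scene = IhcScene(positive_fraction=pf, seed=7)
    img, truth = synthesize_ihc_image(scene)
    res = measure_expression(img, truth["tumor_mask"], seed=11)
    rows.append({"designed_pct": 100 * pf,
                 "measured_pct": res.image_metric,
                 "background_pct": res.background_percent})
    if pf == 0.3:
        save_image(img, OUT / "ihc_scene.tif")
        save_image(truth["tumor_mask"].astype("uint8") * 255,
                   OUT / "ihc_tumor_mask.tif")
        fig, ax = plt.subplots(figsize=(6, 4.5))
        ax.imshow(img)
        ax.set_title("synthetic H-DAB scene, 30% positive")
        ax.axis("off")
        fig.tight_layout()
        fig.savefig(OUT / "ihc_scene.png", dpi=100)

table = pd.DataFrame(rows)
table.to_csv(OUT / "ihc_recovery.csv", index=False)
print(table.to_string(index=False))
worst = (table.measured_pct - table.designed_pct).abs().max()
print(f"\nWorst deviation from the designed positive fraction: "
      f"{worst:.2f} percentage points (three random 340x256 ROIs per "
      "image, one background ROI subtracted).")
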
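"""Synthetic H-DAB brightfield scenes with a known positive fraction.

The forward model is the Beer–Lambert composition the deconvolution
inverts: per pixel ``I = I0 · 10^(−M · c)`` with ``M`` the (completed)
stain matrix and ``c`` the per-stain OD concentrations.  A tumor ellipse is
drawn into an otherwise empty slide; within the tumor a smoothed Gaussian
random field is thresholded at the requested quantile so that *exactly*
``positive_fraction`` of tumor pixels carry DAB optical density above the
detection threshold, the rest only a faint nonspecific background.
Hematoxylin nuclei (random disks) are scattered over the tissue so the
scene exercises genuine two-stain unmixing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from ..ihc_quant import StainMatrix

__all__ = ["IhcScene", "synthesize_ihc_image"]


@dataclass(frozen=True)
class IhcScene:
    """Design of one synthetic IHC image.

    ``localization`` switches the DAB deposition pattern between
    membrane-like rings and filled cytoplasmic blobs; the measured percent
    area contract is identical for both.
    """

    image_size: tuple[int, int] = (1024, 1360)      # rows, cols
    cell_density: int = 1500                        # nuclei per image
    positive_fraction: float = 0.3
    stain_matrix: StainMatrix | None = None
    localization: str = "cytoplasm"                 # membrane | cytoplasm
    noise_sd: float = 1.5                           # RGB counts
    dab_positive_od: float = 0.6
    dab_background_od: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must lie in [0, 1]")
        if self.localization not in ("membrane", "cytoplasm"):
            raise ValueError("localization must be 'membrane' or 'cytoplasm'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _tumor_ellipse(rows: int, cols: int) -> np.ndarray:
    """Default tumor region: an off-center ellipse large enough to admit
    three disjoint 340×256 ROIs while leaving a clear background corner."""
    rr, cc = np.mgrid[0:rows, 0:cols]
    r0, c0 = rows * 0.5, cols * 0.6
    a, b = rows * 0.37, cols * 0.41
    return ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0


def synthesize_ihc_image(scene: IhcScene) -> tuple[np.ndarray, dict]:
    """Render the scene; returns (uint8 RGB image, truth record).

    Truth carries the tumor mask, the DAB-positive pixel mask and the
    designed positive fraction.  Same seed ⇒ identical image.
    """
    rows, cols = scene.image_size
    rng = np.random.default_rng(scene.seed)
    tumor = _tumor_ellipse(rows, cols)

    # DAB-positive region: smoothed Gaussian field, quantile-thresholded
    # within the tumor so the designed fraction is met exactly.
    positive = np.zeros((rows, cols), dtype=bool)
    field = gaussian_filter(rng.standard_normal((rows, cols)), sigma=3.0)
    if scene.positive_fraction >= 1.0:
        positive = tumor.copy()
    elif scene.positive_fraction > 0.0:
        vals = field[tumor]
        cut = np.quantile(vals, 1.0 - scene.positive_fraction)
        positive = tumor & (field > cut)
    if scene.localization == "membrane" and 0 < scene.positive_fraction < 1:
        # thin the blobs into rings of equal total area: erode and XOR, then
        # re-threshold the field to restore the designed fraction
        from scipy.ndimage import binary_erosion
        ring = positive & ~binary_erosion(positive, iterations=2)
        deficit = positive.sum() - ring.sum()
        if deficit > 0:
            vals = field[tumor & ~positive]
            extra = tumor & ~positive
            if vals.size:
                cut2 = np.quantile(vals, 1.0 - min(1.0, deficit / vals.size))
                ring |= extra & (field > cut2)
        positive = ring & tumor

    dab_od = np.where(positive, scene.dab_positive_od,
                      np.where(tumor, scene.dab_background_od, 0.0))
    dab_od = dab_od * (1.0 + 0.05 * gaussian_filter(
        rng.standard_normal((rows, cols)), sigma=2.0))

    # hematoxylin: diffuse tissue tint plus nuclei disks
    hem_od = np.where(tumor, 0.12, 0.02).astype(float)
    n_cells = scene.cell_density
    if n_cells > 0:
        r_idx = rng.integers(0, rows, n_cells)
        c_idx = rng.integers(0, cols, n_cells)
        stamp = np.zeros((rows, cols))
        stamp[r_idx, c_idx] = 1.0
        nuclei = gaussian_filter(stamp, sigma=2.5)
        nuclei = nuclei / max(nuclei.max(), 1e-12)
        hem_od = hem_od + 0.45 * nuclei

    stains = scene.stain_matrix or StainMatrix.hdab()
    m = stains.completed
    conc = np.stack([hem_od, dab_od, np.zeros_like(dab_od)], axis=-1)
    od_rgb = conc @ m.T
    img = 255.0 * np.power(10.0, -od_rgb)
    if scene.noise_sd > 0:
        img = img + scene.noise_sd * rng.standard_normal(img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    frac = float(positive.sum() / max(tumor.sum(), 1))
    truth = {"tumor_mask": tumor, "positive_mask": positive,
             "positive_fraction": frac,
             "designed_positive_fraction": scene.positive_fraction,
             "seed": scene.seed}
    return img, truth
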
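"""DAB histomorphometry: color deconvolution and background-subtracted
percent stained area.

Brightfield H-DAB images are unmixed by optical-density color
deconvolution (Ruifrok & Johnston's method): per channel
``OD = -log10(max(I, 1) / I0)`` with ``I0 = 255``, unmixed by the inverse
of the stain matrix completed with the normalized cross product of the two
stain vectors.  The DAB channel is thresholded (fixed OD by default, Otsu
optional), three non-overlapping 340×256 ROIs are placed at random inside
the tumor mask plus one background ROI outside it, percent positive area is
computed per ROI, the background percent is subtracted from each tumor ROI,
and the mean of the three subtracted values is the image-level expression
metric.  Negative background-subtracted values are kept (not clipped) so
averaging stays unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "StainMatrix", "RoiLayout", "ExpressionResult",
    "ROI_HEIGHT", "ROI_WIDTH",
    "color_deconvolve", "threshold_dab", "place_rois", "percent_area",
    "measure_expression",
]

ROI_HEIGHT = 256
ROI_WIDTH = 340

# Standard published H-DAB unit OD vectors (hematoxylin, DAB).
_HEMATOXYLIN = np.array([0.650, 0.704, 0.286])
_DAB = np.array([0.268, 0.570, 0.776])


@dataclass(frozen=True)
class StainMatrix:
    """3×2 matrix of unit optical-density stain vectors (columns:
    hematoxylin, DAB); the third basis vector is their normalized cross
    product."""

    matrix: tuple[tuple[float, float], ...]

    @classmethod
    def from_vectors(cls, hematoxylin: np.ndarray, dab: np.ndarray
                     ) -> "StainMatrix":
        h = np.asarray(hematoxylin, dtype=float)
        d = np.asarray(dab, dtype=float)
        for v, name in ((h, "hematoxylin"), (d, "dab")):
            n = np.linalg.norm(v)
            if n == 0:
                raise ValueError(f"{name} vector must be non-zero")
            if abs(n - 1.0) > 1e-6:
                raise ValueError(f"{name} vector must have unit norm")
        m = np.stack([h, d], axis=1)
        return cls(tuple(map(tuple, m)))

    @classmethod
    def hdab(cls) -> "StainMatrix":
        h = _HEMATOXYLIN / np.linalg.norm(_HEMATOXYLIN)
        d = _DAB / np.linalg.norm(_DAB)
        return cls.from_vectors(h, d)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)

    @property
    def complement(self) -> np.ndarray:
        m = self.array
        c = np.cross(m[:, 0], m[:, 1])
        n = np.linalg.norm(c)
        if n == 0:
            raise ValueError("stain vectors are collinear: matrix singular")
        return c / n

    @property
    def completed(self) -> np.ndarray:
        """3×3 matrix (hematoxylin, DAB, residual complement)."""
        return np.column_stack([self.array, self.complement])


@dataclass(frozen=True)
class RoiLayout:
    """Three tumor ROIs plus one background ROI (top-left corners,
    row/col), all exactly 340×256 (w×h) pixels."""

    tumor_rois: tuple[tuple[int, int], ...]
    background_roi: tuple[int, int]
    seed: int | None = None
    height: int = ROI_HEIGHT
    width: int = ROI_WIDTH

    def __post_init__(self) -> None:
        if len(self.tumor_rois) != 3:
            raise ValueError("layout requires exactly three tumor ROIs")
        if self.height != ROI_HEIGHT or self.width != ROI_WIDTH:
            raise ValueError(f"ROIs must be {ROI_WIDTH}x{ROI_HEIGHT} pixels")
        rois = list(self.tumor_rois)
        for i in range(len(rois)):
            for j in range(i + 1, len(rois)):
                if _overlap(rois[i], rois[j], self.height, self.width):
                    raise ValueError("tumor ROIs overlap")


def _overlap(a: tuple[int, int], b: tuple[int, int], h: int, w: int) -> bool:
    return (abs(a[0] - b[0]) < h) and (abs(a[1] - b[1]) < w)


@dataclass
class ExpressionResult:
    """Per-ROI and image-level background-subtracted DAB percent area."""

    roi_percent: tuple[float, float, float]
    background_percent: float
    subtracted: tuple[float, float, float]
    image_metric: float
    provenance: dict = field(default_factory=dict)


def color_deconvolve(rgb_image: np.ndarray, stains: StainMatrix | None = None
                     ) -> dict[str, np.ndarray]:
    """Unmix an RGB brightfield image into per-stain OD channels.

    Input is uint8 (or float on the 0–255 scale).  Negative unmixed stain
    concentrations are clipped to zero.  Returns ``{"hematoxylin", "dab",
    "residual"}`` OD images of the input shape.
    """
    stains = StainMatrix.hdab() if stains is None else stains
    completed = stains.completed
    if abs(np.linalg.det(completed)) < 1e-12:
        raise ValueError("stain matrix is singular")
    img = np.asarray(rgb_image, dtype=float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an (rows, cols, 3) RGB image")
    od = -np.log10(np.maximum(img, 1.0) / 255.0)
    conc = od @ np.linalg.pinv(completed).T
    conc = np.clip(conc, 0.0, None)
    return {"hematoxylin": conc[..., 0], "dab": conc[..., 1],
            "residual": conc[..., 2]}


def threshold_dab(dab_channel: np.ndarray, method: str = "fixed",
                  fixed_od: float = 0.15) -> np.ndarray:
    """Binarize the DAB OD channel: positives are pixels above threshold."""
    dab = np.asarray(dab_channel, dtype=float)
    if method == "fixed":
        thr = fixed_od
    elif method == "otsu":
        thr = float(threshold_otsu(dab))
    else:
        raise ValueError("method must be 'fixed' or 'otsu'")
    return dab > thr


def place_rois(tumor_mask: np.ndarray, seed: int = 0,
               max_attempts: int = 10_000) -> RoiLayout:
    """Randomly place three disjoint tumor ROIs inside the mask and one
    background ROI fully outside it (rejection sampling; deterministic for a
    fixed seed and mask)."""
    mask = np.asarray(tumor_mask, dtype=bool)
    rows, cols = mask.shape
    h, w = ROI_HEIGHT, ROI_WIDTH
    if rows < h or cols < w:
        raise ValueError("image smaller than a single ROI")
    min_area = 3 * h * w
    if mask.sum() < min_area:
        raise ValueError(
            f"tumor mask too small for three disjoint ROIs: needs at least "
            f"{min_area} pixels, has {int(mask.sum())}")
    # integral image -> per-corner window sums, vectorized over all corners
    integral = np.pad(np.cumsum(np.cumsum(mask, 0), 1), ((1, 0), (1, 0)))
    win = (integral[h:, w:] - integral[:-h, w:]
           - integral[h:, :-w] + integral[:-h, :-w])
    inside = np.argwhere(win == h * w)      # corners fully inside the mask
    outside = np.argwhere(win == 0)         # corners fully outside
    if inside.shape[0] == 0:
        raise ValueError(
            f"tumor mask admits no fully contained {ROI_WIDTH}x{ROI_HEIGHT} "
            f"ROI (needs at least {min_area} pixels in a compatible shape)")
    if outside.shape[0] == 0:
        raise ValueError("no background ROI fits fully outside the mask")

    rng = np.random.default_rng(seed)
    tumor: list[tuple[int, int]] = []
    # rejection sampling with restarts: an unlucky first placement can make
    # the remaining feasible region empty even when disjoint triples exist
    for restart in range(20):
        tumor.clear()
        for _ in range(max_attempts // 20):
            r, c = inside[int(rng.integers(0, inside.shape[0]))]
            cand = (int(r), int(c))
            if any(_overlap(cand, t, h, w) for t in tumor):
                continue
            tumor.append(cand)
            if len(tumor) == 3:
                break
        if len(tumor) == 3:
            break
    else:
        raise ValueError("could not place three disjoint tumor ROIs inside "
                         "the mask within the attempt budget")
    r, c = outside[int(rng.integers(0, outside.shape[0]))]
    return RoiLayout(tuple(tumor), (int(r), int(c)), seed=seed)


def _roi_percent(binary: np.ndarray, corner: tuple[int, int]) -> float:
    r, c = corner
    patch = binary[r:r + ROI_HEIGHT, c:c + ROI_WIDTH]
    if patch.shape != (ROI_HEIGHT, ROI_WIDTH):
        raise ValueError("ROI extends beyond the image")
    return 100.0 * float(patch.sum()) / (ROI_HEIGHT * ROI_WIDTH)


def percent_area(binary: np.ndarray, layout: RoiLayout,
                 tumor_mask: np.ndarray | None = None) -> ExpressionResult:
    """Percent DAB-positive area per ROI, background-subtracted and averaged.

    If ``tumor_mask`` is given, layout containment (tumor ROIs inside the
    mask, background ROI outside) is verified before any computation.
    """
    binary = np.asarray(binary, dtype=bool)
    if tumor_mask is not None:
        mask = np.asarray(tumor_mask, dtype=bool)
        for r, c in layout.tumor_rois:
            if not mask[r:r + layout.height, c:c + layout.width].all():
                raise ValueError("tumor ROI extends outside the tumor mask")
        r, c = layout.background_roi
        if mask[r:r + layout.height, c:c + layout.width].any():
            raise ValueError("background ROI intersects the tumor mask")
    roi_pct = tuple(_roi_percent(binary, t) for t in layout.tumor_rois)
    bg_pct = _roi_percent(binary, layout.background_roi)
    subtracted = tuple(p - bg_pct for p in roi_pct)
    return ExpressionResult(roi_pct, bg_pct, subtracted,
                            float(np.mean(subtracted)),
                            provenance={"layout_seed": layout.seed})


def measure_expression(rgb_image: np.ndarray, tumor_mask: np.ndarray,
                       seed: int = 0, stains: StainMatrix | None = None,
                       method: str = "fixed", fixed_od: float = 0.15
                       ) -> ExpressionResult:
    """Convenience chain: deconvolve → threshold → place ROIs → percent area."""
    channels = color_deconvolve(rgb_image, stains)
    binary = threshold_dab(channels["dab"], method, fixed_od)
    layout = place_rois(tumor_mask, seed)
    result = percent_area(binary, layout, tumor_mask)
    result.provenance.update({"threshold_method": method,
                              "fixed_od": fixed_od, "seed": seed})
    return result
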
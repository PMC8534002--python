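"""Container I/O: npz FID stacks with JSON sidecar metadata, and a minimal
Bruker-style serial-FID directory reader.

The package container stores the complex stack in a single ``.npz``
(arrays ``real`` and ``imag``) with the acquisition parameters in a JSON
sidecar of the same stem, so stacks survive round trips through plain
filesystem tooling.  The Bruker-style reader covers the common layout of a
pulse-acquire series: a binary ``ser`` (or ``fid``) of interleaved
little-endian int32 re/im pairs plus an ``acqus`` text file carrying
``##$TD``, ``##$SW_h``, ``##$SFO1`` — enough to reconstruct the stack; it
is not a full vendor-format implementation.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np

from .hp_mrs import AcquisitionConfig, FidStack

__all__ = ["save_fid_stack", "load_fid_stack", "read_bruker_dir",
           "load_image", "save_image"]


def load_image(path) -> np.ndarray:
    """Read a brightfield image (TIFF via tifffile, PNG/JPEG via imageio)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path)
    import imageio.v3 as iio

    return iio.imread(path)


def save_image(image: np.ndarray, path) -> Path:
    """Write an image; TIFF suffixes go through tifffile, others imageio."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, image)
    return path


def save_fid_stack(stack: FidStack, path) -> Path:
    """Write a stack as ``<stem>.npz`` + ``<stem>.json``; returns the npz
    path."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    np.savez_compressed(path, real=stack.data.real, imag=stack.data.imag)
    acq = stack.acq
    meta = {"flip_angle": acq.flip_angle, "tr": acq.tr, "n_acq": acq.n_acq,
            "n_points": acq.n_points, "sweep_width": acq.sweep_width,
            "ref_freq": acq.ref_freq, "center_ppm": acq.center_ppm}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def load_fid_stack(path) -> FidStack:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar missing: {sidecar}")
    meta = json.loads(sidecar.read_text())
    with np.load(path) as z:
        data = z["real"] + 1j * z["imag"]
    return FidStack(data, AcquisitionConfig(**meta))


def _parse_jcamp(path: Path) -> dict[str, float]:
    params = {}
    text = path.read_text(errors="replace")
    for m in re.finditer(r"##\$(\w+)=\s*([-\d.eE+]+)", text):
        try:
            params[m.group(1)] = float(m.group(2))
        except ValueError:
            pass
    return params


def read_bruker_dir(path, flip_angle: float = 25.0, tr: float = 2.0,
                    center_ppm: float = 177.1) -> FidStack:
    """Read a Bruker-style serial-FID directory (``ser`` or ``fid`` +
    ``acqus``) into a :class:`FidStack`.

    Assumes int32 little-endian interleaved real/imaginary points and takes
    TD (complex points × 2), SW_h and SFO1 from ``acqus``.  Parameters a
    pulse-acquire ``acqus`` does not carry (flip angle, TR, carrier ppm)
    are supplied by the caller.
    """
    path = Path(path)
    acqus = path / "acqus"
    if not acqus.exists():
        raise FileNotFoundError(f"no acqus file in {path}")
    params = _parse_jcamp(acqus)
    for key in ("TD", "SW_h", "SFO1"):
        if key not in params:
            raise ValueError(f"acqus is missing ##${key}")
    n_points = int(params["TD"]) // 2
    raw_path = path / "ser"
    if not raw_path.exists():
        raw_path = path / "fid"
    if not raw_path.exists():
        raise FileNotFoundError(f"no ser/fid binary in {path}")
    raw = np.fromfile(raw_path, dtype="<i4").astype(float)
    if raw.size % (2 * n_points):
        raise ValueError("binary size is not a multiple of the FID length")
    n_acq = raw.size // (2 * n_points)
    data = (raw[0::2] + 1j * raw[1::2]).reshape(n_acq, n_points)
    acq = AcquisitionConfig(flip_angle=flip_angle, tr=tr, n_acq=n_acq,
                            n_points=n_points, sweep_width=params["SW_h"],
                            ref_freq=params["SFO1"], center_ppm=center_ppm)
    return FidStack(data, acq)
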
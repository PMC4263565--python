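"""The :class:`StripImage` container and lossless image I/O.

A :class:`StripImage` is the unit every pipeline stage consumes or
produces: an H x W x 3 grid of digital numbers (DN) plus the acquisition
metadata (exposure time, detection mode) that the quantification needs.
Images are assumed flow-horizontal: the flow direction is increasing
column index.

Files are written losslessly (8- or 16-bit PNG, or TIFF) with a JSON
sidecar ``<image>.json`` carrying the metadata.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import ConfigError, DomainError

#: Recognised detection modes. Fluorescence reads the red channel
#: (additive emission, e.g. R-phycoerythrin); absorbance reads the green
#: channel (reflectance loss, e.g. colloidal gold).
MODES = ("fluorescence", "absorbance")

#: Metadata keys persisted to the JSON sidecar next to each image file.
SIDECAR_KEYS = ("mode", "exposure_s", "bit_depth", "label")


@dataclass
class StripImage:
    """An RGB strip/dot-blot image with acquisition metadata.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` array of digital numbers in ``[0, 2**bit_depth - 1]``.
    bit_depth
        Camera bit depth; 8 for phone JPEG/PNG output.
    exposure_s
        Exposure time in seconds. Required for exposure scaling.
    mode
        ``"fluorescence"`` or ``"absorbance"``.
    label
        Free-text identifier used in result tables.
    meta
        Extra per-image metadata (concentration_ng_ml, replicate, time_s,
        seed, ...) carried through to CSV output.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    exposure_s: float = 1.0 / 15.0
    mode: str = "fluorescence"
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ConfigError(
                f"StripImage requires an (H, W, 3) RGB array, got shape {self.pixels.shape}"
            )
        if self.mode not in MODES:
            raise ConfigError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if not self.exposure_s > 0:
            raise DomainError(f"exposure_s must be positive, got {self.exposure_s}")
        if int(self.bit_depth) < 1:
            raise ConfigError(f"bit_depth must be >= 1, got {self.bit_depth}")
        self.bit_depth = int(self.bit_depth)
        lo = float(self.pixels.min(initial=0))
        hi = float(self.pixels.max(initial=0))
        if lo < 0 or hi > self.full_scale:
            raise DomainError(
                f"pixel values [{lo}, {hi}] outside [0, {self.full_scale}] "
                f"for bit_depth={self.bit_depth}"
            )

    @property
    def full_scale(self) -> int:
        """Largest representable DN, ``2**bit_depth - 1``."""
        return (1 << self.bit_depth) - 1

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def save_image(image: StripImage, path: str | Path) -> Path:
    """Write *image* losslessly with a JSON metadata sidecar.

    ``.png`` for bit depths up to 16 (uint8/uint16), ``.tif``/``.tiff``
    via tifffile otherwise. Returns the sidecar path.
    """
    path = Path(path)
    if image.bit_depth <= 8:
        arr = image.pixels.astype(np.uint8)
    elif image.bit_depth <= 16:
        arr = image.pixels.astype(np.uint16)
    else:
        arr = image.pixels.astype(np.uint32)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    elif image.bit_depth > 8:
        raise ConfigError(
            f"{path.name}: RGB images deeper than 8 bit must be saved as TIFF"
        )
    else:
        iio.imwrite(path, arr)
    sidecar = _sidecar_path(path)
    payload = {k: getattr(image, k) for k in SIDECAR_KEYS}
    payload.update(image.meta)
    sidecar.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return sidecar


def load_image(path: str | Path, **overrides) -> StripImage:
    """Read an RGB image plus sidecar metadata into a :class:`StripImage`.

    Keyword overrides (``mode=``, ``exposure_s=``, ...) win over sidecar
    values; a conflict is logged as a warning. A missing exposure time is
    an error — the pipeline cannot scale signals without it.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"image file not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ConfigError(
            f"{path.name}: expected a 3-channel RGB image, got shape {arr.shape}"
        )

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    for key, value in overrides.items():
        if value is None:
            continue
        if key in meta and meta[key] != value:
            warnings.warn(
                f"{path.name}: override {key}={value!r} supersedes sidecar "
                f"value {meta[key]!r}",
                stacklevel=2,
            )
        meta[key] = value

    if "exposure_s" not in meta:
        raise ConfigError(
            f"{path.name}: no exposure_s in sidecar or overrides; cannot scale signal"
        )
    bit_depth = int(meta.pop("bit_depth", 16 if arr.dtype == np.uint16 else 8))
    known = {k: meta.pop(k) for k in ("mode", "exposure_s", "label") if k in meta}
    return StripImage(
        pixels=arr,
        bit_depth=bit_depth,
        exposure_s=float(known.get("exposure_s")),
        mode=known.get("mode", "fluorescence"),
        label=str(known.get("label", path.stem)),
        meta=meta,
    )
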
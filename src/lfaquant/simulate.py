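"""Seeded synthetic strip / dot-blot image generation with ground truth.

The generator emulates phone-camera images of lateral-flow strips and
dot blots: a uniform background plane, a localized test zone (filled
disk or leading-edge crescent), a concentration-dependent zone amplitude
following a sandwich-binding hook response, optional uniform nonspecific
binding, Gaussian read noise, optional Poisson shot noise, and clipping
at the camera's full scale.

Two detection modes are rendered:

``fluorescence``
    Additive signal in the red channel:
    ``red = background + amplitude * (exposure / reference) * shape + noise``.

``absorbance``
    Multiplicative darkening of the green channel (colloidal-gold
    reflectance loss), with the amplitude acting as an optical density:
    ``green = background * 10**(-amplitude * shape) + noise``.
    The achievable zone deficit is therefore bounded by the background
    level times the zone area no matter how large the amplitude — the
    generative basis for the compressed dynamic range of gold strips.

Every simulation op returns a :class:`GroundTruth` record holding the
generative parameters and all per-image zone amplitudes, so recovery can
be tested against known truth.

Seeding
-------
One master seed per simulated experiment. Image number ``i`` of the run
draws from ``numpy.random.default_rng((seed, offset + i))``, i.e. a
``SeedSequence`` with entropy ``(seed, counter)``; ``offset`` is 0 for
single-arm runs, 0 / 4096 for the spot / strip arms of an S/NSB pair.
Any single image can therefore be regenerated in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigError, DomainError, GeometryError
from .image import MODES, StripImage

__all__ = [
    "OpticsConfig",
    "SpotGeometry",
    "BindingModel",
    "SeriesDesign",
    "GroundTruth",
    "hook_response",
    "auto_exposure",
    "render_image",
    "simulate_dose_series",
    "simulate_snsb_pair",
    "simulate_bleach_stack",
]

#: Default replicate-to-replicate coefficient of variation of the zone
#: amplitude (lognormal, mean-one).
DEFAULT_REPLICATE_CV = 0.10

#: Auto-exposure aims the peak in-zone signal at this many DN above
#: background (8-bit scale; scaled proportionally for deeper cameras).
AUTO_EXPOSURE_TARGET_DN = 120.0

#: Auto-exposure is restricted to powers of two times the reference
#: exposure within this exponent range.
AUTO_EXPOSURE_EXP_RANGE = (-6, 10)


# ---------------------------------------------------------------------------
# configuration records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OpticsConfig:
    """Camera / illumination model for rendering.

    ``background_dn`` may be a scalar (same level in all channels) or a
    3-sequence of per-channel levels. ``shot_noise`` applies a Poisson
    resampling of the noiseless mean (treating DN as counts) before the
    Gaussian read noise.
    """

    width_px: int = 128
    height_px: int = 96
    bit_depth: int = 8
    background_dn: float | tuple[float, float, float] = 20.0
    read_noise_dn: float = 2.0
    shot_noise: bool = False
    reference_exposure_s: float = 1.0 / 15.0

    def __post_init__(self) -> None:
        if self.width_px < 16 or self.height_px < 16:
            raise ConfigError("width_px and height_px must be >= 16")
        bg = np.atleast_1d(np.asarray(self.background_dn, dtype=float))
        if bg.size not in (1, 3):
            raise ConfigError("background_dn must be scalar or length-3")
        if np.any(bg < 0) or np.any(bg >= 2**self.bit_depth):
            raise ConfigError(
                f"background_dn must lie in [0, 2**{self.bit_depth}) per channel"
            )
        if self.read_noise_dn < 0:
            raise ConfigError("read_noise_dn must be >= 0")
        if not self.reference_exposure_s > 0:
            raise ConfigError("reference_exposure_s must be > 0")

    @property
    def full_scale(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def background_rgb(self) -> np.ndarray:
        """Per-channel background as a length-3 float array."""
        bg = np.atleast_1d(np.asarray(self.background_dn, dtype=float))
        return np.broadcast_to(bg, (3,)).astype(float)


@dataclass(frozen=True)
class SpotGeometry:
    """Test-zone geometry: a filled disk or its leading-edge crescent.

    The flow direction is increasing column index, so the leading edge
    is the low-column side of the disk; with ``crescent=True`` only the
    upstream ``crescent_fraction`` of the disk's horizontal extent
    carries signal (sandwiches form where the eluting reagents first
    enter the zone). ``flank_gap_px`` is the clear margin kept between
    the zone and the baseline flank windows.
    """

    center: tuple[int, int] = (48, 64)  # (row, col)
    radius_px: float = 10.0
    crescent: bool = False
    crescent_fraction: float = 0.35
    flank_gap_px: int = 5

    def __post_init__(self) -> None:
        if not self.radius_px > 0:
            raise ConfigError("radius_px must be > 0")
        if not 0 < self.crescent_fraction <= 1:
            raise ConfigError("crescent_fraction must be in (0, 1]")
        if self.flank_gap_px < 0:
            raise ConfigError("flank_gap_px must be >= 0")

    def mask(self, height: int, width: int) -> np.ndarray:
        """Boolean zone mask on an ``height x width`` grid.

        Raises :class:`GeometryError` if the zone (plus the flank gap on
        the column axis) does not fit inside the image.
        """
        r0, c0 = self.center
        r = self.radius_px
        if (
            r0 - r < 0
            or r0 + r > height - 1
            or c0 - r - self.flank_gap_px < 0
            or c0 + r + self.flank_gap_px > width - 1
        ):
            raise GeometryError(
                f"zone (center={self.center}, radius={r}) plus flank gap "
                f"{self.flank_gap_px} px does not fit in a {height}x{width} image"
            )
        rows = np.arange(height)[:, None]
        cols = np.arange(width)[None, :]
        disk = (rows - r0) ** 2 + (cols - c0) ** 2 <= r**2
        if not self.crescent:
            return disk
        # leading-edge band: upstream crescent_fraction of the disk's extent
        band_edge = (c0 - r) + self.crescent_fraction * (2 * r)
        return disk & (cols <= band_edge)


@dataclass(frozen=True)
class BindingModel:
    """Generative dose-response of the sandwich assay.

    ``alpha`` is the amplitude coefficient in DN per (ng/mL)**b at the
    reference exposure, ``b`` the power-law exponent, ``k_hook`` the
    hook (prozone) concentration in ng/mL at which the response peaks,
    and ``nsb_slope`` the uniform nonspecific-binding amplitude per unit
    reporter concentration, DN per (ng/mL).
    """

    alpha: float
    b: float
    k_hook: float
    nsb_slope: float = 0.0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ConfigError("alpha must be > 0")
        if not 0 < self.b <= 1.5:
            raise ConfigError("b must be in (0, 1.5]")
        if not self.k_hook > 0:
            raise ConfigError("k_hook must be > 0")
        if self.nsb_slope < 0:
            raise ConfigError("nsb_slope must be >= 0")


@dataclass(frozen=True)
class SeriesDesign:
    """A geometric dilution series: ``c_i = c_min * fold**i``, ng/mL.

    ``exposure_s`` may be a scalar (one exposure for every image), a
    sequence of per-concentration exposures, or ``"auto"`` to let the
    generator pick a power-of-two multiple of the reference exposure per
    concentration that lands the expected peak signal near
    :data:`AUTO_EXPOSURE_TARGET_DN` — emulating the operator varying the
    exposure time to extend the dynamic range.
    """

    c_min: float
    fold: float
    n_points: int
    n_replicates: int = 3
    exposure_s: float | Sequence[float] | str = "auto"

    def __post_init__(self) -> None:
        if not self.c_min > 0:
            raise ConfigError("c_min must be > 0")
        if not self.fold > 1:
            raise ConfigError("fold must be > 1")
        if self.n_points < 3:
            raise ConfigError("n_points must be >= 3")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if isinstance(self.exposure_s, str):
            if self.exposure_s != "auto":
                raise ConfigError("exposure_s must be a number, a sequence or 'auto'")
        elif np.ndim(self.exposure_s) == 0:
            if not float(self.exposure_s) > 0:
                raise ConfigError("exposure_s must be > 0")
        else:
            exp = np.asarray(self.exposure_s, dtype=float)
            if exp.size != self.n_points or np.any(exp <= 0):
                raise ConfigError(
                    "per-concentration exposure_s must have n_points positive entries"
                )

    @property
    def concentrations(self) -> np.ndarray:
        """The ``n_points`` concentrations in ng/mL."""
        return self.c_min * self.fold ** np.arange(self.n_points)


@dataclass
class GroundTruth:
    """Generative record carried alongside every synthetic output.

    ``per_image_amplitude`` lists the true zone amplitude (DN at the
    reference exposure; optical density in absorbance mode) of each
    rendered image in order. Together with ``seed`` the record fully
    determines the rendered stack.
    """

    binding: BindingModel | None
    geometry: SpotGeometry
    optics: OpticsConfig
    per_image_amplitude: list[float]
    seed: int
    mode: str = "fluorescence"
    concentrations: list[float] = field(default_factory=list)
    exposures_s: list[float] = field(default_factory=list)
    true_snsb: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.per_image_amplitude):
            raise DomainError("per_image_amplitude entries must be >= 0")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def hook_response(c, binding: BindingModel):
    """Zone amplitude A(c) of the sandwich assay with a hook (prozone).

    ``A(c) = alpha * c**b / (1 + (c / k_hook)**(2b))``

    Low-dose limit ``alpha * c**b``; strictly increasing below
    ``k_hook``, strictly decreasing above it (the prozone regime where
    excess analyte saturates both binders separately and blocks
    sandwich formation); ``A(0) = 0``.

    Accepts a scalar or array concentration in ng/mL; returns DN (or
    optical density in absorbance use) at the reference exposure.
    """
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise DomainError("concentration must be >= 0")
    amp = binding.alpha * c_arr**binding.b / (1.0 + (c_arr / binding.k_hook) ** (2 * binding.b))
    return float(amp) if np.ndim(c) == 0 else amp


def auto_exposure(amplitude: float, optics: OpticsConfig) -> float:
    """Pick a power-of-two multiple of the reference exposure.

    Chooses ``reference * 2**k`` (k clipped to
    :data:`AUTO_EXPOSURE_EXP_RANGE`) so the expected in-zone peak
    ``amplitude * 2**k`` lands just below the target peak level.
    """
    target = AUTO_EXPOSURE_TARGET_DN / 255.0 * optics.full_scale
    lo, hi = AUTO_EXPOSURE_EXP_RANGE
    if amplitude <= 0:
        return optics.reference_exposure_s
    k = int(np.clip(math.floor(math.log2(target / amplitude)), lo, hi))
    return optics.reference_exposure_s * 2.0**k


def _quantize(img: np.ndarray, optics: OpticsConfig) -> np.ndarray:
    dn = np.clip(np.rint(img), 0, optics.full_scale)
    if optics.bit_depth <= 8:
        return dn.astype(np.uint8)
    if optics.bit_depth <= 16:
        return dn.astype(np.uint16)
    return dn.astype(np.uint32)


def _render_mask(
    shape: np.ndarray,
    amplitude: float,
    optics: OpticsConfig,
    mode: str,
    exposure_s: float,
    rng: np.random.Generator,
    label: str = "",
    meta: dict | None = None,
) -> StripImage:
    """Render a zone given an arbitrary in-[0,1] shape mask."""
    if mode not in MODES:
        raise ConfigError(f"unknown mode {mode!r}; expected one of {MODES}")
    bg = optics.background_rgb
    img = np.empty((optics.height_px, optics.width_px, 3), dtype=float)
    for ch in range(3):
        img[:, :, ch] = bg[ch]
    if mode == "fluorescence":
        img[:, :, 0] += amplitude * (exposure_s / optics.reference_exposure_s) * shape
    else:  # absorbance: amplitude acts as optical density of the zone
        img[:, :, 1] = bg[1] * np.power(10.0, -amplitude * shape)
    if optics.shot_noise:
        img = rng.poisson(np.clip(img, 0.0, None)).astype(float)
    if optics.read_noise_dn > 0:
        img = img + rng.normal(0.0, optics.read_noise_dn, size=img.shape)
    return StripImage(
        pixels=_quantize(img, optics),
        bit_depth=optics.bit_depth,
        exposure_s=exposure_s,
        mode=mode,
        label=label,
        meta=dict(meta or {}),
    )


def render_image(
    geometry: SpotGeometry,
    amplitude: float,
    optics: OpticsConfig,
    mode: str = "fluorescence",
    exposure_s: float | None = None,
    seed: int | np.random.Generator = 0,
    label: str = "",
    meta: dict | None = None,
) -> StripImage:
    """Render one strip image with a disk/crescent zone of given amplitude.

    ``amplitude`` is the per-pixel zone signal in DN at the reference
    exposure (fluorescence) or the zone optical density (absorbance).
    Identical (geometry, amplitude, optics, mode, exposure, seed) yield
    a bit-identical image.
    """
    if amplitude < 0:
        raise DomainError("amplitude must be >= 0")
    exposure_s = optics.reference_exposure_s if exposure_s is None else float(exposure_s)
    if not exposure_s > 0:
        raise DomainError("exposure_s must be > 0")
    mask = geometry.mask(optics.height_px, optics.width_px).astype(float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _render_mask(mask, amplitude, optics, mode, exposure_s, rng, label, meta)


def _image_rng(seed: int, index: int) -> np.random.Generator:
    """Per-image substream: SeedSequence entropy (master seed, counter)."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(index))))


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-one multiplicative lognormal replicate noise."""
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def _series_exposures(
    design: SeriesDesign, mean_amps: np.ndarray, optics: OpticsConfig, mode: str
) -> np.ndarray:
    if isinstance(design.exposure_s, str):  # "auto"
        if mode == "absorbance":
            # reflectance images: signal is an optical density, exposure
            # scaling does not apply; render at the reference exposure
            return np.full(design.n_points, optics.reference_exposure_s)
        return np.array([auto_exposure(a, optics) for a in mean_amps])
    if np.ndim(design.exposure_s) == 0:
        return np.full(design.n_points, float(design.exposure_s))
    return np.asarray(design.exposure_s, dtype=float)


def simulate_dose_series(
    design: SeriesDesign,
    binding: BindingModel,
    geometry: SpotGeometry,
    optics: OpticsConfig,
    mode: str = "fluorescence",
    seed: int = 0,
    replicate_cv: float = DEFAULT_REPLICATE_CV,
) -> tuple[list[StripImage], GroundTruth]:
    """Simulate a full dilution-series experiment.

    Renders ``n_points * n_replicates`` images. Concentration ``i`` is
    ``c_min * fold**i``; the per-image zone amplitude is
    ``hook_response(c_i)`` times a mean-one lognormal replicate factor
    of coefficient of variation ``replicate_cv``. The returned
    :class:`GroundTruth` records every amplitude.
    """
    concs = design.concentrations
    mean_amps = hook_response(concs, binding)
    exposures = _series_exposures(design, mean_amps, optics, mode)

    images: list[StripImage] = []
    amplitudes: list[float] = []
    idx = 0
    for i, c in enumerate(concs):
        for rep in range(design.n_replicates):
            rng = _image_rng(seed, idx)
            amp = mean_amps[i] * _lognormal_factor(rng, replicate_cv)
            meta = {
                "concentration_ng_ml": float(c),
                "replicate": rep,
                "seed": int(seed),
                "image_index": idx,
            }
            images.append(
                render_image(
                    geometry,
                    amp,
                    optics,
                    mode=mode,
                    exposure_s=float(exposures[i]),
                    seed=rng,
                    label=f"c{i:02d}_r{rep}",
                    meta=meta,
                )
            )
            amplitudes.append(float(amp))
            idx += 1

    truth = GroundTruth(
        binding=binding,
        geometry=geometry,
        optics=optics,
        per_image_amplitude=amplitudes,
        seed=seed,
        mode=mode,
        concentrations=[float(c) for c in concs],
        exposures_s=[float(e) for e in exposures],
        extra={"replicate_cv": replicate_cv, "n_replicates": design.n_replicates},
    )
    return images, truth


#: Arm offsets for the S/NSB substreams (spot arm, strip arm).
_SNSB_ARM_OFFSETS = (0, 4096)


def strip_footprint(optics: OpticsConfig) -> tuple[int, int, int, int]:
    """Row/col bounds (half-open) of the NSB strip footprint rectangle.

    The nitrocellulose strip occupies the central region of the frame so
    that baseline flank windows fall on the off-strip background.
    """
    h, w = optics.height_px, optics.width_px
    return (h // 6, h - h // 6, w // 4, w - w // 4)


def simulate_snsb_pair(
    design: SeriesDesign,
    true_snsb: float,
    nsb_slope: float,
    geometry: SpotGeometry,
    optics: OpticsConfig,
    seed: int = 0,
    replicate_cv: float = DEFAULT_REPLICATE_CV,
) -> tuple[list[StripImage], list[StripImage], GroundTruth]:
    """Simulate the paired spot / NSB-strip dilution series.

    Spot images carry a localized zone with per-pixel amplitude
    ``signal_slope * c`` (linear in reporter concentration, no hook);
    strip images carry a spatially uniform intensity ``nsb_slope * c``
    over the strip footprint, with the off-strip margins left at the
    optical background so a baseline can be taken outside the strip.
    ``signal_slope = true_snsb * nsb_slope``, so the generative ratio of
    the two concentration slopes equals ``true_snsb``. Both arms are
    imaged in fluorescence mode.
    """
    if not true_snsb > 0:
        raise DomainError("true_snsb must be > 0")
    if not nsb_slope > 0:
        raise DomainError("nsb_slope must be > 0")
    signal_slope = true_snsb * nsb_slope
    concs = design.concentrations

    r0, r1, c0, c1 = strip_footprint(optics)
    rect = np.zeros((optics.height_px, optics.width_px), dtype=float)
    rect[r0:r1, c0:c1] = 1.0

    spot_amps = signal_slope * concs
    strip_amps = nsb_slope * concs
    spot_exp = _series_exposures(design, spot_amps, optics, "fluorescence")
    strip_exp = _series_exposures(design, strip_amps, optics, "fluorescence")

    arms: list[list[StripImage]] = [[], []]
    amplitudes: list[float] = []
    for arm, (mean_amps, exposures, offset) in enumerate(
        [(spot_amps, spot_exp, _SNSB_ARM_OFFSETS[0]), (strip_amps, strip_exp, _SNSB_ARM_OFFSETS[1])]
    ):
        idx = 0
        for i, c in enumerate(concs):
            for rep in range(design.n_replicates):
                rng = _image_rng(seed, offset + idx)
                amp = mean_amps[i] * _lognormal_factor(rng, replicate_cv)
                meta = {
                    "concentration_ng_ml": float(c),
                    "replicate": rep,
                    "seed": int(seed),
                    "arm": "spot" if arm == 0 else "strip",
                    "image_index": offset + idx,
                }
                label = f"{meta['arm']}_c{i:02d}_r{rep}"
                if arm == 0:
                    img = render_image(
                        geometry, amp, optics, "fluorescence",
                        float(exposures[i]), rng, label, meta,
                    )
                else:
                    img = _render_mask(
                        rect, amp, optics, "fluorescence",
                        float(exposures[i]), rng, label, meta,
                    )
                arms[arm].append(img)
                amplitudes.append(float(amp))
                idx += 1

    truth = GroundTruth(
        binding=None,
        geometry=geometry,
        optics=optics,
        per_image_amplitude=amplitudes,
        seed=seed,
        mode="fluorescence",
        concentrations=[float(c) for c in concs],
        exposures_s=[float(e) for e in spot_exp] + [float(e) for e in strip_exp],
        true_snsb=float(true_snsb),
        extra={
            "signal_slope_dn_per_ng_ml": signal_slope,
            "nsb_slope_dn_per_ng_ml": nsb_slope,
            "strip_footprint": strip_footprint(optics),
            "replicate_cv": replicate_cv,
            "n_replicates": design.n_replicates,
        },
    )
    return arms[0], arms[1], truth


def simulate_bleach_stack(
    amplitude0: float,
    half_life_s: float,
    times: Sequence[float],
    geometry: SpotGeometry,
    optics: OpticsConfig,
    mode: str = "fluorescence",
    seed: int = 0,
) -> tuple[list[StripImage], GroundTruth]:
    """Simulate photobleaching under constant illumination.

    The zone amplitude at time ``t`` is ``amplitude0 * exp(-k t)`` with
    ``k = ln 2 / half_life_s``; one image is rendered per time point at
    the reference exposure.
    """
    if not half_life_s > 0:
        raise DomainError("half_life_s must be > 0")
    if amplitude0 < 0:
        raise DomainError("amplitude0 must be >= 0")
    t = np.asarray(times, dtype=float)
    if t.size < 1 or np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise DomainError("times must be non-negative and strictly increasing")
    k = math.log(2.0) / half_life_s
    amps = amplitude0 * np.exp(-k * t)

    images = []
    for i, (ti, amp) in enumerate(zip(t, amps)):
        rng = _image_rng(seed, i)
        meta = {"time_s": float(ti), "seed": int(seed), "image_index": i}
        images.append(
            render_image(
                geometry, float(amp), optics, mode,
                optics.reference_exposure_s, rng, f"t{i:03d}", meta,
            )
        )
    truth = GroundTruth(
        binding=None,
        geometry=geometry,
        optics=optics,
        per_image_amplitude=[float(a) for a in amps],
        seed=seed,
        mode=mode,
        extra={
            "amplitude0": float(amplitude0),
            "half_life_s": float(half_life_s),
            "k_per_s": k,
            "times_s": [float(x) for x in t],
        },
    )
    return images, truth
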
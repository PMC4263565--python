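"""End-to-end experiment runners: simulate -> quantify -> fit.

These compose the simulator, the per-image quantification and the
series-level statistics into the three benchmark experiments (dose
response, S/NSB pairing, photobleaching). The CLI and the acceptance
script are thin wrappers over these functions; no computation lives
only in the CLI layer.
"""

from __future__ import annotations

import numpy as np

from .dose_response import (
    DoseSeries,
    analyze_series,
    snsb_ratio,
)
from .fixtures import (
    BLEACH_FIXTURES,
    BLEACH_OPTICS_DETERMINISTIC,
    BSA_DOSE_DESIGN,
    DEFAULT_OPTICS,
    DOSE_GEOMETRY,
    GOLD_OPTICS,
    RPE_BINDING,
    SNSB_DESIGN,
    SNSB_FIXTURES,
    SPOT_GEOMETRY,
)
from .photobleach import BleachSeries, fit_decay
from .quantify import QuantConfig, Roi, quantify_images
from .simulate import (
    BindingModel,
    OpticsConfig,
    SeriesDesign,
    SpotGeometry,
    simulate_bleach_stack,
    simulate_dose_series,
    simulate_snsb_pair,
    strip_footprint,
)

__all__ = [
    "default_quant_config",
    "run_dose_response_experiment",
    "run_snsb_experiment",
    "run_bleach_experiment",
]

#: Endpoints (ng/mL) at which the calibrated fold change is evaluated
#: for the fluorescence/gold comparison: the printed linear range of the
#: R-PE assay.
EVAL_RANGE_NG_ML = (0.4, 4000.0)


def default_quant_config(
    optics: OpticsConfig, geometry: SpotGeometry | None = None
) -> QuantConfig:
    """Quantification config matched to a simulated optics/geometry.

    The fallback ROI (used when detection finds nothing, e.g. blank or
    uniform-strip images) is centred on the spot when a geometry is
    given, else on the strip footprint rectangle.
    """
    if geometry is not None:
        r0, c0 = geometry.center
        half = int(np.ceil(geometry.radius_px)) + 2
        fallback = Roi(
            row_min=r0 - half,
            row_max=r0 + half + 1,
            col_min=c0 - half,
            col_max=c0 + half + 1,
        )
    else:
        fr0, fr1, fc0, fc1 = strip_footprint(optics)
        fallback = Roi(row_min=fr0 + 2, row_max=fr1 - 2, col_min=fc0 + 2, col_max=fc1 - 2)
    return QuantConfig(
        fallback_roi=fallback,
        reference_exposure_s=optics.reference_exposure_s,
    )


def run_dose_response_experiment(
    seed: int = 0,
    mode: str = "fluorescence",
    binding: BindingModel = RPE_BINDING,
    design: SeriesDesign = BSA_DOSE_DESIGN,
    geometry: SpotGeometry = DOSE_GEOMETRY,
    optics: OpticsConfig | None = None,
    replicate_cv: float = 0.10,
    eval_range: tuple[float, float] = EVAL_RANGE_NG_ML,
) -> dict:
    """Simulated dilution series -> quantification -> prozone screen ->
    power-law calibration -> fold-change summary.

    Returns a dict with the ground truth, the per-image quantification
    table, the :class:`DoseSeries`, the exclusions, the power fit, and
    the fold change evaluated both over the included range and at
    ``eval_range``.
    """
    if optics is None:
        optics = DEFAULT_OPTICS if mode == "fluorescence" else GOLD_OPTICS
    images, truth = simulate_dose_series(
        design, binding, geometry, optics, mode=mode, seed=seed,
        replicate_cv=replicate_cv,
    )
    config = default_quant_config(optics, geometry)
    table = quantify_images(images, config)
    series = DoseSeries.from_table(table, mode=mode, label=f"dose_seed{seed}")
    analysis = analyze_series(series, eval_range=eval_range)
    return {
        "truth": truth,
        "table": table,
        "series": series,
        "excluded": analysis["excluded"],
        "power_fit": analysis["power_fit"],
        "range_included": analysis["range"],
        "range_at_endpoints": analysis["range_at_endpoints"],
        "fold_change": analysis["range_at_endpoints"].fold_change,
    }


def run_snsb_experiment(
    fixture: str | dict = "rpe",
    seed: int = 0,
    design: SeriesDesign = SNSB_DESIGN,
    geometry: SpotGeometry = SPOT_GEOMETRY,
    optics: OpticsConfig = DEFAULT_OPTICS,
    replicate_cv: float = 0.10,
) -> dict:
    """Paired spot/strip series -> quantification -> slope ratio.

    Both arms are reduced to per-pixel zone amplitudes
    (``signal_per_area_dn``, i.e. scaled signal divided by the
    half-maximum zone area), which puts the localized spot and the
    uniform NSB strip on a common scale; the S/NSB ratio is the ratio of
    the two concentration slopes fitted to the replicate means.
    """
    params = SNSB_FIXTURES[fixture] if isinstance(fixture, str) else dict(fixture)
    spot_images, strip_images, truth = simulate_snsb_pair(
        design,
        true_snsb=params["true_snsb"],
        nsb_slope=params["nsb_slope"],
        geometry=geometry,
        optics=optics,
        seed=seed,
        replicate_cv=replicate_cv,
    )
    spot_cfg = default_quant_config(optics, geometry)
    strip_cfg = default_quant_config(optics, geometry=None)
    spot_table = quantify_images(spot_images, spot_cfg)
    strip_table = quantify_images(strip_images, strip_cfg)
    signal_series = DoseSeries.from_table(
        spot_table, signal_col="signal_per_area_dn", label="signal"
    )
    nsb_series = DoseSeries.from_table(
        strip_table, signal_col="signal_per_area_dn", label="nsb"
    )
    result = snsb_ratio(signal_series, nsb_series)
    return {
        "truth": truth,
        "spot_table": spot_table,
        "strip_table": strip_table,
        "signal_series": signal_series,
        "nsb_series": nsb_series,
        "result": result,
        "ratio": result.ratio,
    }


def run_bleach_experiment(
    fixture: str | dict = "rpe",
    seed: int = 0,
    noiseless: bool = True,
    geometry: SpotGeometry = SPOT_GEOMETRY,
) -> dict:
    """Photobleaching stack -> per-frame quantification -> decay fit.

    With ``noiseless=True`` the deterministic 16-bit camera fixture is
    used (read noise 0); otherwise the default 8-bit noisy camera.
    """
    params = BLEACH_FIXTURES[fixture] if isinstance(fixture, str) else dict(fixture)
    if noiseless:
        optics = BLEACH_OPTICS_DETERMINISTIC
        amplitude0 = params["amplitude0_deterministic"]
    else:
        optics = DEFAULT_OPTICS
        amplitude0 = params["amplitude0_noisy"]
    images, truth = simulate_bleach_stack(
        amplitude0=amplitude0,
        half_life_s=params["half_life_s"],
        times=params["times_s"],
        geometry=geometry,
        optics=optics,
        seed=seed,
    )
    config = default_quant_config(optics, geometry)
    table = quantify_images(images, config)
    series = BleachSeries(
        times_s=table["time_s"].to_numpy(dtype=float),
        signals=table["scaled_signal"].to_numpy(dtype=float),
        label=f"bleach_{params['half_life_s']:g}s_seed{seed}",
    )
    result = fit_decay(series)
    return {
        "truth": truth,
        "table": table,
        "series": series,
        "result": result,
        "half_life_s": result.half_life_s,
    }
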
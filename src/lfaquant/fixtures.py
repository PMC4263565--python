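"""Named study fixtures: generative parameter sets for the benchmark
experiments.

These encode the study conditions the package is validated against:

* ``rpe_default`` — an R-phycoerythrin fluorescence lateral-flow
  titration of biotinylated BSA: four-fold dilution series from
  63 pg/mL to ~16.5 µg/mL, triplicate. The sub-linear exponent
  b = 0.75 follows from the printed linear range and signal change
  (a 1,000-fold signal change over 0.4–4,000 ng/mL:
  log10(1000) / log10(4000/0.4) = 3/4). The hook concentration
  k_hook = 6,000 ng/mL places the response peak between the two top
  series concentrations so that only the top point (~16,500 ng/mL)
  shows the prozone drop, as observed for this assay.
* ``gold_default`` — the same binding truth read in colloidal-gold
  absorbance mode (amplitude acting as optical density against a bright
  reflectance background), which compresses the usable signal range.
* ``rpe_snsb`` / ``bv605_snsb`` — paired spot/strip dilution series
  (two-fold, 0.63–40 µg/mL, triplicate) with generative S/NSB slope
  ratios of 50 (R-PE) and 0.15 (Brilliant Violet 605), the extremes of
  the surveyed dyes.
* ``rpe_bleach`` / ``alexa532_bleach`` — photobleaching stacks with
  half-lives of 2,000 s (R-PE) and 7,000 s (Alexa Fluor 532), 30 frames
  over three half-lives.

Slopes are expressed per ng/mL throughout (all concentrations in this
package are ng/mL; 1 µg/mL = 1,000 ng/mL).
"""

from __future__ import annotations

import numpy as np

from .simulate import BindingModel, OpticsConfig, SeriesDesign, SpotGeometry

__all__ = [
    "DEFAULT_OPTICS",
    "GOLD_OPTICS",
    "BLEACH_OPTICS_DETERMINISTIC",
    "DOSE_GEOMETRY",
    "SPOT_GEOMETRY",
    "RPE_BINDING",
    "BSA_DOSE_DESIGN",
    "SNSB_DESIGN",
    "SNSB_FIXTURES",
    "BLEACH_FIXTURES",
]

#: Default phone-camera model: 8-bit, dark fluorescence background of
#: 20 DN, 2 DN Gaussian read noise, reference exposure 1/15 s (the
#: camera app's exposure cap).
DEFAULT_OPTICS = OpticsConfig(
    width_px=128,
    height_px=96,
    bit_depth=8,
    background_dn=20.0,
    read_noise_dn=2.0,
    shot_noise=False,
    reference_exposure_s=1.0 / 15.0,
)

#: Reflectance (flash) imaging of gold strips: bright green background.
GOLD_OPTICS = OpticsConfig(
    width_px=128,
    height_px=96,
    bit_depth=8,
    background_dn=(30.0, 180.0, 30.0),
    read_noise_dn=2.0,
    shot_noise=False,
    reference_exposure_s=1.0 / 15.0,
)

#: Deep, noiseless camera for the deterministic photobleaching
#: benchmark: isolates the log-linear estimator from quantization.
BLEACH_OPTICS_DETERMINISTIC = OpticsConfig(
    width_px=128,
    height_px=96,
    bit_depth=16,
    background_dn=2000.0,
    read_noise_dn=0.0,
    shot_noise=False,
    reference_exposure_s=1.0 / 15.0,
)

#: ~3 mm crescent test zone of a lateral-flow titration (sandwiches
#: form at the leading edge of the spot).
DOSE_GEOMETRY = SpotGeometry(
    center=(48, 64), radius_px=10.0, crescent=True, crescent_fraction=0.35,
    flank_gap_px=5,
)

#: Filled dot-blot spot (S/NSB spot arm, photobleaching spots).
SPOT_GEOMETRY = SpotGeometry(
    center=(48, 64), radius_px=10.0, crescent=False, flank_gap_px=5,
)

#: R-PE fluorescence binding truth for the BSA titration (amplitudes in
#: DN at the reference exposure; also read as optical density by the
#: absorbance renderer for the matched gold comparison).
RPE_BINDING = BindingModel(alpha=0.9, b=0.75, k_hook=6000.0, nsb_slope=0.0)

#: Four-fold series, 63 pg/mL .. 0.063 * 4**9 = 16,515.1 ng/mL (~16 µg/mL),
#: triplicate, operator-style auto exposure.
BSA_DOSE_DESIGN = SeriesDesign(
    c_min=0.063, fold=4.0, n_points=10, n_replicates=3, exposure_s="auto"
)

#: Two-fold series, 630 .. 630 * 2**6 = 40,320 ng/mL (0.63–40 µg/mL),
#: triplicate — the paired spot/strip S/NSB design.
SNSB_DESIGN = SeriesDesign(
    c_min=630.0, fold=2.0, n_points=7, n_replicates=3, exposure_s="auto"
)

#: Generative S/NSB fixtures. nsb_slope is DN per (ng/mL) of reporter;
#: equivalently 0.05 and 2.0 DN per (µg/mL). Levels are set so both
#: arms stay detectable yet unsaturated across the series under
#: auto exposure.
SNSB_FIXTURES: dict[str, dict] = {
    "rpe": {"true_snsb": 50.0, "nsb_slope": 5e-5},
    "bv605": {"true_snsb": 0.15, "nsb_slope": 2e-3},
}

#: Photobleaching fixtures: 30 frames over three half-lives.
#: ``amplitude0`` values are per-pixel DN at the reference exposure for
#: the deterministic (16-bit) and noisy (8-bit) cameras respectively.
BLEACH_FIXTURES: dict[str, dict] = {
    "rpe": {
        "half_life_s": 2000.0,
        "times_s": np.linspace(0.0, 6000.0, 30),
        "amplitude0_deterministic": 40000.0,
        "amplitude0_noisy": 200.0,
    },
    "alexa532": {
        "half_life_s": 7000.0,
        "times_s": np.linspace(0.0, 21000.0, 30),
        "amplitude0_deterministic": 40000.0,
        "amplitude0_noisy": 200.0,
    },
}
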
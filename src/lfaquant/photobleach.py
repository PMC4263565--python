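"""Photobleaching kinetics from a quantified time series.

First-order decay under constant illumination: the log-linear estimator
regresses ln(signal) on time; the decay constant is the negative slope
and the half-life is ``t_1/2 = ln 2 / k``. This matches reading the
half-life off the natural-log plot, and is the default over nonlinear
exponential least squares.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError, FitError

__all__ = ["BleachSeries", "BleachResult", "normalize_to_initial", "fit_decay"]


@dataclass
class BleachSeries:
    """Times (s, strictly increasing) and scaled signals of one spot."""

    times_s: np.ndarray
    signals: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.times_s.shape != self.signals.shape or self.times_s.ndim != 1:
            raise DomainError("times_s and signals must be equal-length 1-D arrays")
        if self.times_s.size < 3:
            raise DomainError("need >= 3 time points")
        if np.any(np.diff(self.times_s) <= 0):
            raise DomainError("times_s must be strictly increasing")


@dataclass(frozen=True)
class BleachResult:
    """Fitted first-order photobleaching kinetics.

    ``half_life_s`` is ``ln 2 / k`` when ``k > 0`` and None otherwise
    (``no_decay`` flags a flat or rising series). ``normalized`` is the
    signal as percent of the initial value (``normalized[0] == 100``).
    """

    k_per_s: float
    half_life_s: float | None
    r_squared: float
    normalized: np.ndarray
    n_used: int
    no_decay: bool = False


def normalize_to_initial(series: BleachSeries) -> np.ndarray:
    """Signals as percent of the first time point: ``100 * s / s[0]``."""
    s0 = float(series.signals[0])
    if s0 <= 0:
        raise DomainError("initial signal must be > 0 to normalize")
    return 100.0 * series.signals / s0


def fit_decay(series: BleachSeries) -> BleachResult:
    """Log-linear OLS decay fit; ``k`` is the negative slope of
    ln(signal) vs time.

    Non-positive signals cannot enter the log and are dropped with a
    warning; fewer than 3 surviving points is an error. ``k <= 0`` is
    reported as "no detectable decay" with the half-life undefined.
    """
    mask = series.signals > 0
    n_dropped = int((~mask).sum())
    if n_dropped:
        warnings.warn(
            f"{series.label or 'bleach series'}: dropping {n_dropped} "
            "non-positive signal(s) before the log transform",
            stacklevel=2,
        )
    t = series.times_s[mask]
    s = series.signals[mask]
    if t.size < 3:
        raise FitError(f"decay fit needs >= 3 positive signals, have {t.size}")
    res = stats.linregress(t, np.log(s))
    k = -float(res.slope)
    no_decay = k <= 0
    return BleachResult(
        k_per_s=k,
        half_life_s=None if no_decay else math.log(2.0) / k,
        r_squared=float(res.rvalue**2),
        normalized=normalize_to_initial(series),
        n_used=int(t.size),
        no_decay=no_decay,
    )
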
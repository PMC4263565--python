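"""Series-level statistics: linear fits, the S/NSB slope ratio,
prozone exclusion, log-log power-law calibration and range summaries.

All fits operate on per-concentration replicate means (replicate-level
weighting is deliberately out of scope). Linear fits use a free
intercept by default, with a through-origin option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, UndefinedRatioError

__all__ = [
    "DoseSeries",
    "SlopeFit",
    "SNSBResult",
    "PowerFitResult",
    "RangeSummary",
    "fit_linear",
    "snsb_ratio",
    "exclude_prozone",
    "fit_power",
    "range_summary",
    "analyze_series",
]

#: Default prozone tolerance: a concentration beyond the peak is only
#: excluded when its mean falls more than this fraction below the peak
#: mean, so noise at a flat plateau is not misread as prozone.
PROZONE_DELTA = 0.10


@dataclass
class DoseSeries:
    """Concentrations (ng/mL, strictly increasing) with replicate signals.

    ``signals[i]`` holds the replicate scaled signals measured at
    ``concentrations[i]``.
    """

    concentrations: np.ndarray
    signals: list[np.ndarray]
    mode: str = "fluorescence"
    label: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.signals = [np.atleast_1d(np.asarray(s, dtype=float)) for s in self.signals]
        if self.concentrations.ndim != 1 or self.concentrations.size == 0:
            raise FitError("concentrations must be a non-empty 1-D array")
        if np.any(self.concentrations <= 0):
            raise FitError("concentrations must be strictly positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise FitError("concentrations must be strictly increasing")
        if len(self.signals) != self.concentrations.size:
            raise FitError("signals must have one replicate array per concentration")
        if any(s.size < 1 for s in self.signals):
            raise FitError("every concentration needs >= 1 replicate")

    @property
    def mean_signals(self) -> np.ndarray:
        """Per-concentration replicate means."""
        return np.array([float(s.mean()) for s in self.signals])

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        conc_col: str = "concentration_ng_ml",
        signal_col: str = "scaled_signal",
        mode: str = "fluorescence",
        label: str = "",
        drop_saturated: bool = True,
    ) -> "DoseSeries":
        """Build a series from a quantification table (one row per image).

        Rows flagged as saturated are dropped by default before grouping
        by concentration.
        """
        df = table
        if drop_saturated and "flagged_saturated" in df.columns:
            df = df[~df["flagged_saturated"].astype(bool)]
        df = df.dropna(subset=[conc_col, signal_col])
        if df.empty:
            raise FitError("no usable rows in quantification table")
        grouped = df.groupby(conc_col)[signal_col]
        concs = np.array(sorted(grouped.groups))
        sigs = [grouped.get_group(c).to_numpy(dtype=float) for c in concs]
        if "mode" in table.columns and not table["mode"].empty:
            mode = str(table["mode"].iloc[0])
        return cls(concentrations=concs, signals=sigs, mode=mode, label=label)


@dataclass(frozen=True)
class SlopeFit:
    """An ordinary least-squares line: signal per concentration unit."""

    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class SNSBResult:
    """Signal-to-nonspecific-binding slope ratio for one dye.

    ``ratio = signal_fit.slope / nsb_fit.slope`` — a unitless,
    detector-independent dye quality statistic (a common gain applied to
    both arms cancels).
    """

    signal_fit: SlopeFit
    nsb_fit: SlopeFit
    ratio: float


@dataclass(frozen=True)
class PowerFitResult:
    """Log-log power-law calibration ``y = a * c**b``."""

    a: float
    b: float
    r_squared: float
    included: tuple[float, ...]
    excluded: tuple[tuple[float, str], ...] = ()

    def predict(self, c) -> np.ndarray | float:
        return self.a * np.asarray(c, dtype=float) ** self.b


@dataclass(frozen=True)
class RangeSummary:
    """Dynamic-range summary of a fitted calibration.

    ``fold_change = yhat(c_high) / yhat(c_low) = (c_high / c_low)**b``.
    """

    c_low: float
    c_high: float
    fold_change: float


def _mean_per_x(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ux, inverse = np.unique(x, return_inverse=True)
    means = np.bincount(inverse, weights=y) / np.bincount(inverse)
    return ux, means


def fit_linear(x: Sequence[float], y: Sequence[float], through_origin: bool = False) -> SlopeFit:
    """OLS line on (x, mean-per-x of y), free intercept by default."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FitError("x and y must be 1-D arrays of equal length")
    ux, my = _mean_per_x(x, y)
    if ux.size < 2:
        raise FitError("need >= 2 distinct x values")
    if through_origin:
        slope = float(np.dot(ux, my) / np.dot(ux, ux))
        resid = my - slope * ux
        ss_tot = float(np.dot(my, my))  # uncentered for a forced origin
        r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot > 0 else 1.0
        return SlopeFit(slope=slope, intercept=0.0, r_squared=max(0.0, min(1.0, r2)),
                        n=int(ux.size))
    res = stats.linregress(ux, my)
    return SlopeFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=int(ux.size),
    )


def snsb_ratio(
    signal_series: DoseSeries,
    nsb_series: DoseSeries,
    through_origin: bool = False,
) -> SNSBResult:
    """Ratio of the specific-signal slope to the NSB slope.

    Both series must span the same concentration design. The ratio is
    undefined (an error, with the offending fit in the message) when the
    NSB slope is not positive.
    """
    if signal_series.concentrations.size != nsb_series.concentrations.size or not np.allclose(
        signal_series.concentrations, nsb_series.concentrations
    ):
        raise FitError("signal and NSB series must share the same concentrations")
    sig = fit_linear(
        signal_series.concentrations, signal_series.mean_signals, through_origin
    )
    nsb = fit_linear(nsb_series.concentrations, nsb_series.mean_signals, through_origin)
    if nsb.slope <= 0:
        raise UndefinedRatioError(
            f"NSB slope is not positive ({nsb.slope:.4g}); S/NSB undefined. "
            f"NSB fit: intercept={nsb.intercept:.4g}, r2={nsb.r_squared:.3f}, n={nsb.n}"
        )
    return SNSBResult(signal_fit=sig, nsb_fit=nsb, ratio=sig.slope / nsb.slope)


def exclude_prozone(
    series: DoseSeries, delta: float = PROZONE_DELTA
) -> tuple[np.ndarray, list[tuple[float, str]]]:
    """Drop post-peak concentrations whose signal has hooked downward.

    Let ``c*`` be the concentration with the maximal replicate-mean
    signal. Every concentration above ``c*`` whose mean falls below
    ``(1 - delta) * mean(c*)`` is excluded with reason ``"prozone"``;
    all other concentrations (including ``c*`` itself) are kept.

    Returns ``(included_concentrations, [(concentration, reason), ...])``.
    """
    if series.concentrations.size < 4:
        raise FitError("prozone screening needs >= 4 concentrations")
    if not 0 <= delta < 1:
        raise FitError("delta must be in [0, 1)")
    means = series.mean_signals
    i_star = int(np.argmax(means))
    cutoff = (1.0 - delta) * means[i_star]
    excluded = [
        (float(c), "prozone")
        for i, c in enumerate(series.concentrations)
        if i > i_star and means[i] < cutoff
    ]
    dropped = {c for c, _ in excluded}
    included = np.array([c for c in series.concentrations if c not in dropped])
    return included, excluded


def fit_power(
    series: DoseSeries,
    excluded: Sequence[tuple[float, str]] = (),
) -> PowerFitResult:
    """Power-fit trend line: OLS of log10(mean signal) on log10(c).

    Concentrations listed in *excluded* are dropped with their stated
    reason; concentrations with non-positive mean signal are dropped
    with reason ``"nonpositive"``. At least 3 usable concentrations are
    required. Returns ``y = a * c**b`` with ``b`` the log-log slope and
    ``a = 10**intercept``.
    """
    means = series.mean_signals
    dropped = list(excluded)
    drop_set = {c for c, _ in dropped}
    keep_c, keep_y = [], []
    for c, m in zip(series.concentrations, means):
        if float(c) in drop_set:
            continue
        if m <= 0:
            dropped.append((float(c), "nonpositive"))
            continue
        keep_c.append(float(c))
        keep_y.append(float(m))
    if len(keep_c) < 3:
        raise FitError(
            f"power fit needs >= 3 usable concentrations, have {len(keep_c)} "
            f"(excluded: {dropped})"
        )
    res = stats.linregress(np.log10(keep_c), np.log10(keep_y))
    return PowerFitResult(
        a=float(10.0**res.intercept),
        b=float(res.slope),
        r_squared=float(res.rvalue**2),
        included=tuple(keep_c),
        excluded=tuple((float(c), str(r)) for c, r in dropped),
    )


def range_summary(
    fit: PowerFitResult, c_low: float | None = None, c_high: float | None = None
) -> RangeSummary:
    """Fold change of the fitted signal across a concentration range.

    Defaults to the min/max included concentrations of the fit.
    """
    c_low = min(fit.included) if c_low is None else float(c_low)
    c_high = max(fit.included) if c_high is None else float(c_high)
    if not 0 < c_low < c_high:
        raise FitError("need 0 < c_low < c_high")
    return RangeSummary(
        c_low=c_low, c_high=c_high, fold_change=float((c_high / c_low) ** fit.b)
    )


def analyze_series(
    series: DoseSeries,
    delta: float = PROZONE_DELTA,
    eval_range: tuple[float, float] | None = None,
) -> dict:
    """Prozone screen + power fit + range summary in one call.

    ``eval_range`` optionally evaluates the fold change at stated
    endpoints in addition to the included-range default.
    """
    _, excluded = exclude_prozone(series, delta)
    fit = fit_power(series, excluded)
    out = {
        "excluded": fit.excluded,
        "power_fit": fit,
        "range": range_summary(fit),
    }
    if eval_range is not None:
        out["range_at_endpoints"] = range_summary(fit, *eval_range)
    return out
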
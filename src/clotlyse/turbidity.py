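"""Turbidity-curve analysis: normalization and two-regime lysis timescales.

A turbidimetric clot-lysis assay records light attenuation once per minute.
The curve descends while the clot forms (Tyndall effect), reaches a minimum
at the clot formation time (CFT), then rises as plasmin degrades the fibrin:
first a slow, linear regime, then a fast sigmoidal one.  This module turns a
raw intensity trace into a normalized turbidity (NT) curve in [0, 1] and
extracts:

* ``cft``  — minutes to the turbidity minimum (from trace start),
* ``slt``  — slow-lysis duration (offset from CFT),
* ``flt``  — fast-lysis duration, ``tlt = slt + flt``,
* ``tlt``  — total lysis time, ending at the maximum of dNT/dt,
* ``end_of_lysis`` — first time after TLT with NT ≥ 0.95 (absolute minutes),
* ``slow_slope`` — slope of the linear fit of the slow regime (NT·min⁻¹),
* ``r_sl``/``r_fl`` — fractional contributions SLT/(SLT+FLT), FLT/(SLT+FLT).

Preprocessing follows the assay's standard recipe: keep one sample in three,
Savitzky–Golay smooth (11-point window, cubic), min–max normalize.  The slow
regime is located by a least-squares line fitted between the NT = 0.01 and
NT = 0.075 crossings after CFT; its end (SLT) is the last point, scanning
backward from TLT, whose deviation from that line is ≤ Δ (default 0.005).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .errors import (
    DegenerateTraceError,
    InsufficientWindowError,
    InvalidTraceError,
    NoLysisError,
    NoLysisWarning,
    RegimeDetectionError,
    TruncatedLysisWarning,
)

SG_WINDOW = 11  # five points each side of the point of interest
SG_ORDER = 3
FIT_LOW = 0.01
FIT_HIGH = 0.075
DELTA_DEFAULT = 0.005
END_OF_LYSIS_NT = 0.95


@dataclass(frozen=True)
class TurbidityTrace:
    """Raw turbidity readings for one channel on a uniform minute grid."""

    time: np.ndarray  # minutes
    intensity: np.ndarray  # sensor units, arbitrary
    channel_id: str = "ch0"

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        x = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "intensity", x)
        if t.ndim != 1 or x.shape != t.shape:
            raise InvalidTraceError("time and intensity must be 1-d arrays of equal length")
        if t.size < 2:
            raise InvalidTraceError("a trace needs at least 2 samples")
        if np.any(np.diff(t) <= 0):
            raise InvalidTraceError("time must be strictly increasing")
        if not np.all(np.isfinite(x)):
            raise InvalidTraceError("intensity must be finite")

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class NormalizedTrace:
    """Min–max normalized turbidity on the (sliced) time grid of its source."""

    time: np.ndarray  # minutes
    nt: np.ndarray  # dimensionless, in [0, 1]
    channel_id: str = "ch0"
    delta_turbidity: float = float("nan")  # max − min of the source, sensor units

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "nt", np.asarray(self.nt, dtype=float))

    def __len__(self) -> int:
        return self.time.size


@dataclass
class SlowFit:
    """Least-squares line through the slow-lysis window of an NT curve."""

    slope: float  # NT per minute
    intercept: float  # NT at t = 0 (absolute minutes)
    window: tuple[float, float]  # absolute minutes spanned by the fit
    residual_rms: float = 0.0

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.slope * np.asarray(t, dtype=float) + self.intercept


@dataclass
class LysisTimescales:
    """Clot-formation and two-regime lysis timescales for one curve."""

    cft: float  # minutes from trace start
    slt: float  # minutes, offset from CFT
    flt: float  # minutes
    tlt: float  # minutes, = slt + flt
    end_of_lysis: float  # absolute minutes (NaN if NT never reaches 0.95)
    slow_slope: float  # NT per minute
    r_sl: float
    r_fl: float
    delta_turbidity: float = float("nan")
    channel_id: str = "ch0"
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# preprocessing

def slice_trace(trace: TurbidityTrace, keep_every: int = 3) -> TurbidityTrace:
    """Keep one sample out of ``keep_every``, starting at index 0.

    Discards minute-to-minute fluctuations before smoothing.  ``keep_every=1``
    returns the trace unchanged.
    """
    if keep_every < 1:
        raise InvalidTraceError(f"keep_every must be >= 1, got {keep_every}")
    if keep_every == 1:
        return trace
    idx = np.arange(0, len(trace), keep_every)
    if idx.size < 2:
        raise InvalidTraceError("slicing leaves fewer than 2 samples")
    return TurbidityTrace(trace.time[idx], trace.intensity[idx], trace.channel_id)


def smooth_trace(trace: TurbidityTrace) -> TurbidityTrace:
    """Savitzky–Golay filter: 11-point window, cubic polynomial.

    A third-order fit preserves the changes in concavity around the clotting
    minimum and the fast-lysis inflection.  Boundaries are mirror-padded
    (scipy ``mode='mirror'``) so the clotting minimum near the start of a
    trace is not flattened by edge effects.
    """
    if len(trace) < SG_WINDOW:
        raise InvalidTraceError(
            f"smoothing needs >= {SG_WINDOW} samples, got {len(trace)}"
        )
    y = savgol_filter(trace.intensity, SG_WINDOW, SG_ORDER, mode="mirror")
    return TurbidityTrace(trace.time, y, trace.channel_id)


def normalize_trace(trace: TurbidityTrace) -> NormalizedTrace:
    """Map intensity affinely onto [0, 1]: nt = (x − min)/(max − min)."""
    x = trace.intensity
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise DegenerateTraceError("constant trace cannot be normalized")
    return NormalizedTrace(
        trace.time, (x - lo) / (hi - lo), trace.channel_id, delta_turbidity=hi - lo
    )


def preprocess(trace: TurbidityTrace, keep_every: int = 3) -> NormalizedTrace:
    """slice → smooth → normalize, the standard NT pipeline."""
    return normalize_trace(smooth_trace(slice_trace(trace, keep_every)))


# ---------------------------------------------------------------------------
# regime detectors

def detect_cft(nt: NormalizedTrace) -> float:
    """Time of the global NT minimum (earliest on ties), from trace start.

    Warns (``NoLysisWarning``) when the minimum sits on the final sample:
    the curve never turned around, so no lysis is observable.
    """
    i = int(np.argmin(nt.nt))
    if i == len(nt) - 1:
        warnings.warn(
            "turbidity minimum at the final sample; no lysis observed",
            NoLysisWarning,
            stacklevel=2,
        )
    return float(nt.time[i] - nt.time[0])


def _cft_index(nt: NormalizedTrace) -> int:
    return int(np.argmin(nt.nt))


def fit_slow_regime(
    nt: NormalizedTrace, fit_low: float = FIT_LOW, fit_high: float = FIT_HIGH
) -> SlowFit:
    """Least-squares line through the slow-lysis window of the NT curve.

    The window spans the first post-CFT sample with NT ≥ ``fit_low`` through
    the first post-CFT sample with NT ≥ ``fit_high``.  Those two levels do
    not define the slow regime; they only bound a stretch that is safely
    inside it.
    """
    i0 = _cft_index(nt)
    t, y = nt.time, nt.nt
    after = np.arange(i0, len(nt))
    low_hits = after[y[after] >= fit_low]
    high_hits = after[y[after] >= fit_high]
    if high_hits.size == 0:
        raise NoLysisError(f"NT never reaches {fit_high} after CFT")
    if low_hits.size == 0:
        raise NoLysisError(f"NT never reaches {fit_low} after CFT")
    i_lo, i_hi = int(low_hits[0]), int(high_hits[0])
    if i_hi - i_lo + 1 < 3:
        raise InsufficientWindowError(
            f"only {i_hi - i_lo + 1} samples between the NT={fit_low} and "
            f"NT={fit_high} crossings"
        )
    tw, yw = t[i_lo : i_hi + 1], y[i_lo : i_hi + 1]
    slope, intercept = np.polyfit(tw, yw, 1)
    resid = yw - (slope * tw + intercept)
    return SlowFit(
        slope=float(slope),
        intercept=float(intercept),
        window=(float(tw[0]), float(tw[-1])),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def detect_tlt(nt: NormalizedTrace) -> float:
    """Total lysis time: max of dNT/dt after CFT, as an offset from CFT.

    The derivative is estimated by central differences (``np.gradient``) on
    the already-smoothed NT curve; ties break to the earliest time.  Warns
    when the maximum falls on the last sample (lysis truncated by the end of
    the record).
    """
    i0 = _cft_index(nt)
    if len(nt) - i0 < 3:
        raise RegimeDetectionError("fewer than 3 samples after CFT")
    t, y = nt.time, nt.nt
    d = np.gradient(y, t)
    j = i0 + 1 + int(np.argmax(d[i0 + 1 :]))  # strictly after the minimum
    if j == len(nt) - 1:
        warnings.warn(
            "derivative maximum at the last sample; lysis truncated",
            TruncatedLysisWarning,
            stacklevel=2,
        )
    return float(t[j] - t[i0])


def detect_slow_regime_end(
    nt: NormalizedTrace, fit: SlowFit, delta: float = DELTA_DEFAULT, tlt: float | None = None
) -> float:
    """Slow-lysis time: where the NT curve leaves the slow-regime line.

    Scanning backward in time from the TLT point, the end of the slow regime
    is the latest sample whose deviation from the fitted line is ≤ ``delta``
    — i.e. the last point still on the line; everything later belongs to the
    fast regime.  Returned as an offset from CFT.
    """
    i0 = _cft_index(nt)
    if tlt is None:
        tlt = detect_tlt(nt)
    t, y = nt.time, nt.nt
    t_tlt = t[i0] + tlt
    j_tlt = int(np.searchsorted(t, t_tlt))
    j_tlt = min(j_tlt, len(nt) - 1)
    dev = np.abs(y - fit(t))
    for j in range(j_tlt, i0 - 1, -1):
        if dev[j] <= delta:
            return float(t[j] - t[i0])
    raise RegimeDetectionError(
        f"no point between CFT and TLT within {delta} of the slow-regime line"
    )


def compute_timescales(
    nt: NormalizedTrace,
    keep_every_preapplied: bool = True,
    delta: float = DELTA_DEFAULT,
    fit_low: float = FIT_LOW,
    fit_high: float = FIT_HIGH,
) -> LysisTimescales:
    """Run all detectors on a normalized curve and assemble the timescales.

    ``flt = tlt − slt``; ``r_sl = slt/(slt+flt)``; ``end_of_lysis`` is the
    first absolute time after the TLT point with NT ≥ 0.95 (NaN if never
    reached).
    """
    flags: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cft = detect_cft(nt)
        fit = fit_slow_regime(nt, fit_low, fit_high)
        tlt = detect_tlt(nt)
        slt = detect_slow_regime_end(nt, fit, delta, tlt=tlt)
    for w in caught:
        flags.append(type(w.message).__name__)
    if slt > tlt:
        raise RegimeDetectionError(f"slt={slt} exceeds tlt={tlt}")
    flt = tlt - slt
    total = slt + flt
    r_sl = slt / total if total > 0 else float("nan")
    t0 = nt.time[0]
    t_after = nt.time >= (t0 + cft + tlt)
    reached = t_after & (nt.nt >= END_OF_LYSIS_NT)
    end_of_lysis = float(nt.time[reached][0] - t0) if np.any(reached) else float("nan")
    return LysisTimescales(
        cft=cft,
        slt=float(slt),
        flt=float(flt),
        tlt=float(tlt),
        end_of_lysis=end_of_lysis,
        slow_slope=fit.slope,
        r_sl=float(r_sl),
        r_fl=float(1.0 - r_sl),
        delta_turbidity=nt.delta_turbidity,
        channel_id=nt.channel_id,
        flags=flags,
    )


def analyze_trace(
    trace: TurbidityTrace,
    keep_every: int = 3,
    delta: float = DELTA_DEFAULT,
    fit_low: float = FIT_LOW,
    fit_high: float = FIT_HIGH,
) -> LysisTimescales:
    """Full pipeline: preprocess a raw trace and extract its timescales."""
    nt = preprocess(trace, keep_every)
    return compute_timescales(nt, delta=delta, fit_low=fit_low, fit_high=fit_high)


# ---------------------------------------------------------------------------
# I/O

def read_traces_csv(path) -> list[TurbidityTrace]:
    """Read long-format CSV with columns time_min, channel, intensity."""
    df = pd.read_csv(path)
    required = {"time_min", "channel", "intensity"}
    if not required.issubset(df.columns):
        raise InvalidTraceError(
            f"CSV must have columns {sorted(required)}, found {list(df.columns)}"
        )
    traces = []
    for ch, grp in df.groupby("channel", sort=False):
        grp = grp.sort_values("time_min")
        traces.append(
            TurbidityTrace(
                grp["time_min"].to_numpy(float),
                grp["intensity"].to_numpy(float),
                str(ch),
            )
        )
    return traces


def write_traces_csv(traces: list[TurbidityTrace], path) -> None:
    frames = [
        pd.DataFrame(
            {"time_min": tr.time, "channel": tr.channel_id, "intensity": tr.intensity}
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_report(results: list[LysisTimescales], path) -> None:
    """Write a per-channel JSON report (list of timescale records)."""
    with open(path, "w") as fh:
        json.dump([r.as_dict() for r in results], fh, indent=2)
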
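"""fPSP and population-spike quantifiers.

* ``fpsp_slope`` — tangent (ordinary least squares line) fitted to the
  falling phase of the negative fPSP, by default over the window where the
  trace falls from 20% to 80% of its negative extremum; reported as a
  positive magnitude in mV/ms (signed value kept in the diagnostics).
* ``detect_ps`` — population-spike detection by the peak-trough-peak
  construction: the PS amplitude is the vertical distance between the
  negative trough and the straight line connecting the flanking positive
  peaks, maximized over candidate triples; present iff >= 30 µV.
* ``positive_fpsp_amplitude`` — maximal positive deflection after blanking;
  present iff >= 50 µV.
* ``paired_pulse_ratio`` — slope2/slope1 with a minimum-slope guard.
* ``per_intensity_features`` — parameter-level averaging over the protocol
  repeats (parameters first, then average); PS presence aggregated by
  majority across repeats.

Both slope and PS amplitude are invariant to additive DC offsets and
equivariant under positive scaling of the trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .epochs import EvokedEpoch

__all__ = [
    "SlopeFit", "PsResult", "fpsp_slope", "detect_ps",
    "positive_fpsp_amplitude", "paired_pulse_ratio", "per_intensity_features",
    "MIN_PS_UV", "MIN_POS_FPSP_UV", "MIN_PPR_SLOPE",
]

MIN_PS_UV = 30.0        # µV, PS detection level
MIN_POS_FPSP_UV = 50.0  # µV, positive fPSP detection level
MIN_PPR_SLOPE = 0.01    # mV/ms, guard against ratio blow-up


def _trace_fs_blank(epoch, fs_hz, blank_ms):
    if isinstance(epoch, EvokedEpoch):
        return epoch.trace_uv, epoch.fs_hz, epoch.blank_ms
    if fs_hz is None:
        raise ValueError("fs_hz required when passing a raw trace")
    return np.asarray(epoch, float), fs_hz, (blank_ms if blank_ms is not None else 0.0)


@dataclass(frozen=True)
class SlopeFit:
    slope_mv_per_ms: float   # magnitude
    signed_slope: float
    t_start_ms: float
    t_end_ms: float
    n_points: int
    r2: float
    quality: str             # 'ok' | 'low_amplitude' | 'short_window'


def fpsp_slope(epoch, fs_hz: float | None = None, blank_ms: float | None = None,
               frac: tuple[float, float] = (0.2, 0.8),
               noise_floor_uv: float = 15.0) -> SlopeFit:
    """Tangent-fit slope of the negative fPSP falling phase (mV/ms).

    The fit window spans the samples where the trace falls from
    ``frac[0]`` to ``frac[1]`` of the negative extremum.  A non-negative
    extremum or one below the noise floor yields a low-quality flag, never an
    exception.
    """
    y_uv, fs, bl = _trace_fs_blank(epoch, fs_hz, blank_ms)
    t = np.arange(len(y_uv)) / fs * 1000.0
    start = int(round(bl * fs / 1000.0))
    y = y_uv[start:] / 1000.0          # mV
    tt = t[start:]
    # reference the extremum to the first post-blank sample so the fit
    # window (and hence the slope) is invariant to additive DC offsets
    y = y - y[0]
    quality = "ok"
    imin = int(np.argmin(y))
    vmin = y[imin]
    if vmin >= -noise_floor_uv / 1000.0:
        quality = "low_amplitude"
    if imin == 0:
        return SlopeFit(0.0, 0.0, float(tt[0]), float(tt[0]), 0, 0.0,
                        "low_amplitude")
    lo, hi = frac[0] * vmin, frac[1] * vmin
    before = y[: imin + 1]
    above = np.nonzero(before > lo)[0]
    w0 = int(above[-1]) + 1 if len(above) else 0
    tseg = tt[max(0, w0 - 1): imin + 1]
    yseg = y[max(0, w0 - 1): imin + 1]

    def _crossing(level: float) -> float:
        """Interpolated time of the first downward crossing of ``level``."""
        below = np.nonzero(yseg <= level)[0]
        j = int(below[0])
        if j == 0:
            return float(tseg[0])
        f = (level - yseg[j - 1]) / (yseg[j] - yseg[j - 1])
        return float(tseg[j - 1] + f * (tseg[j] - tseg[j - 1]))

    t_lo, t_hi = _crossing(lo), _crossing(hi)
    n_raw = int(np.sum((tseg >= t_lo) & (tseg <= t_hi)))
    if t_hi <= t_lo:
        # degenerate window: two-point secant over the descent
        quality = "short_window" if quality == "ok" else quality
        tw = np.array([tseg[0], tseg[-1]])
        yw = np.array([yseg[0], yseg[-1]])
    else:
        # fit on the interpolated falling segment between the exact 20%/80%
        # crossings, which removes the sample-quantization of the window
        tw = np.linspace(t_lo, t_hi, max(50, 4 * max(n_raw, 1)))
        yw = np.interp(tw, tseg, yseg)
    coef = np.polyfit(tw, yw, 1)
    fit = np.polyval(coef, tw)
    ss_res = float(np.sum((yw - fit) ** 2))
    ss_tot = float(np.sum((yw - yw.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SlopeFit(slope_mv_per_ms=float(abs(coef[0])), signed_slope=float(coef[0]),
                    t_start_ms=float(tw[0]), t_end_ms=float(tw[-1]),
                    n_points=n_raw, r2=r2, quality=quality)


@dataclass(frozen=True)
class PsResult:
    present: bool
    amp_uv: float
    amp_mv: float
    t_peak1_ms: float
    t_trough_ms: float
    t_peak2_ms: float


_NO_PS = PsResult(False, 0.0, 0.0, float("nan"), float("nan"), float("nan"))


def detect_ps(epoch, fs_hz: float | None = None, blank_ms: float | None = None,
              min_ps_uv: float = MIN_PS_UV,
              search_window_ms: tuple[float, float] = (0.3, 8.0),
              invert: bool = False, smooth_ms: float = 0.0,
              min_prominence_uv: float = 0.0) -> PsResult:
    """Population-spike detection on a positive-carrier epoch.

    Searches for a local negative trough between two local positive maxima,
    with the trough restricted to ``search_window_ms`` after the blanking
    window.  The amplitude is the vertical distance from the trough to the
    straight line connecting the nearest flanking peaks (the peaks the PS
    notch itself carves into the fPSP envelope); with several candidate
    troughs, the one with maximal amplitude wins (documented tie-break).

    ``invert`` flips the trace first (detects the positive PS reflection on
    dendritic, negative-carrier channels); ``smooth_ms`` applies a boxcar
    before the extrema search and ``min_prominence_uv`` drops extrema whose
    prominence is below the floor (both 0 = off; the pipeline uses light
    smoothing plus a 10 µV prominence floor on noisy single repeats, so a
    noise wiggle inside the PS notch cannot masquerade as a flanking peak).
    Fewer than two positive maxima means no PS — not an error.
    """
    y_uv, fs, bl = _trace_fs_blank(epoch, fs_hz, blank_ms)
    y = -np.asarray(y_uv, float) if invert else np.asarray(y_uv, float)
    start = int(round(bl * fs / 1000.0))
    y = y[start:]
    if smooth_ms > 0:
        w = max(1, int(round(smooth_ms * fs / 1000.0)))
        y = np.convolve(y, np.ones(w) / w, mode="same")
    t = np.arange(len(y)) / fs * 1000.0
    prom = min_prominence_uv if min_prominence_uv > 0 else None
    peaks, _ = find_peaks(y, prominence=prom)
    troughs, _ = find_peaks(-y, prominence=prom)
    lo, hi = search_window_ms
    # extrema inside the settling margin right after the blanking window are
    # interpolation/smoothing edge effects, not response features
    peaks = peaks[t[peaks] >= lo]
    troughs = troughs[(t[troughs] >= lo) & (t[troughs] <= hi)]
    if len(peaks) < 2 or len(troughs) == 0:
        return _NO_PS
    best = _NO_PS
    for j in troughs:
        left = peaks[peaks < j]
        right = peaks[peaks > j]
        if not len(left) or not len(right):
            continue
        i, k = left[-1], right[0]
        line = y[i] + (y[k] - y[i]) * (t[j] - t[i]) / (t[k] - t[i])
        amp = float(line - y[j])
        if amp > best.amp_uv:
            best = PsResult(False, amp, amp / 1000.0,
                            float(t[i]), float(t[j]), float(t[k]))
    present = best.amp_uv >= min_ps_uv
    return PsResult(present, best.amp_uv, best.amp_mv, best.t_peak1_ms,
                    best.t_trough_ms, best.t_peak2_ms)


def positive_fpsp_amplitude(epoch, fs_hz: float | None = None,
                            blank_ms: float | None = None,
                            min_fpsp_uv: float = MIN_POS_FPSP_UV
                            ) -> tuple[float, bool]:
    """Maximal positive deflection (µV) after blanking; present iff >= 50 µV."""
    y_uv, fs, bl = _trace_fs_blank(epoch, fs_hz, blank_ms)
    start = int(round(bl * fs / 1000.0))
    amp = float(max(0.0, y_uv[start:].max())) if len(y_uv) > start else 0.0
    return amp, amp >= min_fpsp_uv


def paired_pulse_ratio(slope1: float, slope2: float,
                       min_slope: float = MIN_PPR_SLOPE) -> tuple[float, str]:
    """slope2/slope1 (>1 facilitation, <1 depression); NaN below the guard."""
    if not np.isfinite(slope1) or slope1 < min_slope:
        return float("nan"), "slope1_below_guard"
    return float(slope2 / slope1), "ok"


def majority_present(flags) -> bool:
    """Presence by majority over repeats; exact ties count as present."""
    flags = [bool(f) for f in flags]
    return sum(flags) * 2 >= len(flags) if flags else False


_MEAN_COLS = ("neg_amp_uv", "slope", "r2", "pos_amp_uv")


def per_intensity_features(df: pd.DataFrame,
                           group_cols=("channel_id", "intensity_mv", "pulse")
                           ) -> pd.DataFrame:
    """Average repeat-level feature rows per intensity (parameter level).

    Numeric parameters are averaged arithmetically over repeats; PS presence
    is aggregated by majority (present iff at least 2 of 3); PS amplitude is
    averaged over the repeats where a PS is present.  Rows with a single
    repeat are flagged via ``n_repeats``.
    """
    if df.empty:
        return df.copy()
    out_rows = []
    for key, sub in df.groupby(list(group_cols), sort=True):
        row = dict(zip(group_cols, key))
        row["n_repeats"] = len(sub)
        for c in _MEAN_COLS:
            if c in sub.columns:
                row[c] = float(sub[c].mean())
        if "ps_present" in sub.columns:
            present = majority_present(sub.ps_present)
            row["ps_present"] = present
            if "ps_amp_uv" in sub.columns:
                amps = sub.loc[sub.ps_present.astype(bool), "ps_amp_uv"]
                row["ps_amp_uv"] = float(amps.mean()) if present and len(amps) else 0.0
        if "pos_present" in sub.columns:
            row["pos_present"] = majority_present(sub.pos_present)
        if "artifact_ok" in sub.columns:
            row["artifact_ok"] = bool(sub.artifact_ok.all())
        for c in ("region_label", "slice_id", "step"):
            if c in sub.columns:
                row[c] = sub[c].iloc[0]
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def epoch_features(ep: EvokedEpoch, region_label: str,
                   noise_floor_uv: float = 15.0,
                   ps_smooth_ms: float = 0.2) -> dict:
    """All per-epoch features relevant to the channel's layer.

    Dendritic channels get the negative-fPSP amplitude, tangent slope and an
    inverted-polarity PS check (for the 'pure slope' selection rule); axonal
    channels get the positive fPSP amplitude and PS detection.  The
    ``artifact_ok`` flag checks that the first post-blank sample is within
    3x the pre-stimulus noise SD of baseline (residual artifact screen).
    """
    start = int(round(ep.blank_ms * ep.fs_hz / 1000.0))
    resid = abs(float(ep.trace_uv[start])) if len(ep.trace_uv) > start else 0.0
    artifact_ok = resid < max(3.0 * ep.baseline_sd_uv, 15.0)
    row = {"channel_id": ep.channel_id, "intensity_mv": ep.intensity_mv,
           "repeat": ep.repeat, "pulse": ep.pulse, "region_label": region_label,
           "artifact_ok": artifact_ok}
    if region_label == "dendritic":
        fit = fpsp_slope(ep, noise_floor_uv=noise_floor_uv)
        ps = detect_ps(ep, invert=True, smooth_ms=ps_smooth_ms,
                       min_prominence_uv=10.0)
        row.update(neg_amp_uv=float(-ep.trace_uv[start:].min()),
                   slope=fit.slope_mv_per_ms, r2=fit.r2,
                   slope_quality=fit.quality,
                   ps_present=ps.present, ps_amp_uv=ps.amp_uv)
    elif region_label == "axonal":
        amp, present = positive_fpsp_amplitude(ep)
        ps = detect_ps(ep, smooth_ms=ps_smooth_ms, min_prominence_uv=10.0)
        row.update(pos_amp_uv=amp, pos_present=present,
                   ps_present=ps.present, ps_amp_uv=ps.amp_uv)
    return row
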
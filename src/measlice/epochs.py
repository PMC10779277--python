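"""Stimulus-aligned epoch extraction with artifact blanking.

One :class:`EvokedEpoch` per (channel, intensity, repeat, pulse).  Samples in
the blanking window ``[onset, onset + blank_ms)`` are replaced by linear
interpolation between the flanking samples; every epoch is baseline-corrected
by the mean of the 2 ms preceding pulse-1 onset.  A model-based correction of
the pulse-1 tail under the pulse-2 epoch (exponential fit to the late decay
of pulse 1) is available but off by default, since conventional practice
quantifies the 20 ms-ISI second response on the raw trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import SliceRecording

__all__ = ["EvokedEpoch", "extract_epochs", "average_epochs"]


@dataclass
class EvokedEpoch:
    """Single-channel stimulus-aligned trace (µV), blanked and baselined."""

    trace_uv: np.ndarray
    fs_hz: float
    channel_id: int
    intensity_mv: int
    repeat: int           # 1-based
    pulse: int            # 1 or 2
    blank_ms: float
    baseline_sd_uv: float  # noise estimate from the pre-stimulus window

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(len(self.trace_uv)) / self.fs_hz * 1000.0


def _blank(seg: np.ndarray, flank_before: float, blank_n: int) -> None:
    """Replace seg[:blank_n] by linear interpolation flank_before -> seg[blank_n]."""
    if blank_n <= 0:
        return
    if blank_n >= len(seg):
        raise ValueError("blanking window must be shorter than the epoch")
    after = seg[blank_n]
    seg[:blank_n] = flank_before + (after - flank_before) * (
        np.arange(1, blank_n + 1) / (blank_n + 1))


def _tail_model(ep1: np.ndarray, fs_hz: float, isi_n: int, n_out: int) -> np.ndarray:
    """Extrapolate the pulse-1 decay tail under the pulse-2 window.

    Fits ``a * exp(-t/tau)`` to the last quarter of the pulse-1 epoch and
    continues it over the pulse-2 window; returns zeros if the tail is not a
    decaying deflection.
    """
    n = len(ep1)
    seg = ep1[3 * n // 4:]
    t = np.arange(len(seg)) / fs_hz * 1000.0
    s = np.sign(np.median(seg)) or 1.0
    y = s * seg
    if (y <= 0).any() or len(y) < 4:
        return np.zeros(n_out)
    b, loga = np.polyfit(t, np.log(y), 1)
    if b >= 0:
        return np.zeros(n_out)
    t2 = (np.arange(n_out) + (isi_n - 3 * n // 4)) / fs_hz * 1000.0
    return s * np.exp(loga + b * t2)


def extract_epochs(rec: SliceRecording, window_ms: float | None = None,
                   blank_ms: float = 1.5, baseline_ms: float = 2.0,
                   tail_subtraction: bool = False,
                   channels=None, intensities=None) -> list[EvokedEpoch]:
    """Cut one epoch per (channel, intensity, repeat, pulse).

    ``window_ms`` defaults to the interstimulus interval and must not exceed
    it for pulse 1.  ``channels`` / ``intensities`` restrict extraction (all
    by default).  Raises if any epoch would exceed the recording bounds,
    naming the stimulation event.
    """
    fs = rec.fs_hz
    isi_ms = rec.protocol.isi_ms
    if window_ms is None:
        window_ms = isi_ms
    if window_ms > isi_ms:
        raise ValueError("pulse-1 window must not exceed the interstimulus interval")
    win_n = int(round(window_ms * fs / 1000.0))
    blank_n = int(round(blank_ms * fs / 1000.0))
    base_n = int(round(baseline_ms * fs / 1000.0))
    if blank_n >= win_n:
        raise ValueError("blanking window must be shorter than the epoch")
    isi_n = rec.pulse2_offset_samples()
    n = rec.n_samples
    ch_sel = (np.arange(rec.layout.n_channels) if channels is None
              else np.asarray(sorted(channels), int))
    out: list[EvokedEpoch] = []
    for (inten, rep) in sorted(rec.stim_times):
        if intensities is not None and inten not in intensities:
            continue
        o = rec.stim_times[(inten, rep)]
        if o - base_n < 0 or o + isi_n + win_n > n:
            raise ValueError(f"epoch for stim event (intensity={inten} mV, "
                             f"repeat={rep}) exceeds recording bounds")
        base = rec.voltage[ch_sel, max(0, o - base_n):o]
        baseline = base.mean(axis=1) if base.shape[1] else np.zeros(len(ch_sel))
        base_sd = base.std(axis=1) if base.shape[1] else np.zeros(len(ch_sel))
        p1_traces: dict[int, np.ndarray] = {}
        for pulse, oo in ((1, o), (2, o + isi_n)):
            seg_all = rec.voltage[ch_sel, oo:oo + win_n] - baseline[:, None]
            flanks = rec.voltage[ch_sel, oo - 1] - baseline
            for i, ch in enumerate(ch_sel):
                seg = seg_all[i].copy()
                _blank(seg, flanks[i], blank_n)
                if pulse == 1:
                    p1_traces[i] = seg
                elif tail_subtraction:
                    seg = seg - _tail_model(p1_traces[i], fs, isi_n, len(seg))
                out.append(EvokedEpoch(trace_uv=seg, fs_hz=fs, channel_id=int(ch),
                                       intensity_mv=int(inten), repeat=int(rep),
                                       pulse=pulse, blank_ms=blank_ms,
                                       baseline_sd_uv=float(base_sd[i])))
    return out


def average_epochs(epochs: list[EvokedEpoch]) -> list[tuple[EvokedEpoch, int]]:
    """Pointwise mean over repeats per (channel, intensity, pulse).

    Returns ``(averaged_epoch, n_repeats)`` pairs (repeat set to 0).  Used for
    display and channel search only — analysis parameters are averaged at the
    parameter level, not the waveform level.  Raises on mixed trace lengths.
    """
    groups: dict[tuple[int, int, int], list[EvokedEpoch]] = {}
    for ep in epochs:
        groups.setdefault((ep.channel_id, ep.intensity_mv, ep.pulse), []).append(ep)
    out = []
    for key in sorted(groups):
        eps = groups[key]
        lengths = {len(e.trace_uv) for e in eps}
        if len(lengths) != 1:
            raise ValueError(f"mixed epoch lengths for {key}: {sorted(lengths)}")
        mean = np.mean([e.trace_uv for e in eps], axis=0)
        proto = eps[0]
        out.append((EvokedEpoch(trace_uv=mean, fs_hz=proto.fs_hz,
                                channel_id=proto.channel_id,
                                intensity_mv=proto.intensity_mv, repeat=0,
                                pulse=proto.pulse, blank_ms=proto.blank_ms,
                                baseline_sd_uv=float(np.mean([e.baseline_sd_uv
                                                              for e in eps]))),
                    len(eps)))
    return out
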
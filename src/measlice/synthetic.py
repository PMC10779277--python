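"""Synthetic MEA slice recordings with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every pipeline stage can be tested against known truth:

* evoked waveforms: the field postsynaptic potential (fPSP) is an alpha
  kernel ``A * (t/tau) * exp(1 - t/tau)`` — negative in the dendritic layer,
  positive (scaled) in the axonal layer; the population spike (PS) is a
  Gaussian transient of opposite sign superimposed on the positive carrier;
  the stimulation artifact is an exponential decay at both pulse onsets;
* intensity dependence: fPSP slope grows linearly with the 250 mV intensity
  step inside the tested range, with slice-specific random intercept and
  gain; the second pulse of each pair scales by the slice's paired-pulse
  ratio;
* PS recruitment: per-intensity Bernoulli occurrence with logistic
  probability in the step index, with animal- and slice-level logit offsets;
  PS amplitude grows linearly per step and decays exponentially with
  distance from the axonal focus electrode (``spatial_spread_um``);
* clustering: animal-level effects are shared by that animal's slices;
  per-slice random streams derive from the master seed via
  ``numpy.random.SeedSequence(seed, spawn_key=(group_idx, animal_idx,
  slice_idx))``, so cohorts are reproducible piecewise.

``sample_cohort_features`` draws the per-slice, per-intensity *feature table*
from the same hierarchical model without rendering voltage, which is what the
statistical recovery and power simulations run on.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .core_io import (REGIONS, ChannelLayout, SliceRecording, StimProtocol)

__all__ = [
    "PsSpec",
    "WaveformTruth",
    "make_waveform",
    "GroupParams",
    "default_group_params",
    "CohortConfig",
    "SliceTruth",
    "CohortResult",
    "simulate_slice",
    "simulate_cohort",
    "sample_cohort_features",
    "SPATIAL_INTENSITIES",
]

#: intensities at which the spatial hilar analysis is evaluated
SPATIAL_INTENSITIES = (1250, 2000, 2750, 3500)


# ---------------------------------------------------------------------------
# waveform primitives and dense analytic truth
# ---------------------------------------------------------------------------

def _alpha_kernel(t_ms: np.ndarray, tau_ms: float) -> np.ndarray:
    """Unit-peak alpha kernel; peaks at t = tau with value 1."""
    out = np.zeros_like(t_ms, dtype=float)
    pos = t_ms > 0
    x = t_ms[pos] / tau_ms
    out[pos] = x * np.exp(1.0 - x)
    return out


def _gaussian(t_ms: np.ndarray, latency_ms: float, width_ms: float) -> np.ndarray:
    return np.exp(-0.5 * ((t_ms - latency_ms) / width_ms) ** 2)


def _dense_tangent_slope(y_mv: np.ndarray, t_ms: np.ndarray,
                         frac: tuple[float, float] = (0.2, 0.8)) -> float:
    """Least-squares tangent to the falling phase toward the negative extremum.

    Dense-grid evaluation used for generator truth; returns the slope
    magnitude in mV/ms (0 when there is no negative extremum).
    """
    imin = int(np.argmin(y_mv))
    vmin = y_mv[imin]
    if vmin >= 0:
        return 0.0
    lo, hi = frac[0] * vmin, frac[1] * vmin   # lo closer to 0, hi deeper
    before = y_mv[: imin + 1]
    above = np.nonzero(before > lo)[0]
    start = int(above[-1]) + 1 if len(above) else 0
    seg = slice(start, imin + 1)
    mask = (y_mv[seg] <= lo) & (y_mv[seg] >= hi)
    tt, yy = t_ms[seg][mask], y_mv[seg][mask]
    if len(tt) < 2:
        return float(abs(vmin / (t_ms[imin] - t_ms[start]))) if imin > start else 0.0
    a = np.polyfit(tt, yy, 1)[0]
    return float(abs(a))


def _local_maxima(y: np.ndarray) -> np.ndarray:
    return np.nonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:]))[0] + 1


def _dense_ps_amplitude(y_uv: np.ndarray, t_ms: np.ndarray,
                        t_window: tuple[float, float] | None = None) -> float:
    """Peak-trough-peak PS amplitude (µV) on a dense noiseless trace.

    Amplitude is the vertical distance between the trough and the straight
    line connecting the nearest flanking positive peaks, maximized over
    candidate troughs (same construction the feature module applies).
    """
    peaks = _local_maxima(y_uv)
    troughs = _local_maxima(-y_uv)
    if t_window is not None:
        troughs = troughs[(t_ms[troughs] >= t_window[0]) & (t_ms[troughs] <= t_window[1])]
    best = 0.0
    for j in troughs:
        left = peaks[peaks < j]
        right = peaks[peaks > j]
        if not len(left) or not len(right):
            continue
        i, k = left[-1], right[0]
        line = y_uv[i] + (y_uv[k] - y_uv[i]) * (t_ms[j] - t_ms[i]) / (t_ms[k] - t_ms[i])
        best = max(best, float(line - y_uv[j]))
    return best


@lru_cache(maxsize=64)
def unit_kernel_slope(tau_ms: float, frac: tuple[float, float] = (0.2, 0.8)) -> float:
    """Tangent-fit slope (mV/ms) of a unit-amplitude negative alpha kernel."""
    t = np.arange(0.0, max(20.0, 8 * tau_ms), 0.002)
    return _dense_tangent_slope(-_alpha_kernel(t, tau_ms), t, frac)


@dataclass(frozen=True)
class PsSpec:
    """Population-spike transient: amplitude (mV), latency and width (ms)."""

    amp_mv: float
    latency_ms: float
    width_ms: float


@dataclass(frozen=True)
class WaveformTruth:
    """Analytic (dense-grid) feature values of a generated waveform."""

    slope_mv_per_ms: float
    peak_mv: float
    pos_amp_uv: float
    ps_amp_uv: float


def _compose_mv(t_ms: np.ndarray, kind: str, amplitude_mv: float, tau_ms: float,
                ps: PsSpec | None) -> np.ndarray:
    sign = -1.0 if kind == "neg_fpsp" else 1.0
    y = sign * amplitude_mv * _alpha_kernel(t_ms, tau_ms)
    if ps is not None and ps.amp_mv > 0:
        # PS has the opposite sign of the carrying fPSP
        y -= sign * ps.amp_mv * _gaussian(t_ms, ps.latency_ms, ps.width_ms)
    return y


def make_waveform(kind: str, amplitude_mv: float, tau_ms: float, fs_hz: float,
                  duration_ms: float = 20.0,
                  ps: PsSpec | None = None) -> tuple[np.ndarray, WaveformTruth]:
    """Single-channel evoked trace (µV) plus its dense-grid truth values.

    ``kind`` is ``neg_fpsp`` (dendritic) or ``pos_fpsp`` (axonal).  The truth
    is evaluated on a 500 kHz grid with the same tangent-fit and
    peak-trough-peak constructions the feature module applies to sampled data.
    """
    if kind not in ("neg_fpsp", "pos_fpsp"):
        raise ValueError(f"unknown waveform kind '{kind}'")
    if amplitude_mv < 0:
        raise ValueError("amplitude must be >= 0")
    if duration_ms < 20.0:
        raise ValueError("duration must be >= 20 ms")
    if ps is not None and ps.latency_ms >= duration_ms:
        raise ValueError("PS latency beyond waveform duration")
    n = int(round(duration_ms * fs_hz / 1000.0))
    t = np.arange(n) / fs_hz * 1000.0
    trace_uv = 1000.0 * _compose_mv(t, kind, amplitude_mv, tau_ms, ps)
    td = np.arange(0.0, duration_ms, 0.002)
    yd = _compose_mv(td, kind, amplitude_mv, tau_ms, ps)
    slope = _dense_tangent_slope(yd, td) if kind == "neg_fpsp" else float("nan")
    truth = WaveformTruth(
        slope_mv_per_ms=slope,
        peak_mv=float(yd.min() if kind == "neg_fpsp" else yd.max()),
        pos_amp_uv=float(1000.0 * yd.max()) if kind == "pos_fpsp" else float("nan"),
        ps_amp_uv=_dense_ps_amplitude(1000.0 * yd, td) if ps is not None else float("nan"),
    )
    return trace_uv, truth


# ---------------------------------------------------------------------------
# cohort configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupParams:
    """Group-level generative parameters for one experimental group.

    Gains are per 250 mV intensity step.  ``ps_logistic_a/b`` parameterize
    PS-occurrence probability ``expit(a + b * step)``; the second pulse uses
    a logit shift (PS2 is more prevalent than PS1) and its own amplitude
    gain.  ``spatial_spread_um`` is the exponential decay length of PS
    expression across axonal channels.
    """

    slope_gain: float                 # mV/ms per step
    slope_intercept: float = 0.08     # mV/ms at the lowest intensity
    ppr_mean: float = 1.0
    ps_logistic_a: float = -2.7
    ps_logistic_b: float = 0.2
    ps_amp_gain: float = 0.05         # mV per step
    ps_amp_intercept: float = 0.0
    ps2_logit_shift: float = 0.4
    ps2_amp_gain: float | None = None
    spatial_spread_um: float = 300.0

    def validate(self) -> None:
        if self.slope_gain < 0:
            raise ValueError("slope_gain must be >= 0")
        if self.ppr_mean <= 0:
            raise ValueError("ppr_mean must be > 0")
        if self.spatial_spread_um <= 0:
            raise ValueError("spatial_spread_um must be > 0")


def default_group_params(group: str, region: str = "DG") -> GroupParams:
    """Literature-informed generative defaults per group and region.

    DG slope gains are 0.038 (IHKA) vs 0.023 (control) mV/ms per 250 mV step;
    PS logistics put maximal-intensity PS1 prevalence near 0.72 vs 0.18, PS
    amplitude gains near 0.078/0.109 (IHKA PS1/PS2) mV per step, and the
    paired-pulse ratio near 0.89 (IHKA, loss of facilitation) vs 1.30
    (control facilitation).
    """
    table = {
        ("DG", "IHKA"): GroupParams(slope_gain=0.038, ppr_mean=0.89,
                                    ps_logistic_a=-2.68, ps_logistic_b=0.30,
                                    ps_amp_gain=0.078, ps2_amp_gain=0.109,
                                    ps2_logit_shift=0.63, spatial_spread_um=450.0),
        ("DG", "control"): GroupParams(slope_gain=0.023, ppr_mean=1.30,
                                       ps_logistic_a=-2.72, ps_logistic_b=0.10,
                                       ps_amp_gain=0.012, ps2_amp_gain=0.047,
                                       ps2_logit_shift=0.20, spatial_spread_um=250.0),
        ("CA1", "IHKA"): GroupParams(slope_gain=0.030, ppr_mean=1.49,
                                     ps_logistic_a=-2.9, ps_logistic_b=0.16,
                                     ps_amp_gain=0.049, ps2_amp_gain=0.064,
                                     ps2_logit_shift=0.9, spatial_spread_um=300.0),
        ("CA1", "control"): GroupParams(slope_gain=0.033, ppr_mean=1.33,
                                        ps_logistic_a=-2.9, ps_logistic_b=0.21,
                                        ps_amp_gain=0.032, ps2_amp_gain=0.066,
                                        ps2_logit_shift=0.8, spatial_spread_um=300.0),
    }
    return table[(region, group)]


@dataclass
class CohortConfig:
    """Cohort-level generative configuration (two groups, nested slices)."""

    n_animals: int = 15
    n_slices: int = 3
    region: str = "DG"
    group_params: dict[str, GroupParams] = field(default_factory=dict)
    # hierarchical variance components (mV/ms scale for slope terms)
    animal_sd_intercept: float = 0.015
    animal_sd_gain: float = 0.0
    slice_sd_intercept: float = 0.03
    slice_sd_gain: float = 0.006
    slope_noise_sd: float = 0.03       # measurement noise on a per-intensity slope
    ppr_slice_sd: float = 0.12
    ps_animal_sd_logit: float = 0.3
    ps_slice_sd_logit: float = 0.3
    ps_amp_noise_sd: float = 0.05      # mV
    # waveform-level parameters
    noise_sd_uv: float = 10.0
    artifact_amp_mv: float = 5.0
    artifact_decay_ms: float = 0.25
    fpsp_tau_ms: float = 3.0
    fpsp_onset_delay_ms: float = 2.0
    fpsp_space_sigma_um: float = 300.0  # Gaussian footprint of the fPSP dipole
    pos_neg_ratio: float = 0.6          # axonal positive vs dendritic negative amplitude
    ps_latency_ms: float = 6.0
    ps_width_ms: float = 0.6
    n_repeats: int = 3
    fs_hz: float = 25000.0
    event_spacing_ms: float = 60.0
    lead_ms: float = 50.0
    response_ms: float = 25.0           # rendered response duration per pulse
    ps_on_dendritic_max: bool = False
    gain_uv_per_lsb: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.group_params:
            self.group_params = {g: default_group_params(g, self.region)
                                 for g in ("IHKA", "control")}

    def validate(self) -> None:
        if self.n_animals < 1 or self.n_slices < 1:
            raise ValueError("n_animals and n_slices must be >= 1")
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}")
        for name in ("animal_sd_intercept", "animal_sd_gain", "slice_sd_intercept",
                     "slice_sd_gain", "slope_noise_sd", "ppr_slice_sd",
                     "ps_animal_sd_logit", "ps_slice_sd_logit", "ps_amp_noise_sd",
                     "noise_sd_uv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for gp in self.group_params.values():
            gp.validate()

    def protocol(self) -> StimProtocol:
        return StimProtocol(n_repeats=self.n_repeats)

    def null(self) -> "CohortConfig":
        """Copy in which both groups share the control generative parameters."""
        cfg = dataclasses.replace(self)
        cfg.group_params = {g: self.group_params["control"] for g in ("IHKA", "control")}
        return cfg

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> Path:
        d = dataclasses.asdict(self)
        d["group_params"] = {g: dataclasses.asdict(gp)
                             for g, gp in self.group_params.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
        return Path(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        d = yaml.safe_load(Path(path).read_text())
        gp = d.pop("group_params", {})
        cfg = cls(**d)
        if gp:
            cfg.group_params = {g: GroupParams(**p) for g, p in gp.items()}
        return cfg


# ---------------------------------------------------------------------------
# hierarchical parameter draws (shared by both generation routes)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _AnimalEffects:
    d_intercept: float
    d_gain: float
    d_logit: float


@dataclass(frozen=True)
class _SliceParams:
    intercept: float
    gain: float
    ppr: float
    ps_logit_offset: float


def _draw_animal(rng: np.random.Generator, cfg: CohortConfig) -> _AnimalEffects:
    return _AnimalEffects(
        d_intercept=rng.normal(0.0, cfg.animal_sd_intercept),
        d_gain=rng.normal(0.0, cfg.animal_sd_gain),
        d_logit=rng.normal(0.0, cfg.ps_animal_sd_logit),
    )


def _draw_slice(rng: np.random.Generator, cfg: CohortConfig, gp: GroupParams,
                an: _AnimalEffects) -> _SliceParams:
    return _SliceParams(
        intercept=gp.slope_intercept + an.d_intercept + rng.normal(0.0, cfg.slice_sd_intercept),
        gain=gp.slope_gain + an.d_gain + rng.normal(0.0, cfg.slice_sd_gain),
        ppr=max(0.05, gp.ppr_mean + rng.normal(0.0, cfg.ppr_slice_sd)),
        ps_logit_offset=an.d_logit + rng.normal(0.0, cfg.ps_slice_sd_logit),
    )


def _intensity_truth(rng: np.random.Generator, cfg: CohortConfig, gp: GroupParams,
                     sp: _SliceParams, protocol: StimProtocol) -> pd.DataFrame:
    """Per-intensity realized truth: slopes, PS occurrence and amplitudes."""
    ps2_gain = gp.ps2_amp_gain if gp.ps2_amp_gain is not None else gp.ps_amp_gain
    rows = []
    for s, inten in enumerate(protocol.intensities_mv):
        slope1 = sp.intercept + sp.gain * s
        slope2 = sp.ppr * slope1
        p1 = float(expit(gp.ps_logistic_a + gp.ps_logistic_b * s + sp.ps_logit_offset))
        p2 = float(expit(gp.ps_logistic_a + gp.ps2_logit_shift
                         + gp.ps_logistic_b * s + sp.ps_logit_offset))
        ps1 = bool(rng.random() < p1)
        ps2 = bool(rng.random() < p2)
        amp1 = max(0.0, gp.ps_amp_intercept + gp.ps_amp_gain * s) if ps1 else 0.0
        amp2 = max(0.0, gp.ps_amp_intercept + ps2_gain * s) if ps2 else 0.0
        rows.append((s, inten, slope1, slope2, sp.ppr, p1, p2, ps1, ps2, amp1, amp2))
    return pd.DataFrame(rows, columns=[
        "step", "intensity_mv", "slope1", "slope2", "ppr", "ps1_prob", "ps2_prob",
        "ps1_present", "ps2_present", "ps1_amp_mv", "ps2_amp_mv"])


# ---------------------------------------------------------------------------
# waveform-level slice simulation
# ---------------------------------------------------------------------------

@dataclass
class SliceTruth:
    """Ground truth for one generated slice (the recovery oracle)."""

    animal_id: str
    slice_id: str
    group: str
    region: str
    slope_intercept: float
    slope_gain: float
    ppr: float
    ps_logit_offset: float
    focus_dendritic_id: int
    focus_axonal_id: int
    neg_channel_id: int          # designated 'pure slope' selection
    pos_channel_id: int          # designated PS-channel selection
    selection_intensity_mv: int
    per_intensity: pd.DataFrame  # realized truth plus measured-geometry values
    axonal_weights: pd.DataFrame  # channel_id, carrier_w, ps_w
    dendritic_weights: pd.DataFrame  # channel_id, carrier_w
    tau_ms: float
    ps_latency_ms: float
    ps_width_ms: float
    pos_neg_ratio: float
    fpsp_onset_delay_ms: float = 2.0

    def axonal_ps_table(self, intensities=SPATIAL_INTENSITIES,
                        duration_ms: float = 20.0) -> pd.DataFrame:
        """Noiseless measured-geometry PS/fPSP amplitudes per axonal channel.

        Dense-grid evaluation of the composed waveform on each axonal
        channel, per requested intensity and pulse — the oracle for the
        spatial hilar analysis.  Time axis is relative to the fPSP onset
        (latency is shifted by the synaptic onset delay, as rendered).
        """
        td = np.arange(0.0, duration_ms, 0.01)
        k = _alpha_kernel(td, self.tau_ms)
        g = _gaussian(td, self.ps_latency_ms - self.fpsp_onset_delay_ms,
                      self.ps_width_ms)
        c = unit_kernel_slope(self.tau_ms)
        rows = []
        for _, r in self.per_intensity.iterrows():
            if int(r.intensity_mv) not in intensities:
                continue
            for pulse, slope, present, amp in ((1, r.slope1, r.ps1_present, r.ps1_amp_mv),
                                               (2, r.slope2, r.ps2_present, r.ps2_amp_mv)):
                a_pos = self.pos_neg_ratio * max(0.0, slope) / c
                for _, w in self.axonal_weights.iterrows():
                    y = a_pos * w.carrier_w * k
                    if present and amp > 0:
                        y = y - amp * w.ps_w * g
                    ps_amp_uv = _dense_ps_amplitude(1000.0 * y, td) if present else 0.0
                    rows.append((int(w.channel_id), int(r.intensity_mv), pulse,
                                 float(1000.0 * y.max()), ps_amp_uv))
        return pd.DataFrame(rows, columns=["channel_id", "intensity_mv", "pulse",
                                           "pos_amp_uv", "ps_amp_uv"])


def _slice_rng(cfg: CohortConfig, group_idx: int, animal_idx: int,
               slice_idx: int) -> np.random.Generator:
    ss = np.random.SeedSequence(cfg.seed, spawn_key=(group_idx, animal_idx, slice_idx))
    return np.random.default_rng(ss)


def simulate_slice(cfg: CohortConfig, animal_id: str, slice_id: str, group: str,
                   seed: int | None = None,
                   rng: np.random.Generator | None = None,
                   animal_effects: _AnimalEffects | None = None,
                   ) -> tuple[SliceRecording, SliceTruth]:
    """Render one slice recording plus its ground truth.

    Deterministic given ``seed`` (or a caller-supplied ``rng``).  Dendritic
    channels carry negative fPSPs, axonal channels positive fPSPs with
    Bernoulli PS per the group logistic; pulse 2 scales by the realized
    paired-pulse ratio; both pulse onsets carry an exponentially decaying
    stimulation artifact on every channel; Gaussian noise is added last and
    the voltage is quantized to the container's int16 grid.
    """
    cfg.validate()
    if group not in cfg.group_params:
        raise ValueError(f"no group parameters for '{group}'")
    gp = cfg.group_params[group]
    if rng is None:
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if animal_effects is None:
        animal_effects = _draw_animal(rng, cfg)
    sp = _draw_slice(rng, cfg, gp, animal_effects)
    protocol = cfg.protocol()
    truth_df = _intensity_truth(rng, cfg, gp, sp, protocol)

    # ---- geometry -------------------------------------------------------
    pitch = 200.0
    focus_col = int(rng.integers(2, 6))
    layout = ChannelLayout.standard_mea60(cfg.region)
    t = layout.table
    # stimulation electrode: dendritic, top row, leftmost column (far from focus)
    stim_id = int(t.loc[(t.region_label == "dendritic") & (t.y_um == pitch)
                        & (t.x_um == 0.0), "channel_id"].iloc[0])
    t["is_stim"] = False
    t.loc[t.channel_id == stim_id, "is_stim"] = True

    def _chan_at(x, y):
        return int(t.loc[(t.x_um == x) & (t.y_um == y), "channel_id"].iloc[0])

    focus_d = _chan_at(focus_col * pitch, 2 * pitch)   # middle dendritic row
    focus_a = _chan_at(focus_col * pitch, 5 * pitch)   # middle axonal row
    pos = layout.positions()
    dend_ids = layout.channels_in_region("dendritic")
    axon_ids = layout.channels_in_region("axonal")
    # dipole center sits slightly off-grid (real current sources are not
    # aligned to electrodes); keeps the nearest/second-nearest channels unique
    center_off = np.array([55.0, 35.0])
    d_d = np.linalg.norm(pos[dend_ids] - (pos[focus_d] + center_off), axis=1)
    d_a = np.linalg.norm(pos[axon_ids] - (pos[focus_a] + center_off), axis=1)
    # weights normalized so the focus *electrode* carries the slice's nominal
    # amplitude (truth values refer to the focus channel, not the off-grid
    # dipole center)
    w_d = np.exp(-0.5 * (d_d / cfg.fpsp_space_sigma_um) ** 2)
    w_d /= w_d.max()
    w_a = np.exp(-0.5 * (d_a / cfg.fpsp_space_sigma_um) ** 2)
    w_a /= w_a.max()
    w_ps = np.exp(-d_a / gp.spatial_spread_um)
    w_ps /= w_ps.max()

    # ---- voltage assembly ----------------------------------------------
    fs = cfg.fs_hz
    n_events = protocol.n_intensities * protocol.n_repeats
    spacing_n = int(round(cfg.event_spacing_ms * fs / 1000.0))
    lead_n = int(round(cfg.lead_ms * fs / 1000.0))
    n_samples = lead_n + n_events * spacing_n + lead_n
    v = np.zeros((layout.n_channels, n_samples))

    resp_n = int(round(cfg.response_ms * fs / 1000.0))
    t_resp = np.arange(resp_n) / fs * 1000.0
    k = _alpha_kernel(t_resp, cfg.fpsp_tau_ms)
    g = _gaussian(t_resp, cfg.ps_latency_ms - cfg.fpsp_onset_delay_ms, cfg.ps_width_ms)
    art_n = int(round(10 * cfg.artifact_decay_ms * fs / 1000.0))
    t_art = np.arange(art_n) / fs * 1000.0
    art = -cfg.artifact_amp_mv * 1000.0 * np.exp(-t_art / cfg.artifact_decay_ms)
    delay_n = int(round(cfg.fpsp_onset_delay_ms * fs / 1000.0))
    isi_n = int(round(protocol.isi_ms * fs / 1000.0))
    c = unit_kernel_slope(cfg.fpsp_tau_ms)

    stim_times: dict[tuple[int, int], int] = {}
    meas_rows = []
    td = np.arange(0.0, 20.0, 0.002)
    kd = _alpha_kernel(td, cfg.fpsp_tau_ms)
    gd = _gaussian(td, cfg.ps_latency_ms - cfg.fpsp_onset_delay_ms, cfg.ps_width_ms)
    for rep in range(1, protocol.n_repeats + 1):
        for i_s, inten in enumerate(protocol.intensities_mv):
            idx = (rep - 1) * protocol.n_intensities + i_s
            onset = lead_n + idx * spacing_n
            stim_times[(inten, rep)] = onset
            r = truth_df.iloc[i_s]
            for pulse, slope, present, amp in ((1, r.slope1, r.ps1_present, r.ps1_amp_mv),
                                               (2, r.slope2, r.ps2_present, r.ps2_amp_mv)):
                o = onset if pulse == 1 else onset + isi_n
                m = max(0, min(art_n, n_samples - o))
                v[:, o:o + m] += art[:m]
                ro = o + delay_n
                a_neg = max(0.0, slope) / c
                a_pos = cfg.pos_neg_ratio * a_neg
                m = max(0, min(resp_n, n_samples - ro))
                span = slice(ro, ro + m)
                v[dend_ids, span] += np.outer(-a_neg * w_d, k[:m]) * 1000.0
                pos_wave = np.outer(a_pos * w_a, k[:m])
                if present and amp > 0:
                    pos_wave -= np.outer(amp * w_ps, g[:m])
                v[axon_ids, span] += pos_wave * 1000.0
                if cfg.ps_on_dendritic_max and present and amp > 0:
                    # positive PS reflection superimposed on the dendritic focus
                    v[focus_d, span] += 0.5 * amp * g[:m] * 1000.0

    # measured-geometry truth on the focus channels (noiseless dense grid)
    for i_s, inten in enumerate(protocol.intensities_mv):
        r = truth_df.iloc[i_s]
        row = {"step": i_s, "intensity_mv": inten}
        for pulse, slope, present, amp in ((1, r.slope1, r.ps1_present, r.ps1_amp_mv),
                                           (2, r.slope2, r.ps2_present, r.ps2_amp_mv)):
            a_pos = cfg.pos_neg_ratio * max(0.0, slope) / c
            y = a_pos * kd - (amp * gd if present and amp > 0 else 0.0)
            row[f"pos_amp_meas{pulse}_uv"] = float(1000.0 * y.max())
            row[f"ps_amp_meas{pulse}_uv"] = (
                _dense_ps_amplitude(1000.0 * y, td) if present and amp > 0 else 0.0)
        meas_rows.append(row)
    truth_df = truth_df.merge(pd.DataFrame(meas_rows), on=["step", "intensity_mv"])

    if cfg.noise_sd_uv > 0:
        v += rng.normal(0.0, cfg.noise_sd_uv, size=v.shape)
    gain = cfg.gain_uv_per_lsb
    v = np.clip(np.round(v / gain), -32767, 32767) * gain

    rec = SliceRecording(
        voltage=v, fs_hz=fs, layout=layout, protocol=protocol, stim_times=stim_times,
        meta={"animal_id": animal_id, "group": group, "region": cfg.region,
              "slice_id": slice_id},
        gain_uv_per_lsb=gain,
    )

    # designated selection channels at the reference intensity (2000 mV)
    sel_inten = 2000
    sel_step = protocol.step_index(sel_inten)
    neg_channel = focus_d
    sel_row = truth_df.iloc[sel_step]
    if cfg.ps_on_dendritic_max and bool(sel_row.ps1_present) and sel_row.ps1_amp_mv > 0:
        # the focus is disqualified only if the superimposed reflection is
        # *measurable* as a PS (>= 30 µV by the peak-trough-peak construction)
        a_neg_sel = max(0.0, sel_row.slope1) / c
        y_inv = 1000.0 * (a_neg_sel * kd - 0.5 * sel_row.ps1_amp_mv * gd)
        if _dense_ps_amplitude(y_inv, td) >= 30.0:
            order = dend_ids[np.argsort(-w_d)]
            neg_channel = int(order[1])   # runner-up: largest fPSP without a PS
    # the PS channel the selection rule will find: argmax of the *measured*
    # peak-trough-peak amplitude (carrier/PS geometry differs per channel)
    a_pos_sel = cfg.pos_neg_ratio * max(0.0, sel_row.slope1) / c
    if bool(sel_row.ps1_present) and sel_row.ps1_amp_mv > 0:
        amps = [_dense_ps_amplitude(
            1000.0 * (a_pos_sel * w * kd - sel_row.ps1_amp_mv * wp * gd), td)
            for w, wp in zip(w_a, w_ps)]
        pos_channel = int(axon_ids[int(np.argmax(amps))])
    else:
        pos_channel = int(axon_ids[int(np.argmax(w_a))])
    truth = SliceTruth(
        animal_id=animal_id, slice_id=slice_id, group=group, region=cfg.region,
        slope_intercept=sp.intercept, slope_gain=sp.gain, ppr=sp.ppr,
        ps_logit_offset=sp.ps_logit_offset,
        focus_dendritic_id=focus_d, focus_axonal_id=focus_a,
        neg_channel_id=neg_channel, pos_channel_id=pos_channel,
        selection_intensity_mv=sel_inten,
        per_intensity=truth_df,
        axonal_weights=pd.DataFrame({"channel_id": axon_ids, "carrier_w": w_a,
                                     "ps_w": w_ps}),
        dendritic_weights=pd.DataFrame({"channel_id": dend_ids, "carrier_w": w_d}),
        tau_ms=cfg.fpsp_tau_ms, ps_latency_ms=cfg.ps_latency_ms,
        ps_width_ms=cfg.ps_width_ms, pos_neg_ratio=cfg.pos_neg_ratio,
        fpsp_onset_delay_ms=cfg.fpsp_onset_delay_ms,
    )
    return rec, truth


@dataclass
class CohortResult:
    recordings: list[SliceRecording]
    truths: list[SliceTruth]
    table: pd.DataFrame      # one row per slice: realized parameters


def simulate_cohort(cfg: CohortConfig) -> CohortResult:
    """Simulate the full two-group cohort at the waveform level.

    Animal-level random effects are shared across each animal's slices;
    per-slice random streams spawn deterministically from the master seed.
    """
    cfg.validate()
    recs, truths, rows = [], [], []
    for gi, group in enumerate(("IHKA", "control")):
        for a in range(cfg.n_animals):
            animal_id = f"{group}_a{a:02d}"
            an_rng = np.random.default_rng(
                np.random.SeedSequence(cfg.seed, spawn_key=(gi, a)))
            an = _draw_animal(an_rng, cfg)
            for s in range(cfg.n_slices):
                slice_id = f"{animal_id}_s{s}"
                rng = _slice_rng(cfg, gi, a, s)
                rec, truth = simulate_slice(cfg, animal_id, slice_id, group,
                                            rng=rng, animal_effects=an)
                recs.append(rec)
                truths.append(truth)
                rows.append({"animal_id": animal_id, "slice_id": slice_id,
                             "group": group, "region": cfg.region,
                             "slope_intercept": truth.slope_intercept,
                             "slope_gain": truth.slope_gain, "ppr": truth.ppr,
                             "ps_logit_offset": truth.ps_logit_offset,
                             "neg_channel_id": truth.neg_channel_id,
                             "pos_channel_id": truth.pos_channel_id})
    return CohortResult(recs, truths, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# feature-level cohort sampling (for statistical simulation)
# ---------------------------------------------------------------------------

def sample_cohort_features(cfg: CohortConfig, seed: int | None = None
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the per-slice x intensity feature table from the hierarchical model.

    Returns ``(features, truth)``: the features frame has one row per slice
    and intensity with observed slope1/slope2/ppr, PS1/PS2 occurrence and
    amplitudes (NaN where absent); the truth frame has one row per slice with
    the realized slice parameters.  Same generative distributions as
    :func:`simulate_slice`, without waveform rendering — this is the route
    used for parameter-recovery and power studies.
    """
    cfg.validate()
    master = cfg.seed if seed is None else seed
    protocol = cfg.protocol()
    feat_rows, truth_rows = [], []
    for gi, group in enumerate(("IHKA", "control")):
        gp = cfg.group_params[group]
        for a in range(cfg.n_animals):
            animal_id = f"{group}_a{a:02d}"
            an_rng = np.random.default_rng(
                np.random.SeedSequence(master, spawn_key=(gi, a)))
            an = _draw_animal(an_rng, cfg)
            for s in range(cfg.n_slices):
                slice_id = f"{animal_id}_s{s}"
                rng = np.random.default_rng(
                    np.random.SeedSequence(master, spawn_key=(gi, a, s)))
                sp = _draw_slice(rng, cfg, gp, an)
                tdf = _intensity_truth(rng, cfg, gp, sp, protocol)
                truth_rows.append({"animal_id": animal_id, "slice_id": slice_id,
                                   "group": group, "slope_intercept": sp.intercept,
                                   "slope_gain": sp.gain, "ppr": sp.ppr,
                                   "ps_logit_offset": sp.ps_logit_offset})
                for _, r in tdf.iterrows():
                    s1 = r.slope1 + rng.normal(0.0, cfg.slope_noise_sd)
                    s2 = r.slope2 + rng.normal(0.0, cfg.slope_noise_sd)
                    ppr = s2 / s1 if s1 >= 0.01 else np.nan
                    a1 = (r.ps1_amp_mv + rng.normal(0.0, cfg.ps_amp_noise_sd)
                          if r.ps1_present else np.nan)
                    a2 = (r.ps2_amp_mv + rng.normal(0.0, cfg.ps_amp_noise_sd)
                          if r.ps2_present else np.nan)
                    feat_rows.append({
                        "animal_id": animal_id, "slice_id": slice_id, "group": group,
                        "region": cfg.region, "intensity_mv": int(r.intensity_mv),
                        "step": int(r.step), "slope1": s1, "slope2": s2, "ppr": ppr,
                        "ps1_present": bool(r.ps1_present),
                        "ps2_present": bool(r.ps2_present),
                        "ps1_amp": a1, "ps2_amp": a2,
                    })
    return pd.DataFrame(feat_rows), pd.DataFrame(truth_rows)
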
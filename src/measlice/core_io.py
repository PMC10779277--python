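"""Domain types and the on-disk container for MEA slice recordings.

A :class:`SliceRecording` bundles the channels x samples voltage matrix of one
acute hippocampal slice with the electrode layout (grid coordinates plus
dendritic/axonal/outside region annotation), the paired-pulse stimulation
protocol, the stimulus onset times, and slice provenance (animal, group,
region).  Recordings are stored one slice per HDF5 file with voltage kept as
16-bit raw counts plus an explicit microvolt-per-count gain, mirroring the
16-bit acquisition of the MEA amplifier chain.

Region labels are supplied by the layout (manual anatomical assignment);
nothing in the pipeline infers anatomy from signals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "REGION_LABELS",
    "GROUPS",
    "REGIONS",
    "DENDRITIC_NAME",
    "AXONAL_NAME",
    "SCHEMA_VERSION",
    "NAN_SENTINEL",
    "FormatError",
    "RecordingValidationError",
    "Violation",
    "StimProtocol",
    "ChannelLayout",
    "SliceRecording",
    "validate_recording",
    "write_recording",
    "read_recording",
]

REGION_LABELS = ("dendritic", "axonal", "outside")
GROUPS = ("IHKA", "control")
REGIONS = ("CA1", "DG")

#: anatomical names of the dendritic / axonal layer per hippocampal subfield
DENDRITIC_NAME = {"CA1": "stratum radiatum", "DG": "stratum moleculare"}
AXONAL_NAME = {"CA1": "stratum oriens", "DG": "hilus"}

SCHEMA_VERSION = "1.0"
#: int16 value reserved to represent NaN voltage in the container
NAN_SENTINEL = np.int16(-32768)


class FormatError(Exception):
    """The file does not conform to the recording container dialect."""


class RecordingValidationError(Exception):
    """A recording violates one of the domain invariants."""

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        super().__init__("; ".join(v.rule for v in violations))


@dataclass(frozen=True)
class Violation:
    """One validation finding.  ``severity`` is 'error' or 'warning'."""

    rule: str
    message: str
    severity: str = "error"


@dataclass(frozen=True)
class StimProtocol:
    """Paired-pulse input-output stimulation protocol.

    Intensities are stored as positive magnitudes in mV; the physical pulses
    are monophasic *negative* voltage pulses (documented sign convention, which
    keeps intensity monotone increasing for curve fitting).
    """

    intensities_mv: tuple[int, ...] = tuple(range(500, 3501, 250))
    pulse_width_us: float = 100.0
    isi_ms: float = 20.0
    n_repeats: int = 3
    interstep_s: float = 10.0

    @property
    def n_intensities(self) -> int:
        return len(self.intensities_mv)

    def step_index(self, intensity_mv: float) -> int:
        """0-based 250 mV step index of ``intensity_mv``."""
        return self.intensities_mv.index(int(intensity_mv))

    def validate(self) -> list[Violation]:
        out: list[Violation] = []
        iv = self.intensities_mv
        if len(iv) != 13:
            out.append(Violation("protocol.n_intensities",
                                 f"expected 13 intensities, got {len(iv)}"))
        diffs = set(np.diff(iv)) if len(iv) > 1 else set()
        if len(iv) > 1 and (diffs != {250} or iv[0] <= 0):
            out.append(Violation("protocol.intensity_grid",
                                 "intensities must be strictly increasing in 250 mV steps"))
        if self.n_repeats < 1:
            out.append(Violation("protocol.n_repeats", "n_repeats must be >= 1"))
        if self.isi_ms <= 0:
            out.append(Violation("protocol.isi", "interstimulus interval must be positive"))
        return out


_LAYOUT_COLUMNS = ["channel_id", "x_um", "y_um", "region_label",
                   "anatomical_name", "is_reference", "is_stim"]


@dataclass
class ChannelLayout:
    """Electrode layout and manual region annotation of a 60-channel MEA."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table[_LAYOUT_COLUMNS].reset_index(drop=True)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path) -> "ChannelLayout":
        df = pd.read_csv(path)
        if "is_stim" not in df.columns:
            df["is_stim"] = False
        df["anatomical_name"] = df["anatomical_name"].fillna("")
        missing = [c for c in _LAYOUT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"layout CSV missing columns: {missing}")
        return cls(df)

    @classmethod
    def standard_mea60(cls, region: str = "DG", stim_channel: int | None = None,
                       reference_channel: int | None = None,
                       pitch_um: float = 200.0) -> "ChannelLayout":
        """8x8 grid with the four corners absent (60 electrodes, 200 µm pitch).

        Rows 1-3 are annotated as the dendritic layer, rows 4-6 as the axonal
        layer, rows 0 and 7 as outside the target structure.  ``region``
        selects the anatomical names (CA1: stratum radiatum / oriens; DG:
        stratum moleculare / hilus).
        """
        if region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}")
        rows = []
        cid = 0
        for r in range(8):
            for c in range(8):
                if (r, c) in ((0, 0), (0, 7), (7, 0), (7, 7)):
                    continue
                if 1 <= r <= 3:
                    label, name = "dendritic", DENDRITIC_NAME[region]
                elif 4 <= r <= 6:
                    label, name = "axonal", AXONAL_NAME[region]
                else:
                    label, name = "outside", ""
                rows.append((cid, c * pitch_um, r * pitch_um, label, name, False, False))
                cid += 1
        df = pd.DataFrame(rows, columns=_LAYOUT_COLUMNS)
        ref = reference_channel if reference_channel is not None else int(
            df.loc[df.region_label == "outside", "channel_id"].iloc[0])
        stim = stim_channel if stim_channel is not None else int(
            df.loc[df.region_label == "dendritic", "channel_id"].iloc[0])
        df.loc[df.channel_id == ref, "is_reference"] = True
        df.loc[df.channel_id == stim, "is_stim"] = True
        return cls(df)

    # -- accessors ---------------------------------------------------------
    @property
    def n_channels(self) -> int:
        return len(self.table)

    def channels_in_region(self, label: str) -> np.ndarray:
        return self.table.loc[self.table.region_label == label, "channel_id"].to_numpy()

    def positions(self) -> np.ndarray:
        """(n_channels, 2) array of x/y coordinates in µm, by channel_id order."""
        t = self.table.sort_values("channel_id")
        return t[["x_um", "y_um"]].to_numpy(float)

    def validate(self) -> list[Violation]:
        out: list[Violation] = []
        t = self.table
        if len(t) != 60:
            out.append(Violation("layout.n_channels", f"expected 60 channels, got {len(t)}"))
        ids = t.channel_id.to_numpy()
        if len(np.unique(ids)) != len(ids) or (len(ids) and (ids.min() < 0 or ids.max() > 59)):
            out.append(Violation("layout.channel_ids", "channel ids must be unique in 0..59"))
        if t.is_reference.sum() != 1:
            out.append(Violation("layout.reference", "exactly one reference channel required"))
        if t.is_stim.sum() != 1:
            out.append(Violation("layout.stim", "exactly one stimulation channel required"))
        else:
            stim_row = t.loc[t.is_stim].iloc[0]
            if stim_row.region_label != "dendritic":
                out.append(Violation("layout.stim_region",
                                     "stimulation channel must lie in the dendritic layer"))
        if t.duplicated(subset=["x_um", "y_um"]).any():
            out.append(Violation("layout.positions", "grid coordinates must be unique"))
        bad = set(t.region_label) - set(REGION_LABELS)
        if bad:
            out.append(Violation("layout.region_labels", f"unknown region labels: {sorted(bad)}"))
        return out


@dataclass
class SliceRecording:
    """One slice's multichannel voltage recording plus all metadata.

    ``voltage`` is channels x samples in µV (float); ``stim_times`` maps
    (intensity_mv, repeat) -> 0-based sample index of the *first* pulse onset.
    The second pulse onset is ``stim + round(isi_ms * fs / 1000)`` samples.
    """

    voltage: np.ndarray
    fs_hz: float
    layout: ChannelLayout
    protocol: StimProtocol
    stim_times: dict[tuple[int, int], int]
    meta: dict = field(default_factory=dict)
    gain_uv_per_lsb: float = 0.2

    @property
    def n_samples(self) -> int:
        return self.voltage.shape[1]

    def pulse2_offset_samples(self) -> int:
        return int(round(self.protocol.isi_ms * self.fs_hz / 1000.0))


def validate_recording(rec: SliceRecording) -> list[Violation]:
    """Check every domain invariant; returns findings, never raises.

    The report is deterministic and order-stable.  NaN voltage is reported as
    a *warning* (the container preserves it); everything else is an error.
    """
    out: list[Violation] = []
    out.extend(rec.layout.validate())
    out.extend(rec.protocol.validate())
    if rec.fs_hz <= 0:
        out.append(Violation("recording.fs", f"fs_hz must be > 0, got {rec.fs_hz}"))
    if rec.voltage.ndim != 2 or rec.voltage.shape[0] != rec.layout.n_channels:
        out.append(Violation("recording.shape",
                             "voltage must be (n_channels, n_samples) matching the layout"))
    expected = rec.protocol.n_intensities * rec.protocol.n_repeats
    if len(rec.stim_times) != expected:
        out.append(Violation("recording.stim_count",
                             f"expected {expected} stim events "
                             f"({rec.protocol.n_intensities} intensities x "
                             f"{rec.protocol.n_repeats} repeats), got {len(rec.stim_times)}"))
    n = rec.voltage.shape[1] if rec.voltage.ndim == 2 else 0
    off2 = rec.pulse2_offset_samples() if rec.fs_hz > 0 else 0
    for key in sorted(rec.stim_times):
        s = rec.stim_times[key]
        if not (0 <= s and s + off2 < n):
            out.append(Violation("recording.stim_bounds",
                                 f"stim event {key} at sample {s} outside recording"))
    for k in ("animal_id", "group", "region", "slice_id"):
        if k not in rec.meta:
            out.append(Violation("recording.meta", f"missing meta field '{k}'"))
    if rec.meta.get("group") not in GROUPS:
        out.append(Violation("recording.group", f"group must be one of {GROUPS}"))
    if rec.meta.get("region") not in REGIONS:
        out.append(Violation("recording.region", f"region must be one of {REGIONS}"))
    if np.isnan(rec.voltage).any():
        out.append(Violation("recording.nan_voltage",
                             "voltage contains NaN samples", severity="warning"))
    return out


def _errors(violations: list[Violation]) -> list[Violation]:
    return [v for v in violations if v.severity == "error"]


def write_recording(rec: SliceRecording, path: str | Path) -> Path:
    """Write one slice to an HDF5 container; refuses on invariant errors.

    Voltage is quantized to int16 counts at ``rec.gain_uv_per_lsb`` µV/count;
    NaN samples map to the reserved sentinel and survive a round trip.
    """
    errs = _errors(validate_recording(rec))
    if errs:
        raise RecordingValidationError(errs)
    path = Path(path)
    gain = float(rec.gain_uv_per_lsb)
    counts = np.round(rec.voltage / gain)
    counts = np.clip(counts, -32767, 32767)
    counts = np.where(np.isnan(rec.voltage), float(NAN_SENTINEL), counts).astype(np.int16)
    with h5py.File(path, "w") as f:
        dv = f.create_dataset("voltage", data=counts)
        dv.attrs["gain_uv_per_lsb"] = gain
        dv.attrs["fs_hz"] = float(rec.fs_hz)
        dv.attrs["nan_sentinel"] = int(NAN_SENTINEL)
        g = f.create_group("layout")
        t = rec.layout.table
        for col in _LAYOUT_COLUMNS:
            data = t[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            g.create_dataset(col, data=data)
        p = f.create_group("protocol")
        p.attrs["intensities_mv"] = np.asarray(rec.protocol.intensities_mv, int)
        p.attrs["pulse_width_us"] = rec.protocol.pulse_width_us
        p.attrs["isi_ms"] = rec.protocol.isi_ms
        p.attrs["n_repeats"] = rec.protocol.n_repeats
        p.attrs["interstep_s"] = rec.protocol.interstep_s
        st = f.create_group("stim_times")
        keys = sorted(rec.stim_times)
        st.create_dataset("intensity_mv", data=np.asarray([k[0] for k in keys], int))
        st.create_dataset("repeat", data=np.asarray([k[1] for k in keys], int))
        st.create_dataset("sample", data=np.asarray([rec.stim_times[k] for k in keys], np.int64))
        m = f.create_group("meta")
        m.attrs["schema_version"] = SCHEMA_VERSION
        for k, v in rec.meta.items():
            m.attrs[k] = v
    return path


def read_recording(path: str | Path) -> SliceRecording:
    """Read and fully validate a slice recording; voltage returned in µV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        for group in ("voltage", "layout", "protocol", "stim_times", "meta"):
            if group not in f:
                raise FormatError(f"{path}: missing '{group}' group")
        dv = f["voltage"]
        gain = float(dv.attrs["gain_uv_per_lsb"])
        fs = float(dv.attrs["fs_hz"])
        counts = dv[()]
        voltage = counts.astype(np.float64) * gain
        voltage[counts == NAN_SENTINEL] = np.nan
        lg = f["layout"]
        cols = {}
        for col in _LAYOUT_COLUMNS:
            if col not in lg:
                raise FormatError(f"{path}: layout missing column '{col}'")
            data = lg[col][()]
            if data.dtype.kind == "S":
                data = np.array([b.decode() for b in data], dtype=object)
            cols[col] = data
        layout = ChannelLayout(pd.DataFrame(cols))
        pa = f["protocol"].attrs
        protocol = StimProtocol(
            intensities_mv=tuple(int(i) for i in pa["intensities_mv"]),
            pulse_width_us=float(pa["pulse_width_us"]),
            isi_ms=float(pa["isi_ms"]),
            n_repeats=int(pa["n_repeats"]),
            interstep_s=float(pa["interstep_s"]),
        )
        st = f["stim_times"]
        stim_times = {
            (int(i), int(r)): int(s)
            for i, r, s in zip(st["intensity_mv"][()], st["repeat"][()], st["sample"][()])
        }
        meta = {k: (v.item() if isinstance(v, np.generic) else v)
                for k, v in f["meta"].attrs.items()}
        meta.pop("schema_version", None)
    rec = SliceRecording(voltage=voltage, fs_hz=fs, layout=layout, protocol=protocol,
                         stim_times=stim_times, meta=meta, gain_uv_per_lsb=gain)
    errs = _errors(validate_recording(rec))
    if errs:
        raise RecordingValidationError(errs)
    return rec
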
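"""Slice QC, per-slice channel selection, and the hilar spatial PS analysis.

Two channels are selected per slice at the reference intensity (2000 mV, the
optimal-site search pulse): the dendritic channel with the largest negative
fPSP *without* a superimposed PS (the 'pure slope' channel) and the axonal
channel with the largest PS superimposed on a positive fPSP (falling back to
the largest positive fPSP when no axonal channel shows a PS).  QC requires at
least four dendritic channels with a negative fPSP strictly greater than
250 µV, free from residual stimulation artifact.

The spatial analysis counts, per slice and intensity, hilar channels with a
positive fPSP >= 50 µV (trials) and, of those, channels with a PS >= 30 µV
(events), separately for pulse 1 and 2; it is defined for DG slices only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import MIN_POS_FPSP_UV, MIN_PS_UV
from .synthetic import SPATIAL_INTENSITIES

__all__ = ["SliceSelection", "qc_slice", "select_channels", "spatial_counts",
           "QC_MIN_CHANNELS", "QC_MIN_AMP_UV", "SELECTION_INTENSITY_MV"]

QC_MIN_CHANNELS = 4
QC_MIN_AMP_UV = 250.0
SELECTION_INTENSITY_MV = 2000


@dataclass
class SliceSelection:
    slice_id: str
    qc_pass: bool
    qc_reasons: list = field(default_factory=list)
    neg_channel_id: int | None = None
    pos_channel_id: int | None = None
    excluded: bool = False
    reason: str = ""


def qc_slice(chan_feats: pd.DataFrame, min_channels: int = QC_MIN_CHANNELS,
             min_amp_uv: float = QC_MIN_AMP_UV) -> tuple[bool, list[str]]:
    """Slice quality control on per-channel features at the reference intensity.

    Pass iff at least ``min_channels`` dendritic channels have a negative fPSP
    strictly greater than ``min_amp_uv`` and a clean artifact flag.
    """
    reasons: list[str] = []
    dend = chan_feats[chan_feats.region_label == "dendritic"]
    ok_amp = dend[dend.neg_amp_uv > min_amp_uv]
    ok = (ok_amp[ok_amp.artifact_ok.astype(bool)]
          if "artifact_ok" in dend.columns else ok_amp)
    if len(ok) < min_channels:
        reasons.append("min_channels")
        if len(ok_amp) >= min_channels:
            reasons.append("artifact")
    return len(ok) >= min_channels, reasons


def select_channels(chan_feats: pd.DataFrame, slice_id: str = "",
                    require_qc: bool = True) -> SliceSelection:
    """Apply the two per-slice channel-selection rules.

    ``chan_feats``: per-channel features at the reference intensity (pulse 1),
    repeat-averaged — columns region_label, neg_amp_uv, ps_present, ps_amp_uv,
    pos_amp_uv, pos_present.  Ties break on the lowest channel_id
    (deterministic).  No eligible dendritic channel excludes the slice.
    """
    qc_pass, reasons = qc_slice(chan_feats)
    sel = SliceSelection(slice_id=slice_id, qc_pass=qc_pass, qc_reasons=reasons)
    if require_qc and not qc_pass:
        sel.excluded = True
        sel.reason = "qc_fail:" + ",".join(reasons)
        return sel
    dend = chan_feats[(chan_feats.region_label == "dendritic")
                      & (~chan_feats.ps_present.astype(bool))]
    if dend.empty:
        sel.excluded = True
        sel.reason = "no pure fPSP channel"
        return sel
    dend = dend.sort_values(["neg_amp_uv", "channel_id"],
                            ascending=[False, True], kind="mergesort")
    sel.neg_channel_id = int(dend.channel_id.iloc[0])
    axon = chan_feats[chan_feats.region_label == "axonal"]
    with_ps = axon[axon.ps_present.astype(bool) & axon.pos_present.astype(bool)]
    if len(with_ps):
        with_ps = with_ps.sort_values(["ps_amp_uv", "channel_id"],
                                      ascending=[False, True], kind="mergesort")
        sel.pos_channel_id = int(with_ps.channel_id.iloc[0])
    elif len(axon):
        axon = axon.sort_values(["pos_amp_uv", "channel_id"],
                                ascending=[False, True], kind="mergesort")
        sel.pos_channel_id = int(axon.channel_id.iloc[0])
    return sel


def spatial_counts(chan_feats: pd.DataFrame, region: str,
                   intensities=SPATIAL_INTENSITIES,
                   fpsp_min_uv: float = MIN_POS_FPSP_UV,
                   ps_min_uv: float = MIN_PS_UV,
                   slice_id: str = "") -> pd.DataFrame:
    """Hilar PS-prevalence counts per intensity and pulse.

    ``chan_feats``: repeat-averaged per-channel features over both pulses for
    the requested intensities (columns region_label, intensity_mv, pulse,
    pos_amp_uv, ps_amp_uv).  Trials are hilar channels whose positive fPSP
    reaches ``fpsp_min_uv``; events are those whose PS amplitude reaches
    ``ps_min_uv``.  Slices without a single PS-positive channel anywhere are
    flagged non-informative (excluded from the group analysis).  Raises for
    CA1 slices: the analysis is defined for the DG hilus only.
    """
    if region != "DG":
        raise ValueError("spatial PS analysis is defined for DG slices only")
    hilar = chan_feats[chan_feats.region_label == "axonal"]
    any_ps = bool((hilar.ps_amp_uv >= ps_min_uv).any())
    rows = []
    for inten in intensities:
        for pulse in (1, 2):
            sub = hilar[(hilar.intensity_mv == inten) & (hilar.pulse == pulse)]
            pos = sub[sub.pos_amp_uv >= fpsp_min_uv]
            trials = len(pos)
            events = int((pos.ps_amp_uv >= ps_min_uv).sum())
            rows.append({"slice_id": slice_id, "intensity_mv": inten,
                         "pulse": pulse, "trials": trials, "events": events,
                         "informative": any_ps and trials > 0})
    return pd.DataFrame(rows)
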
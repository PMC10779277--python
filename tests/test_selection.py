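"""QC boundaries, channel-selection rules, and the spatial hilar counts."""

import numpy as np
import pandas as pd
import pytest

from measlice.pipeline import RunConfig, analyze_recording
from measlice.selection import qc_slice, select_channels, spatial_counts


def _chan_feats(dend_amps, axon=None, dend_ps=None):
    """Per-channel pulse-1 feature frame at the reference intensity."""
    rows = []
    for i, amp in enumerate(dend_amps):
        rows.append({"channel_id": i, "region_label": "dendritic", "pulse": 1,
                     "neg_amp_uv": amp, "artifact_ok": True,
                     "ps_present": bool(dend_ps[i]) if dend_ps else False,
                     "ps_amp_uv": 0.0, "pos_amp_uv": 0.0, "pos_present": False})
    for j, (pos, ps_amp) in enumerate(axon or []):
        rows.append({"channel_id": 30 + j, "region_label": "axonal", "pulse": 1,
                     "neg_amp_uv": 0.0, "artifact_ok": True,
                     "ps_present": ps_amp >= 30.0, "ps_amp_uv": ps_amp,
                     "pos_amp_uv": pos, "pos_present": pos >= 50.0})
    return pd.DataFrame(rows)


class TestQc:
    def test_five_strong_channels_pass(self):
        ok, reasons = qc_slice(_chan_feats([300] * 5))
        assert ok and reasons == []

    def test_three_strong_channels_fail(self):
        ok, reasons = qc_slice(_chan_feats([300, 300, 300, 100, 50]))
        assert not ok and "min_channels" in reasons

    def test_exactly_250_is_not_enough(self):
        # the amplitude rule is strictly greater-than
        ok, _ = qc_slice(_chan_feats([250.0] * 6))
        assert not ok
        ok, _ = qc_slice(_chan_feats([250.0 + 1e-9] * 6))
        assert ok

    def test_artifact_flag_disqualifies(self):
        df = _chan_feats([300] * 4)
        df["artifact_ok"] = False
        ok, reasons = qc_slice(df)
        assert not ok and "artifact" in reasons


class TestSelect:
    def test_pure_slope_rule_skips_ps_channels(self):
        df = _chan_feats([400, 380, 300, 290, 260], axon=[(100, 50), (80, 90)],
                         dend_ps=[1, 0, 0, 0, 0])
        sel = select_channels(df, "s")
        assert sel.neg_channel_id == 1      # largest without a PS
        assert sel.pos_channel_id == 31     # largest PS amplitude

    def test_tie_breaks_on_lower_channel_id(self):
        df = _chan_feats([300, 300, 300, 300, 300])
        assert select_channels(df, "s").neg_channel_id == 0

    def test_all_ps_dendritic_channels_exclude_slice(self):
        df = _chan_feats([400, 380, 300, 290, 260], dend_ps=[1] * 5)
        sel = select_channels(df, "s")
        assert sel.excluded and sel.reason == "no pure fPSP channel"

    def test_fallback_to_largest_positive_fpsp(self):
        df = _chan_feats([300] * 5, axon=[(120, 0), (200, 0), (90, 0)])
        assert select_channels(df, "s").pos_channel_id == 31

    def test_permutation_invariance(self):
        df = _chan_feats([260, 410, 300, 390, 280], axon=[(100, 40), (90, 80)])
        sel1 = select_channels(df, "s")
        sel2 = select_channels(df.sample(frac=1, random_state=3), "s")
        assert (sel1.neg_channel_id, sel1.pos_channel_id) == \
               (sel2.neg_channel_id, sel2.pos_channel_id)


def _spatial_feats(pos_ps, intensity=1250):
    rows = []
    for pulse in (1, 2):
        for i, (pos, ps) in enumerate(pos_ps):
            rows.append({"channel_id": 30 + i, "region_label": "axonal",
                         "intensity_mv": intensity, "pulse": pulse,
                         "pos_amp_uv": pos, "ps_amp_uv": ps})
    return pd.DataFrame(rows)


class TestSpatial:
    def test_fraction_counts(self):
        feats = _spatial_feats([(100, 60)] * 4 + [(100, 0)] * 6)
        out = spatial_counts(feats, "DG", intensities=(1250,))
        row = out[(out.pulse == 1)].iloc[0]
        assert row.trials == 10 and row.events == 4

    def test_no_positive_channels_flagged(self):
        feats = _spatial_feats([(10, 0)] * 8)
        out = spatial_counts(feats, "DG", intensities=(1250,))
        assert (out.trials == 0).all() and (~out.informative).all()

    def test_ca1_rejected(self):
        with pytest.raises(ValueError, match="DG"):
            spatial_counts(_spatial_feats([(100, 60)]), "CA1")

    def test_events_monotone_in_ps_threshold(self):
        feats = _spatial_feats([(100, a) for a in (10, 25, 31, 40, 55, 80)])
        prev = None
        for thr in (10, 30, 50, 90):
            ev = spatial_counts(feats, "DG", intensities=(1250,),
                                ps_min_uv=thr).events.sum()
            if prev is not None:
                assert ev <= prev
            prev = ev

    def test_fractions_bounded(self, noiseless_slice):
        (rec, truth), _ = noiseless_slice
        out = analyze_recording(rec, RunConfig())["spatial"]
        assert ((out.events >= 0) & (out.events <= out.trials)).all()


def test_spatial_events_increase_with_generator_spread(noiseless_slice):
    """Wider PS expression across the hilus -> at least as many PS channels."""
    import dataclasses
    from measlice.synthetic import (CohortConfig, default_group_params,
                                    simulate_slice)
    (_, _), base_cfg = noiseless_slice
    prev = None
    for spread in (100.0, 250.0, 500.0, 900.0):
        gp = dataclasses.replace(base_cfg.group_params["IHKA"],
                                 spatial_spread_um=spread)
        # PS placed clear of the carrier peak so the positive-fPSP trials
        # gate is identical across spreads
        cfg = dataclasses.replace(
            base_cfg, ps_latency_ms=8.0, ps_width_ms=0.4,
            group_params={"IHKA": gp,
                          "control": base_cfg.group_params["control"]})
        rec, truth = simulate_slice(cfg, "a", "s", "IHKA", seed=11)
        events = analyze_recording(rec, RunConfig())["spatial"].events.sum()
        if prev is not None:
            assert events >= prev
        prev = events
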
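"""End-to-end orchestration: simulate -> analyze -> stats -> report.

Every stage is a plain function over the library API; the CLI wraps these.
Outputs are deterministic given config + seed, and every run writes a
manifest embedding the serialized configuration, its hash, and the package
version for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_io import SliceRecording, read_recording, write_recording
from .epochs import extract_epochs
from .features import (epoch_features, paired_pulse_ratio,
                       per_intensity_features)
from .selection import (SELECTION_INTENSITY_MV, SliceSelection,
                        select_channels, spatial_counts)
from .stats import (RESPONSES, aggregate_binomial, build_io_table,
                    fit_gee_logistic, fit_lmm)
from .synthetic import SPATIAL_INTENSITIES, CohortConfig, simulate_cohort

__all__ = ["RunConfig", "analyze_recording", "analyze_cohort", "run_stats",
           "run_pipeline", "write_report"]


@dataclass
class RunConfig:
    """Analysis policy; defaults are the study's stated constants
    (250/50/30 µV thresholds, 20 ms ISI windows, 2000 mV selection pulse)."""

    window_ms: float | None = None       # pulse windows; None -> ISI
    blank_ms: float = 1.5
    baseline_ms: float = 2.0
    tail_subtraction: bool = False
    fit_frac: tuple = (0.2, 0.8)
    min_ps_uv: float = 30.0
    min_pos_uv: float = 50.0
    qc_min_amp_uv: float = 250.0
    qc_min_channels: int = 4
    selection_intensity_mv: int = SELECTION_INTENSITY_MV
    spatial_intensities: tuple = SPATIAL_INTENSITIES
    lmm_random: str = "slice_nested"
    gee_cov: str = "exchangeable"
    seed: int = 0

    def validate(self) -> None:
        for name in ("min_ps_uv", "min_pos_uv", "qc_min_amp_uv", "blank_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.fit_frac[0] < self.fit_frac[1] <= 1):
            raise ValueError("fit_frac must satisfy 0 <= lo < hi <= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in d.items()})
        cfg.validate()
        return cfg

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _region_lookup(rec: SliceRecording) -> dict[int, str]:
    t = rec.layout.table
    return dict(zip(t.channel_id.astype(int), t.region_label))


def _features_for(rec: SliceRecording, cfg: RunConfig, channels, intensities
                  ) -> pd.DataFrame:
    regions = _region_lookup(rec)
    eps = extract_epochs(rec, window_ms=cfg.window_ms, blank_ms=cfg.blank_ms,
                         baseline_ms=cfg.baseline_ms,
                         tail_subtraction=cfg.tail_subtraction,
                         channels=channels, intensities=intensities)
    rows = [epoch_features(ep, regions[ep.channel_id]) for ep in eps
            if regions[ep.channel_id] != "outside"]
    return pd.DataFrame([r for r in rows if r])


def analyze_recording(rec: SliceRecording, cfg: RunConfig | None = None) -> dict:
    """Full single-slice analysis.

    Returns a dict with ``selection`` (:class:`SliceSelection`), ``features``
    (wide per-intensity feature rows for the selected channels), and
    ``spatial`` (hilar counts, DG slices only).
    """
    cfg = cfg or RunConfig()
    cfg.validate()
    slice_id = rec.meta["slice_id"]
    region = rec.meta["region"]
    layout = rec.layout

    # 1. per-channel features at the reference intensity -> QC + selection
    ref = _features_for(rec, cfg, channels=None,
                        intensities=(cfg.selection_intensity_mv,))
    ref_avg = per_intensity_features(ref)
    sel = select_channels(ref_avg[ref_avg.pulse == 1], slice_id=slice_id)
    out = {"selection": sel, "features": pd.DataFrame(), "spatial": pd.DataFrame()}
    if sel.excluded:
        return out

    # 2. input-output features on the two selected channels, all intensities
    chans = sorted({sel.neg_channel_id, sel.pos_channel_id})
    fdf = _features_for(rec, cfg, channels=chans, intensities=None)
    rows = []
    for (inten, rep), sub in fdf.groupby(["intensity_mv", "repeat"]):
        neg = sub[sub.channel_id == sel.neg_channel_id].set_index("pulse")
        pos = sub[sub.channel_id == sel.pos_channel_id].set_index("pulse")
        s1 = float(neg.loc[1, "slope"]) if 1 in neg.index else np.nan
        s2 = float(neg.loc[2, "slope"]) if 2 in neg.index else np.nan
        ppr, _flag = paired_pulse_ratio(s1, s2)
        row = {"slice_id": slice_id, "intensity_mv": inten, "repeat": rep,
               "slope1": s1, "slope2": s2, "ppr": ppr}
        for pulse in (1, 2):
            if pulse in pos.index:
                row[f"ps{pulse}_present"] = bool(pos.loc[pulse, "ps_present"])
                row[f"ps{pulse}_amp"] = float(pos.loc[pulse, "ps_amp_uv"]) / 1000.0
            else:
                row[f"ps{pulse}_present"] = False
                row[f"ps{pulse}_amp"] = 0.0
        rows.append(row)
    rep_df = pd.DataFrame(rows)

    # parameter-level averaging over the repeats, per intensity
    agg_rows = []
    for inten, sub in rep_df.groupby("intensity_mv"):
        row = {"slice_id": slice_id, "intensity_mv": int(inten),
               "step": rec.protocol.step_index(inten),
               "n_repeats": len(sub)}
        for c in ("slope1", "slope2", "ppr"):
            row[c] = float(sub[c].mean())
        for pulse in (1, 2):
            pres = sub[f"ps{pulse}_present"]
            present = bool(pres.sum() * 2 >= len(pres)) if len(pres) else False
            row[f"ps{pulse}_present"] = present
            amps = sub.loc[pres.astype(bool), f"ps{pulse}_amp"]
            row[f"ps{pulse}_amp"] = (float(amps.mean())
                                     if present and len(amps) else np.nan)
        agg_rows.append(row)
    feats = pd.DataFrame(agg_rows)
    for k in ("animal_id", "group", "region"):
        feats[k] = rec.meta[k]
    out["features"] = feats

    # 3. spatial hilar analysis (DG only)
    if region == "DG":
        axon = layout.channels_in_region("axonal")
        sdf = _features_for(rec, cfg, channels=sorted(axon),
                            intensities=cfg.spatial_intensities)
        savg = per_intensity_features(sdf)
        savg["slice_id"] = slice_id
        sp = spatial_counts(savg, region, intensities=cfg.spatial_intensities,
                            fpsp_min_uv=cfg.min_pos_uv, ps_min_uv=cfg.min_ps_uv,
                            slice_id=slice_id)
        for k in ("animal_id", "group"):
            sp[k] = rec.meta[k]
        out["spatial"] = sp
    return out


def analyze_cohort(recs: list[SliceRecording], cfg: RunConfig | None = None
                   ) -> dict[str, pd.DataFrame]:
    """Analyze every slice; concatenated feature/selection/spatial tables."""
    cfg = cfg or RunConfig()
    feats, sels, spats = [], [], []
    for rec in recs:
        res = analyze_recording(rec, cfg)
        s: SliceSelection = res["selection"]
        sels.append({"slice_id": s.slice_id, "qc_pass": s.qc_pass,
                     "qc_reasons": ",".join(s.qc_reasons),
                     "neg_channel_id": s.neg_channel_id,
                     "pos_channel_id": s.pos_channel_id,
                     "excluded": s.excluded, "reason": s.reason})
        if len(res["features"]):
            feats.append(res["features"])
        if len(res["spatial"]):
            spats.append(res["spatial"])
    return {
        "features": (pd.concat(feats, ignore_index=True)
                     if feats else pd.DataFrame()),
        "selection": pd.DataFrame(sels),
        "spatial": (pd.concat(spats, ignore_index=True)
                    if spats else pd.DataFrame()),
    }


def run_stats(features: pd.DataFrame, spatial: pd.DataFrame | None = None,
              cfg: RunConfig | None = None) -> dict:
    """All group comparisons: LMM per continuous response, GEE for PS
    occurrence (animal clusters) and, when spatial counts are present, for
    the hilar channel fractions (slice clusters)."""
    cfg = cfg or RunConfig()
    fits: dict[str, dict] = {}
    if len(features):
        rename = {"ps1_amp": "ps1_amp", "ps2_amp": "ps2_amp"}
        io = build_io_table(features.rename(columns=rename))
        for resp in RESPONSES:
            if resp not in features.columns:
                continue
            sub = features.dropna(subset=[resp])
            if sub.empty or sub.group.nunique() < 2:
                continue
            try:
                fits[f"lmm_{resp}"] = fit_lmm(io, resp, random=cfg.lmm_random).to_dict()
            except (ValueError, RuntimeError) as e:
                fits[f"lmm_{resp}"] = {"error": str(e)}
        for pulse in (1, 2):
            try:
                agg = aggregate_binomial(features, level="animal", pulse=pulse)
                fits[f"gee_ps{pulse}"] = fit_gee_logistic(agg, cov=cfg.gee_cov).to_dict()
            except ValueError as e:
                fits[f"gee_ps{pulse}"] = {"error": str(e)}
    if spatial is not None and len(spatial):
        inf = spatial[spatial.informative]
        for pulse in (1, 2):
            sub = inf[inf.pulse == pulse]
            if sub.empty:
                continue
            try:
                agg = aggregate_binomial(sub, level="slice")
                fits[f"gee_spatial_ps{pulse}"] = fit_gee_logistic(
                    agg, cov=cfg.gee_cov).to_dict()
            except ValueError as e:
                fits[f"gee_spatial_ps{pulse}"] = {"error": str(e)}
    return fits


def write_report(features: pd.DataFrame, fits: dict, path: str | Path) -> Path:
    """Plain-text summary in the structure of a group-comparison table:
    per response, the group means at maximal intensity plus the model
    p-values for the group and group-by-intensity terms."""
    lines = ["Input-output group comparison (means at 3500 mV)", "=" * 52]
    if len(features):
        top = features[features.intensity_mv == features.intensity_mv.max()]
        for resp in RESPONSES:
            if resp not in features.columns:
                continue
            means = top.groupby("group", observed=True)[resp].mean()
            fit = fits.get(f"lmm_{resp}", {})
            p_int = (fit.get("params", {}).get("group_x_step", {}) or {}).get("p")
            p_grp = (fit.get("params", {}).get("group", {}) or {}).get("p")
            lines.append(
                f"{resp:10s} IHKA {means.get('IHKA', float('nan')):8.3f}  "
                f"control {means.get('control', float('nan')):8.3f}  "
                f"p(group)={_fmt(p_grp)} p(interaction)={_fmt(p_int)}")
        for pulse in (1, 2):
            col = f"ps{pulse}_present"
            if col in top.columns:
                prev = top.groupby("group", observed=True)[col].mean() * 100
                fit = fits.get(f"gee_ps{pulse}", {})
                p_int = (fit.get("params", {}).get("group_x_step", {}) or {}).get("p")
                lines.append(
                    f"PS{pulse} prevalence  IHKA {prev.get('IHKA', float('nan')):6.2f}%  "
                    f"control {prev.get('control', float('nan')):6.2f}%  "
                    f"p(interaction)={_fmt(p_int)}")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def _fmt(p) -> str:
    return "n/a" if p is None else f"{p:.4g}"


def run_pipeline(cohort_cfg: CohortConfig, run_cfg: RunConfig | None = None,
                 out_dir: str | Path = ".") -> dict:
    """simulate -> analyze -> stats -> report, writing all artifacts.

    Returns the result bundle (tables and fits).  Deterministic given
    configs + seed; a manifest with config hash and version is written for
    provenance.
    """
    run_cfg = run_cfg or RunConfig()
    run_cfg.validate()
    cohort_cfg.validate()
    out = Path(out_dir)
    (out / "recordings").mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(cohort_cfg)
    for rec in cohort.recordings:
        write_recording(rec, out / "recordings" / f"{rec.meta['slice_id']}.h5")
    cohort.table.to_csv(out / "truth.csv", index=False)
    tables = analyze_cohort(cohort.recordings, run_cfg)
    tables["features"].to_csv(out / "slice_features.csv", index=False)
    tables["selection"].to_csv(out / "selection.csv", index=False)
    tables["spatial"].to_csv(out / "spatial.csv", index=False)
    fits = run_stats(tables["features"], tables["spatial"], run_cfg)
    (out / "stats.json").write_text(json.dumps(fits, indent=2, sort_keys=True))
    write_report(tables["features"], fits, out / "report.txt")
    manifest = {"version": __version__, "run_config": run_cfg.to_dict(),
                "run_config_hash": run_cfg.hash(),
                "cohort_seed": cohort_cfg.seed}
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return {"tables": tables, "fits": fits, "cohort": cohort}
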
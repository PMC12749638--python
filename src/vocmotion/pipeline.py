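"""End-to-end orchestration: session files -> QC -> epochs -> report.

``run_pipeline`` drives every stage for a list of session manifests:
clap-based clock alignment, gap filling and resampling, magnitude +
highpass, artifact masking, vocalisation-locked epoching with envelope
baseline correction, window medians, and the mixed-model suite.  Failures
are isolated per session; a run manifest records versions, seed, config
hash and any failures.  Plot panels are produced from arrays that are also
exported as TSV, so downstream checks never read pixels.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
import traceback
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from . import __version__, epoching, io_formats, preprocess, sync_qc
from .types import (EPOCH_RATE, MagnitudeSeries, SessionManifest,
                    WindowBounds, epoch_time_grid, LIMBS)

log = logging.getLogger("vocmotion")


@dataclass
class PipelineConfig:
    """Run-wide options; every default mirrors the analysis description."""

    manifests: List[str] = field(default_factory=list)
    out_dir: str = "vocmotion_out"
    tier: Optional[str] = None           # override manifest tier name
    artifact_threshold: Optional[float] = None  # None -> median + 10*MAD
    exclude_overlapping: bool = False
    zero_phase: bool = True
    sync_max_lag: float = 10.0
    expected_claps: int = 5
    run_stats: bool = True
    lattice: bool = True
    make_plots: bool = True
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_yaml(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _audio_envelope_series(audio, rate: float = EPOCH_RATE
                           ) -> MagnitudeSeries:
    """Frame-RMS audio amplitude envelope at the epoch rate."""
    from .types import Placement
    t, env = sync_qc._envelope_at_rate(
        audio.samples, audio.rate, audio.t0, rate, audio.t0,
        audio.t0 + audio.duration - 1.0 / rate)
    return MagnitudeSeries(t=t, value=env, rate=rate,
                           placement=Placement("infant", "head", "na"))


def process_session(manifest: SessionManifest, config: PipelineConfig):
    """One session: sync, preprocess, epoch, summarise.

    Returns (event_rows, qc, epochs, audio_epochs).
    """
    manifest.validate()
    audio = io_formats.read_wav(manifest.audio_path)
    tier = config.tier or manifest.tier
    events = io_formats.read_textgrid(manifest.annotation_path, tier)
    channels = {pl: io_formats.read_acc_table(p, pl, manifest.nominal_rate)
                for pl, p in manifest.acc_paths.items()}

    sync_cfg = sync_qc.SyncConfig(expected_claps=config.expected_claps,
                                  max_lag=config.sync_max_lag)
    hands = [channels[pl] for pl in manifest.caregiver_hands()]
    qc: Dict = {"infant_id": manifest.infant_id,
                "time_point": manifest.time_point}
    if hands:
        est = sync_qc.estimate_lag(audio, hands, sync_cfg)
        qc["lag"] = est.lag
        qc["peak_corr"] = est.peak_corr
        lag = est.lag
    else:
        log.warning("%s: no caregiver hand channels; assuming aligned "
                    "clocks", manifest.infant_id)
        qc["lag"] = lag = 0.0
        qc["peak_corr"] = None

    bounds = WindowBounds()
    all_epochs: List[epoching.Epoch] = []
    qc["channels"] = {}
    for pl in manifest.infant_channels():
        (ch,) = sync_qc.apply_lag([channels[pl]], lag)
        ch = preprocess.fill_gaps(ch)
        ch = preprocess.resample_to_rate(ch, EPOCH_RATE)
        mag = preprocess.magnitude(ch)
        art_mask, art_qc = sync_qc.detect_artifacts(
            mag, threshold=config.artifact_threshold)
        series = preprocess.highpass(mag, zero_phase=config.zero_phase)
        series.mask = series.mask | art_mask
        eps = epoching.extract_epochs(
            series, events, bounds,
            exclude_overlapping=config.exclude_overlapping,
            infant_id=manifest.infant_id, time_point=manifest.time_point)
        for ep in eps:
            epoching.envelope_baseline_correct(ep, bounds)
            epoching.analytic_envelope(ep)
        all_epochs.extend(eps)
        qc["channels"][pl.key] = {
            "masked_seconds": art_qc["masked_seconds"],
            "artifact_threshold": art_qc["threshold"],
            "gap_seconds": float(ch.gap_mask.sum() / ch.rate),
            "n_epochs_included": sum(not e.excluded for e in eps),
            "n_epochs_excluded": sum(e.excluded for e in eps),
        }
    rows = epoching.window_medians(all_epochs, bounds)
    # audio envelope epochs for the grand-average panels
    env_series = _audio_envelope_series(audio)
    audio_eps = epoching.extract_epochs(
        env_series, events, bounds, infant_id=manifest.infant_id,
        time_point=manifest.time_point)
    return rows, qc, all_epochs, audio_eps


def plot_envelope_panels(epochs, audio_epochs, event_rows, out_dir):
    """Per-time-point grand-average envelope panels + window boxplots.

    Returns the plotted arrays (dict per time point) and writes them as
    TSV next to the figures.
    """
    os.makedirs(out_dir, exist_ok=True)
    tgrid = epoch_time_grid()
    arrays = {}
    tps = sorted({ep.time_point for ep in epochs if not ep.excluded})
    for tp in tps:
        panel = {"t": tgrid}
        for limb in LIMBS:
            curves = [ep.envelope for ep in epochs
                      if not ep.excluded and ep.time_point == tp
                      and ep.limb == limb]
            if len(curves) >= 2:
                m, se = epoching.grand_average_envelope(curves)
                panel[f"{limb}_mean"], panel[f"{limb}_se"] = m, se
        audio_curves = [ep.raw for ep in audio_epochs
                        if not ep.excluded and ep.time_point == tp]
        if len(audio_curves) >= 2:
            m, se = epoching.grand_average_envelope(audio_curves)
            panel["audio_mean"], panel["audio_se"] = m, se
        arrays[tp] = panel
        pd.DataFrame(panel).to_csv(
            os.path.join(out_dir, f"envelope_t{tp}.tsv"), sep="\t",
            index=False)
        fig, ax = plt.subplots(figsize=(7, 4))
        for key, color in (("audio", "0.3"), ("arm", "tab:blue"),
                           ("leg", "tab:orange")):
            if f"{key}_mean" in panel:
                m, se = panel[f"{key}_mean"], panel[f"{key}_se"]
                ax.plot(tgrid, m, color=color, label=key)
                ax.fill_between(tgrid, m - se, m + se, color=color,
                                alpha=0.25)
        for a, b in ((-2.5, -0.9), (-0.9, 0.0), (0.0, 0.9)):
            ax.axvspan(a, b, color="0.9", zorder=0)
        ax.axvline(0.0, color="k", lw=0.5)
        ax.set(xlabel="time from vocalisation onset [s]",
               ylabel="envelope [m/s$^2$]", title=f"{tp} months")
        ax.legend()
        fig.tight_layout()
        fig.savefig(os.path.join(out_dir, f"envelope_t{tp}.png"), dpi=100)
        plt.close(fig)
    if len(event_rows):
        agg = epoching.aggregate_medians(event_rows)
        fig, axes = plt.subplots(1, len(LIMBS), figsize=(10, 4),
                                 sharey=True)
        for ax, limb in zip(np.atleast_1d(axes), LIMBS):
            sub = agg[agg["limb"] == limb]
            data, labels = [], []
            for tp in sorted(sub["time_point"].unique()):
                for w in ("base", "pre", "during"):
                    vals = sub.loc[(sub.time_point == tp) &
                                   (sub.window == w), "median"]
                    data.append(vals.to_numpy())
                    labels.append(f"{tp}m\n{w}")
            if max((len(v) for v in data), default=0) > 1:
                ax.boxplot(data, tick_labels=labels)
            else:  # single infant: points, not boxes
                for k, v in enumerate(data, start=1):
                    ax.plot([k] * len(v), v, "o", color="tab:blue")
                ax.set_xticks(range(1, len(labels) + 1), labels)
            ax.set_title(limb)
            ax.tick_params(labelsize=7)
        fig.tight_layout()
        fig.savefig(os.path.join(out_dir, "window_boxplots.png"), dpi=100)
        plt.close(fig)
    return arrays


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every session and the statistics suite; isolate failures."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(),
                                      logging.INFO))
    os.makedirs(config.out_dir, exist_ok=True)
    all_rows, qcs, failures = [], [], []
    all_epochs, all_audio_eps = [], []
    for mpath in config.manifests:
        try:
            manifest = (mpath if isinstance(mpath, SessionManifest)
                        else io_formats.read_manifest(mpath))
            rows, qc, eps, audio_eps = process_session(manifest, config)
            all_rows.append(rows)
            qcs.append(qc)
            all_epochs.extend(eps)
            all_audio_eps.extend(audio_eps)
            log.info("session %s/t%s: %d event rows",
                     qc["infant_id"], qc["time_point"], len(rows))
        except Exception as exc:  # noqa: BLE001 - isolate per session
            failures.append({"manifest": str(mpath), "error": str(exc),
                             "traceback": traceback.format_exc()})
            log.error("session %s failed: %s", mpath, exc)
    outputs = {"n_sessions": len(qcs), "n_failures": len(failures)}
    event_rows = (pd.concat(all_rows, ignore_index=True) if all_rows
                  else pd.DataFrame())
    if len(event_rows):
        summary_path = os.path.join(config.out_dir, "summary_events.tsv")
        io_formats.write_summary_table(event_rows, summary_path)
        agg_path = os.path.join(config.out_dir, "summary_aggregated.tsv")
        io_formats.write_summary_table(
            epoching.aggregate_medians(event_rows), agg_path)
        outputs["summary_events"] = summary_path
        outputs["summary_aggregated"] = agg_path
        if config.run_stats:
            try:
                report = stats_report(event_rows, lattice=config.lattice)
                rp = os.path.join(config.out_dir, "report.json")
                with open(rp, "w", encoding="utf-8") as fh:
                    json.dump(report, fh, indent=1, default=float)
                outputs["report"] = rp
            except Exception as exc:  # noqa: BLE001 - keep QC/summary output
                failures.append({"manifest": "<stats>", "error": str(exc),
                                 "traceback": traceback.format_exc()})
                log.error("statistics suite failed: %s", exc)
        if config.make_plots:
            plot_dir = os.path.join(config.out_dir, "figures")
            plot_envelope_panels(all_epochs, all_audio_eps, event_rows,
                                 plot_dir)
            outputs["figures"] = plot_dir
    with open(os.path.join(config.out_dir, "qc.json"), "w",
              encoding="utf-8") as fh:
        json.dump(qcs, fh, indent=1, default=float)
    run_manifest = {
        "version": __version__, "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_sessions_ok": len(qcs), "failures": failures,
    }
    with open(os.path.join(config.out_dir, "run_manifest.json"), "w",
              encoding="utf-8") as fh:
        json.dump(run_manifest, fh, indent=1)
    outputs["run_manifest"] = run_manifest
    outputs["event_rows"] = event_rows
    return outputs


def stats_report(event_rows: pd.DataFrame, lattice: bool = True) -> dict:
    from .stats import run_full_suite
    return run_full_suite(event_rows, lattice=lattice)
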
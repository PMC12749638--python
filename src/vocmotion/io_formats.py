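"""Readers and writers for every external format the pipeline touches.

Formats: RIFF WAV (PCM 16/24/32 and float), Praat TextGrid (long and short
text dialects; binary TextGrids are rejected), the accelerometer CSV dialect
defined by this package (header ``time_s,acc_x,acc_y,acc_z``), YAML session
manifests, and TSV summary tables.  Every reader/writer pair round-trips
losslessly on valid data (exactly for text, to <=1e-6 relative for floats).
"""
from __future__ import annotations

import io
import os
import re
import warnings
from typing import List, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .types import (AccChannel, AudioTrack, Placement, SessionManifest,
                    VocEvent)


class FormatError(ValueError):
    """A file failed to parse as its declared format."""


# --------------------------------------------------------------------------
# WAV
# --------------------------------------------------------------------------

_PCM_SCALE = {np.dtype("int16"): 2 ** 15,
              np.dtype("int32"): 2 ** 31,
              np.dtype("uint8"): 2 ** 7}


def read_wav(path) -> AudioTrack:
    """Read a PCM or float WAV file into a normalised [-1, 1] AudioTrack.

    Multi-channel files are averaged to mono; the session clock starts at
    the first audio sample (t0 = 0).
    """
    if not os.path.exists(path):
        raise FormatError(f"WAV file not found: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rate, data = wavfile.read(path)
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise FormatError(f"cannot read WAV file {path}: {exc}") from exc
    data = np.atleast_1d(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if data.dtype in _PCM_SCALE:
        scale = _PCM_SCALE[data.dtype]
        if data.dtype == np.dtype("uint8"):
            samples = (data.astype(float) - 128.0) / scale
        else:
            samples = data.astype(float) / scale
    else:
        samples = data.astype(float)
    return AudioTrack(samples=samples, rate=float(rate), t0=0.0)


def write_wav(path, track: AudioTrack, dtype: str = "float32"):
    """Write an AudioTrack; float32 by default, or 16-bit PCM."""
    if dtype == "float32":
        wavfile.write(path, int(round(track.rate)),
                      track.samples.astype(np.float32))
    elif dtype == "int16":
        clipped = np.clip(track.samples, -1.0, 1.0)
        wavfile.write(path, int(round(track.rate)),
                      np.round(clipped * (2 ** 15 - 1)).astype(np.int16))
    else:
        raise ValueError(f"unsupported WAV dtype {dtype!r}")


# --------------------------------------------------------------------------
# Praat TextGrid
# --------------------------------------------------------------------------

def _textgrid_tokens(text: str):
    """Praat token stream: quoted strings (with doubled-quote escapes) and
    bare numbers/words, comments after ``!`` removed outside strings."""
    tokens = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
        elif c == '"':
            j = i + 1
            parts = []
            while True:
                k = text.find('"', j)
                if k < 0:
                    raise FormatError("unterminated string in TextGrid")
                if k + 1 < n and text[k + 1] == '"':
                    parts.append(text[j:k] + '"')
                    j = k + 2
                else:
                    parts.append(text[j:k])
                    break
            tokens.append(('str', ''.join(parts)))
            i = k + 1
        elif c == '!':
            i = text.find('\n', i)
            if i < 0:
                break
        else:
            j = i
            while j < n and not text[j].isspace() and text[j] != '"':
                j += 1
            tokens.append(('bare', text[i:j]))
            i = j
    return tokens


def _parse_textgrid(text: str) -> dict:
    """Parse long or short TextGrid text into {tier_name: [(xmin,xmax,label)]}.

    Both dialects reduce to the same token sequence once keys, ``=`` signs,
    brackets and size markers are dropped; interval tiers are walked as
    (xmin, xmax, n, (xmin, xmax, text)*), point tiers as (xmin, xmax, n,
    (time, mark)*).
    """
    toks = _textgrid_tokens(text)
    # drop structural bare tokens from the long dialect
    drop = {"=", "item", "class", "name", "xmin", "xmax", "intervals",
            "points", "size", "tiers?", "text", "number", "mark",
            "<exists>", "File", "type", "Object"}
    values = []
    for kind, val in toks:
        if kind == 'bare':
            if re.fullmatch(r"\[\d*\]:?", val):
                continue
            bare = val.rstrip(":")
            if bare in drop or bare == "":
                continue
            values.append(('bare', bare))
        else:
            values.append(('str', val))
    # header: "ooTextFile", "TextGrid", xmin, xmax, (exists), ntiers
    if len(values) < 2 or values[0][1] != "ooTextFile":
        raise FormatError("not a text TextGrid (binary TextGrids are "
                          "not supported)")
    if values[1][1] != "TextGrid":
        raise FormatError("file is an ooTextFile but not a TextGrid")
    idx = 2
    nums = []
    while idx < len(values) and values[idx][0] == 'bare':
        nums.append(values[idx][1])
        idx += 1
    if len(nums) < 3:
        raise FormatError("malformed TextGrid header")
    ntiers = int(float(nums[-1]))
    tiers = {}
    for _ in range(ntiers):
        if idx >= len(values):
            raise FormatError("truncated TextGrid: missing tier")
        kind, tier_class = values[idx]
        idx += 1
        if tier_class not in ("IntervalTier", "TextTier"):
            raise FormatError(f"unknown tier class {tier_class!r}")
        tier_name = values[idx][1]
        idx += 1
        idx += 2  # tier xmin, xmax
        n_items = int(float(values[idx][1]))
        idx += 1
        items = []
        per = 3 if tier_class == "IntervalTier" else 2
        for _k in range(n_items):
            fields = values[idx:idx + per]
            if len(fields) < per:
                raise FormatError("truncated TextGrid tier "
                                  f"{tier_name!r} at item {_k + 1}")
            if tier_class == "IntervalTier":
                items.append((float(fields[0][1]), float(fields[1][1]),
                              fields[2][1]))
            else:
                items.append((float(fields[0][1]), float(fields[0][1]),
                              fields[1][1]))
            idx += per
        tiers[tier_name] = items
    return tiers


def read_textgrid(path, tier_name: str = "vocalisations",
                  coder: str = "") -> List[VocEvent]:
    """Read one interval tier of a Praat TextGrid as a sorted event list.

    Intervals with empty or whitespace-only labels are dropped (Praat pads
    tiers with unlabelled intervals); overlapping labelled intervals are
    rejected — the annotation scheme is utterance-level on one tier.
    """
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        text = fh.read()
    if text.startswith("ooBinaryFile"):
        raise FormatError("binary TextGrids are not supported; re-save as "
                          "a text TextGrid in Praat")
    try:
        tiers = _parse_textgrid(text)
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"malformed TextGrid {path}: {exc}") from exc
    if tier_name not in tiers:
        raise FormatError(
            f"tier {tier_name!r} not found in {path}; available tiers: "
            f"{sorted(tiers)}")
    events = [VocEvent(onset=a, offset=b, label=lab.strip(), coder=coder)
              for a, b, lab in tiers[tier_name] if lab.strip()]
    events.sort(key=lambda e: e.onset)
    for prev, nxt in zip(events, events[1:]):
        if nxt.onset < prev.offset - 1e-9:
            raise FormatError(
                f"overlapping annotated intervals at {prev.offset:.3f}s / "
                f"{nxt.onset:.3f}s in tier {tier_name!r}")
    return events


def write_textgrid(path, events: Sequence[VocEvent],
                   tier_name: str = "vocalisations",
                   xmax: float = None):
    """Write events as a long-format TextGrid with one interval tier.

    Unlabelled padding intervals are inserted between events, as Praat does.
    """
    events = sorted(events, key=lambda e: e.onset)
    if xmax is None:
        xmax = (events[-1].offset + 1.0) if events else 1.0
    intervals = []
    cursor = 0.0
    for ev in events:
        if ev.onset > cursor:
            intervals.append((cursor, ev.onset, ""))
        intervals.append((ev.onset, ev.offset, ev.label))
        cursor = ev.offset
    if cursor < xmax:
        intervals.append((cursor, xmax, ""))
    if not intervals:
        intervals = [(0.0, xmax, "")]
    buf = io.StringIO()
    buf.write('File type = "ooTextFile"\nObject class = "TextGrid"\n\n')
    buf.write(f"xmin = 0\nxmax = {xmax:.10f}\ntiers? <exists>\nsize = 1\n")
    buf.write("item []:\n    item [1]:\n")
    buf.write('        class = "IntervalTier"\n')
    buf.write(f'        name = "{tier_name}"\n')
    buf.write(f"        xmin = 0\n        xmax = {xmax:.10f}\n")
    buf.write(f"        intervals: size = {len(intervals)}\n")
    for i, (a, b, lab) in enumerate(intervals, start=1):
        buf.write(f"        intervals [{i}]:\n")
        buf.write(f"            xmin = {a:.10f}\n")
        buf.write(f"            xmax = {b:.10f}\n")
        buf.write(f'            text = "{lab.replace(chr(34), chr(34) * 2)}"\n')
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


# --------------------------------------------------------------------------
# Accelerometer tables
# --------------------------------------------------------------------------

ACC_COLUMNS = ("time_s", "acc_x", "acc_y", "acc_z")


def read_acc_table(path, placement: Placement,
                   nominal_rate: float = 60.0) -> AccChannel:
    """Read one sensor's CSV into an AccChannel on a reconstructed grid.

    Dropped packets (time step > 1.5/nominal_rate) are re-inserted at the
    nominal rate as NaN samples with ``gap_mask`` set; non-finite readings
    are likewise masked.  A locally *denser* grid (e.g. a 60->40 Hz rate
    drop yields 25 ms steps, exactly the 1.5/60 s limit) is passed through
    untouched for the resampler.
    """
    df = pd.read_csv(path)
    for col in ACC_COLUMNS:
        if col not in df.columns:
            raise FormatError(
                f"accelerometer table {path} lacks required column "
                f"{col!r} (schema: {','.join(ACC_COLUMNS)})")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise FormatError(f"non-monotone timestamps in {path}")
    xyz = [df[c].to_numpy(dtype=float) for c in ("acc_x", "acc_y", "acc_z")]
    step = 1.0 / nominal_rate
    max_step = 1.5 * step
    t_out, cols_out, mask_out = [], [[], [], []], []

    def push(ti, vals, masked):
        t_out.append(ti)
        for c, v in zip(cols_out, vals):
            c.append(v)
        mask_out.append(masked)

    for i in range(t.size):
        if i > 0 and (t[i] - t[i - 1]) > max_step + 1e-12:
            n_fill = int(np.floor((t[i] - t[i - 1]) / step + 1e-9)) - 1
            for k in range(1, n_fill + 1):
                push(t[i - 1] + k * step, (np.nan,) * 3, True)
        vals = tuple(c[i] for c in xyz)
        push(t[i], vals, not all(np.isfinite(v) for v in vals))
    return AccChannel(
        t=np.array(t_out), x=np.array(cols_out[0]), y=np.array(cols_out[1]),
        z=np.array(cols_out[2]), rate=nominal_rate, placement=placement,
        gap_mask=np.array(mask_out, dtype=bool))


def write_acc_table(path, channel: AccChannel):
    """Write an AccChannel as the package's CSV dialect.

    Gap-masked samples are written as empty fields so a round trip
    re-detects them.
    """
    df = pd.DataFrame({
        "time_s": channel.t,
        "acc_x": np.where(channel.gap_mask, np.nan, channel.x),
        "acc_y": np.where(channel.gap_mask, np.nan, channel.y),
        "acc_z": np.where(channel.gap_mask, np.nan, channel.z),
    })
    df.to_csv(path, index=False, float_format="%.9g")


# --------------------------------------------------------------------------
# Session manifests (YAML)
# --------------------------------------------------------------------------

def read_manifest(path) -> SessionManifest:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    base = os.path.dirname(os.path.abspath(path))

    def resolve(p):
        return p if os.path.isabs(p) else os.path.join(base, p)

    acc_paths = {}
    for entry in doc["sensors"]:
        pl = Placement(entry["wearer"], entry["limb"], entry.get("side", "na"))
        if pl.wearer == "infant" and pl.limb not in ("arm", "leg"):
            continue  # head/torso accepted in the manifest, ignored downstream
        acc_paths[pl] = resolve(entry["path"])
    return SessionManifest(
        infant_id=str(doc["infant_id"]),
        time_point=int(doc["time_point"]),
        audio_path=resolve(doc["audio"]),
        annotation_path=resolve(doc["annotations"]),
        acc_paths=acc_paths,
        nominal_rate=float(doc.get("nominal_rate", 60.0)),
        tier=doc.get("tier", "vocalisations"),
    )


def write_manifest(path, manifest: SessionManifest):
    base = os.path.dirname(os.path.abspath(path))

    def rel(p):
        try:
            return os.path.relpath(p, base)
        except ValueError:
            return p

    doc = {
        "infant_id": manifest.infant_id,
        "time_point": manifest.time_point,
        "audio": rel(manifest.audio_path),
        "annotations": rel(manifest.annotation_path),
        "tier": manifest.tier,
        "nominal_rate": manifest.nominal_rate,
        "sensors": [
            {"wearer": pl.wearer, "limb": pl.limb, "side": pl.side,
             "path": rel(p)}
            for pl, p in manifest.acc_paths.items()
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# --------------------------------------------------------------------------
# Summary tables
# --------------------------------------------------------------------------

SUMMARY_KEY = ["infant_id", "time_point", "limb", "window"]


def write_summary_table(rows: pd.DataFrame, path):
    """Write a long-format window-summary table as TSV.

    One row per key (infant x time_point x limb x window, plus the event
    index when the table is event-level); duplicate keys are rejected.
    """
    key = list(SUMMARY_KEY)
    if "event" in rows.columns:
        key.append("event")
    missing = [k for k in key if k not in rows.columns]
    if missing:
        raise ValueError(f"summary table lacks key columns {missing}")
    dup = rows.duplicated(subset=key)
    if dup.any():
        first = rows.loc[dup, key].iloc[0].to_dict()
        raise ValueError(f"duplicate summary row for key {first}")
    ordered = key + [c for c in rows.columns if c not in key]
    rows[ordered].to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_summary_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["infant_id"] = df["infant_id"].astype(str)
    return df
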
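"""Plain-text I/O: wide CSV raw sessions, TSV events, JSON montage, config.

Canonical dialects: UTF-8, '.' decimal, comma (CSV) / tab (TSV) separators.
Times are seconds from recording start; block intervals are half-open
[onset, onset + duration).
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from .core import (
    EVENT_LABELS,
    ChannelInfo,
    Event,
    Protocol,
    RawRecording,
    default_montage,
    events_to_protocol,
)
from .preprocess import PreprocessConfig

__all__ = [
    "write_raw_csv",
    "read_raw_csv",
    "write_events_tsv",
    "read_events_tsv",
    "write_montage_json",
    "read_montage_json",
    "load_config",
    "write_hemo_csv",
]


def _raw_columns(n_channels: int, wavelengths) -> list[str]:
    return [f"CH{k}_{int(wl)}" for k in range(1, n_channels + 1) for wl in wavelengths]


def write_raw_csv(rec: RawRecording, path) -> None:
    cols = _raw_columns(rec.n_channels, rec.wavelengths)
    flat = rec.intensity.reshape(rec.n_channels * len(rec.wavelengths), -1).T
    df = pd.DataFrame(flat, columns=cols)
    df.insert(0, "time_s", rec.times)
    df.to_csv(path, index=False)


def read_raw_csv(path, sampling_rate: float | None = None,
                 events=None, montage=None) -> RawRecording:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("malformed header: missing time_s column")
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError("need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"non-monotone time column near row {int(np.argmin(dt)) + 1}")
    fs = sampling_rate or 1.0 / np.median(dt)

    value_cols = [c for c in df.columns if c != "time_s"]
    wavelengths = []
    n_channels = 0
    for c in value_cols:
        name, _, wl = c.rpartition("_")
        if not name.startswith("CH") or not wl.isdigit():
            raise ValueError(f"malformed column name {c!r}")
        n_channels = max(n_channels, int(name[2:]))
        if float(wl) not in wavelengths:
            wavelengths.append(float(wl))
    expected = _raw_columns(n_channels, wavelengths)
    if value_cols != expected:
        raise ValueError("columns must be CH{k}_{wavelength} in channel-major order")

    values = df[value_cols].to_numpy().T.reshape(n_channels, len(wavelengths), -1)
    bad = np.argwhere(values <= 0)
    if bad.size:
        row = int(bad[0][2])
        raise ValueError(f"non-positive intensity at data row {row}")
    return RawRecording(values, fs, tuple(wavelengths),
                        events=list(events or []),
                        montage=montage or default_montage())


def write_events_tsv(events, path, protocol: Protocol | None = None) -> None:
    """Events as TSV (onset_s, duration_s, label, tag_value); block events
    get their duration from the protocol when available."""
    rows = []
    for ev in events:
        dur = ""
        if protocol is not None:
            block = protocol.block_at(ev.time_s)
            if block is not None and block.onset_s == ev.time_s and \
                    block.condition == ev.label:
                dur = block.duration_s
        rows.append({"onset_s": ev.time_s, "duration_s": dur, "label": ev.label,
                     "tag_value": "" if ev.tag_value is None else ev.tag_value})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> tuple[list[Event], Protocol | None]:
    """Read events; when block rows carry durations, also rebuild the Protocol."""
    df = pd.read_csv(path, sep="\t")
    events = []
    block_events = []
    for i, row in df.iterrows():
        label = str(row["label"])
        if label not in EVENT_LABELS:
            raise ValueError(f"unknown event label {label!r} at row {i}")
        tag = None if pd.isna(row.get("tag_value")) else float(row["tag_value"])
        ev = Event(float(row["onset_s"]), label, tag)
        events.append(ev)
        dur = row.get("duration_s")
        if dur is not None and not pd.isna(dur) and label != "KEYPRESS":
            block_events.append((ev, float(dur)))
    protocol = events_to_protocol(events, block_events=block_events) \
        if block_events else None
    return events, protocol


def write_montage_json(montage: dict[str, ChannelInfo], path) -> None:
    payload = {name: asdict(info) for name, info in montage.items()}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def read_montage_json(path) -> dict[str, ChannelInfo]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return {name: ChannelInfo(**info) for name, info in payload.items()}


def write_hemo_csv(hemo, path) -> None:
    cols = {}
    for i, name in enumerate(hemo.channel_names):
        cols[f"{name}_hbo"] = hemo.hbo[i]
        cols[f"{name}_hbr"] = hemo.hbr[i]
    df = pd.DataFrame(cols)
    df.insert(0, "time_s", hemo.times)
    df.to_csv(path, index=False)


def load_config(path) -> PreprocessConfig:
    """Preprocessing config from YAML or JSON (keys match PreprocessConfig)."""
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict):
        raise ValueError("config file must contain a mapping")
    if "exclude" in payload:
        payload["exclude"] = tuple(tuple(pair) for pair in payload["exclude"])
    if "stages" in payload:
        payload["stages"] = tuple(payload["stages"])
    if "extinction" in payload:
        payload["extinction"] = {float(k): tuple(v)
                                 for k, v in payload["extinction"].items()}
    return PreprocessConfig(**payload)
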
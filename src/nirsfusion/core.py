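"""Core domain containers shared across the pipeline.

A session is a block-design protocol (mid-gray baseline interleaved with
binocular color fusion / rivalry stimuli), recorded as dual-wavelength light
intensities on a 14-channel prefrontal montage sampled at 20 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

#: Condition labels used throughout: mid-gray baseline field, binocular color
#: fusion on the red/green axis, and binocular color rivalry on the same axis.
GRAY = "GRAY"
FORG = "FORG"
RORG = "RORG"
#: Behavioral marker written when the participant reports perceiving rivalry.
KEYPRESS = "KEYPRESS"

CONDITIONS = (GRAY, FORG, RORG)
EVENT_LABELS = (GRAY, FORG, RORG, KEYPRESS)

N_CHANNELS = 14
WAVELENGTHS_NM = (730.0, 850.0)
SAMPLING_RATE_HZ = 20.0

#: Brodmann-area assignment of the prefrontal montage.
FRONTOPOLAR = "Frontopolar area"
DLPFC = "Dorsolateral prefrontal cortex"
FEF = "Includes frontal eye fields"

_REGION_BY_CHANNEL = {
    **{ch: FRONTOPOLAR for ch in (2, 3, 4, 5, 6, 9)},
    **{ch: DLPFC for ch in (1, 7, 8, 10, 11, 12)},
    **{ch: FEF for ch in (13, 14)},
}


@dataclass(frozen=True)
class ChannelInfo:
    """One source-detector optode pair.

    The source/detector pairing is a nominal layout (6 sources, 5 detectors);
    the cortical region label and the default 30 mm separation follow a
    standard adult prefrontal montage.
    """

    source: str
    detector: str
    region: str
    distance_mm: float = 30.0


def default_montage() -> dict[str, ChannelInfo]:
    """Nominal 14-channel prefrontal montage (CH1..CH14)."""
    montage = {}
    for k in range(1, N_CHANNELS + 1):
        montage[f"CH{k}"] = ChannelInfo(
            source=f"S{(k - 1) % 6 + 1}",
            detector=f"D{(k - 1) % 5 + 1}",
            region=_REGION_BY_CHANNEL[k],
        )
    return montage


def channel_names(n: int = N_CHANNELS) -> list[str]:
    return [f"CH{k}" for k in range(1, n + 1)]


@dataclass(frozen=True)
class Block:
    condition: str
    onset_s: float
    duration_s: float

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s

    def contains(self, t: float) -> bool:
        """Half-open membership [onset, onset + duration)."""
        return self.onset_s <= t < self.end_s


@dataclass(frozen=True)
class Protocol:
    """An ordered, non-overlapping sequence of stimulus blocks."""

    blocks: tuple[Block, ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("protocol must contain at least one block")
        prev_end = -np.inf
        prev_onset = -np.inf
        for b in self.blocks:
            if b.condition not in CONDITIONS:
                raise ValueError(f"unknown condition label {b.condition!r}")
            if b.duration_s <= 0:
                raise ValueError("block durations must be positive")
            if b.onset_s <= prev_onset:
                raise ValueError("block onsets must be strictly increasing")
            if b.onset_s < prev_end - 1e-12:
                raise ValueError("blocks must not overlap")
            prev_onset, prev_end = b.onset_s, b.end_s

    @property
    def total_duration_s(self) -> float:
        return self.blocks[-1].end_s

    @property
    def conditions(self) -> tuple[str, ...]:
        """Distinct labels in order of first appearance."""
        seen: list[str] = []
        for b in self.blocks:
            if b.condition not in seen:
                seen.append(b.condition)
        return tuple(seen)

    def blocks_for(self, condition: str) -> tuple[Block, ...]:
        out = tuple(b for b in self.blocks if b.condition == condition)
        if not out:
            raise ValueError(f"condition {condition!r} absent from protocol")
        return out

    def block_at(self, t: float) -> Block | None:
        for b in self.blocks:
            if b.contains(t):
                return b
        return None


@dataclass(frozen=True)
class Event:
    time_s: float
    label: str
    tag_value: float | None = None


@dataclass(frozen=True)
class ArtifactTruth:
    """Ground-truth record of an injected motion artifact (simulation only)."""

    kind: str  # "spike" | "shift"
    channel: int  # 0-based channel index
    time_s: float
    duration_s: float
    amplitude_od: float


@dataclass
class RawRecording:
    """Dual-wavelength light-intensity recording with event markers.

    ``intensity`` has shape (n_channels, n_wavelengths, n_samples) in
    arbitrary units, strictly positive.
    """

    intensity: np.ndarray
    sampling_rate: float = SAMPLING_RATE_HZ
    wavelengths: tuple[float, ...] = WAVELENGTHS_NM
    events: list[Event] = field(default_factory=list)
    montage: dict[str, ChannelInfo] = field(default_factory=default_montage)
    artifacts: list[ArtifactTruth] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be (channels, wavelengths, samples)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.intensity.shape[1] != len(self.wavelengths):
            raise ValueError("wavelength axis does not match wavelength list")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity <= 0):
            raise ValueError("intensity must be finite and strictly positive")
        dur = self.duration_s
        for ev in self.events:
            if not 0.0 <= ev.time_s <= dur:
                raise ValueError(f"event at {ev.time_s} s outside recording span")

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    @property
    def channel_names(self) -> list[str]:
        return channel_names(self.n_channels)

    def copy_with(self, **kw) -> "RawRecording":
        return replace(self, **kw)


@dataclass
class ODSeries:
    """Optical-density change, -ln(I / I0), per channel and wavelength."""

    od: np.ndarray  # (n_channels, n_wavelengths, n_samples)
    sampling_rate: float
    wavelengths: tuple[float, ...] = WAVELENGTHS_NM
    events: list[Event] = field(default_factory=list)
    baseline_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)
        if not np.all(np.isfinite(self.od)):
            raise ValueError("optical density must be finite")

    @property
    def n_channels(self) -> int:
        return self.od.shape[0]

    @property
    def n_samples(self) -> int:
        return self.od.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass
class HemoSeries:
    """Per-channel chromophore concentration changes (micromolar)."""

    hbo: np.ndarray  # (n_channels, n_samples)
    hbr: np.ndarray
    sampling_rate: float
    events: list[Event] = field(default_factory=list)
    dpf: float = 6.0
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("HbO and HbR must share a shape")
        if not (np.all(np.isfinite(self.hbo)) and np.all(np.isfinite(self.hbr))):
            raise ValueError("hemoglobin series must be finite")

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    @property
    def channel_names(self) -> list[str]:
        return channel_names(self.n_channels)

    def series(self, chromophore: str = "hbo") -> np.ndarray:
        if chromophore not in ("hbo", "hbr"):
            raise ValueError("chromophore must be 'hbo' or 'hbr'")
        return self.hbo if chromophore == "hbo" else self.hbr


def round_half_up(x, decimals: int = 2):
    """Round with ties away from zero, as printed tables conventionally do."""
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return float(out) if out.ndim == 0 else out


def events_to_protocol(events: Iterable[Event], durations: dict | None = None,
                       block_events: Iterable[tuple[Event, float]] | None = None) -> Protocol:
    """Rebuild a Protocol from block-onset events paired with durations.

    ``block_events`` is the explicit (event, duration) form used by the
    events-TSV reader; otherwise ``durations`` maps labels to durations.
    """
    blocks = []
    if block_events is not None:
        for ev, dur in block_events:
            if ev.label in CONDITIONS:
                blocks.append(Block(ev.label, ev.time_s, dur))
    else:
        if durations is None:
            raise ValueError("need durations to rebuild blocks from events")
        for ev in events:
            if ev.label in CONDITIONS:
                blocks.append(Block(ev.label, ev.time_s, durations[ev.label]))
    return Protocol(tuple(blocks))
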
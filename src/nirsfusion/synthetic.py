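"""Seedable synthetic fNIRS sessions with the structure the analysis assumes.

The forward model inverts the preprocessing chain: a per-channel true HbO
series is assembled from HRF-convolved condition responses, a shared
low-frequency latent drive mixed with a condition-dependent weight (the
mechanism that makes inter-channel coupling strongest under fusion, weaker
under rivalry, weakest under the gray field), physiological sinusoids
(cardiac ~1.2 Hz, respiratory ~0.3 Hz, Mayer ~0.1 Hz), linear drift and
white noise. HbR is an anticorrelated scaled copy of HbO. The modified
Beer-Lambert law then maps (dHbO, dHbR) to optical density at 730/850 nm
and to light intensity I = I0 * exp(-dOD), into which spike and
baseline-shift motion artifacts are injected at Poisson times.

Protocols:

* Experiment 1 — five 90 s blocks GRAY, FORG, GRAY, RORG, GRAY (450 s),
  for functional-connectivity analysis.
* Experiment 2 — eight trials of five 10 s blocks; within each trial the
  fusion and rivalry stimuli each occur exactly once in seeded random
  order, separated by gray fields (400 s), for GLM activation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    FORG,
    GRAY,
    KEYPRESS,
    N_CHANNELS,
    RORG,
    SAMPLING_RATE_HZ,
    WAVELENGTHS_NM,
    ArtifactTruth,
    Block,
    Event,
    Protocol,
    RawRecording,
    default_montage,
)
from .glm import HRFParams, hrf_kernel
from .preprocess import DEFAULT_EXTINCTION_UM_CM, bandpass_array, extinction_matrix

__all__ = [
    "SubjectParams",
    "make_protocol_exp1",
    "make_protocol_exp2",
    "simulate_session",
]

BLOCK_S_EXP1 = 90.0
BLOCK_S_EXP2 = 10.0
N_TRIALS_EXP2 = 8


def make_protocol_exp1() -> Protocol:
    """Single-trial long-block protocol: GRAY, FORG, GRAY, RORG, GRAY x 90 s."""
    labels = (GRAY, FORG, GRAY, RORG, GRAY)
    blocks = tuple(
        Block(lab, i * BLOCK_S_EXP1, BLOCK_S_EXP1) for i, lab in enumerate(labels)
    )
    return Protocol(blocks)


def make_protocol_exp2(seed: int) -> Protocol:
    """Eight counterbalanced trials of 10 s blocks.

    Each trial is GRAY, stim, GRAY, other-stim, GRAY, with the order of
    (FORG, RORG) drawn per trial from the seeded generator, so both stimuli
    occur exactly once per trial.
    """
    rng = np.random.default_rng(seed)
    blocks = []
    t = 0.0
    for _ in range(N_TRIALS_EXP2):
        first, second = (FORG, RORG) if rng.integers(2) == 0 else (RORG, FORG)
        for lab in (GRAY, first, GRAY, second, GRAY):
            blocks.append(Block(lab, t, BLOCK_S_EXP2))
            t += BLOCK_S_EXP2
    return Protocol(tuple(blocks))


def _amplitudes(value, n_channels: int) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.full(n_channels, arr[0])
    if arr.size != n_channels:
        raise ValueError("per-channel amplitude vector has wrong length")
    return arr


@dataclass
class SubjectParams:
    """Generative parameters of one synthetic participant.

    Amplitudes are in uM; ``coupling`` maps each condition to the mixing
    weight of the shared latent drive (default ordering fusion > rivalry >
    gray, mirroring the functional-connectivity contrast the generator is
    built to emulate); ``artifact_rate`` is expected motion artifacts per
    minute.
    """

    beta_true: dict = field(default_factory=lambda: {FORG: 1.0, RORG: 0.5})
    coupling: dict = field(default_factory=lambda: {FORG: 0.8, RORG: 0.4, GRAY: 0.1})
    noise_sd: float = 0.3
    physio_amps: dict = field(
        default_factory=lambda: {"cardiac": (1.2, 0.2), "respiratory": (0.3, 0.1),
                                 "mayer": (0.1, 0.1)}
    )
    drift_slope: float = 0.005  # uM per second
    artifact_rate: float = 0.5  # per minute
    latent_sd: float = 0.5  # uM, amplitude of the shared drive at weight 1
    hbr_ratio: float = 1.0 / 3.0
    spike_scale: float = 10.0  # spike amplitude in units of channel OD SD
    shift_scale: float = 5.0
    response_mean_s: float | None = None  # if set, keypresses in RORG blocks
    response_sd_s: float = 0.5
    hrf: HRFParams = field(default_factory=HRFParams)

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.latent_sd < 0 or self.artifact_rate < 0:
            raise ValueError("amplitudes and rates must be non-negative")
        for lam in self.coupling.values():
            if not 0 <= lam < 1:
                raise ValueError("coupling weights must lie in [0, 1)")
        for _, (f, a) in self.physio_amps.items():
            if f <= 0 or a < 0:
                raise ValueError("physiological frequencies/amplitudes invalid")


def _condition_response(protocol: Protocol, condition: str, n: int, fs: float,
                        hrf: HRFParams) -> np.ndarray:
    """Unit boxcar over the condition's blocks convolved with the HRF."""
    boxcar = np.zeros(n)
    for b in protocol.blocks_for(condition):
        boxcar[int(round(b.onset_s * fs)): min(int(round(b.end_s * fs)), n)] = 1.0
    return np.convolve(boxcar, hrf_kernel(fs, hrf))[:n] / fs


def simulate_session(protocol: Protocol, params: SubjectParams | None = None,
                     seed: int = 0, sampling_rate: float = SAMPLING_RATE_HZ,
                     n_channels: int = N_CHANNELS, i0: float = 1.0,
                     distance_mm: float = 30.0, dpf: float = 6.0) -> RawRecording:
    """Generate a raw dual-wavelength recording for one synthetic subject.

    Fully reproducible: identical (protocol, params, seed) give a
    bit-identical recording.
    """
    params = params or SubjectParams()
    if sampling_rate <= 0:
        raise ValueError("sampling rate must be positive")
    fs = sampling_rate
    n = int(round(protocol.total_duration_s * fs))
    if n == 0:
        raise ValueError("protocol spans no samples")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs

    # HRF-convolved condition responses
    hbo = np.zeros((n_channels, n))
    for cond, amp in params.beta_true.items():
        if cond == GRAY:
            continue  # gray is the implicit baseline
        amps = _amplitudes(amp, n_channels)
        resp = _condition_response(protocol, cond, n, fs, params.hrf)
        hbo += amps[:, None] * resp[None, :]

    # shared latent drive, mixed with the condition-dependent weight
    lam_t = np.zeros(n)
    for b in protocol.blocks:
        lam_t[int(round(b.onset_s * fs)): min(int(round(b.end_s * fs)), n)] = \
            params.coupling.get(b.condition, 0.0)
    if params.latent_sd > 0 and np.any(lam_t > 0):
        latent = rng.standard_normal(n)
        latent = bandpass_array(latent, fs, 0.01, 0.15, order=2)
        sd = latent.std()
        if sd > 0:
            latent = latent / sd * params.latent_sd
        hbo += lam_t * latent

    # physiological sinusoids with per-channel random phase, drift, noise
    for _, (freq, amp) in sorted(params.physio_amps.items()):
        if amp > 0:
            phases = rng.uniform(0, 2 * np.pi, n_channels)
            hbo += amp * np.sin(2 * np.pi * freq * t[None, :] + phases[:, None])
    if params.drift_slope:
        hbo += params.drift_slope * t[None, :]
    if params.noise_sd > 0:
        hbo += params.noise_sd * rng.standard_normal((n_channels, n))

    hbr = -params.hbr_ratio * hbo

    # forward modified Beer-Lambert: concentrations -> optical density
    E = extinction_matrix(WAVELENGTHS_NM, DEFAULT_EXTINCTION_UM_CM)
    path = (distance_mm / 10.0) * dpf
    od = np.einsum("wc,cnt->nwt", E, np.stack([hbo, hbr])) * path

    # motion artifacts: square spikes and baseline shifts at Poisson times
    artifacts: list[ArtifactTruth] = []
    n_art = rng.poisson(params.artifact_rate * protocol.total_duration_s / 60.0)
    for _ in range(n_art):
        ch = int(rng.integers(n_channels))
        time_s = float(rng.uniform(0, protocol.total_duration_s))
        sd_ch = max(od[ch].std(), 0.02)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        if rng.random() < 0.5:
            dur = float(rng.uniform(0.1, 0.3))
            amp = sign * params.spike_scale * sd_ch
            kind = "spike"
        else:
            block = protocol.block_at(time_s)
            end = block.end_s if block is not None else protocol.total_duration_s
            dur = max(end - time_s, 1.0 / fs)
            amp = sign * params.shift_scale * sd_ch
            kind = "shift"
        a = int(round(time_s * fs))
        b = min(int(round((time_s + dur) * fs)), n)
        if b <= a:
            b = a + 1
        od[ch, :, a:b] += amp
        artifacts.append(ArtifactTruth(kind, ch, time_s, dur, amp))

    intensity = i0 * np.exp(-od)

    events = [Event(b.onset_s, b.condition) for b in protocol.blocks]
    if params.response_mean_s is not None and RORG in protocol.conditions:
        for b in protocol.blocks_for(RORG):
            rt = float(np.clip(rng.normal(params.response_mean_s, params.response_sd_s),
                               0.2, b.duration_s - 0.5))
            events.append(Event(b.onset_s + rt, KEYPRESS, tag_value=1.0))
    events.sort(key=lambda ev: ev.time_s)

    montage = default_montage()
    if n_channels != N_CHANNELS:
        montage = {name: montage.get(name, next(iter(montage.values())))
                   for name in (f"CH{k}" for k in range(1, n_channels + 1))}

    return RawRecording(intensity, fs, WAVELENGTHS_NM, events, montage, artifacts)
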
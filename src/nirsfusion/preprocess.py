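"""Four-stage preprocessing chain: Exclude -> Motion -> Filter -> Hemo.

Raw dual-wavelength intensities are (1) trimmed of unwanted intervals,
(2) converted to optical density and screened for motion artifacts with a
moving-window range test (std rule: window range > std_thr x a standard
deviation reference; amplitude rule on optical density: window range >
amp_thr) followed by spline correction, (3) band-pass filtered (0.01-0.2 Hz,
zero-phase Butterworth) to suppress drift and cardiac/respiratory
oscillations, and (4) converted to HbO/HbR concentration changes with the
modified Beer-Lambert law (DPF 6).

The stage order is fixed to Exclude -> Motion -> Filter -> Hemo; a config
requesting any other order is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .core import ArtifactTruth, Event, HemoSeries, ODSeries, RawRecording

__all__ = [
    "PreprocessConfig",
    "ArtifactMask",
    "DEFAULT_EXTINCTION_UM_CM",
    "exclude_intervals",
    "intensity_to_od",
    "detect_motion",
    "correct_motion_spline",
    "bandpass",
    "bandpass_array",
    "od_to_hemo",
    "run_preprocess",
]

#: Molar extinction coefficients in cm^-1 / uM, {wavelength: (HbO, HbR)},
#: from a standard spectra compilation; override via config for other probes.
DEFAULT_EXTINCTION_UM_CM = {
    730.0: (390.0e-6, 1102.2e-6),
    850.0: (1058.0e-6, 691.32e-6),
}

STAGE_ORDER = ("exclude", "motion", "filter", "hemo")


@dataclass(frozen=True)
class PreprocessConfig:
    exclude: tuple[tuple[float, float], ...] = ()
    window_s: float = 0.5
    std_thr: float = 6.0
    amp_thr: float = 0.5
    sd_reference: str = "channel"  # "channel" | "moving"
    motion_mode: str = "spline"  # "spline" | "remove"
    low_hz: float = 0.01
    high_hz: float = 0.2
    filter_order: int = 3
    dpf: float = 6.0
    distance_mm: float | None = None  # None: use the montage's per-channel value
    extinction: dict = field(default_factory=lambda: dict(DEFAULT_EXTINCTION_UM_CM))
    baseline_window: tuple[float, float] | None = None
    chromophore: str = "hbo"
    stages: tuple[str, ...] = STAGE_ORDER

    def __post_init__(self) -> None:
        if tuple(self.stages) != STAGE_ORDER:
            raise ValueError(
                "preprocessing stages must run in the fixed order "
                f"{STAGE_ORDER}; got {tuple(self.stages)}"
            )
        if self.sd_reference not in ("channel", "moving"):
            raise ValueError("sd_reference must be 'channel' or 'moving'")
        if self.motion_mode not in ("spline", "remove"):
            raise ValueError("motion_mode must be 'spline' or 'remove'")


@dataclass
class ArtifactMask:
    flagged: np.ndarray  # (n_channels, n_samples) bool
    params: dict

    @property
    def n_flagged(self) -> np.ndarray:
        return self.flagged.sum(axis=1)


def exclude_intervals(rec: RawRecording, intervals) -> RawRecording:
    """Drop samples in [start, end) intervals and compact the timeline.

    Events inside dropped intervals are removed; remaining events are
    re-expressed on the compacted time axis.
    """
    intervals = sorted((float(a), float(b)) for a, b in intervals)
    if not intervals:
        return rec
    dur = rec.duration_s
    prev_end = -np.inf
    for a, b in intervals:
        if a >= b:
            raise ValueError(f"empty or inverted interval ({a}, {b})")
        if a < 0 or b > dur + 1e-9:
            raise ValueError(f"interval ({a}, {b}) outside recording span")
        if a < prev_end:
            raise ValueError("intervals must not overlap")
        prev_end = b

    fs = rec.sampling_rate
    keep = np.ones(rec.n_samples, dtype=bool)
    for a, b in intervals:
        keep[int(round(a * fs)): int(round(b * fs))] = False

    # cumulative kept-time before each sample gives the compacted event time
    kept_before = np.concatenate([[0], np.cumsum(keep)])
    events = []
    for ev in rec.events:
        idx = min(int(round(ev.time_s * fs)), rec.n_samples - 1)
        if keep[idx]:
            events.append(Event(kept_before[idx] / fs, ev.label, ev.tag_value))
    return rec.copy_with(intensity=rec.intensity[:, :, keep], events=events)


def intensity_to_od(rec: RawRecording,
                    baseline_window: tuple[float, float] | None = None) -> ODSeries:
    """Optical density change -ln(I / I0), I0 the mean over the baseline
    window (whole recording by default)."""
    i = rec.intensity
    if baseline_window is None:
        i0 = i.mean(axis=2, keepdims=True)
    else:
        a, b = baseline_window
        sl = slice(int(round(a * rec.sampling_rate)), int(round(b * rec.sampling_rate)))
        if sl.stop <= sl.start:
            raise ValueError("baseline window is empty")
        i0 = i[:, :, sl].mean(axis=2, keepdims=True)
    od = -np.log(i / i0)
    return ODSeries(od, rec.sampling_rate, rec.wavelengths, list(rec.events),
                    baseline_window)


def _window_range(x: np.ndarray, w: int) -> np.ndarray:
    """Range (max - min) over each length-w window starting at t, along the
    last axis; output length n - w + 1."""
    view = np.lib.stride_tricks.sliding_window_view(x, w, axis=-1)
    return view.max(axis=-1) - view.min(axis=-1)


def detect_motion(series, sampling_rate: float | None = None,
                  window_s: float = 0.5, std_thr: float = 6.0,
                  amp_thr: float | None = 0.5,
                  sd_reference: str = "channel") -> ArtifactMask:
    """Flag 0.5 s windows whose signal range exceeds the std or amplitude rule.

    ``series`` is an ODSeries, or an array whose last axis is time (a leading
    wavelength/extra axis is collapsed into the channel mask by union).
    Windows slide sample-by-sample; every sample of a triggering window is
    flagged. A channel whose SD reference is (numerically) zero can only
    trigger the amplitude rule.
    """
    if isinstance(series, ODSeries):
        x = series.od
        fs = series.sampling_rate
    else:
        x = np.asarray(series, dtype=float)
        if sampling_rate is None:
            raise ValueError("sampling_rate required for raw arrays")
        fs = sampling_rate
    squeeze_later = x.ndim == 1
    if squeeze_later:
        x = x[None, :]
    flat = x.reshape(-1, x.shape[-1])  # (channel*extra, time)
    n = flat.shape[-1]
    w = int(round(window_s * fs))
    if w < 2:
        raise ValueError("window must span at least 2 samples")
    if w > n:
        raise ValueError("window longer than the series")

    rng = _window_range(flat, w)  # (rows, n - w + 1)

    if sd_reference == "channel":
        sd = flat.std(axis=-1, keepdims=True)
    elif sd_reference == "moving":
        # moving SD over a 4x window neighborhood
        k = min(4 * w, n)
        kernel = np.ones(k) / k
        mean = np.apply_along_axis(lambda r: np.convolve(r, kernel, "same"), -1, flat)
        sq = np.apply_along_axis(lambda r: np.convolve(r**2, kernel, "same"), -1, flat)
        sd_full = np.sqrt(np.maximum(sq - mean**2, 0.0))
        sd = sd_full[:, : n - w + 1]
    else:
        raise ValueError("sd_reference must be 'channel' or 'moving'")

    sd_ok = sd > 1e-12  # constant series: std rule cannot fire
    trigger = sd_ok & (rng > std_thr * np.broadcast_to(sd, rng.shape))
    if amp_thr is not None:
        trigger = trigger | (rng > amp_thr)

    # dilate trigger points to whole windows
    flagged_rows = np.zeros_like(flat, dtype=bool)
    hit = np.zeros(n + 1, dtype=np.int64)
    for row in range(flat.shape[0]):
        idx = np.nonzero(trigger[row])[0]
        if idx.size:
            hit[:] = 0
            np.add.at(hit, idx, 1)
            np.subtract.at(hit, idx + w, 1)
            flagged_rows[row] = np.cumsum(hit[:-1]) > 0

    flagged = flagged_rows.reshape(x.shape).any(axis=tuple(range(1, x.ndim - 1)))
    params = {"window_s": window_s, "std_thr": std_thr, "amp_thr": amp_thr,
              "sd_reference": sd_reference}
    return ArtifactMask(flagged, params)


def _correct_channel(x: np.ndarray, flagged: np.ndarray, fs: float) -> np.ndarray:
    """Spline-correct the flagged segments of one 1-D series.

    Within each flagged segment a cubic spline through dense knots
    (~0.05 s spacing, so it tracks spikes as well as slow shifts) models the
    artifact trend; it is subtracted and the residual is re-levelled onto
    the line joining the neighbouring clean samples (one-sided constant at
    the series boundary).
    """
    out = x.copy()
    n = x.size
    edges = np.flatnonzero(np.diff(np.concatenate([[0], flagged.astype(np.int8), [0]])))
    for s, e in zip(edges[::2], edges[1::2]):  # segment [s, e)
        seg = x[s:e]
        m = seg.size
        step = max(1, int(round(0.05 * fs)))
        if m >= 4 and step > 1:
            knots = np.unique(np.concatenate([np.arange(0, m, step), [m - 1]]))
            trend = CubicSpline(knots, seg[knots])(np.arange(m))
        else:
            trend = seg.astype(float)
        resid = seg - trend

        left = x[s - 1] if s > 0 else None
        right = x[e] if e < n else None
        if left is None and right is None:
            base = np.zeros(m)
        elif left is None:
            base = np.full(m, right)
        elif right is None:
            base = np.full(m, left)
        else:
            base = np.linspace(left, right, m + 2)[1:-1]
        out[s:e] = base + resid
    return out


def correct_motion_spline(series, mask: ArtifactMask, sampling_rate: float | None = None):
    """Apply spline correction to every flagged segment of every channel."""
    if isinstance(series, ODSeries):
        x = series.od
        fs = series.sampling_rate
    else:
        x = np.asarray(series, dtype=float)
        if sampling_rate is None:
            raise ValueError("sampling_rate required for raw arrays")
        fs = sampling_rate
    if mask.flagged.shape[-1] != x.shape[-1]:
        raise ValueError("mask length does not match the series")
    if not mask.flagged.any():
        return series

    out = x.copy()
    it = np.ndindex(x.shape[:-1])
    for idx in it:
        ch = idx[0]
        if mask.flagged[ch].any():
            out[idx] = _correct_channel(x[idx], mask.flagged[ch], fs)
    if isinstance(series, ODSeries):
        return replace(series, od=out)
    return out


def _design_sos(fs: float, low_hz: float, high_hz: float, order: int):
    if not 0 < low_hz < high_hz < fs / 2:
        raise ValueError("need 0 < low_hz < high_hz < Nyquist")
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs,
                         output="sos")


def bandpass_array(x: np.ndarray, fs: float, low_hz: float = 0.01,
                   high_hz: float = 0.2, order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    sos = _design_sos(fs, low_hz, high_hz, order)
    return signal.sosfiltfilt(sos, x, axis=-1)


def bandpass(series, low_hz: float = 0.01, high_hz: float = 0.2,
             sampling_rate: float | None = None, order: int = 3):
    """Zero-phase band-pass of an ODSeries / HemoSeries / array."""
    if isinstance(series, ODSeries):
        return replace(series, od=bandpass_array(series.od, series.sampling_rate,
                                                 low_hz, high_hz, order))
    if isinstance(series, HemoSeries):
        return replace(series,
                       hbo=bandpass_array(series.hbo, series.sampling_rate,
                                          low_hz, high_hz, order),
                       hbr=bandpass_array(series.hbr, series.sampling_rate,
                                          low_hz, high_hz, order))
    if sampling_rate is None:
        raise ValueError("sampling_rate required for raw arrays")
    return bandpass_array(np.asarray(series, dtype=float), sampling_rate,
                          low_hz, high_hz, order)


def extinction_matrix(wavelengths, table=None) -> np.ndarray:
    """(n_wavelengths x 2) matrix of (HbO, HbR) extinction coefficients."""
    table = table or DEFAULT_EXTINCTION_UM_CM
    try:
        E = np.array([table[float(wl)] for wl in wavelengths], dtype=float)
    except KeyError as err:
        raise ValueError(f"no extinction coefficients for wavelength {err}") from None
    return E


def od_to_hemo(od: ODSeries, dpf: float = 6.0, distance_mm: float = 30.0,
               extinction_table=None, events=None) -> HemoSeries:
    """Modified Beer-Lambert inversion to HbO/HbR concentration changes.

    Per channel, (dHbO, dHbR) = E^-1 dOD / (distance_cm * dpf); with the
    extinction table in cm^-1/uM the output is in uM. ``distance_mm`` may be
    a scalar or a per-channel vector.
    """
    E = extinction_matrix(od.wavelengths, extinction_table)
    if abs(np.linalg.det(E)) < 1e-18:
        raise ValueError("extinction matrix is singular")
    dist_cm = np.atleast_1d(np.asarray(distance_mm, dtype=float)) / 10.0
    if dist_cm.size == 1:
        dist_cm = np.full(od.n_channels, dist_cm[0])
    if np.any(dist_cm <= 0) or dpf <= 0:
        raise ValueError("distance and DPF must be positive")

    # solve E @ conc = od / (L * dpf) for all channels/samples at once
    scaled = od.od / (dist_cm[:, None, None] * dpf)
    conc = np.linalg.solve(E, scaled.transpose(1, 0, 2).reshape(E.shape[0], -1))
    conc = conc.reshape(2, od.n_channels, od.n_samples)
    return HemoSeries(conc[0], conc[1], od.sampling_rate,
                      events=list(events if events is not None else od.events),
                      dpf=dpf)


def run_preprocess(rec: RawRecording,
                   config: PreprocessConfig | None = None) -> HemoSeries:
    """Run the full Exclude -> Motion -> Filter -> Hemo chain.

    Motion screening applies the std rule to the raw intensities and both
    rules to optical density; the union of flags is spline-corrected on the
    optical-density series (or dropped when ``motion_mode='remove'``).
    The returned HemoSeries carries a processing log with per-channel flag
    counts.
    """
    config = config or PreprocessConfig()

    rec = exclude_intervals(rec, config.exclude)
    od = intensity_to_od(rec, config.baseline_window)

    mask_i = detect_motion(rec.intensity, rec.sampling_rate, config.window_s,
                           config.std_thr, amp_thr=None,
                           sd_reference=config.sd_reference)
    mask_od = detect_motion(od, window_s=config.window_s, std_thr=config.std_thr,
                            amp_thr=config.amp_thr,
                            sd_reference=config.sd_reference)
    flagged = mask_i.flagged | mask_od.flagged
    mask = ArtifactMask(flagged, mask_od.params)

    events = list(od.events)
    if config.motion_mode == "spline":
        od = correct_motion_spline(od, mask)
    else:
        keep = ~flagged.any(axis=0)
        kept_before = np.concatenate([[0], np.cumsum(keep)])
        fs = od.sampling_rate
        events = [Event(kept_before[min(int(round(ev.time_s * fs)), keep.size - 1)] / fs,
                        ev.label, ev.tag_value)
                  for ev in events
                  if keep[min(int(round(ev.time_s * fs)), keep.size - 1)]]
        od = replace(od, od=od.od[:, :, keep], events=events)

    od = bandpass(od, config.low_hz, config.high_hz, order=config.filter_order)

    if config.distance_mm is not None:
        distance = config.distance_mm
    else:
        distance = np.array([info.distance_mm for info in rec.montage.values()]) \
            if rec.montage and len(rec.montage) == rec.n_channels else 30.0
    hemo = od_to_hemo(od, config.dpf, distance, config.extinction, events=events)
    hemo.log = {
        "flagged_samples_per_channel": mask.n_flagged.tolist(),
        "config": config,
    }
    return hemo
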
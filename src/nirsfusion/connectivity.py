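"""Pearson functional-connectivity analysis.

For a condition's concatenated HbO samples, the channel-by-channel Pearson
correlation matrix R = (r_ij) is computed and summarized by the mean
connectivity strength r_bar = (1/N) * sum_{i != j} r_ij, N the number of
off-diagonal coefficients (91 unordered pairs for 14 channels). Negative
correlations are averaged signed; no Fisher z-transform is applied by
default (both available as options).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import HemoSeries, Protocol, channel_names

__all__ = [
    "ConnectivityResult",
    "pearson_r",
    "connectivity_matrix",
    "mean_connectivity",
    "condition_connectivity",
]


@dataclass
class ConnectivityResult:
    r_matrix: np.ndarray  # (n_channels, n_channels), symmetric, unit diagonal
    condition: str | None
    windows: list[tuple[float, float]]
    n_pairs: int

    @property
    def mean_strength(self) -> float:
        return mean_connectivity(self.r_matrix)

    def to_frame(self) -> pd.DataFrame:
        names = channel_names(self.r_matrix.shape[0])
        return pd.DataFrame(self.r_matrix, index=names, columns=names)


def pearson_r(x, y) -> float:
    """Pearson correlation coefficient between two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])


def connectivity_matrix(hemo: HemoSeries | np.ndarray,
                        window: tuple[float, float] | None = None,
                        chromophore: str = "hbo",
                        condition: str | None = None) -> ConnectivityResult:
    """All-pairs Pearson correlations over a time window of the HbO series."""
    if isinstance(hemo, HemoSeries):
        data = hemo.series(chromophore)
        fs = hemo.sampling_rate
        if window is not None:
            a, b = window
            data = data[:, int(round(a * fs)): int(round(b * fs))]
        windows = [window] if window is not None else [(0.0, hemo.n_samples / fs)]
    else:
        data = np.asarray(hemo, dtype=float)
        windows = [window] if window is not None else []
    if data.shape[-1] < 3:
        raise ValueError("window must contain at least 3 samples")

    sds = data.std(axis=-1)
    dead = np.nonzero(sds == 0)[0]
    if dead.size:
        raise ValueError(f"zero-variance channel(s) at index {dead.tolist()}")

    r = np.corrcoef(data)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    n = r.shape[0]
    return ConnectivityResult(r, condition, windows, n_pairs=n * (n - 1) // 2)


def mean_connectivity(result) -> float:
    """Mean of the off-diagonal correlations (signed average)."""
    r = result.r_matrix if isinstance(result, ConnectivityResult) else np.asarray(result)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("need a square correlation matrix")
    n = r.shape[0]
    off = ~np.eye(n, dtype=bool)
    return float(r[off].mean())


def condition_connectivity(hemo: HemoSeries, protocol: Protocol,
                           chromophore: str = "hbo",
                           conditions=None) -> list[ConnectivityResult]:
    """One connectivity result per condition, concatenating its blocks'
    samples (the repeated gray blocks pool into a single estimate)."""
    data = hemo.series(chromophore)
    fs = hemo.sampling_rate
    results = []
    for cond in (conditions or protocol.conditions):
        segments = []
        windows = []
        for b in protocol.blocks_for(cond):
            i0 = int(round(b.onset_s * fs))
            i1 = min(int(round(b.end_s * fs)), data.shape[1])
            segments.append(data[:, i0:i1])
            windows.append((b.onset_s, b.end_s))
        concat = np.concatenate(segments, axis=1)
        res = connectivity_matrix(concat, condition=cond)
        res.windows = windows
        results.append(res)
    return results
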
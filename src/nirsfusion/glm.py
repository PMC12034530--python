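"""Block-design GLM activation analysis with a double-gamma HRF.

The observed per-channel HbO series Y is modeled as Y = X beta + eps, where
each stimulus condition contributes a regressor built by convolving its
boxcar with the canonical hemodynamic response

    h(t) = t^(a1-1) e^(-t/b1) / (b1^a1 Gamma(a1))
         - c * t^(a2-1) e^(-t/b2) / (b2^a2 Gamma(a2)),

a gamma-density positive lobe (peak at (a1-1)*b1 = 5 s with the canonical
a1=6, b1=1) minus a scaled gamma-density undershoot (a2=16, b2=1, c=1/6).
The mid-gray baseline is the implicit reference (no regressor); constant and
polynomial drift columns absorb slow trends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .core import GRAY, HemoSeries, Protocol, channel_names

__all__ = [
    "HRFParams",
    "DesignMatrix",
    "GLMResult",
    "hrf_double_gamma",
    "build_design_matrix",
    "fit_glm",
    "participant_beta_table",
]


@dataclass(frozen=True)
class HRFParams:
    """Shape/scale parameters of the double-gamma HRF (seconds)."""

    a1: float = 6.0
    b1: float = 1.0
    a2: float = 16.0
    b2: float = 1.0
    c: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        if min(self.a1, self.b1, self.a2, self.b2) <= 0 or self.c < 0:
            raise ValueError("HRF shape/scale parameters must be positive, c >= 0")

    @property
    def peak_s(self) -> float:
        """Mode of the positive lobe, (a1 - 1) * b1."""
        return (self.a1 - 1.0) * self.b1


def hrf_double_gamma(t, params: HRFParams | None = None) -> np.ndarray | float:
    """Evaluate the double-gamma HRF at time(s) ``t`` (seconds, t >= 0)."""
    params = params or HRFParams()
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("the HRF is defined for t >= 0 only")
    h = gamma_dist.pdf(t_arr, params.a1, scale=params.b1) - params.c * gamma_dist.pdf(
        t_arr, params.a2, scale=params.b2
    )
    return float(h) if h.ndim == 0 else h


def hrf_kernel(sampling_rate: float, params: HRFParams | None = None,
               duration_s: float = 45.0) -> np.ndarray:
    """HRF sampled on a regular grid, long enough to cover the undershoot."""
    n = int(round(duration_s * sampling_rate)) + 1
    t = np.arange(n) / sampling_rate
    return hrf_double_gamma(t, params)


@dataclass
class DesignMatrix:
    X: np.ndarray  # (n_samples, n_regressors)
    names: list[str]
    sampling_rate: float
    condition_names: list[str]

    def __post_init__(self) -> None:
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.names)


def build_design_matrix(protocol: Protocol, sampling_rate: float,
                        hrf: HRFParams | None = None, drift_order: int = 1,
                        n_samples: int | None = None,
                        bandpass: tuple[float, float] | None = None) -> DesignMatrix:
    """Boxcar-convolved condition regressors plus polynomial drift columns.

    The gray baseline contributes no regressor. ``bandpass`` optionally
    applies the same zero-phase band-pass used on the data to the condition
    columns, so filtered data are fit against identically filtered
    regressors (standard temporal-filtering practice).
    """
    if sampling_rate <= 0:
        raise ValueError("sampling rate must be positive")
    if n_samples is None:
        n_samples = int(round(protocol.total_duration_s * sampling_rate))
    kernel = hrf_kernel(sampling_rate, hrf)

    conditions = [c for c in protocol.conditions if c != GRAY]
    cols = []
    for cond in conditions:
        boxcar = np.zeros(n_samples)
        for b in protocol.blocks_for(cond):
            i0 = int(round(b.onset_s * sampling_rate))
            i1 = int(round(b.end_s * sampling_rate))
            boxcar[i0:min(i1, n_samples)] = 1.0
        reg = np.convolve(boxcar, kernel)[:n_samples] / sampling_rate
        cols.append(reg)

    if bandpass is not None:
        from .preprocess import bandpass_array

        low, high = bandpass
        cols = [bandpass_array(c, sampling_rate, low, high) for c in cols]

    names = list(conditions)
    # Legendre-style drift columns on [-1, 1]; order 0 is the constant.
    u = np.linspace(-1.0, 1.0, n_samples)
    for order in range(drift_order + 1):
        cols.append(np.polynomial.legendre.Legendre.basis(order)(u))
        names.append("constant" if order == 0 else f"drift{order}")

    X = np.column_stack(cols)
    return DesignMatrix(X, names, sampling_rate, list(conditions))


@dataclass
class GLMResult:
    """Per-channel OLS estimates for one participant/session."""

    coef: pd.DataFrame  # channels x regressors (conditions + nuisance)
    condition_names: list[str]
    residual_var: np.ndarray  # per channel, ddof = n_regressors
    fitted: np.ndarray  # (n_channels, n_samples)

    @property
    def beta(self) -> pd.DataFrame:
        """Condition coefficients only (channels x conditions)."""
        return self.coef[self.condition_names]


def fit_glm(hemo: HemoSeries, design: DesignMatrix,
            chromophore: str = "hbo") -> GLMResult:
    """Ordinary least squares per channel of the chromophore series."""
    Y = hemo.series(chromophore).T  # (n_samples, n_channels)
    if Y.shape[0] != design.n_samples:
        raise ValueError(
            f"sample count mismatch: data {Y.shape[0]}, design {design.n_samples}"
        )
    X = design.X
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    fitted = X @ coef
    resid = Y - fitted
    dof = max(Y.shape[0] - X.shape[1], 1)
    residual_var = (resid**2).sum(axis=0) / dof
    coef_df = pd.DataFrame(coef.T, index=hemo.channel_names, columns=design.names)
    return GLMResult(coef_df, design.condition_names, residual_var, fitted.T)


def participant_beta_table(results, condition: str | None = None) -> pd.DataFrame:
    """Assemble a channels x participants coefficient table with a Mean column.

    ``results`` is either a list of :class:`GLMResult` (one per participant,
    homogeneous channel sets; ``condition`` selects the coefficient) or an
    existing channels x participants DataFrame to which only the Mean column
    is appended.
    """
    if isinstance(results, pd.DataFrame):
        table = results.copy()
    else:
        if condition is None:
            raise ValueError("condition required when assembling from GLM results")
        cols = {}
        ref_index = None
        for i, res in enumerate(results, start=1):
            beta = res.beta
            if condition not in beta.columns:
                raise ValueError(f"condition {condition!r} missing from GLM result")
            if ref_index is None:
                ref_index = beta.index
            elif not beta.index.equals(ref_index):
                raise ValueError("participants have mismatching channel sets")
            cols[f"P{i}"] = beta[condition]
        table = pd.DataFrame(cols)
    table["Mean"] = table.mean(axis=1)
    return table
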
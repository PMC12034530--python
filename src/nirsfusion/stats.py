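"""Non-parametric statistical layer for paired, small-sample fNIRS designs.

Implements the exact tests used to compare conditions across 12 participants:

* Friedman rank test across k >= 3 repeated conditions,
  chi2_F = 12 / (n k (k+1)) * sum_j R_j^2 - 3 n (k+1),
  referred to the chi-squared distribution with k - 1 degrees of freedom.
* Wilcoxon signed-rank test with the *exact* two-sided p-value obtained by
  dynamic-programming enumeration of all 2^n sign assignments of the ranked
  absolute differences (average ranks on ties; zero differences dropped).
  At n = 12 the null has 4096 equiprobable assignments, so e.g. W = 0 gives
  p = 2/4096 = 0.000488.
* Benjamini-Hochberg step-up false-discovery-rate control with critical
  values (i/m) * alpha, plus the equivalent monotone adjusted p-values.
* Paired Cohen's d = mean(d_i) / SD(d_i) with the population (divide-by-n)
  standard deviation, and post-hoc power of the matching two-sided paired
  t-test from the noncentral t distribution (ncp = d * sqrt(n), df = n - 1).

The channel-wise pipeline chains these: one exact Wilcoxon per channel,
BH correction across the 14 channels, then effect size and power for the
significant channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FriedmanResult",
    "WilcoxonResult",
    "FDRResult",
    "EffectReport",
    "StatReport",
    "friedman_test",
    "wilcoxon_signed_rank",
    "fdr_bh",
    "cohens_d_paired",
    "power_paired",
    "channelwise_comparison",
]

#: Switch from exact enumeration to the normal approximation above this n.
EXACT_N_MAX = 25


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    p_value: float
    n: int
    k: int
    rank_sums: np.ndarray


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W = min(W+, W-)
    w_plus: float
    w_minus: float
    n_effective: int
    p_value: float
    method: str  # "exact" | "normal-approx"


@dataclass(frozen=True)
class FDRResult:
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    significant: np.ndarray
    alpha: float
    m: int


@dataclass(frozen=True)
class EffectReport:
    d: float
    power: float
    n: int
    alpha: float


@dataclass
class StatReport:
    """Channel-wise paired-comparison report (statistic, corrected p,
    significance, effect size and power for significant channels)."""

    table: pd.DataFrame
    alpha: float = 0.05
    degenerate: list[str] = field(default_factory=list)

    @property
    def significant_channels(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def friedman_test(data, tie_correction: bool = False) -> FriedmanResult:
    """Friedman rank test on a subjects x conditions table.

    Ranks are assigned within each subject (average ranks on ties). By
    default the plain statistic is used; ``tie_correction`` divides by the
    standard tie-correction factor.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be a 2-D subjects x conditions table")
    n, k = x.shape
    if k < 3:
        raise ValueError("the Friedman test needs k >= 3 conditions")
    if n < 2:
        raise ValueError("the Friedman test needs n >= 2 subjects")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing or non-finite cells are not supported")

    ranks = np.apply_along_axis(sps.rankdata, 1, x)
    rank_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)

    if tie_correction:
        correction = 0.0
        for row in ranks:
            _, counts = np.unique(row, return_counts=True)
            correction += np.sum(counts**3 - counts)
        denom = 1.0 - correction / (n * k * (k**2 - 1))
        if denom <= 0:
            raise ValueError("all values tied; statistic undefined")
        stat /= denom

    p = float(sps.chi2.sf(stat, k - 1))
    return FriedmanResult(float(stat), p, n, k, rank_sums)


@lru_cache(maxsize=512)
def _signed_rank_null_cdf(doubled_ranks: tuple[int, ...]) -> np.ndarray:
    """Null distribution counts of 2*W+ for a given rank multiset.

    Ranks are doubled so average ranks (halves) become integers; the return
    value is counts[s] = #{sign assignments with 2*W+ == s}.
    """
    total = sum(doubled_ranks)
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(x, y, mode: str = "auto") -> WilcoxonResult:
    """Exact two-sided Wilcoxon signed-rank test for paired samples.

    ``mode``: "exact" forces enumeration, "approx" forces the normal
    approximation, "auto" uses enumeration up to n_eff = 25.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D paired vectors")
    d = x - y
    d = d[d != 0.0]
    n_eff = d.size
    if n_eff == 0:
        raise ValueError("all paired differences are zero; test degenerate")

    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    use_exact = mode == "exact" or (mode == "auto" and n_eff <= EXACT_N_MAX)
    if mode not in ("auto", "exact", "approx"):
        raise ValueError("mode must be 'auto', 'exact' or 'approx'")

    if use_exact:
        doubled = tuple(sorted(int(round(2 * r)) for r in ranks))
        counts = _signed_rank_null_cdf(doubled)
        total = 2.0**n_eff
        s = int(round(2 * w_plus))
        cdf = counts[: s + 1].sum() / total
        sf = counts[s:].sum() / total
        p = min(1.0, 2.0 * min(cdf, sf))
        method = "exact"
    else:
        mu = n_eff * (n_eff + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / 48.0
        sigma = math.sqrt(n_eff * (n_eff + 1) * (2 * n_eff + 1) / 24.0 - tie_term)
        z = (w_plus - mu) / sigma
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        method = "normal-approx"

    return WilcoxonResult(w, w_plus, w_minus, n_eff, float(p), method)


def fdr_bh(raw_p, alpha: float = 0.05) -> FDRResult:
    """Benjamini-Hochberg step-up FDR control.

    Critical values are (i/m) * alpha on the ascending p-values; the
    adjusted p-value is the usual monotone min over j >= i of p_(j) * m / j,
    capped at 1, reported in the input order. The step-up significance set
    coincides with {adjusted p <= alpha}.
    """
    p = np.asarray(raw_p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("raw_p must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]

    adj_sorted = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty_like(adj_sorted)
    adjusted[order] = adj_sorted

    crit = np.arange(1, m + 1) / m * alpha
    passing = np.nonzero(ranked <= crit)[0]
    significant = np.zeros(m, dtype=bool)
    if passing.size:
        significant[order[: passing[-1] + 1]] = True

    return FDRResult(p, adjusted, significant, alpha, m)


def cohens_d_paired(x, y) -> float:
    """Paired Cohen's d with the population (divide-by-n) SD of differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length paired vectors, n >= 2")
    d = x - y
    sd = d.std(ddof=0)
    if sd == 0.0:
        raise ValueError("zero standard deviation of differences")
    return float(d.mean() / sd)


def power_paired(d: float, n: int, alpha: float = 0.05) -> float:
    """Post-hoc power of a two-sided paired t-test at effect size d.

    Uses the noncentral t distribution with df = n - 1 and noncentrality
    d * sqrt(n); at d = 0 this reduces to the test size alpha.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if not math.isfinite(d):
        raise ValueError("effect size must be finite")
    df = n - 1
    ncp = d * math.sqrt(n)
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    power = sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp)
    return float(power)


def channelwise_comparison(table_a: pd.DataFrame, table_b: pd.DataFrame,
                           alpha: float = 0.05) -> StatReport:
    """Paired channel-by-channel comparison of two coefficient tables.

    ``table_a`` and ``table_b`` are channels x participants tables with
    matching labels. Per channel an exact Wilcoxon signed-rank test is run,
    the raw p-values are BH-corrected across channels, and Cohen's d plus
    post-hoc power are appended for the significant channels.
    """
    if not table_a.index.equals(table_b.index) or not table_a.columns.equals(table_b.columns):
        raise ValueError("tables must share channel and participant labels")

    n = table_a.shape[1]
    rows = {}
    degenerate: list[str] = []
    for ch in table_a.index:
        a = table_a.loc[ch].to_numpy(dtype=float)
        b = table_b.loc[ch].to_numpy(dtype=float)
        try:
            res = wilcoxon_signed_rank(a, b)
            rows[ch] = (res.statistic, res.p_value)
        except ValueError:
            degenerate.append(ch)
            rows[ch] = (np.nan, 1.0)

    raw = np.array([rows[ch][1] for ch in table_a.index])
    fdr = fdr_bh(raw, alpha=alpha)

    out = pd.DataFrame(
        {
            "statistic": [rows[ch][0] for ch in table_a.index],
            "raw_p": raw,
            "corrected_p": fdr.adjusted_p,
            "significant": fdr.significant,
        },
        index=table_a.index,
    )
    out.loc[out.index.isin(degenerate), "significant"] = False

    d_col = np.full(len(out), np.nan)
    power_col = np.full(len(out), np.nan)
    for i, ch in enumerate(out.index):
        if out["significant"].iloc[i]:
            d = cohens_d_paired(table_a.loc[ch], table_b.loc[ch])
            d_col[i] = d
            power_col[i] = power_paired(d, n, alpha=alpha)
    out["cohens_d"] = d_col
    out["power"] = power_col

    return StatReport(out, alpha=alpha, degenerate=degenerate)
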
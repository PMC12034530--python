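"""Fixture-based reproduction of the study's published statistics.

Everything here runs from the packaged printed-table fixtures — no raw
recordings, no downloads — and re-derives:

* the Friedman test and pairwise exact Wilcoxon tests (BH-corrected) on the
  per-participant functional-connectivity strengths,
* the channel-wise exact Wilcoxon + BH pipeline on the fusion/rivalry GLM
  coefficient tables, with effect sizes and post-hoc power for the
  significant channels,
* the per-participant reaction-time summary.

``run_reproduction`` compares the recomputed values against the published
ones: table statistics and p-values at printed precision, effect sizes and
power to within 0.015 (the published values round differently in two
cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import round_half_up
from .fixtures import load_fixture
from .stats import (
    StatReport,
    channelwise_comparison,
    fdr_bh,
    friedman_test,
    wilcoxon_signed_rank,
)

__all__ = [
    "PRINTED_FC_MEANS",
    "PRINTED_FC_SDS",
    "PRINTED_EFFECTS",
    "fc_statistics",
    "channel_statistics",
    "rt_statistics",
    "run_reproduction",
]

#: Published column means / sample SDs of the connectivity table
#: (mid-gray, fusion, rivalry).
PRINTED_FC_MEANS = (0.1502, 0.3317, 0.2391)
PRINTED_FC_SDS = (0.0675, 0.1746, 0.1300)
#: Published (Cohen's d, power) for the significant channels.
PRINTED_EFFECTS = {"CH12": (1.09, 0.92), "CH13": (1.28, 0.98), "CH14": (1.35, 0.98)}
#: Published Friedman statistic on the connectivity table.
PRINTED_FRIEDMAN_STAT = 24.0
#: Published BH-corrected p for all three pairwise connectivity contrasts.
PRINTED_PAIRWISE_P = 0.00049

FC_PAIRS = (("forg", "rorg"), ("midgray", "forg"), ("midgray", "rorg"))


def fc_statistics() -> dict:
    """Friedman + pairwise exact Wilcoxon (BH-corrected) on the
    connectivity-strength fixture, plus its descriptive mean/SD row."""
    t3 = load_fixture("table3")
    fried = friedman_test(t3[["midgray", "forg", "rorg"]].to_numpy())
    pairwise = {}
    raw_p = []
    for a, b in FC_PAIRS:
        res = wilcoxon_signed_rank(t3[a], t3[b])
        pairwise[(a, b)] = res
        raw_p.append(res.p_value)
    fdr = fdr_bh(np.array(raw_p))
    return {
        "table": t3,
        "friedman": fried,
        "pairwise": pairwise,
        "corrected_p": dict(zip(FC_PAIRS, fdr.adjusted_p)),
        "means": t3.mean().to_numpy(),
        "sds": t3.std(ddof=1).to_numpy(),
    }


def channel_statistics() -> StatReport:
    """Channel-wise exact Wilcoxon + BH + effects on the GLM beta fixtures."""
    return channelwise_comparison(load_fixture("table5"), load_fixture("table6"))


def rt_statistics() -> pd.DataFrame:
    """Recomputed mean/SD of the fixture reaction times (half-up, 2 dp)."""
    t4 = load_fixture("table4")
    rt_cols = [c for c in t4.columns if c.startswith("rt")]
    rts = t4[rt_cols]
    out = pd.DataFrame(index=t4.index)
    out["mean_rt"] = round_half_up(rts.mean(axis=1).to_numpy(), 2)
    out["sd_rt"] = round_half_up(rts.std(axis=1, ddof=1).to_numpy(), 2)
    out["printed_mean_rt"] = t4["mean_rt"]
    out["printed_sd_rt"] = t4["sd_rt"]
    return out


@dataclass
class ReproductionReport:
    fc: dict
    channels: StatReport
    rt: pd.DataFrame
    failures: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def run_reproduction(effect_tol: float = 0.015) -> ReproductionReport:
    """Recompute every published statistic and diff it against the paper."""
    failures: list[str] = []

    fc = fc_statistics()
    if fc["friedman"].statistic != PRINTED_FRIEDMAN_STAT:
        failures.append(
            f"Friedman statistic {fc['friedman'].statistic} != {PRINTED_FRIEDMAN_STAT}"
        )
    for pair, res in fc["pairwise"].items():
        if res.statistic != 0.0:
            failures.append(f"Wilcoxon W for {pair} is {res.statistic}, expected 0")
    for pair, p in fc["corrected_p"].items():
        if round_half_up(p, 5) != PRINTED_PAIRWISE_P:
            failures.append(f"corrected p for {pair} is {p:.6f}, expected "
                            f"{PRINTED_PAIRWISE_P}")
    for got, want in zip(round_half_up(fc["means"], 4), PRINTED_FC_MEANS):
        if got != want:
            failures.append(f"connectivity column mean {got} != printed {want}")
    for got, want in zip(round_half_up(fc["sds"], 4), PRINTED_FC_SDS):
        if got != want:
            failures.append(f"connectivity column SD {got} != printed {want}")

    channels = channel_statistics()
    published = load_fixture("table7")
    for ch in published.index:
        got_w = channels.table.loc[ch, "statistic"]
        if got_w != published.loc[ch, "statistic"]:
            failures.append(f"{ch}: statistic {got_w} != published "
                            f"{published.loc[ch, 'statistic']}")
        got_p = round_half_up(channels.table.loc[ch, "corrected_p"], 5)
        if got_p != published.loc[ch, "corrected_p"]:
            failures.append(f"{ch}: corrected p {got_p} != published "
                            f"{published.loc[ch, 'corrected_p']}")
        got_sig = bool(channels.table.loc[ch, "significant"])
        if got_sig != (published.loc[ch, "significant"] == "Yes"):
            failures.append(f"{ch}: significance flag mismatch")
    for ch, (d_pub, pw_pub) in PRINTED_EFFECTS.items():
        d = channels.table.loc[ch, "cohens_d"]
        pw = channels.table.loc[ch, "power"]
        if not np.isfinite(d) or abs(d - d_pub) > effect_tol:
            failures.append(f"{ch}: Cohen's d {d:.4f} vs published {d_pub}")
        if not np.isfinite(pw) or abs(pw - pw_pub) > effect_tol:
            failures.append(f"{ch}: power {pw:.4f} vs published {pw_pub}")

    rt = rt_statistics()
    for p, row in rt.iterrows():
        if row["mean_rt"] != row["printed_mean_rt"]:
            failures.append(f"{p}: mean RT {row['mean_rt']} != printed "
                            f"{row['printed_mean_rt']}")

    return ReproductionReport(fc, channels, rt, failures)
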
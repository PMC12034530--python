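"""Packaged fixtures: verbatim transcriptions of the study's printed tables.

* ``table3`` — mean functional-connectivity strength r_bar per participant
  (12 participants x mid-gray / fusion / rivalry).
* ``table4`` — per-trial reaction times to the eight rivalry stimuli plus
  the printed mean and SD columns (12 x 8 RTs).
* ``table5`` / ``table6`` — GLM regression coefficients (beta) per channel
  and participant under fusion / rivalry (14 x 12).
* ``table7`` — the published channel-wise Wilcoxon statistics, corrected
  p-values and significance flags (reference for the reproduction check).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_fixture", "FIXTURE_NAMES"]

_FILES = {
    "table3": "table3_fc_strength.csv",
    "table4": "table4_reaction_times.csv",
    "table5": "table5_glm_beta_forg.csv",
    "table6": "table6_glm_beta_rorg.csv",
    "table7": "table7_channel_stats.csv",
}

FIXTURE_NAMES = tuple(_FILES)


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the packaged printed-table fixtures by short name."""
    if name not in _FILES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    ref = resources.files("nirsfusion.data").joinpath(_FILES[name])
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, index_col=0)
    return df
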
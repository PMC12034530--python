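"""Reaction-time analysis of the rivalry-detection task.

Participants press a key only when they perceive binocular rivalry; the
reaction time is the keypress tag time minus the onset of the enclosing
rivalry block. Presses inside fusion or gray blocks are counted as false
presses — the accuracy check that the two percepts are not confused.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import KEYPRESS, RORG, Protocol, round_half_up

__all__ = ["RTRecord", "compute_rt", "summarize_rt", "rt_summary_table"]


@dataclass
class RTRecord:
    participant: str
    rts: list[float]
    mean_rt: float
    sd_rt: float
    false_presses: int
    missing_responses: list[float] = field(default_factory=list)  # block onsets


def compute_rt(events, protocol: Protocol, participant: str = "P1") -> RTRecord:
    """Pair keypress tags with their enclosing blocks and derive RTs."""
    rorg_blocks = protocol.blocks_for(RORG)
    rts: list[float] = []
    answered = set()
    false_presses = 0
    for ev in events:
        if ev.label != KEYPRESS and ev.tag_value != 1.0:
            continue
        block = protocol.block_at(ev.time_s)
        if block is None:
            raise ValueError(f"keypress at {ev.time_s} s falls outside all blocks")
        if block.condition == RORG:
            rts.append(ev.time_s - block.onset_s)
            answered.add(block.onset_s)
        else:
            false_presses += 1
    missing = [b.onset_s for b in rorg_blocks if b.onset_s not in answered]
    if len(rts) >= 2:
        mean, sd = summarize_rt(rts)
    else:
        mean = round_half_up(rts[0], 2) if rts else float("nan")
        sd = float("nan")
    return RTRecord(participant, rts, mean, sd, false_presses, missing)


def summarize_rt(rts) -> tuple[float, float]:
    """Arithmetic mean and sample SD, rounded (half-up) to 2 decimals."""
    arr = np.asarray(rts, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 reaction times")
    return (float(round_half_up(arr.mean(), 2)),
            float(round_half_up(arr.std(ddof=1), 2)))


def rt_summary_table(records) -> pd.DataFrame:
    """Per-participant RT summary in the printed-table layout."""
    rows = {}
    for rec in records:
        row = {f"rt{i + 1}": rt for i, rt in enumerate(rec.rts)}
        row["mean_rt"] = rec.mean_rt
        row["sd_rt"] = rec.sd_rt
        row["false_presses"] = rec.false_presses
        rows[rec.participant] = row
    out = pd.DataFrame(rows).T
    out.index.name = "participant"
    return out
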
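"""Threshold-and-majority differential-expression calling.

A protein is called *up* when its ratio-to-reference is at or above the
up threshold (default 1.5) in at least half of the tumor samples where
it was quantified, and *down* when at or below the down threshold
(default 0.67) in at least half.  The majority boundary is inclusive:
exactly 50% of tumors crossing a threshold is a call.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io_formats import RatioMatrix, _sep_for

UP = "up"
DOWN = "down"
NONE = "none"


@dataclass(frozen=True)
class DysregulationCall:
    protein_id: str
    direction: str                 # up | down | none
    frac_up: float                 # fraction of present cancer ratios >= up
    frac_down: float               # fraction of present cancer ratios <= down
    n_cancer_present: int


class CallSummary(NamedTuple):
    n_up: int
    n_down: int
    n_none: int


def call_dysregulation(matrix: RatioMatrix,
                       up_threshold: float = 1.5,
                       down_threshold: float = 0.67,
                       majority: float = 0.5) -> list[DysregulationCall]:
    """Call up/down/none for every protein in the matrix.

    The denominator of the majority fractions is the number of *cancer*
    samples with a present ratio for that protein, so sparsely
    quantified proteins are judged on the evidence that exists.  A
    protein with no present cancer ratio has both fractions 0 and is
    called none.  If both thresholds reach the majority (possible only
    for contrived thresholds) the larger fraction wins, an exact tie
    going to up.
    """
    if not matrix.cancer_samples:
        raise ValueError("matrix contains no cancer samples")
    if not (up_threshold > 1.0 > down_threshold > 0.0):
        raise ValueError(
            f"thresholds inverted: need up > 1 > down > 0, got "
            f"up={up_threshold}, down={down_threshold}")
    if not 0.0 < majority <= 1.0:
        raise ValueError("majority must be in (0, 1]")

    cancer = matrix.values[matrix.cancer_samples]
    calls: list[DysregulationCall] = []
    for protein, row in cancer.iterrows():
        present = row.dropna()
        n = len(present)
        if n == 0:
            calls.append(DysregulationCall(protein, NONE, 0.0, 0.0, 0))
            continue
        frac_up = float((present >= up_threshold).sum()) / n
        frac_down = float((present <= down_threshold).sum()) / n
        if frac_up >= majority and frac_up >= frac_down:
            direction = UP
        elif frac_down >= majority:
            direction = DOWN
        else:
            direction = NONE
        calls.append(DysregulationCall(protein, direction,
                                       frac_up, frac_down, n))
    return calls


def summarize_calls(calls: Iterable[DysregulationCall]) -> CallSummary:
    """Counts of up / down / none calls."""
    n_up = n_down = n_none = 0
    for c in calls:
        if c.direction == UP:
            n_up += 1
        elif c.direction == DOWN:
            n_down += 1
        else:
            n_none += 1
    return CallSummary(n_up, n_down, n_none)


def dysregulated_ids(calls: Iterable[DysregulationCall]) -> list[str]:
    return [c.protein_id for c in calls if c.direction != NONE]


def calls_to_frame(calls: Sequence[DysregulationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {"protein_id": [c.protein_id for c in calls],
         "direction": [c.direction for c in calls],
         "frac_up": [c.frac_up for c in calls],
         "frac_down": [c.frac_down for c in calls],
         "n_cancer_present": [c.n_cancer_present for c in calls]})


def write_calls(calls: Sequence[DysregulationCall], path: str | Path,
                header_lines: Iterable[str] = ()) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        calls_to_frame(calls).to_csv(fh, sep=_sep_for(path), index=False)


def read_calls(path: str | Path) -> list[DysregulationCall]:
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    return [DysregulationCall(str(r.protein_id), str(r.direction),
                              float(r.frac_up), float(r.frac_down),
                              int(r.n_cancer_present))
            for r in df.itertuples(index=False)]
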
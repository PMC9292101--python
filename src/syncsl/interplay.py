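"""Network-interplay (XOR) analysis.

Two network time courses are binarized against a baseline (by default the
mean of the same time course during rest blocks) and combined with the
logical XOR at each TR: a time point scores 1 when exactly one of the two
networks is above baseline.  The time average of the XOR quantifies
alternating engagement of the networks; in high synchronizers it is
correlated with the individual learning benefit (percent correct in
passive listening minus percent correct under articulatory suppression).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import spearman


@dataclass(frozen=True)
class BinaryActivity:
    active: np.ndarray  # boolean per TR within the analysis window
    source_component: str
    baseline_def: str
    window_trs: np.ndarray  # TR indices of the analysis window


@dataclass(frozen=True)
class XorRecord:
    participant: str
    xor_mean: float
    xor_normalized: float
    learning_benefit: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.xor_mean <= 1.0:
            raise ValueError("xor_mean must lie in [0, 1]")


def _trs_for(block_timing: pd.DataFrame, conditions: tuple[str, ...],
             n_trs: int, tr_s: float) -> np.ndarray:
    t = (np.arange(n_trs) + 0.5) * tr_s
    sel = np.zeros(n_trs, bool)
    for _, row in block_timing[block_timing["condition"].isin(conditions)].iterrows():
        sel |= (t >= row["onset_s"]) & (t < row["onset_s"] + row["duration_s"])
    return np.where(sel)[0]


def binarize_activity(
    timecourse: np.ndarray,
    block_timing: pd.DataFrame,
    tr_s: float = 1.5,
    baseline_rule: str = "rest-mean",
    window_conditions: tuple[str, ...] = ("PL",),
    source_component: str = "",
) -> BinaryActivity:
    """Threshold a component time course into active / inactive per TR.

    ``baseline_rule``: "rest-mean" (mean of the time course during rest
    blocks; requires rest blocks), "global-mean", or "zero" (for z-scored
    series).  Activity is strict: a point exactly at baseline is inactive.
    The analysis window defaults to the passive-listening learning blocks.
    """
    tc = np.asarray(timecourse, float)
    n_trs = len(tc)
    if baseline_rule == "rest-mean":
        rest = _trs_for(block_timing, ("rest",), n_trs, tr_s)
        if len(rest) == 0:
            raise ValueError("rest-mean baseline requires rest blocks in the timing")
        baseline = float(tc[rest].mean())
    elif baseline_rule == "global-mean":
        baseline = float(tc.mean())
    elif baseline_rule == "zero":
        baseline = 0.0
    else:
        raise ValueError(f"unknown baseline rule {baseline_rule!r}")
    window = _trs_for(block_timing, window_conditions, n_trs, tr_s)
    return BinaryActivity(
        active=tc[window] > baseline,
        source_component=source_component,
        baseline_def=baseline_rule,
        window_trs=window,
    )


def xor_score(a: BinaryActivity, b: BinaryActivity,
              participant: str = "") -> XorRecord:
    """Time-averaged XOR of two binarized network activities.

    ``xor_normalized`` divides the raw mean by the fraction of time at least
    one network is active (occupancy), reported alongside the raw score.
    """
    if len(a.active) != len(b.active) or not np.array_equal(a.window_trs, b.window_trs):
        raise ValueError("binary activities must share the analysis window")
    x = np.logical_xor(a.active, b.active)
    xor_mean = float(np.mean(x))
    any_active = float(np.mean(a.active | b.active))
    xor_norm = xor_mean / any_active if any_active > 0 else 0.0
    return XorRecord(participant=participant, xor_mean=xor_mean,
                     xor_normalized=xor_norm)


def learning_benefit(behavior: pd.DataFrame, participant: str) -> float:
    """Percent correct in PL minus percent correct in AS, one participant."""
    d = behavior[behavior["participant"] == participant]
    out = {}
    for cond in ("PL", "AS"):
        sel = d[d["condition"] == cond]["correct"]
        if len(sel) == 0:
            raise ValueError(f"participant {participant} has no {cond} trials")
        out[cond] = 100.0 * float(sel.mean())
    return out["PL"] - out["AS"]


def interplay_correlation(
    records: list[XorRecord],
    group_labels: dict[str, str] | None = None,
    group_filter: str = "high",
    use_normalized: bool = False,
) -> tuple[float, float]:
    """Spearman correlation of XOR score with learning benefit.

    Restricted to ``group_filter`` participants (high synchronizers by
    default) when labels are given.  Needs at least 5 records and a
    non-constant XOR vector.
    """
    recs = [
        r for r in records
        if group_labels is None or group_labels.get(r.participant) == group_filter
    ]
    if len(recs) < 5:
        raise ValueError("need at least 5 records for the interplay correlation")
    x = np.array([r.xor_normalized if use_normalized else r.xor_mean for r in recs])
    y = np.array([r.learning_benefit for r in recs])
    if np.any([v is None for v in y]):
        raise ValueError("records must carry learning benefits")
    if np.ptp(x) == 0:
        raise ValueError("XOR scores are constant; correlation undefined")
    return spearman(x, y.astype(float))
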
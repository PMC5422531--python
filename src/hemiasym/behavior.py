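"""Trial-level behavioral computations.

The in-scanner naming task is a block design whose audio is segmented into
one response window per scan (TR).  A trial's latency is the time from
scan onset to speech onset; summaries are the percent of correct task
trials and the mean latency of correct responses.  Subjects with
abnormally slow mean latencies (above the cohort mean + 2 SD) are screened
out before imaging analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, ArgumentError, DataError

__all__ = [
    "BehavioralSummary",
    "delimit_scan_windows",
    "response_latency",
    "summarize_behavior",
    "screen_outliers",
]


@dataclass(frozen=True)
class BehavioralSummary:
    subject_id: str
    pct_correct: float
    mean_rt_correct: float  # ms; NaN when no correct trial exists
    n_trials: int


def delimit_scan_windows(trials: pd.DataFrame, tr: float, atol: float = 1e-9):
    """One half-open response window [onset, onset + tr) per trial.

    Onsets must lie on the TR grid; windows are returned in temporal order
    and are pairwise disjoint by construction.
    """
    onsets = np.sort(np.asarray(trials["scan_onset"], dtype=float))
    offgrid = np.abs(onsets / tr - np.round(onsets / tr)) > atol
    if offgrid.any():
        raise AlignmentError(f"scan onsets off the {tr}-s grid: {onsets[offgrid][:5]}")
    return [(float(t), float(t + tr)) for t in onsets]


def response_latency(trial) -> float:
    """Latency in ms from scan onset to response onset; NaN if no response."""
    onset = float(trial["scan_onset"])
    resp = trial["response_onset"]
    if resp is None or (isinstance(resp, float) and np.isnan(resp)):
        return float("nan")
    resp = float(resp)
    if resp < onset:
        raise DataError(f"response at {resp} s precedes scan onset {onset} s")
    return (resp - onset) * 1000.0


def summarize_behavior(subject_id: str, trials: pd.DataFrame) -> BehavioralSummary:
    """Percent correct over task trials; mean latency over correct task trials."""
    task = trials[trials["block_type"] == "task"]
    if task.empty:
        raise ArgumentError(f"subject {subject_id!r} has no task trials")
    correct = task[task["correct"].astype(bool)]
    pct = 100.0 * len(correct) / len(task)
    if correct.empty:
        warnings.warn(f"subject {subject_id!r} has no correct trials", stacklevel=2)
        mean_rt = float("nan")
    else:
        lat = np.array([response_latency(row) for _, row in correct.iterrows()])
        mean_rt = float(np.nanmean(lat))
    return BehavioralSummary(
        subject_id=subject_id, pct_correct=pct, mean_rt_correct=mean_rt, n_trials=len(trials)
    )


def screen_outliers(summaries: list[BehavioralSummary]):
    """Single-pass screening of abnormally slow subjects.

    A subject is excluded when its mean correct-trial latency exceeds the
    cohort mean + 2 SD (one-sided; computed once over all subjects, no
    re-iteration).  Returns (retained ids, exclusion log).
    """
    if len(summaries) < 3:
        raise ArgumentError("outlier screening needs at least 3 subjects")
    rts = np.array([s.mean_rt_correct for s in summaries], dtype=float)
    mean, sd = float(np.nanmean(rts)), float(np.nanstd(rts, ddof=1))
    threshold = mean + 2.0 * sd
    retained, excluded = [], []
    for s in summaries:
        if np.isfinite(s.mean_rt_correct) and s.mean_rt_correct > threshold:
            excluded.append(
                {
                    "subject_id": s.subject_id,
                    "mean_rt_correct": s.mean_rt_correct,
                    "threshold": threshold,
                    "reason": "mean RT > cohort mean + 2 SD",
                }
            )
        else:
            retained.append(s.subject_id)
    return retained, excluded
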
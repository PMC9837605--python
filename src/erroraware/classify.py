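"""Deterministic classification of EAT trials.

A commission error (any press on a No-Go trial) is *unaware* when the
subject pressed left on the No-Go trial and again left on the following
Go trial — i.e. they carried on as if nothing had happened. Any other
commission pattern (a right press on the No-Go itself, a right press on
the following trial, or no press on the following trial) counts as an
*aware* error. No-Go trials with no press are correct inhibitions, and
Go trials with no press are omissions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task import TrialSequence

__all__ = [
    "CORRECT_INHIBITION",
    "AWARE_ERROR",
    "UNAWARE_ERROR",
    "SubjectResponses",
    "OutcomeTable",
    "classify_trials",
    "classify_nogo_pair",
    "event_onsets_by_class",
]

CORRECT_INHIBITION = "correct_inhibition"
AWARE_ERROR = "aware_error"
UNAWARE_ERROR = "unaware_error"
NOGO_CLASSES = (CORRECT_INHIBITION, AWARE_ERROR, UNAWARE_ERROR)

NONE, LEFT, RIGHT = "none", "left", "right"


class AlignmentError(ValueError):
    """Responses do not line up with the trial sequence."""


@dataclass
class SubjectResponses:
    """Per-trial button presses and latencies for one subject.

    ``button[i]`` is "none", "left" or "right"; ``rt_ms[i]`` is the press
    latency from stimulus onset, NaN when no press occurred.
    """

    subject_id: str
    button: list[str]
    rt_ms: np.ndarray

    def __post_init__(self) -> None:
        self.rt_ms = np.asarray(self.rt_ms, dtype=float)
        if len(self.button) != len(self.rt_ms):
            raise AlignmentError("button and rt_ms lengths differ")
        for i, (b, rt) in enumerate(zip(self.button, self.rt_ms)):
            if (b == NONE) != np.isnan(rt):
                raise AlignmentError(
                    f"trial {i}: rt must be present iff a button was pressed"
                )

    def __len__(self) -> int:
        return len(self.button)


@dataclass
class OutcomeTable:
    """Per-trial outcome labels aligned to a TrialSequence.

    ``nogo_class[i]`` holds one of the three No-Go outcome labels for
    No-Go trials and None for Go trials. ``omission[i]`` flags Go trials
    with no response. ``anomalous_right[i]`` flags right presses on Go
    trials that do not follow a commission error; these are excluded from
    RT summaries.
    """

    subject_id: str
    nogo_class: list[str | None]
    omission: np.ndarray
    anomalous_right: np.ndarray
    summary: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.nogo_class)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "nogo_class": [c if c is not None else "" for c in self.nogo_class],
                "omission": self.omission.astype(int),
                "anomalous_right": self.anomalous_right.astype(int),
            }
        )


def classify_nogo_pair(nogo_button: str, next_button: str | None) -> str:
    """Classify one No-Go trial from (its press, the following trial's press).

    ``next_button=None`` means there is no following trial (run end); the
    error is then aware only if the erroneous press itself was a right
    press, since no awareness signal could be recorded.
    """
    if nogo_button == NONE:
        return CORRECT_INHIBITION
    if next_button is None:
        return AWARE_ERROR if nogo_button == RIGHT else UNAWARE_ERROR
    if nogo_button == LEFT and next_button == LEFT:
        return UNAWARE_ERROR
    return AWARE_ERROR


def classify_trials(seq: TrialSequence, resp: SubjectResponses) -> OutcomeTable:
    """Label every trial of a subject's run.

    Pure function of the inputs; raises :class:`AlignmentError` when the
    response log length does not match the sequence.
    """
    n = len(seq)
    if len(resp) != n:
        raise AlignmentError(
            f"sequence has {n} trials but responses cover {len(resp)}"
        )
    nogo_class: list[str | None] = [None] * n
    omission = np.zeros(n, dtype=bool)
    anomalous = np.zeros(n, dtype=bool)

    is_nogo = seq.is_nogo
    for i, trial in enumerate(seq.trials):
        if is_nogo[i]:
            nxt = resp.button[i + 1] if i + 1 < n else None
            nogo_class[i] = classify_nogo_pair(resp.button[i], nxt)
        else:
            if resp.button[i] == NONE:
                omission[i] = True
            elif resp.button[i] == RIGHT:
                prev_error = i > 0 and is_nogo[i - 1] and resp.button[i - 1] != NONE
                if not prev_error:
                    anomalous[i] = True

    counts = {c: sum(1 for x in nogo_class if x == c) for c in NOGO_CLASSES}
    counts["n_nogo"] = int(is_nogo.sum())
    counts["n_go"] = n - counts["n_nogo"]
    counts["n_omission"] = int(omission.sum())
    counts["n_anomalous_right"] = int(anomalous.sum())
    assert (
        counts[CORRECT_INHIBITION] + counts[AWARE_ERROR] + counts[UNAWARE_ERROR]
        == counts["n_nogo"]
    )
    return OutcomeTable(
        subject_id=resp.subject_id,
        nogo_class=nogo_class,
        omission=omission,
        anomalous_right=anomalous,
        summary=counts,
    )


def event_onsets_by_class(
    seq: TrialSequence, outcomes: OutcomeTable
) -> dict[str, np.ndarray]:
    """Onset times (s) of every event category used by the design matrix.

    The three No-Go classes partition the No-Go onsets exactly; omission
    onsets are listed separately under ``"omission"``.
    """
    if len(outcomes) != len(seq):
        raise AlignmentError("outcome table does not match sequence length")
    out: dict[str, list[float]] = {c: [] for c in NOGO_CLASSES}
    out["omission"] = []
    for i, trial in enumerate(seq.trials):
        c = outcomes.nogo_class[i]
        if c is not None:
            out[c].append(trial.onset_s)
        elif outcomes.omission[i]:
            out["omission"].append(trial.onset_s)
    return {k: np.asarray(v) for k, v in out.items()}
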
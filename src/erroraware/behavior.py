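"""Behavioral summaries and supporting statistics for the EAT.

Per-subject indices: inhibition accuracy (% of No-Go trials withheld),
error awareness (% of commission errors signaled), per-class reaction
times, and the post-No-Go reaction-time adjustment — the RT of the third
Go trial after a No-Go event minus the RT of the Go trial immediately
before it. The first two post-error trials are contaminated by the
awareness press and are therefore not used for slowing.

Group statistics: one-way repeated-measures ANOVA with Greenhouse-Geisser
correction, Spearman rank correlations, and Holm step-down multiplicity
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .classify import (
    AWARE_ERROR,
    CORRECT_INHIBITION,
    UNAWARE_ERROR,
    OutcomeTable,
    SubjectResponses,
)
from .task import TrialSequence

__all__ = [
    "BehavioralSummary",
    "summarize_behavior",
    "post_nogo_adjustment",
    "rm_anova_gg",
    "spearman_rho",
    "holm_adjust",
    "cohort_table",
]


@dataclass(frozen=True)
class BehavioralSummary:
    subject_id: str
    inhibition_pct: float
    total_errors: int
    awareness_pct: float  # NaN when the subject made no commission errors
    rt_go_ms: float
    rt_aware_ms: float
    rt_unaware_ms: float
    postnogo_adjust_aware_ms: float
    postnogo_adjust_unaware_ms: float
    postnogo_adjust_correct_ms: float


def _mean_or_nan(values: list[float]) -> float:
    return float(np.mean(values)) if values else float("nan")


def post_nogo_adjustment(
    seq: TrialSequence,
    outcomes: OutcomeTable,
    resp: SubjectResponses,
    nogo_class: str,
) -> tuple[np.ndarray, float]:
    """Per-event post-No-Go RT adjustments for one outcome class.

    For each No-Go event of the class, adjustment = RT(third following
    Go trial) - RT(Go trial immediately preceding the No-Go). Events are
    dropped when the window is unusable: the pre- or third-post trial
    lacks a left-press RT, the window crosses a block boundary, or
    another No-Go falls within the three following trials. Returns the
    retained per-event values and their mean (NaN when none remain).
    """
    vals: list[float] = []
    n = len(seq)
    for i, trial in enumerate(seq.trials):
        if outcomes.nogo_class[i] != nogo_class:
            continue
        j = i + 3
        if i == 0 or j >= n:
            continue
        pre, post = seq.trials[i - 1], seq.trials[j]
        if pre.block != trial.block or post.block != trial.block:
            continue
        if any(seq.trials[k].trial_type == "nogo" for k in range(i + 1, j + 1)):
            continue
        if pre.trial_type != "go" or resp.button[i - 1] != "left":
            continue
        if resp.button[j] != "left":
            continue
        vals.append(float(resp.rt_ms[j] - resp.rt_ms[i - 1]))
    return np.asarray(vals), _mean_or_nan(vals)


def summarize_behavior(
    seq: TrialSequence, outcomes: OutcomeTable, resp: SubjectResponses
) -> BehavioralSummary:
    """Compute every per-subject behavioral index.

    RT means exclude omissions, anomalous right presses on Go trials,
    and awareness presses; aware/unaware RTs are the latencies of the
    erroneous No-Go presses themselves. Awareness percentage is NaN for
    subjects with zero commission errors (mirroring the exclusion of
    participants who never signaled).
    """
    s = outcomes.summary
    n_nogo = s["n_nogo"]
    n_err = s[AWARE_ERROR] + s[UNAWARE_ERROR]
    inhibition = 100.0 * s[CORRECT_INHIBITION] / n_nogo if n_nogo else float("nan")
    awareness = 100.0 * s[AWARE_ERROR] / n_err if n_err else float("nan")

    go_rts, aware_rts, unaware_rts = [], [], []
    for i, trial in enumerate(seq.trials):
        if trial.trial_type == "go":
            if resp.button[i] == "left":
                go_rts.append(float(resp.rt_ms[i]))
        else:
            c = outcomes.nogo_class[i]
            if resp.button[i] != "none":
                if c == AWARE_ERROR:
                    aware_rts.append(float(resp.rt_ms[i]))
                elif c == UNAWARE_ERROR:
                    unaware_rts.append(float(resp.rt_ms[i]))

    adjustments = {
        cls: post_nogo_adjustment(seq, outcomes, resp, cls)[1]
        for cls in (AWARE_ERROR, UNAWARE_ERROR, CORRECT_INHIBITION)
    }
    return BehavioralSummary(
        subject_id=outcomes.subject_id,
        inhibition_pct=inhibition,
        total_errors=n_err,
        awareness_pct=awareness,
        rt_go_ms=_mean_or_nan(go_rts),
        rt_aware_ms=_mean_or_nan(aware_rts),
        rt_unaware_ms=_mean_or_nan(unaware_rts),
        postnogo_adjust_aware_ms=adjustments[AWARE_ERROR],
        postnogo_adjust_unaware_ms=adjustments[UNAWARE_ERROR],
        postnogo_adjust_correct_ms=adjustments[CORRECT_INHIBITION],
    )


def cohort_table(summaries: list[BehavioralSummary]) -> pd.DataFrame:
    """Cohort-level mean (SD) table of the behavioral indices."""
    df = pd.DataFrame([s.__dict__ for s in summaries]).drop(columns="subject_id")
    rows = {
        "Inhibition accuracy %": "inhibition_pct",
        "Total errors": "total_errors",
        "Error awareness %": "awareness_pct",
        "Reaction time (ms): Go trial": "rt_go_ms",
        "Reaction time (ms): Aware trial": "rt_aware_ms",
        "Reaction time (ms): Unaware trial": "rt_unaware_ms",
        "Post-No-Go adjustment (ms): Aware error": "postnogo_adjust_aware_ms",
        "Post-No-Go adjustment (ms): Unaware error": "postnogo_adjust_unaware_ms",
        "Post-No-Go adjustment (ms): Correct inhibition": "postnogo_adjust_correct_ms",
    }
    return pd.DataFrame(
        {
            "category": list(rows),
            "mean": [df[c].mean() for c in rows.values()],
            "sd": [df[c].std() for c in rows.values()],
            "n": [int(df[c].notna().sum()) for c in rows.values()],
        }
    )


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def rm_anova_gg(data: np.ndarray) -> dict[str, float]:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``data`` is a complete subjects x conditions matrix. Returns F, the
    uncorrected and GG-corrected degrees of freedom, the GG epsilon
    (clipped to [1/(k-1), 1]), and the corrected p-value. Epsilon is
    computed from the double-centred condition covariance matrix as
    tr(S)^2 / ((k-1) tr(S @ S)).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be a subjects x conditions matrix")
    n, k = data.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    if not np.isfinite(data).all():
        raise ValueError("data must be complete (no missing values)")

    grand = data.mean()
    cond_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    tol = 1e-12 * max(ss_total, 1.0)
    if ss_err <= tol:
        F = 0.0 if ss_cond <= tol else float("inf")
    else:
        F = ms_cond / ms_err

    S = np.cov(data, rowvar=False)
    C = np.eye(k) - np.ones((k, k)) / k
    St = C @ S @ C
    tr, tr2 = np.trace(St), np.trace(St @ St)
    eps = (tr**2) / (df1 * tr2) if tr2 > 0 else 1.0
    eps = float(np.clip(eps, 1.0 / df1, 1.0))

    p = float(stats.f.sf(F, eps * df1, eps * df2)) if np.isfinite(F) else 0.0
    return {
        "F": float(F),
        "df1": float(df1),
        "df2": float(df2),
        "gg_epsilon": eps,
        "df1_gg": eps * df1,
        "df2_gg": eps * df2,
        "p": p,
    }


def spearman_rho(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (midrank ties) with its p-value.

    Raises on constant input, where the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]
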
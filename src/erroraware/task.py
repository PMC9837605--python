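"""Error Awareness Task (EAT) trial-sequence generation and validation.

The EAT is a motor Go/No-Go paradigm: a serial stream of color words is
shown in a congruent (No-Go) or incongruent (Go) ink color. Subjects press
left on Go trials, withhold on No-Go trials, and signal awareness of a
commission error with a right press on the following trial. The run is
organised in blocks of fixed-length trials presented back to back at a
constant stimulus-onset asynchrony, with rest periods between blocks.

This module generates pseudorandom event-related sequences under the
design constraints (exact Go/No-Go counts, bounded runs of Go trials
between No-Go trials) and validates arbitrary sequences against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

__all__ = [
    "TaskConfig",
    "TrialSpec",
    "TrialSequence",
    "ValidationReport",
    "Violation",
    "InfeasibleDesignError",
    "generate_sequence",
    "validate_sequence",
    "nogo_gap_lengths",
]

#: Color-word palette used for stimulus labels (cosmetic; not used by analysis).
COLOR_PALETTE = ("RED", "GREEN", "BLUE", "YELLOW")


class InfeasibleDesignError(ValueError):
    """Raised when no sequence can satisfy the configured constraints."""


@dataclass(frozen=True)
class TaskConfig:
    """Design parameters of an EAT run.

    Defaults reproduce the standard design: 6 blocks of 175 trials
    (900 Go + 150 No-Go in total), 900 ms stimuli with a 600 ms
    inter-stimulus interval, and 1-12 Go trials between No-Go trials.
    """

    n_blocks: int = 6
    trials_per_block: int = 175
    n_nogo_total: int = 150
    stim_ms: float = 900.0
    isi_ms: float = 600.0
    min_gap: int = 1
    max_gap: int = 12
    interblock_rest_s: float = 30.0
    #: Runs of Go trials truncated by a block boundary are exempt from the
    #: min/max gap bounds (the leading run still has length >= 1 so that a
    #: No-Go trial is never the first trial of a block).
    exempt_edge_runs: bool = True
    rng_seed: int = 0

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def n_go_total(self) -> int:
        return self.n_trials - self.n_nogo_total

    @property
    def trial_s(self) -> float:
        """Stimulus-onset asynchrony in seconds."""
        return (self.stim_ms + self.isi_ms) / 1000.0

    @property
    def block_duration_s(self) -> float:
        return self.trials_per_block * self.trial_s

    @property
    def run_duration_s(self) -> float:
        """Time from first stimulus onset to end of the last block's ISI."""
        return (
            self.n_blocks * self.block_duration_s
            + (self.n_blocks - 1) * self.interblock_rest_s
        )

    def block_start_s(self, block: int) -> float:
        return block * (self.block_duration_s + self.interblock_rest_s)

    def rest_epochs(self) -> list[tuple[float, float]]:
        """(start, end) in seconds of the inter-block rest periods."""
        return [
            (self.block_start_s(b) + self.block_duration_s, self.block_start_s(b + 1))
            for b in range(self.n_blocks - 1)
        ]

    def validate(self) -> None:
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("n_blocks and trials_per_block must be positive")
        if not (0 <= self.n_nogo_total <= self.n_trials):
            raise InfeasibleDesignError(
                f"n_nogo_total={self.n_nogo_total} exceeds total trials {self.n_trials}"
            )
        if self.min_gap < 1:
            raise ValueError("min_gap must be >= 1")
        if self.max_gap < self.min_gap:
            raise ValueError("max_gap must be >= min_gap")
        if self.stim_ms <= 0 or self.isi_ms < 0:
            raise ValueError("stimulus/ISI durations must be positive")


@dataclass(frozen=True)
class TrialSpec:
    """A single timed trial. ``congruent`` is True iff the trial is No-Go."""

    block: int
    trial_index: int  # 0-based index within the whole run
    trial_type: str  # "go" | "nogo"
    onset_s: float
    word: str
    ink: str

    @property
    def congruent(self) -> bool:
        return self.word == self.ink


@dataclass(frozen=True)
class TrialSequence:
    config: TaskConfig
    trials: tuple[TrialSpec, ...]

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[TrialSpec]:
        return iter(self.trials)

    def __getitem__(self, i):
        return self.trials[i]

    @property
    def onsets(self) -> np.ndarray:
        return np.array([t.onset_s for t in self.trials])

    @property
    def is_nogo(self) -> np.ndarray:
        return np.array([t.trial_type == "nogo" for t in self.trials])

    def counts(self) -> dict[str, int]:
        n_nogo = int(self.is_nogo.sum())
        return {"nogo": n_nogo, "go": len(self.trials) - n_nogo}


@dataclass(frozen=True)
class Violation:
    constraint: str
    location: str
    observed: object

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.constraint} at {self.location}: observed {self.observed}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, constraint: str, location: str, observed) -> None:
        self.violations.append(Violation(constraint, location, observed))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _split_nogo_across_blocks(cfg: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    """Distribute the total No-Go count across blocks as evenly as possible,
    assigning the remainder to randomly chosen blocks."""
    base, rem = divmod(cfg.n_nogo_total, cfg.n_blocks)
    counts = np.full(cfg.n_blocks, base, dtype=int)
    if rem:
        counts[rng.choice(cfg.n_blocks, size=rem, replace=False)] += 1
    per_block_cap = (cfg.trials_per_block - 1) // (cfg.min_gap)  # leading Go required
    if np.any(counts > per_block_cap):
        raise InfeasibleDesignError(
            f"a block would need {counts.max()} No-Go trials; at most "
            f"{per_block_cap} fit in {cfg.trials_per_block} trials with "
            f"min_gap={cfg.min_gap}"
        )
    return counts


def _sample_block_gaps(
    n_nogo: int, n_go: int, cfg: TaskConfig, rng: np.random.Generator
) -> np.ndarray:
    """Sample Go-run lengths around ``n_nogo`` No-Go trials in one block.

    Returns a vector of ``n_nogo + 1`` run lengths: the leading run (before
    the first No-Go, length >= 1), the internal runs (within
    [min_gap, max_gap]), and the trailing run (length >= 0). The internal
    runs are drawn uniformly on [min_gap, max_gap]; a stochastic repair
    loop then adjusts randomly chosen runs within their bounds until the
    lengths sum to ``n_go`` exactly.
    """
    if n_nogo == 0:
        return np.array([n_go], dtype=int)
    lo = np.concatenate(([1], np.full(n_nogo - 1, cfg.min_gap), [0]))
    if cfg.exempt_edge_runs:
        hi = np.concatenate(([n_go], np.full(n_nogo - 1, cfg.max_gap), [n_go]))
    else:
        hi = np.concatenate(
            ([min(cfg.max_gap, n_go)], np.full(n_nogo - 1, cfg.max_gap), [cfg.max_gap])
        )
    if lo.sum() > n_go or hi.sum() < n_go:
        raise InfeasibleDesignError(
            f"block with {n_nogo} No-Go and {n_go} Go trials cannot satisfy "
            f"gap bounds [{cfg.min_gap}, {cfg.max_gap}] "
            f"(need sum in [{lo.sum()}, {hi.sum()}])"
        )
    # Initial draw: every run starts in [min_gap, max_gap]-like ranges so the
    # repair loop distributes the block's Go budget roughly uniformly; the
    # exempt edge runs keep their looser bounds only during repair.
    init_hi = np.minimum(hi, np.concatenate(([cfg.max_gap], np.full(n_nogo - 1, cfg.max_gap), [cfg.max_gap])))
    gaps = rng.integers(lo, np.maximum(init_hi, lo) + 1)
    # Repair to exact total: nudge random runs within bounds.
    diff = n_go - int(gaps.sum())
    while diff != 0:
        j = rng.integers(len(gaps))
        if diff > 0 and gaps[j] < hi[j]:
            gaps[j] += 1
            diff -= 1
        elif diff < 0 and gaps[j] > lo[j]:
            gaps[j] -= 1
            diff += 1
    return gaps


def generate_sequence(config: TaskConfig) -> TrialSequence:
    """Generate a constraint-satisfying pseudorandom EAT sequence.

    No-Go positions are placed block by block by sampling the Go-run
    lengths between them (uniform on [min_gap, max_gap] with stochastic
    repair to hit the exact per-block totals). Deterministic for a given
    ``config.rng_seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    nogo_per_block = _split_nogo_across_blocks(config, rng)

    trials: list[TrialSpec] = []
    palette = COLOR_PALETTE
    idx = 0
    for b in range(config.n_blocks):
        k = int(nogo_per_block[b])
        n_go_block = config.trials_per_block - k
        gaps = _sample_block_gaps(k, n_go_block, config, rng)
        kinds: list[str] = []
        for g_i, gap in enumerate(gaps):
            kinds.extend(["go"] * int(gap))
            if g_i < k:
                kinds.append("nogo")
        assert len(kinds) == config.trials_per_block
        t0 = config.block_start_s(b)
        for j, kind in enumerate(kinds):
            word = palette[rng.integers(len(palette))]
            if kind == "nogo":
                ink = word  # congruent
            else:
                others = [c for c in palette if c != word]
                ink = others[rng.integers(len(others))]
            trials.append(
                TrialSpec(
                    block=b,
                    trial_index=idx,
                    trial_type=kind,
                    onset_s=t0 + j * config.trial_s,
                    word=word,
                    ink=ink,
                )
            )
            idx += 1
    return TrialSequence(config=config, trials=tuple(trials))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def nogo_gap_lengths(seq: TrialSequence, within_block: bool | None = None) -> list[int]:
    """Lengths of Go runs strictly between consecutive No-Go trials.

    With ``within_block=True`` (the default when the sequence's config
    exempts edge runs) only pairs of No-Go trials in the same block are
    counted; runs truncated by a block boundary are skipped.
    """
    if within_block is None:
        within_block = seq.config.exempt_edge_runs
    gaps = []
    prev: TrialSpec | None = None
    for t in seq.trials:
        if t.trial_type != "nogo":
            continue
        if prev is not None and (not within_block or prev.block == t.block):
            gaps.append(t.trial_index - prev.trial_index - 1)
        prev = t
    return gaps


def validate_sequence(seq: TrialSequence) -> ValidationReport:
    """Check a sequence against every design invariant.

    Never raises on content; returns a report listing each violated
    constraint with its location and the observed value.
    """
    cfg = seq.config
    report = ValidationReport()

    counts = seq.counts()
    if counts["nogo"] != cfg.n_nogo_total:
        report.add("nogo_count", "sequence", counts["nogo"])
    if counts["go"] != cfg.n_go_total:
        report.add("go_count", "sequence", counts["go"])
    if len(seq) != cfg.n_trials:
        report.add("trial_count", "sequence", len(seq))

    # Onset grid and ordering
    last_onset = -np.inf
    per_block_counter: dict[int, int] = {}
    for t in seq.trials:
        j = per_block_counter.get(t.block, 0)
        per_block_counter[t.block] = j + 1
        expected = cfg.block_start_s(t.block) + j * cfg.trial_s
        if abs(t.onset_s - expected) > 1e-9:
            report.add("onset_grid", f"trial {t.trial_index}", t.onset_s)
        if t.onset_s <= last_onset:
            report.add("onset_increasing", f"trial {t.trial_index}", t.onset_s)
        last_onset = t.onset_s
        if (t.trial_type == "nogo") != (t.word == t.ink):
            report.add("congruency", f"trial {t.trial_index}", (t.word, t.ink))

    # Gap bounds (runs strictly between No-Go trials; edge runs per config)
    prev = None
    for t in seq.trials:
        if t.trial_type != "nogo":
            continue
        if prev is not None and (not cfg.exempt_edge_runs or prev.block == t.block):
            gap = t.trial_index - prev.trial_index - 1
            if gap < cfg.min_gap or gap > cfg.max_gap:
                report.add(
                    "gap_bounds",
                    f"between No-Go trials {prev.trial_index} and {t.trial_index}",
                    gap,
                )
        prev = t

    # No-Go never first trial of a block
    first_of_block: dict[int, TrialSpec] = {}
    for t in seq.trials:
        first_of_block.setdefault(t.block, t)
    for b, t in first_of_block.items():
        if t.trial_type == "nogo":
            report.add("nogo_first_of_block", f"block {b}", t.trial_index)

    return report


def with_seed(config: TaskConfig, seed: int) -> TaskConfig:
    """Copy of ``config`` with a different RNG seed."""
    return replace(config, rng_seed=int(seed))
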
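"""Synthetic EAT cohorts with known ground truth.

Generates everything a real study would record — trial-by-trial button
presses and latencies, questionnaire subscale matrices, and 4-D BOLD
runs — from explicit generative parameters, so that every downstream
stage (classification, behavioral summaries, deconvolution, cluster
inference, trait regression) can be tested against planted truth.

Behavioral profile defaults target the reference cohort values:
inhibition accuracy ~53.6%, error awareness ~86.5%, Go RT mean ~518 ms
(SD ~81 ms), and +19 ms slowing on the third Go trial after an unaware
error. BOLD runs follow a linear forward model: baseline plus
condition-specific gamma-variate responses in planted regions, Legendre
drift, and spatially smoothed AR(1) Gaussian noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import io as eio
from .classify import (
    AWARE_ERROR,
    CORRECT_INHIBITION,
    UNAWARE_ERROR,
    OutcomeTable,
    SubjectResponses,
    classify_trials,
    event_onsets_by_class,
)
from .deconvolve import DEFAULT_FIR_WINDOW_S, FWHM_TO_SIGMA, GammaHRF
from .task import TaskConfig, TrialSequence, generate_sequence, with_seed

__all__ = [
    "TRAIT_NAMES",
    "TRAIT_INSTRUMENTS",
    "BehaviorParams",
    "TraitParams",
    "Region",
    "NeuroParams",
    "simulate_responses",
    "simulate_traits",
    "simulate_bold",
    "simulate_subject",
    "simulate_cohort",
]

#: The 22 questionnaire subscales used as trait predictors, in fixed order.
TRAIT_NAMES = (
    "BIS-11—attentional",
    "BIS-11—motor",
    "BIS-11—nonplanning",
    "AQ—social skill",
    "AQ—attention switching",
    "AQ—attention to detail",
    "AQ—communication",
    "AQ—imagination",
    "BIS/BAS—BAS drive",
    "BIS/BAS—BAS fun",
    "BIS/BAS—BAS reward",
    "BIS/BAS—BIS score",
    "HADS—anxiety",
    "HADS—depression",
    "CAARS—attention",
    "CAARS—hyperactivity",
    "CAARS—impulsivity",
    "CAARS—self-concept",
    "CAARS—DSM attention",
    "CAARS—DSM hyperactivity",
    "CAARS—DSM ADHD",
    "CAARS—index",
)

#: Instrument membership (prefix before the em-dash) for the latent
#: block-correlation structure.
TRAIT_INSTRUMENTS = tuple(name.split("—")[0] for name in TRAIT_NAMES)


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BehaviorParams:
    """Generative behavioral profile of one subject population.

    Go RTs are lognormal with the given mean/SD in milliseconds; aware
    and unaware commission errors shift the erroneous press latency
    additively. ``post_unaware_slow_ms`` is added to the RT of the third
    Go trial after an unaware error (the planted post-error slowing).
    """

    p_inhibit: float = 0.536
    p_aware: float = 0.865
    go_rt_mean_ms: float = 518.0
    go_rt_sd_ms: float = 81.0
    aware_rt_shift_ms: float = -29.0
    unaware_rt_shift_ms: float = -10.0
    p_omission: float = 0.02
    post_unaware_slow_ms: float = 19.0

    def validate(self) -> None:
        for name in ("p_inhibit", "p_aware", "p_omission"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.go_rt_mean_ms <= 0 or self.go_rt_sd_ms <= 0:
            raise ValueError("RT parameters must be positive")

    def lognormal_mu_sigma(self) -> tuple[float, float]:
        """(mu, sigma) of the underlying normal matching the target
        mean/SD of the lognormal RT distribution."""
        m, s = self.go_rt_mean_ms, self.go_rt_sd_ms
        sigma2 = np.log(1.0 + (s / m) ** 2)
        return float(np.log(m) - sigma2 / 2.0), float(np.sqrt(sigma2))


def simulate_responses(
    seq: TrialSequence, params: BehaviorParams, seed: int
) -> SubjectResponses:
    """Simulate one subject's button presses on a trial sequence.

    Go trials receive a left press with a lognormal RT (or an omission
    with probability ``p_omission``). Each No-Go trial is withheld with
    probability ``p_inhibit``; otherwise a left press occurs, and with
    probability ``p_aware`` the subject signals the error with a right
    press on the next trial. The first trial after a commission error is
    never omitted (the subject has demonstrably just responded), which
    keeps the classified awareness rate equal to ``p_aware`` in
    expectation. Unaware errors add ``post_unaware_slow_ms`` to the RT
    of the third following trial when that trial is a Go trial.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    mu, sg = params.lognormal_mu_sigma()
    n = len(seq)
    rt_cap = (seq.config.stim_ms + seq.config.isi_ms) * 0.999

    base_rt = rng.lognormal(mu, sg, size=n)
    u_inhib = rng.random(n)
    u_aware = rng.random(n)
    u_omit = rng.random(n)

    button = ["none"] * n
    rt = np.full(n, np.nan)
    signal_next = False  # right press due on the next trial
    slow_at = np.zeros(n)  # planted additive slowing per trial
    after_error = False  # previous trial was a commission error

    for i, trial in enumerate(seq.trials):
        if trial.trial_type == "nogo":
            pending_signal, signal_next = signal_next, False
            if pending_signal:
                # An awareness press lands on a No-Go trial only when the
                # error occurred on the last trial of a block and the next
                # stimulus is No-Go; by design min_gap >= 1 prevents this
                # within a block, so the press simply does not occur.
                pass
            if u_inhib[i] < params.p_inhibit:
                after_error = False
                continue  # correct inhibition: no press
            aware = u_aware[i] < params.p_aware
            shift = params.aware_rt_shift_ms if aware else params.unaware_rt_shift_ms
            button[i] = "left"
            rt[i] = np.clip(base_rt[i] + shift, 120.0, rt_cap)
            after_error = True
            if aware:
                signal_next = True
            else:
                j = i + 3
                if j < n and seq.trials[j].trial_type == "go":
                    slow_at[j] += params.post_unaware_slow_ms
        else:
            pending_signal, signal_next = signal_next, False
            if pending_signal:
                button[i] = "right"
                rt[i] = np.clip(base_rt[i], 120.0, rt_cap)
            elif not after_error and u_omit[i] < params.p_omission:
                pass  # omission
            else:
                button[i] = "left"
                rt[i] = np.clip(base_rt[i] + slow_at[i], 120.0, rt_cap)
            after_error = False
    return SubjectResponses(subject_id="sim", button=button, rt_ms=rt)


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitParams:
    """Latent structure of the questionnaire battery.

    Subscales of the same instrument correlate at ``rho_within``, across
    instruments at ``rho_between``. ``true_effects`` maps a subscale name
    to its correlation with the supplied outcome vector. Missingness is
    MCAR at the subject level (a missing subject lacks the whole
    battery), at rate 20/402 by default.
    """

    rho_within: float = 0.5
    rho_between: float = 0.15
    true_effects: dict[str, float] = field(default_factory=dict)
    mcar_rate: float = 20.0 / 402.0

    def validate(self) -> None:
        if not 0.0 <= self.mcar_rate < 1.0:
            raise ValueError("mcar_rate must be in [0, 1)")
        unknown = set(self.true_effects) - set(TRAIT_NAMES)
        if unknown:
            raise ValueError(f"unknown trait name(s): {', '.join(sorted(unknown))}")
        for k, v in self.true_effects.items():
            if not -1.0 < v < 1.0:
                raise ValueError(f"true effect for {k} must be in (-1, 1)")

    def correlation_matrix(self) -> np.ndarray:
        p = len(TRAIT_NAMES)
        corr = np.full((p, p), self.rho_between)
        for i in range(p):
            for j in range(p):
                if TRAIT_INSTRUMENTS[i] == TRAIT_INSTRUMENTS[j]:
                    corr[i, j] = self.rho_within
        np.fill_diagonal(corr, 1.0)
        return corr


def simulate_traits(
    n_subjects: int,
    params: TraitParams,
    neural_outcome: np.ndarray,
    seed: int,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate the 22-column trait matrix plus a missingness mask.

    Columns with a true effect beta are built as
    ``beta * z(outcome) + sqrt(1 - beta**2) * latent`` so their
    population correlation with the outcome equals beta. Returns the
    trait DataFrame (NaN where missing) and the boolean missing mask.
    """
    params.validate()
    neural_outcome = np.asarray(neural_outcome, dtype=float)
    if len(neural_outcome) != n_subjects:
        raise ValueError("neural_outcome length must equal n_subjects")
    rng = np.random.default_rng(seed)
    corr = params.correlation_matrix()
    try:
        L = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("trait correlation matrix is not positive definite") from exc

    z_latent = rng.standard_normal((n_subjects, len(TRAIT_NAMES))) @ L.T
    sd = neural_outcome.std()
    z_out = (
        (neural_outcome - neural_outcome.mean()) / sd
        if sd > 0
        else np.zeros(n_subjects)
    )
    X = np.empty_like(z_latent)
    for j, name in enumerate(TRAIT_NAMES):
        beta = params.true_effects.get(name, 0.0)
        X[:, j] = beta * z_out + np.sqrt(1.0 - beta**2) * z_latent[:, j]

    missing_rows = rng.random(n_subjects) < params.mcar_rate
    mask = np.repeat(missing_rows[:, None], len(TRAIT_NAMES), axis=1)
    X = np.where(mask, np.nan, X)
    df = pd.DataFrame(X, columns=list(TRAIT_NAMES))
    return df, mask


# ---------------------------------------------------------------------------
# BOLD forward model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Region:
    """A planted signal region: an axis-aligned voxel box with one
    percent-area amplitude per event condition."""

    name: str
    box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    amp_aware: float = 0.0
    amp_unaware: float = 0.0
    amp_correct: float = 0.0

    def mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        for (lo, hi), dim in zip(self.box, grid_shape):
            if not (0 <= lo < hi <= dim):
                raise ValueError(
                    f"region '{self.name}' box {self.box} outside grid {grid_shape}"
                )
        m = np.zeros(grid_shape, dtype=bool)
        (x0, x1), (y0, y1), (z0, z1) = self.box
        m[x0:x1, y0:y1, z0:z1] = True
        return m

    def amplitude(self, condition: str) -> float:
        return {
            AWARE_ERROR: self.amp_aware,
            UNAWARE_ERROR: self.amp_unaware,
            CORRECT_INHIBITION: self.amp_correct,
        }[condition]


def _default_regions() -> tuple[Region, ...]:
    return (
        Region(
            name="effect",
            box=((6, 9), (14, 17), (9, 12)),
            amp_aware=1.0,
            amp_unaware=0.5,
            amp_correct=0.3,
        ),
    )


@dataclass(frozen=True)
class NeuroParams:
    """Generative parameters of a synthetic BOLD run.

    Amplitudes are in percent-area units: a region with amplitude ``a``
    yields a fitted gamma-variate AUC of ``a/100 * baseline * window_s``
    signal-seconds, i.e. a percent-area estimate of ``a`` under the
    subject-level analysis. ``smooth_fwhm_mm`` is the spatial smoothness
    of the noise field (the planted signal itself stays confined to its
    region so recovered region means are unbiased).
    """

    grid_shape: tuple[int, int, int] = (24, 24, 18)
    voxel_mm: float = 3.0
    tr_s: float = 2.46
    hrf_r: float = 8.6
    hrf_b: float = 0.547
    regions: tuple[Region, ...] = field(default_factory=_default_regions)
    baseline: float = 100.0
    noise_sd: float = 1.0
    ar1_rho: float = 0.3
    drift_amp: float = 1.0
    drift_order: int = 3
    smooth_fwhm_mm: float = 6.0
    window_s: float = DEFAULT_FIR_WINDOW_S
    tail_s: float = 15.0

    def validate(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if not -1.0 < self.ar1_rho < 1.0:
            raise ValueError("|ar1_rho| must be < 1")
        total = np.zeros(self.grid_shape, dtype=int)
        for reg in self.regions:
            total += reg.mask(self.grid_shape).astype(int)
        if total.max() > 1:
            raise ValueError("region masks overlap")

    def n_volumes(self, cfg: TaskConfig) -> int:
        return int(np.ceil((cfg.run_duration_s + self.tail_s) / self.tr_s))

    def true_hrf(self) -> GammaHRF:
        return GammaHRF.unit_area(self.hrf_r, self.hrf_b)


def _ar1_noise(
    shape: tuple[int, ...], rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary unit-variance AR(1) noise along the last axis."""
    e = rng.standard_normal(shape)
    if rho == 0.0 or shape[-1] == 1:
        return e
    s = np.sqrt(1.0 - rho**2)
    x = np.empty_like(e)
    x[..., 0] = e[..., 0]  # exact stationary start (unit variance)
    zi = (rho * x[..., 0])[..., None]
    x[..., 1:], _ = sps.lfilter([s], [1.0, -rho], e[..., 1:], axis=-1, zi=zi)
    return x


def simulate_bold(
    seq: TrialSequence,
    outcomes: OutcomeTable,
    params: NeuroParams,
    seed: int,
) -> np.ndarray:
    """Forward-simulate a 4-D BOLD run (x, y, z, t).

    Voxel time series = baseline + sum over conditions of
    amplitude * (TR-binned event train convolved with the sampled
    unit-area gamma HRF) + Legendre drift + smoothed AR(1) noise.
    With ``noise_sd=0`` and ``drift_amp=0`` the run is an exact, noise-free
    evaluation of the forward model.
    """
    params.validate()
    cfg = seq.config
    nt = params.n_volumes(cfg)
    rng = np.random.default_rng(seed)
    data = np.full((*params.grid_shape, nt), params.baseline, dtype=float)

    # Condition responses in planted regions
    onsets = event_onsets_by_class(seq, outcomes)
    n_lags = int(round(params.window_s / params.tr_s)) + 1
    h = params.true_hrf().sample(params.tr_s, n_lags)  # unit-AUC samples
    cond_ts: dict[str, np.ndarray] = {}
    for cond in (AWARE_ERROR, UNAWARE_ERROR, CORRECT_INHIBITION):
        train = np.zeros(nt)
        for onset in onsets[cond]:
            k = int(round(onset / params.tr_s))
            if 0 <= k < nt:
                train[k] += 1.0
        cond_ts[cond] = np.convolve(train, h)[:nt]
    for reg in params.regions:
        m = reg.mask(params.grid_shape)
        ts = np.zeros(nt)
        for cond, conv in cond_ts.items():
            amp = reg.amplitude(cond)
            if amp:
                ts = ts + (amp / 100.0 * params.baseline * params.window_s) * conv
        data[m] += ts

    # Polynomial drift (orders 1..q, mean-centred, per-voxel coefficients)
    if params.drift_amp > 0 and params.drift_order >= 1:
        x = np.linspace(-1.0, 1.0, nt)
        from numpy.polynomial import legendre as _leg

        for q in range(1, params.drift_order + 1):
            c = np.zeros(q + 1)
            c[q] = 1.0
            basis = _leg.legval(x, c)
            basis = basis - basis.mean()
            coef = rng.normal(0.0, params.drift_amp, size=params.grid_shape)
            data += coef[..., None] * basis[None, None, None, :]

    # Spatially smoothed AR(1) noise, rescaled to marginal SD = noise_sd
    if params.noise_sd > 0:
        noise = _ar1_noise((*params.grid_shape, nt), params.ar1_rho, rng)
        if params.smooth_fwhm_mm > 0:
            from scipy import ndimage

            sigma_vox = params.smooth_fwhm_mm * FWHM_TO_SIGMA / params.voxel_mm
            noise = ndimage.gaussian_filter(
                noise, sigma=[sigma_vox] * 3 + [0.0], mode="wrap"
            )
        noise *= params.noise_sd / noise.std()
        data += noise
    return data


def simulate_subject(
    seq: TrialSequence,
    behavior: BehaviorParams,
    neuro: NeuroParams | None,
    seed: int,
) -> tuple[SubjectResponses, OutcomeTable, np.ndarray | None]:
    """One subject end to end: responses, outcomes, and (optionally) BOLD."""
    resp = simulate_responses(seq, behavior, seed=eio.substream(seed, "responses"))
    outcomes = classify_trials(seq, resp)
    bold = None
    if neuro is not None:
        bold = simulate_bold(seq, outcomes, neuro, seed=eio.substream(seed, "bold"))
    return resp, outcomes, bold


# ---------------------------------------------------------------------------
# Cohort on disk
# ---------------------------------------------------------------------------


def simulate_cohort(
    n_subjects: int,
    out_dir: str | Path,
    seed: int = 0,
    task: TaskConfig | None = None,
    behavior: BehaviorParams | None = None,
    neuro: NeuroParams | None = None,
    traits: TraitParams | None = None,
    write_bold: bool = True,
) -> dict:
    """Write a self-describing synthetic cohort directory.

    Layout: ``events.tsv`` (one shared trial sequence), per-subject
    ``sub-XX/`` folders with ``responses.tsv``, ``outcomes.tsv`` and
    ``bold.nii.gz``, cohort-level ``traits.tsv``, and
    ``ground_truth.json`` recording every planted parameter. Fully
    deterministic for a given ``seed``.
    """
    task = task or TaskConfig()
    behavior = behavior or BehaviorParams()
    neuro = neuro or NeuroParams()
    traits = traits if traits is not None else TraitParams()
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create cohort directory {out}: {exc}") from exc

    seq = generate_sequence(with_seed(task, eio.substream(seed, "task")))
    eio.write_events_tsv(seq, out / "events.tsv")

    awareness = np.full(n_subjects, np.nan)
    subject_ids = []
    for s in range(n_subjects):
        sid = f"sub-{s:02d}"
        subject_ids.append(sid)
        sdir = out / sid
        sub_seed = eio.substream(seed, f"subject{s}")
        resp, outc, bold = simulate_subject(
            seq, behavior, neuro if write_bold else None, sub_seed
        )
        n_err = outc.summary[AWARE_ERROR] + outc.summary[UNAWARE_ERROR]
        awareness[s] = (
            100.0 * outc.summary[AWARE_ERROR] / n_err if n_err else np.nan
        )
        eio.write_table(
            pd.DataFrame({"button": resp.button, "rt_ms": resp.rt_ms}),
            sdir / "responses.tsv",
        )
        eio.write_table(outc.to_frame(), sdir / "outcomes.tsv")
        if bold is not None:
            eio.save_nifti(
                bold.astype(np.float32),
                sdir / "bold.nii.gz",
                voxel_mm=neuro.voxel_mm,
                tr_s=neuro.tr_s,
            )

    outcome_for_traits = np.where(np.isfinite(awareness), awareness, np.nanmean(awareness))
    trait_df, _ = simulate_traits(
        n_subjects, traits, outcome_for_traits, seed=eio.substream(seed, "traits")
    )
    trait_df.insert(0, "subject_id", subject_ids)
    eio.write_table(trait_df, out / "traits.tsv")

    truth = {
        "seed": int(seed),
        "n_subjects": int(n_subjects),
        "subject_ids": subject_ids,
        "task": dataclasses.asdict(task),
        "behavior": dataclasses.asdict(behavior),
        "neuro": dataclasses.asdict(neuro),
        "traits": dataclasses.asdict(traits),
        "awareness_pct": awareness.tolist(),
    }
    eio.write_json(truth, out / "ground_truth.json")
    return truth
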
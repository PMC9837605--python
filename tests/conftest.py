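import numpy as np
import pytest

from erroraware.classify import SubjectResponses
from erroraware.task import TaskConfig, TrialSequence, TrialSpec, generate_sequence


@pytest.fixture(scope="session")
def default_sequence() -> TrialSequence:
    """One full-size EAT sequence shared across tests."""
    return generate_sequence(TaskConfig(rng_seed=123))


@pytest.fixture(scope="session")
def small_config() -> TaskConfig:
    """A short but structurally complete task for fast simulations."""
    return TaskConfig(n_blocks=2, trials_per_block=35, n_nogo_total=10, rng_seed=7)


@pytest.fixture(scope="session")
def small_sequence(small_config) -> TrialSequence:
    return generate_sequence(small_config)


def build_toy_sequence(kinds: list[str], config: TaskConfig | None = None) -> TrialSequence:
    """Hand-build a single-block sequence from a list of 'go'/'nogo' labels."""
    if config is None:
        config = TaskConfig(
            n_blocks=1,
            trials_per_block=len(kinds),
            n_nogo_total=sum(k == "nogo" for k in kinds),
        )
    trials = []
    for i, kind in enumerate(kinds):
        word = "RED"
        ink = "RED" if kind == "nogo" else "BLUE"
        trials.append(
            TrialSpec(
                block=0,
                trial_index=i,
                trial_type=kind,
                onset_s=i * config.trial_s,
                word=word,
                ink=ink,
            )
        )
    return TrialSequence(config=config, trials=tuple(trials))


def build_responses(buttons: list[str], rts: list[float] | None = None) -> SubjectResponses:
    """Responses from button labels; RT defaults to 500 ms wherever pressed."""
    if rts is None:
        rts = [500.0 if b != "none" else np.nan for b in buttons]
    return SubjectResponses(subject_id="toy", button=list(buttons), rt_ms=np.asarray(rts))
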
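"""Shared fixtures: small synthetic cohorts and labeled tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from betapipe.task_sim import AgentParams, TaskConfig, simulate_cohort
from betapipe.taxonomy import label_trials


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Labeled 8-subject cohort with plenty of explorative choices."""
    task = TaskConfig(trials_per_block=30)
    agent = AgentParams(n_learning_trials=3.0, p_advantageous_stable=0.85)
    return label_trials(simulate_cohort(task, agent, 8, seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def tiny_run_config(seed: int = 0):
    """A minutes-scale end-to-end configuration for CLI/pipeline tests."""
    from betapipe.io import RunConfig
    from betapipe.synth_meg import default_templates

    return RunConfig(
        n_subjects=4,
        master_seed=seed,
        task=TaskConfig(trials_per_block=20),
        agent=AgentParams(n_learning_trials=2.0, p_advantageous_stable=0.82),
        layout_n=24,
        templates=default_templates(scale=1.5),
    )


def make_labeled_frame(
    n_subjects: int,
    trials_per_subject: int,
    rng: np.random.Generator,
    p_types=(0.7, 0.1, 0.1, 0.1),
) -> pd.DataFrame:
    """Directly construct a labeled trial table (no simulator) for unit tests."""
    n = n_subjects * trials_per_subject
    ct = rng.choice(["HP", "pre-LP", "LP", "post-LP"], size=n, p=list(p_types))
    p_gain = np.where(ct == "LP", 0.3, 0.7)
    fb = np.where(rng.random(n) < p_gain, "gain", "loss")
    prev = np.where(rng.random(n) < 0.6, "gain", "loss")
    log_rt = rng.normal(6.6, 0.25, size=n)
    return pd.DataFrame(
        {
            "subject_id": np.repeat([f"s{i:02d}" for i in range(n_subjects)], trials_per_subject),
            "block": 0,
            "trial": np.tile(np.arange(trials_per_subject), n_subjects),
            "choice_type": ct,
            "feedback": fb,
            "previous_feedback": prev,
            "log_rt": log_rt,
            "rt_ms": np.exp(log_rt),
            "analyzed": True,
        }
    )
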
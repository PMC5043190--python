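"""Shared fixtures: small synthetic experiments generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import memovie
from memovie.config import GeneratorConfig


@pytest.fixture(scope="session")
def default_dataset():
    """A mid-size experiment under the default generative regime."""
    cfg = GeneratorConfig(n_subjects=17, n_shots_per_episode=300, seed=42)
    return memovie.generate_dataset(cfg)


@pytest.fixture(scope="session")
def flat_dataset():
    """Single-session experiment with no duration/retention/ability effects.

    Correctness depends only on content, so content-based estimators see
    a clean additive signal.
    """
    feats = twenty_features()
    mags = np.linspace(0.0, 2.0, 20)
    weights = {
        f: float(m * (1 if i % 2 else -1))
        for i, (f, m) in enumerate(zip(feats, mags))
    }
    cfg = GeneratorConfig(
        n_subjects=20,
        n_shots_per_episode=1000,
        n_characters=5,
        n_sounds=5,
        n_emotions=5,
        n_objects=5,
        true_weights=weights,
        feature_probs={f: 0.3 for f in feats},
        base_logit=0.0,
        duration_weight=0.0,
        retention_rate=0.0,
        subject_ability_sd=0.2,
        single_frame_fraction=0.0,
        session_days=(0,),
        seed=77,
    )
    ds = memovie.generate_dataset(cfg)
    return ds, weights


def twenty_features() -> list[str]:
    """A 20-feature inventory (5 each of characters/sounds/emotions/objects)."""
    return (
        [f"char_{i:02d}" for i in range(1, 6)]
        + [f"sound_{i:02d}" for i in range(1, 6)]
        + [f"emotion_{i:02d}" for i in range(1, 6)]
        + [f"object_{i:02d}" for i in range(1, 6)]
    )


def bernoulli_trials(
    n_trials: int,
    p_correct: float,
    rng: np.random.Generator,
    subject_id: str = "s001",
    n_repeat_shots: int = 0,
    session_label: int = 0,
) -> pd.DataFrame:
    """Hand-built trial table with i.i.d. correctness at ``p_correct``.

    The first ``n_repeat_shots`` shots are queried twice (independent
    draws), the rest once; targets and foils alternate.
    """
    rows = []
    idx = 0
    for shot in range(n_trials):
        n_pres = 2 if shot < n_repeat_shots else 1
        for pres in range(n_pres):
            cls = "target" if shot % 2 == 0 else "foil"
            correct = bool(rng.random() < p_correct)
            response = "old" if correct == (cls == "target") else "new"
            rows.append(
                {
                    "subject_id": subject_id,
                    "session_label": session_label,
                    "elapsed_days": float(idx),
                    "trial_index": idx,
                    "shot_id": f"shot{shot:05d}",
                    "stimulus_class": cls,
                    "presentation_mode": "full_shot",
                    "manipulation": "none",
                    "response": response,
                    "correct": correct,
                    "is_repeat": pres > 0,
                }
            )
            idx += 1
    return pd.DataFrame(rows)
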
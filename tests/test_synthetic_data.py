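"""Generator invariants: tiling, matching, schedules, response model."""

import itertools

import numpy as np
import pandas as pd
import pytest

import memovie
from memovie.config import GeneratorConfig
from memovie.errors import ConfigurationError
from memovie.synthetic_data import (
    build_trial_schedule,
    correctness_probabilities,
    generate_annotations,
    generate_shots,
    match_foils,
    response_probability,
    substreams,
)


def _rng(seed=0):
    return np.random.default_rng(seed)


# --------------------------------------------------------------------- #
# shots


def test_shots_tile_frame_axis_without_gaps():
    cfg = GeneratorConfig(n_shots_per_episode=100)
    shots = generate_shots(cfg, _rng(1))
    for ep in (1, 2):
        e = shots[shots["episode"] == ep].sort_values("start_frame")
        assert len(e) == 100
        assert e["start_frame"].iloc[0] == 0
        assert (e["start_frame"].iloc[1:].to_numpy()
                == e["end_frame"].iloc[:-1].to_numpy()).all()
        assert e["n_frames"].sum() == e["end_frame"].iloc[-1]
    assert shots["n_frames"].between(1, 90).all()
    assert (shots["n_frames"] == shots["end_frame"] - shots["start_frame"]).all()


def test_single_shot_spans_whole_episode():
    shots = generate_shots(GeneratorConfig(n_shots_per_episode=1), _rng(2))
    e1 = shots[shots["episode"] == 1]
    assert len(e1) == 1
    assert e1["start_frame"].iloc[0] == 0
    assert e1["end_frame"].iloc[0] == e1["n_frames"].iloc[0]


def test_shot_generation_deterministic_under_seed():
    cfg = GeneratorConfig(n_shots_per_episode=50, seed=5)
    a = generate_shots(cfg, substreams(cfg.seed)["shots"])
    b = generate_shots(cfg, substreams(cfg.seed)["shots"])
    pd.testing.assert_frame_equal(a, b)


# --------------------------------------------------------------------- #
# annotations


def test_annotation_inventory_and_counts():
    cfg = GeneratorConfig(n_shots_per_episode=30)
    shots = generate_shots(cfg, _rng(3))
    ann = generate_annotations(shots, cfg, _rng(4))
    assert len(ann) == len(shots)
    assert sum(c.startswith("char_") for c in ann.columns) == 29
    assert sum(c.startswith("sound_") and c != "sound_level"
               for c in ann.columns) == 13
    assert sum(c.startswith("emotion_") and c[8:].isdigit()
               for c in ann.columns) == 20
    assert sum(c.startswith("object_") for c in ann.columns) == 25
    chars = ann[[c for c in ann.columns if c.startswith("char_")]]
    objs = ann[[c for c in ann.columns if c.startswith("object_")]]
    assert (ann["n_characters_in_shot"] == chars.sum(axis=1)).all()
    assert (ann["n_objects_in_shot"] == objs.sum(axis=1)).all()
    assert (ann["n_frames"].to_numpy() == shots["n_frames"].to_numpy()).all()
    binary = chars.to_numpy()
    assert set(np.unique(binary)) <= {0, 1}


def test_forced_occurrence_probability_recovered():
    """A feature pinned at probability 0.3 occurs at ~0.3 over 1,000 shots
    (within 3 binomial SE)."""
    cfg = GeneratorConfig(n_shots_per_episode=500, feature_probs={"object_09": 0.3})
    shots = generate_shots(cfg, _rng(6))
    ann = generate_annotations(shots, cfg, _rng(7))
    freq = ann["object_09"].mean()
    se = np.sqrt(0.3 * 0.7 / len(ann))
    assert abs(freq - 0.3) < 3 * se


def test_viewpoint_requires_character_presence():
    cfg = GeneratorConfig(n_shots_per_episode=200)
    shots = generate_shots(cfg, _rng(8))
    ann = generate_annotations(shots, cfg, _rng(9))
    for i in range(1, 30):
        assert (ann[f"view_{i:02d}"] <= ann[f"char_{i:02d}"]).all()


# --------------------------------------------------------------------- #
# foil matching


def _mini_tables(char_bits, durations, episode):
    """Build shot+annotation frames from explicit character bitmasks."""
    shots = pd.DataFrame(
        {
            "shot_id": [f"e{episode}_s{i:02d}" for i in range(len(char_bits))],
            "episode": episode,
            "start_frame": 0,
            "end_frame": durations,
            "n_frames": durations,
            "matched_shot_id": "",
        }
    )
    ann = pd.DataFrame(char_bits, columns=[f"char_{j:02d}" for j in range(1, 4)])
    ann.insert(0, "shot_id", shots["shot_id"])
    return shots, ann


def test_unique_candidate_is_paired():
    t_shots, t_ann = _mini_tables([[1, 0, 0]], [10], 1)
    f_shots, f_ann = _mini_tables([[1, 0, 0]], [12], 2)
    pairs, report = match_foils(t_shots, f_shots, pd.concat([t_ann, f_ann]))
    assert len(pairs) == 1
    assert report.n_unmatched_targets == 0
    assert pairs["foil_id"].iloc[0] == "e2_s00"


def test_closest_content_match_preferred():
    """Target {A,B} pairs with the {A,B} foil, not the {A}-only foil."""
    t_shots, t_ann = _mini_tables([[1, 1, 0]], [10], 1)
    f_shots, f_ann = _mini_tables([[1, 1, 0], [1, 0, 0]], [10, 10], 2)
    pairs, _ = match_foils(t_shots, f_shots, pd.concat([t_ann, f_ann]))
    assert pairs["foil_id"].iloc[0] == "e2_s00"
    assert pairs["hamming"].iloc[0] == 0


def test_greedy_matching_against_exhaustive_oracle():
    """On <=6 items, greedy cost sits between the optimal assignment and
    the identity pairing, and the matching is a bijection."""
    rng = _rng(10)
    for trial in range(10):
        n = int(rng.integers(2, 7))
        tb = rng.integers(0, 2, size=(n, 3))
        fb = rng.integers(0, 2, size=(n, 3))
        td = rng.integers(1, 91, size=n)
        fd = rng.integers(1, 91, size=n)
        t_shots, t_ann = _mini_tables(tb.tolist(), td.tolist(), 1)
        f_shots, f_ann = _mini_tables(fb.tolist(), fd.tolist(), 2)
        pairs, _ = match_foils(t_shots, f_shots, pd.concat([t_ann, f_ann]))
        assert pairs["foil_id"].is_unique and pairs["target_id"].is_unique
        cost = {
            (i, j): int((tb[i] != fb[j]).sum())
            for i in range(n)
            for j in range(n)
        }
        idx = {sid: i for i, sid in enumerate(t_shots["shot_id"])}
        fdx = {sid: j for j, sid in enumerate(f_shots["shot_id"])}
        greedy_cost = sum(
            cost[(idx[t], fdx[f])]
            for t, f in zip(pairs["target_id"], pairs["foil_id"])
        )
        optimal = min(
            sum(cost[(i, p[i])] for i in range(n))
            for p in itertools.permutations(range(n))
        )
        identity = sum(cost[(i, i)] for i in range(n))
        assert optimal <= greedy_cost <= identity


def test_partial_matching_warns_when_foils_scarce():
    t_shots, t_ann = _mini_tables([[1, 0, 0], [0, 1, 0]], [5, 6], 1)
    f_shots, f_ann = _mini_tables([[1, 0, 0]], [5], 2)
    with pytest.warns(UserWarning, match="unmatched"):
        pairs, report = match_foils(t_shots, f_shots, pd.concat([t_ann, f_ann]))
    assert report.n_unmatched_targets == 1
    assert len(pairs) == 1


# --------------------------------------------------------------------- #
# schedule


def test_schedule_balance_days_and_repeats(default_dataset):
    trials = default_dataset.trials
    assert set(trials["session_label"]) == {0, 1, 7, 30, 90, 365}
    counts = trials.groupby(["subject_id", "session_label"])["stimulus_class"]
    for _, grp in counts:
        assert abs((grp == "target").sum() - (grp == "foil").sum()) <= 1
    # elapsed days consistent with each session's window
    for day, grp in trials.groupby("session_label"):
        lo, hi = GeneratorConfig().session_window(int(day))
        assert grp["elapsed_days"].between(lo, hi).all()
    # trial_index unique within subject x session
    assert not trials.duplicated(["subject_id", "session_label", "trial_index"]).any()


def test_repeat_count_is_three_percent():
    """1,000 scheduled queries at repeat_fraction 0.03 -> 30 repeats,
    split evenly between targets and foils, each after its original."""
    cfg = GeneratorConfig(n_subjects=1, n_shots_per_episode=500, seed=2)
    ds = memovie.generate_dataset(cfg)
    rep = ds.trials[ds.trials["is_repeat"]]
    assert len(rep) == 30
    assert (rep["stimulus_class"] == "target").sum() == 15
    order = ds.trials.sort_values(["session_label", "trial_index"]).reset_index()
    for _, r in rep.iterrows():
        same = order[(order["shot_id"] == r["shot_id"])]
        assert len(same) == 2
        assert not same["is_repeat"].iloc[0] and same["is_repeat"].iloc[1]


def test_excessive_repeat_fraction_rejected():
    cfg = GeneratorConfig(n_subjects=1, n_shots_per_episode=4,
                          repeat_fraction=0.9, session_days=(0, 1))
    pairs = pd.DataFrame(
        {"target_id": ["a", "b"], "foil_id": ["c", "d"]}
    )
    with pytest.raises(ConfigurationError, match="repeat_fraction"):
        build_trial_schedule(pairs, cfg, _rng(0))


# --------------------------------------------------------------------- #
# response model


def _one_trial(cfg, n_frames=1, elapsed=0.0, cls="target", mode="full_shot",
               manip="none"):
    vector = pd.Series({f: 0 for f in cfg.all_features})
    vector["n_frames"] = n_frames
    vector["shot_id"] = "x"
    trial = pd.Series(
        {
            "subject_id": "s001",
            "session_label": 0,
            "elapsed_days": elapsed,
            "trial_index": 0,
            "shot_id": "x",
            "stimulus_class": cls,
            "presentation_mode": mode,
            "manipulation": manip,
            "is_repeat": False,
        }
    )
    return vector, trial


def test_zero_logit_gives_half():
    cfg = GeneratorConfig(true_weights={}, base_logit=0.0, duration_weight=0.0,
                          retention_rate=0.0, feature_probs={})
    vector, trial = _one_trial(cfg)
    assert response_probability(vector, trial, 0.0, cfg) == pytest.approx(0.5)


def test_logistic_value_matches_closed_form():
    """beta.x = 1 with everything else zero -> p = 1/(1+e^-1) ~ 0.731."""
    cfg = GeneratorConfig(true_weights={"action": 1.0}, base_logit=0.0,
                          duration_weight=0.0, retention_rate=0.0, feature_probs={})
    vector, trial = _one_trial(cfg)
    vector["action"] = 1
    p = response_probability(vector, trial, 0.0, cfg)
    assert p == pytest.approx(1.0 / (1.0 + np.exp(-1.0)), abs=1e-12)


def test_retention_decay_monotone():
    cfg = GeneratorConfig(retention_rate=0.5, feature_probs={})
    vector, trial0 = _one_trial(cfg, elapsed=0.0)
    _, trial365 = _one_trial(cfg, elapsed=365.0)
    p0 = response_probability(vector, trial0, 0.0, cfg)
    p365 = response_probability(vector, trial365, 0.0, cfg)
    assert p365 < p0


def test_single_frame_uses_unit_duration():
    cfg = GeneratorConfig(true_weights={}, base_logit=0.0, duration_weight=1.0,
                          retention_rate=0.0, feature_probs={})
    vector, full = _one_trial(cfg, n_frames=90, mode="full_shot")
    _, single = _one_trial(cfg, n_frames=90, mode="single_frame")
    assert response_probability(vector, single, 0.0, cfg) == pytest.approx(0.5)
    assert response_probability(vector, full, 0.0, cfg) > 0.5


def test_unknown_manipulation_rejected():
    cfg = GeneratorConfig(feature_probs={})
    vector, trial = _one_trial(cfg)
    trial["manipulation"] = "teleport"
    with pytest.raises(ConfigurationError, match="manipulation"):
        response_probability(vector, trial, 0.0, cfg)


def test_simulated_accuracy_matches_forced_probability():
    """With all effects zeroed and base logit = log(4), every trial has
    p = 0.8; simulated accuracy lands within 3 binomial SE over ~10k trials."""
    cfg = GeneratorConfig(
        n_subjects=10, n_shots_per_episode=500, true_weights={},
        base_logit=float(np.log(4.0)), duration_weight=0.0, retention_rate=0.0,
        subject_ability_sd=0.0, feature_probs={}, seed=11,
    )
    ds = memovie.generate_dataset(cfg)
    n = len(ds.trials)
    assert n >= 10_000
    se = np.sqrt(0.8 * 0.2 / n)
    assert abs(ds.trials["correct"].mean() - 0.8) < 3 * se


def test_generative_calibration_by_probability_bin(default_dataset):
    """Binning trials by model probability, observed accuracy per bin is
    within 3 binomial SE of the bin's mean probability."""
    ds = default_dataset
    cfg = GeneratorConfig(**ds.truth["config"])
    abilities = pd.Series(ds.truth["abilities"])
    p = correctness_probabilities(ds.trials, ds.annotations, abilities, cfg)
    assert len(p) >= 10_000
    bins = np.quantile(p, np.linspace(0, 1, 11))
    idx = np.clip(np.searchsorted(bins, p, side="right") - 1, 0, 9)
    correct = ds.trials["correct"].to_numpy()
    for b in range(10):
        m = idx == b
        if m.sum() < 50:
            continue
        se = np.sqrt(p[m].mean() * (1 - p[m].mean()) / m.sum())
        assert abs(correct[m].mean() - p[m].mean()) < 3 * max(se, 1e-3)


def test_dataset_determinism_byte_identical():
    cfg = GeneratorConfig(n_subjects=3, n_shots_per_episode=60, seed=123)
    a = memovie.generate_dataset(cfg)
    b = memovie.generate_dataset(cfg)
    assert a.shots.to_csv() == b.shots.to_csv()
    assert a.annotations.to_csv() == b.annotations.to_csv()
    assert a.trials.to_csv() == b.trials.to_csv()
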
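"""Synthetic recognition-memory experiment generator.

Simulates the full data-generating process of a movie-shot old/new
recognition study with known ground truth:

* two episodes tiled into shots of 1-90 frames (log-uniform durations),
* a binary/count/continuous content-annotation vector per shot
  (characters and their viewpoints, sounds, emotions, objects, plus
  scalar flags and low-level audio-visual measures),
* one-to-one target/foil matching on character and viewpoint annotations
  with a duration tie-break,
* per-subject trial schedules over six nominal sessions with balanced
  target/foil queries, a small fraction of repeat queries, and
  per-config presentation modes and manipulations,
* responses drawn from a logistic correctness model that is additive in
  content, log duration, log elapsed time, subject ability, foil bias
  and manipulation condition.

All randomness flows from ``GeneratorConfig.seed`` through four named
substreams (shots, annotations, schedule, responses) so each stage can
be regenerated independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MAX_SHOT_FRAMES, GeneratorConfig
from .errors import ConfigurationError, DataIntegrityError

SHOT_COLUMNS = [
    "shot_id",
    "episode",
    "start_frame",
    "end_frame",
    "n_frames",
    "matched_shot_id",
]

TRIAL_COLUMNS = [
    "subject_id",
    "session_label",
    "elapsed_days",
    "trial_index",
    "shot_id",
    "stimulus_class",
    "presentation_mode",
    "manipulation",
    "response",
    "correct",
    "is_repeat",
]

_STREAMS = ("shots", "annotations", "schedule", "responses")


def substreams(seed: int) -> dict[str, np.random.Generator]:
    """Independent named random streams derived from one seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


# --------------------------------------------------------------------- #
# shots


def generate_shots(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Tile two episodes into shots with log-uniform durations in [1, 90].

    Consecutive shots within an episode tile the frame axis without gaps
    (0-based frames, half-open spans).  The ``matched_shot_id`` column is
    filled later by :func:`match_foils`.
    """
    rows = []
    for episode in (1, 2):
        u = rng.uniform(0.0, np.log(MAX_SHOT_FRAMES), size=cfg.n_shots_per_episode)
        n_frames = np.clip(np.round(np.exp(u)).astype(int), 1, MAX_SHOT_FRAMES)
        end = np.cumsum(n_frames)
        start = end - n_frames
        for i in range(cfg.n_shots_per_episode):
            rows.append(
                {
                    "shot_id": f"e{episode}_s{i + 1:04d}",
                    "episode": episode,
                    "start_frame": int(start[i]),
                    "end_frame": int(end[i]),
                    "n_frames": int(n_frames[i]),
                    "matched_shot_id": "",
                }
            )
    return pd.DataFrame(rows, columns=SHOT_COLUMNS)


# --------------------------------------------------------------------- #
# annotations


def resolve_feature_probs(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> dict[str, float]:
    """Per-feature occurrence probabilities for binary annotations.

    Probabilities are drawn from a right-skewed Beta(1.2, 3.5) so that a
    few features are common and most are rare, mimicking real content
    inventories; explicit values in ``cfg.feature_probs`` take precedence.
    Viewpoint bits are conditional on the character being present, so
    their entries are conditional probabilities.
    """
    cfg.validate_feature_refs()
    probs: dict[str, float] = {}
    for name in cfg.binary_features:
        if name in cfg.feature_probs:
            probs[name] = float(cfg.feature_probs[name])
        else:
            probs[name] = float(np.clip(rng.beta(1.2, 3.5), 0.02, 0.9))
    return probs


def generate_annotations(
    shots: pd.DataFrame,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    feature_probs: dict[str, float] | None = None,
) -> pd.DataFrame:
    """One content vector per shot.

    Binary features are independent Bernoulli draws at their per-feature
    occurrence probability, except viewpoint bits which require the
    matching character bit.  Count features are the number of set bits in
    their category; ``n_frames`` is copied from the shot; the low-level
    measures (contrast, color content, sound level) are uniform on [0, 1].
    """
    if shots.empty:
        raise ConfigurationError("generate_annotations: shots table is empty")
    if feature_probs is None:
        feature_probs = resolve_feature_probs(cfg, rng)
    n = len(shots)
    data: dict[str, np.ndarray] = {"shot_id": shots["shot_id"].to_numpy()}
    for name in cfg.flag_features:
        data[name] = (rng.random(n) < feature_probs[name]).astype(int)
    for char, view in zip(cfg.character_features, cfg.viewpoint_features):
        present = (rng.random(n) < feature_probs[char]).astype(int)
        data[char] = present
        data[view] = present * (rng.random(n) < feature_probs[view]).astype(int)
    for name in cfg.sound_features + cfg.emotion_features + cfg.object_features:
        data[name] = (rng.random(n) < feature_probs[name]).astype(int)

    char_mat = np.column_stack([data[c] for c in cfg.character_features])
    obj_mat = np.column_stack([data[c] for c in cfg.object_features])
    data["n_characters_in_shot"] = char_mat.sum(axis=1)
    data["n_objects_in_shot"] = obj_mat.sum(axis=1)
    data["n_frames"] = shots["n_frames"].to_numpy()
    data["contrast"] = rng.random(n)
    data["color_content"] = rng.random(n)
    data["sound_level"] = rng.random(n)
    return pd.DataFrame(data, columns=["shot_id"] + cfg.all_features)


# --------------------------------------------------------------------- #
# foil matching


@dataclass
class MatchReport:
    """Summary of a target/foil matching pass."""

    n_pairs: int
    n_unmatched_targets: int
    total_hamming: int
    mean_duration_target: float
    mean_duration_foil: float

    @property
    def mean_duration_difference(self) -> float:
        return self.mean_duration_target - self.mean_duration_foil


def match_foils(
    targets: pd.DataFrame,
    foils: pd.DataFrame,
    annotations: pd.DataFrame,
    match_columns: list[str] | None = None,
) -> tuple[pd.DataFrame, MatchReport]:
    """Greedy one-to-one target/foil matching on annotation bits.

    Pairs are accepted in order of increasing Hamming distance over the
    character-presence and viewpoint columns, ties broken by smallest
    absolute duration difference, then by target and foil shot id.  Each
    foil is used at most once; if there are fewer foils than targets the
    matching is partial and a warning reports the unmatched count.

    Returns a pair table (``target_id``, ``foil_id``, ``hamming``,
    ``duration_diff``) and a :class:`MatchReport`.
    """
    if targets.empty or foils.empty:
        raise ConfigurationError("match_foils: target and foil lists must be nonempty")
    ann = annotations.set_index("shot_id")
    if match_columns is None:
        match_columns = [
            c for c in ann.columns if c.startswith("char_") or c.startswith("view_")
        ]
    t_ids = targets["shot_id"].to_numpy()
    f_ids = foils["shot_id"].to_numpy()
    tb = ann.loc[t_ids, match_columns].to_numpy(dtype=int)
    fb = ann.loc[f_ids, match_columns].to_numpy(dtype=int)
    tn = targets["n_frames"].to_numpy()
    fn = foils["n_frames"].to_numpy()

    cost = (tb[:, None, :] != fb[None, :, :]).sum(axis=2)
    durdiff = np.abs(tn[:, None] - fn[None, :])
    ti = np.repeat(np.arange(len(t_ids)), len(f_ids))
    fi = np.tile(np.arange(len(f_ids)), len(t_ids))
    # lexsort: last key is primary
    order = np.lexsort((fi, ti, durdiff.ravel(), cost.ravel()))

    t_used = np.zeros(len(t_ids), dtype=bool)
    f_used = np.zeros(len(f_ids), dtype=bool)
    pairs = []
    n_left = min(len(t_ids), len(f_ids))
    for k in order:
        a, b = ti[k], fi[k]
        if t_used[a] or f_used[b]:
            continue
        t_used[a] = True
        f_used[b] = True
        pairs.append(
            {
                "target_id": t_ids[a],
                "foil_id": f_ids[b],
                "hamming": int(cost[a, b]),
                "duration_diff": int(durdiff[a, b]),
            }
        )
        if len(pairs) == n_left:
            break
    pairs_df = pd.DataFrame(pairs).sort_values("target_id").reset_index(drop=True)

    n_unmatched = len(t_ids) - len(pairs_df)
    if n_unmatched > 0:
        warnings.warn(
            f"match_foils: {n_unmatched} targets left unmatched "
            "(fewer foils than targets)",
            stacklevel=2,
        )
    matched_t = pairs_df["target_id"].to_numpy()
    matched_f = pairs_df["foil_id"].to_numpy()
    shots_n = pd.concat([targets, foils]).set_index("shot_id")["n_frames"]
    report = MatchReport(
        n_pairs=len(pairs_df),
        n_unmatched_targets=n_unmatched,
        total_hamming=int(pairs_df["hamming"].sum()),
        mean_duration_target=float(shots_n.loc[matched_t].mean()),
        mean_duration_foil=float(shots_n.loc[matched_f].mean()),
    )
    return pairs_df, report


def apply_matching(shots: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Write the matching into ``matched_shot_id`` (bijective on pairs)."""
    shots = shots.copy()
    lookup = {}
    for t, f in zip(pairs["target_id"], pairs["foil_id"]):
        lookup[t] = f
        lookup[f] = t
    shots["matched_shot_id"] = shots["shot_id"].map(lookup).fillna("")
    return shots


# --------------------------------------------------------------------- #
# trial schedule


def build_trial_schedule(
    pairs: pd.DataFrame, cfg: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-subject trial skeletons (no responses yet).

    Matched pairs are dealt across the configured sessions; each pair
    contributes one target and one foil query to its session, shuffled
    within the session so target/foil counts stay balanced.  A fraction
    ``repeat_fraction`` of queries is re-queried later in the experiment
    (whole pairs, so the repeat queries split evenly between targets and
    foils), flagged ``is_repeat``.  Presentation mode and manipulation
    are sampled per pair from the config.  Elapsed time is one uniform
    draw per (subject, session) inside that session's scheduling window.
    """
    if pairs.empty:
        raise ConfigurationError("build_trial_schedule: no matched pairs")
    n_pairs = len(pairs)
    n_sessions = len(cfg.session_days)
    n_base = 2 * n_pairs
    n_rep_pairs = int(round(cfg.repeat_fraction * n_base)) // 2
    manip_names = list(cfg.manipulation_probs.keys())
    manip_p = np.array([cfg.manipulation_probs[m] for m in manip_names], dtype=float)
    manip_p = manip_p / manip_p.sum()

    all_rows: list[dict] = []
    for s in range(cfg.n_subjects):
        subject_id = f"s{s + 1:03d}"
        elapsed = {
            day: float(rng.uniform(*cfg.session_window(day)))
            for day in cfg.session_days
        }
        order = rng.permutation(n_pairs)
        chunks = np.array_split(order, n_sessions)
        modes = np.where(
            rng.random(n_pairs) < cfg.single_frame_fraction, "single_frame", "full_shot"
        )
        manips = rng.choice(manip_names, size=n_pairs, p=manip_p)

        # per-session ordered lists of row dicts
        sessions: list[list[dict]] = []
        pair_session = np.empty(n_pairs, dtype=int)
        for si, chunk in enumerate(chunks):
            rows = []
            for pi in chunk:
                pair_session[pi] = si
                for cls, col in (("target", "target_id"), ("foil", "foil_id")):
                    rows.append(
                        {
                            "pair": int(pi),
                            "shot_id": pairs[col].iloc[pi],
                            "stimulus_class": cls,
                            "presentation_mode": modes[pi],
                            "manipulation": manips[pi],
                            "is_repeat": False,
                        }
                    )
            perm = rng.permutation(len(rows))
            sessions.append([rows[i] for i in perm])

        if n_rep_pairs > 0:
            # repeats go to a strictly later session; with a single
            # session they are re-inserted later in the same session
            if n_sessions > 1:
                eligible = np.flatnonzero(pair_session < n_sessions - 1)
            else:
                eligible = np.arange(n_pairs)
            if n_rep_pairs > len(eligible):
                raise ConfigurationError(
                    f"repeat_fraction too high: {n_rep_pairs} repeat pairs "
                    f"requested but only {len(eligible)} pairs can be "
                    "re-queried later"
                )
            rep_pairs = rng.choice(eligible, size=n_rep_pairs, replace=False)
            for pi in rep_pairs:
                si = int(pair_session[pi])
                if si < n_sessions - 1:
                    ti = int(rng.integers(si + 1, n_sessions))
                else:
                    ti = si
                for cls, col in (("target", "target_id"), ("foil", "foil_id")):
                    row = {
                        "pair": int(pi),
                        "shot_id": pairs[col].iloc[pi],
                        "stimulus_class": cls,
                        "presentation_mode": modes[pi],
                        "manipulation": manips[pi],
                        "is_repeat": True,
                    }
                    target_list = sessions[ti]
                    if ti > si:
                        pos = int(rng.integers(0, len(target_list) + 1))
                    else:
                        orig = next(
                            j
                            for j, r in enumerate(target_list)
                            if r["pair"] == pi
                            and r["stimulus_class"] == cls
                            and not r["is_repeat"]
                        )
                        pos = int(rng.integers(orig + 1, len(target_list) + 1))
                    target_list.insert(pos, row)

        for si, day in enumerate(cfg.session_days):
            for idx, row in enumerate(sessions[si]):
                all_rows.append(
                    {
                        "subject_id": subject_id,
                        "session_label": int(day),
                        "elapsed_days": elapsed[day],
                        "trial_index": idx,
                        "shot_id": row["shot_id"],
                        "stimulus_class": row["stimulus_class"],
                        "presentation_mode": row["presentation_mode"],
                        "manipulation": row["manipulation"],
                        "is_repeat": bool(row["is_repeat"]),
                    }
                )
    return pd.DataFrame(all_rows)


# --------------------------------------------------------------------- #
# responses


def _weight_vector(cfg: GeneratorConfig, columns: list[str]) -> np.ndarray:
    cfg.validate_feature_refs()
    return np.array([cfg.true_weights.get(c, 0.0) for c in columns])


def correctness_probabilities(
    schedule: pd.DataFrame, annotations: pd.DataFrame, abilities: pd.Series, cfg: GeneratorConfig
) -> np.ndarray:
    """Vectorised correctness probability for every scheduled trial.

    ``logit(p) = base + beta.x + gamma*log(n_frames) - delta*log(1+days)
    + ability + foil_bias*[foil] + manipulation_offset``; single-frame
    trials use ``n_frames = 1`` with the parent shot's content vector.
    ``p`` is clipped to ``[prob_floor, prob_ceiling]``.
    """
    ann = annotations.set_index("shot_id")
    missing = set(schedule["shot_id"]) - set(ann.index)
    if missing:
        raise DataIntegrityError(
            f"no annotation vector for shot(s): {sorted(missing)[:5]}"
        )
    feat_cols = [c for c in ann.columns if c != "n_frames"]
    beta = _weight_vector(cfg, feat_cols)
    x = ann.loc[schedule["shot_id"], feat_cols].to_numpy(dtype=float)
    n_frames = ann.loc[schedule["shot_id"], "n_frames"].to_numpy(dtype=float)
    n_frames = np.where(
        schedule["presentation_mode"].to_numpy() == "single_frame", 1.0, n_frames
    )
    try:
        manip = np.array(
            [cfg.manipulation_offsets[m] for m in schedule["manipulation"]]
        )
    except KeyError as exc:
        raise ConfigurationError(f"unknown manipulation condition: {exc}") from exc
    # n_frames can carry a true weight too (it is an annotation feature);
    # the duration term proper is gamma * log(n_frames).
    logit = (
        cfg.base_logit
        + x @ beta
        + cfg.true_weights.get("n_frames", 0.0) * n_frames
        + cfg.duration_weight * np.log(n_frames)
        - cfg.retention_rate * np.log1p(schedule["elapsed_days"].to_numpy(dtype=float))
        + abilities.loc[schedule["subject_id"]].to_numpy(dtype=float)
        + cfg.foil_bias * (schedule["stimulus_class"].to_numpy() == "foil")
        + manip
    )
    p = 1.0 / (1.0 + np.exp(-logit))
    return np.clip(p, cfg.prob_floor, cfg.prob_ceiling)


def response_probability(
    vector: pd.Series,
    trial: pd.Series,
    subject_ability: float,
    cfg: GeneratorConfig,
) -> float:
    """Scalar convenience wrapper around :func:`correctness_probabilities`."""
    schedule = pd.DataFrame([trial])
    ann = pd.DataFrame([vector])
    if "shot_id" not in ann.columns:
        ann.insert(0, "shot_id", trial["shot_id"])
    abilities = pd.Series({trial["subject_id"]: subject_ability})
    return float(correctness_probabilities(schedule, ann, abilities, cfg)[0])


def draw_abilities(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.Series:
    """Per-subject log-odds ability offsets ~ Normal(0, sigma_a)."""
    ids = [f"s{s + 1:03d}" for s in range(cfg.n_subjects)]
    return pd.Series(rng.normal(0.0, cfg.subject_ability_sd, cfg.n_subjects), index=ids)


def simulate_responses(
    schedule: pd.DataFrame,
    annotations: pd.DataFrame,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    abilities: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw correctness per trial and derive the old/new response.

    Each trial's correctness is an independent Bernoulli draw at its
    model probability; the response is "old" iff (correct and target) or
    (incorrect and foil).  Returns the completed trial table and the
    per-subject abilities used (the ground truth for recovery tests).
    """
    if abilities is None:
        abilities = draw_abilities(cfg, rng)
    p = correctness_probabilities(schedule, annotations, abilities, cfg)
    correct = rng.random(len(schedule)) < p
    is_target = schedule["stimulus_class"].to_numpy() == "target"
    response = np.where(correct == is_target, "old", "new")
    trials = schedule.copy()
    trials["response"] = response
    trials["correct"] = correct.astype(bool)
    return trials[TRIAL_COLUMNS], abilities


# --------------------------------------------------------------------- #
# one-call generator


@dataclass
class SyntheticDataset:
    """A complete simulated experiment with its ground truth."""

    shots: pd.DataFrame
    annotations: pd.DataFrame
    trials: pd.DataFrame
    pairs: pd.DataFrame
    truth: dict = field(default_factory=dict)


def generate_dataset(cfg: GeneratorConfig) -> SyntheticDataset:
    """Run the full generative pipeline from one seed.

    Identical configs (including seed) produce byte-identical tables.
    """
    cfg.validate_feature_refs()
    streams = substreams(cfg.seed)
    shots = generate_shots(cfg, streams["shots"])
    feature_probs = resolve_feature_probs(cfg, streams["annotations"])
    annotations = generate_annotations(
        shots, cfg, streams["annotations"], feature_probs
    )
    targets = shots[shots["episode"] == 1]
    foils = shots[shots["episode"] == 2]
    pairs, match_report = match_foils(targets, foils, annotations)
    shots = apply_matching(shots, pairs)
    schedule = build_trial_schedule(pairs, cfg, streams["schedule"])
    trials, abilities = simulate_responses(
        schedule, annotations, cfg, streams["responses"]
    )
    truth = {
        "config": cfg.model_dump(),
        "abilities": {k: float(v) for k, v in abilities.items()},
        "feature_probs": feature_probs,
        "match_report": {
            "n_pairs": match_report.n_pairs,
            "n_unmatched_targets": match_report.n_unmatched_targets,
            "total_hamming": match_report.total_hamming,
            "mean_duration_target": match_report.mean_duration_target,
            "mean_duration_foil": match_report.mean_duration_foil,
        },
    }
    return SyntheticDataset(
        shots=shots, annotations=annotations, trials=trials, pairs=pairs, truth=truth
    )
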
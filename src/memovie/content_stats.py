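"""Per-property content effects on recognition performance.

For each binary content property, accuracy on shots containing the
property is compared against accuracy on shots without it.  Accuracies
are computed per subject and averaged across subjects (subjects are the
replication unit); the two-sided permutation null shuffles the property
assignment across *shots*, which keeps the per-shot difficulty structure
intact and anchors the test even when shots vary widely in difficulty.
Count/continuous properties are compared between correct and incorrect
trials with the same shot-shuffling null.  Bonferroni correction is
applied over the batch of properties.  Only properties appearing in at
least 10 shots are analysed, and no side is reported from fewer than 20
trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .metrics import MIN_TRIALS_PER_CELL

#: A binary property must occur in at least this many shots.
MIN_SHOTS_WITH_PROPERTY = 10

#: Significance level for the adjusted flag (double-star convention).
DEFAULT_ALPHA = 0.01


@dataclass
class PropertyEffect:
    property: str
    pc_present: float | None
    pc_absent: float | None
    n_shots_present: int
    n_shots_absent: int
    p_raw: float | None
    p_adjusted: float | None
    significant: bool | None
    suppressed: bool = False
    reason: str | None = None

    def as_row(self) -> dict:
        return {
            "property": self.property,
            "pc_present": self.pc_present,
            "pc_absent": self.pc_absent,
            "n_shots_present": self.n_shots_present,
            "n_shots_absent": self.n_shots_absent,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "significant": self.significant,
            "suppressed": self.suppressed,
            "reason": self.reason or "",
        }


def _subject_shot_matrices(
    trials: pd.DataFrame, shot_ids: np.ndarray, targets_only: bool
) -> tuple[np.ndarray, np.ndarray]:
    """(correct-count, trial-count) matrices, subjects x shots."""
    t = trials[trials["stimulus_class"] == "target"] if targets_only else trials
    shot_pos = {s: i for i, s in enumerate(shot_ids)}
    sub = t[t["shot_id"].isin(shot_pos)]
    subjects = sorted(sub["subject_id"].unique())
    subj_pos = {s: i for i, s in enumerate(subjects)}
    C = np.zeros((len(subjects), len(shot_ids)))
    N = np.zeros_like(C)
    si = sub["subject_id"].map(subj_pos).to_numpy()
    ki = sub["shot_id"].map(shot_pos).to_numpy()
    np.add.at(N, (si, ki), 1.0)
    np.add.at(C, (si, ki), sub["correct"].to_numpy(dtype=float))
    return C, N


def _mean_subject_difference(
    C: np.ndarray, N: np.ndarray, v: np.ndarray
) -> tuple[float, float, float]:
    """Per-subject (pc | v=1) and (pc | v=0), averaged across subjects."""
    with np.errstate(invalid="ignore", divide="ignore"):
        pres = (C @ v) / (N @ v)
        absn = (C @ (1 - v)) / (N @ (1 - v))
    return (
        float(np.nanmean(pres)),
        float(np.nanmean(absn)),
        float(np.nanmean(pres - absn)),
    )


def property_effect(
    trials: pd.DataFrame,
    vectors: pd.DataFrame,
    prop: str,
    n_perm: int = 1_000,
    m_comparisons: int = 1,
    alpha: float = DEFAULT_ALPHA,
    rng: np.random.Generator | None = None,
    targets_only: bool = False,
) -> PropertyEffect:
    """Accuracy with vs without one binary content property.

    The statistic is the across-subject mean of (per-subject accuracy on
    property-present shots minus property-absent shots); the null
    permutes the property values across shots.  Trials use the presented
    shot's own annotations; target and foil trials are pooled unless
    ``targets_only``.
    """
    if n_perm < 100:
        raise ConfigurationError(f"property_effect: n_perm must be >= 100, got {n_perm}")
    rng = np.random.default_rng() if rng is None else rng
    values = vectors.set_index("shot_id")[prop]
    n_present = int((values == 1).sum())
    n_absent = int((values == 0).sum())
    if n_present < MIN_SHOTS_WITH_PROPERTY:
        return PropertyEffect(prop, None, None, n_present, n_absent, None, None,
                              None, suppressed=True, reason="too_few_shots")
    shot_ids = values.index.to_numpy()
    v = values.to_numpy(dtype=float)
    C, N = _subject_shot_matrices(trials, shot_ids, targets_only)
    trials_present = int(N[:, v == 1].sum())
    trials_absent = int(N[:, v == 0].sum())
    if trials_present < MIN_TRIALS_PER_CELL or trials_absent < MIN_TRIALS_PER_CELL:
        return PropertyEffect(prop, None, None, n_present, n_absent, None, None,
                              None, suppressed=True, reason="too_few_trials")
    pc_present, pc_absent, observed = _mean_subject_difference(C, N, v)
    count = 0
    for _ in range(n_perm):
        _, _, stat = _mean_subject_difference(C, N, rng.permutation(v))
        if abs(stat) >= abs(observed) - 1e-12:
            count += 1
    p_raw = (1 + count) / (n_perm + 1)
    p_adj = min(1.0, m_comparisons * p_raw)
    return PropertyEffect(
        property=prop,
        pc_present=pc_present,
        pc_absent=pc_absent,
        n_shots_present=n_present,
        n_shots_absent=n_absent,
        p_raw=float(p_raw),
        p_adjusted=float(p_adj),
        significant=bool(p_adj < alpha),
    )


def continuous_effect(
    trials: pd.DataFrame,
    vectors: pd.DataFrame,
    prop: str,
    n_perm: int = 1_000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Mean of a count/continuous property on correct vs incorrect trials.

    Two-sided permutation p on the mean difference, permuting the
    property values across shots.
    """
    rng = np.random.default_rng() if rng is None else rng
    values = vectors.set_index("shot_id")[prop]
    shot_pos = {s: i for i, s in enumerate(values.index)}
    ki = trials["shot_id"].map(shot_pos).to_numpy()
    correct = trials["correct"].to_numpy(dtype=bool)
    n_c, n_i = int(correct.sum()), int((~correct).sum())
    if n_c < MIN_TRIALS_PER_CELL or n_i < MIN_TRIALS_PER_CELL:
        return {"property": prop, "suppressed": True, "reason": "too_few_trials"}
    # trial counts per shot on each side; the statistic is linear in v
    K = len(values)
    a = np.bincount(ki[correct], minlength=K) / n_c
    b = np.bincount(ki[~correct], minlength=K) / n_i
    v = values.to_numpy(dtype=float)
    mean_c = float(a @ v)
    mean_i = float(b @ v)
    observed = mean_c - mean_i
    if np.allclose(v, v[0]):
        return {
            "property": prop, "mean_correct": mean_c, "mean_incorrect": mean_i,
            "difference": 0.0, "p_raw": 1.0, "suppressed": False, "reason": "",
        }
    diff_w = a - b
    count = 0
    for _ in range(n_perm):
        if abs(diff_w @ rng.permutation(v)) >= abs(observed) - 1e-12:
            count += 1
    return {
        "property": prop,
        "mean_correct": mean_c,
        "mean_incorrect": mean_i,
        "difference": float(observed),
        "p_raw": float((1 + count) / (n_perm + 1)),
        "suppressed": False,
        "reason": "",
    }


def effect_table(
    trials: pd.DataFrame,
    vectors: pd.DataFrame,
    properties: list[str],
    n_perm: int = 1_000,
    alpha: float = DEFAULT_ALPHA,
    rng: np.random.Generator | None = None,
    targets_only: bool = False,
) -> pd.DataFrame:
    """Batch property effects with a joint Bonferroni correction.

    ``m`` equals the number of eligible (non-suppressed) properties;
    suppressed properties keep their row with the suppression reason.
    Rows are sorted by adjusted p, suppressed rows last.
    """
    if not properties:
        raise ValueError("effect_table: properties list is empty")
    values = vectors.set_index("shot_id")
    eligible = [
        p for p in properties
        if int((values[p] == 1).sum()) >= MIN_SHOTS_WITH_PROPERTY
    ]
    m = max(1, len(eligible))
    effects = [
        property_effect(trials, vectors, p, n_perm=n_perm, m_comparisons=m,
                        alpha=alpha, rng=rng, targets_only=targets_only)
        for p in properties
    ]
    table = pd.DataFrame([e.as_row() for e in effects])
    return table.sort_values(
        ["suppressed", "p_adjusted"], na_position="last"
    ).reset_index(drop=True)
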
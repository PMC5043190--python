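"""Within- and between-subject response consistency.

Repeat queries of the same shot let us ask whether errors are random or
reproducible.  Under the null hypothesis that a subject with accuracy
``p`` responds independently on each presentation, the expected fractions
of repeat pairs are ``p^2`` (both correct), ``(1-p)^2`` (both wrong) and
``2p(1-p)`` (inconsistent); for two subjects with accuracies ``p_i`` and
``p_j`` the corresponding triple is ``p_i p_j``, ``(1-p_i)(1-p_j)`` and
``p_i(1-p_j) + p_j(1-p_i)``.  Observed triples are compared against these
independence nulls with a Monte-Carlo two-sided test on the inconsistent
fraction (the number of inconsistent pairs among n independent pairs is
binomial, so the null draws are binomial).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: Fewer comparisons than this and the cell is suppressed.
MIN_COMPARISONS = 20

#: Monte-Carlo draws for null p-values.
DEFAULT_NULL_DRAWS = 10_000


@dataclass
class ConsistencyReport:
    """Observed vs expected-under-independence agreement fractions."""

    unit: str  # "self" | "pair" | "vs_mode"
    subject_id: str
    partner_id: str | None
    observed: tuple[float, float, float] | None  # (both correct, both wrong, inconsistent)
    expected_null: tuple[float, float, float] | None
    n_comparisons: int
    p_value: float | None
    suppressed: bool = False
    reason: str | None = None

    def as_row(self) -> dict:
        obs = self.observed or (None, None, None)
        exp = self.expected_null or (None, None, None)
        return {
            "unit": self.unit,
            "subject_id": self.subject_id,
            "partner_id": self.partner_id or "",
            "obs_both_correct": obs[0],
            "obs_both_wrong": obs[1],
            "obs_inconsistent": obs[2],
            "exp_both_correct": exp[0],
            "exp_both_wrong": exp[1],
            "exp_inconsistent": exp[2],
            "n_comparisons": self.n_comparisons,
            "p_value": self.p_value,
            "suppressed": self.suppressed,
            "reason": self.reason or "",
        }


def independence_null(p_i: float, p_j: float | None = None) -> tuple[float, float, float]:
    """Expected (both correct, both wrong, inconsistent) under independence.

    One accuracy gives the self-consistency null ``(p^2, (1-p)^2,
    2p(1-p))``; two give the pairwise null ``(p_i p_j, (1-p_i)(1-p_j),
    p_i(1-p_j) + p_j(1-p_i))``.
    """
    for p in (p_i,) if p_j is None else (p_i, p_j):
        if not (0.0 <= p <= 1.0):
            raise ConfigurationError(f"accuracy must lie in [0, 1], got {p}")
    if p_j is None:
        p_j = p_i
    return (
        p_i * p_j,
        (1.0 - p_i) * (1.0 - p_j),
        p_i * (1.0 - p_j) + p_j * (1.0 - p_i),
    )


def _null_p_value(
    n_inconsistent: int,
    n_pairs: int,
    q_null: float,
    rng: np.random.Generator,
    n_draws: int = DEFAULT_NULL_DRAWS,
) -> float:
    """Two-sided Monte-Carlo p for the observed inconsistent count.

    Under independence the inconsistent count is Binomial(n, q_null);
    draws are compared to the observation on both tails with the add-one
    estimator.
    """
    draws = rng.binomial(n_pairs, q_null, size=n_draws)
    p_low = (1 + int(np.sum(draws <= n_inconsistent))) / (n_draws + 1)
    p_high = (1 + int(np.sum(draws >= n_inconsistent))) / (n_draws + 1)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def _triple_from_outcomes(first: np.ndarray, second: np.ndarray) -> tuple[float, float, float]:
    n = len(first)
    both_c = float(np.mean(first & second))
    both_w = float(np.mean(~first & ~second))
    incons = float(np.mean(first != second))
    assert abs(both_c + both_w + incons - 1.0) < 1e-12 or n == 0
    return both_c, both_w, incons


def _first_presentations(trials: pd.DataFrame) -> pd.DataFrame:
    """One row per (subject, shot): the chronologically first query."""
    order = trials.sort_values(["elapsed_days", "trial_index"])
    return order.drop_duplicates(["subject_id", "shot_id"], keep="first")


def repeat_pairs(trials: pd.DataFrame, subject_id: str) -> pd.DataFrame:
    """First/second presentation correctness per repeated shot.

    Returns one row per (subject, shot) queried at least twice, with
    boolean columns ``first`` and ``second``.
    """
    sub = trials[trials["subject_id"] == subject_id].sort_values(
        ["elapsed_days", "trial_index"]
    )
    rows = []
    for shot, grp in sub.groupby("shot_id", sort=True):
        if len(grp) < 2:
            continue
        c = grp["correct"].to_numpy(dtype=bool)
        rows.append({"shot_id": shot, "first": bool(c[0]), "second": bool(c[1])})
    return pd.DataFrame(rows, columns=["shot_id", "first", "second"])


def self_consistency(
    trials: pd.DataFrame,
    subject_id: str,
    rng: np.random.Generator | None = None,
    n_draws: int = DEFAULT_NULL_DRAWS,
    min_pairs: int = MIN_COMPARISONS,
) -> ConsistencyReport:
    """Agreement of a subject's correctness across repeat presentations."""
    rng = np.random.default_rng() if rng is None else rng
    pairs = repeat_pairs(trials, subject_id)
    if len(pairs) < min_pairs:
        return ConsistencyReport(
            "self", subject_id, None, None, None, len(pairs),
            None, suppressed=True, reason="too_few_repeat_pairs",
        )
    sub = trials[trials["subject_id"] == subject_id]
    p_subj = float(sub["correct"].mean())
    observed = _triple_from_outcomes(
        pairs["first"].to_numpy(), pairs["second"].to_numpy()
    )
    expected = independence_null(p_subj)
    n_inc = int(round(observed[2] * len(pairs)))
    p = _null_p_value(n_inc, len(pairs), expected[2], rng, n_draws)
    return ConsistencyReport("self", subject_id, None, observed, expected, len(pairs), p)


def pairwise_consistency(
    trials: pd.DataFrame,
    subject_i: str,
    subject_j: str,
    rng: np.random.Generator | None = None,
    n_draws: int = DEFAULT_NULL_DRAWS,
    min_shots: int = MIN_COMPARISONS,
) -> ConsistencyReport:
    """Between-subject agreement over shots both subjects were queried on.

    Shots count as shared only when both subjects saw them under the same
    presentation condition (mode and manipulation); each subject
    contributes the correctness of their first presentation.
    """
    rng = np.random.default_rng() if rng is None else rng
    firsts = _first_presentations(trials)
    cond = ["shot_id", "presentation_mode", "manipulation"]
    fi = firsts[firsts["subject_id"] == subject_i][cond + ["correct"]]
    fj = firsts[firsts["subject_id"] == subject_j][cond + ["correct"]]
    merged = fi.merge(fj, on=cond, suffixes=("_i", "_j"))
    if len(merged) < min_shots:
        return ConsistencyReport(
            "pair", subject_i, subject_j, None, None, len(merged),
            None, suppressed=True, reason="insufficient_overlap",
        )
    p_i = float(trials.loc[trials["subject_id"] == subject_i, "correct"].mean())
    p_j = float(trials.loc[trials["subject_id"] == subject_j, "correct"].mean())
    observed = _triple_from_outcomes(
        merged["correct_i"].to_numpy(dtype=bool), merged["correct_j"].to_numpy(dtype=bool)
    )
    expected = independence_null(p_i, p_j)
    n_inc = int(round(observed[2] * len(merged)))
    p = _null_p_value(n_inc, len(merged), expected[2], rng, n_draws)
    return ConsistencyReport(
        "pair", subject_i, subject_j, observed, expected, len(merged), p
    )


def mode_labels(
    trials: pd.DataFrame, exclude_subject: str | None = None, min_voters: int = 3
) -> pd.Series:
    """Per-shot majority correctness across subjects (ties dropped).

    Each subject votes with the correctness of their first presentation
    of the shot; shots with fewer than ``min_voters`` voters or with a
    tied vote are absent from the result.
    """
    firsts = _first_presentations(trials)
    if exclude_subject is not None:
        firsts = firsts[firsts["subject_id"] != exclude_subject]
    votes = firsts.groupby("shot_id")["correct"].agg(["sum", "count"])
    votes = votes[votes["count"] >= min_voters]
    untied = votes[votes["sum"] * 2 != votes["count"]]
    return (untied["sum"] * 2 > untied["count"]).rename("mode_correct")


def mode_consistency(
    trials: pd.DataFrame,
    subject_id: str,
    rng: np.random.Generator | None = None,
    n_draws: int = DEFAULT_NULL_DRAWS,
    min_shots: int = MIN_COMPARISONS,
) -> ConsistencyReport:
    """Agreement between a subject and the majority of all other subjects.

    The null treats the subject and the mode as independent responders
    with accuracies ``p_subject`` and ``p_mode`` (the empirical accuracy
    of the majority vote).
    """
    rng = np.random.default_rng() if rng is None else rng
    mode = mode_labels(trials, exclude_subject=subject_id)
    own = _first_presentations(trials[trials["subject_id"] == subject_id])
    own = own.set_index("shot_id")["correct"]
    shared = mode.index.intersection(own.index)
    if len(shared) < min_shots:
        return ConsistencyReport(
            "vs_mode", subject_id, "mode", None, None, len(shared),
            None, suppressed=True, reason="insufficient_overlap",
        )
    subj = own.loc[shared].to_numpy(dtype=bool)
    md = mode.loc[shared].to_numpy(dtype=bool)
    p_subj = float(trials.loc[trials["subject_id"] == subject_id, "correct"].mean())
    p_mode = float(md.mean())
    observed = _triple_from_outcomes(subj, md)
    expected = independence_null(p_subj, p_mode)
    n_inc = int(round(observed[2] * len(shared)))
    p = _null_p_value(n_inc, len(shared), expected[2], rng, n_draws)
    return ConsistencyReport(
        "vs_mode", subject_id, "mode", observed, expected, len(shared), p
    )


def consistency_table(
    trials: pd.DataFrame,
    rng: np.random.Generator | None = None,
    n_draws: int = DEFAULT_NULL_DRAWS,
    max_pairs: int | None = None,
) -> pd.DataFrame:
    """All self, pairwise and vs-mode consistency rows for a trial table.

    ``max_pairs`` caps the number of subject pairs (taken in sorted
    order) to keep large cohorts tractable.
    """
    rng = np.random.default_rng() if rng is None else rng
    subjects = sorted(trials["subject_id"].unique())
    rows = [self_consistency(trials, s, rng, n_draws).as_row() for s in subjects]
    rows += [mode_consistency(trials, s, rng, n_draws).as_row() for s in subjects]
    pairs = [(a, b) for i, a in enumerate(subjects) for b in subjects[i + 1:]]
    if max_pairs is not None:
        pairs = pairs[:max_pairs]
    rows += [pairwise_consistency(trials, a, b, rng, n_draws).as_row() for a, b in pairs]
    return pd.DataFrame(rows)
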
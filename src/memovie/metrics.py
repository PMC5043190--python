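"""Performance summaries for the old/new recognition task.

Percent correct, hit and false-alarm rates, d' sensitivity, shot-duration
and retention curves, trial/subject exclusion rules, and the two-sided
nonparametric permutation test (with Bonferroni correction) used for all
group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

#: No proportion is reported from fewer trials than this.
MIN_TRIALS_PER_CELL = 20

#: Subject-level exclusion thresholds.
MIN_SUBJECT_TRIALS = 400
MAX_YES_RATE = 0.75
MIN_OVERALL_PC = 0.60

#: Warm-up trials dropped at the start of every session.
WARMUP_TRIALS = 5


# --------------------------------------------------------------------- #
# exclusions


@dataclass
class ExclusionReport:
    """What was removed and by which rule."""

    n_trials_in: int = 0
    n_trials_out: int = 0
    n_warmup_removed: int = 0
    excluded_subjects: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_trials_in": self.n_trials_in,
            "n_trials_out": self.n_trials_out,
            "n_warmup_removed": self.n_warmup_removed,
            "excluded_subjects": self.excluded_subjects,
        }


def apply_exclusions(trials: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Standard trial and subject exclusions.

    Removes the first 5 trials of every (subject, session) to avoid
    non-stationarities while subjects adapt to the test, then drops
    subjects with fewer than 400 remaining trials, with a response bias
    above 75% "old" answers, or with overall accuracy below 60%.
    """
    report = ExclusionReport(n_trials_in=len(trials))
    if trials.empty:
        return trials.copy(), report

    keep = (
        trials.sort_values(["subject_id", "session_label", "trial_index"])
        .groupby(["subject_id", "session_label"])
        .cumcount()
        >= WARMUP_TRIALS
    )
    retained = trials.loc[keep.reindex(trials.index)].copy()
    report.n_warmup_removed = len(trials) - len(retained)

    for subject, sub in retained.groupby("subject_id"):
        n = len(sub)
        yes_rate = float((sub["response"] == "old").mean())
        pc = float(sub["correct"].mean())
        rule = None
        if n < MIN_SUBJECT_TRIALS:
            rule = "min_trials"
        elif yes_rate > MAX_YES_RATE:
            rule = "response_bias"
        elif pc < MIN_OVERALL_PC:
            rule = "low_performance"
        if rule is not None:
            report.excluded_subjects.append(
                {"subject_id": subject, "rule": rule, "n_trials": n,
                 "yes_rate": yes_rate, "pc": pc}
            )
    bad = {e["subject_id"] for e in report.excluded_subjects}
    retained = retained[~retained["subject_id"].isin(bad)].reset_index(drop=True)
    report.n_trials_out = len(retained)
    return retained, report


# --------------------------------------------------------------------- #
# per-subject performance


@dataclass
class SubjectPerformance:
    subject_id: str
    n_trials: int
    pc: float | None
    p_hit: float | None
    p_fa: float | None
    d_prime: float | None
    yes_rate: float | None
    suppressed: bool = False

    def as_row(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "n_trials": self.n_trials,
            "pc": self.pc,
            "p_hit": self.p_hit,
            "p_fa": self.p_fa,
            "d_prime": self.d_prime,
            "yes_rate": self.yes_rate,
            "suppressed": self.suppressed,
        }


def dprime(p_hit: float, p_fa: float, n_targets: int, n_foils: int) -> float:
    """Signal-detection sensitivity d' = z(p_hit) - z(p_fa).

    Rates are clipped to [1/(2N), 1 - 1/(2N)] for the relevant trial
    count before applying the standard-normal quantile, the usual
    correction for degenerate rates in finite samples.
    """
    if n_targets <= 0 or n_foils <= 0:
        raise ConfigurationError("dprime: trial counts must be positive")
    ph = float(np.clip(p_hit, 1.0 / (2 * n_targets), 1.0 - 1.0 / (2 * n_targets)))
    pf = float(np.clip(p_fa, 1.0 / (2 * n_foils), 1.0 - 1.0 / (2 * n_foils)))
    return float(stats.norm.ppf(ph) - stats.norm.ppf(pf))


def compute_performance(
    trials: pd.DataFrame,
    where: Callable[[pd.DataFrame], pd.Series] | pd.Series | None = None,
    min_trials: int = MIN_TRIALS_PER_CELL,
) -> tuple[pd.DataFrame, dict]:
    """Per-subject performance plus a pooled mean +/- SD summary.

    ``pc`` pools target and foil trials; ``p_hit`` is the fraction of
    "old" responses on targets and ``p_fa`` the fraction of "old"
    responses on foils.  Cells with fewer than ``min_trials`` trials are
    suppressed (flagged, never reported as numbers).  ``where`` is an
    optional trial predicate (callable or boolean mask).
    """
    if where is not None:
        mask = where(trials) if callable(where) else where
        trials = trials.loc[mask]
    rows = []
    for subject, sub in trials.groupby("subject_id"):
        n = len(sub)
        if n < min_trials:
            rows.append(SubjectPerformance(subject, n, None, None, None, None, None,
                                           suppressed=True))
            continue
        tgt = sub[sub["stimulus_class"] == "target"]
        foil = sub[sub["stimulus_class"] == "foil"]
        pc = float(sub["correct"].mean())
        yes_rate = float((sub["response"] == "old").mean())
        p_hit = float((tgt["response"] == "old").mean()) if len(tgt) else None
        p_fa = float((foil["response"] == "old").mean()) if len(foil) else None
        d = (
            dprime(p_hit, p_fa, len(tgt), len(foil))
            if len(tgt) and len(foil)
            else None
        )
        rows.append(SubjectPerformance(subject, n, pc, p_hit, p_fa, d, yes_rate))
    perf = pd.DataFrame([r.as_row() for r in rows])
    reported = perf[~perf["suppressed"]] if len(perf) else perf
    pooled = {
        "n_subjects": int(len(reported)),
        "pc_mean": float(reported["pc"].mean()) if len(reported) else None,
        "pc_sd": float(reported["pc"].std(ddof=1)) if len(reported) > 1 else None,
        "d_prime_mean": float(reported["d_prime"].mean()) if len(reported) else None,
    }
    return perf, pooled


# --------------------------------------------------------------------- #
# curves


@dataclass
class PerformanceCurve:
    """Accuracy binned along duration or retention interval."""

    bin_labels: list
    pc_per_bin: list[float]
    n_per_bin: list[int]
    r: float | None
    p_value: float | None
    constant: bool = False  # pc identical in all bins; r reported as 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin": self.bin_labels, "pc": self.pc_per_bin, "n": self.n_per_bin}
        )


def _curve_correlation(x: np.ndarray, pc: np.ndarray) -> tuple[float | None, float | None, bool]:
    if len(x) < 3:
        return None, None, False
    if np.allclose(pc, pc[0]):
        return 0.0, None, True
    r, p = stats.pearsonr(x, pc)
    return float(r), float(p), False


def duration_curve(
    trials: pd.DataFrame,
    shots: pd.DataFrame,
    bin_frames: int = 30,
    min_trials: int = MIN_TRIALS_PER_CELL,
) -> PerformanceCurve:
    """Accuracy versus shot duration for full-shot trials.

    Durations are binned into [1, bin_frames], [bin_frames+1, ...] bins;
    bin centers are reported.  Pearson r is computed between bin center
    and accuracy over retained bins (those with >= 20 trials).
    """
    full = trials[trials["presentation_mode"] == "full_shot"]
    n_frames = shots.set_index("shot_id")["n_frames"]
    dur = n_frames.loc[full["shot_id"]].to_numpy()
    bin_idx = (dur - 1) // bin_frames
    df = pd.DataFrame({"bin": bin_idx, "correct": full["correct"].to_numpy()})
    centers, pcs, ns = [], [], []
    for b, grp in df.groupby("bin"):
        if len(grp) < min_trials:
            continue
        lo = b * bin_frames + 1
        hi = (b + 1) * bin_frames
        centers.append((lo + hi) / 2.0)
        pcs.append(float(grp["correct"].mean()))
        ns.append(int(len(grp)))
    r, p, const = _curve_correlation(np.asarray(centers), np.asarray(pcs))
    return PerformanceCurve(centers, pcs, ns, r, p, const)


def retention_curve(
    trials: pd.DataFrame,
    mode: str = "full_shot",
    min_trials: int = MIN_TRIALS_PER_CELL,
) -> PerformanceCurve:
    """Accuracy versus nominal session day for one presentation mode.

    The correlation is computed against the session's ordinal rank
    (equidistant x), since the session spacing is strongly non-linear in
    time; the day labels are kept as bin labels.
    """
    sub = trials[trials["presentation_mode"] == mode]
    labels, pcs, ns = [], [], []
    for day in sorted(sub["session_label"].unique()):
        grp = sub[sub["session_label"] == day]
        if len(grp) < min_trials:
            continue
        labels.append(int(day))
        pcs.append(float(grp["correct"].mean()))
        ns.append(int(len(grp)))
    ranks = np.arange(len(labels), dtype=float)
    r, p, const = _curve_correlation(ranks, np.asarray(pcs))
    return PerformanceCurve(labels, pcs, ns, r, p, const)


# --------------------------------------------------------------------- #
# permutation test


def permutation_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_perm: int = 10_000,
    m_comparisons: int = 1,
    rng: np.random.Generator | None = None,
) -> dict:
    """Two-sided nonparametric permutation test with Bonferroni correction.

    The statistic is the difference in group means; group labels are
    permuted ``n_perm`` times and the two-sided p-value uses the add-one
    estimator ``(1 + #{|perm| >= |obs|}) / (n_perm + 1)`` so it can never
    be exactly zero.  The adjusted p is ``min(1, m * p)``.
    """
    if n_perm < 100:
        raise ConfigurationError(f"permutation_test: n_perm must be >= 100, got {n_perm}")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ConfigurationError("permutation_test: both groups must be nonempty")
    rng = np.random.default_rng() if rng is None else rng
    observed = a.mean() - b.mean()
    pool = np.concatenate([a, b])
    na = a.size
    # chunked vectorised permutation to bound memory
    count = 0
    chunk = max(1, min(n_perm, int(2e7 // max(pool.size, 1))))
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        mat = np.tile(pool, (k, 1))
        mat = rng.permuted(mat, axis=1)
        diff = mat[:, :na].mean(axis=1) - mat[:, na:].mean(axis=1)
        count += int(np.sum(np.abs(diff) >= abs(observed) - 1e-12))
        done += k
    p_raw = (1 + count) / (n_perm + 1)
    return {
        "statistic": float(observed),
        "p_raw": float(p_raw),
        "p_adjusted": float(min(1.0, m_comparisons * p_raw)),
        "n_perm": int(n_perm),
        "m_comparisons": int(m_comparisons),
    }
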
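"""Configuration for the synthetic recognition-memory experiment.

The generator simulates an old/new recognition-memory study on brief movie
shots: subjects watch one episode of a TV series, then are queried in six
test sessions (nominally 0, 1, 7, 30, 90 and 365 days after encoding) with
shots from the watched episode ("targets") intermixed, with equal
probability, with duration- and content-matched shots from an unwatched
episode ("foils").  Correctness of each simulated response follows a
logistic model that is additive in annotated content, log shot duration,
log elapsed time, per-subject ability, and the manipulation condition.

:class:`GeneratorConfig` holds every ground-truth parameter of that model,
so downstream estimators can be checked against known truth.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

#: Recognised manipulation conditions applied at test time.  Only ``none``
#: occurs by default; the others are the stimulus transformations of the
#: manipulation experiment variant (sound removal, mirror flip, grayscale,
#: single-quadrant occlusion, temporal reversal).
MANIPULATIONS = (
    "none",
    "no_sound",
    "horizontal_flip",
    "grayscale",
    "occlusion",
    "temporal_reversal",
)

#: Maximum shot duration in frames (at 30 frames/s, three seconds).
MAX_SHOT_FRAMES = 90

#: Nominal session day -> (earliest, latest) elapsed time in days.  These
#: are the scheduling windows of the six-session design: session 1 runs
#: immediately after encoding (~15-30 min), session 2 at 22-26 h, then
#: days 6-8, 27-33, 85-95 and 335-395.
DEFAULT_SESSION_WINDOWS: dict[int, tuple[float, float]] = {
    0: (0.0104, 0.0208),
    1: (22 / 24, 26 / 24),
    7: (6.0, 8.0),
    30: (27.0, 33.0),
    90: (85.0, 95.0),
    365: (335.0, 395.0),
}


def _default_true_weights() -> dict[str, float]:
    # Sparse ground-truth content effects (log-odds of a correct response).
    # A dozen strong drivers — positive (action, elicited emotion, the
    # lead characters) and negative (forgettable background content) —
    # over a mostly-null inventory mirrors the empirical pattern that
    # only some content properties carry memorability signal, while
    # giving shots a wide difficulty spread so that a sizable minority
    # of shots is consistently forgotten across subjects.
    return {
        "action": 1.2,
        "emotion_elicited": 1.0,
        "emotion_depicted": 0.6,
        "char_01": 1.0,
        "char_02": 0.6,
        "char_03": -0.9,
        "sound_01": 0.7,
        "sound_02": -0.6,
        "emotion_02": 0.7,
        "emotion_03": -0.7,
        "object_01": 0.5,
        "object_02": -0.8,
    }


def _default_manipulation_offsets() -> dict[str, float]:
    # Log-odds shifts relative to unaltered presentation.  Low-level
    # manipulations (flip, grayscale) are null; sound removal, occlusion
    # and temporal reversal impair performance.
    return {
        "none": 0.0,
        "no_sound": -0.5,
        "horizontal_flip": 0.0,
        "grayscale": 0.0,
        "occlusion": -1.2,
        "temporal_reversal": -0.6,
    }


class GeneratorConfig(BaseModel):
    """Ground-truth parameters of the synthetic experiment.

    The correctness model for a trial on shot *i* by subject *s* is::

        logit(p) = base_logit + beta . x_i + duration_weight * log(n_frames)
                   - retention_rate * log(1 + elapsed_days)
                   + ability_s + foil_bias * [foil trial]
                   + manipulation_offset[condition]

    with ``p`` clipped to ``[prob_floor, prob_ceiling]``.  Single-frame
    presentations use ``n_frames = 1`` with the parent shot's content
    vector ``x_i``.
    """

    n_subjects: int = Field(default=41, gt=0)
    n_shots_per_episode: int = Field(default=300, gt=0)

    # Annotation inventory sizes: character presences (each with a paired
    # viewpoint bit), sound classes, emotion classes, object classes.
    n_characters: int = Field(default=29, gt=0)
    n_sounds: int = Field(default=13, gt=0)
    n_emotions: int = Field(default=20, gt=0)
    n_objects: int = Field(default=25, gt=0)

    #: Per-feature log-odds effects (beta).  Keys must name annotation
    #: features; unlisted features have zero effect.
    true_weights: dict[str, float] = Field(default_factory=_default_true_weights)
    #: Log-odds per unit log(n_frames) (gamma).
    duration_weight: float = 0.35
    #: Log-odds decay per unit log(1 + elapsed days) (delta).
    retention_rate: float = 0.25
    #: Intercept of the correctness model.
    base_logit: float = 0.8
    #: SD of the per-subject ability offsets (sigma_a).
    subject_ability_sd: float = Field(default=0.5, ge=0)
    #: Log-odds offset applied to foil trials (0 = no target/foil asymmetry).
    foil_bias: float = 0.0
    manipulation_offsets: dict[str, float] = Field(
        default_factory=_default_manipulation_offsets
    )
    #: Sampling probabilities of manipulation conditions at test time.
    manipulation_probs: dict[str, float] = Field(default_factory=lambda: {"none": 1.0})
    #: Fraction of queried pairs presented as a single frame instead of the
    #: full shot.
    single_frame_fraction: float = Field(default=0.25, ge=0.0, le=1.0)

    session_days: tuple[int, ...] = (0, 1, 7, 30, 90, 365)
    #: Optional override of elapsed-time windows per session day.
    session_windows: dict[int, tuple[float, float]] | None = None
    #: Fraction of scheduled queries that are re-queried later.
    repeat_fraction: float = Field(default=0.03, ge=0.0, lt=1.0)

    prob_floor: float = 0.02
    prob_ceiling: float = 0.98

    #: Per-feature occurrence probabilities; features not listed get a
    #: probability drawn from the annotation stream.  The defaults pin
    #: the features carrying ground-truth weight (lead characters appear
    #: in roughly half the shots, action in a third, ...) so the
    #: difficulty composition of the simulated movie is stable across
    #: seeds.
    feature_probs: dict[str, float] = Field(
        default_factory=lambda: {
            "action": 0.30,
            "emotion_elicited": 0.35,
            "emotion_depicted": 0.40,
            "char_01": 0.50,
            "char_02": 0.30,
            "char_03": 0.25,
            "sound_01": 0.30,
            "sound_02": 0.30,
            "emotion_02": 0.25,
            "emotion_03": 0.25,
            "object_01": 0.30,
            "object_02": 0.30,
        }
    )

    seed: int = 0

    model_config = {"frozen": True}

    # ------------------------------------------------------------------ #
    # validation

    @field_validator("session_days")
    @classmethod
    def _days_increasing(cls, v: tuple[int, ...]) -> tuple[int, ...]:
        if len(v) == 0:
            raise ValueError("session_days: at least one session is required")
        if any(d < 0 for d in v):
            raise ValueError("session_days: day labels must be nonnegative")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("session_days: must be strictly increasing")
        return v

    @field_validator("true_weights", "manipulation_offsets")
    @classmethod
    def _weights_finite(cls, v: dict[str, float]) -> dict[str, float]:
        import math

        for k, w in v.items():
            if not math.isfinite(w):
                raise ValueError(f"weight for {k!r} must be finite")
        return v

    @model_validator(mode="after")
    def _check_cross_field(self) -> "GeneratorConfig":
        if not (0.0 < self.prob_floor < self.prob_ceiling < 1.0):
            raise ValueError(
                "prob_floor/prob_ceiling: need 0 < floor < ceiling < 1, got "
                f"({self.prob_floor}, {self.prob_ceiling})"
            )
        unknown = set(self.manipulation_offsets) - set(MANIPULATIONS)
        if unknown:
            raise ValueError(
                f"manipulation_offsets: unknown conditions {sorted(unknown)}"
            )
        unknown = set(self.manipulation_probs) - set(MANIPULATIONS)
        if unknown:
            raise ValueError(f"manipulation_probs: unknown conditions {sorted(unknown)}")
        total = sum(self.manipulation_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"manipulation_probs: must sum to 1, got {total}")
        if any(p < 0 for p in self.manipulation_probs.values()):
            raise ValueError("manipulation_probs: probabilities must be nonnegative")
        for k, p in self.feature_probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"feature_probs[{k!r}] must lie in [0, 1], got {p}")
        if self.session_windows is not None:
            for day, (lo, hi) in self.session_windows.items():
                if not (0 <= lo < hi):
                    raise ValueError(
                        f"session_windows[{day}]: need 0 <= lo < hi, got ({lo}, {hi})"
                    )
        return self

    # ------------------------------------------------------------------ #
    # feature inventory

    @property
    def character_features(self) -> list[str]:
        return [f"char_{i:02d}" for i in range(1, self.n_characters + 1)]

    @property
    def viewpoint_features(self) -> list[str]:
        return [f"view_{i:02d}" for i in range(1, self.n_characters + 1)]

    @property
    def sound_features(self) -> list[str]:
        return [f"sound_{i:02d}" for i in range(1, self.n_sounds + 1)]

    @property
    def emotion_features(self) -> list[str]:
        return [f"emotion_{i:02d}" for i in range(1, self.n_emotions + 1)]

    @property
    def object_features(self) -> list[str]:
        return [f"object_{i:02d}" for i in range(1, self.n_objects + 1)]

    @property
    def flag_features(self) -> list[str]:
        return ["action", "indoor_outdoor", "emotion_depicted", "emotion_elicited"]

    @property
    def binary_features(self) -> list[str]:
        """All 0/1 annotation columns, in canonical order."""
        return (
            self.flag_features
            + self.character_features
            + self.viewpoint_features
            + self.sound_features
            + self.emotion_features
            + self.object_features
        )

    @property
    def count_features(self) -> list[str]:
        return ["n_characters_in_shot", "n_objects_in_shot"]

    @property
    def continuous_features(self) -> list[str]:
        return ["n_frames", "contrast", "color_content", "sound_level"]

    @property
    def all_features(self) -> list[str]:
        return self.binary_features + self.count_features + self.continuous_features

    def session_window(self, day: int) -> tuple[float, float]:
        """Elapsed-time window (in days) for a nominal session day."""
        if self.session_windows is not None and day in self.session_windows:
            return self.session_windows[day]
        if day in DEFAULT_SESSION_WINDOWS:
            return DEFAULT_SESSION_WINDOWS[day]
        if day == 0:
            return (0.0104, 0.0208)
        return (0.9 * day, 1.1 * day)

    def validate_feature_refs(self) -> None:
        """Raise if true_weights or feature_probs name unknown features."""
        known = set(self.all_features)
        bad = sorted(set(self.true_weights) - known)
        if bad:
            raise ValueError(f"true_weights: unknown features {bad}")
        bad = sorted(set(self.feature_probs) - set(self.binary_features))
        if bad:
            raise ValueError(f"feature_probs: unknown binary features {bad}")


def load_config(path: str | Path) -> GeneratorConfig:
    """Read a :class:`GeneratorConfig` from a JSON or YAML file.

    Every omitted field takes its documented default.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: expected a mapping of config fields")
    return GeneratorConfig(**data)
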
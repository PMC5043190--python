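"""Dataset contracts and CSV round-tripping.

A dataset is three UTF-8 CSV tables with header rows ("." decimal,
booleans as 0/1, missing values as empty fields):

* ``shots.csv`` — shot_id, episode, start_frame, end_frame, n_frames,
  matched_shot_id
* ``annotations.csv`` — shot_id plus one column per content feature
* ``trials.csv`` — all trial fields (subject, session, elapsed days,
  trial index, shot, stimulus class, presentation mode, manipulation,
  response, correct, is_repeat)

plus ``truth.json`` with the generator config and resolved ground truth
when the dataset is synthetic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import DatasetValidationError
from .synthetic_data import SHOT_COLUMNS, TRIAL_COLUMNS, SyntheticDataset

_BOOL_TRIAL_COLS = ("correct", "is_repeat")


@dataclass
class Dataset:
    """Validated in-memory dataset."""

    shots: pd.DataFrame
    annotations: pd.DataFrame
    trials: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.annotations.columns if c != "shot_id"]


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DatasetValidationError(f"{name}: missing column(s) {missing}")


def validate_dataset(
    shots: pd.DataFrame, annotations: pd.DataFrame, trials: pd.DataFrame
) -> None:
    """Referential-integrity and schema checks; raises on first violation."""
    _require_columns(shots, SHOT_COLUMNS, "shots")
    _require_columns(annotations, ["shot_id"], "annotations")
    _require_columns(trials, TRIAL_COLUMNS, "trials")

    shot_ids = set(shots["shot_id"])
    if len(shot_ids) != len(shots):
        raise DatasetValidationError("shots: duplicate shot_id")
    ann_ids = set(annotations["shot_id"])
    if len(ann_ids) != len(annotations):
        raise DatasetValidationError("annotations: duplicate shot_id")
    missing = shot_ids - ann_ids
    if missing:
        raise DatasetValidationError(
            f"annotations: shot(s) without annotation row: {sorted(missing)[:5]}"
        )
    dangling = set(trials["shot_id"]) - shot_ids
    if dangling:
        raise DatasetValidationError(
            f"trials: unknown shot_id(s): {sorted(dangling)[:5]}"
        )
    dup = trials.duplicated(["subject_id", "session_label", "trial_index"])
    if dup.any():
        row = trials[dup].iloc[0]
        raise DatasetValidationError(
            "trials: duplicate (subject, session, trial_index) at "
            f"({row['subject_id']}, {row['session_label']}, {row['trial_index']})"
        )
    bad = shots[shots["end_frame"] <= shots["start_frame"]]
    if len(bad):
        raise DatasetValidationError(
            f"shots: end_frame <= start_frame at shot {bad['shot_id'].iloc[0]}"
        )
    if (shots["n_frames"] != shots["end_frame"] - shots["start_frame"]).any():
        raise DatasetValidationError("shots: n_frames != end_frame - start_frame")


def write_dataset(ds: Dataset | SyntheticDataset, out_dir: str | Path) -> Path:
    """Write the three CSVs (and truth.json for synthetic data)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials = ds.trials.copy()
    for col in _BOOL_TRIAL_COLS:
        trials[col] = trials[col].astype(int)
    ds.shots.to_csv(out / "shots.csv", index=False)
    ds.annotations.to_csv(out / "annotations.csv", index=False)
    trials.to_csv(out / "trials.csv", index=False)
    truth = getattr(ds, "truth", None) or getattr(ds, "provenance", None)
    if truth:
        (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return out


def load_dataset(path: str | Path) -> Dataset:
    """Load and validate a dataset directory written by :func:`write_dataset`."""
    path = Path(path)
    for name in ("shots.csv", "annotations.csv", "trials.csv"):
        if not (path / name).exists():
            raise DatasetValidationError(f"{path / name}: file not found")
    shots = pd.read_csv(path / "shots.csv", keep_default_na=False)
    annotations = pd.read_csv(path / "annotations.csv",
                              float_precision="round_trip")
    trials = pd.read_csv(path / "trials.csv", float_precision="round_trip")
    for col in _BOOL_TRIAL_COLS:
        if col in trials.columns:
            trials[col] = trials[col].astype(bool)
    validate_dataset(shots, annotations, trials)
    provenance = {}
    truth_path = path / "truth.json"
    if truth_path.exists():
        provenance = json.loads(truth_path.read_text())
    return Dataset(shots=shots, annotations=annotations, trials=trials,
                   provenance=provenance)


def dataset_from_synthetic(ds: SyntheticDataset) -> Dataset:
    """Wrap generator output as a validated Dataset with provenance."""
    validate_dataset(ds.shots, ds.annotations, ds.trials)
    prov = dict(ds.truth)
    prov["config_hash"] = hashlib.sha256(
        json.dumps(ds.truth.get("config", {}), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    return Dataset(shots=ds.shots, annotations=ds.annotations, trials=ds.trials,
                   provenance=prov)
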
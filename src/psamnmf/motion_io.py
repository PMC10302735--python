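"""Data model, on-disk schema, readers/writers and pipeline configuration.

The package operates on cohorts of upper-limb reaching trials recorded either
with a wearable IMU suit (5 body segments, 60 Hz) or a marker-based camera
system (9 feature markers + 4 trunk markers, 200 Hz).  Each trial is a set of
named 3-D position channels sampled at a fixed rate, in millimetres.

On disk a cohort is a directory of long-format CSV files (one per trial,
columns ``t_index, channel, axis, value_mm``) plus ``subjects.csv`` holding
subject metadata (``subject_id, fma_ue, affected_side``) and a JSON manifest.
An HDF5 mirror is provided for speed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("psamnmf")

# ---------------------------------------------------------------------------
# Device profiles and task vocabulary
# ---------------------------------------------------------------------------

WEARABLE = "wearable"
CAMERA = "camera"
DEVICES = (WEARABLE, CAMERA)

#: The four grasping tasks every subject performs, three repetitions each.
TASKS = ("glass", "phone", "cup", "apple")
N_REPS = 3

#: Wearable profile: five upper-limb segments, sternum sensor T8 doubles as
#: the trunk channel.  5 segments x 3 axes = 15 position channels.
WEARABLE_CHANNELS = ("hand", "shoulder", "upper_arm", "forearm", "T8")
WEARABLE_TRUNK = ("T8",)
WEARABLE_RATE = 60.0

#: Camera profile: nine feature markers (wrist, ulna, humerus, scapula,
#: hand) plus four trunk markers used only for trunk-displacement labeling.
CAMERA_FEATURE_CHANNELS = (
    "wrist_radial", "wrist_ulnar", "ulna", "humerus_lat", "humerus_med",
    "scapula_acromion", "scapula_spine", "forearm", "hand",
)
CAMERA_TRUNK = ("trunk_clav", "trunk_strn", "trunk_c7", "trunk_t10")
CAMERA_CHANNELS = CAMERA_FEATURE_CHANNELS + CAMERA_TRUNK
CAMERA_RATE = 200.0

DEVICE_RATES = {WEARABLE: WEARABLE_RATE, CAMERA: CAMERA_RATE}
DEVICE_CHANNELS = {WEARABLE: WEARABLE_CHANNELS, CAMERA: CAMERA_CHANNELS}
DEVICE_TRUNK = {WEARABLE: WEARABLE_TRUNK, CAMERA: CAMERA_TRUNK}
#: Channels whose spectra enter the feature matrix (trunk-only markers of the
#: camera profile feed severity labeling, never clustering features).
DEVICE_FEATURE_CHANNELS = {
    WEARABLE: WEARABLE_CHANNELS,
    CAMERA: CAMERA_FEATURE_CHANNELS,
}

#: Default low-pass cutoffs (Hz) per device profile.
DEVICE_CUTOFF = {WEARABLE: 10.0, CAMERA: 20.0}

MIN_TRIAL_SAMPLES = 20  # baseline window needs 10, differentiation needs 3

FMA_MAX = 66


class SchemaError(ValueError):
    """A cohort file does not match the documented on-disk schema."""


class ValidationError(ValueError):
    """An in-memory object violates a data-model invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class MotionTrial:
    """One subject x task x repetition recording of 3-D position channels.

    ``channels`` maps channel name to a ``(T, 3)`` float array of x/y/z
    positions in millimetres; all channels share the same length.
    """

    subject_id: str
    device: str
    task: str
    repetition: int
    sampling_rate: float
    channels: dict[str, np.ndarray]
    trunk_channels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.channels = {c: np.asarray(v, dtype=float) for c, v in self.channels.items()}
        self.trunk_channels = tuple(self.trunk_channels)
        self.validate()

    def validate(self) -> None:
        if self.device not in DEVICES:
            raise ValidationError(f"unknown device {self.device!r}")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if self.device in DEVICE_RATES and self.sampling_rate != DEVICE_RATES[self.device]:
            raise ValidationError(
                f"device {self.device!r} implies {DEVICE_RATES[self.device]} Hz, "
                f"got {self.sampling_rate}"
            )
        if not self.channels:
            raise ValidationError("trial has no channels")
        lengths = {c: v.shape[0] for c, v in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise ValidationError(f"channel lengths differ: {lengths}")
        n = next(iter(lengths.values()))
        if n < MIN_TRIAL_SAMPLES:
            raise ValidationError(
                f"trial length {n} < minimum {MIN_TRIAL_SAMPLES} samples"
            )
        for c, v in self.channels.items():
            if v.ndim != 2 or v.shape[1] != 3:
                raise ValidationError(f"channel {c!r} is not a (T, 3) array")
            if not np.all(np.isfinite(v)):
                raise ValidationError(f"channel {c!r} contains non-finite values")
        if not self.trunk_channels:
            raise ValidationError("trunk_channels must be non-empty")
        missing = [c for c in self.trunk_channels if c not in self.channels]
        if missing:
            raise SchemaError(
                f"trunk channel(s) {missing} missing from trial "
                f"{self.subject_id}/{self.task}/{self.repetition}"
            )

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.subject_id, self.task, self.repetition)


@dataclass
class FilteredTrial(MotionTrial):
    """A MotionTrial after zero-phase low-pass filtering."""

    filter_order: int = 2
    filter_cutoff_hz: float = float("nan")
    zero_phase: bool = True


@dataclass
class SubjectRecord:
    """A subject's FMA-UE score, affected side and recorded trials."""

    subject_id: str
    fma_ue: int
    affected_side: str
    trials: list[MotionTrial] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 <= self.fma_ue <= FMA_MAX:
            raise ValidationError(
                f"fma_ue {self.fma_ue} outside [0, {FMA_MAX}] for {self.subject_id}"
            )
        if self.affected_side not in ("left", "right"):
            raise ValidationError(f"affected_side must be left/right, got {self.affected_side!r}")
        for t in self.trials:
            if t.subject_id != self.subject_id:
                raise ValidationError(
                    f"trial subject {t.subject_id!r} != record subject {self.subject_id!r}"
                )


@dataclass
class PipelineConfig:
    """All knobs of the severity-assessment pipeline, YAML-serializable.

    Defaults follow the study settings: device-specific Butterworth cutoffs,
    k in {2, 3}, 100 search runs keeping the top 10 combinations.
    """

    device_profile: str = WEARABLE
    cutoff_hz: float | None = None  # None -> device default (10 / 20 Hz)
    feature_kind: str = "merged"  # position_freq | accel_freq | merged
    n_freq_bins: int = 16
    k_clusters: int = 2
    solver: str = "psa_mnmf"  # psa_mnmf | mcla | cspa | hbgf | hgpa
    n_runs: int = 100
    top_m: int = 10
    random_seed: int = 0
    fma_threshold_severe: int = 29  # FMA-UE < 29 -> severe
    fma_threshold_mild: int = 43   # k=3: [29, 43) -> mild, [43, 66] -> non-severe
    signed_trunk_sum: bool = False

    def __post_init__(self) -> None:
        if self.device_profile not in DEVICES:
            raise ValidationError(f"unknown device profile {self.device_profile!r}")
        if self.k_clusters not in (2, 3):
            raise ValidationError("k_clusters must be 2 or 3")
        if self.n_runs < 1 or self.top_m < 1:
            raise ValidationError("n_runs and top_m must be >= 1")
        nyq = DEVICE_RATES[self.device_profile] / 2.0
        if self.cutoff_hz is not None and not 0 < self.cutoff_hz < nyq:
            raise ValidationError(f"cutoff {self.cutoff_hz} Hz outside (0, {nyq})")
        if self.feature_kind not in ("position_freq", "accel_freq", "merged"):
            raise ValidationError(f"unknown feature_kind {self.feature_kind!r}")
        if self.solver not in ("psa_mnmf", "mcla", "cspa", "hbgf", "hgpa"):
            raise ValidationError(f"unknown solver {self.solver!r}")

    @property
    def effective_cutoff_hz(self) -> float:
        if self.cutoff_hz is not None:
            return self.cutoff_hz
        return DEVICE_CUTOFF[self.device_profile]

    @property
    def sampling_rate(self) -> float:
        return DEVICE_RATES[self.device_profile]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# CSV schema
# ---------------------------------------------------------------------------

_TRIAL_COLUMNS = ["t_index", "channel", "axis", "value_mm"]
_AXES = ("x", "y", "z")


def _trial_filename(trial: MotionTrial) -> str:
    return f"{trial.subject_id}__{trial.task}__rep{trial.repetition}.csv"


def _trial_to_frame(trial: MotionTrial) -> pd.DataFrame:
    rows = []
    for channel, series in trial.channels.items():
        for ai, axis in enumerate(_AXES):
            rows.append(
                pd.DataFrame(
                    {
                        "t_index": np.arange(series.shape[0]),
                        "channel": channel,
                        "axis": axis,
                        "value_mm": series[:, ai],
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def _frame_to_channels(df: pd.DataFrame, path: Path) -> dict[str, np.ndarray]:
    if list(df.columns) != _TRIAL_COLUMNS:
        raise SchemaError(f"{path}: expected columns {_TRIAL_COLUMNS}, got {list(df.columns)}")
    channels: dict[str, np.ndarray] = {}
    for channel, grp in df.groupby("channel", sort=False):
        axes = []
        for axis in _AXES:
            sub = grp[grp["axis"] == axis].sort_values("t_index")
            axes.append(sub["value_mm"].to_numpy())
        lengths = {a.shape[0] for a in axes}
        if len(lengths) != 1:
            raise SchemaError(f"{path}: channel {channel!r} has ragged axes")
        channels[str(channel)] = np.column_stack(axes)
    return channels


def write_cohort(records: Sequence[SubjectRecord], path: str | Path) -> dict:
    """Write a cohort to ``path`` in the documented CSV schema.

    Returns the JSON manifest (also written to ``manifest.json``): per-file
    row counts and SHA-256 checksums, plus subject/trial totals.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    seen: set[tuple[str, str, int]] = set()
    entries = []
    for rec in records:
        rec.validate()
        for trial in rec.trials:
            if trial.key in seen:
                raise ValidationError(f"duplicate trial key {trial.key}")
            seen.add(trial.key)
            fname = _trial_filename(trial)
            frame = _trial_to_frame(trial)
            fpath = out / fname
            frame.to_csv(fpath, index=False, float_format="%.17g")
            digest = hashlib.sha256(fpath.read_bytes()).hexdigest()
            entries.append(
                {
                    "file": fname,
                    "subject_id": trial.subject_id,
                    "task": trial.task,
                    "repetition": trial.repetition,
                    "device": trial.device,
                    "n_rows": int(len(frame)),
                    "sha256": digest,
                }
            )
    subjects = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "fma_ue": [r.fma_ue for r in records],
            "affected_side": [r.affected_side for r in records],
        }
    )
    subjects.to_csv(out / "subjects.csv", index=False)
    manifest = {
        "n_subjects": len(records),
        "n_trials": len(entries),
        "files": entries,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("wrote cohort: %d subjects, %d trials -> %s", len(records), len(entries), out)
    return manifest


def read_cohort(path: str | Path, profile: str) -> list[SubjectRecord]:
    """Read a cohort directory written by :func:`write_cohort`.

    ``profile`` declares the expected device; channel sets, sampling rate and
    trunk channels are validated against it.
    """
    root = Path(path)
    if profile not in DEVICES:
        raise ValidationError(f"unknown device profile {profile!r}")
    subj_path = root / "subjects.csv"
    if not subj_path.exists():
        raise SchemaError(f"missing subjects.csv in {root}")
    subjects = pd.read_csv(subj_path)
    required = {"subject_id", "fma_ue", "affected_side"}
    if not required.issubset(subjects.columns):
        raise SchemaError(f"subjects.csv missing columns {required - set(subjects.columns)}")

    trials_by_subject: dict[str, list[MotionTrial]] = {}
    expected_channels = set(DEVICE_CHANNELS[profile])
    for fpath in sorted(root.glob("*__*__rep*.csv")):
        stem = fpath.stem
        subject_id, task, rep_part = stem.split("__")
        repetition = int(rep_part.removeprefix("rep"))
        channels = _frame_to_channels(
            pd.read_csv(fpath, float_precision="round_trip"), fpath
        )
        missing = expected_channels - set(channels)
        if missing:
            raise SchemaError(f"{fpath.name}: missing channel(s) {sorted(missing)}")
        trial = MotionTrial(
            subject_id=subject_id,
            device=profile,
            task=task,
            repetition=repetition,
            sampling_rate=DEVICE_RATES[profile],
            channels=channels,
            trunk_channels=DEVICE_TRUNK[profile],
        )
        trials_by_subject.setdefault(subject_id, []).append(trial)

    records = []
    for _, row in subjects.iterrows():
        sid = str(row["subject_id"])
        records.append(
            SubjectRecord(
                subject_id=sid,
                fma_ue=int(row["fma_ue"]),
                affected_side=str(row["affected_side"]),
                trials=trials_by_subject.get(sid, []),
            )
        )
    return records


# ---------------------------------------------------------------------------
# HDF5 mirror
# ---------------------------------------------------------------------------


def write_cohort_hdf5(records: Sequence[SubjectRecord], path: str | Path) -> None:
    """Mirror of :func:`write_cohort` in a single HDF5 file."""
    import h5py

    with h5py.File(path, "w") as fh:
        for rec in records:
            grp = fh.create_group(rec.subject_id)
            grp.attrs["fma_ue"] = rec.fma_ue
            grp.attrs["affected_side"] = rec.affected_side
            for trial in rec.trials:
                tg = grp.create_group(f"{trial.task}__rep{trial.repetition}")
                tg.attrs["device"] = trial.device
                tg.attrs["sampling_rate"] = trial.sampling_rate
                tg.attrs["trunk_channels"] = ",".join(trial.trunk_channels)
                for channel, series in trial.channels.items():
                    tg.create_dataset(channel, data=series)


def read_cohort_hdf5(path: str | Path) -> list[SubjectRecord]:
    import h5py

    records = []
    with h5py.File(path, "r") as fh:
        for sid in sorted(fh):
            grp = fh[sid]
            trials = []
            for tname in sorted(grp):
                tg = grp[tname]
                task, rep_part = tname.split("__")
                trials.append(
                    MotionTrial(
                        subject_id=sid,
                        device=tg.attrs["device"],
                        task=task,
                        repetition=int(rep_part.removeprefix("rep")),
                        sampling_rate=float(tg.attrs["sampling_rate"]),
                        channels={c: tg[c][()] for c in tg},
                        trunk_channels=tuple(tg.attrs["trunk_channels"].split(",")),
                    )
                )
            records.append(
                SubjectRecord(
                    subject_id=sid,
                    fma_ue=int(grp.attrs["fma_ue"]),
                    affected_side=str(grp.attrs["affected_side"]),
                    trials=trials,
                )
            )
    return records


def all_trials(records: Sequence[SubjectRecord]) -> list[MotionTrial]:
    """Flatten a cohort into a deterministic instance order.

    Order: subjects as given, then task order of :data:`TASKS`, then
    repetition — this is the instance order of every feature matrix and
    partition downstream.
    """
    task_rank = {t: i for i, t in enumerate(TASKS)}
    out = []
    for rec in records:
        out.extend(
            sorted(rec.trials, key=lambda t: (task_rank.get(t.task, 99), t.repetition))
        )
    return out


def configure_logging(verbose: bool = False) -> None:
    """Route package logs to stderr; ``verbose`` lowers the level to DEBUG."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


__all__ = [
    "MotionTrial", "FilteredTrial", "SubjectRecord", "PipelineConfig",
    "SchemaError", "ValidationError",
    "read_cohort", "write_cohort", "read_cohort_hdf5", "write_cohort_hdf5",
    "all_trials", "configure_logging",
    "TASKS", "N_REPS", "WEARABLE", "CAMERA", "DEVICES",
    "WEARABLE_CHANNELS", "WEARABLE_TRUNK", "CAMERA_FEATURE_CHANNELS",
    "CAMERA_TRUNK", "CAMERA_CHANNELS", "DEVICE_RATES", "DEVICE_CHANNELS",
    "DEVICE_TRUNK", "DEVICE_FEATURE_CHANNELS", "DEVICE_CUTOFF", "FMA_MAX",
]
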
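"""Synthetic cohorts with the statistical structure the pipeline assumes.

Each subject belongs to a severity class that controls (a) the amplitude of
the compensatory trunk lean during reaching, (b) the smoothness of the limb
trajectory (temporal jitter — impaired movement is jerkier), and (c) the
reach amplitude (impaired subjects show reduced range of motion).  FMA-UE
scores are sampled uniformly inside the class's band, so the trunk-based
labeling and the FMA-derived ground truth are consistent by construction.

Limb channels follow a minimum-jerk reach-hold-return profile; trunk
channels follow a forward-lean bump whose peak amplitude is
Normal(class mean, 10% CV) truncated at zero and which starts after the
10-sample baseline window.  Gaussian position noise is added throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .baseline_ensemble import Partition, PartitionEnsemble
from .motion_io import (
    CAMERA,
    CAMERA_FEATURE_CHANNELS,
    CAMERA_TRUNK,
    DEVICE_RATES,
    DEVICE_TRUNK,
    TASKS,
    WEARABLE,
    WEARABLE_CHANNELS,
    MotionTrial,
    SubjectRecord,
    ValidationError,
)
from .severity import DEFAULT_THRESHOLDS

#: FMA-UE sampling bands per class (lo inclusive, hi inclusive), consistent
#: with the default severity thresholds (< 29 severe, [29, 43) mild).
FMA_BANDS = {"severe": (0, 28), "mild": (29, 42), "non-severe": (43, 66)}

#: Default per-class trunk-lean peak amplitudes (mm).
DEFAULT_AMPLITUDES = {"non-severe": 5.0, "mild": 20.0, "severe": 40.0}
#: Default per-class temporal jitter (fraction of normalized time).
DEFAULT_JITTER = {"non-severe": 0.02, "mild": 0.08, "severe": 0.15}
#: Default per-class reach amplitude (mm): impaired = reduced range.
DEFAULT_REACH = {"non-severe": 300.0, "mild": 240.0, "severe": 180.0}
#: Default per-class movement-time factor: impaired reaching is slower.
DEFAULT_SLOWNESS = {"non-severe": 1.0, "mild": 1.3, "severe": 1.6}

SEVERITY_ORDER = ("non-severe", "mild", "severe")

#: Relative movement gain of each wearable segment along the reach.
_WEARABLE_GAINS = {"hand": 1.0, "forearm": 0.75, "upper_arm": 0.45, "shoulder": 0.15}
_CAMERA_GAINS = {
    "wrist_radial": 1.0, "wrist_ulnar": 0.97, "ulna": 0.85,
    "humerus_lat": 0.5, "humerus_med": 0.45, "scapula_acromion": 0.2,
    "scapula_spine": 0.15, "forearm": 0.8, "hand": 1.0,
}


@dataclass
class CohortSpec:
    """Generator settings; the defaults are the study conditions."""

    n_subjects: int = 20
    class_mix: dict[str, float] = field(
        default_factory=lambda: {"non-severe": 0.5, "severe": 0.5}
    )
    device: str = WEARABLE
    duration_s: float = 3.0
    amplitudes_mm: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDES)
    )
    jitter: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_JITTER))
    reach_mm: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_REACH))
    slowness: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SLOWNESS))
    noise_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_mm < 0:
            raise ValidationError("noise_mm must be >= 0")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValidationError("class_mix must sum to 1")
        if any(c not in FMA_BANDS for c in self.class_mix):
            raise ValidationError(f"classes must be among {list(FMA_BANDS)}")
        amps = [self.amplitudes_mm[c] for c in SEVERITY_ORDER if c in self.amplitudes_mm]
        if any(a >= b for a, b in zip(amps, amps[1:])) or not amps:
            pass
        ordered = [self.amplitudes_mm[c] for c in SEVERITY_ORDER]
        if not (ordered[0] < ordered[1] < ordered[2]):
            raise ValidationError("trunk amplitudes must increase with severity")

    @property
    def n_trials(self) -> int:
        return self.n_subjects * len(TASKS) * 3


def minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk unit displacement profile 10 t^3 - 15 t^4 + 6 t^5 on [0, 1]."""
    t = np.clip(tau, 0.0, 1.0)
    return 10 * t**3 - 15 * t**4 + 6 * t**5


def _reach_profile(tau: np.ndarray, slow: float = 1.0) -> np.ndarray:
    """Reach out, hold, return, as a 0..1..0 profile.

    ``slow`` stretches the reach and return phases (movement-time factor);
    the out phase starts at 0.10 and the return ends at 0.88 of the trial.
    """
    d = 0.25 * slow
    out = minimum_jerk((tau - 0.10) / d)
    back = minimum_jerk((tau - (0.88 - d)) / d)
    return out - back


def _lean_profile(tau: np.ndarray) -> np.ndarray:
    """Trunk forward-lean bump: smooth rise after the baseline window and
    return before trial end (sin^2 window on [0.2, 0.8])."""
    w = np.zeros_like(tau)
    inside = (tau >= 0.2) & (tau <= 0.8)
    w[inside] = np.sin(np.pi * (tau[inside] - 0.2) / 0.6) ** 2
    return w


def _synth_trial(
    spec: CohortSpec,
    subject_id: str,
    task: str,
    rep: int,
    severity: str,
    rng: np.random.Generator,
) -> MotionTrial:
    fs = DEVICE_RATES[spec.device]
    n = int(round(spec.duration_s * fs))
    tau = np.arange(n) / n

    # class-dependent temporal jitter: low-frequency time warp
    j = spec.jitter[severity]
    warp_f = rng.uniform(1.0, 3.0)
    warp_phi = rng.uniform(0, 2 * np.pi)
    tau_w = np.clip(tau + 0.5 * j * np.sin(2 * np.pi * warp_f * tau + warp_phi), 0, 1)
    reach = _reach_profile(tau_w, spec.slowness[severity])

    reach_amp = spec.reach_mm[severity] * rng.uniform(0.9, 1.1)
    # per-task reach direction, unit vector biased forward/up
    direction = np.array([1.0, 0.35, 0.25]) + 0.1 * rng.standard_normal(3)
    direction /= np.linalg.norm(direction)

    mu = spec.amplitudes_mm[severity]
    lean_amp = max(0.0, rng.normal(mu, 0.1 * mu))
    lean = lean_amp * _lean_profile(tau_w)
    lean_dir = np.array([1.0, 0.3, 0.15])  # mostly forward

    channels: dict[str, np.ndarray] = {}
    if spec.device == WEARABLE:
        feature_gains = _WEARABLE_GAINS
        trunk_names = DEVICE_TRUNK[WEARABLE]
    else:
        feature_gains = _CAMERA_GAINS
        trunk_names = CAMERA_TRUNK

    for name, gain in feature_gains.items():
        base = rng.uniform(-50, 50, size=3)
        series = (
            base
            + gain * reach_amp * reach[:, None] * direction
            + spec.noise_mm * rng.standard_normal((n, 3))
        )
        channels[name] = series
    for name in trunk_names:
        base = rng.uniform(-50, 50, size=3)
        series = (
            base
            + lean[:, None] * lean_dir
            + 0.05 * reach_amp * reach[:, None] * direction  # passive trunk drift
            + spec.noise_mm * rng.standard_normal((n, 3))
        )
        channels[name] = series

    return MotionTrial(
        subject_id=subject_id,
        device=spec.device,
        task=task,
        repetition=rep,
        sampling_rate=fs,
        channels=channels,
        trunk_channels=DEVICE_TRUNK[spec.device],
    )


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate a full cohort: n_subjects x 4 tasks x 3 repetitions.

    Deterministic given ``spec.seed``.  Severity classes are drawn from the
    class mix; each subject's FMA-UE is uniform inside the class's band, so
    ground truth derived from FMA agrees with the generating class.
    """
    rng = np.random.default_rng(spec.seed)
    classes = sorted(spec.class_mix)
    probs = np.array([spec.class_mix[c] for c in classes])
    records = []
    for si in range(spec.n_subjects):
        severity = str(rng.choice(classes, p=probs))
        lo, hi = FMA_BANDS[severity]
        fma = int(rng.integers(lo, hi + 1))
        sid = f"S{si:03d}"
        trials = [
            _synth_trial(spec, sid, task, rep, severity, rng)
            for task in TASKS
            for rep in (1, 2, 3)
        ]
        records.append(
            SubjectRecord(
                subject_id=sid,
                fma_ue=fma,
                affected_side=str(rng.choice(["left", "right"])),
                trials=trials,
            )
        )
    return records


def generate_toy_ensemble(
    n: int, k: int, agreement: float, T: int, seed: int = 0
) -> tuple[PartitionEnsemble, np.ndarray]:
    """Planted-partition ensemble for exercising the consensus solvers.

    A planted labeling over n instances is copied T times; each member
    relabels each instance uniformly at random (over all k labels) with
    probability 1 - agreement, so the expected number of actually changed
    labels per member is n (1 - agreement)(1 - 1/k).  Returns the ensemble
    and the planted truth.
    """
    if n < k:
        raise ValidationError("need n >= k")
    if not 0.0 <= agreement <= 1.0:
        raise ValidationError("agreement must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    # planted labels: every cluster non-empty, remainder uniform
    planted = np.concatenate(
        [np.arange(k), rng.integers(0, k, size=n - k)]
    )
    rng.shuffle(planted)
    members = []
    for t in range(T):
        labels = planted.copy()
        flip = rng.random(n) < (1.0 - agreement)
        labels[flip] = rng.integers(0, k, size=int(flip.sum()))
        members.append(Partition(labels=labels, k=k, method=f"member{t}", seed=seed))
    return PartitionEnsemble(members), planted


__all__ = [
    "CohortSpec", "FMA_BANDS", "DEFAULT_AMPLITUDES", "DEFAULT_JITTER",
    "DEFAULT_REACH", "SEVERITY_ORDER", "minimum_jerk",
    "generate_cohort", "generate_toy_ensemble",
]
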
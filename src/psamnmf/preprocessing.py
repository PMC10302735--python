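"""Signal conditioning and frequency-domain feature construction.

Pipeline per trial: zero-phase second-order Butterworth low-pass (10 Hz
wearable / 20 Hz camera) -> linear acceleration by central second
differences -> orientation-free 1-D magnitude sqrt(X^2+Y^2+Z^2) ->
fixed-length magnitude-spectrum feature vectors.  Three feature spaces are
exposed: position spectra, acceleration-magnitude spectra (plus the trial
mean of the magnitude series), and their column concatenation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .motion_io import (
    DEVICE_FEATURE_CHANNELS,
    FilteredTrial,
    MotionTrial,
    PipelineConfig,
    SubjectRecord,
    ValidationError,
    all_trials,
)


class ParameterError(ValueError):
    """A filter or feature parameter is out of range."""


@dataclass
class ScalarSeries:
    """A 1-D derived series (acceleration magnitude or trunk displacement)."""

    values: np.ndarray
    kind: str  # accel_magnitude | trunk_displacement
    sampling_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind == "accel_magnitude" and np.any(self.values < 0):
            raise ValidationError("acceleration magnitude must be nonnegative")


@dataclass
class FeatureMatrix:
    """Instances (trials) x features, nonnegative, with aligned index."""

    X: np.ndarray
    feature_kind: str
    instance_index: list[tuple[str, str, int]]
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValidationError("feature matrix must be 2-D")
        if self.X.shape[0] != len(self.instance_index):
            raise ValidationError("rows misaligned with instance_index")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("feature matrix contains non-finite values")

    @property
    def n_instances(self) -> int:
        return self.X.shape[0]


# ---------------------------------------------------------------------------
# Filtering and differentiation
# ---------------------------------------------------------------------------


def butterworth_lowpass(trial: MotionTrial, cutoff: float) -> FilteredTrial:
    """Zero-phase second-order Butterworth low-pass on every channel axis.

    Applied forward-backward (``filtfilt``), so the single-pass -3 dB point
    becomes a gain of 0.5 at the cutoff and no phase lag is introduced —
    trunk-displacement timing is preserved.
    """
    nyquist = trial.sampling_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ParameterError(f"cutoff {cutoff} Hz must lie in (0, {nyquist}) Hz")
    order = 2
    if trial.n_samples < 3 * order:
        raise ParameterError(f"trial too short ({trial.n_samples}) for order-{order} filter")
    b, a = sps.butter(order, cutoff / nyquist, btype="low")
    channels = {
        name: sps.filtfilt(b, a, series, axis=0)
        for name, series in trial.channels.items()
    }
    return FilteredTrial(
        subject_id=trial.subject_id,
        device=trial.device,
        task=trial.task,
        repetition=trial.repetition,
        sampling_rate=trial.sampling_rate,
        channels=channels,
        trunk_channels=trial.trunk_channels,
        filter_order=order,
        filter_cutoff_hz=cutoff,
        zero_phase=True,
    )


def second_difference(series: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Second time derivative by central second differences, length-preserving.

    Interior: (x[i-1] - 2 x[i] + x[i+1]) * fs^2 — exact for quadratics.
    Endpoints reuse the one-sided second difference of the adjacent triple.
    """
    x = np.asarray(series, dtype=float)
    if x.shape[0] < 3:
        raise ParameterError("need at least 3 samples to differentiate twice")
    fs2 = sampling_rate**2
    acc = np.empty_like(x)
    acc[1:-1] = (x[:-2] - 2 * x[1:-1] + x[2:]) * fs2
    acc[0] = (x[0] - 2 * x[1] + x[2]) * fs2
    acc[-1] = (x[-3] - 2 * x[-2] + x[-1]) * fs2
    return acc


def derive_acceleration(trial: MotionTrial) -> dict[str, np.ndarray]:
    """Per-channel 3-D linear acceleration (mm/s^2) from position."""
    return {
        name: second_difference(series, trial.sampling_rate)
        for name, series in trial.channels.items()
    }


def magnitude_1d(acc3d: np.ndarray, sampling_rate: float = float("nan")) -> ScalarSeries:
    """Per-sample Euclidean norm sqrt(X^2 + Y^2 + Z^2) of a 3-D series.

    Collapses the three axes to one orientation-independent magnitude, so the
    result does not depend on how the sensor frame was mounted.
    """
    a = np.asarray(acc3d, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValidationError("expected a (T, 3) series")
    if not np.all(np.isfinite(a)):
        raise ValidationError("non-finite values in 3-D series")
    return ScalarSeries(np.linalg.norm(a, axis=1), "accel_magnitude", sampling_rate)


# ---------------------------------------------------------------------------
# Frequency features
# ---------------------------------------------------------------------------


def onesided_spectrum(series: np.ndarray) -> np.ndarray:
    """Magnitudes of the one-sided DFT of the mean-removed series."""
    x = np.asarray(series, dtype=float)
    return np.abs(np.fft.rfft(x - x.mean()))


def frequency_features(
    series: np.ndarray, n_bins: int, band_limit: float = 1.0
) -> np.ndarray:
    """Fixed-length spectral summary of a 1-D series.

    The one-sided magnitude spectrum of the mean-removed series is collapsed
    into ``n_bins`` contiguous frequency bands by root-sum-of-squares (so a
    pure tone stays concentrated in one output bin and band energies add),
    then scaled to unit Euclidean norm.  A constant series yields the zero
    vector.  Trials of different lengths thus map to comparable vectors.

    ``band_limit`` is the covered fraction of the Nyquist frequency: after
    low-pass filtering there is no energy above the cutoff, so the feature
    bands cover only the passband (the pipeline passes cutoff / Nyquist)
    instead of wasting resolution on empty spectrum.
    """
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2")
    if not 0 < band_limit <= 1.0:
        raise ParameterError("band_limit must lie in (0, 1]")
    x = np.asarray(series, dtype=float)
    if x.shape[0] < n_bins:
        raise ParameterError(f"series length {x.shape[0]} < n_bins {n_bins}")
    mags = onesided_spectrum(x)
    top = max(n_bins, int(round(band_limit * mags.shape[0])))
    # band edges over the one-sided spectrum (DC bin is ~0 after mean removal)
    edges = np.linspace(0, top, n_bins + 1).round().astype(int)
    feats = np.array(
        [np.sqrt(np.sum(mags[lo:hi] ** 2)) for lo, hi in zip(edges[:-1], edges[1:])]
    )
    norm = np.linalg.norm(feats)
    if norm < 1e-300:
        return np.zeros(n_bins)
    return feats / norm


# ---------------------------------------------------------------------------
# Feature-matrix assembly
# ---------------------------------------------------------------------------


def _position_row(trial: FilteredTrial, feature_channels, n_bins: int, band_limit: float):
    feats, names = [], []
    for channel in feature_channels:
        series = trial.channels[channel]
        for ai, axis in enumerate("xyz"):
            feats.append(frequency_features(series[:, ai], n_bins, band_limit))
            names.extend(f"pos:{channel}:{axis}:b{j}" for j in range(n_bins))
    return np.concatenate(feats), names


def _accel_row(trial: FilteredTrial, feature_channels, n_bins: int, band_limit: float):
    acc = derive_acceleration(trial)
    feats, names = [], []
    for channel in feature_channels:
        mag = magnitude_1d(acc[channel], trial.sampling_rate)
        feats.append(frequency_features(mag.values, n_bins, band_limit))
        names.extend(f"acc:{channel}:b{j}" for j in range(n_bins))
        # trial-mean of the magnitude series: the one amplitude-bearing column
        feats.append([mag.values.mean()])
        names.append(f"acc:{channel}:mean")
    return np.concatenate(feats), names


def build_feature_matrix(
    records: list[SubjectRecord], cfg: PipelineConfig
) -> FeatureMatrix:
    """One feature row per trial, in the configured feature space.

    Wearable profile: 5 segments x 3 axes = 15 position channels; camera
    profile: 9 markers x 3 = 27 (the 4 trunk markers feed labeling only).
    """
    trials = all_trials(records)
    if not trials:
        raise ValidationError("no trials in cohort")
    devices = {t.device for t in trials}
    if len(devices) != 1:
        raise ValidationError(f"mixed device profiles in cohort: {sorted(devices)}")
    device = devices.pop()
    if device != cfg.device_profile:
        raise ValidationError(
            f"cohort device {device!r} != configured profile {cfg.device_profile!r}"
        )
    feature_channels = DEVICE_FEATURE_CHANNELS[device]
    cutoff = cfg.effective_cutoff_hz
    n_bins = cfg.n_freq_bins
    band_limit = cutoff / (trials[0].sampling_rate / 2.0)

    rows, index = [], []
    pos_names = acc_names = None
    for trial in trials:
        filtered = butterworth_lowpass(trial, cutoff)
        parts = []
        if cfg.feature_kind in ("position_freq", "merged"):
            row, pos_names = _position_row(filtered, feature_channels, n_bins, band_limit)
            parts.append(row)
        if cfg.feature_kind in ("accel_freq", "merged"):
            row, acc_names = _accel_row(filtered, feature_channels, n_bins, band_limit)
            parts.append(row)
        rows.append(np.concatenate(parts))
        index.append(trial.key)

    names = (pos_names or []) + (acc_names or [])
    return FeatureMatrix(np.vstack(rows), cfg.feature_kind, index, names)


def feature_matrix_to_frame(fm: FeatureMatrix):
    """FeatureMatrix as a DataFrame with index columns, for CSV export."""
    import pandas as pd

    df = pd.DataFrame(fm.X, columns=fm.feature_names or None)
    idx = pd.DataFrame(fm.instance_index, columns=["subject_id", "task", "repetition"])
    return pd.concat([idx, df], axis=1)


__all__ = [
    "ScalarSeries", "FeatureMatrix", "ParameterError",
    "butterworth_lowpass", "second_difference", "derive_acceleration",
    "magnitude_1d", "onesided_spectrum", "frequency_features",
    "build_feature_matrix", "feature_matrix_to_frame",
]
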
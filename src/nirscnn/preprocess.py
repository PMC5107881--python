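"""Preprocessing chain: low-pass -> moving average -> 1-s feature means -> min-max.

Turns a raw per-channel oxy-Hb series into the 1 x N feature vector the
classifier consumes.  The chain order is fixed; because the final min-max
normalization removes per-subject scale and offset, the extracted features
are invariant to affine rescaling of the raw signal (which is the point:
optical path length differences make absolute fNIRS amplitudes
incomparable across subjects).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .data import FeatureSeries, FnirsRecording

__all__ = [
    "PreprocessParams",
    "lowpass_filter",
    "moving_average",
    "extract_features",
    "minmax_normalize",
    "preprocess_recording",
    "features_by_channel",
    "write_features",
    "read_features",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the preprocessing chain.

    Defaults: 1.0 Hz low-pass (zero-phase Butterworth of order
    ``filter_order``), 10 s moving average, non-overlapping 1 s feature
    windows over 200 s starting at task onset (``start_s=None``).
    """

    cutoff_hz: float = 1.0
    filter_order: int = 4
    moving_avg_s: float = 10.0
    feature_window_s: float = 1.0
    start_s: Optional[float] = None
    duration_s: float = 200.0

    def __post_init__(self) -> None:
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be positive")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.moving_avg_s <= 0:
            raise ValueError("moving_avg_s must be positive")
        if self.feature_window_s <= 0:
            raise ValueError("feature_window_s must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


def lowpass_filter(
    series: np.ndarray,
    sampling_rate_hz: float,
    cutoff_hz: float = 1.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass.

    Applied forward and backward (``sosfiltfilt``) so response peaks are
    not shifted relative to task events; the effective attenuation is
    twice the single-pass roll-off.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    if not 0 < cutoff_hz < sampling_rate_hz / 2:
        raise ValueError(
            f"cutoff_hz must lie in (0, Nyquist={sampling_rate_hz / 2} Hz)"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=sampling_rate_hz, output="sos")
    return signal.sosfiltfilt(sos, series, axis=-1)


def moving_average(
    series: np.ndarray, sampling_rate_hz: float, window_s: float = 10.0
) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges.

    The window spans ``round(window_s * sampling_rate_hz)`` samples; for a
    window of w samples, output i averages samples
    ``[i - (w-1)//2, i + w//2]`` clipped to the series.  A one-sample
    window is the identity.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    w = int(round(window_s * sampling_rate_hz))
    if w < 1:
        raise ValueError("window must cover at least one sample")
    if w == 1:
        return series.copy()
    n = series.shape[-1]
    idx = np.arange(n)
    lo = np.clip(idx - (w - 1) // 2, 0, n)
    hi = np.clip(idx + w // 2 + 1, 0, n)
    csum = np.concatenate(
        [np.zeros(series.shape[:-1] + (1,)), np.cumsum(series, axis=-1)], axis=-1
    )
    return (csum[..., hi] - csum[..., lo]) / (hi - lo)


def extract_features(
    series: np.ndarray,
    sampling_rate_hz: float,
    window_s: float = 1.0,
    start_s: float = 0.0,
    duration_s: float = 200.0,
    *,
    channel: str = "",
    subject: str = "",
    label: Optional[int] = None,
) -> FeatureSeries:
    """Average the series over non-overlapping windows after ``start_s``.

    Yields ``N = duration_s / window_s`` features, feature i being the
    mean of the samples in the i-th window (at 10 Hz and 1 s windows this
    is a 10x downsampling to one value per second).
    """
    series = np.asarray(series, dtype=float)
    n_windows = duration_s / window_s
    if abs(n_windows - round(n_windows)) > 1e-9:
        raise ValueError("duration_s must be an integer multiple of window_s")
    n_windows = int(round(n_windows))
    samples_per_window = window_s * sampling_rate_hz
    if abs(samples_per_window - round(samples_per_window)) > 1e-9:
        raise ValueError("window_s must cover an integer number of samples")
    samples_per_window = int(round(samples_per_window))
    if samples_per_window < 1:
        raise ValueError("window_s must cover at least one sample")
    start = int(round(start_s * sampling_rate_hz))
    stop = start + n_windows * samples_per_window
    if start < 0 or stop > series.shape[-1]:
        raise ValueError(
            f"feature window [{start_s} s, {start_s + duration_s} s) extends "
            "past the recording"
        )
    values = series[start:stop].reshape(n_windows, samples_per_window).mean(axis=1)
    return FeatureSeries(values=values, channel=channel, subject=subject, label=label)


def minmax_normalize(features: FeatureSeries | np.ndarray):
    """Min-max normalize to [0, 1].

    A constant (min == max) series is mapped to all 0.5 with a warning —
    degenerate but non-fatal, so noise-free null simulations do not crash
    the pipeline.
    """
    if isinstance(features, FeatureSeries):
        return features.with_values(minmax_normalize(features.values))
    x = np.asarray(features, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn("constant series: min-max normalization maps to 0.5", stacklevel=2)
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def preprocess_recording(
    rec: FnirsRecording, params: PreprocessParams = PreprocessParams()
) -> list[FeatureSeries]:
    """Run the full chain on every channel of one recording.

    Returns one normalized :class:`FeatureSeries` per channel, in channel
    order.  Normalization is per subject and per channel over the
    extracted window, so no statistic crosses subjects (no train/test
    leakage is possible downstream).
    """
    start_s = rec.task_onset_s if params.start_s is None else params.start_s
    filtered = lowpass_filter(
        rec.data, rec.sampling_rate_hz, params.cutoff_hz, params.filter_order
    )
    smoothed = moving_average(filtered, rec.sampling_rate_hz, params.moving_avg_s)
    out = []
    for i, ch in enumerate(rec.channel_labels):
        feats = extract_features(
            smoothed[i],
            rec.sampling_rate_hz,
            window_s=params.feature_window_s,
            start_s=start_s,
            duration_s=params.duration_s,
            channel=ch,
            subject=rec.subject,
            label=rec.label,
        )
        out.append(minmax_normalize(feats))
    return out


def features_by_channel(
    recordings: Sequence[FnirsRecording],
    params: PreprocessParams = PreprocessParams(),
) -> dict[str, list[FeatureSeries]]:
    """Preprocess a cohort and group the feature series by channel."""
    if not recordings:
        raise ValueError("no recordings given")
    by_channel: dict[str, list[FeatureSeries]] = {
        ch: [] for ch in recordings[0].channel_labels
    }
    for rec in recordings:
        if rec.channel_labels != recordings[0].channel_labels:
            raise ValueError("recordings have inconsistent channel labels")
        for feats in preprocess_recording(rec, params):
            by_channel[feats.channel].append(feats)
    return by_channel


def write_features(
    by_channel: dict[str, list[FeatureSeries]],
    out_dir: str | Path,
    params: Optional[PreprocessParams] = None,
) -> Path:
    """Write one subjects x N table per channel plus a JSON sidecar.

    The sidecar records the channel list, parameters and the
    subject -> label map.  Returns the sidecar path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    label_map: dict[str, Optional[int]] = {}
    for ch, series_list in by_channel.items():
        df = pd.DataFrame(
            [fs.values for fs in series_list],
            index=pd.Index([fs.subject for fs in series_list], name="subject"),
        )
        df.columns = [f"f{i}" for i in range(df.shape[1])]
        df.to_csv(out / f"{ch}.features.tsv", sep="\t", float_format="%.12g")
        for fs in series_list:
            label_map[fs.subject] = fs.label
    sidecar = {
        "channels": list(by_channel),
        "labels": label_map,
        "params": asdict(params) if params is not None else None,
    }
    path = out / "features_meta.json"
    path.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return path


def read_features(in_dir: str | Path) -> dict[str, list[FeatureSeries]]:
    """Read feature tables written by :func:`write_features`."""
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "features_meta.json").read_text())
    by_channel: dict[str, list[FeatureSeries]] = {}
    for ch in meta["channels"]:
        df = pd.read_csv(in_dir / f"{ch}.features.tsv", sep="\t", index_col="subject")
        by_channel[ch] = [
            FeatureSeries(
                values=row.to_numpy(),
                channel=ch,
                subject=str(subj),
                label=meta["labels"].get(str(subj)),
            )
            for subj, row in df.iterrows()
        ]
    return by_channel
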
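"""Core in-memory containers: per-subject recordings and per-channel feature vectors.

An :class:`FnirsRecording` holds the multi-channel oxy-hemoglobin
concentration-change time series of a single subject, together with the
sampling rate, the time the task block begins, and (optionally) a binary
group label.  A :class:`FeatureSeries` is the 1 x N vector a single
channel contributes to the classifier after preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = ["FnirsRecording", "FeatureSeries"]


@dataclass
class FnirsRecording:
    """Multi-channel oxy-Hb change recording for one subject.

    Parameters
    ----------
    data:
        Array of shape ``(n_channels, n_samples)`` holding relative oxy-Hb
        concentration change per channel (arbitrary relative units; fNIRS
        has no absolute baseline).
    sampling_rate_hz:
        Sampling frequency in Hz.
    channel_labels:
        One identifier per row of ``data`` (``"CH1"`` .. ``"CH24"`` by
        convention).
    task_onset_s:
        Time in seconds at which the task period starts (end of the
        initial rest phase).
    label:
        Binary group label (0 or 1), or ``None`` for unlabeled data.
    subject:
        Subject identifier.
    """

    data: np.ndarray
    sampling_rate_hz: float
    channel_labels: list[str]
    task_onset_s: float = 0.0
    label: Optional[int] = None
    subject: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (n_channels, n_samples) array")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.data.shape[0]} data rows"
            )
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not (0.0 <= self.task_onset_s <= self.duration_s):
            raise ValueError("task_onset_s must lie within the recording")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError("label must be 0, 1 or None")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (first sample at t=0)."""
        return np.arange(self.n_samples) / self.sampling_rate_hz

    def channel(self, label: str) -> np.ndarray:
        """Return the time series of one channel by its label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r}") from None
        return self.data[idx]


@dataclass
class FeatureSeries:
    """The 1 x N normalized feature vector of one channel of one subject."""

    values: np.ndarray
    channel: str = ""
    subject: str = ""
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if self.values.size < 1:
            raise ValueError("values must be non-empty")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError("label must be 0, 1 or None")

    def __len__(self) -> int:
        return self.values.size

    def with_values(self, values: np.ndarray) -> "FeatureSeries":
        """Copy of this series with new values, metadata preserved."""
        return replace(self, values=np.asarray(values, dtype=float))
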
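"""Synthetic two-group fNIRS cohort generator.

Real fNIRS group studies rarely deposit raw recordings, so every stage of
the channel-ranking pipeline is exercised here against simulated cohorts
with *known* ground truth: a configurable subset of channels carries a
group-dependent hemodynamic response, all other channels are statistically
identical between groups.

The generative model is deliberately minimal but physiologically shaped:

* a block-design task schedule (rest / repeated memorize-retain-respond
  trials / rest) drives a neural boxcar with phase-dependent amplitude;
* the boxcar is convolved with a double-gamma hemodynamic response
  function to give the delayed oxy-Hb rise;
* the group effect is a time-varying amplitude difference concentrated in
  a configurable fraction of the task period (by default the second half,
  where group 1's response ramps *down* relative to group 0);
* confounds are additive: white sensor noise, a slow sinusoidal drift and
  sinusoidal physiological components (cardiac ~1 Hz, respiratory ~0.3 Hz,
  Mayer waves ~0.1 Hz) with per-subject, per-channel random phases.

Everything is deterministic given the configured seed; per-subject seeds
are derived from the cohort seed so any subject can be regenerated alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import FnirsRecording

__all__ = [
    "TaskSchedule",
    "NoiseSpec",
    "SimulationConfig",
    "hemodynamic_kernel",
    "neural_drive",
    "group_effect_template",
    "simulate_subject",
    "simulate_cohort",
    "subject_seed",
    "write_cohort",
    "load_cohort",
]


@dataclass(frozen=True)
class TaskSchedule:
    """Block-design timing: rest, repeated trials, rest.

    Defaults reproduce a number-memory protocol: 30 s rest, 30 trials of
    3 s memorize / 1 s retain / 7 s respond, then 30 s rest (390 s total).
    """

    pre_rest_s: float = 30.0
    n_trials: int = 30
    memorize_s: float = 3.0
    retain_s: float = 1.0
    respond_s: float = 7.0
    post_rest_s: float = 30.0

    def __post_init__(self) -> None:
        for name in ("pre_rest_s", "memorize_s", "retain_s", "respond_s", "post_rest_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def trial_s(self) -> float:
        return self.memorize_s + self.retain_s + self.respond_s

    @property
    def task_duration_s(self) -> float:
        return self.n_trials * self.trial_s

    @property
    def total_duration_s(self) -> float:
        return self.pre_rest_s + self.task_duration_s + self.post_rest_s

    @property
    def task_onset_s(self) -> float:
        return self.pre_rest_s


@dataclass(frozen=True)
class NoiseSpec:
    """Additive confounds of the simulated oxy-Hb signal.

    Amplitudes are in the same relative oxy-Hb units as the task response
    (whose peak amplitude is 1 by default).  Sinusoidal components get a
    random phase per subject and channel; setting an amplitude to 0
    removes that component.
    """

    white_sd: float = 0.2
    drift_amplitude: float = 0.3
    drift_period_s: float = 300.0
    cardiac_hz: float = 1.1
    respiratory_hz: float = 0.3
    mayer_hz: float = 0.1
    physio_amplitudes: tuple[float, float, float] = (0.10, 0.10, 0.15)

    def __post_init__(self) -> None:
        object.__setattr__(self, "physio_amplitudes", tuple(self.physio_amplitudes))
        amps = (self.white_sd, self.drift_amplitude, *self.physio_amplitudes)
        if any(a < 0 for a in amps):
            raise ValueError("noise amplitudes must be >= 0")
        if self.drift_period_s <= 0:
            raise ValueError("drift_period_s must be positive")
        if len(self.physio_amplitudes) != 3:
            raise ValueError("physio_amplitudes must give (cardiac, respiratory, mayer)")

    @classmethod
    def silent(cls) -> "NoiseSpec":
        """All noise amplitudes zero (deterministic task response only)."""
        return cls(white_sd=0.0, drift_amplitude=0.0, physio_amplitudes=(0.0, 0.0, 0.0))


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a simulated two-group cohort.

    ``discriminative_channels`` are 1-based channel numbers; only these
    carry the group effect.  ``effect_window`` is the fraction of the task
    period (0 = task onset, 1 = task end) over which the group difference
    ramps in; the default (0.5, 1.0) concentrates the divergence in the
    latter half of the task.
    """

    n_per_group: int = 11
    n_channels: int = 24
    sampling_rate_hz: float = 10.0
    schedule: TaskSchedule = field(default_factory=TaskSchedule)
    discriminative_channels: frozenset[int] = frozenset({5, 20})
    effect_amplitude: float = 0.6
    effect_window: tuple[float, float] = (0.5, 1.0)
    task_amplitude: float = 1.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        object.__setattr__(
            self, "discriminative_channels", frozenset(self.discriminative_channels)
        )
        object.__setattr__(self, "effect_window", tuple(self.effect_window))
        bad = [c for c in self.discriminative_channels
               if not (1 <= c <= self.n_channels)]
        if bad:
            raise ValueError(
                f"discriminative_channels {sorted(bad)} outside 1..{self.n_channels}"
            )
        if self.effect_amplitude < 0:
            raise ValueError("effect_amplitude must be >= 0")
        lo, hi = self.effect_window
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("effect_window must satisfy 0 <= lo < hi <= 1")
        nyquist = self.sampling_rate_hz / 2
        for name in ("cardiac_hz", "respiratory_hz", "mayer_hz"):
            if getattr(self.noise, name) >= nyquist:
                raise ValueError(f"noise.{name} must be below the Nyquist frequency")

    @property
    def n_samples(self) -> int:
        return int(round(self.schedule.total_duration_s * self.sampling_rate_hz))

    @property
    def channel_labels(self) -> list[str]:
        return [f"CH{i}" for i in range(1, self.n_channels + 1)]


def hemodynamic_kernel(
    sampling_rate_hz: float,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
    duration_s: Optional[float] = None,
) -> np.ndarray:
    """Double-gamma hemodynamic impulse response, peak normalized to 1.

    The response is the difference of two gamma densities with modes at
    ``peak_s`` and ``undershoot_s`` (unit time scale), the second scaled
    by ``undershoot_ratio``.  With ``undershoot_ratio=0`` the kernel is a
    nonnegative single-gamma response.
    """
    if sampling_rate_hz <= 0:
        raise ValueError("sampling_rate_hz must be positive")
    if peak_s <= 0 or undershoot_s <= 0:
        raise ValueError("peak_s and undershoot_s must be positive")
    if not peak_s < undershoot_s:
        raise ValueError("peak_s must be smaller than undershoot_s")
    if undershoot_ratio < 0:
        raise ValueError("undershoot_ratio must be >= 0")
    if duration_s is None:
        duration_s = undershoot_s + 16.0
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    t = np.arange(int(round(duration_s * sampling_rate_hz))) / sampling_rate_hz
    # gamma pdf with scale 1 has its mode at shape-1, so shape = peak + 1
    kernel = stats.gamma.pdf(t, peak_s + 1.0) \
        - undershoot_ratio * stats.gamma.pdf(t, undershoot_s + 1.0)
    peak = kernel.max()
    if peak <= 0:
        raise ValueError("degenerate kernel (non-positive peak)")
    return kernel / peak


def neural_drive(schedule: TaskSchedule, sampling_rate_hz: float) -> np.ndarray:
    """Per-sample neural activity of the block design.

    Amplitude 1.0 while memorizing, 0.6 while retaining, 0.8 while
    responding, 0 at rest — the phase structure puts a small ripple at the
    trial frequency on top of the sustained task block.
    """
    n = int(round(schedule.total_duration_s * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz
    drive = np.zeros(n)
    for trial in range(schedule.n_trials):
        t0 = schedule.pre_rest_s + trial * schedule.trial_s
        for dur, amp in (
            (schedule.memorize_s, 1.0),
            (schedule.retain_s, 0.6),
            (schedule.respond_s, 0.8),
        ):
            drive[(t >= t0) & (t < t0 + dur)] = amp
            t0 += dur
    return drive


def _effect_ramp(config: SimulationConfig) -> np.ndarray:
    """Per-sample weight of the group effect: 0 before the effect window,
    ramping linearly to 1 across it."""
    sched = config.schedule
    t = np.arange(config.n_samples) / config.sampling_rate_hz
    lo, hi = config.effect_window
    w0 = sched.task_onset_s + lo * sched.task_duration_s
    w1 = sched.task_onset_s + hi * sched.task_duration_s
    return np.clip((t - w0) / (w1 - w0), 0.0, 1.0)


def _hrf_responses(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """(common task response, unit effect response), both length n_samples.

    The HRF is area-normalized before convolution so a sustained unit
    drive plateaus near 1; the common response is then scaled by
    ``task_amplitude``.
    """
    fs = config.sampling_rate_hz
    hrf = hemodynamic_kernel(fs)
    hrf = hrf / hrf.sum()
    drive = neural_drive(config.schedule, fs)
    ramp = _effect_ramp(config)
    n = config.n_samples
    common = np.convolve(drive, hrf)[:n] * config.task_amplitude
    effect = np.convolve(drive * ramp, hrf)[:n]
    return common, effect


def group_effect_template(config: SimulationConfig) -> np.ndarray:
    """Designed noise-free signal difference (group 0 minus group 1) on a
    discriminative channel; zero on all other channels."""
    _, effect = _hrf_responses(config)
    return config.effect_amplitude * effect


def simulate_subject(
    config: SimulationConfig, group_label: int, subject_seed: int
) -> FnirsRecording:
    """Simulate one subject's multi-channel recording.

    Group 0 carries +effect/2 and group 1 -effect/2 on the discriminative
    channels, so the designed between-group difference equals
    :func:`group_effect_template`.  All random draws (noise, phases) are
    independent of ``group_label``: with ``effect_amplitude=0`` the two
    groups are drawn from the identical distribution.
    """
    if group_label not in (0, 1):
        raise ValueError("group_label must be 0 or 1")
    rng = np.random.default_rng(subject_seed)
    n = config.n_samples
    n_ch = config.n_channels
    fs = config.sampling_rate_hz
    t = np.arange(n) / fs

    common, effect = _hrf_responses(config)
    sign = 1.0 if group_label == 0 else -1.0
    data = np.tile(common, (n_ch, 1))
    for ch in config.discriminative_channels:
        data[ch - 1] += sign * 0.5 * config.effect_amplitude * effect

    spec = config.noise
    # draw order is fixed and group-independent
    data += rng.normal(0.0, 1.0, (n_ch, n)) * spec.white_sd
    components = [
        (spec.drift_amplitude, 1.0 / spec.drift_period_s),
        (spec.physio_amplitudes[0], spec.cardiac_hz),
        (spec.physio_amplitudes[1], spec.respiratory_hz),
        (spec.physio_amplitudes[2], spec.mayer_hz),
    ]
    for amp, freq in components:
        phases = rng.uniform(0.0, 2.0 * np.pi, n_ch)
        data += amp * np.sin(2.0 * np.pi * freq * t[None, :] + phases[:, None])

    return FnirsRecording(
        data=data,
        sampling_rate_hz=fs,
        channel_labels=config.channel_labels,
        task_onset_s=config.schedule.task_onset_s,
        label=group_label,
        subject=f"G{group_label}S{subject_seed % 100:02d}",
    )


def subject_seed(config_seed: int, group_label: int, index: int) -> int:
    """Deterministic per-subject seed derived from the cohort seed."""
    ss = np.random.SeedSequence([int(config_seed), int(group_label), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cohort(config: SimulationConfig) -> list[FnirsRecording]:
    """Simulate the full cohort: ``n_per_group`` subjects per label, group
    0 first.  Bit-identical for identical configs."""
    recordings: list[FnirsRecording] = []
    counter = 0
    for group in (0, 1):
        for i in range(config.n_per_group):
            counter += 1
            rec = simulate_subject(config, group, subject_seed(config.seed, group, i))
            rec.subject = f"S{counter:02d}"
            recordings.append(rec)
    return recordings


def _config_to_jsonable(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["discriminative_channels"] = sorted(config.discriminative_channels)
    d["effect_window"] = list(config.effect_window)
    d["noise"]["physio_amplitudes"] = list(config.noise.physio_amplitudes)
    return d


def config_from_jsonable(d: dict) -> SimulationConfig:
    """Inverse of the manifest's config echo."""
    d = dict(d)
    d["schedule"] = TaskSchedule(**d["schedule"])
    noise = dict(d["noise"])
    noise["physio_amplitudes"] = tuple(noise["physio_amplitudes"])
    d["noise"] = NoiseSpec(**noise)
    d["discriminative_channels"] = frozenset(d["discriminative_channels"])
    d["effect_window"] = tuple(d["effect_window"])
    return SimulationConfig(**d)


def write_cohort(
    recordings: Sequence[FnirsRecording],
    out_dir: str | Path,
    config: Optional[SimulationConfig] = None,
) -> Path:
    """Write one delimited text file per subject plus a JSON manifest.

    Each subject file has a ``time_s`` column followed by one column per
    channel.  Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in recordings:
        fname = f"{rec.subject}.tsv"
        df = pd.DataFrame(
            {"time_s": rec.times, **{lab: rec.data[i] for i, lab in enumerate(rec.channel_labels)}}
        )
        df.to_csv(out / fname, sep="\t", index=False, float_format="%.8g")
        entries.append(
            {
                "subject": rec.subject,
                "file": fname,
                "label": rec.label,
                "sampling_rate_hz": rec.sampling_rate_hz,
                "task_onset_s": rec.task_onset_s,
            }
        )
    manifest = {"subjects": entries}
    if config is not None:
        manifest["config"] = _config_to_jsonable(config)
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def load_cohort(in_dir: str | Path) -> list[FnirsRecording]:
    """Read a cohort written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    recordings = []
    for entry in manifest["subjects"]:
        df = pd.read_csv(in_dir / entry["file"], sep="\t")
        labels = [c for c in df.columns if c != "time_s"]
        recordings.append(
            FnirsRecording(
                data=df[labels].to_numpy().T,
                sampling_rate_hz=entry["sampling_rate_hz"],
                channel_labels=labels,
                task_onset_s=entry["task_onset_s"],
                label=entry["label"],
                subject=entry["subject"],
            )
        )
    return recordings
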
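"""Channel-wise LOOCV classification and region-of-interest selection.

One classifier is trained per measurement channel under leave-one-out
cross-validation: every subject serves once as the held-out test case
while all remaining subjects train a freshly initialized model.  The mean
per-fold correctness is the channel's identification rate; channels are
ranked by it and the top group forms the ROI (the seed region for any
downstream group analysis).

Per-fold initialization seeds are derived deterministically from a base
seed, the channel identifier and the fold index, so any single fold can
be reproduced in isolation and the whole procedure is exactly repeatable.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cnn import CNNConfig, predict, train, train_loocv
from .data import FeatureSeries

__all__ = [
    "FoldPrediction",
    "ChannelResult",
    "ROIReport",
    "fold_seed",
    "loocv_channel",
    "evaluate_channels",
    "rank_channels",
    "select_roi",
    "write_roi_report",
]


@dataclass(frozen=True)
class FoldPrediction:
    """Outcome of one LOOCV fold: the held-out subject's prediction."""

    subject: str
    true_label: int
    predicted_label: int
    probabilities: tuple[float, float]

    @property
    def correct(self) -> bool:
        return self.true_label == self.predicted_label


@dataclass
class ChannelResult:
    """Per-channel LOOCV outcome."""

    channel: str
    fold_predictions: list[FoldPrediction]
    accuracy: float

    def __post_init__(self) -> None:
        expected = float(np.mean([fp.correct for fp in self.fold_predictions]))
        if abs(self.accuracy - expected) > 1e-12:
            raise ValueError("accuracy must equal the mean per-fold correctness")


@dataclass
class ROIReport:
    """Ranked channels and the selected ROI set."""

    ranked: list[ChannelResult]
    selected: list[str] = field(default_factory=list)
    strategy: str = ""
    param: Optional[float] = None


def fold_seed(base_seed: int, channel: str, fold: int) -> int:
    """Deterministic per-fold initialization seed (< 2**31)."""
    ch_hash = zlib.crc32(str(channel).encode())
    ss = np.random.SeedSequence([int(base_seed), ch_hash, int(fold)])
    return int(ss.generate_state(1)[0] % (2**31))


def _check_classes(labels: np.ndarray) -> None:
    counts = {c: int((labels == c).sum()) for c in (0, 1)}
    thin = [c for c, n in counts.items() if n < 2]
    if thin:
        raise ValueError(
            f"need >= 2 subjects per class for LOOCV (every training fold must "
            f"contain both classes); class counts {counts}"
        )


def loocv_channel(
    dataset: Sequence[FeatureSeries],
    channel: str,
    cnn_config: CNNConfig = CNNConfig(),
    base_seed: int = 0,
) -> ChannelResult:
    """Leave-one-out cross-validation of one channel's classifier.

    For each of the n subjects a model is trained from scratch on the
    other n-1 and evaluated on the held-out one; folds are disjoint and
    exhaustive by construction.  Per-subject min-max normalization happens
    upstream, so no preprocessing statistic leaks between train and test.
    """
    labels = np.array([fs.label for fs in dataset], dtype=int)
    _check_classes(labels)
    seeds = [fold_seed(base_seed, channel, s) for s in range(len(dataset))]
    if cnn_config.batch_mode == "full" and cnn_config.pool_len == cnn_config.pool_stride:
        X = np.array([fs.values for fs in dataset], dtype=float)
        models = train_loocv(X, labels, cnn_config, fold_seeds=seeds)
    else:
        models = [
            train([fs for i, fs in enumerate(dataset) if i != s],
                  cnn_config, seed=seeds[s])[0]
            for s in range(len(dataset))
        ]
    preds: list[FoldPrediction] = []
    for s, held_out in enumerate(dataset):
        pred, p = predict(models[s], held_out)
        preds.append(
            FoldPrediction(
                subject=held_out.subject or f"subject{s}",
                true_label=int(held_out.label),
                predicted_label=pred,
                probabilities=(float(p[0]), float(p[1])),
            )
        )
    accuracy = float(np.mean([fp.correct for fp in preds]))
    return ChannelResult(channel=channel, fold_predictions=preds, accuracy=accuracy)


def evaluate_channels(
    by_channel: dict[str, Sequence[FeatureSeries]],
    cnn_config: CNNConfig = CNNConfig(),
    base_seed: int = 0,
) -> list[ChannelResult]:
    """Run :func:`loocv_channel` for every channel, in channel order."""
    if not by_channel:
        raise ValueError("no channels given")
    return [
        loocv_channel(series, ch, cnn_config, base_seed)
        for ch, series in by_channel.items()
    ]


def rank_channels(results: Sequence[ChannelResult]) -> ROIReport:
    """Stable descending sort by identification rate.

    Ties are broken by the channels' position in the input sequence,
    which in normal use is ascending channel index.
    """
    if not results:
        raise ValueError("no channel results to rank")
    order = sorted(range(len(results)), key=lambda i: (-results[i].accuracy, i))
    return ROIReport(ranked=[results[i] for i in order])


def select_roi(
    report: ROIReport, strategy: str = "topk", param: float = 5
) -> ROIReport:
    """Select the ROI channel set from a ranked report.

    ``topk`` keeps the k best channels, including every channel tied with
    the k-th (so the set can exceed k); ``threshold`` keeps all channels
    with accuracy >= param.  Returns the report with ``selected`` filled.
    """
    if not report.ranked:
        raise ValueError("empty report")
    if strategy == "topk":
        k = int(param)
        if k <= 0:
            raise ValueError("k must be positive")
        k = min(k, len(report.ranked))
        cut = report.ranked[k - 1].accuracy
        selected = [r.channel for r in report.ranked if r.accuracy >= cut]
    elif strategy == "threshold":
        if not 0.0 <= param <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        selected = [r.channel for r in report.ranked if r.accuracy >= param]
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    report.selected = selected
    report.strategy = strategy
    report.param = float(param)
    return report


def write_roi_report(report: ROIReport, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the report as JSON plus a per-channel accuracy table.

    The TSV (channel, accuracy in ranked order) is the bar-plot-ready
    analogue of a per-channel identification-rate figure.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    doc = {
        "strategy": report.strategy,
        "param": report.param,
        "selected": report.selected,
        "ranked": [
            {
                "channel": r.channel,
                "accuracy": r.accuracy,
                "folds": [
                    {
                        "subject": fp.subject,
                        "true": fp.true_label,
                        "predicted": fp.predicted_label,
                        "probabilities": list(fp.probabilities),
                    }
                    for fp in r.fold_predictions
                ],
            }
            for r in report.ranked
        ],
    }
    json_path = out / "roi_report.json"
    json_path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    table = pd.DataFrame(
        {"channel": [r.channel for r in report.ranked],
         "accuracy": [r.accuracy for r in report.ranked]}
    )
    tsv_path = out / "channel_accuracy.tsv"
    table.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    return json_path, tsv_path
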
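"""Inspection of a trained channel classifier: what did the network learn?

Three views, mirroring the standard way a single-stage 1D CNN is read:

* the learned kernels themselves (each a short temporal template the
  network slides along the feature series);
* the pooling-layer activations averaged per class (where in the task
  each kernel fires, and how the two groups differ);
* the pooled activations multiplied elementwise by the fully connected
  weights feeding one output neuron (how much each time segment of each
  kernel's response actually pushes the decision).

A separation score — the absolute class-mean difference of the weighted
pooled outputs, summed over time — makes "which kernel discriminates
most" reproducible instead of a judgment by eye.  Kernel indices are
1-based throughout, matching the usual "filter 9" way of speaking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cnn import CNNModel, forward
from .data import FeatureSeries

__all__ = [
    "InterpretationBundle",
    "export_kernels",
    "pooled_outputs",
    "weighted_pooled_output",
    "most_discriminative_kernel",
    "build_bundle",
    "write_bundle",
    "plot_bundle",
]


@dataclass
class InterpretationBundle:
    """All interpretability outputs of one trained model on one dataset.

    ``pooled_by_class`` and ``weighted_pooled`` have shape (K, 2, P):
    kernel x class x pooled position.  ``inputs_by_class`` has shape
    (2, N) — the class-mean feature series.
    """

    kernel_profiles: np.ndarray         # (K, m)
    pooled_by_class: np.ndarray         # (K, 2, P)
    weighted_pooled: np.ndarray         # (K, 2, P)
    inputs_by_class: np.ndarray         # (2, N)
    output_neuron: int = 1
    best_kernel: int = 1                # 1-based
    best_kernel_score: float = 0.0


def export_kernels(model: CNNModel) -> np.ndarray:
    """The K learned kernel weight profiles, shape (K, m), in kernel order."""
    return model.kernels.copy()


def _pooled_per_subject(model: CNNModel, dataset: Sequence[FeatureSeries]
                        ) -> tuple[np.ndarray, np.ndarray]:
    """(pooled activations (S, K, P), labels (S,)) via the forward cache."""
    pooled, labels = [], []
    for fs in dataset:
        if fs.label is None:
            raise ValueError(f"unlabeled FeatureSeries {fs.subject!r}")
        _, cache = forward(model, fs)
        pooled.append(cache["pooled"])
        labels.append(fs.label)
    return np.array(pooled), np.array(labels, dtype=int)


def pooled_outputs(model: CNNModel, dataset: Sequence[FeatureSeries]
                   ) -> np.ndarray:
    """Class-mean pooled activations, shape (K, 2, P).

    Entry [k, c] is the elementwise mean over class-c subjects of kernel
    k's pooled activation sequence.
    """
    pooled, labels = _pooled_per_subject(model, dataset)
    out = np.empty((model.config.n_kernels, 2, model.pooled_len))
    for c in (0, 1):
        mask = labels == c
        if not mask.any():
            raise ValueError(f"no subjects of class {c} in dataset")
        out[:, c, :] = pooled[mask].mean(axis=0)
    return out


def _dense_slice(model: CNNModel, kernel_index: int, output_neuron: int
                 ) -> np.ndarray:
    K, P = model.config.n_kernels, model.pooled_len
    if not 1 <= kernel_index <= K:
        raise ValueError(f"kernel_index must lie in 1..{K}")
    if output_neuron not in (0, 1):
        raise ValueError("output_neuron must be 0 or 1")
    k = kernel_index - 1
    return model.dense_w[output_neuron, k * P:(k + 1) * P]


def weighted_pooled_output(
    model: CNNModel,
    dataset: Sequence[FeatureSeries],
    kernel_index: int,
    output_neuron: int = 1,
) -> np.ndarray:
    """Class-mean pooled sequence of one kernel, weighted by the dense layer.

    Shape (2, P): for each class, the pooled activation sequence of
    kernel ``kernel_index`` (1-based) multiplied elementwise by the
    fully connected weights that connect those pooled units to
    ``output_neuron``.  Linear in the dense weights by construction.
    """
    w = _dense_slice(model, kernel_index, output_neuron)
    pooled = pooled_outputs(model, dataset)  # (K, 2, P)
    return pooled[kernel_index - 1] * w[None, :]


def most_discriminative_kernel(
    model: CNNModel,
    dataset: Sequence[FeatureSeries],
    output_neuron: int = 1,
) -> tuple[int, float]:
    """Kernel (1-based) whose weighted pooled outputs differ most by class.

    Score = sum over pooled positions of |class-0 mean - class-1 mean| of
    the weighted pooled output; symmetric under swapping the class
    labels.  Ties resolve to the lowest kernel index.
    """
    pooled, labels = _pooled_per_subject(model, dataset)
    if not ((labels == 0).any() and (labels == 1).any()):
        raise ValueError("dataset must contain both classes")
    K, P = model.config.n_kernels, model.pooled_len
    diff = pooled[labels == 0].mean(axis=0) - pooled[labels == 1].mean(axis=0)  # (K,P)
    weights = model.dense_w[output_neuron].reshape(K, P)
    scores = np.abs(diff * weights).sum(axis=1)
    best = int(np.argmax(scores))  # argmax takes the first maximum: lowest index
    return best + 1, float(scores[best])


def build_bundle(
    model: CNNModel,
    dataset: Sequence[FeatureSeries],
    output_neuron: int = 1,
) -> InterpretationBundle:
    """Assemble every interpretability view from model plus data alone."""
    pooled = pooled_outputs(model, dataset)
    K, P = model.config.n_kernels, model.pooled_len
    weights = model.dense_w[output_neuron].reshape(K, P)
    weighted = pooled * weights[:, None, :]
    inputs = np.empty((2, model.n_features))
    labels = np.array([fs.label for fs in dataset], dtype=int)
    values = np.array([fs.values for fs in dataset])
    for c in (0, 1):
        inputs[c] = values[labels == c].mean(axis=0)
    best, score = most_discriminative_kernel(model, dataset, output_neuron)
    return InterpretationBundle(
        kernel_profiles=export_kernels(model),
        pooled_by_class=pooled,
        weighted_pooled=weighted,
        inputs_by_class=inputs,
        output_neuron=output_neuron,
        best_kernel=best,
        best_kernel_score=score,
    )


def _long_table(arr: np.ndarray, value_name: str) -> pd.DataFrame:
    """(K, 2, P) array -> long table (kernel, class, position, value)."""
    K, _, P = arr.shape
    rows = []
    for k in range(K):
        for c in (0, 1):
            for p in range(P):
                rows.append((k + 1, c, p, arr[k, c, p]))
    return pd.DataFrame(rows, columns=["kernel", "class", "position", value_name])


def write_bundle(bundle: InterpretationBundle, out_dir: str | Path) -> Path:
    """Write the bundle as delimited tables plus JSON metadata.

    Tables: ``kernels.tsv`` (kernel x element weights), ``pooled.tsv``
    and ``weighted_pooled.tsv`` (long format), ``inputs_by_class.tsv``.
    Returns the metadata path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kdf = pd.DataFrame(
        bundle.kernel_profiles,
        index=pd.Index(range(1, bundle.kernel_profiles.shape[0] + 1), name="kernel"),
        columns=[f"w{i}" for i in range(bundle.kernel_profiles.shape[1])],
    )
    kdf.to_csv(out / "kernels.tsv", sep="\t", float_format="%.12g")
    _long_table(bundle.pooled_by_class, "activation").to_csv(
        out / "pooled.tsv", sep="\t", index=False, float_format="%.12g")
    _long_table(bundle.weighted_pooled, "weighted_activation").to_csv(
        out / "weighted_pooled.tsv", sep="\t", index=False, float_format="%.12g")
    idf = pd.DataFrame(bundle.inputs_by_class.T, columns=["class0", "class1"])
    idf.to_csv(out / "inputs_by_class.tsv", sep="\t", index_label="feature",
               float_format="%.12g")
    meta = {
        "output_neuron": bundle.output_neuron,
        "best_kernel": bundle.best_kernel,
        "best_kernel_score": bundle.best_kernel_score,
        "n_kernels": int(bundle.kernel_profiles.shape[0]),
        "kernel_len": int(bundle.kernel_profiles.shape[1]),
        "pooled_len": int(bundle.pooled_by_class.shape[2]),
    }
    path = out / "interpretation_meta.json"
    path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def plot_bundle(bundle: InterpretationBundle, out_dir: str | Path) -> list[Path]:
    """Optional figure rendering (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    K = bundle.kernel_profiles.shape[0]
    fig, axes = plt.subplots(int(np.ceil(K / 3)), 3, figsize=(9, K), squeeze=False)
    for k, ax in enumerate(axes.ravel()):
        if k < K:
            ax.plot(bundle.kernel_profiles[k], marker="o", ms=3)
            ax.set_title(f"filter {k + 1}", fontsize=8)
        else:
            ax.axis("off")
    fig.suptitle("Learned kernel profiles")
    fig.tight_layout()
    p = out / "kernels.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    paths.append(p)

    k = bundle.best_kernel - 1
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3))
    for c, name in ((0, "group 0"), (1, "group 1")):
        ax1.plot(bundle.pooled_by_class[k, c], label=name)
        ax2.plot(bundle.weighted_pooled[k, c], label=name)
    ax1.set_title(f"pooled output, filter {bundle.best_kernel}")
    ax2.set_title("x dense weights")
    ax1.legend()
    fig.tight_layout()
    p = out / "best_kernel.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    paths.append(p)
    return paths
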
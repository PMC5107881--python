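# nirscnn

Channel-wise CNN classification and region-of-interest (ROI) selection
for fNIRS group studies — with a synthetic cohort generator that makes
the whole pipeline testable against known ground truth.

## The problem

Functional near-infrared spectroscopy (fNIRS) measures relative changes
in oxy-hemoglobin (oxy-Hb) concentration at dozens of scalp channels.
Group analyses — e.g. comparing two populations during a cognitive
task — usually need a seed ROI, and choosing it by hand is subjective.
`nirscnn` automates the choice: train a small one-dimensional
convolutional network **per channel** to classify subjects into the two
groups from that channel's time series alone, score every channel by its
leave-one-out cross-validated (LOOCV) identification rate, and select
the best-classifying channels as the ROI.  Because the classifier slides
learned kernels along the time series, the temporal structure of the
response — *when* the groups diverge, not just how much — is preserved
and can be read back out of the trained network.

The classifier is a single convolution stage (nine 1×10 kernels), an
elementwise activation, 1×2 max pooling, and a two-neuron softmax output
layer, trained with momentum SGD (learning rate 0.05, momentum 0.998,
5000 epochs) on min–max-normalized 1 s feature means:

    u_k = x * w_k            (valid convolution, stride 1)
    y_k = f(u_k)             (logistic sigmoid)
    y'_k = maxpool(y_k)      (width 2, stride 2)
    p = softmax(W y' + b)    (class probabilities)

Since no public recordings accompany the method, the package ships a
block-design fNIRS simulator (hemodynamic responses from a double-gamma
kernel, physiological confounds, configurable group effects on known
channels) so that calibration and recovery are measurable facts, not
hopes.

## A worked example

```python
from nirscnn import PreprocessParams, SimulationConfig, features_by_channel, simulate_cohort
from nirscnn.cnn import CNNConfig
from nirscnn.roi import evaluate_channels, rank_channels, select_roi

sim = SimulationConfig(n_channels=6, discriminative_channels={2, 5},
                       effect_amplitude=4.0, seed=9)
features = features_by_channel(simulate_cohort(sim),
                               PreprocessParams(start_s=160.0))
results = evaluate_channels(features, CNNConfig().fast(), base_seed=5)
report = select_roi(rank_channels(results), strategy="topk", param=2)
for r in report.ranked:
    print(f"{r.channel}: {r.accuracy:.2f}")
print("ROI:", report.selected)
```

prints

```
CH2: 1.00
CH5: 1.00
CH3: 0.55
CH1: 0.50
CH4: 0.45
CH6: 0.45
ROI: ['CH2', 'CH5']
```

The cohort has 22 subjects (11 per group) and a strong group-dependent
response planted on channels 2 and 5.  Those channels classify every
held-out subject correctly (identification rate 1.00) and become the
ROI; the other channels hover around 0.5 — chance for a two-class
problem — exactly as they should when they carry no group information.

More narrative walk-throughs live in `examples/` (simulation,
preprocessing, single-channel training, ranking, interpretation), each
runnable as `python examples/04_rank_channels_roi.py`.

A thin CLI mirrors the pipeline stages
(`nirscnn simulate | preprocess | train | roi | interpret | run`);
`nirscnn run --out results/ --seed 1` executes everything end to end and
writes a per-channel accuracy table, the ROI report, the trained model
of the best channel, interpretation tables and a provenance record.

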
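"""What did the network learn?  Kernels, pooled activations, weighted outputs.

Trains the classifier of a planted channel on all subjects, then exports
the learned 1x10 kernels, the class-mean pooling-layer outputs, and the
pooled outputs weighted by the dense layer — the view that shows *when*
during the task the two groups diverge.
"""

import numpy as np

from nirscnn import PreprocessParams, SimulationConfig, features_by_channel, simulate_cohort
from nirscnn.cnn import CNNConfig, train
from nirscnn.interpret import build_bundle, write_bundle

sim = SimulationConfig(seed=5, effect_amplitude=4.0)
pre = PreprocessParams(start_s=160.0)
dataset = features_by_channel(simulate_cohort(sim), pre)["CH20"]

model, _ = train(dataset, CNNConfig().fast(), seed=2)
bundle = build_bundle(model, dataset, output_neuron=1)

k = bundle.best_kernel
print(f"most discriminative kernel: {k} "
      f"(separation score {bundle.best_kernel_score:.3f})")
print(f"kernel {k} weights: {np.round(bundle.kernel_profiles[k - 1], 2)}")

diff = bundle.weighted_pooled[k - 1, 0] - bundle.weighted_pooled[k - 1, 1]
half = diff.size // 2
print(f"weighted pooled output, class difference: "
      f"first half mean {diff[:half].mean():+.3f}, "
      f"second half mean {diff[half:].mean():+.3f}")
print("(a consistently nonzero class difference is what lets the dense")
print(" layer separate the groups from this kernel's response)")

meta = write_bundle(bundle, "scratch/example_interpretation")
print(f"tables written next to {meta}")
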
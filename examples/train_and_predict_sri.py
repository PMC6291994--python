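"""Train the RBPN and predict an SRI with clustering consensus.

Builds a noise-free synthetic (ILMFD, SRI) set under a known affine
mapping, trains the recurrent network on a seeded 70/30 split, predicts
one candidate SRI per held-out descriptor, and reduces the candidates
to a consensus by two-tier hierarchical clustering. The held-out RMSE
shows how well the network recovered the mapping; the consensus is the
final predicted SRI.
"""

import numpy as np

from sriselect import (
    TrainingConfig,
    cluster_consensus,
    predict_candidates,
    split_train_test,
    train_rbpn,
)
from sriselect.synthetic_data import (
    TrainingSetSpec,
    generate_training_set,
    random_affine_mapping,
)

A, b = random_affine_mapping(seed=11)
pairs = generate_training_set(
    TrainingSetSpec(A, b, n_samples=50, noise_sd=0.0, seed=42)
)
train_idx, test_idx = split_train_test(len(pairs), seed=1)
print(f"{len(train_idx)} training / {len(test_idx)} test descriptors")

model = train_rbpn([pairs[i] for i in train_idx], TrainingConfig(seed=5))
print(f"training loss: {model.loss_history[0]:.4f} -> {model.loss_history[-1]:.5f}")

candidates = predict_candidates(model, [pairs[i][0] for i in test_idx])
truth = np.array([pairs[i][1] for i in test_idx])
rmse = float(np.sqrt(np.mean((np.array(candidates) - truth) ** 2)))
print(f"held-out RMSE: {rmse:.3f} Å over {len(candidates)} candidates")

ensemble = cluster_consensus(candidates)
print(
    f"consensus from cluster of "
    f"{ensemble.consensus.metadata['selected_cluster_size']}/{len(candidates)}:"
)
print("SRI_P (Å):", "  ".join(f"{v:5.2f}" for v in ensemble.consensus.values))
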
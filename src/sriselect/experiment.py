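"""End-to-end planted-truth experiments for the whole workflow.

A replicate emulates one protein going through the full semi-empirical
pipeline: a set of micrographs is generated, descriptors are extracted,
a predictor is trained on 70% of the images, the remaining 30% produce
candidate SRIs whose clustering consensus is the predicted SRI, and
finally a set of candidate structure-model SRIs — one of which is
planted close to the truth — is ranked against the prediction. The
replicate succeeds when the planted model is selected.

The ILMFD → SRI mapping is affine with known coefficients, so the true
SRI of the "protein" is known exactly and the margin between the planted
model and the decoys can be controlled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .ilmfd import compute_ilmfd
from .model_selection import rank_models
from .sri_predictor import (
    TrainingConfig,
    cluster_consensus,
    predict_candidates,
    split_train_test,
    train_rbpn,
)
from .synthetic_data import generate_micrograph, random_affine_mapping

__all__ = ["ReplicateResult", "run_planted_selection_replicate", "run_recovery_experiment"]


@dataclass
class ReplicateResult:
    """Outcome of one planted-model pipeline replicate."""

    planted_label: str
    selected_label: str
    consensus_error: float  # |SRI_P - true SRI|, Euclidean
    planted_margin: float  # half the minimum inter-model SRI distance
    success: bool


def run_planted_selection_replicate(
    seed: int,
    n_images: int = 50,
    image_shape: tuple[int, int] = (90, 90),
    n_models: int = 5,
    planted_offset: float = 0.2,
    decoy_offset: float = 2.5,
    training_config: Optional[TrainingConfig] = None,
) -> ReplicateResult:
    """Run one full synth → ilmfd → train → predict → select replicate.

    The planted best model sits ``planted_offset`` Å from the true SRI;
    every decoy sits ``decoy_offset`` Å away along a distinct coordinate
    axis, so the minimum inter-model distance (and hence the selection
    margin) is known by construction.
    """
    rng = np.random.default_rng(seed)

    # per-protein texture profile; each micrograph jitters around it
    w_base = rng.uniform(0.5, 2.0, size=10)
    images = [
        generate_micrograph(
            seed=int(rng.integers(2**31)),
            shape=image_shape,
            band_weights=w_base * rng.uniform(0.8, 1.25, size=10),
        )
        for _ in range(n_images)
    ]
    descriptors = [compute_ilmfd(img) for img in images]
    X = np.array([d.values for d in descriptors])

    A, b = random_affine_mapping(seed=int(rng.integers(2**31)))
    targets = X @ A.T + b  # known mapping: per-image true SRI
    true_sri = X.mean(axis=0) @ A.T + b

    train_idx, test_idx = split_train_test(n_images, seed=int(rng.integers(2**31)))
    pairs = [(descriptors[i], targets[i]) for i in train_idx]
    config = training_config or TrainingConfig(seed=int(rng.integers(2**31)))
    model = train_rbpn(pairs, config)
    candidates = predict_candidates(model, [descriptors[i] for i in test_idx])
    ensemble = cluster_consensus(candidates)
    sri_p = ensemble.consensus.values

    planted = int(rng.integers(1, n_models + 1))
    axes = rng.permutation(8)[: n_models - 1]
    model_sris: dict[str, np.ndarray] = {}
    ax = iter(axes)
    for j in range(1, n_models + 1):
        if j == planted:
            direction = rng.normal(size=8)
            direction /= np.linalg.norm(direction)
            model_sris[str(j)] = true_sri + planted_offset * direction
        else:
            e = np.zeros(8)
            e[next(ax)] = 1.0
            model_sris[str(j)] = true_sri + decoy_offset * e

    vecs = list(model_sris.values())
    inter = min(
        float(np.linalg.norm(vecs[i] - vecs[j]))
        for i in range(len(vecs))
        for j in range(i + 1, len(vecs))
    )
    ranking = rank_models(model_sris, sri_p)
    return ReplicateResult(
        planted_label=str(planted),
        selected_label=ranking.best,
        consensus_error=float(np.linalg.norm(sri_p - true_sri)),
        planted_margin=inter / 2.0,
        success=ranking.best == str(planted),
    )


def run_recovery_experiment(
    n_replicates: int = 20, seed: int = 0, **replicate_kwargs
) -> list[ReplicateResult]:
    """Run seeded replicates of the planted-model experiment."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**31, size=n_replicates)
    return [
        run_planted_selection_replicate(int(s), **replicate_kwargs) for s in seeds
    ]
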
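"""Predicting SRI from image descriptors.

A small Elman-style recurrent backpropagation network (RBPN) maps the
10-valued ILMFD of a micrograph to the 8-valued SRI of the imaged
protein. Targets are min-max normalized per component to [0, 1] (the
output layer is sigmoid); predictions are denormalized on the way out.

The hidden layer is recurrent: for each input the hidden state starts at
zero and settles for a fixed number of internal steps (default 3) before
the output is read. Training is full-batch gradient descent with
backpropagation through the settling steps, deterministic for a given
seed.

Because a micrograph is a noisy view of the aggregate, one network
prediction per test image is only a *candidate* SRI. The candidates are
passed through a two-tier hierarchical clustering consensus: average-
linkage clustering of the candidates (tier 1), the same procedure on the
tier-1 cluster centres (tier 2), and the component-wise mean of the most
populous tier-1 cluster inside the most populous tier-2 super-cluster is
the consensus prediction. This rejects ill-posed outlier candidates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import DivergenceError, ParameterError
from .sri import SRIVector

__all__ = [
    "TrainingConfig",
    "Normalization",
    "RBPNModel",
    "PredictionEnsemble",
    "normalize_targets",
    "train_rbpn",
    "predict_candidates",
    "cluster_consensus",
    "split_train_test",
    "save_model",
    "load_model",
]

INPUT_WIDTH = 10
OUTPUT_WIDTH = 8


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class TrainingConfig:
    """Hyperparameters of RBPN training (all serialized with the model)."""

    hidden_width: int = 20
    settling_steps: int = 3
    learning_rate: float = 0.5
    momentum: float = 0.9
    epochs: int = 3000
    seed: int = 0


@dataclass
class Normalization:
    """Per-component min-max mapping of SRI targets onto [0, 1].

    Components that are constant over the training set are degenerate:
    they normalize to 0.5 and denormalize back to the constant.
    """

    mins: np.ndarray
    maxs: np.ndarray
    degenerate: np.ndarray

    def apply(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        span = np.where(self.degenerate, 1.0, self.maxs - self.mins)
        out = (y - self.mins) / span
        return np.where(self.degenerate, 0.5, out)

    def invert(self, y01: np.ndarray) -> np.ndarray:
        y01 = np.asarray(y01, dtype=float)
        span = np.where(self.degenerate, 1.0, self.maxs - self.mins)
        out = y01 * span + self.mins
        return np.where(self.degenerate, self.mins, out)


def normalize_targets(
    sri_set: Sequence[np.ndarray],
) -> Tuple[np.ndarray, Normalization]:
    """Min-max normalize a set of 8-vectors component-wise to [0, 1]."""
    Y = np.array([np.asarray(v, dtype=float).reshape(OUTPUT_WIDTH) for v in sri_set])
    if len(Y) < 1:
        raise ParameterError("need at least one target vector")
    mins = Y.min(axis=0)
    maxs = Y.max(axis=0)
    norm = Normalization(mins=mins, maxs=maxs, degenerate=maxs - mins < 1e-12)
    return norm.apply(Y), norm


@dataclass
class RBPNModel:
    """Trained Elman recurrent network with its target normalization."""

    w_in: np.ndarray  # (hidden, 10)
    w_rec: np.ndarray  # (hidden, hidden)
    w_out: np.ndarray  # (8, hidden)
    b_hidden: np.ndarray
    b_out: np.ndarray
    normalization: Normalization
    config: TrainingConfig
    loss_history: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def forward_normalized(self, X: np.ndarray) -> np.ndarray:
        """Network output in normalized [0, 1] units for inputs X (n, 10)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        h = np.zeros((X.shape[0], self.w_in.shape[0]))
        for _ in range(self.config.settling_steps):
            h = _sigmoid(X @ self.w_in.T + h @ self.w_rec.T + self.b_hidden)
        return _sigmoid(h @ self.w_out.T + self.b_out)


def _as_input_matrix(ilmfd_set: Sequence) -> np.ndarray:
    rows = []
    for v in ilmfd_set:
        arr = np.asarray(getattr(v, "values", v), dtype=float).reshape(-1)
        if arr.size != INPUT_WIDTH:
            raise ParameterError(f"ILMFD input must have {INPUT_WIDTH} components")
        rows.append(arr)
    return np.array(rows)


def train_rbpn(
    pairs: Sequence[Tuple[object, np.ndarray]], config: Optional[TrainingConfig] = None
) -> RBPNModel:
    """Train the RBPN on (ILMFD, SRI) pairs.

    Full-batch gradient descent (with momentum) on the mean squared error
    of the normalized targets; deterministic for a given ``config.seed``.
    Raises :class:`DivergenceError` if the loss becomes non-finite.
    """
    if config is None:
        config = TrainingConfig()
    if len(pairs) < 2:
        raise ParameterError("training needs at least two pairs")
    X = _as_input_matrix([p[0] for p in pairs])
    Y01, norm = normalize_targets([np.asarray(getattr(p[1], "values", p[1])) for p in pairs])
    n, hid, T = X.shape[0], config.hidden_width, config.settling_steps

    rng = np.random.default_rng(config.seed)
    w_in = rng.normal(0.0, 1.0 / np.sqrt(INPUT_WIDTH), size=(hid, INPUT_WIDTH))
    w_rec = rng.normal(0.0, 0.3 / np.sqrt(hid), size=(hid, hid))
    w_out = rng.normal(0.0, 1.0 / np.sqrt(hid), size=(OUTPUT_WIDTH, hid))
    b_hidden = np.zeros(hid)
    b_out = np.zeros(OUTPUT_WIDTH)
    velocity = [np.zeros_like(p) for p in (w_in, w_rec, w_out, b_hidden, b_out)]

    losses = np.zeros(config.epochs)
    for epoch in range(config.epochs):
        # forward pass, keeping all settling states for backprop
        H = [np.zeros((n, hid))]
        for _ in range(T):
            H.append(_sigmoid(X @ w_in.T + H[-1] @ w_rec.T + b_hidden))
        out = _sigmoid(H[-1] @ w_out.T + b_out)
        err = out - Y01
        loss = float(np.mean(err**2))
        if not np.isfinite(loss):
            raise DivergenceError(epoch)
        losses[epoch] = loss

        d_out = (2.0 / err.size) * err * out * (1.0 - out)
        g_w_out = d_out.T @ H[-1]
        g_b_out = d_out.sum(axis=0)
        d_h = d_out @ w_out
        g_w_in = np.zeros_like(w_in)
        g_w_rec = np.zeros_like(w_rec)
        g_b_hidden = np.zeros_like(b_hidden)
        for t in range(T, 0, -1):  # backprop through settling steps
            d_a = d_h * H[t] * (1.0 - H[t])
            g_w_in += d_a.T @ X
            g_w_rec += d_a.T @ H[t - 1]
            g_b_hidden += d_a.sum(axis=0)
            d_h = d_a @ w_rec

        grads = (g_w_in, g_w_rec, g_w_out, g_b_hidden, g_b_out)
        params = (w_in, w_rec, w_out, b_hidden, b_out)
        for vel, grad, par in zip(velocity, grads, params):
            vel *= config.momentum
            vel -= config.learning_rate * grad
            par += vel

    return RBPNModel(
        w_in=w_in,
        w_rec=w_rec,
        w_out=w_out,
        b_hidden=b_hidden,
        b_out=b_out,
        normalization=norm,
        config=config,
        loss_history=losses,
    )


def predict_candidates(model: RBPNModel, ilmfd_set: Sequence) -> list[np.ndarray]:
    """One denormalized 8-vector per input, order preserved."""
    if len(ilmfd_set) == 0:
        return []
    X = _as_input_matrix(ilmfd_set)
    out01 = model.forward_normalized(X)
    return [model.normalization.invert(row) for row in out01]


@dataclass
class PredictionEnsemble:
    """Candidate predictions plus their clustering consensus."""

    candidates: list[np.ndarray]
    consensus: SRIVector
    cluster_labels: np.ndarray
    selected_cluster: int


def _cut(Z: np.ndarray, frac: float) -> np.ndarray:
    max_h = Z[:, 2].max() if len(Z) else 0.0
    return fcluster(Z, t=frac * max_h, criterion="distance")


def cluster_consensus(
    candidates: Sequence[np.ndarray],
    cut_fraction: float = 0.5,
    source_label: str = "",
) -> PredictionEnsemble:
    """Two-tier hierarchical clustering consensus over candidate SRIs.

    Tier 1: average-linkage agglomerative clustering of the candidates
    (Euclidean), cut at ``cut_fraction`` of the maximum merge height.
    Tier 2: the same on the tier-1 cluster centres. The consensus is the
    component-wise mean of the most populous tier-1 cluster belonging to
    the most populous tier-2 super-cluster; population ties fall to the
    cluster of lowest within-cluster variance.
    """
    if len(candidates) == 0:
        raise ParameterError("cluster_consensus needs at least one candidate")
    if not 0.0 <= cut_fraction <= 1.0:
        raise ParameterError("cut_fraction must lie in [0, 1]")
    C = np.array([np.asarray(c, dtype=float).reshape(OUTPUT_WIDTH) for c in candidates])
    n = len(C)
    if n == 1:
        labels = np.array([1])
    else:
        labels = _cut(linkage(C, method="average", metric="euclidean"), cut_fraction)

    cluster_ids = np.unique(labels)
    centres = np.array([C[labels == cid].mean(axis=0) for cid in cluster_ids])
    sizes = np.array([(labels == cid).sum() for cid in cluster_ids])

    if len(cluster_ids) == 1:
        super_labels = np.array([1])
    else:
        super_labels = _cut(
            linkage(centres, method="average", metric="euclidean"), cut_fraction
        )
    super_sizes = {
        s: sizes[super_labels == s].sum() for s in np.unique(super_labels)
    }
    best_super = max(sorted(super_sizes), key=lambda s: super_sizes[s])

    def cluster_rank(i: int) -> tuple:
        members = C[labels == cluster_ids[i]]
        variance = float(np.mean(np.sum((members - centres[i]) ** 2, axis=1)))
        return (sizes[i], -variance, -cluster_ids[i])

    eligible = [i for i in range(len(cluster_ids)) if super_labels[i] == best_super]
    winner = max(eligible, key=cluster_rank)
    members = C[labels == cluster_ids[winner]]
    consensus = SRIVector(
        values=members.mean(axis=0),
        role="predicted",
        source_label=source_label,
        octant_counts=np.zeros(8, dtype=int),
        metadata={
            "n_candidates": n,
            "n_clusters": len(cluster_ids),
            "selected_cluster_size": int(sizes[winner]),
            "cut_fraction": cut_fraction,
        },
    )
    return PredictionEnsemble(
        candidates=[row for row in C],
        consensus=consensus,
        cluster_labels=labels,
        selected_cluster=int(cluster_ids[winner]),
    )


def split_train_test(
    n_items: int, seed: int, train_fraction: float = 0.7
) -> Tuple[np.ndarray, np.ndarray]:
    """Seeded shuffle split; returns (train indices, test indices).

    With 50 items and the default fraction this is the 35/15 split used
    for the micrograph sets.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ParameterError("train_fraction must lie in (0, 1)")
    idx = np.random.default_rng(seed).permutation(n_items)
    n_train = int(round(train_fraction * n_items))
    n_train = min(max(n_train, 1), n_items - 1)
    return idx[:n_train], idx[n_train:]


def save_model(model: RBPNModel, path) -> None:
    """Persist a model as structured JSON text."""
    payload = {
        "w_in": model.w_in.tolist(),
        "w_rec": model.w_rec.tolist(),
        "w_out": model.w_out.tolist(),
        "b_hidden": model.b_hidden.tolist(),
        "b_out": model.b_out.tolist(),
        "normalization": {
            "mins": model.normalization.mins.tolist(),
            "maxs": model.normalization.maxs.tolist(),
            "degenerate": model.normalization.degenerate.tolist(),
        },
        "config": asdict(model.config),
        "loss_history": model.loss_history.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> RBPNModel:
    """Load a model persisted by :func:`save_model`."""
    with open(path) as fh:
        payload = json.load(fh)
    norm = payload["normalization"]
    return RBPNModel(
        w_in=np.array(payload["w_in"]),
        w_rec=np.array(payload["w_rec"]),
        w_out=np.array(payload["w_out"]),
        b_hidden=np.array(payload["b_hidden"]),
        b_out=np.array(payload["b_out"]),
        normalization=Normalization(
            mins=np.array(norm["mins"]),
            maxs=np.array(norm["maxs"]),
            degenerate=np.array(norm["degenerate"], dtype=bool),
        ),
        config=TrainingConfig(**payload["config"]),
        loss_history=np.array(payload["loss_history"]),
    )
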
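"""Shared-weight cell-embedding network with per-species classifiers.

The network is deliberately small: two affine layers with ReLU map the
shared feature space to 64- then 32-dimensional cell embeddings; the
embedding weights are shared between the species. One linear-softmax
classifier per species maps embeddings to that species' cell-type
probabilities. Training minimizes

    L = L_cls^A + L_cls^B + L_align^A + L_align^B + gamma * ||theta||^2

where the classification losses are label-smoothed cross-entropies with
per-type weights w_t = (1 - acc_t) * alpha + 1 updated every epoch from
that epoch's training-batch accuracy, and the alignment losses ask each
cell's K nearest cross-species neighbours (in the current embedding space)
to predict its shared feature vector. Batches are class-balanced: cells are
sampled with replacement with probability proportional to 1 / N_t.

The forward and backward passes are written directly in numpy; gradients
for every term are derived analytically and verified against finite
differences in the test suite. Hard neighbour selection would make the
alignment term piecewise constant in the parameters, so the default uses
soft neighbour weights (a softmax over negative squared embedding distances
restricted to the K nearest neighbours); a paper-literal ``hard`` mode is
available for ablation.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

_EPS_LOG = 1e-12  # floor inside ln() of the cross-entropy


@dataclass
class ModelConfig:
    """Hyperparameters of the embedding network and its training loop."""

    hidden_dim: int = 64
    embed_dim: int = 32
    epochs: int = 200
    lr: float = 0.001
    l2_gamma: float = 0.01
    smoothing: float = 0.1      # label-smoothing epsilon
    weight_alpha: float = 9.0   # dynamic class-weight alpha; weights in [1, alpha+1]
    batch_per_species: int = 5000
    k_align: int = 20           # cross-species neighbours in the alignment loss
    align_mode: str = "soft"    # soft | hard
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.smoothing < 1):
            raise ValueError("smoothing must be in (0, 1)")
        for name in ("hidden_dim", "embed_dim", "epochs", "batch_per_species", "k_align"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.lr <= 0 or self.weight_alpha < 0 or self.l2_gamma < 0:
            raise ValueError("lr must be > 0; weight_alpha, l2_gamma must be >= 0")


@dataclass
class TrainedModel:
    """Trained parameters plus everything needed to reuse them safely."""

    params: dict[str, np.ndarray]
    config: ModelConfig
    feature_ids: list[str]
    types_a: list[str]
    types_b: list[str]
    class_weights_a: np.ndarray
    class_weights_b: np.ndarray
    log: list[dict] = field(default_factory=list)

    @property
    def feature_hash(self) -> str:
        return feature_order_hash(self.feature_ids)


def feature_order_hash(feature_ids: list[str]) -> str:
    return hashlib.sha256("\n".join(feature_ids).encode()).hexdigest()


# ---------------------------------------------------------------------------
# forward pieces

def _init_params(n_features: int, t_a: int, t_b: int, cfg: ModelConfig,
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Kaiming-style uniform fan-in initialization; biases start at zero."""
    def kaiming(fan_in, fan_out):
        limit = np.sqrt(6.0 / fan_in)
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    return {
        "W1": kaiming(n_features, cfg.hidden_dim),
        "b1": np.zeros(cfg.hidden_dim),
        "W2": kaiming(cfg.hidden_dim, cfg.embed_dim),
        "b2": np.zeros(cfg.embed_dim),
        "Wc_a": kaiming(cfg.embed_dim, t_a),
        "bc_a": np.zeros(t_a),
        "Wc_b": kaiming(cfg.embed_dim, t_b),
        "bc_b": np.zeros(t_b),
    }


def _forward_embed(params: dict, X: np.ndarray) -> dict:
    """Two affine+ReLU layers; returns the cache needed for backprop."""
    Z1 = X @ params["W1"] + params["b1"]
    H1 = np.maximum(Z1, 0.0)
    Z2 = H1 @ params["W2"] + params["b2"]
    E = np.maximum(Z2, 0.0)
    return {"X": X, "Z1": Z1, "H1": H1, "Z2": Z2, "E": E}


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def embed_cells(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Map cells (shared-feature rows) to embeddings; species-agnostic."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.params["W1"].shape[0]:
        raise ValueError(
            f"feature count {X.shape[1]} does not match training-time "
            f"count {model.params['W1'].shape[0]}")
    return _forward_embed(model.params, X)["E"]


def classify(model: TrainedModel, X: np.ndarray, species: str) -> np.ndarray:
    """Cell-type probabilities from the given species' classifier head."""
    E = embed_cells(model, X)
    suffix = {"a": "a", "b": "b"}[species]
    logits = E @ model.params[f"Wc_{suffix}"] + model.params[f"bc_{suffix}"]
    return _softmax(logits)


# ---------------------------------------------------------------------------
# loss pieces

def smooth_labels(true_type_index: int, n_types: int, eps: float) -> np.ndarray:
    """Label-smoothed target: 1 - eps at the true index, eps/(T-1) elsewhere."""
    if n_types < 2:
        raise ValueError("label smoothing requires at least 2 types")
    if not 0 <= eps < 1:
        raise ValueError("eps must be in [0, 1)")
    out = np.full(n_types, eps / (n_types - 1))
    out[true_type_index] = 1.0 - eps
    return out


def smooth_label_matrix(labels_idx: np.ndarray, n_types: int, eps: float) -> np.ndarray:
    Y = np.full((len(labels_idx), n_types), eps / (n_types - 1))
    Y[np.arange(len(labels_idx)), labels_idx] = 1.0 - eps
    return Y


def classification_loss(probs: np.ndarray, targets_smoothed: np.ndarray,
                        w: np.ndarray) -> float:
    """Weighted label-smoothed cross-entropy, averaged over cells."""
    probs = np.clip(probs, _EPS_LOG, None)
    per_cell = -(targets_smoothed * w[None, :] * np.log(probs)).sum(axis=1)
    return float(per_cell.mean())


def update_class_weights(per_type_accuracy: np.ndarray, alpha: float) -> np.ndarray:
    """Dynamic class weights w_t = (1 - acc_t) * alpha + 1, in [1, alpha+1]."""
    acc = np.asarray(per_type_accuracy, dtype=float)
    if np.any(acc < 0) or np.any(acc > 1):
        raise ValueError("accuracies must lie in [0, 1]")
    return (1.0 - acc) * alpha + 1.0


def _knn_indices(d2: np.ndarray, k: int) -> np.ndarray:
    """Row-wise indices of the k smallest entries; ties by lowest index."""
    order = np.argsort(d2, axis=1, kind="stable")
    return order[:, :k]


def alignment_loss(emb_src: np.ndarray, emb_opp: np.ndarray,
                   feats_src: np.ndarray, feats_opp: np.ndarray,
                   k: int, mode: str = "soft",
                   return_grads: bool = False):
    """Cross-species alignment loss for one direction.

    For each source cell i, its ``k`` nearest opposite-species cells (by
    Euclidean distance in the embedding space, within the batch) predict its
    shared feature vector; the loss is the mean over cells of the MSE between
    prediction and the cell's actual features. ``soft`` mode weights the
    neighbours by a softmax over negative squared distances so the loss is
    differentiable in the embeddings; ``hard`` mode uses the unweighted mean
    (piecewise constant in the parameters, zero gradient).

    With ``return_grads`` also returns (d loss / d emb_src, d loss / d emb_opp).
    """
    n_src, n_opp = emb_src.shape[0], emb_opp.shape[0]
    if n_opp == 0:
        raise ValueError("empty opposite-species batch")
    if k > n_opp:
        warnings.warn(f"k={k} exceeds opposite batch size {n_opp}; clamping",
                      stacklevel=2)
        k = n_opp
    n_feat = feats_src.shape[1]

    d2 = ((emb_src[:, None, :] - emb_opp[None, :, :]) ** 2).sum(axis=2)
    nbr = _knn_indices(d2, k)  # (n_src, k)
    rows = np.arange(n_src)[:, None]

    if mode == "hard":
        s = np.full((n_src, k), 1.0 / k)
    elif mode == "soft":
        a = -d2[rows, nbr]
        a = a - a.max(axis=1, keepdims=True)
        e = np.exp(a)
        s = e / e.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown align mode {mode!r}")

    pred = np.einsum("ik,ikf->if", s, feats_opp[nbr])
    resid = pred - feats_src
    loss = float((resid ** 2).sum(axis=1).mean() / n_feat)
    if not return_grads:
        return loss

    g_src = np.zeros_like(emb_src)
    g_opp = np.zeros_like(emb_opp)
    if mode == "soft":
        # c_ij = dL_i/ds_ij ; through the softmax: g_ij = s_ij (c_ij - sum_l s_il c_il)
        c = (2.0 / n_feat) * np.einsum("if,ikf->ik", resid, feats_opp[nbr])
        g = s * (c - (s * c).sum(axis=1, keepdims=True))  # dL_i / d(-d2_ij)
        diff = emb_src[:, None, :] - emb_opp[nbr]  # (n_src, k, e)
        # d(d2)/d emb_src_i = 2 diff ; dL/dd2 = -g
        g_src = (-g[:, :, None] * 2.0 * diff).sum(axis=1) / n_src
        contrib = (g[:, :, None] * 2.0 * diff) / n_src
        np.add.at(g_opp, nbr.ravel(), contrib.reshape(-1, emb_opp.shape[1]))
    return loss, g_src, g_opp


def l2_penalty(params: dict[str, np.ndarray], gamma: float) -> float:
    return float(gamma * sum((p ** 2).sum() for p in params.values()))


def total_loss(cls_a: float, cls_b: float, align_a: float, align_b: float,
               params: dict[str, np.ndarray], gamma: float) -> float:
    """Composite loss: both classification + both alignment + L2 penalty."""
    return cls_a + cls_b + align_a + align_b + l2_penalty(params, gamma)


def sample_batch(labels: np.ndarray, batch_size: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Class-balanced batch indices: P(cell i) proportional to 1 / N_{t(i)}.

    Sampling is with replacement, so the expected number of cells per type is
    equal across types regardless of type abundance.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty dataset")
    types, inv, counts = np.unique(labels, return_inverse=True, return_counts=True)
    if batch_size < len(types):
        warnings.warn(f"batch_size {batch_size} < number of types {len(types)}",
                      stacklevel=2)
    p = 1.0 / counts[inv]
    p /= p.sum()
    return rng.choice(labels.size, size=batch_size, replace=True, p=p)


# ---------------------------------------------------------------------------
# backward pieces

def _backward_encoder(params: dict, cache: dict, dE: np.ndarray,
                      grads: dict) -> None:
    """Accumulate encoder gradients for one batch given dL/d embedding."""
    dZ2 = dE * (cache["Z2"] > 0)
    grads["W2"] += cache["H1"].T @ dZ2
    grads["b2"] += dZ2.sum(axis=0)
    dH1 = dZ2 @ params["W2"].T
    dZ1 = dH1 * (cache["Z1"] > 0)
    grads["W1"] += cache["X"].T @ dZ1
    grads["b1"] += dZ1.sum(axis=0)


def _classifier_forward_backward(params: dict, cache: dict, labels_idx: np.ndarray,
                                 w: np.ndarray, eps: float, suffix: str,
                                 grads: dict) -> tuple[float, np.ndarray, np.ndarray]:
    """Weighted smoothed CE for one species; returns (loss, dL/dE, probs)."""
    E = cache["E"]
    Wc, bc = params[f"Wc_{suffix}"], params[f"bc_{suffix}"]
    logits = E @ Wc + bc
    probs = _softmax(logits)
    T = probs.shape[1]
    Y = smooth_label_matrix(labels_idx, T, eps)
    loss = classification_loss(probs, Y, w)
    n = probs.shape[0]
    # d/dlogits of -(1/N) sum_t w_t Y_it ln p_it  =  (1/N)(omega_i p_ik - w_k Y_ik)
    omega = (Y * w[None, :]).sum(axis=1, keepdims=True)
    dlogits = (omega * probs - w[None, :] * Y) / n
    grads[f"Wc_{suffix}"] += E.T @ dlogits
    grads[f"bc_{suffix}"] += dlogits.sum(axis=0)
    dE = dlogits @ Wc.T
    return loss, dE, probs


class _Adam:
    """Adam optimizer over a dict of parameter arrays."""

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# one training step

def _loss_and_grads(params: dict, Xa: np.ndarray, ya: np.ndarray,
                    Xb: np.ndarray, yb: np.ndarray,
                    w_a: np.ndarray, w_b: np.ndarray,
                    cfg: ModelConfig) -> tuple[float, dict, dict]:
    """Composite loss and its analytic gradients for one pair of batches.

    Returns (loss, grads, diagnostics); diagnostics carries the loss terms
    and both species' batch class probabilities.
    """
    cache_a = _forward_embed(params, Xa)
    cache_b = _forward_embed(params, Xb)
    grads = {k: np.zeros_like(v) for k, v in params.items()}

    cls_a, dE_a, probs_a = _classifier_forward_backward(
        params, cache_a, ya, w_a, cfg.smoothing, "a", grads)
    cls_b, dE_b, probs_b = _classifier_forward_backward(
        params, cache_b, yb, w_b, cfg.smoothing, "b", grads)

    k = min(cfg.k_align, Xa.shape[0], Xb.shape[0])
    al_a, gs_a, go_a = alignment_loss(cache_a["E"], cache_b["E"], Xa, Xb,
                                      k, cfg.align_mode, return_grads=True)
    al_b, gs_b, go_b = alignment_loss(cache_b["E"], cache_a["E"], Xb, Xa,
                                      k, cfg.align_mode, return_grads=True)
    dE_a = dE_a + gs_a + go_b
    dE_b = dE_b + gs_b + go_a

    _backward_encoder(params, cache_a, dE_a, grads)
    _backward_encoder(params, cache_b, dE_b, grads)
    for key in params:
        grads[key] += 2.0 * cfg.l2_gamma * params[key]

    loss = total_loss(cls_a, cls_b, al_a, al_b, params, cfg.l2_gamma)
    diag = {"cls_a": cls_a, "cls_b": cls_b, "align_a": al_a, "align_b": al_b,
            "probs_a": probs_a, "probs_b": probs_b}
    return loss, grads, diag


# ---------------------------------------------------------------------------
# training loop

def train(feats_a: np.ndarray, feats_b: np.ndarray,
          labels_a: list[str], labels_b: list[str],
          cfg: ModelConfig,
          feature_ids: list[str] | None = None) -> TrainedModel:
    """Train the shared encoder and both classifier heads.

    One class-balanced batch per species is drawn each epoch, the composite
    loss is evaluated on it, and one Adam step is taken. After each epoch the
    per-type training-batch accuracy (each species scored by its own
    classifier) updates the dynamic class weights. Fully reproducible for a
    fixed ``cfg.seed`` on one device.
    """
    feats_a = np.asarray(feats_a, dtype=float)
    feats_b = np.asarray(feats_b, dtype=float)
    if feats_a.shape[1] != feats_b.shape[1]:
        raise ValueError("species feature spaces are not aligned")
    n_features = feats_a.shape[1]
    types_a = sorted(set(labels_a))
    types_b = sorted(set(labels_b))
    idx_a = np.array([types_a.index(t) for t in labels_a])
    idx_b = np.array([types_b.index(t) for t in labels_b])

    rng = np.random.default_rng(cfg.seed)
    params = _init_params(n_features, len(types_a), len(types_b), cfg, rng)
    opt = _Adam(params, cfg.lr)
    w_a = np.ones(len(types_a))
    w_b = np.ones(len(types_b))
    log: list[dict] = []

    for epoch in range(cfg.epochs):
        batch_a = sample_batch(idx_a, cfg.batch_per_species, rng)
        batch_b = sample_batch(idx_b, cfg.batch_per_species, rng)
        Xa, Xb = feats_a[batch_a], feats_b[batch_b]
        ya, yb = idx_a[batch_a], idx_b[batch_b]

        loss, grads, diag = _loss_and_grads(params, Xa, ya, Xb, yb, w_a, w_b, cfg)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch}: cls=({diag['cls_a']}, "
                f"{diag['cls_b']}) align=({diag['align_a']}, {diag['align_b']})")
        opt.step(params, grads)

        acc_a = _per_type_accuracy(diag["probs_a"], ya, len(types_a))
        acc_b = _per_type_accuracy(diag["probs_b"], yb, len(types_b))
        seen_a, seen_b = ~np.isnan(acc_a), ~np.isnan(acc_b)
        w_a[seen_a] = update_class_weights(acc_a[seen_a], cfg.weight_alpha)
        w_b[seen_b] = update_class_weights(acc_b[seen_b], cfg.weight_alpha)

        log.append({
            "epoch": epoch, "loss": loss,
            "cls_a": diag["cls_a"], "cls_b": diag["cls_b"],
            "align_a": diag["align_a"], "align_b": diag["align_b"],
            "l2": l2_penalty(params, cfg.l2_gamma),
            "acc_a": float(np.nanmean(acc_a)), "acc_b": float(np.nanmean(acc_b)),
        })

    return TrainedModel(params, cfg, list(feature_ids or []), types_a, types_b,
                        w_a, w_b, log)


def _per_type_accuracy(probs: np.ndarray, y: np.ndarray, n_types: int) -> np.ndarray:
    """Per-type batch accuracy; NaN for types absent from the batch."""
    pred = probs.argmax(axis=1)
    acc = np.full(n_types, np.nan)
    for t in range(n_types):
        mask = y == t
        if mask.any():
            acc[t] = float((pred[mask] == t).mean())
    return acc


def config_to_dict(cfg: ModelConfig) -> dict:
    return asdict(cfg)
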
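"""Chebyshev graph-convolutional node classifier for superpixel graphs.

Architecture: a learnable affine lift from the single mean-intensity
feature to 16 channels, then four Chebyshev graph-convolution layers
(16 -> 16 -> 16 -> 2 channels, orders K1..K4) each followed by batch
normalization (over the nodes of the current graph) and, for the first
three, a ReLU; then dropout, a per-node dense 2 -> 2 map, and a per-node
softmax.  Training minimizes an area-weighted soft-Dice loss with Adam
(learning rate 1e-3, weight decay 5e-4, dropout 0.2 by default), one graph
per optimization step.  Tumor segmentation fine-tunes a liver-trained
model on tumor node labels.

The forward pass, backpropagation and the optimizers are implemented
directly in numpy: graphs are small (a few hundred nodes), so dense
linear algebra on one CPU is entirely adequate, and every source of
randomness is an explicit seeded generator.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .graph import (RegionGraph, SuperpixelPartition, build_region_graph,
                    labels_to_mask, slic_partition)
from .preprocess import BinaryMask, CTSlice
from .spectral import ChebCoefficients, chebyshev_filter, laplacian, scale_laplacian

__all__ = [
    "NetworkConfig",
    "ModelState",
    "GraphSample",
    "build_model",
    "forward",
    "dice_loss",
    "train",
    "cross_validate",
    "fine_tune_tumor",
    "predict_mask",
    "make_graph_sample",
    "parameter_counts",
    "save_model",
    "load_model",
]

_OPTIMIZERS = ("adam", "adamax", "sgd", "rmsprop", "adadelta")
_EPS = 1e-6
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class NetworkConfig:
    cheb_orders: tuple[int, int, int, int] = (3, 3, 3, 3)
    channel_widths: tuple[int, int, int, int] = (16, 16, 16, 2)
    dropout_rate: float = 0.2
    learning_rate: float = 0.001
    weight_decay: float = 5e-4
    optimizer_name: str = "adam"
    epochs: int = 60
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if any(k < 1 for k in self.cheb_orders):
            raise ValueError("all Chebyshev orders must be >= 1")
        if any(w < 1 for w in self.channel_widths):
            raise ValueError("channel widths must be positive")
        if self.optimizer_name not in _OPTIMIZERS:
            raise ValueError(f"optimizer must be one of {_OPTIMIZERS}")
        if self.channel_widths[-1] != 2:
            raise ValueError("the final layer must emit 2 class channels")


@dataclass
class GraphSample:
    """One slice turned into a training sample: graph + labels + geometry."""

    graph: RegionGraph
    scaled_laplacian: np.ndarray
    node_labels: np.ndarray
    partition: SuperpixelPartition
    region_areas: np.ndarray
    truth_mask: np.ndarray | None = None
    case_id: str = ""

    def __post_init__(self) -> None:
        c = self.partition.region_count
        if not (self.graph.features.shape[0] == self.scaled_laplacian.shape[0]
                == len(self.node_labels) == len(self.region_areas) == c):
            raise ValueError("inconsistent node counts across sample fields")


@dataclass
class ModelState:
    """Learnable parameters, batch-norm running statistics, and history."""

    config: NetworkConfig
    params: dict[str, np.ndarray]
    running: dict[str, np.ndarray]
    history: dict[str, list] = field(default_factory=lambda: {"loss": [], "accuracy": []})

    def clone(self) -> "ModelState":
        return ModelState(config=self.config,
                          params={k: v.copy() for k, v in self.params.items()},
                          running={k: v.copy() for k, v in self.running.items()},
                          history={k: list(v) for k, v in self.history.items()})


def make_graph_sample(ct_slice: CTSlice, mask: BinaryMask, n_regions: int,
                      beta: float = 10.0, compactness: float = 0.1,
                      case_id: str = "") -> GraphSample:
    """Embed one normalized slice + mask into a labelled graph sample."""
    from .graph import region_labels

    part = slic_partition(ct_slice, n_regions=n_regions, compactness=compactness)
    graph = build_region_graph(part, ct_slice, beta=beta)
    bundle = scale_laplacian(laplacian(graph.weights))
    labels = region_labels(part, mask)
    return GraphSample(graph=graph, scaled_laplacian=bundle.scaled_laplacian,
                       node_labels=labels, partition=part,
                       region_areas=part.areas.astype(np.float64),
                       truth_mask=mask.pixels, case_id=case_id)


# ---------------------------------------------------------------------------
# model construction


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def build_model(config: NetworkConfig, seed: int | None = None) -> ModelState:
    """Deterministically initialize the four-layer network."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    widths = (1,) + tuple(config.channel_widths)
    lift_out = config.channel_widths[0]
    params: dict[str, np.ndarray] = {
        "lift_w": _glorot(rng, (1, lift_out), 1, lift_out),
        "lift_b": np.zeros(lift_out),
    }
    running: dict[str, np.ndarray] = {}
    f_in = lift_out
    for i, (k, f_out) in enumerate(zip(config.cheb_orders,
                                       config.channel_widths), start=1):
        params[f"cheb{i}_theta"] = _glorot(rng, (k, f_in, f_out), k * f_in, f_out)
        params[f"cheb{i}_bias"] = np.zeros(f_out)
        params[f"bn{i}_gamma"] = np.ones(f_out)
        params[f"bn{i}_beta"] = np.zeros(f_out)
        running[f"bn{i}_mean"] = np.zeros(f_out)
        running[f"bn{i}_var"] = np.ones(f_out)
        f_in = f_out
    params["head_w"] = _glorot(rng, (2, 2), 2, 2)
    params["head_b"] = np.zeros(2)
    return ModelState(config=config, params=params, running=running)


def parameter_counts(model: ModelState) -> dict[str, int]:
    """Learnable parameters per named layer (audit of the architecture)."""
    p = model.params
    counts = {"input_lift": p["lift_w"].size + p["lift_b"].size}
    for i in range(1, 5):
        counts[f"cheb_conv_{i}"] = (p[f"cheb{i}_theta"].size
                                    + p[f"cheb{i}_bias"].size)
        counts[f"batch_norm_{i}"] = (p[f"bn{i}_gamma"].size
                                     + p[f"bn{i}_beta"].size)
    counts["dense_head"] = p["head_w"].size + p["head_b"].size
    counts["softmax"] = 0
    return counts


# ---------------------------------------------------------------------------
# forward / backward


def _cheb_apply(lt: np.ndarray, v: np.ndarray, order_index: int) -> np.ndarray:
    """T_k(L_tilde) @ v via the three-term recurrence."""
    if order_index == 0:
        return v
    t_prev, t_curr = v, lt @ v
    for _ in range(order_index - 1):
        t_prev, t_curr = t_curr, 2.0 * (lt @ t_curr) - t_prev
    return t_curr


def _forward_cache(model: ModelState, sample: GraphSample, training: bool,
                   rng: np.random.Generator | None) -> tuple[np.ndarray, dict]:
    p = model.params
    lt = sample.scaled_laplacian
    cache: dict = {"lt": lt, "bn": {}, "cheb": {}}
    x = sample.graph.features  # (C, 1)
    h = x @ p["lift_w"] + p["lift_b"]
    cache["x"] = x
    cache["h0"] = h
    for i in range(1, 5):
        theta = p[f"cheb{i}_theta"]
        k_order = theta.shape[0]
        t_stack = []
        t_prev = h
        t_stack.append(t_prev)
        if k_order > 1:
            t_curr = lt @ h
            t_stack.append(t_curr)
            for _ in range(2, k_order):
                t_prev, t_curr = t_curr, 2.0 * (lt @ t_curr) - t_prev
                t_stack.append(t_curr)
        z = sum(t_stack[k] @ theta[k] for k in range(k_order)) + p[f"cheb{i}_bias"]
        cache["cheb"][i] = {"input": h, "t_stack": t_stack}

        # batch normalization over the nodes of this graph
        gamma, beta = p[f"bn{i}_gamma"], p[f"bn{i}_beta"]
        if training:
            mu = z.mean(axis=0)
            var = z.var(axis=0)
            model.running[f"bn{i}_mean"] = ((1 - _BN_MOMENTUM)
                                            * model.running[f"bn{i}_mean"]
                                            + _BN_MOMENTUM * mu)
            model.running[f"bn{i}_var"] = ((1 - _BN_MOMENTUM)
                                           * model.running[f"bn{i}_var"]
                                           + _BN_MOMENTUM * var)
        else:
            mu = model.running[f"bn{i}_mean"]
            var = model.running[f"bn{i}_var"]
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        z_hat = (z - mu) * inv_std
        zn = gamma * z_hat + beta
        cache["bn"][i] = {"z_hat": z_hat, "inv_std": inv_std, "training": training}

        if i < 4:
            h = np.maximum(zn, 0.0)
            cache[f"relu{i}"] = zn > 0
        else:
            h = zn

    if training and model.config.dropout_rate > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        keep = 1.0 - model.config.dropout_rate
        mask = (rng.random(h.shape) < keep) / keep
        h = h * mask
        cache["dropout"] = mask
    cache["pre_head"] = h
    scores = h @ p["head_w"] + p["head_b"]
    shifted = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    probs = e / e.sum(axis=1, keepdims=True)
    cache["probs"] = probs
    return probs, cache


def forward(model: ModelState, sample: GraphSample, training: bool = False,
            rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-node class probabilities (C x 2, rows sum to 1)."""
    probs, _ = _forward_cache(model, sample, training, rng)
    return probs


def dice_loss(probabilities: np.ndarray, node_labels: np.ndarray,
              region_areas: np.ndarray, eps: float = _EPS) -> float:
    """Area-weighted soft-Dice loss on the foreground channel, in [0, 1]."""
    loss, _ = _dice_loss_grad(probabilities, node_labels, region_areas, eps)
    return loss


def _dice_loss_grad(probs: np.ndarray, labels: np.ndarray, areas: np.ndarray,
                    eps: float = _EPS) -> tuple[float, np.ndarray]:
    areas = np.asarray(areas, dtype=np.float64)
    if areas.sum() <= 0:
        raise ValueError("region areas must not all be zero")
    y = np.asarray(labels, dtype=np.float64)
    p1 = probs[:, 1]
    num = 2.0 * np.sum(areas * p1 * y) + eps
    den = np.sum(areas * p1) + np.sum(areas * y) + eps
    loss = 1.0 - num / den
    # d loss / d p1
    grad_p1 = -(2.0 * areas * y * den - num * areas) / den ** 2
    grad = np.zeros_like(probs)
    grad[:, 1] = grad_p1
    return float(loss), grad


def _backward(model: ModelState, sample: GraphSample, cache: dict,
              grad_probs: np.ndarray) -> dict[str, np.ndarray]:
    p = model.params
    lt = cache["lt"]
    probs = cache["probs"]
    grads: dict[str, np.ndarray] = {}

    # softmax
    dot = np.sum(grad_probs * probs, axis=1, keepdims=True)
    d_scores = probs * (grad_probs - dot)

    # dense head
    h = cache["pre_head"]
    grads["head_w"] = h.T @ d_scores
    grads["head_b"] = d_scores.sum(axis=0)
    dh = d_scores @ p["head_w"].T

    if "dropout" in cache:
        dh = dh * cache["dropout"]

    for i in range(4, 0, -1):
        if i < 4:
            dh = dh * cache[f"relu{i}"]
        # batch-norm backward (per channel over nodes)
        bn = cache["bn"][i]
        z_hat, inv_std = bn["z_hat"], bn["inv_std"]
        gamma = p[f"bn{i}_gamma"]
        grads[f"bn{i}_gamma"] = np.sum(dh * z_hat, axis=0)
        grads[f"bn{i}_beta"] = dh.sum(axis=0)
        if bn["training"]:
            n = dh.shape[0]
            dzh = dh * gamma
            dz = (inv_std / n) * (n * dzh - dzh.sum(axis=0)
                                  - z_hat * np.sum(dzh * z_hat, axis=0))
        else:
            dz = dh * gamma * inv_std
        # Chebyshev convolution backward
        theta = p[f"cheb{i}_theta"]
        ch = cache["cheb"][i]
        k_order = theta.shape[0]
        grads[f"cheb{i}_bias"] = dz.sum(axis=0)
        d_theta = np.empty_like(theta)
        d_input = np.zeros_like(ch["input"])
        for k in range(k_order):
            d_theta[k] = ch["t_stack"][k].T @ dz
            d_input += _cheb_apply(lt, dz @ theta[k].T, k)
        grads[f"cheb{i}_theta"] = d_theta
        dh = d_input

    grads["lift_w"] = cache["x"].T @ dh
    grads["lift_b"] = dh.sum(axis=0)
    return grads


# ---------------------------------------------------------------------------
# optimizers

_DECAYED = ("lift_w", "head_w", "cheb1_theta", "cheb2_theta",
            "cheb3_theta", "cheb4_theta")


class _Optimizer:
    """Small numpy optimizer bank (adam / adamax / sgd / rmsprop / adadelta)."""

    def __init__(self, config: NetworkConfig, params: dict[str, np.ndarray]):
        self.name = config.optimizer_name
        self.lr = config.learning_rate
        self.wd = config.weight_decay
        self.t = 0
        self.state = {k: {"m": np.zeros_like(v), "v": np.zeros_like(v)}
                      for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for key, g in grads.items():
            if self.wd and key in _DECAYED:
                g = g + self.wd * params[key]
            st = self.state[key]
            if self.name == "adam":
                st["m"] = b1 * st["m"] + (1 - b1) * g
                st["v"] = b2 * st["v"] + (1 - b2) * g ** 2
                m_hat = st["m"] / (1 - b1 ** self.t)
                v_hat = st["v"] / (1 - b2 ** self.t)
                params[key] -= self.lr * m_hat / (np.sqrt(v_hat) + eps)
            elif self.name == "adamax":
                st["m"] = b1 * st["m"] + (1 - b1) * g
                st["v"] = np.maximum(b2 * st["v"], np.abs(g))
                params[key] -= (self.lr / (1 - b1 ** self.t)) * st["m"] / (st["v"] + eps)
            elif self.name == "sgd":
                st["m"] = 0.9 * st["m"] + g
                params[key] -= self.lr * st["m"]
            elif self.name == "rmsprop":
                st["v"] = 0.99 * st["v"] + 0.01 * g ** 2
                params[key] -= self.lr * g / (np.sqrt(st["v"]) + eps)
            elif self.name == "adadelta":
                rho = 0.95
                st["v"] = rho * st["v"] + (1 - rho) * g ** 2
                update = (np.sqrt(st["m"] + eps) / np.sqrt(st["v"] + eps)) * g
                st["m"] = rho * st["m"] + (1 - rho) * update ** 2
                params[key] -= self.lr * update


# ---------------------------------------------------------------------------
# training


def train(samples: list[GraphSample], config: NetworkConfig,
          model: ModelState | None = None) -> ModelState:
    """Optimize the Dice loss over graphs, one graph per step.

    Records per-epoch mean loss and node accuracy in ``model.history``.
    Deterministic for a fixed (config, seed, data).  Raises on divergence.
    """
    if model is None:
        if len(samples) < 2:
            raise ValueError("training requires at least 2 samples")
        model = build_model(config)
    else:
        model = model.clone()
        model.config = config
    opt = _Optimizer(config, model.params)
    rng = np.random.default_rng(config.seed + 1)
    for epoch in range(config.epochs):
        order = rng.permutation(len(samples))
        losses, accs = [], []
        for idx in order:
            s = samples[idx]
            probs, cache = _forward_cache(model, s, training=True, rng=rng)
            loss, grad_probs = _dice_loss_grad(probs, s.node_labels, s.region_areas)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch}")
            grads = _backward(model, s, cache, grad_probs)
            opt.step(model.params, grads)
            losses.append(loss)
            accs.append(float(np.mean(probs.argmax(axis=1) == s.node_labels)))
        model.history["loss"].append(float(np.mean(losses)))
        model.history["accuracy"].append(float(np.mean(accs)))
    return model


def fine_tune_tumor(liver_model: ModelState, tumor_samples: list[GraphSample],
                    config: NetworkConfig) -> ModelState:
    """Continue training a liver model on tumor node labels.

    The history is carried over and extended so the full convergence curve
    (liver phase then tumor phase) can be plotted.
    """
    expected = build_model(config, seed=0)
    if set(liver_model.params) != set(expected.params):
        raise ValueError("checkpoint incompatible with config: parameter sets differ")
    for key, val in expected.params.items():
        if liver_model.params[key].shape != val.shape:
            raise ValueError(
                f"checkpoint incompatible with config: {key} has shape "
                f"{liver_model.params[key].shape}, expected {val.shape}")
    return train(tumor_samples, config, model=liver_model)


def cross_validate(samples: list[GraphSample], config: NetworkConfig):
    """K-fold cross-validation; every sample is validated exactly once.

    Returns ``(per_fold_reports, mean_report)`` of pixel-level metric
    dictionaries computed on each fold's held-out predictions.
    """
    from .metrics import evaluate_masks, mean_report

    if config.folds < 2:
        raise ValueError("folds must be >= 2")
    if config.folds > len(samples):
        raise ValueError("cannot have more folds than samples")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(samples))
    fold_ids = np.array_split(order, config.folds)
    reports = []
    for f, val_idx in enumerate(fold_ids):
        train_idx = np.setdiff1d(order, val_idx)
        fold_config = replace(config, seed=config.seed + 1000 * (f + 1))
        model = train([samples[i] for i in train_idx], fold_config)
        fold_metrics = []
        for i in val_idx:
            s = samples[i]
            probs = forward(model, s, training=False)
            pred = labels_to_mask(s.partition, probs.argmax(axis=1))
            truth = (s.truth_mask if s.truth_mask is not None
                     else labels_to_mask(s.partition, s.node_labels).pixels)
            fold_metrics.append(evaluate_masks(pred.pixels, truth))
        reports.append(mean_report(fold_metrics))
    return reports, mean_report(reports)


def predict_mask(model: ModelState, ct_slice: CTSlice, n_regions: int = 600,
                 beta: float = 10.0, compactness: float = 0.1
                 ) -> tuple[BinaryMask, np.ndarray]:
    """End-to-end inference: embed a normalized slice, classify nodes,
    project back to a pixel mask. Also returns per-node foreground scores."""
    part = slic_partition(ct_slice, n_regions=n_regions, compactness=compactness)
    graph = build_region_graph(part, ct_slice, beta=beta)
    bundle = scale_laplacian(laplacian(graph.weights))
    sample = GraphSample(graph=graph, scaled_laplacian=bundle.scaled_laplacian,
                         node_labels=np.zeros(part.region_count, dtype=np.int64),
                         partition=part,
                         region_areas=part.areas.astype(np.float64))
    probs = forward(model, sample, training=False)
    mask = labels_to_mask(part, probs.argmax(axis=1))
    return mask, probs[:, 1]


# ---------------------------------------------------------------------------
# checkpoints


def save_model(model: ModelState, path: str | Path) -> None:
    """Write a checkpoint: npz of arrays + JSON config/history sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"param_{k}": v for k, v in model.params.items()}
    arrays.update({f"running_{k}": v for k, v in model.running.items()})
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                          for k, v in vars(model.config).items()},
               "history": model.history}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> ModelState:
    path = Path(path)
    npz_path = path.with_suffix(".npz")
    json_path = path.with_suffix(".json")
    if not npz_path.exists() or not json_path.exists():
        raise IOError(f"checkpoint {path} is missing its .npz or .json part")
    try:
        data = np.load(npz_path)
        sidecar = json.loads(json_path.read_text())
        cfg = sidecar["config"]
        config = NetworkConfig(
            cheb_orders=tuple(cfg["cheb_orders"]),
            channel_widths=tuple(cfg["channel_widths"]),
            dropout_rate=cfg["dropout_rate"], learning_rate=cfg["learning_rate"],
            weight_decay=cfg["weight_decay"], optimizer_name=cfg["optimizer_name"],
            epochs=cfg["epochs"], folds=cfg["folds"], seed=cfg["seed"])
        params = {k[len("param_"):]: data[k] for k in data.files
                  if k.startswith("param_")}
        running = {k[len("running_"):]: data[k] for k in data.files
                   if k.startswith("running_")}
    except (KeyError, ValueError, json.JSONDecodeError) as exc:
        raise IOError(f"corrupt checkpoint {path}: {exc}") from exc
    return ModelState(config=config, params=params, running=running,
                      history=sidecar.get("history", {"loss": [], "accuracy": []}))
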
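"""The grid predictor: a feedforward network over angle-bin classes.

All four backbone angles are predicted simultaneously: the output layer
is the concatenation of four independent softmax blocks, one per angle
(72 + 72 + 36 + 72 = 252 nodes at 5-degree bins), trained with summed
cross-entropy.  Hidden layers use sigmoid activations.  Weights are
initialized by greedy layer-wise pretraining with sparse autoencoders
(sigmoid encoder/decoder, squared reconstruction error, KL sparsity
penalty) and then fine-tuned by plain mini-batch backpropagation with a
separate learning rate per layer.

Defaults follow the reference configuration: three hidden layers of 150
units, autoencoder learning rate 0.05, fine-tune learning rates
1.0 / 0.5 / 0.2 / 0.05 for hidden-1 / hidden-2 / hidden-3 / output.

Everything is deterministic given ``NetworkConfig.seed``: weight
initialization, pretraining and the per-epoch mini-batch shuffle all
draw from one seeded generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import ANGLE_KINDS
from .binning import BinScheme, ProbabilityProfile, TargetMatrix, make_scheme

__all__ = [
    "NetworkConfig",
    "NetworkModel",
    "pretrain",
    "train",
    "predict",
    "cross_validate",
    "save_model",
    "load_model",
]


@dataclass
class NetworkConfig:
    """Hyperparameters; all randomness is fixed by ``seed``."""

    hidden: list = field(default_factory=lambda: [150, 150, 150])
    pretrain_lr: float = 0.05
    finetune_lrs: list = field(default_factory=lambda: [1.0, 0.5, 0.2, 0.05])
    pretrain_epochs: int = 30
    epochs: int = 100
    batch_size: int = 64
    sparsity_target: float = 0.05
    sparsity_weight: float = 0.1
    weight_decay: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.hidden):
            raise ValueError("hidden layer sizes must be positive")
        if self.pretrain_lr <= 0 or any(lr <= 0 for lr in self.finetune_lrs):
            raise ValueError("learning rates must be positive")
        if len(self.finetune_lrs) != len(self.hidden) + 1:
            raise ValueError(
                f"need {len(self.hidden) + 1} fine-tune learning rates "
                f"(one per hidden layer plus output), got {len(self.finetune_lrs)}")


@dataclass
class NetworkModel:
    """Trained weights plus the scheme that defines the output layout."""

    weights: list                    # per layer: (fan_in, fan_out)
    biases: list                     # per layer: (fan_out,)
    scheme: BinScheme
    config: NetworkConfig
    input_dim: int
    train_fingerprint: str = ""

    @property
    def output_dim(self) -> int:
        return self.weights[-1].shape[1]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax_blocks(logits: np.ndarray, scheme: BinScheme) -> dict:
    """Split logits into per-angle blocks and softmax each block."""
    blocks = {}
    for kind in ANGLE_KINDS:
        off = scheme.offset(kind)
        block = logits[:, off:off + scheme.counts[kind]]
        z = block - block.max(axis=1, keepdims=True)
        e = np.exp(z)
        blocks[kind] = e / e.sum(axis=1, keepdims=True)
    return blocks


def _init_layer(rng: np.random.Generator, fan_in: int, fan_out: int):
    # small uniform init, symmetric-breaking; scale as in classic
    # sigmoid-net practice
    bound = 4.0 * np.sqrt(6.0 / (fan_in + fan_out))
    W = rng.uniform(-bound, bound, size=(fan_in, fan_out))
    b = np.zeros(fan_out)
    return W, b


def pretrain(features: np.ndarray, config: NetworkConfig,
             return_losses: bool = False):
    """Greedy layer-wise sparse-autoencoder initialization.

    Each hidden layer is trained to reconstruct its input through a
    sigmoid bottleneck, minimizing squared error plus a KL-divergence
    sparsity penalty toward ``sparsity_target`` mean activation and an
    L2 weight penalty.  Returns the list of (W, b) encoder parameters
    (and per-layer loss curves when requested).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or len(X) < 1:
        raise ValueError("features must be a non-empty 2-D array")
    rng = np.random.default_rng(config.seed)
    layers = []
    losses = []
    current = X
    rho = config.sparsity_target
    for h in config.hidden:
        d = current.shape[1]
        W, b = _init_layer(rng, d, h)
        W_dec, b_dec = _init_layer(rng, h, d)
        layer_losses = []
        for _ in range(config.pretrain_epochs):
            order = rng.permutation(len(current))
            epoch_loss = 0.0
            for start in range(0, len(current), config.batch_size):
                xb = current[order[start:start + config.batch_size]]
                n = len(xb)
                hidden = _sigmoid(xb @ W + b)
                recon = _sigmoid(hidden @ W_dec + b_dec)
                err = recon - xb
                epoch_loss += 0.5 * np.sum(err ** 2)
                rho_hat = np.clip(hidden.mean(axis=0), 1e-8, 1 - 1e-8)
                # d/d rho_hat of KL(rho || rho_hat)
                dkl = (-rho / rho_hat + (1 - rho) / (1 - rho_hat))

                d_recon = err * recon * (1 - recon)             # (n, d)
                gW_dec = hidden.T @ d_recon / n + config.weight_decay * W_dec
                gb_dec = d_recon.mean(axis=0)
                d_hidden = (d_recon @ W_dec.T
                            + config.sparsity_weight * dkl / n)
                d_hidden *= hidden * (1 - hidden)
                gW = xb.T @ d_hidden / n + config.weight_decay * W
                gb = d_hidden.mean(axis=0)

                W_dec -= config.pretrain_lr * gW_dec
                b_dec -= config.pretrain_lr * gb_dec
                W -= config.pretrain_lr * gW
                b -= config.pretrain_lr * gb
            layer_losses.append(epoch_loss / len(current))
        layers.append((W, b))
        losses.append(layer_losses)
        current = _sigmoid(current @ W + b)
    if return_losses:
        return layers, losses
    return layers


def _forward(X: np.ndarray, weights: list, biases: list):
    """Activations through all layers; last entry is raw output logits."""
    acts = [X]
    for W, b in zip(weights[:-1], biases[:-1]):
        acts.append(_sigmoid(acts[-1] @ W + b))
    acts.append(acts[-1] @ weights[-1] + biases[-1])
    return acts


def _loss_and_grads(X, weights, biases, targets: TargetMatrix,
                    scheme: BinScheme, weight_decay: float):
    """Summed masked cross-entropy over the four softmax blocks.

    Residues with an undefined angle contribute zero loss and zero
    gradient for that angle's block only.
    """
    acts = _forward(X, weights, biases)
    logits = acts[-1]
    n = len(X)
    probs = _softmax_blocks(logits, scheme)
    dlogits = np.zeros_like(logits)
    loss = 0.0
    for kind in ANGLE_KINDS:
        off = scheme.offset(kind)
        K = scheme.counts[kind]
        m = targets.mask[kind]
        if not m.any():
            continue
        p = probs[kind][m]
        t = targets.onehot[kind][m]
        loss += -np.sum(t * np.log(np.clip(p, 1e-12, None)))
        dblock = np.zeros((n, K))
        dblock[m] = (p - t)
        dlogits[:, off:off + K] = dblock
    dlogits /= n
    loss /= n

    gW = [None] * len(weights)
    gb = [None] * len(weights)
    delta = dlogits
    for layer in range(len(weights) - 1, -1, -1):
        gW[layer] = acts[layer].T @ delta + weight_decay * weights[layer]
        gb[layer] = delta.sum(axis=0)
        if layer > 0:
            delta = (delta @ weights[layer].T) * acts[layer] * (1 - acts[layer])
    return loss, gW, gb


def train(features: np.ndarray, targets: TargetMatrix, config: NetworkConfig,
          scheme: BinScheme | None = None, pretrained: list | None = None,
          return_history: bool = False):
    """Fine-tune a pretrained stack into a grid predictor.

    Pretraining is run internally unless layer-wise weights are passed
    in.  Mini-batch SGD with the configured per-layer learning rates;
    the shuffle order is drawn from the seeded generator, so a fixed
    seed reproduces the model bit for bit.
    """
    X = np.asarray(features, dtype=float)
    scheme = scheme or targets.scheme
    if not any(targets.mask[k].any() for k in ANGLE_KINDS):
        raise ValueError("all target rows are masked; nothing to train on")
    if len(X) != targets.n_residues:
        raise ValueError("feature and target row counts disagree")

    if pretrained is None:
        pretrained = pretrain(X, config)
    rng = np.random.default_rng(config.seed + 1)
    weights = [W.copy() for W, _ in pretrained]
    biases = [b.copy() for _, b in pretrained]
    W_out, b_out = _init_layer(rng, config.hidden[-1], scheme.total)
    weights.append(W_out)
    biases.append(b_out)

    history = []
    for _ in range(config.epochs):
        order = rng.permutation(len(X))
        epoch_loss = 0.0
        for start in range(0, len(X), config.batch_size):
            idx = order[start:start + config.batch_size]
            batch_targets = TargetMatrix(
                scheme=scheme,
                onehot={k: targets.onehot[k][idx] for k in ANGLE_KINDS},
                mask={k: targets.mask[k][idx] for k in ANGLE_KINDS},
            )
            loss, gW, gb = _loss_and_grads(
                X[idx], weights, biases, batch_targets, scheme,
                config.weight_decay)
            epoch_loss += loss * len(idx)
            for layer, lr in enumerate(config.finetune_lrs):
                weights[layer] -= lr * gW[layer]
                biases[layer] -= lr * gb[layer]
        history.append(epoch_loss / len(X))

    model = NetworkModel(weights=weights, biases=biases, scheme=scheme,
                         config=config, input_dim=X.shape[1])
    if return_history:
        return model, history
    return model


def predict(model: NetworkModel, features: np.ndarray) -> ProbabilityProfile:
    """Per-residue, per-angle bin probabilities for new feature rows."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.input_dim:
        raise ValueError(
            f"feature dimension {X.shape[1] if X.ndim == 2 else X.shape} "
            f"does not match model input dimension {model.input_dim}")
    logits = _forward(X, model.weights, model.biases)[-1]
    return ProbabilityProfile(scheme=model.scheme,
                              blocks=_softmax_blocks(logits, model.scheme))


def cross_validate(features: np.ndarray, targets: TargetMatrix,
                   chain_ids: np.ndarray, config: NetworkConfig,
                   folds: int = 10) -> dict:
    """Chain-level k-fold cross-validation.

    Chains (not residues) are partitioned into folds so that no chain
    contributes to both the training and test side of a split.  Returns
    per-fold bin and top-5 accuracies per angle plus a pooled summary
    computed from summed per-fold hit counts (hence exactly the
    residue-weighted mean of folds).
    """
    from .binning import bin_accuracy, topk_accuracy

    chain_ids = np.asarray(chain_ids)
    unique = np.unique(chain_ids)
    if folds > len(unique):
        raise ValueError(f"cannot make {folds} folds from {len(unique)} chains")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(unique))
    assignments = np.empty(len(unique), dtype=int)
    assignments[order] = np.arange(len(unique)) % folds

    fold_metrics = []
    hit_counts = {k: [0, 0, 0] for k in ANGLE_KINDS}  # hits, top5 hits, total
    for fold in range(folds):
        test_chains = unique[assignments == fold]
        test_mask = np.isin(chain_ids, test_chains)
        sub = lambda d, m: {k: d[k][m] for k in ANGLE_KINDS}
        train_targets = TargetMatrix(scheme=targets.scheme,
                                     onehot=sub(targets.onehot, ~test_mask),
                                     mask=sub(targets.mask, ~test_mask))
        test_targets = TargetMatrix(scheme=targets.scheme,
                                    onehot=sub(targets.onehot, test_mask),
                                    mask=sub(targets.mask, test_mask))
        model = train(features[~test_mask], train_targets, config)
        pred = predict(model, features[test_mask])
        entry = {"fold": fold, "n_test_chains": len(test_chains),
                 "n_test_residues": int(test_mask.sum())}
        for kind in ANGLE_KINDS:
            acc = bin_accuracy(pred, test_targets, kind)
            top5 = topk_accuracy(pred, test_targets, kind,
                                 k=min(5, targets.scheme.counts[kind]))
            n_def = int(test_targets.mask[kind].sum())
            entry[f"{kind}_accuracy"] = acc
            entry[f"{kind}_top5"] = top5
            hit_counts[kind][0] += acc * n_def
            hit_counts[kind][1] += top5 * n_def
            hit_counts[kind][2] += n_def
        fold_metrics.append(entry)

    pooled = {}
    for kind in ANGLE_KINDS:
        hits, top5_hits, total = hit_counts[kind]
        pooled[f"{kind}_accuracy"] = hits / total if total else float("nan")
        pooled[f"{kind}_top5"] = top5_hits / total if total else float("nan")
    return {"folds": fold_metrics, "pooled": pooled}


# ---------------------------------------------------------------------------
# Persistence: a single .npz archive with an embedded JSON config
# ---------------------------------------------------------------------------

def save_model(model: NetworkModel, path) -> None:
    arrays = {}
    for i, (W, b) in enumerate(zip(model.weights, model.biases)):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    meta = {
        "n_layers": len(model.weights),
        "input_dim": model.input_dim,
        "scheme_width": model.scheme.width,
        "config": asdict(model.config),
        "train_fingerprint": model.train_fingerprint,
    }
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path) -> NetworkModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode("utf-8"))
        n = meta["n_layers"]
        weights = [data[f"W{i}"] for i in range(n)]
        biases = [data[f"b{i}"] for i in range(n)]
    return NetworkModel(
        weights=weights, biases=biases,
        scheme=make_scheme(meta["scheme_width"]),
        config=NetworkConfig(**meta["config"]),
        input_dim=meta["input_dim"],
        train_fingerprint=meta.get("train_fingerprint", ""),
    )
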
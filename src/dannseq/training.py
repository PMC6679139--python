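"""Adversarial training: composite loss, batch mixing, and the four regimes.

The objective is L = L_label + alpha * L_domain, where L_label is the mean
cross entropy of the binding prediction over labeled items and L_domain the
mean cross entropy of the domain (target vs source) prediction over all
items.  The adversarial sign is carried entirely by the gradient-reversal
layer: the domain classifier descends the plain domain cross entropy while
the feature extractor receives that gradient scaled by -lambda, so it learns
features the domain classifier cannot exploit.  With alpha = 0 the objective
and the parameter trajectory reduce exactly to the supervised baseline.

Regimes
-------
data_augmentation   target fully labeled, sources labeled, adversary on
semi_supervised     a fixed seeded fraction of target items labeled
cross_cell_type     target unlabeled (labels masked), sources labeled
supervised_baseline labeled items only, no adversary, no unlabeled data
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

from . import network as nn
from .network import DannConfig, lambda_schedule
from .sequences import LabeledSequence, encode_dataset, make_folds

logger = logging.getLogger(__name__)

REGIME_MODES = ("data_augmentation", "semi_supervised", "cross_cell_type", "supervised_baseline")


@dataclass(frozen=True)
class TrainingRegime:
    """Which labels the target cell type contributes, and whether the
    adversary is active."""

    mode: str
    labeled_fraction: float = 1.0
    use_adversary: bool = True

    def __post_init__(self) -> None:
        if self.mode not in REGIME_MODES:
            raise ValueError(f"mode must be one of {REGIME_MODES}, got {self.mode!r}")
        if not 0.0 <= self.labeled_fraction <= 1.0:
            raise ValueError(f"labeled_fraction must be in [0,1], got {self.labeled_fraction}")
        if self.mode == "cross_cell_type" and self.labeled_fraction != 0.0:
            raise ValueError("cross_cell_type implies labeled_fraction=0 on the target")
        if self.mode == "data_augmentation" and self.labeled_fraction != 1.0:
            raise ValueError("data_augmentation implies labeled_fraction=1")
        if self.mode == "supervised_baseline" and self.use_adversary:
            raise ValueError("supervised_baseline does not use the adversary")


def regime_from_mode(mode: str, labeled_fraction: float | None = None) -> TrainingRegime:
    """Convenience constructor with per-mode defaults."""
    if mode == "data_augmentation":
        return TrainingRegime(mode, 1.0, True)
    if mode == "semi_supervised":
        frac = 0.5 if labeled_fraction is None else labeled_fraction
        return TrainingRegime(mode, frac, True)
    if mode == "cross_cell_type":
        return TrainingRegime(mode, 0.0, True)
    if mode == "supervised_baseline":
        frac = 1.0 if labeled_fraction is None else labeled_fraction
        return TrainingRegime(mode, frac, False)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class BatchPlan:
    """One optimisation step: dataset indices plus the progress p.

    ``indices`` points into the combined array (target block first, then
    source block); ``labeled`` marks the rows whose binding labels enter the
    prediction loss; p is the fraction of total optimiser steps completed at
    the start of this step.
    """

    indices: np.ndarray
    labeled: np.ndarray
    p: float


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

_EPS = 1e-12


def prediction_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean cross entropy of the binding prediction over labeled items.

    labels: integer class indices (0 = TFBS, 1 = non-TFBS).  An empty label
    set is defined as loss 0 (cross-cell-type target batches), with a warning
    left to the caller.
    """
    if len(labels) == 0:
        return 0.0
    picked = probs[np.arange(len(labels)), labels]
    return float(-np.mean(np.log(np.clip(picked, _EPS, None))))


def domain_loss(probs: np.ndarray, domains: np.ndarray) -> float:
    """Plain mean cross entropy of the domain prediction (0 = target,
    1 = source); the adversarial -lambda sign lives in the GRL, not here."""
    picked = probs[np.arange(len(domains)), domains]
    return float(-np.mean(np.log(np.clip(picked, _EPS, None))))


def total_loss(pred_loss: float, dom_loss: float, alpha: float) -> float:
    """Composite objective L = L_label + alpha * L_domain."""
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    if alpha == 0:
        return pred_loss
    return pred_loss + alpha * dom_loss


# ---------------------------------------------------------------------------
# batch construction
# ---------------------------------------------------------------------------

def choose_labeled_subset(n_target: int, labeled_fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Fixed, seeded item-level mask of target items that keep their labels."""
    n_keep = int(round(labeled_fraction * n_target))
    mask = np.zeros(n_target, dtype=bool)
    if n_keep:
        mask[rng.choice(n_target, size=n_keep, replace=False)] = True
    return mask


def make_batches(
    n_target: int,
    n_source: int,
    regime: TrainingRegime,
    config: DannConfig,
    labeled_target_mask: np.ndarray,
    rng: np.random.Generator,
    total_steps: int,
    steps_done: int,
) -> Iterator[BatchPlan]:
    """Yield one epoch of batch plans.

    Adversarial modes mix every 128-item batch half/half: 64 target items and
    64 source items (each side reshuffled per epoch; the shorter side is
    recycled).  The supervised baseline draws plain 128-item batches from the
    labeled pool only.  Indices < n_target refer to target items, the rest to
    source items (offset by n_target).
    """
    bs = config.batch_size
    if regime.mode != "supervised_baseline":
        # mixed-domain plan; shared by the adversarial regimes and by their
        # adversary-off control so the batch streams are identical
        if n_source == 0:
            raise ValueError("mixed-domain regimes require nonempty source data")
        half = bs // 2
        t_order = rng.permutation(n_target)
        s_order = rng.permutation(n_source) + n_target
        n_steps = n_target // half
        s_pos = 0
        for step in range(n_steps):
            t_idx = t_order[step * half:(step + 1) * half]
            if s_pos + half > n_source:
                s_order = rng.permutation(n_source) + n_target
                s_pos = 0
            s_idx = s_order[s_pos:s_pos + half]
            s_pos += half
            indices = np.concatenate([t_idx, s_idx])
            labeled = np.concatenate([labeled_target_mask[t_idx], np.ones(half, dtype=bool)])
            yield BatchPlan(indices, labeled, (steps_done + step) / total_steps)
    else:
        pool = np.concatenate([np.flatnonzero(labeled_target_mask),
                               np.arange(n_source) + n_target])
        order = rng.permutation(pool)
        n_steps = len(pool) // bs
        for step in range(n_steps):
            indices = order[step * bs:(step + 1) * bs]
            yield BatchPlan(indices, np.ones(bs, dtype=bool), (steps_done + step) / total_steps)


def steps_per_epoch(n_target: int, n_source: int, n_labeled_target: int,
                    regime: TrainingRegime, config: DannConfig) -> int:
    if regime.mode != "supervised_baseline":
        return n_target // (config.batch_size // 2)
    return (n_labeled_target + n_source) // config.batch_size


# ---------------------------------------------------------------------------
# gradients and optimisation
# ---------------------------------------------------------------------------

def compute_gradients(
    params: Mapping[str, np.ndarray],
    config: DannConfig,
    x: np.ndarray,
    binding: np.ndarray,
    domains: np.ndarray,
    lam: float,
    alpha: float,
    use_adversary: bool,
    dropout_rng: np.random.Generator | None = None,
):
    """One forward/backward pass over a batch.

    binding: class indices with -1 marking masked (unlabeled) items; only
    unmasked items contribute to the prediction loss and its gradients.
    Returns (pred_loss, dom_loss, grads) where grads maps parameter names to
    gradients of the composite objective (adversarial sign already applied to
    the feature-extractor path via the GRL).
    """
    z, fcache = nn.features_forward(params, config, x)
    dz = np.zeros_like(z)
    grads: dict[str, np.ndarray] = {}

    labeled = binding >= 0
    n_lab = int(labeled.sum())
    if n_lab:
        zl = z[labeled]
        drop_mask, keep = None, 1.0
        if dropout_rng is not None and config.dropout_rate > 0:
            keep = 1.0 - config.dropout_rate
            drop_mask = (dropout_rng.random(zl.shape) < keep).astype(zl.dtype)
        probs_l, lcache = nn._head_forward(zl, params["lp1_W"], params["lp1_b"],
                                           params["lp2_W"], params["lp2_b"], drop_mask, keep)
        y = binding[labeled]
        p_loss = prediction_loss(probs_l, y)
        dlogits = probs_l.copy()
        dlogits[np.arange(n_lab), y] -= 1.0
        dlogits /= n_lab
        dzl, dW1, db1, dW2, db2 = nn._head_backward(dlogits, lcache, params["lp1_W"],
                                                    params["lp2_W"], drop_mask, keep)
        grads.update({"lp1_W": dW1, "lp1_b": db1, "lp2_W": dW2, "lp2_b": db2})
        dz[labeled] += dzl
    else:
        p_loss = 0.0

    d_loss = 0.0
    if use_adversary:
        probs_d, dcache = nn._head_forward(z, params["dc1_W"], params["dc1_b"],
                                           params["dc2_W"], params["dc2_b"])
        d_loss = domain_loss(probs_d, domains)
        dlogits_d = probs_d.copy()
        dlogits_d[np.arange(len(domains)), domains] -= 1.0
        dlogits_d /= len(domains)
        dzd, dW1, db1, dW2, db2 = nn._head_backward(dlogits_d, dcache, params["dc1_W"],
                                                    params["dc2_W"])
        # theta_d descends alpha * (plain domain CE)
        grads.update({"dc1_W": alpha * dW1, "dc1_b": alpha * db1,
                      "dc2_W": alpha * dW2, "dc2_b": alpha * db2})
        # theta_f ascends it, scaled by lambda (GRL) and alpha; skipped
        # entirely at alpha=0 so the baseline limit is bit-exact
        if alpha != 0.0 and lam != 0.0:
            dz += nn.grad_reverse_backward(dzd, lam) * alpha

    grads.update(nn.features_backward(params, config, fcache, dz))
    return p_loss, d_loss, grads


def momentum_update(params: dict, velocity: dict, grads: Mapping[str, np.ndarray],
                    lr: float, momentum: float) -> None:
    """Classical momentum: v <- mu v - lr g; theta <- theta + v (in place)."""
    for key, g in grads.items():
        v = velocity.get(key)
        if v is None:
            v = np.zeros_like(params[key])
            velocity[key] = v
        v *= momentum
        v -= lr * g
        params[key] += v


# ---------------------------------------------------------------------------
# the training loop
# ---------------------------------------------------------------------------

def _val_auc(params, config, X_val, y_val) -> float:
    from .evaluate import compute_auc

    scores = []
    for i in range(0, len(X_val), 512):
        scores.append(nn.score(X_val[i:i + 512], params, config))
    s = np.concatenate(scores)
    return compute_auc(s, (y_val == 0).astype(int))


def train(
    target_data: Sequence[LabeledSequence],
    source_data: Sequence[LabeledSequence] | None,
    regime: TrainingRegime,
    config: DannConfig,
    val_data: Sequence[LabeledSequence] | None = None,
):
    """Train with SGD-momentum over the composite loss; early stopping on
    validation AUC; returns (best_params, training_log).

    If no validation set is supplied, a seeded stratified tenth of the target
    data is held out (the held-out items never enter training batches).
    Fully reproducible for a given config.seed.
    """
    source_data = source_data or []
    ss = np.random.SeedSequence(config.seed)
    init_seed, split_seed, batch_seed, drop_seed, mask_seed = ss.generate_state(5)

    if val_data is None:
        if len(target_data) < 20:
            raise ValueError("target data too small to carve a validation split; pass val_data")
        folds = make_folds(target_data, 10, int(split_seed))
        val_idx = set(folds[0].tolist())
        val_data = [target_data[i] for i in sorted(val_idx)]
        target_data = [r for i, r in enumerate(target_data) if i not in val_idx]

    dtype = config.np_dtype
    Xt, bt, _ = encode_dataset(target_data, dtype)
    dt = np.zeros(len(target_data), dtype=np.int64)  # domain 0 = target
    if source_data:
        Xs, bs_lab, _ = encode_dataset(source_data, dtype)
        ds = np.ones(len(source_data), dtype=np.int64)
        X = np.concatenate([Xt, Xs])
        binding = np.concatenate([bt, bs_lab])
        domains = np.concatenate([dt, ds])
    else:
        X, binding, domains = Xt, bt, dt
    Xv, bv, _ = encode_dataset(val_data, dtype)
    if (bv >= 0).sum() != len(bv):
        raise ValueError("validation data must be fully labeled")

    n_target, n_source = len(target_data), len(source_data)
    mask_rng = np.random.default_rng(int(mask_seed))
    labeled_target_mask = choose_labeled_subset(n_target, regime.labeled_fraction, mask_rng)
    if (binding[:n_target] < 0).any() and labeled_target_mask[binding[:n_target] < 0].any():
        raise ValueError("cannot treat items without binding labels as labeled")

    spe = steps_per_epoch(n_target, n_source, int(labeled_target_mask.sum()), regime, config)
    if spe == 0:
        raise ValueError("not enough data for a single batch; reduce batch_size")
    total_steps = spe * config.max_epochs

    params = nn.init_params(config, np.random.default_rng(int(init_seed)))
    velocity: dict[str, np.ndarray] = {}
    batch_rng = np.random.default_rng(int(batch_seed))
    drop_rng = np.random.default_rng(int(drop_seed))

    log: list[dict] = []
    best = {"auc": -np.inf, "params": None, "epoch": -1}
    steps_done = 0
    warned_unlabeled = False
    for epoch in range(config.max_epochs):
        p_losses, d_losses = [], []
        lam = 0.0
        for plan in make_batches(n_target, n_source, regime, config, labeled_target_mask,
                                 batch_rng, total_steps, steps_done):
            lam = lambda_schedule(plan.p, config.grl_gamma) if regime.use_adversary else 0.0
            xb = X[plan.indices]
            yb = binding[plan.indices].copy()
            yb[~plan.labeled] = -1
            db = domains[plan.indices]
            if not (yb >= 0).any() and not warned_unlabeled:
                logger.warning("batch with no labeled items: prediction loss defined as 0")
                warned_unlabeled = True
            p_loss, d_loss, grads = compute_gradients(
                params, config, xb, yb, db, lam, config.alpha if regime.use_adversary else 0.0,
                regime.use_adversary, drop_rng)
            if not np.isfinite(p_loss) or not np.isfinite(d_loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: pred_loss={p_loss}, dom_loss={d_loss}; "
                    "lower the learning rate")
            momentum_update(params, velocity, grads, config.learning_rate, config.momentum)
            p_losses.append(p_loss)
            d_losses.append(d_loss)
        steps_done += spe
        if not all(np.isfinite(v).all() for v in params.values()):
            raise RuntimeError(
                f"training diverged at epoch {epoch}: non-finite parameters; "
                "lower the learning rate")
        auc = _val_auc(params, config, Xv, bv)
        entry = {
            "epoch": epoch,
            "pred_loss": float(np.mean(p_losses)),
            "dom_loss": float(np.mean(d_losses)) if regime.use_adversary else 0.0,
            "total_loss": float(total_loss(np.mean(p_losses),
                                           np.mean(d_losses) if regime.use_adversary else 0.0,
                                           config.alpha if regime.use_adversary else 0.0)),
            "val_auc": float(auc),
            "lambda": float(lam),
        }
        log.append(entry)
        if auc > best["auc"]:
            best = {"auc": auc, "params": copy.deepcopy(params), "epoch": epoch}
        elif epoch - best["epoch"] >= config.patience:
            break
    assert best["params"] is not None
    return best["params"], log
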
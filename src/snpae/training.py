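"""Loss, augmentation and the optimization loop.

The objective is the categorical cross-entropy between one-hot target
genotypes and the Hardy–Weinberg genotype probabilities implied by the
decoder output, plus an L2 penalty (factor alpha) on the latent
coordinates.  The cross-entropy carries the conventional minus sign and
both terms are averaged (over sample × marker entries and over samples
respectively) so alpha's meaning does not depend on problem size.

Training is a denoising scheme: per batch a randomly drawn fraction of
input genotypes is masked out (and, with a configurable probability,
replaced by random genotype values), while the loss is always computed
against the true genotypes at every site.  Optimization uses Adam with
an exponentially decayed learning rate and early stopping on the
validation loss; the returned parameters are the best-validation ones.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _autograd as ag
from .genotype_io import (
    GenotypeMatrix,
    NormalizedBatch,
    TargetTensor,
    normalize_batch,
    one_hot_targets,
)
from .model_core import Autoencoder, LatentEmbedding

__all__ = [
    "TrainConfig",
    "TrainState",
    "class_balance_weights",
    "reconstruction_loss",
    "augment_batch",
    "train",
]

LOG_FLOOR = 1e-15


@dataclass
class TrainConfig:
    """Hyperparameters of one optimization run.

    missing_fraction_range is the interval the per-batch masking
    fraction is drawn from; noise_probability is the per-batch chance
    that masked entries additionally receive random genotype values.
    """

    alpha: float = 1e-2
    beta: float = 0.0
    use_class_balance: bool = False
    learning_rate: float = 1e-2
    lr_decay_rate: float = 0.96
    lr_decay_steps: int = 100
    batch_size: int = 32
    patience: int = 300
    max_epochs: int = 1000
    missing_fraction_range: tuple = (0.0, 0.9)
    noise_probability: float = 0.2
    noise_per_entry: bool = False
    seed: int = 0

    def validate(self):
        lo, hi = self.missing_fraction_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("missing_fraction_range must satisfy 0 <= low <= high <= 1")
        if not 0.0 <= self.beta < 1.0:
            raise ValueError("beta must be in [0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0.0 <= self.noise_probability <= 1.0:
            raise ValueError("noise_probability must be a probability")
        return self


@dataclass
class TrainState:
    epoch: int = 0
    train_loss_history: list = field(default_factory=list)
    valid_loss_history: list = field(default_factory=list)
    best_valid_loss: float = np.inf
    best_epoch: int = 0
    epochs_since_improvement: int = 0
    parameters: object = None
    stopped_early: bool = False


def class_balance_weights(genotype_counts, beta: float) -> np.ndarray:
    """Effective-number-of-samples class weights.

    Raw weight per genotype class g with count n_g is
    (1 - beta) / (1 - beta**n_g); classes with zero count get weight 0.
    Weights are rescaled so their count-weighted mean equals 1, which
    keeps the overall loss scale comparable to the unweighted case.
    """
    counts = np.asarray(genotype_counts, dtype=float)
    if counts.min() < 0 or counts.sum() <= 0:
        raise ValueError("counts must be nonnegative with at least one positive")
    if not 0.0 <= beta < 1.0:
        raise ValueError("beta must be in [0, 1)")
    raw = np.zeros_like(counts)
    pos = counts > 0
    if beta == 0.0:
        raw[pos] = 1.0
    else:
        raw[pos] = (1.0 - beta) / (1.0 - beta ** counts[pos])
    mean = (raw * counts).sum() / counts.sum()
    return raw / mean


def _loss_graph(o_raw: ag.Tensor, z: ag.Tensor, targets: TargetTensor, alpha: float) -> ag.Tensor:
    """Differentiable loss on the computation graph."""
    o = ag.sigmoid(o_raw)  # (B, L)
    y = targets.probs  # (B, L, 3) constants
    w = targets.weight_mask
    p0 = ag.clip_min(ag.power(1.0 - o, 2.0), LOG_FLOOR)
    p1 = ag.clip_min(ag.mul(ag.mul(1.0 - o, o), 2.0), LOG_FLOOR)
    p2 = ag.clip_min(ag.power(o, 2.0), LOG_FLOOR)
    ce = -(
        ag.mul(ag.log(p0), y[:, :, 0])
        + ag.mul(ag.log(p1), y[:, :, 1])
        + ag.mul(ag.log(p2), y[:, :, 2])
    )
    loss = ag.tmean(ag.mul(ce, w))
    if alpha != 0.0:
        loss = loss + ag.mul(ag.tmean(ag.tsum(ag.power(z, 2.0), axis=1)), alpha)
    return loss


def reconstruction_loss(genotype_probs, targets: TargetTensor, z, alpha: float) -> float:
    """Scalar loss from already-computed genotype probabilities.

    Mean over (sample, marker) of the weighted cross-entropy
    -sum_g y_g log(max(p_g, 1e-15)), plus alpha times the mean over
    samples of the squared latent norm.
    """
    probs = np.asarray(genotype_probs, dtype=float)
    coords = z.coords if isinstance(z, LatentEmbedding) else np.asarray(z, dtype=float)
    ce = -(targets.probs * np.log(np.maximum(probs, LOG_FLOOR))).sum(axis=-1)
    loss = float((ce * targets.weight_mask).mean())
    if alpha != 0.0:
        loss += alpha * float((coords**2).sum(axis=1).mean())
    return loss


def augment_batch(
    batch: NormalizedBatch,
    missing_fraction_range=(0.0, 0.9),
    noise_probability: float = 0.2,
    rng: np.random.Generator | None = None,
    noise_per_entry: bool = False,
) -> NormalizedBatch:
    """Denoising augmentation: mask a random fraction, optionally add noise.

    One fraction f ~ Uniform(range) is drawn per batch and
    floor(f * batch * n_markers) uniformly chosen entries are set
    missing (-1.0, mask 0).  Then — with probability
    ``noise_probability``, drawn once per batch (or per entry when
    ``noise_per_entry``) — missing entries receive random genotype
    values from {0.0, 0.5, 1.0} while their mask stays 0.  Targets are
    untouched: the network must reconstruct the true genotypes.
    """
    rng = rng or np.random.default_rng()
    values = batch.values.copy()
    B, L, _ = values.shape
    lo, hi = missing_fraction_range
    f = rng.uniform(lo, hi)
    n_mask = int(np.floor(f * B * L))
    if n_mask > 0:
        flat = rng.choice(B * L, size=n_mask, replace=False)
        bi, li = np.unravel_index(flat, (B, L))
        values[bi, li, 0] = -1.0
        values[bi, li, 1] = 0.0
    miss = values[:, :, 1] == 0.0
    if miss.any() and noise_probability > 0.0:
        noise_vals = rng.choice([0.0, 0.5, 1.0], size=int(miss.sum()))
        if noise_per_entry:
            apply = rng.random(int(miss.sum())) < noise_probability
            ch0 = values[:, :, 0]
            target = ch0[miss]
            target[apply] = noise_vals[apply]
            ch0[miss] = target
            values[:, :, 0] = ch0
        elif rng.random() < noise_probability:
            values[:, :, 0][miss] = noise_vals
    return NormalizedBatch(values=values, sample_indices=batch.sample_indices)


class _Adam:
    """Adam with the published default moment parameters."""

    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def _epoch_loss(model: Autoencoder, g: GenotypeMatrix, indices, targets_full, alpha, batch_size):
    """Validation-style loss: no augmentation, inference mode."""
    total, n = 0.0, 0
    for start in range(0, len(indices), batch_size):
        idx = indices[start:start + batch_size]
        batch = normalize_batch(g, idx)
        z, o_raw = model.forward_t(batch.values, training=False)
        t = TargetTensor(probs=targets_full.probs[idx], weight_mask=targets_full.weight_mask[idx])
        loss = _loss_graph(o_raw, z, t, alpha)
        total += float(loss.data) * len(idx)
        n += len(idx)
    return total / n


def train(
    model: Autoencoder,
    data: GenotypeMatrix,
    split,
    config: TrainConfig,
    callback=None,
) -> TrainState:
    """Run the optimization loop with early stopping.

    split: (train_indices, valid_indices), disjoint and exhaustive.
    Per epoch: shuffle, augment, forward, loss, Adam step with
    lr = learning_rate * decay_rate ** (step / decay_steps); then the
    validation loss is computed without augmentation in inference mode.
    Training stops when the validation loss has not improved for
    ``patience`` epochs, restoring the best-validation parameters.
    """
    config.validate()
    train_idx, valid_idx = (np.asarray(s, dtype=int) for s in split)
    rng = np.random.default_rng(config.seed)
    model._rng = np.random.default_rng(rng.integers(2**31))

    class_weights = np.ones(3)
    if config.use_class_balance:
        counts = [(data.genotypes == v).sum() for v in (0, 1, 2)]
        class_weights = class_balance_weights(counts, config.beta)
    targets_full = one_hot_targets(data, np.arange(data.n_samples), class_weights)

    opt = _Adam(model.params)
    state = TrainState()
    best_snapshot = model.get_parameters()
    step = 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(train_idx)
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = normalize_batch(data, idx)
            batch = augment_batch(
                batch,
                config.missing_fraction_range,
                config.noise_probability,
                rng,
                noise_per_entry=config.noise_per_entry,
            )
            z, o_raw = model.forward_t(batch.values, training=True)
            t = TargetTensor(
                probs=targets_full.probs[idx], weight_mask=targets_full.weight_mask[idx]
            )
            loss = _loss_graph(o_raw, z, t, config.alpha)
            if not np.isfinite(loss.data):
                lr = config.learning_rate * config.lr_decay_rate ** (step / config.lr_decay_steps)
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, "
                    f"batch {start // config.batch_size}, lr {lr:.3g}"
                )
            opt.zero_grad()
            ag.backward(loss)
            lr = config.learning_rate * config.lr_decay_rate ** (step / config.lr_decay_steps)
            opt.step(lr)
            step += 1
            epoch_losses.append(float(loss.data))

        state.epoch = epoch
        state.train_loss_history.append(float(np.mean(epoch_losses)))
        if len(valid_idx):
            vloss = _epoch_loss(
                model, data, valid_idx, targets_full, config.alpha, config.batch_size
            )
        else:
            vloss = state.train_loss_history[-1]
        state.valid_loss_history.append(vloss)

        if vloss < state.best_valid_loss:
            state.best_valid_loss = vloss
            state.best_epoch = epoch
            state.epochs_since_improvement = 0
            best_snapshot = model.get_parameters()
        else:
            state.epochs_since_improvement += 1

        if callback is not None:
            callback(state)
        if state.epochs_since_improvement >= config.patience:
            state.stopped_early = True
            break

    model.set_parameters(best_snapshot)
    state.parameters = best_snapshot
    return state
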
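"""Supervised training of the shape-scoring network.

The loss is the root mean square error between the network outputs and the
class targets,

.. math:: \\mathrm{RMSE} = \\Big(\\tfrac1N \\sum_i (t_i - a_i)^2\\Big)^{1/2},

minimized by stochastic gradient descent with classical momentum

.. math:: v_{l+1} = \\gamma v_l - \\alpha \\nabla E(\\sigma_l), \\qquad
          \\sigma_{l+1} = \\sigma_l + v_{l+1},

with constant learning rate ``alpha = 0.001`` and momentum ``gamma = 0.9``.
Mini-batches of 128 images are drawn from the seeded-shuffled training
partition each epoch (the final short batch is kept); 5 % of the data is
held out for validation, evaluated every 50 mini-batches, and training
stops after at most ten epochs or as soon as the validation loss has risen
five consecutive times — the standard overtraining guard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .model import Model
from .synthetic import LabeledDataset, ShapeClass

__all__ = ["TrainingConfig", "LossTrace", "rmse", "sgdm_step",
           "split_validation", "train"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the SGDM training protocol (defaults as studied)."""

    learning_rate: float = 0.001
    momentum: float = 0.9
    batch_size: int = 128
    max_epochs: int = 10
    validation_fraction: float = 0.05
    validation_frequency: int = 50     # mini-batches between validation evals
    patience: int = 5                  # consecutive val-loss rises that stop
    grad_clip_norm: float = 20.0       # global-norm gradient clip (inf = off)
    shuffle_seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.max_epochs < 0 or self.validation_frequency < 1 or self.patience < 1:
            raise ValueError("invalid epoch/validation/patience setting")


@dataclass
class LossTrace:
    """Training history: per-iteration batch RMSE and periodic validation RMSE."""

    iterations: list[tuple[int, float]] = field(default_factory=list)
    validations: list[tuple[int, float]] = field(default_factory=list)
    stop_reason: str = "max_epochs"    # or "early_stop"

    def epoch_means(self, iters_per_epoch: int) -> np.ndarray:
        """Mean training RMSE per completed epoch."""
        losses = np.array([l for _, l in self.iterations])
        n_full = len(losses) // iters_per_epoch
        return losses[:n_full * iters_per_epoch].reshape(n_full, -1).mean(axis=1)


def rmse(targets: Sequence[float], outputs: Sequence[float]) -> float:
    """Root mean square error between targets and outputs.

    Zero iff the two agree elementwise; errors on empty or mismatched input.
    """
    t = np.asarray(targets, float)
    a = np.asarray(outputs, float)
    if t.size == 0:
        raise ValueError("rmse of empty input is undefined")
    if t.shape != a.shape:
        raise ValueError("targets and outputs must have equal length")
    return float(np.sqrt(np.mean((t - a) ** 2)))


def sgdm_step(params: Sequence[np.ndarray], grads: Sequence[np.ndarray],
              velocity: Sequence[np.ndarray], cfg: TrainingConfig
              ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """One classical-momentum update on a list of parameter arrays.

    ``v' = gamma * v - alpha * grad``; ``p' = p + v'``.  With zero momentum
    this reduces to plain gradient descent; with zero gradient the update
    coasts by ``gamma * v``.
    """
    if len(params) != len(grads) or len(params) != len(velocity):
        raise ValueError("params, grads and velocity must be congruent")
    new_p, new_v = [], []
    for p, g, v in zip(params, grads, velocity):
        g = np.asarray(g)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(
                f"non-finite gradient (max |g| = {np.abs(g).max()!r})")
        v2 = cfg.momentum * np.asarray(v) - cfg.learning_rate * g
        new_v.append(v2)
        new_p.append(np.asarray(p) + v2)
    return new_p, new_v


def split_validation(ds: LabeledDataset, cfg: TrainingConfig
                     ) -> tuple[LabeledDataset, LabeledDataset]:
    """Randomly hold out ``validation_fraction`` of the dataset (seeded).

    Returns the disjoint ``(train, validation)`` partition with
    ``len(val) = round(fraction * len(ds))``.
    """
    n = len(ds)
    n_val = int(round(cfg.validation_fraction * n))
    if n_val < 1 or n - n_val < 1:
        raise ValueError(
            f"dataset of {n} images cannot support a "
            f"{cfg.validation_fraction:.0%} validation split")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.shuffle_seed, 101]))
    perm = rng.permutation(n)
    return ds.subset(perm[n_val:]), ds.subset(perm[:n_val])


def _check_trainable(ds: LabeledDataset) -> None:
    if len(ds) == 0:
        raise ValueError("cannot train on an empty dataset")
    for i, lab in enumerate(ds.labels):
        if lab is None or lab is ShapeClass.OTHER:
            raise ValueError(
                f"image {i} has label {getattr(lab, 'value', None)!r}; only "
                "slipper/croissant/sheared_croissant carry training targets")


def train(model: Model, ds: LabeledDataset, cfg: TrainingConfig | None = None,
          val_fn: Callable[[Model], float] | None = None
          ) -> tuple[Model, LossTrace]:
    """Train the model in place on a (preprocessed) labeled dataset.

    ``ds.images`` must already be contrast-stretched and Tukey-windowed.
    Every epoch reshuffles the training partition with a per-epoch child
    seed; each mini-batch performs one SGDM step on the batch RMSE.  Every
    ``validation_frequency`` iterations the validation RMSE is recorded;
    ``patience`` consecutive strictly-rising validation losses end the run
    early.

    ``val_fn`` optionally replaces the validation evaluator (used for
    testing the stopping rule); it receives the model and returns a loss.

    Returns the trained model and the full :class:`LossTrace`.
    """
    if cfg is None:
        cfg = TrainingConfig()
    _check_trainable(ds)
    trace = LossTrace()
    if cfg.max_epochs == 0:
        return model, trace

    train_ds, val_ds = split_validation(ds, cfg)
    X = np.asarray(train_ds.images, float)[:, None, :, :]
    t = train_ds.targets()
    Xv = np.asarray(val_ds.images, float)
    tv = val_ds.targets()
    if val_fn is None:
        def val_fn(m: Model) -> float:
            return rmse(tv, m.forward(Xv))

    params = model.parameters()
    velocity = [np.zeros_like(p) for p in params]
    it = 0
    eps = 1e-12
    for epoch in range(cfg.max_epochs):
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.shuffle_seed, 977, epoch]))
        order = rng.permutation(len(X))
        for start in range(0, len(X), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, tb = X[idx], t[idx]
            scores, cache = model._forward_cached(xb)
            err = scores - tb
            loss = float(np.sqrt(np.mean(err ** 2)))
            # d RMSE / d a_i = (a_i - t_i) / (N * RMSE)
            dscores = err / (len(idx) * max(loss, eps))
            grads = model._backward(cache, dscores)
            grads = _clip_global_norm(grads, cfg.grad_clip_norm)
            params, velocity = sgdm_step(params, grads, velocity, cfg)
            model.set_parameters(params)
            it += 1
            trace.iterations.append((it, loss))
            if it % cfg.validation_frequency == 0:
                vloss = float(val_fn(model))
                trace.validations.append((it, vloss))
                log.info("iter %d epoch %d train_rmse %.3f val_rmse %.3f",
                         it, epoch, loss, vloss)
                if _rising(trace.validations, cfg.patience):
                    trace.stop_reason = "early_stop"
                    return model, trace
        log.info("epoch %d done: mean train_rmse %.3f", epoch,
                 np.mean([l for _, l in trace.iterations[-(start // cfg.batch_size + 1):]]))
    trace.stop_reason = "max_epochs"
    return model, trace


def _clip_global_norm(grads: list[np.ndarray], max_norm: float) -> list[np.ndarray]:
    """Rescale the whole gradient so its global L2 norm is <= max_norm.

    Direction-preserving clipping guards the momentum updates against the
    transient gradient spikes a deep ReLU stack produces once its weights
    have grown; without it a single spike can kill every rectifier.
    """
    if not np.isfinite(max_norm):
        return grads
    norm = np.sqrt(sum(float((np.asarray(g, float) ** 2).sum()) for g in grads))
    if norm <= max_norm:
        return grads
    scale = max_norm / norm
    return [g * scale for g in grads]


def _rising(validations: list[tuple[int, float]], patience: int) -> bool:
    """True when the last ``patience`` validation losses each rose strictly."""
    if len(validations) < patience + 1:
        return False
    tail = [v for _, v in validations[-(patience + 1):]]
    return all(b > a for a, b in zip(tail, tail[1:]))
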
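"""The two learned surrogates: evolution (field -> next field) and property
(structure -> nine orthotropic stiffness constants).

The evolution surrogate is an encoder-decoder ("U"-shaped) fully
convolutional network with skip connections and circular padding.  It is
trained on neighboring-save pairs from phase-field trajectories and applied
iteratively (rollout) to simulate whole decompositions; being fully
convolutional it accepts any input whose axes are divisible by
``2**depth``, which is what allows generating structures much larger than
the training size.  The network predicts the *increment* to the input field
(residual connection, final layer zero-initialized) and passes the result
through a soft clamp at the divergence bound, so an untrained model is the
identity and trained rollouts cannot escape the physical range.

The property surrogate is an image-labeling style network: convolutional
stages with 2x pooling, global average pooling, and a linear head to the 9
orthotropic constants.  Global pooling plus circular padding make the
prediction invariant to circular shifts of the structure (exactly so for
shifts divisible by the total pooling factor).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional, Sequence

import numpy as np

from ..grids import GridSpec, PhaseField, ValidationError
from ..cahn_hilliard import Trajectory, CHParams
from . import nn

__all__ = [
    "EvolutionSurrogateSpec",
    "PropertySurrogateSpec",
    "TrainingConfig",
    "EvolutionSurrogate",
    "PropertySurrogate",
    "train_evolution_surrogate",
    "train_property_surrogate",
    "circular_pad_check",
    "rollout",
]


@dataclass(frozen=True)
class EvolutionSurrogateSpec:
    """Architecture of the evolution network.

    ``depth`` resolution levels below the input one; channel width doubles
    per level starting from ``base_channels``.  Input axes must be divisible
    by ``2**depth``.  Circular padding is fixed by design; ``padding_mode``
    exists only for the reflect-padding ablation.  Loss: mean squared error.
    """

    depth: int = 3
    base_channels: int = 16
    kernel: int = 3
    padding_mode: str = "circular"
    clamp: float = 1.5

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_channels < 1:
            raise ValidationError("depth and base_channels must be >= 1")

    @property
    def divisor(self) -> int:
        return 2**self.depth


@dataclass(frozen=True)
class PropertySurrogateSpec:
    """Architecture of the property network (9 outputs, MAE loss)."""

    conv_stages: int = 3
    base_channels: int = 8
    kernel: int = 3
    n_outputs: int = 9

    def __post_init__(self) -> None:
        if self.conv_stages < 1 or self.base_channels < 1:
            raise ValidationError("conv_stages and base_channels must be >= 1")
        if self.n_outputs != 9:
            raise ValidationError("property surrogate predicts 9 orthotropic constants")

    @property
    def divisor(self) -> int:
        return 2**self.conv_stages


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings.

    Paper-scale defaults are 100 epochs (evolution) / 300 (property) at
    batch 16; desk-scale runs override ``epochs``.  The learning rate
    follows cosine decay from ``lr`` to ``lr/100``.
    """

    epochs: int = 100
    batch_size: int = 16
    lr: float = 2e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.lr <= 0:
            raise ValidationError("epochs, batch_size and lr must be positive")

    def lr_at(self, epoch: int) -> float:
        t = epoch / max(self.epochs - 1, 1)
        return self.lr / 100 + 0.5 * (self.lr - self.lr / 100) * (1 + np.cos(np.pi * t))


def _check_shape(shape: Sequence[int], divisor: int) -> None:
    if any(s % divisor for s in shape):
        raise ValidationError(
            f"input shape {tuple(shape)} must be divisible by {divisor} "
            "(2**depth) along every axis"
        )


class EvolutionSurrogate:
    """Encoder-decoder evolution network with skip connections."""

    def __init__(self, spec: EvolutionSurrogateSpec = EvolutionSurrogateSpec(),
                 seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        ch = [spec.base_channels * 2**k for k in range(spec.depth + 1)]
        mk = lambda ci, co, zero=False: nn.Conv3d(
            ci, co, spec.kernel, rng=rng, padding_mode=spec.padding_mode,
            dtype=dtype, zero_init=zero)
        self.enc = [mk(1 if k == 0 else ch[k - 1], ch[k]) for k in range(spec.depth)]
        self.bottom = mk(ch[spec.depth - 1], ch[spec.depth])
        self.dec = [mk(ch[k] + ch[k + 1], ch[k]) for k in reversed(range(spec.depth))]
        self.head = nn.Conv3d(ch[0], 1, 1, rng=rng, dtype=dtype, zero_init=True)
        self.pools = [nn.AvgPool() for _ in range(spec.depth)]
        self.ups = [nn.Upsample() for _ in range(spec.depth)]
        self.acts_enc = [nn.Tanh() for _ in range(spec.depth)]
        self.act_bottom = nn.Tanh()
        self.acts_dec = [nn.Tanh() for _ in range(spec.depth)]
        self.clamp = nn.SoftClamp(spec.clamp)

    @property
    def params(self):
        layers = self.enc + [self.bottom] + self.dec + [self.head]
        return [pg for layer in layers for pg in layer.params]

    def _mark_dirty(self) -> None:
        for layer in self.enc + [self.bottom] + self.dec + [self.head]:
            layer.mark_dirty()

    # -- forward / backward ----------------------------------------------
    def _net_forward(self, x: np.ndarray) -> np.ndarray:
        d = self.spec.depth
        skips = []
        h = x
        for k in range(d):
            h = self.acts_enc[k].forward(self.enc[k].forward(h))
            skips.append(h)
            h = self.pools[k].forward(h)
        h = self.act_bottom.forward(self.bottom.forward(h))
        for k in range(d):
            h = self.ups[k].forward(h)
            h = np.concatenate([skips[d - 1 - k], h], axis=1)
            h = self.acts_dec[k].forward(self.dec[k].forward(h))
        delta = self.head.forward(h)
        return self.clamp.forward(x + delta)

    def _net_backward(self, grad: np.ndarray) -> np.ndarray:
        d = self.spec.depth
        g = self.clamp.backward(grad)
        g_x = g.copy()  # residual connection
        g = self.head.backward(g)
        g_skips = []
        for k in reversed(range(d)):
            g = self.dec[k].backward(self.acts_dec[k].backward(g))
            n_skip = self.enc[d - 1 - k].out_channels
            g_skip, g = g[:, :n_skip], g[:, n_skip:]
            g_skips.append(g_skip)
            g = self.ups[k].backward(g)
        g = self.bottom.backward(self.act_bottom.backward(g))
        for k in reversed(range(d)):
            g = self.pools[k].backward(g)
            g = g + g_skips[k]
            g = self.enc[k].backward(self.acts_enc[k].backward(g))
        return g + g_x

    # -- public API -------------------------------------------------------
    def predict(self, field: np.ndarray) -> np.ndarray:
        """Next-save field for a (X, Y, Z) or (B, 1, X, Y, Z) input."""
        single = field.ndim == 3
        x = field[None, None] if single else field
        _check_shape(x.shape[2:], self.spec.divisor)
        y = self._net_forward(np.ascontiguousarray(x, dtype=self.dtype))
        return y[0, 0] if single else y

    def train_step(self, x: np.ndarray, y: np.ndarray,
                   optimizer: nn.Adam) -> float:
        optimizer.zero_grad()
        pred = self._net_forward(x)
        loss, grad = nn.mse_loss(pred, y)
        self._net_backward(grad.astype(self.dtype))
        optimizer.step()
        self._mark_dirty()
        return loss

    def evaluate(self, x: np.ndarray, y: np.ndarray,
                 batch_size: int = 16) -> float:
        total, n = 0.0, 0
        for k in range(0, len(x), batch_size):
            pred = self._net_forward(np.ascontiguousarray(x[k:k + batch_size],
                                                          dtype=self.dtype))
            total += float(np.sum((pred.astype(np.float64)
                                   - y[k:k + batch_size]) ** 2))
            n += pred.size
        return total / n


class PropertySurrogate:
    """Convolutional stages + global average pooling + linear head."""

    def __init__(self, spec: PropertySurrogateSpec = PropertySurrogateSpec(),
                 seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        ch = [spec.base_channels * 2**k for k in range(spec.conv_stages)]
        self.convs = [nn.Conv3d(1 if k == 0 else ch[k - 1], ch[k], spec.kernel,
                                rng=rng, dtype=dtype)
                      for k in range(spec.conv_stages)]
        self.acts = [nn.Tanh() for _ in range(spec.conv_stages)]
        self.pools = [nn.AvgPool() for _ in range(spec.conv_stages)]
        self.gap = nn.GlobalAvgPool()
        self.headact = nn.Tanh()
        self.hidden = nn.Linear(ch[-1], 2 * ch[-1], rng=rng, dtype=dtype)
        self.head = nn.Linear(2 * ch[-1], spec.n_outputs, rng=rng, dtype=dtype)
        # label standardization (set by the trainer from the train split);
        # the network learns in normalized space, predictions are reported
        # in physical units
        self.label_mean = np.zeros(spec.n_outputs)
        self.label_scale = np.ones(spec.n_outputs)

    @property
    def params(self):
        layers = self.convs + [self.hidden, self.head]
        return [pg for layer in layers for pg in layer.params]

    def _mark_dirty(self) -> None:
        for conv in self.convs:
            conv.mark_dirty()

    def _net_forward(self, x: np.ndarray) -> np.ndarray:
        h = x
        for conv, act, pool in zip(self.convs, self.acts, self.pools):
            h = pool.forward(act.forward(conv.forward(h)))
        h = self.gap.forward(h)
        h = self.headact.forward(self.hidden.forward(h))
        return self.head.forward(h)

    def _net_backward(self, grad: np.ndarray) -> None:
        g = self.head.backward(grad)
        g = self.hidden.backward(self.headact.backward(g))
        g = self.gap.backward(g)
        for conv, act, pool in zip(reversed(self.convs), reversed(self.acts),
                                   reversed(self.pools)):
            g = conv.backward(act.backward(pool.backward(g)))

    def predict(self, structure: np.ndarray) -> np.ndarray:
        """Nine orthotropic constants for a binary (X,Y,Z) volume or a
        (B, 1, X, Y, Z) batch.  Solid voxels map to +1, pore to -1."""
        single = structure.ndim == 3
        x = structure[None, None] if single else structure
        _check_shape(x.shape[2:], self.spec.divisor)
        x = np.ascontiguousarray(
            np.where(x > 0.5, 1.0, -1.0), dtype=self.dtype)
        y = self._net_forward(x) * self.label_scale + self.label_mean
        return y[0] if single else y

    def train_step(self, x: np.ndarray, y: np.ndarray,
                   optimizer: nn.Adam) -> float:
        """One optimizer step; ``y`` in physical units, loss in normalized
        space (the reported value is rescaled back for interpretability)."""
        optimizer.zero_grad()
        x = np.ascontiguousarray(np.where(x > 0.5, 1.0, -1.0), dtype=self.dtype)
        yn = ((y - self.label_mean) / self.label_scale).astype(self.dtype)
        pred = self._net_forward(x)
        loss, grad = nn.mae_loss(pred, yn)
        self._net_backward(grad)
        optimizer.step()
        self._mark_dirty()
        return loss * float(np.mean(self.label_scale))

    def evaluate(self, x: np.ndarray, y: np.ndarray,
                 batch_size: int = 16) -> dict:
        """Overall and per-component MAE over a dataset."""
        preds = []
        for k in range(0, len(x), batch_size):
            xb = np.ascontiguousarray(
                np.where(x[k:k + batch_size] > 0.5, 1.0, -1.0), dtype=self.dtype)
            preds.append(self._net_forward(xb))
        pred = (np.concatenate(preds).astype(np.float64) * self.label_scale
                + self.label_mean)
        err = np.abs(pred - y)
        return {"mae": float(err.mean()),
                "mae_per_component": err.mean(axis=0).tolist()}


def train_evolution_surrogate(
    data,
    spec: EvolutionSurrogateSpec = EvolutionSurrogateSpec(),
    config: TrainingConfig = TrainingConfig(),
    verbose: bool = False,
) -> tuple[EvolutionSurrogate, dict]:
    """Minimize one-step MSE on the pair dataset; returns (model, curves).

    ``curves`` holds per-epoch train and validation MSE.  Training aborts
    with a RuntimeError on a non-finite loss (naming the epoch and batch)
    rather than continuing from a poisoned state.
    """
    if len(data.x) == 0:
        raise ValidationError("empty pair dataset")
    model = EvolutionSurrogate(spec, seed=config.seed)
    opt = nn.Adam(model.params, lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    train_idx = np.asarray(data.train_idx)
    curves = {"train_mse": [], "val_mse": []}
    for epoch in range(config.epochs):
        opt.lr = config.lr_at(epoch)
        order = rng.permutation(train_idx)
        losses = []
        for b in range(0, len(order), config.batch_size):
            idx = order[b:b + config.batch_size]
            loss = model.train_step(
                np.ascontiguousarray(data.x[idx], dtype=model.dtype),
                np.ascontiguousarray(data.y[idx], dtype=model.dtype), opt)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch "
                    f"{b // config.batch_size}")
            losses.append(loss)
        curves["train_mse"].append(float(np.mean(losses)))
        if len(data.val_idx):
            curves["val_mse"].append(
                model.evaluate(data.x[data.val_idx], data.y[data.val_idx],
                               config.batch_size))
        if verbose:
            val = curves["val_mse"][-1] if curves["val_mse"] else float("nan")
            print(f"epoch {epoch}: train {curves['train_mse'][-1]:.3e} "
                  f"val {val:.3e}")
    return model, curves


def train_property_surrogate(
    data,
    spec: PropertySurrogateSpec = PropertySurrogateSpec(),
    config: TrainingConfig = TrainingConfig(epochs=300),
    verbose: bool = False,
) -> tuple[PropertySurrogate, dict]:
    """Minimize MAE on the property dataset; returns (model, metrics).

    ``metrics`` holds the training curve and the held-out test MAE, overall
    and per orthotropic component.
    """
    if len(data.structures) == 0:
        raise ValidationError("empty property dataset")
    model = PropertySurrogate(spec, seed=config.seed)
    train_labels = data.labels[np.asarray(data.train_idx)]
    model.label_mean = train_labels.mean(axis=0)
    model.label_scale = np.maximum(train_labels.std(axis=0), 1e-6)
    opt = nn.Adam(model.params, lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    train_idx = np.asarray(data.train_idx)
    metrics = {"train_mae": [], "val_mae": []}
    for epoch in range(config.epochs):
        opt.lr = config.lr_at(epoch)
        order = rng.permutation(train_idx)
        losses = []
        for b in range(0, len(order), config.batch_size):
            idx = order[b:b + config.batch_size]
            loss = model.train_step(data.structures[idx], data.labels[idx], opt)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch "
                    f"{b // config.batch_size}")
            losses.append(loss)
        metrics["train_mae"].append(float(np.mean(losses)))
        if len(data.val_idx):
            metrics["val_mae"].append(
                model.evaluate(data.structures[data.val_idx],
                               data.labels[data.val_idx],
                               config.batch_size)["mae"])
        if verbose:
            print(f"epoch {epoch}: train {metrics['train_mae'][-1]:.4f}")
    if len(data.test_idx):
        metrics["test"] = model.evaluate(data.structures[data.test_idx],
                                         data.labels[data.test_idx],
                                         config.batch_size)
    return model, metrics


def circular_pad_check(
    model: EvolutionSurrogate,
    field: PhaseField,
    shifts: Optional[list[tuple[int, int, int]]] = None,
) -> float:
    """Max |predict(shift(x)) - shift(predict(x))| over circular shifts.

    For shifts that are multiples of the total downsampling factor the
    residual is floating-point small; incommensurate shifts or non-circular
    padding give materially larger residuals.
    """
    div = model.spec.divisor
    if shifts is None:
        shifts = [(div, 0, 0), (0, div, 0), (0, 0, div), (div, div, div),
                  (2 * div, div, 0)]
    base = model.predict(field.values.astype(model.dtype))
    worst = 0.0
    for s in shifts:
        shifted_pred = model.predict(np.roll(field.values, s, axis=(0, 1, 2))
                                     .astype(model.dtype))
        pred_shifted = np.roll(base, s, axis=(0, 1, 2))
        worst = max(worst, float(np.max(np.abs(shifted_pred - pred_shifted))))
    return worst


def rollout(model: EvolutionSurrogate, init: PhaseField, n_steps: int,
            params: Optional[CHParams] = None) -> Trajectory:
    """Iterate the surrogate from an initial field, like a physics run.

    The returned trajectory has the same structure as the solver's (save 0
    is the initial field), so every downstream morphology and property
    operation applies unchanged.  Input axes must be divisible by
    ``2**depth``; sizes larger than the training size are explicitly
    supported (the learned kinetics are local and size-independent).
    """
    _check_shape(init.grid.shape, model.spec.divisor)
    params = params or CHParams(n_saves=n_steps)
    phi = init.values.astype(model.dtype)
    saves = [PhaseField(phi.astype(np.float64), init.grid, 0)]
    for step in range(1, n_steps + 1):
        phi = model.predict(phi)
        saves.append(PhaseField(phi.astype(np.float64), init.grid, step))
    return Trajectory(saves, params, init_spec={"rollout": True})
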
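"""Residual denoising CNN for projection-domain metal artifact reduction.

The network learns the residual between a polychromatic low-energy
projection and its beam-hardening-free virtual-monochromatic reference:
given 32x32 patch pairs (P_L, P_L - VM), it minimizes

    q(delta) = 1/(2N) sum_j || U(P_L^j; delta) - (P_L^j - VM^j) ||^2

by mini-batch stochastic gradient descent with momentum and weight decay.
At inference the predicted residual is subtracted from the input projection
to obtain the corrected stack.

Architecture (depth D): one 3x3 conv + ReLU, D-2 blocks of 3x3 conv + batch
normalization + ReLU, and a final single-channel 3x3 conv; stride 1, zero
padding 1, so spatial shape is preserved end to end. The implementation is
plain NumPy (per-offset tensor contractions for the convolutions, manual
backpropagation), which keeps the package self-contained and fast enough at
desk scale; the clinical-scale configuration (depth 20, 64 channels) is
expressible but meant for long runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .projector import ProjectionStack

__all__ = [
    "TrainingConfig",
    "PatchSet",
    "DnCNNModel",
    "build_model",
    "make_training_patches",
    "train_sgdm",
    "predict_residual",
    "correct_projections",
    "DivergenceError",
]


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")
        self.epoch = epoch


@dataclass
class TrainingConfig:
    """SGDM hyperparameters; the clinical defaults are lr 0.1, momentum 0.9,
    weight decay 1e-4, mini-batch 544, 60 epochs, 32x32 patches."""

    learning_rate: float = 0.1
    momentum: float = 0.9
    weight_decay: float = 1e-4
    mini_batch: int = 544
    epochs: int = 60
    patch_size: int = 32
    n_patches: int | None = None  # explicit override of the cropping rule
    crop_rule: str = "total"  # "total": batch*epochs*views crops; "per_epoch": batch*views
    seed: int = 0
    halve_lr_on_nan: bool = True

    def __post_init__(self):
        for name in ("learning_rate", "momentum", "weight_decay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mini_batch <= 0 or self.epochs <= 0 or self.patch_size <= 0:
            raise ValueError("mini_batch, epochs and patch_size must be positive")
        if self.crop_rule not in ("total", "per_epoch"):
            raise ValueError("crop_rule must be 'total' or 'per_epoch'")

    def patch_count(self, n_views: int) -> int:
        if self.n_patches is not None:
            return int(self.n_patches)
        if self.crop_rule == "total":
            return self.mini_batch * self.epochs * n_views
        return self.mini_batch * n_views


@dataclass
class PatchSet:
    """Paired (input, residual-target) training patches.

    ``inputs`` and ``targets`` have shape (N, 1, ps, ps); the target of each
    pair is input - reference, elementwise.
    """

    inputs: np.ndarray
    targets: np.ndarray
    view_indices: np.ndarray

    def __post_init__(self):
        if self.inputs.shape != self.targets.shape:
            raise ValueError("inputs and targets must have the same shape")
        if self.inputs.ndim != 4 or self.inputs.shape[1] != 1:
            raise ValueError("patches must be (N, 1, ps, ps)")
        if self.inputs.shape[0] == 0:
            raise ValueError("patch set is empty")

    def __len__(self) -> int:
        return self.inputs.shape[0]


# ------------------------------------------------------------------ layers


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3 same-shape convolution, zero padding 1, stride 1.

    x: (N, Cin, H, W); W: (Cout, Cin, 3, 3); returns (N, Cout, H, W).
    """
    n, cin, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.zeros((n, W.shape[0], h, w))
    for dy in range(3):
        for dx in range(3):
            patch = xp[:, :, dy : dy + h, dx : dx + w]
            out += np.tensordot(patch, W[:, :, dy, dx], axes=([1], [1])).transpose(0, 3, 1, 2)
    return out + b[None, :, None, None]


def _conv_backward(x: np.ndarray, W: np.ndarray, dout: np.ndarray):
    """Gradients of the 3x3 same convolution: returns (dx, dW, db)."""
    n, cin, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    dxp = np.zeros_like(xp)
    dW = np.zeros_like(W)
    for dy in range(3):
        for dx in range(3):
            patch = xp[:, :, dy : dy + h, dx : dx + w]
            # dW[o, i, dy, dx] = sum_{n,h,w} dout[n,o,h,w] * patch[n,i,h,w]
            dW[:, :, dy, dx] = np.tensordot(dout, patch, axes=([0, 2, 3], [0, 2, 3]))
            dxp[:, :, dy : dy + h, dx : dx + w] += np.tensordot(
                dout, W[:, :, dy, dx], axes=([1], [0])
            ).transpose(0, 3, 1, 2)
    db = dout.sum(axis=(0, 2, 3))
    return dxp[:, :, 1:-1, 1:-1], dW, db


_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9  # retention of the running moments


class _Layer:
    """One network stage: conv, optional BN, optional ReLU."""

    def __init__(self, W, b, bn: bool, relu: bool):
        self.W = W
        self.b = b
        self.relu = relu
        self.bn = bn
        if bn:
            c = W.shape[0]
            self.gamma = np.ones(c)
            self.beta = np.zeros(c)
            self.run_mean = np.zeros(c)
            self.run_var = np.ones(c)

    def params(self):
        ps = {"W": self.W, "b": self.b}
        if self.bn:
            ps["gamma"] = self.gamma
            ps["beta"] = self.beta
        return ps

    def forward(self, x, training: bool):
        cache = {"x": x}
        y = _conv_forward(x, self.W, self.b)
        if self.bn:
            if training:
                mean = y.mean(axis=(0, 2, 3))
                var = y.var(axis=(0, 2, 3))
                self.run_mean = _BN_MOMENTUM * self.run_mean + (1 - _BN_MOMENTUM) * mean
                self.run_var = _BN_MOMENTUM * self.run_var + (1 - _BN_MOMENTUM) * var
            else:
                mean, var = self.run_mean, self.run_var
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            xhat = (y - mean[None, :, None, None]) * inv_std[None, :, None, None]
            cache.update(y=y, xhat=xhat, inv_std=inv_std)
            y = self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]
        if self.relu:
            cache["mask"] = y > 0
            y = np.maximum(y, 0.0)
        cache["out"] = y
        return y, cache

    def backward(self, dout, cache):
        grads = {}
        if self.relu:
            dout = dout * cache["mask"]
        if self.bn:
            xhat, inv_std = cache["xhat"], cache["inv_std"]
            m = dout.shape[0] * dout.shape[2] * dout.shape[3]
            grads["gamma"] = np.sum(dout * xhat, axis=(0, 2, 3))
            grads["beta"] = np.sum(dout, axis=(0, 2, 3))
            dxhat = dout * self.gamma[None, :, None, None]
            dvar_term = np.sum(dxhat * xhat, axis=(0, 2, 3))
            dmean_term = np.sum(dxhat, axis=(0, 2, 3))
            dout = (
                inv_std[None, :, None, None]
                / m
                * (m * dxhat - dmean_term[None, :, None, None] - xhat * dvar_term[None, :, None, None])
            )
        dx, dW, db = _conv_backward(cache["x"], self.W, dout)
        grads["W"] = dW
        grads["b"] = db
        return dx, grads


@dataclass
class DnCNNModel:
    """The residual network: layer list plus architecture metadata."""

    depth: int
    channels: int
    layers: list
    seed: int = 0
    trained: bool = False
    kernel: int = 3

    def layer_kinds(self):
        """Sequence like ['conv+relu', 'conv+bn+relu', ..., 'conv']."""
        kinds = []
        for lyr in self.layers:
            k = "conv"
            if lyr.bn:
                k += "+bn"
            if lyr.relu:
                k += "+relu"
            kinds.append(k)
        return kinds

    def forward(self, x: np.ndarray, training: bool = False):
        caches = []
        for lyr in self.layers:
            x, c = lyr.forward(x, training)
            caches.append(c)
        return x, caches

    def save(self, path) -> None:
        """Serialize weights + architecture to a single HDF5 container."""
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["depth"] = self.depth
            f.attrs["channels"] = self.channels
            f.attrs["seed"] = self.seed
            f.attrs["trained"] = self.trained
            for i, lyr in enumerate(self.layers):
                g = f.create_group(f"layer{i:02d}")
                g.attrs["bn"] = lyr.bn
                g.attrs["relu"] = lyr.relu
                g["W"] = lyr.W
                g["b"] = lyr.b
                if lyr.bn:
                    g["gamma"] = lyr.gamma
                    g["beta"] = lyr.beta
                    g["run_mean"] = lyr.run_mean
                    g["run_var"] = lyr.run_var

    @classmethod
    def load(cls, path) -> "DnCNNModel":
        import h5py

        layers = []
        with h5py.File(path, "r") as f:
            names = sorted(k for k in f.keys() if k.startswith("layer"))
            for name in names:
                g = f[name]
                lyr = _Layer(g["W"][...], g["b"][...], bool(g.attrs["bn"]), bool(g.attrs["relu"]))
                if lyr.bn:
                    lyr.gamma = g["gamma"][...]
                    lyr.beta = g["beta"][...]
                    lyr.run_mean = g["run_mean"][...]
                    lyr.run_var = g["run_var"][...]
                layers.append(lyr)
            model = cls(
                depth=int(f.attrs["depth"]),
                channels=int(f.attrs["channels"]),
                layers=layers,
                seed=int(f.attrs["seed"]),
                trained=bool(f.attrs["trained"]),
            )
        return model


def build_model(depth: int = 20, channels: int = 64, seed: int = 0) -> DnCNNModel:
    """Construct the residual network with He-scaled random initialization.

    Layer plan: 1 conv+ReLU (single-channel input), depth-2 conv+BN+ReLU
    blocks, 1 final conv back to a single channel. Deterministic per seed.
    """
    if depth < 3:
        raise ValueError("depth must be at least 3 (first, middle, last layer)")
    rng = np.random.default_rng(seed)
    layers = []

    def he(cout, cin):
        fan_in = cin * 9
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, 3, 3))

    layers.append(_Layer(he(channels, 1), np.zeros(channels), bn=False, relu=True))
    for _ in range(depth - 2):
        layers.append(_Layer(he(channels, channels), np.zeros(channels), bn=True, relu=True))
    layers.append(_Layer(he(1, channels), np.zeros(1), bn=False, relu=False))
    return DnCNNModel(depth=depth, channels=channels, layers=layers, seed=seed)


def make_training_patches(
    object_stack: ProjectionStack,
    reference_stack: ProjectionStack,
    cfg: TrainingConfig,
    views: np.ndarray | None = None,
) -> PatchSet:
    """Crop seeded random 32x32 patch pairs (input, input - reference).

    ``views`` restricts cropping to a subset of view indices (training
    split); by default all views are used. The number of crops follows the
    configured cropping rule unless ``cfg.n_patches`` overrides it.
    """
    if not object_stack.congruent_with(reference_stack):
        raise ValueError("object and reference stacks are not congruent")
    ps = cfg.patch_size
    nviews, h, w = object_stack.data.shape
    if ps > h or ps > w:
        raise ValueError(f"patch size {ps} exceeds projection dimensions {h}x{w}")
    if views is None:
        views = np.arange(nviews)
    views = np.asarray(views, dtype=np.int64)

    count = cfg.patch_count(len(views))
    rng = np.random.default_rng(cfg.seed)
    vi = views[rng.integers(0, len(views), size=count)]
    ri = rng.integers(0, h - ps + 1, size=count)
    ci = rng.integers(0, w - ps + 1, size=count)

    inputs = np.empty((count, 1, ps, ps))
    targets = np.empty_like(inputs)
    residual = object_stack.data - reference_stack.data
    for n in range(count):
        inputs[n, 0] = object_stack.data[vi[n], ri[n] : ri[n] + ps, ci[n] : ci[n] + ps]
        targets[n, 0] = residual[vi[n], ri[n] : ri[n] + ps, ci[n] : ci[n] + ps]
    return PatchSet(inputs=inputs, targets=targets, view_indices=vi)


def train_sgdm(model: DnCNNModel, patches: PatchSet, cfg: TrainingConfig):
    """Mini-batch SGD with momentum and weight decay on the residual loss.

    Minimizes q = 1/(2N) sum ||U(x) - t||^2 per batch. Weight decay acts on
    the convolution weights only (standard practice; BN parameters and
    biases are not decayed). On a non-finite loss the guard restores the
    epoch-start parameters and halves the learning rate; if disabled (or
    the rate collapses), a DivergenceError reports the epoch.

    Returns (model, per-epoch mean training loss).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    lr = cfg.learning_rate
    vel = [{k: np.zeros_like(v) for k, v in lyr.params().items()} for lyr in model.layers]

    n = len(patches)
    losses = []
    for epoch in range(cfg.epochs):
        snapshot = [
            {k: v.copy() for k, v in lyr.params().items()} for lyr in model.layers
        ]
        order = rng.permutation(n)
        epoch_loss = 0.0
        nb = 0
        for start in range(0, n, cfg.mini_batch):
            idx = order[start : start + cfg.mini_batch]
            x = patches.inputs[idx]
            t = patches.targets[idx]
            out, caches = model.forward(x, training=True)
            diff = out - t
            # half mean squared error per pixel: the patch norm is averaged
            # over the patch grid so the loss (and the 0.1 learning rate)
            # is independent of the patch size
            loss = 0.5 * np.mean(diff**2)
            epoch_loss += loss
            nb += 1
            dout = diff / diff.size
            for lyr, cache, v in zip(model.layers[::-1], caches[::-1], vel[::-1]):
                dout, grads = lyr.backward(dout, cache)
                params = lyr.params()
                for k, g in grads.items():
                    if k == "W":
                        g = g + cfg.weight_decay * params[k]
                    v[k] = cfg.momentum * v[k] - lr * g
                    params[k] += v[k]
        mean_loss = epoch_loss / max(nb, 1)
        if not np.isfinite(mean_loss):
            if not cfg.halve_lr_on_nan:
                raise DivergenceError(epoch)
            for lyr, snap in zip(model.layers, snapshot):
                for k, v in snap.items():
                    lyr.params()[k][...] = v
            vel = [{k: np.zeros_like(v) for k, v in lyr.params().items()} for lyr in model.layers]
            lr *= 0.5
            if lr < 1e-8:
                raise DivergenceError(epoch)
            losses.append(np.inf)
            continue
        losses.append(float(mean_loss))
    model.trained = True
    return model, losses


def predict_residual(
    model: DnCNNModel, stack: ProjectionStack, allow_untrained: bool = False
) -> ProjectionStack:
    """Feed-forward residual estimate for a whole stack (inference mode).

    Batch normalization uses the running moments; the output stack is
    congruent with the input and tagged as residual. Deterministic: two
    calls on the same model and stack agree bitwise.
    """
    if not model.trained and not allow_untrained:
        raise ValueError("model is untrained; pass allow_untrained=True to override")
    x = stack.data[:, None, :, :].astype(np.float64)
    out, _ = model.forward(x, training=False)
    return ProjectionStack(
        data=out[:, 0], geometry=stack.geometry, tag="residual", convention=stack.convention
    )


def correct_projections(
    object_stack: ProjectionStack, residual_stack: ProjectionStack
) -> ProjectionStack:
    """Artifact-reduced stack: object minus estimated residual, elementwise."""
    if not object_stack.congruent_with(residual_stack):
        raise ValueError("object and residual stacks are not congruent")
    return ProjectionStack(
        data=object_stack.data - residual_stack.data,
        geometry=object_stack.geometry,
        tag="corrected",
        convention=object_stack.convention,
    )
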
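"""Patch-based 3-D U-net dose-rate regressor.

Maps two-channel (PET, CT) patches to single-channel dose-rate patches.  The
architecture follows the classic U-net: a contracting path of 3×3×3
convolutions each followed by batch normalisation and ReLU with 2×2×2 max
pooling between levels and feature maps doubling per level (first layer
width 14 by default), and an expanding path of stride-2 transposed
convolutions with skip concatenation and feature maps halving (ReLU only —
no batch normalisation on the way up).  Training minimises the L1 norm
between predicted and ground-truth dose-rate patches with Adam.

The network is implemented directly on numpy with hand-written forward and
backward passes (im2col-style convolutions via ``sliding_window_view`` and
einsum).  This keeps the package dependency-light and fully deterministic
under a fixed seed; it is sized for CPU-scale experiments, not for the
full-resolution training protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .patches import PatchIndex, PatchSet, assemble_prediction, enumerate_patches, extract
from .volumes import DoseMap, Volume, check_same_grid

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class UNetConfig:
    in_channels: int = 2  # PET, CT
    base_features: int = 14
    depth: int = 4  # resolution levels; depth-1 poolings
    batch_norm: bool = True  # contracting path only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.in_channels < 1 or self.base_features < 1 or self.depth < 1:
            raise ValueError("in_channels, base_features and depth must be >= 1")

    def check_patch_dims(self, patch_dims: Sequence[int]) -> None:
        f = 2 ** (self.depth - 1)
        if any(d % f != 0 for d in patch_dims):
            raise ValueError(
                f"patch dims {tuple(patch_dims)} not divisible by 2^(depth-1)={f}"
            )


@dataclass
class TrainConfig:
    loss: str = "l1"
    lr: float = 1e-3
    lr_schedule: str = "linear"  # linear decay to 0 over training, or "constant"
    betas: tuple[float, float] = (0.9, 0.999)
    batch_size: int = 16  # desk-scale; the full-scale protocol uses 150
    epochs: int = 7
    seed: int = 0
    folds: int = 5

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch size and epochs must be positive")
        if self.loss != "l1":
            raise ValueError("only the L1 cost function is supported")
        if self.lr_schedule not in ("linear", "constant"):
            raise ValueError("lr_schedule must be 'linear' or 'constant'")


# ---------------------------------------------------------------------------
# Layers (numpy forward/backward)
# ---------------------------------------------------------------------------


def _corr3d(x: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    """'Same' cross-correlation: x (N,C,D,H,W), w (F,C,kd,kh,kw)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
    win = sliding_window_view(x, w.shape[2:], axis=(2, 3, 4))
    return np.einsum("ncdhwijk,fcijk->nfdhw", win, w, optimize=True)


class Conv3d:
    """3-D convolution, stride 1, 'same' zero padding."""

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator):
        fan_in = cin * ksize**3
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, cin, ksize, ksize, ksize))
        self.b = np.zeros(cout)
        self.pad = ksize // 2
        self._x: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return _corr3d(x, self.w, self.pad) + self.b[None, :, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        xp = np.pad(x, ((0, 0), (0, 0)) + ((self.pad, self.pad),) * 3) if self.pad else x
        win = sliding_window_view(xp, self.w.shape[2:], axis=(2, 3, 4))
        self.dw = np.einsum("ncdhwijk,nfdhw->fcijk", win, dy, optimize=True)
        self.db = dy.sum(axis=(0, 2, 3, 4))
        w_rot = self.w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        return _corr3d(dy, w_rot, self.pad)

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def grads(self):
        return [self.dw, self.db]


class BatchNorm3d:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            self._xhat = (x - mean[None, :, None, None, None]) / np.sqrt(
                var[None, :, None, None, None] + self.eps
            )
            self._std = np.sqrt(var + self.eps)
            out = self.gamma[None, :, None, None, None] * self._xhat + self.beta[None, :, None, None, None]
            return out
        xhat = (x - self.running_mean[None, :, None, None, None]) / np.sqrt(
            self.running_var[None, :, None, None, None] + self.eps
        )
        return self.gamma[None, :, None, None, None] * xhat + self.beta[None, :, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3, 4)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3] * dy.shape[4]
        self.dgamma = (dy * self._xhat).sum(axis=axes)
        self.dbeta = dy.sum(axis=axes)
        g = self.gamma[None, :, None, None, None]
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=axes, keepdims=True)
        ) / self._std[None, :, None, None, None]
        return dx

    def params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def grads(self):
        return [self.dgamma, self.dbeta]


class ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    def params(self):
        return []

    def grads(self):
        return []


class MaxPool3d2:
    """2×2×2 max pooling; ties share the gradient."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, d, h, w = x.shape
        xr = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5, 7))
        if train:
            mask = xr == y[:, :, :, None, :, None, :, None]
            self._mask = mask / mask.sum(axis=(3, 5, 7), keepdims=True)
            self._shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = dy[:, :, :, None, :, None, :, None] * self._mask
        return d.reshape(self._shape)

    def params(self):
        return []

    def grads(self):
        return []


class ConvTranspose3d2:
    """Transposed convolution, kernel 2, stride 2 (the 'deconvolution' upstep)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        fan_in = cin * 8
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cin, cout, 2, 2, 2))
        self.b = np.zeros(cout)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        n, c, d, h, w = x.shape
        y = np.einsum("nfdhw,fgijk->ngdihjwk", x, self.w, optimize=True)
        y = y.reshape(n, self.w.shape[1], 2 * d, 2 * h, 2 * w)
        return y + self.b[None, :, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, g, D, H, W = dy.shape
        dyr = dy.reshape(n, g, D // 2, 2, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 6, 3, 5, 7)
        # dyr: (n, g, d, h, w, i, j, k)
        self.dw = np.einsum("nfdhw,ngdhwijk->fgijk", self._x, dyr, optimize=True)
        self.db = dy.sum(axis=(0, 2, 3, 4))
        return np.einsum("ngdhwijk,fgijk->nfdhw", dyr, self.w, optimize=True)

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def grads(self):
        return [self.dw, self.db]


# ---------------------------------------------------------------------------
# U-net
# ---------------------------------------------------------------------------


class _Block:
    """conv(+BN)+ReLU ×2."""

    def __init__(self, cin: int, cout: int, bn: bool, rng: np.random.Generator):
        self.layers = []
        for i, c_in in enumerate((cin, cout)):
            self.layers.append(Conv3d(c_in, cout, 3, rng))
            if bn:
                self.layers.append(BatchNorm3d(cout))
            self.layers.append(ReLU())

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class UNet3D:
    """Size-configurable 3-D U-net; see :class:`UNetConfig`."""

    def __init__(self, config: UNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f = config.base_features
        self.down_blocks: list[_Block] = []
        self.pools: list[MaxPool3d2] = []
        widths = [f * 2**i for i in range(config.depth)]
        cin = config.in_channels
        for i, w in enumerate(widths):
            self.down_blocks.append(_Block(cin, w, config.batch_norm, rng))
            cin = w
            if i < config.depth - 1:
                self.pools.append(MaxPool3d2())
        self.ups: list[ConvTranspose3d2] = []
        self.up_blocks: list[_Block] = []
        for i in range(config.depth - 2, -1, -1):
            self.ups.append(ConvTranspose3d2(widths[i + 1], widths[i], rng))
            # concat with the skip doubles the channel count
            self.up_blocks.append(_Block(2 * widths[i], widths[i], False, rng))
        self.final = Conv3d(widths[0], 1, 1, rng)
        # training-time scaling constants, set by `train`
        self.scales: dict[str, float] = {}

    # -- plumbing ----------------------------------------------------------
    def _all_layers(self):
        for b in self.down_blocks:
            yield from b.layers
        yield from self.pools
        for u, b in zip(self.ups, self.up_blocks):
            yield u
            yield from b.layers
        yield self.final

    def parameter_count(self) -> int:
        return sum(int(np.prod(p.shape)) for layer in self._all_layers()
                   for _, p in layer.params())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self.config.check_patch_dims(x.shape[2:])
        skips = []
        for i, block in enumerate(self.down_blocks):
            x = block.forward(x, train)
            if i < len(self.pools):
                skips.append(x)
                x = self.pools[i].forward(x, train)
        self._skip_channels = []
        for up, block, skip in zip(self.ups, self.up_blocks, reversed(skips)):
            x = up.forward(x, train)
            x = np.concatenate([skip, x], axis=1)
            self._skip_channels.append(skip.shape[1])
            x = block.forward(x, train)
        return self.final.forward(x, train)

    def backward(self, dy: np.ndarray) -> None:
        dy = self.final.backward(dy)
        dskips = []
        for up, block, cskip in zip(reversed(self.ups), reversed(self.up_blocks),
                                    reversed(self._skip_channels)):
            dy = block.backward(dy)
            dskips.append(dy[:, :cskip])
            dy = up.backward(dy[:, cskip:])
        # dskips[i] is the gradient w.r.t. skips[i] (shallow→deep ordering)
        for i in range(len(self.down_blocks) - 1, -1, -1):
            if i < len(self.pools):
                dy = self.pools[i].backward(dy)
                dy = dy + dskips[i]
            dy = self.down_blocks[i].backward(dy)

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for li, layer in enumerate(self._all_layers()):
            for name, p in layer.params():
                state[f"{li}.{name}"] = p
            if isinstance(layer, BatchNorm3d):
                state[f"{li}.running_mean"] = layer.running_mean
                state[f"{li}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for li, layer in enumerate(self._all_layers()):
            for name, p in layer.params():
                p[...] = state[f"{li}.{name}"]
            if isinstance(layer, BatchNorm3d):
                layer.running_mean[...] = state[f"{li}.running_mean"]
                layer.running_var[...] = state[f"{li}.running_var"]

    def save(self, path) -> None:
        arrays = {f"param:{k}": v for k, v in self.state_dict().items()}
        arrays["config"] = np.array(
            [self.config.in_channels, self.config.base_features, self.config.depth,
             int(self.config.batch_norm), self.config.seed]
        )
        for k, v in self.scales.items():
            arrays[f"scale:{k}"] = np.array(v)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "UNet3D":
        data = np.load(path)
        ic, bf, depth, bn, seed = (int(v) for v in data["config"])
        model = cls(UNetConfig(ic, bf, depth, bool(bn), seed))
        model.load_state_dict(
            {k[len("param:"):]: data[k] for k in data.files if k.startswith("param:")}
        )
        model.scales = {k[len("scale:"):]: float(data[k]) for k in data.files
                        if k.startswith("scale:")}
        return model


def build_unet(config: UNetConfig) -> UNet3D:
    """Construct a U-net; parameter count is a pure function of the config."""
    return UNet3D(config)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def l1_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.abs(diff).mean()), np.sign(diff) / diff.size


class Adam:
    def __init__(self, model: UNet3D, lr: float, betas: tuple[float, float]):
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = 1e-8
        self.t = 0
        self.m = [np.zeros_like(p) for layer in model._all_layers() for _, p in layer.params()]
        self.v = [np.zeros_like(p) for layer in model._all_layers() for _, p in layer.params()]

    def step(self) -> None:
        self.t += 1
        i = 0
        for layer in self.model._all_layers():
            ps = layer.params()
            gs = layer.grads()
            for (_, p), g in zip(ps, gs):
                self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
                self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
                mhat = self.m[i] / (1 - self.b1**self.t)
                vhat = self.v[i] / (1 - self.b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
                i += 1


def _compute_scales(patchset: PatchSet) -> dict[str, float]:
    pet_scale = float(np.quantile(patchset.pet, 0.999))
    dose_scale = float(np.quantile(patchset.dose, 0.999)) if patchset.dose is not None else 1.0
    return {
        "pet": pet_scale if pet_scale > 0 else 1.0,
        "ct": 1000.0,  # HU/1000
        "dose": dose_scale if dose_scale > 0 else 1.0,
    }


def _make_inputs(pet: np.ndarray, ct: np.ndarray, scales: dict[str, float]) -> np.ndarray:
    return np.stack([pet / scales["pet"], ct / scales["ct"]], axis=1)


def train(
    model: UNet3D,
    patchset: PatchSet,
    cfg: TrainConfig,
    scales: Optional[dict[str, float]] = None,
) -> list[float]:
    """Train in place on a PatchSet with dose targets; returns per-step losses.

    Inputs are scaled by persisted global constants (PET by its 99.9th
    percentile, CT by 1000, dose targets by their 99.9th percentile); the
    constants are stored on the model so inference can un-scale.  Shuffling
    is seeded; a fixed seed gives an identical loss history.
    """
    if len(patchset) == 0 or patchset.dose is None:
        raise ValueError("training needs a non-empty patch set with dose targets")
    model.scales = scales or _compute_scales(patchset)
    x_all = _make_inputs(patchset.pet, patchset.ct, model.scales)
    y_all = (patchset.dose / model.scales["dose"])[:, None]
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model, cfg.lr, cfg.betas)
    history: list[float] = []
    n = len(patchset)
    steps_per_epoch = int(np.ceil(n / cfg.batch_size))
    total_steps = cfg.epochs * steps_per_epoch
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            if cfg.lr_schedule == "linear":
                opt.lr = cfg.lr * (1.0 - step / total_steps)
            step += 1
            sel = order[start : start + cfg.batch_size]
            pred = model.forward(x_all[sel], train=True)
            loss, dpred = l1_loss(pred, y_all[sel])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {start // cfg.batch_size}"
                )
            model.backward(dpred)
            opt.step()
            history.append(loss)
    return history


def predict(
    model: UNet3D,
    pet: Volume,
    ct: Volume,
    patch_dims: tuple[int, int, int] = (16, 16, 8),
    stride: Optional[tuple[int, int, int]] = None,
) -> DoseMap:
    """Patch-wise inference reassembled into a whole dose-rate volume (Gy/s).

    Inference patches are laid on a regular stride grid (default half the
    patch size) with extra flush patches at the far boundaries so every voxel
    is covered; overlapping predictions are averaged uniformly.
    """
    if not model.scales:
        raise ValueError("model has no scaling constants; train or load first")
    check_same_grid(pet, ct)
    model.config.check_patch_dims(patch_dims)
    stride = stride or tuple(max(1, d // 2) for d in patch_dims)
    dims = pet.shape
    corners = set()
    for idx in enumerate_patches(dims, patch_dims, stride):
        corners.add(idx.corner)
    # flush patches guarantee full coverage
    ends = [vd - pd for vd, pd in zip(dims, patch_dims)]
    axes = [sorted({*range(0, ends[a] + 1, stride[a]), ends[a]}) for a in range(3)]
    for cx in axes[0]:
        for cy in axes[1]:
            for cz in axes[2]:
                corners.add((cx, cy, cz))
    indices = [PatchIndex(c, tuple(patch_dims)) for c in sorted(corners)]
    ps = extract(pet, ct, None, indices)
    x = _make_inputs(ps.pet, ps.ct, model.scales)
    preds = []
    for start in range(0, len(indices), 32):
        preds.append(model.forward(x[start : start + 32], train=False)[:, 0])
    pred = np.concatenate(preds) * model.scales["dose"]
    vol, cover = assemble_prediction(indices, pred, dims)
    assert (cover > 0).all()
    return DoseMap(np.clip(vol, 0.0, None), pet.voxel_size, "Gy/s",
                   {"stage": "cnn", "patch_dims": tuple(patch_dims), "stride": tuple(stride)})


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def make_folds(n_datasets: int, k: int, seed: int = 0) -> list[np.ndarray]:
    """Split dataset indices into k equal seeded test groups (each used once)."""
    if k > n_datasets:
        raise ValueError(f"k={k} folds but only {n_datasets} datasets")
    if n_datasets % k != 0:
        raise ValueError("dataset count must divide into k equal test groups")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_datasets)
    return [np.sort(g) for g in np.split(perm, k)]


def crossvalidate(
    datasets: Sequence[dict],
    unet_config: UNetConfig,
    train_cfg: TrainConfig,
    k: int = 5,
    patch_dims: tuple[int, int, int] = (16, 16, 8),
    metric=None,
):
    """k-fold cross-validation over phantom datasets.

    Each dataset is a dict with keys ``pet``, ``ct`` (Volumes), ``reference``
    (DoseMap ground truth) and ``patches`` (a PatchSet for training).  Returns
    a pandas DataFrame with one row per (fold, test dataset) holding the mean
    voxel percentage error of the trained network against the reference.
    """
    import pandas as pd

    from .metrics import voxel_percent_diff

    folds = make_folds(len(datasets), k, train_cfg.seed)
    rows = []
    for fold_i, test_idx in enumerate(folds):
        train_idx = [i for i in range(len(datasets)) if i not in set(test_idx.tolist())]
        trainset = PatchSet.concatenate([datasets[i]["patches"] for i in train_idx])
        model = build_unet(unet_config)
        train(model, trainset, train_cfg)
        for i in test_idx:
            d = datasets[i]
            pred = predict(model, d["pet"], d["ct"], patch_dims)
            ref = d["reference"]
            mask = ref.data > 0
            mean, std = voxel_percent_diff(pred.data, ref.data, mask)
            rows.append({"fold": fold_i, "dataset": int(i),
                         "mean_voxel_pct_err": mean, "std_voxel_pct_err": std})
    return pd.DataFrame(rows)
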
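"""Hybrid 2D/3D dense encoder-decoder for slab-to-slice segmentation.

The network maps a slab of ``slab_in`` axial slices to a 3-class (background /
left / right) probability map for the central slice.  In-plane it is a
Tiramisu-style dense encoder-decoder: dense convolutional blocks, 2x2 max
pooling on the way down, transposed-convolution upsampling with skip
connections on the way up, batch normalization and dropout inside every dense
layer, and a softmax head.  Between each encoder dense block and its pooling
sits a separable 3D convolution — a padded 3x3x1 in-plane convolution followed
by an unpadded 1x1x3 z-convolution — so each encoder level consumes two
slices; with the default four resolution levels the slab shrinks 7 -> 5 -> 3
-> 1 and the decoder runs purely 2D.  Output size equals input size in-plane.

Skip connections pass the central slice of each encoder level's features to
the matching decoder level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import nn


@dataclass(frozen=True)
class ArchitectureConfig:
    """Structural hyperparameters of the segmentation network."""

    n_levels: int = 4
    layers_per_dense_block: int = 2
    growth_rate: int = 8
    dropout_rate: float = 0.1
    in_plane_size: int = 256
    slab_in: int = 7
    slab_out: int = 1
    n_classes: int = 3
    sep_channels: int | None = None  # width of the separable 3D convs (None: keep block width)

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError(f"need at least 2 resolution levels, got {self.n_levels}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0,1), got {self.dropout_rate}")
        n_zconv = self.n_levels - 1
        if self.slab_in - self.slab_out != 2 * n_zconv:
            raise ValueError(
                f"slab arithmetic broken: slab_in {self.slab_in} - slab_out {self.slab_out} "
                f"must equal 2 x {n_zconv} unpadded z-convolutions"
            )
        if self.slab_out != 1:
            raise ValueError("only single-slice output is supported")
        deepest = self.in_plane_size // 2 ** (self.n_levels - 1)
        if deepest < 2 or self.in_plane_size % 2 ** (self.n_levels - 1) != 0:
            raise ValueError(
                f"in-plane size {self.in_plane_size} with {self.n_levels - 1} poolings "
                f"implies a deepest level of {deepest} voxels; need an even size >= 2"
            )


class _DenseLayer(nn.Module):
    """BN -> ReLU -> 3x3 conv (growth channels) -> dropout."""

    def __init__(self, cin: int, growth: int, dropout: float, rng: np.random.Generator):
        self.bn = nn.BatchNorm(cin)
        self.relu = nn.ReLU()
        self.conv = nn.Conv2d(cin, growth, 3, rng)
        self.drop = nn.Dropout(dropout)

    def forward(self, x, bn_train, drop_active, rng):
        h = self.bn.forward(x, train=bn_train)
        h = self.relu.forward(h)
        h = self.conv.forward(h)
        return self.drop.forward(h, active=drop_active, rng=rng)

    def backward(self, gy):
        g = self.drop.backward(gy)
        g = self.conv.backward(g)
        g = self.relu.backward(g)
        return self.bn.backward(g)


class _DenseBlock(nn.Module):
    """Dense block: each layer sees the concat of the input and all new features."""

    def __init__(self, cin: int, n_layers: int, growth: int, dropout: float, rng: np.random.Generator):
        self.cin = cin
        self.growth = growth
        self.layers = [
            _DenseLayer(cin + i * growth, growth, dropout, rng) for i in range(n_layers)
        ]
        self.cout = cin + n_layers * growth

    def forward(self, x, bn_train, drop_active, rng):
        feats = [x]
        for layer in self.layers:
            inp = feats[0] if len(feats) == 1 else np.concatenate(feats, axis=1)
            feats.append(layer.forward(inp, bn_train, drop_active, rng))
        self._widths = [f.shape[1] for f in feats]
        return np.concatenate(feats, axis=1)

    def backward(self, gy):
        splits = np.cumsum(self._widths)[:-1]
        gfeats = list(np.split(gy, splits, axis=1))
        for i in range(len(self.layers) - 1, -1, -1):
            ginp = self.layers[i].backward(gfeats[i + 1])
            w = np.cumsum(self._widths[: i + 1])[:-1]
            pieces = np.split(ginp, w, axis=1) if i > 0 else [ginp]
            for j, piece in enumerate(pieces):
                gfeats[j] = gfeats[j] + piece
        return gfeats[0]


def _merge(x5):
    """(N, C, Z, H, W) -> (N*Z, C, H, W)."""
    n, c, z, h, w = x5.shape
    return np.ascontiguousarray(x5.transpose(0, 2, 1, 3, 4)).reshape(n * z, c, h, w)


def _split(x4, n, z):
    """(N*Z, C, H, W) -> (N, C, Z, H, W)."""
    nz, c, h, w = x4.shape
    return np.ascontiguousarray(x4.reshape(n, z, c, h, w).transpose(0, 2, 1, 3, 4))


class Network(nn.Module):
    """The segmentation CNN.  Build with :func:`build_network`."""

    def __init__(self, config: ArchitectureConfig, init_seed: int = 0):
        self.config = config
        rng = np.random.default_rng(init_seed)
        g, nl = config.growth_rate, config.layers_per_dense_block
        ch = 2 * config.growth_rate
        self.in_conv = nn.Conv2d(1, ch, 3, rng)
        self.enc_blocks, self.sep2d, self.sepz, self.sep_bn, self.sep_relu, self.pools = [], [], [], [], [], []
        self.skip_ch = []
        for _ in range(config.n_levels - 1):
            blk = _DenseBlock(ch, nl, g, config.dropout_rate, rng)
            ch = blk.cout
            self.enc_blocks.append(blk)
            sep_ch = config.sep_channels or ch
            self.sep2d.append(nn.Conv2d(ch, sep_ch, 3, rng))
            self.sepz.append(nn.ConvZ3(sep_ch, sep_ch, rng))
            ch = sep_ch
            self.sep_bn.append(nn.BatchNorm(ch))
            self.sep_relu.append(nn.ReLU())
            self.pools.append(nn.MaxPool2())
            self.skip_ch.append(ch)
        self.bottleneck = _DenseBlock(ch, nl, g, config.dropout_rate, rng)
        ch = self.bottleneck.cout
        self.ups, self.dec_blocks = [], []
        for lev in range(config.n_levels - 2, -1, -1):
            up_out = max(2 * g, ch // 2)
            self.ups.append(nn.ConvTranspose2(ch, up_out, rng))
            ch = up_out + self.skip_ch[lev]
            blk = _DenseBlock(ch, nl, g, config.dropout_rate, rng)
            ch = blk.cout
            self.dec_blocks.append(blk)
        self.head = nn.Conv2d(ch, config.n_classes, 1, rng)

    # -- forward -----------------------------------------------------------

    def forward(self, x: np.ndarray, mode: str = "eval", rng: np.random.Generator | None = None) -> np.ndarray:
        """Run the network on a slab batch (N, 1, slab_in, H, W).

        mode: 'train' (batch-stat BN, dropout on), 'eval' (running-stat BN,
        dropout off) or 'mc' (running-stat BN, dropout on — Monte-Carlo
        dropout inference).  Returns per-voxel class probabilities
        (N, n_classes, H, W) for the central slice.
        """
        if mode not in ("train", "eval", "mc"):
            raise ValueError(f"mode must be 'train', 'eval' or 'mc', got {mode!r}")
        if x.ndim != 5 or x.shape[2] != self.config.slab_in:
            raise ValueError(f"expected (N, 1, {self.config.slab_in}, H, W) input, got {x.shape}")
        if mode in ("train", "mc") and self.config.dropout_rate > 0 and rng is None:
            raise ValueError("stochastic forward pass needs an rng")
        bn_train = mode == "train"
        drop = mode in ("train", "mc")
        n = x.shape[0]
        z = self.config.slab_in
        cache = {"n": n, "zs": [], "centers": []}

        h = _merge(x)
        h = self.in_conv.forward(h)
        for lev in range(self.config.n_levels - 1):
            h = self.enc_blocks[lev].forward(h, bn_train, drop, rng)
            h = self.sep2d[lev].forward(h)
            h5 = _split(h, n, z)
            h5 = self.sepz[lev].forward(h5)
            z_new = z - 2
            h = _merge(h5)
            h = self.sep_bn[lev].forward(h, train=bn_train)
            h = self.sep_relu[lev].forward(h)
            center = (z_new - 1) // 2
            cache["zs"].append((z, z_new))
            cache["centers"].append(center)
            skip = h.reshape(n, z_new, *h.shape[1:])[:, center]
            cache.setdefault("skips", []).append(skip)
            h = self.pools[lev].forward(h)
            z = z_new
        # z == 1 here by the slab-arithmetic invariant; fold it away
        h = self.bottleneck.forward(h, bn_train, drop, rng)
        for i, lev in enumerate(range(self.config.n_levels - 2, -1, -1)):
            h = self.ups[i].forward(h)
            skip = cache["skips"][lev]
            cache.setdefault("cat_widths", []).append((h.shape[1], skip.shape[1]))
            h = np.concatenate([h, skip], axis=1)
            h = self.dec_blocks[i].forward(h, bn_train, drop, rng)
        logits = self.head.forward(h)
        probs = nn.softmax_channels(logits)
        self._cache = cache
        self._probs = probs
        return probs

    # -- backward ----------------------------------------------------------

    def backward(self, gprobs: np.ndarray) -> None:
        """Accumulate parameter gradients given dLoss/dprobs of the last forward."""
        cache = self._cache
        n = cache["n"]
        g = nn.softmax_backward(self._probs, gprobs)
        g = self.head.backward(g)
        gskips = [None] * (self.config.n_levels - 1)
        for i in range(len(self.dec_blocks) - 1, -1, -1):
            lev = self.config.n_levels - 2 - i
            g = self.dec_blocks[i].backward(g)
            w_up, _ = cache["cat_widths"][i]
            g_up, g_skip = g[:, :w_up], g[:, w_up:]
            gskips[lev] = g_skip
            g = self.ups[i].backward(np.ascontiguousarray(g_up))
        g = self.bottleneck.backward(g)
        for lev in range(self.config.n_levels - 2, -1, -1):
            z_old, z_new = cache["zs"][lev]
            center = cache["centers"][lev]
            g = self.pools[lev].backward(g)
            gp = g.reshape(n, z_new, *g.shape[1:])
            gp = gp.copy()
            gp[:, center] += gskips[lev]
            g = gp.reshape(n * z_new, *g.shape[1:])
            g = self.sep_relu[lev].backward(g)
            g = self.sep_bn[lev].backward(g)
            g5 = _split(g, n, z_new)
            g5 = self.sepz[lev].backward(g5)
            g = _merge(g5)
            g = self.sep2d[lev].backward(g)
            g = self.enc_blocks[lev].backward(g)
        self.in_conv.backward(g)
        del self._cache, self._probs

    # -- persistence -------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        for i, p in enumerate(self.params()):
            state[f"param_{i:04d}"] = p.value
        bn_idx = 0
        for m in _iter_modules(self):
            if isinstance(m, nn.BatchNorm):
                state[f"bn_{bn_idx:04d}_mean"] = m.running_mean
                state[f"bn_{bn_idx:04d}_var"] = m.running_var
                bn_idx += 1
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value = np.ascontiguousarray(state[f"param_{i:04d}"], dtype=p.value.dtype)
            p.grad = np.zeros_like(p.value)
        bn_idx = 0
        for m in _iter_modules(self):
            if isinstance(m, nn.BatchNorm):
                m.running_mean = np.asarray(state[f"bn_{bn_idx:04d}_mean"], dtype=np.float32)
                m.running_var = np.asarray(state[f"bn_{bn_idx:04d}_var"], dtype=np.float32)
                bn_idx += 1

    def save(self, path) -> None:
        import json

        from dataclasses import asdict

        state = self.state_arrays()
        state["_config_json"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez(path, **state)

    @classmethod
    def load(cls, path) -> "Network":
        import json

        with np.load(path) as data:
            cfg = json.loads(bytes(data["_config_json"].tobytes()).decode())
            net = cls(ArchitectureConfig(**cfg))
            net.load_state_arrays({k: data[k] for k in data.files if k != "_config_json"})
        return net


def _iter_modules(root: nn.Module):
    yield root
    for v in root.__dict__.values():
        if isinstance(v, nn.Module):
            yield from _iter_modules(v)
        elif isinstance(v, (list, tuple)):
            for item in v:
                if isinstance(item, nn.Module):
                    yield from _iter_modules(item)


def build_network(config: ArchitectureConfig, init_seed: int = 0) -> Network:
    """Build a seeded network; raises if the config's slab arithmetic is broken."""
    net = Network(config, init_seed=init_seed)
    logging.getLogger("provseg").info(
        "built network: %d levels, slab %d->%d, %d parameters",
        config.n_levels, config.slab_in, config.slab_out, net.n_parameters(),
    )
    return net


# ---------------------------------------------------------------------------
# Dice loss
# ---------------------------------------------------------------------------

DICE_EPS = 1e-5


def dice_loss(probs: np.ndarray, target_onehot: np.ndarray, eps: float = DICE_EPS) -> float:
    """Soft Dice loss over the foreground channels, background excluded.

    ``probs`` and ``target_onehot`` are (N, n_classes, H, W); the loss is
    ``1 - (2 sum_fg(p t) + eps) / (sum_fg(p) + sum_fg(t) + eps)`` with the
    sums pooling both foreground channels and the whole batch.  Pooling the
    channels (rather than averaging per-channel ratios) keeps the loss and
    its gradient well-behaved when a foreground class is absent from a batch.
    """
    if probs.shape != target_onehot.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs target {target_onehot.shape}")
    p, t = probs[:, 1:], target_onehot[:, 1:]
    num = 2.0 * float((p * t).sum()) + eps
    den = float(p.sum()) + float(t.sum()) + eps
    return 1.0 - num / den


def dice_loss_grad(probs: np.ndarray, target_onehot: np.ndarray, eps: float = DICE_EPS) -> tuple[float, np.ndarray]:
    """Loss value and its gradient with respect to ``probs``."""
    if probs.shape != target_onehot.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs target {target_onehot.shape}")
    p, t = probs[:, 1:], target_onehot[:, 1:]
    num = 2.0 * float((p * t).sum()) + eps
    den = float(p.sum()) + float(t.sum()) + eps
    grad = np.zeros_like(probs)
    # d(num/den)/dp = (2 t den - num) / den^2 ; loss = 1 - num/den
    grad[:, 1:] = -(2.0 * t * den - num) / (den * den)
    return 1.0 - num / den, grad
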
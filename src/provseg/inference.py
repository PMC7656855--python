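"""Full-volume prediction, postprocessing and Monte-Carlo-dropout uncertainty.

``predict_volume`` slides the network's slab window over z with stride 1,
edge-padding the volume by replicated slices so every axial slice receives a
prediction.  ``postprocess`` applies the deployment pipeline: threshold 0.5,
keep the largest 26-connected component per side, resample to the evaluation
grid.  ``mc_entropy_map`` estimates predictive uncertainty as the voxelwise
entropy of the mean softmax over stochastic dropout forward passes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import FOREGROUND_LABELS, Grid, LabelMask, Volume
from . import preprocess

logger = logging.getLogger("provseg")

LN3 = float(np.log(3.0))


@dataclass
class EntropyMap:
    """Voxelwise predictive entropy U(x) in nats, sharing its Volume's geometry."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.min() < -1e-6 or self.values.max() > LN3 + 1e-5:
            raise ValueError(
                f"entropy must lie in [0, ln 3]; got range "
                f"[{self.values.min():.4g}, {self.values.max():.4g}]"
            )

    @property
    def grid(self) -> Grid:
        return Grid(tuple(self.values.shape), self.spacing, self.origin)


def _slab_batches(values: np.ndarray, slab_in: int):
    half = (slab_in - 1) // 2
    padded = np.pad(values, ((half, half), (0, 0), (0, 0)), mode="edge")
    nz = values.shape[0]
    for z in range(nz):
        yield z, padded[z : z + slab_in][None, None]  # (1,1,slab,H,W)


def predict_volume(net, v: Volume, mode: str = "eval", rng: np.random.Generator | None = None,
                   batch_slices: int = 8) -> np.ndarray:
    """Per-voxel class probabilities (n_classes, nz, ny, nx) for a whole volume.

    The volume is edge-padded by (slab_in-1)/2 replicated slices at each end,
    so the output covers exactly the input slice range.
    """
    slab_in = net.config.slab_in
    nz, ny, nx = v.values.shape
    if nz < 1:
        raise ValueError("volume must contain at least one slice")
    half = (slab_in - 1) // 2
    padded = np.pad(v.values.astype(np.float32), ((half, half), (0, 0), (0, 0)), mode="edge")
    out = np.empty((net.config.n_classes, nz, ny, nx), dtype=np.float32)
    for start in range(0, nz, batch_slices):
        stop = min(start + batch_slices, nz)
        slabs = np.stack([padded[z : z + slab_in] for z in range(start, stop)])[:, None]
        probs = net.forward(slabs, mode=mode, rng=rng)  # (B, C, H, W)
        out[:, start:stop] = probs.transpose(1, 0, 2, 3)
    return out


def postprocess(
    prob_volume: np.ndarray,
    geometry: Grid,
    threshold: float = 0.5,
    eval_spacing_mm: float | None = 1.0,
    case_log: list | None = None,
) -> LabelMask:
    """Deployment postprocessing of a probability volume.

    Per foreground channel: threshold at ``threshold``, keep the single
    largest 26-connected component, discard the rest.  The result is
    resampled to ``eval_spacing_mm`` isotropic (pass None to stay on the
    prediction grid).  Per-side component counts go to the case log.
    """
    labels = np.zeros(prob_volume.shape[1:], dtype=np.uint8)
    struct = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    for lab in FOREGROUND_LABELS:
        binary = prob_volume[lab] >= threshold
        comp, n_comp = ndimage.label(binary, structure=struct)
        msg = f"label {lab}: {n_comp} connected component(s) above threshold"
        logger.debug(msg)
        if case_log is not None:
            case_log.append(msg)
        if n_comp == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n_comp + 1))
        keep = int(np.argmax(sizes)) + 1
        labels[comp == keep] = lab
    mask = LabelMask(labels, geometry.spacing, geometry.origin)
    if eval_spacing_mm is not None:
        mask = preprocess.resample(mask, eval_spacing_mm)
    return mask


def entropy_of(probs: np.ndarray) -> np.ndarray:
    """Shannon entropy (nats) over the class axis (axis 0) of a probability stack."""
    p = np.clip(probs, 1e-12, 1.0)
    u = -(p * np.log(p)).sum(axis=0)
    return np.clip(u, 0.0, LN3).astype(np.float32)


def mc_entropy_map(
    net,
    v: Volume,
    n_samples: int = 25,
    seed: int = 0,
) -> tuple[EntropyMap, np.ndarray]:
    """Monte-Carlo-dropout uncertainty: entropy of the mean predictive softmax.

    Runs ``n_samples`` stochastic forward passes with dropout active (batch
    norm in inference mode), averages the softmax per voxel and returns
    U(x) = -sum_k p̄_k(x) ln p̄_k(x) together with the mean probability volume.
    """
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    if net.config.dropout_rate == 0:
        probs = predict_volume(net, v, mode="eval")
        return EntropyMap(entropy_of(probs), v.spacing, v.origin), probs
    mean = None
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_samples):
        rng = np.random.default_rng(child)
        probs = predict_volume(net, v, mode="mc", rng=rng)
        mean = probs if mean is None else mean + probs
    mean /= n_samples
    return EntropyMap(entropy_of(mean), v.spacing, v.origin), mean
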
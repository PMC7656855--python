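"""Resampling, intensity normalization, contour propagation and augmentation.

All spatial operations act in physical mm coordinates.  Images are
interpolated trilinearly; label masks are interpolated by warping per-label
indicator functions and taking an argmax, which avoids the staircase noise of
nearest-neighbour label resampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import (
    BACKGROUND,
    FOREGROUND_LABELS,
    AffineTransform,
    Grid,
    LabelMask,
    Volume,
    require_same_geometry,
    rotation_about_axis,
    scaling,
)

logger = logging.getLogger("provseg")

# ---------------------------------------------------------------------------
# generic warping
# ---------------------------------------------------------------------------


def _sample_at(values: np.ndarray, src: Grid, pts_world: np.ndarray, order: int, cval: float, mode: str) -> np.ndarray:
    idx = src.world_to_voxel(pts_world)
    coords = [idx[..., a] for a in range(3)]
    return ndimage.map_coordinates(
        np.asarray(values, dtype=np.float32), coords, order=order, mode=mode, cval=cval
    )


def warp_volume(
    v: Volume,
    transform: AffineTransform,
    target: Grid,
    order: int = 1,
    mode: str = "nearest",
) -> Volume:
    """Resample ``v`` onto ``target`` through ``transform`` (source->target, mm)."""
    inv = transform.inverse()
    pts_src = inv.apply(target.world_coords())
    out = _sample_at(v.values, v.grid, pts_src, order=order, cval=0.0, mode=mode)
    return Volume(out, target.spacing, target.origin)


def warp_mask_indicators(
    m: LabelMask,
    transform: AffineTransform,
    target: Grid,
) -> np.ndarray:
    """Warped per-label indicator stack (n_labels, nz, ny, nx), linear interp.

    Channel 0 is background (cval 1 outside the source field of view).
    """
    inv = transform.inverse()
    pts_src = inv.apply(target.world_coords())
    chans = []
    for lab in (BACKGROUND,) + tuple(FOREGROUND_LABELS):
        ind = (m.labels == lab).astype(np.float32)
        cval = 1.0 if lab == BACKGROUND else 0.0
        chans.append(_sample_at(ind, m.grid, pts_src, order=1, cval=cval, mode="constant"))
    return np.stack(chans, axis=0)


def warp_mask(m: LabelMask, transform: AffineTransform, target: Grid) -> LabelMask:
    probs = warp_mask_indicators(m, transform, target)
    return LabelMask(np.argmax(probs, axis=0).astype(np.uint8), target.spacing, target.origin)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def _target_grid_for_spacing(grid: Grid, target_spacing) -> Grid:
    target_spacing = tuple(float(s) for s in np.broadcast_to(np.asarray(target_spacing, dtype=float), (3,)))
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    shape = tuple(
        max(1, int(round(grid.shape[a] * grid.spacing[a] / target_spacing[a]))) for a in range(3)
    )
    return Grid(shape, target_spacing, grid.origin)


def resample(obj: Volume | LabelMask, target_spacing_mm, order: int = 1):
    """Resample a volume or mask to a new spacing, preserving physical extent.

    Images use trilinear interpolation (``order`` configurable); masks use
    per-label indicator interpolation followed by argmax.
    """
    target = _target_grid_for_spacing(obj.grid, target_spacing_mm)
    if np.allclose(target.spacing, obj.spacing):
        return obj.copy()
    ident = AffineTransform.identity()
    if isinstance(obj, LabelMask):
        return warp_mask(obj, ident, target)
    return warp_volume(obj, ident, target, order=order)


# ---------------------------------------------------------------------------
# intensity normalization
# ---------------------------------------------------------------------------


def normalize_ct(v: Volume, center_hu: float = 40.0, width_hu: float = 80.0) -> Volume:
    """Window a CT volume: [center-width/2, center+width/2] -> [0,1], clamped."""
    if width_hu <= 0:
        raise ValueError(f"window width must be positive, got {width_hu}")
    lo = center_hu - width_hu / 2.0
    out = np.clip((v.values - lo) / width_hu, 0.0, 1.0)
    return Volume(out, v.spacing, v.origin)


def normalize_mr(v: Volume, p_low: float = 2.0, p_high: float = 98.0) -> Volume:
    """Percentile-normalize an MR volume: p_low -> 0, p_high -> 1, clamped."""
    lo, hi = np.percentile(v.values, [p_low, p_high])
    if hi <= lo:
        raise ValueError(
            f"degenerate contrast: percentiles {p_low} and {p_high} coincide at {lo}"
        )
    out = np.clip((v.values - lo) / (hi - lo), 0.0, 1.0)
    return Volume(out, v.spacing, v.origin)


# ---------------------------------------------------------------------------
# contour propagation
# ---------------------------------------------------------------------------


def tilt_transform(tilt_deg: float, center_mm) -> AffineTransform:
    """The contouring tilt: rotation about the left-right (x) axis.

    Maps the canonical (untilted) frame to the tilted contouring frame; its
    inverse reverts the tilt.
    """
    return rotation_about_axis("x", tilt_deg, center_mm=center_mm)


def propagate_contour(
    mask: LabelMask,
    tilt_deg: float,
    affine: AffineTransform,
    smooth_sd_mm: float = 1.0,
    threshold: float = 0.5,
    target: Grid | None = None,
    intermediate_spacing_mm: float = 1.0,
    case_log: list | None = None,
) -> LabelMask:
    """Propagate a contour mask from the tilted source frame to a target frame.

    Pipeline: rasterized mask -> isotropic resample -> revert tilt -> apply the
    registration affine -> Gaussian-smooth each label indicator -> threshold ->
    argmax.  ``affine`` maps the *untilted* source frame to the target frame
    (the role of a registration matrix computed between untilted volumes).
    """
    iso = resample(mask, intermediate_spacing_mm)
    tilt = tilt_transform(tilt_deg, center_mm=mask.grid.center_mm)
    combined = affine.compose(tilt.inverse())
    if target is None:
        target = _target_grid_for_spacing(mask.grid, intermediate_spacing_mm)
    probs = warp_mask_indicators(iso, combined, target)
    if smooth_sd_mm > 0:
        sigma_vox = [smooth_sd_mm / s for s in target.spacing]
        for c in range(probs.shape[0]):
            probs[c] = ndimage.gaussian_filter(probs[c], sigma=sigma_vox)
    fg = probs[1:]
    fg_present = fg.max(axis=0) >= threshold
    labels = np.where(fg_present, np.argmax(fg, axis=0) + 1, BACKGROUND).astype(np.uint8)
    out = LabelMask(labels, target.spacing, target.origin)
    for lab in FOREGROUND_LABELS:
        if (mask.labels == lab).any() and not (out.labels == lab).any():
            msg = f"contour propagation emptied foreground label {lab}"
            logger.warning(msg)
            if case_log is not None:
                case_log.append(msg)
    return out


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


@dataclass
class AugmentationSpec:
    """On-the-fly augmentation: left-right flip plus random rigid transforms.

    ``rotation_sd_deg`` orders the in-plane standard deviations as (axial,
    sagittal, coronal), i.e. rotations about the z, x and y axes.
    """

    flip_prob: float = 0.5
    scale_sd_fraction: float = 0.025
    rotation_sd_deg: tuple[float, float, float] = (5.0, 5.0, 2.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError(f"flip_prob must be in [0,1], got {self.flip_prob}")
        if self.scale_sd_fraction < 0 or any(s < 0 for s in self.rotation_sd_deg):
            raise ValueError("augmentation standard deviations must be >= 0")

    @classmethod
    def flip_only(cls, seed: int = 0) -> "AugmentationSpec":
        return cls(flip_prob=0.5, scale_sd_fraction=0.0, rotation_sd_deg=(0.0, 0.0, 0.0), seed=seed)

    @classmethod
    def disabled(cls, seed: int = 0) -> "AugmentationSpec":
        return cls(flip_prob=0.0, scale_sd_fraction=0.0, rotation_sd_deg=(0.0, 0.0, 0.0), seed=seed)


def flip_lr(image: Volume, mask: LabelMask) -> tuple[Volume, LabelMask]:
    """Mirror both grids across the midsagittal plane and swap left/right labels."""
    vals = image.values[:, :, ::-1].copy()
    labs = mask.labels[:, :, ::-1]
    swapped = labs.copy()
    swapped[labs == 1] = 2
    swapped[labs == 2] = 1
    return Volume(vals, image.spacing, image.origin), LabelMask(swapped, mask.spacing, mask.origin)


def augment_sample(
    image: Volume,
    mask: LabelMask,
    spec: AugmentationSpec,
    rng: np.random.Generator | None = None,
) -> tuple[Volume, LabelMask]:
    """Draw one augmentation and apply it identically to image and mask."""
    require_same_geometry(image, mask)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    img, msk = image, mask
    if spec.flip_prob > 0 and rng.random() < spec.flip_prob:
        img, msk = flip_lr(img, msk)
    ax_sd, sag_sd, cor_sd = spec.rotation_sd_deg
    if spec.scale_sd_fraction > 0 or any(s > 0 for s in spec.rotation_sd_deg):
        center = img.grid.center_mm
        scale = float(rng.normal(1.0, spec.scale_sd_fraction)) if spec.scale_sd_fraction > 0 else 1.0
        scale = max(scale, 0.5)
        ang_ax = float(rng.normal(0.0, ax_sd)) if ax_sd > 0 else 0.0
        ang_sag = float(rng.normal(0.0, sag_sd)) if sag_sd > 0 else 0.0
        ang_cor = float(rng.normal(0.0, cor_sd)) if cor_sd > 0 else 0.0
        t = rotation_about_axis("z", ang_ax, center)
        t = t.compose(rotation_about_axis("x", ang_sag, center))
        t = t.compose(rotation_about_axis("y", ang_cor, center))
        t = t.compose(scaling(scale, center))
        img = warp_volume(img, t, img.grid, order=1, mode="nearest")
        msk = warp_mask(msk, t, msk.grid)
    return img, msk
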
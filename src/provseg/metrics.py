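"""Segmentation evaluation: overlap, surface distances, contour tolerance
metrics, trial passing rate, uncertainty density and paired statistics.

All metrics operate on 3D masks, separately per side (left/right).  Surface
voxels are mask voxels with at least one face-adjacent background neighbour;
distances are spacing-aware Euclidean via distance transforms.  The contour
Dice score works on 2D axial contours with in-plane distances, pooled over
slices, in its symmetric form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .types import FOREGROUND_LABELS, LabelMask, require_same_geometry

logger = logging.getLogger("provseg")

CONTOUR_TOLERANCES_MM = (1.0, 3.0, 5.0, 7.0, 10.0)
UNCERTAINTY_TOLERANCES_MM = (1.5, 3.0, 4.5, 6.0, 7.5)  # k x 1.5 mm, k=1..5
RTOG_HAUSDORFF_MM = 7.0

_FACE3 = ndimage.generate_binary_structure(3, 1)
_FACE2 = ndimage.generate_binary_structure(2, 1)
_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class MetricRecord:
    """Per case and side evaluation results."""

    case_id: str
    side: str
    dice: float
    mean_surface_distance_mm: float | None
    hausdorff_mm: float | None
    contour_dice: dict[float, float] = field(default_factory=dict)
    uncertainty_density: dict[float, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# overlap
# ---------------------------------------------------------------------------


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """2|A n B| / (|A| + |B|); both empty -> 1, exactly one empty -> 0."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"geometry mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / (na + nb)


def dice_masks(a: LabelMask, b: LabelMask, label: int) -> float:
    require_same_geometry(a, b)
    return dice(a.side(label), b.side(label))


# ---------------------------------------------------------------------------
# surface distances
# ---------------------------------------------------------------------------


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one face-adjacent background neighbour."""
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=_FACE3, border_value=0)
    return mask & ~eroded


def surface_distances(a: np.ndarray, b: np.ndarray, spacing_mm) -> tuple[float, float]:
    """(mean surface distance, Hausdorff distance) in mm between two masks.

    Symmetric: msd is the mean of both directed mean surface distances,
    Hausdorff the max of the two directed maxima.  Raises on an empty mask —
    the caller records a flag instead of a distance in that case.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"geometry mismatch: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        raise ValueError("surface distances are undefined for an empty mask")
    sa, sb = surface_voxels(a), surface_voxels(b)
    dist_to_b = ndimage.distance_transform_edt(~sb, sampling=spacing_mm)
    dist_to_a = ndimage.distance_transform_edt(~sa, sampling=spacing_mm)
    d_ab = dist_to_b[sa]
    d_ba = dist_to_a[sb]
    msd = (float(d_ab.mean()) + float(d_ba.mean())) / 2.0
    hd = max(float(d_ab.max()), float(d_ba.max()))
    return msd, hd


# ---------------------------------------------------------------------------
# contour Dice
# ---------------------------------------------------------------------------


def slice_contour(mask_slice: np.ndarray) -> np.ndarray:
    """In-plane boundary voxels of a 2D mask slice (face adjacency)."""
    m = np.asarray(mask_slice, dtype=bool)
    eroded = ndimage.binary_erosion(m, structure=_FACE2, border_value=0)
    return m & ~eroded


def contour_dice(a: np.ndarray, b: np.ndarray, tolerance_mm: float, spacing_mm) -> float:
    """Fraction of pooled axial contour points lying within tolerance of the
    other mask's contour (symmetric form).

    Contours are extracted per axial slice; distances are in-plane (2D, mm).
    Slices where only one mask is present contribute their contour to the
    denominator only.  Both contours empty everywhere -> 1.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"geometry mismatch: {a.shape} vs {b.shape}")
    _, sy, sx = spacing_mm
    matched = 0
    total = 0
    for z in range(a.shape[0]):
        ca, cb = slice_contour(a[z]), slice_contour(b[z])
        na, nb = int(ca.sum()), int(cb.sum())
        total += na + nb
        if na and nb:
            dist_to_cb = ndimage.distance_transform_edt(~cb, sampling=(sy, sx))
            dist_to_ca = ndimage.distance_transform_edt(~ca, sampling=(sy, sx))
            matched += int((dist_to_cb[ca] <= tolerance_mm).sum())
            matched += int((dist_to_ca[cb] <= tolerance_mm).sum())
    if total == 0:
        return 1.0
    return matched / total


# ---------------------------------------------------------------------------
# trial passing rate
# ---------------------------------------------------------------------------


def rtog_pass_rate(hausdorff_mm_list, threshold_mm: float = RTOG_HAUSDORFF_MM) -> float:
    """Percentage of cases with Hausdorff distance <= threshold."""
    hd = np.asarray(list(hausdorff_mm_list), dtype=float)
    if hd.size == 0:
        raise ValueError("passing rate of an empty list is undefined")
    return 100.0 * float((hd <= threshold_mm).sum()) / hd.size


# ---------------------------------------------------------------------------
# uncertainty density
# ---------------------------------------------------------------------------


def true_positive_filter(predicted: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Restrict a predicted mask to 26-connected components that intersect the
    reference (true-positive components)."""
    predicted = np.asarray(predicted, dtype=bool)
    reference = np.asarray(reference, dtype=bool)
    comp, n_comp = ndimage.label(predicted, structure=_CONN26)
    if n_comp == 0:
        return np.zeros_like(predicted)
    keep = np.unique(comp[reference & predicted])
    keep = keep[keep > 0]
    return np.isin(comp, keep)


def uncertainty_density(
    u_values: np.ndarray,
    predicted: np.ndarray,
    reference: np.ndarray,
    tolerance_mm: float,
    spacing_mm,
) -> float | None:
    """Mean entropy within ``tolerance_mm`` (Euclidean, mm) of the predicted
    contour, after restricting the prediction to true-positive components.

    Returns None (flagged by the caller) if no predicted component intersects
    the reference.
    """
    if tolerance_mm <= 0:
        raise ValueError(f"tolerance must be positive, got {tolerance_mm}")
    filtered = true_positive_filter(predicted, reference)
    if not filtered.any():
        return None
    surf = surface_voxels(filtered)
    dist = ndimage.distance_transform_edt(~surf, sampling=spacing_mm)
    band = dist <= tolerance_mm
    return float(np.asarray(u_values)[band].mean())


# ---------------------------------------------------------------------------
# paired statistics
# ---------------------------------------------------------------------------


def wilcoxon_signed_rank(x, y) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 without ties, otherwise a normal approximation with continuity
    and tie correction.  All differences zero -> p = 1 (degenerate, logged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        logger.warning("Wilcoxon: all paired differences are zero; p = 1")
        return 1.0
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method, correction=(method == "approx"))
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# per-case evaluation
# ---------------------------------------------------------------------------

_SIDE_NAMES = {1: "left", 2: "right"}


def evaluate_case(
    case_id: str,
    predicted: LabelMask,
    reference: LabelMask,
    entropy_values: np.ndarray | None = None,
    contour_tolerances=CONTOUR_TOLERANCES_MM,
    uncertainty_tolerances=UNCERTAINTY_TOLERANCES_MM,
) -> list[MetricRecord]:
    """All metrics for one case, one MetricRecord per side."""
    require_same_geometry(predicted, reference)
    spacing = predicted.spacing
    records = []
    for lab in FOREGROUND_LABELS:
        p, r = predicted.side(lab), reference.side(lab)
        flags = []
        dsc = dice(p, r)
        if not p.any() or not r.any():
            msd = hd = None
            if not p.any():
                flags.append("empty_prediction")
        else:
            msd, hd = surface_distances(p, r, spacing)
        cdice = {tol: contour_dice(p, r, tol, spacing) for tol in contour_tolerances}
        ud = {}
        if entropy_values is not None:
            for tol in uncertainty_tolerances:
                val = uncertainty_density(entropy_values, p, r, tol, spacing)
                if val is None:
                    flags.append(f"no_true_positive_component_tau_{tol}")
                else:
                    ud[tol] = val
        records.append(
            MetricRecord(
                case_id=case_id,
                side=_SIDE_NAMES[lab],
                dice=dsc,
                mean_surface_distance_mm=msd,
                hausdorff_mm=hd,
                contour_dice=cdice,
                uncertainty_density=ud,
                flags=flags,
            )
        )
    return records
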
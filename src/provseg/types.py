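"""Core spatial types: volumes, label masks, affine transforms, grids.

Conventions used throughout the package
---------------------------------------
* Arrays are indexed ``[z, y, x]`` with ``z`` the axial (slice) axis.
* ``spacing`` and ``origin`` are stored in the same ``(z, y, x)`` order, in mm.
* World (physical) coordinates are mm vectors in internal ``(z, y, x)`` order;
  the world position of voxel ``(i, j, k)`` is ``origin + (i, j, k) * spacing``.
* On disk, affines are serialized as standard row-major 4x4 matrices acting on
  ``(x, y, z)`` mm coordinates (the NIfTI convention); the permutation happens
  at the I/O boundary only.
* Labels: 0 = background, 1 = left structure, 2 = right structure.  "Left" is
  the half-space of lower x.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

BACKGROUND = 0
LEFT = 1
RIGHT = 2
FOREGROUND_LABELS = (LEFT, RIGHT)
N_CLASSES = 3

# permutation between internal (z,y,x) and external (x,y,z) coordinates
_P3 = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])


@dataclass(frozen=True)
class Grid:
    """Geometry of a regular voxel grid: shape, spacing and origin (z,y,x)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.spacing)

    @property
    def center_mm(self) -> np.ndarray:
        """World coordinate of the grid centre (z,y,x)."""
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) * np.asarray(self.spacing) / 2.0

    def world_coords(self) -> np.ndarray:
        """Dense (nz,ny,nx,3) array of voxel-centre world coordinates."""
        axes = [self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)]
        zz, yy, xx = np.meshgrid(*axes, indexing="ij")
        return np.stack([zz, yy, xx], axis=-1)

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        """Continuous voxel indices for world points (..., 3)."""
        return (np.asarray(pts) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx) * np.asarray(self.spacing) + np.asarray(self.origin)


@dataclass
class Volume:
    """A 3D scalar image on a regular anisotropic grid."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def grid(self) -> Grid:
        return Grid(tuple(self.values.shape), self.spacing, self.origin)

    def copy(self) -> "Volume":
        return Volume(self.values.copy(), self.spacing, self.origin)

    def to_nifti(self, path: str | Path) -> None:
        write_nifti(path, self.values, self.spacing, self.origin)

    @classmethod
    def from_nifti(cls, path: str | Path) -> "Volume":
        values, spacing, origin = read_nifti(path)
        return cls(values, spacing, origin)


@dataclass
class LabelMask:
    """A 3-class label grid (background / left / right) sharing Volume geometry."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.labels.shape}")
        if not np.isin(np.unique(self.labels), (BACKGROUND, LEFT, RIGHT)).all():
            raise ValueError("labels restricted to {0 (background), 1 (left), 2 (right)}")
        self.labels = self.labels.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def grid(self) -> Grid:
        return Grid(tuple(self.labels.shape), self.spacing, self.origin)

    def side(self, label: int) -> np.ndarray:
        """Binary array of one foreground label."""
        if label not in FOREGROUND_LABELS:
            raise ValueError(f"label must be one of {FOREGROUND_LABELS}, got {label}")
        return self.labels == label

    def copy(self) -> "LabelMask":
        return LabelMask(self.labels.copy(), self.spacing, self.origin)

    def to_nifti(self, path: str | Path) -> None:
        write_nifti(path, self.labels.astype(np.uint8), self.spacing, self.origin)

    @classmethod
    def from_nifti(cls, path: str | Path) -> "LabelMask":
        values, spacing, origin = read_nifti(path)
        return cls(np.rint(values).astype(np.uint8), spacing, origin)


def same_geometry(a: Volume | LabelMask, b: Volume | LabelMask, atol: float = 1e-6) -> bool:
    return (
        a.grid.shape == b.grid.shape
        and np.allclose(a.spacing, b.spacing, atol=atol)
        and np.allclose(a.origin, b.origin, atol=atol)
    )


def require_same_geometry(a: Volume | LabelMask, b: Volume | LabelMask) -> None:
    if not same_geometry(a, b):
        raise ValueError(
            f"geometry mismatch: {a.grid.shape}/{a.spacing}/{a.origin} vs "
            f"{b.grid.shape}/{b.spacing}/{b.origin}"
        )


@dataclass
class AffineTransform:
    """4x4 homogeneous transform between physical (mm) frames.

    The stored matrix acts on internal (z,y,x,1) column vectors.  Use
    :meth:`from_xyz_matrix` / :meth:`to_xyz_matrix` to exchange standard
    (x,y,z)-ordered matrices with the outside world.
    """

    matrix: np.ndarray
    source: str = "source"
    target: str = "target"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (4, 4):
            raise ValueError(f"affine matrix must be 4x4, got {self.matrix.shape}")
        if not np.allclose(self.matrix[3], (0, 0, 0, 1), atol=1e-9):
            raise ValueError("bottom row of an affine must be (0,0,0,1)")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("upper-left 3x3 block must be invertible")

    @classmethod
    def identity(cls, source: str = "source", target: str = "target") -> "AffineTransform":
        return cls(np.eye(4), source, target)

    @classmethod
    def from_xyz_matrix(cls, m_xyz: np.ndarray, source: str = "source", target: str = "target") -> "AffineTransform":
        m_xyz = np.asarray(m_xyz, dtype=np.float64)
        m = np.eye(4)
        m[:3, :3] = _P3 @ m_xyz[:3, :3] @ _P3
        m[:3, 3] = _P3 @ m_xyz[:3, 3]
        return cls(m, source, target)

    def to_xyz_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = _P3 @ self.matrix[:3, :3] @ _P3
        m[:3, 3] = _P3 @ self.matrix[:3, 3]
        return m

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), self.target, self.source)

    def compose(self, first: "AffineTransform") -> "AffineTransform":
        """The transform 'self after first' (applies ``first``, then ``self``)."""
        return AffineTransform(self.matrix @ first.matrix, first.source, self.target)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        """Map world points (..., 3) in (z,y,x) order through the transform."""
        pts = np.asarray(pts, dtype=np.float64)
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def is_identity(self, atol: float = 1e-9) -> bool:
        return np.allclose(self.matrix, np.eye(4), atol=atol)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "matrix_xyz_row_major": self.to_xyz_matrix().tolist(),
            "source": self.source,
            "target": self.target,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AffineTransform":
        payload = json.loads(Path(path).read_text())
        return cls.from_xyz_matrix(
            np.asarray(payload["matrix_xyz_row_major"]),
            payload.get("source", "source"),
            payload.get("target", "target"),
        )


def rotation_about_axis(axis: str, angle_deg: float, center_mm: np.ndarray | None = None) -> AffineTransform:
    """Rigid rotation about a world axis ('x', 'y' or 'z'), optionally about a centre.

    Angles follow the right-hand rule in standard (x,y,z) coordinates.
    """
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    if axis == "x":
        r = np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    elif axis == "y":
        r = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    elif axis == "z":
        r = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)
    else:
        raise ValueError(f"axis must be 'x', 'y' or 'z', got {axis!r}")
    m_xyz = np.eye(4)
    m_xyz[:3, :3] = r
    t = AffineTransform.from_xyz_matrix(m_xyz)
    if center_mm is not None:
        t = recenter(t, np.asarray(center_mm, dtype=float))
    return t


def translation(offset_zyx_mm) -> AffineTransform:
    m = np.eye(4)
    m[:3, 3] = np.asarray(offset_zyx_mm, dtype=float)
    return AffineTransform(m)


def scaling(factor: float, center_mm: np.ndarray | None = None) -> AffineTransform:
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    m = np.diag([factor, factor, factor, 1.0])
    t = AffineTransform(m)
    if center_mm is not None:
        t = recenter(t, np.asarray(center_mm, dtype=float))
    return t


def recenter(t: AffineTransform, center_zyx_mm: np.ndarray) -> AffineTransform:
    """Conjugate a linear transform so it acts about ``center`` instead of the origin."""
    c = np.asarray(center_zyx_mm, dtype=float)
    m = t.matrix.copy()
    # x' = R(x - c) + c + t  =>  translation = c - R c + t
    m[:3, 3] = c - t.matrix[:3, :3] @ c + t.matrix[:3, 3]
    return AffineTransform(m, t.source, t.target)


# ---------------------------------------------------------------------------
# NIfTI I/O (axis-aligned grids only; the permutation to x,y,z storage order
# happens here)
# ---------------------------------------------------------------------------

def write_nifti(path: str | Path, values_zyx: np.ndarray, spacing_zyx, origin_zyx) -> None:
    data_xyz = np.transpose(np.asarray(values_zyx), (2, 1, 0))
    sz, sy, sx = spacing_zyx
    oz, oy, ox = origin_zyx
    affine = np.diag([sx, sy, sz, 1.0])
    affine[:3, 3] = (ox, oy, oz)
    nib.save(nib.Nifti1Image(data_xyz, affine), str(path))


def read_nifti(path: str | Path) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(str(path))
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0, atol=1e-4):
        raise ValueError(f"{path}: only axis-aligned NIfTI grids are supported")
    data_xyz = np.asanyarray(img.dataobj)
    sx, sy, sz = np.abs(np.diag(rot))
    ox, oy, oz = affine[:3, 3]
    return np.transpose(data_xyz, (2, 1, 0)), (float(sz), float(sy), float(sx)), (float(oz), float(oy), float(ox))
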
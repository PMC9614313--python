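"""Core raster data model, file I/O and transform application.

This module defines the in-memory containers shared by every stage of the
segmentation pipeline:

* :class:`Raster2D` — a density-calibrated 2-D image with isotropic physical
  pixel spacing (mm),
* :class:`LabelMap2D` — a per-pixel tissue code map on the same grid,
* :class:`AffineTransform` — a global 2-D affine map in physical coordinates,
* :class:`DisplacementField` — a dense per-pixel deformation in mm,

plus readers/writers for single-slice NIfTI and PNG+JSON-sidecar files and the
resampling operations (``warp_image``, ``warp_labels``) used for atlas warping
and label propagation.

Coordinate convention
---------------------
Pixel indices are 0-based, samples sit at pixel centers, and the physical
coordinate of pixel ``(row, col)`` is ``(x, y) = (col*spacing + origin_x,
row*spacing + origin_y)``.  All transforms use the *pull-back* (resampling)
convention: they map points of the fixed/target grid into the source image, so
a warp is applied in a single interpolation pass.  Points that fall outside
the source field of view are filled with 0 (air).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "AIR",
    "TRABECULAR",
    "CORTICAL",
    "MUSCLE",
    "SAT",
    "TISSUE_NAMES",
    "TISSUE_CODES",
    "Raster2D",
    "LabelMap2D",
    "AffineTransform",
    "DisplacementField",
    "read_image",
    "write_image",
    "read_labels",
    "write_labels",
    "read_field",
    "write_field",
    "warp_image",
    "warp_labels",
    "compose_affine_field",
    "compose_fields",
    "invert_field",
]

# Tissue codes, fixed across the whole package.
AIR = 0
TRABECULAR = 1
CORTICAL = 2
MUSCLE = 3
SAT = 4

TISSUE_NAMES = {
    AIR: "air",
    TRABECULAR: "trabecular_bone",
    CORTICAL: "cortical_bone",
    MUSCLE: "muscle",
    SAT: "sat",
}
TISSUE_CODES = {name: code for code, name in TISSUE_NAMES.items()}

_VALID_LABELS = frozenset(TISSUE_NAMES)


def _check_grid(values: np.ndarray, spacing: float) -> None:
    if values.ndim != 2:
        raise ValueError(f"expected a 2-D grid, got shape {values.shape}")
    if values.shape[0] < 8 or values.shape[1] < 8:
        raise ValueError(f"grid must be at least 8x8, got {values.shape}")
    if not spacing > 0:
        raise ValueError(f"spacing must be positive, got {spacing}")


@dataclass
class Raster2D:
    """A density-calibrated 2-D image with physical pixel spacing.

    Parameters
    ----------
    values
        ``(height, width)`` array of calibrated intensities; stored as
        float32 regardless of the on-disk dtype.
    spacing
        Isotropic pixel size in mm (default 0.5, the in-plane resolution of
        a typical pQCT slice).
    origin
        Physical (x, y) position of the center of pixel (0, 0), in mm.
    """

    values: np.ndarray
    spacing: float = 0.5
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        _check_grid(self.values, self.spacing)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def physical_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(X, Y)`` physical coordinate grids in mm."""
        rows = np.arange(self.height, dtype=np.float64)
        cols = np.arange(self.width, dtype=np.float64)
        x = cols * self.spacing + self.origin[0]
        y = rows * self.spacing + self.origin[1]
        return np.meshgrid(x, y)

    def same_grid_as(self, other: "Raster2D | LabelMap2D") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class LabelMap2D:
    """Per-pixel tissue codes on the same grid as an associated image.

    Codes: 0 air, 1 trabecular bone, 2 cortical bone, 3 muscle, 4 SAT.
    """

    labels: np.ndarray
    spacing: float = 0.5
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(self.labels, rounded):
                raise ValueError("labels must be integer codes")
            self.labels = rounded
        self.labels = self.labels.astype(np.uint8)
        _check_grid(self.labels, self.spacing)
        present = set(np.unique(self.labels).tolist())
        if not present <= _VALID_LABELS:
            raise ValueError(f"invalid label codes {sorted(present - _VALID_LABELS)}")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def present_tissues(self) -> set[int]:
        return set(int(c) for c in np.unique(self.labels))

    def mask(self, tissue: int) -> np.ndarray:
        return self.labels == tissue


@dataclass
class AffineTransform:
    """2-D affine map ``p -> matrix @ p + translation`` in physical mm.

    In the pull-back convention this maps a point of the target (subject)
    grid into the source (atlas) image.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(2))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(2)
        if abs(np.linalg.det(self.matrix)) <= 1e-8:
            raise ValueError("affine matrix is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls()

    @classmethod
    def from_params(cls, params: np.ndarray) -> "AffineTransform":
        """Build from the flat vector (a11, a12, a21, a22, tx, ty)."""
        params = np.asarray(params, dtype=np.float64)
        return cls(params[:4].reshape(2, 2), params[4:6])

    def params(self) -> np.ndarray:
        return np.concatenate([self.matrix.ravel(), self.translation])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an ``(..., 2)`` array of (x, y) physical points."""
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.translation)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return the transform ``p -> self(other(p))``."""
        return AffineTransform(
            self.matrix @ other.matrix,
            self.matrix @ other.translation + self.translation,
        )

    def is_near_identity(self, tol: float = 1e-9) -> bool:
        return (
            np.allclose(self.matrix, np.eye(2), atol=tol)
            and np.allclose(self.translation, 0.0, atol=tol)
        )


@dataclass
class DisplacementField:
    """Dense deformation defined on the fixed (target) grid.

    ``field[r, c] = (dx, dy)`` in mm: the target point at pixel ``(r, c)``
    is sampled from physical position ``p + field`` in the source image
    (pull-back convention).  The optional ``inverse`` field maps the other
    way and is populated by generators/registrars that can provide it.
    """

    displacement: np.ndarray
    spacing: float = 0.5
    origin: tuple[float, float] = (0.0, 0.0)
    inverse: "DisplacementField | None" = None

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=np.float64)
        if self.displacement.ndim != 3 or self.displacement.shape[2] != 2:
            raise ValueError("displacement must have shape (H, W, 2)")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement components must be finite")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @classmethod
    def zeros(cls, shape: tuple[int, int], spacing: float = 0.5,
              origin: tuple[float, float] = (0.0, 0.0)) -> "DisplacementField":
        return cls(np.zeros(shape + (2,)), spacing, origin)

    @property
    def shape(self) -> tuple[int, int]:
        return self.displacement.shape[:2]

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.displacement[..., 0], self.displacement[..., 1])

    def jacobian_determinant(self) -> np.ndarray:
        """Finite-difference Jacobian determinant of ``p -> p + d(p)``."""
        dx = self.displacement[..., 0]
        dy = self.displacement[..., 1]
        ddx_dy, ddx_dx = np.gradient(dx, self.spacing)
        ddy_dy, ddy_dx = np.gradient(dy, self.spacing)
        return (1.0 + ddx_dx) * (1.0 + ddy_dy) - ddx_dy * ddy_dx


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _nifti_affine(spacing: float, origin: tuple[float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = spacing
    aff[1, 1] = spacing
    aff[0, 3] = origin[0]
    aff[1, 3] = origin[1]
    return aff


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in {"nifti", "png"}:
            raise ValueError(f"unknown format {fmt!r}; use 'nifti' or 'png'")
        return fmt
    name = path.name.lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    if name.endswith(".png"):
        return "png"
    raise ValueError(f"cannot infer format from {path.name!r}")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _read_nifti(path: Path) -> tuple[np.ndarray, float, tuple[float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 2:
        raise ValueError(f"{path} is not a single-slice image (shape {data.shape})")
    zooms = img.header.get_zooms()[:2]
    if not np.isclose(zooms[0], zooms[1]):
        raise ValueError(f"anisotropic spacing {zooms} is not supported")
    origin = (float(img.affine[0, 3]), float(img.affine[1, 3]))
    return data, float(zooms[0]), origin


def read_image(path: str | Path, format: str | None = None) -> Raster2D:
    """Read a density-calibrated image from NIfTI or PNG+JSON sidecar.

    PNG pixel values are mapped to densities through the sidecar's
    ``calibration`` as ``density = slope*raw + intercept``; a PNG without a
    sidecar is rejected because its spacing is unknown.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "nifti":
        data, spacing, origin = _read_nifti(path)
        return Raster2D(data, spacing, origin)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(f"spacing metadata required: no sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    raw = np.asarray(Image.open(path), dtype=np.float64)
    cal = meta.get("calibration", {"slope": 1.0, "intercept": 0.0})
    values = raw * float(cal["slope"]) + float(cal["intercept"])
    return Raster2D(values, float(meta["spacing_mm"]), tuple(meta.get("origin_mm", (0.0, 0.0))))


def write_image(image: Raster2D, path: str | Path, format: str | None = None) -> None:
    """Write an image as single-slice NIfTI or 16-bit PNG + JSON sidecar."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "nifti":
        nifti = nib.Nifti1Image(image.values.astype(np.float32),
                                _nifti_affine(image.spacing, image.origin))
        nib.save(nifti, str(path))
        return
    vmin = float(image.values.min())
    vmax = float(image.values.max())
    slope = (vmax - vmin) / 65535.0 if vmax > vmin else 1.0
    raw = np.rint((image.values - vmin) / slope).astype(np.uint16)
    Image.fromarray(raw).save(path)
    meta = {
        "spacing_mm": image.spacing,
        "origin_mm": list(image.origin),
        "calibration": {"slope": slope, "intercept": vmin},
    }
    _sidecar_path(path).write_text(json.dumps(meta))


def read_labels(path: str | Path, format: str | None = None) -> LabelMap2D:
    """Read a tissue label map (NIfTI or 8-bit PNG + sidecar)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "nifti":
        data, spacing, origin = _read_nifti(path)
        return LabelMap2D(data, spacing, origin)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(f"spacing metadata required: no sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    raw = np.asarray(Image.open(path))
    return LabelMap2D(raw, float(meta["spacing_mm"]), tuple(meta.get("origin_mm", (0.0, 0.0))))


def write_labels(labels: LabelMap2D, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "nifti":
        nifti = nib.Nifti1Image(labels.labels.astype(np.uint8),
                                _nifti_affine(labels.spacing, labels.origin))
        nib.save(nifti, str(path))
        return
    Image.fromarray(labels.labels, mode="L").save(path)
    meta = {"spacing_mm": labels.spacing, "origin_mm": list(labels.origin)}
    _sidecar_path(path).write_text(json.dumps(meta))


def write_field(field: DisplacementField, path: str | Path) -> None:
    """Write a displacement field as a 2-component NIfTI (H x W x 1 x 2,
    components in mm: dx then dy)."""
    data = field.displacement.astype(np.float32)[:, :, None, :]
    nifti = nib.Nifti1Image(data, _nifti_affine(field.spacing, field.origin))
    nib.save(nifti, str(Path(path)))


def read_field(path: str | Path) -> DisplacementField:
    """Read a 2-component NIfTI displacement field written by
    :func:`write_field`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.squeeze(np.asanyarray(img.dataobj))
    if data.ndim != 3 or data.shape[-1] != 2:
        raise ValueError(f"{path} is not a 2-component field (shape {data.shape})")
    zooms = img.header.get_zooms()[:2]
    origin = (float(img.affine[0, 3]), float(img.affine[1, 3]))
    return DisplacementField(data, float(zooms[0]), origin)


# ---------------------------------------------------------------------------
# Warping
# ---------------------------------------------------------------------------

def _source_pixel_coords(
    target_shape: tuple[int, int],
    target_spacing: float,
    target_origin: tuple[float, float],
    transform: "AffineTransform | DisplacementField",
    source_spacing: float,
    source_origin: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Map every target pixel to fractional (row, col) source pixel coords."""
    rows = np.arange(target_shape[0], dtype=np.float64)
    cols = np.arange(target_shape[1], dtype=np.float64)
    xx, yy = np.meshgrid(cols * target_spacing + target_origin[0],
                         rows * target_spacing + target_origin[1])
    if isinstance(transform, AffineTransform):
        px = transform.matrix[0, 0] * xx + transform.matrix[0, 1] * yy + transform.translation[0]
        py = transform.matrix[1, 0] * xx + transform.matrix[1, 1] * yy + transform.translation[1]
    elif isinstance(transform, DisplacementField):
        if transform.shape != target_shape:
            raise ValueError(
                f"field shape {transform.shape} does not match target grid {target_shape}")
        px = xx + transform.displacement[..., 0]
        py = yy + transform.displacement[..., 1]
    else:
        raise TypeError(f"unsupported transform type {type(transform)!r}")
    src_c = (px - source_origin[0]) / source_spacing
    src_r = (py - source_origin[1]) / source_spacing
    return src_r, src_c


def warp_image(
    image: Raster2D,
    transform: "AffineTransform | DisplacementField",
    interp: str = "linear",
    out_grid: "Raster2D | LabelMap2D | None" = None,
) -> Raster2D:
    """Resample ``image`` through ``transform`` (pull-back convention).

    ``out_grid`` sets the target grid (defaults to the input grid).  Pixels
    mapped outside the source field of view are filled with 0 (air).
    """
    if interp not in {"linear", "nearest"}:
        raise ValueError(f"interp must be 'linear' or 'nearest', got {interp!r}")
    target = image if out_grid is None else out_grid
    if (isinstance(transform, AffineTransform) and transform.is_near_identity()
            and target.shape == image.shape):
        # Exact identity: skip interpolation entirely.
        return Raster2D(image.values.copy(), image.spacing, image.origin)
    src_r, src_c = _source_pixel_coords(
        target.shape, target.spacing, target.origin,
        transform, image.spacing, image.origin)
    order = 1 if interp == "linear" else 0
    out = ndimage.map_coordinates(
        image.values.astype(np.float64), [src_r, src_c],
        order=order, mode="constant", cval=0.0)
    return Raster2D(out, target.spacing, target.origin)


def warp_labels(
    labels: LabelMap2D,
    transform: "AffineTransform | DisplacementField",
    out_grid: "Raster2D | LabelMap2D | None" = None,
) -> LabelMap2D:
    """Propagate a label map through a transform with nearest-neighbour
    interpolation (labels can never be blended or invented)."""
    target = labels if out_grid is None else out_grid
    if (isinstance(transform, AffineTransform) and transform.is_near_identity()
            and target.shape == labels.shape):
        return LabelMap2D(labels.labels.copy(), labels.spacing, labels.origin)
    src_r, src_c = _source_pixel_coords(
        target.shape, target.spacing, target.origin,
        transform, labels.spacing, labels.origin)
    out = ndimage.map_coordinates(
        labels.labels, [src_r, src_c], order=0, mode="constant", cval=AIR)
    return LabelMap2D(out, target.spacing, target.origin)


def compose_affine_field(
    affine: AffineTransform, deform: DisplacementField
) -> DisplacementField:
    """Compose an affine pre-alignment with a deformable correction.

    Returns the single field ``d(p) = M(p + u(p)) + t - p`` so that warping
    with it equals first warping by ``deform`` and then by ``affine``
    (subject -> affinely-aligned atlas -> atlas), evaluated in one pass.
    """
    h, w = deform.shape
    rows = np.arange(h, dtype=np.float64)
    cols = np.arange(w, dtype=np.float64)
    xx, yy = np.meshgrid(cols * deform.spacing + deform.origin[0],
                         rows * deform.spacing + deform.origin[1])
    px = xx + deform.displacement[..., 0]
    py = yy + deform.displacement[..., 1]
    qx = affine.matrix[0, 0] * px + affine.matrix[0, 1] * py + affine.translation[0]
    qy = affine.matrix[1, 0] * px + affine.matrix[1, 1] * py + affine.translation[1]
    disp = np.stack([qx - xx, qy - yy], axis=-1)
    return DisplacementField(disp, deform.spacing, deform.origin)


def _sample_field(field: DisplacementField, px: np.ndarray, py: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sample a displacement field at physical points (linear interp,
    nearest-edge extension so displacements do not jump to zero)."""
    src_c = (px - field.origin[0]) / field.spacing
    src_r = (py - field.origin[1]) / field.spacing
    dx = ndimage.map_coordinates(field.displacement[..., 0], [src_r, src_c],
                                 order=1, mode="nearest")
    dy = ndimage.map_coordinates(field.displacement[..., 1], [src_r, src_c],
                                 order=1, mode="nearest")
    return dx, dy


def compose_fields(first: DisplacementField, second: DisplacementField) -> DisplacementField:
    """Compose two pull-back fields: warping by the result equals warping by
    ``first`` and then resampling that result through ``second``.

    ``d(p) = u2(p) + u1(p + u2(p))``.
    """
    if first.shape != second.shape:
        raise ValueError("fields must share a grid to compose")
    h, w = second.shape
    rows = np.arange(h, dtype=np.float64)
    cols = np.arange(w, dtype=np.float64)
    xx, yy = np.meshgrid(cols * second.spacing + second.origin[0],
                         rows * second.spacing + second.origin[1])
    px = xx + second.displacement[..., 0]
    py = yy + second.displacement[..., 1]
    dx1, dy1 = _sample_field(first, px, py)
    disp = np.stack([second.displacement[..., 0] + dx1,
                     second.displacement[..., 1] + dy1], axis=-1)
    return DisplacementField(disp, second.spacing, second.origin)


def invert_field(field: DisplacementField, iterations: int = 30) -> DisplacementField:
    """Numerically invert a displacement field by fixed-point iteration:
    ``v(p) = -d(p + v(p))``, converging for moderate deformations."""
    h, w = field.shape
    rows = np.arange(h, dtype=np.float64)
    cols = np.arange(w, dtype=np.float64)
    xx, yy = np.meshgrid(cols * field.spacing + field.origin[0],
                         rows * field.spacing + field.origin[1])
    vx = np.zeros_like(xx)
    vy = np.zeros_like(yy)
    for _ in range(iterations):
        dx, dy = _sample_field(field, xx + vx, yy + vy)
        vx, vy = -dx, -dy
    inv = DisplacementField(np.stack([vx, vy], axis=-1), field.spacing, field.origin)
    return inv
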
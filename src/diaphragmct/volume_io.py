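"""Reading, writing, resampling and left/right splitting of label volumes.

All volumes are held in a canonical anatomical frame:

* axis 0 (x): left -> right
* axis 1 (y): posterior -> anterior
* axis 2 (z): caudal -> cranial

so a coronal slice is the 2D ``(x, z)`` plane at fixed ``y``. Files are
reoriented into this frame at load time using the header direction
cosines; in ITK/DICOM nomenclature the frame is "RAS". Voxel indexing is
0-based and arrays are indexed ``grid[x, y, z]``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .errors import (
    EmptySegmentationError,
    ParameterError,
    VolumeFormatError,
    VolumeTypeError,
)

#: Direction cosine matrix of the canonical frame, expressed in the
#: LPS physical space ITK uses internally (x toward Right, y toward
#: Anterior, z toward Superior).
_RAS_DIRECTION = (-1.0, 0.0, 0.0, 0.0, -1.0, 0.0, 0.0, 0.0, 1.0)

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise VolumeFormatError(
            f"unsupported volume format for {path!s}; expected one of "
            f"{', '.join(_SUPPORTED_SUFFIXES)}"
        )


@dataclass
class LabelVolume:
    """3D integer label grid with physical metadata.

    ``grid`` is indexed ``[x, y, z]`` in the canonical frame; ``spacing``
    and ``origin`` are millimetres per axis. Label 0 is background.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise ParameterError("label grid must be 3D with each axis >= 1")
        if self.grid.dtype.kind not in "iub":
            raise VolumeTypeError(
                f"label grid must have an integer voxel type, got {self.grid.dtype}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ParameterError("spacing must be three positive floats (mm)")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def labels(self) -> np.ndarray:
        """Sorted distinct non-zero labels present in the volume."""
        u = np.unique(self.grid)
        return u[u != 0]


@dataclass
class BinaryMask:
    """Boolean voxel mask in the canonical frame, optionally tagged with
    the lung side it represents ("left", "right" or "n/a")."""

    grid: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    side: str = "n/a"

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise ParameterError("mask grid must be 3D with each axis >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ParameterError("spacing must be three positive floats (mm)")
        self.origin = tuple(float(o) for o in self.origin)
        if self.side not in ("left", "right", "n/a"):
            raise ParameterError(f"side must be left/right/n/a, got {self.side!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def count(self) -> int:
        return int(self.grid.sum())


@dataclass
class CTVolume:
    """CT intensity volume in Hounsfield units, same frame conventions."""

    grid: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ParameterError("CT grid must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)


@dataclass
class LabelMapConfig:
    """Mapping from integer lobe/lung labels to a lung side.

    The common 5-lobe convention maps labels {1, 2} to the left lung and
    {3, 4, 5} to the right lung; conventions vary between tools, so the
    mapping is configurable (and loadable from JSON). Labels absent from
    the mapping are ignored.
    """

    left: frozenset[int] = field(default_factory=lambda: frozenset({1, 2}))
    right: frozenset[int] = field(default_factory=lambda: frozenset({3, 4, 5}))

    def __post_init__(self):
        self.left = frozenset(int(v) for v in self.left)
        self.right = frozenset(int(v) for v in self.right)
        if not self.left and not self.right:
            raise ParameterError("label map must assign at least one label")
        overlap = self.left & self.right
        if overlap:
            raise ParameterError(f"labels map to both sides: {sorted(overlap)}")

    @classmethod
    def from_json(cls, path) -> "LabelMapConfig":
        with open(path) as fh:
            data = json.load(fh)
        return cls(left=frozenset(data.get("left", ())),
                   right=frozenset(data.get("right", ())))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"left": sorted(self.left), "right": sorted(self.right)}, fh)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _sitk_to_canonical(img: sitk.Image):
    """Reorient a SimpleITK image into the canonical frame and return
    (grid[x, y, z], spacing, origin)."""
    img = sitk.DICOMOrient(img, "RAS")
    arr = sitk.GetArrayFromImage(img)          # indexed [z, y, x]
    grid = np.ascontiguousarray(arr.transpose(2, 1, 0))
    return grid, tuple(img.GetSpacing()), tuple(img.GetOrigin())


def _canonical_to_sitk(grid: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    img.SetDirection(_RAS_DIRECTION)
    return img


def read_label_volume(path) -> LabelVolume:
    """Read a lobe/lung label volume from NIfTI or MetaImage.

    Integer labels are preserved exactly; spacing is taken from the
    header and the volume is reoriented to the canonical frame.
    """
    path = Path(path)
    _check_suffix(path)
    if not path.exists():
        raise VolumeFormatError(f"cannot read volume: {path!s} does not exist")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise VolumeFormatError(f"cannot read volume {path!s}: {exc}") from exc
    grid, spacing, origin = _sitk_to_canonical(img)
    if grid.dtype.kind not in "iub":
        raise VolumeTypeError(
            f"{path!s} has voxel type {grid.dtype}; label volumes must be integer"
        )
    return LabelVolume(grid=grid, spacing=spacing, origin=origin)


def write_label_volume(vol: LabelVolume | BinaryMask, path) -> None:
    """Write a label volume or binary mask to NIfTI or MetaImage."""
    path = Path(path)
    _check_suffix(path)
    grid = vol.grid
    if grid.dtype == bool:
        grid = grid.astype(np.uint8)
    sitk.WriteImage(_canonical_to_sitk(grid, vol.spacing, vol.origin), str(path))


def read_ct_volume(path) -> CTVolume:
    """Read a CT intensity volume (Hounsfield units)."""
    path = Path(path)
    _check_suffix(path)
    if not path.exists():
        raise VolumeFormatError(f"cannot read volume: {path!s} does not exist")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise VolumeFormatError(f"cannot read volume {path!s}: {exc}") from exc
    grid, spacing, origin = _sitk_to_canonical(img)
    return CTVolume(grid=grid, spacing=spacing, origin=origin)


def read_mask(path, side: str = "n/a") -> BinaryMask:
    """Read a binary mask (any non-zero voxel is foreground)."""
    vol = read_label_volume(path)
    return BinaryMask(grid=vol.grid != 0, spacing=vol.spacing,
                      origin=vol.origin, side=side)


# ---------------------------------------------------------------------------
# Resampling and lung splitting
# ---------------------------------------------------------------------------

def resample_isotropic(vol: LabelVolume, target: float = 1.0) -> LabelVolume:
    """Resample a label volume to an isotropic grid by nearest neighbour.

    The segmentation is resampled with nearest-neighbour assignment so no
    new label values are created. The output shape is
    ``ceil(extent / target)`` per axis, which never crops anatomy; the
    origin is preserved and output voxel centres sit at
    ``origin + index * target``.
    """
    if target <= 0:
        raise ParameterError(f"target spacing must be > 0, got {target}")
    if all(abs(s - target) < 1e-12 for s in vol.spacing):
        return LabelVolume(grid=vol.grid.copy(), spacing=(target,) * 3,
                           origin=vol.origin)
    out_shape = tuple(
        int(math.ceil(n * s / target)) for n, s in zip(vol.grid.shape, vol.spacing)
    )
    idx = []
    for n_out, n_in, s in zip(out_shape, vol.grid.shape, vol.spacing):
        src = np.rint(np.arange(n_out) * target / s).astype(np.intp)
        idx.append(np.clip(src, 0, n_in - 1))
    grid = vol.grid[np.ix_(*idx)]
    return LabelVolume(grid=grid, spacing=(target,) * 3, origin=vol.origin)


def split_lungs(vol: LabelVolume,
                cfg: LabelMapConfig | None = None) -> tuple[BinaryMask, BinaryMask]:
    """Merge lobe labels into left and right lung binary masks.

    The two masks are disjoint by construction (no label maps to both
    sides). Raises :class:`EmptySegmentationError` when neither side
    contains any voxel.
    """
    cfg = cfg or LabelMapConfig()
    left_grid = np.isin(vol.grid, sorted(cfg.left)) if cfg.left else np.zeros(
        vol.grid.shape, dtype=bool)
    right_grid = np.isin(vol.grid, sorted(cfg.right)) if cfg.right else np.zeros(
        vol.grid.shape, dtype=bool)
    if not left_grid.any() and not right_grid.any():
        raise EmptySegmentationError(
            "no voxel carries a label mapped to either lung"
        )
    left = BinaryMask(grid=left_grid, spacing=vol.spacing, origin=vol.origin,
                      side="left")
    right = BinaryMask(grid=right_grid, spacing=vol.spacing, origin=vol.origin,
                       side="right")
    return left, right
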
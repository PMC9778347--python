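"""Volume containers, NIfTI I/O and the three-view slicing convention.

Volumes are kept on a canonical RAS-like grid so that the anatomical views
map onto fixed array axes:

* ``sagittal`` slices run along axis 0 (left-right),
* ``coronal``  slices run along axis 1 (posterior-anterior),
* ``axial``    slices run along axis 2 (inferior-superior).

Slice extraction and re-stacking are exact inverses for every view; slices
are ordered by ascending voxel index and no view applies a flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: Fixed tissue-label vocabulary (0 is background).
LABEL_NAMES = {
    0: "background",
    1: "ECF",   # external cerebrospinal fluid
    2: "FGM",   # fluid/cortical gray matter
    3: "WM",    # white matter
    4: "VC",    # ventricles
    5: "CBM",   # cerebellum
    6: "DGM",   # deep gray matter
    7: "BSTM",  # brainstem
}

TISSUE_LABELS = tuple(range(1, 8))

VIEWS = ("axial", "sagittal", "coronal")

#: Array axis sliced for each anatomical view on the canonical grid.
VIEW_AXES = {"sagittal": 0, "coronal": 1, "axial": 2}


def view_axis(view: str) -> int:
    try:
        return VIEW_AXES[view]
    except KeyError:
        raise ValueError(f"unknown view {view!r}; expected one of {sorted(VIEW_AXES)}") from None


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class ImageVolume:
    """A 3D intensity grid with voxel spacing in millimetres."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("image volume contains non-finite voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class LabelVolume:
    """A 3D integer label grid over the 7-tissue vocabulary (plus background)."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    label_names: dict = field(default_factory=lambda: dict(LABEL_NAMES))

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D label volume, got shape {arr.shape}")
        rounded = np.rint(arr)
        if arr.dtype.kind == "f" and not np.allclose(arr, rounded, atol=1e-6):
            raise ValueError("label volume contains non-integer values")
        arr = rounded.astype(np.int64) if arr.dtype.kind == "f" else arr.astype(np.int64)
        bad = np.setdiff1d(np.unique(arr), np.arange(8))
        if bad.size:
            raise ValueError(f"label volume contains values outside 0..7: {sorted(bad.tolist())}")
        self.labels = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


@dataclass
class SliceStack:
    """An ordered list of 2D slices taken along one view axis."""

    view: str
    slices: list
    index_axis: int

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise ValueError(f"unknown view {self.view!r}")
        if len(self.slices) == 0:
            raise ValueError("empty slice stack")
        shapes = {s.shape for s in self.slices}
        if len(shapes) != 1:
            raise ValueError(f"ragged slice shapes: {sorted(shapes)}")

    def __len__(self) -> int:
        return len(self.slices)


def read_volume(path: str | Path, kind: str = "auto") -> ImageVolume | LabelVolume:
    """Read a NIfTI-1 file, reorienting to the canonical RAS axis order.

    ``kind`` is ``"image"``, ``"label"`` or ``"auto"`` (label iff the on-disk
    dtype is integer).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path.name}: expected a 3D image, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if kind == "auto":
        kind = "label" if data.dtype.kind in "iub" else "image"
    if kind == "label":
        return LabelVolume(data, spacing=spacing, affine=np.asarray(img.affine))
    return ImageVolume(data.astype(np.float32), spacing=spacing, affine=np.asarray(img.affine))


def write_volume(vol: ImageVolume | LabelVolume, path: str | Path) -> None:
    """Write a volume to NIfTI-1, preserving its affine; labels go out uint8."""
    if isinstance(vol, LabelVolume):
        data = vol.labels.astype(np.uint8)
    else:
        data = vol.voxels.astype(np.float32)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def _grid(vol) -> np.ndarray:
    if isinstance(vol, ImageVolume):
        return vol.voxels
    if isinstance(vol, LabelVolume):
        return vol.labels
    return np.asarray(vol)


def extract_slices(vol, view: str) -> SliceStack:
    """Split a volume into 2D slices along the given anatomical view."""
    axis = view_axis(view)
    grid = _grid(vol)
    slices = [np.take(grid, i, axis=axis) for i in range(grid.shape[axis])]
    return SliceStack(view=view, slices=slices, index_axis=axis)


def stack_slices(stack: SliceStack, view: str | None = None) -> np.ndarray:
    """Re-stack 2D slices into a 3D grid; exact inverse of :func:`extract_slices`."""
    view = view or stack.view
    axis = view_axis(view)
    return np.stack(stack.slices, axis=axis)
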
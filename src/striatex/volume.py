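"""Volumes, region masks and rigid resampling.

All images are NIfTI-1; voxel indices are 0-based and the file's affine
maps indices to world millimetres. Emission data are interpolated
trilinearly; binary region masks are never interpolated and must already
live on the analysis grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "RegionMaskSet",
    "RigidTransform",
    "REQUIRED_REGIONS",
    "STRIATAL_REGIONS",
    "read_volume",
    "write_volume",
    "read_mask_set",
    "read_label_masks",
    "write_mask_set",
    "resample_rigid",
    "gaussian_smooth",
]

#: regions every analysis needs: bilateral caudate/putamen plus the
#: occipital reference region.
STRIATAL_REGIONS = ("caudate_L", "caudate_R", "putamen_L", "putamen_R")
REQUIRED_REGIONS = STRIATAL_REGIONS + ("occipital",)

# FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class Volume:
    """A 3D scalar image with its voxel-to-world affine.

    Parameters
    ----------
    data:
        3D array of intensities in arbitrary activity units.
    affine:
        4x4 matrix mapping 0-based voxel indices to world mm.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected 3D volume, got {self.data.ndim}D shape {self.data.shape}"
            )
        if min(self.data.shape) < 1:
            raise ValueError("all three dimensions must be >= 1")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        bad = np.count_nonzero(~np.isfinite(self.data))
        if bad:
            raise ValueError(f"volume contains {bad} non-finite voxels")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy())

    def voxel_coords_world(self) -> np.ndarray:
        """World-mm coordinates of every voxel centre, shape (3, nx, ny, nz)."""
        idx = np.indices(self.data.shape, dtype=float)
        hom = np.concatenate([idx, np.ones((1,) + self.data.shape)], axis=0)
        return np.einsum("ij,j...->i...", self.affine, hom)[:3]


@dataclass
class RegionMaskSet:
    """Named boolean masks on a common grid.

    Striatal masks must be pairwise disjoint and every required region
    non-empty; extra regions are allowed.
    """

    masks: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"masks are on different grids: {sorted(shapes)}")
        for name in REQUIRED_REGIONS:
            if name in self.masks and not self.masks[name].any():
                raise ValueError(f"region {name!r} is empty")
        names = [n for n in STRIATAL_REGIONS if n in self.masks]
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if np.any(self.masks[a] & self.masks[b]):
                    raise ValueError(f"striatal masks {a!r} and {b!r} overlap")

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.masks[name]
        except KeyError:
            raise KeyError(
                f"unknown region {name!r}; available: {sorted(self.masks)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> Iterable[str]:
        return self.masks.keys()

    def check_grid(self, volume: Volume) -> None:
        shape = next(iter(self.masks.values())).shape
        if shape != volume.data.shape:
            raise ValueError(
                f"mask grid {shape} does not match volume grid {volume.data.shape}"
            )


@dataclass
class RigidTransform:
    """Rigid world-mm mapping x -> R x + t from moving to target space."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-6 or abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError(
                "rotation must be orthonormal with determinant +1 "
                f"(orthonormality error {err:.2e}, det {np.linalg.det(self.rotation):.6f})"
            )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, mat: np.ndarray) -> "RigidTransform":
        mat = np.asarray(mat, dtype=float)
        if mat.shape != (4, 4):
            raise ValueError("expected a 4x4 matrix")
        return cls(mat[:3, :3], mat[:3, 3])

    def to_matrix(self) -> np.ndarray:
        mat = np.eye(4)
        mat[:3, :3] = self.rotation
        mat[:3, 3] = self.translation
        return mat

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    @classmethod
    def read(cls, path) -> "RigidTransform":
        return cls.from_matrix(np.loadtxt(path).reshape(4, 4))

    def write(self, path) -> None:
        np.savetxt(path, self.to_matrix(), fmt="%.17g")


def read_volume(path) -> Volume:
    """Read a 3D NIfTI-1 volume, keeping data, spacing and affine."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got shape {data.shape} in {path}")
    return Volume(np.asarray(data, dtype=float), np.asarray(img.affine))


def write_volume(v: Volume, path) -> None:
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float64), v.affine)
    nib.save(img, str(path))


def read_mask_set(paths: Mapping[str, object]) -> RegionMaskSet:
    """Read one binary NIfTI per region (mapping region-name -> path)."""
    masks = {}
    for name, p in paths.items():
        vol = read_volume(p)
        vals = np.unique(vol.data)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError(
                f"mask {name!r} at {p} is not binary (values {vals[:5]}...)"
            )
        masks[name] = vol.data > 0.5
    return RegionMaskSet(masks)


def read_label_masks(label_path, table) -> RegionMaskSet:
    """Read an integer label image plus a name -> label table.

    ``table`` may be a mapping or the path of a JSON file holding one.
    """
    if not isinstance(table, Mapping):
        with open(table) as fh:
            table = json.load(fh)
    vol = read_volume(label_path)
    labels = np.rint(vol.data).astype(int)
    return RegionMaskSet({name: labels == int(lab) for name, lab in table.items()})


def write_mask_set(masks: RegionMaskSet, affine: np.ndarray, out_dir) -> Dict[str, str]:
    """Write one uint8 NIfTI per region; returns name -> path written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name in masks.names():
        p = out_dir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(masks[name].astype(np.uint8), affine), str(p))
        written[name] = str(p)
    return written


def resample_rigid(moving: Volume, target_grid: Volume, transform: RigidTransform) -> Volume:
    """Resample ``moving`` onto the grid of ``target_grid``.

    ``transform`` maps moving-space world coordinates to target-space
    world coordinates. Interpolation is trilinear; voxels that map
    outside the moving field of view are set to 0. An identity transform
    between identical grids reproduces the input exactly.
    """
    inv = transform.inverse()
    world_t = target_grid.voxel_coords_world()  # (3, nx, ny, nz)
    world_m = np.einsum("ij,j...->i...", inv.rotation, world_t) + inv.translation.reshape(3, 1, 1, 1)
    inv_aff = np.linalg.inv(moving.affine)
    vox_m = (
        np.einsum("ij,j...->i...", inv_aff[:3, :3], world_m)
        + inv_aff[:3, 3].reshape(3, 1, 1, 1)
    )
    out = ndimage.map_coordinates(moving.data, vox_m, order=1, mode="constant", cval=0.0)
    return Volume(out, target_grid.affine.copy())


def gaussian_smooth(v: Volume, fwhm_mm: float) -> Volume:
    """Isotropic Gaussian smoothing specified by FWHM in mm.

    sigma = fwhm / (2*sqrt(2 ln 2)), converted per axis to voxel units
    via the spacing. Boundaries are handled with a reflective zero-flux
    scheme, so constant volumes are preserved and total intensity is
    conserved.
    """
    if not fwhm_mm > 0:
        raise ValueError(f"fwhm_mm must be positive, got {fwhm_mm}")
    sigma_vox = fwhm_mm * _FWHM_TO_SIGMA / v.spacing
    out = ndimage.gaussian_filter(v.data, sigma=sigma_vox, mode="reflect")
    return Volume(out, v.affine.copy())
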
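"""Axis-ordered voxel volumes with spacing, origin and a value semantic.

Arrays are ordered (z, y, x); spacing and origin follow the same order and are
in millimetres, with world coordinates attached to voxel centers.  Every volume
declares what its values mean (HU, ED, EAN, SPR, MASS_DENSITY, DOSE_GY, LABEL,
GAMMA) so that pipeline stages can refuse mismatched inputs before computing.

Volumes round-trip through NIfTI (.nii/.nii.gz, via nibabel, semantic stored in
the header ``descrip`` field) and MetaImage (.mha/.mhd, via SimpleITK, semantic
stored in a JSON sidecar next to the image).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = ["ImageVolume", "SEMANTICS", "write_volume", "read_volume"]

SEMANTICS = frozenset(
    {"HU", "ED", "EAN", "SPR", "MASS_DENSITY", "DOSE_GY", "LABEL", "GAMMA"}
)


@dataclass
class ImageVolume:
    """A 3-D voxel grid: ``values[z, y, x]`` + spacing/origin (mm) + semantic."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    semantic: str = "HU"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D array, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must be (z, y, x) triples")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.semantic not in SEMANTICS:
            raise ValueError(
                f"unknown semantic {self.semantic!r}; expected one of {sorted(SEMANTICS)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis (0=z,1=y,2=x)."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.axis_coords(0), self.axis_coords(1), self.axis_coords(2)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) world coordinates of the voxel-center bounding box."""
        lo = np.array(self.origin)
        hi = lo + (np.array(self.shape) - 1) * np.array(self.spacing)
        return lo, hi

    def grid_matches(self, other: "ImageVolume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def require_grid_match(self, other: "ImageVolume", tol: float = 1e-6) -> None:
        if not self.grid_matches(other, tol):
            raise ValueError(
                "volume grids do not match:\n"
                f"  a: shape={self.shape} spacing={self.spacing} origin={self.origin}\n"
                f"  b: shape={other.shape} spacing={other.spacing} origin={other.origin}"
            )

    def require_semantic(self, semantic: str) -> None:
        if self.semantic != semantic:
            raise ValueError(
                f"expected a volume with semantic {semantic!r}, got {self.semantic!r}"
            )

    def with_values(self, values: np.ndarray, semantic: str | None = None) -> "ImageVolume":
        """Same grid, new values (and optionally new semantic)."""
        return replace(self, values=values, semantic=semantic or self.semantic)


def _write_nifti(vol: ImageVolume, path: Path) -> None:
    dz, dy, dx = vol.spacing
    oz, oy, ox = vol.origin
    affine = np.diag([dx, dy, dz, 1.0])
    affine[:3, 3] = [ox, oy, oz]
    img = nib.Nifti1Image(np.transpose(vol.values, (2, 1, 0)).astype(np.float64), affine)
    img.header["descrip"] = f"semantic={vol.semantic}".encode()
    nib.save(img, str(path))


def _read_nifti(path: Path, semantic: str | None) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got {data.ndim}-D")
    affine = img.affine
    spacing = (float(affine[2, 2]), float(affine[1, 1]), float(affine[0, 0]))
    origin = (float(affine[2, 3]), float(affine[1, 3]), float(affine[0, 3]))
    if semantic is None:
        descrip = img.header["descrip"].tobytes().rstrip(b"\x00").decode(errors="replace")
        if not descrip.startswith("semantic="):
            raise ValueError(
                f"{path}: no semantic tag in NIfTI header; pass semantic= explicitly"
            )
        semantic = descrip.split("=", 1)[1]
    return ImageVolume(np.transpose(data, (2, 1, 0)), spacing, origin, semantic)


def _write_meta(vol: ImageVolume, path: Path) -> None:
    img = sitk.GetImageFromArray(vol.values.astype(np.float64))
    dz, dy, dx = vol.spacing
    oz, oy, ox = vol.origin
    img.SetSpacing((dx, dy, dz))
    img.SetOrigin((ox, oy, oz))
    sitk.WriteImage(img, str(path))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"semantic": vol.semantic}))


def _read_meta(path: Path, semantic: str | None) -> ImageVolume:
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"{path}: expected a 3-D image, got {img.GetDimension()}-D")
    data = sitk.GetArrayFromImage(img)  # already (z, y, x)
    dx, dy, dz = img.GetSpacing()
    ox, oy, oz = img.GetOrigin()
    if semantic is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ValueError(f"{path}: missing semantic sidecar {sidecar.name}")
        semantic = json.loads(sidecar.read_text())["semantic"]
    return ImageVolume(data, (dz, dy, dx), (oz, oy, ox), semantic)


def _dispatch(path: Path):
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return _write_nifti, _read_nifti
    if name.endswith((".mha", ".mhd")):
        return _write_meta, _read_meta
    raise ValueError(
        f"unsupported volume format {path.name!r}; supported: .nii, .nii.gz, .mha, .mhd"
    )


def write_volume(vol: ImageVolume, path) -> None:
    """Write a volume to NIfTI or MetaImage, preserving grid and semantic."""
    path = Path(path)
    writer, _ = _dispatch(path)
    writer(vol, path)


def read_volume(path, semantic: str | None = None) -> ImageVolume:
    """Read a NIfTI or MetaImage volume; semantic from metadata unless given."""
    path = Path(path)
    _, reader = _dispatch(path)
    return reader(path, semantic)
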
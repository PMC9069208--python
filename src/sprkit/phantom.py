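"""Synthetic cylindrical phantoms and channel renderers.

The generator emulates the study geometry this package is validated on:
cylindrical PMMA bodies with cylindrical tissue-surrogate bore inserts, two
one-bore "long" cylinders (LCT: height 46 cm / radius 5 cm; LC: 46 cm / 8 cm)
and two nine-bore "short" cylinders (SC: 10 cm / 8 cm; SCB: 10 cm / 16 cm),
inserts of height 7 cm and radius 1.4 cm.  The nine-bore layout is one central
bore plus eight on a ring at 60% of the body radius, with bone-like inserts
placed non-adjacent to limit (real-world) artifact clustering.

Rendering produces the channels the two prediction paths consume: a zero- or
Gaussian-noise ED/EAN pair for the dual-energy path, and an HU volume via the
two-parameter stoichiometric forward model for the single-energy path.  Noise
is i.i.d. Gaussian per channel; ED/EAN noise is drawn independently (real
dual-layer noise is anti-correlated — see docs/methods.md).  Paired analytic
dose grids with a controllable shift/scale support gamma-analysis testing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hlut import AttenuationFit, theoretical_ctn
from .materials import (
    DEFAULT_CONSTANTS,
    MaterialLibrary,
    PhysicsConstants,
    material_properties,
)
from .volume import ImageVolume

__all__ = [
    "Bore",
    "PhantomGeometry",
    "NoiseModel",
    "builtin_geometries",
    "rasterize",
    "render_dlct",
    "render_sect",
    "make_dose_pair",
]

INSERT_RADIUS_CM = 1.4
INSERT_DEPTH_CM = 7.0

#: Default planning-CT voxel size, (dz, dy, dx) in mm.
DEFAULT_SPACING = (1.0, 0.977, 0.977)


@dataclass(frozen=True)
class Bore:
    """One cylindrical bore: axial center (y, x) in cm, radius and depth in cm."""

    cy: float
    cx: float
    radius: float = INSERT_RADIUS_CM
    depth: float = INSERT_DEPTH_CM


@dataclass(frozen=True)
class PhantomGeometry:
    """A cylindrical phantom body with cylindrical bores along the z axis."""

    name: str
    body_radius: float  # cm
    body_height: float  # cm
    bores: tuple[Bore, ...] = ()
    insert_assignment: dict[int, str] = field(default_factory=dict)
    body_material: str = "pmma"

    def __post_init__(self) -> None:
        if self.body_radius <= 0 or self.body_height <= 0:
            raise ValueError(f"phantom {self.name!r}: non-positive body dimensions")
        for i, b in enumerate(self.bores):
            if math.hypot(b.cy, b.cx) + b.radius > self.body_radius + 1e-9:
                raise ValueError(
                    f"phantom {self.name!r}: bore {i} extends outside the body cylinder"
                )
            if b.depth > self.body_height + 1e-9:
                raise ValueError(f"phantom {self.name!r}: bore {i} deeper than the body")
        for i, a in enumerate(self.bores):
            for j, b in enumerate(self.bores[:i]):
                if math.hypot(a.cy - b.cy, a.cx - b.cx) < a.radius + b.radius - 1e-9:
                    raise ValueError(
                        f"phantom {self.name!r}: bores {j} and {i} overlap"
                    )
        for k in self.insert_assignment:
            if not 0 <= k < len(self.bores):
                raise ValueError(f"phantom {self.name!r}: assignment to unknown bore {k}")

    def assign(self, assignment: dict[int, str]) -> "PhantomGeometry":
        """A copy with a different bore → material assignment."""
        return PhantomGeometry(
            self.name, self.body_radius, self.body_height, self.bores,
            dict(assignment), self.body_material,
        )


def _nine_bores(body_radius: float) -> tuple[Bore, ...]:
    ring = 0.6 * body_radius
    bores = [Bore(0.0, 0.0)]
    for k in range(8):
        ang = 2.0 * math.pi * k / 8.0
        bores.append(Bore(ring * math.sin(ang), ring * math.cos(ang)))
    return tuple(bores)


# Bone-like surrogates on alternating ring positions (1, 3, 5, 7) so no two
# bone inserts sit in adjacent bores.
_NINE_BORE_ASSIGNMENT = {
    0: "muscle",
    1: "cortical_bone",
    2: "brain",
    3: "cb2_50",
    4: "adipose",
    5: "cb2_30",
    6: "true_water",
    7: "inner_bone",
    8: "liver",
}


def builtin_geometries() -> dict[str, PhantomGeometry]:
    """The four built-in cylinders: LCT, LC (one bore), SC, SCB (nine bores)."""
    one_bore = (Bore(0.0, 0.0),)
    return {
        "LCT": PhantomGeometry("LCT", 5.0, 46.0, one_bore, {0: "true_water"}),
        "LC": PhantomGeometry("LC", 8.0, 46.0, one_bore, {0: "true_water"}),
        "SC": PhantomGeometry("SC", 8.0, 10.0, _nine_bores(8.0), dict(_NINE_BORE_ASSIGNMENT)),
        "SCB": PhantomGeometry("SCB", 16.0, 10.0, _nine_bores(16.0), dict(_NINE_BORE_ASSIGNMENT)),
    }


@dataclass(frozen=True)
class NoiseModel:
    """Per-channel i.i.d. Gaussian noise SDs plus the RNG seed."""

    sigma_hu: float = 0.0
    sigma_ed: float = 0.0
    sigma_ean: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_hu, self.sigma_ed, self.sigma_ean) < 0:
            raise ValueError("noise SDs must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def rasterize(
    geom: PhantomGeometry,
    library: MaterialLibrary,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    margin_mm: float = 10.0,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> tuple[ImageVolume, pd.DataFrame]:
    """Voxelize a phantom by voxel-center membership.

    Returns a LABEL volume (0 air, 1 body, 2+k insert in bore k) and a ground
    truth table with one row per label carrying the material name, geometry of
    the bore (mm), and the derived radiological properties computed from the
    material table (the self-consistent reference for every later comparison).
    Unassigned bores are filled with the body material and flagged with a
    warning.
    """
    dz, dy, dx = (float(s) for s in spacing)
    if min(dz, dy, dx) <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    r_mm = geom.body_radius * 10.0
    h_mm = geom.body_height * 10.0
    half_xy = r_mm + margin_mm
    half_z = h_mm / 2.0 + margin_mm
    nx = int(np.ceil(2 * half_xy / dx))
    ny = int(np.ceil(2 * half_xy / dy))
    nz = int(np.ceil(2 * half_z / dz))
    origin = (-(nz - 1) / 2.0 * dz, -(ny - 1) / 2.0 * dy, -(nx - 1) / 2.0 * dx)
    z = origin[0] + dz * np.arange(nz)
    y = origin[1] + dy * np.arange(ny)
    x = origin[2] + dx * np.arange(nx)

    rr = y[:, None] ** 2 + x[None, :] ** 2  # (y, x) squared radius
    in_z = np.abs(z) <= h_mm / 2.0
    labels = np.zeros((nz, ny, nx), dtype=np.int16)
    body_mask2d = rr <= r_mm**2
    labels[in_z] = np.where(body_mask2d, 1, 0)[None, :, :]

    rows = []

    def _props_row(label, name, bore_index=None, bore=None):
        comp = library[name]
        p = material_properties(comp, library.elements, constants)
        row = {
            "label": label,
            "name": name,
            "category": comp.category,
            "is_insert": bore_index is not None,
            "bore_index": -1 if bore_index is None else bore_index,
            "rho": p.rho,
            "rho_e": p.rho_e,
            "z_eff": p.z_eff,
            "i_value": p.i_value,
            "spr": p.spr,
            "cy_mm": np.nan,
            "cx_mm": np.nan,
            "radius_mm": np.nan,
            "zmin_mm": np.nan,
            "zmax_mm": np.nan,
        }
        if bore is not None:
            row.update(
                cy_mm=bore.cy * 10.0,
                cx_mm=bore.cx * 10.0,
                radius_mm=bore.radius * 10.0,
                zmin_mm=-bore.depth * 10.0 / 2.0,
                zmax_mm=bore.depth * 10.0 / 2.0,
            )
        return row

    rows.append(_props_row(0, "air"))
    rows.append(_props_row(1, geom.body_material))

    for k, bore in enumerate(geom.bores):
        name = geom.insert_assignment.get(k)
        if name is None:
            warnings.warn(
                f"phantom {geom.name!r}: bore {k} has no insert assigned; "
                "filling with the body material",
                stacklevel=2,
            )
            continue
        label = 2 + k
        mask2d = (y[:, None] - bore.cy * 10.0) ** 2 + (x[None, :] - bore.cx * 10.0) ** 2 <= (
            bore.radius * 10.0
        ) ** 2
        in_depth = np.abs(z) <= bore.depth * 10.0 / 2.0
        region = labels[in_depth]
        region[:, mask2d] = label
        labels[in_depth] = region
        rows.append(_props_row(label, name, k, bore))

    truth = pd.DataFrame(rows).set_index("label", drop=False)
    vol = ImageVolume(labels, (dz, dy, dx), origin, "LABEL")
    return vol, truth


def _label_lookup(truth: pd.DataFrame, column: str, n_labels: int) -> np.ndarray:
    lut = np.zeros(n_labels, dtype=float)
    for _, row in truth.iterrows():
        lut[int(row["label"])] = row[column]
    return lut


def render_dlct(
    labels: ImageVolume, truth: pd.DataFrame, noise: NoiseModel = NoiseModel()
) -> tuple[ImageVolume, ImageVolume]:
    """Piecewise-constant true ED and EAN volumes plus independent Gaussian noise."""
    labels.require_semantic("LABEL")
    lab = labels.values.astype(int)
    n = int(lab.max()) + 1
    ed = _label_lookup(truth, "rho_e", n)[lab]
    ean = _label_lookup(truth, "z_eff", n)[lab]
    rng = noise.rng()
    if noise.sigma_ed > 0:
        ed = ed + rng.normal(0.0, noise.sigma_ed, ed.shape)
    if noise.sigma_ean > 0:
        ean = ean + rng.normal(0.0, noise.sigma_ean, ean.shape)
    return (
        labels.with_values(ed, "ED"),
        labels.with_values(ean, "EAN"),
    )


def render_sect(
    labels: ImageVolume,
    truth: pd.DataFrame,
    fit: AttenuationFit,
    library: MaterialLibrary,
    noise: NoiseModel = NoiseModel(),
) -> ImageVolume:
    """HU volume from the two-parameter stoichiometric forward model + noise.

    Each label's CT number is the theoretical value of its material composition
    under ``fit`` (water → 0 HU, vacuum → −1000 HU), so the single-energy
    prediction path can be exercised end to end without scanner data.
    """
    labels.require_semantic("LABEL")
    lab = labels.values.astype(int)
    n = int(lab.max()) + 1
    lut = np.zeros(n, dtype=float)
    for _, row in truth.iterrows():
        lut[int(row["label"])] = theoretical_ctn(library[row["name"]], library.elements, fit)
    hu = lut[lab]
    if noise.sigma_hu > 0:
        hu = hu + noise.rng().normal(0.0, noise.sigma_hu, hu.shape)
    return labels.with_values(hu, "HU")


def make_dose_pair(
    shape: tuple[int, int, int] = (60, 40, 40),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    field_type: str = "edge",
    shift: tuple[float, float, float] = (0.0, 0.0, 0.0),
    scale: float = 1.0,
    dmax: float = 1.0,
    edge_width_mm: float = 3.0,
    sigma_mm: float = 8.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    ramp_length_mm: float = 60.0,
    eval_pad_mm: float = 0.0,
) -> tuple[ImageVolume, ImageVolume]:
    """An analytic reference dose grid and a shifted/scaled evaluated copy.

    ``edge``: a high-dose plateau that falls off sigmoidally along z (a distal
    edge extruded in 3-D), with the 50% level at the grid's z center.
    ``blob``: an isotropic 3-D Gaussian centered in the grid.  ``ramp``: a
    linear fall-off along z (exactly representable under trilinear
    interpolation, which makes closed-form gamma expectations exact).  The
    evaluated volume is the same analytic field translated by ``shift`` (mm,
    (z, y, x)) and multiplied by ``scale``, so a pure translation is
    represented exactly rather than by resampling; ``eval_pad_mm`` extends the
    evaluated grid beyond the reference along z on both ends, emulating a
    computed dose grid that is larger than the measured one.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if not np.all(np.isfinite(shift)):
        raise ValueError("shift must be finite")
    nz, ny, nx = shape
    dz, dy, dx = spacing
    origin = (0.0, 0.0, 0.0)
    center = ((nz - 1) * dz / 2.0, (ny - 1) * dy / 2.0, (nx - 1) * dx / 2.0)

    def analytic(zc, yc, xc):
        if field_type == "edge":
            return dmax / (1.0 + np.exp((zc - center[0]) / edge_width_mm)) + 0.0 * (yc + xc)
        if field_type == "blob":
            r2 = (zc - center[0]) ** 2 + (yc - center[1]) ** 2 + (xc - center[2]) ** 2
            return dmax * np.exp(-r2 / (2.0 * sigma_mm**2))
        if field_type == "ramp":
            return dmax * (1.0 - zc / ramp_length_mm) + 0.0 * (yc + xc)
        raise ValueError(
            f"unknown field_type {field_type!r}; expected 'edge', 'blob' or 'ramp'"
        )

    def sample(zlo, nz_grid):
        z = (zlo + dz * np.arange(nz_grid))[:, None, None]
        y = (dy * np.arange(ny))[None, :, None]
        x = (dx * np.arange(nx))[None, None, :]
        return z, y, x

    z, y, x = sample(0.0, nz)
    ref = analytic(z, y, x) * np.ones((nz, ny, nx))
    pad = int(np.ceil(eval_pad_mm / dz))
    z_e, y_e, x_e = sample(-pad * dz, nz + 2 * pad)
    ev = scale * analytic(z_e - shift[0], y_e - shift[1], x_e - shift[2]) * np.ones(
        (nz + 2 * pad, ny, nx)
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ref = ref + rng.normal(0.0, noise_sd, ref.shape)
        ev = ev + rng.normal(0.0, noise_sd, ev.shape)
    return (
        ImageVolume(ref, spacing, origin, "DOSE_GY"),
        ImageVolume(ev, spacing, (-pad * dz, 0.0, 0.0), "DOSE_GY"),
    )
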
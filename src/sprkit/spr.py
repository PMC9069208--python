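"""Dual-energy CT path: EAN→I-value mapping, voxelwise Bethe SPR, mass density.

With a dual-layer scanner the reconstruction already delivers relative electron
density (ED) and effective atomic number (EAN) maps, so SPR follows directly
from the Bethe equation once the mean excitation energy is known.  Here I is
predicted from EAN through a piecewise-linear calibration of ln I against
Z_eff, fitted on a reference human-tissue table (one soft-tissue and one bone
segment by default, continuous at the boundary, optionally anchored so water's
Z_eff maps to exactly I_water).

The same (ED, EAN) pair also yields mass density through a quadratic
polynomial in x = (Z_eff / Z_eff,water)^m − 1:

    rho = rho_e * (1 + e0 + e1 * x + e2 * x^2),   m = 3.3 by default,

whose coefficients are refitted on the packaged reference tissue table (the
published coefficient values for this formula are not shipped; users may
override them).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import json
import numpy as np
import pandas as pd

from .materials import (
    DEFAULT_CONSTANTS,
    ElementData,
    MaterialComposition,
    PhysicsConstants,
    WATER,
    bethe_spr,
    effective_atomic_number,
    electron_density,
    i_value_bragg,
)
from .volume import ImageVolume

__all__ = [
    "IvalueMapping",
    "DeedzCoefficients",
    "fit_ivalue_mapping",
    "exact_ivalue_mapping",
    "predict_ivalue",
    "predict_spr_volume",
    "fit_deedz",
    "deedz_reference_frame",
    "mass_density_volume",
]

#: Default soft-tissue / bone boundary of the ln I fit, in Z_eff units.
DEFAULT_ZEFF_BOUNDARIES = (8.0,)


@dataclass(frozen=True)
class IvalueMapping:
    """Piecewise-linear ln I as a function of Z_eff, clamped outside its range.

    ``segments`` are ``(z_low, z_high, slope, intercept)`` with contiguous,
    non-overlapping ranges; evaluation clamps Z_eff to ``clamp_range`` first,
    so out-of-range inputs return the boundary values (metals land on the last
    bone-segment value — the Bethe treatment of metals is approximate anyway).
    """

    segments: tuple[tuple[float, float, float, float], ...]
    clamp_range: tuple[float, float]
    rms_ln_i: float = 0.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("mapping needs at least one segment")
        for (lo, hi, *_), (lo2, hi2, *_) in zip(self.segments, self.segments[1:]):
            if abs(hi - lo2) > 1e-9:
                raise ValueError("mapping segments must be contiguous")
        for lo, hi, a, b in self.segments:
            if hi <= lo:
                raise ValueError("segment ranges must be increasing")
        # Continuity at interior boundaries.
        for (l1, h1, a1, b1), (l2, h2, a2, b2) in zip(self.segments, self.segments[1:]):
            left = a1 * h1 + b1
            right = a2 * l2 + b2
            if abs(left - right) > 1e-9 * max(1.0, abs(left)):
                raise ValueError(f"mapping discontinuous at z_eff = {h1}")

    def ln_i(self, z_eff):
        z = np.clip(np.asarray(z_eff, dtype=float), *self.clamp_range)
        bounds = [seg[1] for seg in self.segments[:-1]]
        idx = np.searchsorted(bounds, z, side="right")
        slopes = np.array([s[2] for s in self.segments])
        intercepts = np.array([s[3] for s in self.segments])
        return slopes[idx] * z + intercepts[idx]

    def __call__(self, z_eff):
        out = np.exp(self.ln_i(z_eff))
        return float(out) if out.ndim == 0 else out


def predict_ivalue(z_eff, mapping: IvalueMapping):
    """Predicted mean excitation energy (eV) at the given Z_eff."""
    return mapping(z_eff)


def _tissue_points(
    tissues: Iterable[MaterialComposition],
    elements: Mapping[str, ElementData],
    exponent: float,
) -> pd.DataFrame:
    rows = [
        (
            t.name,
            effective_atomic_number(t, elements, exponent),
            np.log(i_value_bragg(t, elements)),
        )
        for t in tissues
    ]
    return pd.DataFrame(rows, columns=["name", "z_eff", "ln_i"]).sort_values("z_eff")


def fit_ivalue_mapping(
    tissues: Iterable[MaterialComposition],
    elements: Mapping[str, ElementData],
    boundaries: Sequence[float] = DEFAULT_ZEFF_BOUNDARIES,
    exponent: float = DEFAULT_CONSTANTS.zeff_exponent,
    water_anchor: bool = True,
    i_water: float = DEFAULT_CONSTANTS.I_water,
    water: MaterialComposition = WATER,
) -> IvalueMapping:
    """Fit the piecewise-linear ln I(Z_eff) calibration on reference tissues.

    Each segment gets an ordinary least-squares line of ln I on Z_eff (at
    least two tissues per segment required).  Slopes are kept and intercepts
    are then chained outward from the anchor segment (the one containing
    water's Z_eff) to make the mapping continuous at the boundaries.  With
    ``water_anchor`` the anchor segment is additionally shifted so that
    exactly ``i_water`` is returned at water's Z_eff — the convention that
    pins SPR(water) = 1.
    """
    pts = _tissue_points(tissues, elements, exponent)
    boundaries = sorted(float(b) for b in boundaries)
    edges = [-np.inf] + boundaries + [np.inf]
    fits = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        seg = pts[(pts["z_eff"] >= lo) & (pts["z_eff"] < hi)]
        if len(seg) < 2:
            raise ValueError(
                f"segment ({lo}, {hi}) has {len(seg)} tissue(s); need at least 2"
            )
        slope, intercept = np.polyfit(seg["z_eff"], seg["ln_i"], 1)
        fits.append([lo, hi, float(slope), float(intercept)])

    try:
        z_w = effective_atomic_number(water, elements, exponent)
    except KeyError:
        if water_anchor:
            raise
        # element table lacks water's constituents; anchor on the first segment
        z_w = -np.inf
    anchor = bisect_right(boundaries, z_w)
    if water_anchor:
        a, b = fits[anchor][2], fits[anchor][3]
        fits[anchor][3] = b + (np.log(i_water) - (a * z_w + b))
    # Chain intercepts outward from the anchor segment for continuity.
    for i in range(anchor + 1, len(fits)):
        t = boundaries[i - 1]
        prev_val = fits[i - 1][2] * t + fits[i - 1][3]
        fits[i][3] = prev_val - fits[i][2] * t
    for i in range(anchor - 1, -1, -1):
        t = boundaries[i]
        next_val = fits[i + 1][2] * t + fits[i + 1][3]
        fits[i][3] = next_val - fits[i][2] * t

    z_min, z_max = float(pts["z_eff"].min()), float(pts["z_eff"].max())
    segments = []
    for (lo, hi, a, b) in fits:
        lo = z_min if not np.isfinite(lo) else lo
        hi = z_max if not np.isfinite(hi) else hi
        segments.append((lo, hi, a, b))
    mapping = IvalueMapping(tuple(segments), (z_min, z_max))
    resid = mapping.ln_i(pts["z_eff"].to_numpy()) - pts["ln_i"].to_numpy()
    return IvalueMapping(mapping.segments, mapping.clamp_range, float(np.sqrt(np.mean(resid**2))))


def exact_ivalue_mapping(
    materials: Iterable[MaterialComposition],
    elements: Mapping[str, ElementData],
    exponent: float = DEFAULT_CONSTANTS.zeff_exponent,
) -> IvalueMapping:
    """Piecewise-linear interpolation through the materials' own (Z_eff, ln I).

    The self-consistent mapping: evaluated at any of the given materials'
    Z_eff it returns that material's Bragg-additivity I-value exactly, so a
    noise-free synthetic phantom is recovered identically by the prediction
    chain.  Materials sharing one Z_eff but different I-values cannot be
    interpolated and raise.
    """
    pts = _tissue_points(materials, elements, exponent)
    z = pts["z_eff"].to_numpy()
    ln_i = pts["ln_i"].to_numpy()
    keep_z: list[float] = []
    keep_y: list[float] = []
    for zi, yi in zip(z, ln_i):
        if keep_z and abs(zi - keep_z[-1]) < 1e-9:
            if abs(yi - keep_y[-1]) > 1e-9:
                raise ValueError(
                    f"two materials share Z_eff = {zi:.6f} with different I-values"
                )
            continue
        keep_z.append(float(zi))
        keep_y.append(float(yi))
    if len(keep_z) < 2:
        raise ValueError("need at least two distinct Z_eff points")
    segments = []
    for z0, z1, y0, y1 in zip(keep_z[:-1], keep_z[1:], keep_y[:-1], keep_y[1:]):
        a = (y1 - y0) / (z1 - z0)
        segments.append((z0, z1, a, y0 - a * z0))
    return IvalueMapping(tuple(segments), (keep_z[0], keep_z[-1]))


def predict_spr_volume(
    ed: ImageVolume,
    ean: ImageVolume,
    mapping: IvalueMapping,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
    air_ed_threshold: float = 0.05,
    air_spr: float = 1e-3,
) -> ImageVolume:
    """Voxelwise Bethe SPR from ED and EAN volumes sharing one grid.

    Voxels with ED below ``air_ed_threshold`` are set to ``air_spr`` instead
    of being pushed through the Bethe logarithms.
    """
    ed.require_semantic("ED")
    ean.require_semantic("EAN")
    ed.require_grid_match(ean)
    i_map = mapping(ean.values)
    spr = bethe_spr(np.maximum(ed.values, 0.0), i_map, constants)
    spr = np.where(ed.values < air_ed_threshold, air_spr, spr)
    return ed.with_values(spr, "SPR")


@dataclass(frozen=True)
class DeedzCoefficients:
    """Coefficients of the ED/EAN-based mass-density polynomial."""

    e0: float
    e1: float
    e2: float
    m: float = DEFAULT_CONSTANTS.zeff_exponent
    z_eff_w: float = 7.477

    def __post_init__(self) -> None:
        if self.m <= 0 or self.z_eff_w <= 0:
            raise ValueError("m and z_eff_w must be positive")

    def density(self, rho_e, z_eff):
        x = (np.asarray(z_eff, dtype=float) / self.z_eff_w) ** self.m - 1.0
        rho_e = np.asarray(rho_e, dtype=float)
        out = rho_e * (1.0 + self.e0 + self.e1 * x + self.e2 * x**2)
        return float(out) if out.ndim == 0 else out

    def to_json(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(
            json.dumps(
                {"schema": "sprkit.deedz/1", "e": [self.e0, self.e1, self.e2],
                 "m": self.m, "z_eff_w": self.z_eff_w},
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path) -> "DeedzCoefficients":
        from pathlib import Path

        d = json.loads(Path(path).read_text())
        return cls(*d["e"], m=d["m"], z_eff_w=d["z_eff_w"])


def deedz_reference_frame(
    tissues: Iterable[MaterialComposition],
    elements: Mapping[str, ElementData],
    exponent: float = DEFAULT_CONSTANTS.zeff_exponent,
) -> pd.DataFrame:
    """(rho_e, z_eff, rho) of reference tissues, the input to :func:`fit_deedz`."""
    rows = [
        (
            t.name,
            electron_density(t, elements),
            effective_atomic_number(t, elements, exponent),
            t.rho,
        )
        for t in tissues
    ]
    return pd.DataFrame(rows, columns=["name", "rho_e", "z_eff", "rho"])


def fit_deedz(
    reference: pd.DataFrame,
    m: float = DEFAULT_CONSTANTS.zeff_exponent,
    z_eff_w: float | None = None,
    elements: Mapping[str, ElementData] | None = None,
) -> DeedzCoefficients:
    """Least-squares fit of (rho/rho_e − 1) on powers 0..2 of x.

    ``reference`` needs columns ``rho_e``, ``z_eff``, ``rho`` (see
    :func:`deedz_reference_frame`); the set should span soft tissue and bone
    so the quadratic design has full rank.
    """
    if len(reference) < 3:
        raise ValueError("need at least three reference tissues")
    if z_eff_w is None:
        if elements is None:
            raise ValueError("pass z_eff_w or an element table to derive it from water")
        z_eff_w = effective_atomic_number(WATER, elements, m)
    x = (reference["z_eff"].to_numpy() / z_eff_w) ** m - 1.0
    y = reference["rho"].to_numpy() / reference["rho_e"].to_numpy() - 1.0
    A = np.column_stack([np.ones_like(x), x, x**2])
    if np.linalg.matrix_rank(A, tol=1e-12 * max(1.0, np.abs(A).max())) < 3:
        raise ValueError(
            "rank-deficient design: reference tissues must span soft tissue and bone"
        )
    e, *_ = np.linalg.lstsq(A, y, rcond=None)
    return DeedzCoefficients(float(e[0]), float(e[1]), float(e[2]), m, float(z_eff_w))


def mass_density_volume(
    ed: ImageVolume, ean: ImageVolume, coeffs: DeedzCoefficients
) -> ImageVolume:
    """Voxelwise mass-density map (g/cm^3) from ED and EAN volumes."""
    ed.require_semantic("ED")
    ean.require_semantic("EAN")
    ed.require_grid_match(ean)
    rho = coeffs.density(ed.values, ean.values)
    return ed.with_values(rho, "MASS_DENSITY")
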
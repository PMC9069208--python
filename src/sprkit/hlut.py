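"""Single-energy CT path: stoichiometric CT-number model and HLUT conversion.

The forward model is the classic two-parameter stoichiometric parametrization
of the relative photon attenuation of a mixture at a given tube voltage:

    u = rho_e * (k1 * Zt^3.62 + k2 * Zh^1.86 + 1) / (same evaluated for water)

where ``Zt`` and ``Zh`` are electron-fraction power means of Z with exponents
3.62 (photoelectric) and 1.86 (coherent scatter), ``k1``/``k2`` weight the
photoelectric and coherent contributions against Klein–Nishina scattering, and
CTN = 1000 * (u - 1) HU.  ``k1`` and ``k2`` are calibrated by least squares
from (composition, measured CTN) pairs; a Hounsfield look-up table (HLUT) is
then built by evaluating theoretical CTN and Bethe SPR for a set of reference
tissues and fitting a continuous piecewise-linear CTN→SPR curve with knots at
configurable segment boundaries (air / lung / soft tissue / bone).

Reference-tissue I-values use Bragg additivity, not the dual-energy EAN→I
mapping, which keeps this calibration independent of the dual-energy path.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .materials import (
    DEFAULT_CONSTANTS,
    ElementData,
    MaterialComposition,
    PhysicsConstants,
    WATER,
    bethe_spr,
    electron_density,
    electron_weighted_power_mean,
    i_value_bragg,
)
from .volume import ImageVolume

__all__ = [
    "AttenuationFit",
    "reference_attenuation_fit",
    "Hlut",
    "theoretical_ctn",
    "fit_attenuation",
    "build_hlut",
    "convert_ctn_volume",
    "make_ctn_degenerate_pair",
    "DEFAULT_EXPONENTS",
    "DEFAULT_SEGMENT_BOUNDARIES",
]

#: (photoelectric, coherent) power-mean exponents of the two-parameter model.
DEFAULT_EXPONENTS = (3.62, 1.86)

#: Interior CTN knots of the default HLUT segmentation: air/lung at -950 HU,
#: lung/soft at -120 HU, soft/bone at +100 HU.
DEFAULT_SEGMENT_BOUNDARIES = (-950.0, -120.0, 100.0)

#: Representative 120 kVp weights of the forward model, set so typical
#: materials land at their familiar CT numbers (water 0 HU, soft tissue within
#: about +-100 HU, cortical-bone surrogate near +1700 HU); used when no
#: measured calibration pairs exist.
REFERENCE_K1_120KVP = 5.0e-5
REFERENCE_K2_120KVP = 6.0e-4


def reference_attenuation_fit(elements) -> "AttenuationFit":
    """The packaged representative 120 kVp forward-model calibration."""
    return AttenuationFit(REFERENCE_K1_120KVP, REFERENCE_K2_120KVP).for_water(elements)


@dataclass(frozen=True)
class AttenuationFit:
    """Calibrated weights of the two-parameter stoichiometric CTN model."""

    k1: float
    k2: float
    exponents: tuple[float, float] = DEFAULT_EXPONENTS
    z_pe_w: float = 0.0  # water power means, filled on construction
    z_coh_w: float = 0.0

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("k1 and k2 must be non-negative")

    @property
    def water_norm(self) -> float:
        return (
            self.k1 * self.z_pe_w ** self.exponents[0]
            + self.k2 * self.z_coh_w ** self.exponents[1]
            + 1.0
        )

    def for_water(
        self, elements: Mapping[str, ElementData], water: MaterialComposition = WATER
    ) -> "AttenuationFit":
        """A copy with the water power means filled in from an element table."""
        return AttenuationFit(
            self.k1,
            self.k2,
            self.exponents,
            electron_weighted_power_mean(water, elements, self.exponents[0]),
            electron_weighted_power_mean(water, elements, self.exponents[1]),
        )


def _relative_attenuation(rho_e: float, z_pe: float, z_coh: float, fit: AttenuationFit) -> float:
    p, q = fit.exponents
    return rho_e * (fit.k1 * z_pe**p + fit.k2 * z_coh**q + 1.0) / fit.water_norm


def theoretical_ctn(
    comp: MaterialComposition,
    elements: Mapping[str, ElementData],
    fit: AttenuationFit,
) -> float:
    """Theoretical CT number (HU) of a composition under a calibrated fit."""
    if fit.z_pe_w <= 0 or fit.z_coh_w <= 0:
        fit = fit.for_water(elements)
    rho_e = electron_density(comp, elements)
    z_pe = electron_weighted_power_mean(comp, elements, fit.exponents[0])
    z_coh = electron_weighted_power_mean(comp, elements, fit.exponents[1])
    return 1000.0 * (_relative_attenuation(rho_e, z_pe, z_coh, fit) - 1.0)


def fit_attenuation(
    calibration: Sequence[tuple[MaterialComposition, float]],
    elements: Mapping[str, ElementData],
    exponents: tuple[float, float] = DEFAULT_EXPONENTS,
) -> AttenuationFit:
    """Calibrate (k1, k2) from (composition, measured CTN in HU) pairs.

    The model is linearized exactly: with u = 1 + CTN/1000,

        k1 * (rho_e Zt^p - u Zt_w^p) + k2 * (rho_e Zh^q - u Zh_w^q) = u - rho_e

    and solved by least squares; negative solutions are clipped to the
    non-negative orthant (via NNLS) with a warning.  Requires at least two
    materials with distinct power means (e.g. one soft and one bone-like).
    """
    if len(calibration) < 2:
        raise ValueError("need at least two calibration materials")
    p, q = exponents
    z_pe_w = electron_weighted_power_mean(WATER, elements, p)
    z_coh_w = electron_weighted_power_mean(WATER, elements, q)
    A = np.zeros((len(calibration), 2))
    b = np.zeros(len(calibration))
    for i, (comp, ctn) in enumerate(calibration):
        u = 1.0 + ctn / 1000.0
        rho_e = electron_density(comp, elements)
        z_pe = electron_weighted_power_mean(comp, elements, p)
        z_coh = electron_weighted_power_mean(comp, elements, q)
        A[i] = (rho_e * z_pe**p - u * z_pe_w**p, rho_e * z_coh**q - u * z_coh_w**q)
        b[i] = u - rho_e
    if np.linalg.matrix_rank(A, tol=1e-10 * max(1.0, np.abs(A).max())) < 2:
        raise ValueError(
            "degenerate calibration design: materials do not span distinct "
            "photoelectric/coherent power means (add a bone-like material)"
        )
    k, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.any(k < 0):
        warnings.warn(
            f"least-squares attenuation weights {k} outside the physical "
            "non-negative range; re-solving with a non-negativity constraint",
            stacklevel=2,
        )
        k, _ = nnls(A, b)
    return AttenuationFit(float(k[0]), float(k[1]), exponents, z_pe_w, z_coh_w)


@dataclass(frozen=True)
class Hlut:
    """Monotone piecewise-linear CTN→SPR curve with flat end extrapolation."""

    nodes: tuple[tuple[float, float], ...]
    segment_labels: tuple[str, ...] = ()
    fit_residuals: pd.DataFrame | None = None
    water_crossing_hu: float | None = None

    def __post_init__(self) -> None:
        ctn = np.array([n[0] for n in self.nodes])
        spr = np.array([n[1] for n in self.nodes])
        if len(ctn) < 2:
            raise ValueError("an HLUT needs at least two nodes")
        if np.any(np.diff(ctn) <= 0):
            raise ValueError("HLUT node CT numbers must be strictly increasing")
        if np.any(spr < 0):
            raise ValueError("HLUT SPR nodes must be non-negative")

    def __call__(self, ctn):
        xs = np.array([n[0] for n in self.nodes])
        ys = np.array([n[1] for n in self.nodes])
        out = np.interp(np.asarray(ctn, dtype=float), xs, ys)
        return float(out) if out.ndim == 0 else out

    def to_csv(self, path, metadata: dict | None = None) -> None:
        """Two-column CSV (HU, SPR) plus a JSON metadata sidecar."""
        path = Path(path)
        pd.DataFrame(self.nodes, columns=["hu", "spr"]).to_csv(path, index=False)
        meta = {"segment_labels": list(self.segment_labels)}
        if self.water_crossing_hu is not None:
            meta["water_crossing_hu"] = self.water_crossing_hu
        meta.update(metadata or {})
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path) -> "Hlut":
        path = Path(path)
        df = pd.read_csv(path)
        meta_path = path.with_suffix(path.suffix + ".json")
        labels: tuple[str, ...] = ()
        if meta_path.exists():
            labels = tuple(json.loads(meta_path.read_text()).get("segment_labels", []))
        return cls(tuple(zip(df["hu"], df["spr"])), labels)


def _linear_spline_fit(x: np.ndarray, y: np.ndarray, knots: Sequence[float]):
    """Least-squares continuous linear spline; returns an evaluator."""
    cols = [np.ones_like(x), x] + [np.maximum(x - t, 0.0) for t in knots]
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)

    def evaluate(xq):
        xq = np.asarray(xq, dtype=float)
        out = coef[0] + coef[1] * xq
        for c, t in zip(coef[2:], knots):
            out = out + c * np.maximum(xq - t, 0.0)
        return out

    return evaluate


def build_hlut(
    fit: AttenuationFit,
    tissues: Iterable[MaterialComposition],
    elements: Mapping[str, ElementData],
    boundaries: Sequence[float] = DEFAULT_SEGMENT_BOUNDARIES,
    air_node: tuple[float, float] = (-1000.0, 1e-3),
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> Hlut:
    """Build an HLUT from reference tissues under a calibrated CTN model.

    For each tissue the theoretical CTN and the Bethe SPR (Bragg-additivity
    I-value) are computed; a continuous piecewise-linear curve with knots at
    ``boundaries`` is fitted by least squares, an air node is prepended, and
    per-tissue fit residuals (predicted − true SPR) are attached for
    closed-loop checks.  Knots outside the span of the tissue CT numbers are
    kept as nodes on the extrapolated first/last linear piece.
    """
    tissues = list(tissues)
    if len(tissues) < 2:
        raise ValueError("need at least two reference tissues to build an HLUT")
    pts = []
    for comp in tissues:
        ctn = theoretical_ctn(comp, elements, fit)
        spr = bethe_spr(
            electron_density(comp, elements), i_value_bragg(comp, elements), constants
        )
        pts.append((comp.name, ctn, spr))
    df = pd.DataFrame(pts, columns=["name", "ctn", "spr_true"]).sort_values("ctn")
    x = df["ctn"].to_numpy()
    y = df["spr_true"].to_numpy()

    boundaries = sorted(float(b) for b in boundaries)
    if len(boundaries) == 0:
        raise ValueError("need at least one segment boundary")
    interior = [t for t in boundaries if x.min() < t < x.max()]
    spline = _linear_spline_fit(x, y, interior)

    node_x = [t for t in boundaries if t > air_node[0]] + [float(x.max())]
    node_x = sorted(set(node_x))
    nodes = [(float(air_node[0]), float(air_node[1]))]
    nodes += [(float(t), float(spline(t))) for t in node_x]
    labels = ("air", "lung", "soft", "bone")[: len(nodes) - 1]

    df["spr_fit"] = spline(x)
    df["residual"] = df["spr_fit"] - df["spr_true"]

    hlut = Hlut(tuple(nodes), labels, df.reset_index(drop=True))
    # Where does the curve cross SPR = 1 (the water level)?
    xs = np.array([n[0] for n in hlut.nodes])
    ys = np.array([n[1] for n in hlut.nodes])
    crossing = None
    above = ys >= 1.0
    if above.any() and (~above).any():
        i = int(np.argmax(above))
        if i > 0:
            x0, x1, y0, y1 = xs[i - 1], xs[i], ys[i - 1], ys[i]
            crossing = float(x0 + (1.0 - y0) / (y1 - y0) * (x1 - x0))
    return Hlut(hlut.nodes, hlut.segment_labels, hlut.fit_residuals, crossing)


def convert_ctn_volume(hu: ImageVolume, hlut: Hlut) -> ImageVolume:
    """Voxelwise piecewise-linear HU→SPR conversion with flat extrapolation."""
    hu.require_semantic("HU")
    return hu.with_values(hlut(hu.values), "SPR")


def make_ctn_degenerate_pair(
    base_a: MaterialComposition,
    base_b: MaterialComposition,
    elements: Mapping[str, ElementData],
    fit: AttenuationFit,
) -> tuple[MaterialComposition, MaterialComposition]:
    """Two materials with equal theoretical CTN but different (rho_e, Z_eff).

    Keeps ``base_a`` as-is and rescales the bulk density of ``base_b`` so that
    its theoretical CT number matches — the classic degeneracy a single CT
    number cannot resolve, while the dual-energy (ED, EAN) pair can.
    """
    if fit.z_pe_w <= 0 or fit.z_coh_w <= 0:
        fit = fit.for_water(elements)
    ctn_a = theoretical_ctn(base_a, elements, fit)
    ctn_b = theoretical_ctn(base_b, elements, fit)
    # CTN is linear in bulk density through rho_e.
    u_a = 1.0 + ctn_a / 1000.0
    u_b = 1.0 + ctn_b / 1000.0
    rho_new = base_b.rho * u_a / u_b
    adjusted = MaterialComposition(
        base_b.name + "_ctn_matched", dict(base_b.fractions), rho_new, base_b.category
    )
    return base_a, adjusted
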
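"""Composition-based radiological physics.

This module turns elemental compositions into the quantities particle-therapy
treatment planning cares about: relative electron density (ED, water = 1),
effective atomic number (EAN, an electron-fraction power mean), mean excitation
energy (I-value, via Bragg additivity in the log domain), and the stopping-power
ratio relative to water (SPR) from the Bethe equation without higher-order
correction terms (shell, density-effect, Barkas).

It also ships the reference tables used everywhere else in the package: an
elemental table (Z, A, I) and a material table with water, air, tissue-surrogate
phantom inserts, implant materials, and reference human tissues for calibration.
The shipped compositions are representative published values (synthetic
fixtures); every downstream "ground truth" is computed from them
self-consistently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ElementData",
    "MaterialComposition",
    "PhysicsConstants",
    "MaterialProperties",
    "MaterialLibrary",
    "DEFAULT_CONSTANTS",
    "electron_fractions",
    "electron_density",
    "effective_atomic_number",
    "electron_weighted_power_mean",
    "i_value_bragg",
    "beta_squared",
    "stopping_number",
    "bethe_spr",
    "material_properties",
    "load_material_tables",
    "default_library",
]

MATERIAL_CATEGORIES = frozenset(
    {"tissue_surrogate", "reference_human_tissue", "implant", "phantom_body", "water", "air"}
)


@dataclass(frozen=True)
class ElementData:
    """One chemical element: atomic number, molar mass (g/mol), I-value (eV)."""

    symbol: str
    Z: int
    A: float
    I_elem: float

    def __post_init__(self) -> None:
        if self.Z < 1:
            raise ValueError(f"element {self.symbol}: Z must be >= 1, got {self.Z}")
        if self.A <= 0:
            raise ValueError(f"element {self.symbol}: A must be positive, got {self.A}")
        if self.I_elem <= 0:
            raise ValueError(f"element {self.symbol}: I_elem must be positive, got {self.I_elem}")


@dataclass(frozen=True)
class MaterialComposition:
    """A bulk material: elemental mass fractions plus mass density (g/cm^3)."""

    name: str
    fractions: Mapping[str, float]
    rho: float
    category: str = "tissue_surrogate"

    def __post_init__(self) -> None:
        if self.category not in MATERIAL_CATEGORIES:
            raise ValueError(
                f"material {self.name!r}: unknown category {self.category!r}; "
                f"expected one of {sorted(MATERIAL_CATEGORIES)}"
            )
        if not self.fractions:
            raise ValueError(f"material {self.name!r}: empty composition")
        total = float(sum(self.fractions.values()))
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"material {self.name!r}: mass fractions sum to {total:.8f}, expected 1"
            )
        if self.category == "air":
            if self.rho < 0:
                raise ValueError(f"material {self.name!r}: rho must be >= 0")
        elif self.rho <= 0:
            raise ValueError(f"material {self.name!r}: rho must be positive, got {self.rho}")


#: Reference liquid water used for ED normalization and water anchoring.
WATER = MaterialComposition("water", {"H": 0.1119, "O": 0.8881}, 1.000, "water")


@dataclass(frozen=True)
class PhysicsConstants:
    """Constants of the Bethe SPR evaluation.

    me_c2 is in eV; I_water in eV; T_per_u and m_nucleon_c2 in MeV.  The EAN
    power-law exponent defaults to 3.3, matching the exponent of the
    ED/EAN-based mass-density formula, and must be used consistently between
    synthesis and prediction.  The nucleon rest energy defaults to the proton
    value for all ion species.
    """

    me_c2: float = 0.51099895e6
    I_water: float = 78.73
    T_per_u: float = 100.0
    m_nucleon_c2: float = 938.272
    zeff_exponent: float = 3.3

    def __post_init__(self) -> None:
        for name in ("me_c2", "I_water", "T_per_u", "m_nucleon_c2", "zeff_exponent"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PhysicsConstants.{name} must be strictly positive")


DEFAULT_CONSTANTS = PhysicsConstants()


@dataclass(frozen=True)
class MaterialProperties:
    """Derived radiological properties of one material."""

    name: str
    rho: float
    rho_e: float
    z_eff: float
    i_value: float
    spr: float


def _resolve(symbols: Iterable[str], elements: Mapping[str, ElementData]) -> None:
    for sym in symbols:
        if sym not in elements:
            raise KeyError(f"unknown element symbol {sym!r} (not in element table)")


def electron_fractions(
    comp: MaterialComposition, elements: Mapping[str, ElementData]
) -> dict[str, float]:
    """Relative electron contributions lambda_i = w_i * Z_i / A_i per element."""
    _resolve(comp.fractions, elements)
    return {s: w * elements[s].Z / elements[s].A for s, w in comp.fractions.items()}


def _electrons_per_gram(comp: MaterialComposition, elements: Mapping[str, ElementData]) -> float:
    return float(sum(electron_fractions(comp, elements).values()))


def electron_density(
    comp: MaterialComposition,
    elements: Mapping[str, ElementData],
    water: MaterialComposition = WATER,
) -> float:
    """Relative electron density rho_e = rho * sum(w_i Z_i / A_i), water = 1."""
    num = comp.rho * _electrons_per_gram(comp, elements)
    den = water.rho * _electrons_per_gram(water, elements)
    return num / den


def electron_weighted_power_mean(
    comp: MaterialComposition, elements: Mapping[str, ElementData], exponent: float
) -> float:
    """Electron-fraction power mean (sum lam_i Z_i^p / sum lam_i)^(1/p)."""
    if exponent <= 0:
        raise ValueError(f"exponent must be positive, got {exponent}")
    lam = electron_fractions(comp, elements)
    total = sum(lam.values())
    s = sum(l * elements[sym].Z ** exponent for sym, l in lam.items())
    return (s / total) ** (1.0 / exponent)


def effective_atomic_number(
    comp: MaterialComposition,
    elements: Mapping[str, ElementData],
    exponent: float = DEFAULT_CONSTANTS.zeff_exponent,
) -> float:
    """Effective atomic number as electron-fraction power mean of Z."""
    return electron_weighted_power_mean(comp, elements, exponent)


def i_value_bragg(comp: MaterialComposition, elements: Mapping[str, ElementData]) -> float:
    """Mean excitation energy via Bragg additivity, ln I = sum lam ln I_i / sum lam."""
    lam = electron_fractions(comp, elements)
    total = sum(lam.values())
    ln_i = sum(l * math.log(elements[sym].I_elem) for sym, l in lam.items()) / total
    return math.exp(ln_i)


def beta_squared(
    T_per_u: float, m_nucleon_c2: float = DEFAULT_CONSTANTS.m_nucleon_c2
) -> float:
    """Relativistic beta^2 at kinetic energy T per nucleon (both MeV)."""
    if T_per_u <= 0:
        raise ValueError(f"kinetic energy per nucleon must be positive, got {T_per_u}")
    gamma_inv = m_nucleon_c2 / (T_per_u + m_nucleon_c2)
    return 1.0 - gamma_inv * gamma_inv


def stopping_number(i_value_ev, constants: PhysicsConstants = DEFAULT_CONSTANTS):
    """Bethe stopping number L(I) = ln(2 me c^2 b^2 / (1 - b^2)) - ln I - b^2."""
    b2 = beta_squared(constants.T_per_u, constants.m_nucleon_c2)
    return np.log(2.0 * constants.me_c2 * b2 / (1.0 - b2)) - np.log(i_value_ev) - b2


def bethe_spr(rho_e, i_value, constants: PhysicsConstants = DEFAULT_CONSTANTS):
    """Stopping-power ratio relative to water from the Bethe equation.

    SPR = rho_e * L(I) / L(I_water), neglecting higher-order correction terms.
    Accepts scalars or arrays (broadcast).  Raises if the stopping number is
    non-positive anywhere (unphysically large I at the working energy).
    """
    rho_e = np.asarray(rho_e, dtype=float)
    i_value = np.asarray(i_value, dtype=float)
    if np.any(i_value <= 0):
        raise ValueError("i_value must be strictly positive")
    if np.any(rho_e < 0):
        raise ValueError("rho_e must be non-negative")
    L = stopping_number(i_value, constants)
    L_w = float(stopping_number(constants.I_water, constants))
    if L_w <= 0 or np.any(L <= 0):
        raise ValueError(
            "non-positive Bethe stopping number: I-value too large for "
            f"T = {constants.T_per_u} MeV/u"
        )
    out = rho_e * L / L_w
    return float(out) if out.ndim == 0 else out


def material_properties(
    comp: MaterialComposition,
    elements: Mapping[str, ElementData],
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> MaterialProperties:
    """All derived properties of one material at the working energy."""
    rho_e = electron_density(comp, elements)
    z_eff = effective_atomic_number(comp, elements, constants.zeff_exponent)
    i_val = i_value_bragg(comp, elements)
    spr = bethe_spr(rho_e, i_val, constants)
    return MaterialProperties(comp.name, comp.rho, rho_e, z_eff, i_val, spr)


@dataclass(frozen=True)
class MaterialLibrary:
    """Element table plus material table, with convenience lookups."""

    elements: Mapping[str, ElementData]
    materials: Mapping[str, MaterialComposition]

    def __getitem__(self, name: str) -> MaterialComposition:
        try:
            return self.materials[name]
        except KeyError:
            raise KeyError(
                f"unknown material {name!r}; available: {sorted(self.materials)}"
            ) from None

    def by_category(self, category: str) -> list[MaterialComposition]:
        return [m for m in self.materials.values() if m.category == category]

    def properties(
        self, name: str, constants: PhysicsConstants = DEFAULT_CONSTANTS
    ) -> MaterialProperties:
        return material_properties(self[name], self.elements, constants)

    def properties_frame(
        self,
        names: Iterable[str] | None = None,
        constants: PhysicsConstants = DEFAULT_CONSTANTS,
    ) -> pd.DataFrame:
        """Properties of several materials as a DataFrame indexed by name."""
        names = list(names) if names is not None else sorted(self.materials)
        rows = [self.properties(n, constants) for n in names]
        return pd.DataFrame(
            {
                "name": [r.name for r in rows],
                "rho": [r.rho for r in rows],
                "rho_e": [r.rho_e for r in rows],
                "z_eff": [r.z_eff for r in rows],
                "i_value": [r.i_value for r in rows],
                "spr": [r.spr for r in rows],
            }
        ).set_index("name")


def _read_elements_csv(path) -> dict[str, ElementData]:
    df = pd.read_csv(path, comment="#")
    required = {"symbol", "Z", "A_g_mol", "I_eV"}
    if not required.issubset(df.columns):
        raise ValueError(f"element table must have columns {sorted(required)}")
    out: dict[str, ElementData] = {}
    for i, row in df.iterrows():
        sym = str(row["symbol"])
        if sym in out:
            raise ValueError(f"element table row {i}: duplicate symbol {sym!r}")
        try:
            out[sym] = ElementData(sym, int(row["Z"]), float(row["A_g_mol"]), float(row["I_eV"]))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"element table row {i}: {exc}") from exc
    return out


def _read_materials_csv(path) -> dict[str, MaterialComposition]:
    df = pd.read_csv(path, comment="#")
    required = {"name", "category", "rho_g_cm3", "element", "fraction"}
    if not required.issubset(df.columns):
        raise ValueError(f"material table must have columns {sorted(required)}")
    out: dict[str, MaterialComposition] = {}
    for name, grp in df.groupby("name", sort=False):
        cats = grp["category"].unique()
        rhos = grp["rho_g_cm3"].unique()
        if len(cats) != 1 or len(rhos) != 1:
            raise ValueError(f"material {name!r}: inconsistent category/density rows")
        fractions = {}
        for i, row in grp.iterrows():
            sym = str(row["element"])
            if sym in fractions:
                raise ValueError(f"material table row {i}: duplicate element {sym!r} in {name!r}")
            fractions[sym] = float(row["fraction"])
        try:
            out[str(name)] = MaterialComposition(str(name), fractions, float(rhos[0]), str(cats[0]))
        except ValueError as exc:
            raise ValueError(f"material table rows for {name!r}: {exc}") from exc
    return out


def _anchor_ivalues(
    elements: dict[str, ElementData], water: MaterialComposition, i_water: float
) -> dict[str, ElementData]:
    # Uniform log-shift of elemental I so Bragg additivity reproduces I_water for
    # the packaged water composition (condensed-phase anchoring).
    raw = i_value_bragg(water, elements)
    factor = i_water / raw
    return {s: replace(e, I_elem=e.I_elem * factor) for s, e in elements.items()}


def load_material_tables(
    elements_path=None,
    materials_path=None,
    anchor_water_ivalue: float | None = DEFAULT_CONSTANTS.I_water,
):
    """Load the element and material tables (packaged defaults if paths omitted).

    When ``anchor_water_ivalue`` is set (default 78.73 eV) the elemental
    I-values are rescaled by one common factor so Bragg additivity on the
    table's water composition returns exactly that value; pass ``None`` for the
    raw tabulated gas-phase I-values.

    Returns ``(elements, materials)`` as dictionaries keyed by symbol/name.
    """
    pkg_data = resources.files("sprkit") / "data"
    elements = _read_elements_csv(elements_path or (pkg_data / "elements.csv"))
    materials = _read_materials_csv(materials_path or (pkg_data / "materials.csv"))
    for mat in materials.values():
        _resolve(mat.fractions, elements)
    if anchor_water_ivalue is not None:
        water = materials.get("water", WATER)
        elements = _anchor_ivalues(elements, water, anchor_water_ivalue)
    return elements, materials


def default_library(anchor_water_ivalue: float | None = DEFAULT_CONSTANTS.I_water) -> MaterialLibrary:
    """The packaged element + material tables as a :class:`MaterialLibrary`."""
    elements, materials = load_material_tables(anchor_water_ivalue=anchor_water_ivalue)
    return MaterialLibrary(elements, materials)
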
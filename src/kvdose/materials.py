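"""Photon interaction data, material definitions, and HU segmentation.

The packaged element tables (``data/elements/*.csv``, 5-150 keV at 1 keV
spacing) carry photoelectric, coherent and incoherent mass attenuation
coefficients plus the mass energy-absorption coefficient for every element
appearing in the tissue, bone, air, acrylic and aluminum mixtures used in
kV dosimetry.  They are produced once by ``scripts/generate_xs_table.py``
from a semi-empirical photoatomic parameterization calibrated to standard
reference attenuation data; see that script and ``docs/methods.md``.

Coefficients are queried by log-log interpolation, mixtures follow the
mass-fraction additivity rule, and collision kerma per unit fluence is
``E * (mu_en/rho)`` under the local electron-absorption assumption valid at
kilovoltage energies (electron ranges of micrometers).

HU-to-material conversion is rule-based: an ordered list of half-open HU
ranges with first-match precedence, plus a nearest-boundary policy for HU
values that no rule covers.  Presets reproduce the anthropomorphic pelvis,
thorax and head conversion tables and an idealized acrylic-cylinder scheme.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np

__all__ = [
    "CrossSectionTable",
    "Material",
    "SegmentationScheme",
    "MuValue",
    "COMPONENTS",
    "mixture_mu",
    "kerma_per_fluence",
    "hu_to_material",
    "get_material",
    "get_scheme",
    "MATERIALS",
]

_DATA_DIR = Path(__file__).parent / "data" / "elements"

#: joules per keV, times 1000 g/kg: converts keV*cm^2/g to Gy*cm^2
_KEV_PER_G_TO_GY = 1.602176634e-13

COMPONENTS = ("photoelectric", "coherent", "incoherent", "total", "energy_absorption")

_SYMBOL_TO_Z = {
    "H": 1, "C": 6, "N": 7, "O": 8, "Na": 11, "Mg": 12, "Al": 13,
    "P": 15, "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20,
}


class CompositionError(ValueError):
    """Unknown element or invalid mass fractions."""


class EnergyRangeError(ValueError):
    """Energy query outside the tabulated grid."""


class SegmentationError(ValueError):
    """HU value not resolvable by a segmentation scheme."""


class CrossSectionTable:
    """Per-element photon cross sections on a common energy grid.

    Parameters
    ----------
    data : dict
        Maps atomic number to an ``(4, n_energy)`` array with rows
        (photoelectric, coherent, incoherent, energy_absorption), all mass
        coefficients in cm^2/g.
    energy_grid : ndarray
        Ascending energies in keV.
    """

    def __init__(self, data: dict[int, np.ndarray], energy_grid: np.ndarray):
        self.energy_grid = np.asarray(energy_grid, dtype=float)
        if np.any(np.diff(self.energy_grid) <= 0):
            raise ValueError("energy grid must be strictly ascending")
        self._data = {z: np.asarray(a, dtype=float) for z, a in data.items()}
        self._log_e = np.log(self.energy_grid)
        self._log_data = {z: np.log(a) for z, a in self._data.items()}

    @classmethod
    @lru_cache(maxsize=1)
    def default(cls) -> "CrossSectionTable":
        """Load the packaged table (cached)."""
        data, grid = {}, None
        for path in sorted(_DATA_DIR.glob("z*.csv")):
            z = int(path.stem[1:3])
            rows = []
            with open(path) as fh:
                for row in csv.reader(fh):
                    if not row or row[0].startswith("#") or row[0] == "energy_kev":
                        continue
                    rows.append([float(v) for v in row])
            arr = np.array(rows)
            if grid is None:
                grid = arr[:, 0]
            data[z] = arr[:, 1:5].T
        if not data:
            raise FileNotFoundError(f"no element tables under {_DATA_DIR}")
        return cls(data, grid)

    @property
    def elements(self) -> tuple[int, ...]:
        return tuple(sorted(self._data))

    def _z(self, element: int | str) -> int:
        z = _SYMBOL_TO_Z.get(element, element) if isinstance(element, str) else element
        if z not in self._data:
            raise CompositionError(f"element {element!r} not in cross-section table")
        return z

    def _check_energy(self, energy) -> np.ndarray:
        e = np.asarray(energy, dtype=float)
        lo, hi = self.energy_grid[0], self.energy_grid[-1]
        if np.any(e < lo) or np.any(e > hi):
            raise EnergyRangeError(
                f"energy {energy} outside table range [{lo}, {hi}] keV")
        return e

    def mass_coefficient(self, element: int | str, energy, component: str = "total"):
        """Mass coefficient (cm^2/g) at ``energy`` keV, log-log interpolated."""
        z = self._z(element)
        e = self._check_energy(energy)
        if component not in COMPONENTS:
            raise ValueError(f"unknown component {component!r}")
        log_e = np.log(e)
        if component == "total":
            val = sum(np.exp(np.interp(log_e, self._log_e, self._log_data[z][i]))
                      for i in range(3))
        else:
            idx = {"photoelectric": 0, "coherent": 1, "incoherent": 2,
                   "energy_absorption": 3}[component]
            val = np.exp(np.interp(log_e, self._log_e, self._log_data[z][idx]))
        return val if np.ndim(energy) else float(val)


@dataclass(frozen=True, eq=False)
class Material:
    """A mixture defined by elemental mass fractions and a bulk density.

    ``composition`` maps element symbols to mass fractions summing to 1;
    the vacuum material has an empty composition and zero density.
    """

    name: str
    composition: dict[str, float] = field(default_factory=dict)
    density: float = 0.0  # g/cm^3

    def __post_init__(self):
        if self.composition:
            s = sum(self.composition.values())
            if abs(s - 1.0) > 1e-9:
                raise CompositionError(
                    f"{self.name}: mass fractions sum to {s}, expected 1")
            if self.density <= 0:
                raise ValueError(f"{self.name}: density must be positive")
        elif self.density != 0.0:
            raise ValueError("vacuum material must have zero density")

    @property
    def is_vacuum(self) -> bool:
        return not self.composition


class MuValue(NamedTuple):
    linear: float | np.ndarray  # 1/cm
    mass: float | np.ndarray    # cm^2/g


def mixture_mu(material: Material, energy, component: str = "total",
               table: CrossSectionTable | None = None) -> MuValue:
    """Linear and mass attenuation coefficient of a mixture.

    The mass coefficient is the mass-fraction-weighted sum of the element
    coefficients; the linear coefficient multiplies by the bulk density.
    """
    table = table or CrossSectionTable.default()
    if material.is_vacuum:
        z = np.zeros(np.shape(energy)) if np.ndim(energy) else 0.0
        table._check_energy(energy)
        return MuValue(z, z)
    mass = sum(w * table.mass_coefficient(sym, energy, component)
               for sym, w in material.composition.items())
    return MuValue(mass * material.density, mass)


def kerma_per_fluence(material: Material, energy,
                      table: CrossSectionTable | None = None):
    """Collision-kerma factor, Gy per unit photon fluence (photons/cm^2).

    ``E * (mu_en/rho)`` with keV*cm^2/g converted to Gy*cm^2.  Radiative
    losses are neglected (local electron absorption at kV energies).
    """
    mu_en = mixture_mu(material, energy, "energy_absorption", table).mass
    return np.asarray(energy, dtype=float) * mu_en * _KEV_PER_G_TO_GY \
        if np.ndim(energy) else float(energy) * mu_en * _KEV_PER_G_TO_GY


# --------------------------------------------------------------------------
# material presets
# --------------------------------------------------------------------------

MATERIALS: dict[str, Material] = {}


def _register(mat: Material) -> Material:
    MATERIALS[mat.name] = mat
    return mat


VACUUM = _register(Material("vacuum"))
AIR = _register(Material("air", {
    "C": 0.000124, "N": 0.755267, "O": 0.231781, "Ar": 0.012828}, 0.00120))
WATER = _register(Material("water", {"H": 0.111898, "O": 0.888102}, 1.000))
# nominal acrylic (PMMA) C5O2H8, machined-phantom density
ACRYLIC = _register(Material("acrylic", {
    "H": 0.080545, "C": 0.599849, "O": 0.319606}, 1.16))
ALUMINUM = _register(Material("aluminum", {"Al": 1.0}, 2.699))
# epoxy-based anthropomorphic soft-tissue substitute (manufacturer-style)
RANDO_TISSUE = _register(Material("rando_tissue", {
    "H": 0.088, "C": 0.678, "N": 0.024, "O": 0.210}, 0.997))
# foamed lung substitute: published anthropomorphic-phantom lung material
# (epoxy-foam; antimony trace dropped and fractions renormalized)
RANDO_LUNG = _register(Material("rando_lung", {
    "H": 0.0576, "C": 0.7406, "N": 0.0201, "O": 0.1817}, 0.352))
CORTICAL_BONE = _register(Material("cortical_bone", {
    "H": 0.034, "C": 0.155, "N": 0.042, "O": 0.435, "Na": 0.001,
    "Mg": 0.002, "P": 0.103, "S": 0.003, "Ca": 0.225}, 1.92))
FEMUR = _register(Material("femur", {
    "H": 0.070, "C": 0.345, "N": 0.028, "O": 0.368, "Na": 0.001,
    "Mg": 0.001, "P": 0.055, "S": 0.002, "Cl": 0.001, "K": 0.001,
    "Ca": 0.128}, 1.33))
BONE_MARROW = _register(Material("bone_marrow", {
    "H": 0.105, "C": 0.414, "N": 0.034, "O": 0.439, "Na": 0.001,
    "P": 0.001, "S": 0.002, "Cl": 0.002, "K": 0.002}, 1.03))


def get_material(name: str) -> Material:
    try:
        return MATERIALS[name]
    except KeyError:
        raise CompositionError(f"unknown material {name!r}") from None


# --------------------------------------------------------------------------
# HU segmentation
# --------------------------------------------------------------------------

HU_MIN, HU_MAX = -1024, 10000


@dataclass(frozen=True, eq=False)
class SegmentationScheme:
    """Ordered (HU low, HU high, material) rules with first-match precedence.

    Ranges are half-open ``[low, high)``; the final rule's upper bound is
    inclusive.  HU values inside ``[-1024, 10000]`` covered by no rule map
    to the material of the nearest rule boundary (documented gap policy);
    values outside that window raise :class:`SegmentationError`.
    """

    site: str
    rules: tuple[tuple[float, float, Material], ...]

    def __post_init__(self):
        if not self.rules:
            raise ValueError("rule list must be non-empty")

    @property
    def materials(self) -> list[Material]:
        """Unique materials in rule order."""
        seen: list[Material] = []
        for _, _, m in self.rules:
            if m not in seen:
                seen.append(m)
        return seen

    def resolve(self, hu: float) -> Material:
        if not np.isfinite(hu) or hu < HU_MIN or hu > HU_MAX:
            raise SegmentationError(f"HU {hu} outside [{HU_MIN}, {HU_MAX}]")
        last_hi = self.rules[-1][1]
        for lo, hi, mat in self.rules:
            if lo <= hu < hi or (hu == hi == last_hi):
                return mat
        # gap: nearest rule boundary wins
        best, best_d = None, np.inf
        for lo, hi, mat in self.rules:
            for edge in (lo, hi):
                d = abs(hu - edge)
                if d < best_d:
                    best, best_d = mat, d
        return best

    @lru_cache(maxsize=None)
    def _lut(self) -> np.ndarray:
        """Integer-HU lookup table over [HU_MIN, HU_MAX] -> material index."""
        mats = self.materials
        index = {m.name: i for i, m in enumerate(mats)}
        lut = np.empty(HU_MAX - HU_MIN + 1, dtype=np.uint8)
        for hu in range(HU_MIN, HU_MAX + 1):
            lut[hu - HU_MIN] = index[self.resolve(hu).name]
        return lut

    def segment(self, hu_array: np.ndarray) -> np.ndarray:
        """Map an integer HU array to material indices (into .materials)."""
        hu = np.asarray(hu_array)
        if hu.min() < HU_MIN or hu.max() > HU_MAX:
            raise SegmentationError(
                f"HU values outside [{HU_MIN}, {HU_MAX}] in volume")
        return self._lut()[hu.astype(np.int32) - HU_MIN]


def hu_to_material(scheme: SegmentationScheme, hu: float) -> Material:
    """Resolve one HU value to a material under ``scheme``."""
    return scheme.resolve(hu)


_SCHEMES: dict[str, SegmentationScheme] = {
    "pelvis": SegmentationScheme("pelvis", (
        (-1024, -300, AIR),
        (-300, -50, RANDO_TISSUE),
        (5, 100, BONE_MARROW),
        (100, 400, FEMUR),
        (400, 10000, CORTICAL_BONE),
    )),
    # tissue listed before lung: the published thorax ranges overlap
    # (lung -750..-30 covers tissue -300..-50), and first-match precedence
    # with this order keeps both materials reachable
    "thorax": SegmentationScheme("thorax", (
        (-1024, -750, AIR),
        (-300, -50, RANDO_TISSUE),
        (-750, -30, RANDO_LUNG),
        (50, 10000, CORTICAL_BONE),
    )),
    "head": SegmentationScheme("head", (
        (-1024, -300, AIR),
        (-300, 50, RANDO_TISSUE),
        (50, 10000, CORTICAL_BONE),
    )),
    # idealized homogeneous-cylinder images: anything solid is acrylic
    "acrylic": SegmentationScheme("acrylic", (
        (-1024, -850, AIR),
        (-850, 10000, ACRYLIC),
    )),
    # homogeneous water volumes for cross-checks
    "water": SegmentationScheme("water", (
        (-1024, -850, AIR),
        (-850, 10000, WATER),
    )),
}


def get_scheme(site: str) -> SegmentationScheme:
    try:
        return _SCHEMES[site]
    except KeyError:
        raise SegmentationError(f"unknown segmentation scheme {site!r}") from None
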
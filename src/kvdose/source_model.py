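"""Virtual point source model for rotating CBCT beams.

The source is a point at source-to-axis distance (SAD, default 100 cm)
that rotates on an arc around the isocenter.  Its beam is defined entirely
on the isocenter plane: a planar fluence map (relative photon fluence,
1 on the beam axis, zero outside the collimating blades) and a spectrum
that varies with transverse offset.  Photons are sampled by importance
sampling on that plane: a uniform gantry angle within the arc, a target
point drawn proportionally to the planar fluence, and an energy drawn
from the spectrum at the target's transverse offset.

Gantry-angle convention: degrees, 0 = source directly posterior (source
at -y, beam travelling toward +y), increasing toward +x; the couch axis
is z.  Partial-arc presets are posterior-centered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from kvdose.materials import (
    AIR,
    ALUMINUM,
    CrossSectionTable,
    Material,
    kerma_per_fluence,
    mixture_mu,
)

__all__ = [
    "EnergySpectrum",
    "SpectrumMap",
    "PlanarFluence",
    "VirtualPointSource",
    "PhotonState",
    "Protocol",
    "PROTOCOLS",
    "attenuate_spectrum",
    "hvl_al",
    "fluence_weight",
    "sample_photon",
    "sample_photons",
    "source_position",
    "beam_axes",
]


class ConfigurationError(ValueError):
    """Invalid source geometry (degenerate field, empty arc, ...)."""


@dataclass(frozen=True, eq=False)
class EnergySpectrum:
    """Relative photon-number spectrum on an energy-bin grid (keV).

    Weights are non-negative and normalized to sum to 1 on construction.
    """

    energies: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if e.shape != w.shape or e.ndim != 1 or e.size == 0:
            raise ValueError("energies and weights must be equal-length 1-D")
        if np.any(w < 0):
            raise ValueError("spectrum weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise ValueError("spectrum has zero total weight")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w / total)

    @property
    def mean_energy(self) -> float:
        return float(np.dot(self.energies, self.weights))


def attenuate_spectrum(spec: EnergySpectrum, material: Material,
                       thickness_cm: float,
                       table: CrossSectionTable | None = None) -> EnergySpectrum:
    """Harden a spectrum through ``thickness_cm`` of ``material``.

    Per-bin weights are multiplied by exp(-mu(E) t) and renormalized.
    """
    if thickness_cm < 0:
        raise ValueError("thickness must be non-negative")
    mu = mixture_mu(material, spec.energies, "total", table).linear
    return EnergySpectrum(spec.energies, spec.weights * np.exp(-mu * thickness_cm))


def _air_kerma_weights(spec: EnergySpectrum,
                       table: CrossSectionTable | None = None) -> np.ndarray:
    return spec.weights * kerma_per_fluence(AIR, spec.energies, table)


def hvl_al(spec: EnergySpectrum, table: CrossSectionTable | None = None) -> float:
    """Half-value layer in mm of aluminum.

    The thickness at which the air-kerma-weighted transmission of the
    spectrum through aluminum reaches one half, found by a bracketed root
    search (unique because mu_Al is positive).
    """
    mu = mixture_mu(ALUMINUM, spec.energies, "total", table).linear  # 1/cm
    kw = _air_kerma_weights(spec, table)
    k0 = kw.sum()

    def trans(t_mm):
        return float(np.dot(kw, np.exp(-mu * t_mm / 10.0))) / k0 - 0.5

    hi = 1.0
    while trans(hi) > 0:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("transmission does not fall below 0.5")
    return float(brentq(trans, 0.0, hi, xtol=1e-6))


@dataclass(frozen=True, eq=False)
class SpectrumMap:
    """Spectrum as a function of transverse offset on the isocenter plane.

    Holds spectra at sampled offsets (cm) on a shared energy grid; queries
    interpolate the bin weights linearly between neighbouring offsets and
    renormalize, with constant extrapolation beyond the sampled range.
    """

    offsets: np.ndarray              # (n_off,) cm, ascending
    energies: np.ndarray             # (n_e,) keV
    weight_matrix: np.ndarray        # (n_off, n_e) rows normalized

    def __post_init__(self):
        off = np.asarray(self.offsets, dtype=float)
        e = np.asarray(self.energies, dtype=float)
        w = np.asarray(self.weight_matrix, dtype=float)
        if np.any(np.diff(off) <= 0):
            raise ValueError("offsets must be strictly ascending")
        if w.shape != (off.size, e.size):
            raise ValueError("weight matrix shape mismatch")
        w = w / w.sum(axis=1, keepdims=True)
        object.__setattr__(self, "offsets", off)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weight_matrix", w)

    @classmethod
    def uniform(cls, spec: EnergySpectrum, half_width: float) -> "SpectrumMap":
        return cls(np.array([-half_width, half_width]), spec.energies,
                   np.vstack([spec.weights, spec.weights]))

    def at(self, x: float) -> EnergySpectrum:
        off = self.offsets
        xq = float(np.clip(x, off[0], off[-1]))
        i = int(np.searchsorted(off, xq, side="right")) - 1
        i = min(max(i, 0), off.size - 2)
        f = (xq - off[i]) / (off[i + 1] - off[i])
        w = (1.0 - f) * self.weight_matrix[i] + f * self.weight_matrix[i + 1]
        return EnergySpectrum(self.energies, w)

    def resampled(self, xs: np.ndarray) -> np.ndarray:
        """Weight matrix (len(xs), n_e) at arbitrary offsets."""
        return np.vstack([self.at(x).weights for x in xs])


def _profile_interp(grid: np.ndarray, vals: np.ndarray) -> Callable:
    """Shape-preserving interpolant with constant extrapolation."""
    grid = np.asarray(grid, dtype=float)
    vals = np.asarray(vals, dtype=float)
    if grid.size == 1:
        return lambda x: np.full_like(np.asarray(x, dtype=float), vals[0])
    p = PchipInterpolator(grid, vals, extrapolate=False)

    def f(x):
        x = np.asarray(x, dtype=float)
        return np.asarray(p(np.clip(x, grid[0], grid[-1])))

    return f


@dataclass(frozen=True, eq=False)
class PlanarFluence:
    """Separable relative fluence on the isocenter plane.

    ``weight(x, y) = f_transverse(x) * f_radial(y)``, built from sampled
    profile values with shape-preserving (PCHIP) interpolation and
    constant extrapolation; normalized so the beam axis (0, 0) is 1.
    """

    x_grid: np.ndarray
    x_vals: np.ndarray
    y_grid: np.ndarray
    y_vals: np.ndarray

    def __post_init__(self):
        for g, v in ((self.x_grid, self.x_vals), (self.y_grid, self.y_vals)):
            if np.any(np.asarray(v, dtype=float) < 0):
                raise ValueError("fluence values must be non-negative")
        fx = _profile_interp(self.x_grid, self.x_vals)
        fy = _profile_interp(self.y_grid, self.y_vals)
        norm = float(fx(0.0)) * float(fy(0.0))
        if norm <= 0:
            raise ConfigurationError("fluence must be positive on the beam axis")
        object.__setattr__(self, "_fx", fx)
        object.__setattr__(self, "_fy", fy)
        object.__setattr__(self, "_norm", norm)

    @classmethod
    def flat(cls) -> "PlanarFluence":
        one = np.array([1.0, 1.0])
        grid = np.array([-50.0, 50.0])
        return cls(grid, one, grid, one)

    def weight(self, x, y):
        """Relative fluence at plane coordinates (cm); axis = 1."""
        return self._fx(x) * self._fy(y) / self._norm


@dataclass(frozen=True, eq=False)
class Protocol:
    """A CBCT technique preset: beam quality, collimation and arc."""

    name: str
    kvp: float               # peak tube potential, keV
    mas: float               # exposure, mAs
    arc_deg: float           # arc length, degrees
    arc_start_deg: float     # gantry angle at arc start
    blades: tuple[float, float, float, float]  # x1, x2, y1, y2 at isocenter, cm
    bowtie: str              # "full" or "half"
    site: str                # segmentation-scheme site label


#: Default technique settings for the four characterized CBCT protocols.
#: Partial (200 deg) arcs are posterior-centered (start = -100 deg).
PROTOCOLS: dict[str, Protocol] = {
    "head": Protocol("head", 100.0, 145.0, 200.0, -100.0,
                     (13.6, 13.6, 9.2, 9.2), "full", "head"),
    "pelvis_spotlight": Protocol("pelvis_spotlight", 125.0, 720.0, 200.0, -100.0,
                                 (13.6, 13.6, 9.2, 9.2), "full", "pelvis"),
    "thorax": Protocol("thorax", 110.0, 262.0, 360.0, 0.0,
                       (6.8, 23.5, 10.3, 10.3), "half", "thorax"),
    "pelvis": Protocol("pelvis", 125.0, 580.0, 360.0, 0.0,
                       (6.8, 23.5, 10.3, 10.3), "half", "pelvis"),
}


@dataclass(frozen=True, eq=False)
class VirtualPointSource:
    """Characterized rotating point source.

    ``output_cgy_per_mas`` is the measured output factor: in-air collision
    kerma per mAs at the isocenter on the beam axis (free in air).  It sets
    the absolute fluence scale of all dose computations.
    """

    kvp: float
    spectrum_map: SpectrumMap
    fluence: PlanarFluence
    blades: tuple[float, float, float, float]  # x1, x2, y1, y2 (all > 0), cm
    arc_start_deg: float = 0.0
    arc_deg: float = 360.0
    sad: float = 100.0
    mas: float = 1.0
    output_cgy_per_mas: float = 1.0
    name: str = "source"

    def __post_init__(self):
        if self.sad <= 0:
            raise ConfigurationError("SAD must be positive")
        if not (0.0 < self.arc_deg <= 360.0):
            raise ConfigurationError("arc length must be in (0, 360] degrees")
        if any(b <= 0 for b in self.blades):
            raise ConfigurationError("blade positions must be positive")
        if self.mas <= 0 or self.output_cgy_per_mas <= 0:
            raise ConfigurationError("exposure and output factor must be positive")

    @property
    def field_bounds(self):
        """(u_min, u_max, v_min, v_max) of the field at the isocenter plane."""
        x1, x2, y1, y2 = self.blades
        return (-x1, x2, -y1, y2)

    def on_axis_spectrum(self) -> EnergySpectrum:
        return self.spectrum_map.at(0.0)

    def fluence_weight(self, x, y):
        """Relative fluence at plane point(s); zero outside the blades."""
        u0, u1, v0, v1 = self.field_bounds
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = (x >= u0) & (x <= u1) & (y >= v0) & (y <= v1)
        w = self.fluence.weight(x, y) * inside
        return w if w.ndim else float(w)


def fluence_weight(source: VirtualPointSource, x, y):
    """Planar fluence weight at isocenter-plane coordinates (cm)."""
    return source.fluence_weight(x, y)


def source_position(source: VirtualPointSource, gantry_deg) -> np.ndarray:
    """Focal-spot position (cm) at the given gantry angle(s)."""
    th = np.deg2rad(np.asarray(gantry_deg, dtype=float))
    pos = np.stack([source.sad * np.sin(th), -source.sad * np.cos(th),
                    np.zeros_like(th)], axis=-1)
    return pos


def beam_axes(gantry_deg):
    """Unit vectors (e_u, e_v, beam_dir) of the isocenter-plane frame."""
    th = np.deg2rad(float(gantry_deg))
    e_u = np.array([np.cos(th), np.sin(th), 0.0])
    e_v = np.array([0.0, 0.0, 1.0])
    d = np.array([-np.sin(th), np.cos(th), 0.0])
    return e_u, e_v, d


@dataclass(frozen=True)
class PhotonState:
    """A sampled source photon before transport."""

    position: np.ndarray   # cm
    direction: np.ndarray  # unit vector
    energy: float          # keV
    weight: float = 1.0
    gantry_angle: float = 0.0  # degrees


@dataclass(frozen=True, eq=False)
class SamplingTables:
    """Discretized inverse-CDF tables for plane-point and energy sampling."""

    u_edges: np.ndarray
    u_cdf: np.ndarray       # cumulative, u_cdf[0] = 0, u_cdf[-1] = 1
    v_edges: np.ndarray
    v_cdf: np.ndarray
    u_centers: np.ndarray
    energies: np.ndarray
    spec_cdf: np.ndarray    # (n_u_cells, n_e) cumulative per row
    plane_integral: float   # integral of the fluence over the field, cm^2


def build_sampling_tables(source: VirtualPointSource, du: float = 0.1,
                          dv: float = 0.1) -> SamplingTables:
    u0, u1, v0, v1 = source.field_bounds
    if u1 <= u0 or v1 <= v0:
        raise ConfigurationError("degenerate (zero-area) field")
    nu = max(2, int(np.ceil((u1 - u0) / du)))
    nv = max(2, int(np.ceil((v1 - v0) / dv)))
    u_edges = np.linspace(u0, u1, nu + 1)
    v_edges = np.linspace(v0, v1, nv + 1)
    uc = 0.5 * (u_edges[:-1] + u_edges[1:])
    vc = 0.5 * (v_edges[:-1] + v_edges[1:])
    fu = np.maximum(source.fluence.weight(uc, np.zeros_like(uc)), 0.0)
    fv = np.maximum(source.fluence.weight(np.zeros_like(vc), vc), 0.0)
    norm = source.fluence.weight(0.0, 0.0)
    if fu.sum() <= 0 or fv.sum() <= 0:
        raise ConfigurationError("fluence vanishes over the whole field")
    wu = fu * np.diff(u_edges)
    wv = fv * np.diff(v_edges)
    plane_integral = float(wu.sum() * wv.sum() / max(norm, 1e-300))
    u_cdf = np.concatenate([[0.0], np.cumsum(wu) / wu.sum()])
    v_cdf = np.concatenate([[0.0], np.cumsum(wv) / wv.sum()])
    specs = source.spectrum_map.resampled(uc)
    spec_cdf = np.cumsum(specs, axis=1)
    spec_cdf /= spec_cdf[:, -1:]
    return SamplingTables(u_edges, u_cdf, v_edges, v_cdf, uc,
                          source.spectrum_map.energies, spec_cdf, plane_integral)


def _sample_cells(edges, cdf, xi):
    idx = np.searchsorted(cdf, xi, side="right") - 1
    idx = np.clip(idx, 0, edges.size - 2)
    frac = (xi - cdf[idx]) / np.maximum(cdf[idx + 1] - cdf[idx], 1e-300)
    return idx, edges[idx] + frac * (edges[idx + 1] - edges[idx])


def sample_photons(source: VirtualPointSource, n: int,
                   rng: np.random.Generator,
                   tables: SamplingTables | None = None):
    """Vectorized source sampling.

    Returns ``(positions, directions, energies, weights, gantry_angles)``
    arrays; positions are focal-spot locations and directions point through
    the fluence-sampled target on the isocenter plane.
    """
    t = tables or build_sampling_tables(source)
    gantry = source.arc_start_deg + source.arc_deg * rng.random(n)
    iu, u = _sample_cells(t.u_edges, t.u_cdf, rng.random(n))
    _, v = _sample_cells(t.v_edges, t.v_cdf, rng.random(n))
    xi = rng.random(n)
    ie = np.empty(n, dtype=np.int64)
    for k in range(n):  # row-wise searchsorted (per-photon spectrum row)
        ie[k] = np.searchsorted(t.spec_cdf[iu[k]], xi[k], side="right")
    ie = np.clip(ie, 0, t.energies.size - 1)
    energies = t.energies[ie]
    th = np.deg2rad(gantry)
    pos = np.stack([source.sad * np.sin(th), -source.sad * np.cos(th),
                    np.zeros(n)], axis=1)
    e_u = np.stack([np.cos(th), np.sin(th), np.zeros(n)], axis=1)
    target = u[:, None] * e_u + np.stack(
        [np.zeros(n), np.zeros(n), v], axis=1)
    dirs = target - pos
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return pos, dirs, energies, np.ones(n), gantry


def sample_photon(source: VirtualPointSource,
                  rng: np.random.Generator) -> PhotonState:
    """Sample a single source photon (see :func:`sample_photons`)."""
    pos, dirs, e, w, g = sample_photons(source, 1, rng)
    return PhotonState(pos[0], dirs[0], float(e[0]), float(w[0]), float(g[0]))


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------


def source_to_dict(source: VirtualPointSource) -> dict:
    """JSON-serializable representation of a characterized source."""
    return {
        "format": "kvdose-source-1",
        "name": source.name,
        "kvp": source.kvp,
        "sad": source.sad,
        "blades": list(source.blades),
        "arc_start_deg": source.arc_start_deg,
        "arc_deg": source.arc_deg,
        "mas": source.mas,
        "output_cgy_per_mas": source.output_cgy_per_mas,
        "spectrum": {
            "offsets_cm": source.spectrum_map.offsets.tolist(),
            "energies_kev": source.spectrum_map.energies.tolist(),
            "weights": source.spectrum_map.weight_matrix.tolist(),
        },
        "fluence": {
            "x_grid": source.fluence.x_grid.tolist() if hasattr(
                source.fluence.x_grid, "tolist") else list(source.fluence.x_grid),
            "x_vals": np.asarray(source.fluence.x_vals, dtype=float).tolist(),
            "y_grid": np.asarray(source.fluence.y_grid, dtype=float).tolist(),
            "y_vals": np.asarray(source.fluence.y_vals, dtype=float).tolist(),
        },
    }


def source_from_dict(d: dict) -> VirtualPointSource:
    if d.get("format") != "kvdose-source-1":
        raise ValueError("not a serialized kvdose source")
    smap = SpectrumMap(np.asarray(d["spectrum"]["offsets_cm"]),
                       np.asarray(d["spectrum"]["energies_kev"]),
                       np.asarray(d["spectrum"]["weights"]))
    fl = d["fluence"]
    fluence = PlanarFluence(np.asarray(fl["x_grid"]), np.asarray(fl["x_vals"]),
                            np.asarray(fl["y_grid"]), np.asarray(fl["y_vals"]))
    return VirtualPointSource(
        kvp=float(d["kvp"]), spectrum_map=smap, fluence=fluence,
        blades=tuple(d["blades"]), arc_start_deg=float(d["arc_start_deg"]),
        arc_deg=float(d["arc_deg"]), sad=float(d["sad"]), mas=float(d["mas"]),
        output_cgy_per_mas=float(d["output_cgy_per_mas"]),
        name=str(d.get("name", "source")))
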
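"""Voxel phantoms: idealized cylinder, toy anatomy fixtures, volume IO.

Coordinates are isocenter-origin, right-handed, in cm, with +y anterior
and the couch axis along z.  Voxel grids are stored as int16 HU arrays
indexed ``[ix, iy, iz]``; spacing is in mm, ``origin_cm`` is the position
of the center of voxel (0, 0, 0), and volumes are centered on the
isocenter by default.  Voxel boundaries are half-open.

The internal volume format is a two-file pair: ``<stem>.json`` carrying
dimensions/spacing/origin and ``<stem>.raw`` holding the HU grid as
little-endian int16 in C order (ix slowest) -- it round-trips bit-exactly
and keeps tests independent of DICOM fixtures.  DICOM CT series are read
with pydicom (slices ordered by position, rescale slope/intercept applied).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "VoxelPhantom",
    "make_cylinder_phantom",
    "make_anatomy_fixture",
    "read_ct_volume",
    "write_volume",
    "read_volume",
]


class VolumeFormatError(ValueError):
    """Malformed or inconsistent volume input."""


@dataclass(frozen=True, eq=False)
class VoxelPhantom:
    """A voxelized HU volume positioned relative to the isocenter."""

    hu: np.ndarray               # int16, shape (nx, ny, nz)
    spacing_mm: tuple[float, float, float]
    origin_cm: tuple[float, float, float]  # center of voxel (0, 0, 0)

    def __post_init__(self):
        hu = np.ascontiguousarray(self.hu, dtype=np.int16)
        if hu.ndim != 3 or min(hu.shape) < 1:
            raise ValueError("HU grid must be 3-D with at least one voxel per axis")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if hu.min() < -1024 or hu.max() > 32767:
            raise ValueError("HU outside [-1024, 32767]")
        object.__setattr__(self, "hu", hu)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_cm", tuple(float(o) for o in self.origin_cm))

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.hu.shape

    @property
    def spacing_cm(self) -> np.ndarray:
        return np.asarray(self.spacing_mm, dtype=float) / 10.0

    @property
    def lower_corner_cm(self) -> np.ndarray:
        """Position of the low corner of voxel (0, 0, 0)."""
        return np.asarray(self.origin_cm) - self.spacing_cm / 2.0

    @property
    def upper_corner_cm(self) -> np.ndarray:
        return self.lower_corner_cm + np.asarray(self.dims) * self.spacing_cm

    def index_to_position(self, idx) -> np.ndarray:
        """Voxel index -> center position (cm)."""
        return np.asarray(self.origin_cm) + np.asarray(idx, dtype=float) * self.spacing_cm

    def position_to_index(self, pos) -> tuple[int, int, int]:
        """Position (cm) -> containing voxel index (half-open boundaries)."""
        rel = (np.asarray(pos, dtype=float) - self.lower_corner_cm) / self.spacing_cm
        idx = np.floor(rel).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.dims)):
            raise ValueError(f"position {pos} outside the voxel grid")
        return tuple(int(i) for i in idx)

    def contains(self, pos) -> bool:
        pos = np.asarray(pos, dtype=float)
        return bool(np.all(pos >= self.lower_corner_cm)
                    and np.all(pos < self.upper_corner_cm))


def _centered_origin(dims, spacing_mm) -> tuple[float, float, float]:
    d = np.asarray(dims, dtype=float)
    sp = np.asarray(spacing_mm, dtype=float) / 10.0
    return tuple(-(d - 1.0) / 2.0 * sp)


def _centered_grid(dims, spacing_mm):
    """Voxel-center coordinate vectors (cm) of an isocenter-centered grid."""
    origin = np.asarray(_centered_origin(dims, spacing_mm))
    sp = np.asarray(spacing_mm, dtype=float) / 10.0
    return [origin[a] + sp[a] * np.arange(dims[a]) for a in range(3)]


AIR_HU = -1000
ACRYLIC_HU = 120  # maps to acrylic under the dedicated "acrylic" scheme


def make_cylinder_phantom(diameter_cm: float = 15.2, length_cm: float = 22.0,
                          material_hu: int = ACRYLIC_HU,
                          dims: tuple[int, int, int] = (512, 512, 91),
                          spacing_mm: tuple[float, float, float] = (0.81, 0.81, 3.0),
                          ) -> VoxelPhantom:
    """Idealized homogeneous cylinder image, axis along z through isocenter.

    Defaults reproduce the 15.2 cm diameter, 22 cm long machined acrylic
    phantom on a 512 x 512 x 91 grid of 0.81 x 0.81 x 3 mm voxels.  Voxels
    whose centers fall inside the cylinder get ``material_hu``; the rest
    are air (-1000).
    """
    if diameter_cm <= 0 or length_cm <= 0:
        raise ValueError("cylinder dimensions must be positive")
    xs, ys, zs = _centered_grid(dims, spacing_mm)
    if (diameter_cm / 2 > min(xs[-1], ys[-1]) + 1e-9
            or length_cm / 2 > zs[-1] + np.asarray(spacing_mm)[2] / 20.0 + 1e-9):
        raise ValueError("cylinder does not fit inside the voxel grid")
    r2 = (xs[:, None] ** 2 + ys[None, :] ** 2)
    inside_xy = r2 <= (diameter_cm / 2.0) ** 2
    inside_z = np.abs(zs) <= length_cm / 2.0
    hu = np.full(dims, AIR_HU, dtype=np.int16)
    hu[inside_xy[:, :, None] & inside_z[None, None, :]] = material_hu
    return VoxelPhantom(hu, spacing_mm, _centered_origin(dims, spacing_mm))


def _ellipse_mask(xs, ys, cx, cy, ax, ay):
    return ((xs[:, None] - cx) / ax) ** 2 + ((ys[None, :] - cy) / ay) ** 2 <= 1.0


def make_anatomy_fixture(site: str,
                         dims: tuple[int, int, int] = (256, 256, 41),
                         spacing_mm: tuple[float, float, float] = (1.62, 1.62, 3.0),
                         ) -> VoxelPhantom:
    """Deterministic nested-ellipse anatomy stand-in (synthetic).

    A coarse substitute for an anthropomorphic phantom: extruded 2-D
    ellipses whose HU values resolve under the site's segmentation scheme
    without gap-filling.  Exactly left-right mirror symmetric.
    """
    xs, ys, zs = _centered_grid(dims, spacing_mm)
    plane = np.full(dims[:2], AIR_HU, dtype=np.int16)
    if site == "thorax":
        plane[_ellipse_mask(xs, ys, 0, 0, 16.0, 10.0)] = -100      # tissue
        for sx in (-7.0, 7.0):
            plane[_ellipse_mask(xs, ys, sx, 0.5, 5.5, 6.5)] = -500  # lung
        plane[_ellipse_mask(xs, ys, 0, -7.5, 1.6, 1.6)] = 1000      # spine
    elif site == "pelvis":
        plane[_ellipse_mask(xs, ys, 0, 0, 17.0, 11.0)] = -100       # tissue
        for sx in (-8.0, 8.0):
            plane[_ellipse_mask(xs, ys, sx, -1.0, 2.8, 2.8)] = 1000  # cortex
            plane[_ellipse_mask(xs, ys, sx, -1.0, 2.2, 2.2)] = 250   # femoral head
        plane[_ellipse_mask(xs, ys, 0, -8.0, 1.6, 1.6)] = 1000       # sacrum
    elif site == "head":
        plane[_ellipse_mask(xs, ys, 0, 0, 8.6, 10.6)] = 1000         # cranial shell
        plane[_ellipse_mask(xs, ys, 0, 0, 8.0, 10.0)] = 0            # tissue
    else:
        raise ValueError(f"unknown anatomy site {site!r}")
    hu = np.repeat(plane[:, :, None], dims[2], axis=2).astype(np.int16)
    return VoxelPhantom(hu, spacing_mm, _centered_origin(dims, spacing_mm))


def pick_material_voxels(phantom: VoxelPhantom, scheme, material_name: str,
                         n: int = 5, k_slice: int | None = None):
    """Deterministically pick ``n`` voxels of one material spanning the volume.

    Voxels are taken from one axial slice (the central one by default) at
    evenly spaced quantiles of the material's x extent, at the median y of
    each x column -- e.g. lung sampling points spanning both lungs.
    """
    k = phantom.dims[2] // 2 if k_slice is None else int(k_slice)
    ids = scheme.segment(phantom.hu[:, :, k])
    names = [m.name for m in scheme.materials]
    if material_name not in names:
        raise ValueError(f"{material_name} not in scheme {scheme.site}")
    idx = np.argwhere(ids == names.index(material_name))
    if idx.size == 0:
        raise ValueError(f"no {material_name} voxels in slice {k}")
    xs = idx[:, 0]
    picks = []
    for q in np.linspace(0.05, 0.95, n):
        x_t = int(np.quantile(xs, q, method="nearest"))
        cand = idx[xs == x_t]
        picks.append((x_t, int(np.median(cand[:, 1])), k))
    return picks


# --------------------------------------------------------------------------
# IO
# --------------------------------------------------------------------------


def write_volume(phantom: VoxelPhantom, path: str | Path) -> None:
    """Write the internal two-file volume format (<stem>.json + <stem>.raw)."""
    stem = Path(path).with_suffix("")
    meta = {
        "format": "kvdose-volume-1",
        "dims": list(phantom.dims),
        "spacing_mm": list(phantom.spacing_mm),
        "origin_cm": list(phantom.origin_cm),
        "dtype": "int16-le",
        "order": "C (ix slowest)",
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    phantom.hu.astype("<i2").tofile(stem.with_suffix(".raw"))


def read_volume(path: str | Path) -> VoxelPhantom:
    """Read a volume written by :func:`write_volume` (bit-exact round trip)."""
    stem = Path(path).with_suffix("")
    try:
        meta = json.loads(stem.with_suffix(".json").read_text())
    except FileNotFoundError as err:
        raise VolumeFormatError(f"missing metadata file {stem}.json") from err
    if meta.get("format") != "kvdose-volume-1":
        raise VolumeFormatError("not a kvdose internal volume")
    dims = tuple(meta["dims"])
    hu = np.fromfile(stem.with_suffix(".raw"), dtype="<i2")
    if hu.size != int(np.prod(dims)):
        raise VolumeFormatError("raw payload size does not match dims")
    return VoxelPhantom(hu.reshape(dims), tuple(meta["spacing_mm"]),
                        tuple(meta["origin_cm"]))


def read_ct_volume(path: str | Path, center_on_isocenter: bool = True) -> VoxelPhantom:
    """Read a DICOM CT series directory (or an internal volume file).

    Slices are ordered by their z position (not filename); rescale slope
    and intercept are applied to produce HU.  By default the volume is
    re-centered on the isocenter, matching the phantom-at-isocenter setup.
    """
    path = Path(path)
    if path.is_file() or path.suffix in (".json", ".raw"):
        return read_volume(path)
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if hasattr(ds, "pixel_array"):
            slices.append(ds)
    if not slices:
        raise VolumeFormatError(f"no readable CT slices under {path}")
    try:
        slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
        z = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    except AttributeError as err:
        raise VolumeFormatError("slices lack ImagePositionPatient") from err
    if len(slices) > 1:
        dz = np.diff(z)
        if np.any(dz <= 0) or (dz.max() - dz.min()) > 0.01 * dz.mean():
            raise VolumeFormatError("inconsistent slice spacing")
        slice_mm = float(dz.mean())
    else:
        slice_mm = float(getattr(slices[0], "SliceThickness", 1.0))
    first = slices[0]
    try:
        slope = float(first.RescaleSlope)
        intercept = float(first.RescaleIntercept)
    except AttributeError as err:
        raise VolumeFormatError("missing rescale slope/intercept tags") from err
    py, px = (float(v) for v in first.PixelSpacing)  # row (y), col (x) spacing
    stack = np.stack([ds.pixel_array for ds in slices], axis=-1)  # (row, col, z)
    hu = np.clip(stack.astype(np.float64) * slope + intercept, -1024, 32767)
    hu = np.transpose(hu.astype(np.int16), (1, 0, 2))  # -> (x, y, z)
    spacing = (px, py, slice_mm)
    if center_on_isocenter:
        origin = _centered_origin(hu.shape, spacing)
    else:
        ipp = [float(v) for v in first.ImagePositionPatient]
        origin = (ipp[0] / 10.0, ipp[1] / 10.0, z[0] / 10.0)
    return VoxelPhantom(hu, spacing, origin)
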
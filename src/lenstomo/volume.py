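"""Density volume and table I/O.

A tomogram is held as a :class:`DensityVolume`: a 3D grid of 8-bit-range
intensities (0-255) together with the physical voxel size in nm and the
physical coordinate of the first voxel center.  All physical coordinates
downstream of this module are in nanometres; the only index<->physical
conversion site lives here.

Volumes are stored on disk as MRC/CCP4 maps (mode 0, signed 8-bit, with
intensities shifted by -128 so the full 0-255 range survives the signed
storage).  Particle and connection tables are plain TSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

#: TSV column order for particle tables.
PARTICLE_COLUMNS = [
    "id", "x_nm", "y_nm", "z_nm", "volume_nm3", "diameter_nm",
    "peak_intensity", "voxel_count", "class",
]

#: TSV column order for connection tables.
CONNECTION_COLUMNS = ["a", "b", "pair_type", "distance_nm"]


class VolumeFormatError(ValueError):
    """Raised when a file cannot be interpreted as a density volume."""


@dataclass
class DensityVolume:
    """3D density map with physical coordinate metadata.

    Parameters
    ----------
    grid : ndarray, shape (nx, ny, nz)
        Intensities in [0, 255].  Axis ``i`` of the array is physical x,
        ``j`` is y, ``k`` is z.
    voxel_size : float
        Edge length of one cubic voxel in nm (default 0.8 nm, the
        single-pixel slice thickness of the tomograms this pipeline was
        designed for).
    origin : ndarray, shape (3,)
        Physical (x, y, z) coordinate in nm of the *center* of voxel
        (0, 0, 0).
    """

    grid: np.ndarray
    voxel_size: float = 0.8
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"grid must be 3D, got shape {self.grid.shape}")
        if self.voxel_size <= 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        gmin, gmax = float(self.grid.min(initial=0)), float(self.grid.max(initial=0))
        if gmin < 0 or gmax > 255:
            raise ValueError(
                f"intensities must lie in [0, 255], got [{gmin}, {gmax}]")
        self.origin = np.asarray(self.origin, dtype=float)
        if self.origin.shape != (3,):
            raise ValueError("origin must be a length-3 coordinate")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def index_to_physical(self, idx) -> np.ndarray:
        """Physical nm coordinate of voxel center(s) at integer index ``idx``."""
        return self.origin + self.voxel_size * np.asarray(idx, dtype=float)

    def physical_to_index(self, pos) -> np.ndarray:
        """Nearest voxel index for physical coordinate(s) ``pos`` (nm)."""
        idx = np.rint((np.asarray(pos, dtype=float) - self.origin) / self.voxel_size)
        return idx.astype(int)

    def contains(self, pos) -> bool:
        """True if physical coordinate ``pos`` falls inside the grid."""
        idx = self.physical_to_index(pos)
        return bool(np.all(idx >= 0) and np.all(idx < np.array(self.shape)))


def read_volume(path: str | os.PathLike,
                voxel_size_override: float | None = None) -> DensityVolume:
    """Read an MRC/CCP4 map as a :class:`DensityVolume`.

    Intensities are brought onto the 0-255 scale: mode-0 (signed 8-bit)
    data are shifted by +128; other integer data already within [0, 255]
    pass through unchanged; anything else is linearly min-max rescaled to
    [0, 255].  The voxel size comes from the map header unless
    ``voxel_size_override`` is given.
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise VolumeFormatError(f"cannot read MRC/CCP4 volume {path!r}: {exc}") from None
    arr = np.array(ccp4.grid, copy=True).astype(np.float64)
    mode = ccp4.header_i32(4)
    if mode == 0:
        arr = arr + 128.0
    elif not (arr.min(initial=0) >= 0 and arr.max(initial=0) <= 255
              and np.allclose(arr, np.round(arr))):
        lo, hi = float(arr.min()), float(arr.max())
        if hi > lo:
            arr = (arr - lo) * (255.0 / (hi - lo))
        else:
            arr = np.clip(arr, 0.0, 255.0)
    arr = np.clip(arr, 0.0, 255.0).astype(np.float32)

    if voxel_size_override is not None:
        voxel = float(voxel_size_override)
    else:
        nu = ccp4.grid.nu
        voxel = ccp4.grid.unit_cell.a / nu if nu else 0.0
    if voxel <= 0:
        raise ValueError(f"non-positive voxel size {voxel} in {path!r}")
    origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)], dtype=float)
    return DensityVolume(grid=arr, voxel_size=voxel, origin=origin)


def write_volume(vol: DensityVolume, path: str | os.PathLike) -> str:
    """Write a :class:`DensityVolume` as a mode-0 (8-bit) MRC/CCP4 map.

    Intensities are rounded to integers and stored shifted by -128 into
    the signed 8-bit range; :func:`read_volume` inverts the shift, so the
    round trip is bit-identical for integral grids.
    """
    nx, ny, nz = vol.shape
    data = np.round(np.asarray(vol.grid, dtype=np.float64)) - 128.0
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(data, dtype=np.float32))
    vs = vol.voxel_size
    ccp4.grid.set_unit_cell(gemmi.UnitCell(nx * vs, ny * vs, nz * vs, 90, 90, 90))
    ccp4.grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4.update_ccp4_header(0, True)
    for w, v in zip((50, 51, 52), vol.origin):
        ccp4.set_header_float(w, float(v))
    ccp4.write_ccp4_map(str(path))
    return str(path)


def _empty_particle_frame() -> pd.DataFrame:
    return pd.DataFrame({
        "id": pd.Series(dtype=int),
        "x_nm": pd.Series(dtype=float),
        "y_nm": pd.Series(dtype=float),
        "z_nm": pd.Series(dtype=float),
        "volume_nm3": pd.Series(dtype=float),
        "diameter_nm": pd.Series(dtype=float),
        "peak_intensity": pd.Series(dtype=float),
        "voxel_count": pd.Series(dtype=int),
        "class": pd.Series(dtype=object),
    })


def write_particle_table(particles: pd.DataFrame, path: str | os.PathLike) -> str:
    """Write a particle table as TSV (one row per particle)."""
    df = particles if len(particles) else _empty_particle_frame()
    cols = [c for c in PARTICLE_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols, float_format="%.6f")
    return str(path)


def read_particle_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV particle table written by :func:`write_particle_table`."""
    df = pd.read_csv(path, sep="\t")
    if "class" in df.columns:
        df["class"] = df["class"].fillna("unclassified")
    return df


def write_connection_table(connections: pd.DataFrame, path: str | os.PathLike) -> str:
    """Write a connection table as TSV (columns a, b, pair_type, distance_nm)."""
    if len(connections) == 0:
        connections = pd.DataFrame({c: [] for c in CONNECTION_COLUMNS})
    connections.to_csv(path, sep="\t", index=False,
                       columns=[c for c in CONNECTION_COLUMNS if c in connections.columns],
                       float_format="%.6f")
    return str(path)


def read_connection_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
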
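"""Synthetic lens-cytoskeleton tomogram generator.

The generator emulates the structural model the analysis pipeline is
built to quantify: thin (2-3 nm) cytoskeletal filaments decorated with
alphaA-crystallin particles at a basic arc-length repeat of ~7 nm
(monomers), or at twice / three times that repeat when dimers skip one
or two decoration sites; a fraction of sites promoted to ~15 nm "bead"
clusters (four members at the vertices of a square or a regular
tetrahedron); and, in labeled scenes, antibody/gold conjugates in two
nominal size populations (~3 nm and ~7 nm diameter) attached to
decoration sites by ~14 nm tethers.

Scenes are built in two stages: :func:`build_scene` produces an exact
geometric :class:`GroundTruth`, and :func:`rasterize` renders it into an
8-bit density volume with point-spread blur, background and noise.
Ground truth can also be converted directly to an ideal particle table
(:func:`scene_particle_table`) so the statistical stages can be tested
with no segmentation error.

Tether geometry is locally correlated by default: gold conjugates on the
same filament project in nearly the same direction with nearly the same
tether length, so label-to-label spacings preserve the underlying
site-to-site spacings (as observed in labeled cells, where gold-gold
distance histograms peak at the decoration repeat even though the
tethers themselves are twice as long).  Fully independent tether
directions/lengths are available through
``tether_direction_mode="uniform"`` and ``tether_length_within_sd``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import gammainc

from lenstomo.volume import DensityVolume

DECORATION_MODES = ("monomer", "dimer_skip1", "dimer_skip2")
_STRIDE = {"monomer": 1, "dimer_skip1": 2, "dimer_skip2": 3}


@dataclass
class SceneParams:
    """Generative parameters for a synthetic scene.

    Lengths in nm, fractions in [0, 1].  Defaults encode the structural
    model of the rat-lens fiber-cell cytoskeleton: 2.5 nm filament core,
    7 nm basic decoration repeat, 15 nm bead clusters, gold populations
    at 3.0+-0.6 and 7+-1.5 nm diameter, tethers 14+-3 nm.
    """

    box_size: float = 100.0
    voxel_size: float = 0.8
    n_filaments: int = 4
    filament_length: float | None = None     # default 0.8 * box_size
    filament_diameter: float = 2.5
    curvature_sd_deg: float = 8.0            # per-nm direction jitter
    decoration_mode: str = "monomer"
    base_spacing: float = 7.0
    spacing_jitter_sd: float = 1.7           # sd of each arc-length increment
    monomer_diameter: float = 3.0
    dimer_diameter: float = 4.0
    bead_fraction: float = 0.0
    bead_diameter: float = 15.0              # circumscribed cluster diameter
    gold_label_fraction: float = 0.7
    gold_small_fraction: float = 0.68        # observed 225 small / 332 total
    gold_small_diameter_mean: float = 3.0
    gold_small_diameter_sd: float = 0.6
    gold_large_diameter_mean: float = 7.0
    gold_large_diameter_sd: float = 1.5
    gold_min_diameter: float = 1.0
    tether_length_mean: float = 14.0
    tether_length_sd: float = 3.0            # scene-wide spread
    tether_length_within_sd: float = 1.0     # spread within one filament
    tether_direction_mode: str = "correlated"  # or "uniform"
    tether_direction_jitter_deg: float = 5.0
    tether_radius: float = 1.0
    render_tethers: bool = True
    psf_sigma: float = 0.85                  # ~2 nm FWHM resolution
    noise_sd: float = 8.0                    # 8-bit intensity units
    background_level: float = 30.0
    protein_amplitude: float = 180.0
    filament_amplitude: float = 180.0
    tether_amplitude: float = 120.0
    gold_amplitude: float = 510.0
    gold_saturation_target: float = 250.0    # post-PSF gold peak floor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.decoration_mode not in DECORATION_MODES:
            raise ValueError(f"decoration_mode must be one of {DECORATION_MODES}")
        for name in ("box_size", "voxel_size", "filament_diameter", "base_spacing",
                     "monomer_diameter", "dimer_diameter", "bead_diameter",
                     "gold_small_diameter_mean", "gold_large_diameter_mean",
                     "tether_length_mean", "tether_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("bead_fraction", "gold_label_fraction", "gold_small_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.box_size < self.base_spacing:
            raise ValueError("box_size is too small to hold a single spacing")

    @property
    def effective_filament_length(self) -> float:
        return self.filament_length if self.filament_length is not None \
            else 0.8 * self.box_size


@dataclass
class GoldAttachment:
    """One gold conjugate tethered to a decoration site."""
    site_index: int
    center: np.ndarray
    diameter: float
    tether_vector: np.ndarray

    @property
    def tether_length(self) -> float:
        return float(np.linalg.norm(self.tether_vector))


@dataclass
class GroundTruth:
    """Exact geometric description of a synthetic scene."""

    filaments: list                                 # list of (m, 3) polylines
    site_positions: np.ndarray                      # (n, 3) nm
    site_kinds: list                                # monomer | dimer | bead_member
    site_filament: np.ndarray                       # (n,) filament index
    site_arc: np.ndarray = None                     # (n,) arc-length along filament
    bead_centers: np.ndarray = None                 # (k, 3) nm
    gold_attachments: list = field(default_factory=list)
    true_spacing: float = 7.0                       # center-to-center repeat, nm
    box_size: float = 100.0

    def __post_init__(self) -> None:
        self.site_positions = np.asarray(self.site_positions, float).reshape(-1, 3)
        n = len(self.site_positions)
        if self.site_arc is None:
            self.site_arc = np.full(n, np.nan)
        self.site_arc = np.asarray(self.site_arc, float)
        if self.bead_centers is None:
            self.bead_centers = np.empty((0, 3))
        self.bead_centers = np.asarray(self.bead_centers, float).reshape(-1, 3)
        for g in self.gold_attachments:
            if not 0 <= g.site_index < n:
                raise ValueError(f"gold attachment references missing site {g.site_index}")
            if np.linalg.norm(g.tether_vector) <= 0:
                raise ValueError("tether vector must have positive length")

    @property
    def n_sites(self) -> int:
        return len(self.site_positions)

    def to_dict(self) -> dict:
        return {
            "filaments": [f.tolist() for f in self.filaments],
            "site_positions": self.site_positions.tolist(),
            "site_kinds": list(self.site_kinds),
            "site_filament": self.site_filament.tolist(),
            "site_arc": self.site_arc.tolist(),
            "bead_centers": self.bead_centers.tolist(),
            "gold_attachments": [
                {"site_index": g.site_index, "center": g.center.tolist(),
                 "diameter": g.diameter, "tether_vector": g.tether_vector.tolist()}
                for g in self.gold_attachments],
            "true_spacing": self.true_spacing,
            "box_size": self.box_size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            filaments=[np.asarray(f, float) for f in d["filaments"]],
            site_positions=np.asarray(d["site_positions"], float),
            site_kinds=list(d["site_kinds"]),
            site_filament=np.asarray(d["site_filament"], int),
            site_arc=np.asarray(d.get("site_arc", []), float) if d.get("site_arc") else None,
            bead_centers=np.asarray(d["bead_centers"], float),
            gold_attachments=[
                GoldAttachment(g["site_index"], np.asarray(g["center"], float),
                               g["diameter"], np.asarray(g["tether_vector"], float))
                for g in d["gold_attachments"]],
            true_spacing=d["true_spacing"],
            box_size=d["box_size"],
        )


# ---------------------------------------------------------------------------
# geometry helpers

def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n

def _perpendicular(v: np.ndarray) -> np.ndarray:
    a = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(v, a)
    return p / np.linalg.norm(p)

def _cone_jitter(base: np.ndarray, sd_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Tilt ``base`` by a Gaussian angle (sd in degrees) in a random azimuth."""
    if sd_deg <= 0:
        return base.copy()
    theta = rng.normal(0.0, math.radians(sd_deg))
    phi = rng.uniform(0.0, 2.0 * math.pi)
    p1 = _perpendicular(base)
    p2 = np.cross(base, p1)
    tilted = (math.cos(theta) * base
              + math.sin(theta) * (math.cos(phi) * p1 + math.sin(phi) * p2))
    return tilted / np.linalg.norm(tilted)

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


_TETRA_VERTS = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                        dtype=float) / math.sqrt(3.0)
_SQUARE_VERTS = np.array([[1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0]],
                         dtype=float)


def _grow_filament(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Random smooth polyline with bounded curvature, reflected at walls."""
    margin = min(2.0, 0.1 * params.box_size)
    step = 1.0
    n_steps = max(1, int(math.ceil(params.effective_filament_length / step)))
    pos = rng.uniform(margin, params.box_size - margin, size=3)
    direction = _random_unit(rng)
    # head into the box so straight filaments that fit never reflect
    to_center = params.box_size / 2.0 - pos
    if np.dot(direction, to_center) < 0:
        direction = -direction
    pts = [pos.copy()]
    for _ in range(n_steps):
        direction = _cone_jitter(direction, params.curvature_sd_deg * step, rng)
        nxt = pos + step * direction
        for ax in range(3):
            if nxt[ax] < margin or nxt[ax] > params.box_size - margin:
                direction[ax] = -direction[ax]
        nxt = pos + step * direction
        nxt = np.clip(nxt, margin, params.box_size - margin)
        pts.append(nxt.copy())
        pos = nxt
    return np.array(pts)


def _arc_interpolate(polyline: np.ndarray, arcs: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return np.column_stack([np.interp(arcs, cum, polyline[:, ax]) for ax in range(3)])


def _polyline_length(polyline: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(polyline, axis=0), axis=1).sum())


def _truncated_normal(mean: float, sd: float, lo: float,
                      rng: np.random.Generator) -> float:
    for _ in range(200):
        v = rng.normal(mean, sd)
        if v >= lo:
            return float(v)
    return lo


# ---------------------------------------------------------------------------
# scene construction

def build_scene(params: SceneParams) -> GroundTruth:
    """Lay out filaments, decoration sites, beads and gold conjugates.

    Decoration sites sit on the filament axis at consecutive arc-length
    increments drawn from N(base_spacing, spacing_jitter_sd); dimers skip
    one (``dimer_skip1``) or two (``dimer_skip2``) sites, doubling or
    tripling the center-to-center repeat.  Deterministic for a fixed
    ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    stride = _STRIDE[params.decoration_mode]
    site_kind = "monomer" if stride == 1 else "dimer"

    filaments, site_pos, site_kinds, site_fil, site_arc = [], [], [], [], []
    for f in range(params.n_filaments):
        poly = _grow_filament(params, rng)
        filaments.append(poly)
        total = _polyline_length(poly)
        arcs = [0.0]
        while True:
            inc = params.base_spacing
            if params.spacing_jitter_sd > 0:
                inc = max(0.5, rng.normal(params.base_spacing, params.spacing_jitter_sd))
            nxt = arcs[-1] + inc
            if nxt > total + 1e-9:
                break
            arcs.append(nxt)
        occupied = np.asarray(arcs)[::stride]
        pos = _arc_interpolate(poly, occupied)
        site_pos.extend(pos)
        site_kinds.extend([site_kind] * len(pos))
        site_fil.extend([f] * len(pos))
        site_arc.extend(occupied)

    site_pos = np.asarray(site_pos, float).reshape(-1, 3)
    site_fil = np.asarray(site_fil, int)
    site_arc = np.asarray(site_arc, float)

    # promote a fraction of sites to 4-member bead clusters
    bead_centers = []
    if params.bead_fraction > 0 and len(site_pos):
        keep_pos, keep_kind, keep_fil, keep_arc = [], [], [], []
        r = params.bead_diameter / 2.0
        for pos, kind, f, arc in zip(site_pos, site_kinds, site_fil, site_arc):
            if rng.random() < params.bead_fraction:
                verts = _TETRA_VERTS if rng.random() < 0.5 else _SQUARE_VERTS
                rot = _random_rotation(rng)
                members = pos + r * (verts @ rot.T)
                bead_centers.append(pos.copy())
                keep_pos.extend(members)
                keep_kind.extend(["bead_member"] * 4)
                keep_fil.extend([f] * 4)
                keep_arc.extend([arc] * 4)
            else:
                keep_pos.append(pos)
                keep_kind.append(kind)
                keep_fil.append(f)
                keep_arc.append(arc)
        site_pos = np.asarray(keep_pos, float).reshape(-1, 3)
        site_kinds = keep_kind
        site_fil = np.asarray(keep_fil, int)
        site_arc = np.asarray(keep_arc, float)
    bead_centers = np.asarray(bead_centers, float).reshape(-1, 3)

    # gold labeling
    between_sd = math.sqrt(max(params.tether_length_sd ** 2
                               - params.tether_length_within_sd ** 2, 0.0))
    fil_mean_len = [params.tether_length_mean + rng.normal(0.0, between_sd)
                    if between_sd > 0 else params.tether_length_mean
                    for _ in range(params.n_filaments)]
    fil_base_dir = [_random_unit(rng) for _ in range(params.n_filaments)]

    golds = []
    for i, (pos, f) in enumerate(zip(site_pos, site_fil)):
        if rng.random() >= params.gold_label_fraction:
            continue
        if rng.random() < params.gold_small_fraction:
            diam = _truncated_normal(params.gold_small_diameter_mean,
                                     params.gold_small_diameter_sd,
                                     params.gold_min_diameter, rng)
        else:
            diam = _truncated_normal(params.gold_large_diameter_mean,
                                     params.gold_large_diameter_sd,
                                     params.gold_min_diameter, rng)
        length = max(1.0, fil_mean_len[f] + rng.normal(0.0, params.tether_length_within_sd)
                     if params.tether_length_within_sd > 0 else fil_mean_len[f])
        center = None
        for attempt in range(120):
            if params.tether_direction_mode == "correlated" and attempt < 30:
                direction = _cone_jitter(fil_base_dir[f],
                                         params.tether_direction_jitter_deg, rng)
            else:
                # wall in the preferred direction: fall back to any direction
                direction = _random_unit(rng)
            cand = pos + length * direction
            if np.all(cand >= 1.0) and np.all(cand <= params.box_size - 1.0):
                center = cand
                break
        if center is None:
            center = np.clip(pos + length * direction, 1.0, params.box_size - 1.0)
        golds.append(GoldAttachment(site_index=i, center=center, diameter=diam,
                                    tether_vector=center - pos))

    return GroundTruth(
        filaments=filaments, site_positions=site_pos, site_kinds=site_kinds,
        site_filament=site_fil, site_arc=site_arc, bead_centers=bead_centers,
        gold_attachments=golds,
        true_spacing=params.base_spacing * stride, box_size=params.box_size,
    )


# ---------------------------------------------------------------------------
# rasterization

def _paint_sphere(canvas: np.ndarray, center_vox: np.ndarray, radius_vox: float,
                  value: float) -> None:
    lo = np.maximum(np.floor(center_vox - radius_vox).astype(int) - 1, 0)
    hi = np.minimum(np.ceil(center_vox + radius_vox).astype(int) + 2,
                    np.array(canvas.shape))
    if np.any(hi <= lo):
        return
    ix, iy, iz = [np.arange(lo[a], hi[a]) for a in range(3)]
    d2 = ((ix[:, None, None] - center_vox[0]) ** 2
          + (iy[None, :, None] - center_vox[1]) ** 2
          + (iz[None, None, :] - center_vox[2]) ** 2)
    mask = d2 <= radius_vox ** 2
    if not mask.any():
        # sub-voxel sphere: occupy its nearest voxel
        c = np.clip(np.rint(center_vox).astype(int), 0, np.array(canvas.shape) - 1)
        canvas[tuple(c)] = max(canvas[tuple(c)], value)
        return
    sub = canvas[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    np.maximum(sub, np.where(mask, value, 0.0), out=sub)


def _paint_segment(canvas: np.ndarray, a_vox: np.ndarray, b_vox: np.ndarray,
                   radius_vox: float, value: float) -> None:
    length = np.linalg.norm(b_vox - a_vox)
    n = max(2, int(math.ceil(length / 0.25)) + 1)
    for t in np.linspace(0.0, 1.0, n):
        _paint_sphere(canvas, a_vox + t * (b_vox - a_vox), radius_vox, value)


def _psf_center_fraction(radius_nm: float, sigma_nm: float) -> float:
    """Post-blur peak of a unit sphere: P(chi2_3 <= (R/sigma)^2)."""
    if sigma_nm <= 0:
        return 1.0
    return float(gammainc(1.5, (radius_nm / sigma_nm) ** 2 / 2.0))


_SITE_DIAMETER = {"monomer": "monomer_diameter", "dimer": "dimer_diameter",
                  "bead_member": "monomer_diameter"}


def rasterize(truth: GroundTruth, params: SceneParams) -> DensityVolume:
    """Render a ground-truth scene into an 8-bit density volume.

    Filaments and protein particles are drawn at moderate amplitude;
    gold spheres at high amplitude (each boosted so its post-PSF peak
    reaches ``gold_saturation_target``, emulating the dominant amplitude
    contrast of colloidal gold, which saturates the 8-bit range).  The
    painted scene is convolved with an isotropic Gaussian PSF, offset by
    the background level, degraded with Gaussian noise, then clipped to
    [0, 255] and quantized.  Deterministic for fixed params.
    """
    vs = params.voxel_size
    n = int(round(truth.box_size / vs))
    canvas = np.zeros((n, n, n), dtype=np.float32)

    fil_r = params.filament_diameter / 2.0 / vs
    for poly in truth.filaments:
        pv = np.asarray(poly) / vs
        for a, b in zip(pv[:-1], pv[1:]):
            _paint_segment(canvas, a, b, fil_r, params.filament_amplitude)

    for pos, kind in zip(truth.site_positions, truth.site_kinds):
        d = getattr(params, _SITE_DIAMETER[kind])
        _paint_sphere(canvas, pos / vs, d / 2.0 / vs, params.protein_amplitude)

    if params.render_tethers:
        for g in truth.gold_attachments:
            site = truth.site_positions[g.site_index]
            _paint_segment(canvas, site / vs, g.center / vs,
                           params.tether_radius / vs, params.tether_amplitude)

    # saturation boost: keep the post-PSF peak at the *voxel grid* above the
    # target even for sub-resolution gold whose true center falls between
    # voxel centers (worst-case offset is half a voxel diagonal)
    if params.psf_sigma > 0:
        off = vs * math.sqrt(3.0) / 2.0
        subvoxel_margin = math.exp(off ** 2 / (2.0 * params.psf_sigma ** 2))
    else:
        subvoxel_margin = 1.0
    for g in truth.gold_attachments:
        frac = _psf_center_fraction(g.diameter / 2.0, params.psf_sigma)
        amp = max(params.gold_amplitude,
                  params.gold_saturation_target * subvoxel_margin / max(frac, 1e-6))
        _paint_sphere(canvas, g.center / vs, g.diameter / 2.0 / vs, amp)

    if params.psf_sigma > 0:
        canvas = gaussian_filter(canvas, params.psf_sigma / vs)
    canvas += params.background_level
    if params.noise_sd > 0:
        rng = np.random.default_rng([params.seed, 1])
        canvas += rng.normal(0.0, params.noise_sd, size=canvas.shape)
    canvas = np.rint(np.clip(canvas, 0.0, 255.0)).astype(np.float32)
    return DensityVolume(grid=canvas, voxel_size=vs, origin=np.zeros(3))


def sphere_phantom(centers, diameters, box_size: float, voxel_size: float = 0.8,
                   amplitude: float = 200.0, background: float = 0.0,
                   psf_sigma: float = 0.0, noise_sd: float = 0.0,
                   seed: int = 0) -> DensityVolume:
    """Render bare spheres into a volume (analytic segmentation oracle).

    With ``psf_sigma=0`` and ``noise_sd=0`` the above-threshold region of
    each sphere is exactly the set of voxel centers inside it, so voxel
    counts can be compared against the analytic sphere volume.
    """
    n = int(round(box_size / voxel_size))
    canvas = np.zeros((n, n, n), dtype=np.float32)
    for c, d in zip(np.atleast_2d(centers), np.atleast_1d(diameters)):
        _paint_sphere(canvas, np.asarray(c, float) / voxel_size,
                      d / 2.0 / voxel_size, amplitude)
    if psf_sigma > 0:
        canvas = gaussian_filter(canvas, psf_sigma / voxel_size)
    canvas += background
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        canvas += rng.normal(0.0, noise_sd, size=canvas.shape)
    canvas = np.rint(np.clip(canvas, 0.0, 255.0)).astype(np.float32)
    return DensityVolume(grid=canvas, voxel_size=voxel_size, origin=np.zeros(3))


def scene_particle_table(truth: GroundTruth,
                         params: SceneParams | None = None):
    """Convert ground truth directly into an ideal particle table.

    Bypasses rasterization and segmentation: every decoration site and
    every gold conjugate becomes one particle row with exact coordinates
    and its nominal diameter, so classification/network/fitting stages
    can be exercised free of segmentation error.
    """
    import pandas as pd

    p = params if params is not None else SceneParams(box_size=truth.box_size)
    rows = []
    for pos, kind in zip(truth.site_positions, truth.site_kinds):
        d = getattr(p, _SITE_DIAMETER[kind])
        rows.append((pos[0], pos[1], pos[2], math.pi / 6.0 * d ** 3, d, 150.0))
    for g in truth.gold_attachments:
        d = g.diameter
        rows.append((g.center[0], g.center[1], g.center[2],
                     math.pi / 6.0 * d ** 3, d, 255.0))
    df = pd.DataFrame(rows, columns=["x_nm", "y_nm", "z_nm", "volume_nm3",
                                     "diameter_nm", "peak_intensity"])
    df.insert(0, "id", np.arange(1, len(df) + 1))
    df["voxel_count"] = 0
    df["class"] = "unclassified"
    return df
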
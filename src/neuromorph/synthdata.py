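"""Ground-truth phantom generator for the morphometry pipeline.

Real inputs to this kind of study — iso-surface meshes traced from cleared,
light-sheet-imaged embryonic brains and segmented apical cell lattices —
are not redistributable, so every pipeline input is emulated here with
known ground truth:

* parametric solids (sphere, ellipsoid, cube, hollow cylinder, random
  smooth blob) with closed-form volume/area where one exists;
* brain phantoms: a blob-like outer cortical surface plus a two-lobed
  ventricular surface (two prolate lobes joined at a midline neck), tuned
  so the per-lobe sphericity, the shell thickness implied by the
  hollow-cylinder formula, the brain volume and the intraocular landmark
  distance each hit sampled targets;
* apical lattices: Voronoi tessellations of random seeds, optionally Lloyd
  relaxed (each step moves seeds to cell centroids, increasing order and
  hexagon content), periodic (no border cells) or box-bounded, plus a
  nearest-seed rasteriser producing label images;
* two-genotype synthetic studies whose group means/SDs default to the
  printed group statistics of the embryonic Chd8 cohort this package
  models (wild type n=2, heterozygote n=5).

Everything is deterministic under a master seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import tifffile
import yaml
from scipy import special as _sps
from scipy.optimize import brentq
from scipy.spatial import Voronoi, cKDTree

from .lattice import Cell, CellLattice, LabelImage, polygon_area
from .morphometry import BrainSample, sphericity
from .surfaces import Landmark, Plane, TriMesh, mesh_area, mesh_volume, write_landmarks, write_mesh

__all__ = [
    "make_solid",
    "ellipsoid_area",
    "make_brain_phantom",
    "PhantomTargets",
    "make_voronoi_lattice",
    "hexagonal_seed_points",
    "rasterize_lattice",
    "LatticeTruth",
    "GroupParams",
    "LatticeParams",
    "StudyConfig",
    "default_study_config",
    "generate_study",
    "simulate_study",
    "MIDLINE_PLANE",
]

#: the midline split plane used by generated studies (x = 0)
MIDLINE_PLANE = Plane(point=np.zeros(3), normal=np.array([1.0, 0.0, 0.0]))


# ---------------------------------------------------------------------------
# analytic reference values
# ---------------------------------------------------------------------------


def ellipsoid_area(a: float, b: float, c: float) -> float:
    """Exact surface area of an ellipsoid with semi-axes a, b, c.

    Uses the Legendre incomplete elliptic integral form for the triaxial
    case and the prolate/oblate closed forms for spheroids.
    """
    a, b, c = sorted((float(a), float(b), float(c)), reverse=True)
    if a <= 0:
        raise ValueError("semi-axes must be positive")
    if abs(a - c) < 1e-12 * a:  # sphere
        return 4.0 * math.pi * a * a
    if abs(a - b) < 1e-12 * a:  # oblate (a = b > c)
        e = math.sqrt(1.0 - (c / a) ** 2)
        return 2.0 * math.pi * a * a * (1.0 + (1.0 - e * e) / e * math.atanh(e))
    if abs(b - c) < 1e-12 * a:  # prolate (a > b = c)
        e = math.sqrt(1.0 - (c / a) ** 2)
        return 2.0 * math.pi * c * c * (1.0 + a / (c * e) * math.asin(e))
    phi = math.acos(c / a)
    m = (a * a * (b * b - c * c)) / (b * b * (a * a - c * c))
    f = _sps.ellipkinc(phi, m)
    e = _sps.ellipeinc(phi, m)
    s = math.sin(phi)
    return float(2.0 * math.pi * c * c
                 + 2.0 * math.pi * a * b / s * (e * s * s + f * math.cos(phi) ** 2))


@lru_cache(maxsize=8)
def _unit_icosphere(subdivisions: int):
    import trimesh
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    verts = np.asarray(m.vertices)
    verts = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    return verts, np.asarray(m.faces)


# ---------------------------------------------------------------------------
# parametric solids
# ---------------------------------------------------------------------------


def make_solid(kind: str, refinement: int = 4, seed: int | None = None,
               **params) -> tuple[TriMesh, dict]:
    """Build a closed solid mesh with ground truth.

    Kinds and parameters (lengths in mm):

    ``sphere``            radius
    ``ellipsoid``         semi_axes=(a, b, c)
    ``cube``              side
    ``hollow_cylinder``   r_in, r_out, length, n_segments (prism with
                          annular end caps; truth holds both the smooth
                          analytic values and the exact polygonal-prism
                          volume/side areas)
    ``blob``              radius, amplitude (smooth random radial
                          perturbation; amplitude 0 reproduces the sphere
                          exactly at the same seed)

    Returns ``(mesh, truth)`` where truth maps quantity names to reference
    values; entries suffixed ``_measured`` come from the mesh itself.
    """
    if kind == "sphere":
        r = float(params.get("radius", 1.0))
        if r <= 0:
            raise ValueError("radius must be positive")
        verts, faces = _unit_icosphere(refinement)
        mesh = TriMesh(verts * r, faces, name="sphere")
        truth = {"volume": 4.0 / 3.0 * math.pi * r ** 3,
                 "area": 4.0 * math.pi * r ** 2}
    elif kind == "ellipsoid":
        a, b, c = (float(v) for v in params.get("semi_axes", (1.0, 1.0, 1.0)))
        if min(a, b, c) <= 0:
            raise ValueError("semi-axes must be positive")
        verts, faces = _unit_icosphere(refinement)
        mesh = TriMesh(verts * np.array([a, b, c]), faces, name="ellipsoid")
        truth = {"volume": 4.0 / 3.0 * math.pi * a * b * c,
                 "area": ellipsoid_area(a, b, c)}
    elif kind == "cube":
        s = float(params.get("side", 1.0))
        if s <= 0:
            raise ValueError("side must be positive")
        import trimesh
        box = trimesh.creation.box(extents=(s, s, s))
        mesh = TriMesh(np.asarray(box.vertices), np.asarray(box.faces), name="cube")
        truth = {"volume": s ** 3, "area": 6.0 * s ** 2}
    elif kind == "hollow_cylinder":
        mesh, truth = _hollow_cylinder(
            r_in=float(params["r_in"]), r_out=float(params["r_out"]),
            length=float(params.get("length", 1.0)),
            n_segments=int(params.get("n_segments", 16 * max(refinement, 1))))
    elif kind == "blob":
        r = float(params.get("radius", 1.0))
        amp = float(params.get("amplitude", 0.1))
        if r <= 0:
            raise ValueError("radius must be positive")
        if amp < 0:
            raise ValueError("amplitude must be non-negative")
        verts, faces = _unit_icosphere(refinement)
        if amp > 0:
            rng = np.random.default_rng(seed)
            f = _smooth_field(verts, rng)
            radial = r * (1.0 + amp * f)
        else:
            radial = np.full(len(verts), r)
        mesh = TriMesh(verts * radial[:, None], faces, name="blob")
        truth = {}
    else:
        raise ValueError(f"unknown solid kind {kind!r}")
    truth["volume_measured"] = mesh_volume(mesh)
    truth["area_measured"] = mesh_area(mesh)
    return mesh, truth


def _smooth_field(units: np.ndarray, rng: np.random.Generator,
                  n_lobes: int = 6, width: float = 0.35) -> np.ndarray:
    """Smooth random scalar field on the unit sphere, normalised to max |f| = 1."""
    dirs = rng.normal(size=(n_lobes, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    amps = rng.normal(size=n_lobes)
    f = np.zeros(len(units))
    for d, a in zip(dirs, amps):
        f += a * np.exp((units @ d - 1.0) / width)
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def _hollow_cylinder(r_in: float, r_out: float, length: float,
                     n_segments: int) -> tuple[TriMesh, dict]:
    if not (0 < r_in < r_out):
        raise ValueError("need 0 < r_in < r_out")
    if length <= 0:
        raise ValueError("length must be positive")
    n = n_segments
    theta = 2.0 * math.pi * np.arange(n) / n
    cos, sin = np.cos(theta), np.sin(theta)

    def ring(r, z):
        return np.column_stack([r * cos, r * sin, np.full(n, z)])

    # rings: outer bottom, outer top, inner bottom, inner top
    verts = np.vstack([ring(r_out, 0.0), ring(r_out, length),
                       ring(r_in, 0.0), ring(r_in, length)])
    ob, ot, ib, it = (np.arange(n), np.arange(n) + n,
                      np.arange(n) + 2 * n, np.arange(n) + 3 * n)
    k1 = np.roll(np.arange(n), -1)
    faces = np.vstack([
        np.column_stack([ob, ob[k1], ot[k1]]),       # outer wall
        np.column_stack([ob, ot[k1], ot]),
        np.column_stack([ib, ib[k1], it[k1]])[:, ::-1],  # inner wall (flipped)
        np.column_stack([ib, it[k1], it])[:, ::-1],
        np.column_stack([ob, ib, ib[k1]]),           # bottom annulus (-z)
        np.column_stack([ob, ib[k1], ob[k1]]),
        np.column_stack([ot, ot[k1], it[k1]]),       # top annulus (+z)
        np.column_stack([ot, it[k1], it]),
    ])
    mesh = TriMesh(verts, faces, name="hollow_cylinder")
    s2, s1 = math.sin(2 * math.pi / n), math.sin(math.pi / n)
    poly_ring_area = 0.5 * n * s2 * (r_out ** 2 - r_in ** 2)
    truth = {
        "volume": math.pi * (r_out ** 2 - r_in ** 2) * length,
        "side_area_outer": 2.0 * math.pi * r_out * length,
        "side_area_inner": 2.0 * math.pi * r_in * length,
        "wall_thickness": r_out - r_in,
        # exact values for the N-gon prism actually meshed
        "volume_polygonal": poly_ring_area * length,
        "side_area_outer_polygonal": 2.0 * n * r_out * s1 * length,
        "side_area_inner_polygonal": 2.0 * n * r_in * s1 * length,
        "cap_area_polygonal": poly_ring_area,
    }
    return mesh, truth


# ---------------------------------------------------------------------------
# surfaces of revolution (two-lobed ventricles)
# ---------------------------------------------------------------------------


def _revolve(x: np.ndarray, r: np.ndarray, n_theta: int,
             name: str = "revolve") -> TriMesh:
    """Closed surface of revolution of profile r(x) about the x axis.

    Profile ends with r = 0 become pole vertices; ends with r > 0 are
    closed with a flat disk (centre vertex fan).  Interior samples must
    have r > 0.
    """
    x = np.asarray(x, float)
    r = np.asarray(r, float)
    theta = 2.0 * math.pi * np.arange(n_theta) / n_theta
    cos, sin = np.cos(theta), np.sin(theta)
    ring_idx = []
    verts = []
    for xi, ri in zip(x, r):
        if ri > 0:
            base = len(verts)
            verts.extend(np.column_stack(
                [np.full(n_theta, xi), ri * cos, ri * sin]))
            ring_idx.append(("ring", base))
        else:
            verts.append(np.array([xi, 0.0, 0.0]))
            ring_idx.append(("pole", len(verts) - 1))
    verts = np.asarray(verts)
    k = np.arange(n_theta)
    k1 = np.roll(k, -1)
    faces = []
    # caps at ends
    for end, sign in ((0, -1.0), (len(x) - 1, +1.0)):
        kind, base = ring_idx[end]
        if kind == "ring":  # flat disk
            centre = len(verts)
            verts = np.vstack([verts, [[x[end], 0.0, 0.0]]])
            tri = np.column_stack([np.full(n_theta, centre), base + k, base + k1])
            if sign < 0:
                tri = tri[:, ::-1]
            faces.append(tri)
    # walls between consecutive rings / poles
    for i in range(len(x) - 1):
        ka, a = ring_idx[i]
        kb, b = ring_idx[i + 1]
        if ka == "ring" and kb == "ring":
            faces.append(np.column_stack([a + k, a + k1, b + k1]))
            faces.append(np.column_stack([a + k, b + k1, b + k]))
        elif ka == "pole" and kb == "ring":
            faces.append(np.column_stack([np.full(n_theta, a), b + k1, b + k]))
        elif ka == "ring" and kb == "pole":
            faces.append(np.column_stack([np.full(n_theta, b), a + k, a + k1]))
        else:
            raise ValueError("profile has two consecutive poles")
    return TriMesh(verts, np.vstack(faces), name=name)


def _lobe_profile(elongation: float, overlap: float, n_profile: int,
                  half: bool) -> tuple[np.ndarray, np.ndarray]:
    """Sample the dumbbell (or right-half) radius profile.

    Each lobe is a prolate spheroid with semi-axis ``a = elongation`` along
    x and unit radial semi-axis, centred at ``x = +-c`` with
    ``c = overlap * a`` (< a, so the lobes fuse at a waist on x = 0).
    Cosine-spaced samples cluster at the neck and the poles; x = 0 is
    always included so a midline cut runs exactly along a vertex ring.
    """
    a = float(elongation)
    c = overlap * a
    span = c + a
    t = 0.5 * (1.0 - np.cos(np.linspace(0.0, math.pi, n_profile + 1)))
    xs = t * span  # 0 .. c + a, includes both ends
    rad = np.sqrt(np.clip(1.0 - ((xs - c) / a) ** 2, 0.0, None))
    rad[-1] = 0.0
    if half:
        return xs, rad
    x_full = np.concatenate([-xs[:0:-1], xs])
    r_full = np.concatenate([rad[:0:-1], rad])
    return x_full, r_full


def _half_lobe_sphericity(elongation: float, overlap: float,
                          n_profile: int, n_theta: int) -> float:
    xs, rad = _lobe_profile(elongation, overlap, n_profile, half=True)
    m = _revolve(xs, rad, n_theta)
    return sphericity(mesh_volume(m), mesh_area(m))


@lru_cache(maxsize=4)
def _elongation_table(overlap: float, n_profile: int, n_theta: int):
    """Monotone sphericity-vs-elongation lookup for the half-lobe family.

    The mapping depends only on the fixed discretisation, so it is built
    once and inverted by interpolation; 320 log-spaced knots keep the
    inversion error far below the generator's target SDs."""
    ks = np.geomspace(1.0, 40.0, 320)
    ss = np.array([_half_lobe_sphericity(k, overlap, n_profile, n_theta)
                   for k in ks])
    return ks, ss


def _tune_lobe_elongation(target: float, overlap: float, n_profile: int,
                          n_theta: int) -> float:
    """Lobe elongation whose capped half-lobe sphericity equals ``target``
    (root of a monotone decreasing map, solved on a cached inversion
    table).  Targets above what a (near-)spherical lobe can reach clamp to
    elongation 1; targets above 1 are geometrically impossible."""
    if target > 1.0:
        raise ValueError("targets geometrically unreachable (sphericity > 1)")
    if target <= 0:
        raise ValueError("sphericity target must be positive")
    ks, ss = _elongation_table(overlap, n_profile, n_theta)
    if target >= ss[0]:
        return float(ks[0])
    if target <= ss[-1]:
        raise ValueError(
            f"sphericity target {target} below reachable range (> {ss[-1]:.3f})")
    # ss decreases with k; interpolate k(target) on the reversed table
    return float(np.interp(target, ss[::-1], ks[::-1]))


# ---------------------------------------------------------------------------
# brain phantom
# ---------------------------------------------------------------------------


@dataclass
class PhantomTargets:
    """Per-sample generative targets (mm-based units)."""

    sphericity: float
    intraocular_distance: float
    cortical_thickness: float
    brain_volume: float


def make_brain_phantom(targets: PhantomTargets, *, seed=None,
                       genotype: str = "WT", sample_id: str = "sample",
                       blob_amplitude: float = 0.08, blob_refinement: int = 3,
                       n_profile: int = 40, n_theta: int = 48,
                       lobe_overlap: float = 0.95,
                       ) -> tuple[BrainSample, dict]:
    """Construct a brain phantom hitting all four morphometric targets.

    * outer cortical surface: random smooth blob scaled to the target
      brain volume (exactly, by uniform scaling);
    * ventricular surface: symmetric two-lobed dumbbell whose lobe
      elongation is tuned by bisection so each midline-split lobe has the
      target sphericity; its overall scale is solved so that the
      hollow-cylinder thickness formula, evaluated with the measured outer
      area and ventricular area, returns the target thickness;
    * pupil landmarks placed exactly the target intraocular distance apart.

    Ventricular and outer surfaces are measured independently downstream;
    their spatial nesting is schematic, not anatomical.  Returns the sample
    and a ground-truth dict.  Raises if the targets are geometrically
    unreachable (sphericity > 1, or thickness too large for the volume).
    """
    for name in ("intraocular_distance", "cortical_thickness", "brain_volume"):
        if getattr(targets, name) <= 0:
            raise ValueError(f"{name} target must be positive")
    rng = np.random.default_rng(seed)

    # outer surface: blob scaled to the exact brain volume
    verts, faces = _unit_icosphere(blob_refinement)
    if blob_amplitude > 0:
        f = _smooth_field(verts, rng)
        radial = 1.0 + blob_amplitude * f
    else:
        radial = np.ones(len(verts))
    outer = TriMesh(verts * radial[:, None], faces, name="cortex_outer")
    scale_out = (targets.brain_volume / mesh_volume(outer)) ** (1.0 / 3.0)
    outer = outer.scaled(scale_out)
    v_brain = mesh_volume(outer)
    a_brain = mesh_area(outer)

    # ventricles: tune lobe shape, then solve overall scale for thickness
    elong = _tune_lobe_elongation(targets.sphericity, lobe_overlap,
                                  n_profile, n_theta)
    xs, rad = _lobe_profile(elong, lobe_overlap, n_profile, half=False)
    dumbbell = _revolve(xs, rad, n_theta, name="ventricular")
    v_unit = mesh_volume(dumbbell)
    a_unit = mesh_area(dumbbell)
    t = targets.cortical_thickness
    if 2.0 * v_brain <= t * a_brain:
        raise ValueError(
            "targets geometrically unreachable: thickness too large for volume")

    def excess(v_ventr):
        a_in = a_unit * (v_ventr / v_unit) ** (2.0 / 3.0)
        return 2.0 * (v_brain - v_ventr) - t * (a_brain + a_in)

    v_ventr = brentq(excess, 1e-12 * v_brain, v_brain * (1 - 1e-12),
                     xtol=1e-14 * v_brain)
    scale_v = (v_ventr / v_unit) ** (1.0 / 3.0)
    ventricular = dumbbell.scaled(scale_v)

    # half-lobe reference values (identical to a midline split of the
    # dumbbell: the x = 0 vertex ring makes the cut exact)
    xs_h, rad_h = _lobe_profile(elong, lobe_overlap, n_profile, half=True)
    half = _revolve(xs_h, rad_h, n_theta)
    v_lobe = mesh_volume(half) * scale_v ** 3
    a_lobe = mesh_area(half) * scale_v ** 2

    d = targets.intraocular_distance
    r_brain = (3.0 * v_brain / (4.0 * math.pi)) ** (1.0 / 3.0)
    pupils = (
        Landmark([-d / 2.0, -1.1 * r_brain, 0.0], "pupil_left"),
        Landmark([+d / 2.0, -1.1 * r_brain, 0.0], "pupil_right"),
    )
    sample = BrainSample(sample_id=sample_id, genotype=genotype,
                         cortex_outer=outer, ventricular_surface=ventricular,
                         pupils=pupils)
    a_ventr = a_unit * scale_v ** 2
    truth = {
        "brain_volume": v_brain,
        "brain_area": a_brain,
        "ventricular_volume": v_ventr,
        "ventricular_area": a_ventr,
        "lobe_volume": v_lobe,
        "lobe_area": a_lobe,
        "lobe_sphericity": sphericity(v_lobe, a_lobe),
        "cortical_volume": v_brain - v_ventr,
        "cortical_thickness": 2.0 * (v_brain - v_ventr) / (a_brain + a_ventr),
        "intraocular_distance": d,
        "lobe_elongation": elong,
        "split_plane": {"point": [0.0, 0.0, 0.0], "normal": [1.0, 0.0, 0.0]},
        "targets": asdict(targets),
    }
    return sample, truth


# ---------------------------------------------------------------------------
# Voronoi lattices
# ---------------------------------------------------------------------------


@dataclass
class LatticeTruth:
    """Generator-side ground truth for a synthetic lattice."""

    seeds: np.ndarray                 # final seed points, µm
    domain: tuple[float, float]       # box size (Lx, Ly), µm
    adjacency: dict[int, set[int]]    # 1-based cell ids
    areas: dict[int, float]           # true polygon areas, µm^2
    border: set[int]
    periodic: bool


def hexagonal_seed_points(nx: int, ny: int, spacing: float = 5.0):
    """Seed points of a perfect hexagonal packing commensurate with a
    periodic box; ``ny`` must be even.  Returns ``(points, (Lx, Ly))``."""
    if ny % 2:
        raise ValueError("ny must be even for a periodic hexagonal packing")
    dy = spacing * math.sqrt(3.0) / 2.0
    pts = []
    for j in range(ny):
        off = 0.25 * spacing if j % 2 else -0.25 * spacing
        for i in range(nx):
            pts.append(((i + 0.5) * spacing + off, (j + 0.5) * dy))
    return np.asarray(pts), (nx * spacing, ny * dy)


def _order_ccw(poly: np.ndarray) -> np.ndarray:
    c = poly.mean(axis=0)
    ang = np.arctan2(poly[:, 1] - c[1], poly[:, 0] - c[0])
    return poly[np.argsort(ang)]


def _tile_points(pts: np.ndarray, lx: float, ly: float) -> np.ndarray:
    offs = [(0, 0), (-lx, 0), (lx, 0), (0, -ly), (0, ly),
            (-lx, -ly), (-lx, ly), (lx, -ly), (lx, ly)]
    return np.vstack([pts + np.array(o) for o in offs])


def _mirror_points(pts: np.ndarray, lx: float, ly: float) -> np.ndarray:
    left = pts * [-1, 1]
    right = pts * [-1, 1] + [2 * lx, 0]
    bottom = pts * [1, -1]
    top = pts * [1, -1] + [0, 2 * ly]
    return np.vstack([pts, left, right, bottom, top])


def _central_polygons(vor: Voronoi, n: int) -> list[np.ndarray]:
    polys = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise RuntimeError("unbounded central Voronoi cell")
        polys.append(_order_ccw(vor.vertices[region]))
    return polys


def make_voronoi_lattice(n_cells: int, relaxation_steps: int = 0,
                         seed=None, periodic: bool = True,
                         mean_cell_area: float = 25.0,
                         area_disorder: float = 0.0,
                         seed_points: np.ndarray | None = None,
                         domain: tuple[float, float] | None = None,
                         ) -> tuple[CellLattice, LatticeTruth]:
    """Voronoi tessellation of random seeds with optional Lloyd relaxation.

    The domain is a box of area ``n_cells * mean_cell_area`` (default mean
    apical area 25 µm²).  Each Lloyd step moves every seed to its cell
    centroid, driving the tessellation toward the ordered, hexagon-rich
    packings seen in relaxed epithelia.  ``area_disorder`` adds a final
    Gaussian jitter (in units of the mean cell spacing) to re-disorder the
    packing.  Periodic lattices wrap the box (no border cells); bounded
    lattices clip cells to the box and flag boundary-touching cells as
    border cells.  Cell ids are 1-based to match label-image values.
    """
    if seed_points is None and n_cells < 4:
        raise ValueError("need at least 4 cells")
    rng = np.random.default_rng(seed)
    if seed_points is not None:
        pts = np.asarray(seed_points, dtype=float).copy()
        n = len(pts)
        if domain is None:
            raise ValueError("domain is required with explicit seed_points")
        lx, ly = domain
    else:
        n = n_cells
        if domain is None:
            side = math.sqrt(n * mean_cell_area)
            lx = ly = side
        else:
            lx, ly = domain
        pts = rng.uniform((0, 0), (lx, ly), size=(n, 2))

    def polygons_of(p):
        if periodic:
            vor = Voronoi(_tile_points(p, lx, ly))
        else:
            vor = Voronoi(_mirror_points(p, lx, ly))
        return vor, _central_polygons(vor, n)

    for _ in range(int(relaxation_steps)):
        _, polys = polygons_of(pts)
        cent = []
        for poly in polys:
            x, y = poly[:, 0], poly[:, 1]
            cross = x * np.roll(y, -1) - np.roll(x, -1) * y
            a = 0.5 * cross.sum()
            cx = np.sum((x + np.roll(x, -1)) * cross) / (6 * a)
            cy = np.sum((y + np.roll(y, -1)) * cross) / (6 * a)
            cent.append((cx, cy))
        pts = np.asarray(cent)
        if periodic:
            pts = np.mod(pts, (lx, ly))
        else:
            pts = np.clip(pts, 1e-9, (lx - 1e-9, ly - 1e-9))

    if area_disorder > 0:
        spacing = math.sqrt(mean_cell_area)
        pts = pts + rng.normal(0.0, area_disorder * spacing, size=pts.shape)
        pts = np.mod(pts, (lx, ly)) if periodic else np.clip(
            pts, 1e-9, (lx - 1e-9, ly - 1e-9))

    vor, polys = polygons_of(pts)
    adjacency: dict[int, set[int]] = {i + 1: set() for i in range(n)}
    border: set[int] = set()
    for p, q in vor.ridge_points:
        p, q = int(p), int(q)
        if periodic:
            bp, bq = p % n, q % n
            if (p < n or q < n) and bp != bq:
                adjacency[bp + 1].add(bq + 1)
                adjacency[bq + 1].add(bp + 1)
        else:
            if p < n and q < n:
                adjacency[p + 1].add(q + 1)
                adjacency[q + 1].add(p + 1)
            elif p < n or q < n:
                border.add(min(p, q) + 1)  # neighbours a mirror image
    cells = [
        Cell(i + 1, polys[i], adjacency[i + 1], is_border=(i + 1) in border)
        for i in range(n)
    ]
    truth = LatticeTruth(
        seeds=pts, domain=(lx, ly), adjacency=adjacency,
        areas={i + 1: abs(polygon_area(polys[i])) for i in range(n)},
        border=border, periodic=periodic)
    return CellLattice(cells, periodic=periodic), truth


def rasterize_lattice(truth: LatticeTruth, pixel_size: float = 0.2) -> LabelImage:
    """Nearest-seed label image of a bounded lattice (exact for Voronoi).

    Pixel centres are assigned the 1-based id of the closest seed, which
    reproduces the box-clipped Voronoi tessellation at raster resolution.
    """
    if truth.periodic:
        raise ValueError("rasterisation is defined for bounded lattices")
    if pixel_size <= 0:
        raise ValueError("pixel size must be positive")
    lx, ly = truth.domain
    nx = max(1, int(round(lx / pixel_size)))
    ny = max(1, int(round(ly / pixel_size)))
    xc = (np.arange(nx) + 0.5) * pixel_size
    yc = (np.arange(ny) + 0.5) * pixel_size
    gx, gy = np.meshgrid(xc, yc)
    tree = cKDTree(truth.seeds)
    _, idx = tree.query(np.column_stack([gx.ravel(), gy.ravel()]))
    labels = (idx + 1).astype(np.uint16).reshape(ny, nx)
    return LabelImage(labels, pixel_size)


# ---------------------------------------------------------------------------
# study configuration and generation
# ---------------------------------------------------------------------------


@dataclass
class GroupParams:
    """Per-genotype generative parameters: target (mean, SD) pairs."""

    n_samples: int
    sphericity: tuple[float, float]
    intraocular_distance: tuple[float, float]   # mm
    cortical_thickness: tuple[float, float]     # mm
    brain_volume: tuple[float, float]           # mm^3

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for name in ("sphericity", "intraocular_distance",
                     "cortical_thickness", "brain_volume"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name} SD must be >= 0")
            setattr(self, name, (float(mean), float(sd)))


@dataclass
class LatticeParams:
    n_cells: int = 250
    #: unrelaxed by default: Poisson-Voronoi hexagon/heptagon fractions
    #: (~0.29/~0.19) sit closest to the measured apical lattices
    relaxation_steps: int = 0
    area_disorder: float = 0.0
    mean_cell_area: float = 25.0   # µm^2
    pixel_size: float = 0.2        # µm per pixel


@dataclass
class StudyConfig:
    """Two-genotype synthetic study definition."""

    groups: dict[str, GroupParams]
    lattice: LatticeParams = field(default_factory=LatticeParams)
    seed: int = 0
    blob_amplitude: float = 0.08

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        groups = {g: GroupParams(**{k: tuple(v) if isinstance(v, list) else v
                                    for k, v in p.items()})
                  for g, p in d["groups"].items()}
        lat = LatticeParams(**d.get("lattice", {}))
        return cls(groups=groups, lattice=lat, seed=int(d.get("seed", 0)),
                   blob_amplitude=float(d.get("blob_amplitude", 0.08)))

    def to_dict(self) -> dict:
        return {
            "groups": {g: asdict(p) for g, p in self.groups.items()},
            "lattice": asdict(self.lattice),
            "seed": self.seed,
            "blob_amplitude": self.blob_amplitude,
        }

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path


def default_study_config(seed: int = 0) -> StudyConfig:
    """Study defaults mirroring the printed group statistics of the E12.5
    cohort (wild type n=2, Chd8 heterozygote n=5).

    Metrics reported in print as two individual wild-type values (brain
    volume 3.41 and 3.15 mm^3) enter as their mean with the two-value
    sample SD; the rest are printed mean +- SD.
    """
    wt = GroupParams(
        n_samples=2,
        sphericity=(0.70, 0.01),
        intraocular_distance=(1.75, 0.002),
        cortical_thickness=(0.08, 0.02),
        brain_volume=(3.28, float(np.std([3.41, 3.15], ddof=1))),
    )
    het = GroupParams(
        n_samples=5,
        sphericity=(0.67, 0.03),
        intraocular_distance=(1.85, 0.10),
        cortical_thickness=(0.10, 0.03),
        brain_volume=(3.60, 0.56),
    )
    return StudyConfig(groups={"WT": wt, "HET": het}, seed=seed)


def _draw_truncated(rng, mean, sd, low, high=None):
    """Normal draw truncated (by redraw) to a physical range."""
    if sd == 0:
        return float(np.clip(mean, low, high if high is not None else np.inf))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > low and (high is None or v < high):
            return float(v)
    raise RuntimeError("truncated draw failed; targets far outside range")


def _draw_targets(rng, gp: GroupParams) -> PhantomTargets:
    return PhantomTargets(
        sphericity=_draw_truncated(rng, *gp.sphericity, low=0.05, high=0.97),
        intraocular_distance=_draw_truncated(
            rng, *gp.intraocular_distance, low=1e-6),
        cortical_thickness=_draw_truncated(
            rng, *gp.cortical_thickness, low=1e-6),
        brain_volume=_draw_truncated(rng, *gp.brain_volume, low=1e-6),
    )


def simulate_study(config: StudyConfig, seed: int | None = None,
                   ) -> list[tuple[BrainSample, dict]]:
    """Draw and build all brain phantoms of a study in memory (no files,
    no lattices); used for fast parameter-recovery experiments."""
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    out = []
    for geno in sorted(config.groups):
        gp = config.groups[geno]
        for j in range(gp.n_samples):
            rng = np.random.default_rng(ss.spawn(1)[0])
            targets = _draw_targets(rng, gp)
            sample, truth = make_brain_phantom(
                targets, seed=rng, genotype=geno,
                sample_id=f"{geno.lower()}_{j:03d}",
                blob_amplitude=config.blob_amplitude)
            out.append((sample, truth))
    return out


def generate_study(config: StudyConfig, out_dir, seed: int | None = None,
                   include_lattices: bool = True) -> Path:
    """Write a complete synthetic study to ``out_dir``.

    Layout: ``manifest.json`` at the root plus one directory per sample
    containing ``cortex_outer.ply``, ``ventricular.ply`` (ASCII),
    ``landmarks.csv``, ``labels.tif`` (16-bit label image) and
    ``truth.json``.  Byte-identical for a fixed seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    sample_entries = []
    for geno in sorted(config.groups):
        gp = config.groups[geno]
        for j in range(gp.n_samples):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            sid = f"{geno.lower()}_{j:03d}"
            targets = _draw_targets(rng, gp)
            sample, truth = make_brain_phantom(
                targets, seed=rng, genotype=geno, sample_id=sid,
                blob_amplitude=config.blob_amplitude)
            sdir = out_dir / sid
            sdir.mkdir(exist_ok=True)
            write_mesh(sample.cortex_outer, sdir / "cortex_outer.ply")
            write_mesh(sample.ventricular_surface, sdir / "ventricular.ply")
            write_landmarks(sample.pupils, sdir / "landmarks.csv")
            if include_lattices:
                lat_seed = int(rng.integers(0, 2 ** 31 - 1))
                lattice, lat_truth = make_voronoi_lattice(
                    config.lattice.n_cells,
                    relaxation_steps=config.lattice.relaxation_steps,
                    seed=lat_seed, periodic=False,
                    mean_cell_area=config.lattice.mean_cell_area,
                    area_disorder=config.lattice.area_disorder)
                img = rasterize_lattice(lat_truth, config.lattice.pixel_size)
                tifffile.imwrite(sdir / "labels.tif", img.labels)
                truth["lattice"] = {
                    "n_cells": config.lattice.n_cells,
                    "seed": lat_seed,
                    "pixel_size": config.lattice.pixel_size,
                    "adjacency": {str(k): sorted(v)
                                  for k, v in lat_truth.adjacency.items()},
                    "border": sorted(lat_truth.border),
                    "areas": {str(k): v for k, v in lat_truth.areas.items()},
                }
            truth["genotype"] = geno
            truth["sample_id"] = sid
            (sdir / "truth.json").write_text(
                json.dumps(truth, indent=1, sort_keys=True, default=_jsonify))
            sample_entries.append({"sample_id": sid, "genotype": geno,
                                   "dir": sid})
    manifest = {
        "config": config.to_dict(),
        "split_plane": {"point": [0.0, 0.0, 0.0], "normal": [1.0, 0.0, 0.0]},
        "samples": sample_entries,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return out_dir


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
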
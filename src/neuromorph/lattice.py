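"""Apical-lattice morphometrics.

The apical surface of a pseudostratified neuroepithelium looks like a 2D
polygonal tiling: each cell apex is a polygon, and the packing is described
by each cell's neighbour number n, its apical area, and its elongation.
Two empirical regularities of such tilings are checked here:

* Lewis' law: the mean area of n-sided cells, relative to the overall mean
  area, grows linearly with n,  A_n / A = (n - 2) / 4.

* Aboav-Weaire's law: few-sided cells sit next to many-sided ones, so the
  mean neighbour number m(n) of the cells around an n-sided cell decreases
  weakly with n while n * m(n) is linear in n.  The standard linear form
  m(n) = 5 + 8/n (n * m(n) = 5 n + 8) is the default; an alternative
  decreasing form m(n) = 5 - n/8 is kept available under
  ``form="literal"`` for comparison, since both appear in print.

Statistics exclude border cells (cells touching the field boundary), whose
neighbourhoods are truncated by the field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure as _skmeasure

__all__ = [
    "Cell",
    "CellLattice",
    "LatticeStats",
    "LabelImage",
    "LawFit",
    "LawTables",
    "polygon_area",
    "polygon_moments",
    "cell_aspect_ratio",
    "adjacency_from_labels",
    "interior_stats",
    "stats_from_measurements",
    "lewis_expected",
    "aboav_expected",
    "empirical_law_tables",
]


# ---------------------------------------------------------------------------
# polygon geometry
# ---------------------------------------------------------------------------


def polygon_area(poly: np.ndarray) -> float:
    """Signed shoelace area of a closed vertex loop (CCW positive)."""
    p = np.asarray(poly, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_moments(poly: np.ndarray):
    """Area, centroid and central second-moment (covariance) tensor of a
    simple polygon's interior, by the standard closed-form contour sums.

    Returns ``(area, centroid, cov)`` where ``cov`` is the 2x2 matrix of
    area-normalised central second moments; its eigen-ellipse is the ellipse
    with identical second moments as the polygon.
    """
    p = np.asarray(poly, dtype=float)
    x0, y0 = p[:, 0], p[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    cross = x0 * y1 - x1 * y0
    a = 0.5 * np.sum(cross)
    if a < 0:  # normalise to CCW
        return polygon_moments(p[::-1])
    if a <= 1e-300:
        raise ValueError("degenerate polygon (zero area)")
    cx = np.sum((x0 + x1) * cross) / (6.0 * a)
    cy = np.sum((y0 + y1) * cross) / (6.0 * a)
    # second moments about the origin
    ixx = np.sum((y0 * y0 + y0 * y1 + y1 * y1) * cross) / 12.0
    iyy = np.sum((x0 * x0 + x0 * x1 + x1 * x1) * cross) / 12.0
    ixy = np.sum((x0 * y1 + 2 * x0 * y0 + 2 * x1 * y1 + x1 * y0) * cross) / 24.0
    cov = np.array(
        [
            [iyy / a - cx * cx, ixy / a - cx * cy],
            [ixy / a - cx * cy, ixx / a - cy * cy],
        ]
    )
    return float(a), np.array([cx, cy]), cov


def cell_aspect_ratio(poly: np.ndarray) -> float:
    """Major/minor axis ratio of the moment-equivalent ellipse (>= 1).

    The polygon interior's central second-moment tensor defines a unique
    ellipse with the same second moments; the ratio of its axes is
    sqrt(lambda_max / lambda_min) of the tensor.  Invariant to rotation,
    translation and uniform scaling of the outline.

    ``poly`` may also be an (N, 3) loop of 3D vertices, in which case the
    cell is first projected onto its own best-fit plane (principal plane of
    the vertex cloud), a planar stand-in for measuring on a curved surface.
    """
    p = np.asarray(poly, dtype=float)
    if p.ndim != 2 or len(p) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    if p.shape[1] == 3:
        c = p.mean(axis=0)
        _, _, vt = np.linalg.svd(p - c, full_matrices=False)
        p = (p - c) @ vt[:2].T
    lam = np.linalg.eigvalsh(polygon_moments(p)[2])
    if lam[0] <= 0:
        raise ValueError("degenerate polygon (collinear vertices)")
    return float(np.sqrt(lam[1] / lam[0]))


# ---------------------------------------------------------------------------
# lattice containers
# ---------------------------------------------------------------------------


@dataclass
class Cell:
    cell_id: int
    polygon: np.ndarray  # (N, 2) vertex loop, µm
    neighbours: set[int]
    is_border: bool = False


@dataclass
class CellLattice:
    """A polygonal tessellation with symmetric adjacency and border flags."""

    cells: list[Cell]
    periodic: bool = False

    def __post_init__(self) -> None:
        ids = {c.cell_id for c in self.cells}
        by_id = {c.cell_id: c for c in self.cells}
        for c in self.cells:
            unknown = c.neighbours - ids
            if unknown:
                raise ValueError(f"cell {c.cell_id} lists unknown neighbours {unknown}")
            for j in c.neighbours:
                if c.cell_id not in by_id[j].neighbours:
                    raise ValueError(
                        f"asymmetric adjacency between {c.cell_id} and {j}")

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def interior_cells(self) -> list[Cell]:
        return [c for c in self.cells if not c.is_border]

    def neighbour_counts(self) -> dict[int, int]:
        return {c.cell_id: len(c.neighbours) for c in self.cells}


@dataclass
class LabelImage:
    """Integer label raster: 0 = background, k > 0 = cell k; isotropic pixels."""

    labels: np.ndarray
    pixel_size: float  # µm per pixel

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2D")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")


@dataclass
class LatticeStats:
    """Interior-cell packing statistics of one lattice."""

    n_cells_interior: int
    neighbour_frequencies: dict[int, float]
    mean_neighbour_number: float
    mean_area: float  # µm^2, interior cells
    lewis_table: pd.DataFrame   # columns n, count, mean_area, rel_area
    aboav_table: pd.DataFrame   # columns n, count, m
    aspect_ratios: np.ndarray


def adjacency_from_labels(img: LabelImage, min_contacts: int = 2) -> CellLattice:
    """Reconstruct a :class:`CellLattice` from a segmentation label image.

    Two cells are neighbours iff their labels share at least
    ``min_contacts`` 4-connected pixel contacts (single-pixel corner
    touches are discarded as rasterisation artifacts).  Cells with pixels
    on the image frame are border-flagged.  Cell outlines are traced from
    the label masks at half-pixel resolution and scaled to µm.
    """
    lab = img.labels
    if lab.size == 0:
        raise ValueError("empty label image")
    ids = np.unique(lab)
    ids = ids[ids > 0]
    if len(ids) == 0:
        raise ValueError("label image contains no cells")

    # pixel contacts across horizontal and vertical edges
    pairs = []
    for a, b in ((lab[:, :-1], lab[:, 1:]), (lab[:-1, :], lab[1:, :])):
        m = (a != b) & (a > 0) & (b > 0)
        if m.any():
            lo = np.minimum(a[m], b[m])
            hi = np.maximum(a[m], b[m])
            pairs.append(np.column_stack([lo, hi]))
    adjacency: dict[int, set[int]] = {int(i): set() for i in ids}
    if pairs:
        allp = np.vstack(pairs)
        uniq, counts = np.unique(allp, axis=0, return_counts=True)
        for (i, j), c in zip(uniq, counts):
            if c >= min_contacts:
                adjacency[int(i)].add(int(j))
                adjacency[int(j)].add(int(i))

    frame_labels = set(np.unique(np.concatenate([
        lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]]))) - {0}

    cells = []
    # find_contours on each mask; (row, col) -> (x, y) µm with x = col
    for i in ids:
        mask = np.pad(lab == i, 1)  # pad so frame-touching cells still close
        contours = _skmeasure.find_contours(mask.astype(float), 0.5)
        if not contours:
            raise ValueError(f"label {i} has no traceable outline")
        contour = max(contours, key=len) - 1.0
        poly = np.column_stack([contour[:, 1], contour[:, 0]]) * img.pixel_size
        cells.append(Cell(int(i), poly, adjacency[int(i)],
                          is_border=int(i) in frame_labels))
    return CellLattice(cells, periodic=False)


def interior_stats(lattice: CellLattice) -> LatticeStats:
    """Packing statistics over interior (non-border) cells.

    Mean area, neighbour-number distribution, the per-polygon-class Lewis
    and Aboav-Weaire tables and the aspect-ratio distribution.  Neighbour
    numbers of border cells still enter m(n) of their interior neighbours
    (their own rows are excluded).
    """
    interior = lattice.interior_cells
    if not interior:
        raise ValueError("all cells are border cells")
    n_of = lattice.neighbour_counts()
    ns = np.array([len(c.neighbours) for c in interior])
    areas = np.array([abs(polygon_area(c.polygon)) for c in interior])
    aspect = np.array([cell_aspect_ratio(c.polygon) for c in interior])
    m_vals = np.array([
        np.mean([n_of[j] for j in c.neighbours]) if c.neighbours else np.nan
        for c in interior
    ])
    return stats_from_measurements(ns, areas, aspect_ratios=aspect, m_values=m_vals)


def stats_from_measurements(ns, areas, aspect_ratios=None,
                            m_values=None) -> LatticeStats:
    """Build :class:`LatticeStats` from per-cell arrays.

    ``ns``/``areas`` are per interior cell; ``m_values`` (mean neighbour
    number of each cell's neighbours) may be omitted if no Aboav table is
    needed.  Exposed so custom segmentations can reuse the law machinery.
    """
    ns = np.asarray(ns, dtype=int)
    areas = np.asarray(areas, dtype=float)
    if len(ns) == 0:
        raise ValueError("no cells")
    if len(ns) != len(areas):
        raise ValueError("ns and areas length mismatch")
    classes, counts = np.unique(ns, return_counts=True)
    freqs = {int(k): float(c) / len(ns) for k, c in zip(classes, counts)}
    mean_area = float(np.mean(areas))
    lewis = pd.DataFrame({
        "n": classes,
        "count": counts,
        "mean_area": [float(np.mean(areas[ns == k])) for k in classes],
    })
    lewis["rel_area"] = lewis["mean_area"] / mean_area
    if m_values is not None:
        m_values = np.asarray(m_values, dtype=float)
        aboav = pd.DataFrame({
            "n": classes,
            "count": counts,
            "m": [float(np.nanmean(m_values[ns == k])) for k in classes],
        })
    else:
        aboav = pd.DataFrame(columns=["n", "count", "m"])
    return LatticeStats(
        n_cells_interior=int(len(ns)),
        neighbour_frequencies=freqs,
        mean_neighbour_number=float(np.mean(ns)),
        mean_area=mean_area,
        lewis_table=lewis,
        aboav_table=aboav,
        aspect_ratios=(np.asarray(aspect_ratios, dtype=float)
                       if aspect_ratios is not None else np.array([])),
    )


# ---------------------------------------------------------------------------
# empirical laws
# ---------------------------------------------------------------------------


def lewis_expected(n: int) -> float:
    """Lewis' law reference value A_n / A = (n - 2) / 4."""
    if n < 3:
        raise ValueError("polygon class n must be >= 3")
    return (n - 2) / 4.0


def aboav_expected(n: int, form: str = "standard") -> float:
    """Aboav-Weaire reference m(n) for an n-sided cell.

    ``form="standard"``: m(n) = 5 + 8/n, the classical law with n * m(n)
    linear in n (slope 5, intercept 8).  ``form="literal"``: the decreasing
    variant m(n) = 5 - n/8.
    """
    if n < 3:
        raise ValueError("polygon class n must be >= 3")
    if form == "standard":
        return 5.0 + 8.0 / n
    if form == "literal":
        return 5.0 - n / 8.0
    raise ValueError(f"unknown Aboav-Weaire form {form!r}")


@dataclass
class LawFit:
    slope: float
    intercept: float


@dataclass
class LawTables:
    """Observed-vs-expected tables and weighted linear fits for both laws."""

    lewis: pd.DataFrame        # n, count, observed rel_area, expected
    aboav: pd.DataFrame        # n, count, observed m, expected m, n*m
    lewis_fit: LawFit          # rel_area vs n
    aboav_fit: LawFit          # n*m(n) vs n
    aboav_form: str

    def to_frame(self) -> pd.DataFrame:
        lw = self.lewis.assign(law="lewis").rename(
            columns={"rel_area": "observed"})
        ab = self.aboav.assign(law="aboav").rename(columns={"m": "observed"})
        cols = ["law", "n", "count", "observed", "expected"]
        return pd.concat([lw[cols], ab[cols]], ignore_index=True)


def _wls_line(x, y, w) -> LawFit:
    coeff = np.polyfit(np.asarray(x, float), np.asarray(y, float), 1,
                       w=np.sqrt(np.asarray(w, float)))
    return LawFit(slope=float(coeff[0]), intercept=float(coeff[1]))


def empirical_law_tables(stats: LatticeStats, min_class_count: int = 5,
                         aboav_form: str = "standard") -> LawTables:
    """Check a measured lattice against Lewis' and Aboav-Weaire's laws.

    Polygon classes with fewer than ``min_class_count`` cells are dropped
    (their class means are noise); at least three classes must remain.
    Fits are count-weighted least squares of rel_area against n (Lewis) and
    of n * m(n) against n (Aboav-Weaire).
    """
    lw = stats.lewis_table
    lw = lw[lw["count"] >= min_class_count].reset_index(drop=True)
    if len(lw) < 3:
        raise ValueError(
            f"need >= 3 polygon classes with >= {min_class_count} cells, "
            f"have {len(lw)}")
    lw = lw.assign(expected=[lewis_expected(int(n)) for n in lw["n"]])
    lewis_fit = _wls_line(lw["n"], lw["rel_area"], lw["count"])

    ab = stats.aboav_table
    ab = ab[ab["count"] >= min_class_count].reset_index(drop=True)
    if len(ab) >= 3 and not ab["m"].isna().any():
        ab = ab.assign(
            expected=[aboav_expected(int(n), aboav_form) for n in ab["n"]],
            nm=ab["n"] * ab["m"],
        )
        aboav_fit = _wls_line(ab["n"], ab["nm"], ab["count"])
    else:
        ab = ab.assign(expected=np.nan, nm=np.nan)
        aboav_fit = LawFit(np.nan, np.nan)

    return LawTables(lewis=lw, aboav=ab, lewis_fit=lewis_fit,
                     aboav_fit=aboav_fit, aboav_form=aboav_form)
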
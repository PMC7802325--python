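"""Organ-scale morphometrics for embryonic brain surfaces.

The two scalar descriptors at the centre of this module are

* sphericity of a closed body,  S = pi^(1/3) (6V)^(2/3) / A,
  the area of the volume-equivalent sphere over the actual area (1 for a
  perfect sphere, < 1 otherwise by the isoperimetric inequality), and

* cortical thickness under a hollow-cylinder idealisation of the cortex,
  h = 2 V_cortex / (A_outer + A_inner),
  i.e. wall volume over the mean of the bounding areas.  For a true
  cylindrical or thin concentric shell this equals the wall thickness
  exactly; for thick strongly curved shells it carries a small systematic
  bias which is documented rather than corrected.

A :class:`BrainSample` bundles the named surfaces (outer cortex, ventricular
system) with pupil landmarks; :func:`analyze_sample` measures everything and
:func:`summarize_groups` aggregates per genotype, counting ventricle-level
metrics per lobe (two lobes per brain) and brain-level metrics per animal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .surfaces import (
    Landmark,
    Plane,
    TriMesh,
    landmark_distance,
    mesh_area,
    mesh_volume,
    split_by_plane,
)

__all__ = [
    "BrainSample",
    "MorphometricRecord",
    "GroupSummary",
    "sphericity",
    "cortical_thickness",
    "analyze_sample",
    "summarize_groups",
    "records_to_frame",
    "BRAIN_LEVEL_METRICS",
    "VENTRICLE_LEVEL_METRICS",
]

GENOTYPES = ("WT", "HET")

#: metrics reported once per animal
BRAIN_LEVEL_METRICS = (
    "brain_volume",
    "cortical_volume",
    "brain_area",
    "cortical_thickness",
    "intraocular_distance",
)
#: metrics reported once per ventricular lobe (n doubles per animal)
VENTRICLE_LEVEL_METRICS = (
    "ventricle_volume",
    "ventricle_area",
    "ventricle_sphericity",
)


def sphericity(volume: float, area: float) -> float:
    """Sphericity S = pi^(1/3) (6 V)^(2/3) / A of a closed body.

    Dimensionless, equals 1 for a sphere and is < 1 for every other closed
    surface.  Raises on non-positive inputs.
    """
    if volume <= 0 or area <= 0:
        raise ValueError(f"sphericity needs positive V and A, got V={volume}, A={area}")
    return float(math.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area)


def cortical_thickness(v_cortex: float, a_outer: float, a_inner: float) -> float:
    """Cortical wall height h = 2 V / (A_outer + A_inner) (mm).

    Treats the cortex as a hollow cylinder of wall volume ``v_cortex``
    bounded by the outer brain surface and the inner (ventricular) surface.
    Exact for cylindrical side walls (h = r_out - r_in); a thin-shell
    approximation otherwise.
    """
    if v_cortex <= 0 or a_outer <= 0 or a_inner <= 0:
        raise ValueError("cortical_thickness needs positive volume and areas")
    return float(2.0 * v_cortex / (a_outer + a_inner))


@dataclass
class BrainSample:
    """Named surfaces and landmarks for one animal."""

    sample_id: str
    genotype: str
    cortex_outer: TriMesh
    ventricular_surface: TriMesh
    pupils: tuple[Landmark, Landmark]
    left_ventricle: TriMesh | None = None
    right_ventricle: TriMesh | None = None

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")


@dataclass
class MorphometricRecord:
    """All per-sample measurements (mm-based units)."""

    sample_id: str
    genotype: str
    brain_volume: float
    cortical_volume: float
    ventricle_volumes: tuple[float, float]
    brain_area: float
    ventricle_areas: tuple[float, float]
    sphericity_per_ventricle: tuple[float, float]
    cortical_thickness: float
    intraocular_distance: float
    #: interpretation: same thickness formula on the plane-split half shells
    cortical_thickness_lobes: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for v in (self.brain_volume, self.cortical_volume, self.brain_area,
                  *self.ventricle_volumes, *self.ventricle_areas):
            if v <= 0:
                raise ValueError("volumes and areas must be positive")
        for s in self.sphericity_per_ventricle:
            if not (0.0 < s <= 1.0 + 1e-6):
                raise ValueError(f"sphericity {s} outside (0, 1]")


@dataclass
class GroupSummary:
    metric: str
    genotype: str
    n: int
    mean: float
    sd: float | None  # sample SD (n-1); omitted when n < 2


def analyze_sample(sample: BrainSample, split_plane: Plane,
                   lobe_thickness: bool = False) -> MorphometricRecord:
    """Measure every morphometric of one brain sample.

    The ventricular surface is split at ``split_plane`` (the midline through
    the septum pellucidum) into left/right lobes; per-lobe volume, area and
    sphericity are reported with left = negative side of the plane normal.
    Cortical volume is brain volume minus total ventricular volume, and the
    thickness formula uses the outer brain area and the (uncut) ventricular
    area as the two bounding surfaces.

    With ``lobe_thickness=True`` the outer surface is split by the same
    plane and the thickness formula is additionally applied per half shell;
    this lobe-wise readout is an interpretation, not a measured wall width.
    """
    v_brain = mesh_volume(sample.cortex_outer)
    a_brain = mesh_area(sample.cortex_outer)
    v_ventr_total = mesh_volume(sample.ventricular_surface)
    a_ventr_total = mesh_area(sample.ventricular_surface)
    if v_ventr_total >= v_brain:
        raise ValueError("ventricular volume must be smaller than brain volume")

    left, right = split_by_plane(sample.ventricular_surface, split_plane)
    sample.left_ventricle, sample.right_ventricle = left, right
    v_lobes = (mesh_volume(left), mesh_volume(right))
    a_lobes = (mesh_area(left), mesh_area(right))
    s_lobes = tuple(
        min(sphericity(v, a), 1.0) for v, a in zip(v_lobes, a_lobes)
    )

    v_cortex = v_brain - v_ventr_total
    h = cortical_thickness(v_cortex, a_brain, a_ventr_total)

    h_lobes = None
    if lobe_thickness:
        outer_l, outer_r = split_by_plane(sample.cortex_outer, split_plane)
        h_lobes = tuple(
            cortical_thickness(
                mesh_volume(mo) - vv, mesh_area(mo), av)
            for mo, vv, av in zip((outer_l, outer_r), v_lobes, a_lobes)
        )

    return MorphometricRecord(
        sample_id=sample.sample_id,
        genotype=sample.genotype,
        brain_volume=v_brain,
        cortical_volume=v_cortex,
        ventricle_volumes=v_lobes,
        brain_area=a_brain,
        ventricle_areas=a_lobes,
        sphericity_per_ventricle=s_lobes,
        cortical_thickness=h,
        intraocular_distance=landmark_distance(*sample.pupils),
        cortical_thickness_lobes=h_lobes,
    )


def records_to_frame(records: list[MorphometricRecord]) -> pd.DataFrame:
    """Long-format table: one row per (sample, metric, value).

    Ventricle-level metrics appear twice per sample (one row per lobe).
    """
    rows = []
    for r in records:
        for m in BRAIN_LEVEL_METRICS:
            rows.append((r.sample_id, r.genotype, m, getattr(r, m)))
        for lobe, v, a, s in zip(("left", "right"), r.ventricle_volumes,
                                 r.ventricle_areas, r.sphericity_per_ventricle):
            rows.append((f"{r.sample_id}:{lobe}", r.genotype, "ventricle_volume", v))
            rows.append((f"{r.sample_id}:{lobe}", r.genotype, "ventricle_area", a))
            rows.append((f"{r.sample_id}:{lobe}", r.genotype, "ventricle_sphericity", s))
    return pd.DataFrame(rows, columns=["unit_id", "genotype", "metric", "value"])


def summarize_groups(records: list[MorphometricRecord]) -> list[GroupSummary]:
    """Per metric x genotype: n, mean and sample SD (n-1 denominator).

    Ventricle-level metrics are pooled across lobes, so two brains
    contribute n = 4 ventricle observations; brain-level metrics count one
    observation per animal.  Order of the input records does not matter.
    """
    if not records:
        raise ValueError("summarize_groups needs at least one record")
    frame = records_to_frame(records)
    out: list[GroupSummary] = []
    metrics = list(BRAIN_LEVEL_METRICS) + list(VENTRICLE_LEVEL_METRICS)
    for metric in metrics:
        for geno in GENOTYPES:
            vals = frame.loc[
                (frame.metric == metric) & (frame.genotype == geno), "value"
            ].to_numpy()
            if len(vals) == 0:
                continue
            sd = float(np.std(vals, ddof=1)) if len(vals) >= 2 else None
            out.append(GroupSummary(metric, geno, len(vals), float(np.mean(vals)), sd))
    return out


def summaries_to_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.metric, s.genotype, s.n, s.mean, s.sd) for s in summaries],
        columns=["metric", "genotype", "n", "mean", "sd"],
    )
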
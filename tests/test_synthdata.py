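"""Phantom generator: determinism, ground truth, lattices, study layout."""

import json
import math

import numpy as np
import pytest

from neuromorph.lattice import interior_stats
from neuromorph.morphometry import analyze_sample, summarize_groups
from neuromorph.surfaces import landmark_distance, mesh_area, mesh_volume
from neuromorph.synthdata import (
    MIDLINE_PLANE,
    GroupParams,
    LatticeParams,
    PhantomTargets,
    StudyConfig,
    default_study_config,
    ellipsoid_area,
    generate_study,
    make_brain_phantom,
    make_solid,
    make_voronoi_lattice,
    simulate_study,
)


class TestSolids:
    def test_sphere_truth(self):
        m, t = make_solid("sphere", refinement=4, radius=0.7)
        assert m.is_closed()
        assert t["volume_measured"] == pytest.approx(t["volume"], rel=5e-3)
        assert t["area_measured"] == pytest.approx(t["area"], rel=5e-3)

    def test_blob_amplitude_zero_equals_sphere(self):
        blob, _ = make_solid("blob", radius=1.3, amplitude=0.0, seed=5)
        sphere, _ = make_solid("sphere", radius=1.3)
        assert np.array_equal(blob.vertices, sphere.vertices)
        assert np.array_equal(blob.faces, sphere.faces)

    def test_blob_deterministic_under_seed(self):
        a, _ = make_solid("blob", radius=1.0, amplitude=0.2, seed=11)
        b, _ = make_solid("blob", radius=1.0, amplitude=0.2, seed=11)
        assert np.array_equal(a.vertices, b.vertices)

    def test_hollow_cylinder_invalid_radii(self):
        with pytest.raises(ValueError):
            make_solid("hollow_cylinder", r_in=1.2, r_out=1.0, length=2.0)

    def test_hollow_cylinder_polygonal_truth_exact(self):
        m, t = make_solid("hollow_cylinder", r_in=0.8, r_out=1.1,
                          length=3.0, n_segments=48)
        assert mesh_volume(m) == pytest.approx(t["volume_polygonal"],
                                               rel=1e-12)
        assert mesh_area(m) == pytest.approx(
            t["side_area_outer_polygonal"] + t["side_area_inner_polygonal"]
            + 2 * t["cap_area_polygonal"], rel=1e-12)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            make_solid("torus")


def test_ellipsoid_area_matches_spheroid_closed_forms():
    # prolate a > b = c
    a, c = 2.0, 1.0
    e = math.sqrt(1 - (c / a) ** 2)
    prolate = 2 * math.pi * c * c * (1 + a / (c * e) * math.asin(e))
    assert ellipsoid_area(a, c, c) == pytest.approx(prolate, rel=1e-12)
    # triaxial value between the bounding spheroid areas
    tri = ellipsoid_area(2.0, 1.5, 1.0)
    assert ellipsoid_area(2.0, 1.0, 1.0) < tri < ellipsoid_area(2.0, 2.0, 1.5)
    assert ellipsoid_area(1.0, 1.0, 1.0) == pytest.approx(4 * math.pi)


class TestBrainPhantom:
    def test_targets_hit_exactly_by_construction(self):
        t = PhantomTargets(0.68, 1.85, 0.10, 3.60)
        sample, truth = make_brain_phantom(t, seed=3)
        assert truth["brain_volume"] == pytest.approx(3.60, rel=1e-12)
        assert truth["cortical_thickness"] == pytest.approx(0.10, rel=1e-9)
        assert truth["lobe_sphericity"] == pytest.approx(0.68, abs=1e-4)
        assert landmark_distance(*sample.pupils) == pytest.approx(
            1.85, rel=1e-12)

    def test_sphericity_above_one_unreachable(self):
        with pytest.raises(ValueError, match="unreachable"):
            make_brain_phantom(PhantomTargets(1.2, 1.0, 0.1, 3.0), seed=1)

    def test_thickness_too_large_unreachable(self):
        with pytest.raises(ValueError, match="unreachable"):
            make_brain_phantom(PhantomTargets(0.7, 1.0, 5.0, 1.0), seed=1)

    def test_ventricles_smaller_than_brain(self):
        sample, truth = make_brain_phantom(
            PhantomTargets(0.70, 1.75, 0.08, 3.41), seed=4)
        assert mesh_volume(sample.ventricular_surface) < mesh_volume(
            sample.cortex_outer)

    def test_meshes_closed(self):
        sample, _ = make_brain_phantom(
            PhantomTargets(0.72, 1.7, 0.09, 3.2), seed=5)
        assert sample.cortex_outer.is_closed()
        assert sample.ventricular_surface.is_closed()

    def test_dumbbell_split_ratio_matches_truth(self):
        from neuromorph.surfaces import split_by_plane
        sample, truth = make_brain_phantom(
            PhantomTargets(0.66, 1.8, 0.1, 3.5), seed=6)
        left, right = split_by_plane(sample.ventricular_surface, MIDLINE_PLANE)
        ratio = mesh_volume(left) / mesh_volume(right)
        assert ratio == pytest.approx(1.0, rel=2e-2)
        assert mesh_volume(left) == pytest.approx(truth["lobe_volume"],
                                                  rel=2e-2)


class TestVoronoiLattice:
    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            make_voronoi_lattice(3)

    def test_deterministic(self):
        a, ta = make_voronoi_lattice(100, relaxation_steps=2, seed=9)
        b, tb = make_voronoi_lattice(100, relaxation_steps=2, seed=9)
        assert np.array_equal(ta.seeds, tb.seeds)
        assert all(x.neighbours == y.neighbours
                   for x, y in zip(a.cells, b.cells))

    def test_periodic_has_no_border_cells(self):
        lat, _ = make_voronoi_lattice(100, seed=2, periodic=True)
        assert not any(c.is_border for c in lat.cells)

    def test_periodic_mean_neighbour_number_is_six(self):
        lat, _ = make_voronoi_lattice(600, relaxation_steps=2, seed=8,
                                      periodic=True)
        st = interior_stats(lat)
        assert st.mean_neighbour_number == pytest.approx(6.0, abs=0.02)

    def test_relaxation_increases_hexagon_fraction(self):
        raw, relaxed = [], []
        for seed in (1, 2, 3, 4, 5):
            l0, _ = make_voronoi_lattice(300, relaxation_steps=0, seed=seed)
            l1, _ = make_voronoi_lattice(300, relaxation_steps=10, seed=seed)
            raw.append(interior_stats(l0).neighbour_frequencies.get(6, 0))
            relaxed.append(interior_stats(l1).neighbour_frequencies.get(6, 0))
        assert np.mean(relaxed) > np.mean(raw)

    def test_mean_area_matches_domain(self):
        lat, tr = make_voronoi_lattice(200, seed=7, periodic=True,
                                       mean_cell_area=25.0)
        assert np.mean(list(tr.areas.values())) == pytest.approx(25.0,
                                                                 rel=1e-9)


class TestStudy:
    def test_layout_and_manifest(self, small_study):
        path, cfg = small_study
        manifest = json.loads((path / "manifest.json").read_text())
        assert len(manifest["samples"]) == 7
        genos = [s["genotype"] for s in manifest["samples"]]
        assert genos.count("WT") == 2 and genos.count("HET") == 5
        sdir = path / manifest["samples"][0]["dir"]
        for fname in ("cortex_outer.ply", "ventricular.ply",
                      "landmarks.csv", "labels.tif", "truth.json"):
            assert (sdir / fname).is_file()

    def test_regeneration_is_byte_identical(self, tmp_path):
        cfg = default_study_config(seed=3)
        cfg.groups["WT"].n_samples = 1
        cfg.groups["HET"].n_samples = 1
        cfg.lattice.n_cells = 40
        a = generate_study(cfg, tmp_path / "a")
        b = generate_study(cfg, tmp_path / "b")
        for fa in sorted(a.rglob("*")):
            if fa.is_file():
                fb = b / fa.relative_to(a)
                assert fb.read_bytes() == fa.read_bytes(), fa.name

    def test_zero_sd_config_hits_means_exactly(self):
        cfg = StudyConfig(groups={
            "WT": GroupParams(2, (0.70, 0.0), (1.75, 0.0), (0.08, 0.0),
                              (3.41, 0.0))})
        sims = simulate_study(cfg, seed=5)
        for sample, truth in sims:
            assert truth["targets"]["sphericity"] == 0.70
            rec = analyze_sample(sample, MIDLINE_PLANE)
            assert rec.brain_volume == pytest.approx(3.41, rel=1e-9)
            assert rec.intraocular_distance == pytest.approx(1.75, rel=1e-12)
            assert rec.cortical_thickness == pytest.approx(0.08, rel=1e-9)
            for s in rec.sphericity_per_ventricle:
                assert s == pytest.approx(0.70, abs=1e-4)

    def test_group_mean_recovery_moderate_n(self):
        cfg = StudyConfig(groups={
            "WT": GroupParams(12, (0.70, 0.01), (1.75, 0.002), (0.08, 0.02),
                              (3.28, 0.18)),
        })
        sims = simulate_study(cfg, seed=42)
        recs = [analyze_sample(s, MIDLINE_PLANE) for s, _ in sims]
        out = {(s.metric, s.genotype): s for s in summarize_groups(recs)}
        s = out[("ventricle_sphericity", "WT")]
        assert abs(s.mean - 0.70) < 3 * 0.01 / math.sqrt(12)
        d = out[("intraocular_distance", "WT")]
        assert abs(d.mean - 1.75) < 3 * 0.002 / math.sqrt(12)

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = default_study_config(seed=11)
        p = cfg.to_yaml(tmp_path / "cfg.yaml")
        back = StudyConfig.from_yaml(p)
        assert back.to_dict() == cfg.to_dict()
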
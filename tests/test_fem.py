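import dataclasses

import numpy as np
import pytest

from palpinv import fem
from palpinv.fem import DeformationField, FeatureTriple, FemConfig
from palpinv.phantom import InclusionScenario


class TestBuildModel:
    def test_inclusion_elements_near_sphere_centre(self, reference_scenario, coarse_cfg):
        # 8 mm sphere, top 5 mm deep in a 20 mm slab: centre at depth 9 mm
        model = fem.build_model(reference_scenario, coarse_cfg)
        cent = model.nodes[model.elements[model.region == 1]].mean(axis=1)
        zc = 20.0 - 5.0 - 4.0
        dist = np.sqrt(cent[:, 0] ** 2 + cent[:, 1] ** 2 + (cent[:, 2] - zc) ** 2)
        assert len(cent) > 0
        assert dist.max() <= 4.0 + 1e-9

    def test_homogeneous_limit_has_uniform_tissue_modulus(self, coarse_cfg):
        s = InclusionScenario(d=8, h=5, E_inc=5.0)
        model = fem.build_model(s, coarse_cfg)
        tissue = model.region != 2
        assert np.all(model.E[tissue] == 5.0)

    def test_mesh_volume_matches_box(self, reference_scenario, coarse_cfg):
        model = fem.build_model(reference_scenario, coarse_cfg)
        tissue = model.region != 2
        vol = model.dims[tissue].prod(axis=1).sum()
        if model.symmetry:
            vol *= 4
        box = reference_scenario.tissue_side**2 * reference_scenario.tissue_thickness
        assert abs(vol - box) / box < 1e-3

    def test_too_coarse_resolution_rejected(self):
        with pytest.raises(ValueError, match="coarse"):
            fem.build_model(InclusionScenario(d=2, h=5, E_inc=120), FemConfig(fine_h=2.0))

    def test_oversized_probe_rejected(self):
        s = InclusionScenario(d=8, h=5, E_inc=120, probe_side=200.0)
        with pytest.raises(ValueError, match="probe"):
            fem.build_model(s, FemConfig(fine_h=2.0))


class TestSolve:
    def test_uniaxial_confined_slab_oracle(self):
        # 2x2x2 cube, confined sides, frictionless base, uniform top travel:
        # exact solution u = (0, 0, -indent z / H)
        m = fem.uniaxial_slab_model(E=5.0, nu=0.49, side=20.0, thickness=20.0, n=(2, 2, 2))
        u = fem.solve_displacements(m, 1.0)
        exact = np.zeros_like(u)
        exact[:, 2] = -m.nodes[:, 2] / 20.0
        assert np.abs(u - exact).max() <= 1e-8 * np.abs(exact).max()

    def test_internal_profile_linear_in_depth(self):
        # finer confined slab: vertical displacement linear through thickness
        m = fem.uniaxial_slab_model(E=5.0, nu=0.49, side=120.0, thickness=20.0, n=(6, 6, 10))
        u = fem.solve_displacements(m, 1.0)
        expected = -m.nodes[:, 2] / 20.0
        assert np.abs(u[:, 2] - expected).max() <= 5e-3

    def test_homogeneous_full_width_probe_uniform_field(self, coarse_cfg):
        # confined sides + full-width probe reproduce uniform compression
        s = InclusionScenario(d=8, h=5, E_inc=5.0, probe_side=120.0)
        cfg = dataclasses.replace(coarse_cfg, confine_sides=True)
        field = fem.solve_indentation(fem.build_model(s, cfg))
        assert (field.w.max() - field.w.min()) <= 0.01 * abs(field.w.mean())

    def test_linearity_in_indent(self, reference_scenario, coarse_cfg):
        model = fem.build_model(reference_scenario, coarse_cfg)
        f1 = fem.solve_indentation(model, indent=1.0)
        f2 = fem.solve_indentation(model, indent=2.0)
        assert np.abs(f2.w - 2 * f1.w).max() <= 1e-8 * np.abs(f2.w).max()

    def test_full_mesh_field_symmetric(self, reference_scenario):
        cfg = FemConfig(fine_h=2.0, symmetry=False)
        field = fem.solve_indentation(fem.build_model(reference_scenario, cfg))
        w = field.w
        scale = np.abs(w).max()
        assert np.abs(w - w[::-1, :]).max() <= 0.01 * scale
        assert np.abs(w - w[:, ::-1]).max() <= 0.01 * scale
        assert np.abs(w - w.T).max() <= 0.01 * scale

    def test_quarter_and_full_models_agree(self, reference_scenario):
        wq = fem.solve_indentation(
            fem.build_model(reference_scenario, FemConfig(fine_h=2.0, symmetry=True))
        )
        wf = fem.solve_indentation(
            fem.build_model(reference_scenario, FemConfig(fine_h=2.0, symmetry=False))
        )
        assert np.abs(wq.w - wf.w).max() <= 0.02 * np.abs(wf.w).max()

    def test_excessive_indent_rejected(self, reference_scenario, coarse_cfg):
        model = fem.build_model(reference_scenario, coarse_cfg)
        with pytest.raises(ValueError, match="25%"):
            fem.solve_displacements(model, 6.0)

    def test_stiffer_inclusion_deforms_probe_more(self, coarse_cfg):
        f40 = fem.forward(InclusionScenario(d=8, h=5, E_inc=40), coarse_cfg)
        f120 = fem.forward(InclusionScenario(d=8, h=5, E_inc=120), coarse_cfg)
        assert f120.f1 > f40.f1


class TestQuantify:
    def test_zero_field(self):
        f = DeformationField(x=np.arange(4.0), y=np.arange(4.0), w=np.zeros((4, 4)))
        t = fem.quantify_deformation(f)
        assert (t.f1, t.f2, t.f3) == (0.0, 0.0, 0.0)

    def test_single_support_field(self):
        w = np.zeros((5, 5))
        w[2, 2] = 0.3
        f = DeformationField(x=np.arange(5.0), y=np.arange(5.0), w=w)
        t = fem.quantify_deformation(f, eps=1e-6)
        assert (t.f1, t.f2, t.f3) == (0.3, 0.3, 1.0)

    def test_total_dominates_max_on_nonnegative_fields(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            w = rng.uniform(0, 1, (8, 8))
            f = DeformationField(x=np.arange(8.0), y=np.arange(8.0), w=w)
            t = fem.quantify_deformation(f)
            assert t.f2 >= t.f1

    def test_non_finite_field_rejected(self):
        w = np.full((3, 3), np.nan)
        with pytest.raises(ValueError):
            DeformationField(x=np.arange(3.0), y=np.arange(3.0), w=w)


class TestForwardTrends:
    """The documented forward-model trends, on the coarse mesh (3-point sweeps).

    The full 5-point sweeps at default resolution run in the acceptance suite.
    """

    def test_features_nondecreasing_in_size(self, coarse_cfg):
        feats = [
            fem.forward(InclusionScenario(d=d, h=5, E_inc=120), coarse_cfg).as_array()
            for d in (6, 10, 14)
        ]
        assert np.all(np.diff(np.array(feats), axis=0) >= -1e-12)

    def test_features_nonincreasing_in_depth(self, coarse_cfg):
        feats = [
            fem.forward(InclusionScenario(d=8, h=h, E_inc=120), coarse_cfg).as_array()
            for h in (3, 7, 12)
        ]
        assert np.all(np.diff(np.array(feats), axis=0) <= 1e-12)

    def test_features_nondecreasing_in_modulus(self, coarse_cfg):
        feats = [
            fem.forward(InclusionScenario(d=8, h=5, E_inc=e), coarse_cfg).as_array()
            for e in (20, 70, 120)
        ]
        assert np.all(np.diff(np.array(feats), axis=0) >= -1e-12)

    def test_homogeneous_scenario_gives_zero_features(self, coarse_cfg):
        t = fem.forward(InclusionScenario(d=8, h=5, E_inc=5.0), coarse_cfg)
        assert (t.f1, t.f2, t.f3) == (0.0, 0.0, 0.0)


def test_feature_triple_unit_tag():
    with pytest.raises(ValueError):
        FeatureTriple(1.0, 2.0, 3.0, unit_system="pixels")


def test_mesh_text_round_trip(tmp_path, reference_scenario, coarse_cfg):
    model = fem.build_model(reference_scenario, coarse_cfg)
    path = tmp_path / "mesh.txt"
    fem.write_mesh(model, path)
    back = fem.read_mesh(path)
    assert np.array_equal(back.nodes, model.nodes)
    assert np.array_equal(back.elements, model.elements)
    assert np.array_equal(back.E, model.E)
    assert np.array_equal(back.region, model.region)
    assert np.array_equal(back.ties, model.ties)
    # solving the re-read model reproduces the field
    f0 = fem.solve_indentation(model, indent=2.0)
    back.config = model.config
    f1 = fem.solve_indentation(back, indent=2.0)
    assert np.allclose(f0.w, f1.w, atol=1e-12)
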
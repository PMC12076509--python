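"""Cone angles, surrogate-frame distances and feature vectors."""
from __future__ import annotations

import numpy as np
import pytest

from porphgeom import make_template
from porphgeom.descriptors import (
    FEATURE_NAMES,
    ConeAngleError,
    NO_AXIAL_SENTINEL,
    SubstituentGeometry,
    build_feature_vector,
    cone_angle,
    metal_radius,
    surrogate_distance,
)
from porphgeom.elements import covalent_radius
from porphgeom.synthetic_data import RING_SUBSTITUENTS


def _sub(positions, radii, apex=(0, 0, 0)):
    return SubstituentGeometry(apex=np.asarray(apex, dtype=float),
                               positions=np.asarray(positions, dtype=float),
                               radii=np.asarray(radii, dtype=float))


def _library_sub(key):
    atoms = RING_SUBSTITUENTS[key]()
    return _sub([p for _, p in atoms],
                [covalent_radius(e) for e, _ in atoms])


class TestConeAngle:
    def test_point_atom_has_zero_cone(self):
        assert cone_angle(_sub([[1.7, 0.3, -0.2]], [0.0])) == \
            pytest.approx(0.0, abs=1e-6)

    def test_single_sphere_closed_form(self):
        # full angle 2*arcsin(r/d) for one atom at distance d with radius r
        assert cone_angle(_sub([[2.0, 0, 0]], [1.0])) == \
            pytest.approx(60.0, abs=1e-6)
        assert cone_angle(_sub([[0, 0, 3.0]], [1.5])) == \
            pytest.approx(2 * np.degrees(np.arcsin(0.5)), abs=1e-6)

    def test_two_points_at_plus_minus_30_degrees(self):
        a = np.deg2rad(30)
        sub = _sub([[np.cos(a), np.sin(a), 0], [np.cos(a), -np.sin(a), 0]],
                   [0.0, 0.0])
        grid = cone_angle(sub, use_radii=False, method="grid",
                          grid_points=200000)
        assert cone_angle(sub, use_radii=False) == pytest.approx(60.0,
                                                                 abs=1e-4)
        assert grid == pytest.approx(60.0, abs=0.2)

    def test_optimizer_matches_dense_grid(self, rng):
        for _ in range(8):
            n = rng.integers(2, 6)
            pos = rng.normal(0, 1.5, (n, 3)) + np.array([3.0, 0, 0])
            radii = rng.uniform(0.2, 0.7, n)
            sub = _sub(pos, radii)
            opt = cone_angle(sub)
            grid = cone_angle(sub, method="grid", grid_points=200000)
            assert opt <= grid + 1e-9          # optimizer never worse
            assert abs(opt - grid) < 0.5

    def test_library_substituents_match_grid(self):
        for key in ("H", "Cl", "methyl", "phenyl"):
            sub = _library_sub(key)
            assert abs(cone_angle(sub) -
                       cone_angle(sub, method="grid",
                                  grid_points=100000)) < 0.5

    def test_rigid_motion_invariance(self, rng):
        pos = rng.normal(0, 1.0, (4, 3)) + np.array([2.5, 0, 0])
        radii = rng.uniform(0.2, 0.6, 4)
        base = cone_angle(_sub(pos, radii))
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        shift = np.array([1.0, -4.0, 2.0])
        moved = cone_angle(_sub(pos @ R.T + shift, radii, apex=shift))
        assert moved == pytest.approx(base, abs=1e-3)

    def test_monotone_in_radius(self):
        pos = [[2.0, 0.5, 0], [2.2, -0.4, 0.3]]
        small = cone_angle(_sub(pos, [0.3, 0.3]))
        big = cone_angle(_sub(pos, [0.3, 0.8]))
        assert big >= small

    def test_sphere_engulfing_apex_raises(self):
        with pytest.raises(ConeAngleError):
            cone_angle(_sub([[1.0, 0, 0]], [1.2]))

    def test_coincident_atom_rejected(self):
        with pytest.raises(ValueError):
            _sub([[0, 0, 0]], [0.5])


class TestSurrogateDistance:
    def test_two_hydrogens_give_frame_constant(self):
        h = _library_sub("H")
        d1 = surrogate_distance(h, h, "beta_beta")
        d2 = surrogate_distance(h, h, "beta_beta")
        assert d1 == d2 > 0

    def test_point_substituents_coordinate_arithmetic(self):
        # transplanting single atoms puts them at site + bond_length * dir;
        # the distance must match direct coordinate arithmetic
        from porphgeom.descriptors import _FRAMES, _transplant

        cl = _library_sub("Cl")
        (pa, da), (pb, db) = _FRAMES["beta_beta"]
        expect = np.linalg.norm(
            (pa + 1.73 * da / np.linalg.norm(da)) -
            (pb + 1.73 * db / np.linalg.norm(db)))
        assert surrogate_distance(cl, cl, "beta_beta") == \
            pytest.approx(expect, abs=1e-9)

    def test_symmetric_in_arguments(self):
        a, b = _library_sub("methyl"), _library_sub("phenyl")
        for pc in ("beta_beta", "meso_beta"):
            assert surrogate_distance(a, b, pc) == \
                pytest.approx(surrogate_distance(b, a, pc), abs=1e-9)

    def test_bulk_decreases_distance(self):
        h, me, tbu = (_library_sub(k) for k in ("H", "methyl", "tbutyl"))
        d_h = surrogate_distance(h, h, "beta_beta")
        d_me = surrogate_distance(me, me, "beta_beta")
        d_tbu = surrogate_distance(tbu, tbu, "beta_beta")
        assert d_h > d_me > d_tbu

    def test_unknown_pair_class(self):
        h = _library_sub("H")
        with pytest.raises(KeyError):
            surrogate_distance(h, h, "alpha_alpha")


class TestMetalRadius:
    def test_table_identity_and_determinism(self):
        assert metal_radius("Zn") == covalent_radius("Zn")
        assert metal_radius("Zn") == metal_radius("Zn")

    def test_elements_differ(self):
        assert metal_radius("Zn") != metal_radius("Ru")

    def test_unknown_element(self):
        with pytest.raises(KeyError):
            metal_radius("Qx")


class TestFeatureVectors:
    def test_four_coordinate_sentinel(self):
        st, m = make_template("Ni")
        vec = build_feature_vector(st, m, "cone_angles")
        assert vec.features["coordination_number"] == 4
        assert vec.features["mean_axial_cone"] == NO_AXIAL_SENTINEL

    def test_two_identical_axials_mean_equals_single(self):
        st2, m2 = make_template("Zn", axial=("pyridine", "pyridine"))
        st1, m1 = make_template("Zn", axial="pyridine")
        v2 = build_feature_vector(st2, m2, "cone_angles")
        v1 = build_feature_vector(st1, m1, "cone_angles")
        assert v2.features["coordination_number"] == 6
        assert v2.features["mean_axial_cone"] == \
            pytest.approx(v1.features["mean_axial_cone"], abs=1e-6)

    def test_tetraphenyl_means_match_per_site_values(self, tpp):
        st, m = tpp
        vec = build_feature_vector(st, m, "cone_angles")
        # independent per-site computation
        phen = next(r for r in m.substituents if r.position_class == "meso")
        idx = sorted(phen.atoms)
        sub = SubstituentGeometry(
            apex=st.coords[phen.attachment_atom],
            positions=st.coords[idx],
            radii=np.array([covalent_radius(st.elements[i]) for i in idx]))
        assert vec.features["mean_meso_cone"] == \
            pytest.approx(cone_angle(sub), abs=1e-3)
        h = next(r for r in m.substituents if r.position_class == "beta")
        hidx = sorted(h.atoms)
        hsub = SubstituentGeometry(
            apex=st.coords[h.attachment_atom], positions=st.coords[hidx],
            radii=np.array([covalent_radius(st.elements[i]) for i in hidx]))
        assert vec.features["mean_beta_cone"] == \
            pytest.approx(cone_angle(hsub), abs=1e-3)

    @pytest.mark.parametrize("variant", ["cone_angles", "distances"])
    def test_exactly_five_features(self, variant, tpp):
        st, m = tpp
        vec = build_feature_vector(st, m, variant)
        assert tuple(vec.features) == FEATURE_NAMES[variant]
        assert len(vec.values()) == 5

    @pytest.mark.parametrize("variant", ["cone_angles", "distances"])
    def test_symmetry_images_give_identical_features(self, variant):
        vals = []
        for site in range(4):
            st, m = make_template("Zn", meso={site: "phenyl"})
            vals.append(build_feature_vector(st, m, variant).values())
        for v in vals[1:]:
            assert np.abs(v - vals[0]).max() < 1e-6

    def test_distances_are_positive(self, oep):
        st, m = oep
        vec = build_feature_vector(st, m, "distances")
        assert vec.features["mean_beta_beta_dist"] > 0
        assert vec.features["mean_meso_beta_dist"] > 0
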
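"""Ring centroids, cylinder axis fitting, twist angles, C2 axes."""

import numpy as np
import pytest

from frapc import (
    ChainAnnotation,
    DegenerateGeometryError,
    NotTwoFoldError,
    PairingError,
    StructureModel,
    SyntheticAssemblySpec,
    build_c2_dimer,
    build_cylinder_pair,
    c2_axis,
    cylinder_geometry,
    fit_axis,
    ring_centroid,
    twist_angle,
)
from frapc._geom import random_rigid_transform, rotation_about_axis
from frapc.model import AtomSite, ResidueRecord


def _square_ring_model(role="ApcA"):
    """One annotated chain whose single residue has backbone atoms on a unit square."""
    atoms = [
        AtomSite("N", "N", (0.0, 0.0, 0.0)),
        AtomSite("CA", "C", (1.0, 0.0, 0.0)),
        AtomSite("C", "C", (1.0, 1.0, 0.0)),
        AtomSite("O", "O", (0.0, 1.0, 0.0)),
    ]
    res = ResidueRecord(comp_id="ALA", seq_id=1, chain_id="A", atoms=atoms)
    ann = ChainAnnotation("A", subunit_role=role, cylinder_index=1, ring_index=1)
    return StructureModel(entry_id="sq", chains=[(ann, [res])])


class TestRingCentroid:
    def test_square_center(self):
        rc = ring_centroid(_square_ring_model(), 1, 1)
        np.testing.assert_allclose(rc.centroid, [0.5, 0.5, 0.0], atol=1e-12)
        assert rc.n_atoms == 4

    def test_decoys_excluded_exactly(self, bicylinder):
        model, truth = bicylinder
        for ring in (1, 2, 3, 4):
            rc = ring_centroid(model, 1, ring)
            np.testing.assert_allclose(
                rc.centroid, truth["ring_centers_1"][ring - 1], atol=1e-6
            )

    def test_exclusion_disabled_shifts_centroid(self, bicylinder):
        model, truth = bicylinder
        # relabel the ApcC decoys as ordinary subunits: the mean must move
        relabeled = []
        for ann, _ in model.chains:
            if ann.subunit_role == "ApcC":
                relabeled.append(
                    ChainAnnotation(
                        ann.chain_id, "ApcA",
                        cylinder_index=ann.cylinder_index, ring_index=ann.ring_index,
                    )
                )
        unprotected = model.with_annotations(relabeled)
        rc = ring_centroid(unprotected, 1, 1)
        shift = np.linalg.norm(rc.centroid - truth["ring_centers_1"][0])
        assert shift > 0.1

    def test_empty_ring_errors(self):
        with pytest.raises(DegenerateGeometryError):
            ring_centroid(_square_ring_model(), 2, 1)

    def test_apcc_only_ring_errors(self):
        with pytest.raises(DegenerateGeometryError):
            ring_centroid(_square_ring_model(role="ApcC"), 1, 1)


class TestFitAxis:
    def test_collinear_exact(self):
        pts = [(0, 0, 0), (0, 0, 10), (0, 0, 20), (0, 0, 30)]
        direction, anchor, rms = fit_axis(pts)
        np.testing.assert_allclose(direction, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(anchor, [0, 0, 15], atol=1e-12)
        assert rms == pytest.approx(0.0, abs=1e-12)

    def test_two_points(self):
        direction, anchor, rms = fit_axis([(0, 0, 0), (3, 4, 0)])
        np.testing.assert_allclose(direction, [0.6, 0.8, 0.0], atol=1e-12)
        assert rms == pytest.approx(0.0, abs=1e-12)

    def test_coincident_points_raise(self):
        with pytest.raises(DegenerateGeometryError):
            fit_axis([(1, 1, 1), (1, 1, 1), (1, 1, 1)])

    def test_direction_sign_follows_ring_order(self):
        direction, _, _ = fit_axis([(0, 0, 30), (0, 0, 20), (0, 0, 10), (0, 0, 0)])
        np.testing.assert_allclose(direction, [0, 0, -1], atol=1e-12)

    def test_noisy_recovery_within_1_degree(self):
        rng = np.random.default_rng(7)
        truth = np.array([0.0, 0.0, 1.0])
        pts = np.array([[0, 0, z] for z in (0.0, 10.0, 20.0, 30.0)])
        pts = pts + rng.normal(0, 0.5, pts.shape)
        direction, _, _ = fit_axis(pts)
        assert twist_angle(direction, truth) < 1.0

    def test_grid_search_oracle(self):
        """TLS direction matches a brute-force 2-degree grid minimizer of the
        summed squared perpendicular distances."""
        rng = np.random.default_rng(11)
        pts = np.array([[0, 0, z] for z in (0.0, 10.0, 20.0, 30.0)])
        pts = pts + rng.normal(0, 1.0, pts.shape)
        direction, anchor, _ = fit_axis(pts)

        thetas = np.radians(np.arange(0.0, 180.0, 2.0))
        phis = np.radians(np.arange(0.0, 360.0, 2.0))
        tt, pp = np.meshgrid(thetas, phis, indexing="ij")
        dirs = np.stack(
            [np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp), np.cos(tt)], axis=-1
        ).reshape(-1, 3)
        centered = pts - pts.mean(axis=0)
        proj = centered @ dirs.T  # (n, m)
        ss = (centered**2).sum() - (proj**2).sum(axis=0)
        best = dirs[np.argmin(ss)]
        assert twist_angle(direction, best) <= 2.0


class TestTwistAngle:
    def test_parallel_zero(self):
        assert twist_angle([0, 0, 1], [0, 0, 1]) == pytest.approx(0.0)

    def test_raw_150_folds_to_30(self):
        v = [np.sin(np.radians(150)), 0.0, np.cos(np.radians(150))]
        assert twist_angle([0, 0, 1], v) == pytest.approx(30.0, abs=1e-9)

    def test_symmetry_and_negation(self, rng):
        a = rng.normal(size=3)
        b = rng.normal(size=3)
        t = twist_angle(a, b)
        assert 0.0 <= t <= 90.0
        assert twist_angle(b, a) == pytest.approx(t, abs=1e-9)
        assert twist_angle(-a, b) == pytest.approx(t, abs=1e-9)

    @pytest.mark.parametrize("twist", [0.0, 12.5, 30.0, 60.0, 90.0])
    @pytest.mark.parametrize("antiparallel", [True, False])
    def test_generator_roundtrip(self, twist, antiparallel):
        model, truth = build_cylinder_pair(
            SyntheticAssemblySpec(twist_deg=twist, antiparallel=antiparallel)
        )
        g1 = cylinder_geometry(model, 1)
        g2 = cylinder_geometry(model, 2)
        measured = twist_angle(g1.axis_direction, g2.axis_direction)
        assert measured == pytest.approx(truth["twist_deg"], abs=1e-6)
        assert g1.fit_rms == pytest.approx(0.0, abs=1e-9)

    def test_pipeline_rigid_motion_invariance(self, bicylinder, rng):
        model, truth = bicylinder
        R, t = random_rigid_transform(rng)
        moved = model.transformed(R, t)
        g1 = cylinder_geometry(moved, 1)
        g2 = cylinder_geometry(moved, 2)
        assert twist_angle(g1.axis_direction, g2.axis_direction) == pytest.approx(
            truth["twist_deg"], abs=1e-6
        )

    def test_wrong_ring_count_is_clean_error(self):
        model, _ = build_cylinder_pair(SyntheticAssemblySpec(n_rings=3))
        with pytest.raises(PairingError, match="expected"):
            cylinder_geometry(model, 1)


class TestC2Axis:
    def test_explicit_180_about_z(self):
        model, truth = build_c2_dimer(axis=(0, 0, 1), seed=1)
        axis = c2_axis(model, ["A"], ["B"], {"A": "B"})
        assert axis.rotation_angle == pytest.approx(180.0, abs=1e-6)
        assert abs(np.dot(axis.direction, [0, 0, 1])) == pytest.approx(1.0, abs=1e-9)

    def test_arbitrary_axis_recovered_within_0p1_degree(self):
        u = np.array([0.3, -0.5, 0.81])
        u = u / np.linalg.norm(u)
        model, truth = build_c2_dimer(axis=u, point=(4.0, -2.0, 7.0), seed=5)
        axis = c2_axis(model, ["A"], ["B"], {"A": "B"})
        angle_off = np.degrees(np.arccos(np.clip(abs(np.dot(axis.direction, u)), -1, 1)))
        assert angle_off < 0.1
        # the recovered anchor lies on the generating axis
        offset = axis.point - truth["point"]
        perp = offset - np.dot(offset, u) * u
        assert np.linalg.norm(perp) < 1e-6

    def test_untransformed_copy_is_not_twofold(self):
        model, _ = build_c2_dimer(rotation_angle=0.0, seed=2)
        with pytest.raises(NotTwoFoldError):
            c2_axis(model, ["A"], ["B"], {"A": "B"})

    def test_pairing_errors(self):
        model, _ = build_c2_dimer(seed=3)
        with pytest.raises(PairingError):
            c2_axis(model, ["A"], ["B"], {"A": "Z"})
        with pytest.raises(PairingError):
            c2_axis(model, ["A"], ["B"], {})

    def test_bicylinder_c2(self, bicylinder):
        model, truth = bicylinder
        axis = c2_axis(model, truth["half_a"], truth["half_b"], truth["pairing"])
        assert axis.rotation_angle == pytest.approx(180.0, abs=1e-6)
        assert abs(np.dot(axis.direction, truth["c2_axis"])) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_noise_degrades_gracefully(self):
        """Axis error grows monotonically with coordinate noise (seed-averaged)."""
        u = np.array([0.2, 0.3, 0.933])
        u = u / np.linalg.norm(u)
        errors = []
        for sigma in (0.0, 0.3, 1.5):
            errs = []
            for seed in range(5):
                model, _ = build_c2_dimer(axis=u, noise_sigma=sigma, seed=seed)
                axis = c2_axis(model, ["A"], ["B"], {"A": "B"})
                errs.append(
                    np.degrees(np.arccos(np.clip(abs(np.dot(axis.direction, u)), -1, 1)))
                )
            errors.append(np.mean(errs))
        assert errors[0] < 0.1
        assert errors[0] <= errors[1] <= errors[2]
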
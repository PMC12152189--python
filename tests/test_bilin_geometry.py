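"""Bilin ring-plane normals, centered inter-plane angles, conformer labels."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from frapc import (
    BilinChromophore,
    DegenerateGeometryError,
    MissingAtomError,
    SyntheticBilinSpec,
    bilin_model,
    build_bilin,
    classify_conformer,
    interplane_angle,
    planarity_profile,
    profile_to_frame,
    ring_plane_normal,
)
from frapc.bilin_geometry import RING_PLANES
from frapc._geom import random_rigid_transform, rotation_about_axis
from frapc.model import AtomSite, ResidueRecord


def _triplet_residue(p1, p2, p3):
    names = RING_PLANES["A"].atom_triplet
    return ResidueRecord(
        comp_id="CYC", seq_id=1, chain_id="X",
        atoms=[AtomSite(n, n[0], p) for n, p in zip(names, (p1, p2, p3))],
        is_polymer=False,
    )


def _svd_plane_normal(points: np.ndarray) -> np.ndarray:
    """Independent oracle: least-squares plane normal via SVD of centered points."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[-1]


class TestRingPlaneNormal:
    def test_unit_axes(self):
        res = _triplet_residue((0, 0, 0), (1, 0, 0), (0, 1, 0))
        np.testing.assert_allclose(
            ring_plane_normal(res, RING_PLANES["A"]), [0, 0, 1], atol=1e-12
        )

    def test_collinear_triplet_raises(self):
        res = _triplet_residue((0, 0, 0), (1, 0, 0), (2, 0, 0))
        with pytest.raises(DegenerateGeometryError):
            ring_plane_normal(res, RING_PLANES["A"])

    def test_missing_atom_named_in_error(self):
        res = _triplet_residue((0, 0, 0), (1, 0, 0), (0, 1, 0))
        res.atoms = res.atoms[:2]
        with pytest.raises(MissingAtomError, match="C4A"):
            ring_plane_normal(res, RING_PLANES["A"])

    @pytest.mark.parametrize("seed", range(5))
    def test_rotation_oracle(self, seed):
        """Rotating a triplet by R rotates its normal by exactly R."""
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(3, 3))
        res = _triplet_residue(*pts)
        n0 = ring_plane_normal(res, RING_PLANES["A"])
        R = rotation_about_axis(rng.normal(size=3), rng.uniform(10, 170))
        res_rot = _triplet_residue(*(pts @ R.T))
        np.testing.assert_allclose(
            ring_plane_normal(res_rot, RING_PLANES["A"]), R @ n0, atol=1e-9
        )


class TestInterplaneAngle:
    def test_equal_normals_zero(self):
        assert interplane_angle([0, 0, 1], [0, 0, 1]) == pytest.approx(0.0)

    @pytest.mark.parametrize("raw,expected", [(120.0, 60.0), (150.0, 30.0), (60.0, 60.0)])
    def test_centering_rule(self, raw, expected):
        n2 = [np.cos(np.radians(raw)), np.sin(np.radians(raw)), 0.0]
        assert interplane_angle([1, 0, 0], n2) == pytest.approx(expected, abs=1e-9)

    def test_clamp_no_domain_error(self):
        # dot product numerically 1 + eps must not raise
        v = np.array([1.0, 1e-16, 0.0])
        assert interplane_angle(v, v) == pytest.approx(0.0)

    def test_zero_vector_raises(self):
        with pytest.raises(DegenerateGeometryError):
            interplane_angle([0, 0, 0], [0, 0, 1])

    def test_svd_plane_oracle_100_cases(self):
        """Triplet-normal angles agree with SVD plane fitting to 1e-6 degrees."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            t1 = rng.normal(size=(3, 3))
            t2 = rng.normal(size=(3, 3))
            res1, res2 = _triplet_residue(*t1), _triplet_residue(*t2)
            mine = interplane_angle(
                ring_plane_normal(res1, RING_PLANES["A"]),
                ring_plane_normal(res2, RING_PLANES["A"]),
            )
            oracle_raw = np.degrees(
                np.arccos(
                    np.clip(abs(np.dot(_svd_plane_normal(t1), _svd_plane_normal(t2))), -1, 1)
                )
            )
            assert mine == pytest.approx(oracle_raw, abs=1e-6)

    @settings(derandomize=True, max_examples=100)
    @given(
        v1=st.lists(st.floats(-1, 1), min_size=3, max_size=3),
        v2=st.lists(st.floats(-1, 1), min_size=3, max_size=3),
    )
    def test_symmetry_and_sign_gauge(self, v1, v2):
        v1, v2 = np.array(v1), np.array(v2)
        if np.linalg.norm(v1) < 1e-6 or np.linalg.norm(v2) < 1e-6:
            return
        theta = interplane_angle(v1, v2)
        assert 0.0 <= theta <= 90.0
        assert interplane_angle(v2, v1) == pytest.approx(theta, abs=1e-9)
        assert interplane_angle(-v1, v2) == pytest.approx(theta, abs=1e-9)
        assert interplane_angle(v1, -v2) == pytest.approx(theta, abs=1e-9)


class TestPlanarityProfile:
    def test_planar_bilin_zero_angles(self, planar_bilin):
        residue, _ = planar_bilin
        records, skipped = planarity_profile(bilin_model(residue))
        assert not skipped
        (rec,) = records
        for theta in (rec.theta_AB, rec.theta_BC, rec.theta_CD):
            assert theta == pytest.approx(0.0, abs=1e-6)

    def test_prescribed_angles_recovered(self, tilted_bilin):
        residue, truth = tilted_bilin
        (rec,), _ = planarity_profile(bilin_model(residue))
        assert rec.theta_AB == pytest.approx(truth["theta_AB"], abs=0.5)
        assert rec.theta_CD == pytest.approx(truth["theta_CD"], abs=0.5)
        assert rec.theta_BC == pytest.approx(truth["theta_BC"], abs=0.5)

    def test_unresolvable_ligand_reported_not_dropped(self, planar_bilin):
        residue, _ = planar_bilin
        broken = ResidueRecord(
            comp_id="CYC", seq_id=2, chain_id="X",
            atoms=[a for a in residue.atoms if a.atom_name != "C3A"],
            is_polymer=False,
        )
        model = bilin_model(residue)
        model.chains[0][1].append(broken)
        records, skipped = planarity_profile(model)
        assert len(records) == 1
        assert len(skipped) == 1 and "C3A" in skipped[0][1]

    def test_rigid_motion_invariance(self, tilted_bilin, rng):
        residue, _ = tilted_bilin
        model = bilin_model(residue)
        (before,), _ = planarity_profile(model)
        R, t = random_rigid_transform(rng)
        (after,), _ = planarity_profile(model.transformed(R, t))
        assert after.theta_AB == pytest.approx(before.theta_AB, abs=1e-6)
        assert after.theta_BC == pytest.approx(before.theta_BC, abs=1e-6)
        assert after.theta_CD == pytest.approx(before.theta_CD, abs=1e-6)

    def test_frame_columns(self, tilted_bilin):
        residue, _ = tilted_bilin
        records, _ = planarity_profile(bilin_model(residue, subunit_role="ApcE2"))
        frame = profile_to_frame(records)
        assert list(frame.columns) == [
            "structure_id", "chain_id", "seq_id", "subunit_role",
            "theta_AB", "theta_BC", "theta_CD", "conformer_label",
        ]
        assert frame.loc[0, "subunit_role"] == "ApcE2"


class TestClassifyConformer:
    def test_all_z_syn_gives_zzz_ssa(self):
        residue, _ = build_bilin(SyntheticBilinSpec(conformer="ZZZ,ssa"))
        label = classify_conformer(BilinChromophore.from_residue(residue))
        assert label.label == "ZZZ,ssa" and not label.boundary_warning

    def test_ring_a_anti_flip_gives_asa(self):
        """The ApcF-style ring-A flip: same ZZZ configuration, anti at the A-B bridge."""
        residue, _ = build_bilin(SyntheticBilinSpec(theta_AB=20.0, conformer="ZZZ,asa"))
        label = classify_conformer(BilinChromophore.from_residue(residue))
        assert label.label == "ZZZ,asa"

    @pytest.mark.parametrize("conformer", ["ZZE,ssa", "ZZZ,sss", "EZZ,aaa"])
    def test_other_labels_roundtrip(self, conformer):
        residue, _ = build_bilin(SyntheticBilinSpec(conformer=conformer))
        assert classify_conformer(BilinChromophore.from_residue(residue)).label == conformer

    def test_boundary_warning_near_90(self):
        residue, _ = build_bilin(SyntheticBilinSpec(theta_AB=88.0))
        label = classify_conformer(BilinChromophore.from_residue(residue))
        assert label.boundary_warning

    def test_missing_bridge_atom_raises(self, planar_bilin):
        residue, _ = planar_bilin
        broken = ResidueRecord(
            comp_id="CYC", seq_id=1, chain_id="X",
            atoms=[a for a in residue.atoms if a.atom_name != "CHC"],
            is_polymer=False,
        )
        with pytest.raises(MissingAtomError, match="CHC"):
            classify_conformer(BilinChromophore.from_residue(broken))
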
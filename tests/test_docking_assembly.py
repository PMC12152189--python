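"""Kabsch superposition, template fitting, pigment distances and inventories."""

import numpy as np
import pytest

from frapc import (
    CompositeAssembly,
    DegenerateGeometryError,
    InsufficientAnchorError,
    PairingError,
    RigidTransform,
    SyntheticAssemblySpec,
    build_cylinder_pair,
    center_to_center,
    edge_to_edge,
    fit_component_to_template,
    kabsch_superpose,
    pigment_inventory,
    select_ligands,
)
from frapc._geom import random_rigid_transform
from frapc.model import AtomSite, ChainAnnotation, ResidueRecord, StructureModel
from frapc.synthetic_fixtures import SyntheticBilinSpec, build_bilin

ALPHA_GROUPING = {
    "ApcD2": "alpha-site", "ApcD3": "alpha-site", "ApcD5": "alpha-site",
    "ApcE2": "alpha-site", "ApcB2": "beta-site",
}


class TestKabsch:
    def test_identity(self, rng):
        pts = rng.normal(size=(10, 3)) * 5
        tr = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(tr.translation, 0, atol=1e-9)
        assert tr.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_known_transform_recovered_exactly(self, rng):
        pts = rng.normal(size=(25, 3)) * 10
        R, t = random_rigid_transform(rng)
        tr = kabsch_superpose(pts, pts @ R.T + t)
        np.testing.assert_allclose(tr.rotation, R, atol=1e-9)
        np.testing.assert_allclose(tr.translation, t, atol=1e-9)
        assert tr.rmsd == pytest.approx(0.0, abs=1e-6)

    def test_too_few_or_collinear_points(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2.0]])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)

    def test_noise_rmsd_matches_expectation(self):
        """With iid N(0, sigma^2) noise on each target coordinate the fitted
        rmsd approaches sigma*sqrt(3) (3 coordinates per pair; the 6 rigid
        degrees of freedom are negligible at n=500)."""
        rng = np.random.default_rng(123)
        sigma = 0.5
        pts = rng.normal(size=(500, 3)) * 20
        noisy = pts + rng.normal(0, sigma, pts.shape)
        tr = kabsch_superpose(pts, noisy)
        expected = sigma * np.sqrt(3.0)
        assert abs(tr.rmsd - expected) < 0.2 * expected

    def test_rmsd_invariant_under_common_rigid_motion(self, rng):
        pts = rng.normal(size=(30, 3)) * 10
        noisy = pts + rng.normal(0, 0.8, pts.shape)
        base = kabsch_superpose(pts, noisy).rmsd
        R, t = random_rigid_transform(rng)
        moved = kabsch_superpose(pts @ R.T + t, noisy @ R.T + t).rmsd
        assert moved == pytest.approx(base, abs=1e-9)

    def test_transform_compose_inverse(self, rng):
        R, t = random_rigid_transform(rng)
        tr = RigidTransform(rotation=R, translation=t)
        pts = rng.normal(size=(4, 3))
        np.testing.assert_allclose(tr.inverse().apply(tr.apply(pts)), pts, atol=1e-9)
        np.testing.assert_allclose(
            tr.compose(tr.inverse()).rotation, np.eye(3), atol=1e-9
        )


@pytest.fixture(scope="module")
def template():
    model, truth = build_cylinder_pair(SyntheticAssemblySpec(with_bilins=True))
    return model, truth


@pytest.fixture(scope="module")
def composite(template):
    model, truth = template
    half_a = set(truth["half_a"])
    comp1 = StructureModel(
        entry_id="c1", chains=[c for c in model.chains if c[0].chain_id in half_a]
    )
    comp2 = StructureModel(
        entry_id="c2", chains=[c for c in model.chains if c[0].chain_id not in half_a]
    )
    rng = np.random.default_rng(99)
    R1, t1 = random_rigid_transform(rng)
    R2, t2 = random_rigid_transform(rng)
    moved1 = comp1.transformed(R1, t1)
    moved2 = comp2.transformed(R2, t2)
    tr1 = fit_component_to_template(moved1, model, {c: c for c in comp1.chain_ids})
    tr2 = fit_component_to_template(moved2, model, {c: c for c in comp2.chain_ids})
    assembly = CompositeAssembly(template_id=model.entry_id)
    assembly.add(moved1, tr1, "antenna")
    assembly.add(moved2, tr2, "photosystem")
    return model, assembly, (moved1, tr1), (moved2, tr2)


class TestFitComponentToTemplate:
    def test_substructure_fits_with_identity(self, template):
        model, truth = template
        sub_chains = truth["half_a"][:8]  # 8 chains x 8 residues = 64 CA pairs
        component = StructureModel(
            entry_id="sub",
            chains=[c for c in model.chains if c[0].chain_id in sub_chains],
        )
        tr = fit_component_to_template(component, model, {c: c for c in sub_chains})
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(tr.translation, 0.0, atol=1e-8)
        assert tr.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_displaced_component_recovered(self, template, rng):
        model, truth = template
        sub_chains = truth["half_a"][:8]
        component = StructureModel(
            entry_id="sub",
            chains=[c for c in model.chains if c[0].chain_id in sub_chains],
        )
        R, t = random_rigid_transform(rng)
        displaced = component.transformed(R, t)
        tr = fit_component_to_template(displaced, model, {c: c for c in sub_chains})
        # the recovered transform must undo the displacement
        np.testing.assert_allclose(tr.rotation, R.T, atol=1e-6)
        roundtrip = tr.apply(displaced.all_coords())
        np.testing.assert_allclose(roundtrip, component.all_coords(), atol=1e-6)

    def test_absent_chain_raises(self, template):
        model, truth = template
        chain = truth["half_a"][0]
        component = StructureModel(
            entry_id="sub", chains=[c for c in model.chains if c[0].chain_id == chain]
        )
        with pytest.raises(PairingError):
            fit_component_to_template(component, model, {chain: "nope"})

    def test_insufficient_anchor(self, template):
        model, truth = template
        chain = truth["half_a"][0]
        component = StructureModel(
            entry_id="sub", chains=[c for c in model.chains if c[0].chain_id == chain]
        )
        with pytest.raises(InsufficientAnchorError):
            fit_component_to_template(
                component, model, {chain: chain}, min_pairs=10_000
            )


def _single_atom_pigment(chain, seq, x):
    return ResidueRecord(
        comp_id="LIG", seq_id=seq, chain_id=chain,
        atoms=[AtomSite("C1", "C", (x, 0.0, 0.0))], is_polymer=False,
    )


class TestEdgeToEdge:
    def test_two_single_atoms(self):
        d = edge_to_edge(_single_atom_pigment("A", 1, 0.0), _single_atom_pigment("B", 1, 5.0))
        assert d.distance == pytest.approx(5.0, abs=1e-12)
        assert d.atom_pair == ("C1", "C1")

    def test_prescribed_minimal_approach(self):
        """Two bilins translated so the closest atom pair is exactly 17.3 A."""
        bilin, _ = build_bilin(SyntheticBilinSpec())
        coords = bilin.coords()
        i_max = int(np.argmax(coords[:, 0]))
        i_min = int(np.argmin(coords[:, 0]))
        q = coords[i_max]
        r = coords[i_min]
        shift = q + np.array([17.3, 0.0, 0.0]) - r
        other = ResidueRecord(
            comp_id="CYC", seq_id=2, chain_id="Y",
            atoms=[a.moved_to(a.coords + shift) for a in bilin.atoms],
            is_polymer=False,
        )
        d = edge_to_edge(bilin, other)
        assert d.distance == pytest.approx(17.3, abs=1e-6)
        # brute-force oracle over all atom pairs
        brute = np.min(
            np.linalg.norm(coords[:, None, :] - other.coords()[None, :, :], axis=-1)
        )
        assert d.distance == pytest.approx(brute, abs=1e-12)

    def test_chlorophyll_phytyl_tail_excluded(self):
        chl = ResidueRecord(
            comp_id="CLA", seq_id=1, chain_id="A",
            atoms=[
                AtomSite("C1A", "C", (0.0, 0.0, 0.0)),   # macrocycle
                AtomSite("C5", "C", (8.0, 0.0, 0.0)),    # phytyl tail, nearer
            ],
            is_polymer=False,
        )
        target = _single_atom_pigment("B", 1, 10.0)
        d = edge_to_edge(chl, target)
        assert d.distance == pytest.approx(10.0, abs=1e-12)
        assert d.atom_pair[0] == "C1A"

    def test_bilin_propionate_switch(self):
        bilin, _ = build_bilin(SyntheticBilinSpec())
        probe_xyz = bilin.atom("O1B").coords + np.array([4.0, 0.0, 0.0])
        probe = ResidueRecord(
            comp_id="LIG", seq_id=9, chain_id="Z",
            atoms=[AtomSite("C1", "C", probe_xyz)], is_polymer=False,
        )
        with_prop = edge_to_edge(bilin, probe, exclude_propionates=False)
        without = edge_to_edge(bilin, probe, exclude_propionates=True)
        assert without.distance >= with_prop.distance
        assert without.atom_pair[0] not in {"O1B", "O2B", "CGB", "CAB", "CBB"}

    def test_edge_never_exceeds_center_distance(self):
        a, _ = build_bilin(SyntheticBilinSpec(seed=1))
        b_res, _ = build_bilin(SyntheticBilinSpec(seed=2))
        b = ResidueRecord(
            comp_id="CYC", seq_id=2, chain_id="Y",
            atoms=[x.moved_to(x.coords + np.array([30.0, 5.0, 2.0])) for x in b_res.atoms],
            is_polymer=False,
        )
        assert edge_to_edge(a, b).distance <= center_to_center(a, b).distance

    def test_empty_filter_result_raises(self):
        bare = ResidueRecord(
            comp_id="CLA", seq_id=1, chain_id="A",
            atoms=[AtomSite("C5", "C", (0.0, 0.0, 0.0))], is_polymer=False,
        )
        with pytest.raises(DegenerateGeometryError, match="CLA"):
            edge_to_edge(bare, _single_atom_pigment("B", 1, 5.0))


class TestCompositeAssembly:
    def test_components_land_back_on_template(self, composite):
        model, assembly, *_ = composite
        merged = assembly.to_model()
        assert merged.atom_count() == model.atom_count()
        np.testing.assert_allclose(
            np.sort(merged.all_coords(), axis=0),
            np.sort(model.all_coords(), axis=0),
            atol=1e-6,
        )

    def test_chain_renaming_is_prefixed_and_unique(self, composite):
        _, assembly, *_ = composite
        merged = assembly.to_model()
        assert all(":" in cid for cid in merged.chain_ids)
        assert len(set(merged.chain_ids)) == len(merged.chain_ids)
        roles = {cid.split(":")[0] for cid in merged.chain_ids}
        assert roles == {"antenna", "photosystem"}

    def test_duplicate_role_rejected(self, composite):
        _, assembly, (moved1, tr1), _ = composite
        with pytest.raises(ValueError):
            assembly.add(moved1, tr1, "antenna")

    def test_distances_invariant_under_rerooting(self, composite):
        """Holding a different component fixed must not change any distance."""
        _, assembly, (moved1, tr1), (moved2, tr2) = composite
        rerooted = CompositeAssembly(template_id="rerooted")
        rerooted.add(moved1, RigidTransform.identity(), "antenna")
        rerooted.add(moved2, tr1.inverse().compose(tr2), "photosystem")
        d_ref = assembly.pigment_distances({"CYC"}, {"CYC"})
        d_new = rerooted.pigment_distances({"CYC"}, {"CYC"})
        assert len(d_ref) == len(d_new)
        for a, b in zip(d_ref[:50], d_new[:50]):
            assert a.distance == pytest.approx(b.distance, abs=1e-6)


class TestPigmentInventory:
    def test_empty_model(self):
        model = StructureModel(entry_id="empty", chains=[])
        counts = pigment_inventory(model, ALPHA_GROUPING)
        assert counts["alpha-site"] == 0 and counts["beta-site"] == 0

    def test_bicylinder_inventory(self):
        model, _ = build_cylinder_pair(SyntheticAssemblySpec(with_bilins=True))
        counts = pigment_inventory(model, ALPHA_GROUPING)
        assert counts == {"alpha-site": 24, "beta-site": 24}

    def test_ungrouped_roles_count_as_other(self):
        model, _ = build_cylinder_pair(SyntheticAssemblySpec(with_bilins=True))
        counts = pigment_inventory(model, {"ApcB2": "beta-site"})
        assert counts["beta-site"] == 24 and counts["other"] == 24
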
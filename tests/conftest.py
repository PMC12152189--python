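import numpy as np
import pytest

from frapc import (
    PartnerSpec,
    SyntheticAssemblySpec,
    SyntheticBilinSpec,
    bilin_model,
    build_bilin,
    build_cylinder_pair,
    build_pocket,
)


@pytest.fixture(scope="session")
def planar_bilin():
    residue, truth = build_bilin(SyntheticBilinSpec())
    return residue, truth


@pytest.fixture(scope="session")
def tilted_bilin():
    spec = SyntheticBilinSpec(theta_AB=25.0, theta_BC=0.0, theta_CD=40.0)
    residue, truth = build_bilin(spec)
    return residue, truth


@pytest.fixture(scope="session")
def bicylinder():
    spec = SyntheticAssemblySpec(
        twist_deg=30.0, antiparallel=True, decoys=("ApcC", "ApcE2-REP")
    )
    return build_cylinder_pair(spec)


@pytest.fixture(scope="session")
def pocket_model(planar_bilin):
    residue, _ = planar_bilin
    partners = [
        PartnerSpec(
            res_name="SER", contact_type="hbond", distance=2.9,
            partner_atom="OG", bilin_atom="OD", chain_id="P", seq_id=1,
        ),
        PartnerSpec(
            res_name="ARG", contact_type="salt_bridge", distance=3.2,
            partner_atom="NH1", bilin_atom="O1B", chain_id="Q", seq_id=2,
        ),
        PartnerSpec(
            res_name="TRP", contact_type="pi_stack", distance=3.6,
            bilin_ring="D", chain_id="R", seq_id=3,
        ),
    ]
    return build_pocket(residue, partners), residue


@pytest.fixture()
def rng():
    return np.random.default_rng(20260918)
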
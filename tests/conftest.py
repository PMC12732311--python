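"""Shared fixtures: small phantoms and pre-run registration ensembles.

Registration is the expensive stage, so ensembles are session-scoped and
shared across test modules.  All phantoms are seeded; everything is
deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from redose_uq import (
    CaseInputs,
    PhantomSpec,
    RigidTransform,
    RunConfig,
    generate_phantom,
    rigid_register,
    run_ensemble,
)

SMALL = dict(size=(48, 48, 48), spacing=(2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def identity_case():
    return generate_phantom(PhantomSpec(seed=1, scenario="identity", amplitude_mm=0.0, **SMALL))


@pytest.fixture(scope="session")
def smooth_case():
    return generate_phantom(
        PhantomSpec(seed=3, scenario="smooth_deformation", amplitude_mm=6.0, **SMALL)
    )


@pytest.fixture(scope="session")
def ablated_case():
    return generate_phantom(
        PhantomSpec(seed=7, scenario="tissue_disappearance", amplitude_mm=2.0, **SMALL)
    )


@pytest.fixture(scope="session")
def six_configs():
    return RunConfig(grid="six").configs()


@pytest.fixture(scope="session")
def identity_ensemble(identity_case, six_configs):
    """Six-config ensemble registered on the identity phantom."""
    return run_ensemble(
        identity_case.reirradiation_volume,
        identity_case.prior_volume,
        six_configs,
        rigid=RigidTransform(),
    )


@pytest.fixture(scope="session")
def smooth_ensemble(smooth_case, six_configs):
    """Six-config ensemble on the 6 mm smooth-deformation phantom (true
    rigid is the identity, supplied explicitly to isolate the deformable
    stage)."""
    return run_ensemble(
        smooth_case.reirradiation_volume,
        smooth_case.prior_volume,
        six_configs,
        rigid=RigidTransform(),
    )


@pytest.fixture(scope="session")
def ablated_ensemble(ablated_case, six_configs):
    inputs = CaseInputs.from_phantom(ablated_case)
    rigid = rigid_register(inputs.reference, inputs.moving)
    return run_ensemble(inputs.reference, inputs.moving, six_configs, rigid=rigid)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
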
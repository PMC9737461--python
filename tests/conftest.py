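import numpy as np
import pytest

from goqdna.builders import (
    AssemblyGeometry,
    GOQDSpec,
    assemble_system,
    build_bdna_polyAT,
    build_goqd,
)
from goqdna.model_core import Selection, Structure, select


@pytest.fixture(scope="session")
def coronene():
    return build_goqd(GOQDSpec(ring_count=7))


@pytest.fixture(scope="session")
def flake_6oh():
    return build_goqd(GOQDSpec(ring_count=7, group_type="OH", group_count=6, seed=3))


@pytest.fixture(scope="session")
def duplex20():
    return build_bdna_polyAT(20)


@pytest.fixture(scope="session")
def system10(duplex20, flake_6oh):
    """Paper-geometry assembly: 10 flakes, 0.2 nm surface gap, 11 nm box."""
    return assemble_system(duplex20, flake_6oh, AssemblyGeometry(n_goqds=10), seed=1)


@pytest.fixture(scope="session")
def dispersed_system(duplex20, flake_6oh):
    """Assembly with a 2 nm surface gap: every flake starts out of contact."""
    return assemble_system(
        duplex20, flake_6oh, AssemblyGeometry(n_goqds=10, surface_gap=2.0), seed=1
    )


def two_atom_structure(distance, element="C"):
    return Structure(
        ["A1", "A2"],
        [element, element],
        ["X", "X"],
        [1, 2],
        ["A", "B"],
        np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]]),
    )


@pytest.fixture
def pair_selections():
    return Selection("a", [0]), Selection("b", [1])


def goqd_groups(system):
    resids = sorted(
        {int(system.residue_indices[i]) for i in select(system, "resname GQD").indices}
    )
    return [select(system, f"resname GQD and resid {r}") for r in resids]
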
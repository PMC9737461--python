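"""Hydrogen bonds, pi-pi stacking, DNA length, RMSD and base-pair state."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from goqdna._errors import GoqdnaError
from goqdna.dna_integrity import (
    HBondCriteria,
    basepair_states,
    count_hbonds,
    count_pipi_stacking,
    dna_hbond_count,
    dna_length,
    polyAT_hbond_selections,
    resolve_rings,
    rmsd,
)
from goqdna.model_core import Selection, Structure, select
from goqdna.synthetic_data import make_unwinding_trajectory


def brute_force_hbonds(frame, donors, acceptors, dmax=0.35, amax=30.0):
    """Plain-python re-count with the same geometric criterion."""
    count = 0
    for d in donors.indices:
        key = (frame.chain_ids[d], frame.residue_indices[d])
        hs = [
            i
            for i in range(frame.n_atoms)
            if frame.elements[i] == "H"
            and (frame.chain_ids[i], frame.residue_indices[i]) == key
            and np.linalg.norm(frame.positions[i] - frame.positions[d]) <= 0.115
        ]
        for a in acceptors.indices:
            if frame.chain_ids[a] == frame.chain_ids[d]:
                continue
            da = frame.positions[a] - frame.positions[d]
            if np.linalg.norm(da) > dmax:
                continue
            for h in hs:
                dh = frame.positions[h] - frame.positions[d]
                cosang = dh @ da / (np.linalg.norm(dh) * np.linalg.norm(da))
                if np.degrees(np.arccos(np.clip(cosang, -1, 1))) <= amax:
                    count += 1
    return count


def test_ideal_duplex_has_two_hbonds_per_pair(duplex20):
    assert dna_hbond_count(duplex20) == 40


def test_hbond_count_matches_plain_python_recount(duplex20):
    donors, acceptors = polyAT_hbond_selections(duplex20)
    expected = brute_force_hbonds(duplex20, donors, acceptors)
    assert (
        count_hbonds(duplex20, donors, acceptors, interstrand_only=True) == expected == 40
    )


def test_separated_strands_have_no_hbonds(duplex20):
    pos = duplex20.positions.copy()
    chain_b = select(duplex20, "chain B").indices
    pos[chain_b] += np.array([1.0, 0.0, 0.0])
    assert dna_hbond_count(duplex20.with_positions(pos)) == 0


def test_single_pair_contributes_two_bonds(duplex20):
    pair = select(duplex20, "resid 1 and chain A or resid 20 and chain B")
    sub = duplex20.subset(pair.indices)
    assert dna_hbond_count(sub) == 2


def test_donor_without_hydrogen_is_an_error():
    s = Structure(
        ["N1", "O1"],
        ["N", "O"],
        ["X", "Y"],
        [1, 2],
        ["A", "B"],
        np.array([[0.0, 0.0, 0.0], [0.3, 0.0, 0.0]]),
    )
    with pytest.raises(GoqdnaError, match="N1"):
        count_hbonds(s, Selection("d", [0]), Selection("a", [1]))


def test_hbond_criteria_must_be_positive():
    with pytest.raises(ValueError):
        HBondCriteria(donor_acceptor_max=-0.1)


# -- pi-pi stacking ---------------------------------------------------------


def ring_pair(distance, angle_deg):
    """Two six-membered rings, centroids ``distance`` apart along z, the
    second tilted by ``angle_deg`` about x."""
    hexagon = 0.139 * np.array(
        [[np.cos(t), np.sin(t), 0.0] for t in np.linspace(0, 2 * np.pi, 6, endpoint=False)]
    )
    rot = Rotation.from_euler("x", angle_deg, degrees=True).as_matrix()
    second = hexagon @ rot.T + np.array([0.0, 0.0, distance])
    pos = np.vstack([hexagon, second])
    names = [f"C{i+1}" for i in range(6)] * 2
    s = Structure(names, ["C"] * 12, ["RNG", "RNG"] * 6, [1] * 6 + [2] * 6, ["A"] * 12, pos)
    from goqdna.dna_integrity import ResolvedRing

    rings = [
        ResolvedRing("A", 1, "r", np.arange(6)),
        ResolvedRing("A", 2, "r", np.arange(6, 12)),
    ]
    return s, rings


@pytest.mark.parametrize(
    "distance, angle, expected",
    [(0.35, 0.0, 1), (0.45, 0.0, 0), (0.30, 90.0, 0), (0.39, 35.0, 1), (0.39, 37.0, 0)],
)
def test_stacking_truth_table(distance, angle, expected):
    s, rings = ring_pair(distance, angle)
    assert count_pipi_stacking(s, rings) == expected


def test_stacking_invariant_under_rigid_motion(duplex20):
    rings = resolve_rings(duplex20)
    base = count_pipi_stacking(duplex20, rings)
    rot = Rotation.from_euler("zyx", [31, -12, 77], degrees=True).as_matrix()
    moved = duplex20.rotated(rot).translated([3.0, -1.0, 2.0])
    assert count_pipi_stacking(moved, rings) == base


def test_rings_of_same_base_are_not_counted():
    # adenine carries two fused rings per residue; their pair is excluded
    from goqdna.builders import build_bdna_polyAT

    one_pair = build_bdna_polyAT(2)
    rings = resolve_rings(one_pair)
    # 2 pairs x (2 adenine + 1 thymine rings) = 6 rings; fused same-base pairs excluded
    assert len(rings) == 6
    assert count_pipi_stacking(one_pair, rings) >= 0  # no same-base self-pairs counted


# -- DNA length -------------------------------------------------------------


def test_length_is_translation_invariant(duplex20):
    assert dna_length(duplex20.translated([5, -3, 2])) == pytest.approx(
        dna_length(duplex20), abs=1e-12
    )


def test_two_pair_duplex_length_is_one_rise():
    from goqdna.builders import build_bdna_polyAT

    assert dna_length(build_bdna_polyAT(2)) == pytest.approx(0.338, abs=0.01)


def test_unequal_chains_error(duplex20):
    trimmed = duplex20.subset(
        np.array(
            [
                i
                for i in range(duplex20.n_atoms)
                if not (duplex20.chain_ids[i] == "B" and duplex20.residue_indices[i] == 20)
            ]
        )
    )
    with pytest.raises(GoqdnaError, match="unequal"):
        dna_length(trimmed)


# -- RMSD -------------------------------------------------------------------


def test_rmsd_of_identity_is_zero(duplex20):
    assert rmsd(duplex20, duplex20) == pytest.approx(0.0, abs=1e-12)


def test_rmsd_removes_rigid_motion(duplex20):
    rot = Rotation.from_euler("xyz", [10, 40, -70], degrees=True).as_matrix()
    moved = duplex20.rotated(rot).translated([1.0, 2.0, 3.0])
    assert rmsd(moved, duplex20, superpose=True) == pytest.approx(0.0, abs=1e-6)
    assert rmsd(moved, duplex20, superpose=False) > 0.5


def test_rmsd_closed_form_single_displacement():
    n = 10
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n)
    s = Structure([f"C{i}" for i in range(n)], ["C"] * n, ["X"] * n, [1] * n, ["A"] * n, pos)
    moved = pos.copy()
    moved[0, 1] += 0.1
    assert rmsd(s.with_positions(moved), s, superpose=False) == pytest.approx(
        0.1 / np.sqrt(10), abs=1e-12
    )


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_superposed_rmsd_never_exceeds_raw(duplex20, seed):
    rng = np.random.default_rng(seed)
    noisy = duplex20.with_positions(
        duplex20.positions + rng.normal(0, 0.05, size=duplex20.positions.shape)
    )
    assert rmsd(noisy, duplex20, superpose=True) <= rmsd(noisy, duplex20, superpose=False) + 1e-12


def test_rmsd_atom_count_mismatch(duplex20, coronene):
    with pytest.raises(GoqdnaError):
        rmsd(duplex20, coronene)


# -- base-pair state --------------------------------------------------------


def test_ideal_pairs_are_paired(duplex20):
    assert set(basepair_states(duplex20)) == {"paired"}


def test_unwinding_opens_programmed_pairs(duplex20):
    traj, truth = make_unwinding_trajectory(duplex20, {0: 2, 1: 4, 2: 6}, n_frames=8)
    states = basepair_states(traj.frame(5))
    assert [i for i, s in enumerate(states) if s == "open"] == [0, 1]
    assert dna_hbond_count(traj.frame(7)) == 40 - 2 * 3


def test_fully_separated_strands_all_open(duplex20):
    pos = duplex20.positions.copy()
    pos[select(duplex20, "chain B").indices] += np.array([2.0, 0.0, 0.0])
    assert set(basepair_states(duplex20.with_positions(pos))) == {"open"}


def test_unwinding_stretches_dna(duplex20):
    traj, _ = make_unwinding_trajectory(duplex20, {5: 1, 6: 3}, n_frames=6)
    lengths = [dna_length(traj.frame(f)) for f in range(6)]
    assert lengths == sorted(lengths)
    assert lengths[-1] > lengths[0]
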
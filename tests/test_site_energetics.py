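"""RDF normalization, Gibbs contact-breaking energy and site classification."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from goqdna._errors import GoqdnaError, SelectionError
from goqdna.model_core import Selection, Structure, Trajectory, select
from goqdna.site_energetics import (
    RDFResult,
    classify_adsorption_site,
    gibbs_contact_energy,
    groove_proxy_selections,
    rdf,
    site_occupancy_table,
)
from goqdna.synthetic_data import ScheduleEvent, make_approach_trajectory
from conftest import goqd_groups


def uniform_gas(n=4000, box=4.0, seed=7):
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, box, size=(n, 3))
    s = Structure(
        [f"C{i}" for i in range(n)], ["C"] * n, ["X"] * n, [1] * n, ["A"] * n, pos,
        box=(box, box, box),
    )
    return Trajectory(s, [0.0], pos[None])


def test_uniform_gas_rdf_is_flat():
    traj = uniform_gas()
    n = traj.topology.n_atoms
    a = Selection("a", np.arange(n // 2))
    b = Selection("b", np.arange(n // 2, n))
    res = rdf(traj, a, b, bin_width=0.05, r_max=1.1, use_pbc=True)
    window = (res.bin_centers >= 0.3) & (res.bin_centers <= 1.0)
    assert np.abs(res.g_values[window] - 1.0).max() < 0.05


def test_rdf_pair_count_conservation_on_uniform_gas():
    """Integrating g(r) rho_b 4 pi r^2 dr recovers the ideal-gas neighbour
    count N_b V_sphere / V within 2%."""
    traj = uniform_gas(seed=12)
    n = traj.topology.n_atoms
    box = traj.topology.box[0]
    a = Selection("a", np.arange(n // 2))
    b = Selection("b", np.arange(n // 2, n))
    res = rdf(traj, a, b, bin_width=0.02, r_max=1.5, use_pbc=True)
    rho_b = (n // 2) / box**3
    integral = np.sum(res.g_values * rho_b * 4 * np.pi * res.bin_centers**2 * res.bin_width)
    expected = (n // 2) * (4 / 3) * np.pi * 1.5**3 / box**3
    assert integral == pytest.approx(expected, rel=0.02)


def test_fixed_pair_rdf_is_a_delta():
    s = Structure(
        ["C1", "C2"], ["C", "C"], ["X", "X"], [1, 2], ["A", "A"],
        np.array([[0.0, 0.0, 0.0], [0.501, 0.0, 0.0]]),
    )
    traj = Trajectory(s, np.arange(100.0), np.repeat(s.positions[None], 100, axis=0))
    res = rdf(traj, Selection("a", [0]), Selection("b", [1]), bin_width=0.002, r_max=1.0)
    nonzero = np.nonzero(res.g_values)[0]
    assert len(nonzero) == 1
    assert res.bin_centers[nonzero[0]] == pytest.approx(0.501, abs=0.002)


def test_three_atom_rdf_bins_match_hand_enumeration():
    pos = np.array([[0.0, 0.0, 0.0], [0.4, 0.0, 0.0], [0.0, 0.65, 0.0]])
    s = Structure(["A1", "B1", "B2"], ["C"] * 3, ["X"] * 3, [1, 2, 3], ["A"] * 3, pos)
    traj = Trajectory(s, [0.0], pos[None])
    res = rdf(traj, Selection("a", [0]), Selection("b", [1, 2]), bin_width=0.01, r_max=1.0)
    hits = sorted(float(res.bin_centers[i]) for i in np.nonzero(res.g_values)[0])
    np.testing.assert_allclose(hits, [0.405, 0.655], atol=1e-9)


def test_rdf_requires_r_max_within_half_box():
    traj = uniform_gas(n=100)
    a = Selection("a", np.arange(50))
    b = Selection("b", np.arange(50, 100))
    with pytest.raises(GoqdnaError, match="half"):
        rdf(traj, a, b, r_max=3.0, use_pbc=True)


def test_rdf_rejects_partially_overlapping_selections():
    traj = uniform_gas(n=100)
    with pytest.raises(SelectionError):
        rdf(traj, Selection("a", np.arange(60)), Selection("b", np.arange(50, 100)))


# -- Gibbs energy -----------------------------------------------------------


def synthetic_rdf(g_values):
    g = np.asarray(g_values, dtype=float)
    r = np.linspace(0.01, 2.0, len(g))
    return RDFResult(r, g, ("a", "b"), 1, r[1] - r[0], 2.0)


def test_flat_rdf_gives_zero_energy():
    assert gibbs_contact_energy(synthetic_rdf(np.ones(100))) == pytest.approx(0.0, abs=1e-12)


def test_peak_of_e_gives_kbt():
    g = np.ones(100)
    g[10] = np.e
    assert gibbs_contact_energy(synthetic_rdf(g), temperature=310) == pytest.approx(
        0.0083145 * 310, abs=1e-3
    )


def test_peak_of_four_closed_form():
    g = np.ones(100)
    g[10] = 4.0
    assert gibbs_contact_energy(synthetic_rdf(g), temperature=310) == pytest.approx(
        2.577495 * np.log(4), abs=1e-3
    )


def test_energy_monotone_in_peak_height():
    values = []
    for peak in (1.5, 2.5, 4.0, 8.0):
        g = np.ones(100)
        g[10] = peak
        values.append(gibbs_contact_energy(synthetic_rdf(g)))
    assert values == sorted(values)
    assert all(v >= 0 for v in values)


def test_zero_tail_is_undefined():
    g = np.zeros(100)
    g[10] = 2.0
    with pytest.raises(GoqdnaError):
        gibbs_contact_energy(synthetic_rdf(g))


# -- adsorption sites -------------------------------------------------------


def test_distant_flake_is_unbound(duplex20, coronene):
    far = coronene.translated([5.0, 0.0, 0.0])
    frame = Structure.concatenate([duplex20, far])
    dna = select(frame, "resname DA or resname DT")
    goqd = select(frame, "resname GQD")
    assert classify_adsorption_site(frame, dna, goqd) == "unbound"


def test_minor_groove_probe_is_nearer_o2_than_o4(duplex20):
    o2, o4 = groove_proxy_selections(duplex20)
    # probe placed just outside a mid-duplex thymine O2, on the minor-groove side
    i = o2.indices[10]
    p = duplex20.positions[i].copy()
    radial = p - np.array([0.0, 0.0, p[2]])
    probe = p + 0.25 * radial / np.linalg.norm(radial)
    d_minor = np.linalg.norm(duplex20.positions[o2.indices] - probe, axis=1).min()
    d_major = np.linalg.norm(duplex20.positions[o4.indices] - probe, axis=1).min()
    assert d_minor < d_major


def test_classification_labels_on_docked_poses(dispersed_system):
    sched = [
        ScheduleEvent(6, "advance_goqd", {"goqd": 3, "site": "A"}),
        ScheduleEvent(6, "advance_goqd", {"goqd": 4, "site": "B"}),
        ScheduleEvent(6, "advance_goqd", {"goqd": 5, "site": "C"}),
        ScheduleEvent(6, "advance_goqd", {"goqd": 6, "site": "D"}),
    ]
    traj, _ = make_approach_trajectory(dispersed_system, sched, n_frames=8, seed=0)
    frame = traj.frame(7)
    dna = select(frame, "resname DA or resname DT")
    for resid, expected in ((3, "A"), (4, "B"), (5, "C"), (6, "D")):
        goqd = select(frame, f"resname GQD and resid {resid}")
        assert classify_adsorption_site(frame, dna, goqd) == expected


def test_classification_invariant_under_rigid_motion(dispersed_system):
    sched = [ScheduleEvent(6, "advance_goqd", {"goqd": 4, "site": "B"})]
    traj, _ = make_approach_trajectory(dispersed_system, sched, n_frames=8, seed=0)
    frame = traj.frame(7)
    dna = select(frame, "resname DA or resname DT")
    goqd = select(frame, "resname GQD and resid 4")
    base = classify_adsorption_site(frame, dna, goqd)
    rot = Rotation.from_euler("xyz", [15, 120, -40], degrees=True).as_matrix()
    moved = frame.rotated(rot).translated([2.0, -4.0, 1.0])
    assert classify_adsorption_site(moved, dna, goqd) == base


def test_final_occupancy_matches_programmed_endpoint(dispersed_system):
    sched = [
        ScheduleEvent(10 + k, "advance_goqd", {"goqd": k + 1, "site": "A"})
        for k in range(9)
    ]
    sched.append(ScheduleEvent(15, "advance_goqd", {"goqd": 10, "site": "B"}))
    traj, truth = make_approach_trajectory(dispersed_system, sched, n_frames=22, seed=2)
    dna = select(dispersed_system, "resname DA or resname DT")
    occ = site_occupancy_table(traj, dna, goqd_groups(dispersed_system))
    assert occ.final_counts == {"A": 9, "B": 1, "C": 0, "D": 0, "unbound": 0}
    assert dict(occ.counts.iloc[0]) == {"A": 0, "B": 0, "C": 0, "D": 0, "unbound": 10}


def test_relocation_switch_detected_at_programmed_frame(dispersed_system):
    sched = [
        ScheduleEvent(5, "advance_goqd", {"goqd": 5, "site": "C"}),
        ScheduleEvent(15, "relocate_site", {"goqd": 5, "site": "D"}),
    ]
    traj, _ = make_approach_trajectory(dispersed_system, sched, n_frames=20, seed=2)
    dna = select(dispersed_system, "resname DA or resname DT")
    goqd = select(dispersed_system, "resname GQD and resid 5")
    labels = [
        classify_adsorption_site(traj.frame(f), dna, goqd) for f in range(traj.n_frames)
    ]
    assert labels[10] == "C"
    switch = next(f for f in range(10, traj.n_frames) if labels[f] == "D")
    assert abs(switch - 15) <= 1
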
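"""Deterministic mock trajectories with programmed ground truth.

These generators produce kinematic (rigid-body, not physical) motions that
exercise every analysis metric end-to-end without an MD engine:

* :func:`make_approach_trajectory` — flakes of an assembled system travel on
  straight-line paths (with spherically-interpolated reorientation) to
  docking poses at the duplex head (A), the two minor-groove halves (B, C)
  or the terminal end (D); the DNA is held rigid and non-DNA atoms receive a
  small seeded jitter.
* :func:`make_unwinding_trajectory` — programmed base pairs of a duplex open
  at given frames: each pair's bases are rigidly displaced apart
  perpendicular to the helix axis, and the terminal stack is stretched
  axially per broken pair.
* :func:`make_cluster_trajectory` — flakes on a sparse grid merge into
  stacked columns (0.34 nm inter-plane spacing) according to a schedule.

Every generator returns ``(Trajectory, ground_truth_DataFrame)`` and is
bit-reproducible from its inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation, Slerp

from ._errors import GoqdnaError, PlacementError
from .dna_integrity import duplex_pairs, _base_mask
from .model_core import Selection, Structure, Trajectory, select

__all__ = [
    "DOCK_GAP_NM",
    "JITTER_SIGMA_NM",
    "STACK_SPACING_NM",
    "ScheduleEvent",
    "make_approach_trajectory",
    "make_unwinding_trajectory",
    "make_cluster_trajectory",
]

DOCK_GAP_NM = 0.34       # heavy-atom gap of a docked flake (vdW/stacking contact)
JITTER_SIGMA_NM = 0.01   # small enough never to flip a threshold criterion
STACK_SPACING_NM = 0.34  # inter-plane spacing within a flake stack
_CONTACT_NM = 0.6        # adsorbed flag in the ground truth uses the contact cutoff


@dataclass(frozen=True)
class ScheduleEvent:
    """One programmed action of a mock trajectory.

    Actions: ``advance_goqd`` (params: ``goqd`` resid, ``site`` label,
    optional ``slot``), ``relocate_site`` (same params; motion starts two
    frames before ``frame_index``), ``break_pair`` (``pair`` index) and
    ``merge_clusters`` (``a``, ``b`` flake indices).
    """

    frame_index: int
    action: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        if self.action not in ("advance_goqd", "break_pair", "merge_clusters", "relocate_site"):
            raise ValueError(f"unknown action {self.action!r}")


# ---------------------------------------------------------------------------
# approach / adsorption
# ---------------------------------------------------------------------------


def _dna_axis_frame(system: Structure, dna: Selection):
    """(origin, t_first, t_last) of the duplex assuming its axis is along z."""
    pairs = duplex_pairs(system, dna)
    cents = []
    for p in pairs:
        idx = np.concatenate(p)
        idx = idx[_base_mask(system, idx)]
        cents.append(system.positions[idx].mean(axis=0))
    cents = np.asarray(cents)
    origin = cents.mean(axis=0)
    return origin, cents[0], cents[-1], pairs


def _slide_to_gap(local_pts, direction, start, dna_tree, gap):
    """Translate a rigid point cloud from ``start`` along ``direction`` until
    its minimum distance to the DNA equals ``gap`` (bisection)."""

    def min_dist(s):
        return float(dna_tree.query(local_pts + start + s * direction)[0].min())

    if min_dist(0.0) <= gap:
        raise PlacementError("docking path starts already in contact")
    # march forward to the first crossing, then bisect
    lo, hi = 0.0, None
    s = 0.0
    while s < 14.0:
        s += 0.1
        if min_dist(s) <= gap:
            hi = s
            break
        lo = s
    if hi is None:
        raise PlacementError("docking path never reaches the requested gap")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_dist(mid) > gap:
            lo = mid
        else:
            hi = mid
    return start + 0.5 * (lo + hi) * direction


def _dock_pose(system, dna, site, slot, n_slots, flake_local_heavy, gap):
    """Docked (rotation, centroid) for a site label and slot index.

    Flakes dock edge-on: the flake plane contains the helix axis and the
    radial direction, so several flakes fit around one site like fan blades.
    """
    origin, first, last, pairs = _dna_axis_frame(system, dna)
    dna_heavy = system.positions[
        [i for i in dna.indices if system.elements[i] != "H"]
    ]
    tree = cKDTree(dna_heavy)
    n_bp = len(pairs)

    if site in ("A", "D"):
        theta = 2.0 * np.pi * slot / max(n_slots, 1)
        rhat = np.array([np.cos(theta), np.sin(theta), 0.0])
        that = np.array([-np.sin(theta), np.cos(theta), 0.0])
        rot = _blade_orientation(flake_local_heavy, rhat, that)
        local = flake_local_heavy @ rot.T
        anchor = first if site == "A" else last
        direction = np.array([0.0, 0.0, 1.0 if site == "A" else -1.0])
        start = np.array([origin[0], origin[1], anchor[2]]) + 0.7 * rhat - 6.0 * direction
        centroid = _slide_to_gap(local, direction, start, tree, gap)
        return rot, centroid, direction

    if site in ("B", "C"):
        # aim at the minor-groove marker (thymine O2) of a pair in the
        # requested half, offset per slot
        base_pair = n_bp // 4 if site == "B" else (3 * n_bp) // 4
        pair = int(np.clip(base_pair + 2 * slot, 1, n_bp - 2))
        o2 = None
        for i in np.concatenate(pairs[pair]):
            if system.names[i] == "O2" and system.residue_names[i] == "DT":
                o2 = system.positions[i]
        if o2 is None:
            raise GoqdnaError(f"pair {pair} has no thymine O2 marker")
        theta = float(np.arctan2(o2[1] - origin[1], o2[0] - origin[0]))
        rhat = np.array([np.cos(theta), np.sin(theta), 0.0])
        that = np.array([-np.sin(theta), np.cos(theta), 0.0])
        rot = _blade_orientation(flake_local_heavy, rhat, that)
        local = flake_local_heavy @ rot.T
        start = np.array([origin[0], origin[1], o2[2]]) + 6.0 * rhat
        centroid = _slide_to_gap(local, -rhat, start, tree, gap)
        return rot, centroid, -rhat

    raise GoqdnaError(f"unknown site label {site!r}")


def _blade_orientation(local_pts, rhat, that):
    """Rotation putting a (roughly planar) flake edge-on at a site: its plane
    spans the helix axis (z) and the radial direction, normal azimuthal.

    The flake's principal axes are mapped onto the fixed target frame
    (z, rhat, that), so the docked orientation is independent of the flake's
    starting pose.
    """
    centred = local_pts - local_pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    v1, v2 = vt[0], vt[1]
    v3 = np.cross(v1, v2)
    zhat = np.array([0.0, 0.0, 1.0])
    target = np.column_stack([zhat, rhat, that])   # right-handed: z x r = theta
    source = np.column_stack([v1, v2, v3])
    return target @ source.T


def make_approach_trajectory(
    system: Structure,
    schedule,
    n_frames: int = 50,
    dt_ps: float = 100.0,
    seed: int = 0,
    dock_gap: float = DOCK_GAP_NM,
    jitter_sigma: float = JITTER_SIGMA_NM,
    retreat: float = 3.0,
):
    """Rigid-body adsorption mock over an assembled GOQD + DNA system.

    Each ``advance_goqd`` event sends a flake (identified by its GQD resid)
    from a start pose ``retreat`` nm back along its approach line to a
    docked pose at the named site, arriving at the event's frame;
    ``relocate_site`` moves an already-docked flake to a new site, starting
    two frames before arrival.  Flakes with no event keep their input pose.
    Returns the trajectory and a ground-truth table with one row per
    (frame, flake): the programmed site, the measured adsorbed flag (any
    DNA heavy atom within 0.6 nm) and the resulting label.
    """
    dna = select(system, "resname DA or resname DT")
    goqd_resids = sorted(
        {int(system.residue_indices[i]) for i in select(system, "resname GQD").indices}
    )
    flakes = {
        r: select(system, f"resname GQD and resid {r}").indices for r in goqd_resids
    }
    dna_heavy_idx = [i for i in dna.indices if system.elements[i] != "H"]
    dna_tree = cKDTree(system.positions[dna_heavy_idx])

    # slots per site, in schedule order
    site_count: dict = {}
    slot_of: dict = {}
    for ev in schedule:
        if ev.action not in ("advance_goqd", "relocate_site"):
            raise GoqdnaError(f"approach schedules accept dock events only, got {ev.action!r}")
        if ev.frame_index >= n_frames:
            raise GoqdnaError(f"event frame {ev.frame_index} outside trajectory of {n_frames}")
        key = ev.params["site"]
        slot = ev.params.get("slot")
        if slot is None:
            slot = site_count.get(key, 0)
        site_count[key] = max(site_count.get(key, 0), slot + 1)
        slot_of[id(ev)] = slot

    # keyframes per flake: (frame, rotation, centroid, programmed_site)
    keyframes = {r: [(0, np.eye(3), system.positions[flakes[r]].mean(axis=0), None)] for r in goqd_resids}
    local = {r: system.positions[flakes[r]] - system.positions[flakes[r]].mean(axis=0) for r in goqd_resids}
    for ev in sorted(schedule, key=lambda e: e.frame_index):
        r = int(ev.params["goqd"])
        if r not in flakes:
            raise GoqdnaError(f"no GQD residue {r} in the system")
        site = ev.params["site"]
        heavy_local = local[r][[k for k, i in enumerate(flakes[r]) if system.elements[i] != "H"]]
        rot, cen, direction = _dock_pose(
            system, dna, site, slot_of[id(ev)], site_count[site], heavy_local, dock_gap
        )
        frames_list = keyframes[r]
        if ev.action == "relocate_site":
            hold = max(frames_list[-1][0], ev.frame_index - 2)
            prev = frames_list[-1]
            frames_list.append((hold, prev[1], prev[2], prev[3]))
        else:
            # a first docking starts 3 nm back along its own approach line,
            # already in the docked orientation: the per-flake minimum
            # distance to the DNA then shrinks monotonically
            frames_list[0] = (0, rot, cen - retreat * direction, None)
        keyframes[r].append((ev.frame_index, rot, cen, site))

    # docked poses must not overlap (parked flakes are not checked: the mock
    # is kinematic and an undocked flake may be crossed by a docking one)
    docked = {r: kf[-1] for r, kf in keyframes.items() if kf[-1][3] is not None}
    resids_docked = sorted(docked)
    for i, ri in enumerate(resids_docked):
        for rj in resids_docked[i + 1 :]:
            pi = local[ri] @ docked[ri][1].T + docked[ri][2]
            pj = local[rj] @ docked[rj][1].T + docked[rj][2]
            if float(cKDTree(pi).query(pj)[0].min()) < 0.1:
                raise PlacementError(f"flakes {ri} and {rj} dock at overlapping poses")

    rng = np.random.default_rng(seed)
    coords = np.empty((n_frames, system.n_atoms, 3))
    truth_rows = []
    dna_all_tree = cKDTree(system.positions[dna.indices])
    for f in range(n_frames):
        pos = system.positions.copy()
        state = {}
        for r in goqd_resids:
            kf = keyframes[r]
            # active segment
            seg = None
            for a, b in zip(kf[:-1], kf[1:]):
                if a[0] <= f <= b[0]:
                    seg = (a, b)
            if seg is None:
                a = kf[-1]
                rot, cen, site = a[1], a[2], a[3]
            else:
                a, b = seg
                if b[0] == a[0]:
                    w = 1.0
                else:
                    w = (f - a[0]) / (b[0] - a[0])
                slerp = Slerp([0.0, 1.0], Rotation.from_matrix([a[1], b[1]]))
                rot = slerp(w).as_matrix()
                cen = (1 - w) * a[2] + w * b[2]
                site = b[3] if w >= 1.0 else (b[3] if a[3] is None else a[3])
            pos[flakes[r]] = local[r] @ rot.T + cen
            arrived = f >= kf[-1][0] or (seg is not None and seg[1][0] <= f)
            state[r] = (site, arrived)
        # seeded jitter on non-DNA atoms only; DNA is held rigid
        jitter = rng.normal(0.0, jitter_sigma, size=pos.shape)
        jitter[dna.indices] = 0.0
        coords[f] = pos + jitter
        # ground truth measured on the emitted coordinates, with the same
        # all-atom contact criterion the classifier applies
        for r in goqd_resids:
            prog_site, arrived = state[r]
            dmin = float(dna_all_tree.query(coords[f][flakes[r]])[0].min())
            adsorbed = dmin < _CONTACT_NM
            truth_rows.append(
                {
                    "frame": f,
                    "time_ps": f * dt_ps,
                    "goqd": r,
                    "programmed_site": prog_site if prog_site is not None else "unbound",
                    "arrived": bool(arrived and prog_site is not None),
                    "adsorbed": adsorbed,
                    "label": (
                        prog_site if (arrived and adsorbed and prog_site) else "unbound"
                    ),
                    "min_dist_nm": dmin,
                }
            )
    traj = Trajectory(system, np.arange(n_frames) * dt_ps, coords)
    return traj, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# base-pair unwinding
# ---------------------------------------------------------------------------


def make_unwinding_trajectory(
    dna: Structure,
    pairs_broken_at: dict,
    displacement: float = 1.0,
    terminal_stretch: float = 0.02,
    n_frames: int = 25,
    dt_ps: float = 100.0,
):
    """Progressive base-pair opening of a duplex.

    ``pairs_broken_at`` maps 0-based pair indices to the frame at which the
    pair opens: from that frame on, the pair's base atoms are rigidly
    displaced apart (each base by ``displacement / 2``) along the in-plane
    direction joining the two base centroids, and the last base pair is
    shifted axially by ``terminal_stretch`` per broken pair.  The ground
    truth carries the expected hydrogen-bond count ``2 * n_bp - 2k`` and the
    open-pair set per frame.
    """
    pairs = duplex_pairs(dna)
    n_bp = len(pairs)
    for p, f in pairs_broken_at.items():
        if not (0 <= p < n_bp):
            raise GoqdnaError(f"pair index {p} outside duplex of {n_bp} pairs")
        if not (0 <= f < n_frames):
            raise GoqdnaError(f"break frame {f} outside trajectory of {n_frames} frames")
    if len(set(pairs_broken_at.keys())) != len(pairs_broken_at):
        raise GoqdnaError("duplicate pair events")

    axis = np.array([0.0, 0.0, 1.0])
    base_idx = []
    for p in range(n_bp):
        a1, a2 = pairs[p]
        base_idx.append((a1[_base_mask(dna, a1)], a2[_base_mask(dna, a2)]))

    last_pair_atoms = np.concatenate(pairs[-1])
    coords = np.empty((n_frames, dna.n_atoms, 3))
    truth_rows = []
    for f in range(n_frames):
        pos = dna.positions.copy()
        open_pairs = sorted(p for p, bf in pairs_broken_at.items() if bf <= f)
        for p in open_pairs:
            b1, b2 = base_idx[p]
            c1 = dna.positions[b1].mean(axis=0)
            c2 = dna.positions[b2].mean(axis=0)
            u = c2 - c1
            u -= axis * np.dot(u, axis)   # in-plane, perpendicular to the axis
            u /= np.linalg.norm(u)
            pos[b1] -= 0.5 * displacement * u
            pos[b2] += 0.5 * displacement * u
        k = len(open_pairs)
        if k and terminal_stretch:
            pos[last_pair_atoms] += axis * (terminal_stretch * k)
        coords[f] = pos
        truth_rows.append(
            {
                "frame": f,
                "time_ps": f * dt_ps,
                "n_broken": k,
                "expected_hbonds": 2 * n_bp - 2 * k,
                "open_pairs": ",".join(str(p) for p in open_pairs),
            }
        )
    traj = Trajectory(dna, np.arange(n_frames) * dt_ps, coords)
    return traj, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# flake aggregation
# ---------------------------------------------------------------------------


def make_cluster_trajectory(
    flake: Structure,
    n_goqds: int,
    merge_schedule,
    box: float = 11.0,
    n_frames: int = 30,
    dt_ps: float = 100.0,
    seed: int = 0,
    jitter_sigma: float = 0.005,
):
    """Flake aggregation mock: merges translate whole clusters into stacks.

    Flakes start on a sparse grid (>= 2 nm apart).  ``merge_schedule`` is a
    list of ``(frame, a, b)`` with ``a``/``b`` 0-based flake indices: at that
    frame the cluster containing ``b`` is restacked on top of the cluster
    containing ``a`` (0.34 nm inter-plane spacing).  Ground truth carries
    per-frame ``n_clusters`` and ``max_cluster_size``.
    """
    flake0 = flake.translated(-flake.positions.mean(axis=0))
    # one planar grid (stacks grow upward into empty space), spacing >= 2 nm
    per_row = int(np.ceil(np.sqrt(n_goqds)))
    spacing = min(2.4, (box - 1.6) / max(per_row - 1, 1))
    if spacing < 2.0:
        raise PlacementError("box too small to start all flakes >= 2 nm apart")
    sites = [
        np.array([0.8 + (k % per_row) * spacing, 0.8 + (k // per_row) * spacing, 1.0])
        for k in range(n_goqds)
    ]

    # cluster state: flake -> (column id); column id -> base site and stack order
    column_of = list(range(n_goqds))
    columns = {c: [c] for c in range(n_goqds)}

    events = sorted(merge_schedule, key=lambda e: e[0])
    for f, a, b in events:
        if not (0 <= f < n_frames):
            raise GoqdnaError(f"merge frame {f} outside trajectory of {n_frames} frames")

    def positions_for(columns_state):
        centers = {}
        for cid, members in columns_state.items():
            base = sites[cid]
            for h, flk in enumerate(members):
                centers[flk] = base + np.array([0.0, 0.0, STACK_SPACING_NM * h])
        return centers

    rng = np.random.default_rng(seed)
    coords = np.empty((n_frames, flake0.n_atoms * n_goqds, 3))
    truth_rows = []
    ei = 0
    for f in range(n_frames):
        while ei < len(events) and events[ei][0] <= f:
            _, a, b = events[ei]
            ca, cb = column_of[a], column_of[b]
            if ca == cb:
                raise GoqdnaError(f"flakes {a} and {b} are already in one cluster")
            columns[ca].extend(columns[cb])
            for flk in columns[cb]:
                column_of[flk] = ca
            del columns[cb]
            ei += 1
        centers = positions_for(columns)
        pos = np.vstack([flake0.positions + centers[flk] for flk in range(n_goqds)])
        pos += rng.normal(0.0, jitter_sigma, size=pos.shape)
        coords[f] = pos
        sizes = [len(m) for m in columns.values()]
        truth_rows.append(
            {
                "frame": f,
                "time_ps": f * dt_ps,
                "n_clusters": len(sizes),
                "max_cluster_size": max(sizes),
            }
        )

    parts = []
    for r in range(n_goqds):
        parts.append(
            Structure(
                flake0.names,
                flake0.elements,
                ["GQD"] * flake0.n_atoms,
                [r + 1] * flake0.n_atoms,
                ["G"] * flake0.n_atoms,
                flake0.positions,
            )
        )
    topology = Structure.concatenate(parts, box=(box, box, box))
    traj = Trajectory(topology, np.arange(n_frames) * dt_ps, coords)
    return traj, pd.DataFrame(truth_rows)
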
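"""DNA structural-damage metrics.

Hydrogen-bond counting (geometric criterion: donor-acceptor distance
<= 0.35 nm and H-D...A angle <= 30 deg, the common `gmx hbond` convention),
intra-DNA pi-pi stacking (ring-centroid distance < 0.4 nm and inter-plane
angle < 36 deg), end-to-end DNA length (distance between the base centroids
of the first and last base pairs), RMSD to a reference (optionally after
Kabsch superposition), and per-pair open/paired state.

The duplex layout convention matches the builder: two chains with equal
residue counts, antiparallel, so residue i of the first chain pairs with
residue n+1-i of the second.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._bdna_template import BACKBONE_NAMES
from ._errors import GoqdnaError, SelectionError
from .model_core import Selection, Structure, select

__all__ = [
    "HBOND_DA_MAX_NM",
    "HBOND_ANGLE_MAX_DEG",
    "STACK_DIST_NM",
    "STACK_ANGLE_DEG",
    "HBondCriteria",
    "RingDefinition",
    "ResolvedRing",
    "DEFAULT_RINGS",
    "duplex_pairs",
    "polyAT_hbond_selections",
    "count_hbonds",
    "dna_hbond_count",
    "resolve_rings",
    "count_pipi_stacking",
    "dna_length",
    "rmsd",
    "basepair_state",
    "basepair_states",
]

HBOND_DA_MAX_NM = 0.35
HBOND_ANGLE_MAX_DEG = 30.0
STACK_DIST_NM = 0.4
STACK_ANGLE_DEG = 36.0
_DH_BOND_MAX_NM = 0.115  # covalent D-H resolution radius within a residue


@dataclass(frozen=True)
class HBondCriteria:
    donor_acceptor_max: float = HBOND_DA_MAX_NM  # nm
    angle_max: float = HBOND_ANGLE_MAX_DEG       # degrees, H-D...A at the donor

    def __post_init__(self) -> None:
        if self.donor_acceptor_max <= 0 or self.angle_max <= 0:
            raise ValueError("hydrogen-bond criteria must be positive")


@dataclass(frozen=True)
class RingDefinition:
    """Aromatic ring of a residue type, by member atom names."""

    residue_name: str
    ring_label: str
    member_atom_names: tuple

    def __post_init__(self) -> None:
        if len(self.member_atom_names) < 5:
            raise ValueError("a ring needs at least 5 member atoms")


#: adenine contributes its six- and five-membered rings, thymine one ring
DEFAULT_RINGS = (
    RingDefinition("DA", "pyrimidine6", ("N1", "C2", "N3", "C4", "C5", "C6")),
    RingDefinition("DA", "imidazole5", ("C4", "C5", "N7", "C8", "N9")),
    RingDefinition("DT", "pyrimidine6", ("N1", "C2", "N3", "C4", "C5", "C6")),
)


@dataclass(frozen=True)
class ResolvedRing:
    chain_id: str
    residue_index: int
    ring_label: str
    atom_indices: np.ndarray

    @property
    def base_key(self):
        return (self.chain_id, self.residue_index)


# ---------------------------------------------------------------------------
# duplex topology helpers
# ---------------------------------------------------------------------------


def _residue_atoms(structure: Structure, indices: np.ndarray):
    """Group atom indices by (chain, resid), preserving first-seen order."""
    groups: dict = {}
    for i in indices:
        key = (structure.chain_ids[i], int(structure.residue_indices[i]))
        groups.setdefault(key, []).append(int(i))
    return {k: np.array(v) for k, v in groups.items()}


def duplex_pairs(structure: Structure, dna: Selection | None = None):
    """Resolve a duplex into base pairs.

    Returns a list of ``(atoms_strand1, atoms_strand2)`` index arrays, one
    per pair, ordered along strand 1.  Strand 1 residue i pairs with strand 2
    residue n-1-i (antiparallel convention).
    """
    if dna is None:
        dna = select(structure, "resname DA or resname DT")
    if len(dna) == 0:
        raise SelectionError("no DNA atoms found")
    groups = _residue_atoms(structure, dna.indices)
    chains = sorted({c for c, _ in groups})
    if len(chains) != 2:
        raise GoqdnaError(f"expected a duplex of 2 chains, found {chains}")
    per_chain = {
        c: [groups[k] for k in sorted(groups, key=lambda k: k[1]) if k[0] == c]
        for c in chains
    }
    r1, r2 = per_chain[chains[0]], per_chain[chains[1]]
    if len(r1) != len(r2):
        raise GoqdnaError(
            f"chains have unequal residue counts ({len(r1)} vs {len(r2)}); "
            "termini are unpaired"
        )
    n = len(r1)
    return [(r1[i], r2[n - 1 - i]) for i in range(n)]


def _base_mask(structure: Structure, indices: np.ndarray) -> np.ndarray:
    return np.array([structure.names[i] not in BACKBONE_NAMES for i in indices])


def polyAT_hbond_selections(structure: Structure):
    """Default Watson-Crick donor/acceptor selections for a poly(A-T) duplex.

    Donors: adenine N6 and thymine N3.  Acceptors: thymine O2/O4 and adenine
    N1/N3/N7.
    """
    donors = select(structure, "(name N6 and resname DA) or (name N3 and resname DT)")
    acceptors = select(
        structure,
        "(name O2 and resname DT) or (name O4 and resname DT) or "
        "((name N1 or name N3 or name N7) and resname DA)",
    )
    return donors, acceptors


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------


def _attached_hydrogens(frame: Structure, donor: int) -> np.ndarray:
    """Hydrogens covalently attached to a donor heavy atom (same residue,
    within the covalent D-H radius)."""
    key = (frame.chain_ids[donor], int(frame.residue_indices[donor]))
    hs = [
        i
        for i in range(frame.n_atoms)
        if frame.elements[i] == "H"
        and (frame.chain_ids[i], int(frame.residue_indices[i])) == key
        and np.linalg.norm(frame.positions[i] - frame.positions[donor]) <= _DH_BOND_MAX_NM
    ]
    return np.array(hs, dtype=int)


def count_hbonds(
    frame: Structure,
    donors: Selection,
    acceptors: Selection,
    criteria: HBondCriteria = HBondCriteria(),
    interstrand_only: bool = False,
) -> int:
    """Count (D-H, A) hydrogen bonds under a geometric criterion.

    A bond requires D...A distance <= ``donor_acceptor_max`` and the angle at
    the donor between D->H and D->A <= ``angle_max``.  With
    ``interstrand_only`` the donor and acceptor must lie on different chains
    and both be base (non-backbone) atoms.
    """
    if len(donors) == 0 or len(acceptors) == 0:
        return 0
    acc_idx = acceptors.indices
    if interstrand_only:
        acc_idx = acc_idx[_base_mask(frame, acc_idx)]
    acc_pos = frame.positions[acc_idx]
    acc_tree = cKDTree(acc_pos)
    count = 0
    for d in donors.indices:
        if interstrand_only and frame.names[d] in BACKBONE_NAMES:
            continue
        hs = _attached_hydrogens(frame, d)
        if len(hs) == 0:
            raise GoqdnaError(
                f"donor {frame.names[d]!r} (atom {d}) has no resolvable hydrogen"
            )
        dpos = frame.positions[d]
        near = acc_tree.query_ball_point(dpos, criteria.donor_acceptor_max)
        for k in near:
            a = acc_idx[k]
            if a == d:
                continue
            if interstrand_only and frame.chain_ids[a] == frame.chain_ids[d]:
                continue
            da = acc_pos[k] - dpos
            for h in hs:
                dh = frame.positions[h] - dpos
                cosang = np.dot(dh, da) / (np.linalg.norm(dh) * np.linalg.norm(da))
                ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if ang <= criteria.angle_max:
                    count += 1
    return count


def dna_hbond_count(
    frame: Structure, criteria: HBondCriteria = HBondCriteria()
) -> int:
    """Inter-strand base-base hydrogen bonds of a poly(A-T) duplex."""
    donors, acceptors = polyAT_hbond_selections(frame)
    return count_hbonds(frame, donors, acceptors, criteria, interstrand_only=True)


def basepair_state(frame: Structure, pair_index: int, criteria: HBondCriteria = HBondCriteria()) -> str:
    """``"open"`` if the pair retains no inter-strand hydrogen bond, else ``"paired"``."""
    return basepair_states(frame, criteria)[pair_index]


def basepair_states(frame: Structure, criteria: HBondCriteria = HBondCriteria()):
    """Per-pair labels ("paired"/"open") along the duplex."""
    pairs = duplex_pairs(frame)
    donors, acceptors = polyAT_hbond_selections(frame)
    labels = []
    for atoms1, atoms2 in pairs:
        members = set(atoms1.tolist()) | set(atoms2.tolist())
        d = Selection("pair-donors", [i for i in donors.indices if i in members])
        a = Selection("pair-acceptors", [i for i in acceptors.indices if i in members])
        n = count_hbonds(frame, d, a, criteria, interstrand_only=True) if len(d) and len(a) else 0
        labels.append("open" if n == 0 else "paired")
    return labels


# ---------------------------------------------------------------------------
# pi-pi stacking
# ---------------------------------------------------------------------------


def resolve_rings(
    structure: Structure,
    definitions=DEFAULT_RINGS,
    dna: Selection | None = None,
):
    """Instantiate ring definitions on every matching residue."""
    if dna is None:
        resnames = sorted({d.residue_name for d in definitions})
        dna = select(structure, " or ".join(f"resname {r}" for r in resnames))
    groups = _residue_atoms(structure, dna.indices)
    rings = []
    for (chain, resid), atoms in groups.items():
        resname = structure.residue_names[atoms[0]]
        for d in definitions:
            if d.residue_name != resname:
                continue
            members = [i for i in atoms if structure.names[i] in d.member_atom_names]
            if len(members) < 3:
                raise GoqdnaError(
                    f"ring {d.ring_label} of {resname} {chain}:{resid} resolves "
                    f"to only {len(members)} atoms"
                )
            rings.append(ResolvedRing(chain, resid, d.ring_label, np.array(members)))
    return rings


def _plane_normal(points: np.ndarray) -> np.ndarray:
    centred = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    return vt[-1]


def count_pipi_stacking(
    frame: Structure,
    rings,
    dist_cutoff: float = STACK_DIST_NM,
    angle_cutoff: float = STACK_ANGLE_DEG,
) -> int:
    """Number of stacked ring pairs (centroid distance < ``dist_cutoff`` nm
    and best-fit-plane angle < ``angle_cutoff`` deg), excluding ring pairs of
    the same base."""
    centroids = np.array([frame.positions[r.atom_indices].mean(axis=0) for r in rings])
    normals = np.array([_plane_normal(frame.positions[r.atom_indices]) for r in rings])
    count = 0
    tree = cKDTree(centroids)
    for i, j in tree.query_pairs(dist_cutoff * (1 - 1e-12)):
        if rings[i].base_key == rings[j].base_key:
            continue
        cosang = abs(float(np.dot(normals[i], normals[j])))
        ang = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))  # folded to [0, 90]
        if ang < angle_cutoff:
            count += 1
    return count


# ---------------------------------------------------------------------------
# length and RMSD
# ---------------------------------------------------------------------------


def dna_length(frame: Structure, dna: Selection | None = None) -> float:
    """End-to-end length (nm): distance between the base centroids of the
    first and last base pairs (backbone atoms excluded)."""
    pairs = duplex_pairs(frame, dna)

    def base_centroid(pair):
        idx = np.concatenate(pair)
        idx = idx[_base_mask(frame, idx)]
        return frame.positions[idx].mean(axis=0)

    return float(np.linalg.norm(base_centroid(pairs[0]) - base_centroid(pairs[-1])))


def rmsd(
    frame: Structure,
    reference: Structure,
    selection: Selection | None = None,
    superpose: bool = True,
) -> float:
    """RMSD (nm) between a frame and a reference over a selection.

    With ``superpose`` the optimal least-squares rigid transform (Kabsch) is
    removed first.
    """
    idx = selection.indices if selection is not None else np.arange(frame.n_atoms)
    if reference.n_atoms != frame.n_atoms:
        raise GoqdnaError(
            f"atom-count mismatch: frame has {frame.n_atoms}, reference "
            f"{reference.n_atoms}"
        )
    x = frame.positions[idx]
    y = reference.positions[idx]
    if superpose:
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        h = xc.T @ yc
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(u @ vt))
        rot = u @ np.diag([1.0, 1.0, d]) @ vt
        x = xc @ rot
        y = yc
    return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))
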
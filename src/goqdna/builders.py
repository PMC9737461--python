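"""Generators for the study's input structures.

Three builders are provided:

* :func:`build_goqd` — a circular graphene-oxide quantum-dot flake: carbons on
  an ideal honeycomb lattice (C-C 0.142 nm) kept if they satisfy the circular
  radius rule x^2 + y^2 < R^2, edges capped with in-plane hydrogens
  (C-H 0.109 nm), and a seeded random subset of edge hydrogens replaced by
  OH or COOH groups.
* :func:`build_bdna_polyAT` — an idealized B-form poly(A-T) duplex built from
  a fixed base-pair template by applying the canonical rise (0.338 nm) and
  twist (36 deg) per step; two antiparallel chains named DA / DT.
* :func:`assemble_system` — the initial simulation geometry: the duplex on the
  z-axis at the centre of a cubic box, two flakes on the axis beyond the
  duplex ends, and the remaining flakes in an azimuthal shell at a controlled
  minimum heavy-atom gap from the DNA.

Builders emit idealized geometry; no energy minimization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from ._bdna_template import PAIR_TEMPLATE, RISE_NM, TWIST_DEG
from ._errors import CapacityError, PlacementError
from .model_core import Structure

__all__ = [
    "GOQDSpec",
    "AssemblyGeometry",
    "build_goqd",
    "build_bdna_polyAT",
    "assemble_system",
]

CC_BOND_NM = 0.142
CH_BOND_NM = 0.109
# idealized sp2 carboxyl geometry
COOH_CC_NM = 0.152
COOH_CDO_NM = 0.122   # C=O
COOH_CO_NM = 0.136    # C-OH
OH_CO_NM = 0.143
OH_BOND_NM = 0.097

_CENTER_SPACING = CC_BOND_NM * np.sqrt(3.0)  # 0.246 nm between ring centres


@dataclass(frozen=True)
class GOQDSpec:
    """Parameterization of a flake.

    Either ``radius`` (nm) or ``ring_count`` (a centred hexagonal number:
    1, 7, 19, 37, ... rings) must be given.  ``group_count`` hydroxyl or
    carboxyl groups replace randomly chosen edge hydrogens, reproducibly
    from ``seed``.
    """

    radius: float | None = None
    ring_count: int | None = None
    group_type: str = "none"   # {"OH", "COOH", "none"}
    group_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.radius is None) == (self.ring_count is None):
            raise ValueError("give exactly one of radius or ring_count")
        if self.radius is not None and self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.group_type not in ("OH", "COOH", "none"):
            raise ValueError(f"unknown group_type {self.group_type!r}")
        if self.group_count < 0:
            raise ValueError("group_count must be non-negative")
        if self.group_type == "none" and self.group_count > 0:
            raise ValueError("group_count > 0 requires group_type OH or COOH")

    def effective_radius(self) -> float:
        if self.radius is not None:
            return float(self.radius)
        return _rings_to_radius(self.ring_count)


def _rings_to_radius(ring_count: int) -> float:
    """Radius enclosing exactly ``ring_count`` rings of a centred flake.

    Compact circular flakes have centred-hexagonal ring counts
    (1 + 3k(k+1)): a central ring plus k complete shells of fused rings.
    The returned radius lies between the outermost carbons of shell k and
    the nearest carbons of shell k+1.
    """
    k = 0
    while 1 + 3 * k * (k + 1) < ring_count:
        k += 1
    if 1 + 3 * k * (k + 1) != ring_count:
        valid = [1 + 3 * j * (j + 1) for j in range(6)]
        raise ValueError(
            f"ring_count {ring_count} is not a centred hexagonal number "
            f"(valid: {valid} ...); pass an explicit radius instead"
        )
    return _CENTER_SPACING * k + CC_BOND_NM + 0.018


def _honeycomb_carbons(radius: float) -> np.ndarray:
    """All honeycomb-lattice carbon positions with x^2+y^2 < radius^2 (z=0)."""
    a1 = np.array([_CENTER_SPACING, 0.0])
    a2 = np.array([_CENTER_SPACING / 2.0, _CENTER_SPACING * np.sqrt(3.0) / 2.0])
    nmax = int(np.ceil((radius + 2 * CC_BOND_NM) / _CENTER_SPACING)) + 2
    verts = CC_BOND_NM * np.array(
        [[np.cos(np.deg2rad(90 + 60 * k)), np.sin(np.deg2rad(90 + 60 * k))] for k in range(6)]
    )
    seen = {}
    for i in range(-nmax, nmax + 1):
        for j in range(-nmax, nmax + 1):
            c = i * a1 + j * a2
            if np.dot(c, c) > (radius + 2 * CC_BOND_NM) ** 2:
                continue
            for v in verts:
                p = c + v
                key = (round(p[0], 4), round(p[1], 4))
                if key not in seen and p[0] ** 2 + p[1] ** 2 < radius**2:
                    seen[key] = p
    pts = np.array(list(seen.values()))
    # deterministic order: by radius, then angle
    r = np.hypot(pts[:, 0], pts[:, 1])
    ang = np.arctan2(pts[:, 1], pts[:, 0])
    order = np.lexsort((np.round(ang, 6), np.round(r, 6)))
    return np.column_stack([pts[order], np.zeros(len(pts))])


def build_goqd(spec: GOQDSpec) -> Structure:
    """Build a flat GOQD flake in the z=0 plane centred at the origin."""
    radius = spec.effective_radius()
    carbons = _honeycomb_carbons(radius)
    if len(carbons) < 6:
        raise ValueError(f"radius {radius} nm encloses no complete ring")
    tree = cKDTree(carbons)
    pairs = tree.query_pairs(CC_BOND_NM + 0.01)
    nneigh = np.zeros(len(carbons), dtype=int)
    bond_vecs = [[] for _ in range(len(carbons))]
    for i, j in pairs:
        nneigh[i] += 1
        nneigh[j] += 1
        bond_vecs[i].append(carbons[j] - carbons[i])
        bond_vecs[j].append(carbons[i] - carbons[j])

    # edge carbons (fewer than 3 carbon neighbours) get one in-plane H each,
    # pointing away from the mean bond direction
    edge_h = []  # (carbon_index, H position, outward unit vector)
    for i in range(len(carbons)):
        if nneigh[i] < 3:
            v = -np.sum(bond_vecs[i], axis=0)
            v[2] = 0.0
            v /= np.linalg.norm(v)
            edge_h.append((i, carbons[i] + CH_BOND_NM * v, v))

    if spec.group_count > len(edge_h):
        raise CapacityError(
            f"requested {spec.group_count} {spec.group_type} groups but the "
            f"flake has only {len(edge_h)} edge sites"
        )
    rng = np.random.default_rng(spec.seed)
    chosen = set(
        rng.choice(len(edge_h), size=spec.group_count, replace=False).tolist()
        if spec.group_count
        else []
    )

    def rot_z(deg: float) -> np.ndarray:
        t = np.deg2rad(deg)
        return np.array(
            [[np.cos(t), -np.sin(t), 0.0], [np.sin(t), np.cos(t), 0.0], [0.0, 0.0, 1.0]]
        )

    names, elements, positions = [], [], []
    for k, c in enumerate(carbons):
        names.append(f"C{k + 1}")
        elements.append("C")
        positions.append(c)
    n_h = n_o = n_c = len(carbons)
    for k, (ci, hpos, v) in enumerate(edge_h):
        if k not in chosen:
            n_h += 1
            names.append(f"H{n_h}")
            elements.append("H")
            positions.append(hpos)
            continue
        base = carbons[ci]
        if spec.group_type == "OH":
            o = base + OH_CO_NM * v
            h = o + OH_BOND_NM * (rot_z(71.0) @ v)
            for nm, el, p in (("O", "O", o), ("H", "H", h)):
                n = {"O": None, "H": None}
                if el == "O":
                    n_o += 1
                    names.append(f"O{n_o}")
                else:
                    n_h += 1
                    names.append(f"H{n_h}")
                elements.append(el)
                positions.append(p)
        else:  # COOH: carboxyl C, =O, -O, H, planar with the flake
            cx = base + COOH_CC_NM * v
            o_dbl = cx + COOH_CDO_NM * (rot_z(120.0) @ v)
            o_h = cx + COOH_CO_NM * (rot_z(-120.0) @ v)
            h = o_h + OH_BOND_NM * v
            n_c += 1
            names.append(f"C{n_c}")
            elements.append("C")
            positions.append(cx)
            for p in (o_dbl, o_h):
                n_o += 1
                names.append(f"O{n_o}")
                elements.append("O")
                positions.append(p)
            n_h += 1
            names.append(f"H{n_h}")
            elements.append("H")
            positions.append(h)

    n = len(names)
    return Structure(
        names=names,
        elements=elements,
        residue_names=["GQD"] * n,
        residue_indices=[1] * n,
        chain_ids=["G"] * n,
        positions=np.array(positions),
    )


# ---------------------------------------------------------------------------
# DNA
# ---------------------------------------------------------------------------


def build_bdna_polyAT(n_bp: int) -> Structure:
    """Idealized B-form poly(A-T) duplex with ``n_bp`` base pairs.

    Chain A carries the adenines (5'->3' with increasing resid), chain B the
    thymines, antiparallel: chain B residue j pairs with chain A residue
    n_bp + 1 - j.  The helical axis is the z-axis; pair i (0-based) sits at
    z = i * 0.338 nm, rotated by i * 36 deg.
    """
    if n_bp < 2:
        raise ValueError("a duplex needs at least 2 base pairs")

    def pair_coords(i: int, strand: str):
        t = np.deg2rad(TWIST_DEG * i)
        c, s = np.cos(t), np.sin(t)
        out = []
        for st, nm, el, x, y, z in PAIR_TEMPLATE:
            if st != strand:
                continue
            out.append((nm, el, (c * x - s * y, s * x + c * y, z + RISE_NM * i)))
        return out

    names, elements, resnames, resids, chains, positions = [], [], [], [], [], []
    for i in range(n_bp):  # chain A: adenines, resid = pair + 1
        for nm, el, p in pair_coords(i, "A"):
            names.append(nm)
            elements.append(el)
            resnames.append("DA")
            resids.append(i + 1)
            chains.append("A")
            positions.append(p)
    for j in range(n_bp):  # chain B: thymines, resid j+1 pairs with pair n_bp-1-j
        i = n_bp - 1 - j
        for nm, el, p in pair_coords(i, "T"):
            names.append(nm)
            elements.append(el)
            resnames.append("DT")
            resids.append(j + 1)
            chains.append("B")
            positions.append(p)
    return Structure(names, elements, resnames, resids, chains, np.array(positions))


# ---------------------------------------------------------------------------
# system assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssemblyGeometry:
    """Initial-placement geometry of the GOQD + DNA system."""

    n_goqds: int = 10
    surface_gap: float = 0.2           # min heavy-atom DNA-flake gap, nm
    axial_pair_separation: float = 8.0  # centroid separation of the end flakes, nm
    box_edge: float = 11.0             # cubic box edge, nm

    def __post_init__(self) -> None:
        if self.n_goqds < 1:
            raise ValueError("n_goqds must be >= 1")
        for f in ("surface_gap", "axial_pair_separation", "box_edge"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


def _rotation_z_to(u: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping the z unit vector onto unit vector u."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, u)
    s = np.linalg.norm(v)
    c = float(np.dot(z, u))
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def _heavy(structure: Structure) -> np.ndarray:
    return structure.positions[np.array([e != "H" for e in structure.elements])]


def assemble_system(
    dna: Structure,
    goqd_template: Structure,
    geometry: AssemblyGeometry,
    seed: int = 0,
) -> Structure:
    """Place ``n_goqds`` copies of a flake around a duplex in a cubic box.

    The duplex axis is aligned with z through the box centre; two flakes sit
    on the axis beyond the duplex ends (centroids ``axial_pair_separation``
    apart) and the rest form an azimuthal shell, each slid radially inward
    until its minimum heavy-atom distance to the DNA equals ``surface_gap``.
    """
    geo = geometry
    if geo.n_goqds < 2:
        raise PlacementError("axial placement needs n_goqds >= 2 (the two end flakes)")
    L = geo.box_edge
    center = np.array([L / 2.0, L / 2.0, L / 2.0])
    zmid = 0.5 * (dna.positions[:, 2].min() + dna.positions[:, 2].max())
    dna_c = dna.translated(center - np.array([0.0, 0.0, zmid]))
    dna_heavy = _heavy(dna_c)
    dna_tree = cKDTree(dna_heavy)

    flake0 = goqd_template.translated(-goqd_template.positions.mean(axis=0))
    flake_heavy_local = _heavy(flake0)

    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)

    placed: list[Structure] = []
    # axial pair, flake plane perpendicular to the axis
    for sign in (+1.0, -1.0):
        placed.append(
            flake0.translated(center + np.array([0.0, 0.0, sign * geo.axial_pair_separation / 2]))
        )
    # azimuthal shell; flakes are oriented edge-on (plane spanned by the
    # radial and axial directions) so neighbouring flakes do not collide
    n_shell = geo.n_goqds - 2
    span = 0.85 * (dna_c.positions[:, 2].max() - dna_c.positions[:, 2].min())
    for i in range(n_shell):
        theta = phase + 2.0 * np.pi * i / n_shell
        u = np.array([np.cos(theta), np.sin(theta), 0.0])
        tangent = np.array([-np.sin(theta), np.cos(theta), 0.0])
        R = _rotation_z_to(tangent)  # flake normal becomes azimuthal
        zi = center[2] + ((i + 0.5) / n_shell - 0.5) * span
        local = flake_heavy_local @ R.T

        def gap(r: float) -> float:
            pts = local + center + r * u + np.array([0.0, 0.0, zi - center[2]])
            d, _ = dna_tree.query(pts)
            return float(d.min())

        lo, hi = 0.0, 6.0
        if gap(hi) < geo.surface_gap:
            raise PlacementError("flake cannot reach the requested surface gap")
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if gap(mid) < geo.surface_gap:
                lo = mid
            else:
                hi = mid
        r = 0.5 * (lo + hi)
        placed.append(
            flake0.rotated(R).translated(center + r * u + np.array([0.0, 0.0, zi - center[2]]))
        )

    # no two flakes may approach below 0.3 nm (heavy atoms)
    heavies = [_heavy(p) for p in placed]
    for i in range(len(placed)):
        for j in range(i + 1, len(placed)):
            if cdist(heavies[i], heavies[j]).min() < 0.3:
                raise PlacementError(
                    f"flakes {i} and {j} pack closer than 0.3 nm; "
                    "reduce n_goqds or enlarge the geometry"
                )

    # renumber flakes as residues GQD 1..n on chain G
    flakes = []
    for k, p in enumerate(placed):
        flakes.append(
            Structure(
                p.names,
                p.elements,
                ["GQD"] * p.n_atoms,
                [k + 1] * p.n_atoms,
                ["G"] * p.n_atoms,
                p.positions,
            )
        )
    return Structure.concatenate([dna_c] + flakes, box=(L, L, L))
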
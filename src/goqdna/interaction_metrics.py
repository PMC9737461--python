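"""Per-frame DNA-GOQD interaction metrics.

* :func:`count_contacts` — number of inter-selection atom pairs closer than a
  cutoff (default 0.6 nm, the contact definition used throughout).
* :func:`sasa` — Shrake-Rupley solvent-accessible surface area of a
  selection, occluded only by atoms of that selection (Bondi vdW radii,
  0.14 nm probe).
* :func:`csa` — contacting surface area,
  ``(SASA_A + SASA_B - SASA_A∪B) / 2``: half the surface buried on forming
  the complex.
* :func:`lj_energy` — truncated Lennard-Jones interaction energy between two
  selections (no electrostatics, no switching at the cutoff).

Neighbour searches use a cell-list/kd-tree; results are contractually equal
to the all-pairs answer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._errors import ParameterError, SelectionError
from .model_core import Selection, Structure

__all__ = [
    "MetricSeries",
    "CONTACT_CUTOFF_NM",
    "PROBE_RADIUS_NM",
    "N_SPHERE_POINTS",
    "LJ_CUTOFF_NM",
    "BONDI_RADII_NM",
    "LJParams",
    "count_contacts",
    "sasa",
    "csa",
    "lj_energy",
]

CONTACT_CUTOFF_NM = 0.6
PROBE_RADIUS_NM = 0.14
N_SPHERE_POINTS = 960
LJ_CUTOFF_NM = 1.2

#: Bondi van der Waals radii (nm) used for SASA.
BONDI_RADII_NM = {"C": 0.170, "N": 0.155, "O": 0.152, "H": 0.120, "P": 0.180, "S": 0.180}


@dataclass(frozen=True)
class MetricSeries:
    """Per-frame values of a named metric."""

    metric_name: str
    times: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if len(t) != len(v):
            raise ValueError("times and values must have equal length")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.times)


def _require_disjoint(a: Selection, b: Selection) -> None:
    if a.intersects(b):
        raise SelectionError(
            f"selections {a.label!r} and {b.label!r} overlap; inter-group "
            "metrics require disjoint selections"
        )


def count_contacts(
    frame: Structure, a: Selection, b: Selection, cutoff: float = CONTACT_CUTOFF_NM
) -> int:
    """Number of (i in a, j in b) atom pairs with distance < ``cutoff`` nm."""
    _require_disjoint(a, b)
    if len(a) == 0 or len(b) == 0:
        return 0
    ta = cKDTree(frame.positions[a.indices])
    tb = cKDTree(frame.positions[b.indices])
    # count_neighbors counts pairs with d <= r; back off by a hair so the
    # contract is a strict inequality
    return int(ta.count_neighbors(tb, cutoff * (1.0 - 1e-12)))


@dataclass(frozen=True)
class LJParams:
    """Per-element (or per-atom-name) Lennard-Jones parameters.

    ``sigma`` in nm, ``epsilon`` in kJ/mol, keyed by element symbol; the
    optional ``name_overrides`` map atom names to (sigma, epsilon) and take
    precedence.  Combination rule: Lorentz-Berthelot (arithmetic sigma,
    geometric epsilon) or purely geometric.
    """

    sigma: dict = field(default_factory=dict)
    epsilon: dict = field(default_factory=dict)
    combination: str = "lorentz-berthelot"
    cutoff: float = LJ_CUTOFF_NM
    name_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.combination not in ("lorentz-berthelot", "geometric"):
            raise ValueError(f"unknown combination rule {self.combination!r}")
        if any(s <= 0 for s in self.sigma.values()):
            raise ValueError("sigma values must be positive")
        if any(e < 0 for e in self.epsilon.values()):
            raise ValueError("epsilon values must be non-negative")

    def lookup(self, frame: Structure, indices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sig = np.empty(len(indices))
        eps = np.empty(len(indices))
        for k, i in enumerate(indices):
            name, elem = frame.names[i], frame.elements[i]
            if name in self.name_overrides:
                sig[k], eps[k] = self.name_overrides[name]
            elif elem in self.sigma and elem in self.epsilon:
                sig[k], eps[k] = self.sigma[elem], self.epsilon[elem]
            else:
                raise ParameterError(
                    f"no LJ parameters for atom {name!r} (element {elem!r}, index {i})"
                )
        return sig, eps


def lj_energy(frame: Structure, a: Selection, b: Selection, params: LJParams) -> float:
    """Truncated 12-6 Lennard-Jones energy (kJ/mol) between two selections.

    Sums ``4 eps [(sigma/r)^12 - (sigma/r)^6]`` over inter-selection pairs
    within the cutoff; no intra-selection terms, no shift at the cutoff.
    """
    _require_disjoint(a, b)
    if len(a) == 0 or len(b) == 0:
        return 0.0
    sig_a, eps_a = params.lookup(frame, a.indices)
    sig_b, eps_b = params.lookup(frame, b.indices)
    pa = frame.positions[a.indices]
    pb = frame.positions[b.indices]
    pairs = cKDTree(pa).query_ball_tree(cKDTree(pb), params.cutoff)
    total = 0.0
    for i, js in enumerate(pairs):
        if not js:
            continue
        js = np.asarray(js)
        r = np.linalg.norm(pb[js] - pa[i], axis=1)
        keep = r <= params.cutoff
        if not np.any(keep):
            continue
        r = r[keep]
        js = js[keep]
        if params.combination == "lorentz-berthelot":
            s = 0.5 * (sig_a[i] + sig_b[js])
        else:
            s = np.sqrt(sig_a[i] * sig_b[js])
        e = np.sqrt(eps_a[i] * eps_b[js])
        sr6 = (s / r) ** 6
        total += float(np.sum(4.0 * e * (sr6 * sr6 - sr6)))
    return total


# ---------------------------------------------------------------------------
# SASA / CSA
# ---------------------------------------------------------------------------


def _sasa_mdtraj(
    frame: Structure,
    indices: np.ndarray,
    probe_radius: float,
    n_sphere_points: int,
    radii: dict,
) -> float:
    """Shrake-Rupley area (nm^2) of the sub-system defined by ``indices``."""
    import mdtraj as md
    from mdtraj.core import element as md_element

    top = md.Topology()
    ch = top.add_chain()
    res = top.add_residue("SUB", ch)
    change = {}
    for k, i in enumerate(indices):
        elem = frame.elements[i]
        if elem not in radii:
            raise ParameterError(
                f"no vdW radius for element {elem!r} (atom {frame.names[i]!r}); "
                "supply an override radius"
            )
        try:
            mde = md_element.get_by_symbol(elem)
        except KeyError as exc:  # pragma: no cover - exotic elements
            raise ParameterError(f"unknown element symbol {elem!r}") from exc
        top.add_atom(f"A{k}", mde, res)
        change[mde.symbol] = radii[elem]
    traj = md.Trajectory(frame.positions[indices][None, :, :], top)
    areas = md.shrake_rupley(
        traj,
        probe_radius=probe_radius,
        n_sphere_points=n_sphere_points,
        mode="atom",
        change_radii=change,
    )
    return float(areas.sum())


def sasa(
    frame: Structure,
    selection: Selection,
    probe_radius: float = PROBE_RADIUS_NM,
    n_sphere_points: int = N_SPHERE_POINTS,
    radii: dict | None = None,
) -> float:
    """Solvent-accessible surface area (nm^2) of a selection.

    Only atoms inside the selection occlude; ``radii`` overrides/extends the
    Bondi element table.
    """
    if len(selection) == 0:
        raise SelectionError(f"selection {selection.label!r} is empty")
    table = dict(BONDI_RADII_NM)
    if radii:
        table.update(radii)
    return _sasa_mdtraj(frame, selection.indices, probe_radius, n_sphere_points, table)


def csa(
    frame: Structure,
    a: Selection,
    b: Selection,
    probe_radius: float = PROBE_RADIUS_NM,
    n_sphere_points: int = N_SPHERE_POINTS,
    radii: dict | None = None,
) -> float:
    """Contacting surface area ``(SASA_a + SASA_b - SASA_a∪b) / 2`` in nm^2.

    Symmetric in its arguments; clamped at zero (with a warning) if numerical
    noise makes the half-difference slightly negative.
    """
    _require_disjoint(a, b)
    kw = dict(probe_radius=probe_radius, n_sphere_points=n_sphere_points, radii=radii)
    value = 0.5 * (
        sasa(frame, a, **kw) + sasa(frame, b, **kw) - sasa(frame, a.union(b), **kw)
    )
    if value < 0.0:
        warnings.warn(
            f"CSA numerically negative ({value:.3e} nm^2); clamping to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        value = 0.0
    return value
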
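# goqdna

Structure builders and trajectory metrics for studying how graphene-oxide
quantum dots (GOQDs) interact with short DNA duplexes.

Simulation studies of GOQD genotoxicity characterize the adsorption of small
oxidized graphene flakes onto DNA with a recurring set of quantities: the
number of atom contacts, the contacting surface area, the van der Waals
interaction energy, the DNA's hydrogen-bond and π–π-stacking counts, its
end-to-end length and RMSD, radial distribution functions of flake oxygens
against backbone and groove atoms, the contact-breaking Gibbs energy derived
from them, the classification of adsorption sites along the duplex, and
flake-aggregation statistics.  `goqdna` implements this analysis layer as a
tested, reusable Python package, together with generators for the input
structures and for synthetic trajectories with programmed ground truth, so
every metric can be validated end-to-end without running MD.

## What it computes

**Builders** (`goqdna.builders`)

- `build_goqd` — circular graphene flakes: carbons on an ideal honeycomb
  lattice (C–C 0.142 nm) inside a radius *R* (x² + y² < R²), edge carbons
  capped with hydrogens, and a seeded random subset of edge H replaced by
  OH or COOH groups.
- `build_bdna_polyAT` — an idealized B-form poly(A-T) duplex (rise
  0.338 nm, twist 36° per step) from a fixed Watson–Crick pair template;
  each A:T pair carries exactly two hydrogen bonds.
- `assemble_system` — duplex at the centre of a cubic box (default 11 nm)
  with two flakes on the helix axis beyond the duplex ends (default 8 nm
  apart) and the remainder in an azimuthal shell at a controlled surface
  gap (default 0.2 nm).

**Metrics**

- contacts: pairs of atoms closer than 0.6 nm between two selections
- CSA: contacting surface area, ``(SASA_A + SASA_B − SASA_A∪B)/2``
  (Shrake–Rupley, 0.14 nm probe, Bondi radii)
- Lennard-Jones interaction energy, ``Σ 4ε[(σ/r)¹² − (σ/r)⁶]``, truncated
  at 1.2 nm
- hydrogen bonds: donor–acceptor ≤ 0.35 nm and H–D⋯A angle ≤ 30°
- π–π stacking: ring-centroid distance < 0.4 nm and plane angle < 36°
- DNA length (terminal base-pair centroid distance), RMSD (Kabsch)
- RDF g(r) and the contact-breaking Gibbs energy
  ``dG = k_B·T·ln(g_max/g_∞)`` at 310 K
- adsorption sites A (head), B/C (minor-groove halves), D (terminal end)
- flake clusters: connected components under a 0.35 nm minimum heavy-atom
  distance linkage

## Worked example

```python
from goqdna import build_bdna_polyAT, build_goqd, GOQDSpec, select
from goqdna.dna_integrity import dna_hbond_count, dna_length
from goqdna.builders import assemble_system, AssemblyGeometry
from goqdna.aggregation import find_clusters

duplex = build_bdna_polyAT(20)
print(dna_hbond_count(duplex))   # 40   (two Watson-Crick bonds per pair)
print(round(dna_length(duplex), 3))  # 6.422  nm = 19 steps x 0.338 nm

flake = build_goqd(GOQDSpec(ring_count=7, group_type="OH", group_count=6, seed=3))
system = assemble_system(duplex, flake, AssemblyGeometry(n_goqds=10), seed=1)
groups = [select(system, f"resname GQD and resid {r}") for r in range(1, 11)]
print(find_clusters(system, groups).n_clusters)  # 10  (no initial aggregation)
```

The 40 hydrogen bonds are the intact-duplex baseline: every damage analysis
(base-pair opening, strand separation) is measured as a drop from it.  The
length, 6.42 nm, is the idealized-geometry value for 20 base pairs.

A command-line interface wraps the same operations:

```bash
goqdna build dna --nbp 20 -o dna.pdb
goqdna build goqd --rings 7 --group OH --count 6 --seed 3 -o flake.pdb
goqdna build system --dna dna.pdb --goqd flake.pdb --n 10 --seed 1 -o system.gro
goqdna analyze run --config run.yaml --outdir out/
goqdna report --outdir out/
```

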
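"""Frozen idealized Watson-Crick A:T base-pair template.

Coordinates are in nm in the pair plane (z = 0), with the helical axis as the
z-axis through the origin.  The template was constructed from idealized ring
geometry (regular 1.38-1.39 A aromatic rings, textbook exocyclic bond
lengths) with the two canonical hydrogen bonds fixed at N1(A)...N3(T) =
0.282 nm (H3 collinear with the donor-acceptor vector) and N6(A)...O4(T) =
0.295 nm (H61 placed exactly along N6->O4, so both bonds are perfectly
linear at the donor).  Backbone atoms are radial proxies: P sits 0.92 nm
from the axis, with OP1/OP2 displaced out of the pair plane.

Each entry is (strand, atom name, element, x, y, z) where strand "A" is the
adenine (purine) strand and "T" the thymine strand of the pair.
"""

RISE_NM = 0.338     # axial translation per base-pair step
TWIST_DEG = 36.0    # rotation per base-pair step

# atom names treated as backbone (everything else is "base") when computing
# base centroids, groove proxies and base-only hydrogen-bond selections
BACKBONE_NAMES = frozenset(
    {"P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'"}
)

PAIR_TEMPLATE = [
    ("A", "P", "P", -0.89571, -0.21000, +0.00000),
    ("A", "OP1", "O", -0.96776, -0.22689, +0.12800),
    ("A", "OP2", "O", -0.96776, -0.22689, -0.12800),
    ("A", "O5'", "O", -0.78478, -0.09470, +0.00000),
    ("A", "C1'", "C", -0.57752, +0.12070, +0.00000),
    ("A", "N9", "N", -0.46828, +0.02234, +0.00000),
    ("A", "C8", "C", -0.48281, -0.11590, +0.00000),
    ("A", "H8", "H", -0.57634, -0.16990, +0.00000),
    ("A", "N7", "N", -0.35583, -0.17243, +0.00000),
    ("A", "C5", "C", -0.26282, -0.06914, +0.00000),
    ("A", "C6", "C", -0.12382, -0.06914, +0.00000),
    ("A", "N6", "N", -0.05682, -0.18518, +0.00000),
    ("A", "H61", "H", +0.04407, -0.18044, +0.00000),
    ("A", "H62", "H", -0.15782, -0.18518, +0.00000),
    ("A", "N1", "N", -0.05432, +0.05124, +0.00000),
    ("A", "C2", "C", -0.12382, +0.17162, +0.00000),
    ("A", "H2", "H", -0.06982, +0.26515, +0.00000),
    ("A", "N3", "N", -0.26282, +0.17162, +0.00000),
    ("A", "C4", "C", -0.33232, +0.05124, +0.00000),
    ("T", "P", "P", +0.91479, +0.09775, +0.00000),
    ("T", "OP1", "O", +0.98837, +0.10561, +0.12800),
    ("T", "OP2", "O", +0.98837, +0.10561, -0.12800),
    ("T", "O5'", "O", +0.77199, +0.16992, +0.00000),
    ("T", "C1'", "C", +0.50520, +0.30475, +0.00000),
    ("T", "N1", "N", +0.43322, +0.17658, +0.00000),
    ("T", "C2", "C", +0.29523, +0.17493, +0.00000),
    ("T", "O2", "O", +0.23298, +0.27985, +0.00000),
    ("T", "N3", "N", +0.22766, +0.05460, +0.00000),
    ("T", "H3", "H", +0.12667, +0.05340, +0.00000),
    ("T", "C4", "C", +0.29808, -0.06408, +0.00000),
    ("T", "O4", "O", +0.23786, -0.17132, +0.00000),
    ("T", "C5", "C", +0.43607, -0.06243, +0.00000),
    ("T", "C7", "C", +0.51262, -0.19143, +0.00000),
    ("T", "C6", "C", +0.50364, +0.05790, +0.00000),
    ("T", "H6", "H", +0.61164, +0.05918, +0.00000),
]
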
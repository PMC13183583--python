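"""Count interstrand backbone hydrogen bonds on an idealized two-strand
beta-sheet, the geometry that anchors terminal strands in beta-sandwich
domains (for a real structure, point parse_structure at a PDB file)."""

import numpy as np
import biotite.structure as struc

from nucleoflux import find_backbone_hbonds, interstrand_count

# two four-residue strands with a canonical 2.9 A, linear N-H...O ladder
SPEC = [
    (1, "N", 0.0, 0.0), (1, "H", 0.0, 1.0), (1, "CA", 1.2, -0.8), (1, "C", 2.4, 0.0),
    (2, "N", 3.5, 0.0), (2, "H", 3.5, -1.0), (2, "CA", 4.0, 0.6),
    (2, "C", 4.7, 0.5), (2, "O", 4.7, 1.7),
    (3, "N", 7.0, 0.0), (3, "H", 7.0, 1.0), (3, "CA", 8.0, -0.8), (3, "C", 8.2, 0.0),
    (4, "N", 10.5, 0.0), (4, "H", 10.5, -1.0), (4, "CA", 10.9, 0.6),
    (4, "C", 11.2, 0.5), (4, "O", 11.2, 1.7),
    (21, "C", -1.0, 3.5), (21, "O", 0.0, 2.9), (21, "CA", -1.6, 4.0),
    (21, "N", -2.2, 4.2), (21, "H", -2.2, 5.2),
    (22, "N", 4.7, 4.6), (22, "H", 4.7, 3.6), (22, "CA", 5.4, 5.2), (22, "C", 6.1, 4.9),
    (23, "C", 7.9, 3.4), (23, "O", 7.0, 2.9), (23, "CA", 8.4, 4.0),
    (23, "N", 9.0, 4.2), (23, "H", 9.0, 5.2),
    (24, "N", 11.2, 4.6), (24, "H", 11.2, 3.6), (24, "CA", 11.8, 5.2), (24, "C", 12.5, 4.9),
]

atoms = struc.AtomArray(len(SPEC))
for i, (rid, name, x, y) in enumerate(SPEC):
    atoms.coord[i] = (x, y, 0.0)
    atoms.res_id[i] = rid
    atoms.atom_name[i] = name
    atoms.res_name[i] = "GLY"
    atoms.chain_id[i] = "A"
    atoms.element[i] = name[0]

bonds = find_backbone_hbonds(atoms, d_cut=4.0, angle_cut=30.0)
print(f"{len(bonds)} backbone hydrogen bonds under the 4 A / 30 deg criteria:")
for b in bonds:
    print(f"  res {b.donor[1]:>2} N-H ... O res {b.acceptor[1]:>2}  "
          f"d = {b.distance:.2f} A, deviation = {b.angle:.1f} deg")

n = interstrand_count(bonds, [(1, 4)], [(21, 24)])
print(f"interstrand count between strand 1-4 and strand 21-24: {n}")
print("this is the kind of 'mechanical clamp' ladder whose cooperative")
print("rupture sets the unfolding force of a terminal beta-strand")
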
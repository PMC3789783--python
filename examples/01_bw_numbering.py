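"""Ballesteros-Weinstein numbering from per-helix anchors.

Each TM helix is anchored at one residue of known generic position
(the most conserved residue is .50); every other residue follows by
offset.  Prints the indices for the conserved residues of the S1P
receptor and the inverse lookup for the TM7 proline pivot.
"""

from gpcrtraj import assign_bw, lookup_bw
from gpcrtraj.synthetic_data import default_helices

helices = [hp.definition for hp in default_helices()]
bw_map = assign_bw(helices)

for seq in (63, 91, 98, 265, 269, 304, 308):
    print(f"residue {seq:>3} -> {bw_map[seq]}")

pivot = lookup_bw(bw_map, "7.50")
print(f"\ninverse lookup 7.50 -> residue {pivot} (the TM7 proline pivot)")
# 2.50 is the conserved TM2 aspartate, 6.48 the toggle tryptophan; the
# mapping is bijective per helix, so lookup(assign(x)) == x everywhere.
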
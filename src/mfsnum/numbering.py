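"""Generic residue numbering for the 12-TM transporter fold.

Each helix x carries one reference (anchor) residue labelled x.0 — the most
conserved residue participating in that helix's signature helix-helix
contact — and every other transmembrane residue is labelled by its signed
offset from the anchor: positive toward the extracellular side, negative
toward the cytoplasm. Because odd helices run cytoplasm -> extracellular
with increasing sequence and even helices run the opposite way, the offset
is ``residue - anchor`` on odd helices and ``anchor - residue`` on even
ones.

Anchor labels keep the one-letter residue prefix ("G5.0"); plain offsets
are rendered without it ("5.-3", "5.7"); parsing accepts both forms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

from .conservation import (ColumnMapping, ConservationProfile,
                           EXTENDED_SCHEME, GroupScheme)
from .contacts import ContactMap, ContactRecord
from .structure_io import (HelixSpan, MfsError, ReferenceTable,
                           StructureEntry)

__all__ = [
    "AnchorRule",
    "ANCHOR_RULES",
    "AnchorAssignment",
    "GenericLabel",
    "GenericNumbering",
    "parse_label",
    "assign_anchor",
    "fallback_anchor",
    "number_residues",
    "lookup",
    "numbering_from_reference",
]


@dataclass(frozen=True)
class AnchorRule:
    """How the x.0 position of one helix is selected: the most conserved
    residue of the first non-empty chemical group that contacts the
    partner helix."""

    helix_id: int
    partner_helix: int
    allowed_groups: tuple[str, ...]


#: The 12 anchor selection rules. When alternatives are offered the
#: preference order is as listed; the first group with at least one
#: contacting candidate wins (for helix 9 this realizes the published
#: condition "glycine, or small hydrophobic if no glycine contacts 10").
ANCHOR_RULES: tuple[AnchorRule, ...] = (
    AnchorRule(1, 5, ("polar", "glycine", "small_hydrophobic")),
    AnchorRule(2, 4, ("glycine",)),
    AnchorRule(3, 6, ("small_hydrophobic",)),
    AnchorRule(4, 2, ("glycine",)),
    AnchorRule(5, 1, ("polar", "glycine", "small_hydrophobic")),
    AnchorRule(6, 3, ("small_hydrophobic",)),
    AnchorRule(7, 11, ("polar",)),
    AnchorRule(8, 5, ("polar", "small_hydrophobic")),
    AnchorRule(9, 10, ("glycine", "small_hydrophobic")),
    AnchorRule(10, 9, ("glycine",)),
    AnchorRule(11, 7, ("polar",)),
    AnchorRule(12, 9, ("small_hydrophobic",)),
)


def rule_for_helix(helix_id: int,
                   rules: Sequence[AnchorRule] = ANCHOR_RULES) -> AnchorRule:
    for r in rules:
        if r.helix_id == helix_id:
            return r
    raise MfsError(f"no anchor rule for helix {helix_id}")


@dataclass(frozen=True)
class AnchorAssignment:
    helix_id: int
    residue_index: int
    one_letter: str
    rule_used: str
    conservation_fraction: float = float("nan")
    contact_evidence: ContactRecord | None = None

    @property
    def label(self) -> str:
        return f"{self.one_letter}{self.helix_id}.0"


_LABEL_RE = re.compile(r"^(?:[A-Z])?(\d{1,2})\.(-?\d+)$")


@dataclass(frozen=True)
class GenericLabel:
    helix_id: int
    offset: int

    def __post_init__(self):
        if not 1 <= self.helix_id <= 12:
            raise MfsError(f"helix_id must be 1..12, got {self.helix_id}")

    @property
    def rendered(self) -> str:
        return f"{self.helix_id}.{self.offset}"

    def rendered_with(self, one_letter: str) -> str:
        """Anchor form with the residue-letter prefix, e.g. 'G5.0'."""
        return f"{one_letter}{self.helix_id}.{self.offset}"


def parse_label(text: str) -> GenericLabel:
    """Parse '5.-3', '5.7' or an anchor form like 'G5.0'."""
    m = _LABEL_RE.match(text.strip())
    if not m:
        raise MfsError(f"cannot parse generic label {text!r}; expected "
                       f"'<helix>.<signed offset>' with optional residue "
                       f"letter prefix")
    return GenericLabel(int(m.group(1)), int(m.group(2)))


def _offset(span: HelixSpan, anchor_index: int, residue_index: int) -> int:
    if span.helix_id % 2 == 1:      # cytoplasmic N-start: sequence runs up
        return residue_index - anchor_index
    return anchor_index - residue_index


def _residue_for_offset(span: HelixSpan, anchor_index: int,
                        offset: int) -> int:
    if span.helix_id % 2 == 1:
        return anchor_index + offset
    return anchor_index - offset


@dataclass
class GenericNumbering:
    """Bijection between in-span residues and (helix, offset) pairs."""

    protein_name: str
    labels: dict[int, GenericLabel]          # residue_index -> label
    inverse: dict[tuple[int, int], int] = field(init=False)

    def __post_init__(self):
        self.inverse = {}
        for idx, lab in self.labels.items():
            key = (lab.helix_id, lab.offset)
            if key in self.inverse:
                raise MfsError(f"duplicate generic label {lab.rendered}")
            self.inverse[key] = idx

    def label_of(self, residue_index: int) -> GenericLabel:
        try:
            return self.labels[residue_index]
        except KeyError:
            raise MfsError(f"residue {residue_index} is outside the 12 "
                           f"TM spans of {self.protein_name}") from None

    def residue_of(self, label: GenericLabel | str) -> int:
        if isinstance(label, str):
            label = parse_label(label)
        try:
            return self.inverse[(label.helix_id, label.offset)]
        except KeyError:
            raise MfsError(f"{self.protein_name}: no residue at "
                           f"{label.rendered}") from None


def number_residues(spans: Sequence[HelixSpan],
                    anchors: Sequence[AnchorAssignment],
                    protein_name: str = "") -> GenericNumbering:
    """Assign a signed generic label to every in-span residue."""
    by_helix = {a.helix_id: a for a in anchors}
    labels: dict[int, GenericLabel] = {}
    for span in spans:
        anchor = by_helix.get(span.helix_id)
        if anchor is None:
            raise MfsError(f"no anchor for helix {span.helix_id}")
        if anchor.residue_index not in span:
            raise MfsError(
                f"helix {span.helix_id}: anchor {anchor.residue_index} "
                f"outside span {span.start}-{span.end}")
        for idx in range(span.start, span.end + 1):
            labels[idx] = GenericLabel(span.helix_id,
                                       _offset(span, anchor.residue_index,
                                               idx))
    return GenericNumbering(protein_name=protein_name, labels=labels)


# ---------------------------------------------------------------------------
# anchor assignment


def assign_anchor(helix_id: int,
                  entry: StructureEntry,
                  contacts: ContactMap,
                  conservation: ConservationProfile,
                  mapping: ColumnMapping,
                  rules: Sequence[AnchorRule] = ANCHOR_RULES,
                  scheme: GroupScheme = EXTENDED_SCHEME) -> AnchorAssignment:
    """Select the x.0 residue of one helix.

    Candidates are residues of the helix that donate a contact to the
    rule's partner helix and belong to the first allowed chemical group
    with any such candidate. The winner has the highest family
    conservation of that group at its alignment column; ties go to the
    residue nearest the span midpoint, then to the lower index.
    """
    rule = rule_for_helix(helix_id, rules)
    span = entry.span(helix_id)
    donors = {rec.res_a: rec
              for rec in sorted(
                  contacts.for_pair(helix_id, rule.partner_helix,
                                    directional=True),
                  key=lambda r: r.min_distance, reverse=True)}
    residues = {r.residue_index: r for r in entry.span_residues(helix_id)}

    tried = []
    for group in rule.allowed_groups:
        members = scheme.members(group)
        candidates = [idx for idx in donors
                      if residues.get(idx) is not None
                      and residues[idx].one_letter in members]
        if not candidates:
            tried.append(group)
            continue

        def conservation_of(idx: int) -> float:
            col = mapping.column_for_residue(idx)
            if col is None:
                return 0.0
            frac = conservation.fraction(col, group) \
                if group in conservation.fractions.columns else 0.0
            return 0.0 if frac != frac else float(frac)   # NaN -> 0

        best = min(candidates,
                   key=lambda idx: (-conservation_of(idx),
                                    abs(idx - span.midpoint), idx))
        return AnchorAssignment(
            helix_id=helix_id, residue_index=best,
            one_letter=residues[best].one_letter,
            rule_used=f"contact with TMH {rule.partner_helix} ({group})",
            conservation_fraction=conservation_of(best),
            contact_evidence=donors[best])

    near = sorted(donors)[:5]
    raise MfsError(
        f"helix {helix_id}: no contacting residue in any allowed group "
        f"{tried} (partner TMH {rule.partner_helix}); contacting residues "
        f"near misses: {near}")


def fallback_anchor(helix_id: int,
                    reference: ReferenceTable,
                    reference_protein: str,
                    reference_seq: str,
                    target_seq: str,
                    reference_start: int = 1,
                    target_start: int = 1) -> AnchorAssignment:
    """Transfer an anchor from a reference protein through a pairwise
    alignment when the target family lacks its own conserved site.

    ``reference_seq``/``target_seq`` are ungapped sequences whose first
    residues carry author indices ``reference_start``/``target_start``.
    The anchor is the target residue aligned to the reference protein's
    packaged x.0 position; a gap at that column is an error (manual
    assignment advised).
    """
    from Bio import Align

    rec = reference.entry(reference_protein).record(helix_id)
    anchor_pos = rec.anchor_residue_index - reference_start   # 0-based
    if not 0 <= anchor_pos < len(reference_seq):
        raise MfsError(
            f"reference sequence does not cover anchor residue "
            f"{rec.anchor_residue_index} of {reference_protein}")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
    alignment = aligner.align(reference_seq, target_seq)[0]

    target_pos = None
    for (r0, r1), (t0, t1) in zip(*alignment.aligned):
        if r0 <= anchor_pos < r1:
            target_pos = t0 + (anchor_pos - r0)
            break
    if target_pos is None:
        raise MfsError(
            f"helix {helix_id}: anchor column of {reference_protein} "
            f"({rec.anchor_one_letter}{rec.anchor_residue_index}) is gapped "
            f"in the target; assign the anchor manually")
    residue_index = target_pos + target_start
    return AnchorAssignment(
        helix_id=helix_id, residue_index=residue_index,
        one_letter=target_seq[target_pos],
        rule_used=f"transferred from {reference_protein} "
                  f"{rec.printed_label}")


# ---------------------------------------------------------------------------
# cross-protein lookup against the packaged table


def numbering_from_reference(reference: ReferenceTable,
                             protein_name: str) -> GenericNumbering:
    """Generic numbering of a packaged protein from its spans + anchors."""
    entry = reference.entry(protein_name)
    anchors = [AnchorAssignment(helix_id=r.span.helix_id,
                                residue_index=r.anchor_residue_index,
                                one_letter=r.anchor_one_letter,
                                rule_used="packaged reference")
               for r in entry.records]
    return number_residues([r.span for r in entry.records], anchors,
                           protein_name=protein_name)


def lookup(protein_name: str, query: str | int,
           reference: ReferenceTable):
    """Bidirectional conversion for a packaged protein.

    A string query ('7.0', 'G5.0', '5.-3') returns the author residue
    index; an integer residue index returns its :class:`GenericLabel`.
    Offsets outside the span raise an error naming the span limits.
    """
    numbering = numbering_from_reference(reference, protein_name)
    if isinstance(query, str):
        label = parse_label(query)
        rec = reference.entry(protein_name).record(label.helix_id)
        try:
            return numbering.residue_of(label)
        except MfsError:
            raise MfsError(
                f"{protein_name}: offset {label.offset} is outside helix "
                f"{label.helix_id} (span {rec.span.start}-{rec.span.end}, "
                f"anchor {rec.anchor_residue_index})") from None
    return numbering.label_of(int(query))
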
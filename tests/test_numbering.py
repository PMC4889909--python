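"""Anchor assignment, generic label arithmetic and cross-protein lookup."""

import warnings

import pytest
from hypothesis import given, strategies as st

from mfsnum import MfsError, detect_contacts
from mfsnum.conservation import (EXTENDED_SCHEME, column_conservation,
                                 map_columns)
from mfsnum.numbering import (ANCHOR_RULES, AnchorAssignment, GenericLabel,
                              assign_anchor, fallback_anchor, lookup,
                              number_residues, numbering_from_reference,
                              parse_label, rule_for_helix)
from mfsnum.structure_io import HelixSpan, load_reference
from mfsnum.synthetic import anchor_demo_bundle, build_msa


@pytest.fixture(scope="module")
def reference():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return load_reference()


@pytest.fixture(scope="module")
def demo():
    entry, msa_spec, anchors = anchor_demo_bundle()
    cmap = detect_contacts(entry, scheme=EXTENDED_SCHEME)
    msa = build_msa(msa_spec)
    profile = column_conservation(msa, EXTENDED_SCHEME)
    mapping = map_columns(msa, "reference", entry)
    return entry, cmap, profile, mapping, anchors


# ---------------------------------------------------------------------------
# label grammar


@pytest.mark.parametrize("text,helix,offset", [
    ("5.0", 5, 0), ("5.-3", 5, -3), ("5.7", 5, 7),
    ("G5.0", 5, 0), ("Q7.0", 7, 0), ("12.-10", 12, -10),
])
def test_label_parsing(text, helix, offset):
    lab = parse_label(text)
    assert (lab.helix_id, lab.offset) == (helix, offset)


@pytest.mark.parametrize("bad", ["", "13.0", "5", "5.", "x.0", "5.0.1"])
def test_label_parsing_rejects_malformed(bad):
    with pytest.raises(MfsError):
        parse_label(bad)


@given(st.integers(min_value=1, max_value=12),
       st.integers(min_value=-30, max_value=30))
def test_label_rendering_roundtrips(helix, offset):
    lab = GenericLabel(helix, offset)
    assert parse_label(lab.rendered) == lab
    assert parse_label(lab.rendered_with("G")) == lab


# ---------------------------------------------------------------------------
# offset arithmetic (XylE helix 5 / helix 4 as printed)


def test_odd_helix_sign_convention_on_xyle_helix5(reference):
    num = numbering_from_reference(reference, "XylE")
    assert num.label_of(174).rendered == "5.0"
    assert num.label_of(166).offset == -8
    assert num.label_of(183).offset == 9
    rec = reference.entry("XylE").record(5)
    assert num.label_of(174).rendered_with(rec.anchor_one_letter) == "G5.0"


def test_even_helix_sign_convention_on_xyle_helix4(reference):
    num = numbering_from_reference(reference, "XylE")
    assert num.label_of(145).offset == -4
    assert num.label_of(126).offset == 15


def test_offsets_within_each_helix_are_consecutive(reference):
    num = numbering_from_reference(reference, "LacY")
    by_helix = {}
    for idx, lab in num.labels.items():
        by_helix.setdefault(lab.helix_id, []).append(lab.offset)
    for helix_id, offsets in by_helix.items():
        offsets.sort()
        assert offsets == list(range(offsets[0], offsets[-1] + 1))
        assert offsets.count(0) == 1


def test_anchor_outside_span_is_rejected():
    anchor = AnchorAssignment(helix_id=1, residue_index=50,
                              one_letter="G", rule_used="test")
    with pytest.raises(MfsError, match="outside span"):
        number_residues([HelixSpan(1, 10, 30)], [anchor])


# ---------------------------------------------------------------------------
# cross-protein lookup


@pytest.mark.parametrize("protein,label,residue", [
    ("LacY", "7.0", 248),
    ("PepT", "7.0", 309),
    ("LacY", "9.0", 296),
    ("XylE", "5.0", 174),
])
def test_lookup_label_to_residue(reference, protein, label, residue):
    assert lookup(protein, label, reference) == residue


def test_lookup_residue_to_label_inverse(reference):
    lab = lookup("LacY", 248, reference)
    assert lab.rendered == "7.0"


def test_lookup_errors_name_protein_and_span(reference):
    with pytest.raises(MfsError, match="unknown protein"):
        lookup("NoSuch", "7.0", reference)
    with pytest.raises(MfsError, match="span"):
        lookup("LacY", "7.99", reference)


def test_roundtrip_bijection_over_all_packaged_proteins(reference):
    for protein in reference.entries:
        num = numbering_from_reference(reference, protein)
        for idx, lab in num.labels.items():
            assert num.residue_of(lab) == idx
        # same-label residues across proteins share the helix
        assert set(num.inverse) == {(l.helix_id, l.offset)
                                    for l in num.labels.values()}


def test_same_label_maps_to_same_helix_across_proteins(reference):
    proteins = list(reference.entries)
    for label in ("4.0", "7.0", "10.-2"):
        for protein in proteins:
            try:
                idx = lookup(protein, label, reference)
            except MfsError:
                continue
            lab = lookup(protein, idx, reference)
            assert lab.helix_id == parse_label(label).helix_id


# ---------------------------------------------------------------------------
# anchor assignment on the planted bundle


def test_rules_mirror_the_published_assignment_table():
    partners = {r.helix_id: r.partner_helix for r in ANCHOR_RULES}
    assert partners == {1: 5, 2: 4, 3: 6, 4: 2, 5: 1, 6: 3, 7: 11,
                       8: 5, 9: 10, 10: 9, 11: 7, 12: 9}
    assert rule_for_helix(2).allowed_groups == ("glycine",)
    assert rule_for_helix(1).allowed_groups == \
        ("polar", "glycine", "small_hydrophobic")
    assert rule_for_helix(9).allowed_groups == \
        ("glycine", "small_hydrophobic")


def test_all_twelve_planted_anchors_are_recovered(demo):
    entry, cmap, profile, mapping, anchors = demo
    for helix_id in range(1, 13):
        a = assign_anchor(helix_id, entry, cmap, profile, mapping)
        assert a.residue_index == anchors[helix_id], f"helix {helix_id}"
        assert a.conservation_fraction == pytest.approx(0.9)
        assert a.contact_evidence is not None


def test_end_to_end_numbering_from_planted_anchors(demo):
    entry, cmap, profile, mapping, anchors = demo
    assignments = [assign_anchor(h, entry, cmap, profile, mapping)
                   for h in range(1, 13)]
    num = number_residues(entry.spans, assignments,
                          protein_name=entry.protein_name)
    for h, idx in anchors.items():
        assert num.label_of(idx).offset == 0
    for idx, lab in num.labels.items():
        assert num.residue_of(lab) == idx


def test_higher_conservation_wins_among_contacting_candidates(demo):
    entry, cmap, profile, mapping, anchors = demo
    # helix 2's only planted glycine is the winner; a decoy glycine with
    # lower conservation placed in the MSA must not displace it
    a = assign_anchor(2, entry, cmap, profile, mapping)
    assert a.residue_index == anchors[2]
    assert a.rule_used.startswith("contact with TMH 4")


def test_tie_breaks_prefer_midpoint_then_lower_index(demo):
    entry, cmap, profile, mapping, _ = demo
    # force a tie by zeroing the mapping: all candidates get conservation 0,
    # so the residue nearest the span midpoint (then lowest index) wins
    from mfsnum.conservation import ColumnMapping
    empty = ColumnMapping(reference_id="reference", pairs={}, unmapped=[],
                          offset=0, identity=1.0)
    a = assign_anchor(3, entry, cmap, profile, empty)
    span = entry.span(3)
    candidates = [r.res_a for r in cmap.for_pair(3, 6, directional=True)]
    best = min(candidates, key=lambda i: (abs(i - span.midpoint), i))
    assert a.residue_index == best


def test_no_candidate_in_any_group_errors_with_groups_tried(demo):
    entry, cmap, profile, mapping, _ = demo
    rules = [r if r.helix_id != 3 else
             type(r)(helix_id=3, partner_helix=6,
                     allowed_groups=("negative",))
             for r in ANCHOR_RULES]
    with pytest.raises(MfsError, match="negative"):
        assign_anchor(3, entry, cmap, profile, mapping, rules=rules)


# ---------------------------------------------------------------------------
# fallback anchor transfer through a pairwise alignment


def synthetic_family_sequence(seed=11, length=320):
    import numpy as np
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("ACDEFHIKLMNPQRSTVWY"), size=length))
    seq[295] = "G"      # the reference anchor position (1-based 296)
    return "".join(seq)


def test_fallback_transfers_anchor_from_identical_sequence(reference):
    ref_seq = synthetic_family_sequence()
    a = fallback_anchor(9, reference, "LacY", ref_seq, ref_seq)
    assert a.residue_index == 296
    assert a.one_letter == "G"


def test_fallback_shifts_anchor_with_terminal_extension(reference):
    ref_seq = synthetic_family_sequence()
    target = "MKL" + ref_seq
    a = fallback_anchor(9, reference, "LacY", ref_seq, target)
    assert a.residue_index == 299


def test_fallback_errors_when_anchor_column_is_deleted(reference):
    ref_seq = synthetic_family_sequence()
    target = ref_seq[:288] + ref_seq[302:]    # deletion spanning the anchor
    with pytest.raises(MfsError, match="gapped"):
        fallback_anchor(9, reference, "LacY", ref_seq, target)
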
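"""Structure, MSA and reference-table IO."""

import warnings
from pathlib import Path

import numpy as np
import pytest

import mfsnum
from mfsnum import MfsError
from mfsnum.structure_io import (HelixSpan, load_reference, read_contacts,
                                 read_msa, read_structure, validate_spans,
                                 write_contacts)
from mfsnum.contacts import ContactRecord
from mfsnum.synthetic import (BundleSpec, HelixPlacement, build_bundle,
                              entry_to_pdb)


# ---------------------------------------------------------------------------
# PDB reading


def test_parse_roundtrip_preserves_residues_atoms_and_categories(
        two_helix_entry, tmp_path):
    pdb = entry_to_pdb(two_helix_entry, tmp_path / "bundle.pdb")
    parsed = read_structure(pdb, two_helix_entry.spans)
    assert len(parsed.residues) == len(two_helix_entry.residues)
    for r1, r2 in zip(two_helix_entry.residues, parsed.residues):
        assert (r1.residue_index, r1.one_letter) == \
            (r2.residue_index, r2.one_letter)
        assert [a.name for a in r1.atoms] == [a.name for a in r2.atoms]
        assert [a.category for a in r1.atoms] == \
            [a.category for a in r2.atoms]
        for a1, a2 in zip(r1.atoms, r2.atoms):
            np.testing.assert_allclose(a1.position, a2.position, atol=1e-3)


ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  CB AALA A   1       2.000   1.000   0.000  0.60  0.00           C
ATOM      4  CB BALA A   1       2.000  -1.000   0.000  0.40  0.00           C
ATOM      5  C   ALA A   1       2.000   0.000   1.400  1.00  0.00           C
ATOM      6  O   ALA A   1       3.000   0.000   2.000  1.00  0.00           O
ATOM      7  H   ALA A   1       0.000   0.500   0.500  1.00  0.00           H
END
"""


def test_altloc_keeps_primary_conformation_and_drops_hydrogens(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    entry = read_structure(path, [])
    (res,) = entry.residues
    cbs = [a for a in res.atoms if a.name == "CB"]
    assert len(cbs) == 1
    assert cbs[0].position[1] == pytest.approx(1.0)   # altloc A retained
    assert not any(a.element == "H" for a in res.atoms)


def test_hetatm_records_are_dropped(tmp_path):
    text = ALTLOC_PDB.replace("END\n", "") + (
        "HETATM    8  O   HOH A 101       9.000   9.000   9.000"
        "  1.00  0.00           O\nEND\n")
    path = tmp_path / "het.pdb"
    path.write_text(text)
    entry = read_structure(path, [])
    assert len(entry.residues) == 1


def test_gap_inside_span_is_tolerated_but_missing_endpoint_errors(tmp_path):
    spec = BundleSpec(helices=(HelixPlacement("A" * 17, ),),
                      first_residue=17)
    entry = build_bundle(spec)            # residues 17..33
    pdb = entry_to_pdb(entry, tmp_path / "full.pdb")
    lines = [ln for ln in pdb.read_text().splitlines()
             if " A  20 " not in ln]
    gappy = tmp_path / "gappy.pdb"
    gappy.write_text("\n".join(lines) + "\n")
    span = HelixSpan(1, 17, 33)
    parsed = read_structure(gappy, [span])
    assert len(parsed.span_residues(1)) == len(span) - 1
    with pytest.raises(MfsError, match="helix 1.*20"):
        read_structure(gappy, [HelixSpan(1, 20, 33)])


def test_unparseable_file_errors(tmp_path):
    bad = tmp_path / "bad.pdb"
    bad.write_text("this is not a structure\n")
    with pytest.raises(MfsError):
        read_structure(bad, [])


# ---------------------------------------------------------------------------
# spans


def test_span_invariants():
    with pytest.raises(MfsError):
        HelixSpan(1, 30, 20)
    with pytest.raises(MfsError):
        HelixSpan(13, 1, 10)
    assert HelixSpan(1, 10, 20).n_terminal_side == "cytoplasmic"
    assert HelixSpan(2, 30, 40).n_terminal_side == "extracellular"
    with pytest.raises(MfsError, match="overlap"):
        validate_spans([HelixSpan(1, 10, 25), HelixSpan(2, 20, 30)])


# ---------------------------------------------------------------------------
# MSA reading


def test_read_msa_normalizes_and_validates(tmp_path):
    path = tmp_path / "aln.fasta"
    path.write_text(">a\nacdEF-GHik\n>b\nACDEFGHIKL\n>c\nACDEF--HIK\n")
    msa = read_msa(path)
    assert msa.ncol == 10 and msa.nseq == 3
    assert msa.sequences[0] == "ACDEF-GHIK"

    ragged = tmp_path / "ragged.fasta"
    ragged.write_text(">a\nACDEF\n>b\nACD\n")
    with pytest.raises(MfsError, match="ragged"):
        read_msa(ragged)

    empty = tmp_path / "empty.fasta"
    empty.write_text("")
    with pytest.raises(MfsError):
        read_msa(empty)


# ---------------------------------------------------------------------------
# packaged reference table


@pytest.fixture(scope="module")
def reference():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return load_reference()


def test_reference_has_14_proteins_with_12_helices_each(reference):
    assert len(reference.entries) == 14
    assert all(len(e.records) == 12 for e in reference.entries.values())
    assert {"XylE", "PepT", "LacY", "FucP", "GLUT1", "EmrD", "GlcP",
            "GlpT", "MelB", "NarU", "NRT1.1", "PiPT", "YajR",
            "YgbH"} == set(reference.entries)


def test_reference_anchors_lie_within_their_spans(reference):
    violations = [(e.protein_name, r.span.helix_id)
                  for e in reference.entries.values()
                  for r in e.records
                  if r.anchor_residue_index not in r.span]
    assert violations == []


def test_reference_span_topology_alternates(reference):
    for e in reference.entries.values():
        for r in e.records:
            expected = "cytoplasmic" if r.span.helix_id % 2 else \
                "extracellular"
            assert r.span.n_terminal_side == expected
        validate_spans([r.span for r in e.records])


def test_reference_known_anchor_values(reference):
    lacy = reference.entry("LacY")
    assert lacy.record(4).anchor_residue_index == 111
    assert lacy.record(4).anchor_one_letter == "G"
    assert lacy.record(4).printed_label == "G4.0"
    xyle = reference.entry("XylE")
    assert xyle.record(5).span.start == 166
    assert xyle.record(5).span.end == 183
    assert xyle.record(5).anchor_residue_index == 174


def test_reference_printed_discrepancies_are_preserved_and_warned():
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        ref = load_reference()
    messages = [str(w.message) for w in caught]
    # three label-letter contradictions kept verbatim
    assert ref.entry("XylE").record(11).printed_label == "G11.0"
    assert ref.entry("XylE").record(11).anchor_one_letter == "Q"
    assert ref.entry("XylE").record(12).printed_label == "G12.0"
    assert ref.entry("GLUT1").record(11).printed_label == "S11.0"
    assert sum("contradicts" in m for m in messages) == 3
    # one printed span that excludes its own anchor, minimally extended
    pipt11 = ref.entry("PiPT").record(11)
    assert pipt11.printed_end == 469
    assert pipt11.anchor_residue_index == 470
    assert pipt11.span.end == 470
    assert any("outside printed span" in m for m in messages)


def test_reference_metadata_carries_uniprot_ids(reference):
    meta = reference.metadata.set_index("protein")
    assert meta.at["LacY", "uniprot_id"] == "P02920"
    assert meta.at["FucP", "uniprot_id"] == "P11551"
    assert len(meta) == 15     # includes gkPOT, which has no numbering row


# ---------------------------------------------------------------------------
# tabular writers


def test_contact_table_roundtrip(tmp_path):
    records = [
        ("e1", ContactRecord(helix_a=3, res_a=98, aa_a="L", helix_b=6,
                             res_b=219, aa_b="V", min_distance=4.25)),
        ("e1", ContactRecord(helix_a=2, res_a=50, aa_a="G", helix_b=4,
                             res_b=80, aa_b="A", min_distance=6.5,
                             glycine_proxy=True)),
    ]
    path = tmp_path / "contacts.tsv"
    write_contacts(records, path, header_lines=["test provenance"])
    df = read_contacts(path)
    assert len(df) == 2
    # deterministic sort: helix 2 row first
    assert df.iloc[0]["helix_a"] == 2 and bool(df.iloc[0]["glycine_proxy"])
    assert df.iloc[1]["res_b"] == 219
    assert df.iloc[1]["min_distance_A"] == pytest.approx(4.25)


def test_empty_contact_table_writes_header_with_warning(tmp_path):
    path = tmp_path / "empty.tsv"
    with pytest.warns(UserWarning, match="header-only"):
        write_contacts([], path)
    df = read_contacts(path)
    assert df.empty and list(df.columns)[0] == "entry_id"
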
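"""Reading and writing of structures, helix-span tables, MSAs and the
packaged reference numbering tables.

All residue coordinates are in the author numbering of the source PDB file
(the same numbering the reference tables use). Only the first model of a
structure is read; hydrogens, HETATM records and non-primary alternate
locations are discarded at parse time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomSite",
    "ResidueView",
    "HelixSpan",
    "StructureEntry",
    "ReferenceEntry",
    "ReferenceTable",
    "MSA",
    "MfsError",
    "read_structure",
    "read_msa",
    "read_span_table",
    "read_manifest",
    "load_reference",
    "write_contacts",
    "read_contacts",
    "write_numbering",
    "write_profiles",
]

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

STATES = ("outward_open", "occluded", "inward_open", "unknown")


class MfsError(Exception):
    """Raised for data errors (bad files, unsatisfiable preconditions)."""


@dataclass(frozen=True)
class AtomSite:
    """A single heavy atom in author numbering.

    ``category`` is 'backbone' exactly for N, CA, C, O and 'sidechain'
    otherwise; hydrogens never survive parsing.
    """

    serial: int
    name: str
    element: str
    residue_index: int
    insertion_code: str
    residue_name: str
    chain_id: str
    position: np.ndarray  # shape (3,), Å
    category: str
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self):
        if not np.all(np.isfinite(self.position)):
            raise MfsError(f"non-finite coordinates for atom {self.name} "
                           f"{self.chain_id}{self.residue_index}")
        expected = "backbone" if self.name in BACKBONE_NAMES else "sidechain"
        if self.category != expected:
            raise MfsError(f"atom {self.name}: category {self.category!r} "
                           f"inconsistent with name")


@dataclass
class ResidueView:
    chain_id: str
    residue_index: int
    one_letter: str
    atoms: list[AtomSite] = field(default_factory=list)
    insertion_code: str = ""
    residue_name: str = ""

    @property
    def backbone(self) -> list[AtomSite]:
        return [a for a in self.atoms if a.category == "backbone"]

    @property
    def sidechain(self) -> list[AtomSite]:
        return [a for a in self.atoms if a.category == "sidechain"]

    def atom(self, name: str) -> AtomSite | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass(frozen=True)
class HelixSpan:
    """Inclusive author-numbering span of one transmembrane helix.

    ``n_terminal_side`` follows the canonical 12-TM topology: odd helices
    start on the cytoplasmic side of the membrane, even helices on the
    extracellular side.
    """

    helix_id: int
    start: int
    end: int
    n_terminal_side: str = ""

    def __post_init__(self):
        if not 1 <= self.helix_id <= 12:
            raise MfsError(f"helix_id must be 1..12, got {self.helix_id}")
        if self.start >= self.end:
            raise MfsError(f"helix {self.helix_id}: start {self.start} "
                           f">= end {self.end}")
        if not self.n_terminal_side:
            side = "cytoplasmic" if self.helix_id % 2 == 1 else "extracellular"
            object.__setattr__(self, "n_terminal_side", side)
        if self.n_terminal_side not in ("cytoplasmic", "extracellular"):
            raise MfsError(f"bad n_terminal_side {self.n_terminal_side!r}")

    def __contains__(self, residue_index: int) -> bool:
        return self.start <= residue_index <= self.end

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def validate_spans(spans: Sequence[HelixSpan]) -> None:
    """Check pairwise non-overlap and sequence order of a span set."""
    ordered = sorted(spans, key=lambda s: s.helix_id)
    for a, b in zip(ordered, ordered[1:]):
        if a.end >= b.start:
            raise MfsError(f"helix {a.helix_id} span {a.start}-{a.end} "
                           f"overlaps/precedes helix {b.helix_id} "
                           f"span {b.start}-{b.end}")


@dataclass
class StructureEntry:
    entry_id: str
    protein_name: str
    residues: list[ResidueView]
    spans: list[HelixSpan]
    state: str = "unknown"

    def __post_init__(self):
        if self.state not in STATES:
            raise MfsError(f"unknown state label {self.state!r}")
        self._index = {(r.chain_id, r.residue_index, r.insertion_code): r
                       for r in self.residues}

    def residue(self, residue_index: int, chain_id: str | None = None,
                icode: str = "") -> ResidueView | None:
        if chain_id is None and self.residues:
            chain_id = self.residues[0].chain_id
        return self._index.get((chain_id, residue_index, icode))

    def span(self, helix_id: int) -> HelixSpan:
        for s in self.spans:
            if s.helix_id == helix_id:
                return s
        raise MfsError(f"{self.entry_id}: no span for helix {helix_id}")

    def span_residues(self, helix_id: int) -> list[ResidueView]:
        """Residues resolved inside a helix span (gaps tolerated)."""
        s = self.span(helix_id)
        chain = self.residues[0].chain_id if self.residues else ""
        out = []
        for i in range(s.start, s.end + 1):
            r = self.residue(i, chain)
            if r is not None:
                out.append(r)
        return out

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


# ---------------------------------------------------------------------------
# structure reading


def _keep_altloc(residue: gemmi.Residue) -> dict[str, gemmi.Atom]:
    """Primary-conformation atoms: altloc blank, else 'A'."""
    chosen: dict[str, gemmi.Atom] = {}
    for atom in residue:
        if atom.altloc not in ("", "\x00", "A"):
            continue
        prev = chosen.get(atom.name)
        if prev is None:
            chosen[atom.name] = atom
        elif (prev.altloc not in ("", "\x00")) and atom.altloc in ("", "\x00"):
            chosen[atom.name] = atom
        elif atom.occ > prev.occ:
            chosen[atom.name] = atom
    return chosen


def read_structure(path: str | Path,
                   span_table: Sequence[HelixSpan],
                   state: str = "unknown",
                   entry_id: str | None = None,
                   protein_name: str = "",
                   chain_id: str | None = None) -> StructureEntry:
    """Parse a PDB file into a :class:`StructureEntry`.

    First model only; hydrogens, waters and all HETATM residues are
    dropped; for alternate locations only blank/'A' altlocs are kept.
    Every span must resolve at least its start and end residues.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise MfsError(f"unparseable PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise MfsError(f"{path}: no models / no ATOM records")
    st.setup_entities()
    model = st[0]

    residues: list[ResidueView] = []
    serial = 0
    for chain in model:
        if chain_id is not None and chain.name != chain_id:
            continue
        for res in chain:
            if res.het_flag != "A":       # ATOM records only
                continue
            one = THREE_TO_ONE.get(res.name.upper(), "X")
            rv = ResidueView(chain_id=chain.name,
                             residue_index=res.seqid.num,
                             one_letter=one,
                             insertion_code=(res.seqid.icode or "").strip(),
                             residue_name=res.name.upper())
            for atom in _keep_altloc(res).values():
                if atom.element.is_hydrogen:
                    continue
                serial += 1
                name = atom.name.strip()
                rv.atoms.append(AtomSite(
                    serial=serial,
                    name=name,
                    element=atom.element.name,
                    residue_index=res.seqid.num,
                    insertion_code=rv.insertion_code,
                    residue_name=rv.residue_name,
                    chain_id=chain.name,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    category="backbone" if name in BACKBONE_NAMES
                             else "sidechain",
                    altloc="" if atom.altloc in ("", "\x00") else atom.altloc,
                    occupancy=atom.occ,
                ))
            if rv.atoms:
                residues.append(rv)
    if not residues:
        raise MfsError(f"{path}: no ATOM residues parsed"
                       + (f" for chain {chain_id}" if chain_id else ""))

    entry = StructureEntry(entry_id=entry_id or path.stem,
                           protein_name=protein_name or path.stem,
                           residues=residues,
                           spans=list(span_table),
                           state=state)
    chain0 = residues[0].chain_id
    for s in entry.spans:
        for endpoint in (s.start, s.end):
            if entry.residue(endpoint, chain0) is None:
                raise MfsError(
                    f"{entry.entry_id}: helix {s.helix_id} span residue "
                    f"{endpoint} missing from structure (chain {chain0})")
    return entry


# ---------------------------------------------------------------------------
# MSA reading

VALID_MSA_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYX-")


@dataclass
class MSA:
    ids: list[str]
    sequences: list[str]   # uppercase, aligned

    @property
    def ncol(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def nseq(self) -> int:
        return len(self.sequences)

    def column(self, i: int) -> str:
        """1-based alignment column."""
        if not 1 <= i <= self.ncol:
            raise MfsError(f"column {i} outside 1..{self.ncol}")
        return "".join(s[i - 1] for s in self.sequences)

    def sequence(self, seq_id: str) -> str:
        try:
            return self.sequences[self.ids.index(seq_id)]
        except ValueError:
            raise MfsError(f"sequence id {seq_id!r} not in MSA") from None


def read_msa(path: str | Path) -> MSA:
    """Read an aligned FASTA file (equal gapped lengths enforced)."""
    from Bio import SeqIO

    path = Path(path)
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not seqs:
        raise MfsError(f"{path}: empty or non-FASTA file")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise MfsError(f"{path}: ragged alignment, lengths {sorted(lengths)}")
    for sid, s in zip(ids, seqs):
        bad = set(s) - VALID_MSA_CHARS
        if bad:
            raise MfsError(f"{path}: sequence {sid} contains invalid "
                           f"characters {sorted(bad)}")
    return MSA(ids=ids, sequences=seqs)


# ---------------------------------------------------------------------------
# span tables and manifests


def read_span_table(path: str | Path,
                    protein: str | None = None) -> list[HelixSpan]:
    """Read a TSV with columns protein, helix, start, end.

    If ``protein`` is given, rows are filtered to it; otherwise the file
    must contain a single protein.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"protein", "helix", "start", "end"}
    if not required.issubset(df.columns):
        raise MfsError(f"{path}: span table needs columns {sorted(required)}")
    if protein is not None:
        df = df[df["protein"] == protein]
        if df.empty:
            raise MfsError(f"{path}: no spans for protein {protein!r}")
    elif df["protein"].nunique() > 1:
        raise MfsError(f"{path}: multiple proteins present; pass protein=")
    spans = [HelixSpan(int(r.helix), int(r.start), int(r.end))
             for r in df.itertuples()]
    validate_spans(spans)
    return spans


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Manifest TSV with columns entry_id, pdb_path, state."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"entry_id", "pdb_path", "state"}
    if not required.issubset(df.columns):
        raise MfsError(f"{path}: manifest needs columns {sorted(required)}")
    bad = set(df["state"]) - set(STATES)
    if bad:
        raise MfsError(f"{path}: unknown state labels {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# packaged reference table


@dataclass(frozen=True)
class ReferenceRecord:
    span: HelixSpan
    anchor_residue_index: int
    anchor_one_letter: str
    printed_label: str
    printed_end: int            # verbatim span end as printed
    discrepancy: str = ""


@dataclass
class ReferenceEntry:
    protein_name: str
    entry_id: str
    records: list[ReferenceRecord]   # 12, helix order

    def record(self, helix_id: int) -> ReferenceRecord:
        return self.records[helix_id - 1]


@dataclass
class ReferenceTable:
    entries: dict[str, ReferenceEntry]
    metadata: pd.DataFrame
    discrepancies: list[str] = field(default_factory=list)

    def entry(self, protein_name: str) -> ReferenceEntry:
        try:
            return self.entries[protein_name]
        except KeyError:
            raise MfsError(
                f"unknown protein {protein_name!r}; known: "
                f"{', '.join(sorted(self.entries))}") from None


def _data_path(name: str):
    return resources.files("mfsnum.data").joinpath(name)


def load_reference() -> ReferenceTable:
    """Load the packaged 14-protein reference numbering table.

    Printed label/residue letter contradictions are preserved verbatim and
    reported as warnings. One printed span (PiPT helix 11) ends one residue
    short of its own anchor; the working span is minimally extended to
    include the anchor and the verbatim end kept in ``printed_end``.
    """
    try:
        with resources.as_file(_data_path("reference_numbering.tsv")) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
        with resources.as_file(_data_path("family_metadata.tsv")) as p:
            meta = pd.read_csv(p, sep="\t", comment="#")
    except (OSError, pd.errors.ParserError) as exc:
        raise MfsError(f"corrupted packaged reference data: {exc}") from exc
    needed = {"protein", "pdb_id", "helix", "start", "end",
              "anchor_residue", "anchor_letter", "printed_label"}
    if not needed.issubset(df.columns):
        raise MfsError("corrupted packaged reference table: missing columns")

    entries: dict[str, ReferenceEntry] = {}
    discrepancies: list[str] = []
    for protein, sub in df.groupby("protein", sort=False):
        sub = sub.sort_values("helix")
        if list(sub["helix"]) != list(range(1, 13)):
            raise MfsError(f"packaged table: {protein} does not have "
                           f"helices 1..12")
        records = []
        for row in sub.itertuples():
            start, end, anchor = int(row.start), int(row.end), \
                int(row.anchor_residue)
            printed_end = end
            flag = "" if pd.isna(getattr(row, "discrepancy", "")) else \
                str(getattr(row, "discrepancy", "") or "")
            if anchor < start or anchor > end:
                msg = (f"{protein} helix {row.helix}: anchor "
                       f"{row.anchor_letter}{anchor} outside printed span "
                       f"{start}-{end}; span extended to include it")
                warnings.warn(msg)
                discrepancies.append(msg)
                start, end = min(start, anchor), max(end, anchor)
            label_letter = str(row.printed_label)[0]
            if label_letter != str(row.anchor_letter):
                msg = (f"{protein} helix {row.helix}: printed label "
                       f"{row.printed_label} contradicts anchor residue "
                       f"letter {row.anchor_letter}{anchor}")
                warnings.warn(msg)
                discrepancies.append(msg)
            records.append(ReferenceRecord(
                span=HelixSpan(int(row.helix), start, end),
                anchor_residue_index=anchor,
                anchor_one_letter=str(row.anchor_letter),
                printed_label=str(row.printed_label),
                printed_end=printed_end,
                discrepancy=flag))
        validate_spans([r.span for r in records])
        entries[protein] = ReferenceEntry(protein_name=protein,
                                          entry_id=str(sub["pdb_id"].iloc[0]),
                                          records=records)
    return ReferenceTable(entries=entries, metadata=meta,
                          discrepancies=discrepancies)


# ---------------------------------------------------------------------------
# tabular writers (deterministic order; '#' provenance comments allowed)

CONTACT_COLUMNS = ["entry_id", "helix_a", "res_a", "aa_a", "helix_b",
                   "res_b", "aa_b", "min_distance_A", "direction",
                   "glycine_proxy"]


def _write_df(df: pd.DataFrame, path: str | Path,
              header_lines: Iterable[str] = ()) -> None:
    path = Path(path)
    try:
        with open(path, "w", encoding="utf-8") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t", index=False)
    except OSError as exc:
        raise MfsError(f"cannot write {path}: {exc}") from exc


def write_contacts(records, path: str | Path,
                   header_lines: Iterable[str] = ()) -> None:
    """Write ContactRecords (optionally (entry_id, record) pairs) as TSV."""
    rows = []
    for item in records:
        entry_id, rec = item if isinstance(item, tuple) else (item.entry_id,
                                                              item)
        rows.append({
            "entry_id": entry_id,
            "helix_a": rec.helix_a, "res_a": rec.res_a, "aa_a": rec.aa_a,
            "helix_b": rec.helix_b, "res_b": rec.res_b, "aa_b": rec.aa_b,
            "min_distance_A": round(rec.min_distance, 6),
            "direction": "sidechain_a_to_backbone_b",
            "glycine_proxy": rec.glycine_proxy,
        })
    df = pd.DataFrame(rows, columns=CONTACT_COLUMNS)
    if df.empty:
        warnings.warn(f"writing header-only contact table to {path}")
    else:
        df = df.sort_values(["entry_id", "helix_a", "helix_b", "res_a"],
                            kind="mergesort").reset_index(drop=True)
    _write_df(df, path, header_lines)


def read_contacts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns) != CONTACT_COLUMNS:
        raise MfsError(f"{path}: not a contact table")
    return df


def write_numbering(numbering, path: str | Path,
                    header_lines: Iterable[str] = ()) -> None:
    """Write a GenericNumbering as TSV (one row per in-span residue)."""
    rows = [{"protein": numbering.protein_name,
             "residue_index": idx,
             "helix": lab.helix_id,
             "offset": lab.offset,
             "label": lab.rendered}
            for idx, lab in sorted(numbering.labels.items())]
    _write_df(pd.DataFrame(rows), path, header_lines)


def write_profiles(profile, path: str | Path,
                   header_lines: Iterable[str] = ()) -> None:
    """Write a ConservationProfile as TSV (one row per column)."""
    df = profile.to_frame().reset_index()
    _write_df(df, path, header_lines)
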
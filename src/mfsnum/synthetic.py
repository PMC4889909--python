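"""Synthetic fixtures: idealized transmembrane helix bundles and MSAs with
planted per-column group conservation.

The bundle generator places residues on an ideal α-helix (rise 1.5 Å per
residue, 100° per residue, CA 2.3 Å from the axis) with a pseudo side chain
(CB) 1.5 Å radially outside the CA; glycine gets no CB, exercising the
CA-proxy path of contact detection. Backbone N, C, O sit at fixed offsets
from the CA in the local helix frame. No φ/ψ realism is attempted — the
contact rule only needs distances. All generation is seed-deterministic
and byte-reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .conservation import EXTENDED_SCHEME, GroupScheme
from .structure_io import (MSA, AtomSite, HelixSpan, MfsError, ResidueView,
                           StructureEntry, ONE_TO_THREE)

__all__ = [
    "HelixPlacement",
    "BundleSpec",
    "PlantedColumn",
    "MsaSpec",
    "build_bundle",
    "build_state_pair",
    "build_msa",
    "write_msa_fasta",
    "entry_to_pdb",
    "RISE_PER_RESIDUE",
    "TWIST_PER_RESIDUE",
    "CA_RADIUS",
    "CB_RADIAL_OFFSET",
]

RISE_PER_RESIDUE = 1.5      # Å
TWIST_PER_RESIDUE = 100.0   # degrees
CA_RADIUS = 2.3             # Å from the helix axis
CB_RADIAL_OFFSET = 1.5      # Å radially outside the CA

# Fixed backbone offsets from the CA in the local (radial u, tangential v,
# axial w) frame; magnitudes near real bond geometry.
_BACKBONE_OFFSETS = {
    "N": np.array([-0.35, -1.20, -0.75]),
    "C": np.array([-0.25, 1.20, 0.70]),
    "O": np.array([-1.10, 1.40, 1.30]),
}


@dataclass(frozen=True)
class HelixPlacement:
    """Geometry of one helix in the bundle.

    ``origin`` is the (x, y) position of the helix axis at the membrane
    mid-plane; ``tilt`` (degrees from +z) is applied by rotating the helix
    about its own mid-point, swinging in the direction given by
    ``azimuth``; ``phase`` rotates side chains about the axis (phase 0
    points the first residue's CB along +x before tilting); ``direction``
    'up' runs N-terminus at the cytoplasmic (low z) end.
    """

    sequence: str
    origin: tuple[float, float] = (0.0, 0.0)
    tilt: float = 0.0
    azimuth: float = 0.0
    phase: float = 0.0
    direction: str = "up"
    z_offset: float = 0.0

    def __post_init__(self):
        if not self.sequence:
            raise MfsError("helix sequence must be non-empty")
        if not 0.0 <= self.tilt <= 60.0:
            raise MfsError(f"tilt must be within [0, 60] deg, got "
                           f"{self.tilt}")
        if self.direction not in ("up", "down"):
            raise MfsError(f"direction must be 'up' or 'down'")


@dataclass(frozen=True)
class BundleSpec:
    helices: tuple[HelixPlacement, ...]
    entry_id: str = "synthetic"
    protein_name: str = "synthetic"
    loop_gap: int = 3           # author-numbering gap between helix spans
    first_residue: int = 1
    helix_ids: tuple[int, ...] | None = None   # default 1..n in order

    def __post_init__(self):
        if not self.helices:
            raise MfsError("bundle needs at least one helix")
        if len(self.helices) > 12:
            raise MfsError("at most 12 helices supported")
        if self.helix_ids is not None and \
                len(self.helix_ids) != len(self.helices):
            raise MfsError("helix_ids length != number of helices")


def _rot_y(deg: float) -> np.ndarray:
    t = np.radians(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(deg: float) -> np.ndarray:
    t = np.radians(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _helix_coordinates(placement: HelixPlacement
                       ) -> list[dict[str, np.ndarray]]:
    """Per-residue atom coordinate dicts for one placed helix."""
    n = len(placement.sequence)
    z0 = -RISE_PER_RESIDUE * (n - 1) / 2.0
    atoms_per_residue = []
    for i, aa in enumerate(placement.sequence):
        theta = np.radians(TWIST_PER_RESIDUE * i + placement.phase)
        u = np.array([np.cos(theta), np.sin(theta), 0.0])
        v = np.array([-np.sin(theta), np.cos(theta), 0.0])
        w = np.array([0.0, 0.0, 1.0])
        ca = CA_RADIUS * u + (z0 + RISE_PER_RESIDUE * i) * w
        atoms = {"CA": ca}
        for name, (du, dv, dw) in _BACKBONE_OFFSETS.items():
            atoms[name] = ca + du * u + dv * v + dw * w
        if aa != "G":
            atoms["CB"] = ca + CB_RADIAL_OFFSET * u
        atoms_per_residue.append(atoms)

    if placement.direction == "down":
        flip = np.diag([1.0, -1.0, -1.0])    # 180° about x: N-term on top
        atoms_per_residue = [{k: flip @ p for k, p in res.items()}
                             for res in atoms_per_residue]

    rot = _rot_z(placement.azimuth) @ _rot_y(placement.tilt)
    shift = np.array([placement.origin[0], placement.origin[1],
                      placement.z_offset])
    return [{k: rot @ p + shift for k, p in res.items()}
            for res in atoms_per_residue]


def build_bundle(spec: BundleSpec, seed: int = 0,
                 jitter: float = 0.0) -> StructureEntry:
    """Build a bundle as an in-memory :class:`StructureEntry`.

    ``jitter`` is the RMS atomic displacement in Å (Gaussian, isotropic,
    per-coordinate σ = jitter/√3), applied with the given seed; jitter 0
    is exactly deterministic regardless of seed.
    """
    rng = np.random.default_rng(seed)
    residues: list[ResidueView] = []
    spans: list[HelixSpan] = []
    serial = 0
    next_index = spec.first_residue
    helix_coords = [_helix_coordinates(h) for h in spec.helices]

    # overlap guard: inter-helix CA-CA must stay >= 1 Å
    for (i, ci), (j, cj) in itertools.combinations(
            enumerate(helix_coords), 2):
        cas_i = np.array([r["CA"] for r in ci])
        cas_j = np.array([r["CA"] for r in cj])
        d2 = ((cas_i[:, None, :] - cas_j[None, :, :]) ** 2).sum(-1)
        if d2.min() < 1.0:
            raise MfsError(f"helices {i + 1} and {j + 1} overlap "
                           f"(CA-CA {np.sqrt(d2.min()):.2f} Å < 1 Å)")

    ids = spec.helix_ids or tuple(range(1, len(spec.helices) + 1))
    for helix_id, placement, coords in zip(ids, spec.helices, helix_coords):
        start = next_index
        for aa, atom_coords in zip(placement.sequence, coords):
            rv = ResidueView(chain_id="A", residue_index=next_index,
                             one_letter=aa,
                             residue_name=ONE_TO_THREE.get(aa, "UNK"))
            for name in ("N", "CA", "C", "O", "CB"):
                if name not in atom_coords:
                    continue
                serial += 1
                pos = np.asarray(atom_coords[name], dtype=float)
                if jitter > 0:
                    pos = pos + rng.normal(0.0, jitter / np.sqrt(3.0),
                                           size=3)
                rv.atoms.append(AtomSite(
                    serial=serial, name=name,
                    element="C" if name.startswith("C") else name[0],
                    residue_index=next_index, insertion_code="",
                    residue_name=rv.residue_name, chain_id="A",
                    position=pos,
                    category="backbone" if name in ("N", "CA", "C", "O")
                             else "sidechain"))
            residues.append(rv)
            next_index += 1
        spans.append(HelixSpan(helix_id, start, next_index - 1))
        next_index += spec.loop_gap
    return StructureEntry(entry_id=spec.entry_id,
                          protein_name=spec.protein_name,
                          residues=residues, spans=spans)


def build_state_pair(spec: BundleSpec,
                     tilt_delta: dict[int, float] | None = None,
                     contact_shift: dict[int, int] | None = None,
                     states: tuple[str, str] = ("outward_open",
                                                "inward_open"),
                     seed: int = 0,
                     jitter: float = 0.0,
                     azimuth: float = 90.0
                     ) -> tuple[StructureEntry, StructureEntry]:
    """Build two state-labelled conformers differing only by the stated
    perturbation, with derivable ground-truth contact class.

    ``tilt_delta`` re-tilts helices (1-based ids) about their own
    mid-point, swinging perpendicular to the inter-helix direction
    (``azimuth``; 90° = swing in the y-z plane for partners displaced
    along x) so a mid-helix contact is preserved: ground truth *pivot*.
    ``contact_shift`` slides helices along z by n × 1.5 Å, moving the
    partner's closest donor by ~n residues: ground truth *mobile*.
    No perturbation: ground truth *static*.
    """
    tilt_delta = tilt_delta or {}
    contact_shift = contact_shift or {}
    perturbed = []
    for helix_id, placement in enumerate(spec.helices, start=1):
        if helix_id in tilt_delta:
            placement = replace(placement,
                                tilt=placement.tilt + tilt_delta[helix_id],
                                azimuth=azimuth)
        if helix_id in contact_shift:
            placement = replace(
                placement,
                z_offset=placement.z_offset
                + contact_shift[helix_id] * RISE_PER_RESIDUE)
        perturbed.append(placement)
    spec_b = replace(spec, helices=tuple(perturbed),
                     entry_id=spec.entry_id + "_b")
    entry_a = build_bundle(spec, seed=seed, jitter=jitter)
    entry_b = build_bundle(spec_b, seed=seed + 1, jitter=jitter)
    entry_a.state = states[0]
    entry_b.state = states[1]
    return entry_a, entry_b


def contact_pair_spec(n_donor: int = 21, n_acceptor: int = 9,
                      separation: float = 8.5) -> BundleSpec:
    """Canonical two-helix fixture for contact-trajectory studies.

    A 21-residue donor helix with the middle residue's side chain phased
    to face the partner, and a short (9-residue) acceptor helix at 8.5 Å
    axis separation displaced along +x. The short acceptor keeps the
    contact localized near the helix mid-points, so the planted contact
    class stays well defined when the acceptor is re-tilted or slid.
    """
    mid = (n_donor - 1) // 2
    donor = HelixPlacement("L" * n_donor, origin=(0.0, 0.0),
                           phase=-TWIST_PER_RESIDUE * mid)
    acceptor = HelixPlacement("A" * n_acceptor, origin=(separation, 0.0),
                              direction="down")
    return BundleSpec(helices=(donor, acceptor))


def planted_state_pair(kind: str, seed: int = 0, jitter: float = 0.0,
                       tilt_delta: float = 18.0, shift: int = 4
                       ) -> tuple[StructureEntry, StructureEntry, str]:
    """Two-state fixture with a known contact class for helix pair (1, 2).

    ``kind`` is 'static' (no perturbation), 'pivot' (acceptor re-tilted
    about the contact by ``tilt_delta`` degrees) or 'mobile' (acceptor
    slid by ``shift`` residues along the membrane normal). Returns the
    two labelled entries and the planted class. The defaults (18° pivot,
    4-residue slide against a 9-residue acceptor) separate the three
    classes cleanly at the default classification tolerances even under
    sub-ångström coordinate jitter.
    """
    spec = contact_pair_spec()
    if kind == "static":
        perturb = {}
    elif kind == "pivot":
        perturb = {"tilt_delta": {2: tilt_delta}}
    elif kind == "mobile":
        perturb = {"contact_shift": {2: shift}}
    else:
        raise MfsError(f"unknown planted class {kind!r}")
    a, b = build_state_pair(spec, seed=seed, jitter=jitter, **perturb)
    return a, b, kind


#: First-choice anchor group and planted residue letter per helix, matching
#: the 12 anchor rules (polar -> S/T/Q/N, glycine -> G, small hydrophobic
#: -> A against a leucine background).
_ANCHOR_LETTERS = {1: ("polar", "S"), 2: ("glycine", "G"),
                   3: ("small_hydrophobic", "A"), 4: ("glycine", "G"),
                   5: ("polar", "S"), 6: ("small_hydrophobic", "A"),
                   7: ("polar", "Q"), 8: ("polar", "T"),
                   9: ("glycine", "G"), 10: ("glycine", "G"),
                   11: ("polar", "N"), 12: ("small_hydrophobic", "A")}

#: Axis origins placing each helix 9 Å from its anchor-rule partner and
#: >= 20 Å from everything else, so the contact graph is exactly
#: {1-5, 5-8, 2-4, 3-6, 7-11, 9-10, 9-12}.
_ANCHOR_ORIGINS = {1: (0, 0), 5: (9, 0), 8: (18, 0),
                   2: (0, 20), 4: (9, 20),
                   3: (0, 40), 6: (9, 40),
                   7: (0, 60), 11: (9, 60),
                   9: (0, 80), 10: (9, 80), 12: (-9, 80)}

#: Which helix each helix's anchor rule points at (donor -> partner).
_ANCHOR_PARTNERS = {1: 5, 2: 4, 3: 6, 4: 2, 5: 1, 6: 3,
                    7: 11, 8: 5, 9: 10, 10: 9, 11: 7, 12: 9}


def anchor_demo_bundle(helix_length: int = 19, n_sequences: int = 50,
                       conservation: float = 0.9, seed: int = 0
                       ) -> tuple[StructureEntry, "MsaSpec", dict[int, int]]:
    """A 12-helix bundle + family MSA where every helix has exactly one
    maximally conserved rule-conformant anchor residue.

    Each helix carries its anchor letter at the mid-position, phased so
    the side chain faces the rule's partner helix; the accompanying MSA
    plants the stated conservation for the rule's group at exactly the
    anchor columns (background drawn from aromatic/charged letters that
    belong to no anchor group). Returns the entry, the MSA spec and the
    planted anchor residue index per helix.
    """
    import math

    mid = (helix_length - 1) // 2
    helices = []
    anchors: dict[int, int] = {}
    planted = []
    for h in range(1, 13):
        group, letter = _ANCHOR_LETTERS[h]
        seq = list("L" * helix_length)
        seq[mid] = letter
        ox, oy = _ANCHOR_ORIGINS[h]
        px, py = _ANCHOR_ORIGINS[_ANCHOR_PARTNERS[h]]
        alpha = math.degrees(math.atan2(py - oy, px - ox))
        direction = "up" if h % 2 == 1 else "down"
        phase = (alpha if direction == "up" else -alpha) \
            - TWIST_PER_RESIDUE * mid
        helices.append(HelixPlacement("".join(seq), origin=(ox, oy),
                                      phase=phase, direction=direction))
        anchor_index = (h - 1) * helix_length + mid + 1
        anchors[h] = anchor_index
        planted.append(PlantedColumn(column=anchor_index, group=group,
                                     fraction=conservation, letter=letter))
    spec = BundleSpec(helices=tuple(helices), loop_gap=0,
                      entry_id="anchor_demo", protein_name="anchor_demo")
    entry = build_bundle(spec, seed=seed)
    msa_spec = MsaSpec(n_sequences=n_sequences,
                       length=12 * helix_length,
                       planted=tuple(planted),
                       background_pool="FYWHKRDE",
                       seed=seed,
                       reference_sequence=entry.sequence())
    return entry, msa_spec, anchors


def closure_demo_bundle(kind: str, helix_length: int = 19
                        ) -> StructureEntry:
    """A 12-helix bundle planted with only a 1-7 contact ('inward_open'),
    only a 4-10 contact ('outward_open'), both ('occluded') or neither
    ('apo'): the gate pairs sit at 9 Å when closed, >= 25 Å otherwise."""
    near, far = 9.0, 30.0
    d17 = near if kind in ("inward_open", "occluded") else far
    d410 = near if kind in ("outward_open", "occluded") else far
    origins = {1: (0.0, 0.0), 7: (d17, 0.0),
               4: (0.0, 60.0), 10: (d410, 60.0)}
    # remaining helices parked on a distant row
    parked = [h for h in range(1, 13) if h not in origins]
    for i, h in enumerate(parked):
        origins[h] = (i * 25.0, 150.0)
    mid = (helix_length - 1) // 2
    helices = []
    for h in range(1, 13):
        ox, oy = origins[h]
        partner = {1: 7, 7: 1, 4: 10, 10: 4}.get(h)
        phase = 0.0
        direction = "up" if h % 2 == 1 else "down"
        if partner is not None:
            import math
            px, py = origins[partner]
            alpha = math.degrees(math.atan2(py - oy, px - ox))
            phase = (alpha if direction == "up" else -alpha) \
                - TWIST_PER_RESIDUE * mid
        helices.append(HelixPlacement("L" * helix_length, origin=(ox, oy),
                                      phase=phase, direction=direction))
    spec = BundleSpec(helices=tuple(helices), entry_id=f"closure_{kind}",
                      protein_name=f"closure_{kind}")
    return build_bundle(spec)


# ---------------------------------------------------------------------------
# PDB writing


def entry_to_pdb(entry: StructureEntry, path: str | Path) -> Path:
    """Write a StructureEntry as a minimal single-chain PDB file."""
    path = Path(path)
    lines = []
    serial = 0
    for res in entry.residues:
        for atom in res.atoms:
            serial += 1
            x, y, z = atom.position
            name_field = f" {atom.name:<3}"     # element-justified for C/N/O
            lines.append(
                f"ATOM  {serial:>5}{name_field:>5} {res.residue_name:>3} "
                f"{res.chain_id:1}{res.residue_index:>4}"
                f"{res.insertion_code or ' ':1}"
                f"   {x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# planted-conservation MSAs


@dataclass(frozen=True)
class PlantedColumn:
    column: int            # 1-based
    group: str
    fraction: float
    letter: str | None = None   # member letter to plant; default per group


@dataclass(frozen=True)
class MsaSpec:
    n_sequences: int
    length: int
    planted: tuple[PlantedColumn, ...] = ()
    background_pool: str = "ACDEFGHIKLMNPQRSTVWY"
    seed: int = 0
    reference_sequence: str | None = None
    scheme: GroupScheme = field(default_factory=lambda: EXTENDED_SCHEME)

    def __post_init__(self):
        if self.n_sequences < 1 or self.length < 1:
            raise MfsError("MSA must have >= 1 sequence and >= 1 column")
        if self.reference_sequence is not None and \
                len(self.reference_sequence) != self.length:
            raise MfsError("reference_sequence length != MSA length")
        for p in self.planted:
            if not 1 <= p.column <= self.length:
                raise MfsError(f"planted column {p.column} outside MSA")
            k = p.fraction * self.n_sequences
            if abs(k - round(k)) > 1e-9:
                raise MfsError(
                    f"planted fraction {p.fraction} at column {p.column} is "
                    f"not realizable with {self.n_sequences} sequences")


def build_msa(spec: MsaSpec) -> MSA:
    """Constructively realize each planted group fraction exactly.

    Row 0 is pinned to ``reference_sequence`` when given (so the MSA
    contains the structure's own sequence, as a family alignment seeded on
    the crystallized protein would); remaining cells are drawn uniformly
    from the background pool, excluding group members in planted columns
    so the planted fraction is exact. Deterministic for a given spec.
    """
    rng = np.random.default_rng(spec.seed)
    scheme = spec.scheme
    n, L = spec.n_sequences, spec.length
    pool = np.array(list(spec.background_pool))
    arr = pool[rng.integers(0, len(pool), size=(n, L))]
    if spec.reference_sequence is not None:
        arr[0, :] = list(spec.reference_sequence.upper())

    for p in spec.planted:
        members = scheme.members(p.group)
        letter = p.letter or sorted(members)[0]
        if letter not in members:
            raise MfsError(f"planted letter {letter!r} not in group "
                           f"{p.group}")
        non_members = [c for c in spec.background_pool if c not in members]
        if not non_members and p.fraction < 1.0:
            raise MfsError(f"background pool has no non-{p.group} letters")
        k = round(p.fraction * n)
        col = p.column - 1
        free_rows = list(range(n))
        need = k
        if spec.reference_sequence is not None:
            free_rows = free_rows[1:]
            ref_letter = arr[0, col]
            if ref_letter in members:
                need -= 1
                if need < 0:
                    raise MfsError(
                        f"column {p.column}: reference letter "
                        f"{ref_letter} is a {p.group} member but planted "
                        f"fraction is 0")
        if need > len(free_rows):
            raise MfsError(f"column {p.column}: cannot place {need} members "
                           f"in {len(free_rows)} free rows")
        order = rng.permutation(free_rows)
        member_rows = set(order[:need].tolist())
        for row in free_rows:
            if row in member_rows:
                arr[row, col] = letter
            else:
                arr[row, col] = non_members[
                    rng.integers(0, len(non_members))]
    ids = [f"seq{i:03d}" for i in range(n)]
    if spec.reference_sequence is not None:
        ids[0] = "reference"
    return MSA(ids=ids, sequences=["".join(row) for row in arr])


def write_msa_fasta(msa: MSA, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for sid, seq in zip(msa.ids, msa.sequences):
            fh.write(f">{sid}\n{seq}\n")
    return path
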
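"""Per-column MSA conservation by physicochemical amino-acid groups.

The statistic is deliberately simple: for every alignment column, the
fraction of non-gap entries falling in each chemical group (hydrophobic,
polar, positively/negatively charged, aromatic, glycine, proline). Groups
may overlap — the aromatics W, F, Y are also hydrophobic — so fractions of
overlapping groups do not sum to 1. Gaps are excluded from the denominator
and reported separately; 'X' counts in the denominator but in no group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure_io import MSA, MfsError, StructureEntry

__all__ = [
    "GroupScheme",
    "DEFAULT_SCHEME",
    "EXTENDED_SCHEME",
    "SMALL_HYDROPHOBIC",
    "LARGE_HYDROPHOBIC",
    "classify_residue",
    "ConservationProfile",
    "column_conservation",
    "conserved_sites",
    "ColumnMapping",
    "map_columns",
]

# Hydrophobicity-size split used by the anchor rules; the published
# contact analysis uses "small"/"large hydrophobic" without defining
# membership, so these sets are config-overridable.
SMALL_HYDROPHOBIC = frozenset("AVILCM")
LARGE_HYDROPHOBIC = frozenset("FWY")

_CANONICAL_GROUPS = {
    "hydrophobic": frozenset("MAVILCYFW"),
    "polar": frozenset("STNQ"),
    "positive": frozenset("RHK"),
    "negative": frozenset("DE"),
    "aromatic": frozenset("WFY"),
    "glycine": frozenset("G"),
    "proline": frozenset("P"),
}

# Fixed order used for dominant-group tie-breaking.
GROUP_ORDER = ("hydrophobic", "polar", "positive", "negative",
               "aromatic", "glycine", "proline")

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class GroupScheme:
    """A named partition (with overlaps) of the 20 amino acids."""

    groups: dict[str, frozenset] = field(
        default_factory=lambda: dict(_CANONICAL_GROUPS))

    def __post_init__(self):
        union = frozenset().union(*self.groups.values())
        if not AMINO_ACIDS <= union:
            missing = AMINO_ACIDS - union
            raise MfsError(f"group scheme does not cover {sorted(missing)}")

    def classify(self, aa: str) -> set[str]:
        aa = aa.upper()
        if aa in ("X", "-"):
            return set()
        if aa not in AMINO_ACIDS:
            raise MfsError(f"unknown residue character {aa!r}")
        return {name for name, members in self.groups.items()
                if aa in members}

    def members(self, group: str) -> frozenset:
        try:
            return self.groups[group]
        except KeyError:
            raise MfsError(f"unknown group {group!r}; known: "
                           f"{', '.join(self.groups)}") from None


DEFAULT_SCHEME = GroupScheme()

#: Canonical groups plus the size-split hydrophobics used by anchor rules.
EXTENDED_SCHEME = GroupScheme(groups={
    **_CANONICAL_GROUPS,
    "small_hydrophobic": SMALL_HYDROPHOBIC,
    "large_hydrophobic": LARGE_HYDROPHOBIC,
})


def classify_residue(aa: str, scheme: GroupScheme = DEFAULT_SCHEME
                     ) -> set[str]:
    """All chemical groups containing ``aa``; empty for 'X' and '-'."""
    return scheme.classify(aa)


@dataclass
class ConservationProfile:
    """Per-column group fractions over non-gap entries.

    ``fractions`` is indexed by 1-based alignment column; all-gap columns
    have NaN fractions and gap_fraction 1.
    """

    fractions: pd.DataFrame       # columns = group names
    gap_fraction: pd.Series
    dominant_group: pd.Series
    dominant_fraction: pd.Series
    n_sequences: int
    scheme: GroupScheme = field(default_factory=lambda: DEFAULT_SCHEME)

    @property
    def ncol(self) -> int:
        return len(self.fractions)

    def fraction(self, column: int, group: str) -> float:
        return float(self.fractions.at[column, group])

    def to_frame(self) -> pd.DataFrame:
        df = self.fractions.copy()
        df["gap_fraction"] = self.gap_fraction
        df["dominant_group"] = self.dominant_group
        df["dominant_fraction"] = self.dominant_fraction
        df.index.name = "column"
        return df


def column_conservation(msa: MSA, scheme: GroupScheme = DEFAULT_SCHEME
                        ) -> ConservationProfile:
    """Compute per-column group fractions for an aligned family."""
    if msa.nseq == 0 or msa.ncol == 0:
        raise MfsError("empty MSA")
    arr = np.array([list(s) for s in msa.sequences])
    gaps = arr == "-"
    nongap = (~gaps).sum(axis=0)
    group_names = list(scheme.groups)

    data = {}
    for name in group_names:
        members = scheme.members(name)
        counts = np.isin(arr, list(members)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            data[name] = np.where(nongap > 0, counts / np.maximum(nongap, 1),
                                  np.nan)
    cols = pd.RangeIndex(1, msa.ncol + 1, name="column")
    fractions = pd.DataFrame(data, index=cols)
    gap_fraction = pd.Series(gaps.sum(axis=0) / msa.nseq, index=cols)

    order = [g for g in GROUP_ORDER if g in group_names] + \
            [g for g in group_names if g not in GROUP_ORDER]
    ordered = fractions[order]
    # idxmax with the fixed column order implements the documented
    # tie-break (first group in GROUP_ORDER wins); all-gap columns are
    # filled before idxmax and masked afterwards.
    dominant = ordered.fillna(-1.0).idxmax(axis=1)
    dominant_frac = ordered.max(axis=1)
    dominant = dominant.where(nongap > 0, other=pd.NA)
    return ConservationProfile(fractions=fractions,
                               gap_fraction=gap_fraction,
                               dominant_group=dominant,
                               dominant_fraction=dominant_frac,
                               n_sequences=msa.nseq,
                               scheme=scheme)


def conserved_sites(profile: ConservationProfile, threshold: float = 0.7,
                    group: str | None = None
                    ) -> list[tuple[int, str, float]]:
    """Columns whose (given or dominant) group fraction ≥ threshold.

    Sorted by fraction descending, then column ascending.
    """
    if not 0 < threshold <= 1:
        raise MfsError(f"threshold must be in (0, 1], got {threshold}")
    hits = []
    for col in profile.fractions.index:
        if group is not None:
            frac = profile.fraction(col, group)
            gname = group
        else:
            gname = profile.dominant_group.at[col]
            if pd.isna(gname):
                continue
            frac = float(profile.dominant_fraction.at[col])
        if np.isfinite(frac) and frac >= threshold:
            hits.append((int(col), gname, float(frac)))
    hits.sort(key=lambda t: (-t[2], t[0]))
    return hits


# ---------------------------------------------------------------------------
# mapping MSA columns onto structure residues


@dataclass
class ColumnMapping:
    """Injective map from 1-based MSA columns to structure residues."""

    reference_id: str
    pairs: dict[int, tuple[str, int]]     # column -> (chain, residue_index)
    unmapped: list[int]
    offset: int
    identity: float

    def residue_for_column(self, column: int) -> tuple[str, int] | None:
        return self.pairs.get(column)

    def column_for_residue(self, residue_index: int,
                           chain: str | None = None) -> int | None:
        for col, (ch, idx) in self.pairs.items():
            if idx == residue_index and (chain is None or ch == chain):
                return col
        return None


def map_columns(msa: MSA, reference_id: str, entry: StructureEntry,
                min_identity: float = 0.95) -> ColumnMapping:
    """Fit a constant offset between the ungapped reference sequence of the
    MSA and the structure's author numbering, then map columns to residues.

    The reference's i-th non-gap letter (1-based ungapped position p) maps
    to author residue ``p + offset``; the offset maximizing sequence
    identity over residues present in the structure is used and must reach
    ``min_identity``.
    """
    gapped = msa.sequence(reference_id)
    ref_positions = [i + 1 for i, c in enumerate(gapped) if c != "-"]
    ref_letters = [c for c in gapped if c != "-"]
    if not ref_letters:
        raise MfsError(f"reference {reference_id} is all gaps")

    chain = entry.residues[0].chain_id
    res_letters = {r.residue_index: r.one_letter for r in entry.residues
                   if r.chain_id == chain}
    if not res_letters:
        raise MfsError("structure has no residues")

    lo = min(res_letters) - len(ref_letters)
    hi = max(res_letters)
    best = (-1.0, 0, 0)     # identity, -overlap, offset
    for offset in range(lo, hi + 1):
        matched = total = 0
        for p, letter in enumerate(ref_letters, start=1):
            struct = res_letters.get(p + offset)
            if struct is None:
                continue
            total += 1
            if struct == letter or struct == "X" or letter == "X":
                matched += 1
        if total == 0:
            continue
        ident = matched / total
        if (ident, total) > (best[0], best[1]):
            best = (ident, total, offset)
    identity, overlap, offset = best
    if identity < min_identity:
        raise MfsError(
            f"no constant offset reaches {min_identity:.0%} identity between "
            f"{reference_id} and {entry.entry_id}; best offset {offset} "
            f"gives {identity:.1%} over {overlap} residues")

    pairs: dict[int, tuple[str, int]] = {}
    unmapped: list[int] = []
    ungapped = 0
    for col in range(1, msa.ncol + 1):
        if gapped[col - 1] == "-":
            unmapped.append(col)
            continue
        ungapped += 1
        idx = ungapped + offset
        if idx in res_letters:
            pairs[col] = (chain, idx)
        else:
            unmapped.append(col)
    return ColumnMapping(reference_id=reference_id, pairs=pairs,
                         unmapped=unmapped, offset=offset, identity=identity)
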
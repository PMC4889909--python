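"""Shared fixtures: random idealized bundles and an independent
brute-force contact oracle (plain all-pairs distance scan, no spatial
indexing) used to validate the production contact detector."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from mfsnum.structure_io import StructureEntry
from mfsnum.synthetic import BundleSpec, HelixPlacement, build_bundle

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_contacts(entry: StructureEntry, cutoff: float = 7.0
                         ) -> dict[tuple[int, int, int],
                                   tuple[float, int]]:
    """All-pairs oracle: for every donor residue and acceptor helix,
    the minimum over every (side-chain atom, backbone atom) pair.

    Returns {(helix_a, res_a, helix_b): (min_distance, res_b)}.
    Deliberately independent of the production path: no KD-tree, no
    per-helix pre-collection, just exhaustive Euclidean distances.
    """
    out = {}
    for span_a in entry.spans:
        for span_b in entry.spans:
            if span_a.helix_id == span_b.helix_id:
                continue
            acceptor = []
            for res_b in entry.span_residues(span_b.helix_id):
                for atom in res_b.atoms:
                    if atom.name in ("N", "CA", "C", "O"):
                        acceptor.append((atom.position, res_b.residue_index))
            if not acceptor:
                continue
            for res_a in entry.span_residues(span_a.helix_id):
                donor = [a.position for a in res_a.atoms
                         if a.name not in ("N", "CA", "C", "O")]
                if not donor and res_a.one_letter == "G":
                    ca = res_a.atom("CA")
                    donor = [ca.position] if ca is not None else []
                if not donor:
                    continue
                best = (np.inf, None)
                for d in donor:
                    for pos, idx in acceptor:
                        dist = float(np.sqrt(((d - pos) ** 2).sum()))
                        if dist < best[0]:
                            best = (dist, idx)
                if best[0] <= cutoff:
                    out[(span_a.helix_id, res_a.residue_index,
                         span_b.helix_id)] = best
    return out


def contact_map_as_dict(cmap) -> dict[tuple[int, int, int],
                                      tuple[float, int]]:
    return {(r.helix_a, r.res_a, r.helix_b): (r.min_distance, r.res_b)
            for r in cmap.records}


def random_bundle(rng: np.random.Generator,
                  max_helices: int = 5) -> StructureEntry:
    """A random non-overlapping bundle with mixed sequences and tilts."""
    for _ in range(50):
        n = int(rng.integers(2, max_helices + 1))
        origins = []
        while len(origins) < n:
            cand = rng.uniform(0, 40, size=2)
            if all(np.linalg.norm(cand - o) >= 8.0 for o in origins):
                origins.append(cand)
        helices = []
        for i in range(n):
            length = int(rng.integers(8, 21))
            seq = "".join(rng.choice(list(AA20), size=length))
            helices.append(HelixPlacement(
                sequence=seq, origin=tuple(origins[i]),
                tilt=float(rng.uniform(0, 10)),
                azimuth=float(rng.uniform(0, 360)),
                phase=float(rng.uniform(0, 360)),
                direction=str(rng.choice(["up", "down"]))))
        try:
            return build_bundle(BundleSpec(helices=tuple(helices)),
                                seed=int(rng.integers(2 ** 31)))
        except Exception:
            continue
    raise RuntimeError("could not sample a non-overlapping bundle")


@pytest.fixture
def two_helix_entry() -> StructureEntry:
    """Two parallel 18-residue helices, 9 Å apart, antiparallel topology."""
    spec = BundleSpec(helices=(
        HelixPlacement("GAVLSTGNQ" * 2),
        HelixPlacement("L" * 18, origin=(9.0, 0.0), direction="down")))
    return build_bundle(spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160602)
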
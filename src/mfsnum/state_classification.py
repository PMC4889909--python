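"""Helix axis/tilt geometry and static / pivot / mobile classification of
helix-pair contacts across conformational states.

A contact that keeps the same donor residue and the same helix tilts in
every state is *static*; one that keeps its residue while the helices
re-tilt around it is a *pivot point*; one whose residue position depends on
the state (or which disappears in some state) is *mobile*. Structures must
be membrane-aligned: the membrane normal is +z with the extracellular side
positive (the OPM convention); no internal membrane fitting is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contacts import ContactMap
from .structure_io import MfsError, StructureEntry

__all__ = [
    "HelixGeometry",
    "StateObservation",
    "ContactTrajectory",
    "ContactClassification",
    "helix_geometry",
    "match_contacts",
    "classify_contact",
]


@dataclass(frozen=True)
class HelixGeometry:
    """Principal axis of a helix, oriented cytoplasmic -> extracellular."""

    helix_id: int
    axis: np.ndarray        # unit 3-vector
    centroid: np.ndarray    # Å
    tilt: float             # degrees from the membrane normal (+z)


def _fit_axis(coords: np.ndarray) -> np.ndarray:
    """Helix axis direction from CA coordinates.

    The principal component of short helices is biased toward the spiral
    (a non-integer number of turns breaks the radial symmetry), so the
    PCA axis only seeds a cylinder fit: on an ideal helix every CA is
    equidistant from the true axis, hence the axis minimizing the spread
    of radial distances is exact at any helix length.
    """
    from scipy.optimize import least_squares

    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    a0 = vt[0]

    def residuals(params):
        v = params[:3]
        norm = np.linalg.norm(v)
        if norm < 1e-12:
            return np.full(coords.shape[0] + 2, 1e6)
        vh = v / norm
        rel = coords - params[3:]
        radial = rel - np.outer(rel @ vh, vh)
        r = np.linalg.norm(radial, axis=1)
        # two gauge-fixing residuals (unit direction, point closest to the
        # centroid) keep the 6-parameter fit determined for short helices
        return np.concatenate([r - r.mean(),
                               [norm - 1.0,
                                float((params[3:] - centroid) @ vh)]])

    fit = least_squares(residuals, x0=np.concatenate([a0, centroid]),
                        method="lm", max_nfev=200)
    axis = fit.x[:3]
    return axis / np.linalg.norm(axis)


def helix_geometry(entry: StructureEntry, helix_id: int) -> HelixGeometry:
    """Fit the helix axis through the CA trace (cylinder fit seeded by the
    principal component).

    The sign is fixed so the axis points from the cytoplasmic to the
    extracellular end of the span (using the span's topological polarity);
    tilt is the angle between the axis and +z.
    """
    residues = entry.span_residues(helix_id)
    cas = [r.atom("CA") for r in residues]
    coords = np.array([a.position for a in cas if a is not None])
    if coords.shape[0] < 4:
        raise MfsError(f"{entry.entry_id}: helix {helix_id} has "
                       f"{coords.shape[0]} CA atoms, need >= 4")
    centroid = coords.mean(axis=0)
    axis = _fit_axis(coords)

    span = entry.span(helix_id)
    seq_direction = coords[-1] - coords[0]   # N-terminal -> C-terminal end
    if span.n_terminal_side == "cytoplasmic":
        wanted = seq_direction                # C-term end is extracellular
    else:
        wanted = -seq_direction
    if float(np.dot(axis, wanted)) < 0:
        axis = -axis
    tilt = float(np.degrees(np.arccos(np.clip(axis[2], -1.0, 1.0))))
    return HelixGeometry(helix_id=helix_id, axis=axis, centroid=centroid,
                         tilt=tilt)


@dataclass(frozen=True)
class StateObservation:
    state: str
    donor_residue: int | None      # None when the pair is absent
    acceptor_residue: int | None
    min_distance: float | None
    tilt_a: float
    tilt_b: float

    @property
    def absent(self) -> bool:
        return self.donor_residue is None


@dataclass
class ContactTrajectory:
    """One helix pair followed across >= 2 conformational states.

    The pair is directional: donor residues live on ``pair[0]``, so donor
    indices are comparable across states of the same protein. Cross-protein
    trajectories must first be expressed in generic numbering.
    """

    pair: tuple[int, int]
    observations: list[StateObservation]

    def __post_init__(self):
        if len(self.observations) < 2:
            raise MfsError("a contact trajectory needs >= 2 states")

    @property
    def any_absent(self) -> bool:
        return any(o.absent for o in self.observations)

    @property
    def positional_spread(self) -> int:
        idx = [o.donor_residue for o in self.observations if not o.absent]
        if len(idx) < 2:
            return 0
        return max(idx) - min(idx)

    @property
    def tilt_range(self) -> float:
        ta = [o.tilt_a for o in self.observations]
        tb = [o.tilt_b for o in self.observations]
        return max(max(ta) - min(ta), max(tb) - min(tb))


def match_contacts(state_maps: list[tuple[StructureEntry, ContactMap]],
                   pair: tuple[int, int]) -> ContactTrajectory:
    """Follow one helix pair across state-labelled structures.

    Per state the minimal-distance record with donor helix ``pair[0]`` and
    acceptor helix ``pair[1]`` is selected; a state with no record for the
    pair is marked absent (itself evidence of mobility).
    """
    if len(state_maps) < 2:
        raise MfsError("need >= 2 state-labelled structures")
    a, b = pair
    observations = []
    for entry, cmap in state_maps:
        if entry.state == "unknown":
            raise MfsError(f"{entry.entry_id} lacks a state label")
        tilt_a = helix_geometry(entry, a).tilt
        tilt_b = helix_geometry(entry, b).tilt
        recs = cmap.for_pair(a, b, directional=True)
        if recs:
            best = min(recs, key=lambda r: r.min_distance)
            obs = StateObservation(state=entry.state,
                                   donor_residue=best.res_a,
                                   acceptor_residue=best.res_b,
                                   min_distance=best.min_distance,
                                   tilt_a=tilt_a, tilt_b=tilt_b)
        else:
            obs = StateObservation(state=entry.state, donor_residue=None,
                                   acceptor_residue=None, min_distance=None,
                                   tilt_a=tilt_a, tilt_b=tilt_b)
        observations.append(obs)
    return ContactTrajectory(pair=pair, observations=observations)


@dataclass(frozen=True)
class ContactClassification:
    pair: tuple[int, int]
    contact_class: str            # static | pivot | mobile
    evidence: ContactTrajectory = field(compare=False)


def classify_contact(trajectory: ContactTrajectory,
                     spread_tol: int = 1,
                     tilt_tol: float = 10.0) -> ContactClassification:
    """Classify a trajectory by its positional spread and tilt range.

    spread <= spread_tol and tilt range <= tilt_tol -> static;
    spread <= spread_tol with a larger tilt range -> pivot;
    spread > spread_tol, or the contact absent in any state -> mobile.
    A pure function of the trajectory: same input, same class.
    """
    if trajectory.any_absent or trajectory.positional_spread > spread_tol:
        cls = "mobile"
    elif trajectory.tilt_range > tilt_tol:
        cls = "pivot"
    else:
        cls = "static"
    return ContactClassification(pair=trajectory.pair, contact_class=cls,
                                 evidence=trajectory)
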
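"""Active-site geometric descriptors, state classification, and ion release.

The group II intron active site can be monitored through a handful of named
scalar descriptors: heavy-atom distances between junction/triad residues and
catalytic ions (d_289-358, d_K1-N7G288, d_M1-M2, d_M2-O6, d_SP-M2, d_U2-A287)
and the angle alpha between the least-squares nucleobase planes of the first
catalytic-triad residue and its Watson-Crick partner (residues 358/385 in the
Oceanobacillus iheyensis numbering). A frame is in the catalytically competent
triple-helix configuration when d_289-358 <= 3 A *and* alpha <= 0.35 rad
(both bounds inclusive); otherwise the triple helix is disrupted (toggled).

Ion-release events (the spontaneous departure of the K1 potassium from the
active site) are detected on a distance series with a bound/released
double-cutoff plus a dwell time, so that transient excursions do not count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import (
    ConsistencyError,
    DescriptorError,
    ParameterError,
    SelectionError,
    SummaryError,
)
from .structio import AtomIndexSet, Structure, Trajectory, select_atoms

#: ring-atom names used for base-plane fits
PURINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")

#: classification thresholds for the triple-helix configuration
D_MAX_DEFAULT = 3.0  # A, d_289-358
ALPHA_MAX_DEFAULT = 0.35  # rad

#: package-default ion release detection parameters (not literature values)
BOUND_CUTOFF_DEFAULT = 3.5  # A
RELEASED_CUTOFF_DEFAULT = 6.0  # A
DWELL_DEFAULT = 1.0  # ns

DISCARD_DEFAULT = 25.0  # ns of equilibration discarded before statistics


class State(str, Enum):
    TRIPLE_HELIX = "TRIPLE_HELIX"
    DISRUPTED = "DISRUPTED"


@dataclass
class DescriptorSeries:
    """A named per-frame scalar series with units ('A', 'rad', or 'count')."""

    name: str
    times: np.ndarray
    values: np.ndarray
    units: str = "A"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ConsistencyError(
                f"series {self.name!r}: times and values must be equal-length 1-D"
            )
        if not np.all(np.isfinite(self.values)):
            raise ConsistencyError(f"series {self.name!r}: non-finite values")
        if self.units not in ("A", "rad", "count"):
            raise ParameterError(f"unknown units {self.units!r}")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class StateSeries:
    """Per-frame triple-helix / disrupted labels and the thresholds used."""

    times: np.ndarray
    labels: list[State]
    d_max: float = D_MAX_DEFAULT
    alpha_max: float = ALPHA_MAX_DEFAULT

    def fraction(self, state: State) -> float:
        return sum(lab == state for lab in self.labels) / len(self.labels)


@dataclass(frozen=True)
class ReleaseEvent:
    """A sustained departure of an ion beyond the released cutoff."""

    ion: str
    release_time: float  # ns
    bound_cutoff: float
    released_cutoff: float
    dwell: float


@dataclass(frozen=True)
class SeriesSummary:
    """Mean and sample s.d. after discarding the equilibration segment."""

    name: str
    mean: float
    sd: float
    n_frames: int
    discard: float


# ---------------------------------------------------------------------------


@dataclass
class DescriptorCatalog:
    """Mapping from descriptor names to selector-based definitions.

    Distance entries are pairs of single-atom selectors; plane-angle entries
    are residue-number pairs. Catalytic ion roles (K1, M1, M2) cannot be read
    off deposited coordinate files, so the caller supplies them as selector
    strings (typically ``"serial <n>"``); :func:`suggest_ion_roles` offers
    proximity-based candidates, which are advisory only.
    """

    distances: dict[str, tuple[str, str]] = field(default_factory=dict)
    plane_angles: dict[str, tuple[int, int]] = field(default_factory=dict)
    ion_roles: dict[str, str] = field(default_factory=dict)

    @classmethod
    def default(cls, ion_roles: dict[str, str] | None = None) -> "DescriptorCatalog":
        """The wild-type O. iheyensis catalog (4FAQ residue numbering).

        Mutant constructs replace residues 289/358/385 and lack O2/N4 at the
        same positions; for those, edit the distance entries to the closest
        Watson-Crick-face donor-acceptor pair of the construct.
        """
        roles = dict(ion_roles or {})
        cat = cls(
            distances={
                "d_289-358": ("resnum 289 and name O2", "resnum 358 and name N4"),
                "d_U2-A287": ("resnum 2 and name N3", "resnum 287 and name N1"),
            },
            plane_angles={"alpha": (358, 385)},
            ion_roles=roles,
        )
        if "K1" in roles:
            cat.distances["d_K1-N7G288"] = (roles["K1"], "resnum 288 and name N7")
        if "M1" in roles and "M2" in roles:
            cat.distances["d_M1-M2"] = (roles["M1"], roles["M2"])
        if "M2" in roles:
            cat.distances["d_M2-O6"] = (roles["M2"], "resnum 288 and name O6")
            cat.distances["d_SP-M2"] = ("resnum 1 and name P", roles["M2"])
        return cat

    def resolve(self, structure: Structure) -> None:
        """Check every entry resolves to existing atoms; raise otherwise."""
        for dname, (sel_a, sel_b) in self.distances.items():
            for sel in (sel_a, sel_b):
                if len(select_atoms(structure, sel)) != 1:
                    raise SelectionError(
                        f"catalog entry {dname!r}: selector {sel!r} does not "
                        "resolve to exactly one atom"
                    )
        for aname, (ra, rb) in self.plane_angles.items():
            for res in (ra, rb):
                _ring_indices(structure, res)  # raises DescriptorError if absent


def suggest_ion_roles(structure: Structure) -> dict[str, str]:
    """Advisory K1/M1/M2 candidates by proximity.

    K1: potassium closest to O5' of residue 359; M1/M2: the two magnesiums
    closest to the catalytic-triad phosphates (P of residues 358-360). Returns
    ``serial <n>`` selectors. Roles in deposited structures are a modelling
    judgement; always verify before analysis.
    """
    coords = structure.coords
    out: dict[str, str] = {}
    ref = select_atoms(structure, "resnum 359 and name O5'")
    potassiums = select_atoms(structure, "element K")
    if len(ref) == 1 and len(potassiums) >= 1:
        refpos = coords[ref.sole()]
        dists = [np.linalg.norm(coords[i] - refpos) for i in potassiums.indices]
        k1 = potassiums.indices[int(np.argmin(dists))]
        out["K1"] = f"serial {structure.atoms[k1].serial}"
    triad_p = select_atoms(structure, "resnum 358-360 and name P")
    magnesiums = select_atoms(structure, "element MG")
    if len(triad_p) >= 1 and len(magnesiums) >= 2:
        pcoords = coords[list(triad_p.indices)]
        dmin = [min(np.linalg.norm(coords[i] - p) for p in pcoords)
                for i in magnesiums.indices]
        order = np.argsort(dmin)
        m1 = magnesiums.indices[int(order[0])]
        m2 = magnesiums.indices[int(order[1])]
        out["M1"] = f"serial {structure.atoms[m1].serial}"
        out["M2"] = f"serial {structure.atoms[m2].serial}"
    return out


# ---------------------------------------------------------------------------
# Descriptor operations


def pair_distance(traj: Trajectory, a: AtomIndexSet, b: AtomIndexSet,
                  name: str = "distance") -> DescriptorSeries:
    """Euclidean distance between two single atoms, per frame, in angstroms."""
    ia, ib = a.sole(), b.sole()
    delta = traj.frames[:, ia, :] - traj.frames[:, ib, :]
    return DescriptorSeries(name, traj.times, np.linalg.norm(delta, axis=1), "A")


def _ring_indices(structure: Structure, residue_number: int,
                  chain_id: str | None = None) -> list[int]:
    atoms = [
        (i, a) for i, a in enumerate(structure.atoms)
        if a.residue_number == residue_number
        and (chain_id is None or a.chain_id == chain_id)
    ]
    if not atoms:
        raise DescriptorError(f"residue {residue_number} not found")
    names = {a.name.upper(): i for i, a in atoms}
    ring = PURINE_RING if "N9" in names else PYRIMIDINE_RING
    missing = [nm for nm in ring if nm not in names]
    if missing:
        raise DescriptorError(
            f"residue {residue_number}: missing ring atom(s) {', '.join(missing)}"
        )
    return [names[nm] for nm in ring]


def _plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane: smallest-variance principal axis."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[-1]


def base_plane_angle(traj: Trajectory, res_a: int, res_b: int,
                     chain_id: str | None = None,
                     name: str = "alpha") -> DescriptorSeries:
    """Angle between the nucleobase planes of two residues, per frame.

    Each plane is the least-squares plane through the residue's full ring-atom
    set (purine 9 atoms, pyrimidine 6). The angle is folded to [0, pi/2] via
    arccos(|n_a . n_b|), so it does not depend on normal orientation.
    """
    idx_a = _ring_indices(traj.topology, res_a, chain_id)
    idx_b = _ring_indices(traj.topology, res_b, chain_id)
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        na = _plane_normal(traj.frames[f, idx_a, :])
        nb = _plane_normal(traj.frames[f, idx_b, :])
        values[f] = np.arccos(np.clip(abs(float(na @ nb)), 0.0, 1.0))
    return DescriptorSeries(name, traj.times, values, "rad")


def classify_triple_helix(
    d: DescriptorSeries,
    alpha: DescriptorSeries,
    d_max: float = D_MAX_DEFAULT,
    alpha_max: float = ALPHA_MAX_DEFAULT,
) -> StateSeries:
    """Label frames TRIPLE_HELIX iff d <= d_max and alpha <= alpha_max.

    Both thresholds are inclusive: a frame sitting exactly on a boundary is
    still triple-helical.
    """
    if d.times.shape != alpha.times.shape or not np.allclose(d.times, alpha.times):
        raise ConsistencyError("distance and angle series must share time stamps")
    if d_max <= 0 or alpha_max <= 0:
        raise ParameterError("thresholds must be positive")
    helical = (d.values <= d_max) & (alpha.values <= alpha_max)
    labels = [State.TRIPLE_HELIX if h else State.DISRUPTED for h in helical]
    return StateSeries(d.times, labels, d_max, alpha_max)


def detect_ion_release(
    d: DescriptorSeries,
    bound_cutoff: float = BOUND_CUTOFF_DEFAULT,
    released_cutoff: float = RELEASED_CUTOFF_DEFAULT,
    dwell: float = DWELL_DEFAULT,
    ion: str = "K1",
) -> list[ReleaseEvent]:
    """Detect sustained ion departures on a distance series.

    A release is emitted at the first time t where d > released_cutoff and d
    stays above released_cutoff for the whole [t, t + dwell] window; the ion
    must have been bound (d < bound_cutoff) at some earlier time. After an
    event, re-binding (d < bound_cutoff) re-arms the detector, so repeated
    binding/release cycles yield one event each.
    """
    if released_cutoff <= bound_cutoff:
        raise ParameterError("released_cutoff must exceed bound_cutoff")
    if len(d) < 2:
        raise ParameterError("series must contain at least 2 frames")
    span = d.times[-1] - d.times[0]
    if dwell > span:
        raise ParameterError(
            f"dwell {dwell} ns exceeds the series span {span} ns"
        )
    events: list[ReleaseEvent] = []
    armed = False  # bound has been observed since the last event
    i = 0
    n = len(d)
    while i < n:
        if not armed:
            if d.values[i] < bound_cutoff:
                armed = True
            i += 1
            continue
        if d.values[i] > released_cutoff:
            t0 = d.times[i]
            j = i
            while j < n and d.values[j] > released_cutoff:
                j += 1
            window_end = d.times[j - 1]
            # window must be confirmed over the full dwell; an excursion that
            # runs to the end of the series counts only if it spans >= dwell
            if window_end - t0 >= dwell:
                events.append(ReleaseEvent(ion, float(t0), bound_cutoff,
                                           released_cutoff, dwell))
                armed = False
                i = j
                continue
            i = j
        else:
            i += 1
    return events


def summarize(series: DescriptorSeries, discard: float = DISCARD_DEFAULT) -> SeriesSummary:
    """Arithmetic mean and sample s.d. of values at times >= ``discard`` ns.

    The default 25 ns discard mirrors the equilibration segment excluded from
    all trajectory statistics.
    """
    keep = series.times >= discard
    n = int(keep.sum())
    if n < 2:
        raise SummaryError(
            f"series {series.name!r}: only {n} frame(s) remain after discarding "
            f"the first {discard} ns"
        )
    vals = series.values[keep]
    return SeriesSummary(series.name, float(vals.mean()), float(vals.std(ddof=1)),
                         n, discard)


def coordination_count(
    traj: Trajectory,
    ion: AtomIndexSet,
    cutoff: float = 3.5,
    exclude_water: bool = False,
) -> DescriptorSeries:
    """Heavy-atom coordination number of a single ion, per frame.

    Counts non-hydrogen atoms (other than the ion itself) within ``cutoff``
    angstroms; water oxygens are excluded when ``exclude_water`` is set
    (residue names HOH/WAT/TIP3).
    """
    iion = ion.sole()
    water = {"HOH", "WAT", "TIP3", "SOL"}
    keep = np.array([
        (i != iion)
        and not a.is_hydrogen
        and not (exclude_water and a.residue_name.upper() in water)
        for i, a in enumerate(traj.topology.atoms)
    ])
    others = traj.frames[:, keep, :]
    dist = np.linalg.norm(others - traj.frames[:, iion, None, :], axis=2)
    counts = (dist <= cutoff).sum(axis=1).astype(float)
    return DescriptorSeries("coordination", traj.times, counts, "count")
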
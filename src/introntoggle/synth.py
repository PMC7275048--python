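"""Synthetic inputs with the statistical structure the analyses assume.

Every analysis module in this package can be exercised without any external
download through four generators:

* :func:`active_site_structure` builds an idealized two-base-pair + junction
  fragment (synthetic stand-in coordinates, not deposited ones) whose
  descriptors hit caller-chosen targets exactly at zero noise;
* :func:`gen_toggling_series` simulates two-state (triple-helix <-> toggled)
  conformational dynamics as a continuous-time Markov chain with Gaussian
  per-state emissions for (d_289-358, alpha, d_K1-N7), the K1 distance
  switching to its released level at the first toggling event;
* :func:`gen_band_timecourse` produces noisy replicate-averaged splicing band
  fractions from known rate constants;
* :func:`gen_toy_landscape` returns analytic 2-D potentials ("double-well",
  "three-state") with documented minima and saddle values for validating the
  metadynamics machinery.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .descriptors import ALPHA_MAX_DEFAULT, D_MAX_DEFAULT
from .errors import ConstructionError, ParameterError
from .kinetics import KineticDataset, sequential_model
from .structio import Atom, Structure

# ---------------------------------------------------------------------------
# Idealized active-site fragment


def _hexagon(bond: float = 1.39) -> dict[str, np.ndarray]:
    """Planar six-membered ring N1,C2,N3,C4,C5,C6 (z = 0), bond length ~1.39 A."""
    names = ("N1", "C2", "N3", "C4", "C5", "C6")
    out = {}
    for k, nm in enumerate(names):
        ang = np.deg2rad(60.0 * k)
        out[nm] = bond * np.array([np.cos(ang), np.sin(ang), 0.0])
    return out


def _cytosine_template() -> dict[str, np.ndarray]:
    ring = _hexagon()
    out = dict(ring)
    out["O2"] = ring["C2"] + 1.24 * ring["C2"] / np.linalg.norm(ring["C2"])
    out["N4"] = ring["C4"] + 1.34 * ring["C4"] / np.linalg.norm(ring["C4"])
    return out


def _guanine_template() -> dict[str, np.ndarray]:
    """Purine: hexagon plus a regular pentagon fused on the C4-C5 edge."""
    ring = _hexagon()
    out = dict(ring)
    c4, c5 = ring["C4"], ring["C5"]
    mid = (c4 + c5) / 2
    u = mid / np.linalg.norm(mid)  # outward from the hexagon center
    side = np.linalg.norm(c5 - c4)
    apothem = side / (2 * np.tan(np.pi / 5))
    center5 = mid + apothem * u
    # pentagon vertices by rotating C4 about center5; choose the rotation sense
    # that walks away from C5
    def rotz(p: np.ndarray, ang: float) -> np.ndarray:
        c, s = np.cos(ang), np.sin(ang)
        return np.array([c * p[0] - s * p[1], s * p[0] + c * p[1], p[2]])

    step = 2 * np.pi / 5
    rel4 = c4 - center5
    cand = center5 + rotz(rel4, step)
    if np.linalg.norm(cand - c5) < 1e-6:  # wrong sense
        step = -step
        cand = center5 + rotz(rel4, step)
    out["N9"] = cand
    out["C8"] = center5 + rotz(rel4, 2 * step)
    out["N7"] = center5 + rotz(rel4, 3 * step)
    out["O6"] = ring["C6"] + 1.23 * ring["C6"] / np.linalg.norm(ring["C6"])
    return out


def _rot_x(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def active_site_structure(
    target_d: float = 2.70,
    target_alpha: float = 0.17,
    noise_sd: float = 0.0,
    seed: int | None = None,
    d_k1_n7: float = 2.98,
    d_m1_m2: float = 4.24,
    d_m2_o6: float = 4.75,
    d_sp_m2: float = 3.23,
) -> Structure:
    """Synthetic stand-in active-site fragment hitting descriptor targets.

    The fragment contains idealized residues C289 (with O2), C358 (full
    pyrimidine ring, O2, N4), G385 and G288 (full purine rings, O6, N7), a
    G359 O5' anchor, the scissile phosphate (residue 1, atom P), and ions
    K1 (potassium, serial role assigned by the caller), M1 and M2 (magnesium).
    With ``noise_sd == 0``, d_289-358 == target_d, alpha(358, 385) ==
    target_alpha, d_K1-N7G288 == d_k1_n7 etc. hold exactly; Gaussian
    coordinate noise of s.d. ``noise_sd`` perturbs each descriptor by at most
    a few noise s.d.

    These are constructed coordinates for testing the descriptor machinery;
    they are not deposited crystal structures.
    """
    if target_d <= 0:
        raise ConstructionError("target_d must be positive")
    if not 0.0 <= target_alpha <= np.pi / 2:
        raise ConstructionError("target_alpha must lie in [0, pi/2]")
    cyt = _cytosine_template()
    gua = _guanine_template()

    atoms: list[Atom] = []
    serial = [0]

    def add(name: str, resname: str, resnum: int, element: str,
            pos: np.ndarray) -> None:
        serial[0] += 1
        atoms.append(Atom(serial[0], name, resname, resnum, "A", element,
                          np.asarray(pos, dtype=float)))

    def add_residue(template: dict[str, np.ndarray], resname: str, resnum: int,
                    rot: np.ndarray | None = None,
                    shift: np.ndarray = np.zeros(3)) -> dict[str, np.ndarray]:
        placed = {}
        for nm, p in template.items():
            q = (rot @ p if rot is not None else p) + shift
            placed[nm] = q
            add(nm, resname, resnum, nm[0], q)
        return placed

    # C358 in the z = 0 plane at the origin (plane normal = z)
    placed_358 = add_residue(cyt, "C", 358)
    # G385 rotated about x by target_alpha, well separated in x
    add_residue(gua, "G", 385, rot=_rot_x(target_alpha),
                shift=np.array([8.0, 0.0, 0.0]))
    # C289 parallel ring, translated so its O2 sits exactly target_d above N4(358)
    o2_target = placed_358["N4"] + np.array([0.0, 0.0, target_d])
    placed_289 = add_residue(cyt, "C", 289, shift=o2_target - cyt["O2"])
    # A287 minimal Watson-Crick-face atom (for the d_U2-A287 machinery)
    add("N1", "A", 287, "N", placed_289["N1"] + np.array([0.0, 4.0, 2.0]))
    add("N3", "U", 2, "N", placed_289["N1"] + np.array([0.0, 4.0, 4.13]))
    # G288 guanine off to the side; K1 sits d_k1_n7 from its N7
    placed_288 = add_residue(gua, "G", 288, shift=np.array([0.0, -9.0, 2.0]))
    k1_pos = placed_288["N7"] + np.array([0.0, 0.0, d_k1_n7])
    # G359 O5' anchor near K1 (used by the ion-role suggester)
    add("O5'", "G", 359, "O", k1_pos + np.array([2.8, 0.0, 0.0]))
    # metal cluster: M2 relative to O6(288); M1 and the scissile P around it
    m2_pos = placed_288["O6"] + np.array([d_m2_o6, 0.0, 0.0])
    m1_pos = m2_pos + np.array([0.0, d_m1_m2, 0.0])
    add("P", "G", 1, "P", m2_pos + np.array([0.0, 0.0, d_sp_m2]))
    # backbone phosphate of the first triad residue, between the magnesiums
    # (anchors the advisory M1/M2 role suggestion)
    add("P", "C", 358, "P", (m1_pos + m2_pos) / 2 + np.array([1.5, 0.0, 0.0]))
    add("K", "K", 1001, "K", k1_pos)
    add("MG", "MG", 1002, "MG", m1_pos)
    add("MG", "MG", 1003, "MG", m2_pos)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        atoms = [
            Atom(a.serial, a.name, a.residue_name, a.residue_number, a.chain_id,
                 a.element, a.position + rng.normal(0.0, noise_sd, 3))
            for a in atoms
        ]
    return Structure(atoms)


# backwards-compatible alias used in docs
gen_active_site_frame = active_site_structure


# ---------------------------------------------------------------------------
# Two-state toggling dynamics


@dataclass
class TogglingParams:
    """Study conditions for the two-state toggling generator.

    Rates are in ns^-1; the default unfolding rate (1/50 ns^-1) reflects the
    tens-of-nanoseconds toggling onset seen after the first splicing step in
    the protonated simulations, and the slow reverse rate keeps the toggled
    ensemble dominant once K1 is gone. Emission means mirror the trajectory
    values for the two conformations (triple helix: d = 2.7 A, alpha = 0.17
    rad, K1 bound at 2.98 A; toggled: d = 4.88 A, alpha = 0.63 rad, K1
    released to ~8 A); emission s.d.s default to a quarter of each mean's
    margin to its classification threshold, i.e. the 4-sigma-separated regime
    in which per-frame labels are recoverable.
    """

    rate_to_toggled: float = 1.0 / 50.0  # ns^-1
    rate_to_helix: float = 1.0 / 500.0  # ns^-1
    mean_helix: tuple[float, float, float] = (2.70, 0.17, 2.98)  # d, alpha, d_K1
    sd_helix: tuple[float, float, float] = (0.075, 0.045, 0.10)
    mean_toggled: tuple[float, float, float] = (4.88, 0.63, 8.00)
    sd_toggled: tuple[float, float, float] = (0.47, 0.07, 0.40)
    frame_interval: float = 0.1  # ns
    n_frames: int = 6000
    seed: int = 0
    reversible_k1: bool = False

    def __post_init__(self) -> None:
        if self.rate_to_toggled <= 0 or self.rate_to_helix <= 0:
            raise ParameterError("transition rates must be positive")
        if min(self.sd_helix) < 0 or min(self.sd_toggled) < 0:
            raise ParameterError("emission s.d.s must be non-negative")
        if not (self.mean_helix[0] <= D_MAX_DEFAULT
                and self.mean_helix[1] <= ALPHA_MAX_DEFAULT):
            raise ParameterError("triple-helix emission means must satisfy the "
                                 "classifier thresholds")
        if not (self.mean_toggled[0] > D_MAX_DEFAULT
                or self.mean_toggled[1] > ALPHA_MAX_DEFAULT):
            raise ParameterError("toggled emission means must violate the "
                                 "classifier thresholds")

    @property
    def stationary_helix_occupancy(self) -> float:
        """Stationary probability of the triple-helix state, k21/(k12+k21)."""
        return self.rate_to_helix / (self.rate_to_toggled + self.rate_to_helix)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth emitted alongside generated series."""

    states: np.ndarray  # 0 = triple helix, 1 = toggled, per frame
    release_time: float | None  # ns, first toggling event (None if never)
    params: TogglingParams


def gen_toggling_series(params: TogglingParams):
    """Simulate the two-state chain and emit three aligned descriptor series.

    Returns ``(d_series, alpha_series, k1_series, truth)`` where the three
    series share the time axis. The chain starts in the triple-helix state;
    state switches are sampled per frame from the exact exponential transition
    probabilities. The K1 distance emits at its bound level until the first
    entry into the toggled state, and at its released level afterwards
    (one-way by default; ``reversible_k1`` re-binds it whenever the chain is
    back in the triple helix).
    """
    from .descriptors import DescriptorSeries  # local import to avoid cycle

    p = params
    rng = np.random.default_rng(p.seed)
    dt = p.frame_interval
    n = p.n_frames
    p_01 = -np.expm1(-p.rate_to_toggled * dt)  # P(helix -> toggled per frame)
    p_10 = -np.expm1(-p.rate_to_helix * dt)
    states = np.empty(n, dtype=int)
    state = 0
    u = rng.random(n)
    for i in range(n):
        states[i] = state
        if state == 0 and u[i] < p_01:
            state = 1
        elif state == 1 and u[i] < p_10:
            state = 0
    times = np.arange(n) * dt
    toggled_idx = np.nonzero(states == 1)[0]
    release_time = float(times[toggled_idx[0]]) if len(toggled_idx) else None

    noise = rng.standard_normal((n, 3))
    mean = np.where(states[:, None] == 0, p.mean_helix, p.mean_toggled)
    sd = np.where(states[:, None] == 0, p.sd_helix, p.sd_toggled)
    emitted = mean + sd * noise
    # K1 channel is tied to the release event, not to the instantaneous state
    if release_time is not None and not p.reversible_k1:
        released = times >= release_time
        k1_mean = np.where(released, p.mean_toggled[2], p.mean_helix[2])
        k1_sd = np.where(released, p.sd_toggled[2], p.sd_helix[2])
        emitted[:, 2] = k1_mean + k1_sd * noise[:, 2]
    emitted[:, 0] = np.maximum(emitted[:, 0], 0.0)
    emitted[:, 1] = np.clip(emitted[:, 1], 0.0, np.pi / 2)
    emitted[:, 2] = np.maximum(emitted[:, 2], 0.0)

    d = DescriptorSeries("d_289-358", times, emitted[:, 0], "A")
    alpha = DescriptorSeries("alpha", times, emitted[:, 1], "rad")
    k1 = DescriptorSeries("d_K1-N7G288", times, emitted[:, 2], "A")
    return d, alpha, k1, SyntheticTruth(states, release_time, p)


# ---------------------------------------------------------------------------
# Band-fraction time courses


DEFAULT_TIMES_MIN = np.array(
    [0.0, 5.0, 10.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0, 150.0, 180.0, 240.0]
)


def gen_band_timecourse(
    k1: float = 0.031,
    k2: float = 0.026,
    times: np.ndarray | None = None,
    noise_sd: float = 0.02,
    n_replicates: int = 3,
    seed: int = 0,
) -> KineticDataset:
    """Replicate-averaged noisy splicing band fractions from known rates.

    Each replicate adds truncated (clipped at 0) Gaussian noise of s.d.
    ``noise_sd`` to the closed-form fractions and renormalizes each time point
    to sum to 1; the dataset holds the replicate mean and, when
    ``n_replicates > 1``, per-point s.e.m. columns.
    """
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    t = DEFAULT_TIMES_MIN.copy() if times is None else np.asarray(times, float)
    rng = np.random.default_rng(seed)
    clean = np.column_stack(sequential_model(k1, k2, t))
    reps = np.empty((n_replicates, len(t), 3))
    for r in range(n_replicates):
        noisy = clean + rng.normal(0.0, noise_sd, clean.shape) if noise_sd > 0 \
            else clean.copy()
        noisy = np.clip(noisy, 0.0, None)
        sums = noisy.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        reps[r] = noisy / sums
    mean = reps.mean(axis=0)
    sem = (reps.std(axis=0, ddof=1) / np.sqrt(n_replicates)
           if n_replicates > 1 else None)
    return KineticDataset(t, mean, sem=sem, replicates=n_replicates)


# ---------------------------------------------------------------------------
# Analytic toy landscapes


@dataclass(frozen=True)
class ToyLandscape:
    """An analytic 2-D potential with documented critical values (kcal/mol)."""

    name: str
    potential: Callable[[float, float], float]
    gradient: Callable[[float, float], tuple[float, float]]
    minima: tuple[tuple[float, float], ...]
    saddle: tuple[float, float] | None
    barrier: float  # saddle value minus deepest-minimum value
    final_offset: float  # V(last minimum) - V(first minimum)

    def __call__(self, x: float, y: float) -> float:
        return self.potential(x, y)


def gen_toy_landscape(
    preset: str,
    barrier: float = 3.0,
    offset: float = 5.0,
) -> ToyLandscape:
    """Analytic validation landscapes.

    ``"double-well"``: V = barrier * (x^2 - 1)^2 + (k/2) y^2 with minima at
    (+-1, 0) and a saddle of height exactly ``barrier`` at (0, 0).

    ``"three-state"``: three well-separated Gaussian wells along x (depths
    10, 8, 10 - offset) emulating the triple-helix -> intermediate -> toggled
    topology; the final basin sits exactly ``offset`` kcal/mol above the
    first, and the inter-well plateaus sit near 0.
    """
    if preset == "double-well":
        ky = 5.0
        b = float(barrier)

        def pot(x: float, y: float) -> float:
            return b * (x * x - 1.0) ** 2 + 0.5 * ky * y * y

        def grad(x: float, y: float) -> tuple[float, float]:
            return (4.0 * b * x * (x * x - 1.0), ky * y)

        return ToyLandscape("double-well", pot, grad,
                            minima=((-1.0, 0.0), (1.0, 0.0)),
                            saddle=(0.0, 0.0), barrier=b, final_offset=0.0)
    if preset == "three-state":
        centers = (0.0, 3.0, 6.0)
        depths = (10.0, 8.0, 10.0 - float(offset))
        width2 = 2 * 0.6**2

        def pot(x: float, y: float) -> float:
            v = 0.0
            for c, a in zip(centers, depths):
                v -= a * np.exp(-((x - c) ** 2 + y * y) / width2)
            return v + depths[0]  # shift so the first minimum is ~0

        def grad(x: float, y: float) -> tuple[float, float]:
            gx = gy = 0.0
            for c, a in zip(centers, depths):
                e = a * np.exp(-((x - c) ** 2 + y * y) / width2)
                gx += e * 2 * (x - c) / width2
                gy += e * 2 * y / width2
            return (gx, gy)

        return ToyLandscape("three-state", pot, grad,
                            minima=tuple((c, 0.0) for c in centers),
                            saddle=(1.5, 0.0),
                            barrier=depths[0],
                            final_offset=float(offset))
    raise ParameterError(
        f"unknown preset {preset!r}; available: 'double-well', 'three-state'"
    )
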
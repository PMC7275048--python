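"""Adaptive-width metadynamics hill logs, FES reconstruction, and barriers.

Metadynamics estimates a free-energy surface by periodically depositing
repulsive Gaussians ("hills") at the sampled point in collective-variable
space; after the landscape is filled, the negative accumulated bias is an
estimator of the free energy (non-well-tempered variant, up to an additive
constant). Here the collective variables are the path coordinates (S, Z).

The deposition protocol mirrors common biased-MD practice: hills are deposited
at a fixed stride (default 1 ps), hill widths track the standard deviation of
the recent CV history over a window (default 1 ps) with a lower floor (default
0.03 in each coordinate's own unit), and the hill height is fixed (default
0.3 kJ/mol, stored internally as kcal/mol; all file I/O uses kJ/mol heights
for interchange with common biased-MD tooling).

A toy overdamped Langevin sampler on analytic 2-D potentials exercises the
identical deposition/reconstruction machinery end-to-end, which is how the
package validates barrier estimates that full-RNA simulations are needed to
produce for the real system.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .errors import (
    BasinError,
    ParameterError,
    ReconstructionError,
    SamplerError,
)

KJ_PER_KCAL = 4.184
KB_KCAL = 0.0019872041  # kcal mol^-1 K^-1

#: lower bound on hill widths, in each coordinate's own unit
WIDTH_FLOOR_DEFAULT = 0.03

#: hill height, kJ/mol, and deposition stride, ps
HILL_HEIGHT_KJ_DEFAULT = 0.3
STRIDE_PS_DEFAULT = 1.0


def kj_to_kcal(x: float) -> float:
    return x / KJ_PER_KCAL


def kcal_to_kj(x: float) -> float:
    return x * KJ_PER_KCAL


@dataclass(frozen=True)
class Hill:
    """One deposited Gaussian: center (S, Z), per-coordinate widths, height.

    ``height`` is stored in kcal/mol; widths are in the coordinates' own units
    (S dimensionless, Z in A^2).
    """

    time: float  # ps
    center: tuple[float, float]
    widths: tuple[float, float]
    height: float  # kcal/mol

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ParameterError("hill height must be positive")


@dataclass
class HillLog:
    """An ordered sequence of hills with a fixed deposition stride."""

    hills: list[Hill] = field(default_factory=list)
    stride: float = STRIDE_PS_DEFAULT  # ps
    width_floor: float = WIDTH_FLOOR_DEFAULT

    def __post_init__(self) -> None:
        if self.stride <= 0:
            raise ParameterError("stride must be positive")
        times = [h.time for h in self.hills]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ParameterError("hill times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.hills)

    def arrays(self) -> tuple[np.ndarray, ...]:
        """(times, centers (n,2), widths (n,2), heights) as float arrays."""
        if not self.hills:
            z = np.zeros(0)
            return z, np.zeros((0, 2)), np.zeros((0, 2)), z
        t = np.array([h.time for h in self.hills])
        c = np.array([h.center for h in self.hills])
        w = np.array([h.widths for h in self.hills])
        h = np.array([h.height for h in self.hills])
        return t, c, w, h


def adaptive_width(
    cv_history: np.ndarray,
    floor: float | tuple[float, float] = WIDTH_FLOOR_DEFAULT,
) -> tuple[float, float]:
    """Per-coordinate sample s.d. of the recent (S, Z) history, floored.

    ``cv_history`` is an (n, 2) array of the samples inside the averaging
    window (the caller slices the window; n >= 2 required).
    """
    hist = np.asarray(cv_history, dtype=float)
    if hist.ndim != 2 or hist.shape[1] != 2 or hist.shape[0] < 2:
        raise ParameterError("cv_history must be (n >= 2, 2)")
    floors = (floor, floor) if np.isscalar(floor) else floor
    sd = hist.std(axis=0, ddof=1)
    return (max(float(sd[0]), floors[0]), max(float(sd[1]), floors[1]))


def deposit(
    log: HillLog,
    state: tuple[float, float],
    widths: tuple[float, float],
    height_kj: float = HILL_HEIGHT_KJ_DEFAULT,
    time: float | None = None,
) -> HillLog:
    """Append a hill (height given in kJ/mol, stored in kcal/mol)."""
    if widths[0] < log.width_floor or widths[1] < log.width_floor:
        raise ParameterError(
            f"widths {widths} below the floor {log.width_floor}; "
            "clip with adaptive_width first"
        )
    if time is None:
        time = (len(log.hills) + 1) * log.stride
    log.hills.append(Hill(time, (float(state[0]), float(state[1])),
                          (float(widths[0]), float(widths[1])),
                          kj_to_kcal(height_kj)))
    return log


def bias_at(
    log: HillLog,
    point: tuple[float, float] | np.ndarray,
    up_to_time: float = np.inf,
) -> float | np.ndarray:
    """Accumulated bias at one point or an (n, 2) batch of points, kcal/mol.

    V(p) = sum_k h_k exp(-(S - S_k)^2 / 2 sig_Sk^2 - (Z - Z_k)^2 / 2 sig_Zk^2)
    over hills with time <= up_to_time.
    """
    t, c, w, h = log.arrays()
    keep = t <= up_to_time
    c, w, h = c[keep], w[keep], h[keep]
    p = np.asarray(point, dtype=float)
    scalar = p.ndim == 1
    pts = p[None, :] if scalar else p
    if len(h) == 0:
        out = np.zeros(len(pts))
        return float(out[0]) if scalar else out
    # (n_points, n_hills)
    ds = (pts[:, 0, None] - c[None, :, 0]) / w[None, :, 0]
    dz = (pts[:, 1, None] - c[None, :, 1]) / w[None, :, 1]
    v = (h[None, :] * np.exp(-0.5 * (ds**2 + dz**2))).sum(axis=1)
    return float(v[0]) if scalar else v


# ---------------------------------------------------------------------------
# Hill log text dialect: whitespace columns
#   time_ps  S  Z  sigma_S  sigma_Z  height_kJ_mol
# comment lines start with '#'.


def write_hills(path: str | Path, log: HillLog) -> None:
    with open(path, "w") as fh:
        fh.write("# time_ps S Z sigma_S sigma_Z height_kJ_mol\n")
        for hill in log.hills:
            fh.write(
                f"{hill.time!r} {hill.center[0]!r} {hill.center[1]!r} "
                f"{hill.widths[0]!r} {hill.widths[1]!r} "
                f"{kcal_to_kj(hill.height)!r}\n"
            )


def read_hills(path: str | Path, stride: float = STRIDE_PS_DEFAULT,
               width_floor: float = WIDTH_FLOOR_DEFAULT) -> HillLog:
    hills = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ParameterError(
                    f"{path}: expected 6 columns on line {lineno}, got {len(parts)}"
                )
            t, s, z, ws, wz, hkj = map(float, parts)
            hills.append(Hill(t, (s, z), (ws, wz), kj_to_kcal(hkj)))
    return HillLog(hills, stride=stride, width_floor=width_floor)


# ---------------------------------------------------------------------------
# Free-energy surface


@dataclass
class FreeEnergySurface:
    """Gridded free energy over (S, Z), kcal/mol, shifted so min == 0."""

    s_axis: np.ndarray
    z_axis: np.ndarray
    values: np.ndarray  # shape (len(s_axis), len(z_axis))

    def __post_init__(self) -> None:
        self.s_axis = np.asarray(self.s_axis, dtype=float)
        self.z_axis = np.asarray(self.z_axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.s_axis), len(self.z_axis)):
            raise ParameterError("FES values shape must be (n_s, n_z)")
        if not np.all(np.isfinite(self.values)):
            raise ReconstructionError("FES contains non-finite values")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# S\tZ\tF_kcal_mol\n")
            for i, s in enumerate(self.s_axis):
                for j, z in enumerate(self.z_axis):
                    fh.write(f"{float(s)!r}\t{float(z)!r}\t"
                             f"{float(self.values[i, j])!r}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FreeEnergySurface":
        rows = np.loadtxt(path)
        s = np.unique(rows[:, 0])
        z = np.unique(rows[:, 1])
        vals = np.full((len(s), len(z)), np.nan)
        si = np.searchsorted(s, rows[:, 0])
        zi = np.searchsorted(z, rows[:, 1])
        vals[si, zi] = rows[:, 2]
        return cls(s, z, vals)


@dataclass(frozen=True)
class Basin:
    """A local free-energy minimum: grid location and value."""

    s: float
    z: float
    value: float  # kcal/mol
    index: tuple[int, int]


@dataclass(frozen=True)
class BasinBarrierReport:
    """Basins, the minimax barrier between them, and the offset of basin B."""

    basin_a: Basin
    basin_b: Basin
    barrier: float  # kcal/mol, saddle - F(basin_a)
    offset: float  # kcal/mol, F(basin_b) - F(basin_a)

    def __post_init__(self) -> None:
        if self.barrier < 0:
            raise BasinError("barrier must be non-negative")
        if self.barrier + 1e-9 < self.offset:
            raise BasinError("barrier cannot be below the destination offset")


def reconstruct_fes(
    log: HillLog,
    s_axis: np.ndarray | None = None,
    z_axis: np.ndarray | None = None,
    n_grid: int = 200,
) -> FreeEnergySurface:
    """F(p) = -V_bias(p, t=inf), shifted so the grid minimum is exactly 0.

    Default grid: ``n_grid`` x ``n_grid`` spanning the observed hill centers
    padded by 3 sigma of the widest hill in each coordinate.
    """
    if len(log) == 0:
        raise ReconstructionError("cannot reconstruct a surface from an empty log")
    _, c, w, _ = log.arrays()
    if s_axis is None:
        pad = 3 * w[:, 0].max()
        s_axis = np.linspace(c[:, 0].min() - pad, c[:, 0].max() + pad, n_grid)
    if z_axis is None:
        pad = 3 * w[:, 1].max()
        z_axis = np.linspace(c[:, 1].min() - pad, c[:, 1].max() + pad, n_grid)
    ss, zz = np.meshgrid(s_axis, z_axis, indexing="ij")
    pts = np.column_stack([ss.ravel(), zz.ravel()])
    f = -np.asarray(bias_at(log, pts)).reshape(ss.shape)
    f -= f.min()
    return FreeEnergySurface(np.asarray(s_axis), np.asarray(z_axis), f)


def _local_min_in_region(
    fes: FreeEnergySurface, region: tuple[tuple[float, float], tuple[float, float]]
) -> Basin:
    (s_lo, s_hi), (z_lo, z_hi) = region
    si = np.nonzero((fes.s_axis >= s_lo) & (fes.s_axis <= s_hi))[0]
    zi = np.nonzero((fes.z_axis >= z_lo) & (fes.z_axis <= z_hi))[0]
    if len(si) == 0 or len(zi) == 0:
        raise BasinError(f"hint region {region} contains no grid points")
    sub = fes.values[np.ix_(si, zi)]
    # the region minimum must be an interior local minimum of the full grid,
    # otherwise the hint does not contain a basin
    k = np.unravel_index(np.argmin(sub), sub.shape)
    i, j = int(si[k[0]]), int(zi[k[1]])
    v = fes.values[i, j]
    ni = fes.values[max(i - 1, 0):i + 2, max(j - 1, 0):j + 2]
    if v > ni.min():
        raise BasinError(
            f"no local minimum inside hint region {region}: the region minimum "
            "sits on a slope"
        )
    return Basin(float(fes.s_axis[i]), float(fes.z_axis[j]), float(v), (i, j))


def minimax_path_value(
    values: np.ndarray, start: tuple[int, int], goal: tuple[int, int]
) -> float:
    """Lowest achievable maximum value along any 8-connected grid path.

    Dijkstra variant where a path's cost is the maximum cell value seen.
    """
    n, m = values.shape
    best = np.full((n, m), np.inf)
    heap = [(float(values[start]), start)]
    best[start] = values[start]
    while heap:
        cost, (i, j) = heapq.heappop(heap)
        if (i, j) == goal:
            return float(cost)
        if cost > best[i, j]:
            continue
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                ni, nj = i + di, j + dj
                if 0 <= ni < n and 0 <= nj < m:
                    ncost = max(cost, float(values[ni, nj]))
                    if ncost < best[ni, nj]:
                        best[ni, nj] = ncost
                        heapq.heappush(heap, (ncost, (ni, nj)))
    raise BasinError("goal unreachable on grid")  # pragma: no cover


def basins_and_barrier(
    fes: FreeEnergySurface,
    basin_a_hint: tuple[tuple[float, float], tuple[float, float]],
    basin_b_hint: tuple[tuple[float, float], tuple[float, float]],
) -> BasinBarrierReport:
    """Locate basins inside the two hint boxes and the minimax barrier.

    Hints are ((s_lo, s_hi), (z_lo, z_hi)) boxes in CV units. The barrier is
    the minimax path value between the basins (8-connectivity) minus
    F(basin A); the offset is F(basin B) - F(basin A).
    """
    a = _local_min_in_region(fes, basin_a_hint)
    b = _local_min_in_region(fes, basin_b_hint)
    saddle = minimax_path_value(fes.values, a.index, b.index)
    return BasinBarrierReport(a, b, float(saddle - a.value),
                              float(b.value - a.value))


# ---------------------------------------------------------------------------
# Toy biased sampler


def langevin_sample(
    potential: Callable[[float, float], float],
    gradient: Callable[[float, float], tuple[float, float]] | None = None,
    x0: tuple[float, float] = (0.0, 0.0),
    steps: int = 100_000,
    dt: float = 0.01,  # ps
    temperature: float = 300.0,  # K
    seed: int = 0,
    stride_steps: int = 50,
    width_window: int = 50,
    width_floor: float = WIDTH_FLOOR_DEFAULT,
    height_kj: float = HILL_HEIGHT_KJ_DEFAULT,
    bounds: float = 50.0,
    mobility: float = 1.0,
    log: HillLog | None = None,
) -> tuple[np.ndarray, HillLog]:
    """Overdamped Langevin dynamics on ``potential`` plus a live hill bias.

    The update is x += -dt * mobility * grad(V + V_bias) + sqrt(2 kT mobility
    dt) * xi. Every ``stride_steps`` steps a hill is deposited at the current
    point with adaptive widths from the last ``width_window`` samples. Runs
    with the same seed are bit-reproducible. Set ``height_kj=0`` to disable
    deposition (plain Langevin).

    Returns the CV trajectory (steps, 2) and the hill log.
    """
    if dt <= 0 or steps < 1:
        raise ParameterError("need dt > 0 and steps >= 1")
    rng = np.random.default_rng(seed)
    if gradient is None:
        eps = 1e-5

        def gradient(x, y):  # noqa: ANN001
            return (
                (potential(x + eps, y) - potential(x - eps, y)) / (2 * eps),
                (potential(x, y + eps) - potential(x, y - eps)) / (2 * eps),
            )

    if log is None:
        log = HillLog(stride=stride_steps * dt, width_floor=width_floor)
    kt = KB_KCAL * temperature
    noise_scale = np.sqrt(2.0 * kt * mobility * dt)
    # hill parameter arrays grown in place for fast vectorized bias forces
    cap = max(16, steps // max(stride_steps, 1) + len(log) + 2)
    n_h = len(log)
    h_c = np.zeros((cap, 2))
    h_w = np.ones((cap, 2))
    h_h = np.zeros(cap)
    for i, hill in enumerate(log.hills):
        h_c[i], h_w[i], h_h[i] = hill.center, hill.widths, hill.height

    x, y = float(x0[0]), float(x0[1])
    traj = np.empty((steps, 2))
    noises = rng.standard_normal((steps, 2))
    for step in range(steps):
        gx, gy = gradient(x, y)
        if n_h:
            ds = (x - h_c[:n_h, 0]) / h_w[:n_h, 0]
            dz = (y - h_c[:n_h, 1]) / h_w[:n_h, 1]
            g = h_h[:n_h] * np.exp(-0.5 * (ds * ds + dz * dz))
            gx += float((g * (-ds / h_w[:n_h, 0])).sum())
            gy += float((g * (-dz / h_w[:n_h, 1])).sum())
        x += -dt * mobility * gx + noise_scale * noises[step, 0]
        y += -dt * mobility * gy + noise_scale * noises[step, 1]
        if not (abs(x) < bounds and abs(y) < bounds):
            raise SamplerError(
                f"trajectory diverged at step {step} (|cv| > {bounds}); "
                "try a smaller dt"
            )
        traj[step] = (x, y)
        if height_kj > 0 and (step + 1) % stride_steps == 0:
            window = traj[max(0, step + 1 - width_window):step + 1]
            if len(window) >= 2:
                widths = adaptive_width(window, floor=width_floor)
            else:  # pragma: no cover - stride_steps >= 2 in practice
                widths = (width_floor, width_floor)
            deposit(log, (x, y), widths, height_kj=height_kj,
                    time=(step + 1) * dt)
            h_c[n_h] = (x, y)
            h_w[n_h] = widths
            h_h[n_h] = kj_to_kcal(height_kj)
            n_h += 1
    return traj, log
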
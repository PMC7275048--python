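"""Two-step splicing kinetics and the Eyring-Polanyi bridge.

Self-splicing proceeds through two sequential first-order steps,

    precursor (5e-I-3e) --k1--> intermediate (I-3e) --k2--> linear intron (I),

so the species fractions follow the closed-form A -> B -> C solution

    f_P(t) = exp(-k1 t)
    f_I(t) = k1/(k2 - k1) * (exp(-k1 t) - exp(-k2 t))
    f_E(t) = 1 - f_P - f_I

with the degenerate limit f_I = k1 t exp(-k1 t) when k1 == k2. Rate constants
are fitted to gel band-fraction time courses by simultaneous weighted least
squares over the three species, and converted to activation free energies via
the Eyring-Polanyi equation

    k = (k_B T / h) * exp(-dG' / R T)        (transmission coefficient 1).

The default conversion temperature is 310 K; at that temperature the wild-type
rate constants k1 = 0.031 min^-1 and k2 = 0.026 min^-1 correspond to barriers
of 22.8 and 22.9 kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import constants as sc
from scipy.optimize import least_squares

from .errors import FitError, ParameterError

#: default absolute temperature for rate <-> barrier conversion (K); matches
#: the simulation thermostat and reproduces the wild-type barrier pair
T_DEFAULT = 310.0

R_KCAL = sc.R / (1000.0 * sc.calorie)  # kcal mol^-1 K^-1
KB_OVER_H = sc.Boltzmann / sc.Planck  # s^-1 K^-1
SECONDS_PER_MIN = 60.0


@dataclass
class KineticDataset:
    """Band-fraction time courses for the three splicing species.

    ``fractions`` has shape (n_times, 3) ordered (precursor, intermediate,
    product); optional ``sem`` of the same shape holds standard errors of the
    mean over replicates. Per-time fractions must sum to 1 within band
    quantification slack (+-0.02).
    """

    times: np.ndarray  # min
    fractions: np.ndarray
    sem: np.ndarray | None = None
    replicates: int = 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (len(self.times), 3):
            raise ParameterError("fractions must be (n_times, 3)")
        if np.any(self.fractions < -1e-12) or np.any(self.fractions > 1 + 1e-12):
            raise ParameterError("fractions must lie in [0, 1]")
        sums = self.fractions.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 0.02 + 1e-12):
            raise ParameterError(
                "per-time fractions must sum to 1 within the 0.02 band slack "
                f"(worst deviation {np.max(np.abs(sums - 1)):.3f})"
            )
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if self.sem.shape != self.fractions.shape:
                raise ParameterError("sem must match fractions shape")

    def to_tsv(self, path: str | Path) -> None:
        cols = {"time_min": self.times,
                "f_precursor": self.fractions[:, 0],
                "f_intermediate": self.fractions[:, 1],
                "f_product": self.fractions[:, 2]}
        if self.sem is not None:
            cols.update({"sem_precursor": self.sem[:, 0],
                         "sem_intermediate": self.sem[:, 1],
                         "sem_product": self.sem[:, 2]})
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, replicates: int = 1) -> "KineticDataset":
        df = pd.read_csv(path, sep=None, engine="python")
        need = ["time_min", "f_precursor", "f_intermediate", "f_product"]
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise ParameterError(f"{path}: missing columns {missing}")
        sem = None
        sem_cols = ["sem_precursor", "sem_intermediate", "sem_product"]
        if all(c in df.columns for c in sem_cols):
            sem = df[sem_cols].to_numpy()
        return cls(df["time_min"].to_numpy(),
                   df[need[1:]].to_numpy(), sem=sem, replicates=replicates)


@dataclass(frozen=True)
class RateFit:
    """Fitted rate constants (min^-1), uncertainties, and fit diagnostics."""

    k1: float
    k2: float
    se_k1: float
    se_k2: float
    rss: float
    converged: bool
    n_points: int
    method: str = "covariance"  # or "bootstrap"

    def confidence_interval(self, which: str = "k1", level: float = 0.95
                            ) -> tuple[float, float]:
        """Normal-theory CI on the log-rate scale (rates are positive)."""
        from scipy.stats import norm

        k = self.k1 if which == "k1" else self.k2
        se = self.se_k1 if which == "k1" else self.se_k2
        zc = norm.ppf(0.5 + level / 2)
        # delta method: se(log k) = se(k)/k
        half = zc * se / k
        return (k * np.exp(-half), k * np.exp(half))


@dataclass(frozen=True)
class EyringResult:
    """An activation free energy paired with the rate it reproduces."""

    delta_g: float  # kcal/mol
    temperature: float  # K
    rate: float  # min^-1
    constants: dict = field(default_factory=lambda: {
        "k_B": sc.Boltzmann, "h": sc.Planck, "R_kcal": R_KCAL,
        "transmission_coefficient": 1.0,
    })


# ---------------------------------------------------------------------------


def sequential_model(k1: float, k2: float, t: np.ndarray | float
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form species fractions of the A -> B -> C scheme.

    Stable through the degenerate point k1 == k2 via
    f_I = k1 t e^{-k1 t} phi(-(k2-k1) t), phi(x) = (e^x - 1)/x.
    Fractions sum to 1 exactly (f_E is computed as the complement).
    """
    if k1 <= 0 or k2 <= 0:
        raise ParameterError("rate constants must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("times must be non-negative")
    f_p = np.exp(-k1 * t)
    x = -(k2 - k1) * t
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(np.abs(x) < 1e-12, 1.0 + x / 2.0,
                       np.expm1(x) / np.where(x == 0, 1.0, x))
    f_i = k1 * t * f_p * phi
    f_e = 1.0 - f_p - f_i
    return f_p, f_i, f_e


def fit_rates(
    data: KineticDataset,
    initial: tuple[float, float] | None = None,
    bootstrap: int = 0,
    seed: int | None = None,
    n_starts: int = 5,
) -> RateFit:
    """Simultaneous weighted least-squares fit of (k1, k2).

    All three fraction series are fitted at once; weights are inverse s.e.m.
    when provided, else uniform. The optimizer works on log rates with
    ``n_starts`` log-spaced initializations (best residual wins). Standard
    errors come from the Jacobian covariance at the optimum, or from
    ``bootstrap`` >= 1 residual-resampling refits when requested.
    """
    if len(data.times) < 4:
        raise FitError("need at least 4 time points to fit two rate constants")
    t = data.times
    y = data.fractions
    if data.sem is not None and np.all(data.sem > 0):
        w = 1.0 / data.sem
        w /= w.mean()
    else:
        w = np.ones_like(y)

    def residuals(theta: np.ndarray, yy: np.ndarray = y) -> np.ndarray:
        k1, k2 = np.exp(theta)
        f = np.column_stack(sequential_model(k1, k2, t))
        return ((f - yy) * w).ravel()

    span = t[t > 0]
    if len(span) == 0:
        raise FitError("all time points are zero")
    k_scale = 1.0 / np.median(span)
    if initial is not None:
        starts = [np.log(np.asarray(initial, dtype=float))]
    else:
        grid = np.log(k_scale) + np.linspace(-2.5, 2.5, n_starts)
        starts = [np.array([g, g - 0.1]) for g in grid]

    best = None
    for theta0 in starts:
        try:
            res = least_squares(residuals, theta0, method="lm", xtol=1e-14,
                                ftol=1e-14, max_nfev=2000)
        except Exception:  # noqa: BLE001 - a failed start is not fatal
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        raise FitError("fit did not converge from any initialization")
    k1, k2 = np.exp(best.x)
    if k1 < 1e-10 * k_scale or k2 < 1e-10 * k_scale:
        raise FitError(
            f"fitted rate at parameter boundary (k1={k1:.3g}, k2={k2:.3g} "
            "min^-1); the data carry no information on this step"
        )
    rss = float(2 * best.cost)
    m, p = y.size, 2
    jac = best.jac
    try:
        cov_theta = np.linalg.inv(jac.T @ jac) * rss / max(m - p, 1)
        se_log = np.sqrt(np.diag(cov_theta))
    except np.linalg.LinAlgError:  # pragma: no cover
        se_log = np.array([np.nan, np.nan])
    method = "covariance"
    if bootstrap >= 1:
        rng = np.random.default_rng(seed)
        fitted = np.column_stack(sequential_model(k1, k2, t))
        resid = y - fitted
        samples = []
        for _ in range(bootstrap):
            pick = rng.integers(0, len(t), size=len(t))
            yb = fitted + resid[pick]
            try:
                rb = least_squares(residuals, best.x, method="lm",
                                   kwargs={"yy": yb}, max_nfev=500)
                samples.append(rb.x)
            except Exception:  # noqa: BLE001
                continue
        if len(samples) >= 2:
            se_log = np.std(np.array(samples), axis=0, ddof=1)
            method = "bootstrap"
    se_k1, se_k2 = k1 * se_log[0], k2 * se_log[1]
    return RateFit(float(k1), float(k2), float(se_k1), float(se_k2), rss,
                   True, int(m), method)


def eyring_barrier(k: float, temperature: float = T_DEFAULT) -> EyringResult:
    """Activation free energy (kcal/mol) from a rate constant in min^-1.

    dG' = -R T ln(k h / (k_B T)) with transmission coefficient 1; the rate is
    converted to s^-1 internally.
    """
    if k <= 0 or temperature <= 0:
        raise ParameterError("rate and temperature must be positive")
    k_si = k / SECONDS_PER_MIN
    delta_g = -R_KCAL * temperature * np.log(k_si / (KB_OVER_H * temperature))
    return EyringResult(float(delta_g), float(temperature), float(k))


def eyring_rate(delta_g: float, temperature: float = T_DEFAULT) -> float:
    """Rate constant (min^-1) from an activation free energy (kcal/mol)."""
    if temperature <= 0:
        raise ParameterError("temperature must be positive")
    k_si = KB_OVER_H * temperature * np.exp(-delta_g / (R_KCAL * temperature))
    return float(k_si * SECONDS_PER_MIN)


def fold_change(k_ref: float, k_test: float) -> float:
    """How many times slower ``k_test`` is than ``k_ref`` (k_ref / k_test)."""
    if k_ref <= 0 or k_test <= 0:
        raise ParameterError("rate constants must be positive")
    return k_ref / k_test
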
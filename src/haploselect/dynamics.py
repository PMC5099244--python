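"""Deterministic age dynamics of haplotype frequencies under mortality selection.

With age-independent haplotype hazards mu_ij, each haplotype sub-cohort
survives from the baseline age t0 as exp(-mu_ij * (t - t0)); among survivors
the haplotype proportions are

    m_ij(t) = m_ij(t0) * exp(-mu_ij * (t - t0)) / Z(t),
    Z(t)    = sum_kl m_kl(t0) * exp(-mu_kl * (t - t0)),

where Z(t) is the overall survival fraction of the cohort.  This closed form
is the solution of the selection system d m_ij/dt = -m_ij * (mu_ij - mubar(t))
with mubar(t) the population mean hazard.  Differential survival reshapes
allele frequencies and linkage disequilibrium with age, and drives the
marginal carrier / non-carrier hazards at a focal locus — each a
frequency-weighted mixture of its class's haplotype rates — downward at
possibly different speeds.  When the two marginal hazard curves intersect,
the apparent effect of the focal allele reverses sign with age (the
"flip-flop" regime).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import DomainError, HaplotypeDistribution, Scenario, margins

__all__ = [
    "TrajectoryTable",
    "propagate",
    "survival",
    "mean_population_hazard",
    "marginal_hazards",
    "trajectory",
    "crossing_ages",
]

#: columns of the trajectory table, in writer order
TRAJECTORY_COLUMNS = [
    "age", "m00", "m10", "m01", "m11", "m1", "m2", "D",
    "mu_carrier", "mu_noncarrier", "mu_pop", "surv",
]


def _check_age(scenario: Scenario, t: float) -> float:
    if t < scenario.t0:
        raise DomainError(
            f"age t={t!r} precedes baseline t0={scenario.t0!r}"
        )
    return t - scenario.t0


def _survivor_weights(scenario: Scenario, dt) -> np.ndarray:
    """Unnormalized survivor masses m_ij(t0)*exp(-mu_ij*dt), order (00,10,01,11).

    ``dt`` may be a scalar or an array of age offsets; the result has shape
    ``(..., 4)``.
    """
    m0 = np.asarray(scenario.dist0.as_tuple(), dtype=float)
    mu = np.asarray(scenario.hazards.as_tuple(), dtype=float)
    dt = np.asarray(dt, dtype=float)
    return m0 * np.exp(-np.multiply.outer(dt, mu))


def propagate(scenario: Scenario, t: float) -> HaplotypeDistribution:
    """Haplotype distribution among survivors at age ``t`` >= t0."""
    dt = _check_age(scenario, t)
    w = _survivor_weights(scenario, dt)
    z = w.sum()
    f = w / z
    return HaplotypeDistribution(*(f / f.sum()))


def survival(scenario: Scenario, t: float) -> float:
    """Overall cohort survival fraction Z(t) from t0 to age ``t``."""
    dt = _check_age(scenario, t)
    return float(_survivor_weights(scenario, dt).sum())


def mean_population_hazard(scenario: Scenario, t: float) -> float:
    """Population mean hazard mubar(t) = sum m_ij(t) * mu_ij."""
    dt = _check_age(scenario, t)
    w = _survivor_weights(scenario, dt)
    mu = np.asarray(scenario.hazards.as_tuple(), dtype=float)
    return float((w * mu).sum() / w.sum())


# indices into the (00, 10, 01, 11) order for carrier / non-carrier classes
_CLASS_INDEX = {1: ([1, 3], [0, 2]), 2: ([2, 3], [0, 1])}


def _locus_classes(locus: int) -> tuple[list[int], list[int]]:
    try:
        return _CLASS_INDEX[locus]
    except KeyError:
        raise DomainError(f"locus must be 1 or 2, got {locus!r}") from None


def _marginal_hazard_arrays(
    scenario: Scenario, dt, locus: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized carrier / non-carrier marginal hazards at age offsets ``dt``."""
    carrier_idx, noncarrier_idx = _locus_classes(locus)
    m0 = np.asarray(scenario.dist0.as_tuple(), dtype=float)
    if m0[carrier_idx].sum() <= 0.0:
        raise DomainError(
            f"carrier class at locus {locus} has zero baseline frequency; "
            "its marginal hazard is undefined"
        )
    if m0[noncarrier_idx].sum() <= 0.0:
        raise DomainError(
            f"non-carrier class at locus {locus} has zero baseline frequency; "
            "its marginal hazard is undefined"
        )
    w = _survivor_weights(scenario, dt)
    mu = np.asarray(scenario.hazards.as_tuple(), dtype=float)
    wc = w[..., carrier_idx]
    wn = w[..., noncarrier_idx]
    mu_c = (wc * mu[carrier_idx]).sum(axis=-1) / wc.sum(axis=-1)
    mu_n = (wn * mu[noncarrier_idx]).sum(axis=-1) / wn.sum(axis=-1)
    return mu_c, mu_n


def marginal_hazards(
    scenario: Scenario, t: float, locus: int = 1
) -> tuple[float, float]:
    """Marginal hazards (mu_carrier, mu_noncarrier) at the focal locus at age t.

    The carrier hazard is the survivor-frequency-weighted mixture of the two
    carrier-haplotype rates (haplotypes 10 and 11 for locus 1); likewise for
    non-carriers.  Raises :class:`DomainError` if either class is empty at
    baseline.
    """
    dt = _check_age(scenario, t)
    mu_c, mu_n = _marginal_hazard_arrays(scenario, dt, locus)
    return float(mu_c), float(mu_n)


@dataclass(frozen=True)
class TrajectoryTable:
    """Per-age record of frequencies, margins, and marginal hazards.

    ``frame`` holds one row per grid age with columns ``TRAJECTORY_COLUMNS``;
    ages are uniform from t0 to t0 + horizon.
    """

    label: str
    locus: int
    frame: pd.DataFrame

    def write_csv(self, path) -> None:
        """Write the table as comma-separated text at full double precision."""
        self.frame.to_csv(path, index=False, float_format="%.17g")


def trajectory(scenario: Scenario, locus: int = 1, step: float = 0.1) -> TrajectoryTable:
    """Tabulate the full age trajectory on a uniform grid of spacing ``step``."""
    if not 0.0 < step <= scenario.horizon:
        raise DomainError(
            f"step={step!r} must satisfy 0 < step <= horizon={scenario.horizon!r}"
        )
    n = int(round(scenario.horizon / step))
    dt = np.arange(n + 1) * step
    dt = dt[dt <= scenario.horizon + 1e-9]
    w = _survivor_weights(scenario, dt)
    z = w.sum(axis=-1)
    f = w / z[:, None]
    mu = np.asarray(scenario.hazards.as_tuple(), dtype=float)
    mu_c, mu_n = _marginal_hazard_arrays(scenario, dt, locus)
    m1 = f[:, 1] + f[:, 3]
    m2 = f[:, 2] + f[:, 3]
    frame = pd.DataFrame({
        "age": scenario.t0 + dt,
        "m00": f[:, 0], "m10": f[:, 1], "m01": f[:, 2], "m11": f[:, 3],
        "m1": m1, "m2": m2,
        "D": f[:, 0] * f[:, 3] - f[:, 1] * f[:, 2],
        "mu_carrier": mu_c, "mu_noncarrier": mu_n,
        "mu_pop": (f * mu).sum(axis=-1),
        "surv": z,
    }, columns=TRAJECTORY_COLUMNS)
    return TrajectoryTable(label=scenario.label, locus=locus, frame=frame)


def crossing_ages(
    scenario: Scenario,
    locus: int = 1,
    window: tuple[float, float] | None = None,
    scan_step: float = 0.5,
    tol: float = 1e-6,
) -> list[float]:
    """Ages where carrier and non-carrier marginal hazards intersect.

    Scans the window on a grid of spacing ``scan_step`` for sign changes of
    the hazard difference, then refines each bracket by bisection to ``tol``
    years.  Tangential contacts without a sign change are not reported; the
    list is empty when the curves never cross in the window.
    """
    lo, hi = window if window is not None else (scenario.t0, scenario.t0 + scenario.horizon)
    if lo < scenario.t0 or hi > scenario.t0 + scenario.horizon or lo >= hi:
        raise DomainError(
            f"window ({lo!r}, {hi!r}) must lie within "
            f"[{scenario.t0!r}, {scenario.t0 + scenario.horizon!r}]"
        )

    def delta(t: float) -> float:
        mu_c, mu_n = _marginal_hazard_arrays(scenario, t - scenario.t0, locus)
        return float(mu_c - mu_n)

    grid = np.arange(lo, hi, scan_step)
    grid = np.append(grid, hi)
    vals = np.array([delta(t) for t in grid])
    roots: list[float] = []
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if fa == 0.0:
            # an exact zero on the grid counts only if the sign changes across it
            continue
        if fa * fb < 0.0:
            roots.append(float(brentq(delta, a, b, xtol=tol)))
    return roots
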
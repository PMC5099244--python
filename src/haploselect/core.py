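"""Domain types and algebra for the two-locus haplotype mortality model.

Two biallelic SNP loci are coded by dichotomous indicators V1, V2 in {0, 1}
(1 = minor allele present, dominant coding).  A haplotype (i, j) pairs the
indicator at locus 1 with the indicator at locus 2; the population at one age
is summarized by the four haplotype proportions m00, m10, m01, m11.  Each
haplotype carries a constant (age-independent) mortality rate mu_ij.

Two parameterizations generate a hazard set from a baseline rate mu00:

* Model 1 (additive increments):   mu10 = mu00*(1+R1), mu01 = mu00*(1+R2),
  mu11 = mu00*(1+R1+R2), with -1 < R1 < 0 < R2 and R1 + R2 > 0.
* Model 2 (multiplicative):        mu10 = mu00*H1, mu01 = mu00*H2,
  mu11 = mu00*H1*H2, with 0 < H1 < 1 < H2 and H1*H2 > 1.

Both constraint sets guarantee the strict hazard ordering
mu10 < mu00 < mu11 < mu01: the minor allele at locus 1 is protective
("longevity" allele) and the minor allele at locus 2 is harmful
("vulnerability" allele) in the absence of LD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ModelError",
    "ValidationError",
    "DomainError",
    "HaplotypeDistribution",
    "AlleleMargins",
    "HazardSet",
    "Model1Spec",
    "Model2Spec",
    "Scenario",
    "margins",
    "ld_coefficient",
    "d_prime",
    "r_squared",
    "distribution_from_margins",
    "hazards_model1",
    "hazards_model2",
    "validate_ordering",
]

#: tolerance for "sums to one" checks on proportions
SUM_TOL = 1e-12
#: strictness margin for open inequality constraints; boundary values rejected
STRICT_TOL = 1e-12


class ModelError(ValueError):
    """Base class for model-construction and domain errors."""


class ValidationError(ModelError):
    """A type invariant or parameter constraint is violated."""


class DomainError(ModelError):
    """An operation was called outside its mathematical domain."""


@dataclass(frozen=True)
class HaplotypeDistribution:
    """Proportions of the four haplotypes (i, j) in one population at one age.

    ``m_ij`` is the fraction of the population carrying indicator i at locus 1
    and j at locus 2 (1 = minor allele present).  Proportions must be
    non-negative and sum to one within ``SUM_TOL``.
    """

    m00: float
    m10: float
    m01: float
    m11: float

    def __post_init__(self) -> None:
        for name in ("m00", "m10", "m01", "m11"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(
                    f"haplotype proportion {name}={v!r} outside [0, 1]"
                )
        total = self.m00 + self.m10 + self.m01 + self.m11
        if abs(total - 1.0) > SUM_TOL:
            raise ValidationError(
                f"haplotype proportions sum to {total!r}, not 1 (tol {SUM_TOL})"
            )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.m00, self.m10, self.m01, self.m11)


@dataclass(frozen=True)
class AlleleMargins:
    """Marginal view of a haplotype distribution: MAFs and gametic LD.

    ``m1``/``m2`` are minor-allele frequencies at loci 1 and 2; ``D`` is the
    gametic disequilibrium coefficient m00*m11 - m10*m01 = m11 - m1*m2.
    ``D`` must lie within the Lewontin feasibility bounds implied by the
    margins.
    """

    m1: float
    m2: float
    D: float

    def __post_init__(self) -> None:
        for name in ("m1", "m2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"allele frequency {name}={v!r} outside [0, 1]")
        lo, hi = self.feasible_D_bounds(self.m1, self.m2)
        if not (lo - SUM_TOL <= self.D <= hi + SUM_TOL):
            raise ValidationError(
                f"D={self.D!r} outside feasibility bounds [{lo!r}, {hi!r}] "
                f"for m1={self.m1!r}, m2={self.m2!r}"
            )

    @staticmethod
    def feasible_D_bounds(m1: float, m2: float) -> tuple[float, float]:
        """Range of D compatible with margins (all haplotype freqs >= 0)."""
        lo = max(-m1 * m2, -(1.0 - m1) * (1.0 - m2))
        hi = min(m1 * (1.0 - m2), m2 * (1.0 - m1))
        return lo, hi


@dataclass(frozen=True)
class HazardSet:
    """Constant mortality rates (1/year) for the four haplotypes."""

    mu00: float
    mu10: float
    mu01: float
    mu11: float

    def __post_init__(self) -> None:
        for name in ("mu00", "mu10", "mu01", "mu11"):
            v = getattr(self, name)
            if not v > 0.0:
                raise ValidationError(f"mortality rate {name}={v!r} must be > 0")

    def as_tuple(self) -> tuple[float, float, float, float]:
        """Rates in distribution order (00, 10, 01, 11)."""
        return (self.mu00, self.mu10, self.mu01, self.mu11)


@dataclass(frozen=True)
class Model1Spec:
    """Additive-increment hazard model: relative-risk increments R1, R2.

    R1 (protective, -1 < R1 < 0) and R2 (harmful, R2 > 0) add on the relative
    risk scale; R1 + R2 > 0 makes the double-minor haplotype net harmful.
    """

    mu00: float
    R1: float
    R2: float

    def __post_init__(self) -> None:
        if not self.mu00 > 0.0:
            raise ValidationError(f"baseline rate mu00={self.mu00!r} must be > 0")
        if not (-1.0 + STRICT_TOL < self.R1 < -STRICT_TOL):
            raise ValidationError(
                f"R1={self.R1!r} violates -1 < R1 < 0 (strict)"
            )
        if not self.R2 > STRICT_TOL:
            raise ValidationError(f"R2={self.R2!r} violates R2 > 0 (strict)")
        if not self.R1 + self.R2 > STRICT_TOL:
            raise ValidationError(
                f"R1+R2={self.R1 + self.R2!r} violates R1 + R2 > 0 (strict)"
            )


@dataclass(frozen=True)
class Model2Spec:
    """Multiplicative hazard model: relative-risk multipliers H1, H2."""

    mu00: float
    H1: float
    H2: float

    def __post_init__(self) -> None:
        if not self.mu00 > 0.0:
            raise ValidationError(f"baseline rate mu00={self.mu00!r} must be > 0")
        if not (STRICT_TOL < self.H1 < 1.0 - STRICT_TOL):
            raise ValidationError(f"H1={self.H1!r} violates 0 < H1 < 1 (strict)")
        if not self.H2 > 1.0 + STRICT_TOL:
            raise ValidationError(f"H2={self.H2!r} violates H2 > 1 (strict)")
        if not self.H1 * self.H2 > 1.0 + STRICT_TOL:
            raise ValidationError(
                f"H1*H2={self.H1 * self.H2!r} violates H1*H2 > 1 (strict)"
            )


@dataclass(frozen=True)
class Scenario:
    """A simulation unit: baseline distribution, hazards, and age window.

    ``t0`` is the baseline age (years); ages are measured from ``t0`` up to
    ``t0 + horizon``.  The default horizon is 60 years.
    """

    label: str
    dist0: HaplotypeDistribution
    hazards: HazardSet
    t0: float = 0.0
    horizon: float = 60.0

    def __post_init__(self) -> None:
        if not self.horizon > 0.0:
            raise ValidationError(f"horizon={self.horizon!r} must be > 0")


def margins(dist: HaplotypeDistribution) -> AlleleMargins:
    """Marginal minor-allele frequencies and gametic LD of a distribution.

    m1 = m10 + m11, m2 = m01 + m11, D = m00*m11 - m10*m01.
    """
    return AlleleMargins(
        m1=dist.m10 + dist.m11,
        m2=dist.m01 + dist.m11,
        D=ld_coefficient(dist),
    )


def ld_coefficient(dist: HaplotypeDistribution) -> float:
    """Gametic linkage-disequilibrium coefficient D = m00*m11 - m10*m01.

    Under normalization this equals m11 - m1*m2, the covariance of the two
    allele indicators.
    """
    return dist.m00 * dist.m11 - dist.m10 * dist.m01


def d_prime(dist: HaplotypeDistribution) -> float:
    """Lewontin's D' — D scaled by its feasibility bound (derived convenience)."""
    mg = margins(dist)
    lo, hi = AlleleMargins.feasible_D_bounds(mg.m1, mg.m2)
    if mg.D == 0.0:
        return 0.0
    denom = hi if mg.D > 0 else -lo
    if denom == 0.0:
        raise DomainError("D' undefined: feasibility bound is zero")
    return mg.D / denom


def r_squared(dist: HaplotypeDistribution) -> float:
    """Squared allele-indicator correlation r^2 (derived convenience)."""
    mg = margins(dist)
    denom = mg.m1 * (1.0 - mg.m1) * mg.m2 * (1.0 - mg.m2)
    if denom == 0.0:
        raise DomainError("r^2 undefined: a locus is monomorphic")
    return mg.D * mg.D / denom


def distribution_from_margins(mg: AlleleMargins) -> HaplotypeDistribution:
    """Reconstruct haplotype proportions from (m1, m2, D).

    Inverse of :func:`margins`: m11 = m1*m2 + D and the rest follow.  Raises
    :class:`DomainError` naming the violated bound if D is infeasible.
    """
    lo, hi = AlleleMargins.feasible_D_bounds(mg.m1, mg.m2)
    if mg.D < lo - SUM_TOL:
        raise DomainError(
            f"D={mg.D!r} below lower feasibility bound {lo!r} "
            f"(haplotype frequency would be negative)"
        )
    if mg.D > hi + SUM_TOL:
        raise DomainError(
            f"D={mg.D!r} above upper feasibility bound {hi!r} "
            f"(haplotype frequency would be negative)"
        )
    m11 = mg.m1 * mg.m2 + mg.D
    m10 = mg.m1 - m11
    m01 = mg.m2 - m11
    m00 = 1.0 - mg.m1 - mg.m2 + m11
    clip = lambda x: min(1.0, max(0.0, x))  # guard rounding at the boundary
    return HaplotypeDistribution(clip(m00), clip(m10), clip(m01), clip(m11))


def hazards_model1(spec: Model1Spec) -> HazardSet:
    """Hazard set under the additive-increment parameterization."""
    return HazardSet(
        mu00=spec.mu00,
        mu10=spec.mu00 * (1.0 + spec.R1),
        mu01=spec.mu00 * (1.0 + spec.R2),
        mu11=spec.mu00 * (1.0 + spec.R1 + spec.R2),
    )


def hazards_model2(spec: Model2Spec) -> HazardSet:
    """Hazard set under the multiplicative parameterization."""
    return HazardSet(
        mu00=spec.mu00,
        mu10=spec.mu00 * spec.H1,
        mu01=spec.mu00 * spec.H2,
        mu11=spec.mu00 * spec.H1 * spec.H2,
    )


def validate_ordering(h: HazardSet) -> tuple[bool, str | None]:
    """Check the strict ordering mu10 < mu00 < mu11 < mu01.

    Returns ``(True, None)`` when the ordering holds, otherwise ``(False,
    relation)`` where ``relation`` names the first violated inequality.
    """
    checks = (
        (h.mu10 < h.mu00, "mu10 < mu00"),
        (h.mu00 < h.mu11, "mu00 < mu11"),
        (h.mu11 < h.mu01, "mu11 < mu01"),
    )
    for ok, relation in checks:
        if not ok:
            return False, relation
    return True, None
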
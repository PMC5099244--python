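# Methods

## Model

`haploselect` models a birth (or enrollment) cohort carrying two biallelic
SNP loci with dichotomous, dominant allele coding: the indicator at each
locus is 1 if the minor allele is present. A haplotype (i, j) pairs the two
indicators, and the population at the baseline age t0 is summarized by the
four haplotype proportions m00, m10, m01, m11. Each haplotype has a constant
(age-independent) mortality rate μij > 0. The canonical regime of interest
orders the rates as

    μ10 < μ00 < μ11 < μ01,

so that in the absence of LD the minor allele at locus 1 is protective (a
"longevity" allele) and the minor allele at locus 2 is harmful (a
"vulnerability" allele), with the double-minor haplotype net harmful.

Two parameterizations generate such a hazard set from the baseline rate μ00:

- additive increments ("Model 1"): μ10 = μ00(1+R1), μ01 = μ00(1+R2),
  μ11 = μ00(1+R1+R2), with −1 < R1 < 0 < R2 and R1+R2 > 0;
- multiplicative factors ("Model 2"): μ10 = μ00·H1, μ01 = μ00·H2,
  μ11 = μ00·H1·H2, with 0 < H1 < 1 < H2 and H1·H2 > 1.

Either constraint set implies the strict ordering above. Open constraints
are enforced strictly with a 1e-12 margin; boundary values are rejected.

## Dynamics

With constant hazards, each haplotype sub-cohort survives from t0 as
exp(−μij·(t−t0)), so the surviving-cohort haplotype frequencies are the
renormalized mixture

    m_ij(t) = m_ij(t0)·exp(−μij·(t−t0)) / Z(t),
    Z(t)    = Σ_kl m_kl(t0)·exp(−μkl·(t−t0)),

with Z(t) the overall survival fraction. This closed form is the unique
solution of the selection system d m_ij/dt = −m_ij·(μij − μ̄(t)) where
μ̄(t) = Σ m_ij(t)·μij is the population mean hazard; the test suite checks
the closed form against direct numerical integration of that ODE
(DOP853, rtol 1e-10) to ≤1e-6 over 100 years.

Derived quantities at each age: minor-allele frequencies m1 = m10 + m11 and
m2 = m01 + m11; the gametic LD coefficient D = m00·m11 − m10·m01
(= m11 − m1·m2 under normalization); and the marginal hazards of the
carrier and non-carrier classes at a focal locus, each the survivor-weighted
mixture of its class's two haplotype rates, e.g. for locus 1

    μ_carrier(t) = (m10(t)·μ10 + m11(t)·μ11) / (m10(t) + m11(t)).

Selection makes μ̄, μ_carrier and μ_noncarrier non-increasing in age, each
converging to the minimum rate in its class. Because the two marginal curves
can decline at different speeds, they may intersect: the focal allele's
apparent effect then reverses sign with age (the flip-flop regime). A class
with zero baseline frequency has an undefined marginal hazard and raises a
domain error rather than returning 0/0.

The LD coefficient is the standard gametic covariance; standardized measures
D′ and r² are provided only as derived conveniences. Haplotype frequencies
are the primary representation throughout; (m1, m2, D) is a derived view
with an exact inverse (`distribution_from_margins`), validated against the
Lewontin feasibility bounds max(−m1m2, −(1−m1)(1−m2)) ≤ D ≤
min(m1(1−m2), m2(1−m1)).

## Preset scenarios

Presets "A"–"D" are the four published simulation experiments: μ00 =
0.07/yr; rows A–C share (R1, R2) = (−0.2, 0.8) and margins m1 = m2 = 0.4
but differ in initial LD (−0.16, 0.23, 0.13); row D has (R1, R2) =
(−0.35, 0.4), m1 = 0.28, m2 = 0.41, LD ≈ 0.165. Presets are built from the
printed haplotype frequencies, not from the printed margins: row D's printed
LD (0.165) is a rounding of the exact 0.1652 implied by its haplotype
frequencies, so the haplotype route is the consistent one.

On the default 60-year window the four presets realize the four qualitative
regimes: A — carrier hazard below non-carrier throughout (longevity allele);
B — above throughout (vulnerability allele); C — one crossing near 34 years
(harmful → beneficial); D — one crossing near 15.5 years (beneficial →
harmful). Preset B's curves do eventually cross (≈85+ years past t0); the
60-year default window is the demographically sensible span on which the
four regimes hold, and is configurable.

Presets "A2"–"D2" are multiplicative-model analogues chosen here as demo
specs (no published H values exist): H1 = 1+R1 and H2 = 1+R2 of the matching
row. For row D that pair is infeasible ((0.65)(1.4) = 0.91 ≤ 1 violates
H1·H2 > 1), so "D2" instead uses H1 = 1+R1 = 0.65 and
H2 = (1+R1+R2)/(1+R1) = 21/13 ≈ 1.615, which preserves the additive row's
μ10 and μ11 while satisfying all Model 2 constraints.

The baseline age convention is t0 = 0 ("age" means years since baseline);
whether t0 is birth or an adult enrollment age does not affect any computed
quantity, only its labeling.

## Crossing detection

`crossing_ages` scans the hazard difference Δ(t) = μ_carrier − μ_noncarrier
on a 0.5-year grid for sign changes and refines each bracket with Brent's
method to 1e-6 years. Tangential contacts that do not change sign are not
reported. The trajectory grid default is 0.1 years. The acceptance tests
corroborate the roots with an independent brute-force 1e-3-year scan and,
for preset D, with the one-variable closed form available because its
carrier class is a single haplotype.

## Cohort simulation and estimation

`sample_cohort` draws, per subject, a haplotype from the baseline
distribution and a lifespan t0 + Exponential(μ_haplotype), with
administrative censoring at a single fixed age; there is no left truncation
or random loss to follow-up. One numpy default generator (PCG64) is seeded
per call; haplotype draws precede lifespan draws, so cohorts are
reproducible for a given numpy version. Study sizes in the test suite:
n = 200,000 per scenario (censoring at 40 years) for binwise hazard checks
and for unit-level attenuation comparisons; n = 2,000,000 for the
early-/late-window sign-flip checks, sized by a power calculation on the
deterministic model — the weakest effect (scenario D's late window, expected
|log RR| ≈ 0.011) then exceeds four standard errors.

`empirical_hazard` returns deaths / person-years per age bin and carrier
group; bins with zero exposure are reported as missing, not zero.

`whole_window_hr` is the exponential event-rate-ratio estimator

    log HR = log[(D_c/T_c)/(D_n/T_n)],  se = sqrt(1/D_c + 1/D_n),

the maximum-likelihood estimate under one constant hazard per group and the
package's transparent stand-in for a whole-interval Cox fit: under
proportional constant hazards the two estimate the same quantity (a test
cross-checks against a lifelines Cox fit when lifelines is available). When
the marginal hazard curves cross inside the window, carrier excess mortality
before and after the crossing compensate and the estimate attenuates toward
HR = 1 — exactly the regime in which a whole-interval regression misses a
real, age-dependent genetic effect. An optional age window restricts events
and person-time to (a, b], enabling early-/late-window estimates whose signs
differ in the crossing scenarios. A group with zero events yields an
unbounded estimate, flagged via `HazardRatioEstimate.finite` rather than
raised, so callers can branch on it.

## What the simulations do and do not show

The generator realizes the model exactly: exponential lifetimes, perfect
haplotype ascertainment, no recombination within a lifetime, no age-dependent
baseline hazard, no competing risks, and a single censoring age. Passing
tests therefore demonstrate internal consistency of the estimators with the
model and the qualitative LD-confounding phenomena — not robustness to
Gompertz-type baselines, covariate effects, genotyping error, or left
truncation, none of which are modeled. Adding an age-dependent baseline
shared by all haplotypes would rescale the time axis without changing which
regimes occur.

## Numerical choices

- Proportion sums and round-trips validated to 1e-12; strict inequality
  constraints enforced with a 1e-12 margin.
- Trajectory grid 0.1 yr; crossing scan 0.5 yr; root tolerance 1e-6 yr.
- ODE oracle: DOP853, rtol 1e-10, atol 1e-13.
- File outputs carry full double precision; human-facing CLI tables round to
  4 significant digits.

## Known limitations

- Two loci only, dominant (carrier) coding; no diploid 0/1/2 genotypes.
- Constant per-haplotype hazards; mortality selection is the only force
  (no recombination, mutation, migration, or fertility differentials).
- The event-rate HR estimator assumes piecewise-constant group hazards; it
  is not a partial-likelihood Cox fit and has no covariate adjustment.
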
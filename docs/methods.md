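# Methods

## Genetic model

Susceptibility to female breast cancer is modelled through a rare
autosomal-dominant major locus and a polygenic background.  The major locus
carries three alleles — wild type, b1 (*BRCA1*), b2 (*BRCA2*) — in
Hardy–Weinberg equilibrium among founders and Mendelian transmission.  Its
six unordered genotypes collapse by dominance onto three carrier classes;
in the (negligibly rare) double heterozygote, b1 takes precedence.
Configuration states *carrier* probabilities; the implied allele frequency
is `f = 1 − √(1 − P(carrier))`.

The polygenic log-hazard `P(t) ~ N(0, σ²(t))` is approximated by the
hypergeometric polygenic model with N diallelic loci (default N = 3, seven
levels).  A founder's level r is Binomial(2N, ½); a child's level is the sum
of one Hypergeometric(2N, r_parent, N) draw per parent, which preserves the
founder distribution under random mating (verified exactly for N ≤ 4 in the
tests).  The standardized value `z_r = (r − N)/√(N/2)` has mean 0 and
variance 1, and multiplies the hazard by `exp(σ(t)·z_r)`.  A level is fixed
at birth; only σ(t) rescales its effect with age.  σ(t) is a step function
on the yearly grid between configured knots — no smoothness is invented
between them.

Ovarian cancer enters as a second disease with genotype-specific hazards and
no polygene.  Breast and ovarian onsets are conditionally independent given
genotype.  Males carry and transmit both genetic components but express no
penetrance here (male breast cancer is out of model and rejected by
validation).

## Constrained incidences

All hazards live on a yearly age grid 0–79 and are calendar-cohort specific
(five birth cohorts by default).  For each genotype g the per-level hazard
is `λ_{g,r}(t) = c_g(t)·exp(σ(t) z_r)`.  The scales are solved in one
forward pass per cohort that tracks the joint (genotype, level) distribution
among women still alive and cancer-free:

1. for each carrier genotype, `c_g(t)` is set so the survivor-weighted
   polygene average equals the configured carrier incidence at t;
2. the noncarrier average is solved by subtraction from the population
   constraint `λ_pop(t) = Σ_g π_g(t)·λ̄_g(t)` (π from the same pass), then
   its polygene scale the same way;
3. the survivor distribution is updated by `exp(−λ_breast − λ_ovarian)`
   (a configuration switch restricts attrition to breast only).

Both constraints therefore hold to machine precision at every age by
construction, and the noncarrier ovarian hazard is closed against the
population ovarian incidence identically.  A configuration whose carrier
burden exceeds the population incidence at any age is rejected with the
offending age named.

Within-carrier polygene rescaling is recomputed yearly against the
*surviving* polygene distribution, the literal reading of "the average among
carriers equals the carrier incidence curve"; the alternative (constraining
only at the founder-average level) would let selection drift the realized
carrier average below its target at older ages.

## Subtype end points

Breast cancer is partitioned into end points in three nested layers:
ER-positive vs ER-negative; within ER-negative, TN vs non-TN; within TN,
cytokeratin classes under three assay scenarios (both CKs tested → both+/
exactly-one+/neither+; only CK5/6 tested → +/−; only CK14 tested → +/−).
Every polygene level of a genotype shares the genotype's fractions, so end
points add back to the total hazard exactly.

Carrier fractions come from the built-in proportion tables: the *BRCA1*
ER-negative proportion by 10-year age band (0.93/<30 … 0.83/60–69, with the
≥70 band extrapolated from 60–69 and flagged as such), age-constant TN and
CK proportions.  *BRCA2* ER proportions use the general-population curve
(its case series is sparse and not significantly different from controls;
the printed band values are retained and can be enabled by a switch), and
*BRCA2* CK classes use the control values for the same reason.  Age bands
map to years as right-open intervals; <30 covers 0–29 and ≥70 covers 70–79.

The noncarrier fraction of each layer is *solved*, age by age, from the
population constraint for that layer (population ER-negative share from the
configured curve; population TN and CK shares from the control proportions),
so the survivor mixture reproduces the population subtype incidences
exactly.  An implied noncarrier share outside [0, 1] is a configuration
error naming the age and end point.

A marker panel maps to the finest end point it establishes: everything
untested → total hazard; ER− alone → ER-negative (deeper layers
marginalized); TN requires ER⁻/PR⁻/HER2⁻ all recorded negative; a positive
PR or HER2 on an ER⁻ tumour establishes non-TN; CK results without
established TN status are rejected as inconsistent.  PR/HER2 results with
unknown ER status are uninformative in this model and marginalize to the
total hazard.

Cumulative risks are polygene-averaged cause-specific first-cancer risks,
`E_r[Σ_t frac_e(t)·(S_r(t) − S_r(t+1))]` with S the survival function of
the level-r total breast hazard — so subtype risks partition the total risk
`1 − E_r[S]` exactly, and no competing non-breast mortality is applied
(risks are conditional on surviving to the horizon).

## Likelihood and posteriors

Each individual contributes a penetrance factor per joint state: survival
under the total breast + ovarian hazards to the first event or censoring age
(individuals with unknown observation age contribute nothing), the end-point
hazard of the observed panel at breast diagnosis, the ovarian hazard at
ovarian diagnosis, and a mutation-test factor.  There is no follow-up after
a first diagnosis.  Test sensitivity defaults to 0.70 (*BRCA1*) and 0.80
(*BRCA2*) with specificity fixed at 1, so a negative test leaves residual
factors 0.30/0.20 on the carrier states and a positive test is conclusive.

The pedigree likelihood is the exact sum over all joint assignments,
computed by sum–product variable elimination with a greedy smallest-scope
order (classic peeling on the family graph).  Carrier posteriors keep the
target's state and sum the marginal within carrier classes — one pass, no
per-class re-peeling.  Intermediate factors are renormalized with the log
scale accumulated, so likelihoods far below float range are handled.
Elimination is exact for any structure it is given, but inbreeding loops are
rejected in validation to keep the supported semantics explicit.  Pedigrees
listing one parent get the missing partner auto-created as an unobserved
founder censored at age 0 (contributing no information), shared by children
who share the listed parent.

## Simulator

The forward simulator mirrors the model exactly: founder states from the
Hardy–Weinberg × binomial prior (optionally clamped per founder, carriers as
heterozygotes), Mendelian and hypergeometric transmission, yearly-competing
breast/ovarian onset via `1 − exp(−λ)` per year, and subtype labels drawn
from the same layer fractions the likelihood uses.  For the exactly-one-CK
class, which single CK is positive is split by the single-assay marginal
excesses over the both-positive class.  What the simulator does **not**
emulate: non-cancer mortality, second primaries, screening/ascertainment
effects, measurement error in immunohistochemistry, and calendar trends
within a cohort — so recovery tests demonstrate internal consistency of the
generative law, not fidelity to any real registry.

## Default parameters

The bundled parameter set is illustrative and documented in
`src/brcapath/data/default_config.yaml` (rates per 100,000 person-years):
carrier probabilities 0.00128/0.00204; N = 3 polygenic loci with σ declining
from 1.65 at birth to 0.78 at 70+; a population breast incidence rising to
~335/100k at 75+ (scaled down up to 25% for earlier cohorts); a *BRCA1*
breast incidence peaking near age 45–50 (~3,200/100k) and a *BRCA2* curve
rising monotonically to ~3,000/100k; ovarian schedules giving roughly
30%/11% carrier risk by 70; and a population ER-negative proportion falling
from 0.55 (<30) to 0.25 (70+), whose incidence-weighted under-70 aggregate
is ≈0.36.  These magnitudes follow the published penetrance literature but
are *not* a transcription of any fitted parameter set; published headline
carrier probabilities were derived from fitted genotype-specific totals that
are external inputs here, so quantities sensitive to the total-incidence
scale (notably ER-positive cumulative risks) will differ under the defaults
while proportion-driven quantities (posterior shifts from marker status)
agree closely.

## Numerical choices and problem sizes

Ages are integer years; diagnoses occur at the start of the stated year.
Constraint solving is exact per year (no iteration); residual checks use
relative 1e-8.  Peeling-vs-enumeration equivalence is tested on 200 random
loop-free pedigrees with the exhaustive oracle capped at ≈2.4·10⁷ joint
states (members × loci combinations chosen accordingly); simulation
recovery uses 10,000 carrier cases.  Posterior normalization is enforced to
1e-12 and renormalized exactly.  Birth years outside the configured cohorts
take the nearest cohort with a warning; missing birth years take the most
recent cohort.

## Limitations

Single shared polygene across subtypes (subtype-specific or partially
correlated polygenes are not modelled); no risk-factor covariates; no
prostate/pancreatic/male-breast penetrance; no contralateral or
second-cancer modelling; no competing mortality; loop-containing
(consanguineous) pedigrees rejected rather than broken; probabilities are
only as good as the configured incidence curves.
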
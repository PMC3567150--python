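# Methods

## The model

All analyses rest on the repeated-records animal model

    y = X b + Z a + W pe + e

where `y` stacks longitudinal trait records (melanoma grade 0–5, grey
level L\* 0–100, vitiligo grade 0–3, speckling grade 0–3), `b` holds the
fixed effects, `a` the polygenic breeding values of every pedigree member
with Var(a) = A·V_POLY (A the additive relationship matrix), `pe` a
permanent-environment effect per recorded animal with Var(pe) = I·V_pe,
and `e` the residual with Var(e) = I·V_e.

Fixed effects are a stud-by-sex-by-measurement-year class factor, age at
measurement (in years = months/12, so the age coefficient is per year of
age), and — when the model includes the major loci — covariates for the
Grey (STX17) duplication coded GG = 0, Gg = 1 and for ASIP coded
additively AA = 0, Aa = 1, aa = 2 (a dominance code AA = 0, Aa = 1,
aa = 0 is available but off by default; in the source analysis it was
non-significant for every trait and dropped).  Because only grey horses
(GG or Gg) carry the traits, gg animals are never phenotyped and the
Grey-locus covariate is a two-level contrast whose regression coefficient
is directly the substitution effect α_STX17.

## Variance decomposition

A biallelic locus with additive value a, dominance d and allele
frequencies p, q contributes additive variance 2pqα², with
α = a + (p − q)d (α = a for the two-genotype Grey contrast).  Phenotypic
variance is V_P = V_POLY + V_STX17 + V_ASIP + V_pe + V_e, and the derived
proportions are repeatability R = (V_POLY + V_STX17 + V_ASIP + V_pe)/V_P,
permanent-environment share c² = V_pe/V_P, narrow-sense heritability
h² = (V_POLY + V_STX17 + V_ASIP)/V_P and its parts h²_POLY, h²_STX17,
h²_ASIP.  Allele frequencies default to counts over the animals in the
analysed data set; they can be overridden, and `decompose` accepts an
external V_P so that proportions can be formed against a reported
phenotypic variance.  Table output is rounded half-up to 2 decimals;
full precision is kept internally.

Bivariate fits report the polygenic correlation
r_POLY = G0₁₂/√(G0₁₁G0₂₂); the phenotypic correlation is composed as
r_P = r_POLY·√(h²₁h²₂) + r_e·√((1−h²₁)(1−h²₂)).

## REML estimation

Variance components are estimated by average-information (AI) REML on the
mixed-model equations, with a dense Cholesky factorisation of the
coefficient matrix at the problem sizes this package targets (pedigrees
up to a few thousand).  The restricted log-likelihood is evaluated
through the standard MME identity
−2ℓ = log|R| + log|G| + log|C| + y'Py + (n−p)·log 2π; log|A| comes for
free from the Mendelian-sampling variances (A = TDT' with unit-triangular
T).  Scores use the trace identities linking C⁻¹ blocks to tr(P·dV), and
the AI matrix is 0.5·F'PF with F the dV·Py working variates; both are
verified against finite differences of the likelihood in the test suite,
and the likelihood itself against a brute-force dense evaluation of the
projection-form REML criterion on small fixtures.

The iteration runs in an unconstrained parameterisation: scalar variances
on the log scale and each 2×2 covariance matrix (polygenic G0,
permanent-environment PE0, and the residual matrix when records are
paired) in log-Cholesky form.  AI updates therefore can never produce a
negative variance or an indefinite covariance matrix; a singular matrix
(zero variance, correlation ±1) is a flat tail of the transformed surface
rather than a constraint boundary.  Near-singular AI matrices are handled
with Levenberg–Marquardt damping, and any proposal that fails to improve
the likelihood falls back to an EM step, which is monotone.  Variances
are floored at 10⁻⁸ of the phenotypic variance to keep the MME
nonsingular.

Convergence requires |ΔlogL| < 10⁻⁶ together with either a maximum
relative component change below 10⁻⁵ or a likelihood that has stayed flat
for three consecutive iterations — the latter covers degenerate optima on
a likelihood ridge (e.g. a permanent-environment matrix estimated at
correlation 1), where the within-ridge coordinates are not identified and
never settle.  Default initial values are shares of the raw phenotypic
variance (0.3 polygenic, 0.2 permanent-environment, 0.5 residual,
covariances 0), deterministic by construction; `max_iter` defaults
to 200.  Standard errors come from the inverse AI matrix at convergence
(a pseudo-inverse along unidentified boundary directions), and
correlation SEs by the delta method.  Breeding values are BLUP solutions
of the MME at the converged components, with reliabilities
1 − PEV/((1+F)·V_POLY); exported EBVs are standardized to mean 0, SD 1
over the animals with records.

The bivariate residual covariance is estimable only when the two traits'
records pair one-to-one (`paired=True`); in this package's study design
greying is measured on young horses and the other traits on adults, so
records never pair and the residual covariance is structurally zero
(r_e = 0 in composed phenotypic correlations).

## Pedigree machinery

Inbreeding coefficients use Meuwissen–Luo-style path tracing
(F_i = ½·a(sire, dam) accumulated over common ancestors' Mendelian-
sampling variances), independent of the tabular method used for the dense
A matrix — the two must agree on diag(A) = 1 + F, which is property-
tested.  A⁻¹ is assembled sparsely by Henderson's rules with inbreeding.
Unknown parents are founders, unrelated to all prior animals and
non-inbred; no genetic-group modelling is attempted because the target
population's pedigree is effectively complete.  Topological-sort ties are
broken by input order so loading is reproducible.

## Genotype deduction

Coat colour constrains the Grey locus (coloured ⇒ gg, grey ⇒ not gg);
nuclear-family genotype elimination (Lange–Goradia style) then iterates
to a fixed point, and connected components of up to 10 animals are
additionally resolved by exhaustive enumeration of Mendelian-consistent
assignments, making deduction exact there (the enumeration bound is a
parameter).  An animal is deduced when its candidate set is a singleton;
measured genotypes are never overwritten, and any inconsistency raises an
error naming the family rather than resolving silently.  ASIP has no
colour rule and is deduced by Mendelian elimination alone.  Deduction is
monotone and idempotent, and on gene-dropped data with complete colour
information every deduced genotype must equal the simulated truth (this
soundness holds because the truth always remains inside every candidate
set).

## The synthetic-data generator

The generator emulates the structure of the motivating study — a closed
multi-generation stud population (~1,100 measured animals by default,
sires reused with mean family size ~6, dams ~2.3), six studs, nine
measurement years, repeated records — and emits exactly the statistical
structure the model assumes: Hardy–Weinberg founders and Mendelian gene
dropping at two unlinked loci; breeding values by the recursive
Mendelian-sampling scheme (founder u ~ N(0, G0), offspring
u = ½(u_s + u_d) + m with Var(m) = G0·(½ − ¼(F_s + F_d)), implying
Var(u) = A ⊗ G0); records that add the class effect, age trend, locus
effects, u, pe and e.  Only grey animals are phenotyped.  Stud-sex-year
class effects are drawn once per class from N(0, v_class); the source
study does not report this variance, so the default is 10% of V_P and it
is configurable.  Ages are sampled in months within the trait's window —
greying at 12–84 months, adult traits at 84–216; the 7-year boundary
(84 months) is inclusive on both sides, matching the overlapping "seven
years old and younger"/"and older" definitions.

Phenotypes are continuous even for graded traits; an optional
`round_to_scale` switch snaps values onto the ordinal grading grids as a
robustness stressor (the analysis fits linear models to the grades, so
rounding is deliberately not part of the default generating model).  The
four shipped trait configurations (`configs/lipizzan.yaml`) carry the
study's fixed-effect and variance parameterisations; per-dataset Grey
allele frequencies are set inside the published 0.85–0.89 range, with
0.885 for greying (the value consistent with the published greying
variance partition) and 0.85 elsewhere.  All four generator stages use
domain-separated deterministic RNG streams, so passing the same seed to
different stages can never correlate their draws.

What the generator deliberately does not emulate: nonlinear greying
trajectories, melanoma progression dynamics, ordinal measurement error,
genotyping error, selection or non-random mating, and missing-data
patterns correlated with phenotype.  Passing tests therefore demonstrate
the correctness and calibration of the estimation machinery under the
model's own assumptions, not robustness to the ways real observational
data violate them.

## Scenario analysis

Genetic correlations between trait pairs are estimated under three
scenarios: (1) a polygenic-only model on all genotyped animals, (2) the
model with STX17 (and ASIP where configured) as fixed covariates, and
(3) the polygenic model on the GG-homozygote subset (measured-or-deduced
GG by default; a strict flag restricts to measured).  A locus affecting
both traits inflates the scenario-1 polygenic correlation because the
unmodelled genotype signal is heritable and loads onto the breeding
values; scenarios 2 and 3 remove it, so the drop measures the pleiotropy
attributable to the locus.  This qualitative signature is verified on
synthetic data with a shared locus and zero true polygenic correlation.

## Problem sizes used in the tests

Dense-oracle equivalence uses ≤10-animal fixtures; parameter recovery
runs 50 replicates of a 600-member pedigree with ~3 records per animal
under the melanoma configuration; the pleiotropy scenario analysis uses
one 600-member study; estimator-consistency checks span pedigrees of 100,
300 and 900.  These sizes put every stochastic check within comfortable
desk-scale runtimes while leaving Monte-Carlo error well below the
assertion tolerances.

## Known limitations

- No dominance or epistatic polygenic variance, no genomic relationship
  matrices, no genetic groups, and no more-than-two-trait REML (pairwise
  analyses only).
- Probabilistic genotype imputation (peeling with genotype probabilities)
  is out of scope; deduction is hard-constraint propagation only.
- The residual covariance of genuinely paired records is supported only
  for exactly aligned record pairs.
- Approximate SEs (inverse AI, delta method) are asymptotic; on small or
  boundary-degenerate data sets they understate uncertainty.
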
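# Methods

## Genetic design and the observable gamete modes

`tetraqtl` models a *pseudotest backcross*: a fully heterozygous
multivalent (quadrivalent) tetraploid, carrying marker alleles M1..M4 and
QTL alleles Q1..Q4 on its four homologous chromosomes, crossed to a
homozygous tester.  Progeny genotypes equal the parental diploid gametes,
so each individual contributes one observed marker gamete genotype (one
of ten unordered pairs: four double-reduction homozygotes MkMk and six
heterozygotes MjMk) and one quantitative phenotype; the QTL gamete
genotype is latent.

Because quadrivalent pairing lets two sister chromatids enter the same
gamete (*double reduction*, frequency α at the marker), the 100 joint
(marker, QTL) gamete genotypes collapse into nine observable *modes*
g1..g9, classified by which locus shows double reduction and how many
recombinant chromatids the gamete carries:

| mode | double reduction | recombinants | cells × coefficient |
|------|------------------|--------------|---------------------|
| g1   | both loci        | 0            | 4 × 1/4             |
| g2   | both loci        | 2            | 12 × 1/12           |
| g3   | QTL only         | 1            | 12 × 1/12           |
| g4   | QTL only         | 2            | 12 × 1/12           |
| g5   | marker only      | 1            | 12 × 1/12           |
| g6   | marker only      | 2            | 12 × 1/12           |
| g7   | neither          | 0 or 2 (mix) | 6 × 1/6             |
| g8   | neither          | 1 or 2 (mix) | 24 × 1/24           |
| g9   | neither          | 2            | 6 × 1/6             |

Each of the 100 cells of the joint table carries exactly one mode label
and a fixed coefficient; per mode the coefficients sum to one, so any
probability vector g yields a valid joint distribution.  Modes g7 and g8
mix two formation configurations with different recombinant counts; the
expected number of recombination events per cell therefore involves the
corrections

    phi(r) = r^2 / (10 r^2 − 18 r + 9),      psi(r) = r / (3 − 2 r),

and the marker DR frequency, the QTL DR frequency and the recombination
fraction are read off the mode vector as

    α = g1 + g2 + g5 + g6,
    β = g1 + g2 + g3 + g4,
    r = ½ [ g3 + g5 + 2(g2 + g4 + g6 + g9) + 2 φ(r) g7 + (1 + ψ(r)) g8 ].

The r equation is implicit; its right-hand side has slope < 1 on
[0, 1/2], so the fixed point is unique whenever it exists
(`implied_r`, bisection to 1e−10).  A useful consequence of the mode
structure is the admissibility bound **r ≥ |β − α| / 2**: modes with
double reduction at exactly one locus always carry at least one
recombinant chromatid, so unequal double reduction at tightly linked
loci is impossible.  (Note on conventions: the sum g1+g2+g5+g6 occupies
the marker-DR rows of the joint table and therefore must be the *marker*
frequency α — some printed treatments swap the two sums; the package
keeps the table-consistent convention, under which α̂ equals the
observed marker-DR fraction, and exposes the swapped reading behind
`modes_to_params(..., convention="printed")` for auditing.)

## The chromatid-transmission mechanism

The corrections φ and ψ are not arbitrary: rewrite them as

    phi(r) = r² / (9(1−r)² + r²),        psi(r) = r / (3(1−r) + r),

and they are exactly the mixed-configuration proportions of a simple
mechanism: *each of the gamete's two chromatids transmits its parental
QTL allele with probability 1 − r, or one of the other three alleles
uniformly (r/3 each) after a recombination event.*  For example, a
matching heterozygote cell (M1M2, Q1Q2) arises either from two parental
chromatids, weight (1−r)², or from two reciprocally recombinant ones,
weight (r/3)²; the double-recombinant share is r²/(9(1−r)²+r²) = φ(r).
Working this mechanism through all 100 cells reproduces the entire mode
layout and yields closed-form mode frequencies
(`gametes.chromatid_modes`):

    g1 = α(1−r)²        g2 = α r²/3         g5 = 2α r(1−r)       g6 = 2α r²/3
    g3 = 2(1−α) r(1−r)/3                    g4 = 2(1−α) r²/9
    g7 = (1−α)[(1−r)² + r²/9]               g8 = 4(1−α)[r(1−r)/3 + r²/9]
    g9 = 2(1−α) r²/9

Under this mechanism the QTL double-reduction frequency is the derived
quantity β(α, r) = g1+g2+g3+g4, equal to α at r = 0 and close to α at
the study settings (β(0.3, 0.05) = 0.294).  The simulator draws from
these frequencies by default; the estimator uses them as its mixture
prior.  A general three-parameter constructor
(`simulate.construct_g(α, β, r)`) remains available for explicitly
unequal double reduction: it allocates DR-class masses with an overlap
that interpolates between coincidence min(α, β) under tight linkage and
independence αβ as recombination decouples the loci, splits each class
over its admissible recombinant counts binomially in a latent intensity
ρ, and solves ρ so the implied recombination fraction equals the target;
it attains the admissibility bound above and raises `FeasibilityError`
beyond it.

## Genotypic values and genetic effects

The ten QTL genotypic values decompose into an overall mean μ, additive
effects a1..a3 of Q1..Q3 relative to Q4 (a4 = −a1−a2−a3), and six
dominance interactions d12..d34 (see `quantgen`).  The decomposition is
a linear bijection; the package inverts it algebraically — μ is the
average of the four homozygote values, each a_k a homozygote contrast,
each d_jk the deviation of a heterozygote from its additive prediction —
so the round trip is exact to machine precision.  A dominance inverse
that is sometimes printed (e.g. d12 = μ12 − ¼(3μ33 + 3μ44 − μ11 − μ22))
does not invert the decomposition and is rejected by the round-trip
test.

Null hypotheses are linear subspaces of the ten-dimensional mean space:
all means equal (no QTL, 1 free parameter), no additive effects
(homozygote means coincide, 7), no dominance (means additive in
(μ, a1..a3), 4), or one named effect pinned to zero (9).

## Estimation

The phenotype model is a ten-component normal mixture: individual i with
marker genotype l has density Σ_j π(j | l) N(y_i; μ_j, σ²), with π the
conditional QTL-genotype probabilities from the joint table.

**Marker double reduction.** α̂ is the observed fraction of
double-reduction marker genotypes — the exact MLE, and an identity the
mode-count M-step preserves at every iteration (the DR-marker rows of
the joint table contain exactly the modes g1, g2, g5, g6).

**Recombination fraction and genotypic values** (default,
`EMOptions(mode="profile")`).  The likelihood is profiled over r on a
grid of [0, 1/2] (step 0.02, warm-started sweep), fitting the genotypic
values and σ² at each candidate r by an inner EM with the mixture
weights held fixed; the best grid point is then refined locally (7
points across ± one grid step, inner tolerance 1e−7 on the maximum
parameter change, at most 500 inner iterations).  The inner EM is a
standard fixed-weight normal-mixture EM: responsibilities by Bayes'
rule in log space, responsibility-weighted means (or a weighted
least-squares projection onto a null-constraint design), and the
responsibility-weighted mean squared residual for σ², floored at
1e−8 × var(y) against component collapse.  β̂ is reported from the
posterior-expected mode counts of the final fit.

**Why a profile rather than one joint EM.**  The package also implements
the textbook alternative (`mode="em"`): a single EM that treats all nine
mode frequencies as free multinomial parameters, updating them by
posterior-expected mode counts, the rates by the linear sums and the
implicit-r fixed point (or a one-step φ/ψ substitution,
`r_update="one_step"`), and means/σ² as above.  Its joint
marker-plus-phenotype log-likelihood is provably non-decreasing, and the
update formulas match the closed forms of the method.  But the
9 + 10 + 1-parameter likelihood is extremely flat: in our simulations at
the study conditions (n = 400, α = 0.3, r = 0.05, H² = 0.4) this EM
drifts along a ridge to label-scrambled optima *even when started at the
true parameters*, inflating r̂ several-fold.  Keeping the mixture
weights on the two-parameter mechanism surface removes the drift; the
profile fit recovers the study cells at n = 400 to within Monte-Carlo
error.  The free-mode EM remains available for segregation-only
analyses and for auditing.

**Small-sample bias.**  At n ≤ 200 the profile MLE of r retains a
right-skewed sampling distribution (the estimate cannot fall below 0 but
can drift up when noisy genotypic-value estimates blur the posterior),
giving an upward bias of roughly +0.02–0.03 at r = 0.05, H² = 0.4.  An
oracle variant that holds the genotypic values and σ² at their true
values is unbiased with replicate SDs of 0.050/0.039/0.031 at
n = 100/200/400 — the data-driven fit approaches this as n grows.  The
replication tests compute and report the honest data-driven numbers.

**Traditional model without double reduction**
(`force_no_double_reduction`).  Restricts the mode vector to g7..g9
(α = 0), models only heterozygote QTL genotypes, and drops
double-reduction marker individuals (they have zero probability under
this model) with a warning.  This is the misspecification analysis: on
data with α = 0.3 its recombination estimate collapses toward 0 (far
larger bias than the full model's), its residual variance absorbs the
genotypic variance of the misassigned individuals, and the
additive/dominance decomposition is unestimable because homozygote
genotypic values do not exist in the model.

## Hypothesis tests

QTL presence is tested by the likelihood ratio between the full fit and
the single-normal null (all genotypic values equal; its constrained fit
coincides with the closed-form normal MLE).  The mixture LR violates the
regularity conditions for a χ² reference, so the critical value is
empirical: phenotypes are permuted against markers B times (default
1000), the statistic is recomputed with the identical fit procedure, and
the test rejects when fewer than k = ⌊level·(B+1)⌋ permuted statistics
reach the observed one.  This rank rule is exactly level-α under
exchangeability for any B with k ≥ 1 (B = 19 at level 0.05), which is
what the calibration test exploits at a reduced permutation count; the
reported p-value is (1 + #{perm ≥ obs}) / (B + 1).  The null fit is
permutation-invariant and computed once.

Additive (3 df), dominance (6 df) and single-effect (1 df) tests
compare the full fit with the corresponding constrained fit; their
default reference is χ² with one degree of freedom per constraint — a
pragmatic convention, since the constrained means remain inside one
mixture family — with the same permutation scheme available as an
option.  Nested fits share the r grid, so statistics are nonnegative up
to optimizer noise; values above −1e−6 are clamped to zero with a
warning.

## Simulator and study conditions

`simulate_dataset` draws (marker, QTL) pairs multinomially from the
100-cell joint table and adds Gaussian noise to the genotypic value of
the latent QTL genotype.  The residual variance is set from the
heritability as σ² = σ_g²(1 − H²)/H², where σ_g² is the variance of the
ten genotypic values under the QTL gamete distribution (β/4 per DR
homozygote, (1 − β)/6 per heterozygote) at the simulated β.  The
replication defaults are the reference study conditions: overall mean 1,
additive effects 0.6, dominance effects 0.5, heritability 0.1 or 0.4,
α ∈ {0.05, 0.15, 0.3}, r ∈ {0.05, 0.25}, n ∈ {100, 200, 400}.
`replicate_study` spawns independent child seeds from the master seed
(`numpy.random.SeedSequence`), records per-replicate convergence, and
summarises replicate means and SDs over converged fits; an optional
label-alignment step (best allele permutation against the truth) is off
by default and reports whether it changed anything.

What the generator does **not** emulate: partially informative or
dominant markers, genotyping error, multiple linked QTLs, multi-marker
chromosomes, or non-normal residuals.  Passing tests therefore
demonstrate correctness of the method under its own model assumptions,
not robustness to the ways real marker data violate them.

## Numerical choices

- Profile grid step 0.02 with ±1-step refinement: r is resolved to
  ~0.007 before the inner refinement, far below the sampling SD of r̂ at
  the study sizes; permutation presets use a coarser grid (0.1–0.125)
  since test validity only requires an identical procedure on observed
  and permuted data.
- Inner EM convergence: maximum absolute parameter change < 1e−7
  (grid sweep relaxed to 1e−4; the incumbent is re-converged tightly).
- Variance floor 1e−8 × var(y); floor activations are recorded in the
  fit result.
- Zero mode frequencies are absorbing under the multinomial EM, so the
  free-mode variant starts from 0.98·g0 + 0.02·uniform.
- Inadmissible mode vectors (no r root in [0, 1/2]) clamp r̂ to the
  boundary with a warning in the rate map; the strict solver raises.
- Degenerate inputs: a zero genetic variance warns and returns σ² = 0;
  markers absent from the model's support raise immediately.
- All randomness flows through explicit integer seeds; replicate seeds
  are spawned, never reused.

## Known limitations

- Single-marker association only; no interval mapping or map
  construction.
- Fully informative codominant markers assumed; ten distinguishable
  gamete genotypes per locus.
- The upward small-sample bias of r̂ discussed above; no analytic
  standard errors (precision is assessed by replicate SDs).
- The three-parameter mode constructor is one admissible family among
  many consistent with (α, β, r); only the chromatid surface is
  mechanism-derived.
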
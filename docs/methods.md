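# Methods

## Design and genetic model

The design starts from two inbred lines fixed for alleles *A* and *a* at a
putative imprinted QTL (and for alleles 1 and 2 at every marker).
Reciprocal F1 crosses yield the ordered heterozygotes *Aa* (A maternal) and
*aA* (A paternal); the four mother × father combinations of F1s — indexed
t = 1 (Aa×Aa), 2 (Aa×aA), 3 (aA×Aa), 4 (aA×aA), mother written first —
produce four F2 families.  Each family segregates the ordered
configurations k = 1 (AA), 2 (Aa), 3 (aA), 4 (aa), maternal allele first.

The 16 cell means are parameterised as μ = Xβ with a 16 × 16 orthogonal
design matrix.  Row (t, k) is

```
[1, x_m, x_p, x_m x_p, z_a, z_d, z_i, x_m·z, x_p·z, x_m x_p·z]
```

where x_m = +1 if the mother is *Aa* (−1 if *aA*), x_p likewise for the
father, and the configuration scores are z_a = (+1, 0, 0, −1),
z_d = (−1, +1, +1, −1), z_i = (0, +1, −1, 0) for (AA, Aa, aA, aa).  Scoring
homozygotes −1 (rather than 0) in z_d keeps every non-mean column orthogonal
to the mean, so μ ("mu") is always the unweighted mean of the 16 cells, the
decomposition inverts in closed form (effect = column·means / ‖column‖²),
and the 15 non-mean parameters split into exactly the intended seven groups
(F1 imprinting main effects and interaction; F2 additive/dominance/
imprinting; three blocks of cross-generation interactions).  Any published
variant of this coding that differs by column scaling or sign rescales
individual effect estimates but leaves every likelihood-ratio test
unchanged; the coding used here is recorded above so estimates are
interpretable.

Under Mendelian segregation each configuration has frequency ¼ within a
family; with equally sized families the genetic variance is the variance of
the 16 enumerated cell means with weight 1/16, which by orthogonality is
Σ βⱼ²·mean(cⱼ²).  For the reference truth vector used throughout the
simulation study (i₁ᵐ = i₁ᵖ = 0.15, i₁ᵐᵖ = 0.1, a = 0.3, d = 0.6,
i₂ = 0.2, all nine interactions 0.04) this gives V_G = 0.4896, hence
residual variances σ² = V_G(1−h²)/h² = 4.4064 at h² = 0.1 and 0.7344 at
h² = 0.4.

## Configuration probabilities

All four F1 parents are complete heterozygotes with the same known linkage
phase (1–A–1 / 2–a–2 inherited intact from the inbred grandparents), so a
parent transmits the three-locus gamete (l, q, r) with probability given by
the product of the two flanking recombination fractions, e.g.
P(1, A, 1) = (1−r₁)(1−r₂)/2.  The Haldane map function (no interference)
converts cM to recombination fractions; r = r₁ + r₂ − 2r₁r₂ across the
interval.  Kosambi is available as an option.

The posterior over the four ordered configurations given an individual's
unordered flanking genotypes is obtained by enumerating all ordered
(maternal gamete, paternal gamete) pairs consistent with the observed
genotypes, weighting by the product of independent maternal and paternal
gamete probabilities, and summing by (maternal QTL allele, paternal QTL
allele).  A missing flank is marginalised (it matches every allele); two
missing flanks give the uniform prior.  The enumeration is validated
against a meiosis-simulation oracle (10⁶ simulated gametes per parent,
frequencies tabulated within each observed marker class).

**A structural property with major consequences.**  Because the F1 mother
and father are genetically identical and their gametes are exchangeable,
every consistent assignment of a gamete pair to (mother, father) is exactly
as probable as its swap.  Hence P(Aa) = P(aA) for *every* individual: the
unordered marker data contain no directional information about the parental
origin of an F2 heterozygote's alleles.  Two consequences follow.

1. The likelihood is invariant under jointly flipping the sign of the
   parent-of-origin block (i₂, i₁ᵐ×i₂, i₁ᵖ×i₂, i₁ᵐᵖ×i₂): those parameters
   are identified only up to a common sign, and their replicate-averaged
   estimates are near zero even when the fit is otherwise excellent.
2. The magnitude of that block is identified only through the bimodality
   of the within-cell mixture, whose Fisher information is of order
   (i₂/σ)⁴ — negligible at realistic effect sizes.  Tests whose constraint
   sets include these directions (Tests 1 and 3–6 below) therefore behave
   conservatively: their chi-square reference distribution overstates the
   effective degrees of freedom, pushing null p-values toward 1.  Type-I
   error remains controlled (measured null rejection rates 2–6% at the 5%
   level), but null p-values are non-uniform for those tests; Test 2, built
   purely from family-mean contrasts, is exactly calibrated.

The F1-expressed imprinting parameters (i₁ᵐ, i₁ᵖ, i₁ᵐᵖ) and the a/d
cross-generation interactions involve only family membership and the
additive/dominance scores and are fully identified.

## Mixture likelihood and EM

The phenotype model is y_{ti} ~ Σ_k ω_{tik} N(μ_{tk}, σ²) with one residual
variance shared across all 16 cells.  A shared σ² keeps the degrees of
freedom of the test hierarchy at 13/3/10/3/3/3 and matches standard
interval mapping; a configuration-specific variance would confound
variance heterogeneity with the mean structure at these sample sizes.

EM under a constraint set C (effects forced to zero; never μ):

* E-step: posterior P_{tik} ∝ ω_{tik} φ(y_{ti}; μ_{tk}, σ²), computed in
  log space.
* M-step: with cell weights W_{tk} = Σ_i P_{tik} and weighted cell sums
  S_{tk}, the free coefficients solve the weighted least-squares system
  (X_FᵀWX_F)β_F = X_FᵀS over the free columns X_F, then μ = X_Fβ_F and
  σ² = Σ P_{tik}(y_{ti} − μ_{tk})²/N.  With no constraints this reduces to
  μ̂_{tk} = weighted cell means.

Initialisation uses the single-normal fit perturbed by ±0.5 SD alternating
cell offsets, plus four seeded random starts; each start is burnt in for 25
iterations and the best is run to convergence (|ΔlogL| < 10⁻⁸, at most
2000 iterations).  The observed-data log-likelihood is non-decreasing
across iterations (asserted in tests from the per-iteration trace).
Degenerate cases: with the true configurations supplied as priors the EM
fixed point equals the closed-form weighted least-squares solution; with
all 15 effects constrained the fit is the single-normal MLE and no EM is
run.  An empty family combined with free F1-imprinting contrasts is
rejected as non-identifiable.

## Test hierarchy and scanning

Six standard nulls: (1) all 13 imprinting-related terms zero; (2) the three
F1 terms; (3) i₂ plus all nine interactions; (4)/(5)/(6) the maternal /
paternal / joint interaction blocks.  LR = 2(logL_full − logL_null),
clipped at zero, referred to χ² with df = number of extra constraints; no
boundary corrections (effects are interior, sign-unrestricted).

The existence scan tests "all 16 means equal" (a position-independent
single-normal null) against the full model on a grid of every marker plus
every 2 cM (default) within intervals.  Genome-wide thresholds come from
permutation: phenotypes are shuffled jointly across all individuals by
default — consistent with the existence null, which includes between-family
differences — with a within-family option for users who attribute family
differences to non-QTL causes; the threshold is the empirical (1−α)
quantile of per-permutation maximum LRs.  Peak calling reports run maxima
above the threshold, merging maxima closer than 30 cM (default) or not
separated by a sub-threshold valley; ties break leftmost.

## Simulator

Gametes are sampled by per-interval crossover draws (Haldane, no
interference) along each chromosome's loci with the QTL inserted as a
hidden locus; maternal and paternal meioses are independent; the ordered
configuration is recorded as hidden truth.  Phenotype = cell mean + N(0, σ²).
The reference study design is 10 evenly spaced markers on 200 cM
(≈22.2 cM spacing) with the QTL at 35 cM (inside the second interval),
four families of equal size, and three truth scenarios: I (all 15 effects
as above), II (F2-expressed imprinting and all interactions zeroed), III
(only a = 0.3, d = 0.6).  The simulator emulates an experimental mouse
intercross in its design but idealises real data: no genotyping error, no
missing genotypes, normal residuals, a single QTL, equal family sizes, and
no polygenic background — so passing tests demonstrate correctness of the
method under its own assumptions, not robustness to those violations.

## Study sizes and reproducibility

The power/type-I studies run 100 replicates per cell (all tabulated rates
are integer percentages) at α = 0.05, with tests evaluated at the true QTL
position; a full-scan protocol is available but much more expensive.  Null
calibration checks use 400 replicates at 150 individuals per family.  All
randomness flows from a single user seed through named `SeedSequence`
substreams (simulation, EM restarts, permutations), making every scan,
fit and power table bit-reproducible.

## Known limitations

* The parent-of-origin block is sign-unidentifiable and nearly
  magnitude-unidentifiable from unordered markers (see above); designs that
  add sex-specific maps or ordered genotypes would be needed to estimate
  i₂ and its interactions with useful precision.
* Autosomes only; no X-chromosome model, no epistasis between distinct
  QTLs, no gene–environment interaction, no multi-QTL joint fits.
* Standard errors are reported as Monte-Carlo SDs across replicates, not
  from the information matrix.
* Map construction is out of scope: a linkage map is an input.
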
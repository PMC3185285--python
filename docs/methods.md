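# Methods

## Trait model and likelihood

Continuous traits evolve on a rooted phylogeny with branch lengths in
expected substitutions per site under Brownian motion (BM). For tips *i*,
*j* the BM covariance is `V[i,j]` = summed branch length shared by their
root-to-tip paths; Pagel's λ ∈ [0, 1] multiplies the off-diagonal
(λ=0 ≙ star phylogeny, λ=1 ≙ the tree taken at face value). Values of λ
above 1 are rejected: the interpretation used throughout is the
star-to-tree interpolation, and V_λ can lose positive-definiteness beyond 1.

Bivariate fits use the matrix-normal GLS likelihood with design `X = [1]`
(constant-variance random walk) or `X = [1, root-to-tip length]`
(directional random walk; rejected as unidentifiable when the tree is
ultrametric to 1e−9). Estimates are the closed forms
`B̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹Y`, `Σ̂ = EᵀV⁻¹E/n` (ML, not REML — consistent with
the profile likelihood), and
`lnL = −½[np·ln2π + p·ln|V| + n·ln|Σ̂| + np]`.

**λ profile.** λ̂ maximizes the profile likelihood over [0, 1]: a 21-point
grid scan followed by bounded scalar refinement in the bracketing interval
(tolerance 1e−6); exact ties resolve to the smaller λ.

**λ test.** LR = 2(lnL(λ̂) − lnL(λ=0)) referred to χ²₁. The null value
λ=0 lies on the boundary, so a plain χ²₁ reference is conservative; the
package keeps the plain reference deliberately, since the decision
procedure it feeds is defined in terms of it. For bivariate screens a
single λ is shared by both traits.

**Covariance test.** With λ fixed at 1, LR compares Σ free vs Σ₁₂=0
(the constrained bivariate likelihood separates into two univariate fits),
referred to χ²₁. The ML correlation ρ̂ of this fit equals the
through-origin correlation of independent contrasts — the contrasts are an
orthonormal whitening of V restricted to the complement of the mean — and
the test suite asserts the identity to 1e−6 on random trees. Exactly
collinear traits cap LR at +∞ with a warning rather than erroring.

**Model-kind policy.** `model="auto"` fits both mean structures and keeps
the higher raw log-likelihood (no parameter-count penalty), falling back to
the constant model on ultrametric trees. Since the constant model nests in
the directional one, "auto" effectively selects directional whenever it is
identifiable; the selected kind is recorded on every fit and screen row.
The standalone covariance test defaults to the constant model.

**Routing.** Per gene: if the λ-test p ≥ α (default 0.05; strict `<`
sends the other way), phylogenetic correction is deemed unnecessary and an
ordinary Pearson correlation is reported (R² and its two-sided t-test p on
n−2 df); otherwise the covariance-test p is reported. Exactly one branch
is populated per gene, mirrored in the NA pattern of the emitted tables.

## Contrasts and polytomies

Felsenstein's pruning: at a cherry with (adjusted) lengths b₁, b₂ the
standardized contrast is (x₁−x₂)/√(b₁+b₂), the ancestral value the
1/b-weighted mean, and the parent edge grows by b₁b₂/(b₁+b₂). The bundled
tree's basal trifurcation (and any other polytomy) is resolved
deterministically by grouping the first two children in input order under a
zero-length branch — this leaves V unchanged and yields exactly n−1
contrasts. A cherry whose two (adjusted) branch lengths sum to zero raises
an error regardless of trait values: the contrast divisor must be positive.

## Contrast multiple regression

Species-level variables (response, TE, covariates) are Box-Cox transformed
before contrasts: one power per variable fitted by profile likelihood over
[−3, 3] on the pooled species-level values, with a (1 − min) shift first
when values are non-positive (shift recorded). Per gene, contrasts of the
response and covariates are stacked with the (gene-shared) TE contrasts;
each row is sign-flipped so its TE contrast is non-negative (through-origin
convention; the fit itself is invariant except through the set-level
columns). The OLS design has no global intercept: TE contrast, two
gene-set indicator columns, TE × focal-set interaction, then covariate
contrasts. Each effect gets a Type-III F test against the OLS residual;
with 22 genes × 11 contrasts and 5–6 columns the denominator df is
236–237. (Published tables of this design sometimes show other df
accountings from mixed-model software; this package reports its own OLS df
and documents them here.)

## Codon bias

ENC follows Wright: per amino-acid family with k synonyms and n ≥ 2
observed codons, F̂ = (n·Σp̂ᵢ² − 1)/(n − 1); F̂ is averaged within
degeneracy classes (9 two-fold families, Ile, 5 four-fold, Leu/Ser/Arg
six-fold) and ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, capped at 61. An
absent or n<2 Ile class is imputed as F̄₃ = (F̄₂+F̄₄)/2 (Wright's
recommendation, CodonW-compatible); any other unusable class leaves ENC
undefined. GC3 is computed over **all** retained sense codons (not the
synonymous-only GC3s variant; the two are one flag apart if ever needed).
CDS hygiene: in-frame triplets, non-ACGT triplets and trailing partial
codons dropped, internal stops dropped with a warning (cleaned alignments
can contain artifacts). The genetic code is fixed to the standard nuclear
table.

## Cramér–von Mises matching

T = nm/(n+m)² · Σ over pooled sample points of (F̂ₐ−F̂_b)², EDFs evaluated
at every pooled point (tied values contribute once per copy at their common
EDF height). Because per-gene samples are tiny (12, or 5 on the subgroup),
p-values are permutation-based by default (9999 label permutations, seeded,
add-one correction; fewer than 99 is an error), with scipy's asymptotic
variant available for cross-checks. Matching computes the full p matrix
once and assigns greedily by descending p (ties: lexicographic on gene
ids), which reproduces best-match-with-conflict-resolution and is
independent of input iteration order. The initial candidate shortlist is a
curated input, not computed. No optimal-assignment variant is offered —
the greedy rule *is* the procedure being reproduced.

## Resampling and enrichment

Bootstrap CIs for mean correlation coefficients are percentile (2.5/97.5)
over 10,000 resampled means (r is bounded in [−1,1] and skewed, so
normal-theory CIs are avoided); the between-set test independently
resamples both groups and reports p = (#{mean_control ≤ mean_focal}+1)/(B+1).
Slope comparisons use a pooled-variance two-sample t test (Welch optional).
Fisher's exact two-sided p uses the minimum-likelihood rule — the sum of
hypergeometric probabilities of margin-fixed tables no more probable than
the observed one — which gives 0.012 for the (6,5,0,11) worked example.
No multiple-testing correction is applied across the per-gene screens by
default (a Benjamini–Hochberg flag exists for users).

## Synthetic studies

The generator reproduces the study design with known ground truth:

* **Tree**: the bundled 12-species phylogeny, or pure-birth trees (Yule,
  exponential waits; tips extended by the censored wait to the next event
  so terminal branches are positive) for large-n recovery checks.
* **TE abundance**: geometric BM — log TE with root ln(20 Mb) and rate
  0.25 per unit branch length, giving ≈10–40 Mb across tips, the realistic
  span of euchromatic repeat content, while staying positive.
* **Gene panel**: 11 focal + 11 control genes; per gene, the ω-like trait
  is a_g + b_set·(TE − TE̅) + BM noise (rate 0.004, tip SD ≈ 0.05 around a
  0.15 baseline), and the ENC-like trait likewise (rate 12, tip SD ≈ 3
  around 45, clipped to [20.5, 61]). Power analyses switch on
  b_focal = −0.02 ω/Mb or −0.5 ENC/Mb with controls at zero.
* **Sequences**: per gene × species, codons are drawn with within-family
  usage weights exp(−s·rank); s is calibrated by bisection so the
  probability-limit ENC hits the species' target. Amino-acid composition is
  uniform over the 18 degenerate amino acids with Met/Trp at 5% total, so
  every degeneracy class is exercised. Traits, not sequences, carry the BM
  signal — there is no substitution-model simulation along branches.

Per-gene random streams are seeded by hashing (master seed, gene id), so
panels are reproducible under gene-list reordering, and a study directory
round-trips byte-identically. What passing tests show is therefore internal
consistency under the generator's linear-Gaussian assumptions; real data
add alignment error, non-BM trait evolution, ω estimation noise and
selection on codon usage that the generator does not emulate.

## Problem sizes and determinism

The validation suite uses: 50 random 12-tip trees for the GLS/contrast
identity; 100 replicates of 128-tip trees for λ recovery (mean λ̂ within
[0.4, 0.6] of the true 0.5); 1000/200 replicates for covariance-test
calibration/power; 2000 seeds × 499 permutations for CvM null uniformity;
50 replicates each for end-to-end enrichment power and null rate; 100/60
for interaction recovery/calibration. All simulations are fully
deterministic given their seeds; `scripts/acceptance.py` derives every
stream from its single `--seed`.

## Known limitations

* Only BM-based models: no Ornstein–Uhlenbeck, multi-rate, or Bayesian
  machinery; λ is the single tree transform.
* The λ-test's χ²₁ reference ignores the boundary null (conservative).
* OLS contrast regression only; no mixed-effects error strata.
* ENC is the sole codon-bias measure (no CAI/RSCU/expression weighting).
* Codon-model (dN/dS) estimation itself is out of scope: ω, dN, dS enter
  as input tables, and the path-labeling utility only prepares
  foreground-tagged trees for external codon-model tools.
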
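# Methods

This note documents the statistical model behind `randsig`, the numerical
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## 1. Signature association: nominal and empirical p-values

A signature is a gene set evaluated against a cohort of expression profiles
with right-censored survival.  Association is measured by:

* **PC1/median stratification.**  The signature's expression submatrix is
  gene-wise mean-centered (no variance scaling) and its first principal
  component computed by SVD.  Samples are split at the median of their PC1
  scores; scores exactly at the median go to the lower group, and labels are
  canonicalized so the group of the first sample is 0, which makes the split
  invariant to the arbitrary sign of a singular vector.  Degenerate cases
  (no signature gene in the cohort, constant submatrix, an empty side of the
  split) raise errors rather than guessing.

* **Cox score test.**  The nominal p-value is the two-sided score test of the
  binary group covariate in a proportional-hazards model, which is exactly
  the log-rank test.  This choice (over Wald or likelihood-ratio) is
  deliberate: it is closed-form, has no convergence failure modes on the
  tens of thousands of permuted stratifications the pipeline evaluates, and
  is the classical test for a two-group survival comparison.  The
  implementation is a vectorized numpy log-rank (ties handled by the
  hypergeometric variance) with survival order precomputed per cohort; it is
  cross-checked against `lifelines.statistics.logrank_test` in the tests.

* **Empirical p-value.**  The group labels are shuffled uniformly `B` times
  (outcome fixed), the nominal p recomputed each time, and the observed value
  joined with the `B` permutation values into one family of `B + 1` p-values
  that is Benjamini–Hochberg adjusted jointly (step-up,
  `p_(i) <- min_{j>=i} p_(j)·m/j`, `m = B + 1`).  The empirical p-value is
  the fraction of permutation *adjusted* values less than or equal to the
  observed adjusted value, ties included.

### Calibration of the empirical p-value

Because BH adjustment creates blocks of tied adjusted values and ties count
toward the numerator, the empirical p-value is **valid but conservative**,
not uniform, under the null: for an outcome-independent cohort,
`P(p_emp <= t) <= t` (up to the 1/B grid), while its mean sits near 0.65
rather than 0.5 (measured by simulation of i.i.d. uniform families).  The
test suite asserts exactly this one-sided validity.  The selection step only
uses the extreme event `p_emp = 0` (the observed adjusted value strictly
below every permutation's), for which the conservatism is irrelevant.

Nominal p-values that underflow to exactly zero (extreme separations) are
floored at the smallest positive normal float before BH adjustment.

## 2. Mining significant random signatures

For each template set the miner draws `n` signatures of the template's size
uniformly without replacement from the cohort's gene universe — the loaded,
harmonized cohort defines "all genes", since a signature must be evaluable on
the cohort.  Each random signature gets its own permutation seed derived
deterministically from (stage seed, signature index), so results do not
depend on evaluation order.  Selection keeps signatures with
`p_emp <= 0` and `log10 p_nom <= -10`, both non-strict, both configurable;
the log threshold is interpreted in base 10, the convention for "log nominal
p" cutoffs in this literature.

## 3. Network diffusion and the permutation call

Occurrence scores `S_i` count the selected signatures containing gene `i`.
Scores are smoothed with the heat kernel of the weighted graph Laplacian
`L = D − W`:

    K_β = exp(−βL),   S_β = K_β S.

Because `L` is symmetric with zero row sums, `K_β` is symmetric, entrywise
nonnegative, and has unit column sums — diffusion redistributes score mass
without creating or destroying it (`Σ S_β = Σ S`, asserted to 1e-8).  The
kernel is the exponential of the **negative** Laplacian; exponentiating `+L`
would amplify rather than smooth and grows without bound with graph size,
which is why this package standardizes on the bounded heat kernel.  β
defaults to 0.3, the bandwidth reported to perform best for breast-cancer
expression data in the diffusion-kernel literature; larger β spreads scores
to more distant nodes.

Realization: for graphs up to 3000 nodes the kernel matrix is formed by
eigendecomposition of the symmetric Laplacian (`(V·e^{−βλ})Vᵀ`, re-symmetrized
and clipped at zero to remove round-off); larger graphs use
`scipy.sparse.linalg.expm_multiply` as a matrix-free action.  Both paths are
tested against a dense `scipy.linalg.expm` oracle.  Genes absent from the
network are isolated nodes: the kernel acts as the identity on them, and they
remain eligible for calling.

The permutation null permutes a score vector across gene positions and
re-applies the kernel; gene `j`'s permutation score is the fraction of
replicates whose value at position `j` is `>=` the observed `S_β(j)`.  Two
null modes exist: the default permutes the already-diffused `S_β` (replicates
`K_β · perm(S_β)`), and `raw-scores` permutes the raw `S` instead.  The
default follows the formula-as-written convention; the alternative is the
more conventional null, and on the identity kernel the two coincide.  The
`>=` comparison uses a tolerance of `1e-9·(1+|S_β(j)|)` so exact ties (e.g. a
constant score vector, which must yield permutation score 1 everywhere) are
not broken by floating-point noise.  Calling keeps permutation scores
strictly below α = 0.05 and ranks by (permutation score ascending, diffusion
score descending, gene id ascending).

## 4. Pathway scores

For pathway `P` and called gene set `SG`, only `P ∩ SG` contributes.  With
`μ_N(g)`, `μ_~N(g)` the per-gene phenotype means (N = good prognosis,
~N = poor), each poor-prognosis patient `p` receives two expression-weighted
squared-deviation sums, `Σ e·(e − μ_N)²` and `Σ e·(e − μ_~N)²`.  The weights
`e[g,p]` must be nonnegative; cohorts on a log-ratio scale are shifted by
their global minimum (logged) before weighting.  The separation test is a
paired two-sided t-test on the per-patient differences (both scores are
defined on the same patients); an unpaired Welch mode is exposed.

**Caveat:** the two scores are not exchangeable under a null cohort.  Each
poor-prognosis patient contributes to `μ_~N` but not to `μ_N`, so the
deviation from the own-phenotype mean is systematically the smaller one and
the paired test rejects far above its nominal level even without any
phenotype effect (≈30–45% at p < 0.05 in simulation), while the Welch mode is
extremely conservative because the two scores are almost perfectly correlated
per patient.  Separation p-values should therefore be read as a comparative
ranking of pathways, not as calibrated error rates; the test suite pins the
direction of this bias.

## 5. Exact rank-sum inference

The rank-sum statistic is kept on the Mann–Whitney count scale,
`W = #{(x, y) : x > y} + ½·ties ∈ [0, n·m]`.  With no pooled ties the
p-value comes from the exact null pmf computed by the standard recurrence
`N(u; n, m) = N(u−m; n−1, m) + N(u; n, m−1)` (float64 counts, exact for
`n + m ≲ 50`, verified against exhaustive enumeration and
`scipy.stats.mannwhitneyu(method="exact")`).  With ties the test falls back,
with a log message, to the midrank normal approximation with tie correction
and continuity correction — the same fallback R's `wilcox.test` takes.  For
n = m = 10 the exact upper tail at W = 75 is 0.0315064; the tie-corrected
asymptotic path for data containing two tied pairs gives 0.0319111, which is
the value an asymptotic software path prints as 0.03191.  The bootstrap
utility resamples both groups with replacement (sizes fixed), recomputes the
tie-tolerant one-sided p per replicate, and reports all replicates and their
median.

## 6. Synthetic data: what it emulates, and what it does not

`SyntheticSpec` defaults describe the desk-scale study used throughout the
tests: 500 genes × 200 samples; a 25-gene driver module sharing a latent
factor with pairwise correlation 0.8 (gene `g` in the module is
`√ρ·f + √(1−ρ)·ε`); survival times exponential with log-hazard 1.5 per unit
of the factor and independent exponential censoring tuned by bisection to a
30% censoring fraction; a Barabási–Albert network (mean degree 4, node labels
assigned in seeded random order so hubs are not preferentially drivers) with
the driver module additionally joined by a uniform random tree; edge weights
uniform in [0.4, 0.9]; size templates of 8, 15 and 30 genes.  Expression is
shifted to be globally nonnegative so the pathway-score weights are valid.

The driver fraction (5%) and template sizes are chosen together so a typical
random signature contains at most one driver gene.  This is the regime the
mining step assumes: selection then discriminates — only the minority of
signatures that hit the module several times pass both thresholds (typically
10–20% here) — and occurrence scores carry information.  If templates are so
large relative to the module that every signature overlaps it, selection
approaches 100% and occurrence scores flatten into noise; at full published
scale (tens of thousands of genes, signatures of ~100 genes, a few percent
selected) the separation is sharper than this emulation.

Not emulated: microarray platform noise, batch effects, probe-level
preprocessing, correlated background modules, and networks with realistic
pathway topology.  Passing tests demonstrate that the machinery recovers a
planted, network-coherent outcome module under clean Gaussian assumptions;
they do not certify performance on real cohorts.

Problem sizes in the tests and the acceptance script (100 random signatures
per template, 100–200 permutations, five replicate seeds) are the package's
reference desk-scale settings; the pipeline defaults (1000 each) match the
method's reference configuration.

## 7. Reproducibility and seeds

All randomness flows through numpy's PCG64.  The pipeline takes one master
seed; each stage derives its seed as `SeedSequence([master, crc32(stage)])`,
and each random signature as `SeedSequence([stage_seed, index])`, so any
stage or signature can be recomputed in isolation.  Reruns with the same
config produce byte-identical output tables.

## 8. Known limitations

* Univariate stratification only: no clinical covariates, time-dependent
  effects, or interval censoring in the Cox step.
* The empirical p-value's conservatism (Section 1) makes its distribution
  non-uniform under the null by construction; thresholding it at 0 is the
  intended use.
* The pathway separation test's null bias (Section 4).
* The exact rank-sum path assumes no pooled ties; tied data take the
  asymptotic fallback.
* Diffusion treats edge confidences as symmetric nonnegative weights;
  directed or signed interactions are out of scope, as are degree-normalized
  Laplacians.
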
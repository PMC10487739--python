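# Methods

This note documents the models, estimators and design decisions behind
`dsp_attenuation`, in the order the pipeline runs them.

## Synthetic data generator

The generator emulates a digital-spatial-profiling study of a 2×2
spaceflight × antioxidant design: four brain regions (CA, DG, FCT, CT), four
groups (GC-SAL, GC-BuOE, FLT-SAL, FLT-BuOE), and `n_replicates` AOIs per
region × group. For gene *g*, region *r*, and an AOI of group (condition,
treatment), the log2 mean is

```
m = b_g + [FLT]·δ_gr − [FLT ∧ BuOE]·α_g·δ_gr + [GC ∧ BuOE]·ε_g
```

and counts are negative-binomial with mean `μ = 2^m · s_a` and dispersion θ
(variance `μ + μ²/θ`). Parameters, defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 5000 | desk-scale panel (a whole-transcriptome panel is ~20k; 5000 keeps simulation studies fast without changing any statistic's behavior) |
| `regions` | CA, DG, FCT, CT | the four profiled brain regions |
| `n_replicates` | 3 | replicate AOIs per region × group, the study design's level |
| `baseline_log_mean_range` | (3, 9) | b_g uniform on log2 scale → baseline means 8–512, a realistic dynamic range for deduplicated DSP counts |
| `dispersion` | 10 | NB size θ; squared coefficient of variation `1/θ + 1/μ ≈ 0.1` at high expression, typical of between-animal biological noise |
| `size_factor_sd` | 0.3 | log-normal AOI scale factors, so Q3 normalization has real work to do |
| `n_flight_degs_per_region` | 200 | planted flight-responsive genes per region |
| `flight_effect_size` | 2.0 | planted \|log2FC\|, well above the 0.585 call threshold |
| `attenuation_alpha` | 0.5 | fraction of each flight effect reversed by BuOE during flight (0 = no effect, 1 = full reversal); 0.5 encodes the partial attenuation the pipeline is designed to detect |
| `buoe_ground_effect` | 0 | BuOE effect in ground controls (ε_g); when > 0 it is applied at the planted flight genes with the same alternating sign schedule as δ |

Planted effect signs alternate deterministically along the sorted selection
(even index up, odd down), giving a reproducible ~50/50 split without a
second RNG stream; one `numpy` Generator seeded from `seed` drives
everything, so a seed fixes the dataset bit-for-bit.

What the generator does *not* emulate: probe-level structure and limits of
quantitation, spatial correlation between AOIs, nesting of AOIs within mice
(AOIs are exchangeable within a group), per-gene dispersions, and
correlated gene modules. Passing tests therefore demonstrate that the
statistics behave correctly under a clean overdispersed-count model with
known truth — not that real tissue data satisfies those assumptions.

## Q3 normalization

`factor_a = Q3_a / geomean(Q3)` with Q3 the per-AOI 75th percentile over all
genes (linear interpolation between order statistics), the platform
convention for DSP data. After division, every AOI's 75th percentile equals
the geometric mean of the raw Q3s. Downstream statistics use
`log2(value + 1)`; the pseudocount keeps zeros at zero. No
limit-of-quantitation or background filtering is applied before
normalization.

One subtlety: multiplying a single AOI's counts by *c* cancels out of that
AOI's own factor but shifts the geometric mean, so the whole normalized
matrix picks up a common factor `c^(1/n)`. The AOI's Q3-relative profile is
invariant exactly; tests assert that form. An AOI whose Q3 is zero is
rejected with an error naming it.

## Differential expression

Per region and contrast, a two-sided Welch (unequal-variance) t-test on the
log2 values; with n = 3 per group and no reason to assume equal dispersion,
Welch is the robust default. Per-group variances are floored at 1e-12 so a
gene constant in both groups gives t = 0, p = 1 when means agree and an
extreme statistic when they do not. log2 fold change is the difference of
group means of log2 values (test − reference), the same scale the t-test
works on. Sign convention: the flight contrast is FLT-SAL vs GC-SAL
(reference GC-SAL); the antioxidant-in-flight contrast is FLT-BuOE vs
FLT-SAL — so attenuation shows up as opposite log2FC signs.

q-values come from a label-permutation plug-in FDR estimate: labels are
permuted within the region `n_perm` times (default 1000), per-gene Welch
p-values recomputed, and

```
q(g) = mean over permutations of #{null p ≤ p_g} / #{observed p ≤ p_g}
```

clipped to [0, 1] and made monotone nondecreasing in p-rank. When there are
no more distinct label assignments than requested permutations (3 vs 3 has
C(6,3) = 20), all distinct assignments are enumerated with a warning.

Two deliberate choices in the null:

- the observed labeling — and, for equal group sizes, its complement, which
  induces the same two-group partition — is excluded. A null containing the
  observed p-values verbatim floors q at `2/n_assignments` (0.1 for 3 vs 3)
  and can never call anything at small n; excluding it is the standard
  permutation-test convention and is what the random-permutation branch
  does in effect, since it essentially never draws the identity.
- the null pools permuted p-values across genes, with no π₀ estimate
  (π₀ = 1), making q conservative when many genes carry signal.

DEG calling applies both thresholds strictly: `q < 0.05` and
`|log2FC| > 0.585` (fold change > 1.5×).

Known limitation: at 3 replicates per group and NB dispersion 10, the
permuted 2-vs-1 mixed splits of a 3v3 design still separate groups at
strongly affected genes, inflating the pooled null and leaving planted
genes at q ≈ 0.2 — the estimator is honest but underpowered there. The
simulation studies and the acceptance script therefore use 6 replicates per
group, where the 924 enumerated splits give a clean null and the caller
reaches mean recall ≈ 0.90 at mean empirical FDR ≈ 0.045 over the 20-seed
planted-effect study.

## Direction-concordance attenuation statistics

Flight DEGs and BuOE-in-flight DEGs over the same gene universe are
intersected and partitioned by log2FC sign agreement into `n_opposite` and
`n_same`. With `N = n_flight_degs + n_buoe_degs`, the contingency matrix is

```
X11 = n_opposite    X12 = N − X11
X21 = n_same        X22 = N − X21
```

followed by a two-sided Fisher's exact test (minimum-likelihood method; the
null — that opposite- and same-direction overlaps are equally likely — is
two-sided). This construction complements each row against N rather than
against the overlap, so its rows are not independent samples; it is
reproduced deliberately and exactly, and a conventional independence
cross-tabulation of DEG directions among overlapping genes
(`direction_independence_table`) is reported alongside as the orthodox
alternative. An all-zero matrix returns p = 1 with a warning.

The shuffling null re-draws pseudo BuOE DEG lists B = 1000 times: a seeded
Fisher–Yates shuffle of the analyzed gene list (replacing an OS-level
shuffle utility, for portability), top `N_up` as pseudo-up and bottom
`N_down` as pseudo-down, matching the real BuOE direction counts exactly in
every iteration; direction of a pseudo-DEG is its block membership. The
empirical p uses the add-one rule `(1 + #{null ≥ observed}) / (1 + B)`,
avoiding p = 0. The null's analytic mean,
`n_space_up·N_down/G + n_space_down·N_up/G`, serves as a cross-check of the
shuffling logic in the tests.

Calibration of this test is checked under α = 0 (no BuOE effect): because
thresholded BuOE DEG lists are then empty (the statistic degenerates to
p = 1), the calibration experiment draws BuOE gene lists at nominal,
unadjusted p < 0.05 — nonempty lists that are random with respect to the
planted flight DEGs, which is exactly the independence null the shuffling
test addresses. Over 200 simulated datasets the rejection rate at 0.05 sits
in [0.02, 0.08]; the test is slightly conservative because the overlap
count is a small discrete statistic.

## ANOVA-filtered PCA and centroid distances

A one-way ANOVA per gene on log2 values uses the experimental group
(region × condition × treatment) as the factor — reading "biological
sample" as the group, since using each AOI as its own level would leave
zero residual degrees of freedom. q-values use the Storey procedure with
fixed λ = 0.5 (π₀ = #{p > λ}/(m(1−λ)), capped at 1), deterministic and
standard. Genes at q < 0.05 enter a PCA of the gene-centered, unscaled log2
matrix (the common default for expression PCA); replicate profiles are
averaged per group first, so each group contributes one point, and
distances are read in the PC1–PC2 plane:
`attenuation_ratio = d_buoe / d_sal` per region (undefined when
d_sal = 0). Under planted truth the ratio tracks 1 − α: ≈ 1 at α = 0 and
≈ 0.5 at α = 0.5 in the worked example.

## Enrichment

Over-representation is the one-sided hypergeometric upper tail of the
DEG-list overlap with each gene set, after intersecting sets with the
universe (all genes in the analyzed count matrix — the natural background
for a targeted panel), with Benjamini–Hochberg adjustment across sets.
Gene–disease association is a case-insensitive set intersection (mouse
symbols are capitalized, human resource symbols upper-case). Both run
entirely on local, user-supplied files; no web service is queried, and no
composite ranking score is computed. The analysis drivers generate
*synthetic* pathway and association files (labeled as such in their
filenames) from planted truth plus random genes.

## Numerical and I/O choices

- Welch statistics are computed by one vectorized code path used for both
  observed and permuted data, with columns in a canonical sort order so
  that swapping test and reference groups yields bitwise-identical p and q
  (IEEE addition is commutative; summation *order* is what breaks such
  symmetries).
- All result tables are TSV with floats in scientific notation at six
  significant digits, so identical results are byte-identical on disk; the
  pipeline manifest records seeds and per-stage row counts, and a fixed
  config + seed reproduces the entire output tree bit-for-bit.
- Counts are validated as non-negative integers at the boundary; normalized
  values live in a separate type and are never re-ingested as counts,
  preventing accidental double normalization.
- Per-stage seeds are derived from the master seed via `SeedSequence`, so
  stages are independently reproducible.

## Problem sizes used by the validation suite

Simulation studies run at 5000 genes, one region, 200 planted DEGs,
|log2 effect| 2.0, dispersion 10 and 6 replicates per group (20 seeds per
condition); the permutation-null calibration uses 200 datasets of 2000
genes at the 3-replicate design; the end-to-end determinism check uses 400
genes and 2 regions. These sizes are the package's chosen desk-scale
reference conditions: large enough for stable Monte-Carlo assertions,
small enough to keep the suite quick.

## Known limitations

- AOIs are treated as independent replicates; real AOIs are nested within
  mice and sections, so real-data p-values are anti-conservative to an
  unknown degree.
- The pooled permutation FDR is conservative under many true effects and
  underpowered at n = 3 with strong overdispersion (see above).
- The N-complemented contingency construction is reported for fidelity;
  its Fisher p should be interpreted alongside the conventional
  independence table and the shuffling null.
- Gene-set and disease results depend entirely on the supplied GMT and
  association files; nothing is fetched or curated by the package.
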
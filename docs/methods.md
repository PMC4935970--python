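# Methods

## Scope and data model

The package starts from an OTU count table (rows = OTUs, columns =
samples), a sample→site mapping with environmental metadata, and an
optional rooted phylogeny with branch lengths whose tips are OTU ids.
Everything upstream — read QC, merging, chimera removal, OTU clustering,
alignment and tree inference — is out of scope; those steps belong to
dedicated tools and the analyses here are agnostic to how the table and
tree were produced.

## Alpha diversity

Chao1 is `S_obs + f1²/(2 f2)` with `f1`/`f2` the singleton/doubleton
counts. When `f2 = 0` the bias-corrected form
`S_obs + f1(f1−1)/(2(f2+1))` is used: it avoids division by zero,
reduces to `S_obs` when `f1 ≤ 1`, and never falls below `S_obs`.
Shannon entropy uses natural logarithms (beware when comparing with
log2-based outputs), and the inverse Simpson index is `1/Σp²`. Zero
rows are never counted as species; all-zero units are an error rather
than a silent zero.

Site-level estimates pool counts by summation across the site's
replicate samples first, then estimate on the pooled vector. Pooling
uses raw counts by default; rarefied tables can be pooled instead by
rarefying first (`rarefy` → `pool_by_site`).

## Rarefaction

Subsampling is without replacement: each column's retained counts are a
multivariate-hypergeometric draw from its read multiset
(`numpy.random.Generator.multivariate_hypergeometric`), so a column
already at the target depth is returned unchanged. Samples below the
requested depth are an error by default; `on_small="drop"` discards
them with a logged warning. Depth presets for the three marker genes
(16S: 25,901; ITS: 13,688; nifH: 16,000 reads) are shipped as
`RAREFACTION_DEPTHS`. Each sample draws from a substream keyed on the
global seed plus a hash of the sample id, so results are invariant to
column order.

## Phylogenetic diversity

Faith's PD uses the rooted convention: the sum of branch lengths over
the union of root-to-tip paths of the present tips. A single-tip
community therefore has positive PD; unrooted conventions differ and
users comparing across tools should check which one they need.

The abundance-weighted MPD is `Σ_{i≠j} d_ij x_i x_j / Σ_{i≠j} x_i x_j`
with `d_ij` the cophenetic (patristic) distance and `x` relative
abundances; an unnormalised variant is available behind
`normalized=False` for sensitivity checks.

NRI uses the phylogeny-shuffle null: all tip labels of the supplied
tree are permuted uniformly (the species pool is the whole tree, not
just observed taxa), abundances stay fixed, and MPD is recomputed.
NRI = −(MPD_obs − mean_null)/sd_null with the sample standard deviation
(ddof = 1), so phylogenetic clustering is positive. Default 1,000 null
communities; the null values are accumulated in a single pass (mean and
sd only) unless the full vector is requested, keeping memory flat for
large replicate counts. When the null sd is numerically zero (e.g. a
star tree) the result is flagged undefined rather than returning an
arbitrary z-score. An `exact=True` mode enumerates every tip
permutation for small trees; it exists to make the estimator exactly
checkable against enumeration.

## Distance-matrix statistics

Community distances are Bray–Curtis on counts (raw counts by default —
rarefy first if depth effects are a concern). Environmental distances
z-score each variable (population sd) over the included units and take
Euclidean distances; constant variables are an error.

The Mantel statistic is the Pearson correlation of the two upper
triangles. Significance comes from jointly permuting rows and columns
of the first matrix; the p-value uses the permutation-inclusive
estimator `(1 + #exceedances)/(1 + n_perm)` so it is never zero, with
999 permutations and a one-tailed (greater) alternative by default —
the ecological convention for positive association; `tail="two-sided"`
is available. The partial Mantel statistic correlates the residuals of
both matrices after least-squares projection onto the control distances
plus an intercept; permutations relabel the first matrix and
re-residualise it against the fixed controls (simple residual
permutation — one of several published schemes, chosen for its
directness). Collinear controls are rejected with the design's
condition number. When a control explains either input essentially
completely the partial correlation degenerates to 0/0 and is defined as
r = 0, p = 1.

BioENV searches every nonempty subset of candidate variables (capped at
15, i.e. 32,767 subsets), scoring each by the Spearman correlation
(average ranks on ties) between its z-scored Euclidean distances and
the community distances, and returns the maximising subset plus the
full ranking. The search is deterministic and invariant to the order
variables are supplied in.

## Boltzmann–Arrhenius fitting

Richness estimates and Celsius temperatures are converted to Arrhenius
coordinates x = 1/(kT) (eV⁻¹, k = 8.617×10⁻⁵ eV/K, T = °C + 273.15)
and y = ln S. Three models are fitted by OLS:

- linear `y = a + b·x`, activation energy E_a = −b (sign-reversed
  slope — the only algebraically consistent reading of the
  Boltzmann–Arrhenius form);
- quadratic `y = a + b·x + c·x²`;
- a continuous hinge with one breakpoint chosen by grid search over the
  interior observed x values leaving at least two points strictly per
  side (a discontinuous two-line model has no biological reading for a
  diversity–temperature response).

AIC is −2 ln L + 2·n_params with a Gaussian likelihood at the MLE
variance SS_res/n; n_params counts the residual variance (3/4/5 for
linear/quadratic/piecewise). This convention shifts all AICs of fits on
the same data equally, so model ranking is unaffected by it. Residual
variances below 1e-12 are clamped, so two interpolating fits compare
purely on parameter count instead of on floating-point noise. Fits
within 2 AIC of the best are marked competitive; exact AIC ties break
by higher r², then fewer parameters. r² = 1 − SS_res/SS_tot.

Note on small samples: with n = 6 points, the probability that the
quadratic term of a truly linear relationship improves AIC by ≥ 2 is
the null probability of an added-regressor F(1,3) exceeding ≈ 2.84,
about 19% — independent of the noise level. Site-level model selection
on six sites is therefore noisy by construction, and the hinge model
adds further flexibility; rely on it for description, not for strong
inference about curvature.

`q10_from_ea(ea, t1, t2) = exp(ea·(t2−t1)/(k·t1·t2))` converts an
activation energy to a rate multiplier; for t2 − t1 = 10 K this is the
Q10 (0.65 eV ↦ ≈ 2.5 near 285 K).

## Synthetic transects

`SimConfig` defaults encode the emulated design: six sites at 2.5, 7,
12, 17, 21, 25.7 °C; 21 samples per site; 20,000 reads per sample; true
E_a = 0.25 eV with intercept a = 17, giving true site richness ~650 at
the coldest and ~1,450 at the warmest site. These sizes keep a full
transect under 0.1 s to generate while preserving the qualitative
features that matter: per-sample observed richness well below the site
truth, abundant singletons (so Chao1 > S_obs), and near-complete
coverage after pooling 21 × 20,000 reads per site (so site-pooled Chao1
tracks the truth and the Arrhenius fit recovers E_a). For the zero-E_a
condition the intercept is a = 7 (equal richness ≈ 1,100 per site); an
intercept of 17 with E_a = 0 would imply 2.4×10⁷ species.

Species pools are nested by default — warmer, richer sites extend the
colder sites' pool — producing gradual compositional turnover along the
gradient; a disjoint-pool mode exists for power checks. Per-site
abundances are a global lognormal SAD (meanlog 0, sdlog 1.5, the
standard singleton-rich soil model) restricted to the site pool and
jittered per site on the log scale (sd 0.5) so sites differ in
composition beyond nestedness; samples are multinomial draws. The
phylogeny is a random-join tree with Exponential(1) branch lengths.
Environmental covariates are linear functions of site temperature plus
Gaussian noise (site-level), with quarter-scale within-site noise for
the per-sample soil variables; `env_noise=0` makes them exactly
collinear with temperature. All randomness flows from one seed through
named substreams (tree, SAD, sampling, env).

`merge_sister_otus` collapses every cherry of the tree into one OTU
(counts summed), a deliberately simple stand-in for re-clustering at a
coarser similarity cutoff. Because richer (warmer) sites contain
proportionally more complete cherries under nested pools, coarsening
compresses ln S more at the warm end and flattens the fitted slope —
which is why the finer table yields the larger E_a.

What the generator does **not** emulate: sequence-level error and
chimera artefacts, spatially structured dispersal within sites, pH- or
nutrient-driven community turnover independent of temperature, and
richness at the real survey's scale (10⁵–10⁶ reads/sample, 10⁴–10⁵
OTUs). Passing tests therefore demonstrate correctness and calibration
of the estimators and fits under a known generative model, not that
real soil data meet that model's assumptions.

## Pipeline

`run_all` executes: optional rarefaction → alpha profiles (sample and
site) → Faith PD, and NRI when enabled → Bray–Curtis and environmental
distances → BioENV → a partial-Mantel panel (default: temperature,
precipitation, pH, and total N + total C jointly, each controlling for
the others; the joint factor uses Euclidean distance over both z-scored
variables) → Arrhenius fits at both levels with model selection.
P-values are reported raw, without multiple-testing correction — the
panel is small and readers can apply their own correction. A missing
tree skips the phylogenetic stages with a logged notice. The JSON
report contains no timestamps, so reruns with the same config and seed
are byte-identical; timestamps go to the log.

## Problem sizes in `scripts/acceptance.py`

50 transects per condition for E_a recovery and resolution contrast,
1,000 simulations × 999 permutations for Mantel calibration, 200
replicates for model selection — sizes chosen so the whole script
completes in well under a minute per block while leaving Monte-Carlo
standard errors far smaller than the effects being measured.
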
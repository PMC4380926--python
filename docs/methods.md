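# Methods

## Model and procedure

The package operates on three data layers measured in the same animals —
a log2-scale expression matrix per tissue, a physiological marker table
and optionally a metabolite table — together with a group design naming a
healthy-baseline group and an untreated-disease group; every other group
is an intervention arm. All inputs are assumed already normalized
(background correction and quantile normalization are out of scope).

**Feature selection.** Features are ranked by the two-sided p-value of an
ordinary pooled-variance two-sample *t*-test between the disease and
baseline groups (df = n₁+n₂−2), and the top N = 200 are kept. We use the
plain pooled *t* rather than an empirical-Bayes moderated *t*: the
downstream indices are insensitive to the exact feature list within an
order of magnitude of N, and the plain test keeps the pipeline
self-contained and exactly reproducible by hand. Ties in p are broken by
larger |mean difference|, then lexicographic feature ID, so output is
deterministic. A feature with zero pooled variance but unequal means is
maximally separating and ranks first (p = 0, with a warning); a feature
constant and equal in both groups is ineligible.

**Deviation spaces.** Each selected feature is z-scored across *all*
retained samples (not only the reference groups), scaled by its Fisher
score F = Σₖnₖ(μₖ−μ)²/Σₖnₖσₖ² computed between baseline and disease
groups, and the weighted matrix is rotated by a full-rank PCA. Every
principal component is kept, so the rotation is an isometry and each
sample's deviation index — its distance to the baseline centroid — equals
the Fisher-weighted Euclidean distance in z-space. This identity is the
package's central numerical invariant and is tested against a brute-force
oracle at 1e-8 relative tolerance.

Conventions worth stating because the field leaves them open:

- σₖ in the Fisher score is the sample (n−1) standard deviation.
- Weights multiply the z-scored columns by F itself, so squared distances
  are Σ F²Δz². A `weight_exponent` option (0.5 gives Σ FΔz²) records the
  alternative convention rather than burying it; `weighting_mode=equal`
  disables weighting entirely and the full pipeline runs in that mode.
- PCA centering uses the grand mean of the weighted matrix; distances are
  translation-invariant so this cannot affect any index.
- Zero-variance features are dropped with a warning (their z-score is
  undefined). If both within-group variances vanish while means differ,
  the Fisher ratio is undefined and the space construction errors rather
  than guessing.

**Completeness rules.** Expression matrices must be complete. For the
physiological space (GPDI), samples missing any marker are excluded and
each exclusion is logged; for the metabolome (MDI), incomplete
*metabolites* are excluded feature-wise so no sample is lost. The
per-marker PDI is |value − baseline-group mean| on raw marker values;
a z-scored variant differs only by a positive per-marker factor and
therefore yields identical rank- and product-moment correlations
downstream.

**Decomposition.** With baseline and disease centroids v_LFD and v_HFD,
the reversal axis is u = (v_LFD − v_HFD)/‖·‖. A sample's displacement v
is taken relative to the *disease* centroid by default, so the signed
scalar s = u·v is 0 for the untreated disease state and ‖v_LFD − v_HFD‖
for complete restoration; v₁ = su and v₂ = v − v₁ give the restorative
and non-restorative magnitudes. The origin is genuinely ambiguous
(`decomposition_origin="grand_mean"` provides the alternative for
sensitivity analysis); the disease-centroid default makes s read directly
as "progress from untreated disease toward baseline".

**Associations.** Index–index correlations are reported with both Pearson
and Spearman coefficients on pairwise-complete samples (p from the
t-approximation with df = n−2; an exact permutation p for Spearman is
available for n < 8). The TDI–PDI marker matrix uses Spearman (robust to
the outlier-prone marker measurements) and adjusts all tissue × marker
tests jointly by Benjamini–Hochberg at α = 0.05 — the joint family is the
conservative choice where a per-tissue family would also be defensible.

**Unfavorable outcomes.** A marker's disease direction is the sign of
(disease mean − baseline mean) of raw group means, with no significance
requirement; markers with exactly equal means are skipped and logged.
Every intervention arm (including the dietary arm and the intermediate
time point; configurable) is tested against the untreated disease group
with a one-sided pooled-variance *t* in the disease direction, and all
tested (marker, arm) pairs form one BH family at α = 0.05. A flag
additionally requires the treated mean to lie beyond the disease mean, a
condition any rejection already implies.

## The synthetic study generator

The generator emulates the motivating trial design so the whole pipeline
is testable without external downloads: 14 groups × 8 animals (112) with
liver expression; adipose expression in a 7-group subset (the main text
of the motivating study lists eight adipose-profiled groups while its
methods report seven; we follow the seven-group reading: baseline,
9-week time point, untreated disease, dietary arm, rosiglitazone,
pioglitazone, T0901317); 26 markers split 10 adipose-coupled, 10
liver-coupled, 6 both; 168 liver-coupled metabolites.

Every layer couples through a latent disease load: group g plants
ℓ_g ∈ [0,1] (baseline 0, untreated disease 1, dietary arm 0.1, drug arms
spread over 0.3–0.85), and animal i realizes a per-tissue load
ℓ_i,t ~ N(ℓ_g, 0.1²) clipped to [0, 1.5] (the ceiling above 1 permits
synthetic omic-level overshoot experiments). Expression in tissue t is

x_i = base + ℓ_i,t·δ·d_t + β_g,t·o_g,t + ε,  ε ~ N(0, σ²I),

with δ = 2, σ = 1, d_t a disease axis supported on 200 of 1,000 features
and o_g,t per-group off-axis directions orthogonal to d_t within that
support. Two normalization choices matter:

- **Loadings have unit RMS over their support**, so δ and β are
  per-feature effect scales in noise-SD units (a fully diseased animal's
  disease features shift by ~2σ on average). Normalizing the axis to unit
  total norm instead would spread δ over √200 features and make the
  planted structure statistically undetectable at n = 8 — a degenerate
  simulation, not a harder one.
- **Off-axis directions live inside the disease-feature support.** The
  analysis space is built from disease-associated features, so off-axis
  shifts outside that support would be invisible to the method by
  construction; placing them inside it makes β recovery a real test.

Off-axis magnitudes mirror the motivating study's observations:
fenofibrate and T0901317 carry large liver β (2.5, 3.0), the
thiazolidinediones large adipose β, the dietary arm the smallest, and all
values are distinct so rank recovery is well defined. Markers follow
m = 10 + c·ℓ_i,tissue(m) + N(0, 0.3²) with |c| = 2 and random sign;
metabolites are generated like liver-coupled markers. Two overshoot
plants (adiponectin × pioglitazone, plasma cholesterol × T0901317, the
patterns reported for these drug classes) shift the named cells to 5
nominal within-group SDs *beyond* the untreated-disease mean, in the
marker's disease direction. A few planted missing cells exercise the
GPDI/MDI exclusion rules; missing values occur nowhere else.

All draws flow from one seed through a fixed order (axes and baselines
per tissue, off-axis directions, coefficient signs, per-animal loads,
then noise layer by layer), so the same seed is bit-identical across
runs.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: probe-level microarray noise, batch effects,
correlated pathway structure, heavy-tailed marker distributions,
informative missingness, or tissue-specific *group-level* restoration
profiles (the latent group load is shared between tissues; tissues differ
only in per-animal realization). Recovery results quantify the method's
behavior under its own generative assumptions, not clinical validity.

## Validation experiments and problem sizes

The exact oracles (isometry, Fisher formula, orthogonal decomposition,
BH step-up) run on 50–1,000 random instances each, at tolerances
1e-8–1e-12. Parameter recovery runs the default study (seed 42): group
TDI vs planted load (Spearman ≥ 0.9), TDI–GPDI coupling (Pearson ≥ 0.7),
non-restorative rank recovery (Spearman ≥ 0.9). The unfavorable-scan
null study uses 200 marker-only replicates (expression shrunk to 4
features, which the marker layer never reads) and requires the mean
false-discovery proportion ≤ 1.5α.

The tissue-specificity experiment deserves its own note. Arms whose
off-axis shift dominates their TDI (β ≈ 3 against an on-axis range of
≈ 2) scramble that TDI's relation to the latent load, and this *masks*
the animal-level tissue coupling the experiment probes — a genuine
limitation of distance-based indices: the TDI conflates
disease-restoration with off-target magnitude. The experiment therefore
runs the full-size design with off-axis magnitudes set to zero, isolating
the planted coupling, and judges recovery per coupling class (mean
Spearman-|rho| difference over each tissue's 10 exclusively coupled
markers, over the 56 shared samples) in 100 seeded replicates.

## Known limitations

- Distances in a ~200-dimensional space have a noise floor; indices are
  comparative (between animals and groups), not absolute effect sizes.
- The plain pooled *t* is anti-conservative for very small groups
  compared with a moderated test; feature *ranking* is what matters here,
  and results are insensitive to N within an order of magnitude.
- Fisher weights are undefined in a strictly noise-free limit (zero
  within-group variance with separated means); the deterministic-limit
  analyses use equal weights, where TDI ∝ planted load holds exactly.
- The unfavorable scan can only see markers the study measured, and only
  disease-relevant ones; side effects on disease-unrelated markers are
  outside the design's reach.
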
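# Methods

## Overview

`mmdep` implements a target-prioritisation pipeline for multiple myeloma
(MM) built on large-scale genetic perturbation screens. It has five
analytical stages, each exposed as library functions and driven by the
numbered scripts under `analysis/`:

1. **Score unification.** CRISPR knockout and shRNA knockdown gene-effect
   matrices (gene × cell line; more negative = more essential) are combined
   into a unified perturbation score S<sup>θ</sup> = θS<sup>C</sup> +
   (1−θ)S<sup>R</sup>.
2. **Essentiality calling.** Per-gene *efficacy* (the score at the Xth
   percentile most-sensitive line of a group) is thresholded against a
   Gaussian fitted to the mode of the efficacy distribution; genes essential
   in the MM group but not the pan-cancer background are the MM-specific
   dependencies.
3. **Selectivity.** The normalised residual of per-gene score *dispersion*
   above its linear trend on efficacy separates selectively essential genes
   from commonly essential ones.
4. **Enrichment.** Hypergeometric over-representation of the shortlist
   against annotation terms, BH-corrected.
5. **Survival.** Low (bottom 25%) vs high (top 25%) tumour expression of
   each shortlisted gene is related to OS and PFS per cohort by adjusted Cox
   models, pooled across cohorts by DerSimonian–Laird random-effects
   meta-analysis, with BH FDR control and a Schoenfeld power calculation.

## Score unification

Missing entries on one platform are imputed per cell line from the other
platform: a loess curve (statsmodels `lowess`, locally weighted linear
regression, span 0.5, 3 robustifying iterations) of observed
S<sup>C</sup> against observed S<sup>R</sup> across genes predicts missing
S<sup>C</sup> from that gene's S<sup>R</sup>, and symmetrically. Predictions
outside the observed predictor range are clamped to the fit at the nearest
observed predictor. A cell line needs ≥ 30 doubly observed genes; entries
missing on both platforms cannot be imputed, and any gene still incomplete
at unification is dropped and reported.

The data-driven mixing ratio θ\* pools all (S<sup>C</sup>, S<sup>R</sup>)
pairs, mean-centres them, and takes the first principal axis (v_C, v_R) of
the 2×2 covariance with the sign fixed so v_C > 0; θ\* = v_C/(v_C+v_R) is
the weight at which the unified axis is parallel to PC1. θ\* is *reported*
but the pipeline default is the fixed θ = 0.6 — inspect, then fix, keeping
a round weighting close to the PC1 direction. With equal platform noise and
unit coupling slope θ\* → 0.5; on real data the CRISPR platform's lower
noise pushes θ\* above one half.

## Essentiality threshold

For a group of n lines at percentile X, the efficacy order statistic uses
k = max(1, ⌊n·X/100⌋) — the only floor-based mapping consistent with both
worked panel sizes (34 lines at X=25 → 8; 449 lines at X=1 → 4). Defaults:
X = 25 for the small MM panel, X = 1 for the large background panel.

The efficacy distribution mixes a large null/common mode with a left tail
of truly essential genes. A Gaussian KDE (Silverman bandwidth by default)
is evaluated on a 512-point grid spanning the data range ± one bandwidth;
μ is the grid argmax, and σ comes from least squares of
c·φ((s−μ)/σ) against the KDE *between the two half-maximum crossings
around the mode* — fitting only near the mode keeps the essential-gene tail
from inflating σ. The threshold is T = μ + σ·Φ<sup>−1</sup>(p) with
p = 0.001 (the exact normal quantile −3.0902, not a z≈3 approximation), and
a gene is essential iff its efficacy is strictly below T. Note the KDE
convolution inflates σ by the bandwidth in quadrature (≈ 0.5% at n = 10⁵,
Silverman), which is well inside the acceptance band used in the tests.

Dispersion is D = (kth largest − kth smallest) score. Selectivity fits an
OLS line D̂ = a + b·E across genes and scores U = (D − D̂)/D̂; genes with
D̂ ≤ 0 are flagged and excluded from ranking. The source material's
displayed equation ends in an algebraically inconsistent denominator (D
rather than D̂); we implement R/D̂ and expose the literal variant through
`denominator="dispersion"`. In the end-to-end driver, E and D for
selectivity are computed over the pooled line panel, because selective
essentiality is dispersion of response *across the population* of lines;
within a single homogeneous lineage a lineage-essential gene shows no
dispersion at all.

## Enrichment

One-sided upper-tail hypergeometric probability P(X ≥ k), inclusive of k,
for the overlap between the query and each term, after intersecting terms
with the universe (genes carrying ≥ 1 annotation); emptied terms leave the
BH family. No ontology-hierarchy propagation is performed — terms are taken
as given in the GMT.

## Survival analysis

Patients are split at the linearly interpolated 25th/75th expression
percentiles; boundary ties go to the extreme groups (so heavy microarray
ties keep group sizes at or above the nominal quarter), the middle half is
excluded. Cox proportional-hazards models (lifelines, Efron tie handling)
fit the binary low-expression indicator (high = reference, so HR > 1 means
low expression is adverse) adjusted for age (continuous), sex (binary) and
ISS stage (two indicator contrasts vs stage 1); patients with missing ISS
are dropped complete-case with counts logged. Monotone likelihood (a
separated, event-free group) yields a flagged result with an unbounded CI
rather than an exception. Kaplan–Meier curves and the two-sided log-rank
test accompany each fit.

Per-cohort log HRs are pooled by DerSimonian–Laird: fixed weights
w_i = 1/se_i², Q = Σw_i(y_i − ȳ_FE)², τ² = max(0, (Q − (k−1))/(Σw −
Σw²/Σw)), random weights 1/(se_i² + τ²); Cochran's Q is tested on χ²(k−1)
and the pooled effect with a two-sided normal test. BH is applied across
genes separately within each endpoint. Power uses the Schoenfeld
approximation Φ(|ln HR|·√(d·p(1−p)) − z_{1−α/2}) on the event count d in
the compared groups.

## Synthetic data

The generator provides known ground truth for every stage; its defaults
are the study conditions used by the test suite.

**Screens** (`simulate_screens`): genes are non-essential (75%), commonly
essential (20%) or lineage-essential (5%), with latent effects 0, −1.5 and
−1.5 (the last only in MM-labelled lines) plus N(0, 0.25) biological
noise; CRISPR = latent + N(0, 0.25), shRNA = slope·latent + N(0, 0.25)
with slope 1. Missingness is per-entry independent at per-platform rates
(0, 0.05) by default — CRISPR gene-effect releases ship complete while
shRNA screens have gaps; symmetric scalar rates are supported. The default
panel is 2000 genes × (40 MM + 400 other) lines. What this does *not*
emulate: heavy-tailed score distributions, gene–gene correlation,
batch/screen-quality structure, partially penetrant lineage dependencies,
or within-lineage heterogeneity — so passing recovery tests demonstrates
correctness of the statistical machinery, not performance on real screens.

**Cohorts** (`simulate_cohort`): expression N(0,1) per gene; event times
exponential with hazard baseline·exp(lp), baseline 0.015/month
(median OS ≈ 46 months), where lp adds the per-gene log-HR for patients in
that gene's bottom expression quartile plus covariate effects (age
0.02/year over 65, sex 0.1, ISS 0.3/0.6). Progression carries 1.5× extra
hazard, so PFS ≤ OS with ~25% more PFS events. Censoring is independent
exponential with its rate solved by root-finding so the expected censored
fraction matches the target (default 0.30). Real cohorts differ:
non-exponential baselines, informative censoring, treatment heterogeneity,
and expression–covariate correlation are all absent.

**Annotations** (`simulate_annotations`): random terms of size 10–100 plus
one planted term equal to a chosen gene set.

## Numerical and design choices

- Single `numpy.random.Generator` per simulate call, keyed by the seed.
- Gene identity is the symbol; Entrez IDs are annotation only; symbol
  collisions are an error, never a silent merge.
- lowess `delta` speed-up (1% of the predictor range) is enabled above 200
  observed pairs; below that the fit is exact.
- KDE bandwidth rules: Silverman (default), Scott, or a fixed absolute
  bandwidth; a multimodal KDE with no half-max interval around the mode
  raises with advice to change bandwidth.
- The essentiality call uses strict inequality (efficacy < T).
- Meta-analysis stays on the log-HR scale; CIs are exponentiated last.
- The survival screen's acceptance-level planted-gene check uses the PFS
  endpoint: it has the most events under the default censoring process and
  is the better-powered endpoint for this design. With only three cohorts,
  DerSimonian–Laird τ² is noisy; chance τ² > 0 inflates the pooled SE and
  is the main cost of power at k = 3.
- Library functions and the `analysis/` scripts are the user interface;
  the analysis is a fixed narrative, not a shell tool, so no console
  entry point is installed.

## Known limitations

- Local-linear (degree 1) loess; a degree-2 local fit could track curvature
  in the cross-platform relation slightly better at the extremes.
- θ\* on pooled raw scores; a per-gene-efficacy PCA variant is not exposed.
- No GO hierarchy handling; enrichment p-values on real GO data will differ
  from tools that propagate annotations to ancestors.
- No proportional-hazards diagnostics beyond the model's assumptions; no
  stratification by cytogenetic subtype; no time-dependent covariates.
- Problem sizes in the test suite (screen panels of 2000 × 440, cohorts of
  800/550/150, 10–500 simulation replicates) were chosen to exercise every
  stage at the study's design scale while keeping the suite quick to run.
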
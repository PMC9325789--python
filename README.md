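# mmdep — gene dependency to drug target prioritisation in multiple myeloma

Multiple myeloma (MM) remains essentially incurable, and genes that MM
cells depend on for survival — but that other cancers (standing in for
normal tissue) do not — are candidate drug targets. `mmdep` implements an
end-to-end pipeline for finding and vetting such targets from large-scale
genetic perturbation screens and patient cohorts:

1. **Unified perturbation score.** CRISPR and shRNA gene-effect matrices
   are merged as S<sup>θ</sup> = θS<sup>C</sup> + (1−θ)S<sup>R</sup>, with
   cross-platform loess imputation of missing entries and a PCA-derived
   estimate θ\* of the mixing ratio (pipeline default θ = 0.6).
2. **Essential-gene calling.** Per-gene *efficacy*
   E<sub>θG,X</sub> — the unified score at the Xth-percentile most
   sensitive cell line (X = 25 for the MM panel, X = 1 for the pan-cancer
   background) — is thresholded at T<sub>θ</sub> = μ + σ·Φ<sup>−1</sup>(0.001),
   where (μ, σ) come from a Gaussian fitted to the mode of the efficacy
   distribution via kernel density estimation. MM-specific dependencies are
   genes essential in MM but not in the background.
3. **Selectivity.** U<sub>θG,X</sub> = (D − D̂)/D̂, the normalised residual
   of a gene's dispersion D (spread between the (100−X)th and Xth
   percentile scores) above its linear trend D̂ on efficacy.
4. **Enrichment.** Hypergeometric over-representation of the shortlist
   against annotation terms (GMT), BH-corrected.
5. **Survival meta-analysis.** Low (bottom 25%) vs high (top 25%) tumour
   expression of each shortlisted gene vs OS and PFS: Kaplan–Meier +
   log-rank, Cox models adjusted for age, sex and ISS stage, pooled across
   cohorts by DerSimonian–Laird random-effects meta-analysis with
   Cochran's Q and BH FDR control, plus Schoenfeld power calculations.

A first-class synthetic-data module generates DepMap-like screen pairs and
multi-cohort survival data with planted ground truth, so the entire
pipeline runs and is tested without any downloads. Readers for the real
file dialects (DepMap gene-effect CSVs, expression TSVs, clinical CSVs,
GMT) are included.

## Worked example

The numbered scripts under `analysis/` run the full pipeline on synthetic
screens (2000 genes; 40 MM + 400 background lines; 109 planted MM-specific
essential genes) and three synthetic cohorts (800/550/150 patients, two
planted prognostic genes among 23 shortlisted):

```sh
python analysis/01_simulate_screens.py
python analysis/02_unify_scores.py
python analysis/03_call_essential_genes.py
python analysis/04_enrichment.py
python analysis/05_survival_meta.py
python analysis/06_power_analysis.py
```

Output (abridged):

```
PCA-derived mixing ratio theta* = 0.502; unified with theta = 0.6
essential in myeloma: 515; in background: 406
shared: 406; myeloma-specific: 109
thresholds: T_mm = -0.733, T_background = -1.203
recovery of planted myeloma-specific genes: sensitivity 1.000, specificity 1.0000
...
planted term ranked first (p = 4.46e-183)
...
planted: G00007 (log-HR +0.5), G00048 (log-HR -0.45)
OS: 1 BH rejections at FDR 0.05
  gene  pooled_hr  ci_low  ci_high  tau2  p_meta  q_bh
G00007     1.9218  1.6134   2.2891   0.0     0.0   0.0
PFS: 2 BH rejections at FDR 0.05
...
OS: 538 events in the compared quartiles; 80% power reaches HR = 1.27
```

θ\* ≈ 0.5 is the expected mixing ratio when both simulated platforms carry
equal noise. The essentiality stage recovers exactly the planted
MM-specific genes; the survival screen flags the two planted prognostic
genes (low expression of G00007 adverse, HR ≈ 1.9; low G00048 protective
on PFS, HR ≈ 0.68) and nothing else; the power analysis reports the
smallest hazard ratio detectable at 80% power from the realised event
counts. Tables land under `results/`.

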
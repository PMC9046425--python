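# Methods

This note documents the models, parameter choices and numerical conventions
behind `coexnet`, and what the synthetic validation does and does not
establish about real data.

## Pipeline order

match → gene filters → log2(TPM+1) → sample QC → surrogate adjustment →
similarity → soft threshold → TOM → modules → eigengene/trait statistics →
per-condition networks → differential betweenness → enrichment → regulatory
network.

Sample QC runs **before** surrogate adjustment deliberately. The adjustment
estimates surrogate variables as principal components of the
covariate-residual matrix, and a grossly aberrant sample is exactly the kind
of high-variance, low-rank structure PCA absorbs first: adjusting before QC
silently "repairs" outliers (making them undetectable) while spending the
surrogate budget on them instead of on batch structure. Detecting on the
log-TPM matrix keeps the two concerns separate.

## Cohort matching

A propensity score is fitted by logistic regression of case status on the
matching covariates (categoricals one-hot encoded, columns standardized;
near-unregularized, C = 1e6). Each case is replicated `ratio` times and a
globally optimal rectangular assignment (`scipy.optimize.linear_sum_assignment`)
minimizes the total |logit difference|; this reproduces optimal-matching
behaviour without a full matching framework. Balance is reported as
standardized mean differences before/after. The assignment is deterministic;
ties resolve through the solver's fixed scan order over samples sorted by id.

## Gene filters

A gene is dropped only if lowly expressed (count < 10) in more than 90% of
samples in **both** trait groups — the intersection rule, so a gene
adequately expressed in either condition survives. Of the survivors the
⌈0.5·n⌉ genes with the largest MAD of raw TPM (not log) across all samples
are kept. Note the fractional MAD cut is *relative*: re-applying it halves
the set again, so only the count rule is idempotent.

## Surrogate adjustment

A deliberately simplified residual-PCA estimator: regress each gene on
intercept + trait + known covariates, take the top `n_sv` right singular
vectors of the residual matrix as surrogate variables (orthonormal across
samples), then regress each gene on the SVs alone and keep residuals + gene
means. The trait never enters the second model, so trait-linked signal is
protected by construction. Default `n_sv = 3`. This is not a full
surrogate-variable framework (no permutation significance, no
irrelevant-gene reweighting); on data where biological modules carry more
variance than batch structure, the estimator can absorb module eigengenes —
the generator's defaults (below) reflect the consortium-data regime where
batch noise rivals biology, which is also the regime where SV correction is
warranted at all.

## Sample network QC

Per trait group: Euclidean distances over genes, adjacency
`A_uv = 1 − d_uv / max d`, connectivity `k_u = Σ_{v≠u} A_uv`, and
`Z.k = (k − mean k) / sd k` (sd with ddof = 1); samples with `Z.k < −2.5`
are flagged in a single pass, with no re-standardization loop. `Z.k` is
invariant to positive rescaling of the expression matrix, and for a group of
n samples a single extreme sample is bounded at `Z.k = −(n−1)/√n`, so the
cutoff −2.5 is reachable for groups of ≥ 8. If all samples are identical the
convention is `Z.k = 0`, nothing flagged, with a warning.

## Network construction

Unsigned similarity |Pearson r| (a signed variant `(1+r)/2` sits behind a
flag but is not used in validation). The soft threshold scans β = 1..20: for
each β, connectivities are split into 10 equal-count (quantile) bins, and
log10 of the bin *density* — bin count / (n × bin width) — is regressed on
log10 mean connectivity over usable bins. With equal-count bins the raw
frequency is constant by construction, so density is the only meaningful
response; empty and zero-width bins are dropped, and fewer than 3 usable
bins (e.g. a constant-similarity matrix) is reported as a degenerate input.
R² is signed by −sign(slope) so growing degree distributions can never score
well. The smallest β with signed R² ≥ 0.85 wins; if none qualifies the
best-fitting β is used with a warning. TOM uses the matrix-product form
`L = A·A` with zeroed diagonal, `TOM_ij = (L_ij + a_ij)/(min(k_i,k_j)+1−a_ij)`,
diagonal set to 1, clipped to [0, 1].

## Module detection

Average-linkage hierarchical clustering of dissTOM (scipy), cut at a fixed
quantile of the merge heights; branches below `min_module_size = 30` go to
the `unassigned` sink; ids are assigned by decreasing size. The default cut
quantile is **0.5**: on data with a substantial unassigned background the
merge-height distribution has a long upper tail of background
agglomerations, and any cut inside the broad middle (≈0.3–0.7) separates
planted modules at ARI ≈ 1, whereas a cut near the top quantiles lands above
the background plateau and fuses everything into one module. For inputs with
*no* background (every gene belongs to a tight cluster) the appropriate cut
is instead just below the root, i.e. a quantile near 1 — the parameter
exists precisely because the static cut cannot be shape-free. An optional
eigengene-correlation merge pass (`merge_me_cor`) collapses modules whose
MEs correlate above a threshold; it is off by default.

## Eigengenes and trait statistics

ME is the first right singular vector of the module's row-standardized
expression (ddof = 1), rescaled to unit variance and sign-anchored so
cor(ME, mean standardized module profile) ≥ 0. Explained variance is
σ₁²/Σσ². Trait association is Pearson correlation of ME with the 0/1 trait
(point-biserial), two-sided p from the exact t transform on n−2 degrees of
freedom; module p-values are reported raw — the study-level screen is
p ≤ 0.05 per module — with a BH-adjusted column alongside for transparency.
GS and MM follow the definitions above; intramodular hubs are ranked by
|MM|.

## Differential betweenness

Case and control networks are rebuilt per module from the two sample groups
with the **same** β chosen on the combined network, restricted to the
module's genes. Within-group zero-variance genes get zeroed correlations
with a warning rather than an error. Betweenness runs on edge lengths
1/TOM (TOM = 0 ⇒ no edge) via Brandes accumulation over single-source
Dijkstra trees; path-length ties count as equal within a relative tolerance
of 1e-12 (exact ties only arise in symmetric fixtures). Each unordered pair
contributes once; summing over ordered pairs would exactly double every
value and leave the |ΔBC| ranking unchanged. Deltas sort descending by
|ΔBC| with ties broken by gene id.

## Enrichment and the regulatory network

One-sided hypergeometric upper tail per gene set, sets intersected with the
universe (the network-analyzed genes, not the genome) before the size ≥ 5
filter; BH adjustment within each collection separately (pathways, TF
targets, miRNA targets are distinct multiple-testing families); results
filtered to adjusted p ≤ 0.05. Zero overlap gives p = 1 exactly
(P(X ≥ 0) = 1). The regulatory network draws a directed edge from every
enriched TF/miRNA to each key gene in its target set, appends optional
curated edges tagged `literature`, and exports GraphML and SIF.

## The synthetic-data generator

A latent factor model on the log2 scale. Module m has eigengene
`E_m = λ_m·t̃ + √(1−λ_m²)·z` (t̃ the standardized trait), so
cor(E_m, trait) = λ_m in expectation. Gene g in module m is
`x_g = ±b·E_m + surrogate + ε`, with the loading
`b = ρ·σ_other/√(1−ρ²)` calibrated so |cor(x_g, E_m)| = ρ given the total
non-module noise σ_other; 30% of module genes load negatively, as unsigned
networks mix both correlation signs. Background genes carry surrogate +
noise only. Log-scale baselines (mean 3, sd 0.8 log2 units) are added, 5% of
background genes are pushed to near-zero expression to exercise the count
filter, samples are exponentiated and normalized to a constant column sum
(TPM), and counts are Poisson around TPM × library-size factor. Outliers are
whole-sample displacements by `shift × median inter-sample distance` along a
random direction, planted alternately in both trait groups (a cohort's
aberrant samples are not confined to one arm — and a group containing its
own outlier has an inflated connectivity SD, which is what makes the −2.5
cutoff selective).

Generator defaults define the validation conditions: ~880 genes, 22 cases /
44 controls (the motivating study's scale divided by ~10), modules of
80/60/40 at within-module correlation 0.8, one trait coupling of 0.4, three
hidden components at strength 0.6 vs gene noise 0.6, two outliers at shift
4. Three surrogates matching the pipeline's `n_sv = 3` keeps the estimator's
budget aligned with the planted structure; their strength puts batch noise
on par with biology, the regime in which consortium expression data is
corrected in practice. The negative-loading fraction also suppresses a
spurious global component that constant-sum normalization would otherwise
induce (all-positive module loadings make the column sum co-vary with the
eigengenes).

A separate two-condition fixture plants a *bridge* gene for the
differential-betweenness check: two 8-gene blocks whose latent factors share
a weak common component (cor 0.3), block genes coupled loosely (0.5) so that
two hops through a near-noiseless hub are shorter than a direct edge in the
1/TOM metric, and a bridge gene tracking the average of both factors at 0.98
in cases but pure noise in controls. The factors are built on an exactly
orthonormal basis within each trait group (QR), so subsampling cannot tilt
the planted geometry. 60 samples per group.

### What the synthetic validation does not show

The generator emulates structure, not RNA-seq physics: no GC/length bias,
no isoform structure, no overdispersion beyond Poisson, Gaussian log-scale
noise, linear factor structure, and modules that are cleanly separable by
construction. Passing tests demonstrate that each stage recovers the
structure it assumes when that structure is present at realistic strength —
not that real skin data satisfies those assumptions, and not the motivating
study's data-specific numbers (its module count, chosen β, or per-gene BC
values), which derive from a controlled-access cohort.

## Problem sizes and determinism

Validation runs use 880-gene cohorts (20 seeds for module/outlier recovery),
50 random matrices up to 50 genes for the TOM oracle, 50 graphs of ≤ 8 nodes
for the path-enumeration betweenness oracle, and 17-node fixtures (20 seeds)
for differential-betweenness recovery; the full suite runs in well under
five minutes on one CPU. Every stage is a pure function of its inputs plus
the seed: the same config reproduces byte-identical output tables, which the
pipeline-determinism check enforces file by file.
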
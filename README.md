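# coexnet

Weighted gene co-expression network analysis for case/control RNA-seq
cohorts, with differential betweenness-centrality discovery of *coordinator*
genes — genes whose information-transfer role in a module's network differs
between disease and healthy conditions even when their expression does not.

The package implements the full analysis chain used to study dysregulated
co-expression in diabetic skin: cohort matching, expression preprocessing,
sample-network quality control, weighted network and topological-overlap
construction, module detection, module–trait statistics, per-condition
betweenness centrality, and gene-set / regulatory-network enrichment. Because
the motivating cohort is controlled-access, the package ships a synthetic
cohort generator that plants every structure the analysis assumes (modules,
trait coupling, batch noise, outliers), so the entire pipeline is validated
end-to-end against known ground truth.

## The model

For genes *i, j* with expression profiles *x_i, x_j* across samples:

- **Similarity** `s_ij = |cor(x_i, x_j)|` (unsigned Pearson).
- **Soft threshold** β ≥ 1 chosen by the scale-free topology criterion: the
  smallest β for which the connectivity distribution `k_i = Σ_j s_ij^β` fits
  `log p(k) ~ −γ log k` with signed R² ≥ 0.85.
- **Adjacency** `a_ij = s_ij^β`.
- **Topological overlap**
  `TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)` with
  `l_ij = Σ_u a_iu a_uj`; modules are branches of average-linkage clustering
  of `dissTOM = 1 − TOM`.
- **Module eigengene** (ME): first principal component of a module's
  standardized expression; **module membership** `MM_i = cor(ME, x_i)`;
  **gene significance** `GS_i = |cor(x_i, trait)|` with the trait coded 0/1.
- **Betweenness centrality** on the per-condition module network with edge
  length `1 / TOM_ij`:
  `BC(v) = Σ_{ {i,j} : i≠v≠j } g_ivj / g_ij`,
  where `g_ij` counts shortest *i–j* paths and `g_ivj` those through *v*.
  Genes are ranked by `|BC_case − BC_control|`.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort (880 genes, 22 cases / 44 controls, three planted modules of 80/60/40
genes, the first coupled to the trait at r = 0.4, three hidden batch
components, two planted outliers):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_preprocess_cohort.py
python analysis/03_network_modules.py
python analysis/04_differential_centrality.py
python analysis/05_enrichment_regnet.py
```

Representative output (seed 1):

```
matching: 22 cases kept 44 of 44 controls (2:1 optimal)
gene filters: 880 -> 423 genes (low-count intersection rule, then top 50% MAD)
sample QC: flagged ['S0003', 'S0024'] ({'control': 1, 'case': 1})
adjustment: removed 3 surrogate components; final matrix 423 genes x 64 samples
soft threshold: beta = 5 (signed R^2 = 0.850, mean connectivity = 1.66)
modules: 2 detected ({'M1': 87, 'M2': 37}, 299 unassigned)
module-trait associations:
module     cor      p  p.adj
    M1  0.6064 0.0000 0.0000
    M2 -0.1389 0.2736 0.2736
recovery vs planted labels: ARI = 0.945 (assigned genes only)
trait-significant modules (p <= 0.05): ['M1']
```

The two planted outliers are exactly the flagged samples; the detected M1
contains the planted trait module (adjusted Rand index 0.945 against the
planted partition) and is the only module passing the trait screen, so it
proceeds to differential centrality, where the largest |ΔBC| genes are the
candidates whose network role flips between conditions. The enrichment step
then recovers the module's synthetic pathway/TF/miRNA sets at adjusted
p ≈ 0 and assembles the regulator → gene network (GraphML + SIF).

The same stages are available as a CLI (`coexnet simulate / preprocess / qc /
network / modules / centrality / enrich / run`); `coexnet run --config
pipeline.yaml` executes everything from one YAML config and writes a run
manifest.

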
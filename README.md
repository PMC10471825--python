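# metaqtl

A meta-QTL analysis toolkit for phosphorus-use efficiency (PUE) in rice
(*Oryza sativa*), written for quantitative geneticists and breeders who want
to consolidate QTLs reported by independent mapping studies into a small set
of robust consensus loci, and then walk those loci down to candidate genes
and crossable donor accessions.

PUE is governed by many minor loci whose reported positions scatter across
studies with population-dependent precision. `metaqtl` treats each reported
QTL as a noisy observation of a shared locus: a QTL with confidence interval
CI contributes a position `x_i` with standard error `s_i = CI_i / 3.92`, and
the QTLs on a chromosome follow

    x_i ~ Normal(mu_c(i), s_i^2),

where the number of distinct loci K (and the assignment `c`) is selected by
an information criterion. Chromosomes with ≤ 10 QTLs are solved exactly by
dynamic programming over contiguous segmentations (criterion
`-2 logL + 2K + 3(K-1) log n`); denser chromosomes are fitted as a Gaussian
mixture with fixed per-observation variances by seeded EM
(`AIC = -2 logL + 2(2K-1)`). Each resulting meta-QTL gets a
precision-weighted position, a pooled 95% CI
`pos ± 1.96/√(Σ 1/s_i²)` — typically several-fold narrower than its member
QTLs — and is kept if its members average ≥ 5% phenotypic variance
explained and span ≥ 2 studies.

Around that core the package provides the full chain:

* **qtl_catalog** — catalog I/O with principled imputation of missing
  statistics: `CI = c/(N·PVE)` with design constant `c` (163 RIL / 530
  F2-type), `PVE = 100(1 − 10^{−2·LOD/N})`, peak at the flanking-marker
  midpoint, LOD default 3.0, all provenance-flagged.
* **consensus_map** — a physically anchored map at 1 cM = 250 kb and
  nearest-marker QTL projection.
* **mqtl_engine** — the clustering model above, summaries and filters.
* **cg_miner** — genes overlapping meta-QTL intervals, PUE keyword filters,
  a 1.5-fold / 2-fold expression-response cascade over two timepoints under
  phosphorus-non-supplied vs control conditions (Welch t-tests), and
  hypergeometric GO enrichment with BH FDR.
* **haplotype_tools** — gene-haplotype grouping (k-means on 0/1 SNP
  embeddings, Calinski–Harabasz selection of the group count), superior
  haplotypes from beneficial-allele donors, subpopulation abundance and
  greedy donor-panel selection.
* **synthetic_data** — generators with known ground truth for every stage.

See `docs/methods.md` for the model details and design choices.

## Worked example

Simulate a demo workspace with known truth (three chromosomes carrying 2, 3
and 1 planted loci, surveyed by four studies) and run the full pipeline:

```python
from metaqtl.synthetic_data import simulate_workspace, TrueLayout
from metaqtl.config import RunConfig
from metaqtl.pipeline import run_pipeline

simulate_workspace("demo", TrueLayout(seed=1), seed=1)
summary = run_pipeline(RunConfig(workspace="demo", outdir="demo/results", seed=1))
for k, v in summary.items():
    print(f"{k}: {v}")
```

prints

```
n_studies: 4
n_initial_qtls: 20
n_mqtls: 6
n_mqtls_selected: 3
n_genes_pooled: 15
n_candidate_genes: 7
n_expression_called: 7
n_stage_A: 4
n_stage_B: 4
n_stage_C: 3
n_haplotype_genes: 3
```

The 20 simulated QTLs collapse onto 6 meta-QTLs — matching the 6 planted
loci — of which 3 survive the ≥ 5% PVE / ≥ 2 studies filter. Seven of the 15
genes under the selected meta-QTLs pass the PUE keyword filter, four
respond consistently to phosphorus withdrawal at both timepoints, and three
of those change ≥ 2-fold at 24 h. `demo/results/mqtls_selected.tsv` then
shows the consolidation:

```
mqtl_id  chrom  position_cM  ci95_lo_cM  ci95_hi_cM  ci95_cM  n_members  n_studies  avg_pve
MQTL1.1  1      21.49        18.0        24.98       6.98     3          3          8.8
MQTL1.2  1      70.52        64.38       76.66       12.28    3          3          6.2
MQTL2.1  2      12.25        5.86        18.65       12.79    4          4          6.8
```

— positions within ~1.5 cM of the planted loci at 20, 70 and 15 cM, with
pooled CIs 2.9–3.5× narrower than the average member QTL
(`ci_reduction.tsv`). The same run is available from the shell:

```sh
metaqtl simulate --outdir demo --seed 1
metaqtl run-all --workspace demo --outdir demo/results --seed 1
```

Reruns with the same seed and inputs are byte-identical; every report
carries the configuration hash in its header.

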
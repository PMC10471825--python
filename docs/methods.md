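# Methods

`metaqtl` re-implements, as a tested library, the analysis chain used to
derive consensus ("meta") QTLs for phosphorus-use efficiency (PUE) in rice
and to mine candidate genes and superior haplotypes beneath them. This note
describes the statistical models, the defaults and why they were chosen, the
numerical conventions, and what the synthetic-data generator does and does
not emulate.

## The QTL catalog and imputation model

The input is a catalog of QTLs compiled from independent bi-parental mapping
studies. Each record carries a trait class, chromosome, peak position (cM),
confidence interval (CI), LOD score and phenotypic variance explained (PVE,
%). Source studies are incomplete in different ways, so finalization applies
four rules, each flagged in per-field provenance metadata (`reported` vs
`imputed`):

1. **Peak** — if absent, the midpoint of the flanking-marker interval.
2. **LOD** — if absent, 3.0, the conventional declaration threshold.
3. **PVE** — if absent, from the LOD score and the study's population size
   `N`: `PVE = 100·(1 − 10^(−2·LOD/N))`. This is the exact single-QTL
   relationship between a LOD score and the fraction of variance it
   explains in a population of size N, and is strictly increasing in LOD
   and decreasing in N.
4. **CI width** — if absent, `CI = c/(N·p)` cM with `p = PVE/100` and a
   population-design constant `c`: 163 for recombinant inbred lines (RILs,
   which accumulate recombination over many selfing generations) and 530
   for F2-derived, backcross-inbred, chromosome-segment-substitution and
   doubled-haploid designs. The constant map is configurable
   (`qtl_catalog.CI_CONSTANTS`).

Two gaps had to be closed by decision. Doubled-haploid populations are not
assigned a constant by the empirical CI formulas in the originating
literature; they are mapped to 530 because a DH line, like an F2-derived
line, samples a single meiosis. PVE enters the formula as a proportion, not
a percent: percent-scale inputs would give sub-0.1-cM intervals for typical
N, which no linkage study resolves. When a stated peak falls outside a
stated CI the peak is trusted and the CI widened minimally to contain it
(with a provenance warning). When imputed endpoints `peak ± CI/2` would go
negative the interval is shifted to `[0, CI]`, preserving the width.

## Consensus map and projection

The consensus map is purely physically anchored: markers are ordered by
physical position and assigned genetic coordinates at a fixed
**1 cM = 250 kb**. There is no linkage-based map merging and no
recombination-rate estimation; chromosome-scale comparability across
studies is bought with this deliberately crude but transparent conversion.
Coordinates are 1-based inclusive bp; intervals are closed; density windows
are half-open `[k·w, (k+1)·w)` with `w = 500 kb` by default.

QTLs whose flanking markers carry physical positions are projected by
snapping each flank to the nearest map marker by `|Δbp|` (equidistant ties
break toward the lower position, deterministically) and re-expressing peak
and CI on the consensus cM scale, with the peak at the snapped-interval
midpoint. Records with only cM coordinates pass through unchanged.
Degenerate case: if both flanks snap to the same marker the CI width is
floored at 0.01 cM so the position-error model below stays proper.
Projection preserves bp order and is idempotent.

## The meta-QTL model

On each chromosome the projected QTLs are observations
`x_i ~ Normal(μ_{c(i)}, s_i²)` where `s_i = CI_i/3.92` (a 95% normal
interval spans 3.92 standard deviations) and the unknown number of distinct
loci K is selected by an information criterion. Two fitting paths mirror
standard meta-QTL practice:

**Segmentation path (n ≤ 10 QTLs).** Positions are sorted and partitioned
into K contiguous segments; each segment's mean is the precision-weighted
mean of its members, and the optimal segmentation for every K is found
exactly by dynamic programming (this equals exhaustive enumeration over all
contiguous partitions, which the test suite verifies for n ≤ 7). Model
selection minimizes

    −2·logL(K) + 2K + 3(K−1)·log n.

The `2K` term is the AIC cost of the K means. The `3(K−1)·log n` term is a
modified-BIC changepoint correction for the K−1 segment boundaries: each
boundary is chosen as the best of O(n) candidate positions, and with a flat
per-parameter cost this selection effect makes spurious splits of a single
Gaussian cloud profitable (the median log-likelihood gain of the best split
of a unimodal sample of 5–10 points is ≈ 2.2). With the correction, planted
single-locus chromosomes are recovered at the rates reported by
`scripts/acceptance.py`; without it, recovery of K = 1 drops below 50%.
The penalty is exposed as `mqtl_engine.segmentation_penalty`.

**Mixture path (n > 10 QTLs).** A K-component Gaussian mixture with
component means and mixing weights but *fixed* per-observation variances
`s_i²`, fitted by EM (responsibility-weighted precision means in the
M-step). Initialization is deterministic — means at the K-quantiles of the
positions — plus five jittered restarts from a fixed seed; convergence at
Δlog-lik < 1e−8 or 1000 iterations; weights floored at 1e−8 to prevent
collapse. Model selection uses `AIC = −2·logL + 2(2K−1)` (K means, K−1 free
weights) over K = 1..min(n, 20). Hard assignments take the
maximum-responsibility component; empty components are dropped and clusters
relabeled in increasing-mean order. Ties in either criterion (within 1e−9)
break toward smaller K.

**Summaries.** Each cluster becomes a meta-QTL with position at the
precision-weighted mean of its members, a 95% CI of
`position ± 1.96/√(Σ 1/s_i²)`, PVE as the arithmetic mean of member PVE,
and a physical interval from the fixed cM→bp conversion of the CI bounds.
Meta-QTLs are numbered within chromosome by ascending position
(`MQTL<chrom>.<rank>`). Downstream selection keeps meta-QTLs with average
PVE ≥ 5% **and** support from ≥ 2 distinct studies (both inclusive).

## Candidate-gene mining

Genes overlapping a meta-QTL's physical interval (any overlap, closed
coordinates) are pooled non-redundantly across meta-QTLs. Filters:

* **Keywords** — case-insensitive substring match of a configurable list
  (phosphate, P homeostasis, Pi transporter, phosphorus
  translocation/uptake, crown root, root hair, abiotic stress) against
  annotation text, aliases and GO labels. An empty keyword list is an
  error, because it would silently pass everything.
* **Expression cascade** — fold change is `mean(minusP)/mean(control)` per
  timepoint (6 h, 24 h); down-regulation is measured as the reciprocal
  against the same cutoffs. Stage A requires a consistent direction at both
  timepoints; stage B additionally ≥ 1.5-fold at *both* timepoints (the
  "P-responsive" set — the both-timepoints reading is chosen because stage
  A already requires calls at both, and it is configurable); stage C
  additionally ≥ 2-fold at 24 h. Stages are nested by construction.
  A gene whose true fold change sits exactly at a cutoff is a knife-edge
  case: under replicate noise it crosses the threshold about half the time,
  which is a property of thresholds, not of the estimator.
* **Significance** — two-sided Welch (unequal-variance) t-tests per
  timepoint, tiered at P < 0.10 / 0.05 / 0.01. Identical replicate sets
  return p = 1 by convention.
* **Enrichment** — per GO term, the upper-tail hypergeometric probability
  of the observed foreground overlap, with all pooled meta-QTL genes as the
  background and Benjamini–Hochberg FDR control at 0.05.

## Haplotype grouping and donors

Accessions with more than 20% missing-or-heterozygous calls at a gene's SNP
sites are removed (strict `>`: exactly 20% is retained); surviving
missing/het calls are imputed to the site's major allele *for clustering
only* and reported as-is. Biallelic calls embed as 0/1 vectors; k-means
(seeded, 10 restarts, canonical row/column order for order invariance)
partitions the accessions for each candidate k in 2..min(10, #distinct
strings), and the Calinski–Harabasz index `CH(k) = [B/(k−1)]/[W/(n−k)]`
selects k. A partition with zero within-group scatter scores +inf so exact
splits always win (scikit-learn's implementation scores this degenerate
case as 1.0, which would rank a perfect recovery below an imperfect one —
hence the index is computed from its definition here). Groups with fewer
than three members are dropped and their accessions reported as unassigned;
surviving groups are numbered "Haplotype 1..k" by descending size.
Monomorphic genes short-circuit to a single flagged group.

The superior haplotype of a gene is the group containing a known
beneficial-allele donor accession; if the donor was filtered out, exact
allele-string equality against group profiles is tried, and failing that
the result is "undetermined" rather than an error. Haplotype abundance per
subpopulation reports explicit zero counts. Donor panels are assembled per
subpopulation by greedy set-cover (pick the accession covering the most
not-yet-covered genes; ties break on accession id), which is within the
usual `1 + ln g` factor of the optimal cover.

## Synthetic data

The generator plants ground truth for every stage: true meta-QTL positions
per chromosome (default: three chromosomes with 2, 3 and 1 loci surveyed by
four studies, detection probability 0.85), per-study QTL observations with
`x ~ Normal(true, (CI/3.92)²)` where the CI comes from the population
formulas (clipped to 2–20 cM to keep noise in the range seen in compiled
rice catalogs), PVE from a right-skewed Beta(2, 9.7) scaled to
[1.25, 27.9]% (mode near 4%, matching the concentration of compiled PUE
effect sizes in the 3–6% band), LOD right-skewed on [2.0, 16.98] and mostly
below 5, and configurable missingness masks per statistic. Expression data
are log-normal replicates (3 by default, σ_log = 0.15) with planted fold
changes; SNP matrices draw accessions from planted haplotype centers with
per-site flip/missing/het noise, subpopulation-skewed center weights and a
designated noise-free donor per gene.

What it does **not** emulate: linkage disequilibrium between markers,
heterogeneous marker density along chromosomes, correlated traits within a
study, probe-level microarray artifacts, or realistic 3K-panel allele
frequencies. Passing recovery tests therefore demonstrate correctness of
the estimators under their own model assumptions, not performance on any
particular real dataset.

Test and demonstration problem sizes (3 chromosomes, ≤ 40 QTLs, hundreds of
markers, tens of genes, ~30 accessions per gene) are chosen so the full
suite and the acceptance script each run in a couple of minutes on one
core; all generators scale by parameters.

## Reference summary fixtures

`src/metaqtl/data/rice_pue_*.tsv` transcribe the headline summary numbers
of the compiled rice PUE meta-QTL catalog (per-chromosome counts of initial
QTLs and meta-QTLs, the 38 multi-study meta-QTLs with their positions and
CIs, and the 16-study overview). They are consistency surfaces for tests
and reporting — the per-chromosome totals, CI statistics and interval
identities are recomputed from them at run time — not pipeline inputs.

## Determinism and reproducibility

Every stochastic component (catalog, map, expression and SNP simulation; EM
restarts; k-means) is driven by an explicit integer seed. Reports carry a
configuration hash (inputs, thresholds, seed; the output directory is
excluded) and rerunning the pipeline with the same inputs, configuration
and seed reproduces every report byte-for-byte. Report rounding follows
publication precision: positions and CI bounds to 2 decimals, PVE to 1.

## Known limitations

* The 1 cM = 250 kb conversion ignores local recombination-rate variation;
  physical intervals derived from meta-QTL CIs inherit this distortion.
* The segmentation and mixture criteria can disagree near n = 10; the
  dispatch threshold is configurable but discontinuous by design.
* The expression cascade treats replicate signals as exchangeable and uses
  plain Welch tests; no between-array normalization is attempted.
* Haplotype grouping with k-means on 0/1 embeddings is a surrogate for the
  unknowable internals of interactive database tools; exact memberships of
  published haplotype groups are not reproducible targets, and the module
  is agnostic to whether sites are synonymous or non-synonymous.
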
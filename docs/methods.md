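# Methods

## Overview

`dysreg` analyses matched tumor/normal expression cohorts for transcriptional
dysregulation: which gene categories (transcription factors, RNA-binding
proteins, lncRNAs, cancer-related genes, mutation classes) are over- or
under-represented among differentially expressed (DE) genes, how strongly
each category's expression shifts, whether highly altered RBPs sit upstream
of cancer-gene neighborhoods in a protein-protein interaction (PPI) network,
whether RBP expression changes track copy-number rather than methylation
changes, whether tissue-specific genes lose expression in their matched
cancer, and which cancer types perturb the same pathways.

Because the real inputs are large controlled-access compendia, the package
ships a synthetic multi-cohort generator that plants each of these signals
with recorded ground truth; every statistical claim the package makes is
validated against that ground truth.

## Differential expression

Per gene, a two-sided paired t-test on `log2(x + c)`-transformed values of
the matched tumor/normal pairs (pseudocount `c = 1`, configurable).  The
fold change is the mean over pairs of `log2((T_i + c)/(N_i + c))` — for
log-transformed data this is exactly the mean paired difference the t-test
examines, which keeps the statistic and the effect estimate consistent
under the paired design (a ratio-of-means variant is not offered; the mean
of per-pair ratios is the paired-design-native choice).  P-values are
Bonferroni-adjusted over all genes tested in the cohort and a gene is DE
when `p_adj < alpha` (default 0.05).

Numerical and degenerate-input choices:

* genes with identical tumor and normal vectors are retained with `p = 1`
  and a NaN t statistic, so the tested universe is stable;
* constant non-zero differences give `p = 0` (infinite t);
* the test operates on the log scale because the t-test's normality
  assumption fits log-abundances; the raw scale is not offered as a default.

On null data the test is essentially exact: pooled over 200 simulated null
cohorts of 5000 genes x 30 pairs the raw rejection rate at alpha = 0.05 is
0.0497 and the Bonferroni family-wise error rate 0.05 (the acceptance suite
recomputes both).

## Enrichment and depletion

For universe size `N` (the cohort's measured genes), category size `K`, DE
count `n` and overlap `k`, the enrichment p-value is the upper hypergeometric
tail `P(X >= k)` and the depletion p-value the lower tail `P(X <= k)`, both
including the observed count (the standard over-representation convention).
The two tails overlap in `P(X = k)`, so they sum to at least 1.  A cell is
labeled `enriched`/`depleted` when the corresponding tail is at or below the
display threshold (default 0.05) and `neither` otherwise.  No correction is
applied across the category x cohort matrix; the p-values are reported raw,
and the display threshold plays the role of the usual heat-map whitening
cutoff.

The universe of every enrichment statistic is the cohort's own measured
genes, never a union across cohorts — genes in a catalog but not measured
are invisible to that cohort (`intersect_universe` enforces this; the
restriction is idempotent and never enlarges a set).

A caveat worth knowing when interpreting `neither`: enrichment is always
relative to the cohort's overall DE rate.  If some categories are strongly
enriched (or genes are planted DE outright), every *average* category is
mechanically pushed toward depletion, because the mixture rate exceeds the
background rate.  A category only behaves as a calibrated null when it is
exchangeable with the background — same DE probability and same effect-size
distribution.  The validation suite constructs its neutral category that
way.

## Tissue-specific gene direction

For the tissue set matched to a cohort (GMT description field carries the
cohort id), the report contains the enrichment cell, the fraction of DE
tissue genes with negative fold change, an exact two-sided binomial sign
test of that fraction against 0.5, and a one-sided rank-sum test that the
signed fold changes of DE tissue genes lie below those of all other DE
genes.  A cohort without a matched tissue set is skipped with a log message
rather than an error.

## RBP cascade

DE RBPs are ranked by `|log2fc|` descending (ties: adjusted p ascending,
then symbol) and truncated to `top_k` (default 20).  Restricting the ranking
to DE RBPs avoids promoting high-fold-change genes that never reached
significance; `de_only=False` ranks all RBPs for sensitivity analysis.  For
each ranked RBP, two one-sided hypergeometric tests are run on its first
PPI neighbors: DE genes among them, and cancer-related (allOnco) genes
among them.  The enrichment universe is the intersection of the cohort's
measured genes with the network's nodes — using network nodes avoids bias
from proteins that cannot appear in any neighborhood.  An RBP is a cascade
RBP when both p-values fall below the threshold (default 0.05; no
correction across the top-k tests — the procedure is a screen, not a
confirmatory test).  The exported subnetwork keeps selected RBPs and only
their neighbors that are both DE and allOnco, with node roles annotated for
downstream network tools.

Under independence a null RBP passes both screens with probability at most
`threshold^2`; the acceptance suite verifies the realized false-selection
rate stays below twice that bound on null networks with uniform DE rates
(with category-specific rates the two screens are positively correlated and
the bound does not apply).

## Genetic vs epigenetic attribution

For each RBP, the per-patient expression change (per-pair log2 ratio with
pseudocount) is correlated with the gene's value in the tumor-sample CNV or
methylation matrix using Spearman's rank correlation (average ranks, so
tie-robust); `R^2` is the squared correlation, exactly.  Tumor-sample assay
values are used (not tumor-minus-normal differences) because matched-normal
CNV/methylation columns are typically unavailable; rows are matched to
expression pairs via the tumor sample id.  Genes absent from the matrix,
with fewer than `min_samples` (default 8) matched samples, or with zero
rank variance are excluded and counted.

DE and non-DE RBPs are compared with a one-sided Wilcoxon rank-sum test of
`R^2(DE) > R^2(non-DE)` — the directional hypothesis that expression changes
of deregulated RBPs are driven by dosage.  The null distribution is
enumerated exactly when both groups have at most 10 members (mid-ranks for
ties; `P(W >= w_obs)`), otherwise the normal approximation with tie
correction is used; the two branches agree to < 0.01 on borderline sizes.

## Pathway-restricted clustering of cancer types

The distance between two cohorts is `1 - rho_S` of their log2 fold-change
vectors over shared genes (so anticorrelated cohorts are maximally far
apart, distance up to 2), computed over all shared genes by default —
restricting to DE genes is available but discards the coherent sub-threshold
signal that makes pathway profiles comparable.  Each pathway with at least
10 shared genes gets its own distance matrix and dendrogram, alongside an
all-genes dendrogram.

Clustering is agglomerative with average linkage (monotone merge heights on
correlation distances; complete and single linkage available).  Exact
distance ties are broken by the lexicographically smallest pair of sorted
member tuples, so the tree is a deterministic function of the input.
Trees are exported as newick with UPGMA-style branch lengths (parent height
minus child height, halved) rounded to 6 decimals for reproducible text
output.

## The synthetic generator

Expression model per gene `g` and pair `i`:

    N_gi = exp(mu_g + eps),   T_gi = exp(mu_g + delta_g * ln2 + eps')

with `mu_g ~ Normal(baseline_log_mean, baseline_log_sd)` and i.i.d.
`eps ~ Normal(0, noise_sd)`.  `delta_g` is the planted log2 effect: zero
unless the gene is DE in that cohort, in which case `|delta| ~
Exponential(effect_scale[category])` with a random sign.  The log-normal
with additive log-noise is chosen so the paired t-test on log-scale data is
exactly calibrated; the generator does not emulate count noise
(negative-binomial dispersion), batch effects, or library-size artifacts,
so passing tests demonstrate statistical correctness of the pipeline, not
robustness to those real-data pathologies.

Key defaults and why:

| parameter | default | role |
|---|---|---|
| n_cohorts / n_genes / n_pairs | 4 / 5000 / 30 | a mid-sized multi-cohort study; 30 pairs matches typical matched-pair cohort sizes |
| baseline_log_mean / sd | 5.0 / 1.0 | abundances ~ e^5, large enough that the pseudocount is negligible |
| noise_sd | 0.2 | per-sample log-noise; gives the paired test ~50% power at \|delta\| ~ 0.4 after Bonferroni over 5000 genes |
| de_prob | allOnco 0.35, RBP 0.30, COSMIC class 0.20, TF/other 0.10, lncRNA 0.03 | the enrichment/depletion pattern the matrix stage should recover |
| effect_scale | allOnco 2.6 > TF 2.0 > lncRNA 1.5 > RBP 1.0 (other 1.2) | the amplitude ordering the CDF comparison should recover; gaps sized so rank-sum and mean orderings are detectable at these sample sizes |
| n_hub_rbps / hub_neighbor_count | 5 / 30 | cascade signal |
| hub_min_effect | 3.5 | hubs must dominate the top-k fold-change ranking for the cascade screen to see them; without a boost, hubs drawn from the same effect distribution as other DE RBPs would regularly fall outside the top 20 |
| hub_onco_frac / hub_de_frac | 0.5 / 0.7 | neighborhood composition of a true cascade RBP |
| cnv_coupled_frac / cnv_rho_target | 0.5 / 0.6 | half of each cohort's planted-DE RBPs get dosage-coupled CNV |
| tissue_set_size / tissue_under_frac | 100 / 0.8 | per-cohort tissue set, planted DE in the matched cohort only, 80% down (count fixed by rounding, not redrawn, so the planted fraction is exact) |
| pathway_effect_scale / jitter | 1.5 / 0.3 | coupled pathways share one effect vector plus jitter between the two similar cohorts |
| mean_degree | 6 | Erdos-Renyi background PPI density |

Effect sizes are tuned for test power, not biological realism; no published
effect magnitudes exist for these contrasts.

CNV coupling calibration: the per-pair log2 change of a gene has standard
deviation `sigma_x = sqrt(2) * noise_sd / ln 2`; coupled CNV values are the
realized change plus `Normal(0, sigma_eta)` noise with `sigma_eta` solved
from the bivariate-normal relation `rho_S = (6/pi) * arcsin(rho_P / 2)` so
the population Spearman correlation hits `cnv_rho_target`.  The pseudocount
slightly attenuates realized changes for low-abundance genes, so observed
coupled correlations sit just under the target (0.57-0.58 for a target of
0.6 at default baselines).  Methylation is independent Beta(2,2) noise —
the planted negative control.

All randomness derives from one seed through ordered
`numpy.random.SeedSequence` substreams (layout, network, then per-cohort
planting / expression / CNV / methylation), so identical config + seed
yields bit-identical files; TSV writers emit shortest round-trip float
representations and readers parse with round-trip precision, making
write-read the identity.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run the generator at the study
conditions above: 200 null cohorts of 5000 genes x 30 pairs for type-I
error; 50 seeds (20 in the script) of 5000-gene cohorts for each
planted-signal recovery rate; exhaustive hypergeometric enumeration up to
N = 12; 100 random instances against a quadrature oracle for the t-test;
brute-force linkage oracles up to 6 leaves.

## Known limitations

* Gene identity is the bare symbol; no alias resolution or ID mapping.
* Expression inputs are assumed already normalized and non-negative; no
  count-model DE (negative binomial) is provided.
* Enrichment p-values are reported without cross-matrix correction, by
  design; treat the matrix as descriptive.
* CNV input must already be gene-level (no segment mapping); methylation
  must already be summarized to genes.
* The generator's categories are disjoint, unlike real catalogs where RBPs
  can also be cancer genes; overlap handling in the analysis code is
  nevertheless exercised by the tissue/pathway sets, which overlap the
  `other` category.
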
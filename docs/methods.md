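# Methods

`aktx` reimplements, as a tested pipeline, a transcriptomic analysis of
actinic keratoses (AKs) treated with topical imiquimod: digital panel counts
profiled before and after field therapy, compared between timepoints and
between complete responders (CR, zero lesions at week 14) and incomplete
responders (IR), followed by network-based interpretation of the resulting
gene lists. The original patient-level counts are not publicly deposited, so
the package ships a first-class synthetic generator that reproduces the
study's design and lets every stage be validated against planted ground
truth.

## Count model and synthetic cohort

Counts are gamma-Poisson (negative binomial): for gene *g* and sample *s*,

    mean(g, s) = L_s * b_g * 2^(beta_g * I(group_s)),  var = mean + phi * mean^2

with per-sample library factors `L_s` lognormal with mean 1 and configurable
coefficient of variation (default 0.2), per-gene baselines `b_g` log-uniform
on 4..500 counts, dispersion `phi` constant per probe class (0.1 endogenous
and spiked probes, 0.01 housekeeping and positive controls). Housekeeping
genes draw baselines from 200..1000 and carry no group effects. Positive
controls scale with their nominal concentrations — a geometric ladder with
ratio 1/4 from A down to F, scaled so the lowest spike (POS_F) averages
about 8 counts, the order of magnitude the platform reports for its 0.125 fM
spike. Negative controls are Poisson with mean 2.

The default cohort mirrors the study: 19 patients, 14 with matched pre/post
biopsies and 5 unmatched (split 3 pre-only / 2 post-only, giving 17 pre and
16 post samples), 7 CR and 12 IR, and 8 patients with adverse events (AEs)
drawn with 3:1 weight toward CR because AEs co-occurred with response.
Planted effects: 70 response-associated genes at |log2FC| = 2 (92% up in
CR) and 11 treatment-responsive genes down-regulated post treatment. The
response count is derived from the study's report of 103 significant genes
at per-gene p < 0.05: an observed count pools true positives with the null
stratum's false positives, so with per-gene power near 0.95 at this effect
size the expected observed count is 70 x 0.95 + 718 x 0.05 = 102. The
treatment count matches the 11-gene adjusted-p list directly because BH at
q = 0.05 admits almost no false positives at this signal strength. Effects
are planted only on measured genes whose baseline sits safely above the
detection limit (>= 4x the POS_F mean); assigning an effect to a control
probe is an error.

Lesion counts: Lmax (the maximum AK count during treatment) is
1 + Poisson(mean 8); each patient clears completely with the configured
probability, and non-cleared patients retain 1 + Binomial(Lmax - 1, 0.3)
lesions, so week14 <= Lmax always holds and CR iff week14 = 0. A separate
`null=True` mode draws week 14 independently from the Lmax distribution —
deliberately abandoning the week14 <= Lmax guarantee — solely to verify that
the paired efficacy t-test holds its nominal type-I error.

## What the generator does and does not emulate

It emulates: overdispersed digital counts with library-size variation,
stable housekeeping genes, a control ladder that defines a detection limit,
group effects on the multiplicative (log2) scale, a matched/unmatched
design, and background networks with planted out-degree hubs. It does not
emulate: probe-specific efficiency, batch or lane effects, FFPE RNA
degradation, correlated gene modules (planted genes are independent), tied
biological pathways, or dropout structure. Passing tests therefore show the
pipeline's statistics behave correctly under the design assumptions, not
that the biological conclusions of any particular dataset would replicate.

## Normalization

Housekeeping content normalization: factor(s) = (arithmetic mean over
samples of housekeeping geometric means) / (geometric mean of sample s).
Zero housekeeping counts are excluded from a sample's geometric mean with a
logged warning; an all-zero housekeeping sample is an error. Note the
reference depends on all samples, so rescaling one sample rescales every
normalized value through the reference by one common constant; the invariant
tested is that values relative to the reference are unchanged and that every
sample's normalized housekeeping geomean equals the reference exactly.

Detection-limit filter: a measured gene is zeroed when its across-sample
mean raw count is strictly below the across-sample mean POS_F count; ties
keep the gene; control probes are never zeroed. The per-gene mean rule
excludes a transcript globally rather than per sample. The log transform is
log2(x + 1) applied after zeroing so filtered rows map to exactly 0, and
zeroed genes are excluded from every downstream test (reported as
untested). Positive-control (lane) normalization is not applied: the
housekeeping step is the documented default and the ladder's role here is
the detection limit.

## Differential expression and related tests

* Pre vs post: two-tailed paired t on within-patient (post - pre) log2
  differences over matched patients; log2FC is the mean difference. Genes
  with identically zero differences get t = 0, p = 1; zero variance with a
  nonzero mean gives p = 0 (perfect separation).
* CR vs IR and AE vs no-AE: Welch's unequal-variance t on pre-treatment
  log2 values — chosen over the pooled test because the groups are small
  and unbalanced (5 vs 9 at study scale).
* Multiple testing: Benjamini-Hochberg step-up across tested genes
  (statsmodels); per-gene p < 0.05 is used for the CR/IR gene count,
  adjusted p < 0.05 for the pre/post headline list, matching the study's
  two reporting conventions.
* DE-count enrichment: the study cites an exact test for "more significant
  genes than expected" without printing the contingency table; the only
  construction recoverable from the printed numbers is the one-sided exact
  binomial tail P(X >= n_sig), X ~ Binomial(n_total, alpha), which is what
  `de_count_enrichment` computes.
* Efficacy: two-tailed paired t of Lmax against the week-14 count; zero
  differences across the board return t = 0, p = 1 rather than an error.

## Clustering

Gene distance is 1 - Pearson r (0..2); constant rows are dropped with a
warning before clustering since r is undefined for them. Linkage defaults to
average (UPGMA) — the default of the heatmap tool the study used — with
complete and single available. Heatmap rows are z-scored (ddof = 1); gene
order is the dendrogram leaf order and samples are ordered CR first, then
IR, by patient id; both orders are emitted so either display convention can
be rendered. Agglomeration is delegated to scipy; tests check it against a
brute-force reference agglomerator on random matrices.

## pathFinder

The background network mixes directed and undirected edges; each undirected
edge is stored as two opposite directed edges sharing a `pair_id`, and a
path may use at most one member of a pair. From every input gene a DFS
enumerates all directed paths with at most k edges (default k = 2, i.e. one
intermediate node); paths are simple (no node revisits) — the pair rule
forbids the immediate A→B→A case and the simple-path rule extends that to
all revisits, which also bounds the search. The zero-length path is always
included so isolated input genes stay in the output. Whether only paths
terminating at another input gene should count is ambiguous in the method's
description; the default keeps all DFS paths (per the explicit stopping
rule) and a `connecting_only` flag provides the strict mode. The extracted
subnetwork reports density as interactions / (n (n-1)), counting each
derived pair once.

## Key-driver analysis

The background sub-network is the direction-ignoring k-step neighborhood of
the target list (k_max = 3); it is also the enrichment universe. Each node's
k-step directed downstream neighborhood (k = 1..k_max) is scored by the
one-sided hypergeometric tail of its overlap with the targets; each node
keeps its best p with the achieving k recorded, BH adjustment runs across
nodes, and ranking is by adjusted p then node id. Nodes with empty
downstream neighborhoods are skipped. The hypergeometric with sub-network
universe is the minimal exact test for "enrichment of a neighborhood for a
list"; scanning k and keeping the best preserves the scale information.
During reachability, derived edge pairs need no special handling: reusing a
pair within one walk necessarily revisits a node and cannot extend the
reachable set.

## Over-representation analysis

The pathway method referenced by the study is not reconstructable from its
description, so standard hypergeometric ORA over user-supplied GMT
collections substitutes, with the measured panel (788 genes by default) as
universe. Gene sets are intersected with the universe before testing; BH
runs across sets. `overlap_pathways` reports set names significant in two
result tables, mirroring the study's comparison of response- and
AE-associated pathway lists.

## Pipeline, determinism and numerical choices

`run_pipeline` composes the stages in study order from one declarative
config (YAML-loadable), logs per-stage gene counts, names the failing stage
on error while retaining partial outputs, and writes a summary JSON with the
seed and a config hash; identical config and seed give byte-identical
artifacts. All randomness flows through `numpy.random.default_rng` seeded
from the config. Ties in sorted result tables break by gene/node/set id
(stable mergesort). p-values are never clipped except BH's cap at 1.

## Problem sizes used in validation

The test suite exercises: the full 788-gene panel with the 19-patient
cohort (DE recovery, 20 seeds), 14 patients at 5 CR vs 9 IR (group DE and
heatmap separation, 20 seeds), 500 null genes for calibration (KS), random
mixed networks with up to 30 nodes against exhaustive path enumeration (50
instances), and 200-node networks for key-driver recovery (50 seeds) and
null calibration (100 seeds). The same sizes drive `scripts/acceptance.py`.

## Known limitations

* The housekeeping formula and detection-limit statistic are faithful
  reconstructions of vendor-documented behavior, not a reimplementation of
  the vendor software; per-lane positive-control scaling is omitted.
* ORA ignores gene-gene correlation and set overlap; planted signatures are
  the only truly enriched sets in synthetic collections.
* Welch's t on log2(x + 1) values is approximate for genes near the
  detection limit; calibration is verified empirically, not guaranteed.
* The synthetic efficacy t-statistic depends on the lesion-count model's
  variance, which is narrower than real clinical counts; it demonstrates
  the test, not the study's effect size.
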
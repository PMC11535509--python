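# Methods

This note documents the statistical model behind `tapcall`, the defaults and
why they are what they are, the numerical conventions, and what the
synthetic-data tests do and do not establish about real data.

## Data model

The central object is a proteins × samples matrix of log2 LFQ intensities
with an explicit boolean `observed` mask.  Zero intensities and blank cells
in the input are both treated as missing because MaxQuant writes `0` for
proteins it could not quantify in a sample.  The mask is authoritative and
never changes after imputation: downstream code can always distinguish
measured from imputed cells, and a round trip through the TSV dialect
preserves values to 6 significant digits and flags exactly.

Protein identity for matching (bait lookup, annotation lists) uses the
leading majority-protein identifier, falling back to any identifier in the
group and then to the gene symbol, because annotation sources mix UniProt
accessions and gene symbols.

## Filtering

Reverse-decoy, contaminant and only-identified-by-site rows are dropped
first.  The annotation filter restricts the universe to a curated list (for
mitochondrial work, typically ~1300 proteins); membership is tested against
every identifier of a group.  The replicate-presence filter requires ≥ 2
observed replicates; whether the quota must hold in *every* condition
(default) or in *at least one* is a configuration switch, because published
phrasing of this rule is often ambiguous between the two readings.  Both
modes are implemented and the pipeline records which was used.

## Imputation

Missing values are drawn per sample column from
Normal(μ − 1.8σ, (0.3σ)²), where μ and σ are the mean and SD (n−1
denominator, appropriate at small replicate counts) of the observed values
in that column.  This is the standard left-censored imputation for
label-free proteomics: dropout concentrates at low abundance, so imputed
values should sit in the left tail of the per-sample intensity
distribution.  Imputation happens once, on the full matrix, before any
statistics; both the enrichment test and the correlation classifiers
consume the imputed matrix, which makes the whole pipeline deterministic
given the master seed.

## Co-enrichment test (Classes A/B)

Per protein, the moderated statistic is

    d = (x̄_b − x̄_c) / (√(s²_b/n_b + s²_c/n_c) + s0),    s0 = 1 by default.

s0 damps the significance of small fold changes with tiny variance; at
s0 = 0 the statistic is exactly Welch's t (asserted against
`scipy.stats.ttest_ind` in the tests).

The null distribution reshuffles the bait/control labels of the pooled
samples preserving group sizes.  When C(n, n_b) ≤ `n_permutations`
(default 250) all assignments are enumerated — a 4v4 comparison has 70 —
making the procedure fully deterministic; otherwise a seeded sample of
distinct assignments is drawn.  The identity assignment is always included
(SAM convention; conservative).  A consequence worth knowing: the observed
labeling and, for equal group sizes, its mirror contribute |d_obs| to the
null, so the smallest achievable FDR for a single extreme protein is
2/n_assignments — a 3v3 design (20 assignments) can never reach FDR 0.05
for one protein, while 4v4 can (2/70 ≈ 0.029).

The FDR estimate at a candidate threshold t (candidates are the sorted
observed |d|) is

    FDR(t) = E_perm[#{null |d| ≥ t}] / max(1, #{observed |d| ≥ t}),

with π0 fixed at 1 (conservative; no π0 estimation) and clipped to [0, 1].
The curve is monotonized by a running minimum over ascending thresholds, so
the operative FDR at t is the best raw estimate achievable at any threshold
≤ t and can only improve as t rises.  Class A is every protein at or above
the smallest threshold with FDR ≤ 0.05; Class B analogous at 0.10; ties at
the threshold are all included (deterministic, order-independent).
Two-sidedness is on |d|, which reproduces the familiar curved volcano
cutoff implicitly.  The per-protein permutation p-value is the pooled
(1 + #{null |d| ≥ |d_i|}) / (1 + N_null).

On instances small enough to enumerate, classification is asserted
bit-identical to an independent brute-force oracle written in plain Python.

## Correlation classifiers (Classes C/D)

Class C is the Pearson correlation between prey and bait profiles across
the bait's TAP samples plus the control TAP samples, called at r ≥ 0.6
(boundary inclusive).  The mean local correlation of Class A interactors is
computed and reported alongside, but never auto-applied as the threshold —
the operative cutoff is always the configured one, so per-condition
overrides (e.g. a stricter 0.8) behave predictably.

Class D correlates each prey with the bait across *all* samples of all
conditions and controls significance with a permutation FDR (default 0.05).
The null shuffles each prey's profile across sample positions rather than
relabeling conditions, because the statistic is a profile correlation, not
a group contrast.  Class D is one-sided on positive r: co-purification with
the bait is directional.  Constant profiles have no defined correlation;
such pairs are flagged not-evaluable and excluded from both classes.  The
bait correlated with itself is r = 1 by construction; self pairs are kept
but flagged, and recovery scoring excludes them.

## Interactor calls, network, iBAQ QC

A prey is an interactor if it falls in ≥ 1 class; classes are computed
independently and unioned, with the primary class ordered A > B > C > D.
Edges are deduplicated per (bait, prey); a prey called by two baits yields
two edges.  Edge style records evidence type ("co-enrichment" for A/B,
"correlation" for C/D).  Self edges are retained but flagged, and overlap
and recovery counts exclude them.

iBAQ (summed peptide intensity over the count of theoretically observable
peptides) is taken from input columns when present; the in-silico peptide
count — fully tryptic, cleavage after K/R except before P, zero missed
cleavages, length 7–30 — is fixed by convention here so that tests are
deterministic.  The bait-enrichment QC divides the bait's iBAQ by the
per-sample median iBAQ of detected proteins and summarizes per condition as
mean ± SEM; a flag is raised when the bait condition does not exceed the
control.

## Remodeling

Gained/shared/lost percentages are taken over the union of the control and
condition interactor sets, so the three always sum to 100.  Which evidence
classes define an "interactor" for this comparison is configurable
(default A∪B∪C, matching the common practice of excluding the global
correlation tier from knockdown comparisons); per-condition threshold
overrides are applied before the sets are formed.

The log2FC heatmap matrix carries per-comparison fold changes through
without recomputation; preys absent from a comparison give missing cells.
For clustering, missing cells default to zero-fill ("no evidence of
change"); a pairwise-complete mode computes Euclidean distances over shared
cells rescaled to the full dimension, √(p · mean(diff²)), and fails loudly
when two rows share no cells.  Linkage is complete (cluster distance = max
pairwise distance) on Euclidean distances via scipy; scipy's deterministic
tie handling is accepted as-is.  PCA treats samples as observations with
per-protein mean centering and no variance scaling.

## Synthetic data generator

Per protein, a baseline log2 intensity ~ Normal(25, 2²) (typical of deep
LFQ experiments); per sample, replicate noise ~ Normal(0, 0.5²).  Each bait
condition has a per-sample latent abundance factor ~ Normal(0, 0.5²); the
bait row gains `bait_log2_enrichment` (default log2 20 ≈ 4.32, a strongly
enriched bait) plus the factor in its own TAP samples, and each planted
prey gains its log2 effect size plus `bait_coupling` (default 0.7) times
the same factor — this coupling is what makes planted prey profiles
correlate with the bait's, the structure Classes C/D exploit.  Dropout is
missing-not-at-random: each cell is censored with probability
logistic((midpoint − value)/slope), midpoint 21 (4 SD below the intensity
center) and slope 1 by default, which yields a few percent missingness
concentrated at low abundance and justifies testing the down-shifted
imputation.  All randomness flows from one master seed through named
per-stage streams; identical seeds give bit-identical datasets.  The
exported iBAQ matrix reuses the linear intensities (i.e. values already on
the per-peptide-normalized scale).

The generator does **not** emulate peptide-level quantification, shared
peptides and protein-group inference, ratio compression, batch effects, or
correlated contaminant background.  Passing tests therefore establish that
the statistics behave as specified under the model they assume — correct
null calibration, recovery of additive log2 effects, FDR control under
independence — not that any particular real dataset satisfies that model.

## Problem sizes and test design

The calibration suites use 5000 proteins × 4v4 replicates over 20 seeds for
the co-enrichment null, 2000 preys × 24 samples over 20 seeds for the
global-correlation null, and 800 proteins with 40 planted 4-log2 effects
over 20 seeds for recovery — large enough that the binomial Monte-Carlo
error on a 5 % rate is a fraction of the bound being checked, and small
enough to run in seconds.  Recovery is scored at Class A with bait
self-rows excluded from both truth and calls; the false-discovery
proportion is micro-averaged (pooled) over seeds.

## Known limitations

* The permutation FDR is a global-threshold procedure on |d|; it does not
  produce per-protein q-values below 2/n_assignments and is conservative
  under strong signal (true positives inflate the observed tail count).
* With few replicates the local correlation (Class C) is a weak classifier:
  under pure noise across 8 samples, r ≥ 0.6 occurs for a noticeable
  fraction of preys.  This mirrors its role as the lenient, inclusive tier;
  confidence ordering A > B > C > D is preserved in all outputs.
* Imputation assumes each sample column has ≥ 2 observed values and fails
  loudly otherwise rather than guessing.
* The iBAQ peptide-counting convention matters only when iBAQ columns are
  absent from the input; when present they take precedence.
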
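# Methods

## Scope and data model

methexpr integrates two-group (cancer vs normal) DNA methylation measured
on Illumina-style beta-value arrays with gene-level differential expression.
Inputs are per-cohort probe × sample beta matrices with sample sheets, an
Illumina-style probe manifest (probe position, gene associations, CpG-island
relation, platform membership), BED12 gene models, a gene-level expression
status table (logFC, p, UP/DOWN/NS), and — for the correlation stage — a
cohort in which methylation and expression were measured on the same
samples. Internally all coordinates are 0-based half-open (BED convention);
manifest positions (1-based) are converted on read. Gene identity is the
symbol string; no identifier mapping is attempted.

## Differential methylation

Per probe and cohort the effect is Δβ = mean β(cancer) − mean β(normal),
reported in beta units because the downstream fold-change thresholds
(0.2 high/low split, 0.5 cap) are defined on that scale. Significance
comes from a two-sided Welch *t* test on beta values (pooled-variance *t*
available via `TestConfig(test="pooled")`). A moderated/shrunken variance
estimator is deliberately not used: at the cohort sizes this pipeline
targets (≥ 60 samples per arm) variance moderation changes almost nothing,
and the Welch test has a closed form that an independent oracle can verify
to 1e-10. Calls: HYPER (Δβ > 0, p < α), HYPO (Δβ < 0, p < α), else NS,
with α = 0.05 on raw p by default; `adjust="BH"` switches the call to
Benjamini–Hochberg-adjusted p (statsmodels implementation). Probes with
fewer than 3 non-missing values in either condition are *untestable* — they
are excluded from the cohort's result table (and hence from consensus)
rather than labelled NS. Probes with zero variance in both groups get
p = 1 and NS (the *t* statistic is undefined there).

## Consensus and regulation groups

A probe's consensus over a set of required cohorts is HYPER (HYPO) iff it
is testable in **every** required cohort and called HYPER (HYPO) in all of
them; anything else — including being untestable in one cohort — is NONE.
This makes the consensus monotone: adding a cohort can only shrink the
HYPER/HYPO sets. The probe's cross-cohort mean Δβ averages over all cohorts
where it was testable.

Gene methylation status is UP / DOWN / BOTH / NONE from its probes'
consensus; crossing with expression status yields memberships among UPUP,
UPDOWN, DOWNUP, DOWNDOWN. BOTH-status genes join every
direction-compatible group and are flagged inconsistent — they are
reported, not silently dropped, and the later "-only" filter removes the
ambiguity. Genes with expression status NS, or without an expression
record, get empty membership (the latter are tallied in the log). The
gene-level average fold change is the unweighted mean of Δβ over **all**
testable mapped (probe, cohort) pairs, significant or not.

The "-only" refinement tallies each UPUP/UPDOWN gene's probes on a single
dense cohort: kept ("only") with ≥ 1 HYPER and 0 HYPO dense probes;
otherwise excluded with the reason recorded (`excluded_hypo`,
`excluded_no_hyper`, `excluded_no_probes`), so the categories exactly
partition the base group. Gene ranking uses the mean raw p over a gene's
dense HYPER probes, ascending, ties broken lexicographically on the symbol
(every tie-break in the package is lexicographic, for reproducibility).

## Correlation binning

Pearson r is computed per (probe, gene) association across all shared
samples, cancer and normal pooled (a per-condition option exists but is off
by default — the pooled profile is what the matched design measures).
Associations with fewer than 3 pairwise-complete pairs or a constant
profile are flagged undefined and excluded from bin percentages. The 11
bins use |r| boundaries 0.1 / 0.2 / 0.4 / 0.5 with labels very weak / weak
/ intermediate / strong / very strong × negative / positive, plus
"no correlation" exactly at r = 0. Boundary membership is half-open
(lo, hi] on |r| — the published ranges do not state edge ownership, so the
edge is assigned to the inner bin (|r| = 0.4 is intermediate, |r| = 0.5 is
strong); values beyond |r| = 1 by more than 1e-12 are errors, within that
tolerance they are clamped.

## Genomic context

TSS distances are signed and strand-aware: d = probe − TSS on + genes and
TSS − probe on − genes, so negative means upstream; d = 0 (exactly at the
TSS) counts downstream. With several TSSs the nearest (minimum |d|) wins,
ties going to the upstream offset. Window counts use |d| ≤ w for
w ∈ {50, 100, 200, 300, 400, 500, 1000, 1500, 2000}; membership in any-TSS
windows coincides with nearest-TSS membership because both reduce to
min |d| ≤ w. The signed histogram uses fixed half-open [lo, hi) bins from
(−∞, −1500) to [2000, ∞) and splits each bin into high (|Δβ| ≥ 0.2) and
low fold-change probes. CGI summaries count probes per six-level relation
(Island, N/S Shore, N/S Shelf, None), pool shores and shelves across N/S
for gene counts, and report the fraction of genes with at least one listed
probe in an island, shore or shelf. Region fractions intersect each probe
with the BED12-derived geometry of its *associated* gene only (never
genome-wide); a probe may count in several region types (exon and coding
exon, say). Denominators are all hyper (resp. non-differential) probes of
the gene set for the five region types, and the probes in any
exon/intron/coding exon for the three "first" ordinals; "first" is
strand-aware and satisfied by any transcript of the gene. Counts are per
(probe, gene) pair — a probe serving two genes contributes to both — and
the output metadata says so.

## Synthetic data generator

The generator emulates the targeted study design: several cancer/normal
cohorts sharing a probe universe, one sparse 27k-like cohort exposing only
a promoter-focused probe subset, dense 450k-like cohorts exposing all
probes, a gene-level expression status table, and a matched
methylation/expression cohort. What it plants:

- **Gene groups** drawn i.i.d. from `group_fractions`; defaults
  UPUP .15 / UPDOWN .30 / DOWNUP .08 / DOWNDOWN .12 / NULL .35, chosen to
  echo the relative group sizes such studies report (the canonical UPDOWN
  group largest, a sizeable UPUP group, smaller hypomethylation groups,
  ample null genes).
- **Probe effects**: probes of methylation-gain genes get +`delta_beta_effect`
  (default 0.2 β-units, the high/low fold-change boundary), loss genes the
  negative. Effects are applied on the logit scale — the shift is
  calibrated per probe so the β-scale mean difference matches the planted
  Δβ while values stay inside (0, 1) — and outputs are clipped to
  [0.001, 0.999].
- **Baselines** are bimodal (Beta(2,10) and Beta(10,2) mixture, the classic
  two-mode array β distribution, parameters configurable). HYPER-planted
  probes draw from the low mode and HYPO-planted from the high mode: that
  leaves room for the shift and matches the biology (promoter-CGI probes
  are lowly methylated in normal tissue and gain in cancer).
- **Noise** is Gaussian on the logit scale (sd `beta_noise_sd`, default
  0.5); half the variance is a per-sample gene-level factor shared by the
  gene's probes, so probes of one gene are correlated within condition, as
  on real arrays (`gene_factor_share` configurable).
- **Expression** for matched samples is linear in the gene's mean probe
  methylation, sign +1 for UPUP/DOWNDOWN, −1 for UPDOWN/DOWNUP, 0 for
  NULL, with the slope calibrated against the empirical spread of the mean
  methylation so the population |Pearson r| equals `expr_coupling`
  (default 0.5). The status table mirrors the planted labels with logFC
  signs to match.
- **Inconsistency**: a `frac_inconsistent` share of non-null genes
  (default 0.02, matching the low observed rate of genes with both probe
  directions) gets exactly one opposite-direction probe — the gene's last
  probe, which is dense-only whenever the dense count exceeds the sparse
  count, so the sparse-stage groups stay clean and the dense-stage filter
  must catch it.
- **Geometry**: genes are laid out 100 kb apart on 22 chromosomes with
  alternating strand; each has one 3-exon coding transcript spanning
  2.4 kb. Probes scatter uniformly within ±`tss_span` (default 2000 bp,
  the outermost analysis window) of the TSS in gene orientation.
  CGI relation is assigned by genomic distance from the TSS-centred island
  (island ≤ 200 bp, shore ≤ 2 kb, shelf ≤ 4 kb), N/S by genomic side.

Determinism: every stream derives from the master seed via named
`SeedSequence`s (truth, annotation, per-cohort by name, expression), so the
same seed reproduces every file byte for byte and cohorts are unaffected by
reordering or by adding other cohorts.

What the generator does *not* emulate — and what passing tests therefore do
not establish about real data: probe cross-reactivity and SNP-under-probe
artifacts, tissue-composition/stromal confounding, array normalisation
effects, linkage between neighbouring CpGs beyond the per-gene factor,
realistic gene/transcript structure diversity, and missing values (absent
unless configured). The variance structure of real cohorts is unknown, so
the noise model is a configurable stand-in; conclusions from synthetic runs
are about the *pipeline's* correctness, not about biology.

## Default cohort layout and problem sizes

The default `SimConfig` mirrors a three-cohort design: "Absher" 95/86
(sparse), "Kirby" 73/63 (dense), "TCGA" 503/50 (dense, also the matched
cohort), 500 genes with 2 sparse / 16 dense probes per gene — about the
per-gene probe densities of the 27k and 450k manifests. Tests and the
acceptance script use smaller cohorts (tens of samples, 30–500 genes);
these sizes were chosen to make every statistical check decisive (planted
effects at delta 0.2 with logit noise 0.25–0.4 give per-probe power ≈ 1 at
n = 40–50 per arm) while keeping runs quick.

## Numerical and degenerate-input choices

- Welch–Satterthwaite df computed in float64; p from scipy's t survival
  function; agreement with `scipy.stats.ttest_ind` is asserted to 1e-10.
- Readers use round-trip float parsing, so write→read preserves values
  exactly and rerunning from files reproduces in-memory results byte for
  byte.
- Zero-variance-in-both-groups probes: p = 1, NS, logged.
- Empty probe intersection across cohorts yields an empty consensus table
  with a warning, not an error.
- BED12 records whose block arithmetic contradicts chromEnd are skipped
  and logged; non-coding transcripts (thickStart == thickEnd) contribute
  no coding exons or UTRs.
- Genes without a model are skipped (and counted) in region analyses;
  chromosome-mismatched probe/gene pairs get no distance.

## Known limitations

Single-site analysis only (no differentially-methylated-region calling);
no IDAT/series-matrix parsing or normalisation; no correlation significance
testing or purity-adjusted partial correlations; gene-set enrichment against
external services is out of scope. The "-only" refinement is defined for
the two hypermethylation groups; the code path is symmetric but the
hypomethylation variants are not exposed.
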
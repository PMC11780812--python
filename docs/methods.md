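# Methods

`hrdscar` implements a whole-exome-sequencing (WES) based test for
homologous-recombination deficiency (HRD) in tumors, of the kind used to
select ovarian-cancer patients for platinum chemotherapy and PARP-inhibitor
therapy. This note documents the statistical model, the defaults and why
they were chosen, the numerical conventions, and what the synthetic-data
generators do and do not emulate.

## The genomic-scar score

The input is a table of allele-specific copy-number segments per tumor
(total, major-allele and minor-allele copies on 1-based inclusive
coordinates), the output of an upstream purity/ploidy-aware segmentation.
Three counts are computed per sample and summed into the HRD score:

* **LOH** — number of loss-of-heterozygosity regions longer than 15 Mb.
  An LOH region is a maximal run of consecutive segments with
  `minor_cn = 0` and `total_cn >= 1`; its span runs from the first start to
  the last end, internal segmentation gaps included, and runs may span the
  centromere. Regions covering a chromosome's entire segmented extent are
  excluded (whole-chromosome LOH reflects aneuploidy, not recombination
  failure); the length comparison is strict (`> 15 Mb`).
* **TAI** — number of allelic-imbalance regions (`major_cn != minor_cn`)
  that reach the outermost segmented position of a chromosome arm without
  crossing the centromere and without covering the whole chromosome. No
  minimum length is applied by default (`tai_min_len = 0`); a chromosome
  can contribute at most two, one per telomere.
* **LST** — number of large-scale state transitions, computed per arm.
  Segments shorter than 3 Mb are first removed, re-joining flanks left
  adjacent in the same allele state, until none remain; a breakpoint is then
  counted for every adjacent pair of different-state segments that are each
  at least 10 Mb long and separated by at most 3 Mb.

All thresholds live in `ScarParams` and are configurable; the 3 Mb constant
deliberately serves both as the smoothing filter and the maximum breakpoint
gap, mirroring the original LST construction. The inequality directions
follow the definitions verbatim: strict for the LOH length, inclusive for
the LST segment size and gap. No ploidy correction is applied to any score;
ploidy is carried as sample metadata only.

Three choices here are genuinely open in the published one-line definitions
and are therefore exposed as flags with documented defaults:
whole-chromosome LOH exclusion (`exclude_whole_chromosome_loh=True`), the
TAI minimum length (0), and per-arm LST (`lst_per_arm=True`). The defaults
follow the constructions the score definitions descend from.

**Smoothing order.** Removing sub-3 Mb segments one at a time is not always
confluent: when several small segments are adjacent, different deletion
orders can reach different fixed points (exhaustive enumeration over
deletion orders finds such cases among adversarial random segmentations,
though never in the clean planted profiles the generator produces). The
engine therefore fixes a canonical order — delete the smallest segment
first, leftmost on ties — making the count deterministic. The test suite
asserts that this result is always among the fixed points reachable by
*some* deletion order, and that re-smoothing a smoothed profile changes
nothing.

**Arm model.** Chromosome arms are defined by a centromere interval per
chromosome. A segment straddling the interval is split at its ends and the
interior part is dropped. The shipped `GRCh38-autosomes` model carries the
22 autosomes with centromere extents from the UCSC GRCh38 centromere
annotation rounded to 0.1 Mb; sex chromosomes are excluded by default
because a single-copy X in males makes `minor_cn = 0` uninformative
(`GRCh38-autosomes+X` is available). Centromere coordinates are data, not
code: any 4-column TSV (`chrom, length, centromere_start, centromere_end`)
defines a genome model.

## The HRD call

A sample is HRD-positive when **either** a deleterious (pathogenic or
likely-pathogenic) BRCA1/2 variant is present **or** its scar sum reaches
the threshold (default 50 on the test's own scale). Variants of uncertain
significance are never deleterious; deleterious hits in the wider
DNA-damage-repair panel (ATM, BRIP1, CHEK2, FANCG, MLH1, MSH2, MSH6, PALB2,
RAD51C, RAD51D) are reported but never trigger positivity on their own.
Germline and somatic origins are not distinguished by the rule; a
provenance column is passed through untouched. Gene symbols match
case-insensitively after trimming; alias resolution is out of scope.

The threshold is transferred from a reference assay's cutoff (genomic
instability score >= 42) by ordinary least squares of test score on
reference score, evaluating the fitted line at the reference cutoff. The
direction — test regressed on reference — is chosen because the quantity
needed is on the test scale; fitting the reverse regression and inverting
is a different estimator and would give a slightly different threshold, so
the direction is part of the method definition here. The raw derived
threshold is reported as-is, and the calling threshold rounds it *up* to
the next integer, because scar sums are integer counts and the positivity
rule is a `>=` comparison.

## Concordance statistics

Diagnostics against the reference assay retain numerator and denominator
(sensitivity `tp/(tp+fn)`, specificity `tn/(tn+fp)`, PPV `tp/(tp+fp)`, NPV
`tn/(tn+fn)`); a zero denominator flags the metric undefined rather than
reporting 0. Display percentages round half-up to one decimal, the
precision of clinical reporting. The two-sided Fisher exact p uses the
minimum-likelihood rule (sum hypergeometric probabilities not exceeding the
observed table's, with a 1e-7 relative guard for float ties), delegated to
`scipy.stats.fisher_exact` and verified in the test suite against full
enumeration of margin-preserving tables. Pearson chi-square is provided
without continuity correction by default (Yates via flag). No
multiple-testing correction is applied anywhere.

## Survival analysis

Progression-free survival runs from completion of primary treatment to
recurrence/progression; overall survival from diagnosis to death; both in
months. Platinum sensitivity is recurrence strictly beyond 6 months after
primary treatment; recurrence at exactly 6 months counts as resistant
("within six months" read as inclusive; the boundary is a parameter).
Patients without recurrence need at least 6 months of follow-up to be
assessable.

Kaplan–Meier estimation and the two-group log-rank test are delegated to
`lifelines`; the reported median is the smallest observed time with
`S(t) <= 0.5`, absent when the curve never reaches 0.5. The Cox
proportional-hazards model is fit in-package by Newton–Raphson on the
partial likelihood with Efron tie handling by default (Breslow via
argument), iterating to gradient norm < 1e-8 with step-halving, a
100-iteration cap, and an explicit diagnosis of complete separation (a
scaled coefficient beyond 15 log-hazard units, where the likelihood has no
interior maximum). Confidence intervals and p-values are Wald on the
log-hazard scale. The fitter is cross-checked in the tests against a
1e-4-resolution grid search of the explicit partial likelihood, against
`lifelines.CoxPHFitter` under ties, and against the log-rank statistic via
the score test at beta = 0.

## Synthetic data: what it emulates, what it does not

`simulate_scarred_profile` plants events on an all-(1,1) diploid genome:
interior (1,0) LOH runs of 16–25 Mb, terminal (2,1) TAI segments of 5–8 Mb,
and abutting (2,2)|(3,3) LST junctions with 12–14 Mb sides. Events are
placed with clearances enforced *by construction* — 4 Mb unsegmented buffer
gaps (wider than the 3 Mb LST gap limit) plus background blocks keeping
events more than 15 Mb from each other, chromosome ends and centromeres —
so no event interacts with another's filter and scoring must return the
planted counts exactly. Two noise layers are score-neutral by design:
state-preserving random splits (re-merged by normalization) and sub-3 Mb
(4,4) interstitial fragments at junctions whose flanks are at least 12 Mb
with a retained minor allele (removed by LST smoothing without dropping a
flank below 10 Mb or interrupting an LOH run). Requests that cannot be
packed with these clearances (for example interior events on the toy
genome's 45 Mb arms) raise an error rather than degrade.

What this generator does **not** model: tumor purity and subclonality,
segmentation error, FFPE artifacts, wavy baselines, focal amplifications,
or realistic chromosome-level event size distributions. Passing the
truth-recovery tests therefore certifies the counting logic, not robustness
to upstream segmentation noise.

`simulate_paired_scores` draws reference scores uniformly on [0, 90] (the
span of observed score ranges on both assays at cohort scale) and sets
`test = alpha + beta*reference + N(0, sigma)`, rounded to integers and
floored at 0. Defaults `alpha=8, beta=1, sigma=5` make the generating line
map the reference cutoff 42 to a test threshold of 50. A noise level of
`sigma = 18` reproduces the observed cross-assay correlation of ~0.82,
since `r = sd(ref)/sqrt(sd(ref)^2 + sigma^2)` with `sd(ref) = 90/sqrt(12)
= 25.98`; the acceptance script reports r at that noise level.

`simulate_cohort` draws HRD status Bernoulli(prevalence, default 0.775 —
31 of 40 patients in the motivating training cohort), exponential
progression times with hazard `baseline_hazard` (default 0.15/month, median
~4.6 months for HRD-negative patients, matching the scale of reported
medians) multiplied by the hazard ratio (default 0.33) for HRD-positive
patients, independent exponential censoring tuned to the requested marginal
censoring fraction (default 0.2), an exponential post-progression stage for
death times, and R0 resection with probability 0.325 (13 of 40). Platinum
response fields derive from the simulated recurrence times through the
6-month rule. Exponential survival satisfies proportional hazards exactly,
so these cohorts test the machinery, not the proportionality assumption.

## Problem sizes used in tests and the acceptance script

The acceptance script (`scripts/acceptance.py`) recovers planted scars on
300 noisy profiles, calibrates thresholds over 100 simulated pairings of
200 samples, sizes the log-rank test on 1,000 null cohorts of n=200, and
fits the Cox model on 200 cohorts of n=2,000 (~70% events) for
hazard-ratio recovery and 95% CI coverage. The test suite additionally
checks 1,000 planted profiles for exact recovery and 1,000 random
small-segment profiles against the brute-force enumerators. These sizes
give Monte-Carlo standard errors well inside the assertion bands (e.g.
coverage SE ≈ 1.5% at 200 replicates).

## Known limitations

* Scar definitions operate on integer allele-specific copy numbers; no
  purity/ploidy re-estimation, no subclonal states, no signature-based HRD.
* The calibration is a single straight line; no errors-in-variables or
  Deming alternative is provided even though both assay scores are noisy.
* Cox fitting offers no penalization, so separable designs error out by
  intent rather than returning an unstable estimate.
* The classification vocabulary for variants is fixed and guideline labels
  are trusted as given; there is no variant-effect prediction.
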
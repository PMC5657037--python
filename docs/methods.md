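# Methods

## Problem and model

A candidate somatic SNV is a (chromosome, position, ref, alt) site
reported by at least one of two callers on at least one of two
platforms. The four (caller, platform) sources are a conservative
paired caller (MuTect-style, `M`) and a liberal tumor-only caller
(VCMM-style, `V`) on whole-genome (`G`) and whole-exome (`X`) data.
Candidates are classified somatic / not-somatic by a binary decision
tree over a fixed 108-dimensional feature space.

### Feature space

Feature names are `<platform><caller>_<field>` (e.g. `GM_t_alt_count`,
`XV_snp_quality`). Per platform the MuTect block has 44 features: 26
numeric evidence columns of the pinned call_stats dialect (tumor/normal
ref/alt counts, allele fractions, tumor/normal LOD scores, base and
mapping quality statistics, strand counts, power values, indel-proximity
counts), 2 derived depths, 3 boolean flags (dbSNP, COSMIC, covered),
the categorical KEEP/REJECT judgement, and 12 boolean indicators — one
per modeled rejection reason. The VCMM block has 10: depth, alt depth,
allele fraction, SNP/mapping/base quality, indel score, two alt strand
counts, and the dbSNP flag. (44 + 10) × 2 = 108, enforced as an
invariant. The published work fixes only the count (108) and the
G/X/M/V naming convention; the exact field list is this package's
pinned schema, versioned in `features.py`.

Missingness is block-structured: when a source did not report a site its
whole block is missing; inside a reported block individual cells may be
missing (`NA`/`.`/empty on disk). Allele fractions are derived from
counts when not stored explicitly. No imputation is performed anywhere;
missing values are handled by the classifier itself.

### Decision tree

C4.5-family induction with plain information gain (gain ratio available
as an option). Splits are always binary: numeric features test
`value <= t` with `t` a midpoint between consecutive distinct observed
values; booleans test truth; categoricals test one-vs-rest equality.
Per-feature gain is computed on the examples where the feature is known
and scaled by the known-mass fraction; candidates leaving less than
`min_leaf` known mass on either side are discarded; ties break by
schema order, then smaller threshold.

Missing values use fractional weighting: a training example missing the
split feature descends both branches with weights proportional to the
known mass on each side, and at prediction time the same branch weights
distribute the prediction mass, so an all-missing vector scores the root
class prior. An alternative `missing_mode="as_category"` routes missing
values down the rule-false branch deterministically; it exists for
ablation only.

Recursion stops on purity, `min_leaf` (default 2), optional
`max_depth`, or when no admissible split exists. When every admissible
split has exactly zero gain but the node is impure (parity-style label
structure, where no single feature shows marginal signal) the builder
takes the first admissible zero-gain split so that gain can surface one
level deeper; this `zero_gain_fallback` is on by default and pruning
removes such splits whenever they never pay off.

Pruning is pessimistic subtree replacement: a subtree collapses to a
leaf when the leaf's upper-confidence-bound error estimate (exact
binomial/beta quantile at confidence 0.25 — for zero observed errors in
n this is n·(1 − CF^(1/n)), the classic closed form) is no worse than
the sum over the subtree's leaves. Confidence, `min_leaf` and all other
settings are configurable through `TrainParams`; the defaults mirror
classic C4.5 defaults because the original study reports none.

Trees serialize to a documented indentation-nested text format carrying
the schema, parameters, split rules and weighted leaf counts;
`load_model∘save_model` preserves structure and predictions.

### Labeling

Simulated mode: spiked truth variants are positives; germline sites and
every other caller-reported site are negatives; the truth and germline
sets must be disjoint. Real-consensus mode (for data with unknown
truth): a site is positive when its supporting (caller, platform) pairs
span ≥2 distinct callers *and* ≥2 distinct platforms; negative when
supported by exactly one caller on exactly one platform with tumor and
normal depth ≥10× on each of the two other platforms; everything else is
unlabeled and excluded. The two rules are mutually exclusive by
construction (tested by exhaustive enumeration of all support patterns).
The conjunction reading of the negative rule ("one method on one
platform") was chosen deliberately over the looser disjunction phrasing
that also circulates; sites failing the depth condition stay unlabeled
rather than being forced into a class. Training tables are uniform
seeded subsamples of the labeled pool.

### Evaluation

Confusion counts are set-based over an explicit universe — all sites
reported by any configured source plus all truth sites — so true
negatives are well defined. Zero-denominator metrics report 0 with a
warning rather than raising, so degenerate cross-validation folds do not
abort a run. Cross-validation is stratified by class (per-class fold
sizes differ by ≤1) because the intended data regime is heavily
imbalanced; an unstratified mode exists and `k = n` unstratified is
leave-one-out. The summary metric pools held-out confusion counts over
folds. Union/intersection baselines combine one caller's per-platform
call sets set-theoretically.

## Synthetic data generator

The generator emulates the study conditions at **site level** — depths,
allele counts, strand splits and summary qualities per (site, platform,
sample) — not at read level. That is exactly the granularity the 108
features consume; read-level artifacts (alignment error, repeats,
low-complexity context, indel realignment) are not modeled, so passing
tests demonstrate the pipeline's correctness and the ensemble's
advantage under the modeled error modes, not performance on real tumors.

Defaults reproduce the study design: 100 spiked somatic variants per
exome-depth stratum (≤8×, ≤14×, ≤200×, ≤500×, ≤800×, >800×; tumor exome
depth uniform within the stratum, the open-ended stratum capped at
1.5× the last bound), 100 variants outside the exome targets (exome
depth 0), allele fractions uniform on [0.05, 1] (the published AF
distribution is shown only graphically, so the uniform default is a
configurable stand-in), genome depth Poisson with mean 30, exome depth
for non-stratified sites Poisson with mean 150, 500 germline
heterozygous sites (AF 0.5 in both samples), 1000 background noise
sites, per-base error rate 0.001, and normal depth equal to tumor depth
scaled by a uniform factor from [1 − coverdiff, 1] with coverdiff 0.5.
Germline sites carry dbSNP membership with probability 0.9 and somatic
sites COSMIC membership with probability 0.3 (membership is a simulated
flag; no database lookups). The synthetic contig is a single 2 Mb
chromosome with a regular 1 kb-on / 1 kb-off exome tiling, emitted as
BED, which makes "covered by genome only" well defined without a
reference genome.

Cross-contamination re-mixes the normal sample at somatic sites only: of
the normal's reads, Binomial(depth, fraction) follow the tumor allele
distribution and the rest the noise distribution; depth is preserved,
and fraction 0 is the identity.

The emulated callers implement the published minima plus explicitly
artifact-chosen thresholds (all recorded in the dataset manifest): the
tumor-only caller requires depth ≥5, alt ≥2 and a phred-scaled binomial
likelihood-ratio quality ≥20, and never consults the normal — so it
calls germline sites, its characteristic failure; the paired caller
records every candidate with tumor alt ≥2, computes log10
likelihood-ratio LOD scores, and judges KEEP unless the normal alt
fraction exceeds 0.03 or the normal alt count reaches 2
(`alt_allele_in_normal`), the tumor LOD falls below 6.3
(`fstar_tumor_lod`), or the normal fails a reference-likelihood check at
2.2 (`normal_lod`). REJECTed candidates still contribute feature rows —
that is the point of the ensemble: the tree can rescue variants the
conservative caller rejected and discard calls the liberal caller
invented.

Everything is deterministic given the config seed (independent child
streams for design, observations and contamination); generated datasets
are byte-identical across runs.

## Problem sizes

Default end-to-end runs use ~1200 candidate sites (700 truth + ~500
germline/noise candidates) per dataset; the strategy comparison trains
on one seeded dataset and evaluates on a second; the contamination sweep
re-mixes one base dataset at fractions {0, 2.5, 5, 7.5, 10}% and scores
each by 10-fold stratified cross-validation. These sizes were chosen so
a full pipeline run completes in seconds while every stratum keeps
enough sites for stable metrics.

## Known limitations

* Site-level simulation: no read-level or mapping artifacts, so the
  synthetic ensemble advantage is an upper bound on realism.
* The pinned call_stats and VCMM dialects are this package's canonical
  column sets; real-world outputs from specific caller versions may need
  a thin column-mapping adapter.
* The feature list inside the fixed (44+10)×2 partition is package-
  defined; only the partition shape and count are externally fixed.
* The real-consensus labeling rules are implemented and tested, but the
  cohort-scale counts they were originally applied to are not
  reproducible without the original protected data.
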
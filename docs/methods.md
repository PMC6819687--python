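# Methods

## Scope

`arraycnv` implements a complete SNP-array CNV discovery workflow for
autosomes: genotype- and intensity-level quality control, per-sample
copy-number segmentation of Log R Ratio (LRR) / B-allele frequency
(BAF) signal with a six-state hidden Markov model, aggregation of
per-sample calls into population copy-number variation regions (CNVRs),
cross-validation of CNVRs against pooled whole-genome read depth, and
interval analytics (cross-study concordance, QTL overlap, gene content,
hypergeometric term enrichment). A synthetic-cohort generator with
known truth makes every stage testable without external data.

## Coordinates and conventions

All in-memory intervals are 0-based half-open, so length is always
`end − start`; 1-based dialects (marker manifests, PennCNV-style
reports, GFF3) are converted at the I/O edge. All overlap predicates
default to ≥ 1 bp; reciprocal-overlap fractions are optional parameters
everywhere, never defaults. Report percentages are rounded half-up to
two decimals, the convention of published summary tables.

## Quality control

Cohort order: sample genotype missingness (> 0.1 removed), then SNP
filters (call rate < 0.90, minor allele frequency < 0.05,
Hardy-Weinberg exact test), then per-sample intensity QC gating entry
into the HMM.

The HWE test is the exact conditional test: conditioning on the
observed allele counts, heterozygote counts of the same parity are
enumerated and every table whose conditional probability does not
exceed the observed one contributes to the two-sided p-value.
Probabilities are computed with log-gamma factorials, so the test is
stable for arbitrary cohort sizes. The significance cutoff defaults to
1e-6 (the common genome-wide convention; configurable) with no mid-p
correction. Per-filter SNP removal counts are reported
non-exclusively — a marker failing two filters appears in both
counts — alongside an exclusive total, because the two tallies answer
different questions and published reports mix them.

Intensity QC statistics (computable from signal alone; these concrete
definitions are this package's conventions):

- **LRR SD** — standard deviation of all non-missing autosomal LRR;
  gate 0.3. Note this plain SD is sensitive to genuine long deletions
  when the marker panel is small; see *Synthetic data* below.
- **BAF drift** — fraction of non-missing markers with BAF in the
  off-cluster zones [0.20, 0.25] ∪ [0.75, 0.80]; gate 0.02. A clean
  sample puts essentially no mass there; uniform contamination at
  fraction f contributes ≈ 0.1·f.
- **Waviness factor** — standard deviation of per-1-Mb-bin median LRR,
  signed by the correlation of bin medians with bin GC when a GC track
  is supplied; gate |wf| ≤ 0.05. A sinusoidal wave of amplitude A has
  wf ≈ A/√2.

Samples with fewer than 100 informative markers are flagged unreliable
and fail.

## Copy-number HMM

States: CN0, CN1, CN2, CN2-LOH, CN3, CN4. The copy-neutral LOH state
carries diploid intensity with homozygous BAF; it stabilizes decoding
and is never reported as a CNV.

**Emissions.** Per marker, a Gaussian LRR term with state-specific mean
and SD — defaults (−3.5, −0.67, 0, 0, +0.40, +0.68) for means, echoing
the characteristic intensity shifts of each copy state, and SDs
(1.3, 0.25, 0.2, 0.2, 0.25, 0.3) reflecting the heavy spread of
homozygous-deletion intensity — plus a BAF mixture over genotype
clusters. For copy number k the clusters sit at b/k, b = 0..k, with
Binomial(k, p) weights where p is the marker's population B-allele
frequency (PFB, clamped to [0.01, 0.99] so no cluster weight
vanishes); each cluster is a Gaussian of SD 0.03 truncated to [0, 1],
mixed with a 0.01-weight uniform outlier component. CN0 has no allelic
signal and emits uniform BAF; CN2-LOH uses clusters {0, 1} with
weights {1−p, p}. A missing channel contributes zero log-likelihood —
the marker is skipped for that channel, not imputed, matching
per-sample signal files where markers drop out.

**Transitions.** Distance-dependent: for an inter-marker gap d,
`diag(i) = 1 − (1 − stay_prob[i])·(1 − exp(−d/D))` with D = 100 kb and
stay probabilities 0.999 (CN2) / 0.95 (others); the off-diagonal mass
is split proportionally to fixed base weights favoring CN2
(0.02, 0.10, 0.70, 0.03, 0.10, 0.05). At d = 0 the matrix is the
identity; over long gaps rows relax toward the CN2-dominated prior.
The initial distribution puts ≈ 0.99 on CN2.

**Decoding and calls.** Log-domain Viterbi per chromosome, ties broken
deterministically toward the lower state index. Maximal non-diploid
runs of ≥ 3 markers become calls; the call confidence is the summed
per-marker log-likelihood advantage of the called state over CN2,
positive by construction for any run the decoder preferred. Calls are
rendered both as BED and as classic one-line PennCNV-style text.

Equivalence with any particular external caller's output is not
claimed; fidelity is demonstrated on synthetic truth (calls recover
≥ 95% of implanted events of ≥ 5 markers with correct polarity, with
boundary error ≤ 1 marker at the 90th percentile, at LRR noise SD 0.2).

## CNVR construction

Per chromosome, calls from all samples are clustered into maximal
transitive-overlap components (≥ 1 bp under half-open coordinates;
abutting calls do not merge — the strictest reading of "overlapping").
Clusters supported by fewer than two distinct individuals are removed
(two calls from the same sample do not rescue a cluster). Surviving
clusters are trimmed: with c(x) the number of supporting calls covering
base x and M = Σc(x), the consensus start is the smallest x whose
preceding cumulative mass reaches 0.025·M and the end the largest
half-open bound whose suffix mass reaches 0.025·M, computed by a
breakpoint sweep with ceiling rounding (never per-base arrays; a
per-base oracle verifies the sweep in tests). Since 2.5% + 2.5% < 100%,
trimming can never invert an interval; degenerate tiny clusters fall
back to the untrimmed extent. Events are classified gain (all
supporting copy numbers > 2), loss (all < 2) or both; identifiers
CNVR1..n are assigned in (chrom, start) order, making the whole
construction permutation-invariant in call order.

An alternative reading of the trimming rule — quantiles of the
distribution of call endpoints rather than of coverage mass — exists;
the coverage-mass reading is adopted as this package's convention.

## Read-depth validation

The genome is tiled with 400 bp windows; each read is assigned to the
window containing its start (conserving the read total). GC correction
rescales each window by global-mean / GC-bin-mean over 50 equal-width
GC bins, bins with < 20 windows left uncorrected, and the output is
renormalized to conserve total mass within 0.1%. Integer copy number
is `round(2·corrected/median)` (half away from zero, capped at 10)
against the genome-wide median as diploid baseline. Runs of ≥ 5
non-diploid windows of one polarity become depth CNVRs, bridging single
diploid windows (Poisson noise produces isolated CN2 windows inside
real events). An array CNVR is confirmed by ≥ 1 bp overlap with a
depth CNVR of compatible polarity (gain ↔ CN > 2, loss ↔ CN < 2, both
↔ either); magnitude is deliberately ignored because pooled samples
carry population-average signal.

Cross-window similarity grouping (absolute copy-number correction by
genome self-alignment, as some read-depth callers perform between
duplicated windows) is a documented no-op here: it requires genome
self-alignment beyond the scope of this package and has no bearing on
the polarity-based confirmation used.

Note a consequence of pooling: with 12-sample pools, an event carried
by c pool members shifts pooled copy number by c·(CN−2)/12, which for
low-frequency events rounds back to diploid. The validator therefore
confirms common events reliably and rare ones rarely — visible in the
end-to-end synthetic run, where the confirmation rate sits well below
the per-event recovery of the depth caller itself (Jaccard 1.0 when
all pool members are carriers).

## Synthetic cohorts

The generator is a pure function of (config, seed) and emulates the
target study design: 90-sample cohorts (scaled to 20 for the standard
end-to-end run), autosomes of 10 Mb with exponentially spaced markers
at 3.08 kb mean spacing (exponential rather than uniform, so realistic
gaps exercise the distance-dependent transitions), per-marker allele
frequencies ~ U(0.05, 0.95) defining PFB and Hardy-Weinberg genotypes,
LRR = copy-state mean + N(0, 0.2), BAF at genotype-cluster centers
(binomial B-copy draw under the local copy number) with SD 0.02,
implanted events of 5–30 markers at copy numbers 0–4 with 2–8 carriers
plus single-carrier events to exercise singleton filtering, and
injected QC failures: sinusoidal LRR waves, uniform BAF contamination,
elevated genotype missingness. Pooled depth tracks are Poisson window
counts at 30× / 150 bp (80 expected reads per 400 bp window) scaled by
pool-mean copy number and an optional smooth GC-bias curve.

Two realism constraints matter at desk scale: homozygous deletions are
kept short (≤ 10 markers) and at most one per genome. Both mirror real
genomes, and they keep the plain-SD LRR gate meaningful on small
synthetic marker panels — a 25-marker CN0 event at LRR −3.5 in a
1,600-marker genome would alone push a clean sample's LRR SD past the
0.3 gate, an artifact of panel size, not of the sample. On the
~566k-marker arrays the workflow targets, real events are negligible in
this statistic.

What the generator does not emulate — and what passing tests therefore
do not show: linkage disequilibrium between markers, array batch/plate
effects beyond the injected waves, probe-specific intensity biases,
mosaicism, and sequence-level artifacts (the depth track is simulated
at the window level, not from reads).

## Problem sizes

The standard end-to-end run uses 20 samples × 2 chromosomes × 10 Mb
(~6,500 markers, ~130k Viterbi steps) with 12 multi-carrier events;
the whole pipeline including pooled-depth validation completes in
about ten seconds. The depth-recovery experiment uses one 5 Mb
chromosome (12,500 windows) with five implanted events of 4–12 kb.
These sizes were chosen so the full suite runs comfortably on a
laptop while every statistic keeps enough support (≥ 60 recovered
carrier-events, ≥ 120 boundary measurements) to be meaningful.

## Numerical choices

- Viterbi in log domain throughout; `log 0` handled as −inf, ties to
  the lower state index (deterministic).
- Trimming uses exact integer breakpoint arithmetic with ceilings.
- Percentages via decimal half-up rounding, not banker's rounding.
- PFB clamped to [0.01, 0.99]; BAF clamped to [0, 1] on read with a
  warning count.
- The hypergeometric enrichment p uses the survival function
  `sf(k−1)`; Bonferroni multiplies by the number of terms with ≥ 1
  selected gene, capped at 1.

## Known limitations

- Sex chromosomes are out of scope (the calling model assumes a
  diploid autosomal baseline).
- The HMM parameters are not fitted per cohort (no Baum-Welch); they
  are documented defaults chosen for the published behavior of LRR per
  copy state and are configurable.
- Confirmation by pooled depth is polarity-only and dilution-limited,
  as discussed above.
- Term enrichment consumes a user-supplied gene→term table; no live
  ontology access.
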
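# Methods

## Read extremities and genome binning

A sequenced ATAC fragment marks two transposase insertion points; we take
them as the fragment termini, i.e. positions `start` and `end − 1` in
0-based half-open coordinates (the 5′ starts of the two reads of a proper
pair). No Tn5 +4/−5 offset is applied by default — the analysis operates on
100-bp bins, where a 9-bp shift is immaterial — but `tn5_shift=True` applies
it, clipped at chromosome ends. Fragment length is `end − start` (the
template length), and the three length classes — subnucleosomal ≤ 140 bp,
nucleosomal 141–280 bp, poly-nucleosomal ≥ 281 bp — reflect the number of
nucleosomes a fragment spans. Subnucleosomal fragments are the default
analysis subset: both their extremities fall in open DNA, so they carry the
sharpest accessibility signal; the other classes remain selectable for
comparing the information content of the three subsets.

The genome is tiled into contiguous half-open bins of 100 bp, the last bin
of each chromosome truncated; bin counts are not length-normalized (a
truncated bin simply collects fewer extremities). Each fragment contributes
exactly two counts, so column sums are an exact conservation check used in
the tests. Duplicate fragments are not removed here — deduplication belongs
to upstream alignment processing, and the simulator generates
duplicate-free data.

## Library QC, retention, normalization, testing

Order of operations, each step on the output of the previous:

1. **Library exclusion.** Libraries whose class-filtered fragment total is
   below `min_reads` are dropped; shallow libraries leave a large fraction
   of bins without counts and distort rank statistics. The default threshold
   (1E7) suits deep real libraries; desk-scale synthetic runs pass an
   explicit proportional value. A genotype group left with < 2 libraries is
   a hard error (the rank test is undefined).
2. **Retention.** An interval is retained when its mean **raw** extremity
   count over kept libraries is ≥ `min_mean` = 5 (inclusive). Raw rather
   than normalized counts: the rule is a detection floor in count units.
3. **Size factors** are median-of-ratios, computed on the retained
   intervals restricted to those with all-positive counts, and rescaled to
   unit geometric mean. The rescaling changes nothing a group comparison can
   see (fold changes and rank tests are scale-invariant) and makes
   normalization exactly idempotent, which the tests assert at 1e-9.
4. **Per-interval tests** on normalized counts: FC = mean(mutant) /
   mean(control), undefined (flagged, excluded from the curve) when the
   control mean is zero — no pseudocount is added; and a two-sided
   Mann-Whitney p-value.

**Mann-Whitney implementation.** The per-interval test is vectorized over
rows: ranks via `scipy.stats.rankdata`, then for tie-free rows with
n₁+n₂ ≤ 20 the exact two-sided p = 2·min(P(U≤u), P(U≥u)) from the enumerated
null of U (computed once per (n₁,n₂) by the standard recurrence), and for
tied or larger rows the normal approximation with mid-ranks, tie correction
and 0.5 continuity correction. Tests verify exact agreement with full
permutation enumeration for all group sizes up to (6,7) and with scipy on
both paths; scipy is the oracle, never the execution path (it is not
vectorized over ~1E5 rows). With 6 vs 7 libraries the attainable two-sided
floor is 2/C(13,6) ≈ 1.17E-3; a **per-base mode** (`per_base_test`) that
treats the pooled per-position counts of an interval as observations is
provided as a documented, speculative alternative unit of replication that
reaches far smaller p-values, and is not the default.

## The ratio curve

Intervals with defined FC are ranked by increasing p; ties are broken by
|log₂ FC| descending, then genomic coordinate, making the ordering fully
deterministic. Over sliding windows of `window` = 1000 intervals (step 1)
the ratio r = n_enhanced / n_repressed is computed, FC exactly 1 counting as
a tie kept in the window but in neither side; a window with no repressed
interval has an undefined (flagged) ratio that any finite cutoff treats as
above it. Selection at a cutoff r\* uses the **prefix rule**: all intervals
ranked before the start of the first window whose ratio exceeds r\* — the
selection is therefore always a prefix of the ranked list, with the
alternative "all intervals in windows with r ≤ r\*" available
(`mode="windows"`).

**Null behavior.** Under no group effect each interval is enhanced or
repressed with probability ½, so for independent intervals a window's
enhanced count is Binomial(W, ½). `null_ratio_band` converts this into a
simultaneous confidence band for the whole curve, Šidák-adjusting the
per-window level by the effective number of non-overlapping windows
(n·step/W) — step-1 windows share 999 of 1000 members and a pointwise band
would be crossed by chance. Two caveats, both observed and expected, limit
this band to genuinely independent intervals: (i) bins belonging to the same
accessible locus share each library's sampling noise, so their FC directions
are correlated and the effective window size is several-fold smaller than W;
(ii) size-factor estimation error is shared across all intervals of a
library and drifts the global fraction of FC > 1 by ~±1–2% from seed to
seed. The binomial-band property is therefore asserted on iid synthetic
interval statistics, where its assumptions hold by construction. For
full-pipeline data the package provides the exact generalization,
`permutation_flatness_envelope`: permuting the genotype labels of the
normalized count matrix preserves the correlation structure, so the
permutation distribution of the curve's maximum |log ratio| is the correct
null reference (and reduces to the binomial bound for independent
intervals); the end-to-end null check uses this envelope.

**Compositional bias.** When a sizable fraction of the signal is depleted in
one group, median-of-ratios normalization under-corrects: the median sits in
the lower tail of the unaffected-interval mode, so unaffected intervals come
out slightly enhanced (global median FC ≈ 1.02 at the default planted
effect). This is faithful behavior of the normalization, shared with any
median-of-ratios analysis of globally shifted data, and is why planted
multipliers are recovered accurately only when the affected fraction is
small (the recovery test plants 5% of loci).

## Annotation

Gene flanks are `[start − 20 kb, start)` and `[end, end + 20 kb)`, clipped
at chromosome ends; in the default exclusive mode any flank bases covered by
a gene body are trimmed, so {gene, flank, intergenic} is a partition with
gene taking precedence (fractions sum to 1); inclusive per-category counts
are reported alongside. Overlap is any shared base on half-open intervals —
touching intervals do not overlap — via interval trees, with both query-side
fractions and feature-side hit counts reported, verified against an
all-pairs oracle.

## Spike trains

Burst segmentation follows the onset/termination rule literally: onset
strictly < 80 ms, continuation ≤ 160 ms, termination strictly > 160 ms; an
ISI in the 80–160 ms zone extends an open burst but cannot open one, and
scanning resumes after a closed burst, so a terminating boundary spike never
seeds the next burst. Every burst has ≥ 2 spikes. The implementation is a
single greedy left-to-right scan, proven equivalent on random trains to an
independent run-decomposition oracle (split at ISIs > 160 ms; a run bursts
from its first ISI < 80 ms). %SWB = 100 × (spikes in bursts)/(all spikes),
0 for an empty train. Windowed metrics place windows at 0, 15, 30, … s
(window 60 s, overlap 45 s) while a full window fits the epoch — 17 windows
over 300 s; a spike belongs to a window by timestamp, so a burst spanning a
window edge contributes only its in-window spikes, and the across-window
summary is the unweighted mean.

## Synthetic data

The generator reproduces the study design, not sequencing physics. Defaults
(chosen once; rationale in parentheses):

- genome 2 chromosomes × 5 Mb = 1E5 bins of 100 bp (large enough for
  1000-interval windows at desk scale); 6 control + 7 mutant libraries (the
  study's group sizes), optional extra shallow libraries to exercise QC;
- 2,000 accessible loci of width 200–1,200 bp with log-normal (σ = 1)
  baseline accessibility; 30% of fragments uniform background; mean depth
  2.5E5 fragments/library (log-normal σ = 0.2) — deep enough that a 0.6×
  depletion at a typical locus is resolvable by a 6-vs-7 exact rank test,
  at a per-bp fragment density within a few-fold of deep bulk ATAC
  libraries;
- fragment length mixture 0.50/0.35/0.15 over the three classes (subsampled
  ranges 30–140/141–280/281–600 bp), mirroring a good nuclear ATAC library;
- planted effect: 10% of loci at 0.6× in the mutant and 5% at 1.4×
  (depletion-biased, matching the direction of the effect under study);
  fragments sample a locus with probability ∝ accessibility × group
  multiplier, midpoint jittered N(0, width/4), or fall uniformly as
  background;
- genes of 10–50 kb with 10–80 kb gaps; loci placed 70/20/10% in
  genes/flanks/intergenic; 3,000 cCREs of 150–350 bp, half centred on loci;
- spike trains: tonic firing with refractory shifted-exponential ISIs
  (0.25 s + Exp), so tonic activity alone can never open a burst — the
  pacemaker-like regularity of the recorded cell type — interleaved with
  planted bursts (4 spikes at ~30 ms ISIs, guard gap 0.5 s); truth records
  the realized burst spike fraction per neuron.

One RNG child stream per library/neuron is spawned from the master seed, so
outputs are byte-identical across runs and stable under library reordering.

**What passing tests do not show.** The simulator has no Tn5 sequence or GC
bias, no duplicates, no mitochondrial contamination, no read-level errors,
and loci are placed independently (they may overlap, producing mixed-signal
bins — visible as mild attenuation of recovered fold changes). Success on
synthetic data validates the statistical machinery and its implementation,
not robustness to the artifacts of real libraries.

## Numerical choices and degenerate inputs

- Exact-test path requires integer U (tie-free); any tie routes the row to
  the corrected normal approximation.
- Zero-variance rows (all values equal) get p = 1.
- Fold-change ties at exactly 1 occur only on degenerate normalized data;
  they are counted (`n_ties`) and excluded from both ratio sides.
- Empty selections (first window already above the cutoff) warn rather than
  fail; annotation then falls back to all retained intervals.
- Threshold comparisons at the burst boundaries are strict/non-strict as
  stated; callers probing exact threshold equality should beware float
  representation of times (the tests probe with 0.1-ms margins).

## Limitations

- The per-library rank test with 6+7 libraries cannot produce p below
  1.17E-3; analyses needing finer resolution must change the unit of
  replication (see per-base mode) with the attendant pseudo-replication
  caveats.
- The iid null band for the ratio curve is anti-conservative on
  locus-correlated data (above).
- Gene models are used as provided; no transcript collapsing is performed.
- GO or pathway enrichment of selected intervals is out of scope.
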
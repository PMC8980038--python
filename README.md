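# atacburst

Differential chromatin-accessibility analysis on fixed-width genome bins,
together with in vivo spike-train burst metrics — the two quantitative arms
of a study design comparing a conditional-mutant mouse genotype against
littermate controls in bulk ATAC-seq of brain tissue, with electrophysiology
of midbrain dopamine neurons on the side.

## What it computes

**Accessibility arm.** Paired-end ATAC fragments are read from BED or BAM,
classified by length ℓ into subnucleosomal (ℓ ≤ 140 bp), nucleosomal
(141 ≤ ℓ ≤ 280 bp) and poly-nucleosomal (ℓ ≥ 281 bp) classes, and the two
extremities of each (by default subnucleosomal) fragment are counted over a
100-bp tiling of the genome. After excluding shallow libraries, genome
intervals with a mean of ≥ 5 raw read extremities across libraries are
retained; counts are normalized with median-of-ratios size factors
(s_j = median_i x_ij / (∏_k x_ik)^(1/n)); per interval the fold change
FC = mean(mutant)/mean(control) and a two-sided Mann-Whitney p-value are
computed (exact enumerated null for tie-free data with n₁+n₂ ≤ 20, else the
tie- and continuity-corrected normal approximation). The genome-wide effect
statistic is the **enhanced/repressed ratio curve**: intervals are ranked by
increasing p and the ratio r = #(FC>1) / #(FC<1) is computed over sliding
windows of 1000 intervals, plotted against each window's leading p-value. A
flat curve at r ≈ 1 means no directional effect; r < 1 sustained at the
low-p end is the signature of a genome-wide accessibility decrease in the
mutant. Intervals below a ratio cutoff (default r\* = 0.60) are selected as
a prefix of the ranked list and annotated by overlap with genes, 20-kb gene
flanks and candidate cis-regulatory elements (cCREs), with half-open
interval semantics throughout.

**Spike-train arm.** Bursts are segmented with the 80/160 ms rule: a burst
opens at two consecutive spikes with an inter-spike interval < 80 ms,
extends while ISIs stay ≤ 160 ms, and terminates at the first ISI > 160 ms.
%SWB is the percentage of spikes within bursts. Firing rate and %SWB are
measured on 60-s windows overlapping by 45 s over a 300-s epoch (17
windows). Dopamine neurons are identified by a triphasic waveform, action
potential duration > 2.0 ms, start-to-trough width > 1.1 ms and a firing
rate between 1 and 10 Hz; ΔF/F = (Ft − F0)/F0 covers the calcium-imaging
readout.

A deterministic synthetic-data generator (`atacburst.simulate`) produces the
whole study design at desk scale — 6 control + 7 mutant fragment libraries
over a 2×5-Mb genome with planted depletion/enhancement effects and known
ground truth, plus annotation fixtures and bursty/tonic spike trains — so
every stage is exercised end to end without downloads.

## Worked example

```bash
atacburst simulate --outdir demo --seed 7
atacburst run --libraries demo/libraries.tsv --chrom-sizes demo/chrom.sizes \
    --genes demo/genes.bed --ccres demo/ccres.bed \
    --outdir demo/out --min-reads 10000 --seed 7
atacburst ephys --spikes demo/spikes.csv --outdir demo/eph
```

prints

```
simulated 13 libraries -> demo
13 libraries kept, 8738 retained intervals, 0 selected -> demo/out
10 neurons -> demo/eph/neurons.tsv
```

`demo/out/ratio_curve.tsv` starts with

```
start_rank  leading_p  n_enhanced  n_repressed  n_ties  ratio
0           0.0011655  438         562          0       0.779359
```

i.e. in the 1000 lowest-p intervals there are 562 repressed per 438 enhanced
intervals (r = 0.78 < 1): the planted genome-wide depletion (10% of loci at
0.6×) is visible at the low-p end, and the curve climbs back to ≈ 1 at high
p. The leading p of 1.17E-3 = 2/C(13,6) is the exact floor of a 6-vs-7
two-sided rank test. No window reaches the 0.60 cutoff at this planted
effect size, so the selection is empty and annotation falls back to all
retained intervals: 73% overlap genes, 24% gene flanks, 2% intergenic
(`demo/out/exclusive_fractions.tsv`), and 46% hit a cCRE. The per-neuron
table reports, e.g., neuron_1: 2.23 Hz mean rate, 20.4 %SWB over 34 bursts.

Stages are also available individually (`count`, `diff`, `ratio`,
`annotate`), every run writes a `manifest.json` with the config snapshot and
input checksums, and reruns with the same seed are byte-identical.

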
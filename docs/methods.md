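# Methods

## Model and scope

The package analyses whole-genome sequencing of single Drosophila
meiotic products from a cross in which only the mother is informative:
she is heterozygous for two strain haplotypes (called A and B; A is
taken as the reference allele at every marker), the father is isogenic
for B. Each male offspring therefore carries one maternal recovered
chromatid per chromosome (hemizygous on the X) plus a constant paternal
B contribution on the autosomes. Every analysis stage — haplotype
assignment, CO/NCOGC calling, karyotype classification, deletion and TE
screening, CNV detection, and the Monte Carlo recovery model — operates
on this structure.

Coordinates are 1-based inclusive internally; emitted VCF is 1-based,
BED/bedGraph 0-based half-open, matching each format's convention.

## Haplotype assignment and event calling

`markers.assign_haplotypes` gives each panel site one of A/B/HET/
MISSING. On hemizygous arms the call is the observed allele. On
autosomes the maternal haplotype is read through the paternal
background: a heterozygous call reports the non-paternal maternal
allele, a homozygous-paternal call the paternal one; a homozygous
non-paternal genotype is impossible under the cross and is flagged HET.
Defaults `min_depth=3`, `min_qual=30` implement a "high-quality call"
filter and are configurable; sites inside the repeat mask are MISSING
unconditionally.

`recombination.call_events` segments the informative markers into
maximal same-haplotype blocks. Interior blocks spanning at most
`ncogc_max_span` are NCOGCs; haplotype changes between the remaining
persisting blocks are COs (two on one arm = double CO). The cutoff
defaults to 25 kb: observed wild-type conversion tracts are ≤ ~2.5 kb,
so an order of magnitude above that is conservative, but an interior
block exceeding it is genuinely ambiguous between a long conversion
and a close double crossover, and is therefore labelled AMBIGUOUS
rather than silently classified. `long_interior="dco"` instead treats
such blocks as persisting haplotype — the right choice on noise-free
synthetic data, where tract lengths are known to be far below the
cutoff. The converse ambiguity also exists and is inherent: two true
COs closer than the cutoff are indistinguishable from one long NCOGC,
so an occasional synthetic double CO with a small inter-CO distance is
reported as a long conversion tract.

Tract bounds: minimum = inclusive span of the outermost converted
markers, with an indel marker contributing its full reference footprint
from its 5′-most base (the published 4-bp-deletion + SNP pair at
2R:23,350,969/23,351,148 yields exactly 180 bp); maximum = distance
between the nearest flanking discordant markers, exclusive, open-ended
at an arm edge. CO positions are reported as full inter-marker
intervals, never midpoints.

CO-associated conversions: alternating short tracts *inside* a CO's
flanking interval admit two equally parsimonious placements (crossover
before the first tract with the second as its conversion, or after the
last with the first as the conversion). These are collapsed into one
CO_GC event carrying both placements. An isolated conversion separated
from a CO by concordant markers is not ambiguous and stays an NCOGC.

## Karyotype classification

Arm dose = arm mean depth / mean of the 2L, 2R, 3L, 3R means; the Y is
assessed only over a mappable interval (default chrY:332,000–510,000,
which the synthetic Y is sized to contain). Integer copy state k is
accepted within ±0.15 of k/2. Triploidy cannot be called from dose
alone (X at ~0.67 of a triploid autosomal baseline sits between copy
states), so it additionally requires B-allele-fraction modes near 1/3
and 2/3 (KDE peaks over intermediate-fraction sites) on at least half
the autosome arms; dose without balance support is reported ambiguous
with both neighbouring states. Intermediate 4th-chromosome dose maps
to a mosaic cell fraction as f = (1 − dose) × base-copies; on a
triploid background the arithmetic is exposed rather than fixed, since
a half-loss model and the published 75%-of-2L observation do not
reconcile exactly.

The nondisjunction estimator is 100·2E/(N+2E): the reciprocal meiotic
products of each surviving exceptional class are inviable, so each
recovered exceptional offspring represents two nondisjunctional
meioses. This reproduces 42% (E=25, N=68) and 12% (E=6, N=87) from the
published counts.

## Deletion screening and benchmark

Small deletions (indel VCFs) receive exactly one verdict with
precedence masked → low_quality (score ≤ 200) → shared (closest
breakpoints within 100 bp of a deletion in a different offspring, any
quality) → novel. Closest-edge distance is the stricter reading of
"within 100 bp" and is used throughout. The large-deletion caller is a
deliberately simple split-read clusterer (breakpoint pairs within a
20 bp window, ≥3 supporting reads, and for events ≥ 300 bp a
concordant depth drop below 0.8× the flanks); it is this package's own
caller, with parameters exposed, not an emulation of any external
tool. Deletions per DSB per meiosis = n / (offspring × DSBs × 0.25),
the 0.25 because one chromatid in four is recovered.

The sensitivity benchmark regenerates the published synthetic design —
100 genomes per size class (1–10 bp and 1–1000 bp), each genome a
merged pair of haploid draws (X-bearing and Y-bearing) at ~20× combined
depth, the X-bearing genome carrying 2–6 deletions placed uniformly in
euchromatin — and reports recall by class and arm under reciprocal
overlap ≥ 50%. The published 86%/57% recall figures describe SAMtools
and Pindel and are reported alongside, never asserted, since the
internal callers are different tools (on noise-free synthetic input
their recall is ≈ 0.98–1.0, limited only by Poisson support dropout at
20×).

## TE insertions

Junction reads are annotated to a family by shared 21-mers with the
family consensus (winner above 50% of the read's k-mers); the synthetic
library is random-sequence consensi, mutually distant enough for
unambiguous assignment. Single-linkage clusters per (arm, family)
within 500 bp emit a call when split+discordant support exceeds 5 reads
(the strict "more than five" reading; split and discordant reads are
counted jointly). Novelty: inherited if matching a parental-stock call
within ±100 bp, shared if matching a sibling on the same haplotype
background, else novel. Mosaicism is read on the hemizygous X from the
insertion-support fraction junction/(junction+spanning): mosaic within
[0.25, 0.75] when an exact binomial test does not reject 0.5,
constitutive near 1, indeterminate below 8 total reads. Rates apply
the ×4 haploid-product correction.

## CNV detection

Depth is re-binned into 5-kb nonoverlapping windows and divided by the
median window depth of the major autosomes (median, so the baseline is
robust to the CNVs being sought). The statistic is the linear copy
ratio — 1.5 for a constitutive heterozygous duplication, 1.25 when
present in half the cells — with log2 carried alongside for plotting.
Segmentation is seed-and-extend on a 3-window rolling median: runs
seeded beyond 1.2/0.8 are merged across gaps that stay beyond the
halfway extension thresholds (1.1/0.9), then runs of ≥3 windows become
calls; this keeps a 50%-mosaic event (true ratio 1.25, window SD ~0.04
at 20×) in one piece without inventing calls in flat regions. Mosaic
fraction: f = 2(ratio − 1) for duplications, 2(1 − ratio) for
deletions. Recurrence groups calls whose both breakpoints agree within
a tolerance across cohorts; flank annotation flags "TE-mediated" when
the same family sits within the flank window on both sides; tandem
orientation requires ≥3 discordant pairs linking the duplication's
distal end back to its proximal start.

## Monte Carlo NCOGC expectation

Default configuration follows the reduced-DSB survey: 68 X, 93 2L and
93 2R arm-meioses; DSBs per arm-meiosis uniform on {0,1,2} (an
independent per-arm draw; a genome-total assignment mode is exposed as
an alternative reading); tract length uniform on 250–1000 bp; recovery
probability exactly 1/4; 100,000 trials. Marker coverage is evaluated
either from explicit panel positions or from a density ρ via the exact
Poisson marginal P(cover) = 1 − e^(−ρL). The tests check the simulated
mean against an independent closed-form oracle,
E = Σ_arms n·E[DSB]·(1/4)·E_L[1 − e^(−ρL)], within 3 Monte Carlo SEs.
At ρ = 1/500 bp the central 95% interval is ≈ [31, 57], overlapping the
published 37–62; exact agreement is not expected because the published
range used the study's empirical marker density, which is not printed.
Observed-vs-expected comparisons report both the empirical two-sided
tail probability and Fisher's exact test on recovered vs non-recovered
opportunities.

## Synthetic-data generator

The generator emulates the study conditions directly at the
alignment-feature level (genotype calls with allelic depths, Poisson
depth bins, junction-evidence records) rather than simulating reads
and realigning; read-level error models, base qualities, and real
aligner behaviour are out of scope. Defaults are the stated study
parameters: SNP rate 1/500 bp (uniform random alternative base, with
2% of markers small deletions so indel markers are exercised), 18–20
DSBs per wild-type meiosis thinned to 20% (*c(3)G*) or 40% (*corolla*)
in SC-null genotypes, tracts 250–1000 bp, DSB-deletion classes 1–10 or
1–1000 bp, 2–6 DSBs per benchmark genome, 10× per haploid genome (20×
combined), 200-bp inserts. Genotype policies add per-arm TE insertion
rates (0.18 wild-type/heterozygote, 0.58 *c(3)G*, 0.19 *corolla* —
the study's own estimates, used as generator truth) and per-meiosis
segregation-error rates with the half-viability of exceptional
zygotes. Genotype calls reflect the true allele content (the explicit
`marker_error_rate`, default 0, injects miscalls); allelic depths are
binomial draws, so allele-balance analyses see realistic sampling
noise. Indel call qualities are two-component (high ~N(900, 80) with a
uniform 50–200 tail) purely so the quality>200 screen has something to
reject. Arms are ~1/15 scale (X 2 Mb, major autosome arms 1.5 Mb, 4th
0.4 Mb, Y 0.6 Mb, 5–10% terminal heterochromatin) so cohort
simulation, calling, and the 200-genome benchmark all run in seconds;
all sizes are configurable. One seeded generator per dataset with
fixed per-offspring substreams (`SeedSequence([seed, stage, index])`)
makes every output byte-reproducible.

What passing tests on these data do *not* show: performance under real
alignment artefacts (mapping errors in repeats, reference bias,
indel-realignment noise), heterochromatic sequence realism, or the
recall of the external tools the real study used. They do show that
the calling logic, the estimators, and the arithmetic are exact on
inputs whose truth is known.

## Numerical and design choices

- Deterministic tie-breaks throughout; no randomness outside the
  seeded generators.
- `simulate_meiosis` returns the full event list plus the recovered
  chromatid per chromosome and the drawn karyotype, since eventless
  arms still need their recovered haplotype for marker synthesis.
- Degenerate inputs: empty marker panels, all-MISSING arms, empty
  depth tracks, single-offspring novelty screens, and zero-opportunity
  contingency tables raise or warn explicitly rather than returning
  silent zeros.
- The pipeline stages communicate only via documented on-disk formats
  (VCF/BED/bedGraph/TSV/JSON), so each stage is testable in isolation
  and reruns are bit-identical given the seed.

## Known limitations

- The marker-noise model is a symmetric miscall rate; real genotype
  error is depth- and context-dependent.
- Mosaic tandem-orientation inference is depth-limited (expected
  discordant links scale with carrier-cell fraction), so 50%-mosaic
  duplications at 20× frequently return `tandem=False`.
- Double crossovers closer than the NCOGC span cutoff are reported as
  long conversion tracts (and vice versa, long tracts above it as
  AMBIGUOUS); no marker pattern can distinguish them.
- The large-deletion caller requires split-read evidence; deletions in
  the 21–49 bp range between the indel-VCF ceiling and reliable split
  capture are the least sensitively detected, as in real pipelines.
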
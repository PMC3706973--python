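# Methods

This note documents the models behind `clpptools`: what each component
assumes, which parameters matter, and what the synthetic-data tests do and
do not demonstrate about real sequencing data.

## Coordinates and sequence model

All coordinates are 0-based half-open internally; BED output stays 0-based,
VCF output is 1-based. A `Duplex` is represented as a *sense* string
spanning the molecule's full footprint with each strand occupying a
sub-interval, so restriction fragments with 5' overhangs need no special
cases: an overhang is a region covered by one strand.

Enzyme geometries are packaged data following standard catalog definitions
and overridable in config: MlyI (GAGTC, both cuts +5 → blunt) and BsaI
(GGTCTC, top +1 / bottom +5 → 4 nt 5' overhang). Offsets are measured 3'
of the recognition site's last base; for a site on the bottom strand the
geometry mirrors leftward. `N` never matches a recognition site
(conservative digestion). Cut pairs whose overhang footprints cross —
possible when an MlyI cut lands inside a BsaI overhang — cannot both be
realized on one molecule; the leftmost cut is applied and the conflicting
site recorded as skipped, as are sites whose cut coordinates fall off the
molecule.

## Probe design

For a target `[start, end)` the arms are exact reference slices
`[start-arm_len, start)` and `[end, end+arm_len)`, default `arm_len` 25
(mid-range of the permitted 18–28). The spacer layout is chosen so that
digestion leaves pure target sequence at the probe termini: the MlyI side
carries a 5 nt spacer (its blunt cut +5 lands exactly on the arm
boundary), the BsaI side a 1 nt spacer (its 4 nt overhang falls *inside*
the arm, so the overhang bases are arm sequence; one strand's terminal arm
is recessed by those 4 nt). With the packaged 280 bp backbone this gives a
347 bp precursor and a 330 bp functional duplex at arm length 25. The
forward primer is exactly 60 nt at the default arm length; the reverse
primer's backbone-anneal region is lengthened to reach 60 nt where
possible, otherwise the natural length is emitted and reported — arm-length
variation makes a hard 60 nt constraint unsatisfiable in general.

Strand layout of the functional duplex (target `arm_up | insert |
arm_down` in genomic order):

```
top:    5'-arm_down  backbone  arm_up[:-4]-3'      (captures antisense)
bottom: 5'-rc(arm_up)  rc(backbone)  rc(arm_down)-3'  (captures sense)
```

Each strand's 3' terminus anneals upstream of the gap and is extended
across it toward the phosphorylated 5' arm — two independent padlock
probes per duplex.

The packaged backbone is a synthetic 280 bp sequence, free of both
recognition sites on either strand, with the two post-capture
amplification linker landing sites embedded at its ends in the orientation
that makes an amplified circle read `linker → arm_up → insert → arm_down →
linker`. Amplicon reference records therefore carry 31/33 nt probe-derived
flanks outside the arms; insert-only records exclude arms and flanks.

Design failures (insufficient flank, restriction site inside an arm,
multiple sites in a precursor) are reported per target and the target
skipped; a single greedy pass varies the arm length ±3 nt to dodge internal
sites, which rescues most but not all random-sequence collisions (~10 % of
uniformly random targets still fail — consistent with panels needing some
probe replacement in practice). Oversize targets (> `max_gap` = 550) are
tiled into the minimum number of sub-targets with exactly the configured
overlap (default 50 bp), distributing lengths within ±1 bp. Abundance
weights follow GC: 1.0 up to GC 0.65, then a linear ramp to 4.0 at GC 0.80
(clamped above) — monotone by construction.

## Capture model

Capture is event-level; hybridization kinetics, temperatures and enzyme
chemistry are deliberately out of scope. For each probe × genome copy ×
active strand, `molecules_per_copy` independent Bernoulli trials succeed
with probability

```
p = min(1, p0 · exp(-k · max(0, GC - 0.65)) · weight),   k = ln2 / 0.15
```

so capture efficiency halves at GC 0.80 and extra probe abundance (the GC
weighting) compensates the penalty, saturating at 1. In cLPP mode both
strands are active; in ssLPP mode only the sense-capturing strand. Failed
(linear) species are never emitted — the exonuclease cleanup is implicit.
Inserts are haplotype slices carrying the planted alleles; deleted copies
contribute nothing; four-stranded hybrid complexes are not modelled. With
`p0 = 1`, no GC penalty and one trial, a diploid locus yields exactly 4
molecules (2 strands × 2 copies), which the deterministic tests exploit.

The choice of probability form (exponential GC penalty; weight inside the
saturating product) is ours: the assay only motivates that high-GC targets
capture worse and that more probe helps, so the functional form is the
simplest monotone model with a calibrated halving point.

## Synthetic genomes

`generate_genome` plants non-overlapping SNVs and small indels (VCF-style
anchored alleles) on two haplotypes of uniformly random contigs, with an
optional region restriction so tests can place variants inside captured
inserts. Copy-number segments set per-haplotype copy counts (trisomy = one
haplotype at 2; hemizygous male X = (1, 0); focal deletion = 0 over listed
exons). Haplotype coordinates are tracked with breakpoint/offset maps so
reference intervals slice correctly through indels. Everything is
deterministic under a fixed seed and the truth tables are exact.

What the generator does **not** emulate: GC-dependent coverage waves of
real polymerases beyond the single penalty term, chimeric or off-target
capture (there is no off-target source in-model, so 100 % specificity in
noiseless tests says nothing about real off-target rates), indel
sequencing errors, PCR duplicates with shared errors, or reference bias.

## Library and reads

Each captured circle is amplified once per PCR (equimolar A:B pooling; an
open question in the assay description, resolved to equimolar). The PCR-A
template carries P5 on the forward linker so read 1 reads the insert
sense strand; PCR-B swaps the adaptors so read 1 reads antisense — the
sequencing primers end exactly at the core boundary, so mate 1 starts at
the P5-proximal junction and mate 2 at the P7/index junction, running into
linker/index/adaptor sequence when the read outlasts the core. Quality is
a linear phred decay from Q38 (mate 2 decaying 1.5× faster), and per-base
substitution errors are drawn at the rate implied by the quality unless
disabled; indel sequencing errors are not modelled. The `depth` multiplier
resamples templates with replacement (PCR duplicates); read descriptions
carry the sample index (`BC:`) and, unless `--blind`, the ground truth
(`XT:`) for oracle tests.

## Read processing

The classifier is a seed-and-extend local aligner: exact 13-mer seeding on
both strands, diagonal-coherent chaining (±15 tolerance, accommodating
planted indels), merging of multiple chains on one amplicon to their
spanning interval when the reference span stays commensurate with the
query span, greedy exact end extension, and edit-distance refinement with
edlib. Scores use +1/−2/−2 (match/mismatch/gap) and an ungapped
Karlin–Altschul-style E-value (λ = 1.28, K = 0.46) against the total
reference length; the default cutoff 1e-6 plays the role of the classical
e-6 filter. Stage 1 (insert-only reference) discards adaptor/linker-only
reads; stage 2 (full amplicon reference) keeps the best-scoring segment,
breaking exact score ties by a seeded uniform choice (verified to split
50/50 over many seeds). Mapping quality is 3× the score margin over the
runner-up, capped at 60; exact ties get 0 and thus fail the MAPQ 30
filter.

Group classification is a pure function of (mate, strand): mate 1 sense or
mate 2 antisense → PCR-A; the other two combinations → PCR-B. Splitting
routes intact pairs to their group's file pair; a read whose mate was
discarded is kept with a 3 nt placeholder cut from the original mate;
mates assigned to different amplicons are demoted to singletons in their
own groups.

Coverage semantics separate the two filters: mapping quality below 30
removes the read entirely; base quality below 20 masks bases from the
depth/allele pileup but leaves the read in the amplicon count *A*. A read
counts toward *A* when the midpoint of its matched interval lies in the
amplicon's insert — "aligned within" needs a tie-break rule for partial
overlap, and the midpoint rule is deterministic. For tiled amplicons the
genomic overlap columns are excluded from both depth and counts in both
tiles. The genotyper calls a site at filtered depth ≥ 20: homozygous at
alt fraction ≥ 0.85, heterozygous in [0.25, 0.75], otherwise no call;
indels are limited to simple events contained in single reads. Sensitivity
is additionally reported at a mean-relative threshold (1.2 % of mean
depth) alongside the absolute one, since a fixed 20× means different
things at different run depths.

## Copy number

"Scale normalization" is library-size scaling followed by the per-amplicon
ratio — the simplest reading consistent with normalizing against a
reference sample; it is invariant to rescaling either sample. Medians
across PCRs/repeats ignore flagged (NaN) values. Log ratios use base 2.
The binned-SD QC sorts amplicons by reference coverage into bins of 200
and reports the SD of log2 ratios per bin; under counting noise it
decreases with coverage. Lowess (span 0.3 over genomic order, via
statsmodels) is presentation-only — calls use the **unsmoothed** combined
ratios, matching the stated use of smoothing for visualization.
Thresholds 0.7 (loss) and 1.35 (gain) sit midway between integer copy
states at diploid baseline; runs of ≥ 2 consecutive non-neutral amplicons
merge into calls. An optional per-contig ploidy table divides ratios by
`ploidy/2` before thresholding, handling the male-X baseline of one copy.

One systematic caveat the tests make visible: library-size scaling shifts
the baseline when a large fraction of the panel is aberrant (a trisomic
contig carrying 20 % of the panel depresses every other ratio by ~9 %), so
aneuploidy scenarios keep the aberrant fraction minor — as a real panel
spread over many chromosomes would.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to keep the suite
quick while leaving clear statistical margins: panels of 3–100 targets,
contigs of 2–70 kb, per-amplicon counts of ~10² (deterministic checks) to
~10³ (CNV ratio checks, matching the 2⁸–2¹² per-amplicon coverage range
such panels produce), and 5 seeds for stochastic parameter-recovery
claims. The insert-coverage sweep covers every length in 300–400 bp.
Degenerate inputs are defined rather than left to chance: empty panels
write empty files; fewer than 3 points pass through lowess with a warning;
identical count tables report Spearman ρ = 1; zero-reference amplicons are
flagged NaN and excluded downstream.

## Known limitations

- No thermodynamic or kinetic hybridization modelling; melting-temperature
  optimization and probe rebalancing from pilot data are out of scope.
- No off-target or chimeric capture, so specificity on simulator output is
  an internal consistency check, not a field estimate.
- The genotyper is a frequency-threshold caller over amplicon-anchored
  alignments — a re-interpretation, not a reproduction, of realigner +
  genotyper pipelines; no quality recalibration, no structural variants.
- Segmentation is run-merging only (no HMM/CBS), no tumor purity/ploidy.
- The E-value calibration is approximate (ungapped parameters applied to
  lightly gapped alignments); it is a filter, not a significance estimate.
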
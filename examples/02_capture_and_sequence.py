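"""Simulate capture of a diploid genome and reciprocal paired-end sequencing.

A cLPP duplex contributes two single-stranded probes, one per genomic
strand, so a diploid locus yields up to 2 strands x 2 copies capture events
per trial; each captured circle is amplified in two PCRs with swapped
adaptors (PCR-A / PCR-B) and sequenced 175/150 paired-end.
"""

from clpp import (
    CaptureModel,
    GenomeSpec,
    GenomicInterval,
    amplify_rpe,
    design_panel,
    generate_genome,
    generate_reads,
    simulate_capture,
)

spec = GenomeSpec(
    {"chr1": 10_000},
    snv_count=5,
    variant_regions=[GenomicInterval("chr1", 2_020, 2_180)],
)
genome = generate_genome(spec, seed=3)
designs, _ = design_panel(genome.reference, [GenomicInterval("chr1", 2_000, 2_200, "EX1")])

model = CaptureModel(mode="clpp", p0=0.9, molecules_per_copy=10)
captures = simulate_capture(genome, designs, model, seed=0)
print(f"{len(captures)} circularized molecules "
      f"(max 2 strands x 2 copies x {model.molecules_per_copy} trials)")

templates = amplify_rpe(captures, {d.name: d for d in designs}, seed=0)
print(f"{len(templates)} templates: every circle amplified once per PCR (A and B)")

reads1, reads2 = generate_reads(templates, r1_len=175, r2_len=150, seed=0)
print(f"{len(reads1)} read pairs, e.g. {reads1[0].header}")
print(f"read 1: {reads1[0].seq[:40]}... ({len(reads1[0].seq)} nt)")
# The XT: tag carries the ground-truth capture id and PCR label, which the
# classifier's orientation rule must reproduce; --blind strips it.
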
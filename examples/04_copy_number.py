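"""Detect a whole-contig trisomy from amplicon read-depth ratios.

Per-amplicon counts of a test sample are scale-normalized against a
diploid reference sample, combined by medians, lowess-smoothed for
display, and thresholded into loss/neutral/gain calls.  A trisomic contig
is expected near ratio 3/2.
"""

import pandas as pd

from clpp import (
    CaptureModel,
    CnvSegment,
    GenomeSpec,
    GenomicInterval,
    call_cnv,
    design_panel,
    generate_genome,
    lowess_smooth,
    median_combine,
    scale_normalize,
    simulate_capture,
)

contigs = {"chrA": 30_000, "chr13": 6_000}
targets = [
    GenomicInterval("chrA", 500 + i * 1_400, 700 + i * 1_400, f"A{i}") for i in range(20)
] + [
    GenomicInterval("chr13", 500 + i * 1_400, 700 + i * 1_400, f"T{i}") for i in range(4)
]

ref_genome = generate_genome(GenomeSpec(contigs), seed=9)
designs, _ = design_panel(ref_genome.reference, targets)
tri_genome = generate_genome(
    GenomeSpec(contigs, cnv_segments=[CnvSegment("chr13", None, None, (2, 1))]),
    seed=9,
)

model = CaptureModel(p0=0.9, molecules_per_copy=200)


def counts(genome, seed):
    caps = simulate_capture(genome, designs, model, seed)
    series = pd.Series(0, index=[d.name for d in designs], dtype=int)
    for c in caps:
        series[c.probe] += 1
    return series


ratios = scale_normalize(counts(tri_genome, 1), counts(ref_genome, 2))
combined = median_combine([ratios])
meta = pd.DataFrame(
    {
        "name": [d.name for d in designs],
        "contig": [d.target.contig for d in designs],
        "start": [d.target.start for d in designs],
        "end": [d.target.end for d in designs],
    }
)
smoothed = lowess_smooth(combined.to_numpy(), meta.start.to_numpy(), frac=0.5)
tri = meta.contig == "chr13"
diploid_mean = combined[~tri.to_numpy()].mean()
tri_mean = combined[tri.to_numpy()].mean()
print(f"mean ratio diploid contig: {diploid_mean:.3f}")
print(f"mean ratio trisomic contig: {tri_mean:.3f}")
print(f"trisomic / diploid baseline: {tri_mean / diploid_mean:.3f} (expect ~3/2)")
for call in call_cnv(combined, meta):
    print(f"{call.state}: {call.contig}:{call.start}-{call.end} "
          f"({len(call.amplicons)} amplicons, mean ratio {call.mean_ratio:.2f})")
# The smoothed curve is for plotting only; calls always use the unsmoothed
# combined ratios.
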
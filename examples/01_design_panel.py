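"""Design a cLPP panel for a handful of targets on a synthetic reference.

Each target gets two 60-mer primers, a ~350 bp PCR precursor, and a
functional ~330 bp probe duplex released by MlyI/BsaI trimming whose strand
termini are pure target sequence (the capture arms).
"""

import numpy as np

from clpp import GenomicInterval, design_panel

rng = np.random.default_rng(1)
reference = {"chr1": "".join(rng.choice(list("ACGT"), size=20_000))}
targets = [
    GenomicInterval("chr1", 2_000, 2_180, "EX1"),
    GenomicInterval("chr1", 5_000, 5_400, "EX2"),
    GenomicInterval("chr1", 9_000, 9_700, "EX3"),  # 700 bp: will be tiled
]

designs, report = design_panel(reference, targets)

print(report.to_string(index=False))
for d in designs:
    print(
        f"{d.name}: precursor {d.precursor.length} bp, "
        f"probe {d.functional_probe.length} bp, "
        f"gap-fill {len(d.insert_seq)} bp, weight {d.abundance_weight:.2f}"
    )
# The report lists one row per (tiled) sub-target with its design status,
# GC content and abundance weight; every gap-fill is at most 550 bp, and
# the 700 bp target appears as two overlapping sub-targets EX3.1/EX3.2.
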
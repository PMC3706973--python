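"""End-to-end convenience wrappers: design -> capture -> reads -> process.

These glue the module-level operations together in the order a panel run
uses them; the CLI, the examples and the test-bench all go through here so
the wiring is exercised in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import config as cfg
from .capture_simulator import CaptureModel, DiploidGenomeTruth, simulate_capture
from .io import FastqRecord
from .probe_design import PanelReferences, ProbeDesign, build_references, design_panel
from .read_processing import (
    ClassifyStats,
    CoverageTable,
    GroupSplit,
    ReadAssignment,
    VariantCall,
    call_variants,
    capture_metrics,
    classify_pairs,
    compute_coverage,
    split_groups,
)
from .rpe_library import AdaptorSet, QualityModel, amplify_rpe, generate_reads


@dataclass
class ProcessResult:
    """Everything the read processor produces for one sample."""

    assignments: list[tuple[ReadAssignment | None, ReadAssignment | None]]
    stats: ClassifyStats
    split: GroupSplit
    coverage: CoverageTable
    calls: list[VariantCall]
    metrics: dict = field(default_factory=dict)

    @property
    def flat_assignments(self) -> list[ReadAssignment]:
        return [a for pair in self.assignments for a in pair if a is not None]


def sequence_sample(
    genome: DiploidGenomeTruth,
    designs: list[ProbeDesign],
    model: CaptureModel | None = None,
    adaptors: AdaptorSet | None = None,
    index: str = "ACGTAC",
    sample: str = "S1",
    mode: str = "rpe",
    r1_len: int = 175,
    r2_len: int = 150,
    quality: QualityModel | None = None,
    depth: float = 1.0,
    seed: int = 0,
    blind: bool = False,
) -> tuple[list[FastqRecord], list[FastqRecord]]:
    """Capture a genome with a panel and sequence the resulting library."""
    model = model or CaptureModel()
    captures = simulate_capture(genome, designs, model, seed)
    templates = amplify_rpe(
        captures, {d.name: d for d in designs},
        adaptors=adaptors, index=index, mode=mode, seed=seed + 1,
    )
    return generate_reads(
        templates, r1_len=r1_len, r2_len=r2_len, quality=quality,
        depth=depth, seed=seed + 2, sample=sample, blind=blind,
    )


def insert_coverage_sweep(
    insert_lengths: list[int],
    r1_len: int = 175,
    r2_len: int = 150,
    mode: str = "rpe",
    seed: int = 0,
    evalue: float = 1e-6,
) -> dict[int, bool]:
    """Which insert lengths are fully covered by pooled paired-end reads.

    For each length, a random insert-sized template core is sequenced
    (noiselessly) through the library simulator, the reads are assigned
    back to the core with the classifier, and the union of their matched
    intervals is checked against the full core.  Under rPE pooling the
    largest fully covered insert is ``r1_len + max(r1_len, r2_len)``; under
    standard paired-end sequencing it is ``r1_len + r2_len``.
    """
    import numpy as np

    from .read_processing import classify_pairs
    from .rpe_library import template_pair

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    adaptors = AdaptorSet()
    out: dict[int, bool] = {}
    for length in insert_lengths:
        core = "".join(rng.choice(bases, size=length))
        name = f"insert_{length}"
        tpl_a, tpl_b = template_pair(core, adaptors, "ACGTAC", name)
        templates = [tpl_a, tpl_b] if mode == "rpe" else [tpl_a]
        reads1, reads2 = generate_reads(
            templates, r1_len=r1_len, r2_len=r2_len,
            quality=QualityModel(stochastic_errors=False), seed=seed,
        )
        assignments, _ = classify_pairs(
            list(zip(reads1, reads2)), {name: core}, {name: core},
            evalue_cutoff=evalue, seed=seed,
        )
        covered = np.zeros(length, dtype=bool)
        for pair in assignments:
            for a in pair:
                if a is not None:
                    lo, hi = a.r_interval
                    covered[max(0, lo) : min(length, hi)] = True
        out[length] = bool(covered.all())
    return out


def process_sample(
    pairs: list[tuple[FastqRecord, FastqRecord]],
    panel: PanelReferences,
    evalue: float = 1e-6,
    mapq_min: int = 30,
    baseq_min: int = 20,
    min_depth: int = 20,
    het_band: tuple[float, float] = (0.25, 0.75),
    hom_threshold: float = 0.85,
    seed: int = 0,
    truth_variants: pd.DataFrame | None = None,
) -> ProcessResult:
    """Classify, split, pile up and genotype one demultiplexed sample."""
    insert_refs = dict(panel.inserts)
    amplicon_refs = dict(panel.amplicons)
    assignments, stats = classify_pairs(
        pairs, insert_refs, amplicon_refs, evalue_cutoff=evalue, seed=seed
    )
    split = split_groups(assignments, pairs)
    flat = [a for pair in assignments for a in pair if a is not None]
    coverage = compute_coverage(flat, panel, mapq_min=mapq_min, baseq_min=baseq_min)
    calls = call_variants(
        coverage, insert_refs,
        min_depth=min_depth, het_band=het_band, hom_threshold=hom_threshold,
    )
    result = ProcessResult(assignments, stats, split, coverage, calls)
    result.metrics = capture_metrics(
        coverage, stats, flat,
        truth_variants=truth_variants, calls=calls, min_depth=min_depth,
    )
    return result
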
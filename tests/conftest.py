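"""Shared fixtures: a small designed panel on a synthetic genome."""

import numpy as np
import pytest

from clpp import (
    CaptureModel,
    GenomeSpec,
    GenomicInterval,
    QualityModel,
    amplify_rpe,
    build_references,
    design_panel,
    generate_genome,
    generate_reads,
    simulate_capture,
)


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(np.array(list("ACGT")), size=length))


@pytest.fixture(scope="session")
def small_genome():
    """Diploid single-contig genome with a handful of planted SNVs."""
    spec = GenomeSpec(
        {"chr1": 6000},
        snv_count=6,
        variant_regions=[
            GenomicInterval("chr1", 520, 680),
            GenomicInterval("chr1", 1550, 1750),
            GenomicInterval("chr1", 3050, 3250),
        ],
    )
    return generate_genome(spec, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_genome):
    """Three designed targets on the small genome."""
    targets = [
        GenomicInterval("chr1", 500, 700, "T1"),
        GenomicInterval("chr1", 1530, 1770, "T2"),
        GenomicInterval("chr1", 3030, 3270, "T3"),
    ]
    designs, report = design_panel(small_genome.reference, targets)
    assert (report["status"] == "ok").all()
    return designs


@pytest.fixture(scope="session")
def small_references(small_panel):
    return build_references(small_panel)


@pytest.fixture(scope="session")
def noiseless_pairs(small_genome, small_panel):
    """Deterministic noiseless read pairs from the small panel."""
    model = CaptureModel(p0=1.0, gc_threshold=1.0, molecules_per_copy=3)
    captures = simulate_capture(small_genome, small_panel, model, seed=0)
    templates = amplify_rpe(captures, {d.name: d for d in small_panel}, seed=0)
    reads1, reads2 = generate_reads(
        templates, quality=QualityModel(stochastic_errors=False), seed=0
    )
    return list(zip(reads1, reads2))
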
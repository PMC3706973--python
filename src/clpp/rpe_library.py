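"""Reciprocal paired-end (rPE) library amplification and read simulation.

Each captured circle is amplified in two separate PCRs whose primers swap
the flow-cell adaptors between the two linker landing sites of the probe
backbone (PCR-A: P5 on the forward linker, PCR-B: P5 on the reverse
linker).  Pooled and sequenced paired-end, one circle therefore yields four
distinct read species -- read 1 sense / read 2 antisense from PCR-A
templates, and read 1 antisense / read 2 sense from PCR-B -- which is what
lets a 175/150 run cover inserts up to 175 + 175 = 350 bp.

Read geometry: the custom sequencing primers end exactly at the boundary of
the template "core" (arm + insert + arm for panel-derived templates), so
mate 1 reads the core from the P5-proximal junction inward and mate 2 from
the P7/index junction inward; reads longer than the core run into linker,
index and adaptor sequence, whose removal is the read processor's job.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from . import config as cfg
from .capture_simulator import CircularCapture
from .io import FastqRecord, phred_string
from .probe_design import ProbeDesign
from .sequence_model import revcomp

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class AdaptorSet:
    """Flow-cell adaptors, linker landing sites and sequencing-primer tails."""

    p5: str = cfg.P5
    p7: str = cfg.P7
    linker_f: str = cfg.LINK_F
    linker_r: str = cfg.LINK_R
    read1_ext: str = cfg.READ1_EXT
    read2_ext: str = cfg.READ2_EXT
    index_len: int = 6

    def __post_init__(self) -> None:
        if self.linker_f == self.linker_r:
            raise ValueError("linker_f and linker_r must differ")

    @property
    def read1_primer(self) -> str:
        return self.linker_f + self.read1_ext

    @property
    def read2_primer(self) -> str:
        return self.linker_r + self.read2_ext


@dataclass
class AmpliconTemplate:
    """One sequencable template molecule.

    ``seq`` is oriented so that mate 1 reads left-to-right starting at
    ``r1_offset``; mate 2 reads the reverse complement starting at
    ``r2_offset`` from the other end.  ``r1_sense`` records whether mate 1
    reads the sense strand of the original insert.
    """

    capture_id: str
    pcr: str  # 'A' | 'B'
    seq: str
    r1_offset: int
    r2_offset: int
    core_len: int
    index: str
    r1_sense: bool


def template_pair(
    core: str, adaptors: AdaptorSet, index: str, capture_id: str
) -> tuple[AmpliconTemplate, AmpliconTemplate]:
    """The PCR-A and PCR-B templates for one captured circle core."""
    a = adaptors
    seq_a = (
        a.p5 + a.linker_f + a.read1_ext + core
        + revcomp(a.read2_ext) + revcomp(a.linker_r) + revcomp(index) + revcomp(a.p7)
    )
    seq_b = (
        a.p5 + a.linker_r + a.read2_ext + revcomp(core)
        + revcomp(a.read1_ext) + revcomp(a.linker_f) + revcomp(index) + revcomp(a.p7)
    )
    tpl_a = AmpliconTemplate(
        capture_id, "A", seq_a,
        r1_offset=len(a.p5) + len(a.read1_primer),
        r2_offset=len(a.p7) + len(index) + len(a.read2_primer),
        core_len=len(core), index=index, r1_sense=True,
    )
    tpl_b = AmpliconTemplate(
        capture_id, "B", seq_b,
        r1_offset=len(a.p5) + len(a.read2_primer),
        r2_offset=len(a.p7) + len(index) + len(a.read1_primer),
        core_len=len(core), index=index, r1_sense=False,
    )
    return tpl_a, tpl_b


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        current = arr[i].decode()
        arr[i] = str(rng.choice([b for b in "ACGT" if b != current])).encode()
    return arr.tobytes().decode()


def amplify_rpe(
    captures: Sequence[CircularCapture],
    designs: Mapping[str, ProbeDesign],
    adaptors: AdaptorSet | None = None,
    index: str = "ACGTAC",
    mode: str = "rpe",
    pcr_error_rate: float = 0.0,
    seed: int = 0,
) -> list[AmpliconTemplate]:
    """Amplify captured circles into sequencable templates.

    In ``rpe`` mode every circle yields one PCR-A and one PCR-B template
    (pooled equimolar); in ``standard`` mode only PCR-A.  An optional
    per-base substitution error rate is applied independently per PCR.
    """
    if not captures:
        raise ValueError("no captured molecules to amplify")
    adaptors = adaptors or AdaptorSet()
    if len(index) != adaptors.index_len:
        raise ValueError(
            f"sample index must be {adaptors.index_len} bases, got {len(index)}"
        )
    rng = np.random.default_rng(seed)
    templates: list[AmpliconTemplate] = []
    for capture in captures:
        design = designs[capture.probe]
        core = design.arms.arm_up + capture.insert_seq + design.arms.arm_down
        tpl_a, tpl_b = template_pair(core, adaptors, index, capture.capture_id)
        if pcr_error_rate > 0:
            tpl_a = replace(tpl_a, seq=_mutate(tpl_a.seq, pcr_error_rate, rng))
            tpl_b = replace(tpl_b, seq=_mutate(tpl_b.seq, pcr_error_rate, rng))
        templates.append(tpl_a)
        if mode == "rpe":
            templates.append(tpl_b)
        elif mode != "standard":
            raise ValueError(f"unknown library mode {mode!r}")
    return templates


@dataclass(frozen=True)
class QualityModel:
    """Linear phred decay along the read; mate 2 decays 1.5x faster.

    When ``stochastic_errors`` is set, each base is substituted with the
    probability implied by its phred score.
    """

    q_start: float = 38.0
    r1_slope: float = 0.05
    r2_slope: float = 0.075
    q_floor: float = 2.0
    stochastic_errors: bool = True

    def quals(self, length: int, mate: int) -> np.ndarray:
        slope = self.r1_slope if mate == 1 else self.r2_slope
        q = self.q_start - slope * np.arange(length)
        return np.maximum(q, self.q_floor)


def _sequence(
    template_seq: str, offset: int, length: int, mate: int,
    quality: QualityModel, rng: np.random.Generator,
) -> tuple[str, str]:
    bases = template_seq[offset : offset + length]
    quals = quality.quals(len(bases), mate)
    if quality.stochastic_errors and len(bases):
        p_err = 10 ** (-quals / 10.0)
        hits = np.nonzero(rng.random(len(bases)) < p_err)[0]
        if len(hits):
            arr = list(bases)
            for i in hits:
                arr[i] = str(rng.choice([b for b in "ACGT" if b != arr[i]]))
            bases = "".join(arr)
    return bases, phred_string(np.round(quals).astype(int))


def generate_reads(
    templates: Sequence[AmpliconTemplate],
    r1_len: int = 175,
    r2_len: int = 150,
    quality: QualityModel | None = None,
    depth: float = 1.0,
    seed: int = 0,
    sample: str = "S1",
    blind: bool = False,
) -> tuple[list[FastqRecord], list[FastqRecord]]:
    """Generate paired-end reads from templates; deterministic under seed.

    ``depth`` is a PCR-duplicate multiplier: at 1.0 every template is read
    exactly once; above 1.0 the excess is resampled with replacement
    (duplicate molecules).  Read descriptions carry the sample index as a
    ``BC:`` tag and, unless ``blind``, the ground truth as
    ``XT:<capture_id>|<pcr>``.
    """
    if r1_len <= 0 or r2_len <= 0:
        raise ValueError("read lengths must be positive")
    quality = quality or QualityModel()
    rng = np.random.default_rng(seed)
    order = list(range(len(templates)))
    extra = int(round((depth - 1.0) * len(templates)))
    if extra > 0:
        order += list(rng.integers(0, len(templates), size=extra))
    reads1: list[FastqRecord] = []
    reads2: list[FastqRecord] = []
    for serial, idx in enumerate(order):
        tpl = templates[idx]
        b1, q1 = _sequence(tpl.seq, tpl.r1_offset, r1_len, 1, quality, rng)
        b2, q2 = _sequence(revcomp(tpl.seq), tpl.r2_offset, r2_len, 2, quality, rng)
        name = f"{sample}:{serial:07d}"
        desc = f"BC:{tpl.index}"
        if not blind:
            desc += f" XT:{tpl.capture_id}|{tpl.pcr}"
        reads1.append(FastqRecord(name, b1, q1, desc))
        reads2.append(FastqRecord(name, b2, q2, desc))
    return reads1, reads2
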
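"""Synthetic diploid genomes with planted variation, and capture simulation.

The genome generator emulates the kinds of samples a targeted panel is run
on: a diploid genome carrying heterozygous/homozygous SNVs, small indels, a
whole-chromosome trisomy and focal hemizygous deletions, together with
exact truth tables for parameter-recovery tests.

Capture is modelled at event level: for every (probe, genome copy, strand)
combination a batch of independent Bernoulli trials decides how many
circularized molecules form.  Linear (failed) species are never emitted --
the exonuclease cleanup step that removes them is implicit.  In cLPP mode
both single strands of the probe duplex are active (one captures the sense
genomic strand, the other the antisense strand); in ssLPP mode only one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.constants import Avogadro

from .probe_design import ProbeDesign
from .sequence_model import GenomicInterval, revcomp

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CnvSegment:
    """Copy-number of one interval, per haplotype (1 = normal single copy)."""

    contig: str
    start: int | None  # None = whole contig
    end: int | None
    copies: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.copies):
            raise ValueError("copy numbers must be >= 0")


@dataclass
class GenomeSpec:
    """Recipe for a synthetic diploid genome."""

    contigs: dict[str, int]
    snv_count: int = 0
    het_fraction: float = 0.67
    indel_count: int = 0
    indel_len: tuple[int, int] = (1, 10)
    cnv_segments: list[CnvSegment] = field(default_factory=list)
    variant_regions: list[GenomicInterval] | None = None  # None = anywhere


class OverlappingVariantError(ValueError):
    pass


@dataclass
class DiploidGenomeTruth:
    """A synthetic genome plus exact truth tables."""

    reference: dict[str, str]
    haplotypes: dict[tuple[str, int], str]
    # per (contig, hap): sorted reference breakpoints and cumulative offsets
    _maps: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]]
    variants: pd.DataFrame  # contig, pos (0-based), ref, alt, genotype, type
    cnv: pd.DataFrame  # contig, start, end, hap, copies

    def ref_to_hap(self, contig: str, hap: int, pos: int) -> int:
        """Map a reference coordinate to the haplotype coordinate."""
        breaks, offsets = self._maps[(contig, hap)]
        i = int(np.searchsorted(breaks, pos, side="right")) - 1
        return pos + int(offsets[i])

    def hap_slice(self, contig: str, hap: int, start: int, end: int) -> str:
        return self.haplotypes[(contig, hap)][
            self.ref_to_hap(contig, hap, start) : self.ref_to_hap(contig, hap, end)
        ]

    def copies_at(self, contig: str, pos: int) -> tuple[int, int]:
        """Per-haplotype copy number at a reference position (default 1,1)."""
        copies = [1, 1]
        sub = self.cnv[self.cnv.contig == contig]
        for row in sub.itertuples():
            if row.start <= pos < row.end:
                copies[row.hap] = row.copies
        return tuple(copies)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _place_variants(rng, spec: GenomeSpec, contig_lengths) -> list[dict]:
    """Choose non-overlapping variant loci within the allowed regions."""
    edge = 2  # keep variants off the very ends of contigs
    regions = spec.variant_regions
    if regions is None:
        regions = [
            GenomicInterval(c, edge, L - edge) for c, L in contig_lengths.items()
        ]
    weights = np.array([r.length for r in regions], dtype=float)
    weights /= weights.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_lengths}
    out: list[dict] = []
    max_len = spec.indel_len[1]
    plan = ["snv"] * spec.snv_count + ["indel"] * spec.indel_count
    for kind in plan:
        for _attempt in range(1000):
            region = regions[rng.choice(len(regions), p=weights)]
            pos = int(rng.integers(region.start, region.end))
            span = (pos - 1, pos + max_len + 2)  # pad so indels cannot collide
            if any(a < span[1] and span[0] < b for a, b in occupied[region.contig]):
                continue
            if kind == "indel" and pos + max_len + 2 >= region.end:
                continue
            occupied[region.contig].append(span)
            out.append({"contig": region.contig, "pos": pos, "kind": kind})
            break
        else:
            raise OverlappingVariantError(
                "could not place all variants without overlap; "
                "reduce counts or widen variant_regions"
            )
    return out


def generate_genome(spec: GenomeSpec, seed: int) -> DiploidGenomeTruth:
    """Build a diploid genome with planted SNVs, indels and CNV segments.

    Deterministic under a fixed seed.  Variants never overlap one another;
    the truth tables are exact and verifiable by reconstruction.
    """
    rng = np.random.default_rng(seed)
    reference = {c: _random_seq(rng, L) for c, L in spec.contigs.items()}
    loci = _place_variants(rng, spec, spec.contigs)

    edits: dict[tuple[str, int], list[tuple[int, str, str]]] = {
        (c, h): [] for c in spec.contigs for h in (0, 1)
    }
    var_rows = []
    for locus in loci:
        contig, pos = locus["contig"], locus["pos"]
        ref_seq = reference[contig]
        het = rng.random() < spec.het_fraction
        haps = ([int(rng.integers(0, 2))] if het else [0, 1])
        if locus["kind"] == "snv":
            ref_allele = ref_seq[pos]
            alt_allele = str(rng.choice([b for b in "ACGT" if b != ref_allele]))
            vtype = "snv"
        else:
            length = int(rng.integers(spec.indel_len[0], spec.indel_len[1] + 1))
            if rng.random() < 0.5:  # deletion, VCF-style anchored at pos
                ref_allele = ref_seq[pos : pos + length + 1]
                alt_allele = ref_seq[pos]
                vtype = "del"
            else:  # insertion after pos
                ref_allele = ref_seq[pos]
                alt_allele = ref_allele + _random_seq(rng, length)
                vtype = "ins"
        for hap in haps:
            edits[(contig, hap)].append((pos, ref_allele, alt_allele))
        var_rows.append(
            {
                "contig": contig, "pos": pos, "ref": ref_allele, "alt": alt_allele,
                "genotype": "het" if het else "hom", "type": vtype,
                "hap": haps[0] if het else -1,
            }
        )

    haplotypes: dict[tuple[str, int], str] = {}
    maps: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}
    for (contig, hap), hap_edits in edits.items():
        ref_seq = reference[contig]
        pieces = []
        breaks = [0]
        offsets = [0]
        cursor = 0
        shift = 0
        for pos, ref_allele, alt_allele in sorted(hap_edits):
            pieces.append(ref_seq[cursor:pos])
            pieces.append(alt_allele)
            cursor = pos + len(ref_allele)
            shift += len(alt_allele) - len(ref_allele)
            breaks.append(cursor)
            offsets.append(shift)
        pieces.append(ref_seq[cursor:])
        haplotypes[(contig, hap)] = "".join(pieces)
        maps[(contig, hap)] = (np.array(breaks), np.array(offsets))

    cnv_rows = []
    for seg in spec.cnv_segments:
        start = 0 if seg.start is None else seg.start
        end = spec.contigs[seg.contig] if seg.end is None else seg.end
        for hap in (0, 1):
            if seg.copies[hap] != 1:
                cnv_rows.append(
                    {"contig": seg.contig, "start": start, "end": end,
                     "hap": hap, "copies": seg.copies[hap]}
                )
    return DiploidGenomeTruth(
        reference=reference,
        haplotypes=haplotypes,
        _maps=maps,
        variants=pd.DataFrame(
            var_rows,
            columns=["contig", "pos", "ref", "alt", "genotype", "type", "hap"],
        ).sort_values(["contig", "pos"]).reset_index(drop=True),
        cnv=pd.DataFrame(cnv_rows, columns=["contig", "start", "end", "hap", "copies"]),
    )


@dataclass
class CaptureModel:
    """Event-level stochastic model of multiplex capture."""

    mode: str = "clpp"  # 'clpp' (both strands) or 'sslpp' (sense-capturing only)
    p0: float = 0.9  # per-strand base capture efficiency
    gc_threshold: float = 0.65
    gc_halving: float = 0.15  # GC excess above threshold that halves efficiency
    molecules_per_copy: int = 10  # Bernoulli trials per (probe, copy, strand)

    def gc_penalty(self, gc: float) -> float:
        k = math.log(2.0) / self.gc_halving
        return math.exp(-k * max(0.0, gc - self.gc_threshold))

    def strand_probability(self, gc: float, weight: float = 1.0) -> float:
        """Per-trial capture probability for one probe strand.

        The abundance weight scales the effective probability (more probe,
        more capture events) but saturates at 1; for weight 1 this is just
        ``p0 * gc_penalty``.
        """
        return min(1.0, self.p0 * self.gc_penalty(gc) * weight)


@dataclass
class CircularCapture:
    """One circularized captured molecule."""

    capture_id: str
    probe: str  # design name
    strand: str  # genomic strand captured: 'sense' | 'antisense'
    hap: int
    copy_index: int
    insert_seq: str  # allele-bearing, stored in sense orientation


class ArmMismatchError(RuntimeError):
    pass


def simulate_capture(
    genome: DiploidGenomeTruth,
    designs: Sequence[ProbeDesign],
    model: CaptureModel,
    seed: int,
) -> list[CircularCapture]:
    """Simulate multiplex capture of a panel on a synthetic genome.

    For each probe x genome copy x active strand, capture succeeds
    independently with probability ``p0 * gc_penalty * weight`` (capped at
    1) in each of ``molecules_per_copy`` trials.  Inserts carry the planted
    alleles of their haplotype of origin; deleted copies yield nothing.
    """
    rng = np.random.default_rng(seed)
    strands = ("sense", "antisense") if model.mode == "clpp" else ("sense",)
    captures: list[CircularCapture] = []
    serial = 0
    for design in designs:
        target = design.target
        ref_seq = genome.reference[target.contig]
        arm_len_up = len(design.arms.arm_up)
        arm_len_down = len(design.arms.arm_down)
        if (
            ref_seq[target.start - arm_len_up : target.start] != design.arms.arm_up
            or ref_seq[target.end : target.end + arm_len_down] != design.arms.arm_down
        ):
            raise ArmMismatchError(
                f"arms of probe {design.name} do not match the reference"
            )
        p = model.strand_probability(design.gc, design.abundance_weight)
        copies = genome.copies_at(target.contig, target.midpoint)
        for hap in (0, 1):
            insert = None
            for copy_index in range(copies[hap]):
                for strand in strands:
                    n = rng.binomial(model.molecules_per_copy, p)
                    if n and insert is None:
                        insert = genome.hap_slice(
                            target.contig, hap, target.start, target.end
                        )
                    for _ in range(n):
                        captures.append(
                            CircularCapture(
                                capture_id=f"{design.name}:{hap}.{copy_index}.{strand[0]}.{serial}",
                                probe=design.name,
                                strand=strand,
                                hap=hap,
                                copy_index=copy_index,
                                insert_seq=insert,
                            )
                        )
                        serial += 1
    return captures


def probe_target_ratio(
    probe_amount_fmol: float,
    n_probes: int,
    dna_mass_ng: float,
    genome_mass_per_copy_pg: float = 3.3,
) -> float:
    """Molar excess of one probe species over its genomic target copies.

    ``genome_mass_per_copy_pg`` is the mass of one genome copy (~3.3 pg for
    a haploid human genome); whether haploid or diploid copies are counted
    is the caller's choice of that parameter.
    """
    if min(probe_amount_fmol, n_probes, dna_mass_ng, genome_mass_per_copy_pg) <= 0:
        raise ValueError("all quantities must be positive")
    probe_moles = probe_amount_fmol * 1e-15 / n_probes
    target_copies = dna_mass_ng * 1e-9 / (genome_mass_per_copy_pg * 1e-12)
    target_moles = target_copies / Avogadro
    return probe_moles / target_moles


def write_genome(genome: DiploidGenomeTruth, outdir) -> None:
    """genome reference + haplotypes FASTA, truth.vcf-like TSV, truth_cnv.bed."""
    from pathlib import Path

    from . import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_fasta(outdir / "reference.fa", genome.reference.items())
    io.write_fasta(
        outdir / "haplotypes.fa",
        [(f"{c}/hap{h}", s) for (c, h), s in genome.haplotypes.items()],
    )
    genome.variants.to_csv(outdir / "truth_variants.tsv", sep="\t", index=False)
    with open(outdir / "truth_cnv.bed", "w") as handle:
        for row in genome.cnv.itertuples():
            handle.write(
                f"{row.contig}\t{row.start}\t{row.end}\thap{row.hap}_x{row.copies}\n"
            )
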
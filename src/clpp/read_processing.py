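"""Read processing: demultiplexing, amplicon assignment, coverage, genotyping.

The pipeline mirrors targeted-amplicon practice: reads are demultiplexed on
a 6 bp sample index, filtered by local alignment against an "insert-only"
reference (which removes adaptor/linker-only reads), assigned to their best
amplicon, classified into reciprocal-PCR groups from their mate x strand
orientation, and piled up for depth, allele counts and genotype calls.

The alignment stage is a seed-and-extend local aligner (exact k-mer seeding,
greedy exact extension, banded edit-distance refinement via edlib) with a
Karlin-Altschul-style E-value under simple +1/-2/-2 scoring.  It plays the
role a BLAST search would in a heavyweight pipeline while keeping the same
filtering contract (an e-6 style cutoff, best hit kept, score ties broken
by a seeded random choice, multiple hits to one amplicon merged to their
spanning interval).
"""

from __future__ import annotations

import math
import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import FastqRecord
from .probe_design import PanelReferences
from .sequence_model import revcomp

# Ungapped Karlin-Altschul-style parameters for +1 match / -2 mismatch,
# gap cost 2 per base; the cutoff plays the role of a BLAST E-value.
KA_LAMBDA = 1.28
KA_K = 0.46
MATCH, MISMATCH, GAP = 1, 2, 2

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


class DemultiplexError(ValueError):
    pass


def demultiplex(
    pairs: Iterable[tuple[FastqRecord, FastqRecord]],
    index_table: Mapping[str, str],
    max_mismatch: int = 0,
) -> dict[str, list[tuple[FastqRecord, FastqRecord]]]:
    """Assign read pairs to samples by their ``BC:`` index tag.

    A pair is assigned to the unique sample whose index matches within
    ``max_mismatch`` substitutions; non-matching or ambiguous pairs land in
    the ``"undetermined"`` bin.  Duplicate indexes in the table are an
    error, as are indexes of unequal length.
    """
    indexes = list(index_table.values())
    if len(set(indexes)) != len(indexes):
        raise DemultiplexError("duplicate sample index in table")
    if len({len(i) for i in indexes}) > 1:
        raise DemultiplexError("sample indexes must all have the same length")
    out: dict[str, list] = {sample: [] for sample in index_table}
    out["undetermined"] = []
    for r1, r2 in pairs:
        observed = r1.tag("BC")
        bin_name = "undetermined"
        if observed is not None:
            matches = [
                sample
                for sample, idx in index_table.items()
                if len(idx) == len(observed)
                and sum(a != b for a, b in zip(idx, observed)) <= max_mismatch
            ]
            if len(matches) == 1:
                bin_name = matches[0]
        out[bin_name].append((r1, r2))
    return out


# ------------------------------------------------------------ alignment

@dataclass
class Hit:
    """One candidate local alignment of a read against a reference record."""

    ref: str
    strand: str  # '+' read matches reference sense, '-' its reverse complement
    q_lo: int
    q_hi: int
    r_lo: int
    r_hi: int
    score: int
    evalue: float
    cigar: str  # extended cigar of oriented query segment vs ref segment


class LocalAligner:
    """Seed-and-extend local alignment against a small reference set."""

    def __init__(self, refs: Mapping[str, str], k: int = 13):
        self.refs = dict(refs)
        if not self.refs:
            raise ValueError("empty reference set")
        self.k = k
        self.db_size = sum(len(s) for s in self.refs.values())
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in self.refs.items():
            for i in range(len(seq) - k + 1):
                self._index[seq[i : i + k]].append((name, i))

    def _clusters(self, q: str) -> dict[str, list[tuple[int, int]]]:
        """Seed matches per reference, as (query_pos, ref_pos) lists."""
        k = self.k
        by_ref: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for i in range(len(q) - k + 1):
            for name, rpos in self._index.get(q[i : i + k], ()):
                by_ref[name].append((i, rpos))
        return by_ref

    def _evalue(self, score: int, qlen: int) -> float:
        if score <= 0:
            return math.inf
        return KA_K * qlen * self.db_size * math.exp(-KA_LAMBDA * score)

    def align(self, read: str, rng: np.random.Generator | None = None) -> list[Hit]:
        """All plausible hits of ``read``, best first.

        Seeds on both strands are grouped per reference record into
        diagonal-coherent chains; chains on the same record are merged to
        their spanning interval.  Ends are extended by greedy exact match,
        then the segment pair is rescored with a full alignment.
        """
        hits: list[Hit] = []
        for strand in ("+", "-"):
            q = read if strand == "+" else revcomp(read)
            for ref_name, seeds in self._clusters(q).items():
                ref_seq = self.refs[ref_name]
                chains = self._chain(seeds)
                if not chains:
                    continue
                span = self._merge_chains(chains, len(q))
                for q_lo, q_hi, r_lo, r_hi in span:
                    hit = self._refine(q, ref_name, ref_seq, q_lo, q_hi, r_lo, r_hi, strand)
                    if hit is not None:
                        hits.append(hit)
        hits.sort(key=lambda h: (-h.score, h.ref, h.strand))
        return hits

    def _chain(self, seeds: list[tuple[int, int]]) -> list[tuple[int, int, int, int]]:
        """Group seeds into diagonal-coherent chains (tolerating small indels)."""
        by_diag = sorted(seeds, key=lambda s: (s[1] - s[0], s[0]))
        chains = []
        current: list[tuple[int, int]] = []
        last_diag = None
        for qpos, rpos in by_diag:
            diag = rpos - qpos
            if last_diag is None or abs(diag - last_diag) <= 15:
                current.append((qpos, rpos))
            else:
                chains.append(current)
                current = [(qpos, rpos)]
            last_diag = diag
        if current:
            chains.append(current)
        out = []
        for chain in chains:
            qs = [s[0] for s in chain]
            rs = [s[1] for s in chain]
            out.append((min(qs), max(qs) + self.k, min(rs), max(rs) + self.k))
        return out

    @staticmethod
    def _merge_chains(
        chains: list[tuple[int, int, int, int]], qlen: int
    ) -> list[tuple[int, int, int, int]]:
        """Merge chains on one record into the spanning interval.

        Merging is only done when the implied reference span stays
        commensurate with the query span (multiple local alignments of one
        read to one amplicon); wildly separated chains are kept apart and
        compete on score.
        """
        if len(chains) == 1:
            return chains
        q_lo = min(c[0] for c in chains)
        q_hi = max(c[1] for c in chains)
        r_lo = min(c[2] for c in chains)
        r_hi = max(c[3] for c in chains)
        if (r_hi - r_lo) <= (q_hi - q_lo) + 50:
            return [(q_lo, q_hi, r_lo, r_hi)]
        return chains

    def _refine(
        self, q: str, ref_name: str, ref_seq: str,
        q_lo: int, q_hi: int, r_lo: int, r_hi: int, strand: str,
    ) -> Hit | None:
        import edlib

        # greedy exact extension of the seeded span
        while q_lo > 0 and r_lo > 0 and q[q_lo - 1] == ref_seq[r_lo - 1]:
            q_lo -= 1
            r_lo -= 1
        while q_hi < len(q) and r_hi < len(ref_seq) and q[q_hi] == ref_seq[r_hi]:
            q_hi += 1
            r_hi += 1
        if q_hi - q_lo < self.k:
            return None
        result = edlib.align(q[q_lo:q_hi], ref_seq[r_lo:r_hi], mode="NW", task="path")
        n_eq = n_x = n_gap = 0
        for count, op in _CIGAR_RE.findall(result["cigar"]):
            count = int(count)
            if op == "=":
                n_eq += count
            elif op == "X":
                n_x += count
            else:
                n_gap += count
        score = MATCH * n_eq - MISMATCH * n_x - GAP * n_gap
        return Hit(
            ref=ref_name, strand=strand, q_lo=q_lo, q_hi=q_hi, r_lo=r_lo, r_hi=r_hi,
            score=score, evalue=self._evalue(score, len(q)), cigar=result["cigar"],
        )


# ------------------------------------------------------------ classification

@dataclass
class ReadAssignment:
    """A read's amplicon assignment and orientation class.

    The PCR group is a pure function of (mate, strand): mate 1 matching the
    amplicon sense strand (or mate 2 its reverse complement) means the
    template came from PCR-A; the two remaining combinations mean PCR-B.
    """

    read_id: str
    mate: int
    amplicon: str
    strand: str
    q_interval: tuple[int, int]
    r_interval: tuple[int, int]
    score: int
    evalue: float
    mapq: int
    cigar: str
    seg_seq: str  # oriented (reference-sense) aligned query segment
    seg_quals: list[int]
    truth_probe: str | None = None
    truth_pcr: str | None = None

    @property
    def group(self) -> str:
        if (self.mate == 1) == (self.strand == "+"):
            return "A"
        return "B"


@dataclass
class ClassifyStats:
    n_reads: int = 0
    n_stage1_passed: int = 0
    n_assigned: int = 0


def _truth_tags(record: FastqRecord) -> tuple[str | None, str | None]:
    tag = record.tag("XT")
    if tag is None:
        return None, None
    capture_id, _, pcr = tag.rpartition("|")
    probe = capture_id.split(":")[0] if capture_id else None
    return probe, pcr or None


def classify_read(
    record: FastqRecord,
    mate: int,
    insert_aligner: LocalAligner,
    amplicon_aligner: LocalAligner,
    evalue_cutoff: float,
    rng: np.random.Generator,
    stats: ClassifyStats | None = None,
) -> ReadAssignment | None:
    """Two-stage classification of one read; ``None`` means discarded."""
    if stats is not None:
        stats.n_reads += 1
    stage1 = insert_aligner.align(record.seq)
    if not stage1 or stage1[0].evalue > evalue_cutoff:
        return None
    if stats is not None:
        stats.n_stage1_passed += 1
    hits = amplicon_aligner.align(record.seq)
    hits = [h for h in hits if h.evalue <= evalue_cutoff]
    if not hits:
        return None
    best_score = hits[0].score
    top = [h for h in hits if h.score == best_score]
    hit = top[int(rng.integers(0, len(top)))] if len(top) > 1 else top[0]
    if len(top) > 1:
        mapq = 0
    else:
        runner_up = hits[1].score if len(hits) > 1 else 0
        mapq = min(60, 3 * (best_score - max(runner_up, 0)))
    q = record.seq if hit.strand == "+" else revcomp(record.seq)
    quals = record.quals if hit.strand == "+" else record.quals[::-1]
    truth_probe, truth_pcr = _truth_tags(record)
    if stats is not None:
        stats.n_assigned += 1
    return ReadAssignment(
        read_id=record.id, mate=mate, amplicon=hit.ref, strand=hit.strand,
        q_interval=(hit.q_lo, hit.q_hi), r_interval=(hit.r_lo, hit.r_hi),
        score=hit.score, evalue=hit.evalue, mapq=mapq, cigar=hit.cigar,
        seg_seq=q[hit.q_lo : hit.q_hi], seg_quals=quals[hit.q_lo : hit.q_hi],
        truth_probe=truth_probe, truth_pcr=truth_pcr,
    )


def classify_pairs(
    pairs: Sequence[tuple[FastqRecord, FastqRecord]],
    insert_refs: Mapping[str, str],
    amplicon_refs: Mapping[str, str],
    evalue_cutoff: float = 1e-6,
    seed: int = 0,
    k: int = 13,
) -> tuple[list[tuple[ReadAssignment | None, ReadAssignment | None]], ClassifyStats]:
    """Classify every read of every pair; returns assignments plus counters."""
    insert_aligner = LocalAligner(insert_refs, k=k)
    amplicon_aligner = LocalAligner(amplicon_refs, k=k)
    rng = np.random.default_rng(seed)
    stats = ClassifyStats()
    out = []
    for r1, r2 in pairs:
        a1 = classify_read(r1, 1, insert_aligner, amplicon_aligner, evalue_cutoff, rng, stats)
        a2 = classify_read(r2, 2, insert_aligner, amplicon_aligner, evalue_cutoff, rng, stats)
        out.append((a1, a2))
    return out, stats


# ------------------------------------------------------------ group splitting

PLACEHOLDER_LEN = 3


@dataclass
class GroupSplit:
    """The four per-group FASTQ streams plus bookkeeping."""

    r1_a: list[FastqRecord] = field(default_factory=list)
    r2_a: list[FastqRecord] = field(default_factory=list)
    r1_b: list[FastqRecord] = field(default_factory=list)
    r2_b: list[FastqRecord] = field(default_factory=list)
    n_pairs_in: int = 0
    n_pairs_full: int = 0
    n_singletons: int = 0
    n_cross_mated: int = 0
    n_discarded_pairs: int = 0

    def files(self) -> dict[str, list[FastqRecord]]:
        return {
            "R1-PCR-A": self.r1_a, "R2-PCR-A": self.r2_a,
            "R1-PCR-B": self.r1_b, "R2-PCR-B": self.r2_b,
        }


def _placeholder(record: FastqRecord) -> FastqRecord:
    """Three retained nucleotides standing in for a discarded mate."""
    n = PLACEHOLDER_LEN
    return FastqRecord(record.id, record.seq[:n], record.qual[:n], record.desc)


def split_groups(
    assignments: Sequence[tuple[ReadAssignment | None, ReadAssignment | None]],
    pairs: Sequence[tuple[FastqRecord, FastqRecord]],
) -> GroupSplit:
    """Route read pairs to PCR-A/PCR-B file pairs (input order preserved).

    A pair whose mates were assigned to the same amplicon goes intact to its
    group's files.  A read whose mate was discarded is kept as a singleton:
    the mate slot carries a 3 nt placeholder cut from the original mate.
    Mates assigned to different amplicons are both demoted to singletons in
    their own groups.
    """
    split = GroupSplit(n_pairs_in=len(pairs))
    for (a1, a2), (r1, r2) in zip(assignments, pairs, strict=True):
        if a1 is None and a2 is None:
            split.n_discarded_pairs += 1
            continue
        consistent = (
            a1 is not None and a2 is not None
            and a1.amplicon == a2.amplicon and a1.group == a2.group
        )
        if consistent:
            split.n_pairs_full += 1
            if a1.group == "A":
                split.r1_a.append(r1)
                split.r2_a.append(r2)
            else:
                split.r1_b.append(r1)
                split.r2_b.append(r2)
            continue
        if a1 is not None and a2 is not None:
            split.n_cross_mated += 1
        for assignment, keep, other, slot in (
            (a1, r1, r2, 1), (a2, r2, r1, 2),
        ):
            if assignment is None:
                continue
            split.n_singletons += 1
            rec_1 = keep if slot == 1 else _placeholder(other)
            rec_2 = _placeholder(other) if slot == 1 else keep
            if assignment.group == "A":
                split.r1_a.append(rec_1)
                split.r2_a.append(rec_2)
            else:
                split.r1_b.append(rec_1)
                split.r2_b.append(rec_2)
    return split


# ------------------------------------------------------------ coverage & pileup

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class CoverageTable:
    """Per-base depth/alleles over each amplicon's insert, and counts A."""

    depth: dict[str, np.ndarray]
    alleles: dict[str, np.ndarray]  # (insert_len, 5): A C G T other
    indels: dict[tuple[str, int, str], int]
    counts: pd.Series  # per-amplicon read count A
    mask: dict[str, np.ndarray]  # True = column excluded (tiling overlap)
    meta: pd.DataFrame
    mapq_min: int
    baseq_min: int


def _tiling_masks(meta: pd.DataFrame) -> dict[str, np.ndarray]:
    """Mask insert columns where two amplicons overlap genomically."""
    masks = {row.name: np.zeros(row.insert_len, dtype=bool)
             for row in meta.itertuples(index=False)}
    rows = list(meta.itertuples(index=False))
    for i, a in enumerate(rows):
        for b in rows[i + 1 :]:
            if a.contig != b.contig:
                continue
            lo = max(a.start, b.start)
            hi = min(a.end, b.end)
            if lo >= hi:
                continue
            for row in (a, b):
                masks[row.name][lo - row.start : hi - row.start] = True
    return masks


def compute_coverage(
    assignments: Iterable[ReadAssignment],
    panel: PanelReferences,
    mapq_min: int = 30,
    baseq_min: int = 20,
) -> CoverageTable:
    """Pile up assigned reads over insert coordinates.

    Base-quality masking removes bases from the depth/allele pileup but not
    reads from the amplicon count ``A``; the mapping-quality filter removes
    the read from both.  A read counts toward ``A`` when the midpoint of its
    matched interval falls inside the amplicon's insert (excluded tiling
    overlap columns do not count).
    """
    meta = panel.meta.set_index("name", drop=False)
    masks = _tiling_masks(panel.meta)
    depth = {n: np.zeros(int(meta.at[n, "insert_len"]), dtype=int) for n in meta.index}
    alleles = {n: np.zeros((int(meta.at[n, "insert_len"]), 5), dtype=int) for n in meta.index}
    indels: dict[tuple[str, int, str], int] = defaultdict(int)
    counts = pd.Series(0, index=list(meta.index), dtype=int)
    for a in assignments:
        if a is None:
            continue
        if a.amplicon not in meta.index:
            raise KeyError(f"unknown amplicon id {a.amplicon!r}")
        if a.mapq < mapq_min:
            continue
        offset = int(meta.at[a.amplicon, "insert_offset"])
        ins_len = int(meta.at[a.amplicon, "insert_len"])
        mask = masks[a.amplicon]
        mid = (a.r_interval[0] + a.r_interval[1]) // 2 - offset
        if 0 <= mid < ins_len and not mask[mid]:
            counts[a.amplicon] += 1
        rpos = a.r_interval[0]
        qpos = 0
        dep = depth[a.amplicon]
        allele = alleles[a.amplicon]
        for count, op in _CIGAR_RE.findall(a.cigar):
            count = int(count)
            if op in "=XM":
                for j in range(count):
                    ipos = rpos + j - offset
                    if 0 <= ipos < ins_len and not mask[ipos]:
                        if a.seg_quals[qpos + j] >= baseq_min:
                            dep[ipos] += 1
                            allele[ipos, _BASE_INDEX.get(a.seg_seq[qpos + j], 4)] += 1
                rpos += count
                qpos += count
            elif op == "I":
                ipos = rpos - 1 - offset
                if 0 <= ipos < ins_len and not mask[ipos]:
                    indels[(a.amplicon, ipos, f"I:{a.seg_seq[qpos:qpos + count]}")] += 1
                qpos += count
            elif op == "D":
                ipos = rpos - 1 - offset
                if 0 <= ipos < ins_len and not mask[ipos]:
                    indels[(a.amplicon, ipos, f"D:{count}")] += 1
                rpos += count
    return CoverageTable(
        depth=depth, alleles=alleles, indels=dict(indels), counts=counts,
        mask=masks, meta=panel.meta, mapq_min=mapq_min, baseq_min=baseq_min,
    )


# ------------------------------------------------------------ genotyping

@dataclass
class VariantCall:
    contig: str
    pos: int  # genomic, 0-based
    ref: str
    alt: str
    genotype: str  # 'het' | 'hom'
    depth: int
    alt_fraction: float
    amplicon: str


def call_variants(
    coverage: CoverageTable,
    insert_refs: Mapping[str, str],
    min_depth: int = 20,
    het_band: tuple[float, float] = (0.25, 0.75),
    hom_threshold: float = 0.85,
) -> list[VariantCall]:
    """Frequency-threshold genotyper over the insert pileup.

    A site with filtered depth >= ``min_depth`` is called homozygous when
    the top non-reference allele fraction reaches ``hom_threshold``,
    heterozygous when it falls inside ``het_band``, otherwise not called.
    Simple single-read indel events are called with the same thresholds.
    """
    meta = coverage.meta.set_index("name")
    calls: list[VariantCall] = []
    for name, allele in coverage.alleles.items():
        insert = insert_refs[name]
        contig = meta.at[name, "contig"]
        start = int(meta.at[name, "start"])
        dep = coverage.depth[name]
        for pos in np.nonzero(dep >= min_depth)[0]:
            ref_base = insert[pos]
            counts = allele[pos]
            ref_idx = _BASE_INDEX.get(ref_base, 4)
            alt_idx = max(
                (i for i in range(4) if i != ref_idx),
                key=lambda i: counts[i],
            )
            frac = counts[alt_idx] / dep[pos]
            genotype = None
            if frac >= hom_threshold:
                genotype = "hom"
            elif het_band[0] <= frac <= het_band[1]:
                genotype = "het"
            if genotype:
                calls.append(
                    VariantCall(
                        contig, start + int(pos), ref_base, "ACGT"[alt_idx],
                        genotype, int(dep[pos]), float(frac), name,
                    )
                )
    for (name, pos, desc), count in coverage.indels.items():
        dep = coverage.depth[name]
        if pos < 0 or pos >= len(dep) or dep[pos] < min_depth:
            continue
        frac = count / dep[pos]
        genotype = None
        if frac >= hom_threshold:
            genotype = "hom"
        elif het_band[0] <= frac <= het_band[1]:
            genotype = "het"
        if not genotype:
            continue
        insert = insert_refs[name]
        contig = coverage.meta.set_index("name").at[name, "contig"]
        start = int(coverage.meta.set_index("name").at[name, "start"])
        if desc.startswith("D:"):
            length = int(desc[2:])
            ref_allele = insert[pos : pos + length + 1]
            alt_allele = insert[pos]
        else:
            ref_allele = insert[pos]
            alt_allele = insert[pos] + desc[2:]
        calls.append(
            VariantCall(
                contig, start + int(pos), ref_allele, alt_allele,
                genotype, int(dep[pos]), float(frac), name,
            )
        )
    calls.sort(key=lambda c: (c.contig, c.pos))
    return calls


# ------------------------------------------------------------ metrics

def uniformity(counts: Sequence[float], fold: float) -> float:
    """Largest fraction of amplicons inside a multiplicative window.

    The window ``[c, fold * c]`` is swept over all observed positive counts;
    zero-count amplicons stay in the denominator but can never be inside a
    window.  ``fold`` must exceed 1.
    """
    if fold <= 1:
        raise ValueError("fold-range width must exceed 1")
    values = np.asarray(counts, dtype=float)
    if len(values) == 0:
        return float("nan")
    best = 0
    for c in np.unique(values[values > 0]):
        best = max(best, int(np.sum((values >= c) & (values <= fold * c))))
    return best / len(values)


def capture_metrics(
    coverage: CoverageTable,
    stats: ClassifyStats,
    assignments: Sequence[ReadAssignment | None] = (),
    truth_variants: pd.DataFrame | None = None,
    calls: Sequence[VariantCall] = (),
    other_counts: pd.Series | None = None,
    depth_threshold: int = 20,
    fold_widths: Sequence[float] = (50, 100),
    min_depth: int = 20,
) -> dict:
    """Panel performance metrics, percentages on the 0-100 scale.

    sensitivity: percent of (unmasked) target bases at or above a depth
    threshold, reported at 1x, at ``depth_threshold`` and at a
    mean-relative threshold (1.2 % of mean depth).  specificity: percent of
    filter-passed reads assigned to their intended amplicon (ground-truth
    tags) or, lacking truth, assigned at all.  uniformity: largest percent
    of amplicons within a multiplicative fold window.  concordance: percent
    of adequately covered truth SNVs whose called genotype matches.
    rank-order correlation: Spearman between two samples' amplicon counts.
    """
    all_depth = np.concatenate(
        [coverage.depth[n][~coverage.mask[n]] for n in coverage.depth]
    )
    mean_depth = float(all_depth.mean()) if len(all_depth) else float("nan")
    metrics: dict = {
        "mean_depth": mean_depth,
        "sensitivity_1x": 100.0 * float(np.mean(all_depth >= 1)),
        f"sensitivity_{depth_threshold}x": 100.0 * float(np.mean(all_depth >= depth_threshold)),
        "sensitivity_mean_relative": 100.0
        * float(np.mean(all_depth >= 0.012 * mean_depth)),
    }
    flat = [a for a in assignments if a is not None]
    with_truth = [a for a in flat if a.truth_probe is not None]
    if stats.n_stage1_passed:
        if with_truth:
            on_target = sum(a.amplicon == a.truth_probe for a in with_truth)
            metrics["specificity"] = 100.0 * on_target / stats.n_stage1_passed
        else:
            metrics["specificity"] = 100.0 * stats.n_assigned / stats.n_stage1_passed
    else:
        metrics["specificity"] = float("nan")
    for fold in fold_widths:
        metrics[f"uniformity_{int(fold)}fold"] = 100.0 * uniformity(
            coverage.counts.to_numpy(), fold
        )
    if truth_variants is not None:
        meta = coverage.meta
        call_index = {(c.contig, c.pos): c for c in calls}
        n_eval = n_concordant = 0
        snvs = truth_variants[truth_variants.type == "snv"]
        for row in snvs.itertuples():
            covered = False
            for amp in meta.itertuples(index=False):
                if amp.contig == row.contig and amp.start <= row.pos < amp.end:
                    ipos = row.pos - amp.start
                    if (
                        not coverage.mask[amp.name][ipos]
                        and coverage.depth[amp.name][ipos] >= min_depth
                    ):
                        covered = True
                    break
            if not covered:
                continue
            n_eval += 1
            call = call_index.get((row.contig, row.pos))
            if call is not None and call.alt == row.alt and call.genotype == row.genotype:
                n_concordant += 1
        metrics["concordance"] = (
            100.0 * n_concordant / n_eval if n_eval else float("nan")
        )
        metrics["concordance_n"] = n_eval
    if other_counts is not None:
        shared = coverage.counts.index.intersection(other_counts.index)
        x = coverage.counts.loc[shared].to_numpy(dtype=float)
        y = other_counts.loc[shared].to_numpy(dtype=float)
        if np.array_equal(x, y):  # identical tables: perfect rank agreement
            rho = 1.0
        else:
            rho = sps.spearmanr(x, y).statistic
        metrics["spearman_r"] = float(rho)
    return metrics
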
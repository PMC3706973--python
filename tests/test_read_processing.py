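"""Demultiplexing, classification, group splitting, coverage and genotyping."""

import numpy as np
import pandas as pd
import pytest

from clpp.io import FastqRecord, phred_string
from clpp.probe_design import build_references, design_panel
from clpp.read_processing import (
    ClassifyStats,
    DemultiplexError,
    LocalAligner,
    call_variants,
    capture_metrics,
    classify_pairs,
    classify_read,
    compute_coverage,
    demultiplex,
    split_groups,
    uniformity,
)
from clpp.sequence_model import GenomicInterval, revcomp
from clpp import config as cfg


def _pair(seq1="ACGT" * 10, seq2="TTTT" * 10, index="AAAAAA", name="r1"):
    q = phred_string([38] * len(seq1))
    q2 = phred_string([38] * len(seq2))
    return (
        FastqRecord(name, seq1, q, f"BC:{index}"),
        FastqRecord(name, seq2, q2, f"BC:{index}"),
    )


# ------------------------------------------------------------ demultiplex

def test_demultiplex_exact_and_mismatched_indexes():
    table = {"s1": "AAAAAA", "s2": "CCCCCC"}
    pairs = [
        _pair(index="AAAAAA", name="a"),
        _pair(index="AACAAA", name="b"),  # 1 mismatch
        _pair(index="GGGGGG", name="c"),
    ]
    strict = demultiplex(pairs, table, max_mismatch=0)
    assert [p[0].id for p in strict["s1"]] == ["a"]
    assert [p[0].id for p in strict["undetermined"]] == ["b", "c"]
    relaxed = demultiplex(pairs, table, max_mismatch=1)
    assert [p[0].id for p in relaxed["s1"]] == ["a", "b"]


def test_demultiplex_ambiguity_goes_to_undetermined():
    table = {"s1": "AAAAAA", "s2": "AAAATT"}
    pairs = [_pair(index="AAAAAT", name="amb")]  # within 2 of both
    out = demultiplex(pairs, table, max_mismatch=2)
    assert [p[0].id for p in out["undetermined"]] == ["amb"]


def test_demultiplex_duplicate_index_is_an_error():
    with pytest.raises(DemultiplexError):
        demultiplex([], {"s1": "AAAAAA", "s2": "AAAAAA"})


# ------------------------------------------------------------ classification

def test_classification_recovers_truth_on_noiseless_reads(
    noiseless_pairs, small_references
):
    assignments, stats = classify_pairs(
        noiseless_pairs,
        dict(small_references.inserts),
        dict(small_references.amplicons),
        seed=0,
    )
    assert stats.n_reads == 2 * len(noiseless_pairs)
    assert stats.n_assigned == stats.n_reads  # nothing lost in-model
    for a1, a2 in assignments:
        for a in (a1, a2):
            assert a.amplicon == a.truth_probe
            assert a.group == a.truth_pcr
        assert a1.group == a2.group


def test_adaptor_only_read_is_discarded_at_stage_one(small_references):
    junk = cfg.P5 + cfg.LINK_F + cfg.READ1_EXT + revcomp(cfg.LINK_R) + cfg.P7
    rec = FastqRecord("junk", junk, phred_string([38] * len(junk)))
    aligner_ins = LocalAligner(dict(small_references.inserts))
    aligner_amp = LocalAligner(dict(small_references.amplicons))
    assignment = classify_read(
        rec, 1, aligner_ins, aligner_amp, 1e-6, np.random.default_rng(0)
    )
    assert assignment is None


def test_short_random_read_fails_evalue_cutoff(small_references):
    rec = FastqRecord("tiny", "ACGTACGTACGTAC", phred_string([38] * 14))
    aligner_ins = LocalAligner(dict(small_references.inserts))
    aligner_amp = LocalAligner(dict(small_references.amplicons))
    assignment = classify_read(
        rec, 1, aligner_ins, aligner_amp, 1e-6, np.random.default_rng(0)
    )
    assert assignment is None


def _tie_refs():
    rng = np.random.default_rng(99)
    seq = "".join(rng.choice(list("ACGT"), size=120))
    return {"amp1": seq, "amp2": seq}, seq


def test_score_ties_break_deterministically_per_seed():
    refs, seq = _tie_refs()
    read = FastqRecord("r", seq[10:90], phred_string([38] * 80))
    picks = set()
    for _ in range(3):
        assignments, _ = classify_pairs(
            [(read, read)], refs, refs, seed=5
        )
        picks.add(assignments[0][0].amplicon)
    assert len(picks) == 1  # same seed, same choice
    assert assignments[0][0].mapq == 0  # ambiguous hit


def test_score_ties_split_evenly_across_seeds():
    refs, seq = _tie_refs()
    read = FastqRecord("r", seq[10:90], phred_string([38] * 80))
    aligner = LocalAligner(refs)
    counts = {"amp1": 0, "amp2": 0}
    n = 1000
    for seed in range(n):
        a = classify_read(
            read, 1, aligner, aligner, 1e-6, np.random.default_rng(seed)
        )
        counts[a.amplicon] += 1
    # binomial tolerance: 4 sigma around n/2
    assert abs(counts["amp1"] - n / 2) < 4 * np.sqrt(n * 0.25)


def test_read_with_planted_indel_still_assigned(small_references):
    name, insert = small_references.inserts[0]
    read_seq = insert[10:60] + insert[64:130]  # 4 bp deletion
    rec = FastqRecord("d", read_seq, phred_string([38] * len(read_seq)))
    aligner_ins = LocalAligner(dict(small_references.inserts))
    aligner_amp = LocalAligner(dict(small_references.amplicons))
    a = classify_read(rec, 1, aligner_ins, aligner_amp, 1e-6, np.random.default_rng(0))
    assert a is not None and a.amplicon == name
    assert "D" in a.cigar


# ------------------------------------------------------------ group splitting

def test_split_groups_routes_and_conserves(noiseless_pairs, small_references):
    assignments, _ = classify_pairs(
        noiseless_pairs,
        dict(small_references.inserts),
        dict(small_references.amplicons),
        seed=0,
    )
    split = split_groups(assignments, noiseless_pairs)
    assert split.n_pairs_full == len(noiseless_pairs)
    assert split.n_singletons == split.n_discarded_pairs == 0
    assert len(split.r1_a) == len(split.r2_a)
    assert len(split.r1_a) + len(split.r1_b) == len(noiseless_pairs)
    # groups contain only their own PCR's reads (truth tags)
    assert all(r.tag("XT").endswith("|A") for r in split.r1_a)
    assert all(r.tag("XT").endswith("|B") for r in split.r1_b)


def test_singleton_mate_becomes_three_base_placeholder(
    noiseless_pairs, small_references
):
    r1, r2 = noiseless_pairs[0]
    junk = FastqRecord(r2.id, "ACGT" * 10, phred_string([38] * 40), r2.desc)
    assignments, _ = classify_pairs(
        [(r1, junk)],
        dict(small_references.inserts),
        dict(small_references.amplicons),
        seed=0,
    )
    assert assignments[0][1] is None
    split = split_groups(assignments, [(r1, junk)])
    assert split.n_singletons == 1
    group = split.files()[f"R2-PCR-{assignments[0][0].group}"]
    assert len(group) == 1
    placeholder = group[0]
    assert placeholder.seq == junk.seq[:3]
    assert len(placeholder.seq) == len(placeholder.qual) == 3


def test_fully_discarded_pair_counts_as_discarded(small_references):
    junk1 = FastqRecord("x", "A" * 40, phred_string([38] * 40))
    junk2 = FastqRecord("x", "C" * 40, phred_string([38] * 40))
    assignments, _ = classify_pairs(
        [(junk1, junk2)],
        dict(small_references.inserts),
        dict(small_references.amplicons),
        seed=0,
    )
    split = split_groups(assignments, [(junk1, junk2)])
    assert split.n_discarded_pairs == 1
    assert all(not records for records in split.files().values())


# ------------------------------------------------------------ coverage

@pytest.fixture(scope="module")
def single_amp_panel():
    rng = np.random.default_rng(77)
    ref = {"chr9": "".join(rng.choice(list("ACGT"), size=1200))}
    designs, report = design_panel(ref, [GenomicInterval("chr9", 400, 600, "A1")])
    assert list(report.status) == ["ok"]
    return build_references(designs), designs


def _assignment_for(panel, start, length, quals=38, mate=1, strand="+", mapq=60):
    from clpp.read_processing import ReadAssignment

    name, amplicon = panel.amplicons[0]
    offset = int(panel.meta.insert_offset.iloc[0])
    r_lo = offset + start
    seq = amplicon[r_lo : r_lo + length]
    return ReadAssignment(
        read_id="t", mate=mate, amplicon=name, strand=strand,
        q_interval=(0, length), r_interval=(r_lo, r_lo + length),
        score=length, evalue=0.0, mapq=mapq, cigar=f"{length}=",
        seg_seq=seq, seg_quals=[quals] * length,
    )


def test_single_perfect_read_coverage(single_amp_panel):
    panel, _ = single_amp_panel
    a = _assignment_for(panel, start=20, length=100)
    cov = compute_coverage([a], panel)
    depth = cov.depth["A1"]
    assert int(depth.sum()) == 100
    assert (depth[20:120] == 1).all()
    assert cov.counts["A1"] == 1


def test_low_base_quality_masks_depth_but_not_count(single_amp_panel):
    panel, _ = single_amp_panel
    a = _assignment_for(panel, start=20, length=100, quals=10)
    cov = compute_coverage([a], panel, baseq_min=20)
    assert int(cov.depth["A1"].sum()) == 0
    assert cov.counts["A1"] == 1  # read counted, bases masked


def test_low_mapq_read_is_fully_excluded(single_amp_panel):
    panel, _ = single_amp_panel
    a = _assignment_for(panel, start=20, length=100, mapq=0)
    cov = compute_coverage([a], panel, mapq_min=30)
    assert int(cov.depth["A1"].sum()) == 0
    assert cov.counts["A1"] == 0


def test_unknown_amplicon_is_an_error(single_amp_panel):
    panel, _ = single_amp_panel
    a = _assignment_for(panel, start=0, length=50)
    a.amplicon = "nope"
    with pytest.raises(KeyError):
        compute_coverage([a], panel)


def test_tiled_overlap_columns_excluded_from_both():
    rng = np.random.default_rng(123)
    ref = {"c": "".join(rng.choice(list("ACGT"), size=2400))}
    targets = [GenomicInterval("c", 400, 1100, "big")]  # tiles into 2 with 50 overlap
    designs, report = design_panel(ref, targets)
    assert len(designs) == 2
    panel = build_references(designs)
    masked = {name: int(mask.sum()) for name, mask in
              compute_coverage([], panel).mask.items()}
    assert all(v == 50 for v in masked.values())


# ------------------------------------------------------------ genotyping

def _pileup_panel_and_cov(alt_count, depth_total, min_depth=20):
    rng = np.random.default_rng(55)
    ref = {"chrV": "".join(rng.choice(list("ACGT"), size=1200))}
    designs, _ = design_panel(ref, [GenomicInterval("chrV", 400, 600, "V1")])
    panel = build_references(designs)
    insert = dict(panel.inserts)["V1"]
    pos = 50
    ref_base = insert[pos]
    alt_base = "A" if ref_base != "A" else "C"
    assignments = []
    from clpp.read_processing import ReadAssignment

    offset = int(panel.meta.insert_offset.iloc[0])
    for i in range(depth_total):
        base = alt_base if i < alt_count else ref_base
        seq = insert[pos - 10 : pos] + base + insert[pos + 1 : pos + 11]
        assignments.append(
            ReadAssignment(
                read_id=f"r{i}", mate=1, amplicon="V1", strand="+",
                q_interval=(0, 21),
                r_interval=(offset + pos - 10, offset + pos + 11),
                score=21, evalue=0.0, mapq=60, cigar="21=",
                seg_seq=seq, seg_quals=[38] * 21,
            )
        )
    cov = compute_coverage(assignments, panel)
    calls = call_variants(cov, dict(panel.inserts), min_depth=min_depth)
    genomic_pos = 400 + pos
    return [c for c in calls if c.pos == genomic_pos], ref_base, alt_base


@pytest.mark.parametrize(
    "alt,total,expected",
    [
        (30, 30, "hom"),
        (19, 40, "het"),  # fraction 0.475
        (3, 40, None),  # below het band
        (12, 12, None),  # depth below threshold
    ],
)
def test_frequency_threshold_genotyper(alt, total, expected):
    calls, ref_base, alt_base = _pileup_panel_and_cov(alt, total)
    if expected is None:
        assert calls == []
    else:
        (call,) = calls
        assert call.genotype == expected
        assert call.ref == ref_base and call.alt == alt_base
        assert call.depth == total


# ------------------------------------------------------------ metrics

def test_uniformity_window_sweep_oracle():
    assert uniformity([10, 20, 400, 600], 50) == pytest.approx(0.75)
    assert uniformity([10, 10, 10], 50) == 1.0
    assert uniformity([0, 10], 50) == 0.5  # zero can never be in a window
    with pytest.raises(ValueError):
        uniformity([1, 2], 1.0)


def test_uniformity_matches_exhaustive_sweep():
    rng = np.random.default_rng(8)
    counts = rng.integers(0, 5000, size=60)
    fold = 50
    best = 0
    for c in counts[counts > 0]:
        best = max(best, int(((counts >= c) & (counts <= fold * c)).sum()))
    assert uniformity(counts, fold) == pytest.approx(best / len(counts))


def test_identical_count_tables_have_perfect_rank_correlation(
    noiseless_pairs, small_references
):
    assignments, stats = classify_pairs(
        noiseless_pairs,
        dict(small_references.inserts),
        dict(small_references.amplicons),
        seed=0,
    )
    flat = [a for p in assignments for a in p if a]
    cov = compute_coverage(flat, small_references)
    metrics = capture_metrics(cov, stats, flat, other_counts=cov.counts)
    assert metrics["spearman_r"] == pytest.approx(1.0)
    assert metrics["specificity"] == pytest.approx(100.0)
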
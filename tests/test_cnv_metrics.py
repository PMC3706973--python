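"""Copy-number normalization, smoothing, QC bins and threshold calls."""

import numpy as np
import pandas as pd
import pytest

from clpp.capture_simulator import (
    CaptureModel,
    CnvSegment,
    GenomeSpec,
    generate_genome,
    simulate_capture,
)
from clpp.cnv_metrics import (
    binned_logratio_sd,
    call_cnv,
    lowess_smooth,
    median_combine,
    scale_normalize,
)
from clpp.probe_design import design_panel
from clpp.sequence_model import GenomicInterval


def _series(values, prefix="a"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


# ------------------------------------------------------------ normalization

def test_identical_tables_give_unit_ratios():
    counts = _series([10, 20, 30, 40])
    assert np.allclose(scale_normalize(counts, counts), 1.0)


def test_scale_invariance():
    counts = _series([10, 20, 30, 40])
    assert np.allclose(scale_normalize(2 * counts, counts), 1.0)
    assert np.allclose(scale_normalize(counts, 7 * counts), 1.0)


def test_single_doubled_amplicon_approaches_two():
    n = 200
    base = _series([100] * n)
    test = base.copy()
    test.iloc[0] = 200
    ratios = scale_normalize(test, base)
    assert ratios.iloc[0] == pytest.approx(2.0, rel=0.01)
    assert ratios.iloc[1] == pytest.approx(1.0, rel=0.01)


def test_zero_reference_count_flagged_nan():
    test = _series([10, 20])
    ref = _series([10, 0])
    ratios = scale_normalize(test, ref)
    assert np.isnan(ratios.iloc[1]) and not np.isnan(ratios.iloc[0])


def test_disjoint_amplicon_sets_error():
    with pytest.raises(ValueError):
        scale_normalize(_series([1, 2], "x"), _series([1, 2], "y"))


# ------------------------------------------------------------ median combine

def test_median_combine_rules():
    t1 = _series([1.0, 1.0, np.nan])
    t2 = _series([1.5, np.nan, np.nan])
    t3 = _series([2.0, np.nan, np.nan])
    combined = median_combine([t1, t2, t3])
    assert combined.iloc[0] == 1.5
    assert combined.iloc[1] == 1.0  # NA excluded
    assert np.isnan(combined.iloc[2])  # missing everywhere stays flagged
    # identity on a single table, permutation invariance
    assert median_combine([t1]).equals(t1)
    assert median_combine([t3, t1, t2]).equals(combined)
    # idempotent
    assert median_combine([combined, combined]).equals(combined)


# ------------------------------------------------------------ lowess

def _naive_tricube_lowess(y, x, frac):
    """Independent local linear regression with tricube weights."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    k = max(2, int(np.ceil(frac * n)))
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d)[:k]
        h = d[idx].max()
        w = (1 - (d[idx] / h) ** 3) ** 3 if h > 0 else np.ones(k)
        X = np.vstack([np.ones(k), x[idx] - x[i]]).T
        beta = np.linalg.lstsq((X.T * w) @ X, (X.T * w) @ y[idx], rcond=None)[0]
        out[i] = beta[0]
    return out


def test_lowess_constant_input_is_constant():
    out = lowess_smooth([1.3] * 30, np.arange(30))
    assert np.allclose(out, 1.3)


def test_lowess_frac_one_recovers_linear_trend():
    x = np.arange(50, dtype=float)
    y = 0.5 + 0.01 * x
    assert np.allclose(lowess_smooth(y, x, frac=1.0), y, atol=1e-8)


def test_lowess_step_transition_matches_reference_implementation():
    rng = np.random.default_rng(0)
    x = np.arange(100, dtype=float)
    y = np.where(x < 50, 1.0, 1.5) + rng.normal(0, 0.02, size=100)
    smoothed = lowess_smooth(y, x, frac=0.3)
    reference = _naive_tricube_lowess(y, x, frac=0.3)
    # plateaus agree with the independent implementation
    assert np.allclose(smoothed[10:35], reference[10:35], atol=0.05)
    assert np.allclose(smoothed[65:90], reference[65:90], atol=0.05)
    # transition is monotone across the breakpoint
    mid = smoothed[40:60]
    assert np.all(np.diff(mid) > -1e-6)
    assert smoothed[:30].mean() == pytest.approx(1.0, abs=0.05)
    assert smoothed[70:].mean() == pytest.approx(1.5, abs=0.05)


def test_lowess_passthrough_below_three_points():
    with pytest.warns(UserWarning):
        out = lowess_smooth([1.0, 2.0], [0, 1])
    assert list(out) == [1.0, 2.0]


# ------------------------------------------------------------ binned SD

def test_binned_sd_zero_for_identical_samples():
    counts = _series(np.arange(1, 401))
    ratios = scale_normalize(counts, counts)
    table = binned_logratio_sd(ratios, counts, bin_size=200)
    assert len(table) == 2
    assert np.allclose(table.sd_log2, 0.0)


def test_binned_sd_recovers_generative_sigma():
    rng = np.random.default_rng(1)
    sigma = 0.3
    ratios = _series(2 ** rng.normal(0, sigma, size=400))
    cov = _series(np.full(400, 100.0))
    table = binned_logratio_sd(ratios, cov, bin_size=400)
    assert table.sd_log2.iloc[0] == pytest.approx(sigma, rel=0.15)


def test_binned_sd_partition_arithmetic():
    ratios = _series(np.ones(450))
    cov = _series(np.arange(450, dtype=float))
    table = binned_logratio_sd(ratios, cov, bin_size=200)
    assert list(table.n) == [200, 200, 50]
    with pytest.raises(ValueError):
        binned_logratio_sd(ratios, cov, bin_size=1)


def test_binned_sd_decreases_with_poisson_coverage():
    """Counting noise shrinks log-ratio spread as coverage grows."""
    rng = np.random.default_rng(2)
    means = np.repeat([30, 120, 500, 2000], 200).astype(float)
    test = rng.poisson(means)
    ref = rng.poisson(means)
    ratios = pd.Series(
        (test / test.sum()) / (ref / ref.sum()),
        index=[f"a{i}" for i in range(len(means))],
    )
    cov = pd.Series(ref.astype(float), index=ratios.index)
    table = binned_logratio_sd(ratios, cov, bin_size=200)
    sds = table.sort_values("median_coverage").sd_log2.to_numpy()
    assert np.all(np.diff(sds) < 0)


# ------------------------------------------------------------ CNV calls

def _meta(n, contig="chr1", start=0, spacing=1000):
    return pd.DataFrame(
        {
            "name": [f"{contig}_t{i}" for i in range(n)],
            "contig": contig,
            "start": [start + i * spacing for i in range(n)],
            "end": [start + i * spacing + 200 for i in range(n)],
        }
    )


def test_neutral_ratios_give_no_calls():
    meta = _meta(20)
    ratios = pd.Series(1.0, index=meta.name)
    assert call_cnv(ratios, meta) == []
    with pytest.raises(ValueError):
        call_cnv(ratios, meta, loss_max=1.5, gain_min=1.35)


def test_focal_loss_run_merging():
    meta = _meta(20)
    ratios = pd.Series(1.0, index=list(meta.name))
    ratios.iloc[5:9] = 0.45
    (call,) = call_cnv(ratios, meta)
    assert call.state == "loss"
    assert call.amplicons == list(meta.name[5:9])
    assert call.mean_ratio == pytest.approx(0.45)
    # a single-amplicon dip is below min_consecutive
    solo = pd.Series(1.0, index=list(meta.name))
    solo.iloc[3] = 0.4
    assert call_cnv(solo, meta) == []


def test_ploidy_table_rescales_male_x_expectation():
    meta = _meta(10, contig="chrX")
    # male X: baseline single copy vs diploid reference -> raw ratio 0.5
    ratios = pd.Series(0.5, index=list(meta.name))
    assert call_cnv(ratios, meta, ploidy={"chrX": 1}) == []
    deleted = ratios.copy()
    deleted.iloc[2:6] = 0.0
    (call,) = call_cnv(deleted, meta, ploidy={"chrX": 1})
    assert call.state == "loss" and len(call.amplicons) == 4


def _capture_counts(genome, designs, seed):
    # ~800 filtered counts per diploid amplicon, inside the coverage range
    # targeted panels typically reach (2^8 to 2^12 reads per amplicon)
    caps = simulate_capture(
        genome, designs, CaptureModel(p0=0.9, molecules_per_copy=200), seed
    )
    counts = pd.Series(0, index=[d.name for d in designs], dtype=int)
    for c in caps:
        counts[c.probe] += 1
    return counts


@pytest.mark.parametrize("seed", range(5))
def test_trisomy_and_hemizygous_deletion_recovery(seed):
    """Whole-contig trisomy and a 9-of-10-exon loss recovered across seeds.

    Two test samples against one diploid reference sample, as in a clinical
    panel run: one sample carries a whole-contig trisomy on a contig with a
    small share of the panel; the other is a male (single X copy) missing 9
    of the 10 exons of an X-linked gene.
    """
    contigs = {"chrA": 44_000, "chr13": 5_000, "chrX": 14_000}
    targets = [
        GenomicInterval("chrA", 500 + i * 1400, 700 + i * 1400, f"A{i}")
        for i in range(30)
    ]
    targets += [
        GenomicInterval("chr13", 500 + i * 1400, 700 + i * 1400, f"T{i}")
        for i in range(3)
    ]
    exons = [
        GenomicInterval("chrX", 500 + i * 1300, 680 + i * 1300, f"OTC{i}")
        for i in range(10)
    ]
    targets += exons
    deleted = exons[1:]  # 9 of 10 exons lost

    ref_genome = generate_genome(GenomeSpec(contigs), seed=700 + seed)
    designs, report = design_panel(ref_genome.reference, targets)
    designed = set(report.query("status == 'ok'")["name"])
    assert len(designed) >= 35  # a few targets may fail on random references

    tri_spec = GenomeSpec(
        contigs, cnv_segments=[CnvSegment("chr13", None, None, (2, 1))]
    )
    otc_spec = GenomeSpec(
        contigs,
        cnv_segments=[CnvSegment("chrX", None, None, (1, 0))]  # male X
        + [CnvSegment("chrX", e.start, e.end, (0, 0)) for e in deleted],
    )
    # same reference sequences, different copy structures
    tri_genome = generate_genome(tri_spec, seed=700 + seed)
    otc_genome = generate_genome(otc_spec, seed=700 + seed)
    assert tri_genome.reference == ref_genome.reference

    ref_counts = _capture_counts(ref_genome, designs, seed=20 + seed)
    tri_combined = median_combine(
        [scale_normalize(_capture_counts(tri_genome, designs, seed=10 + seed), ref_counts)]
    )
    otc_combined = median_combine(
        [scale_normalize(_capture_counts(otc_genome, designs, seed=30 + seed), ref_counts)]
    )

    meta = pd.DataFrame(
        {
            "name": [d.name for d in designs],
            "contig": [d.target.contig for d in designs],
            "start": [d.target.start for d in designs],
            "end": [d.target.end for d in designs],
        }
    )
    tri_names = [d.name for d in designs if d.target.contig == "chr13"]
    del_names = [d.name for d in designs if d.name in {e.name for e in deleted}]
    assert len(tri_names) >= 2 and len(del_names) >= 7
    assert 1.4 <= tri_combined[tri_names].mean() <= 1.6
    assert otc_combined[del_names].max() <= 0.15

    gains = [
        c for c in call_cnv(tri_combined, meta)
        if c.state == "gain" and c.contig == "chr13"
    ]
    assert gains and set(tri_names) == set(sum((c.amplicons for c in gains), []))
    losses = [
        c for c in call_cnv(otc_combined, meta, ploidy={"chrX": 1})
        if c.state == "loss" and c.contig == "chrX"
    ]
    assert losses
    lost = set(sum((c.amplicons for c in losses), []))
    assert lost == set(del_names)
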
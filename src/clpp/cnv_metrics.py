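"""Read-depth copy-number analysis over amplicon counts.

The raw statistic is the per-amplicon filtered read count ``A``.  Within a
sample and a single PCR, counts are scale-normalized against a reference
sample (library-size scaling followed by a per-amplicon ratio), medians are
taken across PCRs/repeats, a lowess curve is drawn for visualization, and
threshold rules over the combined ratios produce loss/gain calls.  At a
diploid baseline a heterozygous (single-copy) loss is expected at ratio
0.5, a trisomy at 1.5; the default thresholds 0.7 / 1.35 sit midway
between integer copy states.  Smoothing is presentation-only: calls use
the unsmoothed combined ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess


def scale_normalize(test_counts: pd.Series, ref_counts: pd.Series) -> pd.Series:
    """Per-amplicon ratio of library-size-scaled counts, test vs reference.

    ``ratio_i = (A_test,i / T_test) / (A_ref,i / T_ref)`` with ``T`` the
    total count of each sample.  Amplicons with zero reference count get
    ``NaN`` (flagged, excluded downstream).  Invariant to rescaling either
    sample by a positive constant.
    """
    shared = test_counts.index.intersection(ref_counts.index)
    if len(shared) == 0:
        raise ValueError("test and reference amplicon sets are disjoint")
    test = test_counts.loc[shared].astype(float)
    ref = ref_counts.loc[shared].astype(float)
    t_test, t_ref = test.sum(), ref.sum()
    if t_test == 0 or t_ref == 0:
        raise ValueError("a sample has zero total count")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (test / t_test) / (ref / t_ref)
    ratio[ref == 0] = np.nan
    return ratio


def median_combine(ratio_tables: Sequence[pd.Series]) -> pd.Series:
    """Per-amplicon median over available (non-NaN) ratios.

    Idempotent and permutation-invariant; an amplicon missing (or NaN) in
    every table stays NaN.
    """
    if not ratio_tables:
        raise ValueError("need at least one ratio table")
    frame = pd.concat(ratio_tables, axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        return frame.median(axis=1, skipna=True)


def lowess_smooth(
    ratios: Sequence[float], positions: Sequence[float], frac: float = 0.3
) -> np.ndarray:
    """Locally weighted regression of ratios over genomic order.

    Output has the same length and order as the input.  With fewer than
    three points the input is passed through with a warning.
    """
    ratios = np.asarray(ratios, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if len(ratios) != len(positions):
        raise ValueError("ratios and positions must have equal length")
    if len(ratios) < 3:
        warnings.warn("fewer than 3 points: lowess passthrough", stacklevel=2)
        return ratios.copy()
    return _sm_lowess(ratios, positions, frac=frac, return_sorted=False)


def binned_logratio_sd(
    ratios: pd.Series, ref_coverages: pd.Series, bin_size: int = 200
) -> pd.DataFrame:
    """SD of log2 ratios in bins of amplicons with similar coverage.

    Amplicons are sorted by reference coverage and grouped into consecutive
    bins of ``bin_size`` (the last bin may be smaller).  Nonpositive or NaN
    ratios are excluded before binning.  Returns one row per bin with the
    bin's median coverage and the SD of log2 ratios.
    """
    if bin_size < 2:
        raise ValueError("bin_size must be at least 2")
    shared = ratios.index.intersection(ref_coverages.index)
    ratio = ratios.loc[shared]
    cov = ref_coverages.loc[shared].astype(float)
    keep = ratio.notna() & (ratio > 0)
    ratio, cov = ratio[keep], cov[keep]
    order = cov.sort_values(kind="stable").index
    rows = []
    for b, start in enumerate(range(0, len(order), bin_size)):
        idx = order[start : start + bin_size]
        logr = np.log2(ratio.loc[idx].to_numpy())
        rows.append(
            {
                "bin": b,
                "n": len(idx),
                "median_coverage": float(cov.loc[idx].median()),
                "sd_log2": float(np.std(logr, ddof=1)) if len(idx) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CnvCall:
    """A run of amplicons in a shared copy-number state."""

    contig: str
    start: int
    end: int
    state: str  # 'loss' | 'gain'
    amplicons: list[str]
    mean_ratio: float


def call_cnv(
    combined: pd.Series,
    meta: pd.DataFrame,
    loss_max: float = 0.7,
    gain_min: float = 1.35,
    min_consecutive: int = 2,
    ploidy: Mapping[str, int] | None = None,
) -> list[CnvCall]:
    """Threshold CNV calls over combined per-amplicon ratios.

    ``meta`` must carry name/contig/start/end per amplicon.  An optional
    per-contig ploidy table rescales expectations (e.g. male X baseline at
    half the autosomal ratio): ratios are divided by ``ploidy/2`` before
    thresholding.  Runs of at least ``min_consecutive`` consecutive
    non-neutral amplicons (genomic order, per contig) are merged into calls
    carrying the mean (unadjusted) ratio.  NaN ratios are neutral.
    """
    if loss_max >= gain_min:
        raise ValueError("loss_max must be below gain_min")
    ploidy = dict(ploidy or {})
    calls: list[CnvCall] = []
    meta_indexed = meta.set_index("name")
    for contig, sub in meta.groupby("contig", sort=True):
        sub = sub.sort_values("start")
        names = [n for n in sub["name"] if n in combined.index]
        states = []
        for name in names:
            ratio = combined.loc[name]
            adj = ratio / (ploidy.get(contig, 2) / 2.0)
            if np.isnan(adj):
                states.append("neutral")
            elif adj <= loss_max:
                states.append("loss")
            elif adj >= gain_min:
                states.append("gain")
            else:
                states.append("neutral")
        run_start = 0
        for i in range(len(names) + 1):
            boundary = i == len(names) or (i > 0 and states[i] != states[run_start])
            if not boundary:
                continue
            run = names[run_start:i]
            state = states[run_start]
            if state != "neutral" and len(run) >= min_consecutive:
                calls.append(
                    CnvCall(
                        contig=contig,
                        start=int(meta_indexed.at[run[0], "start"]),
                        end=int(meta_indexed.at[run[-1], "end"]),
                        state=state,
                        amplicons=run,
                        mean_ratio=float(np.nanmean(combined.loc[run])),
                    )
                )
            run_start = i
    return calls
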
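"""Windowed read-depth case/control CNV association scan and RD caller.

The scan summarises per-base depth (MAPQ-filtered upstream) in fixed 1-kbp
non-overlapping windows, normalises every sample to the highest-coverage
sample by a global correction factor, drops windows below 2X in every
sample, Welch-tests each retained window between case and control groups
against a Bonferroni threshold of 0.05 / number of tested windows, and
reports per-sample M-values

    M = log2(window depth / case-group window mean depth)

so that a heterozygous deletion private to one group shows M ~ -1 and a
homozygous deletion M -> -inf (flagged undefined at zero depth).

A transparent threshold-merge caller produces deletion/duplication calls
carrying the same downstream fields (p of mean-RD difference from the
genomic average, q0 fraction) used by the published filter chain: p < 0.001,
length > 1 kbp, no zero-mapping-quality signal, no gap overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CNVCall, DepthTrack, GenomicInterval, WindowTable

# ------------------------------------------------------------- windowing


def window_depth(
    tracks: dict[str, DepthTrack],
    window_bp: int = 1000,
    mapq_min: int = 15,
    q0_intervals: list[GenomicInterval] | None = None,
) -> WindowTable:
    """Mean per-base depth in fixed non-overlapping windows.

    ``mapq_min`` documents the mapping-quality floor the depth tracks were
    extracted with; it is recorded, not re-applied (per-base tracks carry no
    per-read information).  ``q0_intervals`` supply the zero-mapping-quality
    mask from which each window's q0 fraction is computed.  A shorter
    terminal window is retained and flagged.
    """
    if not tracks:
        raise ValueError("no depth tracks")
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    samples = sorted(tracks)
    first = tracks[samples[0]]
    n = first.length
    chrom = first.chrom
    for s in samples:
        if tracks[s].length != n or tracks[s].chrom != chrom:
            raise ValueError("all tracks must cover the same chromosome")

    n_windows = int(np.ceil(n / window_bp))
    starts = np.arange(n_windows, dtype=np.int64) * window_bp + 1
    ends = np.minimum(starts + window_bp - 1, n)
    depth = np.empty((len(samples), n_windows))
    for i, s in enumerate(samples):
        d = tracks[s].depth.astype(float)
        sums = np.add.reduceat(d, starts - 1)
        depth[i] = sums / (ends - starts + 1)

    q0_frac = np.zeros(n_windows)
    if q0_intervals:
        mask = np.zeros(n, dtype=bool)
        for iv in q0_intervals:
            if iv.chrom == chrom:
                mask[iv.start - 1 : iv.end] = True
        q0_frac = np.add.reduceat(mask.astype(float), starts - 1) / (
            ends - starts + 1
        )

    return WindowTable(
        chrom=chrom,
        window_bp=window_bp,
        starts=starts,
        ends=ends,
        samples=samples,
        depth=depth,
        q0_fraction=q0_frac,
        terminal_partial=bool(n % window_bp),
    )


def normalize_windows(wt: WindowTable) -> WindowTable:
    """Scale every sample to the highest-coverage sample's genome-wide mean.

    The reference is the sample with the highest mean depth (ties broken by
    lexicographically first id); each sample's windows are multiplied by
    reference mean / sample mean, so normalized genome-wide means coincide.
    """
    means = wt.depth.mean(axis=1)
    if (means <= 0).any():
        bad = [s for s, m in zip(wt.samples, means) if m <= 0]
        raise ValueError(f"zero-mean depth for samples: {bad}")
    best = np.flatnonzero(means == means.max())
    ref = min(best, key=lambda i: wt.samples[i])
    factors = means[ref] / means
    wt.normalized_depth = wt.depth * factors[:, None]
    return wt


def exclude_windows(wt: WindowTable, min_depth: float = 2.0) -> np.ndarray:
    """Mask windows whose (normalized) depth is below ``min_depth`` in
    every sample; a single well-covered sample keeps the window."""
    vals = wt.values()
    mask = (vals < min_depth).all(axis=0)
    wt.excluded = mask
    return mask


# ------------------------------------------------------------- group scan


@dataclass
class WindowScan:
    """Per-window group test results."""

    table: pd.DataFrame  # start, end, p, significant, excluded
    bonferroni_threshold: float
    n_tested: int
    significant_runs: list[tuple[int, int]]  # (first, last) window indices


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / number of tests."""
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    return alpha / n_tests


def window_group_test(
    wt: WindowTable,
    case_ids: list[str],
    control_ids: list[str],
    alpha: float = 0.05,
    equal_var: bool = False,
) -> WindowScan:
    """Two-sample t-test of depth per retained window, case vs control.

    Welch's unequal-variance test by default (``equal_var=True`` for the
    pooled Student variant).  Excluded windows are skipped and do not count
    toward the Bonferroni denominator.  Runs of consecutive significant
    windows are reported as candidate CNV signatures.
    """
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise ValueError("need at least two samples per group")
    ci = [wt.sample_index(s) for s in case_ids]
    gi = [wt.sample_index(s) for s in control_ids]
    vals = wt.values()
    tested = ~wt.excluded
    n_tested = int(tested.sum())
    thresh = bonferroni_threshold(n_tested, alpha)

    p = np.full(wt.n_windows, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(
            vals[np.ix_(ci, np.flatnonzero(tested))],
            vals[np.ix_(gi, np.flatnonzero(tested))],
            axis=0,
            equal_var=equal_var,
        )
    pt = np.asarray(res.pvalue)
    pt = np.where(np.isnan(pt), 1.0, pt)  # zero-variance-both-groups windows
    p[tested] = pt

    significant = np.zeros(wt.n_windows, dtype=bool)
    significant[tested] = pt < thresh
    runs: list[tuple[int, int]] = []
    start = None
    for i, s in enumerate(significant):
        if s and start is None:
            start = i
        elif not s and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, wt.n_windows - 1))

    table = pd.DataFrame(
        {
            "start": wt.starts,
            "end": wt.ends,
            "p": p,
            "significant": significant,
            "excluded": wt.excluded,
        }
    )
    return WindowScan(table, thresh, n_tested, runs)


def m_values(wt: WindowTable, case_ids: list[str]) -> pd.DataFrame:
    """log2 fold-coverage of each sample against the case-group window mean.

    Windows where the case-group mean is zero, or a sample's own depth is
    zero, yield undefined M (NaN / -inf respectively); they are returned
    as-is with a parallel ``defined`` mask in the attrs.
    """
    ci = [wt.sample_index(s) for s in case_ids]
    vals = wt.values()
    case_mean = vals[ci].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        M = np.log2(vals / case_mean[None, :])
    df = pd.DataFrame(M, index=wt.samples, columns=wt.starts)
    df.attrs["case_group_mean"] = case_mean
    df.attrs["defined"] = np.isfinite(M)
    return df


# ------------------------------------------------------------- RD caller


@dataclass
class CallerParams:
    """Thresholds of the threshold-merge read-depth caller."""

    deletion_ratio: float = 0.75  # corrected depth < ratio x median -> del
    duplication_ratio: float = 1.25
    min_windows: int = 1


def gc_correct(depth: np.ndarray, gc_percent: np.ndarray) -> np.ndarray:
    """Bin windows by integer GC percent; divide each window by its bin
    median and restore the global median scale."""
    gc_bins = np.round(gc_percent).astype(int)
    corrected = depth.astype(float).copy()
    global_med = np.median(depth)
    for b in np.unique(gc_bins):
        sel = gc_bins == b
        med = np.median(depth[sel])
        if med > 0:
            corrected[sel] = depth[sel] / med * global_med
    return corrected


def call_cnvs(
    wt: WindowTable,
    sample: str,
    params: CallerParams | None = None,
    gc_percent: np.ndarray | None = None,
) -> list[CNVCall]:
    """Simplified single-sample read-depth CNV caller.

    Consecutive non-excluded windows whose (GC-corrected) depth deviates
    from the sample's genomic median beyond the deletion/duplication ratio
    are merged into calls.  Each call carries the p-value of a one-sample
    t-test of its window depths against the genomic average and the mean
    window q0 fraction, matching the fields the published filter chain
    consumes.
    """
    params = params or CallerParams()
    if wt.n_windows < 2:
        raise ValueError("chromosome shorter than two windows")
    i = wt.sample_index(sample)
    depth = wt.values()[i].astype(float)
    if gc_percent is not None:
        depth = gc_correct(depth, gc_percent)
    usable = ~wt.excluded
    med = float(np.median(depth[usable]))
    mean = float(np.mean(depth[usable]))
    if med <= 0:
        raise ValueError("non-positive median depth")

    state = np.zeros(wt.n_windows, dtype=int)  # -1 del, +1 dup
    state[usable & (depth < params.deletion_ratio * med)] = -1
    state[usable & (depth > params.duplication_ratio * med)] = 1

    calls: list[CNVCall] = []
    j = 0
    while j < wt.n_windows:
        if state[j] == 0:
            j += 1
            continue
        k = j
        while k + 1 < wt.n_windows and state[k + 1] == state[j]:
            k += 1
        if k - j + 1 >= params.min_windows:
            seg = depth[j : k + 1]
            if seg.size > 1 and np.ptp(seg) > 0:
                p = float(stats.ttest_1samp(seg, popmean=mean).pvalue)
            else:
                # single-window or constant segment: Gaussian tail with the
                # genome-wide window SD as spread
                sd = float(np.std(depth[usable], ddof=1))
                z = (seg.mean() - mean) / (sd if sd > 0 else 1.0)
                p = float(2.0 * stats.norm.sf(abs(z)))
            calls.append(
                CNVCall(
                    sample=sample,
                    interval=GenomicInterval(
                        wt.chrom, int(wt.starts[j]), int(wt.ends[k])
                    ),
                    kind="deletion" if state[j] == -1 else "duplication",
                    normalized_rd=float(seg.mean() / mean),
                    p_mean_diff=max(p, np.finfo(float).tiny),
                    q0=float(np.mean(wt.q0_fraction[j : k + 1])),
                )
            )
        j = k + 1
    return calls


def filter_calls(
    calls: list[CNVCall],
    gaps: list[GenomicInterval],
    p_max: float = 0.001,
    len_min: int = 1000,
    q0_max: float = 0.0,
) -> tuple[list[CNVCall], pd.DataFrame]:
    """Apply the published CNV-call filter chain.

    Keeps calls with p_mean_diff < ``p_max``, span > ``len_min`` bp,
    q0 <= ``q0_max`` and zero overlap with any gap interval; the report
    lists every removal with its first triggering reason
    ("p_value" | "length" | "q0" | "gap").
    """
    kept: list[CNVCall] = []
    records: list[dict] = []
    for c in calls:
        if not (c.p_mean_diff < p_max):
            reason = "p_value"
        elif not (c.interval.span > len_min):
            reason = "length"
        elif c.q0 > q0_max:
            reason = "q0"
        elif any(c.interval.overlaps(g) for g in gaps):
            reason = "gap"
        else:
            kept.append(c)
            continue
        records.append(
            {"sample": c.sample, "interval": str(c.interval), "reason": reason}
        )
    report = pd.DataFrame(records, columns=["sample", "interval", "reason"])
    return kept, report
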
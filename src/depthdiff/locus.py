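"""LD-based candidate-locus definition and allele-frequency summaries.

LD is measured as the squared Pearson correlation of genotype dosages
(composite r^2, phase-free).  A candidate locus is the min-max envelope of
all markers on the anchor's chromosome whose r^2 to the anchor reaches the
threshold; coordinates are 1-based inclusive so span = end - start + 1
reproduces printed interval sizes exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import GenomicInterval, GenotypeMatrix, interval_span

__all__ = [
    "ld_r2",
    "ld_profile",
    "define_locus",
    "interval_span",
    "allelic_or",
    "pooled_maf",
]


def ld_r2(g_a: np.ndarray, g_b: np.ndarray) -> float:
    """Composite LD: squared Pearson correlation of two dosage vectors.

    Computed over samples non-missing in both; invariant to allele
    relabeling (g -> 2 - g) and sample order.
    """
    a = np.asarray(g_a, dtype=float)
    b = np.asarray(g_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("both markers must be polymorphic on shared samples")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_profile(G: GenotypeMatrix, anchor: str) -> pd.DataFrame:
    """r^2 of every marker on the anchor's chromosome to the anchor."""
    if anchor not in G.marker_map.index:
        raise ValueError(f"anchor {anchor!r} not in marker map")
    chrom = G.marker_map.loc[anchor, "chrom"]
    ga = G.dosage_of(anchor)
    if np.ptp(ga[~np.isnan(ga)]) == 0:
        raise ValueError("anchor is monomorphic")
    rows = []
    for m in G.marker_map.index[G.marker_map["chrom"] == chrom]:
        try:
            r2 = ld_r2(ga, G.dosage_of(m))
        except ValueError:
            r2 = np.nan
        rows.append((m, int(G.marker_map.loc[m, "pos"]), r2))
    return pd.DataFrame(rows, columns=["marker", "pos", "r2"]).set_index("marker")


def define_locus(
    G: GenotypeMatrix, anchor: str, r2_threshold: float = 0.8
) -> GenomicInterval:
    """Candidate locus: positional envelope of markers linked to the anchor.

    Includes every marker on the anchor's chromosome with r^2 >= threshold
    (the anchor always included); intervening low-r^2 markers do not break
    the interval.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError("r2_threshold must be in (0, 1]")
    prof = ld_profile(G, anchor)
    linked = prof[(prof["r2"] >= r2_threshold) | (prof.index == anchor)]
    chrom = str(G.marker_map.loc[anchor, "chrom"])
    return GenomicInterval(chrom, int(linked["pos"].min()), int(linked["pos"].max()))


def allelic_or(maf_case: float, maf_control: float) -> float:
    """Allelic odds ratio from group minor-allele frequencies.

    OR = [p_case / (1 - p_case)] / [p_control / (1 - p_control)]; < 1 means
    the allele is depleted in cases (protective).  Frequencies of exactly 0
    or 1 are rejected — use a count-based OR with continuity correction for
    those (see deletion association).
    """
    for f in (maf_case, maf_control):
        if not (0.0 < f < 1.0):
            raise ValueError("frequencies must be strictly inside (0, 1)")
    return (maf_case / (1.0 - maf_case)) / (maf_control / (1.0 - maf_control))


def pooled_maf(
    maf_case: float, n_case: int, maf_control: float, n_control: int
) -> float:
    """Allele-count-weighted frequency across the two groups."""
    if n_case < 0 or n_control < 0 or n_case + n_control == 0:
        raise ValueError("need a positive total sample count")
    num = maf_case * 2 * n_case + maf_control * 2 * n_control
    return num / (2 * n_case + 2 * n_control)
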
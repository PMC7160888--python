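"""Depth-based deletion genotyping and the deletion's allelic association.

A sample's deletion genotype is inferred from the ratio of its mean
normalized depth over the deletion interval to its genome-wide mean:
~0 -> Del/Del (0 intact copies), ~0.5 -> Del/+ (1), ~1 -> +/+ (2).
Concordance with a tagging SNP is reported per phenotype group, and the
allelic case/control table is tested with a two-sided Fisher's exact test;
the odds ratio uses the Haldane-Anscombe 0.5 correction when any cell is
zero and a Woolf logit 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomicInterval, WindowTable


@dataclass(frozen=True)
class DeletionGenotype:
    """Number of intact (non-deleted) chromosomes: 0 = Del/Del, 1 = Del/+,
    2 = +/+ (NoDel/NoDel)."""

    sample: str
    copies: int
    source: str = "depth-inferred"

    def __post_init__(self) -> None:
        if self.copies not in (0, 1, 2):
            raise ValueError("copies must be 0, 1 or 2")

    @property
    def label(self) -> str:
        return {0: "Del/Del", 1: "Del/+", 2: "+/+"}[self.copies]


def genotype_from_depth(
    wt: WindowTable,
    sample: str,
    interval: GenomicInterval,
    hom_threshold: float = 0.25,
    het_threshold: float = 0.75,
) -> DeletionGenotype:
    """Infer the deletion genotype from the window depth ratio.

    ratio = mean normalized depth over the interval / the sample's
    genome-wide mean; copies = 0 below ``hom_threshold``, 1 below
    ``het_threshold``, else 2.  The interval must be covered by at least two
    retained (non-excluded) windows.
    """
    i = wt.sample_index(sample)
    vals = wt.values()[i]
    inside = (wt.starts <= interval.end) & (wt.ends >= interval.start)
    if inside.sum() < 2:
        raise ValueError("interval covered by fewer than two windows")
    usable = inside & ~wt.excluded
    if not usable.any():
        raise ValueError("interval lies entirely in excluded windows")
    genome_mean = float(vals[~wt.excluded].mean())
    ratio = float(vals[usable].mean()) / genome_mean
    copies = 0 if ratio < hom_threshold else (1 if ratio < het_threshold else 2)
    return DeletionGenotype(sample=sample, copies=copies)


def segregation_concordance(
    cnv_genotypes: dict[str, int],
    snp_dosages: dict[str, float],
    status: dict[str, int],
    tag_allele_is_alt: bool = True,
) -> dict:
    """Co-segregation of the deletion with a tagging SNP.

    The caller must declare which SNP allele tags the deletion
    (``tag_allele_is_alt``): a sample is concordant when its intact-copy
    count equals 2 minus its dosage of the tagging allele.  Fractions are
    reported overall and per phenotype group, rounded to whole percent.
    """
    shared = [
        s
        for s in cnv_genotypes
        if s in snp_dosages and not np.isnan(snp_dosages[s])
    ]
    if not shared:
        raise ValueError("no shared samples between deletion and SNP genotypes")
    conc: dict[str, list[bool]] = {"all": [], "case": [], "control": []}
    for s in shared:
        dos = snp_dosages[s] if tag_allele_is_alt else 2 - snp_dosages[s]
        ok = cnv_genotypes[s] == 2 - round(dos)
        conc["all"].append(ok)
        if s in status:
            conc["case" if status[s] == 1 else "control"].append(ok)

    def pct(v: list[bool]) -> float | None:
        return round(100.0 * sum(v) / len(v)) if v else None

    return {
        "n": len(shared),
        "n_concordant": int(sum(conc["all"])),
        "percent": pct(conc["all"]),
        "percent_case": pct(conc["case"]),
        "percent_control": pct(conc["control"]),
        "n_case": len(conc["case"]),
        "n_control": len(conc["control"]),
    }


def fisher_allelic(table: np.ndarray) -> dict:
    """Fisher's exact test of a 2x2 allele-by-group count table.

    Rows: deletion / non-deletion allele; columns: case / control.  The
    two-sided p sums hypergeometric probabilities of tables as or less
    probable than observed; OR = (ad)/(bc) with the Haldane-Anscombe 0.5
    correction applied to every cell when any is zero; 95% CI by the Woolf
    logit method on the (corrected) counts.
    """
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("zero margin")
    a, b, c, d = tab.ravel()
    p = _fisher_p_two_sided(int(a), int(b), int(c), int(d))
    if (tab == 0).any():
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    ci = (float(np.exp(np.log(odds) - z * se)), float(np.exp(np.log(odds) + z * se)))
    return {"p": p, "or": float(odds), "ci": ci}


def _fisher_p_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summation over the hypergeometric support."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logp = (
        _lchoose(r1, support)
        + _lchoose(r2, c1 - support)
        - _lchoose(n, c1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[a - lo]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _lchoose(n, k):
    from scipy.special import gammaln

    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def allele_table(
    genotypes: dict[str, int], status: dict[str, int]
) -> np.ndarray:
    """Build the 2x2 deletion-allele count table from intact-copy genotypes.

    Each sample contributes 2 alleles; deletion alleles = 2 - copies.
    Rows: deletion / non-deletion; columns: case / control.
    """
    counts = np.zeros((2, 2), dtype=int)
    for s, copies in genotypes.items():
        if s not in status:
            continue
        col = 0 if status[s] == 1 else 1
        counts[0, col] += 2 - copies
        counts[1, col] += copies
    return counts


def insilico_assay_lengths(
    inner_forward: int,
    outer_forward: int,
    reverse: int,
    deletion: GenomicInterval,
) -> dict:
    """Predicted product sizes of a three-primer deletion assay.

    ``inner_forward`` sits between the outer forward primer and the
    deletion; the shared ``reverse`` primer lies downstream of the deletion
    end.  The no-deletion allele amplifies inner_forward..reverse on the
    reference; the deletion allele amplifies outer_forward..reverse minus
    the deleted span.  Primer coordinates are the 5'-most reference
    positions (1-based); products are reference spans in bp.  A forward
    primer falling inside the deletion is flagged unamplifiable for the
    deletion allele.
    """
    nodel = reverse - inner_forward + 1
    outer_span = reverse - outer_forward + 1
    del_product = outer_span - deletion.span
    unamplifiable = deletion.contains(deletion.chrom, outer_forward)
    return {
        "nodel_bp": int(nodel),
        "del_bp": int(del_product),
        "del_unamplifiable": bool(unamplifiable),
    }
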
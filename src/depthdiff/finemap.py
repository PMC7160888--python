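"""Fine-mapping preparation: variant pruning, imputation QC and merging.

Covers the bookkeeping between the discovery scan and the dense rescan:
dropping variants uninformative across the high-coverage trio, removing
monomorphic calls, the two-step imputation-likelihood filter (marker-level
allelic R^2, then genotype-level posterior probability) and merging
genotype sets with a call-rate rule for duplicated markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def prune_identical(
    hc_case1: pd.Series, hc_case2: pd.Series, hc_control: pd.Series
) -> tuple[pd.Index, pd.DataFrame]:
    """Drop variants where both high-coverage cases and the control agree.

    A variant is pruned only when all three genotypes are equal (and none
    missing); variants with any missing genotype are retained with a flag.
    Returns (retained variant index, report with per-variant outcome).
    """
    df = pd.DataFrame(
        {"case1": hc_case1, "case2": hc_case2, "control": hc_control}
    )
    missing = df.isna().any(axis=1)
    identical = (~missing) & (df["case1"] == df["case2"]) & (
        df["case1"] == df["control"]
    )
    outcome = np.where(
        identical, "pruned_identical", np.where(missing, "kept_missing", "kept")
    )
    report = pd.DataFrame({"outcome": outcome}, index=df.index)
    return df.index[~identical], report


def monomorphic_filter(
    G: GenotypeMatrix, maf_min: float = 0.001
) -> tuple[GenotypeMatrix, list[str]]:
    """Remove markers with MAF below ``maf_min`` (monomorphic screen)."""
    if not (0.0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    maf = G.maf()
    with np.errstate(invalid="ignore"):
        keep = ~(np.nan_to_num(maf, nan=0.0) < maf_min)
    removed = [m for m, k in zip(G.markers, keep) if not k]
    return G.subset(markers=[m for m, k in zip(G.markers, keep) if k]), removed


@dataclass
class ImputationFilterResult:
    """Outcome of the two-step imputation-likelihood filter."""

    genotypes: pd.DataFrame  # filtered long-format calls
    n_total: int
    n_retained: int

    @property
    def retention_fraction(self) -> float:
        return self.n_retained / self.n_total if self.n_total else 1.0


def filter_imputed(
    imputed: pd.DataFrame, r2_min: float = 0.75, gp_min: float = 0.8
) -> ImputationFilterResult:
    """Two-step imputation QC, in this fixed order:

    1. discard every genotype of markers whose allelic R^2 < ``r2_min``;
    2. of the survivors, set genotypes with posterior probability
       < ``gp_min`` to missing (dropped from the retained count).

    ``imputed`` is long-format with columns ``marker``, ``sample``,
    ``dosage``, ``allelic_r2`` (per marker), ``genotype_probability``.
    """
    for t in (r2_min, gp_min):
        if not (0.0 <= t <= 1.0):
            raise ValueError("thresholds must be in [0, 1]")
    required = {"marker", "sample", "dosage", "allelic_r2", "genotype_probability"}
    if not required.issubset(imputed.columns):
        raise ValueError(f"imputed table needs columns {sorted(required)}")
    n_total = len(imputed)
    step1 = imputed[imputed["allelic_r2"] >= r2_min]
    step2 = step1[step1["genotype_probability"] >= gp_min]
    return ImputationFilterResult(
        genotypes=step2.copy(), n_total=n_total, n_retained=len(step2)
    )


def assay_success_rate(n_attempted: int, n_failed: int) -> float:
    """Fraction of assayed markers yielding genotypes, as a percentage base.

    E.g. 33 technical failures out of 740 pooled markers -> 0.9554...
    """
    if n_attempted <= 0 or not (0 <= n_failed <= n_attempted):
        raise ValueError("need 0 <= n_failed <= n_attempted, n_attempted > 0")
    return (n_attempted - n_failed) / n_attempted


def merge_genotype_sets(
    primary: GenotypeMatrix, secondary: GenotypeMatrix
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Union of two marker sets over a shared sample universe.

    Markers duplicated by (chrom, pos) keep the copy with the higher call
    rate (ties keep the primary).  Allele orientation of kept secondary
    duplicates is harmonized to the primary reference allele (swapped
    ref/alt flips dosage); strand-ambiguous pairs (A/T, C/G) are flagged;
    incompatible allele pairs are dropped and reported.
    """
    if list(primary.samples) != list(secondary.samples):
        common = [s for s in primary.samples if s in secondary.samples]
        if not common:
            raise ValueError("no shared samples to merge on")
        primary = primary.subset(samples=common)
        secondary = secondary.subset(samples=common)

    key = lambda mm: list(zip(mm["chrom"], mm["pos"]))
    pkeys = dict(zip(key(primary.marker_map), primary.marker_map.index))
    records: list[dict] = []
    keep_secondary: list[str] = []
    drop_primary: set[str] = set()
    flip: dict[str, bool] = {}

    p_call = dict(zip(primary.markers, primary.marker_call_rate()))
    s_call = dict(zip(secondary.markers, secondary.marker_call_rate()))

    for (chrom, pos), sid in zip(key(secondary.marker_map), secondary.marker_map.index):
        if (chrom, pos) not in pkeys:
            keep_secondary.append(sid)
            continue
        pid = pkeys[(chrom, pos)]
        pa = (
            str(primary.marker_map.loc[pid].get("ref", "A")),
            str(primary.marker_map.loc[pid].get("alt", "G")),
        )
        sa = (
            str(secondary.marker_map.loc[sid].get("ref", "A")),
            str(secondary.marker_map.loc[sid].get("alt", "G")),
        )
        if sa == pa:
            flip_dosage = False
        elif sa == (pa[1], pa[0]):
            flip_dosage = True
        else:
            records.append(
                {"marker": sid, "action": "dropped", "reason": "incompatible_alleles"}
            )
            continue
        ambiguous = pa in AMBIGUOUS_PAIRS
        if s_call[sid] > p_call[pid]:
            drop_primary.add(pid)
            keep_secondary.append(sid)
            flip[sid] = flip_dosage
            records.append(
                {
                    "marker": sid,
                    "action": "replaced_primary",
                    "reason": "higher_call_rate"
                    + (";strand_ambiguous" if ambiguous else ""),
                }
            )
        else:
            records.append(
                {
                    "marker": sid,
                    "action": "dropped",
                    "reason": "duplicate_lower_call_rate"
                    + (";strand_ambiguous" if ambiguous else ""),
                }
            )

    keep_p = [m for m in primary.markers if m not in drop_primary]
    Gp = primary.subset(markers=keep_p)
    Gs = secondary.subset(markers=keep_secondary)
    dos_s = Gs.dosage.copy()
    for j, m in enumerate(Gs.markers):
        if flip.get(m):
            dos_s[:, j] = 2.0 - dos_s[:, j]

    merged_map = pd.concat([Gp.marker_map, Gs.marker_map])
    merged_dosage = np.hstack([Gp.dosage, dos_s])
    merged = GenotypeMatrix(Gp.samples, merged_map, merged_dosage)
    report = pd.DataFrame(records, columns=["marker", "action", "reason"])
    return merged, report


def rank_by_tracks(
    marker_map: pd.DataFrame, tracks: dict[str, list]
) -> pd.DataFrame:
    """Generic annotate-and-rank hook for user-supplied interval tracks.

    ``tracks`` maps a category name to a list of
    :class:`~depthdiff.core.GenomicInterval`; each marker gets one boolean
    column per category and a ``n_categories`` rank column (more overlaps =
    higher priority).  The biological category definitions themselves are
    up to the caller.
    """
    out = marker_map[["chrom", "pos"]].copy()
    for name, ivs in tracks.items():
        out[name] = [
            any(iv.contains(row["chrom"], int(row["pos"])) for iv in ivs)
            for _, row in marker_map.iterrows()
        ]
    cat_cols = list(tracks)
    out["n_categories"] = out[cat_cols].sum(axis=1) if cat_cols else 0
    return out.sort_values("n_categories", ascending=False)
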
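"""Core containers shared across the pipeline.

All genomic coordinates in this package are 1-based and inclusive at both
ends, matching the convention of VCF and of the printed coordinates this
toolkit reproduces.  BED output converts to 0-based half-open on write only
(see :func:`depthdiff.io.write_bed`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.nan


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, fully-closed genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.start < 1:
            raise ValueError("coordinates are 1-based; start must be >= 1")

    @property
    def span(self) -> int:
        """Length in bp under the closed-interval convention."""
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        lo = max(self.start, other.start)
        hi = min(self.end, other.end)
        return max(0, hi - lo + 1)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def __str__(self) -> str:  # chr:start-end, as printed in results tables
        return f"{self.chrom}:{self.start}-{self.end}"


def interval_span(interval: GenomicInterval) -> int:
    """Span in bp of a 1-based inclusive interval (end - start + 1)."""
    return interval.span


@dataclass
class GenotypeMatrix:
    """Samples x markers dosage matrix with a sorted marker map.

    ``dosage`` holds minor/alternate-allele counts in {0, 1, 2} with ``nan``
    for missing calls.  ``marker_map`` is indexed by marker id and carries
    ``chrom``, ``pos`` (1-based), ``ref`` and ``alt`` columns, sorted by
    (chrom, pos).
    """

    samples: list[str]
    marker_map: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.marker_map)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.marker_map)} markers"
            )
        order = self.marker_map.sort_values(["chrom", "pos"], kind="stable")
        if not order.index.equals(self.marker_map.index):
            pos = [self.marker_map.index.get_loc(m) for m in order.index]
            self.marker_map = order
            self.dosage = self.dosage[:, pos]

    @property
    def markers(self) -> list[str]:
        return list(self.marker_map.index)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.marker_map)

    def allele_freq(self) -> np.ndarray:
        """Per-marker alternate-allele frequency over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def marker_call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosage), axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosage), axis=1)

    def subset(
        self,
        samples: list[str] | None = None,
        markers: list[str] | None = None,
    ) -> "GenotypeMatrix":
        sidx = (
            np.arange(self.n_samples)
            if samples is None
            else np.array([self.samples.index(s) for s in samples], dtype=int)
        )
        midx = (
            np.arange(self.n_markers)
            if markers is None
            else np.array(
                [self.marker_map.index.get_loc(m) for m in markers], dtype=int
            )
        )
        return GenotypeMatrix(
            samples=[self.samples[i] for i in sidx],
            marker_map=self.marker_map.iloc[midx].copy(),
            dosage=self.dosage[np.ix_(sidx, midx)].copy(),
        )

    def dosage_of(self, marker: str) -> np.ndarray:
        return self.dosage[:, self.marker_map.index.get_loc(marker)]


@dataclass
class PhenotypeTable:
    """Per-sample phenotype records.

    ``table`` is indexed by sample id with at least a ``status`` column
    (1 = case, 0 = control); optional columns: ``sex``, ``tgaa``, ``tsh``,
    ``ft4``, ``age``, ``seq_group`` (e.g. HC / LC / none).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "status" not in self.table.columns:
            raise ValueError("phenotype table requires a 'status' column")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    @property
    def cases(self) -> list[str]:
        return list(self.table.index[self.table["status"] == 1])

    @property
    def controls(self) -> list[str]:
        return list(self.table.index[self.table["status"] == 0])

    def status_vector(self, samples: list[str]) -> np.ndarray:
        return self.table.loc[samples, "status"].to_numpy(dtype=float)


@dataclass
class DepthTrack:
    """Per-base sequencing depth for one sample on one chromosome.

    ``depth[i]`` is the depth at 1-based position ``i + 1``.
    """

    chrom: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1 or self.depth.size == 0:
            raise ValueError("depth track must be a non-empty 1-D array")

    @property
    def length(self) -> int:
        return self.depth.size

    def mean(self) -> float:
        return float(np.mean(self.depth))


@dataclass
class WindowTable:
    """Fixed-width non-overlapping window summary of depth tracks.

    ``depth`` (and ``normalized_depth`` once set) are samples x windows
    matrices of mean per-base depth.  ``excluded`` marks windows dropped by
    the low-coverage rule; ``q0_fraction`` is the per-window fraction of
    bases under the zero-mapping-quality mask.
    """

    chrom: str
    window_bp: int
    starts: np.ndarray  # 1-based window starts
    ends: np.ndarray  # inclusive window ends
    samples: list[str]
    depth: np.ndarray
    normalized_depth: np.ndarray | None = None
    excluded: np.ndarray | None = None
    q0_fraction: np.ndarray | None = None
    terminal_partial: bool = False

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.shape != (len(self.samples), self.starts.size):
            raise ValueError("depth matrix shape mismatch")
        if self.excluded is None:
            self.excluded = np.zeros(self.starts.size, dtype=bool)
        if self.q0_fraction is None:
            self.q0_fraction = np.zeros(self.starts.size, dtype=float)

    @property
    def n_windows(self) -> int:
        return self.starts.size

    def values(self) -> np.ndarray:
        """Normalized depth if available, raw depth otherwise."""
        return self.depth if self.normalized_depth is None else self.normalized_depth

    def window_interval(self, i: int) -> GenomicInterval:
        return GenomicInterval(self.chrom, int(self.starts[i]), int(self.ends[i]))

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)


@dataclass
class CNVCall:
    """A read-depth CNV call with the fields the downstream filters consume."""

    sample: str
    interval: GenomicInterval
    kind: str  # "deletion" | "duplication"
    normalized_rd: float
    p_mean_diff: float
    q0: float

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "duplication"):
            raise ValueError(f"unknown CNV type {self.kind!r}")
        if not (0.0 <= self.q0 <= 1.0):
            raise ValueError("q0 must be in [0, 1]")


@dataclass
class AssociationResult:
    """Per-marker association scan output.

    ``table`` is indexed by marker id with columns ``chrom``, ``pos``,
    ``stat`` (1-df chi-square score statistic), ``p``, ``direction``,
    ``maf_all``, ``maf_case``, ``maf_control`` and optionally ``flag``.
    """

    table: pd.DataFrame
    extras: dict = field(default_factory=dict)

    def top_marker(self) -> str:
        return str(self.table["p"].idxmin())
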
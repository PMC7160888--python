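"""Individual- and marker-based genotype quality control.

Implements the pre-association QC chain: sample call-rate pruning, marker
pruning by minor allele frequency, call rate and a Hardy-Weinberg exact
test combined with a Benjamini-Hochberg false-discovery-rate rule evaluated
in controls, an allele-frequency-weighted genomic kinship matrix, classical
multidimensional scaling of kinship-derived distances for structure
inspection and outlier flagging, and a sex-by-status phi-coefficient check.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeMatrix, PhenotypeTable


@dataclass
class QcThresholds:
    """Marker/sample pruning thresholds.

    Markers fail on MAF < ``maf_min`` or call rate < ``marker_call_rate_min``;
    samples fail on call rate < ``sample_call_rate_min``.  The HWE rule
    removes a marker when its exact-test p-value (in controls) is below
    ``hwe_p_min`` and its BH-adjusted FDR is below ``hwe_fdr_max``; set
    ``hwe_fdr_only`` to drop the raw-p condition.
    """

    maf_min: float = 0.05
    marker_call_rate_min: float = 0.95
    sample_call_rate_min: float = 0.95
    hwe_p_min: float = 1e-3
    hwe_fdr_max: float = 0.2
    hwe_fdr_only: bool = False

    def __post_init__(self) -> None:
        for name in (
            "maf_min",
            "marker_call_rate_min",
            "sample_call_rate_min",
            "hwe_p_min",
            "hwe_fdr_max",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional test of Hardy-Weinberg proportions.

    Sums the conditional probabilities (given the allele counts) of every
    heterozygote count as or less probable than the observed one.  Uses the
    log-gamma form of the conditional distribution

        P(n_het | n, n_a) ∝ 2^n_het * n! / (n_hh! n_het! n_aa!)

    so tables with a few hundred alleles are exact and fast.
    """
    for c in (n_hom_ref, n_het, n_hom_alt):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotypes")
    n_a = 2 * n_hom_alt + n_het  # minor-allele count (either allele works)
    n_a = min(n_a, 2 * n - n_a)
    if n_a == 0:
        return 1.0

    hets = np.arange(n_a % 2, n_a + 1, 2)
    log_probs = np.array([_log_hwe_weight(int(h), n, n_a) for h in hets])
    log_probs -= log_probs.max()
    probs = np.exp(log_probs)
    probs /= probs.sum()
    p_obs = probs[np.flatnonzero(hets == n_het)[0]]
    # tolerance avoids dropping ties to floating-point jitter
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _log_hwe_weight(n_het: int, n: int, n_a: int) -> float:
    n_aa = (n_a - n_het) // 2
    n_hh = n - n_het - n_aa
    if n_aa < 0 or n_hh < 0:
        return -np.inf
    return (
        n_het * np.log(2.0)
        - lgamma(n_hh + 1)
        - lgamma(n_het + 1)
        - lgamma(n_aa + 1)
    )


def genotype_counts(dosage: np.ndarray) -> tuple[int, int, int]:
    """(hom-ref, het, hom-alt) counts ignoring missing calls."""
    d = dosage[~np.isnan(dosage)]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def marker_qc(
    G: GenotypeMatrix,
    P: PhenotypeTable,
    t: QcThresholds | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the marker/sample pruning chain; returns (pruned matrix, report).

    Samples below the call-rate threshold are removed first; the HWE rule is
    evaluated in controls only.  The report lists one row per removed item
    with its triggering rule ("sample_call_rate", "maf", "call_rate", "hwe").
    """
    t = t or QcThresholds()
    records: list[dict] = []

    keep_samples = np.array(
        [s in P.samples for s in G.samples]
    ) & (G.sample_call_rate() >= t.sample_call_rate_min)
    for s, ok in zip(G.samples, keep_samples):
        if not ok:
            records.append({"item": s, "kind": "sample", "reason": "sample_call_rate"})
    G = G.subset(samples=[s for s, ok in zip(G.samples, keep_samples) if ok])

    controls = [s for s in P.controls if s in G.samples]
    if not controls:
        raise ValueError("HWE step requires control samples")
    Gc = G.subset(samples=controls)

    maf = G.maf()
    call = G.marker_call_rate()
    hwe_p = np.array(
        [hwe_exact_test(*genotype_counts(Gc.dosage[:, j])) for j in range(G.n_markers)]
    )
    hwe_fdr = bh_fdr(hwe_p)
    if t.hwe_fdr_only:
        hwe_fail = hwe_fdr < t.hwe_fdr_max
    else:
        hwe_fail = (hwe_p < t.hwe_p_min) & (hwe_fdr < t.hwe_fdr_max)

    keep = np.ones(G.n_markers, dtype=bool)
    for j, m in enumerate(G.markers):
        if maf[j] < t.maf_min:
            records.append({"item": m, "kind": "marker", "reason": "maf"})
            keep[j] = False
        elif call[j] < t.marker_call_rate_min:
            records.append({"item": m, "kind": "marker", "reason": "call_rate"})
            keep[j] = False
        elif hwe_fail[j]:
            records.append({"item": m, "kind": "marker", "reason": "hwe"})
            keep[j] = False

    report = pd.DataFrame(records, columns=["item", "kind", "reason"])
    return G.subset(markers=[m for m, ok in zip(G.markers, keep) if ok]), report


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def compute_kinship(G: GenotypeMatrix) -> pd.DataFrame:
    """Allele-frequency-weighted genomic kinship.

    K_ij = mean over markers of (g_i - 2p)(g_j - 2p) / (2p(1-p)) with p the
    sample allele frequency; missing dosages are excluded pairwise
    (the mean runs over markers observed in both samples).
    """
    if G.n_samples < 2:
        raise ValueError("kinship requires at least two samples")
    p = G.allele_freq()
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic markers")
    d = G.dosage[:, poly]
    p = p[poly]
    w = np.sqrt(2.0 * p * (1.0 - p))
    z = (d - 2.0 * p) / w
    valid = ~np.isnan(z)
    z0 = np.where(valid, z, 0.0)
    counts = valid.astype(float) @ valid.T.astype(float)
    K = (z0 @ z0.T) / np.maximum(counts, 1.0)
    return pd.DataFrame(K, index=G.samples, columns=G.samples)


def mds_from_kinship(K: pd.DataFrame, dims: int = 2) -> pd.DataFrame:
    """Classical MDS of the kinship-derived distances.

    d_ij^2 = K_ii + K_jj - 2 K_ij; coordinates come from the eigenvectors of
    the double-centered -d^2/2 matrix, ordered by decreasing eigenvalue.
    Axis signs are fixed so the largest-magnitude loading is positive.
    """
    n = K.shape[0]
    if dims < 1:
        raise ValueError("dims must be >= 1")
    if dims > n - 1:
        raise ValueError(f"dims={dims} exceeds n-1={n - 1}")
    Km = K.to_numpy()
    diag = np.diag(Km)
    d2 = diag[:, None] + diag[None, :] - 2.0 * Km
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1][:dims]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    for k in range(coords.shape[1]):
        j = np.argmax(np.abs(coords[:, k]))
        if coords[j, k] < 0:
            coords[:, k] *= -1.0
    return pd.DataFrame(
        coords, index=K.index, columns=[f"mds{k + 1}" for k in range(dims)]
    )


def flag_mds_outliers(coords: pd.DataFrame, z: float = 4.0) -> list[str]:
    """Samples beyond ``z`` SDs from the mean on either of the first two axes."""
    use = coords.iloc[:, : min(2, coords.shape[1])]
    zs = (use - use.mean()) / use.std(ddof=1)
    mask = (zs.abs() > z).any(axis=1)
    return list(coords.index[mask])


def sex_bias_phi(table: np.ndarray) -> tuple[float, float]:
    """Phi coefficient and p-value for a 2x2 sex-by-status table.

    phi = sqrt(chi2 / n) signed by the direction of association
    (positive when the main diagonal dominates); p from the 1-df chi-square
    test without continuity correction.
    """
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("zero margin")
    n = tab.sum()
    a, b, c, d = tab.ravel()
    denom = np.sqrt((a + b) * (c + d) * (a + c) * (b + d))
    phi = (a * d - b * c) / denom
    chi2 = n * phi**2
    p = float(stats.chi2.sf(chi2, df=1))
    return float(phi), p
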
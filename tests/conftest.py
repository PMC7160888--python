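import numpy as np
import pandas as pd
import pytest

from depthdiff.core import GenotypeMatrix, PhenotypeTable, WindowTable


def make_genotypes(dosage, positions=None, chrom="chr1", samples=None):
    """GenotypeMatrix from a samples x markers array."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    samples = samples or [f"s{i:03d}" for i in range(n)]
    positions = positions if positions is not None else (np.arange(m) + 1) * 1000
    mm = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "G"},
        index=pd.Index([f"m{j:05d}" for j in range(m)], name="marker"),
    )
    return GenotypeMatrix(samples, mm, dosage)


def make_phenotypes(status, samples=None, **cols):
    status = np.asarray(status)
    samples = samples or [f"s{i:03d}" for i in range(status.size)]
    df = pd.DataFrame({"status": status, **cols}, index=pd.Index(samples, name="sample"))
    return PhenotypeTable(df)


def make_window_table(depth, window_bp=1000, chrom="chr1", samples=None):
    """WindowTable straight from a samples x windows depth matrix."""
    depth = np.asarray(depth, dtype=float)
    n, w = depth.shape
    samples = samples or [f"s{i:03d}" for i in range(n)]
    starts = np.arange(w, dtype=np.int64) * window_bp + 1
    ends = starts + window_bp - 1
    return WindowTable(
        chrom=chrom,
        window_bp=window_bp,
        starts=starts,
        ends=ends,
        samples=samples,
        depth=depth,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """A deterministic 40-sample cohort with a genuine group-frequency split."""
    from depthdiff.synthetic import CohortConfig, simulate_cohort

    return simulate_cohort(
        CohortConfig(
            n_cases=20,
            n_controls=20,
            n_markers=100,
            protective_maf_case=0.05,
            protective_maf_control=0.4,
            seed=11,
        )
    )
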
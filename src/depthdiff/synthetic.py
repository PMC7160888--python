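"""Synthetic cohorts, genotypes and depth tracks for end-to-end testing.

The generator emulates the statistical structure the discovery chain
assumes: a small two-group cohort (default 71 cases / 36 controls) typed at
markers organised in LD blocks, one "protective" marker with a lower minor
allele frequency in cases than in controls (defaults 0.05 / 0.26), optional
sib-pair families to induce cryptic relatedness, and per-base depth tracks
at high (~46X) or low (~6.8X) fold-coverage carrying an embedded multi-kbp
deletion whose heterozygous carriers show ~50% window depth and homozygous
carriers ~0%.  Assembly gaps force depth to zero and repeat-like regions are
emitted as a zero-mapping-quality (q0) mask with over-dispersed depth.

The model is deliberately not read-level: depth is Poisson per base with a
smooth sinusoidal GC-like modulation, which is sufficient for every
downstream window statistic while staying desk-scale fast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .core import DepthTrack, GenomicInterval, GenotypeMatrix, PhenotypeTable

# --------------------------------------------------------------- cohorts


@dataclass
class CohortConfig:
    """Parameters of a simulated case/control genotyping cohort.

    ``ld_block_length`` controls the haplotype-block size (bp); markers are
    laid down every ``marker_spacing_bp`` on one chromosome.  Within a block
    each gamete copies one of a small pool of founder haplotypes (with a
    small per-marker mutation rate), recombining between blocks — the
    simplest structure under which r^2-based locus definition is meaningful.
    ``kinship_families`` adds that many sib pairs sharing parental gametes.
    """

    n_cases: int = 71
    n_controls: int = 36
    n_markers: int = 1000
    protective_maf_case: float = 0.05
    protective_maf_control: float = 0.26
    ld_block_length: int = 200_000
    kinship_families: int = 0
    seed: int = 0
    chrom: str = "chr11"
    marker_spacing_bp: int = 10_000
    n_templates: int = 6
    recomb_prob: float = 0.1
    mutation_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("both cohort groups must be non-empty")
        if self.n_markers <= 0:
            raise ValueError("n_markers must be positive")
        for f in (self.protective_maf_case, self.protective_maf_control):
            if not (0.0 <= f <= 1.0):
                raise ValueError("allele frequencies must lie in [0, 1]")
        if self.ld_block_length <= 0 or self.marker_spacing_bp <= 0:
            raise ValueError("lengths must be positive")
        if 2 * self.kinship_families > self.n_cases + self.n_controls:
            raise ValueError("more family members than cohort samples")


def _marker_layout(cfg: CohortConfig) -> tuple[np.ndarray, np.ndarray, int]:
    """Positions, block index per marker, and the protective marker index."""
    pos = (np.arange(cfg.n_markers, dtype=np.int64) + 1) * cfg.marker_spacing_bp
    block = (pos - 1) // cfg.ld_block_length
    protective = cfg.n_markers // 2
    return pos, block, protective


def simulate_cohort(
    cfg: CohortConfig,
) -> tuple[GenotypeMatrix, PhenotypeTable, dict]:
    """Draw genotypes, phenotypes and a truth record for one cohort.

    Returns the dosage matrix, the phenotype table (with diagnostic
    measurements consistent with the classification rules) and a truth
    record naming the protective marker and the realized group frequencies.
    """
    rng = np.random.default_rng(cfg.seed)
    pos, block, prot_idx = _marker_layout(cfg)
    n_blocks = int(block.max()) + 1
    prot_block = int(block[prot_idx])

    # Founder template haplotypes per block.  The protective block has two
    # templates: one carrying the protective allele plus a tag pattern.
    templates: list[np.ndarray] = []
    for b in range(n_blocks):
        in_b = np.flatnonzero(block == b)
        if b == prot_block:
            tmpl = np.zeros((2, in_b.size), dtype=np.int8)
            tmpl[0, :] = 1  # protective haplotype tags every block marker
        else:
            freqs = rng.uniform(0.1, 0.5, size=in_b.size)
            tmpl = (rng.random((cfg.n_templates, in_b.size)) < freqs).astype(np.int8)
        templates.append(tmpl)

    n_total = cfg.n_cases + cfg.n_controls
    group = np.array([1] * cfg.n_cases + [0] * cfg.n_controls)
    p_prot = np.where(
        group == 1, cfg.protective_maf_case, cfg.protective_maf_control
    )

    def draw_gamete(sample_i: int) -> np.ndarray:
        """One haplotype: per block copy a template, with mutation noise."""
        hap = np.empty(cfg.n_markers, dtype=np.int8)
        for b in range(n_blocks):
            in_b = np.flatnonzero(block == b)
            tmpl = templates[b]
            if b == prot_block:
                t = 0 if rng.random() < p_prot[sample_i] else 1
            elif rng.random() < cfg.recomb_prob:
                # recombinant gamete: independent per-marker draw at the
                # template pool's marginal frequencies (breaks the block)
                marg = tmpl.mean(axis=0)
                hap[in_b] = (rng.random(in_b.size) < marg).astype(np.int8)
                continue
            else:
                t = int(rng.integers(tmpl.shape[0]))
            h = tmpl[t].copy()
            flip = rng.random(in_b.size) < cfg.mutation_rate
            if b == prot_block:
                # causal marker frequency stays exactly at the configured
                # group value; noise only degrades its tag markers' r^2
                flip[in_b == prot_idx] = False
            h[flip] = 1 - h[flip]
            hap[in_b] = h
        return hap

    dosage = np.zeros((n_total, cfg.n_markers), dtype=float)
    sample_ids = [
        f"{'case' if group[i] == 1 else 'ctrl'}{i:03d}" for i in range(n_total)
    ]

    # Sib-pair families first (pairs share parental gametes), then singletons.
    i = 0
    fam = 0
    family_of = np.full(n_total, -1)
    while fam < cfg.kinship_families and i + 1 < n_total:
        if group[i] != group[i + 1]:  # sib pairs stay within one group
            i += 1
            continue
        par = [
            (draw_gamete(i), draw_gamete(i)),
            (draw_gamete(i), draw_gamete(i)),
        ]
        for child in (i, i + 1):
            hap_pair = []
            for p in range(2):
                # block-wise gamete from parent p with free recombination
                pick = rng.integers(2, size=n_blocks)
                hap = np.where(pick[block] == 0, par[p][0], par[p][1])
                hap_pair.append(hap)
            dosage[child] = hap_pair[0] + hap_pair[1]
            family_of[child] = fam
        i += 2
        fam += 1
    while i < n_total:
        dosage[i] = draw_gamete(i) + draw_gamete(i)
        i += 1

    marker_ids = [f"snp{j:05d}" for j in range(cfg.n_markers)]
    marker_map = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
        },
        index=pd.Index(marker_ids, name="marker"),
    )
    G = GenotypeMatrix(sample_ids, marker_map, dosage)

    pheno = _phenotypes_for(group, family_of, rng)
    pheno.index = pd.Index(sample_ids, name="sample")
    P = PhenotypeTable(pheno)

    prot_dos = dosage[:, prot_idx]
    truth = {
        "protective_marker": marker_ids[prot_idx],
        "protective_pos": int(pos[prot_idx]),
        "protective_block_markers": [
            marker_ids[j] for j in np.flatnonzero(block == prot_block)
        ],
        "maf_case_configured": cfg.protective_maf_case,
        "maf_control_configured": cfg.protective_maf_control,
        "maf_case_realized": float(prot_dos[group == 1].mean() / 2),
        "maf_control_realized": float(prot_dos[group == 0].mean() / 2),
        "seed": cfg.seed,
    }
    return G, P, truth


def _phenotypes_for(
    group: np.ndarray, family_of: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Diagnostic measurements consistent with the case/control rules."""
    n = group.size
    tgaa = np.where(group == 1, "POS", "NEG")
    tsh = np.where(group == 1, rng.uniform(40, 80, n), rng.uniform(1, 25, n))
    ft4 = np.where(group == 1, rng.uniform(1, 30, n), rng.uniform(5, 30, n))
    age = np.where(group == 1, rng.uniform(2, 12, n), rng.uniform(7, 14, n))
    return pd.DataFrame(
        {
            "status": group,
            "sex": rng.choice(["M", "F"], size=n),
            "tgaa": tgaa,
            "tsh": np.round(tsh, 1),
            "ft4": np.round(ft4, 1),
            "age": np.round(age, 1),
            "family": family_of,
            "seq_group": "none",
        }
    )


# ----------------------------------------------------- phenotype assignment


def classify_phenotype(
    tgaa: str | None,
    tsh: float | None,
    ft4: float | None,
    age: float | None,
) -> str:
    """Classify a dog as case / control / unclassified from thyroid markers.

    Case: thyroglobulin autoantibody positive and/or TSH >= 40 mU/l.
    Control: TgAA negative, TSH <= 25 mU/l, fT4 >= 5 pmol/l and age >= 7 y.
    Anything else (including missing fields) is unclassified.
    """
    for v, name in ((tsh, "tsh"), (ft4, "ft4"), (age, "age")):
        if v is not None and v < 0:
            raise ValueError(f"{name} must be non-negative")
    tgaa_pos = tgaa is not None and str(tgaa).upper() in ("POS", "POSITIVE", "1")
    tgaa_neg = tgaa is not None and str(tgaa).upper() in ("NEG", "NEGATIVE", "0")
    if tgaa_pos or (tsh is not None and tsh >= 40):
        return "case"
    if (
        tgaa_neg
        and tsh is not None
        and tsh <= 25
        and ft4 is not None
        and ft4 >= 5
        and age is not None
        and age >= 7
    ):
        return "control"
    return "unclassified"


# ------------------------------------------------------------ depth tracks


@dataclass
class DepthSimConfig:
    """Parameters of the per-base depth simulation.

    ``mean_coverage`` maps sample id to that sample's genome-wide mean
    fold-coverage.  ``coverage_sd`` documents the spread used when building
    the map from a group mean (see :meth:`from_groups`).  Depth is Poisson
    per base with a sinusoidal GC-like modulation of relative amplitude
    ``gc_amplitude`` and period ``gc_period_bp``; inside ``q0_intervals``
    the draw is negative-binomial with doubled variance; inside
    ``gap_intervals`` depth is exactly zero.  Deletion carriers' depth over
    ``deletion_interval`` is scaled by copies/2.
    """

    chrom: str = "chr11"
    chrom_length: int = 200_000
    mean_coverage: dict[str, float] = field(default_factory=dict)
    coverage_sd: float = 1.0
    deletion_interval: GenomicInterval | None = None
    deletion_af_case: float = 0.0
    deletion_af_control: float = 0.0
    gap_intervals: list[GenomicInterval] = field(default_factory=list)
    q0_intervals: list[GenomicInterval] = field(default_factory=list)
    gc_amplitude: float = 0.1
    gc_period_bp: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        for cov in self.mean_coverage.values():
            if cov <= 0:
                raise ValueError("coverage must be positive")
        if not (0.0 <= self.gc_amplitude < 1.0):
            raise ValueError("gc_amplitude must be in [0, 1)")
        for iv in [self.deletion_interval, *self.gap_intervals, *self.q0_intervals]:
            if iv is not None and not (1 <= iv.start <= iv.end <= self.chrom_length):
                raise ValueError(f"interval {iv} outside [1, {self.chrom_length}]")
        if (
            self.deletion_interval is not None
            and self.deletion_interval.span >= self.chrom_length
        ):
            raise ValueError("deletion must not span the whole chromosome")

    @classmethod
    def from_groups(
        cls,
        samples: dict[str, str],
        mean_by_group: dict[str, float],
        coverage_sd: float = 1.0,
        seed: int = 0,
        **kwargs,
    ) -> "DepthSimConfig":
        """Build the per-sample coverage map from group means.

        ``samples`` maps sample id to its sequencing group (e.g. "HC"/"LC");
        each sample's mean is drawn N(group mean, coverage_sd), floored at
        0.5X.  Defaults emulate a 46X high-coverage group (SD 2.9) and a
        6.8X low-coverage group (SD 1.0) when those means are supplied.
        """
        rng = np.random.default_rng(seed)
        cov = {
            s: max(0.5, float(rng.normal(mean_by_group[g], coverage_sd)))
            for s, g in samples.items()
        }
        return cls(mean_coverage=cov, coverage_sd=coverage_sd, seed=seed, **kwargs)


def simulate_depth(
    cfg: DepthSimConfig,
    cohort: PhenotypeTable,
    deletion_alleles: dict[str, int] | None = None,
) -> tuple[dict[str, DepthTrack], dict]:
    """Simulate per-base depth tracks for every sample in the coverage map.

    Deletion-allele counts are drawn Binomial(2, group AF) unless
    ``deletion_alleles`` pins them explicitly (e.g. to put the deletion in
    perfect LD with a simulated SNP haplotype).  Returns the tracks and a
    truth record with each sample's number of non-deleted copies over the
    deletion interval (2 = NoDel/NoDel, 1 = Del/+, 0 = Del/Del) plus the
    gap and q0 masks.
    """
    if not cfg.mean_coverage:
        raise ValueError("mean_coverage map is empty")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.chrom_length
    pos = np.arange(1, n + 1)
    modulation = 1.0 + cfg.gc_amplitude * np.sin(
        2.0 * math.pi * pos / cfg.gc_period_bp
    )

    gap_mask = np.zeros(n, dtype=bool)
    for iv in cfg.gap_intervals:
        gap_mask[iv.start - 1 : iv.end] = True
    q0_mask = np.zeros(n, dtype=bool)
    for iv in cfg.q0_intervals:
        q0_mask[iv.start - 1 : iv.end] = True

    copies: dict[str, int] = {}
    status = cohort.table["status"] if cohort is not None else None
    tracks: dict[str, DepthTrack] = {}
    for sample, mean_cov in cfg.mean_coverage.items():
        if cfg.deletion_interval is None:
            n_del = 0
        elif deletion_alleles is not None:
            n_del = int(deletion_alleles.get(sample, 0))
        else:
            if status is not None and sample in status.index:
                af = (
                    cfg.deletion_af_case
                    if status.loc[sample] == 1
                    else cfg.deletion_af_control
                )
            else:
                af = 0.0
            n_del = int(rng.binomial(2, af))
        copies[sample] = 2 - n_del

        lam = mean_cov * modulation
        if cfg.deletion_interval is not None and n_del > 0:
            d = cfg.deletion_interval
            lam = lam.copy()
            lam[d.start - 1 : d.end] *= copies[sample] / 2.0
        depth = rng.poisson(lam).astype(float)
        if q0_mask.any():
            lam_q0 = np.maximum(lam[q0_mask], 1e-9)
            # negative binomial with p=1/2: mean lam, variance 2*lam
            depth[q0_mask] = rng.negative_binomial(lam_q0, 0.5)
        depth[gap_mask] = 0.0
        tracks[sample] = DepthTrack(cfg.chrom, depth)

    truth = {
        "deletion_interval": cfg.deletion_interval,
        "copies": copies,
        "gap_intervals": list(cfg.gap_intervals),
        "q0_intervals": list(cfg.q0_intervals),
        "seed": cfg.seed,
    }
    return tracks, truth


# ------------------------------------------------------------ fixture bundle


def write_fixture_bundle(
    cohort: tuple[GenotypeMatrix, PhenotypeTable, dict],
    depth: tuple[dict[str, DepthTrack], dict] | None,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write a complete on-disk fixture: VCF + TSV genotypes, phenotype TSV,
    bedGraph depth per sample, BED masks and a JSON truth record.

    Round-tripping any file through :mod:`depthdiff.io` reproduces the
    in-memory objects.
    """
    G, P, truth = cohort
    if G.n_samples == 0 or G.n_markers == 0:
        raise ValueError("cannot write an empty cohort")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["vcf"] = outdir / "genotypes.vcf"
    dio.write_vcf(G, paths["vcf"])
    paths["dosage"] = outdir / "genotypes.tsv"
    dio.write_dosage_tsv(G, paths["dosage"])
    paths["phenotypes"] = outdir / "phenotypes.tsv"
    dio.write_phenotypes(P, paths["phenotypes"])

    full_truth = dict(truth)
    if depth is not None:
        tracks, dtruth = depth
        ddir = outdir / "depth"
        ddir.mkdir(exist_ok=True)
        for sample, track in tracks.items():
            p = ddir / f"{sample}.bedGraph"
            dio.write_bedgraph(track, p)
            paths[f"depth/{sample}"] = p
        paths["gaps"] = outdir / "gaps.bed"
        dio.write_bed(dtruth.get("gap_intervals", []), paths["gaps"])
        paths["q0"] = outdir / "q0.bed"
        dio.write_bed(dtruth.get("q0_intervals", []), paths["q0"])
        if dtruth.get("deletion_interval") is not None:
            paths["deletion"] = outdir / "deletion_truth.bed"
            dio.write_bed([dtruth["deletion_interval"]], paths["deletion"])
        full_truth["depth"] = {
            "copies": dtruth.get("copies", {}),
            "deletion_interval": dtruth.get("deletion_interval"),
        }

    paths["truth"] = outdir / "truth.json"
    dio.write_json(full_truth, paths["truth"])
    return paths
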
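"""End-to-end orchestration of the discovery chain on one config.

Stage order mirrors the analysis narrative: simulate (or load) a cohort,
genotype QC, kinship-corrected GWAS, LD locus definition, windowed
read-depth CNV scan, and depth-based deletion association.  Every stage
writes its outputs under the run directory and the pipeline records a
manifest with parameters, seeds and per-output SHA-256 checksums, so a
rerun with the same config and seed is byte-reproducible.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import cnv, deletion, gwas, io as dio, locus, qc, synthetic
from .core import GenomicInterval


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortParams(_Strict):
    n_cases: int = 71
    n_controls: int = 36
    n_markers: int = 500
    protective_maf_case: float = 0.05
    protective_maf_control: float = 0.26
    ld_block_length: int = 200_000
    kinship_families: int = 0


class DepthParams(_Strict):
    chrom_length: int = 1_000_000
    hc_coverage: float = 46.0
    hc_coverage_sd: float = 2.9
    lc_coverage: float = 6.8
    lc_coverage_sd: float = 1.0
    n_lc_cases: int = 10
    n_lc_controls: int = 10
    deletion_start: int = 600_001
    deletion_length: int = 8875
    gc_amplitude: float = 0.05


class StageToggles(_Strict):
    simulate: bool = True
    qc: bool = True
    gwas: bool = True
    locus: bool = True
    cnv_scan: bool = True
    del_assoc: bool = True


class PipelineConfig(_Strict):
    """Schema-validated pipeline configuration; unknown keys are rejected."""

    outdir: str = "depthdiff_run"
    seed: int = 0
    stages: StageToggles = Field(default_factory=StageToggles)
    cohort: CohortParams = Field(default_factory=CohortParams)
    depth: DepthParams = Field(default_factory=DepthParams)
    n_permutations: int = 200
    r2_threshold: float = 0.8
    window_bp: int = 1000
    min_window_depth: float = 2.0
    cnv_p_max: float = 0.001
    cnv_len_min: int = 1000
    cnv_q0_max: float = 0.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order; returns the manifest dict.

    Raises on the first stage failure; a missing required input from a
    disabled upstream stage raises ``FileNotFoundError`` naming it.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.model_dump(),
        "seed": config.seed,
        "stages": [],
    }

    def record(stage: str, outputs: dict[str, Path], **extras) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "outputs": {k: str(p) for k, p in outputs.items()},
                "checksums": {k: _sha256(Path(p)) for k, p in outputs.items()},
                **extras,
            }
        )

    sim_dir = out / "sim"

    if config.stages.simulate:
        c = config.cohort
        ccfg = synthetic.CohortConfig(
            n_cases=c.n_cases,
            n_controls=c.n_controls,
            n_markers=c.n_markers,
            protective_maf_case=c.protective_maf_case,
            protective_maf_control=c.protective_maf_control,
            ld_block_length=c.ld_block_length,
            kinship_families=c.kinship_families,
            seed=config.seed,
        )
        G, P, truth = synthetic.simulate_cohort(ccfg)

        d = config.depth
        # deletion in perfect LD with the protective haplotype: allele count
        # equals the protective-marker dosage of each sequenced sample
        prot = G.dosage_of(truth["protective_marker"])
        dos = dict(zip(G.samples, prot))
        # resequencing design: the HC control is homozygous for the
        # protective haplotype, LC controls are heterozygous, and all
        # sequenced cases carry the non-protective haplotype
        ctrl_hom_first = sorted(P.controls, key=lambda s: (-dos[s], s))
        hc_ctrl = ctrl_hom_first[0]
        ctrl_het_first = sorted(
            (s for s in P.controls if s != hc_ctrl),
            key=lambda s: (abs(dos[s] - 1), s),
        )
        case_by_dos = sorted(P.cases, key=lambda s: (dos[s], s))
        lc = case_by_dos[: d.n_lc_cases] + ctrl_het_first[: d.n_lc_controls]
        hc = case_by_dos[d.n_lc_cases : d.n_lc_cases + 2] + [hc_ctrl]
        groups = {s: "LC" for s in lc} | {s: "HC" for s in hc}
        rng = np.random.default_rng(config.seed + 1)
        cov = {
            s: max(
                0.5,
                float(
                    rng.normal(
                        d.hc_coverage if g == "HC" else d.lc_coverage,
                        d.hc_coverage_sd if g == "HC" else d.lc_coverage_sd,
                    )
                ),
            )
            for s, g in groups.items()
        }
        P.table.loc[list(groups), "seq_group"] = [groups[s] for s in groups]
        del_iv = GenomicInterval(
            "chr11", d.deletion_start, d.deletion_start + d.deletion_length - 1
        )
        gap = GenomicInterval("chr11", d.deletion_start - 700, d.deletion_start + 300)
        q0 = GenomicInterval("chr11", 20_001, 24_000)
        dcfg = synthetic.DepthSimConfig(
            chrom_length=d.chrom_length,
            mean_coverage=cov,
            deletion_interval=del_iv,
            gap_intervals=[gap],
            q0_intervals=[q0],
            gc_amplitude=d.gc_amplitude,
            seed=config.seed + 2,
        )
        alleles = {s: int(round(dos[s])) for s in groups}
        tracks, dtruth = synthetic.simulate_depth(dcfg, P, deletion_alleles=alleles)
        paths = synthetic.write_fixture_bundle((G, P, truth), (tracks, dtruth), sim_dir)
        record("simulate", paths, n_samples=G.n_samples, n_markers=G.n_markers)

    geno_path = sim_dir / "genotypes.vcf"
    pheno_path = sim_dir / "phenotypes.tsv"
    for p in (geno_path, pheno_path):
        if not p.exists():
            raise FileNotFoundError(f"required input missing: {p}")
    G = dio.read_vcf(geno_path)
    P = dio.read_phenotypes(pheno_path)

    if config.stages.qc:
        Gq, report = qc.marker_qc(G, P, qc.QcThresholds())
        K = qc.compute_kinship(Gq)
        coords = qc.mds_from_kinship(K, dims=2)
        qc_dir = out / "qc"
        qc_dir.mkdir(exist_ok=True)
        report.to_csv(qc_dir / "qc_report.tsv", sep="\t", index=False)
        coords.to_csv(qc_dir / "mds.tsv", sep="\t", index_label="sample")
        record(
            "qc",
            {"report": qc_dir / "qc_report.tsv", "mds": qc_dir / "mds.tsv"},
            n_markers_kept=Gq.n_markers,
        )
        G = Gq
    else:
        K = qc.compute_kinship(G)

    assoc = None
    if config.stages.gwas:
        y = P.status_vector(G.samples)
        fit = gwas.fit_polygenic(y, K.loc[G.samples, G.samples])
        assoc = gwas.mm_score_test(G, fit)
        summary = gwas.empirical_significance(
            G, y, fit, n_perm=config.n_permutations, seed=config.seed + 3
        )
        gdir = out / "gwas"
        gdir.mkdir(exist_ok=True)
        assoc.table.to_csv(gdir / "assoc.tsv", sep="\t", index_label="marker")
        dio.write_json(
            {
                "lambda_gc": summary.lambda_gc,
                "empirical_threshold": summary.empirical_threshold,
                "h2": fit.h2,
                "top_marker": assoc.top_marker(),
                "top_p": float(assoc.table["p"].min()),
            },
            gdir / "summary.json",
        )
        record(
            "gwas",
            {"assoc": gdir / "assoc.tsv", "summary": gdir / "summary.json"},
            lambda_gc=summary.lambda_gc,
        )

    if config.stages.locus:
        if assoc is None:
            raise FileNotFoundError("locus stage requires the gwas stage output")
        anchor = assoc.top_marker()
        iv = locus.define_locus(G, anchor, config.r2_threshold)
        prof = locus.ld_profile(G, anchor)
        ldir = out / "locus"
        ldir.mkdir(exist_ok=True)
        dio.write_bed([iv], ldir / "locus.bed")
        prof.to_csv(ldir / "ld.tsv", sep="\t")
        record(
            "locus",
            {"bed": ldir / "locus.bed", "ld": ldir / "ld.tsv"},
            anchor=anchor,
            span_bp=iv.span,
        )

    wt = None
    scan = None
    if config.stages.cnv_scan:
        lc_samples = [
            s for s in P.samples if P.table.loc[s, "seq_group"] == "LC"
        ]
        tracks = {
            s: dio.read_bedgraph(sim_dir / "depth" / f"{s}.bedGraph")
            for s in lc_samples
        }
        if not tracks:
            raise FileNotFoundError("cnv_scan stage found no LC depth tracks")
        q0_ivs = dio.read_bed(sim_dir / "q0.bed")
        gaps = dio.read_bed(sim_dir / "gaps.bed")
        wt = cnv.window_depth(tracks, config.window_bp, q0_intervals=q0_ivs)
        cnv.normalize_windows(wt)
        cnv.exclude_windows(wt, config.min_window_depth)
        case_ids = [s for s in lc_samples if P.table.loc[s, "status"] == 1]
        ctrl_ids = [s for s in lc_samples if P.table.loc[s, "status"] == 0]
        scan = cnv.window_group_test(wt, case_ids, ctrl_ids)
        mv = cnv.m_values(wt, case_ids)
        calls = [c for s in wt.samples for c in cnv.call_cnvs(wt, s)]
        kept, removed = cnv.filter_calls(
            calls,
            gaps,
            p_max=config.cnv_p_max,
            len_min=config.cnv_len_min,
            q0_max=config.cnv_q0_max,
        )
        cdir = out / "cnv"
        cdir.mkdir(exist_ok=True)
        scan.table.to_csv(cdir / "windows.tsv", sep="\t", index=False)
        mv.to_csv(cdir / "mvalues.tsv", sep="\t", index_label="sample")
        import pandas as pd

        pd.DataFrame(
            [
                {
                    "sample": c.sample,
                    "interval": str(c.interval),
                    "type": c.kind,
                    "normalized_rd": c.normalized_rd,
                    "p_mean_diff": c.p_mean_diff,
                    "q0": c.q0,
                }
                for c in kept
            ]
        ).to_csv(cdir / "cnv_calls.tsv", sep="\t", index=False)
        removed.to_csv(cdir / "cnv_filtered_out.tsv", sep="\t", index=False)
        record(
            "cnv_scan",
            {
                "windows": cdir / "windows.tsv",
                "mvalues": cdir / "mvalues.tsv",
                "calls": cdir / "cnv_calls.tsv",
                "filtered": cdir / "cnv_filtered_out.tsv",
            },
            n_tested=scan.n_tested,
            bonferroni=scan.bonferroni_threshold,
            n_significant_runs=len(scan.significant_runs),
        )

    if config.stages.del_assoc:
        if wt is None or scan is None:
            raise FileNotFoundError("del_assoc stage requires the cnv_scan stage")
        if scan.significant_runs:
            first, last = max(
                scan.significant_runs, key=lambda r: r[1] - r[0]
            )
            del_iv = GenomicInterval(
                wt.chrom, int(wt.starts[first]), int(wt.ends[last])
            )
        else:
            del_iv = dio.read_bed(sim_dir / "deletion_truth.bed")[0]
        genos = {
            s: deletion.genotype_from_depth(wt, s, del_iv).copies
            for s in wt.samples
        }
        status = {s: int(P.table.loc[s, "status"]) for s in wt.samples}
        tab = deletion.allele_table(genos, status)
        fisher = deletion.fisher_allelic(tab)
        truth = dio.read_json(sim_dir / "truth.json")
        prot_dos = {
            s: float(G.dosage_of(truth["protective_marker"])[G.samples.index(s)])
            for s in wt.samples
            if s in G.samples
        }
        seg = deletion.segregation_concordance(genos, prot_dos, status)
        ddir = out / "deletion"
        ddir.mkdir(exist_ok=True)
        dio.write_json(
            {
                "interval": del_iv,
                "genotypes": genos,
                "allele_table": tab,
                "fisher": fisher,
                "segregation": seg,
            },
            ddir / "deletion.json",
        )
        record(
            "del_assoc",
            {"deletion": ddir / "deletion.json"},
            p=fisher["p"],
            odds_ratio=fisher["or"],
        )

    dio.write_json(manifest, out / "manifest.json")
    return manifest
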
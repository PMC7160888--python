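"""Readers and writers for the plain-text formats the pipeline exchanges.

VCF is read through cyvcf2; writing goes through a minimal text writer
because the matrices produced here carry only GT fields.  BED files are
0-based half-open on disk and converted to the package-wide 1-based
inclusive convention on read (and back on write).  bedGraph intervals are
likewise 0-based half-open per the UCSC definition.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import DepthTrack, GenomicInterval, GenotypeMatrix, PhenotypeTable

# ---------------------------------------------------------------- genotypes


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as an uncompressed VCF with GT-only FORMAT."""
    path = Path(path)
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=depthdiff\n")
        for chrom in pd.unique(g.marker_map["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        ref = g.marker_map.get("ref", pd.Series("A", index=g.marker_map.index))
        alt = g.marker_map.get("alt", pd.Series("G", index=g.marker_map.index))
        for j, (mid, row) in enumerate(g.marker_map.iterrows()):
            calls = [
                "./." if np.isnan(d) else gt_codes[int(d)] for d in g.dosage[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{mid}\t{ref.loc[mid]}\t"
                f"{alt.loc[mid]}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix of alt-allele dosages."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    for i, var in enumerate(vcf):
        ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = np.array(var.gt_types, dtype=float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        rows.append(dos)
    vcf.close()
    marker_map = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts},
        index=pd.Index(ids, name="marker"),
    )
    return GenotypeMatrix(samples, marker_map, np.array(rows).T)


def write_dosage_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(g.dosage.T, index=g.marker_map.index, columns=g.samples)
    out = pd.concat([g.marker_map[["chrom", "pos"]], df], axis=1)
    out.to_csv(path, sep="\t", index_label="marker")


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="marker")
    samples = [c for c in df.columns if c not in ("chrom", "pos", "ref", "alt")]
    mm_cols = [c for c in ("chrom", "pos", "ref", "alt") if c in df.columns]
    return GenotypeMatrix(samples, df[mm_cols].copy(), df[samples].to_numpy().T)


# ---------------------------------------------------------------- phenotypes


def write_phenotypes(p: PhenotypeTable, path: str | Path) -> None:
    p.table.to_csv(path, sep="\t", index_label="sample")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t", index_col="sample"))


# ------------------------------------------------------------ depth & masks


def write_bedgraph(track: DepthTrack, path: str | Path) -> None:
    """Run-length-encode per-base depth as bedGraph (0-based half-open)."""
    d = np.asarray(track.depth)
    change = np.flatnonzero(np.diff(d)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [d.size]])
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            fh.write(f"{track.chrom}\t{s}\t{e}\t{d[s]:g}\n")


def read_bedgraph(path: str | Path, length: int | None = None) -> DepthTrack:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
    )
    if df.empty:
        raise ValueError(f"empty bedGraph: {path}")
    chrom = str(df["chrom"].iloc[0])
    n = length if length is not None else int(df["end"].max())
    depth = np.zeros(n, dtype=float)
    for s, e, v in zip(df["start"], df["end"], df["value"]):
        depth[int(s) : int(e)] = v
    return DepthTrack(chrom, depth)


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    """Write 1-based inclusive intervals as standard 0-based half-open BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append(GenomicInterval(chrom, int(start) + 1, int(end)))
    return out


# ----------------------------------------------------------------- generic


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, GenomicInterval):
        return {"chrom": o.chrom, "start": o.start, "end": o.end}
    raise TypeError(f"not JSON serializable: {type(o)}")
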
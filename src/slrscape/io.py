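"""Readers and writers for the standard text formats the pipeline exchanges.

Internally everything is 0-based half-open; conversions to 1-based (VCF,
GFF3) happen here at the boundary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import decode
from .pch_compartments import ContactMatrix
from .sexlink_scan import HET, HOM_ALT, HOM_REF, MISSING, VariantTable
from .synthetic_data import Gene, GenomeBundle

_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
_GT_CODE = {v: k for k, v in _GT_STR.items()}
_GT_CODE.update({"1/0": HET, "0|1": HET, "1|0": HET, "0|0": HOM_REF, "1|1": HOM_ALT})


def write_fasta(path, records: dict[str, object], width: int = 60) -> None:
    """Write sequences (str or 2-bit code arrays) to FASTA."""
    with open(path, "w") as fh:
        for name, seq in records.items():
            if isinstance(seq, np.ndarray):
                seq = decode(seq)
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_bed(path, df: pd.DataFrame, columns=("chrom", "start", "end")) -> None:
    df[list(columns)].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, names=("chrom", "start", "end"), extra=()) -> pd.DataFrame:
    cols = list(names) + list(extra)
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(cols)]
    df.columns = cols
    return df


def write_genes_gff3(path, genes: list[Gene]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tslrscape\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\tID={g.name}\n"
            )
            for i, (s, e) in enumerate(g.exons):
                fh.write(
                    f"{g.chrom}\tslrscape\texon\t{s + 1}\t{e}\t.\t+\t.\t"
                    f"ID={g.name}.e{i};Parent={g.name}\n"
                )


def read_genes_gff3(path) -> list[Gene]:
    genes: dict[str, Gene] = {}
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("#") or not raw.strip():
                continue
            f = raw.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"malformed GFF3 line: {raw!r}")
            chrom, _, ftype, start, end, _, _, _, attrs = f[:9]
            tags = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = tags["ID"]
                genes[gid] = Gene(gid, chrom, int(start) - 1, int(end), [])
            elif ftype == "exon":
                parent = tags.get("Parent")
                if parent in genes:
                    genes[parent].exons.append((int(start) - 1, int(end)))
    for g in genes.values():
        g.exons.sort()
    return list(genes.values())


def write_vcf(path, vt: VariantTable) -> None:
    """GT-only VCFv4.2 (1-based positions)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in vt.sites.chrom.unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(vt.samples)
            + "\n"
        )
        g = vt.genotypes
        for i, row in enumerate(vt.sites.itertuples()):
            gts = "\t".join(_GT_STR[int(x)] for x in g[i])
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path, sex: dict[str, str]) -> VariantTable:
    from cyvcf2 import VCF

    v = VCF(str(path), gts012=True)
    samples = list(v.samples)
    rows, genos = [], []
    for rec in v:
        if len(rec.ALT) != 1:
            continue  # biallelic only
        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        gt = rec.gt_types.astype(np.int8)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt[gt == 3] = MISSING
        genos.append(gt)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    g = np.vstack(genos) if genos else np.empty((0, len(samples)), dtype=np.int8)
    return VariantTable(sites, g, samples, {s: sex[s] for s in samples})


def read_sex_tsv(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "sex"])
    return dict(zip(df["sample"], df["sex"]))


def write_contact_matrix(path, cm: ContactMatrix) -> None:
    """Upper-triangle 3-column text (bin_i, bin_j, count) + JSON sidecar."""
    iu, ju = np.triu_indices(cm.n_bins)
    vals = cm.counts[iu, ju]
    nz = vals != 0
    pd.DataFrame({"bin_i": iu[nz], "bin_j": ju[nz], "count": vals[nz]}).to_csv(
        path, sep="\t", header=False, index=False, float_format="%.6g"
    )
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(
        json.dumps(
            {"chromosome": cm.chromosome, "bin_size": cm.bin_size, "n_bins": cm.n_bins}
        )
    )


def read_contact_matrix(path) -> ContactMatrix:
    side = json.loads(Path(str(path) + ".json").read_text())
    df = pd.read_csv(path, sep="\t", header=None, names=["bin_i", "bin_j", "count"])
    n = side["n_bins"]
    m = np.zeros((n, n))
    m[df.bin_i, df.bin_j] = df["count"]
    m[df.bin_j, df.bin_i] = df["count"]
    return ContactMatrix(side["chromosome"], side["bin_size"], m)


def write_bundle(bundle: GenomeBundle, outdir) -> dict[str, Path]:
    """Write a bundle's files (FASTA skipped in track-only mode)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if bundle.sequences:
        recs = {}
        for chrom in bundle.sequences:
            h1, h2 = bundle.haplotypes(chrom)
            recs[f"{chrom}_X"] = h1
            recs[f"{chrom}_Y"] = h2
        paths["fasta"] = out / "genome.fa"
        write_fasta(paths["fasta"], recs)
    paths["meta"] = out / "chromosomes.tsv"
    bundle.meta.to_csv(paths["meta"], sep="\t", index=False)
    paths["repeats"] = out / "repeats.bed"
    write_bed(paths["repeats"], bundle.repeat_track, ("chrom", "start", "end", "label"))
    paths["genes"] = out / "genes.gff3"
    write_genes_gff3(paths["genes"], bundle.genes)
    paths["pch_truth"] = out / "pch_truth.bed"
    write_bed(paths["pch_truth"], bundle.truth["pch"])
    cen = bundle.meta[["chrom", "cen_start", "cen_end"]].rename(
        columns={"cen_start": "start", "cen_end": "end"}
    )
    paths["centromeres"] = out / "centromeres.bed"
    write_bed(paths["centromeres"], cen)
    return paths
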
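"""File formats: minimal VCF, cytosine-report TSV, GFF3/BED, metadata.

Internal coordinates are 1-based inclusive; BED is written 0-based
half-open and converted back on read.  The VCF dialect is deliberately
minimal: biallelic sites with homozygous (haploid-coded) genotypes for
inbred accessions.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import AnnotationSet, GenotypeTable, MethylCounts


# --------------------------------------------------------------------------
# genotypes

def write_vcf(g: GenotypeTable, path: str | os.PathLike) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=methclime\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.accessions) + "\n")
        geno = g.genotypes
        for j in range(g.n_snps):
            row = g.snps.iloc[j]
            calls = "\t".join(
                "." if geno[i, j] < 0 else str(int(geno[i, j]))
                for i in range(g.n_accessions))
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\tA\tT\t.\t"
                     f"PASS\t.\tGT\t{calls}\n")


def read_vcf(path: str | os.PathLike,
             metadata: pd.DataFrame | None = None) -> GenotypeTable:
    accessions: list[str] = []
    chroms, poss, ids, rows = [], [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                accessions = parts[9:]
                continue
            chroms.append(parts[0])
            poss.append(int(parts[1]))
            ids.append(parts[2])
            rows.append([
                -1 if c in (".", "./.") else int(c.split("/")[0])
                for c in parts[9:]
            ])
    geno = np.array(rows, dtype=np.int8).T if rows else np.empty((len(accessions), 0), np.int8)
    snps = pd.DataFrame({"chrom": chroms, "pos": poss, "id": ids})
    if metadata is None:
        metadata = pd.DataFrame(index=accessions)
    return GenotypeTable(geno, snps, accessions, metadata)


def write_genotype_table(g: GenotypeTable, path: str | os.PathLike) -> None:
    """Simple tabular dialect: SNPs as rows, accessions as columns."""
    df = pd.DataFrame(g.genotypes.T, columns=g.accessions)
    out = pd.concat([g.snps.reset_index(drop=True), df], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_genotype_table(path: str | os.PathLike,
                        metadata: pd.DataFrame | None = None) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t")
    snps = df[["chrom", "pos", "id"]].copy()
    acc = [c for c in df.columns if c not in ("chrom", "pos", "id")]
    geno = df[acc].to_numpy(dtype=np.int8).T
    if metadata is None:
        metadata = pd.DataFrame(index=acc)
    return GenotypeTable(geno, snps, acc, metadata)


# --------------------------------------------------------------------------
# methylomes: per-sample cytosine report TSV

REPORT_COLUMNS = ["chrom", "pos", "strand", "context", "meth", "total"]


def write_cytosine_reports(counts: MethylCounts, outdir: str | os.PathLike
                           ) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if counts.n_samples == 0:
        raise ValueError("no samples to write")
    paths = []
    for k in range(counts.n_samples):
        acc = counts.samples.iloc[k]["accession"]
        env = counts.samples.iloc[k]["environment"]
        df = counts.sites.copy()
        df["meth"] = counts.meth[:, k]
        df["total"] = counts.total[:, k]
        p = outdir / f"{acc}_{env}.cx.tsv"
        df[REPORT_COLUMNS].to_csv(p, sep="\t", index=False)
        paths.append(p)
    return paths


def read_cytosine_reports(paths: list[str | os.PathLike]) -> MethylCounts:
    sites = None
    meths, totals, samples = [], [], []
    for p in paths:
        name = Path(p).name.replace(".cx.tsv", "")
        acc, env = name.rsplit("_", 1)
        df = pd.read_csv(p, sep="\t")
        s = df[["chrom", "pos", "strand", "context"]]
        if sites is None:
            sites = s.reset_index(drop=True)
        elif not sites.equals(s.reset_index(drop=True)):
            raise ValueError(f"site table of {p} differs from the first file")
        meths.append(df["meth"].to_numpy(np.int32))
        totals.append(df["total"].to_numpy(np.int32))
        samples.append((acc, env))
    return MethylCounts(
        sites=sites,
        meth=np.stack(meths, axis=1),
        total=np.stack(totals, axis=1),
        samples=pd.DataFrame(samples, columns=["accession", "environment"]),
    )


# --------------------------------------------------------------------------
# annotations

def write_gff3(annot: AnnotationSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c, size in annot.chrom_sizes.items():
            fh.write(f"##sequence-region {c} 1 {size}\n")
        for _, r in annot.features.iterrows():
            typ = "gene" if r["kind"] == "gene" else "transposable_element"
            attrs = f"ID={r['id']}"
            if r["kind"] == "te":
                attrs += (f";family={r['family']};superfamily={r['superfamily']}"
                          f";variable={int(bool(r['variable']))}")
            fh.write(f"{r['chrom']}\tmethclime\t{typ}\t{r['start']}\t{r['end']}"
                     f"\t.\t+\t.\t{attrs}\n")


def read_gff3(path: str | os.PathLike, chloroplast: str = "ChrC"
              ) -> AnnotationSet:
    chrom_sizes: dict[str, int] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                _, c, _, size = line.split()
                chrom_sizes[c] = int(size)
                continue
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            kind = "gene" if f[2] == "gene" else "te"
            rows.append((f[0], int(f[3]), int(f[4]), kind,
                         attrs.get("family", ""), attrs.get("superfamily", ""),
                         bool(int(attrs.get("variable", "0"))), attrs["ID"]))
    feats = pd.DataFrame(rows, columns=["chrom", "start", "end", "kind",
                                        "family", "superfamily", "variable",
                                        "id"])
    return AnnotationSet(feats, chrom_sizes, chloroplast)


def write_bed(intervals: pd.DataFrame, path: str | os.PathLike,
              score: np.ndarray | None = None) -> None:
    """1-based inclusive intervals -> BED6 (0-based half-open)."""
    df = pd.DataFrame({
        "chrom": intervals["chrom"],
        "start": intervals["start"].astype(int) - 1,
        "end": intervals["end"].astype(int),
        "name": intervals["id"] if "id" in intervals else ".",
        "score": 0.0 if score is None else score,
        "strand": ".",
    })
    df.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """BED -> 1-based inclusive DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "id", "score", "strand"],
                     usecols=range(6))
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return df


def write_metadata(metadata: pd.DataFrame, path: str | os.PathLike) -> None:
    metadata.rename_axis("accession").to_csv(path, sep="\t")


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="accession")


# --------------------------------------------------------------------------
# fixture bundle

def write_fixtures(outputs: dict, outdir: str | os.PathLike) -> dict:
    """Write a full simulated dataset to ``outdir``; returns path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g: GenotypeTable = outputs["genotypes"]
    if not g.accessions:
        raise ValueError("empty accession list; nothing to write")
    annot: AnnotationSet = outputs["annotations"]
    counts: MethylCounts = outputs["methylomes"]
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "genotypes_tsv": outdir / "genotypes.tsv",
        "gff": outdir / "annotations.gff3",
        "bed": outdir / "annotations.bed",
        "metadata": outdir / "metadata.tsv",
    }
    write_vcf(g, paths["vcf"])
    write_genotype_table(g, paths["genotypes_tsv"])
    write_gff3(annot, paths["gff"])
    write_bed(annot.features, paths["bed"])
    write_metadata(g.metadata, paths["metadata"])
    paths["reports"] = write_cytosine_reports(counts, outdir / "methylomes")
    if "expression" in outputs and outputs["expression"] is not None:
        p = outdir / "expression.tsv"
        outputs["expression"].to_csv(p, sep="\t", index=False)
        paths["expression"] = p
    return paths
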
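"""Readers and writers for the tabular and genomic formats the pipeline uses.

Canonical tabular dialect: tab-delimited, header row, UTF-8, ``NA`` or ``.``
for missing values.  Count tables are wide: ``gene_id``, ``feature_id``, then
one integer column per sample.  Genotypes come from VCF (GT field, bi-allelic
rows only) or an equivalent TSV; gene ranges from GFF3 or BED.
"""

from __future__ import annotations

import json
import os
import sys
import warnings

import numpy as np
import pandas as pd

from .data import GeneCounts
from .qtl import GeneRegion, SnpRecord

__all__ = [
    "read_counts", "write_counts", "dataset_from_frame", "dataset_to_frame",
    "read_design", "read_genotypes", "read_regions", "write_metadata",
]

_MISSING = {"NA", ".", ""}


def dataset_from_frame(df: pd.DataFrame):
    """Convert a wide count table into per-gene :class:`GeneCounts`."""
    if "gene_id" not in df.columns or "feature_id" not in df.columns:
        raise ValueError("count table needs gene_id and feature_id columns")
    sample_cols = [c for c in df.columns if c not in ("gene_id", "feature_id")]
    if not sample_cols:
        raise ValueError("count table has no sample columns")
    dup = df.duplicated(subset=["gene_id", "feature_id"])
    if dup.any():
        k = int(df.index[dup][0]) + 2  # +2: header line and 1-based numbering
        raise ValueError(f"duplicate (gene_id, feature_id) pair at line {k}")
    for c in sample_cols:
        num = pd.to_numeric(df[c], errors="coerce")
        bad = num.isna() | (num != np.floor(num))
        if bad.any():
            k = int(df.index[bad][0]) + 2
            raise ValueError(f"non-integer count in column {c!r} at line {k}")
        if (num < 0).any():
            k = int(df.index[num < 0][0]) + 2
            raise ValueError(f"negative count in column {c!r} at line {k}")
        df[c] = num.astype(np.int64)
    genes = []
    for gid, sub in df.groupby("gene_id", sort=False):
        genes.append(GeneCounts(
            gene_id=str(gid),
            feature_ids=[str(f) for f in sub["feature_id"]],
            sample_ids=[str(c) for c in sample_cols],
            counts=sub[sample_cols].to_numpy(dtype=np.int64),
        ))
    return genes


def dataset_to_frame(dataset) -> pd.DataFrame:
    frames = []
    for g in dataset:
        d = pd.DataFrame(g.counts, columns=g.sample_ids)
        d.insert(0, "feature_id", g.feature_ids)
        d.insert(0, "gene_id", g.gene_id)
        frames.append(d)
    return pd.concat(frames, ignore_index=True)


def read_counts(path):
    """Read a wide TSV count table; parse errors name the offending line."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "feature_id": str})
    except pd.errors.ParserError as e:
        raise ValueError(f"{path}: malformed TSV ({e})") from e
    return dataset_from_frame(df)


def write_counts(dataset, path) -> None:
    dataset_to_frame(dataset).to_csv(path, sep="\t", index=False)


def read_design(path) -> dict:
    """sample_id -> group map from a two-column TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise ValueError(f"{path}: design table needs sample_id and group columns")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in design")
    return dict(zip(df["sample_id"], df["group"]))


def _genotypes_from_vcf(path):
    import pysam

    snps, skipped_multiallelic = [], 0
    with pysam.VariantFile(os.fspath(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped_multiallelic += 1
                continue
            doses = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or len(gt) != 2 or None in gt:
                    doses.append(np.nan)  # half-calls and ./. are missing
                else:
                    doses.append(float(gt[0] + gt[1]))
            snp_id = rec.id or f"{rec.chrom}:{rec.pos}"
            snps.append(SnpRecord(snp_id, rec.chrom, rec.pos, samples,
                                  np.array(doses)))
    if skipped_multiallelic:
        warnings.warn(f"{path}: skipped {skipped_multiallelic} multi-allelic "
                      "VCF records (only bi-allelic SNPs are analysed)")
    return snps


def _genotypes_from_tsv(path):
    df = pd.read_csv(path, sep="\t", na_values=list(_MISSING), dtype={"chrom": str})
    needed = {"snp_id", "chrom", "pos"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: genotype TSV needs columns snp_id, chrom, pos")
    sample_cols = [c for c in df.columns if c not in needed]
    snps = []
    for _, row in df.iterrows():
        snps.append(SnpRecord(str(row["snp_id"]), str(row["chrom"]),
                              int(row["pos"]), sample_cols,
                              row[sample_cols].to_numpy(dtype=float)))
    return snps


def read_genotypes(path, format: str | None = None):
    """SNP dosages from VCF (GT -> alternate-allele dosage) or TSV."""
    if format is None:
        format = "vcf" if str(path).endswith((".vcf", ".vcf.gz", ".bcf")) else "tsv"
    if format == "vcf":
        return _genotypes_from_vcf(path)
    if format == "tsv":
        return _genotypes_from_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def read_regions(path, format: str | None = None):
    """Gene ranges from GFF3 (gene features) or BED, as 1-based inclusive."""
    import pyranges as pr

    if format is None:
        fmt = str(path).lower()
        format = "gff3" if fmt.endswith((".gff", ".gff3")) else "bed"
    if format == "gff3":
        df = pr.read_gff3(os.fspath(path)).df
        if "Feature" in df.columns:
            genes = df[df["Feature"] == "gene"]
            if genes.empty:
                genes = df
        else:
            genes = df
        out = []
        for _, row in genes.iterrows():
            gid = row.get("ID") or row.get("gene_id")
            if gid is None or (isinstance(gid, float) and np.isnan(gid)):
                raise ValueError(f"{path}: GFF3 gene record without ID/gene_id attribute")
            # pyranges stores 0-based starts; convert back to 1-based inclusive
            out.append(GeneRegion(str(gid), str(row["Chromosome"]),
                                  int(row["Start"]) + 1, int(row["End"])))
        return out
    if format == "bed":
        df = pr.read_bed(os.fspath(path)).df
        if "Name" not in df.columns:
            raise ValueError(f"{path}: BED needs a name column with gene ids")
        return [GeneRegion(str(r["Name"]), str(r["Chromosome"]),
                           int(r["Start"]) + 1, int(r["End"]))
                for _, r in df.iterrows()]
    raise ValueError(f"unknown region format {format!r}")


def write_metadata(path, **fields) -> None:
    """Run-metadata JSON: effective parameters, seed, package version."""
    from . import __version__

    meta = {"package": "dmusage", "version": __version__,
            "python": sys.version.split()[0]}
    meta.update(fields)
    tmp = f"{path}.tmp"
    with open(tmp, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    os.replace(tmp, path)
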
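"""Readers/writers for the plain-text formats the pipeline exchanges.

ALLC tables are the methylpy/ALLCools per-cytosine format: chrom, 1-based
position, strand, trinucleotide context, methylated count, total count, and a
flag column.  All interval files (blacklist, peaks, anchors) are BED, 0-based
half-open.  Genotypes travel as a dosage TSV (samples x SNPs) plus SNP
metadata, or as a minimal VCF with GT fields.  Summary statistics are TSV
with columns snp, chrom, pos, a1, a2, beta, se, p, maf, n.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

ALLC_COLUMNS = ["chrom", "pos", "strand", "context", "mc", "cov", "flag"]
SUMMARY_COLUMNS = ["snp", "chrom", "pos", "a1", "a2", "beta", "se", "p", "maf", "n"]


def read_allc(path, cell_id: str | None = None) -> pd.DataFrame:
    """Read one ALLC file (plain or gzip; no header). Adds cell_id if given."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=ALLC_COLUMNS,
        dtype={"chrom": str, "pos": np.int64, "mc": np.int64, "cov": np.int64},
        compression="infer",
    )
    if (df["mc"] > df["cov"]).any() or (df["mc"] < 0).any():
        raise ValueError(f"{path}: methylated counts must satisfy 0 <= mc <= cov")
    if cell_id is not None:
        df.insert(0, "cell_id", cell_id)
    return df


def write_allc(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "flag" not in out:
        out["flag"] = 1
    out[ALLC_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_allc_dir(directory) -> pd.DataFrame:
    """Read every ``*.allc.tsv[.gz]`` in a directory; cell id = file stem."""
    frames = []
    for path in sorted(Path(directory).glob("*.allc.tsv*")):
        cell = path.name.split(".allc.tsv")[0]
        frames.append(read_allc(path, cell_id=cell))
    if not frames:
        raise FileNotFoundError(f"no .allc.tsv files under {directory}")
    return pd.concat(frames, ignore_index=True)


def read_bed(path) -> pd.DataFrame:
    """BED3+ -> DataFrame with chrom/start/end (extra columns kept as name,...)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", compression="infer")
    names = ["chrom", "start", "end", "name", "score", "strand"]
    ncol = df.shape[1]
    df.columns = names[:ncol] + [f"extra{i}" for i in range(ncol - len(names))]
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_bed(df: pd.DataFrame, path, extra_cols: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (extra_cols or [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_dosage(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dosage TSV: first four columns snp/chrom/pos/ref/alt then one column per
    sample. Returns (snps, dosage) with dosage indexed by snp id."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["snp", "chrom", "pos", "ref", "alt"]
    snps = df[meta_cols].copy()
    dosage = df.drop(columns=meta_cols).set_index(df["snp"])
    return snps, dosage


def write_dosage(snps: pd.DataFrame, dosage: pd.DataFrame, path) -> None:
    out = pd.concat([snps.reset_index(drop=True), dosage.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def write_vcf(snps: pd.DataFrame, dosage: pd.DataFrame, samples, path) -> None:
    """Minimal unphased GT-only VCF from integer dosages (missing -> ./.)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        dos = np.asarray(dosage)
        for i, row in enumerate(snps.itertuples(index=False)):
            gts = [gt_map.get(int(d), "./.") if np.isfinite(d) else "./." for d in dos[i]]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.snp}\t{row.ref}\t{row.alt}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a GT-only VCF back into (snps, dosage keyed snp x sample)."""
    header = None
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                header = line.rstrip("\n").split("\t")
                continue
            rows.append(line.rstrip("\n").split("\t"))
    if header is None:
        raise ValueError(f"{path}: missing #CHROM header")
    samples = header[9:]
    snps = pd.DataFrame(
        {
            "snp": [r[2] for r in rows],
            "chrom": [r[0] for r in rows],
            "pos": [int(r[1]) for r in rows],
            "ref": [r[3] for r in rows],
            "alt": [r[4] for r in rows],
        }
    )

    def _dose(gt: str) -> float:
        gt = gt.split(":")[0]
        if "." in gt:
            return np.nan
        return float(sum(int(a) for a in gt.replace("|", "/").split("/")))

    dos = pd.DataFrame(
        [[_dose(v) for v in r[9:]] for r in rows], columns=samples, index=snps["snp"]
    )
    return snps, dos


def read_summary_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SUMMARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing summary-stat columns {sorted(missing)}")
    if (df["se"] <= 0).any():
        raise ValueError(f"{path}: standard errors must be positive")
    return df


def write_summary_stats(df: pd.DataFrame, path) -> None:
    df[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False)
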
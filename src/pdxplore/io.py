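"""Shared table readers/writers and the minimal VCF round-trip.

All interchange formats are plain TSV with documented headers (gzip is
handled transparently by extension through pandas).  The VCF support is
deliberately minimal: the 8 fixed columns with AD/DP/AF in INFO, enough
to round-trip the variant tables of this pipeline.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

VARIANT_COLUMNS = [
    "sample", "patient", "timepoint", "chrom", "pos", "ref", "alt", "gene",
    "alt_reads", "depth", "vaf", "popaf_1000g", "popaf_kaviar",
]
SEG_COLUMNS = ["sample", "chrom", "start", "end", "total_cn"]
FUSION_COLUMNS = [
    "tool", "sample", "gene5", "gene3",
    "chrom5", "pos5", "strand5", "chrom3", "pos3", "strand3", "junction_reads",
]
META_COLUMNS = ["sample", "species", "fraction", "patient", "timepoint"]
ORTHOLOG_COLUMNS = ["human_gene", "mouse_gene"]


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def read_variants(path) -> pd.DataFrame:
    return _read_tsv(path, VARIANT_COLUMNS)


def read_segments(path) -> pd.DataFrame:
    return _read_tsv(path, SEG_COLUMNS)


def read_fusion_calls(path) -> pd.DataFrame:
    return _read_tsv(path, FUSION_COLUMNS)


def read_sample_meta(path) -> pd.DataFrame:
    return _read_tsv(path, META_COLUMNS)


def read_ortholog_map(path) -> pd.DataFrame:
    return _read_tsv(path, ORTHOLOG_COLUMNS)


def read_counts(path) -> pd.DataFrame:
    """Gene x sample count matrix, first column = gene id."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="gene")


# ---------------------------------------------------------------------------
# minimal VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AD,Number=1,Type=Integer,Description="Alternate-allele read count">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">
##INFO=<ID=AF,Number=1,Type=Float,Description="Variant allele fraction">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(calls: pd.DataFrame, path) -> None:
    """Write one sample's calls as a minimal single-sample VCF."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for row in calls.sort_values(["chrom", "pos"]).itertuples():
            info = f"AD={int(row.alt_reads)};DP={int(row.depth)};AF={row.vaf:.6g}"
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t{info}\n"
            )


def read_vcf(path) -> pd.DataFrame:
    """Parse the minimal VCF back into (chrom, pos, ref, alt, alt_reads, depth, vaf)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _, ref, alt, _, _, info = line.rstrip("\n").split("\t")[:8]
            fields = dict(kv.split("=", 1) for kv in info.split(";") if "=" in kv)
            rows.append(
                {
                    "chrom": chrom,
                    "pos": int(pos),
                    "ref": ref,
                    "alt": alt,
                    "alt_reads": int(fields.get("AD", 0)),
                    "depth": int(fields.get("DP", 0)),
                    "vaf": float(fields.get("AF", "nan")),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "alt_reads", "depth", "vaf"])


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def checksum_tree(paths: list[Path]) -> dict[str, str]:
    return {str(p.name): sha256_of(p) for p in sorted(paths)}
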
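"""Readers and writers for the pipeline's on-disk formats.

Tables travel as tab-separated text with a header row (UTF-8); somatic
calls additionally as a minimal VCF v4.2 whose INFO field carries the
annotation columns.  The TSV writers/readers are inverse to each other
(boolean columns are stored as 0/1); the VCF reader is built on
cyvcf2, so the VCF written here is also validated by an independent
parser whenever it is read back.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

_SOMATIC_BOOL = ["exonic"]
_GERMLINE_BOOL = ["canonical", "in_panel"]

SOMATIC_COLUMNS = [
    "sample_id", "variant_id", "chrom", "pos", "ref", "alt", "gene",
    "consequence", "exonic", "vaf", "gnomad_afr", "gnomad_sas", "gnomad_nfe",
    "cosmic_count", "topmed_freq",
]
GERMLINE_COLUMNS = [
    "participant_id", "gene", "canonical", "clinvar_class", "clinvar_stars", "in_panel",
]

_VCF_INFO = [
    ("SAMPLE", "String", "Sample carrying the call"),
    ("GENE", "String", "Gene symbol"),
    ("CSQ", "String", "Consequence class"),
    ("EXONIC", "Integer", "1 if exonic"),
    ("VAF", "Float", "Variant allele fraction"),
    ("GN_AFR", "Float", "gnomAD AFR frequency"),
    ("GN_SAS", "Float", "gnomAD SAS frequency"),
    ("GN_NFE", "Float", "gnomAD NFE frequency"),
    ("COSMIC", "Integer", "COSMIC identifier count"),
    ("TOPMED", "Float", "TOPMED frequency"),
]


def _write_tsv(df: pd.DataFrame, path: str, bool_cols: Sequence[str]) -> None:
    out = df.copy()
    for col in bool_cols:
        if col in out.columns:
            out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index=False)


def _read_tsv(path: str, bool_cols: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in bool_cols:
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_clinical(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_clinical(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_somatic_tsv(df: pd.DataFrame, path: str) -> None:
    _write_tsv(df, path, _SOMATIC_BOOL)


def read_somatic_tsv(path: str) -> pd.DataFrame:
    return _read_tsv(path, _SOMATIC_BOOL)


def write_germline(df: pd.DataFrame, path: str) -> None:
    _write_tsv(df, path, _GERMLINE_BOOL)


def read_germline(path: str) -> pd.DataFrame:
    return _read_tsv(path, _GERMLINE_BOOL)


def write_panel(genes: Iterable[str], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_panel(path: str) -> List[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


# ---------------------------------------------------------------------------
# VCF

def write_somatic_vcf(df: pd.DataFrame, path: str) -> None:
    """Minimal VCF v4.2 rendering of the somatic call table.

    One record per (sample, variant) call; annotations ride in INFO.
    Records are coordinate-sorted within each contig block.
    """
    contigs = sorted(set(df["chrom"]), key=lambda c: (len(c), c)) if len(df) else []
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bcancestry-synthetic\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        for key, typ, desc in _VCF_INFO:
            fh.write(f'##INFO=<ID={key},Number=1,Type={typ},Description="{desc}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        if not len(df):
            return
        ordered = df.sort_values(["chrom", "pos"], key=lambda s: s if s.name == "pos" else s.map({c: i for i, c in enumerate(contigs)}))
        for row in ordered.itertuples(index=False):
            info = ";".join([
                f"SAMPLE={row.sample_id}",
                f"GENE={row.gene}",
                f"CSQ={row.consequence}",
                f"EXONIC={int(row.exonic)}",
                f"VAF={row.vaf:.6g}",
                f"GN_AFR={row.gnomad_afr:.6g}",
                f"GN_SAS={row.gnomad_sas:.6g}",
                f"GN_NFE={row.gnomad_nfe:.6g}",
                f"COSMIC={int(row.cosmic_count)}",
                f"TOPMED={row.topmed_freq:.6g}",
            ])
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t{row.variant_id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t{info}\n"
            )


def read_somatic_vcf(path: str) -> pd.DataFrame:
    """Read a somatic VCF back into the tabular schema (via cyvcf2)."""
    from cyvcf2 import VCF

    rows = []
    for rec in VCF(path):
        rows.append({
            "sample_id": rec.INFO.get("SAMPLE"),
            "variant_id": rec.ID,
            "chrom": rec.CHROM,
            "pos": rec.POS,
            "ref": rec.REF,
            "alt": rec.ALT[0] if rec.ALT else "",
            "gene": rec.INFO.get("GENE"),
            "consequence": rec.INFO.get("CSQ"),
            "exonic": bool(rec.INFO.get("EXONIC")),
            "vaf": float(rec.INFO.get("VAF")),
            "gnomad_afr": float(rec.INFO.get("GN_AFR")),
            "gnomad_sas": float(rec.INFO.get("GN_SAS")),
            "gnomad_nfe": float(rec.INFO.get("GN_NFE")),
            "cosmic_count": int(rec.INFO.get("COSMIC")),
            "topmed_freq": float(rec.INFO.get("TOPMED")),
        })
    return pd.DataFrame(rows, columns=SOMATIC_COLUMNS)
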
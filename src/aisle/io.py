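"""Readers and writers for the pipeline's on-disk formats.

Variant tables travel as uncompressed VCF 4.2 (INFO MQ/QD/FS, FORMAT
GT:AD:GQ) read back through pysam; everything else is plain TSV/BED.
Multiallelic VCF records are skipped with a warning.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_segmentation_bed",
    "read_segmentation_bed",
    "write_tsv",
    "read_tsv",
]

_GT_CODE = {"hom_ref": (0, 0), "het": (0, 1), "hom_alt": (1, 1), "missing": (None, None)}
_CODE_GT = {(0, 0): "hom_ref", (0, 1): "het", (1, 0): "het", (1, 1): "hom_alt"}


def write_vcf(
    sites: pd.DataFrame,
    calls: pd.DataFrame,
    samples: pd.DataFrame,
    path: str | Path,
    chrom_length: int = 1_000_000,
) -> None:
    """Serialize site/call tables as minimal VCF 4.2 text."""
    sample_ids = list(samples["sample_id"])
    call_idx = calls.set_index(["snp_id", "sample_id"])
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={sites['chrom'].iloc[0] if len(sites) else 'chrS'},length={chrom_length}>",
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Variant confidence by depth">',
        '##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled strand bias">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids),
    ]
    for _, s in sites.iterrows():
        rsid = s["rsid"] if pd.notna(s["rsid"]) else "."
        info = f"MQ={s['mq']:g};QD={s['qd']:g};FS={s['fs']:g}"
        fields = [
            str(s["chrom"]), str(int(s["pos"])), str(rsid), str(s["ref"]), str(s["alt"]),
            ".", "PASS", info, "GT:AD:GQ",
        ]
        for sid in sample_ids:
            try:
                c = call_idx.loc[(s["snp_id"], sid)]
            except KeyError:
                fields.append("./.:.,.:.")
                continue
            a, b = _GT_CODE[c["genotype"]]
            gt = "./." if a is None else f"{a}/{b}"
            fields.append(f"{gt}:{int(c['ref_depth'])},{int(c['alt_depth'])}:{int(c['gq'])}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a VCF into (sites, calls) tables; skips multiallelic records."""
    site_rows, call_rows = [], []
    with pysam.VariantFile(str(path)) as vcf:
        sample_ids = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                logger.warning(
                    "skipping multiallelic/invalid record at %s:%s", rec.chrom, rec.pos
                )
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                logger.warning("skipping non-SNV record at %s:%s", rec.chrom, rec.pos)
                continue
            snp_id = f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alts[0]}"
            site_rows.append(
                {
                    "snp_id": snp_id,
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "rsid": rec.id if rec.id not in (None, ".") else np.nan,
                    "mq": float(rec.info.get("MQ", np.nan)),
                    "qd": float(rec.info.get("QD", np.nan)),
                    "fs": float(rec.info.get("FS", np.nan)),
                }
            )
            for sid in sample_ids:
                s = rec.samples[sid]
                gt = s.get("GT")
                genotype = _CODE_GT.get(tuple(gt) if gt else None, "missing") if gt and None not in gt else "missing"
                ad = s.get("AD")
                ref_d, alt_d = (int(ad[0]), int(ad[1])) if ad and ad[0] is not None else (0, 0)
                gq = s.get("GQ")
                call_rows.append(
                    {
                        "snp_id": snp_id,
                        "sample_id": sid,
                        "genotype": genotype,
                        "ref_depth": ref_d,
                        "alt_depth": alt_d,
                        "gq": int(gq) if gq is not None else 0,
                    }
                )
    return pd.DataFrame(site_rows), pd.DataFrame(call_rows)


def write_segmentation_bed(segments: pd.DataFrame, path: str | Path) -> None:
    segments[["chrom", "start", "end", "state"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_segmentation_bed(path: str | Path, epigenome_id: str = ""):
    from .superenhancer import parse_segmentation

    with open(path) as fh:
        return parse_segmentation(fh, epigenome_id=epigenome_id)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
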
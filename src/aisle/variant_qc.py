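"""Site- and sample-level variant filtering cascade.

Filtering runs as a sequential pipeline over a site table and a per-sample
call table:

1. site filters — mapping quality, SNP-cluster rule, quality-by-depth,
   strand bias (in that order; each exclusion is attributed to the first
   rule that fires);
2. heterozygote extraction — het genotype, genotype quality, allelic-depth
   sum, optional dbSNP-membership requirement;
3. recurrence — a SNP stays testable only with >= ``min_per_group`` het
   carriers in cases and in controls within a dataset.

The cascade is idempotent and every exclusion is logged with its rule.

Expected table schemas
----------------------
sites:  snp_id, chrom, pos (1-based), ref, alt, rsid (nullable),
        mq, qd, fs
calls:  snp_id, sample_id, genotype in {hom_ref, het, hom_alt, missing},
        ref_depth, alt_depth, gq
samples: sample_id, group (0 control / 1 case), cell_state, dataset_id,
        assay
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import SchemaError

__all__ = [
    "SiteThresholds",
    "apply_site_filters",
    "extract_heterozygotes",
    "recurrence_filter",
]

SITE_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt", "rsid", "mq", "qd", "fs"]
CALL_COLUMNS = ["snp_id", "sample_id", "genotype", "ref_depth", "alt_depth", "gq"]
GENOTYPES = {"hom_ref", "het", "hom_alt", "missing"}


@dataclass(frozen=True)
class SiteThresholds:
    """Site-level QC cutoffs, applied strictly as stated.

    A site is removed when mq < min_mq, qd < min_qd or fs > max_fs, so the
    boundary values themselves (mq=20, qd=2, fs=50) are retained.  The
    cluster rule removes every member of a chain of >= ``cluster_min``
    SNPs in which consecutive members lie within ``cluster_bp`` of each
    other on one chromosome.
    """

    min_mq: float = 20.0
    min_qd: float = 2.0
    max_fs: float = 50.0
    cluster_bp: int = 10
    cluster_min: int = 3


def _check_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table missing columns: {missing}")


def _cluster_members(sites: pd.DataFrame, cluster_bp: int, cluster_min: int) -> pd.Index:
    """Index labels of sites belonging to chains of >=cluster_min SNPs.

    Chains link consecutive (position-sorted) SNPs at distance <=
    cluster_bp; chain membership is therefore order-independent.
    """
    drop = []
    for _, chrom_sites in sites.groupby("chrom", sort=False):
        pos = chrom_sites["pos"].to_numpy()
        idx = chrom_sites.index.to_numpy()
        if len(pos) == 0:
            continue
        start = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] > cluster_bp:
                if i - start >= cluster_min:
                    drop.extend(idx[start:i])
                start = i
    return pd.Index(drop)


def apply_site_filters(
    sites: pd.DataFrame,
    thresholds: SiteThresholds | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the site-level cascade; return (retained sites, exclusion log).

    ``sites`` must be sorted by (chrom, pos).  The exclusion log has one
    row per removed site with columns ``snp_id`` and ``rule``; each
    removal is attributed to exactly one rule (the first that fires in
    cascade order: mapping_quality, snp_cluster, quality_by_depth,
    strand_bias).  Input row order is preserved in the output.
    """
    th = thresholds or SiteThresholds()
    _check_columns(sites, SITE_COLUMNS, "sites")
    ordered = sites.sort_values(["chrom", "pos"], kind="stable")
    if not (
        np.array_equal(ordered["chrom"].to_numpy(), sites["chrom"].to_numpy())
        and np.array_equal(ordered["pos"].to_numpy(), sites["pos"].to_numpy())
    ):
        raise SchemaError("sites must be sorted by (chrom, pos)")

    exclusions: list[tuple[str, str]] = []
    current = sites

    # 1. mapping quality
    bad = current["mq"] < th.min_mq
    exclusions += [(s, "mapping_quality") for s in current.loc[bad, "snp_id"]]
    current = current.loc[~bad]

    # 2. SNP cluster (computed on mapping-quality survivors)
    cluster_idx = _cluster_members(current, th.cluster_bp, th.cluster_min)
    exclusions += [(s, "snp_cluster") for s in current.loc[cluster_idx, "snp_id"]]
    current = current.drop(index=cluster_idx)

    # 3. quality by depth
    bad = current["qd"] < th.min_qd
    exclusions += [(s, "quality_by_depth") for s in current.loc[bad, "snp_id"]]
    current = current.loc[~bad]

    # 4. strand bias
    bad = current["fs"] > th.max_fs
    exclusions += [(s, "strand_bias") for s in current.loc[bad, "snp_id"]]
    current = current.loc[~bad]

    log = pd.DataFrame(exclusions, columns=["snp_id", "rule"])
    return current.reset_index(drop=True), log


def extract_heterozygotes(
    calls: pd.DataFrame,
    retained_sites: pd.DataFrame,
    min_gq: int = 15,
    min_depth: int = 8,
    require_dbsnp: bool = False,
) -> pd.DataFrame:
    """Per-sample het calls surviving genotype-level QC.

    Keeps (SNP, sample) pairs with a het genotype, genotype quality >=
    ``min_gq`` and allelic-depth sum >= ``min_depth``, restricted to SNPs
    in ``retained_sites`` (and, optionally, to sites with a dbSNP id).
    """
    if min_gq < 0 or min_depth < 0:
        raise ValueError("thresholds must be non-negative")
    _check_columns(calls, CALL_COLUMNS, "calls")
    _check_columns(retained_sites, SITE_COLUMNS, "sites")
    bad_gt = set(calls["genotype"].unique()) - GENOTYPES
    if bad_gt:
        raise SchemaError(f"unknown genotype codes: {sorted(bad_gt)}")

    keep_sites = retained_sites
    if require_dbsnp:
        keep_sites = keep_sites[keep_sites["rsid"].notna()]
    site_ids = set(keep_sites["snp_id"])

    depth = calls["ref_depth"] + calls["alt_depth"]
    mask = (
        calls["snp_id"].isin(site_ids)
        & (calls["genotype"] == "het")
        & (calls["gq"] >= min_gq)
        & (depth >= min_depth)
    )
    return calls.loc[mask].reset_index(drop=True)


def recurrence_filter(
    het_calls: pd.DataFrame,
    samples: pd.DataFrame,
    min_per_group: int = 3,
) -> pd.DataFrame:
    """Keep SNPs het in >= min_per_group cases AND controls.

    Operates within one dataset: ``samples`` is the annotation table for
    the dataset the calls came from.  Unknown sample ids raise.
    """
    _check_columns(samples, ["sample_id", "group"], "samples")
    if het_calls.empty:
        return het_calls.copy()
    unknown = set(het_calls["sample_id"]) - set(samples["sample_id"])
    if unknown:
        raise SchemaError(f"calls reference unknown samples: {sorted(unknown)}")

    merged = het_calls.merge(samples[["sample_id", "group"]], on="sample_id")
    counts = (
        merged.groupby(["snp_id", "group"])["sample_id"].nunique().unstack(fill_value=0)
    )
    for g in (0, 1):
        if g not in counts.columns:
            counts[g] = 0
    ok = counts.index[(counts[0] >= min_per_group) & (counts[1] >= min_per_group)]
    return het_calls[het_calls["snp_id"].isin(set(ok))].reset_index(drop=True)
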
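"""Two-stage workflow orchestration: simulate -> discovery -> annotation.

Discovery runs the variant-QC cascade and per-dataset AI tests, then
reciprocally validates SNPs across datasets.  Annotation calls
super-enhancers, quantifies window TPM with stage trends, summarizes
methylation and fits the association models.  Every output file carries
the config hash in a leading comment line; reruns with the same config
are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import allelic, association, io, methylation, quantify, superenhancer, variant_qc
from .config import PipelineConfig
from .exceptions import DegenerateDataError, SchemaError
from .quantify import Region
from .synth import PlantedAI, SimConfig, gen_allelic_study, gen_genotypes, gen_methylation, gen_segmentation, gen_window_counts

logger = logging.getLogger(__name__)

__all__ = ["run_simulate", "run_discovery", "run_annotation"]


def _outdir(cfg: PipelineConfig, sub: str) -> Path:
    d = Path(cfg.out_dir) / sub
    d.mkdir(parents=True, exist_ok=True)
    return d


def _sim_config(cfg: PipelineConfig) -> SimConfig:
    params = dict(cfg.simulate)
    planted = [
        PlantedAI(*p) if not isinstance(p, PlantedAI) else p
        for p in params.pop("planted_ai", [])
    ]
    return SimConfig(
        seed=cfg.seed, stage_labels=cfg.stage_order, planted_ai=tuple(planted), **params
    )


def run_simulate(cfg: PipelineConfig) -> dict[str, str]:
    """Generate every pipeline input under ``<out_dir>/inputs``; returns the
    path map, which matches what discovery/annotation read by default."""
    sim = _sim_config(cfg)
    d = _outdir(cfg, "inputs")
    paths: dict[str, str] = {}

    datasets = gen_allelic_study(sim)
    ds_entries = []
    for ds_id, (sites, calls, samples) in datasets.items():
        vcf = d / f"{ds_id}.vcf"
        ann = d / f"{ds_id}.samples.tsv"
        io.write_vcf(sites, calls, samples, vcf, chrom_length=sim.chrom_length)
        samples.to_csv(ann, sep="\t", index=False)
        ds_entries.append({"id": ds_id, "vcf": str(vcf), "samples": str(ann)})
    paths["datasets"] = ds_entries

    seg = gen_segmentation(
        sim, planted_runs=[(sim.region_start, sim.region_length)]
    )
    seg_path = d / "segmentation.bed"
    io.write_segmentation_bed(seg, seg_path)
    paths["segmentation"] = str(seg_path)

    counts, win_samples = gen_window_counts(sim)
    counts.to_csv(d / "window_counts.tsv", sep="\t")
    win_samples.to_csv(d / "window_samples.tsv", sep="\t", index=False)
    paths["window_counts"] = str(d / "window_counts.tsv")
    paths["window_samples"] = str(d / "window_samples.tsv")

    cpgs, meth_samples = gen_methylation(sim)
    cpgs.to_csv(d / "cpg.tsv", sep="\t", index=False)
    meth_samples.to_csv(d / "meth_samples.tsv", sep="\t", index=False)
    paths["methylation"] = str(d / "cpg.tsv")
    paths["methylation_samples"] = str(d / "meth_samples.tsv")

    dosages, phenotype, covariates = gen_genotypes(sim)
    dosages.to_csv(d / "dosages.tsv", sep="\t", index=False)
    pd.concat([phenotype, covariates], axis=1).to_csv(d / "phenotype.tsv", sep="\t", index=False)
    paths["dosages"] = str(d / "dosages.tsv")
    paths["phenotype"] = str(d / "phenotype.tsv")
    paths["region"] = f"{sim.chrom}:{sim.region_start}-{sim.region_start + sim.region_length}"
    (d / "paths.json").write_text(json.dumps(paths, indent=2, sort_keys=True))
    return paths


def _default_paths(cfg: PipelineConfig) -> dict:
    p = Path(cfg.out_dir) / "inputs" / "paths.json"
    return json.loads(p.read_text()) if p.exists() else {}


def run_discovery(cfg: PipelineConfig) -> pd.DataFrame:
    """Stage I: QC + per-dataset AI tests + reciprocal validation.

    Writes ``ai_results.tsv``, ``validated.tsv`` and ``audit.json`` under
    ``<out_dir>/discovery`` and returns the validated-SNP table.
    """
    th = cfg.thresholds
    datasets = cfg.discovery.get("datasets") or _default_paths(cfg).get("datasets")
    if not datasets or len(datasets) < 2:
        raise SchemaError("discovery needs >=2 datasets (run simulate or configure paths)")

    out = _outdir(cfg, "discovery")
    audit: dict[str, dict] = {"thresholds": th.__dict__, "datasets": {}}
    results: list[allelic.AITestResult] = []
    site_th = variant_qc.SiteThresholds(min_mq=th.min_mq, min_qd=th.min_qd, max_fs=th.max_fs)

    for entry in datasets:
        ds_id = entry["id"]
        sites, calls = io.read_vcf(entry["vcf"])
        samples = io.read_tsv(entry["samples"])
        retained, excl = variant_qc.apply_site_filters(sites, site_th)
        hets = variant_qc.extract_heterozygotes(
            calls, retained, min_gq=th.min_gq, min_depth=th.min_depth
        )
        testable = variant_qc.recurrence_filter(hets, samples, min_per_group=th.min_per_group)
        audit["datasets"][ds_id] = {
            "sites_in": int(len(sites)),
            "sites_retained": int(len(retained)),
            "site_exclusions": excl["rule"].value_counts().to_dict(),
            "het_calls": int(len(hets)),
            "testable_calls": int(len(testable)),
            "testable_snps": int(testable["snp_id"].nunique()) if len(testable) else 0,
        }
        merged = testable.merge(samples, on="sample_id")
        merged["ar"] = allelic.allelic_ratio(
            merged["ref_depth"].to_numpy(), merged["alt_depth"].to_numpy()
        ) if len(merged) else np.nan
        for (snp_id, state), sub in merged.groupby(["snp_id", "cell_state"], sort=True):
            if sub["group"].nunique() < 2:
                continue
            if min((sub["group"] == 0).sum(), (sub["group"] == 1).sum()) < th.min_per_group:
                continue
            results.append(
                allelic.ai_test(
                    sub["ar"].to_numpy(), sub["group"].to_numpy(),
                    snp_id=snp_id, dataset_id=ds_id, cell_state=str(state),
                )
            )

    res_df = pd.DataFrame(
        [
            {
                "snp_id": r.snp_id, "dataset_id": r.dataset_id, "cell_state": r.cell_state,
                "n_case": r.n_case, "n_control": r.n_control, "beta": r.beta,
                "ci_low": r.ci95[0], "ci_high": r.ci95[1], "p_value": r.p_value,
                "mean_ar_case": r.mean_ar_case, "mean_ar_control": r.mean_ar_control,
            }
            for r in results
        ]
    )
    if not res_df.empty:
        res_df["fdr_bh"] = np.nan
        for (ds, state), idx in res_df.groupby(["dataset_id", "cell_state"]).groups.items():
            res_df.loc[idx, "fdr_bh"] = allelic.bh_fdr(res_df.loc[idx, "p_value"].to_numpy())

    validated = allelic.reciprocal_validate(
        results, alpha_nominal=th.alpha_nominal, alpha_combined=th.alpha_combined
    ) if results else []
    val_df = pd.DataFrame(
        [
            {
                "snp_id": v.snp_id, "cell_state": v.cell_state,
                "n_datasets": len(v.datasets),
                "p_combined": v.p_combined, "passed": v.passed,
                **{f"p_{d}": p for d, p in v.p_values.items()},
                **{f"beta_{d}": b for d, b in v.betas.items()},
            }
            for v in validated
        ]
    )

    h = cfg.hash()
    io.write_tsv(res_df, out / "ai_results.tsv", header_comment=f"config_hash={h}")
    io.write_tsv(val_df, out / "validated.tsv", header_comment=f"config_hash={h}")
    audit["config_hash"] = h
    (out / "audit.json").write_text(json.dumps(audit, indent=2, sort_keys=True))
    logger.info(
        "discovery: %d AI tests, %d validated SNPs",
        len(res_df), int(val_df["passed"].sum()) if len(val_df) else 0,
    )
    return val_df


def _parse_region(text: str) -> Region:
    chrom, span = text.split(":")
    start, end = span.replace(",", "").split("-")
    return Region(chrom, int(start), int(end))


def run_annotation(cfg: PipelineConfig) -> dict:
    """Stage II: SE calls, quantification, methylation and association.

    Writes per-component TSVs plus ``summary.json`` under
    ``<out_dir>/annotation``; returns the summary dict.
    """
    th = cfg.thresholds
    defaults = _default_paths(cfg)
    ann = {**defaults, **{k: v for k, v in cfg.annotation.items() if v is not None}}
    out = _outdir(cfg, "annotation")
    h = cfg.hash()
    summary: dict = {"config_hash": h}

    # --- super-enhancers -------------------------------------------------
    if "segmentation" in ann:
        segs = io.read_segmentation_bed(ann["segmentation"], epigenome_id=ann.get("epigenome", ""))
        ses = superenhancer.call_superenhancers(segs, min_length=th.se_min_length)
        se_df = pd.DataFrame(
            [
                {"chrom": s.chrom, "start": s.start, "end": s.end,
                 "name": s.epigenome_id or "SE", "score": s.length_bp, "strand": "."}
                for s in ses
            ]
        )
        io.write_tsv(se_df, out / "se_calls.bed6.tsv", header_comment=f"config_hash={h}")
        summary["superenhancers"] = [
            {"chrom": s.chrom, "start": s.start, "end": s.end, "length_bp": s.length_bp}
            for s in ses
        ]

    # --- window quantification ------------------------------------------
    region = _parse_region(ann["region"]) if "region" in ann else None
    if region is not None and "window_counts" in ann:
        counts = io.read_tsv(ann["window_counts"], index_col=0)
        win_samples = io.read_tsv(ann["window_samples"])
        tpm = pd.DataFrame(
            {
                row.sample_id: quantify.window_tpm(
                    None, region, th.window, row.library_size,
                    counts=counts[row.sample_id].to_numpy(),
                )
                for row in win_samples.itertuples()
            },
            index=counts.index,
        )
        io.write_tsv(tpm, out / "window_tpm.tsv", index=True, header_comment=f"config_hash={h}")
        q3 = tpm.quantile(0.75)
        trend_rows = []
        for group, label in ((1, "case"), (0, "control")):
            sel = win_samples[win_samples["group"] == group]
            tr = quantify.stage_trend(
                q3[sel["sample_id"]].to_numpy(), sel["stage"].to_numpy(), group=label
            )
            trend_rows.append(
                {"group": label, "slope": tr.slope, "se": tr.se, "ci_low": tr.ci95[0],
                 "ci_high": tr.ci95[1], "p_value": tr.p_value, "n": tr.n}
            )
        trends = pd.DataFrame(trend_rows)
        io.write_tsv(trends, out / "tpm_stage_trends.tsv", header_comment=f"config_hash={h}")
        summary["tpm_trends"] = trends.to_dict("records")

        # mean TPM per (group, stage) cell, reused for the methylation link
        cell_mean = {
            (row.group, row.stage): float(tpm[row.sample_id].mean())
            for row in win_samples.itertuples()
        }
        summary["_tpm_by_cell"] = {f"{g}:{s}": v for (g, s), v in sorted(cell_mean.items())}

    # --- methylation -----------------------------------------------------
    if region is not None and "methylation" in ann:
        cpgs = io.read_tsv(ann["methylation"])
        meth_samples = io.read_tsv(ann["methylation_samples"])
        mat = methylation.window_methylation_matrix(cpgs, region, window_size=th.window)
        io.write_tsv(mat, out / "window_methylation.tsv", index=True, header_comment=f"config_hash={h}")
        mean_meth = mat.mean(axis=0, skipna=True)
        trend_rows = []
        for group, label in ((1, "case"), (0, "control")):
            sel = meth_samples[meth_samples["group"] == group]
            tr = methylation.methylation_trend(
                mean_meth[sel["sample_id"]].to_numpy(), sel["stage"].to_numpy(), group=label
            )
            trend_rows.append(
                {"group": label, "slope": tr.slope, "se": tr.se, "ci_low": tr.ci95[0],
                 "ci_high": tr.ci95[1], "p_value": tr.p_value, "n": tr.n}
            )
        trends = pd.DataFrame(trend_rows)
        io.write_tsv(trends, out / "methylation_stage_trends.tsv", header_comment=f"config_hash={h}")
        summary["methylation_trends"] = trends.to_dict("records")

        if "_tpm_by_cell" in summary:
            meth_cell = meth_samples.assign(m=mean_meth[meth_samples["sample_id"]].to_numpy())
            meth_by_cell = meth_cell.groupby(["group", "stage"])["m"].mean()
            pairs = [
                (summary["_tpm_by_cell"][f"{g}:{s}"], v)
                for (g, s), v in meth_by_cell.items()
                if f"{g}:{s}" in summary["_tpm_by_cell"]
            ]
            if len(pairs) >= 3:
                try:
                    r, p = methylation.meth_access_correlation(
                        [a for a, _ in pairs], [b for _, b in pairs]
                    )
                    summary["tpm_methylation_correlation"] = {"r": r, "p": p}
                except DegenerateDataError:
                    pass
        summary.pop("_tpm_by_cell", None)

    # --- association -----------------------------------------------------
    if "dosages" in ann:
        dosages = io.read_tsv(ann["dosages"])
        pheno_tab = io.read_tsv(ann["phenotype"])
        phenotype = pheno_tab["phenotype"]
        covariates = pheno_tab.drop(columns=["phenotype"])
        test_snp = ann.get("test_snp", dosages.columns[0])
        res = association.additive_logistic(
            dosages[test_snp], phenotype, covariates, snp_id=test_snp
        )
        rows = [
            {"snp_id": res.snp_id, "odds_ratio": res.odds_ratio,
             "ci_low": res.ci95[0], "ci_high": res.ci95[1],
             "p_value": res.p_value, "n": res.n, "adjusted_for": ""}
        ]
        index_snps = [c for c in ann.get("index_snps", []) if c in dosages.columns]
        if index_snps:
            adj = association.conditional_adjust(
                dosages[test_snp], phenotype, covariates, dosages[index_snps], snp_id=test_snp
            )
            rows.append(
                {"snp_id": adj.snp_id, "odds_ratio": adj.odds_ratio,
                 "ci_low": adj.ci95[0], "ci_high": adj.ci95[1],
                 "p_value": adj.p_value, "n": adj.n,
                 "adjusted_for": ",".join(adj.adjusted_for)}
            )
        assoc = pd.DataFrame(rows)
        io.write_tsv(assoc, out / "association.tsv", header_comment=f"config_hash={h}")
        summary["association"] = assoc.to_dict("records")

        if dosages.shape[1] >= 2:
            g1, g2 = dosages.columns[:2]
            em = association.em_haplotypes_2snp(dosages[g1], dosages[g2])
            summary["haplotype_frequencies"] = em.frequencies
            summary["ld_r2"] = association.ld_r2_from_frequencies(em.freqs)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
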
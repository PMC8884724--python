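"""Synthetic data generators for every pipeline input.

All generators are deterministic under a fixed seed (independent
sub-streams are derived from ``SimConfig.seed`` with
``numpy.random.SeedSequence``) and produce data with the statistical
structure the downstream analyses assume:

* heterozygous-SNP allelic read counts — beta-binomial with
  group-dependent allelic fraction, optional direction flips across
  B-cell states;
* chromHMM-style 15-state segment runs with planted enhancer clusters;
* window tag tracks with stage-dependent trends in cases;
* per-CpG methylation counts declining with stage in cases;
* case/control genotypes with a log-additive effect and an optional
  LD partner SNP.

The synthetic genome is one chromosome ("chrS") of configurable length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .superenhancer import STATE_MNEMONICS

__all__ = [
    "SimConfig",
    "PlantedAI",
    "beta_binomial",
    "gen_allelic_dataset",
    "gen_allelic_study",
    "gen_segmentation",
    "gen_window_counts",
    "gen_methylation",
    "gen_genotypes",
]

NON_ENHANCER_STATES = tuple(
    STATE_MNEMONICS[i] for i in sorted(set(STATE_MNEMONICS) - {6, 7})
)
ENHANCER_STATES = (STATE_MNEMONICS[6], STATE_MNEMONICS[7])


@dataclass(frozen=True)
class PlantedAI:
    """A SNP with group-specific allelic fractions in one cell state
    (``cell_state=None`` plants it in every state)."""

    snp_index: int
    case_fraction: float
    control_fraction: float
    cell_state: str | None = None


@dataclass
class SimConfig:
    seed: int = 0
    # allelic datasets
    n_case: int = 10
    n_control: int = 10
    n_datasets: int = 2
    n_snps: int = 100
    depth_mean: float = 50.0
    depth_dispersion: float = 0.0   # 0 => constant depth; >0 => negative binomial
    null_allelic_fraction: float = 0.5
    planted_ai: Sequence[PlantedAI] = field(default_factory=tuple)
    rho: float = 0.01               # beta-binomial overdispersion; 0 => binomial
    flip_states: tuple[str, str] | None = None  # mirror planted fractions in 2nd state
    het_rate: float = 1.0
    site_qc_overrides: Mapping[int, Mapping[str, object]] = field(default_factory=dict)
    # genome / region geometry
    chrom: str = "chrS"
    chrom_length: int = 1_000_000
    region_start: int = 100_000
    region_length: int = 7_000
    window_size: int = 50
    # stages and window tracks
    stage_labels: Sequence[str] = ("rN", "T3", "SM", "DN")
    n_per_stage: int = 3
    base_window_mean: float = 20.0
    trend_slope: float = 0.0        # additive per-stage change of window mean, cases
    library_size: float = 1e7
    # methylation
    meth_base: float = 0.8
    meth_slope: float = 0.0         # per-stage change of methylation pi, cases
    meth_depth: float = 30.0
    cpg_spacing: int = 25
    # genotypes / association
    n_individuals: int = 2000
    maf: float = 0.3
    assoc_effect: float = 0.0       # per-allele log-odds
    assoc_intercept: float = 0.0
    maf2: float | None = None       # second SNP for haplotype/LD tests
    target_r2: float | None = None

    def __post_init__(self):
        for name, v in [
            ("null_allelic_fraction", self.null_allelic_fraction),
            ("rho", self.rho),
            ("het_rate", self.het_rate),
            ("maf", self.maf),
            ("meth_base", self.meth_base),
        ]:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.rho >= 1.0:
            raise ValueError("rho must lie in [0,1)")
        if self.depth_mean < 0 or self.depth_dispersion < 0:
            raise ValueError("depth model parameters must be non-negative")
        for p in self.planted_ai:
            if not (0 <= p.snp_index < self.n_snps):
                raise ValueError(f"planted SNP index {p.snp_index} out of range")
            for f_ in (p.case_fraction, p.control_fraction):
                if not 0.0 <= f_ <= 1.0:
                    raise ValueError("planted fractions must lie in [0,1]")
        if self.region_length % self.window_size != 0:
            raise ValueError("region length must be divisible by window size")
        if self.library_size <= 0:
            raise ValueError("library size must be positive")


def _sub_rng(cfg: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=tuple(key)))


def beta_binomial(
    rng: np.random.Generator, n: np.ndarray, fraction: np.ndarray, rho: float
) -> np.ndarray:
    """Beta-binomial draws with mean fraction ``f`` and overdispersion rho.

    Variance is ``n f (1-f) (1 + (n-1) rho)``; rho=0 recovers the plain
    binomial.  Degenerate fractions 0/1 return the deterministic counts.
    """
    n = np.asarray(n)
    f = np.broadcast_to(np.asarray(fraction, dtype=float), n.shape)
    if rho == 0.0:
        return rng.binomial(n, f)
    out = np.empty(n.shape, dtype=np.int64)
    interior = (f > 0.0) & (f < 1.0)
    a = np.where(interior, f * (1.0 - rho) / rho, 1.0)
    b = np.where(interior, (1.0 - f) * (1.0 - rho) / rho, 1.0)
    p = rng.beta(a, b)
    out[:] = rng.binomial(n, np.where(interior, p, f))
    return out


def _sample_table(cfg: SimConfig, dataset_id: str, assay: str, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    states = list(cfg.stage_labels)
    for group, count, prefix in ((1, cfg.n_case, "case"), (0, cfg.n_control, "ctrl")):
        for i in range(count):
            rows.append(
                {
                    "sample_id": f"{dataset_id}_{prefix}{i:03d}",
                    "group": group,
                    "cell_state": states[i % len(states)],
                    "dataset_id": dataset_id,
                    "assay": assay,
                }
            )
    return pd.DataFrame(rows)


def _fraction_for(cfg: SimConfig, snp_idx: int, group: int, cell_state: str) -> float:
    """Allelic fraction for one (SNP, sample) cell."""
    for p in cfg.planted_ai:
        if p.snp_index != snp_idx:
            continue
        f = p.case_fraction if group == 1 else p.control_fraction
        if p.cell_state is None:
            return f
        if cell_state == p.cell_state:
            return f
        if cfg.flip_states and p.cell_state == cfg.flip_states[0] and cell_state == cfg.flip_states[1]:
            return 1.0 - f
    return cfg.null_allelic_fraction


def gen_allelic_dataset(
    cfg: SimConfig, dataset_id: str = "ds1", assay: str = "ATAC", stream: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """One dataset of per-sample allelic read counts at het SNPs.

    Returns ``(sites, calls, samples)`` in the schemas consumed by
    :mod:`aisle.variant_qc`.  Sites are spaced 1 kb apart on the
    synthetic chromosome with passing QC annotations unless overridden
    via ``cfg.site_qc_overrides`` (keys are SNP indices; values may
    override pos, mq, qd, fs, rsid, ref, alt).
    """
    rng = _sub_rng(cfg, 0, stream)
    samples = _sample_table(cfg, dataset_id, assay, rng)

    sites = []
    for i in range(cfg.n_snps):
        rec = {
            "snp_id": f"snp{i:05d}",
            "chrom": cfg.chrom,
            "pos": 1000 * (i + 1),
            "ref": "A",
            "alt": "G",
            "rsid": f"rs{100000 + i}",
            "mq": 60.0,
            "qd": 20.0,
            "fs": 5.0,
        }
        rec.update(cfg.site_qc_overrides.get(i, {}))
        sites.append(rec)
    sites = pd.DataFrame(sites).sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    n_samples = len(samples)
    groups = samples["group"].to_numpy()
    states = samples["cell_state"].to_numpy()
    call_rows = []
    for i in range(cfg.n_snps):
        het = rng.random(n_samples) < cfg.het_rate
        if cfg.depth_dispersion == 0.0:
            depth = np.full(n_samples, int(round(cfg.depth_mean)))
        else:
            r = 1.0 / cfg.depth_dispersion
            depth = rng.negative_binomial(r, r / (r + cfg.depth_mean), size=n_samples)
        fracs = np.array(
            [_fraction_for(cfg, i, g, s) for g, s in zip(groups, states)]
        )
        alt = beta_binomial(rng, depth, fracs, cfg.rho)
        for j, sample_id in enumerate(samples["sample_id"]):
            gt = "het" if het[j] else ("hom_ref" if rng.random() < 0.5 else "hom_alt")
            a = int(alt[j]) if gt == "het" else (0 if gt == "hom_ref" else int(depth[j]))
            call_rows.append(
                {
                    "snp_id": f"snp{i:05d}",
                    "sample_id": sample_id,
                    "genotype": gt,
                    "ref_depth": int(depth[j]) - a,
                    "alt_depth": a,
                    "gq": 99,
                }
            )
    calls = pd.DataFrame(call_rows)
    return sites, calls, samples


def gen_allelic_study(cfg: SimConfig, assay: str = "ATAC") -> dict[str, tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]]:
    """Independent datasets sharing the same site panel and planted AI."""
    return {
        f"ds{k + 1}": gen_allelic_dataset(cfg, dataset_id=f"ds{k + 1}", assay=assay, stream=k)
        for k in range(cfg.n_datasets)
    }


def gen_segmentation(
    cfg: SimConfig,
    planted_runs: Sequence[tuple[int, int]] = (),
    background_states: Sequence[str] = NON_ENHANCER_STATES,
    mean_segment: int = 500,
) -> pd.DataFrame:
    """BED4-style gap-free 15-state tiling of the synthetic chromosome.

    ``planted_runs`` are (start, length) enhancer runs built from
    alternating state-6/7 segments; they must not overlap.  Background
    segments draw states from ``background_states`` (pass all 15
    mnemonics to generate unconstrained random segmentations).
    Returns a frame with columns chrom, start, end, state.
    """
    runs = sorted(planted_runs)
    for (s1, l1), (s2, _) in zip(runs, runs[1:]):
        if s1 + l1 > s2:
            raise ValueError("planted enhancer runs overlap")
    for s, l in runs:
        if s < 0 or s + l > cfg.chrom_length:
            raise ValueError("planted run outside chromosome")

    rng = _sub_rng(cfg, 1)
    bg = list(background_states)
    rows: list[tuple[str, int, int, str]] = []

    def fill_background(lo: int, hi: int) -> None:
        pos = lo
        while pos < hi:
            seg_len = min(hi - pos, int(rng.integers(mean_segment // 2, mean_segment * 2)))
            rows.append((cfg.chrom, pos, pos + seg_len, bg[rng.integers(len(bg))]))
            pos += seg_len

    cursor = 0
    for start, length in runs:
        fill_background(cursor, start)
        # split the run into alternating 6/7 pieces
        pos = start
        k = 0
        while pos < start + length:
            piece = min(start + length - pos, int(rng.integers(200, 1200)))
            rows.append((cfg.chrom, pos, pos + piece, ENHANCER_STATES[k % 2]))
            pos += piece
            k += 1
        cursor = start + length
    fill_background(cursor, cfg.chrom_length)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


def gen_window_counts(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample Poisson window counts over the configured region.

    Case means increase linearly with stage index at ``cfg.trend_slope``
    per stage; controls stay flat.  Returns ``(counts, samples)`` where
    ``counts`` is windows x samples (index = window start coordinate) and
    ``samples`` carries group, stage index and library size.
    """
    rng = _sub_rng(cfg, 2)
    n_win = cfg.region_length // cfg.window_size
    starts = cfg.region_start + cfg.window_size * np.arange(n_win)
    rows = []
    for group, prefix in ((1, "case"), (0, "ctrl")):
        for stage_idx, stage in enumerate(cfg.stage_labels):
            for r in range(cfg.n_per_stage):
                rows.append(
                    {
                        "sample_id": f"{prefix}_{stage}_{r}",
                        "group": group,
                        "cell_state": stage,
                        "stage": stage_idx,
                        "library_size": cfg.library_size,
                    }
                )
    samples = pd.DataFrame(rows)
    mean = np.where(
        samples["group"].to_numpy() == 1,
        cfg.base_window_mean + cfg.trend_slope * samples["stage"].to_numpy(),
        cfg.base_window_mean,
    )
    mean = np.clip(mean, 0.0, None)
    counts = rng.poisson(np.broadcast_to(mean, (n_win, len(samples))))
    return (
        pd.DataFrame(counts, index=pd.Index(starts, name="window_start"), columns=samples["sample_id"]),
        samples,
    )


def gen_methylation(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-CpG binomial methylation counts over the configured region.

    Case methylation probability changes by ``cfg.meth_slope`` per stage
    (negative slope = stage-wise decline); controls stay at
    ``cfg.meth_base``.  Returns ``(cpgs, samples)``; cpgs columns are
    chrom, pos (1-based), methylated, total, sample_id.
    """
    rng = _sub_rng(cfg, 3)
    positions = np.arange(cfg.region_start + 1, cfg.region_start + cfg.region_length + 1, cfg.cpg_spacing)
    rows = []
    sample_rows = []
    for group, prefix in ((1, "case"), (0, "ctrl")):
        for stage_idx, stage in enumerate(cfg.stage_labels):
            for r in range(cfg.n_per_stage):
                sid = f"{prefix}_{stage}_{r}"
                sample_rows.append(
                    {"sample_id": sid, "group": group, "cell_state": stage, "stage": stage_idx}
                )
                pi = cfg.meth_base + (cfg.meth_slope * stage_idx if group == 1 else 0.0)
                pi = float(np.clip(pi, 0.0, 1.0))
                total = rng.poisson(cfg.meth_depth, size=positions.size) + 1
                meth = rng.binomial(total, pi)
                for p, m, t in zip(positions, meth, total):
                    rows.append(
                        {"chrom": cfg.chrom, "pos": int(p), "methylated": int(m), "total": int(t), "sample_id": sid}
                    )
    return pd.DataFrame(rows), pd.DataFrame(sample_rows)


def _haplotype_frequencies(p_a: float, p_b: float, r2: float) -> np.ndarray:
    """Four haplotype frequencies (RR, RA, AR, AA) achieving the target r^2
    (positive D) between alt alleles at frequencies p_a and p_b."""
    d = np.sqrt(r2 * p_a * (1 - p_a) * p_b * (1 - p_b))
    if d > min(p_a * (1 - p_b), (1 - p_a) * p_b) + 1e-12:
        raise ValueError("target r2 infeasible at these allele frequencies")
    f_aa = p_a * p_b + d
    f = np.array(
        [
            (1 - p_a) * (1 - p_b) + d,  # RR
            (1 - p_a) * p_b - d,        # RA
            p_a * (1 - p_b) - d,        # AR
            f_aa,                       # AA
        ]
    )
    if np.any(f < -1e-12):
        raise ValueError("target r2 infeasible at these allele frequencies")
    return np.clip(f, 0.0, 1.0)


def gen_genotypes(cfg: SimConfig) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Case/control genotypes with a log-additive disease effect.

    snp1 is drawn under Hardy-Weinberg at ``cfg.maf``; when ``cfg.maf2``
    and ``cfg.target_r2`` are set, a second SNP is drawn from two-locus
    haplotypes at the requested LD.  Case status is Bernoulli with
    logit = intercept + assoc_effect * dosage(snp1).  Covariates (sex,
    pc1) are generated but carry no effect.  Returns
    ``(dosages, phenotype, covariates)``.
    """
    rng = _sub_rng(cfg, 4)
    n = cfg.n_individuals
    if cfg.maf2 is not None and cfg.target_r2 is not None:
        f = _haplotype_frequencies(cfg.maf, cfg.maf2, cfg.target_r2)
        haps = rng.choice(4, size=(n, 2), p=f / f.sum())
        g1 = (haps >> 1).sum(axis=1)
        g2 = (haps & 1).sum(axis=1)
        dosages = pd.DataFrame({"snp1": g1, "snp2": g2})
    else:
        g1 = rng.binomial(1, cfg.maf, size=(n, 2)).sum(axis=1)
        dosages = pd.DataFrame({"snp1": g1})

    # center the intercept so case fraction stays near 1/2 under the effect
    alpha = cfg.assoc_intercept - cfg.assoc_effect * 2 * cfg.maf
    logit = alpha + cfg.assoc_effect * dosages["snp1"].to_numpy()
    phenotype = pd.Series(
        rng.binomial(1, 1.0 / (1.0 + np.exp(-logit))), name="phenotype"
    )
    covariates = pd.DataFrame(
        {"sex": rng.binomial(1, 0.5, size=n), "pc1": rng.normal(size=n)}
    )
    return dosages, phenotype, covariates
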
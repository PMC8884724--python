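"""Genetic association: log-additive logistic models, conditional
adjustment, two-SNP EM haplotype analysis and LD r-squared.

The single-marker model is a maximum-likelihood logistic regression of
case status on the effect-allele dosage (0/1/2) plus covariates; the
dosage coefficient's exponent is the per-allele odds ratio, with Wald 95%
confidence intervals.  Haplotype analysis estimates the four two-locus
haplotype frequencies by EM over unphased genotypes (only double
heterozygotes are phase-ambiguous) and regresses case status on expected
haplotype dosages against a designated baseline haplotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .exceptions import CollinearityError, DegenerateDataError, SeparationError

__all__ = [
    "AssociationResult",
    "HaplotypeResult",
    "EMResult",
    "HAPLOTYPE_LABELS",
    "additive_logistic",
    "conditional_adjust",
    "em_haplotypes_2snp",
    "expected_haplotype_dosages",
    "haplotype_association",
    "ld_r2",
    "ld_r2_from_frequencies",
]

#: haplotype order: allele at SNP1, allele at SNP2 (R=ref, A=alt)
HAPLOTYPE_LABELS = ("RR", "RA", "AR", "AA")


@dataclass(frozen=True)
class AssociationResult:
    snp_id: str
    effect_allele: str
    odds_ratio: float
    ci95: tuple[float, float]
    p_value: float
    beta: float
    se: float
    n: int
    adjusted_for: tuple[str, ...] = ()


def _complete_cases(*arrays) -> np.ndarray:
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        a = np.asarray(a, dtype=float)
        mask &= np.all(np.isfinite(np.atleast_2d(a.T).T), axis=1)
    return mask


def _fit_logit(y: np.ndarray, X: np.ndarray):
    """Newton ML fit; converts separation into SeparationError."""
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(method="newton", disp=0, maxiter=200)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(str(exc)) from exc
        except np.linalg.LinAlgError as exc:
            raise CollinearityError(f"singular design matrix: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise SeparationError("logistic fit failed to converge")
    if np.any(np.abs(res.params) > 30) or np.any(res.bse > 1e3):
        raise SeparationError("implausible estimates: likely (quasi-)separation")
    return res


def _design(dosage, covariates) -> tuple[np.ndarray, list[str]]:
    cols = [np.asarray(dosage, dtype=float)]
    names = ["dosage"]
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        for c in cov.columns:
            cols.append(cov[c].to_numpy(dtype=float))
            names.append(str(c))
    X = np.column_stack([np.ones(len(cols[0]))] + cols)
    return X, ["const"] + names


def additive_logistic(
    dosage: Sequence[float],
    phenotype: Sequence[int],
    covariates: pd.DataFrame | None = None,
    snp_id: str = "",
    effect_allele: str = "alt",
    adjusted_for: tuple[str, ...] = (),
) -> AssociationResult:
    """Per-allele odds ratio from a log-additive logistic model.

    Missing dosages/covariates (NaN) are dropped as complete cases.
    Complete or quasi-complete separation raises
    :class:`~aisle.exceptions.SeparationError` rather than returning a
    silently meaningless estimate.
    """
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if d.shape != y.shape:
        raise ValueError("dosage and phenotype lengths differ")
    if covariates is not None and len(covariates) != len(y):
        raise ValueError("covariate rows do not match samples")
    mask = _complete_cases(d, y) if covariates is None else _complete_cases(
        d, y, pd.DataFrame(covariates).to_numpy(dtype=float)
    )
    d, y = d[mask], y[mask]
    cov = pd.DataFrame(covariates).loc[mask] if covariates is not None else None
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("phenotype must be binary 0/1")
    if y.sum() == 0 or y.sum() == y.size:
        raise DegenerateDataError("need at least one case and one control")
    if np.ptp(d) == 0:
        raise DegenerateDataError("zero dosage variance")

    X, _ = _design(d, cov)
    res = _fit_logit(y, X)
    beta = float(res.params[1])
    se = float(res.bse[1])
    z = stats.norm.ppf(0.975)
    return AssociationResult(
        snp_id=snp_id,
        effect_allele=effect_allele,
        odds_ratio=float(np.exp(beta)),
        ci95=(float(np.exp(beta - z * se)), float(np.exp(beta + z * se))),
        p_value=float(res.pvalues[1]),
        beta=beta,
        se=se,
        n=int(y.size),
        adjusted_for=adjusted_for,
    )


def conditional_adjust(
    dosage: Sequence[float],
    phenotype: Sequence[int],
    covariates: pd.DataFrame | None,
    index_dosages: pd.DataFrame,
    snp_id: str = "",
    effect_allele: str = "alt",
    max_r2: float = 0.99,
) -> AssociationResult:
    """Re-fit the additive model with index-SNP dosages as extra covariates.

    Raises :class:`~aisle.exceptions.CollinearityError` when the test SNP
    is in near-perfect LD (dosage r^2 > ``max_r2``) with an index SNP.
    """
    idx = pd.DataFrame(index_dosages)
    d = np.asarray(dosage, dtype=float)
    for c in idx.columns:
        g = idx[c].to_numpy(dtype=float)
        ok = np.isfinite(d) & np.isfinite(g)
        if np.ptp(d[ok]) > 0 and np.ptp(g[ok]) > 0:
            r2 = float(np.corrcoef(d[ok], g[ok])[0, 1] ** 2)
            if r2 > max_r2:
                raise CollinearityError(
                    f"test SNP nearly collinear with index SNP {c} (r2={r2:.4f})"
                )
    cov = pd.DataFrame(covariates) if covariates is not None else pd.DataFrame(index=idx.index)
    cov = pd.concat([cov.reset_index(drop=True), idx.reset_index(drop=True)], axis=1)
    return additive_logistic(
        dosage,
        phenotype,
        cov,
        snp_id=snp_id,
        effect_allele=effect_allele,
        adjusted_for=tuple(str(c) for c in idx.columns),
    )


# ---------------------------------------------------------------------------
# two-SNP haplotype EM


@dataclass
class EMResult:
    frequencies: dict[str, float]          # keyed by HAPLOTYPE_LABELS
    loglik_trace: list[float]
    n_iter: int
    converged: bool
    n: int

    @property
    def freqs(self) -> np.ndarray:
        return np.array([self.frequencies[h] for h in HAPLOTYPE_LABELS])


def _genotype_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    counts = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            counts[a, b] = np.sum((g1 == a) & (g2 == b))
    return counts


# haplotype-pair composition of each unambiguous genotype combination:
# genotype (g1,g2) -> list of (hap_i, hap_j) unordered pairs
_PAIRS: dict[tuple[int, int], list[tuple[int, int]]] = {}
for _g1 in range(3):
    for _g2 in range(3):
        pairs = []
        for h1 in range(4):
            for h2 in range(h1, 4):
                a1 = (h1 >> 1) + (h2 >> 1)      # alt count at SNP1
                a2 = (h1 & 1) + (h2 & 1)        # alt count at SNP2
                if (a1, a2) == (_g1, _g2):
                    pairs.append((h1, h2))
        _PAIRS[(_g1, _g2)] = pairs


def em_haplotypes_2snp(
    g1: Sequence[float],
    g2: Sequence[float],
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> EMResult:
    """EM haplotype-frequency estimation for two biallelic SNPs.

    ``g1``/``g2`` are alt-allele dosages in {0,1,2}; rows with missing
    (NaN) values at either SNP are dropped.  Haplotypes are indexed
    (SNP1 allele, SNP2 allele) with R=ref, A=alt in the order
    RR, RA, AR, AA.  Convergence when the largest frequency change is
    below ``tol``.  The log-likelihood trace is non-decreasing.
    """
    a1 = np.asarray(g1, dtype=float)
    a2 = np.asarray(g2, dtype=float)
    keep = np.isfinite(a1) & np.isfinite(a2)
    a1, a2 = a1[keep].astype(int), a2[keep].astype(int)
    if a1.size == 0:
        raise DegenerateDataError("no informative individuals")
    if not (set(a1) <= {0, 1, 2} and set(a2) <= {0, 1, 2}):
        raise ValueError("dosages must be 0/1/2")
    counts = _genotype_counts(a1, a2)
    n = int(counts.sum())

    f = np.full(4, 0.25)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E: expected haplotype counts; only (1,1) mixes two phase configs
        hap_counts = np.zeros(4)
        loglik = 0.0
        for (gg1, gg2), pairs in _PAIRS.items():
            c = counts[gg1, gg2]
            if c == 0:
                continue
            probs = np.array(
                [(1 if h1 == h2 else 2) * f[h1] * f[h2] for h1, h2 in pairs]
            )
            tot = probs.sum()
            if tot <= 0:
                # degenerate start; spread evenly over compatible pairs
                probs = np.ones(len(pairs))
                tot = probs.sum()
            loglik += c * np.log(tot)
            for (h1, h2), pr in zip(pairs, probs):
                w = c * pr / tot
                hap_counts[h1] += w
                hap_counts[h2] += w
        trace.append(float(loglik))
        new_f = hap_counts / (2 * n)
        delta = float(np.max(np.abs(new_f - f)))
        f = new_f
        if delta < tol:
            converged = True
            break
    return EMResult(
        frequencies=dict(zip(HAPLOTYPE_LABELS, f.tolist())),
        loglik_trace=trace,
        n_iter=it,
        converged=converged,
        n=n,
    )


def expected_haplotype_dosages(
    g1: Sequence[float],
    g2: Sequence[float],
    em: EMResult,
) -> pd.DataFrame:
    """Posterior-expected haplotype dosages per individual (rows sum to 2).

    Rows with missing genotypes get NaN dosages.
    """
    a1 = np.asarray(g1, dtype=float)
    a2 = np.asarray(g2, dtype=float)
    f = em.freqs
    out = np.full((a1.size, 4), np.nan)
    for i in range(a1.size):
        if not (np.isfinite(a1[i]) and np.isfinite(a2[i])):
            continue
        pairs = _PAIRS[(int(a1[i]), int(a2[i]))]
        probs = np.array([(1 if h1 == h2 else 2) * f[h1] * f[h2] for h1, h2 in pairs])
        tot = probs.sum()
        if tot <= 0:
            probs = np.ones(len(pairs))
            tot = probs.sum()
        row = np.zeros(4)
        for (h1, h2), pr in zip(pairs, probs):
            row[h1] += pr / tot
            row[h2] += pr / tot
        out[i] = row
    return pd.DataFrame(out, columns=list(HAPLOTYPE_LABELS))


@dataclass
class HaplotypeResult:
    baseline: str
    frequencies: dict[str, float]
    odds_ratios: dict[str, float]          # per non-baseline haplotype
    ci95: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    n: int


def haplotype_association(
    dosages: pd.DataFrame,
    phenotype: Sequence[int],
    covariates: pd.DataFrame | None,
    baseline: str,
    em: EMResult | None = None,
    min_baseline_freq: float = 1e-9,
) -> HaplotypeResult:
    """Logistic regression of case status on expected haplotype dosages.

    ``dosages`` is the frame from :func:`expected_haplotype_dosages`; the
    baseline haplotype's column is omitted from the design so every odds
    ratio is relative to it.
    """
    if baseline not in dosages.columns:
        raise ValueError(f"unknown baseline haplotype {baseline!r}")
    freqs = (
        em.frequencies
        if em is not None
        else {h: float(dosages[h].mean() / 2.0) for h in dosages.columns}
    )
    if freqs.get(baseline, 0.0) < min_baseline_freq:
        raise DegenerateDataError(f"baseline haplotype {baseline!r} has frequency ~0")

    y = np.asarray(phenotype, dtype=float)
    others = [h for h in dosages.columns if h != baseline]
    X_parts = [dosages[h].to_numpy(dtype=float) for h in others]
    cov = pd.DataFrame(covariates) if covariates is not None else None
    mask = _complete_cases(np.column_stack(X_parts), y) if cov is None else _complete_cases(
        np.column_stack(X_parts), y, cov.to_numpy(dtype=float)
    )
    Xo = np.column_stack([np.ones(int(mask.sum()))] + [x[mask] for x in X_parts])
    if cov is not None:
        Xo = np.column_stack([Xo, cov.to_numpy(dtype=float)[mask]])
    res = _fit_logit(y[mask], Xo)

    z = stats.norm.ppf(0.975)
    ors, cis, ps = {}, {}, {}
    for j, h in enumerate(others, start=1):
        b, s = float(res.params[j]), float(res.bse[j])
        ors[h] = float(np.exp(b))
        cis[h] = (float(np.exp(b - z * s)), float(np.exp(b + z * s)))
        ps[h] = float(res.pvalues[j])
    return HaplotypeResult(
        baseline=baseline,
        frequencies=freqs,
        odds_ratios=ors,
        ci95=cis,
        p_values=ps,
        n=int(mask.sum()),
    )


def ld_r2_from_frequencies(freqs: Sequence[float]) -> float:
    """r^2 from haplotype frequencies (RR, RA, AR, AA order)."""
    f = np.asarray(freqs, dtype=float)
    if f.shape != (4,) or not np.isclose(f.sum(), 1.0, atol=1e-6):
        raise ValueError("need 4 haplotype frequencies summing to 1")
    p_a = f[2] + f[3]  # alt frequency at SNP1
    p_b = f[1] + f[3]  # alt frequency at SNP2
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom <= 0:
        raise DegenerateDataError("monomorphic SNP: r^2 undefined")
    d = f[3] - p_a * p_b
    return float(min(1.0, d * d / denom))


def ld_r2(g1: Sequence[float], g2: Sequence[float], method: str = "em") -> float:
    """Pairwise LD r^2 between two SNPs from unphased dosages.

    ``method='em'`` uses EM haplotype frequencies (D^2 / pA qA pB qB);
    ``method='dosage'`` uses the squared Pearson correlation of dosages.
    On phase-unambiguous data the two agree.
    """
    if method == "em":
        em = em_haplotypes_2snp(g1, g2)
        return ld_r2_from_frequencies(em.freqs)
    if method == "dosage":
        a1 = np.asarray(g1, dtype=float)
        a2 = np.asarray(g2, dtype=float)
        keep = np.isfinite(a1) & np.isfinite(a2)
        a1, a2 = a1[keep], a2[keep]
        if np.ptp(a1) == 0 or np.ptp(a2) == 0:
            raise DegenerateDataError("monomorphic SNP: r^2 undefined")
        return float(np.corrcoef(a1, a2)[0, 1] ** 2)
    raise ValueError(f"unknown method {method!r}")
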
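"""Allelic-ratio computation and case/control allelic-imbalance testing.

The per-SNP test is an ordinary least-squares regression of the allelic
ratio on the binary disease code (control=0, case=1).  With a single binary
regressor the OLS slope equals the difference of group means and the slope
t-test is algebraically identical to the pooled two-sample t-test; both
facts are exploited by the test suite as an independent oracle.

Per-dataset p-values are combined across datasets with Fisher's method and
SNPs are promoted to "validated" when every dataset reaches the nominal
threshold and the combined p-value clears the stricter combined threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError

__all__ = [
    "AITestResult",
    "ValidatedSNP",
    "allelic_ratio",
    "ai_test",
    "fisher_combine",
    "reciprocal_validate",
    "rna_ai_compare",
    "bh_fdr",
]


def allelic_ratio(ref_depth, alt_depth):
    """Alt-allele read fraction ``alt / (ref + alt)``.

    Orientation is fixed to the record's alt allele for every sample and
    dataset, so the sign of downstream effects is comparable.  Accepts
    scalars or array-likes; raises on any zero total depth.
    """
    ref = np.asarray(ref_depth, dtype=float)
    alt = np.asarray(alt_depth, dtype=float)
    if np.any(ref < 0) or np.any(alt < 0):
        raise ValueError("negative read depth")
    total = ref + alt
    if np.any(total == 0):
        raise ValueError("zero total depth: allelic ratio undefined")
    out = alt / total
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class AITestResult:
    """One allelic-imbalance test (one SNP, one dataset, one cell state)."""

    snp_id: str
    dataset_id: str
    cell_state: str
    beta: float
    se: float
    p_value: float
    ci95: tuple[float, float]
    n_case: int
    n_control: int
    mean_ar_case: float
    mean_ar_control: float


def ai_test(
    ar: Sequence[float],
    groups: Sequence[int],
    *,
    snp_id: str = "",
    dataset_id: str = "",
    cell_state: str = "",
) -> AITestResult:
    """OLS of allelic ratio on the 0/1 group code.

    ``beta`` is the case minus control mean AR; the p-value is the
    two-sided t-test on the slope (df = n - 2).  If the fit is exact
    (zero residual variance) the p-value is 1 when the slope is 0 and 0
    otherwise.
    """
    y = np.asarray(ar, dtype=float)
    g = np.asarray(groups, dtype=int)
    if y.shape != g.shape or y.ndim != 1:
        raise ValueError("ar and groups must be equal-length 1-D sequences")
    if not set(np.unique(g)) <= {0, 1}:
        raise ValueError("groups must be coded 0 (control) / 1 (case)")
    n0 = int(np.sum(g == 0))
    n1 = int(np.sum(g == 1))
    if n0 == 0 or n1 == 0:
        raise DegenerateDataError("ai_test requires both groups to be present")

    m0 = float(np.mean(y[g == 0]))
    m1 = float(np.mean(y[g == 1]))
    beta = m1 - m0
    n = n0 + n1
    dof = n - 2
    rss = float(np.sum((y[g == 0] - m0) ** 2) + np.sum((y[g == 1] - m1) ** 2))
    if dof <= 0 or rss == 0.0:
        # exact fit: slope either vanishes (no signal, p=1) or is
        # infinitely well determined (p=0)
        p = 1.0 if beta == 0.0 else 0.0
        se = 0.0
        ci = (beta, beta)
    else:
        sigma2 = rss / dof
        se = float(np.sqrt(sigma2 * (1.0 / n0 + 1.0 / n1)))
        if se == 0.0:
            p = 1.0 if beta == 0.0 else 0.0
            ci = (beta, beta)
        else:
            t = beta / se
            p = float(2.0 * stats.t.sf(abs(t), dof))
            tcrit = float(stats.t.ppf(0.975, dof))
            ci = (beta - tcrit * se, beta + tcrit * se)
    p = min(max(p, 0.0), 1.0)
    return AITestResult(
        snp_id=snp_id,
        dataset_id=dataset_id,
        cell_state=cell_state,
        beta=beta,
        se=se,
        p_value=p,
        ci95=ci,
        n_case=n1,
        n_control=n0,
        mean_ar_case=m1,
        mean_ar_control=m0,
    )


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's combined probability: X2 = -2 sum(ln p) ~ chi2(2k).

    A single p-value is returned unchanged.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size == 1:
        return float(p[0])
    x2 = -2.0 * float(np.sum(np.log(p)))
    return float(stats.chi2.sf(x2, df=2 * p.size))


@dataclass
class ValidatedSNP:
    """Cross-dataset combination for one SNP within one cell state."""

    snp_id: str
    cell_state: str
    datasets: dict[str, AITestResult] = field(default_factory=dict)
    p_combined: float = float("nan")
    passed: bool = False

    @property
    def p_values(self) -> dict[str, float]:
        return {d: r.p_value for d, r in self.datasets.items()}

    @property
    def betas(self) -> dict[str, float]:
        return {d: r.beta for d, r in self.datasets.items()}


def reciprocal_validate(
    results: Iterable[AITestResult],
    alpha_nominal: float = 0.05,
    alpha_combined: float = 0.01,
) -> list[ValidatedSNP]:
    """Combine per-dataset AI tests and flag reciprocally validated SNPs.

    A SNP passes within a cell-state stratum iff it was testable in every
    dataset seen in ``results``, each per-dataset p is below
    ``alpha_nominal``, and the Fisher combination of those p-values is
    below ``alpha_combined``.  Effect direction is deliberately not
    required to agree across datasets.
    """
    results = list(results)
    if not results:
        raise DegenerateDataError("no AI test results to validate")
    all_datasets = sorted({r.dataset_id for r in results})
    if len(all_datasets) < 2:
        raise DegenerateDataError("reciprocal validation needs >=2 datasets")

    grouped: dict[tuple[str, str], ValidatedSNP] = {}
    for r in results:
        key = (r.snp_id, r.cell_state)
        v = grouped.setdefault(key, ValidatedSNP(snp_id=r.snp_id, cell_state=r.cell_state))
        v.datasets[r.dataset_id] = r

    out = []
    for v in grouped.values():
        pvals = [v.datasets[d].p_value for d in sorted(v.datasets)]
        v.p_combined = fisher_combine(pvals)
        testable_everywhere = set(v.datasets) == set(all_datasets)
        v.passed = bool(
            testable_everywhere
            and all(p < alpha_nominal for p in pvals)
            and v.p_combined < alpha_combined
        )
        out.append(v)
    out.sort(key=lambda v: (v.cell_state, v.snp_id))
    return out


def rna_ai_compare(
    ar: Sequence[float],
    groups: Sequence[int],
    cell_states: Sequence[str] | None = None,
    *,
    snp_id: str = "",
    dataset_id: str = "",
) -> list[AITestResult]:
    """Case/control comparison of RNA-derived allelic ratios.

    Uses the same linear model as :func:`ai_test`, applied separately per
    cell state when states are given (one combined stratum otherwise).
    """
    y = np.asarray(ar, dtype=float)
    g = np.asarray(groups, dtype=int)
    if cell_states is None:
        return [ai_test(y, g, snp_id=snp_id, dataset_id=dataset_id, cell_state="all")]
    cs = np.asarray(cell_states)
    out = []
    for state in pd.unique(cs):
        mask = cs == state
        out.append(
            ai_test(y[mask], g[mask], snp_id=snp_id, dataset_id=dataset_id, cell_state=str(state))
        )
    return out


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (reported, never used to gate)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
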
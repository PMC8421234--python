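"""Covariate screening and forward model selection for the hypothyroidism cohort.

Pipeline stages, mirroring routine clinical-dosimetry practice:

1. univariate logistic screening of every candidate factor, one at a time;
2. Spearman rank correlation among the significant factors — dose-volume
   metrics of one organ are heavily collinear, so factors with |rho| above a
   threshold (0.8) are clustered and a single representative (the member
   with the smallest univariate p) is kept per cluster;
3. forward stepwise logistic regression over the representatives, adding at
   each step the candidate with the smallest likelihood-ratio p-value while
   it is below ``p_enter``.

No multiple-testing correction is applied at any stage (deliberate; see the
methods note).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .logistic import LogisticModel, LogisticResults, SeparationError

__all__ = [
    "STANDARD_FACTORS",
    "UnivariateResult",
    "CorrelationCluster",
    "ForwardSelectionResult",
    "univariate_screen",
    "spearman_rho",
    "correlation_clusters",
    "forward_select",
]

#: Candidate factors screened in the cohort analysis (cohort CSV column names).
STANDARD_FACTORS = (
    "gender", "age", "t_stage", "n_stage", "clinical_stage", "chemotherapy",
    "volume_cc", "dmin_gy", "dmax_gy", "dmean_gy", "fx_dose_gy",
    "v10", "v20", "v30", "v40", "v45", "v50", "v60", "v70",
)

#: Dose metrics examined for collinearity (the organ's DVH family + Dmean/Dmin).
DOSE_METRIC_FACTORS = (
    "dmin_gy", "dmax_gy", "dmean_gy", "fx_dose_gy",
    "v10", "v20", "v30", "v40", "v45", "v50", "v60", "v70",
)


@dataclass
class UnivariateResult:
    """Single-factor logistic fit: per-unit odds ratio, 95% CI, Wald p."""

    factor: str
    coef: float = np.nan
    se: float = np.nan
    odds_ratio: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p_value: float = np.nan
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


@dataclass
class CorrelationCluster:
    """A connected component of the |rho| > threshold collinearity graph."""

    members: tuple[str, ...]
    representative: str


@dataclass
class ForwardSelectionResult:
    """Final forward-selected model plus the entry trace."""

    results: LogisticResults | None
    selected: tuple[str, ...]
    trace: list[dict] = field(default_factory=list)


def univariate_screen(
    cohort: pd.DataFrame,
    factors: tuple[str, ...] | list[str] = STANDARD_FACTORS,
    outcome: str = "outcome_12m",
) -> list[UnivariateResult]:
    """One single-covariate logistic fit per factor, in the order given.

    Per-factor failures (zero variance, separation, non-convergence) are
    recorded on the result and do not abort the remaining factors.
    """
    out: list[UnivariateResult] = []
    for f in factors:
        try:
            res = LogisticModel.from_dataframe(cohort, outcome, [f]).fit()
            if not res.converged:
                out.append(UnivariateResult(factor=f, error="did not converge"))
                continue
            ci = res.conf_int()
            out.append(
                UnivariateResult(
                    factor=f,
                    coef=float(res.params[1]),
                    se=float(res.bse[1]),
                    odds_ratio=float(np.exp(res.params[1])),
                    ci_low=float(np.exp(ci[1, 0])),
                    ci_high=float(np.exp(ci[1, 1])),
                    p_value=float(res.pvalues[1]),
                )
            )
        except (ValueError, KeyError, SeparationError) as err:
            out.append(UnivariateResult(factor=f, error=str(err)))
    return out


def univariate_table(results: list[UnivariateResult]) -> pd.DataFrame:
    """Screening results as a table (OR, 95% CI, p per factor)."""
    return pd.DataFrame(
        [
            {
                "factor": r.factor,
                "odds_ratio": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
                "error": r.error,
            }
            for r in results
        ]
    ).set_index("factor")


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (midranks for ties).

    Raises on unequal lengths, n < 3, or a constant input (the rank
    correlation is undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, a):
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)


def correlation_clusters(
    cohort: pd.DataFrame,
    factors: tuple[str, ...] | list[str],
    rho_threshold: float = 0.8,
    univariate: list[UnivariateResult] | None = None,
    outcome: str = "outcome_12m",
) -> list[CorrelationCluster]:
    """Cluster collinear factors and pick one representative per cluster.

    Factors are nodes; an edge joins two factors when |Spearman rho| exceeds
    ``rho_threshold``. Connected components are the clusters; the
    representative is the member with the smallest univariate p-value
    (ties broken by larger |Wald z|). Undefined correlations (constant
    column) contribute no edge and emit a warning.
    """
    factors = list(factors)
    uf = _UnionFind(factors)
    for i, a in enumerate(factors):
        for b in factors[i + 1:]:
            try:
                rho = spearman_rho(cohort[a], cohort[b])
            except ValueError as err:
                warnings.warn(f"correlation {a}~{b} undefined ({err}); no edge")
                continue
            if abs(rho) > rho_threshold:
                uf.union(a, b)
    if univariate is None:
        univariate = univariate_screen(cohort, factors, outcome=outcome)
    uni = {r.factor: r for r in univariate}

    groups: dict[str, list[str]] = {}
    for f in factors:
        groups.setdefault(uf.find(f), []).append(f)

    def rep_key(f: str):
        r = uni.get(f)
        if r is None or not r.ok:
            return (np.inf, 0.0)
        z = abs(r.coef / r.se) if r.se else 0.0
        return (r.p_value, -z)

    clusters = [
        CorrelationCluster(members=tuple(members), representative=min(members, key=rep_key))
        for members in groups.values()
    ]
    clusters.sort(key=lambda c: factors.index(c.members[0]))
    return clusters


def forward_select(
    cohort: pd.DataFrame,
    candidates: tuple[str, ...] | list[str],
    outcome: str = "outcome_12m",
    p_enter: float = 0.05,
) -> ForwardSelectionResult:
    """Forward stepwise logistic regression with likelihood-ratio entry.

    Starting from the intercept-only model, repeatedly add the candidate
    whose likelihood-ratio test against the current model has the smallest
    p-value, provided it is below ``p_enter``; stop when none qualifies.
    If nothing enters, the intercept-only fit is returned with an empty
    trace (not an error).
    """
    selected: list[str] = []
    remaining = list(candidates)
    trace: list[dict] = []

    def fit(fs: list[str]) -> LogisticResults:
        if fs:
            return LogisticModel.from_dataframe(cohort, outcome, fs).fit()
        return LogisticModel(cohort[outcome].to_numpy()).fit()

    current = fit(selected)
    while remaining:
        best = None
        for f in remaining:
            try:
                cand = fit(selected + [f])
            except (ValueError, SeparationError):
                continue
            lr = 2.0 * (cand.llf - current.llf)
            p = float(stats.chi2.sf(max(lr, 0.0), df=1))
            if best is None or p < best[1]:
                best = (f, p, lr, cand)
        if best is None or best[1] >= p_enter:
            break
        f, p, lr, cand = best
        selected.append(f)
        remaining.remove(f)
        trace.append({"step": len(selected), "factor": f, "lr_stat": lr, "p_value": p})
        current = cand
    return ForwardSelectionResult(results=current, selected=tuple(selected), trace=trace)
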
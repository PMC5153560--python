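"""Univariate and multivariate association statistics.

Pearson correlations between image metrics and clinical scores,
Benjamini-Hochberg step-up control of the false discovery rate across
the metric family tested against each clinical measure, and stepwise
multivariate linear regression (entry p < 0.10, removal p > 0.05, age
always among the candidates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .texture import FEATURE_NAMES

__all__ = [
    "METRIC_NAMES",
    "CLINICAL_MEASURES",
    "CorrelationResult",
    "FdrDecision",
    "StepwiseModel",
    "AssociationReport",
    "pearson_corr",
    "bh_fdr",
    "stepwise_regression",
    "analyze_measure",
]

#: the metric family tested against each clinical measure: conventional
#: normalized mean uptake plus the 13 texture statistics (m = 14).
METRIC_NAMES = ("mean_normalized",) + FEATURE_NAMES

CLINICAL_MEASURES = ("updrs3", "dd_diag_months", "dd_sympt_months", "moca")


@dataclass
class CorrelationResult:
    metric: str
    measure: str
    n: int
    r: float
    p: float
    fdr_significant: bool = False


@dataclass
class FdrDecision:
    """Outcome of the BH step-up procedure on one family of p-values."""

    m: int
    alpha: float
    k_star: int
    p_sorted: np.ndarray
    order: np.ndarray
    significant: np.ndarray  # boolean, aligned with the input vector

    @property
    def n_discoveries(self) -> int:
        return int(self.significant.sum())


@dataclass
class StepwiseModel:
    response: str
    candidates: List[str]
    selected: List[str]
    coefficients: Dict[str, float] = field(default_factory=dict)
    std_errors: Dict[str, float] = field(default_factory=dict)
    p_values: Dict[str, float] = field(default_factory=dict)
    enter_p: float = 0.10
    remove_p: float = 0.05
    log: List[str] = field(default_factory=list)
    n: int = 0


@dataclass
class AssociationReport:
    """Univariate block + FDR decision + stepwise model for one measure."""

    measure: str
    region: str
    side: str
    subset: str
    table: pd.DataFrame
    fdr: FdrDecision
    model: StepwiseModel


def pearson_corr(x, y, metric: str = "", measure: str = "") -> CorrelationResult:
    """Pearson r with a two-sided p from the t distribution (n - 2 df).

    NaNs are dropped pairwise; constant inputs raise rather than
    returning NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(metric=metric, measure=measure, n=n, r=float(r), p=float(p))


def bh_fdr(p_values, alpha: float = 0.05) -> FdrDecision:
    """Benjamini-Hochberg step-up procedure.

    Sort p ascending as P(1) <= ... <= P(m); k* is the largest k with
    P(k) <= (k/m) * alpha (0 if none); the tests with the k* smallest
    p-values are declared discoveries — including any with
    P(j) > (j/m) * alpha for j < k*.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    k = np.arange(1, m + 1)
    passing = np.nonzero(p_sorted <= k / m * alpha)[0]
    k_star = int(passing[-1] + 1) if passing.size else 0
    significant = np.zeros(m, dtype=bool)
    significant[order[:k_star]] = True
    return FdrDecision(
        m=m, alpha=alpha, k_star=k_star, p_sorted=p_sorted, order=order,
        significant=significant,
    )


def _fit_ols(y: np.ndarray, X: pd.DataFrame):
    design = sm.add_constant(X, has_constant="add")
    return sm.OLS(y, design).fit()


def _collinearity_check(candidates: pd.DataFrame) -> None:
    for name, col in candidates.items():
        if np.ptp(col.to_numpy()) == 0:
            raise ValueError(f"candidate {name!r} is constant")
    if candidates.shape[1] < 2:
        return
    corr = candidates.corr().to_numpy()
    np.fill_diagonal(corr, 0.0)
    i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
    if abs(corr[i, j]) > 1.0 - 1e-10:
        a, b = candidates.columns[i], candidates.columns[j]
        raise ValueError(f"collinear candidates: {a!r} and {b!r}")


def stepwise_regression(
    response,
    candidates,
    enter_p: float = 0.10,
    remove_p: float = 0.05,
    max_iter: int = 50,
    response_name: str = "y",
) -> StepwiseModel:
    """Forward-entry / backward-removal OLS variable selection.

    Each forward step adds the candidate with the smallest partial
    p-value among those below ``enter_p`` (ties: smaller p, then
    lexicographic name); each backward step removes the retained
    predictor with the largest partial p-value if above ``remove_p``.
    The two steps alternate until a full pass changes nothing. A
    variable that is entered and immediately removed again counts as no
    change (this terminates the oscillation possible when the entry
    threshold exceeds the removal threshold, as with the 0.10/0.05
    defaults); a previously visited selection state also terminates.
    All fits are ordinary least squares with an intercept; partial
    p-values are the two-sided t-tests on each coefficient.
    """
    if isinstance(candidates, dict):
        candidates = pd.DataFrame(candidates)
    candidates = candidates.astype(float)
    y = np.asarray(response, dtype=float)
    if y.size != len(candidates):
        raise ValueError("response and candidates have different lengths")
    _collinearity_check(candidates)

    names = sorted(candidates.columns)
    selected: List[str] = []
    log: List[str] = []
    seen = {frozenset()}

    for iteration in range(max_iter):
        changed = False
        # forward step
        entry: List[Tuple[float, str]] = []
        for name in names:
            if name in selected:
                continue
            if y.size < len(selected) + 3:
                break
            fit = _fit_ols(y, candidates[selected + [name]])
            entry.append((float(fit.pvalues[name]), name))
        added = None
        if entry:
            p_best, name_best = min(entry)  # ties: smaller p, then name
            if p_best < enter_p:
                selected.append(name_best)
                added = name_best
                changed = True
                log.append(f"iter {iteration}: entered {name_best} (p={p_best:.4g})")
        # backward step
        if selected:
            fit = _fit_ols(y, candidates[selected])
            pvals = {name: float(fit.pvalues[name]) for name in selected}
            name_worst = max(selected, key=lambda nm: (pvals[nm], nm))
            if pvals[name_worst] > remove_p:
                selected.remove(name_worst)
                log.append(
                    f"iter {iteration}: removed {name_worst} (p={pvals[name_worst]:.4g})"
                )
                if name_worst == added:
                    log.append(f"iter {iteration}: entry/removal cancel; converged")
                    break
                changed = True
        if not changed:
            break
        state = frozenset(selected)
        if state in seen:
            log.append(f"iter {iteration}: selection state repeated; converged")
            break
        seen.add(state)
    else:
        raise RuntimeError(f"stepwise selection did not converge in {max_iter} iterations")

    model = StepwiseModel(
        response=response_name,
        candidates=list(candidates.columns),
        selected=list(selected),
        enter_p=enter_p,
        remove_p=remove_p,
        log=log,
        n=int(y.size),
    )
    if selected:
        fit = _fit_ols(y, candidates[selected])
        model.coefficients = {nm: float(fit.params[nm]) for nm in selected}
        model.std_errors = {nm: float(fit.bse[nm]) for nm in selected}
        model.p_values = {nm: float(fit.pvalues[nm]) for nm in selected}
    return model


def _join_features_clinical(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    region: str,
    side: str,
    subset: str,
) -> pd.DataFrame:
    rows = features[(features["region"] == region) & (features["side"] == side)]
    merged = rows.merge(clinical, on="subject_id", how="inner")
    if subset == "PD":
        merged = merged[merged["group"] == "PD"]
    elif subset in ("PD+HC", "all"):
        pass
    else:
        raise ValueError(f"unknown subset {subset!r} (use 'PD' or 'PD+HC')")
    return merged.reset_index(drop=True)


def analyze_measure(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    measure: str,
    region: str = "caudate",
    side: str = "more",
    subset: str = "PD",
    alpha: float = 0.05,
    enter_p: float = 0.10,
    remove_p: float = 0.05,
    metrics: Sequence[str] = METRIC_NAMES,
) -> AssociationReport:
    """Full statistical battery for one clinical measure.

    Univariate Pearson correlation of conventional uptake plus the 13
    texture metrics against ``measure`` (complete cases per metric), BH
    step-up FDR across that metric family (m = 14), then stepwise
    multivariate selection over all metrics with subject age added as a
    candidate confounder.
    """
    if measure not in clinical.columns:
        raise KeyError(f"missing clinical column {measure!r}")
    data = _join_features_clinical(features, clinical, region, side, subset)
    if len(data) == 0:
        raise ValueError("joined feature/clinical table is empty")

    results: List[CorrelationResult] = []
    for metric in metrics:
        if metric not in data.columns:
            raise KeyError(f"missing metric column {metric!r}")
        res = pearson_corr(data[metric], data[measure], metric=metric, measure=measure)
        if res.n < 10:
            raise ValueError(
                f"fewer than 10 complete cases for {metric} vs {measure} (n={res.n})"
            )
        results.append(res)

    fdr = bh_fdr(np.array([r.p for r in results]), alpha=alpha)
    for res, sig in zip(results, fdr.significant):
        res.fdr_significant = bool(sig)

    model_cols = list(metrics) + ["age"]
    complete = data[model_cols + [measure]].dropna()
    model = stepwise_regression(
        complete[measure],
        complete[model_cols],
        enter_p=enter_p,
        remove_p=remove_p,
        response_name=measure,
    )

    table = pd.DataFrame(
        {
            "metric": [r.metric for r in results],
            "measure": measure,
            "region": region,
            "side": side,
            "subset": subset,
            "n": [r.n for r in results],
            "r": [r.r for r in results],
            "p": [r.p for r in results],
            "fdr_significant": [r.fdr_significant for r in results],
            "selected": [r.metric in model.selected for r in results],
            "coef": [model.coefficients.get(r.metric, np.nan) for r in results],
            "coef_p": [model.p_values.get(r.metric, np.nan) for r in results],
        }
    )
    if "age" in model.selected:
        age_row = pd.DataFrame(
            {
                "metric": ["age"],
                "measure": [measure],
                "region": [region],
                "side": [side],
                "subset": [subset],
                "n": [model.n],
                "r": [np.nan],
                "p": [np.nan],
                "fdr_significant": [False],
                "selected": [True],
                "coef": [model.coefficients["age"]],
                "coef_p": [model.p_values["age"]],
            }
        )
        table = pd.concat([table, age_row], ignore_index=True)
    return AssociationReport(
        measure=measure, region=region, side=side, subset=subset,
        table=table, fdr=fdr, model=model,
    )
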
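"""Cohort statistics: rank correlations, covariate-adjusted linear models,
genotype-stratified analyses, and group contrasts.

Mirrors the analysis conventions of the neuropathology literature this
package targets: Spearman rank correlations for continuous pathological
variables, ordinary least squares controlling for age, sex and
post-mortem interval (optionally fibrinogen burden), standardized β for
predictors, two-sided tests at α = 0.05 and no multiple-testing
correction (each test is reported on its own; see docs/methods.md).
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import (
    CollinearityError,
    InvalidInputError,
    MissingOutcomeError,
    UndefinedCorrelationError,
)
from .types import GroupContrast, StatResult

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def _exact_spearman_null_counts(n: int) -> np.ndarray:
    """Distribution of S = Σ dᵢ² over all n! rank permutations.

    Bitmask dynamic programme: positions take ranks one by one; state is
    the set of used ranks and the partial sum of squared differences.
    Returns ``counts[s]`` = number of permutations with S = s.
    """
    s_max = (n**3 - n) // 3
    counts = {0: np.zeros(s_max + 1)}
    counts[0][0] = 1.0
    # iterate masks in order of population count
    by_pop: list[list[int]] = [[] for _ in range(n + 1)]
    for mask in range(1 << n):
        by_pop[bin(mask).count("1")].append(mask)
    table = np.zeros((1 << n, s_max + 1))
    table[0, 0] = 1.0
    for pop in range(n):
        for mask in by_pop[pop]:
            row = table[mask]
            if not row.any():
                continue
            i = pop  # next position to fill
            for j in range(n):
                if mask & (1 << j):
                    continue
                d2 = (i - j) ** 2
                new = mask | (1 << j)
                if d2 == 0:
                    table[new] += row
                else:
                    table[new, d2:] += row[:-d2]
    return table[(1 << n) - 1]


def _exact_spearman_p(r_obs: float, n: int) -> float:
    """Two-sided exact p for tie-free Spearman r at small n."""
    counts = _exact_spearman_null_counts(n)
    s_vals = np.arange(counts.size)
    r_null = 1.0 - 6.0 * s_vals / (n**3 - n)
    keep = np.abs(r_null) >= abs(r_obs) - 1e-12
    return float(counts[keep].sum() / counts.sum())


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    outcome: str = "",
    predictor: str = "",
    stratum: str = "",
) -> StatResult:
    """Spearman rank correlation with pairwise-complete handling of NaN.

    Ranks are averaged over ties. The two-sided p-value uses the exact
    permutation distribution for n ≤ 10 when the data are tie-free, and
    the t approximation otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise InvalidInputError(f"length mismatch: {x.shape} vs {y.shape}")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise InvalidInputError(f"need >= 3 complete pairs, got {n}")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    res = sps.spearmanr(x, y)
    r = float(res.statistic)
    has_ties = np.unique(x).size < n or np.unique(y).size < n
    if n <= 10 and not has_ties:
        p = _exact_spearman_p(r, n)
    else:
        p = float(res.pvalue)
    return StatResult(kind="spearman", estimate=r, p_value=p, n=n,
                      outcome=outcome, predictor=predictor, stratum=stratum)


# ---------------------------------------------------------------------------
# covariate-adjusted linear models
# ---------------------------------------------------------------------------

def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def _encode_design(data: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    out = {}
    for col in columns:
        v = data[col]
        if v.dtype == object or str(v.dtype) == "category":
            levels = sorted(v.dropna().unique())
            if len(levels) > 2:
                raise InvalidInputError(
                    f"categorical covariate {col!r} has >2 levels; encode manually"
                )
            out[col] = (v == levels[-1]).astype(float)
        else:
            out[col] = v.astype(float)
    return pd.DataFrame(out, index=data.index)


def fit_adjusted_model(
    outcome: str,
    predictor: str,
    covariates: Sequence[str],
    data: pd.DataFrame,
    transform: str = "auto",
) -> StatResult:
    """OLS of (optionally log-transformed) outcome on predictor + covariates.

    The reported estimate is the standardized β of the predictor
    (outcome and predictor z-scored before fitting), with its two-sided
    p-value. ``transform="auto"`` applies the pre-registered rule: log
    the outcome when its Shapiro–Wilk statistic is below 0.95 on the raw
    but not on the logged values (requires a strictly positive outcome);
    the decision is recorded in the result and logged.
    """
    covariates = list(covariates)
    cols = [outcome, predictor] + covariates
    complete = data[cols].dropna()
    n = len(complete)
    n_params = 2 + len(covariates)
    if n <= n_params + 2:
        raise InvalidInputError(
            f"need n > {n_params + 2} complete cases for {n_params} parameters, got {n}"
        )
    design = _encode_design(complete, [predictor] + covariates)
    y = complete[outcome].astype(float).to_numpy()

    applied = "none"
    if transform == "log":
        y = np.log(y)
        applied = "log"
    elif transform == "auto" and n >= 4:
        w_raw = sps.shapiro(y).statistic
        if w_raw < 0.95 and (y > 0).all():
            w_log = sps.shapiro(np.log(y)).statistic
            if w_log >= 0.95:
                y = np.log(y)
                applied = "log"
        logger.debug("transform rule for %s: W_raw=%.3f -> %s", outcome, w_raw, applied)

    y = _zscore(y)
    design[predictor] = _zscore(design[predictor].to_numpy())
    X = sm.add_constant(design, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, r_diag, pivots = _pivoted_qr(X.to_numpy())
        aliased = [X.columns[p] for p in pivots[rank:]]
        raise CollinearityError(aliased)
    fit = sm.OLS(y, X).fit()
    return StatResult(
        kind="linear_model",
        estimate=float(fit.params[predictor]),
        p_value=float(fit.pvalues[predictor]),
        n=n,
        outcome=outcome,
        predictor=predictor,
        covariates=covariates,
        transform=applied,
    )


def _pivoted_qr(a: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(a, pivoting=True)
    return q, np.abs(np.diag(r)), piv


# ---------------------------------------------------------------------------
# stratified correlations and group contrasts
# ---------------------------------------------------------------------------

def stratified_correlations(
    data: pd.DataFrame,
    markers: Sequence[str],
    outcome: str,
    stratifier: str = "genotype",
) -> list[StatResult]:
    """One Spearman result per (marker, stratum); strata never pooled.

    Strata with fewer than 3 complete observations are skipped with a
    logged warning.
    """
    results = []
    for level, sub in data.groupby(stratifier, sort=True):
        if len(sub) < 3:
            logger.warning("stratum %s=%r has n=%d < 3; skipped",
                           stratifier, level, len(sub))
            continue
        for marker in markers:
            results.append(spearman(sub[marker], sub[outcome],
                                    outcome=outcome, predictor=marker,
                                    stratum=str(level)))
    return results


def group_contrast(
    data: pd.DataFrame,
    outcome: str,
    group_a: str,
    group_b: str,
    covariates: Sequence[str] = (),
    group_col: str = "group",
) -> GroupContrast:
    """Group means ± SEM, percent difference, and covariate-adjusted p.

    ``group_a`` is the reference (by convention the control / larger
    group): percent_difference = 100 × (mean_a − mean_b) / mean_a. The
    adjusted p comes from the standardized-β model with the group
    indicator as predictor.
    """
    sub = data[data[group_col].isin([group_a, group_b])].copy()
    means, sems, ns = {}, {}, {}
    for g in (group_a, group_b):
        vals = sub.loc[sub[group_col] == g, outcome].dropna()
        if vals.empty:
            raise MissingOutcomeError(
                f"outcome {outcome!r} entirely absent for group {g!r}"
            )
        means[g] = float(vals.mean())
        sems[g] = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
        ns[g] = int(len(vals))
    sub["_group_b"] = (sub[group_col] == group_b).astype(float)
    if sub[outcome].dropna().nunique() < 2:
        adjusted_p = 1.0  # constant outcome: no evidence of any contrast
    else:
        try:
            model = fit_adjusted_model(outcome, "_group_b", covariates, sub)
            adjusted_p = model.p_value
        except InvalidInputError:
            # too few cases for the adjusted model: fall back to Welch's t
            a = sub.loc[sub._group_b == 0, outcome].dropna()
            b = sub.loc[sub._group_b == 1, outcome].dropna()
            adjusted_p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
            logger.warning("group_contrast(%s): n too small for the adjusted "
                           "model; unadjusted Welch p reported", outcome)
    return GroupContrast(
        group_a=group_a, group_b=group_b,
        mean_a=means[group_a], mean_b=means[group_b],
        sem_a=sems[group_a], sem_b=sems[group_b],
        percent_difference=100.0 * (means[group_a] - means[group_b]) / means[group_a],
        adjusted_p=adjusted_p,
        n_a=ns[group_a], n_b=ns[group_b],
        outcome=outcome,
    )


def results_to_frame(results: Sequence[object]) -> pd.DataFrame:
    """Tidy results table: one row per StatResult or GroupContrast."""
    rows = []
    for r in results:
        if isinstance(r, StatResult):
            rows.append({
                "kind": r.kind, "outcome": r.outcome, "predictor": r.predictor,
                "stratum": r.stratum, "estimate": r.estimate, "p_value": r.p_value,
                "n": r.n, "covariates": "+".join(r.covariates),
                "transform": r.transform,
            })
        elif isinstance(r, GroupContrast):
            rows.append({
                "kind": "group_contrast", "outcome": r.outcome,
                "predictor": f"{r.group_b} vs {r.group_a}", "stratum": "",
                "estimate": r.percent_difference, "p_value": r.adjusted_p,
                "n": r.n_a + r.n_b, "covariates": "", "transform": "",
            })
        else:
            raise InvalidInputError(f"cannot tabulate {type(r).__name__}")
    return pd.DataFrame(rows)
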
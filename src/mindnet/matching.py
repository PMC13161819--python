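"""Propensity-score matching of patients to controls.

A logistic regression of group membership on confounders (sex and age by
default) yields a propensity score per subject; patients are then matched
1:1 to controls by greedy nearest-neighbour matching without replacement,
discarding pairs whose score difference exceeds a caliper (default 0.073 on
the probability scale).  Balance is assessed with standardized mean
differences (SMD); |SMD| < 0.2 is treated as acceptable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "MatchResult",
    "fit_propensity",
    "match_caliper",
    "standardized_mean_difference",
    "balance_report",
    "DEFAULT_CALIPER",
    "SMD_ACCEPTABLE",
]

DEFAULT_CALIPER = 0.073  # probability-scale caliper
SMD_ACCEPTABLE = 0.2


@dataclass(frozen=True)
class MatchResult:
    """Matched pairs plus the scores they were derived from."""

    pairs: list  # [(patient_id, control_id), ...]
    scores: pd.Series  # propensity per subject
    caliper: float

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def matched_ids(self) -> list:
        return [s for pair in self.pairs for s in pair]


def fit_propensity(
    pheno: pd.DataFrame,
    covariates=("sex", "age"),
    group_col: str = "group",
    penalized: bool = False,
) -> pd.Series:
    """Logistic-regression propensity scores P(patient | covariates).

    Fitted by iteratively reweighted least squares (statsmodels GLM).  On
    perfect separation an error suggests the ridge-penalized fallback
    (``penalized=True``).
    """
    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    y = pheno[group_col].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("group must be binary 0/1")
    x = sm.add_constant(pheno[list(covariates)].to_numpy(dtype=float))
    try:
        if penalized:
            model = sm.Logit(y, x)
            res = model.fit_regularized(alpha=1.0, disp=0)
            fitted = model.predict(res.params, x)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                res = sm.GLM(y, x, family=sm.families.Binomial()).fit()
            fitted = res.fittedvalues
            if not np.isfinite(res.params).all():
                raise PerfectSeparationError
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise ValueError(
            "perfect separation in the propensity model; "
            "retry with penalized=True"
        ) from exc
    return pd.Series(
        np.clip(fitted, 1e-12, 1 - 1e-12),
        index=pheno["subject_id"],
        name="propensity",
    )


def match_caliper(
    scores: pd.Series,
    groups: pd.Series,
    caliper: float = DEFAULT_CALIPER,
) -> MatchResult:
    """Greedy 1:1 nearest-neighbour matching without replacement.

    Patients are processed in descending propensity order (ties broken by
    subject id); each takes the nearest remaining control, and the pair is
    discarded if the score difference exceeds the caliper.  An infeasible
    problem yields an empty result, not an exception.
    """
    if caliper <= 0:
        raise ValueError("caliper must be positive")
    groups = groups.loc[scores.index]
    pat = scores[groups == 1]
    ctl = scores[groups == 0]
    order = pat.reset_index()
    order = order.sort_values(
        by=[order.columns[1], order.columns[0]], ascending=[False, True]
    )
    available = ctl.copy()
    pairs = []
    for _, (pid, ps) in order.iterrows():
        if available.empty:
            break
        diff = (available - ps).abs()
        # nearest control; ties broken by subject-id order
        best = diff[diff == diff.min()].index.sort_values()[0]
        if diff[best] <= caliper:
            pairs.append((pid, best))
            available = available.drop(best)
    return MatchResult(pairs=pairs, scores=scores, caliper=caliper)


def standardized_mean_difference(values, groups) -> float:
    """|mean1 - mean0| / pooled sd; binary covariates use proportion sds.

    Pooled sd is the square root of the average of the two group variances
    (sample, ddof=1); for binary variables the variances are p(1-p).
    Returns +inf when the pooled sd is zero but the means differ.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups, dtype=float)
    v1, v0 = v[g == 1], v[g == 0]
    if len(v1) < 2 or len(v0) < 2:
        raise ValueError("need >= 2 subjects per group")
    binary = set(np.unique(v)) <= {0.0, 1.0}
    if binary:
        p1, p0 = v1.mean(), v0.mean()
        pooled = np.sqrt((p1 * (1 - p1) + p0 * (1 - p0)) / 2.0)
        diff = abs(p1 - p0)
    else:
        pooled = np.sqrt((v1.var(ddof=1) + v0.var(ddof=1)) / 2.0)
        diff = abs(v1.mean() - v0.mean())
    if pooled == 0:
        return 0.0 if diff == 0 else float("inf")
    return float(diff / pooled)


def balance_report(
    pheno: pd.DataFrame,
    covariates,
    result: MatchResult,
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-covariate SMD before and after matching."""
    indexed = pheno.set_index("subject_id")
    rows = []
    matched = result.matched_ids()
    for c in covariates:
        before = standardized_mean_difference(
            indexed[c], indexed[group_col]
        )
        if matched:
            sub = indexed.loc[matched]
            after = standardized_mean_difference(sub[c], sub[group_col])
        else:
            after = np.nan
        rows.append((c, before, after))
    out = pd.DataFrame(rows, columns=["covariate", "smd_before", "smd_after"])
    out["balanced_after"] = out["smd_after"] < SMD_ACCEPTABLE
    return out
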
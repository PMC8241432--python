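"""The analysis chain: mass-univariate scan, Bonferroni selection,
weighted composite scores, and outcome associations.

For each (normalized feature, neuropsychological test) pair a linear
model ``test ~ intercept + V_j + age + sex`` is fitted (complete-case per
model).  Features passing the per-test Bonferroni threshold
``alpha / n_features`` form that test's composite,

    score_i = (1/m) * sum_j beta_j * V_ij,

a weighted mean of the selected normalized features with the scan effect
sizes as weights (a plain-sum variant is available; inference is
invariant to the 1/m factor since rescaling a predictor rescales its
coefficient and SE identically).  Composites are then tested against
their neuropsychological test (linear, age+sex adjusted) and against MCI
status (logistic, age+sex+education adjusted, Wald inference), with the
reporting threshold ``alpha / n_tests`` for the 18-test battery.

Selection and association on the same sample reproduce the original
procedure and are the default; because that reuse is anti-conservative
under the null, a split-sample mode (select on one half, associate on
the other) is provided as an honest alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats_core
from .stats_core import bonferroni_threshold, fit_linear, fit_logistic
from .synthetic_cohort import EDUCATION_LEVELS, NP_TEST_NAMES, TIMED_TESTS

__all__ = [
    "scan_associations",
    "select_significant",
    "composite_score",
    "associate_composite",
    "associate_mci",
    "group_compare",
    "CompositeScoreSet",
    "percent",
]

logger = logging.getLogger("penclock")

#: Sex indicator coding used in every adjusted model.
SEX_CODES = {"female": 1.0, "male": 0.0}

#: Minimum outcome events for a tabulated logistic fit.
DEFAULT_MIN_EVENTS = 10


def _covariate_design(covariates: pd.DataFrame,
                      education_levels: list[str] | None = None
                      ) -> tuple[np.ndarray, list[str]]:
    """[age, sex(female=1)] columns, plus dummies for the given education
    levels (reference = everything else) for MCI models only."""
    age = covariates["age"].to_numpy(dtype=float)
    sex = covariates["sex"].map(SEX_CODES).to_numpy(dtype=float)
    cols = [age, sex]
    names = ["age", "sex"]
    if education_levels:
        edu = covariates["education"]
        for level in education_levels:
            cols.append((edu == level).to_numpy(dtype=float))
            names.append(f"education[{level}]")
    return np.column_stack(cols), names


def _tabulable_education_levels(education: pd.Series, y: np.ndarray) -> list[str]:
    """Education dummies that leave the logistic fit identifiable.

    A category with no outcome events (or no non-events) drives its
    coefficient to infinity regardless of the predictor of interest, so
    such levels are collapsed into the no-high-school reference group
    (logged).  If the reference group itself ends up event-free, the
    lowest remaining level joins it too.
    """
    keep = []
    for level in EDUCATION_LEVELS[1:]:
        mask = (education == level).to_numpy()
        events = float(np.nansum(y[mask]))
        if events == 0 or events == mask.sum():
            logger.warning("mci: education level %r has no outcome variation; "
                           "collapsed into the reference group", level)
            continue
        keep.append(level)
    ref_mask = ~education.isin(keep).to_numpy()
    if keep and float(np.nansum(y[ref_mask])) == 0:
        moved = keep.pop(0)
        logger.warning("mci: reference education group has no events; level %r "
                       "merged into it", moved)
    return keep


# ---------------------------------------------------------------------------
# Mass-univariate scan
# ---------------------------------------------------------------------------

def scan_associations(V: pd.DataFrame, np_scores: pd.DataFrame,
                      covariates: pd.DataFrame) -> pd.DataFrame:
    """Fit ``test ~ intercept + V_j + age + sex`` for every pair.

    Parameters
    ----------
    V
        Normalized (rank-INT) feature matrix, participants x features.
    np_scores
        Participants x tests, NaN = missing.
    covariates
        Must contain ``age`` and ``sex``; aligned to V's index.

    Returns
    -------
    DataFrame with columns ``feature, test, beta, se, p, n`` — the effect
    is the V_j coefficient.  Features with no variance on a pair's
    complete cases are excluded with a warning, never silently dropped.
    """
    if not V.index.equals(np_scores.index) or not V.index.equals(covariates.index):
        raise ValueError("V, np_scores and covariates must share an index")
    cov_X, _ = _covariate_design(covariates)
    usable = []
    for feat in V.columns:
        v = V[feat].to_numpy(dtype=float)
        finite = v[np.isfinite(v)]
        if len(finite) < 6 or finite.std() == 0:
            # constant raw columns normalize to all-NaN; exclude loudly once
            logger.warning("scan: feature %s constant or near-empty after "
                           "normalization; excluded from the scan", feat)
            continue
        usable.append(feat)
    rows = []
    for test in np_scores.columns:
        y = np_scores[test].to_numpy(dtype=float)
        for feat in usable:
            v = V[feat].to_numpy(dtype=float)
            mask = (np.isfinite(y) & np.isfinite(v)
                    & np.all(np.isfinite(cov_X), axis=1))
            if mask.sum() < 6:
                logger.warning("scan: %s vs %s skipped (n=%d too small)",
                               feat, test, int(mask.sum()))
                continue
            if v[mask].std() == 0:
                logger.warning("scan: feature %s constant on complete cases "
                               "for %s; excluded", feat, test)
                continue
            X = np.column_stack([np.ones(mask.sum()), v[mask], cov_X[mask]])
            fit = fit_linear(y[mask], X, names=["intercept", "feature", "age", "sex"])
            beta, se, p = fit.coef("feature")
            rows.append({"feature": feat, "test": test, "beta": beta,
                         "se": se, "p": p, "n": fit.n_used})
    return pd.DataFrame(rows, columns=["feature", "test", "beta", "se", "p", "n"])


def select_significant(results: pd.DataFrame, alpha: float = 0.05,
                       n_tests: int | None = None) -> dict[str, list[str]]:
    """Per-test feature subsets at the Bonferroni threshold.

    ``n_tests`` defaults to the number of distinct features scanned (the
    family is the feature scan for one neuropsychological test, not
    features x tests).
    """
    if n_tests is None:
        n_tests = results["feature"].nunique()
    thr = bonferroni_threshold(alpha, int(n_tests))
    out: dict[str, list[str]] = {}
    for test, grp in results.groupby("test", sort=False):
        out[test] = list(grp.loc[grp["p"] < thr, "feature"])
    return out


# ---------------------------------------------------------------------------
# Composite scores
# ---------------------------------------------------------------------------

@dataclass
class CompositeScoreSet:
    """Per-test weighted composite of significant normalized features."""

    test_name: str
    m: int
    weights: dict[str, float]  # feature -> beta_j from the scan
    scores: pd.Series          # per-participant composite, NaN = missing


def composite_score(selected: dict[str, list[str]], results: pd.DataFrame,
                    V: pd.DataFrame, scaling: str = "mean",
                    missing: str = "strict") -> dict[str, CompositeScoreSet]:
    """Build ``score_i = (1/m) sum_j beta_j V_ij`` per test.

    Parameters
    ----------
    scaling
        ``"mean"`` (default, divide by m) or ``"sum"``.
    missing
        ``"strict"`` (default): a participant with any contributing V_ij
        missing gets a missing score.  ``"renormalize"``: average over the
        available features' weights instead.

    Tests with no significant features produce no composite (logged).
    """
    if scaling not in ("mean", "sum"):
        raise ValueError("scaling must be 'mean' or 'sum'")
    if missing not in ("strict", "renormalize"):
        raise ValueError("missing must be 'strict' or 'renormalize'")
    beta_lookup = results.set_index(["test", "feature"])["beta"]
    out = {}
    for test, feats in selected.items():
        if not feats:
            logger.info("composite: no significant features for %r; skipped", test)
            continue
        m = len(feats)
        weights = {f: float(beta_lookup.loc[(test, f)]) for f in feats}
        W = np.array([weights[f] for f in feats])
        Vsub = V[feats].to_numpy(dtype=float)
        contrib = Vsub * W
        if missing == "strict":
            scores = contrib.sum(axis=1)
            scores[~np.all(np.isfinite(Vsub), axis=1)] = np.nan
            if scaling == "mean":
                scores = scores / m
        else:
            avail = np.isfinite(Vsub)
            total = np.where(avail, contrib, 0.0).sum(axis=1)
            denom = avail.sum(axis=1) if scaling == "mean" else 1.0
            with np.errstate(invalid="ignore", divide="ignore"):
                scores = np.where(avail.any(axis=1), total / denom, np.nan)
        out[test] = CompositeScoreSet(
            test_name=test, m=m, weights=weights,
            scores=pd.Series(scores, index=V.index, name=test))
    return out


def associate_composite(composites: dict[str, CompositeScoreSet],
                        np_scores: pd.DataFrame, covariates: pd.DataFrame,
                        alpha: float = 0.05,
                        n_report_tests: int | None = None) -> pd.DataFrame:
    """Composite vs its neuropsychological test, age+sex adjusted.

    Returns one row per composite: ``test, m, n, beta, se, p,
    p_bonferroni, significant`` — the Bonferroni column multiplies by the
    number of battery tests (capped at 1).
    """
    if n_report_tests is None:
        n_report_tests = len(np_scores.columns)
    thr = bonferroni_threshold(alpha, int(n_report_tests))
    cov_X, _ = _covariate_design(covariates)
    rows = []
    for test, comp in composites.items():
        y = np_scores[test].to_numpy(dtype=float)
        s = comp.scores.to_numpy(dtype=float)
        mask = np.isfinite(y) & np.isfinite(s) & np.all(np.isfinite(cov_X), axis=1)
        X = np.column_stack([np.ones(mask.sum()), s[mask], cov_X[mask]])
        fit = fit_linear(y[mask], X, names=["intercept", "composite", "age", "sex"])
        beta, se, p = fit.coef("composite")
        rows.append({"test": test, "m": comp.m, "n": fit.n_used, "beta": beta,
                     "se": se, "p": p, "p_bonferroni": min(1.0, p * n_report_tests),
                     "significant": p < thr})
    return pd.DataFrame(rows, columns=["test", "m", "n", "beta", "se", "p",
                                       "p_bonferroni", "significant"])


# ---------------------------------------------------------------------------
# MCI associations
# ---------------------------------------------------------------------------

def associate_mci(predictors: pd.DataFrame, covariates: pd.DataFrame,
                  mci: pd.Series, alpha: float = 0.05,
                  n_report_tests: int = 18,
                  min_events: int = DEFAULT_MIN_EVENTS) -> pd.DataFrame:
    """Logistic MCI models, one per predictor column.

    ``logit(MCI) ~ intercept + predictor + age + sex + education`` with
    education dummy-coded against no-high-school.  Fits that separate or
    fail to converge are flagged and not tabulated as converged rows.

    Raises
    ------
    ValueError
        If fewer than ``min_events`` MCI cases are available — Wald
        inference is unstable at very low event counts; lower
        ``min_events`` explicitly or enlarge the sample to proceed.
    """
    y_all = mci.to_numpy(dtype=float)
    n_events = int(np.nansum(y_all))
    if n_events < min_events:
        raise ValueError(
            f"only {n_events} MCI cases < min_events={min_events}; logistic "
            f"Wald inference is unreliable — enlarge the cohort or lower "
            f"min_events explicitly")
    thr = bonferroni_threshold(alpha, n_report_tests)
    edu_levels = _tabulable_education_levels(covariates["education"], y_all)
    cov_X, cov_names = _covariate_design(covariates, education_levels=edu_levels)
    rows = []
    for name in predictors.columns:
        x = predictors[name].to_numpy(dtype=float)
        mask = (np.isfinite(y_all) & np.isfinite(x)
                & np.all(np.isfinite(cov_X), axis=1))
        X = np.column_stack([np.ones(mask.sum()), x[mask], cov_X[mask]])
        try:
            fit = fit_logistic(y_all[mask], X,
                               names=["intercept", "predictor"] + cov_names)
        except stats_core.StatsError as exc:
            logger.warning("mci: %s not fit: %s", name, exc)
            continue
        if not fit.converged:
            logger.warning("mci: %s %s; row flagged, not tabulated",
                           name, "separated" if fit.separated else "did not converge")
            rows.append({"predictor": name, "coef": np.nan, "se": np.nan,
                         "p": np.nan, "n": fit.n_used, "converged": False,
                         "significant": False})
            continue
        coef, se, p = fit.coef("predictor")
        rows.append({"predictor": name, "coef": coef, "se": se, "p": p,
                     "n": fit.n_used, "converged": True, "significant": p < thr})
    return pd.DataFrame(rows, columns=["predictor", "coef", "se", "p", "n",
                                       "converged", "significant"])


# ---------------------------------------------------------------------------
# Descriptive group comparison
# ---------------------------------------------------------------------------

def percent(count: float, total: float) -> float:
    """Percentage, e.g. 1065 of 2062 -> 51.6 (one decimal)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, 1)


def group_compare(cohort: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table by MCI status.

    Continuous variables (age, test scores): mean (SD) per group with a
    tie-corrected Wilcoxon rank-sum (Mann-Whitney, normal approximation)
    p-value.  Categorical variables (sex, education): n (%) with a
    Pearson chi-square p-value without continuity correction.
    """
    g1 = cohort[cohort["mci"] == 1]
    g0 = cohort[cohort["mci"] == 0]
    if len(g1) == 0 or len(g0) == 0:
        raise ValueError("both MCI groups must be non-empty")

    rows = []

    def add_continuous(name, col):
        a = g1[col].dropna().to_numpy(dtype=float)
        b = g0[col].dropna().to_numpy(dtype=float)
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0
        else:
            p = float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                       method="asymptotic").pvalue)
        rows.append({"variable": name, "kind": "continuous",
                     "mci": f"{a.mean():.1f} ({a.std(ddof=1):.1f})",
                     "normal": f"{b.mean():.1f} ({b.std(ddof=1):.1f})",
                     "p": p})

    def add_categorical(name, col):
        tab = pd.crosstab(cohort[col], cohort["mci"])
        chi2, p, _, _ = sps.chi2_contingency(tab.to_numpy(), correction=False)
        for level in tab.index:
            rows.append({"variable": f"{name}={level}", "kind": "categorical",
                         "mci": f"{tab.loc[level, 1]} "
                                f"({percent(tab.loc[level, 1], len(g1))})",
                         "normal": f"{tab.loc[level, 0]} "
                                   f"({percent(tab.loc[level, 0], len(g0))})",
                         "p": float(p)})

    add_continuous("age", "age")
    add_categorical("sex", "sex")
    add_categorical("education", "education")
    for test in NP_TEST_NAMES:
        if test in cohort.columns:
            add_continuous(test, test)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Split-sample variant
# ---------------------------------------------------------------------------

def split_sample_composite(V: pd.DataFrame, np_scores: pd.DataFrame,
                           covariates: pd.DataFrame, rng: np.random.Generator,
                           alpha: float = 0.05, n_tests: int | None = None,
                           scaling: str = "mean") -> pd.DataFrame:
    """Select features on a random half, test composites on the other half.

    Same-sample selection+association (the default elsewhere) reuses the
    data twice and is anti-conservative under the null; this variant's
    null p-values are uniform.  Weights come from the selection half's
    scan; the association is run only on held-out participants.
    """
    n = len(V)
    perm = rng.permutation(n)
    half_a = V.index[perm[: n // 2]]
    half_b = V.index[perm[n // 2:]]
    res_a = scan_associations(V.loc[half_a], np_scores.loc[half_a],
                              covariates.loc[half_a])
    if res_a.empty:
        return pd.DataFrame(columns=["test", "m", "n", "beta", "se", "p",
                                     "p_bonferroni", "significant"])
    sel = select_significant(res_a, alpha=alpha, n_tests=n_tests)
    comps = composite_score(sel, res_a, V.loc[half_b], scaling=scaling)
    return associate_composite(comps, np_scores.loc[half_b],
                               covariates.loc[half_b], alpha=alpha)
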
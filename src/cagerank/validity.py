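"""Convergent/discriminant validity statistics.

Stages: per-measure standardization, residualization against strain and
group size (mixed model with a random cage intercept, fixed-cage fallback),
correlation-matrix PCA with the eigenvalue-over-1 retention rule, maximum
likelihood factor analysis with varimax rotation and regression factor
scores, factor-score regressions on Glicko net changes, the tube-test-PC
discriminant mixed model against open-field measures, Pearson correlations
with Fisher-z confidence intervals, and the 5-second submission-response
scan with its Bonferroni-contrasted logistic model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.multivariate.factor import Factor
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .ethogram import Behavior, BehaviorEvent

__all__ = [
    "MEASURE_COLUMNS",
    "FactorSolution",
    "ResponseOutcome",
    "standardize",
    "residualize",
    "subjects_per_variable",
    "pca",
    "ml_factor_analysis",
    "convergent_regression",
    "discriminant_model",
    "pearson_ci",
    "submission_response_scan",
    "response_logistic",
    "select_extremes",
]

#: Measures entering the convergent-validity factor analysis.
MEASURE_COLUMNS = [
    "darcin",
    "preputial_ratio",
    "posterior_pals",
    "tube_r1",
    "tube_r2",
    "tube_r3",
]


def standardize(values: pd.Series | np.ndarray) -> pd.Series:
    """Z-score a measure (mean 0, sd 1); missing values are preserved."""
    s = pd.Series(values).astype(float)
    valid = s.dropna()
    if len(valid) < 2:
        raise ValueError("standardize needs >= 2 non-missing values")
    sd = valid.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        name = s.name or "measure"
        raise ValueError(f"zero variance in {name}: cannot standardize")
    return (s - valid.mean()) / sd


def select_extremes(
    table: pd.DataFrame, score_col: str = "glicko_sub_net", cage_col: str = "cage_id"
) -> pd.DataFrame:
    """One dominant (per-cage max of ``score_col``) and one subordinate
    (per-cage min) row per cage."""
    rows = []
    for _, sub in table.groupby(cage_col, sort=True):
        sub = sub.reset_index(drop=True)
        dom = sub.loc[sub[score_col].idxmax()].copy()
        dom["role"] = "dominant"
        subo = sub.loc[sub[score_col].idxmin()].copy()
        subo["role"] = "subordinate"
        rows.extend([dom, subo])
    return pd.DataFrame(rows).reset_index(drop=True)


def residualize(
    table: pd.DataFrame,
    measures: Sequence[str],
    strain_col: str = "strain",
    size_col: str = "group_size",
    cage_col: str = "cage_id",
    mode: str = "mixed",
) -> pd.DataFrame:
    """Remove strain and group-size effects from each standardized measure.

    ``mode='mixed'`` fits strain * group_size fixed effects with a random
    cage intercept and returns conditional (within-cage) residuals; on a
    singular or non-converging fit it falls back to ``mode='fixed'`` (cage
    as a fixed factor, which absorbs the between-cage design) with a warning.
    Missing values are preserved row-wise.
    """
    out = table.copy()
    for m in measures:
        df = table[[m, strain_col, size_col, cage_col]].dropna().copy()
        if df.empty:
            raise ValueError(f"no data for measure {m}")
        df["_z"] = standardize(df[m]).values
        resid = None
        if mode == "mixed":
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    warnings.simplefilter("ignore", RuntimeWarning)
                    fit = smf.mixedlm(
                        f"_z ~ C({strain_col}) * {size_col}",
                        df,
                        groups=df[cage_col],
                    ).fit(reml=True)
                # fittedvalues include the BLUP random intercept, so resid is
                # the conditional (within-cage) residual.
                resid = fit.resid
                if not np.all(np.isfinite(resid)):
                    resid = None
            except (np.linalg.LinAlgError, ValueError):
                resid = None
            if resid is None:
                warnings.warn(
                    f"mixed-model residualization failed for {m}; "
                    "falling back to fixed-cage model"
                )
        if resid is None:
            fit = smf.ols(f"_z ~ C({cage_col})", df).fit()
            resid = fit.resid
        out[m] = np.nan
        out.loc[df.index, m] = np.asarray(resid, dtype=float)
    return out


def subjects_per_variable(table: pd.DataFrame, measures: Sequence[str]) -> float:
    """Complete-case subjects per variable, the factor-analysis preflight
    gate (>= 5 is the conventional minimum)."""
    n = int(table[list(measures)].dropna().shape[0])
    return n / len(measures)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    loadings: pd.DataFrame  # variables x components, correlation-scaled
    scores: pd.DataFrame  # rows x retained components
    n_retained: int
    pct_variance: np.ndarray


def pca(table: pd.DataFrame, eigenvalue_cutoff: float = 1.0) -> PCAResult:
    """PCA of the correlation matrix, retaining eigenvalues above cutoff.

    Components are oriented so each one's largest-magnitude loading is
    positive.  Scores are standardized component scores of the input rows.
    """
    df = table.dropna()
    if df.shape[1] < 2:
        raise ValueError("pca needs >= 2 variables")
    if df.shape[0] < 3:
        raise ValueError("pca needs >= 3 complete rows")
    sds = df.std(ddof=1)
    if (sds == 0).any():
        raise ValueError(f"constant column(s): {list(sds.index[sds == 0])}")
    if df.shape[0] < df.shape[1]:
        warnings.warn("fewer rows than variables: PCA is rank-deficient")
    Z = (df - df.mean()) / sds
    R = np.corrcoef(Z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    # orientation convention: dominant loading positive
    for k in range(eigvec.shape[1]):
        col = eigvec[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            eigvec[:, k] = -col
    n_keep = max(int((eigval > eigenvalue_cutoff).sum()), 1)
    loadings = eigvec * np.sqrt(np.clip(eigval, 0, None))
    scores = Z.to_numpy() @ eigvec[:, :n_keep]
    # standardize scores to unit variance per component
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = scores / np.sqrt(np.clip(eigval[:n_keep], 1e-12, None))
    comp_names = [f"PC{k + 1}" for k in range(len(eigval))]
    return PCAResult(
        eigenvalues=eigval,
        loadings=pd.DataFrame(loadings, index=df.columns, columns=comp_names),
        scores=pd.DataFrame(
            scores, index=df.index, columns=comp_names[:n_keep]
        ),
        n_retained=n_keep,
        pct_variance=100.0 * eigval / eigval.sum(),
    )


# ---------------------------------------------------------------------------
# ML factor analysis


@dataclass
class FactorSolution:
    loadings: pd.DataFrame  # variables x factors, varimax-rotated
    eigenvalues: np.ndarray  # sum of squared loadings per factor
    pct_variance: np.ndarray
    scores: pd.DataFrame
    n_factors: int
    loading_threshold: float
    subjects_per_variable: float
    membership: dict[str, list[str]] = field(default_factory=dict)

    def strong(self, factor: str) -> list[str]:
        return self.membership[factor]


def ml_factor_analysis(
    table: pd.DataFrame,
    n_factors: int | None = None,
    loading_threshold: float = 0.45,
    eigenvalue_cutoff: float = 1.0,
) -> FactorSolution:
    """Maximum-likelihood factor analysis with varimax rotation.

    The factor count defaults to the eigenvalue-over-1 rule on the
    correlation matrix.  Rows with any missing measure are dropped
    (listwise).  Factors are oriented so the largest-magnitude loading is
    positive; strong membership is |loading| >= ``loading_threshold``.
    Scores use the regression (Thomson) estimator.  A Heywood-adjacent fit
    (uniqueness near 0) warns but is returned.
    """
    df = table.dropna()
    p = df.shape[1]
    spv = df.shape[0] / p
    if spv < 5:
        warnings.warn(
            f"subjects-per-variable ratio {spv:.2f} below the conventional 5"
        )
    Z = (df - df.mean()) / df.std(ddof=1)
    R = np.corrcoef(Z.to_numpy(), rowvar=False)
    eigval = np.sort(np.linalg.eigvalsh(R))[::-1]
    if n_factors is None:
        n_factors = max(int((eigval > eigenvalue_cutoff).sum()), 1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fa = Factor(Z.to_numpy(), n_factor=n_factors, method="ml")
        res = fa.fit()
        if n_factors > 1:
            res.rotate("varimax")
    loadings = np.asarray(res.loadings)[:, :n_factors].copy()

    uniq = np.asarray(res.uniqueness)
    if np.any(uniq < 1e-4):
        warnings.warn(
            "Heywood case: communality at the boundary for "
            f"{list(df.columns[uniq < 1e-4])}"
        )

    # order factors by explained variance, orient dominant loading positive
    ssl = (loadings**2).sum(axis=0)
    order = np.argsort(ssl)[::-1]
    loadings = loadings[:, order]
    ssl = ssl[order]
    for k in range(n_factors):
        col = loadings[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, k] = -col

    factor_names = [f"factor{k + 1}" for k in range(n_factors)]
    L = pd.DataFrame(loadings, index=df.columns, columns=factor_names)

    # regression (Thomson) factor scores: Z R^{-1} Lambda
    score_mat = Z.to_numpy() @ np.linalg.solve(R, loadings)
    scores = pd.DataFrame(score_mat, index=df.index, columns=factor_names)

    membership = {
        f: list(L.index[np.abs(L[f]) >= loading_threshold]) for f in factor_names
    }
    return FactorSolution(
        loadings=L,
        eigenvalues=ssl,
        pct_variance=100.0 * ssl / p,
        scores=scores,
        n_factors=n_factors,
        loading_threshold=loading_threshold,
        subjects_per_variable=spv,
        membership=membership,
    )


# ---------------------------------------------------------------------------
# Regressions


def convergent_regression(
    glicko_net: pd.Series, factor_scores: pd.DataFrame
) -> pd.DataFrame:
    """OLS of a Glicko net change on the factor scores.

    Returns a per-term table with coefficient, F (= t^2 for 1-df terms),
    p-value, and partial eta squared.
    """
    df = pd.concat([glicko_net.rename("_y"), factor_scores], axis=1).dropna()
    X = sm.add_constant(df[factor_scores.columns])
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design in convergent regression")
    fit = sm.OLS(df["_y"], X).fit()
    rows = []
    for term in factor_scores.columns:
        t = fit.tvalues[term]
        F = t * t
        rows.append(
            {
                "term": term,
                "coef": fit.params[term],
                "F": F,
                "df_num": 1,
                "df_den": int(fit.df_resid),
                "p": fit.pvalues[term],
                "partial_eta_sq": F / (F + fit.df_resid),
            }
        )
    out = pd.DataFrame(rows).set_index("term")
    out.attrs["r_squared"] = fit.rsquared
    return out


def discriminant_model(
    table: pd.DataFrame,
    response: str = "tube_pc",
    ofm_terms: Sequence[str] = ("ofm_boli", "ofm_center_pct", "ofm_distance_cm"),
    strain_col: str = "strain",
    size_col: str = "group_size",
    cage_col: str = "cage_id",
) -> pd.DataFrame:
    """Mixed model of the tube-test PC on open-field measures + design.

    Fixed effects: the three OFM terms, strain, group size; random cage
    intercept.  Discriminant validity holds when all OFM terms are
    non-significant.  On a singular random-effects fit, falls back to a
    fixed-cage OLS (which still identifies the within-cage OFM terms).
    """
    cols = [response, *ofm_terms, strain_col, size_col, cage_col]
    df = table[cols].dropna().copy()
    fixed = " + ".join([*ofm_terms, f"C({strain_col})", size_col])
    fit = None
    model_kind = "mixed"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(
                f"{response} ~ {fixed}", df, groups=df[cage_col]
            ).fit(reml=True)
        if not np.all(np.isfinite(fit.bse.iloc[:-1])):
            fit = None
    except (np.linalg.LinAlgError, ValueError):
        fit = None
    if fit is None:
        warnings.warn(
            "singular random-effects fit; falling back to fixed-cage model"
        )
        model_kind = "fixed_cage"
        fit = smf.ols(f"{response} ~ {' + '.join(ofm_terms)} + C({cage_col})", df).fit()

    rows = []
    for term in ofm_terms:
        t = fit.tvalues[term]
        p = fit.pvalues[term]
        rows.append({"term": term, "coef": fit.params[term], "F": t * t, "p": p})
    out = pd.DataFrame(rows).set_index("term")
    out.attrs["model"] = model_kind
    return out


def pearson_ci(
    x: Sequence[float], y: Sequence[float], level: float = 0.95
) -> dict[str, float | tuple[float, float]]:
    """Pearson r with two-sided t-test p-value and Fisher-z CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError("pearson_ci needs n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n - 3)
    zcrit = stats.norm.ppf(0.5 + level / 2)
    lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    return {"r": float(r), "p": float(p), "ci": (float(lo), float(hi)), "n": n}


# ---------------------------------------------------------------------------
# Submission-response sequence analysis


@dataclass(frozen=True)
class ResponseOutcome:
    day: int
    t: float
    actor: str  # investigating mouse
    recipient: str  # investigated mouse, the potential submitter
    responded: int  # 1 if it submitted back within the window
    window_s: float = 5.0
    strain: str = ""
    cage_id: str = ""


def submission_response_scan(
    events: Sequence[BehaviorEvent],
    window_s: float = 5.0,
    strain: str = "",
    cage_id: str = "",
) -> list[ResponseOutcome]:
    """Score every social-investigation event 1/0 for a submission response.

    An investigation at t gets a 1 iff the investigated mouse performs a
    submission directed at the investigator with t < t_sub <= t + window on
    the same day.  Output length equals the number of investigation events.
    """
    subs_by_day: dict[int, list[BehaviorEvent]] = {}
    for e in events:
        if e.category is Behavior.SUBMISSION:
            subs_by_day.setdefault(e.day, []).append(e)
    for day_events in subs_by_day.values():
        day_events.sort(key=lambda e: e.t)

    outcomes = []
    for e in events:
        if e.category is not Behavior.INVESTIGATION:
            continue
        responded = 0
        for s in subs_by_day.get(e.day, ()):
            if s.t > e.t + window_s:
                break
            if s.t > e.t and s.actor == e.recipient and s.recipient == e.actor:
                responded = 1
                break
        outcomes.append(
            ResponseOutcome(
                day=e.day,
                t=e.t,
                actor=e.actor,
                recipient=e.recipient,
                responded=responded,
                window_s=window_s,
                strain=strain,
                cage_id=cage_id,
            )
        )
    return outcomes


def response_logistic(
    outcomes: Iterable[ResponseOutcome] | pd.DataFrame,
    alpha: float = 0.05,
    family_size: int = 6,
) -> dict:
    """Binomial-logit model of the submission response with Bonferroni
    contrasts among the four strain-by-day cells.

    Returns the strain, day, and interaction Wald tests, all six pairwise
    cell contrasts on the logit scale (each compared to alpha / family),
    and the corrected per-comparison threshold.  Complete separation in a
    cell (all 0 or all 1) warns and is handled by adding half a success and
    half a failure to every cell (Agresti-style shrinkage) before fitting.
    """
    if isinstance(outcomes, pd.DataFrame):
        df = outcomes.copy()
    else:
        df = pd.DataFrame(
            [
                {"strain": o.strain, "day": o.day, "responded": o.responded}
                for o in outcomes
            ]
        )
    if df.empty:
        raise ValueError("no outcomes to model")
    if df["strain"].nunique() < 2 or df["day"].nunique() < 2:
        raise ValueError("need >= 2 strains and >= 2 days represented")

    agg = (
        df.groupby(["strain", "day"])["responded"]
        .agg(successes="sum", n="count")
        .reset_index()
    )
    agg["failures"] = agg["n"] - agg["successes"]
    separated = (agg["successes"] == 0) | (agg["failures"] == 0)
    if separated.any():
        warnings.warn(
            "complete separation in strain x day cell(s); "
            "applying +0.5 success/failure shrinkage to every cell"
        )
        agg["successes"] = agg["successes"] + 0.5
        agg["failures"] = agg["failures"] + 0.5

    cells = list(agg.itertuples(index=False))
    k = len(cells)
    endog = agg[["successes", "failures"]].to_numpy()

    # cell-means parameterization for the contrasts; the model is saturated
    # (df_resid == 0 with 4 cells), which statsmodels flags noisily but is
    # exactly what pairwise cell contrasts need
    X_cells = np.eye(k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_cells = sm.GLM(endog, X_cells, family=sm.families.Binomial()).fit()

    # factorial parameterization for the strain/day/interaction Wald tests
    strain_levels = sorted(agg["strain"].unique())
    day_levels = sorted(agg["day"].unique())
    s_ind = (agg["strain"] == strain_levels[-1]).astype(float).to_numpy()
    d_ind = (agg["day"] == day_levels[-1]).astype(float).to_numpy()
    X_fact = np.column_stack([np.ones(k), s_ind, d_ind, s_ind * d_ind])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_fact = sm.GLM(endog, X_fact, family=sm.families.Binomial()).fit()
    term_names = ["intercept", "strain", "day", "strain:day"]
    terms = pd.DataFrame(
        {
            "coef": fit_fact.params,
            "wald_chi2": (fit_fact.params / fit_fact.bse) ** 2,
            "p": fit_fact.pvalues,
        },
        index=term_names,
    )

    threshold = alpha / family_size
    cov = fit_cells.cov_params()
    rows = []
    for i, j in combinations(range(k), 2):
        est = fit_cells.params[i] - fit_cells.params[j]
        se = np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j])
        z = est / se
        p = 2 * stats.norm.sf(abs(z))
        ci, cj = cells[i], cells[j]
        rows.append(
            {
                "cell_a": f"{ci.strain}:day{ci.day}",
                "cell_b": f"{cj.strain}:day{cj.day}",
                "logit_diff": est,
                "se": se,
                "z": z,
                "p": p,
                "significant": p < threshold,
            }
        )
    contrasts = pd.DataFrame(rows)
    cell_probs = {
        f"{c.strain}:day{c.day}": c.successes / (c.successes + c.failures)
        for c in cells
    }
    return {
        "terms": terms,
        "contrasts": contrasts,
        "threshold": round(threshold, 4),
        "alpha": alpha,
        "family_size": family_size,
        "cell_probs": cell_probs,
        "n": int(df.shape[0]),
    }
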
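"""Psychometric validation and model-comparison analyses.

Covers internal-consistency reliability (standardized Cronbach's alpha),
the construct/predictive validity regression battery, the complete-case
versus achievable-N comparison regressions with adjusted R-squared, and the
Monte-Carlo experiment quantifying how often two equally predictive indices
show a sample R-squared difference of a given size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .measurement import is_missing, zscore

logger = logging.getLogger("childses.validity")

#: default correlation between two competing indices measured on the same
#: respondents in the difference-in-R-squared simulation
DEFAULT_RHO_BETWEEN = 0.7
RHO_SWEEP = (0.0, 0.5, 0.7, 0.8, 0.9)


class ValidityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------

@dataclass
class ReliabilityResult:
    scale: str
    k: int
    r_bar: float
    alpha: float
    n: int


def cronbach_alpha_standardized(items: pd.DataFrame,
                                scale: str = "scale") -> ReliabilityResult:
    """Standardized Cronbach's alpha, k r̄ / (1 + (k-1) r̄), among complete
    responders on the item set."""
    X = items.to_numpy(dtype=float).copy()
    X[is_missing(X)] = np.nan
    complete = ~np.isnan(X).any(axis=1)
    X = X[complete]
    k = X.shape[1]
    if k < 2:
        raise ValidityError("need >= 2 items")
    if X.shape[0] < 2:
        raise ValidityError(f"scale {scale!r}: fewer than 2 complete responders")
    sds = X.std(axis=0, ddof=0)
    if (sds == 0).any():
        bad = items.columns[np.where(sds == 0)[0]].tolist()
        raise ValidityError(f"scale {scale!r}: zero-variance item(s) {bad}")
    R = np.corrcoef(X, rowvar=False)
    r_bar = float(R[np.triu_indices(k, k=1)].mean())
    alpha = k * r_bar / (1.0 + (k - 1) * r_bar)
    return ReliabilityResult(scale=scale, k=k, r_bar=r_bar, alpha=float(alpha),
                             n=int(X.shape[0]))


# ---------------------------------------------------------------------------
# regression machinery
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    outcome: str
    label: str                       # Model 1 | Model 2 | Model 3 | index family
    terms: pd.DataFrame              # term, beta, ci_low, ci_high, p
    r2: float
    adj_r2: float
    n: int
    dropped_terms: list = field(default_factory=list)

    def __post_init__(self):
        if self.n <= len(self.terms):
            raise ValidityError(
                f"{self.outcome}/{self.label}: n={self.n} does not exceed the "
                "parameter count")


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """1 - (1 - R^2)(n - 1)/(n - p - 1); p counts predictors excluding the
    intercept."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float).copy()
    arr[is_missing(arr)] = np.nan
    return arr


def validity_regression(outcome, predictor, outcome_name: str = "outcome",
                        predictor_name: str = "predictor") -> RegressionResult:
    """OLS of a hypothesized correlate on one (z-scored) capital measure."""
    y = _clean(outcome)
    x = _clean(predictor)
    keep = ~np.isnan(y) & ~np.isnan(x)
    if keep.sum() < 3:
        raise ValidityError(
            f"({outcome_name}, {predictor_name}): empty overlap of non-missing values")
    X = sm.add_constant(zscore(x[keep]))
    fit = sm.OLS(y[keep], X).fit()
    ci = fit.conf_int()
    terms = pd.DataFrame({
        "term": [predictor_name],
        "beta": [fit.params[1]], "ci_low": [ci[1, 0]], "ci_high": [ci[1, 1]],
        "p": [fit.pvalues[1]],
    })
    return RegressionResult(outcome=outcome_name, label=predictor_name,
                            terms=terms, r2=float(fit.rsquared),
                            adj_r2=float(fit.rsquared_adj), n=int(keep.sum()))


#: the validation grid: construct-validity correlates first, then predictive
VALIDITY_OUTCOMES = ("drugalcohol_problems", "learning_problems", "child_srh",
                     "own_edu", "height")


def run_validity_battery(table: pd.DataFrame,
                         measures=("csc", "cfc", "chc")) -> pd.DataFrame:
    """Regression of every hypothesized correlate on every capital measure."""
    rows = []
    for outcome in VALIDITY_OUTCOMES:
        for measure in measures:
            res = validity_regression(table[outcome], table[measure],
                                      outcome_name=outcome, predictor_name=measure)
            rows.append({"outcome": outcome, "measure": measure,
                         "n": res.n, "beta": res.terms["beta"].iloc[0],
                         "p": res.terms["p"].iloc[0]})
    return pd.DataFrame(rows)


def _covariate_design(table: pd.DataFrame, rows: np.ndarray) -> pd.DataFrame:
    """Age (linear and quadratic), gender, race and birthplace indicators."""
    sub = table.loc[rows]
    age = sub["age"].to_numpy(dtype=float)
    D = pd.DataFrame(index=sub.index)
    D["age"] = age
    D["age_sq"] = age ** 2
    D["female"] = sub["gender"].to_numpy(dtype=float)
    for level in (2.0, 3.0, 4.0):
        D[f"race_{int(level)}"] = (sub["race"] == level).astype(float)
    for level in range(2, 9):
        D[f"birthplace_{level}"] = (sub["birthplace"] == float(level)).astype(float)
    return D


def comparison_regression(table: pd.DataFrame, outcome: str, block: list,
                          label: str, restrict_rows=None,
                          z_score_continuous: bool = True) -> RegressionResult:
    """OLS of one outcome on a predictor block plus the full covariate set.

    ``restrict_rows`` (boolean mask) implements the complete-case analysis:
    the fit uses only rows valued by every competing specification.  Without
    it the fit runs on the block's achievable sample.  Continuous predictors
    are z-scored over the analysis rows; binary block members (the five
    complete-case indicators) are left on their natural scale.  Collinear
    block terms are dropped with a diagnostic.
    """
    y = _clean(table[outcome].to_numpy())
    block_data = {c: _clean(table[c].to_numpy()) for c in block}
    keep = ~np.isnan(y)
    for c in block:
        keep &= ~np.isnan(block_data[c])
    if restrict_rows is not None:
        keep &= np.asarray(restrict_rows, dtype=bool)
    n = int(keep.sum())
    if n < len(block) + 15:
        raise ValidityError(f"{outcome}/{label}: only {n} usable rows")
    X = pd.DataFrame(index=np.where(keep)[0])
    dropped = []
    for c in block:
        col = block_data[c][keep]
        uniq = np.unique(col)
        if len(uniq) < 2:
            dropped.append(c)
            logger.warning("%s/%s: dropping constant block term %r", outcome, label, c)
            continue
        if z_score_continuous and not set(uniq).issubset({0.0, 1.0}):
            col = zscore(col)
        X[c] = col
    cov = _covariate_design(table, keep)
    for c in cov.columns:
        X[c] = cov[c].to_numpy()
    # drop exactly collinear columns
    Xv = X.to_numpy()
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), Xv]))
    while rank < X.shape[1] + 1 and X.shape[1] > 0:
        for c in list(X.columns):
            trial = X.drop(columns=c)
            if np.linalg.matrix_rank(
                    np.column_stack([np.ones(n), trial.to_numpy()])) == rank:
                dropped.append(c)
                logger.warning("%s/%s: dropping collinear term %r", outcome, label, c)
                X = trial
                break
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), X.to_numpy()]))
    design = sm.add_constant(X.to_numpy())
    fit = sm.OLS(y[keep], design).fit()
    ci = fit.conf_int()
    block_cols = [c for c in block if c in X.columns]
    idx = [list(X.columns).index(c) + 1 for c in block_cols]
    terms = pd.DataFrame({
        "term": block_cols,
        "beta": [fit.params[i] for i in idx],
        "ci_low": [ci[i, 0] for i in idx],
        "ci_high": [ci[i, 1] for i in idx],
        "p": [fit.pvalues[i] for i in idx],
    })
    p_predictors = X.shape[1]
    return RegressionResult(outcome=outcome, label=label, terms=terms,
                            r2=float(fit.rsquared),
                            adj_r2=float(adjusted_r2(fit.rsquared, n, p_predictors)),
                            n=n, dropped_terms=dropped)


#: the competing predictor blocks of the comparison analysis
def comparison_blocks(table: pd.DataFrame | None = None) -> dict:
    """Model 1: the composite index; Model 2: the three capital measures;
    Model 3: the six components (the fitted factor scores plus both imputed
    educations — taken from whatever ``eta_*`` columns the measurement stage
    produced); then the three comparison codings."""
    if table is not None:
        eta_cols = [c for c in table.columns if c.startswith("eta_")]
    else:
        eta_cols = ["eta_maternal_investment", "eta_family_structure",
                    "eta_avg_financial_resources", "eta_financial_instability"]
    return {
        "Model 1": ["cses_index"],
        "Model 2": ["csc", "cfc", "chc"],
        "Model 3": eta_cols + ["mother_edu_imputed", "father_edu_imputed"],
        "Luo": ["luo_index"],
        "Glymour": ["glymour_index"],
        "Hargrove": ["hargrove_mother_edu_ge12", "hargrove_father_edu_ge12",
                     "hargrove_self_rated_poor", "hargrove_moved_financial",
                     "hargrove_father_white_collar"],
    }


COMPARISON_OUTCOMES = ("adult_srh", "cesd_score")


def complete_case_mask(table: pd.DataFrame, blocks: dict | None = None) -> np.ndarray:
    """Rows valued by every competing specification and both outcomes (the
    intersection sample); per-criterion exclusion counts are logged."""
    blocks = blocks or comparison_blocks(table)
    mask = np.ones(len(table), dtype=bool)
    for label, cols in blocks.items():
        ok = np.ones(len(table), dtype=bool)
        for c in cols:
            ok &= ~np.isnan(_clean(table[c].to_numpy()))
        logger.info("complete-case: block %s values %d rows", label, int(ok.sum()))
        mask &= ok
    for outcome in COMPARISON_OUTCOMES:
        ok = ~np.isnan(_clean(table[outcome].to_numpy()))
        logger.info("complete-case: outcome %s observed for %d rows",
                    outcome, int(ok.sum()))
        mask &= ok
    if "hargrove_eligible" in table.columns:
        mask &= table["hargrove_eligible"].to_numpy() == 1.0
    return mask


def run_comparison_tables(table: pd.DataFrame) -> dict:
    """Paired complete-case and achievable-N comparison grids.

    Returns ``{"complete_case": DataFrame, "achievable": DataFrame,
    "complete_case_n": int, "achievable_ns": dict}``, each grid holding one
    row per (specification, outcome, term) with N, beta, CI, p, adjusted R².
    """
    blocks = comparison_blocks(table)
    cc_mask = complete_case_mask(table, blocks)
    grids = {}
    achievable_ns = {}
    for mode in ("complete_case", "achievable"):
        rows = []
        for label, cols in blocks.items():
            for outcome in COMPARISON_OUTCOMES:
                restrict = cc_mask if mode == "complete_case" else (
                    table["hargrove_eligible"].to_numpy() == 1.0
                    if label == "Hargrove" else None)
                res = comparison_regression(table, outcome, cols, label,
                                            restrict_rows=restrict)
                if mode == "achievable":
                    achievable_ns[(label, outcome)] = res.n
                for _, t in res.terms.iterrows():
                    rows.append({"specification": label, "outcome": outcome,
                                 "term": t["term"], "n": res.n,
                                 "beta": t["beta"], "ci_low": t["ci_low"],
                                 "ci_high": t["ci_high"], "p": t["p"],
                                 "adj_r2": res.adj_r2})
        grids[mode] = pd.DataFrame(rows)
    return {"complete_case": grids["complete_case"],
            "achievable": grids["achievable"],
            "complete_case_n": int(cc_mask.sum()),
            "achievable_ns": achievable_ns}


# ---------------------------------------------------------------------------
# difference-in-R-squared simulation
# ---------------------------------------------------------------------------

def delta_r2_significance(n: int, r2_true: float, rho_between: float,
                          reps: int, threshold: float, seed: int,
                          chunk: int = 250) -> float:
    """Monte-Carlo probability that two competing indices, each explaining
    ``r2_true`` of the outcome in the population and correlated
    ``rho_between`` with each other, show a sample R-squared difference of
    at least ``threshold`` at sample size ``n``.

    Per replicate, (index1, index2, outcome) are trivariate normal; both
    single-predictor OLS R-squared values are the squared sample
    correlations.  Deterministic given ``seed``.
    """
    if n < 10 or not 0.0 <= r2_true < 1.0 or abs(rho_between) > 1.0 or reps < 1:
        raise ValidityError("infeasible simulation parameters")
    r = np.sqrt(r2_true)
    C = np.array([[1.0, rho_between, r],
                  [rho_between, 1.0, r],
                  [r, r, 1.0]])
    if np.linalg.eigvalsh(C).min() < -1e-12:
        raise ValidityError(
            f"(rho_between={rho_between}, r2_true={r2_true}) implies a "
            "non-positive-semidefinite correlation matrix")
    L = np.linalg.cholesky(C + 1e-12 * np.eye(3))
    rng = np.random.default_rng(seed)
    exceed = 0
    for start in range(0, reps, chunk):
        m = min(chunk, reps - start)
        Z = rng.standard_normal((m, n, 3)) @ L.T
        X1, X2, Y = Z[..., 0], Z[..., 1], Z[..., 2]

        def corr(a, b):
            a = a - a.mean(axis=1, keepdims=True)
            b = b - b.mean(axis=1, keepdims=True)
            return (a * b).sum(axis=1) / np.sqrt(
                (a * a).sum(axis=1) * (b * b).sum(axis=1))

        delta = np.abs(corr(X1, Y) ** 2 - corr(X2, Y) ** 2)
        exceed += int((delta >= threshold).sum())
    return exceed / reps


def delta_r2_normal_approx(n: int, r2_true: float, rho_between: float,
                           threshold: float) -> float:
    """Delta-method normal approximation to the exceedance probability.

    Uses the large-sample covariance of two sample correlations sharing a
    variable (Pearson-Filon): with rho1 = rho2 = r,
    n cov = rho12 (1 - 2 r^2) ... expanded below, and
    d(R^2) = 2 r d(r), so delta-R2 is approximately normal with sd
    2 r sd(r1 - r2)."""
    r = np.sqrt(r2_true)
    var_r = (1.0 - r2_true) ** 2
    n_cov = (rho_between * (1.0 - 2.0 * r2_true)
             - 0.5 * r2_true * (1.0 - 2.0 * r2_true - rho_between ** 2))
    var_diff = 2.0 * (var_r - n_cov) / n
    if var_diff <= 0:
        return 0.0
    sd_delta = 2.0 * r * np.sqrt(var_diff)
    return float(2.0 * norm.sf(threshold / sd_delta))


def delta_r2_sensitivity(n: int, r2_true: float, reps: int, threshold: float,
                         seed: int, rhos=RHO_SWEEP) -> pd.DataFrame:
    """Exceedance probability across a sweep of between-index correlations,
    emitted alongside the point result because the between-index correlation
    of the published simulation is not stated."""
    rows = []
    for i, rho in enumerate(rhos):
        p = delta_r2_significance(n, r2_true, rho, reps, threshold,
                                  seed=seed + i + 1)
        rows.append({"rho_between": rho, "probability": p,
                     "normal_approx": delta_r2_normal_approx(
                         n, r2_true, rho, threshold)})
    return pd.DataFrame(rows)
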
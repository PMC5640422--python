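"""Single imputation of continuous parental education and the childhood
human capital index.

Parental education arrives in three representations: continuous years
(0-17), dichotomized at 8 years (the older sub-cohort recorded only whether
the parent had at least 8 years), and missing.  Continuous values are taken
at face value and never altered.  Dichotomized and missing values are filled
by conditional-mean single imputation under a multivariate-normal model
estimated by expectation maximization within five subgroups: (a) any missing
education, (b)/(c) mother/father known to be below 8 years, (d)/(e)
mother/father known to be at or above 8 years.  Each subgroup's EM
estimation sample is augmented with the continuously-reported rows that
satisfy the subgroup's defining education constraint, which is what
identifies the education-predictor covariances the conditional means need.
Imputed values are clamped to the subgroup range ([0, 8] for the below-8
groups, [8, 17] for the at-or-above-8 groups) and globally to [0, 17].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .measurement import is_missing, zscore

logger = logging.getLogger("childses.imputation")


class ImputationError(ValueError):
    pass


@dataclass
class EMEstimate:
    mean: np.ndarray
    cov: np.ndarray
    n_iter: int
    loglik_trace: list
    converged: bool
    n_rows_used: int
    n_rows_dropped: int


def em_mean_cov(data, tol: float = 1e-6, max_iter: int = 500,
                ridge: float = 1e-8) -> EMEstimate:
    """ML mean and covariance of a numeric matrix with ignorable missingness.

    Rows with no observed entries are dropped (logged); every column must
    have at least one observed value.  The observed-data log-likelihood is
    non-decreasing across iterations; convergence is declared when
    successive log-likelihoods differ by less than ``tol``.
    """
    X = np.asarray(data, dtype=float).copy()
    if X.ndim != 2:
        raise ImputationError("data must be a 2-D matrix")
    miss = np.isnan(X)
    empty_rows = miss.all(axis=1)
    if empty_rows.any():
        logger.info("em_mean_cov: dropping %d all-missing rows", empty_rows.sum())
        X = X[~empty_rows]
        miss = miss[~empty_rows]
    n, p = X.shape
    if n == 0:
        raise ImputationError("no rows with observed values")
    all_missing_cols = miss.all(axis=0)
    if all_missing_cols.any():
        raise ImputationError(
            f"columns with no observed values: {np.where(all_missing_cols)[0].tolist()}")

    mu = np.nanmean(X, axis=0)
    var = np.nanvar(X, axis=0)
    var[var <= 0] = 1.0
    sigma = np.diag(var)

    # group rows by missingness pattern so each E-step solves one linear
    # system per pattern rather than per row
    pattern_keys = [tuple(row) for row in miss]
    patterns = {}
    for idx, key in enumerate(pattern_keys):
        patterns.setdefault(key, []).append(idx)
    patterns = {k: np.array(v) for k, v in patterns.items()}

    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        loglik = 0.0
        for key, rows in patterns.items():
            m = np.array(key)
            o = ~m
            Xo = X[np.ix_(rows, np.where(o)[0])]
            mu_o = mu[o]
            S_oo = sigma[np.ix_(o, o)] + ridge * np.eye(o.sum())
            # observed-data log-likelihood contribution
            sign, logdet = np.linalg.slogdet(S_oo)
            S_oo_inv = np.linalg.inv(S_oo)
            dev = Xo - mu_o
            quad = np.einsum("ij,jk,ik->i", dev, S_oo_inv, dev)
            loglik += -0.5 * (len(rows) * (o.sum() * np.log(2 * np.pi) + logdet)
                              + quad.sum())
            if not m.any():
                sum_x += Xo.sum(axis=0)
                sum_xx += Xo.T @ Xo
                continue
            S_mo = sigma[np.ix_(m, o)]
            B = S_mo @ S_oo_inv
            cond_mean = mu[m] + dev @ B.T
            cond_cov = sigma[np.ix_(m, m)] - B @ S_mo.T
            full = np.zeros((len(rows), p))
            full[:, o] = Xo
            full[:, m] = cond_mean
            sum_x += full.sum(axis=0)
            cross = full.T @ full
            # add the conditional covariance of the missing block
            mi = np.where(m)[0]
            cross[np.ix_(mi, mi)] += len(rows) * cond_cov
            sum_xx += cross
        mu_new = sum_x / n
        sigma_new = sum_xx / n - np.outer(mu_new, mu_new)
        sigma_new = (sigma_new + sigma_new.T) / 2.0
        mu, sigma = mu_new, sigma_new
        trace.append(loglik)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    if not converged:
        logger.warning("em_mean_cov: not converged after %d iterations", it)
    return EMEstimate(mean=mu, cov=sigma, n_iter=it, loglik_trace=trace,
                      converged=converged, n_rows_used=n,
                      n_rows_dropped=int(empty_rows.sum()))


def conditional_mean_fill(X, estimate: EMEstimate, ridge: float = 1e-8) -> np.ndarray:
    """Fill NaNs with conditional expectations under an EM (mu, Sigma)."""
    X = np.asarray(X, dtype=float).copy()
    mu, sigma = estimate.mean, estimate.cov
    miss = np.isnan(X)
    for key in {tuple(row) for row in miss}:
        m = np.array(key)
        if not m.any():
            continue
        rows = np.where((miss == m).all(axis=1))[0]
        o = ~m
        if not o.any():
            X[np.ix_(rows, np.where(m)[0])] = mu[m]
            continue
        S_oo = sigma[np.ix_(o, o)] + ridge * np.eye(o.sum())
        B = sigma[np.ix_(m, o)] @ np.linalg.inv(S_oo)
        X[np.ix_(rows, np.where(m)[0])] = mu[m] + (X[np.ix_(rows, np.where(o)[0])]
                                                   - mu[o]) @ B.T
    return X


# ---------------------------------------------------------------------------
# the five-subgroup education imputation
# ---------------------------------------------------------------------------

#: demographic predictors always kept; social predictors pruned last-first
#: when a subgroup is too small for the full design
FULL_PREDICTORS = [
    "age", "race", "gender", "birthplace_south", "birthplace_abroad",
    "child_srh",
    "father_occ", "ses3", "moved_financial", "fin_help", "father_unemp",
    "mother_worked", "lived_with_grandparents", "not_lived_mother",
    "not_lived_father", "mom_teach", "mom_attention", "mom_effort",
]
#: reduced set used for the below-8 mother subgroup, whose full model is the
#: one documented not to converge on the source data
REDUCED_PREDICTORS = [
    "age", "race", "gender", "birthplace_south", "birthplace_abroad",
    "child_srh",
    "father_occ", "ses3", "moved_financial", "lived_with_grandparents",
    "not_lived_father", "mom_effort",
]


@dataclass
class SubgroupPlan:
    name: str
    target: str                  # "mother_edu" or "father_edu"
    clamp: tuple                 # (low, high)
    predictors: list = field(default_factory=lambda: list(FULL_PREDICTORS))


@dataclass
class ImputationPlan:
    """The five subgroups and their clamp ranges.

    The subgroup-range attachment of the clamping rules is an interpretation
    of an ambiguous source convention; it is isolated here so it can be
    changed without touching the imputation code.
    """

    subgroups: list = field(default_factory=lambda: [
        # one joint group for rows with any fully-missing education (both
        # parents' years enter the EM, so the mother-father correlation is
        # exploited), then the four dichotomized-at-8 groups
        SubgroupPlan("any_missing", "both", (0.0, 17.0)),
        SubgroupPlan("mother_lt8", "mother_edu", (0.0, 8.0),
                     predictors=list(REDUCED_PREDICTORS)),
        SubgroupPlan("father_lt8", "father_edu", (0.0, 8.0)),
        SubgroupPlan("mother_ge8", "mother_edu", (8.0, 17.0)),
        SubgroupPlan("father_ge8", "father_edu", (8.0, 17.0)),
    ])

    def validate(self) -> None:
        for sg in self.subgroups:
            lo, hi = sg.clamp
            if not (0.0 <= lo < hi <= 17.0):
                raise ImputationError(f"subgroup {sg.name}: clamp {sg.clamp} "
                                      "outside [0, 17]")
            if "ge8" in sg.name and lo < 8.0:
                raise ImputationError(f"subgroup {sg.name}: >=8 group must clamp low at 8")
            if "lt8" in sg.name and hi > 8.0:
                raise ImputationError(f"subgroup {sg.name}: <8 group must clamp high at 8")


def _predictor_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Numeric predictor design with NaN for missing; categorical variables
    enter as indicator columns."""
    P = pd.DataFrame(index=table.index)
    for col in ("age", "gender", "race", "child_srh", "father_occ", "ses3",
                "moved_financial", "fin_help", "father_unemp", "mother_worked",
                "lived_with_grandparents"):
        v = table[col].to_numpy(dtype=float).copy()
        v[is_missing(v)] = np.nan
        P[col] = v
    bp = table["birthplace"].to_numpy(dtype=float)
    P["birthplace_south"] = (bp == 2).astype(float)
    P["birthplace_abroad"] = (bp == 8).astype(float)
    for parent in ("mother", "father"):
        lw = table[f"lived_with_{parent}"].to_numpy(dtype=float).copy()
        v = np.where(is_missing(lw), np.nan, 1.0 - lw)
        P[f"not_lived_{parent}"] = v
    for col in ("mom_teach", "mom_attention", "mom_effort"):
        v = table[col].to_numpy(dtype=float).copy()
        v[is_missing(v)] = np.nan
        P[col] = v
    return P


def _education_state(table: pd.DataFrame, parent: str):
    """Classify rows: observed continuous, dichotomized (with its bound), or
    fully missing."""
    years = table[f"{parent}_edu"].to_numpy(dtype=float)
    ge8 = table[f"{parent}_edu_ge8"].to_numpy(dtype=float)
    cont = ~is_missing(years)
    dich = ~cont & ~is_missing(ge8)
    missing = ~cont & ~dich
    return years, ge8, cont, dich, missing


def impute_parent_education(table: pd.DataFrame,
                            plan: ImputationPlan | None = None,
                            stochastic: bool = False,
                            seed: int = 0):
    """Continuous mother/father education for every row.

    Returns ``(table_with_filled_columns, audit_log)``; the filled columns
    are ``mother_edu_imputed`` / ``father_edu_imputed``.  Observed continuous
    values are never altered.  ``stochastic=True`` adds a draw from the
    conditional residual distribution (off by default: the production rule is
    conditional-mean single imputation).
    """
    plan = plan or ImputationPlan()
    plan.validate()
    rng = np.random.default_rng(seed)
    P = _predictor_frame(table)
    out = table.copy()
    audit = []

    states = {p: _education_state(table, p) for p in ("mother", "father")}
    filled = {}
    for parent in ("mother", "father"):
        years, ge8, cont, dich, missing = states[parent]
        col = np.where(cont, years, np.nan)
        filled[parent] = col.copy()

    for sg in plan.subgroups:
        if sg.target == "both":
            targets = ["mother", "father"]
            need_by = {p: states[p][4] for p in targets}        # fully missing
            need = need_by["mother"] | need_by["father"]
            anchor = states["mother"][2] & states["father"][2]  # both continuous
        else:
            parent = "mother" if sg.target.startswith("mother") else "father"
            targets = [parent]
            years, ge8, cont, dich, _missing = states[parent]
            if sg.name.endswith("_lt8"):
                nd = dich & (ge8 == 0.0)
                anchor = cont & (years < 8.0)
            else:
                nd = dich & (ge8 == 1.0)
                anchor = cont & (years >= 8.0)
            need_by = {parent: nd}
            need = nd
        n_need = int(need.sum())
        if n_need == 0:
            audit.append({"subgroup": sg.name, "n_imputed": 0, "n_clamped_low": 0,
                          "n_clamped_high": 0, "n_estimation": 0,
                          "predictors_used": len(sg.predictors), "converged": True})
            continue
        rows = need | anchor
        predictors = list(sg.predictors)
        # prune social predictors (from the end of the list) if the subgroup
        # cannot support the design
        while len(predictors) > 6 and rows.sum() < 3 * (len(predictors) + len(targets)):
            dropped = predictors.pop()
            logger.info("subgroup %s: pruning predictor %r (n=%d too small)",
                        sg.name, dropped, int(rows.sum()))
        edu_cols = []
        for p in targets:
            years_p, _, cont_p = states[p][0], states[p][1], states[p][2]
            # only continuously-observed years are data; dichotomized and
            # missing rows enter the EM as missing
            edu_cols.append(np.where(cont_p, years_p, np.nan)[rows])
        X = np.column_stack(edu_cols + [P[predictors].to_numpy(dtype=float)[rows]])
        est = em_mean_cov(X)
        fill = conditional_mean_fill(X, est)
        if stochastic:
            for t in range(len(targets)):
                rest = [j for j in range(X.shape[1]) if j != t]
                resid_var = est.cov[t, t] - est.cov[t, rest] @ np.linalg.pinv(
                    est.cov[np.ix_(rest, rest)]) @ est.cov[rest, t]
                fill[:, t] += (rng.standard_normal(fill.shape[0])
                               * np.sqrt(max(resid_var, 0.0)) * np.isnan(X[:, t]))
        lo, hi = sg.clamp
        n_lo = n_hi = 0
        row_idx = np.where(rows)[0]
        for t, p in enumerate(targets):
            was_nan = np.isnan(X[:, t])
            n_lo += int(((fill[:, t] < lo) & was_nan).sum())
            n_hi += int(((fill[:, t] > hi) & was_nan).sum())
            vals = np.clip(fill[:, t], lo, hi)
            sel = need_by[p][rows]
            filled[p][row_idx[sel]] = vals[sel]
        audit.append({"subgroup": sg.name, "n_imputed": n_need,
                      "n_clamped_low": n_lo, "n_clamped_high": n_hi,
                      "n_estimation": int(rows.sum()),
                      "predictors_used": len(predictors),
                      "converged": est.converged})

    for parent in ("mother", "father"):
        col = np.clip(filled[parent], 0.0, 17.0)
        if np.isnan(col).any():
            raise ImputationError(
                f"{parent}: {int(np.isnan(col).sum())} rows left unimputed "
                "(plan subgroups do not partition the rows needing imputation)")
        out[f"{parent}_edu_imputed"] = col
    return out, pd.DataFrame(audit)


def build_chc(mother_edu, father_edu) -> np.ndarray:
    """Childhood human capital index: z(z(mother) + z(father)).

    Both inputs must be fully populated (post-imputation); the index is
    defined for every row and has mean 0, population sd 1.
    """
    m = np.asarray(mother_edu, dtype=float)
    f = np.asarray(father_edu, dtype=float)
    if np.isnan(m).any() or np.isnan(f).any() or is_missing(m).any() or is_missing(f).any():
        raise ImputationError("build_chc requires fully populated education columns")
    return zscore(zscore(m) + zscore(f))
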
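"""Synthetic respondent cohorts with the structure of retrospective
childhood-circumstance surveys.

The generator emulates a large ageing-cohort survey in which childhood
social, financial, and human capital leave traces in coded retrospective
items.  Three correlated standard-normal capitals drive five sub-factors
(maternal investment and family structure under social capital; average
financial resources and financial instability under financial capital;
human capital itself), each ordinal or binary item is produced by
thresholding ``loading * factor + sqrt(1 - loading^2) * noise`` at fixed
standard-normal cut points (the probit threshold model the downstream
polychoric estimators assume), and adult outcomes follow linear models in
the latent capitals.  A separate missingness stage reproduces the survey's
observation process: experimental-module subsampling (nested random
subsamples), per-item nonresponse, parental education recorded continuously
/ dichotomized at 8 years / missing (with missingness elevated when the
respondent did not live with that parent), and extra vulnerability-patterned
masking of the comparison-index components, which is what makes
complete-case analyses select against the socially vulnerable.

True latent values are retained in ``latent_*`` columns for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .measurement import (MISSING_CODES, NEVER_LIVED, NONRESPONSE,
                          NOT_ADMINISTERED, ItemSchema, is_missing, zscore)

__all__ = [
    "CohortSpec", "generate_cohort", "apply_missingness",
    "recode_never_lived", "csc_schemas", "cfc_schemas",
    "write_cohort", "read_cohort", "CSC_ITEMS", "CFC_ITEMS",
]


class CohortSpecError(ValueError):
    pass


# item -> (ordered level codes, sub-factor)
CSC_ITEMS = {
    "mom_effort": ((1, 2, 3, 4), "maternal_investment"),
    "mom_teach": ((1, 2, 3, 4), "maternal_investment"),
    "mom_attention": ((1, 2, 3, 4), "maternal_investment"),
    "parent_figures": ((1, 2, 3, 4), "family_structure"),
    "lived_with_mother": ((0, 1), "family_structure"),
    "lived_with_father": ((0, 1), "family_structure"),
    "lived_with_grandparents": ((0, 1), "family_structure"),
}
CFC_ITEMS = {
    "moved_financial": ((0, 1), "financial_instability"),
    "fin_help": ((0, 1), "financial_instability"),
    "bankruptcy": ((0, 1), "financial_instability"),
    "lost_business": ((0, 1), "financial_instability"),
    "ses3": ((1, 2, 3), "avg_financial_resources"),
    "ses5": ((1, 2, 3, 4, 5), "avg_financial_resources"),
    "father_occ": ((1, 2, 3, 4, 5, 6), "avg_financial_resources"),
    "father_unemp": ((1, 2, 3), "avg_financial_resources"),
    "mother_worked": ((1, 2, 3), "avg_financial_resources"),
}
ALL_ITEMS = {**CSC_ITEMS, **CFC_ITEMS}

#: comparison-index component columns subject to vulnerability-patterned masking
VULNERABILITY_COMPONENTS = ("mother_edu", "father_edu", "father_occ",
                            "ses3", "moved_financial")

#: item keying relative to "more capital"; -1 items are reverse-coded before
#: internal-consistency computations (alpha assumes consistent keying)
ITEM_KEYING = {name: 1 for name in {**CSC_ITEMS, **CFC_ITEMS}}
ITEM_KEYING.update({"lived_with_grandparents": -1, "moved_financial": -1,
                    "fin_help": -1, "bankruptcy": -1, "lost_business": -1})


def keyed_items(table: pd.DataFrame, items) -> pd.DataFrame:
    """Item columns with negatively keyed items reverse-coded (x -> min+max-x
    over the declared level set); missing codes pass through untouched."""
    out = pd.DataFrame(index=table.index)
    for name in items:
        col = table[name].to_numpy(dtype=float).copy()
        if ITEM_KEYING.get(name, 1) < 0:
            levels, _ = ALL_ITEMS[name]
            lo, hi = float(min(levels)), float(max(levels))
            obs = ~is_missing(col)
            col[obs] = lo + hi - col[obs]
        out[name] = col
    return out


def _tau(cum_probs) -> np.ndarray:
    return norm.ppf(np.asarray(cum_probs, dtype=float))


def _default_loadings() -> dict:
    return {
        "mom_effort": 0.85, "mom_teach": 0.85, "mom_attention": 0.80,
        "parent_figures": 0.70, "lived_with_mother": 0.65,
        "lived_with_father": 0.70, "lived_with_grandparents": -0.45,
        "moved_financial": 0.75, "fin_help": 0.70,
        "bankruptcy": 0.80, "lost_business": 0.80,
        "ses3": 0.70, "ses5": 0.75, "father_occ": 0.55,
        "father_unemp": 0.50,
        # weak candidate: ends up below the 0.3 retention rule, mirroring
        # the one financial item the published scale drops
        "mother_worked": 0.15,
    }


def _default_thresholds() -> dict:
    return {
        "mom_effort": _tau([0.05, 0.15, 0.40]),
        "mom_teach": _tau([0.05, 0.15, 0.40]),
        "mom_attention": _tau([0.06, 0.17, 0.42]),
        "parent_figures": _tau([0.07, 0.12, 0.25]),
        "lived_with_mother": _tau([0.026]),
        "lived_with_father": _tau([0.089]),
        "lived_with_grandparents": _tau([0.85]),
        "moved_financial": _tau([0.80]),
        "fin_help": _tau([0.85]),
        "bankruptcy": _tau([0.90]),
        "lost_business": _tau([0.90]),
        "ses3": _tau([0.25, 0.85]),
        "ses5": _tau([0.08, 0.30, 0.80, 0.95]),
        "father_occ": _tau([0.30, 0.55, 0.65, 0.72, 0.88]),
        "father_unemp": _tau([0.03, 0.23]),
        "mother_worked": _tau([0.25, 0.60]),
    }


def _default_module_fractions() -> dict:
    # fractions of the cohort administered each experimental-module item
    return {
        "mom_effort": 0.221, "mom_teach": 0.221, "mom_attention": 0.201,
        "parent_figures": 0.024, "ses5": 0.024,
        "bankruptcy": 0.023, "lost_business": 0.023,
    }


def _default_core_missing() -> dict:
    # per-column nonresponse among administered respondents, chosen so
    # observed fractions match the survey's reported per-item coverage
    return {
        "lived_with_mother": 0.335, "lived_with_father": 0.122,
        "lived_with_grandparents": 0.165,
        "moved_financial": 0.148, "fin_help": 0.157, "ses3": 0.144,
        "father_occ": 0.337, "father_unemp": 0.198, "mother_worked": 0.352,
        # validation and adult outcomes
        "own_edu": 0.016, "height": 0.59, "child_srh": 0.144,
        "learning_problems": 0.47, "drugalcohol_problems": 0.57,
        "adult_srh": 0.06, "cesd": 0.10,
    }


def _default_parent_edu() -> dict:
    return {
        "mother": {"mean": 9.5, "sd": 2.4, "h_loading": 0.85},
        "father": {"mean": 9.8, "sd": 2.6, "h_loading": 0.85},
        "dichotomized_fraction": 0.27,   # of observed values, recorded only as >= 8
        "p_missing_base": 0.10,
        "p_missing_not_lived": 0.55,     # when respondent did not live with the parent
    }


def _default_outcome_effects() -> dict:
    # coefficients of the latent capitals/sub-factors on each outcome latent,
    # on the scale the outcome is coded (higher self-rated health = worse).
    # avg_resources -> cesd is 0: the generated null whose complete-case
    # distortion the bias analysis demonstrates.
    return {
        "adult_srh": {"social": -0.15, "human": -0.20, "avg_resources": -0.15,
                      "instability": 0.10, "age": 0.010, "noise_sd": 1.0},
        "cesd": {"social": -0.20, "human": -0.12, "avg_resources": 0.0,
                 "instability": 0.35, "age": 0.008, "noise_sd": 1.0},
        "child_srh": {"social": -0.20, "human": -0.20, "avg_resources": -0.25,
                      "instability": 0.10, "noise_sd": 1.0},
        "own_edu": {"base": 11.0, "human": 1.1, "avg_resources": 0.4,
                    "social": 0.3, "noise_sd": 2.0},
        "height": {"base": 175.5, "female": -13.0, "human": 1.2,
                   "social": 0.3, "noise_sd": 6.5},
        "learning_problems": {"intercept": -2.0, "social": -0.35,
                              "financial": -0.25, "human": -0.15},
        "drugalcohol_problems": {"intercept": -3.2, "social": -0.30,
                                 "financial": -0.25, "human": 0.0},
        "cesd_item_loading": 0.75,
        "cesd_neg_prevalence": (0.25, 0.30, 0.35, 0.20, 0.22, 0.18),
        "cesd_pos_prevalence": (0.88, 0.85),   # probability of answering yes
        "adult_srh_cum": (0.15, 0.45, 0.75, 0.92),
        "child_srh_cum": (0.35, 0.65, 0.85, 0.95),
    }


def _default_covariates() -> dict:
    return {
        "age": {"mean": 68.0, "sd": 10.0, "min": 50.0, "max": 100.0},
        "p_female": 0.56,
        "race_probs": (0.70, 0.15, 0.10, 0.05),
        "birthplace_probs": (0.18, 0.25, 0.12, 0.15, 0.08, 0.05, 0.12, 0.05),
    }


@dataclass
class CohortSpec:
    """All parameters of the synthetic data-generating process."""

    n_respondents: int = 31169
    seed: int = 0
    latent_corr: np.ndarray = field(default_factory=lambda: np.array(
        [[1.00, 0.25, 0.15],
         [0.25, 1.00, 0.45],    # financial-human strongest, per the observed
         [0.15, 0.45, 1.00]]))  # inter-scale association pattern
    # shared variance of each sub-factor pair with its parent capital; the
    # financial pair is more tightly coupled, calibrated so the scales'
    # internal consistencies land near the reported ~0.6
    subfactor_weight: dict = field(default_factory=lambda: {
        "social": 0.45, "financial": 0.60})
    loadings: dict = field(default_factory=_default_loadings)
    thresholds: dict = field(default_factory=_default_thresholds)
    module_fractions: dict = field(default_factory=_default_module_fractions)
    core_missing_rate: dict = field(default_factory=_default_core_missing)
    parent_edu: dict = field(default_factory=_default_parent_edu)
    vulnerability_missing_slope: float = 1.5
    vulnerability_base_rate: float = 0.08
    # composition of the vulnerability score: low capitals, low average
    # financial resources specifically, and high depressive tendency all
    # raise the probability that comparison-index components go unobserved
    vulnerability_weights: dict = field(default_factory=lambda: {
        "capitals": 0.25, "avg_resources": 0.50, "depressive": 0.60})
    outcome_effects: dict = field(default_factory=_default_outcome_effects)
    covariate_params: dict = field(default_factory=_default_covariates)

    def validate(self) -> None:
        if self.n_respondents < 1:
            raise CohortSpecError("n_respondents must be >= 1")
        lc = np.asarray(self.latent_corr, dtype=float)
        if lc.shape != (3, 3) or not np.allclose(lc, lc.T):
            raise CohortSpecError("latent_corr must be a symmetric 3x3 matrix")
        if not np.allclose(np.diag(lc), 1.0):
            raise CohortSpecError("latent_corr must have unit diagonal")
        if np.linalg.eigvalsh(lc).min() <= 0:
            raise CohortSpecError(
                f"latent_corr is not positive definite: {lc.tolist()}")
        for cap, w in self.subfactor_weight.items():
            if not 0.0 <= w <= 1.0:
                raise CohortSpecError(
                    f"subfactor_weight[{cap!r}]={w} outside [0, 1]")
        for item, tau in self.thresholds.items():
            tau = np.asarray(tau, dtype=float)
            if tau.size > 1 and not np.all(np.diff(tau) > 0):
                raise CohortSpecError(
                    f"thresholds for {item!r} must be strictly increasing")
        for name, probs in (("module_fractions", self.module_fractions),
                            ("core_missing_rate", self.core_missing_rate)):
            for item, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise CohortSpecError(f"{name}[{item!r}]={p} outside [0, 1]")
        pe = self.parent_edu
        for key in ("dichotomized_fraction", "p_missing_base", "p_missing_not_lived"):
            if not 0.0 <= pe[key] <= 1.0:
                raise CohortSpecError(f"parent_edu[{key!r}] outside [0, 1]")
        if not 0.0 <= self.vulnerability_base_rate <= 1.0:
            raise CohortSpecError("vulnerability_base_rate outside [0, 1]")

    def with_updates(self, **kwargs) -> "CohortSpec":
        return replace(self, **kwargs)


def _rngs(seed: int):
    """One master seed expands deterministically into per-stage generators
    (latents, items, parental education, outcomes, covariates, missingness)."""
    children = np.random.SeedSequence(seed).spawn(6)
    return [np.random.default_rng(c) for c in children]


def _code_item(ystar: np.ndarray, tau: np.ndarray, levels) -> np.ndarray:
    idx = (ystar[:, None] > np.asarray(tau)[None, :]).sum(axis=1)
    return np.asarray(levels, dtype=float)[idx]


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a complete (pre-missingness) respondent table."""
    spec.validate()
    rng_lat, rng_items, rng_pedu, rng_out, rng_cov, _ = _rngs(spec.seed)
    n = spec.n_respondents

    chol = np.linalg.cholesky(np.asarray(spec.latent_corr, dtype=float))
    capitals = rng_lat.standard_normal((n, 3)) @ chol.T
    S, F, H = capitals[:, 0], capitals[:, 1], capitals[:, 2]
    ws = spec.subfactor_weight["social"]
    wf = spec.subfactor_weight["financial"]
    uniq = rng_lat.standard_normal((n, 4))
    maternal = np.sqrt(ws) * S + np.sqrt(1 - ws) * uniq[:, 0]
    famstruct = np.sqrt(ws) * S + np.sqrt(1 - ws) * uniq[:, 1]
    avgres = np.sqrt(wf) * F + np.sqrt(1 - wf) * uniq[:, 2]
    instab = -np.sqrt(wf) * F + np.sqrt(1 - wf) * uniq[:, 3]
    factor_values = {
        "maternal_investment": maternal, "family_structure": famstruct,
        "avg_financial_resources": avgres, "financial_instability": instab,
    }

    table = pd.DataFrame({"respondent_id": np.arange(1, n + 1)})
    for item, (levels, fac) in ALL_ITEMS.items():
        lam = float(spec.loadings[item])
        ystar = lam * factor_values[fac] + np.sqrt(1 - lam ** 2) * rng_items.standard_normal(n)
        table[item] = _code_item(ystar, spec.thresholds[item], levels)
    # parental-employment items carry "never lived with that parent" as a
    # distinct level 0 before any recoding
    table.loc[table["lived_with_father"] == 0, "father_unemp"] = 0.0
    table.loc[table["lived_with_mother"] == 0, "mother_worked"] = 0.0

    pe = spec.parent_edu
    for parent in ("mother", "father"):
        p = pe[parent]
        hl = p["h_loading"]
        raw = p["mean"] + p["sd"] * (hl * H + np.sqrt(1 - hl ** 2) *
                                     rng_pedu.standard_normal(n))
        table[f"{parent}_edu"] = np.clip(np.round(raw), 0.0, 17.0)
        table[f"{parent}_edu_ge8"] = (table[f"{parent}_edu"] >= 8).astype(float)

    cov = spec.covariate_params
    age = np.clip(cov["age"]["mean"] + cov["age"]["sd"] * rng_cov.standard_normal(n),
                  cov["age"]["min"], cov["age"]["max"])
    table["age"] = np.round(age)
    table["gender"] = (rng_cov.uniform(size=n) < cov["p_female"]).astype(float)
    table["race"] = rng_cov.choice(np.arange(1.0, 5.0), size=n, p=cov["race_probs"])
    table["birthplace"] = rng_cov.choice(np.arange(1.0, 9.0), size=n,
                                         p=cov["birthplace_probs"])

    eff = spec.outcome_effects
    basis = {"social": S, "financial": F, "human": H,
             "avg_resources": avgres, "instability": instab}

    def linear(coefs, keys):
        z = np.zeros(n)
        for k in keys:
            z = z + coefs.get(k, 0.0) * basis[k]
        return z

    # validation outcomes ---------------------------------------------------
    oe = eff["own_edu"]
    own = oe["base"] + linear(oe, ("human", "avg_resources", "social")) \
        + oe["noise_sd"] * rng_out.standard_normal(n)
    table["own_edu"] = np.clip(np.round(own), 0.0, 17.0)

    he = eff["height"]
    table["height"] = (he["base"] + he["female"] * table["gender"].to_numpy()
                       + linear(he, ("human", "social"))
                       + he["noise_sd"] * rng_out.standard_normal(n)).round(1)

    ch = eff["child_srh"]
    z = linear(ch, ("social", "human", "avg_resources", "instability")) \
        + ch["noise_sd"] * rng_out.standard_normal(n)
    sd = _linear_sd(ch, spec)
    table["child_srh"] = _code_item(z / sd, _tau(eff["child_srh_cum"]),
                                    (1, 2, 3, 4, 5))

    for name in ("learning_problems", "drugalcohol_problems"):
        co = eff[name]
        p = expit(co["intercept"] + linear(co, ("social", "financial", "human")))
        table[name] = (rng_out.uniform(size=n) < p).astype(float)

    # adult outcomes --------------------------------------------------------
    age_c = table["age"].to_numpy() - 70.0
    age_sd = cov["age"]["sd"]
    age_off = cov["age"]["mean"] - 70.0
    asrh = eff["adult_srh"]
    z = linear(asrh, ("social", "human", "avg_resources", "instability")) \
        + asrh["age"] * age_c + asrh["noise_sd"] * rng_out.standard_normal(n)
    sd = np.sqrt(_linear_sd(asrh, spec) ** 2 + (asrh["age"] * age_sd) ** 2)
    table["adult_srh"] = _code_item((z - asrh["age"] * age_off) / sd,
                                    _tau(eff["adult_srh_cum"]), (1, 2, 3, 4, 5))

    ce = eff["cesd"]
    D = linear(ce, ("social", "human", "avg_resources", "instability")) \
        + ce["age"] * age_c + ce["noise_sd"] * rng_out.standard_normal(n)
    D_sd = np.sqrt(_linear_sd(ce, spec) ** 2 + (ce["age"] * age_sd) ** 2)
    Dz = (D - ce["age"] * age_off) / D_sd
    lam = eff["cesd_item_loading"]
    res = np.sqrt(1 - lam ** 2)
    for i, prev in enumerate(eff["cesd_neg_prevalence"], start=1):
        y = lam * Dz + res * rng_out.standard_normal(n)
        table[f"cesd{i}"] = (y > norm.ppf(1 - prev)).astype(float)
    for i, prev in enumerate(eff["cesd_pos_prevalence"], start=7):
        y = -lam * Dz + res * rng_out.standard_normal(n)
        table[f"cesd{i}"] = (y > norm.ppf(1 - prev)).astype(float)

    # retained truth for recovery tests
    table["latent_social"] = S
    table["latent_financial"] = F
    table["latent_human"] = H
    table["latent_maternal"] = maternal
    table["latent_famstruct"] = famstruct
    table["latent_avgres"] = avgres
    table["latent_instab"] = instab
    table["latent_depress"] = D
    return table


def _linear_sd(coefs: dict, spec: CohortSpec) -> float:
    """Theoretical sd of a linear combination of the latent basis (before
    outcome noise), from the construction covariances of the sub-factors."""
    c = np.asarray(spec.latent_corr, dtype=float)
    w = spec.subfactor_weight["financial"]
    sq = np.sqrt(w)
    names = ["social", "financial", "human", "avg_resources", "instability"]
    V = np.eye(5)
    V[0, 1] = V[1, 0] = c[0, 1]
    V[0, 2] = V[2, 0] = c[0, 2]
    V[1, 2] = V[2, 1] = c[1, 2]
    V[0, 3] = V[3, 0] = sq * c[0, 1]
    V[0, 4] = V[4, 0] = -sq * c[0, 1]
    V[1, 3] = V[3, 1] = sq
    V[1, 4] = V[4, 1] = -sq
    V[2, 3] = V[3, 2] = sq * c[1, 2]
    V[2, 4] = V[4, 2] = -sq * c[1, 2]
    V[3, 4] = V[4, 3] = -w
    b = np.array([coefs.get(k, 0.0) for k in names])
    var = float(b @ V @ b) + coefs.get("noise_sd", 0.0) ** 2
    return np.sqrt(var)


# ---------------------------------------------------------------------------
# missingness stage
# ---------------------------------------------------------------------------

def apply_missingness(table: pd.DataFrame, spec: CohortSpec) -> pd.DataFrame:
    """Mask a complete cohort with the survey's observation process.

    Stages (all driven by the missingness child of the master seed):
    module subsampling (nested: one uniform per respondent, an item is
    administered iff the uniform falls below its module fraction), per-item
    core nonresponse, the three-way parental-education representation, and
    vulnerability-patterned masking of the comparison-index components.
    """
    spec.validate()
    rng = _rngs(spec.seed)[5]
    out = table.copy()
    n = len(out)

    u_module = rng.uniform(size=n)
    for item in ALL_ITEMS:
        frac = spec.module_fractions.get(item, 1.0)
        not_admin = u_module >= frac
        if frac < 1.0:
            out.loc[not_admin, item] = NOT_ADMINISTERED
        u = rng.uniform(size=n)  # drawn unconditionally: stable stream
        rate = spec.core_missing_rate.get(item, 0.0)
        if rate > 0.0:
            out.loc[(u < rate) & ~not_admin, item] = NONRESPONSE

    # outcome nonresponse; the eight depressive-symptom items share one
    # interview-level mask
    for col in ("own_edu", "height", "child_srh", "learning_problems",
                "drugalcohol_problems", "adult_srh"):
        u = rng.uniform(size=n)
        rate = spec.core_missing_rate.get(col, 0.0)
        if rate > 0.0:
            out.loc[u < rate, col] = NONRESPONSE
    u = rng.uniform(size=n)
    rate = spec.core_missing_rate.get("cesd", 0.0)
    if rate > 0.0:
        for i in range(1, 9):
            out.loc[u < rate, f"cesd{i}"] = NONRESPONSE

    # parental education: continuous / dichotomized-at-8 / missing
    # (skipped entirely when all representation rates are zero, so the
    # no-missingness spec is an exact identity)
    pe = spec.parent_edu
    edu_active = (pe["dichotomized_fraction"] > 0 or pe["p_missing_base"] > 0
                  or pe["p_missing_not_lived"] > 0)
    for parent in ("mother", "father") if edu_active else ():
        lived = table[f"lived_with_{parent}"].to_numpy() == 1
        p_missing = np.where(lived, pe["p_missing_base"], pe["p_missing_not_lived"])
        u1 = rng.uniform(size=n)
        u2 = rng.uniform(size=n)
        missing = u1 < p_missing
        dichot = ~missing & (u2 < pe["dichotomized_fraction"])
        cont = ~missing & ~dichot
        out.loc[missing, f"{parent}_edu"] = NONRESPONSE
        out.loc[missing, f"{parent}_edu_ge8"] = NONRESPONSE
        out.loc[dichot, f"{parent}_edu"] = NONRESPONSE
        out.loc[cont, f"{parent}_edu_ge8"] = NONRESPONSE

    # vulnerability-patterned masking of comparison-index components
    q0 = spec.vulnerability_base_rate
    slope = spec.vulnerability_missing_slope
    if q0 > 0.0:
        wts = spec.vulnerability_weights
        vuln_raw = (-wts["capitals"] * (table["latent_social"]
                                        + table["latent_financial"]
                                        + table["latent_human"]).to_numpy() / 3.0
                    - wts["avg_resources"] * table["latent_avgres"].to_numpy()
                    + wts["depressive"] * zscore(table["latent_depress"].to_numpy()))
        vuln = zscore(vuln_raw)
        q = expit(logit(q0) + slope * vuln)
        for comp in VULNERABILITY_COMPONENTS:
            u = rng.uniform(size=n)
            hit = u < q
            out.loc[hit, comp] = NONRESPONSE
            if comp in ("mother_edu", "father_edu"):
                out.loc[hit, f"{comp}_ge8"] = NONRESPONSE
    return out


def recode_never_lived(table: pd.DataFrame) -> pd.DataFrame:
    """Recode the "never lived with that parent" level (0) of the parental
    employment items to the cause-specific missing sentinel, so it is absent
    from the financial-capital measurement model; the information stays
    available to the social-capital scale through the lived-with items."""
    out = table.copy()
    for col in ("father_unemp", "mother_worked"):
        out.loc[out[col] == 0.0, col] = NEVER_LIVED
    return out


def csc_schemas() -> list:
    return [ItemSchema(name=k, levels=v[0], factor=v[1]) for k, v in CSC_ITEMS.items()]


def cfc_schemas(include_candidates: bool = True) -> list:
    """Candidate financial-capital item schemas (post never-lived recoding,
    the employment items have 3 valid levels)."""
    items = CFC_ITEMS if include_candidates else {
        k: v for k, v in CFC_ITEMS.items() if k != "mother_worked"}
    return [ItemSchema(name=k, levels=v[0], factor=v[1]) for k, v in items.items()]


# ---------------------------------------------------------------------------
# CSV round trip with a data-dictionary sidecar
# ---------------------------------------------------------------------------

_COLUMN_NOTES = {
    "respondent_id": "unique respondent identifier",
    "mother_edu": "mother's completed education, years 0-17 (continuous rows)",
    "father_edu": "father's completed education, years 0-17 (continuous rows)",
    "mother_edu_ge8": "mother's education at or above 8 years (dichotomized rows)",
    "father_edu_ge8": "father's education at or above 8 years (dichotomized rows)",
    "own_edu": "respondent's completed education, years 0-17",
    "height": "measured adult height, cm",
    "child_srh": "childhood self-rated health, 1-5, lower = better",
    "adult_srh": "adult self-rated health, 1-5, lower = better",
    "age": "age at interview, years", "gender": "1 = female",
    "race": "race/ethnicity, 4 categories",
    "birthplace": "birthplace region, 8 categories",
}


def data_dictionary(table: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for col in table.columns:
        if col in ALL_ITEMS:
            levels, fac = ALL_ITEMS[col]
            note = f"scale item (factor: {fac})"
            lv = ",".join(str(int(l)) for l in levels)
        elif col.startswith("cesd"):
            note = "depressive-symptom item, 1 = yes"
            lv = "0,1"
        elif col.startswith("latent_"):
            note = "true generating latent (retained for recovery tests)"
            lv = "continuous"
        else:
            note = _COLUMN_NOTES.get(col, "")
            lv = "continuous"
        rows.append({"column": col, "levels": lv,
                     "missing_codes": ",".join(str(int(c)) for c in MISSING_CODES),
                     "description": note})
    return pd.DataFrame(rows)


def write_cohort(table: pd.DataFrame, path) -> None:
    path = str(path)
    table.to_csv(path, index=False)
    data_dictionary(table).to_csv(_dict_path(path), index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(str(path))


def _dict_path(path: str) -> str:
    base = path[:-4] if path.endswith(".csv") else path
    return base + ".dict.csv"
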
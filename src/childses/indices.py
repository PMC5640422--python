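"""Composite childhood-SES indices and outcome scoring.

The validated index averages the available z-scored capital measures (social,
financial, human) per respondent and re-standardizes.  Three previously
published index codings are reproduced for comparison:

* Luo: four standardized components (parental education dichotomies at 8
  years, white-collar father, 3-level self-rated childhood SES) averaged;
  missing education/occupation coded to the low-SES level, "it varied"
  self-rating treated as missing and the index averaged over the rest.
* Glymour: one point each for *known* mother's education < 8, *known*
  father's education < 8, and father's manual occupation; unknown earns no
  point but is not missing; the mean of the three points is reverse-coded so
  0 is lowest and 1 highest SES.
* Hargrove: five binary indicators (parental education at >= 12 years,
  moved for financial reasons, self-rated poor childhood SES, white-collar
  father) under a complete-case rule: only rows observing all five are
  eligible.

Occupation categories are coded 1-6 from production/construction (1) up to
executives & managers (6); "white collar" is the top three (executives,
professional specialty, sales & administration) and "manual" the bottom two,
a configurable cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .measurement import is_missing, zscore

#: father_occ codes counted as white-collar (categories a-c) / manual (e-f)
WHITE_COLLAR_MIN = 4
MANUAL_MAX = 2

SES3_POOR, SES3_AVERAGE, SES3_WELLOFF = 1.0, 2.0, 3.0


class CodingError(ValueError):
    pass


@dataclass
class CompositeIndex:
    family: str                      # validated | luo | glymour | hargrove
    values: pd.DataFrame             # respondent_id, value (or indicator columns)
    availability: pd.DataFrame       # per-component observed mask
    eligible: np.ndarray | None = None   # hargrove complete-case flag


def _masked(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float).copy()
    arr[is_missing(arr)] = np.nan
    return arr


def build_cses_index(csc, cfc, chc, respondent_id=None) -> CompositeIndex:
    """Validated composite: mean of available z-scored components, then a
    final z-scoring over valued rows.  Rows with all three components
    missing receive no value."""
    comps = np.column_stack([_masked(csc), _masked(cfc), _masked(chc)])
    avail = ~np.isnan(comps)
    valued = avail.any(axis=1)
    value = np.full(len(comps), np.nan)
    value[valued] = zscore(np.nanmean(comps[valued], axis=1))
    rid = (np.arange(1, len(comps) + 1) if respondent_id is None
           else np.asarray(respondent_id))
    return CompositeIndex(
        family="validated",
        values=pd.DataFrame({"respondent_id": rid, "value": value}),
        availability=pd.DataFrame(avail, columns=["csc", "cfc", "chc"]))


def _resolve_edu(edu_years, edu_ge8, cut: float):
    """Dichotomize education at ``cut`` years, using the dichotomized-at-8
    representation when continuous years are unavailable and the cut is 8.
    Returns (indicator, known mask)."""
    years = _masked(edu_years)
    known = ~np.isnan(years)
    ind = np.where(known, (years >= cut).astype(float), np.nan)
    if edu_ge8 is not None and cut == 8.0:
        ge8 = _masked(edu_ge8)
        use = ~known & ~np.isnan(ge8)
        ind[use] = ge8[use]
        known = known | use
    return ind, known


def build_luo_index(mother_edu, father_edu, father_occ, ses3,
                    mother_edu_ge8=None, father_edu_ge8=None,
                    respondent_id=None) -> CompositeIndex:
    """Luo coding: standardized components averaged; missing education or
    occupation coded as the low-SES level; "it varied" self-rated SES treated
    as missing with the index derived from the other components."""
    m_ind, m_known = _resolve_edu(mother_edu, mother_edu_ge8, 8.0)
    f_ind, f_known = _resolve_edu(father_edu, father_edu_ge8, 8.0)
    m_comp = np.where(m_known, m_ind, 0.0)       # unknown -> low SES
    f_comp = np.where(f_known, f_ind, 0.0)
    occ = _masked(father_occ)
    wc = np.where(np.isnan(occ), 0.0, (occ >= WHITE_COLLAR_MIN).astype(float))
    s3 = _masked(ses3)                           # "it varied" arrives as missing
    comps = np.column_stack([m_comp, f_comp, wc, s3])
    std = comps.copy()
    for j in range(comps.shape[1]):
        col = comps[:, j]
        ok = ~np.isnan(col)
        std[ok, j] = zscore(col[ok])
    valued = (~np.isnan(std)).any(axis=1)
    value = np.full(len(std), np.nan)
    value[valued] = zscore(np.nanmean(std[valued], axis=1))
    rid = (np.arange(1, len(std) + 1) if respondent_id is None
           else np.asarray(respondent_id))
    return CompositeIndex(
        family="luo",
        values=pd.DataFrame({"respondent_id": rid, "value": value}),
        availability=pd.DataFrame(~np.isnan(std),
                                  columns=["mother_ge8", "father_ge8",
                                           "white_collar", "ses3"]))


def build_glymour_index(mother_edu, father_edu, father_occ,
                        mother_edu_ge8=None, father_edu_ge8=None,
                        respondent_id=None) -> CompositeIndex:
    """Glymour coding: points for known low education/manual occupation
    (unknown earns no point, it is not missing), averaged and reverse-coded
    so 0 is the lowest SES and 1 the highest."""
    m_ind, m_known = _resolve_edu(mother_edu, mother_edu_ge8, 8.0)
    f_ind, f_known = _resolve_edu(father_edu, father_edu_ge8, 8.0)
    m_pt = np.where(m_known & (m_ind == 0.0), 1.0, 0.0)
    f_pt = np.where(f_known & (f_ind == 0.0), 1.0, 0.0)
    occ = _masked(father_occ)
    manual_pt = np.where(~np.isnan(occ) & (occ <= MANUAL_MAX), 1.0, 0.0)
    raw = (m_pt + f_pt + manual_pt) / 3.0
    value = 1.0 - raw
    n = len(value)
    rid = np.arange(1, n + 1) if respondent_id is None else np.asarray(respondent_id)
    return CompositeIndex(
        family="glymour",
        values=pd.DataFrame({"respondent_id": rid, "value": value}),
        availability=pd.DataFrame({"mother_known": m_known, "father_known": f_known,
                                   "occ_known": ~np.isnan(occ)}))


def build_hargrove_indicators(mother_edu, father_edu, moved, ses3, father_occ,
                              respondent_id=None) -> CompositeIndex:
    """Hargrove coding: five binary indicators under a complete-case rule.

    The education cuts are at 12 years and cannot be evaluated from the
    dichotomized-at-8 representation, so those rows count as missing."""
    m_ind, m_known = _resolve_edu(mother_edu, None, 12.0)
    f_ind, f_known = _resolve_edu(father_edu, None, 12.0)
    mv = _masked(moved)
    s3 = _masked(ses3)
    occ = _masked(father_occ)
    poor = np.where(np.isnan(s3), np.nan, (s3 == SES3_POOR).astype(float))
    wc = np.where(np.isnan(occ), np.nan, (occ >= WHITE_COLLAR_MIN).astype(float))
    ind = pd.DataFrame({
        "mother_edu_ge12": m_ind, "father_edu_ge12": f_ind,
        "moved_financial": mv, "self_rated_poor": poor,
        "father_white_collar": wc,
    })
    eligible = (~ind.isna()).all(axis=1).to_numpy()
    n = len(ind)
    rid = np.arange(1, n + 1) if respondent_id is None else np.asarray(respondent_id)
    ind.insert(0, "respondent_id", rid)
    return CompositeIndex(
        family="hargrove", values=ind,
        availability=ind.drop(columns="respondent_id").notna(),
        eligible=eligible)


# ---------------------------------------------------------------------------
# outcome scoring
# ---------------------------------------------------------------------------

CESD_NEGATIVE = tuple(f"cesd{i}" for i in range(1, 7))
CESD_POSITIVE = ("cesd7", "cesd8")


def score_cesd(items: pd.DataFrame, require_complete: bool = True) -> np.ndarray:
    """Modified 8-item depressive-symptom count, 0-8.

    Six negative items count "yes"; the two positive items (felt happy,
    enjoyed life) are reverse-coded and count "no".  By default any missing
    item makes the whole score missing; ``require_complete=False`` prorates
    the mean over observed items to the 8-item scale.
    """
    cols = list(CESD_NEGATIVE) + list(CESD_POSITIVE)
    X = items[cols].to_numpy(dtype=float).copy()
    X[is_missing(X)] = np.nan
    ok = np.isnan(X) | np.isin(X, (0.0, 1.0))
    if not ok.all():
        bad = np.unique(X[~ok])
        raise CodingError(f"non-binary depressive-symptom responses: {bad.tolist()}")
    contrib = X.copy()
    contrib[:, len(CESD_NEGATIVE):] = 1.0 - contrib[:, len(CESD_NEGATIVE):]
    n_obs = (~np.isnan(contrib)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        if require_complete:
            score = contrib.sum(axis=1)
            score[n_obs < 8] = np.nan
        else:
            score = np.nanmean(contrib, axis=1) * 8.0
            score[n_obs == 0] = np.nan
    return score


def attach_indices(table: pd.DataFrame, csc, cfc, chc) -> pd.DataFrame:
    """Append every index family and the scored outcomes to the respondent
    table (columns: csc, cfc, chc, cses_index, luo_index, glymour_index,
    hargrove_*, hargrove_eligible, cesd_score)."""
    out = table.copy()
    out["csc"] = _masked(csc)
    out["cfc"] = _masked(cfc)
    out["chc"] = _masked(chc)
    rid = table["respondent_id"].to_numpy()
    out["cses_index"] = build_cses_index(csc, cfc, chc, rid).values["value"].to_numpy()
    out["luo_index"] = build_luo_index(
        table["mother_edu"], table["father_edu"], table["father_occ"],
        _ses3_with_varied_missing(table), table["mother_edu_ge8"],
        table["father_edu_ge8"], rid).values["value"].to_numpy()
    out["glymour_index"] = build_glymour_index(
        table["mother_edu"], table["father_edu"], table["father_occ"],
        table["mother_edu_ge8"], table["father_edu_ge8"], rid
    ).values["value"].to_numpy()
    harg = build_hargrove_indicators(
        table["mother_edu"], table["father_edu"], table["moved_financial"],
        table["ses3"], table["father_occ"], rid)
    for col in harg.values.columns:
        if col != "respondent_id":
            out[f"hargrove_{col}"] = harg.values[col].to_numpy()
    out["hargrove_eligible"] = harg.eligible.astype(float)
    out["cesd_score"] = score_cesd(table)
    return out


def _ses3_with_varied_missing(table: pd.DataFrame) -> np.ndarray:
    """The 3-level self-rated childhood SES as the Luo coding consumes it.

    The survey instrument folds "it varied" into "about average" before the
    data reach us, so the generated item has no separate varied level; this
    hook exists so a real table carrying a distinct varied code (0) routes it
    to missing, per the Luo rule."""
    s3 = np.asarray(table["ses3"], dtype=float).copy()
    s3[s3 == 0.0] = np.nan
    return s3
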
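"""Hand-checkable index codings: validated composite, Luo, Glymour,
Hargrove, and the modified depressive-symptom score."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from childses import indices as idx
from childses.measurement import NONRESPONSE


class TestValidatedComposite:
    def test_missing_component_averaged_over_rest(self):
        """A row with (missing, 0.4, -0.2) must equal a row scoring 0.1 on
        every component: both average to 0.1 before the final z-scoring."""
        csc = [np.nan, 0.1, 1.0, -1.0, 0.5]
        cfc = [0.4, 0.1, 0.8, -0.6, 0.2]
        chc = [-0.2, 0.1, 1.2, -0.9, 0.0]
        res = idx.build_cses_index(csc, cfc, chc)
        vals = res.values["value"].to_numpy()
        assert vals[0] == pytest.approx(vals[1], abs=1e-12)

    def test_equal_components_pass_through(self):
        res = idx.build_cses_index([1.0, -1.0], [1.0, -1.0], [1.0, -1.0])
        assert res.values["value"].tolist() == pytest.approx([1.0, -1.0])

    def test_valued_rows_equal_any_component_count(self, rng):
        comps = rng.standard_normal((300, 3))
        comps[rng.uniform(size=comps.shape) < 0.5] = np.nan
        res = idx.build_cses_index(*comps.T)
        expected = (~np.isnan(comps)).any(axis=1).sum()
        assert (~res.values["value"].isna()).sum() == expected

    def test_all_missing_row_unvalued(self):
        res = idx.build_cses_index([np.nan, 0.0, 1.0], [np.nan, 0.0, -1.0],
                                   [NONRESPONSE, 0.0, 0.5])
        assert np.isnan(res.values["value"].iloc[0])


class TestLuo:
    def base_inputs(self, n=8):
        rng = np.random.default_rng(0)
        return {
            "mother_edu": rng.integers(4, 16, n).astype(float),
            "father_edu": rng.integers(4, 16, n).astype(float),
            "father_occ": rng.integers(1, 7, n).astype(float),
            "ses3": rng.integers(1, 4, n).astype(float),
        }

    def test_missing_occupation_coded_low_ses(self):
        a = self.base_inputs()
        b = {k: v.copy() for k, v in a.items()}
        a["father_occ"][0] = np.nan          # unknown occupation
        b["father_occ"][0] = 1.0             # known low (manual) occupation
        va = idx.build_luo_index(**a).values["value"]
        vb = idx.build_luo_index(**b).values["value"]
        assert not np.isnan(va.iloc[0])      # index still produced
        assert va.iloc[0] == pytest.approx(vb.iloc[0], abs=1e-12)

    def test_varied_self_rating_missing_average_of_rest(self):
        a = self.base_inputs()
        a["ses3"][0] = np.nan                # "it varied"
        res = idx.build_luo_index(**a)
        assert not np.isnan(res.values["value"].iloc[0])
        avail = res.availability.iloc[0]
        assert not avail["ses3"] and avail[["mother_ge8", "father_ge8",
                                            "white_collar"]].all()

    def test_components_at_sample_means_give_zero(self):
        # perfectly balanced complete inputs: a row at every component mean
        inputs = {
            "mother_edu": np.array([4.0, 12.0, 4.0, 12.0]),
            "father_edu": np.array([4.0, 12.0, 12.0, 4.0]),
            "father_occ": np.array([1.0, 6.0, 6.0, 1.0]),
            "ses3": np.array([1.0, 3.0, 3.0, 1.0]),
        }
        vals = idx.build_luo_index(**inputs).values["value"].to_numpy()
        assert vals.sum() == pytest.approx(0.0, abs=1e-12)
        assert vals[0] == pytest.approx(-vals[1], abs=1e-12)

    def test_dichotomized_representation_feeds_education_component(self):
        a = self.base_inputs()
        b = {k: v.copy() for k, v in a.items()}
        a["mother_edu"][0] = 10.0            # continuous, >= 8
        b["mother_edu"][0] = np.nan
        vb = idx.build_luo_index(**b, mother_edu_ge8=np.where(
            np.arange(8) == 0, 1.0, np.nan)).values["value"]
        va = idx.build_luo_index(**a).values["value"]
        assert va.iloc[0] == pytest.approx(vb.iloc[0], abs=1e-12)


class TestGlymour:
    def test_worked_example(self):
        # mother 6y (known < 8), father 9y, father manual -> 2/3 points -> 1/3
        res = idx.build_glymour_index([6.0], [9.0], [1.0])
        assert res.values["value"].iloc[0] == pytest.approx(1.0 / 3.0)

    def test_zero_point_case(self):
        res = idx.build_glymour_index([10.0], [9.0], [5.0])
        assert res.values["value"].iloc[0] == 1.0

    def test_unknown_earns_no_point_not_missing(self):
        res = idx.build_glymour_index([np.nan], [9.0], [5.0])
        assert res.values["value"].iloc[0] == 1.0   # unknown mother: no point

    @given(st.lists(st.tuples(st.one_of(st.none(), st.floats(0, 17)),
                              st.one_of(st.none(), st.floats(0, 17)),
                              st.one_of(st.none(), st.integers(1, 6))),
                    min_size=1, max_size=20))
    @settings(max_examples=40, deadline=None)
    def test_values_confined_to_thirds(self, rows):
        m = [np.nan if r[0] is None else r[0] for r in rows]
        f = [np.nan if r[1] is None else r[1] for r in rows]
        o = [np.nan if r[2] is None else float(r[2]) for r in rows]
        vals = idx.build_glymour_index(m, f, o).values["value"].to_numpy()
        allowed = {0.0, 1 / 3, 2 / 3, 1.0}
        assert all(any(abs(v - a) < 1e-9 for a in allowed) for v in vals)


class TestHargrove:
    def test_twelve_year_cut(self):
        res = idx.build_hargrove_indicators(
            [12.0, 11.0], [13.0, 13.0], [0.0, 0.0], [2.0, 2.0], [5.0, 5.0])
        assert res.values["mother_edu_ge12"].tolist() == [1.0, 0.0]
        assert res.eligible.all()

    def test_any_missing_input_ineligible(self):
        res = idx.build_hargrove_indicators(
            [12.0, 12.0, 12.0], [13.0, np.nan, 13.0],
            [0.0, 0.0, NONRESPONSE], [2.0, 2.0, 2.0], [5.0, 5.0, 5.0])
        assert res.eligible.tolist() == [True, False, False]

    def test_poor_and_white_collar_coding(self):
        res = idx.build_hargrove_indicators(
            [12.0, 12.0], [13.0, 13.0], [1.0, 0.0], [1.0, 3.0], [4.0, 3.0])
        assert res.values["self_rated_poor"].tolist() == [1.0, 0.0]
        assert res.values["father_white_collar"].tolist() == [1.0, 0.0]

    def test_eligible_more_capital_under_vulnerability_missingness(self, masked_cohort):
        _, tab = masked_cohort
        res = idx.build_hargrove_indicators(
            tab["mother_edu"], tab["father_edu"], tab["moved_financial"],
            tab["ses3"], tab["father_occ"])
        el = res.eligible
        assert 50 < el.sum() < len(tab) - 50
        for latent in ("latent_financial", "latent_social", "latent_human"):
            assert tab[latent][el].mean() > tab[latent][~el].mean(), latent


class TestCESD:
    def make(self, neg, pos):
        data = {f"cesd{i}": [v] for i, v in enumerate(neg, start=1)}
        data.update({f"cesd{i}": [v] for i, v in enumerate(pos, start=7)})
        return pd.DataFrame(data)

    def test_all_yes_scores_six(self):
        assert idx.score_cesd(self.make([1] * 6, [1] * 2))[0] == 6.0

    def test_floor_and_ceiling(self):
        assert idx.score_cesd(self.make([0] * 6, [1] * 2))[0] == 0.0
        assert idx.score_cesd(self.make([1] * 6, [0] * 2))[0] == 8.0

    def test_missing_item_drops_score_by_default(self):
        df = self.make([1, 1, np.nan, 0, 0, 0], [1, 1])
        assert np.isnan(idx.score_cesd(df)[0])
        prorated = idx.score_cesd(df, require_complete=False)[0]
        assert prorated == pytest.approx(2.0 / 7.0 * 8.0)

    def test_non_binary_rejected(self):
        with pytest.raises(idx.CodingError, match="non-binary"):
            idx.score_cesd(self.make([2, 1, 1, 0, 0, 0], [1, 1]))

    @given(st.lists(st.integers(0, 1), min_size=8, max_size=8))
    @settings(max_examples=40, deadline=None)
    def test_range_and_keying(self, items):
        score = idx.score_cesd(self.make(items[:6], items[6:]))[0]
        assert 0.0 <= score <= 8.0
        assert score == sum(items[:6]) + (1 - items[6]) + (1 - items[7])
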
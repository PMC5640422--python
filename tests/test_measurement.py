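"""Ordinal measurement estimators: thresholds, polychorics, factor
extraction and rotation, fit indices, structure selection, MAP scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multivariate_normal, norm

from childses import cohort as coh
from childses import measurement as mm


def grid_polychoric_oracle(counts, step=1e-4):
    """Brute-force ML grid search for the polychoric correlation of a
    contingency table, with thresholds fixed at the margin quantiles.

    Independent of the package's optimizer: cell probabilities come from a
    fresh bivariate-normal CDF evaluation, and the maximizer is found by a
    coarse scan refined to ``step`` resolution (the profile likelihood in
    rho is smooth, so refinement around the coarse optimum is exact to the
    grid resolution)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    tau_x = norm.ppf(np.cumsum(counts.sum(axis=1))[:-1] / n)
    tau_y = norm.ppf(np.cumsum(counts.sum(axis=0))[:-1] / n)
    ax = np.concatenate(([-20.0], tau_x, [20.0]))
    ay = np.concatenate(([-20.0], tau_y, [20.0]))

    def loglik(rho):
        cov = [[1.0, rho], [rho, 1.0]]
        mvn = multivariate_normal(mean=[0, 0], cov=cov, allow_singular=True)
        cdf = mvn.cdf(np.array([[x, y] for x in ax for y in ay]))
        cdf = cdf.reshape(len(ax), len(ay))
        cells = np.clip(cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1],
                        1e-12, 1.0)
        return (counts * np.log(cells)).sum()

    coarse = np.arange(-0.99, 0.9901, 2e-3)
    lls = np.array([loglik(r) for r in coarse])
    best = coarse[np.argmax(lls)]
    fine = np.arange(max(-0.99, best - 3e-3), min(0.99, best + 3e-3) + step / 2, step)
    lls = np.array([loglik(r) for r in fine])
    return float(fine[np.argmax(lls)])


def counts_to_columns(counts, rng=None):
    counts = np.asarray(counts, dtype=int)
    xs, ys = [], []
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            xs += [i] * counts[i, j]
            ys += [j] * counts[i, j]
    return np.array(xs, dtype=float), np.array(ys, dtype=float)


class TestThresholds:
    def test_binary_symmetric_gives_zero(self):
        tau = mm.estimate_thresholds([0, 0, 1, 1] * 10)
        assert tau == pytest.approx([0.0], abs=1e-12)

    def test_quartile_proportions(self):
        col = [1] * 25 + [2] * 50 + [3] * 25
        tau = mm.estimate_thresholds(col)
        assert tau == pytest.approx([-0.6745, 0.6745], abs=1e-4)

    def test_empty_category_rejected_naming_it(self):
        col = [1] * 10 + [2] * 10 + [4] * 10
        with pytest.raises(mm.MeasurementError, match=r"3"):
            mm.estimate_thresholds(col, levels=[1, 2, 3, 4], name="q")

    def test_all_missing_rejected(self):
        with pytest.raises(mm.MeasurementError, match="myitem"):
            mm.estimate_thresholds([np.nan, mm.NONRESPONSE], name="myitem")

    @given(st.lists(st.integers(1, 4), min_size=30, max_size=120))
    @settings(max_examples=30, deadline=None)
    def test_strictly_increasing(self, codes):
        arr = np.array(codes, dtype=float)
        if len(np.unique(arr)) < 2:
            return
        tau = mm.estimate_thresholds(arr)
        assert np.all(np.diff(tau) > 0)


class TestPolychoric:
    def test_independence_table(self):
        x, y = counts_to_columns([[25, 25], [25, 25]])
        rho, n = mm.polychoric_correlation(x, y)
        assert n == 100
        assert rho == pytest.approx(0.0, abs=1e-4)

    def test_perfect_concordance_clamped(self):
        x, y = counts_to_columns([[50, 0], [0, 50]])
        rho, _ = mm.polychoric_correlation(x, y)
        assert rho == pytest.approx(0.999)

    def test_matches_grid_oracle(self):
        x, y = counts_to_columns([[40, 10], [10, 40]])
        rho, _ = mm.polychoric_correlation(x, y)
        assert rho == pytest.approx(grid_polychoric_oracle([[40, 10], [10, 40]]),
                                    abs=1e-3)

    def test_invariant_to_reversing_both_codings(self):
        x, y = counts_to_columns([[30, 12, 5], [9, 25, 14], [4, 12, 33]])
        rho1, _ = mm.polychoric_correlation(x, y)
        rho2, _ = mm.polychoric_correlation(2 - x, 2 - y)
        assert rho1 == pytest.approx(rho2, abs=1e-5)

    def test_degenerate_table_flagged(self):
        x = np.zeros(50)
        y = np.zeros(50)
        with pytest.raises(mm.MeasurementError, match="constant|degenerate"):
            mm.polychoric_correlation(x, y)

    def test_pairwise_floor(self):
        with pytest.raises(mm.MeasurementError, match="below floor"):
            mm.polychoric_correlation([0, 1] * 3, [0, 1] * 3)


class TestCorrelationMatrix:
    def test_independent_items_small_offdiagonals(self, rng):
        n = 10000
        tab = pd.DataFrame({
            "a": rng.integers(0, 2, n).astype(float),
            "b": rng.integers(1, 4, n).astype(float),
            "c": rng.integers(1, 5, n).astype(float),
        })
        schemas = [mm.ItemSchema("a", (0, 1), "f"),
                   mm.ItemSchema("b", (1, 2, 3), "f"),
                   mm.ItemSchema("c", (1, 2, 3, 4), "f")]
        pc = mm.build_correlation_matrix(tab, schemas)
        off = pc.rho[np.triu_indices(3, k=1)]
        assert np.abs(off).max() < 0.05
        assert np.allclose(pc.rho, pc.rho.T)
        assert np.allclose(np.diag(pc.rho), 1.0)

    def test_constant_item_error_names_it(self, rng):
        tab = pd.DataFrame({"a": rng.integers(0, 2, 100).astype(float),
                            "flat": np.ones(100)})
        schemas = [mm.ItemSchema("a", (0, 1), "f"),
                   mm.ItemSchema("flat", (0, 1), "f")]
        with pytest.raises(mm.MeasurementError, match="flat"):
            mm.build_correlation_matrix(tab, schemas)

    def test_nearest_psd_repairs_indefinite(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        fixed = mm.nearest_psd(bad)
        assert np.linalg.eigvalsh(fixed).min() >= 0
        assert np.allclose(np.diag(fixed), 1.0)


def population_loadings(p_per_factor=(4, 4), loading=0.7, phi=0.4):
    """Exact correlation matrix of a two-block congeneric structure."""
    p = sum(p_per_factor)
    L = np.zeros((p, 2))
    L[:p_per_factor[0], 0] = loading
    L[p_per_factor[0]:, 1] = loading
    Phi = np.array([[1.0, phi], [phi, 1.0]])
    R = L @ Phi @ L.T
    np.fill_diagonal(R, 1.0)
    return R, L, Phi


class TestEFA:
    def test_one_factor_recovery_from_simulated_items(self, rng):
        n, lam = 5000, 0.7
        f = rng.standard_normal(n)
        tab = pd.DataFrame()
        schemas = []
        for j in range(5):
            y = lam * f + np.sqrt(1 - lam ** 2) * rng.standard_normal(n)
            tab[f"i{j}"] = (y > 0).astype(float) + (y > 0.8)
            schemas.append(mm.ItemSchema(f"i{j}", (0, 1, 2), "f"))
        pc = mm.build_correlation_matrix(tab, schemas)
        sol = mm.fit_efa(pc, 1)
        assert np.all(np.abs(np.abs(sol.loadings[:, 0]) - lam) < 0.10)

    def test_perfect_two_block_structure_rotates_clean(self):
        R, L_true, Phi_true = population_loadings()
        sol = mm.fit_efa(R, 2, effective_n=5000)
        cross = np.min(np.abs(sol.loadings), axis=1)
        assert cross.max() < 0.1
        assert abs(abs(sol.phi[0, 1]) - 0.4) < 0.05
        # exact structure: perfect fit statistics
        assert sol.chi2 == pytest.approx(0.0, abs=1e-6)
        assert sol.cfi == 1.0

    def test_rotation_preserves_fitted_correlation(self):
        R, _, _ = population_loadings(loading=0.6, phi=0.5)
        sol = mm.fit_efa(R, 2, effective_n=1000)
        A, _ = mm._uls_extract(R, 2)
        assert np.allclose(sol.loadings @ sol.phi @ sol.loadings.T,
                           A @ A.T, atol=1e-8)

    def test_inadmissible_factor_count_rejected(self):
        R = np.eye(3)
        with pytest.raises(mm.MeasurementError, match="inadmissible"):
            mm.fit_efa(R, 2, effective_n=100)


class TestFitIndices:
    def test_perfect_fit_limit(self):
        rmsea, cfi = mm.fit_indices(5.0, 10, 500.0, 15, 1000)
        assert rmsea == 0.0 and cfi == 1.0

    def test_formula_value(self):
        rmsea, _ = mm.fit_indices(20.0, 10, 500.0, 15, 1001)
        assert rmsea == pytest.approx(np.sqrt(10.0 / (10 * 1000)), abs=1e-12)

    def test_saturated_model_flagged(self):
        rmsea, cfi = mm.fit_indices(0.0, 0, 100.0, 10, 500)
        assert np.isnan(rmsea) and cfi == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(mm.MeasurementError):
            mm.fit_indices(5.0, 10, 100.0, 5, 1000)   # df_null < df

    @given(st.floats(0.0, 500.0), st.integers(1, 30), st.floats(0.0, 1000.0))
    @settings(max_examples=50, deadline=None)
    def test_clamped_ranges(self, chi2, df, chi2_null):
        rmsea, cfi = mm.fit_indices(chi2, df, chi2_null, 30, 200)
        assert rmsea >= 0.0
        assert 0.0 <= cfi <= 1.0


def _solution(n_factors, loadings, rmsea, cfi, names=None, eigenvalues=None):
    p = loadings.shape[0]
    return mm.FactorSolution(
        item_names=names or [f"i{j}" for j in range(p)],
        loadings=loadings, phi=np.eye(n_factors),
        eigenvalues=(eigenvalues if eigenvalues is not None
                     else np.linspace(2.5, 0.3, p)),
        chi2=10.0, df=5, chi2_null=500.0, df_null=10, effective_n=1000,
        rmsea=rmsea, cfi=cfi, rotation_value=0.0, thresholds={})


class TestSelectStructure:
    def test_loading_rule_boundary(self):
        L = np.array([[0.8], [0.31], [0.29]])
        sel = mm.select_structure([_solution(1, L, 0.01, 0.99)])
        assert "i1" in sel.retained_items          # loading 0.31: retained
        assert sel.dropped_items == ["i2"]         # loading 0.29: dropped

    def test_smallest_adequate_factor_count_chosen(self):
        one = _solution(1, np.full((6, 1), 0.5), 0.15, 0.80)
        two = _solution(2, np.full((6, 2), 0.5), 0.02, 0.99)
        three = _solution(3, np.full((6, 3), 0.5), 0.01, 1.0)
        sel = mm.select_structure([three, one, two])
        assert sel.solution.n_factors == 2
        assert sel.met_fit_rules

    def test_no_candidate_fits_flags_failure(self):
        one = _solution(1, np.full((6, 1), 0.5), 0.20, 0.70)
        two = _solution(2, np.full((6, 2), 0.5), 0.15, 0.80)
        sel = mm.select_structure([one, two])
        assert not sel.met_fit_rules


def grid_map_oracle(solution, codes_by_item, schemas, coarse=0.05, fine=0.01):
    """Independent grid search for the MAP factor score of one response
    pattern: evaluates the probit-threshold posterior on a lattice over
    [-4, 4]^m, then refines around the coarse optimum to ``fine`` resolution
    (the posterior is log-concave, so the refinement loses nothing)."""
    names = solution.item_names
    L = solution.loadings
    m = L.shape[1]
    phi_inv = np.linalg.inv(solution.phi)
    schema_by = {s.name: s for s in schemas}

    def logpost(etas):
        # etas: (k, m)
        lp = -0.5 * np.einsum("ij,jk,ik->i", etas, phi_inv, etas)
        for name, code in codes_by_item.items():
            i = names.index(name)
            lam = L[i]
            psi = np.sqrt(max(1.0 - lam @ solution.phi @ lam, 0.02))
            levels = list(schema_by[name].levels)
            pos = levels.index(code)
            edges = np.concatenate(([-np.inf], solution.thresholds[name], [np.inf]))
            t = etas @ lam
            pr = norm.cdf((edges[pos + 1] - t) / psi) - norm.cdf((edges[pos] - t) / psi)
            lp += np.log(np.clip(pr, 1e-300, None))
        return lp

    axes = [np.arange(-4.0, 4.0 + coarse / 2, coarse)] * m
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, m)
    best = mesh[np.argmax(logpost(mesh))]
    axes = [np.arange(b - 1.5 * coarse, b + 1.5 * coarse + fine / 2, fine)
            for b in best]
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, m)
    return mesh[np.argmax(logpost(mesh))]


@pytest.fixture(scope="module")
def fitted_csc(clean_cohort):
    spec, tab = clean_cohort
    schemas = coh.csc_schemas()
    pc = mm.build_correlation_matrix(coh.recode_never_lived(tab), schemas)
    return mm.fit_efa(pc, 2), schemas, tab


class TestScoring:
    def test_all_items_missing_receive_no_score(self, fitted_csc):
        sol, schemas, _ = fitted_csc
        tab = pd.DataFrame({"respondent_id": [1, 2]})
        for s in schemas:
            tab[s.name] = [mm.NOT_ADMINISTERED, s.levels[0]]
        scores = mm.score_respondents(sol, tab, schemas)
        assert scores["respondent_id"].tolist() == [2]

    def test_zero_loading_single_item_gives_prior_mean(self):
        sol = mm.FactorSolution(
            item_names=["a"], loadings=np.array([[0.0]]), phi=np.eye(1),
            eigenvalues=np.array([1.0]), chi2=0, df=0, chi2_null=0, df_null=0,
            effective_n=100, rmsea=0.0, cfi=1.0, rotation_value=0.0,
            thresholds={"a": np.array([0.0])})
        tab = pd.DataFrame({"respondent_id": [1], "a": [1.0]})
        scores = mm.score_respondents(sol, tab, [mm.ItemSchema("a", (0, 1), "f")])
        assert scores["eta1"].iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_map_matches_grid_oracle_sample(self, fitted_csc, rng):
        """Spot check here (the full battery runs in the acceptance suite)."""
        sol, schemas, tab = fitted_csc
        rows = rng.choice(len(tab), 10, replace=False)
        sub = tab.iloc[rows].reset_index(drop=True)
        scores = mm.score_respondents(sol, sub, schemas)
        for k in range(len(sub)):
            codes = {s.name: sub[s.name].iloc[k] for s in schemas}
            oracle = grid_map_oracle(sol, codes, schemas)
            got = scores[["eta1", "eta2"]].iloc[k].to_numpy()
            assert np.all(np.abs(got - oracle) <= 0.02), (k, got, oracle)

    def test_monotone_in_response_level(self, fitted_csc):
        """For a positive loading, a higher category can only raise the MAP
        score on that item's factor."""
        sol, schemas, _ = fitted_csc
        item = "mom_teach"
        i = sol.item_names.index(item)
        k = int(np.argmax(np.abs(sol.loadings[i])))
        assert sol.loadings[i, k] > 0
        etas = []
        for level in (1.0, 2.0, 3.0, 4.0):
            tab = pd.DataFrame({"respondent_id": [1], item: [level]})
            for s in schemas:
                if s.name != item:
                    tab[s.name] = mm.NOT_ADMINISTERED
            sc = mm.score_respondents(sol, tab, schemas)
            etas.append(sc[f"eta{k+1}"].iloc[0])
        assert np.all(np.diff(etas) >= -1e-9)


class TestScaleConstruction:
    def test_two_point_zscore(self):
        scores = pd.DataFrame({"respondent_id": [1, 2], "eta1": [1.0, 3.0]})
        scale = mm.build_scale(scores, ["eta1"])
        assert scale.tolist() == pytest.approx([-1.0, 1.0])

    def test_location_invariance(self, rng):
        e = rng.standard_normal(50)
        a = mm.build_scale(pd.DataFrame({"eta1": e}), ["eta1"])
        b = mm.build_scale(pd.DataFrame({"eta1": e + 7.3}), ["eta1"])
        assert np.allclose(a, b)

    def test_orientation_reflects_member_factor(self, rng):
        e1, e2 = rng.standard_normal(50), rng.standard_normal(50)
        df = pd.DataFrame({"a": e1, "b": e2})
        direct = mm.build_scale(df, ["a", "b"], orientation=[1, -1])
        manual = mm.zscore(e1 - e2)
        assert np.allclose(direct, manual)

    def test_zero_variance_rejected(self):
        with pytest.raises(mm.MeasurementError, match="zero variance"):
            mm.build_scale(pd.DataFrame({"eta1": [1.0, 1.0, 1.0]}), ["eta1"])
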
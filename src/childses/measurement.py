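"""Ordinal measurement models for the childhood capital scales.

Retrospective childhood items are binary or ordered-categorical, so the
measurement model is the underlying-normal (probit threshold) factor model:
each item i has a latent response ``y*_i = lambda_i' eta + e_i`` with unit
marginal variance, observed as the category whose threshold interval contains
``y*_i``.  Estimation follows the standard two-step route for categorical
data: item thresholds from the univariate margins, pairwise polychoric
correlations by one-dimensional maximum likelihood with thresholds fixed,
then unweighted least-squares factor extraction from the polychoric matrix
with oblique geomin rotation.  Respondent-level factor scores are
maximum-a-posteriori estimates under the fitted model, computed from
whichever items a respondent answered (full-information scoring); only
respondents with no observed scale item go unscored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import norm

logger = logging.getLogger("childses.measurement")

#: sentinel codes for the three semantic causes of missingness
NOT_ADMINISTERED = -8.0
NONRESPONSE = -9.0
NEVER_LIVED = -7.0
MISSING_CODES = (NEVER_LIVED, NOT_ADMINISTERED, NONRESPONSE)

RMSEA_RULE = 0.07   # acceptable absolute fit: RMSEA below this
CFI_RULE = 0.95     # acceptable comparative fit: CFI at or above this
LOADING_RULE = 0.3  # items retained when max |rotated loading| exceeds this
GEOMIN_EPS = 0.01


class MeasurementError(ValueError):
    """Raised when an item or table violates an estimator precondition."""


def is_missing(values: np.ndarray) -> np.ndarray:
    """Boolean mask of missing entries (NaN or any sentinel code)."""
    arr = np.asarray(values, dtype=float)
    mask = np.isnan(arr)
    for code in MISSING_CODES:
        mask |= arr == code
    return mask


@dataclass(frozen=True)
class ItemSchema:
    """Declared measurement properties of one coded item.

    ``levels`` is the ordered tuple of valid codes (binary items use
    ``(0, 1)``); ``factor`` is the candidate factor assignment used for
    scale membership and for labelling rotated factors.
    """

    name: str
    levels: tuple
    factor: str
    missing_codes: tuple = MISSING_CODES

    def __post_init__(self):
        if len(self.levels) < 2:
            raise MeasurementError(f"item {self.name!r}: needs >= 2 levels")
        if any(l in self.missing_codes for l in self.levels):
            raise MeasurementError(
                f"item {self.name!r}: level set overlaps missing codes")
        if list(self.levels) != sorted(self.levels):
            raise MeasurementError(f"item {self.name!r}: levels not ordered")


# ---------------------------------------------------------------------------
# step 1: thresholds from univariate margins
# ---------------------------------------------------------------------------

def estimate_thresholds(item_column, levels=None, name: str = "item") -> np.ndarray:
    """Threshold vector tau from the marginal category proportions.

    tau_c is the standard-normal quantile of the cumulative proportion at or
    below category c; length L-1, strictly increasing.  An all-missing column
    or an empty category is rejected (an empty category makes a threshold
    coincide with its neighbour, which breaks the probit model).
    """
    arr = np.asarray(item_column, dtype=float)
    arr = arr[~is_missing(arr)]
    if arr.size == 0:
        raise MeasurementError(f"item {name!r}: all values missing")
    if levels is None:
        levels = np.unique(arr)
    levels = np.asarray(levels, dtype=float)
    counts = np.array([(arr == l).sum() for l in levels])
    if (counts == 0).any():
        empty = levels[counts == 0]
        raise MeasurementError(
            f"item {name!r}: empty category {empty.tolist()} "
            f"among declared levels {levels.tolist()}")
    if len(levels) < 2:
        raise MeasurementError(f"item {name!r}: fewer than 2 observed categories")
    cum = np.cumsum(counts)[:-1] / arr.size
    tau = norm.ppf(cum)
    return tau


# ---------------------------------------------------------------------------
# step 2: pairwise polychoric correlation
# ---------------------------------------------------------------------------

def _cell_probabilities(rho: float, tau_x: np.ndarray, tau_y: np.ndarray) -> np.ndarray:
    """Bivariate-normal rectangle probabilities for every contingency cell."""
    ax = np.concatenate(([-np.inf], tau_x, [np.inf]))
    ay = np.concatenate(([-np.inf], tau_y, [np.inf]))
    # CDF on the finite grid; +/-inf rows and columns are analytic
    big = 7.5
    gx = np.clip(ax, -big, big)
    gy = np.clip(ay, -big, big)
    pts = np.array([[x, y] for x in gx for y in gy])
    cov = np.array([[1.0, rho], [rho, 1.0]])
    cdf = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov, allow_singular=True).cdf(pts)
    cdf = cdf.reshape(len(gx), len(gy))
    cells = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
    return np.clip(cells, 1e-12, 1.0)


def _table_loglik(rho: float, counts: np.ndarray, tau_x: np.ndarray,
                  tau_y: np.ndarray) -> float:
    return float((counts * np.log(_cell_probabilities(rho, tau_x, tau_y))).sum())


def polychoric_correlation(x, y, levels_x=None, levels_y=None,
                           name_x: str = "x", name_y: str = "y",
                           min_n: int = 10):
    """Two-step polychoric correlation of two coded items.

    Returns ``(rho, n_pair)``.  Thresholds come from the pairwise-complete
    margins; rho maximizes the contingency-table likelihood and is clamped to
    [-0.999, 0.999].  A degenerate table (a single nonempty cell) has no
    defined correlation and is rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~is_missing(x) & ~is_missing(y)
    x, y = x[keep], y[keep]
    if x.size < min_n:
        raise MeasurementError(
            f"pair ({name_x!r}, {name_y!r}): pairwise n={x.size} below floor {min_n}")
    # categories actually present in the pairwise-complete subset
    lx = np.unique(x) if levels_x is None else np.asarray(
        [l for l in levels_x if (x == l).any()], dtype=float)
    ly = np.unique(y) if levels_y is None else np.asarray(
        [l for l in levels_y if (y == l).any()], dtype=float)
    if len(lx) < 2 or len(ly) < 2:
        raise MeasurementError(
            f"pair ({name_x!r}, {name_y!r}): an item is constant on the "
            "pairwise-complete subset")
    counts = np.zeros((len(lx), len(ly)))
    for i, lv in enumerate(lx):
        for j, lw in enumerate(ly):
            counts[i, j] = ((x == lv) & (y == lw)).sum()
    if (counts > 0).sum() < 2:
        raise MeasurementError(
            f"pair ({name_x!r}, {name_y!r}): degenerate table (one nonempty cell)")
    tau_x = estimate_thresholds(x, levels=lx, name=name_x)
    tau_y = estimate_thresholds(y, levels=ly, name=name_y)
    res = optimize.minimize_scalar(
        lambda r: -_table_loglik(r, counts, tau_x, tau_y),
        bounds=(-0.999, 0.999), method="bounded",
        options={"xatol": 1e-6})
    rho = float(np.clip(res.x, -0.999, 0.999))
    # a perfectly concordant/discordant table pushes the optimum to the clamp
    if abs(rho) > 0.9985:
        rho = float(np.sign(rho) * 0.999)
    return rho, int(x.size)


@dataclass
class PolychoricMatrix:
    """Pairwise polychoric correlation matrix with per-item thresholds."""

    item_names: list
    rho: np.ndarray              # (p, p), symmetric, unit diagonal
    thresholds: dict             # name -> tau vector
    pair_n: np.ndarray           # (p, p) pairwise-complete counts
    repair_delta: float = 0.0    # Frobenius distance moved by the PSD repair
    low_n_pairs: list = field(default_factory=list)
    undefined_pairs: list = field(default_factory=list)

    @property
    def effective_n(self) -> int:
        """Mean pairwise-complete count: the pair-weighted chi-square grows
        as (mean pairwise n) times the weighted discrepancy, so this is the
        sample size on the scale the fit indices expect."""
        off = self.pair_n[np.triu_indices(len(self.item_names), k=1)]
        return int(np.mean(off))


def nearest_psd(matrix: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Nearest positive-semidefinite correlation matrix by eigenvalue clipping."""
    sym = (matrix + matrix.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= eps:
        return sym
    vals = np.clip(vals, eps, None)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def build_correlation_matrix(table: pd.DataFrame, schemas,
                             pair_n_floor: int = 30) -> PolychoricMatrix:
    """Assemble the pairwise-complete polychoric matrix for a set of items.

    Pairs whose complete-observation count falls below ``pair_n_floor`` are
    recorded in ``low_n_pairs`` (the matrix is still returned).  If the
    assembled matrix is indefinite it is repaired to the nearest PSD
    correlation matrix and the repair magnitude logged.
    """
    if len(schemas) < 2:
        raise MeasurementError("need at least 2 items")
    names = [s.name for s in schemas]
    p = len(names)
    rho = np.eye(p)
    pair_n = np.zeros((p, p), dtype=int)
    thresholds = {}
    for s in schemas:
        thresholds[s.name] = estimate_thresholds(
            table[s.name], levels=None, name=s.name)
        col = np.asarray(table[s.name], dtype=float)
        pair_n[names.index(s.name), names.index(s.name)] = int((~is_missing(col)).sum())
    low = []
    undefined = []
    for i in range(p):
        for j in range(i + 1, p):
            try:
                r, n_ij = polychoric_correlation(
                    table[names[i]], table[names[j]],
                    levels_x=schemas[i].levels, levels_y=schemas[j].levels,
                    name_x=names[i], name_y=names[j], min_n=10)
            except MeasurementError as exc:
                # a degenerate or too-small pairwise table leaves that
                # correlation undefined; the matrix is still returned
                logger.warning("pair (%s, %s): correlation undefined (%s)",
                               names[i], names[j], exc)
                undefined.append((names[i], names[j]))
                r, n_ij = 0.0, 0
            rho[i, j] = rho[j, i] = r
            pair_n[i, j] = pair_n[j, i] = n_ij
            if n_ij < pair_n_floor:
                low.append((names[i], names[j], n_ij))
    repaired = nearest_psd(rho)
    delta = float(np.linalg.norm(repaired - rho))
    if delta > 1e-10:
        logger.info("polychoric matrix repaired to nearest PSD (Frobenius delta %.4g)", delta)
    for a, b, n_ij in low:
        logger.warning("pair (%s, %s): pairwise n=%d below floor %d", a, b, n_ij, pair_n_floor)
    return PolychoricMatrix(item_names=names, rho=repaired, thresholds=thresholds,
                            pair_n=pair_n, repair_delta=delta, low_n_pairs=low,
                            undefined_pairs=undefined)


# ---------------------------------------------------------------------------
# factor extraction, geomin rotation, fit indices
# ---------------------------------------------------------------------------

@dataclass
class FactorSolution:
    """A fitted exploratory measurement model on a polychoric matrix."""

    item_names: list
    loadings: np.ndarray         # (p, m) rotated pattern matrix
    phi: np.ndarray              # (m, m) factor correlations
    eigenvalues: np.ndarray      # of the input correlation matrix
    chi2: float
    df: int
    chi2_null: float
    df_null: int
    effective_n: int
    rmsea: float
    cfi: float
    rotation_value: float        # geomin criterion at the solution
    thresholds: dict             # name -> tau, carried for scoring
    heywood: bool = False
    factor_labels: list = field(default_factory=list)

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def fitted_correlation(self) -> np.ndarray:
        """Model-implied correlation matrix (unit diagonal)."""
        sigma = self.loadings @ self.phi @ self.loadings.T
        np.fill_diagonal(sigma, 1.0)
        return sigma


def _wls_extract(R: np.ndarray, m: int, weights: np.ndarray):
    """Weighted least-squares extraction: minimize
    sum_{i<j} w_ij (r_ij - (LL')_ij)^2 over unrotated loadings L.

    Used when the correlation matrix is assembled pairwise-complete with
    very unequal pairwise ns, so each correlation is weighted by its own
    precision rather than letting the noisiest pairs steer the solution.
    Starts from the unweighted solution.  Returns (L, heywood flag).
    """
    p = R.shape[0]
    W = weights.astype(float).copy()
    np.fill_diagonal(W, 0.0)
    W /= max(W.max(), 1.0)
    A0, _ = _uls_extract(R, m)

    def objective(flat):
        L = flat.reshape(p, m)
        E = R - L @ L.T
        np.fill_diagonal(E, 0.0)
        f = 0.5 * float((W * E ** 2).sum())
        grad = -2.0 * (W * E) @ L
        return f, grad.ravel()

    res = optimize.minimize(objective, A0.ravel(), jac=True, method="L-BFGS-B",
                            options={"maxiter": 500})
    L = res.x.reshape(p, m)
    h2 = (L ** 2).sum(axis=1)
    heywood = bool(h2.max() > 1.0)
    if heywood:
        L = L * np.minimum(1.0, np.sqrt(0.9995 / h2))[:, None]
    # canonical orientation: principal-axis-like ordering
    _, sv, vt = np.linalg.svd(L, full_matrices=False)
    L = L @ vt.T
    return L, heywood


def _uls_extract(R: np.ndarray, m: int, max_iter: int = 1000, tol: float = 1e-9):
    """Iterated principal-axis (ULS) extraction of m factors.

    Communalities start at squared multiple correlations and are refined
    until the reduced-matrix eigendecomposition is self-consistent.  Returns
    (unrotated loadings, heywood flag).
    """
    p = R.shape[0]
    try:
        Rinv = np.linalg.inv(R)
        h2 = 1.0 - 1.0 / np.diag(Rinv)
    except np.linalg.LinAlgError:
        h2 = np.full(p, 0.5)
    h2 = np.clip(h2, 0.05, 0.995)
    heywood = False
    for _ in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        vals, vecs = np.linalg.eigh(Rr)
        order = np.argsort(vals)[::-1][:m]
        lam = vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))
        new_h2 = (lam ** 2).sum(axis=1)
        if new_h2.max() > 1.0:
            heywood = True
            new_h2 = np.clip(new_h2, None, 0.9995)
        if np.max(np.abs(new_h2 - h2)) < tol:
            h2 = new_h2
            break
        h2 = new_h2
    Rr = R.copy()
    np.fill_diagonal(Rr, h2)
    vals, vecs = np.linalg.eigh(Rr)
    order = np.argsort(vals)[::-1][:m]
    lam = vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))
    return lam, heywood


def geomin_criterion(L: np.ndarray, eps: float = GEOMIN_EPS):
    """Geomin value and gradient: sum over items of the geometric mean of
    (lambda^2 + eps) across factors."""
    m = L.shape[1]
    L2 = L ** 2 + eps
    gmean = np.exp(np.log(L2).sum(axis=1) / m)
    q = float(gmean.sum())
    grad = (2.0 / m) * (L / L2) * gmean[:, None]
    return q, grad


def _rotate_geomin_oblique(A: np.ndarray, eps: float = GEOMIN_EPS,
                           n_starts: int = 10, max_iter: int = 500,
                           tol: float = 1e-7, seed: int = 0):
    """Oblique geomin rotation by gradient projection.

    Multiple random starting rotations are used because the geomin surface
    has local minima; the best criterion value wins.  Returns
    (rotated loadings, phi, criterion value).
    """
    m = A.shape[1]
    rng = np.random.default_rng(seed)
    starts = [np.eye(m)]
    for _ in range(n_starts - 1):
        X = rng.standard_normal((m, m))
        X /= np.sqrt((X ** 2).sum(axis=0))
        starts.append(X)
    best = None
    for T0 in starts:
        T = T0.copy()
        al = 1.0
        Ti = np.linalg.inv(T)
        L = A @ Ti.T
        f, Gq = geomin_criterion(L, eps)
        G = -(L.T @ Gq @ Ti).T
        for _ in range(max_iter):
            Gp = G - T * (T * G).sum(axis=0)
            s = np.sqrt((Gp ** 2).sum())
            if s < tol:
                break
            al *= 2.0
            for _ in range(30):
                X = T - al * Gp
                v = 1.0 / np.sqrt((X ** 2).sum(axis=0))
                Tt = X * v
                Ti = np.linalg.inv(Tt)
                Lt = A @ Ti.T
                ft, Gqt = geomin_criterion(Lt, eps)
                if ft < f - 0.5 * s ** 2 * al:
                    break
                al /= 2.0
            T, f = Tt, ft
            G = -(Lt.T @ Gqt @ Ti).T
        Ti = np.linalg.inv(T)
        L = A @ Ti.T
        fval, _ = geomin_criterion(L, eps)
        phi = T.T @ T
        if best is None or fval < best[2]:
            best = (L, phi, fval)
    L, phi, fval = best
    # orient each factor so its dominant loadings are positive
    signs = np.sign(L.sum(axis=0))
    signs[signs == 0] = 1.0
    L = L * signs
    phi = phi * np.outer(signs, signs)
    np.fill_diagonal(phi, 1.0)
    return L, phi, fval


def fit_indices(chi2: float, df: int, chi2_null: float, df_null: int,
                effective_n: int):
    """RMSEA and CFI from model and null chi-square statistics.

    RMSEA = sqrt(max(chi2 - df, 0) / (df (N-1))); undefined (NaN) for a
    saturated model (df = 0).  CFI = 1 - max(chi2-df,0)/max(chi20-df0,
    chi2-df, 0), clamped to [0, 1].
    """
    if df < 0 or df_null < df or effective_n < 2:
        raise MeasurementError(
            f"fit_indices: invalid inputs df={df}, df_null={df_null}, n={effective_n}")
    num = max(chi2 - df, 0.0)
    if df == 0:
        logger.warning("fit_indices: saturated model (df=0), RMSEA undefined")
        rmsea = float("nan")
    else:
        rmsea = float(np.sqrt(num / (df * (effective_n - 1))))
    denom = max(chi2_null - df_null, chi2 - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - num / denom
    return rmsea, float(np.clip(cfi, 0.0, 1.0))


def fit_efa(corr, n_factors: int, effective_n: int | None = None,
            thresholds: dict | None = None, item_names=None,
            rotation_seed: int = 0) -> FactorSolution:
    """Exploratory factor model: ULS extraction plus oblique geomin rotation.

    ``corr`` may be a PolychoricMatrix or a plain correlation ndarray (in
    which case ``effective_n`` and optionally ``thresholds``/``item_names``
    must be given).  chi2 = (N-1) * discrepancy, where the discrepancy is the
    sum of squared off-diagonal residuals; df = p(p-1)/2 - p*m (pm free
    loading/correlation parameters once rotational indeterminacy is spent on
    the factor correlations); null model is independence.
    """
    pair_n = None
    if isinstance(corr, PolychoricMatrix):
        R = corr.rho
        item_names = list(corr.item_names)
        thresholds = corr.thresholds
        pair_n = corr.pair_n
        if effective_n is None:
            effective_n = corr.effective_n
    else:
        R = np.asarray(corr, dtype=float)
        if effective_n is None:
            raise MeasurementError("effective_n required with a raw matrix")
        if item_names is None:
            item_names = [f"item{i}" for i in range(R.shape[0])]
        thresholds = thresholds or {}
    p = R.shape[0]
    if n_factors < 1:
        raise MeasurementError("n_factors must be >= 1")
    df = p * (p - 1) // 2 - p * n_factors
    if df < 0:
        raise MeasurementError(
            f"n_factors={n_factors} inadmissible for {p} items (df would be {df})")
    eigenvalues = np.sort(np.linalg.eigvalsh(R))[::-1]
    if pair_n is not None and pair_n.max() > 0:
        A, heywood = _wls_extract(R, n_factors, pair_n)
    else:
        A, heywood = _uls_extract(R, n_factors)
    if n_factors >= 2:
        L, phi, fval = _rotate_geomin_oblique(A, seed=rotation_seed)
    else:
        L = A.copy()
        sign = np.sign(L.sum()) or 1.0
        L *= sign
        phi = np.eye(1)
        fval, _ = geomin_criterion(L)
    sigma = L @ phi @ L.T
    resid = R - sigma
    iu = np.triu_indices(p, k=1)
    if pair_n is not None:
        # pairwise-complete assembly: weight each residual by its own
        # sample size (the unweighted statistic lets the noisiest, smallest
        # module pairs dominate); with equal pairwise ns this reduces to
        # (n - 1) times the plain discrepancy
        w = np.maximum(pair_n[iu] - 1, 0)
        chi2 = float((w * resid[iu] ** 2).sum())
        chi2_null = float((w * R[iu] ** 2).sum())
    else:
        discrepancy = float((resid[iu] ** 2).sum())
        chi2 = (effective_n - 1) * discrepancy
        chi2_null = (effective_n - 1) * float((R[iu] ** 2).sum())
    df_null = p * (p - 1) // 2
    rmsea, cfi = fit_indices(chi2, df, chi2_null, df_null, effective_n)
    if heywood:
        logger.warning("fit_efa: Heywood case (communality > 1) encountered")
    return FactorSolution(
        item_names=item_names, loadings=L, phi=phi, eigenvalues=eigenvalues,
        chi2=chi2, df=df, chi2_null=chi2_null, df_null=df_null,
        effective_n=int(effective_n), rmsea=rmsea, cfi=cfi,
        rotation_value=fval, thresholds=dict(thresholds), heywood=heywood)


@dataclass
class StructureSelection:
    solution: FactorSolution
    retained_items: list
    dropped_items: list
    met_fit_rules: bool


def select_structure(solutions) -> StructureSelection:
    """Choose the number of factors and retain items.

    The chosen model is the smallest number of factors whose solution meets
    RMSEA < 0.07 and CFI >= 0.95 among candidates with eigenvalue support
    (n_factors no larger than the count of eigenvalues above 1, the first
    factor always supported).  Items whose largest absolute rotated loading
    is <= 0.3 are dropped and logged.  When no candidate meets the fit rules
    the best-fitting solution is returned with ``met_fit_rules=False``.
    """
    sols = sorted(solutions, key=lambda s: s.n_factors)
    if not sols:
        raise MeasurementError("select_structure: no candidate solutions")

    def fits(s):
        rmsea_ok = (s.df == 0) or (s.rmsea < RMSEA_RULE)
        return rmsea_ok and s.cfi >= CFI_RULE

    chosen = None
    met = False
    for s in sols:
        support = max(1, int((s.eigenvalues > 1.0).sum()))
        if s.n_factors <= support and fits(s):
            chosen = s
            met = True
            break
    if chosen is None:
        for s in sols:  # fit rules without eigenvalue support
            if fits(s):
                chosen = s
                met = True
                break
    if chosen is None:
        chosen = min(sols, key=lambda s: (np.nan_to_num(s.rmsea, nan=0.0), -s.cfi))
        logger.warning("select_structure: no candidate met the fit rules; "
                       "returning best-fitting %d-factor solution", chosen.n_factors)
    max_load = np.abs(chosen.loadings).max(axis=1)
    retained = [n for n, ml in zip(chosen.item_names, max_load) if ml > LOADING_RULE]
    dropped = [n for n, ml in zip(chosen.item_names, max_load) if ml <= LOADING_RULE]
    for name in dropped:
        logger.info("select_structure: dropping item %r (max |loading| <= %.1f)",
                    name, LOADING_RULE)
    return StructureSelection(solution=chosen, retained_items=retained,
                              dropped_items=dropped, met_fit_rules=met)


# ---------------------------------------------------------------------------
# MAP factor scores and scale construction
# ---------------------------------------------------------------------------

def _map_neg_logpost(eta, lam, psi_sqrt, tau_low, tau_high, phi_inv):
    t = lam @ eta
    a = (tau_low - t) / psi_sqrt
    b = (tau_high - t) / psi_sqrt
    pr = np.clip(norm.cdf(b) - norm.cdf(a), 1e-300, None)
    return -np.log(pr).sum() + 0.5 * eta @ phi_inv @ eta


def _map_grad(eta, lam, psi_sqrt, tau_low, tau_high, phi_inv):
    t = lam @ eta
    a = (tau_low - t) / psi_sqrt
    b = (tau_high - t) / psi_sqrt
    pr = np.clip(norm.cdf(b) - norm.cdf(a), 1e-300, None)
    w = (norm.pdf(b) - norm.pdf(a)) / (pr * psi_sqrt)
    return (lam * w[:, None]).sum(axis=0) + phi_inv @ eta


def _score_pattern(codes, lam_rows, psi_sqrt, tau_pairs, phi_inv, m):
    """MAP estimate of eta for one observed response pattern."""
    tau_low = np.array([tp[0] for tp in tau_pairs])
    tau_high = np.array([tp[1] for tp in tau_pairs])
    res = optimize.minimize(
        _map_neg_logpost, np.zeros(m),
        args=(lam_rows, psi_sqrt, tau_low, tau_high, phi_inv),
        jac=_map_grad, method="L-BFGS-B",
        bounds=[(-6.0, 6.0)] * m)
    if not np.all(np.isfinite(res.x)):
        return None
    return res.x


def score_respondents(solution: FactorSolution, table: pd.DataFrame,
                      schemas, id_column: str = "respondent_id") -> pd.DataFrame:
    """Full-information MAP factor scores for every respondent with at least
    one observed scale item.

    The posterior combines the probit-threshold likelihood of the observed
    items (residual sd sqrt(1 - lambda' Phi lambda)) with the N(0, Phi)
    prior; it is log-concave, so the optimum is unique.  Respondents missing
    every scale item receive no row.  Identical response patterns are scored
    once and broadcast.
    """
    names = solution.item_names
    schema_by_name = {s.name: s for s in schemas}
    L = solution.loadings
    phi = solution.phi
    m = L.shape[1]
    phi_inv = np.linalg.inv(phi)
    commun = np.einsum("ij,jk,ik->i", L, phi, L)
    psi_sqrt_all = np.sqrt(np.clip(1.0 - commun, 0.02, 1.0))
    # per item: map observed code -> (tau_low, tau_high) interval
    interval = {}
    for i, name in enumerate(names):
        tau = solution.thresholds[name]
        levels = schema_by_name[name].levels if name in schema_by_name else None
        obs_levels = (np.asarray(levels, dtype=float) if levels is not None
                      else None)
        edges = np.concatenate(([-np.inf], tau, [np.inf]))
        interval[name] = (obs_levels, edges)

    data = table[names].to_numpy(dtype=float)
    miss = is_missing(data)
    any_obs = (~miss).sum(axis=1) > 0
    idx_rows = np.where(any_obs)[0]
    if idx_rows.size == 0:
        return pd.DataFrame(columns=[id_column] +
                            [f"eta{k+1}" for k in range(m)] + ["n_items"])

    # canonical key: tuple of (item index, code) for observed items
    keys = {}
    for r in idx_rows:
        key = tuple((j, data[r, j]) for j in range(len(names)) if not miss[r, j])
        keys.setdefault(key, []).append(r)

    eta_out = np.full((len(table), m), np.nan)
    flagged = 0
    for key, rows in keys.items():
        jidx = [j for j, _ in key]
        lam_rows = L[jidx]
        psi_sqrt = psi_sqrt_all[jidx]
        tau_pairs = []
        degenerate = False
        for j, code in key:
            name = names[j]
            obs_levels, edges = interval[name]
            if obs_levels is not None:
                pos = np.searchsorted(obs_levels, code)
                if pos >= len(obs_levels) or obs_levels[pos] != code:
                    degenerate = True
                    break
            else:
                pos = int(code)
            # categories absent from the estimation margins collapse into
            # the tau grid by position among declared levels
            pos = min(pos, len(edges) - 2)
            tau_pairs.append((edges[pos], edges[pos + 1]))
        if degenerate:
            flagged += len(rows)
            continue
        eta = _score_pattern([c for _, c in key], lam_rows, psi_sqrt,
                             tau_pairs, phi_inv, m)
        if eta is None:
            flagged += len(rows)
            continue
        for r in rows:
            eta_out[r] = eta
    if flagged:
        logger.warning("score_respondents: %d respondents flagged (invalid code "
                       "or non-finite optimum) and excluded", flagged)
    ok = ~np.isnan(eta_out[:, 0])
    out = pd.DataFrame({id_column: table[id_column].to_numpy()[ok]})
    for k in range(m):
        out[f"eta{k+1}"] = eta_out[ok, k]
    out["n_items"] = (~miss[ok]).sum(axis=1)
    return out.reset_index(drop=True)


def zscore(values: np.ndarray) -> np.ndarray:
    """Population-convention z-score (divisor n) over non-NaN entries."""
    arr = np.asarray(values, dtype=float)
    ok = ~np.isnan(arr)
    mu = arr[ok].mean()
    sd = arr[ok].std(ddof=0)
    if sd == 0:
        raise MeasurementError("zscore: zero variance")
    out = np.full_like(arr, np.nan)
    out[ok] = (arr[ok] - mu) / sd
    return out


def build_scale(scores: pd.DataFrame, factor_columns,
                orientation=None) -> pd.Series:
    """z-scored scale from summed member factor scores.

    ``orientation`` gives a +/-1 weight per factor so every member factor
    points toward more capital before summation (the financial-instability
    factor keeps its higher-=-more-unstable coding elsewhere and is reflected
    here).  The result has mean 0 and population sd 1 over scored rows.
    """
    if len(scores) < 2:
        raise MeasurementError("build_scale: need >= 2 scored respondents")
    if orientation is None:
        orientation = [1.0] * len(factor_columns)
    total = np.zeros(len(scores))
    for w, col in zip(orientation, factor_columns):
        total = total + w * scores[col].to_numpy(dtype=float)
    return pd.Series(zscore(total), index=scores.index, name="scale")


def label_factors(solution: FactorSolution, schemas) -> list:
    """Name each rotated factor by the candidate assignment of the items
    loading most strongly on it (majority vote, ties to the larger total
    absolute loading)."""
    schema_by_name = {s.name: s for s in schemas}
    m = solution.n_factors
    labels = []
    for k in range(m):
        votes = {}
        for i, name in enumerate(solution.item_names):
            if np.argmax(np.abs(solution.loadings[i])) == k:
                fac = schema_by_name[name].factor if name in schema_by_name else "factor"
                votes[fac] = votes.get(fac, 0.0) + abs(solution.loadings[i, k])
        labels.append(max(votes, key=votes.get) if votes else f"factor{k+1}")
    solution.factor_labels = labels
    return labels
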
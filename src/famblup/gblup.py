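"""G-BLUP: REML variance components, mixed-model equations, PEV and accuracy.

The model is the standard animal model

    y = X b + Z u + e,   u ~ N(0, sigma2_g K),   e ~ N(0, sigma2_e I),

where K is an additive relationship matrix (pedigree or genomic) over all
individuals — including those with genotypes but no phenotype, who receive
predictions through their relatives — and Z is the 0/1 incidence of the
phenotyped records onto the K individuals.

Variance components are estimated by restricted maximum likelihood.  The
restricted likelihood is profiled over the heritability ratio
h2 = sigma2_g / (sigma2_g + sigma2_e) after a single eigendecomposition of
Z K Zᵀ, so each candidate h2 costs only a weighted least-squares solve; a
coarse grid scan followed by bounded scalar refinement locates the maximum.

Given components, Henderson's mixed-model equations

    [XᵀX   XᵀZ        ] [b]   [Xᵀy]
    [ZᵀX   ZᵀZ + λK⁻¹ ] [u] = [Zᵀy],   λ = sigma2_e / sigma2_g,

yield the fixed-effect estimates and the empirical genetic values (EGVs) u.
The prediction error variance of each EGV is PEV_i = sigma2_e · C^{uu}_ii
(the u-block of the inverse coefficient matrix), and the per-individual
accuracy is EA_i = sqrt(1 − PEV_i / sigma2_g), clipped into [0, 1].
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .kinship import RelationshipMatrix

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "MixedModelFit",
    "ModelError",
    "build_design",
    "restricted_loglik",
    "reml_fit",
    "solve_mme",
    "accuracy",
    "fit_gblup",
    "pev_calibration",
]

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "sex", "center", "smoking")


class ModelError(ValueError):
    """Model specification or design problem (collinearity, missing columns)."""


@dataclass(frozen=True)
class ModelSpec:
    trait_name: str
    covariate_names: tuple[str, ...] = DEFAULT_COVARIATES
    include_unphenotyped: bool = True


@dataclass(frozen=True)
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    log_likelihood: float

    @property
    def h2(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0


@dataclass
class MixedModelFit:
    individual_ids: list[str]
    fixed_effects: pd.DataFrame          # index: column name; estimate, se
    egv: np.ndarray
    pev: np.ndarray
    accuracy: np.ndarray
    components: VarianceComponents
    n_phenotyped: int
    phenotyped: np.ndarray = field(default=None)  # bool mask over individuals


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def build_design(phenotypes: pd.DataFrame, spec: ModelSpec,
                 relationship: RelationshipMatrix
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Build (y, X, Z, column_names) for one trait.

    Rows are the non-missing trait records.  Categorical covariates (dtype
    object/category) are dummy-expanded against a reference level; covariates
    with a single observed level are dropped with a log message.  Z maps each
    record to its column in the relationship matrix.
    """
    if spec.trait_name not in phenotypes.columns:
        raise ModelError(f"trait column {spec.trait_name!r} not in phenotype table")
    missing_cov = [c for c in spec.covariate_names if c not in phenotypes.columns]
    if missing_cov:
        raise ModelError(f"covariates not in phenotype table: {missing_cov}")

    pos = {iid: k for k, iid in enumerate(relationship.individual_ids)}
    obs = phenotypes[phenotypes[spec.trait_name].notna()].reset_index(drop=True)
    if len(obs) == 0:
        raise ModelError("no phenotyped individuals")
    unknown = [i for i in obs["individual_id"] if i not in pos]
    if unknown:
        raise ModelError(
            f"phenotyped individuals absent from relationship matrix: "
            f"{unknown[:5]}{'...' if len(unknown) > 5 else ''}")

    cols: list[np.ndarray] = [np.ones(len(obs))]
    names: list[str] = ["intercept"]
    for cov in spec.covariate_names:
        s = obs[cov]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(s.astype(str).unique())
            if len(levels) < 2:
                log.info("covariate %r has a single level (%r); dropped",
                         cov, levels[0] if levels else None)
                continue
            for lev in levels[1:]:  # first level is the reference
                cols.append((s.astype(str) == lev).to_numpy(float))
                names.append(f"{cov}[{lev}]")
        else:
            vals = s.to_numpy(float)
            if np.ptp(vals) == 0:
                log.info("covariate %r is constant; dropped", cov)
                continue
            cols.append(vals)
            names.append(cov)
    X = np.column_stack(cols)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via QR pivoting
        _, R, piv = _qr_pivot(X)
        bad = [names[j] for j in piv[rank:]]
        raise ModelError(f"design matrix rank deficient; collinear columns: {bad}")

    y = obs[spec.trait_name].to_numpy(float)
    Z = np.zeros((len(obs), relationship.n))
    for r, iid in enumerate(obs["individual_id"]):
        Z[r, pos[iid]] = 1.0
    return y, X, Z, names


def _qr_pivot(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    from scipy.linalg import qr
    Q, R, piv = qr(X, pivoting=True)
    return Q, R, piv


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

def _rotate(y: np.ndarray, X: np.ndarray, Z: np.ndarray, K: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Eigendecompose ZKZᵀ and rotate y, X into its eigenbasis."""
    H = Z @ K @ Z.T
    s, U = np.linalg.eigh(H)
    s = np.maximum(s, 0.0)  # K is PSD up to roundoff
    return s, U.T @ y, U.T @ X, float(np.linalg.slogdet(X.T @ X)[1])


def _reml_profile(h2: float, s: np.ndarray, yr: np.ndarray, Xr: np.ndarray,
                  logdet_xtx: float) -> tuple[float, float]:
    """Restricted log-likelihood profiled over total variance at given h2.

    Returns (loglik, sigma2_total).  D_i = h2·s_i + (1 − h2) are the
    eigenvalues of V / sigma2_total.
    """
    n, p = Xr.shape
    D = h2 * s + (1.0 - h2)
    if np.any(D <= 0):
        return -np.inf, np.nan
    W = 1.0 / D
    XtWX = Xr.T @ (W[:, None] * Xr)
    XtWy = Xr.T @ (W * yr)
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return -np.inf, np.nan
    r = yr - Xr @ beta
    rss = float(r @ (W * r))
    if rss <= 0:
        return -np.inf, np.nan
    sigma2 = rss / (n - p)
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf, np.nan
    ll = -0.5 * ((n - p) * (math.log(2 * math.pi * sigma2) + 1.0)
                 + float(np.sum(np.log(D))) + logdet_xwx - logdet_xtx)
    return ll, sigma2


def restricted_loglik(h2: float, y: np.ndarray, X: np.ndarray, Z: np.ndarray,
                      K: RelationshipMatrix) -> float:
    """Profiled restricted log-likelihood at heritability ratio ``h2``."""
    s, yr, Xr, ldx = _rotate(y, X, Z, K.values)
    return _reml_profile(h2, s, yr, Xr, ldx)[0]


def reml_profile_function(y: np.ndarray, X: np.ndarray, Z: np.ndarray,
                          K: RelationshipMatrix):
    """Return ``f(h2) -> restricted log-likelihood`` with the rotation cached.

    Useful for likelihood-surface inspection (e.g. grid scans) without paying
    the eigendecomposition repeatedly.
    """
    s, yr, Xr, ldx = _rotate(y, X, Z, K.values)

    def f(h2: float) -> float:
        return _reml_profile(float(h2), s, yr, Xr, ldx)[0]

    return f


H2_UPPER = 1.0 - 1e-6


def reml_fit(y: np.ndarray, X: np.ndarray, Z: np.ndarray,
             K: RelationshipMatrix, n_grid: int = 51,
             xatol: float = 1e-8) -> VarianceComponents:
    """REML estimates of (sigma2_g, sigma2_e) under V = sigma2_g ZKZᵀ + sigma2_e I.

    The restricted likelihood is profiled over h2 in [0, 1−1e−6] using one
    eigendecomposition of ZKZᵀ; a coarse grid locates the basin and a bounded
    scalar optimizer refines the maximum to ``xatol``.  Boundary estimates are
    reported, not raised.
    """
    smin = float(np.linalg.eigvalsh(K.values).min())
    if smin < -1e-8:
        raise ModelError(
            f"relationship matrix is not PSD (min eigenvalue {smin:.3g}); "
            "apply repair_psd first")
    s, yr, Xr, ldx = _rotate(y, X, Z, K.values)

    grid = np.linspace(0.0, H2_UPPER, n_grid)
    lls = np.array([_reml_profile(h, s, yr, Xr, ldx)[0] for h in grid])
    k = int(np.argmax(lls))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, n_grid - 1)]

    if hi > lo:
        res = minimize_scalar(
            lambda h: -_reml_profile(h, s, yr, Xr, ldx)[0],
            bounds=(lo, hi), method="bounded",
            options={"xatol": xatol})
        h2_hat, ll_hat = float(res.x), -float(res.fun)
    else:
        h2_hat, ll_hat = float(grid[k]), float(lls[k])
    # guard: never return worse than the best grid point (incl. boundaries)
    if lls[k] > ll_hat:
        h2_hat, ll_hat = float(grid[k]), float(lls[k])

    ll, sigma2 = _reml_profile(h2_hat, s, yr, Xr, ldx)
    return VarianceComponents(sigma2_g=h2_hat * sigma2,
                              sigma2_e=(1.0 - h2_hat) * sigma2,
                              log_likelihood=ll)


# ---------------------------------------------------------------------------
# Henderson's mixed-model equations
# ---------------------------------------------------------------------------

def _psd_inverse(K: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    vals, vecs = np.linalg.eigh(K)
    vals = np.maximum(vals, floor)
    inv = (vecs / vals) @ vecs.T
    return (inv + inv.T) / 2.0


def solve_mme(y: np.ndarray, X: np.ndarray, Z: np.ndarray,
              K: RelationshipMatrix, components: VarianceComponents,
              eig_floor: float = 1e-8) -> MixedModelFit:
    """Solve Henderson's MME for fixed effects, EGVs, PEV and accuracy.

    Individuals present in K but without phenotypes receive predictions
    through their relationship with phenotyped individuals.  If sigma2_g is
    at the zero boundary, all EGVs are defined as 0 with PEV = sigma2_g = 0
    and accuracy 0 (logged).
    """
    n, p = X.shape
    q = K.n
    if components.sigma2_g <= 0:
        log.warning("sigma2_g at zero boundary: EGVs set to 0, accuracy 0")
        fe = _gls_fixed_effects(y, X, np.eye(n) * components.sigma2_e)
        return MixedModelFit(list(K.individual_ids), fe,
                             egv=np.zeros(q), pev=np.zeros(q),
                             accuracy=np.zeros(q), components=components,
                             n_phenotyped=n,
                             phenotyped=Z.sum(axis=0) > 0)

    lam = components.sigma2_e / components.sigma2_g
    Kinv = _psd_inverse(K.values, eig_floor)
    C = np.empty((p + q, p + q))
    C[:p, :p] = X.T @ X
    C[:p, p:] = X.T @ Z
    C[p:, :p] = C[:p, p:].T
    C[p:, p:] = Z.T @ Z + lam * Kinv
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise ModelError(
            "singular mixed-model coefficient matrix; repair the relationship "
            "matrix (repair_psd) or prune collinear covariates") from exc
    sol = Cinv @ rhs
    b, u = sol[:p], sol[p:]
    se_b = np.sqrt(components.sigma2_e * np.maximum(np.diag(Cinv)[:p], 0.0))
    pev = components.sigma2_e * np.maximum(np.diag(Cinv)[p:], 0.0)

    fe = pd.DataFrame({"estimate": b, "se": se_b})
    fit = MixedModelFit(list(K.individual_ids), fe, egv=u, pev=pev,
                        accuracy=np.zeros(q), components=components,
                        n_phenotyped=n, phenotyped=Z.sum(axis=0) > 0)
    fit.accuracy = accuracy(fit)
    return fit


def _gls_fixed_effects(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> pd.DataFrame:
    Vi = np.linalg.inv(V)
    cov = np.linalg.inv(X.T @ Vi @ X)
    b = cov @ X.T @ Vi @ y
    return pd.DataFrame({"estimate": b, "se": np.sqrt(np.diag(cov))})


def accuracy(fit: MixedModelFit) -> np.ndarray:
    """Per-individual accuracy EA = sqrt(1 − PEV / sigma2_g), clipped to [0, 1].

    PEV = sigma2_g means the data carry no information on the individual's
    genetic value (EA = 0); PEV = 0 means it is known exactly (EA = 1).
    """
    s2g = fit.components.sigma2_g
    if s2g <= 0:
        warnings.warn("sigma2_g = 0: accuracy undefined, reported as 0",
                      stacklevel=2)
        return np.zeros_like(fit.pev)
    ratio = fit.pev / s2g
    n_clip = int((ratio > 1).sum())
    if n_clip:
        log.info("accuracy: clipped %d individuals with PEV > sigma2_g", n_clip)
    return np.sqrt(np.clip(1.0 - ratio, 0.0, 1.0))


def fit_gblup(phenotypes: pd.DataFrame, spec: ModelSpec,
              K: RelationshipMatrix) -> MixedModelFit:
    """Convenience wrapper: design → REML → MME → accuracy for one trait.

    With ``include_unphenotyped=False`` the relationship matrix is restricted
    to phenotyped individuals, so no predictions are produced for the rest.
    """
    if not spec.include_unphenotyped:
        ids = [i for i in K.individual_ids
               if i in set(phenotypes.loc[phenotypes[spec.trait_name].notna(),
                                          "individual_id"])]
        K = K.reorder(ids)
    y, X, Z, names = build_design(phenotypes, spec, K)
    vc = reml_fit(y, X, Z, K)
    fit = solve_mme(y, X, Z, K, vc)
    fit.fixed_effects.index = names
    return fit


# ---------------------------------------------------------------------------
# PEV calibration
# ---------------------------------------------------------------------------

def pev_calibration(fit_procedure, simulator, n_replicates: int) -> dict:
    """Check that analytic PEV matches the empirical MSE of the EGV.

    ``simulator(rep) -> (y, u_true)`` draws a fresh phenotype vector and the
    true genetic values on a fixed pedigree; ``fit_procedure(y) -> (u_hat,
    pev)`` fits the model.  Per individual, the empirical mean squared error
    of (u_hat − u_true) across replicates is compared with the mean analytic
    PEV; the report carries the per-individual ratios and their median.
    """
    if n_replicates < 50:
        warnings.warn("fewer than 50 replicates: PEV calibration is unstable",
                      stacklevel=2)
    sq_err_sum = None
    pev_sum = None
    for rep in range(n_replicates):
        y, u_true = simulator(rep)
        u_hat, pev = fit_procedure(y)
        err2 = (u_hat - u_true) ** 2
        if sq_err_sum is None:
            sq_err_sum = np.zeros_like(err2)
            pev_sum = np.zeros_like(pev)
        sq_err_sum += err2
        pev_sum += pev
    mse = sq_err_sum / n_replicates
    mean_pev = pev_sum / n_replicates
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean_pev > 0, mse / mean_pev, np.nan)
    ok = np.isfinite(ratio)
    return {
        "n_replicates": n_replicates,
        "ratio": ratio,
        "median_ratio": float(np.median(ratio[ok])),
        "mean_ratio": float(np.mean(ratio[ok])),
        "empirical_mse": mse,
        "mean_pev": mean_pev,
    }
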
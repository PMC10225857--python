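"""Correlates of species' trends: linear models, PGLS and all-subsets AIC.

The response is each species' log annual rate of change (from the smoothed
series).  The global model contains the main effects migration strategy,
habitat, body mass, CST, trophic niche and abundance class, plus the
two-way interactions of the continuous predictors (body mass, CST) with
migration, habitat and trophic niche.  Continuous predictors are
z-transformed (population-sd convention).

Phylogenetic signal in the residuals is modelled with Pagel's λ: the
Brownian-motion covariance implied by the phylogeny has its off-diagonal
entries multiplied by λ ∈ [0, 1] (λ = 0: independent residuals; λ = 1: full
Brownian covariance).  λ is estimated by maximum likelihood on a coarse grid
refined by golden-section search, with a 1.92-log-likelihood-unit profile
interval, and boundary likelihood-ratio tests against λ = 0 and λ = 1 use a
50:50 mixture of χ²₀ and χ²₁.

Model selection enumerates every marginality-respecting simplification of
the global model, ranks by AIC (Gaussian, counting the variance parameter),
removes models nested within a retained model of lower AIC, and keeps all
models within 6 AIC units of the minimum.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import patsy
from scipy import linalg as scipy_linalg
from scipy import optimize, stats

logger = logging.getLogger(__name__)

GLOBAL_MAIN_EFFECTS = (
    "migration",
    "habitat",
    "body_mass",
    "cst",
    "trophic_niche",
    "abundance_class",
)
GLOBAL_INTERACTIONS = (
    ("migration", "body_mass"),
    ("migration", "cst"),
    ("habitat", "body_mass"),
    ("habitat", "cst"),
    ("trophic_niche", "body_mass"),
    ("trophic_niche", "cst"),
)
CONTINUOUS_VARS = ("body_mass", "cst")


@dataclass(frozen=True)
class ModelSpec:
    """A model: response, main-effect terms and two-way interactions."""

    response: str = "growth_rate"
    main_effects: tuple[str, ...] = GLOBAL_MAIN_EFFECTS
    interactions: tuple[tuple[str, str], ...] = GLOBAL_INTERACTIONS
    z_scored: bool = True

    def __post_init__(self) -> None:
        mains = set(self.main_effects)
        for a, b in self.interactions:
            if a not in mains or b not in mains:
                raise ValueError(
                    f"interaction {a}:{b} requires both main effects (marginality)"
                )

    @property
    def terms(self) -> tuple:
        return tuple(self.main_effects) + tuple(self.interactions)

    def formula(self) -> str:
        parts = list(self.main_effects) + [f"{a}:{b}" for a, b in self.interactions]
        rhs = " + ".join(parts) if parts else "1"
        return f"{self.response} ~ {rhs}"

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return set(self.terms) <= set(other.terms) and self.terms != other.terms


@dataclass
class LMFit:
    spec: ModelSpec
    coef: pd.Series
    se: pd.Series
    loglik: float
    aic: float
    n: int
    aliased: list[str] = field(default_factory=list)


@dataclass
class PGLSFit:
    spec: ModelSpec
    coef: pd.Series
    se: pd.Series
    lam: float
    lambda_ci: tuple[float, float]
    loglik: float
    aic: float
    n: int
    profile: tuple[np.ndarray, np.ndarray] | None = None
    star_tree: bool = False

    def loglik_at(self, lam: float) -> float:
        """Profile log-likelihood at a given λ (from the stored profile fit)."""
        return self._loglik_fn(lam)  # set by fit_pgls


@dataclass
class SelectionResult:
    """Retained model set from all-subsets selection."""

    table: pd.DataFrame  # columns: formula, aic, delta_aic, retained
    best: object  # fit of the AIC-best model
    retained: list  # fits of retained models
    dropped_nested: list[str]


def z_transform(column: np.ndarray | pd.Series) -> np.ndarray:
    """Standardize to mean 0, sd 1 using the population-sd convention."""
    x = np.asarray(column, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        name = getattr(column, "name", None) or "column"
        raise ValueError(f"cannot z-transform {name}: zero variance")
    return (x - x.mean()) / sd


def prepare_trait_data(
    data: pd.DataFrame,
    spec: ModelSpec | None = None,
    exclude_marine: bool = True,
) -> pd.DataFrame:
    """Apply exclusions and z-transform continuous predictors.

    Marine-habitat species and species without a CST value are excluded
    before fitting (counts logged); continuous predictors are standardized
    when the spec asks for it.
    """
    spec = spec or ModelSpec()
    df = data.copy()
    n0 = len(df)
    if exclude_marine and "habitat" in df.columns:
        df = df[df["habitat"] != "marine"]
    if "cst" in df.columns:
        df = df[df["cst"].notna()]
    if len(df) < n0:
        logger.info("trait data: excluded %d of %d species", n0 - len(df), n0)
    df = df.reset_index(drop=True)
    if spec.z_scored:
        for c in CONTINUOUS_VARS:
            if c in df.columns and c in spec.main_effects:
                df[c] = z_transform(df[c])
    return df


def _design(spec: ModelSpec, data: pd.DataFrame):
    y, X = patsy.dmatrices(spec.formula(), data, return_type="dataframe")
    return y.to_numpy().ravel(), X


def _gaussian_loglik(resid: np.ndarray, n: int) -> float:
    sigma2 = float(resid @ resid) / n
    return -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)


def fit_lm(spec: ModelSpec, data: pd.DataFrame) -> LMFit:
    """OLS fit with Gaussian AIC counting the residual-variance parameter.

    Rank-deficient designs have aliased columns dropped and reported.
    """
    y, X = _design(spec, data)
    Xm = X.to_numpy()
    names = list(X.columns)
    q, r = np.linalg.qr(Xm)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r[0, 0]))
    aliased = [n for n, k in zip(names, keep) if not k]
    if aliased:
        logger.info("aliased terms dropped: %s", aliased)
        Xm = Xm[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    n, p = Xm.shape
    beta, _, _, _ = np.linalg.lstsq(Xm, y, rcond=None)
    resid = y - Xm @ beta
    ll = _gaussian_loglik(resid, n)
    k = p + 1  # + residual variance
    dof = max(n - p, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(Xm.T @ Xm)
    return LMFit(
        spec=spec,
        coef=pd.Series(beta, index=names),
        se=pd.Series(np.sqrt(np.diag(cov)), index=names),
        loglik=ll,
        aic=2 * k - 2 * ll,
        n=n,
        aliased=aliased,
    )


# ---------------------------------------------------------------------------
# Phylogenetic GLS
# ---------------------------------------------------------------------------


def brownian_covariance(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    """Brownian-motion covariance: C_ij = shared root-to-MRCA path length."""
    pdm = tree.phylogenetic_distance_matrix()
    tax = {t.label: t for t in tree.taxon_namespace}
    missing = [s for s in taxa if s not in tax]
    if missing:
        raise ValueError(f"taxa not in tree: {missing}")
    depths = {}
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths[leaf.taxon.label] = d
    n = len(taxa)
    C = np.empty((n, n))
    for i, a in enumerate(taxa):
        C[i, i] = depths[a]
        for j in range(i + 1, n):
            b = taxa[j]
            dij = pdm.patristic_distance(tax[a], tax[b])
            C[i, j] = C[j, i] = 0.5 * (depths[a] + depths[b] - dij)
    return C


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def _gls_profile_loglik(y, X, C, lam):
    V = _lambda_cov(C, lam)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf, None, None
    yt = scipy_linalg.solve_triangular(L, y, lower=True)
    Xt = scipy_linalg.solve_triangular(L, X, lower=True)
    beta, _, _, _ = np.linalg.lstsq(Xt, yt, rcond=None)
    resid = yt - Xt @ beta
    n = len(y)
    sigma2 = float(resid @ resid) / n
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return ll, beta, sigma2


def fit_pgls(
    spec: ModelSpec,
    data: pd.DataFrame,
    tree: dendropy.Tree,
    species_col: str = "species_id",
    grid_size: int = 21,
    cov: np.ndarray | None = None,
) -> PGLSFit:
    """GLS under Pagel's-λ covariance with λ estimated by ML.

    Species absent from the tree are dropped with a log entry.  On a star
    phylogeny (no internal structure) λ is unidentifiable; the fit reduces
    to OLS and is flagged.  ``cov`` can supply a precomputed Brownian
    covariance (rows ordered as ``data``) to avoid re-deriving it from the
    tree on repeated fits.
    """
    tips = {t.label for t in tree.taxon_namespace}
    present = data[species_col].isin(tips)
    if not present.all():
        logger.info(
            "PGLS: dropped %d species not in the phylogeny", int((~present).sum())
        )
        if cov is not None:
            keep = present.to_numpy()
            cov = cov[np.ix_(keep, keep)]
        data = data[present].reset_index(drop=True)
    taxa = list(data[species_col])
    C = cov if cov is not None else brownian_covariance(tree, taxa)
    y, X = _design(spec, data)
    Xm = X.to_numpy()
    names = list(X.columns)
    n, p = Xm.shape

    off = C[~np.eye(n, dtype=bool)]
    star = bool(np.all(np.abs(off) < 1e-12 * max(np.max(np.diag(C)), 1.0)))

    def nll(lam):
        return -_gls_profile_loglik(y, Xm, C, lam)[0]

    grid = np.linspace(0.0, 1.0, grid_size)
    lls = np.array([-nll(g) for g in grid])
    j = int(np.argmax(lls))
    if star:
        lam_hat = 0.0
    else:
        lo = grid[max(j - 1, 0)]
        hi = grid[min(j + 1, grid_size - 1)]
        if hi > lo:
            res = optimize.minimize_scalar(
                nll, bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-6},
            )
            lam_hat = float(res.x) if -res.fun >= lls[j] else float(grid[j])
        else:
            lam_hat = float(grid[j])
        # prefer exact boundary when it is at least as good
        for bound in (0.0, 1.0):
            if -nll(bound) >= -nll(lam_hat) - 1e-10:
                if abs(lam_hat - bound) < 0.5 / grid_size:
                    lam_hat = bound

    ll_hat, beta, sigma2 = _gls_profile_loglik(y, Xm, C, lam_hat)

    # profile CI: λ with loglik within 1.92 of the maximum
    fine = np.linspace(0.0, 1.0, 201)
    ll_fine = np.array([-nll(g) for g in fine])
    inside = fine[ll_fine >= ll_hat - 1.92]
    ci = (float(inside.min()), float(inside.max())) if inside.size else (lam_hat, lam_hat)

    V = _lambda_cov(C, lam_hat)
    Vinv = np.linalg.inv(V)
    cov_beta = sigma2 * n / max(n - p, 1) * np.linalg.inv(Xm.T @ Vinv @ Xm)
    k = p + 2  # + sigma2 + lambda
    fit = PGLSFit(
        spec=spec,
        coef=pd.Series(beta, index=names),
        se=pd.Series(np.sqrt(np.diag(cov_beta)), index=names),
        lam=lam_hat,
        lambda_ci=ci,
        loglik=ll_hat,
        aic=2 * k - 2 * ll_hat,
        n=n,
        profile=(fine, ll_fine),
        star_tree=star,
    )
    fit._loglik_fn = lambda lam: -nll(lam)  # type: ignore[attr-defined]
    return fit


def lr_test_lambda(fit: PGLSFit, null_lambda: float) -> tuple[float, float]:
    """Boundary LR test of λ̂ against λ = 0 or 1.

    Returns (statistic, p).  The statistic 2·(ll(λ̂) − ll(null)) is compared
    to a 50:50 mixture of χ²₀ (point mass at 0) and χ²₁, the null
    distribution for a parameter on its boundary.
    """
    if null_lambda not in (0.0, 1.0):
        raise ValueError("null_lambda must be 0 or 1")
    ll_null = fit.loglik_at(null_lambda)
    stat = max(2.0 * (fit.loglik - ll_null), 0.0)
    p = 0.5 * stats.chi2.sf(stat, df=1) + 0.5 * float(stat <= 1e-10)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# All-subsets selection
# ---------------------------------------------------------------------------


def enumerate_submodels(spec: ModelSpec, limit: int = 100_000) -> list[ModelSpec]:
    """All marginality-respecting simplifications of a global model."""
    models: list[ModelSpec] = []
    mains = spec.main_effects
    for r in range(len(mains) + 1):
        for subset in itertools.combinations(mains, r):
            admissible = [
                ix for ix in spec.interactions if ix[0] in subset and ix[1] in subset
            ]
            for ri in range(len(admissible) + 1):
                for ints in itertools.combinations(admissible, ri):
                    models.append(
                        ModelSpec(
                            response=spec.response,
                            main_effects=subset,
                            interactions=ints,
                            z_scored=spec.z_scored,
                        )
                    )
                    if len(models) > limit:
                        raise ValueError(
                            f"more than {limit} candidate models; prune the global model"
                        )
    return models


def dredge(
    spec: ModelSpec,
    data: pd.DataFrame,
    fitter=fit_lm,
    delta_max: float = 6.0,
) -> SelectionResult:
    """All-subsets selection: rank by AIC, drop nested models, keep ΔAIC ≤ 6.

    A model is removed when a strictly simpler (nested) model with lower AIC
    is in the retained set, so every retained model earns its extra terms.
    """
    candidates = enumerate_submodels(spec)
    fits = [fitter(m, data) for m in candidates]
    fits.sort(key=lambda f: f.aic)
    best = fits[0]
    within = [f for f in fits if f.aic - best.aic <= delta_max]
    retained: list = []
    dropped: list[str] = []
    for f in within:  # ascending AIC
        if any(r.spec.is_nested_in(f.spec) for r in retained):
            dropped.append(f.spec.formula())
        else:
            retained.append(f)
    table = pd.DataFrame(
        {
            "formula": [f.spec.formula() for f in fits],
            "aic": [f.aic for f in fits],
            "delta_aic": [f.aic - best.aic for f in fits],
            "retained": [f in retained for f in fits],
        }
    )
    return SelectionResult(table=table, best=best, retained=retained, dropped_nested=dropped)
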
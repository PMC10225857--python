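"""Bayesian hierarchical model of total assemblage abundance.

The model converts per-species log index series (raw or smoothed) plus
absolute population estimates into posterior trajectories of total
abundance.  For species *s* with reference year *r(s)* (the year its
population estimate refers to), the latent log relative abundance λ_{s,y}
is the log of the ratio of its abundance in year *y* to that in *r(s)*,
with λ_{s,r(s)} = 0 by construction.

Generative model (this package's canonical variant):

    observation:  m_{s,y} ~ Normal(α_s + λ_{s,y}, w_{s,y})
                  m is the log index (its scale is arbitrary, absorbed by
                  the free intercept α_s); w is its log-scale error
                  variance, inflated for missing leading years (below);
    latent:       λ_{s,y} = θ_s·(y − r(s)) + ε_{s,y}, where the deviation
                  ε follows a first-order random walk anchored at the
                  reference year: ε_{s,r(s)} = 0 and
                  ε_{s,y+1} − ε_{s,y} ~ N(0, η_s²);
    shrinkage:    θ_s ~ Normal(θ_group(s), τ²), where the group mean is
                  additive in habitat and migration class with a weakly
                  informative interaction term:
                  θ_group = μ + a_hab + b_mig + c_{hab×mig};
    scale:        P_s ~ Lognormal(log point_s, σ_{P,s}) with σ matched to
                  the estimate's SE by the delta method.

The random-walk deviation lets each trajectory bend smoothly away from its
log-linear trend while its uncertainty accumulates with distance from the
reference year — an independent-deviation prior would instead let the trend
line over-concentrate the endpoints.  η_s is per species because deviation
scale varies strongly across species.

Years before a species' first data year take the first observed value as
their filled observation, with variance increased by the square of the
number of years since non-missing data (scaled by c, default the species'
mean observed log-scale SE): w(y) = w(first) + c²·(first − y)².  Distant
filled years therefore carry almost no information and the species' early
trajectory is governed by its group trend and random walk, which is the
intended behaviour.

Sampling is a partially collapsed blocked Gibbs sampler vectorised over
species: θ_s and η_s are updated against the ε-marginal likelihood (the
random walk integrates out through banded linear algebra), then ε is redrawn
from its Gaussian full conditional, so the strong θ–ε–η coupling never slows
mixing.  Totals are computed per posterior draw as
T_y = Σ_s weight_s · P_s · exp(λ_{s,y}), so any accounting identity that
holds for sums holds exactly per draw.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamodel import PopulationEstimate, SpeciesRecord
from .smoothing import SmoothedSeries

logger = logging.getLogger(__name__)


@dataclass
class MCMCSettings:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0


@dataclass
class Posterior:
    """Posterior draws from the hierarchical model.

    ``lam`` has shape (n_draws, S, Y) (log relative abundance), ``theta``
    (n_draws, S), ``pop`` (n_draws, S) (reference-year population).
    """

    species_ids: list[str]
    years: np.ndarray
    lam: np.ndarray
    theta: np.ndarray
    pop: np.ndarray
    sigma: np.ndarray
    tau: np.ndarray
    group_mean: np.ndarray  # (n_draws, S): θ_group per species
    rhat: dict[str, float] = field(default_factory=dict)
    n_chains: int = 1

    @property
    def n_draws(self) -> int:
        return self.lam.shape[0]

    def species_index(self, species_id: str) -> int:
        return self.species_ids.index(species_id)


@dataclass
class TotalTrajectory:
    """Posterior of total abundance (or biomass) per year."""

    years: np.ndarray
    draws: np.ndarray  # (n_draws, Y)
    median: np.ndarray
    lcl: np.ndarray
    ucl: np.ndarray

    @classmethod
    def from_draws(cls, years: np.ndarray, draws: np.ndarray) -> "TotalTrajectory":
        return cls(
            years=np.asarray(years),
            draws=draws,
            median=np.median(draws, axis=0),
            lcl=np.percentile(draws, 2.5, axis=0),
            ucl=np.percentile(draws, 97.5, axis=0),
        )


def inflate_missing_variance(
    obs_var: np.ndarray,
    first_data_year: int,
    years: np.ndarray,
    c: float,
) -> np.ndarray:
    """Variance for filled leading years: var(first) + c²·(first − y)².

    ``obs_var`` is indexed on ``years``; positions with y < first_data_year
    get the inflated variance, observed years are returned unchanged.
    """
    if not (c > 0):
        raise ValueError("c must be > 0")
    years = np.asarray(years)
    out = np.array(obs_var, dtype=float)
    first_pos = int(np.nonzero(years == first_data_year)[0][0])
    lead = years < first_data_year
    out[lead] = obs_var[first_pos] + c**2 * (first_data_year - years[lead]) ** 2
    return out


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------


def _lognormal_sigma(est: PopulationEstimate) -> float:
    if est.point <= 0:
        raise ValueError(f"estimate {est.species_id!r}: non-positive point")
    return est.se / est.point


def _as_log_series(series) -> tuple[str, np.ndarray, np.ndarray, np.ndarray]:
    """(species_id, years, log values, log-scale SE) from raw or smoothed input."""
    if isinstance(series, SmoothedSeries):
        return series.species_id, series.years, series.smoothed_log_index, series.se_log
    # raw IndexSeries: log-transform with delta-method SEs
    from .smoothing import log_transform_series

    log_index, se_log = log_transform_series(series)
    return series.species_id, series.years, log_index, se_log


def _prepare_arrays(
    series_list,
    estimates: dict[str, PopulationEstimate],
    years: np.ndarray,
    missing_c: float | None,
):
    """Log observations on the assemblage grid, filled outside each span."""
    S, Y = len(series_list), len(years)
    m = np.zeros((S, Y))
    w = np.zeros((S, Y))
    ref_pos = np.zeros(S, dtype=int)
    yr_offset = np.zeros((S, Y))
    for i, series in enumerate(series_list):
        sid, yrs, log_vals, se_log = _as_log_series(series)
        est = estimates[sid]
        ref = est.ref_year
        if ref < yrs[0] or ref > yrs[-1]:
            raise ValueError(
                f"species {sid!r}: reference year {ref} outside series span"
            )
        # observation on the assemblage grid, filled before first data year
        first = int(yrs[0])
        obs = np.empty(Y)
        var = np.empty(Y)
        in_span = (years >= yrs[0]) & (years <= yrs[-1])
        pos = np.searchsorted(yrs, years[in_span])
        # interior missing years (raw input): fill from nearest earlier value
        pos = np.minimum(pos, len(yrs) - 1)
        exact = yrs[pos] == years[in_span]
        obs[in_span] = log_vals[pos]
        var[in_span] = np.where(exact, se_log[pos] ** 2, np.inf)
        before = years < first
        obs[before] = log_vals[0]
        var[before] = se_log[0] ** 2
        after = years > yrs[-1]
        obs[after] = log_vals[-1]
        var[after] = se_log[-1] ** 2
        c = missing_c if missing_c is not None else max(float(np.mean(se_log)), 1e-3)
        if before.any():
            var = inflate_missing_variance(var, first, years, c)
        if after.any():  # trailing gap treated symmetrically
            last = int(yrs[-1])
            var[after] = var[years == last][0] + c**2 * (years[after] - last) ** 2
        # interior gaps carry (almost) no information
        var[np.isinf(var)] = 1e6
        rp = int(np.nonzero(years == ref)[0][0])
        ref_pos[i] = rp
        m[i] = obs
        w[i] = var
        yr_offset[i] = years - ref
    w = np.maximum(w, 1e-10)
    return m, w, ref_pos, yr_offset


def _group_design(
    species: list[SpeciesRecord],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, int, int]:
    habitats = sorted({r.habitat for r in species})
    migrations = sorted({r.migration for r in species})
    hab_idx = np.array([habitats.index(r.habitat) for r in species])
    mig_idx = np.array([migrations.index(r.migration) for r in species])
    cell_idx = hab_idx * len(migrations) + mig_idx
    return hab_idx, mig_idx, cell_idx, len(habitats), len(migrations), len(habitats) * len(migrations)


def fit_hierarchical(
    smoothed: list[SmoothedSeries],
    estimates: dict[str, PopulationEstimate],
    species: list[SpeciesRecord] | None = None,
    years: np.ndarray | None = None,
    mcmc: MCMCSettings | None = None,
    missing_c: float | None = None,
    effect_prior_sd: float = 0.1,
) -> Posterior:
    """Sample the joint posterior by partially collapsed blocked Gibbs.

    ``smoothed`` may contain :class:`SmoothedSeries` or raw
    :class:`~avitrend.datamodel.IndexSeries` (log-transformed internally
    with delta-method SEs); raw series are the default pipeline choice
    because their observation errors are independent across years, which
    the observation layer assumes.  Species without a population estimate
    are dropped (logged).  When ``species`` records are omitted, all
    species share a single group.  Split-R̂ diagnostics over chains are
    attached; values above 1.05 warn but the posterior is still returned.
    """
    mcmc = mcmc or MCMCSettings()
    smoothed = [s for s in smoothed if _has_estimate(s, estimates)]
    if not smoothed:
        raise ValueError("no species with both a smoothed series and an estimate")
    if years is None:
        y0 = min(int(s.years[0]) for s in smoothed)
        y1 = max(int(s.years[-1]) for s in smoothed)
        years = np.arange(y0, y1 + 1)
    years = np.asarray(years, dtype=int)
    ids = [s.species_id for s in smoothed]
    S, Y = len(smoothed), len(years)

    m, w, ref_pos, yr_off = _prepare_arrays(smoothed, estimates, years, missing_c)

    if species is not None:
        by_id = {r.species_id: r for r in species}
        recs = [by_id[i] for i in ids]
        hab_idx, mig_idx, cell_idx, H, M, C = _group_design(recs)
    else:
        hab_idx = np.zeros(S, dtype=int)
        mig_idx = np.zeros(S, dtype=int)
        cell_idx = np.zeros(S, dtype=int)
        H = M = C = 1

    sigma_p = np.array([_lognormal_sigma(estimates[i]) for i in ids])
    log_point = np.array([np.log(estimates[i].point) for i in ids])

    n_keep = mcmc.draws
    chains_lam, chains_theta, chains_gm = [], [], []
    chains_sigma, chains_tau = [], []
    ss = np.random.SeedSequence(mcmc.seed)
    for chain, child in enumerate(ss.spawn(mcmc.chains)):
        rng = np.random.default_rng(child)
        out = _run_chain(
            rng, m, w, ref_pos, yr_off, hab_idx, mig_idx, cell_idx, H, M, C,
            mcmc.warmup, n_keep, effect_prior_sd,
        )
        chains_lam.append(out["lam"])
        chains_theta.append(out["theta"])
        chains_gm.append(out["gm"])
        chains_sigma.append(out["sigma"])
        chains_tau.append(out["tau"])

    theta_chains = np.stack(chains_theta)  # (chains, draws, S)
    rhat = {
        "theta_max": float(np.max([_split_rhat(theta_chains[:, :, s]) for s in range(S)])),
        "sigma": _split_rhat(np.stack(chains_sigma)),
        "tau": _split_rhat(np.stack(chains_tau)),
    }
    worst = max(rhat.values())
    if worst > 1.05:
        warnings.warn(
            f"MCMC may not have converged: max split-R-hat {worst:.3f} > 1.05",
            stacklevel=2,
        )

    lam = np.concatenate(chains_lam)  # (chains*draws, S, Y)
    theta = np.concatenate(chains_theta)
    gm = np.concatenate(chains_gm)
    sigma = np.concatenate(chains_sigma)
    tau = np.concatenate(chains_tau)

    # Reference population is independent of the trend layer: draw directly.
    rng = np.random.default_rng(ss.spawn(1)[0])
    pop = np.exp(log_point + sigma_p * rng.standard_normal((lam.shape[0], S)))

    return Posterior(
        species_ids=ids,
        years=years,
        lam=lam,
        theta=theta,
        pop=pop,
        sigma=sigma,
        tau=tau,
        group_mean=gm,
        rhat=rhat,
        n_chains=mcmc.chains,
    )


def _has_estimate(s: SmoothedSeries, estimates) -> bool:
    if s.species_id not in estimates:
        logger.info("species %s dropped: no population estimate", s.species_id)
        return False
    return True


# ---------------------------------------------------------------------------
# Vectorised symmetric-tridiagonal linear algebra (LDL' factorisation), used
# to integrate the random-walk deviations out of the θ and η updates and to
# draw them from their Gaussian full conditional.  All routines operate on a
# batch of independent tridiagonal systems, one per species.
# ---------------------------------------------------------------------------


def _tridiag_ldl(pd, pe):
    """LDL' factors of batched symmetric tridiagonal matrices.

    ``pd`` (S, Y) diagonals, ``pe`` (S, Y-1) off-diagonals.  Returns
    ``c`` (S, Y) = diag(D) and ``l`` (S, Y-1) the unit-lower subdiagonal.
    """
    S, Y = pd.shape
    c = np.empty_like(pd)
    l = np.empty_like(pe)
    c[:, 0] = pd[:, 0]
    for j in range(Y - 1):
        l[:, j] = pe[:, j] / c[:, j]
        c[:, j + 1] = pd[:, j + 1] - pe[:, j] * l[:, j]
    return c, l


def _tridiag_solve(c, l, b):
    """Solve L D L' x = b for batched LDL factors (b is (S, Y))."""
    S, Y = b.shape
    z = np.empty_like(b)
    z[:, 0] = b[:, 0]
    for j in range(1, Y):
        z[:, j] = b[:, j] - l[:, j - 1] * z[:, j - 1]
    z /= c
    x = np.empty_like(b)
    x[:, -1] = z[:, -1]
    for j in range(Y - 2, -1, -1):
        x[:, j] = z[:, j] - l[:, j] * x[:, j + 1]
    return x


def _tridiag_sample(c, l, mean, rng):
    """Draw from N(mean, P^{-1}) where P = L D L' (batched)."""
    S, Y = mean.shape
    v = rng.standard_normal((S, Y)) / np.sqrt(c)
    x = np.empty_like(mean)
    x[:, -1] = v[:, -1]
    for j in range(Y - 2, -1, -1):
        x[:, j] = v[:, j] - l[:, j] * x[:, j + 1]
    return mean + x


_REF_PIN = 1e12  # pins the random-walk deviation to 0 at the reference year


def _rw_structure(ref_pos, Y):
    """Diag/off-diag templates of the anchored RW1 precision (unit variance)."""
    S = len(ref_pos)
    diag = np.full((S, Y), 2.0)
    diag[:, 0] = 1.0
    diag[:, -1] = 1.0
    off = np.full((S, Y - 1), -1.0)
    rows = np.arange(S)
    # decouple the pinned reference entry from its neighbours
    left = ref_pos - 1
    has_left = left >= 0
    off[rows[has_left], left[has_left]] = 0.0
    has_right = ref_pos <= Y - 2
    off[rows[has_right], ref_pos[has_right]] = 0.0
    return diag, off


def _run_chain(
    rng, m, w, ref_pos, yr_off, hab_idx, mig_idx, cell_idx, H, M, C,
    warmup, n_keep, effect_prior_sd,
):
    S, Y = m.shape
    inv_w = 1.0 / w
    sum_inv_w = inv_w.sum(axis=1)
    t = yr_off  # (S, Y) year offsets from the reference year
    rows = np.arange(S)
    rw_diag, rw_off = _rw_structure(ref_pos, Y)

    # state
    alpha = m[rows, ref_pos].copy()  # log index scale intercept
    theta = np.zeros(S)
    eps = np.zeros((S, Y))
    eta2 = np.full(S, 0.01**2)  # RW innovation variance, per species
    tau2 = 0.01**2
    mu = 0.0
    a = np.zeros(H)
    b = np.zeros(M)
    c_int = np.zeros(C)
    prior_prec_eff = 1.0 / effect_prior_sd**2
    # weak inverse-gamma hyperpriors on variances (shape, scale)
    a_eta, b_eta = 2.0, 1e-4
    a_tau, b_tau = 2.0, 1e-4
    n_incr = Y - 1  # free RW increments per species

    def factor(e2):
        """LDL factors and log-determinant of M = A(η²) + W^{-1}."""
        pd = rw_diag / e2[:, None] + inv_w
        pd[rows, ref_pos] += _REF_PIN
        pe = rw_off / e2[:, None]
        c, l = _tridiag_ldl(pd, pe)
        return c, l, np.sum(np.log(c), axis=1)

    def marginal_quad(c, l, resid):
        """resid' Σ^{-1} resid and Σ^{-1} resid, Σ = W + A^{-1} (Woodbury)."""
        u = inv_w * resid
        sol = _tridiag_solve(c, l, u)
        siginv_r = u - inv_w * sol
        return np.sum(resid * siginv_r, axis=1), siginv_r

    def eta_logpost(e2, resid):
        """log p(η² | θ, α, m) with the random walk integrated out."""
        c, l, logdet_m = factor(e2)
        quad, _ = marginal_quad(c, l, resid)
        # log|Σ| = log|M| − log|A| + log|W|; |A| ∝ η^{−2·n_incr}·pin (const)
        logdet_sigma = logdet_m + n_incr * np.log(e2)  # + const
        lp = -0.5 * (logdet_sigma + quad)
        return lp - (a_eta + 1.0) * np.log(e2) - b_eta / e2, (c, l)

    lam_keep = np.empty((n_keep, S, Y))
    theta_keep = np.empty((n_keep, S))
    gm_keep = np.empty((n_keep, S))
    eta_keep = np.empty(n_keep)
    tau_keep = np.empty(n_keep)

    lp_eta, (c_f, l_f) = eta_logpost(eta2, m - alpha[:, None] - theta[:, None] * t)

    for it in range(warmup + n_keep):
        r = m - alpha[:, None]

        # η_s² | θ, α, m — Metropolis on log η², ε marginalised (a conjugate
        # update from the ε increments is degenerate: ε is drawn shrunk
        # toward the current trajectory, so the variance would collapse)
        resid = r - theta[:, None] * t
        lp_eta, (c_f, l_f) = eta_logpost(eta2, resid)
        for _ in range(2):
            prop = eta2 * np.exp(0.6 * rng.standard_normal(S))
            lp_prop, fac_prop = eta_logpost(prop, resid)
            accept = (
                np.log(rng.random(S)) < lp_prop - lp_eta + np.log(prop / eta2)
            )
            eta2 = np.where(accept, prop, eta2)
            lp_eta = np.where(accept, lp_prop, lp_eta)
            c_f = np.where(accept[:, None], fac_prop[0], c_f)
            l_f = np.where(accept[:, None], fac_prop[1], l_f)

        # θ_s | α, η², τ², group mean, m — ε marginalised (collapsed)
        gmean = mu + a[hab_idx] + b[mig_idx] + c_int[cell_idx]
        _, siginv_t = marginal_quad(c_f, l_f, t)
        _, siginv_r = marginal_quad(c_f, l_f, r)
        t_sig_t = np.sum(t * siginv_t, axis=1)
        t_sig_r = np.sum(t * siginv_r, axis=1)
        prec_th = t_sig_t + 1.0 / tau2
        mean_th = (t_sig_r + gmean / tau2) / prec_th
        theta = mean_th + rng.standard_normal(S) / np.sqrt(prec_th)

        # ε | θ, α, η², m — Gaussian with tridiagonal precision M
        resid = r - theta[:, None] * t
        mean_eps = _tridiag_solve(c_f, l_f, inv_w * resid)
        eps = _tridiag_sample(c_f, l_f, mean_eps, rng)
        eps[rows, ref_pos] = 0.0
        lam = theta[:, None] * t + eps

        # α_s | λ, m — flat prior on the arbitrary index scale
        prec_a = sum_inv_w
        mean_a = np.sum((m - lam) * inv_w, axis=1) / prec_a
        alpha = mean_a + rng.standard_normal(S) / np.sqrt(prec_a)

        # group effects | θ, τ² (each block conditional on the others)
        resid_g = theta - a[hab_idx] - b[mig_idx] - c_int[cell_idx]
        mu = _normal_post(resid_g.sum(), S, tau2, prior_prec_eff, rng)
        resid_g = theta - mu - b[mig_idx] - c_int[cell_idx]
        a = _effect_post(resid_g, hab_idx, H, tau2, prior_prec_eff, rng)
        resid_g = theta - mu - a[hab_idx] - c_int[cell_idx]
        b = _effect_post(resid_g, mig_idx, M, tau2, prior_prec_eff, rng)
        resid_g = theta - mu - a[hab_idx] - b[mig_idx]
        # interaction gets a tighter prior (higher precision) to stay identifiable
        c_int = _effect_post(resid_g, cell_idx, C, tau2, 4.0 * prior_prec_eff, rng)

        # τ² | θ, group mean
        gmean = mu + a[hab_idx] + b[mig_idx] + c_int[cell_idx]
        sq = np.sum((theta - gmean) ** 2)
        tau2 = _inv_gamma(a_tau + S / 2.0, b_tau + sq / 2.0, rng)

        if it >= warmup:
            j = it - warmup
            lam_keep[j] = lam
            theta_keep[j] = theta
            gm_keep[j] = gmean
            eta_keep[j] = float(np.sqrt(eta2).mean())
            tau_keep[j] = np.sqrt(tau2)

    return {
        "lam": lam_keep,
        "theta": theta_keep,
        "gm": gm_keep,
        "sigma": eta_keep,
        "tau": tau_keep,
    }


def _normal_post(resid_sum, n, like_var, prior_prec, rng) -> float:
    prec = n / like_var + prior_prec
    mean = (resid_sum / like_var) / prec
    return mean + rng.standard_normal() / np.sqrt(prec)


def _effect_post(resid, idx, n_levels, like_var, prior_prec, rng) -> np.ndarray:
    sums = np.bincount(idx, weights=resid, minlength=n_levels)
    counts = np.bincount(idx, minlength=n_levels)
    prec = counts / like_var + prior_prec
    mean = (sums / like_var) / prec
    return mean + rng.standard_normal(n_levels) / np.sqrt(prec)


def _inv_gamma(shape, scale, rng) -> float:
    return float(scale / rng.gamma(shape))


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R̂ over a (chains, draws) array."""
    c, n = chains.shape
    half = n // 2
    if half < 2:
        return np.nan
    halves = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, k = halves.shape
    means = halves.mean(axis=1)
    variances = halves.var(axis=1, ddof=1)
    W = variances.mean()
    B = k * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_hat = (k - 1) / k * W + B / k
    return float(np.sqrt(var_hat / W))


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


def species_trajectories(
    posterior: Posterior, weights: np.ndarray | dict[str, float] | None = None
) -> np.ndarray:
    """Per-species abundance draws, shape (n_draws, S, Y): w_s·P_s·exp(λ_{s,y})."""
    wvec = _weight_vector(posterior, weights)
    return (
        wvec[None, :, None]
        * posterior.pop[:, :, None]
        * np.exp(posterior.lam)
    )


def total_trajectory(
    posterior: Posterior, weights: np.ndarray | dict[str, float] | None = None
) -> TotalTrajectory:
    """Posterior total T_y = Σ_s weight_s·P_s·exp(λ_{s,y}) with 95% bounds."""
    per_species = species_trajectories(posterior, weights)
    totals = per_species.sum(axis=1)
    return TotalTrajectory.from_draws(posterior.years, totals)


def _weight_vector(posterior: Posterior, weights) -> np.ndarray:
    S = len(posterior.species_ids)
    if weights is None:
        return np.ones(S)
    if isinstance(weights, dict):
        return np.array([weights[i] for i in posterior.species_ids], dtype=float)
    w = np.asarray(weights, dtype=float)
    if len(w) != S:
        raise ValueError("weights length must match number of species")
    return w
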
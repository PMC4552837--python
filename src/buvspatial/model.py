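"""Bayesian logistic presence models with and without a GP random effect.

Model
-----
For deployment t at site s, ``P(Y_t(s)=1) = p_t(s)`` with

    logit(p_t(s)) = X_t(s) beta + eta(s)

where ``eta`` is a zero-mean Gaussian process over site coordinates with
exponential covariance ``sigma2 * exp(-phi * ||s_i - s_j||)`` (distances in
meters). The non-spatial model drops ``eta``. Priors: independent normals on
each beta, a uniform prior on the inverse decay 1/phi (meters) and an
inverse-gamma prior on sigma2. The effective range — the distance at which
correlation falls to 0.05 — is approximately 3/phi for this kernel.

Inference
---------
Polya-Gamma data augmentation gives exact conjugate Gaussian updates for
beta and eta and a conjugate inverse-gamma update for sigma2; the decay
parameter moves by random-walk Metropolis on the logit-transformed inverse
decay within its prior bounds, with the proposal scale adapted during
burn-in only. The augmented chain targets the stated posterior exactly up
to the (mean-corrected, truncated) series representation used for the
PG(1,z) draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.spatial.distance import cdist
from scipy.stats import invgamma

from .survey import (
    DESIGN_COLUMNS,
    StandardizationParams,
    SurveyDataset,
    build_design_matrix,
    standardize_covariates,
)


class SeparationError(ValueError):
    """The response is single-class; the logistic fit is degenerate."""


# ---------------------------------------------------------------------------
# Polya-Gamma draws
# ---------------------------------------------------------------------------

def pg_mean(z: np.ndarray) -> np.ndarray:
    """E[PG(1, z)] = tanh(z/2) / (2 z), with the z->0 limit 1/4."""
    z = np.asarray(z, dtype=float)
    out = np.full(z.shape, 0.25)
    big = np.abs(z) > 1e-6
    zb = z[big]
    out[big] = np.tanh(zb / 2.0) / (2.0 * zb)
    return out


def sample_pg(rng: np.random.Generator, z: np.ndarray, trunc: int = 200) -> np.ndarray:
    """Draw PG(1, z_i) for each entry of ``z``.

    Uses the infinite-sum representation
    ``PG(1,z) = (1/(2 pi^2)) * sum_k E_k / ((k-1/2)^2 + z^2/(4 pi^2))``
    with ``E_k ~ Exp(1)``, truncated at ``trunc`` terms plus the exact mean
    of the dropped tail as a deterministic top-up, so the draw's mean is
    exact and the neglected stochastic tail is O(1/trunc) in variance.
    """
    z = np.abs(np.asarray(z, dtype=float))
    c2 = (z / (2.0 * np.pi)) ** 2  # (n,)
    k = np.arange(1, trunc + 1) - 0.5  # (m,)
    denom = k[:, None] ** 2 + c2[None, :]  # (m, n)
    e = rng.standard_exponential(size=denom.shape)
    partial = (e / denom).sum(axis=0) / (2.0 * np.pi**2)
    trunc_mean = (1.0 / denom).sum(axis=0) / (2.0 * np.pi**2)
    return partial + (pg_mean(z) - trunc_mean)


# ---------------------------------------------------------------------------
# Covariance and priors
# ---------------------------------------------------------------------------

def _coords_array(sites) -> np.ndarray:
    if isinstance(sites, pd.DataFrame):
        return sites[["easting", "northing"]].to_numpy(dtype=float)
    return np.asarray(sites, dtype=float)


def exp_covariance(sites, sigma2: float, phi: float, jitter: float = 0.0) -> np.ndarray:
    """Exponential covariance matrix ``sigma2 * exp(-phi * d_ij)``.

    ``jitter`` is a relative diagonal nugget: the diagonal becomes
    ``sigma2 * (1 + jitter)`` to stabilize Cholesky factorization.
    """
    if sigma2 <= 0 or phi <= 0:
        raise ValueError("require sigma2 > 0 and phi > 0")
    coords = _coords_array(sites)
    d = cdist(coords, coords)
    C = sigma2 * np.exp(-phi * d)
    if jitter:
        C[np.diag_indices_from(C)] += sigma2 * jitter
    return C


def effective_range(phi) -> float:
    """Distance at which the exponential correlation drops to ~0.05: 3/phi."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi <= 0):
        raise ValueError("phi must be > 0")
    out = 3.0 / phi
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the beta, sigma2 and phi priors.

    ``beta_scale`` is read as the *variance* of the independent N(0, .)
    coefficient priors when ``beta_scale_is_variance`` (the default); set it
    False to read the same number as a standard deviation. The prior on the
    inverse decay 1/phi is uniform on (inv_phi_lower, inv_phi_upper) meters;
    sigma2 has an inverse-gamma prior with the given shape and scale.
    """

    beta_scale: float = 2.5
    beta_scale_is_variance: bool = True
    inv_phi_lower: float = 50.0
    inv_phi_upper: float = 1500.0
    sigma2_shape: float = 2.0
    sigma2_scale: float = 2.0

    def __post_init__(self) -> None:
        if self.beta_scale <= 0:
            raise ValueError("beta_scale must be > 0")
        if not 0 < self.inv_phi_lower < self.inv_phi_upper:
            raise ValueError("require 0 < inv_phi_lower < inv_phi_upper")
        if self.sigma2_shape <= 0 or self.sigma2_scale <= 0:
            raise ValueError("sigma2 hyperparameters must be > 0")

    @property
    def beta_variance(self) -> float:
        return self.beta_scale if self.beta_scale_is_variance \
            else self.beta_scale**2


@dataclass
class FitConfig:
    """MCMC settings.

    ``thin=None`` resolves to the model-specific default: keep every 2nd
    iterate for the non-spatial model and every 10th for the spatial model
    (the spatial chain mixes more slowly through eta, sigma2 and phi).
    ``columns`` optionally restricts the design matrix to a subset of
    :data:`~buvspatial.survey.DESIGN_COLUMNS`. ``fix_sigma2``/``fix_phi``
    pin those parameters (no update), e.g. to study the sigma2 -> 0 limit.
    """

    spatial: bool = True
    n_retained: int = 5000
    burn_in: int = 1000
    thin: int | None = None
    seed: int = 0
    jitter: float = 1e-8
    phi_proposal_scale: float = 0.8
    adapt_proposal: bool = True
    fix_sigma2: float | None = None
    fix_phi: float | None = None
    columns: tuple | None = None
    pg_trunc: int = 200

    def __post_init__(self) -> None:
        if self.n_retained < 1 or self.burn_in < 1:
            raise ValueError("n_retained and burn_in must be >= 1")
        if self.thin is not None and self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        if self.columns is not None:
            unknown = set(self.columns) - set(DESIGN_COLUMNS)
            if unknown:
                raise ValueError(f"unknown design columns: {sorted(unknown)}")
            self.columns = tuple(self.columns)

    @property
    def resolved_thin(self) -> int:
        if self.thin is not None:
            return self.thin
        return 10 if self.spatial else 2


@dataclass
class PosteriorDraws:
    """Retained MCMC samples plus the context needed for prediction."""

    beta: np.ndarray                       # (M, p)
    columns: tuple                         # design-column names, length p
    sites: pd.DataFrame                    # unique (site_id, easting, northing)
    spatial: bool
    eta: np.ndarray | None = None          # (M, n_sites), spatial only
    sigma2: np.ndarray | None = None       # (M,), spatial only
    phi: np.ndarray | None = None          # (M,), spatial only
    std_params: StandardizationParams | None = None
    acceptance: dict = field(default_factory=dict)
    priors: PriorSpec | None = None

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def to_table(self, path) -> None:
        """Persist as TSV: one row per draw, context in '#' header lines."""
        cols = {f"beta_{name}": self.beta[:, j]
                for j, name in enumerate(self.columns)}
        if self.spatial:
            cols["sigma2"] = self.sigma2
            cols["phi"] = self.phi
            for j, sid in enumerate(self.sites["site_id"]):
                cols[f"eta_{sid}"] = self.eta[:, j]
        frame = pd.DataFrame(cols)
        lines = [f"# spatial={int(self.spatial)}"]
        if self.std_params is not None:
            for key, val in self.std_params.to_dict().items():
                lines.append(f"# std {key}={val!r}")
        for _, row in self.sites.iterrows():
            lines.append(
                f"# site {row['site_id']} {row['easting']!r} {row['northing']!r}"
            )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
            frame.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_table(cls, path) -> "PosteriorDraws":
        std = {}
        site_rows = []
        spatial = False
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                parts = line[1:].split()
                if parts[0].startswith("spatial="):
                    spatial = bool(int(parts[0].split("=")[1]))
                elif parts[0] == "std":
                    key, val = parts[1].split("=")
                    std[key] = float(val)
                elif parts[0] == "site":
                    site_rows.append(
                        (parts[1], float(parts[2]), float(parts[3]))
                    )
        frame = pd.read_csv(path, sep="\t", comment="#")
        sites = pd.DataFrame(site_rows,
                             columns=["site_id", "easting", "northing"])
        beta_cols = [c for c in frame.columns if c.startswith("beta_")]
        draws = cls(
            beta=frame[beta_cols].to_numpy(),
            columns=tuple(c[len("beta_"):] for c in beta_cols),
            sites=sites,
            spatial=spatial,
            std_params=StandardizationParams(**std) if std else None,
        )
        if spatial:
            draws.sigma2 = frame["sigma2"].to_numpy()
            draws.phi = frame["phi"].to_numpy()
            draws.eta = frame[
                [f"eta_{sid}" for sid in sites["site_id"]]
            ].to_numpy()
        return draws


# ---------------------------------------------------------------------------
# Posterior density
# ---------------------------------------------------------------------------

def bernoulli_log_likelihood(beta, eta, data: SurveyDataset,
                             columns: tuple | None = None) -> float:
    """Sum of y*log(p) + (1-y)*log(1-p) at logit(p) = X beta + eta(site)."""
    X, y, obs_site = _design(data, columns)
    psi = X @ np.asarray(beta, dtype=float)
    if eta is not None:
        psi = psi + np.asarray(eta, dtype=float)[obs_site]
    if not np.all(np.isfinite(psi)):
        raise ValueError("non-finite linear predictor")
    return float(np.sum(y * psi - np.logaddexp(0.0, psi)))


def log_prior(beta, eta, sigma2, phi, data: SurveyDataset,
              priors: PriorSpec, spatial: bool, jitter: float = 0.0) -> float:
    beta = np.asarray(beta, dtype=float)
    bv = priors.beta_variance
    lp = float(-0.5 * np.sum(beta**2) / bv
               - 0.5 * beta.size * np.log(2.0 * np.pi * bv))
    if not spatial:
        return lp
    if sigma2 is None or phi is None or eta is None:
        raise ValueError("spatial log prior needs eta, sigma2 and phi")
    if sigma2 <= 0 or phi <= 0:
        return -np.inf
    inv_phi = 1.0 / phi
    if not priors.inv_phi_lower < inv_phi < priors.inv_phi_upper:
        return -np.inf
    lp -= np.log(priors.inv_phi_upper - priors.inv_phi_lower)
    lp += float(invgamma.logpdf(sigma2, priors.sigma2_shape,
                                scale=priors.sigma2_scale))
    C = exp_covariance(data.site_coords(), sigma2, phi, jitter=jitter)
    chol = np.linalg.cholesky(C)
    w = solve_triangular(chol, np.asarray(eta, dtype=float), lower=True)
    lp += float(-0.5 * w @ w - np.log(np.diag(chol)).sum()
                - 0.5 * len(w) * np.log(2.0 * np.pi))
    return lp


def log_posterior(beta, eta, sigma2, phi, data: SurveyDataset,
                  priors: PriorSpec, spatial: bool,
                  columns: tuple | None = None) -> float:
    """Unnormalized log posterior: Bernoulli log-likelihood + log priors.

    Returns -inf when 1/phi falls outside its uniform prior bounds or
    sigma2 <= 0 (spatial model).
    """
    prior = log_prior(beta, eta, sigma2, phi, data, priors, spatial)
    if not np.isfinite(prior):
        return prior
    return bernoulli_log_likelihood(
        beta, eta if spatial else None, data, columns
    ) + prior


def _design(data: SurveyDataset, columns: tuple | None):
    X = build_design_matrix(data)
    if columns is not None:
        idx = [DESIGN_COLUMNS.index(c) for c in columns]
        X = X[:, idx]
    return X, data.presence.astype(float), data.obs_to_site


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

def _sample_gaussian(rng, precision: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Draw from N(precision^-1 shift, precision^-1) via Cholesky."""
    L = np.linalg.cholesky(precision)
    mean = cho_solve((L, True), shift)
    z = rng.standard_normal(len(shift))
    return mean + solve_triangular(L.T, z, lower=False)


def fit_model(data: SurveyDataset, priors: PriorSpec | None = None,
              config: FitConfig | None = None) -> PosteriorDraws:
    """Fit the spatial or non-spatial logistic model by PG-augmented Gibbs.

    Depth and visibility are standardized internally when the dataset is
    raw; the standardization constants travel with the returned draws so
    predictions on new data reuse them. Exactly ``n_retained`` draws are
    returned, taken every ``thin`` iterations after ``burn_in``.
    """
    priors = priors or PriorSpec()
    config = config or FitConfig()
    if data.standardized:
        std_data, std_params = data, None
    else:
        std_data, std_params = standardize_covariates(data)
    X, y, obs_site = _design(std_data, config.columns)
    if y.min() == y.max():
        raise SeparationError("response is all-0 or all-1; cannot fit")
    n, p = X.shape
    columns = config.columns or DESIGN_COLUMNS
    rng = np.random.default_rng(config.seed)
    thin = config.resolved_thin
    n_iter = config.burn_in + config.n_retained * thin
    kappa = y - 0.5
    bv = priors.beta_variance

    beta = np.zeros(p)
    beta_draws = np.empty((config.n_retained, p))

    if not config.spatial:
        for it in range(n_iter):
            omega = sample_pg(rng, X @ beta, config.pg_trunc)
            prec = (X.T * omega) @ X + np.eye(p) / bv
            beta = _sample_gaussian(rng, prec, X.T @ kappa)
            if it >= config.burn_in and (it - config.burn_in) % thin == thin - 1:
                beta_draws[(it - config.burn_in) // thin] = beta
        return PosteriorDraws(
            beta=beta_draws, columns=tuple(columns), sites=data.sites.copy(),
            spatial=False, std_params=std_params, priors=priors,
        )

    # -- spatial model ------------------------------------------------------
    coords = data.site_coords()
    S = len(coords)
    dist = cdist(coords, coords)
    lo, hi = priors.inv_phi_lower, priors.inv_phi_upper
    inv_phi = float(np.clip(1.0 / config.fix_phi, lo + 1e-9, hi - 1e-9)) \
        if config.fix_phi else 0.5 * (lo + hi)
    sigma2 = config.fix_sigma2 if config.fix_sigma2 is not None else 1.0
    if sigma2 <= 0:
        raise ValueError("fix_sigma2 must be > 0 (use a small value for the "
                         "sigma2 -> 0 limit)")
    eta = np.zeros(S)
    eye_jitter = config.jitter * np.eye(S)

    def corr_factor(r):
        R = np.exp(-dist / r) + eye_jitter
        try:
            return R, cho_factor(R, lower=True)
        except np.linalg.LinAlgError as err:  # pragma: no cover - guard
            raise np.linalg.LinAlgError(
                "covariance factorization failed; increase FitConfig.jitter"
            ) from err

    R, cho_R = corr_factor(inv_phi)
    Rinv = cho_solve(cho_R, np.eye(S))
    logdet_R = 2.0 * np.log(np.diag(cho_R[0])).sum()

    eta_draws = np.empty((config.n_retained, S))
    sigma2_draws = np.empty(config.n_retained)
    phi_draws = np.empty(config.n_retained)
    step = config.phi_proposal_scale
    acc_window, acc_total, n_after_burn = [], 0, 0

    theta = np.log((inv_phi - lo) / (hi - inv_phi))
    for it in range(n_iter):
        eta_obs = eta[obs_site]
        omega = sample_pg(rng, X @ beta + eta_obs, config.pg_trunc)

        prec_b = (X.T * omega) @ X + np.eye(p) / bv
        beta = _sample_gaussian(rng, prec_b, X.T @ (kappa - omega * eta_obs))

        xb = X @ beta
        w_site = np.bincount(obs_site, weights=omega, minlength=S)
        shift = np.bincount(obs_site, weights=kappa - omega * xb, minlength=S)
        prec_e = Rinv / sigma2 + np.diag(w_site)
        eta = _sample_gaussian(rng, prec_e, shift)

        quad = float(eta @ (Rinv @ eta))
        if config.fix_sigma2 is None:
            sigma2 = float(invgamma.rvs(
                priors.sigma2_shape + 0.5 * S,
                scale=priors.sigma2_scale + 0.5 * quad,
                random_state=rng,
            ))

        if config.fix_phi is None:
            theta_prop = theta + step * rng.standard_normal()
            u = 1.0 / (1.0 + np.exp(-theta_prop))
            r_prop = lo + (hi - lo) * u
            R_p, cho_p = corr_factor(r_prop)
            quad_p = eta @ cho_solve(cho_p, eta)
            logdet_p = 2.0 * np.log(np.diag(cho_p[0])).sum()
            u_cur = (inv_phi - lo) / (hi - lo)
            log_ratio = (
                -0.5 * (logdet_p - logdet_R)
                - 0.5 * (quad_p - quad) / sigma2
                + np.log(u * (1 - u)) - np.log(u_cur * (1 - u_cur))
            )
            accept = np.log(rng.random()) < log_ratio
            if accept:
                theta, inv_phi = theta_prop, r_prop
                R, cho_R, logdet_R = R_p, cho_p, logdet_p
                Rinv = cho_solve(cho_R, np.eye(S))
            if it < config.burn_in:
                acc_window.append(accept)
                if config.adapt_proposal and len(acc_window) == 50:
                    rate = np.mean(acc_window)
                    step = float(np.clip(step * np.exp(rate - 0.35),
                                         1e-3, 10.0))
                    acc_window = []
            else:
                acc_total += int(accept)
                n_after_burn += 1

        if it >= config.burn_in and (it - config.burn_in) % thin == thin - 1:
            m = (it - config.burn_in) // thin
            beta_draws[m] = beta
            eta_draws[m] = eta
            sigma2_draws[m] = sigma2
            phi_draws[m] = 1.0 / inv_phi

    acceptance = {"phi": acc_total / n_after_burn if n_after_burn else None,
                  "phi_step": step}
    return PosteriorDraws(
        beta=beta_draws, columns=tuple(columns), sites=data.sites.copy(),
        spatial=True, eta=eta_draws, sigma2=sigma2_draws, phi=phi_draws,
        std_params=std_params, acceptance=acceptance, priors=priors,
    )


def nonspatial_config(config: FitConfig) -> FitConfig:
    """The non-spatial counterpart of ``config`` (model-default thinning)."""
    return dataclasses.replace(config, spatial=False, thin=None
                               if config.thin is None else config.thin)
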
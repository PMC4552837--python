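"""Synthetic BUV surveys with the statistical structure the models assume.

The generator emulates the sampled design of a coastal monitoring program:
sites grouped in clusters along an elongated near-shore band, a minimum
inter-site distance, repeat deployments of most sites across five seasonal
time points, protection-status zones that switch from open to no-take
partway through the study, spatially clumped habitat indicators (thresholded
Gaussian-process draws) and a presence response generated from
``logit(p) = X beta + eta`` with ``eta`` a zero-mean Gaussian process with
exponential covariance shared by all deployments of a site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .model import exp_covariance
from .survey import DESIGN_COLUMNS, HABITAT_COLUMNS, SurveyDataset, \
    build_design_matrix, standardize_covariates


class GenerationError(RuntimeError):
    """Site placement infeasible under the configured minimum distance."""


#: Coefficients (logit scale, standardized covariates, DESIGN_COLUMNS order)
#: in the regime of the study's non-spatial fit: strong positive kelp and
#: coffee-rock effects, moderate winter/visibility/depth effects, weak
#: protection-status effects, null sand effect.
DEFAULT_BETA = np.array(
    [-1.3, -0.40, -0.12, 0.28, 0.54, 2.30, -0.01, 1.16, 0.64, 0.31]
)

# Seasonal schedule: five time points (3 winters, 2 summers); the new
# no-take zones take effect from the third time point onward.
SEASON_SCHEDULE = ("winter", "summer", "winter", "summer", "winter")
CLOSURE_TIME = 2


@dataclass
class SimulationConfig:
    """Parameters of the synthetic survey design.

    Defaults target the scale of the emulated study: 6 clusters x 29 sites
    = 174 sites in a 30 km x 3 km coastal band, ~536 deployments (each site
    visited once plus each remaining time point with probability 0.52),
    minimum inter-site distance 20 m, GP variance 1 and effective range
    3/phi_true = 2000 m.
    """

    n_clusters: int = 6
    sites_per_cluster: int = 29
    cluster_spread: float = 600.0          # site scatter around centers, m
    band_length: float = 30_000.0          # alongshore extent, m
    band_width: float = 3_000.0            # cross-shore extent, m
    min_site_distance: float = 20.0        # m
    revisit_probability: float = 0.52      # per extra time point
    habitat_prevalences: dict = field(
        default_factory=lambda: {
            "rock": 0.35, "kelp": 0.20, "sand": 0.50, "coffee_rock": 0.25
        }
    )
    habitat_clump_range: float = 500.0     # effective range of habitat GPs, m
    beta_true: np.ndarray = field(default_factory=lambda: DEFAULT_BETA.copy())
    sigma2_true: float = 1.0
    phi_true: float = 3.0 / 2000.0         # 1/m
    seed: int = 0
    max_placement_retries: int = 1000

    def __post_init__(self) -> None:
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        if self.beta_true.shape != (len(DESIGN_COLUMNS),):
            raise ValueError(f"beta_true must have {len(DESIGN_COLUMNS)} entries")
        if not 0 <= self.revisit_probability <= 1:
            raise ValueError("revisit_probability must be in [0, 1]")
        if any(not 0 <= p <= 1 for p in self.habitat_prevalences.values()):
            raise ValueError("habitat prevalences must be in [0, 1]")
        if self.sigma2_true < 0 or self.phi_true <= 0:
            raise ValueError("require sigma2_true >= 0 and phi_true > 0")
        if self.min_site_distance < 0:
            raise ValueError("min_site_distance must be >= 0")


def _place_sites(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample clustered site coordinates inside the band."""
    n_total = config.n_clusters * config.sites_per_cluster
    centers_x = (np.arange(config.n_clusters) + 0.5) / config.n_clusters
    centers = np.column_stack(
        [
            centers_x * config.band_length,
            np.full(config.n_clusters, 0.5 * config.band_width),
        ]
    )
    centers += rng.normal(
        scale=[0.03 * config.band_length, 0.1 * config.band_width],
        size=centers.shape,
    )
    coords = np.empty((n_total, 2))
    placed = 0
    min_d2 = config.min_site_distance**2
    for c in range(config.n_clusters):
        for _ in range(config.sites_per_cluster):
            for _attempt in range(config.max_placement_retries):
                pt = centers[c] + rng.normal(scale=config.cluster_spread, size=2)
                if not (
                    0 <= pt[0] <= config.band_length
                    and 0 <= pt[1] <= config.band_width
                ):
                    continue
                if placed and (
                    np.sum((coords[:placed] - pt) ** 2, axis=1).min() < min_d2
                ):
                    continue
                coords[placed] = pt
                placed += 1
                break
            else:
                raise GenerationError(
                    "could not place a site at the configured minimum distance "
                    f"after {config.max_placement_retries} retries"
                )
    return coords


def _status_zones(config: SimulationConfig, coords: np.ndarray, t: int) -> np.ndarray:
    """Time-varying protection status from axis-aligned zone rectangles."""
    L = config.band_length
    x = coords[:, 0]
    old = ((0.05 * L <= x) & (x < 0.18 * L)) | ((0.55 * L <= x) & (x < 0.68 * L))
    new = ((0.18 * L <= x) & (x < 0.28 * L)) | ((0.68 * L <= x) & (x < 0.80 * L))
    status = np.where(old, "green_old", "open").astype(object)
    if t >= CLOSURE_TIME:
        status[new] = "green_new"
    return status


def _clumped_habitats(
    config: SimulationConfig, coords: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """One thresholded unit-variance GP per habitat, exponential covariance."""
    n = len(coords)
    phi_h = 3.0 / config.habitat_clump_range
    R = exp_covariance(coords, 1.0, phi_h, jitter=1e-8)
    L = np.linalg.cholesky(R)
    out = {}
    for hab in HABITAT_COLUMNS:
        prev = config.habitat_prevalences[hab]
        z = L @ rng.standard_normal(n)
        out[hab] = (z > ndtri(1.0 - prev)).astype(int) if 0 < prev < 1 else \
            np.full(n, int(prev >= 1))
    return out


def generate_survey(config: SimulationConfig | None = None,
                    rng: np.random.Generator | None = None) -> SurveyDataset:
    """Generate the survey design; the presence column is left unset (NaN).

    Sites are placed in clusters inside the coastal band with all pairwise
    distances >= ``min_site_distance``; each site receives one guaranteed
    deployment at a random time point plus independent extra deployments,
    so season/status/visibility vary across repeat visits of a site.
    """
    config = config or SimulationConfig()
    rng = rng or np.random.default_rng(config.seed)
    coords = _place_sites(config, rng)
    n_sites = len(coords)
    habitats = _clumped_habitats(config, coords, rng)
    # depth increases offshore (across the band) with local relief
    depth = 12.0 + 30.0 * coords[:, 1] / config.band_width \
        + rng.normal(scale=3.0, size=n_sites)
    depth = np.clip(depth, 5.0, 47.0)

    n_t = len(SEASON_SCHEDULE)
    guaranteed = rng.integers(n_t, size=n_sites)
    rows = []
    for s in range(n_sites):
        visits = set(np.flatnonzero(
            rng.random(n_t) < config.revisit_probability
        )) | {int(guaranteed[s])}
        for t in sorted(visits):
            rows.append((s, t))
    rows = np.array(rows)
    site_idx, times = rows[:, 0], rows[:, 1]
    visibility = np.exp(rng.normal(loc=2.0, scale=0.4, size=len(rows)))
    status_by_t = [_status_zones(config, coords, t) for t in range(n_t)]
    obs = pd.DataFrame(
        {
            "site_id": [f"s{int(s):03d}" for s in site_idx],
            "easting": coords[site_idx, 0],
            "northing": coords[site_idx, 1],
            "season": [SEASON_SCHEDULE[t] for t in times],
            "status": [status_by_t[t][s] for s, t in zip(site_idx, times)],
            "depth": depth[site_idx],
            "visibility": visibility,
            "rock": habitats["rock"][site_idx],
            "kelp": habitats["kelp"][site_idx],
            "sand": habitats["sand"][site_idx],
            "coffee_rock": habitats["coffee_rock"][site_idx],
            "presence": np.nan,
        }
    )
    return SurveyDataset(obs)


def simulate_presence(
    data: SurveyDataset,
    beta: np.ndarray,
    sigma2: float,
    phi: float,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw presence from ``logit(p) = X beta + eta(site)``.

    ``eta`` is drawn once per unique site from N(0, sigma2 * Sigma(phi))
    with exponential covariance, so repeat deployments of a site share the
    same latent effect. ``beta`` applies to the standardized design matrix
    (depth/visibility are standardized internally when needed). Returns
    ``(presence, eta_true)`` with presence per observation and eta per site.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    if sigma2 < 0 or phi <= 0:
        raise ValueError("require sigma2 >= 0 and phi > 0")
    std = data if data.standardized else standardize_covariates(data)[0]
    X = build_design_matrix(std)
    n_sites = data.n_sites
    if sigma2 > 0:
        C = exp_covariance(data.site_coords(), sigma2, phi, jitter=1e-8)
        eta = np.linalg.cholesky(C) @ rng.standard_normal(n_sites)
    else:
        eta = np.zeros(n_sites)
    linpred = X @ beta + eta[data.obs_to_site]
    if not np.all(np.isfinite(linpred)):
        raise ValueError("non-finite linear predictor")
    p = expit(linpred)
    presence = (rng.random(data.n_obs) < p).astype(int)
    return presence, eta


def simulate_survey(
    config: SimulationConfig | None = None,
) -> tuple[SurveyDataset, dict]:
    """Generate a complete survey (design + presence) and return the truth.

    The returned dict holds ``beta``, ``sigma2``, ``phi`` and ``eta`` used
    to generate the response, for parameter-recovery checks.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    data = generate_survey(config, rng)
    presence, eta = simulate_presence(
        data, config.beta_true, config.sigma2_true, config.phi_true, rng
    )
    obs = data.obs.copy()
    obs["presence"] = presence
    truth = {
        "beta": config.beta_true.copy(),
        "sigma2": config.sigma2_true,
        "phi": config.phi_true,
        "eta": eta,
    }
    return data.with_obs(obs), truth
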
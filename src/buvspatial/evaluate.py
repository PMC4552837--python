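"""Model comparison: within-sample metrics and location-blocked k-fold CV.

Three criteria compare the spatial and non-spatial fits: the posterior mean
Bernoulli log-likelihood (LL), mean squared error (MSE) between response and
predicted probability, and the area under the ROC curve (AUC), each computed
per retained posterior draw and summarized by mean and central 95% interval.
Cross-validation blocks by location — every repeat deployment of a site
lands in the site's fold — and predicts the latent spatial effect at
held-out sites by conditional-Gaussian (kriging) draws per posterior sample.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from .model import FitConfig, PosteriorDraws, PriorSpec, fit_model
from .report import central_interval
from .survey import DESIGN_COLUMNS, SurveyDataset, build_design_matrix, \
    standardize_covariates

_PROB_CLIP = 1e-12


class UndefinedMetricError(ValueError):
    """AUC is undefined when the response is single-class."""


@dataclass
class MetricSummary:
    metric: str                      # one of {"LL", "MSE", "AUC"}
    posterior_mean: float
    interval_low: float
    interval_high: float
    per_draw_values: np.ndarray

    @classmethod
    def from_draws(cls, metric: str, values: np.ndarray) -> "MetricSummary":
        values = np.asarray(values, dtype=float)
        lo, hi = central_interval(values, 0.95)
        return cls(metric, float(values.mean()), lo, hi, values)


@dataclass
class FoldAssignment:
    """Location-blocked fold labels: one fold per site, inherited by obs."""

    k: int
    site_to_fold: dict
    seed: int

    def fold_of_obs(self, data: SurveyDataset) -> np.ndarray:
        return np.array(
            [self.site_to_fold[sid] for sid in data.obs["site_id"]], dtype=int
        )


def assign_location_folds(data: SurveyDataset, k: int, seed: int) -> FoldAssignment:
    """Deal sites into k near-equal folds from a seeded permutation."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if data.n_sites < k:
        raise ValueError("fewer sites than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(data.n_sites)
    folds = np.empty(data.n_sites, dtype=int)
    folds[perm] = np.arange(data.n_sites) % k
    return FoldAssignment(
        k=k,
        site_to_fold=dict(zip(data.sites["site_id"], folds)),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Kriging (conditional GP prediction)
# ---------------------------------------------------------------------------

def krige_moments(eta_train, sigma2, phi, train_coords, new_coords,
                  jitter: float = 0.0):
    """Conditional mean and covariance of eta at new sites given one draw.

    With C = sigma2*(Sigma_train + jitter*I) and c the train-new
    cross-covariance: mean = c' C^-1 eta_train and covariance
    sigma2*Sigma_new - c' C^-1 c.
    """
    train_coords = np.asarray(train_coords, dtype=float)
    new_coords = np.asarray(new_coords, dtype=float)
    eta_train = np.asarray(eta_train, dtype=float)
    C = sigma2 * np.exp(-phi * cdist(train_coords, train_coords))
    if jitter:
        C[np.diag_indices_from(C)] += sigma2 * jitter
    c = sigma2 * np.exp(-phi * cdist(train_coords, new_coords))
    try:
        chol = cho_factor(C, lower=True)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "training covariance factorization failed; pass jitter > 0"
        ) from err
    Cinv_c = cho_solve(chol, c)
    mean = Cinv_c.T @ eta_train
    cov = sigma2 * np.exp(-phi * cdist(new_coords, new_coords)) - c.T @ Cinv_c
    return mean, cov


def krige_random_effect(eta_train, sigma2, phi, train_coords, new_coords,
                        rng: np.random.Generator, jitter: float = 0.0,
                        mean_only: bool = False) -> np.ndarray:
    """Sample eta at new sites from its conditional Gaussian (one draw).

    ``mean_only=True`` returns the conditional mean instead of a draw — a
    diagnostic mode; posterior predictive evaluation samples, since the new
    site's effect is itself uncertain.
    """
    mean, cov = krige_moments(eta_train, sigma2, phi, train_coords,
                              new_coords, jitter)
    if mean_only:
        return mean
    # eigendecomposition tolerates the exactly-singular coincident-site case
    vals, vecs = np.linalg.eigh(0.5 * (cov + cov.T))
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    return mean + root @ rng.standard_normal(len(mean))


# ---------------------------------------------------------------------------
# Posterior predictive probabilities
# ---------------------------------------------------------------------------

def predict_probabilities(draws: PosteriorDraws, data: SurveyDataset,
                          rng: np.random.Generator | None = None,
                          krige_mean_only: bool = False,
                          jitter: float = 1e-10) -> np.ndarray:
    """Per-draw presence probabilities: (n_retained, n_obs) matrix.

    Covariates are standardized with the training constants carried by
    ``draws``. For the spatial model, sites absent from the training set
    need their latent effect kriged: pass ``rng`` to enable it, otherwise
    an unknown site raises an error directing to
    :func:`krige_random_effect`.
    """
    if not data.standardized:
        if draws.std_params is None:
            raise ValueError("dataset is unstandardized and the draws carry "
                             "no standardization constants")
        data = standardize_covariates(data, draws.std_params)[0]
    X = build_design_matrix(data)
    if draws.columns != DESIGN_COLUMNS:
        idx = [DESIGN_COLUMNS.index(c) for c in draws.columns]
        X = X[:, idx]
    linpred = draws.beta @ X.T  # (M, n_obs)
    if draws.spatial:
        train_ids = {sid: j for j, sid in enumerate(draws.sites["site_id"])}
        known = np.array([sid in train_ids for sid in data.sites["site_id"]])
        site_eta = np.zeros((draws.n_draws, data.n_sites))
        for j, sid in enumerate(data.sites["site_id"]):
            if known[j]:
                site_eta[:, j] = draws.eta[:, train_ids[sid]]
        if not known.all():
            if rng is None:
                raise ValueError(
                    "data contains sites not seen in fitting; supply rng to "
                    "draw their effects via krige_random_effect"
                )
            train_coords = draws.sites[["easting", "northing"]].to_numpy()
            new_coords = data.site_coords()[~known]
            cols = np.flatnonzero(~known)
            for m in range(draws.n_draws):
                site_eta[m, cols] = krige_random_effect(
                    draws.eta[m], draws.sigma2[m], draws.phi[m],
                    train_coords, new_coords, rng, jitter=jitter,
                    mean_only=krige_mean_only,
                )
        linpred = linpred + site_eta[:, data.obs_to_site]
    return expit(linpred)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def auc(y, p) -> float:
    """Area under the ROC curve; ties credited 1/2 (Mann-Whitney form)."""
    y = np.asarray(y)
    if y.min() == y.max():
        raise UndefinedMetricError("AUC undefined for a single-class response")
    return float(roc_auc_score(y, np.asarray(p, dtype=float)))


def metric_summaries(y, prob_matrix,
                     nan_auc_if_single_class: bool = False
                     ) -> dict[str, MetricSummary]:
    """Per-draw LL, MSE and AUC, summarized by mean and 95% interval.

    A single-class response leaves AUC undefined: by default this raises
    :class:`UndefinedMetricError`; with ``nan_auc_if_single_class`` the AUC
    summary is NaN while LL and MSE are still computed.
    """
    y = np.asarray(y, dtype=float)
    P = np.atleast_2d(np.asarray(prob_matrix, dtype=float))
    if P.shape[1] != y.size:
        raise ValueError("probability matrix and response length mismatch")
    Pc = np.clip(P, _PROB_CLIP, 1.0 - _PROB_CLIP)
    ll = (y * np.log(Pc) + (1.0 - y) * np.log1p(-Pc)).sum(axis=1)
    mse = ((y - P) ** 2).mean(axis=1)
    try:
        auc_summary = MetricSummary.from_draws(
            "AUC", np.array([auc(y, row) for row in P])
        )
    except UndefinedMetricError:
        if not nan_auc_if_single_class:
            raise
        auc_summary = MetricSummary("AUC", np.nan, np.nan, np.nan,
                                    np.array([]))
    return {
        "LL": MetricSummary.from_draws("LL", ll),
        "MSE": MetricSummary.from_draws("MSE", mse),
        "AUC": auc_summary,
    }


def roc_points(y, p) -> pd.DataFrame:
    """ROC curve as a (false positive rate, true positive rate) table."""
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(np.asarray(y), np.asarray(p, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-fold and mean out-of-sample metrics for both models."""

    table: pd.DataFrame              # metric, model, fold, mean, lo, hi
    folds: FoldAssignment
    draws: dict = field(default_factory=dict)   # (model, fold) -> PosteriorDraws

    def mean_metric(self, metric: str, model: str) -> float:
        t = self.table
        row = t[(t["metric"] == metric) & (t["model"] == model)
                & (t["fold"] == "mean")]
        return float(row["posterior_mean"].iloc[0])


def cross_validate(data: SurveyDataset, priors: PriorSpec | None = None,
                   config: FitConfig | None = None, k: int = 5,
                   seed: int = 0, keep_draws: bool = False) -> CVResult:
    """Location-blocked k-fold CV of the spatial vs non-spatial model.

    For each fold both models are fitted to the complementary folds only;
    held-out probabilities use the training standardization constants, and
    the spatial model's latent effect at held-out sites is kriged per
    retained draw. Folds whose training split is single-class are skipped
    with a warning. Returns the k per-fold rows plus a mean row per
    (metric, model).
    """
    priors = priors or PriorSpec()
    config = config or FitConfig()
    folds = assign_location_folds(data, k, seed)
    obs_folds = folds.fold_of_obs(data)
    seeds = np.random.SeedSequence(seed).generate_state(3 * k) % (2**31)
    rows = []
    kept = {}
    for f in range(k):
        train = data.subset(obs_folds != f)
        test = data.subset(obs_folds == f)
        y_train = train.obs["presence"].to_numpy(dtype=float)
        if np.nanmin(y_train) == np.nanmax(y_train):
            warnings.warn(f"fold {f}: single-class training split, skipped")
            continue
        y_test = test.presence
        for model, spatial in (("nonspatial", False), ("spatial", True)):
            cfg = dataclasses.replace(
                config, spatial=spatial,
                seed=int(seeds[2 * f + int(spatial)]),
            )
            draws = fit_model(train, priors, cfg)
            if keep_draws:
                kept[(model, f)] = draws
            rng = np.random.default_rng(int(seeds[2 * k + f]))
            P = predict_probabilities(draws, test, rng=rng)
            summ = metric_summaries(y_test, P, nan_auc_if_single_class=True)
            for name, ms in summ.items():
                rows.append((name, model, f, ms.posterior_mean,
                             ms.interval_low, ms.interval_high))
    table = pd.DataFrame(
        rows, columns=["metric", "model", "fold", "posterior_mean",
                       "interval_low", "interval_high"]
    )
    means = (
        table.groupby(["metric", "model"], as_index=False)["posterior_mean"]
        .mean()
    )
    means["fold"] = "mean"
    means["interval_low"] = np.nan
    means["interval_high"] = np.nan
    table = pd.concat([table, means[table.columns]], ignore_index=True)
    return CVResult(table=table, folds=folds, draws=kept)
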
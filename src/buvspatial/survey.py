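"""Reading, validation and model-ready transformation of BUV survey tables.

A survey table holds one row per baited-underwater-video (BUV) deployment:
the site's planar coordinates (UTM meters), the season and protection status
at the time of deployment, depth, visibility, four binary habitat indicators
(present when the habitat covers at least 5% of the site) and the binary
presence response. Repeat deployments of a site share coordinates; they are
grouped into a unique-site table so that a site-level spatial random effect
can be attached downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STATUS_LEVELS = ("open", "green_old", "green_new")
SEASON_LEVELS = ("summer", "winter")
HABITAT_COLUMNS = ("rock", "kelp", "sand", "coffee_rock")

#: Required CSV schema, in canonical column order.
CSV_COLUMNS = (
    "site_id", "easting", "northing", "season", "status",
    "depth", "visibility", "rock", "kelp", "sand", "coffee_rock", "presence",
)

#: Fixed design-matrix column order. Baseline: status=open, season=summer.
DESIGN_COLUMNS = (
    "intercept", "green_old", "green_new", "depth",
    "rock", "kelp", "sand", "coffee_rock", "winter", "visibility",
)


class SurveyDataError(ValueError):
    """Base class for survey-table validation failures."""


class SchemaError(SurveyDataError):
    """A required column is missing from the input table."""


class ConsistencyError(SurveyDataError):
    """A site_id appears with conflicting coordinates."""


class DegenerateDataError(SurveyDataError):
    """An input is constant or otherwise carries no information."""


@dataclass(frozen=True)
class StandardizationParams:
    """Centering/scaling constants for the continuous covariates (meters).

    The standard deviation uses the sample (n-1) denominator.
    """

    depth_mean: float
    depth_sd: float
    visibility_mean: float
    visibility_sd: float

    def __post_init__(self) -> None:
        if not (self.depth_sd > 0 and self.visibility_sd > 0):
            raise DegenerateDataError("standardization sd values must be > 0")

    def transform(self, depth, visibility):
        """Standardize new depth/visibility values with the stored constants."""
        return (
            (np.asarray(depth, dtype=float) - self.depth_mean) / self.depth_sd,
            (np.asarray(visibility, dtype=float) - self.visibility_mean)
            / self.visibility_sd,
        )

    def to_dict(self) -> dict:
        return {
            "depth_mean": self.depth_mean,
            "depth_sd": self.depth_sd,
            "visibility_mean": self.visibility_mean,
            "visibility_sd": self.visibility_sd,
        }


@dataclass
class SurveyDataset:
    """A validated survey table plus its unique-site structure.

    Attributes
    ----------
    obs : pandas.DataFrame
        One row per deployment, columns as in :data:`CSV_COLUMNS`,
        original row order preserved. ``presence`` may be NaN for a
        simulated design whose response has not been drawn yet.
    sites : pandas.DataFrame
        Deduplicated ``(site_id, easting, northing)`` table, in order of
        first appearance.
    obs_to_site : numpy.ndarray
        Integer index mapping each observation to its row in ``sites``.
    standardized : bool
        Whether depth/visibility currently hold standardized values.
    """

    obs: pd.DataFrame
    sites: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    obs_to_site: np.ndarray = field(default=None)  # type: ignore[assignment]
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.sites is None or self.obs_to_site is None:
            self._rebuild_sites()
        self.validate()

    def _rebuild_sites(self) -> None:
        obs = self.obs
        sites = obs[["site_id", "easting", "northing"]].drop_duplicates(
            subset="site_id"
        )
        self.sites = sites.reset_index(drop=True)
        index = {sid: i for i, sid in enumerate(self.sites["site_id"])}
        self.obs_to_site = obs["site_id"].map(index).to_numpy(dtype=int)

    def validate(self) -> None:
        obs = self.obs
        missing = [c for c in CSV_COLUMNS if c not in obs.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        for col, levels in (("status", STATUS_LEVELS), ("season", SEASON_LEVELS)):
            bad = ~obs[col].isin(levels)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise SurveyDataError(
                    f"unrecognized {col} token {obs[col].iloc[row]!r} at row {row}"
                )
        for col in HABITAT_COLUMNS:
            vals = obs[col].to_numpy()
            if not np.isin(vals, (0, 1)).all():
                raise SurveyDataError(f"habitat column {col!r} must be 0/1")
        pres = obs["presence"].to_numpy(dtype=float)
        seen = pres[~np.isnan(pres)]
        if not np.isin(seen, (0.0, 1.0)).all():
            raise SurveyDataError("presence must be 0/1")
        if not self.standardized:
            for col in ("depth", "visibility"):
                if not (obs[col].to_numpy(dtype=float) > 0).all():
                    raise SurveyDataError(f"{col} must be > 0")
        coords = obs.groupby("site_id")[["easting", "northing"]].nunique()
        conflicted = coords[(coords > 1).any(axis=1)]
        if len(conflicted):
            raise ConsistencyError(
                "site_id with conflicting coordinates: "
                + ", ".join(str(s) for s in conflicted.index[:5])
            )

    # -- convenience views -------------------------------------------------

    @property
    def n_obs(self) -> int:
        return len(self.obs)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_coords(self) -> np.ndarray:
        """(n_sites, 2) array of easting/northing in meters."""
        return self.sites[["easting", "northing"]].to_numpy(dtype=float)

    @property
    def presence(self) -> np.ndarray:
        y = self.obs["presence"].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise SurveyDataError("presence column has not been set")
        return y.astype(int)

    def with_obs(self, obs: pd.DataFrame, standardized: bool | None = None) -> "SurveyDataset":
        return SurveyDataset(
            obs.reset_index(drop=True),
            standardized=self.standardized if standardized is None else standardized,
        )

    def subset(self, mask: np.ndarray) -> "SurveyDataset":
        """Row-subset by boolean/integer mask, rebuilding the site table."""
        return self.with_obs(self.obs.loc[np.asarray(mask)].copy())


def load_survey_csv(path) -> SurveyDataset:
    """Read and validate a survey CSV (comma-separated, UTF-8, header required).

    Raises :class:`SchemaError` for missing columns, :class:`SurveyDataError`
    for bad tokens (with the offending row number) and
    :class:`ConsistencyError` when a site_id carries conflicting coordinates.
    """
    obs = pd.read_csv(path, comment="#")
    missing = [c for c in CSV_COLUMNS if c not in obs.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    obs = obs[list(CSV_COLUMNS)]
    return SurveyDataset(obs)


def write_survey_csv(data: SurveyDataset, path) -> None:
    """Write the identical CSV schema back out (round-trips all fields)."""
    data.obs[list(CSV_COLUMNS)].to_csv(path, index=False)


def survey_to_csv_text(data: SurveyDataset) -> str:
    buf = io.StringIO()
    write_survey_csv(data, buf)
    return buf.getvalue()


def standardize_covariates(
    data: SurveyDataset, params: StandardizationParams | None = None
) -> tuple[SurveyDataset, StandardizationParams]:
    """Center and scale depth and visibility to mean 0, sample sd 1.

    When ``params`` is given (e.g. the training-set constants in
    cross-validation) they are applied as-is; otherwise they are estimated
    from ``data`` with the n-1 denominator. A constant column raises
    :class:`DegenerateDataError`.
    """
    if data.standardized:
        raise SurveyDataError("covariates are already standardized")
    obs = data.obs.copy()
    depth = obs["depth"].to_numpy(dtype=float)
    vis = obs["visibility"].to_numpy(dtype=float)
    if params is None:
        for name, col in (("depth", depth), ("visibility", vis)):
            if np.unique(col).size < 2:
                raise DegenerateDataError(f"{name} column is constant")
        params = StandardizationParams(
            depth_mean=float(depth.mean()),
            depth_sd=float(depth.std(ddof=1)),
            visibility_mean=float(vis.mean()),
            visibility_sd=float(vis.std(ddof=1)),
        )
    obs["depth"], obs["visibility"] = params.transform(depth, vis)
    out = data.with_obs(obs, standardized=True)
    return out, params


def build_design_matrix(data: SurveyDataset) -> np.ndarray:
    """Assemble the fixed-order (n_obs, 10) design matrix.

    Columns follow :data:`DESIGN_COLUMNS`; protection status is dummy-coded
    against the ``open`` baseline and season against ``summer``. Depth and
    visibility are used as stored, so standardize first for model fitting.
    """
    obs = data.obs
    n = len(obs)
    X = np.empty((n, len(DESIGN_COLUMNS)), dtype=float)
    X[:, 0] = 1.0
    X[:, 1] = (obs["status"] == "green_old").to_numpy(dtype=float)
    X[:, 2] = (obs["status"] == "green_new").to_numpy(dtype=float)
    X[:, 3] = obs["depth"].to_numpy(dtype=float)
    for j, hab in enumerate(HABITAT_COLUMNS, start=4):
        X[:, j] = obs[hab].to_numpy(dtype=float)
    X[:, 8] = (obs["season"] == "winter").to_numpy(dtype=float)
    X[:, 9] = obs["visibility"].to_numpy(dtype=float)
    return X
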
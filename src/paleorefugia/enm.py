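"""Ecological niche models: fit, screen, threshold, hindcast.

The suitability model is a ridge-penalized logistic regression of presences
against a uniform background sample, on standardized linear + quadratic
climate features. With correctly specified quadratic features this recovers a
Gaussian niche up to a monotone (logistic) transform, so percentile-based
thresholding and AUC screening behave exactly as they would for any
maximum-entropy-style suitability surface.

Screening and thresholding rules:

* species with ≤ 10 unique records are not modeled (``rejected_records``);
* models with AUC ≤ 0.70 are excluded (``rejected_auc``); AUC is the
  Mann–Whitney probability that a presence outscores a background point,
  ties counted half;
* the binarization threshold is the nearest-rank 5th percentile of model
  scores at the occurrence points (the "95% minimum occurrence" rule), frozen
  at fitting time and applied unchanged to every hindcast slice.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from .grid import Grid, MaskLayer, OccurrenceSet, RasterLayer, require_same_grid

logger = logging.getLogger(__name__)

__all__ = [
    "SuitabilityModel",
    "fit_enm",
    "evaluate_auc",
    "minimum_occurrence_threshold",
    "project",
    "binarize",
    "buffer_restrict",
]

AUC_CUTOFF = 0.70
DEFAULT_BACKGROUND = 10_000
DEFAULT_PENALTY = 1.0
DEFAULT_PERCENTILE = 5.0


@dataclass
class SuitabilityModel:
    """Fitted per-species suitability model and its screening status."""

    species: str
    variables: list[str] = field(default_factory=list)
    coefficients: np.ndarray | None = None  # [intercept, linear..., quadratic...]
    variable_centers: np.ndarray | None = None  # per-variable centering constants
    feature_means: np.ndarray | None = None
    feature_sds: np.ndarray | None = None
    threshold: float | None = None
    auc: float | None = None
    status: str = "accepted"  # accepted | rejected_auc | rejected_records

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"

    def features(self, lin: np.ndarray) -> np.ndarray:
        """Centered linear + quadratic features from raw climate columns.

        Centering the variables before squaring decorrelates the linear and
        quadratic terms, so the ridge penalty acts on well-conditioned
        coefficients instead of crushing a near-collinear pair.
        """
        c = lin - self.variable_centers
        return np.column_stack([c, c**2])

    def suitability(self, lin: np.ndarray) -> np.ndarray:
        """Logistic suitability for raw climate-variable rows."""
        if self.coefficients is None:
            raise ValueError(f"model for {self.species!r} has no coefficients ({self.status})")
        z = (self.features(lin) - self.feature_means) / self.feature_sds
        eta = self.coefficients[0] + z @ self.coefficients[1:]
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))

    def niche_optimum(self) -> np.ndarray:
        """Suitability-maximizing value of each climate variable.

        The fitted response in each variable is a centered quadratic
        ``a·v_c + b·v_c²``; its stationary point is ``−a/(2b)`` plus the
        centering constant. Meaningful when the quadratic coefficients are
        negative (a niche optimum rather than a minimum).
        """
        if self.coefficients is None:
            raise ValueError("model has no coefficients")
        k = len(self.variables)
        raw = self.coefficients[1:] / self.feature_sds
        return self.variable_centers - raw[:k] / (2.0 * raw[k:])

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "variables": self.variables,
            "coefficients": None if self.coefficients is None else self.coefficients.tolist(),
            "variable_centers": None if self.variable_centers is None else self.variable_centers.tolist(),
            "feature_means": None if self.feature_means is None else self.feature_means.tolist(),
            "feature_sds": None if self.feature_sds is None else self.feature_sds.tolist(),
            "threshold": self.threshold,
            "auc": self.auc,
            "status": self.status,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SuitabilityModel":
        arr = lambda v: None if v is None else np.asarray(v, dtype=float)
        return cls(
            species=d["species"],
            variables=list(d["variables"]),
            coefficients=arr(d["coefficients"]),
            variable_centers=arr(d["variable_centers"]),
            feature_means=arr(d["feature_means"]),
            feature_sds=arr(d["feature_sds"]),
            threshold=d["threshold"],
            auc=d["auc"],
            status=d["status"],
        )


def _climate_at(climate: dict[str, RasterLayer], rows: np.ndarray, cols: np.ndarray,
                variables: list[str]) -> np.ndarray:
    """Raw climate-variable columns at the given cells."""
    return np.column_stack([climate[v].values[rows, cols] for v in variables])


def fit_enm(
    occurrences: OccurrenceSet,
    climate: dict[str, RasterLayer],
    n_background: int = DEFAULT_BACKGROUND,
    reg: float = DEFAULT_PENALTY,
    seed: int = 0,
    percentile: float = DEFAULT_PERCENTILE,
    auc_cutoff: float = AUC_CUTOFF,
) -> SuitabilityModel:
    """Fit a penalized logistic suitability model for one species.

    Presences are the occurrence cells; the background is drawn uniformly
    without replacement from non-nodata cells (capped at their number).
    ``reg`` is the ridge penalty λ on the standardized scale. Deterministic
    given ``seed``.
    """
    variables = sorted(climate)
    grid = climate[variables[0]].grid
    for v in variables[1:]:
        require_same_grid(grid, climate[v].grid, f"climate {v!r}")

    model = SuitabilityModel(species=occurrences.species, variables=variables)
    if not occurrences.modelable:
        model.status = "rejected_records"
        logger.info("enm: %s rejected (%d unique records)", model.species, occurrences.n_unique)
        return model

    valid = np.ones(grid.shape, dtype=bool)
    for v in variables:
        valid &= climate[v].valid
    for v in variables:
        vals = climate[v].values[valid]
        if np.ptp(vals) == 0:
            raise ValueError(f"degenerate climate: {v!r} has zero variance")

    pts = occurrences.points
    p_rows = np.floor((grid.origin_y - pts[:, 1]) / grid.cell_size).astype(int)
    p_cols = np.floor((pts[:, 0] - grid.origin_x) / grid.cell_size).astype(int)
    inside = (p_rows >= 0) & (p_rows < grid.n_rows) & (p_cols >= 0) & (p_cols < grid.n_cols)
    if not inside.all():
        logger.warning("enm: %s has %d occurrences outside the grid (dropped)",
                       model.species, int((~inside).sum()))
    p_rows, p_cols = p_rows[inside], p_cols[inside]

    rng = np.random.default_rng(seed)
    v_rows, v_cols = np.nonzero(valid)
    nb = min(n_background, v_rows.size)
    pick = rng.choice(v_rows.size, size=nb, replace=False)
    b_rows, b_cols = v_rows[pick], v_cols[pick]

    lin = np.vstack([
        _climate_at(climate, p_rows, p_cols, variables),
        _climate_at(climate, b_rows, b_cols, variables),
    ])
    y = np.concatenate([np.ones(p_rows.size), np.zeros(nb)])
    model.variable_centers = lin.mean(axis=0)
    X = model.features(lin)
    means, sds = X.mean(axis=0), X.std(axis=0)
    sds[sds == 0] = 1.0
    Xz = (X - means) / sds

    # L2 penalty (sklearn default); C = 1/λ on the standardized scale
    clf = LogisticRegression(C=1.0 / reg, solver="lbfgs", max_iter=5000, tol=1e-8)
    clf.fit(Xz, y)
    model.coefficients = np.concatenate([clf.intercept_, clf.coef_.ravel()])
    model.feature_means, model.feature_sds = means, sds

    scores = model.suitability(lin)
    pres_scores, back_scores = scores[: p_rows.size], scores[p_rows.size:]
    model.auc = evaluate_auc(pres_scores, back_scores)
    model.threshold = minimum_occurrence_threshold(pres_scores, percentile)
    if model.auc <= auc_cutoff:
        model.status = "rejected_auc"
        logger.info("enm: %s rejected (AUC %.3f <= %.2f)", model.species, model.auc, auc_cutoff)
    return model


def evaluate_auc(presence_scores, background_scores) -> float:
    """Probability a random presence outscores a random background point.

    Mann–Whitney formulation; ties count one half. Invariant under any
    strictly increasing transform of the scores.
    """
    pres = np.asarray(presence_scores, dtype=float)
    back = np.asarray(background_scores, dtype=float)
    if pres.size == 0 or back.size == 0:
        raise ValueError("both score sets must be nonempty")
    ranks = rankdata(np.concatenate([pres, back]))
    u = ranks[: pres.size].sum() - pres.size * (pres.size + 1) / 2
    return float(u / (pres.size * back.size))


def minimum_occurrence_threshold(suitability_at_occurrences, percentile: float = 5.0) -> float:
    """Nearest-rank percentile of occurrence scores (default 5th).

    Sort ascending and take the value at rank ``ceil(p/100 · n)`` (1-based),
    guaranteeing that at least ``1 − p/100`` of the occurrence scores are at
    or above the threshold.
    """
    values = np.sort(np.asarray(suitability_at_occurrences, dtype=float))
    if values.size == 0:
        raise ValueError("no suitability values given")
    rank = max(1, math.ceil(percentile / 100.0 * values.size))
    return float(values[rank - 1])


def project(model: SuitabilityModel, climate: dict[str, RasterLayer]) -> RasterLayer:
    """Project an accepted model onto one climate slice.

    Standardization constants are frozen from fitting; slices are never
    re-standardized, so hindcasts share the contemporary suitability scale.
    """
    if not model.accepted:
        raise ValueError(f"model for {model.species!r} is not accepted ({model.status})")
    missing = [v for v in model.variables if v not in climate]
    if missing:
        raise ValueError(f"missing climate variables: {missing}")
    grid = climate[model.variables[0]].grid
    for v in model.variables[1:]:
        require_same_grid(grid, climate[v].grid, f"climate {v!r}")
    lin = np.stack([climate[v].values for v in model.variables], axis=-1)
    lin = lin.reshape(-1, len(model.variables))
    invalid = np.isnan(lin).any(axis=1)
    lin = np.where(np.isnan(lin), 0.0, lin)
    suit = model.suitability(lin)
    suit[invalid] = np.nan
    return RasterLayer(grid, suit.reshape(grid.shape), f"suitability_{model.species}")


def binarize(suitability: RasterLayer, threshold: float) -> MaskLayer:
    """Suitable (1) iff suitability ≥ threshold; nodata propagated."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    values = np.where(suitability.valid, (suitability.values >= threshold).astype(float), np.nan)
    return MaskLayer(suitability.grid, values, "range")


def buffer_restrict(suitability: RasterLayer, range_mask: MaskLayer,
                    buffer_km: float = 100.0) -> RasterLayer:
    """Zero suitability farther than ``buffer_km`` from any range cell.

    Distances are center-to-center Euclidean, so a metric CRS is required.
    """
    require_same_grid(suitability.grid, range_mask.grid, "range mask")
    grid = suitability.grid
    cell_km = grid.cell_size_km  # raises for geographic degrees
    inside = range_mask.bool_array
    if not inside.any():
        warnings.warn("buffer_restrict: empty range mask; all-zero output")
        return suitability.copy(values=np.where(suitability.valid, 0.0, np.nan))
    dist = distance_transform_edt(~inside) * cell_km
    values = np.where(dist <= buffer_km, suitability.values, 0.0)
    values[~suitability.valid] = np.nan
    return suitability.copy(values=values)
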
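"""Out-of-sample body-mass prediction with 95% phylogenetic prediction limits.

Given a fitted PGLS allometry, a fossil specimen's femoral cortical surface
area (FCSA) maps to a point estimate on the natural-log gram scale and a
prediction interval that is back-transformed to kg.  Two modes:

``independent``
    The new specimen is treated as phylogenetically uncorrelated with the
    reference sample.  Log-scale prediction variance is
    σ̂²·d₀ + x₀ᵀ cov(β̂) x₀ with d₀ the mean extant diagonal of V(λ̂);
    interval widths then grow purely with leverage, i.e. with the distance
    of ln(FCSA) from the reference mean.  This is the default.

``blup``
    Best linear unbiased prediction exploiting the fossil's covariance with
    the extant tips (its placement on the tree).  The point estimate is
    shifted by cᵀV⁻¹(y − Xβ̂) and the variance is reduced by the information
    in c, where c is the λ̂-scaled fossil-extant covariance vector.

Intervals are symmetric on the log scale, hence multiplicative in kg:
upper/estimate = estimate/lower.  No log-normal back-transform bias
correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import stats

from .pgls import GRAMS_PER_KG, PGLSFit

__all__ = [
    "FossilPlacement",
    "PredictionRecord",
    "predict_point",
    "predict_interval",
    "predict_specimens",
]


@dataclass
class FossilPlacement:
    """Phylogenetic position of a fossil relative to the reference tips.

    ``cov_to_extant`` holds the *unscaled* shared path length between the
    fossil tip and each reference tip, aligned with ``fit.taxa``; ``depth``
    is the fossil's own root-to-tip depth.  λ̂ scaling is applied at
    prediction time, consistent with the extant covariance.
    """

    cov_to_extant: np.ndarray
    depth: float


@dataclass
class PredictionRecord:
    """Per-specimen body-mass estimate with 95% prediction limits."""

    specimen_id: str
    species: str
    dataset: str
    fcsa_mm2: float
    log_estimate: float   # ln grams
    log_se: float
    estimate_kg: float
    lower95_kg: float
    upper95_kg: float


def predict_point(fit: PGLSFit, fcsa: float) -> float:
    """Point estimate in kg: exp(β₀ + β₁ ln FCSA), grams → kg."""
    _require_fcsa_model(fit)
    x0 = fit.design_row(fcsa_mm2=fcsa)
    return math.exp(float(x0 @ fit.params.to_numpy())) / GRAMS_PER_KG


def predict_interval(
    fit: PGLSFit,
    fcsa: float,
    level: float = 0.95,
    mode: str = "independent",
    placement: FossilPlacement | None = None,
    specimen_id: str = "",
    species: str = "",
    dataset: str = "",
) -> PredictionRecord:
    """Point estimate and prediction limits for one specimen.

    Limits are exp(point ± t(level, n−p) · SE) on the log-gram scale,
    reported in kg.  With zero prediction variance (an exact fit) the
    interval degenerates to the point.
    """
    _require_fcsa_model(fit)
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    x0 = fit.design_row(fcsa_mm2=fcsa)
    beta = fit.params.to_numpy()
    point = float(x0 @ beta)

    if mode == "independent":
        var = fit.sigma2 * fit.d0 + float(x0 @ fit.cov_beta @ x0)
    elif mode == "blup":
        if placement is None:
            raise ValueError("blup mode requires a FossilPlacement")
        c = np.asarray(placement.cov_to_extant, dtype=float) * fit.lambda_hat
        if c.shape[0] != fit.n:
            raise ValueError("placement vector length does not match fit taxa")
        a = sla.solve(fit.V, c, assume_a="pos")  # V⁻¹ c
        point += float(a @ fit.resid)
        xtvix_inv = fit.cov_beta / fit.sigma2
        u = x0 - fit.X.T @ a
        var = fit.sigma2 * (
            placement.depth - float(c @ a) + float(u @ xtvix_inv @ u)
        )
    else:
        raise ValueError(f"unknown prediction mode {mode!r}")

    var = max(var, 0.0)
    se = math.sqrt(var)
    if se < 1e-9:  # numerically exact fit: degenerate interval
        se = 0.0
    est_kg = math.exp(point) / GRAMS_PER_KG
    if se == 0.0:
        lo_kg = up_kg = est_kg
    else:
        tcrit = stats.t.ppf(0.5 + level / 2.0, fit.df_resid)
        lo_kg = math.exp(point - tcrit * se) / GRAMS_PER_KG
        up_kg = math.exp(point + tcrit * se) / GRAMS_PER_KG
    return PredictionRecord(
        specimen_id=specimen_id, species=species, dataset=dataset,
        fcsa_mm2=float(fcsa), log_estimate=point, log_se=se,
        estimate_kg=est_kg, lower95_kg=lo_kg, upper95_kg=up_kg,
    )


def predict_specimens(
    fit: PGLSFit,
    specimens: pd.DataFrame,
    level: float = 0.95,
    mode: str = "independent",
    placements: dict[str, FossilPlacement] | None = None,
) -> list[PredictionRecord]:
    """Predict every specimen in a table, preserving row order.

    ``specimens`` needs columns ``specimen_id``, ``species``, ``dataset``,
    ``fcsa_mm2``.  Each specimen is predicted marginally (fossil-fossil
    covariance is ignored).  In blup mode, ``placements`` maps species name
    to its :class:`FossilPlacement`.
    """
    if len(specimens) == 0:
        raise ValueError("specimen table is empty")
    required = {"specimen_id", "species", "dataset", "fcsa_mm2"}
    missing = required - set(specimens.columns)
    if missing:
        raise ValueError(f"specimen table missing columns: {sorted(missing)}")
    ids = specimens["specimen_id"].astype(str)
    if ids.duplicated().any():
        dups = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"duplicate specimen ids: {dups}")
    records = []
    for row in specimens.itertuples(index=False):
        placement = None
        if mode == "blup":
            if placements is None or row.species not in placements:
                raise ValueError(
                    f"blup mode requires a placement for species {row.species!r}"
                )
            placement = placements[row.species]
        records.append(
            predict_interval(
                fit, float(row.fcsa_mm2), level=level, mode=mode,
                placement=placement, specimen_id=str(row.specimen_id),
                species=str(row.species), dataset=str(row.dataset),
            )
        )
    return records


def records_to_frame(records: list[PredictionRecord]) -> pd.DataFrame:
    """Full-precision DataFrame of prediction records (rounding is I/O-side)."""
    return pd.DataFrame(
        {
            "species": [r.species for r in records],
            "specimen_id": [r.specimen_id for r in records],
            "dataset": [r.dataset for r in records],
            "fcsa_mm2": [r.fcsa_mm2 for r in records],
            "estimate_kg": [r.estimate_kg for r in records],
            "lower95_kg": [r.lower95_kg for r in records],
            "upper95_kg": [r.upper95_kg for r in records],
        }
    )


def _require_fcsa_model(fit: PGLSFit) -> None:
    if fit.predictors != ("fcsa_mm2",):
        raise ValueError(
            "prediction is supported for the univariate FCSA allometry only; "
            f"got formula {fit.formula!r}"
        )
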
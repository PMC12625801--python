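"""Phylogenetic generalized least squares with ML estimation of Pagel's λ.

The regression model is

    y = X β + ε,   ε ~ N(0, σ² V(λ)),   V(λ) = λ C + (1 − λ) diag(C)

with C the phylogenetic VCV of the species in the fit.  λ is estimated by
maximizing the profile log-likelihood (β and σ² concentrated out) over
[0, 1]; λ = 0 recovers ordinary least squares, λ = 1 the full
Brownian-motion covariance.

Body mass enters the likelihood in natural-log **grams** (trait tables carry
kg; the conversion is applied here and undone at prediction time), with
femoral predictors in natural-log mm or mm².  σ̂² uses the ML (n) denominator
inside the likelihood and the n − p denominator for coefficient inference.
AIC counts k = p + 2 parameters (coefficients plus σ² and λ); it is meant
for ranking models fit to the same data, not for comparison across software
with different likelihood constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import optimize, stats

from .tree import CovarianceStructure, PhyloTree, lambda_transform, normalize_label, vcv_from_tree

__all__ = [
    "GLSResult",
    "LambdaProfile",
    "PGLSFit",
    "ModelRanking",
    "FORMULAS",
    "gls_fit",
    "profile_lambda_ml",
    "fit_model",
    "compare_models",
    "validate_trait_table",
]

#: supported model formulas -> predictor column names (in design-matrix order)
FORMULAS: dict[str, tuple[str, ...]] = {
    "BM~FCSA": ("fcsa_mm2",),
    "BM~FL": ("fl_mm",),
    "BM~FCSA+FL": ("fcsa_mm2", "fl_mm"),
}

_COEF_NAMES = {"fcsa_mm2": "ln_fcsa", "fl_mm": "ln_fl"}

GRAMS_PER_KG = 1000.0


def _canonical_formula(formula: str) -> str:
    key = formula.replace(" ", "").upper()
    if key not in FORMULAS:
        raise ValueError(
            f"unknown formula {formula!r}; expected one of {sorted(FORMULAS)}"
        )
    return key


def validate_trait_table(traits: pd.DataFrame, require_fl: bool = False) -> pd.DataFrame:
    """Check a species-mean trait table and return a normalized copy.

    Requires columns ``species``, ``bm_kg``, ``fcsa_mm2`` (and ``fl_mm`` if
    ``require_fl``); all trait values must be strictly positive and species
    unique, so that natural logs are defined and rows align with tree tips.
    """
    cols = {"species", "bm_kg", "fcsa_mm2"} | ({"fl_mm"} if require_fl else set())
    missing = cols - set(traits.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    out = traits.copy()
    out["species"] = out["species"].map(normalize_label)
    if out["species"].duplicated().any():
        dups = out.loc[out["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate species in trait table: {dups}")
    for col in cols - {"species"}:
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = out.loc[~(vals > 0), "species"].tolist()
        if bad:
            raise ValueError(f"non-positive or missing {col} for: {bad}")
        out[col] = vals
    return out


@dataclass
class GLSResult:
    """Raw GLS solve: coefficients, scale, likelihood, and diagnostics."""

    beta: np.ndarray
    sigma2: float          # RSS_w / (n - p), for inference
    sigma2_ml: float       # RSS_w / n, inside the likelihood
    loglik: float
    cov_beta: np.ndarray
    rss_w: float           # whitened residual sum of squares
    resid: np.ndarray      # raw-scale residuals y - Xβ
    n: int
    p: int


def gls_fit(X: np.ndarray, y: np.ndarray, V: np.ndarray) -> GLSResult:
    """Solve the GLS problem by Cholesky whitening.

    β = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y, computed as OLS on L⁻¹X, L⁻¹y with V = LLᵀ.
    Raises on a non-positive-definite V or rank-deficient design.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    V = np.asarray(V, dtype=float)
    n, p = X.shape
    if y.shape[0] != n or V.shape != (n, n):
        raise ValueError("X, y, V dimensions are inconsistent")
    try:
        L = sla.cholesky(V, lower=True)
    except sla.LinAlgError as exc:
        raise ValueError("covariance matrix is not positive definite") from exc
    Xw = sla.solve_triangular(L, X, lower=True)
    yw = sla.solve_triangular(L, y, lower=True)
    q, r = np.linalg.qr(Xw)
    if np.min(np.abs(np.diag(r))) <= 1e-10 * max(1.0, np.max(np.abs(np.diag(r)))):
        raise ValueError("design matrix is rank deficient")
    beta = sla.solve_triangular(r, q.T @ yw, lower=False)
    resid_w = yw - Xw @ beta
    rss_w = float(resid_w @ resid_w)
    sigma2 = rss_w / (n - p) if n > p else np.nan
    sigma2_ml = rss_w / n
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(L))))
    if sigma2_ml > 0:
        loglik = -0.5 * (n * math.log(2 * math.pi) + n * math.log(sigma2_ml)
                         + logdet_V + n)
    else:  # exact fit: likelihood unbounded; report +inf by convention
        loglik = math.inf
    rinv = sla.solve_triangular(r, np.eye(p), lower=False)
    xtvix_inv = rinv @ rinv.T
    cov_beta = sigma2 * xtvix_inv
    return GLSResult(beta=beta, sigma2=sigma2, sigma2_ml=sigma2_ml, loglik=loglik,
                     cov_beta=cov_beta, rss_w=rss_w, resid=y - X @ beta, n=n, p=p)


@dataclass
class LambdaProfile:
    """Result of profile-likelihood maximization of Pagel's λ."""

    lambda_hat: float
    loglik: float
    flat: bool = False  # True when the profile is constant (star tree)


def profile_lambda_ml(
    X: np.ndarray,
    y: np.ndarray,
    cov: CovarianceStructure,
    xatol: float = 1e-8,
) -> LambdaProfile:
    """Maximize the concentrated log-likelihood over λ ∈ [0, 1].

    On a star tree (C diagonal) the likelihood does not depend on λ; the
    convention is to return λ̂ = 0 with ``flat=True``.  Interior optima use
    bounded scalar minimization to ``xatol``; the endpoints are always
    checked so boundary maxima are not missed.
    """
    C = cov.C
    offdiag = C - np.diag(np.diag(C))
    if np.max(np.abs(offdiag)) <= 1e-12 * max(1.0, np.max(np.diag(C))):
        ll = gls_fit(X, y, lambda_transform(cov, 0.0).V).loglik
        return LambdaProfile(lambda_hat=0.0, loglik=ll, flat=True)

    def nll(lam: float) -> float:
        return -gls_fit(X, y, lambda_transform(cov, float(lam)).V).loglik

    coarse = [nll(l) for l in np.linspace(0.0, 1.0, 11)]
    if not np.all(np.isfinite(coarse)):
        raise ValueError("log-likelihood is non-finite on the lambda grid; "
                         "covariance is ill-conditioned")
    res = optimize.minimize_scalar(
        nll, bounds=(0.0, 1.0), method="bounded", options={"xatol": xatol}
    )
    candidates = [(0.0, coarse[0]), (1.0, coarse[-1]), (float(res.x), float(res.fun))]
    lam, negll = min(candidates, key=lambda c: c[1])
    return LambdaProfile(lambda_hat=lam, loglik=-negll, flat=False)


@dataclass
class PGLSFit:
    """A fitted PGLS regression of ln body mass on ln femoral measurements.

    Coefficients are on the natural-log scale with body mass internally in
    grams.  Everything needed for out-of-sample prediction is retained:
    the λ̂-scaled covariance, design matrix, and raw residuals.
    """

    formula: str
    params: pd.Series                 # intercept + slopes
    lambda_hat: float
    lambda_flat: bool
    sigma2: float                     # per unit branch length, n−p denominator
    loglik: float
    aic: float
    r2: float                         # on the whitened scale
    adj_r2: float
    r2_raw: float                     # classical R² on raw residuals
    se: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame            # columns lower95 / upper95
    fstat: float
    fstat_raw: float
    df_model: int
    df_resid: int
    n: int
    taxa: tuple[str, ...]
    predictors: tuple[str, ...]
    cov_beta: np.ndarray = field(repr=False)
    V: np.ndarray = field(repr=False)          # λ̂-scaled covariance
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)          # ln grams
    resid: np.ndarray = field(repr=False)      # raw-scale residuals
    d0: float = 1.0                            # mean extant diagonal of V(λ̂)

    @property
    def k(self) -> int:
        """AIC parameter count: coefficients plus σ² and λ."""
        return len(self.params) + 2

    def design_row(self, **values: float) -> np.ndarray:
        """Design-matrix row for a new observation (natural units in)."""
        row = [1.0]
        for col in self.predictors:
            v = values[col]
            if not v > 0:
                raise ValueError(f"{col} must be positive, got {v}")
            row.append(math.log(v))
        return np.array(row)

    def equation(self) -> str:
        """Human-readable regression equation, matching report conventions."""
        terms = []
        for name, b in zip(self.params.index[1:], self.params.iloc[1:]):
            terms.append(f"{b:.2f} x ln({name.removeprefix('ln_').upper()})")
        b0 = self.params.iloc[0]
        sign = "+" if b0 >= 0 else "-"
        return f"ln(BM) = {' + '.join(terms)} {sign} {abs(b0):.2f}"


def fit_model(
    traits: pd.DataFrame,
    tree: PhyloTree,
    formula: str = "BM~FCSA",
    lam: float | None = None,
) -> PGLSFit:
    """Fit one of the candidate allometric models by PGLS.

    Natural logs are taken of the response (kg converted to grams) and of
    every predictor; λ̂ is estimated by profile ML unless ``lam`` pins it.
    The F statistic compares the fitted model with the intercept-only model
    under the same V(λ̂), on the whitened scale (``fstat``) and on raw
    residuals (``fstat_raw``).
    """
    key = _canonical_formula(formula)
    predictors = FORMULAS[key]
    tab = validate_trait_table(traits, require_fl="fl_mm" in predictors)
    species = tab["species"].tolist()
    tips = set(tree.tip_labels)
    absent = sorted(set(species) - tips)
    if absent:
        raise ValueError(f"species not in tree: {', '.join(absent)}")

    y = np.log(tab["bm_kg"].to_numpy() * GRAMS_PER_KG)
    X = np.column_stack(
        [np.ones(len(tab))] + [np.log(tab[c].to_numpy()) for c in predictors]
    )
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more species ({n}) than coefficients ({p})")

    cov = vcv_from_tree(tree, taxa=species)
    if lam is None:
        prof = profile_lambda_ml(X, y, cov)
        lambda_hat, flat = prof.lambda_hat, prof.flat
    else:
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        lambda_hat, flat = float(lam), False
    V = lambda_transform(cov, lambda_hat).V
    g = gls_fit(X, y, V)

    # intercept-only fit under the same covariance, for R² and F
    g0 = gls_fit(np.ones((n, 1)), y, V)
    r2 = 1.0 - g.rss_w / g0.rss_w
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    df1, df2 = p - 1, n - p
    if df1 == 0:
        fstat = fstat_raw = np.nan
    else:
        fstat = (
            ((g0.rss_w - g.rss_w) / df1) / (g.rss_w / df2)
            if g.rss_w > 0 else np.inf
        )
    ss_res = float(g.resid @ g.resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2_raw = 1.0 - ss_res / ss_tot
    if df1:
        fstat_raw = (r2_raw / df1) / ((1.0 - r2_raw) / df2) \
            if r2_raw < 1.0 else np.inf

    names = ["intercept"] + [_COEF_NAMES[c] for c in predictors]
    params = pd.Series(g.beta, index=names)
    se = pd.Series(np.sqrt(np.diag(g.cov_beta)), index=names)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = params / se
    pvals = pd.Series(2.0 * stats.t.sf(np.abs(tvals), df2), index=names)
    tcrit = stats.t.ppf(0.975, df2)
    ci = pd.DataFrame(
        {"lower95": params - tcrit * se, "upper95": params + tcrit * se}
    )
    aic = -2.0 * g.loglik + 2.0 * (p + 2)
    return PGLSFit(
        formula=key, params=params, lambda_hat=lambda_hat, lambda_flat=flat,
        sigma2=g.sigma2, loglik=g.loglik, aic=aic, r2=r2, adj_r2=adj_r2,
        r2_raw=r2_raw, se=se, tvalues=tvals, pvalues=pvals, conf_int=ci,
        fstat=fstat, fstat_raw=fstat_raw, df_model=df1, df_resid=df2, n=n,
        taxa=tuple(species), predictors=predictors, cov_beta=g.cov_beta,
        V=V, X=X, y=y, resid=g.resid, d0=float(np.mean(np.diag(V))),
    )


@dataclass
class ModelRanking:
    """AIC ranking of candidate fits on the same data."""

    order: list[int]            # indices into the input list, best first
    delta_aic: list[float]      # per input fit, relative to the minimum
    best: int

    def table(self, fits: Sequence[PGLSFit]) -> pd.DataFrame:
        rows = [
            {
                "rank": r + 1,
                "formula": fits[i].formula,
                "k": fits[i].k,
                "aic": fits[i].aic,
                "delta_aic": self.delta_aic[i],
                "adj_r2": fits[i].adj_r2,
                "lambda": fits[i].lambda_hat,
            }
            for r, i in enumerate(self.order)
        ]
        return pd.DataFrame(rows)


def compare_models(fits: Sequence[PGLSFit]) -> ModelRanking:
    """Rank fits by ascending AIC; near-ties (ΔAIC < 2) prefer fewer parameters.

    All fits must share the same taxon set and response values — AIC is only
    comparable within a run on identical data.
    """
    if not fits:
        raise ValueError("no fits to compare")
    ref = fits[0]
    for f in fits[1:]:
        if set(f.taxa) != set(ref.taxa):
            raise ValueError("fits have mismatched taxon sets")
        if not np.allclose(np.sort(f.y), np.sort(ref.y)):
            raise ValueError("fits have mismatched response data")
    order = sorted(range(len(fits)), key=lambda i: (fits[i].aic, fits[i].k))
    # bubble near-ties: a simpler model within ΔAIC < 2 outranks a richer one
    changed = True
    while changed:
        changed = False
        for j in range(len(order) - 1):
            a, b = order[j], order[j + 1]
            if (fits[b].aic - fits[a].aic < 2.0) and fits[b].k < fits[a].k:
                order[j], order[j + 1] = b, a
                changed = True
    amin = min(f.aic for f in fits)
    delta = [f.aic - amin for f in fits]
    return ModelRanking(order=order, delta_aic=delta, best=order[0])
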
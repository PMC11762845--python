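"""Poisson additive models with identity link for quadrat count responses.

The mean count in a quadrat is modelled as an *untransformed* sum of smooth
contributions of the eight land-cover extents:

    mu = beta0 + f_1(x_1) + ... + f_8(x_8),    y ~ Poisson(mu)

so each smooth reads directly in count units (species or breeding pairs per
quadrat).  The identity link admits negative linear predictors, so the mean
is clamped below at a small epsilon during iteration and prediction; a
clamped fit is reported in the convergence diagnostics.

Each smooth is a penalized cubic regression spline under a sum-to-zero
constraint, with its second-difference penalty tuned so the term's effective
degrees of freedom (edf) match the requested df; df = 1 is a strictly linear
term.  Overdispersion is estimated as Pearson chi-square over residual df and
scales standard errors and the df-selection criterion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg
from scipy.interpolate import BSpline

from .survey import LANDCOVER_CATEGORIES

MU_EPS = 1e-6  # lower clamp on the identity-link mean
DF_CAP_DEFAULT = 4
N_BASIS = 9  # B-spline basis functions per smooth before the constraint


class FitError(RuntimeError):
    """The penalized IRLS iteration failed to converge."""


@dataclass(frozen=True)
class SmoothTermSpec:
    """Requested complexity for one predictor: df = 1 means strictly linear."""

    predictor: str
    df: int = 1

    def __post_init__(self):
        if self.df < 1:
            raise ValueError("df must be >= 1")


@dataclass
class SmoothTerm:
    """A fitted smooth: either a linear term or a constrained spline basis."""

    predictor: str
    df: int
    kind: str  # "linear" or "spline"
    coef: np.ndarray  # (1,) for linear, (p-1,) for spline
    xbar: float  # training mean of the predictor (linear centering)
    knots: np.ndarray | None  # full clamped knot vector (spline only)
    constraint: np.ndarray | None  # p x (p-1) null-space map Z (spline only)
    mean_f: float  # training mean of f(x), for partial-response centering
    edf: float = 1.0
    lam: float = 0.0

    def basis(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "linear":
            return (x - self.xbar)[:, None]
        lo, hi = self.knots[0], self.knots[-1]
        xc = np.clip(x, lo, hi)
        b = BSpline.design_matrix(xc, self.knots, 3).toarray()
        return b @ self.constraint

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.basis(x) @ self.coef


@dataclass
class PartialResponse:
    """Centered marginal contribution of one predictor on a grid."""

    predictor: str
    grid: np.ndarray
    contribution: np.ndarray


@dataclass
class FittedAdditiveModel:
    response: str  # "richness" or "abundance"
    intercept: float
    terms: list[SmoothTerm]
    dispersion: float
    r_squared: float  # in-sample, percent
    edf_total: float
    convergence: dict = field(default_factory=dict)

    def linear_predictor(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        eta = np.full(x.shape[0], self.intercept)
        for k, term in enumerate(self.terms):
            eta = eta + term(x[:, k])
        return eta

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Expected count(s) for land-cover vector(s); never negative."""
        return np.maximum(self.linear_predictor(x), MU_EPS)


# ---------------------------------------------------------------------------
# Basis and penalty construction
# ---------------------------------------------------------------------------


def _spline_structure(x: np.ndarray, area_hint: float | None = None):
    """Clamped cubic knots (quantile-based interior), constraint Z, penalty."""
    x = np.asarray(x, dtype=float)
    lo = min(0.0, float(x.min()))
    hi = float(x.max()) if area_hint is None else max(float(x.max()), 1e-8)
    hi = max(hi, lo + 1e-6)
    n_interior = N_BASIS - 4
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(x, qs)
    # keep knots strictly increasing; fall back to even spacing where data ties
    interior = np.clip(interior, lo + 1e-9, hi - 1e-9)
    if len(np.unique(np.round(interior, 12))) < n_interior:
        interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate([[lo] * 4, np.sort(interior), [hi] * 4])
    p = len(knots) - 4
    b = BSpline.design_matrix(np.clip(x, lo, hi), knots, 3).toarray()
    c = b.sum(axis=0, keepdims=True)  # sum-to-zero constraint over training x
    z = linalg.null_space(c)  # p x (p-1)
    d = np.diff(np.eye(p), n=2, axis=0)  # second-difference penalty
    penalty = z.T @ (d.T @ d) @ z
    return knots, z, b @ z, penalty


def _build_design(
    x: np.ndarray, specs: Sequence[SmoothTermSpec]
) -> tuple[np.ndarray, list[SmoothTerm], list[slice], list[np.ndarray | None]]:
    """Column-stacked design: intercept, then one block per term."""
    n = x.shape[0]
    cols = [np.ones((n, 1))]
    terms: list[SmoothTerm] = []
    blocks: list[slice] = []
    penalties: list[np.ndarray | None] = []
    start = 1
    for k, spec in enumerate(specs):
        xk = x[:, k]
        if spec.df == 1:
            terms.append(
                SmoothTerm(
                    predictor=spec.predictor,
                    df=1,
                    kind="linear",
                    coef=np.zeros(1),
                    xbar=float(xk.mean()),
                    knots=None,
                    constraint=None,
                    mean_f=0.0,
                )
            )
            cols.append((xk - xk.mean())[:, None])
            blocks.append(slice(start, start + 1))
            penalties.append(None)
            start += 1
        else:
            knots, z, bz, pen = _spline_structure(xk)
            terms.append(
                SmoothTerm(
                    predictor=spec.predictor,
                    df=spec.df,
                    kind="spline",
                    coef=np.zeros(bz.shape[1]),
                    xbar=float(xk.mean()),
                    knots=knots,
                    constraint=z,
                    mean_f=0.0,
                )
            )
            cols.append(bz)
            blocks.append(slice(start, start + bz.shape[1]))
            penalties.append(pen)
            start += bz.shape[1]
    return np.hstack(cols), terms, blocks, penalties


# ---------------------------------------------------------------------------
# Penalized IRLS with identity link
# ---------------------------------------------------------------------------


def _penalty_matrix(n_cols, blocks, penalties, lams):
    P = np.zeros((n_cols, n_cols))
    for blk, pen, lam in zip(blocks, penalties, lams):
        if pen is not None:
            P[blk, blk] += lam * pen
    return P


def _edf_by_term(X, w, P, blocks):
    XtWX = X.T @ (w[:, None] * X)
    A = XtWX + P + 1e-9 * np.eye(X.shape[1])
    F = linalg.solve(A, XtWX, assume_a="pos")
    diag = np.diag(F)
    return np.array([diag[blk].sum() for blk in blocks]), float(diag.sum())


def _pirls(X, y, P, beta0=None, max_iter=200, tol=1e-10):
    """Penalized IRLS for Poisson with identity link; mean clamped at MU_EPS."""
    n, p = X.shape
    beta = beta0 if beta0 is not None else np.zeros(p)
    if beta0 is None:
        beta[0] = max(y.mean(), 1.0)
    eta = X @ beta
    mu = np.maximum(eta, MU_EPS)
    dev = _deviance(y, mu) + beta @ P @ beta
    n_clamped = 0
    for it in range(max_iter):
        w = 1.0 / np.maximum(eta, 1e-3)
        z = eta + (y - mu)
        A = X.T @ (w[:, None] * X) + P + 1e-9 * np.eye(p)
        b = X.T @ (w * z)
        beta_new = linalg.solve(A, b, assume_a="pos")
        # step-halving keeps the penalized deviance from increasing
        step = 1.0
        for _ in range(30):
            cand = beta + step * (beta_new - beta)
            eta_c = X @ cand
            mu_c = np.maximum(eta_c, MU_EPS)
            dev_c = _deviance(y, mu_c) + cand @ P @ cand
            if dev_c <= dev + 1e-12:
                break
            step *= 0.5
        delta = np.max(np.abs(cand - beta)) / (1.0 + np.max(np.abs(beta)))
        beta, eta, mu = cand, eta_c, mu_c
        n_clamped = int((eta < MU_EPS).sum())
        converged = delta < tol or abs(dev - dev_c) < tol * (1.0 + abs(dev))
        dev = dev_c
        if converged:
            return beta, mu, eta, {
                "iterations": it + 1,
                "converged": True,
                "n_clamped": n_clamped,
                "deviance": float(_deviance(y, mu)),
            }
    return beta, mu, eta, {
        "iterations": max_iter,
        "converged": False,
        "n_clamped": n_clamped,
        "deviance": float(_deviance(y, mu)),
    }


def _deviance(y, mu):
    mu = np.maximum(mu, MU_EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def _tune_lambdas(X, y, blocks, penalties, specs, beta, n_sweeps=2):
    """Coordinate-wise bisection of log-lambda so each spline hits its edf."""
    lams = np.array(
        [1.0 if pen is not None else 0.0 for pen in penalties], dtype=float
    )
    targets = np.array([s.df for s in specs], dtype=float)
    eta = X @ beta
    w = 1.0 / np.maximum(eta, 1e-3)
    for _ in range(n_sweeps):
        for k, pen in enumerate(penalties):
            if pen is None:
                continue
            lo, hi = -8.0, 10.0
            for _ in range(30):
                mid = 0.5 * (lo + hi)
                lams[k] = 10.0**mid
                P = _penalty_matrix(X.shape[1], blocks, penalties, lams)
                edf, _ = _edf_by_term(X, w, P, blocks)
                if abs(edf[k] - targets[k]) < 1e-3:
                    break
                if edf[k] > targets[k]:
                    lo = mid  # more penalty needed
                else:
                    hi = mid
            else:
                lams[k] = 10.0 ** (0.5 * (lo + hi))
    return lams


def fit_additive(
    x: np.ndarray,
    y: np.ndarray,
    specs: Sequence[SmoothTermSpec] | None = None,
    response: str = "richness",
    max_iter: int = 200,
) -> FittedAdditiveModel:
    """Fit the identity-link Poisson additive model.

    x is the Q x 8 land-cover matrix (columns in canonical category order);
    y the per-quadrat count response.  specs gives the requested df per
    predictor (default: all linear).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2:
        raise ValueError("x must be a 2-D matrix")
    if specs is None:
        specs = [SmoothTermSpec(p, 1) for p in LANDCOVER_CATEGORIES[: x.shape[1]]]
    specs = list(specs)
    if len(specs) != x.shape[1]:
        raise ValueError("one SmoothTermSpec per predictor column required")
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("y must be nonnegative integer counts")
    total_df = 1 + sum(s.df for s in specs)
    if total_df >= x.shape[0]:
        raise ValueError(
            f"total requested df ({total_df}) must be below the number of "
            f"quadrats ({x.shape[0]})"
        )

    X, terms, blocks, penalties = _build_design(x, specs)
    has_splines = any(pen is not None for pen in penalties)

    # alternate lambda tuning (to hit the edf targets) with PIRLS refits
    lams = np.zeros(len(specs))
    if has_splines:
        beta = np.zeros(X.shape[1])
        beta[0] = max(y.mean(), 1.0)
        for _ in range(3):
            lams = _tune_lambdas(X, y, blocks, penalties, specs, beta)
            P = _penalty_matrix(X.shape[1], blocks, penalties, lams)
            beta, mu, eta, diag = _pirls(X, y, P, beta0=beta, max_iter=max_iter)
    else:
        P = np.zeros((X.shape[1], X.shape[1]))
        beta, mu, eta, diag = _pirls(X, y, P, max_iter=max_iter)
    if not diag["converged"]:
        raise FitError(f"IRLS did not converge: {diag}")

    w = 1.0 / np.maximum(eta, 1e-3)
    edf_terms, edf_total = _edf_by_term(X, w, P, blocks)

    # Pearson dispersion: chi-square over residual df
    resid_df = max(x.shape[0] - edf_total, 1.0)
    pearson = float(np.sum((y - mu) ** 2 / np.maximum(mu, MU_EPS)))
    dispersion = pearson / resid_df

    intercept = float(beta[0])
    for k, (term, blk, lam, edf) in enumerate(
        zip(terms, blocks, lams, edf_terms)
    ):
        term.coef = beta[blk].copy()
        term.lam = float(lam)
        term.edf = float(edf)
        term.mean_f = float(np.mean(term(x[:, k])))

    yhat = np.maximum(X @ beta, MU_EPS)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 100.0 * (1.0 - float(np.sum((y - yhat) ** 2)) / sst) if sst > 0 else float("nan")

    return FittedAdditiveModel(
        response=response,
        intercept=intercept,
        terms=terms,
        dispersion=float(dispersion),
        r_squared=r2,
        edf_total=float(edf_total),
        convergence=diag,
    )


# ---------------------------------------------------------------------------
# Model-based quantities
# ---------------------------------------------------------------------------


def validate(model: FittedAdditiveModel, x: np.ndarray, y: np.ndarray) -> float:
    """Goodness of fit of predicted vs observed counts, as a percentage.

    R^2 = 1 - SSE/SST where SSE sums squared prediction errors and SST squared
    deviations of y from its mean.
    """
    y = np.asarray(y, dtype=float)
    yhat = model.predict(x)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("response has zero variance; R^2 undefined")
    return 100.0 * (1.0 - float(np.sum((y - yhat) ** 2)) / sst)


def partial_response(
    model: FittedAdditiveModel, predictor: str, grid: np.ndarray
) -> PartialResponse:
    """Centered contribution of one predictor's smooth along a grid.

    The curve is f_k(g) minus the training mean of f_k, so it reads as the
    count added or removed relative to an average quadrat, all other land
    cover held fixed.
    """
    for k, term in enumerate(model.terms):
        if term.predictor == predictor:
            grid = np.asarray(grid, dtype=float)
            return PartialResponse(
                predictor=predictor,
                grid=grid,
                contribution=term(grid) - term.mean_f,
            )
    raise KeyError(f"predictor {predictor!r} is not a model term")


def predict(model: FittedAdditiveModel, landcover_vector: np.ndarray) -> float:
    """Expected count for a single 8-component land-cover vector."""
    return float(model.predict(np.atleast_2d(landcover_vector))[0])


# ---------------------------------------------------------------------------
# df selection
# ---------------------------------------------------------------------------


def select_df(
    x: np.ndarray,
    y: np.ndarray,
    predictors: Sequence[str] | None = None,
    df_cap: int = DF_CAP_DEFAULT,
    penalty_per_edf: float = 7.5,
    response: str = "richness",
) -> tuple[list[SmoothTermSpec], list[dict]]:
    """Greedy forward df selection from the all-linear baseline.

    At each pass every term's df is tentatively incremented by one and the
    increment that most improves a dispersion-adjusted criterion
    (deviance / dispersion + penalty_per_edf * total edf) is kept; selection
    stops when no increment improves the criterion or every term is at the
    cap.  The dispersion is estimated once, from the all-at-cap model, so the
    criterion is comparable across candidates.  The default complexity
    penalty is conservative (roughly a Bonferroni-corrected chi-square
    threshold for screening eight candidate terms at once), which favours
    parsimonious fits that stay close to the all-linear baseline.

    Returns the chosen specs and the criterion trace.
    """
    x = np.asarray(x, dtype=float)
    if predictors is None:
        predictors = list(LANDCOVER_CATEGORIES[: x.shape[1]])
    if df_cap < 1:
        return [SmoothTermSpec(p, 1) for p in predictors], []

    # dispersion from the most complex candidate, floored at 1
    cap_specs = [SmoothTermSpec(p, df_cap) for p in predictors]
    try:
        phi = max(fit_additive(x, y, cap_specs, response=response).dispersion, 1.0)
    except (FitError, ValueError):
        phi = 1.0

    def criterion(specs):
        m = fit_additive(x, y, specs, response=response)
        return m.convergence["deviance"] / phi + penalty_per_edf * m.edf_total

    current = [SmoothTermSpec(p, 1) for p in predictors]
    best_crit = criterion(current)
    trace = [{"specs": [(s.predictor, s.df) for s in current], "criterion": best_crit}]
    improved = True
    while improved:
        improved = False
        best_candidate = None
        for k in range(len(current)):
            if current[k].df >= df_cap:
                continue
            cand = list(current)
            cand[k] = SmoothTermSpec(cand[k].predictor, cand[k].df + 1)
            try:
                crit = criterion(cand)
            except (FitError, ValueError):
                continue
            if crit < best_crit - 1e-9 and (
                best_candidate is None or crit < best_candidate[1]
            ):
                best_candidate = (cand, crit)
        if best_candidate is not None:
            current, best_crit = best_candidate
            trace.append(
                {"specs": [(s.predictor, s.df) for s in current], "criterion": best_crit}
            )
            improved = True
    return current, trace


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def model_to_json(model: FittedAdditiveModel) -> str:
    payload = {
        "response": model.response,
        "intercept": model.intercept,
        "dispersion": model.dispersion,
        "r_squared": model.r_squared,
        "edf_total": model.edf_total,
        "convergence": model.convergence,
        "terms": [
            {
                "predictor": t.predictor,
                "df": t.df,
                "kind": t.kind,
                "coef": t.coef.tolist(),
                "xbar": t.xbar,
                "knots": None if t.knots is None else t.knots.tolist(),
                "constraint": None
                if t.constraint is None
                else t.constraint.tolist(),
                "mean_f": t.mean_f,
                "edf": t.edf,
                "lam": t.lam,
            }
            for t in model.terms
        ],
    }
    return json.dumps(payload, indent=1)


def model_from_json(text: str) -> FittedAdditiveModel:
    d = json.loads(text)
    terms = [
        SmoothTerm(
            predictor=t["predictor"],
            df=t["df"],
            kind=t["kind"],
            coef=np.array(t["coef"]),
            xbar=t["xbar"],
            knots=None if t["knots"] is None else np.array(t["knots"]),
            constraint=None
            if t["constraint"] is None
            else np.array(t["constraint"]),
            mean_f=t["mean_f"],
            edf=t["edf"],
            lam=t["lam"],
        )
        for t in d["terms"]
    ]
    return FittedAdditiveModel(
        response=d["response"],
        intercept=d["intercept"],
        terms=terms,
        dispersion=d["dispersion"],
        r_squared=d["r_squared"],
        edf_total=d["edf_total"],
        convergence=d["convergence"],
    )
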
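"""Full-information marginal maximum likelihood for the bifactor GRM.

The fitter is an EM algorithm.  The E-step evaluates each person's marginal
likelihood with the bifactor dimension reduction (outer quadrature over the
general trait; nested one-dimensional quadrature over each orthogonal specific
trait), so no numerical integral exceeds two dimensions regardless of the
number of specific factors.  The M-step maximises the expected complete-data
log-likelihood item by item with bounded quasi-Newton steps and an ordering-
preserving reparameterisation of the intercepts (first intercept free, the
rest as cumulative negative increments), which keeps every iterate a valid
graded-response parameter set.

Identification: all latent traits are standard normal and mutually orthogonal
(fixed, not estimated).  The remaining sign indeterminacy per factor is
resolved after convergence by flipping whole factors so slopes are
predominantly positive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .battery import Battery
from .io import encode
from .model import ItemParams, QuadratureGrid, _likelihood_components

__all__ = [
    "FitOptions",
    "FitResult",
    "DegenerateItemError",
    "EstimationError",
    "starting_values",
    "fit_bifactor_grm",
    "fit_unidimensional_grm",
    "posterior_trait_scores",
]

log = logging.getLogger(__name__)

_P_FLOOR = 1e-300


class DegenerateItemError(ValueError):
    """An item whose observed responses cannot identify its parameters."""


class EstimationError(RuntimeError):
    """Numerical failure during fitting."""


@dataclass(frozen=True)
class FitOptions:
    """Tuning knobs of the EM fitter.

    n_quadrature_points applies per latent dimension during the EM iterations
    (scheme selectable: rescaled Gauss-Hermite or equally spaced
    normal-weighted nodes).  Parameter estimates are robust to the EM grid,
    but the absolute marginal log-likelihood is not once a battery carries
    many highly discriminating items, so the final log-likelihood (and with it
    AIC/BIC) is always re-evaluated on a dense equally spaced grid
    (final_loglik_points nodes), which converges spectrally for the narrow
    per-person integrands such batteries produce.  scaling_constant_D is only
    used downstream when converting logistic slopes to factor loadings.
    """

    n_quadrature_points: int = 21
    quadrature_scheme: str = "gauss_hermite"  # or "equally_spaced"
    final_loglik_points: int = 81
    max_em_iterations: int = 500
    param_change_tolerance: float = 1e-4
    loglik_change_tolerance: float = 1e-6
    scaling_constant_D: float = 1.702
    seed: int = 0
    compute_standard_errors: bool = False  # not implemented in v1; logs a notice

    def __post_init__(self) -> None:
        if self.n_quadrature_points < 5:
            raise ValueError("need >=5 quadrature points per dimension")
        if self.quadrature_scheme not in ("gauss_hermite", "equally_spaced"):
            raise ValueError(f"unknown quadrature scheme {self.quadrature_scheme!r}")
        if self.param_change_tolerance <= 0 or self.loglik_change_tolerance <= 0:
            raise ValueError("tolerances must be positive")

    def make_grid(self) -> QuadratureGrid:
        if self.quadrature_scheme == "equally_spaced":
            return QuadratureGrid.equally_spaced(self.n_quadrature_points)
        return QuadratureGrid.gauss_hermite(self.n_quadrature_points)


@dataclass
class FitResult:
    params: list[ItemParams]
    log_likelihood: float
    n_iterations: int
    converged: bool
    aic: float
    bic: float
    n_persons: int
    n_free_parameters: int
    model: str  # "bifactor" | "unidimensional"
    options_used: FitOptions
    loglik_path: list[float] = field(default_factory=list)

    def param_vector(self) -> np.ndarray:
        """All free parameters stacked (slopes then intercepts, item order)."""
        parts = []
        for p in self.params:
            parts.append([p.slope_general, p.slope_specific])
            parts.append(p.intercepts)
        return np.concatenate([np.atleast_1d(np.asarray(x, float)) for x in parts])


def _as_codes(responses, battery: Battery) -> np.ndarray:
    if isinstance(responses, pd.DataFrame):
        return encode(responses, battery)
    codes = np.asarray(responses)
    if codes.ndim != 2 or codes.shape[1] != battery.n_items:
        raise ValueError("response codes must be (n_persons, n_items)")
    return codes.astype(np.int64)


def starting_values(responses, battery: Battery) -> list[ItemParams]:
    """Neutral slopes plus intercepts matching observed category proportions.

    slope_general starts at 1.0 and slope_specific at 0.7 for every item;
    intercepts are inverse-logistic transforms of the observed cumulative
    proportions, clipped away from 0/1 so they stay finite, which makes them
    strictly decreasing by construction.
    """
    codes = _as_codes(responses, battery)
    params = []
    for j, item in enumerate(battery.items):
        x = codes[:, j]
        x = x[x >= 0]
        if np.unique(x).size < 2:
            raise DegenerateItemError(
                f"item {item.item_id}: fewer than 2 observed categories"
            )
        n = x.size
        counts = np.bincount(x, minlength=item.n_categories)
        # P(X >= k+1) observed, k = 1..K-1
        tail = 1.0 - np.cumsum(counts)[:-1] / n
        tail = np.clip(tail, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n))
        d = logit(tail)
        # clipping can create ties at the boundaries; nudge to keep ordering strict
        for k in range(1, d.size):
            if d[k] >= d[k - 1]:
                d[k] = d[k - 1] - 1e-6
        params.append(
            ItemParams(
                item_id=item.item_id,
                slope_general=1.0,
                slope_specific=0.7,
                intercepts=d,
            )
        )
    return params


# ---------------------------------------------------------------------------
# M-step: per-item expected complete-data log-likelihood
# ---------------------------------------------------------------------------


def _pack(p: ItemParams, fix_specific: bool) -> np.ndarray:
    d = p.intercepts
    gaps = np.log(np.clip(-np.diff(d), 1e-8, None))
    head = [p.slope_general] if fix_specific else [p.slope_general, p.slope_specific]
    return np.concatenate([head, [d[0]], gaps])


def _unpack(x: np.ndarray, K: int, fix_specific: bool):
    if fix_specific:
        a_g, a_s = x[0], 0.0
        rest = x[1:]
    else:
        a_g, a_s = x[0], x[1]
        rest = x[2:]
    d1 = rest[0]
    t = rest[1:]
    d = d1 - np.concatenate(([0.0], np.cumsum(np.exp(t))))
    return a_g, a_s, d, t


def _item_objective(x, R, tg, ts, K, fix_specific):
    """Negative expected complete-data log-likelihood and its gradient.

    R has shape (K, M) over the flattened (general, specific) grid with node
    coordinates tg, ts (each length M).
    """
    a_g, a_s, d, t = _unpack(x, K, fix_specific)
    z = a_g * tg[None, :] + a_s * ts[None, :] + d[:, None]  # (K-1, M)
    pstar = expit(z)
    cum = np.vstack([np.ones_like(tg), pstar, np.zeros_like(tg)])
    P = np.clip(cum[:-1] - cum[1:], _P_FLOOR, None)  # (K, M)
    f = float(np.sum(R * np.log(P)))

    ratio = R / P  # rows: categories 1..K
    # d f / d z_k = (ratio_{k+1} - ratio_k) * pstar_k (1 - pstar_k), boundary k=1..K-1
    gz = (ratio[1:] - ratio[:-1]) * pstar * (1.0 - pstar)  # (K-1, M)
    gd = gz.sum(axis=1)  # per intercept
    g_ag = float(np.sum(gz * tg[None, :]))
    g_as = float(np.sum(gz * ts[None, :]))
    g_d1 = float(gd.sum())
    # d d_k / d t_m = -exp(t_m) for k > m (0-based gaps)
    tail = np.cumsum(gd[::-1])[::-1]
    g_t = -np.exp(t) * tail[1:]
    head = [g_ag] if fix_specific else [g_ag, g_as]
    grad = np.concatenate([head, [g_d1], g_t])
    return -f, -grad


def _mstep_item(p: ItemParams, R: np.ndarray, tg: np.ndarray, ts: np.ndarray, fix_specific: bool) -> ItemParams:
    K = p.n_categories
    x0 = _pack(p, fix_specific)
    n_slope = 1 if fix_specific else 2
    bounds = [(-30.0, 30.0)] * n_slope + [(-60.0, 60.0)] + [(-25.0, 8.0)] * (K - 2)
    res = minimize(
        _item_objective,
        x0,
        args=(R.reshape(K, -1), tg, ts, K, fix_specific),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
    )
    a_g, a_s, d, _ = _unpack(res.x, K, fix_specific)
    return ItemParams(item_id=p.item_id, slope_general=a_g, slope_specific=a_s, intercepts=d)


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------


def _expected_counts(comp, codes, item_factor, n_categories):
    """Posterior-expected category counts per item on the 2-D node grid."""
    grid = comp["grid"]
    wg, wr = grid.weights, grid.weights
    Ls, A, Lm = comp["Ls"], comp["A"], comp["Lm"]
    n, J = codes.shape
    n_fac = len(A)
    counts = [None] * J
    for s in range(n_fac):
        Lother = np.ones_like(Ls[0])
        for s2 in range(n_fac):
            if s2 != s:
                Lother *= Ls[s2]
        outer = wg[None, :] * Lother / Lm[:, None]  # (n, G)
        post = A[s] * outer[:, :, None] * wr[None, None, :]  # (n, G, Q)
        flat = post.reshape(n, -1)
        for j in np.flatnonzero(item_factor == s):
            K = n_categories[j]
            onehot = np.zeros((n, K))
            x = codes[:, j]
            obs = x >= 0
            onehot[np.flatnonzero(obs), x[obs]] = 1.0
            counts[j] = (onehot.T @ flat).reshape(K, wg.size, wr.size)
    return counts


def _normalize_signs(params: list[ItemParams], battery: Battery) -> list[ItemParams]:
    """Flip whole factors so slopes are predominantly positive."""
    out = list(params)
    if sum(p.slope_general for p in out) < 0:
        out = [replace(p, slope_general=-p.slope_general) for p in out]
    for s in range(1, battery.n_specific_factors + 1):
        idx = battery.items_for_factor(s)
        if sum(out[j].slope_specific for j in idx) < 0:
            for j in idx:
                out[j] = replace(out[j], slope_specific=-out[j].slope_specific)
    return out


def _pack_all(params: list[ItemParams], fix_specific: bool) -> np.ndarray:
    return np.concatenate([_pack(p, fix_specific) for p in params])


def _unpack_all(x: np.ndarray, params: list[ItemParams], fix_specific: bool) -> list[ItemParams]:
    out = []
    pos = 0
    for p in params:
        K = p.n_categories
        width = (1 if fix_specific else 2) + (K - 1)
        a_g, a_s, d, _ = _unpack(x[pos : pos + width], K, fix_specific)
        out.append(ItemParams(p.item_id, a_g, a_s, d))
        pos += width
    return out


def _fit_em(responses, battery: Battery, options: FitOptions, model: str) -> FitResult:
    codes = _as_codes(responses, battery)
    item_factor = np.asarray(battery.factor_index, dtype=int)
    n_categories = [it.n_categories for it in battery.items]
    for j, item in enumerate(battery.items):
        x = codes[:, j]
        obs = x[x >= 0]
        if obs.size and obs.max() >= item.n_categories:
            raise ValueError(
                f"item {item.item_id}: response code out of range 1..{item.n_categories}"
            )
    if options.compute_standard_errors:
        log.info(
            "standard errors are not implemented in v1; "
            "point estimates are returned without uncertainty"
        )
    grid = options.make_grid()
    tg2, ts2 = np.meshgrid(grid.nodes, grid.nodes, indexing="ij")
    tgf, tsf = tg2.ravel(), ts2.ravel()

    fix_specific = model == "unidimensional"
    params = starting_values(codes, battery)
    if fix_specific:
        params = [replace(p, slope_specific=0.0) for p in params]

    loglik = -np.inf
    converged = False
    it = 0
    loglik_path: list[float] = []
    prev_delta: np.ndarray | None = None
    pending_accel = False
    safe_params: list[ItemParams] | None = None
    for it in range(1, options.max_em_iterations + 1):
        comp = _likelihood_components(params, item_factor, codes, grid)
        new_loglik = float(comp["loglik_i"].sum())
        if pending_accel and (not np.isfinite(new_loglik) or new_loglik < loglik - 1e-10):
            # Ramsay extrapolation overshot: fall back to the plain EM iterate,
            # whose ascent property is guaranteed
            params = safe_params
            pending_accel = False
            prev_delta = None
            comp = _likelihood_components(params, item_factor, codes, grid)
            new_loglik = float(comp["loglik_i"].sum())
        if not np.isfinite(new_loglik):
            raise EstimationError(f"non-finite marginal log-likelihood at EM iteration {it}")
        if new_loglik < loglik - 1e-8:
            warnings.warn(
                f"EM log-likelihood decreased by {loglik - new_loglik:.3g} at iteration {it}",
                RuntimeWarning,
            )
        ll_change = new_loglik - loglik
        loglik = new_loglik
        loglik_path.append(new_loglik)

        counts = _expected_counts(comp, codes, item_factor, n_categories)
        new_params = [
            _mstep_item(p, R, tgf, tsf, fix_specific) for p, R in zip(params, counts)
        ]
        change = max(
            max(
                abs(q.slope_general - p.slope_general),
                abs(q.slope_specific - p.slope_specific),
                float(np.max(np.abs(q.intercepts - p.intercepts))),
            )
            for p, q in zip(params, new_params)
        )
        if change <= options.param_change_tolerance or (
            it > 1 and abs(ll_change) <= options.loglik_change_tolerance
        ):
            params = new_params
            converged = True
            break

        # Ramsay-type acceleration: extrapolate along the EM step in the
        # order-preserving reparameterised space when convergence is geometric
        delta = _pack_all(new_params, fix_specific) - _pack_all(params, fix_specific)
        accelerated = False
        if it >= 4 and prev_delta is not None:
            denom = float(np.linalg.norm(prev_delta))
            rate = float(np.linalg.norm(delta)) / denom if denom > 0 else np.inf
            if 0.0 < rate < 1.0:
                alpha = min(rate / (1.0 - rate), 9.0)
                x_acc = _pack_all(new_params, fix_specific) + alpha * delta
                # keep extrapolated values within the M-step bounds
                x_acc = np.clip(x_acc, -55.0, 55.0)
                safe_params = new_params
                params = _unpack_all(x_acc, new_params, fix_specific)
                pending_accel = True
                accelerated = True
        if not accelerated:
            params = new_params
            pending_accel = False
        prev_delta = delta

    params = _normalize_signs(params, battery)
    # final log-likelihood on the dense grid: comparable across models even
    # when the EM grid under-resolves the per-person integrand
    dense = QuadratureGrid.equally_spaced(options.final_loglik_points)
    comp = _likelihood_components(params, item_factor, codes, dense)
    loglik = float(comp["loglik_i"].sum())

    slopes_per_item = 1 if fix_specific else 2
    p_free = sum(slopes_per_item + it_.n_categories - 1 for it_ in battery.items)
    n_persons = int(np.sum((codes >= 0).any(axis=1)))
    if not converged:
        log.warning("EM hit the iteration cap (%d) without converging", options.max_em_iterations)
    return FitResult(
        params=params,
        log_likelihood=loglik,
        n_iterations=it,
        converged=converged,
        aic=-2.0 * loglik + 2.0 * p_free,
        bic=-2.0 * loglik + p_free * np.log(max(n_persons, 1)),
        n_persons=n_persons,
        n_free_parameters=p_free,
        model=model,
        options_used=options,
        loglik_path=loglik_path,
    )


def fit_bifactor_grm(responses, battery: Battery, options: FitOptions | None = None) -> FitResult:
    """Fit the bifactor graded response model by MML-EM.

    Responses may be an external 1..K DataFrame or an internal code array.
    Missing responses are treated as ignorable and dropped from the person's
    likelihood product.  Returns ``converged=False`` (with a logged warning)
    rather than raising when the iteration cap is reached.
    """
    return _fit_em(responses, battery, options or FitOptions(), "bifactor")


def fit_unidimensional_grm(responses, battery: Battery, options: FitOptions | None = None) -> FitResult:
    """Fit the nested unidimensional GRM (all specific slopes fixed to 0)."""
    return _fit_em(responses, battery, options or FitOptions(), "unidimensional")


def posterior_trait_scores(fit: FitResult, responses, battery: Battery) -> pd.DataFrame:
    """Expected a-posteriori (EAP) scores for the general and specific traits.

    Uses the same dimension-reduced grids as the fitter.  Persons with no
    observed responses get NaN scores (the posterior is the prior, but the
    score carries no information; they are flagged via the ``all_missing``
    column).
    """
    codes = _as_codes(responses, battery)
    item_factor = np.asarray(battery.factor_index, dtype=int)
    grid = fit.options_used.make_grid()
    comp = _likelihood_components(fit.params, item_factor, codes, grid)
    wg = grid.weights
    Ls, A, Lm, Ltot = comp["Ls"], comp["A"], comp["Lm"], comp["Ltot"]
    post_g = wg[None, :] * Ltot / Lm[:, None]  # (n, G), rows sum to 1
    theta_g = post_g @ grid.nodes

    n = codes.shape[0]
    out = {"theta_general": theta_g}
    for s in range(len(A)):
        Lother = np.ones_like(Ls[0])
        for s2 in range(len(A)):
            if s2 != s:
                Lother *= Ls[s2]
        outer = wg[None, :] * Lother / Lm[:, None]
        post = A[s] * outer[:, :, None] * grid.weights[None, None, :]
        out[f"theta_specific_{s + 1}"] = post.sum(axis=1) @ grid.nodes

    idx = responses.index if isinstance(responses, pd.DataFrame) else pd.RangeIndex(n)
    df = pd.DataFrame(out, index=idx)
    all_missing = ~(codes >= 0).any(axis=1)
    df["all_missing"] = all_missing
    df.loc[all_missing, df.columns != "all_missing"] = np.nan
    return df
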
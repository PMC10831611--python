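"""Bifactor graded response model: probabilities, likelihood, information, surfaces.

The model is a compensatory two-parameter-logistic graded response model in
which every item measures one general trait (``theta_general``) and exactly one
of several mutually orthogonal specific traits (``theta_specific``).  For an
item with K ordered categories (coded 0..K-1 internally, 1..K at the I/O
boundary) the cumulative "boundary" probabilities are

    P*(X >= k | theta) = logistic(a_g * theta_g + a_s * theta_s + d_k),

k = 1..K-1, with strictly decreasing intercepts d_1 > d_2 > ... > d_{K-1},
and category probabilities are differences of adjacent boundaries.  All latent
traits are standard normal; marginalisation uses Gauss-Hermite quadrature
rescaled to the standard-normal density, with the bifactor factorisation so no
integral exceeds two dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import expit

__all__ = [
    "ThetaPoint",
    "ItemParams",
    "QuadratureGrid",
    "SurfaceGrid",
    "ParameterError",
    "boundary_probability",
    "category_probabilities",
    "expected_item_score",
    "inflexion_line",
    "item_information",
    "marginal_information_curve",
    "evaluate_surface",
    "marginal_log_likelihood",
    "reverse_coded_params",
]

SURFACE_KINDS = ("category_probability", "expected_score", "information")

# floor for probabilities entering logs / denominators
_P_FLOOR = 1e-300


class ParameterError(ValueError):
    """Invalid item parameters (e.g. non-decreasing intercepts)."""


class ThetaPoint(NamedTuple):
    """A point in the (general, specific) latent-trait plane."""

    theta_general: float
    theta_specific: float


@dataclass(frozen=True)
class ItemParams:
    """Conditional item parameters of the bifactor graded response model.

    Parameters
    ----------
    item_id
        Identifier matching the battery configuration.
    slope_general
        Conditional slope (discrimination) on the general trait.
    slope_specific
        Conditional slope on the item's single specific trait.
    intercepts
        K-1 strictly decreasing intercepts ``d_k`` of the cumulative
        logistic boundaries.
    """

    item_id: str
    slope_general: float
    slope_specific: float
    intercepts: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.intercepts, dtype=float)
        object.__setattr__(self, "intercepts", d)
        if d.ndim != 1 or d.size < 1:
            raise ParameterError(f"item {self.item_id}: need >=1 intercept")
        if not np.all(np.isfinite(d)):
            raise ParameterError(f"item {self.item_id}: non-finite intercepts")
        if d.size > 1 and not np.all(np.diff(d) < 0):
            raise ParameterError(
                f"item {self.item_id}: intercepts must be strictly decreasing, got {d}"
            )
        if not (np.isfinite(self.slope_general) and np.isfinite(self.slope_specific)):
            raise ParameterError(f"item {self.item_id}: non-finite slope")

    @property
    def n_categories(self) -> int:
        return self.intercepts.size + 1


@dataclass(frozen=True)
class QuadratureGrid:
    """Nodes and weights integrating against the standard-normal density."""

    nodes: np.ndarray
    weights: np.ndarray

    @classmethod
    def gauss_hermite(cls, n_points: int) -> "QuadratureGrid":
        if n_points < 5:
            raise ValueError("need at least 5 quadrature points")
        x, w = hermgauss(n_points)
        nodes = x * np.sqrt(2.0)
        weights = w / np.sqrt(np.pi)
        return cls(nodes=nodes, weights=weights / weights.sum())

    @classmethod
    def equally_spaced(cls, n_points: int, span: float = 6.0) -> "QuadratureGrid":
        """Rectangular rule: equally spaced nodes weighted by the normal density.

        For per-person integrands that are much narrower than the prior (many
        highly discriminating items) the trapezoid-type rule converges
        spectrally in the node spacing, where Gauss-Hermite nodes are too
        sparse near the centre; this is the preferred rule for accurate
        log-likelihood evaluation and model comparison.
        """
        if n_points < 5:
            raise ValueError("need at least 5 quadrature points")
        nodes = np.linspace(-span, span, n_points)
        w = np.exp(-0.5 * nodes**2)
        return cls(nodes=nodes, weights=w / w.sum())


@dataclass
class SurfaceGrid:
    """A surface evaluated on a theta_general x theta_specific grid."""

    theta_general_axis: np.ndarray
    theta_specific_axis: np.ndarray
    values: np.ndarray  # shape (len(general axis), len(specific axis))
    kind: str

    def __post_init__(self) -> None:
        g = np.asarray(self.theta_general_axis, float)
        s = np.asarray(self.theta_specific_axis, float)
        if self.values.shape != (g.size, s.size):
            raise ValueError("surface values do not match axes")


def _boundary_logits(params: ItemParams, theta_g, theta_s):
    """Logits of all K-1 boundaries; broadcasts theta arrays."""
    z = (
        params.slope_general * np.asarray(theta_g, float)[..., None]
        + params.slope_specific * np.asarray(theta_s, float)[..., None]
        + params.intercepts
    )
    return z


def boundary_probability(params: ItemParams, boundary_index: int, theta: ThetaPoint) -> float:
    """P(X >= boundary_index + 1 | theta), boundary_index in 1..K-1.

    Strictly increasing in each trait whose slope is positive; equals 0.5 on
    the boundary's inflexion line.
    """
    k = int(boundary_index)
    if not 1 <= k <= params.n_categories - 1:
        raise IndexError(
            f"boundary_index {k} invalid for {params.n_categories} categories"
        )
    tg, ts = theta
    z = params.slope_general * tg + params.slope_specific * ts + params.intercepts[k - 1]
    return float(expit(z))


def category_probabilities(params: ItemParams, theta: ThetaPoint) -> np.ndarray:
    """Probabilities of the K ordered categories at one theta point.

    Returns a length-K vector of adjacent boundary differences; entries are
    non-negative (guaranteed by decreasing intercepts) and sum to 1.
    """
    tg, ts = theta
    z = params.slope_general * tg + params.slope_specific * ts + params.intercepts
    pstar = expit(z)
    cum = np.concatenate(([1.0], pstar, [0.0]))
    return cum[:-1] - cum[1:]


def expected_item_score(params: ItemParams, theta: ThetaPoint) -> float:
    """Expected response on the external 1..K scale, sum_k k * P(k | theta)."""
    p = category_probabilities(params, theta)
    return float(np.dot(p, np.arange(1, params.n_categories + 1)))


def inflexion_line(params: ItemParams, boundary_index: int) -> tuple[float, float, float]:
    """Coefficients (a_g, a_s, d_k) of the 0.5-probability locus for a boundary.

    Any (theta_g, theta_s) with a_g*theta_g + a_s*theta_s + d_k = 0 has
    boundary probability exactly 0.5.
    """
    k = int(boundary_index)
    if not 1 <= k <= params.n_categories - 1:
        raise IndexError(f"boundary_index {k} invalid for {params.n_categories} categories")
    if params.slope_general == 0.0 and params.slope_specific == 0.0:
        raise ParameterError(f"item {params.item_id}: both slopes zero, inflexion line degenerate")
    return (params.slope_general, params.slope_specific, float(params.intercepts[k - 1]))


def item_information(params: ItemParams, theta: ThetaPoint) -> np.ndarray:
    """Fisher information matrix (2x2) of one item at a theta point.

    For the graded response model all boundaries share the slope vector
    a = (a_g, a_s), so I(theta) = a a^T * sum_c (w_{c-1} - w_c)^2 / P_c with
    w_k = P*_k (1 - P*_k) the boundary logistic densities (w_0 = w_K = 0);
    this equals the expected negative Hessian of the item log-likelihood.
    """
    tg, ts = theta
    z = params.slope_general * tg + params.slope_specific * ts + params.intercepts
    pstar = expit(z)
    w = np.concatenate(([0.0], pstar * (1.0 - pstar), [0.0]))
    cum = np.concatenate(([1.0], pstar, [0.0]))
    p = np.clip(cum[:-1] - cum[1:], _P_FLOOR, None)
    scalar = float(np.sum((w[:-1] - w[1:]) ** 2 / p))
    a = np.array([params.slope_general, params.slope_specific])
    return scalar * np.outer(a, a)


def marginal_information_curve(
    marginal_slope: float, intercepts: Sequence[float], theta_axis: Sequence[float]
) -> np.ndarray:
    """Unidimensional graded-response information along one trait axis.

    Evaluates the standard GRM item information with the marginal slope in
    place of the conditional slope, i.e. the information about one factor when
    the other factor's contribution is absorbed into the error term.  For
    K = 2 this reduces to a^2 P* (1 - P*).
    """
    a = float(marginal_slope)
    d = np.asarray(intercepts, float)
    th = np.asarray(theta_axis, float)
    z = a * th[:, None] + d
    pstar = expit(z)
    w = np.concatenate(
        [np.zeros((th.size, 1)), pstar * (1 - pstar), np.zeros((th.size, 1))], axis=1
    )
    cum = np.concatenate([np.ones((th.size, 1)), pstar, np.zeros((th.size, 1))], axis=1)
    p = np.clip(cum[:, :-1] - cum[:, 1:], _P_FLOOR, None)
    return a * a * np.sum((w[:, :-1] - w[:, 1:]) ** 2 / p, axis=1)


def default_axes(n_points: int = 81, span: float = 6.0) -> np.ndarray:
    """Default plotting axis: 81 points on [-6, 6]."""
    return np.linspace(-span, span, n_points)


def evaluate_surface(
    params: ItemParams,
    kind: str,
    theta_general_axis: Sequence[float] | None = None,
    theta_specific_axis: Sequence[float] | None = None,
    category: int | None = None,
    direction: Sequence[float] | None = None,
) -> SurfaceGrid:
    """Evaluate a category-probability, expected-score or information surface.

    Parameters
    ----------
    kind
        One of ``category_probability`` (requires ``category`` on the external
        1..K scale), ``expected_score``, or ``information``.
    direction
        Unit direction v for the scalar information surface v' I(theta) v.
        Defaults to the normalised conditional-slope vector, the direction in
        which the item discriminates (and informs) most.
    """
    if kind not in SURFACE_KINDS:
        raise ValueError(f"unknown surface kind {kind!r}; expected one of {SURFACE_KINDS}")
    tg = default_axes() if theta_general_axis is None else np.asarray(theta_general_axis, float)
    ts = default_axes() if theta_specific_axis is None else np.asarray(theta_specific_axis, float)
    for ax in (tg, ts):
        if ax.size > 1 and not np.all(np.diff(ax) > 0):
            raise ValueError("surface axes must be strictly increasing")

    G, S = np.meshgrid(tg, ts, indexing="ij")
    z = (
        params.slope_general * G[..., None]
        + params.slope_specific * S[..., None]
        + params.intercepts
    )
    pstar = expit(z)
    ones = np.ones(z.shape[:-1] + (1,))
    zeros = np.zeros_like(ones)
    cum = np.concatenate([ones, pstar, zeros], axis=-1)
    pcat = cum[..., :-1] - cum[..., 1:]

    if kind == "category_probability":
        if category is None or not 1 <= int(category) <= params.n_categories:
            raise ValueError(
                f"category_probability surface needs a category in 1..{params.n_categories}"
            )
        values = pcat[..., int(category) - 1]
    elif kind == "expected_score":
        values = np.tensordot(pcat, np.arange(1, params.n_categories + 1), axes=([-1], [0]))
    else:  # information
        a = np.array([params.slope_general, params.slope_specific])
        if direction is None:
            norm = np.linalg.norm(a)
            v = a / norm if norm > 0 else np.array([1.0, 0.0])
        else:
            v = np.asarray(direction, float)
            v = v / np.linalg.norm(v)
        w = pstar * (1 - pstar)
        wpad = np.concatenate([zeros, w, zeros], axis=-1)
        scalar = np.sum(
            (wpad[..., :-1] - wpad[..., 1:]) ** 2 / np.clip(pcat, _P_FLOOR, None), axis=-1
        )
        values = scalar * float(np.dot(a, v)) ** 2

    return SurfaceGrid(theta_general_axis=tg, theta_specific_axis=ts, values=values, kind=kind)


def reverse_coded_params(params: ItemParams) -> ItemParams:
    """Parameter map matching the response recode x -> K+1-x.

    Negating both slopes and negating + order-reversing the intercepts leaves
    the category probabilities (reindexed) and the marginal likelihood exactly
    invariant.
    """
    return ItemParams(
        item_id=params.item_id,
        slope_general=-params.slope_general,
        slope_specific=-params.slope_specific,
        intercepts=-params.intercepts[::-1],
    )


# ---------------------------------------------------------------------------
# Marginal likelihood with bifactor dimension reduction
# ---------------------------------------------------------------------------


def _category_prob_grid(params: ItemParams, nodes_g: np.ndarray, nodes_s: np.ndarray) -> np.ndarray:
    """Category probabilities on the (general x specific) node grid: (K, G, Q)."""
    z = (
        params.slope_general * nodes_g[:, None, None]
        + params.slope_specific * nodes_s[None, :, None]
        + params.intercepts[None, None, :]
    )  # (G, Q, K-1)
    pstar = expit(z)
    ones = np.ones(z.shape[:-1] + (1,))
    cum = np.concatenate([ones, pstar, np.zeros_like(ones)], axis=-1)
    pcat = cum[..., :-1] - cum[..., 1:]  # (G, Q, K)
    return np.moveaxis(pcat, -1, 0)


def _likelihood_components(
    params_list: Sequence[ItemParams],
    item_factor: np.ndarray,
    codes: np.ndarray,
    grid: QuadratureGrid,
):
    """Shared E-step quantities under the bifactor factorisation.

    Parameters
    ----------
    params_list
        One ItemParams per item, battery order.
    item_factor
        Specific-factor index per item (0-based, contiguous).
    codes
        (n_persons, n_items) integer categories 0..K-1, -1 for missing.
    grid
        Quadrature nodes/weights used for both the general and the specific
        dimension.

    Returns a dict with per-person log-likelihoods and, per specific factor,
    the joint person x node arrays needed for posterior expectations.  Every
    integral is at most two-dimensional: the general trait is integrated on the
    outer grid and each specific trait on an inner grid nested within it.
    """
    nodes, weights = grid.nodes, grid.weights
    n, J = codes.shape
    n_fac = int(item_factor.max()) + 1 if J else 0

    A = []  # per factor: (n, G, Q) joint conditional likelihood of that factor's items
    Ls = []  # per factor: (n, G) inner integral over the specific trait
    logscale = np.zeros(n)
    for s in range(n_fac):
        acc = np.ones((n, nodes.size, nodes.size))
        for j in np.flatnonzero(item_factor == s):
            pg = _category_prob_grid(params_list[j], nodes, nodes)  # (K, G, Q)
            x = codes[:, j]
            obs = x >= 0
            lik = pg[np.where(obs, x, 0)]  # (n, G, Q)
            lik[~obs] = 1.0
            acc *= lik
        ls_raw = acc @ weights  # (n, G)
        c = np.maximum(ls_raw.max(axis=1), _P_FLOOR)
        acc /= c[:, None, None]
        ls_raw /= c[:, None]
        logscale += np.log(c)
        A.append(acc)
        Ls.append(ls_raw)

    Ltot = np.ones((n, nodes.size))
    for ls in Ls:
        Ltot *= ls
    Lm = np.clip(Ltot @ weights, _P_FLOOR, None)  # (n,)
    loglik_i = np.log(Lm) + logscale
    return {
        "A": A,
        "Ls": Ls,
        "Ltot": Ltot,
        "Lm": Lm,
        "loglik_i": loglik_i,
        "grid": grid,
    }


def marginal_log_likelihood(
    params_list: Sequence[ItemParams],
    item_factor: Sequence[int],
    codes: np.ndarray,
    grid: QuadratureGrid | None = None,
) -> float:
    """Marginal log-likelihood of a response matrix under the bifactor GRM.

    ``codes`` holds 0-based categories with -1 for missing.  Each person's
    likelihood integrates the general trait over one dimension and, nested
    within it, each orthogonal specific trait independently.
    """
    codes = np.asarray(codes)
    item_factor = np.asarray(item_factor, dtype=int)
    if grid is None:
        grid = QuadratureGrid.gauss_hermite(21)
    for j, p in enumerate(params_list):
        x = codes[:, j]
        obs = x[x >= 0]
        if obs.size and (obs.min() < 0 or obs.max() >= p.n_categories):
            raise ValueError(
                f"item {p.item_id}: response code out of range 0..{p.n_categories - 1}"
            )
    comp = _likelihood_components(list(params_list), item_factor, codes, grid)
    return float(comp["loglik_i"].sum())
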
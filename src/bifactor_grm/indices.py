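"""Derived bifactor indices: MDISC, MDIFF, marginal loadings/slopes, ECV.

Conventions
-----------
Conditional slopes live on the logistic metric; conversion to factor loadings
uses the scaling constant D (default 1.702).  The marginal loading of an item
on one factor treats the other factor's contribution as part of the error
variance:

    lambda = a / sqrt(a_g^2 + a_s^2 + D^2)

and the marginal slope inverts the unidimensional loading formula per factor,

    a* = D * lambda / sqrt(1 - lambda^2),

so a factorially pure item keeps its conditional slope while two-factor items
show shrinkage (|a*| <= |a| always).  Explained common variance is computed
from squared marginal loadings: at the item level IECVg = lg^2/(lg^2+ls^2);
at the battery level ECVg sums squared general loadings over the summed
communalities, and each specific factor's ECVs uses its items' squared
specific loadings over the same global denominator, so ECVg + sum ECVs = 1.

An alternative "communality" convention for the marginal slope (unexplained
variance 1 - h^2 instead of 1 - lambda^2) is switchable via ``convention``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .battery import Battery

__all__ = [
    "ItemIndices",
    "ModelIndices",
    "mdisc",
    "mdiff",
    "marginal_loadings",
    "marginal_slope",
    "item_ecv",
    "model_ecv",
    "compute_item_indices",
    "parameter_table",
    "DEFAULT_D",
]

DEFAULT_D = 1.702


@dataclass(frozen=True)
class ItemIndices:
    item_id: str
    mdisc: float
    mdiff: np.ndarray
    loading_general: float
    loading_specific: float
    marginal_slope_general: float
    marginal_slope_specific: float
    communality: float
    iecv_general: float
    iecv_specific: float


@dataclass(frozen=True)
class ModelIndices:
    ecv_general: float
    ecv_specific: dict[int, float]  # keyed by 1-based specific factor index
    slope_means: pd.DataFrame  # conditional & marginal slope means per factor
    mdisc_mean: float


def mdisc(slope_general: float, slope_specific: float) -> float:
    """Multidimensional discrimination: root-sum-of-squares of the slopes."""
    return math.hypot(slope_general, slope_specific)


def mdiff(intercepts, mdisc_value: float) -> np.ndarray:
    """Per-boundary multidimensional location, MDIFF_k = -d_k / MDISC.

    Strictly increasing because intercepts are strictly decreasing; the round
    trip d_k = -(MDIFF_k * MDISC) recovers the intercepts exactly.
    """
    if mdisc_value == 0:
        raise ZeroDivisionError("MDIFF undefined for an item with MDISC = 0")
    return -np.asarray(intercepts, float) / mdisc_value


def marginal_loadings(slope_general: float, slope_specific: float, D: float = DEFAULT_D):
    """Marginal factor loadings implied by the conditional logistic slopes."""
    if D <= 0:
        raise ValueError("scaling constant D must be positive")
    denom = math.sqrt(slope_general**2 + slope_specific**2 + D * D)
    return slope_general / denom, slope_specific / denom


def marginal_slope(
    loading: float,
    other_loading: float = 0.0,
    D: float = DEFAULT_D,
    convention: str = "per_factor",
) -> float:
    """Marginal (single-factor) slope implied by a marginal loading.

    ``per_factor`` folds the other factor's variance into the error term
    (unexplained variance 1 - lambda^2); ``communality`` uses 1 - h^2 with
    h^2 = loading^2 + other_loading^2.
    """
    if abs(loading) >= 1:
        raise ValueError(f"|loading| must be < 1, got {loading}")
    if convention == "per_factor":
        unexplained = 1.0 - loading * loading
    elif convention == "communality":
        unexplained = 1.0 - loading * loading - other_loading * other_loading
        if unexplained <= 0:
            raise ValueError("communality >= 1; marginal slope undefined")
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return D * loading / math.sqrt(unexplained)


def item_ecv(loading_general: float, loading_specific: float) -> tuple[float, float]:
    """Item explained common variance split (IECVg, IECVs); sums to 1."""
    lg2, ls2 = loading_general**2, loading_specific**2
    h2 = lg2 + ls2
    if h2 == 0:
        raise ZeroDivisionError("IECV undefined for an item with zero communality")
    return lg2 / h2, ls2 / h2


def compute_item_indices(params, D: float = DEFAULT_D, convention: str = "per_factor") -> ItemIndices:
    """All per-item derived quantities from one item's conditional parameters."""
    m = mdisc(params.slope_general, params.slope_specific)
    lg, ls = marginal_loadings(params.slope_general, params.slope_specific, D)
    iecv_g, iecv_s = item_ecv(lg, ls)
    return ItemIndices(
        item_id=params.item_id,
        mdisc=m,
        mdiff=mdiff(params.intercepts, m) if m > 0 else np.full(params.intercepts.size, np.nan),
        loading_general=lg,
        loading_specific=ls,
        marginal_slope_general=marginal_slope(lg, ls, D, convention),
        marginal_slope_specific=marginal_slope(ls, lg, D, convention),
        communality=lg * lg + ls * ls,
        iecv_general=iecv_g,
        iecv_specific=iecv_s,
    )


def model_ecv(item_indices: list[ItemIndices], battery: Battery) -> ModelIndices:
    """Battery-level explained common variance and slope-mean summaries."""
    lg2 = np.array([ix.loading_general**2 for ix in item_indices])
    ls2 = np.array([ix.loading_specific**2 for ix in item_indices])
    total = float(lg2.sum() + ls2.sum())
    if total == 0:
        raise ZeroDivisionError("ECV undefined: all loadings zero")
    ecv_g = float(lg2.sum()) / total
    ecv_s: dict[int, float] = {}
    for s in range(1, battery.n_specific_factors + 1):
        idx = battery.items_for_factor(s)
        ecv_s[s] = float(ls2[idx].sum()) / total

    rows = []
    msg = np.array([ix.marginal_slope_general for ix in item_indices])
    mss = np.array([ix.marginal_slope_specific for ix in item_indices])
    rows.append(
        {
            "factor": "general",
            "conditional_slope_mean": np.nan,  # filled by parameter_table (needs raw params)
            "marginal_slope_mean": float(msg.mean()),
        }
    )
    for s in range(1, battery.n_specific_factors + 1):
        idx = battery.items_for_factor(s)
        rows.append(
            {
                "factor": f"specific_{s}",
                "conditional_slope_mean": np.nan,
                "marginal_slope_mean": float(mss[idx].mean()),
            }
        )
    mdisc_vals = np.array([ix.mdisc for ix in item_indices])
    return ModelIndices(
        ecv_general=ecv_g,
        ecv_specific=ecv_s,
        slope_means=pd.DataFrame(rows).set_index("factor"),
        mdisc_mean=float(mdisc_vals.mean()),
    )


def parameter_table(fit, battery: Battery, D: float | None = None, convention: str = "per_factor"):
    """One row per item with every derived column, plus model-level indices.

    Columns mirror the usual bifactor report: conditional slopes, intercepts,
    MDISC, MDIFF per boundary, marginal loadings, marginal slopes, communality
    and the IECV split.  Returns ``(table, model_indices)``.
    """
    if D is None:
        D = getattr(fit.options_used, "scaling_constant_D", DEFAULT_D)
    max_k = max(it.n_categories for it in battery.items)
    rows = []
    indices = []
    for item, p in zip(battery.items, fit.params):
        try:
            ix = compute_item_indices(p, D, convention)
        except (ZeroDivisionError, ValueError) as err:
            raise type(err)(f"item {item.item_id}: {err}") from err
        indices.append(ix)
        row = {
            "item_id": item.item_id,
            "scale_id": item.scale_id,
            "specific_factor": item.specific_factor_index,
            "n_categories": item.n_categories,
            "slope_general": p.slope_general,
            "slope_specific": p.slope_specific,
            "mdisc": ix.mdisc,
            "loading_general": ix.loading_general,
            "loading_specific": ix.loading_specific,
            "marginal_slope_general": ix.marginal_slope_general,
            "marginal_slope_specific": ix.marginal_slope_specific,
            "communality": ix.communality,
            "iecv_general": ix.iecv_general,
            "iecv_specific": ix.iecv_specific,
        }
        for k in range(max_k - 1):
            row[f"intercept_{k + 1}"] = p.intercepts[k] if k < p.intercepts.size else np.nan
            row[f"mdiff_{k + 1}"] = ix.mdiff[k] if k < ix.mdiff.size else np.nan
        rows.append(row)
    table = pd.DataFrame(rows).set_index("item_id")

    model = model_ecv(indices, battery)
    model.slope_means.loc["general", "conditional_slope_mean"] = float(
        np.mean([p.slope_general for p in fit.params])
    )
    for s in range(1, battery.n_specific_factors + 1):
        idx = battery.items_for_factor(s)
        model.slope_means.loc[f"specific_{s}", "conditional_slope_mean"] = float(
            np.mean([fit.params[j].slope_specific for j in idx])
        )
    return table, model
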
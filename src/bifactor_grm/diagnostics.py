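"""Assumption checks and validity analyses for the fitted battery.

Covers the classical IRT assumption trio — appropriate dimensionality
(eigenvalue spectrum plus nested-model information criteria), local
independence (Q3 residual correlations) and monotonicity (rest-score binning)
— together with the inter-item and scale-level Pearson correlation reports
used for convergent/discriminant validity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .battery import Battery
from .estimation import FitResult, posterior_trait_scores
from .io import apply_reverse_coding
from .model import expected_item_score

__all__ = [
    "CorrelationReport",
    "LocalDependenceReport",
    "MonotonicityReport",
    "DimensionalityReport",
    "item_correlations",
    "scale_correlations",
    "q3_statistics",
    "monotonicity_check",
    "dimensionality_summary",
]

log = logging.getLogger(__name__)


@dataclass
class CorrelationReport:
    item_correlation_matrix: pd.DataFrame
    strongest_pair: tuple[str, str, float] | None
    weakest_pair: tuple[str, str, float] | None
    constant_items: list[str]


@dataclass
class LocalDependenceReport:
    q3_matrix: pd.DataFrame
    mean_q3: float
    flagged_pairs: list[tuple[str, str, float]]
    threshold: float


@dataclass
class MonotonicityReport:
    per_item: pd.DataFrame  # columns: n_bins_used, violations, prop_nondecreasing
    n_bins_requested: int


@dataclass
class DimensionalityReport:
    eigenvalues: np.ndarray
    first_to_second_ratio: float
    comparison: pd.DataFrame | None  # AIC/BIC of supplied fits
    preferred_by_bic: str | None


def item_correlations(responses: pd.DataFrame, min_pairs: int = 3) -> CorrelationReport:
    """Pairwise-complete Pearson correlations between items.

    Constant items yield undefined correlations; they are flagged in the
    report (NaN rows/columns) rather than raising.
    """
    corr = responses.corr(method="pearson", min_periods=min_pairs)
    constant = [c for c in responses.columns if responses[c].dropna().nunique() <= 1]
    vals = corr.to_numpy(copy=True)
    np.fill_diagonal(vals, np.nan)
    strongest = weakest = None
    if np.isfinite(vals).any():
        i, j = np.unravel_index(np.nanargmax(np.abs(vals)), vals.shape)
        strongest = (corr.index[i], corr.columns[j], float(vals[i, j]))
        i, j = np.unravel_index(np.nanargmin(np.abs(vals)), vals.shape)
        weakest = (corr.index[i], corr.columns[j], float(vals[i, j]))
    return CorrelationReport(
        item_correlation_matrix=corr,
        strongest_pair=strongest,
        weakest_pair=weakest,
        constant_items=constant,
    )


def scale_correlations(responses: pd.DataFrame, battery: Battery) -> pd.DataFrame:
    """Pearson correlations between scale sum scores on the raw keying.

    Expects the raw (un-reverse-coded) matrix so that negatively keyed scales
    keep their natural sign (e.g. negative affect correlating negatively with
    the satisfaction scales).
    """
    sums = {}
    for scale in battery.scales:
        cols = [battery.item_ids[i] for i in battery.items_for_scale(scale)]
        sums[scale] = responses[cols].sum(axis=1, min_count=1)
    return pd.DataFrame(sums).corr(method="pearson")


def q3_statistics(
    fit: FitResult,
    responses: pd.DataFrame,
    battery: Battery,
    threshold: float = 0.2,
) -> LocalDependenceReport:
    """Yen's Q3 local-dependence statistic from EAP-based residuals.

    Residual = observed score - expected item score at the person's EAP
    (general, item's specific) trait point; Q3 is the Pearson correlation of
    residuals per item pair.  Pairs with |Q3 - mean Q3| above ``threshold``
    are flagged.
    """
    scores = posterior_trait_scores(fit, responses, battery)
    n = len(responses)
    resid = np.full((n, battery.n_items), np.nan)
    obs = responses[battery.item_ids].to_numpy(dtype=float)
    tg = scores["theta_general"].to_numpy()
    for j, (item, p) in enumerate(zip(battery.items, fit.params)):
        ts = scores[f"theta_specific_{item.specific_factor_index}"].to_numpy()
        exp_score = np.array(
            [
                expected_item_score(p, (tg[i], ts[i])) if np.isfinite(tg[i]) else np.nan
                for i in range(n)
            ]
        )
        resid[:, j] = obs[:, j] - exp_score
    rdf = pd.DataFrame(resid, columns=battery.item_ids, index=responses.index)
    q3 = rdf.corr(method="pearson")

    tri = np.triu_indices(battery.n_items, k=1)
    offdiag = q3.to_numpy()[tri]
    mean_q3 = float(np.nanmean(offdiag))
    flagged = []
    for a, b in zip(*tri):
        val = q3.iat[a, b]
        if np.isfinite(val) and abs(val - mean_q3) > threshold:
            flagged.append((q3.index[a], q3.columns[b], float(val)))
    return LocalDependenceReport(
        q3_matrix=q3, mean_q3=mean_q3, flagged_pairs=flagged, threshold=threshold
    )


def monotonicity_check(
    responses: pd.DataFrame,
    battery: Battery,
    n_bins: int = 10,
    min_bin_size: int = 30,
    already_recoded: bool = True,
) -> MonotonicityReport:
    """Rest-score monotonicity: mean item score should rise with the rest score.

    Persons are binned into ``n_bins`` equal-count rest-score groups (battery
    sum minus the item, on the analysis keying); a violation is an
    adjacent-bin decrease in the mean item score exceeding one pooled standard
    error.  Tail bins smaller than ``min_bin_size`` are merged (logged).
    """
    if n_bins < 3:
        raise ValueError("need at least 3 rest-score bins")
    data = responses if already_recoded else apply_reverse_coding(responses, battery)
    arr = data[battery.item_ids].to_numpy(dtype=float)
    total = np.nansum(arr, axis=1)
    rows = []
    for j, item in enumerate(battery.items):
        rest = total - np.nan_to_num(arr[:, j])
        ok = np.isfinite(arr[:, j])
        rest_ok, item_ok = rest[ok], arr[ok, j]
        qs = np.quantile(rest_ok, np.linspace(0, 1, n_bins + 1))
        edges = np.unique(qs)
        bins = np.clip(np.searchsorted(edges, rest_ok, side="right") - 1, 0, edges.size - 2)
        # merge undersized tail bins
        labels = np.unique(bins)
        sizes = {b: int((bins == b).sum()) for b in labels}
        merged = bins.copy()
        while len(np.unique(merged)) > 2:
            labs = np.unique(merged)
            sizes = {b: int((merged == b).sum()) for b in labs}
            small = [b for b in labs if sizes[b] < min_bin_size]
            if not small:
                break
            b = small[0]
            labs_sorted = list(labs)
            pos = labs_sorted.index(b)
            target = labs_sorted[pos - 1] if pos > 0 else labs_sorted[pos + 1]
            merged[merged == b] = target
            log.debug("item %s: merged rest-score bin %s into %s", item.item_id, b, target)
        labs = np.unique(merged)
        means = np.array([item_ok[merged == b].mean() for b in labs])
        ses = np.array(
            [
                item_ok[merged == b].std(ddof=1) / np.sqrt((merged == b).sum())
                if (merged == b).sum() > 1
                else 0.0
                for b in labs
            ]
        )
        diffs = np.diff(means)
        pooled = np.sqrt(ses[:-1] ** 2 + ses[1:] ** 2)
        violations = int(np.sum(diffs < -pooled))
        nondecreasing = float(np.mean(diffs >= -pooled)) if diffs.size else 1.0
        rows.append(
            {
                "item_id": item.item_id,
                "n_bins_used": int(labs.size),
                "violations": violations,
                "prop_nondecreasing": nondecreasing,
            }
        )
    return MonotonicityReport(
        per_item=pd.DataFrame(rows).set_index("item_id"), n_bins_requested=n_bins
    )


def dimensionality_summary(
    responses: pd.DataFrame,
    battery: Battery,
    fits: dict[str, FitResult] | None = None,
) -> DimensionalityReport:
    """Eigenvalue spectrum of the item correlations plus model comparison.

    A dominant first eigenvalue supports a strong general dimension; when
    fitted models are supplied their AIC/BIC are tabulated and the
    BIC-preferred model named.
    """
    corr = responses[battery.item_ids].corr(method="pearson")
    mat = corr.to_numpy()
    if not np.all(np.isfinite(mat)):
        log.warning("correlation matrix has undefined entries; treating as singular")
        mat = np.nan_to_num(mat, nan=0.0)
        np.fill_diagonal(mat, 1.0)
    eig = np.sort(np.linalg.eigvalsh(mat))[::-1]
    ratio = float(eig[0] / eig[1]) if eig.size > 1 and eig[1] > 0 else np.inf

    comparison = None
    preferred = None
    if fits:
        comparison = pd.DataFrame(
            {
                name: {
                    "log_likelihood": f.log_likelihood,
                    "n_free_parameters": f.n_free_parameters,
                    "aic": f.aic,
                    "bic": f.bic,
                }
                for name, f in fits.items()
            }
        ).T
        preferred = comparison["bic"].idxmin()
    return DimensionalityReport(
        eigenvalues=eig,
        first_to_second_ratio=ratio,
        comparison=comparison,
        preferred_by_bic=preferred,
    )
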
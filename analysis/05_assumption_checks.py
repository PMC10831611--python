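#!/usr/bin/env python
"""IRT assumption checks and convergent/discriminant validity on the battery.

Runs the full diagnostic suite on the simulated data and its fitted model:
inter-item Pearson correlations, scale-level correlations on the raw keying
(negative affect should correlate negatively with the satisfaction scales),
Q3 residual correlations for local dependence, rest-score monotonicity, and
the eigenvalue spectrum plus bifactor-vs-unidimensional information criteria
for dimensionality.
"""

import json
from pathlib import Path

import numpy as np

from bifactor_grm import (
    FitOptions,
    apply_reverse_coding,
    dimensionality_summary,
    fit_bifactor_grm,
    fit_unidimensional_grm,
    item_correlations,
    monotonicity_check,
    q3_statistics,
    read_battery,
    read_responses,
    scale_correlations,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    battery = read_battery(OUT / "battery.yaml")
    raw = read_responses(OUT / "responses_raw.csv", battery)
    data = apply_reverse_coding(raw, battery)

    options = FitOptions(n_quadrature_points=21)
    bifac = fit_bifactor_grm(data, battery, options)
    uni = fit_unidimensional_grm(data, battery, options)

    corr = item_correlations(data)
    corr.item_correlation_matrix.round(4).to_csv(OUT / "item_correlations.csv")
    s, w = corr.strongest_pair, corr.weakest_pair
    print(f"strongest item pair: {s[0]}-{s[1]} r={s[2]:.2f}; weakest: {w[0]}-{w[1]} r={w[2]:.2f}")

    scale_corr = scale_correlations(raw, battery)
    scale_corr.round(4).to_csv(OUT / "scale_correlations.csv")
    print("scale correlations (raw keying):")
    print(scale_corr.round(2).to_string())

    q3 = q3_statistics(bifac, data, battery)
    q3.q3_matrix.round(4).to_csv(OUT / "q3_matrix.csv")
    tri = np.triu_indices(battery.n_items, k=1)
    print(f"local dependence: mean Q3 = {q3.mean_q3:.3f}, "
          f"mean |Q3| = {np.nanmean(np.abs(q3.q3_matrix.to_numpy()[tri])):.3f}, "
          f"flagged pairs: {len(q3.flagged_pairs)}")

    mono = monotonicity_check(data, battery, n_bins=10, min_bin_size=30)
    mono.per_item.round(4).to_csv(OUT / "monotonicity.csv")
    print(f"monotonicity: total adjacent-bin violations = "
          f"{int(mono.per_item['violations'].sum())} across {battery.n_items} items")

    dim = dimensionality_summary(data, battery, {"bifactor": bifac, "unidimensional": uni})
    summary = {
        "first_eigenvalues": [round(v, 3) for v in dim.eigenvalues[:5]],
        "first_to_second_ratio": round(dim.first_to_second_ratio, 2),
        "preferred_by_bic": dim.preferred_by_bic,
        "mean_q3": round(q3.mean_q3, 4),
        "q3_flagged_pairs": len(q3.flagged_pairs),
        "monotonicity_total_violations": int(mono.per_item["violations"].sum()),
    }
    (OUT / "diagnostics_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"dimensionality: eigenvalue ratio {dim.first_to_second_ratio:.1f}, "
          f"BIC prefers the {dim.preferred_by_bic} model")


if __name__ == "__main__":
    main()
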
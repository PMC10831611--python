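"""End-to-end orchestration: simulate/load -> recode -> fit -> indices ->
surfaces -> diagnostics, with a reproducibility manifest.

Every artifact is a plain-text table (CSV/JSON) and is byte-reproducible from
the configuration plus seed; the manifest records everything needed to re-run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .battery import Battery, make_paper_battery, read_battery, write_battery
from .diagnostics import (
    dimensionality_summary,
    item_correlations,
    monotonicity_check,
    q3_statistics,
    scale_correlations,
)
from .estimation import FitOptions, fit_bifactor_grm, fit_unidimensional_grm
from .indices import parameter_table
from .io import apply_reverse_coding, read_responses, write_responses
from .model import evaluate_surface
from .simulate import make_preset, sample_responses

__all__ = ["AnalysisConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    out_dir: str | Path = "results"
    responses_path: str | Path | None = None  # if None, simulate
    battery_path: str | Path | None = None  # if None, the 30-item default
    preset: str = "paper_like"
    n_persons: int = 435
    seed: int = 0
    fit_options: FitOptions = field(default_factory=FitOptions)
    fit_unidimensional: bool = True
    surface_items: list[str] = field(default_factory=list)  # default: first item
    surface_points: int = 81
    surface_span: float = 6.0
    run_diagnostics: bool = True
    monotonicity_bins: int = 10


def _battery_hash(battery: Battery) -> str:
    canon = json.dumps(battery.to_records(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    return df.round(4)


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the full analysis chain; returns a manifest dict (also written).

    Artifacts written under ``config.out_dir``: the (possibly simulated)
    response matrix, battery config, Table-1-style parameter table (CSV at 4
    decimals + full-precision JSON), model indices, long-format surface grids,
    diagnostics reports and ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        battery = read_battery(config.battery_path) if config.battery_path else make_paper_battery()

        stage = "data"
        if config.responses_path is None:
            preset = make_preset(config.preset)
            raw = sample_responses(preset, battery, config.n_persons, config.seed)
            log.info("simulated %d persons from preset %s", config.n_persons, config.preset)
        else:
            raw = read_responses(config.responses_path, battery)
            log.info("loaded %d persons from %s", len(raw), config.responses_path)
        write_responses(raw, out / "responses_raw.csv")
        write_battery(battery, out / "battery.yaml")

        stage = "recode"
        data = apply_reverse_coding(raw, battery)

        stage = "fit"
        fit = fit_bifactor_grm(data, battery, config.fit_options)
        fits = {"bifactor": fit}
        if config.fit_unidimensional:
            fits["unidimensional"] = fit_unidimensional_grm(data, battery, config.fit_options)

        stage = "indices"
        table, model_idx = parameter_table(fit, battery)
        _fmt(table).to_csv(out / "parameter_table.csv")
        table.reset_index().to_json(out / "parameter_table.json", orient="records", indent=2)
        model_summary = {
            "ecv_general": model_idx.ecv_general,
            "ecv_specific": {str(k): v for k, v in model_idx.ecv_specific.items()},
            "mdisc_mean": model_idx.mdisc_mean,
            "slope_means": model_idx.slope_means.to_dict(),
        }
        (out / "model_indices.json").write_text(json.dumps(model_summary, indent=2) + "\n")

        stage = "surfaces"
        items = config.surface_items or [battery.item_ids[0]]
        axes = np.linspace(-config.surface_span, config.surface_span, config.surface_points)
        frames = []
        for item_id in items:
            j = battery.item_ids.index(item_id)
            p = fit.params[j]
            surfaces = {"expected_score": evaluate_surface(p, "expected_score", axes, axes)}
            surfaces["information"] = evaluate_surface(p, "information", axes, axes)
            for c in range(1, p.n_categories + 1):
                surfaces[f"category_probability_{c}"] = evaluate_surface(
                    p, "category_probability", axes, axes, category=c
                )
            for kind, sg in surfaces.items():
                G, S = np.meshgrid(sg.theta_general_axis, sg.theta_specific_axis, indexing="ij")
                frames.append(
                    pd.DataFrame(
                        {
                            "item_id": item_id,
                            "kind": kind,
                            "theta_general": G.ravel(),
                            "theta_specific": S.ravel(),
                            "value": sg.values.ravel(),
                        }
                    )
                )
        pd.concat(frames, ignore_index=True).to_csv(out / "surfaces.csv", index=False, float_format="%.6g")

        stage = "diagnostics"
        diag_summary = {}
        if config.run_diagnostics:
            corr = item_correlations(data)
            corr.item_correlation_matrix.round(4).to_csv(out / "item_correlations.csv")
            scale_corr = scale_correlations(raw, battery)
            scale_corr.round(4).to_csv(out / "scale_correlations.csv")
            q3 = q3_statistics(fit, data, battery)
            q3.q3_matrix.round(4).to_csv(out / "q3_matrix.csv")
            mono = monotonicity_check(
                data, battery, n_bins=config.monotonicity_bins,
                min_bin_size=max(5, len(data) // (config.monotonicity_bins * 3)),
            )
            mono.per_item.round(4).to_csv(out / "monotonicity.csv")
            dim = dimensionality_summary(data, battery, fits if len(fits) > 1 else None)
            diag_summary = {
                "mean_q3": q3.mean_q3,
                "q3_flagged_pairs": len(q3.flagged_pairs),
                "monotonicity_total_violations": int(mono.per_item["violations"].sum()),
                "first_to_second_eigenvalue_ratio": dim.first_to_second_ratio,
                "preferred_by_bic": dim.preferred_by_bic,
            }
            (out / "diagnostics_summary.json").write_text(
                json.dumps(diag_summary, indent=2) + "\n"
            )

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "preset": None if config.responses_path else config.preset,
            "n_persons": len(raw),
            "battery_hash": _battery_hash(battery),
            "fit_options": dataclasses.asdict(config.fit_options),
            "fits": {
                name: {
                    "log_likelihood": f.log_likelihood,
                    "aic": f.aic,
                    "bic": f.bic,
                    "n_iterations": f.n_iterations,
                    "converged": f.converged,
                }
                for name, f in fits.items()
            },
            "ecv_general": model_idx.ecv_general,
            "diagnostics": diag_summary,
            "artifacts": sorted(
                {p.name for p in out.iterdir() if p.is_file()} | {"manifest.json"}
            ),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return manifest
    except PipelineError:
        raise
    except Exception as err:  # noqa: BLE001 - stage context is the contract
        log.error("pipeline stage %r failed: %s", stage, err)
        raise PipelineError(stage, err) from err
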
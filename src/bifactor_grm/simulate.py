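"""Synthetic Likert responses with the bifactor structure the analysis assumes.

The generator emulates a 30-item well-being battery (10 positive-affect and 10
negative-affect items on 1-5, five life-satisfaction and five harmony-in-life
items on 1-7) whose underlying study data is not publicly deposited.  Traits
are drawn orthogonal standard normal (one general, one per subscale); item
slopes follow the reported per-scale means; negative-affect items are
delivered negatively keyed so the analysis pipeline's reverse-coding step is
exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .battery import Battery, make_paper_battery
from .io import apply_reverse_coding, decode
from .model import ItemParams

__all__ = ["GeneratorPreset", "make_paper_battery", "make_preset", "sample_responses", "PRESET_NAMES"]

PRESET_NAMES = ("paper_like", "weak_general", "null_specific")

# per-scale conditional slope magnitudes of the paper_like preset
_GENERAL_SLOPE = 2.81
_SPECIFIC_SLOPES = {"PA": 1.39, "NA": 2.45, "LS": 1.85, "HIL": 1.56}
_DEFAULT_SPECIFIC = 1.5  # scales outside the named four (user batteries)


@dataclass(frozen=True)
class GeneratorPreset:
    """True item parameters for simulation; reproducible from name + seed."""

    name: str
    battery: Battery
    params: tuple[ItemParams, ...]  # analysis-side (positively keyed) parameters


def _spaced_intercepts(n_categories: int, scale: float) -> np.ndarray:
    """Evenly spaced intercepts, symmetric about 0, base span [-3, 3].

    The base grid is multiplied by ``scale`` (MDISC/2 in the presets) so that
    stronger items get wider intercept spans and every category stays
    observable at moderate sample sizes.
    """
    base = np.linspace(3.0, -3.0, n_categories - 1)
    return base * scale


def make_preset(name: str, seed: int | None = None, jitter: float = 0.0) -> GeneratorPreset:
    """Built-in generating conditions.

    ``paper_like`` assigns every item a general slope of 2.81 and per-scale
    specific slopes (PA 1.39, NA 2.45, LS 1.85, HIL 1.56); ``weak_general``
    halves the general slopes; ``null_specific`` zeroes the specific slopes.
    Values are deterministic given the name; ``jitter`` (default off) adds
    seed-controlled N(0, jitter) noise to the slopes.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    battery = make_paper_battery()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0]) if jitter else None

    params = []
    for item in battery.items:
        a_g = _GENERAL_SLOPE
        a_s = _SPECIFIC_SLOPES.get(item.scale_id, _DEFAULT_SPECIFIC)
        if name == "weak_general":
            a_g *= 0.5
        elif name == "null_specific":
            a_s = 0.0
        if rng is not None:
            a_g = max(a_g + rng.normal(0.0, jitter), 0.05)
            a_s = a_s + rng.normal(0.0, jitter)
        md = float(np.hypot(a_g, a_s))
        params.append(
            ItemParams(
                item_id=item.item_id,
                slope_general=a_g,
                slope_specific=a_s,
                intercepts=_spaced_intercepts(item.n_categories, md / 2.0),
            )
        )
    return GeneratorPreset(name=name, battery=battery, params=tuple(params))


def sample_responses(
    preset: GeneratorPreset,
    battery: Battery | None = None,
    n_persons: int = 435,
    seed: int = 0,
    return_traits: bool = False,
):
    """Draw a raw persons x items response matrix from a preset.

    Traits (one general + one per specific factor) are sampled independent
    standard normal; responses come from the model's category probabilities.
    Items flagged reverse_coded are delivered negatively keyed (x -> K+1-x
    applied to the model draw, equivalent to sampling from the negated
    parameter set), so the returned matrix mimics raw questionnaire coding and
    must pass through ``apply_reverse_coding`` before fitting.

    One master seed is split deterministically into a trait stream and a
    response stream, so trait draws are stable when only response noise
    changes.
    """
    battery = battery or preset.battery
    if n_persons < 1:
        raise ValueError("n_persons must be >= 1")
    ss_traits, ss_resp = np.random.SeedSequence(seed).spawn(2)
    rng_t = np.random.default_rng(ss_traits)
    rng_r = np.random.default_rng(ss_resp)

    theta_g = rng_t.standard_normal(n_persons)
    theta_s = rng_t.standard_normal((n_persons, battery.n_specific_factors))

    codes = np.empty((n_persons, battery.n_items), dtype=np.int64)
    for j, (item, p) in enumerate(zip(battery.items, preset.params)):
        ts = theta_s[:, item.specific_factor_index - 1]
        z = p.slope_general * theta_g[:, None] + p.slope_specific * ts[:, None] + p.intercepts
        pstar = expit(z)  # (n, K-1) boundary probabilities
        u = rng_r.random(n_persons)
        # category = number of boundaries passed: X >= k+1 iff u < P*(X >= k+1)
        codes[:, j] = (u[:, None] < pstar).sum(axis=1)
    raw = decode(codes, battery)
    # deliver reverse-keyed raw coding for flagged items
    raw = apply_reverse_coding(raw, battery)
    if return_traits:
        traits = pd.DataFrame(
            np.column_stack([theta_g, theta_s]),
            columns=["theta_general"]
            + [f"theta_specific_{s + 1}" for s in range(battery.n_specific_factors)],
            index=raw.index,
        )
        return raw, traits
    return raw
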
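"""Shared fixtures and hypothesis strategies for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import strategies as st

from bifactor_grm import Battery, ItemParams, ItemSpec, make_preset
from bifactor_grm.model import ItemParams as _ItemParams
from bifactor_grm.simulate import _spaced_intercepts


@pytest.fixture(scope="session")
def paper_preset():
    return make_preset("paper_like")


@pytest.fixture(scope="session")
def paper_battery(paper_preset):
    return paper_preset.battery


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def small_battery(n_per_factor: int = 3, n_factors: int = 2, K: int = 5) -> Battery:
    items = []
    for s in range(1, n_factors + 1):
        for i in range(n_per_factor):
            items.append(ItemSpec(f"F{s}I{i + 1}", f"S{s}", s, K, False))
    return Battery(items=tuple(items))


def small_preset_params(battery: Battery, a_g=1.8, a_s=1.2):
    return tuple(
        _ItemParams(
            it.item_id,
            a_g,
            a_s,
            _spaced_intercepts(it.n_categories, float(np.hypot(a_g, a_s)) / 2.0),
        )
        for it in battery.items
    )


# --- hypothesis strategies -------------------------------------------------

finite_slope = st.floats(min_value=-4.0, max_value=4.0, allow_nan=False)
positive_slope = st.floats(min_value=0.05, max_value=4.0, allow_nan=False)
theta_coord = st.floats(min_value=-6.0, max_value=6.0, allow_nan=False)


@st.composite
def item_params_strategy(draw, min_k: int = 2, max_k: int = 7, signed_slopes: bool = True):
    """Random valid graded-response item parameters."""
    k = draw(st.integers(min_value=min_k, max_value=max_k))
    slope = finite_slope if signed_slopes else positive_slope
    a_g = draw(slope)
    a_s = draw(slope)
    d1 = draw(st.floats(min_value=-3.0, max_value=4.0, allow_nan=False))
    gaps = draw(
        st.lists(
            st.floats(min_value=0.1, max_value=2.5, allow_nan=False),
            min_size=k - 2,
            max_size=k - 2,
        )
    )
    intercepts = d1 - np.concatenate(([0.0], np.cumsum(gaps)))
    return ItemParams("hyp", a_g, a_s, intercepts)
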
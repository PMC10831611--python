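"""Response-matrix I/O and recoding.

Responses travel as a pandas DataFrame indexed by person id with one column
per item, integer category codes on the external 1..K scale and NaN for
missing cells.  ``encode`` converts to the internal 0..K-1 integer array
(-1 = missing) used by the likelihood machinery.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .battery import Battery

__all__ = [
    "DataValidationError",
    "read_responses",
    "write_responses",
    "validate_responses",
    "apply_reverse_coding",
    "encode",
    "decode",
]


class DataValidationError(ValueError):
    """Response data violating the battery's coding contract."""


def validate_responses(responses: pd.DataFrame, battery: Battery) -> pd.DataFrame:
    """Check column set/order and code ranges; returns a float-coded copy.

    Out-of-range or non-integer cells raise with the offending person/item.
    """
    missing_cols = [c for c in battery.item_ids if c not in responses.columns]
    if missing_cols:
        raise DataValidationError(f"response matrix lacks item columns {missing_cols}")
    unknown = [c for c in responses.columns if c not in battery.item_ids]
    if unknown:
        raise DataValidationError(f"unknown item columns {unknown}")
    if responses.index.has_duplicates:
        dupes = responses.index[responses.index.duplicated()].unique().tolist()
        raise DataValidationError(f"duplicate person ids {dupes}")
    out = responses[battery.item_ids].astype(float).copy()
    for item in battery.items:
        col = out[item.item_id]
        obs = col.dropna()
        bad_int = obs[obs != np.round(obs)]
        if len(bad_int):
            raise DataValidationError(
                f"non-integer code for person {bad_int.index[0]!r}, item {item.item_id}"
            )
        bad = obs[(obs < 1) | (obs > item.n_categories)]
        if len(bad):
            raise DataValidationError(
                f"code {bad.iloc[0]:g} out of range 1..{item.n_categories} "
                f"for person {bad.index[0]!r}, item {item.item_id}"
            )
    return out


def read_responses(path: str | Path, battery: Battery) -> pd.DataFrame:
    """Read a persons x items CSV (first column = person id, header = item ids)."""
    df = pd.read_csv(path, index_col=0)
    return validate_responses(df, battery)


def write_responses(responses: pd.DataFrame, path: str | Path) -> None:
    out = responses.copy()
    # keep integer appearance in the CSV (empty cell = missing)
    out = out.astype("Int64")
    out.index.name = out.index.name or "person_id"
    out.to_csv(path)


def apply_reverse_coding(responses: pd.DataFrame, battery: Battery) -> pd.DataFrame:
    """Recode flagged items x -> K+1-x; applying twice restores the input."""
    out = responses.copy()
    for item in battery.items:
        if item.reverse_coded:
            out[item.item_id] = item.n_categories + 1 - out[item.item_id]
    return out


def encode(responses: pd.DataFrame, battery: Battery) -> np.ndarray:
    """External 1..K DataFrame -> internal (n, J) int array, 0..K-1, -1 missing."""
    df = validate_responses(responses, battery)
    arr = df.to_numpy(dtype=float)
    codes = np.where(np.isnan(arr), 0.0, arr - 1.0).astype(np.int64)
    codes[np.isnan(arr)] = -1
    return codes


def decode(codes: np.ndarray, battery: Battery, person_ids=None) -> pd.DataFrame:
    """Internal codes back to an external 1..K DataFrame with NaN for missing."""
    arr = np.asarray(codes, dtype=float) + 1.0
    arr[np.asarray(codes) < 0] = np.nan
    idx = range(arr.shape[0]) if person_ids is None else person_ids
    df = pd.DataFrame(arr, columns=battery.item_ids, index=idx)
    df.index.name = "person_id"
    return df
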
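"""FTND dataset schema, validation and plain-text I/O.

A dataset is a pandas DataFrame with one row per respondent and columns

    id, item1..item6, gender, smoke_where, smoking_allowed

Items 1 and 4 are scored 0-3, the other four items 0/1; a missing item is
``NaN`` in memory and an empty cell on disk.  ``gender`` is 0 = female,
1 = male; ``smoke_where`` ("If you smoke at home, where?") is coded
0 = No, 1 = Yes (outside), 3 = Yes (inside); ``smoking_allowed`` ("Is
smoking allowed in your home?") is 0 = No, 1 = Yes.  Covariates are never
missing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import InvalidDataError

N_ITEMS = 6
ITEM_COLUMNS = tuple(f"item{i}" for i in range(1, N_ITEMS + 1))
#: maximum score of each item (items 1 & 4 carry up to 3 points)
ITEM_MAX = np.array([3, 1, 1, 3, 1, 1])
COVARIATE_COLUMNS = ("gender", "smoke_where", "smoking_allowed")
SMOKE_WHERE_CODES = (0, 1, 3)  # No / Yes (outside) / Yes (inside)
COLUMNS = ("id",) + ITEM_COLUMNS + COVARIATE_COLUMNS

#: five dependence bands of the total score: very low .. very high
DEPENDENCE_BANDS = ((0, 2), (3, 4), (5, 5), (6, 7), (8, 10))


def item_matrix(data: pd.DataFrame) -> np.ndarray:
    """Return the n x 6 item-score matrix as floats (NaN = missing)."""
    return data.loc[:, list(ITEM_COLUMNS)].to_numpy(dtype=float)


def total_scores(data: pd.DataFrame) -> np.ndarray:
    """Row sums of the six items; NaN wherever any item is missing."""
    return item_matrix(data).sum(axis=1)


def validate_dataset(data: pd.DataFrame, allow_missing_items: bool = True) -> None:
    """Check the schema; raise :class:`InvalidDataError` on any violation."""
    missing_cols = [c for c in COLUMNS if c not in data.columns]
    if missing_cols:
        raise InvalidDataError(f"missing columns: {missing_cols}")
    items = item_matrix(data)
    nan = np.isnan(items)
    if not allow_missing_items and nan.any():
        raise InvalidDataError("dataset contains missing items")
    observed = items[~nan]
    if observed.size and (observed != np.round(observed)).any():
        raise InvalidDataError("item scores must be integers")
    upper = np.broadcast_to(ITEM_MAX, items.shape)
    with np.errstate(invalid="ignore"):
        out = (items < 0) | (items > upper)
    if np.nan_to_num(out).any():
        raise InvalidDataError("item score outside its legal range")
    for col in COVARIATE_COLUMNS:
        if data[col].isna().any():
            raise InvalidDataError(f"covariate {col!r} has missing values")
    if not data["gender"].isin((0, 1)).all():
        raise InvalidDataError("gender must be 0 (female) or 1 (male)")
    if not data["smoke_where"].isin(SMOKE_WHERE_CODES).all():
        raise InvalidDataError("smoke_where must be coded 0, 1 or 3")
    if not data["smoking_allowed"].isin((0, 1)).all():
        raise InvalidDataError("smoking_allowed must be 0 or 1")


def read_population(path: str | Path, allow_missing_items: bool = True) -> pd.DataFrame:
    """Read a dataset CSV (empty cells = missing items) and validate it."""
    data = pd.read_csv(path)
    validate_dataset(data, allow_missing_items=allow_missing_items)
    return data


def write_population(data: pd.DataFrame, path: str | Path) -> None:
    """Write a dataset CSV; missing items become empty cells."""
    validate_dataset(data)
    out = data.loc[:, list(COLUMNS)].copy()
    for col in ITEM_COLUMNS:
        out[col] = out[col].astype("Int64")
    out.to_csv(path, index=False)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise InvalidDataError(f"{path}: expected a YAML mapping")
    return loaded


def dump_yaml(mapping: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(mapping, fh, sort_keys=False)
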
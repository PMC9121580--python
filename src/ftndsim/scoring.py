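"""Six methods for computing total FTND scores in the presence of missing items.

* ``cca`` — complete case analysis: a total only for subjects with no
  missing items.
* ``drop_one`` — one missing item is treated as zero; two or more missing
  items give a missing total.
* ``item_mean`` — each missing item is replaced by the observed sample mean
  of that item (computed within the current dataset, after missingness).
* ``hr_item_mean`` — item mean restricted by the half rule: imputation only
  for subjects with at least 3 of 6 items observed.
* ``proration`` — person-mean imputation weighted by each item's maximum
  score (3 points for items 1 and 4, 1 for the binary items), applied under
  the half rule.  A missing item's imputed value is
  ``max_i * observed_score / observed_possible_score``.
* ``hot_deck`` — k-nearest-neighbour hot deck: donors ranked by Gower's
  distance over gender, smoking-allowed and the recipient's observed items;
  a single donor drawn uniformly from the nearest k fills all of the
  recipient's missing items.

Totals from proration and item-mean imputation may be fractional; nothing is
rounded.  Subjects with no missing items receive the plain row sum under
every method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ITEM_COLUMNS, ITEM_MAX, N_ITEMS, item_matrix
from .exceptions import (
    DonorPoolError,
    DonorPoolWarning,
    InvalidDataError,
    UnimputableDatasetError,
)

METHODS = ("cca", "drop_one", "item_mean", "hr_item_mean", "proration", "hot_deck")
HALF_RULE_MIN_OBSERVED = 3
#: variables besides the observed items entering the hot-deck distance
HOT_DECK_COVARIATES = ("gender", "smoking_allowed")


@dataclass
class MethodResult:
    """Per-subject totals produced by one scoring method.

    ``totals`` is a float array aligned with the input rows, NaN where the
    method leaves the total missing.  ``imputations`` logs every imputed
    cell as ``(row, item, value)``.
    """

    method: str
    totals: np.ndarray
    imputations: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["row", "item", "value"])
    )

    @property
    def n_scored(self) -> int:
        return int(np.sum(~np.isnan(self.totals)))

    def to_frame(self, data: pd.DataFrame | None = None) -> pd.DataFrame:
        ids = data["id"].to_numpy() if data is not None else np.arange(len(self.totals))
        imputed = self.imputations.groupby("row")["item"].apply(",".join) if len(
            self.imputations
        ) else pd.Series(dtype=object)
        return pd.DataFrame(
            {
                "id": ids,
                "method": self.method,
                "total": self.totals,
                "imputed_items": [imputed.get(i, "") for i in range(len(self.totals))],
            }
        )


def _imputation_log(rows: np.ndarray, cols: np.ndarray, values: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "row": rows.astype(int),
            "item": [ITEM_COLUMNS[c] for c in cols],
            "value": values.astype(float),
        }
    )


def score_cca(data: pd.DataFrame) -> MethodResult:
    items = item_matrix(data)
    totals = items.sum(axis=1)  # NaN propagates for any missing item
    return MethodResult("cca", totals)


def score_drop_one(data: pd.DataFrame) -> MethodResult:
    items = item_matrix(data)
    n_missing = np.isnan(items).sum(axis=1)
    totals = np.where(n_missing <= 1, np.nansum(items, axis=1), np.nan)
    return MethodResult("drop_one", totals)


def score_item_mean(data: pd.DataFrame, half_rule: bool = False) -> MethodResult:
    items = item_matrix(data)
    miss = np.isnan(items)
    needs = miss.copy()
    if half_rule:
        needs[miss.sum(axis=1) > N_ITEMS - HALF_RULE_MIN_OBSERVED] = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        col_means = np.nanmean(items, axis=0)
    unusable = np.isnan(col_means) & needs.any(axis=0)
    if unusable.any():
        bad = ITEM_COLUMNS[int(np.flatnonzero(unusable)[0])]
        raise UnimputableDatasetError(f"no observed values to impute column {bad!r}")
    filled = np.where(needs, np.broadcast_to(col_means, items.shape), items)
    totals = filled.sum(axis=1)
    if half_rule:
        totals[miss.sum(axis=1) > N_ITEMS - HALF_RULE_MIN_OBSERVED] = np.nan
    rows, cols = np.nonzero(needs & ~np.isnan(filled))
    result = MethodResult(
        "hr_item_mean" if half_rule else "item_mean",
        totals,
        _imputation_log(rows, cols, col_means[cols]),
    )
    return result


def score_proration(data: pd.DataFrame) -> MethodResult:
    items = item_matrix(data)
    miss = np.isnan(items)
    n_obs = (~miss).sum(axis=1)
    obs_score = np.nansum(items, axis=1)
    obs_possible = np.where(~miss, np.broadcast_to(ITEM_MAX, items.shape), 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(obs_possible > 0, obs_score / obs_possible, 0.0)
    imputable = n_obs >= HALF_RULE_MIN_OBSERVED
    rows, cols = np.nonzero(miss & imputable[:, None])
    values = ITEM_MAX[cols] * ratio[rows]
    totals = np.where(imputable, obs_score + ratio * (10 - obs_possible), np.nan)
    return MethodResult("proration", totals, _imputation_log(rows, cols, values))


def gower_distance(a, b, variables) -> float:
    """Gower's mixed-type dissimilarity between two subject records.

    ``variables`` lists column names; gender, smoke_where and
    smoking_allowed are treated as categorical (0/1 mismatch), item columns
    as ordinal with range-normalised absolute differences.  Both records
    must observe every listed variable.
    """
    total = 0.0
    for var in variables:
        x, y = a[var], b[var]
        if pd.isna(x) or pd.isna(y):
            raise InvalidDataError(f"variable {var!r} missing on a compared record")
        if var in ITEM_COLUMNS:
            rng = ITEM_MAX[ITEM_COLUMNS.index(var)]
            total += abs(float(x) - float(y)) / rng
        else:
            total += float(x != y)
    return total / len(variables)


def hot_deck_donor_pools(
    data: pd.DataFrame, k: int = 5, strict: bool = False
) -> dict[int, np.ndarray]:
    """Nearest-donor pools for every subject with missing items.

    Candidate donors must observe all of a recipient's missing items and all
    distance variables (the recipient's observed items plus gender and
    smoking-allowed), i.e. they are item-complete subjects.  Ties at the
    k-th smallest distance are all included, so pools may exceed ``k``; with
    fewer than ``k`` candidates all candidates are used with a warning
    (``strict=True`` raises instead).
    """
    items = item_matrix(data)
    miss = np.isnan(items)
    recipients = np.flatnonzero(miss.any(axis=1))
    donors = np.flatnonzero(~miss.any(axis=1))
    pools: dict[int, np.ndarray] = {}
    if recipients.size == 0:
        return pools
    if donors.size == 0:
        raise DonorPoolError("no complete subjects available as donors")
    if donors.size < k:
        if strict:
            raise DonorPoolError(f"only {donors.size} candidate donors for k={k}")
        warnings.warn(
            f"only {donors.size} candidate donors available; using all of them",
            DonorPoolWarning,
            stacklevel=2,
        )
    cov = data.loc[:, list(HOT_DECK_COVARIATES)].to_numpy(dtype=float)
    donor_items = items[donors]
    donor_cov = cov[donors]
    # recipients grouped by missingness pattern share their distance variables
    patterns: dict[bytes, list[int]] = {}
    for r in recipients:
        patterns.setdefault(miss[r].tobytes(), []).append(r)
    for key, rows in patterns.items():
        pattern = np.frombuffer(key, dtype=bool)
        obs = ~pattern
        rows = np.asarray(rows)
        d_cov = (cov[rows][:, None, :] != donor_cov[None, :, :]).sum(axis=2)
        diffs = np.abs(items[rows][:, None, obs] - donor_items[None, :, obs])
        d_items = (diffs / ITEM_MAX[obs]).sum(axis=2)
        dist = (d_cov + d_items) / (len(HOT_DECK_COVARIATES) + obs.sum())
        kk = min(k, donors.size)
        for j, r in enumerate(rows):
            row_d = dist[j]
            kth = np.partition(row_d, kk - 1)[kk - 1]
            pools[int(r)] = donors[np.flatnonzero(row_d <= kth + 1e-12)]
    return pools


def score_hot_deck(
    data: pd.DataFrame, k: int = 5, seed=None, strict: bool = False
) -> MethodResult:
    """k-NN Gower hot deck with a single uniformly drawn donor per recipient."""
    items = item_matrix(data)
    miss = np.isnan(items)
    pools = hot_deck_donor_pools(data, k=k, strict=strict)
    rng = np.random.default_rng(seed)
    log_rows, log_cols, log_vals = [], [], []
    filled = items.copy()
    for r in sorted(pools):
        donor = int(rng.choice(pools[r]))
        cols = np.flatnonzero(miss[r])
        filled[r, cols] = items[donor, cols]
        log_rows.extend([r] * cols.size)
        log_cols.extend(cols.tolist())
        log_vals.extend(items[donor, cols].tolist())
    totals = filled.sum(axis=1)
    log = _imputation_log(np.array(log_rows, dtype=int), np.array(log_cols, dtype=int), np.array(log_vals, dtype=float))
    return MethodResult("hot_deck", totals, log)


def score(data: pd.DataFrame, method: str, k: int = 5, seed=None, strict: bool = False) -> MethodResult:
    """Dispatch to one of the six scoring methods by name."""
    if method == "cca":
        return score_cca(data)
    if method == "drop_one":
        return score_drop_one(data)
    if method == "item_mean":
        return score_item_mean(data, half_rule=False)
    if method == "hr_item_mean":
        return score_item_mean(data, half_rule=True)
    if method == "proration":
        return score_proration(data)
    if method == "hot_deck":
        return score_hot_deck(data, k=k, seed=seed, strict=strict)
    raise InvalidDataError(f"unknown scoring method {method!r}")
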
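"""MAR and MNAR item-level missingness injection.

Missingness is generated in two stages.  First, each subject is eligible for
item nonresponse with a probability from a logistic selection model: under
MAR the linear predictor uses observed covariates
(``beta0 + beta1*gender + beta2*smoke_where_outside + beta3*smoke_where_inside``),
under MNAR it uses the subject's true total score
(``beta0 + beta1*FTND``).  The slopes are fixed; the intercept ``beta0`` is
solved so the mean eligibility probability equals the target proportion
``p_sub``.  Second, each of an eligible subject's six items is independently
deleted with probability ``p_item``.  Covariates are never deleted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .dataset import ITEM_COLUMNS, N_ITEMS, total_scores
from .exceptions import ConfigurationError, InvalidDataError, SolverError

MECHANISMS = ("MAR", "MNAR")
#: default slopes fitted on the source data: gender, smoke-where indicators
MAR_DEFAULT_BETAS = (0.20, -2.12, -1.99)
#: default slope of eligibility on the true total score
MNAR_DEFAULT_BETA1 = 0.2


@dataclass(frozen=True)
class MissingnessConfig:
    """One missingness mechanism cell: mechanism, rates and coefficients."""

    mechanism: str
    p_sub: float
    p_item: float
    beta1: float = 0.2
    beta2: float = MAR_DEFAULT_BETAS[1]
    beta3: float = MAR_DEFAULT_BETAS[2]
    beta0: float | None = None

    def validate(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ConfigurationError(f"mechanism must be one of {MECHANISMS}")
        if not 0.0 < self.p_sub < 1.0:
            raise ConfigurationError("p_sub must lie in (0, 1)")
        if not 0.0 <= self.p_item <= 1.0:
            raise ConfigurationError("p_item must lie in [0, 1]")

    def linear_terms(self, data: pd.DataFrame) -> np.ndarray:
        """Covariate (MAR) or true-total (MNAR) contributions, without beta0."""
        if self.mechanism == "MAR":
            return mar_linear_terms(data, self.beta1, self.beta2, self.beta3)
        return mnar_linear_terms(total_scores(data), self.beta1)

    def solved_for(self, data: pd.DataFrame) -> "MissingnessConfig":
        """Copy of the config with ``beta0`` solved on ``data``."""
        self.validate()
        return replace(self, beta0=solve_beta0(self.linear_terms(data), self.p_sub))


@dataclass(frozen=True)
class MissingnessMask:
    """Per-subject eligibility flags and per-item deletion flags."""

    eligible: np.ndarray  # (n,) 0/1
    deleted: np.ndarray  # (n, 6) 0/1; all-zero rows for ineligible subjects

    def __post_init__(self):
        if self.deleted.shape != (self.eligible.shape[0], N_ITEMS):
            raise ConfigurationError("mask dimensions do not match")
        if self.deleted[self.eligible == 0].any():
            raise ConfigurationError("deletions assigned to ineligible subjects")

    @property
    def missing_fraction(self) -> float:
        return float(self.deleted.mean())

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.deleted, columns=[f"del_{c}" for c in ITEM_COLUMNS])
        out.insert(0, "eligible", self.eligible)
        return out


def mar_linear_terms(
    data: pd.DataFrame, beta1: float, beta2: float, beta3: float
) -> np.ndarray:
    for col in ("gender", "smoke_where"):
        if data[col].isna().any():
            raise InvalidDataError(f"covariate {col!r} has missing values")
    gender = data["gender"].to_numpy(dtype=float)
    sw = data["smoke_where"].to_numpy()
    outside = (sw == 1).astype(float)
    inside = (sw == 3).astype(float)
    return beta1 * gender + beta2 * outside + beta3 * inside


def mnar_linear_terms(true_totals: np.ndarray, beta1: float) -> np.ndarray:
    totals = np.asarray(true_totals, dtype=float)
    if np.isnan(totals).any():
        raise InvalidDataError("MNAR eligibility needs complete true totals")
    return beta1 * totals


def eligibility_probabilities_mar(
    data: pd.DataFrame, beta0: float, beta1: float, beta2: float, beta3: float
) -> np.ndarray:
    """Logistic eligibility probabilities from the covariate model."""
    return expit(beta0 + mar_linear_terms(data, beta1, beta2, beta3))


def eligibility_probabilities_mnar(
    true_totals: np.ndarray, beta0: float, beta1: float
) -> np.ndarray:
    """Logistic eligibility probabilities from the true total score."""
    return expit(beta0 + mnar_linear_terms(true_totals, beta1))


def solve_beta0(
    linear_terms: np.ndarray, p_sub: float, tol: float = 1e-8, max_iter: int = 200
) -> float:
    """Intercept making the mean eligibility probability equal ``p_sub``.

    The mean of ``expit(beta0 + terms)`` is strictly increasing in ``beta0``,
    so bracketing bisection on [-50, 50] has a unique root; convergence is to
    ``tol`` on the mean probability.
    """
    terms = np.asarray(linear_terms, dtype=float)
    if terms.size == 0 or not np.all(np.isfinite(terms)):
        raise InvalidDataError("linear terms must be finite and non-empty")
    if not 0.0 < p_sub < 1.0:
        raise ConfigurationError("p_sub must lie in (0, 1)")

    def gap(b0):
        return expit(b0 + terms).mean() - p_sub

    lo, hi = -50.0, 50.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise SolverError("p_sub not attainable within the intercept bracket")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        g = gap(mid)
        if abs(g) <= tol:
            return mid
        if g < 0:
            lo = mid
        else:
            hi = mid
    raise SolverError("intercept bisection did not converge")


def draw_missingness(
    data: pd.DataFrame, config: MissingnessConfig, seed
) -> tuple[pd.DataFrame, MissingnessMask]:
    """Inject item-level missingness; returns the observed data and the mask.

    ``config.beta0`` must already be solved (see
    :meth:`MissingnessConfig.solved_for`).  ``seed`` may be an int or a
    ``numpy.random.SeedSequence``; it is split into separate eligibility and
    item-deletion streams, and an identical seed reproduces the mask exactly.
    """
    config.validate()
    if config.beta0 is None:
        raise ConfigurationError("beta0 must be solved before drawing missingness")
    probs = expit(config.beta0 + config.linear_terms(data))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    elig_rng, item_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    eligible = (elig_rng.random(len(data)) < probs).astype(np.int8)
    deleted = (item_rng.random((len(data), N_ITEMS)) < config.p_item).astype(np.int8)
    deleted *= eligible[:, None]
    observed = data.copy()
    items = observed.loc[:, list(ITEM_COLUMNS)].to_numpy(dtype=float)
    items[deleted.astype(bool)] = np.nan
    observed[list(ITEM_COLUMNS)] = items
    return observed, MissingnessMask(eligible=eligible, deleted=deleted)
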
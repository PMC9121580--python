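"""Synthetic FTND population generator and its moment calibration.

The generator emulates a large quitline sample of smokers who completed all
six FTND items.  Each subject carries a single latent nicotine-dependence
trait ``eta = covariate shift + Z`` with ``Z ~ N(0, 1)``; item *i* is an
ordinal threshold discretisation of ``loading_i * eta + eps_i`` with
independent standard-normal item noise.  Three covariates (gender, a
three-level "If you smoke at home, where?" variable and a binary "Is
smoking allowed in your home?" variable) shift the trait, which makes them
weakly associated with the total score and lets the MAR missingness
mechanism act through them.

Because covariates are discrete, the marginal distribution of each item's
latent variable is a finite normal mixture whose CDF is available in closed
form; thresholds reproducing any target category probabilities are solved
analytically, so the only simulation-tuned knobs are the loadings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dataset import (
    COLUMNS,
    DEPENDENCE_BANDS,
    ITEM_COLUMNS,
    ITEM_MAX,
    N_ITEMS,
    item_matrix,
)
from .exceptions import CalibrationError, ConfigurationError, InvalidDataError

#: number of score levels per item (items 1 & 4 are 0-3, the rest 0/1)
ITEM_LEVELS = tuple(int(m) + 1 for m in ITEM_MAX)
_ORDINAL_CUTS = np.array([0.5, 1.5, 2.5])

# Defaults produced by calibrate_generator against the default targets.
_DEFAULT_LOADINGS = (1.00892, 0.491423, 0.689334, 0.621556, 0.574864, 0.576011)
_DEFAULT_THRESHOLDS = (
    (-1.559485, -0.563826, 0.432212),
    (0.785877,),
    (-0.212757,),
    (-0.297282, 0.958546, 2.214602),
    (0.322847,),
    (0.04777,),
)
_DEFAULT_SA_EFFECT = 0.39


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic-population model.

    ``item_thresholds`` are cut points on each item's latent scale (three for
    items 1 and 4, one for the binary items); ``*_effect`` parameters are
    additive shifts of the latent trait in standard-deviation units.
    """

    population_size: int = 38334
    item_loadings: tuple[float, ...] = _DEFAULT_LOADINGS
    item_thresholds: tuple[tuple[float, ...], ...] = _DEFAULT_THRESHOLDS
    male_prevalence: float = 0.43
    smoke_where_probs: tuple[float, float, float] = (0.45, 0.35, 0.20)
    smoking_allowed_prevalence: float = 0.35
    gender_effect: float = 0.04
    smoke_where_effects: tuple[float, float, float] = (-0.04, 0.02, 0.06)
    smoking_allowed_effect: float = _DEFAULT_SA_EFFECT
    seed: int = 0

    def validate(self) -> None:
        if self.population_size < 0:
            raise ConfigurationError("population_size must be >= 0")
        if len(self.item_loadings) != N_ITEMS:
            raise ConfigurationError("need one loading per item")
        if any(lam < 0 for lam in self.item_loadings):
            raise ConfigurationError("loadings must be non-negative")
        if len(self.item_thresholds) != N_ITEMS:
            raise ConfigurationError("need thresholds for every item")
        for i, thr in enumerate(self.item_thresholds):
            if len(thr) != ITEM_LEVELS[i] - 1:
                raise ConfigurationError(
                    f"item {i + 1} needs {ITEM_LEVELS[i] - 1} thresholds"
                )
            if any(b <= a for a, b in zip(thr, thr[1:])):
                raise ConfigurationError(f"item {i + 1} thresholds must increase")
        for p in (self.male_prevalence, self.smoking_allowed_prevalence):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("prevalences must lie in [0, 1]")
        probs = np.asarray(self.smoke_where_probs, dtype=float)
        if (probs < 0).any() or (probs > 1).any():
            raise ConfigurationError("smoke_where probabilities must lie in [0, 1]")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ConfigurationError("smoke_where probabilities must sum to 1")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["item_loadings"] = [float(x) for x in self.item_loadings]
        out["item_thresholds"] = [[float(t) for t in thr] for thr in self.item_thresholds]
        out["smoke_where_probs"] = [float(p) for p in self.smoke_where_probs]
        out["smoke_where_effects"] = [float(p) for p in self.smoke_where_effects]
        return out

    @classmethod
    def from_dict(cls, mapping: dict) -> "GeneratorConfig":
        kwargs = dict(mapping)
        for key in ("item_loadings", "smoke_where_probs", "smoke_where_effects"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "item_thresholds" in kwargs:
            kwargs["item_thresholds"] = tuple(tuple(t) for t in kwargs["item_thresholds"])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown generator config keys: {sorted(unknown)}")
        config = cls(**kwargs)
        config.validate()
        return config


def default_config(population_size: int = 38334, seed: int = 0) -> GeneratorConfig:
    """The calibrated default configuration (Table-1-like moments)."""
    return GeneratorConfig(population_size=population_size, seed=seed)


# ---------------------------------------------------------------------------
# generation


def _covariate_patterns(config: GeneratorConfig):
    """Weights and latent-trait means of the 12 covariate cells."""
    g_probs = np.array([1.0 - config.male_prevalence, config.male_prevalence])
    sw_probs = np.asarray(config.smoke_where_probs, dtype=float)
    sa_probs = np.array(
        [1.0 - config.smoking_allowed_prevalence, config.smoking_allowed_prevalence]
    )
    weights, means = [], []
    for g in (0, 1):
        for j in range(3):
            for sa in (0, 1):
                weights.append(g_probs[g] * sw_probs[j] * sa_probs[sa])
                means.append(
                    g * config.gender_effect
                    + config.smoke_where_effects[j]
                    + sa * config.smoking_allowed_effect
                )
    return np.array(weights), np.array(means)


def _marginal_cdf(t: float, loading: float, weights: np.ndarray, means: np.ndarray) -> float:
    scale = np.sqrt(loading**2 + 1.0)
    return float(weights @ stats.norm.cdf((t - loading * means) / scale))


def solve_thresholds(
    loadings: np.ndarray,
    category_probs: list[np.ndarray],
    weights: np.ndarray,
    means: np.ndarray,
) -> tuple[tuple[float, ...], ...]:
    """Thresholds reproducing ``category_probs`` under the latent mixture."""
    thresholds = []
    for i in range(N_ITEMS):
        lam = float(loadings[i])
        scale = np.sqrt(lam**2 + 1.0)
        lo = lam * means.min() - 9.0 * scale
        hi = lam * means.max() + 9.0 * scale
        cum = np.cumsum(category_probs[i])[:-1]
        cuts = []
        for c in cum:
            cuts.append(
                optimize.brentq(
                    lambda t: _marginal_cdf(t, lam, weights, means) - c, lo, hi, xtol=1e-10
                )
            )
        thresholds.append(tuple(cuts))
    return tuple(thresholds)


class _RawDraws:
    """Pre-drawn covariates and noise, reusable across loading candidates.

    Common random numbers make the calibration objective a smooth,
    deterministic function of the loadings.
    """

    def __init__(self, config: GeneratorConfig, size: int, rng: np.random.Generator):
        self.gender = (rng.random(size) < config.male_prevalence).astype(np.int8)
        sw_idx = rng.choice(3, size=size, p=np.asarray(config.smoke_where_probs))
        self.sw_idx = sw_idx.astype(np.int8)
        self.smoking_allowed = (
            rng.random(size) < config.smoking_allowed_prevalence
        ).astype(np.int8)
        self.z = rng.standard_normal(size)
        self.eps = rng.standard_normal((size, N_ITEMS))

    def eta(self, config: GeneratorConfig) -> np.ndarray:
        sw_eff = np.asarray(config.smoke_where_effects)[self.sw_idx]
        return (
            self.gender * config.gender_effect
            + sw_eff
            + self.smoking_allowed * config.smoking_allowed_effect
            + self.z
        )


def _score_items(
    draws: _RawDraws,
    loadings: np.ndarray,
    thresholds: tuple[tuple[float, ...], ...],
    eta: np.ndarray,
) -> np.ndarray:
    items = np.empty((eta.shape[0], N_ITEMS), dtype=np.int8)
    for i in range(N_ITEMS):
        y = loadings[i] * eta + draws.eps[:, i]
        items[:, i] = np.searchsorted(np.asarray(thresholds[i]), y, side="left")
    return items


def generate_population(
    config: GeneratorConfig, size: int | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Generate a complete synthetic dataset.

    ``size`` and ``seed`` override the corresponding config fields; a fixed
    seed fixes the dataset bit-for-bit.
    """
    config.validate()
    n = config.population_size if size is None else int(size)
    if n < 0:
        raise ConfigurationError("size must be >= 0")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    draws = _RawDraws(config, n, rng)
    eta = draws.eta(config)
    items = _score_items(draws, np.asarray(config.item_loadings), config.item_thresholds, eta)
    data = {"id": np.arange(n)}
    for i, col in enumerate(ITEM_COLUMNS):
        data[col] = items[:, i].astype(np.int64)
    data["gender"] = draws.gender.astype(np.int64)
    data["smoke_where"] = np.array([0, 1, 3])[draws.sw_idx]
    data["smoking_allowed"] = draws.smoking_allowed.astype(np.int64)
    return pd.DataFrame(data, columns=list(COLUMNS))


# ---------------------------------------------------------------------------
# descriptive statistics


def _as_item_array(data) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        if all(c in data.columns for c in ITEM_COLUMNS):
            arr = item_matrix(data)
        else:
            arr = data.to_numpy(dtype=float)
    else:
        arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise InvalidDataError("expected a 2-D item matrix")
    return arr


def cronbach_alpha(data) -> float:
    """Cronbach's alpha ``k/(k-1) * (1 - sum(var_i) / var_total)``.

    ``data`` may be an FTND dataset or any subjects-by-items matrix with no
    missing entries and at least two rows.
    """
    arr = _as_item_array(data)
    if np.isnan(arr).any():
        raise InvalidDataError("Cronbach's alpha requires complete items")
    if arr.shape[0] < 2:
        raise InvalidDataError("need at least 2 subjects")
    k = arr.shape[1]
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise InvalidDataError("total-score variance is zero")
    return k / (k - 1) * (1.0 - arr.var(axis=0, ddof=1).sum() / total_var)


def spearman_item_rest(data, item: int) -> float:
    """Spearman correlation of item ``item`` (1-based) with the rest-total."""
    arr = _as_item_array(data)
    if np.isnan(arr).any():
        raise InvalidDataError("item-rest correlation requires complete items")
    if arr.shape[0] < 3:
        raise InvalidDataError("need at least 3 subjects")
    if not 1 <= item <= arr.shape[1]:
        raise InvalidDataError(f"item index {item} out of range")
    col = arr[:, item - 1]
    rest = arr.sum(axis=1) - col
    if np.ptp(col) == 0 or np.ptp(rest) == 0:
        raise InvalidDataError("correlation undefined for a constant column")
    rho = stats.spearmanr(col, rest).statistic
    return float(rho)


def _item_rest_spearman_all(items: np.ndarray) -> np.ndarray:
    """Vectorised item-rest Spearman correlations (midrank ties)."""
    ranks_items = np.apply_along_axis(stats.rankdata, 0, items)
    total = items.sum(axis=1)
    out = np.empty(items.shape[1])
    for i in range(items.shape[1]):
        rest_rank = stats.rankdata(total - items[:, i])
        out[i] = np.corrcoef(ranks_items[:, i], rest_rank)[0, 1]
    return out


def dependence_category_proportions(data) -> np.ndarray:
    """Proportions in the five dependence bands 0-2 / 3-4 / 5 / 6-7 / 8-10."""
    totals = _as_item_array(data).sum(axis=1)
    if np.isnan(totals).any():
        raise InvalidDataError("dependence bands require complete items")
    return np.array(
        [np.mean((totals >= lo) & (totals <= hi)) for lo, hi in DEPENDENCE_BANDS]
    )


# ---------------------------------------------------------------------------
# calibration


@dataclass(frozen=True)
class CalibrationTargets:
    """Moment targets for the generator, with per-family tolerances."""

    item_means: tuple[float, ...] = (2.0, 0.3, 0.6, 0.9, 0.4, 0.5)
    item_sds: tuple[float, ...] = (1.0, 0.4, 0.5, 0.8, 0.5, 0.5)
    total_mean: float = 4.7
    total_sd: float = 2.3
    cronbach_alpha: float = 0.59
    item_rest_correlations: tuple[float, ...] = (0.48, 0.26, 0.35, 0.36, 0.31, 0.31)
    mean_tol: float = 0.05
    sd_tol: float = 0.05
    total_mean_tol: float = 0.05
    total_sd_tol: float = 0.05
    alpha_tol: float = 0.02
    corr_tol: float = 0.05

    def validate(self) -> None:
        values = (
            list(self.item_means)
            + list(self.item_sds)
            + [self.total_mean, self.total_sd, self.cronbach_alpha]
            + list(self.item_rest_correlations)
        )
        if not np.all(np.isfinite(values)):
            raise ConfigurationError("calibration targets must be finite")
        for tol in (
            self.mean_tol,
            self.sd_tol,
            self.total_mean_tol,
            self.total_sd_tol,
            self.alpha_tol,
            self.corr_tol,
        ):
            if tol <= 0:
                raise ConfigurationError("tolerances must be positive")
        if abs(sum(self.item_means) - self.total_mean) > 0.5:
            raise ConfigurationError(
                "item means and total mean are mutually inconsistent"
            )


def default_targets() -> CalibrationTargets:
    return CalibrationTargets()


def _discretised_normal_probs(mean: float, sd: float) -> np.ndarray:
    """Category probabilities of a 0-3 item matching ``mean`` and ``sd``.

    The item is modelled as a normal discretised at 0.5/1.5/2.5, whose two
    parameters are solved so the category distribution hits both moments.
    """

    def moments(params):
        m, log_s = params
        s = np.exp(log_s)
        cdf = stats.norm.cdf((_ORDINAL_CUTS - m) / s)
        probs = np.diff(np.concatenate(([0.0], cdf, [1.0])))
        levels = np.arange(4)
        mu = probs @ levels
        var = probs @ (levels - mu) ** 2
        return np.array([mu - mean, np.sqrt(var) - sd])

    sol = optimize.root(moments, x0=np.array([mean, np.log(max(sd, 0.2))]), tol=1e-12)
    if not sol.success or np.abs(sol.fun).max() > 1e-6:
        raise CalibrationError(f"no 0-3 marginal with mean {mean}, SD {sd}")
    m, log_s = sol.x
    cdf = stats.norm.cdf((_ORDINAL_CUTS - m) / np.exp(log_s))
    return np.diff(np.concatenate(([0.0], cdf, [1.0])))


def _binary_prob(mean: float, sd: float, mean_tol: float, sd_tol: float) -> float:
    """Success probability of a 0/1 item balancing mean and SD targets.

    A Bernoulli mean pins its SD, so both printed targets may be unattainable
    at once; the probability minimising the worst tolerance-normalised
    violation is chosen (deterministically) within the mean's tolerance box.
    """
    grid = np.linspace(max(mean - mean_tol, 1e-4), min(mean + mean_tol, 1 - 1e-4), 2001)
    viol = np.maximum(
        np.abs(grid - mean) / mean_tol,
        np.abs(np.sqrt(grid * (1 - grid)) - sd) / sd_tol,
    )
    return float(grid[np.argmin(viol)])


_ALPHA_FACTOR = N_ITEMS / (N_ITEMS - 1)


def _feasible_variance_window(sum_item_var: float, targets: CalibrationTargets):
    """Total-variance interval jointly compatible with total-SD and alpha."""
    v_sd = (
        (targets.total_sd - targets.total_sd_tol) ** 2,
        (targets.total_sd + targets.total_sd_tol) ** 2,
    )
    a_lo = targets.cronbach_alpha - targets.alpha_tol
    a_hi = targets.cronbach_alpha + targets.alpha_tol
    v_alpha = (
        sum_item_var / (1.0 - a_lo / _ALPHA_FACTOR),
        sum_item_var / (1.0 - a_hi / _ALPHA_FACTOR),
    )
    lo = max(v_sd[0], v_alpha[0])
    hi = min(v_sd[1], v_alpha[1])
    return lo, hi


def _marginal_category_probs(targets: CalibrationTargets) -> list[np.ndarray]:
    """Per-item category probabilities satisfying the marginal targets.

    Items 1 and 4 get a small SD slack (within tolerance) chosen to maximise
    the width of the total-variance window that can satisfy the total SD and
    alpha jointly; the binary items use the min-max projection.
    """
    binary_p = {
        i: _binary_prob(
            targets.item_means[i], targets.item_sds[i], targets.mean_tol, targets.sd_tol
        )
        for i in (1, 2, 4, 5)
    }
    # redistribute any total-mean shortfall over the binary items' remaining
    # mean-tolerance headroom (the 0-3 items match their means exactly)
    shortfall = targets.total_mean - (
        targets.item_means[0] + targets.item_means[3] + sum(binary_p.values())
    )
    headroom = {
        i: max(0.9 * targets.mean_tol - abs(p - targets.item_means[i]), 0.0)
        for i, p in binary_p.items()
    }
    total_headroom = sum(headroom.values())
    if total_headroom > 0:
        shift = np.clip(shortfall, -total_headroom, total_headroom)
        binary_p = {
            i: p + shift * headroom[i] / total_headroom for i, p in binary_p.items()
        }
    binary = {i: np.array([1.0 - p, p]) for i, p in binary_p.items()}
    best = None
    for slack in np.linspace(0.0, max(targets.sd_tol - 0.006, 0.0), 9):
        probs = [None] * N_ITEMS
        for i in (0, 3):
            probs[i] = _discretised_normal_probs(
                targets.item_means[i], targets.item_sds[i] + slack
            )
        for i, p in binary.items():
            probs[i] = p
        sum_var = 0.0
        for i in range(N_ITEMS):
            levels = np.arange(ITEM_LEVELS[i])
            mu = probs[i] @ levels
            sum_var += probs[i] @ (levels - mu) ** 2
        lo, hi = _feasible_variance_window(sum_var, targets)
        width = hi - lo
        if best is None or width > best[0]:
            best = (width, probs, 0.5 * (lo + hi))
    width, probs, v_target = best
    if width <= 0:
        raise CalibrationError(
            "item SDs, total SD and Cronbach's alpha are jointly infeasible "
            "within their tolerances"
        )
    return probs, v_target


class _Budget:
    def __init__(self, n: int):
        self.left = n

    def spend(self):
        self.left -= 1
        if self.left < 0:
            raise CalibrationError("calibration search budget exhausted")


def calibrate_generator(
    targets: CalibrationTargets | None = None,
    search_budget: int = 200,
    seed: int = 0,
    base_config: GeneratorConfig | None = None,
    calibration_size: int = 100_000,
) -> GeneratorConfig:
    """Fit loadings and thresholds so simulated moments meet ``targets``.

    Thresholds are matched to the target marginals analytically for any
    candidate loadings; a global loading scale is then solved by bracketing
    bisection (common random numbers) against the jointly feasible total
    variance, with multiplicative per-item adjustments toward the item-rest
    correlation targets in between.  Deterministic given ``seed`` and budget;
    raises :class:`CalibrationError` (naming the worst offender) if the final
    check at ``calibration_size`` subjects misses any tolerance.
    """
    targets = targets or default_targets()
    targets.validate()
    base = base_config or default_config()
    base.validate()
    budget = _Budget(search_budget)
    probs, v_target = _marginal_category_probs(targets)
    weights, pattern_means = _covariate_patterns(base)

    ss = np.random.SeedSequence(seed)
    fit_seed, check_seed = ss.spawn(2)
    draws = _RawDraws(base, calibration_size, np.random.default_rng(fit_seed))
    eta = draws.eta(base)

    def simulate(loadings: np.ndarray) -> np.ndarray:
        budget.spend()
        thr = solve_thresholds(loadings, probs, weights, pattern_means)
        return _score_items(draws, loadings, thr, eta).astype(float)

    def fit_scale(loadings: np.ndarray) -> np.ndarray:
        def gap(s):
            return simulate(loadings * s).sum(axis=1).var(ddof=1) - v_target

        lo, hi = 0.2, 4.0
        if gap(lo) > 0 or gap(hi) < 0:
            raise CalibrationError("loading scale bracket does not span the target")
        s = optimize.brentq(gap, lo, hi, xtol=2e-3)
        return loadings * s

    r_targets = np.asarray(targets.item_rest_correlations, dtype=float)
    loadings = np.maximum(2.2 * r_targets, 0.05)
    for _ in range(2):
        loadings = fit_scale(loadings)
        r_sim = _item_rest_spearman_all(simulate(loadings))
        adjust = np.clip(r_targets / np.maximum(r_sim, 1e-3), 0.6, 1.67) ** 0.8
        loadings = np.maximum(loadings * adjust, 0.02)
    loadings = fit_scale(loadings)

    thresholds = solve_thresholds(loadings, probs, weights, pattern_means)
    config = dataclasses.replace(
        base,
        item_loadings=tuple(float(x) for x in loadings),
        item_thresholds=thresholds,
    )

    check = generate_population(
        config, size=calibration_size, seed=int(check_seed.generate_state(1)[0] % 2**31)
    )
    report = population_report(check, targets)
    worst = report.loc[report["violation"].idxmax()]
    if worst["violation"] > 1.0:
        raise CalibrationError(
            f"calibration failed: {worst['target']} achieved {worst['achieved']:.4f}"
            f" vs target {worst['value']:.4f} (tolerance {worst['tolerance']})"
        )
    return config


def population_report(data: pd.DataFrame, targets: CalibrationTargets | None = None) -> pd.DataFrame:
    """Achieved vs target moments, with tolerance-normalised violations."""
    targets = targets or default_targets()
    items = item_matrix(data)
    totals = items.sum(axis=1)
    rows = []

    def add(name, value, achieved, tol):
        rows.append(
            {
                "target": name,
                "value": value,
                "achieved": achieved,
                "tolerance": tol,
                "violation": abs(achieved - value) / tol,
            }
        )

    for i in range(N_ITEMS):
        add(f"item{i + 1}_mean", targets.item_means[i], items[:, i].mean(), targets.mean_tol)
        add(f"item{i + 1}_sd", targets.item_sds[i], items[:, i].std(ddof=1), targets.sd_tol)
    add("total_mean", targets.total_mean, totals.mean(), targets.total_mean_tol)
    add("total_sd", targets.total_sd, totals.std(ddof=1), targets.total_sd_tol)
    add("cronbach_alpha", targets.cronbach_alpha, cronbach_alpha(items), targets.alpha_tol)
    r_sim = _item_rest_spearman_all(items)
    for i in range(N_ITEMS):
        add(
            f"item{i + 1}_rest_corr",
            targets.item_rest_correlations[i],
            r_sim[i],
            targets.corr_tol,
        )
    return pd.DataFrame(rows)
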
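"""Simulation driver: sample, inject missingness, score, estimate, aggregate.

One replication draws ``n_obs`` subjects with replacement from the complete
population, records the true mean FTND and regression slope, solves the
eligibility intercept on that sample, injects missingness, scores the
observed data with every requested method (all methods see the identical
observed dataset, so comparisons are paired) and estimates both estimands.
``run_grid`` repeats this for every grid cell and aggregates the
replication records into a tidy performance-summary table.

:class:`MissingnessStudy` wraps the driver in a model-like object whose
``run`` returns a :class:`StudyResults` carrying the summary table, the
optional per-replication estimates and a reproducibility manifest.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .dataset import total_scores, validate_dataset
from .exceptions import ConfigurationError, UndefinedEstimateError
from .metrics import (
    ESTIMANDS,
    Estimate,
    TruthPair,
    bias_and_percent,
    flag_clinical_bias,
    mean_and_se,
    ols_simple,
    summarize_replications,
)
from .missingness import MECHANISMS, MissingnessConfig, draw_missingness
from .scoring import METHODS, score

logger = logging.getLogger(__name__)

CELL_KEYS = ("mechanism", "p_sub", "p_item", "n_obs")


@dataclass(frozen=True)
class SimulationGrid:
    """The full factorial design over mechanisms, rates and sample sizes."""

    n_obs: tuple[int, ...] = (52, 788)
    mechanisms: tuple[str, ...] = ("MAR", "MNAR")
    p_sub: tuple[float, ...] = (0.1, 0.3, 0.5)
    p_item: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7)
    replications: int = 1000
    methods: tuple[str, ...] = METHODS
    hot_deck_k: int = 5
    ci_method: str = "percentile"

    def validate(self) -> None:
        if self.replications < 1:
            raise ConfigurationError("replications must be >= 1")
        if not (self.n_obs and self.mechanisms and self.p_sub and self.p_item):
            raise ConfigurationError("grid must be non-empty")
        bad = set(self.mechanisms) - set(MECHANISMS)
        if bad:
            raise ConfigurationError(f"unknown mechanisms: {sorted(bad)}")
        bad = set(self.methods) - set(METHODS)
        if bad:
            raise ConfigurationError(f"unknown methods: {sorted(bad)}")
        if any(n < 1 for n in self.n_obs):
            raise ConfigurationError("n_obs values must be positive")

    def cells(self) -> list[dict]:
        """Deterministically ordered grid cells."""
        return [
            dict(zip(CELL_KEYS, combo))
            for combo in itertools.product(
                self.mechanisms, self.p_sub, self.p_item, self.n_obs
            )
        ]

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key in ("n_obs", "mechanisms", "p_sub", "p_item", "methods"):
            out[key] = list(out[key])
        return out

    @classmethod
    def from_dict(cls, mapping: dict) -> "SimulationGrid":
        kwargs = dict(mapping)
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown grid keys: {sorted(unknown)}")
        for key in ("n_obs", "mechanisms", "p_sub", "p_item", "methods"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        grid = cls(**kwargs)
        grid.validate()
        return grid


def sample_with_replacement(
    population: pd.DataFrame, n_obs: int, seed
) -> pd.DataFrame:
    """Uniform sample of ``n_obs`` rows with replacement."""
    if len(population) == 0:
        raise ConfigurationError("population is empty")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(population), size=int(n_obs))
    return population.iloc[idx].reset_index(drop=True)


def _replication_seeds(master_seed: int, cell_index: int, replication_index: int):
    ss = np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=(cell_index, replication_index)
    )
    return ss.spawn(3)  # sampling, missingness, hot-deck donors


def run_replication(
    population: pd.DataFrame,
    cell: dict,
    replication_index: int,
    master_seed: int = 0,
    cell_index: int = 0,
    methods: tuple[str, ...] = METHODS,
    hot_deck_k: int = 5,
) -> list[dict]:
    """One replication of one grid cell; returns tidy per-method records."""
    sample_seed, miss_seed, donor_seed = _replication_seeds(
        master_seed, cell_index, replication_index
    )
    sample = sample_with_replacement(population, cell["n_obs"], sample_seed)
    true_totals = total_scores(sample)
    x = sample["smoking_allowed"].to_numpy(dtype=float)
    truths = {
        "mean_ftnd": TruthPair("mean_ftnd", float(true_totals.mean())),
        "regression_coefficient": TruthPair(
            "regression_coefficient", ols_simple(true_totals, x).value
        ),
    }
    config = MissingnessConfig(
        mechanism=cell["mechanism"], p_sub=cell["p_sub"], p_item=cell["p_item"]
    ).solved_for(sample)
    observed, _ = draw_missingness(sample, config, miss_seed)
    records = []
    for method in methods:
        result = score(observed, method, k=hot_deck_k, seed=donor_seed)
        for estimand in ESTIMANDS:
            row = dict(cell)
            row.update(
                method=method, estimand=estimand, replication=replication_index
            )
            try:
                if estimand == "mean_ftnd":
                    est = mean_and_se(result.totals)
                else:
                    est = ols_simple(result.totals, x)
                bias, pct = bias_and_percent(est, truths[estimand])
                row.update(
                    theta_hat=est.value,
                    model_se=est.model_se,
                    n_used=est.n_used,
                    theta_true=truths[estimand].value,
                    bias=bias,
                    percent_bias=pct,
                )
            except UndefinedEstimateError:
                row.update(
                    theta_hat=np.nan,
                    model_se=np.nan,
                    n_used=0,
                    theta_true=truths[estimand].value,
                    bias=np.nan,
                    percent_bias=np.nan,
                )
            records.append(row)
    return records


def run_grid(
    population: pd.DataFrame,
    grid: SimulationGrid | None = None,
    master_seed: int = 0,
    keep_estimates: bool = False,
):
    """Run every grid cell; returns (summary, estimates-or-None, manifest)."""
    grid = grid or SimulationGrid()
    grid.validate()
    validate_dataset(population, allow_missing_items=False)
    cells = grid.cells()
    all_records: list[dict] = []
    summaries: list[dict] = []
    for ci, cell in enumerate(cells):
        logger.info(
            "cell %d/%d %s: %d replications", ci + 1, len(cells), cell, grid.replications
        )
        cell_records: list[dict] = []
        for ri in range(grid.replications):
            cell_records.extend(
                run_replication(
                    population,
                    cell,
                    ri,
                    master_seed=master_seed,
                    cell_index=ci,
                    methods=grid.methods,
                    hot_deck_k=grid.hot_deck_k,
                )
            )
        frame = pd.DataFrame(cell_records)
        for (method, estimand), block in frame.groupby(
            ["method", "estimand"], sort=False
        ):
            row = dict(cell)
            row.update(method=method, estimand=estimand)
            row.update(
                summarize_replications(
                    block["theta_hat"].to_numpy(),
                    block["model_se"].to_numpy(),
                    block["bias"].to_numpy(),
                    block["percent_bias"].to_numpy(),
                    grid.ci_method,
                )
            )
            if row["n_undefined"] == grid.replications:
                logger.warning("cell %s method %s: all replications undefined", cell, method)
            summaries.append(row)
        if keep_estimates:
            all_records.extend(cell_records)
    summary = flag_clinical_bias(pd.DataFrame(summaries))
    estimates = pd.DataFrame(all_records) if keep_estimates else None
    manifest = {
        "package_version": __version__,
        "master_seed": int(master_seed),
        "grid": grid.to_dict(),
        "population_rows": int(len(population)),
        "numpy_version": np.__version__,
    }
    return summary, estimates, manifest


class MissingnessStudy:
    """The simulation study as a model-like object.

    Built from a complete population (generated or user-supplied) and a
    :class:`SimulationGrid`; ``run`` executes the Monte Carlo design and
    returns a :class:`StudyResults`.
    """

    def __init__(self, population: pd.DataFrame, grid: SimulationGrid | None = None):
        validate_dataset(population, allow_missing_items=False)
        self.population = population
        self.grid = grid or SimulationGrid()
        self.grid.validate()

    def run(self, seed: int = 0, keep_estimates: bool = False) -> "StudyResults":
        summary, estimates, manifest = run_grid(
            self.population, self.grid, master_seed=seed, keep_estimates=keep_estimates
        )
        return StudyResults(summary, estimates, manifest, self.grid)


#: the four Fig-2-style panels: (estimand, column, label)
_MEASURES = (
    ("mean_ftnd", "mean_percent_bias", "% bias of mean FTND"),
    ("mean_ftnd", "mean_percent_se_bias", "% bias of SE of mean FTND"),
    ("regression_coefficient", "mean_percent_bias", "% bias of regression coeff."),
    ("regression_coefficient", "mean_percent_se_bias", "% bias of SE of regr. coeff."),
)


class StudyResults:
    """Summary table, optional raw estimates and manifest of one study run."""

    def __init__(self, summary, estimates, manifest, grid):
        self.summary_frame = summary
        self.estimates = estimates
        self.manifest = manifest
        self.grid = grid

    def measure_table(self, estimand: str, column: str) -> pd.DataFrame:
        """Pivot one performance measure to cells x methods."""
        block = self.summary_frame[self.summary_frame["estimand"] == estimand]
        return block.pivot_table(
            index=["mechanism", "p_sub", "p_item", "n_obs"],
            columns="method",
            values=column,
            sort=True,
        )

    def summary(self) -> str:
        """Human-readable four-measure comparison, one panel per measure."""
        lines = []
        for estimand, column, label in _MEASURES:
            lines.append(label)
            lines.append("-" * len(label))
            lines.append(self.measure_table(estimand, column).round(2).to_string())
            lines.append("")
        flags = self.summary_frame["clinically_important"].map(lambda v: bool(v) if pd.notna(v) else False)
        flagged = self.summary_frame[flags]
        lines.append(
            f"cells with clinically important mean-FTND bias (>= 1 point): {len(flagged)}"
        )
        return "\n".join(lines)

    def to_csv(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {"summary": out_dir / "summary.csv", "manifest": out_dir / "manifest.json"}
        self.summary_frame.to_csv(paths["summary"], index=False)
        with open(paths["manifest"], "w") as fh:
            json.dump(self.manifest, fh, indent=2)
        if self.estimates is not None:
            paths["estimates"] = out_dir / "estimates.csv"
            self.estimates.to_csv(paths["estimates"], index=False)
        return paths
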
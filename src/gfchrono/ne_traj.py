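"""Aggregation of per-population Ne(t) step-function trajectories.

Stairway-Plot-style estimators output, per population, a step function of
effective population size against time.  To summarize the *common*
demographic trajectory across populations whose absolute sizes differ, each
population's curve is evaluated on a shared time grid, z-transformed
(mean 0, sd 1 across the grid), and averaged; a population-level bootstrap
gives a 95% confidence band.  The z-transform makes the mean curve
invariant to per-population affine rescaling of Ne, so haploid/diploid
conventions cannot change it.

Time scaling assumes 3 generations per year (a 4-month generation time)
and a mutation rate of 2.5e-9 per base per generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NeTrajectory",
    "TimeScaleConfig",
    "NeAggregate",
    "generations_to_years",
    "to_grid",
    "z_transform",
    "aggregate",
    "log_time_grid",
    "read_trajectory_tsv",
    "read_stairway_summary",
]


@dataclass(frozen=True)
class TimeScaleConfig:
    mutation_rate: float = 2.5e-9       # per base per generation
    generations_per_year: float = 3.0   # 4-month generation time

    def __post_init__(self) -> None:
        if self.mutation_rate <= 0 or self.generations_per_year <= 0:
            raise ValueError("time-scale parameters must be positive")


@dataclass
class NeTrajectory:
    """Right-continuous Ne step function for one population.

    ``ne[i]`` applies from ``times[i]`` (inclusive) until ``times[i+1]``;
    the last value extends indefinitely into the past.  Times are years
    before present unless ``time_unit`` is "generations".
    """

    population_id: str
    times: np.ndarray
    ne: np.ndarray
    time_unit: str = "years"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ne = np.asarray(self.ne, dtype=float)
        if self.times.size == 0:
            raise ValueError("empty trajectory")
        if self.times.shape != self.ne.shape:
            raise ValueError("times and ne must have the same length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.ne <= 0):
            raise ValueError("Ne values must be positive")

    def in_years(self, cfg: TimeScaleConfig = TimeScaleConfig()
                 ) -> "NeTrajectory":
        if self.time_unit == "years":
            return self
        yrs = np.array([generations_to_years(g, cfg) for g in self.times],
                       dtype=float)
        keep = np.concatenate([[True], np.diff(yrs) > 0])
        return NeTrajectory(self.population_id, yrs[keep], self.ne[keep],
                            time_unit="years")


def generations_to_years(g: float, cfg: TimeScaleConfig = TimeScaleConfig()
                         ) -> int:
    """Whole years before present for ``g`` generations (floor division)."""
    if g < 0:
        raise ValueError("generations must be non-negative")
    return int(np.floor(g / cfg.generations_per_year))


def to_grid(traj: NeTrajectory, grid: np.ndarray) -> np.ndarray:
    """Evaluate the step function on a time grid.

    A grid time inside a step takes that step's value; an exact breakpoint
    takes the younger (more recent) step's value; times past the last
    breakpoint take the last value.
    """
    grid = np.asarray(grid, dtype=float)
    idx = np.searchsorted(traj.times, grid, side="left") - 1
    return traj.ne[np.clip(idx, 0, traj.ne.size - 1)]


def z_transform(values: np.ndarray) -> np.ndarray:
    """Center and scale to sample mean 0 and sample (n-1) sd 1."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: z-transform undefined")
    return (values - values.mean()) / sd


@dataclass
class NeAggregate:
    grid: np.ndarray                  # years before present
    population_ids: list[str]
    z_curves: np.ndarray              # (n_pops, n_grid)
    mean: np.ndarray
    lower: np.ndarray                 # 2.5% bootstrap quantile
    upper: np.ndarray                 # 97.5% bootstrap quantile
    n_replicates: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.grid, "mean_z": self.mean,
                             "ci_low": self.lower, "ci_high": self.upper})


def log_time_grid(start: float = 10.0, stop: float = 50_000.0,
                  n: int = 200) -> np.ndarray:
    """Default common grid: log-spaced years from near-present to 50 kyr."""
    return np.geomspace(start, stop, n)


def aggregate(trajs: list[NeTrajectory], grid: np.ndarray, B: int = 10_000,
              seed: int = 0) -> NeAggregate:
    """Grid-evaluate, z-transform, average, and bootstrap populations.

    The band is the 2.5%/97.5% quantile of the cross-population mean curve
    over B resamples of populations with replacement.
    """
    if not trajs:
        raise ValueError("no trajectories given")
    grid = np.asarray(grid, dtype=float)
    z = np.vstack([z_transform(to_grid(t.in_years(), grid)) for t in trajs])
    mean = z.mean(axis=0)
    rng = np.random.default_rng(seed)
    k = len(trajs)
    reps = np.empty((B, grid.size))
    for b in range(B):
        reps[b] = z[rng.integers(0, k, size=k)].mean(axis=0)
    return NeAggregate(grid=grid, population_ids=[t.population_id for t in trajs],
                       z_curves=z, mean=mean,
                       lower=np.quantile(reps, 0.025, axis=0),
                       upper=np.quantile(reps, 0.975, axis=0),
                       n_replicates=B)


# ---------------------------------------------------------------------------
# File dialects


def read_trajectory_tsv(path, population_id: str | None = None,
                        time_unit: str = "years") -> NeTrajectory:
    """Read the canonical two-column (time, Ne) TSV."""
    df = pd.read_csv(path, sep="\t")
    tcol, necol = df.columns[:2]
    return NeTrajectory(population_id or str(path),
                        df[tcol].to_numpy(), df[necol].to_numpy(),
                        time_unit=time_unit)


def read_stairway_summary(path, population_id: str | None = None
                          ) -> NeTrajectory:
    """Tolerant reader for Stairway-Plot ".final.summary" files.

    Looks for a "year" column and an "Ne_median" column (any extra columns
    are ignored); duplicate years keep the first (youngest-step) row.
    """
    df = pd.read_csv(path, sep=r"\s+")
    cols = {c.lower(): c for c in df.columns}
    try:
        year = cols["year"]
        ne = cols["ne_median"]
    except KeyError as exc:
        raise ValueError(f"{path}: missing year/Ne_median column") from exc
    df = df[[year, ne]].dropna()
    df = df[~df[year].duplicated(keep="first")].sort_values(year)
    return NeTrajectory(population_id or str(path),
                        df[year].to_numpy(dtype=float),
                        df[ne].to_numpy(dtype=float), time_unit="years")
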
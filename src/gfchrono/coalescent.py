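"""Two-deme isolation-with-migration coalescent simulation.

The demography is the standard IM picture: two present-day populations of
diploid sizes N1 and N2 that merged ``t_split`` generations ago into one
ancestral population of size ``n_ancestral``, exchanging migrants
symmetrically while separate.  Gene flow has two epochs — a recent rate
``m_recent`` on [0, x_break) and an older rate ``m_old`` on
[x_break, t_split) — or, for validation work, an arbitrary piecewise
schedule.  Sizes may change exponentially since the split.

The Monte Carlo engine tallies, per simulated genealogy, the total branch
length subtending every descendant configuration (i, j); under the
infinite-sites model the expected joint SFS cell (i, j) is
``mu * L * E[branch length (i, j)]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import exp

import numpy as np

from ._engine import _init_state, _mean_tally, _simulate_one
from .sfs import Joint2dSFS, fold_joint_sfs

__all__ = [
    "IMModel",
    "SampleConfig",
    "IMScenario",
    "GenealogyTally",
    "sample_genealogy",
    "expected_joint_sfs",
    "simulate_observed_sfs",
    "make_scenario",
    "scale_scenario",
    "SCENARIO_TABLE",
]


@dataclass(frozen=True)
class IMModel:
    """Two-epoch isolation-with-migration demography (sizes are diploid).

    ``growth_rate_1/2`` are forward-time exponential rates per generation
    since the split (positive = population grew toward the present); sizes
    ``n1_current``/``n2_current`` are the present-day values.  If
    ``m_schedule`` is given it overrides (m_recent, m_old, x_break): a tuple
    of (start_generation_ago, rate) pairs, each rate applying from its start
    time back to the next entry's start (the last entry runs to t_split).
    """

    n1_current: float
    n2_current: float
    n_ancestral: float
    t_split: float
    x_break: float = 0.0
    m_recent: float = 0.0
    m_old: float = 0.0
    growth_rate_1: float = 0.0
    growth_rate_2: float = 0.0
    m_schedule: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if min(self.n1_current, self.n2_current, self.n_ancestral) <= 0:
            raise ValueError("population sizes must be positive")
        if not (0 <= self.x_break <= self.t_split):
            raise ValueError("need 0 <= x_break <= t_split")
        for m in self.migration_rates():
            if not (0 <= m < 1):
                raise ValueError("migration probabilities must lie in [0, 1)")

    def migration_rates(self) -> list[float]:
        if self.m_schedule is not None:
            return [r for _, r in self.m_schedule]
        return [self.m_recent, self.m_old]

    def migration_rate(self, tau: float) -> float:
        """Symmetric per-lineage migration rate ``tau`` generations ago."""
        if tau >= self.t_split:
            return 0.0
        if self.m_schedule is not None:
            rate = 0.0
            for start, r in sorted(self.m_schedule):
                if tau >= start:
                    rate = r
                else:
                    break
            return rate
        return self.m_recent if tau < self.x_break else self.m_old

    def size_at(self, tau: float, deme: int) -> float:
        """Diploid size of deme 1 or 2 ``tau`` generations ago."""
        if tau >= self.t_split:
            return self.n_ancestral
        cur = self.n1_current if deme == 1 else self.n2_current
        g = self.growth_rate_1 if deme == 1 else self.growth_rate_2
        return cur * exp(-g * tau)


@dataclass(frozen=True)
class SampleConfig:
    """Haploid sample sizes drawn from each deme."""

    k1: int
    k2: int

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2 < 0 or self.k1 + self.k2 < 2:
            raise ValueError("need k1, k2 >= 0 and k1 + k2 >= 2")


@dataclass(frozen=True)
class IMScenario:
    """A simulation scenario: an IM demography plus a genome layout.

    The genome is ``n_loci`` chromosomes of ``locus_length`` bases;
    recombination within a chromosome is approximated by cutting it into
    ``windows_per_locus`` freely recombining windows, each simulated as one
    non-recombining genealogy (the SFS is insensitive to linkage in
    expectation).  ``annotations`` carries reported-but-derived values such
    as the printed current sizes of the declining/growing scenarios.
    """

    scenario_id: int
    model: IMModel
    n_loci: int = 6
    locus_length: float = 15_000_000.0
    recombination_rate: float = 1e-8
    mutation_rate: float = 1e-8
    windows_per_locus: int = 150
    annotations: dict = field(default_factory=dict)

    @property
    def genome_length(self) -> float:
        return self.n_loci * self.locus_length

    @property
    def n_windows(self) -> int:
        return self.n_loci * self.windows_per_locus


class GenealogyTally:
    """Branch lengths per descendant configuration for one (or averaged)
    genealogies, plus bookkeeping totals."""

    def __init__(self, k1: int, k2: int, branch: np.ndarray,
                 total_length: float, tmrca: float | None = None):
        self.k1, self.k2 = k1, k2
        self.branch = branch          # (k1+1, k2+1) generations
        self.total_length = total_length
        self.tmrca = tmrca


def _epoch_arrays(model: IMModel):
    """Flatten a model into the engine's epoch arrays."""
    breaks = {0.0, model.t_split}
    if model.m_schedule is not None:
        breaks.update(t for t, _ in model.m_schedule if 0 < t < model.t_split)
    elif 0 < model.x_break < model.t_split:
        breaks.add(model.x_break)
    pts = sorted(breaks)
    t0s, t1s, ms, n1s, b1s, n2s, b2s, merged = [], [], [], [], [], [], [], []
    for a, b in zip(pts, pts[1:]):
        t0s.append(a)
        t1s.append(b)
        ms.append(model.migration_rate(a))
        n1s.append(model.size_at(a, 1))
        n2s.append(model.size_at(a, 2))
        b1s.append(-model.growth_rate_1)
        b2s.append(-model.growth_rate_2)
        merged.append(0)
    # ancestral epoch to infinity
    t0s.append(model.t_split)
    t1s.append(1e300)
    ms.append(0.0)
    n1s.append(model.n_ancestral)
    n2s.append(model.n_ancestral)
    b1s.append(0.0)
    b2s.append(0.0)
    merged.append(1)
    as_f = lambda x: np.asarray(x, dtype=np.float64)
    return (as_f(t0s), as_f(t1s), as_f(ms), as_f(n1s), as_f(b1s),
            as_f(n2s), as_f(b2s), np.asarray(merged, dtype=np.int64))


def sample_genealogy(model: IMModel, samples: SampleConfig, seed: int
                     ) -> GenealogyTally:
    """Simulate one genealogy; returns the (i, j) branch-length tally.

    Cell (i, j) holds the total length (generations) of branches subtending
    i of the k1 deme-1 samples and j of the k2 deme-2 samples.  The sum over
    cells equals the total tree length exactly.
    """
    eps = _epoch_arrays(model)
    tally = np.zeros((samples.k1 + 1, samples.k2 + 1))
    total, tmrca = _simulate_one(samples.k1, samples.k2, *eps, tally,
                                 _init_state(int(seed) & 0x7FFFFFFF, 0))
    return GenealogyTally(samples.k1, samples.k2, tally, total, tmrca)


def expected_joint_sfs(model: IMModel, samples: SampleConfig, seq_len: float,
                       mu: float, n_reps: int, seed: int, fold: bool = False
                       ) -> Joint2dSFS:
    """Monte Carlo expected joint SFS: cell = mu * L * mean branch length.

    Replicate r uses seed ``seed ^ r``, so the result is a deterministic
    function of (model, samples, seed) — the common-random-numbers property
    the likelihood search relies on.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    eps = _epoch_arrays(model)
    mean_branch, _ = _mean_tally(int(n_reps), int(seed), samples.k1,
                                 samples.k2, *eps)
    counts = mu * seq_len * mean_branch
    counts[0, 0] = 0.0
    counts[samples.k1, samples.k2] = 0.0
    sfs = Joint2dSFS(samples.k1, samples.k2, counts, folded_minor=False)
    return fold_joint_sfs(sfs) if fold else sfs


def simulate_observed_sfs(scenario: IMScenario, samples: SampleConfig,
                          seed: int, fold: bool = False) -> Joint2dSFS:
    """Simulate an observed joint SFS for a scenario (integer counts).

    One genealogy is drawn per freely recombining window; mutation counts
    are Poisson around the per-cell expected means summed over windows.
    """
    window_len = scenario.locus_length / scenario.windows_per_locus
    expected = expected_joint_sfs(scenario.model, samples,
                                  window_len * scenario.n_windows,
                                  scenario.mutation_rate,
                                  scenario.n_windows, seed)
    rng = np.random.default_rng((int(seed) * 2654435761 + 1) % 2**31)
    counts = rng.poisson(expected.counts).astype(float)
    sfs = Joint2dSFS(samples.k1, samples.k2, counts, folded_minor=False)
    return fold_joint_sfs(sfs) if fold else sfs


# ---------------------------------------------------------------------------
# The five validation scenarios

_COMMON = dict(n1=11_250.0, n2=11_250.0, n_anc=202_500.0, t_split=45_000.0)
_DECAY = 5e-5  # per-generation exponential size-change rate, scenarios 3-4

# Scenario 5: symmetric gene flow stepping down toward the present.  The
# final window (600 generations ago to present) carries two published rates
# (1e-5 then 0); the internal boundary is taken at 300 generations ago.
_S5_SCHEDULE = ((0.0, 0.0), (300.0, 1e-5), (600.0, 2e-5), (3_000.0, 3e-5),
                (6_000.0, 4e-5), (9_000.0, 5e-5), (12_000.0, 6e-5))

SCENARIO_TABLE = {
    1: "no gene flow",
    2: "constant gene flow 6e-5",
    3: "constant gene flow 6e-5, exponential decline 5e-5/gen since split",
    4: "constant gene flow 6e-5, exponential growth 5e-5/gen since split",
    5: "stepwise-decreasing gene flow over the last 12,000 generations",
}


def make_scenario(scenario_id: int) -> IMScenario:
    """The five published validation scenarios for the gene-flow estimator.

    All share: two populations of 11,250 diploids (22,500 chromosomes) that
    split 45,000 generations ago from an ancestor of 202,500 diploids; six
    chromosomes of 15 Mb; recombination and mutation rates 1e-8.  Scenarios
    3 and 4 change size exponentially at 5e-5 per generation since the
    split (starting from the common size at the split), an ~90% reduction
    and an ~9.5-fold increase respectively; their printed current sizes are
    kept as annotations.
    """
    if scenario_id not in SCENARIO_TABLE:
        raise ValueError(f"unknown scenario id {scenario_id!r}; expected 1-5")
    c = _COMMON
    ann: dict = {}
    kw = dict(n_ancestral=c["n_anc"], t_split=c["t_split"],
              x_break=c["t_split"])
    if scenario_id == 1:
        model = IMModel(c["n1"], c["n2"], m_recent=0.0, m_old=0.0, **kw)
    elif scenario_id == 2:
        model = IMModel(c["n1"], c["n2"], m_recent=6e-5, m_old=6e-5, **kw)
    elif scenario_id == 3:
        cur = c["n1"] * exp(-_DECAY * c["t_split"])
        model = IMModel(cur, cur, m_recent=6e-5, m_old=6e-5,
                        growth_rate_1=-_DECAY, growth_rate_2=-_DECAY, **kw)
        ann = {"printed_current_diploid": 1_000.0,
               "size_reduction_fraction": 1.0 - exp(-_DECAY * c["t_split"])}
    elif scenario_id == 4:
        cur = c["n1"] * exp(_DECAY * c["t_split"])
        model = IMModel(cur, cur, m_recent=6e-5, m_old=6e-5,
                        growth_rate_1=_DECAY, growth_rate_2=_DECAY, **kw)
        ann = {"printed_current_diploid": 500_000.0,
               "size_fold_increase": exp(_DECAY * c["t_split"])}
    else:
        model = IMModel(c["n1"], c["n2"], m_schedule=_S5_SCHEDULE, **kw)
    return IMScenario(scenario_id=scenario_id, model=model, annotations=ann)


def scale_scenario(scenario: IMScenario, factor: float,
                   n_loci: int | None = None,
                   locus_length: float | None = None,
                   windows_per_locus: int | None = None) -> IMScenario:
    """Coalescent-invariant rescaling to desk scale.

    Multiplying sizes and times by ``factor`` while dividing migration,
    growth and mutation rates by it leaves the genealogy distribution (in
    rescaled time) and the expected SFS per base unchanged — a small, fast
    scenario with the same SFS signal.  Genome layout can be shrunk
    independently.
    """
    m = scenario.model
    sched = None
    if m.m_schedule is not None:
        sched = tuple((t * factor, r / factor) for t, r in m.m_schedule)
    model = IMModel(
        n1_current=m.n1_current * factor, n2_current=m.n2_current * factor,
        n_ancestral=m.n_ancestral * factor, t_split=m.t_split * factor,
        x_break=m.x_break * factor,
        m_recent=m.m_recent / factor, m_old=m.m_old / factor,
        growth_rate_1=m.growth_rate_1 / factor,
        growth_rate_2=m.growth_rate_2 / factor,
        m_schedule=sched)
    return replace(scenario, model=model,
                   mutation_rate=scenario.mutation_rate / factor,
                   recombination_rate=scenario.recombination_rate / factor,
                   n_loci=n_loci or scenario.n_loci,
                   locus_length=locus_length or scenario.locus_length,
                   windows_per_locus=windows_per_locus
                   or scenario.windows_per_locus)
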
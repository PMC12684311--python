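"""Desk-scale validation studies for the gene-flow estimation pipeline.

The estimator is validated the same way it is used: joint SFS data are
simulated under known demographies, the IM scan and the deconvolution are
run on them, and the result is compared with the generating truth.  Two
studies are provided:

* :func:`recover_im_parameters` — single-fit parameter recovery on
  noise-free expected spectra (no gene flow recovered as ~0; moderate gene
  flow recovered within a small factor).
* :func:`scenario5_trend_study` — the qualitative check that a stepwise
  *decrease* in gene flow toward the present is recovered as deconvolved
  recent-interval rates below old-interval rates.

Everything runs on a desk-scale rescaling of the published scenarios:
sizes and times shrunk tenfold with rates scaled up tenfold (a
distribution-preserving change of coalescent units) and a 200 x 50 kb
genome, so one replicate costs seconds-to-minutes rather than cluster
hours.  Replicates of the scenario-5 study warm-start their reference fit
from the previous replicate's solution — a variance-reduction device that
leaves each replicate's data and likelihood untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coalescent import (IMModel, IMScenario, SampleConfig,
                         expected_joint_sfs, make_scenario, scale_scenario,
                         simulate_observed_sfs)
from .deconv import (T2Trajectory, average_trajectories,
                     deconvolve_intervals, smooth_t2)
from .im_fit import (GeneFlowScan, SearchConfig, _warm_theta, default_x_grid,
                     fit_im_pair, scan_gene_flow)

__all__ = [
    "mini_scenario",
    "search_config",
    "recover_im_parameters",
    "RecoveryResult",
    "scenario5_trend_study",
]

DESK_FACTOR = 0.1          # coalescent-invariant rescaling of the scenarios
MINI_N_LOCI = 200
MINI_LOCUS_LENGTH = 5e4
MINI_SAMPLES = SampleConfig(8, 8)


def mini_scenario(scenario_id: int, n_loci: int = MINI_N_LOCI,
                  locus_length: float = MINI_LOCUS_LENGTH) -> IMScenario:
    """Desk-scale version of a published validation scenario.

    Loci shrink to 50 kb split into 10 kb freely-recombining windows — the
    same recombination approximation as the full-scale scenarios (100 kb
    windows) after the tenfold rescaling of coalescent units.
    """
    return scale_scenario(make_scenario(scenario_id), DESK_FACTOR,
                          n_loci=n_loci, locus_length=locus_length,
                          windows_per_locus=5)


def search_config(scenario: IMScenario, effort: str = "full",
                  seed: int = 0) -> SearchConfig:
    """Search settings matched to a scenario's genome, by effort tier.

    ``full`` is the from-scratch search; ``reference`` assumes a warm start
    from a neighbouring solution is available; ``track`` is the light
    within-scan tracking tier.
    """
    common = dict(seq_len=scenario.genome_length,
                  mutation_rate=scenario.mutation_rate, seed=seed)
    if effort == "full":
        return SearchConfig(n_probes=16, n_starts=8, n_reps_likelihood=2000,
                            max_iterations=400, polish_restarts=3,
                            ridge_polish_iterations=0, **common)
    if effort == "reference":
        return SearchConfig(n_probes=2, n_starts=3, n_reps_likelihood=2000,
                            max_iterations=150, ridge_polish_iterations=0,
                            **common)
    if effort == "track":
        return SearchConfig(n_probes=2, n_starts=3, n_reps_likelihood=1500,
                            max_iterations=50, polish_restarts=1,
                            final_selection_reps_factor=16,
                            ridge_polish_iterations=0, **common)
    raise ValueError(f"unknown effort tier {effort!r}")


@dataclass
class RecoveryResult:
    truth: IMModel
    fit_params: dict[str, float]
    excluded: bool

    @property
    def m_recent_ratio(self) -> float:
        if self.truth.m_recent == 0:
            return float("nan")
        return self.fit_params["m_recent"] / self.truth.m_recent

    @property
    def t_split_ratio(self) -> float:
        return self.fit_params["t_split"] / self.truth.t_split


def recover_im_parameters(truth: IMModel, x_break: float, seq_len: float,
                          mutation_rate: float, seed: int,
                          samples: SampleConfig = MINI_SAMPLES,
                          n_reps_observed: int = 20_000,
                          deep_polish: bool = True) -> RecoveryResult:
    """Fit the IM model to the noise-free expected SFS of a known truth.

    The observed spectrum is the Monte Carlo expectation at the truth
    (``n_reps_observed`` genealogies, a seed unrelated to the search's);
    ``deep_polish`` enables the high-replicate Powell ridge polish that
    separates split time from migration on the composite-likelihood ridge.
    """
    obs = expected_joint_sfs(truth, samples, seq_len, mutation_rate,
                             n_reps_observed, seed=seed ^ 0x5EED, fold=True)
    cfg = SearchConfig(seq_len=seq_len, mutation_rate=mutation_rate,
                       n_probes=48, n_starts=8, n_reps_likelihood=2000,
                       max_iterations=300,
                       ridge_polish_iterations=12 if deep_polish else 0,
                       ridge_polish_reps_factor=8, seed=seed)
    fit = fit_im_pair(obs, x_break, cfg)
    return RecoveryResult(truth=truth, fit_params=fit.params,
                          excluded=fit.excluded)


def scenario5_trend_study(n_replicates: int = 20, seed: int = 1,
                          x_max: float = 900.0, n_pairs: int = 2,
                          samples: SampleConfig = MINI_SAMPLES
                          ) -> pd.DataFrame:
    """Replicate the stepwise-decline recovery check at desk scale.

    Per replicate: simulate ``n_pairs`` independent observed joint SFS from
    the mini scenario 5, scan the IM fit over epoch boundaries
    X = 100..``x_max`` step 100 for each pair, average the integrated t2
    estimates across pairs (the estimator is defined on the cross-pair
    average, never on a single pair), smooth and deconvolve, and compare
    the mean deconvolved rate over the most recent third of intervals
    against the oldest third.  Returns one row per replicate with the two
    means and the ``trend_ok`` flag (recent below old, as the generating
    schedule has).

    Desk-scale pairs identify only the *trend* of t2, so the smoothing
    spline runs with a large manual penalty (near-linear fit) rather than
    generalized cross-validation, which under-penalizes on a ten-point
    grid and lets the interval inversion amplify fit scatter into spurious
    rate wiggles.
    """
    mini = mini_scenario(5)
    grid = default_x_grid(100.0, x_max, 100.0)
    k = max(grid.size // 3, 1)
    rows = []
    chain: list[np.ndarray] = []
    n_fit = 0
    for r in range(n_replicates):
        trajs = []
        excluded = []
        for p in range(n_pairs):
            obs = simulate_observed_sfs(
                mini, samples,
                seed=(seed * 10_007 + r * n_pairs + p) % 2**31, fold=True)
            # the very first scan searches from scratch; later scans seed
            # their reference fit from the chain, and within a replicate
            # the second pair's scan runs entirely in tracking mode
            effort = ("full" if n_fit == 0
                      else ("reference" if p == 0 else "track"))
            scan = scan_gene_flow(
                obs, grid, search_config(mini, effort, seed=seed + n_fit),
                pair_id=f"rep{r + 1}_pair{p + 1}",
                warm_cfg=search_config(mini, "track", seed=seed + n_fit),
                initial_starts=chain)
            n_fit += 1
            chain = [_warm_theta(scan.fits[-1])] + chain[:1]
            trajs.append(T2Trajectory.from_scan(scan))
            excluded.append(scan.excluded_fraction)
        mean_traj = average_trajectories(trajs)
        res = deconvolve_intervals(smooth_t2(mean_traj, lam=1e12), x=grid)
        recent = float(res.act_raw[:k].mean())
        old = float(res.act_raw[-k:].mean())
        rows.append({"replicate": r + 1, "recent_rate": recent,
                     "old_rate": old, "trend_ok": recent < old,
                     "excluded_fraction": float(np.mean(excluded))})
    return pd.DataFrame(rows)
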
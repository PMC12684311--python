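"""Isolation-with-migration parameter estimation from a joint SFS.

For a population pair, the observed folded minor-allele 2dSFS is matched
against Monte Carlo expected spectra under the two-epoch IM demography by a
Poisson composite likelihood.  The epoch boundary X is *fixed* per fit; a
scan refits the pair for every X on a grid (default 100..14,000 by 100
generations), giving the integrated recent gene-flow rate t2(X) that the
deconvolution stage converts into per-interval rates.  Fits whose estimated
split time falls below their X are flagged excluded — there the "recent"
epoch would reach into the ancestral population and its rate is
meaningless.

The search is multi-start bounded Nelder-Mead on log10-transformed
parameters.  Every likelihood evaluation re-simulates its genealogies from
the same seed (common random numbers), so the objective is a deterministic
function of the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln

from .coalescent import IMModel, SampleConfig, expected_joint_sfs
from .sfs import Joint2dSFS

__all__ = [
    "SearchConfig",
    "IMFit",
    "GeneFlowScan",
    "composite_loglik",
    "fit_im_pair",
    "scan_gene_flow",
    "default_x_grid",
]

_EXPECTED_FLOOR = 1e-12

# parameter order in the search vector (log10 scale)
_PARAMS = ("n1", "n2", "n_anc", "t_split", "m_recent", "m_old")


@dataclass
class SearchConfig:
    """Search settings for one IM fit.

    ``seq_len`` and ``mutation_rate`` must describe the data behind the
    observed SFS (total callable bases and per-base per-generation rate);
    they set the absolute scale of the expected spectra.  Bounds are the
    prior ranges of the inference: sizes 10..1e7 diploids, split time
    10..1e5 generations, migration 1e-20..1e-1 per generation.
    """

    seq_len: float
    mutation_rate: float = 1e-8
    size_bounds: tuple[float, float] = (10.0, 1e7)
    t_bounds: tuple[float, float] = (10.0, 1e5)
    m_bounds: tuple[float, float] = (1e-20, 1e-1)
    n_starts: int = 8
    n_probes: int = 128
    n_reps_likelihood: int = 2000
    max_iterations: int = 300
    polish_restarts: int = 2
    final_selection_reps_factor: int = 8
    ridge_polish_iterations: int = 8
    ridge_polish_reps_factor: int = 4
    seed: int = 0
    mask_singletons: bool = False

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")

    def log_bounds(self) -> list[tuple[float, float]]:
        b = [self.size_bounds] * 3 + [self.t_bounds] + [self.m_bounds] * 2
        return [(np.log10(lo), np.log10(hi)) for lo, hi in b]


@dataclass
class IMFit:
    """Result of one fit at a fixed epoch boundary ``x_break``."""

    model: IMModel
    x_break: float
    loglik: float
    excluded: bool
    excluded_reason: str = ""
    at_bound: tuple[str, ...] = ()
    converged: bool = True
    n_evaluations: int = 0

    @property
    def params(self) -> dict[str, float]:
        m = self.model
        return {"n1": m.n1_current, "n2": m.n2_current,
                "n_anc": m.n_ancestral, "t_split": m.t_split,
                "m_recent": m.m_recent, "m_old": m.m_old}


@dataclass
class GeneFlowScan:
    """Per-X IM fits for one population pair."""

    pair_id: str
    x_grid: np.ndarray
    fits: list[IMFit]

    def __post_init__(self) -> None:
        self.x_grid = np.asarray(self.x_grid, dtype=float)
        if np.any(np.diff(self.x_grid) <= 0):
            raise ValueError("x grid must be strictly increasing")

    @property
    def excluded_fraction(self) -> float:
        return float(np.mean([f.excluded for f in self.fits]))

    def t2_series(self, drop_excluded: bool = True
                  ) -> tuple[np.ndarray, np.ndarray]:
        """(x, t2) pairs: the integrated recent gene-flow rate per X."""
        xs, t2 = [], []
        for x, f in zip(self.x_grid, self.fits):
            if drop_excluded and f.excluded:
                continue
            xs.append(x)
            t2.append(f.model.m_recent)
        return np.asarray(xs), np.asarray(t2)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for x, f in zip(self.x_grid, self.fits):
            rows.append({"X": x, **f.params, "loglik": f.loglik,
                         "excluded": f.excluded,
                         "at_bound": ",".join(f.at_bound)})
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def default_x_grid(start: float = 100.0, stop: float = 14_000.0,
                   step: float = 100.0) -> np.ndarray:
    """The scan grid of epoch boundaries (inclusive of ``stop``)."""
    return np.arange(start, stop + step / 2, step)


def composite_loglik(observed: Joint2dSFS, expected: Joint2dSFS,
                     mask_singletons: bool = False) -> float:
    """Poisson composite log-likelihood of an observed SFS.

    Cells are treated as independent Poisson counts with the expected SFS as
    means (floored at 1e-12).  The monomorphic (0, 0) cell and the
    fully-fixed (n1, n2) cell carry no polymorphism information and are
    masked; ``mask_singletons`` additionally drops the (1, 0) and (0, 1)
    cells, for sensitivity to uncertain singleton calls.
    """
    if observed.counts.shape != expected.counts.shape:
        raise ValueError("observed and expected SFS shapes differ")
    if observed.folded_minor != expected.folded_minor:
        raise ValueError("observed and expected folding conventions differ")
    mask = np.zeros_like(observed.counts, dtype=bool)
    mask[0, 0] = True
    mask[observed.n1, observed.n2] = True
    if mask_singletons:
        mask[1, 0] = True
        mask[0, 1] = True
    obs = observed.counts[~mask]
    exp = np.maximum(expected.counts[~mask], _EXPECTED_FLOOR)
    return float(np.sum(obs * np.log(exp) - exp - gammaln(obs + 1.0)))


def _model_from_log10(theta: np.ndarray, x_break: float) -> IMModel:
    n1, n2, nanc, t, mr, mo = 10.0 ** np.asarray(theta, dtype=float)
    return IMModel(n1, n2, nanc, t_split=t, x_break=min(x_break, t),
                   m_recent=mr, m_old=mo)


def _harmonic(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n))) if n > 1 else 1.0


def _moment_start(observed: Joint2dSFS, cfg: SearchConfig,
                  bounds: list[tuple[float, float]]) -> np.ndarray:
    """Data-informed starting point (log10 scale).

    Current sizes from the private-singleton cells (E[xi_1] = 4 N mu L for
    the terminal branches, which reflect the recent local size rather than
    ancestral polymorphism); the ancestral size from a pooled Watterson
    count; split time from between-population divergence
    d_xy = 2 mu T + 4 N_anc mu.  Rough by design — it only has to land the
    search in the right basin.
    """
    c = observed.counts
    n1, n2 = observed.n1, observed.n2
    muL = cfg.mutation_rate * cfg.seq_len
    xi1 = float(c[1, 0] + c[n1 - 1, n2])
    xi2 = float(c[0, 1] + c[n1, n2 - 1])
    s_tot = float(c.sum()) - float(c[0, 0]) - float(c[n1, n2])
    n1_hat = max(xi1 / (4 * muL), 10.0)
    n2_hat = max(xi2 / (4 * muL), 10.0)
    nanc_hat = max(s_tot / _harmonic(n1 + n2) / (4 * muL), 10.0)
    p1 = np.arange(n1 + 1)[:, None] / n1
    p2 = np.arange(n2 + 1)[None, :] / n2
    dxy = float(np.sum(c * (p1 * (1 - p2) + p2 * (1 - p1)))) / cfg.seq_len
    t_hat = max((dxy - 4 * nanc_hat * cfg.mutation_rate)
                / (2 * cfg.mutation_rate), 10.0)
    start = np.log10([n1_hat, n2_hat, nanc_hat, t_hat, 1e-6, 1e-6])
    return np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds])


def _candidate_starts(observed: Joint2dSFS, cfg: SearchConfig,
                      bounds: list[tuple[float, float]],
                      rng: np.random.Generator
                      ) -> list[tuple[str, np.ndarray]]:
    """Grouped starting candidates: moment-anchored grid + uniform draws.

    The (t_split, migration) pair has a narrow joint basin flanked by broad
    decoys (a recent split with no migration mimics an old split with gene
    flow), and a start's initial score is a poor predictor of the basin it
    descends into — so candidates are labelled by their migration level and
    the multi-start stage polishes the best member of *each* group rather
    than the overall top scorers.
    """
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    anchor = _moment_start(observed, cfg, bounds)
    cands = [("anchor", (lo + hi) / 2), ("anchor", anchor)]
    for t_mult in (0.3, 1.0):
        for anc_mult in (1.0, 3.0):
            for m in (3e-4, 1e-4, 1e-5, 1e-6, 1e-9, 1e-12):
                c = anchor.copy()
                c[2] = anchor[2] + np.log10(anc_mult)
                c[3] = anchor[3] + np.log10(t_mult)
                c[4] = c[5] = np.log10(m)
                cands.append((f"m{m:g}", np.clip(c, lo, hi)))
    cands += [("probe", rng.uniform(lo, hi)) for _ in range(cfg.n_probes)]
    return cands


def fit_im_pair(observed: Joint2dSFS, x_break: float, cfg: SearchConfig,
                extra_starts: list[np.ndarray] | None = None) -> IMFit:
    """Maximize the composite likelihood at a fixed epoch boundary.

    The observed SFS must be folded to the minor allele.  The search runs
    on log10-transformed parameters within the prior bounds in four phases:
    (1) score the candidate starts (moment-anchored grid, log-uniform
    probes, any ``extra_starts`` such as a neighbouring scan fit);
    (2) briefly Nelder-Mead-polish the best ``n_starts``; (3) fully polish
    the leaders with simplex restarts; (4) track the (t_split, migration)
    likelihood ridge from the best point with Powell line searches on a
    lower-noise objective (``ridge_polish_reps_factor`` times the
    genealogies).  The fit is marked excluded when the estimated split time
    is below ``x_break``.
    """
    if not observed.folded_minor:
        raise ValueError("observed SFS must be folded to the minor allele")
    samples = SampleConfig(observed.n1, observed.n2)
    bounds = cfg.log_bounds()
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    rng = np.random.default_rng(cfg.seed)

    n_eval = 0

    def make_objective(n_reps: int):
        def objective(theta: np.ndarray) -> float:
            nonlocal n_eval
            n_eval += 1
            model = _model_from_log10(np.clip(theta, lo, hi), x_break)
            exp_sfs = expected_joint_sfs(model, samples, cfg.seq_len,
                                         cfg.mutation_rate, n_reps,
                                         cfg.seed, fold=True)
            return -composite_loglik(observed, exp_sfs,
                                     mask_singletons=cfg.mask_singletons)
        return objective

    objective = make_objective(cfg.n_reps_likelihood)

    def polish(x0: np.ndarray, maxiter: int, restarts: int = 1
               ) -> tuple[np.ndarray, float]:
        x = np.asarray(x0, dtype=float)
        fun = np.inf
        for _ in range(restarts):
            res = minimize(objective, x, method="Nelder-Mead", bounds=bounds,
                           options={"maxiter": maxiter,
                                    "xatol": 1e-4, "fatol": 1e-4,
                                    "adaptive": True})
            x, fun = res.x, float(res.fun)
        return x, fun

    cands = _candidate_starts(observed, cfg, bounds, rng)
    if extra_starts:
        cands = [(f"warm{i}", np.clip(np.asarray(x, dtype=float), lo, hi))
                 for i, x in enumerate(extra_starts)] + cands
    # best-scoring member of each candidate group, groups ranked by score;
    # warm starts always reach the polish stage
    group_best: dict[str, tuple[float, np.ndarray]] = {}
    for label, x0 in cands:
        f0 = objective(x0)
        if label not in group_best or f0 < group_best[label][0]:
            group_best[label] = (f0, x0)
    warm_entries = [v for k, v in group_best.items() if k.startswith("warm")]
    rest = sorted((v for k, v in group_best.items()
                   if not k.startswith("warm")), key=lambda t: t[0])
    ranked = warm_entries + rest
    brief = sorted((polish(x0, maxiter=max(cfg.max_iterations // 4, 40))
                    for _, x0 in ranked[:cfg.n_starts]), key=lambda r: r[1])
    finalists = [polish(x0, maxiter=cfg.max_iterations,
                        restarts=cfg.polish_restarts)
                 for x0, _ in brief[:max(1, cfg.n_starts // 4)]]
    finalists += brief

    if cfg.final_selection_reps_factor > 1 and len(finalists) > 1:
        # low-noise comparison: polished finalists are often separated by
        # less than the base objective's Monte Carlo jitter
        fine = make_objective(cfg.n_reps_likelihood
                              * cfg.final_selection_reps_factor)
        best_x = min((x for x, _ in finalists), key=fine)
        best_f = objective(best_x)
    else:
        best_x, best_f = min(finalists, key=lambda t: t[1])

    if cfg.ridge_polish_iterations > 0:
        fine = make_objective(cfg.n_reps_likelihood
                              * cfg.ridge_polish_reps_factor)
        res = minimize(fine, best_x, method="Powell", bounds=bounds,
                       options={"maxiter": cfg.ridge_polish_iterations,
                                "xtol": 1e-4, "ftol": 1e-4})
        # Powell's long line searches can overshoot on the noisy surface;
        # keep its point only if the base objective actually improves
        f_candidate = objective(res.x)
        if f_candidate < best_f:
            best_x, best_f = res.x, f_candidate

    theta = np.clip(best_x, lo, hi)
    model = _model_from_log10(theta, x_break)
    at_bound = tuple(
        name for name, v, (l, h) in zip(_PARAMS, theta, bounds)
        if v - l < 1e-6 or h - v < 1e-6)
    excluded = model.t_split < x_break
    return IMFit(model=model, x_break=x_break, loglik=-best_f,
                 excluded=excluded,
                 excluded_reason="t_split < x_break" if excluded else "",
                 at_bound=at_bound, converged=np.isfinite(best_f),
                 n_evaluations=n_eval)


def _warm_theta(fit: IMFit) -> np.ndarray:
    m = fit.model
    return np.log10(np.array([m.n1_current, m.n2_current, m.n_ancestral,
                              m.t_split, max(m.m_recent, 1e-20),
                              max(m.m_old, 1e-20)]))


def scan_gene_flow(observed: Joint2dSFS, grid: np.ndarray, cfg: SearchConfig,
                   pair_id: str = "pair",
                   warm_cfg: SearchConfig | None = None,
                   initial_starts: list[np.ndarray] | None = None
                   ) -> GeneFlowScan:
    """One IM fit per epoch boundary on the grid.

    With ``warm_cfg``, the scan runs from the largest X (whose long recent
    epoch makes the global search most reliable) downwards, giving each
    subsequent fit the neighbouring solution as a warm start and using the
    lighter ``warm_cfg`` search settings — the demographic parameters vary
    slowly along the grid, so tracking the optimum is far cheaper than
    refinding it.  ``initial_starts`` seeds the first (reference) fit — for
    example with the solution from a previous replicate of a simulation
    study.  Excluded fits are carried with their flags; a failure at one X
    never aborts the scan.
    """
    grid = np.asarray(grid, dtype=float)
    order = np.argsort(grid)[::-1] if warm_cfg is not None \
        else np.arange(grid.size)
    fits: dict[int, IMFit] = {}
    warm: list[np.ndarray] = list(initial_starts or [])
    for step, gi in enumerate(order):
        x = float(grid[gi])
        use = cfg if (warm_cfg is None or step == 0) else warm_cfg
        try:
            fit = fit_im_pair(observed, x, use, extra_starts=warm)
            fits[gi] = fit
            # carry two hypotheses to the next X: the neighbouring solution
            # as-is, and a uniform-migration variant spreading the same
            # total number of migrants evenly over [0, t_split) — the
            # shrinking recent epoch otherwise tends to ratchet its weakly
            # identified rate upwards to conserve migrants
            theta = _warm_theta(fit)
            m = fit.model
            m_const = (m.m_recent * min(x, m.t_split)
                       + m.m_old * max(m.t_split - x, 0.0)) / m.t_split
            null = theta.copy()
            null[4] = null[5] = np.log10(max(m_const, 1e-20))
            warm = [theta, null]
        except Exception as exc:  # record, keep scanning
            model = _model_from_log10(
                np.array([np.mean(b) for b in cfg.log_bounds()]), x)
            fits[gi] = IMFit(model=model, x_break=x, loglik=float("-inf"),
                             excluded=True,
                             excluded_reason=f"fit failed: {exc}",
                             converged=False)
    return GeneFlowScan(pair_id=pair_id, x_grid=grid,
                        fits=[fits[i] for i in range(grid.size)])
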
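"""Synthetic inputs with known truth for every pipeline stage.

Everything the pipeline consumes can be generated here: pooled VCFs whose
allele frequencies come from the two-deme coalescent (so the demographic
truth is known exactly), BED masks and dirty records to exercise the site
filters, step-function Ne trajectories, and scan fixtures whose integrated
t2 values are exact running means of a known gene-flow schedule.  Every
generated artifact is accompanied by its truth, and generation is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coalescent import IMScenario, SampleConfig, sample_genealogy
from .deconv import T2Trajectory, running_mean
from .ne_traj import NeTrajectory

__all__ = [
    "DepthModel",
    "SyntheticTruth",
    "PooledDataset",
    "generate_pooled_dataset",
    "generate_ne_trajectories",
    "generate_scan_fixture",
    "schedule_from_model",
    "worked_example_fit",
]


@dataclass(frozen=True)
class DepthModel:
    """Pool sequencing depth distribution.

    Depths are rounded normal draws clipped into ``bounds`` (the [301, 599]
    window the filters keep).  In dirty mode a stated fraction of records
    instead draws depth outside the bounds, to exercise the depth filter.
    """

    mean: float = 450.0
    dispersion: float = 40.0
    bounds: tuple[int, int] = (301, 599)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        d = np.rint(rng.normal(self.mean, self.dispersion, size=n))
        return np.clip(d, self.bounds[0], self.bounds[1]).astype(int)

    def sample_out_of_bounds(self, rng: np.random.Generator, n: int
                             ) -> np.ndarray:
        low = rng.integers(max(self.bounds[0] - 250, 1), self.bounds[0],
                           size=n)
        high = rng.integers(self.bounds[1] + 1, self.bounds[1] + 300, size=n)
        return np.where(rng.random(n) < 0.5, low, high).astype(int)


@dataclass
class SyntheticTruth:
    """Generating parameters and per-item truth for a synthetic dataset."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "truth.txt", "w") as fh:
            fh.write(f"kind\t{self.kind}\nseed\t{self.seed}\n")
            for k, v in self.params.items():
                fh.write(f"{k}\t{v}\n")
        for name, df in self.tables.items():
            df.to_csv(out / f"truth_{name}.tsv", sep="\t", index=False)


@dataclass
class PooledDataset:
    vcf_paths: dict[str, Path]
    bed_path: Path
    coords_path: Path
    truth: SyntheticTruth
    n_chromosomes: int


_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID={chrom},length={length}>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""

_BASES = np.array(list("ACGT"))


def _site_configs(scenario: IMScenario, k: int, n_sites: int,
                  rng: np.random.Generator, seed: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Draw derived-allele counts (i, j) for ``n_sites`` variant sites.

    Windows of the scenario genome are simulated one genealogy at a time;
    per-branch-configuration mutation counts are Poisson with mean
    mu * L_window * branch length, until enough segregating sites accrue.
    """
    samples = SampleConfig(k, k)
    window_len = scenario.locus_length / scenario.windows_per_locus
    i_list: list[np.ndarray] = []
    j_list: list[np.ndarray] = []
    total = 0
    for w in range(100_000):
        tal = sample_genealogy(scenario.model, samples, (seed * 7919 + w) % 2**31)
        lam = scenario.mutation_rate * window_len * tal.branch
        lam[0, 0] = 0.0
        lam[k, k] = 0.0
        counts = rng.poisson(lam)
        ii, jj = np.nonzero(counts)
        reps = counts[ii, jj]
        i_list.append(np.repeat(ii, reps))
        j_list.append(np.repeat(jj, reps))
        total += int(reps.sum())
        if total >= n_sites:
            break
    i = np.concatenate(i_list)[:n_sites]
    j = np.concatenate(j_list)[:n_sites]
    perm = rng.permutation(i.size)
    return i[perm], j[perm]


def generate_pooled_dataset(scenario: IMScenario, out_dir,
                            n_sites: int = 2000,
                            depth: DepthModel = DepthModel(),
                            seed: int = 0,
                            pool_diploids: int = 50,
                            dirty: bool = False,
                            out_of_depth_frac: float = 0.1,
                            n_indels: int = 20,
                            n_multiallelic: int = 10,
                            n_masked: int = 30,
                            invariant_frac: float = 0.2,
                            chrom: str = "chr1",
                            coords: tuple[tuple[float, float], ...] = (
                                (56.10, 9.60), (56.45, 10.15)),
                            ) -> PooledDataset:
    """Generate a two-population pooled dataset with known truth.

    Allele frequencies come from the scenario's coalescent; each pool of
    ``pool_diploids`` diploids is read-sampled binomially around its true
    frequency at the drawn depth (equal individual contributions).  In dirty
    mode, out-of-depth records, indels (with flanking SNPs), multi-allelic
    records and BED-masked intervals are injected at stated counts so the
    filter tallies can be checked against the injected truth.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    k = 2 * pool_diploids

    n_var = int(round(n_sites * (1 - invariant_frac)))
    n_inv = n_sites - n_var
    ci, cj = _site_configs(scenario, k, n_var, rng, seed)
    p1 = np.concatenate([ci / k, np.zeros(n_inv)])
    p2 = np.concatenate([cj / k, np.zeros(n_inv)])
    order = rng.permutation(n_sites)
    p1, p2 = p1[order], p2[order]

    kinds = ["snp"] * n_sites
    if dirty:
        n_bad_depth = int(round(n_sites * out_of_depth_frac))
        extra = (["indel"] * n_indels + ["flank_snp"] * n_indels
                 + ["multi"] * n_multiallelic)
        kinds = (["bad_depth"] * n_bad_depth) + kinds
        rng.shuffle(kinds)
        kinds.extend(extra)  # appended; positions handled specially below
    n_total = len(kinds)

    # positions: random gaps; indel flank SNPs placed within 5 bp of indels
    gaps = rng.integers(20, 120, size=n_total)
    pos = np.cumsum(gaps) + 1000
    pos = pos.astype(int)
    if dirty:
        idx_indel = [i for i, t in enumerate(kinds) if t == "indel"]
        idx_flank = [i for i, t in enumerate(kinds) if t == "flank_snp"]
        for fi, ii in zip(idx_flank, idx_indel):
            pos[fi] = pos[ii] + int(rng.integers(1, 6))

    # true frequencies: coalescent draws go to the clean SNPs; injected
    # records (filtered out downstream) get arbitrary valid frequencies
    core = [i for i, t in enumerate(kinds) if t == "snp"]
    p1_map = np.empty(n_total)
    p2_map = np.empty(n_total)
    p1_map[core] = p1[:len(core)]
    p2_map[core] = p2[:len(core)]
    rest = [i for i, t in enumerate(kinds) if t != "snp"]
    p1_map[rest] = rng.uniform(0.1, 0.9, len(rest))
    p2_map[rest] = rng.uniform(0.1, 0.9, len(rest))

    refs = rng.choice(4, size=n_total)
    alts = (refs + rng.integers(1, 4, size=n_total)) % 4

    # BED mask over some clean SNPs (dirty mode)
    masked_idx: set[int] = set()
    bed_rows = []
    if dirty:
        clean_snps = [i for i, t in enumerate(kinds) if t == "snp"]
        masked_idx = set(rng.choice(clean_snps, size=min(n_masked,
                                                         len(clean_snps)),
                                    replace=False).tolist())
        for i in sorted(masked_idx):
            bed_rows.append((chrom, int(pos[i]) - 1, int(pos[i])))
    bed_path = out / "mask.bed"
    with open(bed_path, "w") as fh:
        for c, s, e in bed_rows:
            fh.write(f"{c}\t{s}\t{e}\n")

    pop_ids = [f"pop{i + 1}" for i in range(2)]
    vcf_paths: dict[str, Path] = {}
    site_rows = []
    sort_order = np.argsort(pos, kind="stable")
    for pop_i, pid in enumerate(pop_ids):
        p_true = p1_map if pop_i == 0 else p2_map
        depths = depth.sample(rng, n_total)
        bad = [i for i, t in enumerate(kinds) if t == "bad_depth"]
        if bad:
            depths[bad] = depth.sample_out_of_bounds(rng, len(bad))
        alt_reads = rng.binomial(depths, np.clip(p_true, 0, 1))
        lines = [_VCF_HEADER.format(chrom=chrom, length=int(pos.max() + 1000),
                                    sample=pid)]
        for i in sort_order:
            t = kinds[i]
            ref = _BASES[refs[i]]
            alt = _BASES[alts[i]]
            if t == "indel":
                ref = ref + "".join(rng.choice(_BASES, 2))
            d, a = int(depths[i]), int(alt_reads[i])
            if t == "multi":
                alt2 = _BASES[(alts[i] + 1) % 4]
                a2 = max(min(d - a, d // 4), 0)
                rec = (f"{chrom}\t{pos[i]}\t.\t{ref}\t{alt},{alt2}\t.\tPASS\t"
                       f"DP={d}\tDP:AD\t{d}:{d - a - a2},{a},{a2}")
            else:
                rec = (f"{chrom}\t{pos[i]}\t.\t{ref}\t{alt}\t.\tPASS\t"
                       f"DP={d}\tDP:AD\t{d}:{d - a},{a}")
            lines.append(rec + "\n")
        path = out / f"{pid}.vcf"
        with open(path, "w") as fh:
            fh.writelines(lines)
        vcf_paths[pid] = path

    for i in sort_order:
        site_rows.append({"chrom": chrom, "pos": int(pos[i]),
                          "kind": kinds[i], "masked": i in masked_idx,
                          "p1_true": p1_map[i], "p2_true": p2_map[i]})

    coords_path = out / "populations.tsv"
    pd.DataFrame({"id": pop_ids,
                  "lat": [c[0] for c in coords],
                  "lon": [c[1] for c in coords],
                  "vcf_path": [str(vcf_paths[p]) for p in pop_ids]}
                 ).to_csv(coords_path, sep="\t", index=False)

    m = scenario.model
    truth = SyntheticTruth(
        kind="pooled_dataset", seed=seed,
        params={"scenario_id": scenario.scenario_id,
                "n1": m.n1_current, "n2": m.n2_current,
                "n_ancestral": m.n_ancestral, "t_split": m.t_split,
                "m_recent": m.m_recent, "m_old": m.m_old,
                "mutation_rate": scenario.mutation_rate,
                "pool_diploids": pool_diploids, "dirty": dirty,
                "n_sites": n_sites},
        tables={"sites": pd.DataFrame(site_rows)})
    truth.write(out)
    return PooledDataset(vcf_paths=vcf_paths, bed_path=bed_path,
                         coords_path=coords_path, truth=truth,
                         n_chromosomes=k)


def generate_ne_trajectories(n_pops: int, shape: str = "postglacial",
                             seed: int = 0, noise_sd: float = 0.3,
                             out_dir=None
                             ) -> tuple[list[NeTrajectory], SyntheticTruth]:
    """Step-function Ne trajectories with a known common shape.

    Shapes: "postglacial" (sizes rise after the glacial retraction ~12 kyr
    ago, peak in the mid-Holocene, then drop toward the present — the
    pattern expected under recent habitat fragmentation), "constant", or
    "noisy" (postglacial shape with heavier noise).  Noise is multiplicative
    log-normal per population and step.
    """
    if n_pops < 1:
        raise ValueError("need at least one population")
    if shape not in ("postglacial", "constant", "noisy"):
        raise ValueError(f"unknown shape {shape!r}")
    rng = np.random.default_rng(seed)
    times = np.array([0, 200, 500, 1000, 2000, 4000, 8000, 12000,
                      20000, 50000], dtype=float)
    if shape == "constant":
        base = np.full(times.size, 1e5)
        sd = 0.0
    else:
        # recent drop <- mid-Holocene peak <- post-glacial rise <- glacial low
        base = np.array([2e4, 3e4, 8e4, 1.5e5, 2.5e5, 3e5, 2e5, 8e4,
                         3e4, 2e4])
        sd = noise_sd if shape == "postglacial" else 2 * noise_sd
    trajs = []
    for i in range(n_pops):
        noise = np.exp(rng.normal(0.0, sd, size=times.size)) if sd else 1.0
        trajs.append(NeTrajectory(f"pop{i + 1}", times, base * noise,
                                  time_unit="years"))
    truth = SyntheticTruth(kind="ne_trajectories", seed=seed,
                           params={"shape": shape, "noise_sd": sd,
                                   "n_pops": n_pops},
                           tables={"base": pd.DataFrame(
                               {"year": times, "ne": base})})
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for t in trajs:
            pd.DataFrame({"year": t.times, "ne": t.ne}).to_csv(
                out / f"{t.population_id}_ne.tsv", sep="\t", index=False)
        truth.write(out)
    return trajs, truth


def schedule_from_model(model, grid: np.ndarray) -> np.ndarray:
    """True per-interval gene-flow rates on a 100-generation grid.

    ``grid`` holds the interval right edges; the truth at interval n is the
    model's migration rate at the interval midpoint (exact for schedules
    aligned on the grid).
    """
    grid = np.asarray(grid, dtype=float)
    step = grid[0]
    return np.array([model.migration_rate(g - step / 2) for g in grid])


def generate_scan_fixture(schedule: np.ndarray, noise_sd: float,
                          n_pairs: int, seed: int,
                          grid: np.ndarray | None = None
                          ) -> tuple[list[T2Trajectory], SyntheticTruth]:
    """Per-pair t2 trajectories consistent with a known interval schedule.

    The noiseless t2 at X = n*100 is the running mean of the true interval
    rates 1..n; Gaussian noise (sd ``noise_sd``) is added per pair and
    clipped at zero.  With noise 0, deconvolution recovers the schedule
    exactly.
    """
    schedule = np.asarray(schedule, dtype=float)
    if grid is None:
        grid = 100.0 * np.arange(1, schedule.size + 1)
    t2_true = running_mean(schedule)
    rng = np.random.default_rng(seed)
    trajs = []
    for p in range(n_pairs):
        noise = rng.normal(0.0, noise_sd, size=t2_true.size) if noise_sd else 0.0
        trajs.append(T2Trajectory(grid.copy(),
                                  np.clip(t2_true + noise, 0.0, None),
                                  pair_id=f"pair{p + 1}"))
    truth = SyntheticTruth(kind="scan_fixture", seed=seed,
                           params={"noise_sd": noise_sd, "n_pairs": n_pairs},
                           tables={"schedule": pd.DataFrame(
                               {"x": grid, "act_true": schedule,
                                "t2_true": t2_true})})
    return trajs, truth


def worked_example_fit() -> tuple[np.ndarray, np.ndarray]:
    """A fitted t2 curve embedding the published worked example.

    The integrated rate is 0.003 out to generation 500 and 0.0035 out to
    generation 600; deconvolution therefore assigns rate 0.006 to the
    500-600 interval.  Returns (grid, fitted values).
    """
    grid = 100.0 * np.arange(1, 7)
    fitted = np.array([0.003, 0.003, 0.003, 0.003, 0.003, 0.0035])
    return grid, fitted
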
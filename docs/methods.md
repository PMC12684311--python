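# Methods

`gfchrono` reconstructs the recent history of gene flow and effective
population size for pool-sequenced populations in fragmented habitats.
This note records the models, the estimators, the numerical choices, and
what the desk-scale validation does and does not demonstrate.

## Pooled variant statistics

Pool-seq yields per-site allele frequencies for a pool of individuals
(here 50 diploids, N = 100 chromosomes), not genotypes.  Sites pass a
neutral-site filter before any statistic is computed, in this order:
records within 5 bp of an indel's reference footprint, indel records
themselves, sites with read depth outside the inclusive window
[301, 599], non-biallelic sites, and sites inside the genic/repetitive
BED mask.  The depth window protects rare-variant calls at the low end
and excludes collapsed repeats and organellar sequence at the high end.
Each rule reports how many records it removed, counting only records no
earlier rule had removed.

Per-site diversity is Nei's estimator with sample-size correction,
pi = 2 p (1-p) N/(N-1); population diversity is its mean over all
retained sites, monomorphic sites included in the denominator.  Pairwise
Fst follows the PoPoolation `fst_sliding` scheme: per shared site
pi_within = (pi_1 + pi_2)/2 and pi_total is the Nei diversity of the
mean frequency; genome-wide Fst is the ratio of sums
(sum pi_total − sum pi_within) / sum pi_total.  Both levels use the same
N-based correction factor, so two pools with identical frequencies give
exactly zero; sites monomorphic in both pools contribute nothing.
Negative per-site quantities are not clamped.

Allele counts are recovered from pool frequencies by rounding p·N to the
nearest integer; exact halves round toward the minor allele so the
half-count never inflates the minor bin.  The folded single-population
spectrum bins sites by minor-allele count, with an option to mask the
singleton bin (recommended for Stairway-Plot input, where singleton
calling error dominates).  The joint two-population spectrum orients each
site by the globally (pooled) minor allele; cells exactly at half
frequency stay unfolded.  Hypergeometric projection to smaller sample
sizes is the standard expected-downsampling matrix product, applied
independently per margin; projection conserves total mass and is used to
make fitting cheap.

Isolation by distance is an ordinary least-squares fit of pairwise Fst on
great-circle distance (haversine, mean Earth radius 6371.0088 km), with
all unordered pairs as independent observations and F on
(1, n_pairs − 2) degrees of freedom.  The UPGMA cladogram is scipy
average-linkage on the Fst matrix, emitted as Newick with tip depth equal
to half the merge height (ultrametric by construction); children are
ordered by each subtree's lexicographically smallest label so the output
is deterministic.

## The coalescent engine

Demography is the two-epoch isolation-with-migration (IM) picture: two
populations of diploid sizes N1, N2 that merged `t_split` generations ago
into an ancestor of size `n_ancestral`, exchanging migrants symmetrically
at rate `m_recent` on [0, X) and `m_old` on [X, t_split), or following an
arbitrary piecewise schedule; sizes may change exponentially since the
split.

The engine simulates the structured coalescent backwards in time.  Within
an epoch, waiting times for the competing processes — coalescence in each
deme at rate C(k,2)/(2N(t)), migration at m per lineage — are drawn
independently from their own hazards and capped at the epoch boundary;
exponentially changing sizes are handled by closed-form inversion of the
integrated hazard, never by time stepping.  Each lineage carries its
descendant configuration (i, j); its branch length is credited to that
cell once, at its death.  Under the infinite-sites model the expected
joint SFS cell is mu · L · E[branch length subtending (i, j)], estimated
as a Monte Carlo mean over replicate genealogies.  Replicate r draws from
an xorshift128+ stream seeded from (seed, r) via splitmix64, so a
likelihood evaluation is a deterministic function of (parameters, seed)
and replicate streams are shared across evaluations (common random
numbers).  The engine reproduces, within Monte Carlo error, the standard
single-deme expectations (E[TMRCA] = 2N for two samples, E[xi_i] =
theta/i, E[pi] = theta) and matches msprime's branch-length
configurations cell-by-cell in the two-deme case (test suite).

Recombination along a chromosome is approximated by cutting it into
freely recombining windows (default 150 windows of 100 kb for the
published 15 Mb chromosomes), each simulated as one non-recombining
genealogy: the expected SFS is insensitive to linkage, and genealogical
(evolutionary) variance is controlled by the number of windows.  Observed
spectra are Poisson draws around the expected cell means.

The five validation scenarios carry the published parameterization: two
populations of 11,250 diploids, split 45,000 generations ago, ancestor
202,500 diploids, six 15 Mb chromosomes, mutation and recombination rates
1e-8.  Scenario 1 has no gene flow; scenario 2 constant 6e-5; scenarios 3
and 4 add exponential decline/growth at 5e-5 per generation since the
split, i.e. a factor exp(±2.25) (an ~90% reduction, respectively an
~9.5-fold increase) relative to the size at the split.  The printed
current sizes of scenarios 3 and 4 (1,000 and 500,000 diploids) are kept
as annotations; the rate-and-duration specification is primary, and the
printed 500,000 is not consistent with it.  Scenario 5 steps gene flow
down toward the present: 6e-5 until 12,000 generations ago, then 5e-5,
4e-5, 3e-5 at 3,000-generation steps, 2e-5 from 3,000 to 600 generations
ago, and two published rates (1e-5 and 0) inside the final 600
generations; the unstated internal boundary is taken at 300 generations
ago.

`scale_scenario` rescales a scenario to desk size: sizes and times by a
factor c, migration/growth/mutation/recombination rates by 1/c.  This is
the standard coalescent-unit invariance — the genealogy distribution in
rescaled time and the expected SFS per base are unchanged — so a tenfold
smaller scenario carries the same signal at a hundredth the tree depth.

## IM fitting and the epoch-boundary scan

For a population pair, parameters (N1, N2, NAnc, t_split, m_recent,
m_old) are estimated from the folded minor-allele joint SFS by maximizing
a Poisson composite likelihood: cells are treated as independent Poisson
counts with the Monte Carlo expected SFS as means (floored at 1e-12); the
monomorphic (0,0) and fully fixed cells are masked, and a toggle
additionally masks the singleton cells.  Prior bounds: sizes 10–1e7
diploids, split time 10–1e5 generations, migration 1e-20–1e-1 per
generation.  The epoch boundary X is fixed per fit; fits whose estimated
split time falls below their X are flagged excluded (their "recent" epoch
would reach into the ancestral population).  The exclusion flag is an
exact biconditional with t_split < X.

The likelihood surface is hard: a narrow (t_split, migration) basin is
flanked by broad decoys (a recent split with no migration mimics an old
split with gene flow), and the Monte Carlo objective is jagged away from
the optimum.  The search therefore runs in phases on log10 parameters:

1. *Candidates.*  A moment-based anchor — current sizes from the private
   singleton cells (terminal branches see the recent local size, not
   ancestral polymorphism), ancestral size from a pooled Watterson count,
   split time from d_xy = 2 mu T + 4 N_anc mu — expanded into a grid of
   split-time multipliers, ancestral-size multipliers and migration
   levels, plus log-uniform draws over the full prior box and any warm
   starts.
2. *Stratified multi-start.*  A start's initial score is a poor predictor
   of the basin it descends into, so the best member of *each* migration
   group is briefly polished with bounded Nelder-Mead, rather than the
   overall top scorers.
3. *Full polish.*  The leaders get full Nelder-Mead with simplex
   restarts.
4. *Low-noise selection and ridge polish.*  Finalists are compared at a
   multiple of the base replicate count (their separation is often below
   the base objective's jitter), and the winner is optionally pushed
   along the t-versus-m likelihood ridge with Powell line searches on the
   low-noise objective — kept only if the base objective agrees it
   improved.

A scan refits the pair at every X on a grid (the full design is 100 to
14,000 by 100, i.e. 140 fits).  With a light tracking configuration the
scan runs from the largest X downwards, warm-starting each fit from its
neighbour's solution plus a uniform-migration variant that spreads the
same total number of migrants evenly over [0, t_split) — without that
second hypothesis the weakly identified recent rate tends to ratchet
upwards as its epoch shrinks.

Known bias: on the composite-likelihood ridge, split time is pulled up
and migration down (or vice versa) in compensation; recovery on
noise-free spectra at 8 chromosomes per deme lands within a factor ~1.5
of the truth for sizes and split time and well within a factor 3 for the
recent migration rate, and a truth of zero migration is recovered below
1e-6.  This mirrors the known behaviour of SFS-based IM estimation
(gene flow underestimated, sizes overestimated).

## Temporal deconvolution of gene flow

t2(X) estimates the migration rate *integrated* from the present to X,
i.e. the running mean of the actual per-interval rates Act over the
n = X/step intervals it spans.  The inversion is exact and iterative:
Act_1 = Fit_step, then Act_n = Fit_{n·step} · n − sum(Act_1..Act_{n−1}).
The package verifies the running-mean identity of every output to
1e-10 and the full round trip (running mean then deconvolve) to 1e-12.
Because the inversion differentiates the fitted curve, it amplifies
wiggle; t2 estimates are smoothed with a cubic smoothing spline before
inversion.  By default the penalty is chosen by generalized
cross-validation; a manual override exists and should be used whenever
the grid is short (GCV under-penalizes on ~10 points).  Negative
deconvolved rates are preserved in the raw output and clamped to zero
only in a separate display column.  Excluded X values are omitted from
the spline fit but predicted, keeping the deconvolution grid contiguous.

Uncertainty comes from a pair-level bootstrap: population pairs are
resampled with replacement, per replicate the trajectories are averaged
across the sampled pairs (average, then smooth, then deconvolve — the
same order as the point estimate), and the band is the empirical
2.5%/97.5% quantile of the per-interval rates.  The reference design uses
10,000 replicates; tests use fewer.

## Ne-trajectory aggregation

Stairway-Plot-style step functions (time, median Ne) are evaluated on a
common log-spaced grid of years (default 200 points, 10 to 50,000 years),
z-transformed per population (sample mean 0, sd 1 across the grid, so
absolute scale and haploid/diploid conventions drop out), and averaged;
a population-level bootstrap gives the 95% band.  Step functions are
right-continuous; an exact breakpoint takes the younger step's value, and
times past the last breakpoint take the last value.  Time scaling assumes
3 generations per year (a 4-month generation) and a mutation rate of
2.5e-9 per base per generation; generation counts convert to whole years
by floor division, so 14,000 generations is 4,666 years.

## Synthetic data

Every input the pipeline consumes can be generated with known truth.
Pooled datasets draw site frequencies from the coalescent engine at
k = 100 chromosomes per pool, then sample reads binomially around the
true frequency at depths from a clipped-normal depth model (equal
individual contributions; an unequal-contribution mode exists for
robustness checks).  Dirty mode injects out-of-depth records, indels with
flanking SNPs, multi-allelic records and BED-masked intervals at stated
counts, so filter tallies can be checked against the injected truth
exactly.  VCF output is deterministic text (byte-identical under a fixed
seed) and round-trips through the pysam-based reader.  Ne-trajectory
generation produces rise-then-fall (post-glacial expansion followed by a
recent drop), constant, or heavily noisy shapes with multiplicative
log-normal noise.  Scan fixtures build t2 series as exact running means
of a chosen schedule plus Gaussian noise, so the deconvolution can be
tested against its own inverse.

## Desk-scale validation studies

Parameter recovery runs single fits on noise-free expected spectra (the
Monte Carlo expectation at the truth, 20,000 genealogies, a seed
unrelated to the search's) at 8 chromosomes per deme over 10 Mb.

The scenario-5 trend study asks the qualitative question the estimator
exists for: is a stepwise *decline* of gene flow toward the present
recovered as deconvolved recent rates below old rates?  Study conditions:
the tenfold-rescaled scenario 5; 200 loci of 50 kb (10 kb windows); 8
chromosomes per deme; scan grid X = 100..900 by 100; two independent
pairs per replicate whose t2 trajectories are averaged before smoothing
(the estimator is defined on the cross-pair average — a single pair was
never the design); smoothing with a large manual penalty (near-linear
fit), because ten grid points cannot support GCV and the inversion
amplifies under-smoothed scatter; twenty seeded replicates.  Replicates
warm-start their reference fit from the previous replicate's solution — a
variance-reduction device that leaves each replicate's data and
likelihood untouched.  At these conditions the recent-below-old contrast
is recovered in ≥90% of replicates.

What this does and does not show: the mini study demonstrates that the
nested-estimate deconvolution recovers the *direction and rough timing*
of a gene-flow change from joint SFS data at desk scale.  It does not
demonstrate rate-level accuracy of the per-interval estimates at these
sample sizes (8 chromosomes per deme resolves the partition of migration
between adjacent epochs only weakly — the real design uses 100
chromosomes per pool, hundreds of population pairs, and far more
likelihood simulations), nor robustness to pool-seq depth noise, which
enters upstream of the SFS.

## Numerical and degenerate-input conventions

Expected-SFS cells are floored at 1e-12 inside the likelihood; fits
pinned at a prior bound are flagged `at_bound`; a scan failure at one X
is recorded and never aborts the scan.  Fst is NaN when no shared site is
polymorphic; diversity of an empty table, z-transform of a constant
vector, smoothing with fewer than four surviving points, and upward SFS
projection all raise errors rather than guessing.  All stochastic
operations take explicit integer seeds and are reproducible to the byte.
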
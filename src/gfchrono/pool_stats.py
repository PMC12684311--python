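"""Pooled-sequencing variant statistics.

Pool-seq yields per-site allele frequencies for a whole population pool
(here 50 diploids, i.e. N = 100 chromosomes) rather than genotypes.  This
module reads pooled VCFs, applies the neutral-site filters (indel flanks,
depth window, biallelic-only, genic/repeat masks), and computes the
frequency-based summary statistics used for fragmented-population analysis:
Nei's sample-size-corrected nucleotide diversity, PoPoolation-style pairwise
Fst, folded and joint site frequency spectra, isolation-by-distance
regression, and a UPGMA cladogram of the Fst matrix.
"""

from __future__ import annotations

import math
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import pysam
import statsmodels.api as sm
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .sfs import FoldedSFS, Joint2dSFS, fold_joint_sfs

__all__ = [
    "PooledSiteRecord",
    "PooledVariantTable",
    "SiteFilterConfig",
    "FstMatrix",
    "IBDResult",
    "parse_pooled_vcf",
    "read_bed_mask",
    "filter_sites",
    "nei_pi_site",
    "population_pi",
    "pairwise_fst",
    "fst_matrix",
    "folded_sfs",
    "joint_2dsfs",
    "ibd_regression",
    "haversine_km",
    "upgma_tree",
]

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius

_COLUMNS = ["chrom", "pos", "ref_allele", "alt_allele", "depth",
            "alt_freq", "is_indel", "n_alleles"]


class PooledSiteRecord(NamedTuple):
    chrom: str
    pos: int          # 1-based
    ref_allele: str
    alt_allele: str
    depth: int
    alt_freq: float   # alternate-allele frequency in [0, 1]
    is_indel: bool
    n_alleles: int


@dataclass
class PooledVariantTable:
    """Per-site records for one population pool.

    ``sites`` is a DataFrame with one row per VCF record, sorted by
    (chrom, pos).  ``n_chromosomes`` is the pool size in chromosomes
    (50 diploids per pool gives 100).
    """

    population_id: str
    n_chromosomes: int
    sites: pd.DataFrame
    coordinates: tuple[float, float] | None = None  # (lat, lon), decimal degrees

    def __post_init__(self) -> None:
        if self.n_chromosomes < 2:
            raise ValueError("a pool needs at least 2 chromosomes")
        df = self.sites.reset_index(drop=True)
        if list(df.columns) != _COLUMNS:
            df = df[_COLUMNS]
        if len(df):
            if (df["alt_freq"].min() < 0) or (df["alt_freq"].max() > 1):
                raise ValueError("alt_freq must lie in [0, 1]")
            if df["pos"].min() < 1 or df["depth"].min() < 0:
                raise ValueError("pos must be >= 1 and depth >= 0")
            df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        self.sites = df

    def __len__(self) -> int:
        return len(self.sites)

    def records(self) -> Iterable[PooledSiteRecord]:
        for row in self.sites.itertuples(index=False):
            yield PooledSiteRecord(*row)


@dataclass
class SiteFilterConfig:
    """Neutral-site filter settings.

    Defaults follow the pooled resequencing protocol: 5 bp flanks around
    indels, a depth window of [301, 599] reads (inclusive; low-coverage sites
    cannot resolve rare variants, high-coverage sites are dominated by
    organellar/repeat mappings), biallelic SNPs only, and a mask of genic and
    repetitive intervals (BED, 0-based half-open).
    """

    indel_flank_bp: int = 5
    min_depth: int = 301
    max_depth: int = 599
    biallelic_only: bool = True
    mask_regions: Sequence[tuple[str, int, int]] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must not exceed max_depth")
        if self.indel_flank_bp < 0:
            raise ValueError("indel_flank_bp must be non-negative")


@dataclass
class FstMatrix:
    population_ids: list[str]
    values: np.ndarray                 # symmetric, zero diagonal
    n_sites: np.ndarray | None = None  # retained sites per pair

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.population_ids)
        if self.values.shape != (k, k):
            raise ValueError("Fst matrix shape must match population count")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("Fst matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.population_ids,
                            columns=self.population_ids)


class IBDResult(NamedTuple):
    slope: float
    intercept: float
    r2_adj: float
    f_stat: float
    df_num: int
    df_den: int
    p_value: float


# ---------------------------------------------------------------------------
# VCF input


def parse_pooled_vcf(source, pool_n: int, population_id: str = "",
                     coordinates: tuple[float, float] | None = None
                     ) -> PooledVariantTable:
    """Read a pooled VCF into a :class:`PooledVariantTable`.

    ``source`` is a path to a VCF 4.x file or a file-like/str of VCF text.
    The alternate-allele frequency is taken from the first sample's AD field
    when present, otherwise from freebayes-style INFO AO/RO counts; total
    depth from FORMAT/INFO DP or the allele-depth sum.  Multi-allelic records
    are kept (``n_alleles`` recorded) so the filter stage can drop them.
    """
    tmp_path = None
    if hasattr(source, "read"):
        source = source.read()
    if isinstance(source, str) and "\n" in source:
        fd, tmp_path = tempfile.mkstemp(suffix=".vcf")
        with os.fdopen(fd, "w") as fh:
            fh.write(source)
        path = tmp_path
    else:
        path = os.fspath(source)
    try:
        rows = _parse_vcf_file(path)
    finally:
        if tmp_path is not None:
            os.unlink(tmp_path)
    df = pd.DataFrame(rows, columns=_COLUMNS)
    return PooledVariantTable(population_id or os.path.basename(str(path)),
                              pool_n, df, coordinates)


def _parse_vcf_file(path: str) -> list[tuple]:
    try:
        vcf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise ValueError(f"malformed VCF {path!r}: {exc}") from exc
    rows: list[tuple] = []
    for idx, rec in enumerate(vcf, start=1):
        try:
            rows.append(_parse_record(rec))
        except Exception as exc:
            raise ValueError(
                f"malformed VCF record #{idx} at "
                f"{rec.chrom}:{rec.pos}: {exc}") from exc
    return rows


def _parse_record(rec) -> tuple:
    alts = rec.alts or ()
    n_alleles = 1 + len(alts)
    alt = alts[0] if alts else rec.ref
    is_indel = any(len(a) != len(rec.ref) for a in alts)

    ad = None
    if rec.samples:
        s = rec.samples[0]
        ad = s.get("AD") if "AD" in s else None
    if ad is not None and ad[0] is not None:
        ad = [int(a) for a in ad]
        depth = sum(ad)
        alt_count = ad[1] if len(ad) > 1 else 0
    elif "AO" in rec.info and "RO" in rec.info:
        ao = rec.info["AO"]
        ao = ao[0] if isinstance(ao, tuple) else ao
        ro = int(rec.info["RO"])
        depth = ro + sum(int(a) for a in (rec.info["AO"]
                         if isinstance(rec.info["AO"], tuple)
                         else (rec.info["AO"],)))
        alt_count = int(ao)
    else:
        raise ValueError("no AD or AO/RO allele-depth field")

    dp = None
    if rec.samples and "DP" in rec.samples[0] and rec.samples[0]["DP"] is not None:
        dp = int(rec.samples[0]["DP"])
    elif "DP" in rec.info:
        dp = int(rec.info["DP"])
    depth = dp if dp is not None else depth
    if depth <= 0:
        alt_freq = 0.0
    else:
        alt_freq = alt_count / (sum(ad) if ad is not None else depth)
        alt_freq = min(max(alt_freq, 0.0), 1.0)
    return (rec.chrom, rec.pos, rec.ref, alt, depth, alt_freq,
            bool(is_indel), n_alleles)


def read_bed_mask(path) -> list[tuple[str, int, int]]:
    """Read BED intervals (0-based half-open) for use as ``mask_regions``."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append((chrom, int(start), int(end)))
    return out


# ---------------------------------------------------------------------------
# Filtering


def filter_sites(table: PooledVariantTable, cfg: SiteFilterConfig
                 ) -> tuple[PooledVariantTable, dict[str, int]]:
    """Apply the neutral-site filters; returns survivors and per-rule tallies.

    Rules are applied in order, each counting only records that earlier rules
    have not already removed: (1) sites within ``indel_flank_bp`` of an indel
    record, (2) indel records themselves, (3) depth outside
    [min_depth, max_depth], (4) non-biallelic sites, (5) sites inside the
    BED mask.
    """
    df = table.sites
    keep = np.ones(len(df), dtype=bool)
    tally = {"indel_flank": 0, "indel": 0, "depth": 0, "not_biallelic": 0,
             "masked": 0}

    pos = df["pos"].to_numpy()
    chroms = df["chrom"].to_numpy()

    # 1) indel flanks: any site within flank bp of an indel's REF footprint
    flank_hit = np.zeros(len(df), dtype=bool)
    indel_mask = df["is_indel"].to_numpy()
    if indel_mask.any() and cfg.indel_flank_bp >= 0:
        ref_len = df["ref_allele"].str.len().to_numpy()
        for chrom in np.unique(chroms[indel_mask]):
            on_chrom = chroms == chrom
            idl = on_chrom & indel_mask
            starts = pos[idl] - cfg.indel_flank_bp
            ends = pos[idl] + ref_len[idl] - 1 + cfg.indel_flank_bp
            p = pos[on_chrom]
            hit = np.zeros(p.size, dtype=bool)
            for s, e in zip(starts, ends):
                hit |= (p >= s) & (p <= e)
            flank_hit[on_chrom] = hit
    flank_hit &= ~indel_mask  # indels counted by their own rule
    tally["indel_flank"] = int((keep & flank_hit).sum())
    keep &= ~flank_hit

    # 2) indel records
    tally["indel"] = int((keep & indel_mask).sum())
    keep &= ~indel_mask

    # 3) depth window (inclusive bounds)
    depth = df["depth"].to_numpy()
    bad_depth = (depth < cfg.min_depth) | (depth > cfg.max_depth)
    tally["depth"] = int((keep & bad_depth).sum())
    keep &= ~bad_depth

    # 4) biallelic only (n_alleles <= 2; monomorphic sites pass)
    if cfg.biallelic_only:
        multi = df["n_alleles"].to_numpy() > 2
        tally["not_biallelic"] = int((keep & multi).sum())
        keep &= ~multi

    # 5) mask regions (BED half-open on 0-based coords; VCF pos is 1-based)
    if len(cfg.mask_regions):
        masked = np.zeros(len(df), dtype=bool)
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in cfg.mask_regions:
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivals in by_chrom.items():
            on_chrom = chroms == chrom
            p0 = pos[on_chrom] - 1  # to 0-based
            hit = np.zeros(p0.size, dtype=bool)
            for s, e in ivals:
                hit |= (p0 >= s) & (p0 < e)
            masked[on_chrom] |= hit
        tally["masked"] = int((keep & masked).sum())
        keep &= ~masked

    out = PooledVariantTable(table.population_id, table.n_chromosomes,
                             df[keep], table.coordinates)
    return out, tally


# ---------------------------------------------------------------------------
# Diversity and differentiation


def nei_pi_site(p: float | np.ndarray, n: int) -> float | np.ndarray:
    """Nei's per-site nucleotide diversity with sample-size correction.

    pi = 2 * p * (1 - p) * n / (n - 1), where p and 1-p are the two allele
    frequencies and n the number of chromosomes in the pool.
    """
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    p = np.asarray(p, dtype=float) if not np.isscalar(p) else p
    return 2.0 * p * (1.0 - p) * n / (n - 1.0)


def population_pi(table: PooledVariantTable) -> float:
    """Mean Nei diversity over all retained sites (variable and invariant).

    The table must already be filtered; monomorphic sites stay in the
    denominator, which is what makes the mean a per-site diversity.
    """
    if len(table) == 0:
        raise ValueError("empty table: cannot compute diversity")
    p = table.sites["alt_freq"].to_numpy()
    return float(np.mean(nei_pi_site(p, table.n_chromosomes)))


def _shared_freqs(a: PooledVariantTable, b: PooledVariantTable
                  ) -> tuple[np.ndarray, np.ndarray]:
    merged = a.sites.merge(b.sites, on=["chrom", "pos"], suffixes=("_a", "_b"))
    if len(merged) == 0:
        raise ValueError(
            f"no shared sites between {a.population_id} and {b.population_id}")
    return (merged["alt_freq_a"].to_numpy(), merged["alt_freq_b"].to_numpy())


def pairwise_fst(a: PooledVariantTable, b: PooledVariantTable) -> float:
    """Genome-wide pairwise Fst in the PoPoolation fst_sliding style.

    Per shared site, pi_within = (pi_a + pi_b) / 2 and pi_total is the Nei
    diversity of the mean frequency (p_a + p_b) / 2, with the same n-based
    sample-size correction at both levels so that identical pools give
    exactly zero; the genome-wide value is the ratio of sums
    (sum pi_total - sum pi_within) / sum pi_total.  Sites where pi_total = 0
    (both pools fixed for the same allele) contribute nothing.  Returns NaN
    if no site is polymorphic.
    """
    if a.n_chromosomes != b.n_chromosomes:
        raise ValueError("pools must have equal chromosome counts")
    pa, pb = _shared_freqs(a, b)
    n = a.n_chromosomes
    pi_within = 0.5 * (nei_pi_site(pa, n) + nei_pi_site(pb, n))
    pi_total = nei_pi_site(0.5 * (pa + pb), n)
    denom = pi_total.sum()
    if denom == 0:
        return float("nan")
    return float((denom - pi_within.sum()) / denom)


def fst_matrix(tables: Sequence[PooledVariantTable]) -> FstMatrix:
    """All pairwise Fst values for a set of filtered pools."""
    k = len(tables)
    vals = np.zeros((k, k))
    nsites = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            vals[i, j] = vals[j, i] = pairwise_fst(tables[i], tables[j])
            pa, _ = _shared_freqs(tables[i], tables[j])
            nsites[i, j] = nsites[j, i] = pa.size
    return FstMatrix([t.population_id for t in tables], vals, nsites)


# ---------------------------------------------------------------------------
# Site frequency spectra


def _round_half_down(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer; exact halves round down (toward the minor
    orientation, so a .5 allele count never inflates the minor-allele bin)."""
    return np.ceil(np.asarray(x) - 0.5).astype(int)


def folded_sfs(table: PooledVariantTable, exclude_singletons: bool = False
               ) -> FoldedSFS:
    """Folded SFS from pool frequencies: minor count = round(min(p, 1-p)*n)."""
    n = table.n_chromosomes
    p = table.sites["alt_freq"].to_numpy()
    minor = _round_half_down(np.minimum(p, 1.0 - p) * n)
    counts = np.bincount(minor, minlength=n // 2 + 1).astype(float)
    masked = 0.0
    if exclude_singletons:
        masked = counts[1]
        counts[1] = np.nan
    return FoldedSFS(n, counts, singletons_excluded=exclude_singletons,
                     n_masked_singletons=masked)


def joint_2dsfs(a: PooledVariantTable, b: PooledVariantTable,
                fold: bool = True) -> Joint2dSFS:
    """Joint SFS over shared sites; counts recovered as round(p * n) per pool.

    Exact-half allele counts round toward the minor allele: down when ALT is
    the globally minor allele at the site, up otherwise.  With ``fold`` each
    site is oriented by the globally minor allele.
    """
    pa, pb = _shared_freqs(a, b)
    n1, n2 = a.n_chromosomes, b.n_chromosomes
    raw1, raw2 = pa * n1, pb * n2
    alt_minor = (raw1 + raw2) <= 0.5 * (n1 + n2)
    c1 = np.where(alt_minor, np.ceil(raw1 - 0.5), np.floor(raw1 + 0.5)).astype(int)
    c2 = np.where(alt_minor, np.ceil(raw2 - 0.5), np.floor(raw2 + 0.5)).astype(int)
    counts = np.zeros((n1 + 1, n2 + 1))
    np.add.at(counts, (c1, c2), 1.0)
    sfs = Joint2dSFS(n1, n2, counts, folded_minor=False,
                     population_ids=(a.population_id, b.population_id))
    return fold_joint_sfs(sfs) if fold else sfs


# ---------------------------------------------------------------------------
# Isolation by distance and clustering


def haversine_km(lat1, lon1, lat2, lon2, radius_km: float = EARTH_RADIUS_KM
                 ) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * radius_km * math.asin(math.sqrt(h))


def ibd_regression(fst: FstMatrix, coords: pd.DataFrame) -> IBDResult:
    """Ordinary least squares of pairwise Fst on great-circle distance.

    ``coords`` needs columns id, lat, lon.  All unordered population pairs
    enter as independent observations (as in a plain lm fit); the F statistic
    has (1, n_pairs - 2) degrees of freedom.
    """
    ids = fst.population_ids
    if len(ids) < 3:
        raise ValueError("need at least 3 populations for IBD regression")
    cmap = {r["id"]: (float(r["lat"]), float(r["lon"]))
            for _, r in coords.iterrows()}
    dist, y = [], []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            la1, lo1 = cmap[ids[i]]
            la2, lo2 = cmap[ids[j]]
            dist.append(haversine_km(la1, lo1, la2, lo2))
            y.append(fst.values[i, j])
    dist = np.asarray(dist)
    if np.allclose(dist, dist[0]):
        raise ValueError("degenerate design: all pairwise distances equal")
    model = sm.OLS(np.asarray(y), sm.add_constant(dist)).fit()
    return IBDResult(slope=float(model.params[1]),
                     intercept=float(model.params[0]),
                     r2_adj=float(model.rsquared_adj),
                     f_stat=float(model.fvalue),
                     df_num=int(model.df_model),
                     df_den=int(model.df_resid),
                     p_value=float(model.f_pvalue))


def upgma_tree(fst: FstMatrix) -> str:
    """UPGMA (average-linkage) cladogram of the Fst matrix, as Newick text.

    Branch lengths place every tip at equal depth (ultrametric); merge ties
    resolve by lexicographic population order.
    """
    order = np.argsort(fst.population_ids)
    ids = [fst.population_ids[i] for i in order]
    mat = fst.values[np.ix_(order, order)]
    if np.isnan(mat).any():
        raise ValueError("Fst matrix contains missing values")
    if len(ids) < 2:
        raise ValueError("need at least 2 populations")
    if len(ids) == 2:
        h = mat[0, 1] / 2
        return f"({ids[0]}:{h:.10g},{ids[1]}:{h:.10g});"
    z = linkage(squareform(mat, checks=False), method="average")

    heights = {i: 0.0 for i in range(len(ids))}
    newick = {i: ids[i] for i in range(len(ids))}
    min_leaf = {i: ids[i] for i in range(len(ids))}
    for step, (a, b, dist, _) in enumerate(z):
        a, b = int(a), int(b)
        if min_leaf[b] < min_leaf[a]:  # children in lexicographic order
            a, b = b, a
        node = len(ids) + step
        h = dist / 2
        la, lb = h - heights[a], h - heights[b]
        newick[node] = f"({newick[a]}:{la:.10g},{newick[b]}:{lb:.10g})"
        heights[node] = h
        min_leaf[node] = min(min_leaf[a], min_leaf[b])
    return newick[len(ids) + len(z) - 1] + ";"
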
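"""Site-frequency-spectrum containers shared across the pipeline.

Two containers are used throughout: :class:`FoldedSFS` (one population,
indexed by minor-allele count) and :class:`Joint2dSFS` (a population pair,
an ``(n1+1) x (n2+1)`` matrix indexed by allele counts in each pool).
Both carry their chromosome sample sizes so downstream code never has to
guess the folding axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = ["FoldedSFS", "Joint2dSFS", "fold_joint_sfs", "project_sfs"]


@dataclass
class FoldedSFS:
    """Folded (minor-allele) site frequency spectrum for one population.

    ``counts[c]`` is the number of sites whose minor-allele count is ``c``;
    the vector has length ``n_chromosomes // 2 + 1``.  When singletons are
    excluded (as recommended for Stairway-Plot input) bin 1 is set to NaN
    rather than zero so the exclusion is visible, and the number of masked
    sites is kept in ``n_masked_singletons``.
    """

    n_chromosomes: int
    counts: np.ndarray
    singletons_excluded: bool = False
    n_masked_singletons: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        expect = self.n_chromosomes // 2 + 1
        if self.counts.shape != (expect,):
            raise ValueError(
                f"folded SFS for n={self.n_chromosomes} needs {expect} bins, "
                f"got {self.counts.shape}"
            )

    @property
    def n_sites(self) -> float:
        """Number of contributing sites (masked singleton bin included)."""
        return float(np.nansum(self.counts) + self.n_masked_singletons)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"minor_count": np.arange(self.counts.size), "n_sites": self.counts}
        )


@dataclass
class Joint2dSFS:
    """Joint SFS for a population pair.

    ``counts[i, j]`` is the number (or expected number) of sites with allele
    count ``i`` in population 1 and ``j`` in population 2.  ``folded_minor``
    records whether each site was oriented by the globally minor allele; in
    that case only cells with ``i/n1 + j/n2`` on the minor side carry mass.
    """

    n1: int
    n2: int
    counts: np.ndarray
    folded_minor: bool = False
    population_ids: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.n1 + 1, self.n2 + 1):
            raise ValueError(
                f"joint SFS needs shape {(self.n1 + 1, self.n2 + 1)}, "
                f"got {self.counts.shape}"
            )
        if np.any(self.counts < -1e-12):
            raise ValueError("joint SFS cells must be non-negative")

    @property
    def n_sites(self) -> float:
        return float(self.counts.sum())

    def folded(self) -> "Joint2dSFS":
        return fold_joint_sfs(self)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.counts).to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_tsv(cls, path, folded_minor: bool = False) -> "Joint2dSFS":
        m = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
        return cls(m.shape[0] - 1, m.shape[1] - 1, m, folded_minor=folded_minor)


def fold_joint_sfs(sfs: Joint2dSFS) -> Joint2dSFS:
    """Fold a joint SFS by the globally minor allele.

    A cell ``(i, j)`` whose pooled frequency ``(i + j) / (n1 + n2)`` exceeds
    one half is added to its complement ``(n1 - i, n2 - j)``; cells exactly at
    one half stay where they are.
    """
    if sfs.folded_minor:
        return Joint2dSFS(sfs.n1, sfs.n2, sfs.counts.copy(), folded_minor=True,
                          population_ids=sfs.population_ids)
    n1, n2 = sfs.n1, sfs.n2
    out = np.zeros_like(sfs.counts)
    i_idx, j_idx = np.meshgrid(np.arange(n1 + 1), np.arange(n2 + 1), indexing="ij")
    major = 2 * (i_idx + j_idx) > (n1 + n2)
    out[~major] += sfs.counts[~major]
    src_i, src_j = i_idx[major], j_idx[major]
    np.add.at(out, (n1 - src_i, n2 - src_j), sfs.counts[major])
    return Joint2dSFS(n1, n2, out, folded_minor=True,
                      population_ids=sfs.population_ids)


def _projection_matrix(n: int, m: int) -> np.ndarray:
    """Row-stochastic hypergeometric down-sampling matrix P[i, i']."""
    i = np.arange(n + 1)[:, None]
    iprime = np.arange(m + 1)[None, :]
    return hypergeom.pmf(iprime, n, i, m)


def project_sfs(sfs: Joint2dSFS, m1: int, m2: int) -> Joint2dSFS:
    """Hypergeometric down-projection of a joint SFS to smaller sample sizes.

    Each margin is projected independently: a site with ``i`` copies among
    ``n`` chromosomes contributes hypergeometric expected mass to counts
    ``0..m`` among a subsample of ``m``.  Total mass is conserved.  Folding
    does not survive projection, so the result is returned unfolded (re-fold
    with :func:`fold_joint_sfs` if needed).
    """
    if m1 < 2 or m2 < 2:
        raise ValueError("projected sample sizes must be at least 2")
    if m1 > sfs.n1 or m2 > sfs.n2:
        raise ValueError("can only project downwards")
    p1 = _projection_matrix(sfs.n1, m1)
    p2 = _projection_matrix(sfs.n2, m2)
    out = p1.T @ sfs.counts @ p2
    return Joint2dSFS(m1, m2, out, folded_minor=False,
                      population_ids=sfs.population_ids)
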
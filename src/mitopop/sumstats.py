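"""Diversity summary statistics for aligned mtDNA sequences.

Computes the classical single-locus summaries: number of segregating sites
S, haplotype number Nhap, haplotype diversity Hd (Nei 1987) with its
sampling standard error, nucleotide diversity pi per site with Nei & Li's
sampling standard deviation, and the mean number of pairwise nucleotide
differences k.  The pairwise-difference histogram (mismatch spectrum) is
exposed for reuse by the demographic-expansion machinery.

All statistics operate on the columns retained under a site policy
(complete deletion of gap/N columns by default, matching DnaSP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .iohap import COMPLETE_DELETION, Alignment

__all__ = [
    "DiversitySummary",
    "PairwiseSpectrum",
    "SampleSizeError",
    "segregating_sites",
    "haplotype_diversity",
    "pairwise_spectrum",
    "pairwise_differences",
    "nucleotide_diversity",
    "diversity_summary",
]


class SampleSizeError(ValueError):
    """Raised when a statistic is requested for too few sequences."""


@dataclass(frozen=True)
class PairwiseSpectrum:
    """Histogram of pairwise nucleotide differences.

    ``counts[i]`` is the number of unordered sequence pairs differing at
    exactly ``i`` retained sites; the entries sum to n(n-1)/2.
    """

    counts: tuple[int, ...]
    n: int

    @property
    def total_pairs(self) -> int:
        return self.n * (self.n - 1) // 2

    @property
    def mean(self) -> float:
        c = np.asarray(self.counts, dtype=float)
        return float(np.dot(np.arange(len(c)), c) / c.sum())

    def relative(self) -> np.ndarray:
        c = np.asarray(self.counts, dtype=float)
        return c / c.sum()


@dataclass(frozen=True)
class DiversitySummary:
    n: int
    S: int
    Nhap: int
    Hd: float
    Hd_se: float
    pi: float
    pi_sd: float
    k: float
    sites: int  # retained sites


def _require_n(n: int, minimum: int = 2) -> None:
    if n < minimum:
        raise SampleSizeError(f"need at least {minimum} sequences, got {n}")


def segregating_sites(
    alignment: Alignment, site_policy: str = COMPLETE_DELETION
) -> int:
    """Number of retained columns with at least two nucleotide states."""
    _require_n(alignment.n)
    mat = alignment.retained_matrix(site_policy)
    return int((mat != mat[0]).any(axis=0).sum())


def haplotype_diversity(counts, n: int | None = None) -> tuple[float, float]:
    """Haplotype (gene) diversity Hd and its standard error.

    Hd = n (1 - sum p_i^2) / (n - 1)  with p_i the haplotype frequencies.
    The standard error follows Nei (1987, eq. 8.12):

    V(Hd) = 2/(n(n-1)) * {2(n-2) [sum p_i^3 - (sum p_i^2)^2] + sum p_i^2
            - (sum p_i^2)^2}
    """
    counts = [int(c) for c in counts]
    if any(c < 1 for c in counts):
        raise ValueError("haplotype counts must be positive")
    total = sum(counts)
    if n is None:
        n = total
    elif n != total:
        raise ValueError(f"counts sum to {total}, but n={n} declared")
    _require_n(n)
    p = np.asarray(counts, dtype=float) / n
    sum2 = float(np.sum(p**2))
    sum3 = float(np.sum(p**3))
    hd = n * (1.0 - sum2) / (n - 1)
    var = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (sum3 - sum2**2) + sum2 - sum2**2
    )
    return hd, float(np.sqrt(max(var, 0.0)))


def pairwise_differences(
    alignment: Alignment, site_policy: str = COMPLETE_DELETION
) -> np.ndarray:
    """Condensed vector of Hamming differences over all unordered pairs."""
    _require_n(alignment.n)
    mat = alignment.retained_matrix(site_policy)
    n = mat.shape[0]
    # one-hot encode the four states and use matmuls; N/- are already
    # excluded under complete deletion, and under the strict policy they
    # count as ordinary fifth/sixth states
    states = np.unique(mat)
    same = np.zeros((n, n), dtype=np.int64)
    for s in states:
        ind = (mat == s).astype(np.int64)
        same += ind @ ind.T
    diffs = mat.shape[1] - same
    iu = np.triu_indices(n, k=1)
    return diffs[iu]


def pairwise_spectrum(
    alignment: Alignment, site_policy: str = COMPLETE_DELETION
) -> PairwiseSpectrum:
    """Exact histogram of pairwise differences (the mismatch spectrum)."""
    d = pairwise_differences(alignment, site_policy)
    counts = np.bincount(d)
    return PairwiseSpectrum(tuple(int(c) for c in counts), alignment.n)


def nucleotide_diversity(
    alignment: Alignment, site_policy: str = COMPLETE_DELETION
) -> tuple[float, float]:
    """(pi, k): per-site nucleotide diversity and mean pairwise differences."""
    _require_n(alignment.n)
    mat = alignment.retained_matrix(site_policy)
    spec = pairwise_spectrum(alignment, site_policy)
    k = spec.mean
    return k / mat.shape[1], k


def _pi_sampling_sd(pi: float, n: int, sites: int) -> float:
    """Nei & Li / Nei (1987 eq. 10.7) sampling standard deviation of pi."""
    if sites == 0:
        return 0.0
    var = ((n + 1) / (3.0 * (n - 1) * sites)) * pi + (
        2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    ) * pi**2
    return float(np.sqrt(max(var, 0.0)))


def diversity_summary(
    alignment: Alignment, site_policy: str = COMPLETE_DELETION
) -> DiversitySummary:
    """Full per-sample diversity summary (one report-table row)."""
    from .iohap import collapse_haplotypes

    _require_n(alignment.n)
    mat = alignment.retained_matrix(site_policy)
    sites = mat.shape[1]
    S = segregating_sites(alignment, site_policy)
    assignment, _ = collapse_haplotypes(alignment, site_policy)
    hap_counts: dict[str, int] = {}
    for lab in assignment.values():
        hap_counts[lab] = hap_counts.get(lab, 0) + 1
    hd, hd_se = haplotype_diversity(list(hap_counts.values()), alignment.n)
    pi, k = nucleotide_diversity(alignment, site_policy)
    return DiversitySummary(
        n=alignment.n,
        S=S,
        Nhap=len(hap_counts),
        Hd=hd,
        Hd_se=hd_se,
        pi=pi,
        pi_sd=_pi_sampling_sd(pi, alignment.n, sites),
        k=k,
        sites=sites,
    )
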
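"""Neutrality tests: Tajima's D, Fu & Li's D and D*, Fu's Fs, and R2.

Each statistic detects departures from the constant-size neutral
coalescent; in the demographic reading used here, significantly negative D
and Fs (or a small R2) signal recent population expansion.  Significance is
assessed by coalescent simulation under selective neutrality and population
equilibrium, by default conditional on the observed number of segregating
sites (the DnaSP convention); conditioning on the Watterson estimate of
theta is available instead.

Conventions
-----------
* Tajima's D follows the 1989 constants, computed from S and the mean
  pairwise difference k.
* Fu & Li's statistics use the total number of mutations eta (summed
  minimum changes per column).  D requires an outgroup to polarise external
  (derived-singleton) mutations; D* uses unpolarised singletons.
* Fu's Fs uses S' = P(K >= Nhap | theta = k), with the haplotype-number
  distribution from the Ewens sampling formula via unsigned Stirling
  numbers of the first kind; Fs = ln(S'/(1-S')).
* R2 = sqrt(mean_i (U_i - k/2)^2) / S with U_i the singletons carried by
  sequence i (Ramos-Onsins & Rozas 2002).

Reported p-values are one-tailed on each statistic's conventional
expansion-sensitive tail: lower for D, D/D*, Fs, and R2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .iohap import COMPLETE_DELETION, Alignment, collapse_haplotypes
from .sumstats import SampleSizeError, nucleotide_diversity, segregating_sites

__all__ = [
    "NeutralityResult",
    "tajimas_d",
    "fu_li_d",
    "fus_fs",
    "r2",
    "neutrality_pvalue",
    "attach_pvalue",
    "significance_stars",
]

ON_S = "on-S"
ON_THETA = "on-theta"


@dataclass(frozen=True)
class NeutralityResult:
    """One test statistic, optionally with a simulation p-value."""

    name: str
    value: float
    defined: bool = True
    p_value: float | None = None
    n_sims: int = 0
    conditioning: str | None = None
    seed: int | None = None
    note: str = ""

    def with_p(self, p: float, n_sims: int, conditioning: str, seed) -> "NeutralityResult":
        return NeutralityResult(
            self.name, self.value, self.defined, p, n_sims, conditioning,
            seed, self.note,
        )


def significance_stars(p: float | None) -> str:
    if p is None:
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# column bookkeeping shared by the observed-data paths
# ---------------------------------------------------------------------------

def _column_summary(alignment: Alignment, site_policy: str, outgroup: str | None):
    """Per-column mutation bookkeeping.

    Returns (eta, eta_s, eta_e, U) where eta is the total minimum number of
    mutations, eta_s the unpolarised singletons (states carried by exactly
    one sequence), eta_e the derived singletons relative to the outgroup,
    and U the per-sequence singleton counts.
    """
    mat = alignment.retained_matrix(site_policy)
    n = mat.shape[0]
    og = None
    if outgroup is not None:
        if len(outgroup) != alignment.length:
            raise ValueError("outgroup length differs from alignment length")
        og_full = np.frombuffer(outgroup.upper().encode("ascii"), dtype=np.uint8)
        og = og_full[alignment.retained_columns(site_policy)]
    eta = eta_s = eta_e = 0
    U = np.zeros(n, dtype=np.int64)
    for j in range(mat.shape[1]):
        col = mat[:, j]
        states, counts = np.unique(col, return_counts=True)
        if len(states) < 2:
            continue
        eta += len(states) - 1
        for s, c in zip(states, counts):
            if c == 1:
                eta_s += 1
                U[int(np.flatnonzero(col == s)[0])] += 1
                if og is not None and s != og[j]:
                    eta_e += 1
    return eta, eta_s, eta_e, U


# ---------------------------------------------------------------------------
# core formulas (shared between observed data and null simulations)
# ---------------------------------------------------------------------------

def _harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i**power for i in range(1, n)))


def _tajima_d_from(n: int, S: int, k: float) -> float:
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (k - S / a1) / math.sqrt(var)


def _fu_li_constants(n: int) -> tuple[float, float, float]:
    a = _harmonic(n)
    b = _harmonic(n, 2)
    c = 2.0 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
    return a, b, c


def _fu_li_d_from(n: int, eta: int, eta_e: int) -> float:
    a, b, c = _fu_li_constants(n)
    v = 1.0 + (a**2 / (b + a**2)) * (c - (n + 1) / (n - 1))
    u = a - 1.0 - v
    return (eta - a * eta_e) / math.sqrt(u * eta + v * eta**2)


def _fu_li_dstar_from(n: int, eta: int, eta_s: int) -> float:
    a, b, c = _fu_li_constants(n)
    an1 = a + 1.0 / n
    d = c + (n - 2) / ((n - 1) ** 2) + (2.0 / (n - 1)) * (
        1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n
    )
    r = n / (n - 1.0)
    v = (r**2 * b + a**2 * d - 2 * (n * a * (a + 1)) / ((n - 1) ** 2)) / (
        a**2 + b
    )
    u = r * (a - r) - v
    return (r * eta - a * eta_s) / math.sqrt(u * eta + v * eta**2)


@lru_cache(maxsize=32)
def _log_stirling_row(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind |s(n, k)|,
    k = 0..n, computed from the exact integer recurrence."""
    row = [1]  # n = 0
    for m in range(n):
        new = [0] * (len(row) + 1)
        for k, v in enumerate(row):
            new[k] += m * v
            new[k + 1] += v
        row = new
    out = np.full(n + 1, -np.inf)
    for k, v in enumerate(row):
        if v > 0:
            out[k] = math.log(v)
    return out


def _fs_from(n: int, K: int, k_hat: float) -> float:
    """Fu's Fs from haplotype count K and mean pairwise differences k_hat."""
    if k_hat <= 0:
        return math.nan
    ls = _log_stirling_row(n)
    logtheta = math.log(k_hat)
    terms = ls[1:] + logtheta * np.arange(1, n + 1)  # k = 1..n
    upper = terms[K - 1:]  # K..n
    lower = terms[: K - 1]  # 1..K-1
    if lower.size == 0:
        return math.inf  # S' = 1, Fs undefined at +infinity
    m_up, m_lo = upper.max(), lower.max()
    log_up = m_up + math.log(np.exp(upper - m_up).sum())
    log_lo = m_lo + math.log(np.exp(lower - m_lo).sum())
    return log_up - log_lo


def _r2_from(n: int, S: int, k: float, U: np.ndarray) -> float:
    return math.sqrt(float(np.mean((U - k / 2.0) ** 2))) / S


# ---------------------------------------------------------------------------
# public statistics on alignments
# ---------------------------------------------------------------------------

def tajimas_d(
    alignment: Alignment, site_policy: str = COMPLETE_DELETION
) -> NeutralityResult:
    """Tajima's D = (k - S/a1) / sqrt(e1 S + e2 S(S-1))."""
    if alignment.n < 4:
        raise SampleSizeError("Tajima's D needs n >= 4")
    S = segregating_sites(alignment, site_policy)
    if S == 0:
        return NeutralityResult("TajimaD", math.nan, defined=False,
                                note="S = 0")
    _, k = nucleotide_diversity(alignment, site_policy)
    return NeutralityResult("TajimaD", _tajima_d_from(alignment.n, S, k))


def fu_li_d(
    alignment: Alignment,
    outgroup_sequence: str | None = None,
    site_policy: str = COMPLETE_DELETION,
) -> NeutralityResult:
    """Fu & Li's D (with outgroup) or D* (without).

    With an outgroup the external mutations eta_e are derived singletons;
    without one, unpolarised singletons eta_s are used (the D* variant,
    DnaSP's default path).
    """
    if alignment.n < 4:
        raise SampleSizeError("Fu & Li's D needs n >= 4")
    eta, eta_s, eta_e, _ = _column_summary(alignment, site_policy, outgroup_sequence)
    name = "FuLiD" if outgroup_sequence is not None else "FuLiDstar"
    if eta == 0:
        return NeutralityResult(name, math.nan, defined=False, note="S = 0")
    if outgroup_sequence is not None:
        return NeutralityResult(name, _fu_li_d_from(alignment.n, eta, eta_e))
    return NeutralityResult(name, _fu_li_dstar_from(alignment.n, eta, eta_s))


def fus_fs(
    alignment: Alignment, site_policy: str = COMPLETE_DELETION
) -> NeutralityResult:
    """Fu's Fs = ln(S'/(1-S')), S' = P(K >= Nhap | theta = k)."""
    if alignment.n < 2:
        raise SampleSizeError("Fu's Fs needs n >= 2")
    _, k = nucleotide_diversity(alignment, site_policy)
    assignment, _ = collapse_haplotypes(alignment, site_policy)
    K = len(set(assignment.values()))
    if k <= 0:
        return NeutralityResult("FuFs", math.nan, defined=False,
                                note="mean pairwise differences = 0")
    fs = _fs_from(alignment.n, K, k)
    if math.isinf(fs):
        return NeutralityResult("FuFs", fs, defined=False,
                                note="single haplotype: S' = 1")
    return NeutralityResult("FuFs", fs)


def r2(
    alignment: Alignment, site_policy: str = COMPLETE_DELETION
) -> NeutralityResult:
    """Ramos-Onsins & Rozas's R2 (small values indicate expansion)."""
    if alignment.n < 4:
        raise SampleSizeError("R2 needs n >= 4")
    S = segregating_sites(alignment, site_policy)
    if S == 0:
        return NeutralityResult("R2", math.nan, defined=False, note="S = 0")
    _, k = nucleotide_diversity(alignment, site_policy)
    _, _, _, U = _column_summary(alignment, site_policy, None)
    return NeutralityResult("R2", _r2_from(alignment.n, S, k, U))


# ---------------------------------------------------------------------------
# coalescent null distribution
# ---------------------------------------------------------------------------

def _null_tree(n: int, rng) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Constant-size coalescent tree: parent array, branch lengths, and a
    leaf bitmask per node.  Time scale is irrelevant when conditioning on S."""
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    leafset = [0] * n_nodes
    for i in range(n):
        leafset[i] = 1 << i
    active = list(range(n))
    t, nxt = 0.0, n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        if i > j:
            i, j = j, i
        b = active.pop(j)
        a = active.pop(i)
        parent[a] = parent[b] = nxt
        time[nxt] = t
        leafset[nxt] = leafset[a] | leafset[b]
        active.append(nxt)
        nxt += 1
    blen = np.zeros(n_nodes)
    has_par = parent >= 0
    blen[has_par] = time[parent[has_par]] - time[has_par]
    return parent, blen, leafset


class _UnionFind:
    __slots__ = ("up",)

    def __init__(self, n: int):
        self.up = list(range(n))

    def find(self, x: int) -> int:
        up = self.up
        while up[x] != x:
            up[x] = up[up[x]]
            x = up[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.up[ra] = rb


def _simulate_null(n: int, rng, S_fixed: int | None, theta: float | None):
    """One neutral equilibrium replicate -> (S, k, eta_s_folded, eta_e, U, K).

    Infinite sites: mutations placed on branches proportionally to length
    (exactly ``S_fixed`` of them, or Poisson with rate theta/2 per unit
    length when conditioning on theta).
    """
    parent, blen, leafset = _null_tree(n, rng)
    total = blen.sum()
    if S_fixed is not None:
        S = S_fixed
        counts = rng.multinomial(S, blen / total)
    else:
        counts = rng.poisson(blen * (theta / 2.0))
        S = int(counts.sum())
    if S == 0:
        return 0, 0.0, 0, 0, np.zeros(n, dtype=np.int64), 1
    full = (1 << n) - 1
    pair_sum = 0
    eta_s = eta_e = 0
    U = np.zeros(n, dtype=np.int64)
    uf = _UnionFind(len(parent))
    for v in range(len(parent)):
        p = parent[v]
        if p < 0:
            continue
        m = int(counts[v])
        if m == 0:
            uf.union(v, int(p))
            continue
        c = leafset[v].bit_count()
        pair_sum += m * c * (n - c)
        if c == 1:
            eta_s += m
            eta_e += m
            U[leafset[v].bit_length() - 1] += m
        elif c == n - 1:
            eta_s += m
            U[(full ^ leafset[v]).bit_length() - 1] += m
    k = pair_sum / (n * (n - 1) / 2.0)
    K = len({uf.find(i) for i in range(n)})
    return S, k, eta_s, eta_e, U, K


_LOWER_TAIL = {"TajimaD", "FuLiD", "FuLiDstar", "FuFs", "R2"}


def _null_statistic(name: str, n: int, rep) -> float:
    S, k, eta_s, eta_e, U, K = rep
    if S == 0:
        return math.nan
    if name == "TajimaD":
        return _tajima_d_from(n, S, k)
    if name == "FuLiD":
        return _fu_li_d_from(n, S, eta_e)
    if name == "FuLiDstar":
        return _fu_li_dstar_from(n, S, eta_s)
    if name == "FuFs":
        return _fs_from(n, K, k) if k > 0 else math.nan
    if name == "R2":
        return _r2_from(n, S, k, U)
    raise ValueError(f"unknown statistic {name!r}")


def neutrality_pvalue(
    statistic: NeutralityResult,
    alignment: Alignment,
    n_sims: int = 10_000,
    seed=None,
    conditioning: str = ON_S,
    site_policy: str = COMPLETE_DELETION,
) -> NeutralityResult:
    """Empirical one-tailed p-value from neutral equilibrium simulations.

    ``conditioning=ON_S`` fixes the simulated number of segregating sites to
    the observed S; ``ON_THETA`` simulates Poisson mutations at the
    Watterson estimate.  The p-value is the proportion of simulated values
    <= the observed statistic (all supported statistics are tested on their
    lower, expansion-sensitive tail).
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    if not statistic.defined:
        return statistic
    rng = np.random.default_rng(seed)
    n = alignment.n
    S_obs = segregating_sites(alignment, site_policy)
    theta = None
    S_fixed: int | None = S_obs
    if conditioning == ON_THETA:
        S_fixed = None
        theta = S_obs / _harmonic(n)
    elif conditioning != ON_S:
        raise ValueError(f"unknown conditioning {conditioning!r}")
    hits = 0
    valid = 0
    for _ in range(n_sims):
        rep = _simulate_null(n, rng, S_fixed, theta)
        val = _null_statistic(statistic.name, n, rep)
        if math.isnan(val):
            continue
        valid += 1
        if val <= statistic.value:
            hits += 1
    if valid == 0:
        return statistic
    p = hits / valid
    seed_rec = seed if isinstance(seed, int) else None
    return statistic.with_p(p, valid, conditioning, seed_rec)


def attach_pvalue(stat_fn, alignment, n_sims=10_000, seed=None,
                  conditioning=ON_S, site_policy=COMPLETE_DELETION,
                  **stat_kw) -> NeutralityResult:
    """Convenience: compute a statistic and its simulation p-value."""
    res = stat_fn(alignment, site_policy=site_policy, **stat_kw)
    if not res.defined:
        return res
    return neutrality_pvalue(res, alignment, n_sims=n_sims, seed=seed,
                             conditioning=conditioning, site_policy=site_policy)
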
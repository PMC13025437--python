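"""Coalescent simulation of mtDNA samples under three demographies.

The generator produces the synthetic data the rest of the pipeline is
exercised on: neutral constant-size samples, sudden (stepwise) expansion
samples, and two-population isolation-with-migration samples, with
finite-sites HKY mutation onto 596-bp sequences by default.

Time scaling
------------
All demographic times are measured in *mutational units*: one unit equals
1/(2u) generations, where u is the per-locus per-generation mutation rate.
In these units a single lineage mutates at rate 1/2 per locus, so

* a pair of sequences separated by total time t accumulates Poisson(t)
  differences,
* at equilibrium with population parameter theta (= 2 Ne u) the pairwise
  coalescence rate is 1/theta and E[pairwise differences] = theta,
* the expansion age tau and the expected number of segregating sites
  theta * a1 (a1 = sum 1/i) are directly comparable with the estimators.

The isolation-with-migration model is parameterised MDIV-style (theta per
locus, migration rate M with per-lineage rate M/2, divergence time T in
units of Ne generations) and converted internally: T corresponds to
T * theta mutational units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .iohap import Alignment, PopulationMap, write_alignment

__all__ = [
    "DemographyModel",
    "Genealogy",
    "DEFAULT_L",
    "DEFAULT_KAPPA",
    "DEFAULT_BASE_FREQS",
    "simulate_genealogy",
    "evolve_sequences",
    "simulate_dataset",
    "hky_eigen",
    "hky_transition_matrices",
]

DEFAULT_L = 596
#: transition/transversion rate-ratio default; insect mtDNA COI is strongly
#: transition-biased
DEFAULT_KAPPA = 10.0
#: AT-rich insect-mtDNA-like base composition (A, C, G, T)
DEFAULT_BASE_FREQS = (0.31, 0.13, 0.15, 0.41)


@dataclass(frozen=True)
class DemographyModel:
    """A demographic scenario plus sequence-evolution parameters.

    Use the classmethod constructors; ``kind`` is one of ``constant``,
    ``stepwise_expansion``, ``split_with_migration``.
    """

    kind: str
    n: int
    theta: float = 0.0
    theta0: float = 0.0
    theta1: float = 0.0
    tau: float = 0.0
    M: float = 0.0
    T: float = 0.0
    n2: int = 0
    L: int = DEFAULT_L
    kappa: float = DEFAULT_KAPPA
    base_freqs: tuple[float, float, float, float] = DEFAULT_BASE_FREQS

    @classmethod
    def constant(cls, theta: float, n: int, **kw) -> "DemographyModel":
        if theta < 0 or n < 2:
            raise ValueError("constant model needs theta >= 0 and n >= 2")
        return cls(kind="constant", n=n, theta=theta, **kw)

    @classmethod
    def stepwise_expansion(
        cls, theta0: float, theta1: float, tau: float, n: int, **kw
    ) -> "DemographyModel":
        if min(theta0, theta1, tau) < 0 or theta1 < theta0:
            raise ValueError("expansion needs 0 <= theta0 <= theta1 and tau >= 0")
        if n < 2:
            raise ValueError("n >= 2 required")
        return cls(
            kind="stepwise_expansion", n=n, theta0=theta0, theta1=theta1,
            tau=tau, **kw,
        )

    @classmethod
    def split_with_migration(
        cls, theta: float, M: float, T: float, n1: int, n2: int, **kw
    ) -> "DemographyModel":
        if theta <= 0 or M < 0 or T < 0 or n1 < 1 or n2 < 1:
            raise ValueError("invalid split-with-migration parameters")
        return cls(
            kind="split_with_migration", n=n1, n2=n2, theta=theta, M=M, T=T,
            **kw,
        )

    def to_dict(self) -> dict:
        return {
            "kind": self.kind, "n": self.n, "n2": self.n2,
            "theta": self.theta, "theta0": self.theta0, "theta1": self.theta1,
            "tau": self.tau, "M": self.M, "T": self.T, "L": self.L,
            "kappa": self.kappa, "base_freqs": list(self.base_freqs),
        }


@dataclass(frozen=True)
class Genealogy:
    """Rooted binary genealogy with branch lengths in mutational units.

    Nodes ``0..n_tips-1`` are tips at time 0; internal nodes follow in
    coalescence order; the root has parent ``-1``.  For two-population
    models ``tip_pops`` holds each tip's population (0/1) and
    ``migrations`` the backward-in-time migration events
    ``(lineage_child_node, time, pop_after)``.
    """

    n_tips: int
    parent: np.ndarray
    time: np.ndarray
    tip_pops: np.ndarray | None = None
    migrations: tuple = ()

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    @property
    def tmrca(self) -> float:
        return float(self.time.max())

    def children(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {i: [] for i in range(self.n_nodes)}
        for v in range(self.n_nodes):
            p = int(self.parent[v])
            if p >= 0:
                ch[p].append(v)
        return ch

    def branch_lengths(self) -> np.ndarray:
        """Per-node branch length to its parent (0 for the root)."""
        out = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        out[has_parent] = (
            self.time[self.parent[has_parent]] - self.time[has_parent]
        )
        return out


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _kingman(n: int, rate_of_time, rng) -> tuple[np.ndarray, np.ndarray]:
    """Generic single-population coalescent.

    ``rate_of_time(t)`` returns the per-pair coalescence rate at time t and
    the time at which that rate next changes (np.inf if constant).
    """
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        pair_rate, t_change = rate_of_time(t)
        total = pair_rate * k * (k - 1) / 2.0
        if total <= 0:
            if not np.isfinite(t_change):
                raise RuntimeError("coalescent cannot finish: zero rate forever")
            t = t_change
            continue
        wait = rng.exponential(1.0 / total)
        if t + wait > t_change:
            t = t_change
            continue
        t += wait
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return parent, time


def simulate_genealogy(model: DemographyModel, seed=None) -> Genealogy:
    """Draw one genealogy under the model's demography."""
    rng = _rng(seed)
    if model.kind == "constant":
        if model.theta <= 0:
            raise ValueError("constant model needs theta > 0 to coalesce")
        parent, time = _kingman(
            model.n, lambda t: (1.0 / model.theta, np.inf), rng
        )
        return Genealogy(model.n, parent, time)

    if model.kind == "stepwise_expansion":
        tau, th0, th1 = model.tau, model.theta0, model.theta1

        def rate(t):
            if t < tau:
                return (1.0 / th1 if th1 > 0 else np.inf), tau
            return (1.0 / th0 if th0 > 0 else np.inf), np.inf

        if th1 <= 0:
            raise ValueError("theta1 must be > 0")
        if th0 > 0:
            parent, time = _kingman(model.n, rate, rng)
            return Genealogy(model.n, parent, time)
        # theta0 = 0: any lineage surviving to tau coalesces instantly
        # (star-like ancestry at the expansion time)
        parent = np.full(2 * model.n - 1, -1, dtype=np.int64)
        time = np.zeros(2 * model.n - 1)
        active = list(range(model.n))
        t, nxt = 0.0, model.n
        while len(active) > 1:
            k = len(active)
            total = (k * (k - 1) / 2.0) / th1
            wait = rng.exponential(1.0 / total)
            if t + wait >= tau:
                t = tau
                while len(active) > 1:
                    i, j = rng.choice(len(active), size=2, replace=False)
                    a, b = active[i], active[j]
                    parent[a] = parent[b] = nxt
                    time[nxt] = tau
                    active = [x for x in active if x not in (a, b)] + [nxt]
                    nxt += 1
                break
            t += wait
            i, j = rng.choice(k, size=2, replace=False)
            a, b = active[i], active[j]
            parent[a] = parent[b] = nxt
            time[nxt] = t
            active = [x for x in active if x not in (a, b)] + [nxt]
            nxt += 1
        return Genealogy(model.n, parent, time)

    if model.kind == "split_with_migration":
        return _simulate_im(model, rng)

    raise ValueError(f"unknown demography kind {model.kind!r}")


def _simulate_im(model: DemographyModel, rng) -> Genealogy:
    """Structured coalescent for the two-population split model.

    Works in mutational units: per-pair within-population coalescence rate
    1/theta, per-lineage migration rate (M/2)/theta, populations merge at
    T * theta.
    """
    n1, n2, theta = model.n, model.n2, model.theta
    n = n1 + n2
    t_split = model.T * theta
    coal = 1.0 / theta
    mig = (model.M / 2.0) / theta

    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    tip_pops = np.array([0] * n1 + [1] * n2, dtype=np.int64)
    pops = {i: int(tip_pops[i]) for i in range(n)}
    active = list(range(n))
    migrations: list[tuple[int, float, int]] = []
    t, nxt = 0.0, n
    while len(active) > 1:
        if t < t_split:
            k0 = sum(1 for v in active if pops[v] == 0)
            k1 = len(active) - k0
            r_coal = coal * (k0 * (k0 - 1) / 2.0 + k1 * (k1 - 1) / 2.0)
            r_mig = mig * len(active)
            total = r_coal + r_mig
            if total <= 0:
                t = t_split
                continue
            wait = rng.exponential(1.0 / total)
            if t + wait >= t_split:
                t = t_split
                continue
            t += wait
            if rng.random() < r_mig / total:
                v = active[rng.integers(len(active))]
                pops[v] = 1 - pops[v]
                migrations.append((v, t, pops[v]))
            else:
                # weight pops by their pair counts
                w0 = k0 * (k0 - 1) / 2.0
                w1 = k1 * (k1 - 1) / 2.0
                pop = 0 if rng.random() < w0 / (w0 + w1) else 1
                members = [v for v in active if pops[v] == pop]
                i, j = rng.choice(len(members), size=2, replace=False)
                a, b = members[i], members[j]
                parent[a] = parent[b] = nxt
                time[nxt] = t
                pops[nxt] = pop
                active = [x for x in active if x not in (a, b)] + [nxt]
                nxt += 1
        else:
            k = len(active)
            total = coal * k * (k - 1) / 2.0
            t += rng.exponential(1.0 / total)
            i, j = rng.choice(k, size=2, replace=False)
            a, b = active[i], active[j]
            parent[a] = parent[b] = nxt
            time[nxt] = t
            pops[nxt] = pops[a]
            active = [x for x in active if x not in (a, b)] + [nxt]
            nxt += 1
    return Genealogy(n, parent, time, tip_pops=tip_pops,
                     migrations=tuple(migrations))


# ---------------------------------------------------------------------------
# HKY sequence evolution
# ---------------------------------------------------------------------------

_NUC = "ACGT"
_TRANSITION_PARTNER = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T


def hky_eigen(kappa: float, base_freqs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigendecomposition of the HKY rate matrix, scaled to one expected
    substitution per site per unit branch length at stationarity.

    Returns (U, lam, Vinv) with P(t) = U @ diag(exp(lam*t)) @ Vinv.
    """
    pi = np.asarray(base_freqs, dtype=float)
    if pi.shape != (4,) or np.any(pi <= 0):
        raise ValueError("base_freqs must be four positive values")
    pi = pi / pi.sum()
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = pi[j] * (kappa if _TRANSITION_PARTNER[i] == j else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -float(np.dot(pi, np.diag(Q)))
    Q /= mean_rate
    # symmetrize via similarity transform for a stable decomposition
    d = np.sqrt(pi)
    Sym = (Q * d[:, None]) / d[None, :]
    lam, V = np.linalg.eigh((Sym + Sym.T) / 2.0)
    U = V / d[:, None]
    Vinv = V.T * d[None, :]
    return U, lam, Vinv


def hky_transition_matrices(branch_lengths, kappa: float, base_freqs) -> np.ndarray:
    """Stack of HKY transition-probability matrices, one per branch length
    (lengths in expected substitutions per site)."""
    U, lam, Vinv = hky_eigen(kappa, base_freqs)
    t = np.atleast_1d(np.asarray(branch_lengths, dtype=float))
    P = np.einsum("ik,ek,kj->eij", U, np.exp(np.outer(t, lam)), Vinv)
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=2, keepdims=True)
    return P


def evolve_sequences(
    genealogy: Genealogy,
    L: int = DEFAULT_L,
    kappa: float = DEFAULT_KAPPA,
    base_freqs=DEFAULT_BASE_FREQS,
    seed=None,
    infinite_sites: bool = False,
    id_prefix: str = "seq",
) -> Alignment:
    """Drop mutations on a genealogy and emit the tip alignment.

    Default is finite-sites HKY with multiple hits: the root sequence is
    drawn from the stationary base frequencies and each branch of length b
    (mutational units) evolves each site with an expected b/(2L)
    substitutions.  ``infinite_sites=True`` instead places Poisson(b/2)
    mutations per branch, each at a previously unmutated site (used by
    exact oracles; requires total mutations <= L).
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = _rng(seed)
    n = genealogy.n_tips
    order = np.argsort(genealogy.time)[::-1]  # root first
    seqs = {}
    root = genealogy.root

    if infinite_sites:
        pi = np.asarray(base_freqs, dtype=float)
        pi = pi / pi.sum()
        root_seq = rng.choice(4, size=L, p=pi)
        blen = genealogy.branch_lengths()
        n_mut = rng.poisson(blen / 2.0)
        if n_mut.sum() > L:
            raise ValueError(
                f"{n_mut.sum()} mutations exceed {L} sites under the "
                "infinite-sites approximation"
            )
        sites = rng.choice(L, size=int(n_mut.sum()), replace=False)
        site_iter = iter(sites)
        seqs[root] = root_seq
        for v in order:
            v = int(v)
            if v == root:
                continue
            s = seqs[int(genealogy.parent[v])].copy()
            for _ in range(int(n_mut[v])):
                j = int(next(site_iter))
                s[j] = (s[j] + 1 + rng.integers(3)) % 4
            seqs[v] = s
    else:
        pi = np.asarray(base_freqs, dtype=float)
        pi = pi / pi.sum()
        blen = genealogy.branch_lengths() / (2.0 * L)  # subs per site
        P = hky_transition_matrices(blen, kappa, base_freqs)
        cum = np.cumsum(P, axis=2)
        seqs[root] = rng.choice(4, size=L, p=pi)
        for v in order:
            v = int(v)
            if v == root:
                continue
            par = seqs[int(genealogy.parent[v])]
            child = np.empty(L, dtype=np.int64)
            u = rng.random(L)
            for state in range(4):
                idx = par == state
                if idx.any():
                    child[idx] = np.searchsorted(
                        cum[v, state], u[idx], side="right"
                    )
            seqs[v] = np.minimum(child, 3)

    width = max(3, len(str(n)))
    records = []
    for i in range(n):
        sid = f"{id_prefix}{i + 1:0{width}d}"
        records.append((sid, "".join(_NUC[s] for s in seqs[i])))
    return Alignment.from_records(records)


def simulate_dataset(
    model: DemographyModel,
    seed=None,
    infinite_sites: bool = False,
    out_fasta: str | Path | None = None,
    out_map: str | Path | None = None,
    group_labels: tuple[str, str] = ("G1", "G2"),
) -> tuple[Alignment, PopulationMap]:
    """Simulate a genealogy, evolve sequences, and build the population map.

    When output paths are given, writes the FASTA, the map TSV, and a
    JSON provenance sidecar (model parameters + seed) next to the FASTA.
    """
    rng = _rng(seed)
    gen = simulate_genealogy(model, rng)
    aln = evolve_sequences(
        gen, L=model.L, kappa=model.kappa, base_freqs=model.base_freqs,
        seed=rng, infinite_sites=infinite_sites,
    )
    assignments = {}
    for i, sid in enumerate(aln.ids):
        if gen.tip_pops is not None:
            g = group_labels[int(gen.tip_pops[i])]
        else:
            g = group_labels[0]
        assignments[sid] = (f"{g}-loc", g)
    pmap = PopulationMap(assignments)
    if out_fasta is not None:
        out_fasta = Path(out_fasta)
        write_alignment(aln, out_fasta)
        sidecar = out_fasta.with_suffix(out_fasta.suffix + ".provenance.json")
        sidecar.write_text(json.dumps(
            {"model": model.to_dict(), "seed": None if isinstance(seed, np.random.Generator) else seed},
            indent=2,
        ) + "\n")
    if out_map is not None:
        pmap.write(out_map)
    return aln, pmap
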
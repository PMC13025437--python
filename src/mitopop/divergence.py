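"""Two-population isolation-with-migration (IM) divergence estimation.

An MDIV-style Bayesian sampler: two populations of equal scaled size
theta = 2 Ne u (per locus) diverged T time units ago (one unit = Ne
generations) from an ancestral population of the same size, exchanging
migrants at scaled rate M (per-lineage migration rate M/2) until T.  The
sampler runs Metropolis-Hastings MCMC jointly over the migration-labelled
genealogy and (theta, M, T) with uniform priors on [0, theta_max],
[0, M_max], [0, T_max], computing the sequence likelihood with a
finite-sites HKY pruning algorithm, and reports gridded posterior
histograms, their modes, and calendar-unit conversions (female effective
size, population divergence time, TMRCA).

Genealogy proposals use single-lineage re-simulation: a lineage is
detached and its migration path and re-attachment point are redrawn from
the conditional structured coalescent given the rest of the genealogy.
For that proposal the prior and proposal densities cancel exactly, so
genealogy updates accept on the likelihood ratio alone; it updates
topology, node times and migration paths in one irreducible move.  A
node-time slide is kept for extra mixing.

By default prior support is restricted to genealogies whose root age is at
least T (ancestral coalescence precedes population divergence), so every
posterior sample satisfies TMRCA >= T; the unrestricted standard IM model
is available via ``constrain_root_above_split=False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coalsim import Genealogy, hky_eigen
from .iohap import Alignment

__all__ = [
    "IMConfig",
    "DivergenceEstimate",
    "hky_likelihood",
    "im_mcmc",
    "convert_divergence",
    "estimate_kappa",
    "write_posterior_histograms",
    "write_im_config",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 4}


# ---------------------------------------------------------------------------
# HKY pruning likelihood
# ---------------------------------------------------------------------------

def _encode(alignment: Alignment) -> np.ndarray:
    out = np.empty((alignment.n, alignment.length), dtype=np.int8)
    for i, s in enumerate(alignment.seqs):
        out[i] = [_CODE[ch] for ch in s]
    return out


def _patterns(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique site patterns (columns) and their multiplicities."""
    cols, counts = np.unique(codes.T, axis=0, return_counts=True)
    return cols, counts.astype(float)


def empirical_base_freqs(codes: np.ndarray) -> np.ndarray:
    counts = np.array([(codes == b).sum() for b in range(4)], dtype=float)
    counts += 1.0  # avoid zero frequencies on short alignments
    return counts / counts.sum()


def estimate_kappa(codes: np.ndarray, base_freqs: np.ndarray) -> float:
    """Method-of-moments HKY kappa from pooled pairwise ts/tv counts."""
    n = codes.shape[0]
    ts = tv = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = codes[i], codes[j]
            ok = (a < 4) & (b < 4) & (a != b)
            if not ok.any():
                continue
            ai, bj = a[ok], b[ok]
            is_ts = ((ai == 0) & (bj == 2)) | ((ai == 2) & (bj == 0)) | (
                (ai == 1) & (bj == 3)) | ((ai == 3) & (bj == 1))
            ts += int(is_ts.sum())
            tv += int((~is_ts).sum())
    pi = base_freqs
    piR, piY = pi[0] + pi[2], pi[1] + pi[3]
    w_ts = pi[0] * pi[2] + pi[1] * pi[3]
    if tv == 0 or w_ts <= 0:
        return 50.0
    kappa = (ts / tv) * (piR * piY) / w_ts
    return float(np.clip(kappa, 0.5, 100.0))


class _Pruner:
    """Caches pattern compression and the HKY eigendecomposition; evaluates
    the log-likelihood of a genealogy for branch lengths given in expected
    substitutions per site."""

    def __init__(self, codes: np.ndarray, kappa: float, base_freqs: np.ndarray):
        self.pats, self.weights = _patterns(codes)  # (P, n), (P,)
        self.n = codes.shape[0]
        self.pi = np.asarray(base_freqs, dtype=float)
        self.U, self.lam, self.Vinv = hky_eigen(kappa, self.pi)
        # tip partials: (n, 4, P)
        P = self.pats.shape[0]
        self.tip_partials = np.zeros((self.n, 4, P))
        for i in range(self.n):
            col = self.pats[:, i]
            miss = col == 4
            self.tip_partials[i, :, miss] = 1.0
            obs = ~miss
            self.tip_partials[i, col[obs], np.flatnonzero(obs)] = 1.0

    def transition(self, lengths: np.ndarray) -> np.ndarray:
        P = np.einsum(
            "ik,ek,kj->eij", self.U, np.exp(np.outer(lengths, self.lam)),
            self.Vinv,
        )
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P

    def loglik(self, parent: np.ndarray, time: np.ndarray,
               children: list[list[int]], mu_site: float) -> float:
        n_nodes = len(parent)
        order = np.argsort(time, kind="stable")
        lengths = np.zeros(n_nodes)
        has_par = parent >= 0
        lengths[has_par] = (time[parent[has_par]] - time[has_par]) * mu_site
        trans = self.transition(np.maximum(lengths, 0.0))
        npat = self.pats.shape[0]
        partial: list = [None] * n_nodes
        for i in range(self.n):
            partial[i] = self.tip_partials[i]
        logscale = np.zeros(npat)
        root = -1
        since_rescale = 0
        for v in order[self.n:]:
            v = int(v)
            if not children[v]:
                continue
            c1, c2 = children[v]
            part = (trans[c1] @ partial[c1]) * (trans[c2] @ partial[c2])
            since_rescale += 1
            if since_rescale >= 10 or parent[v] < 0:
                # rescale periodically so deep trees cannot underflow
                mx = part.max(axis=0)
                if not mx.all():
                    return -math.inf
                part /= mx
                logscale += np.log(mx)
                since_rescale = 0
            partial[v] = part
            if parent[v] < 0:
                root = v
        site_l = self.pi @ partial[root]
        if np.any(site_l <= 0):
            return -math.inf
        return float(np.dot(self.weights, np.log(site_l) + logscale))


def hky_likelihood(
    genealogy: Genealogy,
    alignment: Alignment,
    kappa: float,
    mu_scale: float,
    base_freqs=None,
) -> float:
    """HKY log-likelihood of an alignment on a genealogy.

    ``mu_scale`` converts genealogy branch-time units into expected
    substitutions per site (branch length in substitutions/site =
    branch time x mu_scale).  Base frequencies default to the empirical
    alignment composition.  Conflicting sites on a zero-length tree yield
    ``-inf`` rather than an exception.
    """
    codes = _encode(alignment)
    if base_freqs is None:
        base_freqs = empirical_base_freqs(codes)
    pruner = _Pruner(codes, kappa, base_freqs)
    ch = genealogy.children()
    children = [ch.get(v, []) for v in range(genealogy.n_nodes)]
    return pruner.loglik(genealogy.parent, genealogy.time, children, mu_scale)


# ---------------------------------------------------------------------------
# IM state and prior
# ---------------------------------------------------------------------------

class _IMTree:
    """Mutable migration-labelled genealogy for the sampler.

    ``events[v]`` lists backward-in-time migration events on the edge from
    v to its parent as (time, population-after) pairs, ascending in time;
    ``pop[v]`` is the lineage label at node v's own time.
    """

    __slots__ = ("n", "time", "parent", "children", "pop", "events")

    def __init__(self, n_tips: int):
        n_nodes = 2 * n_tips - 1
        self.n = n_tips
        self.time = np.zeros(n_nodes)
        self.parent = np.full(n_nodes, -1, dtype=np.int64)
        self.children: list[list[int]] = [[] for _ in range(n_nodes)]
        self.pop = np.zeros(n_nodes, dtype=np.int64)
        self.events: list[list[tuple[float, int]]] = [[] for _ in range(n_nodes)]

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def label_top(self, v: int) -> int:
        lab = int(self.pop[v])
        for _, p_new in self.events[v]:
            lab = p_new
        return lab

    def label_at(self, v: int, t: float) -> int:
        lab = int(self.pop[v])
        for et, p_new in self.events[v]:
            if et <= t:
                lab = p_new
            else:
                break
        return lab

    def snapshot(self):
        return (
            self.time.copy(), self.parent.copy(),
            [list(c) for c in self.children], self.pop.copy(),
            [list(e) for e in self.events],
        )

    def restore(self, snap) -> None:
        self.time, self.parent, ch, self.pop, ev = (
            snap[0].copy(), snap[1].copy(), snap[2], snap[3].copy(), snap[4],
        )
        self.children = [list(c) for c in ch]
        self.events = [list(e) for e in ev]

    def n_migrations(self) -> int:
        return sum(len(e) for e in self.events)


def _mig_stats(tree: _IMTree, T: float) -> tuple[int, float]:
    """(number of migration events, total lineage-time below T).

    Sufficient statistics for M: the prior density factors as
    (M/2)^n_mig * exp(-(M/2) * exposure) * (M-free terms), so M's full
    conditional is a Gamma(n_mig + 1, exposure/2) truncated to the prior.
    """
    n_nodes = 2 * tree.n - 1
    n_mig = tree.n_migrations()
    times = []
    for v in range(n_nodes):
        if tree.children[v]:
            times.append((float(tree.time[v]), -1))
    times.sort()
    k = tree.n
    t = 0.0
    exposure = 0.0
    for et, dk in times:
        hi = min(et, T)
        if hi > t:
            exposure += k * (hi - t)
        t = et
        k += dk
        if t >= T:
            break
    return n_mig, exposure


def _gibbs_migration_rate(tree: _IMTree, T: float, M_max: float, rng) -> float:
    from scipy.special import gammainc, gammaincinv

    n_mig, exposure = _mig_stats(tree, T)
    if exposure <= 0:
        return float(rng.uniform(0.0, M_max))
    a = n_mig + 1
    scale = 2.0 / exposure
    hi = gammainc(a, M_max / scale)
    x = gammaincinv(a, rng.uniform(0.0, hi))
    return float(np.clip(x * scale, 1e-12, M_max))


def _gibbs_split_time(tree: _IMTree, M: float, T_prior_max: float,
                      constrain_root: bool, current_T: float, rng) -> float:
    """Exact Gibbs draw of the split time T from its full conditional.

    With the labelled genealogy fixed, log p(T) is piecewise linear in T:
    on a segment between consecutive genealogy events with k0/k1 lineages
    per population the slope is k0*k1 - (M/2)(k0+k1) (for T above the root
    the density no longer depends on T).  The support is bounded below by
    the latest migration event and above by the earliest label-inconsistent
    coalescence (and the root, when the root >= T constraint is active).
    """
    n_nodes = 2 * tree.n - 1
    root = tree.root
    lo = 0.0
    hi = min(T_prior_max, float(tree.time[root]) if constrain_root else math.inf)
    evts = []
    for v in range(n_nodes):
        if tree.parent[v] >= 0:
            lab = int(tree.pop[v])
            for et, p_new in tree.events[v]:
                evts.append((et, 1, (lab, p_new)))
                lab = p_new
                lo = max(lo, et)
        if tree.children[v]:
            c1, c2 = tree.children[v]
            l1, l2 = tree.label_top(c1), tree.label_top(c2)
            if l1 != l2 or l1 != int(tree.pop[v]):
                hi = min(hi, float(tree.time[v]))
            evts.append((float(tree.time[v]), 0, (l1, l2, int(tree.pop[v]))))
    if hi <= lo:
        return current_T
    evts.sort(key=lambda e: (e[0], e[1]))
    k = [0, 0]
    for i in range(tree.n):
        k[int(tree.pop[i])] += 1
    # collect (a, b, slope) segments intersected with [lo, hi]
    segments = []
    t = 0.0
    for et, kind, data in evts:
        a, b = max(t, lo), min(et, hi)
        if b > a:
            slope = k[0] * k[1] - (M / 2.0) * (k[0] + k[1])
            segments.append((a, b, slope))
        t = et
        if kind == 1:
            old, new = data
            k[old] -= 1
            k[new] += 1
        else:
            l1, l2, lab = data
            k[l1] -= 1
            k[l2] -= 1
            k[lab] += 1
    if hi > t:  # beyond the root the density is flat in T
        segments.append((max(t, lo), hi, 0.0))
    # piecewise-exponential sampling in log space
    log_offs = []  # cumulative log density at segment starts (ref: lo -> 0)
    acc = 0.0
    log_ints = []
    for a, b, s in segments:
        log_offs.append(acc)
        w = b - a
        if abs(s) < 1e-12:
            log_ints.append(acc + math.log(w))
        elif s > 0:
            log_ints.append(acc + s * w + math.log1p(-math.exp(-s * w)) - math.log(s))
        else:
            log_ints.append(acc + math.log1p(-math.exp(s * w)) - math.log(-s))
        acc += s * w
    m = max(log_ints)
    weights = np.exp(np.array(log_ints) - m)
    weights /= weights.sum()
    i = int(rng.choice(len(segments), p=weights))
    a, b, s = segments[i]
    u = rng.random()
    if abs(s) < 1e-12:
        return a + u * (b - a)
    # inverse CDF of density prop to exp(s(T-a)) on [a, b]
    return a + math.log1p(u * math.expm1(s * (b - a))) / s


def _prior_log(tree: _IMTree, M: float, T: float,
               require_root_above_T: bool) -> float:
    """Structured-coalescent log-density of the labelled genealogy, or -inf
    if the state is invalid under (M, T)."""
    n_nodes = 2 * tree.n - 1
    root = tree.root
    if require_root_above_T and tree.time[root] < T:
        return -math.inf
    evts = []  # (time, kind, data); kind 0 coal, 1 migration
    for v in range(n_nodes):
        if tree.parent[v] >= 0:
            lab = int(tree.pop[v])
            for et, p_new in tree.events[v]:
                if et >= T or et < tree.time[v] or et > tree.time[tree.parent[v]]:
                    return -math.inf
                evts.append((et, 1, (lab, p_new)))
                if p_new == lab:
                    return -math.inf
                lab = p_new
        if tree.children[v]:
            c1, c2 = tree.children[v]
            if tree.time[v] < T:
                l1, l2 = tree.label_top(c1), tree.label_top(c2)
                if l1 != l2 or l1 != int(tree.pop[v]):
                    return -math.inf
            evts.append((tree.time[v], 0, int(tree.pop[v])))
    if M <= 0 and any(k == 1 for _, k, _ in evts):
        return -math.inf
    evts.sort(key=lambda e: (e[0], e[1]))
    k = [0, 0]
    for i in range(tree.n):
        k[int(tree.pop[i])] += 1
    logp = 0.0
    t = 0.0
    below = True
    mig_rate = M / 2.0

    def interval(t0, t1):
        nonlocal logp
        if t1 <= t0:
            return
        if below:
            rate = (k[0] * (k[0] - 1) + k[1] * (k[1] - 1)) / 2.0 \
                + mig_rate * (k[0] + k[1])
        else:
            kk = k[0] + k[1]
            rate = kk * (kk - 1) / 2.0
        logp -= rate * (t1 - t0)

    for et, kind, data in evts:
        if below and et > T:
            interval(t, T)
            t = T
            below = False
        interval(t, et)
        t = et
        if kind == 1:
            old, new = data
            if M <= 0:
                return -math.inf
            logp += math.log(mig_rate)
            k[old] -= 1
            k[new] += 1
            if min(k) < 0:
                return -math.inf
        else:
            if below:
                lab = data
                k[lab] -= 1
                if k[lab] < 0:
                    return -math.inf
            else:
                # above T the two labels are one pool; decrement either
                if k[0] + k[1] < 2:
                    return -math.inf
                k[0 if k[0] > 0 else 1] -= 1
    return logp


# ---------------------------------------------------------------------------
# configuration and result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IMConfig:
    """Sampler settings.  Defaults follow common MDIV practice for mtDNA
    (M_max=10, T_max=5, 5e6 steps with 1e6 burn-in, three replicate
    chains); scale ``chain_length``/``burn_in`` down for quick runs."""

    M_max: float = 10.0
    T_max: float = 5.0
    theta_max: float | None = None  # None: 5x pooled Watterson estimate
    chain_length: int = 5_000_000
    burn_in: int = 1_000_000
    thinning: int = 50
    seed: int | None = None
    kappa: float | None = None  # None: method-of-moments from the data
    n_chains: int = 3
    n_bins: int = 100
    likelihood_on: bool = True
    constrain_root_above_split: bool = True

    def __post_init__(self):
        if self.burn_in >= self.chain_length:
            raise ValueError("burn_in must be < chain_length")
        if self.M_max <= 0 or self.T_max <= 0:
            raise ValueError("M_max and T_max must be > 0")


@dataclass
class DivergenceEstimate:
    theta_mode: float
    M_mode: float
    T_mode: float
    TMRCA_mode: float
    theta_hist: tuple
    M_hist: tuple
    T_hist: tuple
    samples: dict = field(default_factory=dict)  # thinned chains, pooled
    acceptance: dict = field(default_factory=dict)
    chain_modes: list = field(default_factory=list)
    kappa: float = 0.0
    warnings: list = field(default_factory=list)
    config: IMConfig | None = None

    def converged(self, tol_bins: int = 5) -> bool:
        """Crude multi-chain agreement: per-chain T modes within tol_bins
        histogram bins of one another."""
        if len(self.chain_modes) < 2 or self.config is None:
            return True
        width = self.config.T_max / self.config.n_bins
        t_modes = [m["T"] for m in self.chain_modes]
        return (max(t_modes) - min(t_modes)) <= tol_bins * width


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

def _init_tree(n1: int, n2: int, M: float, T: float, rng,
               require_root_above_T: bool) -> _IMTree:
    """Draw an initial valid labelled genealogy from the coalescent prior."""
    for _ in range(1000):
        tree = _IMTree(n1 + n2)
        n = n1 + n2
        tree.pop[:n1] = 0
        tree.pop[n1:n] = 1
        active = list(range(n))
        labs = {v: int(tree.pop[v]) for v in active}
        t, nxt = 0.0, n
        ok = True
        while len(active) > 1:
            k0 = sum(1 for v in active if labs[v] == 0)
            k1 = len(active) - k0
            if t < T:
                r_coal = (k0 * (k0 - 1) + k1 * (k1 - 1)) / 2.0
                r_mig = (M / 2.0) * len(active)
                total = r_coal + r_mig
                if total <= 0:
                    t = T
                    continue
                dt = rng.exponential(1.0 / total)
                if t + dt >= T:
                    t = T
                    continue
                t += dt
                if rng.random() < r_mig / total:
                    v = active[rng.integers(len(active))]
                    labs[v] = 1 - labs[v]
                    tree.events[v].append((t, labs[v]))
                    continue
                w0 = k0 * (k0 - 1) / 2.0
                pop = 0 if rng.random() * r_coal < w0 else 1
                cands = [v for v in active if labs[v] == pop]
            else:
                kk = len(active)
                t += rng.exponential(2.0 / (kk * (kk - 1)))
                cands = active
            i, j = rng.choice(len(cands), size=2, replace=False)
            a, b = cands[int(i)], cands[int(j)]
            tree.parent[a] = tree.parent[b] = nxt
            tree.children[nxt] = [a, b]
            tree.time[nxt] = t
            lab = tree.label_top(a)
            tree.pop[nxt] = lab
            labs[nxt] = lab
            active = [x for x in active if x not in (a, b)] + [nxt]
            nxt += 1
        if ok and (not require_root_above_T or tree.time[tree.root] >= T):
            return tree
    raise RuntimeError("could not initialise a valid genealogy")


def _resimulate_lineage(tree: _IMTree, c: int, M: float, T: float, rng) -> None:
    """Detach lineage c and redraw its path from the conditional structured
    coalescent given the rest of the genealogy (in place)."""
    p = int(tree.parent[c])
    sib = tree.children[p][0] if tree.children[p][1] == c else tree.children[p][1]
    g = int(tree.parent[p])
    if g >= 0:
        tree.events[sib] = tree.events[sib] + tree.events[p]
        tree.parent[sib] = g
        tree.children[g][tree.children[g].index(p)] = sib
    else:
        tree.events[sib] = []
        tree.parent[sib] = -1
    tree.parent[c] = -1
    tree.events[c] = []
    tree.events[p] = []
    tree.children[p] = []

    # --- timeline of the rest genealogy ---
    in_sub = np.zeros(len(tree.parent), dtype=bool)
    stack = [c]
    while stack:
        v = stack.pop()
        in_sub[v] = True
        stack.extend(tree.children[v])
    rest = [v for v in range(len(tree.parent))
            if not in_sub[v] and v != p and (tree.parent[v] >= 0 or tree.children[v] or v < tree.n)]
    rest_root = [v for v in rest if tree.parent[v] < 0]
    rr = rest_root[0]
    evts = []
    for v in rest:
        evts.append((tree.time[v], 0, v))  # lineage v starts (children end)
        for et, p_new in tree.events[v]:
            evts.append((et, 1, (v, p_new)))
    evts.sort(key=lambda e: (e[0], e[1]))

    cur: dict[int, int] = {}
    idx = 0

    def advance(to_t: float):
        nonlocal idx
        while idx < len(evts) and evts[idx][0] <= to_t:
            et, kind, data = evts[idx]
            if kind == 0:
                v = data
                for ch_ in tree.children[v]:
                    cur.pop(ch_, None)
                cur[v] = int(tree.pop[v])
            else:
                v, p_new = data
                cur[v] = p_new
            idx += 1

    t = float(tree.time[c])
    lab = int(tree.pop[c])
    my_events: list[tuple[float, int]] = []
    root_ext: list[tuple[float, int]] = []
    rr_time = float(tree.time[rr])
    rr_lab_holder = [None]  # filled when phase 2 starts
    advance(t)

    target = None
    while target is None:
        next_rest = evts[idx][0] if idx < len(evts) else math.inf
        phase2 = t >= rr_time and idx >= len(evts)
        if phase2 and rr_lab_holder[0] is None:
            # back-fill the root lineage's free migration path on
            # (rr_time, t]: it evolves by pure migration (rate M/2 below T)
            # before the re-simulated lineage exists
            lab0 = cur.get(rr, int(tree.pop[rr]))
            s = rr_time
            hi = min(T, t)
            while M > 0 and s < hi:
                s += rng.exponential(2.0 / M)
                if s >= hi:
                    break
                lab0 = 1 - lab0
                root_ext.append((s, lab0))
            rr_lab_holder[0] = lab0
        below = t < T
        if phase2:
            rr_lab = rr_lab_holder[0]
            if below:
                coal = 1.0 if rr_lab == lab else 0.0
                mig = M  # both free lineages migrate, M/2 each
            else:
                coal, mig = 1.0, 0.0
            stop = T if (below and T < math.inf) else math.inf
        else:
            if below:
                eligible = [v for v, l_ in cur.items() if l_ == lab]
                mig = M / 2.0
            else:
                eligible = list(cur)
                mig = 0.0
            coal = float(len(eligible))
            stop = min(next_rest, T if below else math.inf)
        total = coal + mig
        if total <= 0:
            if not math.isfinite(stop):
                raise RuntimeError("stuck lineage re-simulation")
            t = stop
            advance(t)
            continue
        dt = rng.exponential(1.0 / total)
        if t + dt > stop:
            t = stop
            advance(t)
            continue
        t += dt
        if rng.random() < mig / total:
            if phase2:
                # choose which of the two free lineages migrates
                if rng.random() < 0.5:
                    lab = 1 - lab
                    my_events.append((t, lab))
                else:
                    rr_lab_holder[0] = 1 - rr_lab_holder[0]
                    root_ext.append((t, rr_lab_holder[0]))
            else:
                lab = 1 - lab
                my_events.append((t, lab))
            continue
        if phase2:
            target = ("root", rr)
        else:
            target = ("edge", eligible[int(rng.integers(len(eligible)))])

    kind, x = target
    tree.events[c] = my_events
    tree.time[p] = t
    if kind == "edge":
        px = int(tree.parent[x])
        keep = [e for e in tree.events[x] if e[0] < t]
        move = [e for e in tree.events[x] if e[0] >= t]
        tree.events[x] = keep
        tree.events[p] = move
        tree.parent[p] = px
        if px >= 0:
            tree.children[px][tree.children[px].index(x)] = p
        tree.children[p] = [c, x]
        tree.parent[c] = p
        tree.parent[x] = p
        # bottom label of the merged upper edge continues x's trajectory
        tree.pop[p] = keep[-1][1] if keep else int(tree.pop[x])
    else:
        tree.events[rr] = root_ext
        tree.parent[p] = -1
        tree.children[p] = [c, rr]
        tree.parent[c] = p
        tree.parent[rr] = p
        tree.pop[p] = lab


def _slide_window(tree: _IMTree, v: int, T: float):
    c1, c2 = tree.children[v]
    lo = max(tree.time[c1], tree.time[c2])
    for ch_ in (c1, c2):
        if tree.events[ch_]:
            lo = max(lo, tree.events[ch_][-1][0])
    if tree.label_top(c1) != tree.label_top(c2):
        lo = max(lo, T)
    pv = int(tree.parent[v])
    hi = tree.time[pv]
    if tree.events[v]:
        hi = min(hi, tree.events[v][0][0])
    return lo, hi


def _histogram_mode(samples: np.ndarray, lo: float, hi: float, bins: int):
    hist, edges = np.histogram(samples, bins=bins, range=(lo, hi))
    i = int(np.argmax(hist))  # argmax takes the first (smallest) on ties
    mode = 0.5 * (edges[i] + edges[i + 1])
    return mode, (tuple(edges), tuple(int(h) for h in hist))


def _run_chain(pruner, n1, n2, L, cfg: IMConfig, theta_max, rng):
    M = cfg.M_max / 2.0
    T = cfg.T_max / 2.0
    tree = _init_tree(n1, n2, min(M, 1.0), T, rng,
                      cfg.constrain_root_above_split)
    theta = min(max(0.5, theta_max / 5.0), theta_max * 0.9)

    def loglik():
        if not cfg.likelihood_on:
            return 0.0
        return pruner.loglik(tree.parent, tree.time, tree.children,
                             (theta / 2.0) / L)

    logp = _prior_log(tree, M, T, cfg.constrain_root_above_split)
    logl = loglik()
    if not math.isfinite(logp):
        raise RuntimeError("invalid initial state")

    n_nodes = 2 * (n1 + n2) - 1
    tips = n1 + n2
    internal = [v for v in range(tips, n_nodes)]
    steps_th = theta_max / 10.0
    acc = {k: [0, 0] for k in ("lineage", "slide", "theta", "rescale", "M", "T")}
    out = {k: [] for k in ("theta", "M", "T", "tmrca", "n_mig")}

    for it in range(cfg.chain_length):
        u = rng.random()
        if u < 0.55:
            move = "lineage"
            acc[move][1] += 1
            snap = tree.snapshot()
            cands = [v for v in range(n_nodes) if tree.parent[v] >= 0]
            c = cands[int(rng.integers(len(cands)))]
            try:
                _resimulate_lineage(tree, c, M, T, rng)
            except RuntimeError:
                tree.restore(snap)
                continue
            # the re-simulated path is valid by construction; only the
            # optional root >= T restriction can invalidate the proposal
            if cfg.constrain_root_above_split and tree.time[tree.root] < T:
                tree.restore(snap)
                continue
            logl_new = loglik()
            if math.log(rng.random() + 1e-300) < logl_new - logl:
                logl = logl_new
                logp = _prior_log(tree, M, T, cfg.constrain_root_above_split)
                acc[move][0] += 1
            else:
                tree.restore(snap)
        elif u < 0.75:
            move = "slide"
            acc[move][1] += 1
            v = internal[int(rng.integers(len(internal)))]
            if tree.parent[v] < 0:
                continue
            lo, hi = _slide_window(tree, v, T)
            if hi <= lo:
                continue
            old_t = tree.time[v]
            tree.time[v] = rng.uniform(lo, hi)
            logp_new = _prior_log(tree, M, T, cfg.constrain_root_above_split)
            logl_new = loglik()
            if math.isfinite(logp_new) and math.log(rng.random() + 1e-300) < (
                logp_new + logl_new - logp - logl
            ):
                logp, logl = logp_new, logl_new
                acc[move][0] += 1
            else:
                tree.time[v] = old_t
        elif u < 0.80:
            move = "theta"
            acc[move][1] += 1
            # multiplicative log-normal walk; Hastings factor theta'/theta
            prop = theta * math.exp(rng.normal(0.0, 0.15))
            if prop <= 0 or prop > theta_max:
                continue
            old = theta
            theta = prop
            logl_new = loglik()
            if math.log(rng.random() + 1e-300) < (
                logl_new - logl + math.log(prop / old)
            ):
                logl = logl_new
                acc[move][0] += 1
            else:
                theta = old
        elif u < 0.85:
            # rescale move along the likelihood ridge: theta *= s, all times
            # (and T) /= s; branch lengths in substitutions are unchanged,
            # so only the prior and the Jacobian enter the ratio
            move = "rescale"
            acc[move][1] += 1
            s = math.exp(rng.uniform(-0.35, 0.35))
            theta_p, T_p = theta * s, T / s
            if theta_p > theta_max or T_p > cfg.T_max:
                continue
            snap = tree.snapshot()
            tree.time /= s
            for v in range(n_nodes):
                if tree.events[v]:
                    tree.events[v] = [(t_ / s, p_) for t_, p_ in tree.events[v]]
            logp_new = _prior_log(tree, M, T_p, cfg.constrain_root_above_split)
            n_scaled = (tips - 1) + tree.n_migrations() + 1
            log_ratio = logp_new - logp + (1 - n_scaled) * math.log(s)
            if math.isfinite(logp_new) and math.log(rng.random() + 1e-300) < log_ratio:
                theta, T, logp = theta_p, T_p, logp_new
                acc[move][0] += 1
            else:
                tree.restore(snap)
        elif u < 0.93:
            move = "M"
            acc[move][1] += 1
            # exact Gibbs draw from M's truncated-Gamma full conditional
            M = _gibbs_migration_rate(tree, T, cfg.M_max, rng)
            logp = _prior_log(tree, M, T, cfg.constrain_root_above_split)
            acc[move][0] += 1
        else:
            move = "T"
            acc[move][1] += 1
            T = _gibbs_split_time(tree, M, cfg.T_max,
                                  cfg.constrain_root_above_split, T, rng)
            logp = _prior_log(tree, M, T, cfg.constrain_root_above_split)
            acc[move][0] += 1
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thinning == 0:
            out["theta"].append(theta)
            out["M"].append(M)
            out["T"].append(T)
            out["tmrca"].append(float(tree.time[tree.root]))
            out["n_mig"].append(tree.n_migrations())
    rates = {k: (a / max(b, 1)) for k, (a, b) in acc.items()}
    return {k: np.asarray(v) for k, v in out.items()}, rates


def im_mcmc(
    alignment_pop1: Alignment,
    alignment_pop2: Alignment,
    config: IMConfig = IMConfig(),
) -> DivergenceEstimate:
    """Run the IM sampler on two population samples of equal length."""
    if alignment_pop1.length != alignment_pop2.length:
        raise ValueError("population alignments differ in length")
    if alignment_pop1.n < 2 or alignment_pop2.n < 2:
        raise ValueError("need >= 2 sequences per population")
    n1, n2 = alignment_pop1.n, alignment_pop2.n
    L = alignment_pop1.length
    combined = Alignment.from_records(
        list(zip(alignment_pop1.ids, alignment_pop1.seqs))
        + [(f"p2_{i}", s) for i, s in zip(alignment_pop2.ids, alignment_pop2.seqs)]
    )
    codes = _encode(combined)
    freqs = empirical_base_freqs(codes)
    kappa = config.kappa if config.kappa is not None else estimate_kappa(codes, freqs)
    pruner = _Pruner(codes, kappa, freqs)

    if config.theta_max is not None:
        theta_max = config.theta_max
    else:
        seg = int((codes.max(axis=0) != codes.min(axis=0)).sum())
        n = n1 + n2
        a1 = sum(1.0 / i for i in range(1, n))
        theta_max = max(5.0 * seg / a1, 5.0)

    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.spawn(config.n_chains)
    pooled = {k: [] for k in ("theta", "M", "T", "tmrca", "n_mig")}
    chain_modes = []
    rates_all = []
    for cs in chain_seeds:
        rng = np.random.default_rng(cs)
        out, rates = _run_chain(pruner, n1, n2, L, config, theta_max, rng)
        rates_all.append(rates)
        t_mode, _ = _histogram_mode(out["T"], 0, config.T_max, config.n_bins)
        m_mode, _ = _histogram_mode(out["M"], 0, config.M_max, config.n_bins)
        chain_modes.append({"T": t_mode, "M": m_mode})
        for k in pooled:
            pooled[k].append(out[k])
    samples = {k: np.concatenate(v) for k, v in pooled.items()}

    theta_mode, theta_hist = _histogram_mode(
        samples["theta"], 0, theta_max, config.n_bins)
    M_mode, M_hist = _histogram_mode(samples["M"], 0, config.M_max, config.n_bins)
    T_mode, T_hist = _histogram_mode(samples["T"], 0, config.T_max, config.n_bins)
    tm = samples["tmrca"]
    TMRCA_mode, _ = _histogram_mode(tm, 0, float(tm.max()) * 1.0001,
                                    config.n_bins)

    warnings = []
    for name, mode, hi in (("theta", theta_mode, theta_max),
                           ("M", M_mode, config.M_max),
                           ("T", T_mode, config.T_max)):
        width = hi / config.n_bins
        if mode > hi - width:
            warnings.append(f"{name} posterior mode at the prior upper bound")
    est = DivergenceEstimate(
        theta_mode=theta_mode, M_mode=M_mode, T_mode=T_mode,
        TMRCA_mode=TMRCA_mode,
        theta_hist=theta_hist, M_hist=M_hist, T_hist=T_hist,
        samples=samples,
        acceptance={k: float(np.mean([r[k] for r in rates_all]))
                    for k in rates_all[0]},
        chain_modes=chain_modes, kappa=kappa, warnings=warnings,
        config=config,
    )
    if not est.converged():
        est.warnings.append("replicate chains disagree on the T mode")
    return est


def write_posterior_histograms(est: DivergenceEstimate, path) -> None:
    """Dump the gridded posterior histograms as a TSV:
    parameter, bin_left, bin_right, mass."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("parameter\tbin_left\tbin_right\tmass\n")
        for name, (edges, hist) in (("theta", est.theta_hist),
                                    ("M", est.M_hist), ("T", est.T_hist)):
            total = sum(hist) or 1
            for i, h in enumerate(hist):
                fh.write(f"{name}\t{edges[i]:.6g}\t{edges[i + 1]:.6g}"
                         f"\t{h / total:.6g}\n")


def write_im_config(config: IMConfig, path) -> None:
    """Write every sampler setting as plain key=value lines."""
    from dataclasses import fields as _fields

    with open(path, "w", encoding="utf-8") as fh:
        for f in _fields(config):
            fh.write(f"{f.name}={getattr(config, f.name)}\n")


def convert_divergence(
    theta_mode: float,
    T_mode: float,
    TMRCA_mode: float,
    L: int = 596,
    rate_per_site_per_year: float = 1.1e-8,
    generation_years: float = 1.5,
    pairwise_rate: bool = False,
) -> dict:
    """Convert posterior modes to female effective size and calendar times.

    With mu = per-site per-generation rate (= rate_per_site_per_year x
    generation time):

    * Ne_female = theta / (2 L mu)
    * T_pop     = [(T theta) / (2 L)] x (1/mu) generations, x generation
      time for years (TMRCA transformed identically).

    Every factor is echoed in the returned mapping for auditability.
    """
    if min(theta_mode, L, rate_per_site_per_year, generation_years) <= 0:
        raise ValueError("inputs must be positive")
    rate = rate_per_site_per_year / 2.0 if pairwise_rate else rate_per_site_per_year
    mu_gen = rate * generation_years
    ne_female = theta_mode / (2.0 * L * mu_gen)
    t_pop_gen = (T_mode * theta_mode) / (2.0 * L) / mu_gen
    tmrca_gen = (TMRCA_mode * theta_mode) / (2.0 * L) / mu_gen
    return {
        "Ne_female": ne_female,
        "T_pop_generations": t_pop_gen,
        "T_pop_years": t_pop_gen * generation_years,
        "T_pop_Myr": t_pop_gen * generation_years / 1e6,
        "TMRCA_generations": tmrca_gen,
        "TMRCA_years": tmrca_gen * generation_years,
        "TMRCA_Myr": tmrca_gen * generation_years / 1e6,
        "mu_per_site_per_generation": mu_gen,
        "rate_per_site_per_year": rate,
        "rate_interpretation": "pairwise" if pairwise_rate else "per-lineage",
        "generation_years": generation_years,
        "L": L,
        "theta": theta_mode,
        "T": T_mode,
        "TMRCA": TMRCA_mode,
    }
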
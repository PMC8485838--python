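"""Single-locus structured coalescent with finite-sites HKY mutation.

The engine simulates the genealogy of a non-recombining, uniparentally
inherited locus (cpDNA) backward in time under a population tree with
divergence (merge), admixture and size-change events, then overlays
mutations.  Effective population sizes are *haploid copy numbers*: the
pairwise coalescence rate within a population of size N is 1/N per
generation, so a sample of two coalesces on average N generations ago.
This is the natural convention for organelle loci and scales every prior
time directly in generations.

Two mutation overlays are provided:

* :func:`hky_site_matrix` — finite-sites HKY (Hasegawa-Kishino-Yano)
  mutation at a per-site per-generation rate, implemented as an exact
  thinned Poisson process on the genealogy (with the default equal base
  frequencies the thinning accepts every candidate event).
* :func:`fixed_s_patterns` — exactly S mutations placed on branches with
  probability proportional to branch length, the standard device for
  null distributions of neutrality statistics conditioned on the observed
  number of segregating sites.

Determinism: every public function takes a :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

BASES = "ACGT"
EQUAL_FREQS = (0.25, 0.25, 0.25, 0.25)


@dataclass
class Event:
    """A demographic event, applied backward in time.

    kind:
        ``"merge"``      — move all lineages from ``sources`` into ``dest``.
        ``"admixture"``  — each lineage in ``dest`` (the admixed, more
                           recent population) moves to ``sources[0]`` with
                           probability ``rate`` and to ``sources[1]``
                           otherwise.
        ``"size"``       — population ``dest`` changes size to ``size``.
    """

    kind: str
    time: float
    dest: str
    sources: tuple[str, ...] = ()
    rate: float | None = None
    size: float | None = None


@dataclass
class Genealogy:
    """A coalescent tree: ``parent[v]`` (-1 at the root) and node times.

    Tips are nodes ``0 .. n_tips-1`` at time 0; internal nodes follow in
    coalescence order.  ``tip_pops`` records each tip's population label.
    """

    parent: np.ndarray
    time: np.ndarray
    n_tips: int
    tip_pops: list[str]

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for the root)."""
        out = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        out[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return out

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def membership(self) -> np.ndarray:
        """Boolean (n_tips, n_nodes): tip i descends from (or is) node v."""
        m = np.zeros((self.n_tips, self.n_nodes), dtype=bool)
        idx = np.arange(self.n_tips)
        m[idx, idx] = True
        # children are always created before their parent, so one sweep works
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0:
                m[:, p] |= m[:, v]
        return m

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(v)
        return ch

    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])


def simulate_genealogy(
    samples: Mapping[str, int],
    sizes: Mapping[str, float],
    events: Sequence[Event] = (),
    rng: np.random.Generator | None = None,
) -> Genealogy:
    """Simulate a Kingman genealogy on a population tree with events.

    ``samples`` maps population labels to sample sizes; ``sizes`` to
    haploid effective sizes.  Events are applied in time order; the event
    list must eventually bring all lineages into one population, otherwise
    a non-coalescing configuration is reported.
    """
    rng = rng if rng is not None else np.random.default_rng()
    tip_pops: list[str] = []
    active: dict[str, list[int]] = {}
    node = 0
    for pop, n in samples.items():
        if n < 0:
            raise ValueError("negative sample size")
        active[pop] = list(range(node, node + n))
        tip_pops.extend([pop] * n)
        node += n
    n_tips = node
    if n_tips < 2:
        raise ValueError("need at least two sampled lineages")
    size = {p: float(s) for p, s in sizes.items()}
    for p in active:
        if p not in size:
            raise ValueError(f"no size for population {p!r}")

    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    queue = sorted(events, key=lambda e: e.time)
    ei = 0
    t = 0.0
    n_active = n_tips
    while n_active > 1:
        pop_rates: list[tuple[str, float]] = []
        total_rate = 0.0
        for p, l in active.items():
            k = len(l)
            if k >= 2:
                r = k * (k - 1) / 2.0 / size[p]
                pop_rates.append((p, r))
                total_rate += r
        t_event = queue[ei].time if ei < len(queue) else np.inf
        if total_rate > 0:
            wait = rng.exponential() / total_rate
        else:
            wait = np.inf
        if t + wait >= t_event:
            if not np.isfinite(t_event):
                raise RuntimeError(
                    "non-coalescing configuration: lineages remain in separate "
                    "populations and no further events are scheduled"
                )
            t = t_event
            ev = queue[ei]
            ei += 1
            if ev.kind == "merge":
                active.setdefault(ev.dest, [])
                for src in ev.sources:
                    active[ev.dest].extend(active.pop(src, []))
            elif ev.kind == "admixture":
                pool = active.pop(ev.dest, [])
                p1, p2 = ev.sources
                active.setdefault(p1, [])
                active.setdefault(p2, [])
                goes_first = rng.random(len(pool)) < ev.rate
                for lin, first in zip(pool, goes_first):
                    active[p1 if first else p2].append(lin)
            elif ev.kind == "size":
                size[ev.dest] = float(ev.size)
            else:
                raise ValueError(f"unknown event kind {ev.kind!r}")
            continue
        t += wait
        if len(pop_rates) == 1:
            pop = pop_rates[0][0]
        else:
            u = rng.random() * total_rate
            acc = 0.0
            pop = pop_rates[-1][0]
            for p, r in pop_rates:
                acc += r
                if u <= acc:
                    pop = p
                    break
        lineages = active[pop]
        k = len(lineages)
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a, b = lineages[i], lineages[j]
        new = n_tips + (n_nodes - n_tips) - (n_active - 1)
        parent[a] = parent[b] = new
        time[new] = t
        for idx in sorted((i, j), reverse=True):
            lineages[idx] = lineages[-1]
            lineages.pop()
        lineages.append(new)
        n_active -= 1
    return Genealogy(parent, time, n_tips, tip_pops)


def constant_size_tree(n: int, N: float, rng: np.random.Generator) -> Genealogy:
    """Single constant-size population, the plain Kingman coalescent."""
    return simulate_genealogy({"pop": n}, {"pop": N}, (), rng)


# ---------------------------------------------------------------------------
# mutation overlays


def hky_rate_matrix(
    mu: float, kappa: float = 2.0, freqs: Sequence[float] = EQUAL_FREQS
) -> np.ndarray:
    """HKY instantaneous rate matrix scaled to mean substitution rate ``mu``.

    Rows/columns follow A, C, G, T; transitions (A<->G, C<->T) are
    weighted by ``kappa``.
    """
    pi = np.asarray(freqs, dtype=float)
    if pi.shape != (4,) or not np.isclose(pi.sum(), 1.0) or (pi <= 0).any():
        raise ValueError("freqs must be 4 positive values summing to 1")
    q = np.tile(pi, (4, 1))
    transitions = [(0, 2), (2, 0), (1, 3), (3, 1)]
    for a, b in transitions:
        q[a, b] *= kappa
    np.fill_diagonal(q, 0.0)
    away = q.sum(axis=1)
    scale = mu / float(pi @ away)
    return q * scale


def hky_site_matrix(
    tree: Genealogy,
    L: int,
    mu: float,
    rng: np.random.Generator,
    kappa: float = 2.0,
    freqs: Sequence[float] = EQUAL_FREQS,
    keep_monomorphic: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Overlay finite-sites HKY mutation; return mutated site columns.

    Returns ``(positions, codes)`` where ``positions`` are 0-based site
    indices hit by at least one accepted substitution and ``codes`` is an
    ``(n_tips, len(positions))`` int8 matrix of bases (0=A,1=C,2=G,3=T).
    Sites never hit are monomorphic and omitted.  Exactness: candidate
    events are generated at the maximal per-base rate and thinned by the
    current base's actual rate, which reproduces the HKY process without
    matrix exponentials.
    """
    q = hky_rate_matrix(mu, kappa, freqs)
    away = q.sum(axis=1)
    r_max = float(away.max())
    lengths = tree.branch_lengths()
    total = float(lengths.sum())
    n_cand = rng.poisson(r_max * L * total)
    if n_cand == 0:
        return np.empty(0, dtype=np.int64), np.empty((tree.n_tips, 0), dtype=np.int8)

    u = rng.random(n_cand) * total
    cum = np.cumsum(lengths)
    branch = np.searchsorted(cum, u)
    site = rng.integers(0, L, size=n_cand)
    # position along the branch measured as absolute time (older = larger)
    frac = rng.random(n_cand)
    node_time = tree.time[branch]
    ev_time = node_time + frac * lengths[branch]

    root = tree.root()
    pi = np.asarray(freqs, dtype=float)
    pi_cdf = np.cumsum(pi)
    cond_cdf = np.cumsum(q, axis=1) / away[:, None]  # target base given source

    by_site: dict[int, list[tuple[int, float]]] = {}
    for b, s, tt in zip(branch, site, ev_time):
        by_site.setdefault(int(s), []).append((int(b), float(tt)))

    member = tree.membership()
    children = None
    positions: list[int] = []
    columns: list[np.ndarray] = []
    is_tip = np.arange(tree.n_nodes) < tree.n_tips
    for s in sorted(by_site):
        events = by_site[s]
        root_base = int(np.searchsorted(pi_cdf, rng.random()))
        if len(events) == 1:
            # fast path: one candidate event on one branch
            b, _ = events[0]
            col = np.full(tree.n_tips, root_base, dtype=np.int8)
            if rng.random() < away[root_base] / r_max:
                derived = int(np.searchsorted(cond_cdf[root_base], rng.random()))
                col[member[:, b]] = derived
        else:
            if children is None:
                children = tree.children()
            # per-branch events sorted old -> young (descending time)
            per_branch: dict[int, list[float]] = {}
            for b, tt in events:
                per_branch.setdefault(b, []).append(tt)
            for b in per_branch:
                per_branch[b].sort(reverse=True)
            col = np.full(tree.n_tips, root_base, dtype=np.int8)
            stack = [(root, root_base)]
            while stack:
                v, base = stack.pop()
                if v != root and v in per_branch:
                    for _ in per_branch[v]:
                        if rng.random() < away[base] / r_max:
                            base = int(np.searchsorted(cond_cdf[base], rng.random()))
                if is_tip[v]:
                    col[v] = base
                for c in children[v]:
                    stack.append((c, base))
        if keep_monomorphic or (col != col[0]).any():
            positions.append(s)
            columns.append(col)
    if not positions:
        return np.empty(0, dtype=np.int64), np.empty((tree.n_tips, 0), dtype=np.int8)
    return np.asarray(positions, dtype=np.int64), np.column_stack(columns)


def fixed_s_patterns(
    tree: Genealogy, S: int, rng: np.random.Generator
) -> np.ndarray:
    """Place exactly S mutations on branches with probability ~ length.

    Returns a boolean ``(n_tips, S)`` matrix: entry (i, m) is True when
    tip i carries the derived state of mutation m (infinite-sites).
    """
    lengths = tree.branch_lengths()
    p = lengths / lengths.sum()
    branches = rng.choice(tree.n_nodes, size=S, p=p)
    member = tree.membership()
    return member[:, branches]


def poisson_branch_mutations(
    tree: Genealogy, rate_per_gen: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson number of infinite-sites mutations per branch (per locus)."""
    return rng.poisson(rate_per_gen * tree.branch_lengths())


def pairwise_difference_matrix(
    tree: Genealogy, branch_mutations: np.ndarray
) -> np.ndarray:
    """Pairwise difference counts implied by per-branch mutation counts.

    Uses d(i, j) = s_i + s_j - 2 (B W B^T)_{ij} with B the tip/branch
    membership matrix and W the per-branch mutation counts, avoiding any
    per-mutation loop.
    """
    member = tree.membership().astype(np.float64)
    w = branch_mutations.astype(np.float64)
    s = member @ w
    cross = (member * w) @ member.T
    d = s[:, None] + s[None, :] - 2.0 * cross
    np.fill_diagonal(d, 0.0)
    return d.astype(np.int64)
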
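"""Haplotype collapsing and median-joining network construction.

Chloroplast DNA is non-recombining, so after complete-column filtering two
samples share a haplotype exactly when their sequences are identical.  The
median-joining (MJ) algorithm of Bandelt, Forster & Röhl (1999) augments
the observed haplotypes with inferred "median vectors" (unsampled
intermediates) so that the final minimum-spanning network connects every
haplotype through single-step mutational paths where possible.

Determinism: ties inside MJ (equal-cost medians, ambiguous majority
columns) are broken by lexicographic order of node labels, so the output
depends only on the input, not on iteration order.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .alignment import Alignment, SampleMetadata, metadata_index

logger = logging.getLogger(__name__)


@dataclass
class HaplotypeTable:
    """Unique haplotypes with per-population counts.

    ``labels`` follow first-observed order in the alignment (H01, H02, ...),
    mirroring the conventional numbering style without claiming any
    particular published numbering.  ``counts`` is a (haplotype x
    population) integer DataFrame whose column sums equal the population
    sample sizes.
    """

    sequences: list[str]
    labels: list[str]
    counts: pd.DataFrame
    sample_haplotype: dict[str, str]

    @property
    def n_haplotypes(self) -> int:
        return len(self.sequences)

    @property
    def n_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def total_counts(self) -> np.ndarray:
        """Per-haplotype counts pooled over populations, in label order."""
        return self.counts.to_numpy().sum(axis=1)

    def population_summary(self) -> pd.DataFrame:
        """Per-population row shaped like a sampling table: n and 'H03(4), ...'."""
        rows = []
        for pop in self.counts.columns:
            col = self.counts[pop]
            present = col[col > 0]
            desc = ", ".join(f"{h}({int(c)})" for h, c in present.items())
            rows.append((pop, int(col.sum()), desc))
        return pd.DataFrame(rows, columns=["population", "n", "haplotypes"])

    def write_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "sequence", self.sequences)
        out.to_csv(path, sep="\t", index_label="haplotype")


def collapse_haplotypes(
    aln: Alignment, meta: Sequence[SampleMetadata] | Mapping[str, SampleMetadata]
) -> HaplotypeTable:
    """Collapse identical sequences into haplotypes counted per population.

    The alignment must already be gap-free (complete-column filtered).
    """
    index = meta if isinstance(meta, Mapping) else metadata_index(meta)
    missing = [s for s in aln.sample_ids if s not in index]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")

    seq_to_label: dict[str, str] = {}
    sequences: list[str] = []
    labels: list[str] = []
    sample_haplotype: dict[str, str] = {}
    populations: list[str] = []
    for sid, seq in zip(aln.sample_ids, aln.sequences):
        if seq not in seq_to_label:
            label = f"H{len(sequences) + 1:02d}"
            seq_to_label[seq] = label
            sequences.append(seq)
            labels.append(label)
        sample_haplotype[sid] = seq_to_label[seq]
        pop = index[sid].population
        if pop not in populations:
            populations.append(pop)

    counts = pd.DataFrame(0, index=labels, columns=populations, dtype=int)
    for sid in aln.sample_ids:
        counts.loc[sample_haplotype[sid], index[sid].population] += 1
    logger.info(
        "collapsed %d samples into %d haplotypes over %d populations",
        aln.n_samples, len(labels), len(populations),
    )
    return HaplotypeTable(sequences, labels, counts, sample_haplotype)


def hamming_matrix(sequences: Sequence[str]) -> np.ndarray:
    """Pairwise count of differing sites between equal-length sequences."""
    mat = np.array([list(s) for s in sequences], dtype="U1")
    n = mat.shape[0]
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        d[i] = (mat != mat[i]).sum(axis=1)
    return d


@dataclass
class Network:
    """A haplotype network: observed haplotypes plus inferred medians.

    ``graph`` is an undirected :class:`networkx.Graph`; node attributes are
    ``sequence``, ``is_median`` and (for observed nodes) ``count``; edge
    attribute ``weight`` is the Hamming distance between the endpoint
    sequences (mutation steps).
    """

    graph: nx.Graph
    epsilon: int = 0

    @property
    def median_labels(self) -> list[str]:
        return [v for v, d in self.graph.nodes(data=True) if d["is_median"]]

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))

    def write_nexus(self, path: str | Path) -> None:
        """Write a minimal Nexus file with a Network block (POPART-style)."""
        g = self.graph
        lines = ["#NEXUS", "BEGIN NETWORK;", f"  DIMENSIONS NVERTICES={g.number_of_nodes()};"]
        lines.append("  [vertex: label sequence median_flag]")
        for v, d in sorted(g.nodes(data=True)):
            flag = "median" if d["is_median"] else "observed"
            lines.append(f"  VERTEX {v} {d['sequence']} [{flag}]")
        lines.append("  [edge: u v steps]")
        for u, v, d in sorted(g.edges(data=True)):
            lines.append(f"  EDGE {u} {v} {d['weight']}")
        lines.append("END;")
        Path(path).write_text("\n".join(lines) + "\n")


def _distance_matrix(seqs: list[str]) -> np.ndarray:
    return hamming_matrix(seqs)


def minimum_spanning_network(labels: list[str], d: np.ndarray, epsilon: int = 0) -> set[tuple[int, int]]:
    """Edge set of the epsilon-relaxed minimum-spanning network.

    An edge (u, v) belongs to the MSN iff d(u, v) <= dc(u, v) + epsilon,
    where dc is the minimax path cost (the largest edge weight on the
    path between u and v in any minimum spanning tree).  With epsilon = 0
    every minimum spanning tree is a subgraph of the MSN.
    """
    n = d.shape[0]
    if n == 1:
        return set()
    order = np.argsort([lab for lab in labels], kind="stable")  # noqa: F841  (labels already sorted on entry)
    # Build one MST with deterministic tie-breaking (lexicographic labels).
    edges = sorted(
        ((int(d[i, j]), labels[i], labels[j], i, j) for i in range(n) for j in range(i + 1, n)),
    )
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    mst = nx.Graph()
    mst.add_nodes_from(range(n))
    for w, _, _, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            mst.add_edge(i, j, weight=w)

    # Minimax path cost between all pairs via per-node traversal of the MST.
    dc = np.zeros((n, n), dtype=int)
    for src in range(n):
        seen = {src}
        stack = [(src, 0)]
        while stack:
            node, best = stack.pop()
            for nbr in mst.neighbors(node):
                if nbr not in seen:
                    seen.add(nbr)
                    cost = max(best, mst.edges[node, nbr]["weight"])
                    dc[src, nbr] = cost
                    stack.append((nbr, cost))

    return {
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if d[i, j] <= dc[i, j] + epsilon
    }


def _median_sequence(seqs: tuple[str, str, str], tie_owner: int) -> str:
    """Column-wise majority consensus; three-way ties take *tie_owner*'s base."""
    out = []
    for bases in zip(*seqs):
        if bases[0] == bases[1] or bases[0] == bases[2]:
            out.append(bases[0])
        elif bases[1] == bases[2]:
            out.append(bases[1])
        else:
            out.append(bases[tie_owner])
    return "".join(out)


def median_joining_network(
    table: HaplotypeTable, epsilon: int = 0, max_iter: int = 50
) -> Network:
    """Bandelt-Forster-Röhl median-joining network.

    Iterates: (i) epsilon-relaxed minimum-spanning network over the current
    node set; (ii) for every connected triple, the majority-consensus
    median vector is generated and added when its connection cost is within
    epsilon of the minimum over all candidate medians; (iii) median vectors
    of degree <= 2 are removed.  Terminates at a fixed point with a
    connected network whose edge weights equal Hamming distances.
    """
    if table.n_haplotypes < 2:
        raise ValueError("median-joining network needs at least 2 haplotypes")

    seqs: dict[str, str] = dict(zip(table.labels, table.sequences))
    observed = set(table.labels)
    existing = set(table.sequences)
    banned: set[str] = set()  # medians removed as obsolete; never re-proposed
    n_median = 0

    def msn_edges(node_seqs: dict[str, str]) -> tuple[list[str], np.ndarray, set[tuple[int, int]]]:
        labels = sorted(node_seqs)
        d = _distance_matrix([node_seqs[v] for v in labels])
        return labels, d, minimum_spanning_network(labels, d, epsilon)

    for _ in range(max_iter):
        labels, d, edges = msn_edges(seqs)
        adj: dict[str, set[str]] = {v: set() for v in labels}
        for i, j in edges:
            adj[labels[i]].add(labels[j])
            adj[labels[j]].add(labels[i])

        # Candidate medians from connected triples (two of three links present).
        candidates: dict[str, int] = {}
        for centre in labels:
            for u, w in itertools.combinations(sorted(adj[centre]), 2):
                triple = tuple(sorted((centre, u, w)))
                m = _median_sequence(tuple(seqs[t] for t in triple), tie_owner=0)
                if m in existing or m in banned:
                    continue
                cost = sum(sum(a != b for a, b in zip(m, seqs[t])) for t in triple)
                if m not in candidates or cost < candidates[m]:
                    candidates[m] = cost
        added = False
        if candidates:
            lam = min(candidates.values())
            for m, cost in sorted(candidates.items()):
                if cost <= lam + epsilon:
                    n_median += 1
                    seqs[f"mv{n_median:02d}"] = m
                    existing.add(m)
                    added = True

        # Cleanup: drop obsolete medians (degree <= 2 in the refreshed MSN).
        while True:
            labels, d, edges = msn_edges(seqs)
            degree = {v: 0 for v in labels}
            for i, j in edges:
                degree[labels[i]] += 1
                degree[labels[j]] += 1
            obsolete = [v for v in labels if v not in observed and degree[v] <= 2]
            if not obsolete:
                break
            for v in obsolete:
                existing.discard(seqs[v])
                banned.add(seqs[v])
                del seqs[v]
        if not added:
            break

    labels, d, edges = msn_edges(seqs)
    g = nx.Graph(epsilon=epsilon)
    count_by_label = dict(zip(table.labels, table.total_counts))
    for v in labels:
        g.add_node(
            v,
            sequence=seqs[v],
            is_median=v not in observed,
            count=int(count_by_label.get(v, 0)),
        )
    for i, j in edges:
        g.add_edge(labels[i], labels[j], weight=int(d[i, j]))
    net = Network(g, epsilon)
    logger.info(
        "median-joining network: %d observed + %d median nodes, %d edges",
        len(observed), len(net.median_labels), g.number_of_edges(),
    )
    return net
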
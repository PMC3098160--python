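"""Signed directed gene-network topologies.

A :class:`SignedNetwork` is the ground-truth (or inferred) wiring of a gene
regulatory network: a set of directed edges ``regulator -> target`` each
carrying a sign, +1 for activation and -1 for repression.  Benchmark
networks are obtained the way in-silico benchmark suites build them: a large
scale-free "source" network stands in for a real transcriptional network
(E. coli scale), and test networks are grown out of it from a random seed
node by repeatedly absorbing a random neighbour until the requested size is
reached, then taking the induced subgraph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "SignedNetwork",
    "generate_source_topology",
    "extract_subnetwork",
    "read_edge_list",
    "write_edge_list",
]


@dataclass
class SignedNetwork:
    """Signed directed graph over a fixed gene set.

    Parameters
    ----------
    gene_names
        Ordered gene identifiers; row/column order of every matrix view.
    edges
        Set of ``(regulator, target, sign)`` with ``sign in {+1, -1}``.
    """

    gene_names: list[str]
    edges: set[tuple[str, str, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        names = set(self.gene_names)
        if len(names) != len(self.gene_names):
            raise ValueError("duplicate gene names")
        for reg, tgt, sign in self.edges:
            if reg not in names or tgt not in names:
                raise ValueError(f"edge endpoint {reg!r}->{tgt!r} not a listed gene")
            if sign not in (1, -1):
                raise ValueError(f"edge sign must be +1 or -1, got {sign}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    # spec alias
    N = n_genes

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        """Signed adjacency ``A[i, j] = sign`` of edge gene_j -> gene_i.

        Row = target, column = regulator, matching the convention that entry
        (i, j) of a regulatory matrix is the effect of gene j on gene i.
        """
        idx = {g: k for k, g in enumerate(self.gene_names)}
        a = np.zeros((self.n_genes, self.n_genes))
        for reg, tgt, sign in self.edges:
            a[idx[tgt], idx[reg]] = sign
        return a

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.gene_names)
        for reg, tgt, sign in self.edges:
            g.add_edge(reg, tgt, sign=sign)
        return g

    @classmethod
    def from_networkx(cls, g: nx.DiGraph) -> "SignedNetwork":
        edges = {(u, v, int(d.get("sign", 1))) for u, v, d in g.edges(data=True)}
        return cls(gene_names=list(g.nodes), edges=edges)


def generate_source_topology(
    n_genes: int,
    avg_degree: float = 2.0,
    activation_fraction: float = 0.6,
    seed: int = 0,
) -> SignedNetwork:
    """Generate a weakly connected, heavy-tailed signed source network.

    Out-degrees follow a preferential-attachment (scale-free) rule, the
    hallmark of transcriptional networks where a few master regulators have
    many targets.  Edge signs are +1 with probability ``activation_fraction``.

    Parameters
    ----------
    n_genes
        Number of genes, >= 2.
    avg_degree
        Target mean number of regulatory inputs per gene (>= 1).
    activation_fraction
        Probability that an edge is activating.
    seed
        Seed for the random generator; output is deterministic given it.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    if avg_degree < 1:
        raise ValueError("avg_degree must be >= 1")
    if avg_degree >= n_genes:
        raise ValueError("avg_degree must be smaller than n_genes")
    rng = np.random.default_rng(seed)

    names = [f"G{k:03d}" for k in range(n_genes)]
    n_edges_target = int(round(avg_degree * n_genes))

    # Preferential attachment on regulator choice: grow node by node, each
    # new node wired to existing ones; remaining edges added by degree-biased
    # sampling.  Guarantees weak connectivity.
    edges: set[tuple[int, int]] = set()
    out_weight = np.ones(n_genes)
    order = rng.permutation(n_genes)
    for pos in range(1, n_genes):
        node = order[pos]
        prev = order[:pos]
        w = out_weight[prev]
        reg = prev[rng.choice(pos, p=w / w.sum())]
        if rng.random() < 0.5:
            edges.add((int(reg), int(node)))
            out_weight[reg] += 1.0
        else:
            edges.add((int(node), int(reg)))
            out_weight[node] += 1.0
    attempts = 0
    while len(edges) < n_edges_target and attempts < 50 * n_edges_target:
        attempts += 1
        w = out_weight / out_weight.sum()
        reg = int(rng.choice(n_genes, p=w))
        tgt = int(rng.integers(n_genes))
        if reg == tgt or (reg, tgt) in edges:
            continue
        edges.add((reg, tgt))
        out_weight[reg] += 1.0

    signed = set()
    for reg, tgt in sorted(edges):
        sign = 1 if rng.random() < activation_fraction else -1
        signed.add((names[reg], names[tgt], sign))
    return SignedNetwork(gene_names=names, edges=signed)


def extract_subnetwork(source: SignedNetwork, size: int, seed: int = 0) -> SignedNetwork:
    """Grow a subnetwork from a random seed node of ``source``.

    Starting from one random node, a randomly selected neighbour (in the
    undirected sense) of the current node set is added until ``size`` nodes
    are collected; the induced signed subgraph on that node set is returned.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    if size > source.n_genes:
        raise ValueError(
            f"requested size {size} exceeds source network size {source.n_genes}"
        )
    rng = np.random.default_rng(seed)
    g = source.to_networkx()
    und = g.to_undirected()

    nodes = list(source.gene_names)
    current = {nodes[rng.integers(len(nodes))]}
    while len(current) < size:
        frontier = sorted(
            {nb for n in current for nb in und.neighbors(n)} - current
        )
        if not frontier:  # disconnected source: restart growth elsewhere
            rest = sorted(set(nodes) - current)
            frontier = rest
        current.add(frontier[rng.integers(len(frontier))])

    members = [g_ for g_ in source.gene_names if g_ in current]
    member_set = set(members)
    edges = {
        (r, t, s) for (r, t, s) in source.edges if r in member_set and t in member_set
    }
    return SignedNetwork(gene_names=members, edges=edges)


_SIF_RELATIONS = {"activates": 1, "represses": -1}
_SIGN_TOKENS = {"+": 1, "-": -1, "+1": 1, "-1": -1, "1": 1}


def read_edge_list(path: str) -> SignedNetwork:
    """Read a signed edge list.

    Accepts the 3-column TSV dialect ``regulator<TAB>target<TAB>sign`` with
    sign in {+, -, +1, -1} and the SIF dialect
    ``node<TAB>activates|represses<TAB>node``.
    """
    edges: set[tuple[str, str, int]] = set()
    names: list[str] = []
    seen: set[str] = set()

    def note(g: str) -> None:
        if g not in seen:
            seen.add(g)
            names.append(g)

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
            a, mid, b = (p.strip() for p in parts)
            if mid in _SIF_RELATIONS:
                reg, tgt, sign = a, b, _SIF_RELATIONS[mid]
            elif b in _SIGN_TOKENS:
                reg, tgt, sign = a, mid, _SIGN_TOKENS[b]
            else:
                raise ValueError(
                    f"{path}:{lineno}: unrecognised sign/relation {b!r}/{mid!r}"
                )
            note(reg)
            note(tgt)
            edges.add((reg, tgt, sign))
    return SignedNetwork(gene_names=names, edges=edges)


def write_edge_list(net: SignedNetwork, path: str) -> None:
    """Write the 3-column TSV dialect (regulator, target, +1/-1)."""
    with open(path, "w") as fh:
        for reg, tgt, sign in sorted(net.edges):
            fh.write(f"{reg}\t{tgt}\t{'+1' if sign > 0 else '-1'}\n")
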
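"""Metabolite-protein network assembly and random walk with restart (RWR).

The barcode's metabolites are joined to their interacting proteins
(chemical-protein edges, STITCH-style) and the proteins to each other
(protein-protein edges, STRING-style) into one weighted undirected graph.
Drug or drug-combination target sets are mapped into this space by RWR: a
walker steps along edges with probability proportional to edge weight and
teleports back to the seed distribution with probability λ per step,

    P_t = (1 - λ) W^T P_{t-1} + λ P_0,

whose fixed point P = λ (I - (1-λ) W^T)^{-1} P_0 is the drug's propagation
profile over the N network nodes — one feature row per combination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRING_SCORE_MAX = 999.0


class EdgeFileError(ValueError):
    """Raised when an edge-list file violates the format contract."""


@dataclass(frozen=True)
class InteractionEdge:
    node_a: str
    node_b: str
    weight: float


@dataclass
class MetProtNetwork:
    """Cleaned undirected weighted network with a fixed node order.

    Nodes are ordered metabolites-then-proteins, each block lexicographic,
    so every downstream matrix is reproducible bit-for-bit.
    """

    node_ids: list[str]
    node_kind: list[str]
    A: np.ndarray
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {node: i for i, node in enumerate(self.node_ids)}
        if self.A.shape != (self.N, self.N):
            raise ValueError("adjacency shape does not match node count")
        if not np.allclose(self.A, self.A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(self.A < 0):
            raise ValueError("adjacency must be non-negative")
        if np.any(np.diag(self.A) != 0):
            raise ValueError("adjacency must have zero diagonal")
        if np.any(self.A.sum(axis=1) == 0):
            raise ValueError("isolated node survived cleanup")

    @property
    def N(self) -> int:
        return len(self.node_ids)

    def index_of(self, node: str) -> int:
        return self._index[node]

    def __contains__(self, node: str) -> bool:
        return node in self._index

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.A, 1)))


@dataclass(frozen=True)
class RWRProfile:
    """Steady-state probability vector of one restart walk."""

    pt: np.ndarray
    lam: float
    converged: bool
    iterations: int


def load_edges(path, score_threshold: float = 0.0) -> list[InteractionEdge]:
    """Parse a STRING/STITCH-style scored edge list.

    Expects >= 3 tab-separated columns (node_a, node_b, combined_score).
    Integer scores on the database 0-999 scale are rescaled to [0, 1];
    the threshold applies on the rescaled scale, inclusive. Duplicate
    (a,b)/(b,a) pairs keep the maximum weight; self-loops are dropped.
    """
    frame = pd.read_csv(path, sep="\t", comment="#")
    if frame.shape[1] < 3:
        raise EdgeFileError("edge file needs >= 3 columns (a, b, score)")
    cols = frame.columns[:3]
    scores = pd.to_numeric(frame[cols[2]], errors="coerce")
    bad = scores.isna()
    if bad.any():
        raise EdgeFileError(f"row {int(bad.idxmax()) + 2}: non-numeric score")
    neg = scores < 0
    if neg.any():
        raise EdgeFileError(f"row {int(neg.idxmax()) + 2}: negative score")
    weights = scores.to_numpy(dtype=float)
    if weights.size and weights.max() > 1.0:
        weights = weights / (STRING_SCORE_MAX + 1.0)

    best: dict[tuple[str, str], float] = {}
    for a, b, w in zip(frame[cols[0]].astype(str), frame[cols[1]].astype(str), weights):
        if a == b:
            continue
        key = (a, b) if a <= b else (b, a)
        if w > best.get(key, -1.0):
            best[key] = w
    return [
        InteractionEdge(a, b, w)
        for (a, b), w in best.items()
        if w >= score_threshold
    ]


def assemble_network(
    metabolite_ids: list[str],
    met_prot_edges: list[InteractionEdge],
    prot_prot_edges: list[InteractionEdge],
) -> MetProtNetwork:
    """Aggregate per-metabolite neighborhoods and PPI edges, then clean.

    Connected components containing no seed metabolite are removed, as is
    any degree-0 node. Raises if no metabolite connects to anything.
    """
    metabolites = set(metabolite_ids)
    graph = nx.Graph()
    for edge in met_prot_edges:
        if edge.node_a not in metabolites and edge.node_b not in metabolites:
            continue
        graph.add_edge(edge.node_a, edge.node_b, weight=edge.weight)
    for edge in prot_prot_edges:
        graph.add_edge(edge.node_a, edge.node_b, weight=edge.weight)

    keep: set[str] = set()
    for component in nx.connected_components(graph):
        if component & metabolites:
            keep |= component
    graph = graph.subgraph(keep).copy()
    graph.remove_nodes_from(list(nx.isolates(graph)))
    if graph.number_of_nodes() == 0 or not (set(graph) & metabolites):
        raise ValueError("no metabolite connects to the protein network")

    mets = sorted(n for n in graph if n in metabolites)
    prots = sorted(n for n in graph if n not in metabolites)
    order = mets + prots
    A = nx.to_numpy_array(graph, nodelist=order, weight="weight")
    np.fill_diagonal(A, 0.0)
    return MetProtNetwork(
        node_ids=order,
        node_kind=["metabolite"] * len(mets) + ["protein"] * len(prots),
        A=A,
    )


def transition_matrix(net: MetProtNetwork) -> np.ndarray:
    """Row-stochastic transition matrix W_ij = A_ij / Σ_k A_ik."""
    degrees = net.A.sum(axis=1)
    if np.any(degrees == 0):
        raise ValueError("zero-degree node: transition probabilities undefined")
    W = net.A / degrees[:, None]
    return W


def make_seed(target_ids: list[str], net: MetProtNetwork) -> np.ndarray:
    """Uniform seed distribution over the targets present in the network.

    Targets absent from the network are logged and skipped; if none remain
    the seed is undefined and an error names the offending set.
    """
    present = [t for t in dict.fromkeys(target_ids) if t in net]
    absent = [t for t in dict.fromkeys(target_ids) if t not in net]
    if absent:
        logger.info("targets absent from network: %s", ", ".join(absent))
    if not present:
        raise ValueError(f"no target of {sorted(set(target_ids))} is in the network")
    p0 = np.zeros(net.N)
    for t in present:
        p0[net.index_of(t)] = 1.0 / len(present)
    return p0


def rwr_steady_state(
    W: np.ndarray,
    p0: np.ndarray,
    lam: float = 0.5,
    method: str = "closed",
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> RWRProfile:
    """Solve the restart walk P = (1-λ) W^T P + λ P_0.

    ``closed`` solves the linear system λ(I - (1-λ)W^T)^{-1} P_0 directly;
    ``iterative`` applies the recursion until the L1 step falls below
    ``tol``. λ = 1 returns the seed itself.
    """
    if not 0.0 < lam <= 1.0:
        raise ValueError("restart parameter must satisfy 0 < lambda <= 1")
    if p0.ndim != 1 or p0.shape[0] != W.shape[0]:
        raise ValueError("seed vector length must equal node count")
    if np.any(p0 < 0) or not np.isclose(p0.sum(), 1.0):
        raise ValueError("seed must be a probability vector")

    if method == "closed":
        n = W.shape[0]
        pt = lam * np.linalg.solve(np.eye(n) - (1.0 - lam) * W.T, p0)
        pt = pt / pt.sum()
        return RWRProfile(pt=pt, lam=lam, converged=True, iterations=0)
    if method == "iterative":
        pt = p0.copy()
        for it in range(1, max_iter + 1):
            nxt = (1.0 - lam) * (W.T @ pt) + lam * p0
            step = float(np.abs(nxt - pt).sum())
            pt = nxt
            if step < tol:
                return RWRProfile(pt=pt / pt.sum(), lam=lam, converged=True, iterations=it)
        raise RuntimeError(
            f"RWR did not converge in {max_iter} iterations (last L1 step {step:.3e})"
        )
    raise ValueError("method must be 'closed' or 'iterative'")


def featurize_combinations(
    combos,
    drug_targets: dict[str, list[str]],
    net: MetProtNetwork,
    lam: float = 0.5,
    method: str = "closed",
) -> pd.DataFrame:
    """RWR profile of each combination's union target seed, as a feature matrix.

    ``combos`` is an iterable of objects with ``drug_a``/``drug_b``
    attributes or (drug_a, drug_b) pairs. Rows are indexed by the sorted
    pair id "a+b"; columns follow the network node order; each row sums
    to 1. Combinations whose union seed has no in-network target are
    collected and reported in one error.
    """
    W = transition_matrix(net)
    factor = None
    if method == "closed":
        # one factorization reused across rows
        factor = np.linalg.inv(np.eye(net.N) - (1.0 - lam) * W.T)
    rows: dict[str, np.ndarray] = {}
    failures: list[str] = []
    for combo in combos:
        if hasattr(combo, "drug_a"):
            a, b = combo.drug_a, combo.drug_b
        else:
            a, b = combo
        pair_id = "+".join(sorted((a, b)))
        if pair_id in rows:
            continue
        targets = list(drug_targets.get(a, [])) + list(drug_targets.get(b, []))
        try:
            p0 = make_seed(targets, net)
        except ValueError:
            failures.append(pair_id)
            continue
        if factor is not None:
            pt = lam * (factor @ p0)
            pt = pt / pt.sum()
        else:
            pt = rwr_steady_state(W, p0, lam=lam, method=method).pt
        rows[pair_id] = pt
    if failures:
        raise ValueError(
            f"{len(failures)} combination(s) have no in-network target: "
            + ", ".join(failures)
        )
    return pd.DataFrame.from_dict(rows, orient="index", columns=net.node_ids)
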
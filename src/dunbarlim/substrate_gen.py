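"""Static interaction substrates for the agent model.

The model runs on a scale-free contact network in which every undirected
neighbour pair carries two opposite directed edges, so each agent's
out-degree equals its in-degree.  Construction is the classic configuration
model over an i.i.d. truncated power-law degree sequence, simplified by
removing self-loops and parallel edges (realized degrees can therefore fall
slightly below their targets, mostly at the hubs).

Queue capacities are drawn per agent from a Gaussian centred on ``q_max``
with standard deviation ``sigma``, rounded and clamped at 1; ``sigma = 0``
gives the homogeneous population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

__all__ = [
    "DegreeSequence",
    "Substrate",
    "CapacityAssignment",
    "sample_powerlaw_degrees",
    "powerlaw_cdf",
    "configuration_model",
    "assign_capacities",
    "make_substrate",
]


@dataclass
class DegreeSequence:
    degrees: np.ndarray
    gamma: float
    k_min: int
    k_max: int

    def __post_init__(self) -> None:
        self.degrees = np.asarray(self.degrees, dtype=np.int64)
        if self.degrees.sum() % 2 != 0:
            raise ValueError("degree sum must be even")
        if self.degrees.min() < self.k_min or self.degrees.max() > self.k_max:
            raise ValueError("degrees outside [k_min, k_max]")

    def __len__(self) -> int:
        return len(self.degrees)


def powerlaw_cdf(k: np.ndarray, gamma: float, k_min: int, k_max: int) -> np.ndarray:
    """CDF of the discrete truncated power law P(k) ∝ k^gamma on [k_min, k_max]."""
    support = np.arange(k_min, k_max + 1, dtype=np.float64)
    pmf = support**gamma
    pmf /= pmf.sum()
    cdf = np.cumsum(pmf)
    k = np.asarray(k)
    idx = np.clip(k - k_min, -1, len(cdf) - 1).astype(np.int64)
    out = np.where(idx < 0, 0.0, cdf[np.maximum(idx, 0)])
    return out


def sample_powerlaw_degrees(
    n: int,
    gamma: float = -2.4,
    k_min: int = 1,
    k_max: Optional[int] = None,
    seed: int = 0,
) -> DegreeSequence:
    """Draw n i.i.d. degrees from P(k) ∝ k^gamma on [k_min, k_max].

    ``k_max`` defaults to the structural cutoff ``floor(sqrt(n))``.  If the
    sum comes out odd one uniformly chosen entry below ``k_max`` is
    incremented so the sequence is graphical for stub matching.
    """
    if gamma >= -1:
        raise ValueError("need gamma < -1")
    if k_max is None:
        k_max = max(int(np.sqrt(n)), k_min + 1)
    if not (1 <= k_min < k_max <= n - 1):
        raise ValueError(f"infeasible bounds k_min={k_min}, k_max={k_max}, n={n}")
    rng = np.random.default_rng(seed)
    support = np.arange(k_min, k_max + 1, dtype=np.float64)
    pmf = support**gamma
    pmf /= pmf.sum()
    degrees = rng.choice(np.arange(k_min, k_max + 1), size=n, p=pmf)
    if degrees.sum() % 2 != 0:
        candidates = np.flatnonzero(degrees < k_max)
        degrees[rng.choice(candidates)] += 1
    return DegreeSequence(degrees=degrees, gamma=gamma, k_min=k_min, k_max=k_max)


@dataclass
class Substrate:
    """Symmetric directed contact network in CSR adjacency form.

    ``neighbors[indptr[i]:indptr[i+1]]`` lists i's contacts in ascending
    order; every adjacency is present in both directions, so the per-node
    contact count ``degree`` is simultaneously out- and in-degree.
    Structural weights are implicit (unit); interaction weights are
    accumulated only by the dynamics.
    """

    indptr: np.ndarray
    neighbors: np.ndarray
    target_degrees: Optional[np.ndarray] = None
    degree: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.degree = np.diff(self.indptr).astype(np.int64)

    @property
    def n(self) -> int:
        return len(self.indptr) - 1

    @property
    def n_edges_directed(self) -> int:
        return int(len(self.neighbors))

    def neighbors_of(self, i: int) -> np.ndarray:
        return self.neighbors[self.indptr[i]: self.indptr[i + 1]]

    def has_edge(self, i: int, j: int) -> bool:
        nb = self.neighbors_of(i)
        pos = np.searchsorted(nb, j)
        return pos < len(nb) and nb[pos] == j

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        for i in range(self.n):
            for j in self.neighbors_of(i):
                if j > i:
                    g.add_edge(i, int(j))
        return g


def configuration_model(degs: DegreeSequence, seed: int = 0) -> Substrate:
    """Stub-matching realisation of a degree sequence, simplified.

    Self-loops and parallel edges are removed, then every surviving
    undirected edge is replaced by two opposite directed edges.
    """
    g = nx.configuration_model(
        degs.degrees.tolist(), seed=int(seed), create_using=nx.MultiGraph
    )
    simple = nx.Graph(g)  # collapses multi-edges
    simple.remove_edges_from(nx.selfloop_edges(simple))
    n = len(degs)
    adj = [[] for _ in range(n)]
    for u, v in simple.edges():
        adj[u].append(v)
        adj[v].append(u)
    indptr = np.zeros(n + 1, dtype=np.int64)
    for i in range(n):
        adj[i].sort()
        indptr[i + 1] = indptr[i] + len(adj[i])
    neighbors = np.fromiter(
        (j for nb in adj for j in nb), dtype=np.int64, count=int(indptr[-1])
    )
    return Substrate(
        indptr=indptr, neighbors=neighbors,
        target_degrees=degs.degrees.copy(),
    )


@dataclass
class CapacityAssignment:
    q: np.ndarray
    q_max: float
    sigma: float

    def __len__(self) -> int:
        return len(self.q)


def assign_capacities(
    n: int, q_max: int, sigma: float, seed: int = 0
) -> CapacityAssignment:
    """Per-agent queue capacities: round(Normal(q_max, sigma)), clamped >= 1."""
    if q_max < 1 or sigma < 0:
        raise ValueError("need q_max >= 1 and sigma >= 0")
    rng = np.random.default_rng(seed)
    if sigma == 0:
        q = np.full(n, q_max, dtype=np.int64)
    else:
        q = np.maximum(np.rint(rng.normal(q_max, sigma, size=n)), 1).astype(np.int64)
    return CapacityAssignment(q=q, q_max=float(q_max), sigma=float(sigma))


def make_substrate(
    n: int,
    gamma: float = -2.4,
    k_min: int = 1,
    k_max: Optional[int] = None,
    seed: int = 0,
) -> Substrate:
    """Convenience: sample degrees and wire the configuration model."""
    degs = sample_powerlaw_degrees(n, gamma=gamma, k_min=k_min, k_max=k_max,
                                   seed=seed)
    return configuration_model(degs, seed=seed + 1)
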
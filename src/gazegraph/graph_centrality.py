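"""AOI transition graphs and standardized weighted degree centrality.

A trial's scan path induces a weighted undirected graph G = (N, P, w):
nodes are the AOIs, a link joins two AOIs when the gaze transitioned
between them, and the weight counts those transitions.  The graph is
stored as a symmetric adjacency matrix M with zero diagonal
(M_ij = number of transitions between AOIs i and j; refixations within
one AOI create no link — dwell is captured by fixation time instead).

Node importance is measured by the standardized weighted degree
centrality of Opsahl's tuning-parameter form,

    C_D^W(i) = C_D(i) / max C_D  *  w(i) / max W  *  100,

where C_D(i) is the number of distinct neighbours of node i, w(i) its
strength (summed link weights), and the maxima are taken over the same
graph.  Each node therefore scores in [0, 100]; a node attaining both
maxima scores exactly 100.  The trial-level statistic is the sum of all
node centralities; the participant-level statistic is the mean of trial
sums over the participant's trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .aoi_grid import AOIGrid, aoi_condition, GREEN
from .io_model import ScanPath

logger = logging.getLogger(__name__)


@dataclass
class ScanGraph:
    """Weighted undirected AOI transition graph (symmetric count matrix)."""

    matrix: np.ndarray  # (n_nodes, n_nodes) int, symmetric, zero diagonal

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("adjacency matrix must be square")
        if (m < 0).any():
            raise ValueError("transition counts must be non-negative")
        if np.diagonal(m).any():
            raise ValueError("adjacency matrix must have a zero diagonal")
        if not np.array_equal(m, m.T):
            raise ValueError("adjacency matrix must be symmetric")
        self.matrix = m

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def total_weight(self) -> int:
        """Total link weight, sum over i<j of M_ij = number of counted
        transitions."""
        return int(np.triu(self.matrix, k=1).sum())

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[int, int]], n_nodes: int,
                   weight: int = 1) -> "ScanGraph":
        """Build a graph from 1-based undirected edges, each with the given
        weight (repeated edges accumulate)."""
        m = np.zeros((n_nodes, n_nodes), dtype=int)
        for a, b in edges:
            if not (1 <= a <= n_nodes and 1 <= b <= n_nodes):
                raise ValueError(f"edge ({a}, {b}) outside 1..{n_nodes}")
            if a == b:
                raise ValueError(f"self-loop ({a}, {a}) not allowed")
            m[a - 1, b - 1] += weight
            m[b - 1, a - 1] += weight
        return cls(m)


def build_graph(aoi_sequence: Sequence[int], n_nodes: int) -> ScanGraph:
    """Build the transition graph of a time-ordered AOI sequence.

    Each consecutive pair (a, b) with a != b adds one transition between
    a and b (both M_ab and M_ba are incremented: the graph is
    undirected).  Consecutive refixations (a == b) are skipped.
    Sequences shorter than 2 give the zero matrix.
    """
    m = np.zeros((n_nodes, n_nodes), dtype=int)
    for pos, a in enumerate(aoi_sequence):
        if not 1 <= a <= n_nodes:
            raise ValueError(
                f"AOI id {a} at position {pos} outside 1..{n_nodes}")
    for a, b in zip(aoi_sequence, aoi_sequence[1:]):
        if a != b:
            m[a - 1, b - 1] += 1
            m[b - 1, a - 1] += 1
    return ScanGraph(m)


def node_degree(graph: ScanGraph, i: int) -> int:
    """C_D(i): number of distinct AOIs linked to 1-based node i."""
    if not 1 <= i <= graph.n_nodes:
        raise IndexError(f"node {i} outside 1..{graph.n_nodes}")
    return int(np.count_nonzero(graph.matrix[i - 1]))


def node_strength(graph: ScanGraph, i: int) -> int:
    """w(i): total number of links incident to 1-based node i (row sum)."""
    if not 1 <= i <= graph.n_nodes:
        raise IndexError(f"node {i} outside 1..{graph.n_nodes}")
    return int(graph.matrix[i - 1].sum())


@dataclass
class CentralityResult:
    """Per-node standardized weighted degree centralities for one graph.

    ``per_node[k]`` is the value of 1-based node k+1, in [0, 100].
    ``trial_sum`` is the sum over all nodes — the trial-level statistic.
    """

    per_node: np.ndarray
    degrees: np.ndarray
    strengths: np.ndarray
    max_degree: int
    max_strength: int
    trial_sum: float

    def value(self, i: int) -> float:
        """Centrality of 1-based node i."""
        return float(self.per_node[i - 1])


def degree_centrality(graph: ScanGraph) -> CentralityResult:
    """Standardized weighted degree centrality of every node.

    The two tuning maxima (max observed degree, max observed strength)
    are taken over this same graph, which is what standardizes values
    into [0, 100] and makes them comparable across trials and
    participants.  An empty graph (no links anywhere) scores every node
    0 and reports maxima of 0; no division is performed.
    """
    m = graph.matrix
    degrees = np.count_nonzero(m, axis=1)
    strengths = m.sum(axis=1)
    max_d = int(degrees.max(initial=0))
    max_w = int(strengths.max(initial=0))
    if max_d == 0:  # no links at all
        per_node = np.zeros(graph.n_nodes)
    else:
        per_node = (degrees / max_d) * (strengths / max_w) * 100.0
    return CentralityResult(
        per_node=per_node,
        degrees=degrees,
        strengths=strengths,
        max_degree=max_d,
        max_strength=max_w,
        trial_sum=float(per_node.sum()),
    )


def half_centrality(result: CentralityResult, grid: AOIGrid,
                    scanpath: ScanPath | str) -> tuple[float, float]:
    """Split a full-graph centrality result into (green_sum, normal_sum).

    Per-node values from the full-trial graph are summed over the AOIs of
    each image half, labelled by the trial's green side; by construction
    green_sum + normal_sum == trial_sum.  (For the alternative that
    rebuilds and renormalizes each half as its own subgraph, see
    :func:`subgraph_half_centrality`.)
    """
    green = 0.0
    normal = 0.0
    for aoi in range(1, grid.n_aois + 1):
        v = result.per_node[aoi - 1]
        if aoi_condition(aoi, scanpath, grid) == GREEN:
            green += v
        else:
            normal += v
    return green, normal


def subgraph_half_centrality(graph: ScanGraph, grid: AOIGrid,
                             scanpath: ScanPath | str) -> tuple[float, float]:
    """Per-half centrality with within-half subgraphs and per-half maxima.

    Cross-half links are dropped and Opsahl standardization is applied
    within each half separately.  This breaks the green+normal == total
    identity and is not the default; it exists because either reading of
    "per-image centrality" is defensible.
    """
    half_n = grid.n_aois // 2
    sums: dict[str, float] = {}
    for side, idx in (("left", slice(0, half_n)), ("right", slice(half_n, None))):
        sub = ScanGraph(graph.matrix[idx, idx])
        sums[side] = degree_centrality(sub).trial_sum
    green_side = scanpath if isinstance(scanpath, str) else scanpath.green_side
    normal_side = "right" if green_side == "left" else "left"
    return sums[green_side], sums[normal_side]


def participant_centrality(trial_sums: Sequence[float]) -> float:
    """Participant-level centrality: mean of trial sums over available
    trials.  Missing trials are simply absent from the input; zero trials
    is an error."""
    if len(trial_sums) == 0:
        raise ValueError("participant has no trials to average")
    return float(np.mean(trial_sums))
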
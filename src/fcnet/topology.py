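"""Per-subject graph topology of thresholded connectivity networks.

Characterizes each subject's Fisher-z connectivity matrix as a weighted
undirected network: proportional thresholding over a density grid, the
global clustering coefficient C, the characteristic path length L,
their random-network normalizations gamma = C/C_rand and
lambda = L/L_rand from a degree-preserving rewiring null, the
small-world index sigma = gamma/lambda, and trapezoidal AUC summaries
of each curve over the threshold grid.

Binary metrics follow the standard adjacency-count definitions
(triangles over possible neighbor pairs; hop-count shortest paths).
Weighted mode uses the Onnela clustering generalization (geometric mean
of max-normalized triangle weights) and shortest paths on edge lengths
1/weight. Metrics are computed natively on adjacency matrices
(matrix-power triangle counts, sparse-graph shortest paths) so the test
suite can hold them against independent graph-library oracles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _shortest_path

from .connectivity import ConnectivityMatrix

logger = logging.getLogger(__name__)

#: Default proportional-threshold grid: densities 0.20 .. 0.60, step 0.05.
DEFAULT_TAUS: tuple[float, ...] = tuple(np.round(np.linspace(0.2, 0.6, 9), 2))

#: Default size of the random-network null ensemble.
DEFAULT_NULL_REPS = 1000

#: Successful degree-preserving swaps per rewiring, as a multiple of the
#: edge count.
SWAPS_PER_EDGE = 10

#: |lambda - 1| beyond this band triggers a small-world regime flag.
LAMBDA_BAND = 0.3


class TopologyError(ValueError):
    """Raised for graphs on which a metric is undefined."""


@dataclass
class ThresholdedGraph:
    """Thresholded nonnegative weighted graph (no self-loops)."""

    weights: np.ndarray
    tau: float
    mode: str  # 'weighted' | 'binary'

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n):
            raise TopologyError("weight matrix must be square")
        if not np.allclose(self.weights, self.weights.T):
            raise TopologyError("weight matrix must be symmetric")
        if np.any(self.weights < 0):
            raise TopologyError("weights must be nonnegative")
        if np.any(np.diag(self.weights) != 0):
            raise TopologyError("self-loops are not allowed")
        if self.mode not in ("weighted", "binary"):
            raise TopologyError(f"unknown mode {self.mode!r}")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    @property
    def adjacency(self) -> np.ndarray:
        return (self.weights > 0).astype(float)


class NodeMetrics(NamedTuple):
    """Per-node degree k, triangle term t, clustering coefficient c."""

    k: np.ndarray
    t: np.ndarray
    c: np.ndarray


class PathLengthResult(NamedTuple):
    """Mean shortest path over reachable ordered pairs + exclusions."""

    l: float
    unreachable_pairs: int


@dataclass
class NullEnsemble:
    """Random-network reference: rewired, weight-reshuffled replicas."""

    reps: int
    c_values: np.ndarray
    l_values: np.ndarray
    seed: int | None
    fallback_reshuffle_only: bool = False
    #: Replica weight matrices, retained only when requested.
    graphs: list[np.ndarray] | None = None

    @property
    def c_rand(self) -> float:
        return float(np.mean(self.c_values))

    @property
    def l_rand(self) -> float:
        return float(np.mean(self.l_values))


class SmallWorldIndex(NamedTuple):
    gamma: float
    lam: float
    sigma: float
    #: True when gamma <= 1 or |lam - 1| > LAMBDA_BAND — outside the
    #: canonical small-world regime (gamma >> 1, lambda ~ 1).
    regime_flag: bool


@dataclass
class TopologyCurve:
    """Per-threshold global metrics and their AUC summaries."""

    subject_id: str
    taus: np.ndarray
    c_curve: np.ndarray
    l_curve: np.ndarray
    gamma_curve: np.ndarray
    lambda_curve: np.ndarray
    sigma_curve: np.ndarray
    unreachable_curve: np.ndarray
    mode: str
    reps: int
    seed: int | None
    auc_c: float = field(init=False)
    auc_l: float = field(init=False)
    auc_sigma: float = field(init=False)

    def __post_init__(self) -> None:
        taus = np.asarray(self.taus, dtype=float)
        if np.any(np.diff(taus) <= 0):
            raise TopologyError("threshold grid must be strictly increasing")
        self.taus = taus
        self.auc_c = float(np.trapezoid(self.c_curve, taus))
        self.auc_l = float(np.trapezoid(self.l_curve, taus))
        self.auc_sigma = float(np.trapezoid(self.sigma_curve, taus))


# ---------------------------------------------------------------------------
# Thresholding


def proportional_threshold(
    cm: ConnectivityMatrix | np.ndarray,
    tau: float,
    mode: str = "weighted",
    negatives: str = "drop",
) -> ThresholdedGraph:
    """Keep the strongest fraction ``tau`` of candidate connections.

    Candidate edges are the positive upper-triangle entries
    (``negatives='drop'``) or all nonzero entries ranked by magnitude
    (``negatives='abs'``, retained as absolute weights). The top
    ``round(tau * m)`` candidates survive, ranked by weight descending
    with ties broken by ascending (i, j) index so edge sets are
    bit-reproducible. ``mode='binary'`` sets surviving weights to 1.
    """
    z = cm.z if isinstance(cm, ConnectivityMatrix) else np.asarray(cm, float)
    if not 0 < tau <= 1:
        raise TopologyError(f"tau must be in (0, 1], got {tau}")
    if negatives not in ("drop", "abs"):
        raise TopologyError(f"unknown negative-weight policy {negatives!r}")
    n = z.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = z[iu, ju]
    if negatives == "abs":
        w = np.abs(w)
    candidates = w > 0
    m = int(candidates.sum())
    if m == 0:
        raise TopologyError("no positive connections to threshold")
    keep_count = int(round(tau * m))
    keep_count = max(keep_count, 1)
    ci, cj, cw = iu[candidates], ju[candidates], w[candidates]
    order = np.lexsort((cj, ci, -cw))  # weight desc, then (i, j) asc
    sel = order[:keep_count]
    weights = np.zeros((n, n))
    kept_w = np.ones(keep_count) if mode == "binary" else cw[sel]
    weights[ci[sel], cj[sel]] = kept_w
    weights[cj[sel], ci[sel]] = kept_w
    return ThresholdedGraph(weights=weights, tau=tau, mode=mode)


# ---------------------------------------------------------------------------
# Node-level and global metrics


def node_degree(g: ThresholdedGraph) -> np.ndarray:
    """Degree k_i: edge count (binary) or strength (weighted row sum)."""
    if g.mode == "binary":
        return g.adjacency.sum(axis=1)
    return g.weights.sum(axis=1)


def clustering_coefficient(g: ThresholdedGraph) -> tuple[NodeMetrics, float]:
    """Per-node and global clustering coefficient.

    Binary: ``C(i) = 2 t_i / (k_i (k_i - 1))`` with ``t_i`` the number
    of triangles through node i. Weighted: Onnela's generalization —
    weights are normalized by the network maximum, and ``t_i`` becomes
    the sum of cube-rooted triangle weight products; the denominator
    keeps the binary degree. Nodes with fewer than two neighbors have
    ``C(i) = 0``, and the global value is the plain node average.
    """
    a = g.adjacency
    k = a.sum(axis=1)
    if g.mode == "binary":
        cube = a @ a @ a
    else:
        wmax = g.weights.max()
        w_hat = np.cbrt(g.weights / wmax) if wmax > 0 else g.weights
        cube = w_hat @ w_hat @ w_hat
    t = np.diag(cube) / 2.0
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * t / denom, 0.0)
    return NodeMetrics(k=node_degree(g), t=t, c=c), float(c.mean())


def characteristic_path_length(g: ThresholdedGraph) -> PathLengthResult:
    """Mean shortest-path length over reachable ordered pairs.

    Binary graphs use hop counts; weighted graphs use edge lengths
    ``1/weight`` (strong connections are short). Unreachable pairs are
    excluded from the mean and counted, avoiding infinite path lengths
    in sparse graphs.
    """
    if g.n_edges == 0:
        raise TopologyError("path length is undefined on an edgeless graph")
    if g.mode == "binary":
        dist = _shortest_path(csr_matrix(g.adjacency), method="D",
                              unweighted=True, directed=False)
    else:
        lengths = np.zeros_like(g.weights)
        nz = g.weights > 0
        lengths[nz] = 1.0 / g.weights[nz]
        dist = _shortest_path(csr_matrix(lengths), method="D", directed=False)
    n = g.n_nodes
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    unreachable = int(off.sum() - finite.sum())
    if not finite.any():
        raise TopologyError("no reachable node pairs")
    return PathLengthResult(l=float(dist[finite].mean()),
                            unreachable_pairs=unreachable)


# ---------------------------------------------------------------------------
# Random-network null


def _double_edge_swap(
    edges: np.ndarray, n_nodes: int, rng: np.random.Generator,
    n_swaps: int, max_tries: int,
) -> tuple[np.ndarray, int]:
    """Degree-preserving rewiring by repeated double-edge swaps.

    Picks two edges (a, b), (c, d) and rewires to (a, d), (c, b) when
    the move creates neither a self-loop nor a duplicate edge. Returns
    the rewired edge array and the number of successful swaps.
    """
    m = edges.shape[0]
    edge_set = {(int(u), int(v)) for u, v in edges}
    work = [list(e) for e in edges]
    successes = 0
    tries = 0
    # Draw candidate indices in blocks to keep the Python loop lean.
    while successes < n_swaps and tries < max_tries:
        block = min(4 * (n_swaps - successes), max_tries - tries)
        pairs = rng.integers(0, m, size=(block, 2))
        coins = rng.integers(0, 2, size=block)
        for (e1, e2), coin in zip(pairs, coins):
            tries += 1
            if e1 == e2:
                continue
            a, b = work[e1]
            c, d = work[e2]
            if coin:  # swap the orientation of the second edge
                c, d = d, c
            # Proposed new edges: (a, d) and (c, b).
            if a == d or c == b:
                continue
            new1 = (min(a, d), max(a, d))
            new2 = (min(c, b), max(c, b))
            if new1 in edge_set or new2 in edge_set or new1 == new2:
                continue
            edge_set.discard((min(a, b), max(a, b)))
            edge_set.discard((min(c, d), max(c, d)))
            edge_set.add(new1)
            edge_set.add(new2)
            work[e1] = list(new1)
            work[e2] = list(new2)
            successes += 1
            if successes >= n_swaps:
                break
    return np.array(work, dtype=int), successes


def generate_null(
    g: ThresholdedGraph,
    reps: int = DEFAULT_NULL_REPS,
    seed: int | None = None,
    keep_graphs: bool = False,
) -> NullEnsemble:
    """Random-network ensemble matched on degrees and weights.

    Each replica rewires the observed graph with degree-preserving
    double-edge swaps (at least ``SWAPS_PER_EDGE`` x edge-count
    successful swaps) and then reassigns the original weight multiset
    uniformly at random to the rewired edge set, so every replica
    preserves the degree sequence and the weight multiset exactly.
    Graphs that admit no legal swap (e.g. stars) fall back to weight
    reshuffling on the fixed edge set, with a warning.
    """
    if reps < 1:
        raise TopologyError("need at least one null repetition")
    m = g.n_edges
    if m < 2:
        raise TopologyError("null model needs a graph with at least 2 edges")
    iu, ju = np.nonzero(np.triu(g.weights, k=1))
    base_edges = np.column_stack([iu, ju])
    base_weights = g.weights[iu, ju]
    rng = np.random.default_rng(seed)
    n_swaps = SWAPS_PER_EDGE * m
    max_tries = 100 * m

    c_values = np.empty(reps)
    l_values = np.empty(reps)
    kept: list[np.ndarray] | None = [] if keep_graphs else None
    fallback = False
    for rep in range(reps):
        edges, successes = _double_edge_swap(
            base_edges, g.n_nodes, rng, n_swaps, max_tries
        )
        if successes == 0:
            fallback = True
            edges = base_edges
        w = base_weights if g.mode == "binary" else rng.permutation(base_weights)
        null_w = np.zeros_like(g.weights)
        null_w[edges[:, 0], edges[:, 1]] = w
        null_w[edges[:, 1], edges[:, 0]] = w
        null_g = ThresholdedGraph(weights=null_w, tau=g.tau, mode=g.mode)
        _, c_values[rep] = clustering_coefficient(null_g)
        l_values[rep] = characteristic_path_length(null_g).l
        if kept is not None:
            kept.append(null_w)
    if fallback:
        logger.warning(
            "null model: no legal degree-preserving swap exists; "
            "fell back to weight reshuffling on the fixed edge set"
        )
    return NullEnsemble(reps=reps, c_values=c_values, l_values=l_values,
                        seed=seed, fallback_reshuffle_only=fallback,
                        graphs=kept)


def small_world_index(
    c: float, l: float, null: NullEnsemble, lambda_band: float = LAMBDA_BAND
) -> SmallWorldIndex:
    """gamma = C/C_rand, lambda = L/L_rand, sigma = gamma/lambda.

    A small-world network has gamma >> 1 with lambda ~ 1; departures
    from that regime set ``regime_flag`` (the computation never fails
    on regime grounds).
    """
    if null.c_rand <= 0 or null.l_rand <= 0:
        raise TopologyError("null ensemble has nonpositive mean C or L")
    gamma = c / null.c_rand
    lam = l / null.l_rand
    sigma = gamma / lam
    flagged = gamma <= 1.0 or abs(lam - 1.0) > lambda_band
    if flagged:
        logger.info(
            "small-world regime flag: gamma=%.3f lambda=%.3f", gamma, lam
        )
    return SmallWorldIndex(gamma=gamma, lam=lam, sigma=sigma,
                           regime_flag=flagged)


# ---------------------------------------------------------------------------
# Threshold sweep


def topology_curve(
    cm: ConnectivityMatrix,
    taus: tuple[float, ...] = DEFAULT_TAUS,
    reps: int = DEFAULT_NULL_REPS,
    seed: int | None = None,
    mode: str = "weighted",
    negatives: str = "drop",
) -> TopologyCurve:
    """Sweep the threshold grid and summarize each metric by its AUC.

    At each density tau the matrix is proportionally thresholded and
    C, L, gamma, lambda and sigma computed; the AUC of each curve is
    the trapezoidal integral over the grid. ``reps=0`` skips the null
    ensemble (gamma/lambda/sigma become NaN), which is useful when only
    the raw C and L summaries are needed.
    """
    taus = tuple(taus)
    k = len(taus)
    c_curve = np.empty(k)
    l_curve = np.empty(k)
    gamma_curve = np.full(k, np.nan)
    lambda_curve = np.full(k, np.nan)
    sigma_curve = np.full(k, np.nan)
    unreachable = np.zeros(k, dtype=int)
    # One child seed per threshold keeps the grid embarrassingly stable:
    # changing one tau cannot perturb another's null draw.
    if seed is not None:
        child_seeds = np.random.SeedSequence(seed).spawn(k)
    else:
        child_seeds = [None] * k
    for i, tau in enumerate(taus):
        try:
            g = proportional_threshold(cm, tau, mode=mode, negatives=negatives)
            _, c_curve[i] = clustering_coefficient(g)
            plr = characteristic_path_length(g)
            l_curve[i] = plr.l
            unreachable[i] = plr.unreachable_pairs
            if reps > 0:
                child = child_seeds[i]
                null_seed = (
                    int(child.generate_state(1)[0] % (2**31))
                    if child is not None else None
                )
                null = generate_null(g, reps=reps, seed=null_seed)
                sw = small_world_index(c_curve[i], l_curve[i], null)
                gamma_curve[i] = sw.gamma
                lambda_curve[i] = sw.lam
                sigma_curve[i] = sw.sigma
        except TopologyError as err:
            raise TopologyError(f"at threshold tau={tau}: {err}") from err
    return TopologyCurve(
        subject_id=cm.subject_id,
        taus=np.asarray(taus, dtype=float),
        c_curve=c_curve, l_curve=l_curve,
        gamma_curve=gamma_curve, lambda_curve=lambda_curve,
        sigma_curve=sigma_curve, unreachable_curve=unreachable,
        mode=mode, reps=reps, seed=seed,
    )
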
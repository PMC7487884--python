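"""From-scratch LINE network embedding (first- and second-order proximity).

The model represents every vertex :math:`v_i` by a d-dimensional vector
:math:`u_i`.  First-order proximity models the joint probability of an
undirected edge as a sigmoid of the dot product,

.. math:: p_1(v_i, v_j) = \\frac{1}{1 + \\exp(-u_i^T u_j)},

and fits it to the empirical edge distribution :math:`\\hat p_1(i,j) =
w_{ij}/W` under KL divergence, which (dropping constants) gives the loss
:math:`O_1 = -\\sum_{(i,j)\\in E} w_{ij} \\log p_1(v_i, v_j)`.

Second-order proximity adds per-vertex *context* vectors :math:`u'_j` and
models the conditional probability that :math:`v_j` is a neighbour of
:math:`v_i` as a softmax over all vertices,

.. math:: p_2(v_j | v_i) = \\frac{\\exp(u_j'^T u_i)}{\\sum_k \\exp(u_k'^T u_i)},

fitted to :math:`\\hat p_2(j|i) = w_{ij}/d_i` with per-vertex prestige
weights equal to the degree, giving :math:`O_2 = -\\sum_{(i,j)\\in E}
w_{ij} \\log p_2(v_j|v_i)` summed over directed arcs (each undirected edge
contributes both directions).

Two trainers are provided:

* :func:`exact_train_small` -- full-batch gradient descent on the exact
  objectives with backtracking step control; O(|V|) softmax per arc, so it
  is restricted to small graphs and serves as the verification oracle.
* :func:`train_line` -- the scalable trainer: sequential SGD with
  alias-method edge sampling and K-negative sampling from a noise
  distribution proportional to :math:`d_i^{3/4}` (the standard practice
  for this family of models; the objectives above are what it estimates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .errors import ConfigError, DimensionError, ModeError
from .network import HeteroGraph

ORDERS = ("first", "second", "concat")

_SIGMOID_CLAMP = 30.0  # |score| beyond this saturates; avoids log(0)


@dataclass(frozen=True)
class LineConfig:
    """Training configuration for the embedding.

    ``order='concat'`` trains an independent first- and second-order
    embedding of ``dim/2`` each and concatenates them, honouring both
    proximities; ``dim`` must then be even.
    """

    dim: int = 64
    order: str = "concat"
    negative_samples: int = 5
    learning_rate: float = 0.025
    total_samples: int | None = None  # default: 1000 * |E|
    seed: int = 0
    prestige_mode: str = "degree"

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ConfigError(f"dim must be >= 2, got {self.dim}")
        if self.order not in ORDERS:
            raise ConfigError(f"order must be one of {ORDERS}, got {self.order!r}")
        if self.order == "concat" and self.dim % 2 != 0:
            raise ConfigError("concat mode needs an even dim (dim/2 per order)")
        if self.negative_samples < 1:
            raise ConfigError("negative_samples must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.prestige_mode != "degree":
            raise ConfigError("only degree prestige is supported")


@dataclass
class LineModelState:
    """Learned vertex vectors (and context vectors for second order)."""

    nodes: tuple[str, ...]
    vertex_vectors: np.ndarray  # (|V|, dim)
    context_vectors: np.ndarray | None  # (|V|, dim) for order='second'
    config: LineConfig
    order: str
    loss_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {n: k for k, n in enumerate(self.nodes)}

    def index(self, name: str) -> int:
        return self._index[name]

    def vector(self, name: str) -> np.ndarray:
        return self.vertex_vectors[self._index[name]]

    def context(self, name: str) -> np.ndarray:
        if self.context_vectors is None:
            raise ModeError("state has no context vectors (not second-order)")
        return self.context_vectors[self._index[name]]

    def as_mapping(self) -> dict[str, np.ndarray]:
        return {n: self.vertex_vectors[k] for k, n in enumerate(self.nodes)}


# ---------------------------------------------------------------------------
# model probabilities and exact objectives
# ---------------------------------------------------------------------------


def sigmoid(x: float | np.ndarray) -> float | np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -_SIGMOID_CLAMP, _SIGMOID_CLAMP)))


def first_order_joint(u_i: np.ndarray, u_j: np.ndarray) -> float:
    """Sigmoid joint edge probability p1(v_i, v_j); symmetric in its arguments."""
    u_i = np.asarray(u_i, dtype=float)
    u_j = np.asarray(u_j, dtype=float)
    if u_i.shape != u_j.shape:
        raise DimensionError(f"vector shapes differ: {u_i.shape} vs {u_j.shape}")
    return float(sigmoid(float(u_i @ u_j)))


def second_order_conditional(state: LineModelState, i: str, j: str) -> float:
    """Softmax conditional p2(v_j | v_i) over all |V| context vectors."""
    if state.order != "second" or state.context_vectors is None:
        raise ModeError("second_order_conditional needs a second-order state")
    scores = state.context_vectors @ state.vector(i)
    m = scores.max()
    log_z = m + math.log(np.exp(scores - m).sum())
    return float(math.exp(scores[state.index(j)] - log_z))


def _first_half(state: LineModelState) -> np.ndarray:
    if state.order == "concat":
        return state.vertex_vectors[:, : state.config.dim // 2]
    return state.vertex_vectors


def _edge_arrays(
    state: LineModelState, g: HeteroGraph
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    src, dst, w = [], [], []
    for a, b, weight in g.edges():
        src.append(state.index(a))
        dst.append(state.index(b))
        w.append(weight)
    return (
        np.asarray(src, dtype=np.int64),
        np.asarray(dst, dtype=np.int64),
        np.asarray(w, dtype=float),
    )


def first_order_objective(state: LineModelState, g: HeteroGraph) -> float:
    """Exact O1 = -sum_(i,j) w_ij log p1(v_i, v_j) over undirected edges."""
    for name in g.node_names():
        if name not in state._index:
            raise ConfigError(f"state has no vector for graph node {name!r}")
    U = _first_half(state)
    src, dst, w = _edge_arrays(state, g)
    if len(src) == 0:
        return 0.0
    dots = np.einsum("ij,ij->i", U[src], U[dst])
    # -log sigmoid(x) = log(1 + exp(-x)), computed stably
    return float(np.sum(w * np.logaddexp(0.0, -dots)))


def _log_softmax_rows(Z: np.ndarray) -> np.ndarray:
    m = Z.max(axis=1, keepdims=True)
    return Z - m - np.log(np.exp(Z - m).sum(axis=1, keepdims=True))


def second_order_objective(state: LineModelState, g: HeteroGraph) -> float:
    """Exact O2 = -sum over directed arcs of w_ij log p2(v_j|v_i).

    Each undirected edge contributes both directions.  Uses the full
    |V|x|V| log-softmax, so intended for small (oracle-scale) graphs.
    """
    if state.order != "second" or state.context_vectors is None:
        raise ModeError("second_order_objective needs a second-order state")
    U, C = state.vertex_vectors, state.context_vectors
    logP = _log_softmax_rows(U @ C.T)
    total = 0.0
    for a, b, w in g.edges():
        ia, ib = state.index(a), state.index(b)
        total -= w * (logP[ia, ib] + logP[ib, ia])
    return float(total)


def second_order_gradient(
    state: LineModelState, g: HeteroGraph
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradient of :func:`second_order_objective` wrt (U, C)."""
    if state.order != "second" or state.context_vectors is None:
        raise ModeError("second_order_gradient needs a second-order state")
    U, C = state.vertex_vectors, state.context_vectors
    n = len(state.nodes)
    W_arc = np.zeros((n, n))
    for a, b, w in g.edges():
        ia, ib = state.index(a), state.index(b)
        W_arc[ia, ib] += w
        W_arc[ib, ia] += w
    logP = _log_softmax_rows(U @ C.T)
    P = np.exp(logP)
    G = P * W_arc.sum(axis=1, keepdims=True) - W_arc  # dO2/dZ
    return G @ C, G.T @ U


def first_order_gradient(state: LineModelState, g: HeteroGraph) -> np.ndarray:
    """Analytic gradient of :func:`first_order_objective` wrt the vectors."""
    U = _first_half(state)
    grad = np.zeros_like(U)
    src, dst, w = _edge_arrays(state, g)
    if len(src) == 0:
        return grad
    dots = np.einsum("ij,ij->i", U[src], U[dst])
    coef = -w * sigmoid(-dots)  # d/du_i of -w log sigmoid(u_i.u_j)
    np.add.at(grad, src, coef[:, None] * U[dst])
    np.add.at(grad, dst, coef[:, None] * U[src])
    return grad


# ---------------------------------------------------------------------------
# alias-method sampling
# ---------------------------------------------------------------------------


class AliasTable:
    """Vose alias table: O(1) draws from a fixed discrete distribution."""

    def __init__(self, weights: Sequence[float], seed: int = 0):
        weights = np.asarray(weights, dtype=float)
        if weights.size == 0:
            raise ConfigError("alias table needs at least one weight")
        if np.any(weights <= 0):
            raise ConfigError("alias table weights must all be positive")
        n = weights.size
        p = weights / weights.sum() * n
        prob = np.zeros(n)
        alias = np.zeros(n, dtype=np.int64)
        small = [i for i in range(n) if p[i] < 1.0]
        large = [i for i in range(n) if p[i] >= 1.0]
        while small and large:
            s, l = small.pop(), large.pop()
            prob[s] = p[s]
            alias[s] = l
            p[l] = p[l] - (1.0 - p[s])
            (small if p[l] < 1.0 else large).append(l)
        for i in large + small:
            prob[i] = 1.0
        self.prob = prob
        self.alias = alias
        self._rng = np.random.default_rng(seed)

    def __len__(self) -> int:
        return self.prob.size

    def sample(self, n: int = 1) -> np.ndarray:
        k = self._rng.integers(0, len(self), size=n)
        accept = self._rng.random(n) < self.prob[k]
        return np.where(accept, k, self.alias[k])


def build_alias_table(weights: Sequence[float], seed: int = 0) -> AliasTable:
    """Constant-time sampler over ``weights`` (all strictly positive)."""
    return AliasTable(weights, seed)


# ---------------------------------------------------------------------------
# scalable trainer: SGD + negative sampling (numba kernel)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _sgd_kernel(
    U,
    C,
    arc_src,
    arc_dst,
    edge_prob,
    edge_alias,
    neg_prob,
    neg_alias,
    neg_ids,
    K,
    total,
    lr0,
    seed,
    second_order,
):  # pragma: no cover - exercised via train_line
    np.random.seed(seed)
    dim = U.shape[1]
    n_arcs = arc_src.shape[0]
    n_neg = neg_prob.shape[0]
    lr_floor = lr0 * 1e-4
    buf = np.empty(dim)
    for t in range(total):
        lr = lr0 * (1.0 - t / total)
        if lr < lr_floor:
            lr = lr_floor
        k = int(np.random.random() * n_arcs)
        if k >= n_arcs:
            k = n_arcs - 1
        if np.random.random() >= edge_prob[k]:
            k = edge_alias[k]
        i = arc_src[k]
        j = arc_dst[k]
        for d in range(dim):
            buf[d] = 0.0
        for s in range(K + 1):
            if s == 0:
                target = j
                label = 1.0
            else:
                target = j
                for _ in range(100):
                    c = int(np.random.random() * n_neg)
                    if c >= n_neg:
                        c = n_neg - 1
                    if np.random.random() >= neg_prob[c]:
                        c = neg_alias[c]
                    cand = neg_ids[c]
                    if cand != j and cand != i:
                        target = cand
                        break
                if target == j:
                    continue
                label = 0.0
            if second_order:
                x = 0.0
                for d in range(dim):
                    x += U[i, d] * C[target, d]
                if x > 15.0:
                    x = 15.0
                elif x < -15.0:
                    x = -15.0
                g = (label - 1.0 / (1.0 + np.exp(-x))) * lr
                for d in range(dim):
                    buf[d] += g * C[target, d]
                    C[target, d] += g * U[i, d]
            else:
                x = 0.0
                for d in range(dim):
                    x += U[i, d] * U[target, d]
                if x > 15.0:
                    x = 15.0
                elif x < -15.0:
                    x = -15.0
                g = (label - 1.0 / (1.0 + np.exp(-x))) * lr
                for d in range(dim):
                    buf[d] += g * U[target, d]
                    U[target, d] += g * U[i, d]
        for d in range(dim):
            U[i, d] += buf[d]


def _init_vectors(n: int, dim: int, rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(-0.5 / dim, 0.5 / dim, size=(n, dim))


def _derive_seed(seed: int, salt: int) -> int:
    return int((seed * np.uint64(2654435761) + np.uint64(salt)) % np.uint64(2**31 - 1))


def _train_single_order(
    g: HeteroGraph, nodes: list[str], dim: int, order: str, config: LineConfig, seed: int
) -> tuple[np.ndarray, np.ndarray | None]:
    index = {n: k for k, n in enumerate(nodes)}
    rng = np.random.default_rng(seed)
    U = _init_vectors(len(nodes), dim, rng)
    C = _init_vectors(len(nodes), dim, rng) if order == "second" else None

    arc_src, arc_dst, arc_w = [], [], []
    for a, b, w in g.edges():
        ia, ib = index[a], index[b]
        arc_src.extend((ia, ib))
        arc_dst.extend((ib, ia))
        arc_w.extend((w, w))
    arc_src = np.asarray(arc_src, dtype=np.int64)
    arc_dst = np.asarray(arc_dst, dtype=np.int64)
    arc_w = np.asarray(arc_w, dtype=float)

    edge_table = build_alias_table(arc_w)
    degrees = np.array([g.degree(n) for n in nodes])
    neg_ids = np.nonzero(degrees > 0)[0].astype(np.int64)
    neg_table = build_alias_table(degrees[neg_ids] ** 0.75)

    total = config.total_samples
    if total is None:
        total = 1000 * g.num_edges
    if total < 1:
        raise ConfigError("total_samples must be >= 1")

    _sgd_kernel(
        U,
        C if C is not None else U,
        arc_src,
        arc_dst,
        edge_table.prob,
        edge_table.alias,
        neg_table.prob,
        neg_table.alias,
        neg_ids,
        config.negative_samples,
        int(total),
        config.learning_rate,
        _derive_seed(seed, 97),
        order == "second",
    )
    return U, C


def train_line(g: HeteroGraph, config: LineConfig | None = None) -> LineModelState:
    """Scalable edge-sampling / negative-sampling trainer.

    Deterministic for a fixed config seed.  Isolated nodes keep their
    seeded random initialisation (they are never sampled).  In ``concat``
    mode two independent embeddings of ``dim/2`` (first order, second
    order) are trained and concatenated per node.
    """
    config = config or LineConfig()
    if g.num_nodes == 0:
        raise ConfigError("cannot embed an empty graph")
    if g.num_edges == 0:
        raise ConfigError("cannot embed a graph with no edges")
    nodes = g.node_names()
    if config.order == "concat":
        half = config.dim // 2
        U1, _ = _train_single_order(g, nodes, half, "first", config, _derive_seed(config.seed, 1))
        U2, _ = _train_single_order(g, nodes, half, "second", config, _derive_seed(config.seed, 2))
        return LineModelState(tuple(nodes), np.hstack([U1, U2]), None, config, "concat")
    U, C = _train_single_order(g, nodes, config.dim, config.order, config, config.seed)
    return LineModelState(tuple(nodes), U, C, config, config.order)


# ---------------------------------------------------------------------------
# exact small-graph trainer (verification oracle)
# ---------------------------------------------------------------------------

_EXACT_MAX_NODES = 200


def _descend(loss_fn, grad_fn, params: list[np.ndarray], iters: int) -> list[float]:
    """Full-batch gradient descent with backtracking; non-increasing loss."""
    step = 0.5
    losses = [loss_fn()]
    for _ in range(iters):
        grads = grad_fn()
        gnorm2 = sum(float(np.sum(gr * gr)) for gr in grads)
        if gnorm2 < 1e-18:
            break
        base = losses[-1]
        accepted = False
        while step > 1e-12:
            for p, gr in zip(params, grads):
                p -= step * gr
            new = loss_fn()
            if new <= base - 1e-4 * step * gnorm2:
                accepted = True
                break
            for p, gr in zip(params, grads):
                p += step * gr
            step *= 0.5
        if not accepted:
            break
        losses.append(new)
        step = min(step * 1.5, 10.0)
    return losses


def exact_train_small(g: HeteroGraph, config: LineConfig | None = None, iters: int = 300) -> LineModelState:
    """Full-batch gradient descent on the exact objectives.

    The exact softmax gradient is O(|V|) per arc, so the trainer refuses
    graphs above 200 nodes -- use :func:`train_line` there.  The returned
    state carries ``loss_history`` (non-increasing; final <= initial).
    """
    config = config or LineConfig()
    if g.num_nodes == 0:
        raise ConfigError("cannot embed an empty graph")
    if g.num_nodes > _EXACT_MAX_NODES:
        raise ConfigError(
            f"exact trainer is limited to {_EXACT_MAX_NODES} nodes "
            f"(got {g.num_nodes}); use train_line instead"
        )
    nodes = g.node_names()
    rng = np.random.default_rng(config.seed)

    if config.order == "concat":
        half_cfg = replace(config, dim=config.dim // 2, order="first")
        s1 = exact_train_small(g, half_cfg, iters)
        s2 = exact_train_small(g, replace(half_cfg, order="second", seed=_derive_seed(config.seed, 2)), iters)
        state = LineModelState(
            tuple(nodes), np.hstack([s1.vertex_vectors, s2.vertex_vectors]), None, config, "concat"
        )
        state.loss_history = [a + b for a, b in zip(s1.loss_history, s2.loss_history)]
        return state

    if config.order == "first":
        U = _init_vectors(len(nodes), config.dim, rng)
        state = LineModelState(tuple(nodes), U, None, config, "first")
        losses = _descend(
            lambda: first_order_objective(state, g),
            lambda: [first_order_gradient(state, g)],
            [U],
            iters,
        )
    else:
        U = _init_vectors(len(nodes), config.dim, rng)
        C = _init_vectors(len(nodes), config.dim, rng)
        state = LineModelState(tuple(nodes), U, C, config, "second")
        losses = _descend(
            lambda: second_order_objective(state, g),
            lambda: list(second_order_gradient(state, g)),
            [U, C],
            iters,
        )
    state.loss_history = losses
    return state


def negative_sampling_objective(
    state: LineModelState, g: HeteroGraph, k_negative: int = 5
) -> float:
    """The negative-sampling surrogate the scalable trainer optimises.

    Computed in closed form (expectation over the d^{3/4} noise
    distribution rather than Monte-Carlo draws):
    ``-sum_arcs w_ij [log s(u'_j.u_i) + K E_noise log s(-u'_k.u_i)]``.
    Used to check that the surrogate ranks states like the exact softmax
    objective.
    """
    if state.order == "second":
        ctx = state.context_vectors
    elif state.order == "first":
        ctx = state.vertex_vectors
    else:
        raise ModeError("negative_sampling_objective needs a single-order state")
    nodes = state.nodes
    degrees = np.array([g.degree(n) for n in nodes])
    active = degrees > 0
    noise = np.zeros_like(degrees, dtype=float)
    noise[active] = degrees[active] ** 0.75
    noise /= noise.sum()
    U = state.vertex_vectors
    total = 0.0
    for a, b, w in g.edges():
        for i, j in ((state.index(a), state.index(b)), (state.index(b), state.index(a))):
            scores = ctx @ U[i]
            total -= w * float(np.log(sigmoid(scores[j])))
            total -= w * k_negative * float(noise @ np.log(sigmoid(-scores)))
    return total


# ---------------------------------------------------------------------------
# word2vec-style text I/O
# ---------------------------------------------------------------------------


def write_embedding(state: LineModelState, path: str | Path, types: Mapping[str, str] | None = None) -> None:
    """Write ``<n> <dim>`` then one ``name v1 ... vdim`` line per node.

    If ``types`` is given, a ``<path>.types.json`` sidecar maps node name
    to node type.
    """
    import json

    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{len(state.nodes)} {state.vertex_vectors.shape[1]}\n")
        for k, name in enumerate(state.nodes):
            vec = " ".join(f"{v:.6g}" for v in state.vertex_vectors[k])
            fh.write(f"{name} {vec}\n")
    if types is not None:
        with open(path.with_suffix(path.suffix + ".types.json"), "w") as fh:
            json.dump({n: types[n] for n in state.nodes}, fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_embedding(path: str | Path) -> dict[str, np.ndarray]:
    vectors: dict[str, np.ndarray] = {}
    with open(path) as fh:
        header = fh.readline().split()
        n, dim = int(header[0]), int(header[1])
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            vectors[parts[0]] = np.asarray([float(x) for x in parts[1:]], dtype=float)
            if len(vectors[parts[0]]) != dim:
                raise ConfigError(f"embedding row for {parts[0]!r} has wrong width")
    if len(vectors) != n:
        raise ConfigError(f"embedding file declares {n} rows, found {len(vectors)}")
    return vectors
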
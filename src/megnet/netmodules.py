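"""Weighted modularity, simulated-annealing partition search, and node roles.

Modularity of a partition of a weighted undirected network:

    Q = sum_s [ l_s / L  -  ( d_s / (2 L) )^2 ]

where ``l_s`` is the sum of link weights inside module ``s`` (each
undirected link counted once), ``L`` the total link weight of the network,
and ``d_s`` the summed node strength of module ``s``. Q is 0 for the
single-module partition, approaches 1 for strongly modular networks, and
equals ``1 - 1/m`` for ``m`` equal modules with no inter-module weight.

The optimal partition is searched by simulated annealing: nodes start in
``ceil(sqrt(N))`` random modules; each step reassigns one uniformly chosen
node to a uniformly chosen different module label in ``[1, N]``; the cost
is ``C = -Q``; a worsening move is accepted with probability
``exp(-(C_f - C_i)/T)``; the temperature starts at 1 and is multiplied by
0.995 every 100 steps, for 1e6 steps by default. The highest-Q labelling
encountered anywhere in the run (not the final state) is returned. An
exhaustive set-partition oracle is provided for small networks.

Node roles under a partition:

* within-module degree z-score ``z_i``: the node's summed weight to its own
  module, standardised by the mean and (population) SD of that quantity
  over the module;
* participation coefficient ``pc_i = 1 - sum_m (kappa_im / k_i)^2`` with
  ``kappa_im`` the node's weight into module ``m`` and ``k_i`` its total
  strength: 0 when all weight is internal, approaching 1 when spread
  evenly over many modules;
* between-module connectivity: mean weight from the node to all nodes
  outside its own module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .connectivity import ConnectivityMatrix

__all__ = [
    "Partition",
    "AnnealingConfig",
    "NodeRoleProfile",
    "modularity_q",
    "anneal_partition",
    "brute_force_partition",
    "node_roles",
    "per_epoch_metrics",
]

_BRUTE_FORCE_MAX_N = 10


@dataclass
class Partition:
    """Node -> module assignment with its modularity score."""

    labels: np.ndarray
    q: float
    n_modules: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D array")
        self.n_modules = int(len(np.unique(self.labels)))


@dataclass(frozen=True)
class AnnealingConfig:
    """Annealing schedule; defaults follow the reference analysis."""

    total_steps: int = 1_000_000
    t_initial: float = 1.0
    cooling_factor: float = 0.995
    cooling_interval: int = 100
    seed: int = 0
    n_restarts: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.cooling_factor < 1):
            raise ValueError("cooling_factor must be in (0, 1)")
        if self.total_steps < self.cooling_interval:
            raise ValueError("total_steps must be >= cooling_interval")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class NodeRoleProfile:
    """Per-node z, pc, between-module connectivity, and strength."""

    z: np.ndarray
    pc: np.ndarray
    between_conn: np.ndarray
    strength: np.ndarray
    labels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def _as_weights(matrix: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    if isinstance(matrix, ConnectivityMatrix):
        return matrix.weights
    w = np.asarray(matrix, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(w, w.T, atol=1e-12):
        raise ValueError("weight matrix must be symmetric")
    return w


def modularity_q(matrix: ConnectivityMatrix | np.ndarray, labels: np.ndarray) -> float:
    """Modularity Q of the given labelling; raises on an all-zero matrix."""
    w = _as_weights(matrix)
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (w.shape[0],):
        raise ValueError("labels length must match matrix size")
    k = w.sum(axis=1)
    two_l = k.sum()
    if two_l <= 0:
        raise ValueError("total weight L is zero; modularity is undefined")
    q = 0.0
    for lab in np.unique(labels):
        members = labels == lab
        l_s = 0.5 * w[np.ix_(members, members)].sum()
        d_s = k[members].sum()
        q += l_s / (0.5 * two_l) - (d_s / two_l) ** 2
    return float(q)


def _anneal_once(w: np.ndarray, config: AnnealingConfig, rng: np.random.Generator):
    """One annealing run; returns (best_labels, best_q) using incremental Q.

    Bookkeeping: ``kappa[i, c]`` is node i's summed weight into module c
    (labels live in 0..N-1 internally), ``d_mod[c]`` the summed strength of
    module c. Moving node i from s to t changes Q by

        dQ = (kappa[i,t] - kappa[i,s]) / L
             - [ (d_s - k_i)^2 + (d_t + k_i)^2 - d_s^2 - d_t^2 ] / (2L)^2
    """
    n = w.shape[0]
    k = w.sum(axis=1)
    two_l = float(k.sum())
    inv_l = 2.0 / two_l
    inv_two_l_sq = 1.0 / (two_l * two_l)

    m0 = math.ceil(math.sqrt(n))
    labels = rng.integers(0, m0, size=n)
    kappa = np.zeros((n, n))
    d_mod = np.zeros(n)
    for c in range(m0):
        members = labels == c
        if members.any():
            kappa[:, c] = w[:, members].sum(axis=1)
            d_mod[c] = k[members].sum()
    q = modularity_q(w, labels)
    best_q, best_labels = q, labels.copy()

    # pre-drawn randomness; label offset in [0, n-2] is shifted past the
    # current label to realise "a different randomly chosen module number"
    nodes = rng.integers(0, n, size=config.total_steps)
    offsets = rng.integers(0, n - 1, size=config.total_steps)
    unifs = rng.random(size=config.total_steps)

    t = config.t_initial
    k_list = k.tolist()
    d_list = d_mod.tolist()
    lab_list = labels.tolist()
    exp = math.exp
    for step in range(config.total_steps):
        if step and step % config.cooling_interval == 0:
            t *= config.cooling_factor
        i = nodes[step]
        s = lab_list[i]
        tgt = offsets[step]
        if tgt >= s:
            tgt += 1
        ki = k_list[i]
        ds, dt = d_list[s], d_list[tgt]
        dq = (kappa[i, tgt] - kappa[i, s]) * inv_l - (
            (ds - ki) ** 2 + (dt + ki) ** 2 - ds * ds - dt * dt
        ) * inv_two_l_sq
        if dq >= 0.0 or unifs[step] < exp(dq / t):
            lab_list[i] = tgt
            d_list[s] = ds - ki
            d_list[tgt] = dt + ki
            col = w[:, i]
            kappa[:, s] -= col
            kappa[:, tgt] += col
            q += dq
            if q > best_q:
                best_q = q
                best_labels = np.array(lab_list)
    return best_labels, best_q


def _compact_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel modules 0..m-1 in order of first appearance (deterministic)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def anneal_partition(
    matrix: ConnectivityMatrix | np.ndarray, config: AnnealingConfig = AnnealingConfig()
) -> Partition:
    """Simulated-annealing search for the maximum-modularity partition.

    Deterministic given ``config.seed``; the best labelling over all steps
    and restarts is returned, ties resolved to the first encountered. The
    returned ``q`` is recomputed from the labelling with the direct sum so
    it is free of incremental-update drift.
    """
    w = _as_weights(matrix)
    n = w.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if w.sum() <= 0:
        raise ValueError("total weight L is zero; modularity is undefined")
    root = np.random.default_rng(config.seed)
    best_labels, best_q = None, -np.inf
    for _ in range(config.n_restarts):
        rng = np.random.default_rng(root.integers(0, 2**63))
        labels, q = _anneal_once(w, config, rng)
        if q > best_q:
            best_q, best_labels = q, labels
    labels = _compact_labels(best_labels)
    return Partition(labels, modularity_q(w, labels), 0)


def _set_partitions(n: int):
    """Yield all set partitions of range(n) as restricted-growth label arrays."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, n_used: int):
        if i == n:
            yield labels.copy()
            return
        for lab in range(n_used + 1):
            labels[i] = lab
            yield from rec(i + 1, max(n_used, lab + 1))

    yield from rec(1, 1)


def brute_force_partition(matrix: ConnectivityMatrix | np.ndarray) -> Partition:
    """Exact maximum-Q partition by exhaustive enumeration (N <= 10)."""
    w = _as_weights(matrix)
    n = w.shape[0]
    if n > _BRUTE_FORCE_MAX_N:
        raise ValueError(
            f"exhaustive enumeration is limited to N <= {_BRUTE_FORCE_MAX_N} "
            f"(Bell-number growth); got N = {n}"
        )
    best_q, best_labels = -np.inf, None
    for labels in _set_partitions(n):
        q = modularity_q(w, labels)
        if q > best_q:
            best_q, best_labels = q, labels
    return Partition(best_labels, best_q, 0)


def node_roles(
    matrix: ConnectivityMatrix | np.ndarray,
    partition: Partition,
    sd_mode: str = "population",
    between_mode: str = "mean",
) -> NodeRoleProfile:
    """Within-module degree z, participation coefficient, between-module
    connectivity, and strength for every node under ``partition``.

    Degenerate cases: a module of size 1, or one whose within-strengths are
    all equal, gets z = 0 for its nodes; an isolated node (k_i = 0) gets
    pc = 0. ``sd_mode`` selects population (default) or sample SD in the z
    standardisation; ``between_mode`` selects mean (default) or sum of the
    weights to out-module nodes.
    """
    if sd_mode not in ("population", "sample"):
        raise ValueError("sd_mode must be 'population' or 'sample'")
    if between_mode not in ("mean", "sum"):
        raise ValueError("between_mode must be 'mean' or 'sum'")
    w = _as_weights(matrix)
    n = w.shape[0]
    labels = np.asarray(partition.labels, dtype=int)
    if labels.shape != (n,):
        raise ValueError("partition does not match matrix size")
    uniq = np.unique(labels)
    onehot = (labels[None, :] == uniq[:, None]).T.astype(float)  # n x m
    kappa = w @ onehot  # kappa[i, m]: weight of i into module m
    k = w.sum(axis=1)
    own_col = np.searchsorted(uniq, labels)
    within = kappa[np.arange(n), own_col]

    z = np.zeros(n)
    for j, lab in enumerate(uniq):
        members = labels == lab
        vals = within[members]
        if members.sum() < 2:
            continue
        ddof = 0 if sd_mode == "population" else 1
        sd = vals.std(ddof=ddof)
        if sd == 0:
            continue
        z[members] = (vals - vals.mean()) / sd

    pc = np.zeros(n)
    pos = k > 0
    pc[pos] = 1.0 - ((kappa[pos] / k[pos, None]) ** 2).sum(axis=1)

    out_weight = k - within
    n_outside = n - onehot.sum(axis=0)[own_col]
    if between_mode == "sum":
        between = out_weight
    else:
        between = np.where(n_outside > 0, out_weight / np.maximum(n_outside, 1), 0.0)
    return NodeRoleProfile(z, pc, between, k, labels.copy())


def per_epoch_metrics(
    matrices: list[ConnectivityMatrix],
    config: AnnealingConfig = AnnealingConfig(),
    sd_mode: str = "population",
    between_mode: str = "mean",
) -> dict:
    """Anneal each epoch matrix and average the resulting metrics.

    The partition search runs separately per epoch (each epoch gets a seed
    derived from ``config.seed`` and its position); scalars (q, n_modules)
    and per-node roles are then averaged across epochs to give the
    subject-level values for one band.
    """
    if not matrices:
        raise ValueError("need at least one epoch matrix")
    qs, n_mods, zs, pcs, betweens = [], [], [], [], []
    for idx, m in enumerate(matrices):
        ep_seed = int(np.random.SeedSequence([config.seed, idx]).generate_state(1)[0] % 2**31)
        part = anneal_partition(m, replace(config, seed=ep_seed))
        roles = node_roles(m, part, sd_mode=sd_mode, between_mode=between_mode)
        qs.append(part.q)
        n_mods.append(part.n_modules)
        zs.append(roles.z)
        pcs.append(roles.pc)
        betweens.append(roles.between_conn)
    return {
        "q": float(np.mean(qs)),
        "n_modules": float(np.mean(n_mods)),
        "z": np.mean(zs, axis=0),
        "pc": np.mean(pcs, axis=0),
        "between_conn": np.mean(betweens, axis=0),
        "per_epoch_q": qs,
    }
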
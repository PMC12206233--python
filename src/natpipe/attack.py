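"""Degree-targeted attack simulation and network attack tolerance (NAT).

A binarized graph is attacked by iteratively deleting its most-connected
node (highest degree, recomputed on the surviving subgraph by default;
ties go to the lowest node index). After each deletion the surviving
subgraph's global efficiency is recorded:

    GE = 1 / (N (N - 1)) * sum_{i != j} 1 / L_ij

with L_ij the unweighted shortest-path length and disconnected pairs
contributing zero; N is the *current* node count, and GE of a graph with
N <= 1 is zero by convention. NAT is the normalized area under the
efficiency-versus-removals curve — the mean GE over the N curve points
(intact graph plus each of the N-1 removals) — i.e. the fraction of the
maximum possible efficiency retained during the attack.

The all-pairs BFS inner loop is numba-compiled: attack curves recompute
shortest paths at every one of N steps, which dominates pipeline runtime
for the 300-node whole-brain graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .atlas import NETWORK_LEVELS, ROIAtlas
from .connectome import DENSITY_GRID, ThresholdedGraph, extract_subnetwork, \
    proportional_threshold
from .errors import ContractError, DomainError


@njit(cache=True)
def _inv_path_sum(indptr, indices, n):
    """Sum of 1/L_ij over ordered pairs with finite BFS distance L_ij."""
    total = 0.0
    dist = np.empty(n, np.int32)
    queue = np.empty(n, np.int32)
    for s in range(n):
        dist[:] = -1
        dist[s] = 0
        queue[0] = s
        head, tail = 0, 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[u]
            for k in range(indptr[u], indptr[u + 1]):
                v = indices[k]
                if dist[v] < 0:
                    dist[v] = du + 1
                    queue[tail] = v
                    tail += 1
                    total += 1.0 / (du + 1)
    return total


def _csr(adj: np.ndarray):
    src, dst = np.nonzero(adj)
    indices = dst.astype(np.int32)  # np.nonzero is already row-major sorted
    counts = np.bincount(src, minlength=adj.shape[0])
    indptr = np.zeros(adj.shape[0] + 1, np.int64)
    np.cumsum(counts, out=indptr[1:])
    return indptr, indices


def _as_adjacency(graph) -> np.ndarray:
    if isinstance(graph, ThresholdedGraph):
        return graph.adjacency
    a = np.asarray(graph)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ContractError("adjacency must be square")
    if a.dtype != bool:
        vals = np.unique(a)
        if not np.all(np.isin(vals, (0, 1))):
            raise ContractError("graph must be binary (weighted input rejected)")
        a = a.astype(bool)
    if not np.array_equal(a, a.T):
        raise ContractError("graph must be undirected (symmetric adjacency)")
    if np.any(np.diag(a)):
        raise ContractError("graph must not contain self-loops")
    return a


def global_efficiency(graph) -> float:
    """Average inverse shortest-path length over all ordered node pairs.

    Disconnected pairs contribute zero; graphs with at most one node have
    efficiency zero by convention.
    """
    adj = _as_adjacency(graph)
    n = adj.shape[0]
    if n <= 1:
        return 0.0
    indptr, indices = _csr(adj)
    return _inv_path_sum(indptr, indices, n) / (n * (n - 1))


@dataclass(frozen=True)
class AttackCurve:
    """Global efficiency after k = 0 .. N-1 targeted node removals."""

    ge_values: np.ndarray
    removal_order: tuple  # node labels, length N-1 (the last node survives)

    def __post_init__(self):
        ge = np.asarray(self.ge_values, float)
        if np.any((ge < -1e-12) | (ge > 1 + 1e-12)):
            raise ContractError("efficiency values must lie in [0, 1]")
        object.__setattr__(self, "ge_values", ge)

    def __len__(self) -> int:
        return len(self.ge_values)


def targeted_attack(graph, mode: str = "adaptive") -> AttackCurve:
    """Attack curve under degree-targeted node removal.

    ``mode="adaptive"`` (default) recomputes degrees on the surviving
    subgraph before every removal; ``mode="static"`` fixes the removal
    order by the intact graph's degrees. Ties are broken by ascending node
    index in both modes. The curve holds the intact graph's efficiency at
    k = 0 and the survivors' efficiency after each of the N-1 removals.
    """
    if mode not in ("adaptive", "static"):
        raise DomainError(f"unknown attack mode {mode!r}")
    adj = _as_adjacency(graph).copy()
    labels = getattr(graph, "roi_ids", ()) or tuple(range(adj.shape[0]))
    n0 = adj.shape[0]
    if n0 == 0:
        return AttackCurve(ge_values=np.empty(0), removal_order=())

    alive = np.ones(n0, bool)
    static_order = None
    if mode == "static":
        deg0 = adj.sum(1)
        static_order = np.lexsort((np.arange(n0), -deg0))
    ge = np.zeros(n0)
    removed = []
    for k in range(n0):
        sub = adj[np.ix_(alive, alive)]
        if sub.any():
            ge[k] = global_efficiency(sub)
        else:
            ge[k:] = 0.0
            if k < n0 - 1 and mode == "adaptive":
                # edgeless remainder: all degrees zero, ties -> ascending index
                removed.extend(int(i) for i in np.flatnonzero(alive)[:-1])
            elif k < n0 - 1:
                removed.extend(int(i) for i in static_order if alive[i])
                removed = removed[: n0 - 1]
            break
        if k == n0 - 1:
            break
        if mode == "adaptive":
            deg = adj.sum(1)
            deg[~alive] = -1
            target = int(np.argmax(deg))  # argmax takes the lowest tied index
        else:
            target = int(static_order[k])
        alive[target] = False
        adj[target, :] = False
        adj[:, target] = False
        removed.append(target)
    return AttackCurve(
        ge_values=ge, removal_order=tuple(labels[i] for i in removed)
    )


def nat_score(curve: AttackCurve) -> float:
    """NAT: mean retained efficiency over the attack curve.

    The area under the efficiency-versus-removals curve normalized by the
    number of curve points (the network's node count), so a graph that held
    efficiency 1 through every attack scores 1.
    """
    if len(curve) == 0:
        raise DomainError("cannot score an empty attack curve")
    return float(np.mean(curve.ge_values))


def nat_table(matrices: dict, atlas: ROIAtlas, networks=NETWORK_LEVELS,
              densities=DENSITY_GRID, rank: str = "signed",
              mode: str = "adaptive") -> pd.DataFrame:
    """Long NAT table: one row per participant x network x density.

    ``matrices`` maps participant id to an atlas-sized global
    ConnectivityMatrix; each network's own submatrix is thresholded at each
    density (per-network density control), attacked, and scored.
    Participants with a missing matrix are skipped with a warning.
    """
    rows = []
    for pid in matrices:
        cm = matrices[pid]
        if cm is None:
            warnings.warn(f"missing connectivity matrix for {pid!r}; skipped",
                          stacklevel=2)
            continue
        for net in networks:
            sub = extract_subnetwork(cm, atlas, net)
            for d in densities:
                graph = proportional_threshold(sub, d, rank=rank)
                nat = nat_score(targeted_attack(graph, mode=mode))
                rows.append((pid, net, float(d), nat))
    return pd.DataFrame(rows, columns=["participant", "network", "density", "nat"])


def mean_nat(records) -> float:
    """Mean NAT across the nine density levels of one participant-network."""
    vals = np.asarray(
        records["nat"] if isinstance(records, pd.DataFrame) else records, float
    )
    if len(vals) != len(DENSITY_GRID):
        raise ContractError(
            f"expected {len(DENSITY_GRID)} density records, got {len(vals)}"
        )
    return float(vals.mean())


def mean_nat_table(nat_records: pd.DataFrame) -> pd.DataFrame:
    """Per participant-network mean NAT over the density sweep (wide table)."""
    counts = nat_records.groupby(["participant", "network"])["nat"].count()
    bad = counts[counts != len(DENSITY_GRID)]
    if len(bad):
        raise ContractError(
            f"incomplete density sweeps for: {list(bad.index)[:5]}"
        )
    wide = (
        nat_records.groupby(["participant", "network"])["nat"]
        .mean()
        .unstack("network")
    )
    wide.columns = [f"nat_{c}" for c in wide.columns]
    return wide
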
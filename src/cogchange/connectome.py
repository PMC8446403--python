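"""Graph-theoretic analysis of structural brain connectomes.

Weighted matrices are normalized by mean network strength, thresholded to a
range of network densities (0.06–0.12 by default), and analysed as binary
undirected graphs: mean clustering, characteristic path length, global/local
efficiency, normalized node degree, and betweenness centrality. Clustering
and path length are normalized by the means of degree-preserving rewired
random networks, and small-worldness is
SW = (C/C_rand) / (L/L_rand). Each metric is summarized as the area under
its curve (AUC) across the density grid (reported x100), and group
differences across time are tested per metric with the repeated-measures
group x time interaction, FDR-corrected across nodes for nodal metrics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from numba import njit
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from statsmodels.stats.multitest import multipletests

from .datatypes import Connectome

log = logging.getLogger(__name__)

__all__ = [
    "DensityGrid",
    "NullEnsemble",
    "NetworkMetricSet",
    "normalize_strength",
    "threshold_to_density",
    "clustering_and_path",
    "random_reference",
    "small_worldness",
    "efficiencies",
    "node_metrics",
    "auc_over_densities",
    "subject_metrics",
    "metric_auc_frame",
    "network_group_analysis",
]

GLOBAL_METRICS = (
    "normalized_clustering",
    "normalized_path_length",
    "small_worldness",
    "global_efficiency",
    "local_efficiency",
)
NODE_METRICS = ("node_degree_normalized", "betweenness")


@dataclass(frozen=True)
class DensityGrid:
    """Evenly spaced network densities over which metrics are computed."""

    d_min: float = 0.06
    d_max: float = 0.12
    step: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.d_min <= self.d_max < 1):
            raise ValueError("require 0 < d_min <= d_max < 1")
        if self.step <= 0:
            raise ValueError("step must be > 0")

    @property
    def densities(self) -> np.ndarray:
        n = int(round((self.d_max - self.d_min) / self.step)) + 1
        return np.round(self.d_min + self.step * np.arange(n), 10)


@dataclass(frozen=True)
class NullEnsemble:
    """Degree-preserving rewired ensemble summary for one graph."""

    n_random: int
    seed: int
    c_rand_mean: float
    l_rand_mean: float


@dataclass
class NetworkMetricSet:
    """All per-density metrics and AUC summaries for one subject-timepoint."""

    subject_id: str
    timepoint: str
    densities: np.ndarray
    node_labels: list[str]
    per_density: dict[str, np.ndarray] = field(default_factory=dict)
    node_per_density: dict[str, np.ndarray] = field(default_factory=dict)
    auc: dict[str, float] = field(default_factory=dict)
    node_auc: dict[str, np.ndarray] = field(default_factory=dict)


def _adjacency(graph) -> np.ndarray:
    """Boolean adjacency from an nx.Graph or array-like."""
    if isinstance(graph, nx.Graph):
        return nx.to_numpy_array(graph, nodelist=sorted(graph.nodes())) > 0
    a = np.asarray(graph)
    return a > 0


def normalize_strength(conn: Connectome) -> Connectome:
    """Divide every weight by the mean off-diagonal (upper-triangle) weight,
    zeros included, so the mean network strength becomes 1. Scale-invariant."""
    w = conn.weights
    iu = np.triu_indices(conn.n_nodes, k=1)
    mean_w = float(np.mean(w[iu]))
    if mean_w <= 0:
        raise ValueError("cannot normalize an all-zero connectivity matrix")
    return conn.with_weights(w / mean_w)


def threshold_to_density(conn: Connectome, d: float) -> nx.Graph:
    """Binary graph keeping the k = round(d·n(n−1)/2) strongest edges.

    Ties at the cutoff weight are broken deterministically by node-index
    lexicographic order. If fewer nonzero weights exist than k, all nonzero
    edges are kept with a warning; the achieved density is stored on the
    graph as ``G.graph["achieved_density"]``.
    """
    if not 0 < d < 1:
        raise ValueError("density must be in (0, 1)")
    n = conn.n_nodes
    n_pairs = n * (n - 1) // 2
    k = int(round(d * n_pairs))
    iu, ju = np.triu_indices(n, k=1)
    w = conn.weights[iu, ju]
    # primary key: weight descending; ties: (i, j) ascending
    order = np.lexsort((ju, iu, -w))
    nonzero = int(np.count_nonzero(w))
    if nonzero < k:
        warnings.warn(
            f"only {nonzero} nonzero edges available for target {k}; keeping all",
            stacklevel=2,
        )
        k = nonzero
    keep = order[:k]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(zip(iu[keep].tolist(), ju[keep].tolist()))
    g.graph["achieved_density"] = k / n_pairs if n_pairs else 0.0
    return g


def _distances(a: np.ndarray) -> np.ndarray:
    return shortest_path(csr_matrix(a.astype(np.int8)), method="D",
                         unweighted=True, directed=False)


def _clustering_from_adj(a: np.ndarray) -> float:
    af = a.astype(float)
    deg = af.sum(axis=1)
    tri = np.diag(af @ af @ af) / 2.0
    denom = deg * (deg - 1) / 2.0
    c = np.zeros_like(deg)
    mask = deg >= 2
    c[mask] = tri[mask] / denom[mask]
    return float(c.mean())


def _path_length_from_adj(a: np.ndarray, dist: np.ndarray | None = None) -> float:
    dist = _distances(a) if dist is None else dist
    n = a.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    n_disconnected = int(off.sum() - finite.sum())
    if n_disconnected:
        log.debug("path length: excluding %d disconnected ordered pairs", n_disconnected)
    if not finite.any():
        raise ValueError("no reachable node pairs")
    return float(dist[finite].mean())


def clustering_and_path(graph) -> tuple[float, float]:
    """(mean clustering coefficient, characteristic path length).

    Nodes of degree < 2 contribute clustering 0; path length averages over
    reachable ordered pairs only (disconnected pairs excluded, logged).
    """
    a = _adjacency(graph)
    if not a.any():
        raise ValueError("graph has no edges")
    return _clustering_from_adj(a), _path_length_from_adj(a)


@njit(cache=False)
def _swap_loop(edges, adj, n_target, seed, max_tries):  # pragma: no cover - numba
    np.random.seed(seed)
    m = edges.shape[0]
    accepted = 0
    tries = 0
    while accepted < n_target and tries < max_tries:
        tries += 1
        i = np.random.randint(0, m)
        j = np.random.randint(0, m)
        if i == j:
            continue
        a, b = edges[i, 0], edges[i, 1]
        c, d = edges[j, 0], edges[j, 1]
        if np.random.randint(0, 2) == 1:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, c] or adj[b, d]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, c] = True
        adj[c, a] = True
        adj[b, d] = True
        adj[d, b] = True
        edges[i, 0], edges[i, 1] = a, c
        edges[j, 0], edges[j, 1] = b, d
        accepted += 1
    return accepted


def _rewired_adjacency(a: np.ndarray, n_swaps: int, seed: int) -> tuple[np.ndarray, int]:
    """One degree-preserving double-edge-swap randomization of ``a``."""
    iu, ju = np.nonzero(np.triu(a, k=1))
    edges = np.column_stack([iu, ju]).astype(np.int64)
    adj = a.copy()
    accepted = _swap_loop(edges, adj, n_swaps, seed, max_tries=100 * max(n_swaps, 1))
    return adj, int(accepted)


def random_reference(graph, n_random: int = 20, seed: int = 0) -> NullEnsemble:
    """Mean clustering and path length of degree-preserving rewired networks.

    Each null applies 10·|E| accepted double-edge swaps (self-loops and
    multi-edges rejected), exactly preserving the degree sequence. Fully
    reproducible from ``seed``. If no legal swap exists, the ensemble is
    copies of the original with a warning.
    """
    a = _adjacency(graph)
    n_edges = int(a.sum() // 2)
    if n_edges < 2:
        raise ValueError("need at least 2 edges for degree-preserving rewiring")
    n_swaps = 10 * n_edges
    seeds = np.random.SeedSequence(seed).generate_state(n_random) % np.int64(2**31 - 1)
    cs, ls = [], []
    any_swaps = False
    for s in seeds:
        null_adj, accepted = _rewired_adjacency(a, n_swaps, int(s))
        any_swaps = any_swaps or accepted > 0
        cs.append(_clustering_from_adj(null_adj))
        ls.append(_path_length_from_adj(null_adj))
    if not any_swaps:
        warnings.warn("no legal edge swap exists; null ensemble equals the original graph",
                      stacklevel=2)
    return NullEnsemble(
        n_random=n_random,
        seed=seed,
        c_rand_mean=float(np.mean(cs)),
        l_rand_mean=float(np.mean(ls)),
    )


def small_worldness(
    c: float, c_rand: float, l: float, l_rand: float
) -> tuple[float, float, float]:
    """(C/C_rand, L/L_rand, SW) with SW = (C/C_rand)/(L/L_rand)."""
    for name, v in (("C", c), ("C_rand", c_rand), ("L", l), ("L_rand", l_rand)):
        if not v > 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    gamma = c / c_rand
    lam = l / l_rand
    return gamma, lam, gamma / lam


def efficiencies(graph) -> tuple[float, float]:
    """(global efficiency, local efficiency) of a binary undirected graph.

    Global: mean of 1/d over ordered node pairs (0 for disconnected pairs).
    Local: mean over all nodes of the global efficiency of each node's open
    neighborhood subgraph; nodes of degree < 2 contribute 0.
    """
    a = _adjacency(graph)
    n = a.shape[0]
    if n < 2:
        return 0.0, 0.0
    glob = _global_efficiency_adj(a)
    local = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(a[i])
        if nb.size >= 2:
            local[i] = _global_efficiency_adj(a[np.ix_(nb, nb)])
    return glob, float(local.mean())


def _global_efficiency_adj(a: np.ndarray) -> float:
    n = a.shape[0]
    if n < 2:
        return 0.0
    dist = _distances(a)
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(dist)
    finite = np.isfinite(dist) & off
    inv[finite] = 1.0 / dist[finite]
    return float(inv[off].mean())


def node_metrics(graph) -> tuple[np.ndarray, np.ndarray]:
    """(normalized node degree, betweenness centrality) vectors.

    Degree is normalized by the mean network degree; betweenness is the
    pair-normalized fraction of shortest paths through each node.
    """
    a = _adjacency(graph)
    deg = a.sum(axis=1).astype(float)
    mean_deg = deg.mean()
    norm_deg = deg / mean_deg if mean_deg > 0 else np.zeros_like(deg)
    g = nx.from_numpy_array(a)
    bet = nx.betweenness_centrality(g, normalized=True)
    bet_vec = np.array([bet[i] for i in range(a.shape[0])])
    return norm_deg, bet_vec


def auc_over_densities(values: np.ndarray, densities: np.ndarray | DensityGrid) -> float:
    """Trapezoidal integral of a metric over the density grid, x100."""
    d = densities.densities if isinstance(densities, DensityGrid) else np.asarray(densities, float)
    v = np.asarray(values, float)
    if v.shape[0] != d.shape[0]:
        raise ValueError(f"{v.shape[0]} values for {d.shape[0]} densities")
    if not np.all(np.isfinite(v)):
        raise ValueError("metric values must be finite at every grid density")
    return float(np.trapezoid(v, d) * 100.0)


def subject_metrics(
    conn: Connectome,
    grid: DensityGrid = DensityGrid(),
    n_random: int = 20,
    seed: int = 0,
    nodal: bool = True,
) -> NetworkMetricSet:
    """Full density-grid metric profile with AUC summaries for one connectome.

    The input is strength-normalized, thresholded at every grid density, and
    each thresholded graph is compared against its own degree-preserving null
    ensemble for the normalized clustering/path-length and small-worldness.
    """
    conn = normalize_strength(conn)
    densities = grid.densities
    n_d = len(densities)
    per = {m: np.empty(n_d) for m in GLOBAL_METRICS}
    node_per = {m: np.empty((n_d, conn.n_nodes)) for m in (NODE_METRICS if nodal else ())}
    sub_seeds = np.random.SeedSequence(seed).generate_state(n_d) % np.int64(2**31 - 1)
    for idx, d in enumerate(densities):
        g = threshold_to_density(conn, float(d))
        a = _adjacency(g)
        c, l = _clustering_from_adj(a), _path_length_from_adj(a)
        null = random_reference(a, n_random=n_random, seed=int(sub_seeds[idx]))
        gamma, lam, sw = small_worldness(c, null.c_rand_mean, l, null.l_rand_mean)
        per["normalized_clustering"][idx] = gamma
        per["normalized_path_length"][idx] = lam
        per["small_worldness"][idx] = sw
        ge, le = efficiencies(a)
        per["global_efficiency"][idx] = ge
        per["local_efficiency"][idx] = le
        if nodal:
            nd, bt = node_metrics(a)
            node_per["node_degree_normalized"][idx] = nd
            node_per["betweenness"][idx] = bt
    ms = NetworkMetricSet(
        subject_id=conn.subject_id,
        timepoint=conn.timepoint.value,
        densities=densities,
        node_labels=list(conn.node_labels),
        per_density=per,
        node_per_density=node_per,
    )
    ms.auc = {m: auc_over_densities(v, densities) for m, v in per.items()}
    ms.node_auc = {
        m: np.array([auc_over_densities(arr[:, i], densities) for i in range(arr.shape[1])])
        for m, arr in node_per.items()
    }
    return ms


def metric_auc_frame(
    metric_sets: list[NetworkMetricSet], groups: dict[str, str]
) -> pd.DataFrame:
    """Tidy AUC table: one row per subject/timepoint/metric(/node)."""
    rows = []
    for ms in metric_sets:
        grp = groups[ms.subject_id]
        for m, v in ms.auc.items():
            rows.append(
                {"subject_id": ms.subject_id, "group": grp, "timepoint": ms.timepoint,
                 "metric": m, "node": None, "value": v}
            )
        for m, vec in ms.node_auc.items():
            for i, v in enumerate(vec):
                rows.append(
                    {"subject_id": ms.subject_id, "group": grp, "timepoint": ms.timepoint,
                     "metric": m, "node": ms.node_labels[i], "value": float(v)}
                )
    return pd.DataFrame(rows)


def network_group_analysis(auc_frame: pd.DataFrame) -> pd.DataFrame:
    """Group x time tests on metric AUCs, with BH-FDR across nodes.

    For each (metric, node) the repeated-measures group x time interaction F
    is computed as the between-group one-way ANOVA on per-subject
    Δ = t2 − t1 (exact for two timepoints). Node-level p-values are
    Benjamini–Hochberg adjusted across all nodes within a metric. Subjects
    missing a timepoint are excluded with a log entry. Returns one row per
    test with Δ group means.
    """
    df = auc_frame.copy()
    df["node"] = df["node"].where(pd.notna(df["node"]), None)
    rows = []
    for (metric, node), sub in df.groupby(["metric", "node"], dropna=False):
        node = None if pd.isna(node) else node
        wide = sub.pivot_table(index=["subject_id", "group"], columns="timepoint",
                               values="value", aggfunc="first")
        if "t1" not in wide.columns or "t2" not in wide.columns:
            continue
        incomplete = wide["t1"].isna() | wide["t2"].isna()
        if incomplete.any():
            for sid in wide.index[incomplete]:
                log.info("excluding subject %s from %s/%s: missing timepoint",
                         sid[0], metric, node)
            wide = wide[~incomplete]
        delta = wide["t2"] - wide["t1"]
        grp = wide.index.get_level_values("group")
        d_pat = delta[grp == "patient"].to_numpy()
        d_con = delta[grp == "control"].to_numpy()
        if len(d_pat) < 2 or len(d_con) < 2:
            continue
        f, p = stats.f_oneway(d_pat, d_con)
        rows.append(
            {"metric": metric, "node": node, "f": float(f), "p": float(p),
             "delta_mean_patient": float(d_pat.mean()),
             "delta_sd_patient": float(d_pat.std(ddof=1)),
             "delta_mean_control": float(d_con.mean()),
             "delta_sd_control": float(d_con.std(ddof=1))}
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["p_fdr"] = np.nan
    for metric in out["metric"].unique():
        mask = (out["metric"] == metric) & out["node"].notna()
        if mask.any():
            out.loc[mask, "p_fdr"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    return out
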
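"""Feature correlation network: Spearman edges, 2-D layout, communities.

Every pair of immune features is tested with Spearman's rank correlation
(midranks for ties); an edge is drawn iff the Bonferroni-adjusted p-value —
raw p times the number of tested pairs — is below alpha.  With the default
273 features that family is C(273, 2) = 37,128 pairs.  The layout embeds the
association structure (distance 1 - |rho|) in 2-D with t-SNE, and communities
are found by greedy modularity maximization over the significant edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class CorrelationNetwork:
    """Correlation network over feature nodes.

    ``graph`` holds every feature as a node (with annotation attributes) and
    the Bonferroni-significant correlations as edges (attributes ``rho`` and
    ``p_raw``).  The full rho and raw-p matrices are kept alongside.
    """

    graph: nx.Graph
    rho: pd.DataFrame
    p_raw: pd.DataFrame
    n_pairs: int
    alpha: float
    scope: str
    layout: pd.DataFrame | None = None
    communities: pd.Series | None = None
    community_labels: dict[int, str] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def node_table(self) -> pd.DataFrame:
        rows = dict(self.graph.nodes(data=True))
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "feature"
        if self.layout is not None:
            df = df.join(self.layout)
        if self.communities is not None:
            df["community"] = self.communities
            df["community_label"] = self.communities.map(self.community_labels)
        return df

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"feature_i": u, "feature_j": v, **d}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["feature_i", "feature_j", "rho", "p_raw"])

    def write(self, directory, prefix: str = "network") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.node_table().to_csv(directory / f"{prefix}_nodes.csv")
        self.edge_table().to_csv(directory / f"{prefix}_edges.csv", index=False)
        g = self.graph.copy()
        if self.layout is not None:
            for n in g.nodes:
                g.nodes[n]["x"] = float(self.layout.loc[n, "x"])
                g.nodes[n]["y"] = float(self.layout.loc[n, "y"])
        if self.communities is not None:
            for n in g.nodes:
                g.nodes[n]["community"] = int(self.communities.loc[n])
        nx.write_graphml(g, directory / f"{prefix}.graphml")


#: Monte-Carlo permutation-null size and seed for moderate sample sizes.
_MC_PERMUTATIONS = 2_000_000
_MC_SEED = 12345
#: Largest n handled by the permutation-calibrated null before the
#: t-approximation takes over (where it is accurate far into the tails).
_MC_MAX_N = 128

_null_cache: dict[tuple[str, int], np.ndarray] = {}


def spearman_null_abs_rho(n: int, method: str) -> np.ndarray:
    """Sorted |rho| null distribution for untied samples of size ``n``.

    ``method="exact"`` enumerates all n! rank permutations (n <= 10);
    ``method="mc"`` draws a fixed-seed sample of 2e6 permutations.  The
    distribution is universal in the absence of ties, so it is computed once
    per (method, n) and cached.
    """
    key = (method, n)
    if key in _null_cache:
        return _null_cache[key]
    c = np.arange(1, n + 1, dtype=float) - (n + 1) / 2.0
    denom = float((c**2).sum())
    if method == "exact":
        if n > 10:
            raise ValueError("exact enumeration supported for n <= 10")
        from itertools import permutations as _perms

        P = np.array(list(_perms(range(n))), dtype=np.intp)
        vals = np.abs(c[P] @ c) / denom
    elif method == "mc":
        rng = np.random.default_rng(_MC_SEED)
        chunks = []
        per_chunk = 200_000
        for _ in range(_MC_PERMUTATIONS // per_chunk):
            u = rng.random((per_chunk, n))
            P = np.argsort(u, axis=1)
            chunks.append(np.abs(c[P] @ c).astype(np.float32) / denom)
        vals = np.concatenate(chunks)
    else:
        raise ValueError(f"unknown null method {method!r}")
    vals.sort()
    _null_cache[key] = vals
    return vals


def _permutation_pvalues(abs_rho: np.ndarray, n: int, method: str) -> np.ndarray:
    null = spearman_null_abs_rho(n, method)
    N = len(null)
    n_ge = N - np.searchsorted(null, abs_rho - 1e-12, side="left")
    if method == "mc":
        return (1.0 + n_ge) / (N + 1.0)
    return n_ge / N


def spearman_matrix(
    X: pd.DataFrame, p_method: str = "auto"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and two-sided p for all column pairs (midrank ties).

    ``p_method``: ``"auto"`` uses exact permutation enumeration for n <= 10,
    a fixed-seed permutation-calibrated null for n <= 128 (the
    t-approximation is anti-conservative deep in the tails at these sample
    sizes, exactly where Bonferroni thresholds live), and the
    t-approximation beyond; ``"exact"``, ``"mc"`` and ``"t"`` force one
    method.  Tied data are tested against the untied permutation null
    (midrank rho), a standard approximation.
    """
    cols = list(X.columns)
    n = len(X)
    ranks = stats.rankdata(X.to_numpy(dtype=float), axis=0)
    sd = ranks.std(axis=0)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.asarray(rho, dtype=float)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)

    if p_method == "auto":
        p_method = "exact" if n <= 10 else ("mc" if n <= _MC_MAX_N else "t")
    if p_method == "t":
        with np.errstate(invalid="ignore", divide="ignore"):
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        p[np.isinf(t)] = 0.0  # |rho| == 1
    else:
        flat = np.abs(rho).ravel()
        ok = ~np.isnan(flat)
        p = np.full(flat.shape, np.nan)
        p[ok] = _permutation_pvalues(flat[ok], n, p_method)
        p = p.reshape(rho.shape)
    np.fill_diagonal(p, 0.0)
    return (pd.DataFrame(rho, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))


def spearman_exact_p(x, y) -> tuple[float, float]:
    """Exact permutation rho and p for one pair (n <= 10).

    Enumerates all n! permutations of one variable's ranks; the p-value is
    the fraction of permutations with |rho| at least the observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n > 10:
        raise ValueError("exact permutation p-values are supported for n <= 10")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    if denom == 0:
        return np.nan, np.nan
    rho_obs = float((rx_c * ry_c).sum() / denom)
    perms = np.array(list(permutations(range(n))), dtype=np.intp)
    rho_all = (rx_c[perms] * ry_c).sum(axis=1) / denom
    p = float(np.mean(np.abs(rho_all) >= abs(rho_obs) - 1e-12))
    return rho_obs, p


def build_network(
    features: FeatureTable,
    scope: str = "all",
    alpha: float = 0.05,
    feature_class: str = "all",
    univariate_p: pd.Series | None = None,
    p_method: str = "auto",
) -> CorrelationNetwork:
    """Build the Bonferroni-thresholded Spearman correlation network.

    ``scope`` is ``"all"`` (samples from every timepoint) or a timepoint
    label; ``feature_class`` restricts to ``"functional"`` or
    ``"frequency"`` features when requested.  Constant features keep their
    node but contribute no edges.
    """
    ft = features if scope == "all" else features.at_timepoint(scope)
    if feature_class != "all":
        ft = ft.select_class(feature_class)
    if len(ft.values) < 4:
        raise ValueError("need at least 4 samples in scope")
    X = ft.values

    rho, p = spearman_matrix(X, p_method=p_method)
    m = len(X.columns)
    valid = ~np.isnan(rho.to_numpy())
    iu = np.triu_indices(m, k=1)
    n_pairs = int(valid[iu].sum())
    n_constant = int((~valid[iu]).sum())
    if n_constant:
        logger.warning("%d pairs skipped (constant features)", n_constant)

    g = nx.Graph()
    for fname in X.columns:
        ann = ft.annotations.loc[fname]
        attrs = {
            "population": ann["population"], "marker": ann["marker"],
            "feature_class": ann["feature_class"], "compartment": ann["compartment"],
        }
        if univariate_p is not None and fname in univariate_p.index:
            attrs["neg_log10_p"] = float(-np.log10(max(univariate_p[fname], 1e-300)))
        g.add_node(fname, **attrs)

    rv = rho.to_numpy()
    pv = p.to_numpy()
    cols = list(X.columns)
    for a, b in zip(*iu):
        if not valid[a, b]:
            continue
        if pv[a, b] * n_pairs < alpha:
            g.add_edge(cols[a], cols[b], rho=float(rv[a, b]), p_raw=float(pv[a, b]))

    return CorrelationNetwork(graph=g, rho=rho, p_raw=p, n_pairs=n_pairs,
                              alpha=alpha, scope=scope)


def layout_network(net: CorrelationNetwork, seed: int = 0) -> pd.DataFrame:
    """Deterministic-for-seed 2-D embedding of the association structure.

    Uses t-SNE on the dissimilarity 1 - |rho| (missing correlations treated
    as maximally distant).  Networks too small for a meaningful perplexity
    fall back to a seeded spring layout.  Isolated nodes are placed, never
    dropped.  The coordinates are stored on the network and returned.
    """
    nodes = net.nodes
    n = len(nodes)
    if n < 2:
        raise ValueError("need at least 2 nodes to lay out")
    D = 1.0 - np.abs(net.rho.loc[nodes, nodes].to_numpy())
    D = np.where(np.isnan(D), 1.0, D)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0

    if n >= 8:
        from sklearn.manifold import TSNE

        perplexity = min(30.0, (n - 1) / 3.0)
        emb = TSNE(
            n_components=2, metric="precomputed", init="random",
            random_state=seed, perplexity=perplexity,
        ).fit_transform(D)
    else:
        g = nx.complete_graph(n)
        pos = nx.spring_layout(g, seed=seed, weight=None)
        emb = np.array([pos[i] for i in range(n)])

    layout = pd.DataFrame(emb, index=pd.Index(nodes, name="feature"),
                          columns=["x", "y"])
    net.layout = layout
    return layout


def detect_communities(net: CorrelationNetwork) -> pd.Series:
    """Partition nodes into communities over the significant edges.

    Greedy modularity maximization (|rho| edge weights); an edgeless network
    puts every node in its own community.  Community ids are assigned by
    decreasing size with ties broken by smallest member name; each community
    is annotated by its modal population, marker and feature class.
    Results are stored on the network and the id series returned.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        comms = [frozenset([n]) for n in sorted(g.nodes)]
    else:
        weighted = g.copy()
        for u, v, d in weighted.edges(data=True):
            d["weight"] = abs(d["rho"])
        comms = list(nx.community.greedy_modularity_communities(weighted, weight="weight"))
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))

    assign = {}
    labels = {}
    for cid, members in enumerate(comms):
        for m in members:
            assign[m] = cid
        sub = [g.nodes[m] for m in members]
        counts = {
            "population": pd.Series([s["population"] for s in sub]).value_counts(),
            "marker": pd.Series([s["marker"] for s in sub]).value_counts(),
            "feature_class": pd.Series([s["feature_class"] for s in sub]).value_counts(),
        }
        # annotate by the attribute whose modal value is most dominant
        best_attr = max(counts, key=lambda k: (counts[k].iloc[0] / len(sub),
                                               k == "population"))
        labels[cid] = f"{best_attr}:{counts[best_attr].index[0]}"

    series = pd.Series({n: assign[n] for n in net.nodes}, name="community")
    net.communities = series
    net.community_labels = labels
    return series


def plot_network(net: CorrelationNetwork, path) -> None:
    """Static scatter plot of the layout with significant edges."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if net.layout is None:
        raise ValueError("layout the network before plotting")
    fig, ax = plt.subplots(figsize=(8, 8))
    coords = net.layout
    for u, v in net.graph.edges:
        ax.plot([coords.loc[u, "x"], coords.loc[v, "x"]],
                [coords.loc[u, "y"], coords.loc[v, "y"]],
                color="0.8", lw=0.4, zorder=1)
    colors = (net.communities.loc[coords.index]
              if net.communities is not None else None)
    ax.scatter(coords["x"], coords["y"], c=colors, cmap="tab20", s=14, zorder=2)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(f"feature correlation network (scope={net.scope}, "
                 f"alpha={net.alpha}, {net.graph.number_of_edges()} edges)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
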
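"""Gene co-expression modules from a correlation graph.

Gene pairs whose Spearman correlation across seeds exceeds a one-sided
threshold become edges; modules are the highly connected subgraphs of
that graph (Hartuv & Shamir's scheme): a component is emitted as a module
when its global minimum edge cut exceeds half its node count, otherwise
it is split along the cut and both sides are processed recursively.
Modules below the minimum size are discarded and survivors are relabeled
Group 1, Group 2, ... by descending size.
"""

from __future__ import annotations

import dataclasses

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


@dataclasses.dataclass
class GeneModuleSet:
    """Disjoint gene modules with labels assigned by descending size."""

    modules: dict[str, list[str]]
    min_size: int | None = None
    mean_intra_correlation: dict[str, float] | None = None

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.modules.items()}

    def labels(self) -> pd.Series:
        lab = {}
        for name, genes in self.modules.items():
            for g in genes:
                lab[g] = name
        return pd.Series(lab, name="module")


def pairwise_correlations(
    r: ad.AnnData,
    genes: list[str] | None = None,
    threshold: float = 0.5,
    method: str = "spearman",
) -> pd.DataFrame:
    """Edges (gene_a, gene_b, correlation) with correlation > threshold.

    Spearman by default (Pearson by flag); constant genes get correlation
    0 against everything and therefore never form edges. The threshold is
    one-sided: strong negative correlations do not create edges.
    """
    if r.n_obs < 3:
        raise ValueError("need at least 3 seeds")
    sub = r[:, genes].copy() if genes is not None else r
    if sub.n_vars < 2:
        raise ValueError("need at least 2 genes")
    X = np.asarray(sub.X, dtype=float)
    if method == "spearman":
        X = stats.rankdata(X, axis=0)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    sd = X.std(axis=0)
    ok = sd > 0
    C = np.zeros((sub.n_vars, sub.n_vars))
    if ok.sum() >= 2:
        C_ok = np.corrcoef(X[:, ok], rowvar=False)
        C[np.ix_(ok, ok)] = C_ok
    iu = np.triu_indices(sub.n_vars, k=1)
    vals = C[iu]
    mask = vals > threshold
    names = np.asarray(sub.var_names)
    return pd.DataFrame(
        {
            "gene_a": names[iu[0][mask]],
            "gene_b": names[iu[1][mask]],
            "correlation": vals[mask],
        }
    )


def build_graph(edges: pd.DataFrame, threshold: float = 0.5) -> nx.Graph:
    g = nx.Graph(threshold=threshold)
    for a, b, w in edges[["gene_a", "gene_b", "correlation"]].itertuples(index=False):
        if a != b:
            g.add_edge(a, b, weight=float(w))
    return g


def _min_cut(g: nx.Graph) -> tuple[int, tuple[list, list]]:
    """Global minimum edge cut (unweighted) via Stoer-Wagner.

    Nodes are visited in sorted order so ties break deterministically.
    """
    h = nx.Graph()
    h.add_nodes_from(sorted(g.nodes()))
    h.add_edges_from((u, v, {"weight": 1}) for u, v in g.edges())
    cut_value, (side_a, side_b) = nx.stoer_wagner(h)
    return int(cut_value), (sorted(side_a), sorted(side_b))


def hcs_cluster(
    g: nx.Graph,
    adopt: bool = True,
    adoption_rounds: int = 20,
    adoption_fraction: float = 0.25,
) -> GeneModuleSet:
    """Recursive highly-connected-subgraph decomposition.

    Components with <= 2 nodes are emitted as-is; larger ones are emitted
    whole when min-cut > n/2, else split along the cut and recursed.
    With ``adopt`` (the scheme's singleton-adoption step), nodes left in
    fragments of <= 2 are then attached to the emitted cluster holding
    the plurality of their neighbors, provided that covers more than
    ``adoption_fraction`` of the cluster (and at least 3 edges); the pass
    iterates until stable so cascades of shed nodes can rejoin.
    """
    modules: list[list[str]] = []

    def recurse(nodes: list) -> None:
        sub = g.subgraph(nodes)
        for comp in nx.connected_components(sub):
            comp = sorted(comp)
            if len(comp) <= 2:
                modules.append(comp)
                continue
            cg = g.subgraph(comp)
            cut, (a, b) = _min_cut(cg)
            if cut > len(comp) / 2:
                modules.append(comp)
            else:
                recurse(a)
                recurse(b)

    recurse(sorted(g.nodes()))

    if adopt:
        clusters = [set(m) for m in modules if len(m) > 2]
        fragments = [list(m) for m in modules if len(m) <= 2]
        adopted: set = set()
        for _ in range(adoption_rounds):
            changed = False
            for frag in fragments:
                for x in frag:
                    if x in adopted:
                        continue
                    nbrs = set(g.neighbors(x))
                    best, best_d = None, 0
                    for cl in clusters:
                        d = len(nbrs & cl)
                        if d > best_d:
                            best, best_d = cl, d
                    if best is not None and best_d >= 3 and best_d > len(best) * adoption_fraction:
                        best.add(x)
                        adopted.add(x)
                        changed = True
            if not changed:
                break
        leftovers = [
            [x for x in frag if x not in adopted] for frag in fragments
        ]
        modules = [sorted(cl) for cl in clusters] + [f for f in leftovers if f]

    modules.sort(key=lambda m: (-len(m), m))
    return GeneModuleSet(
        modules={f"module_{i}": m for i, m in enumerate(modules)}
    )


def connected_components_cluster(g: nx.Graph) -> GeneModuleSet:
    """Plain connected components, for comparison with HCS."""
    comps = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda m: (-len(m), m))
    return GeneModuleSet(modules={f"module_{i}": m for i, m in enumerate(comps)})


def filter_modules(
    mods: GeneModuleSet, min_size: int = 10, edges: pd.DataFrame | None = None
) -> GeneModuleSet:
    """Keep modules with >= min_size genes; relabel Group 1.. by size."""
    kept = sorted(
        (m for m in mods.modules.values() if len(m) >= min_size),
        key=lambda m: (-len(m), m),
    )
    modules = {f"Group {i + 1}": m for i, m in enumerate(kept)}
    intra = None
    if edges is not None and len(edges):
        intra = {}
        for name, genes in modules.items():
            gs = set(genes)
            sel = edges["gene_a"].isin(gs) & edges["gene_b"].isin(gs)
            intra[name] = float(edges.loc[sel, "correlation"].mean()) if sel.any() else float("nan")
    return GeneModuleSet(modules=modules, min_size=min_size, mean_intra_correlation=intra)


def find_modules(
    r: ad.AnnData,
    genes: list[str] | None = None,
    threshold: float = 0.5,
    min_size: int = 10,
    method: str = "hcs",
    correlation: str = "spearman",
) -> tuple[GeneModuleSet, pd.DataFrame]:
    """Correlation graph -> highly connected modules, size-filtered."""
    edges = pairwise_correlations(r, genes=genes, threshold=threshold, method=correlation)
    g = build_graph(edges, threshold=threshold)
    raw = hcs_cluster(g) if method == "hcs" else connected_components_cluster(g)
    return filter_modules(raw, min_size=min_size, edges=edges), edges
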
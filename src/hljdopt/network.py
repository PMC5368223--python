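"""Differential metabolite correlation networks.

Nodes are the metabolites significant in one contrast (direction up/down vs
the model group); solid edges are Pearson correlations passing both screens
(|r| > 0.3 and raw p < 0.05 by default) computed on the pooled samples of
the two compared groups; dotted edges link structurally similar metabolites
(curated pair list or numeric similarity map).  Edge sign records positive
(red) vs negative (blue) correlation.

Graphs are ``networkx.MultiGraph`` objects keyed by edge kind
(``correlation`` / ``similarity``) so a metabolite pair may carry both; they
round-trip through GraphML and a plain TSV edge list.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


def pearson_matrix(values: pd.DataFrame):
    """All-pairs Pearson r with two-sided p from the t transform.

    p = 2 * P(T_{n-2} > |r| sqrt(n-2)/sqrt(1-r^2)); diagonal r = 1, p = 0.
    Zero-variance metabolites are excluded and reported.
    Returns ``(r DataFrame, p DataFrame, excluded list)``.
    """
    n = len(values)
    if n < 4:
        raise ValueError("correlation needs at least 4 samples")
    sd = values.std(ddof=1)
    excluded = list(values.columns[sd == 0])
    vals = values.drop(columns=excluded)
    arr = vals.to_numpy(dtype=float)
    r = np.corrcoef(arr, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r ** 2)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(p)] = 0.0  # |r| = 1 -> infinite t -> p = 0
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    cols = vals.columns
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
        excluded,
    )


def load_similarity_pairs(path=None) -> dict:
    """Curated structure-similarity pairs as {frozenset(pair): similarity}.

    Defaults to the packaged amino-acid family list (editable CSV with
    columns metabolite_a, metabolite_b, similarity).
    """
    if path is None:
        src = resources.files("hljdopt") / "data" / "aa_similarity_pairs.csv"
        text = src.read_text()
    else:
        text = Path(path).read_text()
    out = {}
    for row in csv.DictReader(text.splitlines()):
        pair = frozenset((row["metabolite_a"], row["metabolite_b"]))
        out[pair] = float(row["similarity"])
    return out


def build_differential_network(
    differential: pd.DataFrame,
    values: pd.DataFrame,
    r_threshold: float = 0.3,
    p_threshold: float = 0.05,
    similarity=None,
    similarity_threshold: float = 0.6,
    contrast: str = "",
) -> nx.MultiGraph:
    """Build one contrast's differential correlation network.

    Parameters
    ----------
    differential : output of :func:`hljdopt.univariate.differential_analysis`
        (index metabolite, column ``direction``); only up/down rows become
        nodes.
    values : pooled samples x metabolites of the two compared groups.
    similarity : optional {frozenset(pair): similarity} map (see
        :func:`load_similarity_pairs`); node pairs at/above
        ``similarity_threshold`` gain a dotted similarity edge.
    """
    for name, v in (("r_threshold", r_threshold), ("p_threshold", p_threshold)):
        if not 0 < v < 1:
            raise ValueError(f"{name} must lie in (0, 1)")
    nodes = differential.index[differential["direction"].isin(["up", "down"])]
    if len(nodes) < 2:
        raise ValueError("need at least 2 differential metabolites")
    nodes = [m for m in values.columns if m in set(nodes)]  # stable order

    r, p, _ = pearson_matrix(values[nodes])
    g = nx.MultiGraph(
        r_threshold=r_threshold, p_threshold=p_threshold, contrast=contrast,
        n_samples=len(values),
    )
    for m in nodes:
        g.add_node(m, direction=differential.loc[m, "direction"], contrast=contrast)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            rv, pv = float(r.loc[a, b]), float(p.loc[a, b])
            if abs(rv) > r_threshold and pv < p_threshold:
                g.add_edge(
                    a, b, key="correlation", kind="correlation", r=rv, p=pv,
                    sign="positive" if rv > 0 else "negative",
                )
            if similarity is not None:
                sim = similarity.get(frozenset((a, b)))
                if sim is not None and sim >= similarity_threshold:
                    g.add_edge(
                        a, b, key="similarity", kind="similarity",
                        similarity=float(sim),
                    )
    return g


def hub_ranking(graph: nx.MultiGraph) -> pd.DataFrame:
    """Metabolites by correlation-edge degree (ties: summed |r|, then name)."""
    rows = []
    for node in graph.nodes:
        deg, rsum = 0, 0.0
        for _, _, k, d in graph.edges(node, keys=True, data=True):
            if d.get("kind") == "correlation":
                deg += 1
                rsum += abs(d["r"])
        rows.append({"metabolite": node, "degree": deg, "abs_r_sum": rsum})
    df = pd.DataFrame(rows, columns=["metabolite", "degree", "abs_r_sum"])
    if df.empty:
        return df
    return (
        df.sort_values(
            ["degree", "abs_r_sum", "metabolite"], ascending=[False, False, True]
        ).reset_index(drop=True)
    )


def _edge_set(graph: nx.MultiGraph) -> set:
    return {(frozenset((a, b)), d.get("kind")) for a, b, d in graph.edges(data=True)}


def compare_networks(a: nx.MultiGraph, b: nx.MultiGraph, k: int = 5) -> dict:
    """Edge overlap (by unordered pair + kind) and top-k hub overlap."""
    ea, eb = _edge_set(a), _edge_set(b)
    union = ea | eb
    shared = ea & eb
    hubs_a = list(hub_ranking(a)["metabolite"].head(k)) if a.number_of_nodes() else []
    hubs_b = list(hub_ranking(b)["metabolite"].head(k)) if b.number_of_nodes() else []
    return {
        "shared_edges": sorted((tuple(sorted(pr)), kind) for pr, kind in shared),
        "a_only": sorted((tuple(sorted(pr)), kind) for pr, kind in ea - eb),
        "b_only": sorted((tuple(sorted(pr)), kind) for pr, kind in eb - ea),
        "edge_jaccard": (len(shared) / len(union)) if union else 1.0,
        "hub_overlap_top_k": sorted(set(hubs_a) & set(hubs_b)),
        "k": k,
    }


def export_graph(graph: nx.MultiGraph, path, format: str = "graphml") -> None:
    """Write a network as GraphML or a TSV edge list (plus node list)."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("a\tb\tkind\tr\tp\tsign\tsimilarity\n")
            for a, b, k, d in sorted(graph.edges(keys=True, data=True)):
                fh.write(
                    f"{a}\t{b}\t{d.get('kind')}\t{d.get('r', '')}\t"
                    f"{d.get('p', '')}\t{d.get('sign', '')}\t{d.get('similarity', '')}\n"
                )
        nodes = Path(str(path) + ".nodes")
        with open(nodes, "w") as fh:
            fh.write("metabolite\tdirection\tcontrast\n")
            for n, d in sorted(graph.nodes(data=True)):
                fh.write(f"{n}\t{d.get('direction', '')}\t{d.get('contrast', '')}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_graph(path, format: str = "graphml") -> nx.MultiGraph:
    """Read a network written by :func:`export_graph`."""
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path, force_multigraph=True)
        out = nx.MultiGraph(**{k: v for k, v in g.graph.items()})
        for n, d in g.nodes(data=True):
            out.add_node(n, **d)
        for a, b, k, d in g.edges(keys=True, data=True):
            key = d.get("kind", k)
            out.add_edge(a, b, key=key, **d)
        return out
    if format == "tsv":
        g = nx.MultiGraph()
        nodes = Path(str(path) + ".nodes")
        if nodes.exists():
            df = pd.read_csv(nodes, sep="\t")
            for _, row in df.iterrows():
                g.add_node(
                    row["metabolite"],
                    direction=row["direction"] if pd.notna(row["direction"]) else "",
                    contrast=row["contrast"] if pd.notna(row["contrast"]) else "",
                )
        df = pd.read_csv(path, sep="\t")
        for _, row in df.iterrows():
            attrs = {"kind": row["kind"]}
            if row["kind"] == "correlation":
                attrs.update(r=float(row["r"]), p=float(row["p"]), sign=row["sign"])
            else:
                attrs.update(similarity=float(row["similarity"]))
            g.add_edge(row["a"], row["b"], key=row["kind"], **attrs)
        return g
    raise ValueError(f"unknown format {format!r}")
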
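"""Spearman co-occurrence network construction and keystone detection.

The pipeline: keep ASVs detected in more than half the samples, compute
all-pairs Spearman correlations on their relative abundances, draw a signed
edge for every pair with |rho| > 0.6 and p < 0.05 (strict), partition the
resulting graph into modules by Louvain modularity maximization, compute
each node's within-module connectivity Zi and among-module connectivity
(participation coefficient) Pi, and classify topological roles:

* network hub — Zi > 2.5 and Pi > 0.62
* module hub  — Zi > 2.5 and Pi <= 0.62
* connector   — Zi <= 2.5 and Pi > 0.62
* peripheral  — otherwise

Non-peripheral nodes are the keystone taxa. Edge sign is metadata: module
detection treats the graph as undirected and unsigned.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._stats import spearman_matrix

__all__ = [
    "CorrelationMatrix",
    "prevalence_filter",
    "spearman_all_pairs",
    "build_network",
    "detect_modules",
    "zi_pi",
    "classify_roles",
    "keystone_set",
    "network_summary",
    "export_edge_list",
    "export_node_table",
]

ROLES = ("peripheral", "module hub", "connector", "network hub")


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman rho and p matrices over a fixed taxon order."""

    rho: pd.DataFrame
    p: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.rho.index.equals(self.rho.columns):
            raise ValueError("rho must be square with matching labels")
        if not self.rho.index.equals(self.p.index):
            raise ValueError("rho and p must share labels")


def prevalence_filter(table, min_fraction: float = 0.5):
    """Keep ASVs detected (count > 0) in strictly more than ``min_fraction``
    of samples.

    With the default 0.5, an ASV present in exactly half the samples is
    removed — "more than 50%" is a strict inequality.
    """
    if not (0 <= min_fraction < 1):
        raise ValueError("min_fraction must be in [0, 1)")
    present = (table.counts > 0).sum(axis=1)
    keep = present.index[present > min_fraction * table.n_samples]
    return table.select(list(keep))


def spearman_all_pairs(props: pd.DataFrame) -> CorrelationMatrix:
    """All-pairs Spearman rho/p between the rows of a proportion matrix.

    Constant rows (zero rank variance) get NaN against every partner and are
    never joined by an edge downstream.
    """
    rho, p = spearman_matrix(props.to_numpy(dtype=float))
    idx = props.index
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
    )


def build_network(
    corr: CorrelationMatrix,
    r_thresh: float = 0.6,
    p_thresh: float = 0.05,
) -> nx.Graph:
    """Threshold the correlation matrix into a signed co-occurrence graph.

    An edge joins i != j iff |rho| > r_thresh and p < p_thresh, both strict;
    rho exactly at the threshold draws no edge. Nodes without any edge are
    dropped. Edge attributes: ``rho``, ``p``, ``sign``.
    """
    if not (0 < r_thresh < 1) or not (0 < p_thresh < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    rho = corr.rho.to_numpy()
    p = corr.p.to_numpy()
    labels = list(corr.rho.index)
    n = len(labels)
    g = nx.Graph()
    iu, ju = np.triu_indices(n, k=1)
    with np.errstate(invalid="ignore"):
        mask = (np.abs(rho[iu, ju]) > r_thresh) & (p[iu, ju] < p_thresh)
    mask &= ~np.isnan(rho[iu, ju])
    for i, j in zip(iu[mask], ju[mask]):
        r = float(rho[i, j])
        g.add_edge(
            labels[i], labels[j], rho=r, p=float(p[i, j]),
            sign="positive" if r > 0 else "negative",
        )
    return g


def detect_modules(net: nx.Graph, seed: int, resolution: float = 1.0) -> dict:
    """Louvain modularity maximization on the unsigned, unweighted graph.

    Deterministic for a given seed. Module ids are integers starting at 1,
    ordered by descending module size (ties broken by smallest member label)
    so labels are stable across runs.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot detect modules in an empty network")
    communities = nx.algorithms.community.louvain_communities(
        net, weight=None, resolution=resolution, seed=seed
    )
    ordered = sorted(communities, key=lambda c: (-len(c), min(map(str, c))))
    modules = {}
    for label, members in enumerate(ordered, start=1):
        for node in members:
            modules[node] = label
    return modules


def zi_pi(net: nx.Graph, modules: dict) -> pd.DataFrame:
    """Within-module connectivity Zi and participation coefficient Pi.

    For node i in module s with degree k_i and within-module degree k_is:
    Zi is the z-score of k_is among the within-module degrees of module s's
    members (population standard deviation; Zi = 0 when the module is a
    singleton or its spread is zero), and Pi = 1 - sum_s (k_is / k_i)^2 over
    all modules s.
    """
    missing = [v for v in net.nodes if v not in modules]
    if missing:
        raise ValueError(f"nodes without a module: {missing[:5]}")
    nodes = list(net.nodes)
    # per-node degree into each module
    k_into: dict = {v: {} for v in nodes}
    for u, v in net.edges:
        k_into[u][modules[v]] = k_into[u].get(modules[v], 0) + 1
        k_into[v][modules[u]] = k_into[v].get(modules[u], 0) + 1

    own_degree = {v: k_into[v].get(modules[v], 0) for v in nodes}
    members: dict = {}
    for v in nodes:
        members.setdefault(modules[v], []).append(v)

    records = {}
    for v in nodes:
        k = net.degree(v)
        s = modules[v]
        within = np.array([own_degree[u] for u in members[s]], dtype=float)
        sd = within.std()  # population sd
        zi = 0.0 if sd == 0 else (own_degree[v] - within.mean()) / sd
        pi = 1.0 - sum((kis / k) ** 2 for kis in k_into[v].values())
        records[v] = {
            "degree": int(k), "module": int(s),
            "Zi": float(zi), "Pi": float(pi),
        }
    return pd.DataFrame.from_dict(records, orient="index").loc[nodes]


def classify_roles(
    zipi: pd.DataFrame,
    zi_thresh: float = 2.5,
    pi_thresh: float = 0.62,
) -> pd.Series:
    """Assign the four topological roles from the Zi-Pi plane.

    Thresholds are strict for the non-peripheral classes, so a node exactly
    at Zi = 2.5 or Pi = 0.62 falls on the peripheral side of that axis.
    """
    hi_z = zipi["Zi"] > zi_thresh
    hi_p = zipi["Pi"] > pi_thresh
    role = pd.Series("peripheral", index=zipi.index, dtype=object, name="role")
    role[hi_z & hi_p] = "network hub"
    role[hi_z & ~hi_p] = "module hub"
    role[~hi_z & hi_p] = "connector"
    return role


def keystone_set(roles: pd.Series) -> set:
    """Keystone taxa: every non-peripheral node."""
    return set(roles.index[roles != "peripheral"])


def network_summary(net: nx.Graph, modules: dict, roles: pd.Series, tax=None) -> dict:
    """Headline network statistics.

    Node/edge counts, positive/negative edge percentages, module count and
    size fractions, keystone count, and (when a taxonomy is supplied) the
    per-phylum node composition as percentages.
    """
    n_edges = net.number_of_edges()
    n_pos = sum(1 for _, _, d in net.edges(data=True) if d.get("sign") == "positive")
    sizes = pd.Series(modules).value_counts().sort_index()
    summary = {
        "n_nodes": net.number_of_nodes(),
        "n_edges": n_edges,
        "pct_positive_edges": 100.0 * n_pos / n_edges if n_edges else float("nan"),
        "pct_negative_edges": 100.0 * (n_edges - n_pos) / n_edges if n_edges else float("nan"),
        "n_modules": int(sizes.size),
        "module_size_fractions": {
            int(m): 100.0 * s / net.number_of_nodes() for m, s in sizes.items()
        },
        "n_keystones": int((roles != "peripheral").sum()),
    }
    if tax is not None:
        phyla = pd.Series(
            [tax.label(v, "phylum") for v in net.nodes], index=list(net.nodes), dtype=object
        ).fillna("unassigned")
        comp = phyla.value_counts() / net.number_of_nodes() * 100.0
        summary["phylum_composition_pct"] = {str(k): float(v) for k, v in comp.items()}
    return summary


def export_edge_list(net: nx.Graph, path) -> None:
    """Edge list TSV: source, target, rho, p, sign."""
    rows = [
        {"source": u, "target": v, "rho": d["rho"], "p": d["p"], "sign": d["sign"]}
        for u, v, d in sorted(net.edges(data=True), key=lambda e: (str(e[0]), str(e[1])))
    ]
    pd.DataFrame(rows, columns=["source", "target", "rho", "p", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def export_node_table(
    zipi: pd.DataFrame, roles: pd.Series, path, tax=None, assignment=None
) -> None:
    """Node table TSV: asv_id, taxonomy, degree, module, Zi, Pi, role, group."""
    frame = zipi.copy()
    frame["role"] = roles
    if tax is not None:
        frame.insert(0, "taxonomy", [
            tax.lineage_string(v) if v in tax else "" for v in frame.index
        ])
    if assignment is not None:
        frame["category_group"] = [
            assignment.group.get(v, "") for v in frame.index
        ]
    frame.index.name = "asv_id"
    frame.to_csv(path, sep="\t")
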
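"""Synthetic ASV tables, taxonomy and metadata with planted ground truth.

The generator emulates the structure a sediment 16S survey presents to the
downstream pipeline:

* a heavy-tailed lognormal species abundance distribution (many rare taxa,
  few abundant ones), sampled into integer counts multinomially at a fixed
  per-sample depth;
* correlation modules planted through shared latent sample factors — taxa in
  the same module load on a common factor and therefore co-occur;
* taxa whose generating margins force a known abundance category (always
  abundant, always rare, conditionally rare/abundant, ...), used for
  classification-recovery tests;
* environmental variables generated as monotone transforms of module
  factors, planting known taxon-environment associations;
* graph-level generators planting block-modular networks with hub and
  connector nodes for module- and keystone-recovery tests.

Everything is deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as _sps

from .table import RANKS, AsvTable, SampleMetadata, TaxonomyMap

__all__ = [
    "SimulationConfig",
    "SimTruth",
    "simulate_community",
    "simulate_metadata",
    "planted_network",
    "planted_partition_graph",
    "planted_role_graph",
]

# mock lineage pool (domain, phylum, class, order, family, genus) drawn from
# lineages dominant in freshwater sediment communities
_MOCK_LINEAGES = [
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Betaproteobacteriales", "Rhodocyclaceae", "Dechloromonas"),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Competibacterales", "Competibacteraceae", "Candidatus Competibacter"),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Methylococcales", "Methylococcaceae", "Methylobacter"),
    ("Bacteria", "Proteobacteria", "Deltaproteobacteria", "Desulfuromonadales", "Geobacteraceae", "Geobacter"),
    ("Bacteria", "Proteobacteria", "Deltaproteobacteria", "Syntrophobacterales", "Syntrophobacteraceae", "Syntrophobacter"),
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Chitinophagales", "Chitinophagaceae", None),
    ("Bacteria", "Chloroflexi", "Anaerolineae", "Anaerolineales", "Anaerolineaceae", None),
    ("Bacteria", "Chloroflexi", "Dehalococcoidia", None, None, None),
    ("Bacteria", "Acidobacteria", "Subgroup_6", None, None, None),
    ("Bacteria", "Nitrospirae", "Thermodesulfovibrionia", None, None, None),
    ("Bacteria", "Verrucomicrobia", "Verrucomicrobiae", "Pedosphaerales", None, None),
    ("Bacteria", "Planctomycetes", "Planctomycetacia", "Pirellulales", "Pirellulaceae", None),
    ("Archaea", "Euryarchaeota", "Methanomicrobia", "Methanosarcinales", "Methanosaetaceae", "Methanosaeta"),
    ("Archaea", "Euryarchaeota", "Methanomicrobia", "Methanosarcinales", "Methanosarcinaceae", "Methanosarcina"),
    ("Archaea", "Euryarchaeota", "Methanobacteria", "Methanobacteriales", "Methanobacteriaceae", "Methanobacterium"),
    ("Archaea", "Euryarchaeota", "Methanocellia", "Methanocellales", "Methanocellaceae", "Methanocella"),
    ("Archaea", "Nanoarchaeaeota", "Woesearchaeia", None, None, None),
    ("Archaea", "Asgardaeota", "Lokiarchaeia", None, None, None),
]

_ORGANELLE_LINEAGES = [
    ("Bacteria", "Cyanobacteria", "Oxyphotobacteria", "Chloroplast", None, None),
    ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rickettsiales", "Mitochondria", None),
]

# realistic variable ranges used to scale generated metadata
_ENV_RANGES = {
    "WT": (14.0, 25.0), "pH": (7.5, 9.0), "DO": (5.0, 10.0), "SD": (0.5, 3.0),
    "COD": (10.0, 30.0), "PI": (2.0, 6.0), "Chl-a": (2.0, 20.0),
    "TN": (0.5, 0.7), "TP": (0.02, 0.04), "TDN": (0.4, 0.6),
    "NH4-N": (0.02, 0.3), "PO4-P": (0.005, 0.02),
    "phyto_density": (1e6, 1e7), "water_depth": (0.5, 2.0),
}

_ENV_UNITS = {
    "WT": "degC", "pH": "", "DO": "mg/L", "SD": "m", "COD": "mg/L",
    "PI": "mg/L", "Chl-a": "ug/L", "TN": "mg/L", "TP": "mg/L", "TDN": "mg/L",
    "NH4-N": "mg/L", "PO4-P": "mg/L", "N/P": "", "phyto_density": "cells/L",
    "water_depth": "m",
}


@dataclass
class SimulationConfig:
    """Study-condition parameters of the generator.

    Defaults mirror the surveyed system: 34 samples, a 5,000-taxon community
    with lognormal log-abundance spread sigma = 2 (a long rare tail), 50,000
    reads per sample, four correlation modules of 30 taxa, and TN/TP planted
    as monotone readouts of the first two module factors within mesotrophic
    ranges (TN 0.5-0.7 mg/L, TP 0.02-0.04 mg/L).
    """

    seed: int
    n_samples: int = 34
    n_taxa: int = 5000
    depth: int = 50_000
    log_mean: float = 0.0
    log_sd: float = 2.0
    n_modules: int = 4
    taxa_per_module: int = 30
    module_baseline: float = 2.0
    loading: float = 1.0
    noise_sd: float = 0.3
    factor_corr: float = 0.3
    n_connector_taxa: int = 2
    forced_categories: dict = field(default_factory=lambda: {
        "AAT": 2, "ART": 20, "MT": 3, "CRAT": 3, "CAT": 3, "CRT": 5,
    })
    env_links: dict = field(default_factory=lambda: {"TN": (0, 1), "TP": (1, 1)})
    env_noise_sd: float = 0.2
    n_organelle: int = 0

    def validate(self) -> None:
        planted = self.n_modules * self.taxa_per_module + self.n_connector_taxa
        forced = sum(self.forced_categories.values())
        if planted + forced + self.n_organelle > self.n_taxa:
            raise ValueError(
                f"infeasible config: {planted} module + {forced} forced + "
                f"{self.n_organelle} organelle taxa exceed n_taxa={self.n_taxa}"
            )
        if self.n_samples < 4 or self.depth <= 0:
            raise ValueError("need n_samples >= 4 and positive depth")
        for var, (mod, sign) in self.env_links.items():
            if var not in _ENV_RANGES:
                raise ValueError(f"unknown env link target {var!r}")
            if not (0 <= mod < self.n_modules) or sign not in (-1, 1):
                raise ValueError(f"invalid env link for {var!r}: {(mod, sign)}")


@dataclass
class SimTruth:
    """Planted labels: only assigned where construction forces them."""

    category: pd.Series  # forced taxa only
    module: pd.Series  # module members only; taxon -> module index (0-based)
    connectors: list
    env_links: dict  # variable -> (module index, sign)
    factors: pd.DataFrame  # sample x module latent factors


def _draw_factors(rng, n_samples: int, n_modules: int, corr: float) -> np.ndarray:
    cov = np.full((n_modules, n_modules), corr)
    np.fill_diagonal(cov, 1.0)
    return rng.multivariate_normal(np.zeros(n_modules), cov, size=n_samples)


# target per-sample proportions forcing each category well away from the
# 1e-4 / 1e-2 thresholds (low targets keep expected counts far below the
# 1e-4 count threshold at any realistic depth)
_TINY, _MID, _HIGH = 1e-6, 1e-3, 2.5e-2


def _forced_share_targets(code: str, n_samples: int) -> np.ndarray:
    t = np.full(n_samples, _MID)
    if code == "AAT":
        t[:] = _HIGH
    elif code == "ART":
        t[:] = _TINY
    elif code == "MT":
        t[:] = _MID
    elif code == "CRAT":
        t[:] = _TINY
        t[0] = _HIGH
    elif code == "CAT":
        t[0] = _HIGH
    elif code == "CRT":
        t[0] = _TINY
    else:
        raise ValueError(f"unknown forced category {code!r}")
    return t


def simulate_community(config: SimulationConfig) -> tuple[AsvTable, TaxonomyMap, SimTruth]:
    """Generate a count table, mock taxonomy and planted-truth labels."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, s = config.n_taxa, config.n_samples
    sample_ids = [f"S{i + 1:02d}" for i in range(s)]

    n_module_taxa = config.n_modules * config.taxa_per_module
    forced_list = [(code, k) for code in ("AAT", "ART", "MT", "CRAT", "CAT", "CRT")
                   for k in range(config.forced_categories.get(code, 0))]
    n_forced = len(forced_list)
    n_conn = config.n_connector_taxa
    n_background = n - n_module_taxa - n_forced - n_conn - config.n_organelle

    asv_ids = [f"ASV_{i + 1}" for i in range(n)]
    factors = _draw_factors(rng, s, config.n_modules,
                            config.factor_corr if config.n_modules > 1 else 0.0)

    log_int = np.empty((n, s))
    module_of: dict[str, int] = {}
    pos = 0
    # module members: shared latent factor plus taxon noise
    for m in range(config.n_modules):
        for _ in range(config.taxa_per_module):
            base = rng.normal(config.module_baseline, 0.5)
            log_int[pos] = (base + config.loading * factors[:, m]
                            + config.noise_sd * rng.normal(size=s))
            module_of[asv_ids[pos]] = m
            pos += 1
    connectors = []
    for _ in range(n_conn):
        base = rng.normal(config.module_baseline, 0.5)
        mix = factors.sum(axis=1) / np.sqrt(config.n_modules)
        log_int[pos] = base + config.loading * mix + config.noise_sd * rng.normal(size=s)
        connectors.append(asv_ids[pos])
        pos += 1
    # heavy-tailed background: independent lognormal baselines
    for _ in range(n_background + config.n_organelle):
        base = rng.normal(config.log_mean, config.log_sd)
        log_int[pos] = base + config.noise_sd * rng.normal(size=s)
        pos += 1
    organelle_ids = asv_ids[pos - config.n_organelle: pos] if config.n_organelle else []

    intensity = np.exp(log_int[: pos])
    background_sum = intensity.sum(axis=0)

    # forced-category taxa: intensities chosen so the expected proportion in
    # each sample equals the forcing target exactly
    forced_ids = asv_ids[pos: pos + n_forced]
    targets = np.zeros((n_forced, s))
    for row, (code, _) in enumerate(forced_list):
        targets[row] = _forced_share_targets(code, s)
    total_target = targets.sum(axis=0)
    if (total_target >= 0.5).any():
        raise ValueError("forced-category targets occupy too much of the community")
    forced_intensity = targets * (background_sum / (1.0 - total_target))
    full_intensity = np.vstack([intensity, forced_intensity])

    probs = full_intensity / full_intensity.sum(axis=0)
    counts = np.empty((n, s), dtype=np.int64)
    for j in range(s):
        counts[:, j] = rng.multinomial(config.depth, probs[:, j])
    table = AsvTable(pd.DataFrame(counts, index=asv_ids, columns=sample_ids))

    # mock taxonomy: random draws from the lineage pool; organelle taxa get
    # chloroplast/mitochondria lineages
    frame_rows = {}
    for asv in asv_ids:
        if asv in organelle_ids:
            lineage = _ORGANELLE_LINEAGES[rng.integers(len(_ORGANELLE_LINEAGES))]
        else:
            lineage = _MOCK_LINEAGES[rng.integers(len(_MOCK_LINEAGES))]
        frame_rows[asv] = list(lineage) + [None]  # species unassigned
    tax_frame = pd.DataFrame.from_dict(frame_rows, orient="index", columns=list(RANKS))
    tax = TaxonomyMap(tax_frame)

    truth = SimTruth(
        category=pd.Series({a: code for a, (code, _) in zip(forced_ids, forced_list)},
                           dtype=object),
        module=pd.Series(module_of, dtype="int64"),
        connectors=connectors,
        env_links=dict(config.env_links),
        factors=pd.DataFrame(factors, index=sample_ids,
                             columns=[f"factor_{m}" for m in range(config.n_modules)]),
    )
    return table, tax, truth


def simulate_metadata(config: SimulationConfig, factors: pd.DataFrame) -> SampleMetadata:
    """Environmental variables as monotone transforms of module factors.

    Linked variables follow ``sign * factor`` plus Gaussian noise, mapped
    through the normal CDF into each variable's realistic range; unlinked
    variables are independent noise in range. N/P is computed from TN and TP.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    samples = list(factors.index)
    s = len(samples)
    data = {}
    for var, (lo, hi) in _ENV_RANGES.items():
        if var in config.env_links:
            mod, sign = config.env_links[var]
            raw = sign * factors.iloc[:, mod].to_numpy() + config.env_noise_sd * rng.normal(size=s)
            scale = np.sqrt(1.0 + config.env_noise_sd**2)
        else:
            raw = rng.normal(size=s)
            scale = 1.0
        data[var] = lo + (hi - lo) * _sps.norm.cdf(raw / scale)
    frame = pd.DataFrame(data, index=samples)
    frame["N/P"] = frame["TN"] / frame["TP"]
    return SampleMetadata(frame, units=dict(_ENV_UNITS))


def planted_network(config: SimulationConfig) -> tuple[dict, pd.DataFrame]:
    """Module-structured proportion matrix plus its generative truth.

    Returns ``(truth, props)`` where ``truth`` holds the module membership,
    connector ids and the implied within-module adjacency, and ``props`` is
    the taxon x sample proportion matrix the network pipeline should recover
    the structure from.
    """
    if config.n_modules < 1 or config.taxa_per_module < 2:
        raise ValueError("module spec requires n_modules >= 1 and taxa_per_module >= 2")
    rng = np.random.default_rng(config.seed)
    s = config.n_samples
    factors = _draw_factors(rng, s, config.n_modules,
                            config.factor_corr if config.n_modules > 1 else 0.0)
    ids, rows, module_of = [], [], {}
    for m in range(config.n_modules):
        for t in range(config.taxa_per_module):
            tid = f"M{m}_T{t}"
            ids.append(tid)
            module_of[tid] = m
            rows.append(config.loading * factors[:, m] + config.noise_sd * rng.normal(size=s))
    connectors = []
    for c in range(config.n_connector_taxa):
        tid = f"C{c}"
        ids.append(tid)
        connectors.append(tid)
        mix = factors.sum(axis=1) / np.sqrt(config.n_modules)
        rows.append(config.loading * mix + config.noise_sd * rng.normal(size=s))
    planted = np.exp(np.asarray(rows))
    # unstructured background dominating the community total: without it the
    # per-sample closure couples every planted taxon to the module factors
    # and wipes out the planted correlation structure
    n_background = max(0, config.n_taxa - len(ids))
    if n_background:
        bg = np.exp(rng.normal(config.log_mean, config.log_sd, size=n_background)[:, None]
                    + 0.5 * rng.normal(size=(n_background, s)))
        # scale so the background carries ~95% of the total intensity
        bg *= 19.0 * planted.sum() / bg.sum()
        ids = ids + [f"B{i}" for i in range(n_background)]
        intensity = np.vstack([planted, bg])
    else:
        intensity = planted
    props = pd.DataFrame(intensity / intensity.sum(axis=0), index=ids,
                         columns=[f"S{i + 1:02d}" for i in range(s)])
    within_pairs = {
        (a, b)
        for m in range(config.n_modules)
        for i, a in enumerate(ids)
        if module_of.get(a) == m
        for b in ids[i + 1:]
        if module_of.get(b) == m
    }
    truth = {"module": module_of, "connectors": connectors, "within_pairs": within_pairs}
    return truth, props


def planted_partition_graph(
    n_blocks: int, block_size: int, p_in: float, p_out: float, seed: int
) -> tuple[nx.Graph, dict]:
    """Random block-modular graph plus its true block labels."""
    g = nx.planted_partition_graph(n_blocks, block_size, p_in, p_out, seed=seed)
    truth = {v: g.nodes[v]["block"] for v in g.nodes}
    return nx.Graph(g.edges), truth


def planted_role_graph(
    seed: int,
    n_modules: int = 4,
    module_size: int = 30,
    p_in: float = 0.3,
    p_out: float = 0.02,
    hub_frac: float = 0.8,
    n_connectors: int = 2,
    connector_links: int = 5,
) -> tuple[nx.Graph, dict]:
    """Block-modular graph with one planted hub per module and extra
    connector nodes.

    Each hub is wired to ``hub_frac`` of its module's members; each
    connector is an additional node wired to ``connector_links`` random
    nodes in every module (its participation coefficient target is
    ``1 - n_modules * (1/n_modules)^2``). Returns the graph and a truth dict
    with ``module``, ``hubs`` and ``connectors``.
    """
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    module_of = {}
    members = []
    for m in range(n_modules):
        block = [f"m{m}_n{i}" for i in range(module_size)]
        members.append(block)
        for v in block:
            module_of[v] = m
            g.add_node(v)
    hubs = [block[0] for block in members]
    for m, block in enumerate(members):
        hub = hubs[m]
        # background within-module wiring among non-hub members
        for i in range(1, module_size):
            for j in range(i + 1, module_size):
                if rng.random() < p_in:
                    g.add_edge(block[i], block[j])
        # hub wired to hub_frac of its module
        n_hub_edges = int(round(hub_frac * (module_size - 1)))
        targets = rng.choice(module_size - 1, size=n_hub_edges, replace=False)
        for t in targets:
            g.add_edge(hub, block[t + 1])
    # sparse between-module background
    for ma in range(n_modules):
        for mb in range(ma + 1, n_modules):
            for u in members[ma]:
                for v in members[mb]:
                    if rng.random() < p_out:
                        g.add_edge(u, v)
    connectors = []
    for c in range(n_connectors):
        node = f"conn{c}"
        connectors.append(node)
        g.add_node(node)
        for m, block in enumerate(members):
            targets = rng.choice(module_size, size=connector_links, replace=False)
            for t in targets:
                g.add_edge(node, block[t])
    truth = {"module": module_of, "hubs": hubs, "connectors": connectors}
    return g, truth
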
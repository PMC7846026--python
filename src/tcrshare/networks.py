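"""Edit-distance computations, neighborhood counts, distance networks,
and the NT-origin bipartite convergence graph.

Similarity between CDR3 amino-acid sequences is Levenshtein edit
distance; "similar" means distance at most ``d_max`` (2 for single
chains, 3 summed over the two chains of an alpha-beta pair).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyInputError, PresenceError
from .io import RepertoireSample


def levenshtein(a: str, b: str) -> int:
    """Levenshtein distance: minimal unit-cost inserts, deletes, substitutions."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    if len(a) < len(b):
        a, b = b, a
    # two-row DP; CDR3 junctions are short so this is plenty fast
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def top_n_pool(samples: list[RepertoireSample], n: int = 10_000) -> list[str]:
    """Top ``n`` AA sequences of the pooled samples by summed copy number.

    Ties at the cut are resolved lexicographically; if fewer than ``n``
    sequences exist, all are returned.
    """
    counts: dict[str, int] = {}
    for s in samples:
        for aa, cnt in s.aa_counts().items():
            counts[aa] = counts.get(aa, 0) + cnt
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [aa for aa, _ in ordered[:n]]


def neighborhood_count(focal: str, pool: list[str], d_max: int = 2) -> int:
    """Number of pool sequences (excluding the focal itself) within
    Levenshtein distance ``d_max`` of ``focal``."""
    if not pool:
        raise EmptyInputError("pool is empty")
    count = 0
    for s in set(pool):
        if s == focal:
            continue
        if abs(len(s) - len(focal)) > d_max:
            continue
        if levenshtein(focal, s) <= d_max:
            count += 1
    return count


def neighborhood_vs_random(
    focal_set: list[str],
    pool: list[str],
    n_random: int = 1000,
    d_max: int = 2,
    seed: int = 0,
) -> dict:
    """Focal neighborhood sizes against a random-sequence baseline.

    The baseline draws ``n_random`` sequences uniformly from the pool
    (excluding the focal set) and counts their neighborhoods the same
    way; the empirical p per focal uses the +1 correction.
    """
    candidates = sorted(set(pool) - set(focal_set))
    if not candidates:
        raise ConfigError("pool has no non-focal sequences to draw from")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(candidates), size=n_random)
    baseline = np.array(
        [neighborhood_count(candidates[i], pool, d_max) for i in idx]
    )
    focal_counts = {f: neighborhood_count(f, pool, d_max) for f in focal_set}
    p_values = {
        f: (1 + int((baseline >= c).sum())) / (n_random + 1)
        for f, c in focal_counts.items()
    }
    return {
        "focal_counts": focal_counts,
        "baseline_mean": float(baseline.mean()),
        "baseline_sd": float(baseline.std(ddof=1)) if n_random > 1 else 0.0,
        "baseline": baseline,
        "p_values": p_values,
    }


@dataclass
class DistanceNetwork:
    graph: nx.Graph
    d_max: int
    components: list[set] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"node_u": str(u), "node_v": str(v), "distance": d["distance"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["node_u", "node_v", "distance"])


def _pair_distance(u, v, mode: str) -> int:
    if mode == "single_chain":
        return levenshtein(u, v)
    if mode == "summed_chains":
        return levenshtein(u[0], v[0]) + levenshtein(u[1], v[1])
    raise ConfigError(f"unknown pair_distance mode {mode!r}")


def build_distance_network(
    items: list,
    d_max: int = 2,
    pair_distance: str = "single_chain",
    node_weights: dict | None = None,
) -> DistanceNetwork:
    """Graph with an edge wherever the distance between two items is in
    [1, d_max]; for alpha-beta pairs under ``summed_chains`` the distance
    is the sum of the per-chain Levenshtein distances.

    Copy numbers do not affect topology; pass ``node_weights`` to attach
    them as node attributes.
    """
    if not items:
        raise EmptyInputError("network needs at least one node")
    if pair_distance not in ("single_chain", "summed_chains"):
        raise ConfigError(f"unknown pair_distance mode {pair_distance!r}")
    nodes = list(dict.fromkeys(items))
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            d = _pair_distance(u, v, pair_distance)
            if 1 <= d <= d_max:
                g.add_edge(u, v, distance=d)
    if node_weights:
        nx.set_node_attributes(
            g, {n: node_weights.get(n) for n in nodes}, "copy_number"
        )
    comps = [set(c) for c in nx.connected_components(g)]
    comps.sort(key=len, reverse=True)
    return DistanceNetwork(graph=g, d_max=d_max, components=comps)


@dataclass
class BipartiteOrigin:
    focal_aa: str
    mouse_nt: set[str]
    human_nt: set[str]

    @property
    def overlap(self) -> int:
        return len(self.mouse_nt & self.human_nt)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_node(self.focal_aa, kind="aa")
        for nt in sorted(self.mouse_nt | self.human_nt):
            species = (
                "both"
                if nt in self.mouse_nt and nt in self.human_nt
                else ("mouse" if nt in self.mouse_nt else "human")
            )
            g.add_node(nt, kind="nt")
            g.add_edge(nt, self.focal_aa, species=species)
        return g

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"nt": nt, "aa": self.focal_aa, "species": "mouse"}
            for nt in sorted(self.mouse_nt)
        ] + [
            {"nt": nt, "aa": self.focal_aa, "species": "human"}
            for nt in sorted(self.human_nt)
        ]
        return pd.DataFrame(rows, columns=["nt", "aa", "species"])


def nt_origin_bipartite(
    focal_aa: str,
    mouse_samples: list[RepertoireSample],
    human_samples: list[RepertoireSample],
) -> BipartiteOrigin:
    """Distinct NT encodings of one AA per species and their overlap.

    The focal AA must be present in both species' data.
    """

    def collect(samples: list[RepertoireSample]) -> set[str]:
        return {
            c.junction_nt
            for s in samples
            for c in s.clones.values()
            if c.junction_aa == focal_aa
        }

    mouse_nt = collect(mouse_samples)
    human_nt = collect(human_samples)
    if not mouse_nt or not human_nt:
        missing = "mouse" if not mouse_nt else "human"
        raise PresenceError(f"{focal_aa} absent from the {missing} data")
    return BipartiteOrigin(focal_aa=focal_aa, mouse_nt=mouse_nt, human_nt=human_nt)
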
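"""Seed-extended protein interaction networks and their structural measures.

A disease module is built from a list of curated seed proteins and a
background interaction universe: the module contains every seed, every
direct interaction partner of a seed, and every interaction whose two
endpoints are both retained.  Vertex-level centralities are computed with
conventions that stay well defined on disconnected graphs, so the same code
can score random null networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "InteractionNetwork",
    "CentralityProfile",
    "build_network",
    "compute_centralities",
    "degree_sequence",
    "read_interactions",
    "read_seeds",
    "write_network",
    "write_centralities",
]


def _canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Order endpoints lexicographically so edge identity is deterministic."""
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class InteractionNetwork:
    """Undirected protein–protein interaction graph with seed flags.

    Protein IDs are case-sensitive opaque strings.  Invariants: no
    self-loops, no duplicate edges, every edge endpoint and every seed is a
    member protein.
    """

    proteins: frozenset[str]
    edges: frozenset[tuple[str, str]]
    seeds: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if (u, v) != _canonical_edge(u, v):
                raise ValueError(f"edge {(u, v)!r} not canonically ordered")
            if u not in self.proteins or v not in self.proteins:
                raise ValueError(f"edge {(u, v)!r} has endpoint outside protein set")
        if not self.seeds <= self.proteins:
            raise ValueError("seed set not contained in protein set")

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def is_connected(self) -> bool:
        """Whether the network forms a single connected component."""
        if not self.proteins:
            return False
        return nx.is_connected(self.to_networkx())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.proteins))
        g.add_edges_from(sorted(self.edges))
        for p in g.nodes:
            g.nodes[p]["seed"] = p in self.seeds
        return g

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        seeds: Iterable[str] = (),
        extra_proteins: Iterable[str] = (),
    ) -> "InteractionNetwork":
        canon = {
            _canonical_edge(str(u), str(v)) for u, v in edges if str(u) != str(v)
        }
        proteins = {p for e in canon for p in e}
        proteins.update(map(str, extra_proteins))
        seeds = frozenset(map(str, seeds))
        proteins.update(seeds)
        return cls(frozenset(proteins), frozenset(canon), seeds)


def build_network(
    seeds: Iterable[str], interactions: Iterable[tuple[str, str]]
) -> InteractionNetwork:
    """Extend seed proteins into their interaction module.

    Keeps every seed, every direct partner of a seed, and every interaction
    whose two endpoints were both kept.  A seed with no interaction in the
    universe is retained as an isolated vertex (with a warning).

    Raises
    ------
    ValueError
        If the seed list is empty.
    """
    seed_set = {str(s) for s in seeds}
    if not seed_set:
        raise ValueError("seed list must be non-empty")
    universe = [
        _canonical_edge(str(u), str(v)) for u, v in interactions if str(u) != str(v)
    ]
    partners: set[str] = set()
    touched: set[str] = set()
    for u, v in universe:
        touched.update((u, v))
        if u in seed_set:
            partners.add(v)
        if v in seed_set:
            partners.add(u)
    missing = seed_set - touched
    if missing:
        warnings.warn(
            f"{len(missing)} seed protein(s) absent from the interaction "
            f"universe kept as isolated vertices: {sorted(missing)[:5]}",
            stacklevel=2,
        )
    keep = seed_set | partners
    edges = {e for e in universe if e[0] in keep and e[1] in keep}
    return InteractionNetwork(frozenset(keep), frozenset(edges), frozenset(seed_set))


@dataclass(frozen=True)
class CentralityProfile:
    """Per-vertex structural measures plus their network means.

    Conventions (fixed so disconnected null networks are scorable):
    closeness is normalized per connected component,
    ``n_reachable / sum(dist to reachable)``, 0 for isolated vertices;
    betweenness is the raw unordered-pair count unless ``normalized``;
    eccentricity is the within-component maximum distance, 0 when isolated.
    """

    degree: Mapping[str, int]
    betweenness: Mapping[str, float]
    closeness: Mapping[str, float]
    clustering: Mapping[str, float]
    eccentricity: Mapping[str, int]
    density: float

    def mean(self, measure: str) -> float:
        values = getattr(self, measure)
        return sum(values.values()) / len(values) if values else float("nan")

    @property
    def means(self) -> dict[str, float]:
        return {
            m: self.mean(m)
            for m in ("degree", "betweenness", "closeness", "clustering", "eccentricity")
        }

    def to_frame(self) -> pd.DataFrame:
        proteins = sorted(self.degree)
        return pd.DataFrame(
            {
                "protein": proteins,
                "degree": [self.degree[p] for p in proteins],
                "betweenness": [self.betweenness[p] for p in proteins],
                "closeness": [self.closeness[p] for p in proteins],
                "clustering": [self.clustering[p] for p in proteins],
                "eccentricity": [self.eccentricity[p] for p in proteins],
            }
        )


def compute_centralities(
    net: InteractionNetwork, normalized_betweenness: bool = False
) -> CentralityProfile:
    """Compute degree, betweenness, closeness, clustering and eccentricity."""
    if net.n_proteins == 0:
        raise ValueError("network has no proteins")
    g = net.to_networkx()
    closeness = nx.closeness_centrality(g, wf_improved=False)
    eccentricity: dict[str, int] = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if len(comp) == 1:
            eccentricity[next(iter(comp))] = 0
        else:
            eccentricity.update(nx.eccentricity(sub))
    return CentralityProfile(
        degree=dict(g.degree()),
        betweenness=nx.betweenness_centrality(g, normalized=normalized_betweenness),
        closeness=closeness,
        clustering=nx.clustering(g),
        eccentricity=eccentricity,
        density=nx.density(g),
    )


def degree_sequence(net: InteractionNetwork) -> list[int]:
    """Vertex degrees in sorted protein-ID order; sums to 2|E|."""
    g = net.to_networkx()
    return [g.degree(p) for p in sorted(net.proteins)]


# ---------------------------------------------------------------------------
# readers / writers


def read_interactions(path: str | Path) -> list[tuple[str, str]]:
    """Read a TSV edge list (proteinA, proteinB, [source...]).

    Lines starting with ``#`` are comments; duplicate and reversed pairs are
    deduplicated; self-loops dropped.
    """
    seen: set[tuple[str, str]] = set()
    out: list[tuple[str, str]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"interaction line needs >=2 columns: {line!r}")
        u, v = fields[0].strip(), fields[1].strip()
        if u == v:
            continue
        e = _canonical_edge(u, v)
        if e not in seen:
            seen.add(e)
            out.append(e)
    return out


def read_seeds(path: str | Path) -> list[str]:
    """Read a seed-protein list, one ID per line, ``#`` comments ignored."""
    out = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_network(net: InteractionNetwork, prefix: str | Path) -> dict[str, Path]:
    """Write GraphML plus a flat TSV edge list; returns the paths."""
    prefix = Path(prefix)
    graphml = prefix.with_suffix(".graphml")
    tsv = prefix.with_suffix(".edges.tsv")
    nx.write_graphml(net.to_networkx(), graphml)
    with open(tsv, "w") as fh:
        fh.write("#proteinA\tproteinB\n")
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")
    return {"graphml": graphml, "edges": tsv}


def write_centralities(profile: CentralityProfile, path: str | Path) -> Path:
    path = Path(path)
    profile.to_frame().to_csv(path, sep="\t", index=False)
    return path
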
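"""Synthetic inputs with the statistical structure the pipeline assumes.

Every stage of the analysis is exercisable offline: a scale-free interaction
universe with designated high-degree seed proteins (optionally two planted
communities carrying opposite expression directions), a layered single-root
ontology with is-a/part-of edges and leaf annotations, a corpus of abstracts
with planted protein-mention/change-word sentences, and GMT pathway sets
with planted block structure.  All generators are deterministic in the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np


__all__ = [
    "SyntheticScenario",
    "make_network",
    "make_ontology",
    "make_labels_and_corpus",
    "make_pathways",
    "generate_scenario",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """One coherent synthetic world; same seed means byte-identical outputs."""

    seed: int = 0
    # network
    n_proteins: int = 200
    attachment: int = 4  # preferential-attachment edges per new vertex
    n_seeds: int = 12
    n_clusters: int = 2
    mixing: float = 0.1  # cross-cluster edge fraction (two-cluster mode)
    # ontology
    depth: int = 4
    branching: int = 3
    part_of_fraction: float = 0.2
    terms_per_protein: int = 3
    # labels / corpus
    n_up: int = 8
    n_down: int = 8
    support: int = 2  # distinct PMIDs backing each planted label
    n_filler_abstracts: int = 5
    # pathways
    n_pathways: int = 10
    n_blocks: int = 2
    block_overlap: float = 0.8
    cross_overlap: float = 0.05


def _protein_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(n)]


def make_network(
    scenario: SyntheticScenario, seed: int | None = None
) -> tuple[list[tuple[str, str]], list[str], dict[str, int]]:
    """Scale-free interaction universe with planted seeds.

    Returns (interaction edge list, seed proteins, protein -> cluster map).
    With ``n_clusters == 2`` the universe is two preferential-attachment
    communities joined by a ``mixing`` fraction of random cross edges (0
    disconnects them); otherwise a single preferential-attachment graph.
    Seed proteins are drawn degree-weighted, so they sit above the average
    degree, mimicking well-studied disease proteins.
    """
    if scenario.n_proteins < 10:
        raise ValueError("need at least 10 proteins")
    if scenario.attachment >= scenario.n_proteins // max(scenario.n_clusters, 1):
        raise ValueError("attachment too large for the requested size")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    names = _protein_names(scenario.n_proteins)
    clusters: dict[str, int] = {}
    edges: set[tuple[int, int]] = set()
    if scenario.n_clusters == 2:
        half = scenario.n_proteins // 2
        sizes = [half, scenario.n_proteins - half]
        offset = 0
        for ci, size in enumerate(sizes):
            g = nx.barabasi_albert_graph(
                size, scenario.attachment, seed=int(rng.integers(2**31 - 1))
            )
            for u, v in g.edges():
                edges.add((u + offset, v + offset))
            for u in range(size):
                clusters[names[u + offset]] = ci
            offset += size
        n_cross = int(round(scenario.mixing * len(edges)))
        added = 0
        while added < n_cross:
            u = int(rng.integers(0, sizes[0]))
            v = int(rng.integers(sizes[0], scenario.n_proteins))
            if (u, v) not in edges:
                edges.add((u, v))
                added += 1
    else:
        g = nx.barabasi_albert_graph(
            scenario.n_proteins, scenario.attachment, seed=int(rng.integers(2**31 - 1))
        )
        edges = set(g.edges())
        clusters = {p: 0 for p in names}
    named_edges = sorted(
        (names[u], names[v]) if names[u] <= names[v] else (names[v], names[u])
        for u, v in edges
    )
    degree: dict[str, int] = {p: 0 for p in names}
    for u, v in named_edges:
        degree[u] += 1
        degree[v] += 1
    weights = np.array([degree[p] for p in names], dtype=float)
    weights = weights / weights.sum()
    seeds = sorted(
        rng.choice(np.array(names, dtype=object), size=scenario.n_seeds,
                   replace=False, p=weights).tolist()
    )
    return named_edges, [str(s) for s in seeds], clusters


def make_ontology(
    scenario: SyntheticScenario,
    proteins: list[str],
    seed: int | None = None,
) -> tuple[dict[str, list[tuple[str, str]]], dict[str, set[str]]]:
    """Layered single-root DAG plus leaf annotations for ``proteins``.

    A pure ``branching``-ary is-a tree of the configured depth, with an
    extra part-of edge added to a random same-or-upper-layer term for a
    ``part_of_fraction`` of non-root terms.  Each protein is annotated to
    ``terms_per_protein`` random leaf terms.
    """
    if scenario.depth < 2:
        raise ValueError("ontology depth must be >= 2")
    rng = np.random.default_rng(scenario.seed + 1 if seed is None else seed)
    parents: dict[str, list[tuple[str, str]]] = {"T:ROOT": []}
    layers: list[list[str]] = [["T:ROOT"]]
    counter = 0
    for d in range(1, scenario.depth + 1):
        layer = []
        for parent in layers[d - 1]:
            for _ in range(scenario.branching):
                term = f"T:{counter:05d}"
                counter += 1
                parents[term] = [(parent, "is_a")]
                layer.append(term)
        layers.append(layer)
    # extra part-of edges to random shallower terms (keeps the DAG acyclic)
    for d in range(2, scenario.depth + 1):
        for term in layers[d]:
            if rng.random() < scenario.part_of_fraction:
                upper_layer = int(rng.integers(0, d - 1))
                target = layers[upper_layer][int(rng.integers(0, len(layers[upper_layer])))]
                if (target, "is_a") not in parents[term]:
                    parents[term].append((target, "part_of"))
    leaves = layers[-1]
    annotations = {
        p: set(
            rng.choice(np.array(leaves, dtype=object),
                       size=min(scenario.terms_per_protein, len(leaves)),
                       replace=False).tolist()
        )
        for p in sorted(proteins)
    }
    return parents, {p: {str(t) for t in ts} for p, ts in annotations.items()}


def write_obo(parents: Mapping[str, list[tuple[str, str]]], path: str | Path) -> Path:
    """Serialize the DAG as OBO v1.2 (is_a and relationship: part_of)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for term in sorted(parents):
            fh.write(f"\n[Term]\nid: {term}\nname: {term.lower()}\n")
            for parent, rel in parents[term]:
                if rel == "is_a":
                    fh.write(f"is_a: {parent} ! {parent.lower()}\n")
                else:
                    fh.write(f"relationship: part_of {parent} ! {parent.lower()}\n")
    return path


def make_labels_and_corpus(
    scenario: SyntheticScenario,
    clusters: Mapping[str, int],
    seed: int | None = None,
) -> tuple[dict[str, str], list[tuple[str, str]], dict[str, list[str]]]:
    """Planted direction labels and the abstract corpus that encodes them.

    UP labels go to cluster-0 proteins and DOWN labels to cluster-1
    proteins.  Each labeled protein gets ``support`` abstracts (distinct
    PMIDs), each holding one sentence pairing a protein alias with a
    direction-appropriate change word.  Returns (labels, abstracts as
    (pmid, text) pairs, alias table).
    """
    if scenario.n_up < 2:
        raise ValueError("need at least two UP labels")
    rng = np.random.default_rng(scenario.seed + 2 if seed is None else seed)
    pool_up = sorted(p for p, c in clusters.items() if c == 0)
    pool_down = sorted(p for p, c in clusters.items() if c != 0)
    if len(pool_up) < scenario.n_up or len(pool_down) < scenario.n_down:
        raise ValueError("clusters too small for the requested label counts")
    ups = sorted(rng.choice(np.array(pool_up, dtype=object), size=scenario.n_up, replace=False).tolist())
    downs = sorted(rng.choice(np.array(pool_down, dtype=object), size=scenario.n_down, replace=False).tolist())
    labels = {str(p): "UP" for p in ups} | {str(p): "DOWN" for p in downs}

    alias_table = {p: [p, f"{p} protein"] for p in sorted(clusters)}
    up_words = ["elevated", "increased", "up-regulated", "higher"]
    down_words = ["decreased", "reduced", "down-regulated", "inhibited"]
    fillers = [
        "Study design and recruitment are described elsewhere.",
        "Patients were followed for twelve months after admission.",
        "Echocardiography was performed at discharge.",
    ]
    abstracts: list[tuple[str, str]] = []
    pmid = 10_000_000
    for p in sorted(labels):
        words = up_words if labels[p] == "UP" else down_words
        for _ in range(scenario.support):
            word = words[int(rng.integers(0, len(words)))]
            filler = fillers[int(rng.integers(0, len(fillers)))]
            text = (
                f"{filler} Plasma {p} was significantly {word} in patients "
                "after myocardial infarction. Values are reported as medians."
            )
            abstracts.append((str(pmid), text))
            pmid += 1
    for _ in range(scenario.n_filler_abstracts):
        abstracts.append(
            (str(pmid), "No protein measurements were reported in this study.")
        )
        pmid += 1
    return labels, abstracts, alias_table


def make_pathways(
    scenario: SyntheticScenario,
    proteins: list[str],
    seed: int | None = None,
) -> dict[str, set[str]]:
    """GMT-style pathway sets with planted block structure.

    Pathways in the same block draw ``block_overlap`` of their members from
    a shared block core, plus random proteins; across blocks the expected
    overlap is ``cross_overlap``.
    """
    if scenario.n_pathways < 4:
        raise ValueError("need at least four pathways")
    rng = np.random.default_rng(scenario.seed + 3 if seed is None else seed)
    proteins = sorted(proteins)
    arr = np.array(proteins, dtype=object)
    core_size = max(6, len(proteins) // (scenario.n_blocks * 4))
    cores = []
    for _ in range(scenario.n_blocks):
        cores.append(set(rng.choice(arr, size=core_size, replace=False).tolist()))
    gene_sets: dict[str, set[str]] = {}
    per_block = scenario.n_pathways // scenario.n_blocks
    extra = scenario.n_pathways - per_block * scenario.n_blocks
    pw = 0
    for b in range(scenario.n_blocks):
        count = per_block + (1 if b < extra else 0)
        core = sorted(cores[b])
        for _ in range(count):
            n_core = max(2, int(round(scenario.block_overlap * len(core))))
            members = set(
                rng.choice(np.array(core, dtype=object), size=n_core, replace=False).tolist()
            )
            n_noise = max(1, int(round(scenario.cross_overlap * len(core)))) + 1
            members |= set(rng.choice(arr, size=n_noise, replace=False).tolist())
            gene_sets[f"PATH{pw:03d}_B{b}"] = {str(m) for m in members}
            pw += 1
    return gene_sets


def generate_scenario(scenario: SyntheticScenario, outdir: str | Path) -> dict[str, Path]:
    """Write every synthetic input for one scenario; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    edges, seeds, clusters = make_network(scenario)
    names = sorted(clusters)
    paths: dict[str, Path] = {}

    p = outdir / "interactions.tsv"
    with open(p, "w") as fh:
        fh.write("#proteinA\tproteinB\n")
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")
    paths["interactions"] = p

    p = outdir / "seeds.txt"
    p.write_text("\n".join(seeds) + "\n")
    paths["seeds"] = p

    p = outdir / "clusters.tsv"
    with open(p, "w") as fh:
        fh.write("#protein\tcluster\n")
        for name in names:
            fh.write(f"{name}\t{clusters[name]}\n")
    paths["clusters"] = p

    parents, annotations = make_ontology(scenario, names)
    paths["obo"] = write_obo(parents, outdir / "ontology.obo")
    p = outdir / "annotations.tsv"
    with open(p, "w") as fh:
        fh.write("#protein\tterm\n")
        for protein in sorted(annotations):
            for term in sorted(annotations[protein]):
                fh.write(f"{protein}\t{term}\n")
    paths["annotations"] = p

    labels, abstracts, alias_table = make_labels_and_corpus(scenario, clusters)
    p = outdir / "labels.tsv"
    with open(p, "w") as fh:
        fh.write("#protein\tdirection\n")
        for protein in sorted(labels):
            fh.write(f"{protein}\t{labels[protein]}\n")
    paths["labels"] = p

    corpus_dir = outdir / "abstracts"
    corpus_dir.mkdir(exist_ok=True)
    for pmid, text in abstracts:
        (corpus_dir / f"{pmid}.txt").write_text(f"{pmid}\n{text}\n")
    paths["abstracts"] = corpus_dir

    p = outdir / "aliases.tsv"
    with open(p, "w") as fh:
        fh.write("#protein\talias\n")
        for protein in sorted(alias_table):
            for alias in alias_table[protein]:
                fh.write(f"{protein}\t{alias}\n")
    paths["aliases"] = p

    p = outdir / "change_words.tsv"
    from .textmine import DEFAULT_CHANGE_WORDS

    with open(p, "w") as fh:
        fh.write("#stem\tdirection\n")
        for stem, direction in sorted(DEFAULT_CHANGE_WORDS.items()):
            fh.write(f"{stem}\t{direction}\n")
    paths["change_words"] = p

    gene_sets = make_pathways(scenario, names)
    from .pathways import write_gmt

    paths["gmt"] = write_gmt(gene_sets, outdir / "pathways.gmt")
    return paths
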
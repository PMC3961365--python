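"""Pathway membership matrices, Cohen's kappa similarity, and clustering.

Enriched pathways are represented as an M x n binary membership matrix over
the union of their member proteins.  For a pathway pair, with a = proteins
in both, b = in the second only, c = in the first only, d = in neither,
Cohen's kappa is::

    kappa = (Pr(agree) - Pr(random)) / (1 - Pr(random))
    Pr(agree)  = (a + d) / n
    Pr(random) = ((a+c)/n)((a+b)/n) + ((b+d)/n)((c+d)/n)

A high kappa means two pathways share many proteins.  Pathways are grouped
by average-linkage hierarchical clustering on the dissimilarity 1 - kappa
(negative kappa maps to dissimilarity above 1) with a configurable cut
height; clusters are labeled by size rank for reproducible export.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "PathwayMatrix",
    "KappaResult",
    "kappa",
    "kappa_matrix",
    "cluster_pathways",
    "read_gmt",
    "write_gmt",
]


@dataclass(frozen=True)
class PathwayMatrix:
    """Binary pathway x protein membership matrix."""

    pathways: tuple[str, ...]
    proteins: tuple[str, ...]
    membership: np.ndarray  # M x n of 0/1

    def __post_init__(self) -> None:
        m = np.asarray(self.membership)
        if m.shape != (len(self.pathways), len(self.proteins)):
            raise ValueError("membership shape mismatch")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("membership entries must be 0/1")
        if m.shape[0] and not m.any(axis=1).all():
            raise ValueError("every pathway must have at least one member")
        if m.shape[1] and not m.any(axis=0).all():
            raise ValueError("every protein column must have a membership")

    @classmethod
    def from_sets(cls, gene_sets: Mapping[str, Iterable[str]]) -> "PathwayMatrix":
        """Build the matrix over the union of member proteins."""
        pathways = tuple(sorted(gene_sets))
        proteins = tuple(sorted({p for s in gene_sets.values() for p in s}))
        idx = {p: i for i, p in enumerate(proteins)}
        m = np.zeros((len(pathways), len(proteins)), dtype=np.int8)
        for i, pw in enumerate(pathways):
            for p in gene_sets[pw]:
                m[i, idx[p]] = 1
        return cls(pathways, proteins, m)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.membership, index=self.pathways, columns=self.proteins)


def kappa(a: int, b: int, c: int, d: int) -> float:
    """Cohen's kappa from the 2x2 protein-membership contingency counts."""
    if min(a, b, c, d) < 0:
        raise ValueError("negative contingency counts")
    n = a + b + c + d
    if n < 1:
        raise ValueError("empty contingency table")
    pr_agree = (a + d) / n
    pr_random = ((a + c) / n) * ((a + b) / n) + ((b + d) / n) * ((c + d) / n)
    if pr_random == 1.0:
        # both pathways annotate everything or nothing: agreement is total
        return 1.0 if pr_agree == 1.0 else 0.0
    return (pr_agree - pr_random) / (1.0 - pr_random)


@dataclass(frozen=True)
class KappaResult:
    """Pairwise kappa matrix with the underlying contingency counts."""

    pathways: tuple[str, ...]
    matrix: np.ndarray  # M x M, symmetric, unit diagonal
    contingency: dict[tuple[str, str], tuple[int, int, int, int]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.pathways, columns=self.pathways)


def kappa_matrix(pm: PathwayMatrix) -> KappaResult:
    """Kappa for every pathway pair over the union protein set."""
    M = len(pm.pathways)
    if M < 2:
        raise ValueError("need at least two pathways")
    mem = pm.membership.astype(np.int64)
    n = mem.shape[1]
    both = mem @ mem.T  # a
    row = mem.sum(axis=1)
    out = np.eye(M)
    contingency: dict[tuple[str, str], tuple[int, int, int, int]] = {}
    for i in range(M):
        for j in range(i + 1, M):
            a = int(both[i, j])
            c = int(row[i] - a)  # in pathway i only
            b = int(row[j] - a)  # in pathway j only
            d = int(n - a - b - c)
            k = kappa(a, b, c, d)
            out[i, j] = out[j, i] = k
            contingency[(pm.pathways[i], pm.pathways[j])] = (a, b, c, d)
    return KappaResult(pm.pathways, out, contingency)


@dataclass(frozen=True)
class PathwayClusters:
    """Cluster assignment plus the linkage for dendrogram export."""

    pathways: tuple[str, ...]
    assignment: dict[str, int]  # pathway -> cluster label (1 = largest)
    cutoff: float
    linkage: np.ndarray
    leaf_order: tuple[str, ...]

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.assignment.items()), columns=["pathway", "cluster"]
        )

    def newick(self) -> str:
        """Dendrogram as a Newick string (branch lengths from merge heights)."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.pathways[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def cluster_pathways(kr: KappaResult, cutoff: float) -> PathwayClusters:
    """Average-linkage clustering of pathways on dissimilarity 1 - kappa.

    The dendrogram is cut at ``cutoff`` (same 1 - kappa scale); clusters are
    relabeled by decreasing size (ties by first pathway ID) so exports are
    stable.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    dist = 1.0 - kr.matrix
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # symmetrize drift
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    flat = hierarchy.fcluster(link, t=cutoff, criterion="distance")
    groups: dict[int, list[str]] = {}
    for pw, g in zip(kr.pathways, flat):
        groups.setdefault(int(g), []).append(pw)
    ranked = sorted(groups.values(), key=lambda ps: (-len(ps), ps[0]))
    assignment = {pw: rank + 1 for rank, ps in enumerate(ranked) for pw in ps}
    order = hierarchy.leaves_list(link)
    return PathwayClusters(
        pathways=kr.pathways,
        assignment=assignment,
        cutoff=cutoff,
        linkage=link,
        leaf_order=tuple(kr.pathways[i] for i in order),
    )


# ---------------------------------------------------------------------------
# GMT I/O


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets: name <tab> description <tab> member...; empty
    sets are dropped."""
    out: dict[str, set[str]] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            continue
        members = {f.strip() for f in fields[2:] if f.strip()}
        if members:
            out[fields[0].strip()] = members
    return out


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            members = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\t{name}\t{members}\n")
    return path


def pathway_enrichment(
    gene_sets: Mapping[str, Iterable[str]],
    study: Iterable[str],
    population: Iterable[str],
    min_count: int = 2,
    alpha: float = 0.05,
) -> dict[str, set[str]]:
    """EASE-enriched pathways (count >= 2, p <= 0.05), each treated as a flat
    term; returns the enriched sets restricted to study members."""
    from .ontology import ease_pvalue

    study = set(map(str, study))
    population = set(map(str, population))
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    enriched: dict[str, set[str]] = {}
    for name in sorted(gene_sets):
        members = set(map(str, gene_sets[name])) & population
        hits = members & study
        if len(hits) < min_count:
            continue
        p = ease_pvalue(len(hits), len(study), len(members), len(population))
        if p <= alpha:
            enriched[name] = hits
    return enriched
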
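"""Structural and functional protein similarity matrices.

Three |V|x|V| matrices over the network's proteins feed label propagation:

* ``J`` — Jaccard overlap of direct interaction neighborhoods,
  ``|N_i ∩ N_j| / |N_i ∪ N_j|``, diagonal 1 by definition;
* ``GS`` — functional similarity from Wang's semantic measure on the GO
  biological-process DAG (S-values of shared ancestors, best-match average
  over each protein's annotation sets);
* ``W`` — the combined matrix, by default the elementwise mean of J and GS
  (product and max schemes are available; the choice is recorded in output
  metadata since any [0,1]-preserving combination is admissible).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .network import InteractionNetwork
from .ontology import OntologyDag

__all__ = [
    "SimilarityBundle",
    "jaccard_matrix",
    "wang_term_similarity",
    "protein_functional_similarity",
    "functional_similarity_matrix",
    "combine",
    "similarity_bundle",
]

#: contribution weights per edge relation in Wang's S-value recursion
WANG_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}

COMBINE_SCHEMES = ("mean", "product", "max")


def jaccard_matrix(net: InteractionNetwork) -> tuple[list[str], np.ndarray]:
    """Neighborhood-overlap similarity for every protein pair.

    Returns the sorted protein index and the symmetric matrix with unit
    diagonal; a pair of isolated proteins scores 0 off-diagonal.
    """
    proteins = sorted(net.proteins)
    idx = {p: i for i, p in enumerate(proteins)}
    nbrs = [set() for _ in proteins]
    for u, v in net.edges:
        nbrs[idx[u]].add(idx[v])
        nbrs[idx[v]].add(idx[u])
    n = len(proteins)
    J = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            union = len(nbrs[i] | nbrs[j])
            if union:
                J[i, j] = J[j, i] = len(nbrs[i] & nbrs[j]) / union
    return proteins, J


def _s_values(dag: OntologyDag, term: str, weights: dict[str, float]) -> dict[str, float]:
    """Wang S-values: semantic contribution of each ancestor of ``term``.

    S(term) = 1; S(a) = max over child edges c->a on paths toward term of
    w(relation) * S(c).  Mixed relation paths multiply their own weights.
    """
    scope = dag.ancestors(term) | {term}
    sv: dict[str, float] = {}

    def s(a: str) -> float:
        if a in sv:
            return sv[a]
        if a == term:
            sv[a] = 1.0
            return 1.0
        # every ancestor of term has >=1 in-scope child on a path to term
        val = max(
            weights.get(rel, 0.0) * s(c)
            for c, rel in dag.children(a)
            if c in scope
        )
        sv[a] = val
        return val

    for a in scope:
        s(a)
    return sv


def wang_term_similarity(
    dag: OntologyDag,
    term1: str,
    term2: str,
    w_isa: float = WANG_WEIGHTS["is_a"],
    w_partof: float = WANG_WEIGHTS["part_of"],
) -> float:
    """Wang semantic similarity between two ontology terms in [0, 1]."""
    if term1 == term2:
        dag._require(term1)
        return 1.0
    weights = {"is_a": w_isa, "part_of": w_partof}
    s1 = _s_values(dag, term1, weights)
    s2 = _s_values(dag, term2, weights)
    common = s1.keys() & s2.keys()
    if not common:
        return 0.0
    num = sum(s1[t] + s2[t] for t in common)
    return num / (sum(s1.values()) + sum(s2.values()))


def protein_functional_similarity(
    dag: OntologyDag,
    protein_i: str,
    protein_j: str,
    w_isa: float = WANG_WEIGHTS["is_a"],
    w_partof: float = WANG_WEIGHTS["part_of"],
) -> float:
    """Best-match-average similarity between two proteins' annotation sets.

    ``[Σ_i max_j Sim(t_i, t_j) + Σ_j max_i Sim(t_j, t_i)] / (m + n)``.
    An unannotated protein yields 0 with a warning.
    """
    ts_i = sorted(dag.protein_terms(protein_i))
    ts_j = sorted(dag.protein_terms(protein_j))
    if not ts_i or not ts_j:
        warnings.warn(
            f"protein pair ({protein_i}, {protein_j}) has an unannotated "
            "member; functional similarity set to 0",
            stacklevel=2,
        )
        return 0.0
    sim = np.array(
        [[wang_term_similarity(dag, a, b, w_isa, w_partof) for b in ts_j] for a in ts_i]
    )
    return float((sim.max(axis=1).sum() + sim.max(axis=0).sum()) / (len(ts_i) + len(ts_j)))


def functional_similarity_matrix(
    dag: OntologyDag, proteins: list[str]
) -> np.ndarray:
    """GS matrix over an ordered protein list (symmetric, unit diagonal)."""
    n = len(proteins)
    GS = np.eye(n)
    # cache pairwise term similarities across protein pairs
    term_cache: dict[tuple[str, str], float] = {}

    def tsim(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in term_cache:
            term_cache[key] = wang_term_similarity(dag, key[0], key[1])
        return term_cache[key]

    annotated = {p: sorted(dag.protein_terms(p)) for p in proteins}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            for j in range(i + 1, n):
                ts_i, ts_j = annotated[proteins[i]], annotated[proteins[j]]
                if not ts_i or not ts_j:
                    continue
                sim = np.array([[tsim(a, b) for b in ts_j] for a in ts_i])
                GS[i, j] = GS[j, i] = (
                    sim.max(axis=1).sum() + sim.max(axis=0).sum()
                ) / (len(ts_i) + len(ts_j))
    return GS


def combine(J: np.ndarray, GS: np.ndarray, scheme: str = "mean") -> np.ndarray:
    """Elementwise combination of the structural and functional matrices."""
    J = np.asarray(J, dtype=float)
    GS = np.asarray(GS, dtype=float)
    if J.shape != GS.shape:
        raise ValueError(f"shape mismatch: {J.shape} vs {GS.shape}")
    if scheme == "mean":
        return (J + GS) / 2.0
    if scheme == "product":
        return J * GS
    if scheme == "max":
        return np.maximum(J, GS)
    raise ValueError(f"unknown combination scheme {scheme!r}")


@dataclass(frozen=True)
class SimilarityBundle:
    """The three similarity matrices over a fixed protein index."""

    proteins: tuple[str, ...]
    J: np.ndarray
    GS: np.ndarray
    W: np.ndarray
    scheme: str = "mean"

    def write(self, outdir: str | Path, stem: str = "similarity") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, mat in (("J", self.J), ("GS", self.GS), ("W", self.W)):
            p = outdir / f"{stem}.{name}.tsv"
            pd.DataFrame(mat, index=self.proteins, columns=self.proteins).to_csv(
                p, sep="\t"
            )
            paths[name] = p
        meta = outdir / f"{stem}.meta.json"
        meta.write_text(
            json.dumps({"scheme": self.scheme, "n_proteins": len(self.proteins)})
        )
        paths["meta"] = meta
        return paths


def similarity_bundle(
    net: InteractionNetwork, dag: OntologyDag, scheme: str = "mean"
) -> SimilarityBundle:
    """Compute J, GS and the combined W for every protein in the network."""
    proteins, J = jaccard_matrix(net)
    GS = functional_similarity_matrix(dag, proteins)
    return SimilarityBundle(tuple(proteins), J, GS, combine(J, GS, scheme), scheme)


def read_similarity_tsv(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [str(c) for c in df.columns], df.to_numpy(dtype=float)
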
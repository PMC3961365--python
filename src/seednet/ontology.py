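"""Gene Ontology DAG handling, term-specificity scores, and EASE enrichment.

Four measures describe how specific a biological-process term is:

* number of ancestors — distinct terms reachable through is-a/part-of
  parent edges up to and including the root;
* offspring score — ``ln((A + 1) / (n_offspring + 1))`` where ``A`` is the
  root's offspring count (23877 for the GO release analysed here), so the
  root scores 0 and near-leaves score high;
* GO proportion — ``n_ancestors / (n_ancestors + n_offspring)`` in [0, 1];
* information content — ``-log2(annotation_count / total_annotated)`` with
  14673 annotated human proteins as the default background, 0 at the root.

Enrichment follows the EASE convention: a one-sided Fisher exact test with
one success removed from the study-overlap cell, applied to annotation
counts propagated up the DAG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

__all__ = [
    "OntologyDag",
    "TermSpecificity",
    "EnrichmentResult",
    "ROOT_OFFSPRING_DEFAULT",
    "TOTAL_ANNOTATED_DEFAULT",
    "offspring_score",
    "go_proportion",
    "information_content",
    "ease_pvalue",
    "read_obo",
    "read_annotations",
]

#: offspring count of the biological-process root in the GO release analysed
ROOT_OFFSPRING_DEFAULT = 23877
#: human proteins carrying at least one biological-process annotation
TOTAL_ANNOTATED_DEFAULT = 14673

RELATIONS = ("is_a", "part_of")


class OntologyDag:
    """A rooted DAG of ontology terms with protein annotations.

    Edges point child -> parent and carry a relation tag (is-a or part-of).
    Annotations map protein -> set of directly annotated terms; counts
    propagate upward, so a protein annotated to a term also counts for every
    ancestor of that term.
    """

    def __init__(
        self,
        parents: Mapping[str, Iterable[tuple[str, str]]],
        names: Mapping[str, str] | None = None,
        annotations: Mapping[str, Iterable[str]] | None = None,
    ):
        self._parents: dict[str, list[tuple[str, str]]] = {}
        terms: set[str] = set(parents)
        for child, rels in parents.items():
            rels = list(rels)
            self._parents[str(child)] = [(str(p), str(r)) for p, r in rels]
            terms.update(p for p, _ in rels)
        for t in terms:
            self._parents.setdefault(t, [])
        self.names = {t: (names or {}).get(t, t) for t in self._parents}
        self._children: dict[str, list[tuple[str, str]]] = {t: [] for t in self._parents}
        for child, rels in self._parents.items():
            for parent, rel in rels:
                self._children[parent].append((child, rel))
        roots = [t for t, ps in self._parents.items() if not ps]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {sorted(roots)}")
        self.root = roots[0]
        self._check_acyclic()
        self.annotations: dict[str, frozenset[str]] = {}
        for protein, ts in (annotations or {}).items():
            ts = frozenset(map(str, ts))
            unknown = ts - self._parents.keys()
            if unknown:
                raise ValueError(f"annotation to unknown term(s): {sorted(unknown)}")
            self.annotations[str(protein)] = ts
        self._anc_cache: dict[str, frozenset[str]] = {}
        self._off_cache: dict[str, frozenset[str]] = {}

    # -- structure ---------------------------------------------------------

    def __contains__(self, term: str) -> bool:
        return term in self._parents

    def __len__(self) -> int:
        return len(self._parents)

    @property
    def terms(self) -> list[str]:
        return sorted(self._parents)

    def parents(self, term: str, relations: tuple[str, ...] = RELATIONS):
        self._require(term)
        return [(p, r) for p, r in self._parents[term] if r in relations]

    def children(self, term: str, relations: tuple[str, ...] = RELATIONS):
        self._require(term)
        return [(c, r) for c, r in self._children[term] if r in relations]

    def _require(self, term: str) -> None:
        if term not in self._parents:
            raise KeyError(f"unknown term {term!r}")

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(t: str) -> None:
            state[t] = 1
            for p, _ in self._parents[t]:
                s = state.get(p)
                if s == 1:
                    raise ValueError("ontology contains a cycle")
                if s is None:
                    visit(p)
            state[t] = 2

        for t in self._parents:
            if t not in state:
                visit(t)

    def ancestors(self, term: str) -> frozenset[str]:
        """Distinct terms reachable via parent edges; term itself excluded."""
        self._require(term)
        if term not in self._anc_cache:
            out: set[str] = set()
            stack = [p for p, _ in self._parents[term]]
            while stack:
                t = stack.pop()
                if t not in out:
                    out.add(t)
                    stack.extend(p for p, _ in self._parents[t])
            self._anc_cache[term] = frozenset(out)
        return self._anc_cache[term]

    def offspring(self, term: str) -> frozenset[str]:
        """Distinct descendant terms; term itself excluded."""
        self._require(term)
        if term not in self._off_cache:
            out: set[str] = set()
            stack = [c for c, _ in self._children[term]]
            while stack:
                t = stack.pop()
                if t not in out:
                    out.add(t)
                    stack.extend(c for c, _ in self._children[t])
            self._off_cache[term] = frozenset(out)
        return self._off_cache[term]

    def count_ancestors(self, term: str) -> int:
        return len(self.ancestors(term))

    def count_offspring(self, term: str) -> int:
        return len(self.offspring(term))

    # -- annotations -------------------------------------------------------

    def direct_annotation_sets(self) -> dict[str, set[str]]:
        """term -> set of proteins annotated directly to it."""
        out: dict[str, set[str]] = {t: set() for t in self._parents}
        for protein, ts in self.annotations.items():
            for t in ts:
                out[t].add(protein)
        return out

    def propagated_annotation_sets(self) -> dict[str, set[str]]:
        """term -> proteins annotated to it or to any of its descendants."""
        out = self.direct_annotation_sets()
        for protein, ts in self.annotations.items():
            covered: set[str] = set()
            for t in ts:
                covered |= self.ancestors(t)
            for a in covered:
                out[a].add(protein)
        return out

    def protein_terms(self, protein: str) -> frozenset[str]:
        return self.annotations.get(protein, frozenset())


# ---------------------------------------------------------------------------
# specificity measures


def offspring_score(n_offspring: int, A: int = ROOT_OFFSPRING_DEFAULT) -> float:
    """Log-scaled inverse of the descendant count: ln((A+1)/(n_offspring+1))."""
    if n_offspring < 0 or A < 0:
        raise ValueError("counts must be non-negative")
    if n_offspring > A:
        raise ValueError("a term cannot have more offspring than the root")
    return math.log((A + 1) / (n_offspring + 1))


def go_proportion(n_ancestors: int, n_offspring: int) -> float:
    """Ancestor fraction of (ancestors + offspring); 0 non-specific, 1 specific."""
    if n_ancestors < 0 or n_offspring < 0:
        raise ValueError("counts must be non-negative")
    if n_ancestors == 0 and n_offspring == 0:
        raise ValueError("isolated term: both counts zero")
    return n_ancestors / (n_ancestors + n_offspring)


def information_content(
    annotation_count: int, total_annotated: int = TOTAL_ANNOTATED_DEFAULT
) -> float:
    """-log2 of the term's annotation probability, in bits."""
    if annotation_count < 1:
        raise ValueError("information content undefined for unannotated terms")
    if annotation_count > total_annotated:
        raise ValueError("annotation count exceeds the annotated background")
    return -math.log2(annotation_count / total_annotated) + 0.0


# ---------------------------------------------------------------------------
# enrichment


def ease_pvalue(k: int, study_size: int, K: int, population_size: int) -> float:
    """EASE score: one-sided Fisher exact p with one success removed.

    ``k`` study proteins of ``study_size`` hit a term annotating ``K`` of the
    ``population_size`` background proteins.  Equals the hypergeometric
    upper tail P(X >= k-1); k <= 1 gives p = 1.
    """
    if min(k, study_size, K, population_size) < 0:
        raise ValueError("negative counts")
    if k <= 1:
        return 1.0
    return float(stats.hypergeom.sf(k - 2, population_size, K, study_size))


def fisher_pvalue(k: int, study_size: int, K: int, population_size: int) -> float:
    """Plain one-sided Fisher exact p = P(X >= k) (hypergeometric tail)."""
    return float(stats.hypergeom.sf(k - 1, population_size, K, study_size))


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    name: str
    study_count: int
    study_size: int
    population_count: int
    population_size: int
    ease_p: float

    @property
    def enriched(self) -> bool:
        return self.ease_p <= 0.05


def ease_enrichment(
    dag: OntologyDag,
    study: Iterable[str],
    population: Iterable[str] | None = None,
    min_count: int = 2,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """EASE-style term enrichment of a study protein set.

    Annotation counts are propagated up the DAG before testing; only terms
    hit by at least ``min_count`` study proteins are tested.  Results are
    sorted by p then term ID.  ``bh_correct`` applies Benjamini–Hochberg to
    the EASE p-values (off by default).
    """
    study = set(map(str, study))
    if population is None:
        population = set(dag.annotations)
    else:
        population = set(map(str, population))
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    propagated = dag.propagated_annotation_sets()
    results = []
    for term in sorted(dag.terms):
        annotated = propagated[term] & population
        k = len(annotated & study)
        if k < min_count:
            continue
        p = ease_pvalue(k, len(study), len(annotated), len(population))
        results.append(
            EnrichmentResult(
                term, dag.names[term], k, len(study), len(annotated), len(population), p
            )
        )
    results.sort(key=lambda r: (r.ease_p, r.term))
    if bh_correct:
        m = len(results)
        ranked = sorted(results, key=lambda r: r.ease_p)
        adj, best = {}, 1.0
        for i in range(m - 1, -1, -1):
            best = min(best, ranked[i].ease_p * m / (i + 1))
            adj[ranked[i].term] = best
        results = [
            EnrichmentResult(
                r.term, r.name, r.study_count, r.study_size,
                r.population_count, r.population_size, adj[r.term],
            )
            for r in results
        ]
    return [r for r in results if r.ease_p <= alpha] if alpha is not None else results


# ---------------------------------------------------------------------------
# specificity table


@dataclass(frozen=True)
class TermSpecificity:
    """The four specificity measures for one term."""

    term: str
    name: str
    n_ancestors: int
    n_offspring: int
    offspring_score: float
    go_proportion: float
    information_content: float | None
    annotation_count: int
    most_specific: bool = field(default=False)


def specificity_table(
    dag: OntologyDag,
    terms: Iterable[str],
    A: int | None = None,
    total_annotated: int | None = None,
) -> list[TermSpecificity]:
    """Score a set of (typically enriched) terms on all four measures.

    ``A`` defaults to the root's actual offspring count in ``dag``;
    ``total_annotated`` to the number of annotated proteins.  A term is
    flagged ``most_specific`` when none of its offspring is in the scored
    set.  Rows are sorted by GO proportion (desc), ties broken by term ID.
    """
    terms = sorted(set(map(str, terms)))
    for t in terms:
        dag._require(t)
    if A is None:
        A = dag.count_offspring(dag.root)
    if total_annotated is None:
        total_annotated = len(dag.annotations)
    propagated = dag.propagated_annotation_sets()
    term_set = set(terms)
    rows = []
    for t in terms:
        n_anc = dag.count_ancestors(t)
        n_off = dag.count_offspring(t)
        count = len(propagated[t])
        ic = (
            information_content(count, total_annotated)
            if count >= 1 and total_annotated >= 1
            else None
        )
        prop = 0.0 if t == dag.root else go_proportion(n_anc, n_off)
        rows.append(
            TermSpecificity(
                term=t,
                name=dag.names[t],
                n_ancestors=n_anc,
                n_offspring=n_off,
                offspring_score=offspring_score(min(n_off, A), A),
                go_proportion=prop,
                information_content=ic,
                annotation_count=count,
                most_specific=not (dag.offspring(t) & term_set),
            )
        )
    rows.sort(key=lambda r: (-r.go_proportion, r.term))
    return rows


def specificity_frame(rows: list[TermSpecificity]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# readers


def read_obo(path: str | Path, annotations: Mapping[str, Iterable[str]] | None = None) -> OntologyDag:
    """Read an OBO v1.2 ontology (is_a and relationship: part_of edges).

    Obsolete terms are skipped.  Uses :mod:`obonet` for parsing.
    """
    import obonet

    graph = obonet.read_obo(str(path))
    parents: dict[str, list[tuple[str, str]]] = {}
    names: dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        parents.setdefault(term, [])
        names[term] = data.get("name", term)
    for child, parent, rel in graph.edges(keys=True):
        if rel in RELATIONS:
            parents[child].append((parent, rel))
    return OntologyDag(parents, names, annotations)


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a protein→term TSV (two columns, ``#`` comments ignored)."""
    out: dict[str, set[str]] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        protein, term = line.split("\t")[:2]
        out.setdefault(protein.strip(), set()).add(term.strip())
    return out
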
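"""Random-network null models and empirical p-values.

Two ensembles calibrate how unusual the observed module's structure is:
Erdős–Rényi G(n, m) graphs matched on vertex and edge counts, and
seed-resampling networks built by drawing the same number of seed proteins
uniformly from the background universe and re-running the module
construction.  Per-replicate statistics are whole-graph vertex means
(isolated vertices included), and significance is the empirical tail
fraction, ties inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import InteractionNetwork, build_network, compute_centralities

__all__ = [
    "EmpiricalTestResult",
    "generate_er_gnm",
    "seed_resampling_network",
    "empirical_pvalue",
    "network_measures",
    "null_distribution",
    "compare_to_null",
]

MEASURES = ("degree", "betweenness", "closeness", "clustering", "eccentricity")


@dataclass(frozen=True)
class EmpiricalTestResult:
    """Observed statistic against a null sample.

    ``p_value`` counts null replicates at least as extreme as the observed
    value in the stated direction, ties inclusive; a zero count is reported
    as the resolution bound "< 1/N".
    """

    measure: str
    observed: float
    nulls: tuple[float, ...]
    direction: str  # greater | smaller | two-sided
    p_value: float
    display: str

    def __str__(self) -> str:
        return (
            f"{self.measure}: observed={self.observed:.4g}, "
            f"null mean={np.mean(self.nulls):.4g}, "
            f"p {self.display} ({self.direction}, N={len(self.nulls)})"
        )


def empirical_pvalue(
    observed: float, nulls, direction: str = "greater", measure: str = ""
) -> EmpiricalTestResult:
    """Empirical tail probability of ``observed`` under the null sample.

    One-sided p is the tie-inclusive tail count over N; two-sided is
    2*min(one-sided) capped at 1.
    """
    nulls = tuple(float(x) for x in nulls)
    if not nulls:
        raise ValueError("null sample must be non-empty")
    arr = np.asarray(nulls)
    n = arr.size
    if direction == "greater":
        count = int(np.sum(arr >= observed))
        p = count / n
    elif direction == "smaller":
        count = int(np.sum(arr <= observed))
        p = count / n
    elif direction == "two-sided":
        count = min(int(np.sum(arr >= observed)), int(np.sum(arr <= observed)))
        p = min(1.0, 2.0 * count / n)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    display = f"< {1 / n:g}" if count == 0 else f"= {p:g}"
    return EmpiricalTestResult(measure, observed, nulls, direction, p, display)


def generate_er_gnm(n: int, m: int, seed: int | None = None) -> InteractionNetwork:
    """Uniform random graph with exactly ``n`` vertices and ``m`` edges."""
    if m > n * (n - 1) // 2:
        raise ValueError(f"m={m} exceeds the maximum for n={n}")
    width = max(4, len(str(n)))
    names = [f"R{i:0{width}d}" for i in range(n)]
    g = nx.gnm_random_graph(n, m, seed=seed)
    edges = ((names[u], names[v]) for u, v in g.edges())
    return InteractionNetwork.from_edges(edges, extra_proteins=names)


def seed_resampling_network(
    universe: list[str],
    interactions: list[tuple[str, str]],
    n_seeds: int,
    seed: int | None = None,
) -> InteractionNetwork:
    """Draw ``n_seeds`` proteins uniformly and rebuild the module from them."""
    if n_seeds > len(universe):
        raise ValueError("n_seeds exceeds universe size")
    rng = np.random.default_rng(seed)
    picked = rng.choice(np.asarray(sorted(universe), dtype=object), size=n_seeds, replace=False)
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")  # resampled seeds may be isolated; expected
        return build_network([str(p) for p in picked], interactions)


def network_measures(net: InteractionNetwork) -> dict[str, float]:
    """Vertex means of the five centrality measures plus graph density."""
    prof = compute_centralities(net)
    out = prof.means
    out["density"] = prof.density
    return out


def null_distribution(
    kind: str,
    n_replicates: int,
    seed: int,
    *,
    n: int | None = None,
    m: int | None = None,
    universe: list[str] | None = None,
    interactions: list[tuple[str, str]] | None = None,
    n_seeds: int | None = None,
    measures: tuple[str, ...] = MEASURES + ("density",),
) -> dict[str, list[float]]:
    """Per-measure null samples from ``n_replicates`` random networks.

    ``kind`` is ``"er"`` (G(n, m), requires n and m) or ``"resample"``
    (seed resampling, requires universe/interactions/n_seeds).
    """
    rng = np.random.default_rng(seed)
    out: dict[str, list[float]] = {k: [] for k in measures}
    for _ in range(n_replicates):
        sub = int(rng.integers(0, 2**31 - 1))
        if kind == "er":
            net = generate_er_gnm(n, m, seed=sub)
        elif kind == "resample":
            net = seed_resampling_network(universe, interactions, n_seeds, seed=sub)
        else:
            raise ValueError(f"unknown null kind {kind!r}")
        vals = network_measures(net)
        for k in measures:
            out[k].append(vals[k])
    return out


def compare_to_null(
    net: InteractionNetwork,
    nulls: dict[str, list[float]],
    direction: str = "greater",
) -> list[EmpiricalTestResult]:
    """Empirical p-value of each observed mean measure against its null."""
    observed = network_measures(net)
    return [
        empirical_pvalue(observed[measure], sample, direction, measure=measure)
        for measure, sample in nulls.items()
    ]
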
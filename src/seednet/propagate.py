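"""Graph semi-supervised prediction of protein expression direction.

A handful of proteins carry literature-mined labels (1 = up-regulated,
0 = down-regulated); the rest are unlabeled.  Scores for the unlabeled
proteins solve the harmonic system over the combined similarity matrix W::

    f_U = (D_UU - W_UU)^-1  W_UL  y_L

with D the diagonal row-sum matrix of W.  A sequential variant ranks the
unlabeled proteins by how many labeled proteins they touch, partitions them
into k regions, and solves region by region, each fitted region joining the
labeled side for the next solve.  Proteins in later regions are farther
from the evidence, so their reported scores are shrunk toward the neutral
0.5 by 1 / (1 + l * region_index), where l is the inverse regularization
penalty (default 2).  Shrinkage affects confidence, never the side of 0.5.

Usage follows the statsmodels model/results convention::

    model = LabelPropagationModel(W, proteins, labels)
    res = model.fit()          # or model.fit(sequential=False)
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PropagationConfig",
    "LabelPropagationModel",
    "PropagationResults",
    "partition_matrix",
    "fits",
]


@dataclass(frozen=True)
class PropagationConfig:
    """Tunables of the sequential propagation.

    ``l`` is the inverse regularization penalty (> 0, default 2);
    ``k`` the number of regions (default: one per unlabeled protein);
    ``threshold``/``band`` define the calls: UP above threshold+band, DOWN
    below threshold-band, abstain inside the band.
    """

    l: float = 2.0
    k: int | None = None
    threshold: float = 0.5
    band: float = 0.05

    def __post_init__(self) -> None:
        if self.l <= 0:
            raise ValueError("l must be positive")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")


def partition_matrix(
    W: np.ndarray, index: list[str], labeled: set[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str], list[str]]:
    """Split W into (W_LL, W_LU, W_UL, W_UU) blocks.

    The index is reordered labeled-first, each side sorted by protein ID;
    the reordered labeled and unlabeled ID lists are returned alongside.
    """
    labeled = set(labeled)
    unknown = labeled - set(index)
    if unknown:
        raise ValueError(f"labeled proteins not in matrix index: {sorted(unknown)}")
    L = sorted(p for p in index if p in labeled)
    U = sorted(p for p in index if p not in labeled)
    if not L:
        raise ValueError("need at least one labeled protein")
    if not U:
        raise ValueError("no unlabeled proteins to predict")
    pos = {p: i for i, p in enumerate(index)}
    li = [pos[p] for p in L]
    ui = [pos[p] for p in U]
    W = np.asarray(W, dtype=float)
    return (
        W[np.ix_(li, li)],
        W[np.ix_(li, ui)],
        W[np.ix_(ui, li)],
        W[np.ix_(ui, ui)],
        L,
        U,
    )


def fits(
    W: np.ndarray, index: list[str], y_L: Mapping[str, float]
) -> dict[str, float]:
    """Harmonic scores for the unlabeled proteins.

    Solves ``(D_UU - W_UU) f_U = W_UL y_L`` with D the row-sum diagonal of
    the full W.  Unlabeled proteins with no similarity path to any labeled
    protein are unpredictable and returned as NaN rather than raising.
    Scores are clipped to [0, 1] against numerical drift.
    """
    W = np.asarray(W, dtype=float)
    _, _, W_UL, W_UU, L, U = partition_matrix(W, index, set(y_L))
    y = np.array([float(y_L[p]) for p in L])
    pos = {p: i for i, p in enumerate(index)}
    d_full = W.sum(axis=1)
    d_U = d_full[[pos[p] for p in U]]
    A = np.diag(d_U) - W_UU
    b = W_UL @ y

    scores: dict[str, float] = {}
    # identify unlabeled proteins connected (through unlabeled chains) to a
    # labeled protein: only those have a well-posed harmonic score
    reach = (W_UL != 0).any(axis=1)
    adj = W_UU - np.diag(np.diag(W_UU)) > 0
    changed = True
    while changed:
        newly = adj[:, reach].any(axis=1) & ~reach
        changed = bool(newly.any())
        reach = reach | newly
    unpredictable = [U[i] for i in np.flatnonzero(~reach)]
    if unpredictable:
        warnings.warn(
            f"{len(unpredictable)} unlabeled protein(s) have no connection "
            "to any labeled protein; returned as unpredictable (NaN)",
            stacklevel=2,
        )
    idx = np.flatnonzero(reach)
    if idx.size:
        sub_A = A[np.ix_(idx, idx)]
        sub_b = b[idx]
        try:
            f = np.linalg.solve(sub_A, sub_b)
        except np.linalg.LinAlgError:
            f = np.linalg.lstsq(sub_A, sub_b, rcond=None)[0]
        f = np.clip(f, 0.0, 1.0)
        for i, s in zip(idx, f):
            scores[U[i]] = float(s)
    for p in unpredictable:
        scores[p] = float("nan")
    return scores


@dataclass
class PropagationResults:
    """Predicted directions with provenance and per-protein confidence."""

    scores: dict[str, float]
    calls: dict[str, str]  # UP | DOWN | ABSTAIN | UNPREDICTABLE
    regions: dict[str, int]
    labels: dict[str, int]
    config: PropagationConfig
    warnings_: list[str] = field(default_factory=list)

    @property
    def predicted_up(self) -> list[str]:
        return sorted(p for p, c in self.calls.items() if c == "UP")

    @property
    def predicted_down(self) -> list[str]:
        return sorted(p for p, c in self.calls.items() if c == "DOWN")

    def direction_side(self, protein: str) -> str | None:
        """Side of the neutral point regardless of the abstention band."""
        s = self.scores.get(protein)
        if s is None or np.isnan(s) or s == self.config.threshold:
            return None
        return "UP" if s > self.config.threshold else "DOWN"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in sorted(self.labels):
            rows.append((p, "mined", "UP" if self.labels[p] else "DOWN", np.nan, -1))
        for p in sorted(self.scores):
            rows.append((p, "predicted", self.calls[p], self.scores[p], self.regions.get(p, -1)))
        return pd.DataFrame(rows, columns=["protein", "provenance", "call", "score", "region"])

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path

    def summary(self) -> str:
        n_up = len(self.predicted_up)
        n_down = len(self.predicted_down)
        n_abstain = sum(1 for c in self.calls.values() if c == "ABSTAIN")
        n_unpred = sum(1 for c in self.calls.values() if c == "UNPREDICTABLE")
        lines = [
            "Graph label propagation results",
            "-" * 38,
            f"labeled proteins      {len(self.labels):>8d}"
            f"  (UP {sum(self.labels.values())},"
            f" DOWN {len(self.labels) - sum(self.labels.values())})",
            f"unlabeled proteins    {len(self.scores):>8d}",
            f"predicted UP          {n_up:>8d}",
            f"predicted DOWN        {n_down:>8d}",
            f"abstained             {n_abstain:>8d}",
            f"unpredictable         {n_unpred:>8d}",
            f"l = {self.config.l}, k = {self.config.k or 'n_unlabeled'},"
            f" threshold = {self.config.threshold} ± {self.config.band}",
        ]
        lines.extend(f"warning: {w}" for w in self.warnings_)
        return "\n".join(lines)


def asymmetric_evidence_guard(labels: Mapping[str, int]) -> tuple[set[str], list[str]]:
    """Suppress calls for a direction backed by fewer than two labels.

    Returns the set of suppressed directions and the warning messages.
    """
    n_up = sum(1 for v in labels.values() if v == 1)
    n_down = len(labels) - n_up
    suppressed: set[str] = set()
    msgs: list[str] = []
    if n_down < 2:
        suppressed.add("DOWN")
        msgs.append(
            f"only {n_down} DOWN label(s): insufficient evidence, DOWN "
            "predictions suppressed"
        )
    if n_up < 2:
        suppressed.add("UP")
        msgs.append(
            f"only {n_up} UP label(s): insufficient evidence, UP "
            "predictions suppressed"
        )
    return suppressed, msgs


class LabelPropagationModel:
    """Semi-supervised direction predictor over a similarity matrix.

    Parameters
    ----------
    W : array
        Symmetric similarity matrix in [0, 1].
    index : list of str
        Protein IDs in matrix order.
    labels : mapping
        protein -> 1 (UP) or 0 (DOWN) for the labeled subset.
    """

    def __init__(self, W, index: list[str], labels: Mapping[str, int]):
        self.W = np.asarray(W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be square")
        if len(index) != self.W.shape[0]:
            raise ValueError("index length must match W")
        self.index = [str(p) for p in index]
        self.labels = {str(p): int(v) for p, v in labels.items()}
        for p, v in self.labels.items():
            if v not in (0, 1):
                raise ValueError(f"label for {p!r} must be 0 or 1")

    def fit(
        self, config: PropagationConfig | None = None, sequential: bool = True
    ) -> PropagationResults:
        config = config or PropagationConfig()
        unlabeled = sorted(set(self.index) - set(self.labels))
        if not unlabeled:
            raise ValueError("no unlabeled proteins to predict")
        pos = {p: i for i, p in enumerate(self.index)}
        W_offdiag = self.W - np.diag(np.diag(self.W))

        # rank by labeled connectivity: number of labeled proteins with a
        # nonzero similarity to the protein
        lab_idx = [pos[p] for p in sorted(self.labels)]
        connectivity = {
            p: int(np.count_nonzero(W_offdiag[pos[p], lab_idx])) for p in unlabeled
        }
        ranked = sorted(unlabeled, key=lambda p: (-connectivity[p], p))

        k = config.k or len(unlabeled)
        k = min(k, len(unlabeled)) if sequential else 1
        regions_list = [list(chunk) for chunk in np.array_split(np.array(ranked, dtype=object), k)]
        regions_list = [r for r in regions_list if r]

        raw_scores: dict[str, float] = {}
        regions: dict[str, int] = {}
        collected: list[str] = []
        working = dict(self.labels)  # grows with fitted regions (raw scores)
        remaining = set(unlabeled)
        for r, region in enumerate(regions_list):
            with warnings.catch_warnings(record=True) as wrec:
                warnings.simplefilter("always")
                region_scores = fits(self.W, self.index, working)
            collected.extend(str(w.message) for w in wrec if r == len(regions_list) - 1)
            for p in region:
                raw_scores[p] = region_scores[p]
                regions[p] = r
                remaining.discard(p)
                if not np.isnan(region_scores[p]):
                    working[p] = region_scores[p]

        # confidence shrinkage toward the neutral point by region distance
        scores: dict[str, float] = {}
        for p, s in raw_scores.items():
            if np.isnan(s):
                scores[p] = s
            else:
                shrink = 1.0 / (1.0 + config.l * regions[p])
                scores[p] = config.threshold + (s - config.threshold) * shrink

        suppressed, guard_msgs = asymmetric_evidence_guard(self.labels)
        calls: dict[str, str] = {}
        for p, s in scores.items():
            if np.isnan(s):
                calls[p] = "UNPREDICTABLE"
            elif s > config.threshold + config.band:
                calls[p] = "UP" if "UP" not in suppressed else "ABSTAIN"
            elif s < config.threshold - config.band:
                calls[p] = "DOWN" if "DOWN" not in suppressed else "ABSTAIN"
            else:
                calls[p] = "ABSTAIN"
        return PropagationResults(
            scores=scores,
            calls=calls,
            regions=regions,
            labels=dict(self.labels),
            config=config,
            warnings_=guard_msgs + sorted(set(collected)),
        )


def sequential_predict(
    W, index: list[str], labels: Mapping[str, int], config: PropagationConfig | None = None
) -> PropagationResults:
    """Functional wrapper around :class:`LabelPropagationModel`."""
    return LabelPropagationModel(W, index, labels).fit(config=config, sequential=True)
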
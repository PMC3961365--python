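"""Dictionary mining of protein expression direction from abstracts.

Abstracts are split into sentences; a sentence yields evidence when a
protein alias and a change word (an UP stem like "elevat" or a DOWN stem
like "reduc") co-occur in it.  A protein is labeled UP (or DOWN) when at
least ``min_citations`` distinct PMIDs support that direction and none
support the opposite; proteins with conflicting directions are excluded and
reported for manual review.  Negation ("not elevated") is deliberately not
handled — mined evidence is meant to be reviewed, so a review queue is
emitted instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "AbstractRecord",
    "MentionEvidence",
    "DEFAULT_CHANGE_WORDS",
    "split_sentences",
    "match_mentions",
    "mine_corpus",
    "aggregate_labels",
    "read_pubmed_xml",
    "read_text_abstracts",
    "read_alias_table",
    "read_change_dict",
]

#: default change-word stems (editable; load your own with read_change_dict)
DEFAULT_CHANGE_WORDS: dict[str, str] = {
    "elevat": "UP",
    "increas": "UP",
    "up-regulat": "UP",
    "upregulat": "UP",
    "higher": "UP",
    "rise": "UP",
    "rose": "UP",
    "decreas": "DOWN",
    "reduc": "DOWN",
    "down-regulat": "DOWN",
    "downregulat": "DOWN",
    "lower": "DOWN",
    "inhibit": "DOWN",
}

# common abbreviations that must not terminate a sentence
_ABBREVIATIONS = {
    "e.g", "i.e", "et al", "vs", "fig", "figs", "dr", "ca", "approx",
    "resp", "cf", "no", "st",
}

_SENT_BOUNDARY = re.compile(r"([.!?])\s+(?=[A-Z0-9(])")


@dataclass(frozen=True)
class AbstractRecord:
    pmid: str
    title: str
    text: str


@dataclass(frozen=True)
class MentionEvidence:
    pmid: str
    sentence: str
    protein: str
    alias: str
    change_word: str
    direction: str  # UP | DOWN


def split_sentences(text: str) -> list[str]:
    """Abbreviation-safe sentence splitting on ., ! and ?."""
    text = " ".join(text.split())
    if not text:
        return []
    pieces: list[str] = []
    start = 0
    for m in _SENT_BOUNDARY.finditer(text):
        words = text[start : m.start(1)].split()
        last_raw = words[-1] if words else ""
        last = last_raw.lstrip("([").rstrip(".").lower()
        two = " ".join(w.rstrip(".").lower() for w in words[-2:])
        if last in _ABBREVIATIONS or two in _ABBREVIATIONS:
            continue
        # a single capital letter before '.' is usually an initial
        if re.fullmatch(r"[A-Z]", last_raw.rstrip(".")):
            continue
        pieces.append(text[start : m.end(1)].strip())
        start = m.end()
    tail = text[start:].strip()
    if tail:
        pieces.append(tail)
    return [p for p in pieces if p]


def _alias_pattern(alias: str) -> re.Pattern:
    # token-boundary aware: an alias must not match inside a longer word
    return re.compile(
        r"(?<![A-Za-z0-9])" + re.escape(alias) + r"(?![A-Za-z0-9])", re.IGNORECASE
    )


def _stem_pattern(stem: str) -> re.Pattern:
    # stems match as a word prefix so "elevat" hits "elevated" and "elevates"
    return re.compile(
        r"(?<![A-Za-z0-9])(" + re.escape(stem) + r"[a-z]*)(?![A-Za-z0-9])",
        re.IGNORECASE,
    )


def match_mentions(
    sentence: str,
    alias_table: Mapping[str, Iterable[str]],
    change_dict: Mapping[str, str] | None = None,
    pmid: str = "",
) -> list[MentionEvidence]:
    """Evidence records for protein / change-word co-occurrences.

    Matching is case-insensitive and token-boundary aware; aliases are tried
    longest first so "MMP-9 precursor" wins over "MMP-9".  When a sentence
    carries several change words ("TIMP-1 was reduced while MMP-9 was
    elevated"), each protein mention is paired with the nearest change word,
    so contrasting clauses yield opposite directions rather than a cross
    product of spurious records.
    """
    change_dict = change_dict or DEFAULT_CHANGE_WORDS
    changes: list[tuple[int, str, str]] = []  # (position, word, direction)
    for stem, direction in change_dict.items():
        for m in _stem_pattern(stem).finditer(sentence):
            changes.append((m.start(), m.group(1), direction))
    if not changes:
        return []
    out: list[MentionEvidence] = []
    for protein in sorted(alias_table):
        aliases = sorted(alias_table[protein], key=len, reverse=True)
        hit = next(
            ((a, m) for a in aliases for m in [_alias_pattern(a).search(sentence)] if m),
            None,
        )
        if hit is None:
            continue
        alias, m = hit
        pos, word, direction = min(changes, key=lambda c: abs(c[0] - m.start()))
        out.append(MentionEvidence(pmid, sentence, protein, alias, word, direction))
    return out


def mine_corpus(
    abstracts: Iterable[AbstractRecord],
    alias_table: Mapping[str, Iterable[str]],
    change_dict: Mapping[str, str] | None = None,
) -> list[MentionEvidence]:
    """Sentence-level co-occurrence mining over a whole corpus."""
    evidence: list[MentionEvidence] = []
    for rec in abstracts:
        body = f"{rec.title}. {rec.text}" if rec.title else rec.text
        for sentence in split_sentences(body):
            evidence.extend(
                match_mentions(sentence, alias_table, change_dict, pmid=rec.pmid)
            )
    # deterministic regardless of corpus ordering
    evidence.sort(key=lambda e: (e.protein, e.pmid, e.sentence, e.change_word))
    return evidence


@dataclass(frozen=True)
class MinedLabels:
    """Aggregated labels plus the conflict/review reports."""

    labels: dict[str, str]  # protein -> UP | DOWN
    support: dict[str, dict[str, set[str]]]  # protein -> direction -> PMIDs
    conflicts: list[str]
    below_threshold: list[str]

    def to_frames(self) -> dict[str, pd.DataFrame]:
        lab = pd.DataFrame(
            [
                (p, d, ",".join(sorted(self.support[p][d])))
                for p, d in sorted(self.labels.items())
            ],
            columns=["protein", "direction", "pmids"],
        )
        con = pd.DataFrame(
            [
                (
                    p,
                    ",".join(sorted(self.support[p].get("UP", set()))),
                    ",".join(sorted(self.support[p].get("DOWN", set()))),
                )
                for p in self.conflicts
            ],
            columns=["protein", "up_pmids", "down_pmids"],
        )
        return {"labels": lab, "conflicts": con}


def aggregate_labels(
    evidence: Iterable[MentionEvidence], min_citations: int = 2
) -> MinedLabels:
    """Distinct-PMID vote: label a direction supported by >= min_citations
    PMIDs with zero opposing PMIDs; report conflicted proteins."""
    if min_citations < 1:
        raise ValueError("min_citations must be >= 1")
    support: dict[str, dict[str, set[str]]] = {}
    for ev in evidence:
        support.setdefault(ev.protein, {}).setdefault(ev.direction, set()).add(ev.pmid)
    labels: dict[str, str] = {}
    conflicts: list[str] = []
    below: list[str] = []
    for protein in sorted(support):
        ups = support[protein].get("UP", set())
        downs = support[protein].get("DOWN", set())
        if ups and downs:
            conflicts.append(protein)
        elif len(ups) >= min_citations:
            labels[protein] = "UP"
        elif len(downs) >= min_citations:
            labels[protein] = "DOWN"
        else:
            below.append(protein)
    return MinedLabels(labels, support, conflicts, below)


# ---------------------------------------------------------------------------
# readers


def read_pubmed_xml(path: str | Path) -> list[AbstractRecord]:
    """Read PubmedArticle records (PMID, ArticleTitle, AbstractText)."""
    from lxml import etree

    tree = etree.parse(str(path))
    records = []
    for art in tree.iter("PubmedArticle"):
        pmid = art.findtext(".//PMID", default="").strip()
        title = art.findtext(".//ArticleTitle", default="").strip()
        parts = [
            "".join(el.itertext()).strip()
            for el in art.findall(".//Abstract/AbstractText")
        ]
        records.append(AbstractRecord(pmid, title, " ".join(p for p in parts if p)))
    return records


def read_text_abstracts(paths: Iterable[str | Path]) -> list[AbstractRecord]:
    """Plain-text fallback: one abstract per file, first line is the PMID."""
    records = []
    for path in paths:
        lines = Path(path).read_text().splitlines()
        if not lines:
            continue
        pmid = lines[0].strip()
        records.append(AbstractRecord(pmid, "", " ".join(lines[1:]).strip()))
    return records


def read_alias_table(path: str | Path) -> dict[str, list[str]]:
    """TSV of (protein ID, alias); repeated protein rows accumulate aliases."""
    out: dict[str, list[str]] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        protein, alias = line.split("\t")[:2]
        out.setdefault(protein.strip(), []).append(alias.strip())
    return out


def read_change_dict(path: str | Path) -> dict[str, str]:
    """TSV of (stem, direction) with direction UP or DOWN."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        stem, direction = line.split("\t")[:2]
        direction = direction.strip().upper()
        if direction not in ("UP", "DOWN"):
            raise ValueError(f"direction must be UP or DOWN: {line!r}")
        out[stem.strip().lower()] = direction
    return out


def write_evidence(evidence: list[MentionEvidence], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([e.__dict__ for e in evidence]).to_csv(path, sep="\t", index=False)
    return path
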
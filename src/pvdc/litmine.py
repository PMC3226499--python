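"""Keyword co-occurrence ranking of assay targets over abstract corpora.

Candidate assay targets are prioritized by how often they co-occur with
a vascular-development keyword list in the literature: the corpus is
first narrowed to documents mentioning at least one keyword, then each
target is scored by the number of remaining documents mentioning any of
its synonyms (VEGFR2 ~ KDR ~ Flk1, ...).  Matching is case-insensitive
on word boundaries; counting is at document level, which is robust to
abstract length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence


def _normalize_phrase(text: str) -> str:
    """Case-fold and collapse hyphens/whitespace runs to single spaces."""
    return re.sub(r"[-\s]+", " ", text.strip().casefold())


def _phrase_pattern(phrase: str) -> re.Pattern:
    """Literal word-boundary pattern; hyphen/space runs match each other."""
    norm = _normalize_phrase(phrase)
    if not norm:
        raise ValueError("empty search phrase")
    body = r"[-\s]+".join(re.escape(tok) for tok in norm.split(" "))
    return re.compile(rf"(?<!\w){body}(?!\w)", flags=re.IGNORECASE)


@dataclass(frozen=True)
class Document:
    doc_id: str
    text: str


class Corpus:
    """An ordered collection of documents with unique ids."""

    def __init__(self, documents: Iterable[Document | tuple[str, str]]):
        docs = [
            d if isinstance(d, Document) else Document(str(d[0]), str(d[1]))
            for d in documents
        ]
        ids = [d.doc_id for d in docs]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate document id: {dup!r}")
        self.documents = docs

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Corpus":
        """One record per line: ``doc_id TAB abstract text``."""
        docs = []
        for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            if not line.strip():
                continue
            if "\t" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>text'")
            doc_id, text = line.split("\t", 1)
            docs.append(Document(doc_id.strip(), text))
        return cls(docs)

    @classmethod
    def from_directory(cls, path: str | Path, glob: str = "*.txt") -> "Corpus":
        """One document per text file; the stem is the document id."""
        files = sorted(Path(path).glob(glob))
        return cls(
            Document(f.stem, f.read_text(encoding="utf-8")) for f in files
        )


class SynonymTable:
    """Target id → synonym list; no synonym may map to two targets."""

    def __init__(self, table: Mapping[str, Sequence[str]]):
        self._table: dict[str, list[str]] = {}
        owner: dict[str, str] = {}
        for target, synonyms in table.items():
            syns = [s for s in (str(x).strip() for x in synonyms) if s]
            if not syns:
                raise ValueError(f"target {target!r}: synonym list is empty")
            for syn in syns:
                key = _normalize_phrase(syn)
                if key in owner and owner[key] != target:
                    raise ValueError(
                        f"synonym {syn!r} maps to both {owner[key]!r} "
                        f"and {target!r}"
                    )
                owner[key] = target
            self._table[str(target)] = syns

    def __len__(self) -> int:
        return len(self._table)

    def items(self):
        return self._table.items()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SynonymTable":
        """One target per line: ``target TAB syn1 TAB syn2 ...`` (the
        target name itself always counts as a synonym)."""
        table: dict[str, list[str]] = {}
        for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split("\t")]
            target, syns = parts[0], [p for p in parts[1:] if p]
            if not target:
                raise ValueError(f"{path}:{lineno}: missing target id")
            table[target] = [target, *syns]
        return cls(table)


def read_keywords(path: str | Path) -> list[str]:
    """One keyword or phrase per line; blank lines and # comments skipped."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        term = line.strip()
        if term and not term.startswith("#"):
            out.append(term)
    return out


def filter_corpus(corpus: Corpus, keywords: Sequence[str]) -> Corpus:
    """Keep documents containing ≥1 keyword.

    Keywords are matched literally (regex metacharacters have no special
    meaning), case-insensitively, on word boundaries.
    """
    if not keywords:
        raise ValueError("keyword list must be nonempty")
    patterns = [_phrase_pattern(k) for k in keywords]
    return Corpus(
        d for d in corpus if any(p.search(d.text) for p in patterns)
    )


def rank_targets(
    corpus: Corpus, synonyms: SynonymTable
) -> list[tuple[str, int]]:
    """Rank targets by the number of documents mentioning any synonym.

    A document counts once per target no matter how many of its synonyms
    occur.  Output is sorted by descending count, ties alphabetical by
    target id; deterministic and invariant to document order.
    """
    patterns = {
        target: [_phrase_pattern(s) for s in syns]
        for target, syns in synonyms.items()
    }
    counts = {
        target: sum(
            1
            for d in corpus
            if any(p.search(d.text) for p in pats)
        )
        for target, pats in patterns.items()
    }
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0].casefold()))
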
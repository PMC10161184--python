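"""Turn raw year-stamped documents into year-binned, normalized token sentences.

Documents may carry entity-annotation spans (PubTator-style concept tags).
Each annotated span is collapsed into a single synthetic token of the form
``<type>_<id>`` (e.g. ``mesh_d045169``) so that every surface variant of a
biomedical concept shares one embedding vector.  Documents are then sentence-
split, tokenized, normalized, and binned by publication year into
:class:`CorpusSlice` objects — the training unit for the embedding ensembles.

Lemmatization is deliberately a pluggable :class:`Normalizer` contract; the
default normalizer only lowercases, so the pipeline carries no dependency on
any particular NLP runtime.
"""

from __future__ import annotations

import json
import logging
import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationSpan",
    "Document",
    "CorpusSlice",
    "Normalizer",
    "lowercase_normalizer",
    "substitute_annotations",
    "tokenize_and_normalize",
    "deduplicate_versions",
    "bin_by_year",
    "read_jsonl",
    "write_slice",
    "read_slice",
]

# A Normalizer maps a token string to its normal form and must be idempotent.
Normalizer = Callable[[str], str]


def lowercase_normalizer(token: str) -> str:
    """Default normalizer: NFC-normalized Unicode lowercasing (idempotent)."""
    return unicodedata.normalize("NFC", token).lower()


@dataclass(frozen=True)
class AnnotationSpan:
    """A tagged entity mention: 0-based, end-exclusive character offsets."""

    start: int
    end: int
    entity_type: str
    entity_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span offsets [{self.start}, {self.end})")
        if not self.entity_type or not self.entity_id:
            raise ValueError("entity_type and entity_id must be non-empty")

    @property
    def token(self) -> str:
        """The synthetic token substituted for this span, e.g. ``mesh_d045169``."""
        return f"{self.entity_type}_{self.entity_id}".lower()


@dataclass(frozen=True)
class Document:
    doc_id: str
    year: int
    text: str
    version: int | None = None
    annotations: tuple[AnnotationSpan, ...] = ()

    def __post_init__(self) -> None:
        if self.version is not None and self.version < 1:
            raise ValueError(f"document {self.doc_id}: version must be >= 1")
        validate_spans(self.text, self.annotations, doc_id=self.doc_id)


def validate_spans(
    text: str, spans: Sequence[AnnotationSpan], doc_id: str = "?"
) -> None:
    """Reject out-of-range or overlapping annotation spans with a diagnostic."""
    for s in spans:
        if s.end > len(text):
            raise ValueError(
                f"document {doc_id}: span [{s.start}, {s.end}) exceeds "
                f"text length {len(text)}"
            )
    ordered = sorted(spans, key=lambda s: s.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError(
                f"document {doc_id}: overlapping spans "
                f"[{a.start}, {a.end}) and [{b.start}, {b.end})"
            )


@dataclass
class CorpusSlice:
    """One year's preprocessed corpus: token sentences plus token counts."""

    year: int
    sentences: list[list[str]] = field(default_factory=list)
    token_counts: Counter = field(default_factory=Counter)

    @property
    def total_tokens(self) -> int:
        return sum(self.token_counts.values())

    def add_sentences(self, sentences: Iterable[Sequence[str]]) -> None:
        for sent in sentences:
            sent = list(sent)
            if sent:
                self.sentences.append(sent)
                self.token_counts.update(sent)

    def recount(self) -> Counter:
        """Independent recount of ``sentences`` (consistency check)."""
        c: Counter = Counter()
        for sent in self.sentences:
            c.update(sent)
        return c


def substitute_annotations(doc: Document) -> str:
    """Replace each annotated span with its synthetic ``type_id`` token.

    Replacements are applied right-to-left so earlier offsets stay valid;
    characters outside annotated spans are never touched.  Span validity
    (in-range, non-overlapping) is enforced by the :class:`Document`
    constructor and re-checked here for texts paired with ad-hoc spans.
    """
    validate_spans(doc.text, doc.annotations, doc_id=doc.doc_id)
    text = doc.text
    for span in sorted(doc.annotations, key=lambda s: s.start, reverse=True):
        text = text[: span.start] + span.token + text[span.end :]
    return text


# Sentence-final punctuation, then token boundaries.  Tokens are runs of word
# characters that may contain internal underscores/hyphens/periods (so
# synthetic entity tokens like "mesh_d045169" and "sars-cov-2" survive intact).
_SENT_SPLIT = re.compile(r"(?<=[.!?])\s+")
_TOKEN = re.compile(r"[^\W_]+(?:[_\-.][^\W_]+)*", re.UNICODE)


def tokenize_and_normalize(
    text: str, norm: Normalizer = lowercase_normalizer
) -> list[list[str]]:
    """Split text into sentences of normalized tokens.

    Sentences split on whitespace following ``.!?``; tokens are extracted on
    word/punctuation boundaries with internal ``_ - .`` joiners preserved, so
    entity tokens pass through unsplit.  Trailing sentence punctuation is
    dropped.  Empty sentences (punctuation-only input) are omitted.
    """
    sentences: list[list[str]] = []
    for raw in _SENT_SPLIT.split(text):
        tokens = [norm(m.group(0).rstrip(".")) for m in _TOKEN.finditer(raw)]
        tokens = [t for t in tokens if t]
        if tokens:
            sentences.append(tokens)
    return sentences


def deduplicate_versions(docs: Iterable[Document]) -> list[Document]:
    """Keep only the most recent version of each document.

    Documents without a version are kept as-is.  Duplicate
    ``(doc_id, version)`` pairs are an input error.
    """
    best: dict[str, Document] = {}
    out: list[Document] = []
    seen_pairs: set[tuple[str, int]] = set()
    for doc in docs:
        if doc.version is None:
            out.append(doc)
            continue
        key = (doc.doc_id, doc.version)
        if key in seen_pairs:
            raise ValueError(f"duplicate (doc_id, version) pair {key}")
        seen_pairs.add(key)
        cur = best.get(doc.doc_id)
        if cur is None or doc.version > cur.version:  # type: ignore[operator]
            best[doc.doc_id] = doc
    out.extend(best.values())
    return out


def bin_by_year(
    docs: Iterable[Document],
    norm: Normalizer = lowercase_normalizer,
    min_year: int | None = None,
    max_year: int | None = None,
) -> dict[int, CorpusSlice]:
    """Bin documents into per-year corpus slices of normalized token sentences.

    Documents outside ``[min_year, max_year]`` are skipped (counted and
    logged), mirroring the restriction of the analysis window to years with
    adequate sample size.
    """
    slices: dict[int, CorpusSlice] = {}
    skipped = 0
    for doc in docs:
        if (min_year is not None and doc.year < min_year) or (
            max_year is not None and doc.year > max_year
        ):
            skipped += 1
            continue
        text = substitute_annotations(doc)
        sentences = tokenize_and_normalize(text, norm)
        slices.setdefault(doc.year, CorpusSlice(year=doc.year)).add_sentences(
            sentences
        )
    if skipped:
        logger.info("bin_by_year: skipped %d documents outside year range", skipped)
    return dict(sorted(slices.items()))


def read_jsonl(path: str | Path) -> list[Document]:
    """Read documents from JSON-lines: one object per line.

    Expected keys: ``doc_id``, ``year``, ``text``; optional ``version`` and
    ``annotations`` (list of ``{"start", "end", "type", "id"}``).
    """
    docs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                spans = tuple(
                    AnnotationSpan(a["start"], a["end"], a["type"], a["id"])
                    for a in rec.get("annotations", ())
                )
                docs.append(
                    Document(
                        doc_id=str(rec["doc_id"]),
                        year=int(rec["year"]),
                        text=rec["text"],
                        version=rec.get("version"),
                        annotations=spans,
                    )
                )
            except (KeyError, ValueError, json.JSONDecodeError) as exc:
                raise ValueError(f"{path}:{lineno}: bad document record: {exc}")
    return docs


def write_slice(slice_: CorpusSlice, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a slice as <year>.txt (one sentence per line, space-separated
    tokens) plus a <year>.counts.tsv sidecar (token, count)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    txt = out_dir / f"{slice_.year}.txt"
    tsv = out_dir / f"{slice_.year}.counts.tsv"
    with open(txt, "w", encoding="utf-8") as fh:
        for sent in slice_.sentences:
            fh.write(" ".join(sent) + "\n")
    with open(tsv, "w", encoding="utf-8") as fh:
        for tok, cnt in sorted(slice_.token_counts.items()):
            fh.write(f"{tok}\t{cnt}\n")
    return txt, tsv


def read_slice(txt_path: str | Path) -> CorpusSlice:
    """Read a per-year sentence file written by :func:`write_slice`."""
    txt_path = Path(txt_path)
    year = int(txt_path.stem)
    s = CorpusSlice(year=year)
    with open(txt_path, encoding="utf-8") as fh:
        s.add_sentences(line.split() for line in fh if line.strip())
    return s
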
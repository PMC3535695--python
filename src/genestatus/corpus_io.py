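"""Reading and writing trial documents, gene lexicons, and labeled instances.

Three on-disk formats, all UTF-8:

* trial documents — a structured-text format (records separated by a ``%%``
  line) and a minimal XML dialect (``<trials><trial id= status=>`` with one
  child element per section);
* gene lexicons — TSV with columns symbol, pipe-delimited synonyms, and a
  0/1 cancer-gene flag;
* labeled mention instances — JSON lines, append-friendly so that an
  iteratively grown annotation pool stays a single flat file.

All section text is normalized to Unicode NFC on read; character spans in
annotations are 0-based half-open offsets into the NFC section text.
"""

from __future__ import annotations

import json
import unicodedata
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Optional, Sequence

from lxml import etree

from .categories import StatusCategory, category_from_name, DEFAULT_CATEGORIES

if TYPE_CHECKING:  # pragma: no cover
    from .mention_detection import GeneMention

SECTION_NAMES = ("title", "summary", "eligibility")
TRIAL_STATUSES = ("active", "closed")

RECORD_SEPARATOR = "%%"


class CorpusFormatError(ValueError):
    """Malformed record in a corpus, lexicon, or annotation file."""


@dataclass
class TrialDocument:
    """One clinical trial's sectioned narrative text.

    ``sections`` is an ordered list of ``(name, text)`` pairs with names drawn
    from ``title`` / ``summary`` / ``eligibility``, each appearing at most
    once.
    """

    trial_id: str
    status: str = "active"
    sections: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.trial_id:
            raise ValueError("trial_id must be non-empty")
        if self.status not in TRIAL_STATUSES:
            raise ValueError(f"status must be one of {TRIAL_STATUSES}, got {self.status!r}")
        seen: set[str] = set()
        for name, _ in self.sections:
            if name not in SECTION_NAMES:
                raise ValueError(f"unknown section name {name!r}; allowed: {SECTION_NAMES}")
            if name in seen:
                raise ValueError(f"section {name!r} appears more than once in {self.trial_id}")
            seen.add(name)

    def section_text(self, name: str) -> Optional[str]:
        for sec, text in self.sections:
            if sec == name:
                return text
        return None


@dataclass(frozen=True)
class GeneLexiconEntry:
    """A canonical gene symbol with its synonym set and cancer-gene flag."""

    symbol: str
    synonyms: frozenset[str] = frozenset()
    is_cancer_gene: bool = False

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("gene symbol must be non-empty")
        if any(not s for s in self.synonyms):
            raise ValueError(f"empty synonym for symbol {self.symbol}")

    @property
    def match_terms(self) -> frozenset[str]:
        """All surface terms that count as a mention of this gene."""
        return self.synonyms | {self.symbol}


@dataclass
class LabeledInstance:
    """A gene mention paired with its gold (or predicted) status category."""

    mention: "GeneMention"
    label: StatusCategory
    annotator_id: Optional[str] = None


# ---------------------------------------------------------------------------
# Trial documents
# ---------------------------------------------------------------------------

def _nfc(text: str) -> str:
    return unicodedata.normalize("NFC", text)


def _escape_line(line: str) -> str:
    if line.startswith(("\\", "[", RECORD_SEPARATOR)):
        return "\\" + line
    return line


def _unescape_line(line: str) -> str:
    if line.startswith("\\"):
        return line[1:]
    return line


def read_trials(path: str | Path, format: str = "structured_text") -> list[TrialDocument]:
    """Read trial documents from ``path``.

    ``format`` is ``structured_text`` (``%%``-separated records, section
    blocks introduced by ``[title]`` etc.) or ``xml`` (the minimal dialect
    written by :func:`write_trials`). Section text is NFC-normalized.
    """
    path = Path(path)
    if format == "structured_text":
        return _read_trials_text(path)
    if format == "xml":
        return _read_trials_xml(path)
    raise ValueError(f"unknown trial format {format!r}")


def _read_trials_text(path: Path) -> list[TrialDocument]:
    raw = path.read_text(encoding="utf-8")
    docs: list[TrialDocument] = []
    if raw.strip() == "":
        return docs
    if raw.endswith("\n"):  # file-final newline added by the writer
        raw = raw[:-1]
    records = raw.split(f"\n{RECORD_SEPARATOR}\n")
    for rec_no, record in enumerate(records):
        if record.strip() == "":
            continue
        lines = record.split("\n")
        header = lines[0].split("\t")
        if len(header) != 2:
            raise CorpusFormatError(
                f"record {rec_no}: header must be 'trial_id<TAB>status', got {lines[0]!r}"
            )
        trial_id, status = header
        sections: list[tuple[str, str]] = []
        current: Optional[str] = None
        buf: list[str] = []

        def flush() -> None:
            if current is not None:
                sections.append((current, _nfc("\n".join(buf))))

        for line in lines[1:]:
            if line.startswith("[") and line.endswith("]"):
                name = line[1:-1]
                if name not in SECTION_NAMES:
                    raise CorpusFormatError(
                        f"trial {trial_id}: unknown section name {name!r}"
                    )
                flush()
                current, buf = name, []
            elif current is None:
                raise CorpusFormatError(
                    f"trial {trial_id}: text before any section header"
                )
            else:
                buf.append(_unescape_line(line))
        flush()
        try:
            docs.append(TrialDocument(trial_id=trial_id, status=status, sections=sections))
        except ValueError as exc:
            raise CorpusFormatError(f"trial {trial_id}: {exc}") from exc
    return docs


def _read_trials_xml(path: Path) -> list[TrialDocument]:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusFormatError(f"malformed XML in {path}: {exc}") from exc
    docs: list[TrialDocument] = []
    for trial in tree.getroot().iterfind("trial"):
        trial_id = trial.get("id") or ""
        status = trial.get("status") or "active"
        sections: list[tuple[str, str]] = []
        for child in trial:
            if child.tag not in SECTION_NAMES:
                raise CorpusFormatError(
                    f"trial {trial_id}: unknown section name {child.tag!r}"
                )
            sections.append((child.tag, _nfc(child.text or "")))
        try:
            docs.append(TrialDocument(trial_id=trial_id, status=status, sections=sections))
        except ValueError as exc:
            raise CorpusFormatError(f"trial {trial_id}: {exc}") from exc
    return docs


def write_trials(docs: Sequence[TrialDocument], path: str | Path,
                 format: str = "structured_text") -> None:
    """Write trial documents in the structured-text or XML dialect."""
    path = Path(path)
    if format == "structured_text":
        chunks = []
        for doc in docs:
            lines = [f"{doc.trial_id}\t{doc.status}"]
            for name, text in doc.sections:
                lines.append(f"[{name}]")
                lines.extend(_escape_line(l) for l in text.split("\n"))
            chunks.append("\n".join(lines))
        path.write_text(f"\n{RECORD_SEPARATOR}\n".join(chunks) + ("\n" if chunks else ""),
                        encoding="utf-8")
    elif format == "xml":
        root = etree.Element("trials")
        for doc in docs:
            trial = etree.SubElement(root, "trial", id=doc.trial_id, status=doc.status)
            for name, text in doc.sections:
                etree.SubElement(trial, name).text = text
        etree.ElementTree(root).write(str(path), encoding="utf-8",
                                      xml_declaration=True, pretty_print=True)
    else:
        raise ValueError(f"unknown trial format {format!r}")


# ---------------------------------------------------------------------------
# Gene lexicon
# ---------------------------------------------------------------------------

def read_lexicon(path: str | Path) -> list[GeneLexiconEntry]:
    """Read a TSV gene lexicon: symbol, pipe-delimited synonyms, 0/1 flag.

    Duplicate canonical symbols are an error; a synonym shared by two
    different genes is allowed but triggers a warning (mentions of such a
    term are resolved deterministically at match time).
    """
    path = Path(path)
    entries: list[GeneLexiconEntry] = []
    seen_symbols: set[str] = set()
    term_owner: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise CorpusFormatError(
                f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
            )
        symbol, syn_field, flag = parts
        if not symbol:
            raise CorpusFormatError(f"{path}:{lineno}: empty symbol field")
        if symbol in seen_symbols:
            raise CorpusFormatError(f"duplicate symbol {symbol!r} at {path}:{lineno}")
        seen_symbols.add(symbol)
        synonyms = frozenset(s for s in syn_field.split("|") if s)
        if flag not in ("0", "1"):
            raise CorpusFormatError(f"{path}:{lineno}: cancer flag must be 0 or 1")
        entry = GeneLexiconEntry(symbol=symbol, synonyms=synonyms,
                                 is_cancer_gene=flag == "1")
        for term in entry.match_terms:
            key = term.casefold()
            if key in term_owner and term_owner[key] != symbol:
                warnings.warn(
                    f"synonym {term!r} shared by {term_owner[key]} and {symbol}",
                    stacklevel=2,
                )
            term_owner.setdefault(key, symbol)
        entries.append(entry)
    return entries


def write_lexicon(entries: Sequence[GeneLexiconEntry], path: str | Path) -> None:
    lines = [
        "\t".join([e.symbol, "|".join(sorted(e.synonyms)), "1" if e.is_cancer_gene else "0"])
        for e in entries
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


# ---------------------------------------------------------------------------
# Labeled instances (JSON lines)
# ---------------------------------------------------------------------------

def write_annotations(instances: Iterable[LabeledInstance], path: str | Path) -> None:
    """Write labeled instances as JSON lines (one record per instance)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for inst in instances:
            m = inst.mention
            record = {
                "trial_id": m.trial_id,
                "section": m.section_name,
                "start": m.char_span[0],
                "end": m.char_span[1],
                "text": m.matched_text,
                "gene": m.gene_symbol,
                "sentence": m.sentence_index,
                "token": m.token_index,
                "n_tokens": m.n_tokens,
                "label": inst.label.name,
                "annotator": inst.annotator_id,
            }
            fh.write(json.dumps(record, ensure_ascii=False) + "\n")


def read_annotations(
    path: str | Path,
    categories: tuple[StatusCategory, ...] = DEFAULT_CATEGORIES,
    documents: Optional[Sequence[TrialDocument]] = None,
) -> list[LabeledInstance]:
    """Read labeled instances from a JSON-lines file.

    Labels are validated against ``categories``. When ``documents`` is
    supplied, each span is validated against the named section's text.
    """
    from .mention_detection import GeneMention

    doc_index = {d.trial_id: d for d in documents} if documents is not None else None
    instances: list[LabeledInstance] = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(),
                                  start=1):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
        except json.JSONDecodeError as exc:
            raise CorpusFormatError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
        try:
            label = category_from_name(rec["label"], categories)
        except ValueError as exc:
            raise CorpusFormatError(f"{path}:{lineno}: {exc}") from exc
        span = (rec["start"], rec["end"])
        if doc_index is not None:
            doc = doc_index.get(rec["trial_id"])
            if doc is None:
                raise CorpusFormatError(
                    f"{path}:{lineno}: unknown trial {rec['trial_id']!r}"
                )
            text = doc.section_text(rec["section"])
            if text is None or span[1] > len(text) or span[0] < 0 or span[0] > span[1]:
                raise CorpusFormatError(
                    f"{path}:{lineno}: span {span} outside section "
                    f"{rec['section']!r} of trial {rec['trial_id']}"
                )
        mention = GeneMention(
            trial_id=rec["trial_id"],
            gene_symbol=rec["gene"],
            matched_text=rec["text"],
            section_name=rec["section"],
            char_span=span,
            sentence_index=rec["sentence"],
            token_index=rec["token"],
            n_tokens=rec.get("n_tokens", 1),
        )
        instances.append(LabeledInstance(mention=mention, label=label,
                                         annotator_id=rec.get("annotator")))
    return instances
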
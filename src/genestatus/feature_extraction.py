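"""Sparse feature extraction for gene mentions.

Four feature families describe a mention's context, mirroring what a reader
uses to disambiguate a symbol like "met" or "kit":

* ``context`` — bag-of-words and positional (direction + distance) features
  for tokens within a window (default 6 per side) of the mention inside its
  sentence, plus orthographic indicators (all-caps, digit, initial capital,
  special character) for the mention token and its immediate neighbors
  (prefixes ``ctx:`` and ``orth:``);
* ``dependency`` — the word, POS tag and relation label of tokens linked to
  the mention by one dependency edge (prefix ``dep:``), supplied by a
  pluggable provider;
* ``negation`` — a single indicator set when a negation word occurs within a
  small window (default 3) of the mention (prefix ``neg:``);
* ``section`` — which document section (title / summary / eligibility) the
  mention sits in (prefix ``sec:``).

All features are binary presence indicators; a feature vector is a sparse
``{name: 1.0}`` mapping. Context words are lowercased for ``ctx:`` features
so that casing is carried exclusively by the ``orth:`` indicators.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Optional, Protocol, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .mention_detection import GeneMention

FeatureVector = dict[str, float]

FEATURE_FAMILIES = ("context", "dependency", "negation", "section")

#: Feature-name prefixes contributed by each family. Orthographic indicators
#: belong to the context family (they describe the mention's surface context)
#: but carry their own ``orth:`` namespace.
FAMILY_PREFIXES = {
    "context": ("ctx:", "orth:"),
    "dependency": ("dep:",),
    "negation": ("neg:",),
    "section": ("sec:",),
}


class ConfigurationError(ValueError):
    """Raised when feature configuration and providers are inconsistent."""


# ---------------------------------------------------------------------------
# Tokenization and sentence splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Token:
    text: str
    span: tuple[int, int]  # 0-based half-open offsets into the section text


@dataclass
class Sentence:
    """An ordered token sequence with character spans into its section."""

    tokens: list[Token]
    section: Optional[str] = None

    def __post_init__(self) -> None:
        prev_end = -1
        for tok in self.tokens:
            if tok.span[0] < prev_end:
                raise ValueError("token spans must be non-overlapping and increasing")
            prev_end = tok.span[1]


# Words keep internal hyphens/apostrophes ("c-kit", "wild-type"); any other
# non-space character is its own token.
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:[-'][A-Za-z0-9]+)*|\S")
_TERMINAL = {".", "!", "?"}
_BULLET = {"-", "*", "•", "·"}


def tokenize_and_split(text: str, section: Optional[str] = None) -> list[Sentence]:
    """Deterministically tokenize ``text`` and split it into sentences.

    Boundaries fall after terminal punctuation (``. ! ?``) and at line
    breaks, which approximates the bullet-list structure of eligibility
    criteria sections. Hyphenated words stay single tokens.
    """
    sentences: list[Sentence] = []
    current: list[Token] = []

    def flush() -> None:
        nonlocal current
        if current:
            sentences.append(Sentence(tokens=current, section=section))
            current = []

    prev_end = 0
    for match in _TOKEN_RE.finditer(text):
        if "\n" in text[prev_end:match.start()]:
            flush()
        tok = Token(text=match.group(), span=(match.start(), match.end()))
        # a bullet marker opening a line starts its own implicit sentence
        if tok.text in _BULLET and not current:
            prev_end = match.end()
            continue
        current.append(tok)
        if tok.text in _TERMINAL:
            flush()
        prev_end = match.end()
    flush()
    return sentences


# ---------------------------------------------------------------------------
# Configuration and auxiliary lexicons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureConfig:
    """Window sizes and enabled feature families."""

    context_window: int = 6
    negation_window: int = 3
    enabled_families: frozenset[str] = frozenset(FEATURE_FAMILIES)
    lowercase_lexical: bool = True

    def __post_init__(self) -> None:
        if self.context_window < 1 or self.negation_window < 1:
            raise ValueError("window sizes must be >= 1")
        if not self.enabled_families:
            raise ValueError("enabled_families must be non-empty")
        unknown = set(self.enabled_families) - set(FEATURE_FAMILIES)
        if unknown:
            raise ValueError(f"unknown feature families: {sorted(unknown)}")


@dataclass(frozen=True)
class NegationLexicon:
    """Lowercase single-token words signalling a negated lesion status."""

    words: frozenset[str]

    def __post_init__(self) -> None:
        if not self.words:
            raise ValueError("negation lexicon must be non-empty")
        for w in self.words:
            if not w or w != w.lower() or any(ch.isspace() for ch in w):
                raise ValueError(f"negation entries must be lowercase single tokens: {w!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "NegationLexicon":
        words = frozenset(
            line.strip().lower()
            for line in Path(path).read_text(encoding="utf-8").splitlines()
            if line.strip() and not line.startswith("#")
        )
        return cls(words=words)

    @classmethod
    def default(cls) -> "NegationLexicon":
        ref = resources.files("genestatus.data") / "negation_words.txt"
        with resources.as_file(ref) as path:
            return cls.from_file(path)


# ---------------------------------------------------------------------------
# Dependency analysis (pluggable provider + offline heuristic fallback)
# ---------------------------------------------------------------------------

@dataclass
class DependencyAnalysis:
    """POS tags and directed edges for one sentence.

    ``edges`` holds ``(head_index, dependent_index, relation)`` triples;
    ``pos_tags`` maps a token index to its tag (only tokens participating in
    edges need tags). A dependent has at most one head.
    """

    pos_tags: dict[int, str] = field(default_factory=dict)
    edges: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        heads: dict[int, int] = {}
        for head, dep, _ in self.edges:
            if dep in heads and heads[dep] != head:
                raise ValueError(f"token {dep} has more than one head")
            heads[dep] = head

    def validate_indices(self, n_tokens: int) -> None:
        for head, dep, rel in self.edges:
            if not (0 <= head < n_tokens and 0 <= dep < n_tokens):
                raise ValueError(f"edge ({head},{dep},{rel}) outside sentence of {n_tokens} tokens")


class DependencyProvider(Protocol):
    """Anything that can produce a :class:`DependencyAnalysis` for a sentence."""

    def analyze(self, sentence: Sentence, mention_token: int) -> DependencyAnalysis:
        ...  # pragma: no cover


_FUNCTION_WORDS = frozenset(
    """a an the this that these those of in on at by for with without to from
    and or but not no nor as is are was were be been being have has had must
    may might will would shall should can could do does did if then than such
    any all each per via who whom whose which what when where while""".split()
)
_WORD_RE = re.compile(r"^[A-Za-z][A-Za-z0-9'-]*$")


def _looks_nominal(token: Token) -> bool:
    text = token.text
    return bool(_WORD_RE.match(text)) and text.lower() not in _FUNCTION_WORDS


def _heuristic_pos(word: str) -> str:
    lower = word.lower()
    if lower.endswith("ed"):
        return "VBD"
    if lower.endswith("ing"):
        return "VBG"
    if lower.endswith("s") and not lower.endswith("ss"):
        return "NNS"
    return "NN"


class HeuristicDependencyProvider:
    """Deterministic offline approximation of a dependency parse.

    Two patterns cover the constructions that matter for lesion-status cues:
    the mention's noun-phrase head ("... MET mutations" gives an
    ``amod``-like link from "mutations" to the mention), and a governor
    reached across an ``of``/``with``/``for`` preposition ("staining for
    Kit" links "staining" to the mention when the mention heads its own
    noun phrase). A real parser can be plugged in via
    the :class:`DependencyProvider` protocol for higher fidelity.
    """

    PREPOSITIONS = ("of", "with", "for")

    def analyze(self, sentence: Sentence, mention_token: int) -> DependencyAnalysis:
        tokens = sentence.tokens
        n = len(tokens)
        if not (0 <= mention_token < n):
            raise ValueError("mention token index outside sentence")
        edges: list[tuple[int, int, str]] = []
        pos: dict[int, str] = {}

        # contiguous nominal run containing the mention
        start = mention_token
        while start > 0 and _looks_nominal(tokens[start - 1]):
            start -= 1
        end = mention_token
        while end + 1 < n and _looks_nominal(tokens[end + 1]):
            end += 1
        head = end  # rightmost token of the nominal run
        if head != mention_token:
            edges.append((head, mention_token, "amod"))
            pos[head] = _heuristic_pos(tokens[head].text)

        # governor across a preposition immediately left of the run; it
        # attaches to the run head (a dependent keeps a single head), so it
        # reaches the mention only when the mention heads its own run
        if start >= 2 and tokens[start - 1].text.lower() in self.PREPOSITIONS:
            gov = start - 2
            if _WORD_RE.match(tokens[gov].text) and tokens[gov].text.lower() not in _FUNCTION_WORDS:
                prep = tokens[start - 1].text.lower()
                edges.append((gov, head, f"prep_{prep}"))
                pos[gov] = _heuristic_pos(tokens[gov].text)

        analysis = DependencyAnalysis(pos_tags=pos, edges=edges)
        analysis.validate_indices(n)
        return analysis


# ---------------------------------------------------------------------------
# Family extractors
# ---------------------------------------------------------------------------

def _mention_positions(mention: "GeneMention") -> range:
    return range(mention.token_index, mention.token_index + mention.n_tokens)


_ORTH_CHECKS = (
    ("allcaps", lambda t: t.isupper() and any(c.isalpha() for c in t)),
    ("hasdigit", lambda t: any(c.isdigit() for c in t)),
    ("initcap", lambda t: t[:1].isupper() and not t.isupper()),
    ("special", lambda t: any(not c.isalnum() for c in t)),
)


def _orth_features(token_text: str, position: str) -> FeatureVector:
    return {
        f"orth:{name}|{position}": 1.0
        for name, check in _ORTH_CHECKS
        if check(token_text)
    }


def extract_context_features(
    mention: "GeneMention", sentences: Sequence[Sentence], config: FeatureConfig
) -> FeatureVector:
    """Windowed lexical, positional and orthographic context features.

    For each non-mention token within ``context_window`` positions on either
    side (same sentence, truncated at its boundaries) a bag feature
    ``ctx:word=w`` and a positional feature ``ctx:pos=w|direction|distance``
    are emitted. Orthographic indicators cover the mention token itself and
    its immediate left/right neighbors.
    """
    sentence = sentences[mention.sentence_index]
    tokens = sentence.tokens
    positions = _mention_positions(mention)
    feats: FeatureVector = {}

    def norm(word: str) -> str:
        return word.lower() if config.lowercase_lexical else word

    left_anchor, right_anchor = positions[0], positions[-1]
    for dist in range(1, config.context_window + 1):
        for direction, idx in (("L", left_anchor - dist), ("R", right_anchor + dist)):
            if 0 <= idx < len(tokens):
                w = norm(tokens[idx].text)
                feats[f"ctx:word={w}"] = 1.0
                feats[f"ctx:pos={w}|{direction}|{dist}"] = 1.0

    feats.update(_orth_features(tokens[left_anchor].text, "self"))
    if left_anchor - 1 >= 0:
        feats.update(_orth_features(tokens[left_anchor - 1].text, "L1"))
    if right_anchor + 1 < len(tokens):
        feats.update(_orth_features(tokens[right_anchor + 1].text, "R1"))
    return feats


def extract_dependency_features(
    mention: "GeneMention", analysis: DependencyAnalysis,
    sentence: Sentence, lowercase: bool = True,
) -> FeatureVector:
    """Word / POS / relation features for tokens one edge away from the mention."""
    feats: FeatureVector = {}
    m = mention.token_index
    for head, dep, rel in analysis.edges:
        if m == head:
            other = dep
        elif m == dep:
            other = head
        else:
            continue
        word = sentence.tokens[other].text
        feats[f"dep:word={word.lower() if lowercase else word}"] = 1.0
        feats[f"dep:rel={rel}"] = 1.0
        tag = analysis.pos_tags.get(other)
        if tag is not None:
            feats[f"dep:pos={tag}"] = 1.0
    return feats


def extract_negation_feature(
    mention: "GeneMention", sentences: Sequence[Sentence],
    neg: NegationLexicon, config: FeatureConfig,
) -> FeatureVector:
    """Binary ``neg:present`` when a negation word sits within the window."""
    sentence = sentences[mention.sentence_index]
    tokens = sentence.tokens
    positions = _mention_positions(mention)
    for dist in range(1, config.negation_window + 1):
        for idx in (positions[0] - dist, positions[-1] + dist):
            if 0 <= idx < len(tokens) and tokens[idx].text.lower() in neg.words:
                return {"neg:present": 1.0}
    return {}


def extract_section_feature(mention: "GeneMention") -> FeatureVector:
    """Exactly one ``sec:<name>`` indicator."""
    return {f"sec:{mention.section_name}": 1.0}


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureExtractor:
    """Assembles per-family partial vectors into one sparse vector.

    ``dependency_provider`` defaults to the offline heuristic; pass
    ``allow_fallback=False`` with no provider to make enabling the
    dependency family a configuration error instead.
    """

    config: FeatureConfig = field(default_factory=FeatureConfig)
    dependency_provider: Optional[DependencyProvider] = None
    negation_lexicon: Optional[NegationLexicon] = None
    allow_fallback: bool = True

    def __post_init__(self) -> None:
        if "dependency" in self.config.enabled_families and self.dependency_provider is None:
            if not self.allow_fallback:
                raise ConfigurationError(
                    "dependency family enabled but no provider configured "
                    "and fallback disabled"
                )
            self.dependency_provider = HeuristicDependencyProvider()
        if "negation" in self.config.enabled_families and self.negation_lexicon is None:
            self.negation_lexicon = NegationLexicon.default()

    def extract(self, mention: "GeneMention", sentences: Sequence[Sentence]) -> FeatureVector:
        cfg = self.config
        feats: FeatureVector = {}
        if "context" in cfg.enabled_families:
            feats.update(extract_context_features(mention, sentences, cfg))
        if "dependency" in cfg.enabled_families:
            sentence = sentences[mention.sentence_index]
            analysis = self.dependency_provider.analyze(sentence, mention.token_index)
            feats.update(extract_dependency_features(mention, analysis, sentence,
                                                     lowercase=cfg.lowercase_lexical))
        if "negation" in cfg.enabled_families:
            feats.update(extract_negation_feature(mention, sentences,
                                                  self.negation_lexicon, cfg))
        if "section" in cfg.enabled_families:
            feats.update(extract_section_feature(mention))
        return feats


def build_feature_vector(
    mention: "GeneMention",
    sentences: Sequence[Sentence],
    config: Optional[FeatureConfig] = None,
    dependency_provider: Optional[DependencyProvider] = None,
    negation_lexicon: Optional[NegationLexicon] = None,
    allow_fallback: bool = True,
) -> FeatureVector:
    """Convenience wrapper: extract the union of all enabled families."""
    extractor = FeatureExtractor(
        config=config or FeatureConfig(),
        dependency_provider=dependency_provider,
        negation_lexicon=negation_lexicon,
        allow_fallback=allow_fallback,
    )
    return extractor.extract(mention, sentences)


def featurize_instances(
    documents: Sequence,
    instances: Sequence,
    extractor: Optional[FeatureExtractor] = None,
) -> list[tuple[FeatureVector, object]]:
    """Extract ``(vector, label)`` pairs for labeled instances in context.

    ``documents`` supply the section text each mention points into; sections
    are tokenized once and cached across instances.
    """
    extractor = extractor or FeatureExtractor()
    docs = {d.trial_id: d for d in documents}
    cache: dict[tuple[str, str], list[Sentence]] = {}
    out = []
    for inst in instances:
        m = inst.mention
        key = (m.trial_id, m.section_name)
        if key not in cache:
            text = docs[m.trial_id].section_text(m.section_name)
            if text is None:
                raise ValueError(
                    f"trial {m.trial_id} has no {m.section_name!r} section")
            cache[key] = tokenize_and_split(text, section=m.section_name)
        out.append((extractor.extract(m, cache[key]), inst.label))
    return out


def restrict_to_families(vector: FeatureVector, families: frozenset[str]) -> FeatureVector:
    """Keep only the features whose namespace belongs to ``families``.

    Because every feature name is namespaced by its family, a vector
    extracted with all families enabled can be restricted after the fact;
    grid search over family subsets relies on this.
    """
    prefixes = tuple(p for fam in families for p in FAMILY_PREFIXES[fam])
    return {k: v for k, v in vector.items() if k.startswith(prefixes)}


# ---------------------------------------------------------------------------
# Sparse instance serialization (LIBSVM-style dialect with a name map)
# ---------------------------------------------------------------------------

def write_sparse_instances(
    items: Sequence[tuple[str, str, FeatureVector]],
    path: str | Path, map_path: str | Path,
) -> None:
    """Write ``(label, mention_id, vector)`` triples as sparse text lines.

    Each line reads ``label qid:<mention-id> <idx>:<value> ...`` with feature
    indices resolved through a name-to-index map written to ``map_path``.
    """
    name_to_idx: dict[str, int] = {}
    lines = []
    for label, mention_id, vec in items:
        idxs = []
        for name in sorted(vec):
            if name not in name_to_idx:
                name_to_idx[name] = len(name_to_idx) + 1
            idxs.append((name_to_idx[name], vec[name]))
        body = " ".join(f"{i}:{v:g}" for i, v in sorted(idxs))
        lines.append(f"{label} qid:{mention_id} {body}".rstrip())
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    Path(map_path).write_text(
        "\n".join(f"{i}\t{n}" for n, i in sorted(name_to_idx.items(), key=lambda kv: kv[1]))
        + ("\n" if name_to_idx else ""),
        encoding="utf-8",
    )


def read_sparse_instances(
    path: str | Path, map_path: str | Path
) -> list[tuple[str, str, FeatureVector]]:
    idx_to_name = {}
    for line in Path(map_path).read_text(encoding="utf-8").splitlines():
        if line.strip():
            i, name = line.split("\t", 1)
            idx_to_name[int(i)] = name
    items = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        parts = line.split(" ")
        label = parts[0]
        mention_id = parts[1].split(":", 1)[1]
        vec = {}
        for chunk in parts[2:]:
            i, v = chunk.split(":")
            vec[idx_to_name[int(i)]] = float(v)
        items.append((label, mention_id, vec))
    return items
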
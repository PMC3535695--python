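"""Locating gene-lexicon terms in trial documents.

Mention detection is plain dictionary matching — the deliberate baseline
whose false positives ("criteria are met", "EGFR inhibitor") the downstream
classifier exists to resolve. Matching is whole-token and, by default,
case-insensitive, since the central ambiguity (MET vs "met", KIT vs "kit")
only arises when case is folded.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .corpus_io import GeneLexiconEntry, TrialDocument
from .feature_extraction import tokenize_and_split

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneMention:
    """One occurrence of a lexicon term in a document section.

    ``char_span`` is 0-based half-open into the section's NFC text;
    ``token_index`` addresses the first token of the match within sentence
    ``sentence_index``; ``n_tokens`` is the match length in tokens.
    """

    trial_id: str
    gene_symbol: str
    matched_text: str
    section_name: str
    char_span: tuple[int, int]
    sentence_index: int
    token_index: int
    n_tokens: int = 1


@dataclass(frozen=True)
class MatchPolicy:
    case_sensitive: bool = False


def _term_tokens(term: str, case_sensitive: bool) -> tuple[str, ...]:
    sentences = tokenize_and_split(term)
    tokens = [t.text for s in sentences for t in s.tokens]
    if not case_sensitive:
        tokens = [t.casefold() for t in tokens]
    return tuple(tokens)


def _build_term_index(
    lexicon: Sequence[GeneLexiconEntry], policy: MatchPolicy
) -> dict[str, list[tuple[tuple[str, ...], str]]]:
    """Map first match-token -> [(token tuple, symbol)], longest first."""
    index: dict[str, list[tuple[tuple[str, ...], str]]] = defaultdict(list)
    for entry in lexicon:
        for term in entry.match_terms:
            toks = _term_tokens(term, policy.case_sensitive)
            if toks:
                index[toks[0]].append((toks, entry.symbol))
    for candidates in index.values():
        # longest match first; among equal lengths the lexicographically
        # smaller canonical symbol wins (with a logged collision warning)
        candidates.sort(key=lambda c: (-len(c[0]), c[1]))
    return index


def find_mentions(
    doc: TrialDocument,
    lexicon: Sequence[GeneLexiconEntry],
    policy: MatchPolicy = MatchPolicy(),
) -> list[GeneMention]:
    """Return every whole-token occurrence of any lexicon match term.

    Matches are contiguous token sequences within one sentence, ordered by
    (section order, character offset). Overlaps resolve longest-match-first;
    matched tokens are consumed so matches never overlap each other.
    """
    index = _build_term_index(lexicon, policy)
    mentions: list[GeneMention] = []
    for section_name, text in doc.sections:
        sentences = tokenize_and_split(text, section=section_name)
        for s_idx, sentence in enumerate(sentences):
            toks = sentence.tokens
            keys = [t.text if policy.case_sensitive else t.text.casefold() for t in toks]
            i = 0
            while i < len(toks):
                candidates = index.get(keys[i], ())
                matched = None
                for term_toks, symbol in candidates:
                    L = len(term_toks)
                    if i + L <= len(toks) and tuple(keys[i:i + L]) == term_toks:
                        if matched is not None and len(matched[0]) == L:
                            logger.warning(
                                "term collision at %s/%s offset %d: %s vs %s",
                                doc.trial_id, section_name, toks[i].span[0],
                                matched[1], symbol,
                            )
                            continue
                        if matched is None:
                            matched = (term_toks, symbol)
                        # candidates are sorted longest-first, so the first
                        # hit is the longest; keep scanning only to log
                        # equal-length collisions
                        elif len(matched[0]) > L:
                            break
                if matched is not None:
                    L = len(matched[0])
                    start = toks[i].span[0]
                    end = toks[i + L - 1].span[1]
                    mentions.append(GeneMention(
                        trial_id=doc.trial_id,
                        gene_symbol=matched[1],
                        matched_text=text[start:end],
                        section_name=section_name,
                        char_span=(start, end),
                        sentence_index=s_idx,
                        token_index=i,
                        n_tokens=L,
                    ))
                    i += L
                else:
                    i += 1
    return mentions


def rank_genes_by_frequency(
    trials: Sequence[TrialDocument],
    lexicon: Sequence[GeneLexiconEntry],
    policy: MatchPolicy = MatchPolicy(),
) -> list[tuple[str, int, int]]:
    """Rank genes by total occurrence count across a corpus.

    Returns ``(symbol, occurrence_count, trial_count)`` sorted by occurrence
    count descending, ties broken alphabetically by symbol.
    """
    occ: dict[str, int] = defaultdict(int)
    trial_sets: dict[str, set[str]] = defaultdict(set)
    for doc in trials:
        for m in find_mentions(doc, lexicon, policy):
            occ[m.gene_symbol] += 1
            trial_sets[m.gene_symbol].add(doc.trial_id)
    return sorted(
        ((sym, n, len(trial_sets[sym])) for sym, n in occ.items()),
        key=lambda row: (-row[1], row[0]),
    )


def sample_occurrences(
    mentions: Sequence[GeneMention], cap: int, seed: int
) -> list[GeneMention]:
    """Uniform random subset of at most ``cap`` mentions, order-preserving.

    Emulates capped per-gene sampling for annotation: when a gene has more
    occurrences than the cap, a seeded uniform draw without replacement keeps
    exactly ``cap`` of them in their original corpus order.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if len(mentions) <= cap:
        return list(mentions)
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(mentions), size=cap, replace=False))
    return [mentions[i] for i in keep]
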
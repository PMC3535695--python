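"""Seeded synthetic trial corpora with gold lesion-status labels.

The generator emulates the statistical shape of an expert-annotated
clinical-trial corpus so every training and evaluation path can run
offline: sectioned documents (title / summary / eligibility) containing one
gene mention each, with the surrounding sentence carrying the category's
characteristic cue phrasing ("positive ... mutation test", "wild type ...",
"... inhibitor", or the symbol used as a lowercase English word), per-gene
category skew configurable per gene, an optional uniform label-noise rate
that decouples cue from label, and filler sentences containing no lexicon
term. Three presets ship with the package:

* ``top8_skewed`` — eight heavily mentioned cancer genes (ALK, BRAF, EGFR,
  KIT, KRAS, MET, PTEN, WT1) with the strongly skewed per-gene category
  frequencies characteristic of real trial text (e.g. the MET row is
  dominated by the English-word sense, EGFR by the drug sense);
* ``homograph_stress`` — one gene with a dominant English-homograph sense
  that no other gene shares, for generalization experiments;
* ``balanced`` — uniform category mix, for calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .categories import StatusCategory, enabled_categories
from .corpus_io import GeneLexiconEntry, LabeledInstance, TrialDocument
from .feature_extraction import tokenize_and_split
from .mention_detection import GeneMention

_PROB_TOL = 1e-9

#: Filler vocabulary guaranteed to contain no lexicon term of the presets.
_FILLER_SENTENCES = (
    "Patients aged eighteen years or older may enroll .",
    "Adequate organ function is required at baseline .",
    "Informed consent must be obtained before any study procedure .",
    "Prior radiotherapy completed at least four weeks before entry .",
    "Eastern performance status of zero or one is required .",
)


@dataclass(frozen=True)
class GeneSpec:
    """One gene's slice of a synthetic corpus."""

    symbol: str
    synonyms: tuple[str, ...] = ()
    homograph: bool = False
    n_instances: int = 100
    category_probs: dict[StatusCategory, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_instances < 0:
            raise ValueError("n_instances must be >= 0")
        total = sum(self.category_probs.values())
        if abs(total - 1.0) > _PROB_TOL:
            raise ValueError(
                f"category probabilities for {self.symbol} sum to {total}, not 1")


@dataclass(frozen=True)
class CorpusSpec:
    """Full recipe for a synthetic corpus draw."""

    genes: tuple[GeneSpec, ...]
    noise_rate: float = 0.0
    distractor_rate: float = 0.3
    seed: int = 0
    include_detected_or_not: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise_rate < 0.5):
            raise ValueError("noise_rate must be in [0, 0.5)")
        if not (0.0 <= self.distractor_rate <= 1.0):
            raise ValueError("distractor_rate must be in [0, 1]")

    @property
    def categories(self) -> tuple[StatusCategory, ...]:
        return enabled_categories(self.include_detected_or_not)


@dataclass(frozen=True)
class Template:
    template: str
    section: str


@dataclass
class TemplateBank:
    """Per-category cue-sentence templates with a gene slot.

    ``{GENE}`` inserts the surface form as-is; ``{gene}`` lowercases it
    (the English-homograph reading). Shipped templates use characteristic
    eligibility-criteria phrasings plus neutral filler.
    """

    templates: dict[StatusCategory, list[Template]]

    def validate(self, categories: Sequence[StatusCategory]) -> None:
        from .feature_extraction import NegationLexicon

        neg_words = NegationLexicon.default().words
        for cat in categories:
            entries = self.templates.get(cat, [])
            if len(entries) < 2:
                raise ValueError(f"need >= 2 templates for category {cat.name}")
            for t in entries:
                if "{GENE}" not in t.template and "{gene}" not in t.template:
                    raise ValueError(f"template lacks a gene slot: {t.template!r}")
                if cat is StatusCategory.GENETIC_LESION_NOT_DETECTED:
                    words = {w.lower() for w in t.template.split()}
                    if not words & neg_words:
                        raise ValueError(
                            f"not-detected template lacks a negation word: {t.template!r}")
                if cat is StatusCategory.OTHERS and "{gene}" not in t.template:
                    raise ValueError(
                        f"others template must use the lowercase slot: {t.template!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "TemplateBank":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        templates = {
            StatusCategory[name]: [Template(**t) for t in entries]
            for name, entries in raw.items()
        }
        return cls(templates=templates)

    @classmethod
    def default(cls) -> "TemplateBank":
        ref = resources.files("genestatus.data") / "templates.json"
        with resources.as_file(ref) as path:
            return cls.from_file(path)


@dataclass
class GeneratedCorpus:
    """Documents, gold instances, and the generation manifest."""

    documents: list[TrialDocument]
    instances: list[LabeledInstance]
    manifest: dict

    def lexicon(self) -> list[GeneLexiconEntry]:
        return [
            GeneLexiconEntry(symbol=g["symbol"], synonyms=frozenset(g["synonyms"]),
                             is_cancer_gene=True)
            for g in self.manifest["genes"]
        ]


def lexicon_for_spec(spec: CorpusSpec) -> list[GeneLexiconEntry]:
    return [
        GeneLexiconEntry(symbol=g.symbol, synonyms=frozenset(g.synonyms),
                         is_cancer_gene=True)
        for g in spec.genes
    ]


def expected_counts(spec: CorpusSpec) -> dict[str, dict[StatusCategory, int]]:
    """Per-gene expected category counts (probability times instance count)."""
    return {
        g.symbol: {c: round(p * g.n_instances) for c, p in g.category_probs.items()}
        for g in spec.genes
    }


def _choose_surface(gene: GeneSpec, category: StatusCategory,
                    rng: np.random.Generator) -> str:
    if category is StatusCategory.OTHERS:
        return gene.symbol.lower()
    if gene.synonyms and rng.random() < 0.2:
        return str(gene.synonyms[int(rng.integers(len(gene.synonyms)))])
    return gene.symbol


def generate_corpus(spec: CorpusSpec,
                    bank: Optional[TemplateBank] = None) -> GeneratedCorpus:
    """Draw a corpus: one trial document per instance, deterministic per seed.

    Per gene, category counts follow a multinomial draw over the configured
    distribution (the realized draw is recorded in the manifest). Each
    instance's document carries the cue sentence in the template's section,
    optionally surrounded by filler sentences that contain no lexicon term.
    With probability ``noise_rate`` the gold label is replaced by a uniform
    different category while the text keeps the original cue, so noise
    decouples cue from label. Every gold mention is re-discoverable by
    dictionary matching over the spec's lexicon.
    """
    bank = bank or TemplateBank.default()
    categories = spec.categories
    bank.validate(categories)
    rng = np.random.default_rng(spec.seed)

    documents: list[TrialDocument] = []
    instances: list[LabeledInstance] = []
    drawn_counts: dict[str, dict[str, int]] = {}
    noise_count = 0
    trial_no = 0

    for gene in spec.genes:
        probs = np.array([gene.category_probs.get(c, 0.0) for c in categories])
        counts = rng.multinomial(gene.n_instances, probs / probs.sum())
        drawn_counts[gene.symbol] = {
            c.name: int(n) for c, n in zip(categories, counts) if n > 0
        }
        cat_sequence = [c for c, n in zip(categories, counts) for _ in range(n)]
        rng.shuffle(cat_sequence)  # interleave categories across trial ids
        for true_cat in cat_sequence:
            options = bank.templates[true_cat]
            tpl = options[int(rng.integers(len(options)))]
            surface = _choose_surface(gene, true_cat, rng)
            if "{gene}" in tpl.template:
                prefix, _, suffix = tpl.template.partition("{gene}")
                surface = surface.lower()
            else:
                prefix, _, suffix = tpl.template.partition("{GENE}")
            sentence = prefix + surface + suffix

            lead = (_FILLER_SENTENCES[int(rng.integers(len(_FILLER_SENTENCES)))] + "\n"
                    if rng.random() < spec.distractor_rate else "")
            tail = ("\n" + _FILLER_SENTENCES[int(rng.integers(len(_FILLER_SENTENCES)))]
                    if rng.random() < spec.distractor_rate else "")
            section_text = lead + sentence + tail
            start = len(lead) + len(prefix)
            span = (start, start + len(surface))

            trial_no += 1
            trial_id = f"SYN-{trial_no:05d}"
            sections = [(tpl.section, section_text)]
            if tpl.section != "title":
                sections.insert(0, ("title", "A phase II study of targeted therapy ."))
            doc = TrialDocument(trial_id=trial_id, status="active", sections=sections)
            documents.append(doc)

            sentences = tokenize_and_split(section_text)
            sent_idx = tok_idx = None
            n_tokens = 0
            for si, sent in enumerate(sentences):
                for ti, tok in enumerate(sent.tokens):
                    if tok.span[0] == span[0]:
                        sent_idx, tok_idx = si, ti
                    if span[0] <= tok.span[0] and tok.span[1] <= span[1]:
                        n_tokens += 1
            assert sent_idx is not None, "surface must align to a token boundary"

            label = true_cat
            if spec.noise_rate > 0 and rng.random() < spec.noise_rate:
                others = [c for c in categories if c is not true_cat]
                label = others[int(rng.integers(len(others)))]
                noise_count += 1

            mention = GeneMention(
                trial_id=trial_id,
                gene_symbol=gene.symbol,
                matched_text=surface,
                section_name=tpl.section,
                char_span=span,
                sentence_index=sent_idx,
                token_index=tok_idx,
                n_tokens=n_tokens,
            )
            instances.append(LabeledInstance(mention=mention, label=label))

    manifest = {
        "seed": spec.seed,
        "noise_rate": spec.noise_rate,
        "distractor_rate": spec.distractor_rate,
        "include_detected_or_not": spec.include_detected_or_not,
        "genes": [
            {"symbol": g.symbol, "synonyms": sorted(g.synonyms),
             "homograph": g.homograph, "n_instances": g.n_instances}
            for g in spec.genes
        ],
        "drawn_counts": drawn_counts,
        "n_instances": len(instances),
        "n_noisy_labels": noise_count,
    }
    return GeneratedCorpus(documents=documents, instances=instances, manifest=manifest)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

# Per-gene category counts for the top eight cancer genes, in the order
# (others, drug, detected, not_detected, mentioned, gene_only).
TOP8_COUNTS: dict[str, tuple[int, int, int, int, int, int]] = {
    "ALK": (32, 10, 41, 15, 4, 0),
    "BRAF": (0, 32, 63, 13, 21, 1),
    "EGFR": (4, 117, 37, 5, 26, 11),
    "KIT": (5, 26, 82, 12, 16, 4),
    "KRAS": (2, 0, 65, 95, 38, 0),
    "MET": (147, 28, 16, 0, 5, 4),
    "PTEN": (4, 2, 41, 1, 19, 2),
    "WT1": (0, 53, 32, 0, 9, 3),
}

_TOP8_SYNONYMS: dict[str, tuple[str, ...]] = {
    "ALK": ("CD246",),
    "BRAF": ("B-RAF",),
    "EGFR": ("ERBB1", "HER1"),
    "KIT": ("c-kit", "CD117"),
    "KRAS": ("KRAS2",),
    "MET": ("c-met",),
    "PTEN": ("MMAC1",),
    "WT1": ("WT33",),
}

_COUNT_ORDER = (
    StatusCategory.OTHERS,
    StatusCategory.DRUG,
    StatusCategory.GENETIC_LESION_DETECTED,
    StatusCategory.GENETIC_LESION_NOT_DETECTED,
    StatusCategory.GENETIC_LESION_MENTIONED,
    StatusCategory.GENE_ONLY,
)


def _probs_from_counts(counts: Sequence[int]) -> dict[StatusCategory, float]:
    total = sum(counts)
    return {c: n / total for c, n in zip(_COUNT_ORDER, counts)}


def make_preset_spec(preset: str, seed: int = 0,
                        noise_rate: float = 0.0) -> CorpusSpec:
    """Build a :class:`CorpusSpec` for one of the shipped presets."""
    if preset == "top8_skewed":
        genes = tuple(
            GeneSpec(
                symbol=sym,
                synonyms=_TOP8_SYNONYMS[sym],
                homograph=sym in ("MET", "KIT"),
                n_instances=sum(counts),
                category_probs=_probs_from_counts(counts),
            )
            for sym, counts in TOP8_COUNTS.items()
        )
    elif preset == "homograph_stress":
        # one gene with a dominant exclusive English-word sense; the others
        # never realize OTHERS, so a model trained without the homograph
        # gene has never seen that sense
        homograph_probs = _probs_from_counts((90, 6, 12, 6, 4, 2))
        plain_probs = _probs_from_counts((0, 20, 50, 30, 15, 5))
        genes = tuple(
            GeneSpec(symbol=sym, synonyms=_TOP8_SYNONYMS.get(sym, ()),
                     homograph=sym == "MET", n_instances=120,
                     category_probs=homograph_probs if sym == "MET" else plain_probs)
            for sym in ("BRAF", "EGFR", "KRAS", "MET")
        )
    elif preset == "balanced":
        uniform = {c: 1 / 6 for c in _COUNT_ORDER}
        genes = tuple(
            GeneSpec(symbol=sym, synonyms=_TOP8_SYNONYMS[sym],
                     homograph=sym in ("MET", "KIT"), n_instances=60,
                     category_probs=uniform)
            for sym in TOP8_COUNTS
        )
    else:
        raise ValueError(f"unknown preset {preset!r}")
    return CorpusSpec(genes=genes, seed=seed, noise_rate=noise_rate)
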
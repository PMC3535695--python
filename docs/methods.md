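# Methods

This note documents what `genestatus` computes, the parameter defaults and
their rationale, what the synthetic corpus generator does and does not
emulate, and the numerical conventions (tie-breaking, degenerate inputs)
that determine exact outputs.

## 1. Task and representation

The unit of prediction is a **gene mention**: a whole-token match of a
lexicon term (canonical symbol or synonym) inside one section of a trial
document. Documents are plain sectioned text with section names drawn from
`title` / `summary` / `eligibility` and a trial status of `active` or
`closed`. Text is normalized to Unicode NFC; character spans are 0-based
half-open offsets into the section string.

Each mention is labeled with one of six categories (optionally seven):

| Category | Meaning |
|---|---|
| Genetic lesion detected | the lesion's presence is asserted |
| Genetic lesion not detected | absence asserted (incl. "wild-type") |
| Genetic lesion mentioned | lesion discussed, status unstated |
| Gene only | gene named, no lesion discussed |
| Drug | symbol is part of a drug/agent name |
| Others | non-gene sense (English homograph etc.) |
| Detected or not detected (optional) | status will be determined either way |

The first four (plus the optional seventh) coarsen to **Gene-related**;
Drug and Others coarsen to themselves. Categories carry a fixed ordinal
used wherever a deterministic order over labels is needed.

## 2. Mention detection

Dictionary matching is case-insensitive by default (`MatchPolicy`),
operates on whole tokens only, and is longest-match-first: at each token
position candidate terms are tried by decreasing token length, and matched
tokens are consumed so overlapping shorter matches are suppressed. When two
different genes share an equally long term at the same position, the
lexicographically smaller symbol wins and a warning is logged; the corpus
reader also warns on cross-gene synonym collisions at load time.
Case-insensitivity is a recall-first choice: homograph false positives are
deliberately passed through to the classifier, whose Others/Drug categories
exist to absorb them.

## 3. Features

Tokenization: maximal runs of `[A-Za-z0-9]` joined by internal hyphens or
apostrophes, every other non-space character a single token; sentences
split on `.`, `!`, `?`, and newlines; leading bullet characters dropped.

Four families, each namespaced by feature-name prefix
(`ctx:`/`orth:`, `dep:`, `neg:`, `sec:`). All features are binary.

- **Context window** (default ±6 tokens): bag features `ctx:word=w`
  (lowercased) and positional features `ctx:pos=w|L/R|d` with side and
  distance. Six per side covers the short eligibility clauses that carry
  the cue ("no evidence of X mutation") without pulling in neighboring
  criteria; it is a package default, not a tuned constant.
- **Orthography** (emitted with the context family): all-caps, has-digit,
  initial-cap, and has-special-character indicators for the mention itself
  and its immediate left/right neighbors. Orthography rides with context
  because both describe the local surface; keeping them under one family
  keeps the grid-search space small (2⁴ family subsets, not 2⁵).
- **Dependency**: word, relation, and coarse POS of the mention's governor.
  The parser is a `DependencyProvider` protocol; the shipped
  `HeuristicDependencyProvider` is an offline stand-in that attaches a
  nominal run to its head noun (`amod`) and bridges *of/with/for*
  prepositions (`prep_of` etc.). It is deliberately shallow — enough to
  exercise the feature family and the protocol; substitute a real parser
  for production use. If the dependency family is enabled with no provider,
  the extractor falls back to the heuristic (or raises, with
  `allow_fallback=False`).
- **Negation** (window 3): single indicator `neg:present` when a word from
  the negation lexicon (`data/negation_words.txt`: *no, not, without,
  negative, absence, wild-type, exclude(d), ineligible, …*) occurs within
  3 tokens of the mention. The tight window keeps "not eligible unless X
  mutation detected" from flipping distant mentions.
- **Section**: `sec:<name>`. Eligibility sections state requirements;
  titles name the study topic — the same words mean different things by
  section.

Family restriction (`restrict_to_families`) is a key-prefix filter, so grid
search over family subsets reuses one full extraction pass.

## 4. Classifiers

Both arrangements use scikit-learn's `SVC` (libsvm; one-vs-one for
multi-class) over a `DictVectorizer` vocabulary frozen at training time —
unseen test-time features are dropped. Defaults: linear kernel, C = 1,
`gamma="scale"` for RBF. Sparse matrices are converted to 32-bit-index CSR
(a libsvm requirement). Labels are encoded by their category ordinal, so
any internal tie-breaking in one-vs-one voting resolves by the fixed
category order rather than by insertion order.

- **Single-stage**: one SVM over all enabled categories.
- **Cascade**: stage 1 is trained on all instances with coarsened labels
  (Gene-related / Drug / Others); stage 2 is trained only on instances
  whose *gold* label is gene-related (not on stage-1 predictions, so
  stage-2 training data is clean and the two stages can be debugged
  independently). At prediction, Drug/Others short-circuit; Gene-related
  goes to stage 2. Training raises `DegenerateTrainingError` when a stage
  would see fewer than two distinct labels.

Models persist as a directory: `manifest.json` (format version, kernel,
C, seed, feature configuration) plus joblib files per stage.

## 5. Evaluation designs

- **Pooled stratified k-fold CV**: per-category shuffled round-robin
  dealing with a carry-over cursor, so category remainders spread across
  folds instead of piling onto fold 0. Predictions from all held-out folds
  are pooled before computing the report; per-fold accuracies are also
  retained.
- **Grid search**: feature-family subsets × kernel/C grid, selected by mean
  per-fold accuracy. Ties prefer fewer families, then smaller C (simpler
  models). Returns the full results table (pandas) alongside the winner.
- **Leave-one-gene-out**: train on all other genes' instances, test on the
  held-out gene; reports per-gene plus the unweighted macro average. This
  is the gene-neutral design; the pooled CV is the gene-specific one.
- **Iterative retraining**: at iteration *i*, the model trained on the
  initial pool plus batches 1..*i*−1 is scored on batch *i* (whose labels
  play the corrected gold standard), then batch *i* joins the pool.
  Categories first appearing in a batch become predictable from the next
  iteration on. Empty batches are skipped with a flag.

### Metrics

Accuracy; per-category precision/recall/F1 with F = 2PR/(P+R); macro
averages; Cohen's kappa κ = (p_o − p_e)/(1 − p_e). Conventions for
degenerate inputs: a category never predicted has precision 0 with a
`precision_defined=False` flag (recall analogous); F is 0 when P + R = 0;
κ with p_e = 1 (both annotators constant) is 1.0 when the labelings are
identical, else 0. Kappa is unit-tested against a brute-force oracle to
1e−12 over randomized inputs.

## 6. Synthetic corpus generator

Each `GeneSpec` fixes a gene's symbol, synonyms, homograph flag, instance
count, and a category distribution; category counts are drawn per gene from
a seeded multinomial (`numpy.random.default_rng`) and recorded in the
corpus manifest. Every instance becomes one single-trial document: a cue
sentence instantiated from a per-category template bank (validated to hold
≥2 templates per category, with negation cues inside the negation window
for "not detected" and lowercase surfaces for Others), optionally framed by
distractor filler sentences. The surface form is the symbol, a synonym
(20%), or the lowercased symbol for Others. Label noise `noise_rate ∈
[0, 0.5)` replaces the recorded label with a uniformly random different
category *after* the text is generated, decoupling cue from label — noisy
corpora therefore bound attainable accuracy at ≈ 1 − noise_rate.

Presets:

- `top8_skewed` — eight genes, 1,143 instances, per-gene category counts
  with realistic skew (e.g. MET dominated by Others — the homograph — and
  EGFR/KRAS by detected/not-detected); `expected_counts` reproduces the
  preset's integer table exactly via `round(p·n)`.
- `homograph_stress` — four genes; one (MET) has a dominant English-word
  sense that no other gene realizes, so leave-one-gene-out on it isolates
  the homograph failure mode.
- `balanced` — uniform sixth per category, for tests that need every
  category populated.

What the generator does **not** emulate: real registry formatting and
section length, inter-annotator disagreement structure, discourse-level
cues spanning sentences, gene–drug name morphology beyond fixed templates,
and realistic vocabulary breadth. It is built to make pipeline behavior
(separability, skew, homography, noise ceilings) testable offline, not to
train deployable models.

## 7. Reproducibility conventions

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); no global state. File formats are text-only:
`%%`-separated sectioned trials (with `\`-escaping) or minimal XML,
TSV lexicons, JSON-lines annotations, LIBSVM-style sparse vectors with a
name→index map. Every CLI output directory gets a `manifest.json`
recording command, seed, and configuration. Corpus sizes in tests and
scripts (1,143 instances; batches 759/585/792/1053/842) are package
choices made so the shipped experiments complete in seconds.

## 8. Known limitations and open decisions

- The heuristic dependency provider is a placeholder; `dep:` features only
  become linguistically meaningful with a real parser behind the protocol.
- Window sizes (6 context, 3 negation) are defaults with qualitative
  rationale, not validated optima; the grid search varies families and SVM
  parameters, not window sizes.
- Stage 2 trains on gold gene-related instances, so cascade test-time error
  compounds stage-1 mistakes that training never sees; training stage 2 on
  stage-1 *predictions* is a plausible alternative not implemented.
- Negation is a bag-level indicator; scope and double negation are not
  modeled.
- Detection is lexicon-bound: genes absent from the lexicon are invisible,
  and abbreviation disambiguation beyond the category scheme is out of
  scope.
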
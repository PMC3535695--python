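"""Train and evaluate the two-stage cascade on a synthetic skewed corpus.

Generates the top-eight preset corpus (1,143 instances with realistic
per-gene category skew), extracts features, and compares pooled 5-fold
cross-validation accuracy of the cascade against the flat 6-way baseline.
"""

import genestatus as gs

spec = gs.make_preset_spec("top8_skewed", seed=42)
corpus = gs.generate_corpus(spec)
feat = gs.featurize_instances(corpus.documents, corpus.instances)
print(f"corpus: {len(corpus.instances)} labeled mentions, "
      f"{len(spec.genes)} genes")

for name, trainer in [("two-stage cascade", gs.train_two_stage),
                      ("single-stage baseline", gs.train_single_stage)]:
    report = gs.cross_validate_pooled(
        feat, trainer, gs.ClassifierConfig(seed=42), k=5, seed=42)
    print(f"\n{name}: pooled accuracy {report.accuracy:.1%}")
    print(report.to_table())

# On this noise-free corpus the cue phrases are fully separable, so both
# classifiers sit at or near 100%; the per-category rows show pooled
# held-out precision/recall/F. Pass noise_rate=0.1 to make_preset_spec
# to watch accuracy drop toward the ceiling that 10% label noise imposes.
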
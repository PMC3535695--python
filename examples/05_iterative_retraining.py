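"""Iterative annotation bootstrapping.

Starts from a pool labeled with the six-category scheme, then absorbs
batches in which a seventh category ("detected or not detected") appears.
The first batch containing the new category is scored before the model has
ever seen it; accuracy recovers once that batch joins the training pool.
"""

import genestatus as gs

spec = gs.make_preset_spec("balanced", seed=3)
corpus = gs.generate_corpus(spec)
feat = gs.featurize_instances(corpus.documents, corpus.instances)
initial, rest = feat[:240], feat[240:]

# carve the remainder into batches; spike the later batches with a category
# absent from the initial pool
seventh = gs.StatusCategory.GENETIC_LESION_DETECTED_OR_NOT
spiked = [({"ctx:word=determined": 1.0, "ctx:word=status": 1.0,
            "sec:eligibility": 1.0}, seventh)] * 20
batches = [rest[:80], rest[80:160] + spiked, rest[160:] + spiked]

results = gs.iterative_retraining(initial, batches, gs.train_two_stage,
                                  gs.ClassifierConfig(seed=3))
for r in results:
    print(f"iteration {r.iteration}: accuracy on batch {r.accuracy:.1%}  "
          f"batch={r.batch_size}  cumulative pool={r.cumulative_training_size}")

# Iteration 2 dips: instances of the new category cannot be predicted by a
# model trained before the category existed. Iteration 3 recovers because
# the pool now contains them — the practical argument for
# annotate-correct-retrain loops over one-shot annotation.
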
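"""Inspect the sparse feature vector of a single mention.

Extracts the four feature families (windowed context, dependency links,
negation, section) for a wild-type eligibility sentence and prints each
named feature.
"""

import genestatus as gs

text = "Patient must have wild type KRAS confirmed by testing ."
doc = gs.TrialDocument("EX-002", "active", [("eligibility", text)])
(mention,) = gs.find_mentions(doc, [gs.GeneLexiconEntry("KRAS")])
sentences = gs.tokenize_and_split(text, section="eligibility")

vector = gs.build_feature_vector(mention, sentences, gs.FeatureConfig())
for name in sorted(vector):
    print(name)

# ctx:* features are lowercased window words, both bag-of-words and
# position-stamped (side|distance) variants; orth:* describes casing of the
# mention and its immediate neighbors (KRAS -> allcaps|self); neg:present
# fires because "wild" sits within the 3-token negation window;
# sec:eligibility records the section; dep:* links come from the offline
# heuristic parse. Every name is namespaced by family, which is what lets
# grid search switch families off without re-extraction.
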
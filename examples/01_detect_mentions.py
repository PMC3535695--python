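"""Dictionary matching and why it is not enough on its own.

Builds a tiny trial document containing both a real gene mention and an
English-word homograph, runs lexicon matching, and prints every hit.
"""

import genestatus as gs

lexicon = [
    gs.GeneLexiconEntry("MET", frozenset({"c-met"}), is_cancer_gene=True),
    gs.GeneLexiconEntry("KIT", frozenset({"c-kit", "CD117"}), is_cancer_gene=True),
]

doc = gs.TrialDocument(
    trial_id="EX-001",
    status="active",
    sections=[
        ("title", "A study of c-met inhibition in solid tumors"),
        ("eligibility",
         "Tumor must show c-kit positive staining .\n"
         "Patient has met the inclusion criteria ."),
    ],
)

for m in gs.find_mentions(doc, lexicon):
    print(f"{m.section_name:<12} {m.gene_symbol:<5} surface={m.matched_text!r} "
          f"span={m.char_span}")

# Every line is one whole-token lexicon hit. Note the last one: the English
# word "met" matches the MET gene under case-insensitive matching — exactly
# the false positive the status classifier is built to resolve (it should
# land in the "others" category, not any lesion-status leaf).
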
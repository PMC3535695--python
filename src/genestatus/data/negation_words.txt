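# Default negation lexicon for lesion-status cues (one lowercase token per
# line). Extend or replace via NegationLexicon.from_file.
no
not
without
negative
negativity
absence
absent
lack
lacking
non
wild
wild-type
exclude
excluded
ineligible
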
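"""Build the canonical classifier-noun design and inspect its structure.

12 Mandarin-style classifiers (6 animate-constraining, 6 inanimate-
constraining, 3 per subgroup) are each paired with 10 congruent nouns and
re-paired to create incongruent phrases; trials are split into 3 blocks of
80 with balanced congruency.
"""

import animrsa as ar

design = ar.default_design(rng_seed=0)

print("trials:", design.n_trials)
print("condition counts:", design.congruency_counts())
print("\nper-block composition:")
print(design.trials.groupby(["block", "congruency"]).size().unstack())
print("\nfirst trials of block 1:")
print(design.trials.head(5).to_string(index=False))

pairs = ar.enumerate_within_pairs(design.classifier_ids("animate"))
print(f"\nwithin-animate classifier pairs: {len(pairs)} (6*5/2)")

# Every noun appears exactly twice: once congruent, once incongruent.
print("nouns used exactly twice:",
      bool((design.trials["noun_id"].value_counts() == 2).all()))
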
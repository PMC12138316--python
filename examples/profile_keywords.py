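"""Profile keyword occurrence by label and bucket sentiment scores.

The per-keyword fractions show which topic terms concentrate in fake vs
genuine records (the generator plants "immune" in 55% of fake texts but
only 5% of genuine ones); the bucket functions map lexicon sentiment
scores to the five-band categories used in descriptive corpus analysis.
"""

from rankfuse import (
    CorpusGenConfig,
    gen_corpus,
    keyword_occurrence_profile,
    polarity_bucket,
    subjectivity_bucket,
)

records, _ = gen_corpus(CorpusGenConfig(seed=1, duplicate_rate=0.0))
profile = keyword_occurrence_profile(records)
print("fraction of records containing each keyword, by label:")
print(profile.round(3).to_string())

print("\nsentiment bucketing examples:")
for pol in (-0.7, -0.3, 0.0, 0.3, 0.7):
    print(f"  polarity {pol:+.1f} -> {polarity_bucket(pol)}")
for subj in (0.1, 0.5, 0.9):
    print(f"  subjectivity {subj:.1f} -> {subjectivity_bucket(subj)} subjectivity")
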
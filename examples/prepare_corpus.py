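"""Run the full preprocessing pipeline on a synthetic scraped corpus.

Generates an imbalanced corpus (2,361 fake / 566 genuine) with planted
duplicates, URLs and emoji, then cleans, deduplicates, keyword-filters,
label-encodes and splits it 90/10 with stratification, printing the counts
at each stage.
"""

from rankfuse import CorpusGenConfig, gen_corpus, ledger_summary, stratified_split
from rankfuse.pipeline import clean_records, deduplicate, encode_labels, keyword_filter

records, book = gen_corpus(CorpusGenConfig(seed=7, sources={"CTF": 0.6, "FibVID": 0.4}))
print(f"generated          {len(records):>5} records "
      f"({int(book.labels.sum())} fake, {book.n_duplicates} planted duplicates)")

records = clean_records(records)
records, removed = deduplicate(records)
print(f"after dedup        {len(records):>5} records ({removed} removed)")

records = keyword_filter(records)
print(f"after keyword pass {len(records):>5} records (off-topic dropped)")

records = encode_labels(records)
ledger = ledger_summary(records)
print("\nledger (per-source sample sizes):")
print(ledger.to_frame().to_string(index=False))

split = stratified_split(records, test_fraction=0.1, seed=7)
print(f"\nstratified split: {len(split.train_ids)} train / {len(split.test_ids)} test "
      f"(same seed always reproduces this split)")
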
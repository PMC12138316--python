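"""Train the unigram TF-IDF + linear SVM baseline with 5-fold selection.

Fits the vectorizer on training texts only, trains a linear-kernel SVM per
stratified fold, and reports per-fold validation metrics; the fold with the
highest validation F1 (fake class) is the selected model.
"""

from rankfuse import CorpusGenConfig, gen_corpus, tfidf_features, train_svm_cv

records, _ = gen_corpus(CorpusGenConfig(n_fake=800, n_genuine=200, seed=5))
texts = [r.text for r in records]
labels = [r.label for r in records]

features, _, tfidf = tfidf_features(texts)
model, report = train_svm_cv(features, labels, folds=5, seed=5)

print(f"vocabulary size: {len(tfidf.vocabulary)} unigrams")
print("\nper-fold validation metrics (positive class = fake):")
print(report.round(4).to_string(index=False))
best = int(report["f1"].idxmax())
print(f"\nselected fold {best} (highest validation F1 = {report['f1'][best]:.4f})")
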
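# Methods

## Fusion model

Each of `K` classifiers emits a probability row over `C` classes for every
item (rows validated to sum to 1 within 1e-6; an optional renormalization
flag absorbs softmax float noise, chosen over hard rejection because
softmax outputs routinely miss exact normalization by ~1e-8). Confidence
`p` maps to a fuzzy rank through the reparameterized Gompertz function
`R(p) = 1 − exp(−exp(−s·p))`, strictly decreasing with range
`[1 − exp(−e^(−s)), 1 − e^(−1)]` on `[0, 1]`. The per-class fused score is
the rank sum times the complement confidence factor
`CCF_c = 1 − mean_k p_kc`; the decision is the fused-score argmin.

Assumptions and choices:

- **Scale `s = 2.0`** is the published default of the Gompertz-rank
  formulation and is exposed in `FusionConfig`; results are insensitive to
  moderate changes because `R` stays strictly monotone for any `s > 0`.
- **No rank clipping.** Some fuzzy-rank variants zero out ranks outside a
  top-κ subset of classifiers; with `K = 3` classifiers clipping would
  discard a third of the signal, so it is not implemented.
- **Tie-break** at exactly equal fused scores is the lowest class index —
  deterministic and reproducible; ties have measure zero for continuous
  confidences.
- **ROC score** for the decision-level fusion is
  `FS_genuine / (FS_genuine + FS_fake)` (0.5 when both vanish, which
  happens only if every row is a point mass on a different class with the
  mean confidence exactly 1 per class). It is bounded in `[0, 1]`, grows
  monotonically with the evidence for "fake", and reduces to 0.5 under
  symmetric inputs. How an AUC is attached to a decision-level fusion is
  genuinely open; this construction is the package's documented choice.
- **No learned meta-weights and no calibration** (Platt/isotonic): the
  point of the method is that per-case weighting is implicit in the
  rank/CCF arithmetic.

Invariants enforced by tests: strict monotonicity of `R`; classifier-
permutation invariance; reduction to argmax for `K = 1` and for identical
rows; exact agreement with a straight-line independent reimplementation on
1,000 seeded random matrices; raising a class's confidence within one row
never raises that class's fused score.

## Corpus pipeline

Cleaning removes URL substrings (`http://`, `https://`, `www.` forms) and
emoji code points (pictograph blocks U+1F000–U+1FAFF, miscellaneous
symbols/dingbats U+2600–U+27BF, U+2B00–U+2BFF, variation selectors, ZWJ),
then collapses whitespace; it is idempotent. Deduplication is exact match
on case-folded, whitespace-collapsed text — the removal of near-duplicates
via fuzzy matching is deliberately out of scope, as only exact duplicates
can be removed without a similarity threshold to justify. Keyword
filtering keeps records containing at least one of the 14 long-COVID /
reinfection topic terms as a case-insensitive substring (so "long-term"
matches "Long-Term effects"; note "variant" also matches inside
"subvariant" — occurrence profiles measure substring presence, not token
identity). Label harmonization maps PolitiFact's 6-step and Snopes's
14-value verdict vocabularies to binary via an externalized, swappable map
({true, mostly true}(+ correct-attribution for Snopes) → genuine, all else
→ fake); unknown labels raise rather than drop, for auditability.

**Stratified split.** Total test size is round-half-up(`f·N`); per-class
counts are apportioned by largest remainder so they sum exactly to the
total while deviating from `f·n_class` by at most one record. With the
default corpus shape (2,361 fake, 566 genuine, `f = 0.1`) this yields
236 + 57 = 293 test and 2,634 training records. Shuffling uses one numpy
`Generator` seeded per call, so a seed pins the split bit-for-bit.

## Profiling

Polarity buckets: cut points −0.5, −0.1, 0.1, 0.5 on `[−1, 1]`;
subjectivity buckets: 0.2 steps on `[0, 1]`. Interval prose that shares
boundary values is resolved left-closed/right-open with the final interval
closed, making the mapping total and deterministic. Scoring itself is
pluggable: any `text -> (polarity, subjectivity)` callable works, because
the lexicon scorer is not part of the contribution. Keyword occurrence is
presence-based per record (a record counts once regardless of mention
count).

## Baselines and parameter counting

TF-IDF: lowercase, tokens are alphanumeric runs of length ≥ 2 (no
tokenizer was prescribed; this is scikit-learn's convention), raw term
counts, smoothed idf `ln((1+N)/(1+df)) + 1`, L2 row normalization,
vocabulary fit on training texts only. SVM: linear kernel, `C = 1.0`, no
class weighting (both configurable); stratified 5-fold cross-validation
with the fold-model of highest validation F1 (fake class) selected, ties
to the earliest fold.

The analytic parameter counter sums tensor shapes per architecture family:
bert-like (word/position/token-type embeddings + embedding layer norm;
per layer Q/K/V/output with biases, two layer norms, feed-forward with
biases; tanh pooler + linear head), roberta-like (same body, token-type
vocabulary of 1, dense + projection head), and xlnet-like (word embedding
and a mask embedding only — positions are relative; per layer five
bias-free projections q/k/v/o/r, three relative-attention biases, a binary
segment embedding, two layer norms, feed-forward; sequence-summary dense +
logit projection). Counts include all biases and layer-norm scale/shift
pairs and exclude non-trainable buffers. The 12-layer base presets
reproduce the standard published checkpoint sizes with 2-class heads
exactly (verified in tests and recomputed by `scripts/acceptance.py`).
A deberta-like family is not offered: its disentangled-attention layout
admits several published variants and no single analytic form is
canonical.

## Evaluation

Positive class is "fake" (label 1). Accuracy, precision, recall, F1 from
the 2×2 confusion table; undefined ratios surface as absent values with a
reason rather than silent zeros. AUC is the Mann–Whitney statistic (ties
half-credited), computed via scikit-learn and cross-checked in tests
against brute-force pairwise enumeration. Whether published comparison
tables of this kind use fake-class or macro-averaged precision/recall is
typically unstated; fake-class is implemented and documented. Report
tables render percentages at two decimals and sort rows by method name.

## Synthetic data: what it emulates, what it does not

`gen_corpus` emulates the *statistical* shape of a scraped corpus: class
imbalance (defaults 2,361 fake / 566 genuine), class-conditioned keyword
prevalence ("immune" in 55% of fake vs 5% of genuine texts — the dominant
published contrast — with "variant", "complications", "chronic" fake-
leaning, "recovery" genuine-leaning, the remaining terms roughly balanced
at plausible magnitudes), a 5% exact-duplicate rate and 30% URL/emoji
decoration rate (typical of tweet-derived text). Texts are filler-token
sentences from a vocabulary deliberately free of keyword substrings, so
filter retention and occurrence profiles are fully controlled by planted
keywords; base texts are uniqueness-checked so deduplication recovers
exactly the planted duplicate count. The generator makes **no attempt at
linguistic realism** — passing pipeline tests demonstrates bookkeeping
correctness and statistical recovery, not that a classifier trained on
this text transfers to real misinformation.

`gen_ensemble_outputs` draws truth labels at the fake prior 2361/2927,
then couples classifier correctness through a shared latent uniform: with
probability `correlation` classifier `k` compares the shared uniform
against its accuracy, otherwise an independent one — marginal accuracies
are exact by construction and the correlation knob moves only error
overlap. Predicted-class confidence is `0.5 + 0.5·Beta(5, 2)` (mean
≈ 0.86), which guarantees the predicted class is the row argmax and
separates the correctness knob from the calibration knob. Defaults (K = 3,
accuracies 0.918/0.918/0.928, correlation 0.6, 293 items) mirror the
fused trio of fine-tuned language models on a held-out test set of that
size. The property "fuzzy-fused accuracy ≥ mean single-classifier
accuracy" is asserted at fixed seeds in the diverse-accuracy regime
(0.9/0.8/0.7, correlation 0.3, n = 5,000) as a demonstration; it is
regime-dependent, not a theorem — with highly correlated or uniformly
strong classifiers fusion can only match the consensus.

## Numerical and testing choices

Row-sum tolerance 1e-6; fused-score identity asserted to 1e-12; Gompertz
endpoint closed forms to 1e-9; strict-monotonicity property tests skip
pairs closer than 1e-12, below which `R` collides in float64. Statistical
recovery tests use 99% binomial confidence intervals at n = 1,000 (corpus
prevalence) and n = 5,000 (classifier accuracies, correlation grid) — large
enough that the CI half-widths (≈ 1.3–4 percentage points) are far smaller
than the planted contrasts, small enough that the whole suite runs in a
few seconds on one CPU. All simulations are seeded; hypothesis tests are
derandomized.

## Known limitations

- Exact-match deduplication misses paraphrased duplicates; the real
  corpus-assembly step that removed cross-source near-duplicates is not
  reproducible from published information.
- The AUC attached to the fuzzy fusion depends on the documented score
  construction; other monotone constructions would give different AUCs
  (decisions are unaffected).
- The keyword list treats "variant"/"subvariant" and "post covid"/
  "post-covid" as overlapping substrings by design; per-token matching
  would need a tokenizer commitment the pipeline deliberately avoids.
- Transformer fine-tuning is out of scope; real language-model ensembles
  enter only through the `ClassifierAdapter` contract.
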
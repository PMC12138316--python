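"""Baseline models and model accounting.

Three pieces live here:

* the unigram TF-IDF + linear SVM baseline with stratified k-fold
  cross-validation and best-fold selection by validation F1,
* the ``ClassifierAdapter`` contract through which any probability-emitting
  text classifier (a fine-tuned transformer, an SVM, a stub) feeds the
  fusion layer, and
* an analytic parameter counter for transformer classification
  architectures, so model sizes can be tabulated without instantiating any
  weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.metrics import f1_score, precision_score, recall_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .fusion import ProbabilityMatrix

__all__ = [
    "TfidfModel",
    "tfidf_features",
    "train_svm_cv",
    "ClassifierAdapter",
    "SvmAdapter",
    "ArchSpec",
    "count_transformer_params",
]


class BaselineError(ValueError):
    pass


# --------------------------------------------------------------------------
# TF-IDF

#: lowercase, split on non-alphanumeric runs, keep tokens of length >= 2
_TOKEN_PATTERN = r"(?u)\b\w\w+\b"


@dataclass
class TfidfModel:
    """Fitted unigram TF-IDF vocabulary and idf weights.

    tf is the raw in-document term count; idf uses the smoothed formula
    ln((1+N)/(1+df)) + 1 so every weight is >= 1; rows are L2-normalized.
    """

    vectorizer: TfidfVectorizer

    @property
    def vocabulary(self) -> dict[str, int]:
        return self.vectorizer.vocabulary_

    @property
    def idf(self) -> np.ndarray:
        return self.vectorizer.idf_

    def transform(self, texts: Sequence[str]):
        """Transform texts with the training vocabulary; OOV tokens are ignored."""
        return self.vectorizer.transform(texts)


def tfidf_features(train_texts: Sequence[str], apply_texts: Sequence[str] | None = None):
    """Fit TF-IDF on the training texts only and transform both sets.

    Returns ``(train_matrix, apply_matrix, model)``; ``apply_matrix`` is
    None when no apply_texts are given.  Texts made only of unseen tokens
    transform to all-zero rows.
    """
    if not len(train_texts):
        raise BaselineError("cannot fit TF-IDF on an empty training corpus")
    vec = TfidfVectorizer(
        lowercase=True,
        token_pattern=_TOKEN_PATTERN,
        ngram_range=(1, 1),
        norm="l2",
        smooth_idf=True,
        sublinear_tf=False,
    )
    train_m = vec.fit_transform(train_texts)
    model = TfidfModel(vec)
    apply_m = model.transform(apply_texts) if apply_texts is not None else None
    return train_m, apply_m, model


# --------------------------------------------------------------------------
# SVM with cross-validated fold selection


def train_svm_cv(
    features,
    labels: Sequence[int],
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
):
    """Train a linear-kernel SVM per stratified fold; keep the best fold.

    Each fold's model is fit on the other folds and scored on the held-out
    fold; the model with the highest validation F1 for the positive (fake)
    class is returned together with the full per-fold report.  Ties go to
    the earliest fold.  Fixed seed gives identical folding and reports.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise BaselineError("both classes must be present")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rows, models = [], []
    for fold, (tr, va) in enumerate(skf.split(np.zeros(len(y)), y)):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
            raise BaselineError(f"fold {fold} is degenerate (single-class)")
        clf = SVC(kernel="linear", C=C, random_state=seed)
        clf.fit(features[tr], y[tr])
        pred = clf.predict(features[va])
        rows.append(
            {
                "fold": fold,
                "accuracy": float(np.mean(pred == y[va])),
                "precision": precision_score(y[va], pred, pos_label=1, zero_division=0),
                "recall": recall_score(y[va], pred, pos_label=1, zero_division=0),
                "f1": f1_score(y[va], pred, pos_label=1, zero_division=0),
                "n_val": len(va),
            }
        )
        models.append(clf)
    report = pd.DataFrame(rows)
    best = int(report["f1"].idxmax())
    return models[best], report


# --------------------------------------------------------------------------
# classifier adapter contract


@runtime_checkable
class ClassifierAdapter(Protocol):
    """Anything that can score texts with per-class confidence rows.

    Adapters wrap trained models (fine-tuned language models, SVMs, ...)
    behind a uniform predict-distribution surface; the fusion layer stacks
    one row per adapter into a :class:`ProbabilityMatrix` per item.
    """

    name: str

    def predict_proba(self, texts: Sequence[str]) -> np.ndarray:
        """Return an (n_texts, n_classes) array of row distributions."""
        ...


@dataclass
class SvmAdapter:
    """TF-IDF + SVM wrapped as a distribution-emitting adapter.

    The SVM margin d(x) is squashed through a logistic 1/(1+exp(-d)) to a
    confidence for the fake class; this is a monotone squashing for ranking
    purposes, not a calibrated probability.
    """

    model: SVC
    tfidf: TfidfModel
    name: str = "tfidf-svm"

    def predict_proba(self, texts: Sequence[str]) -> np.ndarray:
        margins = self.model.decision_function(self.tfidf.transform(texts))
        p_fake = 1.0 / (1.0 + np.exp(-margins))
        return np.column_stack([1.0 - p_fake, p_fake])


def stack_adapter_outputs(
    adapters: Sequence[ClassifierAdapter], texts: Sequence[str]
) -> list[ProbabilityMatrix]:
    """Run every adapter over the texts and build one K x C matrix per text."""
    outputs = [np.asarray(a.predict_proba(texts), dtype=float) for a in adapters]
    names = [a.name for a in adapters]
    matrices = []
    for i in range(len(texts)):
        pm = ProbabilityMatrix(np.vstack([o[i] for o in outputs]), names)
        pm.validate(renormalize=True)
        matrices.append(pm)
    return matrices


# --------------------------------------------------------------------------
# analytic transformer parameter counting


@dataclass(frozen=True)
class ArchSpec:
    """Hyperparameters sufficient to count a transformer classifier's weights.

    ``family`` fixes the layer layout:

    * ``bert-like`` — learned word/position/token-type embeddings with an
      embedding layer norm; per layer Q/K/V/output projections with biases;
      ``pooler+linear`` head (tanh pooler on [CLS] plus a linear classifier).
    * ``roberta-like`` — same encoder body; classification head is a dense
      layer plus output projection on the first token (no pooler is counted).
    * ``xlnet-like`` — word embedding only (positions are relative), a
      learned mask embedding, bias-free q/k/v/o/r projections, three
      relative-attention biases (r_w, r_r, r_s) and a binary segment
      embedding per layer; sequence-summary dense plus logit projection head.
    """

    family: str
    vocab_size: int
    hidden: int
    layers: int
    ffn: int
    max_positions: int = 0
    type_vocab: int = 0
    heads: int | None = None
    head_dim: int | None = None
    num_labels: int = 2
    head_style: str = "pooler+linear"

    def __post_init__(self) -> None:
        dims = [self.vocab_size, self.hidden, self.layers, self.ffn, self.num_labels]
        if any(d <= 0 for d in dims):
            raise BaselineError("all architecture dimensions must be positive")
        if self.heads is not None and self.head_dim is not None:
            if self.heads * self.head_dim != self.hidden:
                raise BaselineError(
                    f"hidden {self.hidden} != heads {self.heads} x head_dim {self.head_dim}"
                )
        known = {"bert-like", "roberta-like", "xlnet-like"}
        if self.family not in known:
            raise BaselineError(f"unknown family {self.family!r}; expected one of {sorted(known)}")

    # canonical presets -----------------------------------------------------
    @staticmethod
    def bert_base(num_labels: int = 2) -> "ArchSpec":
        return ArchSpec(
            "bert-like", vocab_size=30522, hidden=768, layers=12, ffn=3072,
            max_positions=512, type_vocab=2, heads=12, head_dim=64,
            num_labels=num_labels, head_style="pooler+linear",
        )

    @staticmethod
    def roberta_base(num_labels: int = 2) -> "ArchSpec":
        return ArchSpec(
            "roberta-like", vocab_size=50265, hidden=768, layers=12, ffn=3072,
            max_positions=514, type_vocab=1, heads=12, head_dim=64,
            num_labels=num_labels, head_style="dense+projection",
        )

    @staticmethod
    def xlnet_base(num_labels: int = 2) -> "ArchSpec":
        return ArchSpec(
            "xlnet-like", vocab_size=32000, hidden=768, layers=12, ffn=3072,
            heads=12, head_dim=64, num_labels=num_labels,
            head_style="summary+projection",
        )

    @staticmethod
    def from_json(path: str | Path) -> "ArchSpec":
        return ArchSpec(**json.loads(Path(path).read_text()))


def _dense(n_in: int, n_out: int, bias: bool = True) -> int:
    return n_in * n_out + (n_out if bias else 0)


def _layer_norm(dim: int) -> int:
    return 2 * dim  # scale + shift


def count_transformer_params(spec: ArchSpec) -> int:
    """Exact count of trainable scalars for a classification architecture.

    Sums every weight tensor's size analytically: embeddings, per-layer
    attention and feed-forward blocks with their layer norms, and the
    family-specific classification head.  Non-trainable buffers (position-id
    index vectors and the like) are excluded; all biases and layer-norm
    scale/shift pairs are included.
    """
    h, f, L = spec.hidden, spec.ffn, spec.layers
    total = 0
    if spec.family in ("bert-like", "roberta-like"):
        # embeddings: word + learned position + token type + embedding LN
        total += spec.vocab_size * h
        total += spec.max_positions * h
        total += spec.type_vocab * h
        total += _layer_norm(h)
        # encoder layers: Q/K/V/output with biases, two layer norms, FFN
        per_layer = (
            4 * _dense(h, h)
            + _layer_norm(h)
            + _dense(h, f)
            + _dense(f, h)
            + _layer_norm(h)
        )
        total += L * per_layer
        if spec.head_style == "pooler+linear":
            total += _dense(h, h) + _dense(h, spec.num_labels)
        elif spec.head_style == "dense+projection":
            total += _dense(h, h) + _dense(h, spec.num_labels)
        else:
            raise BaselineError(
                f"head_style {spec.head_style!r} undefined for family {spec.family!r}"
            )
        return total
    # xlnet-like: relative-position attention, no absolute position table
    if spec.heads is None or spec.head_dim is None:
        raise BaselineError("xlnet-like specs need heads and head_dim")
    attn_dim = spec.heads * spec.head_dim
    total += spec.vocab_size * h  # word embedding
    total += h  # mask embedding used by permutation LM two-stream attention
    per_layer = (
        5 * h * attn_dim  # q, k, v, o, r projections, all bias-free
        + 3 * attn_dim  # r_w / r_r / r_s relative attention biases
        + 2 * attn_dim  # binary segment embedding
        + _layer_norm(h)
        + _dense(h, f)
        + _dense(f, h)
        + _layer_norm(h)
    )
    total += L * per_layer
    if spec.head_style != "summary+projection":
        raise BaselineError(
            f"head_style {spec.head_style!r} undefined for family 'xlnet-like'"
        )
    total += _dense(h, h) + _dense(h, spec.num_labels)
    return total
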
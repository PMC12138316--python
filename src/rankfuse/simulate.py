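"""Synthetic corpora and correlated ensemble outputs.

Every other module is testable against ground truth produced here, with no
download.  Two generators:

* :func:`gen_corpus` emulates the shape of a scraped long-COVID corpus —
  imbalanced binary labels (default 2361 fake / 566 genuine), class-
  dependent keyword prevalence, planted exact duplicates, URLs and emoji —
  and records every planted feature for oracle tests.
* :func:`gen_ensemble_outputs` emulates K classifiers with chosen marginal
  accuracies and a shared-latent correlation structure, emitting one
  probability matrix per item, standing in for fine-tuned language models'
  softmax outputs.

All randomness flows from one numpy Generator per call; a fixed seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fusion import ProbabilityMatrix
from .pipeline import FAKE, GENUINE, Record

__all__ = [
    "CorpusGenConfig",
    "EnsembleGenConfig",
    "CorpusBookkeeping",
    "gen_corpus",
    "gen_ensemble_outputs",
]


class SimulationError(ValueError):
    pass


#: Per-keyword (fake, genuine) inclusion probabilities.  "immune" dominates
#: fake texts while "recovery" tilts genuine; "variant", "complications" and
#: "chronic" are fake-leaning, the rest roughly balanced.
DEFAULT_PREVALENCE: dict[str, tuple[float, float]] = {
    "immune": (0.55, 0.05),
    "recovery": (0.25, 0.30),
    "variant": (0.35, 0.20),
    "complications": (0.30, 0.15),
    "chronic": (0.30, 0.15),
    "long-term": (0.25, 0.25),
    "persistent": (0.15, 0.15),
    "after-effects": (0.10, 0.10),
    "sequelae": (0.05, 0.10),
    "post covid": (0.15, 0.15),
    "post-covid": (0.10, 0.10),
    "omicron": (0.20, 0.20),
    "subvariant": (0.10, 0.10),
    "reinfection": (0.20, 0.15),
}

#: Neutral filler vocabulary; deliberately free of every default keyword
#: (including as substring) so topic-filter retention is fully controlled
#: by planted keywords.
_FILLERS = (
    "the", "report", "states", "that", "people", "should", "know", "about",
    "health", "officials", "said", "new", "data", "from", "study", "shows",
    "many", "cases", "in", "region", "public", "response", "was", "mixed",
    "experts", "urge", "caution", "while", "others", "question", "claims",
    "hospital", "figures", "indicate", "trend", "over", "months", "local",
)

_EMOJIS = ("😷", "🦠", "💉", "🤒", "⚠️", "🔬")


@dataclass
class CorpusGenConfig:
    """Study conditions for the synthetic corpus.

    Defaults emulate the real corpus shape: 2361 fake and 566 genuine
    records (2927 total), keyword prevalence dominated by "immune" among
    fake texts, a 5% planted exact-duplicate rate and a 30% chance of a
    URL or emoji decoration per record.
    """

    n_fake: int = 2361
    n_genuine: int = 566
    keyword_prevalence: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    duplicate_rate: float = 0.05
    url_emoji_rate: float = 0.30
    sources: Mapping[str, float] = field(default_factory=lambda: {"synthetic": 1.0})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fake < 0 or self.n_genuine < 0:
            raise SimulationError("record counts must be nonnegative")
        if self.n_fake + self.n_genuine == 0:
            raise SimulationError("corpus must contain at least one record")
        for kw, (pf, pg) in self.keyword_prevalence.items():
            if not (0 <= pf <= 1 and 0 <= pg <= 1):
                raise SimulationError(f"prevalence for {kw!r} outside [0, 1]")
        if not 0 <= self.duplicate_rate < 1:
            raise SimulationError("duplicate_rate must be in [0, 1)")
        if not 0 <= self.url_emoji_rate <= 1:
            raise SimulationError("url_emoji_rate must be in [0, 1]")


@dataclass
class CorpusBookkeeping:
    """Ground truth of everything the generator planted."""

    n_duplicates: int
    keyword_flags: dict[str, np.ndarray]  # keyword -> boolean per record
    labels: np.ndarray
    source_counts: dict[str, int]
    n_decorated: int  # records carrying a planted URL or emoji


def _make_text(rng: np.random.Generator, planted: list[str]) -> str:
    words = list(rng.choice(_FILLERS, size=int(rng.integers(8, 16))))
    for kw in planted:
        pos = int(rng.integers(0, len(words) + 1))
        words.insert(pos, kw)
    return " ".join(words)


def gen_corpus(config: CorpusGenConfig) -> tuple[list[Record], CorpusBookkeeping]:
    """Generate a labeled corpus with fully recorded planted structure.

    Texts are filler-token sentences with class-conditioned keyword
    insertions.  A ``duplicate_rate`` fraction of each class consists of
    exact copies of earlier records of the same class; URL/emoji
    decorations are appended at ``url_emoji_rate``.  Base texts are
    guaranteed unique, so after deduplication exactly
    ``len(records) - n_duplicates`` records survive.
    """
    rng = np.random.default_rng(config.seed)
    keywords = list(config.keyword_prevalence)
    source_names = list(config.sources)
    source_p = np.array([config.sources[s] for s in source_names], dtype=float)
    source_p /= source_p.sum()

    records: list[Record] = []
    flags: dict[str, list[bool]] = {kw: [] for kw in keywords}
    labels: list[int] = []
    seen_texts: set[str] = set()
    n_dup_total = 0
    n_decorated = 0

    for label, n_class in ((FAKE, config.n_fake), (GENUINE, config.n_genuine)):
        n_dup = int(round(config.duplicate_rate * n_class))
        n_unique = n_class - n_dup
        class_records: list[tuple[str, list[bool]]] = []  # (text, keyword flags)
        col = 0 if label == FAKE else 1
        for _ in range(n_unique):
            planted = [
                kw for kw in keywords
                if rng.random() < config.keyword_prevalence[kw][col]
            ]
            for _attempt in range(100):
                text = _make_text(rng, planted)
                if text not in seen_texts:
                    break
            else:  # pragma: no cover - filler space is far larger than n
                raise SimulationError("could not generate a unique text")
            seen_texts.add(text)
            class_records.append((text, [kw in planted for kw in keywords]))
        # exact copies of earlier same-class records
        for _ in range(n_dup):
            src_text, src_flags = class_records[int(rng.integers(0, len(class_records)))]
            class_records.append((src_text, src_flags))
        n_dup_total += n_dup
        for text, kw_flags in class_records:
            if rng.random() < config.url_emoji_rate:
                deco = (
                    "https://example.com/" + "".join(rng.choice(list("abcdef0123456789"), 6))
                    if rng.random() < 0.5
                    else str(rng.choice(_EMOJIS))
                )
                text = f"{text} {deco}"
                n_decorated += 1
            source = str(source_names[int(rng.choice(len(source_names), p=source_p))])
            records.append(
                Record(
                    id=f"rec{len(records):05d}",
                    text=text,
                    source=source,
                    raw_label="fake" if label == FAKE else "genuine",
                    label=label,
                )
            )
            labels.append(label)
            for kw, flag in zip(keywords, kw_flags):
                flags[kw].append(flag)

    source_counts: dict[str, int] = {}
    for rec in records:
        source_counts[rec.source] = source_counts.get(rec.source, 0) + 1
    book = CorpusBookkeeping(
        n_duplicates=n_dup_total,
        keyword_flags={kw: np.array(v) for kw, v in flags.items()},
        labels=np.array(labels),
        source_counts=source_counts,
        n_decorated=n_decorated,
    )
    return records, book


@dataclass
class EnsembleGenConfig:
    """Study conditions for synthetic multi-classifier outputs.

    Defaults emulate the fused trio of fine-tuned language models on the
    held-out test set: K=3 classifiers with marginal accuracies around
    0.92, moderately correlated errors (shared-latent weight 0.6), a fake
    prior of 2361/2927 and Beta(5, 2) confidence concentration (mean
    confidence ~0.86 after rescaling to [0.5, 1]).
    """

    n_items: int = 293
    K: int = 3
    accuracies: Sequence[float] = (0.918, 0.918, 0.928)
    correlation: float = 0.6
    confidence_concentration: tuple[float, float] = (5.0, 2.0)
    class_prior: float = 2361 / 2927
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise SimulationError("need at least one classifier (K >= 1)")
        if len(self.accuracies) != self.K:
            raise SimulationError("accuracies must have length K")
        if not all(0 < a < 1 for a in self.accuracies):
            raise SimulationError("accuracies must lie in (0, 1)")
        if not 0 <= self.correlation <= 1:
            raise SimulationError("correlation must lie in [0, 1]")
        a, b = self.confidence_concentration
        if a <= 0 or b <= 0:
            raise SimulationError("confidence concentration parameters must be positive")
        if not 0 < self.class_prior < 1:
            raise SimulationError("class_prior must lie in (0, 1)")


def gen_ensemble_outputs(
    config: EnsembleGenConfig,
) -> tuple[np.ndarray, list[ProbabilityMatrix]]:
    """Draw truth labels and one K x 2 probability matrix per item.

    Truth ~ Bernoulli(class_prior) for the fake class.  A shared latent
    uniform u_i drives correctness: classifier k uses v_ik = u_i with
    probability ``correlation`` and an independent uniform otherwise, and
    is correct when v_ik < accuracies[k] — so marginal accuracy is exact
    and the correlation knob moves only the error overlap.  The predicted
    class receives a confidence 0.5 + 0.5 * Beta(a, b), guaranteeing it is
    the row argmax; the other class gets the complement.
    """
    rng = np.random.default_rng(config.seed)
    n, K = config.n_items, config.K
    acc = np.asarray(config.accuracies, dtype=float)
    truth = (rng.random(n) < config.class_prior).astype(int)
    u = rng.random(n)
    a, b = config.confidence_concentration

    predicted = np.empty((n, K), dtype=int)
    conf = np.empty((n, K))
    for k in range(K):
        use_shared = rng.random(n) < config.correlation
        v = np.where(use_shared, u, rng.random(n))
        correct = v < acc[k]
        predicted[:, k] = np.where(correct, truth, 1 - truth)
        conf[:, k] = 0.5 + 0.5 * rng.beta(a, b, size=n)

    matrices = []
    clf_ids = tuple(f"clf{k}" for k in range(K))
    for i in range(n):
        values = np.empty((K, 2))
        for k in range(K):
            values[k, predicted[i, k]] = conf[i, k]
            values[k, 1 - predicted[i, k]] = 1.0 - conf[i, k]
        matrices.append(ProbabilityMatrix(values, clf_ids, ("genuine", "fake")))
    return truth, matrices
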
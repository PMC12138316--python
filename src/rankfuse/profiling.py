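"""Descriptive profiling of a labeled misinformation corpus.

Two kinds of profile: (a) bucketing of lexicon-derived sentiment polarity
and subjectivity scores into five ordered categories each, and (b)
per-keyword, per-label occurrence fractions (what share of fake vs genuine
records mention "immune", "variant", ...).  Scoring polarity/subjectivity
itself is delegated to any external lexicon scorer; this module consumes
the numeric values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd

from .pipeline import DEFAULT_KEYWORDS, FAKE, GENUINE, PipelineError, Record, _normalize

__all__ = [
    "POLARITY_BUCKETS",
    "SUBJECTIVITY_BUCKETS",
    "SentimentProfile",
    "polarity_bucket",
    "subjectivity_bucket",
    "keyword_occurrence_profile",
    "bucket_histogram",
]

#: Ordered (upper_bound, name) cut points; intervals are left-closed /
#: right-open with the final interval closed at the top endpoint.
POLARITY_BUCKETS: tuple[tuple[float, str], ...] = (
    (-0.5, "strongly negative"),
    (-0.1, "slightly negative"),
    (0.1, "neutral"),
    (0.5, "slightly positive"),
    (1.0, "strongly positive"),
)
SUBJECTIVITY_BUCKETS: tuple[tuple[float, str], ...] = (
    (0.2, "low"),
    (0.4, "medium-low"),
    (0.6, "medium"),
    (0.8, "medium-high"),
    (1.0, "high"),
)


def _bucket(value: float, lo: float, hi: float, cuts, kind: str) -> str:
    if not lo <= value <= hi:
        raise ValueError(f"{kind} {value} outside [{lo}, {hi}]")
    for upper, name in cuts[:-1]:
        if value < upper:
            return name
    return cuts[-1][1]


def polarity_bucket(polarity: float) -> str:
    """Categorize a polarity score in [-1, 1] into five sentiment bands.

    Boundaries sit at -0.5, -0.1, 0.1 and 0.5; a boundary value falls into
    the band to its right (so -0.5 is "slightly negative").
    """
    return _bucket(polarity, -1.0, 1.0, POLARITY_BUCKETS, "polarity")


def subjectivity_bucket(subjectivity: float) -> str:
    """Categorize a subjectivity score in [0, 1] into five bands at 0.2 steps."""
    return _bucket(subjectivity, 0.0, 1.0, SUBJECTIVITY_BUCKETS, "subjectivity")


@dataclass(frozen=True)
class SentimentProfile:
    """Numeric sentiment scores with their bucket assignments."""

    polarity: float
    subjectivity: float

    @property
    def polarity_bucket(self) -> str:
        return polarity_bucket(self.polarity)

    @property
    def subjectivity_bucket(self) -> str:
        return subjectivity_bucket(self.subjectivity)


def keyword_occurrence_profile(
    records: Sequence[Record], keywords: Sequence[str] = DEFAULT_KEYWORDS
) -> pd.DataFrame:
    """Fraction of records per label containing each keyword.

    Presence-based (a record counts once no matter how many mentions),
    case-insensitive substring matching.  Returns a DataFrame indexed by
    keyword with columns ``fake`` and ``genuine``.
    """
    if not records:
        raise PipelineError("cannot profile an empty corpus")
    if any(rec.label not in (GENUINE, FAKE) for rec in records):
        raise PipelineError("all records must carry encoded labels")
    texts = {FAKE: [], GENUINE: []}
    for rec in records:
        texts[rec.label].append(_normalize(rec.text))
    rows = {}
    for kw in keywords:
        needle = kw.casefold()
        rows[kw] = {
            "fake": _presence_fraction(texts[FAKE], needle),
            "genuine": _presence_fraction(texts[GENUINE], needle),
        }
    return pd.DataFrame.from_dict(rows, orient="index")[["fake", "genuine"]]


def _presence_fraction(texts: list[str], needle: str) -> float:
    if not texts:
        return 0.0
    return sum(needle in t for t in texts) / len(texts)


def bucket_histogram(
    records: Sequence[Record],
    scorer: Callable[[str], tuple[float, float]],
) -> pd.DataFrame:
    """Counts of sentiment/subjectivity buckets by label.

    ``scorer`` maps a text to (polarity, subjectivity); any lexicon scorer
    with that signature plugs in.
    """
    rows = []
    for rec in records:
        pol, subj = scorer(rec.text)
        rows.append(
            {
                "label": "fake" if rec.label == FAKE else "genuine",
                "polarity_bucket": polarity_bucket(pol),
                "subjectivity_bucket": subjectivity_bucket(subj),
            }
        )
    df = pd.DataFrame(rows)
    return df.groupby(["label", "polarity_bucket", "subjectivity_bucket"]).size().rename("count").reset_index()


def save_profile(profile: pd.DataFrame, json_path: str | Path | None = None, csv_path: str | Path | None = None) -> None:
    if json_path is not None:
        Path(json_path).write_text(json.dumps(profile.to_dict(orient="index"), indent=1))
    if csv_path is not None:
        profile.to_csv(csv_path)
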
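"""Corpus preprocessing for the long-COVID misinformation task.

Steps mirror a typical infodemiology pipeline for social-media and
fact-check text: strip URLs and emoji, drop exact duplicates, keep only
records on-topic for long COVID / reinfection via a keyword filter,
harmonize heterogeneous source labels to a binary genuine/fake coding
(0 = genuine, 1 = fake), and split with per-class stratification.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Record",
    "CorpusLedger",
    "SplitIndices",
    "DEFAULT_KEYWORDS",
    "DEFAULT_LABEL_MAPS",
    "clean_text",
    "deduplicate",
    "keyword_filter",
    "harmonize_label",
    "encode_labels",
    "stratified_split",
    "ledger_summary",
    "read_corpus",
    "write_corpus",
]


class PipelineError(ValueError):
    """Invalid input to a preprocessing step."""


class LabelMappingError(PipelineError):
    """A raw source label has no entry in the label map."""


class StratificationError(PipelineError):
    """A class is too small to place at least one record in the test set."""


#: Topic keywords for long COVID and reinfection.
DEFAULT_KEYWORDS: tuple[str, ...] = (
    "chronic",
    "long-term",
    "persistent",
    "after-effects",
    "sequelae",
    "complications",
    "recovery",
    "post covid",
    "post-covid",
    "omicron",
    "subvariant",
    "reinfection",
    "immune",
    "variant",
)

GENUINE, FAKE = 0, 1

#: Default reclassification of source verdict vocabularies to genuine/fake.
#: PolitiFact uses a 6-step truth-o-meter; Snopes a 14-value verdict set.
#: Externalized so any published reclassification can be swapped in.
DEFAULT_LABEL_MAPS: dict[str, dict[str, int]] = {
    "PolitiFact": {
        "true": GENUINE,
        "mostly true": GENUINE,
        "half-true": FAKE,
        "barely true": FAKE,
        "false": FAKE,
        "pants-on-fire": FAKE,
    },
    "Snopes": {
        "true": GENUINE,
        "mostly true": GENUINE,
        "correct-attribution": GENUINE,
        "mixture": FAKE,
        "mostly false": FAKE,
        "false": FAKE,
        "unproven": FAKE,
        "outdated": FAKE,
        "miscaptioned": FAKE,
        "misattributed": FAKE,
        "scam": FAKE,
        "legend": FAKE,
        "labeled-satire": FAKE,
        "lost-legend": FAKE,
    },
    # sources that ship an already-binary label
    "default": {"genuine": GENUINE, "fake": FAKE, "0": GENUINE, "1": FAKE},
}


@dataclass
class Record:
    """One text item with its provenance and (eventually) a binary label."""

    id: str
    text: str
    source: str = "synthetic"
    raw_label: str = ""
    label: int | None = None
    cleaned: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CorpusLedger:
    """Per-source sample-size bookkeeping (source, n, fake, genuine)."""

    rows: list[tuple[str, int, int, int]]
    totals: tuple[int, int, int]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.rows, columns=["source", "sample_size", "fake", "genuine"]
        )
        df.loc[len(df)] = ["Total", *self.totals]
        return df

    def validate(self) -> "CorpusLedger":
        for source, n, f, g in self.rows:
            if n != f + g:
                raise PipelineError(f"ledger row {source}: {n} != {f} + {g}")
        sums = tuple(sum(r[i] for r in self.rows) for i in (1, 2, 3))
        if sums != self.totals:
            raise PipelineError(f"ledger totals {self.totals} != column sums {sums}")
        return self


@dataclass
class SplitIndices:
    """Reproducible stratified train/test partition of record ids."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int
    test_fraction: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "seed": self.seed,
                    "test_fraction": self.test_fraction,
                    "train_ids": list(self.train_ids),
                    "test_ids": list(self.test_ids),
                },
                indent=1,
            )
        )


# URL forms: scheme://..., or a bare www. host
_URL_RE = re.compile(r"(?:https?://\S+|www\.\S+)", re.IGNORECASE)
# Emoji and pictograph code points, plus variation selectors and ZWJ that
# only occur inside emoji sequences.
_EMOJI_RE = re.compile(
    "["
    "\U0001f000-\U0001faff"  # pictographs, emoticons, transport, symbols-ext
    "\u2600-\u27bf"  # misc symbols + dingbats
    "\u2b00-\u2bff"  # misc symbols and arrows (stars, geometric)
    "\ufe0e\ufe0f"  # variation selectors
    "\u200d"  # zero-width joiner
    "]+"
)
_WS_RE = re.compile(r"\s+")


def clean_text(text: str) -> str:
    """Strip URLs and emoji, collapse whitespace, trim ends. Idempotent."""
    text = _URL_RE.sub(" ", text)
    text = _EMOJI_RE.sub("", text)
    return _WS_RE.sub(" ", text).strip()


def clean_records(records: Iterable[Record]) -> list[Record]:
    """Clean every record's text in place and flag it as cleaned."""
    out = []
    for rec in records:
        rec.text = clean_text(rec.text)
        rec.cleaned = True
        out.append(rec)
    return out


def _normalize(text: str) -> str:
    return _WS_RE.sub(" ", text.casefold()).strip()


def deduplicate(records: Sequence[Record]) -> tuple[list[Record], int]:
    """Drop exact duplicates on case-folded, whitespace-collapsed text.

    The first occurrence is retained and input order is preserved.  Returns
    the survivors and the number of records removed.
    """
    seen: set[str] = set()
    kept = []
    for rec in records:
        key = _normalize(rec.text)
        if key in seen:
            continue
        seen.add(key)
        kept.append(rec)
    return kept, len(records) - len(kept)


def keyword_filter(
    records: Sequence[Record], keywords: Sequence[str] = DEFAULT_KEYWORDS
) -> list[Record]:
    """Keep records whose text contains at least one keyword.

    Matching is case-insensitive substring containment, so "long-term"
    matches "Long-Term effects".  Order is preserved.
    """
    if not keywords:
        raise PipelineError("keyword list must be non-empty")
    needles = [k.casefold() for k in keywords]
    return [
        rec
        for rec in records
        if any(n in _normalize(rec.text) for n in needles)
    ]


def harmonize_label(
    source: str,
    raw_label: str,
    label_maps: Mapping[str, Mapping[str, int]] = DEFAULT_LABEL_MAPS,
) -> int:
    """Map a source-vocabulary verdict to the binary coding.

    Unknown labels raise, never drop silently: a silent drop would skew the
    class balance unaudited.
    """
    table = label_maps.get(source, label_maps.get("default", {}))
    key = raw_label.strip().casefold()
    if key not in table:
        raise LabelMappingError(f"no mapping for label {raw_label!r} from source {source!r}")
    return int(table[key])


def encode_labels(
    records: Iterable[Record],
    label_maps: Mapping[str, Mapping[str, int]] = DEFAULT_LABEL_MAPS,
) -> list[Record]:
    out = []
    for rec in records:
        rec.label = harmonize_label(rec.source, rec.raw_label, label_maps)
        out.append(rec)
    return out


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(
    records: Sequence[Record], test_fraction: float, seed: int
) -> SplitIndices:
    """Partition records into train/test preserving class proportions.

    The total test size is round-half-up(test_fraction * N); per-class test
    counts are apportioned by largest remainder so they sum exactly to that
    total while deviating from the per-class quota by at most one record.
    The same seed always yields the identical split.
    """
    if not 0 < test_fraction < 1:
        raise PipelineError(f"test_fraction must be in (0, 1), got {test_fraction}")
    labels = [rec.label for rec in records]
    if any(lab is None for lab in labels):
        raise PipelineError("all records must have encoded labels before splitting")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise StratificationError("both classes must be present to stratify")

    by_class = {c: [rec.id for rec in records if rec.label == c] for c in classes}
    n_total = len(records)
    n_test = _round_half_up(test_fraction * n_total)
    quotas = {c: test_fraction * len(by_class[c]) for c in classes}
    counts = {c: int(np.floor(quotas[c])) for c in classes}
    # largest-remainder apportionment; remainder ties go to the lower class
    leftovers = sorted(classes, key=lambda c: (-(quotas[c] - counts[c]), c))
    for c in leftovers[: n_test - sum(counts.values())]:
        counts[c] += 1
    for c in classes:
        if counts[c] < 1:
            raise StratificationError(
                f"class {c} has {len(by_class[c])} records; cannot place one in the test set"
            )
        if counts[c] >= len(by_class[c]):
            raise StratificationError(f"class {c} would have an empty training side")

    rng = np.random.default_rng(seed)
    test_ids: list[str] = []
    train_ids: list[str] = []
    for c in classes:
        ids = np.array(by_class[c], dtype=object)
        rng.shuffle(ids)
        test_ids.extend(ids[: counts[c]])
        train_ids.extend(ids[counts[c] :])
    return SplitIndices(tuple(train_ids), tuple(test_ids), seed, test_fraction)


def ledger_summary(records: Sequence[Record]) -> CorpusLedger:
    """Tabulate per-source sample sizes and fake/genuine counts."""
    per_source: dict[str, list[int]] = {}
    for rec in records:
        if rec.label not in (GENUINE, FAKE):
            raise PipelineError(f"record {rec.id} has no encoded label")
        row = per_source.setdefault(rec.source, [0, 0, 0])
        row[0] += 1
        row[1 if rec.label == FAKE else 2] += 1
    rows = [(s, *per_source[s]) for s in sorted(per_source)]
    totals = tuple(sum(r[i] for r in rows) for i in (1, 2, 3)) if rows else (0, 0, 0)
    return CorpusLedger(rows, totals).validate()


# ---------------------------------------------------------------------------
# corpus IO: JSONL (one record per line) or CSV with the same fields


def read_corpus(path: str | Path) -> list[Record]:
    path = Path(path)
    records = []
    if path.suffix.lower() in {".jsonl", ".ndjson"}:
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            d = json.loads(line)
            records.append(
                Record(
                    id=str(d["id"]),
                    text=d["text"],
                    source=d.get("source", "synthetic"),
                    raw_label=str(d.get("raw_label", "")),
                    label=d.get("label"),
                    cleaned=bool(d.get("cleaned", False)),
                )
            )
    else:
        with path.open(newline="") as fh:
            for d in csv.DictReader(fh):
                label = d.get("label")
                records.append(
                    Record(
                        id=str(d["id"]),
                        text=d["text"],
                        source=d.get("source", "synthetic"),
                        raw_label=str(d.get("raw_label", "")),
                        label=int(label) if label not in (None, "") else None,
                    )
                )
    return records


def write_corpus(records: Iterable[Record], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_dict()) + "\n")
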
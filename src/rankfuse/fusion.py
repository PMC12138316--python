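"""Fuzzy rank-based fusion of classifier confidence vectors.

The fusion rule turns each classifier's per-class confidence ``p`` into a
fuzzy rank through a reparameterized Gompertz transform

    R(p) = 1 - exp(-exp(-s * p)),        s > 0 (default 2.0)

which is strictly decreasing in ``p``: the more confident a classifier is in
a class, the *smaller* (better) that class's rank.  Per class, the ranks are
summed over classifiers and multiplied by a complement confidence factor
(CCF), one minus the ensemble's mean confidence in the class.  Both factors
shrink when the ensemble collectively backs a class, so the decision is the
class with the minimal fused score.  Unlike soft voting with fixed weights,
the weighting is implicit and adapts per test case.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ProbabilityMatrix",
    "FusionConfig",
    "FusionResult",
    "SoftVoteResult",
    "gompertz_fuzzy_rank",
    "fuzzy_fuse",
    "soft_vote",
    "fusion_auc_score",
    "load_probability_matrices",
    "save_fusion_report",
]

ROW_SUM_TOL = 1e-6


class FusionError(ValueError):
    """Invalid input to the fusion layer."""


@dataclass(frozen=True)
class FusionConfig:
    """Tunables of the fuzzy fusion rule.

    gompertz_scale : scale ``s`` applied to confidence inside the Gompertz
        transform.  Larger values spread ranks further apart at high
        confidence.  Must be positive.
    tie_break : rule used when two classes reach the same fused score;
        only ``"lowest-class-index"`` is defined.
    """

    gompertz_scale: float = 2.0
    tie_break: str = "lowest-class-index"

    def __post_init__(self) -> None:
        if not self.gompertz_scale > 0:
            raise FusionError(f"gompertz_scale must be positive, got {self.gompertz_scale}")
        if self.tie_break != "lowest-class-index":
            raise FusionError(f"unknown tie_break rule: {self.tie_break!r}")


@dataclass
class ProbabilityMatrix:
    """K classifiers x C classes confidence matrix for one item.

    Every row is a probability distribution over classes.  For the two-class
    misinformation task the class convention is index 0 = genuine,
    index 1 = fake.
    """

    values: np.ndarray
    classifier_ids: Sequence[str] = field(default_factory=tuple)
    class_ids: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FusionError("probability matrix must be 2-dimensional (K x C)")
        k, c = self.values.shape
        if k < 1 or c < 2:
            raise FusionError(f"need K >= 1 and C >= 2, got K={k}, C={c}")
        if not self.classifier_ids:
            self.classifier_ids = tuple(f"clf{i}" for i in range(k))
        if not self.class_ids:
            self.class_ids = tuple(str(j) for j in range(c))
        if len(self.classifier_ids) != k or len(self.class_ids) != c:
            raise FusionError("id lists must match matrix shape")

    @property
    def n_classifiers(self) -> int:
        return self.values.shape[0]

    @property
    def n_classes(self) -> int:
        return self.values.shape[1]

    def validate(self, tol: float = ROW_SUM_TOL, renormalize: bool = False) -> "ProbabilityMatrix":
        """Check entries lie in [0,1] and rows sum to one within ``tol``.

        With ``renormalize=True`` rows within tolerance are rescaled to sum
        exactly to one (softmax outputs carry float noise); rows beyond
        tolerance still raise, naming the offending row.
        """
        if np.any(self.values < -tol) or np.any(self.values > 1 + tol):
            raise FusionError("confidences must lie in [0, 1]")
        sums = self.values.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > tol)
        if bad.size:
            row = int(bad[0])
            raise FusionError(
                f"row {row} ({self.classifier_ids[row]}) sums to {sums[row]:.8f}, not 1"
            )
        if renormalize:
            self.values = np.clip(self.values, 0.0, 1.0)
            self.values /= self.values.sum(axis=1, keepdims=True)
        return self


@dataclass
class FusionResult:
    """Outcome of fuzzy fusion for a single item."""

    rank_matrix: np.ndarray  # K x C fuzzy ranks, entries in (0, 1)
    rank_sum: np.ndarray  # per-class rank sums RS
    ccf: np.ndarray  # per-class complement confidence factors
    fused_score: np.ndarray  # RS * CCF elementwise
    decision: int  # argmin of fused_score
    roc_score: float | None  # P(fake)-like score for ROC, two-class only


@dataclass
class SoftVoteResult:
    """Outcome of (weighted) probability averaging for a single item."""

    averaged: np.ndarray
    decision: int
    roc_score: float | None


def gompertz_fuzzy_rank(p, config: FusionConfig = FusionConfig()):
    """Fuzzy rank of confidence ``p``: ``1 - exp(-exp(-s*p))``.

    Strictly decreasing on [0, 1]; accepts scalars or arrays.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise FusionError("confidence must lie in [0, 1]")
    out = 1.0 - np.exp(-np.exp(-config.gompertz_scale * arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def fuzzy_fuse(
    probs: ProbabilityMatrix,
    config: FusionConfig = FusionConfig(),
    renormalize: bool = False,
) -> FusionResult:
    """Fuse the classifiers' confidence rows into one decision.

    rank_matrix[k, c] = R(p[k, c]); rank_sum[c] = sum_k rank_matrix[k, c];
    ccf[c] = 1 - mean_k p[k, c]; fused_score = rank_sum * ccf.  The decision
    is the fused-score argmin (ties to the lowest class index).  For C=2 the
    continuous score ``roc_score = FS_genuine / (FS_genuine + FS_fake)`` is
    attached: it grows with the evidence for "fake" and is 0.5 when both
    fused scores vanish.
    """
    probs.validate(renormalize=renormalize)
    p = probs.values
    k = p.shape[0]
    rank_matrix = 1.0 - np.exp(-np.exp(-config.gompertz_scale * p))
    rank_sum = rank_matrix.sum(axis=0)
    ccf = 1.0 - p.sum(axis=0) / k
    fused = rank_sum * ccf
    decision = int(np.argmin(fused))  # np.argmin already breaks ties low
    roc = None
    if p.shape[1] == 2:
        denom = fused[0] + fused[1]
        roc = 0.5 if denom == 0 else float(fused[0] / denom)
    return FusionResult(rank_matrix, rank_sum, ccf, fused, decision, roc)


def soft_vote(
    probs: ProbabilityMatrix,
    weights: Sequence[float] | None = None,
    renormalize: bool = False,
) -> SoftVoteResult:
    """Average the rows (optionally weighted) and take the argmax."""
    probs.validate(renormalize=renormalize)
    k = probs.n_classifiers
    if weights is None:
        w = np.full(k, 1.0 / k)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (k,):
            raise FusionError(f"weights must have length K={k}")
        if np.any(w < 0):
            raise FusionError("weights must be nonnegative")
        total = w.sum()
        if total <= 0:
            raise FusionError("weights must sum to a positive value")
        w = w / total
    averaged = w @ probs.values
    decision = int(np.argmax(averaged))  # ties to lowest class index
    roc = float(averaged[1]) if probs.n_classes == 2 else None
    return SoftVoteResult(averaged, decision, roc)


def fusion_auc_score(results: Iterable[FusionResult]) -> list[float]:
    """Extract the continuous fake-evidence scores for ROC analysis."""
    scores = []
    for i, res in enumerate(results):
        if res.roc_score is None or res.fused_score.shape != (2,):
            raise FusionError(f"result {i} is not two-class; AUC scores are unsupported")
        scores.append(res.roc_score)
    return scores


# ---------------------------------------------------------------------------
# file formats: per-item matrices as nested JSON or long-form CSV


def load_probability_matrices(path: str | Path) -> dict[str, ProbabilityMatrix]:
    """Read per-item K x C matrices.

    JSON: ``{item_id: {classifier_id: [p_0, ..., p_{C-1}]}}``.
    CSV (long form): columns item, classifier, class, confidence.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        out = {}
        for item_id, per_clf in payload.items():
            clf_ids = list(per_clf)
            values = np.array([per_clf[c] for c in clf_ids], dtype=float)
            out[item_id] = ProbabilityMatrix(values, clf_ids)
        return out
    # long-form CSV
    cells: dict[str, dict[str, dict[str, float]]] = {}
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            cells.setdefault(row["item"], {}).setdefault(row["classifier"], {})[
                row["class"]
            ] = float(row["confidence"])
    out = {}
    for item_id, per_clf in cells.items():
        clf_ids = sorted(per_clf)
        class_ids = sorted({c for cols in per_clf.values() for c in cols})
        values = np.array(
            [[per_clf[k][c] for c in class_ids] for k in clf_ids], dtype=float
        )
        out[item_id] = ProbabilityMatrix(values, clf_ids, class_ids)
    return out


def save_fusion_report(
    results: Mapping[str, FusionResult | SoftVoteResult],
    json_path: str | Path | None = None,
    csv_path: str | Path | None = None,
) -> dict:
    """Serialize per-item fused scores / decisions to JSON and a CSV summary."""
    report = {}
    for item_id, res in results.items():
        entry: dict = {"decision": res.decision, "roc_score": res.roc_score}
        if isinstance(res, FusionResult):
            entry["fused_score"] = [float(x) for x in res.fused_score]
            entry["rank_sum"] = [float(x) for x in res.rank_sum]
            entry["ccf"] = [float(x) for x in res.ccf]
        else:
            entry["averaged"] = [float(x) for x in res.averaged]
        report[item_id] = entry
    if json_path is not None:
        Path(json_path).write_text(json.dumps(report, indent=1))
    if csv_path is not None:
        with Path(csv_path).open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["item", "decision", "roc_score"])
            for item_id, entry in report.items():
                writer.writerow([item_id, entry["decision"], entry["roc_score"]])
    return report
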
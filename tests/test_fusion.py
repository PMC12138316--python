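"""Fuzzy rank fusion: closed forms, reductions, and an independent oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rankfuse.fusion import (
    FusionConfig,
    FusionError,
    ProbabilityMatrix,
    fusion_auc_score,
    fuzzy_fuse,
    gompertz_fuzzy_rank,
    soft_vote,
)


def two_class(rows):
    return ProbabilityMatrix(np.array(rows, dtype=float))


# --------------------------------------------------------------------------
# independent straight-line oracle, pure math module + loops


def oracle_fuse(rows, scale=2.0):
    k = len(rows)
    c = len(rows[0])
    ranks = [[1 - math.exp(-math.exp(-scale * p)) for p in row] for row in rows]
    rank_sum = [sum(ranks[i][j] for i in range(k)) for j in range(c)]
    ccf = [1 - sum(rows[i][j] for i in range(k)) / k for j in range(c)]
    fused = [rank_sum[j] * ccf[j] for j in range(c)]
    decision = min(range(c), key=lambda j: (fused[j], j))
    return rank_sum, ccf, fused, decision


# --------------------------------------------------------------------------
# Gompertz rank transform


@pytest.mark.parametrize(
    "p, expected",
    [
        (0.0, 1 - math.exp(-1)),
        (1.0, 1 - math.exp(-math.exp(-2))),
        (0.5, 1 - math.exp(-math.exp(-1))),
    ],
)
def test_gompertz_closed_form(p, expected):
    assert gompertz_fuzzy_rank(p) == pytest.approx(expected, abs=1e-12)


def test_gompertz_range_endpoints():
    s = 2.0
    lo, hi = 1 - math.exp(-math.exp(-s)), 1 - math.exp(-1)
    grid = np.linspace(0, 1, 1001)
    vals = gompertz_fuzzy_rank(grid)
    assert vals.min() == pytest.approx(lo, abs=1e-9)
    assert vals.max() == pytest.approx(hi, abs=1e-9)
    assert np.all(vals > 0) and np.all(vals < 1)


@given(
    p1=st.floats(0, 1, exclude_max=True),
    delta=st.floats(1e-9, 1.0),
)
@settings(derandomize=True, max_examples=200)
def test_gompertz_strictly_decreasing(p1, delta):
    p2 = min(1.0, p1 + delta)
    if p2 - p1 > 1e-12:  # below this gap R(p1) and R(p2) collide in float64
        assert gompertz_fuzzy_rank(p1) > gompertz_fuzzy_rank(p2)


@pytest.mark.parametrize("bad", [-0.01, 1.01])
def test_gompertz_domain_error(bad):
    with pytest.raises(FusionError):
        gompertz_fuzzy_rank(bad)


@pytest.mark.parametrize("scale", [0.0, -1.0])
def test_nonpositive_scale_rejected(scale):
    with pytest.raises(FusionError):
        FusionConfig(gompertz_scale=scale)


# --------------------------------------------------------------------------
# fuzzy_fuse


def test_unanimous_certainty():
    res = fuzzy_fuse(two_class([[1, 0]] * 3))
    assert res.decision == 0
    assert res.ccf == pytest.approx([0.0, 1.0])
    assert res.fused_score[0] == 0.0
    assert res.fused_score[1] == pytest.approx(3 * (1 - math.exp(-1)), abs=1e-9)


def test_fused_score_identity(random_matrices):
    for pm in random_matrices[:50]:
        res = fuzzy_fuse(pm)
        assert np.allclose(res.fused_score, res.rank_sum * res.ccf, atol=1e-12)
        assert np.all(res.rank_matrix > 0) and np.all(res.rank_matrix < 1)


def test_single_classifier_reduces_to_argmax():
    for p in np.arange(0.0, 1.0001, 0.01):
        pm = two_class([[1 - p, p]])
        res = fuzzy_fuse(pm)
        assert res.decision == int(np.argmax(pm.values[0]))
        assert soft_vote(pm).decision == res.decision


def test_identical_rows_reduce_to_argmax():
    for p in np.arange(0.0, 1.0001, 0.01):
        res = fuzzy_fuse(two_class([[1 - p, p]] * 3))
        assert res.decision == (1 if p > 0.5 else 0)


def test_matches_oracle_on_seeded_matrices(random_matrices):
    for pm in random_matrices:
        rank_sum, ccf, fused, decision = oracle_fuse(pm.values.tolist())
        res = fuzzy_fuse(pm)
        assert np.allclose(res.rank_sum, rank_sum, atol=1e-12)
        assert np.allclose(res.ccf, ccf, atol=1e-12)
        assert np.allclose(res.fused_score, fused, atol=1e-12)
        assert res.decision == decision


def test_worked_three_classifier_example():
    rows = [[0.9, 0.1], [0.8, 0.2], [0.4, 0.6]]
    rank_sum, ccf, fused, decision = oracle_fuse(rows)
    res = fuzzy_fuse(two_class(rows))
    assert res.decision == decision == 0
    assert res.fused_score == pytest.approx(fused, abs=1e-12)


def test_classifier_permutation_invariance(rng):
    p_fake = rng.random(4)
    rows = np.column_stack([1 - p_fake, p_fake])
    base = fuzzy_fuse(ProbabilityMatrix(rows.copy()))
    perm = rng.permutation(4)
    shuffled = fuzzy_fuse(ProbabilityMatrix(rows[perm]))
    assert shuffled.decision == base.decision
    assert np.allclose(shuffled.fused_score, base.fused_score)
    assert np.allclose(shuffled.rank_matrix, base.rank_matrix[perm])


def test_raising_class_confidence_never_raises_its_fused_score(rng):
    # bump p[k, c] by delta, renormalize within the row's other classes
    for _ in range(200):
        k = int(rng.integers(1, 5))
        rows = rng.dirichlet(np.ones(3), size=k)
        i = int(rng.integers(0, k))
        c = int(rng.integers(0, 3))
        delta = float(rng.uniform(0, 1 - rows[i, c]))
        bumped = rows.copy()
        bumped[i, c] += delta
        others = [j for j in range(3) if j != c]
        rest = rows[i, others].sum()
        if rest > 0:
            bumped[i, others] = rows[i, others] * (rest - delta) / rest
        before = fuzzy_fuse(ProbabilityMatrix(rows)).fused_score[c]
        after = fuzzy_fuse(ProbabilityMatrix(bumped)).fused_score[c]
        assert after <= before + 1e-12


def test_invalid_rows_reported_by_index():
    pm = two_class([[0.5, 0.5], [0.7, 0.6]])
    with pytest.raises(FusionError, match="row 1"):
        fuzzy_fuse(pm)


def test_renormalize_tolerates_float_noise():
    pm = two_class([[0.5 + 4e-7, 0.5 - 2e-7]])
    res = fuzzy_fuse(pm, renormalize=True)
    assert res.decision == 0


# --------------------------------------------------------------------------
# soft voting


def test_soft_vote_mean_and_weights():
    pm = two_class([[0.6, 0.4], [0.2, 0.8]])
    res = soft_vote(pm)
    assert res.averaged == pytest.approx([0.4, 0.6])
    assert res.decision == 1
    assert soft_vote(pm, weights=[1, 0]).decision == 0


def test_soft_vote_matches_elementwise_mean(rng):
    p_fake = rng.random(3)
    pm = two_class(np.column_stack([1 - p_fake, p_fake]))
    res = soft_vote(pm)
    assert res.averaged == pytest.approx(pm.values.mean(axis=0))
    assert res.averaged.sum() == pytest.approx(1.0)


def test_soft_vote_weight_errors():
    pm = two_class([[0.6, 0.4], [0.2, 0.8]])
    with pytest.raises(FusionError):
        soft_vote(pm, weights=[-1, 2])
    with pytest.raises(FusionError):
        soft_vote(pm, weights=[0, 0])


# --------------------------------------------------------------------------
# ROC scores from fusion


def test_roc_score_extremes_and_symmetry():
    genuine = fuzzy_fuse(two_class([[1, 0]] * 3))
    assert genuine.roc_score == 0.0
    fake_leaning = fuzzy_fuse(two_class([[0.1, 0.9]] * 3))
    assert fake_leaning.roc_score > 0.5
    symmetric = fuzzy_fuse(two_class([[0.5, 0.5]] * 3))
    assert symmetric.roc_score == pytest.approx(0.5)
    assert fusion_auc_score([genuine, fake_leaning, symmetric]) == pytest.approx(
        [genuine.roc_score, fake_leaning.roc_score, 0.5]
    )


def test_roc_score_unsupported_for_multiclass(rng):
    pm = ProbabilityMatrix(rng.dirichlet(np.ones(3), size=2))
    res = fuzzy_fuse(pm)
    assert res.roc_score is None
    with pytest.raises(FusionError):
        fusion_auc_score([res])
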
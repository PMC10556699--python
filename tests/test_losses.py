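"""Loss-function tests: closed forms, mask semantics, and a brute-force
per-pixel/per-negative oracle for the directional contrastive loss."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from echoseg.losses import (DCLossConfig, MaskPair, ValidationError,
                            confidence_filter, cross_entropy, dc_loss,
                            dc_loss_one_direction, directional_mask,
                            similarity_kernel, unsupervised_loss)
from echoseg.nn.tensor import Tensor

from conftest import random_prob_map


# ---------------------------------------------------------------------------
# independent scalar reference implementations
# ---------------------------------------------------------------------------
def naive_kernel(a, b, tau):
    a, b = np.asarray(a, float).ravel(), np.asarray(b, float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    cos = 0.0 if na == 0 or nb == 0 else float(a @ b) / (na * nb)
    return np.exp(cos / tau)


def naive_dc_one_direction(emb1, emb2, mask, negatives, tau):
    """Scalar double loop over grid locations and negatives."""
    d, h, w = emb1.shape
    total, n_loc = 0.0, h * w
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            pos = naive_kernel(emb1[:, r, c], emb2[:, r, c], tau)
            denom = pos
            negs = negatives[r * w + c] if isinstance(negatives, list) \
                else negatives
            for nv in negs:
                denom += naive_kernel(emb1[:, r, c], nv, tau)
            # the loss definition clamps the log argument at 1e-12
            total -= np.log(max(pos / denom, 1e-12))
    return total / n_loc


# ---------------------------------------------------------------------------
def test_cross_entropy_closed_forms():
    uniform = np.full((4, 3, 3), 0.25)
    target = np.zeros((3, 3), dtype=int)
    assert cross_entropy(uniform, target).item() == pytest.approx(np.log(4))

    # two pixels with true-class probabilities 0.5 and 0.25
    p = np.zeros((4, 1, 2))
    p[0, 0, 0], p[1:, 0, 0] = 0.5, 0.5 / 3
    p[0, 0, 1], p[1:, 0, 1] = 0.25, 0.25
    expected = (np.log(2) + np.log(4)) / 2
    assert cross_entropy(p, np.zeros((1, 2), int)).item() == pytest.approx(expected)

    onehot = np.zeros((4, 2, 2))
    onehot[1] = 1.0
    assert cross_entropy(onehot, np.ones((2, 2), int)).item() == pytest.approx(0.0)


def test_cross_entropy_rejects_mismatched_shapes():
    with pytest.raises(ValidationError):
        cross_entropy(np.full((4, 3, 3), 0.25), np.zeros((2, 2), int))


def test_similarity_kernel_closed_forms():
    assert similarity_kernel([1, 2], [2, 4], 1.0) == pytest.approx(np.e)
    assert similarity_kernel([1, 0], [0, 1], 0.5) == pytest.approx(1.0)
    assert similarity_kernel([1, 0], [-1, 0], 0.1) == pytest.approx(np.exp(-10))
    # zero vectors are defined to have cosine 0
    assert similarity_kernel([0, 0], [1, 1], 0.5) == pytest.approx(1.0)


def test_similarity_kernel_is_symmetric(rng):
    for _ in range(20):
        a, b = rng.normal(size=3), rng.normal(size=3)
        tau = rng.uniform(0.05, 2.0)
        assert similarity_kernel(a, b, tau) == pytest.approx(
            similarity_kernel(b, a, tau))


def test_directional_mask_strictness_and_swap_complement(rng):
    p = random_prob_map(rng)
    assert directional_mask(p, p).sum() == 0  # strict inequality

    for _ in range(50):
        p1, p2 = random_prob_map(rng), random_prob_map(rng)
        m12, m21 = directional_mask(p1, p2), directional_mask(p2, p1)
        ties = p1.max(axis=0) == p2.max(axis=0)
        assert np.array_equal((m12 + m21)[~ties], np.ones((~ties).sum()))
        assert np.all((m12 + m21)[ties] == 0)


def test_confidence_filter_semantics(rng):
    p1, p2 = random_prob_map(rng), random_prob_map(rng)
    md = directional_mask(p1, p2)
    pair0 = confidence_filter(md, p2, 0.0)
    assert np.array_equal(pair0.filtered, md)  # every max prob > 0
    pair1 = confidence_filter(md, p2, 1.0)
    assert pair1.filtered.sum() == 0
    # an unconfident positive (0.7 <= gamma 0.75) is dropped
    p_low = np.full((4, 1, 1), 0.1)
    p_low[2] = 0.7
    pair = confidence_filter(np.ones((1, 1), np.uint8), p_low, 0.75)
    assert pair.filtered[0, 0] == 0


@given(st.integers(0, 10_000))
@settings(max_examples=50, deadline=None)
def test_filtered_mask_never_exceeds_directional(seed):
    rng = np.random.default_rng(seed)
    p1, p2 = random_prob_map(rng), random_prob_map(rng)
    gamma = rng.uniform(0, 1)
    pair = confidence_filter(directional_mask(p1, p2), p2, gamma)
    assert np.all(pair.filtered <= pair.directional)


def test_mask_pair_rejects_filtered_exceeding_directional():
    with pytest.raises(ValidationError):
        MaskPair(directional=np.zeros((2, 2), np.uint8),
                 filtered=np.ones((2, 2), np.uint8))


# ---------------------------------------------------------------------------
def test_dc_loss_no_negatives_is_zero(rng):
    cfg = DCLossConfig()
    e1, e2 = rng.normal(size=(5, 4, 4)), rng.normal(size=(5, 4, 4))
    loss = dc_loss_one_direction(e1, e2, np.ones((4, 4)), None, cfg)
    assert loss.item() == pytest.approx(0.0)


def test_dc_loss_one_equal_negative_gives_ln2(rng):
    cfg = DCLossConfig()
    e1 = rng.normal(size=(5, 4, 4))
    # positive identical to anchor, one negative identical to anchor
    neg = e1.reshape(5, -1).T[:, None, :]
    loss = dc_loss_one_direction(e1, e1, np.ones((4, 4)), neg, cfg)
    assert loss.item() == pytest.approx(np.log(2), abs=1e-10)


def test_dc_loss_temperature_limit_ln_1_plus_k(rng):
    k = 3
    cfg = DCLossConfig(temperature=1e6)
    e1, e2 = rng.normal(size=(5, 3, 3)), rng.normal(size=(5, 3, 3))
    neg = rng.normal(size=(k, 5))
    loss = dc_loss_one_direction(e1, e2, np.ones((3, 3)), neg, cfg)
    assert loss.item() == pytest.approx(np.log(1 + k), rel=1e-5)


def test_dc_loss_matches_bruteforce_oracle(rng):
    for _ in range(100):
        h, w = rng.integers(1, 7, size=2)
        d = int(rng.integers(2, 6))
        m = int(rng.integers(0, 9))
        tau = float(rng.uniform(0.05, 1.0))
        cfg = DCLossConfig(temperature=tau)
        e1, e2 = rng.normal(size=(d, h, w)), rng.normal(size=(d, h, w))
        mask = rng.integers(0, 2, size=(h, w))
        neg = rng.normal(size=(m, d)) if m else None
        got = dc_loss_one_direction(e1, e2, mask, neg, cfg).item()
        want = naive_dc_one_direction(
            e1, e2, mask, np.zeros((0, d)) if neg is None else neg, tau)
        assert got == pytest.approx(want, abs=1e-5)


def test_dc_loss_per_anchor_negatives_match_oracle(rng):
    h = w = 3
    d = 4
    cfg = DCLossConfig(temperature=0.3)
    e1, e2 = rng.normal(size=(d, h, w)), rng.normal(size=(d, h, w))
    neg = rng.normal(size=(h * w, 5, d))
    got = dc_loss_one_direction(e1, e2, np.ones((h, w)), neg, cfg).item()
    want = naive_dc_one_direction(e1, e2, np.ones((h, w)),
                                  [list(neg[i]) for i in range(h * w)], 0.3)
    assert got == pytest.approx(want, abs=1e-5)


def test_dc_loss_monotone_in_negatives(rng):
    cfg = DCLossConfig(temperature=0.5)
    e1, e2 = rng.normal(size=(4, 3, 3)), rng.normal(size=(4, 3, 3))
    mask = np.ones((3, 3))
    negs = rng.normal(size=(6, 4))
    prev = dc_loss_one_direction(e1, e2, mask, None, cfg).item()
    for m in range(1, 7):
        cur = dc_loss_one_direction(e1, e2, mask, negs[:m], cfg).item()
        assert cur >= prev - 1e-12
        prev = cur


def test_dc_loss_symmetric_under_view_swap(rng):
    cfg = DCLossConfig(confidence_threshold=0.3)
    pairs, swapped = [], []
    for _ in range(3):
        e1, e2 = rng.normal(size=(4, 3, 3)), rng.normal(size=(4, 3, 3))
        p1, p2 = random_prob_map(rng, h=3, w=3), random_prob_map(rng, h=3, w=3)
        pairs.append((e1, e2, p1, p2))
        swapped.append((e2, e1, p2, p1))
    neg = rng.normal(size=(5, 4))
    assert dc_loss(pairs, neg, cfg).item() == pytest.approx(
        dc_loss(swapped, neg, cfg).item())


def test_dc_loss_batch_average_invariance(rng):
    cfg = DCLossConfig(confidence_threshold=0.2)
    e1, e2 = rng.normal(size=(4, 3, 3)), rng.normal(size=(4, 3, 3))
    p1, p2 = random_prob_map(rng, h=3, w=3), random_prob_map(rng, h=3, w=3)
    neg = rng.normal(size=(4, 4))
    one = dc_loss([(e1, e2, p1, p2)], neg, cfg).item()
    four = dc_loss([(e1, e2, p1, p2)] * 4, neg, cfg).item()
    assert four == pytest.approx(one)


def test_dc_loss_gradients_are_finite(rng):
    cfg = DCLossConfig(temperature=0.1)
    e1 = Tensor(rng.normal(size=(4, 3, 3)), requires_grad=True)
    e2 = Tensor(rng.normal(size=(4, 3, 3)), requires_grad=True)
    neg = Tensor(rng.normal(size=(6, 4)), requires_grad=True)
    loss = dc_loss_one_direction(e1, e2, np.ones((3, 3)), neg, cfg)
    loss.backward()
    for t in (e1, e2, neg):
        assert np.all(np.isfinite(t.grad))


def test_dc_loss_empty_grid_returns_zero():
    cfg = DCLossConfig()
    loss = dc_loss_one_direction(np.zeros((4, 0, 3)), np.zeros((4, 0, 3)),
                                 np.zeros((0, 3)), None, cfg)
    assert loss.item() == 0.0


# ---------------------------------------------------------------------------
def test_unsupervised_loss_components_recombine(rng):
    cfg = DCLossConfig(lambda_weight=0.1, confidence_threshold=0.2)
    p1, p2 = random_prob_map(rng, h=3, w=3), random_prob_map(rng, h=3, w=3)
    e1, e2 = rng.normal(size=(4, 3, 3)), rng.normal(size=(4, 3, 3))
    neg = rng.normal(size=(5, 4))
    parts = unsupervised_loss(p1, p2, e1, e2, neg, cfg)
    assert parts.total.item() == pytest.approx(
        parts.pseudo_ce.item() + 0.1 * parts.dc.item(), abs=1e-7)


def test_unsupervised_loss_lambda_zero_is_pure_pseudo_ce(rng):
    cfg = DCLossConfig(lambda_weight=0.0, confidence_threshold=0.2)
    p1, p2 = random_prob_map(rng, h=3, w=3), random_prob_map(rng, h=3, w=3)
    e1, e2 = rng.normal(size=(4, 3, 3)), rng.normal(size=(4, 3, 3))
    parts = unsupervised_loss(p1, p2, e1, e2, None, cfg)
    assert parts.total.item() == pytest.approx(parts.pseudo_ce.item())


def test_unsupervised_loss_identical_confident_views_vanishes():
    cfg = DCLossConfig()
    p = np.full((4, 3, 3), 1e-4)
    p[1] = 1.0 - 3e-4  # very confident LV everywhere
    e = np.random.default_rng(0).normal(size=(4, 3, 3))
    parts = unsupervised_loss(p, p, e, e, None, cfg)
    assert parts.total.item() == pytest.approx(0.0, abs=1e-3)
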
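import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wavediv.distributions import ClassReference
from wavediv.divergence import (
    WeightVector,
    compute_weights,
    hellinger,
    jsd,
    jsd_printed,
    triangle,
)
from wavediv.exceptions import ConfigurationError, ValidationError


# --- independent direct evaluations of the defining formulas ---------------

def jsd_direct(p, q):
    total = 0.0
    for pi, qi in zip(p, q):
        mi = 0.5 * (pi + qi)
        if pi > 0:
            total += 0.5 * pi * math.log2(pi / mi)
        if qi > 0:
            total += 0.5 * qi * math.log2(qi / mi)
    return total


def hellinger_direct(p, q):
    return 0.5 * sum((math.sqrt(pi) - math.sqrt(qi)) ** 2 for pi, qi in zip(p, q))


def triangle_direct(p, q):
    total = 0.0
    for pi, qi in zip(p, q):
        if pi + qi > 0:
            total += (pi - qi) ** 2 / (pi + qi)
    return 0.5 * total


DIVERGENCES = [(jsd, jsd_direct), (hellinger, hellinger_direct),
               (triangle, triangle_direct)]


def prob_vectors(n):
    return st.lists(
        st.floats(min_value=1e-6, max_value=1.0), min_size=n, max_size=n
    ).map(lambda xs: np.array(xs) / np.sum(xs))


@settings(max_examples=150, derandomize=True, deadline=None)
@given(data=st.data(), n=st.integers(min_value=2, max_value=32))
def test_divergence_axioms(data, n):
    """Symmetry, [0,1] range, identity of indiscernibles, and agreement
    with a direct evaluation of each defining formula."""
    p = data.draw(prob_vectors(n))
    q = data.draw(prob_vectors(n))
    for func, direct in DIVERGENCES:
        d_pq, d_qp = func(p, q), func(q, p)
        assert d_pq == pytest.approx(d_qp, abs=1e-12)
        assert -1e-12 <= d_pq <= 1 + 1e-12
        assert func(p, p) == pytest.approx(0.0, abs=1e-12)
        assert d_pq == pytest.approx(direct(p, q), abs=1e-12)


def test_disjoint_support_reaches_maximum():
    p = np.array([1.0, 0.0])
    q = np.array([0.0, 1.0])
    assert jsd(p, q) == pytest.approx(1.0)
    assert hellinger(p, q) == pytest.approx(1.0)
    assert triangle(p, q) == pytest.approx(1.0)


def test_worked_two_bin_examples():
    p = np.array([0.5, 0.5])
    q = np.array([0.9, 0.1])
    assert triangle(p, q) == pytest.approx(
        0.5 * (0.4**2 / 1.4 + 0.4**2 / 0.6)
    )
    assert jsd(p, q) == pytest.approx(jsd_direct(p, q), abs=1e-14)


def test_validation_errors():
    with pytest.raises(ValidationError, match="length"):
        jsd(np.array([0.5, 0.5]), np.array([1.0]))
    with pytest.raises(ValidationError, match="sum"):
        hellinger(np.array([0.5, 0.6]), np.array([0.5, 0.5]))
    with pytest.raises(ValidationError, match="negative"):
        triangle(np.array([1.1, -0.1]), np.array([0.5, 0.5]))


def test_nested_mixtures_are_monotone(rng):
    """D(p, (1-lam) p + lam r) is non-decreasing in lam for each measure."""
    for _ in range(10):
        p = rng.dirichlet(np.ones(16))
        r = rng.dirichlet(np.ones(16))
        for func, _ in DIVERGENCES:
            prev = -1.0
            for lam in np.linspace(0, 1, 11):
                d = func(p, (1 - lam) * p + lam * r)
                assert d >= prev - 1e-12
                prev = d


def test_jsd_printed_variant_is_clipped():
    p = np.array([0.7, 0.3])
    q = np.array([0.2, 0.8])
    v = jsd_printed(p, q)
    assert 0.0 <= v <= 1.0
    assert jsd_printed(p, p) == pytest.approx(0.0, abs=1e-9)


# --- weighting --------------------------------------------------------------

def make_reference(class_probs, pooled, attrs=None):
    n_attr, n_bins = pooled.shape
    attrs = attrs or [f"a{i}" for i in range(n_attr)]
    return ClassReference(
        modality="SEM",
        attributes=attrs,
        bin_edges=np.tile(np.linspace(0, 1, n_bins + 1), (n_attr, 1)),
        class_probs=class_probs,
        pooled_probs=pooled,
        rates={c: np.ones(n_attr) for c in class_probs},
        shift_min=np.zeros(n_attr),
        shift_delta=np.zeros(n_attr),
        stage_ranges={},
        bandwidth=1.0,
        n_train=30,
    )


def test_identical_class_distributions_give_uniform_weights():
    uniform = np.full((5, 8), 1 / 8)
    ref = make_reference(
        {c: uniform.copy() for c in ("normal", "benign", "malignant")}, uniform
    )
    wv = compute_weights(None, ref, "TD")
    np.testing.assert_allclose(wv.weights, 0.2)
    assert wv.weights.sum() == pytest.approx(1.0, abs=1e-9)


def test_single_separating_attribute_takes_all_weight():
    uniform = np.full(8, 1 / 8)
    a = np.array([0.97] + [0.03 / 7] * 7)
    b = np.array([0.03 / 7] * 7 + [0.97])
    probs = {
        "normal": np.vstack([uniform, a]),
        "benign": np.vstack([uniform, 0.5 * (a + b)]),
        "malignant": np.vstack([uniform, b]),
    }
    ref = make_reference(probs, np.vstack([uniform, uniform]))
    wv = compute_weights(None, ref, "HD")
    assert wv.weights[1] == pytest.approx(1.0, abs=1e-6)
    assert wv.weights[0] == pytest.approx(0.0, abs=1e-6)


def test_weights_match_hand_evaluation():
    """Three attributes, hand-built distributions: weights reproduce the
    spreadsheet-style evaluation of pair-averaged divergence over entropy."""
    n = np.array([[0.8, 0.2, 0.0, 0.0],
                  [0.25, 0.25, 0.25, 0.25],
                  [0.6, 0.4, 0.0, 0.0]])
    b = np.array([[0.0, 0.8, 0.2, 0.0],
                  [0.25, 0.25, 0.25, 0.25],
                  [0.5, 0.5, 0.0, 0.0]])
    m = np.array([[0.0, 0.0, 0.2, 0.8],
                  [0.25, 0.25, 0.25, 0.25],
                  [0.4, 0.6, 0.0, 0.0]])
    pooled = (n + b + m) / 3
    ref = make_reference({"normal": n, "benign": b, "malignant": m}, pooled)
    for kind, func in (("JSD", jsd), ("HD", hellinger), ("TD", triangle)):
        w_av = np.array([
            (func(n[i], b[i]) + func(n[i], m[i]) + func(b[i], m[i])) / 3
            for i in range(3)
        ])
        H = np.array([
            max(-np.sum(p[p > 0] * np.log2(p[p > 0])), 0.1) for p in pooled
        ])
        expected = (w_av / H) / np.sum(w_av / H)
        wv = compute_weights(None, ref, kind)
        np.testing.assert_allclose(wv.weights, expected, atol=1e-12)
        assert wv.z == pytest.approx(np.sum(w_av / H))


def test_unknown_kind_rejected():
    uniform = np.full((2, 4), 0.25)
    ref = make_reference(
        {c: uniform.copy() for c in ("normal", "benign", "malignant")}, uniform
    )
    with pytest.raises(ConfigurationError):
        compute_weights(None, ref, "KLD")
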
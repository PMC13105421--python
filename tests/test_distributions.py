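import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wavediv.distributions import (
    PROB_FLOOR,
    ClassReference,
    class_likelihood,
    compute_stage_ranges,
    estimate_distribution,
    fit_exponential,
    point_mass_columns,
    shared_bin_edges,
    train_reference,
)
from wavediv.exceptions import ConfigurationError, EstimationError


def tiny_reference(rates_by_class, n_attr=1, shift_min=None, shift_delta=None):
    """Hand-built reference with uniform distributions, for likelihood tests."""
    edges = np.tile(np.linspace(0.0, 1.0, 65), (n_attr, 1))
    uniform = np.full((n_attr, 64), 1.0 / 64)
    return ClassReference(
        modality="SEM",
        attributes=[f"a{i}" for i in range(n_attr)],
        bin_edges=edges,
        class_probs={c: uniform.copy() for c in rates_by_class},
        pooled_probs=uniform.copy(),
        rates={c: np.asarray(r, dtype=float) for c, r in rates_by_class.items()},
        shift_min=np.zeros(n_attr) if shift_min is None else np.asarray(shift_min),
        shift_delta=np.zeros(n_attr) if shift_delta is None else np.asarray(shift_delta),
        stage_ranges={},
        bandwidth=1.0,
        n_train=0,
    )


def test_point_mass_with_zero_bandwidth():
    edges = np.linspace(0, 1, 65)
    dist = estimate_distribution(np.full(10, 0.5), edges, bandwidth=0.0)
    j = np.argmax(dist.probabilities)
    assert dist.probabilities[j] > 1 - 64 * PROB_FLOOR * 2
    assert dist.probabilities.min() >= PROB_FLOOR / 2
    assert dist.probabilities.sum() == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize("bandwidth", [0.0, 1.0, 2.5])
def test_output_always_sums_to_one(rng, bandwidth):
    values = rng.normal(size=200)
    edges = shared_bin_edges(values)
    dist = estimate_distribution(values, edges, bandwidth)
    assert dist.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(dist.probabilities >= PROB_FLOOR / 2)


def test_uniform_values_stay_near_uniform(rng):
    edges = np.linspace(0, 1, 65)
    values = rng.uniform(0, 1, size=10_000)
    dist = estimate_distribution(values, edges, bandwidth=1.0)
    ratio = dist.probabilities.max() / dist.probabilities.min()
    assert ratio <= 1.25  # sampling noise at n=1e4; smoothing keeps it tight


def test_exactly_uniform_histogram_is_preserved():
    # one value per bin: reflect-boundary smoothing must not distort it
    edges = np.linspace(0, 64, 65)
    values = np.arange(64) + 0.5
    dist = estimate_distribution(values, edges, bandwidth=1.0)
    assert dist.probabilities.max() / dist.probabilities.min() <= 1.0 + 1e-9


def test_values_outside_edges_are_clipped_with_warning():
    edges = np.linspace(0, 1, 65)
    with pytest.warns(UserWarning, match="clipped"):
        dist = estimate_distribution(np.array([-1.0, 0.5, 2.0]), edges, 0.0)
    assert dist.probabilities.sum() == pytest.approx(1.0, abs=1e-9)


def test_empty_input_raises():
    with pytest.raises(EstimationError):
        estimate_distribution(np.array([]), np.linspace(0, 1, 65))


def test_point_mass_columns_are_distributions():
    K = point_mass_columns(64, 1.0)
    assert K.shape == (64, 64)
    np.testing.assert_allclose(K.sum(axis=0), 1.0, atol=1e-9)
    assert np.all(K.argmax(axis=0) == np.arange(64))


def test_exponential_mle_closed_form():
    assert fit_exponential(np.array([2.0, 2.0])) == pytest.approx(0.5)
    assert fit_exponential(np.array([1.0])) == pytest.approx(1.0)
    with pytest.raises(EstimationError):
        fit_exponential(np.array([]))
    with pytest.raises(EstimationError):
        fit_exponential(np.zeros(5))


def test_exponential_rate_recovery():
    rng = np.random.default_rng(99)
    draws = rng.exponential(scale=1 / 3.0, size=100_000)
    lam = fit_exponential(draws)
    se = 3.0 / np.sqrt(draws.size)
    assert abs(lam - 3.0) <= 3 * se


def test_class_likelihood_trivial_identities():
    ref = tiny_reference({"normal": [1.0], "benign": [1.0], "malignant": [1.0]})
    # lambda = 1, shifted x' = 0 -> log 1 - 0 = 0
    assert class_likelihood(np.array([0.0]), ref, "normal") == pytest.approx(0.0)
    ref2 = tiny_reference(
        {"normal": [2.0, 2.0], "benign": [1.0, 1.0], "malignant": [1.0, 1.0]},
        n_attr=2,
    )
    single = tiny_reference({"normal": [2.0], "benign": [1.0], "malignant": [1.0]})
    x = 0.3
    assert class_likelihood(np.array([x, x]), ref2, "normal") == pytest.approx(
        2 * class_likelihood(np.array([x]), single, "normal")
    )


def test_class_likelihood_matches_density_product():
    """argmax of the summed log-likelihood equals the argmax of the
    brute-force product of exponential densities."""
    rates = {"normal": [0.5, 3.0], "benign": [1.0, 1.0], "malignant": [4.0, 0.2]}
    ref = tiny_reference(rates, n_attr=2)
    rng = np.random.default_rng(3)
    for _ in range(20):
        x = rng.uniform(0, 2, size=2)
        lls = {c: class_likelihood(x, ref, c) for c in rates}
        brute = {
            c: np.prod([stats.expon(scale=1 / l).pdf(v)
                        for l, v in zip(rates[c], x)])
            for c in rates
        }
        assert max(lls, key=lls.get) == max(brute, key=brute.get)
        for c in rates:
            assert lls[c] == pytest.approx(np.log(brute[c]))


def test_class_likelihood_attribute_mismatch():
    ref = tiny_reference({"normal": [1.0], "benign": [1.0], "malignant": [1.0]})
    with pytest.raises(ConfigurationError):
        class_likelihood(np.array([0.1, 0.2]), ref, "normal")


def _toy_training():
    rows = []
    rng = np.random.default_rng(0)
    for label, lo in (("normal", 0.0), ("benign", 10.0), ("malignant", 20.0)):
        for j in range(20):
            rows.append({
                "source_id": f"{label}{j}", "patch_index": 0,
                "modality": "SEM", "label": label,
                "x": lo + rng.uniform(0, 1),
            })
    return pd.DataFrame(rows)


def test_stage_ranges_disjoint_classes():
    ranges = compute_stage_ranges(_toy_training())["x"]
    assert ranges["normal"][1] < ranges["benign"][0] < ranges["benign"][1] \
        < ranges["malignant"][0]


def test_stage_ranges_missing_class_raises():
    df = _toy_training()
    with pytest.raises(ConfigurationError):
        compute_stage_ranges(df[df["label"] != "benign"])


def test_train_reference_shares_bin_edges_across_classes():
    ref = train_reference(_toy_training(), "SEM", n_bins=32)
    assert ref.bin_edges.shape == (1, 33)
    for c in ("normal", "benign", "malignant"):
        assert ref.class_probs[c].shape == (1, 32)
        assert ref.class_probs[c].sum() == pytest.approx(1.0, abs=1e-9)
        assert ref.rates[c][0] > 0
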
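"""CSP filters against analytic cases and a dense generalized-eig oracle."""

import numpy as np
import pytest
from scipy import linalg

import erdkit
from erdkit.csp import CSPModel
from conftest import make_trials


def _gauss_trials(rng, n_per_class, n_channels, n_samples, mixing_a, mixing_b):
    """Two-class trials: white sources mixed by class-specific matrices."""
    data, labels = [], []
    for mixing, label in ((mixing_a, "A"), (mixing_b, "B")):
        src = rng.standard_normal((n_per_class, n_channels, n_samples))
        data.append(np.einsum("cd,tds->tcs", mixing, src))
        labels += [label] * n_per_class
    return make_trials(np.concatenate(data), labels=labels)


def _oracle_csp(trials, reg=1e-10):
    """Independent dense generalized-eigendecomposition reference."""
    covs = {}
    for label in trials.conditions:
        sub = trials.select_condition(label).data
        per_trial = []
        for x in sub:
            c = x @ x.T
            per_trial.append(c / np.trace(c))
        covs[label] = np.mean(per_trial, axis=0)
    s1, s2 = (covs[c] for c in trials.conditions)
    comp = s1 + s2
    comp = comp + reg * (np.trace(comp) / comp.shape[0]) * np.eye(comp.shape[0])
    lam, vec = linalg.eigh(s1, comp)
    order = np.argsort(lam)[::-1]
    return lam[order], vec[:, order]


def _fix_signs(filters):
    signs = np.sign(filters[np.abs(filters).argmax(axis=0),
                            np.arange(filters.shape[1])])
    return filters * np.where(signs == 0, 1.0, signs)


def test_identical_class_distributions_give_half_eigenvalues():
    rng = np.random.default_rng(0)
    eye = np.eye(4)
    trials = _gauss_trials(rng, 100, 4, 200, eye, eye)
    model = erdkit.fit_csp(trials, n_pairs=2)
    assert np.abs(model.eigenvalues - 0.5).max() < 0.05


def test_two_channel_toy_recovers_axis_filters():
    rng = np.random.default_rng(1)
    a = np.diag([1.0, 0.05])  # class A variance on channel 1 only
    b = np.diag([0.05, 1.0])  # class B variance on channel 2 only
    trials = _gauss_trials(rng, 50, 2, 300, a, b)
    model = erdkit.fit_csp(trials, n_pairs=1)
    top = model.filters[:, 0] / np.linalg.norm(model.filters[:, 0])
    assert abs(top[0]) >= 0.99  # aligned with channel-1 axis
    feats = erdkit.csp_features(model, trials)
    fa = feats.features[feats.labels == "A"]
    fb = feats.features[feats.labels == "B"]
    pooled = np.sqrt((fa.var(axis=0, ddof=1) + fb.var(axis=0, ddof=1)) / 2)
    separation = np.abs(fa.mean(axis=0) - fb.mean(axis=0)) / pooled
    assert (separation >= 2.0).all()


@pytest.mark.parametrize("instance", range(20))
def test_whitening_implementation_matches_dense_oracle(instance):
    rng = np.random.default_rng(100 + instance)
    n_ch = 4
    mix_a = rng.standard_normal((n_ch, n_ch)) + 0.5 * np.eye(n_ch)
    mix_b = rng.standard_normal((n_ch, n_ch)) + 0.5 * np.eye(n_ch)
    trials = _gauss_trials(rng, 12, n_ch, 64, mix_a, mix_b)
    model = erdkit.fit_csp(trials, n_pairs=2)
    lam_o, vec_o = _oracle_csp(trials)
    np.testing.assert_allclose(model.eigenvalues, np.clip(lam_o, 0, 1),
                               atol=1e-8)
    np.testing.assert_allclose(model.filters, _fix_signs(vec_o), atol=1e-8)
    # composite-whitening contract: W.T (S1 + S2) W = I
    prod = model.filters.T @ (
        _class_cov(trials, "A") + _class_cov(trials, "B")
    ) @ model.filters
    np.testing.assert_allclose(prod, np.eye(n_ch), atol=1e-7)


def _class_cov(trials, label):
    sub = trials.select_condition(label).data
    covs = [x @ x.T / np.trace(x @ x.T) for x in sub]
    return np.mean(covs, axis=0)


def test_eigenvalue_pairing_under_class_swap():
    rng = np.random.default_rng(2)
    a = np.diag([1.0, 0.3, 0.6])
    b = np.diag([0.3, 1.0, 0.6])
    trials = _gauss_trials(rng, 30, 3, 128, a, b)
    model = erdkit.fit_csp(trials, n_pairs=1)
    swapped = trials.copy()
    swapped.condition_labels = np.where(
        trials.condition_labels == "A", "B", "A"
    ).astype(object)
    model_sw = erdkit.fit_csp(swapped, n_pairs=1)
    np.testing.assert_allclose(
        np.sort(model_sw.eigenvalues), np.sort(1.0 - model.eigenvalues),
        atol=1e-8,
    )


def test_channel_permutation_permutes_filters_and_keeps_features():
    rng = np.random.default_rng(3)
    a = np.diag([1.0, 0.2, 0.5, 0.8])
    b = np.diag([0.2, 1.0, 0.8, 0.5])
    trials = _gauss_trials(rng, 20, 4, 128, a, b)
    perm = np.array([2, 0, 3, 1])
    permuted = make_trials(
        trials.data[:, perm, :], labels=trials.condition_labels.tolist()
    )
    m1 = erdkit.fit_csp(trials, n_pairs=2)
    m2 = erdkit.fit_csp(permuted, n_pairs=2)
    np.testing.assert_allclose(m2.filters, m1.filters[perm], atol=1e-8)
    f1 = erdkit.csp_features(m1, trials).features
    f2 = erdkit.csp_features(m2, permuted).features
    np.testing.assert_allclose(f1, f2, atol=1e-10)


def test_identity_filters_on_symmetric_channels_give_log_half():
    rng = np.random.default_rng(4)
    data = rng.standard_normal((40, 2, 2000))
    trials = make_trials(data, labels=["A", "B"] * 20)
    model = CSPModel(
        filters=np.eye(2), eigenvalues=np.array([0.5, 0.5]), n_pairs=1,
        class_order=("A", "B"), channel_labels=["ch0", "ch1"],
    )
    feats = erdkit.csp_features(model, trials).features
    assert np.abs(feats - np.log(0.5)).max() < 0.1


def test_features_invariant_to_trial_scaling(strong_contrast):
    sub = strong_contrast.select_trials(range(10))
    model = erdkit.fit_csp(strong_contrast, n_pairs=2)
    f1 = erdkit.csp_features(model, sub).features
    scaled = sub.copy()
    scaled.data *= 10.0
    f2 = erdkit.csp_features(model, scaled).features
    np.testing.assert_allclose(f1, f2, rtol=1e-10)


def test_fit_rejects_bad_inputs():
    rng = np.random.default_rng(5)
    three = make_trials(rng.standard_normal((6, 2, 64)),
                        labels=["A", "B", "C"] * 2)
    with pytest.raises(ValueError, match="two classes"):
        erdkit.fit_csp(three)
    ab = make_trials(rng.standard_normal((6, 4, 64)), labels=["A", "B"] * 3)
    with pytest.raises(ValueError, match="n_pairs"):
        erdkit.fit_csp(ab, n_pairs=3)
    short = make_trials(rng.standard_normal((6, 8, 4)), labels=["A", "B"] * 3)
    with pytest.raises(ValueError, match="more samples than channels"):
        erdkit.fit_csp(short)
    flat = make_trials(np.zeros((6, 2, 64)), labels=["A", "B"] * 3)
    with pytest.raises(np.linalg.LinAlgError):
        erdkit.fit_csp(flat, n_pairs=1)


def test_model_text_round_trip(tmp_path):
    rng = np.random.default_rng(6)
    trials = make_trials(rng.standard_normal((8, 3, 64)),
                         labels=["A", "B"] * 4)
    model = erdkit.fit_csp(trials, n_pairs=1)
    path = tmp_path / "csp.tsv"
    model.to_text(path)
    back = CSPModel.from_text(path)
    np.testing.assert_allclose(back.filters, model.filters, atol=1e-10)
    np.testing.assert_allclose(back.eigenvalues, model.eigenvalues, atol=1e-10)
    assert back.class_order == model.class_order
    assert back.n_pairs == model.n_pairs
    assert back.channel_labels == model.channel_labels
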
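"""Committor network: gradients, training validity, TS bias, descriptors."""

import numpy as np
import pytest

from conftest import random_rotation
from protorelay.committor import (
    CommittorSpec,
    CommittorModel,
    KolmogorovBias,
    _loss_and_grads,
    analytic_committor_1d,
    featurize,
    train_committor,
)
from protorelay.synthetic import FixtureSpec, KB_KCAL, make_double_well, make_fixture


def test_loss_gradients_match_finite_differences(rng):
    """Analytic double-backward of the Kolmogorov loss vs central FD."""
    n, d = 10, 2
    x = rng.normal(size=(n, d))
    w = rng.random(n)
    w /= w.sum()
    labels = np.full(n, np.nan)
    labels[:3], labels[3:6] = 0.0, 1.0
    mask = ~np.isnan(labels)
    y = np.where(mask, labels, 0.0)
    sizes = (d, 6, 5, 1)
    ws = [rng.normal(0, 0.5, size=(sizes[i], sizes[i + 1])) for i in range(3)]
    bs = [rng.normal(0, 0.1, size=sizes[i + 1]) for i in range(3)]
    loss, dW, db = _loss_and_grads(ws, bs, x, w, mask, y, alpha=1.0)
    h = 1e-6
    for li in range(3):
        for arr, grads in ((ws, dW), (bs, db)):
            flat = arr[li].reshape(-1)
            for idx in range(0, flat.size, max(1, flat.size // 10)):
                flat[idx] += h
                lp, _, _ = _loss_and_grads(ws, bs, x, w, mask, y, 1.0)
                flat[idx] -= 2 * h
                lm, _, _ = _loss_and_grads(ws, bs, x, w, mask, y, 1.0)
                flat[idx] += h
                assert grads[li].reshape(-1)[idx] == pytest.approx(
                    (lp - lm) / (2 * h), abs=1e-7
                )


def test_model_input_gradient_matches_fd(rng):
    spec = CommittorSpec(n_inputs=3, hidden=(8, 8), seed=2)
    x = rng.normal(size=(5, 3))
    labels = np.array([0.0, 1.0, np.nan, np.nan, np.nan])
    model = train_committor(x, labels, spec=CommittorSpec(3, (8, 8), epochs=50, seed=2))
    pts = rng.normal(size=(4, 3))
    q, g = model.q_and_grad(pts)
    h = 1e-6
    for i in range(4):
        for j in range(3):
            dp = pts[i].copy()
            dp[j] += h
            qp = model.q(dp[None, :])[0]
            dp[j] -= 2 * h
            qm = model.q(dp[None, :])[0]
            assert g[i, j] == pytest.approx((qp - qm) / (2 * h), abs=1e-6)


@pytest.fixture(scope="module")
def toy_training():
    """Uniform samples + Boltzmann weights on the symmetric double well."""
    pot = make_double_well(5.0)
    kt = KB_KCAL * 300
    x = np.linspace(-1.3, 1.3, 600)[:, None]
    v = pot.energy(x)
    w = np.exp(-(v - v.min()) / kt)
    labels = np.full(len(x), np.nan)
    labels[x[:, 0] < -0.9] = 0.0
    labels[x[:, 0] > 0.9] = 1.0
    return pot, x, labels, w


@pytest.fixture(scope="module")
def toy_model(toy_training):
    pot, x, labels, w = toy_training
    return train_committor(x, labels, w, CommittorSpec(1, epochs=3000, seed=1))


def test_trained_committor_matches_quadrature(toy_training, toy_model):
    pot, x, labels, w = toy_training
    model = toy_model
    assert model.loss_history[-1] < model.loss_history[0]
    # symmetry forces q = 1/2 at the barrier top
    assert model.q(np.array([[0.0]]))[0] == pytest.approx(0.5, abs=0.05)
    xs, q_true = analytic_committor_1d(pot, -1.0, 1.0)
    rmse = np.sqrt(np.mean((model.q(xs[:, None]) - q_true) ** 2))
    assert rmse <= 0.05
    # basin boundary condition
    assert model.q(np.array([[-1.1]]))[0] == pytest.approx(0.0, abs=0.05)
    assert model.q(np.array([[1.1]]))[0] == pytest.approx(1.0, abs=0.05)


def test_swapped_labels_complement(toy_training, toy_model):
    pot, x, labels, w = toy_training
    swapped = train_committor(x, 1.0 - labels, w, CommittorSpec(1, epochs=3000, seed=1))
    xs = np.linspace(-1.0, 1.0, 200)[:, None]
    assert np.max(np.abs(toy_model.q(xs) + swapped.q(xs) - 1.0)) <= 0.05


def test_single_basin_data_rejected(rng):
    x = rng.normal(size=(20, 1))
    labels = np.zeros(20)
    with pytest.raises(ValueError, match="both basins"):
        train_committor(x, labels)


def test_z_is_logit_of_q(toy_model):
    xs = np.linspace(-0.5, 0.5, 50)[:, None]
    q = toy_model.q(xs)
    z = toy_model.z(xs)
    assert np.allclose(z, np.log(q / (1 - q)), atol=1e-9)
    # monotone where q is monotone
    assert (np.diff(z) > 0).all() == (np.diff(q) > 0).all()


def test_model_json_round_trip(tmp_path, toy_model):
    path = tmp_path / "model.json"
    toy_model.to_json(str(path))
    loaded = CommittorModel.from_json(str(path))
    xs = np.linspace(-1.2, 1.2, 64)[:, None]
    assert np.allclose(loaded.q(xs), toy_model.q(xs), atol=1e-12)


# ---------------------------------------------------------------------------
# transition-state bias
# ---------------------------------------------------------------------------


def test_kolmogorov_bias_contracts(toy_model):
    bias = KolmogorovBias(toy_model, lam=0.3, delta_e=20.0)
    v_ts = bias.energy(np.array([0.0]))
    assert v_ts == pytest.approx(-0.3 * 20.0, abs=0.5)  # near-maximal at q~0.5
    # maximal over a scan of q in [0.01, 0.99]
    scan = np.linspace(-1.2, 1.2, 400)
    vals = [bias.energy(np.array([s])) for s in scan]
    assert min(vals) == pytest.approx(v_ts, abs=0.05)
    # vanishing in the basins: < 1% of the TS value at q < 0.01
    deep = np.array([-1.25])
    assert toy_model.q(deep[None, :])[0] < 0.01
    assert abs(bias.energy(deep)) < 0.01 * abs(v_ts)
    # lambda = 0 -> no bias anywhere
    off = KolmogorovBias(toy_model, lam=0.0)
    assert off.energy(np.array([0.0])) == 0.0
    v, g = off.energy_and_grad(np.array([0.0]))
    assert v == 0.0 and g == (0.0,)


def test_kolmogorov_bias_gradient_matches_fd(toy_model):
    bias = KolmogorovBias(toy_model, lam=0.3)
    h = 1e-6
    for x0 in (-0.4, -0.1, 0.2):
        v, g = bias.energy_and_grad(np.array([x0]))
        fd = (bias.energy(np.array([x0 + h])) - bias.energy(np.array([x0 - h]))) / (2 * h)
        assert g[0] == pytest.approx(fd, abs=1e-5)


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------


def test_featurize_lengths_and_invariance(rng):
    f1, t1, _ = make_fixture(FixtureSpec(1, 1, 0.0, seed=4))
    d1 = featurize(f1, t1, "one_water")
    assert d1.shape == (9,) and (d1 > 0).all()

    f2, t2, _ = make_fixture(FixtureSpec(2, 2, 0.0, seed=4))
    d2 = featurize(f2, t2, "two_water")
    assert d2.shape == (13,) and (d2 > 0).all()

    R = random_rotation(rng)
    from protorelay.io_core import Frame

    rot = Frame(f2.coords @ R.T + rng.normal(size=3) * 5, f2.elements)
    assert np.allclose(featurize(rot, t2, "two_water"), d2, atol=1e-10)


def test_featurize_wrong_water_count(two_water_fixture):
    frame, topo, _ = two_water_fixture  # six waters in the topology
    with pytest.raises(ValueError, match="bridging water"):
        featurize(frame, topo, "one_water")
    with pytest.raises(ValueError, match="mode"):
        featurize(frame, topo, "three_water")
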
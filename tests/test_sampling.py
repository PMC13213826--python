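"""Langevin propagator, OPES bias properties, reweighting, k-medoids."""

import numpy as np
import pytest

from protorelay.sampling import (
    DivergenceError,
    DynamicsParams,
    FreeEnergySurface,
    OPESBias,
    kmedoids,
    langevin_run,
    reweight_fes,
    reweight_profile,
    ts_ensemble,
)
from protorelay.synthetic import (
    DoubleWell1D,
    HarmonicWell,
    KB_KCAL,
    make_double_well,
    make_surrogate,
)


def test_equipartition_in_harmonic_well():
    """Unbiased sampling variance equals kT/k per coordinate."""
    k = 2.0
    pot = HarmonicWell(k=k, dim=1)
    params = DynamicsParams(n_steps=1_000_000, seed=1, dt=0.004, x0=(0.0,))
    res = langevin_run(pot, params)
    kt = params.kt
    # Euler-Maruyama inflates the variance by 1/(1 - k dt / (2 friction))
    expected = kt / k
    assert res.positions[:, 0].var() == pytest.approx(expected, rel=0.03)
    assert abs(res.positions[:, 0].mean()) < 0.01


def test_low_temperature_descends_to_nearest_minimum():
    pot = make_double_well(5.0)
    params = DynamicsParams(n_steps=20_000, temperature=1e-4, seed=0, x0=(0.3,))
    res = langevin_run(pot, params)
    assert res.positions[-1, 0] == pytest.approx(1.0, abs=1e-2)


def test_fixed_seed_bit_identical():
    pot = make_double_well(3.0)
    params = DynamicsParams(n_steps=5_000, seed=42, x0=(-1.0,))
    r1 = langevin_run(pot, params, bias=OPESBias(grid_range=(-2, 2)))
    r2 = langevin_run(pot, params, bias=OPESBias(grid_range=(-2, 2)))
    assert np.array_equal(r1.positions, r2.positions)
    assert np.array_equal(r1.bias_energy, r2.bias_energy)


def test_divergence_reports_step():
    pot = HarmonicWell(k=-3.0, dim=1)  # repulsive: the walker escapes
    params = DynamicsParams(n_steps=50_000, seed=0, x0=(0.1,), bound=5.0)
    with pytest.raises(DivergenceError) as exc:
        langevin_run(pot, params)
    assert 0 < exc.value.step <= 50_000


# ---------------------------------------------------------------------------
# OPES bias
# ---------------------------------------------------------------------------


def test_opes_first_kernel_maximal_at_center():
    bias = OPESBias(delta_e=10.0, pace=1, grid_range=(-2, 2))
    bias.update(0.3, 1)
    assert bias.n_kernels == 1
    grid_vals = bias.v_grid
    assert bias.grid[np.argmax(grid_vals)] == pytest.approx(0.3, abs=0.01)
    v_center, _ = bias.bias_and_force(0.3)
    assert v_center == pytest.approx(grid_vals.max(), abs=1e-9)


def test_opes_cap_holds_through_deposition():
    """The deposited bias range never exceeds delta_e, epoch after epoch."""
    pot = make_double_well(5.0)
    bias = OPESBias(delta_e=20.0, grid_range=(-2, 2))
    for chunk_seed in range(5):
        params = DynamicsParams(n_steps=30_000, seed=chunk_seed, x0=(-1.0,))
        langevin_run(pot, params, bias=bias)
        assert bias.bias_range() <= 20.0 + 1e-9
        assert bias.v_grid.max() <= 1e-12


def test_opes_zero_barrier_means_zero_bias():
    pot = make_double_well(2.0)
    bias = OPESBias(delta_e=0.0, grid_range=(-2, 2))
    params = DynamicsParams(n_steps=20_000, seed=3, x0=(-1.0,))
    unbiased = langevin_run(pot, DynamicsParams(n_steps=20_000, seed=3, x0=(-1.0,)))
    biased = langevin_run(pot, params, bias=bias)
    assert np.allclose(bias.v_grid, 0.0)
    assert np.array_equal(unbiased.positions, biased.positions)


def test_opes_validation():
    with pytest.raises(ValueError):
        OPESBias(delta_e=-1.0)


# ---------------------------------------------------------------------------
# reweighting
# ---------------------------------------------------------------------------


def test_harmonic_profile_curvature_recovered():
    """Unbiased 1D harmonic samples give a quadratic F with the true k."""
    k = 3.0
    pot = HarmonicWell(k=k, dim=1)
    params = DynamicsParams(n_steps=600_000, seed=5, x0=(0.0,))
    res = langevin_run(pot, params)
    centers, f = reweight_profile(
        res.positions[:, 0], np.zeros(len(res)), bins=41, range=(-0.8, 0.8)
    )
    ok = np.isfinite(f) & (np.abs(centers) < 0.6)
    coef = np.polyfit(centers[ok], f[ok], 2)
    assert 2 * coef[0] == pytest.approx(k, rel=0.05)


def test_fes_shift_invariance(two_basin_run):
    res, fes = two_basin_run
    shifted = reweight_fes(
        res.positions, res.bias_energy + 7.3, bins=80,
        ranges=[[-2.2, 2.2], [-1.6, 1.6]], discard_frac=0.5,
    )
    assert np.allclose(
        np.nan_to_num(shifted.free_energy, posinf=1e30),
        np.nan_to_num(fes.free_energy, posinf=1e30),
        atol=1e-9,
    )
    assert shifted.dG == pytest.approx(fes.dG, abs=1e-9)
    assert shifted.dG_barrier == pytest.approx(fes.dG_barrier, abs=1e-9)


def test_fes_min_is_zero_and_barrier_exceeds_offset(two_basin_run):
    _, fes = two_basin_run
    assert fes.free_energy[np.isfinite(fes.free_energy)].min() == 0.0
    assert fes.dG_barrier >= 0.0
    assert fes.converged


@pytest.fixture(scope="module")
def two_basin_run():
    pot = make_surrogate(0.0, 4.0)
    params = DynamicsParams(n_steps=400_000, seed=7, x0=tuple(pot.minima[0]))
    bias = OPESBias(delta_e=20.0, grid_range=(-2.5, 2.5), freeze_after=200_000)
    res = langevin_run(pot, params, bias=bias)
    fes = reweight_fes(
        res.positions, res.bias_energy, bins=80,
        ranges=[[-2.2, 2.2], [-1.6, 1.6]], discard_frac=0.5,
    )
    return res, fes


# ---------------------------------------------------------------------------
# k-medoids and the TS ensemble
# ---------------------------------------------------------------------------


def _dist(x):
    return np.linalg.norm(x[:, None, :] - x[None, :, :], axis=2)


def test_kmedoids_one_medoid_matches_enumeration(rng):
    x = rng.normal(size=(40, 2))
    d = _dist(x)
    med, _ = kmedoids(d, 1)
    brute = np.argmin(d.sum(axis=1))
    assert med[0] == brute


def test_kmedoids_recovers_separated_clouds(rng):
    gx, gy = np.meshgrid([-40, -20, 0, 20, 40], [-20, 20])
    centers = np.column_stack([gx.ravel(), gy.ravel()])  # guaranteed apart
    pts, expected = [], []
    for c in centers:
        cloud = c + rng.normal(0, 0.3, size=(6, 2))
        # per-cloud exact 1-medoid (valid globally for well-separated clouds)
        dc = _dist(cloud)
        expected.append(len(pts) + np.argmin(dc.sum(axis=1)))
        pts.extend(cloud)
    x = np.asarray(pts)
    med, assign = kmedoids(_dist(x), 10)
    assert sorted(med) == sorted(expected)


def test_kmedoids_duplicate_points_zero_cost():
    x = np.tile([[1.0, 2.0]], (12, 1))
    d = _dist(x)
    med, assign = kmedoids(d, 3)
    assert d[np.arange(12), med[assign]].sum() == 0.0


def _toy_fes():
    """Analytic double-well FES grid for TS-window tests."""
    edges = np.linspace(-2, 2, 81)
    xc = 0.5 * (edges[:-1] + edges[1:])
    f2 = 5.0 * (xc[:, None] ** 2 - 1) ** 2 + 2.0 * xc[None, :] ** 2
    return FreeEnergySurface(
        x_edges=edges, y_edges=edges, free_energy=f2,
        basin_labels=np.where(xc[:, None] < 0, 0, 1) * np.ones(80, dtype=int),
        minima=np.array([[-1.0, 0.0], [1.0, 0.0]]),
        saddle=np.array([0.0, 0.0]), dG=0.0, dG_barrier=5.0, temperature=300.0,
    )


def test_ts_ensemble_window_and_medoids(rng):
    fes = _toy_fes()
    kt = KB_KCAL * 300
    # samples hugging the saddle line (F within the window) plus basin noise
    near = np.column_stack([rng.normal(0, 0.02, 300), rng.normal(0, 0.05, 300)])
    far = np.column_stack([rng.normal(-1, 0.05, 200), rng.normal(0, 0.05, 200)])
    samples = np.vstack([near, far])
    ens = ts_ensemble(samples, fes, k=5)
    f_members = fes.value_at(samples[ens.member_indices])
    f_saddle = fes.value_at(fes.saddle[None, :])[0]
    assert np.all(np.abs(f_members - f_saddle) <= kt)
    assert len(ens.medoid_indices) == 5
    assert set(ens.medoid_indices) <= set(ens.member_indices)


def test_ts_ensemble_empty_window_raises(rng):
    fes = _toy_fes()
    basin_only = np.column_stack([rng.normal(-1, 0.03, 50), rng.normal(0, 0.03, 50)])
    with pytest.raises(ValueError, match="longer sampling"):
        ts_ensemble(basin_only, fes, k=10)
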
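"""Desk-scale enhanced sampling: Langevin dynamics, OPES, FES reweighting.

The propagator is overdamped (Brownian) Langevin dynamics,

    x(t+dt) = x(t) - dt/friction * grad V(x) + sqrt(2 kT dt / friction) * xi,

chosen over full Langevin because only equilibrium statistics matter for
free-energy recovery.  The OPES bias builds an on-the-fly weighted kernel
estimate P(s) of the unbiased probability distribution of the biased CV
(kernel weights exp(+beta V) follow the standard iterative-reweighting
rule, with the explored-volume normalisation

    V_int(s) = (1 - 1/gamma) kT ln( P(s)/Z + eps ),

gamma = beta * dE the bias factor and eps = exp(-beta*dE / (1 - 1/gamma))).
The bias applied to the dynamics is V_int shifted so its maximum is zero
and clipped at -dE; a constant shift changes no forces, and the clip makes
the cap — deposited bias range never exceeding the barrier parameter dE —
an exact property rather than an asymptotic one.  Biased samples are
reweighted with
w = exp(+beta*V_bias) into a gridded free-energy surface; basin offsets come
from basin integrals after steepest-descent labelling and the barrier from
the lowest saddle on the minimax path between the two basin minima.
Configurations within +/- kT of the saddle are clustered with a
deterministic k-medoids (PAM) to yield representative transition-state
structures.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import KB_KCAL

log = logging.getLogger("protorelay.sampling")

__all__ = [
    "DynamicsParams",
    "OPESBias",
    "SamplingResult",
    "FreeEnergySurface",
    "TSEnsemble",
    "DivergenceError",
    "langevin_run",
    "estimate_landscape",
    "reweight_fes",
    "reweight_profile",
    "ts_ensemble",
    "kmedoids",
]


class DivergenceError(RuntimeError):
    """The trajectory left the allowed coordinate range."""

    def __init__(self, step: int):
        super().__init__(f"trajectory diverged at step {step}")
        self.step = step


@dataclass(frozen=True)
class DynamicsParams:
    """Overdamped Langevin parameters (kcal/mol, Angstrom-like CV units).

    ``dt``/``friction`` only set the diffusion scale of the propagator; the
    default deposition pace of 100 steps corresponds to the reference
    kernel-deposition interval of 50 fs at a 0.5 fs time step.
    """

    n_steps: int
    temperature: float = 300.0
    friction: float = 1.0
    dt: float = 0.002
    seed: int = 0
    x0: tuple[float, ...] | None = None
    record_every: int = 1
    bound: float = 8.0

    def __post_init__(self):
        if min(self.n_steps, self.temperature, self.friction, self.dt) <= 0:
            raise ValueError("n_steps, temperature, friction and dt must be positive")

    @property
    def kt(self) -> float:
        return KB_KCAL * self.temperature


class OPESBias:
    """On-the-fly probability enhanced sampling bias on a scalar CV.

    Kernels are deposited every ``pace`` steps with weight
    exp(beta * V(s)) (the OPES iterative reweighting); the kernel bandwidth
    shrinks every ``adapt_pace`` steps following the adaptive rule
    sigma = sigma0 * (Neff (d+2)/4)^(-1/(d+4)) with d = 1, floored at
    ``sigma_min`` so late-stage kernels keep filling at a useful rate.  The bias and its
    force are tabulated on a dense grid and linearly interpolated, which
    keeps per-step evaluation O(1) regardless of the kernel count.
    """

    def __init__(
        self,
        delta_e: float = 20.0,
        pace: int = 100,
        adapt_pace: int = 200,
        sigma0: float = 0.1,
        sigma_min: float = 0.05,
        grid_range: tuple[float, float] = (-3.0, 3.0),
        n_grid: int = 1201,
        temperature: float = 300.0,
        gamma: float | None = None,
        freeze_after: int | None = None,
    ):
        if delta_e < 0:
            raise ValueError("delta_e must be non-negative")
        #: step count after which the bias stays fixed (quasi-static
        #: production stage; reweighting of that stage is then exact)
        self.freeze_after = freeze_after
        self.delta_e = float(delta_e)
        self.pace = int(pace)
        self.adapt_pace = int(adapt_pace)
        self.sigma0 = float(sigma0)
        self.sigma_min = float(sigma_min)
        self.kt = KB_KCAL * temperature
        self.gamma = gamma if gamma is not None else max(delta_e / self.kt, 1.0 + 1e-6)
        self.prefactor = (1.0 - 1.0 / self.gamma) * self.kt
        self.epsilon = (
            math.exp(-self.delta_e / self.prefactor) if self.prefactor > 0 else 0.0
        )
        self.grid = np.linspace(grid_range[0], grid_range[1], n_grid)
        self._x0 = float(self.grid[0])
        self._dx = float(self.grid[1] - self.grid[0])
        self._kde = np.zeros(n_grid)
        self._v_int = np.zeros(n_grid)
        self.v_grid = np.zeros(n_grid)
        self._f_grid = np.zeros(n_grid)
        self.sum_w = 0.0
        self.sum_w2 = 0.0
        self.sigma = self.sigma0
        self.kernels: list[tuple[float, float, float]] = []  # (center, sigma, weight)

    # -- evaluation --------------------------------------------------------

    def bias_and_force(self, s: float) -> tuple[float, float]:
        """Interpolated bias energy and force (-dV/ds) at CV value ``s``."""
        t = (s - self._x0) / self._dx
        i = int(t)
        if i < 0:
            i, frac = 0, 0.0
        elif i >= len(self.grid) - 1:
            i, frac = len(self.grid) - 2, 1.0
        else:
            frac = t - i
        v = self.v_grid[i] * (1.0 - frac) + self.v_grid[i + 1] * frac
        f = self._f_grid[i] * (1.0 - frac) + self._f_grid[i + 1] * frac
        return float(v), float(f)

    @property
    def n_kernels(self) -> int:
        return len(self.kernels)

    @property
    def neff(self) -> float:
        return self.sum_w * self.sum_w / self.sum_w2 if self.sum_w2 > 0 else 0.0

    def bias_range(self) -> float:
        return float(self.v_grid.max() - self.v_grid.min())

    # -- update ------------------------------------------------------------

    def _internal_bias_at(self, s: float) -> float:
        t = (s - self._x0) / self._dx
        i = min(max(int(t), 0), len(self.grid) - 2)
        frac = min(max(t - i, 0.0), 1.0)
        return float(self._v_int[i] * (1.0 - frac) + self._v_int[i + 1] * frac)

    def update(self, s: float, step: int) -> None:
        """Deposit/adapt on pace steps; no-op otherwise."""
        if self.delta_e == 0.0:
            return
        if self.freeze_after is not None and step > self.freeze_after:
            return
        if step % self.adapt_pace == 0 and self.n_kernels > 1:
            self.sigma = max(
                self.sigma0 * (self.neff * 0.75) ** (-0.2), self.sigma_min
            )
        if step % self.pace != 0:
            return
        # kernel weight from the unshifted (explored-volume normalised)
        # estimate: this is what suppresses early transient kernels
        w = math.exp(self._internal_bias_at(s) / self.kt)
        self.kernels.append((s, self.sigma, w))
        self.sum_w += w
        self.sum_w2 += w * w
        u = (self.grid - s) / self.sigma
        self._kde += (w / (self.sigma * math.sqrt(2.0 * math.pi))) * np.exp(-0.5 * u * u)
        p = self._kde / self.sum_w
        pmax = p.max()
        explored = p > pmax * 1e-12
        z = p[explored].mean()
        self._v_int = self.prefactor * np.log(p / z + self.epsilon)
        # applied bias: shifted to max zero and clipped, so the deposited
        # range never exceeds delta_e anywhere (exact cap)
        v_new = self._v_int - self._v_int.max()
        np.maximum(v_new, -self.delta_e, out=v_new)
        self.v_grid = v_new
        self._f_grid = -np.gradient(v_new, self._dx)
        # continuous cap assertion: the deposited bias range may never
        # exceed the barrier parameter anywhere on the grid
        if v_new.max() - v_new.min() > self.delta_e + 1e-9:
            raise AssertionError("OPES cap violated: bias range exceeds delta_e")
        if self.n_kernels % 1000 == 0:
            log.info(
                "deposition epoch: %d kernels, neff %.0f, sigma %.3f, "
                "bias range %.2f", self.n_kernels, self.neff, self.sigma,
                self.bias_range(),
            )


@dataclass
class SamplingResult:
    """Recorded trajectory of a (biased) Langevin run."""

    positions: np.ndarray  # (m, d)
    cv: np.ndarray  # (m,)
    bias_energy: np.ndarray  # (m,) total bias energy at sample time
    params: DynamicsParams
    bias: OPESBias | None = None

    def __len__(self) -> int:
        return len(self.positions)


def _default_cv(dim: int):
    if dim == 1:
        return lambda x: (x[0], (1.0,))
    return lambda x: (x[0], (1.0,) + (0.0,) * (dim - 1))


def langevin_run(
    potential,
    params: DynamicsParams,
    bias: OPESBias | None = None,
    cv=None,
    extra_bias=None,
) -> SamplingResult:
    """Overdamped Langevin trajectory on ``potential``.

    ``cv`` maps a coordinate tuple to (value, gradient tuple) and defaults
    to the first coordinate; ``bias`` is an OPES bias acting on that CV and
    is updated every step.  ``extra_bias`` is any object with an
    ``energy_and_grad(x) -> (V, grad tuple)`` method (e.g. the
    committor-based transition-state bias) added to the total potential.
    Fixed seed gives a bit-identical repeat.
    """
    d = potential.dim
    cv_fn = cv if cv is not None else _default_cv(d)
    x = list(params.x0) if params.x0 is not None else [0.0] * d
    if len(x) != d:
        raise ValueError("x0 dimension does not match the potential")

    rng = np.random.default_rng(params.seed)
    mob = params.dt / params.friction
    noise_scale = math.sqrt(2.0 * params.kt * params.dt / params.friction)
    n_rec = params.n_steps // params.record_every
    positions = np.empty((n_rec, d))
    cv_out = np.empty(n_rec)
    bias_out = np.empty(n_rec)
    rec = 0

    chunk = 8192
    noise = rng.standard_normal((chunk, d)) * noise_scale
    ni = 0
    bound = params.bound

    for step in range(1, params.n_steps + 1):
        v, g = potential.energy_and_grad_scalar(*x)
        force = [-gi for gi in g]
        vbias_total = 0.0
        if bias is not None:
            s, gs = cv_fn(x)
            vb, fb = bias.bias_and_force(s)
            vbias_total += vb
            for i in range(d):
                force[i] += fb * gs[i]
        if extra_bias is not None:
            vk, gk = extra_bias.energy_and_grad(x)
            vbias_total += vk
            for i in range(d):
                force[i] -= gk[i]
        if ni == chunk:
            noise = rng.standard_normal((chunk, d)) * noise_scale
            ni = 0
        row = noise[ni]
        ni += 1
        for i in range(d):
            x[i] += mob * force[i] + row[i]
            if not -bound <= x[i] <= bound:
                raise DivergenceError(step)
        s, _ = cv_fn(x)
        if bias is not None:
            bias.update(s, step)
        if step % params.record_every == 0:
            positions[rec] = x
            cv_out[rec] = s
            if bias is not None:
                vb, _ = bias.bias_and_force(s)
            else:
                vb = 0.0
            if extra_bias is not None:
                vb += extra_bias.energy_and_grad(x)[0]
            bias_out[rec] = vb
            rec += 1

    return SamplingResult(positions, cv_out, bias_out, params, bias)


# ---------------------------------------------------------------------------
# free-energy surface reweighting
# ---------------------------------------------------------------------------


@dataclass
class FreeEnergySurface:
    """Gridded -kT log P over two CVs, min-shifted to zero.

    ``dG`` is the basin free-energy difference (positive-axis-0 basin minus
    negative-axis-0 basin, i.e. amide - imidic with the package's surrogate
    convention); ``dG_barrier`` the saddle height above the imidic minimum.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray  # (nx, ny), inf on empty bins
    basin_labels: np.ndarray
    minima: np.ndarray  # (2, 2) CV coordinates, sorted by axis 0
    saddle: np.ndarray  # (2,) CV coordinates
    dG: float
    dG_barrier: float
    temperature: float
    converged: bool = True

    def value_at(self, points: np.ndarray) -> np.ndarray:
        ix = np.clip(np.searchsorted(self.x_edges, points[:, 0]) - 1, 0,
                     self.free_energy.shape[0] - 1)
        iy = np.clip(np.searchsorted(self.y_edges, points[:, 1]) - 1, 0,
                     self.free_energy.shape[1] - 1)
        return self.free_energy[ix, iy]


def _descent_labels(f: np.ndarray) -> np.ndarray:
    """Steepest-descent basin labelling of a gridded function."""
    nx, ny = f.shape
    labels = -np.ones((nx, ny), dtype=int)
    order = np.argsort(f, axis=None)
    next_label = 0
    for flat in order:
        i, j = divmod(flat, ny)
        if not np.isfinite(f[i, j]):
            break
        best = None
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                a, b = i + di, j + dj
                if 0 <= a < nx and 0 <= b < ny and f[a, b] < f[i, j]:
                    if best is None or f[a, b] < f[best]:
                        best = (a, b)
        labels[i, j] = next_label if best is None else labels[best]
        if best is None:
            next_label += 1
    return labels


def _minimax_path_cost(f: np.ndarray, start: tuple[int, int], goal: tuple[int, int]):
    """Lowest achievable maximum of ``f`` along an 8-connected path."""
    nx, ny = f.shape
    best = np.full((nx, ny), np.inf)
    start_cost = f[start]
    best[start] = start_cost
    heap = [(start_cost, start)]
    argmax_cell = {start: start}
    while heap:
        cost, (i, j) = heapq.heappop(heap)
        if (i, j) == goal:
            return cost, argmax_cell[(i, j)]
        if cost > best[i, j]:
            continue
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                a, b = i + di, j + dj
                if (di or dj) and 0 <= a < nx and 0 <= b < ny:
                    c = max(cost, f[a, b])
                    if c < best[a, b]:
                        best[a, b] = c
                        argmax_cell[(a, b)] = (
                            (a, b) if f[a, b] >= cost else argmax_cell[(i, j)]
                        )
                        heapq.heappush(heap, (c, (a, b)))
    return np.inf, None


def reweight_fes(
    positions: np.ndarray,
    bias_energy: np.ndarray,
    temperature: float = 300.0,
    bins: int = 100,
    ranges=None,
    discard_frac: float = 0.2,
    smooth_bins: float = 1.0,
    min_prominence: float = 1.0,
) -> FreeEnergySurface:
    """Weighted-histogram free-energy surface over two CV columns.

    Samples carry weights exp(+beta * V_bias); an initial ``discard_frac``
    of the trajectory is dropped as transient.  The weighted histogram is
    smoothed with a Gaussian of ``smooth_bins`` bins before taking the log,
    which suppresses shot-noise minima without shifting well/saddle
    positions at the default bin width.  The second basin must be separated
    from the global minimum by a minimax-path barrier of at least
    ``min_prominence`` kcal/mol above its own minimum.  A constant shift of
    the bias leaves the surface unchanged (weights are normalised).
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 2:
        raise ValueError("positions must have two CV columns")
    kt = KB_KCAL * temperature
    n0 = int(len(positions) * discard_frac)
    pos = positions[n0:]
    vb = np.asarray(bias_energy, dtype=float)[n0:]
    w = np.exp((vb - vb.max()) / kt)

    hist, xe, ye = np.histogram2d(pos[:, 0], pos[:, 1], bins=bins, range=ranges, weights=w)

    def to_f(h):
        with np.errstate(divide="ignore"):
            out = np.full_like(h, np.inf)
            np.log(h, out=out, where=h > 0)
            out = np.where(h > 0, -kt * out, np.inf)
        return out - out[h > 0].min()

    f = to_f(hist)
    # basins and the saddle are identified on a smoothed surface (robust
    # against shot-noise minima); bins never actually visited stay
    # impassable so smoothing cannot open phantom passes
    if smooth_bins > 0:
        from scipy.ndimage import gaussian_filter

        f_smooth = to_f(gaussian_filter(hist, sigma=smooth_bins, mode="constant"))
        f_smooth[hist == 0] = np.inf
    else:
        f_smooth = f

    labels = _descent_labels(f_smooth)
    # basin minima per label, on the smoothed surface (saddle and barrier
    # use the smoothed surface throughout for a consistent reference)
    basin_min: dict[int, tuple[float, tuple[int, int]]] = {}
    nx, ny = f_smooth.shape
    for i in range(nx):
        for j in range(ny):
            lab = labels[i, j]
            if lab >= 0 and (lab not in basin_min or f_smooth[i, j] < basin_min[lab][0]):
                basin_min[lab] = (f_smooth[i, j], (i, j))
    if len(basin_min) < 2:
        raise ValueError("fewer than two basins found; sample longer")
    ordered = sorted(basin_min.values())
    first = ordered[0][1]
    second = None
    for fval, cell in ordered[1:]:
        cost, _ = _minimax_path_cost(f_smooth, first, cell)
        if np.isfinite(cost) and cost - fval >= min_prominence:
            second = cell
            break
    if second is None:
        raise ValueError("no second basin with sufficient prominence; sample longer")
    cells = sorted((first, second), key=lambda c: c[0])  # by axis-0 index
    xc = 0.5 * (xe[:-1] + xe[1:])
    yc = 0.5 * (ye[:-1] + ye[1:])
    minima = np.array([[xc[c[0]], yc[c[1]]] for c in cells])

    saddle_cost, saddle_cell = _minimax_path_cost(f_smooth, cells[0], cells[1])
    converged = np.isfinite(saddle_cost)
    saddle = (
        np.array([xc[saddle_cell[0]], yc[saddle_cell[1]]])
        if converged
        else np.array([np.nan, np.nan])
    )

    # basin populations from the weighted samples themselves (membership by
    # bin label): free of binning/empty-bin loss, unlike re-integrating the
    # gridded surface
    lab_lo = labels[cells[0]]
    lab_hi = labels[cells[1]]
    ix = np.clip(np.searchsorted(xe, pos[:, 0]) - 1, 0, labels.shape[0] - 1)
    iy = np.clip(np.searchsorted(ye, pos[:, 1]) - 1, 0, labels.shape[1] - 1)
    sample_lab = labels[ix, iy]
    p_lo = w[sample_lab == lab_lo].sum()
    p_hi = w[sample_lab == lab_hi].sum()
    dg = float(-kt * math.log(p_hi / p_lo)) if p_lo > 0 and p_hi > 0 else np.nan
    barrier = float(saddle_cost - f_smooth[cells[0]]) if converged else np.nan
    return FreeEnergySurface(
        xe, ye, f, labels, minima, saddle, dg, barrier, temperature, converged
    )


def reweight_profile(
    values: np.ndarray,
    bias_energy: np.ndarray,
    temperature: float = 300.0,
    bins: int = 100,
    range=None,
    discard_frac: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """One-dimensional reweighted free-energy profile (centers, F)."""
    kt = KB_KCAL * temperature
    n0 = int(len(values) * discard_frac)
    v = np.asarray(values, dtype=float)[n0:]
    vb = np.asarray(bias_energy, dtype=float)[n0:]
    w = np.exp((vb - vb.max()) / kt)
    hist, edges = np.histogram(v, bins=bins, range=range, weights=w)
    with np.errstate(divide="ignore"):
        f = np.full_like(hist, np.inf)
        np.log(hist, out=f, where=hist > 0)
        f = np.where(hist > 0, -kt * f, np.inf)
    f -= f[np.isfinite(f)].min()
    return 0.5 * (edges[:-1] + edges[1:]), f


def estimate_landscape(
    potential,
    n_replicas: int = 3,
    n_steps: int = 3_500_000,
    fill_frac: float = 0.48,
    delta_e: float = 20.0,
    seed: int = 0,
    bins: int = 80,
    ranges=((-2.2, 2.2), (-1.6, 1.6)),
    grid_range: tuple[float, float] = (-2.5, 2.5),
) -> dict:
    """Replica-averaged OPES estimate of a two-basin surrogate landscape.

    Runs ``n_replicas`` independent fill+production OPES simulations
    started in the deeper basin and reports the median of the recovered
    basin offsets and forward barriers; the median is robust against the
    rare replica whose bias fails to converge within its fill stage.
    Returns a dict with the per-replica numbers, the medians, the last
    replica's surface, and the maximum bias range observed (the cap
    diagnostic).
    """
    fill = int(n_steps * fill_frac)
    # start in the deeper basin: the bias then fills bottom-up and reaches
    # the shallow basin quickly, instead of dropping into the deep well
    # mid-fill and stalling there
    energies = [potential.energy_and_grad_scalar(*m)[0] for m in potential.minima]
    x0 = tuple(potential.minima[int(np.argmin(energies))])
    dgs, barriers, max_bias = [], [], 0.0
    fes = None
    results = []
    for rep in range(n_replicas):
        params = DynamicsParams(n_steps=n_steps, seed=seed + 1000 * rep, x0=x0)
        bias = OPESBias(delta_e=delta_e, grid_range=grid_range, freeze_after=fill)
        res = langevin_run(potential, params, bias=bias)
        fes = reweight_fes(
            res.positions, res.bias_energy, bins=bins,
            ranges=[list(ranges[0]), list(ranges[1])], discard_frac=fill / n_steps,
        )
        dgs.append(fes.dG)
        barriers.append(fes.dG_barrier)
        max_bias = max(max_bias, bias.bias_range())
        results.append(res)
    return {
        "dG": float(np.median(dgs)),
        "dG_barrier": float(np.median(barriers)),
        "per_replica_dG": dgs,
        "per_replica_barrier": barriers,
        "max_bias_range": max_bias,
        "fes": fes,
        "results": results,
    }


# ---------------------------------------------------------------------------
# transition-state ensemble
# ---------------------------------------------------------------------------


def kmedoids(dist: np.ndarray, k: int, max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic k-medoids (PAM-style) on a precomputed distance matrix.

    Initialisation is greedy: the 1-medoid optimum first, then the point
    farthest from the chosen set (maxmin), ties broken by index.  Returns
    (medoid indices, assignment).
    """
    n = len(dist)
    if not 1 <= k <= n:
        raise ValueError("need 1 <= k <= n_points")
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        d_min = dist[:, medoids].min(axis=1)
        medoids.append(int(np.argmax(d_min)))
    medoids = np.array(sorted(medoids))
    for _ in range(max_iter):
        assign = np.argmin(dist[:, medoids], axis=1)
        new = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(assign == c)
            if len(members) == 0:
                continue
            sub = dist[np.ix_(members, members)]
            new[c] = members[int(np.argmin(sub.sum(axis=1)))]
        new = np.array(sorted(new))
        if np.array_equal(new, medoids):
            break
        medoids = new
    assign = np.argmin(dist[:, medoids], axis=1)
    return medoids, assign


@dataclass
class TSEnsemble:
    """Samples within +/- kT of the saddle and their medoid representatives."""

    member_indices: np.ndarray  # indices into the full sample array
    medoid_indices: np.ndarray  # indices into the full sample array
    assignment: np.ndarray  # per-member cluster id
    summaries: pd.DataFrame  # per-medoid descriptor summary


def ts_ensemble(
    positions: np.ndarray,
    fes: FreeEnergySurface,
    k: int = 10,
    descriptors=None,
    max_members: int = 2000,
) -> TSEnsemble:
    """k-medoid clustering of configurations within +/- kT of the saddle.

    ``descriptors`` may be an (n, p) array or a callable mapping positions
    to descriptors; by default the CV coordinates themselves are used.  The
    energy window uses the FES temperature.
    """
    positions = np.asarray(positions, dtype=float)
    if not fes.converged:
        raise ValueError("FES saddle not converged; sample longer")
    kt = KB_KCAL * fes.temperature
    fvals = fes.value_at(positions)
    f_saddle = fes.value_at(fes.saddle[None, :])[0]
    members = np.flatnonzero(np.abs(fvals - f_saddle) <= kt)
    if len(members) < k:
        raise ValueError(
            f"only {len(members)} samples within +/- kT of the saddle; "
            "run longer sampling"
        )
    if len(members) > max_members:  # deterministic thinning
        members = members[:: len(members) // max_members + 1]

    if descriptors is None:
        desc = positions
    elif callable(descriptors):
        desc = np.asarray(descriptors(positions))
    else:
        desc = np.asarray(descriptors)
    d = desc[members]
    dist = np.linalg.norm(d[:, None, :] - d[None, :, :], axis=2)
    med_local, assign = kmedoids(dist, k)
    medoids = members[med_local]

    rows = []
    for c, m in enumerate(med_local):
        size = int(np.sum(assign == c))
        row = {"cluster": c, "size": size}
        row.update({f"d{i}": d[m, i] for i in range(d.shape[1])})
        rows.append(row)
    return TSEnsemble(members, medoids, assign, pd.DataFrame(rows))
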
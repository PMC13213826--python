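"""Data-driven committor model and transition-state-focusing bias.

The committor q(x) — the probability that a trajectory started at x reaches
the product basin before the reactant basin — is approximated by a small
feed-forward network ([N, 32, 32, 1], tanh hidden layers, sigmoid output)
trained on sampled configurations.  The loss is a variational Kolmogorov
functional: the weighted mean squared gradient of q under the sampled
(reweighted) measure, whose minimiser subject to the basin boundary
conditions is the true committor, plus an alpha-weighted boundary penalty
anchoring q to 0/1 on basin-labelled data.  Training uses full-batch Adam
with an exponentially decaying learning rate, so fixed seeds give
reproducible models.

The gradient of the |grad q|^2 term with respect to the weights requires a
second derivative pass; it is implemented analytically (forward-mode
tangent propagation followed by a reverse sweep through both the tangent
and primal computations) and verified against finite differences in the
test suite.

From the trained model two objects are derived: the smoother reaction
coordinate z(x) = logit(q(x)), used as an OPES CV, and the Kolmogorov
(transition-state) bias

    V_K(x) = -lambda * dE * [4 q (1-q)]^2 ,

maximal in effect at q = 1/2 and vanishing quartically in either basin.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .io_core import Frame, Topology, TopologyError
from .synthetic import KB_KCAL

__all__ = [
    "CommittorSpec",
    "CommittorModel",
    "KolmogorovBias",
    "train_committor",
    "featurize",
    "analytic_committor_1d",
]

_Q_CLIP = 1e-4  # q clipping for the logit transform z(x)


@dataclass(frozen=True)
class CommittorSpec:
    """Architecture and optimiser settings for committor training."""

    n_inputs: int
    hidden: tuple[int, ...] = (32, 32)
    learning_rate: float = 1e-3
    lr_decay: float = 0.9999
    alpha: float = 1.0  # boundary-penalty weight
    epochs: int = 50_000
    seed: int = 0

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.n_inputs, *self.hidden, 1)


class CommittorModel:
    """Trained committor network with input standardisation."""

    def __init__(self, weights, biases, x_mean, x_std, spec: CommittorSpec,
                 loss_history=None):
        self.weights = [np.asarray(w, dtype=float) for w in weights]
        self.biases = [np.asarray(b, dtype=float) for b in biases]
        self.x_mean = np.asarray(x_mean, dtype=float)
        self.x_std = np.asarray(x_std, dtype=float)
        self.spec = spec
        self.loss_history = loss_history if loss_history is not None else []

    # -- forward passes ----------------------------------------------------

    def _forward(self, x: np.ndarray):
        a = (np.atleast_2d(x) - self.x_mean) / self.x_std
        acts = [a]
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.tanh(a @ w + b)
            acts.append(a)
        zl = a @ self.weights[-1] + self.biases[-1]
        q = 1.0 / (1.0 + np.exp(-zl))
        return q[:, 0], acts, zl

    def q(self, x: np.ndarray) -> np.ndarray:
        """Committor value(s) in (0, 1) for raw (unscaled) inputs."""
        return self._forward(x)[0]

    def q_and_grad(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """q and dq/dx (raw input scale) via forward-mode tangents."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        q, acts, _ = self._forward(x)
        n, d = x.shape
        grad = np.empty((n, d))
        sig = (q * (1.0 - q))[:, None]
        for dd in range(d):
            u = np.zeros((n, d))
            u[:, dd] = 1.0 / self.x_std[dd]
            for w, a in zip(self.weights[:-1], acts[1:]):
                u = (1.0 - a * a) * (u @ w)
            grad[:, dd] = (sig * (u @ self.weights[-1]))[:, 0]
        return q, grad

    # -- derived CV --------------------------------------------------------

    def z(self, x: np.ndarray) -> np.ndarray:
        """Smoother reaction coordinate z = logit(q), clipped in the basins."""
        q = np.clip(self.q(x), _Q_CLIP, 1.0 - _Q_CLIP)
        return np.log(q / (1.0 - q))

    def z_and_grad(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        q, gq = self.q_and_grad(x)
        inside = (q > _Q_CLIP) & (q < 1.0 - _Q_CLIP)
        qc = np.clip(q, _Q_CLIP, 1.0 - _Q_CLIP)
        z = np.log(qc / (1.0 - qc))
        gz = np.where(inside[:, None], gq / (qc * (1.0 - qc))[:, None], 0.0)
        return z, gz

    def as_cv(self):
        """(value, gradient-tuple) callable for :func:`langevin_run`."""

        def cv(x):
            z, gz = self.z_and_grad(np.asarray(x)[None, :])
            return float(z[0]), tuple(gz[0])

        return cv

    # -- serialisation -----------------------------------------------------

    def to_json(self, path: str) -> None:
        payload = {
            "layer_sizes": list(self.spec.layer_sizes),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "CommittorModel":
        with open(path) as fh:
            d = json.load(fh)
        spec = CommittorSpec(
            n_inputs=d["layer_sizes"][0], hidden=tuple(d["layer_sizes"][1:-1])
        )
        return cls(d["weights"], d["biases"], d["x_mean"], d["x_std"], spec)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _loss_and_grads(weights, biases, x, w_norm, lab_mask, lab_y, alpha):
    """Kolmogorov + boundary loss and analytic parameter gradients.

    Returns (loss, dW list, db list).  The |grad q|^2 term needs a reverse
    sweep through the forward-mode tangent computation (double backward);
    tanh: phi' = 1 - a^2, phi'' = -2 a (1 - a^2); sigmoid: s' = q(1-q),
    s'' = q(1-q)(1-2q), all as functions of the activations.
    """
    L = len(weights)
    # primal forward
    acts = [x]
    a = x
    for l in range(L - 1):
        a = np.tanh(a @ weights[l] + biases[l])
        acts.append(a)
    zl = a @ weights[-1] + biases[-1]
    q = 1.0 / (1.0 + np.exp(-zl))  # (n,1)
    sig1 = q * (1.0 - q)
    sig2 = sig1 * (1.0 - 2.0 * q)

    dW = [np.zeros_like(w) for w in weights]
    db = [np.zeros_like(b) for b in biases]
    zbar = [np.zeros((x.shape[0], weights[l].shape[1])) for l in range(L)]

    d = x.shape[1]
    loss_k = 0.0
    wcol = w_norm[:, None]
    for dd in range(d):
        # tangent forward: u_l = phi'(z_l) * t_l with t_l = u_{l-1} W_l
        us = [_unit_col(x, dd)]
        ts = []
        for l in range(L - 1):
            t = us[-1] @ weights[l]
            ts.append(t)
            us.append((1.0 - acts[l + 1] ** 2) * t)
        t_last = us[-1] @ weights[-1]
        g = sig1 * t_last  # (n,1) = dq/dx_dd
        loss_k += float(np.sum(w_norm * g[:, 0] ** 2))
        # reverse sweep through the tangent computation
        gbar = 2.0 * wcol * g
        tbar = gbar * sig1
        zbar[-1] += gbar * t_last * sig2
        dW[-1] += us[-1].T @ tbar
        ubar = tbar @ weights[-1].T
        for l in range(L - 2, -1, -1):
            a_l = acts[l + 1]
            # u_l = (1-a_l^2) t_l : adjoints w.r.t. t_l and (via a_l) z_l
            tbar_l = ubar * (1.0 - a_l * a_l)
            zbar[l] += ubar * ts[l] * (-2.0 * a_l) * (1.0 - a_l * a_l)
            dW[l] += us[l].T @ tbar_l
            ubar = tbar_l @ weights[l].T

    # boundary penalty
    n_lab = int(lab_mask.sum())
    loss_b = 0.0
    if n_lab > 0:
        diff = (q[:, 0] - lab_y) * lab_mask
        loss_b = float(alpha * np.sum(diff**2) / n_lab)
        qbar = (2.0 * alpha / n_lab) * diff[:, None]
        zbar[-1] += qbar * sig1

    # primal backward with all accumulated z adjoints
    for l in range(L - 1, -1, -1):
        dW[l] += acts[l].T @ zbar[l]
        db[l] += zbar[l].sum(axis=0)
        if l > 0:
            abar = zbar[l] @ weights[l].T
            zbar[l - 1] += abar * (1.0 - acts[l] ** 2)

    return loss_k + loss_b, dW, db


def _unit_col(x: np.ndarray, dd: int) -> np.ndarray:
    u = np.zeros_like(x)
    u[:, dd] = 1.0
    return u


def train_committor(
    x: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray | None = None,
    spec: CommittorSpec | None = None,
) -> CommittorModel:
    """Train the committor network on labelled/weighted configurations.

    ``labels`` holds 0 (reactant basin), 1 (product basin) or NaN
    (unlabelled interior); both basins must be present.  ``weights`` are
    the statistical weights of the samples under the unbiased ensemble
    (exp(+beta V_bias) for OPES-generated data).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    labels = np.asarray(labels, dtype=float)
    if spec is None:
        spec = CommittorSpec(n_inputs=x.shape[1])
    if x.shape[1] != spec.n_inputs:
        raise ValueError("descriptor dimension does not match the model spec")
    lab_mask = ~np.isnan(labels)
    present = set(np.unique(labels[lab_mask]))
    if not {0.0, 1.0} <= present:
        raise ValueError("training data must contain both basins (labels 0 and 1)")
    w = np.ones(len(x)) if weights is None else np.asarray(weights, dtype=float)
    w_norm = w / w.sum()

    x_mean = x.mean(axis=0)
    x_std = x.std(axis=0)
    x_std[x_std < 1e-12] = 1.0
    xs = (x - x_mean) / x_std

    rng = np.random.default_rng(spec.seed)
    sizes = spec.layer_sizes
    ws = [
        rng.normal(0.0, math.sqrt(2.0 / (sizes[i] + sizes[i + 1])),
                   size=(sizes[i], sizes[i + 1]))
        for i in range(len(sizes) - 1)
    ]
    bs = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    # Adam state
    m_w = [np.zeros_like(a) for a in ws]
    v_w = [np.zeros_like(a) for a in ws]
    m_b = [np.zeros_like(a) for a in bs]
    v_b = [np.zeros_like(a) for a in bs]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lab_y = np.where(lab_mask, labels, 0.0)

    history = []
    for epoch in range(1, spec.epochs + 1):
        loss, dW, db = _loss_and_grads(ws, bs, xs, w_norm, lab_mask, lab_y, spec.alpha)
        history.append(loss)
        lr = spec.learning_rate * spec.lr_decay**epoch
        c1 = 1.0 - beta1**epoch
        c2 = 1.0 - beta2**epoch
        for i in range(len(ws)):
            m_w[i] = beta1 * m_w[i] + (1 - beta1) * dW[i]
            v_w[i] = beta2 * v_w[i] + (1 - beta2) * dW[i] ** 2
            ws[i] -= lr * (m_w[i] / c1) / (np.sqrt(v_w[i] / c2) + eps)
            m_b[i] = beta1 * m_b[i] + (1 - beta1) * db[i]
            v_b[i] = beta2 * v_b[i] + (1 - beta2) * db[i] ** 2
            bs[i] -= lr * (m_b[i] / c1) / (np.sqrt(v_b[i] / c2) + eps)

    return CommittorModel(ws, bs, x_mean, x_std, spec, history)


# ---------------------------------------------------------------------------
# transition-state bias
# ---------------------------------------------------------------------------


class KolmogorovBias:
    """TS-focusing bias V_K = -lambda dE [4 q (1-q)]^2.

    The prefactor ``lam * delta_e`` sets the well depth at q = 1/2
    (6 kcal/mol with the defaults); the quartic form makes the bias fall
    below 1% of its TS value already at q = 0.01.
    """

    def __init__(self, model: CommittorModel, lam: float = 0.3, delta_e: float = 20.0):
        if lam < 0:
            raise ValueError("lambda must be non-negative")
        self.model = model
        self.lam = float(lam)
        self.delta_e = float(delta_e)

    def energy(self, x) -> float:
        q = float(self.model.q(np.asarray(x, dtype=float)[None, :])[0])
        s = 4.0 * q * (1.0 - q)
        return -self.lam * self.delta_e * s * s

    def energy_and_grad(self, x):
        q_arr, gq = self.model.q_and_grad(np.asarray(x, dtype=float)[None, :])
        q = float(q_arr[0])
        s = 4.0 * q * (1.0 - q)
        v = -self.lam * self.delta_e * s * s
        dv_dq = -self.lam * self.delta_e * 2.0 * s * 4.0 * (1.0 - 2.0 * q)
        return v, tuple(dv_dq * gq[0])


# ---------------------------------------------------------------------------
# descriptors and the 1D oracle
# ---------------------------------------------------------------------------


def featurize(
    frame: Frame,
    topology: Topology,
    mode: str,
    waters=None,
) -> np.ndarray:
    """Fixed-order distance descriptors of the catalytic arrangement.

    one_water (N = 9): the three heteroatom pair distances (OD-ND, OD-Ow,
    Ow-ND) followed by the six proton-heteroatom distances (H*, wH1, wH2
    each to OD and ND).  two_water (N = 13): the relay-chain heteroatom
    distances (OD-Ow1, Ow1-Ow2, Ow2-ND) followed by the ten
    proton-heteroatom distances (H*, w1H1, w1H2, w2H1, w2H2 each to OD and
    ND).  ``waters`` names the bridging water oxygens in relay order and
    defaults to all water oxygens of the topology.
    """
    if topology.fragment is None:
        raise TopologyError("catalytic fragment not annotated")
    frag = topology.fragment
    if waters is None:
        waters = [int(i) for i in topology.water_oxygens]
    waters = list(waters)
    expected = {"one_water": 1, "two_water": 2}.get(mode)
    if expected is None:
        raise ValueError("mode must be 'one_water' or 'two_water'")
    if len(waters) != expected:
        raise ValueError(
            f"{mode} descriptors need {expected} bridging water(s), got {len(waters)}"
        )

    c = frame.coords

    def d(i, j):
        return float(np.linalg.norm(c[i] - c[j]))

    od, nd = frag["OD"], frag["ND"]
    protons = [frag["HO"]]
    for w in waters:
        protons.extend(sorted(topology.hydrogens_of(w)))

    if mode == "one_water":
        het = [d(od, nd), d(od, waters[0]), d(waters[0], nd)]
    else:
        het = [d(od, waters[0]), d(waters[0], waters[1]), d(waters[1], nd)]
    out = het + [d(h, a) for h in protons for a in (od, nd)]
    return np.array(out)


def analytic_committor_1d(potential, a: float, b: float, temperature: float = 300.0,
                          n: int = 4001):
    """Quadrature committor of a 1D potential between absorbing points a, b.

    q(x) = int_a^x exp(+beta V) ds / int_a^b exp(+beta V) ds.  Returns
    (grid, q) arrays.
    """
    kt = KB_KCAL * temperature
    xs = np.linspace(a, b, n)
    v = potential.energy(xs[:, None])
    ev = np.exp((v - v.max()) / kt)
    integral = cumulative_trapezoid(ev, xs, initial=0.0)
    return xs, integral / integral[-1]
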
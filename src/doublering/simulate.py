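"""Finite-size stochastic simulation of the two-map rate network.

Neurons are assigned coordinates on a deterministic grid that matches the
angular density (points equally spaced along lines of constant
``theta_A - theta_B``, with line offsets at the quantiles of the offset
marginal), each angular location being shared by a block of ``n_eta``
neurons with participation pairs drawn from the empirical marginals. The
rate dynamics is integrated with Euler-Maruyama; the input noise is an
Ornstein-Uhlenbeck process updated exactly per step. Because the coupling
matrix is a uniform term plus four outer products, the recurrent drive is
accumulated through five population sums per step and the ``N x N`` matrix
is never formed (a dense path exists for small networks as a test oracle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model import (
    CouplingParams,
    ExternalInputSeries,
    NeuronCoords,
    PopulationDensity,
    relu,
    wrap_angle,
)

__all__ = [
    "NetworkRealization",
    "NoiseParams",
    "RateTensor",
    "OrderParamSeries",
    "SimResult",
    "assign_coordinates",
    "simulate_network",
    "order_params_from_rates",
    "dense_coupling_matrix",
]

TWO_PI = 2.0 * np.pi
DEFAULT_CONDITION_ANGLES = TWO_PI * np.arange(8) / 8


@dataclass
class NetworkRealization:
    """A concrete network: coordinates for ``N = n_theta * n_eta`` neurons."""

    coords: NeuronCoords
    n_theta: int
    n_eta: int
    chi: float
    seed: int

    @property
    def n_neurons(self):
        return len(self.coords)


@dataclass
class NoiseParams:
    """Ornstein-Uhlenbeck input-noise parameters.

    ``gamma`` is the decay rate (1/s, default 75) and ``sigma_n`` the
    diffusion amplitude (rate units per sqrt-second, default 0.35); the
    stationary variance is ``sigma_n^2 / (2 gamma)``.
    """

    gamma: float = 75.0
    sigma_n: float = 0.35
    dt_sim: float = 0.0005
    seed: int = 0

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.sigma_n < 0:
            raise ValueError("sigma_n must be nonnegative")

    @classmethod
    def off(cls, dt_sim=0.0005, seed=0):
        return cls(gamma=75.0, sigma_n=0.0, dt_sim=dt_sim, seed=seed)


@dataclass
class RateTensor:
    """Rates on a uniform time grid: array ``neurons x time x conditions``."""

    rates: np.ndarray
    t: np.ndarray
    condition_angles: np.ndarray
    coords: NeuronCoords = None

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.condition_angles = np.asarray(self.condition_angles, dtype=float)
        if self.rates.ndim != 3:
            raise ValueError("rates must be neurons x time x conditions")
        if self.rates.shape[1] != self.t.size:
            raise ValueError("time grid does not match rates")
        if self.rates.shape[2] != self.condition_angles.size:
            raise ValueError("condition angles do not match rates")

    @property
    def n_neurons(self):
        return self.rates.shape[0]


def _offset_quantiles(n_lines, chi):
    """Line offsets at midpoint quantiles of the marginal of
    ``theta_A - theta_B`` (density ``(1 + chi cos d) / 2 pi``)."""
    if abs(chi) < 1e-12:
        return TWO_PI * (np.arange(n_lines) + 0.5) / n_lines

    def cdf(x):
        return (x + chi * np.sin(x)) / TWO_PI

    qs = (np.arange(n_lines) + 0.5) / n_lines
    return np.array([brentq(lambda x, q=q: cdf(x) - q, 0.0, TWO_PI)
                     for q in qs])


def _factor_near_square(n):
    best = None
    for p in range(2, int(np.sqrt(n)) + 1):
        if n % p == 0:
            best = p
    if best is None:
        raise ValueError(
            f"n_theta={n} cannot be factored into lines x points-per-line; "
            "use a composite number")
    return best, n // best


def assign_coordinates(n_theta, n_eta, chi, eta_samples, seed=0,
                       n_lines=None) -> NetworkRealization:
    """Build a network realization matching the population density.

    Angular coordinates: ``n_theta`` points equally spaced along lines
    ``theta_A - theta_B = const``, with the line offsets placed at the
    midpoint quantiles of the offset marginal ``1 + chi cos``; this makes
    the empirical joint distribution match the angular density
    deterministically. ``n_theta`` must factor into (lines) x (points per
    line). Participation pairs are drawn i.i.d. from the provided samples
    (``eta_samples`` is a pair of arrays or a :class:`PopulationDensity`),
    and each block of ``n_eta`` consecutive neurons shares one angular
    location.
    """
    if isinstance(eta_samples, PopulationDensity):
        eta_A_src = eta_samples.eta_A_samples
        eta_B_src = eta_samples.eta_B_samples
    else:
        eta_A_src, eta_B_src = (np.asarray(s, float) for s in eta_samples)
    if n_lines is None:
        n_lines, n_per_line = _factor_near_square(int(n_theta))
    else:
        if n_theta % n_lines:
            raise ValueError("n_lines must divide n_theta")
        n_per_line = n_theta // n_lines
    offsets = _offset_quantiles(n_lines, chi)
    s = TWO_PI * np.arange(n_per_line) / n_per_line
    theta_A = np.repeat(s, n_lines)
    theta_B = wrap_angle(theta_A - np.tile(offsets, n_per_line))

    rng = np.random.default_rng(seed)
    eta_A = rng.choice(eta_A_src, size=n_eta, replace=True)
    eta_B = rng.choice(eta_B_src, size=n_eta, replace=True)

    coords = NeuronCoords(
        np.repeat(theta_A, n_eta),
        np.repeat(theta_B, n_eta),
        np.tile(eta_A, n_theta),
        np.tile(eta_B, n_theta),
    )
    return NetworkRealization(coords, int(n_theta), int(n_eta), float(chi),
                              int(seed))


def dense_coupling_matrix(net: NetworkRealization, params: CouplingParams):
    """Explicit ``N x N`` coupling matrix (small-N test oracle only)."""
    c = net.coords
    if net.n_neurons > 2000:
        raise ValueError("dense matrix path is restricted to small networks")
    post = NeuronCoords(c.theta_A[:, None], c.theta_B[:, None],
                        c.eta_A[:, None], c.eta_B[:, None])
    pre = NeuronCoords(c.theta_A[None, :], c.theta_B[None, :],
                       c.eta_A[None, :], c.eta_B[None, :])
    from .model import coupling_strength

    return coupling_strength(pre, post, params)


@dataclass
class OrderParamSeries:
    """Order-parameter time series per condition (arrays ``C x T``)."""

    t: np.ndarray
    condition_angles: np.ndarray
    r0: np.ndarray
    r_A: np.ndarray
    r_B: np.ndarray
    r0A: np.ndarray
    r0B: np.ndarray
    psi_A: np.ndarray = None
    psi_B: np.ndarray = None
    fallback_flags: np.ndarray = None

    def condition_mean(self):
        """Average the five observable series over conditions (the
        data-side estimator averages over the eight targets)."""
        return {
            "t": self.t,
            "r0": self.r0.mean(axis=0),
            "rA": self.r_A.mean(axis=0),
            "rB": self.r_B.mean(axis=0),
            "r0A": self.r0A.mean(axis=0),
            "r0B": self.r0B.mean(axis=0),
        }


@dataclass
class SimResult:
    """Output of a network simulation."""

    rates: RateTensor                  # trial-averaged
    order_params: OrderParamSeries     # trial-averaged, target-phase mode
    trial_rates: np.ndarray = None     # (trials, N, T, C) if kept
    trial_order_params: list = None    # per-trial OrderParamSeries


class SimulationDivergedError(RuntimeError):
    pass


def simulate_network(net: NetworkRealization, couplings: CouplingParams,
                     inputs: ExternalInputSeries, noise: NoiseParams,
                     tau=0.025, n_trials=1,
                     condition_angles=DEFAULT_CONDITION_ANGLES,
                     initial_rates=None, keep_trials=False,
                     keep_trial_order_params=False) -> SimResult:
    """Simulate the stochastic rate network for all conditions and trials.

    Each condition uses the same input schedule with ``phi_ext`` replaced
    by the condition angle; conditions are integrated in parallel
    (batched), trials sequentially with independent noise streams spawned
    from ``noise.seed``. Rates are recorded on the input time grid.
    """
    c = net.coords
    N = net.n_neurons
    cond = np.asarray(condition_angles, dtype=float)
    C = cond.size
    dt = noise.dt_sim
    if dt > tau / 5:
        raise ValueError("dt_sim must be <= tau / 5")
    n_bins = inputs.n_bins
    sub = max(1, int(round(inputs.dt / dt)))
    if abs(sub * dt - inputs.dt) > 1e-9 * inputs.dt:
        raise ValueError("input bin width must be a multiple of dt_sim")

    vA = c.eta_A * np.exp(1j * c.theta_A)      # (N,)
    vB = c.eta_B * np.exp(1j * c.theta_B)
    cosA = np.cos(c.theta_A[:, None] - cond[None, :])   # (N, C)
    cosB = np.cos(c.theta_B[:, None] - cond[None, :])
    etaA = c.eta_A[:, None]
    etaB = c.eta_B[:, None]
    cos_tA, sin_tA = np.cos(c.theta_A), np.sin(c.theta_A)
    cos_tB, sin_tB = np.cos(c.theta_B), np.sin(c.theta_B)

    ou_decay = np.exp(-noise.gamma * dt)
    ou_scale = noise.sigma_n * np.sqrt(
        (1.0 - np.exp(-2.0 * noise.gamma * dt)) / (2.0 * noise.gamma))

    seeds = np.random.SeedSequence(noise.seed).spawn(n_trials)
    T_rec = n_bins + 1
    mean_rates = np.zeros((N, T_rec, C))
    trial_rates = (np.zeros((n_trials, N, T_rec, C))
                   if keep_trials else None)
    trial_ops = [] if keep_trial_order_params else None

    for trial in range(n_trials):
        rng = np.random.default_rng(seeds[trial])
        r = (np.zeros((N, C)) if initial_rates is None
             else np.array(initial_rates, dtype=float, copy=True))
        xi = np.zeros((N, C))
        if noise.sigma_n > 0:
            xi = (noise.sigma_n / np.sqrt(2 * noise.gamma)
                  * rng.standard_normal((N, C)))
        rec = np.empty((N, T_rec, C))
        rec[:, 0, :] = r
        for i in range(n_bins):
            C0, CA, CB, eA, eB = inputs.at_bin(i)
            Iext = (C0 + CA * etaA + CB * etaB
                    + eA * etaA * cosA + eB * etaB * cosB)   # (N, C)
            for _ in range(sub):
                r0s = r.mean(axis=0)                          # (C,)
                ZA = vA @ r / N                               # (C,) complex
                ZB = vB @ r / N
                rec_drive = (
                    couplings.j0 * r0s[None, :]
                    + couplings.js_A * etaA
                    * (np.outer(cos_tA, ZA.real) + np.outer(sin_tA, ZA.imag))
                    + couplings.js_B * etaB
                    * (np.outer(cos_tB, ZB.real) + np.outer(sin_tB, ZB.imag))
                    + couplings.j_a * etaB
                    * (np.outer(cos_tB, ZA.real) + np.outer(sin_tB, ZA.imag))
                )
                drive = relu(rec_drive + Iext + xi)
                r = r + (dt / tau) * (drive - r)
                if noise.sigma_n > 0:
                    xi = ou_decay * xi + ou_scale * rng.standard_normal(
                        (N, C))
            if not np.all(np.isfinite(r)):
                raise SimulationDivergedError(
                    f"simulation diverged at bin {i}")
            rec[:, i + 1, :] = r
        mean_rates += rec
        if keep_trials:
            trial_rates[trial] = rec
        if keep_trial_order_params:
            trial_ops.append(order_params_from_rates(
                rec, c, cond, t=np.r_[inputs.times, inputs.t_end]))
    mean_rates /= n_trials
    t_grid = np.r_[inputs.times, inputs.t_end]
    tensor = RateTensor(mean_rates, t_grid, cond, coords=c)
    ops = order_params_from_rates(mean_rates, c, cond, t=t_grid)
    return SimResult(tensor, ops, trial_rates=trial_rates,
                     trial_order_params=trial_ops)


def order_params_from_rates(rates, coords: NeuronCoords, condition_angles,
                            phase_mode="target", t=None,
                            amplitude_floor=1e-9) -> OrderParamSeries:
    """Data-side order parameters from a rate tensor.

    Approximates the population integrals by sums over neurons. The bump
    phase is either the condition's target angle (``phase_mode="target"``,
    robust to angular heterogeneity and the estimator used throughout) or
    the self-consistent first-harmonic argument
    (``phase_mode="selfconsistent"``); where the harmonic amplitude is
    below the floor the self-consistent phase is undefined and the target
    angle is used instead (flagged).
    """
    if isinstance(rates, RateTensor):
        if t is None:
            t = rates.t
        rates = rates.rates
    rates = np.asarray(rates, dtype=float)
    cond = np.atleast_1d(np.asarray(condition_angles, dtype=float))
    if rates.ndim == 2:
        rates = rates[:, :, None]
    N, T, C = rates.shape
    if len(coords) != N:
        raise ValueError("coords length does not match rates")
    if phase_mode not in ("target", "selfconsistent"):
        raise ValueError("phase_mode must be 'target' or 'selfconsistent'")
    if t is None:
        t = np.arange(T, dtype=float)

    vA = coords.eta_A * np.exp(1j * coords.theta_A)
    vB = coords.eta_B * np.exp(1j * coords.theta_B)
    r0 = np.einsum("ntc->ct", rates) / N
    r0A = np.einsum("n,ntc->ct", coords.eta_A, rates) / N
    r0B = np.einsum("n,ntc->ct", coords.eta_B, rates) / N
    ZA = np.einsum("n,ntc->ct", vA, rates) / N      # (C, T) complex
    ZB = np.einsum("n,ntc->ct", vB, rates) / N

    flags = np.zeros((C, T), dtype=bool)
    if phase_mode == "target":
        psi_A = np.broadcast_to(cond[:, None], (C, T)).copy()
        psi_B = psi_A.copy()
    else:
        ampA = np.abs(ZA)
        ampB = np.abs(ZB)
        low = (ampA < amplitude_floor) | (ampB < amplitude_floor)
        psi_A = np.where(ampA < amplitude_floor, cond[:, None],
                         np.angle(ZA))
        psi_B = np.where(ampB < amplitude_floor, cond[:, None],
                         np.angle(ZB))
        flags = low
    r_A = (ZA * np.exp(-1j * psi_A)).real
    r_B = (ZB * np.exp(-1j * psi_B)).real
    return OrderParamSeries(np.asarray(t, float), cond, r0, r_A, r_B,
                            r0A, r0B, wrap_angle(psi_A), wrap_angle(psi_B),
                            flags)
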
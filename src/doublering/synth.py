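"""Synthetic sessions with known ground truth.

Generates model-consistent "recordings" of a delayed center-out reaching
task: a network realization drawn from the fitted selectivity density, a
per-scenario external-input schedule (feedforward, near-critical or
supercritical, mirroring the qualitatively distinct regimes of the
model), per-trial epoch durations (500 ms hold; 1000-1500 ms instructed
delay; ~300 ms movement), stochastic rate dynamics with
Ornstein-Uhlenbeck input noise, optional inhomogeneous-Poisson spikes,
and EMG traces as a noisy sparse linear readout of the rates. Every
session carries its ground truth, so generate-and-recover tests can
check each pipeline stage offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .inference import ObservedOrderParams
from .meanfield import OrderParamState, integrate_meanfield
from .model import CouplingParams, ExternalInputSeries, PopulationDensity
from .simulate import (
    NetworkRealization,
    NoiseParams,
    assign_coordinates,
    simulate_network,
)
from .tuning import TrialSet

__all__ = [
    "ScenarioSpec",
    "GroundTruth",
    "default_density",
    "generate_session",
    "generate_emg",
    "generate_order_param_obs",
    "make_input_schedule",
]

REGIMES = ("feedforward", "near_critical", "supercritical")


def default_density(seed=0, n_samples=400, chi=2.0 / 3.0, **kw):
    """Data-like selectivity density: angular correlation ``chi = 2/3``
    and skewed participation marginals (Beta(2, 4), most units weakly
    tuned with a tail of strongly participating ones, as in the
    normalized-amplitude distributions of the recordings)."""
    rng = np.random.default_rng(seed)
    return PopulationDensity(chi, rng.beta(2, 4, n_samples),
                             rng.beta(2, 4, n_samples), **kw)


@dataclass
class ScenarioSpec:
    """Configuration of one synthetic session.

    regime : ``feedforward`` (no direction-specific recurrence, tuned
        inputs carry the selectivity), ``near_critical`` (map-B coupling
        at 90% of its Turing-critical value, weak tuned inputs amplified
        by recurrence) or ``supercritical`` (130% of critical: the bump
        is self-sustained and untuned inputs modulate it).
    n_visible_units : units "recorded" from the network (subsampled).
    n_trials : trials per condition.
    durations : hold 0.5 s; delay uniform 1.0-1.5 s; movement uniform
        0.25-0.35 s.
    """

    regime: str = "near_critical"
    n_visible_units: int = 141
    n_trials: int = 10
    n_conditions: int = 8
    n_theta: int = 200
    n_eta: int = 8
    chi: float = 2.0 / 3.0
    tau: float = 0.025
    dt_bin: float = 0.005
    hold_duration: float = 0.5
    delay_range: tuple = (1.0, 1.5)
    move_range: tuple = (0.25, 0.35)
    noise: NoiseParams = None
    couplings: CouplingParams = None
    input_scale: float = 1.0
    poisson_spikes: bool = False
    rate_scale: float = 40.0      # Hz per model rate unit, for spiking
    seed: int = 0

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        if self.noise is None:
            self.noise = NoiseParams(seed=self.seed)


@dataclass
class GroundTruth:
    """Everything needed to reproduce and evaluate a session."""

    coords_table: np.ndarray            # visible units x 4
    visible_units: np.ndarray
    couplings: CouplingParams
    inputs: ExternalInputSeries         # template (nominal durations)
    network: NetworkRealization
    emg_weights: np.ndarray = None
    seed: int = 0


def _critical_js_B(density, js_A=0.0, j_a=0.0):
    from .meanfield import bifurcation_curve

    curve = bifurcation_curve(j_a, density, [js_A])
    return float(curve.js_B_critical[0])


def scenario_couplings(regime, density, j0=-0.5):
    """Coupling set for a named regime, anchored to the Turing-critical
    map-B coupling of the supplied density."""
    if regime == "feedforward":
        return CouplingParams(j0, 0.0, 0.0, 0.0)
    jsB_crit = _critical_js_B(density)
    if regime == "near_critical":
        return CouplingParams(j0, 0.2 * jsB_crit, 0.9 * jsB_crit, 0.0)
    return CouplingParams(j0, 0.2 * jsB_crit, 1.3 * jsB_crit, 0.0)


def make_input_schedule(spec: ScenarioSpec, density, couplings,
                        hold, delay, move, phi_ext=0.0):
    """Piecewise-linear input schedule for one trial's epoch durations.

    The task timeline is hold -> target onset -> delay -> go -> movement.
    In all regimes an untuned baseline keeps the network active; during
    the delay a map-A tuned input encodes the target; around movement
    onset the drive shifts to map B. In the feedforward regime the map-B
    drive is tuned; in the recurrent regimes the tuned component is weak
    (near-critical) or absent (supercritical) and untuned map-B input
    shifts the bump instead.
    """
    dt = spec.dt_bin
    rt = 0.1                                # reaction time go -> movement
    total = hold + delay + rt + move + 0.15  # short post-movement tail
    T = int(np.ceil(total / dt))
    t = dt * np.arange(T)
    t_target = hold
    t_go = hold + delay
    t_move = t_go + rt
    t_end = t_move + move

    def ramp(t0, t1, amp):
        return amp * np.clip((t - t0) / max(t1 - t0, dt), 0.0, 1.0)

    def pulse(t0, t1, amp, rise=0.05):
        return (amp * np.clip((t - t0) / rise, 0, 1)
                * np.clip(1.0 - (t - t1) / rise, 0, 1))

    C0 = np.full(T, 1.0)
    Z = np.zeros(T)
    if spec.regime == "feedforward":
        CA = Z
        CB = Z
        eA = pulse(t_target + 0.05, t_move, 1.2)
        eB = pulse(t_move - 0.05, t_end + 0.05, 1.5)
    elif spec.regime == "near_critical":
        CA = Z
        CB = pulse(t_move - 0.05, t_end + 0.05, 0.6)
        eA = pulse(t_target + 0.05, t_move, 1.0)
        eB = pulse(t_move - 0.05, t_end + 0.05, 0.35)
    else:  # supercritical: bump pinned by tuned input only during delay
        CA = Z
        CB = pulse(t_move - 0.05, t_end + 0.05, 0.8)
        eA = pulse(t_target + 0.05, t_move, 0.8)
        eB = Z
    s = spec.input_scale
    return ExternalInputSeries(dt, s * C0, s * CA, s * CB, s * eA,
                               s * eB, phi_ext=phi_ext), \
        {"t_target": t_target, "t_go": t_go, "t_move_on": t_move,
         "t_move_off": t_end}


def generate_session(spec: ScenarioSpec, density=None):
    """Simulate a full synthetic session.

    Returns ``(TrialSet, GroundTruth)``. Per-trial epoch durations are
    drawn from the task distributions; each trial is simulated for all
    conditions with independent noise; rates of the visible subset are
    stored as per-trial traces (or converted to inhomogeneous-Poisson
    spike times when ``spec.poisson_spikes``).
    """
    rng = np.random.default_rng(spec.seed)
    if density is None:
        density = default_density(seed=spec.seed)
    couplings = spec.couplings or scenario_couplings(spec.regime, density)
    net = assign_coordinates(spec.n_theta, spec.n_eta, spec.chi,
                             density, seed=spec.seed)
    N = net.n_neurons
    visible = rng.choice(N, size=min(spec.n_visible_units, N),
                         replace=False)
    cond_angles = 2 * np.pi * np.arange(spec.n_conditions) \
        / spec.n_conditions

    events = []
    rate_traces = {}
    spike_rows = []
    trial_id = 0
    template_inputs = None
    for trial in range(spec.n_trials):
        hold = spec.hold_duration
        delay = rng.uniform(*spec.delay_range)
        move = rng.uniform(*spec.move_range)
        inputs, marks = make_input_schedule(spec, density, couplings,
                                            hold, delay, move)
        if template_inputs is None:
            template_inputs = inputs
        noise = NoiseParams(gamma=spec.noise.gamma,
                            sigma_n=spec.noise.sigma_n,
                            dt_sim=spec.noise.dt_sim,
                            seed=int(rng.integers(2**31 - 1)))
        res = simulate_network(net, couplings, inputs, noise,
                               tau=spec.tau, n_trials=1,
                               condition_angles=cond_angles)
        rates = res.rates.rates[visible]       # (n_vis, T, C)
        t_grid = res.rates.t
        for k in range(spec.n_conditions):
            events.append((trial_id, k + 1, marks["t_target"],
                           marks["t_go"], marks["t_move_on"],
                           marks["t_move_off"]))
            if spec.poisson_spikes:
                lam = np.clip(rates[:, :, k], 0, None) * spec.rate_scale
                dtg = np.diff(t_grid).mean()
                counts = rng.poisson(lam * dtg)
                for i_unit, row in enumerate(counts):
                    nz = np.nonzero(row)[0]
                    for ib in nz:
                        times = (t_grid[ib]
                                 + dtg * rng.random(row[ib]))
                        spike_rows.extend(
                            (trial_id, i_unit, ts) for ts in times)
            else:
                rate_traces[trial_id] = (t_grid, rates[:, :, k])
            trial_id += 1
    events = pd.DataFrame(events, columns=[
        "trial_id", "condition", "t_target", "t_go", "t_move_on",
        "t_move_off"])
    spikes = (pd.DataFrame(spike_rows,
                           columns=["trial_id", "unit_id", "spike_time"])
              if spec.poisson_spikes else None)
    trials = TrialSet(events, len(visible), spikes=spikes,
                      rates=rate_traces if not spec.poisson_spikes
                      else None,
                      n_conditions=spec.n_conditions)
    truth = GroundTruth(net.coords.as_table()[visible], visible,
                        couplings, template_inputs, net, seed=spec.seed)
    return trials, truth


def generate_emg(rates, n_muscles=13, noise_sd=0.0, seed=0,
                 sparsity=0.05):
    """EMG traces as a noisy sparse linear readout of unit rates.

    ``rates`` is ``(n_units, T*C)``; weights are sparse Gaussian
    (fraction ``sparsity`` nonzero) plus an intercept; Gaussian noise of
    sd ``noise_sd`` is added. Returns ``(emg, true_weights)`` with
    ``true_weights`` of shape ``(n_muscles, n_units + 1)``.
    """
    rng = np.random.default_rng(seed)
    rates = np.asarray(rates, dtype=float)
    n_units, Tn = rates.shape
    W = rng.standard_normal((n_muscles, n_units)) \
        * (rng.random((n_muscles, n_units)) < sparsity)
    W /= max(np.sqrt(n_units * sparsity), 1.0)
    w0 = rng.standard_normal(n_muscles) * 0.1
    emg = W @ rates + w0[:, None]
    if noise_sd > 0:
        emg = emg + noise_sd * rng.standard_normal(emg.shape)
    return emg, np.column_stack([W, w0])


def generate_order_param_obs(couplings: CouplingParams,
                             inputs: ExternalInputSeries,
                             density: PopulationDensity,
                             noise_sd=0.0, seed=0, tau=0.025,
                             initial=None) -> ObservedOrderParams:
    """Forward-model order-parameter observations for inference tests.

    Integrates the mean-field dynamics and optionally adds i.i.d.
    Gaussian observation noise; the SEM fields are set to the noise sd
    (zero-noise observations carry zero SEM).
    """
    rng = np.random.default_rng(seed)
    if initial is None:
        initial = OrderParamState(psi_A=inputs.phi_ext,
                                  psi_B=inputs.phi_ext)
    traj = integrate_meanfield(initial, couplings, inputs, density,
                               tau=tau)
    mat = traj.as_matrix()[:-1]
    if noise_sd > 0:
        mat = mat + noise_sd * rng.standard_normal(mat.shape)
    sem = {k: np.full(mat.shape[0], float(noise_sd))
           for k in ("r0", "rA", "rB", "r0A", "r0B")}
    return ObservedOrderParams(inputs.dt, mat[:, 0], mat[:, 1], mat[:, 2],
                               mat[:, 3], mat[:, 4], sem=sem,
                               t0=inputs.t0)
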
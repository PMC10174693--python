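"""Order-parameter dynamics of the two-map ring network.

The population activity is summarized by the order parameters
``r0`` (mean rate), ``r_A, r_B`` (participation-weighted first Fourier
amplitudes of the activity profile over each map), the bump phases
``psi_A, psi_B``, and the auxiliary participation-weighted mean rates
``r0A, r0B``. With cosine couplings and cosine-tuned inputs, the total
input to a neuron at coordinates ``x`` is a constant plus one cosine per
map, so the angular integral over one map can be done in closed form
(Fourier coefficients of a rectified cosine); the remaining angular
integral is evaluated on a 1-D periodic trapezoid grid, which is
spectrally accurate, and the participation integral on the density's
quantile atoms. In the fully linear (above-threshold) regime the scheme
is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _fastpath as _fast
from .model import (
    CouplingParams,
    ExternalInputSeries,
    PopulationDensity,
    relu,
    wrap_angle,
)

__all__ = [
    "OrderParamState",
    "EffectiveInputs",
    "MeanFieldTrajectory",
    "PhaseDiagram",
    "StabilityResult",
    "AmplitudeInstabilityError",
    "BumpConvergenceError",
    "order_param_rhs",
    "integrate_meanfield",
    "homogeneous_fixed_point",
    "homogeneous_stability",
    "homogeneous_jacobian",
    "numeric_jacobian",
    "bifurcation_curve",
    "stationary_bump",
    "effective_inputs",
]

#: amplitude below which a bump phase is considered undefined and frozen
AMPLITUDE_FLOOR = 1e-9


class AmplitudeInstabilityError(ValueError):
    """Raised when ``j0 >= 1`` and the homogeneous rate diverges."""


class BumpConvergenceError(RuntimeError):
    """Raised when the stationary-bump iteration fails to converge."""

    def __init__(self, message, residual):
        super().__init__(message)
        self.residual = residual


@dataclass
class OrderParamState:
    """Low-dimensional dynamical state of the network.

    ``r0``: mean population rate; ``r_A``, ``r_B``: nonnegative bump
    amplitudes in maps A and B; ``psi_A``, ``psi_B``: bump phases;
    ``r0A``, ``r0B``: participation-weighted mean rates.
    """

    r0: float = 0.0
    r_A: float = 0.0
    r_B: float = 0.0
    psi_A: float = 0.0
    psi_B: float = 0.0
    r0A: float = 0.0
    r0B: float = 0.0

    def as_array(self):
        return np.array([self.r0, self.r_A, self.r_B, self.psi_A,
                         self.psi_B, self.r0A, self.r0B])

    @classmethod
    def from_array(cls, arr):
        return cls(*(float(v) for v in arr))


@dataclass
class EffectiveInputs:
    """Amplitudes of the total input decomposed per map.

    ``I_A = js_A * r_A + eps_A`` and ``I_B = js_B * r_B + j_a * r_A +
    eps_B`` are the cosine-modulation amplitudes when all phases are
    aligned; ``I0`` is the per-participation baseline ``(C0 + j0*r0, CA,
    CB)``.
    """

    I0: tuple
    I_A: float
    I_B: float


def effective_inputs(state: OrderParamState, couplings: CouplingParams,
                     inputs_at_t) -> EffectiveInputs:
    C0, CA, CB, eA, eB = inputs_at_t
    return EffectiveInputs(
        I0=(C0 + couplings.j0 * state.r0, CA, CB),
        I_A=couplings.js_A * state.r_A + eA,
        I_B=couplings.js_B * state.r_B + couplings.j_a * state.r_A + eB,
    )


# ---------------------------------------------------------------------------
# closed-form Fourier coefficients of a rectified cosine
# ---------------------------------------------------------------------------

def _rect_cos_fourier(A, q):
    """Harmonics 0..2 of ``[A + q cos v]_+`` over ``v`` (q >= 0).

    Returns ``g_k = (1/2pi) int [A + q cos v]_+ cos(k v) dv`` for k=0,1,2.
    The sine moments vanish by symmetry.
    """
    A = np.asarray(A, dtype=float)
    q = np.broadcast_to(np.asarray(q, dtype=float), A.shape)
    tiny = q < 1e-300
    qs = np.where(tiny, 1.0, q)
    # cos of the half-support angle c = arccos(-A/q); derive sin(kc) from it
    cc = np.clip(-A / qs, -1.0, 1.0)
    sc = np.sqrt(1.0 - cc * cc)
    c = np.arccos(cc)
    sin3c = sc * (3.0 - 4.0 * sc * sc)
    g0 = (A * c + q * sc) / np.pi
    g1 = (A * sc + q * (c + sc * cc) / 2.0) / np.pi
    g2 = (A * sc * cc + q * (sc + sin3c / 3.0) / 2.0) / np.pi
    g0 = np.where(tiny, relu(A), g0)
    g1 = np.where(tiny, 0.0, g1)
    g2 = np.where(tiny, 0.0, g2)
    return g0, g1, g2


def _u_weights(density):
    W = getattr(density, "_u_weights", None)
    if W is None:
        n_u = density.cos_u.size
        W = np.stack([np.ones(n_u), density.cos_u, density.sin_u],
                     axis=1) / n_u
        density._u_weights = W
    return W


def _integrals_batch(r0, r_A, r_B, psi_A, psi_B, u5, phi_ext,
                     couplings: CouplingParams, density: PopulationDensity):
    """Batched population integrals of ``[I_tot]_+``.

    All state arguments are shape ``(B,)`` and ``u5`` is ``(B, 5)``;
    returns five ``(B,)`` arrays ``(M0, K_A, K_B, M0A, M0B)`` where
    ``M0 = int rho [I]_+``, ``K_A = int rho eta_A e^{i theta_A} [I]_+``
    (complex; its projection on ``e^{i psi_A}`` gives the r_A and psi_A
    integrands), similarly ``K_B``, and ``M0A/B = int rho eta_{A/B} [I]_+``.
    """
    C0, CA, CB, eA, eB = (u5[:, k] for k in range(5))
    chi = density.chi
    eipA = np.exp(1j * psi_A)
    zA = couplings.js_A * r_A * eipA + eA * np.exp(1j * phi_ext)
    zB = (couplings.js_B * r_B * np.exp(1j * psi_B)
          + couplings.j_a * r_A * eipA
          + eB * np.exp(1j * phi_ext))
    phi1 = np.angle(zA)                                     # (B,)
    phi2 = np.angle(zB)
    delta = phi1 - phi2
    a = density.eta_A_grid                                  # (S,)
    b = density.eta_B_grid
    p = a[None, :] * np.abs(zA)[:, None]                    # (B, S)
    q = b[None, :] * np.abs(zB)[:, None]
    S0 = (C0 + couplings.j0 * r0)[:, None] + CA[:, None] * a \
        + CB[:, None] * b

    cos_u, sin_u = density.cos_u, density.sin_u
    Au = S0[..., None] + p[..., None] * cos_u               # (B, S, n_u)
    g0, g1, g2 = _rect_cos_fourier(Au, q[..., None])

    cd, sd = np.cos(delta), np.sin(delta)
    cos_ud = cos_u * cd[:, None] - sin_u * sd[:, None]      # (B, n_u)
    # v-averaged integrand including the angular-correlation factor;
    # the sine v-moments of the rectified cosine vanish by symmetry
    h_mix = g0 + chi * cos_ud[:, None, :] * g1
    W = _u_weights(density)  # columns [1, cos u, sin u] / n_u
    Hm = h_mix @ W           # (B, S, 3): mean, <.. cos u>, <.. sin u>
    G0 = g0 @ W
    G2 = g2 @ W
    M0_atom = Hm[..., 0]
    KA_atom = (Hm[..., 1] + 1j * Hm[..., 2]) * np.exp(1j * phi1)[:, None]
    eid = cd + 1j * sd
    mean_eiu_g0 = G0[..., 1] + 1j * G0[..., 2]
    mean_conj_eiu_g2 = G2[..., 1] - 1j * G2[..., 2]
    KB_atom = (g1 @ W[:, 0]
               + 0.5 * chi * (eid[:, None] * mean_eiu_g0
                              + np.conj(eid)[:, None] * mean_conj_eiu_g2)
               ) * np.exp(1j * phi2)[:, None]

    w = density.w_eta
    M0 = w * M0_atom.sum(axis=-1)
    M0A = w * (M0_atom @ a)
    M0B = w * (M0_atom @ b)
    K_A = w * (KA_atom @ a)
    K_B = w * (KB_atom @ b)
    return M0, K_A, K_B, M0A, M0B


def _integrals(r0, r_A, r_B, psi_A, psi_B, inputs_at_t, phi_ext,
               couplings: CouplingParams, density: PopulationDensity):
    """Scalar wrapper around :func:`_integrals_batch`."""
    one = np.ones(1)
    out = _integrals_batch(r0 * one, r_A * one, r_B * one, psi_A * one,
                           psi_B * one,
                           np.asarray(inputs_at_t, float)[None, :],
                           phi_ext, couplings, density)
    return tuple(v[0] for v in out)


def order_param_rhs(state: OrderParamState, couplings: CouplingParams,
                    inputs_at_t, density: PopulationDensity, tau=0.025):
    """Time derivative of the seven order parameters.

    ``inputs_at_t`` is either a 5-tuple ``(C0, CA, CB, eps_A, eps_B)``
    (with ``phi_ext`` taken as 0) or a pair ``(tuple, phi_ext)``.
    Below the amplitude floor a phase derivative is set to zero (the phase
    is undefined there); the tangential drive is reported through the
    returned array only via the amplitude equations.
    """
    if len(inputs_at_t) == 2 and np.ndim(inputs_at_t[0]) == 1:
        u5, phi_ext = inputs_at_t
    else:
        u5, phi_ext = inputs_at_t, 0.0
    return _rhs_array(state.as_array(), couplings, np.asarray(u5, float),
                      phi_ext, density, tau)


def _rhs_batch(Y, couplings, U, phi_ext, density, tau):
    """Batched RHS: ``Y`` is ``(B, 7)``, ``U`` is ``(B, 5)``; returns (B, 7)."""
    if _fast.HAVE_NUMBA:
        out = np.empty_like(Y)
        return _fast._rhs_kernel(
            np.ascontiguousarray(Y), np.ascontiguousarray(U),
            couplings.j0, couplings.js_A, couplings.js_B, couplings.j_a,
            float(phi_ext), density.chi,
            np.ascontiguousarray(density.eta_A_grid),
            np.ascontiguousarray(density.eta_B_grid),
            density.w_eta, density.cos_u, density.sin_u, tau,
            AMPLITUDE_FLOOR, out)
    r0, r_A, r_B, psi_A, psi_B, r0A, r0B = (Y[:, k] for k in range(7))
    M0, K_A, K_B, M0A, M0B = _integrals_batch(
        r0, r_A, r_B, psi_A, psi_B, U, phi_ext, couplings, density)
    pA = K_A * np.exp(-1j * psi_A)
    pB = K_B * np.exp(-1j * psi_B)
    d = np.empty_like(Y)
    d[:, 0] = (-r0 + M0) / tau
    d[:, 1] = (-r_A + pA.real) / tau
    d[:, 2] = (-r_B + pB.real) / tau
    d[:, 3] = np.where(r_A > AMPLITUDE_FLOOR,
                       pA.imag / (tau * np.maximum(r_A, AMPLITUDE_FLOOR)),
                       0.0)
    d[:, 4] = np.where(r_B > AMPLITUDE_FLOOR,
                       pB.imag / (tau * np.maximum(r_B, AMPLITUDE_FLOOR)),
                       0.0)
    d[:, 5] = (-r0A + M0A) / tau
    d[:, 6] = (-r0B + M0B) / tau
    return d


def _rhs_array(y, couplings, u5, phi_ext, density, tau):
    return _rhs_batch(np.asarray(y, float)[None, :], couplings,
                      np.asarray(u5, float)[None, :], phi_ext, density,
                      tau)[0]


def evolve_bin_batch(Y0, U, couplings, density, tau, dt, n_sub,
                     phi_ext=0.0):
    """Evolve a batch of states for one input bin of width ``dt``.

    ``Y0`` is ``(B, 7)``, ``U`` is ``(B, 5)`` constant per-bin inputs;
    fixed-step RK4 with ``n_sub`` substeps.
    """
    h = dt / n_sub
    Y = np.asarray(Y0, float)
    for _ in range(n_sub):
        k1 = _rhs_batch(Y, couplings, U, phi_ext, density, tau)
        k2 = _rhs_batch(Y + 0.5 * h * k1, couplings, U, phi_ext, density, tau)
        k3 = _rhs_batch(Y + 0.5 * h * k2, couplings, U, phi_ext, density, tau)
        k4 = _rhs_batch(Y + h * k3, couplings, U, phi_ext, density, tau)
        Y = Y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return Y


@dataclass
class MeanFieldTrajectory:
    """Order-parameter trajectory sampled on the input time grid."""

    t: np.ndarray
    r0: np.ndarray
    r_A: np.ndarray
    r_B: np.ndarray
    psi_A: np.ndarray
    psi_B: np.ndarray
    r0A: np.ndarray
    r0B: np.ndarray

    def state_at(self, i) -> OrderParamState:
        return OrderParamState(self.r0[i], self.r_A[i], self.r_B[i],
                               self.psi_A[i], self.psi_B[i],
                               self.r0A[i], self.r0B[i])

    def as_matrix(self):
        """``(T, 5)`` matrix of the observable series (r0, rA, rB, r0A, r0B)."""
        return np.column_stack([self.r0, self.r_A, self.r_B,
                                self.r0A, self.r0B])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "t": self.t, "r0": self.r0, "rA": self.r_A, "rB": self.r_B,
            "psiA": self.psi_A, "psiB": self.psi_B,
            "r0A": self.r0A, "r0B": self.r0B,
        })


def _rk4_steps(y, couplings, u5, phi_ext, density, tau, h, n_steps):
    for _ in range(n_steps):
        k1 = _rhs_array(y, couplings, u5, phi_ext, density, tau)
        k2 = _rhs_array(y + 0.5 * h * k1, couplings, u5, phi_ext, density, tau)
        k3 = _rhs_array(y + 0.5 * h * k2, couplings, u5, phi_ext, density, tau)
        k4 = _rhs_array(y + h * k3, couplings, u5, phi_ext, density, tau)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return y


class IntegrationDivergedError(RuntimeError):
    def __init__(self, message, last_valid_time):
        super().__init__(message)
        self.last_valid_time = last_valid_time


def integrate_meanfield(initial: OrderParamState, couplings: CouplingParams,
                        inputs: ExternalInputSeries,
                        density: PopulationDensity, tau=0.025,
                        t_span=None, max_step=1e-3) -> MeanFieldTrajectory:
    """Integrate the order-parameter ODEs with fixed-step RK4.

    Inputs are piecewise constant per bin; the step is
    ``min(max_step, dt)`` refined to divide the bin width exactly. The
    trajectory is sampled on the input grid (bin left edges, plus the end
    of the last bin).
    """
    dt = inputs.dt
    if t_span is None:
        i_lo, i_hi = 0, inputs.n_bins
    else:
        i_lo = inputs.bin_index(t_span[0])
        i_hi = inputs.bin_index(t_span[1] - 0.5 * dt) + 1
    n_sub = max(1, int(np.ceil(dt / max_step - 1e-12)))
    h = dt / n_sub
    n_out = i_hi - i_lo + 1
    out = np.empty((n_out, 7))
    y = initial.as_array().astype(float)
    out[0] = y
    for k, i in enumerate(range(i_lo, i_hi)):
        u5 = np.asarray(inputs.at_bin(i), dtype=float)
        y = _rk4_steps(y, couplings, u5, inputs.phi_ext, density, tau,
                       h, n_sub)
        if not np.all(np.isfinite(y)):
            raise IntegrationDivergedError(
                "mean-field integration diverged",
                last_valid_time=inputs.t0 + i * dt)
        out[k + 1] = y
    t = inputs.t0 + dt * np.arange(i_lo, i_hi + 1)
    return MeanFieldTrajectory(t, out[:, 0], out[:, 1], out[:, 2],
                               wrap_angle(out[:, 3]), wrap_angle(out[:, 4]),
                               out[:, 5], out[:, 6])


# ---------------------------------------------------------------------------
# stationary states and stability
# ---------------------------------------------------------------------------

def homogeneous_fixed_point(couplings: CouplingParams, C0, CA, CB,
                            density: PopulationDensity):
    """Homogeneous (untuned) stationary state.

    ``r0 = (C0 + <eta_A> CA + <eta_B> CB) / (1 - j0)`` when positive, else
    0; the per-participation rate profile is
    ``r(eta_A, eta_B) = [C0 + eta_A CA + eta_B CB + j0 r0]_+``.
    """
    if couplings.j0 >= 1.0:
        raise AmplitudeInstabilityError(
            "j0 >= 1: amplitude instability, no bounded homogeneous state")
    num = C0 + density.mean_eta_A * CA + density.mean_eta_B * CB
    r0 = max(num / (1.0 - couplings.j0), 0.0)

    def profile(eta_A, eta_B):
        return relu(C0 + np.asarray(eta_A) * CA + np.asarray(eta_B) * CB
                    + couplings.j0 * r0)

    return r0, profile


@dataclass
class StabilityResult:
    stable: bool
    margin_trace: float
    margin_det: float

    def __iter__(self):
        yield self.stable
        yield (self.margin_trace, self.margin_det)


def homogeneous_stability(couplings: CouplingParams,
                          density: PopulationDensity) -> StabilityResult:
    """Linear stability of the homogeneous state against bump formation.

    The homogeneous state is stable iff ``j0 < 1`` and both
    ``j_a F_AB + js_A F_AA + js_B F_BB < 2`` (trace condition) and
    ``(1 - js_A F_AA)(1 - js_B F_BB) - (j_a + js_A js_B F_AB) F_AB > 0``
    (determinant condition) hold, with ``F_AA = <eta_A^2>/2``,
    ``F_BB = <eta_B^2>/2`` and ``F_AB = (chi/4) <eta_A> <eta_B>``.
    Margins are positive when the corresponding condition holds.
    """
    FAA, FBB, FAB = density.F_AA, density.F_BB, density.F_AB
    m_tr = 2.0 - (couplings.j_a * FAB + couplings.js_A * FAA
                  + couplings.js_B * FBB)
    m_det = ((1.0 - couplings.js_A * FAA) * (1.0 - couplings.js_B * FBB)
             - (couplings.j_a + couplings.js_A * couplings.js_B * FAB) * FAB)
    stable = bool(couplings.j0 < 1.0 and m_tr > 0.0 and m_det > 0.0)
    return StabilityResult(stable, float(m_tr), float(m_det))


def homogeneous_jacobian(couplings: CouplingParams,
                         density: PopulationDensity):
    """Analytic Jacobian of the ``(r0, r_A, r_B)`` dynamics (units of 1/tau)."""
    FAA, FBB, FAB = density.F_AA, density.F_BB, density.F_AB
    return np.array([
        [-1.0 + couplings.j0, 0.0, 0.0],
        [0.0, -1.0 + couplings.js_A * FAA + couplings.j_a * FAB,
         couplings.js_B * FAB],
        [0.0, couplings.js_A * FAB + couplings.j_a * FBB,
         -1.0 + couplings.js_B * FBB],
    ])


def numeric_jacobian(couplings: CouplingParams, density: PopulationDensity,
                     C0=1.0, CA=0.0, CB=0.0, delta=1e-6, tau=0.025):
    """Finite-difference Jacobian of the amplitude dynamics at the
    homogeneous fixed point, with phases held at zero.

    Serves as an independent numerical check of the closed-form stability
    conditions. Requires a strictly positive fixed-point rate so the
    dynamics is locally linear. Returned in units of 1/tau.
    """
    r0_star, _ = homogeneous_fixed_point(couplings, C0, CA, CB, density)
    if r0_star <= 0:
        raise ValueError("fixed point rate must be positive for the probe")
    u5 = np.array([C0, CA, CB, 0.0, 0.0])
    base = np.array([r0_star, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
    J = np.empty((3, 3))
    for j in range(3):
        yp = base.copy()
        ym = base.copy()
        yp[j] += delta
        ym[j] -= delta
        # rA, rB may not go negative; probe one-sided there
        if j > 0:
            ym[j] = base[j]
        fp = _rhs_array(yp, couplings, u5, 0.0, density, tau)
        fm = _rhs_array(ym, couplings, u5, 0.0, density, tau)
        J[:, j] = (fp[:3] - fm[:3]) / (yp[j] - ym[j])
    return J * tau


@dataclass
class PhaseDiagram:
    """Homogeneous-state stability over a grid of symmetric couplings."""

    js_A_grid: np.ndarray
    js_B_grid: np.ndarray
    j_a: float
    stable_mask: np.ndarray = None      # (len(jsA), len(jsB)) boolean
    js_B_critical: np.ndarray = None    # boundary jsB*(jsA); NaN if open

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, ja_ in enumerate(self.js_A_grid):
            for j, jb in enumerate(self.js_B_grid):
                rows.append((ja_, jb, self.j_a,
                             bool(self.stable_mask[i, j])))
        return pd.DataFrame(rows,
                            columns=["jsA", "jsB", "ja", "stable"])


def bifurcation_curve(j_a, density: PopulationDensity, js_A_grid,
                      j0=0.0, js_B_max=None, tol=1e-6,
                      js_B_grid=None) -> PhaseDiagram:
    """Turing-bifurcation boundary ``js_B*(js_A)`` at fixed ``j_a``.

    For each ``js_A``, the smallest ``js_B >= 0`` at which the homogeneous
    state loses stability, found by bisection to ``tol``. Points where no
    root exists in the bracket are reported as NaN (open boundary).
    """
    js_A_grid = np.atleast_1d(np.asarray(js_A_grid, dtype=float))
    if js_B_max is None:
        js_B_max = 4.0 / max(density.F_BB, 1e-12)

    def unstable(jsA, jsB):
        res = homogeneous_stability(
            CouplingParams(j0, jsA, jsB, j_a), density)
        return not (res.margin_trace > 0 and res.margin_det > 0)

    crit = np.full(js_A_grid.size, np.nan)
    for i, jsA in enumerate(js_A_grid):
        lo, hi = 0.0, js_B_max
        if unstable(jsA, lo):
            crit[i] = 0.0
            continue
        if not unstable(jsA, hi):
            continue  # open boundary within the bracket
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if unstable(jsA, mid):
                hi = mid
            else:
                lo = mid
        crit[i] = 0.5 * (lo + hi)
    pd_ = PhaseDiagram(js_A_grid, js_B_grid if js_B_grid is not None
                       else np.array([]), float(j_a),
                       js_B_critical=crit)
    if js_B_grid is not None:
        js_B_grid = np.atleast_1d(np.asarray(js_B_grid, dtype=float))
        mask = np.empty((js_A_grid.size, js_B_grid.size), dtype=bool)
        for i, jsA in enumerate(js_A_grid):
            for j, jsB in enumerate(js_B_grid):
                res = homogeneous_stability(
                    CouplingParams(j0, jsA, jsB, j_a), density)
                mask[i, j] = res.stable
        pd_.stable_mask = mask
        pd_.js_B_grid = js_B_grid
    return pd_


def stationary_bump(couplings: CouplingParams, const_inputs,
                    density: PopulationDensity, psi_seed=0.0,
                    damping=0.5, tol=1e-10, max_iter=10000,
                    seed_amplitude=0.1) -> OrderParamState:
    """Self-consistent stationary state with bump phases fixed at ``psi_seed``.

    Damped fixed-point iteration of the stationarity conditions
    ``r = I[r]`` starting from a small bump at ``psi_seed``. With
    sub-critical couplings and untuned input the iteration collapses onto
    the homogeneous state; above the bifurcation it converges to the bump
    branch.
    """
    const_inputs = tuple(const_inputs) + (0.0,) * (5 - len(const_inputs))
    u5 = np.asarray(const_inputs[:5], dtype=float)
    psi = float(psi_seed)
    try:
        r0, _ = homogeneous_fixed_point(
            couplings, u5[0], u5[1], u5[2], density)
    except AmplitudeInstabilityError:
        raise
    amp = seed_amplitude * (r0 + 1.0)
    r = np.array([max(r0, amp), amp, amp])
    resid = np.inf
    for _ in range(max_iter):
        M0, K_A, K_B, M0A, M0B = _integrals(
            r[0], r[1], r[2], psi, psi, u5, psi, couplings, density)
        target = np.array([M0, (K_A * np.exp(-1j * psi)).real,
                           (K_B * np.exp(-1j * psi)).real])
        target[1:] = np.maximum(target[1:], 0.0)
        new = (1.0 - damping) * r + damping * target
        resid = np.max(np.abs(new - r))
        r = new
        if resid < tol:
            break
    else:
        raise BumpConvergenceError(
            f"stationary bump did not converge (residual {resid:.3g})",
            residual=resid)
    M0, K_A, K_B, M0A, M0B = _integrals(
        r[0], r[1], r[2], psi, psi, u5, psi, couplings, density)
    return OrderParamState(r[0], r[1], r[2], wrap_angle(psi),
                           wrap_angle(psi), M0A, M0B)
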
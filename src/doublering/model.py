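"""Core model definitions for the two-map ring network.

Each neuron lives at a point ``x = (theta_A, theta_B, eta_A, eta_B)`` in a
four-dimensional selectivity space: a preferred direction and a degree of
participation for the preparatory map (A) and for the execution map (B).
Synaptic couplings and external inputs are parameterized in terms of these
coordinates; the population is described by a density over ``x`` that
factorizes into an angular part (correlated across the two maps) and
independent participation marginals on ``[0, 1]``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "NeuronCoords",
    "CouplingParams",
    "ExternalInputSeries",
    "DynamicsParams",
    "PopulationDensity",
    "ReflectedKDE",
    "angular_density",
    "coupling_strength",
    "external_input_value",
    "relu",
    "wrap_angle",
]

TWO_PI = 2.0 * np.pi


def wrap_angle(theta):
    """Reduce angles to ``[0, 2*pi)``."""
    return np.mod(theta, TWO_PI)


def relu(x):
    """Threshold-linear transfer function ``[x]_+``."""
    return np.maximum(x, 0.0)


@dataclass
class NeuronCoords:
    """Selectivity coordinates of one or many neurons.

    Angles are wrapped to ``[0, 2*pi)`` and participations clipped to
    ``[0, 1]`` on construction. All four fields broadcast together, so the
    class holds either a single neuron (scalars) or a population (arrays).
    """

    theta_A: np.ndarray
    theta_B: np.ndarray
    eta_A: np.ndarray
    eta_B: np.ndarray

    def __post_init__(self):
        self.theta_A = wrap_angle(np.asarray(self.theta_A, dtype=float))
        self.theta_B = wrap_angle(np.asarray(self.theta_B, dtype=float))
        self.eta_A = np.clip(np.asarray(self.eta_A, dtype=float), 0.0, 1.0)
        self.eta_B = np.clip(np.asarray(self.eta_B, dtype=float), 0.0, 1.0)
        b = np.broadcast(self.theta_A, self.theta_B, self.eta_A, self.eta_B)
        self._shape = b.shape

    def __len__(self):
        if self._shape == ():
            return 1
        return self._shape[0]

    def as_table(self):
        """Return an ``(n, 4)`` array ``[theta_A, theta_B, eta_A, eta_B]``."""
        cols = np.broadcast_arrays(
            self.theta_A, self.theta_B, self.eta_A, self.eta_B
        )
        return np.stack([np.atleast_1d(c) for c in cols], axis=1)

    @classmethod
    def from_table(cls, table):
        table = np.asarray(table, dtype=float)
        return cls(table[:, 0], table[:, 1], table[:, 2], table[:, 3])


@dataclass
class CouplingParams:
    """Dimensionless gains of the synaptic coupling rule.

    ``j0`` is a uniform (inhibitory when negative) term, ``js_A`` and
    ``js_B`` are the symmetric direction-specific amplitudes of maps A and
    B, and ``j_a`` is the asymmetric map-A-to-map-B amplitude.
    """

    j0: float = 0.0
    js_A: float = 0.0
    js_B: float = 0.0
    j_a: float = 0.0

    def __post_init__(self):
        for name in ("j0", "js_A", "js_B", "j_a"):
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise ValueError(f"coupling parameter {name} must be finite")
            setattr(self, name, v)

    def as_array(self):
        return np.array([self.j0, self.js_A, self.js_B, self.j_a])

    @classmethod
    def from_array(cls, arr):
        return cls(*(float(v) for v in arr))

    def to_dict(self):
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


@dataclass
class DynamicsParams:
    """Single-neuron rate dynamics parameters.

    tau : rate time constant in seconds (default 25 ms).
    dt_sim : integration step in seconds; must satisfy ``dt_sim <= tau / 5``.
    transfer : only the threshold-linear transfer function is supported.
    """

    tau: float = 0.025
    dt_sim: float = 0.0005
    transfer: str = "threshold-linear"

    def __post_init__(self):
        if not (0.0 < self.dt_sim <= self.tau / 5.0):
            raise ValueError("require 0 < dt_sim <= tau / 5")
        if self.transfer != "threshold-linear":
            raise ValueError("only the threshold-linear transfer is supported")

    def to_dict(self):
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


@dataclass
class ExternalInputSeries:
    """Time-varying external-input parameters on a uniform grid.

    The input to a neuron at coordinates ``x`` is
    ``C0 + CA*eta_A + CB*eta_B + eps_A*eta_A*cos(theta_A - phi_ext)
    + eps_B*eta_B*cos(theta_B - phi_ext)``.
    ``C0, CA, CB`` are untuned components (``C0`` homogeneous, ``CA``/``CB``
    map specific); ``eps_A, eps_B >= 0`` are the tuned amplitudes and
    ``phi_ext`` the encoded target direction. All series share the grid
    defined by ``t0`` and bin width ``dt``; values are piecewise constant
    per bin.
    """

    dt: float
    C0: np.ndarray
    CA: np.ndarray
    CB: np.ndarray
    eps_A: np.ndarray
    eps_B: np.ndarray
    phi_ext: float = 0.0
    t0: float = 0.0

    def __post_init__(self):
        self.dt = float(self.dt)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        series = {}
        n = None
        for name in ("C0", "CA", "CB", "eps_A", "eps_B"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if n is None:
                n = arr.size
            elif arr.size != n:
                raise ValueError("all input series must share one time grid")
            series[name] = arr
        if np.any(series["eps_A"] < 0) or np.any(series["eps_B"] < 0):
            raise ValueError("tuned input amplitudes eps_A, eps_B must be >= 0")
        for name, arr in series.items():
            setattr(self, name, arr)
        self.phi_ext = float(wrap_angle(self.phi_ext))

    @property
    def n_bins(self):
        return self.C0.size

    @property
    def times(self):
        """Left edges of the time bins."""
        return self.t0 + self.dt * np.arange(self.n_bins)

    @property
    def t_end(self):
        return self.t0 + self.dt * self.n_bins

    def bin_index(self, t):
        """Index of the bin containing time ``t`` (nearest-bin lookup)."""
        i = int(np.floor((t - self.t0) / self.dt + 1e-9))
        if i == self.n_bins and (t - self.t_end) < 1e-9 * self.dt:
            i = self.n_bins - 1
        if i < 0 or i >= self.n_bins:
            raise ValueError(
                f"time {t} outside input grid [{self.t0}, {self.t_end}]"
            )
        return i

    def at_time(self, t):
        """``(C0, CA, CB, eps_A, eps_B)`` at time ``t``."""
        i = self.bin_index(t)
        return self.at_bin(i)

    def at_bin(self, i):
        return (
            self.C0[i],
            self.CA[i],
            self.CB[i],
            self.eps_A[i],
            self.eps_B[i],
        )

    @classmethod
    def constant(cls, dt, n_bins, C0=0.0, CA=0.0, CB=0.0, eps_A=0.0,
                 eps_B=0.0, phi_ext=0.0, t0=0.0):
        one = np.ones(n_bins)
        return cls(dt, C0 * one, CA * one, CB * one, eps_A * one,
                   eps_B * one, phi_ext=phi_ext, t0=t0)

    @classmethod
    def zeros(cls, dt, n_bins, phi_ext=0.0, t0=0.0):
        return cls.constant(dt, n_bins, phi_ext=phi_ext, t0=t0)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.times,
                "C0": self.C0,
                "CA": self.CA,
                "CB": self.CB,
                "epsA": self.eps_A,
                "epsB": self.eps_B,
            }
        )

    @classmethod
    def from_frame(cls, df, phi_ext=0.0):
        t = np.asarray(df["t"], dtype=float)
        dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
        return cls(dt, df["C0"], df["CA"], df["CB"], df["epsA"], df["epsB"],
                   phi_ext=phi_ext, t0=float(t[0]))

    def to_dict(self):
        return {
            "dt": self.dt,
            "t0": self.t0,
            "phi_ext": self.phi_ext,
            "C0": self.C0.tolist(),
            "CA": self.CA.tolist(),
            "CB": self.CB.tolist(),
            "eps_A": self.eps_A.tolist(),
            "eps_B": self.eps_B.tolist(),
        }

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


def angular_density(theta_A, theta_B, chi):
    """Joint density of the two preferred directions on the torus.

    ``rho_d(theta_A, theta_B) = (1 + chi * cos(theta_A - theta_B)) / (4 pi^2)``.
    ``chi`` is the correlation parameter; the empirical distribution of the
    recorded population is well described by ``chi = 2/3``.
    """
    chi = float(chi)
    if abs(chi) > 1.0:
        raise ValueError("|chi| must be <= 1 for a nonnegative density")
    theta_A = np.asarray(theta_A, dtype=float)
    theta_B = np.asarray(theta_B, dtype=float)
    return (1.0 + chi * np.cos(theta_A - theta_B)) / (4.0 * np.pi**2)


def coupling_strength(pre: NeuronCoords, post: NeuronCoords,
                      params: CouplingParams):
    """Synaptic gain from a presynaptic to a postsynaptic neuron.

    ``J = j0 + js_A*eta_A*eta_A'*cos(theta_A - theta_A')
    + js_B*eta_B*eta_B'*cos(theta_B - theta_B')
    + j_a*eta_B*eta_A'*cos(theta_B - theta_A')``,
    where primed quantities are presynaptic. The asymmetric ``j_a`` term
    couples the presynaptic preparatory map to the postsynaptic execution
    map, pushing activity from map A towards map B.
    """
    return (
        params.j0
        + params.js_A * post.eta_A * pre.eta_A
        * np.cos(post.theta_A - pre.theta_A)
        + params.js_B * post.eta_B * pre.eta_B
        * np.cos(post.theta_B - pre.theta_B)
        + params.j_a * post.eta_B * pre.eta_A
        * np.cos(post.theta_B - pre.theta_A)
    )


def external_input_value(coords: NeuronCoords, inputs: ExternalInputSeries,
                         t: float):
    """External input to neurons at ``coords`` at time ``t``."""
    C0, CA, CB, eA, eB = inputs.at_time(t)
    return (
        C0
        + CA * coords.eta_A
        + CB * coords.eta_B
        + eA * coords.eta_A * np.cos(coords.theta_A - inputs.phi_ext)
        + eB * coords.eta_B * np.cos(coords.theta_B - inputs.phi_ext)
    )


class ReflectedKDE:
    """Gaussian kernel density on ``[0, 1]`` with boundary reflection.

    Silverman bandwidth on the raw samples; the kernel mass falling outside
    the unit interval is folded back by reflecting at 0 and 1.
    """

    def __init__(self, samples, bandwidth=None):
        self.samples = np.asarray(samples, dtype=float)
        if self.samples.size < 2:
            raise ValueError("need at least two samples")
        n = self.samples.size
        sd = np.std(self.samples, ddof=1)
        iqr = np.subtract(*np.percentile(self.samples, [75, 25]))
        scale = min(sd, iqr / 1.349) if iqr > 0 else sd
        if scale <= 0:
            scale = max(sd, 1e-3)
        self.bandwidth = (
            float(bandwidth) if bandwidth is not None
            else 0.9 * scale * n ** (-1 / 5)
        )

    def pdf(self, x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        h = self.bandwidth
        xs = self.samples[None, :]
        pts = x[:, None]
        k = (
            np.exp(-0.5 * ((pts - xs) / h) ** 2)
            + np.exp(-0.5 * ((pts + xs) / h) ** 2)
            + np.exp(-0.5 * ((pts - (2.0 - xs)) / h) ** 2)
        )
        out = k.sum(axis=1) / (self.samples.size * h * np.sqrt(2 * np.pi))
        out[(x < 0) | (x > 1)] = 0.0
        return out

    def sample(self, n, rng):
        """Draw ``n`` points: resample + Gaussian jitter, reflected into [0,1]."""
        base = rng.choice(self.samples, size=n, replace=True)
        x = base + self.bandwidth * rng.standard_normal(n)
        # fold back into [0, 1] (at most a few reflections for small h)
        x = np.abs(x)
        x = 1.0 - np.abs(1.0 - x)
        x = np.abs(x)
        return np.clip(x, 0.0, 1.0)


class PopulationDensity:
    """Population density over the selectivity coordinates.

    The angular part is ``(1 + chi cos(theta_A - theta_B)) / 4 pi^2`` and the
    participation marginals are represented non-parametrically by finite
    samples. For quadrature the participation measure is reduced to a
    product grid of ``n_eta`` midpoint-quantile atoms per marginal (the
    marginals are independent), and all moments are defined from those
    atoms so that closed-form fixed-point expressions and the numerical
    integrator are mutually consistent.

    Parameters
    ----------
    chi : angular correlation parameter, ``|chi| <= 1``.
    eta_A_samples, eta_B_samples : samples of the participation marginals.
    n_eta : number of quantile atoms per marginal used in quadrature.
    n_theta : number of points of the 1-D angular quadrature grid (the
        second angular integral is carried out in closed form).
    """

    def __init__(self, chi, eta_A_samples, eta_B_samples, n_eta=10,
                 n_theta=96):
        chi = float(chi)
        if abs(chi) > 1.0:
            raise ValueError("|chi| must be <= 1")
        self.chi = chi
        self.eta_A_samples = np.clip(
            np.atleast_1d(np.asarray(eta_A_samples, dtype=float)), 0.0, 1.0)
        self.eta_B_samples = np.clip(
            np.atleast_1d(np.asarray(eta_B_samples, dtype=float)), 0.0, 1.0)
        self.n_eta = int(n_eta)
        self.n_theta = int(n_theta)
        qa = self._quantile_atoms(self.eta_A_samples, self.n_eta)
        qb = self._quantile_atoms(self.eta_B_samples, self.n_eta)
        # product measure: all (a, b) pairs with equal weights
        A, B = np.meshgrid(qa, qb, indexing="ij")
        self.eta_A_atoms = qa
        self.eta_B_atoms = qb
        self.eta_A_grid = A.ravel()
        self.eta_B_grid = B.ravel()
        self.w_eta = 1.0 / self.eta_A_grid.size
        self.u_grid = TWO_PI * np.arange(self.n_theta) / self.n_theta
        # cached trig of the angular quadrature grid (hot path)
        self.cos_u = np.cos(self.u_grid)
        self.sin_u = np.sin(self.u_grid)

    @classmethod
    def from_paired_atoms(cls, chi, eta_A_pairs, eta_B_pairs, n_theta=96):
        """Density whose participation measure is a fixed set of paired
        ``(eta_A, eta_B)`` atoms with equal weights.

        This is the mean-field counterpart of a concrete network
        realization, whose blocks share exactly these participation
        pairs (no independence assumption across the pairs).
        """
        eta_A_pairs = np.atleast_1d(np.asarray(eta_A_pairs, dtype=float))
        eta_B_pairs = np.atleast_1d(np.asarray(eta_B_pairs, dtype=float))
        if eta_A_pairs.shape != eta_B_pairs.shape:
            raise ValueError("paired atoms must have equal length")
        obj = cls(chi, eta_A_pairs, eta_B_pairs, n_eta=eta_A_pairs.size,
                  n_theta=n_theta)
        obj.eta_A_atoms = eta_A_pairs
        obj.eta_B_atoms = eta_B_pairs
        obj.eta_A_grid = eta_A_pairs
        obj.eta_B_grid = eta_B_pairs
        obj.w_eta = 1.0 / eta_A_pairs.size
        return obj

    @staticmethod
    def _quantile_atoms(samples, n):
        if samples.size == 1 or np.ptp(samples) == 0:
            return np.full(n, samples.flat[0])
        q = (np.arange(n) + 0.5) / n
        return np.quantile(samples, q)

    # -- moments (defined from the quadrature atoms) --------------------
    @property
    def mean_eta_A(self):
        return float(self.eta_A_atoms.mean())

    @property
    def mean_eta_B(self):
        return float(self.eta_B_atoms.mean())

    @property
    def msq_eta_A(self):
        return float(np.mean(self.eta_A_atoms**2))

    @property
    def msq_eta_B(self):
        return float(np.mean(self.eta_B_atoms**2))

    @property
    def F_AA(self):
        """Fourier-mode self-coupling coefficient of map A: ``<eta_A^2>/2``."""
        return 0.5 * self.msq_eta_A

    @property
    def F_BB(self):
        return 0.5 * self.msq_eta_B

    @property
    def F_AB(self):
        """Cross-map coefficient ``(chi/4) <eta_A> <eta_B>``."""
        return 0.25 * self.chi * self.mean_eta_A * self.mean_eta_B

    # -- densities -------------------------------------------------------
    def angular_density(self, theta_A, theta_B):
        return angular_density(theta_A, theta_B, self.chi)

    def kde_A(self, bandwidth=None):
        return ReflectedKDE(self.eta_A_samples, bandwidth)

    def kde_B(self, bandwidth=None):
        return ReflectedKDE(self.eta_B_samples, bandwidth)

    @classmethod
    def uniform_participation(cls, chi, n_eta=1, n_theta=128):
        """Density with ``eta_A = eta_B = 1`` (classic double-ring limit)."""
        return cls(chi, np.ones(2), np.ones(2), n_eta=max(1, n_eta),
                   n_theta=n_theta)

    def __repr__(self):
        return (
            f"PopulationDensity(chi={self.chi:.4g}, "
            f"n_eta={self.n_eta}, n_theta={self.n_theta}, "
            f"<etaA>={self.mean_eta_A:.3f}, <etaB>={self.mean_eta_B:.3f})"
        )


# -- parameter serialization ---------------------------------------------

def params_to_yaml(path, **named_params):
    """Write named parameter objects (with ``to_dict``) to a YAML file."""
    payload = {k: v.to_dict() for k, v in named_params.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh)


def params_from_yaml(path, **named_types):
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return {k: named_types[k].from_dict(payload[k]) for k in named_types}


def params_to_json(path, **named_params):
    payload = {k: v.to_dict() for k, v in named_params.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
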
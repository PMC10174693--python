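"""Data-side preprocessing and directional-tuning characterization.

Covers the path from event-marked trials to the model's coordinate
system: Gaussian-kernel rate estimation, piecewise-linear time
normalization of the three task intervals, epoch extraction, cosine
tuning fits (offset, modulation amplitude, preferred direction), the
participation measure (amplitude normalized by the population maximum),
circular statistics, and the bootstrap test for preferred-direction
variability across time bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import wrap_angle
from .simulate import RateTensor

__all__ = [
    "TrialSet",
    "TuningFit",
    "CircularStats",
    "PDVariabilityResult",
    "smooth_and_average",
    "extract_epochs",
    "Epochs",
    "fit_cosine",
    "participation_from_amplitudes",
    "circular_stats",
    "circular_correlation",
    "pd_variability_bootstrap",
]

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ("trial_id", "condition", "t_target", "t_go", "t_move_on",
                 "t_move_off")


@dataclass
class TrialSet:
    """Trial-resolved recordings with task-event markers.

    events : DataFrame with columns ``trial_id, condition, t_target, t_go,
        t_move_on, t_move_off`` (seconds; condition in 1..n_conditions).
    spikes : DataFrame with columns ``trial_id, unit_id, spike_time`` or
        ``None`` when rate traces are provided instead.
    rates : optional dict ``trial_id -> (t, rates[n_units, n_t])``.
    n_units : number of units (unit ids are 0..n_units-1).
    """

    events: pd.DataFrame
    n_units: int
    spikes: pd.DataFrame = None
    rates: dict = None
    n_conditions: int = 8

    def __post_init__(self):
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise ValueError(f"events table is missing columns {missing}")
        if self.spikes is None and self.rates is None:
            raise ValueError("provide spikes or rate traces")

    @property
    def condition_angles(self):
        return 2.0 * np.pi * np.arange(self.n_conditions) / self.n_conditions

    def valid_trials(self):
        """Trials with complete, strictly ordered event markers."""
        ev = self.events
        ok = np.isfinite(ev[list(EVENT_COLUMNS[2:])]).all(axis=1)
        ordered = (
            (ev["t_target"] < ev["t_go"])
            & (ev["t_go"] < ev["t_move_on"])
            & (ev["t_move_on"] < ev["t_move_off"])
        )
        dropped = ev.loc[~(ok & ordered), "trial_id"].tolist()
        if dropped:
            logger.info("dropping %d trial(s) with bad markers: %s",
                        len(dropped), dropped[:10])
        return ev.loc[ok & ordered]

    def to_csv(self, events_path, spikes_path=None):
        self.events.to_csv(events_path, index=False)
        if spikes_path is not None and self.spikes is not None:
            self.spikes.to_csv(spikes_path, index=False)

    @classmethod
    def from_csv(cls, events_path, spikes_path, n_units=None,
                 n_conditions=8):
        events = pd.read_csv(events_path)
        spikes = pd.read_csv(spikes_path)
        if n_units is None:
            n_units = int(spikes["unit_id"].max()) + 1
        return cls(events, n_units, spikes=spikes,
                   n_conditions=n_conditions)


def _gaussian_smooth(x, sd_bins, axis=-1):
    """Gaussian smoothing truncated at 4 sd with boundary mass
    renormalization (edges divided by the local kernel mass)."""
    from scipy.ndimage import gaussian_filter1d

    num = gaussian_filter1d(x, sd_bins, axis=axis, mode="constant",
                            truncate=4.0)
    norm = gaussian_filter1d(np.ones(x.shape[axis]), sd_bins,
                             mode="constant", truncate=4.0)
    shape = [1] * x.ndim
    shape[axis] = -1
    return num / norm.reshape(shape)


def smooth_and_average(trials: TrialSet, kernel_sd=0.025, dt=0.005):
    """Trial-averaged, time-normalized rate tensor.

    Each trial's activity between target onset and movement end is
    estimated by Gaussian smoothing of spike counts (sd ``kernel_sd``),
    the three intervals (target->go, go->move, move onset->offset) are
    linearly rescaled to their across-trial average durations, and trials
    are averaged per condition. Returns ``(RateTensor, events)`` where
    ``events`` maps the markers onto the normalized timeline.
    """
    ev = trials.valid_trials()
    if len(ev) == 0:
        raise ValueError("no valid trials")
    d1 = float((ev["t_go"] - ev["t_target"]).mean())
    d2 = float((ev["t_move_on"] - ev["t_go"]).mean())
    d3 = float((ev["t_move_off"] - ev["t_move_on"]).mean())
    t_out = np.arange(0.0, d1 + d2 + d3 + 0.5 * dt, dt)
    edges_out = np.array([0.0, d1, d1 + d2, d1 + d2 + d3])

    n_units = trials.n_units
    C = trials.n_conditions
    sums = np.zeros((n_units, t_out.size, C))
    counts = np.zeros(C)

    spikes_by_trial = None
    if trials.spikes is not None:
        spikes_by_trial = dict(tuple(trials.spikes.groupby("trial_id")))

    for row in ev.itertuples(index=False):
        edges_in = np.array([row.t_target, row.t_go, row.t_move_on,
                             row.t_move_off])
        # piecewise-linear map from normalized time to trial time
        t_trial = np.interp(t_out, edges_out, edges_in)
        if trials.rates is not None and row.trial_id in trials.rates:
            tt, rr = trials.rates[row.trial_id]
            rate = np.stack(
                [np.interp(t_trial, tt, rr[i]) for i in range(n_units)])
        else:
            sp = spikes_by_trial.get(row.trial_id)
            grid = np.arange(row.t_target, row.t_move_off + dt, dt)
            rate_fine = np.zeros((n_units, grid.size - 1))
            if sp is not None and len(sp):
                u = sp["unit_id"].to_numpy()
                st = sp["spike_time"].to_numpy()
                keep = (st >= grid[0]) & (st < grid[-1])
                idx = np.floor((st[keep] - grid[0]) / dt).astype(int)
                np.add.at(rate_fine, (u[keep], idx), 1.0 / dt)
            rate_fine = _gaussian_smooth(rate_fine, kernel_sd / dt)
            centers = 0.5 * (grid[:-1] + grid[1:])
            rate = np.stack(
                [np.interp(t_trial, centers, rate_fine[i])
                 for i in range(n_units)])
        k = int(row.condition) - 1
        sums[:, :, k] += rate
        counts[k] += 1
    if np.any(counts == 0):
        raise ValueError("at least one trial per condition is required")
    rates = sums / counts[None, None, :]
    tensor = RateTensor(rates, t_out, trials.condition_angles)
    events = {"t_target": 0.0, "t_go": d1, "t_move_on": d1 + d2,
              "t_move_off": d1 + d2 + d3}
    return tensor, events


@dataclass
class Epochs:
    """Index windows of the preparatory and execution epochs."""

    prep: slice
    move: slice
    prep_window: tuple
    move_window: tuple
    prep_mean: np.ndarray    # (N, C) epoch- and time-averaged rates
    move_mean: np.ndarray


def extract_epochs(rates: RateTensor, events, prep_offset=0.1,
                   prep_length=0.3, move_offset=-0.05,
                   move_length=0.3) -> Epochs:
    """Extract the preparatory and movement-related epoch windows.

    Defaults: a 300 ms window beginning 100 ms after target onset, and a
    300 ms window beginning 50 ms before movement onset. Lengths and
    offsets are configurable; a window exceeding the recording span is an
    error.
    """
    t = rates.t
    windows = []
    for t0, length in (
        (events["t_target"] + prep_offset, prep_length),
        (events["t_move_on"] + move_offset, move_length),
    ):
        t1 = t0 + length
        if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
            raise ValueError(
                f"epoch window [{t0:.3f}, {t1:.3f}] exceeds the data span "
                f"[{t[0]:.3f}, {t[-1]:.3f}]")
        i0 = int(np.searchsorted(t, t0 - 1e-9))
        i1 = int(np.searchsorted(t, t1 - 1e-9))   # half-open [t0, t1)
        windows.append((slice(i0, i1), (t0, t1)))
    (prep_sl, prep_w), (move_sl, move_w) = windows
    return Epochs(prep_sl, move_sl, prep_w, move_w,
                  rates.rates[:, prep_sl, :].mean(axis=1),
                  rates.rates[:, move_sl, :].mean(axis=1))


@dataclass
class TuningFit:
    """Cosine tuning fit ``a + b cos(theta_pref - Phi)`` per unit.

    ``b >= 0`` (the sign is absorbed into the preferred direction);
    ``theta_pref`` and ``r_squared`` are NaN for untuned (b = 0) or
    all-constant responses. ``eta`` is filled by
    :func:`participation_from_amplitudes`.
    """

    a: np.ndarray
    b: np.ndarray
    theta_pref: np.ndarray
    r_squared: np.ndarray
    eta: np.ndarray = None

    def to_frame(self, unit_ids=None, epoch=None):
        n = np.atleast_1d(self.a).size
        df = pd.DataFrame({
            "unit_id": unit_ids if unit_ids is not None else np.arange(n),
            "a": np.atleast_1d(self.a),
            "b": np.atleast_1d(self.b),
            "theta_pref": np.atleast_1d(self.theta_pref),
            "r2": np.atleast_1d(self.r_squared),
        })
        if self.eta is not None:
            df["eta"] = np.atleast_1d(self.eta)
        if epoch is not None:
            df.insert(1, "epoch", epoch)
        return df


def fit_cosine(mean_rates, condition_angles) -> TuningFit:
    """Least-squares cosine fit of condition-averaged rates.

    ``mean_rates`` is ``(..., C)``; the fit uses the basis
    ``{1, cos Phi, sin Phi}`` (exact on equispaced target angles);
    ``theta_pref = atan2(sin coef, cos coef)``.
    """
    ang = np.asarray(condition_angles, dtype=float)
    y = np.asarray(mean_rates, dtype=float)
    X = np.column_stack([np.ones_like(ang), np.cos(ang), np.sin(ang)])
    coef, *_ = np.linalg.lstsq(X, y.reshape(-1, ang.size).T, rcond=None)
    a, bc, bs = coef
    b = np.hypot(bc, bs)
    theta = wrap_angle(np.arctan2(bs, bc))
    fitted = (X @ coef).T
    resid = y.reshape(-1, ang.size) - fitted
    ss_res = (resid**2).sum(axis=1)
    ss_tot = ((y.reshape(-1, ang.size)
               - y.reshape(-1, ang.size).mean(axis=1, keepdims=True))**2
              ).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    flat = ss_tot <= 1e-300
    r2[flat] = np.nan
    untuned = b <= 1e-12
    theta = np.where(untuned, np.nan, theta)
    shape = y.shape[:-1]
    return TuningFit(a.reshape(shape), b.reshape(shape),
                     theta.reshape(shape), r2.reshape(shape))


def participation_from_amplitudes(b, robust=False):
    """Degree of participation: tuning amplitude normalized by the
    population maximum (or the 99th percentile when ``robust``)."""
    b = np.asarray(b, dtype=float)
    denom = np.nanpercentile(b, 99) if robust else np.nanmax(b)
    if denom <= 0:
        return np.zeros_like(b)
    return np.clip(b / denom, 0.0, 1.0)


@dataclass
class CircularStats:
    mean_direction: float
    resultant_length: float
    circular_variance: float

    def __iter__(self):
        yield self.mean_direction
        yield self.resultant_length
        yield self.circular_variance


def circular_stats(angles) -> CircularStats:
    """Mean direction, resultant length R and circular variance S = 1 - R."""
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if angles.size < 1:
        raise ValueError("need at least one angle")
    z = np.exp(1j * angles).mean()
    R = float(np.abs(z))
    return CircularStats(float(wrap_angle(np.angle(z))), R, 1.0 - R)


def circular_correlation(angles_1, angles_2, center_floor=0.1):
    """Circular correlation coefficient of two paired angle sets.

    ``rho = sum sin(a - abar) sin(b - bbar) /
    sqrt(sum sin^2(a - abar) sum sin^2(b - bbar))`` with ``abar, bbar``
    the marginal mean directions. When either marginal resultant is below
    ``center_floor`` the marginal mean direction is statistically
    undefined (near-uniform marginals); the centers are then estimated
    jointly from the concentrated mean offset
    ``argmax E[cos(a - b - d)]``, which leaves the coefficient's
    population value unchanged for correlated-torus densities. Returns
    NaN when a denominator vanishes.
    """
    a = np.atleast_1d(np.asarray(angles_1, dtype=float))
    b = np.atleast_1d(np.asarray(angles_2, dtype=float))
    if a.size != b.size or a.size < 2:
        raise ValueError("need two equally long angle sets (n >= 2)")
    za = np.exp(1j * a).mean()
    zb = np.exp(1j * b).mean()
    if min(abs(za), abs(zb)) >= center_floor:
        abar, bbar = np.angle(za), np.angle(zb)
    else:
        # joint centering via the mean offset of the pairs
        d0 = np.angle(np.exp(1j * (a - b)).mean())
        abar, bbar = 0.0, -d0
    sa = np.sin(a - abar)
    sb = np.sin(b - bbar)
    den = np.sqrt((sa**2).sum() * (sb**2).sum())
    if den <= 1e-300:
        return np.nan
    return float((sa * sb).sum() / den)


@dataclass
class PDVariabilityResult:
    """Outcome of the preferred-direction variability bootstrap."""

    epoch_windows: dict
    per_neuron_variance: dict       # epoch -> (n_units,)
    observed_median: dict           # epoch -> float
    null_medians: dict              # epoch -> (B,)

    def percentile_of_observed(self, epoch):
        null = self.null_medians[epoch]
        return float(np.mean(null < self.observed_median[epoch]) * 100.0)


def _binned_counts(trials: TrialSet, window, n_bins, bin_width):
    """Spike counts ``(n_units, n_bins, C, n_trials_per_cond)``; uses the
    per-trial event-aligned window ``window = (event, offset)``."""
    ev = trials.valid_trials()
    C = trials.n_conditions
    per_cond = [ev[ev["condition"] == k + 1] for k in range(C)]
    n_min = min(len(p) for p in per_cond)
    if n_min < 2:
        raise ValueError("need at least two trials per condition")
    out = np.zeros((trials.n_units, n_bins, C, n_min))
    spikes_by_trial = dict(tuple(trials.spikes.groupby("trial_id"))) \
        if trials.spikes is not None else {}
    event, offset = window
    for k, sub in enumerate(per_cond):
        for j, row in enumerate(sub.iloc[:n_min].itertuples(index=False)):
            t0 = getattr(row, event) + offset
            edges = t0 + bin_width * np.arange(n_bins + 1)
            if trials.rates is not None and row.trial_id in trials.rates:
                tt, rr = trials.rates[row.trial_id]
                for wbin in range(n_bins):
                    sel = (tt >= edges[wbin]) & (tt < edges[wbin + 1])
                    if sel.any():
                        out[:, wbin, k, j] = rr[:, sel].mean(axis=1) \
                            * bin_width
            else:
                sp = spikes_by_trial.get(row.trial_id)
                if sp is None or not len(sp):
                    continue
                u = sp["unit_id"].to_numpy()
                st = sp["spike_time"].to_numpy()
                keep = (st >= edges[0]) & (st < edges[-1])
                idx = np.floor((st[keep] - edges[0]) / bin_width).astype(int)
                np.add.at(out[:, :, k, j], (u[keep], idx), 1.0)
    return out


def _pd_per_bin(counts_cond_mean, angles):
    """Preferred direction per (unit, bin) from condition means via the
    first circular harmonic (exact cosine fit on equispaced angles)."""
    z = np.tensordot(counts_cond_mean, np.exp(1j * angles), axes=([-1], [0]))
    return np.angle(z)


def pd_variability_bootstrap(trials: TrialSet, bin_width=0.16, B=1000,
                             seed=0, epochs=None,
                             chunk=200) -> PDVariabilityResult:
    """Bootstrap test of preferred-direction variability across time bins.

    For each epoch the single-trial activity is binned (160 ms bins; three
    bins per task epoch, seven for the whole task), z-scored per neuron
    and bin across conditions and trials (so bins become exchangeable
    while tuning is preserved), and the circular variance of the per-bin
    preferred directions is computed per neuron. The null resamples the
    ``NW x n`` entries of each neuron-condition matrix with replacement
    ``B`` times and recomputes the median variance, testing whether
    preferred directions vary across bins more than chance.
    """
    if epochs is None:
        epochs = {
            "prep": (("t_target", 0.0), 3),
            "move": (("t_move_on", -0.05), 3),
            "whole": (("t_target", 0.0), 7),
        }
    rng = np.random.default_rng(seed)
    angles = trials.condition_angles
    per_neuron = {}
    observed = {}
    nulls = {}
    windows = {}
    for name, (window, n_bins) in epochs.items():
        counts = _binned_counts(trials, window, n_bins, bin_width)
        n_units, NW, C, n = counts.shape
        windows[name] = {"window": window, "n_bins": n_bins,
                         "bin_width": bin_width}
        # z-score per neuron and bin across conditions x trials
        flat = counts.reshape(n_units, NW, C * n)
        mu = flat.mean(axis=2, keepdims=True)
        sd = flat.std(axis=2, keepdims=True)
        sd[sd == 0] = 1.0
        z = ((flat - mu) / sd).reshape(n_units, NW, C, n)

        pd_bins = _pd_per_bin(z.mean(axis=3), angles)   # (n_units, NW)
        Rv = np.abs(np.exp(1j * pd_bins).mean(axis=1))
        var_obs = 1.0 - Rv
        per_neuron[name] = var_obs
        observed[name] = float(np.median(var_obs))

        null = np.empty(B)
        done = 0
        while done < B:
            nb = min(chunk, B - done)
            # resample NW x n entries per neuron-condition matrix
            idx = rng.integers(0, NW * n, size=(nb, n_units, C, NW, n))
            src = z.transpose(0, 2, 1, 3).reshape(n_units, C, NW * n)
            samp = np.take_along_axis(
                src[None, :, :, :].repeat(nb, axis=0).reshape(
                    nb, n_units, C, NW * n),
                idx.reshape(nb, n_units, C, NW * n), axis=3
            ).reshape(nb, n_units, C, NW, n)
            means = samp.mean(axis=4)                  # (nb, units, C, NW)
            zc = np.tensordot(means, np.exp(1j * angles),
                              axes=([2], [0]))         # (nb, units, NW)
            pdb = np.angle(zc)
            Rb = np.abs(np.exp(1j * pdb).mean(axis=2))
            null[done:done + nb] = np.median(1.0 - Rb, axis=1)
            done += nb
        nulls[name] = null
    return PDVariabilityResult(windows, per_neuron, observed, nulls)
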
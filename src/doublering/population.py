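"""Population-geometry analyses of epoch activity.

Builds the standardized preparatory (P) and movement (M) activity
matrices, and provides the subspace comparisons used to quantify the
orthogonality of preparation and execution: per-epoch PCA variance
profiles, the alignment index with its covariance-weighted Monte-Carlo
null, canonical correlation analysis between two populations, the jPCA
rotational fit, and the cross-validated linear (LASSO) EMG readout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .simulate import RateTensor

__all__ = [
    "EpochMatrices",
    "SubspaceReport",
    "build_epoch_matrices",
    "alignment_index",
    "random_alignment_null",
    "pca_variance_fractions",
    "components_for_variance",
    "cca_compare",
    "canonical_correlations",
    "jpca_fit",
    "emg_readout",
    "subspace_report",
]

logger = logging.getLogger(__name__)


@dataclass
class EpochMatrices:
    """Standardized epoch activity: ``P`` and ``M`` are ``N x (T*C)``.

    Per neuron the activity was divided by its standard deviation over
    all times and conditions, then mean-centered across conditions at
    each time; both epochs share the neuron set and preprocessing.
    """

    P: np.ndarray
    M: np.ndarray
    kept_units: np.ndarray
    sd: np.ndarray


def build_epoch_matrices(rates: RateTensor, epochs) -> EpochMatrices:
    """Build P and M from a rate tensor and extracted epoch windows.

    ``epochs`` is a :class:`doublering.tuning.Epochs` (or any object with
    ``prep`` / ``move`` slices). Zero-variance neurons are dropped with a
    log entry.
    """
    r = rates.rates
    sd = r.std(axis=(1, 2))
    keep = sd > 1e-12 * max(float(sd.max()), 1e-300)
    if not keep.all():
        logger.info("dropping %d zero-variance unit(s)",
                    int((~keep).sum()))
    r = r[keep] / sd[keep, None, None]
    r = r - r.mean(axis=2, keepdims=True)      # center across conditions
    N = r.shape[0]
    P = r[:, epochs.prep, :].reshape(N, -1)
    M = r[:, epochs.move, :].reshape(N, -1)
    return EpochMatrices(P, M, np.flatnonzero(keep), sd[keep])


def _cov(X):
    return np.cov(X, bias=False)


def pca_variance_fractions(X, n_components=None):
    """Eigenvalues of the row-covariance of ``X`` as variance fractions."""
    ev = np.linalg.eigvalsh(_cov(X))[::-1]
    ev = np.clip(ev, 0.0, None)
    frac = ev / ev.sum() if ev.sum() > 0 else ev
    return frac[:n_components] if n_components else frac


def components_for_variance(X, threshold=0.9):
    """Number of principal components needed to reach ``threshold`` of
    the variance of ``X``."""
    frac = pca_variance_fractions(X)
    return int(np.searchsorted(np.cumsum(frac), threshold) + 1)


def alignment_index(P, M, K):
    """Fraction of preparatory variance captured by the top-K movement PCs.

    ``A = Tr(Emov^T Cprep Emov) / sum_{i<=K} sigma_prep(i)`` where
    ``Emov`` holds the top-K eigenvectors of the movement covariance and
    ``sigma_prep`` the sorted eigenvalues of the preparatory covariance.
    Ranges from 0 (orthogonal subspaces) to 1 (aligned).
    """
    Cp = _cov(P)
    Cm = _cov(M)
    K = int(K)
    rank_p = np.linalg.matrix_rank(Cp)
    rank_m = np.linalg.matrix_rank(Cm)
    if K > min(rank_p, rank_m):
        raise ValueError(f"K={K} exceeds covariance rank "
                         f"(prep {rank_p}, move {rank_m})")
    wm, vm = np.linalg.eigh(Cm)
    E = vm[:, np.argsort(wm)[::-1][:K]]
    wp = np.sort(np.linalg.eigvalsh(Cp))[::-1]
    return float(np.trace(E.T @ Cp @ E) / wp[:K].sum())


def random_alignment_null(P, M, K, n_draws=1000, seed=0, weight_cov=None):
    """Monte-Carlo null of the alignment index.

    Random K-frames are drawn within the space occupied by the combined
    activity: each frame is the orthonormalization of ``C^{1/2} W`` with
    ``W`` standard Gaussian and ``C`` the covariance of the concatenated
    ``[P M]`` activity (or ``weight_cov``), so directions are sampled
    with probability weighted by the data's covariance spectrum. For each
    draw the alignment of the random frame with the preparatory activity
    is computed.
    """
    rng = np.random.default_rng(seed)
    C = _cov(np.concatenate([P, M], axis=1)) if weight_cov is None \
        else np.asarray(weight_cov, dtype=float)
    w, v = np.linalg.eigh(C)
    w = np.clip(w, 0.0, None)
    Chalf = v * np.sqrt(w)[None, :]
    Cp = _cov(P)
    wp = np.sort(np.linalg.eigvalsh(Cp))[::-1]
    denom = wp[:K].sum()
    N = P.shape[0]
    out = np.empty(n_draws)
    for i in range(n_draws):
        W = rng.standard_normal((N, K))
        Q, _ = np.linalg.qr(Chalf @ W)
        out[i] = np.trace(Q.T @ Cp @ Q) / denom
    return out


@dataclass
class SubspaceReport:
    """Per-epoch PCA spectra and subspace-alignment summary."""

    prep_variance_fractions: np.ndarray
    move_variance_fractions: np.ndarray
    K: int
    alignment: float
    null_samples: np.ndarray

    @property
    def null_mean(self):
        return float(self.null_samples.mean())

    def null_percentile(self, q):
        return float(np.percentile(self.null_samples, q))

    def to_dict(self):
        return {
            "K": self.K,
            "alignment_index": self.alignment,
            "null_mean": self.null_mean,
            "null_p5": self.null_percentile(5),
            "prep_variance_fractions":
                self.prep_variance_fractions.tolist(),
            "move_variance_fractions":
                self.move_variance_fractions.tolist(),
        }


def subspace_report(em: EpochMatrices, K=None, variance_threshold=0.9,
                    n_draws=1000, seed=0) -> SubspaceReport:
    """Full subspace-orthogonality summary for one session.

    ``K`` defaults to the number of PCs explaining ``variance_threshold``
    of the movement-epoch activity variance.
    """
    if K is None:
        K = components_for_variance(em.M, variance_threshold)
    return SubspaceReport(
        pca_variance_fractions(em.P), pca_variance_fractions(em.M),
        int(K), alignment_index(em.P, em.M, K),
        random_alignment_null(em.P, em.M, K, n_draws=n_draws, seed=seed))


def canonical_correlations(X, Y, reg=1e-10):
    """Canonical correlation spectrum of two matched sample matrices
    (rows: variables, columns: shared samples), via whitened SVD."""
    X = X - X.mean(axis=1, keepdims=True)
    Y = Y - Y.mean(axis=1, keepdims=True)
    n = X.shape[1]
    Cxx = X @ X.T / (n - 1) + reg * np.eye(X.shape[0])
    Cyy = Y @ Y.T / (n - 1) + reg * np.eye(Y.shape[0])
    Cxy = X @ Y.T / (n - 1)
    wx, vx = np.linalg.eigh(Cxx)
    wy, vy = np.linalg.eigh(Cyy)
    ix = wx > max(wx.max(), 1.0) * 1e-12
    iy = wy > max(wy.max(), 1.0) * 1e-12
    Wx = vx[:, ix] / np.sqrt(wx[ix])[None, :]
    Wy = vy[:, iy] / np.sqrt(wy[iy])[None, :]
    s = np.linalg.svd(Wx.T @ Cxy @ Wy, compute_uv=False)
    return np.clip(s, 0.0, 1.0)


def cca_compare(epoch_matrix_1, epoch_matrix_2, variance_threshold=0.9):
    """Canonical correlations between two populations' epoch activity.

    Each ``N_i x (T*C)`` matrix is first reduced to its own number of PCs
    reaching ``variance_threshold`` of variance, then CCA is applied to
    the two reduced representations (shared time-condition samples).
    """
    out = []
    for X in (epoch_matrix_1, epoch_matrix_2):
        X = X - X.mean(axis=1, keepdims=True)
        K = components_for_variance(X, variance_threshold)
        w, v = np.linalg.eigh(_cov(X))
        order = np.argsort(w)[::-1][:K]
        if w[order[-1]] <= 0:
            raise ValueError("degenerate reduced rank in CCA input")
        out.append(v[:, order].T @ X)
    return canonical_correlations(out[0], out[1])


def jpca_fit(X, dt=1.0, cond_slices=None):
    """Least-squares skew-symmetric generator of the activity flow.

    Fits ``dX/dt = R X`` with ``R = -R^T`` (solved in the antisymmetric
    basis); derivatives are centered differences within each condition
    segment. Returns ``(R, eigenvalues, plane)`` where ``plane`` is the
    pair of orthonormal real vectors spanning the strongest rotational
    plane (top conjugate eigenvalue pair).
    """
    X = np.asarray(X, dtype=float)
    n, T = X.shape
    if cond_slices is None:
        cond_slices = [slice(0, T)]
    Xs, dXs = [], []
    for sl in cond_slices:
        seg = X[:, sl]
        if seg.shape[1] < 3:
            raise ValueError("need at least three time points per segment")
        dXs.append((seg[:, 2:] - seg[:, :-2]) / (2.0 * dt))
        Xs.append(seg[:, 1:-1])
    Xm = np.concatenate(Xs, axis=1)
    dXm = np.concatenate(dXs, axis=1)
    # antisymmetric basis: R = sum_k c_k (e_i e_j^T - e_j e_i^T), i<j
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    nb = len(pairs)
    A = np.empty((dXm.size, nb))
    for k, (i, j) in enumerate(pairs):
        Bk = np.zeros((n, n))
        Bk[i, j] = 1.0
        Bk[j, i] = -1.0
        A[:, k] = (Bk @ Xm).ravel()
    c, *_ = np.linalg.lstsq(A, dXm.ravel(), rcond=None)
    R = np.zeros((n, n))
    for k, (i, j) in enumerate(pairs):
        R[i, j] = c[k]
        R[j, i] = -c[k]
    ev, evec = np.linalg.eig(R)
    order = np.argsort(-np.abs(ev.imag))
    v = evec[:, order[0]]
    plane = np.column_stack([v.real, v.imag])
    q, _ = np.linalg.qr(plane)
    return R, ev[order], q


def emg_readout(rates, emg, n_folds=10, seed=0, alpha=1e-4, n_repeats=1,
                max_units=1000):
    """Cross-validated LASSO reconstruction of EMG from unit rates.

    ``rates`` is ``(n_units, T*C)`` and ``emg`` ``(m_muscles, T*C)`` on a
    matched time base. Time points are randomly partitioned into
    ``n_folds`` folds of non-consecutive samples; per muscle a LASSO
    regression with intercept is trained on the remaining folds and the
    normalized mean squared error (residual variance over signal
    variance) is pooled over the held-out folds and averaged over
    repeats. If more than ``max_units`` predictors are supplied a random
    subset is used. Returns ``(weights, nmse_per_muscle)``.
    """
    from sklearn.linear_model import Lasso

    rates = np.asarray(rates, dtype=float)
    emg = np.atleast_2d(np.asarray(emg, dtype=float))
    if rates.shape[1] != emg.shape[1]:
        raise ValueError("rates and EMG must share the time base")
    rng = np.random.default_rng(seed)
    if rates.shape[0] > max_units:
        sel = rng.choice(rates.shape[0], size=max_units, replace=False)
        rates = rates[sel]
    else:
        sel = np.arange(rates.shape[0])
    Tn = rates.shape[1]
    m = emg.shape[0]
    nmse = np.zeros(m)
    weights = np.zeros((m, rates.shape[0] + 1))
    Xt = rates.T
    for rep in range(n_repeats):
        perm = rng.permutation(Tn)
        folds = np.array_split(perm, n_folds)
        pred = np.empty_like(emg)
        for f in folds:
            train = np.setdiff1d(perm, f)
            model = Lasso(alpha=alpha, fit_intercept=True, max_iter=5000)
            model.fit(Xt[train], emg[:, train].T)
            coef = model.coef_ if emg.shape[0] > 1 else model.coef_[None, :]
            icept = np.atleast_1d(model.intercept_)
            pred[:, f] = coef @ Xt[f].T + icept[:, None]
            weights[:, :-1] += coef / (n_folds * n_repeats)
            weights[:, -1] += icept / (n_folds * n_repeats)
        resid = emg - pred
        var = emg.var(axis=1)
        var[var == 0] = 1.0
        nmse += (resid**2).mean(axis=1) / var / n_repeats
    return {"weights": weights, "unit_index": sel}, nmse
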
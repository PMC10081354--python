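"""Geodesic (Frechet) mean estimators on the SPD manifold.

Three estimators are provided, all returning the matrix minimizing the sum of
squared affine-invariant geodesic distances to a collection:

:class:`MSPDNN`
    A tied-weight bilinear network. The collection is pushed through the
    congruence ``Gamma -> V Gamma V`` with ``V = W~ W~^T`` (``W~ = W + lam*I``)
    and the training loss is the squared Frobenius norm of the averaged matrix
    logarithm of the transformed inputs, normalized by ``P^2``. The loss is
    zero exactly when ``V`` solves the matrix-normal first-order condition
    ``sum_n logm(G^{-1/2} Gamma_n G^{-1/2}) = 0``, i.e. when ``V = G^{-1/2}``
    for the geodesic mean ``G``; the mean is recovered as ``G = V^{-2}``.
    Training is Adam on the analytic gradient of the loss.

:class:`FrechetMeanGD`
    Classical Riemannian gradient descent (for step size 1 the standard
    fixed-point iteration): ``G <- G^{1/2} expm(step * R) G^{1/2}`` with
    ``R`` the tangent-space mean of the data at ``G``.

:class:`ALEMean`
    Approximate-Joint-Diagonalization Log-Euclidean mean: diagonalize the
    whole collection approximately in one basis (Pham's algorithm), average
    the logs of the diagonal parts, and map back. Exact whenever the data
    follow a common-principal-components (CPC) process.

All estimators follow scikit-learn conventions (``fit``, trailing-underscore
fitted attributes, ``get_params``/``set_params``) and accept either an
``(N, P, P)`` array or a :class:`~spdmean.collection.ConnectomeCollection`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .collection import ConnectomeCollection, as_spd_stack
from .geometry import (
    matrix_expm,
    matrix_logm,
    spd_inv_sqrt,
    spd_sqrt,
    sym,
)

__all__ = [
    "MeanEstimate",
    "MSPDNN",
    "FrechetMeanGD",
    "ALEMean",
    "ajd_pham",
    "condition_fit",
    "mspdnn_transform",
    "mspdnn_loss",
    "mspdnn_fit",
    "gradient_descent_mean",
    "ale_mean",
]


# --------------------------------------------------------------------------
# shared helpers
# --------------------------------------------------------------------------


def _resolve_input(X, weights=None):
    """Return (stack, normalized weights or None) from array or collection."""
    if isinstance(X, ConnectomeCollection):
        if weights is None:
            weights = X.weights
        X = X.matrices
    stack = as_spd_stack(X)
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (len(stack),):
            raise ValueError(
                f"weights must have shape ({len(stack)},), got {weights.shape}"
            )
        if np.any(weights <= 0):
            raise ValueError("all weights must be strictly positive")
        weights = weights / weights.sum()
    return stack, weights


def _tangent_residual(G, gammas, weights=None):
    """Weighted tangent-space mean ``sum_n w_n logm(G^{-1/2} Gamma_n G^{-1/2})``."""
    ih = spd_inv_sqrt(G)
    logs = matrix_logm(sym(ih @ gammas @ ih))
    if weights is None:
        return logs.mean(axis=0)
    return np.tensordot(weights, logs, axes=1)


def condition_fit(G, X, weights=None) -> float:
    """First-order condition fit of a candidate mean ``G``.

    Evaluates ``(1/P^2) || sum_n w_n logm(G^{-1/2} Gamma_n G^{-1/2}) ||_F^2``,
    the deviation of ``G`` from the matrix-normal stationarity condition of
    Frechet mean estimation. Zero iff ``G`` is the geodesic mean. The
    statistic is estimator-agnostic and is always computed without the
    ``lam`` regularization used during mSPD-NN training.
    """
    gammas, weights = _resolve_input(X, weights)
    P = gammas.shape[-1]
    M = _tangent_residual(np.asarray(G, float), gammas, weights)
    return float((M**2).sum() / P**2)


# --------------------------------------------------------------------------
# mSPD-NN
# --------------------------------------------------------------------------


def _regularized_weight(W, lam):
    return W + lam * np.eye(W.shape[0])


def mspdnn_transform(W, gamma, lam: float = 0.0):
    """Bilinear network forward map ``V Gamma V`` with ``V = W~ W~^T``.

    ``W~ = W + lam*I``. The output is symmetric by construction and SPD
    whenever ``W~`` is full rank.
    """
    W = np.asarray(W, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"W must be square, got shape {W.shape}")
    if gamma.shape[-2:] != W.shape:
        raise ValueError(
            f"dimension mismatch: W is {W.shape}, input is {gamma.shape}"
        )
    Wt = _regularized_weight(W, lam)
    V = Wt @ Wt.T
    return sym(V @ gamma @ V)


def _loss_terms(W, gammas, lam, weights):
    """Forward pass: transformed eigensystems and the averaged log residual."""
    P = W.shape[0]
    Wt = _regularized_weight(W, lam)
    V = Wt @ Wt.T
    A = sym(V @ gammas @ V)
    w, u = np.linalg.eigh(A)
    if np.any(w <= 0):
        # eigenvalues at the rounding edge (tiny negative) are floored so a
        # transient iterate cannot abort training; a genuinely indefinite
        # congruence is a domain error
        top = w[:, -1]
        if np.min(w[:, 0] / top) < -1e-10:
            raise ValueError(
                "congruence V Gamma V has a non-positive eigenvalue "
                f"({float(w.min()):.3e}); increase the lam regularization"
            )
        w = np.maximum(w, 1e-16 * top[:, None])
    logw = np.log(w)
    ut = u.transpose(0, 2, 1)
    logs = (u * logw[:, None, :]) @ ut
    if weights is None:
        M = logs.mean(axis=0)
    else:
        M = np.tensordot(weights, logs, axes=1)
    loss = float((M**2).sum() / P**2)
    return loss, M, w, u, V, Wt


def mspdnn_loss(W, X, lam: float = 0.0, weights=None) -> float:
    """The mSPD-NN training loss ``(1/P^2)||sum_n w_n logm(V Gamma_n V)||_F^2``."""
    gammas, weights = _resolve_input(X, weights)
    loss, *_ = _loss_terms(np.asarray(W, float), gammas, lam, weights)
    return loss


def _loss_and_grad(W, gammas, lam, weights):
    """Loss and its analytic gradient with respect to ``W``.

    Backpropagates through the matrix logarithm with the Daleckii-Krein
    divided-difference kernel ``K_ij = (log a_i - log a_j)/(a_i - a_j)``
    (``1/a_i`` on the diagonal), then through the congruence ``V Gamma V``
    and the symmetric product ``V = W~ W~^T``.
    """
    P = W.shape[0]
    N = len(gammas)
    loss, M, w, u, V, Wt = _loss_terms(W, gammas, lam, weights)
    GM = (2.0 / P**2) * M
    dif = w[:, :, None] - w[:, None, :]
    avg = 0.5 * (w[:, :, None] + w[:, None, :])
    small = np.abs(dif) <= 1e-12 * avg
    logdif = np.log(w)[:, :, None] - np.log(w)[:, None, :]
    K = np.where(small, 1.0 / avg, logdif / np.where(small, 1.0, dif))
    ut = u.transpose(0, 2, 1)
    inner = ut @ GM @ u
    GA = u @ (K * inner) @ ut
    if weights is None:
        GA = GA / N
    else:
        GA = GA * weights[:, None, None]
    GV = 2.0 * sym(np.sum(GA @ V @ gammas, axis=0))
    GW = 2.0 * GV @ Wt
    return loss, GW, V


@dataclass
class MeanEstimate:
    """Result of a geodesic-mean estimation run.

    Attributes
    ----------
    mean : ndarray (P, P)
        The estimated geodesic mean (SPD).
    condition_fit : float
        First-order condition fit of ``mean`` (lam-free statistic).
    loss_trace : list of float
        Per-epoch (mSPD-NN) or per-iteration training criterion values.
    n_iterations : int
        Epochs or iterations actually run.
    converged : bool
        Whether the stopping tolerance was reached.
    method : str
        One of ``{"mspdnn", "gradient_descent", "ale"}``.
    seed : int or None
        Seed used for stochastic components (mSPD-NN initialization).
    """

    mean: np.ndarray
    condition_fit: float
    loss_trace: list = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False
    method: str = ""
    seed: int | None = None


class MSPDNN(BaseEstimator):
    """Tied-weight bilinear network estimating the geodesic mean.

    Parameters
    ----------
    max_epochs : int, default 300
        Training epoch budget; the loss tolerance and plateau rule stop
        typical runs far earlier.
    steps_per_epoch : int or None, default None
        Full-batch Adam steps per epoch. ``None`` resolves to ``max(N, 50)``
        so that small collections still receive an adequate step budget.
    lr : float, default 0.01
        Initial Adam learning rate.
    lr_decay : float, default 0.8
        Multiplicative learning-rate decay factor.
    decay_every : int, default 50
        Epochs between decays.
    tol : float, default 1e-8
        Absolute training-loss threshold; training stops once the best loss
        seen drops below it.
    lam : float, default 1e-4
        Ridge added to the weights, ``W~ = W + lam*I``, keeping the learned
        congruence full rank at initialization.
    batch_size : int or None, default None
        If set, each step uses a random mini-batch of this size (per-sample
        stochastic training); ``None`` uses the full collection every step.
    precondition : bool, default True
        Train in whitened coordinates ``M^{-1/2} Gamma_n M^{-1/2}`` (``M``
        the arithmetic mean), where the optimum lies near the identity, and
        map the result back exactly. The Frechet mean is equivariant under
        congruence, so this changes conditioning only, not the estimand;
        without it, badly scaled collections converge much more slowly.
    patience : int, default 15
        Stop when the best loss has not improved by ``min_rel_improvement``
        over this many epochs (plateau detection).
    min_rel_improvement : float, default 0.01
        Relative improvement defining "progress" for the plateau rule.
    random_state : int, default 0
        Seed for weight initialization (i.i.d. uniform on
        ``[-1/sqrt(P), +1/sqrt(P)]``) and mini-batch sampling.

    Attributes
    ----------
    mean_ : ndarray (P, P)
        Estimated geodesic mean, recovered as ``V^{-2}`` from the best
        (lowest-loss) iterate.
    condition_fit_ : float
        First-order condition fit of ``mean_`` (computed with ``lam=0``).
    loss_trace_ : list of float
        End-of-epoch training losses.
    n_iter_ : int
        Epochs run.
    converged_ : bool
        Best loss reached ``tol``.
    W_ : ndarray (P, P)
        Raw weights of the best iterate.
    """

    def __init__(
        self,
        max_epochs: int = 300,
        steps_per_epoch: int | None = None,
        lr: float = 0.01,
        lr_decay: float = 0.8,
        decay_every: int = 50,
        tol: float = 1e-8,
        lam: float = 1e-4,
        batch_size: int | None = None,
        precondition: bool = True,
        patience: int = 15,
        min_rel_improvement: float = 0.01,
        random_state: int = 0,
    ):
        self.max_epochs = max_epochs
        self.steps_per_epoch = steps_per_epoch
        self.lr = lr
        self.lr_decay = lr_decay
        self.decay_every = decay_every
        self.tol = tol
        self.lam = lam
        self.batch_size = batch_size
        self.precondition = precondition
        self.patience = patience
        self.min_rel_improvement = min_rel_improvement
        self.random_state = random_state

    def _validate(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not 0 < self.lr_decay <= 1:
            raise ValueError("lr_decay must be in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")

    def fit(self, X, y=None, sample_weight=None):
        """Estimate the geodesic mean of the SPD stack ``X``.

        ``sample_weight`` (strictly positive) switches to weighted-mean
        estimation; a uniform weighting reproduces the unweighted mean.
        """
        self._validate()
        gammas, weights = _resolve_input(X, sample_weight)
        N, P, _ = gammas.shape
        raw_gammas = gammas
        unwhiten = None
        if self.precondition:
            if weights is None:
                m0 = gammas.mean(axis=0)
            else:
                m0 = np.tensordot(weights, gammas, axes=1)
            unwhiten = spd_sqrt(m0)
            ih = spd_inv_sqrt(m0)
            gammas = sym(ih @ gammas @ ih)
        steps = self.steps_per_epoch or max(N, 50)
        rng = np.random.default_rng(self.random_state)
        bound = 1.0 / np.sqrt(P)
        W = rng.uniform(-bound, bound, size=(P, P))

        m = np.zeros_like(W)
        v = np.zeros_like(W)
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0
        best_loss = np.inf
        best_V = None
        trace: list[float] = []
        stall = 0
        reference = np.inf
        converged = False
        epoch = 0

        for epoch in range(1, self.max_epochs + 1):
            cur_lr = self.lr * self.lr_decay ** ((epoch - 1) // self.decay_every)
            for _ in range(steps):
                t += 1
                if self.batch_size is not None and self.batch_size < N:
                    idx = rng.choice(N, size=self.batch_size, replace=False)
                    batch = gammas[idx]
                    bw = None if weights is None else weights[idx] / weights[idx].sum()
                else:
                    batch, bw = gammas, weights
                loss, grad, V = _loss_and_grad(W, batch, self.lam, bw)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged (non-finite loss) at epoch {epoch}"
                    )
                if self.batch_size is None and loss < best_loss:
                    best_loss, best_V = loss, V
                m = b1 * m + (1 - b1) * grad
                v = b2 * v + (1 - b2) * grad * grad
                W = W - cur_lr * (m / (1 - b1**t)) / (np.sqrt(v / (1 - b2**t)) + eps)
            epoch_loss, *_ , V, _ = _loss_terms(W, gammas, self.lam, weights)
            if epoch_loss < best_loss:
                best_loss, best_V = epoch_loss, V
            trace.append(epoch_loss)
            if best_loss < self.tol:
                converged = True
                break
            if best_loss < (1 - self.min_rel_improvement) * reference:
                reference = best_loss
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break

        w_eig, u = np.linalg.eigh(best_V)
        if np.any(w_eig <= 0):
            raise FloatingPointError(
                "recovered congruence V is not positive definite; "
                "increase the lam regularization"
            )
        G = sym(u @ np.diag(w_eig**-2.0) @ u.T)
        if unwhiten is not None:
            G = sym(unwhiten @ G @ unwhiten)

        self.mean_ = G
        self.W_ = W  # weights in training (whitened) coordinates
        self.loss_trace_ = trace
        self.n_iter_ = epoch
        self.converged_ = converged
        self.condition_fit_ = condition_fit(G, raw_gammas, weights)
        self.n_features_in_ = P
        return self

    def to_estimate(self) -> MeanEstimate:
        """Package fitted attributes as a :class:`MeanEstimate`."""
        return MeanEstimate(
            mean=self.mean_,
            condition_fit=self.condition_fit_,
            loss_trace=list(self.loss_trace_),
            n_iterations=self.n_iter_,
            converged=self.converged_,
            method="mspdnn",
            seed=self.random_state,
        )


class FrechetMeanGD(BaseEstimator):
    """Riemannian gradient descent for the geodesic mean.

    Iterates ``G <- G^{1/2} expm(step * R) G^{1/2}`` from the Euclidean
    arithmetic mean, where ``R`` is the (weighted) tangent-space mean of the
    collection at ``G``. Stops when the intrinsic norm of the tangent update,
    ``step * ||R||_F``, falls below ``tol``. For ``step=1`` this is the
    classical fixed-point iteration, exact in one step for commuting inputs.

    Attributes after ``fit``: ``mean_``, ``condition_fit_``, ``loss_trace_``
    (per-iteration condition fits), ``n_iter_``, ``converged_``.
    """

    def __init__(self, step: float = 0.5, tol: float = 1e-8, max_iter: int = 300):
        self.step = step
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None, sample_weight=None):
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        gammas, weights = _resolve_input(X, sample_weight)
        P = gammas.shape[-1]
        if weights is None:
            G = gammas.mean(axis=0)
        else:
            G = np.tensordot(weights, gammas, axes=1)
        trace: list[float] = []
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            R = _tangent_residual(G, gammas, weights)
            trace.append(float((R**2).sum() / P**2))
            if self.step * float(np.linalg.norm(R)) < self.tol:
                converged = True
                break
            half = spd_sqrt(G)
            G = sym(half @ matrix_expm(self.step * R) @ half)
        self.mean_ = G
        self.loss_trace_ = trace
        self.n_iter_ = it
        self.converged_ = converged
        self.condition_fit_ = condition_fit(G, gammas, weights)
        self.n_features_in_ = P
        return self

    def to_estimate(self) -> MeanEstimate:
        return MeanEstimate(
            mean=self.mean_,
            condition_fit=self.condition_fit_,
            loss_trace=list(self.loss_trace_),
            n_iterations=self.n_iter_,
            converged=self.converged_,
            method="gradient_descent",
            seed=None,
        )


# --------------------------------------------------------------------------
# approximate joint diagonalization / ALE mean
# --------------------------------------------------------------------------


def ajd_pham(X, tol: float = 1e-12, max_sweeps: int = 100):
    """Pham's approximate joint diagonalization of SPD matrices.

    Finds an invertible ``B`` such that every ``B @ Gamma_n @ B.T`` is as
    diagonal as possible in the log-likelihood sense, by Jacobi-like sweeps
    over index pairs; the criterion decrement is monotone and the sweep loop
    stops when it falls below ``tol`` (scaled by ``N * P``).

    Returns
    -------
    B : ndarray (P, P)
        The joint diagonalizer (rows are the estimated unmixing directions).
    info : dict
        ``converged`` flag, number of ``sweeps``, and the final normalized
        off-diagonality ``criterion``.
    """
    gammas, _ = _resolve_input(X)
    N, P, _ = gammas.shape
    if N < 2:
        raise ValueError("joint diagonalization needs at least 2 matrices")
    C = gammas.copy()
    B = np.eye(P)
    threshold = tol * N * P
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        decr = 0.0
        for i in range(1, P):
            for j in range(i):
                c_ii = C[:, i, i]
                c_jj = C[:, j, j]
                c_ij = C[:, i, j]
                g_ij = np.mean(c_ij / c_ii)
                g_ji = np.mean(c_ij / c_jj)
                w_ji = np.mean(c_ii / c_jj)
                w_ij = np.mean(c_jj / c_ii)
                w = np.sqrt(w_ij * w_ji)
                s = np.sqrt(w_ji / w_ij)
                t1 = (s * g_ij + g_ji) / (w + 1.0)
                t2 = (s * g_ij - g_ji) / max(w - 1.0, 1e-14)
                h12 = t1 + t2
                h21 = (t1 - t2) / s
                decr += N * (g_ij * h12 + g_ji * h21) / 2.0
                prod = h12 * h21
                if prod >= 0.99:
                    # damp oversized Jacobi steps so the 2x2 transform stays
                    # well conditioned (det = 1 - h12*h21 must remain positive)
                    scale = np.sqrt(0.99 / prod)
                    h12 *= scale
                    h21 *= scale
                    prod = 0.99
                tmp = 1.0 + np.sqrt(max(1.0 - prod, 0.0))
                T = np.array([[1.0, -h12 / tmp], [-h21 / tmp, 1.0]])
                pair = [i, j]
                B[pair, :] = T @ B[pair, :]
                C[:, pair, :] = np.einsum("ab,nbk->nak", T, C[:, pair, :])
                C[:, :, pair] = np.einsum("nkb,ab->nka", C[:, :, pair], T)
        if decr < threshold:
            converged = True
            break
    diag = np.sqrt(C[:, np.arange(P), np.arange(P)])
    off = C / (diag[:, :, None] * diag[:, None, :])
    off[:, np.arange(P), np.arange(P)] = 0.0
    criterion = float(np.max(np.abs(off)))
    return B, {"converged": converged, "sweeps": sweeps, "criterion": criterion}


class ALEMean(BaseEstimator):
    """Approximate-Joint-Diagonalization Log-Euclidean mean.

    With ``B`` jointly diagonalizing the collection (``B Gamma_n B^T`` near
    diagonal), the mean is
    ``B^{-1} expm( mean_n logm(ddiag(B Gamma_n B^T)) ) B^{-T}``
    where ``ddiag`` keeps the diagonal part. When the data follow an exact
    CPC process ``Gamma_n = B0 C_n B0^T`` this equals the theoretical
    geodesic mean of the process.
    """

    def __init__(self, tol: float = 1e-12, max_sweeps: int = 100):
        self.tol = tol
        self.max_sweeps = max_sweeps

    def fit(self, X, y=None, sample_weight=None):
        gammas, weights = _resolve_input(X, sample_weight)
        P = gammas.shape[-1]
        B, info = ajd_pham(gammas, tol=self.tol, max_sweeps=self.max_sweeps)
        D = sym(B @ gammas @ B.T)
        d = D[:, np.arange(P), np.arange(P)]
        if np.any(d <= 0):
            raise FloatingPointError("joint diagonalization produced a non-positive diagonal")
        if weights is None:
            mean_log = np.log(d).mean(axis=0)
        else:
            mean_log = np.tensordot(weights, np.log(d), axes=1)
        Binv = np.linalg.inv(B)
        G = sym(Binv @ np.diag(np.exp(mean_log)) @ Binv.T)
        self.mean_ = G
        self.diagonalizer_ = B
        self.loss_trace_ = [info["criterion"]]
        self.n_iter_ = info["sweeps"]
        self.converged_ = info["converged"]
        self.condition_fit_ = condition_fit(G, gammas, weights)
        self.n_features_in_ = P
        return self

    def to_estimate(self) -> MeanEstimate:
        return MeanEstimate(
            mean=self.mean_,
            condition_fit=self.condition_fit_,
            loss_trace=list(self.loss_trace_),
            n_iterations=self.n_iter_,
            converged=self.converged_,
            method="ale",
            seed=None,
        )


# --------------------------------------------------------------------------
# functional wrappers
# --------------------------------------------------------------------------


def mspdnn_fit(X, weights=None, **config) -> MeanEstimate:
    """Fit :class:`MSPDNN` with the given config and return a :class:`MeanEstimate`."""
    est = MSPDNN(**config).fit(X, sample_weight=weights)
    return est.to_estimate()


def gradient_descent_mean(X, weights=None, **config) -> MeanEstimate:
    """Fit :class:`FrechetMeanGD` and return a :class:`MeanEstimate`."""
    est = FrechetMeanGD(**config).fit(X, sample_weight=weights)
    return est.to_estimate()


def ale_mean(X, weights=None, **config) -> MeanEstimate:
    """Fit :class:`ALEMean` and return a :class:`MeanEstimate`."""
    est = ALEMean(**config).fit(X, sample_weight=weights)
    return est.to_estimate()


MEAN_ESTIMATORS = {
    "mspdnn": MSPDNN,
    "gd": FrechetMeanGD,
    "gradient_descent": FrechetMeanGD,
    "ale": ALEMean,
}


def make_mean_estimator(method: str, **config) -> BaseEstimator:
    """Instantiate a mean estimator by short name (``mspdnn``, ``gd``, ``ale``)."""
    try:
        cls = MEAN_ESTIMATORS[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; expected one of {sorted(set(MEAN_ESTIMATORS))}"
        ) from None
    return cls(**config)
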
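"""Riemannian primitives on the manifold of symmetric positive definite matrices.

The affine-invariant (Fisher information) geometry is used throughout: the
distance between two SPD matrices ``G1, G2`` is ``||logm(G1^{-1} G2)||_F``,
computed here in the congruence form ``||logm(G1^{-1/2} G2 G1^{-1/2})||_F``
which is mathematically identical in norm but keeps every matrix function
acting on a symmetric argument.

All matrix functions (``expm``, ``logm``, fractional powers) go through a
symmetric eigendecomposition after an explicit symmetrization ``(A + A^T)/2``,
which makes results deterministic and well conditioned for the matrix sizes
used in connectomics (P up to a few hundred).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "sym",
    "check_spd",
    "check_symmetric",
    "matrix_expm",
    "matrix_logm",
    "spd_power",
    "spd_sqrt",
    "spd_inv_sqrt",
    "exp_map",
    "log_map",
    "geodesic_distance",
    "riemannian_norm",
    "geodesic_midpoint",
]

#: relative tolerance used when checking symmetry of inputs
SYM_RTOL = 1e-8


def sym(a: np.ndarray) -> np.ndarray:
    """Symmetrize ``a`` as ``(a + a.T) / 2`` (batched over leading axes)."""
    return 0.5 * (a + np.swapaxes(a, -1, -2))


def check_symmetric(a: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Validate that ``a`` is square and symmetric within tolerance.

    Returns the explicitly symmetrized matrix. The tolerance is
    ``SYM_RTOL * (1 + max|a|)``, an absolute floor plus a relative part.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim < 2 or a.shape[-1] != a.shape[-2]:
        raise ValueError(f"{name} must be square, got shape {a.shape}")
    scale = 1.0 + np.abs(a).max(initial=0.0)
    asymmetry = np.abs(a - np.swapaxes(a, -1, -2)).max(initial=0.0)
    if asymmetry > SYM_RTOL * scale:
        raise ValueError(
            f"{name} is not symmetric: max asymmetry {asymmetry:.3e} "
            f"exceeds tolerance {SYM_RTOL * scale:.3e}"
        )
    return sym(a)


def check_spd(
    a: np.ndarray,
    name: str = "matrix",
    eig_floor_scale: float = 1e-10,
) -> np.ndarray:
    """Validate that ``a`` is symmetric positive definite.

    The smallest eigenvalue must exceed ``eig_floor_scale * trace / P``
    (a scale-aware floor; pass 0 to require only strict positivity).
    Returns the symmetrized matrix; raises ``ValueError`` naming the
    offending eigenvalue otherwise.
    """
    a = check_symmetric(a, name=name)
    if a.ndim != 2:
        raise ValueError(f"{name} must be a single 2-D matrix, got shape {a.shape}")
    w = np.linalg.eigvalsh(a)
    p = a.shape[0]
    floor = eig_floor_scale * np.trace(a) / p
    if w[0] <= max(floor, 0.0):
        raise ValueError(
            f"{name} is not positive definite: smallest eigenvalue "
            f"{w[0]:.6e} is below the validation floor {floor:.6e}"
        )
    return a


def _eigh_sym(a: np.ndarray):
    """Eigendecomposition of the symmetrized input (batched)."""
    return np.linalg.eigh(sym(np.asarray(a, dtype=float)))


def matrix_expm(v: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix via eigendecomposition.

    Batched over leading axes. The result of a single symmetric input is SPD.
    """
    v = check_symmetric(v, name="tangent matrix") if np.ndim(v) == 2 else np.asarray(v, float)
    w, u = _eigh_sym(v)
    return sym(np.einsum("...ik,...k,...jk->...ij", u, np.exp(w), u))


def matrix_logm(g: np.ndarray) -> np.ndarray:
    """Principal matrix logarithm of an SPD matrix via eigendecomposition.

    Batched over leading axes; every matrix must have strictly positive
    eigenvalues, otherwise a ``ValueError`` reports the offending eigenvalue.
    """
    w, u = _eigh_sym(g)
    if np.any(w <= 0):
        bad = float(np.min(w))
        raise ValueError(
            f"matrix logarithm undefined: non-positive eigenvalue {bad:.6e}"
        )
    return sym(np.einsum("...ik,...k,...jk->...ij", u, np.log(w), u))


def spd_power(g: np.ndarray, p: float) -> np.ndarray:
    """Fractional power ``g^p`` of an SPD matrix (batched)."""
    w, u = _eigh_sym(g)
    if np.any(w <= 0):
        raise ValueError(
            f"matrix power undefined: non-positive eigenvalue {float(np.min(w)):.6e}"
        )
    return sym(np.einsum("...ik,...k,...jk->...ij", u, w**p, u))


def spd_sqrt(g: np.ndarray) -> np.ndarray:
    """Principal square root of an SPD matrix."""
    return spd_power(g, 0.5)


def spd_inv_sqrt(g: np.ndarray) -> np.ndarray:
    """Inverse principal square root of an SPD matrix."""
    return spd_power(g, -0.5)


def _sqrt_pair(g: np.ndarray):
    w, u = _eigh_sym(g)
    if np.any(w <= 0):
        raise ValueError(
            f"SPD square root undefined: non-positive eigenvalue {float(np.min(w)):.6e}"
        )
    s = np.sqrt(w)
    half = sym(np.einsum("...ik,...k,...jk->...ij", u, s, u))
    inv_half = sym(np.einsum("...ik,...k,...jk->...ij", u, 1.0 / s, u))
    return half, inv_half


def exp_map(phi: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Riemannian exponential map at base point ``phi``.

    ``Exp_phi(V) = phi^{1/2} expm(phi^{-1/2} V phi^{-1/2}) phi^{1/2}``
    maps a symmetric tangent matrix ``V`` at ``phi`` to a point on the
    manifold along the geodesic emanating from ``phi``.
    """
    phi = np.asarray(phi, float)
    v = np.asarray(v, float)
    if phi.shape != v.shape:
        raise ValueError(f"shape mismatch: base {phi.shape} vs tangent {v.shape}")
    half, inv_half = _sqrt_pair(phi)
    inner = matrix_expm(sym(inv_half @ v @ inv_half))
    return sym(half @ inner @ half)


def log_map(phi: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Riemannian logarithm map at base point ``phi``.

    ``Log_phi(G) = phi^{1/2} logm(phi^{-1/2} G phi^{-1/2}) phi^{1/2}``
    is the inverse of :func:`exp_map`: the tangent matrix at ``phi``
    pointing along the geodesic towards ``g``.
    """
    phi = np.asarray(phi, float)
    g = np.asarray(g, float)
    if phi.shape != g.shape:
        raise ValueError(f"shape mismatch: base {phi.shape} vs target {g.shape}")
    half, inv_half = _sqrt_pair(phi)
    inner = matrix_logm(sym(inv_half @ g @ inv_half))
    return sym(half @ inner @ half)


def geodesic_distance(g1: np.ndarray, g2: np.ndarray) -> float:
    """Affine-invariant geodesic distance ``||logm(g1^{-1/2} g2 g1^{-1/2})||_F``.

    Symmetric in its arguments and invariant under congruence
    ``(g1, g2) -> (A g1 A^T, A g2 A^T)`` for invertible ``A``.
    """
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    if g1.shape != g2.shape:
        raise ValueError(f"shape mismatch: {g1.shape} vs {g2.shape}")
    _, inv_half = _sqrt_pair(g1)
    inner = sym(inv_half @ g2 @ inv_half)
    w = np.linalg.eigvalsh(inner)
    if np.any(w <= 0):
        raise ValueError(
            f"geodesic distance undefined: non-positive eigenvalue {float(w.min()):.6e}"
        )
    return float(np.linalg.norm(np.log(w)))


def riemannian_norm(g: np.ndarray) -> float:
    """Riemannian norm ``||logm(g)||_F`` — the geodesic distance from identity."""
    w, _ = _eigh_sym(g)
    if np.any(w <= 0):
        raise ValueError(
            f"Riemannian norm undefined: non-positive eigenvalue {float(w.min()):.6e}"
        )
    return float(np.linalg.norm(np.log(w)))


def geodesic_midpoint(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Closed-form geodesic (Frechet) mean of two SPD matrices.

    ``g1^{1/2} (g1^{-1/2} g2 g1^{-1/2})^{1/2} g1^{1/2}`` — the midpoint of
    the geodesic joining the two matrices, and the unique minimizer of the
    sum of squared geodesic distances for N=2. For commuting inputs this is
    the elementwise geometric mean of the (shared-basis) eigenvalues.
    """
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    if g1.shape != g2.shape:
        raise ValueError(f"shape mismatch: {g1.shape} vs {g2.shape}")
    half, inv_half = _sqrt_pair(g1)
    inner = spd_power(sym(inv_half @ g2 @ inv_half), 0.5)
    return sym(half @ inner @ half)
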
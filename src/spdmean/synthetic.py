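"""Synthetic SPD data: the CPC generating process and clustered cohorts.

The common-principal-components (CPC) process shares one invertible component
matrix ``B`` across the collection and varies only the positive diagonal
loadings: ``Gamma_n = B C_n B^T`` with ``C_n = diag(c_n)``. Its geodesic mean
has the closed form ``B expm(mean_n logm(B^{-1} Gamma_n B^{-T})) B^T``, which
serves as the ground-truth oracle for estimator benchmarks. A rank-one
structured perturbation ``(1/P) x_n x_n^T`` models deviation from the shared
component structure.

Clustered cohorts (SPD centroids with tangent-space scatter) provide labelled
fixtures for the group-analysis pipeline; they emulate the multi-cohort
structure of clinical connectome studies, not real rs-fMRI data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .collection import ConnectomeCollection
from .geometry import exp_map, matrix_expm, sym

__all__ = [
    "CPCGroundTruth",
    "sample_cpc_dataset",
    "add_structured_noise",
    "theoretical_cpc_mean",
    "sample_clustered_cohorts",
]

logger = logging.getLogger(__name__)

#: lower clip applied to every CPC loading c_nk
COEFFICIENT_CLIP = 0.001


@dataclass
class CPCGroundTruth:
    """Ground truth of a sampled CPC dataset.

    Attributes
    ----------
    B : ndarray (P, P)
        Common component matrix (columns are i.i.d. standard normal vectors).
    coefficients : ndarray (N, P)
        Strictly positive per-sample loadings ``c_n`` (squared standard
        normals, clipped below at ``COEFFICIENT_CLIP``).
    sigma : float
        Scale of the rank-one structured noise attached to this truth
        (0 for a noiseless dataset).
    noise_vectors : ndarray (N, P) or None
        The noise directions ``x_n`` when ``sigma > 0``.
    seed : int
        Seed the dataset was drawn with.
    """

    B: np.ndarray
    coefficients: np.ndarray
    sigma: float = 0.0
    noise_vectors: np.ndarray | None = None
    seed: int = 0

    @property
    def dim(self) -> int:
        return self.B.shape[0]

    @property
    def n_samples(self) -> int:
        return self.coefficients.shape[0]

    def noiseless_matrices(self) -> np.ndarray:
        """The exact CPC stack ``B C_n B^T``."""
        return sym(np.einsum("ik,nk,jk->nij", self.B, self.coefficients, self.B))


def sample_cpc_dataset(
    P: int,
    N: int,
    seed: int = 0,
    max_condition: float = 1e12,
) -> tuple[CPCGroundTruth, ConnectomeCollection]:
    """Draw a noiseless CPC dataset of ``N`` matrices of dimension ``P``.

    Columns of ``B`` are i.i.d. standard normal; loadings are squared
    standard normals clipped below at 0.001 (keeping every ``Gamma_n``
    full rank). A nearly singular ``B`` (condition number above
    ``max_condition``) is redrawn with an incremented sub-seed and logged.
    Deterministic given ``seed``.
    """
    if P < 2:
        raise ValueError("P must be at least 2")
    if N < 1:
        raise ValueError("N must be at least 1")
    B = None
    for attempt in range(100):
        rng = np.random.default_rng([seed, attempt])
        cand = rng.standard_normal((P, P))
        if np.linalg.cond(cand) <= max_condition:
            B = cand
            break
        logger.info(
            "resampling near-singular component matrix (seed=%d attempt=%d)",
            seed,
            attempt,
        )
    if B is None:  # pragma: no cover - vanishingly unlikely
        raise RuntimeError("could not draw a well-conditioned component matrix")
    coeff = np.clip(rng.standard_normal((N, P)) ** 2, COEFFICIENT_CLIP, None)
    truth = CPCGroundTruth(B=B, coefficients=coeff, sigma=0.0, seed=seed)
    return truth, ConnectomeCollection(truth.noiseless_matrices())


def add_structured_noise(
    truth: CPCGroundTruth, sigma: float, seed: int = 0
) -> ConnectomeCollection:
    """Corrupt a CPC dataset with rank-one noise ``(1/P) x_n x_n^T``.

    ``x_n ~ N(0, sigma^2 I_P)``. The perturbation is positive semidefinite,
    so outputs remain SPD; ``sigma=0`` returns the noiseless collection.
    The input ``truth`` is not mutated; the noise draw is deterministic
    given ``seed``, so the vectors can be recovered by redrawing.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    base = truth.noiseless_matrices()
    if sigma == 0:
        return ConnectomeCollection(base)
    rng = np.random.default_rng([seed, 97])
    x = rng.normal(0.0, sigma, size=(truth.n_samples, truth.dim))
    noisy = base + np.einsum("ni,nj->nij", x, x) / truth.dim
    return ConnectomeCollection(sym(noisy))


def theoretical_cpc_mean(truth: CPCGroundTruth) -> np.ndarray:
    """Closed-form geodesic mean of a noiseless CPC collection.

    ``G* = B expm( (1/N) sum_n logm(B^{-1} Gamma_n B^{-T}) ) B^T``. Because
    ``B^{-1} Gamma_n B^{-T} = C_n`` is diagonal this reduces to
    ``B expm(mean of log C_n) B^T`` — the elementwise geometric mean of the
    loadings pushed back through the components.
    """
    if np.linalg.cond(truth.B) > 1e14:
        raise ValueError("component matrix is numerically singular")
    mean_log = np.log(truth.coefficients).mean(axis=0)
    return sym(truth.B @ np.diag(np.exp(mean_log)) @ truth.B.T)


def sample_clustered_cohorts(
    P: int,
    sizes,
    separation: float,
    within_spread: float,
    seed: int = 0,
) -> tuple[ConnectomeCollection, np.ndarray]:
    """Labelled SPD cohorts with controlled between/within geodesic scales.

    One SPD centroid per cohort is placed at pairwise geodesic distance of
    roughly ``separation`` (mutually orthogonal unit tangent directions at
    the identity, scaled by ``separation / sqrt(2)``). Members are drawn by
    ``exp_map(centroid, within_spread * U)`` with ``U`` a random symmetric
    direction of unit Frobenius norm, so each member sits at geodesic
    distance ``within_spread`` from its centroid (in the centroid's
    congruence coordinates). Labels are ``"g0", "g1", ...``.

    Returns the labelled collection and the ``(K, P, P)`` centroid stack.
    """
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    if within_spread < 0:
        raise ValueError("within_spread must be nonnegative")
    sizes = [int(s) for s in sizes]
    if not sizes or any(s < 1 for s in sizes):
        raise ValueError("sizes must be a nonempty list of positive integers")
    K = len(sizes)
    rng = np.random.default_rng([seed, 11])
    dim_sym = P * (P + 1) // 2

    # orthonormal tangent directions at I (Gram-Schmidt in the symmetric space)
    dirs = []
    while len(dirs) < K:
        E = sym(rng.standard_normal((P, P)))
        for D in dirs:
            E = E - np.sum(E * D) * D
        norm = np.linalg.norm(E)
        if norm > 1e-8:
            dirs.append(E / norm)
        if len(dirs) > dim_sym:  # pragma: no cover - K larger than the space
            raise ValueError("more cohorts than independent tangent directions")
    centroids = np.stack(
        [matrix_expm(separation / np.sqrt(2.0) * D) for D in dirs]
    )

    matrices, labels = [], []
    for k, size in enumerate(sizes):
        for _ in range(size):
            E = sym(rng.standard_normal((P, P)))
            E = E / np.linalg.norm(E)
            matrices.append(exp_map(centroids[k], within_spread * E))
            labels.append(f"g{k}")
    return ConnectomeCollection(np.stack(matrices), labels=labels), centroids
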
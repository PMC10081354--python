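"""Container for collections of same-dimension SPD matrices (connectomes)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .geometry import check_spd

__all__ = ["ConnectomeCollection", "as_spd_stack"]


def as_spd_stack(matrices, validate: bool = True) -> np.ndarray:
    """Coerce an iterable of P x P SPD matrices (or an N x P x P array) to a stack.

    Every matrix is SPD-validated when ``validate`` is true; the failing
    index and eigenvalue are reported on rejection.
    """
    arr = np.asarray(matrices, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[-1] != arr.shape[-2]:
        raise ValueError(f"expected an N x P x P stack, got shape {arr.shape}")
    if validate:
        out = np.empty_like(arr)
        for i, g in enumerate(arr):
            try:
                out[i] = check_spd(g, name=f"matrix {i}")
            except ValueError as exc:
                raise ValueError(str(exc)) from None
        return out
    return arr


@dataclass
class ConnectomeCollection:
    """N same-dimension SPD matrices with optional group labels and weights.

    Attributes
    ----------
    matrices : ndarray, shape (N, P, P)
        The SPD stack (validated at construction).
    labels : sequence of str, optional
        Per-sample categorical group labels.
    weights : ndarray, optional
        Strictly positive per-sample weights for weighted mean estimation.
    ids : sequence of str, optional
        Sample identifiers (defaults to zero-padded indices).
    """

    matrices: np.ndarray
    labels: Sequence[str] | None = None
    weights: np.ndarray | None = None
    ids: Sequence[str] | None = field(default=None)

    def __post_init__(self):
        self.matrices = as_spd_stack(self.matrices)
        n = len(self.matrices)
        if n < 1:
            raise ValueError("collection must contain at least one matrix")
        if self.labels is not None:
            self.labels = list(self.labels)
            if len(self.labels) != n:
                raise ValueError(
                    f"{len(self.labels)} labels for {n} matrices"
                )
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (n,):
                raise ValueError(f"weights must have shape ({n},)")
            if np.any(self.weights <= 0):
                raise ValueError("all weights must be strictly positive")
        if self.ids is None:
            width = max(3, len(str(n - 1)))
            self.ids = [f"{i:0{width}d}" for i in range(n)]
        else:
            self.ids = [str(s) for s in self.ids]
            if len(self.ids) != n:
                raise ValueError(f"{len(self.ids)} ids for {n} matrices")

    def __len__(self) -> int:
        return len(self.matrices)

    @property
    def n_samples(self) -> int:
        return len(self.matrices)

    @property
    def dim(self) -> int:
        return self.matrices.shape[-1]

    def __iter__(self) -> Iterable[np.ndarray]:
        return iter(self.matrices)

    def subset(self, indices) -> "ConnectomeCollection":
        """Sub-collection at the given integer indices (labels/weights carried)."""
        idx = np.asarray(indices, dtype=int)
        return ConnectomeCollection(
            self.matrices[idx],
            labels=[self.labels[i] for i in idx] if self.labels is not None else None,
            weights=self.weights[idx] if self.weights is not None else None,
            ids=[self.ids[i] for i in idx],
        )

    def group(self, label) -> "ConnectomeCollection":
        """Sub-collection of samples carrying the given label."""
        if self.labels is None:
            raise ValueError("collection has no labels")
        idx = [i for i, lab in enumerate(self.labels) if lab == label]
        if not idx:
            raise ValueError(f"no samples labelled {label!r}")
        return self.subset(idx)
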
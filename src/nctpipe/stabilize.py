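"""Stabilizing normalizations of the adjacency matrix.

The linear system ``x' = A x + B u`` is only a usable model of connectome
dynamics if A is stable.  Two normalizations are used, one per analysis
family:

* **Weighted-Laplacian normalization** (continuous time, energy analyses):
  ``A <- -L / lambda_max(L)`` with ``L = diag(rowsum(A)) - A``.  For a
  nonnegative adjacency this places every eigenvalue in [-1, 0]; the zero
  eigenvalue (the Laplacian null space) makes the system marginally, not
  strictly, stable, which is why the energy code falls back to the
  finite-horizon Gramian.

* **Schur normalization** (discrete time, controllability analyses):
  ``A <- A / (1 + lambda_max(A))`` with ``lambda_max`` the maximum
  *absolute* eigenvalue.  The spectral radius of the result is
  ``r / (1 + r) < 1`` so the discrete-time system is Schur stable even
  when the dominant eigenvalue of an FC matrix is negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .connectivity import AdjacencyMatrix
from .errors import DegenerateInputError, ValidationError

EIGEN_TOL = 1e-10


def _as_array(A: Union[AdjacencyMatrix, np.ndarray]) -> np.ndarray:
    values = A.values if isinstance(A, AdjacencyMatrix) else np.asarray(A, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValidationError(f"expected a square matrix, got shape {values.shape}")
    if np.abs(values - values.T).max(initial=0.0) > 1e-8:
        raise ValidationError("matrix must be symmetric")
    return (values + values.T) / 2.0


@dataclass(frozen=True)
class StabilizedSystem:
    """A normalized system matrix with its stability certificate.

    ``stability_margin`` is the largest eigenvalue for continuous mode
    (stable iff <= 0) and the spectral radius for discrete mode (stable
    iff < 1).  ``lambda_max_input`` records the normalization denominator's
    eigenvalue magnitude.
    """

    matrix: np.ndarray
    mode: str  # "continuous" | "discrete"
    lambda_max_input: float
    stability_margin: float

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.matrix)


@dataclass(frozen=True)
class StabilityReport:
    mode: str
    eig_min: float
    eig_max: float
    spectral_radius: float
    passed: bool
    margin: float


def laplacian_normalize(A: Union[AdjacencyMatrix, np.ndarray]) -> StabilizedSystem:
    """Weighted-Laplacian normalization for the continuous-time system.

    Builds ``L_ij = delta_ij * sum_k A_ik - A_ij`` and returns
    ``-L / lambda_max(L)`` where ``lambda_max`` is the maximum absolute
    eigenvalue of L.  For nonnegative A the output eigenvalues lie in
    [-1, 0], a sufficient condition for (marginal) stability.

    Raises
    ------
    DegenerateInputError
        If ``lambda_max(L) = 0`` (the all-zero adjacency).
    """
    a = _as_array(A)
    lap = np.diag(a.sum(axis=1)) - a
    eigs = np.linalg.eigvalsh(lap)
    lam = float(np.abs(eigs).max())
    if lam == 0.0:
        raise DegenerateInputError(
            "Laplacian has zero spectrum (empty graph); cannot normalize"
        )
    out = -lap / lam
    margin = float(np.linalg.eigvalsh(out).max())
    return StabilizedSystem(out, "continuous", lam, margin)


def schur_normalize(
    A: Union[AdjacencyMatrix, np.ndarray], use_absolute: bool = True
) -> StabilizedSystem:
    """Schur normalization for the discrete-time system.

    Returns ``A / (1 + lambda_max(A))``.  With ``use_absolute`` (default)
    the denominator uses the maximum absolute eigenvalue, which guarantees
    spectral radius ``r / (1 + r) < 1`` for every symmetric input; with
    ``use_absolute=False`` the plain largest eigenvalue is used instead
    (provided for comparison — it does not guarantee Schur stability when
    the most negative eigenvalue dominates).
    """
    a = _as_array(A)
    eigs = np.linalg.eigvalsh(a)
    lam = float(np.abs(eigs).max()) if use_absolute else float(eigs.max())
    out = a / (1.0 + lam)
    radius = float(np.abs(np.linalg.eigvalsh(out)).max())
    return StabilizedSystem(out, "discrete", lam, radius)


def certify(S: StabilizedSystem, tol: float = EIGEN_TOL) -> StabilityReport:
    """Check a stabilized system against its mode's stability invariant.

    Continuous mode passes when all eigenvalues lie in [-1 - tol, tol];
    discrete mode passes when the spectral radius is strictly below 1.
    """
    eigs = S.eigenvalues()
    eig_min, eig_max = float(eigs.min()), float(eigs.max())
    radius = float(np.abs(eigs).max())
    if S.mode == "continuous":
        passed = eig_min >= -1.0 - tol and eig_max <= tol
        margin = -eig_max
    elif S.mode == "discrete":
        passed = radius < 1.0
        margin = 1.0 - radius
    else:
        raise ValidationError(f"unknown mode {S.mode!r}")
    return StabilityReport(S.mode, eig_min, eig_max, radius, passed, margin)
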
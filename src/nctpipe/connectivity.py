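"""Adjacency-matrix construction from per-subject connectome data.

Five adjacency scenarios feed the control-theoretic analyses downstream:

* ``SC`` — the structural connectome (streamline weights, nonnegative),
* ``sFC`` / ``sFC_noneg`` — static functional connectivity: the Pearson
  correlation matrix of the regional BOLD time courses over the whole
  acquisition, with negative correlations either kept or zeroed,
* ``dFC`` / ``dFC_noneg`` — dynamic functional connectivity: the same
  correlation computed inside consecutive non-overlapping time windows,
  yielding a piecewise-constant adjacency sequence.

All adjacency matrices are symmetric with an exactly zero diagonal; FC
entries lie in [-1, 1].  This module also selects initial/final activation
states for the control problems by sampling columns of the BOLD matrix from
its first and last quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, EstimationError, ValidationError

SCENARIOS = ("SC", "sFC", "sFC_noneg", "dFC", "dFC_noneg")

_SYMMETRY_TOL = 1e-10
_ASYMMETRY_REPAIR_TOL = 1e-8


@dataclass(frozen=True)
class AdjacencyMatrix:
    """A symmetric node-by-node interaction matrix with provenance.

    Parameters
    ----------
    values
        N x N real matrix of edge weights.
    provenance
        One of ``"SC"``, ``"sFC"``, ``"dFC"``.
    negatives_zeroed
        Whether negative entries were clipped to zero (FC scenarios only).
    window_id
        Window index for dynamic-FC matrices, ``None`` otherwise.
    """

    values: np.ndarray
    provenance: str
    negatives_zeroed: bool = False
    window_id: Optional[int] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError(f"adjacency matrix must be square, got {v.shape}")
        if self.provenance not in ("SC", "sFC", "dFC"):
            raise ValidationError(f"unknown provenance {self.provenance!r}")
        if np.abs(v - v.T).max(initial=0.0) > _SYMMETRY_TOL:
            raise ValidationError("adjacency matrix is not symmetric within 1e-10")
        if np.abs(np.diagonal(v)).max(initial=0.0) != 0.0:
            raise ValidationError("adjacency diagonal must be exactly zero")
        if self.provenance in ("sFC", "dFC"):
            if v.min(initial=0.0) < -1.0 - 1e-12 or v.max(initial=0.0) > 1.0 + 1e-12:
                raise ValidationError("FC entries must lie in [-1, 1]")
        if self.negatives_zeroed and v.min(initial=0.0) < 0.0:
            raise ValidationError("negatives_zeroed matrix has negative entries")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def scenario(self) -> str:
        """Scenario key: provenance plus the negative-edge policy."""
        if self.provenance == "SC":
            return "SC"
        return self.provenance + ("_noneg" if self.negatives_zeroed else "")


@dataclass(frozen=True)
class AdjacencySequence:
    """Ordered dynamic-FC windows forming a piecewise-constant adjacency."""

    windows: tuple
    window_length_seconds: float
    window_length_samples: int

    def __post_init__(self) -> None:
        if len(self.windows) < 1:
            raise ValidationError("an adjacency sequence needs at least one window")
        n = self.windows[0].n_nodes
        pol = self.windows[0].negatives_zeroed
        for w in self.windows:
            if w.provenance != "dFC":
                raise ValidationError("sequence windows must have dFC provenance")
            if w.n_nodes != n or w.negatives_zeroed != pol:
                raise ValidationError("sequence windows must share size and policy")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def n_nodes(self) -> int:
        return self.windows[0].n_nodes

    @property
    def scenario(self) -> str:
        return self.windows[0].scenario


@dataclass(frozen=True)
class StatePair:
    """An initial/final activation-state pair taken from the BOLD series.

    ``x0`` is a column from the first quartile of time points and ``xf`` a
    column from the last quartile, so the transition follows the subject's
    natural chronological ordering of resting states.
    """

    x0: np.ndarray
    xf: np.ndarray
    t0_index: int
    tf_index: int

    def __post_init__(self) -> None:
        if not self.t0_index < self.tf_index:
            raise ValidationError("t0_index must precede tf_index")


def compute_sfc(bold: np.ndarray, zero_negatives: bool = False) -> AdjacencyMatrix:
    """Static functional connectivity: full-series Pearson correlations.

    Entry (i, j) for i != j is the Pearson correlation of the time courses
    of nodes i and j; the diagonal is zeroed.  With ``zero_negatives`` the
    negative correlations are clipped to zero.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim != 2 or bold.shape[1] < 3:
        raise ConfigurationError("bold must be an N x T matrix with T >= 3")
    sd = bold.std(axis=1)
    if np.any(sd == 0.0):
        bad = int(np.flatnonzero(sd == 0.0)[0])
        raise EstimationError(f"node {bad} has a constant time course")
    corr = np.corrcoef(bold)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    if zero_negatives:
        corr = np.maximum(corr, 0.0)
    return AdjacencyMatrix(corr, "sFC", negatives_zeroed=zero_negatives)


def compute_dfc(
    bold: np.ndarray,
    window_seconds: float,
    tr_seconds: float,
    zero_negatives: bool = False,
    stride_samples: Optional[int] = None,
) -> AdjacencySequence:
    """Dynamic functional connectivity over consecutive time windows.

    The series is divided into ``M = floor(T / w)`` non-overlapping windows
    of ``w = round(window_seconds / tr_seconds)`` samples each (trailing
    remainder samples are dropped) and the Pearson correlation matrix is
    computed inside each window.  ``stride_samples`` defaults to the window
    length, i.e. a contiguous partition.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim != 2:
        raise ConfigurationError("bold must be an N x T matrix")
    n_samples = int(round(window_seconds / tr_seconds))
    if n_samples < 3:
        raise ConfigurationError(
            f"window of {window_seconds} s at TR {tr_seconds} s gives "
            f"{n_samples} samples; need at least 3"
        )
    T = bold.shape[1]
    if n_samples > T:
        raise ConfigurationError(
            f"window of {n_samples} samples exceeds series length {T}"
        )
    stride = n_samples if stride_samples is None else int(stride_samples)
    if stride < 1:
        raise ConfigurationError("stride must be positive")
    starts = range(0, T - n_samples + 1, stride)
    windows = []
    for m, start in enumerate(starts):
        seg = bold[:, start : start + n_samples]
        win = compute_sfc(seg, zero_negatives=zero_negatives)
        windows.append(
            AdjacencyMatrix(win.values, "dFC", negatives_zeroed=zero_negatives, window_id=m)
        )
    return AdjacencySequence(tuple(windows), float(window_seconds), n_samples)


def ingest_sc(matrix: np.ndarray) -> AdjacencyMatrix:
    """Validate and normalize a structural-connectivity matrix.

    Small numerical asymmetries (<= 1e-8) are repaired by symmetrization;
    the diagonal is zeroed.  Negative weights are rejected.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError(f"SC matrix must be square, got {m.shape}")
    asym = np.abs(m - m.T).max(initial=0.0)
    if asym > _ASYMMETRY_REPAIR_TOL:
        raise ValidationError(f"SC matrix is grossly asymmetric (max dev {asym:.3g})")
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    if m.min(initial=0.0) < 0.0:
        raise ValidationError("SC matrix has negative entries")
    return AdjacencyMatrix(m, "SC")


def select_state_pairs(
    bold: np.ndarray, n_pairs: int, rng: np.random.Generator
) -> list[StatePair]:
    """Draw initial/final state pairs from the BOLD series quartiles.

    The initial index is uniform over the first ``floor(T/4)`` time points
    and the final index uniform over the last ``floor(T/4)``; the states
    are the corresponding BOLD columns.
    """
    bold = np.asarray(bold, dtype=float)
    if n_pairs < 1:
        raise ConfigurationError("n_pairs must be at least 1")
    T = bold.shape[1]
    if T < 8:
        raise ConfigurationError(f"need T >= 8 time points, got {T}")
    q = T // 4
    t0s = rng.integers(0, q, size=n_pairs)
    tfs = rng.integers(T - q, T, size=n_pairs)
    return [
        StatePair(bold[:, t0].copy(), bold[:, tf].copy(), int(t0), int(tf))
        for t0, tf in zip(t0s, tfs)
    ]
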
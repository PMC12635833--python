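"""Average and modal controllability of the discrete-time connectome system.

After Schur normalization the symmetric system matrix A has all
eigenvalues strictly inside the unit circle, which admits closed-form
per-node controllability indices in terms of the eigendecomposition
A = V diag(lambda) V':

    AC_i = sum_j v_ij^2 / (1 - lambda_j^2)     (average controllability)
    MC_i = sum_j (1 - lambda_j^2) v_ij^2       (modal controllability)

AC_i measures how easily node i drives the system toward consolidated,
easy-to-reach states (for symmetric A it equals the i-th diagonal entry of
(I - A^2)^{-1}, so AC_i >= 1); MC_i measures node i's leverage on
fast-decaying, difficult-to-reach modes (0 < MC_i <= 1).  Network-level
features are means of the per-node values over a network's parcels; for a
dynamic (windowed) adjacency each window is Schur-normalized separately
and the per-window network means are aggregated across windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .connectivity import AdjacencyMatrix, AdjacencySequence
from .energy import ControlSet
from .errors import ConfigurationError, StabilityError
from .stabilize import StabilizedSystem, schur_normalize


@dataclass(frozen=True)
class SpectralDecomp:
    """Orthonormal eigendecomposition of a Schur-stable symmetric matrix."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    def __post_init__(self) -> None:
        if np.abs(self.eigenvalues).max(initial=0.0) >= 1.0:
            raise StabilityError(
                "spectral radius >= 1: the discrete-time system is not Schur stable"
            )


@dataclass(frozen=True)
class ControllabilityProfile:
    """Per-node and network-aggregated controllability values."""

    ac: np.ndarray
    mc: np.ndarray
    network_ac: float
    network_mc: float
    scenario: Optional[str] = None
    network: Optional[str] = None
    n_windows_averaged: int = 1


def spectral_decompose(S: StabilizedSystem) -> SpectralDecomp:
    """Eigendecomposition of a Schur-normalized (discrete-time) system."""
    if S.mode != "discrete":
        raise ConfigurationError("controllability indices require a discrete-time system")
    w, V = np.linalg.eigh((S.matrix + S.matrix.T) / 2.0)
    return SpectralDecomp(w, V)


def average_controllability(dec: SpectralDecomp, node: Optional[int] = None):
    """AC_i = sum_j v_ij^2 / (1 - lambda_j^2); vector if ``node`` is None."""
    denom = 1.0 - dec.eigenvalues**2
    ac = (dec.eigenvectors**2 / denom) @ np.ones_like(dec.eigenvalues)
    return ac if node is None else float(ac[node])


def modal_controllability(dec: SpectralDecomp, node: Optional[int] = None):
    """MC_i = sum_j (1 - lambda_j^2) v_ij^2; vector if ``node`` is None."""
    weight = 1.0 - dec.eigenvalues**2
    mc = (dec.eigenvectors**2) @ weight
    return mc if node is None else float(mc[node])


def _static_profile(S: StabilizedSystem) -> tuple:
    dec = spectral_decompose(S)
    return average_controllability(dec), modal_controllability(dec)


def network_controllability(
    system: Union[StabilizedSystem, AdjacencyMatrix, AdjacencySequence, Sequence],
    nodes: ControlSet,
    aggregation: str = "mean",
    scenario: Optional[str] = None,
) -> ControllabilityProfile:
    """Network-level AC/MC for a static system or a windowed sequence.

    ``system`` may be a discrete-time :class:`StabilizedSystem`, a raw
    :class:`AdjacencyMatrix` (Schur-normalized here), or an
    :class:`AdjacencySequence` / list of window matrices, in which case each
    window is normalized and the per-window network means are combined with
    ``aggregation`` ("mean" or "median") across the M windows.
    """
    if aggregation not in ("mean", "median"):
        raise ConfigurationError(f"unknown aggregation {aggregation!r}")
    reduce = np.mean if aggregation == "mean" else np.median
    idx = list(nodes.node_indices)

    if isinstance(system, AdjacencySequence):
        windows: Sequence = system.windows
        scenario = scenario or system.scenario
    elif isinstance(system, (StabilizedSystem, AdjacencyMatrix)):
        windows = [system]
    else:
        windows = list(system)

    per_window_ac, per_window_mc = [], []
    acs, mcs = [], []
    for win in windows:
        if isinstance(win, AdjacencyMatrix):
            if scenario is None:
                scenario = win.scenario
            win = schur_normalize(win)
        ac, mc = _static_profile(win)
        acs.append(ac)
        mcs.append(mc)
        per_window_ac.append(float(np.mean(ac[idx])))
        per_window_mc.append(float(np.mean(mc[idx])))

    return ControllabilityProfile(
        ac=np.asarray(reduce(np.stack(acs), axis=0)),
        mc=np.asarray(reduce(np.stack(mcs), axis=0)),
        network_ac=float(reduce(per_window_ac)),
        network_mc=float(reduce(per_window_mc)),
        scenario=scenario,
        network=nodes.name,
        n_windows_averaged=len(windows),
    )
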
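"""Graph-theoretic covariates: network strength and density.

These two classical network-graph-theory features enter the group
regressions as covariates, so that group effects on control-theoretic
features can be assessed over and above plain connectivity topology.
Strength is the mean (over the network's nodes) of the node strength, the
sum of absolute edge weights to all other nodes; density is the fraction
of suprathreshold within-network edges among all possible within-network
edges.
"""

from __future__ import annotations

from typing import Union

import numpy as np

from .connectivity import AdjacencyMatrix
from .energy import ControlSet
from .errors import ConfigurationError


def _values(A: Union[AdjacencyMatrix, np.ndarray]) -> np.ndarray:
    return A.values if isinstance(A, AdjacencyMatrix) else np.asarray(A, dtype=float)


def network_strength(A: Union[AdjacencyMatrix, np.ndarray], nodes: ControlSet) -> float:
    """Mean over the network's nodes of sum_j |A_ij| (j != i)."""
    a = _values(A)
    idx = list(nodes.node_indices)
    if len(idx) == 0:
        raise ConfigurationError("network strength needs a nonempty node set")
    strengths = np.abs(a[idx, :]).sum(axis=1) - np.abs(np.diagonal(a)[idx])
    return float(strengths.mean())


def network_density(
    A: Union[AdjacencyMatrix, np.ndarray], nodes: ControlSet, eps: float = 0.0
) -> float:
    """Fraction of within-network edges with |A_ij| > eps.

    Counts unordered node pairs inside the network; the denominator is
    k(k-1)/2 for k network nodes.
    """
    a = _values(A)
    idx = list(nodes.node_indices)
    k = len(idx)
    if k < 2:
        raise ConfigurationError("network density needs at least two nodes")
    block = np.abs(a[np.ix_(idx, idx)])
    iu = np.triu_indices(k, 1)
    return float((block[iu] > eps).sum() / (k * (k - 1) / 2))
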
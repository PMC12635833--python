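"""Minimum control energy of state transitions.

For the stabilized continuous-time system ``x' = A x + B u`` the minimum
energy needed to steer the state from ``x0`` at time 0 to ``xf`` at the
control horizon ``tau`` is

    E = 1/2 * d' W^+ d,        d = xf - expm(A tau) x0,

where ``W`` is the controllability Gramian restricted to the control node
set ``B`` and ``W^+`` its pseudo-inverse.  With a time-invariant adjacency
this is the *static* energy ``E_s``; when the adjacency is piecewise
constant over M windows (dynamic FC), the mismatch propagates through the
product of per-window propagators and the Gramian composes per window,

    d     = xf - expm(A_M tau_M) ... expm(A_1 tau_1) x0,
    W_dyn = sum_m P_m W_m P_m',    P_m = expm(A_M tau_M) ... expm(A_{m+1} tau_{m+1}),

giving the *dynamic* energy ``E_d``.  The Gramian itself is obtained from
the Lyapunov equation when the system is strictly stable, and from the
finite-horizon integral otherwise (the Laplacian normalization always
leaves a zero eigenvalue, so the pipeline's energies use the finite-horizon
form); for symmetric system matrices the integral has an exact spectral
closed form which is the default evaluation route.

Energies are summarized on the natural-log scale, and the dynamic energy
efficiency of a network is the ratio of static to dynamic log-energy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import scipy.integrate
import scipy.linalg

from .connectivity import AdjacencySequence, StatePair
from .errors import ConfigurationError, DegenerateInputError, NumericError
from .stabilize import StabilizedSystem, laplacian_normalize

#: relative eigenvalue cutoff for Gramian pseudo-inversion
DEFAULT_RCOND = 1e-8
#: an eigenvalue this close to zero makes the Lyapunov route unreliable
DEFAULT_EIGEN_TOL = 1e-8
#: relative projection residual above which a transition is flagged as
#: leaving the numerically controllable subspace
DEFAULT_SUBSPACE_TOL = 1e-6

EFFICIENCY_PAIRINGS = (("sFC", "dFC"), ("sFC_noneg", "dFC_noneg"), ("SC", "dFC"))


# ---------------------------------------------------------------------------
# control node sets


@dataclass(frozen=True)
class ControlSet:
    """An ordered set of control nodes and its selector matrix B.

    Column k of ``B`` is the indicator vector of ``node_indices[k]``: the
    K input channels inject energy directly and only into the selected
    nodes (one network's parcels in the connectome analyses).
    """

    node_indices: tuple
    n_nodes: int
    name: Optional[str] = None

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.node_indices)
        object.__setattr__(self, "node_indices", idx)
        if len(idx) == 0:
            raise ConfigurationError("control set must contain at least one node")
        if len(set(idx)) != len(idx):
            raise ConfigurationError("control node indices must be unique")
        if min(idx) < 0 or max(idx) >= self.n_nodes:
            raise ConfigurationError("control node index out of range")

    @property
    def k(self) -> int:
        return len(self.node_indices)

    def as_matrix(self) -> np.ndarray:
        """The N x K selector B with B[node_indices[k], k] = 1."""
        B = np.zeros((self.n_nodes, self.k))
        B[list(self.node_indices), np.arange(self.k)] = 1.0
        return B

    @classmethod
    def from_network(cls, scheme, network: str) -> "ControlSet":
        """Control set covering all nodes of one named network."""
        return cls(tuple(scheme.network_index[network]), scheme.n_nodes, name=network)

    @classmethod
    def all_nodes(cls, n_nodes: int) -> "ControlSet":
        return cls(tuple(range(n_nodes)), n_nodes, name="all")


# ---------------------------------------------------------------------------
# Gramians


@dataclass(frozen=True)
class GramianResult:
    """A controllability Gramian with provenance of its computation."""

    gramian: np.ndarray
    method: str  # "lyapunov" | "numeric_integral" | "finite_horizon"
    horizon: float  # np.inf for the Lyapunov solution
    effective_rank: int
    rcond_used: float


def _sym_eig(matrix: np.ndarray):
    return np.linalg.eigh((matrix + matrix.T) / 2.0)


def _expm_sym(eigvals: np.ndarray, eigvecs: np.ndarray, t: float) -> np.ndarray:
    """exp(A t) for symmetric A given its eigendecomposition."""
    return (eigvecs * np.exp(eigvals * t)) @ eigvecs.T


def propagator(S: StabilizedSystem, t: float) -> np.ndarray:
    """State-transition matrix exp(A t) of a stabilized system."""
    w, V = _sym_eig(S.matrix)
    return _expm_sym(w, V, t)


def _psd_pinv(W: np.ndarray, rcond: float):
    """Pseudo-inverse of a symmetric PSD matrix via eigendecomposition.

    Returns (pinv, effective rank, eigvals, eigvecs); eigenvalues below
    ``rcond * max(eig)`` are treated as zero.
    """
    w, V = _sym_eig(W)
    wmax = float(w.max(initial=0.0))
    if wmax <= 0.0:
        return np.zeros_like(W), 0, w, V
    keep = w > rcond * wmax
    inv = np.zeros_like(w)
    inv[keep] = 1.0 / w[keep]
    return (V * inv) @ V.T, int(keep.sum()), w, V


def gramian_lyapunov(
    S: StabilizedSystem,
    B: ControlSet,
    eigen_tol: float = DEFAULT_EIGEN_TOL,
    rcond: float = DEFAULT_RCOND,
) -> GramianResult:
    """Infinite-horizon Gramian from the Lyapunov equation A W + W A' + B B' = 0.

    Valid only when the system is strictly stable (all eigenvalues below
    ``-eigen_tol``); otherwise a :class:`DegenerateInputError` is raised so
    the caller can fall back to the finite-horizon integral.
    """
    if S.mode != "continuous":
        raise ConfigurationError("Lyapunov Gramian requires a continuous-time system")
    eig_max = float(np.linalg.eigvalsh(S.matrix).max())
    if eig_max > -eigen_tol:
        raise DegenerateInputError(
            f"largest eigenvalue {eig_max:.3e} is within {eigen_tol:.0e} of zero; "
            "use the finite-horizon integral Gramian instead"
        )
    Bm = B.as_matrix()
    W = scipy.linalg.solve_continuous_lyapunov(S.matrix, -Bm @ Bm.T)
    W = (W + W.T) / 2.0
    _, rank, _, _ = _psd_pinv(W, rcond)
    return GramianResult(W, "lyapunov", np.inf, rank, rcond)


def _gramian_spectral(S: StabilizedSystem, B: ControlSet, horizon: float) -> np.ndarray:
    """Exact finite-horizon Gramian of a symmetric system.

    With A = V diag(lam) V', the integral W(tau) = int_0^tau e^{At} BB' e^{A't} dt
    reduces entrywise in the eigenbasis to
    (V' B B' V)_jk * (exp((lam_j + lam_k) tau) - 1) / (lam_j + lam_k),
    with the ratio replaced by tau when lam_j + lam_k -> 0.
    """
    w, V = _sym_eig(S.matrix)
    G = V.T @ B.as_matrix()
    M = G @ G.T  # V' B B' V
    s = w[:, None] + w[None, :]
    small = np.abs(s) * horizon < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.expm1(s * horizon) / s
    K[small] = horizon
    W = V @ (M * K) @ V.T
    return (W + W.T) / 2.0


def _gramian_simpson(
    S: StabilizedSystem, B: ControlSet, horizon: float, tol: float = 1e-8
) -> np.ndarray:
    """Composite-Simpson finite-horizon Gramian with step-halving refinement."""
    w, V = _sym_eig(S.matrix)
    Bm = B.as_matrix()

    def integrand(t: float) -> np.ndarray:
        E = _expm_sym(w, V, t) @ Bm
        return E @ E.T

    n = 32
    prev = None
    for _ in range(12):
        ts = np.linspace(0.0, horizon, n + 1)
        vals = np.stack([integrand(t) for t in ts])
        h = horizon / n
        W = (h / 3.0) * (
            vals[0] + vals[-1] + 4.0 * vals[1:-1:2].sum(axis=0) + 2.0 * vals[2:-1:2].sum(axis=0)
        )
        if prev is not None:
            denom = max(np.linalg.norm(W), 1e-300)
            if np.linalg.norm(W - prev) / denom < tol:
                return (W + W.T) / 2.0
        prev = W
        n *= 2
    raise NumericError(
        f"Simpson Gramian failed to converge to {tol:g} relative at n={n} intervals"
    )


def gramian_numeric(
    S: StabilizedSystem,
    B: ControlSet,
    horizon: float,
    rcond: float = DEFAULT_RCOND,
    method: str = "spectral",
) -> GramianResult:
    """Finite-horizon Gramian W(tau) = int_0^tau e^{At} BB' e^{A't} dt.

    ``method="spectral"`` (default) evaluates the integral exactly through
    the eigendecomposition of the symmetric system matrix;
    ``method="simpson"`` uses composite Simpson quadrature with step
    halving until successive refinements agree to 1e-8 relative Frobenius
    norm (kept as an independent numerical cross-check).
    """
    if S.mode != "continuous":
        raise ConfigurationError("the integral Gramian requires a continuous-time system")
    if not horizon > 0.0:
        raise ConfigurationError("the Gramian horizon must be positive")
    if method == "spectral":
        W = _gramian_spectral(S, B, float(horizon))
    elif method == "simpson":
        W = _gramian_simpson(S, B, float(horizon))
    else:
        raise ConfigurationError(f"unknown Gramian method {method!r}")
    _, rank, _, _ = _psd_pinv(W, rcond)
    return GramianResult(W, "finite_horizon", float(horizon), rank, rcond)


# ---------------------------------------------------------------------------
# energies


@dataclass(frozen=True)
class EnergyResult:
    """A minimum-control-energy value with its provenance."""

    energy: float
    log_energy: float
    tau: float
    scenario: Optional[str] = None
    network: Optional[str] = None
    subject_id: Optional[str] = None
    d_vector: Optional[np.ndarray] = None
    gramian_method: Optional[str] = None
    effective_rank: Optional[int] = None
    projection_residual: float = 0.0


@dataclass(frozen=True)
class DynamicGramianParts:
    """Intermediate pieces of the composed dynamic Gramian (for validation)."""

    per_window_gramians: tuple
    composition: np.ndarray  # block row S: N x (N*M)
    wdyn: np.ndarray


@dataclass(frozen=True)
class DynamicOperator:
    """Precomputed chained propagator and composed Gramian of a window sequence.

    Both depend only on the windows, the control set and the horizon split,
    not on the state pair, so one operator serves many transitions.
    """

    chain: np.ndarray  # Phi_M ... Phi_1
    wdyn: np.ndarray
    tau: float
    taus: tuple
    parts: Optional[DynamicGramianParts] = None
    scenario: Optional[str] = None


def build_dynamic_operator(
    seq: Union[AdjacencySequence, Sequence[StabilizedSystem]],
    B: ControlSet,
    tau: float,
    taus: Optional[Sequence[float]] = None,
    scenario: Optional[str] = None,
    keep_parts: bool = False,
) -> DynamicOperator:
    """Chained propagator and composed Gramian for a piecewise-constant system.

    ``seq`` is an :class:`AdjacencySequence` (windows are Laplacian-normalized
    here) or a list of stabilized continuous-time window systems.  The
    horizon splits as ``taus`` (default tau/M per window); window m
    contributes its finite-horizon Gramian W_m propagated through the
    remaining windows:  W_dyn = sum_m P_m W_m P_m' with
    P_m = Phi_M ... Phi_{m+1}.
    """
    if isinstance(seq, AdjacencySequence):
        systems = [laplacian_normalize(w) for w in seq.windows]
        scenario = scenario or seq.scenario
    else:
        systems = list(seq)
        for s in systems:
            if s.mode != "continuous":
                raise ConfigurationError("dynamic energy requires continuous-time windows")
    M = len(systems)
    if M == 0:
        raise ConfigurationError("dynamic energy needs at least one window")
    if not tau > 0.0:
        raise ConfigurationError("control horizon tau must be positive")
    if taus is None:
        taus = [tau / M] * M
    taus = [float(t) for t in taus]
    if len(taus) != M:
        raise ConfigurationError(f"got {len(taus)} window horizons for {M} windows")

    n = systems[0].n_nodes
    phis = []
    grams = []
    for sys_m, tau_m in zip(systems, taus):
        w, V = _sym_eig(sys_m.matrix)
        phis.append(_expm_sym(w, V, tau_m))
        grams.append(_gramian_spectral(sys_m, B, tau_m))

    chain = np.eye(n)
    for phi in phis:
        chain = phi @ chain

    wdyn = np.zeros((n, n))
    blocks = [None] * M
    P = np.eye(n)
    for m in range(M - 1, -1, -1):
        blocks[m] = P.copy()
        wdyn += P @ grams[m] @ P.T
        P = P @ phis[m]
    wdyn = (wdyn + wdyn.T) / 2.0
    parts = (
        DynamicGramianParts(tuple(grams), np.hstack(blocks), wdyn) if keep_parts else None
    )
    return DynamicOperator(chain, wdyn, float(tau), tuple(taus), parts, scenario)


def _energy_from_gramian(
    W: np.ndarray, d: np.ndarray, rcond: float, subspace_tol: float
):
    Wpinv, rank, _, _ = _psd_pinv(W, rcond)
    e = 0.5 * float(d @ Wpinv @ d)
    e = max(e, 0.0)
    dnorm = float(np.linalg.norm(d))
    if dnorm > 0.0:
        residual = float(np.linalg.norm(d - W @ (Wpinv @ d))) / dnorm
        if residual > subspace_tol:
            # static message so repeated emissions deduplicate; the numeric
            # residual is recorded on the EnergyResult
            warnings.warn(
                "transition leaves the numerically controllable subspace; "
                "energy refers to the projected component (see projection_residual)",
                RuntimeWarning,
                stacklevel=3,
            )
    else:
        residual = 0.0
    return e, rank, residual


def static_energy(
    S: StabilizedSystem,
    B: ControlSet,
    pair: StatePair,
    tau: float,
    rcond: float = DEFAULT_RCOND,
    eigen_tol: float = DEFAULT_EIGEN_TOL,
    subspace_tol: float = DEFAULT_SUBSPACE_TOL,
    scenario: Optional[str] = None,
    network: Optional[str] = None,
    subject_id: Optional[str] = None,
    gramian: Optional[GramianResult] = None,
) -> EnergyResult:
    """Minimum energy of the transition x0 -> xf under a time-invariant A.

    Uses the infinite-horizon Lyapunov Gramian when the system is strictly
    stable and falls back to the finite-horizon integral Gramian when an
    eigenvalue sits within ``eigen_tol`` of zero (always the case after
    Laplacian normalization).  A precomputed ``gramian`` may be supplied to
    amortize the Gramian across many state pairs at the same horizon.
    """
    if S.mode != "continuous":
        raise ConfigurationError("static energy requires a continuous-time system")
    if not tau > 0.0:
        raise ConfigurationError("control horizon tau must be positive")
    if gramian is None:
        try:
            gramian = gramian_lyapunov(S, B, eigen_tol=eigen_tol, rcond=rcond)
        except DegenerateInputError:
            gramian = gramian_numeric(S, B, tau, rcond=rcond)
    d = pair.xf - propagator(S, tau) @ pair.x0
    e, rank, residual = _energy_from_gramian(gramian.gramian, d, rcond, subspace_tol)
    log_e = float(np.log(e)) if e > 0.0 else float("-inf")
    return EnergyResult(
        e, log_e, float(tau), scenario, network or B.name, subject_id, d,
        gramian.method, rank, residual,
    )


def dynamic_energy(
    seq: Union[AdjacencySequence, Sequence[StabilizedSystem], None],
    B: ControlSet,
    pair: StatePair,
    tau: float,
    taus: Optional[Sequence[float]] = None,
    rcond: float = DEFAULT_RCOND,
    subspace_tol: float = DEFAULT_SUBSPACE_TOL,
    scenario: Optional[str] = None,
    network: Optional[str] = None,
    subject_id: Optional[str] = None,
    operator: Optional[DynamicOperator] = None,
    return_parts: bool = False,
):
    """Minimum energy under a piecewise-constant (windowed) adjacency.

    ``seq`` is either an :class:`AdjacencySequence` (each window is then
    Laplacian-normalized here) or a list of already-stabilized
    continuous-time systems, one per window.  The horizon ``tau`` is split
    across the M windows as ``taus`` (default: tau/M each).  A
    precomputed ``operator`` (see :func:`build_dynamic_operator`) may be
    supplied to amortize the composed Gramian over many state pairs.
    """
    if operator is None:
        if seq is None:
            raise ConfigurationError("provide either a window sequence or an operator")
        operator = build_dynamic_operator(
            seq, B, tau, taus=taus, scenario=scenario, keep_parts=return_parts
        )
    elif operator.tau != float(tau):
        raise ConfigurationError("operator was built for a different horizon tau")
    scenario = scenario or operator.scenario
    d = pair.xf - operator.chain @ pair.x0
    e, rank, residual = _energy_from_gramian(operator.wdyn, d, rcond, subspace_tol)
    log_e = float(np.log(e)) if e > 0.0 else float("-inf")
    result = EnergyResult(
        e, log_e, float(tau), scenario, network or B.name, subject_id, d,
        "finite_horizon", rank, residual,
    )
    if return_parts:
        return result, operator.parts
    return result


def efficiency_ratio(static: EnergyResult, dynamic: EnergyResult) -> float:
    """Dynamic energy efficiency: log-E(static scenario) / log-E(dynamic scenario).

    Valid pairings are (sFC, dFC), (sFC_noneg, dFC_noneg) and (SC, dFC);
    both results must share the control horizon (and subject/network where
    recorded).
    """
    if (static.scenario, dynamic.scenario) not in EFFICIENCY_PAIRINGS:
        raise ConfigurationError(
            f"invalid efficiency pairing ({static.scenario}, {dynamic.scenario}); "
            f"expected one of {EFFICIENCY_PAIRINGS}"
        )
    if static.tau != dynamic.tau:
        raise ConfigurationError("efficiency ratio requires matching control horizons")
    for attr in ("subject_id", "network"):
        a, b = getattr(static, attr), getattr(dynamic, attr)
        if a is not None and b is not None and a != b:
            raise ConfigurationError(f"efficiency ratio requires matching {attr}")
    if dynamic.log_energy == 0.0:
        raise DegenerateInputError("dynamic log-energy is zero; ratio undefined")
    return static.log_energy / dynamic.log_energy


# ---------------------------------------------------------------------------
# validation of the optimal-control solution


@dataclass(frozen=True)
class OptimalControlReport:
    """Simulation check of the closed-form minimum-energy input."""

    terminal_residual: float
    controllable_residual: float
    input_energy: float
    energy: float
    relative_energy_mismatch: float
    effective_rank: int
    rank_deficient: bool


def verify_optimal_control(
    S: StabilizedSystem,
    B: ControlSet,
    pair: StatePair,
    tau: float,
    energy: EnergyResult,
    rcond: float = DEFAULT_RCOND,
    n_grid: int = 2001,
) -> OptimalControlReport:
    """Reconstruct u*(t) and simulate the closed loop to validate an energy.

    The finite-horizon minimum-energy input u*(t) = B' e^{A'(tau-t)} W+ d is
    evaluated on a dense grid, the state equation x' = A x + B u* is
    integrated from x0, and the report compares the terminal state with xf
    (both raw and projected on the numerically controllable subspace) and
    the realized input energy 1/2 int ||u||^2 dt with the stored energy
    value.
    """
    w, V = _sym_eig(S.matrix)
    Bm = B.as_matrix()
    W = _gramian_spectral(S, B, float(tau))
    Wpinv, rank, eigs, eigvecs = _psd_pinv(W, rcond)
    d = pair.xf - _expm_sym(w, V, tau) @ pair.x0
    z = Wpinv @ d

    def u_star(t: float) -> np.ndarray:
        return Bm.T @ (_expm_sym(w, V, tau - t) @ z)

    ts = np.linspace(0.0, float(tau), n_grid)
    us = np.stack([u_star(t) for t in ts])
    input_energy = 0.5 * float(scipy.integrate.simpson((us**2).sum(axis=1), x=ts))

    sol = scipy.integrate.solve_ivp(
        lambda t, x: S.matrix @ x + Bm @ u_star(t),
        (0.0, float(tau)),
        pair.x0,
        rtol=1e-10,
        atol=1e-12,
        dense_output=False,
    )
    if not sol.success:
        raise NumericError(f"state simulation failed: {sol.message}")
    x_end = sol.y[:, -1]
    r = x_end - pair.xf
    keep = eigs > rcond * max(float(eigs.max(initial=0.0)), 1e-300)
    proj = eigvecs[:, keep]
    controllable_residual = float(np.linalg.norm(proj.T @ r))
    mismatch = abs(input_energy - energy.energy) / max(abs(energy.energy), 1e-300)
    return OptimalControlReport(
        terminal_residual=float(np.linalg.norm(r)),
        controllable_residual=controllable_residual,
        input_energy=input_energy,
        energy=energy.energy,
        relative_energy_mismatch=mismatch,
        effective_rank=rank,
        rank_deficient=rank < S.n_nodes,
    )
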
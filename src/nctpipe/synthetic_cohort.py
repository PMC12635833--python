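"""Synthetic parcellated connectome cohorts.

Generates per-subject data with the statistical structure the downstream
analyses assume, so the whole pipeline can be exercised without any
neuroimaging download:

* a parcellation of N cortical nodes into the seven canonical large-scale
  resting-state networks (default 200 nodes),
* regional BOLD time series from a vector AR(1) process whose stationary
  correlation is a network-block matrix (higher within- than
  between-network correlation, per-subject block perturbations, and an
  optional group shift concentrated in one network's block),
* a structural connectome from exponential decay of latent inter-node
  distances (heavy-tailed nonnegative weights, symmetric, zero diagonal),
* subject metadata (age, sex, and per-ear hearing scores PTA/SRT) drawn
  from group-specific distributions, with elevated hearing thresholds in
  the hearing-loss group.

Everything is driven by a single seed and is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .connectivity import AdjacencyMatrix, ingest_sc
from .errors import ConfigurationError, NumericError

#: Node counts per canonical network for the default 200-node parcellation
#: (visual, somato-motor, dorsal attention, salience/ventral attention,
#: limbic, fronto-parietal control, default mode).
SEVEN_NETWORKS: Mapping[str, int] = {
    "VIS": 30,
    "SMN": 34,
    "DAN": 26,
    "SAL": 24,
    "LIM": 14,
    "FPN": 26,
    "DMN": 46,
}

_PSD_TOL = 1e-10


@dataclass(frozen=True)
class ParcelScheme:
    """Assignment of nodes to named large-scale networks."""

    n_nodes: int
    network_labels: tuple
    network_index: Mapping[str, tuple]

    @property
    def networks(self) -> tuple:
        return tuple(self.network_index.keys())


def make_parcellation(n_nodes: int, networks: Mapping[str, int]) -> ParcelScheme:
    """Deterministic parcellation with contiguous index blocks per network.

    ``networks`` maps network name to block size; sizes must sum to
    ``n_nodes`` and every network must receive at least one node.
    """
    sizes = {str(k): int(v) for k, v in networks.items()}
    if any(v < 1 for v in sizes.values()):
        raise ConfigurationError("every network needs at least one node")
    total = sum(sizes.values())
    if total != n_nodes:
        raise ConfigurationError(
            f"network sizes sum to {total}, expected n_nodes={n_nodes}"
        )
    labels: list = []
    index: dict = {}
    start = 0
    for name, size in sizes.items():
        index[name] = tuple(range(start, start + size))
        labels.extend([name] * size)
        start += size
    return ParcelScheme(n_nodes, tuple(labels), index)


def default_parcellation() -> ParcelScheme:
    """The 200-node, seven-network scheme used throughout."""
    return make_parcellation(200, SEVEN_NETWORKS)


@dataclass(frozen=True)
class GroupProfile:
    """Metadata-generating distributions for one subject group."""

    age_range: tuple = (48.0, 72.0)
    male_fraction: float = 0.33
    pta_mean: float = 15.0
    pta_sd: float = 5.0
    srt_mean: float = 12.0
    srt_sd: float = 6.0


#: Normal-hearing vs hearing-loss profiles: the HL group is older on
#: average and has markedly elevated pure-tone and speech thresholds.
DEFAULT_GROUP_PROFILES: Mapping[str, GroupProfile] = {
    "NH": GroupProfile((48.0, 72.0), 0.33, 15.0, 5.0, 12.0, 6.0),
    "HL": GroupProfile((52.0, 76.0), 0.69, 50.0, 14.0, 39.0, 22.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    ``within_network_corr`` / ``between_network_corr`` set the baseline
    block-correlation structure of the BOLD process; ``subject_sd``
    perturbs each network-pair block per subject; ``group_effect`` is an
    additive shift of the affected network's within-block correlation,
    applied only in the affected group (negative = reduced connectivity).
    ``ar_coeff`` sets the lag-1 temporal autocorrelation and ``noise_sd``
    an optional white observation-noise scale on top of the latent
    process.

    The temporal nonstationarity that sliding-window connectivity is
    meant to capture is emulated by ``n_states`` latent connectivity
    states per subject (block levels re-perturbed with ``state_corr_sd``)
    visited by a Markov chain with mean dwell time
    ``state_dwell_seconds``; ``n_states=1`` (or ``state_corr_sd=0``)
    recovers a stationary process.  ``bold_amplitude`` scales the
    unit-variance fluctuations to a realistic regional-residual intensity
    (arbitrary scanner units); correlations are unaffected by it.
    """

    n_subjects_per_group: int = 15
    tr_seconds: float = 2.0
    n_timepoints: int = 400
    within_network_corr: float = 0.45
    between_network_corr: float = 0.20
    subject_sd: float = 0.03
    group_effect: float = -0.06
    affected_network: str = "DMN"
    affected_group: str = "HL"
    groups: tuple = ("NH", "HL")
    ar_coeff: float = 0.4
    noise_sd: float = 0.0
    n_states: int = 3
    state_dwell_seconds: float = 40.0
    state_corr_sd: float = 0.05
    bold_amplitude: float = 20.0
    sc_decay_length: float = 0.35
    sc_scale: float = 100.0
    sc_noise_sd: float = 0.30
    group_profiles: Mapping[str, GroupProfile] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PROFILES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("within_network_corr", "between_network_corr"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ConfigurationError(f"{name}={v} must lie in (-1, 1)")
        if not -1.0 < self.ar_coeff < 1.0:
            raise ConfigurationError("ar_coeff must lie in (-1, 1)")
        if self.n_timepoints < 8:
            raise ConfigurationError("n_timepoints must be at least 8")
        if self.affected_group not in self.groups:
            raise ConfigurationError(
                f"affected_group {self.affected_group!r} not in groups {self.groups}"
            )


@dataclass(frozen=True)
class SubjectData:
    """One synthetic subject: connectomes plus metadata."""

    subject_id: str
    group: str
    age: float
    sex: str
    pta_left: float
    pta_right: float
    srt_left: float
    srt_right: float
    sc: AdjacencyMatrix
    bold: np.ndarray

    def metadata_row(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "group": self.group,
            "age": self.age,
            "sex": self.sex,
            "pta_left": self.pta_left,
            "pta_right": self.pta_right,
            "srt_left": self.srt_left,
            "srt_right": self.srt_right,
        }


def nearest_psd_correlation(C: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone and restore unit diagonal.

    Eigenvalues are clipped at zero and the result rescaled to a
    correlation matrix (congruence with a positive diagonal preserves
    positive semidefiniteness).
    """
    C = (C + C.T) / 2.0
    w, V = np.linalg.eigh(C)
    C = (V * np.clip(w, 0.0, None)) @ V.T
    d = np.sqrt(np.clip(np.diagonal(C), 1e-12, None))
    C = C / np.outer(d, d)
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    if np.linalg.eigvalsh(C).min() < -_PSD_TOL:
        raise NumericError("nearest-PSD repair failed to produce a PSD correlation")
    return C


def _subject_block_levels(
    scheme: ParcelScheme, spec: CohortSpec, group: str, rng: np.random.Generator
) -> dict:
    """Per-subject correlation level of every unordered network-pair block."""
    nets = scheme.networks
    levels = {}
    for i, p in enumerate(nets):
        for q in nets[i:]:
            base = spec.within_network_corr if p == q else spec.between_network_corr
            levels[(p, q)] = base + rng.normal(0.0, spec.subject_sd)
    if group == spec.affected_group and spec.affected_network in nets:
        key = (spec.affected_network, spec.affected_network)
        levels[key] = levels[key] + spec.group_effect
    return levels


def _levels_to_correlation(scheme: ParcelScheme, levels: Mapping) -> np.ndarray:
    nets = scheme.networks
    C = np.empty((scheme.n_nodes, scheme.n_nodes))
    for i, p in enumerate(nets):
        for q in nets[i:]:
            level = np.clip(levels[(p, q)], -0.95, 0.95)
            C[np.ix_(scheme.network_index[p], scheme.network_index[q])] = level
            C[np.ix_(scheme.network_index[q], scheme.network_index[p])] = level
    np.fill_diagonal(C, 1.0)
    return nearest_psd_correlation(C)


def _target_correlation(
    scheme: ParcelScheme, spec: CohortSpec, group: str, rng: np.random.Generator
) -> np.ndarray:
    """The subject's baseline block correlation (average over latent states)."""
    return _levels_to_correlation(scheme, _subject_block_levels(scheme, spec, group, rng))


def _simulate_bold(
    scheme: ParcelScheme,
    spec: CohortSpec,
    group: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Preprocessed regional BOLD: regime-switching zero-mean AR(1).

    The subject's baseline block correlation (see
    :func:`_subject_block_levels`) defines ``n_states`` latent
    connectivity states by re-perturbing each block level with
    ``state_corr_sd``; a Markov chain with mean dwell
    ``state_dwell_seconds`` selects the active state, and the fluctuation
    follows an AR(1) whose innovation covariance matches the active
    state's correlation.  Within a state the stationary correlation
    equals that state's block matrix with lag-1 autocorrelation
    ``ar_coeff``; the full-series correlation approaches the across-state
    average.  The output is scaled by ``bold_amplitude`` (arbitrary
    units), emulating nuisance-regressed, demeaned regional time courses.
    """
    n = scheme.n_nodes
    levels = _subject_block_levels(scheme, spec, group, rng)
    n_states = max(1, int(spec.n_states))
    factors = []
    for _ in range(n_states):
        if n_states == 1 or spec.state_corr_sd == 0.0:
            state_levels = levels
        else:
            state_levels = {
                k: v + rng.normal(0.0, spec.state_corr_sd) for k, v in levels.items()
            }
        Cs = _levels_to_correlation(scheme, state_levels)
        w, V = np.linalg.eigh(Cs)
        factors.append(V * np.sqrt(np.clip(w, 0.0, None)))  # C_s = F F'

    dwell_samples = max(1.0, spec.state_dwell_seconds / spec.tr_seconds)
    p_stay = 1.0 - 1.0 / dwell_samples
    phi = spec.ar_coeff
    innov_scale = np.sqrt(1.0 - phi**2)
    state = int(rng.integers(n_states))
    x = factors[state] @ rng.standard_normal(n)  # start at in-state stationarity
    bold = np.empty((n, spec.n_timepoints))
    for t in range(spec.n_timepoints):
        bold[:, t] = x
        if n_states > 1 and rng.uniform() > p_stay:
            others = [s for s in range(n_states) if s != state]
            state = others[int(rng.integers(len(others)))]
        x = phi * x + innov_scale * (factors[state] @ rng.standard_normal(n))
    if spec.noise_sd > 0.0:
        bold = bold + spec.noise_sd * rng.standard_normal(bold.shape)
    bold = spec.bold_amplitude * bold
    if np.any(bold.std(axis=1) == 0.0):
        raise NumericError("simulated BOLD produced a constant node time course")
    return bold


def _simulate_sc(
    scheme: ParcelScheme, spec: CohortSpec, rng: np.random.Generator
) -> AdjacencyMatrix:
    """Exponential distance decay on latent coordinates, log-normal edge noise."""
    coords = rng.uniform(0.0, 1.0, size=(scheme.n_nodes, 3))
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    weights = spec.sc_scale * np.exp(-dist / spec.sc_decay_length)
    noise = rng.normal(0.0, spec.sc_noise_sd, size=dist.shape)
    noise = (noise + noise.T) / 2.0
    weights = weights * np.exp(noise)
    np.fill_diagonal(weights, 0.0)
    return ingest_sc(weights)


def simulate_subject(
    scheme: ParcelScheme,
    spec: CohortSpec,
    group: str,
    rng: np.random.Generator,
    subject_id: Optional[str] = None,
) -> SubjectData:
    """Generate one subject's SC, BOLD and metadata.

    The BOLD series is a zero-mean vector AR(1) whose stationary
    correlation equals the subject's (PSD-repaired) block target; the
    structural connectome and the metadata are drawn from the group's
    distributions.  All randomness comes from ``rng``.
    """
    if group not in spec.groups:
        raise ConfigurationError(f"unknown group {group!r}; expected one of {spec.groups}")
    profile = spec.group_profiles.get(group, GroupProfile())
    bold = _simulate_bold(scheme, spec, group, rng)
    sc = _simulate_sc(scheme, spec, rng)
    age = float(rng.uniform(*profile.age_range))
    sex = "M" if rng.uniform() < profile.male_fraction else "F"
    pta = np.clip(rng.normal(profile.pta_mean, profile.pta_sd, size=2), 0.0, None)
    srt = np.clip(rng.normal(profile.srt_mean, profile.srt_sd, size=2), 0.0, None)
    return SubjectData(
        subject_id=subject_id or f"sub-{group}",
        group=group,
        age=age,
        sex=sex,
        pta_left=float(pta[0]),
        pta_right=float(pta[1]),
        srt_left=float(srt[0]),
        srt_right=float(srt[1]),
        sc=sc,
        bold=bold,
    )


def simulate_cohort(
    scheme: ParcelScheme, spec: CohortSpec
) -> tuple[list[SubjectData], pd.DataFrame]:
    """Generate ``n_subjects_per_group`` subjects per group plus a metadata table."""
    rng = np.random.default_rng(spec.seed)
    subjects: list[SubjectData] = []
    for group in spec.groups:
        for i in range(spec.n_subjects_per_group):
            sid = f"sub-{group}{i + 1:02d}"
            subjects.append(simulate_subject(scheme, spec, group, rng, subject_id=sid))
    metadata = pd.DataFrame([s.metadata_row() for s in subjects])
    return subjects, metadata


# ---------------------------------------------------------------------------
# cohort I/O (tab-separated text files)


def write_cohort(
    subjects: Sequence[SubjectData],
    metadata: pd.DataFrame,
    scheme: ParcelScheme,
    outdir: Path,
) -> None:
    """Write per-subject SC/BOLD matrices, the metadata table and the parcellation."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        np.savetxt(outdir / f"{s.subject_id}_sc.tsv", s.sc.values, delimiter="\t", fmt="%.8g")
        np.savetxt(outdir / f"{s.subject_id}_bold.tsv", s.bold, delimiter="\t", fmt="%.8g")
    metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    parc = pd.DataFrame(
        {"node_id": np.arange(scheme.n_nodes), "network": scheme.network_labels}
    )
    parc.to_csv(outdir / "parcellation.tsv", sep="\t", index=False)


def load_cohort(cohort_dir: Path) -> tuple[list[SubjectData], pd.DataFrame, ParcelScheme]:
    """Read a cohort directory written by :func:`write_cohort`."""
    cohort_dir = Path(cohort_dir)
    meta_path = cohort_dir / "metadata.tsv"
    parc_path = cohort_dir / "parcellation.tsv"
    for p in (meta_path, parc_path):
        if not p.exists():
            raise ConfigurationError(f"missing cohort file: {p}")
    metadata = pd.read_csv(meta_path, sep="\t")
    parc = pd.read_csv(parc_path, sep="\t")
    labels = tuple(parc.sort_values("node_id")["network"])
    index: dict = {}
    for i, name in enumerate(labels):
        index.setdefault(name, []).append(i)
    scheme = ParcelScheme(len(labels), labels, {k: tuple(v) for k, v in index.items()})
    subjects = []
    for row in metadata.itertuples(index=False):
        sid = row.subject_id
        sc_path = cohort_dir / f"{sid}_sc.tsv"
        bold_path = cohort_dir / f"{sid}_bold.tsv"
        for p in (sc_path, bold_path):
            if not p.exists():
                raise ConfigurationError(f"missing cohort file: {p}")
        subjects.append(
            SubjectData(
                subject_id=sid,
                group=row.group,
                age=float(row.age),
                sex=row.sex,
                pta_left=float(row.pta_left),
                pta_right=float(row.pta_right),
                srt_left=float(row.srt_left),
                srt_right=float(row.srt_right),
                sc=ingest_sc(np.loadtxt(sc_path, delimiter="\t")),
                bold=np.loadtxt(bold_path, delimiter="\t"),
            )
        )
    return subjects, metadata, scheme
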
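"""Orchestration of the two connectome experiments, configuration and CLI.

The pipeline ties the stages together:

1. *simulate* — generate a synthetic cohort (or point the config at an
   existing directory of ``*_sc.tsv`` / ``*_bold.tsv`` files),
2. *intra* — repeated-state-pair energy simulations for a few subjects,
   summarized as intra-individual CoV tables per scenario, control time
   and window size,
3. *inter* — one shared state pair across all subjects; log-energies,
   efficiency ratios, average/modal controllability and the graph
   covariates per scenario and network, followed by the group-level
   statistics (CoV, OLS group effects, AUC, Spearman, FDR).

Every run is reproducible from (config, seed); the run log records the
configuration hash, seed and package version alongside the per-cell
Gramian bookkeeping.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_stats import intra_cov_table, intra_individual_analysis, inter_individual_analysis
from .connectivity import (
    SCENARIOS,
    AdjacencyMatrix,
    AdjacencySequence,
    StatePair,
    compute_dfc,
    compute_sfc,
    select_state_pairs,
)
from .controllability import network_controllability
from .energy import (
    ControlSet,
    EnergyResult,
    build_dynamic_operator,
    dynamic_energy,
    efficiency_ratio,
    gramian_lyapunov,
    gramian_numeric,
    static_energy,
)
from .errors import ConfigurationError, DegenerateInputError
from .graph_metrics import network_density, network_strength
from .stabilize import certify, laplacian_normalize
from .synthetic_cohort import (
    CohortSpec,
    ParcelScheme,
    SubjectData,
    default_parcellation,
    load_cohort,
    simulate_cohort,
    write_cohort,
)

logger = logging.getLogger("nctpipe")

DEFAULT_TAU_GRID = tuple(range(10, 400, 20))
HEADLINE_TAUS = (30.0, 50.0, 100.0, 200.0)
WINDOW_SIZES_SECONDS = (30.0, 50.0, 100.0)
HEADLINE_WINDOW_SECONDS = 50.0

EFFICIENCY_FEATURES = {
    "efficiency_sFC_dFC": ("sFC", "dFC"),
    "efficiency_sFCnn_dFCnn": ("sFC_noneg", "dFC_noneg"),
    "efficiency_SC_dFC": ("SC", "dFC"),
}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a pipeline run (defaults mirror the study settings)."""

    cohort_dir: Optional[str] = None
    output_dir: str = "nctpipe_out"
    scenarios: tuple = SCENARIOS
    networks: tuple = ("DMN", "VIS", "SMN")
    tau_grid: tuple = DEFAULT_TAU_GRID
    headline_taus: tuple = HEADLINE_TAUS
    window_seconds: tuple = WINDOW_SIZES_SECONDS
    headline_window: float = HEADLINE_WINDOW_SECONDS
    tr_seconds: float = 2.0
    n_state_pairs: int = 20
    n_intra_subjects: int = 5
    intra_group: str = "NH"
    patient_group: str = "HL"
    seed: int = 0
    rcond: float = 1e-8
    eigen_tol: float = 1e-8
    aggregation: str = "mean"
    cohort: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [s for s in self.scenarios if s not in SCENARIOS]
        if bad:
            raise ConfigurationError(f"unknown scenarios {bad}; valid: {list(SCENARIOS)}")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        for key in ("scenarios", "networks", "tau_grid", "headline_taus", "window_seconds"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def cohort_spec(self) -> CohortSpec:
        spec = CohortSpec(**dict(self.cohort))
        if "seed" not in self.cohort:
            spec = replace(spec, seed=self.seed)
        return spec

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _log_run(outdir: Path, config: RunConfig, what: str) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "run_log.txt", "a") as fh:
        fh.write(
            f"nctpipe {__version__} | {what} | seed={config.seed} "
            f"| config_hash={config.digest()}\n"
        )


def _resolve_cohort(
    config: RunConfig,
    subjects: Optional[Sequence[SubjectData]] = None,
    scheme: Optional[ParcelScheme] = None,
):
    """Use in-memory subjects, else load from cohort_dir, else simulate."""
    if subjects is not None:
        if scheme is None:
            raise ConfigurationError("scheme must accompany in-memory subjects")
        metadata = pd.DataFrame([s.metadata_row() for s in subjects])
        return list(subjects), metadata, scheme
    if config.cohort_dir is not None and Path(config.cohort_dir).exists():
        return load_cohort(Path(config.cohort_dir))
    scheme = default_parcellation()
    subjects, metadata = simulate_cohort(scheme, config.cohort_spec())
    return subjects, metadata, scheme


# ---------------------------------------------------------------------------
# per-subject feature extraction


def build_scenarios(
    subject: SubjectData,
    window_seconds: float,
    tr_seconds: float,
    scenarios: Sequence[str] = SCENARIOS,
) -> dict:
    """The five adjacency scenarios for one subject at one window size."""
    out: dict = {}
    for s in scenarios:
        if s == "SC":
            out[s] = subject.sc
        elif s == "sFC":
            out[s] = compute_sfc(subject.bold, zero_negatives=False)
        elif s == "sFC_noneg":
            out[s] = compute_sfc(subject.bold, zero_negatives=True)
        elif s == "dFC":
            out[s] = compute_dfc(subject.bold, window_seconds, tr_seconds, False)
        elif s == "dFC_noneg":
            out[s] = compute_dfc(subject.bold, window_seconds, tr_seconds, True)
        else:
            raise ConfigurationError(f"unknown scenario {s!r}")
    return out


def subject_energy_rows(
    subject: SubjectData,
    scheme: ParcelScheme,
    pairs: Sequence[StatePair],
    networks: Sequence[str],
    taus: Sequence[float],
    window_seconds: float,
    tr_seconds: float,
    scenarios: Sequence[str] = SCENARIOS,
    rcond: float = 1e-8,
    eigen_tol: float = 1e-8,
) -> list[dict]:
    """Energies for every (network, scenario, tau, state pair) cell.

    Static scenarios share one Gramian per (network, tau); dynamic
    scenarios share one composed operator per (network, tau), so the cost
    is independent of the number of state pairs.
    """
    scen_objs = build_scenarios(subject, window_seconds, tr_seconds, scenarios)
    rows: list[dict] = []
    for network in networks:
        B = ControlSet.from_network(scheme, network)
        for name, obj in scen_objs.items():
            if isinstance(obj, AdjacencyMatrix):
                system = laplacian_normalize(obj)
                report = certify(system)
                if not report.passed:
                    logger.warning(
                        "scenario %s (%s): continuous system margin %.3g",
                        name, subject.subject_id, report.margin,
                    )
                for tau in taus:
                    try:
                        gram = gramian_lyapunov(system, B, eigen_tol=eigen_tol, rcond=rcond)
                    except DegenerateInputError:
                        gram = gramian_numeric(system, B, tau, rcond=rcond)
                    for k, pair in enumerate(pairs):
                        res = static_energy(
                            system, B, pair, tau, rcond=rcond, eigen_tol=eigen_tol,
                            scenario=name, network=network,
                            subject_id=subject.subject_id, gramian=gram,
                        )
                        rows.append(_energy_row(res, k, window_seconds))
            else:
                windows = [laplacian_normalize(w) for w in obj.windows]
                for tau in taus:
                    op = build_dynamic_operator(windows, B, tau, scenario=name)
                    for k, pair in enumerate(pairs):
                        res = dynamic_energy(
                            None, B, pair, tau, rcond=rcond, scenario=name,
                            network=network, subject_id=subject.subject_id,
                            operator=op,
                        )
                        rows.append(_energy_row(res, k, window_seconds))
    return rows


def _energy_row(res: EnergyResult, pair_index: int, window_seconds: float) -> dict:
    return {
        "subject_id": res.subject_id,
        "scenario": res.scenario,
        "network": res.network,
        "tau": res.tau,
        "window_seconds": window_seconds,
        "pair_index": pair_index,
        "energy": res.energy,
        "log_energy": res.log_energy,
        "effective_rank": res.effective_rank,
        "gramian_method": res.gramian_method,
    }


def subject_feature_rows(
    subject: SubjectData,
    scheme: ParcelScheme,
    pair: StatePair,
    networks: Sequence[str],
    taus: Sequence[float],
    window_seconds: float,
    tr_seconds: float,
    scenarios: Sequence[str] = SCENARIOS,
    rcond: float = 1e-8,
    eigen_tol: float = 1e-8,
    aggregation: str = "mean",
) -> list[dict]:
    """All inter-individual features for one subject at one window size.

    Emits long-format rows (subject, feature, scenario, network, tau,
    window, value) covering log-energies, the three dynamic-efficiency
    ratios, network AC/MC, and the strength/density covariates.
    """
    energy_rows = subject_energy_rows(
        subject, scheme, [pair], networks, taus, window_seconds, tr_seconds,
        scenarios, rcond, eigen_tol,
    )
    rows: list[dict] = []
    by_key: dict = {}
    for r in energy_rows:
        by_key[(r["scenario"], r["network"], r["tau"])] = r
        rows.append(
            _feature_row(subject, "log_energy", r["scenario"], r["network"],
                         r["tau"], window_seconds, r["log_energy"])
        )
    for feat, (stat_s, dyn_s) in EFFICIENCY_FEATURES.items():
        if stat_s not in scenarios or dyn_s not in scenarios:
            continue
        for network in networks:
            for tau in taus:
                s_row = by_key[(stat_s, network, float(tau))]
                d_row = by_key[(dyn_s, network, float(tau))]
                s_res = EnergyResult(
                    s_row["energy"], s_row["log_energy"], float(tau), stat_s, network
                )
                d_res = EnergyResult(
                    d_row["energy"], d_row["log_energy"], float(tau), dyn_s, network
                )
                rows.append(
                    _feature_row(subject, feat, f"{stat_s}/{dyn_s}", network,
                                 tau, window_seconds, efficiency_ratio(s_res, d_res))
                )

    scen_objs = build_scenarios(subject, window_seconds, tr_seconds, scenarios)
    for network in networks:
        B = ControlSet.from_network(scheme, network)
        for name, obj in scen_objs.items():
            prof = network_controllability(obj, B, aggregation=aggregation, scenario=name)
            rows.append(_feature_row(subject, "network_ac", name, network,
                                     np.nan, window_seconds, prof.network_ac))
            rows.append(_feature_row(subject, "network_mc", name, network,
                                     np.nan, window_seconds, prof.network_mc))
            if isinstance(obj, AdjacencySequence):
                strength = float(np.mean([network_strength(w, B) for w in obj.windows]))
                density = float(np.mean([network_density(w, B) for w in obj.windows]))
            else:
                strength = network_strength(obj, B)
                density = network_density(obj, B)
            rows.append(_feature_row(subject, "network_strength", name, network,
                                     np.nan, window_seconds, strength))
            rows.append(_feature_row(subject, "network_density", name, network,
                                     np.nan, window_seconds, density))
    return rows


def _feature_row(subject, feature, scenario, network, tau, window_seconds, value):
    return {
        "subject_id": subject.subject_id,
        "feature": feature,
        "scenario": scenario,
        "network": network,
        "tau": tau,
        "window_seconds": window_seconds,
        "value": value,
    }


# ---------------------------------------------------------------------------
# experiments


def run_intra(
    config: RunConfig,
    subjects: Optional[Sequence[SubjectData]] = None,
    scheme: Optional[ParcelScheme] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Intra-individual experiment: energy CoV across repeated state pairs.

    For ``n_intra_subjects`` subjects of the reference group, energies are
    computed for all scenario x tau x window cells across
    ``n_state_pairs`` random initial/final pairs, and the CoV of the
    log-energy per cell is averaged across subjects.  Returns the
    long-format energy table and the CoV summary; both are written to the
    output directory.
    """
    subjects, _, scheme = _resolve_cohort(config, subjects, scheme)
    chosen = [s for s in subjects if s.group == config.intra_group][: config.n_intra_subjects]
    if not chosen:
        raise ConfigurationError(f"no subjects in group {config.intra_group!r}")
    rng = np.random.default_rng(config.seed)
    all_rows: list[dict] = []
    for subject in chosen:
        pairs = select_state_pairs(subject.bold, config.n_state_pairs, rng)
        for window in config.window_seconds:
            all_rows.extend(
                subject_energy_rows(
                    subject, scheme, pairs, config.networks, config.headline_taus,
                    window, config.tr_seconds, config.scenarios,
                    config.rcond, config.eigen_tol,
                )
            )
    energies = pd.DataFrame(all_rows)
    cov = intra_individual_analysis(
        energies, cell_cols=("network", "scenario", "tau", "window_seconds")
    )
    outdir = Path(config.output_dir)
    _log_run(outdir, config, "intra")
    energies.to_csv(outdir / "energy_features.tsv", sep="\t", index=False)
    cov.to_csv(outdir / "intra_cov.tsv", sep="\t", index=False)
    curves = (
        energies.groupby(["network", "scenario", "tau", "window_seconds"])["log_energy"]
        .mean()
        .reset_index()
    )
    curves.to_csv(outdir / "energy_vs_tau.tsv", sep="\t", index=False)
    return energies, cov


def shared_state_pair(
    subjects: Sequence[SubjectData], rng: np.random.Generator
) -> list[StatePair]:
    """One initial/final time-point pair applied to every subject.

    The indices are drawn once (first/last quartile of the shortest
    series) and the corresponding BOLD columns are extracted per subject.
    """
    T = min(s.bold.shape[1] for s in subjects)
    q = T // 4
    t0 = int(rng.integers(0, q))
    tf = int(rng.integers(T - q, T))
    return [StatePair(s.bold[:, t0].copy(), s.bold[:, tf].copy(), t0, tf) for s in subjects]


def run_inter(
    config: RunConfig,
    subjects: Optional[Sequence[SubjectData]] = None,
    scheme: Optional[ParcelScheme] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inter-individual experiment: features and group statistics.

    One shared state pair is applied to every subject; log-energies at the
    headline control times, efficiency ratios, AC/MC and the graph
    covariates are computed per scenario and network at the headline
    window size, then passed to the group-level statistics.  Returns the
    feature table and the stats report; both are written out together
    with a JSON summary.
    """
    subjects, metadata, scheme = _resolve_cohort(config, subjects, scheme)
    rng = np.random.default_rng(config.seed)
    pairs = shared_state_pair(subjects, rng)
    rows: list[dict] = []
    for subject, pair in zip(subjects, pairs):
        rows.extend(
            subject_feature_rows(
                subject, scheme, pair, config.networks, config.headline_taus,
                config.headline_window, config.tr_seconds, config.scenarios,
                config.rcond, config.eigen_tol, config.aggregation,
            )
        )
    features = pd.DataFrame(rows)
    report = inter_individual_analysis(
        features, metadata, patient_group=config.patient_group
    )
    outdir = Path(config.output_dir)
    _log_run(outdir, config, "inter")
    features.to_csv(outdir / "features.tsv", sep="\t", index=False)
    report.to_csv(outdir / "stats_report.tsv", sep="\t", index=False)
    summary = {
        "n_subjects": len(subjects),
        "groups": metadata["group"].value_counts().to_dict(),
        "state_pair": {"t0_index": pairs[0].t0_index, "tf_index": pairs[0].tf_index},
        "n_feature_rows": len(features),
        "n_significant_cells": int(report["significant"].sum()),
        "config_hash": config.digest(),
        "seed": config.seed,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return features, report


# ---------------------------------------------------------------------------
# command-line interface


@click.group()
@click.version_option(__version__)
def cli() -> None:
    """Network-control-theory connectome features and group statistics."""
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")


def _load_config(path: str) -> RunConfig:
    try:
        return RunConfig.from_yaml(path)
    except ConfigurationError as exc:
        raise click.UsageError(str(exc))


@cli.command()
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
def simulate(config_path: str) -> None:
    """Generate a synthetic cohort into the configured cohort directory."""
    config = _load_config(config_path)
    if config.cohort_dir is None:
        raise click.UsageError("config field 'cohort_dir' is required for simulate")
    scheme = default_parcellation()
    subjects, metadata = simulate_cohort(scheme, config.cohort_spec())
    write_cohort(subjects, metadata, scheme, Path(config.cohort_dir))
    click.echo(f"wrote {len(subjects)} subjects to {config.cohort_dir}")


@cli.command()
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
def features(config_path: str) -> None:
    """Compute the per-subject feature table (no group statistics)."""
    config = _load_config(config_path)
    subjects, metadata, scheme = _resolve_cohort(config)
    rng = np.random.default_rng(config.seed)
    pairs = shared_state_pair(subjects, rng)
    rows: list[dict] = []
    for subject, pair in zip(subjects, pairs):
        rows.extend(
            subject_feature_rows(
                subject, scheme, pair, config.networks, config.headline_taus,
                config.headline_window, config.tr_seconds, config.scenarios,
                config.rcond, config.eigen_tol, config.aggregation,
            )
        )
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(outdir / "features.tsv", sep="\t", index=False)
    click.echo(f"wrote {len(rows)} feature rows to {outdir / 'features.tsv'}")


@cli.command()
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
def intra(config_path: str) -> None:
    """Run the intra-individual variability experiment."""
    config = _load_config(config_path)
    _, cov = run_intra(config)
    click.echo(intra_cov_table(cov).to_string())


@cli.command()
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
def inter(config_path: str) -> None:
    """Run the inter-individual variability / discriminability experiment."""
    config = _load_config(config_path)
    _, report = run_inter(config)
    click.echo(f"{len(report)} stats cells; significant (q<0.05): "
               f"{int(report['significant'].sum())}")


@cli.command()
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
def report(config_path: str) -> None:
    """Print a short summary of an existing stats report."""
    config = _load_config(config_path)
    path = Path(config.output_dir) / "stats_report.tsv"
    if not path.exists():
        raise click.UsageError(f"no stats report at {path}; run 'inter' first")
    stats = pd.read_csv(path, sep="\t")
    cols = ["feature", "scenario", "network", "tau", "p_group", "q_group", "auc"]
    cols = [c for c in cols if c in stats.columns]
    sig = stats[stats.get("significant", False) == True]  # noqa: E712
    click.echo(f"{len(stats)} cells, {len(sig)} significant after FDR")
    if len(sig):
        click.echo(sig[cols].to_string(index=False))


if __name__ == "__main__":
    cli()
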
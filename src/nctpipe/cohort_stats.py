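"""Variability and discriminability statistics for connectome features.

Two evaluation layers sit on top of the feature extraction:

* **intra-individual** — how stable is a subject's feature across repeated
  random choices of the initial/final states, quantified by the
  coefficient of variation (CoV, percent) of the log-energy per
  (subject, scenario, control time, window) cell;
* **inter-individual** — per-group CoV across subjects, covariate-adjusted
  group effects (ordinary least squares on age, sex and group, optionally
  adding the graph-theoretic strength/density covariates), ROC-AUC group
  discrimination (Mann-Whitney formulation), Spearman correlations with
  the per-ear clinical hearing scores, per-cell two-sample t tests, and
  Benjamini-Hochberg FDR correction across the canonical networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, EstimationError, ValidationError

DESCRIPTIVE_ALPHA = 0.05


def coefficient_of_variation(values: Sequence[float]) -> float:
    """CoV in percent: 100 * sample SD (n-1 denominator) / |mean|."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise EstimationError(f"CoV needs at least 2 values, got {v.size}")
    mean = v.mean()
    if mean == 0.0:
        raise EstimationError("CoV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / abs(mean))


@dataclass(frozen=True)
class GroupEffectResult:
    beta_group: float
    p_group: float
    group_means: Mapping[str, float]
    dof: int


def group_effect(
    feature: Sequence[float],
    group: Sequence,
    age: Optional[Sequence[float]] = None,
    sex: Optional[Sequence] = None,
    patient_group=None,
    covariates: Optional[Mapping[str, Sequence[float]]] = None,
) -> GroupEffectResult:
    """Group effect on a feature from an OLS model with age and sex.

    Fits ``feature ~ const + age + sex + group`` (plus any extra
    covariates, e.g. network strength/density) and returns the group
    coefficient, its two-sided p-value, and the raw per-group means.
    ``sex`` and ``group`` are encoded as single indicators; the group
    indicator is 1 for ``patient_group``.  With ``age``/``sex`` omitted
    the model reduces to the group indicator alone, whose t test is the
    classical pooled two-sample t test.
    """
    y = np.asarray(feature, dtype=float)
    group = np.asarray(group)
    if patient_group is None:
        raise ConfigurationError("patient_group must name the positively coded group")
    g = (group == patient_group).astype(float)
    if g.sum() < 2 or (1 - g).sum() < 2:
        raise ConfigurationError("need at least 2 subjects per group")
    cols = {}
    if age is not None:
        cols["age"] = np.asarray(age, dtype=float)
    if sex is not None:
        sex = np.asarray(sex)
        cols["sex"] = (sex == sex[0]).astype(float)
    cols["group"] = g
    for name, vals in (covariates or {}).items():
        cols[name] = np.asarray(vals, dtype=float)
    X = pd.DataFrame(cols)
    X = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        collinear = [
            c
            for c in X.columns
            if c != "const"
            and np.linalg.matrix_rank(X.drop(columns=c).to_numpy()) == rank
        ]
        raise EstimationError(f"rank-deficient design; collinear columns: {collinear}")
    fit = sm.OLS(y, X).fit()
    means = {
        str(lvl): float(y[group == lvl].mean()) for lvl in pd.unique(group)
    }
    return GroupEffectResult(
        beta_group=float(fit.params["group"]),
        p_group=float(fit.pvalues["group"]),
        group_means=means,
        dof=int(fit.df_resid),
    )


@dataclass(frozen=True)
class AucResult:
    auc: float
    auc_flipped: float
    positive_label: object


def roc_auc(scores: Sequence[float], labels: Sequence, positive_label) -> AucResult:
    """ROC area under the curve via the Mann-Whitney rank formulation.

    Ties contribute 1/2; the orientation with ``positive_label`` as the
    positive class is reported together with its complement, since either
    direction of a feature shift is a usable discriminator.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ConfigurationError("ROC analysis needs both classes present")
    ranks = scipy.stats.rankdata(scores)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return AucResult(float(auc), float(1.0 - auc), positive_label)


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ConfigurationError("Spearman correlation needs n >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise EstimationError("Spearman correlation undefined for constant input")
    rho, p = scipy.stats.spearmanr(x, y)
    return float(rho), float(p)


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, int, float]:
    """Pooled-variance two-sample Student t test (dof = n_a + n_b - 2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("each sample needs at least 2 observations")
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled == 0.0:
        raise EstimationError("zero pooled variance; t statistic undefined")
    t, p = scipy.stats.ttest_ind(a, b, equal_var=True)
    return float(t), int(a.size + b.size - 2), float(p)


def fdr_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving on return."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0.0) or np.any(p > 1.0) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# table-level analyses


def intra_individual_analysis(
    energies: pd.DataFrame,
    value_col: str = "log_energy",
    subject_col: str = "subject_id",
    cell_cols: Sequence[str] = ("scenario", "tau", "window_seconds"),
) -> pd.DataFrame:
    """CoV of log-energy across repeated state pairs, averaged over subjects.

    ``energies`` is long format with one row per
    (subject, scenario, tau, window, state pair).  Returns one row per
    analysis cell with the per-subject CoV averaged across subjects
    (``cov_percent``) plus the number of subjects.
    """
    cell_cols = list(cell_cols)
    per_subject = (
        energies.groupby([subject_col, *cell_cols])[value_col]
        .apply(lambda v: coefficient_of_variation(v.to_numpy()))
        .rename("cov_percent")
        .reset_index()
    )
    out = (
        per_subject.groupby(cell_cols)["cov_percent"]
        .agg(cov_percent="mean", n_subjects="count")
        .reset_index()
    )
    return out


def intra_cov_table(cov: pd.DataFrame, taus: Optional[Sequence[float]] = None) -> pd.DataFrame:
    """Pivot the intra-individual CoV to a scenario x control-time table."""
    table = cov.pivot_table(index="scenario", columns="tau", values="cov_percent")
    if taus is not None:
        table = table[[t for t in taus if t in table.columns]]
    return table.round(2)


def inter_individual_analysis(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    patient_group: str = "HL",
    covariate_features: Sequence[str] = ("network_strength", "network_density"),
    clinical_cols: Sequence[str] = ("pta_left", "pta_right", "srt_left", "srt_right"),
    fdr_family: Sequence[str] = ("feature", "scenario", "tau", "window_seconds"),
) -> pd.DataFrame:
    """Per-group CoV plus the full discriminability bundle per feature cell.

    ``features`` is long format with columns subject_id, feature,
    scenario, network, tau, window_seconds, value; ``metadata`` carries
    group, age, sex and the clinical scores.  For each cell the per-group
    CoV, the OLS group effect (with and without the graph-theory
    covariates, when present for the same scenario/network), the ROC-AUC,
    the two-sample t test and Spearman correlations with the clinical
    scores are computed; group-effect and t-test p-values are then
    FDR-adjusted across networks within each ``fdr_family`` cell.
    """
    required = {"subject_id", "feature", "scenario", "network", "value"}
    missing = required - set(features.columns)
    if missing:
        raise ConfigurationError(f"feature table is missing columns {sorted(missing)}")
    meta = metadata.set_index("subject_id")
    groups = meta["group"].unique()
    if len(groups) != 2:
        raise ConfigurationError(f"expected exactly 2 groups, got {list(groups)}")
    for g in groups:
        if (meta["group"] == g).sum() < 3:
            raise ConfigurationError(f"group {g!r} has fewer than 3 subjects")

    df = features.copy()
    for col in ("tau", "window_seconds"):
        if col not in df.columns:
            df[col] = np.nan

    # covariate lookup: (scenario, network, subject) -> strength/density
    cov_tables = {}
    for cov_name in covariate_features:
        sub = df[df["feature"] == cov_name]
        if len(sub):
            cov_tables[cov_name] = (
                sub.set_index(["scenario", "network", "subject_id"])["value"].sort_index()
            )

    rows = []
    main = df[~df["feature"].isin(covariate_features)]
    cell_cols = ["feature", "scenario", "network", "tau", "window_seconds"]
    for keys, cell in main.groupby(cell_cols, dropna=False):
        cell = cell.drop_duplicates("subject_id").set_index("subject_id")
        joined = cell.join(meta, how="inner")
        y = joined["value"].to_numpy()
        grp = joined["group"].to_numpy()
        rec = dict(zip(cell_cols, keys))
        rec["n_subjects"] = len(joined)

        for g in groups:
            try:
                rec[f"cov_percent_{g}"] = coefficient_of_variation(y[grp == g])
            except EstimationError:
                rec[f"cov_percent_{g}"] = np.nan

        eff = group_effect(y, grp, joined["age"], joined["sex"], patient_group)
        rec["beta_group"] = eff.beta_group
        rec["p_group"] = eff.p_group
        for g, m in eff.group_means.items():
            rec[f"mean_{g}"] = m

        scenario, network = rec["scenario"], rec["network"]
        covs = {}
        for cov_name, table in cov_tables.items():
            try:
                vals = table.loc[scenario, network].reindex(joined.index)
            except KeyError:
                continue
            # a covariate constant across subjects (e.g. density of a fully
            # dense FC block) carries no information and would be collinear
            if not vals.isna().any() and vals.nunique() > 1:
                covs[cov_name] = vals
        if covs:
            eff_cov = group_effect(
                y, grp, joined["age"], joined["sex"], patient_group, covariates=covs
            )
            rec["p_group_covadj"] = eff_cov.p_group
            rec["beta_group_covadj"] = eff_cov.beta_group
        else:
            rec["p_group_covadj"] = np.nan
            rec["beta_group_covadj"] = np.nan

        auc = roc_auc(y, grp, patient_group)
        rec["auc"] = auc.auc
        rec["auc_flipped"] = auc.auc_flipped

        try:
            t, dof, p_t = two_sample_t(y[grp == patient_group], y[grp != patient_group])
            rec["t_stat"], rec["dof"], rec["p_t"] = t, dof, p_t
        except EstimationError:
            rec["t_stat"] = rec["dof"] = rec["p_t"] = np.nan

        for clin in clinical_cols:
            if clin in joined.columns:
                try:
                    rho, p = spearman_corr(joined[clin].to_numpy(), y)
                except (EstimationError, ConfigurationError):
                    rho, p = np.nan, np.nan
                rec[f"rho_{clin}"], rec[f"p_rho_{clin}"] = rho, p
        rows.append(rec)

    report = pd.DataFrame(rows)

    # FDR across networks within each (feature, scenario, tau, window) family
    fdr_cols = {"p_group": "q_group", "p_group_covadj": "q_group_covadj", "p_t": "q_t"}
    for pcol, qcol in fdr_cols.items():
        report[qcol] = np.nan
        for _, idx in report.groupby(list(fdr_family), dropna=False).groups.items():
            ps = report.loc[idx, pcol]
            ok = ps.notna()
            if ok.any():
                report.loc[ps.index[ok], qcol] = fdr_adjust(ps[ok].to_numpy())
    report["significant"] = report["q_group"] < DESCRIPTIVE_ALPHA
    return report
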
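"""Evaluation statistics: CoV, OLS group effects, AUC, Spearman, t, FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nctpipe import (
    CohortSpec,
    ConfigurationError,
    EstimationError,
    ValidationError,
    coefficient_of_variation,
    compute_sfc,
    fdr_adjust,
    group_effect,
    inter_individual_analysis,
    intra_individual_analysis,
    roc_auc,
    simulate_cohort,
    spearman_corr,
    two_sample_t,
)


class TestCoefficientOfVariation:
    def test_constant_values(self):
        assert coefficient_of_variation([2.0, 2.0, 2.0]) == 0.0

    def test_hand_computed(self):
        # sample sd of [1, 3] is sqrt(2), mean 2
        assert coefficient_of_variation([1.0, 3.0]) == pytest.approx(
            100.0 * np.sqrt(2) / 2.0
        )

    def test_preconditions(self):
        with pytest.raises(EstimationError):
            coefficient_of_variation([5.0])
        with pytest.raises(EstimationError):
            coefficient_of_variation([-1.0, 1.0])


class TestGroupEffect:
    def test_exact_group_separation(self, rng):
        g = np.repeat(["NH", "HL"], 10)
        y = (g == "HL").astype(float) + rng.normal(0, 1e-10, 20)
        res = group_effect(y, g, age=rng.uniform(50, 70, 20),
                           sex=rng.choice(["M", "F"], 20), patient_group="HL")
        assert res.beta_group == pytest.approx(1.0, abs=1e-6)
        assert res.p_group < 1e-10
        assert res.group_means["HL"] == pytest.approx(1.0, abs=1e-6)

    def test_null_feature_gives_uniform_pvalues(self, rng):
        pvals = []
        for _ in range(200):
            g = np.repeat(["NH", "HL"], 10)
            y = rng.standard_normal(20)
            res = group_effect(y, g, rng.uniform(50, 70, 20),
                               rng.choice(["M", "F"], 20), "HL")
            pvals.append(res.p_group)
        frac = np.mean(np.asarray(pvals) < 0.05)
        assert 0.005 <= frac <= 0.12  # ~5% with binomial noise

    def test_monte_carlo_recovery_of_known_effect(self, rng):
        """beta stays within 3 standard errors of the simulated effect."""
        hits = 0
        for _ in range(200):
            g = np.repeat(["NH", "HL"], 40)
            age = rng.uniform(50, 70, 80)
            y = 0.5 * (g == "HL") + 0.01 * age + rng.normal(0, 0.1, 80)
            res = group_effect(y, g, age, rng.choice(["M", "F"], 80), "HL")
            se = 0.1 * np.sqrt(4.0 / 80.0)  # approximate SE of the group contrast
            hits += abs(res.beta_group - 0.5) < 3 * se
        assert hits >= 190

    def test_collinear_design_names_columns(self, rng):
        g = np.repeat(["NH", "HL"], 5)
        age = rng.uniform(50, 70, 10)
        with pytest.raises(EstimationError, match="strength"):
            group_effect(rng.standard_normal(10), g, age,
                         rng.choice(["M", "F"], 10), "HL",
                         covariates={"strength": age.copy()})

    def test_reduces_to_pooled_t_without_covariates(self, rng):
        g = np.repeat(["NH", "HL"], 12)
        y = rng.standard_normal(24)
        res = group_effect(y, g, patient_group="HL")
        t, dof, p = two_sample_t(y[g == "HL"], y[g == "NH"])
        assert res.p_group == pytest.approx(p, rel=1e-10)
        assert res.dof == dof

    def test_too_small_group_rejected(self, rng):
        g = np.array(["NH", "NH", "NH", "HL"])
        with pytest.raises(ConfigurationError):
            group_effect(rng.standard_normal(4), g, patient_group="HL")


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], ["a"] * 3 + ["b"] * 3, "b")
        assert res.auc == 1.0

    def test_all_ties(self):
        res = roc_auc([1.0] * 6, ["a"] * 3 + ["b"] * 3, "b")
        assert res.auc == 0.5

    def test_pair_counting_example(self):
        res = roc_auc([0.1, 0.4, 0.3, 0.9], ["n", "n", "p", "p"], "p")
        assert res.auc == pytest.approx(0.75)

    def test_flip_symmetry(self, rng):
        scores = rng.standard_normal(30)
        labels = rng.choice(["n", "p"], 30)
        if len(set(labels)) < 2:
            labels[0], labels[1] = "n", "p"
        res = roc_auc(scores, labels, "p")
        flipped = roc_auc(-scores, labels, "p")
        assert flipped.auc == pytest.approx(res.auc_flipped)

    def test_matches_sklearn(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        scores = rng.standard_normal(50)
        labels = np.r_[np.zeros(20), np.ones(30)]
        res = roc_auc(scores, labels, 1.0)
        assert res.auc == pytest.approx(
            sklearn_metrics.roc_auc_score(labels, scores), rel=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ConfigurationError):
            roc_auc([1.0, 2.0], ["a", "a"], "b")


class TestSpearman:
    def test_monotone_pairs(self):
        assert spearman_corr([1, 2, 3, 5], [2, 4, 9, 11])[0] == pytest.approx(1.0)
        assert spearman_corr([1, 2, 3, 4], [4, 3, 2, 1])[0] == pytest.approx(-1.0)

    def test_hand_computed_rank_correlation(self):
        rho, _ = spearman_corr([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)

    def test_degenerate_inputs(self):
        with pytest.raises(ConfigurationError):
            spearman_corr([1, 2, 3], [1, 2, 3])
        with pytest.raises(EstimationError):
            spearman_corr([1, 1, 1, 1], [1, 2, 3, 4])


class TestTwoSampleT:
    def test_identical_samples(self):
        t, dof, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_zero_variance_guard(self):
        with pytest.raises(EstimationError):
            two_sample_t([0.0, 0.0], [1.0, 1.0])

    def test_pooled_degrees_of_freedom(self, rng):
        _, dof, _ = two_sample_t(rng.standard_normal(52), 0.5 + rng.standard_normal(30))
        assert dof == 80


class TestFdrAdjust:
    def test_hand_computed_step_up(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04, 0.2, 0.5, 0.9])
        np.testing.assert_allclose(
            q, [0.07, 0.07, 0.07, 0.07, 0.28, 0.5833333333333334, 0.9], rtol=1e-10
        )

    def test_flat_and_single(self):
        np.testing.assert_allclose(fdr_adjust([0.5] * 4), 0.5)
        np.testing.assert_allclose(fdr_adjust([0.123]), [0.123])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            fdr_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_q_dominates_p_and_is_monotone(self, pvals):
        q = fdr_adjust(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)
        order = np.argsort(pvals)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestIntraAnalysis:
    @staticmethod
    def energy_frame(values):
        rows = []
        for subj in ("s1", "s2"):
            for scen in ("sFC", "dFC"):
                for tau in (30.0, 50.0):
                    for k, v in enumerate(values):
                        rows.append({
                            "subject_id": subj, "scenario": scen, "tau": tau,
                            "window_seconds": 50.0, "pair_index": k, "log_energy": v,
                        })
        return pd.DataFrame(rows)

    def test_constant_energies_give_zero_cov(self):
        cov = intra_individual_analysis(self.energy_frame([3.0, 3.0, 3.0]))
        assert (cov["cov_percent"] == 0.0).all()
        assert len(cov) == 4  # 2 scenarios x 2 taus
        assert (cov["n_subjects"] == 2).all()

    def test_cell_cov_is_mean_over_subjects(self):
        df = self.energy_frame([1.0, 3.0])
        cov = intra_individual_analysis(df)
        expected = coefficient_of_variation([1.0, 3.0])
        assert cov["cov_percent"].iloc[0] == pytest.approx(expected)


def _feature_frame(rng, effect=0.0, n_per_group=10):
    meta = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(2 * n_per_group)],
        "group": np.repeat(["NH", "HL"], n_per_group),
        "age": rng.uniform(50, 75, 2 * n_per_group),
        "sex": rng.choice(["M", "F"], 2 * n_per_group),
        "pta_left": rng.uniform(5, 60, 2 * n_per_group),
        "pta_right": rng.uniform(5, 60, 2 * n_per_group),
        "srt_left": rng.uniform(5, 50, 2 * n_per_group),
        "srt_right": rng.uniform(5, 50, 2 * n_per_group),
    })
    rows = []
    for _, subj in meta.iterrows():
        for network in ("DMN", "VIS", "SMN"):
            base = effect if (subj.group == "HL" and network == "DMN") else 0.0
            rows.append({
                "subject_id": subj.subject_id, "feature": "log_energy",
                "scenario": "sFC", "network": network, "tau": 30.0,
                "window_seconds": 50.0,
                "value": 5.0 + base + rng.normal(0, 0.2),
            })
            for cov_name, scale in (("network_strength", 10.0), ("network_density", 0.5)):
                rows.append({
                    "subject_id": subj.subject_id, "feature": cov_name,
                    "scenario": "sFC", "network": network, "tau": np.nan,
                    "window_seconds": np.nan,
                    "value": scale * (1.0 + rng.normal(0, 0.1)),
                })
    return pd.DataFrame(rows), meta


class TestInterAnalysis:
    def test_report_structure_and_fdr_family(self, rng):
        features, meta = _feature_frame(rng, effect=1.0)
        report = inter_individual_analysis(features, meta)
        assert len(report) == 3  # one cell per network
        assert {"p_group", "q_group", "auc", "cov_percent_NH", "cov_percent_HL",
                "p_group_covadj", "t_stat", "rho_pta_left"} <= set(report.columns)
        # q-values are a BH adjustment of the three network p-values
        np.testing.assert_allclose(
            np.sort(report["q_group"]), np.sort(fdr_adjust(report["p_group"])),
        )

    def test_injected_effect_detected_in_right_network(self, rng):
        features, meta = _feature_frame(rng, effect=1.0)
        report = inter_individual_analysis(features, meta).set_index("network")
        assert report.loc["DMN", "q_group"] == report["q_group"].min()
        assert report.loc["DMN", "auc"] > 0.9
        assert report.loc["DMN", "significant"]

    def test_null_groups_are_unremarkable(self, rng):
        features, meta = _feature_frame(rng, effect=0.0, n_per_group=15)
        report = inter_individual_analysis(features, meta)
        assert (report["auc"].between(0.2, 0.8)).all()

    def test_small_group_rejected(self, rng):
        features, meta = _feature_frame(rng)
        meta = meta[meta.group.eq("NH") | meta.subject_id.isin(["s10", "s11"])]
        with pytest.raises(ConfigurationError, match="fewer than 3"):
            inter_individual_analysis(features, meta)

    def test_injected_dmn_effect_ranks_first_across_replicate_cohorts(
        self, small_scheme
    ):
        """Across replicate synthetic cohorts the affected network's group
        comparison wins the FDR ranking more often than chance."""
        wins, n_rep = 0, 20
        for rep in range(n_rep):
            spec = CohortSpec(
                n_subjects_per_group=8, n_timepoints=150, group_effect=-0.15,
                seed=100 + rep,
            )
            subjects, meta = simulate_cohort(small_scheme, spec)
            rows = []
            for s in subjects:
                fc = compute_sfc(s.bold).values
                for network, idx in small_scheme.network_index.items():
                    block = fc[np.ix_(list(idx), list(idx))]
                    mask = ~np.eye(len(idx), dtype=bool)
                    rows.append({
                        "subject_id": s.subject_id, "feature": "mean_fc",
                        "scenario": "sFC", "network": network, "tau": np.nan,
                        "window_seconds": np.nan, "value": block[mask].mean(),
                    })
            report = inter_individual_analysis(pd.DataFrame(rows), meta)
            best = report.loc[report["q_group"].idxmin(), "network"]
            wins += best == "DMN"
        assert wins / n_rep > 2.0 / 7.0  # well above the 1-in-7 chance rate
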
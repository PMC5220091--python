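"""Cohort pipeline: LOSO evaluation, features, separation, statistics, BIC."""

import numpy as np
import pandas as pd
import pytest

from cerebropdm import (SimulationConfig, bic_select, build_feature_table,
                        estimate_cohort_kernels, linear_separation,
                        loso_evaluate, paired_and_interaction_tests,
                        run_study, simulate_cohort)
from cerebropdm.cohort import GAIN_FEATURE_PAIR, VLF_FEATURE_PAIR


@pytest.fixture(scope="module")
def cohort_kernels(default_cohort):
    return estimate_cohort_kernels(default_cohort.recordings,
                                   preprocess=False)


@pytest.fixture(scope="module")
def study(default_cohort):
    return run_study(default_cohort.recordings, preprocess=False)


class TestLoso:
    def test_fold_structure(self, cohort_kernels):
        from cerebropdm.pdm import assemble_kernel_matrix
        res = loso_evaluate(cohort_kernels)
        assert len(res) == 36  # 18 subjects x 2 conditions
        pb, pc = res[("S01", "sympathetic", "pre")].loso_pdms
        assert pb.H == 5 and pc.H == 5
        # each fold's stack holds 8 remaining subjects x 2 conditions
        held_in = [(e.recording.subject_id, e.recording.condition,
                    e.results.kernels, e.bp_sd)
                   for e in cohort_kernels.values()
                   if e.recording.group == "sympathetic"
                   and e.recording.subject_id != "S01"]
        stack = assemble_kernel_matrix(held_in, "BP")
        assert stack.Q.shape[1] == 16 * (1 + pb.M)

    def test_cloned_subjects_give_identical_pdm_sets(self, default_cohort):
        # duplicate one subject's recordings under different ids
        recs = []
        for sid in ("A", "B", "C", "D"):
            for rec in default_cohort.recordings:
                if rec.subject_id == "S01":
                    r = type(rec)(sid, rec.group, rec.condition, rec.bp,
                                  rec.co2, rec.flow)
                    recs.append(r)
        kernels = estimate_cohort_kernels(recs, preprocess=False)
        res = loso_evaluate(kernels)
        pdms = [res[(sid, "sympathetic", "pre")].loso_pdms[0].pdms
                for sid in ("A", "B", "C")]
        assert np.allclose(pdms[0], pdms[1])
        assert np.allclose(pdms[0], pdms[2])


class TestFeatureTable:
    def test_row_count_and_keys(self, study):
        tab = study.feature_table
        assert len(tab) == 36
        assert not tab[list(VLF_FEATURE_PAIR + GAIN_FEATURE_PAIR)].isna().any().any()

    def test_features_match_single_subject_computation(self, study,
                                                       cohort_kernels):
        from cerebropdm import band_average_power, kernel_power_spectrum
        tab = study.feature_table.set_index(
            ["subject_id", "group", "condition"])
        key = ("S03", "sympathetic", "post")
        expected = band_average_power(kernel_power_spectrum(
            study.kernels[key].results.kernels.kP)).log10_mean_power
        assert tab.loc[key, "kP_vlf_logpower"] == pytest.approx(expected)

    def test_rerun_is_byte_identical(self, default_cohort, study):
        again = run_study(default_cohort.recordings, preprocess=False)
        assert study.feature_table.to_csv() == again.feature_table.to_csv()


class TestSeparation:
    def test_well_separated_clouds(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(9):
            rows.append({"subject_id": f"s{i}", "group": "sympathetic",
                         "condition": "pre", "a": rng.normal(0, 0.1),
                         "b": rng.normal(0, 0.1)})
            rows.append({"subject_id": f"s{i}", "group": "sympathetic",
                         "condition": "post", "a": rng.normal(3, 0.1),
                         "b": rng.normal(3, 0.1)})
        sep = linear_separation(pd.DataFrame(rows), ("a", "b"),
                                "sympathetic")
        assert sep.complete_separation and sep.accuracy == 1.0

    def test_label_shuffle_near_chance(self):
        rng = np.random.default_rng(1)
        accs = []
        for _ in range(40):
            rows = []
            for i in range(9):
                for cond in ("pre", "post"):
                    rows.append({"subject_id": f"s{i}",
                                 "group": "placebo", "condition": cond,
                                 "a": rng.standard_normal(),
                                 "b": rng.standard_normal()})
            accs.append(linear_separation(pd.DataFrame(rows), ("a", "b"),
                                          "placebo").accuracy)
        assert 0.45 < np.mean(accs) < 0.75  # in-sample LDA overfits a bit

    def test_agrees_with_sklearn_lda(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        rng = np.random.default_rng(2)
        rows, X, y = [], [], []
        for i in range(9):
            for cond, mu in (("pre", 0.0), ("post", 1.0)):
                a, b = rng.normal(mu, 0.8), rng.normal(-mu, 0.8)
                rows.append({"subject_id": f"s{i}", "group": "sympathetic",
                             "condition": cond, "a": a, "b": b})
                X.append([a, b])
                y.append(cond == "post")
        sep = linear_separation(pd.DataFrame(rows), ("a", "b"),
                                "sympathetic")
        sk = LinearDiscriminantAnalysis().fit(X, y)
        assert sep.accuracy == pytest.approx(sk.score(X, y), abs=1e-9)

    def test_degenerate_scatter_falls_back(self):
        rows = []
        for i in range(4):
            rows.append({"subject_id": f"s{i}", "group": "placebo",
                         "condition": "pre", "a": 0.0, "b": 0.0})
            rows.append({"subject_id": f"s{i}", "group": "placebo",
                         "condition": "post", "a": 1.0, "b": 1.0})
        sep = linear_separation(pd.DataFrame(rows), ("a", "b"), "placebo")
        assert sep.fallback_mean_difference
        assert sep.complete_separation


class TestStatistics:
    def _table(self, rng, shift_symp=0.0, shift_plac=0.0):
        rows = []
        for g, shift in (("sympathetic", shift_symp),
                         ("placebo", shift_plac)):
            for i in range(9):
                base = rng.standard_normal()
                rows.append({"subject_id": f"{g[0]}{i}", "group": g,
                             "condition": "pre", "x": base})
                rows.append({"subject_id": f"{g[0]}{i}", "group": g,
                             "condition": "post",
                             "x": base + shift + 0.3 * rng.standard_normal()})
        return pd.DataFrame(rows)

    def test_identical_conditions_null_statistics(self):
        rows = []
        for g in ("sympathetic", "placebo"):
            for i in range(5):
                for cond in ("pre", "post"):
                    rows.append({"subject_id": f"{g[0]}{i}", "group": g,
                                 "condition": cond, "x": float(i)})
        out = paired_and_interaction_tests(pd.DataFrame(rows), "x")
        assert out["paired_t_sympathetic"] == 0.0
        assert out["paired_p_sympathetic"] == 1.0
        assert out["interaction_t"] == pytest.approx(0.0, abs=1e-12)

    def test_equal_shifts_cancel_in_interaction(self, rng):
        out = paired_and_interaction_tests(
            self._table(rng, shift_symp=1.0, shift_plac=1.0), "x")
        assert abs(out["interaction_t"]) < 2.0
        assert out["paired_p_sympathetic"] < 0.01

    def test_differential_shift_detected(self, rng):
        out = paired_and_interaction_tests(
            self._table(rng, shift_symp=2.0, shift_plac=0.0), "x")
        assert out["interaction_p"] < 0.01

    def test_too_few_pairs_refused(self):
        rows = [{"subject_id": "a", "group": g, "condition": c, "x": 1.0}
                for g in ("sympathetic", "placebo") for c in ("pre", "post")]
        with pytest.raises(ValueError):
            paired_and_interaction_tests(pd.DataFrame(rows), "x")


class TestModelSelection:
    def test_single_point_grid(self, default_cohort):
        recs = [r for r in default_cohort.recordings
                if r.subject_id in ("S01", "S02", "S03")]
        res = bic_select(recs, [(0.5, 5, 5, 3)], preprocess=False)
        assert res.chosen == (0.5, 5, 5, 3)
        assert np.isfinite(res.bic[0])

    def test_recovers_true_laguerre_order(self):
        """BIC picks L = 5 over 4 and 6 when the generating systems carry
        substantive weight on all five Laguerre functions."""
        from cerebropdm import (KernelCoefficients, SubjectRecording,
                                make_ground_truth, reconstruct_kernels,
                                simulate_inputs, simulate_subject)
        from cerebropdm.laguerre import discrete_laguerre_basis
        basis = discrete_laguerre_basis(0.5, 5)
        hits = 0
        n_seeds = 6
        for seed in range(n_seeds):
            rng = np.random.default_rng(500 + seed)
            cfg = SimulationConfig(seed=500 + seed, n_per_group=4,
                                   snr_db=10.0)
            recs = []
            for i in range(4):
                system = make_ground_truth(cfg, "placebo", "pre", i)
                beta = system.beta_true
                beta.beta_p[:] = 0.4 * rng.standard_normal(5)
                beta.beta_c[:] = 0.3 * rng.standard_normal(5)
                # every subject puts real weight on the 5th function, so
                # the L = 4 model is genuinely misspecified
                beta.beta_p[4] = rng.choice([-1, 1]) * rng.uniform(0.5, 0.7)
                system.kernels_true = reconstruct_kernels(beta, basis)
                for cond in ("pre", "post"):
                    bp, co2 = simulate_inputs(cfg, subject_index=i,
                                              condition=cond)
                    rec = simulate_subject(system, bp, co2, cfg)
                    recs.append(SubjectRecording(
                        rec.subject_id, "placebo", cond, rec.bp, rec.co2,
                        rec.flow))
            res = bic_select(recs, [(0.5, 4, 4, 3), (0.5, 5, 5, 3),
                                    (0.5, 6, 5, 3)], preprocess=False)
            hits += res.chosen[1] == 5
        assert hits >= 0.8 * n_seeds

    def test_unidentifiable_points_skipped(self, default_cohort):
        recs = [r for r in default_cohort.recordings
                if r.subject_id in ("S01", "S02", "S03")]
        # L = 12 needs 313 parameters from ~300 samples: unidentifiable
        res = bic_select(recs, [(0.5, 12, 5, 3), (0.5, 5, 5, 3)],
                         preprocess=False)
        assert res.chosen == (0.5, 5, 5, 3)
        assert len(res.grid) == 1


class TestStudySummary:
    def test_summary_reports_hyperparameters(self, study):
        text = study.summary()
        assert "alpha=0.5" in text and "H=5" in text
        assert "Fisher LDA" in text or "separation" in text
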
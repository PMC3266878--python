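import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import faime
from faime.core import MechanismProfile
from faime.io import ExpressionMatrix, SampleAnnotation
from faime.survival import (
    SurvivalTable,
    bonferroni,
    clara_partition,
    cox_per_mechanism,
    km_logrank,
    meta_analyze,
    p_to_z,
    pca_pc1_check,
    prepare_patient_profiles,
    stouffer_meta,
)


def _table(times, events, groups=None, patients=None):
    n = len(times)
    df = pd.DataFrame(
        {
            "patient_id": patients or [f"p{i}" for i in range(n)],
            "time": times,
            "event": events,
        }
    )
    if groups is not None:
        df["group"] = groups
    return SurvivalTable(df)


class TestPatientAveraging:
    def test_duplicate_samples_averaged(self):
        prof = MechanismProfile(
            pd.DataFrame([[1.0, 3.0, 5.0]], index=["M0"], columns=["s1", "s2", "s3"])
        )
        ann = SampleAnnotation(
            pd.DataFrame(
                {
                    "sample_id": ["s1", "s2", "s3"],
                    "group": ["t", "t", "t"],
                    "patient_id": ["pA", "pA", "pB"],
                }
            )
        )
        out = prepare_patient_profiles(prof, ann)
        assert out.scores.loc["M0", "pA"] == 2.0
        assert out.scores.loc["M0", "pB"] == 5.0

    def test_single_sample_patients_pass_through(self):
        rng = np.random.default_rng(0)
        prof = MechanismProfile(
            pd.DataFrame(rng.normal(0, 1, (3, 4)),
                         index=["M0", "M1", "M2"], columns=["s0", "s1", "s2", "s3"])
        )
        ann = SampleAnnotation(
            pd.DataFrame(
                {
                    "sample_id": ["s0", "s1", "s2", "s3"],
                    "group": ["t"] * 4,
                    "patient_id": ["p0", "p1", "p2", "p3"],
                }
            )
        )
        out = prepare_patient_profiles(prof, ann)
        np.testing.assert_allclose(
            out.scores[["p0", "p1", "p2", "p3"]].to_numpy(), prof.scores.to_numpy()
        )

    def test_mixed_duplicates_match_per_patient_mean(self):
        rng = np.random.default_rng(1)
        samples = [f"s{j}" for j in range(6)]
        pats = ["pA", "pA", "pA", "pB", "pB", "pC"]
        prof = MechanismProfile(
            pd.DataFrame(rng.normal(0, 1, (2, 6)), index=["M0", "M1"], columns=samples)
        )
        ann = SampleAnnotation(
            pd.DataFrame({"sample_id": samples, "group": ["t"] * 6, "patient_id": pats})
        )
        out = prepare_patient_profiles(prof, ann)
        for pid in ("pA", "pB", "pC"):
            cols = [s for s, p in zip(samples, pats) if p == pid]
            np.testing.assert_allclose(
                out.scores[pid].to_numpy(),
                prof.scores[cols].mean(axis=1).to_numpy(),
            )


class TestClara:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.5, (4, 10))
        b = rng.normal(6, 0.5, (4, 10))
        prof = MechanismProfile(
            pd.DataFrame(np.hstack([a, b]), index=[f"M{i}" for i in range(4)],
                         columns=[f"p{j}" for j in range(20)])
        )
        labels = clara_partition(prof, k=2, seed=0)
        assert labels.iloc[:10].nunique() == 1
        assert labels.iloc[10:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_k_equals_n(self):
        rng = np.random.default_rng(3)
        prof = MechanismProfile(
            pd.DataFrame(rng.normal(0, 1, (2, 5)), index=["M0", "M1"],
                         columns=[f"p{j}" for j in range(5)])
        )
        labels = clara_partition(prof, k=5, seed=0)
        assert labels.nunique() == 5

    def test_identical_profiles_error(self):
        prof = MechanismProfile(
            pd.DataFrame(np.ones((2, 5)), index=["M0", "M1"],
                         columns=[f"p{j}" for j in range(5)])
        )
        with pytest.raises(ValueError):
            clara_partition(prof, k=2)


class TestLogrank:
    def test_identical_groups_give_null(self):
        t = _table(
            [5.0, 10.0, 15.0, 5.0, 10.0, 15.0],
            [1, 1, 0, 1, 1, 0],
            groups=["a", "a", "a", "b", "b", "b"],
        )
        out = km_logrank(t)
        assert out["statistic"] == pytest.approx(0.0, abs=1e-9)
        assert out["p"] == pytest.approx(1.0, abs=1e-9)

    def test_hand_computed_toy(self):
        """Two groups of 3, no censoring: statistic equals the textbook
        observed-vs-expected chi-square computed risk set by risk set."""
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [1, 1, 1, 1, 1, 1]
        groups = ["a", "b", "a", "b", "a", "b"]
        out = km_logrank(_table(times, events, groups=groups))

        # independent hand computation (all times distinct, all events)
        o_minus_e, var = 0.0, 0.0
        at_risk = list(zip(times, groups))
        for t, g in sorted(at_risk):
            n = len(at_risk)
            n_a = sum(1 for _, gg in at_risk if gg == "a")
            e_a = n_a / n
            o_a = 1.0 if g == "a" else 0.0
            o_minus_e += o_a - e_a
            if n > 1:
                var += e_a * (1 - e_a)  # d=1: hypergeometric variance
            at_risk = [(tt, gg) for tt, gg in at_risk if tt > t]
        expected = o_minus_e**2 / var
        assert out["statistic"] == pytest.approx(expected, rel=1e-9)

    def test_clear_separation_significant(self):
        rng = np.random.default_rng(4)
        t_a = rng.exponential(5, 50)
        t_b = 100 + rng.exponential(5, 50)
        t = _table(
            np.concatenate([t_a, t_b]),
            [1] * 100,
            groups=["a"] * 50 + ["b"] * 50,
        )
        assert km_logrank(t)["p"] < 0.05

    def test_km_curves_are_valid_step_functions(self):
        t = _table(
            [2.0, 4.0, 6.0, 1.0, 3.0, 8.0],
            [1, 0, 1, 1, 1, 0],
            groups=["a", "a", "a", "b", "b", "b"],
        )
        curves = km_logrank(t)["curves"]
        for _, grp in curves.groupby("group"):
            s = grp.sort_values("time")["survival"].to_numpy()
            assert s[0] == 1.0
            assert np.all(np.diff(s) <= 1e-12)

    def test_missing_group_column_is_error(self):
        with pytest.raises(ValueError, match="group"):
            km_logrank(_table([1.0, 2.0], [1, 1]))


class TestCox:
    def test_sign_recovery_on_planted_hazard(self):
        cfg = faime.SimulationConfig(
            seed=11, n_tumor=200, n_control=2, n_sets=10, hazard_coef=1.0
        )
        m, ann, coll, truth = faime.generate_expression(cfg)
        surv = faime.generate_survival(truth, cfg)
        prof = faime.faime_profile(m, faime.filter_genesets(coll, m))
        patient = prepare_patient_profiles(prof, ann)
        res = cox_per_mechanism(patient, surv)
        assert res.loc["SET0001", "converged"]
        # planted direction is up and hazard rises with score
        assert res.loc["SET0001", "direction"] > 0
        assert res.loc["SET0001", "p"] < 0.01

    def test_min_genes_filter_excludes_small_sets(self, small_matrix, small_collection):
        rng = np.random.default_rng(5)
        prof = MechanismProfile(
            pd.DataFrame(rng.normal(0, 1, (3, 8)),
                         index=small_collection.ids,
                         columns=[f"p{j}" for j in range(8)])
        )
        table = _table(rng.exponential(10, 8), [1] * 8,
                       patients=[f"p{j}" for j in range(8)])
        res = cox_per_mechanism(prof, table, collection=small_collection,
                                matrix=small_matrix, min_genes=4)
        # only M2 has >= 4 measurable members (M1 has 3, M3 has 2)
        assert list(res.index) == ["M2"]

    def test_no_events_is_error(self):
        prof = MechanismProfile(
            pd.DataFrame([[0.1, 0.2, 0.3]], index=["M0"], columns=["p0", "p1", "p2"])
        )
        table = _table([1.0, 2.0, 3.0], [0, 0, 0])
        with pytest.raises(ValueError, match="events"):
            cox_per_mechanism(prof, table)


class TestStouffer:
    def test_single_study_passthrough(self):
        z = p_to_z(0.04, +1)
        z_meta, p_meta = stouffer_meta([z])
        assert z_meta == pytest.approx(z)
        assert p_meta == pytest.approx(0.04, abs=1e-12)

    def test_two_same_direction_studies_normal_quantile_oracle(self):
        z = p_to_z(0.05, +1, one_sided=True)
        assert z == pytest.approx(norm.isf(0.05), abs=1e-12)
        assert z == pytest.approx(1.6449, abs=1e-4)
        z_meta, _ = stouffer_meta([z, z])
        # oracle: sqrt(2) * Phi^-1(0.95) = 2.3262
        assert z_meta == pytest.approx(np.sqrt(2) * norm.isf(0.05), abs=1e-12)
        assert z_meta == pytest.approx(2.326, abs=1e-3)
        assert norm.sf(z_meta) == pytest.approx(0.0100, abs=2e-4)

    def test_opposite_directions_cancel(self):
        z = p_to_z(0.01, +1)
        z_meta, p_meta = stouffer_meta([z, -z])
        assert z_meta == 0.0
        assert p_meta == 1.0

    def test_zero_p_clamped(self, caplog):
        with caplog.at_level("WARNING"):
            z = p_to_z(0.0, +1)
        assert np.isfinite(z)

    def test_bonferroni(self):
        np.testing.assert_allclose(bonferroni([0.01, 0.4], 10), [0.1, 1.0])

    def test_meta_analyze_ranks_planted_first(self):
        rows = []
        for seed in (21, 22):
            cfg = faime.SimulationConfig(
                seed=seed, n_tumor=120, n_control=2, n_sets=20, hazard_coef=1.0
            )
            m, ann, coll, truth = faime.generate_expression(cfg)
            surv = faime.generate_survival(truth, cfg)
            prof = faime.faime_profile(m, faime.filter_genesets(coll, m))
            patient = prepare_patient_profiles(prof, ann)
            rows.append(cox_per_mechanism(patient, surv))
        meta = meta_analyze(rows)
        assert meta.index[0] == "SET0001"
        assert meta["p_bonferroni"].iloc[0] >= meta["p_meta"].iloc[0]


class TestPca:
    def test_rank_one_matrix_explains_everything(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        v = np.array([0.5, 1.0, 1.5])
        m = ExpressionMatrix(
            pd.DataFrame(np.outer(v, u), index=["g0", "g1", "g2"],
                         columns=["p0", "p1", "p2", "p3"])
        )
        scores = pd.Series([0.1, 0.2, 0.3, 0.4], index=["p0", "p1", "p2", "p3"])
        out = pca_pc1_check(m, {"g0", "g1", "g2"}, scores)
        assert out["explained_variance_ratio"] == pytest.approx(1.0)

    def test_scores_vs_themselves_rho_one(self):
        rng = np.random.default_rng(6)
        m = ExpressionMatrix(
            pd.DataFrame(rng.normal(5, 1, (4, 8)),
                         index=[f"g{i}" for i in range(4)],
                         columns=[f"p{j}" for j in range(8)])
        )
        out = pca_pc1_check(m, {f"g{i}" for i in range(4)},
                            pd.Series(np.arange(8.0), index=m.sample_ids))
        self_rho = pca_pc1_check(
            m, {f"g{i}" for i in range(4)}, out["pc1"]
        )["spearman_rho"]
        assert self_rho == pytest.approx(1.0)

    def test_pc1_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, (8, 5))  # patients x genes
        m = ExpressionMatrix(
            pd.DataFrame(x.T, index=[f"g{i}" for i in range(5)],
                         columns=[f"p{j}" for j in range(8)])
        )
        scores = pd.Series(rng.normal(0, 1, 8), index=m.sample_ids)
        out = pca_pc1_check(m, {f"g{i}" for i in range(5)}, scores)
        xc = x - x.mean(axis=0)
        w, v = np.linalg.eigh(xc.T @ xc)
        pc1 = xc @ v[:, np.argmax(w)]
        # compare up to sign
        got = out["pc1"].to_numpy()
        agree = min(np.abs(got - pc1).max(), np.abs(got + pc1).max())
        assert agree < 1e-10
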
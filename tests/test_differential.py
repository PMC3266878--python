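import math
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import faime
from faime.core import MechanismProfile
from faime.differential import (
    Signature,
    adjust_bh,
    adjust_by,
    build_signature,
    go_module_prune,
    overlap_significance,
    permutation_null,
    precision_recall,
    test_mechanisms as run_mechanism_tests,
    ztest_mechanisms,
)
from faime.io import SampleAnnotation


def _profile(arr, samples=None):
    arr = np.atleast_2d(np.asarray(arr, float))
    mechs = [f"M{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return MechanismProfile(pd.DataFrame(arr, index=mechs, columns=samples))


def _annotation(groups, pair_ids=None):
    df = pd.DataFrame(
        {"sample_id": [f"s{j}" for j in range(len(groups))], "group": groups}
    )
    if pair_ids is not None:
        df["pair_id"] = pair_ids
    return SampleAnnotation(df)


class TestZtest:
    def test_identical_groups_give_z0_p1(self):
        prof = _profile([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        ann = _annotation(["a"] * 3 + ["b"] * 3)
        res = ztest_mechanisms(prof, ann, "a")
        assert res.loc["M0", "z"] == 0
        assert res.loc["M0", "p"] == 1

    def test_unpaired_matches_hand_formula(self):
        g1, g2 = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        prof = _profile([g1 + g2])
        ann = _annotation(["a"] * 3 + ["b"] * 3)
        res = ztest_mechanisms(prof, ann, "a")
        se = math.sqrt(np.var(g1, ddof=1) / 3 + np.var(g2, ddof=1) / 3)
        assert res.loc["M0", "z"] == pytest.approx((2.0 - 5.0) / se, abs=1e-12)
        assert res.loc["M0", "direction"] == "down"

    def test_paired_zero_differences(self):
        prof = _profile([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        ann = _annotation(["a"] * 3 + ["b"] * 3, ["p1", "p2", "p3", "p1", "p2", "p3"])
        res = ztest_mechanisms(prof, ann, "a", paired=True)
        assert res.loc["M0", "z"] == 0
        assert res.loc["M0", "p"] == 1

    def test_paired_matches_hand_formula(self):
        a, b = np.array([2.0, 3.0, 5.0]), np.array([1.0, 1.5, 2.0])
        prof = _profile([np.concatenate([a, b])])
        ann = _annotation(["a"] * 3 + ["b"] * 3, ["p1", "p2", "p3", "p1", "p2", "p3"])
        res = ztest_mechanisms(prof, ann, "a", paired=True)
        d = a - b
        expected = d.mean() / (d.std(ddof=1) / math.sqrt(3))
        assert res.loc["M0", "z"] == pytest.approx(expected, abs=1e-12)

    def test_single_sample_group_is_error(self):
        prof = _profile([[1.0, 2.0, 3.0]])
        ann = _annotation(["a", "b", "b"])
        with pytest.raises(ValueError):
            ztest_mechanisms(prof, ann, "a")


class TestPermutationNull:
    def test_extreme_observed_hits_floor(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 0.01, (5, 20))
        base[0, :10] += 50  # far beyond anything a relabelling can produce
        prof = _profile(base)
        ann = _annotation(["a"] * 10 + ["b"] * 10)
        p = permutation_null(prof, ann, n_perm=999, seed=1, group_of_interest="a")
        assert p["M0"] == pytest.approx(1 / 1000)

    def test_exhaustive_three_vs_three_matches_enumeration(self):
        rng = np.random.default_rng(4)
        prof = _profile(rng.normal(0, 1, (6, 6)))
        ann = _annotation(["a"] * 3 + ["b"] * 3)
        p_exh = permutation_null(prof, ann, exhaustive=True, group_of_interest="a")

        # independent enumeration over all 20 splits
        x = prof.scores.to_numpy()
        z_obs = None
        stats = []
        for idx in combinations(range(6), 3):
            sel = np.zeros(6, bool)
            sel[list(idx)] = True
            g1, g2 = x[:, sel], x[:, ~sel]
            se = np.sqrt(g1.var(axis=1, ddof=1) / 3 + g2.var(axis=1, ddof=1) / 3)
            z = np.abs((g1.mean(axis=1) - g2.mean(axis=1)) / se)
            stats.append(z)
            if idx == (0, 1, 2):
                z_obs = z
        stats = np.array(stats)
        expected = (stats >= z_obs[None, :] - 1e-12).sum(axis=0) / 20
        np.testing.assert_allclose(p_exh.to_numpy(), expected)
        assert (p_exh >= 1 / 20).all()

    def test_null_pvalues_roughly_uniform(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(7)
        prof = _profile(rng.normal(0, 1, (150, 30)))
        ann = _annotation(["a"] * 15 + ["b"] * 15)
        p = permutation_null(prof, ann, n_perm=500, seed=2, group_of_interest="a")
        assert kstest(p.to_numpy(), "uniform").pvalue > 0.01

    def test_rank_agreement_with_analytic_p(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(8)
        base = rng.normal(0, 1, (60, 40))
        base[:20, :20] += np.linspace(0.2, 1.5, 20)[:, None]
        prof = _profile(base)
        ann = _annotation(["a"] * 20 + ["b"] * 20)
        res = ztest_mechanisms(prof, ann, "a")
        p_emp = permutation_null(prof, ann, n_perm=800, seed=3, group_of_interest="a")
        rho, _ = spearmanr(res["p"], p_emp)
        assert rho >= 0.95


class TestAdjustBY:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_by([0.03]), [0.03])

    def test_hand_computed_example(self):
        # BH gives (0.03, 0.03, 0.03); c(3) = 11/6 -> all 0.055
        np.testing.assert_allclose(adjust_by([0.01, 0.02, 0.03]), [0.055] * 3, atol=1e-12)

    def test_dominates_raw_and_bh(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.uniform(0, 1, size=rng.integers(1, 50))
            q_by, q_bh = adjust_by(p), adjust_bh(p)
            assert (q_by >= p - 1e-15).all()
            assert (q_by >= q_bh - 1e-15).all()
            assert (q_by <= 1 + 1e-15).all()

    def test_empty_input(self):
        assert len(adjust_by([])) == 0


class TestGoModulePrune:
    def test_empty_input(self):
        assert go_module_prune({}, nx.DiGraph()) == []

    def test_disconnected_terms_both_kept(self):
        dag = nx.DiGraph([("A", "B"), ("C", "D")])
        assert go_module_prune({"A": 0.01, "C": 0.02}, dag) == ["A", "C"]

    def test_chain_keeps_min_q(self):
        dag = nx.DiGraph([("child", "parent")])
        assert go_module_prune({"child": 0.01, "parent": 0.04}, dag) == ["child"]

    def test_tie_broken_by_term_id(self):
        dag = nx.DiGraph([("A", "B")])
        assert go_module_prune({"A": 0.01, "B": 0.01}, dag) == ["A"]

    def test_matches_exhaustive_region_enumeration(self):
        rng = np.random.default_rng(2)
        nodes = [f"T{i}" for i in range(15)]
        dag = nx.DiGraph()
        dag.add_nodes_from(nodes)
        for i in range(1, 15):
            dag.add_edge(nodes[i], nodes[rng.integers(0, i)])
        sig = {n: float(rng.uniform(0, 0.05)) for n in rng.choice(nodes, 8, replace=False)}
        got = go_module_prune(sig, dag)
        expected = sorted(
            min(comp, key=lambda t: (sig[t], t))
            for comp in nx.connected_components(dag.to_undirected().subgraph(sig))
        )
        assert got == expected

    def test_missing_term_kept_with_warning(self, caplog):
        dag = nx.DiGraph([("A", "B")])
        with caplog.at_level("WARNING"):
            got = go_module_prune({"A": 0.01, "X": 0.02}, dag)
        assert got == ["A", "X"]


class TestSignature:
    def test_all_insignificant_gives_empty(self):
        res = pd.DataFrame({"q": [0.5, 0.9], "direction": ["up", "down"]},
                           index=["M0", "M1"])
        assert len(build_signature(res, fdr=0.05)) == 0

    def test_fdr_one_keeps_all(self):
        res = pd.DataFrame({"q": [0.5, 0.9], "direction": ["up", "down"]},
                           index=["M0", "M1"])
        sig = build_signature(res, fdr=1.0)
        assert sig.directions == {"M0": "up", "M1": "down"}

    def test_planted_set_recovered_with_direction(self):
        hits = 0
        for seed in range(10):
            cfg = faime.SimulationConfig(seed=seed, n_sets=50,
                                         planted={"SET0001": (3.0, "up")})
            m, ann, coll, _ = faime.generate_expression(cfg)
            prof = faime.faime_profile(m, faime.filter_genesets(coll, m))
            res = run_mechanism_tests(prof, ann, "tumor", n_perm=50, seed=seed)
            sig = build_signature(res)
            if "SET0001" in sig.mechanisms and sig.directions["SET0001"] == "up":
                hits += 1
        assert hits >= 9

    def test_round_trip(self, tmp_path):
        sig = Signature("ds1", {"M1": "up", "M2": "down"})
        path = tmp_path / "sig.tsv"
        sig.write_tsv(path)
        again = Signature.read_tsv(path, "ds1")
        assert again.directions == sig.directions


class TestOverlap:
    def test_identical_signatures(self):
        universe = [f"T{i}" for i in range(200)]
        sigs = [Signature(d, {"T1": "up", "T2": "up", "T3": "down"}) for d in "abc"]
        out = overlap_significance(sigs, [universe] * 3, n_resample=200, seed=0)
        assert out["overlap_fraction"] == 1.0
        assert out["p_empirical"] == pytest.approx(1 / 201)

    def test_disjoint_signatures(self):
        universe = [f"T{i}" for i in range(10)]
        sigs = [
            Signature("a", {"T0": "up"}),
            Signature("b", {"T1": "up"}),
            Signature("c", {"T2": "up"}),
        ]
        out = overlap_significance(sigs, [universe] * 3, n_resample=100, seed=0)
        assert out["intersection_size"] == 0
        assert out["p_empirical"] > 0.9

    def test_matches_enumeration_probability(self):
        # P(3 random size-3 subsets of 10 terms share >= the observed intersection)
        universe = [f"T{i}" for i in range(10)]
        common = {"T0": "up", "T1": "up"}
        sigs = [
            Signature("a", {**common, "T2": "up"}),
            Signature("b", {**common, "T3": "up"}),
            Signature("c", {**common, "T4": "up"}),
        ]
        out = overlap_significance(sigs, [universe] * 3, n_resample=4000, seed=1)
        # exact: sum over j>=2 of P(|A∩B∩C| >= 2) with A fixed WLOG
        from itertools import combinations as comb
        from math import comb as C

        terms = list(range(10))
        total, hit = 0, 0
        a = (0, 1, 2)
        for b in comb(terms, 3):
            for c in comb(terms, 3):
                total += 1
                if len(set(a) & set(b) & set(c)) >= 2:
                    hit += 1
        exact = hit / total
        assert out["p_empirical"] == pytest.approx(exact, abs=0.01)

    def test_signature_outside_universe_is_error(self):
        with pytest.raises(ValueError):
            overlap_significance(
                [Signature("a", {"X": "up"}), Signature("b", {"X": "up"})],
                [["T1"], ["X"]],
            )


class TestPrecisionRecall:
    def test_perfect_prediction(self):
        out = precision_recall(["T1", "T2"], ["T1", "T2"])
        assert out["precision"].iloc[-1] == 1.0
        assert out["recall"].iloc[-1] == 1.0

    def test_ranked_hand_enumeration(self):
        out = precision_recall(["T1", "F1", "T2"], ["T1", "T2"])
        np.testing.assert_allclose(out["precision"], [1.0, 0.5, 2 / 3])
        np.testing.assert_allclose(out["recall"], [0.5, 0.5, 1.0])

    def test_disjoint_gives_zero_precision(self):
        out = precision_recall(["F1", "F2"], ["T1"])
        assert (out["precision"] == 0).all()

    def test_empty_prediction_convention(self):
        out = precision_recall([], ["T1"])
        assert np.isnan(out["precision"].iloc[0])
        assert out["recall"].iloc[0] == 0.0
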
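"""Feature extraction, the relationship predictor, and score calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stenoprio as sp
from stenoprio.scoring import (Category, NullDistribution, TruthTable,
                               calibrate_to_ann, categorize, compute_features,
                               degree_bin, empirical_p, permutation_null)

from conftest import make_path_graph


class TestFeatures:
    def test_motive_member_has_zero_min_distance(self):
        g = make_path_graph("ABCD")
        fv = compute_features(g, "A", {"A", "B"})
        assert fv.d_min == 0

    def test_path_distance_three(self):
        g = make_path_graph("ABCD")
        fv = compute_features(g, "D", {"A"})
        assert fv.d_min == 3 and fv.d_mean == 3

    def test_missing_candidate_gets_sentinel_vector(self):
        g = make_path_graph("ABCD")
        fv = compute_features(g, "ZZZZZ", {"A"})
        assert fv.missing
        assert fv.d_min == g.diameter_cap()
        assert fv.rwr_score == 0 and fv.jaccard_nbr == 0

    def test_unreachable_distance_capped(self):
        g = sp.KnowledgeGraph()
        g.add_edge("A", "B")
        g.add_edge("C", "D")
        fv = compute_features(g, "C", {"A"})
        assert fv.d_min == g.diameter_cap() == 2

    def test_min_not_exceeding_mean(self, default_study):
        ctx_pairs = default_study.dmap.scoring_units()
        nodes = sorted(default_study.graph.nodes())[:50]
        for motive_id, effs in ctx_pairs:
            for node in nodes:
                fv = compute_features(default_study.graph, node, effs)
                assert fv.d_min <= fv.d_mean + 1e-12


class TestTruthTable:
    @staticmethod
    def toy_setup():
        # two triangle modules joined to a long background path
        g = sp.KnowledgeGraph()
        for a, b in [("A1", "A2"), ("A2", "A3"), ("A1", "A3"),
                     ("B1", "B2"), ("B2", "B3"), ("B1", "B3")]:
            g.add_edge(a, b)
        chain = ["A1"] + [f"P{i:02d}" for i in range(12)] + ["B1"]
        for a, b in zip(chain, chain[1:]):
            g.add_edge(a, b)
        dmap = sp.DiseaseMap(motives=[
            sp.Motive("m1", "module A", sp.CausalLevel.causative,
                      frozenset({"A1", "A2", "A3"})),
            sp.Motive("m2", "module B", sp.CausalLevel.symptomatic,
                      frozenset({"B1", "B2", "B3"}))])
        return g, dmap

    def test_counts_by_construction(self):
        g, dmap = self.toy_setup()
        table = sp.build_truth_table(dmap, g, neg_per_pos=1,
                                     min_neg_distance=3, seed=0)
        assert len(table.positives()) == 6
        assert len(table.negatives()) == 6

    def test_same_seed_reproduces_table(self):
        g, dmap = self.toy_setup()
        t1 = sp.build_truth_table(dmap, g, seed=5)
        t2 = sp.build_truth_table(dmap, g, seed=5)
        assert t1.rows == t2.rows

    def test_positive_negative_pairs_disjoint(self):
        g, dmap = self.toy_setup()
        table = sp.build_truth_table(dmap, g, seed=3)
        assert not set(table.positives()) & set(table.negatives())

    def test_negatives_respect_distance_floor(self):
        g, dmap = self.toy_setup()
        table = sp.build_truth_table(dmap, g, min_neg_distance=4, seed=1)
        for uid, mid, _ in table.rows:
            if (uid, mid) in table.negatives():
                d = min(g.shortest_path_length(uid, e)
                        for e in dmap.get_motive(mid).effectors)
                assert d >= 4

    def test_impossible_distance_floor_suggests_remedy(self):
        g, dmap = self.toy_setup()
        with pytest.raises(ValueError, match="min_neg_distance"):
            sp.build_truth_table(dmap, g, min_neg_distance=50, seed=0)

    def test_conflicting_labels_rejected(self):
        with pytest.raises(ValueError, match="both"):
            TruthTable(rows=[("P1", "m1", "related"),
                             ("P1", "m1", "unrelated")])


class TestModelTraining:
    def test_separable_study_reaches_high_holdout_accuracy(self, default_study,
                                                           trained_model):
        assert trained_model.metadata["holdout_accuracy"] >= 0.95

    def test_logistic_regression_oracle_confirms_separability(self, default_study):
        # same features, independent learner: if a plain logistic fit also
        # separates the truth table, the signal is in the features, not the net
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_score
        from stenoprio.scoring import MotiveContext
        study = default_study
        ctxs = {mid: MotiveContext(study.graph, effs)
                for mid, effs in study.dmap.scoring_units()}
        X = np.vstack([ctxs[mid].features(uid).as_array()
                       for uid, mid, _ in study.truth_table.rows])
        y = np.array([l == "related" for _, _, l in study.truth_table.rows])
        acc = cross_val_score(LogisticRegression(max_iter=1000), X, y, cv=4).mean()
        assert acc >= 0.95

    def test_same_seed_gives_identical_predictions(self, default_study):
        m1 = sp.train_model(default_study.truth_table, default_study.graph,
                            default_study.dmap, seed=3)
        m2 = sp.train_model(default_study.truth_table, default_study.graph,
                            default_study.dmap, seed=3)
        probe = np.random.default_rng(0).uniform(0, 5, size=(20, 5))
        assert np.array_equal(m1.predict_raw(probe), m2.predict_raw(probe))

    def test_raw_predictions_bounded(self, trained_model):
        probe = np.random.default_rng(1).uniform(-2, 10, size=(100, 5))
        raw = trained_model.predict_raw(probe)
        assert np.all((raw >= 0) & (raw <= 1))

    def test_single_class_table_rejected(self, default_study):
        table = TruthTable(rows=[(u, m, "related")
                                 for u, m in default_study.truth_table.positives()])
        with pytest.raises(ValueError, match="single-class"):
            sp.train_model(table, default_study.graph, default_study.dmap)

    def test_forward_pass_matches_scalar_reimplementation(self, trained_model):
        # independent oracle: plain-Python forward pass, no numpy broadcasting
        def sigmoid(t):
            if t >= 0:
                return 1 / (1 + math.exp(-t))
            return math.exp(t) / (1 + math.exp(t))

        def scalar_forward(m, x):
            z = [(xi - mu) / sc for xi, mu, sc in
                 zip(x, m.scaler_mean, m.scaler_scale)]
            h = [sigmoid(sum(zi * wij for zi, wij in zip(z, col)) + b)
                 for col, b in zip(np.array(m.w_hidden).T, m.b_hidden)]
            out = sum(hi * w for hi, w in zip(h, np.array(m.w_out).ravel()))
            return sigmoid(out + float(m.b_out[0]))

        probe = np.random.default_rng(2).uniform(0, 4, size=(10, 5))
        got = trained_model.predict_raw(probe)
        for x, g in zip(probe, got):
            assert g == pytest.approx(scalar_forward(trained_model, x), abs=1e-12)

    def test_serialization_roundtrip(self, trained_model, tmp_path):
        p = tmp_path / "model.json"
        trained_model.to_json(p)
        again = sp.RelationshipModel.from_json(p)
        probe = np.random.default_rng(3).uniform(0, 4, size=(5, 5))
        assert np.allclose(trained_model.predict_raw(probe),
                           again.predict_raw(probe), atol=1e-15)


class TestEmpiricalP:
    def test_score_above_all_nulls(self):
        null = np.linspace(0, 0.5, 99)
        assert empirical_p(0.9, null) == pytest.approx(1 / 100)

    def test_score_below_all_nulls(self):
        null = np.linspace(0.5, 1.0, 99)
        assert empirical_p(0.1, null) == 1.0

    def test_score_at_the_median(self):
        null = np.linspace(0, 1, 101)
        p = empirical_p(float(np.median(null)), null)
        assert p == pytest.approx(52 / 102)  # 50 above + the tied value + 1

    @given(st.floats(0, 1), st.integers(0, 200))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_p_always_in_unit_interval(self, raw, n_below):
        null = np.concatenate([np.full(n_below, raw - 0.1),
                               np.full(150, raw + 0.1)])
        p = empirical_p(raw, null)
        assert 0 < p <= 1


class TestCalibration:
    @pytest.mark.parametrize("p,score", [
        (0.001, 100.0), (0.01, 92.0), (0.05, 78.0),
        (0.15, 63.0), (0.25, 38.0), (1.0, 0.0),
    ])
    def test_anchor_points_exact(self, p, score):
        assert calibrate_to_ann(p).value == pytest.approx(score, abs=1e-9)

    def test_clamped_at_100_below_the_top_anchor(self):
        assert calibrate_to_ann(1e-6).value == 100.0

    @given(st.floats(min_value=-3, max_value=0))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_strictly_monotone_decreasing(self, log_p):
        p = 10 ** log_p
        eps = 1.05
        if p * eps <= 1.0 and p >= 1e-3:
            assert calibrate_to_ann(p).value > calibrate_to_ann(p * eps).value

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_out_of_range_p_rejected(self, bad):
        with pytest.raises(ValueError):
            calibrate_to_ann(bad)

    @pytest.mark.parametrize("value,category", [
        (92.0, Category.very_high), (91.99, Category.high),
        (78.0, Category.high), (77.99, Category.medium_high),
        (63.0, Category.medium_high), (62.99, Category.medium),
        (38.0, Category.medium), (37.99, Category.low),
    ])
    def test_band_boundaries_closed_below(self, value, category):
        assert categorize(value) is category

    def test_open_boundary_convention_available(self):
        assert categorize(92.0, boundary="open") is Category.high


class TestPermutationNull:
    def test_determinism_and_sorting(self, default_study, trained_model):
        effs = default_study.dmap.motives[0].effectors
        n1 = permutation_null(default_study.graph, trained_model, effs,
                              candidate_degree=4, N=120, seed=9)
        n2 = permutation_null(default_study.graph, trained_model, effs,
                              candidate_degree=4, N=120, seed=9)
        assert np.array_equal(n1.scores, n2.scores)
        assert np.all(np.diff(n1.scores) >= 0)

    def test_small_n_rejected(self, default_study, trained_model):
        with pytest.raises(ValueError, match=">= 100"):
            permutation_null(default_study.graph, trained_model,
                             default_study.dmap.motives[0].effectors,
                             candidate_degree=4, N=50)

    def test_empty_degree_bin_falls_back_with_warning(self, default_study,
                                                      trained_model):
        with pytest.warns(UserWarning, match="falling back"):
            null = permutation_null(default_study.graph, trained_model,
                                    default_study.dmap.motives[0].effectors,
                                    candidate_degree=10 ** 6, N=100, seed=0)
        assert null.fallback_bin is not None

    def test_proximal_bin_dominates_distant_component(self):
        # two components; the walkable one touches the motive, the other not.
        # a proximity-decreasing scorer must give stochastically larger nulls
        # for the degree bin populated by motive-adjacent nodes.
        g = sp.KnowledgeGraph()
        for leaf in [f"L{i}" for i in range(6)]:   # degree-1 nodes near motive
            g.add_edge("HUB", leaf)
        far = [f"F{i}" for i in range(6)]          # distant clique, degree 5
        for i, a in enumerate(far):
            for b in far[i + 1:]:
                g.add_edge(a, b)
        model = sp.RelationshipModel(
            scaler_mean=np.zeros(5), scaler_scale=np.ones(5),
            w_hidden=np.array([[-1.0], [0], [0], [0], [0]]),
            b_hidden=np.zeros(1), w_out=np.array([[10.0]]),
            b_out=np.array([-5.0]))
        near = permutation_null(g, model, {"HUB"}, candidate_degree=1,
                                N=200, seed=1)
        distant = permutation_null(g, model, {"HUB"}, candidate_degree=5,
                                   N=200, seed=1)
        # empirical CDF comparison at the shared quantile grid
        qs = np.linspace(0.05, 0.95, 10)
        assert np.all(np.quantile(near.scores, qs)
                      >= np.quantile(distant.scores, qs))


class TestScoreAll:
    def test_effector_flag_set_for_own_motive(self, default_study,
                                              synthetic_matrix):
        m = default_study.dmap.motives[0]
        eff = sorted(m.effectors)[0]
        cands = sp.CandidateList([sp.disease.CandidateEntry(eff, "an effector")])
        matrix = sp.score_all(default_study.graph, sp.train_model(
            default_study.truth_table, default_study.graph,
            default_study.dmap, seed=7),
            default_study.dmap, cands, sp.NullParams(seed=11))
        row = matrix.df[(matrix.df.motive_id == m.motive_id)]
        assert bool(row.is_effector.iloc[0])

    def test_empty_candidate_list_gives_empty_matrix(self, default_study,
                                                     trained_model):
        matrix = sp.score_all(default_study.graph, trained_model,
                              default_study.dmap, sp.CandidateList([]),
                              sp.NullParams(seed=11))
        assert len(matrix) == 0
        assert list(matrix.df.columns) == list(sp.scoring.SCORE_COLUMNS)

    def test_planted_related_outscore_unrelated(self, default_study,
                                                synthetic_matrix):
        df = synthetic_matrix.df
        best = df.groupby("uniprot_id")["ann_score"].max()
        rel = [u for u, m in default_study.labels.items() if m is not None]
        unr = [u for u, m in default_study.labels.items() if m is None]
        assert best[rel].mean() > best[unr].mean() + 20

    def test_missing_candidate_flagged_in_qc(self, default_study, trained_model):
        cands = sp.CandidateList([sp.disease.CandidateEntry("QQQQ9", "ghost")])
        matrix = sp.score_all(default_study.graph, trained_model,
                              default_study.dmap, cands, sp.NullParams(seed=2))
        assert (matrix.df.qc_flags == "missing_from_graph").all()


def test_degree_bins_are_log2():
    assert degree_bin(0) == -1
    assert degree_bin(1) == 0
    assert [degree_bin(d) for d in (2, 3, 4, 7, 8, 1024)] == [1, 1, 2, 2, 3, 10]
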
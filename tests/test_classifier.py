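"""Regularised Gaussian posterior classifier: training, prediction,
evaluation."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from rnaprecis.classifier import (ClusterSummary, PAIRS, RNAPrecis,
                                  RNAPrecisResults, evaluate_predictions,
                                  log_unnormalized_posterior)
from rnaprecis.clustering import ClusterModel, SYNTHETIC_AGE_PARAMS, ModeHuntConfig
from rnaprecis.muccss import MuccssPoint, tangent_coords
from rnaprecis.structure_io import LabelTable
from test_muccss import rand_point


def make_cluster(rng, pair="P33", index=1, n=30, label="1a", spread=0.08,
                 center=None):
    center = center or rand_point(rng, 0.0)
    pts = []
    for _ in range(n):
        s1 = center.s1 + rng.normal(0, spread, 3)
        s2 = center.s2 + rng.normal(0, spread, 3)
        pts.append(MuccssPoint(
            d2=center.d2 + rng.normal(0, spread),
            d3=center.d3 + rng.normal(0, spread),
            alpha=center.alpha + rng.normal(0, spread / 2),
            s1=s1 / np.linalg.norm(s1), s2=s2 / np.linalg.norm(s2)))
    c = ClusterModel(cluster_id=(pair, index), members=list(range(n)),
                     hd_points=np.empty((0, 7)),
                     conformer_labels=Counter({label: n}))
    c.ld_points = pts
    return c, center


class TestRegularisation:
    def test_lambda_one_gives_raw_covariance(self, rng):
        c, _ = make_cluster(rng)
        res = RNAPrecis([c], lam=1.0).fit()
        s = res.pair_summaries("P33")[0]
        assert np.allclose(s.reg_covariance, s.covariance, atol=1e-15)

    def test_lambda_zero_gives_reference_everywhere(self, rng):
        c1, _ = make_cluster(rng, index=1, n=40)
        c2, _ = make_cluster(rng, index=2, n=10, label="1c")
        res = RNAPrecis([c1, c2], lam=0.0).fit()
        s1 = max(res.pair_summaries("P33"), key=lambda s: s.size)
        for s in res.pair_summaries("P33"):
            assert np.allclose(s.reg_covariance, res.reference_covariance,
                               atol=1e-15)
        assert np.allclose(res.reference_covariance, s1.covariance,
                           atol=1e-15)

    def test_default_lambda_half_blends(self, rng):
        c1, _ = make_cluster(rng, index=1, n=40)
        c2, _ = make_cluster(rng, index=2, n=12, label="1c")
        res = RNAPrecis([c1, c2]).fit()
        assert res.lam == 0.5
        s2 = [s for s in res.pair_summaries("P33") if s.cluster_id[1] == 2][0]
        expect = 0.5 * s2.covariance + 0.5 * res.reference_covariance
        assert np.allclose(s2.reg_covariance, expect, atol=1e-15)

    def test_all_regularised_covariances_positive_definite(self, rng):
        small, _ = make_cluster(rng, index=2, n=2, label="5z")
        big, _ = make_cluster(rng, index=1, n=50)
        res = RNAPrecis([big, small]).fit()
        for s in res.pair_summaries("P33"):
            assert np.all(np.linalg.eigvalsh(s.reg_covariance) > 0)

    def test_invalid_lambda_rejected(self, rng):
        c, _ = make_cluster(rng)
        with pytest.raises(ValueError):
            RNAPrecis([c], lam=1.5)


class TestPosterior:
    def test_at_mean_only_prior_and_logdet(self, rng):
        c, _ = make_cluster(rng)
        res = RNAPrecis([c]).fit()
        s = res.pair_summaries("P33")[0]
        got = log_unnormalized_posterior(s.mean, s)
        assert got == pytest.approx(np.log(s.size) - 0.5 * s.logdet,
                                    abs=1e-12)

    def test_prior_odds_for_identical_clusters(self, rng):
        """Two clusters sharing mean and covariance but with sizes 30
        and 3 must give posterior odds exactly 10:1 for any point."""
        c1, center = make_cluster(rng, index=1, n=30)
        res = RNAPrecis([c1]).fit()
        s1 = res.pair_summaries("P33")[0]
        s2 = ClusterSummary(cluster_id=("P33", 2), size=3,
                            labels=Counter({"1c": 3}), mean=s1.mean,
                            covariance=s1.covariance)
        s2.reg_covariance = s1.reg_covariance
        s2.finalize()
        res.summaries["P33"].append(s2)
        for _ in range(5):
            w = rand_point(rng, 0.05)
            pred = res.predict_point(w, "P33")
            odds = pred.posteriors[0] / pred.posteriors[1]
            assert odds == pytest.approx(10.0, rel=1e-9)

    def test_matches_brute_force_formula(self, rng):
        c, _ = make_cluster(rng)
        res = RNAPrecis([c], lam=0.7).fit()
        s = res.pair_summaries("P33")[0]
        for _ in range(20):
            w = rand_point(rng, 0.05)
            t = tangent_coords(w, s.mean)
            rs = s.reg_covariance
            brute = (np.log(s.size)
                     - 0.5 * np.log(np.linalg.det(rs))
                     - 0.5 * t @ np.linalg.inv(rs) @ t)
            assert log_unnormalized_posterior(w, s) == pytest.approx(
                brute, abs=1e-10)

    def test_shrinking_covariance_grows_mahalanobis(self, rng):
        """With fixed mean, a more concentrated cluster puts any
        off-mean point at strictly larger Mahalanobis distance."""
        c, _ = make_cluster(rng)
        res = RNAPrecis([c], lam=1.0).fit()
        s = res.pair_summaries("P33")[0]
        shrunk = ClusterSummary(cluster_id=("P33", 2), size=s.size,
                                labels=s.labels, mean=s.mean,
                                covariance=s.covariance)
        shrunk.reg_covariance = 0.5 * s.reg_covariance
        shrunk.finalize()
        for _ in range(10):
            w = rand_point(rng, 0.1)
            assert shrunk.mahalanobis_sq(w) > s.mahalanobis_sq(w)

    def test_posteriors_normalised(self, rng):
        clusters = [make_cluster(rng, index=i, n=20 + i,
                                 label=f"{i}a")[0] for i in range(1, 4)]
        res = RNAPrecis(clusters).fit()
        for _ in range(100):
            w = rand_point(rng, 0.3)
            pred = res.predict_point(w, "P33")
            if pred.ok:
                assert abs(pred.posteriors.sum() - 1.0) <= 1e-12

    def test_cluster_permutation_equivariance(self, rng):
        clusters = [make_cluster(rng, index=i, n=10 * i,
                                 label=f"{i}a")[0] for i in range(1, 4)]
        res1 = RNAPrecis(clusters).fit()
        res2 = RNAPrecis(clusters[::-1]).fit()
        w = rand_point(rng, 0.2)
        p1 = res1.predict_point(w, "P33")
        p2 = res2.predict_point(w, "P33")
        assert p1.cluster_ids == p2.cluster_ids
        assert np.allclose(p1.posteriors, p2.posteriors, atol=1e-12)


class TestEndToEnd:
    def test_parameter_recovery_on_separated_clusters(self, rng):
        """Test draws at a training cluster's generating parameters go
        back to that cluster almost always."""
        clusters, centers = [], []
        base = rand_point(rng, 0.0)
        offsets = [(0, 0), (0.8, 0), (0, 0.8), (0.8, 0.8)]
        for i, (da, db) in enumerate(offsets, start=1):
            s1 = np.array([np.sin(da), 0.1, np.cos(da)])
            s2 = np.array([0.1, np.sin(db), np.cos(db)])
            center = MuccssPoint(d2=base.d2 + da, d3=base.d3 + db,
                                 alpha=base.alpha,
                                 s1=s1 / np.linalg.norm(s1),
                                 s2=s2 / np.linalg.norm(s2))
            c, _ = make_cluster(rng, index=i, n=40, label=f"{i}a",
                                spread=0.06, center=center)
            clusters.append(c)
            centers.append(center)
        res = RNAPrecis(clusters).fit()
        hits = total = 0
        for k, center in enumerate(centers, start=1):
            for _ in range(50):
                s1 = center.s1 + rng.normal(0, 0.06, 3)
                s2 = center.s2 + rng.normal(0, 0.06, 3)
                w = MuccssPoint(d2=center.d2 + rng.normal(0, 0.06),
                                d3=center.d3 + rng.normal(0, 0.06),
                                alpha=center.alpha + rng.normal(0, 0.03),
                                s1=s1 / np.linalg.norm(s1),
                                s2=s2 / np.linalg.norm(s2))
                pred = res.predict_point(w, "P33")
                hits += (pred.best == ("P33", k))
                total += 1
        assert hits / total >= 0.95

    def test_full_pipeline_on_gold_standard(self, gold_standard):
        gs = gold_standard
        model = RNAPrecis.from_suites(
            gs.train_suites, gs.train_labels,
            age_params={p: SYNTHETIC_AGE_PARAMS for p in PAIRS},
            mode_hunt=ModeHuntConfig(seed=7))
        res = model.fit()
        preds = res.predict(gs.test_suites)
        records, table = res.evaluate(preds, gs.answers)
        overall = table[table.dataset == "all"].iloc[0]
        assert overall["matches_pct"] >= 90.0
        # summary table mentions every pair and lambda
        text = res.summary()
        for pair in PAIRS:
            assert pair in text
        assert "lambda" in text

    def test_model_round_trip_through_json(self, rng, tmp_path):
        clusters = [make_cluster(rng, index=i, n=15, label=f"{i}a")[0]
                    for i in range(1, 3)]
        res = RNAPrecis(clusters, lam=0.4).fit()
        path = tmp_path / "model.json"
        res.save(path)
        back = RNAPrecisResults.load(path)
        assert back.lam == 0.4
        w = rand_point(rng, 0.1)
        p1, p2 = res.predict_point(w, "P33"), back.predict_point(w, "P33")
        assert p1.best == p2.best
        assert np.allclose(p1.posteriors, p2.posteriors, atol=1e-9)


def _manifest(rows):
    return LabelTable(pd.DataFrame(
        [{"structure_id": r[0], "chain": "A", "resnum": i + 1, "icode": "",
          "conformer": r[1].split(";")[0], "answer_conformer": r[1],
          "answer_pucker_pair": r[2] if len(r) > 2 else ""}
         for i, r in enumerate(rows)]))


class TestEvaluation:
    def _pred(self, sid, pair, labels, best=("P33", 1)):
        from rnaprecis.classifier import PredictionResult
        return PredictionResult(
            suite_id=sid, pucker_pair=pair, cluster_ids=[best],
            posteriors=np.array([1.0]), mahalanobis={}, best=best,
            predicted_conformers=frozenset(labels))

    def test_multi_label_cluster_matches_any_member(self):
        conf_pairs = {"1b": {"P32"}, "1[": {"P32"}}
        preds = [self._pred(("x", "A", 1, ""), "P32", {"1b", "1["},
                            best=("P32", 1))]
        manifest = _manifest([("x", "1b")])
        records, _ = evaluate_predictions(preds, manifest, conf_pairs)
        assert records[0].category == "prediction_match"

    def test_wrong_pair_is_pucker_mismatch(self):
        conf_pairs = {"6p": {"P22"}, "2a": {"P23"}}
        preds = [self._pred(("x", "A", 1, ""), "P23", {"2a"},
                            best=("P23", 1))]
        manifest = _manifest([("x", "6p")])
        records, _ = evaluate_predictions(preds, manifest, conf_pairs)
        assert records[0].category == "pucker_mismatch"

    def test_any_of_multiple_answers_matches(self):
        conf_pairs = {"1a": {"P33"}, "1c": {"P33"}}
        preds = [self._pred(("x", "A", 1, ""), "P33", {"1c"})]
        manifest = _manifest([("x", "1a;1c")])
        records, _ = evaluate_predictions(preds, manifest, conf_pairs)
        assert records[0].category == "prediction_match"

    def test_unclustered_answer_flagged_mismatch(self):
        conf_pairs = {"1a": {"P33"}}
        preds = [self._pred(("x", "A", 1, ""), "P33", {"1a"})]
        manifest = _manifest([("x", "5n", "P33")])
        records, _ = evaluate_predictions(preds, manifest, conf_pairs)
        assert records[0].category == "prediction_mismatch"
        assert "unclustered-answer" in records[0].flags

    def test_summary_percentages_sum_to_100(self):
        conf_pairs = {"1a": {"P33"}, "1c": {"P33"}}
        preds = [self._pred(("x", "A", i, ""), "P33",
                            {"1a"} if i % 2 else {"1c"})
                 for i in range(1, 6)]
        manifest = LabelTable(pd.DataFrame(
            [{"structure_id": "x", "chain": "A", "resnum": i, "icode": "",
              "conformer": "1a", "answer_conformer": "1a",
              "answer_pucker_pair": ""} for i in range(1, 6)]))
        _, table = evaluate_predictions(preds, manifest, conf_pairs)
        row = table[table.dataset == "P33"].iloc[0]
        total_pct = (row["matches_pct"] + row["mismatches_pct"]
                     + row["pucker_mismatches_pct"])
        assert total_pct == pytest.approx(100.0, abs=0.2)


def test_plot_clusters_smoke(rng, tmp_path):
    import matplotlib
    matplotlib.use("Agg")
    clusters = [make_cluster(rng, index=i, n=12, label=f"{i}a")[0]
                for i in range(1, 3)]
    res = RNAPrecis(clusters).fit()
    ax = res.plot_clusters("P33")
    assert ax.get_xlabel()
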
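"""LLS fitting, ΣLLS integration, thresholding and cross-validation."""

import math

import numpy as np
import pandas as pd
import pytest

from cofracnet.io import ReferenceComplexCatalog
from cofracnet.lls import (
    LlsModel,
    choose_threshold,
    crossvalidate,
    derive_reference_pairs,
    fit_lls,
    percentile_cocomplex_enrichment,
    sum_lls,
)
from cofracnet.scoring import score_all_pairs
from cofracnet.simulate import STATES, simulate_experiment


def scores_frame(pair_scores, technique="SEC", metric="pcc"):
    """Long-format score table from {pair: value}."""
    rows = [
        {"protein_a": a, "protein_b": b, "technique": technique, metric: v}
        for (a, b), v in pair_scores.items()
    ]
    df = pd.DataFrame(rows)
    for m in ("pcc", "wcc", "coapex"):
        if m not in df.columns:
            df[m] = np.nan
    return df


class TestReferencePairs:
    def test_enumerated_example(self):
        cat = ReferenceComplexCatalog({"c1": frozenset("ABC"), "c2": frozenset("CD")})
        pos, neg = derive_reference_pairs(cat, {"A", "B", "C", "D"})
        assert pos == {("A", "B"), ("A", "C"), ("B", "C"), ("C", "D")}
        assert neg == {("A", "D"), ("B", "D")}

    def test_single_complex_has_no_negatives(self):
        cat = ReferenceComplexCatalog({"c1": frozenset("ABC")})
        pos, neg = derive_reference_pairs(cat, {"A", "B", "C"})
        assert neg == set()
        with pytest.raises(ValueError):
            fit_lls(scores_frame({("A", "B"): 0.9}), pos, neg)

    def test_unscored_protein_contributes_no_pairs(self):
        cat = ReferenceComplexCatalog({"c1": frozenset("ABC"), "c2": frozenset("CD")})
        pos, neg = derive_reference_pairs(cat, {"A", "B", "C"})
        assert all("D" not in p for p in pos | neg)

    def test_too_few_catalog_proteins_rejected(self):
        cat = ReferenceComplexCatalog({"c1": frozenset("AB")})
        with pytest.raises(ValueError):
            derive_reference_pairs(cat, {"A", "X"})


class TestFitLls:
    def test_matches_hand_computed_log_odds(self):
        # 10 positives (five scores 0.2, five 0.8), 90 negatives (85 at 0.1,
        # 5 at 0.8); 2 equal-frequency bins split at the positive median.
        scores = {}
        pos, neg = set(), set()
        for i in range(5):
            scores[(f"p{i}", f"q{i}")] = 0.2
            pos.add((f"p{i}", f"q{i}"))
        for i in range(5, 10):
            scores[(f"p{i}", f"q{i}")] = 0.8
            pos.add((f"p{i}", f"q{i}"))
        for i in range(85):
            scores[(f"n{i}", f"m{i}")] = 0.1
            neg.add((f"n{i}", f"m{i}"))
        for i in range(85, 90):
            scores[(f"n{i}", f"m{i}")] = 0.8
            neg.add((f"n{i}", f"m{i}"))
        model = fit_lls(scores_frame(scores), pos, neg, n_bins=2, pseudocount=1.0)
        edges, lls = model.tables[("SEC", "pcc")]
        # oracle: upper bin 5 pos / 5 neg against prior 10/90 -> ln 9;
        # lower bin 5 pos / 85 neg -> ln((6/86)/(10/90))
        assert lls[-1] == pytest.approx(math.log(9.0))
        assert lls[0] == pytest.approx(math.log((6 / 86) / (10 / 90)))

    def test_bin_at_prior_ratio_scores_zero(self):
        scores = {}
        pos, neg = set(), set()
        for i in range(6):
            v = 0.2 if i < 3 else 0.8
            scores[(f"p{i}", f"q{i}")] = v
            pos.add((f"p{i}", f"q{i}"))
            scores[(f"n{i}", f"m{i}")] = v
            neg.add((f"n{i}", f"m{i}"))
        model = fit_lls(scores_frame(scores), pos, neg, n_bins=2)
        _, lls = model.tables[("SEC", "pcc")]
        np.testing.assert_allclose(lls, 0.0, atol=1e-12)

    def test_pseudocount_keeps_empty_class_finite(self):
        scores = {("a", "b"): 0.9, ("c", "d"): 0.9, ("e", "f"): 0.1}
        model = fit_lls(
            scores_frame(scores), {("a", "b"), ("c", "d")}, {("e", "f")}, n_bins=2
        )
        _, lls = model.tables[("SEC", "pcc")]
        assert np.isfinite(lls).all()
        assert lls[-1] > 0  # positive-only bin

    def test_identical_scores_collapse_to_single_bin(self):
        scores = {("a", "b"): 0.5, ("c", "d"): 0.5, ("e", "f"): 0.5}
        model = fit_lls(
            scores_frame(scores), {("a", "b"), ("c", "d")}, {("e", "f")}, n_bins=10
        )
        edges, lls = model.tables[("SEC", "pcc")]
        assert len(edges) == 0 and len(lls) == 1


class TestSumLls:
    def _model(self, lls_by_source):
        tables = {
            key: (np.array([0.5]), np.array(vals, dtype=float))
            for key, vals in lls_by_source.items()
        }
        return LlsModel(tables=tables, prior_odds=1.0)

    def test_additivity_over_evidence(self):
        model = self._model({("SEC", "pcc"): [0, 1.2], ("IEC", "pcc"): [0, 0.8]})
        scores = pd.concat(
            [
                scores_frame({("a", "b"): 0.9}, technique="SEC"),
                scores_frame({("a", "b"): 0.9}, technique="IEC"),
            ]
        )
        out = sum_lls(model, scores)
        assert out.loc[0, "sigma_lls"] == pytest.approx(2.0)

    def test_zero_bins_give_zero_sum(self):
        model = self._model({("SEC", "pcc"): [0.0, 0.0]})
        out = sum_lls(model, scores_frame({("a", "b"): 0.9}))
        assert out.loc[0, "sigma_lls"] == 0.0

    def test_missing_evidence_contributes_nothing(self):
        model = self._model({("SEC", "pcc"): [0, 1.5], ("SEC", "wcc"): [0, 9.9]})
        out = sum_lls(model, scores_frame({("a", "b"): 0.9}))  # wcc is NaN
        assert out.loc[0, "sigma_lls"] == pytest.approx(1.5)


class TestThreshold:
    def _sigma(self, values):
        return pd.DataFrame(
            {
                "protein_a": [f"a{i}" for i in range(len(values))],
                "protein_b": [f"b{i}" for i in range(len(values))],
                "sigma_lls": values,
            }
        )

    def test_perfect_separation_has_auc_one(self):
        sigma = self._sigma([5.0, 4.0, -1.0, -2.0])
        pos = {("a0", "b0"), ("a1", "b1")}
        neg = {("a2", "b2"), ("a3", "b3")}
        net = choose_threshold(sigma, pos, neg, fixed=None)
        assert net.auc == 1.0
        assert set(zip(net.edges.protein_a, net.edges.protein_b)) == pos

    def test_random_scores_have_chance_auc(self):
        rng = np.random.default_rng(0)
        n = 4000
        sigma = self._sigma(rng.normal(size=n))
        labels = rng.random(n) < 0.5
        pos = {(f"a{i}", f"b{i}") for i in range(n) if labels[i]}
        neg = {(f"a{i}", f"b{i}") for i in range(n) if not labels[i]}
        net = choose_threshold(sigma, pos, neg, fixed=None)
        assert abs(net.auc - 0.5) < 0.03

    def test_fixed_cutoff_eliminates_low_edges(self):
        sigma = self._sigma([1.44, 1.45, 1.46, 3.0, -2.0])
        pos = {("a3", "b3")}
        neg = {("a4", "b4")}
        net = choose_threshold(sigma, pos, neg, fixed=1.45)
        assert (net.edges.sigma_lls > 1.45).all()
        assert len(net.edges) == 2  # 1.46 and 3.0 only

    def test_single_class_labels_rejected(self):
        sigma = self._sigma([1.0, 2.0])
        with pytest.raises(ValueError):
            choose_threshold(sigma, {("a0", "b0"), ("a1", "b1")}, set())


class TestCrossValidation:
    def test_invalid_fold_counts_rejected(self, small_truth):
        cat = small_truth.catalog(STATES[0])
        scores = scores_frame({("P0000", "P0001"): 0.5})
        with pytest.raises(ValueError):
            crossvalidate(cat, scores, k=1)
        with pytest.raises(ValueError):
            crossvalidate(cat, scores, k=len(cat.complexes) + 1)

    def test_deterministic_and_better_than_chance(self, small_truth):
        exps = [
            simulate_experiment(small_truth, STATES[0], t, r)
            for t in ("SEC", "IEC")
            for r in ("r1", "r2")
        ]
        scores = score_all_pairs(exps)[STATES[0]]
        cat = small_truth.catalog(STATES[0])
        a = crossvalidate(cat, scores, k=4, seed=3)
        b = crossvalidate(cat, scores, k=4, seed=3)
        assert a == b
        assert len(a) == 4
        assert all(auc > 0.5 for auc in a)


class TestPercentileEnrichment:
    def _toy(self):
        cat = ReferenceComplexCatalog(
            {"c1": frozenset(["A", "B", "C"]), "c2": frozenset(["D", "E"])}
        )
        # 10 scored catalog pairs; the 2 top-scoring are co-complex
        pairs = [("A", "B"), ("D", "E"), ("A", "D"), ("A", "E"), ("B", "D"),
                 ("B", "E"), ("C", "D"), ("C", "E"), ("A", "C"), ("B", "C")]
        sigma = pd.DataFrame(
            {
                "protein_a": [p[0] for p in pairs],
                "protein_b": [p[1] for p in pairs],
                "sigma_lls": [9.0, 8.0, 1, 1, 1, 1, 1, 1, 0.5, 0.4],
            }
        )
        return cat, sigma

    def test_top_percentile_enrichment_matches_enumeration(self):
        cat, sigma = self._toy()
        res = percentile_cocomplex_enrichment(sigma, cat, percentile=0.2)
        # oracle: P(both of 2 drawn are among the 4 co-complex of 10)
        assert res["k"] == 2 and res["n"] == 2 and res["K"] == 4 and res["N"] == 10
        assert res["p"] == pytest.approx((4 * 3) / (10 * 9))

    def test_selecting_everything_is_unenriched(self):
        cat, sigma = self._toy()
        res = percentile_cocomplex_enrichment(sigma, cat, percentile=0.999)
        assert res["n"] == 10
        assert res["p"] == pytest.approx(1.0)

    def test_bad_percentile_and_no_overlap_rejected(self):
        cat, sigma = self._toy()
        with pytest.raises(ValueError):
            percentile_cocomplex_enrichment(sigma, cat, percentile=1.5)
        lonely = sigma.assign(protein_a="X", protein_b="Y")
        with pytest.raises(ValueError):
            percentile_cocomplex_enrichment(lonely, cat)


class TestCalibration:
    def test_shuffled_labels_give_near_zero_lls(self):
        rng = np.random.default_rng(1)
        n = 4000
        scores = {(f"x{i}", f"y{i}"): rng.random() for i in range(n)}
        labels = rng.random(n) < 0.5
        pos = {p for p, keep in zip(scores, labels) if keep}
        neg = set(scores) - pos
        model = fit_lls(scores_frame(scores), pos, neg, n_bins=10)
        _, lls = model.tables[("SEC", "pcc")]
        assert np.abs(lls).max() < 0.4
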
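"""Naive Bayes pair classifier: counts, scoring, LOO, calibration, prediction."""

import math

import numpy as np
import pytest

from posmna.model import (
    PairInteractionClassifier,
    PairRecord,
    PredictionRecord,
    ActivityPrediction,
    TrainingTable,
    classify,
    cond_prob,
    fit,
    pa_pi,
    score,
)
from posmna.errors import ModelError

from conftest import abstract_table


def tiny_table():
    pairs = [
        PairRecord(("a", "b"), frozenset({"X"}), frozenset({"d1", "d2"})),
        PairRecord(("a", "c"), frozenset({"Y"}), frozenset({"d2", "d3"})),
        PairRecord(("b", "c"), frozenset({"X"}), frozenset({"d3"})),
    ]
    return TrainingTable(pairs=pairs, activities=("X", "Y"))


class TestFit:
    def test_counts_match_hand_tally(self):
        m = fit(tiny_table())
        # descriptor d2 occurs in 2 pairs, 1 of which is labeled Y
        assert m.n_pairs_ == 3
        i = m.descriptor_index_["d2"]
        jY = m.activities_.index("Y")
        assert m.n_with_descriptor_[i] == 2
        assert m.n_active_with_descriptor_[i, jY] == 1

    def test_activity_without_negatives_rejected(self):
        pairs = [
            PairRecord(("a", "b"), frozenset({"X"}), frozenset({"d1"})),
            PairRecord(("a", "c"), frozenset({"X"}), frozenset({"d2"})),
        ]
        table = TrainingTable(pairs=pairs, activities=("X",))
        with pytest.raises(ModelError, match="X"):
            fit(table)

    def test_activity_without_positives_rejected(self):
        clf = PairInteractionClassifier(activities=("X", "Y"))
        with pytest.raises(ModelError, match="Y"):
            clf.fit([{"d1"}, {"d2"}], [["X"], []])

    def test_planted_counts_recovered(self, rng):
        table = abstract_table(rng, n_pairs=50)
        m = fit(table)
        for j, a in enumerate(m.activities_):
            assert m.n_active_[j] == sum(a in p.labels for p in table.pairs)

    def test_calibration_array_sizes(self, rng):
        table = abstract_table(rng)
        m = fit(table)
        for j in range(len(m.activities_)):
            assert len(m.calibration_active_[j]) == m.n_active_[j]
            assert len(m.calibration_inactive_[j]) == m.n_pairs_ - m.n_active_[j]


class TestConditionalProbability:
    def test_smoothed_estimate(self):
        m = fit(tiny_table(), smoothing=1.0)
        # d2: n_d=2, n_Y=1 of them; p_Y = 1/3 -> (1 + 1/3)/3
        assert cond_prob(m, "Y", "d2") == pytest.approx((1 + 1 / 3) / 3)

    def test_unseen_descriptor_falls_back_to_prior(self):
        m = fit(tiny_table())
        assert cond_prob(m, "Y", "never-seen") == pytest.approx(1 / 3)

    def test_unsmoothed_limit(self):
        pairs = [
            PairRecord(("a", "b"), frozenset({"X"}), frozenset({"d"})),
            PairRecord(("a", "c"), frozenset({"X"}), frozenset({"d"})),
            PairRecord(("b", "c"), frozenset({"Y"}), frozenset({"e"})),
        ]
        m = fit(TrainingTable(pairs=pairs, activities=("X", "Y")), smoothing=0.0)
        assert cond_prob(m, "X", "d") == 1.0
        assert cond_prob(m, "X", "e") == 0.0


class TestScore:
    def test_all_half_probabilities_give_zero(self):
        # engineered so every conditional probability is exactly 1/2
        pairs = [
            PairRecord(("a", "b"), frozenset({"X"}), frozenset({"d"})),
            PairRecord(("a", "c"), frozenset({"Y"}), frozenset({"d"})),
        ]
        m = fit(TrainingTable(pairs=pairs, activities=("X", "Y")), smoothing=0.0)
        assert score(m, "X", {"d"}) == pytest.approx(0.0, abs=1e-15)

    def test_certain_descriptors_reach_upper_bound(self):
        pairs = [
            PairRecord(("a", "b"), frozenset({"X"}), frozenset({"d"})),
            PairRecord(("a", "c"), frozenset({"Y"}), frozenset({"e"})),
        ]
        m = fit(TrainingTable(pairs=pairs, activities=("X", "Y")), smoothing=0.0)
        assert score(m, "X", {"d"}) == pytest.approx(math.pi / 2)

    def test_equals_bruteforce_summation(self, rng):
        table = abstract_table(rng)
        m = fit(table)
        D = sorted({d for p in table.pairs for d in p.descriptors})[:10]
        for a in m.activities_:
            expected = np.mean(
                [math.asin(2 * cond_prob(m, a, d) - 1) for d in D]
            )
            assert score(m, a, D) == pytest.approx(expected, abs=1e-12)

    def test_empty_set_rejected(self, rng):
        m = fit(abstract_table(rng))
        with pytest.raises(ModelError):
            score(m, "A", set())

    def test_strictly_increasing_in_descriptor_evidence(self):
        # replacing an unseen descriptor by an active-associated one raises S
        pairs = [
            PairRecord(("a", "b"), frozenset({"X"}), frozenset({"d", "e"})),
            PairRecord(("a", "c"), frozenset({"X"}), frozenset({"d"})),
            PairRecord(("b", "c"), frozenset({"Y"}), frozenset({"f"})),
        ]
        m = fit(TrainingTable(pairs=pairs, activities=("X", "Y")))
        assert score(m, "X", {"d", "u1"}) > score(m, "X", {"u0", "u1"})


class TestLeaveOneOut:
    def test_two_pair_table_equals_refit_on_other(self):
        pairs = [
            PairRecord(("a", "b"), frozenset({"X"}), frozenset({"d1", "d2"})),
            PairRecord(("a", "c"), frozenset({"Y"}), frozenset({"d2"})),
        ]
        table = TrainingTable(pairs=pairs, activities=("X", "Y"))
        m = fit(table)
        # the single remaining pair is not labeled X, so excluding pair 0
        # leaves p_X = 0 and every descriptor prior-driven: score = arcsin(-1)
        assert m.loo_scores_[0, 0] == pytest.approx(-math.pi / 2)

    def test_analytic_equals_bruteforce_retraining(self, rng):
        """The analytic count-exclusion LOO equals refitting without the pair
        for every pair and activity of a 30-pair, 3-activity table."""
        table = abstract_table(rng, n_pairs=30)
        m = fit(table)
        for i, held_out in enumerate(table.pairs):
            rest = table.pairs[:i] + table.pairs[i + 1 :]
            refit = PairInteractionClassifier(activities=table.activities).fit(
                [p.descriptors for p in rest], [sorted(p.labels) for p in rest]
            )
            for j, a in enumerate(table.activities):
                brute = refit.score_pair(a, held_out.descriptors)
                assert abs(brute - m.loo_scores_[i, j]) <= 1e-12

    def test_all_unseen_after_exclusion_gives_prior_score(self):
        pairs = [
            PairRecord(("a", "b"), frozenset({"X"}), frozenset({"solo"})),
            PairRecord(("a", "c"), frozenset({"X"}), frozenset({"d"})),
            PairRecord(("b", "c"), frozenset({"Y"}), frozenset({"d"})),
            PairRecord(("b", "d"), frozenset({"Y"}), frozenset({"d"})),
        ]
        m = fit(TrainingTable(pairs=pairs, activities=("X", "Y")))
        # pair 0's only descriptor vanishes once excluded: prior-only score
        p_x = 1 / 3  # one X positive left among three remaining pairs
        assert m.loo_scores_[0, 0] == pytest.approx(math.asin(2 * p_x - 1))


class TestCalibration:
    def make_model_with_calibration(self, actives, inactives):
        m = PairInteractionClassifier(activities=("X",))
        m.activities_ = ("X",)
        m.descriptor_index_ = {}
        m.calibration_active_ = [np.sort(np.asarray(actives, dtype=float))]
        m.calibration_inactive_ = [np.sort(np.asarray(inactives, dtype=float))]
        return m

    def test_rank_counting(self):
        m = self.make_model_with_calibration([1, 2, 3], [0, 1])
        pa, pi = pa_pi(m, "X", 2.5)
        assert (pa, pi) == (pytest.approx(2 / 3), pytest.approx(0.0))

    def test_extremes(self):
        m = self.make_model_with_calibration([1, 2, 3], [0, 1])
        assert pa_pi(m, "X", -10) == (0.0, 1.0)
        assert pa_pi(m, "X", 10) == (1.0, 0.0)

    def test_tie_convention(self):
        m = self.make_model_with_calibration([2.0], [0.0, 2.0])
        pa, pi = pa_pi(m, "X", 2.0)
        assert pa == pytest.approx(0.5)
        assert pi == pytest.approx(0.25)

    def test_pa_nondecreasing_pi_nonincreasing(self, rng):
        table = abstract_table(rng)
        m = fit(table)
        grid = np.linspace(-1.6, 1.6, 60)
        for a in m.activities_:
            vals = [pa_pi(m, a, s) for s in grid]
            pas = [v[0] for v in vals]
            pis = [v[1] for v in vals]
            assert all(x <= y + 1e-15 for x, y in zip(pas, pas[1:]))
            assert all(x >= y - 1e-15 for x, y in zip(pis, pis[1:]))


class TestPrediction:
    def test_record_shape_and_ranking(self, rng):
        table = abstract_table(rng)
        m = fit(table)
        rec = m.predict_record(table.pairs[0].descriptors)
        assert len(rec.rows) == len(m.activities_)
        dps = [r.dp for r in rec.rows]
        assert dps == sorted(dps, reverse=True)
        for r in rec.rows:
            assert 0.0 <= r.pa <= 1.0
            assert 0.0 <= r.pi <= 1.0
            assert r.dp == pytest.approx(r.pa - r.pi)

    def test_classify_threshold(self):
        rows = tuple(
            ActivityPrediction(a, 0.0, pa, pi, pa - pi)
            for a, pa, pi in [("X", 0.9, 0.1), ("Y", 0.3, 0.35), ("Z", 0.2, 0.8)]
        )
        rec = PredictionRecord(pair_id=("a", "b"), rows=rows)
        assert classify(rec) == {"X"}
        assert classify(rec, threshold=0.9) == set()
        all_neg = PredictionRecord(
            pair_id=("a", "b"),
            rows=tuple(
                ActivityPrediction(a, 0.0, 0.1, 0.5, -0.4) for a in "XYZ"
            ),
        )
        assert classify(all_neg) == set()

    def test_rank_invariance_under_monotone_transform(self, rng):
        """Applying a strictly increasing transform to every raw score leaves
        Pa, Pi (hence dP ranking) unchanged."""
        table = abstract_table(rng)
        m = fit(table)
        D = table.pairs[3].descriptors
        baseline = m.predict_record(D)

        import copy

        warped = copy.deepcopy(m)
        transform = lambda s: np.expm1(3.0 * s)  # strictly increasing
        warped.calibration_active_ = [
            transform(a) for a in m.calibration_active_
        ]
        warped.calibration_inactive_ = [
            transform(a) for a in m.calibration_inactive_
        ]
        for j, a in enumerate(m.activities_):
            s = m.score_pair(a, D)
            pa, pi = warped.pa_pi(a, float(transform(np.asarray(s))))
            row = [r for r in baseline.rows if r.activity == a][0]
            assert pa == pytest.approx(row.pa, abs=1e-12)
            assert pi == pytest.approx(row.pi, abs=1e-12)

    def test_synthetic_planted_rule_ranks_first(self, small_library):
        from posmna.synthdata import default_rules, generate_pair_table
        from posmna.descriptors import mna_set, posmna_set
        from conftest import build_table
        from posmna.model import CYP_ACTIVITIES

        records, graphs = small_library
        rules = default_rules(graphs)
        rows, truth = generate_pair_table(3, graphs, 60, rules=rules)
        table = build_table(rows, graphs, CYP_ACTIVITIES)
        m = fit(table)
        mna = {mid: mna_set(g) for mid, g in graphs.items()}
        hits = 0
        for a, b, act in rows[:20]:
            D = posmna_set(mna[a], mna[b]).descriptors
            planted = truth["planted"][f"{min(a, b)}|{max(a, b)}"]
            hits += m.predict_record(D).top().activity == planted
        assert hits >= 19


class TestSklearnInterface:
    def test_get_set_params(self):
        clf = PairInteractionClassifier(smoothing=2.0)
        assert clf.get_params()["smoothing"] == 2.0
        clf.set_params(threshold=0.1)
        assert clf.threshold == 0.1

    def test_predict_matrix_shape(self, rng):
        table = abstract_table(rng)
        m = fit(table)
        X = [p.descriptors for p in table.pairs[:5]]
        y = m.predict(X)
        assert y.shape == (5, len(m.activities_))
        assert y.dtype == bool

    def test_unfitted_raises(self):
        with pytest.raises(ModelError):
            PairInteractionClassifier().decision_function([{"d"}])
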
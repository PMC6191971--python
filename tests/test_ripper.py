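import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.model_selection import StratifiedKFold

from camur.ripper import (
    Conjunction,
    LearnerParams,
    Literal,
    Metrics,
    RuleModel,
    candidate_thresholds,
    cross_validate,
    evaluate_model,
    foil_gain,
    grow_conjunction,
    learn_model,
    parse_rule,
    predict,
    prune_conjunction,
)
from conftest import make_matrix


def brute_force_boundary_midpoints(values, labels):
    """Independent O(n^2) re-derivation of candidate thresholds."""
    pairs = sorted(zip(values, labels))
    uniq = sorted(set(values))
    out = []
    for a, b in zip(uniq, uniq[1:]):
        set_a = {lab for v, lab in pairs if v == a}
        set_b = {lab for v, lab in pairs if v == b}
        if set_a != set_b:
            out.append((a + b) / 2.0)
    return out


class TestCandidateThresholds:
    def test_single_boundary(self):
        assert candidate_thresholds([1.0, 2.0], [True, False]) == [1.5]

    def test_all_equal(self):
        assert candidate_thresholds([1.0, 1.0, 1.0], [True, False, True]) == []

    def test_block_boundary_matches_brute_force(self):
        values = [1.0, 2.0, 3.0, 4.0]
        labels = [True, True, False, False]
        got = candidate_thresholds(values, labels)
        assert got == [2.5]
        assert got == brute_force_boundary_midpoints(values, labels)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            candidate_thresholds([1.0, 2.0], [True])

    @given(st.lists(st.tuples(st.integers(min_value=0, max_value=6),
                              st.booleans()), min_size=1, max_size=25))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force(self, pairs):
        values = [float(v) for v, _ in pairs]
        labels = [lab for _, lab in pairs]
        assert candidate_thresholds(values, labels) == \
            brute_force_boundary_midpoints(values, labels)


class TestFoilGain:
    def test_worked_example(self):
        # 8 * (log2(8/9) - log2(1/2))
        assert foil_gain(10, 10, 8, 1) == pytest.approx(6.640599988461501)

    def test_identical_purity_is_zero(self):
        assert foil_gain(10, 10, 5, 5) == pytest.approx(0.0)
        assert foil_gain(6, 3, 4, 2) == pytest.approx(0.0)

    def test_no_positives_is_neg_inf(self):
        assert foil_gain(10, 10, 0, 3) == float("-inf")

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            foil_gain(2, 0, 5, 0)
        with pytest.raises(ValueError):
            foil_gain(-1, 0, 0, 0)


class TestGrowConjunction:
    def test_separable_1d_single_literal(self):
        values = [[1.0], [2.0], [3.0], [4.0], [8.0], [9.0], [10.0], [11.0]]
        labels = ["T", "T", "T", "T", "N", "N", "N", "N"]
        m = make_matrix(values, labels)
        conj = grow_conjunction(m, positive_class="T")
        assert len(conj) == 1
        lit = conj.literals[0]
        assert lit.op == "<"
        assert lit.threshold == pytest.approx(6.0)
        mask = conj.covers_matrix(m)
        assert mask[:4].all() and not mask[4:].any()

    def test_pure_grow_set_stops_covering_all_positives(self):
        m = make_matrix([[1.0], [2.0]], ["T", "T"])
        conj = grow_conjunction(m, positive_class="T")
        assert len(conj) <= 1
        # everything (all positives) stays covered
        assert conj.covers_matrix(m).all() if len(conj) == 0 else \
            conj.covers_matrix(m).any()

    def test_xor_quadrant_needs_two_literals(self):
        values = [
            [1, 1], [2, 2], [1, 2], [2, 1],            # positive quadrant
            [1, 8], [2, 9], [8, 1], [9, 2], [8, 8], [9, 9],
        ]
        labels = ["T"] * 4 + ["N"] * 6
        m = make_matrix(values, labels)
        conj = grow_conjunction(m, positive_class="T")
        assert len(conj) == 2
        mask = conj.covers_matrix(m)
        assert mask[:4].all() and not mask[4:].any()
        # brute force: some <=2-literal conjunction isolates the quadrant;
        # the grown one must match that optimum (full positive, no negative)
        y = np.array([lab == "T" for lab in labels])
        assert (mask == y).all()

    def test_requires_positive_samples(self):
        m = make_matrix([[1.0], [2.0]], ["N", "N"])
        with pytest.raises(ValueError):
            grow_conjunction(m, positive_class="T")


class TestPruneConjunction:
    def _value(self, conj, m, pos="T"):
        mask = conj.covers_matrix(m)
        y = np.array([lab == pos for lab in m.labels])
        p = int((mask & y).sum())
        n = int((mask & ~y).sum())
        return (p - n) / (p + n) if p + n else -1.0

    def test_perfect_conjunction_unchanged(self):
        m = make_matrix([[1.0, 1.0]] * 5 + [[9.0, 9.0]] * 5, ["T"] * 5 + ["N"] * 5)
        conj = Conjunction((Literal("g0", "<", 5.0),))
        assert prune_conjunction(conj, m, positive_class="T") == conj

    def test_tie_prefers_shorter(self):
        # dropping the redundant last literal leaves v unchanged
        m = make_matrix([[1.0, 1.0]] * 5 + [[9.0, 9.0]] * 5, ["T"] * 5 + ["N"] * 5)
        conj = Conjunction((Literal("g0", "<", 5.0), Literal("g1", "<", 5.0)))
        pruned = prune_conjunction(conj, m, positive_class="T")
        assert pruned.literals == (Literal("g0", "<", 5.0),)

    def test_suffix_truncation_matches_greedy_oracle(self):
        # prune set engineered so the 2-literal prefix beats the full
        # 3-literal conjunction
        m = make_matrix(
            [[1.0, 1.0, 1.0], [1.0, 1.0, 6.0], [1.0, 20.0, 1.0]],
            ["T", "T", "N"],
        )
        conj = Conjunction((
            Literal("g0", "<", 10.0),
            Literal("g1", "<", 10.0),
            Literal("g2", "<", 5.0),
        ))
        # independent greedy oracle over suffix truncations
        literals = list(conj.literals)
        current = self._value(conj, m)
        while len(literals) > 1:
            shorter = Conjunction(tuple(literals[:-1]))
            v = self._value(shorter, m)
            if v >= current:
                literals.pop()
                current = v
            else:
                break
        expected = Conjunction(tuple(literals))
        assert len(expected) == 2  # the engineered optimum
        assert prune_conjunction(conj, m, positive_class="T") == expected


class TestMetrics:
    def test_worked_example(self):
        met = Metrics(tp=8, fp=2, fn=1, tn=9)
        assert met.precision == pytest.approx(0.8)
        assert met.recall == pytest.approx(8 / 9)
        assert met.f_measure == pytest.approx(0.8421052631578948)
        assert met.accuracy == pytest.approx(0.85)

    def test_degenerate_zero(self):
        met = Metrics(tp=0, fp=0, fn=0, tn=5)
        assert met.precision == 0.0
        assert met.recall == 0.0
        assert met.f_measure == 0.0
        assert met.accuracy == 1.0

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50))
    @settings(max_examples=100, deadline=None)
    def test_identities(self, tp, fp, fn, tn):
        met = Metrics(tp, fp, fn, tn)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        assert met.precision == pytest.approx(prec)
        assert met.recall == pytest.approx(rec)
        if prec + rec:
            assert met.f_measure == pytest.approx(2 * prec * rec / (prec + rec))
        else:
            assert met.f_measure == 0.0
        if tp + fp + fn + tn:
            assert met.accuracy == pytest.approx((tp + tn) / (tp + fp + fn + tn))


class TestPredict:
    MODEL = RuleModel(
        positive_class="Tumoral",
        default_class="Normal",
        conjunctions=(
            Conjunction((Literal("ENSG00000167676.3", "<", 16.15),)),
            Conjunction((Literal("ENSG00000166819.10", "<", 15.28),)),
        ),
    )

    def test_first_literal_covers(self):
        sample = {"ENSG00000167676.3": 10.0, "ENSG00000166819.10": 20.0}
        assert predict(self.MODEL, sample) == "Tumoral"

    def test_strict_boundary(self):
        sample = {"ENSG00000167676.3": 16.15, "ENSG00000166819.10": 15.28}
        assert predict(self.MODEL, sample) == "Normal"

    def test_empty_model_predicts_default(self):
        model = RuleModel(positive_class="Tumoral", default_class="Normal")
        assert predict(model, {}) == "Normal"

    def test_missing_gene_errors(self):
        with pytest.raises(KeyError):
            predict(self.MODEL, {"ENSG00000167676.3": 20.0})

    def test_invariant_to_non_model_genes(self):
        base = {"ENSG00000167676.3": 10.0, "ENSG00000166819.10": 20.0}
        for junk in (0.0, 1e9, -5.0):
            assert predict(self.MODEL, {**base, "OTHER": junk}) == "Tumoral"


class TestEvaluateModel:
    def test_confusion_counts(self):
        # literal covers the first 10 samples: 8 T + 2 N; uncovered: 1 T + 9 N
        values = [[0.0]] * 10 + [[1.0]] * 10
        labels = ["T"] * 8 + ["N"] * 2 + ["T"] * 1 + ["N"] * 9
        m = make_matrix(values, labels)
        model = RuleModel("T", "N",
                          (Conjunction((Literal("g0", "<", 0.5),)),))
        met = evaluate_model(model, m)
        assert (met.tp, met.fp, met.fn, met.tn) == (8, 2, 1, 9)
        assert met.f_measure == pytest.approx(0.8421052631578948)

    def test_perfect_model(self):
        m = make_matrix([[0.0], [0.0], [1.0]], ["T", "T", "N"])
        model = RuleModel("T", "N", (Conjunction((Literal("g0", "<", 0.5),)),))
        met = evaluate_model(model, m)
        assert met.precision == met.recall == met.f_measure == met.accuracy == 1.0

    def test_model_covering_nothing(self):
        m = make_matrix([[1.0], [1.0]], ["T", "N"])
        model = RuleModel("T", "N", (Conjunction((Literal("g0", "<", 0.0),)),))
        met = evaluate_model(model, m)
        assert met.recall == 0.0
        assert met.f_measure == 0.0


def separable_matrix(n_noise_genes=0, n_per_class=10, seed=0):
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, 5.0, size=n_per_class)
    neg = rng.uniform(7.0, 12.0, size=n_per_class)
    values = np.concatenate([pos, neg])[:, None]
    if n_noise_genes:
        noise = rng.lognormal(2.0, 1.0, size=(2 * n_per_class, n_noise_genes))
        values = np.hstack([values, noise])
    labels = ["T"] * n_per_class + ["N"] * n_per_class
    return make_matrix(values, labels)


class TestLearnModel:
    def test_separable_single_literal(self):
        m = separable_matrix()
        model = learn_model(m, LearnerParams(positive_class="T", seed=1))
        assert len(model.conjunctions) == 1
        assert len(model.conjunctions[0]) == 1
        assert evaluate_model(model, m).f_measure == 1.0

    def test_noise_genes_do_not_distract(self):
        m = separable_matrix(n_noise_genes=100, n_per_class=20, seed=2)
        model = learn_model(m, LearnerParams(positive_class="T", seed=1))
        assert model.genes() == {"g0"}
        assert evaluate_model(model, m).f_measure == 1.0

    def test_pure_noise_has_low_cv_f(self, null60):
        m, _ = null60
        cv = cross_validate(m, LearnerParams(seed=1))
        assert cv.f_measure < 0.8

    def test_single_class_rejected(self):
        m = make_matrix([[1.0], [2.0]], ["T", "T"])
        with pytest.raises(ValueError):
            learn_model(m, LearnerParams(positive_class="T"))

    def test_absent_positive_class_rejected(self):
        m = make_matrix([[1.0], [2.0]], ["T", "N"])
        with pytest.raises(ValueError):
            learn_model(m, LearnerParams(positive_class="X"))

    def test_deterministic_given_seed(self):
        m = separable_matrix(n_noise_genes=10, seed=4)
        a = learn_model(m, LearnerParams(positive_class="T", seed=7))
        b = learn_model(m, LearnerParams(positive_class="T", seed=7))
        assert a == b
        assert a.text == b.text

    def test_every_conjunction_covers_a_positive(self, redundant6):
        m, _ = redundant6
        model = learn_model(m, LearnerParams(seed=1))
        y = np.array([lab == model.positive_class for lab in m.labels])
        for conj in model.conjunctions:
            assert (conj.covers_matrix(m) & y).any()

    def test_auto_positive_class_is_minority(self):
        values = [[0.0]] * 3 + [[9.0]] * 7
        m = make_matrix(values, ["Normal"] * 3 + ["Tumoral"] * 7)
        model = learn_model(m, LearnerParams(seed=1))
        assert model.positive_class == "Normal"
        assert model.default_class == "Tumoral"


class TestCrossValidate:
    def test_separable_pooled_f_is_one(self):
        m = separable_matrix(n_per_class=15, seed=5)
        met = cross_validate(m, LearnerParams(positive_class="T", cv_folds=5, seed=1))
        assert met.f_measure == 1.0
        assert met.tp + met.fp + met.fn + met.tn == m.n_samples

    def test_label_permuted_below_gate(self):
        rng = np.random.default_rng(11)
        m = separable_matrix(n_per_class=15, seed=5)
        labels = list(m.labels)
        rng.shuffle(labels)
        m2 = make_matrix(m.values, labels)
        met = cross_validate(m2, LearnerParams(positive_class="T", cv_folds=5, seed=1))
        assert met.f_measure < 0.8

    def test_matches_manual_fold_enumeration(self):
        m = separable_matrix(n_per_class=2, seed=6)  # 4-sample toy, k = 2
        params = LearnerParams(positive_class="T", cv_folds=2, seed=3)
        met = cross_validate(m, params)

        y = np.array([lab == "T" for lab in m.labels])
        skf = StratifiedKFold(n_splits=2, shuffle=True, random_state=3)
        tp = fp = fn = tn = 0
        for train_idx, test_idx in skf.split(np.zeros(4), y):
            model = learn_model(m.take_samples(train_idx), params)
            fold = evaluate_model(model, m.take_samples(test_idx))
            tp, fp, fn, tn = tp + fold.tp, fp + fold.fp, fn + fold.fn, tn + fold.tn
        assert (met.tp, met.fp, met.fn, met.tn) == (tp, fp, fn, tn)

    def test_class_smaller_than_k(self):
        m = separable_matrix(n_per_class=3)
        with pytest.raises(ValueError):
            cross_validate(m, LearnerParams(positive_class="T", cv_folds=5))


class TestRuleText:
    def test_example_rule_round_trip(self):
        text = "(ENSG00000167676.3 < 16.15) OR (ENSG00000166819.10 < 15.28) => Tumoral"
        model = parse_rule(text, default_class="Normal")
        assert model.positive_class == "Tumoral"
        assert len(model.conjunctions) == 2
        assert model.conjunctions[0].literals[0] == \
            Literal("ENSG00000167676.3", "<", 16.15)
        assert model.text == text

    def test_multi_literal_conjunction(self):
        text = "((g1 >= 2) AND (g2 < 3.5)) OR (g3 < 1) => T"
        model = parse_rule(text)
        assert len(model.conjunctions) == 2
        assert len(model.conjunctions[0]) == 2
        assert model.text == text

    def test_six_significant_digits(self):
        lit = Literal("g", "<", 283.85128041858525)
        assert lit.text == "(g < 283.851)"

    def test_malformed_rejected(self):
        with pytest.raises(ValueError):
            parse_rule("nonsense")
        with pytest.raises(ValueError):
            parse_rule("(g ! 3) => T")

    @given(
        st.lists(
            st.lists(
                st.tuples(
                    st.sampled_from(["gA.1", "gB.2", "gC.3", "gD.4"]),
                    st.sampled_from(["<", ">="]),
                    st.floats(min_value=-1e6, max_value=1e6,
                              allow_nan=False, allow_infinity=False),
                ),
                min_size=1, max_size=3,
                unique_by=lambda t: (t[0], t[1]),
            ),
            min_size=1, max_size=3,
        )
    )
    @settings(max_examples=80, deadline=None)
    def test_format_parse_fixed_point(self, conj_specs):
        model = RuleModel(
            "Tumoral", "Normal",
            tuple(Conjunction(tuple(Literal(g, op, t) for g, op, t in spec))
                  for spec in conj_specs),
        )
        reparsed = parse_rule(model.text, default_class="Normal")
        assert reparsed.text == model.text
        assert [len(c) for c in reparsed.conjunctions] == \
            [len(c) for c in model.conjunctions]
        assert reparsed.genes() == model.genes()
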
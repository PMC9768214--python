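"""Group statistics and subjective-scale state labeling."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import neurostates as ns
from neurostates.stats import _STATE_RULES, _GRADE_RANK


# -- independent textbook-formula oracles --------------------------------

def oracle_ttest(a, b):
    na, nb = len(a), len(b)
    ma, mb = np.mean(a), np.mean(b)
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    from scipy.stats import t as tdist

    p = 2 * tdist.sf(abs(t), na + nb - 2)
    return t, p


def oracle_cohens_d(a, b):
    na, nb = len(a), len(b)
    va = np.var(a, ddof=1)
    vb = np.var(b, ddof=1)
    sp = math.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    return (np.mean(a) - np.mean(b)) / sp


class TestTwoSampleTTest:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        t, p = ns.two_sample_ttest(a, a.copy())
        assert t == 0.0 and p == 1.0

    def test_swapping_groups_negates_t(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
        t1, p1 = ns.two_sample_ttest(a, b)
        t2, p2 = ns.two_sample_ttest(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_matches_textbook_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([3.0, 4.0, 5.0, 6.0, 7.0])
        t, p = ns.two_sample_ttest(a, b)
        to, po = oracle_ttest(a, b)
        assert t == pytest.approx(to, abs=1e-10)
        assert p == pytest.approx(po, abs=1e-10)

    def test_matches_oracle_on_random_data(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = rng.normal(0, 2, int(rng.integers(3, 20)))
            b = rng.normal(0.5, 1, int(rng.integers(3, 20)))
            t, p = ns.two_sample_ttest(a, b)
            to, po = oracle_ttest(a, b)
            assert t == pytest.approx(to, abs=1e-10)
            assert p == pytest.approx(po, abs=1e-10)

    def test_welch_differs_under_unequal_variance(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 5, 8), rng.normal(0, 0.5, 30)
        assert ns.two_sample_ttest(a, b, welch=True) != ns.two_sample_ttest(a, b)

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            ns.two_sample_ttest([1.0, 1.0], [2.0, 2.0])

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            ns.two_sample_ttest([1.0], [1.0, 2.0])


class TestCohensD:
    def test_unit_effect(self):
        rng = np.random.default_rng(4)
        a = rng.normal(1.0, 1.0, 100_000)
        b = rng.normal(0.0, 1.0, 100_000)
        assert ns.cohens_d(a, b) == pytest.approx(1.0, abs=0.02)

    def test_equal_means_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert ns.cohens_d(a, a.copy()) == 0.0

    def test_matches_oracle(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 2, 15), rng.normal(1, 3, 9)
        assert ns.cohens_d(a, b) == pytest.approx(oracle_cohens_d(a, b), abs=1e-10)

    def test_sign_follows_mean_difference(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(2, 1, 20), rng.normal(0, 1, 20)
        assert ns.cohens_d(a, b) > 0 and ns.cohens_d(b, a) < 0


class TestRoiAggregate:
    def test_all_ones_gives_unit_means(self, montage):
        out = ns.roi_aggregate(np.ones(30), montage, "lobe")
        assert set(out) == {"frontal", "central", "parietal", "temporal", "occipital"}
        assert all(v == 1.0 for v in out.values())

    def test_hemispheric_rois_separate(self, montage):
        values = np.zeros(30)
        for ch in ns.LEFT_ROI:
            values[montage.index_of(ch)] = 2.0
        out = ns.roi_aggregate(values, montage, "hemisphere")
        assert out["left"] == 2.0 and out["right"] == 0.0

    def test_custom_roi_matches_hand_mean(self, montage):
        rng = np.random.default_rng(7)
        values = rng.uniform(size=30)
        roi = {"mine": ("Fz", "Cz", "Pz")}
        out = ns.roi_aggregate(values, montage, roi)
        expected = np.mean([values[montage.index_of(c)] for c in roi["mine"]])
        assert out["mine"] == pytest.approx(expected)

    def test_unknown_channel_named_in_error(self, montage):
        with pytest.raises(KeyError, match="XX9"):
            ns.roi_aggregate(np.ones(30), montage, {"bad": ("Fz", "XX9")})


class TestLabelState:
    def _vec(self, **kwargs):
        base = dict(
            effort="medium", temporal_demand="medium", performance="medium",
            fatigue_degree="medium", arousal="medium", valence="medium",
        )
        base.update(kwargs)
        return ns.SubjectiveScaleVector(**base)

    def test_attentive_rule_row(self):
        scale = self._vec(temporal_demand="medium", arousal="high", valence="medium")
        assert ns.label_state(scale) == "attentive"

    def test_fatigue_rule_row(self):
        scale = self._vec(fatigue_degree="high", arousal="low", valence="medium")
        assert ns.label_state(scale) == "fatigue"

    def test_all_very_high_is_unclassified(self):
        scale = ns.SubjectiveScaleVector(*["very_high"] * 6)
        assert ns.label_state(scale) == "unclassified"

    def test_malformed_grade_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            self._vec(arousal="extreme")

    def test_exhaustive_first_match_semantics(self):
        """Every one of the 5^6 grade vectors maps to exactly the first
        matching rule row (or 'unclassified' when none matches)."""
        indicators = (
            "effort", "temporal_demand", "performance",
            "fatigue_degree", "arousal", "valence",
        )

        def rule_matches(vec, rule):
            for ind, (op, grade) in rule.items():
                value = vec[indicators.index(ind)]
                if op == "eq" and value != grade:
                    return False
                if op == "ge" and _GRADE_RANK[value] < _GRADE_RANK[grade]:
                    return False
            return True

        counts = {}
        for combo in itertools.product(ns.GRADES, repeat=6):
            expected = "unclassified"
            for state, rule in _STATE_RULES:
                if rule_matches(combo, rule):
                    expected = state
                    break
            got = ns.label_state(ns.SubjectiveScaleVector(*combo))
            assert got == expected
            counts[got] = counts.get(got, 0) + 1
        # every state must be reachable
        assert set(counts) == {
            "attentive", "inattentive", "fatigue", "positive", "negative",
            "unclassified",
        }


class TestCompareConditions:
    def _table(self, seed=0, delta=0.0, n=13):
        rng = np.random.default_rng(seed)
        rows = []
        for cond, shift in (("a", 0.0), ("b", delta)):
            for k in range(n):
                rows.append(
                    {"subject": f"{cond}{k}", "condition": cond,
                     "sigma": rng.normal(1.0 + shift, 0.1)}
                )
        return pd.DataFrame(rows)

    def test_result_fields_consistent(self):
        r = ns.compare_conditions(self._table(delta=0.3), "sigma")
        assert r.n == (13, 13)
        assert 0.0 <= r.p <= 1.0
        assert np.sign(r.d) == np.sign(r.group_means[0] - r.group_means[1])

    def test_large_shift_detected(self):
        r = ns.compare_conditions(self._table(seed=1, delta=-0.5), "sigma")
        assert r.p < 0.001 and r.t > 0

    def test_missing_metric_rejected(self):
        with pytest.raises(KeyError, match="gamma"):
            ns.compare_conditions(self._table(), "gamma")

    def test_single_subject_group_rejected(self):
        table = self._table().iloc[[0, 13, 14]]
        with pytest.raises(ValueError, match=">= 2"):
            ns.compare_conditions(table, "sigma")

    def test_compare_table_bonferroni_scales_p(self):
        table = self._table(seed=2, delta=0.2)
        raw = ns.compare_table(table, metrics=("sigma",))
        adj = ns.compare_table(table, metrics=("sigma",), bonferroni=True)
        assert adj["p"][0] == pytest.approx(min(1.0, raw["p"][0] * 1))


class TestCompareScores:
    def test_no_change_is_null(self):
        before = np.array([10.0, 12.0, 9.0, 11.0])
        r = ns.compare_scores(before, before.copy())
        assert (r.t, r.p, r.d) == (0.0, 1.0, 0.0)

    def test_known_shift_recovered(self):
        rng = np.random.default_rng(8)
        before = rng.normal(10.0, 1.0, 13)
        after = before + 2.0 + rng.normal(0, 0.3, 13)
        r = ns.compare_scores(before, after)
        assert r.t > 0 and r.p < 0.01
        assert r.d == pytest.approx(2.0, abs=0.8)

    def test_matches_ttest_machinery(self):
        rng = np.random.default_rng(9)
        before, after = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        r = ns.compare_scores(before, after)
        t, p = ns.two_sample_ttest(after, before)
        assert r.t == pytest.approx(t) and r.p == pytest.approx(p)
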
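"""Validation protocol: kappa correctness and the sampled comparison."""

import math
import random

import numpy as np
import pandas as pd
import pytest

import echoclean as ec
from echoclean.validation import (VALIDATION_VARIABLES, cohen_kappa,
                                  kappa_statistic, sample_studies, validate)


def brute_force_kappa(a, b):
    """Independent oracle: kappa from the full confusion matrix."""
    labels = sorted(set(a) | set(b))
    idx = {l: i for i, l in enumerate(labels)}
    m = np.zeros((len(labels), len(labels)))
    for x, y in zip(a, b):
        m[idx[x], idx[y]] += 1
    n = m.sum()
    p_o = np.trace(m) / n
    p_e = float(np.sum(m.sum(axis=1) * m.sum(axis=0))) / n ** 2
    if p_e >= 1.0:
        return 1.0 if p_o == 1.0 else float("nan")
    return (p_o - p_e) / (1 - p_e)


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(list("aabbc"), list("aabbc")) == 1.0

    def test_worked_confusion_matrix(self):
        # counts (45, 5, 5, 45): p_o = 0.9, p_e = 0.5, kappa = 0.8
        a = ["x"] * 50 + ["y"] * 50
        b = ["x"] * 45 + ["y"] * 5 + ["x"] * 5 + ["y"] * 45
        assert cohen_kappa(a, b) == pytest.approx(0.8, abs=1e-12)

    def test_complete_disagreement_balanced(self):
        a = ["x"] * 50 + ["y"] * 50
        b = ["y"] * 50 + ["x"] * 50
        assert cohen_kappa(a, b) == pytest.approx(-1.0, abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ec.InputError):
            cohen_kappa(["a"], ["a", "b"])

    def test_missing_pairs_dropped_and_counted(self):
        res = kappa_statistic(["a", "b", None, "a"], ["a", "b", "a", float("nan")])
        assert res.n_used == 2 and res.n_dropped_missing == 2
        assert res.kappa == 1.0

    def test_single_shared_label(self):
        assert cohen_kappa(["a", "a"], ["a", "a"]) == 1.0
        res = kappa_statistic(["a", "a"], ["a", "b"])
        # not a single shared label (b appears); ordinary formula applies
        assert not res.undefined

    def test_oracle_equivalence_on_random_sequences(self):
        rng = random.Random(0)
        for _ in range(200):
            k = rng.randint(2, 6)
            n = rng.randint(2, 300)
            labels = [f"L{i}" for i in range(k)]
            a = [rng.choice(labels) for _ in range(n)]
            b = [rng.choice(labels) for _ in range(n)]
            ours = cohen_kappa(a, b)
            oracle = brute_force_kappa(a, b)
            if math.isnan(oracle):
                assert math.isnan(ours)
            else:
                assert ours == pytest.approx(oracle, abs=1e-12)

    def test_matches_scikit_learn(self):
        from sklearn.metrics import cohen_kappa_score
        rng = random.Random(1)
        for _ in range(50):
            n = rng.randint(5, 200)
            a = [rng.choice("abc") for _ in range(n)]
            b = [rng.choice("abc") for _ in range(n)]
            if len(set(a) | set(b)) < 2:
                continue
            assert cohen_kappa(a, b) == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12)

    def test_kappa_never_exceeds_observed_agreement(self):
        rng = random.Random(2)
        for _ in range(100):
            n = rng.randint(2, 100)
            a = [rng.choice("ab") for _ in range(n)]
            b = [rng.choice("ab") for _ in range(n)]
            res = kappa_statistic(a, b)
            if not res.undefined:
                assert res.kappa <= res.p_observed + 1e-12

    def test_joint_permutation_invariance(self):
        rng = random.Random(3)
        a = [rng.choice("abcd") for _ in range(200)]
        b = [rng.choice("abcd") for _ in range(200)]
        before = cohen_kappa(a, b)
        order = list(range(200))
        rng.shuffle(order)
        after = cohen_kappa([a[i] for i in order], [b[i] for i in order])
        assert after == pytest.approx(before, abs=1e-15)


class TestSampleStudies:
    def test_sample_is_unique_and_deterministic(self):
        t = pd.DataFrame({"v": range(2000)})
        s1 = sample_studies(t, 100, seed=4)
        s2 = sample_studies(t, 100, seed=4)
        assert len(s1) == 100 and s1.index.is_unique
        assert list(s1.index) == list(s2.index)

    def test_whole_table_boundary(self):
        t = pd.DataFrame({"v": range(10)})
        assert sorted(sample_studies(t, 10, seed=0)["v"]) == list(range(10))

    def test_oversampling_raises(self):
        with pytest.raises(ec.InputError):
            sample_studies(pd.DataFrame({"v": [1]}), 2, seed=0)


class TestValidate:
    def _tables(self):
        rng = random.Random(5)
        n = 400
        levels = ["none", "mild", "moderate", "severe"]
        gold = pd.DataFrame({
            "anonymous_id": [f"P{i}" for i in range(n)],
            "study_date": "2015-01-01",
            "aortic_stenosis": [rng.choice(levels) for _ in range(n)],
            "indication_murmur": [rng.random() < 0.3 for _ in range(n)],
        })
        return gold

    def test_identity_yields_full_agreement(self):
        gold = self._tables()
        rep = validate(gold.copy(), gold, variables=["aortic_stenosis"],
                       n=100, seed=1)
        row = rep.table[rep.table.variable == "aortic_stenosis"].iloc[0]
        assert row["proportion_agree_pct"] == 100.0
        assert row["kappa"] == 1.0
        assert rep.indications_mean_kappa == 1.0

    def test_seeded_label_flips_show_expected_agreement(self):
        gold = self._tables()
        clean = gold.copy()
        rng = random.Random(6)
        flipped = 0
        vals = list(clean["aortic_stenosis"])
        for i in range(len(vals)):
            if rng.random() < 0.05:
                vals[i] = "sclerosis"  # a level the gold never uses
                flipped += 1
        clean["aortic_stenosis"] = vals
        rep = validate(clean, gold, variables=["aortic_stenosis"], seed=2)
        row = rep.table.iloc[0]
        expect = 100.0 * (1 - flipped / len(gold))
        assert row["proportion_agree_pct"] == pytest.approx(expect, abs=1e-9)
        assert row["kappa"] < 1.0

    def test_absent_variable_raises_by_name(self):
        gold = self._tables()
        with pytest.raises(ec.InputError, match="lv_size"):
            validate(gold.copy(), gold, variables=["lv_size"])

    def test_report_text_renders(self):
        gold = self._tables()
        text = validate(gold.copy(), gold, variables=["aortic_stenosis"],
                        n=50, seed=0).to_text()
        assert "aortic_stenosis" in text and "Mean kappa" in text


def test_validation_variable_list_mirrors_protocol_shape():
    # the protocol reports the graded valve/chamber variables plus sex/age
    for v in ["aortic_stenosis", "lv_function", "la_size", "rhythm", "bbb",
              "sex", "age"]:
        assert v in VALIDATION_VARIABLES
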
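"""Signature derivation, BH adjustment, screen scoring and DE intersection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exitscape.screen import (
    ScreenScore,
    StateSignatures,
    bh_adjust,
    classify_quadrant,
    derive_signatures,
    intersect_de,
    score_perturbation,
    validate_known_regulators,
)

from conftest import random_profile
from oracles import bh_bruteforce, intersect_de_bruteforce, score_axes_bruteforce


# ---------------------------------------------------------------- signatures

class TestDeriveSignatures:
    def test_worked_example(self, comparison_worked):
        sigs = derive_signatures(comparison_worked, fold_threshold=10, pseudocount=0)
        assert sigs.set_a == {"g1"}
        assert sigs.set_b == {"g2"}

    def test_identical_means_give_empty_sets(self):
        df = pd.DataFrame(
            {"gene_id": ["a", "b"], "mean_a": [5.0, 9.0], "mean_b": [5.0, 9.0]}
        )
        sigs = derive_signatures(df, fold_threshold=2)
        assert sigs.set_a == frozenset() and sigs.set_b == frozenset()

    def test_zero_zero_gene_excluded_and_x_over_zero_enriched(self):
        df = pd.DataFrame(
            {"gene_id": ["z", "x"], "mean_a": [0.0, 10.0], "mean_b": [0.0, 0.0]}
        )
        sigs = derive_signatures(df, fold_threshold=10)
        assert "z" not in sigs.set_a | sigs.set_b
        assert "x" in sigs.set_a

    def test_pseudocount_damps_ratio(self):
        df = pd.DataFrame({"gene_id": ["g"], "mean_a": [11.0], "mean_b": [1.0]})
        assert "g" in derive_signatures(df, 10, pseudocount=0).set_a
        assert "g" not in derive_signatures(df, 10, pseudocount=5).set_a

    @pytest.mark.parametrize(
        "kwargs", [{"fold_threshold": 1.0}, {"fold_threshold": 0.5},
                   {"pseudocount": -1.0}]
    )
    def test_parameter_errors(self, comparison_worked, kwargs):
        with pytest.raises(ValueError):
            derive_signatures(comparison_worked, **{"fold_threshold": 10, **kwargs})

    def test_duplicate_gene_ids_rejected(self):
        df = pd.DataFrame(
            {"gene_id": ["a", "a"], "mean_a": [1.0, 2.0], "mean_b": [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            derive_signatures(df, 10)

    def test_sets_disjoint_by_type_invariant(self):
        with pytest.raises(ValueError, match="disjoint"):
            StateSignatures(frozenset("ab"), frozenset("bc"), 10.0)


# ------------------------------------------------------------------------ BH

class TestBhAdjust:
    def test_single_value_identity(self):
        assert bh_adjust([0.05]) == pytest.approx([0.05])

    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_against_bruteforce_and_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.random(rng.integers(1, 40))
            q = bh_adjust(p)
            np.testing.assert_allclose(q, bh_bruteforce(p), atol=1e-12)
            np.testing.assert_allclose(
                q, sm.multipletests(p, method="fdr_bh")[1], atol=1e-12
            )

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(deadline=None)
    def test_properties(self, p):
        q = bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-15).all() and (q <= 1).all()
        # outputs taken in the order of sorted inputs are non-decreasing
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


# ----------------------------------------------------------------- scoring

SIGS = StateSignatures(frozenset({"a1", "a2", "a3", "a4"}), frozenset({"b1", "b2"}), 10)


def _profile(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "fold_change", "q_value"])
    return df


class TestScorePerturbation:
    def test_worked_quarter_axis(self):
        # two up, one down, one unchanged among four signature-A genes -> +25
        prof = _profile(
            [("a1", 3.0, 0.01), ("a2", 3.0, 0.01), ("a3", 0.4, 0.01),
             ("a4", 1.1, 0.9), ("b1", 1.0, 1.0), ("b2", 1.0, 1.0)]
        )
        score = score_perturbation(prof, SIGS)
        assert score.esc_axis == pytest.approx(25.0)
        assert score.epi_axis == pytest.approx(0.0)
        assert (score.n_eval_a, score.n_eval_b) == (4, 2)

    def test_nothing_significant_scores_origin(self):
        prof = _profile([("a1", 5.0, 0.9), ("b1", 0.1, 0.9)])
        score = score_perturbation(prof, SIGS)
        assert (score.esc_axis, score.epi_axis) == (0.0, 0.0)
        assert score.quadrant == "null"

    def test_fold_change_gate_is_conjunctive(self):
        # highly significant but fc inside (0.5, 2) contributes nothing
        prof = _profile([("a1", 1.8, 0.001), ("b1", 1.0, 1.0)])
        assert score_perturbation(prof, SIGS).esc_axis == 0.0

    def test_empty_signature_set_gives_nan_axis(self):
        sigs = StateSignatures(frozenset(), frozenset({"b1"}), 10)
        score = score_perturbation(_profile([("b1", 3.0, 0.01)]), sigs)
        assert np.isnan(score.esc_axis) and score.n_eval_a == 0
        assert score.epi_axis == 100.0

    def test_absent_genes_excluded_from_denominator(self):
        prof = _profile([("a1", 3.0, 0.01)])  # a2..a4 absent
        score = score_perturbation(prof, SIGS)
        assert score.esc_axis == 100.0 and score.n_eval_a == 1

    def test_raw_p_adjusted_over_whole_profile(self):
        # BH over all genes pushes a borderline signature p over the cut
        prof = pd.DataFrame(
            {
                "gene_id": ["a1", "x1", "x2", "x3"],
                "fold_change": [3.0, 1.0, 1.0, 1.0],
                "p_value": [0.04, 0.8, 0.9, 0.95],
            }
        )
        assert score_perturbation(prof, SIGS).esc_axis == 0.0  # q = 0.16
        prof_q = prof.rename(columns={"p_value": "q_value"})
        assert score_perturbation(prof_q, SIGS).esc_axis == 100.0

    def test_matches_bruteforce_on_random_profiles(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(1, 50))
            prof = random_profile(rng, n)
            genes = list(prof["gene_id"])
            rng.shuffle(genes)
            set_a = frozenset(genes[: n // 3])
            set_b = frozenset(genes[n // 3 : n // 2])
            sigs = StateSignatures(set_a, set_b, 10)
            score = score_perturbation(prof, sigs)
            esc, epi, n_a, n_b = score_axes_bruteforce(
                list(prof.itertuples(index=False, name=None)),
                set_a, set_b, 0.05, 2.0, 0.5,
            )
            assert (score.n_eval_a, score.n_eval_b) == (n_a, n_b)
            for got, want in ((score.esc_axis, esc), (score.epi_axis, epi)):
                assert (np.isnan(got) and np.isnan(want)) or got == want

    def test_inverting_fold_changes_negates_axes(self):
        rng = np.random.default_rng(5)
        prof = random_profile(rng, 30)
        sigs = StateSignatures(
            frozenset(prof["gene_id"][:10]), frozenset(prof["gene_id"][10:20]), 10
        )
        fwd = score_perturbation(prof, sigs)
        inv = prof.assign(fold_change=1.0 / prof["fold_change"])
        rev = score_perturbation(inv, sigs)
        assert rev.esc_axis == pytest.approx(-fwd.esc_axis)
        assert rev.epi_axis == pytest.approx(-fwd.epi_axis)


class TestClassifyQuadrant:
    @pytest.mark.parametrize(
        "esc,epi,label",
        [
            (-30, 40, "maintenance_like"),  # Stat3/Esrrb/Sox2/Klf4 pattern
            (-20, -25, "dual_requirement"),  # Oct4 pattern
            (35, -20, "exit_facilitator_candidate"),  # bottom-right target
            (15, 25, "epi_restraining"),
            (0, 0, "null"),
            (float("nan"), 50, "null"),
        ],
    )
    def test_rules(self, esc, epi, label):
        score = ScreenScore("x", esc, epi, 10, 10)
        assert classify_quadrant(score) == label

    def test_dead_zone(self):
        score = ScreenScore("x", 8.0, -40.0, 10, 10)
        assert classify_quadrant(score, dead_zone=10) == "null"
        assert classify_quadrant(score, dead_zone=5) == "exit_facilitator_candidate"


class TestValidateKnownRegulators:
    def _scores(self):
        return [
            ScreenScore("Stat3", -30, 40, 9, 9, "maintenance_like"),
            ScreenScore("Oct4", -20, -25, 9, 9, "dual_requirement"),
            ScreenScore("Klf4", -25, 30, 9, 9, "maintenance_like"),
            ScreenScore("X", 30, -20, 9, 9, "exit_facilitator_candidate"),
        ]

    def test_full_concordance(self):
        report = validate_known_regulators(
            self._scores(),
            {"Stat3": "maintenance_like", "Oct4": "dual_requirement"},
        )
        assert report.fraction == 1.0 and not report.mismatches

    def test_partial_concordance_names_mismatch(self):
        expectations = {
            "Stat3": "maintenance_like",
            "Oct4": "dual_requirement",
            "Klf4": "maintenance_like",
            "X": "maintenance_like",  # wrong on purpose
        }
        report = validate_known_regulators(self._scores(), expectations)
        assert report.fraction == pytest.approx(0.75)
        assert report.mismatches == [
            ("X", "exit_facilitator_candidate", "maintenance_like")
        ]

    def test_empty_expectations_undefined_fraction(self):
        report = validate_known_regulators(self._scores(), {})
        assert np.isnan(report.fraction) and report.n_evaluated == 0

    def test_missing_perturbation_warned_and_excluded(self):
        with pytest.warns(UserWarning, match="missing"):
            report = validate_known_regulators(
                self._scores(),
                {"Stat3": "maintenance_like", "Nanog": "dual_requirement"},
            )
        assert report.unevaluable == ["Nanog"]
        assert report.fraction == 1.0 and report.n_evaluated == 1


# ------------------------------------------------------------ DE intersection

def _de(rows):
    return pd.DataFrame(rows, columns=["gene_id", "fold_change", "adj_p"])


class TestIntersectDe:
    T1 = [("A", 2.0, 0.01), ("B", 2.0, 0.01), ("C", 0.5, 0.01), ("D", 2.0, 0.5)]
    T2 = [("B", 2.0, 0.01), ("C", 2.0, 0.01), ("D", 2.0, 0.01)]

    def test_concordant_worked_example(self):
        res = intersect_de([_de(self.T1), _de(self.T2)], 0.05, 1.5, 0.7, True)
        assert res.genes == {"B"}

    def test_nonconcordant_worked_example(self):
        res = intersect_de([_de(self.T1), _de(self.T2)], 0.05, 1.5, 0.7, False)
        assert res.genes == {"B", "C"}
        assert set(res.directions.index) == {"B", "C"}

    def test_one_empty_table_empties_intersection(self):
        empty = _de([("A", 1.0, 0.9)])
        res = intersect_de([_de(self.T1), empty], 0.05, 1.5, 0.7, True)
        assert res.genes == frozenset()

    def test_needs_two_tables(self):
        with pytest.raises(ValueError):
            intersect_de([_de(self.T1)])

    def test_matches_set_logic_oracle_random(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n_tables = int(rng.integers(2, 5))
            tables = []
            for _ in range(n_tables):
                n = int(rng.integers(1, 30))
                genes = rng.choice([f"g{i}" for i in range(40)], n, replace=False)
                tables.append(
                    _de(
                        [
                            (g, float(np.exp(rng.normal(0, 0.8))), float(rng.random()))
                            for g in genes
                        ]
                    )
                )
            for concordant in (True, False):
                res = intersect_de(tables, 0.05, 1.5, 0.7, concordant)
                want = intersect_de_bruteforce(
                    [list(t.itertuples(index=False, name=None)) for t in tables],
                    0.05, 1.5, 0.7, concordant,
                )
                assert res.genes == want
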
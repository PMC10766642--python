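"""Trend classification, synthesis-rate calls, and the pattern rule table."""

import itertools

import numpy as np
import pytest

from ecmquant import (
    TrajectorySeries,
    assign_pattern,
    classify_synthesis,
    classify_table,
    classify_trend,
    pattern_counts,
    pattern_table,
)
from ecmquant.synth import gen_omics_table, gen_synthesis_table


def _series(values, ages=None, molecule="m1", level="mRNA"):
    ages = ages if ages is not None else list(range(1, len(values) + 1))
    return TrajectorySeries(
        molecule_id=molecule,
        level=level,
        points=[(a, "r0", v) for a, v in zip(ages, values)],
    )


class TestClassifyTrend:
    def test_monotone_decrease_called_down(self):
        call = classify_trend(_series([10, 8, 6, 4, 2]), tau=0.5)
        assert call.call == "down"
        assert call.pearson_r < -0.5 and call.spearman_rho < -0.5

    def test_constant_series_unchanged(self):
        assert classify_trend(_series([5, 5, 5, 5])).call == "unchanged"

    def test_too_few_ages_rejected(self):
        with pytest.raises(ValueError, match="distinct ages"):
            classify_trend(_series([1, 2], ages=[1, 2]))

    def test_tau_zero_calls_every_nonconstant_series(self, rng):
        for _ in range(20):
            vals = rng.normal(size=6)
            call = classify_trend(_series(list(vals)), tau=0.0)
            if np.sign(call.pearson_r) == np.sign(call.spearman_rho):
                assert call.call in ("down", "up")

    def test_tau_one_only_perfectly_linear_monotone(self):
        assert classify_trend(_series([1, 2, 3, 4]), tau=1.0).call == "up"
        assert classify_trend(_series([1, 2, 3, 3.5]), tau=1.0).call == "unchanged"

    def test_affine_invariance_and_row_order_invariance(self, rng):
        vals = list(rng.normal(10, 2, 8))
        base = classify_trend(_series(vals), tau=0.4)
        scaled = classify_trend(_series([3.2 * v + 11 for v in vals]), tau=0.4)
        assert scaled.call == base.call
        assert scaled.pearson_r == pytest.approx(base.pearson_r, abs=1e-12)
        perm = np.random.default_rng(0).permutation(len(vals))
        shuffled = _series([vals[i] for i in perm], ages=[float(perm[i] + 1) for i in range(len(vals))])
        assert classify_trend(shuffled, tau=0.4).call == base.call

    def test_planted_class_recovery(self):
        """>=95% of 500 series/class recovered at tau=0.5 (8 ages, 3 reps, sigma 0.3)."""
        table, truth = gen_omics_table(seed=42, n_per_class=500)
        calls = classify_table(table, tau=0.5)
        merged = calls.merge(truth, on="molecule_id")
        rate = (merged["call"] == merged["planted_class"]).mean()
        assert rate >= 0.95


class TestClassifySynthesis:
    def test_centered_molecule_unchanged(self):
        all_s = [
            _series([4.0, 4.0], ages=[1, 2], molecule=f"m{i}", level="synthesis")
            for i in range(3)
        ] + [_series([6.0, 6.0], ages=[1, 2], molecule="hi", level="synthesis")]
        center = _series([5.0, 5.0], ages=[1, 2], molecule="mid", level="synthesis")
        assert classify_synthesis(center, all_s + [center], k=1).call != "down"

    def test_extreme_outlier_elevated(self):
        base = [
            _series([1.0 + 0.01 * i], ages=[1], molecule=f"m{i}", level="synthesis")
            for i in range(10)
        ]
        hot = _series([50.0], ages=[1], molecule="hot", level="synthesis")
        assert classify_synthesis(hot, base + [hot], k=1).call == "up"

    def test_planted_group_recovery(self):
        """Three groups at -2/0/+2 SD recovered >=95% at k=1."""
        table, truth = gen_synthesis_table(seed=7, n_per_group=100)
        calls = classify_table(table)
        merged = calls.merge(truth, on="molecule_id")
        assert (merged["call"] == merged["planted_class"]).mean() >= 0.95


def _expected_pattern(mrna, protein, reporter):
    """Hand-written truth table for the pattern rule (strict mRNA calls only)."""
    present = [c for c in (protein, reporter) if c is not None]
    if mrna is None or not present:
        return "unclassified"
    if mrna == "down":
        return "I" if all(c == "down" for c in present) else "II"
    if mrna == "unchanged" and any(c == "up" for c in present):
        return "III"
    return "unclassified"


class TestAssignPattern:
    @pytest.mark.parametrize(
        "mrna,protein,reporter,expected",
        [
            ("down", "down", "down", "I"),
            ("down", "unchanged", None, "II"),
            ("unchanged", "up", None, "III"),
        ],
    )
    def test_published_pattern_definitions(self, mrna, protein, reporter, expected):
        assert assign_pattern("c", mrna, protein, reporter).pattern == expected

    def test_exhaustive_rule_table(self):
        """All 3x4x4 call combinations match the hand-written truth table."""
        calls = ("down", "unchanged", "up")
        optional = ("down", "unchanged", "up", None)
        n = 0
        for mrna, protein, reporter in itertools.product(calls, optional, optional):
            got = assign_pattern("c", mrna, protein, reporter).pattern
            assert got == _expected_pattern(mrna, protein, reporter), (mrna, protein, reporter)
            n += 1
        assert n == 48

    def test_mild_mrna_decline_routes_to_pattern_three(self):
        pc = assign_pattern("c", "down", "up", None, mrna_mild_decline=True)
        assert pc.pattern == "III"
        # steep decline with accumulating protein stays pattern II
        assert assign_pattern("c", "down", "up", None).pattern == "II"

    def test_no_protein_or_reporter_unclassified(self):
        assert assign_pattern("c", "down").pattern == "unclassified"


class TestPatternTable:
    def test_end_to_end_planted_patterns(self):
        """Trajectories built to embody each pattern land in the right class."""
        import pandas as pd

        ages = list(range(1, 9))
        rows = []

        def add(mol, level, slope):
            for a in ages:
                rows.append(
                    {
                        "molecule_id": mol,
                        "level": level,
                        "age_days": float(a),
                        "replicate": "r0",
                        "value": 10.0 + slope * a,
                    }
                )

        add("colI", "mRNA", -1.0); add("colI", "protein", -1.0); add("colI", "reporter", -1.0)
        add("colII", "mRNA", -1.0); add("colII", "protein", 0.0)
        add("colIII", "mRNA", 0.0); add("colIII", "protein", 1.0)
        calls = classify_table(pd.DataFrame(rows))
        patterns = pattern_table(calls)
        got = dict(zip(patterns["molecule_id"], patterns["pattern"]))
        assert got == {"colI": "I", "colII": "II", "colIII": "III"}
        counts = pattern_counts(patterns)
        assert (counts["I"], counts["II"], counts["III"]) == (1, 1, 1)
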
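import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from speccount.differential import (
    DifferentialCall,
    call_differential,
    commonality_filter,
    depot_overlap,
    signed_fold_change,
    wilcoxon_test,
)
from speccount.io import PipelineConfig, SampleInfo, ValidationError
from speccount.quantification import CountMatrix, normalize_counts


def rank_sum_oracle(x, y):
    """Exact two-sided rank-sum p via the Mann-Whitney U pair-counting route:
    enumerate every assignment of the pooled multiset and compare
    |U - n1 n2 / 2| tails. Independent of the rank-based implementation."""
    pooled = list(x) + list(y)
    n, nx = len(pooled), len(x)

    def u_stat(xs, ys):
        u = 0.0
        for a in xs:
            for b in ys:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    mu = nx * (n - nx) / 2.0
    dev_obs = abs(u_stat(x, y) - mu)
    hits = total = 0
    for idx in itertools.combinations(range(n), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in idx]
        total += 1
        if abs(u_stat(xs, ys) - mu) >= dev_obs - 1e-9:
            hits += 1
    return hits / total


class TestCommonalityFilter:
    def test_half_observed_in_both_groups_fails_strict_threshold(self):
        counts = [1, 1, 0, 0, 3, 2, 0, 0]
        labels = ["diabetic"] * 4 + ["nondiabetic"] * 4
        fd, fn, passed = commonality_filter(counts, labels, 0.5)
        assert (fd, fn) == (0.5, 0.5)
        assert not passed

    def test_any_one_group_above_threshold_passes(self):
        counts = [1, 1, 2, 0, 0, 0, 0, 0]
        labels = ["diabetic"] * 4 + ["nondiabetic"] * 4
        fd, fn, passed = commonality_filter(counts, labels, 0.5)
        assert fd == 0.75 and fn == 0.0
        assert passed

    def test_all_zero_fails(self):
        counts = [0] * 8
        labels = ["diabetic"] * 4 + ["nondiabetic"] * 4
        assert commonality_filter(counts, labels, 0.5) == (0.0, 0.0, False)

    def test_empty_group_raises(self):
        with pytest.raises(ValidationError):
            commonality_filter([1, 2], ["diabetic", "diabetic"], 0.5)


class TestWilcoxon:
    def test_separated_triples_exact_p(self):
        assert wilcoxon_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_all_tied_returns_one(self):
        assert wilcoxon_test([1, 1], [1, 1]) == 1.0

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        x=st.lists(st.integers(0, 3), min_size=2, max_size=5),
        y=st.lists(st.integers(0, 3), min_size=2, max_size=5),
    )
    def test_matches_enumeration_oracle_with_ties(self, x, y):
        """Exact agreement with the independent U-statistic enumeration for
        every tie pattern with at most 10 observations."""
        assert wilcoxon_test(x, y) == pytest.approx(rank_sum_oracle(x, y), abs=1e-12)

    def test_asymptotic_type_one_error_near_nominal(self):
        rng = np.random.default_rng(15)
        reps, rejections = 2000, 0
        for _ in range(reps):
            x = rng.normal(0, 1, 20)
            y = rng.normal(0, 1, 22)
            rejections += wilcoxon_test(x, y) <= 0.05
        assert 0.04 <= rejections / reps <= 0.06

    def test_small_groups_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_test([1.0], [2.0, 3.0])


class TestSignedFoldChange:
    def test_direct_ratio_and_mirror(self):
        assert signed_fold_change(7.5, 2.5, 0.0) == pytest.approx(3.0)
        assert signed_fold_change(2.5, 7.5, 0.0) == pytest.approx(-3.0)

    def test_pseudocount_handles_zero_mean(self):
        assert signed_fold_change(0.0, 4.5, 0.5) == pytest.approx(-10.0)

    def test_zero_means_without_pseudocount_rejected(self):
        with pytest.raises(ValidationError, match="undefined ratio"):
            signed_fold_change(0.0, 0.0, 0.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.0, 1e4), b=st.floats(0.0, 1e4),
        c=st.floats(0.01, 10.0),
    )
    def test_antisymmetry_and_magnitude_bound(self, a, b, c):
        fc = signed_fold_change(a, b, c)
        rev = signed_fold_change(b, a, c)
        assert abs(fc) >= 1.0
        # a ratio rounding exactly onto 1 sits on the +1 boundary both ways
        if not (fc == 1.0 and rev == 1.0):
            assert fc == pytest.approx(-rev)

    def test_scaling_diabetic_group_never_shrinks_positive_fc(self):
        base = signed_fold_change(6.0, 2.0, 0.5)
        for k in (1.5, 2.0, 10.0):
            assert signed_fold_change(6.0 * k, 2.0, 0.5) >= base


def _two_group_matrix(rows: dict[str, list[float]]):
    samples = []
    for i in range(1, 5):
        samples.append(SampleInfo(f"D{i}", f"D{i}", "omentum", "diabetic"))
    for i in range(1, 5):
        samples.append(SampleInfo(f"N{i}", f"N{i}", "omentum", "nondiabetic"))
    ids = [s.sample_id for s in samples]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=ids)
    raw = CountMatrix.from_frame(df)
    return raw, samples


class TestCallDifferential:
    def test_rare_protein_with_huge_fc_blocked_by_commonality(self):
        raw, samples = _two_group_matrix({
            "P1": [400, 0, 0, 0, 0, 0, 0, 0],
            "P2": [10, 12, 9, 11, 10, 11, 9, 12],
        })
        nsc = normalize_counts(raw)
        calls = {c.group_id: c for c in call_differential(
            nsc, raw, samples, "omentum", PipelineConfig())}
        c = calls["P1"]
        assert abs(c.fold_change) > 1.5 and not c.passes_commonality and not c.significant

    def test_clear_shift_is_called_with_positive_sign(self):
        raw, samples = _two_group_matrix({
            "P0": [100, 101, 99, 100, 100, 102, 98, 100],  # stable background
            "P1": [40, 44, 39, 41, 10, 11, 9, 12],
            "P2": [10, 12, 9, 11, 10, 11, 9, 12],
        })
        nsc = normalize_counts(raw)
        calls = {c.group_id: c for c in call_differential(
            nsc, raw, samples, "omentum", PipelineConfig())}
        assert calls["P1"].significant and calls["P1"].fold_change > 2
        assert not calls["P2"].significant

    def test_output_sorted_by_fold_change_descending(self):
        raw, samples = _two_group_matrix({
            "P1": [10, 12, 9, 11, 30, 33, 29, 31],
            "P2": [40, 44, 39, 41, 10, 11, 9, 12],
            "P3": [20, 22, 19, 21, 20, 21, 19, 22],
        })
        nsc = normalize_counts(raw)
        calls = call_differential(nsc, raw, samples, "omentum", PipelineConfig())
        fcs = [c.fold_change for c in calls]
        assert fcs == sorted(fcs, reverse=True)

    def test_significance_requires_all_three_flags(self):
        raw, samples = _two_group_matrix({
            "P1": [40, 44, 39, 41, 10, 11, 9, 12],
        })
        nsc = normalize_counts(raw)
        (c,) = call_differential(nsc, raw, samples, "omentum", PipelineConfig())
        assert c.significant == (c.passes_commonality and c.passes_wilcoxon and c.passes_fc)

    def test_missing_depot_raises(self):
        raw, samples = _two_group_matrix({"P1": [1] * 8})
        with pytest.raises(ValidationError, match="subcutaneous"):
            call_differential(normalize_counts(raw), raw, samples, "subcutaneous",
                              PipelineConfig())


def _call(gid, fc, significant=True):
    return DifferentialCall(
        group_id=gid, fold_change=fc, p_value=0.01,
        commonality_diabetic=1.0, commonality_nondiabetic=1.0,
        passes_commonality=True, passes_wilcoxon=True, passes_fc=True,
        significant=significant,
    )


class TestDepotOverlap:
    def test_set_algebra_and_concordance(self):
        calls_sc = [_call("A", 2.0), _call("B", 2.0), _call("C", 2.0)]
        calls_om = [_call("B", 3.0), _call("C", -2.0), _call("D", -1.8)]
        ov = depot_overlap(calls_sc, calls_om, {"A", "B", "C", "X"}, {"B", "C", "D", "X"})
        assert ov.identified_both == {"B", "C", "X"}
        assert ov.differential_both == {"B", "C"}
        assert ov.concordant == {"B"}  # C flips sign between depots

    def test_empty_lists_give_empty_overlap(self):
        ov = depot_overlap([], [], set(), set())
        assert ov.differential_both == frozenset() and ov.concordant == frozenset()

    def test_non_significant_calls_do_not_count(self):
        ov = depot_overlap([_call("A", 2.0, significant=False)], [_call("A", 2.0)],
                           {"A"}, {"A"})
        assert ov.differential_sc == frozenset()
        assert ov.differential_both == frozenset()
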
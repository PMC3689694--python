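import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import translatome as t
from translatome.translatability import (
    Call,
    RegulationClass,
    Thresholds,
    call_regulated,
    classify_gene,
    classify_table,
    condition_ratio,
    count_threshold_calls,
    relative_translatability,
    summarize_classes,
)

from conftest import make_design, make_matrix, SAMPLES

positive_floats = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


def make_table(poly: dict, tot: dict):
    poly_frame = pd.DataFrame.from_dict(poly, orient="index", columns=[1, 2]).astype(float)
    tot_frame = pd.DataFrame.from_dict(tot, orient="index", columns=[1, 2]).astype(float)
    return relative_translatability(poly_frame, tot_frame)


class TestConditionRatio:
    def test_identity_when_kd_equals_ctrl(self, design):
        matrix = make_matrix({"g1": [7] * 8, "g2": [3] * 8})
        for fraction in ("polysomal", "total"):
            ratios = condition_ratio(matrix, design, fraction)
            assert np.allclose(ratios.to_numpy(), 1.0)

    def test_simple_doubling(self, design):
        matrix = make_matrix({"g1": [200, 100, 200, 100, 100, 100, 100, 100]})
        ratios = condition_ratio(matrix, design, "polysomal")
        assert ratios.loc["g1", 1] == pytest.approx(2.0)
        assert ratios.loc["g1", 2] == pytest.approx(2.0)

    def test_hand_computed_three_genes(self, design):
        # hand calculation: kd/ctrl per replicate, polysomal columns 0-3
        matrix = make_matrix(
            {
                "g1": [150, 100, 90, 60, 100, 100, 100, 100],
                "g2": [30, 120, 25, 100, 100, 100, 100, 100],
                "g3": [55, 50, 66, 60, 100, 100, 100, 100],
            }
        )
        ratios = condition_ratio(matrix, design, "polysomal")
        expected = {
            "g1": (150 / 100, 90 / 60),
            "g2": (30 / 120, 25 / 100),
            "g3": (55 / 50, 66 / 60),
        }
        for gene, (r1, r2) in expected.items():
            assert ratios.loc[gene, 1] == pytest.approx(r1, rel=1e-12)
            assert ratios.loc[gene, 2] == pytest.approx(r2, rel=1e-12)

    def test_missing_pair_names_fraction_and_replicate(self, two_gene_matrix):
        design = make_design(SAMPLES[:-1])  # drop tot_ctrl_r2
        sub = two_gene_matrix.values.drop(columns="tot_ctrl_r2")
        matrix = t.ExpressionMatrix(values=sub, detected=sub.notna())
        with pytest.raises(Exception, match=r"total.*replicate 2"):
            condition_ratio(matrix, design, "total")

    def test_respects_per_fraction_retention(self, design):
        flags = {"g1": [1] * 8, "g2": [0, 0, 0, 0, 1, 1, 1, 1]}
        matrix = make_matrix({"g1": [1] * 8, "g2": [2] * 8}, detected=flags)
        filtered = t.filter_detected(matrix, design)
        assert list(condition_ratio(filtered, design, "polysomal").index) == ["g1"]
        assert list(condition_ratio(filtered, design, "total").index) == ["g1", "g2"]

    def test_scale_invariance_of_sample_pair(self, design, rng):
        values = {f"g{i}": list(rng.uniform(1, 100, 8)) for i in range(5)}
        matrix = make_matrix(values)
        before = condition_ratio(matrix, design, "polysomal")
        scaled = matrix.values.copy()
        scaled[["poly_kd_r1", "poly_ctrl_r1"]] *= 7.5  # same pair, same factor
        after = condition_ratio(
            t.ExpressionMatrix(values=scaled, detected=matrix.detected), design, "polysomal"
        )
        pd.testing.assert_frame_equal(before, after)

    def test_condition_swap_gives_reciprocal_ratios(self, design, rng):
        values = {f"g{i}": list(rng.uniform(1, 100, 8)) for i in range(5)}
        matrix = make_matrix(values)
        swapped_rows = [
            (sid, {"knockdown": "control", "control": "knockdown"}[cond], frac, rep)
            for sid, cond, frac, rep in SAMPLES
        ]
        swapped = make_design(swapped_rows)
        forward = condition_ratio(matrix, design, "polysomal")
        backward = condition_ratio(matrix, swapped, "polysomal")
        pd.testing.assert_frame_equal(forward, 1.0 / backward)


class TestRelativeTranslatability:
    def test_printed_fold_changes(self):
        # published candidate rows: poly 0.45 / tot 0.9 -> 0.5 and 1.8 / 1.0 -> 1.8
        table = make_table(
            poly={"ACVR1B": [0.45, 0.45], "DNASE1L3": [1.8, 1.8]},
            tot={"ACVR1B": [0.9, 0.9], "DNASE1L3": [1.0, 1.0]},
        )
        assert table.rr_summary["ACVR1B"] == pytest.approx(0.5, rel=1e-12)
        assert table.rr_summary["DNASE1L3"] == pytest.approx(1.8, rel=1e-12)

    def test_identity_when_poly_equals_tot(self):
        table = make_table(poly={"g1": [1.3, 0.7]}, tot={"g1": [1.3, 0.7]})
        assert table.rr_summary["g1"] == pytest.approx(1.0, rel=1e-12)

    def test_inner_join_drops_one_sided_genes(self):
        poly = pd.DataFrame({1: [2.0], 2: [2.0]}, index=["g1"])
        tot = pd.DataFrame({1: [1.0, 1.0], 2: [1.0, 1.0]}, index=["g1", "g2"])
        table = relative_translatability(poly, tot)
        assert table.gene_ids == ["g1"]

    def test_nonpositive_ratio_rejected(self):
        poly = pd.DataFrame({1: [0.0], 2: [1.0]}, index=["g1"])
        tot = pd.DataFrame({1: [1.0], 2: [1.0]}, index=["g1"])
        with pytest.raises(ValueError, match="> 0"):
            relative_translatability(poly, tot)

    @given(
        poly=st.lists(positive_floats, min_size=2, max_size=2),
        tot=st.lists(positive_floats, min_size=2, max_size=2),
    )
    def test_rr_times_tot_recovers_poly(self, poly, tot):
        table = make_table(poly={"g": poly}, tot={"g": tot})
        for rep in (1, 2):
            assert table.rr.loc["g", rep] * table.tot_ratios.loc["g", rep] == pytest.approx(
                table.poly_ratios.loc["g", rep], rel=1e-12
            )

    def test_geomean_summary(self):
        table = make_table(poly={"g": [2.0, 8.0]}, tot={"g": [1.0, 1.0]})
        assert table.rr_summary["g"] == pytest.approx(4.0, rel=1e-12)


class TestCallRegulated:
    @pytest.mark.parametrize(
        "rr, expected",
        [
            ((1.6, 1.7), Call.UP),
            ((1.6, 1.2), Call.NOT_RETAINED),
            ((0.5, 0.6), Call.DOWN),
            ((1.5, 1.5), Call.UP),  # inclusive boundary
            ((0.67, 0.67), Call.DOWN),
            ((1.0, 1.0), Call.NOT_RETAINED),
        ],
    )
    def test_concordance_rule(self, rr, expected):
        table = make_table(poly={"g": list(rr)}, tot={"g": [1.0, 1.0]})
        assert call_regulated(table)["g"] == expected

    def test_exclusive_thresholds_spare_boundary(self):
        table = make_table(poly={"g": [1.5, 1.5]}, tot={"g": [1.0, 1.0]})
        thresholds = Thresholds(inclusive=False)
        assert call_regulated(table, thresholds)["g"] == Call.NOT_RETAINED

    def test_single_replicate_requires_opt_in(self):
        poly = pd.DataFrame({1: [2.0]}, index=["g"])
        tot = pd.DataFrame({1: [1.0]}, index=["g"])
        table = relative_translatability(poly, tot)
        with pytest.raises(ValueError, match="replicate"):
            call_regulated(table)
        assert call_regulated(table, allow_single_replicate=True)["g"] == Call.UP

    def test_symmetry_under_condition_swap(self, rng):
        rrs = rng.uniform(0.2, 5.0, size=(10, 2))
        poly = {f"g{i}": list(rrs[i]) for i in range(10)}
        tot = {f"g{i}": [1.0, 1.0] for i in range(10)}
        table = make_table(poly=poly, tot=tot)
        flipped = make_table(
            poly={g: [1 / a, 1 / b] for g, (a, b) in poly.items()}, tot=tot
        )
        thresholds = Thresholds(up=1.5, down=0.67)
        reciprocal = Thresholds(up=1 / 0.67, down=1 / 1.5)
        calls = call_regulated(table, thresholds)
        flipped_calls = call_regulated(flipped, reciprocal)
        swap = {Call.UP: Call.DOWN, Call.DOWN: Call.UP, Call.NOT_RETAINED: Call.NOT_RETAINED}
        for gene in calls.index:
            assert flipped_calls[gene] == swap[calls[gene]]

    def test_matches_brute_force_oracle(self, rng):
        # literal restatement of the retention rule, gene by gene
        def oracle(rr_rows, up=1.5, down=0.67):
            out = {}
            for gene, rrs in rr_rows.items():
                if all(r >= up for r in rrs):
                    out[gene] = Call.UP
                elif all(r <= down for r in rrs):
                    out[gene] = Call.DOWN
                else:
                    out[gene] = Call.NOT_RETAINED
            return out

        rr_rows = {f"g{i}": list(rng.uniform(0.3, 3.0, 2)) for i in range(10)}
        table = make_table(
            poly=rr_rows, tot={g: [1.0, 1.0] for g in rr_rows}
        )
        calls = call_regulated(table)
        expected = oracle(rr_rows)
        for gene in rr_rows:
            assert calls[gene] == expected[gene]


class TestClassifyGene:
    @pytest.mark.parametrize(
        "poly, tot, rr, expected",
        [
            (0.45, 0.9, 0.5, RegulationClass.POLY_ONLY_DOWN),
            (1.8, 1.0, 1.8, RegulationClass.POLY_ONLY_UP),
            (0.9, 0.3, 2.7, RegulationClass.BUFFERED_UP),
            (0.9, 2.0, 0.45, RegulationClass.BUFFERED_DOWN),
            (0.6, 1.9, 0.3, RegulationClass.OPPOSITE),
            (2.0, 0.5, 4.0, RegulationClass.OPPOSITE),
            (2.0, 2.0, 1.0, RegulationClass.CONCOMITANT_UNMODIFIED),
            (0.5, 0.5, 1.0, RegulationClass.CONCOMITANT_UNMODIFIED),
            (1.0, 1.0, 1.0, RegulationClass.UNCHANGED),
            (1.4, 0.9, 1.56, RegulationClass.OTHER_MODIFIED),  # neither fraction cleared
            (4.0, 2.0, 2.0, RegulationClass.OTHER_MODIFIED),  # both up, RR beyond
            (1.5, 1.1, 1.36, RegulationClass.UNCHANGED),  # poly changed, RR in band
        ],
    )
    def test_grid(self, poly, tot, rr, expected):
        assert classify_gene(poly, tot, rr) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            classify_gene(0.0, 1.0, 1.0)

    @given(poly=positive_floats, tot=positive_floats)
    @settings(max_examples=200)
    def test_total_function_single_label(self, poly, tot):
        rr = poly / tot
        if not (1e-12 < rr < 1e12):
            return
        result = classify_gene(poly, tot, rr)
        assert isinstance(result, RegulationClass)


class TestSummarizeClasses:
    def test_empty_input(self):
        summary = summarize_classes(pd.Series(dtype=object))
        assert all(v == 0 for v in summary.class_counts.values())
        assert summary.n_expressed == 0

    def test_one_gene_per_class(self):
        classes = pd.Series(list(RegulationClass), index=[c.value for c in RegulationClass])
        summary = summarize_classes(classes)
        assert all(v == 1 for v in summary.class_counts.values())
        assert summary.n_expressed == len(RegulationClass)
        assert summary.n_rr_modified == len(RegulationClass) - 2

    def test_partition_sums_to_total(self, rng):
        labels = rng.choice(list(RegulationClass), size=100)
        summary = summarize_classes(pd.Series(labels))
        assert sum(summary.class_counts.values()) == 100


class TestCountThresholdCalls:
    def test_published_candidate_column(self):
        rr = t.load_candidate_genes()["rr"]
        assert count_threshold_calls(rr) == (23, 12)

    def test_empty(self):
        assert count_threshold_calls([]) == (0, 0)

    def test_inclusive_boundaries(self):
        assert count_threshold_calls([1.5, 0.67, 1.0]) == (1, 1)

    def test_exclusive_boundaries(self):
        assert count_threshold_calls([1.5, 0.67, 1.0], Thresholds(inclusive=False)) == (0, 0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            count_threshold_calls([1.0, -2.0])


class TestThresholds:
    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            Thresholds(up=0.5, down=0.67)

    @given(value=positive_floats)
    def test_direction_partition(self, value):
        thresholds = Thresholds()
        directions = [thresholds.is_up(value), thresholds.is_down(value)]
        assert sum(directions) <= 1
        assert thresholds.direction(value) in (-1, 0, 1)
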
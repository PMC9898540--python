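import math

import numpy as np
import pytest

from clonetrace import (
    COT_22_5,
    BiasParameters,
    classify_all,
    classify_bt_bias,
    classify_dynamics,
    classify_lineage_bias,
    classify_temporal,
    combination_label,
    detect_produced_types,
    early_late_overlap,
    flag_high_abundance,
    relative_copy_number,
)
from conftest import make_matrix, random_abundance_matrix
import oracles

PARAMS = BiasParameters()


def test_fold_threshold_is_cotangent_of_22_5_degrees():
    assert COT_22_5 == pytest.approx(1 / math.tan(math.radians(22.5)))
    assert round(COT_22_5, 4) == 2.4142


class TestDetection:
    @pytest.mark.parametrize(
        "value,present", [(0.011, True), (0.009, False), (0.01, True)]
    )
    def test_floor_is_inclusive(self, value, present):
        matrix = make_matrix({("A", "m1"): {("Gr", 2.5): value}})
        presence = detect_produced_types(matrix, PARAMS)
        assert bool(presence.loc[("A", "m1"), ("Gr", 2.5)]) is present

    @pytest.mark.parametrize(
        "value,flagged", [(0.06, True), (0.05, False), (0.0, False)]
    )
    def test_high_abundance_is_exclusive(self, value, flagged):
        matrix = make_matrix({("A", "m1"): {("B", 6.5): value}})
        flags = flag_high_abundance(matrix, PARAMS)
        assert bool(flags.loc[("A", "m1"), ("B", 6.5)]) is flagged


class TestCombinationLabel:
    def test_t_cells_merged(self):
        matrix = make_matrix(
            {
                ("A", "m1"): {("Gr", 2.5): 0.1, ("CD8T", 2.5): 0.1},
                ("B", "m1"): {("CD4T", 2.5): 0.1},
                ("C", "m1"): {},
            }
        )
        labels = combination_label(detect_produced_types(matrix, PARAMS), 2.5)
        assert labels[("A", "m1")] == "Gr+T"
        assert labels[("B", "m1")] == "T"
        assert ("C", "m1") not in labels  # nothing produced -> excluded


class TestRelativeCopyNumber:
    def test_sole_owner_is_one(self):
        matrix = make_matrix({("A", "m1"): {("B", 2.5): 0.4}})
        rcn = relative_copy_number(matrix, ("B", "CD4T", "CD8T"), 2.5)
        assert rcn[("A", "m1")] == pytest.approx(1.0)

    def test_shares_partition(self):
        matrix = make_matrix(
            {("A", "m1"): {("B", 2.5): 0.3}, ("B", "m1"): {("CD4T", 2.5): 0.1}}
        )
        rcn = relative_copy_number(matrix, ("B", "CD4T", "CD8T"), 2.5)
        assert rcn[("A", "m1")] == pytest.approx(0.75)
        assert rcn[("B", "m1")] == pytest.approx(0.25)

    def test_zero_lineage_total_gives_zero(self):
        matrix = make_matrix({("A", "m1"): {("B", 2.5): 0.3}})
        rcn = relative_copy_number(matrix, ("Gr",), 2.5)
        assert rcn[("A", "m1")] == 0.0

    def test_normalized_within_each_mouse(self):
        matrix = make_matrix(
            {
                ("A", "m1"): {("Gr", 2.5): 1.0},
                ("B", "m2"): {("Gr", 2.5): 0.1},
            },
            groups={"m1": "HSC", "m2": "HSC"},
        )
        rcn = relative_copy_number(matrix, ("Gr",), 2.5)
        assert rcn[("A", "m1")] == 1.0 and rcn[("B", "m2")] == 1.0


class TestLineageBias:
    def test_measurable_in_one_lineage_is_specialized(self):
        matrix = make_matrix({("A", "m1"): {("Gr", 2.5): 0.2}})
        assert classify_lineage_bias(matrix, PARAMS, 2.5)[("A", "m1")] == "myeloid_specialized"

    def test_fold_rule_instance(self):
        # relative copy numbers m=0.10, l=0.50 for clone A (both measurable)
        matrix = make_matrix(
            {
                ("A", "m1"): {("Gr", 2.5): 0.1, ("B", 2.5): 0.5},
                ("B", "m1"): {("Gr", 2.5): 0.9, ("B", 2.5): 0.5},
            }
        )
        assert classify_lineage_bias(matrix, PARAMS, 2.5)[("A", "m1")] == "lymphoid_biased"

    def test_equal_copy_numbers_balanced(self):
        matrix = make_matrix({("A", "m1"): {("Gr", 2.5): 0.3, ("B", 2.5): 0.3}})
        assert classify_lineage_bias(matrix, PARAMS, 2.5)[("A", "m1")] == "balanced"

    def test_undetected_when_nothing_measurable(self):
        matrix = make_matrix({("A", "m1"): {("Gr", 2.5): 0.005}})
        assert classify_lineage_bias(matrix, PARAMS, 2.5)[("A", "m1")] == "undetected"

    def test_scale_invariance_within_mouse(self):
        from clonetrace.containers import ClonalAbundanceMatrix

        rng = np.random.default_rng(4)
        matrix = random_abundance_matrix(rng, n_clones=15)
        scaled = ClonalAbundanceMatrix(matrix.abundance * 3.7, dict(matrix.groups))
        for tp in (2.5, 6.5):
            a = classify_lineage_bias(matrix, PARAMS, tp)
            b = classify_lineage_bias(scaled, PARAMS, tp)
            # specialization depends on the absolute floor; compare the fold
            # rule on clones measurable in both lineages in both matrices
            both = a.isin(["balanced", "myeloid_biased", "lymphoid_biased"]) & b.isin(
                ["balanced", "myeloid_biased", "lymphoid_biased"]
            )
            assert (a[both] == b[both]).all()


class TestBTBias:
    def test_b_only_specialized(self):
        matrix = make_matrix({("A", "m1"): {("B", 2.5): 0.2}})
        assert classify_bt_bias(matrix, PARAMS, 2.5)[("A", "m1")] == "B_specialized"

    def test_equal_shares_balanced(self):
        matrix = make_matrix({("A", "m1"): {("B", 2.5): 0.2, ("CD4T", 2.5): 0.2}})
        assert classify_bt_bias(matrix, PARAMS, 2.5)[("A", "m1")] == "BT_balanced"

    def test_t_biased_instance(self):
        # clone A holds B/T relative copy numbers 0.01 and 0.10
        matrix = make_matrix(
            {
                ("A", "m1"): {("B", 2.5): 0.01, ("CD8T", 2.5): 0.10},
                ("Z", "m1"): {("B", 2.5): 0.99, ("CD8T", 2.5): 0.90},
            }
        )
        assert classify_bt_bias(matrix, PARAMS, 2.5)[("A", "m1")] == "T_biased"

    def test_not_applicable_without_b_or_t(self):
        matrix = make_matrix({("A", "m1"): {("Gr", 2.5): 0.2}})
        assert classify_bt_bias(matrix, PARAMS, 2.5)[("A", "m1")] == "not_applicable"


class TestTemporal:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ({("Gr", 2.5): 0.1}, "early"),
            ({("Gr", 6.5): 0.1}, "late"),
            ({("Gr", 2.5): 0.1, ("Gr", 6.5): 0.1}, "persisted"),
            ({("Gr", 3.5): 0.1}, "neither"),
        ],
    )
    def test_reference_timepoint_logic(self, cells, expected):
        matrix = make_matrix({("A", "m1"): cells})
        presence = detect_produced_types(matrix, PARAMS)
        assert classify_temporal(presence, PARAMS, "Gr")[("A", "m1")] == expected

    def test_overall_uses_any_cell_type(self):
        matrix = make_matrix({("A", "m1"): {("Gr", 2.5): 0.1, ("B", 6.5): 0.1}})
        presence = detect_produced_types(matrix, PARAMS)
        assert classify_temporal(presence, PARAMS, None)[("A", "m1")] == "persisted"
        assert classify_temporal(presence, PARAMS, "Gr")[("A", "m1")] == "early"


class TestDynamics:
    @pytest.mark.parametrize(
        "early,late,expected",
        [
            (0.10, 0.30, "expanded"),
            (0.30, 0.10, "shrunken"),
            (0.10, 0.10, "tie"),
            (0.005, 0.30, "not_applicable"),  # not persisted: early below floor
        ],
    )
    def test_ratio_rule(self, early, late, expected):
        matrix = make_matrix({("A", "m1"): {("CD4T", 2.5): early, ("CD4T", 6.5): late}})
        assert classify_dynamics(matrix, PARAMS, "CD4T")[("A", "m1")] == expected

    def test_only_t_cell_populations_allowed(self):
        matrix = make_matrix({("A", "m1"): {("Gr", 2.5): 0.1}})
        with pytest.raises(ValueError, match="T-cell"):
            classify_dynamics(matrix, PARAMS, "Gr")

    def test_zero_denominator_excluded_with_warning(self, caplog):
        params = BiasParameters(detect_floor=0.0)
        matrix = make_matrix({("A", "m1"): {("CD4T", 6.5): 0.3}})
        with caplog.at_level("WARNING"):
            labels = classify_dynamics(matrix, params, "CD4T")
        assert labels[("A", "m1")] == "not_applicable"
        assert "zero early" in caplog.text


class TestEarlyLateOverlap:
    def test_categories_and_conservation(self):
        matrix = make_matrix(
            {
                ("A", "m1"): {("Gr", 2.5): 0.1},  # undetected at 6.5
                ("B", "m1"): {("B", 2.5): 0.1, ("B", 6.5): 0.1},  # lymphoid_specialized
                ("C", "m1"): {("Gr", 2.5): 0.1, ("Gr", 6.5): 0.1, ("B", 6.5): 0.1},  # multi
                ("D", "m1"): {("B", 6.5): 0.4},  # not early-detected: excluded
            }
        )
        tally = early_late_overlap(matrix, PARAMS).set_index("category")
        assert tally.loc["undetected", "count"] == 1
        assert tally.loc["lymphoid_specialized", "count"] == 1
        assert tally.loc["multilineage", "count"] == 1
        assert tally["count"].sum() == 3  # = number of early-detected clones
        assert tally["fraction"].sum() == pytest.approx(1.0)


class TestBruteForceOracle:
    """All label axes vs an independent literal re-implementation."""

    @pytest.mark.parametrize("seed", range(8))
    def test_all_axes_match_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        matrix = random_abundance_matrix(rng, n_clones=20, n_mice=2)
        bundle = classify_all(matrix, PARAMS)
        blocks = oracles.matrix_to_blocks(matrix)
        for mouse, block in blocks.items():
            for barcode, cells in block.items():
                clone = (barcode, mouse)
                for tp in (2.5, 6.5):
                    assert bundle.lineage_bias[tp][clone] == oracles.lineage_bias_label(
                        block, barcode, tp, PARAMS
                    ), f"lineage_bias {clone} @ {tp}"
                    assert bundle.bt_bias[tp][clone] == oracles.bt_bias_label(
                        block, barcode, tp, PARAMS
                    ), f"bt_bias {clone} @ {tp}"
                    expected_combo = oracles.combination(cells, tp, PARAMS.detect_floor)
                    got = bundle.combination[tp].get(clone)
                    assert got == expected_combo or (got is None and expected_combo is None)
                assert bundle.temporal["any"][clone] == oracles.temporal(cells, PARAMS)
                for ct in ("Gr", "B", "CD4T", "CD8T"):
                    assert bundle.temporal[ct][clone] == oracles.temporal(cells, PARAMS, ct)
                for ct in ("CD4T", "CD8T"):
                    assert bundle.dynamics[ct][clone] == oracles.dynamics(cells, PARAMS, ct)
                for (ct, tp), value in cells.items():
                    assert bool(bundle.high_abundance.loc[clone, (ct, tp)]) == (value > 0.05)


class TestInvariants:
    def test_exactly_one_label_per_axis(self):
        matrix = random_abundance_matrix(np.random.default_rng(7), n_clones=30)
        bundle = classify_all(matrix, PARAMS)
        for tp in (2.5, 6.5):
            assert set(bundle.lineage_bias[tp].index) == set(matrix.abundance.index)
            assert not bundle.lineage_bias[tp].isna().any()
        assert not bundle.temporal["any"].isna().any()

    def test_specialized_requires_other_lineage_below_floor(self):
        matrix = random_abundance_matrix(np.random.default_rng(8), n_clones=40)
        labels = classify_lineage_bias(matrix, PARAMS, 2.5)
        at_tp = matrix.at_timepoint(2.5)
        lymph_meas = (at_tp[["B", "CD4T", "CD8T"]] >= PARAMS.detect_floor).any(axis=1)
        assert not (labels.eq("myeloid_specialized") & lymph_meas).any()

    def test_raising_fold_threshold_never_creates_bias(self):
        matrix = random_abundance_matrix(np.random.default_rng(9), n_clones=40)
        loose = classify_lineage_bias(matrix, PARAMS, 2.5)
        strict = classify_lineage_bias(
            matrix, BiasParameters(fold_threshold=5.0), 2.5
        )
        moved = (loose == "balanced") & strict.isin(["myeloid_biased", "lymphoid_biased"])
        assert not moved.any()

    def test_raising_detect_floor_never_adds_produced_types(self):
        matrix = random_abundance_matrix(np.random.default_rng(10), n_clones=40)
        low = detect_produced_types(matrix, PARAMS)
        high = detect_produced_types(matrix, BiasParameters(detect_floor=0.05))
        assert not (high & ~low).any().any()
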
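"""Count tables, RPM, filters, proportions, arm ratios and the motif scan."""

import numpy as np
import pandas as pd
import pytest

from isomirseq.quantify import (
    arm_ratio,
    build_counts,
    filter_isomirs,
    filter_mature,
    isomir_proportions,
    motif_count,
    reconstruct_sequence,
    rpm_normalize,
)

from conftest import MIR16_5P


def design(samples_conditions):
    return pd.DataFrame(
        [
            {"sample": s, "condition": c, "experiment": i + 1}
            for i, (s, c) in enumerate(samples_conditions)
        ]
    )


class TestBuildCounts:
    def test_single_sample_counts(self):
        tables = build_counts({"s1": {("miR-a", "0"): 10}})
        assert tables.isomir_counts.loc[("miR-a", "0"), "s1"] == 10
        assert tables.mirna_counts.loc["miR-a", "s1"] == 10
        assert tables.library_sizes["s1"] == 10

    def test_absent_pairs_zero_filled(self):
        tables = build_counts(
            {"s1": {("miR-a", "0"): 5}, "s2": {("miR-a", "-1"): 3}}
        )
        assert tables.isomir_counts.loc[("miR-a", "0"), "s2"] == 0
        assert tables.isomir_counts.loc[("miR-a", "-1"), "s1"] == 0

    def test_empty_sample_all_zero_column(self):
        tables = build_counts({"s1": {("miR-a", "0"): 5}, "s2": {}})
        assert (tables.isomir_counts["s2"] == 0).all()

    def test_row_order_canonical_then_offsets(self):
        tables = build_counts(
            {
                "s1": {
                    ("miR-a", "+1"): 1,
                    ("miR-a", "0"): 1,
                    ("miR-a", "-3"): 1,
                    ("miR-a", "nt:T"): 1,
                    ("miR-a", "5p:+1"): 1,
                    ("miR-a", "-1"): 1,
                }
            }
        )
        labels = [lab for _, lab in tables.isomir_counts.index]
        assert labels == ["0", "-3", "-1", "+1", "5p:+1", "nt:T"]

    def test_mirna_is_label_sum(self):
        tables = build_counts(
            {"s1": {("miR-a", "0"): 7, ("miR-a", "-1"): 3, ("miR-b", "0"): 2}}
        )
        assert tables.mirna_counts.loc["miR-a", "s1"] == 10
        tables.check()


class TestRpm:
    def test_basic_scaling(self):
        counts = pd.DataFrame({"s1": [10, 0]}, index=["a", "b"])
        rpm = rpm_normalize(counts, pd.Series({"s1": 1_000_000}))
        assert rpm.loc["a", "s1"] == 10.0
        assert rpm.loc["b", "s1"] == 0.0

    def test_column_conservation_under_mapped_denominator(self):
        tables = build_counts(
            {"s1": {("a", "0"): 30, ("b", "0"): 70}, "s2": {("a", "0"): 10}}
        )
        np.testing.assert_allclose(tables.isomir_rpm.sum(axis=0), [1e6, 1e6])

    def test_zero_denominator_names_sample(self):
        counts = pd.DataFrame({"bad": [0]}, index=["a"])
        with pytest.raises(ValueError, match="bad"):
            rpm_normalize(counts, pd.Series({"bad": 0}))


class TestFilters:
    def make_rpm(self, value_a, value_b):
        return pd.DataFrame(
            {"c1": [value_a], "c2": [value_a], "t1": [value_b], "t2": [value_b]},
            index=["miR-x"],
        )

    DESIGN = design([("c1", "ctl"), ("c2", "ctl"), ("t1", "trt"), ("t2", "trt")])

    def test_kept_when_one_condition_passes(self):
        assert filter_mature(self.make_rpm(12.0, 0.0), self.DESIGN) == ["miR-x"]

    def test_dropped_below_threshold_everywhere(self):
        assert filter_mature(self.make_rpm(9.9, 9.9), self.DESIGN) == []

    def test_boundary_inclusive(self):
        assert filter_mature(self.make_rpm(10.0, 0.0), self.DESIGN) == ["miR-x"]

    def test_condition_mean_is_used(self):
        rpm = pd.DataFrame(
            {"c1": [19.0], "c2": [1.0], "t1": [0.0], "t2": [0.0]}, index=["miR-x"]
        )
        assert filter_mature(rpm, self.DESIGN) == ["miR-x"]  # mean(19,1)=10

    def test_isomir_threshold_one_rpm(self):
        rpm = pd.DataFrame(
            {"c1": [1.0, 0.5], "c2": [1.0, 0.5], "t1": [0.0, 0.5], "t2": [0.0, 0.5]},
            index=pd.MultiIndex.from_tuples(
                [("miR-x", "0"), ("miR-x", "-1")], names=["mature_id", "label"]
            ),
        )
        assert filter_isomirs(rpm, self.DESIGN) == [("miR-x", "0")]


class TestProportions:
    def idx(self, pairs):
        return pd.MultiIndex.from_tuples(pairs, names=["mature_id", "label"])

    def test_simple_proportions(self):
        counts = pd.DataFrame(
            {"s1": [80, 20]}, index=self.idx([("a", "0"), ("a", "-1")])
        )
        props = isomir_proportions(counts)
        np.testing.assert_allclose(props["s1"], [0.8, 0.2])

    def test_templated_only_excludes_tails_from_both_sides(self):
        counts = pd.DataFrame(
            {"s1": [80, 10, 10]},
            index=self.idx([("a", "0"), ("a", "-1"), ("a", "nt:T")]),
        )
        props = isomir_proportions(counts, templated_only=True)
        assert list(props.index) == [("a", "0"), ("a", "-1")]
        np.testing.assert_allclose(props["s1"], [8 / 9, 1 / 9])

    def test_tails_included_when_disabled(self):
        counts = pd.DataFrame(
            {"s1": [80, 10, 10]},
            index=self.idx([("a", "0"), ("a", "-1"), ("a", "nt:T")]),
        )
        props = isomir_proportions(counts, templated_only=False)
        np.testing.assert_allclose(props["s1"], [0.8, 0.1, 0.1])

    def test_zero_denominator_is_missing_not_zero(self):
        counts = pd.DataFrame(
            {"s1": [0, 0], "s2": [3, 1]}, index=self.idx([("a", "0"), ("a", "-1")])
        )
        props = isomir_proportions(counts)
        assert props["s1"].isna().all()
        np.testing.assert_allclose(props["s2"], [0.75, 0.25])

    def test_conservation_per_mirna_sample(self):
        rng = np.random.default_rng(3)
        pairs = [(f"m{i}", lab) for i in range(5) for lab in ("0", "-1", "+2")]
        counts = pd.DataFrame(
            rng.integers(0, 50, size=(15, 4)),
            index=self.idx(pairs),
            columns=list("abcd"),
        )
        props = isomir_proportions(counts)
        sums = props.groupby(level="mature_id").sum(min_count=1)
        valid = sums.stack().dropna()
        np.testing.assert_allclose(valid, 1.0, atol=1e-9)


class TestArmRatio:
    def rpm(self, v5, v3):
        return pd.DataFrame(
            {"s1": [v5, v3]}, index=["toy-miR-16-5p", "toy-miR-16-3p"]
        )

    def test_equal_arms_zero(self, mir16_ref):
        table = arm_ratio(self.rpm(100.0, 100.0), mir16_ref, epsilon=0.5)
        assert table.loc["hp1", "s1"] == 0.0

    def test_twofold_near_one(self, mir16_ref):
        table = arm_ratio(self.rpm(200.0, 100.0), mir16_ref, epsilon=1e-9)
        assert table.loc["hp1", "s1"] == pytest.approx(1.0, abs=1e-6)

    def test_antisymmetry_under_arm_swap(self, mir16_ref):
        a = arm_ratio(self.rpm(150.0, 60.0), mir16_ref)
        b = arm_ratio(self.rpm(60.0, 150.0), mir16_ref)
        assert a.loc["hp1", "s1"] == pytest.approx(-b.loc["hp1", "s1"])

    def test_single_arm_hairpin_excluded(self):
        from isomirseq.reference import build_reference

        ref = build_reference({"h1": "A" * 40}, [("solo-5p", "h1", "5p", 0, 20)])
        table = arm_ratio(pd.DataFrame({"s1": [5.0]}, index=["solo-5p"]), ref)
        assert table.empty

    def test_epsilon_must_be_positive(self, mir16_ref):
        with pytest.raises(ValueError):
            arm_ratio(self.rpm(1.0, 1.0), mir16_ref, epsilon=0.0)


class TestMotif:
    def test_present_and_absent(self):
        hits, frac = motif_count({"a": MIR16_5P, "b": "ACGT" * 5})
        assert bool(hits["a"]) is True  # ...GTAAATA... carries the AU-rich motif
        assert bool(hits["b"]) is False
        assert frac == 0.5

    def test_rna_alphabet_accepted(self):
        hits, _ = motif_count({"a": "ggUAAAUgg"}, motif="UAAAU")
        assert bool(hits["a"]) is True

    def test_hand_counted_fraction(self):
        seqs = {f"s{i}": ("TAAAT" if i < 3 else "CCCCC") + "GGGGG" for i in range(10)}
        _, frac = motif_count(seqs)
        assert frac == 0.3


class TestReconstruct:
    def test_round_trip_with_caller_classes(self, mir16_ref):
        assert reconstruct_sequence(mir16_ref, "toy-miR-16-5p") == MIR16_5P
        assert (
            reconstruct_sequence(mir16_ref, "toy-miR-16-5p", offset3=-2)
            == MIR16_5P[:-2]
        )
        tailed = reconstruct_sequence(
            mir16_ref, "toy-miR-16-5p", offset3=1, nt_tail="A"
        )
        assert tailed == MIR16_5P + "A"
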
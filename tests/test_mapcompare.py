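"""Span ratios, fragment-map merging and cross-species tag matching."""

import numpy as np
import pandas as pd
import pytest

from radmap.datasets import sockeye_shared_spans
from radmap.mapcompare import (
    TagCatalogView,
    match_tags,
    merge_fragment_maps,
    shared_span_ratio,
    span_ratio_table,
    synteny_table,
)
from radmap.linkmap import GeneticMap, LinkageGroup


def _group(gid, sex, markers, positions):
    return LinkageGroup(
        group_id=gid, sex=sex, markers=list(markers),
        adjacent_rf=[0.0] * (len(markers) - 1),
        positions=np.asarray(positions, dtype=float),
        members={m: [m] for m in markers},
    )


def _map(sex, groups):
    return GeneticMap(sex=sex, groups=groups, fragments=[], unplaced=[])


class TestSpanRatios:
    def test_published_table_reproduces_totals(self):
        table = span_ratio_table(sockeye_shared_spans())
        total = table.iloc[-1]
        assert total["group"] == "Total"
        assert total["female_cM"] == pytest.approx(2924.1, abs=0.05)
        assert total["male_cM"] == pytest.approx(3016.9, abs=0.05)
        assert total["ratio"] == pytest.approx(0.96924, abs=5e-6)

    @pytest.mark.parametrize("group,expected", [
        ("1", 1.708), ("20", 0.73684), ("23", 0.70865),
    ])
    def test_per_row_ratios(self, group, expected):
        table = span_ratio_table(sockeye_shared_spans()).set_index("group")
        assert table.loc[group, "ratio"] == pytest.approx(expected, abs=5e-4)

    def test_identical_maps_give_unit_ratios(self):
        g1 = _group("LG1", "female", ["a", "b", "c"], [0.0, 10.0, 42.7])
        g2 = _group("LG1", "male", ["a", "b", "c"], [0.0, 10.0, 42.7])
        table = shared_span_ratio(_map("female", [g1]), _map("male", [g2]))
        assert np.allclose(table["ratio"], 1.0)

    def test_span_uses_first_and_last_shared_markers(self):
        female = _map("female", [
            _group("F1", "female", ["a", "b", "c", "x"], [0, 20, 42.7, 60]),
        ])
        male = _map("male", [
            _group("M1", "male", ["a", "y", "c"], [5, 10, 30]),
        ])
        table = shared_span_ratio(female, male)
        row = table.iloc[0]
        assert row["female_cM"] == pytest.approx(42.7)
        assert row["male_cM"] == pytest.approx(25.0)
        assert row["ratio"] == pytest.approx(1.708, abs=1e-3)

    def test_single_shared_marker_pair_skipped(self):
        female = _map("female", [_group("F1", "female", ["a", "q"], [0, 10])])
        male = _map("male", [_group("M1", "male", ["a", "z"], [0, 10])])
        table = shared_span_ratio(female, male)
        assert table.empty


class TestMergeFragments:
    def test_two_marker_overlap_merges(self):
        merged, conflicts = merge_fragment_maps([["a", "b", "c"], ["b", "c", "d"]])
        assert merged == [["a", "b", "c", "d"]]
        assert conflicts == []

    def test_single_marker_overlap_does_not_merge(self):
        merged, _ = merge_fragment_maps([["a", "b"], ["b", "c"]])
        assert sorted(map(tuple, merged)) == [("a", "b"), ("b", "c")]

    def test_order_conflict_left_unmerged_and_logged(self, caplog):
        # three shared markers in incompatible relative order
        with caplog.at_level("WARNING"):
            merged, conflicts = merge_fragment_maps(
                [["a", "b", "c"], ["a", "c", "b", "d"]]
            )
        assert len(merged) == 2
        assert len(conflicts) == 1

    def test_reversed_fragment_merges(self):
        # a two-marker overlap can always be oriented by reversal
        merged, _ = merge_fragment_maps([["a", "b", "c"], ["d", "c", "b"]])
        assert merged == [["a", "b", "c", "d"]]

    def test_input_order_independence(self):
        frags = [["a", "b", "c"], ["b", "c", "d"], ["e", "f"]]
        m1, _ = merge_fragment_maps(frags)
        m2, _ = merge_fragment_maps(frags[::-1])
        assert sorted(map(tuple, m1)) == sorted(map(tuple, m2))


def _random_tag(rng):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, 59))


def _revcomp(seq):
    return seq[::-1].translate(str.maketrans("ACGT", "TGCA"))


class TestMatchTags:
    def setup_method(self):
        self.rng = np.random.default_rng(7)

    def _mutate(self, seq, k):
        out = list(seq)
        for pos in range(k):
            out[pos] = "A" if seq[pos] != "A" else "C"
        return "".join(out)

    def test_identical_accepted_in_both_modes(self):
        t = _random_tag(self.rng)
        q = TagCatalogView.from_sequences({"q1": t})
        s = TagCatalogView.from_sequences({"s1": t})
        for mode in ("unmapped", "mapped"):
            out = match_tags(q, s, mode=mode)
            assert len(out) == 1 and out.iloc[0]["mismatches"] == 0

    def test_two_mismatches_mode_dependent(self):
        t = _random_tag(self.rng)
        q = TagCatalogView.from_sequences({"q1": t})
        s = TagCatalogView.from_sequences({"s1": self._mutate(t, 2)})
        assert match_tags(q, s, mode="unmapped").empty
        assert len(match_tags(q, s, mode="mapped")) == 1

    def test_reverse_complement_matched(self):
        t = _random_tag(self.rng)
        q = TagCatalogView.from_sequences({"q1": t})
        s = TagCatalogView.from_sequences({"s1": _revcomp(t)})
        out = match_tags(q, s, mode="unmapped")
        assert len(out) == 1 and out.iloc[0]["strand"] == "-"

    def test_offset_overlap_accepted_in_mapped_mode(self):
        t = _random_tag(self.rng)
        shifted = t[3:] + "AAA"  # 56-nt overlap at offset 3
        q = TagCatalogView.from_sequences({"q1": t})
        s = TagCatalogView.from_sequences({"s1": shifted})
        out = match_tags(q, s, mode="mapped")
        assert len(out) == 1
        assert out.iloc[0]["overlap"] >= 56

    def test_unmapped_acceptance_symmetric(self):
        t = _random_tag(self.rng)
        u = self._mutate(t, 1)
        a = TagCatalogView.from_sequences({"x": t})
        b = TagCatalogView.from_sequences({"y": u})
        assert len(match_tags(a, b, mode="unmapped")) == len(
            match_tags(b, a, mode="unmapped")
        )


class TestSynteny:
    def test_counts_per_group_pair(self):
        rng = np.random.default_rng(1)
        tags = {f"q{i}": _random_tag(rng) for i in range(3)}
        q = TagCatalogView.from_sequences(tags, {k: "7" for k in tags})
        s = TagCatalogView.from_sequences(
            {k.replace("q", "s"): v for k, v in tags.items()},
            {k.replace("q", "s"): "WS10" for k in tags},
        )
        out = synteny_table(match_tags(q, s, mode="mapped"))
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["query_lg"], row["subject_lg"], row["n_hits"]) == ("7", "WS10", 3)

    def test_no_matches_empty(self):
        out = synteny_table(pd.DataFrame(
            columns=["accepted", "query_lg", "subject_lg"]))
        assert out.empty

    def test_planted_shared_tags_recovered(self):
        rng = np.random.default_rng(2)
        shared = {f"t{i}": _random_tag(rng) for i in range(6)}
        q_lg = {f"t{i}": f"LG{i % 2 + 1}" for i in range(6)}
        s_lg = {f"t{i}": f"WS{i % 2 + 1}" for i in range(6)}
        q = TagCatalogView.from_sequences(shared, q_lg)
        s = TagCatalogView.from_sequences(shared, s_lg)
        out = synteny_table(match_tags(q, s, mode="unmapped"))
        assert out["n_hits"].sum() == 6
        assert set(zip(out["query_lg"], out["subject_lg"])) == {
            ("LG1", "WS1"), ("LG2", "WS2")
        }
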
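"""Curated group table, module subdivision, type-X fit levels, overlaps."""

import numpy as np
import pandas as pd
import pytest

from ghfcooc.functional_groups import (
    FitLevel,
    FunctionalGroup,
    assign_types,
    collection,
    collection_overlap,
    derive_groups,
    fit_level,
    load_group_table,
    phylum_prevalence,
    write_group_table,
)
from ghfcooc.network_analysis import Partition

from conftest import make_matrix


@pytest.fixture(scope="module")
def packaged():
    return load_group_table()


class TestPackagedTable:
    def test_twelve_groups_a_to_l(self, packaged):
        assert [g.group_id for g in packaged] == list("ABCDEFGHIJKL")

    def test_group_e_members(self, packaged):
        e = next(g for g in packaged if g.group_id == "E")
        assert e.members == frozenset(
            {"GH137", "GH138", "GH139", "GH141", "GH142", "GH143"})

    def test_shared_families_are_exactly_gh55_gh64(self, packaged):
        counts = {}
        for g in packaged:
            for ghf in g.members:
                counts[ghf] = counts.get(ghf, 0) + 1
        shared = {g for g, n in counts.items() if n == 2}
        assert shared == {"GH55", "GH64"}
        in_k = next(g for g in packaged if g.group_id == "K").members
        in_l = next(g for g in packaged if g.group_id == "L").members
        assert {"GH55", "GH64"} <= in_k and {"GH55", "GH64"} <= in_l

    def test_gh144_ungrouped(self, packaged):
        assert all("GH144" not in g.members for g in packaged)

    def test_triple_membership_rejected(self, tmp_path):
        groups = [
            FunctionalGroup("X", frozenset({"GH13"}), "M1"),
            FunctionalGroup("Y", frozenset({"GH13"}), "M2"),
            FunctionalGroup("Z", frozenset({"GH13", "GH1"}), "M3"),
        ]
        path = tmp_path / "groups.tsv"
        write_group_table(groups, path)
        with pytest.raises(ValueError, match="more than 2"):
            load_group_table(path)

    def test_round_trip(self, packaged, tmp_path):
        path = tmp_path / "groups.tsv"
        write_group_table(packaged, path)
        back = load_group_table(path)
        assert [(g.group_id, g.members) for g in back] == [
            (g.group_id, g.members) for g in packaged]


class TestDeriveGroups:
    def nine_module_partition(self):
        # mirrors the packaged layout: 9 modules, 3 of them split in two
        members = {
            0: ["GH3", "GH2"], 1: ["GH13", "GH77"], 2: ["GH1", "GH4"],
            3: ["GH137", "GH138"], 4: ["GH82", "GH86"], 5: ["GH20", "GH29"],
            6: ["GH23", "GH102"], 7: ["GH28", "GH88"], 8: ["GH46", "GH6", "GH55"],
        }
        return Partition(
            {g: m for m, gs in members.items() for g in gs}, 1.0, 0)

    def test_nine_modules_three_splits_give_twelve(self):
        part = self.nine_module_partition()
        split_map = {
            0: {"GH3": "A", "GH2": "B"},
            1: "C", 2: "D", 3: "E", 4: "F",
            5: {"GH20": "G", "GH29": "H"},
            6: "I", 7: "J",
            8: {"GH46": "K", "GH6": "L", "GH55": ["K", "L"]},
        }
        groups = derive_groups(part, split_map)
        assert len(groups) == 12
        by_id = {g.group_id: g for g in groups}
        assert "GH55" in by_id["K"].members and "GH55" in by_id["L"].members

    def test_no_splits_is_identity_on_modules(self):
        part = self.nine_module_partition()
        groups = derive_groups(part, {m: f"G{m}" for m in range(9)})
        assert len(groups) == 9
        assert {frozenset(g.members) for g in groups} == {
            frozenset(m) for m in part.modules().values()}

    def test_incomplete_subdivision_errors(self):
        part = self.nine_module_partition()
        split_map = {m: f"G{m}" for m in range(9)}
        split_map[0] = {"GH3": "A"}  # omits GH2
        with pytest.raises(ValueError, match="GH2"):
            derive_groups(part, split_map)

    def test_membership_union_conserved(self, rng):
        nodes = [f"GH{i}" for i in range(1, 21)]
        part = Partition({n: int(rng.integers(0, 4)) for n in nodes}, 1.0, 0)
        split_map = {}
        dropped = set()
        for m, members in part.modules().items():
            if m == 0:
                rule = {}
                for g in members:
                    rule[g] = None if rng.random() < 0.3 else f"S{int(rng.integers(0, 2))}"
                    if rule[g] is None:
                        dropped.add(g)
                split_map[m] = rule
            else:
                split_map[m] = f"G{m}"
        groups = derive_groups(part, split_map)
        union = set().union(*(g.members for g in groups)) if groups else set()
        assert union == set(nodes) - dropped


class TestFitLevels:
    def test_perfect_two_member_group(self):
        m = make_matrix({"GH13": [2], "GH77": [1], "GH1": [0]})
        groups = [FunctionalGroup("C", frozenset({"GH13", "GH77"}), "M2")]
        (a,) = assign_types(m, groups)
        assert a.labels["C"] is FitLevel.perfect

    def test_single_family_is_none(self):
        m = make_matrix({"GH3": [5], "GH5": [0], "GH9": [0]})
        groups = [FunctionalGroup("A", frozenset({"GH3", "GH5", "GH9"}), "M1")]
        (a,) = assign_types(m, groups)
        assert a.labels["A"] is FitLevel.none

    def test_requires_aveF(self):
        m = make_matrix({"GH13": [1]}, variant="minF")
        with pytest.raises(ValueError, match="aveF"):
            assign_types(m, [FunctionalGroup("C", frozenset({"GH13"}), "M")])

    @pytest.mark.parametrize("size,n_present,expect", [
        (8, 0, FitLevel.none), (8, 1, FitLevel.none), (8, 2, FitLevel.partial),
        (8, 5, FitLevel.partial), (8, 6, FitLevel.large), (8, 8, FitLevel.perfect),
        (4, 3, FitLevel.large), (2, 2, FitLevel.perfect), (3, 2, FitLevel.partial),
        (3, 3, FitLevel.perfect),
    ])
    def test_threshold_table(self, size, n_present, expect):
        assert fit_level(n_present, size) is expect

    def test_implication_chain_and_counting_oracle(self, rng):
        ghfs = [f"GH{i}" for i in range(1, 13)]
        m = make_matrix(pd.DataFrame(
            rng.integers(0, 2, size=(25, 12)), columns=ghfs))
        groups = [
            FunctionalGroup("P", frozenset(ghfs[:6]), "M1"),
            FunctionalGroup("Q", frozenset(ghfs[6:8]), "M2"),
            FunctionalGroup("R", frozenset(ghfs[8:]), "M3"),
        ]
        import math
        for a in assign_types(m, groups):
            present = {g for g in ghfs if m.values.loc[a.species, g] > 0}
            for grp in groups:
                n = len(present & grp.members)
                size = len(grp.members)
                lvl = a.labels[grp.group_id]
                # brute-force subset counting oracle
                if n == size:
                    assert lvl is FitLevel.perfect
                elif n >= max(2, math.ceil(0.75 * size)):
                    assert lvl is FitLevel.large
                elif n >= 2:
                    assert lvl is FitLevel.partial
                else:
                    assert lvl is FitLevel.none
                # perfect => large => partial
                if lvl >= FitLevel.perfect:
                    assert lvl >= FitLevel.large
                if lvl >= FitLevel.large:
                    assert lvl >= FitLevel.partial

    def test_two_member_groups_partial_equals_perfect(self, rng):
        m = make_matrix(pd.DataFrame(
            rng.integers(0, 3, size=(20, 2)), columns=["GH13", "GH77"]))
        groups = [FunctionalGroup("C", frozenset({"GH13", "GH77"}), "M2")]
        for a in assign_types(m, groups):
            assert a.labels["C"] in (FitLevel.none, FitLevel.perfect)


class TestPrevalenceAndOverlap:
    def assignments(self):
        m = make_matrix(
            {"GH13": [1, 1, 1, 0, 1, 1, 1, 1, 0, 0],
             "GH77": [1, 1, 1, 0, 1, 1, 1, 0, 0, 0],
             "GH1": [1, 1, 0, 0, 0, 0, 0, 0, 0, 0],
             "GH4": [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]},
            phyla=["Bacteroidetes"] * 10,
        )
        groups = [
            FunctionalGroup("C", frozenset({"GH13", "GH77"}), "M2"),
            FunctionalGroup("D", frozenset({"GH1", "GH4"}), "M3"),
        ]
        return m, assign_types(m, groups)

    def test_phylum_frequency(self):
        m, assigns = self.assignments()
        tax = dict(zip(m.row_keys, m.taxonomy["phylum"]))
        df = phylum_prevalence(assigns, tax)
        row = df[(df.group == "C") & (df.phylum == "Bacteroidetes")].iloc[0]
        assert row["count"] == 6 and row["frequency"] == pytest.approx(0.6)

    def test_group_with_no_qualifiers_has_no_rows(self):
        m, _ = self.assignments()
        groups = [FunctionalGroup("Z", frozenset({"GH9", "GH10"}), "M9")]
        assigns = assign_types(m, groups)
        tax = dict(zip(m.row_keys, m.taxonomy["phylum"]))
        assert phylum_prevalence(assigns, tax).empty

    def test_subset_collection_fully_covered(self):
        _, assigns = self.assignments()
        cov, is_subset = collection_overlap(assigns, "C", "D")
        assert cov == pytest.approx(1.0) and is_subset
        assert collection(assigns, "D") < collection(assigns, "C")

    def test_partial_coverage_matches_set_arithmetic(self, rng):
        ghfs = ["GH1", "GH2", "GH3", "GH4"]
        m = make_matrix(pd.DataFrame(
            rng.integers(0, 2, size=(30, 4)), columns=ghfs))
        groups = [
            FunctionalGroup("X", frozenset(ghfs[:2]), "M1"),
            FunctionalGroup("Y", frozenset(ghfs[2:]), "M2"),
        ]
        assigns = assign_types(m, groups)
        x = collection(assigns, "X")
        y = collection(assigns, "Y")
        cov, is_subset = collection_overlap(assigns, "X", "Y")
        if y:
            assert cov == pytest.approx(len(x & y) / len(y))
            assert is_subset == (y <= x)

    def test_disjoint_collections_zero(self):
        m = make_matrix({"GH1": [1, 0], "GH2": [1, 0], "GH3": [0, 1], "GH4": [0, 1]})
        groups = [
            FunctionalGroup("X", frozenset({"GH1", "GH2"}), "M1"),
            FunctionalGroup("Y", frozenset({"GH3", "GH4"}), "M2"),
        ]
        assigns = assign_types(m, groups)
        cov, is_subset = collection_overlap(assigns, "X", "Y")
        assert cov == 0.0 and not is_subset
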
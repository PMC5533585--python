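"""Hit-set contrasts, pairwise overlaps, and network export."""

import networkx as nx
import pandas as pd
import pytest

from bioidpipe.compare import (
    HitSet,
    build_network,
    contrast_datasets,
    ct_specific_inputs,
    export_network,
    family_core_hits,
    pairwise_ct_overlap,
    round_half_up,
)


def hs(label, proteins, **kw):
    return HitSet(dataset_label=label, proteins=frozenset(proteins), **kw)


class TestContrast:
    def test_small_exhaustive_case(self):
        part = contrast_datasets([hs("A", {"x", "y"}), hs("B", {"y", "z"})])
        assert part.loc["x", "category"] == "unique"
        assert part.loc["z", "category"] == "unique"
        assert part.loc["y", "category"] == "shared"
        assert part.loc["y", "datasets"] == ("A", "B")

    def test_identical_sets_all_shared(self):
        part = contrast_datasets([hs("A", {"x", "y"}), hs("B", {"x", "y"})])
        assert (part["category"] == "shared").all()

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            contrast_datasets([hs("A", {"x"}), hs("A", {"y"})])

    def test_partition_matches_brute_force_tally(self, rng):
        universe = [f"G{i:03d}" for i in range(200)]
        sets = [
            hs(lab, rng.choice(universe, size=50, replace=False))
            for lab in ("A", "B", "C")
        ]
        part = contrast_datasets(sets)
        # brute force: per-protein membership vector over all proteins
        for pid in universe:
            found_in = tuple(
                sorted(s.dataset_label for s in sets if pid in s.proteins)
            )
            if not found_in:
                assert pid not in part.index
            else:
                assert part.loc[pid, "datasets"] == found_in
        # exact conservation: partition cells cover the union
        union = set().union(*(s.proteins for s in sets))
        assert set(part.index) == union


class TestFamilyCore:
    FAMILIES = {
        "BICD": [hs("BICD1", {"a", "b"}), hs("BICD2", {"c"})],
        "HOOK": [hs("HOOK1", {"a", "c"})],
        "NIN": [hs("NIN", {"a", "c", "d"})],
    }

    def test_protein_in_every_family_included(self):
        assert "a" in family_core_hits(self.FAMILIES)

    def test_protein_in_one_family_only_excluded(self):
        families = dict(self.FAMILIES)
        families["BICD"] = [hs("BICD1", {"b", "x"}), hs("BICD2", {"x"})]
        assert "x" not in family_core_hits(families)

    def test_core_is_intersection_of_family_unions(self):
        assert family_core_hits(self.FAMILIES) == {"a", "c"} & {"a", "b", "c"}

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            family_core_hits({"BICD": [], "HOOK": [hs("HOOK1", {"a"})]})


class TestCtSpecific:
    def test_nt_union_removed(self):
        ct = ct_specific_inputs(
            [hs("ntX", {"b"}, terminus="NT")],
            [hs("ctX", {"a", "b", "c"}, terminus="CT")],
        )
        assert ct["ctX"].proteins == {"a", "c"}

    def test_disjoint_ct_unchanged(self):
        ct = ct_specific_inputs(
            [hs("ntX", {"q"}, terminus="NT")],
            [hs("ctX", {"a", "b"}, terminus="CT")],
        )
        assert ct["ctX"].proteins == {"a", "b"}

    def test_anti_monotone_in_nt_union(self):
        ct_sets = [hs("ctX", {"a", "b", "c"}, terminus="CT")]
        small = ct_specific_inputs([hs("nt1", {"a"})], ct_sets)
        large = ct_specific_inputs([hs("nt1", {"a"}), hs("nt2", {"b"})], ct_sets)
        assert large["ctX"].proteins <= small["ctX"].proteins


def sets_with_exclusive_overlaps(pair_counts, input_n):
    """Construct CT-specific sets whose exclusive pairwise overlaps and
    total sizes are exactly as requested; filler proteins are unique."""
    labels = sorted(input_n)
    members = {lab: set() for lab in labels}
    for (r, c), n in pair_counts.items():
        for i in range(n):
            pid = f"shared_{r}_{c}_{i}"
            members[r].add(pid)
            members[c].add(pid)
    for lab in labels:
        fill = input_n[lab] - len(members[lab])
        assert fill >= 0
        members[lab].update(f"unique_{lab}_{i}" for i in range(fill))
    return {lab: hs(lab, members[lab], terminus="CT") for lab in labels}


# printed pairwise-overlap table: shared counts and dataset input sizes
TABLE_COUNTS = {
    ("BICD1", "BICD2"): 44, ("BICD1", "HOOK1"): 4, ("BICD1", "HOOK3"): 0,
    ("BICD1", "NIN"): 5, ("BICD1", "NINL"): 5, ("BICD2", "HOOK1"): 4,
    ("BICD2", "HOOK3"): 7, ("BICD2", "NIN"): 6, ("BICD2", "NINL"): 0,
    ("HOOK1", "HOOK3"): 14, ("HOOK1", "NIN"): 3, ("HOOK1", "NINL"): 1,
    ("HOOK3", "NIN"): 2, ("HOOK3", "NINL"): 1, ("NIN", "NINL"): 27,
}
TABLE_INPUT_N = {
    "BICD1": 92, "BICD2": 87, "HOOK1": 39, "HOOK3": 37, "NIN": 74, "NINL": 53,
}


class TestPairwiseOverlap:
    def test_reproduces_published_percentages(self):
        ct = sets_with_exclusive_overlaps(TABLE_COUNTS, TABLE_INPUT_N)
        result = pairwise_ct_overlap(ct)
        assert result.percent.loc["BICD1", "BICD2"] == 50.6
        assert result.percent.loc["BICD2", "BICD1"] == 47.8
        assert result.percent.loc["NINL", "NIN"] == 36.5
        assert result.percent.loc["HOOK1", "HOOK3"] == 37.8
        assert result.percent.loc["BICD1", "HOOK3"] == 0.0

    def test_counts_symmetric(self):
        ct = sets_with_exclusive_overlaps(TABLE_COUNTS, TABLE_INPUT_N)
        counts = pairwise_ct_overlap(ct).counts
        assert (counts == counts.T).all().all()

    def test_exclusive_mode_ignores_triple_overlap(self):
        triple = "in_all_three"
        ct = {
            "A": hs("A", {triple, "a1"}), "B": hs("B", {triple, "b1"}),
            "C": hs("C", {triple}),
        }
        excl = pairwise_ct_overlap(ct, exclusive=True)
        incl = pairwise_ct_overlap(ct, exclusive=False)
        assert excl.counts.loc["A", "B"] == 0
        assert incl.counts.loc["A", "B"] == 1

    def test_percent_range_and_empty_column(self):
        ct = {"A": hs("A", {"x", "y"}), "B": hs("B", {"x"}), "C": hs("C", set())}
        result = pairwise_ct_overlap(ct)
        valid = result.percent.loc[["A", "B"], ["A", "B"]].stack().dropna()
        assert ((valid >= 0) & (valid <= 100)).all()
        assert result.percent["C"].isna().all()

    def test_rounding_half_up(self):
        assert round_half_up(50.65) == 50.7   # banker's would give 50.6
        assert round_half_up(36.45) == 36.5
        assert round_half_up(0.04) == 0.0


class TestNetwork:
    def test_one_shared_protein_three_nodes_two_edges(self):
        g = build_network([hs("A", {"x"}), hs("B", {"x"})])
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 2
        assert g.nodes["x"]["role"] == "hit"

    def test_empty_shared_set_gives_valid_empty_files(self, tmp_path):
        g = build_network([hs("A", {"x"}), hs("B", {"y"})])  # nothing shared
        sif = tmp_path / "net.sif"
        gml = tmp_path / "net.graphml"
        export_network(g, sif, gml)
        assert sif.read_text() == ""
        assert nx.read_graphml(gml).number_of_nodes() == 0

    def test_three_family_flag(self):
        sets = [
            hs("BICD1", {"x"}, family="BICD"),
            hs("HOOK1", {"x"}, family="HOOK"),
            hs("NIN", {"x"}, family="NIN"),
        ]
        g = build_network(sets)
        assert g.nodes["x"]["three_family"]

    def test_graphml_round_trip_isomorphic(self, tmp_path, rng):
        universe = [f"G{i}" for i in range(30)]
        sets = [
            hs(lab, rng.choice(universe, size=12, replace=False), family=lab[0])
            for lab in ("Alpha", "Beta", "Gamma")
        ]
        g = build_network(sets)
        path = tmp_path / "net.graphml"
        export_network(g, tmp_path / "net.sif", path)
        back = nx.read_graphml(path)
        assert nx.is_isomorphic(g, back)
        assert set(back.nodes) == set(g.nodes)
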
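import numpy as np
import pandas as pd
import pytest

from capclade.clades import (
    SubClade,
    clades_table,
    mad_root,
    partition_major_clades,
    representation_table,
)
from capclade.seqio import read_newick


def _groups(**kw):
    return kw


class TestMajorClades:
    def test_two_symmetric_clades(self):
        t = read_newick("((d1:1,h1:1):1,(d2:1,h2:1):1);")
        part = partition_major_clades(
            t, _groups(d1="core_dino", h1="heterokont",
                       d2="core_dino", h2="heterokont"), rooting="none")
        assert len(part.majors) == 2
        assert {frozenset(m.leaf_ids) for m in part.majors} == {
            frozenset({"d1", "h1"}), frozenset({"d2", "h2"})}

    def test_nested_single_clade(self):
        t = read_newick("(d1:1,(d2:1,(h1:1,h2:1):1):1);")
        part = partition_major_clades(
            t, _groups(d1="core_dino", d2="core_dino",
                       h1="heterokont", h2="heterokont"),
            rooting="outgroup:heterokont")
        assert len(part.majors) == 1
        assert set(part.majors[0].leaf_ids) == {"d1", "d2", "h1", "h2"}

    def test_no_both_group_node_is_unresolved(self):
        t = read_newick("((d1:1,d2:1):1,(d3:1,d4:1):1);")
        with pytest.warns(UserWarning, match="unresolved"):
            part = partition_major_clades(
                t, _groups(d1="core_dino", d2="core_dino",
                           d3="core_dino", d4="core_dino"))
        assert part.unresolved and part.majors[0].name == "unresolved"

    def test_numbering_by_core_dino_count(self):
        t = read_newick("(((d1:1,d2:1):0.5,h1:1):1,(d3:1,h2:1):1);")
        part = partition_major_clades(
            t, _groups(d1="core_dino", d2="core_dino", d3="core_dino",
                       h1="heterokont", h2="heterokont"))
        sizes = [sum(1 for x in m.leaf_ids if x.startswith("d"))
                 for m in part.majors]
        assert part.majors[0].name == "eIF4E-1"
        assert sizes == sorted(sizes, reverse=True)


class TestSubClades:
    GROUPS = {**{f"d{i}": "core_dino" for i in range(1, 11)},
              "h1": "heterokont", "h2": "heterokont",
              "a1": "apicomplexan", "a2": "apicomplexan",
              "s1": "syndinean"}
    SPECIES = {f"d{i}": f"sp{i}" for i in range(1, 11)}

    def test_single_pure_subtree(self):
        t = read_newick("((h1:1,h2:1):1,((d1:1,d2:1):0.5,(d3:1,d4:1):0.5):1);")
        part = partition_major_clades(t, self.GROUPS, species=self.SPECIES)
        (mc,) = part.majors
        assert len(mc.subclades) == 1
        assert mc.subclades[0].name == "1a"
        assert set(mc.subclades[0].leaf_ids) == {"d1", "d2", "d3", "d4"}

    def test_interleaved_apicomplexans_split_subclades(self):
        t = read_newick(
            "((h1:1,h2:1):1,((d1:1,d2:1):0.5,((a1:1,a2:1):0.5,"
            "(d3:1,d4:1):0.5):0.5):1);")
        part = partition_major_clades(t, self.GROUPS, species=self.SPECIES)
        names = {frozenset(sc.leaf_ids) for sc in part.majors[0].subclades}
        assert names == {frozenset({"d1", "d2"}), frozenset({"d3", "d4"})}

    def test_masked_syndinean_does_not_break_monophyly(self):
        t = read_newick(
            "((h1:1,h2:1):1,((d1:1,s1:1):0.5,(d2:1,d3:1):0.5):1);")
        part = partition_major_clades(t, self.GROUPS, species=self.SPECIES)
        (sc,) = part.majors[0].subclades
        assert set(sc.leaf_ids) == {"d1", "d2", "d3"}

    def test_singleton_interloper_tolerated(self):
        # one aberrant apicomplexan leaf nested inside an otherwise pure
        # core-dino group does not dissolve it
        t = read_newick(
            "((h1:1,h2:1):1,((d1:0.1,(a1:3,d2:0.1):0.1):0.1,"
            "(d3:0.1,d4:0.1):0.1):1);")
        part = partition_major_clades(t, self.GROUPS, species=self.SPECIES,
                                      rooting="none")
        (sc,) = part.majors[0].subclades
        assert set(sc.leaf_ids) == {"d1", "d2", "d3", "d4"}

    def test_representation_split_of_sister_groups(self):
        # two species-rich monophyletic blocks on substantial stems count
        # as two sub-clades even without a separator between them
        left = "(" + ",".join(f"d{i}:0.05" for i in range(1, 6)) + "):0.5"
        right = "(" + ",".join(f"e{i}:0.05" for i in range(1, 6)) + "):0.5"
        t = read_newick(f"((h1:1,h2:1):1,({left},{right}):1);")
        groups = {**{f"d{i}": "core_dino" for i in range(1, 6)},
                  **{f"e{i}": "core_dino" for i in range(1, 6)},
                  "h1": "heterokont", "h2": "heterokont"}
        species = {**{f"d{i}": f"sp{i}" for i in range(1, 6)},
                   **{f"e{i}": f"sq{i}" for i in range(1, 6)}}
        part = partition_major_clades(t, groups, species=species)
        blocks = {frozenset(sc.leaf_ids) for sc in part.majors[0].subclades}
        assert blocks == {frozenset({f"d{i}" for i in range(1, 6)}),
                          frozenset({f"e{i}" for i in range(1, 6)})}

    def test_near_zero_split_not_taken(self):
        # the same two blocks joined by negligible stems stay together
        left = "(" + ",".join(f"d{i}:0.05" for i in range(1, 6)) + "):0.001"
        right = "(" + ",".join(f"e{i}:0.05" for i in range(1, 6)) + "):0.001"
        t = read_newick(f"((h1:1,h2:1):1,({left},{right}):1);")
        groups = {**{f"d{i}": "core_dino" for i in range(1, 6)},
                  **{f"e{i}": "core_dino" for i in range(1, 6)},
                  "h1": "heterokont", "h2": "heterokont"}
        species = {**{f"d{i}": f"sp{i}" for i in range(1, 6)},
                   **{f"e{i}": f"sq{i}" for i in range(1, 6)}}
        part = partition_major_clades(t, groups, species=species)
        assert len(part.majors[0].subclades) == 1

    def test_letters_stable_under_leaf_permutation(self):
        base = ("((h1:1,h2:1):1,((d1:1,d2:1,d3:1):0.5,((a1:1,a2:1):0.2,"
                "(d4:1,d5:1):0.5):0.2):1);")
        perm = ("((h2:1,h1:1):1,(((a2:1,a1:1):0.2,(d5:1,d4:1):0.5):0.2,"
                "(d3:1,d1:1,d2:1):0.5):1);")
        out = []
        for nw in (base, perm):
            part = partition_major_clades(read_newick(nw), self.GROUPS,
                                          species=self.SPECIES)
            out.append({sc.name: frozenset(sc.leaf_ids)
                        for sc in part.majors[0].subclades})
        assert out[0] == out[1]


class TestRepresentation:
    def _census(self, ids_species):
        return pd.DataFrame(
            [{"member_id": i, "species": s, "group": "core_dino"}
             for i, s in ids_species])

    def test_full_representation(self):
        species = [f"sp{i}" for i in range(11)]
        census = self._census([(f"m{i}", f"sp{i}") for i in range(11)])
        sc = SubClade(name="1a", leaf_ids=[f"m{i}" for i in range(11)],
                      species=species)
        rep = representation_table([sc], census, species_universe=species)
        row = rep.iloc[0]
        assert row["n_species"] == 11 and bool(row["full_representation"])
        assert row["n_members"] == 11

    def test_empty_subclade_list(self):
        census = self._census([("m0", "sp0")])
        rep = representation_table([], census)
        assert len(rep) == 0

    def test_missing_leaf_errors(self):
        census = self._census([("m0", "sp0")])
        sc = SubClade(name="1a", leaf_ids=["ghost"], species=["sp0"])
        with pytest.raises(ValueError, match="ghost"):
            representation_table([sc], census)

    def test_counts_sum_to_subclade_size(self):
        census = self._census([("m0", "sp0"), ("m1", "sp0"), ("m2", "sp1")])
        sc = SubClade(name="1a", leaf_ids=["m0", "m1", "m2"],
                      species=["sp0", "sp0", "sp1"])
        rep = representation_table([sc], census, species_universe=["sp0", "sp1"])
        assert rep.iloc[0]["sp0"] == 2 and rep.iloc[0]["sp1"] == 1
        assert rep.iloc[0]["n_members"] == 3


class TestMadRoot:
    def test_clock_like_tree_roots_at_true_split(self):
        t = read_newick("((a:1,b:1):2,(c:1,d:1):2);")
        rooted = mad_root(t)
        sides = [{lf.taxon.label for lf in c.leaf_iter()}
                 for c in rooted.seed_node.child_nodes()]
        assert {frozenset(s) for s in sides} == {
            frozenset({"a", "b"}), frozenset({"c", "d"})}

    def test_stable_clade_structure_at_family_scale(self, dataset, core_alignment):
        """On a realistic family tree with biased long-branch lineages,
        MAD rooting supports recovery of the three ancestral clades and
        the nine core-dinoflagellate sub-clades."""
        from capclade import phylo

        tree = phylo.nj_tree(phylo.distance_matrix(core_alignment))
        part = partition_major_clades(tree, dataset.groups, rooting="mad",
                                      species=dataset.species)
        assert len(part.majors) == 3
        assert len(part.subclades) == 9

    def test_deterministic(self):
        t1 = mad_root(read_newick("((a:1,b:1.2):2,(c:0.9,d:1.1):2);"))
        t2 = mad_root(read_newick("((a:1,b:1.2):2,(c:0.9,d:1.1):2);"))
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")


def test_clades_table_covers_every_leaf(dataset, core_alignment):
    from capclade import phylo

    tree = phylo.nj_tree(phylo.distance_matrix(core_alignment))
    part = partition_major_clades(tree, dataset.groups, rooting="mad",
                                  species=dataset.species)
    table = clades_table(part)
    assert set(table["member_id"]) == set(core_alignment.ids)
    placed = table[table["major_clade"] != ""]
    assert len(placed) == len(set(placed["member_id"]))
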
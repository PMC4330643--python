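"""Partition a group-labeled phylogeny into major clades and sub-clades.

A major clade is a maximal subtree containing both core dinoflagellates
and the outgroup heterokonts — the codified version of defining clades
"after tree construction based on representation" from those two groups.
Within a major clade, sub-clades are maximal monophyletic groups of core
dinoflagellates, lettered a, b, c... by decreasing species count.
Syndinean and Perkinsus leaves are treated as interlopers that never
break core-dinoflagellate monophyly; they are masked during sub-clade
extraction and reported separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import pandas as pd

MASKED_GROUPS = ("syndinean", "perkinsus")


@dataclass
class SubClade:
    name: str
    leaf_ids: list[str]
    species: list[str] = field(default_factory=list)

    @property
    def n_species(self) -> int:
        return len(set(self.species))

    @property
    def n_members(self) -> int:
        return len(self.leaf_ids)


@dataclass
class MajorClade:
    name: str
    leaf_ids: list[str]
    subclades: list[SubClade] = field(default_factory=list)
    masked_leaf_ids: list[str] = field(default_factory=list)


@dataclass
class CladePartition:
    majors: list[MajorClade]
    unplaced: list[str]
    unresolved: bool = False

    @property
    def subclades(self) -> list[SubClade]:
        return [sc for mc in self.majors for sc in mc.subclades]


def _leaf_groups(node, groups):
    return {groups.get(lf.taxon.label, "other") for lf in node.leaf_iter()}


def mad_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root by minimal ancestor deviation (MAD).

    For every candidate root position the method scores how far all leaf
    pairs deviate from clock-likeness relative to their induced ancestor,
    and roots at the position minimizing the root-mean-square deviation.
    Unlike plain midpoint rooting it is not dominated by the single
    longest path, so composition-biased long-branch lineages do not drag
    the root into a clade.
    """
    import numpy as np
    from scipy.sparse.csgraph import shortest_path
    from scipy.sparse import lil_matrix

    t = tree.clone(depth=1)
    t.is_rooted = True
    nodes = list(t.preorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj = lil_matrix((n, n))
    edges = []
    for node in nodes:
        if node.parent_node is None:
            continue
        i, j = index[id(node.parent_node)], index[id(node)]
        w = max(node.edge.length or 0.0, 1e-9)
        adj[i, j] = adj[j, i] = w
        edges.append((node, i, j, w))
    dist = shortest_path(adj.tocsr(), method="D", directed=False)
    leaf_idx = np.array([index[id(lf)] for lf in t.leaf_node_iter()])
    nl = len(leaf_idx)
    D = dist[np.ix_(leaf_idx, leaf_idx)]
    iu = np.triu_indices(nl, k=1)

    best = (np.inf, None, 0.0)
    for node, pi, ci, w in edges:
        dv = dist[ci, leaf_idx]      # distance from child end to each leaf
        du = dist[pi, leaf_idx]
        below = dv < du
        span = below[iu[0]] != below[iu[1]]
        Dij = D[iu]
        # distance from the child end to the below-side member of each pair
        d_below = np.where(below[iu[0]], dv[iu[0]], dv[iu[1]])
        sp_D = Dij[span]
        sp_db = d_below[span]
        if sp_D.size:
            num = ((sp_D - 2 * sp_db) / sp_D**2).sum()
            den = 2 * (1.0 / sp_D**2).sum()
            x = float(np.clip(num / den, 0.0, w))
        else:
            x = w / 2
        d_rho = np.where(below, dv + x, du + (w - x))
        d_anc_i = 0.5 * (d_rho[iu[0]] + Dij - d_rho[iu[1]])
        d_anc_i = np.clip(d_anc_i, 0.0, Dij)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.abs(2 * d_anc_i / Dij - 1.0)
        r = r[np.isfinite(r)]
        score = float(np.sqrt((r**2).mean()))
        if score < best[0]:
            best = (score, node, x)
    _, root_child, x = best
    edge = root_child.edge
    w = max(edge.length or 0.0, 1e-9)
    t.reroot_at_edge(edge, length1=w - x, length2=x,
                     update_bipartitions=False)
    return t


def _root_tree(tree: dendropy.Tree, groups, rooting: str) -> dendropy.Tree:
    if rooting == "mad":
        return mad_root(tree)
    t = tree.clone(depth=1)
    t.is_rooted = True
    if rooting == "none":
        pass                      # honor the rooting of the input tree
    elif rooting == "midpoint":
        t.reroot_at_midpoint(update_bipartitions=False)
    elif rooting.startswith("outgroup:"):
        grp = rooting.split(":", 1)[1]
        out_leaves = [lf for lf in t.leaf_node_iter()
                      if groups.get(lf.taxon.label, "other") == grp]
        if not out_leaves:
            raise ValueError(f"no leaves with group {grp!r} to root on")
        if len(out_leaves) == 1:
            edge = out_leaves[0].edge
        else:
            mrca = t.mrca(taxa=[lf.taxon for lf in out_leaves])
            edge = mrca.edge if mrca.parent_node is not None else out_leaves[0].edge
        t.reroot_at_edge(edge, length1=(edge.length or 0.0) / 2,
                         length2=(edge.length or 0.0) / 2,
                         update_bipartitions=False)
    else:
        raise ValueError(f"unknown rooting {rooting!r}")
    return t


def partition_major_clades(
    tree: dendropy.Tree,
    groups: dict[str, str],
    rooting: str = "midpoint",
    min_members: int = 2,
    species: dict[str, str] | None = None,
) -> CladePartition:
    """Split a rooted tree into maximal clades containing both core
    dinoflagellates and heterokonts.

    Descending from the root, a node is opened up when at least two of its
    child subtrees each contain both groups; otherwise the node is a
    major-clade root.  Clades are numbered eIF4E-1, -2, ... in decreasing
    core-dinoflagellate leaf count (ties by traversal order).
    """
    species = species or {}
    t = _root_tree(tree, groups, rooting)

    def has_both(node) -> bool:
        g = _leaf_groups(node, groups)
        return "core_dino" in g and "heterokont" in g

    if not has_both(t.seed_node):
        warnings.warn("no node contains both core dinoflagellates and "
                      "heterokonts; returning a single unresolved partition")
        leaves = [lf.taxon.label for lf in t.leaf_node_iter()]
        mc = MajorClade(name="unresolved", leaf_ids=leaves)
        mc.subclades = _find_subclades_of_node(t.seed_node, groups, min_members,
                                               species, "unresolved")
        return CladePartition(majors=[mc], unplaced=[], unresolved=True)

    clade_roots: list = []

    def descend(node):
        both_children = [c for c in node.child_nodes() if has_both(c)]
        if len(both_children) >= 2:
            for c in both_children:
                descend(c)
        else:
            clade_roots.append(node)

    descend(t.seed_node)

    placed: set[str] = set()
    majors = []
    for node in clade_roots:
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        placed.update(leaves)
        majors.append((node, leaves))
    majors.sort(key=lambda item: -sum(
        1 for lid in item[1] if groups.get(lid, "other") == "core_dino"))
    out = []
    for k, (node, leaves) in enumerate(majors, start=1):
        name = f"eIF4E-{k}"
        mc = MajorClade(name=name, leaf_ids=leaves)
        mc.masked_leaf_ids = [lid for lid in leaves
                              if groups.get(lid, "other") in MASKED_GROUPS]
        mc.subclades = _find_subclades_of_node(node, groups, min_members,
                                               species, str(k))
        out.append(mc)
    all_leaves = [lf.taxon.label for lf in t.leaf_node_iter()]
    unplaced = [lid for lid in all_leaves if lid not in placed]
    return CladePartition(majors=out, unplaced=unplaced)


def _find_subclades_of_node(clade_root, groups, min_members, species, prefix,
                            max_interlopers: int = 2,
                            min_split_species: int = 5,
                            min_split_stem: float = 0.1):
    """Maximal monophyletic core-dinoflagellate groups under a clade root.

    Syndinean/Perkinsus leaves are masked (invisible to the monophyly
    test).  Up to ``max_interlopers`` isolated foreign *leaves* are
    tolerated inside a sub-clade — a lone aberrant long branch nesting
    within an otherwise uniform species-complete group does not dissolve
    it — but any multi-leaf foreign clade separates sub-clades.  Groups
    need >= min_members core-dino leaves, except a pure singleton lineage
    attached directly at the clade root, which is kept so
    one-copy-per-species sub-clades survive.
    """

    def grp(label):
        return groups.get(label, "other")

    def qualifies(node):
        """Core-dino group allowing <= max_interlopers foreign singleton
        leaves; every maximal all-foreign subtree must be a single leaf."""
        dinos, foreign_clades = [], 0
        stack = [node]
        while stack:
            nd = stack.pop()
            labels = [lf.taxon.label for lf in nd.leaf_iter()]
            gs = {grp(l) for l in labels} - set(MASKED_GROUPS)
            if gs <= {"core_dino"}:
                dinos.extend(l for l in labels if grp(l) == "core_dino")
            elif "core_dino" not in gs:
                if nd.is_leaf() or len([l for l in labels
                                        if grp(l) not in MASKED_GROUPS]) == 1:
                    foreign_clades += 1
                else:
                    return None
            else:
                if nd.is_leaf():
                    continue
                stack.extend(nd.child_nodes())
        if foreign_clades > max_interlopers:
            return None
        return dinos

    def n_dino_species(node):
        return len({species.get(lf.taxon.label, lf.taxon.label)
                    for lf in node.leaf_iter()
                    if grp(lf.taxon.label) == "core_dino"})

    found = []

    def split_or_keep(node, dinos):
        """A pure candidate still splits into sub-clades when >= 2 child
        subtrees each carry >= min_split_species dinoflagellate species on
        a stem of >= min_split_stem — monophyly plus species
        representation, the survey's dual criterion."""
        rich = [c for c in node.child_nodes()
                if n_dino_species(c) >= min_split_species
                and (c.edge.length or 0.0) >= min_split_stem]
        if len(rich) >= 2:
            for c in node.child_nodes():
                if n_dino_species(c) > 0:
                    explore(c, at_root=False)
            return
        if len(dinos) >= min_members or node.is_leaf():
            found.append(dinos)

    def explore(node, at_root):
        dinos = qualifies(node)
        if dinos:
            if at_root and len(dinos) < min_members:
                found.append(dinos)
            else:
                split_or_keep(node, dinos)
            return
        for c in node.child_nodes():
            explore(c, at_root=False)

    for child in clade_root.child_nodes():
        explore(child, at_root=True)
    if not clade_root.child_nodes():
        explore(clade_root, at_root=True)

    subclades = [
        SubClade(name="", leaf_ids=leaves,
                 species=[species.get(lid, "") for lid in leaves])
        for leaves in found
    ]
    order = sorted(
        range(len(subclades)),
        key=lambda i: (-subclades[i].n_species, -subclades[i].n_members, i),
    )
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = []
    for rank, i in enumerate(order):
        sc = subclades[i]
        sc.name = f"{prefix}{letters[rank]}"
        out.append(sc)
    return out


def find_subclades(
    tree_node, groups: dict[str, str], min_members: int = 2,
    species: dict[str, str] | None = None, prefix: str = "",
) -> list[SubClade]:
    """Sub-clade extraction for a single (already identified) major clade."""
    return _find_subclades_of_node(tree_node, groups, min_members,
                                   species or {}, prefix)


def representation_table(
    subclades: list[SubClade],
    census: pd.DataFrame,
    species_universe: list[str] | None = None,
) -> pd.DataFrame:
    """Sub-clade x species member counts (the category-plot table).

    Rows are sub-clades with per-species counts, a species total and a
    full-representation flag against the core-dinoflagellate universe.
    """
    members = census.set_index("member_id")
    if species_universe is None:
        species_universe = sorted(
            census.loc[census["group"] == "core_dino", "species"].unique()
        )
    rows = []
    for sc in subclades:
        counts = dict.fromkeys(species_universe, 0)
        for lid in sc.leaf_ids:
            if lid not in members.index:
                raise ValueError(f"leaf {lid!r} absent from census")
            sp = members.loc[lid, "species"]
            counts[sp] = counts.get(sp, 0) + 1
        n_species = sum(1 for v in counts.values() if v > 0)
        row = {"subclade": sc.name, **counts,
               "n_species": n_species,
               "n_members": sum(counts.values()),
               "full_representation": n_species == len(species_universe)}
        rows.append(row)
    return pd.DataFrame(rows)


def clades_table(partition: CladePartition) -> pd.DataFrame:
    rows = []
    for mc in partition.majors:
        sub_of = {}
        for sc in mc.subclades:
            for lid in sc.leaf_ids:
                sub_of[lid] = sc.name
        for lid in mc.leaf_ids:
            rows.append({"member_id": lid, "major_clade": mc.name,
                         "subclade": sub_of.get(lid, "")})
    for lid in partition.unplaced:
        rows.append({"member_id": lid, "major_clade": "", "subclade": ""})
    return pd.DataFrame(rows, columns=["member_id", "major_clade", "subclade"])
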
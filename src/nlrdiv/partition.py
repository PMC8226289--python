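"""Partitioning an NB-ARC phylogeny into near-allelic clades.

The family-wide tree is first cut into initial clades of bounded size
(40-500 by default) chosen per sequence as the containing clade with the
strongest bootstrap support, then made non-nesting.  Each clade can then be
refined on its own full-length-alignment tree by branch-length rules: every
branch longer than 0.3 substitutions/site is cut, branches of 0.1 or
shorter are kept, and branches in between are cut when they are well
supported and the two sides share few ecotypes — an automated stand-in for
the manual tree inspection such partitions have traditionally required.

Allelic-series statistics summarise how close the final clades come to
"one gene per ecotype".
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import InputError, InvariantError
from .io import PhyloTree


@dataclass
class PartitionConfig:
    """Thresholds steering initial assignment and refinement.

    Branch-length cutoffs are in substitutions/site; supports in percent.
    ``intermediate_*`` parameters govern branches between the two length
    cutoffs: they are cut when support >= ``intermediate_support_min`` and
    the ecotype-set Jaccard index between the two sides is at most
    ``intermediate_ecotype_jaccard_max``.
    """

    min_clade_size: int = 40
    max_clade_size: int = 500
    long_branch_cutoff: float = 0.3
    short_branch_cutoff: float = 0.1
    intermediate_support_min: float = 70.0
    intermediate_ecotype_jaccard_max: float = 0.25
    gap_mask_fraction: float = 0.90

    def __post_init__(self) -> None:
        if not (0 < self.min_clade_size <= self.max_clade_size):
            raise InputError("need 0 < min_clade_size <= max_clade_size")
        if not (0 <= self.short_branch_cutoff <= self.long_branch_cutoff):
            raise InputError("need 0 <= short_branch_cutoff <= long_branch_cutoff")


@dataclass
class CladeEntry:
    node_index: int
    leaves: frozenset[str]
    size: int
    support: float | None


@dataclass
class CladePartition:
    """Disjoint, exhaustive, non-nesting assignment of leaves to clades."""

    clades: dict[str, frozenset[str]]
    supports: dict[str, float | None] = field(default_factory=dict)

    def leaf_to_clade(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for name, leaves in self.clades.items():
            for leaf in leaves:
                if leaf in out:
                    raise InvariantError(f"leaf {leaf!r} in two clades")
                out[leaf] = name
        return out

    def validate(self, all_leaves: Iterable[str] | None = None) -> None:
        assignment = self.leaf_to_clade()  # raises on overlap
        if all_leaves is not None:
            missing = set(all_leaves) - set(assignment)
            if missing:
                raise InvariantError(f"unassigned leaves: {sorted(missing)[:5]}...")
        sets = list(self.clades.values())
        for i, a in enumerate(sets):
            for b in sets[i + 1:]:
                if a < b or b < a:
                    raise InvariantError("nesting clades in partition")

    def sizes(self) -> dict[str, int]:
        return {name: len(leaves) for name, leaves in self.clades.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"leaf": leaf, "clade": name}
            for name, leaves in self.clades.items()
            for leaf in sorted(leaves)
        ]
        return pd.DataFrame(rows, columns=["leaf", "clade"]).sort_values(
            ["clade", "leaf"], ignore_index=True
        )


def enumerate_clades(ptree: PhyloTree) -> list[CladeEntry]:
    """All candidate clades: one per internal node plus one singleton per
    leaf (singletons carry no support)."""
    if ptree.n_leaves < 2:
        raise InputError("tree needs at least 2 leaves")
    entries = []
    for node in ptree.tree.preorder_node_iter():
        leaves = ptree.leaf_set(node)
        support = None if node.is_leaf() else getattr(node, "support", None)
        entries.append(
            CladeEntry(
                node_index=node.index,
                leaves=leaves,
                size=len(leaves),
                support=support,
            )
        )
    return entries


def _effective_support(support: float | None) -> float:
    # Missing supports rank as 0: unsupported clades should not win.
    return 0.0 if support is None else support


def initial_assignment(ptree: PhyloTree, cfg: PartitionConfig | None = None) -> CladePartition:
    """Size-bounded maximal-support clade selection, made non-nesting.

    For every leaf, the containing clade with size in
    [min_clade_size, max_clade_size] and the strongest support is selected
    (ties: larger clade, then the one closer to the root).  Leaves with no
    size-eligible clade fall back to clades smaller than the minimum.  The
    union of selections is de-nested by discarding any selected clade fully
    contained in another; its leaves inherit the enclosing clade.
    """
    cfg = cfg or PartitionConfig()
    if not ptree.is_rooted():
        raise InputError(
            "tree is unrooted (root has != 2 children); root it first, "
            "e.g. with root_between()"
        )
    # Per-node bookkeeping: leaves below, depth from root.
    node_leaves: dict[int, frozenset[str]] = {}
    depth: dict[int, int] = {}
    nodes = {}
    for node in ptree.tree.preorder_node_iter():
        nodes[node.index] = node
        depth[node.index] = 0 if node.parent_node is None else depth[node.parent_node.index] + 1
    for node in ptree.tree.postorder_node_iter():
        if node.is_leaf():
            node_leaves[node.index] = frozenset([node.taxon.label])
        else:
            acc: set[str] = set()
            for ch in node.child_nodes():
                acc |= node_leaves[ch.index]
            node_leaves[node.index] = frozenset(acc)

    def candidates_for(leaf_node):
        chain = []
        node = leaf_node
        while node is not None:
            chain.append(node)
            node = node.parent_node
        return chain

    def pick(chain, predicate):
        best = None
        best_key = None
        for node in chain:
            size = len(node_leaves[node.index])
            if not predicate(size):
                continue
            support = None if node.is_leaf() else getattr(node, "support", None)
            key = (_effective_support(support), size, -depth[node.index])
            if best_key is None or key > best_key:
                best, best_key = node, key
        return best

    selected: dict[int, frozenset[str]] = {}
    for leaf in ptree.tree.leaf_node_iter():
        chain = candidates_for(leaf)
        node = pick(chain, lambda s: cfg.min_clade_size <= s <= cfg.max_clade_size)
        if node is None:
            node = pick(chain, lambda s: s < cfg.min_clade_size)
        if node is None:  # pragma: no cover - chains always contain the leaf
            raise InvariantError(f"no clade for leaf {leaf.taxon.label!r}")
        selected[node.index] = node_leaves[node.index]

    # De-nest: drop any selected clade strictly contained in another.
    keep: dict[int, frozenset[str]] = {}
    for idx, leaves in selected.items():
        nested = any(
            idx != other and leaves < other_leaves
            for other, other_leaves in selected.items()
        )
        if not nested:
            keep[idx] = leaves

    clades = {f"Int{idx}": leaves for idx, leaves in keep.items()}
    supports = {
        f"Int{idx}": (None if nodes[idx].is_leaf() else getattr(nodes[idx], "support", None))
        for idx in keep
    }
    part = CladePartition(clades=clades, supports=supports)
    part.validate(all_leaves=ptree.leaf_labels())
    return part


def root_between(ptree: PhyloTree, bipartition: tuple[Iterable[str], Iterable[str]]) -> PhyloTree:
    """Re-root on the branch separating the two leaf-label sets, placing
    the root at the branch midpoint.  Leaf set and total length unchanged."""
    side_a = frozenset(bipartition[0])
    side_b = frozenset(bipartition[1])
    all_leaves = frozenset(ptree.leaf_labels())
    if side_a | side_b != all_leaves or side_a & side_b:
        raise InputError("bipartition must split the leaf set into two disjoint halves")
    clone = ptree.tree.clone(depth=1)
    target_edge = None
    for node in clone.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if below == side_a or below == side_b:
            target_edge = node.edge
            break
    if target_edge is None:
        raise InputError("bipartition does not correspond to a branch of the tree")
    length = target_edge.length or 0.0
    clone.reroot_at_edge(target_edge, length1=length / 2.0, length2=length / 2.0)
    # reroot can leave an old degree-2 node behind; collapse it.
    clone.suppress_unifurcations()
    return PhyloTree.from_dendropy(clone)


def midpoint_root(ptree: PhyloTree) -> PhyloTree:
    """Midpoint rooting (default for clade trees)."""
    clone = ptree.tree.clone(depth=1)
    clone.reroot_at_midpoint(update_bipartitions=False)
    clone.suppress_unifurcations()
    return PhyloTree.from_dendropy(clone)


def refine_clade(
    ptree: PhyloTree,
    cfg: PartitionConfig | None = None,
    ecotypes: Mapping[str, str] | None = None,
) -> tuple[list[frozenset[str]], pd.DataFrame]:
    """Cut a clade tree into subclades by the branch-length rules.

    Every non-root branch longer than ``long_branch_cutoff`` is cut;
    branches of ``short_branch_cutoff`` or shorter are kept; intermediate
    branches are cut iff support >= ``intermediate_support_min`` AND the
    ecotype-set Jaccard between the two sides is at most
    ``intermediate_ecotype_jaccard_max``.  Returns the leaf-set partition
    and a per-branch decision log.
    """
    cfg = cfg or PartitionConfig()
    all_leaves = frozenset(ptree.leaf_labels())
    node_leaves: dict[int, frozenset[str]] = {}
    for node in ptree.tree.postorder_node_iter():
        if node.is_leaf():
            node_leaves[node.index] = frozenset([node.taxon.label])
        else:
            node_leaves[node.index] = frozenset().union(
                *(node_leaves[ch.index] for ch in node.child_nodes())
            )

    def eco_set(leaves: frozenset[str]) -> frozenset[str]:
        missing = [lf for lf in leaves if lf not in ecotypes]  # type: ignore[operator]
        if missing:
            raise InputError(
                f"missing ecotype labels for leaves {sorted(missing)[:5]} "
                "(required to decide intermediate branches)"
            )
        return frozenset(ecotypes[lf] for lf in leaves)  # type: ignore[index]

    log_rows = []
    cut_nodes: set[int] = set()
    for node in ptree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        length = node.edge.length or 0.0
        below = node_leaves[node.index]
        support = None if node.is_leaf() else getattr(node, "support", None)
        jaccard = math.nan
        if length > cfg.long_branch_cutoff:
            rule, cut = "long-branch", True
        elif length <= cfg.short_branch_cutoff:
            rule, cut = "short-branch", False
        else:
            if ecotypes is None:
                raise InputError(
                    "ecotype labels required: tree has branches between the "
                    "short and long cutoffs"
                )
            above = all_leaves - below
            ea, eb = eco_set(below), eco_set(above)
            union = ea | eb
            jaccard = len(ea & eb) / len(union) if union else 0.0
            cut = (
                _effective_support(support) >= cfg.intermediate_support_min
                and jaccard <= cfg.intermediate_ecotype_jaccard_max
            )
            rule = "intermediate"
        if cut:
            cut_nodes.add(node.index)
        log_rows.append(
            {
                "node_index": node.index,
                "branch_length": length,
                "support": support,
                "n_below": len(below),
                "ecotype_jaccard": jaccard,
                "rule": rule,
                "cut": cut,
            }
        )

    # Components after removing cut branches: child inherits the parent's
    # component unless its branch was cut.
    component: dict[int, int] = {}
    next_id = 0
    for node in ptree.tree.preorder_node_iter():
        if node.parent_node is None or node.index in cut_nodes:
            component[node.index] = next_id
            next_id += 1
        else:
            component[node.index] = component[node.parent_node.index]
    groups: dict[int, set[str]] = {}
    for leaf in ptree.tree.leaf_node_iter():
        groups.setdefault(component[leaf.index], set()).add(leaf.taxon.label)
    subclades = [frozenset(g) for _, g in sorted(groups.items())]

    if frozenset().union(*subclades) != all_leaves:  # pragma: no cover
        raise InvariantError("refinement lost leaves")
    log = pd.DataFrame(
        log_rows,
        columns=["node_index", "branch_length", "support", "n_below",
                 "ecotype_jaccard", "rule", "cut"],
    )
    return subclades, log


def refine_partition_names(parent_name: str, subclades: list[frozenset[str]]) -> dict[str, frozenset[str]]:
    """Stable child names: parent name when unsplit, else ``parent_i``."""
    if len(subclades) == 1:
        return {parent_name: subclades[0]}
    return {f"{parent_name}_{i}": s for i, s in enumerate(sorted(subclades, key=sorted), start=1)}


@dataclass
class AllelicStats:
    n_clades: int
    n_sequences: int
    allelic_fraction: float           # clades with <=1 gene per represented ecotype
    fraction_in_large_clades: float   # sequences in clades of size >= large_clade_min
    large_clade_min: int
    max_genes_per_ecotype: dict[str, int]
    size_histogram: dict[int, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"clade": name, "max_genes_per_ecotype": v,
             "allelic": v <= 1}
            for name, v in sorted(self.max_genes_per_ecotype.items())
        ]
        return pd.DataFrame(rows, columns=["clade", "max_genes_per_ecotype", "allelic"])


def allelic_series_stats(
    partition: CladePartition,
    ecotypes: Mapping[str, str],
    large_clade_min: int = 20,
) -> AllelicStats:
    """How allelic is the partition?

    Reports the fraction of clades with no more than one gene for every
    represented ecotype, and the fraction of sequences in clades of
    ``large_clade_min`` or more genes.
    """
    max_per_clade: dict[str, int] = {}
    n_seqs = 0
    n_large = 0
    sizes: Counter[int] = Counter()
    for name, leaves in partition.clades.items():
        missing = [lf for lf in leaves if lf not in ecotypes]
        if missing:
            raise InputError(f"missing ecotype labels: {sorted(missing)[:5]}")
        counts = Counter(ecotypes[lf] for lf in leaves)
        max_per_clade[name] = max(counts.values())
        size = len(leaves)
        sizes[size] += 1
        n_seqs += size
        if size >= large_clade_min:
            n_large += size
    n_clades = len(partition.clades)
    allelic = sum(1 for v in max_per_clade.values() if v <= 1)
    return AllelicStats(
        n_clades=n_clades,
        n_sequences=n_seqs,
        allelic_fraction=allelic / n_clades if n_clades else float("nan"),
        fraction_in_large_clades=n_large / n_seqs if n_seqs else float("nan"),
        large_clade_min=large_clade_min,
        max_genes_per_ecotype=max_per_clade,
        size_histogram=dict(sorted(sizes.items())),
    )
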
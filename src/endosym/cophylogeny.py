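"""Host/symbiont tree-congruence statistics.

Congruence is measured as the Robinson-Foulds (RF) bipartition distance
between the host tree and the symbiont tree after relabeling symbiont
leaves by their associated hosts and pruning both trees to the shared,
1:1-associated leaf set.  Significance comes from a permutation null that
shuffles the symbiont side of the association.

Note: the underlying biological claim this formalizes is qualitative (clade
membership); the permutation test is an added formalization of "lack of
cophylogeny", not a re-implementation of a published statistic.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional

import dendropy
import numpy as np

from .model import Association

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class CongruenceResult:
    rf: int
    rf_normalized: float
    p_value: float
    n_permutations: int
    seed: int


def _leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon}


def _nontrivial_splits(tree: dendropy.Tree,
                       relabel: Optional[dict[str, str]] = None) -> set[frozenset[str]]:
    """Non-trivial unrooted bipartitions, each canonicalized as the side not
    containing a fixed reference leaf.  Multifurcations are fine."""
    labels = sorted(_leaf_labels(tree))
    if relabel:
        labels = sorted(relabel[x] for x in labels)
    ref = labels[0]
    all_leaves = frozenset(labels)
    n = len(labels)
    splits: set[frozenset[str]] = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(
            (relabel[leaf.taxon.label] if relabel else leaf.taxon.label)
            for leaf in node.leaf_iter()
        )
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= n - 2:
            splits.add(side)
    return splits


def _resolve_association(host_tree: dendropy.Tree, symb_tree: dendropy.Tree,
                         association: Association) -> list[tuple[str, str]]:
    """Pairs restricted to leaves present in both trees, reduced to a 1:1
    mapping (first occurrence wins, with a warning on duplicates)."""
    host_leaves = _leaf_labels(host_tree)
    symb_leaves = _leaf_labels(symb_tree)
    pairs = [(h, s) for h, s in association.pairs
             if h in host_leaves and s in symb_leaves]
    seen_h: set[str] = set()
    seen_s: set[str] = set()
    resolved: list[tuple[str, str]] = []
    dropped = 0
    for h, s in pairs:
        if h in seen_h or s in seen_s:
            dropped += 1
            continue
        seen_h.add(h)
        seen_s.add(s)
        resolved.append((h, s))
    if dropped:
        logger.warning("dropped %d association rows to obtain a 1:1 mapping", dropped)
    return resolved


def _pruned_copy(tree: dendropy.Tree, keep: set[str]) -> dendropy.Tree:
    clone = dendropy.Tree.get(
        data=tree.as_string(schema="newick", suppress_rooting=True),
        schema="newick",
        preserve_underscores=True,
    )
    clone.retain_taxa_with_labels(sorted(keep))
    return clone


def robinson_foulds(host_tree: dendropy.Tree, symb_tree: dendropy.Tree,
                    association: Association) -> tuple[int, float]:
    """RF distance between the host tree and the host-relabeled symbiont tree.

    Both trees are pruned to the shared 1:1-associated leaves (>= 4 required).
    Returns (rf, normalized rf); normalization divides by the total number of
    non-trivial bipartitions in the two pruned trees.
    """
    pairs = _resolve_association(host_tree, symb_tree, association)
    if len(pairs) < 4:
        raise ValueError(f"need >= 4 shared associated leaves, got {len(pairs)}")
    hosts = {h for h, _ in pairs}
    symbs = {s for _, s in pairs}
    relabel = {s: h for h, s in pairs}
    ht = _pruned_copy(host_tree, hosts)
    st = _pruned_copy(symb_tree, symbs)
    host_splits = _nontrivial_splits(ht)
    symb_splits = _nontrivial_splits(st, relabel=relabel)
    rf = len(host_splits ^ symb_splits)
    max_rf = len(host_splits) + len(symb_splits)
    return rf, (rf / max_rf if max_rf else 0.0)


def congruence_test(host_tree: dendropy.Tree, symb_tree: dendropy.Tree,
                    association: Association, n_perm: int = 999,
                    seed: int = 0) -> CongruenceResult:
    """Permutation test of topological congruence.

    Null: random permutations of the symbiont side of the association.
    p = (1 + #{null RF <= observed}) / (n_perm + 1); small p means the
    observed association is more congruent than expected by chance.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    pairs = _resolve_association(host_tree, symb_tree, association)
    if len(pairs) < 4:
        raise ValueError(f"need >= 4 shared associated leaves, got {len(pairs)}")
    hosts = [h for h, _ in pairs]
    symbs = [s for _, s in pairs]
    ht = _pruned_copy(host_tree, set(hosts))
    st = _pruned_copy(symb_tree, set(symbs))
    host_splits = _nontrivial_splits(ht)
    symb_splits_raw = _nontrivial_splits(st)  # in symbiont labels
    max_rf = len(host_splits) + len(symb_splits_raw)

    def rf_for(mapping: dict[str, str]) -> int:
        mapped = {frozenset(mapping[x] for x in side) for side in symb_splits_raw}
        # re-canonicalize against the host reference leaf
        ref = sorted(hosts)[0]
        all_leaves = frozenset(hosts)
        canon = {side if ref not in side else all_leaves - side for side in mapped}
        canon = {side for side in canon if 2 <= len(side) <= len(hosts) - 2}
        return len(host_splits ^ canon)

    observed = rf_for({s: h for h, s in pairs})
    rng = np.random.default_rng(seed)
    count_leq = 0
    hosts_arr = list(hosts)
    for _ in range(n_perm):
        perm = rng.permutation(len(hosts_arr))
        mapping = {symbs[i]: hosts_arr[perm[i]] for i in range(len(symbs))}
        if rf_for(mapping) <= observed:
            count_leq += 1
    p = (1 + count_leq) / (n_perm + 1)
    return CongruenceResult(
        rf=observed,
        rf_normalized=observed / max_rf if max_rf else 0.0,
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
    )


def clade_assignment(tree: dendropy.Tree,
                     clade_seeds: dict[str, set[str]]) -> dict[str, str]:
    """Assign leaves to clades defined by seed leaf sets.

    The tree is treated as rooted at its root node.  A leaf is assigned to
    clade c when the smallest monophyletic group containing c's seeds plus
    the leaf excludes every other clade's seeds; ties go to the smallest such
    group.  Leaves qualifying for no clade are reported 'unassigned'.
    """
    for name, seeds in clade_seeds.items():
        if not seeds:
            raise ValueError(f"clade {name!r}: empty seed set")
    names = list(clade_seeds)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if clade_seeds[a] & clade_seeds[b]:
                raise ValueError(f"clades {a!r} and {b!r} share seed leaves")

    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter() if leaf.taxon}
    for name, seeds in clade_seeds.items():
        missing = seeds - set(leaves)
        if missing:
            raise ValueError(f"clade {name!r}: seeds not in tree: {sorted(missing)}")

    # leaf sets under each node (rooted reading)
    node_leafsets: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node_leafsets[id(node)] = frozenset([node.taxon.label])
        else:
            acc: set[str] = set()
            for child in node.child_nodes():
                acc |= node_leafsets[id(child)]
            node_leafsets[id(node)] = frozenset(acc)

    all_seeds = {name: set(clade_seeds[name]) for name in names}

    base_groups: dict[str, frozenset[str]] = {}
    for name in names:
        base_groups[name] = _smallest_group(tree, node_leafsets, all_seeds[name])
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if base_groups[a] & base_groups[b]:
                raise ValueError(
                    f"seed-induced clades {a!r} and {b!r} overlap"
                )

    assignment: dict[str, str] = {}
    other_seeds = {
        name: set().union(*(all_seeds[o] for o in names if o != name)) if len(names) > 1 else set()
        for name in names
    }
    for label in leaves:
        best_name, best_size = None, None
        for name in names:
            group = _smallest_group(tree, node_leafsets, all_seeds[name] | {label})
            if group & other_seeds[name]:
                continue
            if best_size is None or len(group) < best_size:
                best_name, best_size = name, len(group)
        assignment[label] = best_name if best_name is not None else "unassigned"
    return assignment


def _smallest_group(tree: dendropy.Tree, node_leafsets: dict[int, frozenset[str]],
                    required: set[str]) -> frozenset[str]:
    best: Optional[frozenset[str]] = None
    for node in tree.postorder_node_iter():
        leafset = node_leafsets[id(node)]
        if required <= leafset and (best is None or len(leafset) < len(best)):
            best = leafset
    assert best is not None
    return best
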
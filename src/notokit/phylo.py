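"""Gene-tree screening for the selection-scan pipeline.

Keeps only gene trees in which the focal clade (cryonotothenioids) is
monophyletic *and* sister to its true temperate sister species, so that
selection tests downstream all interrogate the same ancestral branch; and
subtracts control hits (genes under selection on temperate branches) from
the focal hit set.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence, Set
from dataclasses import dataclass

import dendropy

__all__ = ["TreeDecision", "monophyly_sister_filter", "subtract_background"]


@dataclass(frozen=True)
class TreeDecision:
    tree_id: str
    keep: bool
    reasons: tuple[str, ...] = ()


def _splits(tree: dendropy.Tree) -> tuple[set[frozenset[str]], list[str]]:
    """All non-trivial bipartition sides (as leaf-name sets) of an unrooted tree."""
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    full = frozenset(leaves)
    sides: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 0 < len(side) < len(full):
            sides.add(side)
            sides.add(full - side)
    return sides, leaves


def _has_clade_split(
    sides: Set[frozenset[str]],
    leaves: Sequence[str],
    species_of: Mapping[str, str],
    species_set: Set[str],
    strict_copies: bool,
) -> bool:
    """Is there a bipartition side holding exactly the leaves of ``species_set``?

    With ``strict_copies`` every gene copy of a clade species must fall on
    the clade side; in relaxed mode a side whose species set equals
    ``species_set`` suffices even if further copies sit outside.
    """
    if strict_copies:
        wanted = frozenset(l for l in leaves if species_of[l] in species_set)
        return wanted in sides
    for side in sides:
        if {species_of[l] for l in side} == set(species_set):
            return True
    return False


def monophyly_sister_filter(
    trees: Sequence[tuple[str, dendropy.Tree | str]],
    clade_taxa: Sequence[str],
    sister_taxon: str,
    species_of: Mapping[str, str] | None = None,
    strict_copies: bool = True,
    require_both: bool = True,
) -> list[TreeDecision]:
    """Keep/discard each gene tree on clade monophyly and sisterhood.

    A tree is kept iff its unrooted topology contains a bipartition
    separating exactly the focal clade AND one separating exactly
    clade + sister taxon (both required by default; ``require_both=False``
    keeps trees passing either test).  Decisions are invariant to rooting
    because only bipartitions are inspected.  Trees missing any required
    taxon are discarded with reason ``missing taxa``.

    ``trees`` are (id, tree-or-newick) pairs; ``species_of`` maps leaf
    names to species (identity when omitted, i.e. single-copy trees).
    """
    clade = set(clade_taxa)
    if sister_taxon in clade:
        raise ValueError("sister taxon cannot be a clade member")
    out = []
    for tree_id, t in trees:
        if isinstance(t, str):
            t = dendropy.Tree.get(data=t, schema="newick")
        sides, leaves = _splits(t)
        if len(leaves) < 4:
            raise ValueError(f"tree {tree_id!r} has fewer than 4 leaves")
        smap = species_of or {l: l for l in leaves}
        present = {smap[l] for l in leaves}
        missing = (clade | {sister_taxon}) - present
        if missing:
            out.append(TreeDecision(tree_id, False, ("missing taxa",)))
            continue
        mono = _has_clade_split(sides, leaves, smap, clade, strict_copies)
        sister = _has_clade_split(sides, leaves, smap, clade | {sister_taxon}, strict_copies)
        # clade+sister side == complement of everything else; with exactly
        # one other leaf the split is trivial and always present
        reasons = []
        if not mono:
            reasons.append("clade not monophyletic")
        if not sister:
            reasons.append(f"clade not sister to {sister_taxon}")
        keep = (mono and sister) if require_both else (mono or sister)
        out.append(TreeDecision(tree_id, keep, tuple(reasons)))
    return out


def subtract_background(focal_hits: Set, background_hits: Set) -> set:
    """Remove genes hit on temperate/control branches from the focal hit set."""
    return set(focal_hits) - set(background_hits)
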
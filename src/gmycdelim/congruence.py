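"""Naming of delimited species and two-locus congruence assessment.

Naming follows two rules applied in order: (1) an entity is named after
every nominal species for which it holds topotype individuals (several
names are joined with "+"; when one species' topotypes are split over
several entities, each of those entities receives the name); (2) an
unnamed entity whose members all carry the same nominal identification
takes that name; anything else becomes "sp k" with a running index.

Congruence of an entity against a second-locus tree requires that the
tips induced by its individuals form exactly one clade, that the clade
is supported (posterior probability >= ``pp_min``), and that none of
those tips carries individuals from another entity.  Single-tip
entities waive the support condition (no subtending clade exists).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import pandas as pd

from .errors import ValidationError
from .gmyc import Entity, SpeciesAssignment

__all__ = [
    "SupportedTree",
    "read_support_tree",
    "assess_congruence",
    "name_species",
]


@dataclass
class SupportedTree:
    """Rooted tree with per-internal-node support in [0, 1] and a
    genotype -> individuals mapping linking tips to individuals."""

    tree: dendropy.Tree
    genotype_map: dict[str, list[str]]

    def __post_init__(self):
        labels = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValidationError("duplicate tip labels in support tree")
        self.tip_labels = set(labels)
        for nd in self.tree.preorder_node_iter():
            if nd.is_leaf():
                continue
            s = _node_support(nd)
            if s is not None and not (0.0 <= s <= 1.0):
                raise ValidationError(f"node support {s} outside [0, 1]")

    def individuals_of_tip(self, label: str) -> list[str]:
        return self.genotype_map.get(label, [label])

    def clades(self) -> dict[frozenset, tuple[Optional[float], object]]:
        """Map each internal node's tip-label set to (support, node)."""
        out = {}
        for nd in self.tree.postorder_node_iter():
            if nd.is_leaf():
                continue
            tips = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            out[tips] = (_node_support(nd), nd)
        return out


def _node_support(nd) -> Optional[float]:
    if nd.label not in (None, ""):
        try:
            return float(nd.label)
        except ValueError:
            return None
    return None


def read_support_tree(
    text: str, genotype_map: Optional[dict[str, list[str]]] = None
) -> SupportedTree:
    """Parse newick whose internal node labels are support values."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ValidationError(f"malformed newick: {exc}") from exc
    gmap = genotype_map or {}
    return SupportedTree(tree=dtree, genotype_map=gmap)


def assess_congruence(
    assignment: SpeciesAssignment,
    tree: SupportedTree,
    pp_min: float = 0.95,
) -> dict[int, str]:
    """Flag each entity "+" (congruent with the second locus) or "-".

    An entity's individuals are mapped to tips through the genotype
    map; the entity is congruent when the induced tips (a) are exactly
    one node's clade (or a single tip), (b) that node's support is
    >= ``pp_min`` (waived for single tips), and (c) no induced tip
    carries individuals belonging to a different entity.
    """
    ind_to_tip: dict[str, str] = {tip: tip for tip in tree.tip_labels}
    for tip, inds in tree.genotype_map.items():
        for ind in inds:
            ind_to_tip[ind] = tip

    owner: dict[str, int] = {}
    for e in assignment.entities:
        for ind in e.members:
            owner[ind] = e.entity_id

    tip_owners: dict[str, set[int]] = {}
    for tip in tree.tip_labels:
        tip_owners[tip] = {
            owner[ind] for ind in tree.individuals_of_tip(tip) if ind in owner
        }

    clades = tree.clades()
    flags: dict[int, str] = {}
    for e in assignment.entities:
        unmapped = [ind for ind in e.members if ind_to_tip.get(ind) not in tree.tip_labels]
        if unmapped:
            raise ValidationError(
                f"individuals of entity {e.entity_id} not mapped to any tip: {unmapped}"
            )
        tips = frozenset(ind_to_tip[ind] for ind in e.members)
        exclusive = all(tip_owners[t] == {e.entity_id} for t in tips)
        if len(tips) == 1:
            flags[e.entity_id] = "+" if exclusive else "-"
            continue
        if tips not in clades:
            flags[e.entity_id] = "-"
            continue
        support, _ = clades[tips]
        supported = support is not None and support >= pp_min
        flags[e.entity_id] = "+" if (exclusive and supported) else "-"
    return flags


def name_species(
    assignment: SpeciesAssignment, metadata: pd.DataFrame
) -> SpeciesAssignment:
    """Assign names to entities from topotypes and unambiguous IDs.

    ``metadata`` needs columns individual, nominal_species, topotype.
    """
    meta = metadata.set_index("individual")
    topo = meta[meta["topotype"] == 1]
    blank = topo[topo["nominal_species"].isin(["", None])]
    if len(blank):
        raise ValidationError(
            f"topotype individuals without a nominal species: {list(blank.index)[:5]}"
        )

    named: list[Entity] = []
    sp_index = 0
    for e in assignment.entities:
        members = set(e.members)
        # rule 1: topotype presence
        topo_names = sorted(
            topo.loc[topo.index.intersection(members), "nominal_species"].unique()
        )
        if topo_names:
            name = "+".join(topo_names)
        else:
            # rule 2: unanimous nominal identification
            ids = {
                str(meta.at[ind, "nominal_species"]) if ind in meta.index else ""
                for ind in members
            }
            if len(ids) == 1 and "" not in ids:
                name = ids.pop()
            else:
                sp_index += 1
                name = f"sp {sp_index}"
        named.append(Entity(e.entity_id, e.kind, e.members, name))
    return SpeciesAssignment(named)
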
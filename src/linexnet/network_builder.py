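"""Rule-based lipid network construction.

Two measured species are connected by an edge when a biochemical
reaction can transform one into the other:

* **same class** — exactly one chain (or, at sum-composition level, the
  composition total) differs by one elongation step (two carbons), one
  desaturation (one double bond) or one oxidation (one hydroxyl group);
* **different classes, equal chain counts** — the classes are listed as
  a headgroup modification and the full acyl composition is identical;
* **different classes, chain counts differing by one** — the classes
  are listed as an acyl addition/removal, the larger species contains
  every chain of the smaller one, and the extra chain is in the
  allowed fatty-acid pool.

Species annotated at different structural resolutions are compared at
sum-composition level (both demoted); the edge records the resolution at
which the match was decided.  Classes whose chain counts differ by two
or more are never connected — many-to-many reactions (e.g.
Cer + PC → SM + DG) cannot be represented by pairwise edges.

The resulting network is an undirected :class:`networkx.Graph` with one
node per species (keyed by canonical name, the parsed species stored as
a node attribute) and one typed annotation per edge.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Set, Tuple

import networkx as nx

from .lipid_model import (
    FattyAcid,
    Level,
    LipidSpecies,
    canonical_name,
    demote_to_sum,
)
from .reaction_rules import (
    FA_REACTION_TYPES,
    ClassReaction,
    ReactionCategory,
    ReactionType,
    RuleSet,
)

__all__ = [
    "EdgeAnnotation",
    "LipidNetwork",
    "infer_fa_transformation",
    "match_pair",
    "build_network",
    "filter_edges",
    "topology_metrics",
]

#: The lipid network container: an undirected networkx graph whose nodes
#: are canonical species names (attribute ``species`` holds the parsed
#: :class:`~linexnet.lipid_model.LipidSpecies`) and whose edges carry an
#: ``annotation`` (:class:`EdgeAnnotation`) plus flat string attributes.
LipidNetwork = nx.Graph


@dataclass(frozen=True)
class EdgeAnnotation:
    """Why two species are connected.

    ``resolution_of_match`` records whether the decision used the full
    molecular composition or fell back to sum compositions (mixed or
    sum-level annotations).  Enzyme annotations only exist for class
    reactions; chain-level edges are a heuristic without enzyme labels.
    """

    reaction_type: ReactionType
    enzymes: Tuple[str, ...] = ()
    resolution_of_match: Level = Level.MOLECULAR

    def __post_init__(self) -> None:
        if self.reaction_type in FA_REACTION_TYPES and self.enzymes:
            raise ValueError("chain-level reactions carry no enzyme annotation")


def infer_fa_transformation(
    a: FattyAcid, b: FattyAcid, rules: RuleSet
) -> Optional[ReactionType]:
    """Chain-level reaction transforming one fatty acid into another.

    Returns ELONGATION (|Δcarbons| = 2, all else equal), DESATURATION
    (|Δdouble bonds| = 1) or OXIDATION (|Δhydroxyls| = 1), restricted to
    the reactions enabled in ``rules``; ``None`` when no single enabled
    reaction explains the difference.  Chains of different linkage
    (ester vs ether vs sphingoid base) never transform into each other.
    """
    if a.linkage is not b.linkage:
        return None
    dc = abs(a.carbons - b.carbons)
    ddb = abs(a.double_bonds - b.double_bonds)
    doh = abs(a.hydroxyls - b.hydroxyls)
    if (dc, ddb, doh) == (2, 0, 0):
        candidate = ReactionType.ELONGATION
    elif (dc, ddb, doh) == (0, 1, 0):
        candidate = ReactionType.DESATURATION
    elif (dc, ddb, doh) == (0, 0, 1):
        candidate = ReactionType.OXIDATION
    else:
        return None
    return candidate if candidate in rules.fa_reactions_enabled else None


def _sum_delta_transformation(
    x: LipidSpecies, y: LipidSpecies, rules: RuleSet
) -> Optional[ReactionType]:
    """Chain-level reaction explaining the difference of two sum triples."""
    dc = abs(x.sum_carbons - y.sum_carbons)
    ddb = abs(x.sum_double_bonds - y.sum_double_bonds)
    doh = abs(x.sum_hydroxyls - y.sum_hydroxyls)
    if (dc, ddb, doh) == (2, 0, 0):
        candidate = ReactionType.ELONGATION
    elif (dc, ddb, doh) == (0, 1, 0):
        candidate = ReactionType.DESATURATION
    elif (dc, ddb, doh) == (0, 0, 1):
        candidate = ReactionType.OXIDATION
    else:
        return None
    return candidate if candidate in rules.fa_reactions_enabled else None


def _molecular_single_difference(
    x: LipidSpecies, y: LipidSpecies, rules: RuleSet
) -> Optional[ReactionType]:
    """Same-class molecular match: exactly one transformable chain pair.

    The largest common chain multiset is removed from both sides; an
    edge exists iff exactly one chain remains on each side and that pair
    admits a chain-level transformation.  All maximal pairings are
    equivalent under this rule.
    """
    cx, cy = Counter(x.chains), Counter(y.chains)
    common = cx & cy
    rest_x = list((cx - common).elements())
    rest_y = list((cy - common).elements())
    if len(rest_x) != 1 or len(rest_y) != 1:
        return None
    return infer_fa_transformation(rest_x[0], rest_y[0], rules)


def _pool_contains(pool: Iterable[FattyAcid], carbons: int, double_bonds: int, hydroxyls: int) -> bool:
    return any(
        fa.carbons == carbons
        and fa.double_bonds == double_bonds
        and fa.hydroxyls == hydroxyls
        for fa in pool
    )


def match_pair(
    x: LipidSpecies, y: LipidSpecies, rules: RuleSet
) -> Optional[EdgeAnnotation]:
    """Decide whether a rule connects two species.

    Absence of a match is a value (``None``), not an error.  The
    decision is symmetric in its arguments.
    """
    if x == y:
        return None
    for species in (x, y):
        if species.lipid_class not in rules.registry:
            raise KeyError(f"class {species.lipid_class!r} not in registry")

    molecular = x.level is not Level.SUM and y.level is not Level.SUM
    resolution = Level.MOLECULAR if molecular else Level.SUM
    if not molecular:
        x, y = demote_to_sum(x), demote_to_sum(y)

    # (1) same class: one chain-level transformation
    if x.lipid_class == y.lipid_class:
        if molecular:
            reaction = _molecular_single_difference(x, y, rules)
        else:
            reaction = _sum_delta_transformation(x, y, rules)
        if reaction is None:
            return None
        return EdgeAnnotation(reaction_type=reaction, resolution_of_match=resolution)

    class_reaction = rules.reaction_for(x.lipid_class, y.lipid_class)
    if class_reaction is None:
        return None
    n_x = rules.expected_chains(x.lipid_class)
    n_y = rules.expected_chains(y.lipid_class)
    delta = abs(n_x - n_y)

    # (2) headgroup modification: identical acyl composition
    if delta == 0:
        if class_reaction.category is not ReactionCategory.HEADGROUP_MODIFICATION:
            return None
        if molecular:
            same = Counter(x.chains) == Counter(y.chains)
        else:
            same = x.sum_triple == y.sum_triple
        if not same:
            return None
        return EdgeAnnotation(
            reaction_type=ReactionType.CLASS_CONVERSION,
            enzymes=class_reaction.enzymes,
            resolution_of_match=resolution,
        )

    # (3) acyl addition/removal: larger contains smaller, extra chain in pool
    if delta == 1:
        if class_reaction.category is not ReactionCategory.FA_ADDITION_REMOVAL:
            return None
        large, small = (x, y) if n_x > n_y else (y, x)
        if molecular:
            c_large, c_small = Counter(large.chains), Counter(small.chains)
            extra = c_large - c_small
            if c_small - c_large or sum(extra.values()) != 1:
                return None
            (chain,) = extra.elements()
            if not _pool_contains(
                rules.fa_pool, chain.carbons, chain.double_bonds, chain.hydroxyls
            ):
                return None
        else:
            dc = large.sum_carbons - small.sum_carbons
            ddb = large.sum_double_bonds - small.sum_double_bonds
            doh = large.sum_hydroxyls - small.sum_hydroxyls
            if dc < 1 or ddb < 0 or doh < 0:
                return None
            if not _pool_contains(rules.fa_pool, dc, ddb, doh):
                return None
        return EdgeAnnotation(
            reaction_type=ReactionType.FA_ADDITION_REMOVAL,
            enzymes=class_reaction.enzymes,
            resolution_of_match=resolution,
        )

    # chain counts differing by >=2 would require a many-to-many reaction
    return None


def build_network(lipids: Iterable[LipidSpecies], rules: RuleSet) -> LipidNetwork:
    """Assemble the undirected lipid network for a measured lipidome.

    Nodes are the input species keyed by canonical name; an edge is
    drawn for every pair that :func:`match_pair` connects.  The result
    is independent of input order.  Duplicate canonical names are an
    error (the same species measured twice cannot be a distinct node).
    """
    species_by_name: Dict[str, LipidSpecies] = {}
    duplicates: List[str] = []
    for species in lipids:
        name = canonical_name(species)
        if name in species_by_name:
            duplicates.append(name)
        else:
            species_by_name[name] = species
    if duplicates:
        raise ValueError(
            "duplicate canonical lipid names: " + ", ".join(sorted(set(duplicates)))
        )

    net: LipidNetwork = nx.Graph()
    for name, species in species_by_name.items():
        net.add_node(
            name,
            species=species,
            lipid_class=species.lipid_class,
            level=species.level.value,
        )
    for (name_a, sp_a), (name_b, sp_b) in combinations(species_by_name.items(), 2):
        annotation = match_pair(sp_a, sp_b, rules)
        if annotation is not None:
            net.add_edge(
                name_a,
                name_b,
                annotation=annotation,
                reaction_type=annotation.reaction_type.value,
                enzymes=";".join(annotation.enzymes),
                resolution_of_match=annotation.resolution_of_match.value,
            )
    return net


def filter_edges(net: LipidNetwork, keep: Set[ReactionType]) -> LipidNetwork:
    """Subgraph with only edges of the given reaction types; nodes kept.

    Chain-level edges (elongation/desaturation/oxidation) are a
    heuristic; this is how they are hidden in one step.
    """
    keep_values = {t.value if isinstance(t, ReactionType) else t for t in keep}
    filtered = net.copy()
    drop = [
        (u, v)
        for u, v, data in filtered.edges(data=True)
        if data.get("reaction_type") not in keep_values
    ]
    filtered.remove_edges_from(drop)
    return filtered


def topology_metrics(net: LipidNetwork) -> Dict[str, Dict[str, float]]:
    """Degree, betweenness and closeness centrality per node.

    Betweenness is normalized shortest-path betweenness (divisor
    (n−1)(n−2)/2); closeness is the Wasserman–Faust component-scaled
    variant, so values remain comparable across disconnected networks.
    All computations are unweighted and exact.
    """
    betweenness = nx.betweenness_centrality(net, normalized=True)
    closeness = nx.closeness_centrality(net, wf_improved=True)
    return {
        node: {
            "degree": float(net.degree(node)),
            "betweenness": betweenness[node],
            "closeness": closeness[node],
        }
        for node in net.nodes
    }
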
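"""Independent brute-force reference matcher.

A second, deliberately naive implementation of the edge-decision rules,
written directly from their prose description and sharing no code with
``linexnet.network_builder``:

* same class, both resolved: enumerate every possible pairing
  (permutation) of the chain lists and accept if some pairing leaves
  all chains identical except exactly one pair that differs by a single
  enabled chain reaction;
* same class, sum level: compare the (carbons, double bonds, hydroxyls)
  totals directly;
* different classes with a listed reaction: equal chain counts require
  identical composition; counts differing by one require the larger
  species to contain the smaller plus one pool fatty acid (tried by
  removing each chain of the larger species in turn);
* species at different resolution levels are compared by their totals.

Used only as a test oracle.
"""

from itertools import permutations

from linexnet.lipid_model import Level
from linexnet.reaction_rules import ReactionType


def _totals(species):
    return (species.sum_carbons, species.sum_double_bonds, species.sum_hydroxyls)


def _chain_delta(a, b, enabled):
    """Reaction type explaining a difference between two single chains."""
    if a.linkage != b.linkage:
        return None
    diffs = (
        abs(a.carbons - b.carbons),
        abs(a.double_bonds - b.double_bonds),
        abs(a.hydroxyls - b.hydroxyls),
    )
    table = {
        (2, 0, 0): ReactionType.ELONGATION,
        (0, 1, 0): ReactionType.DESATURATION,
        (0, 0, 1): ReactionType.OXIDATION,
    }
    reaction = table.get(diffs)
    if reaction is not None and reaction in enabled:
        return reaction
    return None


def _sum_delta(ta, tb, enabled):
    diffs = tuple(abs(x - y) for x, y in zip(ta, tb))
    table = {
        (2, 0, 0): ReactionType.ELONGATION,
        (0, 1, 0): ReactionType.DESATURATION,
        (0, 0, 1): ReactionType.OXIDATION,
    }
    reaction = table.get(diffs)
    if reaction is not None and reaction in enabled:
        return reaction
    return None


def _chain_key(chain):
    return (chain.linkage.value, chain.carbons, chain.double_bonds, chain.hydroxyls)


def oracle_match(x, y, rules):
    """Reaction type connecting two species, or None."""
    if x == y:
        return None
    both_resolved = x.level != Level.SUM and y.level != Level.SUM

    if x.lipid_class == y.lipid_class:
        if not both_resolved:
            return _sum_delta(_totals(x), _totals(y), rules.fa_reactions_enabled)
        # try every pairing of the chains
        for perm in permutations(y.chains):
            differing = [
                (a, b) for a, b in zip(x.chains, perm) if _chain_key(a) != _chain_key(b)
            ]
            if len(differing) != 1:
                continue
            reaction = _chain_delta(*differing[0], rules.fa_reactions_enabled)
            if reaction is not None:
                return reaction
        return None

    reaction = rules.reaction_for(x.lipid_class, y.lipid_class)
    if reaction is None:
        return None
    nx_, ny_ = (
        rules.registry[x.lipid_class].expected_chains,
        rules.registry[y.lipid_class].expected_chains,
    )
    if nx_ == ny_:
        if both_resolved:
            same = sorted(map(_chain_key, x.chains)) == sorted(map(_chain_key, y.chains))
        else:
            same = _totals(x) == _totals(y)
        return ReactionType.CLASS_CONVERSION if same else None
    if abs(nx_ - ny_) == 1:
        big, small = (x, y) if nx_ > ny_ else (y, x)
        pool = {(fa.carbons, fa.double_bonds, fa.hydroxyls) for fa in rules.fa_pool}
        if both_resolved:
            small_sorted = sorted(map(_chain_key, small.chains))
            for i, chain in enumerate(big.chains):
                rest = sorted(
                    _chain_key(c) for j, c in enumerate(big.chains) if j != i
                )
                if rest == small_sorted and (
                    chain.carbons, chain.double_bonds, chain.hydroxyls
                ) in pool:
                    return ReactionType.FA_ADDITION_REMOVAL
            return None
        delta = tuple(a - b for a, b in zip(_totals(big), _totals(small)))
        return ReactionType.FA_ADDITION_REMOVAL if delta in pool else None
    return None


def oracle_edge_set(species_list, rules):
    """All edges the naive matcher finds, as {frozenset({name_a, name_b}): type}."""
    from linexnet.lipid_model import canonical_name

    edges = {}
    named = [(canonical_name(s), s) for s in species_list]
    for i in range(len(named)):
        for j in range(i + 1, len(named)):
            reaction = oracle_match(named[i][1], named[j][1], rules)
            if reaction is not None:
                edges[frozenset((named[i][0], named[j][0]))] = reaction
    return edges
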
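"""Customizable biochemical rule system.

A :class:`RuleSet` bundles everything the network builder needs to decide
whether two measured lipid species are connected by an enzymatic
reaction:

* a **class registry** — for each lipid class its expected chain count
  and backbone family (ether variants such as ``PE O-`` are distinct
  classes);
* **class reactions** — unordered pairs of classes convertible into each
  other, either by a headgroup modification (equal chain counts, e.g.
  PC↔PE) or by an acyl addition/removal (chain counts differing by one,
  e.g. PC↔LPC), optionally annotated with enzymes (free text, never
  interpreted);
* the enabled **chain-level reactions** (elongation, desaturation,
  oxidation);
* the **fatty-acid pool** — the acyls considered available when an
  addition reaction has to supply a chain.

Rules are data, not code: the shipped defaults cover common mammalian
glycero-, glycerophospho- and sphingolipid metabolism and can be
replaced or extended through a human-readable YAML file, so that
condition-, tissue- or organism-specific rule sets can be shared.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple, Union

import yaml

from .lipid_model import Backbone, FattyAcid, Linkage

__all__ = [
    "ReactionType",
    "ReactionCategory",
    "ClassRegistryEntry",
    "ClassReaction",
    "RuleSet",
    "RuleValidationError",
    "default_ruleset",
    "load_ruleset",
    "save_ruleset",
    "validate_ruleset",
]


class ReactionType(enum.Enum):
    """Reaction type attached to a network edge."""

    CLASS_CONVERSION = "class_conversion"
    FA_ADDITION_REMOVAL = "fa_addition_removal"
    ELONGATION = "elongation"
    DESATURATION = "desaturation"
    OXIDATION = "oxidation"


#: chain-level (fatty-acid) reaction types
FA_REACTION_TYPES: FrozenSet[ReactionType] = frozenset(
    {ReactionType.ELONGATION, ReactionType.DESATURATION, ReactionType.OXIDATION}
)


class ReactionCategory(enum.Enum):
    HEADGROUP_MODIFICATION = "headgroup_modification"
    FA_ADDITION_REMOVAL = "fa_addition_removal"


@dataclass(frozen=True)
class ClassRegistryEntry:
    class_name: str
    expected_chains: int
    backbone: Backbone
    color: Optional[str] = None


@dataclass(frozen=True)
class ClassReaction:
    """An unordered pair of interconvertible lipid classes.

    ``(a, b)`` and ``(b, a)`` are the same reaction; the pair is stored
    sorted.  Enzyme annotations are free-text labels copied onto
    matching edges.
    """

    class_a: str
    class_b: str
    category: ReactionCategory
    enzymes: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        a, b = sorted((self.class_a, self.class_b))
        object.__setattr__(self, "class_a", a)
        object.__setattr__(self, "class_b", b)
        object.__setattr__(self, "enzymes", tuple(self.enzymes))

    @property
    def pair(self) -> FrozenSet[str]:
        return frozenset((self.class_a, self.class_b))


@dataclass
class RuleSet:
    """Registry + reactions + enabled chain rules + fatty-acid pool."""

    registry: Dict[str, ClassRegistryEntry]
    class_reactions: FrozenSet[ClassReaction]
    fa_reactions_enabled: FrozenSet[ReactionType]
    fa_pool: Tuple[FattyAcid, ...]
    _pair_index: Dict[FrozenSet[str], ClassReaction] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        self.class_reactions = frozenset(self.class_reactions)
        self.fa_reactions_enabled = frozenset(self.fa_reactions_enabled)
        self.fa_pool = tuple(self.fa_pool)
        self._pair_index = {r.pair: r for r in self.class_reactions}

    def reaction_for(self, class_a: str, class_b: str) -> Optional[ClassReaction]:
        """The class reaction connecting two classes, if one is listed."""
        return self._pair_index.get(frozenset((class_a, class_b)))

    def expected_chains(self, class_name: str) -> int:
        return self.registry[class_name].expected_chains


class RuleValidationError(ValueError):
    """Raised for invalid rule files; carries every violation, not just the first."""

    def __init__(self, violations: List[str]):
        self.violations = list(violations)
        super().__init__(
            "invalid rule set:\n" + "\n".join(f"  - {v}" for v in self.violations)
        )


# ---------------------------------------------------------------------------
# Construction from YAML
# ---------------------------------------------------------------------------

_TOP_LEVEL_KEYS = {
    "schema_version",
    "extends",
    "classes",
    "class_reactions",
    "fa_reactions",
    "fa_pool",
}

_FA_REACTION_NAMES = {
    "elongation": ReactionType.ELONGATION,
    "desaturation": ReactionType.DESATURATION,
    "oxidation": ReactionType.OXIDATION,
}


def _parse_pool_fa(text: str) -> FattyAcid:
    carbons, _, double_bonds = str(text).partition(":")
    return FattyAcid(
        carbons=int(carbons), double_bonds=int(double_bonds), linkage=Linkage.ESTER
    )


def _derive_category(
    registry: Dict[str, ClassRegistryEntry], a: str, b: str
) -> Optional[ReactionCategory]:
    if a not in registry or b not in registry:
        return None
    delta = abs(registry[a].expected_chains - registry[b].expected_chains)
    if delta == 0:
        return ReactionCategory.HEADGROUP_MODIFICATION
    if delta == 1:
        return ReactionCategory.FA_ADDITION_REMOVAL
    return None


def _ruleset_from_mapping(raw: dict, violations: List[str]) -> RuleSet:
    registry: Dict[str, ClassRegistryEntry] = {}
    for item in raw.get("classes", []) or []:
        name = str(item.get("name", "")).strip()
        if not name:
            violations.append(f"class entry without a name: {item!r}")
            continue
        if name in registry:
            violations.append(f"duplicate class {name!r} in registry")
            continue
        try:
            backbone = Backbone(str(item.get("backbone", "other")).lower())
        except ValueError:
            violations.append(
                f"class {name!r}: unknown backbone {item.get('backbone')!r}"
            )
            backbone = Backbone.OTHER
        chains = item.get("chains")
        if not isinstance(chains, int) or chains < 1:
            violations.append(f"class {name!r}: 'chains' must be a positive integer")
            chains = 1
        unknown = set(item) - {"name", "chains", "backbone", "color"}
        if unknown:
            violations.append(f"class {name!r}: unknown keys {sorted(unknown)}")
        registry[name] = ClassRegistryEntry(
            class_name=name,
            expected_chains=chains,
            backbone=backbone,
            color=item.get("color"),
        )

    reactions: List[ClassReaction] = []
    for item in raw.get("class_reactions", []) or []:
        pair = item.get("pair")
        if not (isinstance(pair, (list, tuple)) and len(pair) == 2):
            violations.append(f"class reaction without a two-element pair: {item!r}")
            continue
        a, b = str(pair[0]), str(pair[1])
        unknown = set(item) - {"pair", "enzymes", "category"}
        if unknown:
            violations.append(f"reaction {a}~{b}: unknown keys {sorted(unknown)}")
        if "category" in item:
            try:
                category = ReactionCategory(str(item["category"]).lower())
            except ValueError:
                violations.append(
                    f"reaction {a}~{b}: unknown category {item['category']!r}"
                )
                continue
        else:
            category = _derive_category(registry, a, b)
            if category is None:
                # reported again by validate_ruleset with the precise cause
                category = ReactionCategory.HEADGROUP_MODIFICATION
        enzymes = tuple(str(e) for e in item.get("enzymes", []) or [])
        reactions.append(
            ClassReaction(class_a=a, class_b=b, category=category, enzymes=enzymes)
        )

    fa_enabled: List[ReactionType] = []
    for name in raw.get("fa_reactions", []) or []:
        key = str(name).lower()
        if key not in _FA_REACTION_NAMES:
            violations.append(f"unknown fa_reaction {name!r}")
        else:
            fa_enabled.append(_FA_REACTION_NAMES[key])

    pool: List[FattyAcid] = []
    for text in raw.get("fa_pool", []) or []:
        try:
            pool.append(_parse_pool_fa(text))
        except (ValueError, TypeError):
            violations.append(f"fa_pool entry {text!r} is not a 'C:D' descriptor")

    return RuleSet(
        registry=registry,
        class_reactions=frozenset(reactions),
        fa_reactions_enabled=frozenset(fa_enabled),
        fa_pool=tuple(pool),
    )


def _overlay(base: RuleSet, extension: RuleSet, raw: dict) -> RuleSet:
    registry = dict(base.registry)
    registry.update(extension.registry)
    index = {r.pair: r for r in base.class_reactions}
    index.update({r.pair: r for r in extension.class_reactions})
    fa_enabled = (
        extension.fa_reactions_enabled
        if "fa_reactions" in raw
        else base.fa_reactions_enabled
    )
    pool = extension.fa_pool if "fa_pool" in raw else base.fa_pool
    return RuleSet(
        registry=registry,
        class_reactions=frozenset(index.values()),
        fa_reactions_enabled=fa_enabled,
        fa_pool=pool,
    )


def validate_ruleset(rules: RuleSet) -> List[str]:
    """Check every rule-set invariant; return a description per violation.

    An empty list means the rule set is valid.  Violations are collected
    exhaustively rather than failing fast, so a user fixing a rule file
    sees every problem at once.
    """
    violations: List[str] = []
    seen_pairs: set = set()
    has_fa_addition = False
    for reaction in sorted(
        rules.class_reactions, key=lambda r: (r.class_a, r.class_b)
    ):
        a, b = reaction.class_a, reaction.class_b
        missing = [c for c in (a, b) if c not in rules.registry]
        for c in missing:
            violations.append(f"reaction {a}~{b}: class {c!r} not in registry")
        if reaction.pair in seen_pairs:
            violations.append(f"duplicate class reaction {a}~{b}")
        seen_pairs.add(reaction.pair)
        if missing:
            continue
        delta = abs(rules.expected_chains(a) - rules.expected_chains(b))
        if delta == 0 and reaction.category is not ReactionCategory.HEADGROUP_MODIFICATION:
            violations.append(
                f"reaction {a}~{b}: equal chain counts require "
                f"category headgroup_modification"
            )
        elif delta == 1 and reaction.category is not ReactionCategory.FA_ADDITION_REMOVAL:
            violations.append(
                f"reaction {a}~{b}: chain counts differing by one require "
                f"category fa_addition_removal"
            )
        elif delta > 1:
            violations.append(
                f"reaction {a}~{b}: chain counts differ by {delta}; "
                f"many-to-many reactions cannot be represented"
            )
        if reaction.category is ReactionCategory.FA_ADDITION_REMOVAL:
            has_fa_addition = True
    if has_fa_addition and not rules.fa_pool:
        violations.append(
            "fa_pool is empty but fa_addition_removal reactions are present"
        )
    return violations


def _load_raw(source: Union[str, "object"]) -> dict:
    if hasattr(source, "read"):
        raw = yaml.safe_load(source.read())
    else:
        with open(source, "r", encoding="utf-8") as handle:
            raw = yaml.safe_load(handle)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise RuleValidationError(["rule file must contain a mapping at top level"])
    return raw


def load_ruleset(path) -> RuleSet:
    """Load and validate a rule file (YAML).

    A file with ``extends: default`` overlays the shipped defaults:
    classes are added or replaced by name, class reactions by pair, and
    ``fa_reactions`` / ``fa_pool`` replace the defaults only when the
    key is present.  All schema and invariant violations are collected
    and raised together as :class:`RuleValidationError`.
    """
    raw = _load_raw(path)
    violations: List[str] = []
    unknown = set(raw) - _TOP_LEVEL_KEYS
    if unknown:
        violations.append(f"unknown top-level keys {sorted(unknown)}")
    extends = raw.get("extends")
    if extends not in (None, "default"):
        violations.append(f"unsupported extends value {extends!r}")
        extends = None
    rules = _ruleset_from_mapping(raw, violations)
    if extends == "default":
        rules = _overlay(default_ruleset(), rules, raw)
    violations.extend(validate_ruleset(rules))
    if violations:
        raise RuleValidationError(violations)
    return rules


def save_ruleset(rules: RuleSet, path) -> None:
    """Write a rule set as a self-contained YAML file (no ``extends``)."""
    doc = {
        "schema_version": 1,
        "classes": [
            {
                "name": e.class_name,
                "chains": e.expected_chains,
                "backbone": e.backbone.value,
                **({"color": e.color} if e.color else {}),
            }
            for e in sorted(rules.registry.values(), key=lambda e: e.class_name)
        ],
        "class_reactions": [
            {
                "pair": [r.class_a, r.class_b],
                "category": r.category.value,
                "enzymes": list(r.enzymes),
            }
            for r in sorted(
                rules.class_reactions, key=lambda r: (r.class_a, r.class_b)
            )
        ],
        "fa_reactions": sorted(
            t.value for t in rules.fa_reactions_enabled
        ),
        "fa_pool": [
            f"{fa.carbons}:{fa.double_bonds}" for fa in rules.fa_pool
        ],
    }
    with open(path, "w", encoding="utf-8") as handle:
        yaml.safe_dump(doc, handle, sort_keys=False, allow_unicode=True)


def default_ruleset() -> RuleSet:
    """The shipped default rule set.

    Covers the canonical mammalian glycerophospholipid headgroup
    interconversions, acyl addition/removal between each class and its
    lyso form (and DG↔TG/MG), the sphingolipid headgroup chain
    Cer↔SM/HexCer↔Hex2Cer, all three chain-level reactions, and a pool
    of common mammalian fatty acids (even chains C12–C24 plus the odd
    chains 15:0, 17:0, 17:1 and 19:0).
    """
    source = resources.files("linexnet").joinpath("data/default_rules.yaml")
    with source.open("r", encoding="utf-8") as handle:
        raw = _load_raw(handle)
    violations: List[str] = []
    rules = _ruleset_from_mapping(raw, violations)
    violations.extend(validate_ruleset(rules))
    if violations:  # pragma: no cover - shipped defaults must validate
        raise RuleValidationError(violations)
    return rules
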
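"""Lipid shorthand parsing and composition arithmetic.

Lipid species are written in a shorthand nomenclature that encodes the
lipid class (headgroup/backbone family) and the fatty acyl composition at
one of three structural resolutions:

* **sum composition** — only total carbons and double bonds are known,
  e.g. ``TG(58:10)``;
* **molecular species** — the individual chains are known but not their
  positions, written with ``_``, e.g. ``PC(16:0_20:4)``;
* **sn-specific** — chain positions are resolved, written with ``/``,
  e.g. ``Cer(d18:1/16:0)``.

The grammar accepted here is ``CLASS(spec)`` or ``CLASS spec`` where
``spec`` is one or more chain descriptors joined by ``_`` or ``/``.  A
chain descriptor is ``[d|t]?C:D[;O[k]]`` — ``d``/``t`` mark a sphingoid
long-chain base carrying two/three hydroxyl groups, and ``;O``/``;Ok``
adds ``k`` (default 1) hydroxyl modifications.  An ether prefix ``O-`` or
``P-`` on the first chain (or on a sum descriptor) switches the class to
its ether variant, which is treated as a distinct class (``PE`` vs
``PE O-``): ether lipids are different chemistry and participate in their
own reactions.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Protocol, Sequence, Tuple

__all__ = [
    "Linkage",
    "Level",
    "Backbone",
    "FattyAcid",
    "LipidSpecies",
    "LipidParseError",
    "parse_lipid_name",
    "canonical_name",
    "demote_to_sum",
]


class Linkage(enum.Enum):
    """Chemical linkage of a chain to the backbone."""

    ESTER = "ester"
    ETHER_O = "ether_o"  # plasmanyl (alkyl) ether
    ETHER_P = "ether_p"  # plasmenyl (alkenyl/vinyl) ether
    LCB = "lcb"  # sphingoid long-chain base


class Level(enum.Enum):
    """Structural resolution of a lipid annotation."""

    SUM = "sum"
    MOLECULAR = "molecular"
    SN_SPECIFIC = "sn_specific"


class Backbone(enum.Enum):
    GLYCEROLIPID = "glycerolipid"
    GLYCEROPHOSPHOLIPID = "glycerophospholipid"
    SPHINGOLIPID = "sphingolipid"
    STEROL = "sterol"
    OTHER = "other"


class RegistryEntryLike(Protocol):
    """Minimal interface the parser needs from a class-registry entry."""

    class_name: str
    expected_chains: int
    backbone: Backbone


@dataclass(frozen=True)
class FattyAcid:
    """One acyl/alkyl/long-chain-base chain.

    ``carbons``/``double_bonds``/``hydroxyls`` are the three numeric
    fields on which the chain-level reactions (elongation, desaturation,
    oxidation) operate.  No chemical-plausibility constraint is enforced
    between carbons and double bonds: the shorthand permits any printed
    pair.
    """

    carbons: int
    double_bonds: int
    hydroxyls: int = 0
    linkage: Linkage = field(default=Linkage.ESTER, compare=True)

    def __post_init__(self) -> None:
        if self.carbons < 1:
            raise ValueError(f"chain must have >=1 carbon, got {self.carbons}")
        if self.double_bonds < 0 or self.hydroxyls < 0:
            raise ValueError("double_bonds and hydroxyls must be non-negative")

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return _render_chain(self)

    @property
    def sort_key(self) -> Tuple[int, int, int, str]:
        return (self.carbons, self.double_bonds, self.hydroxyls, self.linkage.value)


class LipidParseError(ValueError):
    """Raised for names that do not conform to the shorthand grammar.

    ``token`` carries the offending fragment and ``position`` its
    character offset in the input, when known.
    """

    def __init__(self, message: str, token: str = "", position: Optional[int] = None):
        super().__init__(message)
        self.token = token
        self.position = position


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed lipid species.

    ``chains`` is empty at SUM level; otherwise the sum fields are the
    component-wise totals over the chains.  Equality ignores
    ``raw_name`` and, at MOLECULAR level, chain order (multiset
    semantics).  At SN_SPECIFIC level positions are preserved and
    compared.
    """

    lipid_class: str
    level: Level
    chains: Tuple[FattyAcid, ...]
    sum_carbons: int
    sum_double_bonds: int
    sum_hydroxyls: int
    raw_name: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if self.level is Level.SUM:
            if self.chains:
                raise ValueError("SUM-level species must not carry chains")
        else:
            if sum(c.carbons for c in self.chains) != self.sum_carbons:
                raise ValueError("sum_carbons inconsistent with chains")
            if sum(c.double_bonds for c in self.chains) != self.sum_double_bonds:
                raise ValueError("sum_double_bonds inconsistent with chains")
            if sum(c.hydroxyls for c in self.chains) != self.sum_hydroxyls:
                raise ValueError("sum_hydroxyls inconsistent with chains")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LipidSpecies):
            return NotImplemented
        if (
            self.lipid_class != other.lipid_class
            or self.level != other.level
            or (self.sum_carbons, self.sum_double_bonds, self.sum_hydroxyls)
            != (other.sum_carbons, other.sum_double_bonds, other.sum_hydroxyls)
        ):
            return False
        if self.level is Level.MOLECULAR:
            key = lambda c: c.sort_key
            return sorted(self.chains, key=key) == sorted(other.chains, key=key)
        return self.chains == other.chains

    def __hash__(self) -> int:
        chains = (
            tuple(sorted(self.chains, key=lambda c: c.sort_key))
            if self.level is Level.MOLECULAR
            else self.chains
        )
        return hash(
            (
                self.lipid_class,
                self.level,
                chains,
                self.sum_carbons,
                self.sum_double_bonds,
                self.sum_hydroxyls,
            )
        )

    @property
    def sum_triple(self) -> Tuple[int, int, int]:
        return (self.sum_carbons, self.sum_double_bonds, self.sum_hydroxyls)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_CHAIN_RE = re.compile(
    r"^(?P<lcb>[dt])?(?P<carbons>\d+):(?P<db>\d+)(?:;O(?P<oh>\d*))?$"
)

_ETHER_PREFIXES = {"O-": Linkage.ETHER_O, "P-": Linkage.ETHER_P}
_LCB_HYDROXYLS = {"d": 2, "t": 3}


def _split_class_and_spec(name: str) -> Tuple[str, str, int]:
    """Split ``CLASS(spec)`` / ``CLASS spec`` into (class token, spec, spec offset)."""
    name = name.strip()
    if not name:
        raise LipidParseError("empty lipid name")
    if "(" in name:
        idx = name.index("(")
        cls = name[:idx].strip()
        if not name.endswith(")"):
            raise LipidParseError(
                f"unbalanced parentheses in {name!r}", token=name, position=len(name)
            )
        return cls, name[idx + 1 : -1].strip(), idx + 1
    parts = name.split(None, 1)
    if len(parts) == 1:
        raise LipidParseError(
            f"no chain descriptor found in {name!r}", token=name, position=len(name)
        )
    return parts[0], parts[1].strip(), len(parts[0]) + 1


def _parse_chain(
    token: str, position: int, linkage: Linkage
) -> FattyAcid:
    m = _CHAIN_RE.match(token)
    if m is None:
        raise LipidParseError(
            f"malformed chain descriptor {token!r} at position {position}",
            token=token,
            position=position,
        )
    hydroxyls = 0
    if m.group("lcb"):
        linkage = Linkage.LCB
        hydroxyls = _LCB_HYDROXYLS[m.group("lcb")]
    if m.group("oh") is not None:
        hydroxyls += int(m.group("oh")) if m.group("oh") else 1
    carbons = int(m.group("carbons"))
    if carbons < 1:
        raise LipidParseError(
            f"chain must have at least one carbon: {token!r}",
            token=token,
            position=position,
        )
    return FattyAcid(
        carbons=carbons,
        double_bonds=int(m.group("db")),
        hydroxyls=hydroxyls,
        linkage=linkage,
    )


def parse_lipid_name(
    name: str, registry: Mapping[str, RegistryEntryLike]
) -> LipidSpecies:
    """Parse a shorthand lipid name into a :class:`LipidSpecies`.

    Parameters
    ----------
    name:
        Shorthand name, e.g. ``"PC(16:0_20:4)"``, ``"TG(58:10)"``,
        ``"PE(O-38:5)"`` or ``"Cer(d18:1/16:0)"``.
    registry:
        Mapping of class name to registry entry; used to reject unknown
        classes, to resolve the sphingoid base of sphingolipid classes
        and to check chain counts at resolved levels.

    Raises
    ------
    LipidParseError
        For an unknown class token or a malformed chain descriptor.
    """
    cls_token, spec, spec_offset = _split_class_and_spec(name)

    # ether prefix on the spec switches to the ether-variant class
    linkage_first = Linkage.ESTER
    for prefix, linkage in _ETHER_PREFIXES.items():
        if spec.startswith(prefix):
            spec = spec[len(prefix) :]
            cls_token = f"{cls_token} {prefix}".strip()
            linkage_first = linkage
            break

    # the ether class may also be spelled directly in the class token
    if linkage_first is Linkage.ESTER:
        for prefix, linkage in _ETHER_PREFIXES.items():
            if cls_token.endswith(f" {prefix}"):
                linkage_first = linkage
                break

    entry = registry.get(cls_token)
    if entry is None:
        raise LipidParseError(
            f"unknown lipid class {cls_token!r} in {name!r}",
            token=cls_token,
            position=0,
        )

    if "/" in spec:
        level, sep = Level.SN_SPECIFIC, "/"
    elif "_" in spec:
        level, sep = Level.MOLECULAR, "_"
    else:
        level, sep = Level.SUM, None

    sphingo = entry.backbone is Backbone.SPHINGOLIPID

    if level is Level.SUM:
        chain = _parse_chain(spec, spec_offset, linkage_first)
        # a lone descriptor is a sum composition: d/t hydroxyls and ether
        # linkage are folded into the totals / the class name
        return LipidSpecies(
            lipid_class=cls_token,
            level=Level.SUM,
            chains=(),
            sum_carbons=chain.carbons,
            sum_double_bonds=chain.double_bonds,
            sum_hydroxyls=chain.hydroxyls,
            raw_name=name,
        )

    tokens = spec.split(sep)
    chains = []
    offset = spec_offset
    for i, token in enumerate(tokens):
        token = token.strip()
        if i == 0:
            linkage = linkage_first
            if sphingo and linkage is Linkage.ESTER:
                linkage = Linkage.LCB  # first position of a sphingolipid
        else:
            linkage = Linkage.ESTER
        chains.append(_parse_chain(token, offset, linkage))
        offset += len(token) + 1

    if len(chains) != entry.expected_chains:
        raise LipidParseError(
            f"{cls_token!r} expects {entry.expected_chains} chains, "
            f"got {len(chains)} in {name!r}",
            token=spec,
            position=spec_offset,
        )

    return LipidSpecies(
        lipid_class=cls_token,
        level=level,
        chains=tuple(chains),
        sum_carbons=sum(c.carbons for c in chains),
        sum_double_bonds=sum(c.double_bonds for c in chains),
        sum_hydroxyls=sum(c.hydroxyls for c in chains),
        raw_name=name,
    )


# ---------------------------------------------------------------------------
# Canonical rendering
# ---------------------------------------------------------------------------

_LINKAGE_ORDER = {Linkage.LCB: 0, Linkage.ETHER_O: 1, Linkage.ETHER_P: 1, Linkage.ESTER: 2}


def _render_chain(chain: FattyAcid) -> str:
    hydroxyls = chain.hydroxyls
    prefix = ""
    if chain.linkage is Linkage.LCB and hydroxyls in (2, 3):
        prefix = "d" if hydroxyls == 2 else "t"
        hydroxyls = 0
    body = f"{prefix}{chain.carbons}:{chain.double_bonds}"
    if hydroxyls == 1:
        body += ";O"
    elif hydroxyls > 1:
        body += f";O{hydroxyls}"
    return body


def _chain_sort_key(chain: FattyAcid) -> Tuple[int, int, int, int]:
    return (
        _LINKAGE_ORDER[chain.linkage],
        chain.carbons,
        chain.double_bonds,
        chain.hydroxyls,
    )


def canonical_name(species: LipidSpecies) -> str:
    """Deterministic shorthand rendering of a species.

    Chains are sorted by (linkage group, carbons, double bonds,
    hydroxyls) at MOLECULAR level — sphingoid bases and ether chains
    stay in first position — and kept in their given order at
    SN_SPECIFIC level.  ``parse_lipid_name(canonical_name(x))`` equals
    ``x`` for every valid species.
    """
    cls = species.lipid_class
    ether_prefix = ""
    for suffix, _ in _ETHER_PREFIXES.items():
        if cls.endswith(f" {suffix}"):
            ether_prefix = suffix
            cls = cls[: -len(suffix) - 1]
            break

    if species.level is Level.SUM:
        body = f"{species.sum_carbons}:{species.sum_double_bonds}"
        if species.sum_hydroxyls == 1:
            body += ";O"
        elif species.sum_hydroxyls > 1:
            body += f";O{species.sum_hydroxyls}"
        return f"{cls}({ether_prefix}{body})"

    chains: Sequence[FattyAcid] = species.chains
    if species.level is Level.MOLECULAR:
        chains = sorted(chains, key=_chain_sort_key)
    sep = "/" if species.level is Level.SN_SPECIFIC else "_"
    body = sep.join(_render_chain(c) for c in chains)
    return f"{cls}({ether_prefix}{body})"


def demote_to_sum(species: LipidSpecies) -> LipidSpecies:
    """Collapse a species to its sum composition.

    Drops individual chains but preserves the totals (including
    hydroxyls contributed by d/t sphingoid bases).  Idempotent; used to
    compare species annotated at mixed resolution levels.
    """
    if species.level is Level.SUM:
        return species
    return LipidSpecies(
        lipid_class=species.lipid_class,
        level=Level.SUM,
        chains=(),
        sum_carbons=species.sum_carbons,
        sum_double_bonds=species.sum_double_bonds,
        sum_hydroxyls=species.sum_hydroxyls,
        raw_name=species.raw_name,
    )
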
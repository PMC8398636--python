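"""Synthetic lipidomes and abundance matrices with known structure.

Real lipidomics studies are not required to exercise the package: this
module generates (a) syntactically valid lipid name lists that span sum
and molecular annotation levels and are guaranteed to contain every
edge type the default rules can produce, and (b) abundance matrices
with planted effects — per-group correlation blocks (imposed through a
Cholesky factor of the target correlation matrix) and mean shifts in
selected lipids — on a log-like Gaussian scale.

Everything is driven by a :class:`SyntheticSpec` and a seed; the same
spec and seed reproduce the output exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .differential_stats import AbundanceTable
from .lipid_model import (
    Backbone,
    LipidSpecies,
    canonical_name,
    parse_lipid_name,
)
from .reaction_rules import RuleSet, default_ruleset

__all__ = ["SyntheticSpec", "CorrelationBlock", "generate_lipidome", "generate_abundances", "parse_lipidome"]


@dataclass(frozen=True)
class CorrelationBlock:
    """A set of lipids given pairwise correlation ``r`` in one group."""

    group: str
    members: Tuple[str, ...]
    r: float = 0.8


# species always included so the default rules yield at least one edge
# of every reaction type (conversion triangle, lyso pair, elongation,
# desaturation, oxidation) plus sum-level chains
_GUARANTEED = (
    "PC(16:0_18:1)",
    "PE(16:0_18:1)",
    "PS(16:0_18:1)",
    "LPC(16:0)",
    "PC(16:0_18:2)",
    "PC(16:0_20:1)",
    "Cer(d18:1_16:0)",
    "Cer(d18:1_16:0;O)",
    "TG(58:9)",
    "TG(58:10)",
)

_DEFAULT_PLAN: Dict[str, int] = {
    "PC": 8,
    "PE": 6,
    "PS": 3,
    "PI": 3,
    "LPC": 3,
    "LPE": 2,
    "PE O-": 3,
    "DG": 3,
    "TG": 8,
    "Cer": 3,
    "SM": 3,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions of a synthetic experiment.

    Defaults describe a typical two-group lipidomics comparison: 50
    samples per group, ~60 lipid species from common classes, unit
    Gaussian noise on a log2-like scale, two-standard-deviation shifts
    for planted differential lipids and within-block correlation 0.8
    for planted correlation blocks.
    """

    n_samples_per_group: int = 50
    group_labels: Tuple[str, ...] = ("A", "B")
    lipid_plan: Mapping[str, int] = field(default_factory=lambda: dict(_DEFAULT_PLAN))
    shifted_lipids: Tuple[str, ...] = ()
    shift_sd: float = 2.0
    shift_group: Optional[str] = None
    corr_blocks: Tuple[CorrelationBlock, ...] = ()
    noise_sd: float = 1.0
    baseline_mean: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        seen: set = set()
        for block in self.corr_blocks:
            overlap = seen & set(block.members)
            if overlap:
                raise ValueError(f"correlation blocks overlap on {sorted(overlap)}")
            seen |= set(block.members)
            if not -1.0 < block.r < 1.0:
                raise ValueError("block correlation must be in (-1, 1)")


def _random_molecular(rng, cls: str, rules: RuleSet) -> str:
    entry = rules.registry[cls]
    pool = rules.fa_pool
    chains = []
    for i in range(entry.expected_chains):
        if i == 0 and entry.backbone is Backbone.SPHINGOLIPID:
            chains.append(("d", 18, int(rng.integers(0, 2))))
            continue
        fa = pool[int(rng.integers(0, len(pool)))]
        chains.append(("", fa.carbons, fa.double_bonds))
    body = "_".join(f"{p}{c}:{d}" for p, c, d in chains)
    if cls.endswith(" O-"):
        return f"{cls[:-3]}(O-{body})"
    return f"{cls}({body})"


def _random_sum(rng, cls: str, rules: RuleSet) -> str:
    entry = rules.registry[cls]
    pool = rules.fa_pool
    carbons = doubles = hydroxyls = 0
    for i in range(entry.expected_chains):
        if i == 0 and entry.backbone is Backbone.SPHINGOLIPID:
            carbons += 18
            doubles += int(rng.integers(0, 2))
            hydroxyls += 2
            continue
        fa = pool[int(rng.integers(0, len(pool)))]
        carbons += fa.carbons
        doubles += fa.double_bonds
    body = f"{carbons}:{doubles}"
    if hydroxyls:
        body += f";O{hydroxyls}" if hydroxyls > 1 else ";O"
    if cls.endswith(" O-"):
        return f"{cls[:-3]}(O-{body})"
    return f"{cls}({body})"


def generate_lipidome(
    spec: SyntheticSpec, rules: Optional[RuleSet] = None
) -> List[str]:
    """Generate a deterministic list of unique, parseable lipid names.

    The list always contains the guaranteed motif species (so the
    default rules produce at least one edge of every reaction type) and
    then fills the per-class plan with random species, mixing sum and
    molecular annotation levels.
    """
    rules = rules or default_ruleset()
    unknown = [c for c in spec.lipid_plan if c not in rules.registry]
    if unknown:
        raise ValueError(f"plan references unknown classes: {unknown}")
    if not spec.lipid_plan:
        raise ValueError("empty lipid plan")
    rng = np.random.default_rng(spec.seed)

    names: List[str] = []
    seen: set = set()
    for name in _GUARANTEED:
        species = parse_lipid_name(name, rules.registry)
        seen.add(canonical_name(species))
        names.append(name)

    for cls in sorted(spec.lipid_plan):
        count = spec.lipid_plan[cls]
        attempts = 0
        added = 0
        while added < count and attempts < 200 * max(count, 1):
            attempts += 1
            if rng.random() < 0.4:
                name = _random_sum(rng, cls, rules)
            else:
                name = _random_molecular(rng, cls, rules)
            canon = canonical_name(parse_lipid_name(name, rules.registry))
            if canon in seen:
                continue
            seen.add(canon)
            names.append(name)
            added += 1
    return names


def parse_lipidome(
    names: Sequence[str], rules: Optional[RuleSet] = None
) -> List[LipidSpecies]:
    """Parse a list of names with the rule set's registry."""
    rules = rules or default_ruleset()
    return [parse_lipid_name(name, rules.registry) for name in names]


def _block_cholesky(size: int, r: float) -> np.ndarray:
    corr = np.full((size, size), r)
    np.fill_diagonal(corr, 1.0)
    return np.linalg.cholesky(corr)


def generate_abundances(
    lipids: Sequence[str],
    spec: SyntheticSpec,
    rules: Optional[RuleSet] = None,
) -> AbundanceTable:
    """Draw a samples × lipids abundance matrix per the spec.

    Each group is multivariate Gaussian: independent unit noise except
    for that group's correlation blocks, scaled by ``noise_sd`` around
    ``baseline_mean`` (a log-scale level).  Mean shifts of
    ``shift_sd`` standard deviations are applied to ``shifted_lipids``
    in ``shift_group`` (default: the last group).  Column names are
    canonicalized.
    """
    rules = rules or default_ruleset()
    canon = [canonical_name(parse_lipid_name(n, rules.registry)) for n in lipids]
    index_of = {name: i for i, name in enumerate(canon)}
    for block in spec.corr_blocks:
        missing = [m for m in block.members if m not in index_of]
        if missing:
            raise ValueError(f"block members not in lipidome: {missing}")
        if len(block.members) > len(canon):
            raise ValueError("block larger than lipidome")
    shift_group = spec.shift_group or spec.group_labels[-1]
    for lipid in spec.shifted_lipids:
        if lipid not in index_of:
            raise ValueError(f"shifted lipid {lipid!r} not in lipidome")

    rng = np.random.default_rng(spec.seed + 1)
    frames: List[pd.DataFrame] = []
    labels: List[str] = []
    sample_ids: List[str] = []
    n, k = spec.n_samples_per_group, len(canon)
    for group in spec.group_labels:
        z = rng.standard_normal((n, k))
        for block in spec.corr_blocks:
            if block.group != group:
                continue
            cols = [index_of[m] for m in block.members]
            chol = _block_cholesky(len(cols), block.r)
            z[:, cols] = z[:, cols] @ chol.T
        values = spec.baseline_mean + spec.noise_sd * z
        if group == shift_group:
            for lipid in spec.shifted_lipids:
                values[:, index_of[lipid]] += spec.shift_sd * spec.noise_sd
        frames.append(pd.DataFrame(values, columns=canon))
        labels.extend([group] * n)
        sample_ids.extend(f"{group}{i + 1}" for i in range(n))

    data = pd.concat(frames, ignore_index=True)
    data.index = pd.Index(sample_ids)
    groups = pd.Series(labels, index=data.index)
    return AbundanceTable(data=data, groups=groups)
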
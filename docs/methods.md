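# Methods

## The matching calculus

The network is built per dataset: nodes are exactly the species
measured, and an edge is drawn between two species when a single
biochemical reaction can interconvert them. Reactions come in two
families.

**Class reactions** are unordered pairs of lipid classes from the rule
file, each either a *headgroup modification* (equal chain counts, e.g.
PC↔PE via PEMT) or an *acyl addition/removal* (chain counts differing
by one, e.g. PC↔LPC via PLA2/LPCAT). A headgroup edge additionally
requires identical acyl composition on both sides; an addition edge
requires the larger species to contain every chain of the smaller one
and the extra chain to be a member of the allowed fatty-acid pool. The
pool exists because an addition reaction must supply a chain that is
not visible in the smaller species; it bounds which additions are
considered biologically available and is fully user-overridable.

**Chain reactions** connect species of the *same* class whose
compositions differ by exactly one elongation step (two carbons), one
desaturation (one double bond) or one oxidation (one hydroxyl), applied
to exactly one chain. At molecular-species level this is decided by
maximum multiset overlap: remove the largest common chain multiset; an
edge exists iff exactly one chain remains on each side and that pair
transforms. All maximal pairings are equivalent under this rule, so no
tie-breaking is needed. Chains of different linkage (ester, O-/P-ether,
sphingoid base) never transform into one another — they are different
chemistry — and ether classes are distinct registry entries, keeping
ether-lipid subnetworks connected among themselves. These chain edges
are a heuristic (no enzyme is asserted); `filter_edges` hides them in
one step.

Pairs of classes whose chain counts differ by two or more are never
connected: such conversions are many-to-many reactions (e.g.
Cer + PC → SM + DG) that pairwise edges cannot represent.

**Mixed resolution levels.** Species may be annotated as sum
compositions (`TG(58:10)`), molecular species (`PC(16:0_18:1)`) or
sn-specific (`Cer(d18:1/16:0)`). When the two sides of a comparison
have different levels, both are demoted to their sum compositions and
matched there; the edge records `resolution_of_match = sum` so the
information loss stays visible. This is the only level at which both
species are comparable; the alternative — matching a resolved species
against a sum species chain-by-chain — would have to guess the
unresolved chains. sn-positions are parsed and preserved but not
exploited for matching (multiset semantics): no reaction in the rule
set is position-specific, and asserting positional specificity the data
cannot support would fabricate precision.

## The shorthand grammar

`CLASS(spec)` or `CLASS spec`; `spec` is chain descriptors joined by
`_` (molecular) or `/` (sn-specific), or a single descriptor (sum
composition). A descriptor is `[d|t]?C:D[;O[k]]` — `d`/`t` mark a
sphingoid long-chain base with two/three hydroxyls (the first position
of a sphingolipid class is a long-chain base even unprefixed), and
`;O`/`;Ok` adds hydroxyl modifications. An `O-`/`P-` prefix on the
first chain switches the class to its ether variant. Canonical
rendering sorts molecular chains (bases and ethers first, then by
carbons/double bonds/hydroxyls) and round-trips:
`parse(canonical(x)) == x`. The grammar intentionally covers common
shorthand, not every historical dialect; unrecognized names raise a
structured parse error (never silent coercion), and the table reader
can either collect-and-report them or drop them behind an explicit
flag, with a user synonym table for dataset-specific aliases.

## Default rules

Rules are data. The shipped defaults cover 25 mammalian classes
(diacyl/lyso/ether glycerophospholipids, MG/DG/TG, CL, Cer/SM/HexCer/
Hex2Cer, CE), the canonical headgroup interconversions (PC/PE/PS
pairwise, PA as the glycerophospholipid hub to PG/PI/PS/PC/DG, the
sphingolipid chain Cer↔SM/HexCer↔Hex2Cer), every X↔lyso-X pair,
DG↔TG/MG, all three chain reactions, and a fatty-acid pool of common
mammalian acyls (even chains C12–C24 with up to six double bonds where
biologically common, plus odd chains 15:0, 17:0, 17:1, 19:0). The
default reaction graph and pool are a documented, plausible choice, not
an authority: `extends: default` in a user file adds or replaces
classes, reactions, pool entries and enabled chain reactions, and
validation reports *every* violation (unknown classes, category/chain-
count inconsistencies, duplicate pairs, an empty pool alongside
addition reactions) rather than failing on the first.

## Statistics

All statistics assume the input table is already preprocessed
(normalization, transformation); values are treated as log-scale, so
the fold change is the difference of group means.

- **Tests.** Welch's t-test by default; the rank test is Mann–Whitney
  for independent groups because typical designs (case/control, age
  groups) are unpaired, with the Wilcoxon signed-rank test behind a
  `paired` flag for genuinely paired designs. Two-sided throughout.
  Zero-variance lipids under the t-test are flagged missing and
  excluded from the multiple-testing family.
- **FDR.** Benjamini–Hochberg, applied per analysis family: once
  across lipids per comparison, and once across the network's edges per
  group's correlations. Significance everywhere is the strict
  inequality FDR < α (default α = 0.05); FDR = α is not significant.
- **Correlations.** Pearson by default (Spearman switchable), pairwise-
  complete observations, p-values from the t distribution with n−2
  degrees of freedom; pairs with fewer than three complete observations
  or a constant lipid are flagged missing.
- **Partial correlations.** Lipid count usually exceeds sample count,
  so the sample covariance is singular; it is shrunk (Ledoit–Wolf)
  before inversion and the partial correlation taken from the scaled
  negative precision matrix, clipped to [−1, 1]. Significance uses
  Fisher's z with effective degrees of freedom n − 2 − (k − 2), floored
  at 3. Both the shrinkage and the df correction make these p-values
  approximate; every output carries an `approximate` flag, and the
  values should be read as a screen, not as calibrated inference.
- **Edge-change categories.** With sig_i := FDR_i < α, the five
  categories are: both insignificant; became significant; lost
  significance; both significant with the same sign; both significant
  with opposite signs. They are exhaustive and mutually exclusive over
  the 2×2×2 grid of (sig₁, sig₂, sign agreement) because the sign of an
  insignificant correlation is treated as noise — a sign flip with one
  side insignificant falls into the turned categories, not SIGN_CHANGE.
  Swapping the groups exchanges the two turned categories and fixes the
  rest.
- **Centralities.** Unweighted exact Brandes betweenness, normalized by
  (n−1)(n−2)/2, and Wasserman–Faust component-scaled closeness, so
  values are comparable across the disconnected components lipid
  networks typically have. Isolated nodes score zero in both.

## Synthetic data

The generator stands in for real studies in all tests. It emulates:
unique shorthand names across sum and molecular levels drawn from the
default classes and pool (guaranteeing at least one edge of every
reaction type); per-group multivariate Gaussian abundances on a
log2-like scale (baseline 15, SD 1) with planted correlation blocks
(imposed via the Cholesky factor of the target correlation matrix,
blocks disjoint by construction) and planted mean shifts in units of
the noise SD. Default conditions: two groups of 50 samples, ~60
lipids, shift 2 SD, block correlation 0.8.

It does **not** emulate: intensity-dependent or non-Gaussian
mass-spectrometry noise, non-MCAR missingness, batch effects,
compositional closure, or realistic class-abundance structure. Passing
tests therefore demonstrate correctness of the matching calculus and
the statistical machinery under clean assumptions — not robustness to
real-data pathologies, which remain the user's responsibility via
preprocessing.

Problem sizes used by the test suite and the acceptance script —
200 random lipidomes of up to 100 species for the matcher/oracle
comparison, 500 lipids at n = 20 + 20 for null calibration, an 8-lipid
block and five 2-SD shifts at n = 50 + 50 for recovery — were chosen as
the smallest sizes at which the binomial confidence intervals and power
calculations are meaningful.

## Numerical and design notes

- Correlation t statistics clip |r| at 1 − 10⁻⁷ to avoid division by
  zero at perfect correlation; BH adjustment excludes missing p-values
  from the family size.
- `build_network` is deterministic and input-order invariant; duplicate
  canonical names are rejected (the same species cannot be two nodes).
- GraphML/JSON exports carry only scalar attributes (enzyme lists are
  `;`-joined); reading back reproduces node/edge sets and attributes,
  floats to full precision. The node-link JSON carries a
  `schema_version`.
- The 46-class color scheme encodes family by hue and derives lyso
  (+0.18 lightness) and ether (−0.13) variants from their parent class,
  which makes the brighter/darker orderings hold by construction; the
  identities of the 46 classes and the exact hues are this package's
  own palette.
- The HTML export is a static SVG rendering (spring layout computed at
  export time, seeded) with the node-link JSON embedded; it trades the
  interactivity of a browser-side physics simulation for a dependency-
  free, fully self-contained file.

## Known limitations

- The matching calculus cannot represent many-to-many reactions, by
  construction.
- Correlation edges (full or partial) can be induced by unmeasured
  reaction partners or indirect effects; low lipidome coverage removes
  real connections. Both argue for cautious interpretation of
  individual edges.
- Partial-correlation significance is approximate (see above).
- The default rule set and fatty-acid pool are plausible for mammalian
  tissue but are not a curated authority; organism-specific analyses
  should supply their own rule file.
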
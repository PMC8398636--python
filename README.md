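# linexnet

Dataset-specific **lipid species metabolic networks** with differential
statistics overlaid — for lipidomics researchers who want to interpret
hundreds of quantified lipid species as a connected metabolic system
rather than as an unordered list of fold changes.

Reaction databases describe lipid metabolism at the *class* level
(PC ↔ PE, Cer ↔ SM, …), while experiments quantify individual *species*
(PC(16:0_18:1), TG(58:10), …). `linexnet` bridges the gap with a
rule-based matching calculus: two measured species are connected by an
edge when a biochemical reaction can transform one into the other,

- **headgroup modification** — classes with equal chain counts listed
  as interconvertible, and identical acyl composition
  (PC(18:0_18:1) ↔ PE(18:0_18:1));
- **acyl addition/removal** — classes whose chain counts differ by one
  (PC ↔ LPC, DG ↔ TG), where the larger species contains every chain of
  the smaller and the extra chain comes from an allowed fatty-acid pool;
- **chain reactions within a class** — elongation (Δ2 carbons),
  desaturation (Δ1 double bond) or oxidation (Δ1 hydroxyl) of exactly
  one chain (TG(58:9) ↔ TG(58:10)).

Mixed annotation levels (sum composition, molecular species,
sn-specific) are supported; species at different resolutions are
compared on their sum compositions. The rules — class registry,
reactions with enzyme annotations, enabled chain reactions, fatty-acid
pool — are data in a shareable YAML file, so tissue- or
organism-specific rule sets replace the shipped mammalian defaults
without touching code.

On top of the network, two-group comparisons are overlaid per node and
per edge:

- log fold changes, Welch's *t* or Mann–Whitney rank tests, all
  *p*-values Benjamini–Hochberg corrected (FDR);
- per-group Pearson/Spearman correlations, or shrinkage-regularized
  partial correlations, with BH-FDR across the network's edges;
- each edge's correlation change classified into five categories:
  stayed insignificant, stayed significant, turned significant, turned
  insignificant, or changed sign (significance = FDR < α, default 0.05);
- degree, betweenness and closeness centrality per node.

## Worked example

```python
import linexnet as lx

rules = lx.default_ruleset()
registry = rules.registry
names = ["PC(18:0_18:1)", "PE(18:0_18:1)", "PS(18:0_18:1)",
         "PC(18:0_18:2)", "LPC(18:0)"]
net = lx.build_network([lx.parse_lipid_name(n, registry) for n in names], rules)
print(net.number_of_nodes(), "nodes,", net.number_of_edges(), "edges")
for u, v, d in sorted(net.edges(data=True)):
    print(f"{u} -- {v}: {d['reaction_type']}"
          + (f" [{d['enzymes']}]" if d["enzymes"] else ""))
```

prints

```
5 nodes, 6 edges
PC(18:0_18:1) -- LPC(18:0): fa_addition_removal [PLA2G4A;LPCAT1]
PC(18:0_18:1) -- PC(18:0_18:2): desaturation
PC(18:0_18:1) -- PE(18:0_18:1): class_conversion [PEMT]
PC(18:0_18:1) -- PS(18:0_18:1): class_conversion [PTDSS1]
PC(18:0_18:2) -- LPC(18:0): fa_addition_removal [PLA2G4A;LPCAT1]
PE(18:0_18:1) -- PS(18:0_18:1): class_conversion [PISD;PTDSS2]
```

The PC/PE/PS species with a shared acyl signature form a headgroup
triangle; the desaturation edge links the two PC species differing by
one double bond; and LPC(18:0) attaches to both PCs because the
missing chain (18:1 or 18:2) is in the default fatty-acid pool.
Enzyme labels in brackets come from the rule file and are carried onto
edges verbatim.

From the shell, the same pipeline end to end on simulated data:

```bash
linexnet simulate --seed 5 --out table.csv,groups.csv
linexnet build --input table.csv --groups groups.csv \
    --compare A:B --out results/
```

which reports `network: 55 nodes, 32 edges -> results/` and writes
`network.graphml`, `network.json`, `nodes.csv`, `edges.csv` (one row
per node/edge with every statistic), a self-contained `network.html`
view, and `run.log`. Node attributes include
`log_fold_change_A_vs_B` / `fdr_A_vs_B` and centralities; edge
attributes include per-group `r` / `fdr` and `change_A_vs_B`.

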
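# orevo

Olfactory-receptor (OR) gene repertoire evolution: mine intact genes,
pseudogenes and truncated genes from genome assemblies, group them into
orthologous gene groups (OGGs), reconstruct ancestral gene content on a
dated species tree, and estimate per-branch gene gain and loss rates with
a closed-form birth–death model.

## Who this is for

Comparative genomicists studying multigene-family turnover — the OR
family in particular, where repertoires range from a dozen genes in
cetaceans to nearly two thousand in elephants, driven by lineage-specific
duplication and pseudogenization. The package is equally a test bed: a
ground-truthed synthetic-genome generator exercises every stage end to
end, so the whole pipeline can be validated without downloading genomes.

## The model

On a branch of duration *T* million years (MY) starting from *A₀* genes,
gains and losses accrue in proportion to the current gene count with
per-gene per-MY rates β (gain) and δ (loss):

```
dg/dt = (A₀ + g(t) − l(t)) β
dl/dt = (A₀ + g(t) − l(t)) δ
```

With *G* = g(T) and *L* = l(T), the pair inverts in closed form:

```
β = G / ((G − L) T) · ln(1 + (G − L)/A₀)
δ = L / ((G − L) T) · ln(1 + (G − L)/A₀)
```

and β = G/(A₀T), δ = L/(A₀T) in the G = L limit. Per-branch *A₀*, *G*,
*L* come from an ancestral reconstruction of OGG copy numbers: presence
by Dollo parsimony (a group arises once, may be lost repeatedly), counts
by unit-cost Sankoff parsimony.

Upstream of the model sit the classic OR-mining filters (translated
search at E ≤ 1e-10, highest-scoring regions, ORF extension to ATG..stop,
≥ 250 aa, ≤ 5 aa alignment gap per transmembrane helix, 21–34 aa
N-terminus, phylogenetic confirmation against non-OR GPCR outgroups, and
a second pass at E ≤ 1e-20 that labels disrupted copies pseudogenes and
disruption-free copies ending < 30 bp from a contig end truncated) and
the classification stage (Markov clustering of intact proteins into
OGGs, bootstrap-supported singleton merging, Class I/II assignment by
anchor references, best-hit attachment of non-intact genes).

## Worked example

Simulate OR family evolution on the built-in 23-taxon dated mammal tree
(11 marine species with elevated loss δ = 0.017, terrestrial β = δ =
0.003, 830 ancestral OGGs), then fit the gain/loss model to the tip
contents:

```python
import pandas as pd
from orevo import GeneContentModel
from orevo.simulate import (SimConfig, default_tree, marine_contrast_rates,
                            simulate_family_evolution, HABITAT)

tree = default_tree()
cfg = SimConfig(tree=tree, ancestral_family_count=830,
                per_branch_rates=marine_contrast_rates(tree, (0.003, 0.003), 0.017),
                seed=1)
content, _ = simulate_family_evolution(cfg)
tips = pd.DataFrame({sp: content[sp] for sp in tree.taxa}).T
res = GeneContentModel(tips, tree).fit()
groups = {sp: h for sp, h in HABITAT.items() if h in ("marine", "terrestrial")}
print(res.group_means(groups).round(5).to_string())
```

prints

```
              n  beta_mean  delta_mean flag
group
all          23    0.00364     0.00533
marine       11    0.00420     0.00957
terrestrial  11    0.00314     0.00157
```

The fitted contrast recovers the simulated regime: marine terminal
branches show a ~6× higher mean loss rate than terrestrial ones (0.00957
vs 0.00157 genes per gene per MY; parsimony reconstruction compresses
both toward zero, which is why the terrestrial estimate sits below the
simulated 0.003 — see `docs/methods.md`). Per-species estimates are in
`res.terminal_rates()`, the full per-branch table in `res.summary()`.

The same run end to end from a shell, with genomes, mining and
classification included:

```bash
orevo run --config my_run.yaml --out-dir run1
```

writes one folder per stage (`simulate/`, `mine/`, `classify/`,
`gainloss/`, `stats/`) plus a checksummed `manifest.json`; each stage is
also available as its own subcommand (`orevo mine --genome sp.fa ...`).

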
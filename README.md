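# seepcomm

Community-assembly inference for cold-seep sediment microbiomes — and for
any taxa × samples count table with a phylogeny and per-sample
environmental metadata.

Amplicon surveys of methane-seep sediments typically ask three questions:
how diverse are the communities and how do they differ between sites and
depth layers; which ecological processes — selection, dispersal, drift —
assemble them; and which environmental factors and co-occurrence patterns
structure them. `seepcomm` implements that full chain as a tested Python
library with a CLI, exercised end-to-end on a synthetic community
generator with planted ground truth, so every statistic can be checked
against what was actually simulated.

## What it computes

- **α-diversity**: observed ASVs, Shannon (natural log), ACE, Good's
  coverage, rooted Faith PD; least-significant-difference letters per
  group (compact letter display).
- **β-diversity**: Bray–Curtis, PCoA, one-way PERMANOVA, shared/unique
  ASV counts by grouping.
- **Null-model assembly inference** — the core. Within-sample NTI and
  between-sample βNTI standardize (mean) nearest-taxon distances against
  a taxa-shuffle null:

      βMNTD(j,k) = ½ [ Σ_i w_ij min_{m∈k} d(i,m) + Σ_m w_mk min_{i∈j} d(m,i) ],
      βNTI = (βMNTD_obs − mean βMNTD_null) / sd βMNTD_null,

  and RC-bray ranks observed Bray–Curtis against a richness- and
  abundance-preserving null, rescaled to [−1, 1]. Each sample pair is then
  classified: βNTI > 2 heterogeneous selection, βNTI < −2 homogeneous
  selection, else RC > 0.95 dispersal limitation, RC < −0.95 homogenizing
  dispersal, else undominated — with per-site process fractions.
- **Drivers**: per-variable Mantel tests (Spearman) and random-forest
  out-of-bag mean-decrease-accuracy importance with label-permutation
  significance.
- **Networks**: Spearman + Benjamini–Hochberg co-occurrence graphs over
  abundant ASVs (mean relative abundance > 0.005) and the four standard
  topology metrics (average degree, clustering, path length, modularity).
- **Synthetic benchmark**: 4 sites × 7 depth layers sampled from a
  ladderized 200-taxon pool under selection / neutral / dispersal-limited
  regimes, with a planted CH4 gradient. See `docs/methods.md`.

## Worked example

```bash
seepcomm --seed 7 --out-dir demo simulate          # feature_table.tsv, tree.nwk, metadata.tsv
seepcomm --seed 7 --out-dir demo assembly demo/feature_table.tsv \
    --tree demo/tree.nwk --metadata demo/metadata.tsv
```

or, through the library (as in `analysis/04_assembly_processes.py`):

```python
from seepcomm import (SimulationConfig, NullModelConfig, simulate_dataset,
                      rarefy, assembly_analysis)

table, metadata, tree, truth = simulate_dataset(SimulationConfig(seed=20240901))
rare = rarefy(table, seed=20240902)
res = assembly_analysis(rare, tree, metadata, NullModelConfig(n_null=999, seed=20240904))
print(res["pairs"]["process"].value_counts(normalize=True))
```

On the default (selection-regime) benchmark this prints, per the
`analysis/` drivers:

```
         selection: modal process = homogeneous_selection (91.7% of 84 within-site pairs)
           neutral: modal process = undominated (58.3% of 84 within-site pairs)
 dispersal_limited: modal process = dispersal_limitation (91.7% of 84 within-site pairs)
```

i.e. the null models read back the planted regimes: depth-layer pairs of a
site under strong niche selection turn over among close relatives (βNTI
< −2, homogeneous selection); mass-effects communities show only chance
turnover; independently perturbed local pools show excess taxonomic
turnover (RC > 0.95). The matching driver analysis singles out the planted
gradient —

```
top driver by mean decrease in accuracy: CH4 (14.6%, p = 0.010); Mantel r = 0.73
```

— and the whole-survey co-occurrence network separates the four site
guilds (modularity 0.71).

The numbered scripts under `analysis/` run the complete study on the
synthetic benchmark (simulate → α → β/ordination → assembly → drivers →
networks) and write their tables under `results/`.

## Layout

```
src/seepcomm/     library (tables, trees, synth, diversity, beta, assembly,
                  drivers, network, pipeline, CLI)
analysis/         numbered narrative drivers over the library
tests/            pytest suite, including end-to-end property checks
scripts/          acceptance.py
docs/methods.md   models, conventions, generator design, limitations
```
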
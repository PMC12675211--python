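#!/usr/bin/env python
"""Community assembly inference: NTI, betaNTI, RC-bray and the
five-process classification of within-site pairs for every planted regime.

The point of this analysis: the null models should read back the regime the
generator planted — homogeneous selection where the niche filter acted,
stochastic processes under mass effects, dispersal limitation where local
pools were independently perturbed.

Reads results/data/<regime>; writes per-regime fraction tables and a
combined summary under results/.
"""

from pathlib import Path

import pandas as pd

from seepcomm import (
    NullModelConfig,
    assembly_analysis,
    nti,
    read_feature_table,
    read_metadata,
    read_tree,
)

OUT = Path("results")
SEED = 20240904

summary = []
for regime in ("selection", "neutral", "dispersal_limited"):
    data = Path("results/data") / regime
    table = read_feature_table(data / "feature_table.rarefied.tsv")
    tree = read_tree(data / "tree.nwk")
    metadata = read_metadata(data / "metadata.tsv")
    cfg = NullModelConfig(n_null=999, seed=SEED)
    res = assembly_analysis(table, tree, metadata, cfg)
    res["fractions"].to_csv(OUT / f"process_fractions.{regime}.tsv", sep="\t", index=False)
    res["pairs"].to_csv(OUT / f"pair_classification.{regime}.tsv", sep="\t", index=False)
    nti(table, tree, cfg).to_csv(OUT / f"nti.{regime}.tsv", sep="\t", header=["nti"])
    pooled = res["pairs"]["process"].value_counts(normalize=True)
    summary.append({"regime": regime, **{p: round(100 * f, 1) for p, f in pooled.items()}})
    print(f"{regime:>18}: modal process = {pooled.idxmax()} "
          f"({100 * pooled.max():.1f}% of {len(res['pairs'])} within-site pairs)")

pd.DataFrame(summary).fillna(0.0).to_csv(
    OUT / "assembly_summary.tsv", sep="\t", index=False
)
print("\npooled within-site process percentages written to assembly_summary.tsv")
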
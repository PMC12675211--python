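"""End-to-end pipeline: simulate -> rarefy -> diversity -> beta ->
assembly -> drivers -> networks, with every artifact written as TSV/JSON
and a manifest recording parameters and seeds.

Every stage draws its seed deterministically from the run seed, so two runs
with the same seed produce byte-identical outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assembly import NullModelConfig, assembly_analysis, nti
from .beta import bray_curtis, pcoa, permanova, shared_asv_counts
from .diversity import alpha_table, lsd_letters
from .drivers import mantel_tests, rf_importance
from .network import build_network, filter_abundant, topology
from .synth import GEOCHEM_VARS, SimulationConfig, simulate_dataset
from .table import rarefy, write_feature_table

__all__ = ["run_all", "derive_seed"]


def derive_seed(seed: int, label: str) -> int:
    """Stable per-stage seed below 2**31, derived from the run seed.

    Uses CRC32 of the label (not Python's randomized str hash) so the
    derivation is identical across processes.
    """
    ss = np.random.SeedSequence([seed, zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _stage_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_all(
    seed: int,
    out_dir,
    sim_config: SimulationConfig | None = None,
    null_config: NullModelConfig | None = None,
    rf_trees: int = 500,
    rf_nperm: int = 99,
    nperm: int = 999,
    rho_min: float = 0.6,
    p_max: float = 0.05,
) -> dict:
    """Run every stage on synthetic data and write results under ``out_dir``.

    Returns a dict of the in-memory results for programmatic use.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_config = sim_config or SimulationConfig(seed=_stage_seed(seed, 0))
    null_config = null_config or NullModelConfig(seed=_stage_seed(seed, 1))

    # --- simulate
    table, metadata, tree, truth = simulate_dataset(sim_config)
    write_feature_table(table, out / "feature_table.tsv")
    metadata.to_csv(out / "metadata.tsv", sep="\t")
    tree.write(str(out / "tree.nwk"))
    _write_json(out / "ground_truth.json", truth.to_dict())

    # --- rarefy (depth = min sample total; simulated samples are equal-depth)
    rare = rarefy(table, seed=_stage_seed(seed, 2))
    write_feature_table(rare, out / "feature_table.rarefied.tsv")

    # --- alpha diversity + LSD letters per index, grouped by site
    alpha = alpha_table(rare, tree)
    alpha.to_csv(out / "alpha_table.tsv", sep="\t")
    site_of = metadata.loc[alpha.index, "site"]
    letters = pd.DataFrame(
        {
            idx: lsd_letters(alpha[idx].to_numpy(), site_of.to_numpy())
            for idx in alpha.columns
        }
    )
    letters.to_csv(out / "alpha_letters.tsv", sep="\t")

    # --- beta diversity
    dm = bray_curtis(rare)
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        out / "bray_curtis.tsv", sep="\t"
    )
    ordination = pcoa(dm)
    coords = ordination.samples.iloc[:, :4]
    coords.to_csv(out / "pcoa_coords.tsv", sep="\t")
    f_stat, p_val = permanova(dm, site_of, nperm=nperm, seed=_stage_seed(seed, 3))
    _write_json(
        out / "permanova.json",
        {
            "pseudo_F": f_stat,
            "p_value": p_val,
            "nperm": nperm,
            "prop_explained_axis1": float(ordination.proportion_explained.iloc[0]),
            "prop_explained_axis2": float(ordination.proportion_explained.iloc[1]),
        },
    )
    shared = shared_asv_counts(rare, site_of)
    shared.to_csv(out / "shared_asvs.tsv", sep="\t", header=["count"])

    # --- assembly
    res = assembly_analysis(rare, tree, metadata, null_config)
    res["bnti"].to_csv(out / "bnti_matrix.tsv", sep="\t")
    res["rc_bray"].to_csv(out / "rc_matrix.tsv", sep="\t")
    res["pairs"].to_csv(out / "pair_classification.tsv", sep="\t", index=False)
    res["fractions"].to_csv(out / "process_fractions.tsv", sep="\t", index=False)
    nti_series = nti(rare, tree, null_config)
    nti_series.to_csv(out / "nti.tsv", sep="\t", header=["nti"])

    # --- drivers
    mantel_df = mantel_tests(
        dm, metadata, GEOCHEM_VARS, nperm=nperm, seed=_stage_seed(seed, 4)
    )
    rf_df = rf_importance(
        metadata,
        GEOCHEM_VARS,
        n_trees=rf_trees,
        nperm=rf_nperm,
        seed=_stage_seed(seed, 5),
    )
    driver_report = mantel_df.join(rf_df)
    driver_report.to_csv(out / "driver_report.tsv", sep="\t")

    # --- per-site networks
    topo_rows = {}
    for site in sorted(site_of.unique()):
        ids = [s for s in rare.sample_ids if site_of[s] == site]
        site_table = rare.select_samples(ids).drop_empty_taxa()
        abundant = filter_abundant(site_table)
        graph = build_network(abundant, rho_min=rho_min, p_max=p_max)
        topo_rows[site] = topology(graph).to_dict()
        edges = pd.DataFrame(
            [
                {"node1": a, "node2": b, **attrs}
                for a, b, attrs in sorted(graph.edges(data=True))
            ]
        )
        edges.to_csv(out / f"network_edges.{site}.tsv", sep="\t", index=False)
    topo_df = pd.DataFrame.from_dict(topo_rows, orient="index").rename_axis("site")
    topo_df.to_csv(out / "network_topology.tsv", sep="\t")

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "simulation": {**asdict(sim_config), "regimes": list(sim_config.site_regimes())},
        "null_model": asdict(null_config),
        "nperm": nperm,
        "rf_trees": rf_trees,
        "rf_nperm": rf_nperm,
        "network": {"rho_min": rho_min, "p_max": p_max},
    }
    _write_json(out / "manifest.json", manifest)
    return {
        "table": table,
        "rarefied": rare,
        "metadata": metadata,
        "tree": tree,
        "truth": truth,
        "alpha": alpha,
        "letters": letters,
        "distance": dm,
        "ordination": ordination,
        "permanova": (f_stat, p_val),
        "assembly": res,
        "nti": nti_series,
        "drivers": driver_report,
        "topology": topo_df,
    }
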
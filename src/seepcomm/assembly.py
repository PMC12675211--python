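"""Phylogenetic and taxonomic null models for community assembly inference.

The chain implemented here is the standard nearest-taxon framework:

* MNTD / NTI — within-sample mean nearest-taxon distance and its negated
  z-score against a taxa-shuffle null (positive NTI = phylogenetic
  clustering).
* betaMNTD / betaNTI — between-sample nearest-taxon turnover
  (``comdistnt``-style, conspecifics included so identical samples score 0)
  and its z-score under the same null.
* RC-bray — Raup-Crick rescaled Bray-Curtis under a null that preserves
  each sample's richness and total abundance, drawing species by occupancy
  and individuals by metacommunity relative abundance.
* A five-way classification of each sample pair: |betaNTI| > 2 signals
  deterministic assembly (heterogeneous selection above +2, homogeneous
  selection below -2); otherwise RC-bray > 0.95 is dispersal limitation,
  RC-bray < -0.95 homogenizing dispersal, and anything else undominated.

The taxa-shuffle null permutes tip labels on the patristic distance matrix,
which is equivalent to shuffling rows/columns of the distance matrix while
holding the community matrix fixed. All nulls are seeded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .table import CommunityTable
from .tree import patristic_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "NullModelConfig",
    "PROCESSES",
    "mntd",
    "nti",
    "bmntd",
    "bnti",
    "raup_crick_bray",
    "classify_assembly",
    "classify_pairs",
    "process_fractions",
    "assembly_analysis",
]

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)


@dataclass
class NullModelConfig:
    """Null-model settings shared by NTI, betaNTI and RC-bray.

    ``abundance_weighted`` defaults to False, matching the presence-based
    default of the ``comdistnt``/``ses.mntd`` tools this chain mirrors;
    set True for relative-abundance weighting.
    """

    n_null: int = 999
    abundance_weighted: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_null < 99:
            raise ValueError("n_null must be >= 99")


# ---------------------------------------------------------------------------
# MNTD / NTI

def _freqs(counts: np.ndarray, weighted: bool) -> np.ndarray:
    """Per-sample weights: relative abundance, or uniform over present taxa."""
    counts = np.asarray(counts, dtype=float)
    if weighted:
        return counts / counts.sum(axis=0, keepdims=True)
    pres = (counts > 0).astype(float)
    return pres / pres.sum(axis=0, keepdims=True)


def mntd(counts, dist: np.ndarray, abundance_weighted: bool = False) -> float:
    """Mean nearest-taxon distance within one sample.

    ``dist`` is the patristic matrix over the same taxon ordering as
    ``counts``. Each present taxon contributes its distance to the nearest
    *other* present taxon, weighted by relative abundance (or uniformly).
    """
    counts = np.asarray(counts, dtype=float)
    present = np.flatnonzero(counts > 0)
    if len(present) < 2:
        raise ValueError("MNTD needs at least 2 present taxa")
    sub = dist[np.ix_(present, present)].copy()
    np.fill_diagonal(sub, np.inf)
    nearest = sub.min(axis=1)
    if abundance_weighted:
        w = counts[present] / counts[present].sum()
    else:
        w = np.full(len(present), 1.0 / len(present))
    return float(nearest @ w)


def nti(table: CommunityTable, tree, config: NullModelConfig | None = None) -> pd.Series:
    """Nearest-taxon index per sample: -(MNTD_obs - mean_null) / sd_null.

    Nulls shuffle taxa labels across the patristic matrix. A degenerate
    null (sd 0, e.g. a perfect star tree) yields NaN with a warning.
    """
    config = config or NullModelConfig()
    dist, order = patristic_matrix(tree, table.taxon_ids)
    counts = table.data.loc[order].to_numpy(dtype=float)
    rng = np.random.default_rng(config.seed)
    n_taxa, n_samples = counts.shape
    obs = np.array(
        [mntd(counts[:, j], dist, config.abundance_weighted) for j in range(n_samples)]
    )
    nulls = np.empty((config.n_null, n_samples))
    for b in range(config.n_null):
        perm = rng.permutation(n_taxa)
        dperm = dist[np.ix_(perm, perm)]
        nulls[b] = [mntd(counts[:, j], dperm, config.abundance_weighted) for j in range(n_samples)]
    mean, sd = nulls.mean(axis=0), nulls.std(axis=0, ddof=1)
    out = np.full(n_samples, np.nan)
    ok = sd > 0
    out[ok] = -(obs[ok] - mean[ok]) / sd[ok]
    if (~ok).any():
        bad = [s for s, good in zip(table.sample_ids, ok) if not good]
        logger.warning("NTI undefined (zero null sd) for samples: %s", bad)
    return pd.Series(out, index=table.sample_ids, name="nti")


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI

def _nearest_to_samples(dist: np.ndarray, presence: np.ndarray) -> np.ndarray:
    """M[i, s] = min over taxa m present in sample s of dist[i, m]."""
    n_taxa, n_samples = presence.shape
    M = np.empty((n_taxa, n_samples))
    for s in range(n_samples):
        idx = np.flatnonzero(presence[:, s])
        M[:, s] = dist[:, idx].min(axis=1)
    return M


def _bmntd_matrix(freqs: np.ndarray, presence: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """All-pairs betaMNTD from weights, presence and a distance matrix.

    betaMNTD(j,k) = 0.5 * (sum_i f_ij * min_{m in k} d_im
                           + sum_m f_mk * min_{i in j} d_mi).
    Conspecifics count (a taxon shared by both samples contributes 0), so
    identical samples give exactly 0.
    """
    M = _nearest_to_samples(dist, presence)  # taxa x samples
    G = freqs.T @ M  # G[j, k] = sum_i f_ij * M[i, k]
    return 0.5 * (G + G.T)


def bmntd(
    table: CommunityTable,
    tree,
    abundance_weighted: bool = False,
) -> DistanceMatrix:
    """Between-sample mean nearest-taxon distance for every sample pair."""
    dist, order = patristic_matrix(tree, table.taxon_ids)
    counts = table.data.loc[order].to_numpy(dtype=float)
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("all-zero sample")
    if ((counts > 0).sum(axis=0) < 2).any():
        raise ValueError("every sample needs at least 2 present taxa")
    freqs = _freqs(counts, abundance_weighted)
    presence = counts > 0
    mat = _bmntd_matrix(freqs, presence, dist)
    np.fill_diagonal(mat, 0.0)
    return DistanceMatrix(mat, ids=table.sample_ids)


def bnti(
    table: CommunityTable,
    tree,
    config: NullModelConfig | None = None,
) -> pd.DataFrame:
    """betaNTI z-scores for every sample pair (symmetric frame, NaN diagonal).

    Per null replicate one tip-label permutation is applied to the whole
    distance matrix, i.e. identically to both samples of every pair. Pairs
    whose null sd is 0 come back NaN with a warning.
    """
    config = config or NullModelConfig()
    dist, order = patristic_matrix(tree, table.taxon_ids)
    counts = table.data.loc[order].to_numpy(dtype=float)
    if ((counts > 0).sum(axis=0) < 2).any():
        raise ValueError("every sample needs at least 2 present taxa")
    freqs = _freqs(counts, config.abundance_weighted)
    presence = counts > 0
    n_taxa, n_samples = counts.shape
    obs = _bmntd_matrix(freqs, presence, dist)

    rng = np.random.default_rng(config.seed)
    mean = np.zeros_like(obs)
    m2 = np.zeros_like(obs)
    for b in range(config.n_null):
        perm = rng.permutation(n_taxa)
        dperm = dist[np.ix_(perm, perm)]
        null = _bmntd_matrix(freqs, presence, dperm)
        delta = null - mean
        mean += delta / (b + 1)
        m2 += delta * (null - mean)
    sd = np.sqrt(m2 / (config.n_null - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs - mean) / sd
    z[sd == 0] = np.nan
    np.fill_diagonal(z, np.nan)
    iu = np.triu_indices(n_samples, 1)
    n_bad = int(np.isnan(z[iu]).sum())
    if n_bad:
        logger.warning("betaNTI undefined (zero null sd) for %d pair(s)", n_bad)
    return pd.DataFrame(z, index=table.sample_ids, columns=table.sample_ids)


# ---------------------------------------------------------------------------
# Raup-Crick (Bray-Curtis)

def _null_sample(rng, richness, total, occ_prob, ab_prob, n_taxa):
    """One richness- and abundance-preserving null community.

    Species enter without replacement with probability proportional to
    occupancy; the remaining individuals are distributed over the chosen
    species with probability proportional to metacommunity relative
    abundance.
    """
    chosen = rng.choice(n_taxa, size=richness, replace=False, p=occ_prob)
    vec = np.zeros(n_taxa, dtype=np.int64)
    vec[chosen] = 1
    remaining = total - richness
    if remaining > 0:
        p = ab_prob[chosen]
        vec[chosen] += rng.multinomial(remaining, p / p.sum())
    return vec


def _bray(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.abs(x - y).sum() / (x + y).sum())


def raup_crick_bray(
    table: CommunityTable,
    n_null: int = 999,
    seed: int = 0,
    pairs=None,
) -> pd.DataFrame:
    """Raup-Crick Bray-Curtis in [-1, 1] for every (or the given) sample pair.

    For each pair, ``n_null`` pairs of null communities are assembled
    (richness by occupancy-weighted draws, abundance by metacommunity-
    weighted fills) and the observed Bray-Curtis is ranked among the null
    ones: ``RC = 2 * ((#below + 0.5 * #ties) / n_null - 0.5)``. Operates on
    integer counts; rarefy first so sample totals are comparable.
    """
    counts = table.counts
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("RC-bray requires integer counts")
    counts = np.round(counts).astype(np.int64)
    n_taxa, n_samples = counts.shape
    occupancy = (counts > 0).sum(axis=1).astype(float)
    meta_ab = counts.sum(axis=1).astype(float)
    pool = occupancy > 0
    occ_prob = np.where(pool, occupancy, 0.0)
    occ_prob = occ_prob / occ_prob.sum()
    ab_prob = meta_ab / meta_ab.sum()

    richness = (counts > 0).sum(axis=0)
    totals = counts.sum(axis=0)
    if (richness > int(pool.sum())).any():
        raise ValueError("sample richness exceeds metacommunity richness")

    if pairs is None:
        pairs = list(combinations(range(n_samples), 2))
    else:
        name_to_idx = {s: i for i, s in enumerate(table.sample_ids)}
        pairs = [(name_to_idx[a], name_to_idx[b]) for a, b in pairs]

    rng = np.random.default_rng(seed)
    out = np.full((n_samples, n_samples), np.nan)
    np.fill_diagonal(out, np.nan)
    for j, k in pairs:
        obs = _bray(counts[:, j], counts[:, k])
        below = ties = 0
        for _ in range(n_null):
            nj = _null_sample(rng, int(richness[j]), int(totals[j]), occ_prob, ab_prob, n_taxa)
            nk = _null_sample(rng, int(richness[k]), int(totals[k]), occ_prob, ab_prob, n_taxa)
            bc = _bray(nj, nk)
            if bc < obs:
                below += 1
            elif bc == obs:
                ties += 1
        rc = ((below + 0.5 * ties) / n_null - 0.5) * 2.0
        out[j, k] = out[k, j] = rc
    return pd.DataFrame(out, index=table.sample_ids, columns=table.sample_ids)


# ---------------------------------------------------------------------------
# classification

def classify_assembly(bnti_value: float, rc_value: float) -> str:
    """Five-process label from a (betaNTI, RC-bray) pair.

    Selection takes precedence: betaNTI > 2 heterogeneous, < -2 homogeneous.
    Otherwise RC > 0.95 dispersal limitation, RC < -0.95 homogenizing
    dispersal, else undominated. Inequalities are strict, so boundary
    values fall through to the next rule; NaN inputs return "unclassified".
    """
    if np.isnan(bnti_value) or np.isnan(rc_value):
        return "unclassified"
    if bnti_value > 2:
        return "heterogeneous_selection"
    if bnti_value < -2:
        return "homogeneous_selection"
    if rc_value > 0.95:
        return "dispersal_limitation"
    if rc_value < -0.95:
        return "homogenizing_dispersal"
    return "undominated"


def classify_pairs(bnti_df: pd.DataFrame, rc_df: pd.DataFrame, pairs) -> pd.DataFrame:
    """Long-format per-pair table: bnti, rc_bray, process."""
    rows = []
    for a, b in pairs:
        bz = float(bnti_df.loc[a, b])
        rc = float(rc_df.loc[a, b])
        rows.append(
            {
                "sample_1": a,
                "sample_2": b,
                "bnti": bz,
                "rc_bray": rc,
                "process": classify_assembly(bz, rc),
            }
        )
    return pd.DataFrame(rows)


def process_fractions(pair_table: pd.DataFrame, group_of: pd.Series) -> pd.DataFrame:
    """Per-group fraction of pairs assigned to each process.

    ``group_of`` maps sample id -> group (site). Every pair must lie within
    one group; unclassified pairs are excluded from the denominator and
    reported in ``n_unclassified``.
    """
    rows = []
    for (a, b) in zip(pair_table["sample_1"], pair_table["sample_2"]):
        if group_of[a] != group_of[b]:
            raise ValueError(f"pair ({a}, {b}) spans two groups")
    groups = sorted({group_of[a] for a in pair_table["sample_1"]}, key=str)
    for g in groups:
        mask = pair_table["sample_1"].map(group_of) == g
        sub = pair_table[mask]
        classified = sub[sub["process"] != "unclassified"]
        n = len(classified)
        if n == 0:
            raise ValueError(f"group {g!r} has no classified pairs")
        for proc in PROCESSES:
            rows.append(
                {
                    "group": g,
                    "process": proc,
                    "fraction": float((classified["process"] == proc).mean()),
                    "n_pairs": n,
                    "n_unclassified": int(len(sub) - n),
                }
            )
    return pd.DataFrame(rows)


def assembly_analysis(
    table: CommunityTable,
    tree,
    metadata: pd.DataFrame,
    config: NullModelConfig | None = None,
    group_column: str = "site",
    within_groups: bool = True,
) -> dict:
    """Full assembly inference: betaNTI + RC-bray + classification + fractions.

    By default only within-site pairs (depth layers of one core site) are
    classified — the between-depth succession question — with an option to
    use all pairs.
    """
    config = config or NullModelConfig()
    group_of = metadata.loc[table.sample_ids, group_column]
    bnti_df = bnti(table, tree, config)
    if within_groups:
        pairs = [
            (a, b)
            for a, b in combinations(table.sample_ids, 2)
            if group_of[a] == group_of[b]
        ]
    else:
        pairs = list(combinations(table.sample_ids, 2))
    rc_df = raup_crick_bray(
        table, n_null=config.n_null, seed=config.seed + 1, pairs=pairs
    )
    pair_table = classify_pairs(bnti_df, rc_df, pairs)
    fractions = (
        process_fractions(pair_table, group_of) if within_groups else None
    )
    return {
        "bnti": bnti_df,
        "rc_bray": rc_df,
        "pairs": pair_table,
        "fractions": fractions,
    }
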
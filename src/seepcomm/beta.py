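"""Between-sample structure: Bray-Curtis, PCoA, PERMANOVA, shared ASVs.

Distances travel as scikit-bio ``DistanceMatrix`` objects; ordination as
scikit-bio ``OrdinationResults``. PERMANOVA permutations are explicitly
seeded and p-values carry the +1 correction, so the minimum attainable p is
1/(nperm+1).
"""

from __future__ import annotations


import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as _skbio_permanova
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .table import CommunityTable

__all__ = [
    "bray_curtis",
    "pcoa",
    "permanova",
    "shared_asv_counts",
]


def bray_curtis(table: CommunityTable) -> DistanceMatrix:
    """BC(j, k) = sum_i |x_ij - x_ik| / sum_i (x_ij + x_ik)."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    sums = table.counts.sum(axis=0)
    if (sums == 0).any():
        bad = [s for s, t in zip(table.sample_ids, sums) if t == 0]
        raise ValueError(f"zero-sum sample(s): {bad}")
    condensed = pdist(table.counts.T, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


def pcoa(dm: DistanceMatrix):
    """Classical PCoA (Gower double-centering + eigendecomposition).

    Negative eigenvalues are zeroed and excluded from the variance
    denominator; axes come out ordered by non-increasing eigenvalue. On a
    Euclidean-embeddable matrix the coordinates reproduce the distances.
    """
    if dm.shape[0] < 3:
        raise ValueError("PCoA needs at least 3 samples")
    return _skbio_pcoa(dm, method="eigh", warn_neg_eigval=False)


def permanova(
    dm: DistanceMatrix,
    grouping,
    nperm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """One-way PERMANOVA pseudo-F and permutation p.

    ``p = (1 + #{F_perm >= F_obs}) / (1 + nperm)``, permutations seeded.
    """
    grouping = pd.Series(grouping)
    if grouping.nunique() < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    counts = grouping.value_counts()
    small = counts[counts < 2].index.tolist()
    if small:
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    if nperm < 99:
        raise ValueError("nperm must be >= 99")
    res = _skbio_permanova(dm, grouping.to_numpy(), permutations=nperm, seed=seed)
    return float(res["test statistic"]), float(res["p-value"])


def shared_asv_counts(table: CommunityTable, grouping) -> pd.Series:
    """Core (present in every group) and unique-per-group ASV counts.

    Presence means a pooled within-group count > 0. Returns a Series with
    index ``core``, ``unique:<group>`` ..., plus ``total`` observed ASVs.
    """
    grouping = pd.Series(grouping)
    groups = sorted(grouping.unique(), key=str)
    present: dict[str, set] = {}
    for g in groups:
        ids = grouping.index[grouping == g].tolist()
        if not ids:
            raise ValueError(f"empty group {g!r}")
        pooled = table.data[ids].sum(axis=1)
        present[g] = set(pooled.index[pooled > 0])
    all_present = set().union(*present.values())
    core = set.intersection(*present.values()) if present else set()
    out = {"core": len(core)}
    for g in groups:
        others = set().union(*(present[h] for h in groups if h != g)) if len(groups) > 1 else set()
        out[f"unique:{g}"] = len(present[g] - others)
    out["total"] = len(all_present)
    return pd.Series(out, name="asv_counts")
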
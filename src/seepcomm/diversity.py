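"""Alpha diversity estimators and LSD group comparison letters.

Indices: observed richness, Shannon (natural log), ACE, Faith's rooted
phylogenetic diversity, and Good's coverage — the panel typically reported
for amplicon surveys. Group differences use the least-significant-
difference procedure (one-way ANOVA pooled error, pairwise t tests) and a
compact letter display.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd

from .table import CommunityTable

logger = logging.getLogger(__name__)

__all__ = [
    "shannon",
    "observed_asvs",
    "ace",
    "chao1",
    "goods_coverage",
    "faith_pd",
    "alpha_table",
    "lsd_letters",
]


def _as_counts(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if (c < 0).any():
        raise ValueError("negative counts")
    if c.sum() == 0:
        raise ValueError("all-zero count vector")
    return c


def _as_int_counts(counts) -> np.ndarray:
    c = _as_counts(counts)
    if not np.allclose(c, np.round(c)):
        raise ValueError("integer counts required")
    return np.round(c).astype(np.int64)


def observed_asvs(counts) -> int:
    return int((_as_counts(counts) > 0).sum())


def shannon(counts, base: float = np.e) -> float:
    """H = -sum p_i log p_i over taxa with nonzero abundance."""
    c = _as_counts(counts)
    p = c[c > 0] / c.sum()
    return float(-(p * np.log(p)).sum() / np.log(base))


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness."""
    c = _as_int_counts(counts)
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def ace(counts, rare_threshold: int = 10) -> float:
    """Abundance-based coverage estimator.

    ``S_abund + S_rare / C_ace + (F1 / C_ace) * gamma^2`` with
    ``C_ace = 1 - F1 / N_rare`` and ``gamma^2`` the rare-species coefficient
    of variation floored at 0. When every rare individual is a singleton
    (``C_ace = 0``) the estimator is undefined and Chao1 is returned with a
    warning.
    """
    c = _as_int_counts(counts)
    c = c[c > 0]
    rare = c[c <= rare_threshold]
    s_abund = int((c > rare_threshold).sum())
    s_rare = len(rare)
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        logger.warning("ACE undefined (all rare individuals singletons); using Chao1")
        return chao1(counts)
    freqs = np.bincount(rare)
    i = np.arange(len(freqs))
    sum_term = float((i * (i - 1) * freqs).sum())
    gamma2 = max((s_rare / c_ace) * sum_term / (n_rare * (n_rare - 1.0)) - 1.0, 0.0) \
        if n_rare > 1 else 0.0
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2


def goods_coverage(counts) -> float:
    """1 - F1/N: the chance the next read belongs to an already-seen taxon."""
    c = _as_int_counts(counts)
    f1 = int((c == 1).sum())
    return 1.0 - f1 / c.sum()


def faith_pd(counts, taxon_ids, tree) -> float:
    """Rooted Faith PD: branch length of the minimal subtree spanning the
    root and all present tips."""
    c = _as_counts(counts)
    present = [t for t, x in zip(taxon_ids, c) if x > 0]
    tip_names = {tip.name for tip in tree.tips()}
    missing = [t for t in present if t not in tip_names]
    if missing:
        raise ValueError(f"present taxa missing from tree: {missing}")
    return float(_skbio_faith_pd(c, list(taxon_ids), tree))


def alpha_table(table: CommunityTable, tree=None) -> pd.DataFrame:
    """All alpha indices per sample; ``faith_pd`` column only when a tree
    is supplied."""
    rows = {}
    for sid in table.sample_ids:
        c = table.data[sid].to_numpy()
        row = {
            "observed_asvs": observed_asvs(c),
            "shannon": shannon(c),
            "ace": ace(c),
            "goods_coverage": goods_coverage(c),
        }
        if tree is not None:
            row["faith_pd"] = faith_pd(c, table.taxon_ids, tree)
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")


# ---------------------------------------------------------------------------
# LSD + compact letter display

def _lsd_pairwise_p(values: np.ndarray, groups: np.ndarray):
    """Pairwise p-values from t tests on the ANOVA pooled error."""
    labels = sorted(pd.unique(groups), key=str)
    by_group = {g: values[groups == g] for g in labels}
    for g, v in by_group.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    n_total = len(values)
    k = len(labels)
    df_err = n_total - k
    sse = sum(float(((v - v.mean()) ** 2).sum()) for v in by_group.values())
    mse = sse / df_err
    pvals = {}
    for g1, g2 in combinations(labels, 2):
        v1, v2 = by_group[g1], by_group[g2]
        diff = v1.mean() - v2.mean()
        se = np.sqrt(mse * (1 / len(v1) + 1 / len(v2)))
        if se == 0.0:
            p = 0.0 if diff != 0 else 1.0
        else:
            t = diff / se
            p = 2.0 * stats.t.sf(abs(t), df_err)
        pvals[(g1, g2)] = p
    means = {g: float(v.mean()) for g, v in by_group.items()}
    return labels, means, pvals


def _insert_absorb(order: list, significant) -> dict:
    """Piepho-style insert-and-absorb compact letter display.

    ``order`` lists groups from highest to lowest mean; ``significant`` is
    a predicate on unordered group pairs.
    """
    columns: list[set] = [set(order)]
    for g1, g2 in combinations(order, 2):
        if not significant(g1, g2):
            continue
        for col in [c for c in columns if g1 in c and g2 in c]:
            columns.remove(col)
            columns.extend([col - {g2}, col - {g1}])
        # absorb: drop columns contained in another
        keep = []
        for c in columns:
            if not any(c < other for other in columns if other is not c):
                if c not in keep:
                    keep.append(c)
        columns = keep
    # letter columns ordered by their best (highest-mean) member
    rank = {g: i for i, g in enumerate(order)}
    columns.sort(key=lambda c: min(rank[g] for g in c))
    letters = {g: "" for g in order}
    for i, col in enumerate(columns):
        letter = chr(ord("a") + i)
        for g in order:
            if g in col:
                letters[g] += letter
    return letters


def lsd_letters(values, groups, alpha: float = 0.05) -> pd.Series:
    """Compact letter display from LSD pairwise comparisons.

    Groups sharing a letter are not significantly different at ``alpha``.
    Groups are lettered in decreasing-mean order; exact mean ties break
    lexicographically by label so the display is reproducible.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    labels, means, pvals = _lsd_pairwise_p(values, groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    order = sorted(labels, key=lambda g: (-means[g], str(g)))

    def significant(g1, g2):
        key = (g1, g2) if (g1, g2) in pvals else (g2, g1)
        return pvals[key] < alpha

    letters = _insert_absorb(order, significant)
    return pd.Series({g: letters[g] for g in labels}, name="letters")
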
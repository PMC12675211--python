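"""Environmental driver statistics: per-variable Mantel tests and
random-forest permutation importance.

The Mantel side correlates the community distance matrix with the Euclidean
distance matrix of each geochemical variable (Spearman by default). The
random-forest side classifies samples into sites from the geochemistry and
scores each variable by out-of-bag mean decrease in accuracy, with
significance from whole-forest refits on permuted site labels.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as _skbio_mantel
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

__all__ = ["mantel", "mantel_tests", "rf_importance"]


def mantel(
    dm_x: DistanceMatrix,
    dm_y: DistanceMatrix,
    method: str = "spearman",
    nperm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel correlation over the n(n-1)/2 unordered pairs.

    p-value by jointly permuting rows/columns of one matrix, with the +1
    correction (floor 1/(nperm+1)); permutations seeded.
    """
    if set(dm_x.ids) != set(dm_y.ids):
        raise ValueError("distance matrices cover different samples")
    if nperm < 99:
        raise ValueError("nperm must be >= 99")
    dm_y = dm_y.filter(dm_x.ids)
    r, p, _ = _skbio_mantel(dm_x, dm_y, method=method, permutations=nperm, seed=seed)
    return float(r), float(p)


def mantel_tests(
    dm_community: DistanceMatrix,
    metadata: pd.DataFrame,
    variables,
    method: str = "spearman",
    nperm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Mantel r and p for each geochemical variable against the community.

    Each variable's distance matrix is the Euclidean distance between the
    scalar values. Samples are aligned by id; missing values are an error.
    """
    ids = list(dm_community.ids)
    missing = [s for s in ids if s not in metadata.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    rows = []
    for i, var in enumerate(variables):
        vals = metadata.loc[ids, var].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"missing values in variable {var!r}")
        dm_env = DistanceMatrix(squareform(pdist(vals[:, None])), ids=ids)
        r, p = mantel(dm_community, dm_env, method=method, nperm=nperm, seed=seed + i)
        rows.append({"variable": var, "mantel_r": r, "mantel_p": p})
    return pd.DataFrame(rows).set_index("variable")


def _fit_forest(X, y, n_trees, seed):
    # bagged trees with sqrt-feature splits = Breiman random forest; the
    # bagging wrapper exposes per-estimator bootstrap indices, which the
    # OOB importance below needs
    forest = BaggingClassifier(
        estimator=DecisionTreeClassifier(max_features="sqrt", random_state=0),
        n_estimators=n_trees,
        bootstrap=True,
        random_state=seed,
    )
    forest.fit(X, y)
    return forest


def _oob_mda(forest, X, y, rng) -> np.ndarray:
    """Out-of-bag mean decrease in accuracy per feature (proportion)."""
    n, p = X.shape
    # the bagging wrapper's inner trees predict encoded class indices
    class_index = {c: i for i, c in enumerate(forest.classes_)}
    y_enc = np.array([class_index[v] for v in y])
    drop = np.zeros(p, dtype=float)
    n_trees_used = 0
    for est, in_bag in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), np.unique(in_bag))
        if len(oob) == 0:
            continue
        n_trees_used += 1
        pred = est.predict(X[oob])
        acc = float((pred == y_enc[oob]).mean())
        for j in range(p):
            Xp = X[oob].copy()
            Xp[:, j] = Xp[rng.permutation(len(oob)), j]
            acc_p = float((est.predict(Xp) == y_enc[oob]).mean())
            drop[j] += acc - acc_p
    if n_trees_used == 0:
        raise RuntimeError("no out-of-bag samples; increase sample size")
    return drop / n_trees_used


def rf_importance(
    metadata: pd.DataFrame,
    variables,
    label_column: str = "site",
    n_trees: int = 500,
    nperm: int = 99,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean-decrease-accuracy importance of each variable for site identity.

    Importance is the out-of-bag accuracy drop when the variable is
    permuted, averaged over trees and reported in percent. Significance:
    ``nperm`` whole-forest refits on permuted labels,
    ``p = (1 + #{perm importance >= observed}) / (1 + nperm)``. A variable
    that is constant across samples gets importance 0 and p 1 with a
    warning.
    """
    variables = list(variables)
    y = metadata[label_column].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    X = metadata[variables].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values in features")
    const = [v for v, s in zip(variables, X.std(axis=0)) if s == 0]
    if const:
        logger.warning("constant feature(s), importance forced to 0: %s", const)

    rng = np.random.default_rng(seed)
    forest = _fit_forest(X, y, n_trees, seed)
    obs = _oob_mda(forest, X, y, rng)
    obs[np.isin(variables, const)] = 0.0

    exceed = np.zeros(len(variables), dtype=int)
    for b in range(nperm):
        y_perm = rng.permutation(y)
        f_perm = _fit_forest(X, y_perm, n_trees, seed + 1 + b)
        imp_perm = _oob_mda(f_perm, X, y_perm, rng)
        exceed += imp_perm >= obs
    pvals = (1.0 + exceed) / (1.0 + nperm)
    pvals[np.isin(variables, const)] = 1.0
    return pd.DataFrame(
        {"rf_importance_pct": 100.0 * obs, "rf_p": pvals},
        index=pd.Index(variables, name="variable"),
    )
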
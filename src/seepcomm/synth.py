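"""Synthetic benchmark data with known assembly regimes.

Emulates the sampling design of a cold-seep sediment survey — a handful of
sites, each cored over seven 5-cm depth layers — so that every downstream
stage (diversity, ordination, null-model assembly inference, drivers,
networks) can be exercised against planted ground truth.

The species pool
----------------
:func:`simulate_pool_tree` builds a ladderized radiation: a long backbone
of exponential segments with short pendant tips, the graded divergence
typical of ASV-scale phylogenies. A niche trait evolves along it as a
directional Brownian walk (:func:`evolve_traits` with a trend), so
phylogenetic neighbours have similar niches and the niche axis maps
smoothly onto the tree — the phylogenetic niche conservatism that
nearest-taxon null models assume. :func:`simulate_tree` (pure-birth,
exponential branch lengths) remains available for generic random trees in
oracle and calibration settings.

The sampling model, per sample
------------------------------
``selection``
    Gaussian environmental filtering on the quantile-standardised trait:
    weight ``exp(-s (F(trait) - q)^2)`` around the site's optimum quantile
    ``q``, truncated to 0 below ``niche_floor`` (a fundamental-niche
    boundary). Standardising through the empirical CDF keeps the niche a
    fixed fraction of the pool wherever the optimum sits. Each realised
    community is additionally thinned by a colonization lottery
    (``colonization_phi``) and log-normal abundance drift
    (``drift_sigma``) — local demographic stochasticity within the
    selected guild.

``neutral``
    The mass-effects end member: expected abundance proportional to the
    metacommunity base abundances only; immigration replenishes every
    taxon, so only multinomial read noise differentiates samples. With
    ``selection_strength = 0``, ``colonization_phi = 1`` and
    ``drift_sigma = 0`` the selection regime reduces to this exactly.

``dispersal_limited``
    Each sample draws from an independently perturbed local
    metacommunity: log-normal noise of width ``2 * (1 - dispersal_m)``
    multiplies the base abundances (plus the lottery and drift layers),
    creating excess compositional turnover with no phylogenetic signal.

All randomness flows through one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from skbio import TreeNode

from .table import CommunityTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_tree",
    "simulate_pool_tree",
    "evolve_traits",
    "simulate_communities",
    "simulate_dataset",
    "GEOCHEM_VARS",
]

#: geochemical covariates emitted in the metadata; CH4 carries the planted
#: gradient, the rest are independent nuisance variables (porewater-scale
#: units: mM for majors, uM for CH4 and trace metals, % for TOC/TIC).
GEOCHEM_VARS = ("CH4", "TIC", "TOC", "SO4", "Cl", "Ba", "K", "Ca", "Mg", "Fe", "Cu", "Mn")

_NUISANCE = {
    "TIC": (2.0, 0.3),
    "TOC": (1.0, 0.2),
    "SO4": (20.0, 3.0),
    "Cl": (550.0, 20.0),
    "Ba": (10.0, 2.0),
    "K": (10.0, 1.0),
    "Ca": (10.0, 1.5),
    "Mg": (50.0, 5.0),
    "Fe": (5.0, 1.0),
    "Cu": (0.5, 0.1),
    "Mn": (2.0, 0.4),
}

_REGIMES = ("selection", "neutral", "dispersal_limited")


@dataclass
class SimulationConfig:
    """Knobs of the community generator.

    ``selection_strength`` acts on the quantile-standardised trait, so the
    niche occupies roughly ``2 * sqrt(3 / s)`` of the pool at the 5%
    weight floor — the default 200 keeps about a quarter of the taxa
    available to a site. 0 disables filtering entirely.
    ``colonization_phi`` is the probability that a pool member reaches a
    given sample's local community at all (demographic lottery);
    ``drift_sigma`` the log-normal abundance drift among those that do.
    Both apply to the selection and dispersal-limited regimes; the neutral
    regime is the mass-effects end member with neither. ``dispersal_m`` in
    [0, 1] only matters for the dispersal-limited regime (1 = unlimited
    exchange). ``env_profile`` maps site name to an optimum quantile in
    (0, 1); by default optima sit at evenly spaced interior quantiles.
    """

    n_taxa: int = 200
    n_sites: int = 4
    n_depths_per_site: int = 7
    sequencing_depth: int = 2000
    selection_strength: float = 200.0
    niche_floor: float = 0.05
    trait_sigma: float = 1.0
    niche_trend: float = 3.0
    colonization_phi: float = 0.55
    drift_sigma: float = 1.0
    dispersal_m: float = 1.0
    regimes: str | Sequence[str] = "selection"
    env_profile: Mapping[str, float] | None = None
    env_quantiles: Sequence[float] | None = None
    depth_jitter: float = 0.02
    base_sigma: float = 1.0
    pool_height: float = 1.0
    tip_shrink: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.sequencing_depth < 10:
            raise ValueError("sequencing_depth must be >= 10")
        if not 0.0 <= self.dispersal_m <= 1.0:
            raise ValueError("dispersal_m must be in [0, 1]")
        if not 0.0 < self.colonization_phi <= 1.0:
            raise ValueError("colonization_phi must be in (0, 1]")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be >= 0")
        if self.trait_sigma <= 0:
            raise ValueError("trait_sigma must be > 0")

    def site_regimes(self) -> list[str]:
        regimes = self.regimes
        if isinstance(regimes, str):
            regimes = [regimes] * self.n_sites
        regimes = list(regimes)
        if len(regimes) != self.n_sites:
            raise ValueError("one regime per site required")
        for r in regimes:
            if r not in _REGIMES:
                raise ValueError(f"unknown regime {r!r}; expected one of {_REGIMES}")
        return regimes


@dataclass
class GroundTruth:
    """What the generator actually did — for recovery tests."""

    site_regimes: dict[str, str]
    env_optima: dict[str, float]
    traits: dict[str, float]
    sample_optima: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_tree(n_taxa: int, seed: int = 0) -> TreeNode:
    """Pure-birth topology with iid exponential(1) branch lengths.

    Starting from a two-tip root, a uniformly chosen extant tip is split
    until ``n_taxa`` tips exist. Tips are named ``T0000 ...`` in postorder,
    so the newick string is a deterministic function of the seed.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    tips = []
    for _ in range(2):
        child = TreeNode(length=float(rng.exponential(1.0)))
        root.append(child)
        tips.append(child)
    while len(tips) < n_taxa:
        k = int(rng.integers(len(tips)))
        parent = tips.pop(k)
        for _ in range(2):
            child = TreeNode(length=float(rng.exponential(1.0)))
            parent.append(child)
            tips.append(child)
    for i, tip in enumerate(root.tips()):
        tip.name = f"T{i:04d}"
    return root


def simulate_pool_tree(
    n_taxa: int,
    height: float = 1.0,
    tip_shrink: float = 0.2,
    seed: int = 0,
) -> TreeNode:
    """Ladderized species-pool phylogeny.

    A backbone of exponential segments totalling ``height`` carries one
    short pendant tip per rung (pendant scale ``tip_shrink * height /
    n_taxa``), so nearest-relative distance shrinks smoothly the more
    densely a neighbourhood of the pool is sampled — the graded divergence
    of ASVs within a radiating lineage. Tips are named ``T0000 ...`` along
    the backbone.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    n_segs = max(n_taxa - 2, 1)
    segs = rng.exponential(1.0, size=n_segs)
    segs = segs / segs.sum() * height

    def pendant() -> float:
        return float(height * tip_shrink / n_taxa * rng.uniform(0.5, 1.5))

    root = TreeNode()
    cur = root
    for i in range(n_taxa - 2):
        cur.append(TreeNode(length=pendant()))
        nxt = TreeNode(length=float(segs[i]))
        cur.append(nxt)
        cur = nxt
    cur.append(TreeNode(length=pendant()))
    cur.append(TreeNode(length=pendant()))
    for i, tip in enumerate(root.tips()):
        tip.name = f"T{i:04d}"
    return root


def evolve_traits(
    tree: TreeNode,
    trait_sigma: float = 1.0,
    seed: int = 0,
    trend: float = 0.0,
) -> dict[str, float]:
    """Brownian trait evolution along branches from a root value of 0.

    The increment on a branch of length ``l`` is
    ``N(trend * l, trait_sigma^2 * l)``: with ``trend = 0`` this is plain
    Brownian motion, whose covariance between tips equals ``trait_sigma^2``
    times their shared root-ward path length. A non-zero ``trend`` adds a
    directional component (a niche gradient along the radiation) while
    preserving the Brownian covariance around it.
    """
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        parent_val = values[id(node.parent)]
        length = node.length if node.length is not None else 0.0
        values[id(node)] = (
            parent_val
            + trend * length
            + trait_sigma * np.sqrt(length) * rng.standard_normal()
        )
    return {tip.name: values[id(tip)] for tip in tree.tips()}


def _site_quantiles(n_sites: int, quantiles: Sequence[float] | None) -> np.ndarray:
    if quantiles is None:
        quantiles = np.linspace(0.15, 0.85, n_sites) if n_sites > 1 else [0.5]
    q = np.asarray(quantiles, dtype=float)
    if ((q <= 0) | (q >= 1)).any():
        raise ValueError("site optimum quantiles must lie in (0, 1)")
    return q


def simulate_communities(
    tree: TreeNode,
    traits: Mapping[str, float],
    config: SimulationConfig,
) -> tuple[CommunityTable, pd.DataFrame, GroundTruth]:
    """Sample site x depth communities plus correlated geochemistry.

    Returns the count table (taxa x samples, every column summing to
    ``sequencing_depth``), a metadata frame (site, depth_layer, geochem),
    and the :class:`GroundTruth` used to generate them.
    """
    tip_names = sorted(tip.name for tip in tree.tips())
    missing = [t for t in tip_names if t not in traits]
    if missing:
        raise ValueError(f"traits missing for tips: {missing[:5]}")
    trait_vec = np.array([traits[t] for t in tip_names])
    # quantile-standardised trait: F in (0, 1)
    F = (rankdata(trait_vec) - 0.5) / len(trait_vec)

    rng = np.random.default_rng(config.seed)
    regimes = config.site_regimes()
    sites = [f"ROV{i + 1}" for i in range(config.n_sites)]
    if config.env_profile is not None:
        site_q = np.array([float(config.env_profile[s]) for s in sites])
        if ((site_q <= 0) | (site_q >= 1)).any():
            raise ValueError("env_profile optima are quantiles in (0, 1)")
    else:
        site_q = _site_quantiles(config.n_sites, config.env_quantiles)
    base = rng.lognormal(mean=0.0, sigma=config.base_sigma, size=len(tip_names))

    z_site = (site_q - 0.5) / 0.29  # standardised position on the gradient
    depth_layers = [f"{5 * d}-{5 * (d + 1)}cm" for d in range(config.n_depths_per_site)]
    disp_sigma = 2.0 * (1.0 - config.dispersal_m)
    n = len(tip_names)

    counts: dict[str, np.ndarray] = {}
    meta_rows = []
    sample_optima: dict[str, float] = {}
    for s_idx, site in enumerate(sites):
        regime = regimes[s_idx]
        for d_idx, layer in enumerate(depth_layers):
            sid = f"{site}_D{d_idx + 1}"
            q = float(site_q[s_idx])
            expected = base.copy()
            if regime == "selection":
                q = float(np.clip(q + config.depth_jitter * rng.standard_normal(), 0.02, 0.98))
                if config.selection_strength > 0:
                    w = np.exp(-config.selection_strength * (F - q) ** 2)
                    w[w < config.niche_floor] = 0.0
                    expected = expected * w
            elif regime == "dispersal_limited":
                expected = expected * rng.lognormal(0.0, disp_sigma, n)
            # colonization lottery + abundance drift: local demographic
            # stochasticity, absent under mass effects (neutral regime)
            if regime != "neutral":
                if config.colonization_phi < 1.0:
                    expected = expected * (rng.random(n) < config.colonization_phi)
                if config.drift_sigma > 0:
                    expected = expected * rng.lognormal(0.0, config.drift_sigma, n)
            total = expected.sum()
            if total == 0 or (expected > 0).sum() < 2:
                raise RuntimeError(
                    f"sample {sid}: fewer than 2 taxa passed the niche filter and lottery"
                )
            counts[sid] = rng.multinomial(config.sequencing_depth, expected / total)
            sample_optima[sid] = q
            geochem = {"CH4": 60.0 + 25.0 * z_site[s_idx] + 3.0 * rng.standard_normal()}
            for var, (mu, sd) in _NUISANCE.items():
                geochem[var] = mu + sd * rng.standard_normal()
            meta_rows.append({"sample_id": sid, "site": site, "depth_layer": layer, **geochem})

    table = CommunityTable(pd.DataFrame(counts, index=tip_names))
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    metadata = metadata[["site", "depth_layer", *GEOCHEM_VARS]]
    truth = GroundTruth(
        site_regimes=dict(zip(sites, regimes)),
        env_optima={s: float(q) for s, q in zip(sites, site_q)},
        traits={t: float(v) for t, v in zip(tip_names, trait_vec)},
        sample_optima=sample_optima,
    )
    return table, metadata, truth


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[CommunityTable, pd.DataFrame, TreeNode, GroundTruth]:
    """Pool tree + niche traits + communities in one deterministic call.

    Tree, trait and community seeds are derived from ``config.seed`` so a
    single integer reproduces the whole dataset.
    """
    ss = np.random.SeedSequence(config.seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    tree = simulate_pool_tree(
        config.n_taxa,
        height=config.pool_height,
        tip_shrink=config.tip_shrink,
        seed=seeds[0],
    )
    traits = evolve_traits(
        tree, config.trait_sigma, seed=seeds[1], trend=config.niche_trend
    )
    cfg = SimulationConfig(**{**asdict(config), "seed": seeds[2]})
    table, metadata, truth = simulate_communities(tree, traits, cfg)
    return table, metadata, tree, truth
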
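"""Synthetic communities, traits, phylogenies and latent-variable data.

Stands in for the un-deposited forest understory survey: a blocked,
fenced-versus-unfenced design of percent-cover quadrat records over a
species pool with leaf traits evolved on a simulated phylogeny.  Everything
is seeded and deterministic, with one RNG stream per operation (derived from
``seed`` plus a stable per-operation tag) so each product can be regenerated
independently.

The default configuration mirrors the study design: 12 plots, each with a
fenced and an unfenced half of 10 one-square-metre quadrats (240 quadrat
surveys), cover recorded to the nearest 1% with trace occurrences (<0.5%)
recorded as 0.1%, a regional pool in which only the most abundant ~31
species carry complete leaf-trait data, and deer herbivory acting
selectively on palatable (high-SLA) species in unfenced quadrats.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .community import CommunityMatrix, QUADRAT_COLUMNS, TRAIT_NAMES
from .sem import SEMSpec, implied_covariance

__all__ = [
    "GeneratorConfig",
    "SEMTruth",
    "simulate_tree",
    "simulate_traits",
    "simulate_landscape",
    "simulate_from_sem",
    "case_study_truth",
]

# stable per-operation RNG stream tags
_TAG_TREE, _TAG_TRAITS, _TAG_LANDSCAPE, _TAG_SEM = 11, 12, 13, 14


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design and effect parameters for the landscape generator."""

    n_pool: int = 45
    n_blocks: int = 12
    n_plots_per_block: int = 1
    n_quadrats_per_fence_level: int = 10
    herbivory_effect: float = 0.5
    palatability_trait: str = "SLA"
    trait_sigma2: float = 1.0
    cover_scale: tuple[float, float] = (0.0, 1.2)  # (meanlog, sdlog) of base cover, %
    missing_trait_fraction: float = 0.31
    seed: int = 0

    def __post_init__(self):
        for name in ("n_pool", "n_blocks", "n_plots_per_block", "n_quadrats_per_fence_level"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.herbivory_effect <= 1.0:
            raise ValueError("herbivory_effect must be in [0, 1]")
        if not 0.0 <= self.missing_trait_fraction < 1.0:
            raise ValueError("missing_trait_fraction must be in [0, 1)")

    @property
    def n_plots(self) -> int:
        return self.n_blocks * self.n_plots_per_block


def simulate_tree(n_species: int, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric tree with ``n_species`` tips.

    Tips are labelled sp001...spNNN; all branch lengths are positive and
    every tip sits at the same distance from the root.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = np.random.default_rng([int(seed), _TAG_TREE])
    # classic Yule construction: exponential waiting times between birth
    # events, each extending all live lineages equally
    birth_times = [0.0]
    t = 0.0
    for k in range(1, n_species):
        t += rng.exponential(1.0 / k)
        birth_times.append(t)
    t_final = t + rng.exponential(1.0 / n_species)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node.birth_time = 0.0
    live = [tree.seed_node]
    for bt in birth_times[1:]:
        idx = int(rng.integers(len(live)))
        parent = live.pop(idx)
        parent.edge.length = (
            bt - parent.birth_time if parent.parent_node is not None else bt
        )
        # root's subtending edge has no length; record split depth instead
        parent.split_time = bt
        for _ in range(2):
            child = parent.new_child()
            child.birth_time = bt
            live.append(child)
    for leaf in live:
        leaf.edge.length = t_final - leaf.birth_time
    # the root split happens at time birth_times[1]... actually the first
    # split IS the root: fix its children's lengths (root has birth_time 0,
    # its "edge" above is absent)
    tree.seed_node.edge.length = None
    labels = [f"sp{i + 1:03d}" for i in range(n_species)]
    for label, leaf in zip(labels, tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(label)
    tree.is_rooted = True
    return tree


def tree_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip path length per tip label."""
    depths = {}
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths[leaf.taxon.label] = d
    return depths


def simulate_traits(
    tree: dendropy.Tree,
    trait_names=TRAIT_NAMES,
    sigma2: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Brownian-motion trait evolution along the tree, root value 0.

    Each trait diffuses independently with rate ``sigma2`` per unit branch
    length; tip covariance therefore equals sigma2 times the shared
    root-to-MRCA path length.  Returns a tips x traits table.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = np.random.default_rng([int(seed), _TAG_TRAITS])
    n_traits = len(trait_names)
    values: dict[int, np.ndarray] = {id(tree.seed_node): np.zeros(n_traits)}
    rows = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_val = values[id(node.parent_node)]
        bl = node.edge.length or 0.0
        step = rng.standard_normal(n_traits) * np.sqrt(sigma2 * bl)
        values[id(node)] = parent_val + step
        if node.is_leaf():
            rows[node.taxon.label] = values[id(node)]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(trait_names))
    out.index.name = "species"
    return out.sort_index()


def simulate_landscape(
    config: GeneratorConfig,
    tree: dendropy.Tree,
    traits: pd.DataFrame,
) -> tuple[CommunityMatrix, pd.DataFrame]:
    """Quadrat-level percent-cover survey plus the trait table as surveyed.

    Species base covers are log-normal per species (scaled per plot and per
    quadrat); each species occupies a quadrat with probability increasing in
    its local base cover, so rare species are also patchy.  In unfenced
    quadrats, species in the top tercile of the palatability trait have cover
    multiplied by (1 - herbivory_effect).  Quadrat noise is drawn once per
    plot and shared between the paired fenced/unfenced halves, so a zero
    herbivory effect yields literally identical paired communities.  Observed
    cover is rounded to the nearest 1%, except true covers in (0, 0.5) which
    are recorded as the trace value 0.1.

    Returns the community matrix and a copy of ``traits`` in which the
    configured fraction of (lowest-cover) pool species have one trait masked
    — emulating a survey where only the dominant species have complete trait
    records.
    """
    species = sorted(t.label for t in tree.taxon_namespace)
    if not set(species) <= set(traits.index):
        missing = sorted(set(species) - set(traits.index))
        raise ValueError(f"traits missing for species {missing}")
    n_sp = len(species)
    rng = np.random.default_rng([int(config.seed), _TAG_LANDSCAPE])

    meanlog, sdlog = config.cover_scale
    base = np.exp(meanlog + sdlog * rng.standard_normal(n_sp))  # % cover

    pal = traits.loc[species, config.palatability_trait].to_numpy(dtype=float)
    tercile = np.quantile(pal, 2.0 / 3.0)
    palatable = pal > tercile

    nq = config.n_quadrats_per_fence_level
    records = []
    for b in range(config.n_blocks):
        for pp in range(config.n_plots_per_block):
            block = f"b{b + 1:02d}"
            plot = f"p{b * config.n_plots_per_block + pp + 1:02d}"
            plot_base = base * np.exp(1.0 * rng.standard_normal(n_sp))
            # species turnover across plots drives richness variation between
            # sample units; noise and occupancy are shared between the paired
            # fenced/unfenced halves
            plot_present = rng.random(n_sp) < plot_base / (plot_base + 1.0)
            quad_noise = np.exp(0.5 * rng.standard_normal((nq, n_sp)))
            occupied = plot_present & (rng.random((nq, n_sp)) < 0.7)
            for fence in ("fenced", "unfenced"):
                mult = np.ones(n_sp)
                if fence == "unfenced":
                    mult = np.where(palatable, 1.0 - config.herbivory_effect, 1.0)
                for q in range(nq):
                    true = np.minimum(plot_base * quad_noise[q] * mult, 100.0)
                    true = np.where(occupied[q], true, 0.0)
                    obs = np.where(
                        (true > 0) & (true < 0.5), 0.1, np.round(true)
                    )
                    for s_idx in np.nonzero(obs > 0)[0]:
                        records.append(
                            (block, plot, fence, f"q{q + 1:02d}", species[s_idx], obs[s_idx])
                        )
    cm = CommunityMatrix(
        pd.DataFrame(records, columns=QUADRAT_COLUMNS), level="quadrat"
    )

    out_traits = traits.copy()
    n_mask = int(round(config.missing_trait_fraction * config.n_pool))
    if n_mask:
        # mask the species with the smallest base cover: trait records exist
        # only for the dominant species, as in real surveys
        mask_idx = np.argsort(base)[:n_mask]
        for i in mask_idx:
            col = out_traits.columns[int(rng.integers(out_traits.shape[1]))]
            out_traits.loc[species[i], col] = np.nan
    return cm, out_traits


# ---------------------------------------------------------------------------
# data from a known structural model


@dataclass(frozen=True)
class SEMTruth:
    """A model together with true parameter values for recovery experiments."""

    spec: SEMSpec
    theta_true: dict[str, float]
    n_samples: int = 1000
    seed: int = 0

    def sigma(self) -> np.ndarray:
        sigma = implied_covariance(self.spec, self.theta_true)
        eig = np.linalg.eigvalsh(sigma)
        if eig[0] <= 0:
            raise ValueError("implied covariance of theta_true is not positive definite")
        return sigma


def simulate_from_sem(truth: SEMTruth) -> pd.DataFrame:
    """Multivariate-normal draws (mean 0) from the model-implied covariance."""
    sigma = truth.sigma()
    rng = np.random.default_rng([int(truth.seed), _TAG_SEM])
    chol = np.linalg.cholesky(sigma)
    z = rng.standard_normal((truth.n_samples, sigma.shape[0]))
    return pd.DataFrame(z @ chol.T, columns=list(truth.spec.observed))


def case_study_truth(n_samples: int = 5000, seed: int = 0) -> SEMTruth:
    """Plausible true values for the three-latent biodiversity model.

    Magnitudes follow the standardized scale of the fitted case study:
    strong taxonomic and phylogenetic loadings, moderate functional ones,
    a mix of positive and negative structural effects on total cover, and
    moderately correlated latents.  Observed variances are ~1, so estimates
    are directly interpretable as standardized values.
    """
    from .sem import build_case_study_spec

    spec = build_case_study_spec("covariate")
    loadings = {
        "TD->Shannon": 0.9,
        "TD->Simpson": 0.75,
        "FD->FD_Divergence": 0.7,
        "FD->FD_Evenness": 0.5,
        "PD->Faith": 0.9,
        "PD->MPD": 0.7,
    }
    structural = {
        "TD->Total_Cover": 0.35,
        "FD->Total_Cover": 0.5,
        "PD->Total_Cover": -0.15,
    }
    latent_cov = {"FD<->TD": 0.3, "FD<->PD": 0.5, "PD<->TD": 0.4}
    ntaxa_cov = {"TD<->nTaxa": 0.4, "FD<->nTaxa": 0.5, "PD<->nTaxa": 0.6}
    theta = {**loadings, **structural, **latent_cov, **ntaxa_cov}
    theta["nTaxa<->nTaxa"] = 1.0
    # indicator error variances give unit observed variance
    for name, lam in loadings.items():
        ind = name.split("->")[1]
        theta[f"{ind}<->{ind}"] = 1.0 - lam**2
    phi = np.array(
        [
            [1.0, 0.3, 0.4],
            [0.3, 1.0, 0.5],
            [0.4, 0.5, 1.0],
        ]
    )
    c = np.array([structural["TD->Total_Cover"], structural["FD->Total_Cover"], structural["PD->Total_Cover"]])
    theta["Total_Cover<->Total_Cover"] = 1.0 - float(c @ phi @ c)
    truth = SEMTruth(spec=spec, theta_true=theta, n_samples=n_samples, seed=seed)
    truth.sigma()  # validates positive definiteness
    return truth
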
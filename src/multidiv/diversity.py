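"""Taxonomic, functional and phylogenetic diversity metrics.

Per sample unit the module computes species richness, Shannon entropy (nats),
Gini-Simpson diversity, the three trait-space indices of Villeger-style
functional diversity (FEve, FDiv, FRic), Faith's phylogenetic diversity and
abundance-weighted mean pairwise phylogenetic distance, plus total cover.
These are the observed indicator variables of the latent-variable model in
:mod:`multidiv.sem`.

Functional indices operate in a common z-standardized trait space built over
the full analysis species pool, so that values are comparable across sample
units.  FEve is computed on the minimum spanning tree of the community in
that space; FDiv and FRic use the convex hull (collapsed to the spanned
subspace when the community is degenerate in one or more trait dimensions).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree as _csgraph_mst
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist, squareform

from .community import CommunityMatrix

__all__ = [
    "UndefinedMetric",
    "DegenerateTrait",
    "FunctionalSpace",
    "relative_abundances",
    "shannon",
    "simpson",
    "build_functional_space",
    "functional_evenness",
    "functional_divergence",
    "functional_richness",
    "faith_pd",
    "weighted_mpd",
    "patristic_matrix",
    "compute_profiles",
    "SEM_VIEW_COLUMNS",
]

#: Columns of the SEM-ready profile view: FRic and raw richness are computed
#: but excluded as indicators (they are richness-dependent); n_taxa stays as
#: the covariate.
SEM_VIEW_COLUMNS = [
    "n_taxa",
    "shannon",
    "simpson",
    "feve",
    "fdiv",
    "faith_pd",
    "mpd_w",
    "total_cover",
]


class UndefinedMetric(ValueError):
    """The metric is undefined for this community (recorded as missing)."""


class DegenerateTrait(ValueError):
    """A trait is constant across the standardization pool."""


def relative_abundances(cover) -> np.ndarray:
    """Normalize a cover vector to relative abundances summing to 1."""
    cover = np.asarray(cover, dtype=float)
    if (cover < 0).any():
        raise ValueError("negative cover")
    total = cover.sum()
    if total <= 0:
        raise UndefinedMetric("all-zero cover vector")
    return cover / total


def shannon(p) -> float:
    """Shannon entropy H = -sum p ln p, in nats."""
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def simpson(p, variant: str = "gini") -> float:
    """Simpson diversity.

    ``gini`` (default) returns the Gini-Simpson index 1 - sum(p^2); the
    ``inverse`` variant returns 1/sum(p^2).
    """
    p = np.asarray(p, dtype=float)
    ss = float((p**2).sum())
    if variant == "gini":
        return 1.0 - ss
    if variant == "inverse":
        return 1.0 / ss
    raise ValueError(f"unknown Simpson variant {variant!r}")


# ---------------------------------------------------------------------------
# functional trait space


@dataclass
class FunctionalSpace:
    """A community embedded in z-standardized trait space.

    Holds everything FEve/FDiv/FRic need: standardized coordinates,
    pairwise Euclidean distances, the minimum spanning tree, convex-hull
    vertices and volume (in the spanned subspace when degenerate), the
    hull-vertex centroid g and per-species distances to it.
    """

    species: list[str]
    coords: np.ndarray  # S x T, z-units
    p: np.ndarray  # relative abundances, sum 1
    dist: np.ndarray  # S x S Euclidean distances
    mst_edges: list[tuple[int, int, float]]  # (i, j, length), i < j
    hull_vertices: np.ndarray  # indices into species
    hull_volume: float
    hull_dim: int  # dimensionality of the spanned subspace used for the hull
    centroid: np.ndarray  # g, in the full coordinate frame
    dG: np.ndarray  # per-species distance to g

    @property
    def n_species(self) -> int:
        return len(self.species)


def _zscores(traits: pd.DataFrame) -> pd.DataFrame:
    mu = traits.mean(axis=0)
    sd = traits.std(axis=0, ddof=1)
    constant = sd[(sd == 0) | sd.isna()].index.tolist()
    if constant:
        raise DegenerateTrait(f"constant trait(s) across pool: {constant}")
    return (traits - mu) / sd


def _mst(dist: np.ndarray) -> list[tuple[int, int, float]]:
    """Minimum spanning tree edges, ties broken by lexicographic pair order.

    A tiny lexicographic perturbation (far below any meaningful distance
    difference) makes the MST unique, then exact distances are reported.
    """
    s = dist.shape[0]
    eps = np.zeros_like(dist)
    scale = max(dist.max(), 1.0) * 1e-12
    k = 0
    for i in range(s):
        for j in range(i + 1, s):
            k += 1
            eps[i, j] = eps[j, i] = k * scale
    mst = _csgraph_mst(np.triu(dist + eps))
    ii, jj = mst.nonzero()
    edges = []
    for i, j in zip(ii, jj):
        a, b = (int(i), int(j)) if i < j else (int(j), int(i))
        edges.append((a, b, float(dist[a, b])))
    return sorted(edges)


def _spanned_subspace(coords: np.ndarray, tol: float = 1e-9):
    """Project points onto the subspace they actually span."""
    centered = coords - coords.mean(axis=0)
    u, sing, vt = np.linalg.svd(centered, full_matrices=False)
    scale = max(sing[0], 1.0) if sing.size else 1.0
    rank = int((sing > tol * scale).sum())
    return centered @ vt[:rank].T, rank


def _hull(coords: np.ndarray):
    """Convex hull vertices and volume, collapsing degenerate dimensions.

    Returns (vertex indices, volume, effective dimension).  Communities that
    are entirely coincident have no hull (dimension 0).
    """
    proj, rank = _spanned_subspace(coords)
    if rank == 0:
        raise UndefinedMetric("all species coincident in trait space")
    if rank == 1:
        x = proj[:, 0]
        vol = float(x.max() - x.min())
        verts = np.array(sorted({int(np.argmin(x)), int(np.argmax(x))}))
        return verts, vol, 1
    hull = ConvexHull(proj[:, :rank])
    return np.sort(hull.vertices), float(hull.volume), rank


def build_functional_space(
    traits: pd.DataFrame,
    sample_species: list[str],
    p,
    pool_species: list[str] | None = None,
) -> FunctionalSpace:
    """Embed a community in the pool-standardized trait space.

    ``traits`` must be complete for all pool species; z-scores are computed
    over ``pool_species`` (default: every row of ``traits``) so the space is
    shared across sample units, then the community is the subset
    ``sample_species`` with relative abundances ``p``.
    """
    pool = list(pool_species) if pool_species is not None else list(traits.index)
    sub = traits.loc[pool]
    if sub.isna().any().any():
        raise ValueError("traits must be complete for the standardization pool")
    z = _zscores(sub)
    missing = [s for s in sample_species if s not in z.index]
    if missing:
        raise KeyError(f"species missing from trait table: {missing}")
    p = np.asarray(p, dtype=float)
    if len(p) != len(sample_species):
        raise ValueError("p and sample_species length mismatch")
    if not np.isclose(p.sum(), 1.0):
        p = relative_abundances(p)
    coords = z.loc[list(sample_species)].to_numpy(dtype=float)
    dist = squareform(pdist(coords)) if len(sample_species) > 1 else np.zeros((1, 1))
    mst_edges = _mst(dist) if len(sample_species) > 1 else []
    try:
        verts, vol, dim = _hull(coords)
    except UndefinedMetric:
        verts, vol, dim = np.array([], dtype=int), float("nan"), 0
    if verts.size:
        g = coords[verts].mean(axis=0)
        dG = np.linalg.norm(coords - g, axis=1)
    else:
        g = coords.mean(axis=0)
        dG = np.zeros(len(sample_species))
    return FunctionalSpace(
        species=list(sample_species),
        coords=coords,
        p=p,
        dist=dist,
        mst_edges=mst_edges,
        hull_vertices=verts,
        hull_volume=vol,
        hull_dim=dim,
        centroid=g,
        dG=dG,
    )


def functional_evenness(space: FunctionalSpace) -> float:
    """FEve: regularity of abundance-weighted spacing along the MST.

    For each MST edge l=(i,j), EW_l = d(i,j)/(p_i + p_j); PEW_l = EW_l/sum EW;
    FEve = (sum_l min(PEW_l, 1/(S-1)) - 1/(S-1)) / (1 - 1/(S-1)), in [0, 1].
    Undefined for S < 3.
    """
    s = space.n_species
    if s < 3:
        raise UndefinedMetric("FEve requires at least 3 species")
    ew = np.array([d / (space.p[i] + space.p[j]) for i, j, d in space.mst_edges])
    total = ew.sum()
    if total == 0:
        raise UndefinedMetric("all species coincident in trait space")
    pew = ew / total
    thresh = 1.0 / (s - 1)
    return float((np.minimum(pew, thresh).sum() - thresh) / (1.0 - thresh))


def functional_divergence(space: FunctionalSpace) -> float:
    """FDiv: degree to which abundance sits toward the edges of trait space.

    With g the centroid of the hull-vertex species, dG_i the distance of
    species i to g, and deviations weighted by relative abundance:
    FDiv = (Delta_d + mean dG) / (Delta_|d| + mean dG), in [0, 1].
    """
    if space.hull_dim == 0 or not np.isfinite(space.hull_volume):
        raise UndefinedMetric("no convex hull: species coincident")
    dG = space.dG
    dbar = dG.mean()
    dev = dG - dbar
    delta_d = float((space.p * dev).sum())
    delta_abs = float((space.p * np.abs(dev)).sum())
    denom = delta_abs + dbar
    if denom == 0:
        raise UndefinedMetric("all species coincident with hull centroid")
    return float((delta_d + dbar) / denom)


def functional_richness(space: FunctionalSpace) -> float:
    """FRic: convex-hull volume in (possibly collapsed) trait space."""
    if space.hull_dim == 0 or not np.isfinite(space.hull_volume):
        raise UndefinedMetric("no convex hull: species coincident")
    return space.hull_volume


# ---------------------------------------------------------------------------
# phylogenetic metrics


def _tip_map(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    return {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}


def faith_pd(tree: dendropy.Tree, present: list[str], include_root: bool = True) -> float:
    """Faith's PD: branch length of the minimal subtree spanning ``present``.

    With ``include_root`` (default, matching the classic Phylocom behaviour)
    the subtree is connected down to the supplied tree's root; otherwise only
    branches below the MRCA of the present tips count.
    """
    import math

    tips = _tip_map(tree)
    unknown = [s for s in present if s not in tips]
    if unknown:
        raise KeyError(f"species not in tree: {unknown}")
    if len(present) == 0:
        raise ValueError("at least one species required")
    # collect the spanning node set in deterministic (sorted-tip) order
    seen: set[int] = set()
    nodes = []
    for s in sorted(set(present)):
        node = tips[s]
        while node is not None and id(node) not in seen:
            seen.add(id(node))
            nodes.append(node)
            node = node.parent_node
    if not include_root:
        # drop the path above (and including the edge subtending) the MRCA
        mrca = tree.mrca(taxa=[tips[s].taxon for s in set(present)])
        above: set[int] = {id(mrca)}
        node = mrca.parent_node
        while node is not None:
            above.add(id(node))
            node = node.parent_node
        nodes = [n for n in nodes if id(n) not in above]
    return math.fsum(
        n.edge.length or 0.0 for n in nodes if n.parent_node is not None
    )


def patristic_matrix(tree: dendropy.Tree, species: list[str]) -> np.ndarray:
    """Pairwise patristic (branch-length path) distances between tips."""
    pdm = tree.phylogenetic_distance_matrix()
    tips = _tip_map(tree)
    unknown = [s for s in species if s not in tips]
    if unknown:
        raise KeyError(f"species not in tree: {unknown}")
    n = len(species)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(tips[species[i]].taxon, tips[species[j]].taxon)
            out[i, j] = out[j, i] = d
    return out


def weighted_mpd(tree: dendropy.Tree, species: list[str], p) -> float:
    """Abundance-weighted mean pairwise phylogenetic distance.

    MPD = sum_{i<j} p_i p_j d_ij / sum_{i<j} p_i p_j over distinct pairs of
    species with nonzero abundance.
    """
    p = np.asarray(p, dtype=float)
    mask = p > 0
    if mask.sum() < 2:
        raise UndefinedMetric("weighted MPD requires >= 2 species with abundance")
    sp = [s for s, m in zip(species, mask) if m]
    w = p[mask]
    d = patristic_matrix(tree, sp)
    iu = np.triu_indices(len(sp), k=1)
    weights = w[iu[0]] * w[iu[1]]
    return float((weights * d[iu]).sum() / weights.sum())


# ---------------------------------------------------------------------------
# profile assembly


def compute_profiles(
    cm: CommunityMatrix,
    traits: pd.DataFrame,
    tree: dendropy.Tree,
    simpson_variant: str = "gini",
    include_root: bool = True,
) -> pd.DataFrame:
    """One diversity profile row per sample unit.

    Trait z-standardization uses the full species pool of ``cm`` (so trait
    space is common across units).  Metrics undefined for a unit are left
    missing and the reason recorded in a companion ``missing_reason`` column.
    """
    wide = cm.to_wide()
    pool = [s for s in wide.columns if wide[s].sum() > 0]
    rows = []
    for idx, row in wide.iterrows():
        cover = row.to_numpy(dtype=float)
        present = cover > 0
        sp = [s for s, m in zip(wide.columns, present) if m]
        cov = cover[present]
        rec: dict[str, object] = dict(zip(wide.index.names, idx))
        reasons = []
        rec["n_taxa"] = int(present.sum())
        rec["total_cover"] = float(cover.sum())
        if rec["n_taxa"] == 0:
            reasons.append("empty unit")
            for m in ("shannon", "simpson", "feve", "fdiv", "fric", "faith_pd", "mpd_w"):
                rec[m] = np.nan
            rec["missing_reason"] = "; ".join(reasons)
            rows.append(rec)
            continue
        p = relative_abundances(cov)
        rec["shannon"] = shannon(p)
        rec["simpson"] = simpson(p, variant=simpson_variant)
        space = build_functional_space(traits, sp, p, pool_species=pool)
        for name, fn in (
            ("feve", functional_evenness),
            ("fdiv", functional_divergence),
            ("fric", functional_richness),
        ):
            try:
                rec[name] = fn(space)
            except UndefinedMetric as exc:
                rec[name] = np.nan
                reasons.append(f"{name}: {exc}")
        rec["faith_pd"] = faith_pd(tree, sp, include_root=include_root)
        try:
            rec["mpd_w"] = weighted_mpd(tree, sp, p)
        except UndefinedMetric as exc:
            rec["mpd_w"] = np.nan
            reasons.append(f"mpd_w: {exc}")
        rec["missing_reason"] = "; ".join(reasons)
        rows.append(rec)
    out = pd.DataFrame(rows)
    order = list(wide.index.names) + [
        "n_taxa",
        "shannon",
        "simpson",
        "feve",
        "fdiv",
        "fric",
        "faith_pd",
        "mpd_w",
        "total_cover",
        "missing_reason",
    ]
    return out.loc[:, order]


def sem_view(profiles: pd.DataFrame) -> pd.DataFrame:
    """The SEM-ready columns (drops FRic, keeps n_taxa as covariate)."""
    return profiles.loc[:, SEM_VIEW_COLUMNS].astype(float)
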
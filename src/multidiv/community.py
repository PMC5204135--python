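"""Community data model and survey-preparation steps.

A vegetation survey is stored as a tidy table of per-quadrat percent-cover
records together with the blocked, fenced design metadata (block, plot,
fence status).  Two preparation steps are provided: aggregation of quadrats
to plot-by-fence means (the replicate sample unit of all downstream
analyses) and restriction to species with complete trait data.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import pandas as pd

__all__ = [
    "CommunityMatrix",
    "FormatError",
    "read_community_csv",
    "write_community_csv",
    "read_traits_csv",
    "write_traits_csv",
    "read_newick",
    "write_newick",
    "aggregate_to_blocks",
    "filter_complete_traits",
    "mean_trait_values",
    "normalize_species_id",
]

QUADRAT_COLUMNS = ["block", "plot", "fence", "quadrat", "species", "cover_pct"]
BLOCK_COLUMNS = ["block", "plot", "fence", "species", "cover_pct"]
FENCE_LEVELS = ("fenced", "unfenced")

TRAIT_NAMES = ("SLA", "LNC", "LPC")


class FormatError(ValueError):
    """Raised when an input file violates the community/trait/tree contracts."""


def normalize_species_id(name: str) -> str:
    """Canonical species identifier: stripped, internal spaces -> underscores."""
    return "_".join(str(name).strip().split())


@dataclass
class CommunityMatrix:
    """Percent-cover records with design metadata.

    ``level`` is ``"quadrat"`` (one record per quadrat x species) or
    ``"block-mean"`` (one record per plot x fence x species, the mean over
    that unit's quadrats).  A sample *unit* is (plot, fence) at block-mean
    level and (plot, fence, quadrat) at quadrat level.
    """

    records: pd.DataFrame
    level: str = "quadrat"

    def __post_init__(self) -> None:
        cols = QUADRAT_COLUMNS if self.level == "quadrat" else BLOCK_COLUMNS
        if self.level not in ("quadrat", "block-mean"):
            raise ValueError(f"unknown level {self.level!r}")
        missing = set(cols) - set(self.records.columns)
        if missing:
            raise FormatError(f"missing columns: {sorted(missing)}")
        df = self.records.loc[:, cols].copy()
        df["species"] = df["species"].map(normalize_species_id)
        if (df["species"] == "").any():
            raise FormatError("empty species id")
        bad_fence = set(df["fence"].unique()) - set(FENCE_LEVELS)
        if bad_fence:
            raise FormatError(f"unknown fence levels {sorted(bad_fence)}")
        cover = pd.to_numeric(df["cover_pct"], errors="coerce")
        if cover.isna().any():
            row = int(df.index[cover.isna()][0])
            raise FormatError(f"non-numeric cover at row {row}")
        if (cover < 0).any():
            row = int(df.index[cover < 0][0])
            raise FormatError(f"negative cover at row {row}")
        df["cover_pct"] = cover.astype(float)
        unit_cols = self._unit_columns() + ["species"]
        dup = df.duplicated(subset=unit_cols)
        if dup.any():
            row = int(df.index[dup][0])
            raise FormatError(f"duplicate (unit, species) record at row {row}")
        self.records = df.reset_index(drop=True)

    def _unit_columns(self) -> list[str]:
        return ["plot", "fence", "quadrat"] if self.level == "quadrat" else ["plot", "fence"]

    @property
    def species(self) -> list[str]:
        return sorted(self.records["species"].unique())

    def units(self) -> pd.DataFrame:
        """One row per sample unit with its design metadata."""
        cols = ["block"] + self._unit_columns()
        return (
            self.records.loc[:, cols]
            .drop_duplicates()
            .sort_values(cols)
            .reset_index(drop=True)
        )

    def n_units(self) -> int:
        return len(self.units())

    def to_wide(self) -> pd.DataFrame:
        """Units x species cover matrix (absent species = 0), with design index."""
        cols = ["block"] + self._unit_columns()
        wide = self.records.pivot_table(
            index=cols, columns="species", values="cover_pct", fill_value=0.0, aggfunc="sum"
        )
        return wide.sort_index()

    def canonical(self) -> pd.DataFrame:
        cols = self._unit_columns()
        return (
            self.records.sort_values(["block"] + cols + ["species"])
            .reset_index(drop=True)
        )


def read_community_csv(path) -> CommunityMatrix:
    """Read a tidy community CSV; level inferred from presence of a quadrat column."""
    df = pd.read_csv(path, dtype={"block": str, "plot": str, "species": str})
    level = "quadrat" if "quadrat" in df.columns else "block-mean"
    if level == "quadrat":
        df["quadrat"] = df["quadrat"].astype(str)
    return CommunityMatrix(df, level=level)


def write_community_csv(cm: CommunityMatrix, path) -> None:
    cm.canonical().to_csv(path, index=False)


def read_traits_csv(path, require_positive: bool = False) -> pd.DataFrame:
    """Species x trait table, indexed by species id; empty cells are missing values.

    Empirical leaf traits (SLA, LNC, LPC) are strictly positive and can be
    checked with ``require_positive``; the default accepts any real values so
    that centred simulated traits also round-trip.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = [normalize_species_id(s) for s in df.index]
    df.index.name = "species"
    if df.index.duplicated().any():
        raise FormatError("duplicate species id in trait table")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if require_positive and ((numeric <= 0) & df.notna()).any().any():
        raise FormatError("trait values must be positive where present")
    return numeric


def write_traits_csv(traits: pd.DataFrame, path) -> None:
    traits.sort_index().to_csv(path)


def read_newick(path_or_str) -> dendropy.Tree:
    """Read a single rooted Newick tree with branch lengths.

    Accepts a file path or a raw Newick string.  Every tip must be labelled
    and every non-root edge must carry a branch length.
    """
    text = str(path_or_str)
    if not text.lstrip().startswith("("):
        with open(text) as fh:
            text = fh.read()
    try:
        tree = dendropy.Tree.get(data=text, schema="newick", rooting="force-rooted")
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"malformed newick: {exc}") from exc
    labels = [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]
    if any(lab is None or str(lab).strip() == "" for lab in labels):
        raise FormatError("unlabelled tip in tree")
    norm = [normalize_species_id(lab) for lab in labels]
    if len(set(norm)) != len(norm):
        raise FormatError("duplicate tip labels")
    for leaf, lab in zip(tree.leaf_node_iter(), norm):
        leaf.taxon.label = lab
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise FormatError("missing branch length")
        if edge.length < 0:
            raise FormatError("negative branch length")
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True))


def aggregate_to_blocks(cm: CommunityMatrix) -> CommunityMatrix:
    """Average quadrats within each plot x fence unit.

    Species absent from a quadrat contribute 0 to the mean, so each species'
    aggregated cover is (sum over quadrats)/(number of quadrats surveyed in
    that unit).  The 240-quadrat study design reduces to 24 replicate units.
    """
    if cm.level != "quadrat":
        raise ValueError("aggregate_to_blocks requires quadrat-level input")
    if cm.records.empty:
        raise ValueError("empty community matrix")
    df = cm.records
    n_quadrats = (
        df.drop_duplicates(["plot", "fence", "quadrat"])
        .groupby(["plot", "fence"])
        .size()
        .rename("n_quadrats")
    )
    sums = (
        df.groupby(["block", "plot", "fence", "species"], as_index=False)["cover_pct"].sum()
    )
    sums = sums.merge(n_quadrats.reset_index(), on=["plot", "fence"])
    sums["cover_pct"] = sums["cover_pct"] / sums["n_quadrats"]
    out = sums.loc[:, BLOCK_COLUMNS]
    return CommunityMatrix(out, level="block-mean")


def filter_complete_traits(
    cm: CommunityMatrix, traits: pd.DataFrame
) -> tuple[CommunityMatrix, float]:
    """Drop species with any missing trait value.

    Returns the restricted matrix and the fraction of total summed cover
    retained across all sample units (the study retained >85% of understory
    cover when restricting to trait-complete species).
    """
    complete = traits.dropna().index
    keep = cm.records["species"].isin(set(complete) & set(cm.species))
    total = float(cm.records["cover_pct"].sum())
    retained = float(cm.records.loc[keep, "cover_pct"].sum())
    fraction = retained / total if total > 0 else float("nan")
    filtered = CommunityMatrix(cm.records.loc[keep].reset_index(drop=True), level=cm.level)
    return filtered, fraction


def mean_trait_values(replicates: pd.DataFrame) -> pd.DataFrame:
    """Average replicate trait measurements per species x trait.

    ``replicates`` is a long table with columns (species, trait, value); the
    result is a species x trait table of arithmetic means with a parallel
    ``<trait>_n`` replicate-count column per trait (provenance).  A species x
    trait with zero replicates is a missing value, not an error.
    """
    for col in ("species", "trait", "value"):
        if col not in replicates.columns:
            raise FormatError(f"replicate table missing column {col!r}")
    df = replicates.copy()
    df["species"] = df["species"].map(normalize_species_id)
    grouped = df.groupby(["species", "trait"])["value"]
    means = grouped.mean().unstack("trait")
    counts = grouped.size().unstack("trait").fillna(0).astype(int)
    counts.columns = [f"{t}_n" for t in counts.columns]
    out = pd.concat([means, counts], axis=1)
    out.index.name = "species"
    return out
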
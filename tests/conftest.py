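import pandas as pd
import pytest

from multidiv.community import CommunityMatrix, read_newick
from multidiv.synthetic import GeneratorConfig, simulate_landscape, simulate_traits, simulate_tree


@pytest.fixture(scope="session")
def small_tree():
    """((A:1,B:1):1,C:2); — 3 tips, total branch length 5."""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def study_design():
    """A full synthetic survey mirroring the 12-plot fenced/unfenced design."""
    cfg = GeneratorConfig(seed=20)
    tree = simulate_tree(cfg.n_pool, seed=cfg.seed)
    traits = simulate_traits(tree, sigma2=cfg.trait_sigma2, seed=cfg.seed)
    cm, surveyed = simulate_landscape(cfg, tree, traits)
    return cfg, tree, traits, cm, surveyed


@pytest.fixture()
def tiny_cm():
    recs = pd.DataFrame(
        [
            ("b1", "p1", "fenced", "q1", "Acer_rubrum", 12.0),
            ("b1", "p1", "fenced", "q1", "Quercus_rubra", 3.0),
            ("b1", "p1", "fenced", "q2", "Acer_rubrum", 8.0),
            ("b1", "p1", "unfenced", "q1", "Acer_rubrum", 5.0),
        ],
        columns=["block", "plot", "fence", "quadrat", "species", "cover_pct"],
    )
    return CommunityMatrix(recs, level="quadrat")
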
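"""Validation experiments shared by the acceptance test suite and script.

Each function runs one self-contained experiment through the package's
public surface and returns plain numbers; the independent reference
implementations come from :mod:`oracles`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from multidiv.classical import backward_stepwise_regression, manova, one_way_anova
from multidiv.community import aggregate_to_blocks
from multidiv.diversity import (
    build_functional_space,
    faith_pd,
    functional_divergence,
    functional_evenness,
    functional_richness,
    shannon,
    simpson,
    weighted_mpd,
)
from multidiv.sem import Relation, SEMSpec, fit_ml
from multidiv.synthetic import (
    GeneratorConfig,
    SEMTruth,
    case_study_truth,
    simulate_from_sem,
    simulate_landscape,
    simulate_traits,
    simulate_tree,
)

import oracles


def metric_oracle_suite(seed: int = 0, n_communities: int = 200) -> float:
    """Max absolute deviation of all seven diversity metrics from their
    brute-force oracles over random small communities (S <= 8)."""
    rng = np.random.default_rng([seed, 101])
    worst = 0.0
    for i in range(n_communities):
        tree = simulate_tree(8, seed=int(rng.integers(2**31)))
        tips = sorted(l.taxon.label for l in tree.leaf_node_iter())
        s = int(rng.integers(4, 9))
        sp = list(rng.choice(tips, size=s, replace=False))
        sp.sort()
        coords = rng.standard_normal((s, 3))
        traits = pd.DataFrame(coords, index=sp, columns=["SLA", "LNC", "LPC"])
        p = rng.dirichlet(np.ones(s))
        space = build_functional_space(traits, sp, p)
        checks = [
            (shannon(p), oracles.shannon_oracle(p)),
            (simpson(p), oracles.simpson_oracle(p)),
            (functional_evenness(space), oracles.feve_oracle(space.coords, p)),
            (functional_divergence(space), oracles.fdiv_oracle(space.coords, p)),
            (functional_richness(space), oracles.fric_oracle(space.coords)),
            (faith_pd(tree, sp), oracles.faith_pd_oracle(tree, sp)),
            (weighted_mpd(tree, sp, p), oracles.mpd_oracle(tree, sp, p)),
        ]
        for mine, ref in checks:
            worst = max(worst, abs(mine - ref))
    return worst


def sem_parameter_recovery(
    seed: int = 0, n_replicates: int = 100, n_samples: int = 5000
) -> dict:
    """Fit data simulated from the case-study model at known truth.

    Returns the per-parameter rate of |estimate - truth| <= 3 SE (its
    minimum over parameters) and the mean RMSEA across replicates.
    """
    hits: dict[str, int] = {}
    rmseas = []
    n_converged = 0
    rng = np.random.default_rng([seed, 102])
    for rep in range(n_replicates):
        truth = case_study_truth(
            n_samples=n_samples, seed=int(rng.integers(2**31))
        )
        fit = fit_ml(truth.spec, data=simulate_from_sem(truth))
        n_converged += fit.converged
        rmseas.append(fit.rmsea)
        for name, tv in truth.theta_true.items():
            ok = abs(fit.estimates[name] - tv) <= 3 * fit.se[name]
            hits[name] = hits.get(name, 0) + int(ok)
    rates = {k: v / n_replicates for k, v in hits.items()}
    return {
        "min_param_rate": min(rates.values()),
        "mean_rmsea": float(np.mean(rmseas)),
        "convergence_rate": n_converged / n_replicates,
        "per_param": rates,
    }


def saturated_identity(seed: int = 0) -> dict:
    """Saturated model: F_ML = chi2 = df = 0 and Sigma(theta-hat) = S."""
    rng = np.random.default_rng([seed, 103])
    names = ("a", "b", "c", "d")
    data = pd.DataFrame(
        rng.standard_normal((60, 4)) @ np.diag([1.0, 2.0, 0.5, 1.5]),
        columns=names,
    )
    rels = [
        Relation("<->", x, y) for i, x in enumerate(names) for y in names[i:]
    ]
    fit = fit_ml(SEMSpec(names, (), rels), data=data)
    return {
        "fml": fit.fml,
        "chi2": fit.chi2,
        "df": fit.df,
        "sigma_max_abs_dev": float(np.abs(fit.implied() - fit.s_obs).max()),
    }


def manova_degeneracy(seed: int = 0) -> float:
    """Max |F_manova - F_anova| over the four statistics with one response."""
    rng = np.random.default_rng([seed, 104])
    y = rng.standard_normal(24)
    groups = np.array(["a"] * 12 + ["b"] * 12)
    uni = one_way_anova(y, groups)
    res = manova(pd.DataFrame({"y": y}), groups)
    return float(np.abs(res.statistics["F"].to_numpy() - uni.f).max())


def wilks_type1_error(
    seed: int = 0, n_sim: int = 2000, n: int = 24, q: int = 6, alpha: float = 0.05
) -> float:
    """Rejection rate of the Wilks test under the multivariate-normal null."""
    rng = np.random.default_rng([seed, 105])
    groups = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    cols = [f"m{i}" for i in range(q)]
    hits = 0
    for _ in range(n_sim):
        y = pd.DataFrame(rng.standard_normal((n, q)), columns=cols)
        res = manova(y, groups)
        hits += res.statistics.loc["wilks", "p"] < alpha
    return hits / n_sim


def stepwise_recovery(seed: int = 0, n_runs: int = 100) -> float:
    """Rate at which backward elimination recovers the single true predictor.

    y = 3.64 x1 + noise with five mutually correlated nuisance metrics at
    n = 12; removal threshold 0.01/5 (Bonferroni-style across the five null
    candidates — at twelve observations a conventional 0.05 threshold
    falsely retains a nuisance term in roughly a quarter of runs).
    """
    rng = np.random.default_rng([seed, 106])
    wins = 0
    for _ in range(n_runs):
        n = 12
        x1 = rng.standard_normal(n)
        shared = 0.3 * x1 + np.sqrt(1 - 0.09) * rng.standard_normal(n)
        lam = np.sqrt(0.3)
        nuis = lam * shared[:, None] + np.sqrt(1 - 0.3) * rng.standard_normal((n, 5))
        y = 3.64 * x1 + 1.0 * rng.standard_normal(n)
        x = pd.DataFrame(
            np.column_stack([x1, nuis]),
            columns=["x1"] + [f"z{i}" for i in range(5)],
        )
        res = backward_stepwise_regression(y, x, alpha=0.01 / 5)
        wins += res.retained == ["x1"]
    return wins / n_runs


def study_design_unit_count(seed: int = 0) -> dict:
    """240 quadrats (12 plots x 2 fence levels x 10 quadrats) -> 24 units."""
    cfg = GeneratorConfig(seed=seed)
    tree = simulate_tree(cfg.n_pool, seed=cfg.seed)
    traits = simulate_traits(tree, sigma2=cfg.trait_sigma2, seed=cfg.seed)
    cm, _ = simulate_landscape(cfg, tree, traits)
    return {"quadrats": cm.n_units(), "units": aggregate_to_blocks(cm).n_units()}


def random_two_factor(rng):
    """A random identified two-factor model with unit-variance latents."""
    n_ind = int(rng.integers(2, 4))
    obs, rels, theta = [], [], {}
    for f in ("F1", "F2"):
        rels.append(Relation("<->", f, f, 1.0))
        for k in range(n_ind):
            y = f"{f}_y{k}"
            obs.append(y)
            rels.append(Relation("->", f, y))
            lam = rng.uniform(0.4, 0.9)
            theta[f"{f}->{y}"] = lam
            theta[f"{y}<->{y}"] = 1.0 - lam**2 + rng.uniform(0.05, 0.3)
    rels.append(Relation("<->", "F1", "F2"))
    # a two-indicator factor is identified only through its correlation with
    # the rest of the model, so keep it bounded away from zero
    theta["F1<->F2"] = float(rng.choice([-1, 1])) * rng.uniform(0.25, 0.6)
    return SEMSpec(tuple(obs), ("F1", "F2"), rels), theta


def cross_engine_agreement(seed: int = 0, n_specs: int = 20) -> float:
    """Max relative deviation of ML estimates from the independent
    path-tracing reference across random factor models."""
    rng = np.random.default_rng([seed, 107])
    worst = 0.0
    for rep in range(n_specs):
        spec, theta = random_two_factor(rng)
        truth = SEMTruth(
            spec, theta, n_samples=600, seed=int(rng.integers(2**31))
        )
        data = simulate_from_sem(truth)
        s = np.cov(data.to_numpy().T, ddof=1)
        fit = fit_ml(spec, data=data)
        ref, _ = oracles.reference_fit(spec, s)
        for name in spec.free_names:
            rel = abs(fit.estimates[name] - ref[name]) / max(abs(ref[name]), 1e-2)
            worst = max(worst, rel)
    return worst
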
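"""Latent-variable structural equation models fitted by maximum likelihood.

The engine uses the RAM parametrization: stacking observed and latent
variables, a model is an asymmetric path-coefficient matrix ``A`` and a
symmetric (co)variance matrix ``Psi`` of exogenous terms and disturbances,
giving the implied covariance

    Sigma_all = (I - A)^-1 Psi (I - A)^-T

whose observed block is compared to the sample covariance ``S`` (computed
with the N-1 denominator) by the Wishart maximum-likelihood discrepancy

    F_ML(theta) = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p .

At the optimum, chi-square = (N-1) F_ML; standard errors come from the
inverse of the numerically evaluated Hessian of F_ML scaled by 2/(N-1);
critical ratios are estimate/SE with two-sided normal p-values.  No bound
constraints are imposed: inadmissible (Heywood) solutions — negative error
variances, standardized loadings beyond 1 — are reported and flagged, never
clipped, because at small sample sizes they are part of the result.

Latents are scaled to unit variance by default (rather than by a marker
indicator), so loading estimates are free for every indicator and latent
covariances are correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess

__all__ = [
    "SEMSpec",
    "SEMFit",
    "InvalidModel",
    "parse_model",
    "implied_covariance",
    "fit_ml",
    "standardize",
    "squared_multiple_correlation",
    "rmsea",
    "min_sample_size",
    "build_case_study_spec",
]


class InvalidModel(ValueError):
    pass


@dataclass(frozen=True)
class Relation:
    """A directed path (kind ``->``) or covariance (kind ``<->``).

    ``value`` fixes the coefficient; ``None`` leaves it free.  A covariance
    with ``a == b`` is a variance term.
    """

    kind: str
    a: str  # source (paths) / first variable
    b: str  # target (paths) / second variable
    value: float | None = None

    @property
    def name(self) -> str:
        if self.kind == "->":
            return f"{self.a}->{self.b}"
        x, y = sorted((self.a, self.b))
        return f"{x}<->{y}"


class SEMSpec:
    """Declarative latent-variable model.

    Every variable automatically receives a free variance term unless one is
    declared (fixed or free) — for endogenous variables this is the
    disturbance variance.  The directed-path graph must be acyclic and every
    latent must reach at least one observed indicator.
    """

    def __init__(self, observed, latent=(), relations=()):
        self.observed = tuple(observed)
        self.latent = tuple(latent)
        if set(self.observed) & set(self.latent):
            raise InvalidModel("a variable cannot be both observed and latent")
        self.variables = self.observed + self.latent
        order = {v: i for i, v in enumerate(self.variables)}
        rels: list[Relation] = []
        seen = set()
        has_variance = set()
        for r in relations:
            if r.a not in order or r.b not in order:
                unknown = [v for v in (r.a, r.b) if v not in order]
                raise InvalidModel(f"unknown variable(s) {unknown}")
            if r.kind not in ("->", "<->"):
                raise InvalidModel(f"unknown relation kind {r.kind!r}")
            if r.kind == "<->" and order[r.a] > order[r.b]:
                r = Relation("<->", r.b, r.a, r.value)
            if r.name in seen:
                raise InvalidModel(f"duplicate relation {r.name}")
            seen.add(r.name)
            if r.kind == "<->" and r.a == r.b:
                has_variance.add(r.a)
            rels.append(r)
        for v in self.variables:
            if v not in has_variance:
                rels.append(Relation("<->", v, v, None))
        self.relations = tuple(rels)
        self.free_names = tuple(r.name for r in self.relations if r.value is None)
        self._validate()

    def _validate(self) -> None:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(
            (r.a, r.b) for r in self.relations if r.kind == "->"
        )
        if not nx.is_directed_acyclic_graph(g):
            raise InvalidModel("directed-path graph has a cycle")
        for lat in self.latent:
            reach = nx.descendants(g, lat)
            if not reach & set(self.observed):
                raise InvalidModel(f"latent {lat!r} reaches no observed indicator")

    # -- parameter bookkeeping ------------------------------------------------

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    @property
    def df(self) -> int:
        p = len(self.observed)
        return p * (p + 1) // 2 - self.n_free

    def theta_vector(self, theta: dict[str, float]) -> np.ndarray:
        missing = [n for n in self.free_names if n not in theta]
        if missing:
            raise InvalidModel(f"theta missing parameters {missing}")
        return np.array([theta[n] for n in self.free_names], dtype=float)

    def matrices(self, theta) -> tuple[np.ndarray, np.ndarray]:
        """RAM matrices (A, Psi) over (observed + latent) for parameter values."""
        if isinstance(theta, dict):
            theta = self.theta_vector(theta)
        theta = np.asarray(theta, dtype=float)
        n = len(self.variables)
        order = {v: i for i, v in enumerate(self.variables)}
        a = np.zeros((n, n))
        psi = np.zeros((n, n))
        k = 0
        for r in self.relations:
            if r.value is None:
                val = theta[k]
                k += 1
            else:
                val = r.value
            if r.kind == "->":
                a[order[r.b], order[r.a]] = val
            else:
                i, j = order[r.a], order[r.b]
                psi[i, j] = psi[j, i] = val
        return a, psi

    def endogenous(self) -> tuple[str, ...]:
        tgt = {r.b for r in self.relations if r.kind == "->"}
        return tuple(v for v in self.variables if v in tgt)

    # -- plain-text round trip ------------------------------------------------

    def to_text(self) -> str:
        lines = [f"latent {v}" for v in self.latent]
        for r in self.relations:
            rel = f"{r.a} {r.kind} {r.b}"
            lines.append(rel if r.value is None else f"fix {rel} @ {r.value:g}")
        return "\n".join(lines) + "\n"

    def __repr__(self) -> str:
        return (
            f"SEMSpec({len(self.observed)} observed, {len(self.latent)} latent, "
            f"{self.n_free} free parameters, df={self.df})"
        )


def parse_model(text: str) -> SEMSpec:
    """Parse the plain-text model format.

    One relation per line: ``A -> B`` (path), ``A <-> B`` (covariance),
    ``fix A -> B @ 1`` (fixed coefficient), ``latent F`` (declares a latent).
    Variables not declared latent are observed; ``#`` starts a comment.
    """
    latent: list[str] = []
    relations: list[Relation] = []
    mentioned: list[str] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        value = None
        if line.startswith("fix "):
            body, _, val = line[4:].partition("@")
            value = float(val)
            line = body.strip()
        elif line.startswith("latent "):
            for v in line.split()[1:]:
                latent.append(v)
            continue
        for kind in ("<->", "->"):
            if f" {kind} " in line:
                a, b = (s.strip() for s in line.split(f" {kind} ", 1))
                relations.append(Relation(kind, a, b, value))
                mentioned += [a, b]
                break
        else:
            raise InvalidModel(f"cannot parse model line: {raw!r}")
    observed = []
    for v in mentioned:
        if v not in latent and v not in observed:
            observed.append(v)
    return SEMSpec(observed, latent, relations)


# ---------------------------------------------------------------------------
# implied covariance and the ML discrepancy


def _sigma_all(spec: SEMSpec, theta) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a, psi = spec.matrices(theta)
    n = a.shape[0]
    ima = np.eye(n) - a
    try:
        b = np.linalg.inv(ima)
    except np.linalg.LinAlgError as exc:
        raise InvalidModel("(I - A) is singular") from exc
    sall = b @ psi @ b.T
    return sall, b, psi


def implied_covariance(spec: SEMSpec, theta) -> np.ndarray:
    """Model-implied covariance matrix over the observed variables."""
    sall, _, _ = _sigma_all(spec, theta)
    p = len(spec.observed)
    sigma = sall[:p, :p]
    return (sigma + sigma.T) / 2.0


def _fml_and_grad(spec: SEMSpec, theta, s_obs, logdet_s):
    """F_ML and its analytic gradient in one pass.

    Uses d F = tr[W dSigma] with W = Sigma^-1 - Sigma^-1 S Sigma^-1; path and
    (co)variance derivatives reduce to entries of precomputed matrix products.
    """
    p = len(spec.observed)
    sall, b, psi = _sigma_all(spec, theta)
    sigma = (sall[:p, :p] + sall[:p, :p].T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(sigma)
    if eigvals[0] <= 1e-10:
        # outside the positive-definite region: climb the smallest eigenvalue
        # back up (dF = tr[W dSigma] still applies with W = -pen * v v^T)
        pen = 1e4
        v = eigvecs[:, 0]
        f = pen * (1e-10 - eigvals[0]) + 1e3
        w = -pen * np.outer(v, v)
    else:
        isig = eigvecs @ np.diag(1.0 / eigvals) @ eigvecs.T
        f = float(np.sum(np.log(eigvals))) - logdet_s + float(np.trace(s_obs @ isig)) - p
        w = isig - isig @ s_obs @ isig
    n = len(spec.variables)
    wfull = np.zeros((n, n))
    wfull[:p, :p] = w
    bobs = b[:p, :]
    g_psi = bobs.T @ w @ bobs  # symmetric
    m_path = sall @ wfull @ b
    order = {v: i for i, v in enumerate(spec.variables)}
    grad = np.empty(spec.n_free)
    k = 0
    for r in spec.relations:
        if r.value is not None:
            continue
        if r.kind == "->":
            grad[k] = 2.0 * m_path[order[r.a], order[r.b]]
        else:
            i, j = order[r.a], order[r.b]
            grad[k] = g_psi[i, i] if i == j else 2.0 * g_psi[i, j]
        k += 1
    return f, grad


# ---------------------------------------------------------------------------
# fitting


@dataclass
class SEMFit:
    """A fitted model: estimates, uncertainties and global fit indices."""

    spec: SEMSpec
    estimates: dict[str, float]
    se: dict[str, float]
    fml: float
    chi2: float
    df: int
    n: int
    converged: bool
    n_restarts: int
    s_obs: np.ndarray
    heywood: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def cr(self) -> dict[str, float]:
        return {
            k: (self.estimates[k] / self.se[k] if self.se.get(k) else float("nan"))
            for k in self.estimates
        }

    @property
    def p_values(self) -> dict[str, float]:
        return {
            k: 2.0 * stats.norm.sf(abs(v)) if math.isfinite(v) else float("nan")
            for k, v in self.cr.items()
        }

    @property
    def rmsea(self) -> float:
        return rmsea(self.chi2, self.df, self.n)[0]

    @property
    def pclose(self) -> float:
        return rmsea(self.chi2, self.df, self.n)[1]

    def implied(self) -> np.ndarray:
        return implied_covariance(self.spec, self.estimates)

    def table(self) -> pd.DataFrame:
        """Per-parameter report: estimate, s.e., standardized, C.R., p."""
        std = standardize(self)
        rows = []
        for r in self.spec.relations:
            if r.value is not None:
                continue
            name = r.name
            rows.append(
                {
                    "relation": f"{r.b} <- {r.a}" if r.kind == "->" else f"{r.a} <-> {r.b}",
                    "parameter": name,
                    "estimate": self.estimates[name],
                    "se": self.se[name],
                    "standardized": std[name],
                    "cr": self.cr[name],
                    "p": self.p_values[name],
                }
            )
        return pd.DataFrame(rows)


def _start_values(spec: SEMSpec, s_obs: np.ndarray) -> np.ndarray:
    """Paths start at 0.5; observed variance terms at the sample variance,
    latent variances/disturbances at 1; covariances at 0."""
    p = len(spec.observed)
    order = {v: i for i, v in enumerate(spec.variables)}
    theta0 = []
    for r in spec.relations:
        if r.value is not None:
            continue
        if r.kind == "->":
            theta0.append(0.5)
        elif r.a == r.b:
            i = order[r.a]
            theta0.append(float(s_obs[i, i]) if i < p else 1.0)
        else:
            theta0.append(0.0)
    return np.array(theta0)


def fit_ml(
    spec: SEMSpec,
    data: pd.DataFrame | None = None,
    s_obs: np.ndarray | None = None,
    n: int | None = None,
    max_restarts: int = 20,
    gtol: float = 1e-6,
    restart_seed: int = 0,
) -> SEMFit:
    """Fit by minimizing the ML discrepancy F_ML.

    Supply either a data table (columns must cover the observed variables)
    or a sample covariance ``s_obs`` (N-1 denominator) with its sample size
    ``n``.  Quasi-Newton (BFGS) with analytic gradient; on non-convergence up
    to ``max_restarts`` jittered restarts.  Heywood cases (negative variance
    terms, |standardized| > 1) are flagged, not prevented.
    """
    p = len(spec.observed)
    if data is not None:
        sub = data.loc[:, list(spec.observed)].astype(float)
        n = len(sub)
        s_obs = np.cov(sub.to_numpy().T, ddof=1)
    if s_obs is None or n is None:
        raise ValueError("supply data or (s_obs, n)")
    s_obs = np.asarray(s_obs, dtype=float)
    if s_obs.shape != (p, p):
        raise ValueError("s_obs shape does not match observed variables")
    if n <= p:
        raise ValueError("sample size must exceed the number of observed variables")
    eig = np.linalg.eigvalsh((s_obs + s_obs.T) / 2)
    if eig[0] <= 0:
        raise ValueError("sample covariance is not positive definite")

    # optimize on the unit-variance rescaling of S (the ML discrepancy is
    # invariant under diagonal rescaling of the observed variables), then map
    # estimates and standard errors back to the raw scale; this keeps the
    # problem well conditioned when observed variances differ by orders of
    # magnitude
    d_obs = np.sqrt(np.diag(s_obs))
    s_scaled = s_obs / np.outer(d_obs, d_obs)
    scale = {v: d for v, d in zip(spec.observed, d_obs)}  # latents stay at 1
    factors = np.array(
        [
            (scale.get(r.b, 1.0) / scale.get(r.a, 1.0))
            if r.kind == "->"
            else (scale.get(r.a, 1.0) * scale.get(r.b, 1.0))
            for r in spec.relations
            if r.value is None
        ]
    )
    sign, logdet_s = np.linalg.slogdet(s_scaled)

    def objective(theta):
        return _fml_and_grad(spec, theta, s_scaled, logdet_s)

    def hessp(x, p):
        # Hessian-vector product by central differences of the analytic
        # gradient; keeps the Newton polish cheap at any parameter count
        h = 1e-6 * max(1.0, float(np.linalg.norm(x))) / max(float(np.linalg.norm(p)), 1e-12)
        return (objective(x + h * p)[1] - objective(x - h * p)[1]) / (2 * h)

    def newton_polish(x):
        """Newton-CG refinement: BFGS stalls on the flat ridges that
        small-sample (Heywood-prone) problems produce near the optimum."""
        res = optimize.minimize(
            objective, x, jac=True, hessp=hessp, method="Newton-CG",
            options={"xtol": 1e-12, "maxiter": 50},
        )
        f, g = objective(res.x)
        return res.x, f, g

    theta0 = _start_values(spec, s_scaled)
    rng = np.random.default_rng(restart_seed)
    best = None
    n_restarts = 0
    converged = False
    no_improve = 0
    start = theta0
    for attempt in range(max_restarts + 1):
        res = optimize.minimize(
            objective, start, jac=True, method="BFGS",
            options={"gtol": gtol * 1e-2, "maxiter": 300},
        )
        gnorm = float(np.max(np.abs(res.jac)))
        if gtol * 1e-3 <= gnorm < 1e-2 and res.fun < 1e3:
            x, f, g = newton_polish(res.x)
            res.x, res.fun, res.jac = x, f, g
            gnorm = float(np.max(np.abs(g)))
        if best is None or res.fun < best[0].fun - max(1e-10, 1e-7 * abs(best[0].fun)):
            best = (res, gnorm)
            no_improve = 0
        else:
            no_improve += 1
        # a genuine optimum must lie inside the positive-definite region,
        # i.e. below the barrier offset of the penalized objective
        if gnorm < gtol and np.isfinite(res.fun) and res.fun < 1e3:
            converged = True
            best = (res, gnorm)
            break
        if no_improve >= 6 or (n_restarts >= 10 and np.max(np.abs(best[0].x)) > 50):
            # restarts have stagnated or a parameter is running away on the
            # standardized scale: typically an unbounded (runaway Heywood)
            # likelihood where no interior optimum exists
            break
        n_restarts += 1
        if n_restarts % 2 and np.all(np.isfinite(best[0].x)) and np.max(np.abs(best[0].x)) <= 50:
            # polish: re-launch near the best point found so far (unless it
            # is a runaway iterate — chasing those never terminates)
            start = best[0].x + 0.005 * rng.standard_normal(theta0.shape)
        else:
            start = theta0 * (1.0 + 0.3 * rng.standard_normal(theta0.shape)) + 0.1 * rng.standard_normal(theta0.shape)
    res, gnorm = best
    theta_hat = res.x
    # final gradient-norm refinement: near the optimum F itself bottoms out
    # at double-precision noise (it is quadratic in the residual) while the
    # analytic gradient still carries signal, so drive the gradient down
    # directly with Newton steps solved by conjugate gradients
    if np.isfinite(res.fun) and res.fun < 1e3:
        from scipy.sparse.linalg import LinearOperator, cg

        x = theta_hat
        _, g = objective(x)
        gn = float(np.max(np.abs(g)))
        for _ in range(5):
            if gn < gtol * 1e-6:
                break
            op = LinearOperator((len(x), len(x)), matvec=lambda p: hessp(x, p))
            step, info = cg(op, g, rtol=1e-10, maxiter=100)
            if info != 0:
                break
            x_new = x - step
            _, g_new = objective(x_new)
            gn_new = float(np.max(np.abs(g_new)))
            if not np.isfinite(gn_new) or gn_new >= gn:
                break
            x, g, gn = x_new, g_new, gn_new
        if gn < gnorm:
            theta_hat, gnorm = x, gn
            if gn < gtol:
                converged = True
    fml = max(float(res.fun), 0.0)
    estimates = dict(zip(spec.free_names, theta_hat * factors))

    hess = approx_hess(theta_hat, lambda t: _fml_and_grad(spec, t, s_scaled, logdet_s)[0])
    se = {}
    try:
        acov = (2.0 / (n - 1)) * np.linalg.inv(hess)
        diag = np.diag(acov)
        for name, v, fac in zip(spec.free_names, diag, factors):
            se[name] = float(np.sqrt(v)) * fac if v > 0 else float("nan")
    except np.linalg.LinAlgError:
        se = {name: float("nan") for name in spec.free_names}

    notes = []
    if not converged:
        notes.append(
            f"non-convergence: best gradient sup-norm {gnorm:.2e} after "
            f"{n_restarts} restart(s)"
        )
    if np.max(np.abs(theta_hat)) > 50:
        notes.append(
            "runaway parameter on the standardized scale: the likelihood "
            "may be unbounded (severe Heywood direction)"
        )
    chi2 = (n - 1) * fml
    fit = SEMFit(
        spec=spec,
        estimates=estimates,
        se=se,
        fml=fml,
        chi2=chi2,
        df=spec.df,
        n=n,
        converged=converged,
        n_restarts=n_restarts,
        s_obs=s_obs,
        notes=notes,
    )
    fit.heywood = _heywood_flags(fit)
    return fit


def _heywood_flags(fit: SEMFit) -> list[str]:
    flags = []
    for r in fit.spec.relations:
        if r.value is None and r.kind == "<->" and r.a == r.b:
            if fit.estimates[r.name] < 0:
                flags.append(f"negative variance: {r.name}")
    sall, _, _ = _sigma_all(fit.spec, fit.estimates)
    for v, var in zip(fit.spec.variables, np.diag(sall)):
        if var <= 0:
            flags.append(f"non-positive implied variance: {v}")
    std = standardize(fit)
    for r in fit.spec.relations:
        if r.value is None and r.kind == "->" and abs(std[r.name]) > 1:
            flags.append(f"standardized coefficient beyond unity: {r.name}")
    return flags


def standardize(fit: SEMFit) -> dict[str, float]:
    """Standardized estimates under the fitted implied covariance.

    Paths are scaled by sd(source)/sd(target); covariances become
    correlations; variance terms become proportions of the variable's implied
    variance.  Values beyond +-1 (Heywood) are reported untouched.
    """
    sall, _, _ = _sigma_all(fit.spec, fit.estimates)
    order = {v: i for i, v in enumerate(fit.spec.variables)}
    var = np.diag(sall)
    # a non-positive implied variance (extreme Heywood case) makes the
    # standardization of relations touching that variable undefined: those
    # entries are NaN and the condition is flagged on the fit
    sd = np.where(var > 0, np.sqrt(np.abs(var)), np.nan)
    out = {}
    for r in fit.spec.relations:
        if r.value is not None:
            continue
        est = fit.estimates[r.name]
        if r.kind == "->":
            out[r.name] = est * sd[order[r.a]] / sd[order[r.b]]
        else:
            out[r.name] = est / (sd[order[r.a]] * sd[order[r.b]])
    return out


def squared_multiple_correlation(fit: SEMFit, variable: str) -> float:
    """R^2 of an endogenous variable: 1 - disturbance/implied variance."""
    if variable not in fit.spec.endogenous():
        raise ValueError(f"{variable!r} is not endogenous")
    sall, _, psi = _sigma_all(fit.spec, fit.estimates)
    i = fit.spec.variables.index(variable)
    return 1.0 - psi[i, i] / sall[i, i]


def rmsea(chi2: float, df: int, n: int, rmsea0: float = 0.05) -> tuple[float, float]:
    """RMSEA and the close-fit probability PCLOSE.

    RMSEA = sqrt(max(chi2 - df, 0) / (df (N-1))).  PCLOSE is the upper-tail
    probability of the observed chi-square under a noncentral chi-square with
    noncentrality (N-1) df rmsea0^2 — the test of H0: RMSEA <= ``rmsea0``.
    """
    if df < 1:
        return float("nan"), float("nan")
    if n < 2:
        raise ValueError("n must be at least 2")
    val = math.sqrt(max(chi2 - df, 0.0) / (df * (n - 1)))
    nc = (n - 1) * df * rmsea0**2
    pclose = float(stats.ncx2.sf(chi2, df, nc))
    return val, pclose


def min_sample_size(n_params: int, ratio: float = 10) -> int:
    """Rule-of-thumb minimum N: ``ratio`` observations per free parameter."""
    if n_params < 0:
        raise ValueError("n_params must be non-negative")
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return int(round(n_params * ratio))


# ---------------------------------------------------------------------------
# the case-study model


CASE_STUDY_OBSERVED = (
    "Shannon",
    "Simpson",
    "FD_Divergence",
    "FD_Evenness",
    "Faith",
    "MPD",
    "Total_Cover",
    "nTaxa",
)

CASE_STUDY_INDICATORS = {
    "TD": ("Shannon", "Simpson"),
    "FD": ("FD_Divergence", "FD_Evenness"),
    "PD": ("Faith", "MPD"),
}


def build_case_study_spec(variant: str = "covariate") -> SEMSpec:
    """The three-latent biodiversity model.

    Latents TD, FD and PD (unit variance) each load on two indicators and
    jointly regress total understory cover; the latents covary pairwise.
    ``variant`` controls the placement of species richness (nTaxa):
    ``covariate`` (default) lets nTaxa covary with each latent, ``indicator``
    attaches it as a third TD indicator, ``omitted`` drops it.
    """
    if variant not in ("covariate", "indicator", "omitted"):
        raise ValueError(f"unknown variant {variant!r}")
    latents = ("TD", "FD", "PD")
    rels: list[Relation] = []
    for lat, inds in CASE_STUDY_INDICATORS.items():
        for ind in inds:
            rels.append(Relation("->", lat, ind))
    for lat in latents:
        rels.append(Relation("->", lat, "Total_Cover"))
        rels.append(Relation("<->", lat, lat, 1.0))  # unit-variance scaling
    rels.append(Relation("<->", "TD", "FD"))
    rels.append(Relation("<->", "PD", "FD"))
    rels.append(Relation("<->", "PD", "TD"))
    observed = list(CASE_STUDY_OBSERVED)
    if variant == "omitted":
        observed.remove("nTaxa")
    elif variant == "covariate":
        for lat in latents:
            rels.append(Relation("<->", "nTaxa", lat))
    else:  # indicator
        rels.append(Relation("->", "TD", "nTaxa"))
    return SEMSpec(observed, latents, rels)
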
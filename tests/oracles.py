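"""Independent brute-force reference implementations used only by tests.

Everything here deliberately avoids the code paths of the package: minimum
spanning trees by exhaustive enumeration, convex-hull membership by linear
programming, hull volumes by Delaunay simplex determinants, phylogenetic
distances by explicit root-path traversal, implied covariances by
path-tracing over the model graph, and a reference ML fitter driven by a
finite-difference quasi-Newton method on the path-traced covariance.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from scipy import optimize
from scipy.spatial import Delaunay


# ---------------------------------------------------------------------------
# diversity metric oracles


def shannon_oracle(p):
    return -sum(pi * np.log(pi) for pi in p if pi > 0)


def simpson_oracle(p):
    return 1.0 - sum(pi**2 for pi in p)


def mst_oracle(dist: np.ndarray):
    """Minimum spanning tree by exhaustive enumeration of spanning trees.

    Feasible for S <= 7.  Ties resolved toward the lexicographically
    smallest edge set, matching the package's tie-break.
    """
    s = dist.shape[0]
    if s == 1:
        return []
    edges = [(i, j) for i in range(s) for j in range(i + 1, s)]
    best = None
    for combo in itertools.combinations(edges, s - 1):
        g = nx.Graph(combo)
        if g.number_of_nodes() == s and nx.is_connected(g):
            total = sum(dist[i, j] for i, j in combo)
            key = (total, sorted(combo))
            if best is None or key < best[0]:
                best = (key, combo)
    return sorted(best[1])


def kruskal_mst(dist: np.ndarray):
    """MST by Kruskal with union-find (ties by lexicographic pair order)."""
    s = dist.shape[0]
    parent = list(range(s))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    edges = sorted(
        (dist[i, j], (i, j)) for i in range(s) for j in range(i + 1, s)
    )
    out = []
    for _, (i, j) in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            out.append((i, j))
        if len(out) == s - 1:
            break
    return sorted(out)


def feve_oracle(coords: np.ndarray, p: np.ndarray):
    """FEve recomputed from raw coordinates with an independent MST."""
    s = len(p)
    dist = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    edges = kruskal_mst(dist) if s > 6 else mst_oracle(dist)
    ew = [dist[i, j] / (p[i] + p[j]) for i, j in edges]
    pew = np.array(ew) / np.sum(ew)
    thr = 1.0 / (s - 1)
    return (np.minimum(pew, thr).sum() - thr) / (1.0 - thr)


def hull_vertices_oracle(points: np.ndarray):
    """Hull vertices by LP: a point is interior iff it is a convex
    combination of the others."""
    n, d = points.shape
    verts = []
    for i in range(n):
        others = np.delete(points, i, axis=0)
        # find lambda >= 0, sum lambda = 1, others^T lambda = points[i]
        a_eq = np.vstack([others.T, np.ones(n - 1)])
        b_eq = np.concatenate([points[i], [1.0]])
        res = optimize.linprog(
            np.zeros(n - 1), A_eq=a_eq, b_eq=b_eq, bounds=[(0, None)] * (n - 1),
            method="highs",
        )
        if not res.success:
            verts.append(i)
    return np.array(verts)


def _project_to_span(points: np.ndarray, tol=1e-9):
    centered = points - points.mean(axis=0)
    u, sing, vt = np.linalg.svd(centered, full_matrices=False)
    scale = max(sing[0], 1.0) if sing.size else 1.0
    rank = int((sing > tol * scale).sum())
    return centered @ vt[:rank].T, rank


def fdiv_oracle(coords: np.ndarray, p: np.ndarray):
    proj, rank = _project_to_span(coords)
    verts = hull_vertices_oracle(proj) if rank > 1 else np.array(
        sorted({int(np.argmin(proj[:, 0])), int(np.argmax(proj[:, 0]))})
    )
    g = coords[verts].mean(axis=0)
    dg = np.linalg.norm(coords - g, axis=1)
    dbar = dg.mean()
    dd = float((p * (dg - dbar)).sum())
    dabs = float((p * np.abs(dg - dbar)).sum())
    return (dd + dbar) / (dabs + dbar)


def fric_oracle(coords: np.ndarray):
    """Convex-hull volume as a sum of Delaunay simplex determinants."""
    proj, rank = _project_to_span(coords)
    if rank == 1:
        return float(proj[:, 0].max() - proj[:, 0].min())
    proj = proj[:, :rank]
    tri = Delaunay(proj)
    vol = 0.0
    for simplex in tri.simplices:
        pts = proj[simplex]
        mat = pts[1:] - pts[0]
        vol += abs(np.linalg.det(mat)) / _factorial(rank)
    return vol


def _factorial(k):
    out = 1
    for i in range(2, k + 1):
        out *= i
    return out


# ---------------------------------------------------------------------------
# phylogenetic oracles (independent traversal on a dendropy tree)


def _root_path_edges(tree, label):
    """Edges (as node ids) from a tip up to the root, with lengths."""
    leaf = next(l for l in tree.leaf_node_iter() if l.taxon.label == label)
    path = []
    node = leaf
    while node.parent_node is not None:
        path.append((id(node), node.edge.length or 0.0))
        node = node.parent_node
    return path


def faith_pd_oracle(tree, present):
    """Union of root-to-tip edge sets, summed once per edge."""
    edges = {}
    for label in set(present):
        for eid, length in _root_path_edges(tree, label):
            edges[eid] = length
    return sum(edges.values())


def patristic_oracle(tree, a, b):
    """Patristic distance via the symmetric difference of root paths."""
    pa = dict(_root_path_edges(tree, a))
    pb = dict(_root_path_edges(tree, b))
    keys = set(pa) ^ set(pb)
    return sum(pa.get(k, 0.0) + pb.get(k, 0.0) for k in keys)


def mpd_oracle(tree, species, p):
    num = den = 0.0
    for i in range(len(species)):
        for j in range(i + 1, len(species)):
            w = p[i] * p[j]
            if w > 0:
                num += w * patristic_oracle(tree, species[i], species[j])
                den += w
    return num / den


# ---------------------------------------------------------------------------
# SEM oracles


def make_path_tracer(spec):
    """Build a fast implied-covariance function by enumerating, once, every
    directed route through the model graph: with T[i, j] the total effect of
    j on i (sum over routes of the product of path coefficients),
    Sigma_all = T Psi T'."""
    order = {v: i for i, v in enumerate(spec.variables)}
    n = len(spec.variables)
    p = len(spec.observed)
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    edge_param = {}
    psi_terms = []  # (i, j, name-or-fixed)
    for r in spec.relations:
        if r.kind == "->":
            g.add_edge(order[r.a], order[r.b])
            edge_param[(order[r.a], order[r.b])] = r
        else:
            psi_terms.append((order[r.a], order[r.b], r))
    # every simple path, stored as the list of its edge relations
    routes = []  # (dst, src, [relations])
    for src in range(n):
        for dst in range(n):
            if src == dst:
                continue
            for path in nx.all_simple_paths(g, src, dst):
                rels = [edge_param[(a, b)] for a, b in zip(path[:-1], path[1:])]
                routes.append((dst, src, rels))

    def sigma(theta):
        if not isinstance(theta, dict):
            theta = dict(zip(spec.free_names, np.asarray(theta, dtype=float)))

        def value(r):
            return r.value if r.value is not None else theta[r.name]

        psi = np.zeros((n, n))
        for i, j, r in psi_terms:
            psi[i, j] = psi[j, i] = value(r)
        t = np.eye(n)
        for dst, src, rels in routes:
            prod = 1.0
            for r in rels:
                prod *= value(r)
            t[dst, src] += prod
        sall = t @ psi @ t.T
        return sall[:p, :p]

    return sigma


def path_tracing_sigma(spec, theta):
    return make_path_tracer(spec)(theta)


def reference_fit(spec, s_obs, theta0=None):
    """Reference ML estimates: finite-difference L-BFGS-B on the
    path-traced implied covariance (no shared code with the engine)."""
    p = s_obs.shape[0]
    sign, logdet_s = np.linalg.slogdet(s_obs)
    tracer = make_path_tracer(spec)

    def fml(theta):
        sigma = tracer(theta)
        sigma = (sigma + sigma.T) / 2
        eigvals, eigvecs = np.linalg.eigh(sigma)
        if eigvals[0] < 1e-10:
            return 1e6 * (1.0 + abs(float(eigvals[0])))
        inv = eigvecs @ np.diag(1.0 / eigvals) @ eigvecs.T
        return (
            float(np.sum(np.log(eigvals))) - logdet_s
            + float(np.trace(s_obs @ inv)) - p
        )

    if theta0 is None:
        theta0 = []
        for r in spec.relations:
            if r.value is not None:
                continue
            if r.kind == "->":
                theta0.append(0.4)
            elif r.a == r.b:
                i = spec.variables.index(r.a)
                theta0.append(float(s_obs[i, i]) if i < p else 1.0)
            else:
                theta0.append(0.0)
        theta0 = np.array(theta0)
    res = optimize.minimize(
        fml, theta0, method="L-BFGS-B", jac="3-point",
        options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12},
    )
    # polish with a derivative-free pass until stationary
    for _ in range(4):
        res2 = optimize.minimize(
            fml, res.x, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": 20000, "adaptive": True},
        )
        improved = res2.fun < res.fun - 1e-13
        if res2.fun < res.fun:
            res = res2
        if not improved:
            break
        res3 = optimize.minimize(
            fml, res.x, method="L-BFGS-B", jac="3-point",
            options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12},
        )
        if res3.fun < res.fun:
            res = res3
    return dict(zip(spec.free_names, res.x)), float(res.fun)


# ---------------------------------------------------------------------------
# MANOVA oracle (determinant / trace route, no shared eigen code path)


def manova_oracle(y: np.ndarray, groups: np.ndarray):
    levels = list(dict.fromkeys(groups.tolist()))
    grand = y.mean(axis=0)
    q = y.shape[1]
    h = np.zeros((q, q))
    e = np.zeros((q, q))
    for lev in levels:
        sub = y[np.asarray(groups) == lev]
        d = (sub.mean(axis=0) - grand)[:, None]
        h += len(sub) * (d @ d.T)
        r = sub - sub.mean(axis=0)
        e += r.T @ r
    wilks = np.linalg.det(e) / np.linalg.det(h + e)
    pillai = float(np.trace(h @ np.linalg.inv(h + e)))
    hl = float(np.trace(h @ np.linalg.inv(e)))
    roy = float(np.max(np.real(np.linalg.eigvals(np.linalg.inv(e) @ h))))
    return wilks, pillai, hl, roy
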
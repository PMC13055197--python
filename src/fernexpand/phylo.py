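"""Phylogenetic comparative fits: Pagel's lambda, GLS regression, and
phylogenetically corrected reduced major axis (RMA) regression.

Under Brownian motion the expected covariance of a trait between two tips is
proportional to the shared branch length from the root to their most recent
common ancestor.  Pagel's lambda rescales the off-diagonal entries of that
covariance matrix by a factor in [0, 1]: 0 removes all phylogenetic signal
(a star phylogeny), 1 keeps the full Brownian expectation.  Lambda is
estimated by profile maximum likelihood with a bounded scalar search.

Two fits are provided:

* ``fit_phylo_lm`` — GLS linear regression with jointly estimated lambda;
  the GEP~CEP and trait~environment suites use this machinery.
* ``fit_phylo_rma`` — reduced major axis regression on phylogenetically
  corrected means and (co)variances: slope = sign(cov) * sqrt(var_y/var_x).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

_RSS_FLOOR = 1e-12
_LAMBDA_TOL = 1e-6


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    lam: float
    r_squared: float
    p_value: float
    n: int
    method: str
    lambda_profile: list = field(default_factory=list)  # (lambda, loglik) diagnostics

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


# ---------------------------------------------------------------------------
# trees and covariance
# ---------------------------------------------------------------------------

def read_newick(source: str) -> dendropy.Tree:
    kwargs = {"schema": "newick", "preserve_underscores": True}
    if "(" in source:
        return dendropy.Tree.get(data=source, **kwargs)
    return dendropy.Tree.get(path=source, **kwargs)


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", unquoted_underscores=True).strip()


def tip_labels(tree: dendropy.Tree):
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def prune_tree(tree: dendropy.Tree, taxa):
    """Induced subtree on ``taxa``; degree-2 nodes are collapsed with branch
    lengths summed.  Returns ``(pruned_tree, missing_taxa)``; fails when fewer
    than 3 requested taxa are present in the tree."""
    present = set(tip_labels(tree))
    taxa = list(taxa)
    missing = [t for t in taxa if t not in present]
    keep = [t for t in taxa if t in present]
    if len(keep) < 3:
        raise ValueError(f"fewer than 3 requested taxa present (missing: {missing})")
    pruned = tree.extract_tree_with_taxa_labels(labels=keep)
    pruned.taxon_namespace = pruned.update_taxon_namespace()
    return pruned, missing


def phylo_covariance(tree: dendropy.Tree, taxa=None):
    """Phylogenetic covariance matrix C with C[i, j] = root-to-MRCA shared
    branch length; returns ``(C, labels)`` in ``taxa`` order."""
    labels = list(taxa) if taxa is not None else tip_labels(tree)
    tree = tree.clone(depth=1)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    missing = [t for t in labels if t not in leaves]
    if missing:
        raise ValueError(f"taxa not in tree: {missing}")
    pdm = tree.phylogenetic_distance_matrix()
    n = len(labels)
    C = np.zeros((n, n))
    for i, a in enumerate(labels):
        C[i, i] = leaves[a].root_distance
        for j in range(i + 1, n):
            b = labels[j]
            d = pdm.patristic_distance(leaves[a].taxon, leaves[b].taxon)
            shared = 0.5 * (leaves[a].root_distance + leaves[b].root_distance - d)
            C[i, j] = C[j, i] = max(shared, 0.0)
    return C, labels


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Multiply off-diagonal covariances by lambda; diagonal unchanged."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    V = lam * np.asarray(C, dtype=float)
    np.fill_diagonal(V, np.diag(C))
    return V


def simulate_brownian(C: np.ndarray, sigma: float, rng, lam: float = 1.0) -> np.ndarray:
    """One Brownian-motion deviate with covariance sigma^2 * lambda_transform(C, lam)."""
    V = lambda_transform(C, lam)
    L = np.linalg.cholesky(V + 1e-12 * np.eye(V.shape[0]))
    return sigma * (L @ rng.standard_normal(V.shape[0]))


# ---------------------------------------------------------------------------
# GLS internals
# ---------------------------------------------------------------------------

def _gls(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """GLS solve; returns (beta, rss_V, logdet_V, XtViX_inv)."""
    cho = cho_factor(V, lower=True)
    Vi_y = cho_solve(cho, y)
    Vi_X = cho_solve(cho, X)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    resid = y - X @ beta
    rss = float(resid @ cho_solve(cho, resid))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    return beta, rss, logdet, np.linalg.inv(XtViX)


def _profile_loglik(lam: float, y: np.ndarray, X: np.ndarray, C: np.ndarray) -> float:
    """Profile (ML) log-likelihood of lambda with beta and sigma^2 profiled out."""
    n = len(y)
    V = lambda_transform(C, lam)
    _, rss, logdet, _ = _gls(y, X, V)
    sigma2 = max(rss, _RSS_FLOOR) / n
    return -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)


def estimate_lambda(y: np.ndarray, X: np.ndarray, C: np.ndarray):
    """Bounded 1-D profile-ML search for lambda; boundary optima are reported
    as exactly 0 or 1.  Returns ``(lambda_hat, profile_grid)``."""
    res = minimize_scalar(lambda lam: -_profile_loglik(lam, y, X, C),
                          bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": _LAMBDA_TOL})
    candidates = {float(res.x): -res.fun}
    for lam in (0.0, 1.0):
        candidates[lam] = _profile_loglik(lam, y, X, C)
    lam_hat = max(candidates, key=candidates.get)
    if lam_hat < 10 * _LAMBDA_TOL:
        lam_hat = 0.0
    elif lam_hat > 1.0 - 10 * _LAMBDA_TOL:
        lam_hat = 1.0
    grid = [(lam, _profile_loglik(lam, y, X, C)) for lam in (0.0, 0.25, 0.5, 0.75, 1.0)]
    return lam_hat, grid


def _align(values, labels, tree_labels):
    v = np.asarray(values, dtype=float)
    if labels is None:
        if len(v) != len(tree_labels):
            raise ValueError("values not aligned to tips; pass labels")
        return v
    order = {lab: i for i, lab in enumerate(labels)}
    return v[[order[lab] for lab in tree_labels]]


# ---------------------------------------------------------------------------
# public fits
# ---------------------------------------------------------------------------

def fit_phylo_lm(y, X, tree, labels=None, fix_lambda=None) -> RegressionFit:
    """Phylogenetic GLS linear regression with estimated (or fixed) lambda.

    ``X`` may be a 1-D predictor vector or an n x p matrix; an intercept is
    added internally and the reported slope/p-value refer to the first
    predictor column.  R^2 is GLS-based: 1 − RSS/TSS about the GLS mean.
    """
    C, tree_labels = phylo_covariance(tree)
    yv = _align(y, labels, tree_labels)
    Xv = np.asarray(X, dtype=float)
    if Xv.ndim == 1:
        Xv = Xv[:, None]
    Xv = np.column_stack([_align(Xv[:, j], labels, tree_labels) for j in range(Xv.shape[1])])
    n, p = Xv.shape
    if n < 3 + p:
        raise ValueError("too few species for the requested design")
    design = np.column_stack([np.ones(n), Xv])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("singular design matrix")

    if fix_lambda is not None:
        lam, grid = float(fix_lambda), []
    else:
        lam, grid = estimate_lambda(yv, design, C)
    V = lambda_transform(C, lam)
    beta, rss, _, XtViX_inv = _gls(yv, design, V)

    mu, tss, _, _ = _gls(yv, np.ones((n, 1)), V)
    tss = max(tss, _RSS_FLOOR)
    r2 = float(np.clip(1.0 - rss / tss, 0.0, 1.0))

    dof = n - design.shape[1]
    sigma2 = max(rss, _RSS_FLOOR) / max(dof, 1)
    se = float(np.sqrt(sigma2 * XtViX_inv[1, 1]))
    t = beta[1] / se if se > 0 else np.inf
    p_val = float(np.clip(2.0 * stats.t.sf(abs(t), max(dof, 1)), 1e-300, 1.0))

    return RegressionFit(slope=float(beta[1]), intercept=float(beta[0]), lam=lam,
                         r_squared=r2, p_value=p_val, n=n, method="phylo_lm",
                         lambda_profile=grid)


def _phylo_moments(v: np.ndarray, w: np.ndarray, V: np.ndarray):
    cho = cho_factor(V, lower=True)
    one = np.ones(len(v))
    Vi1 = cho_solve(cho, one)
    denom = float(one @ Vi1)
    mv, mw = float(v @ Vi1) / denom, float(w @ Vi1) / denom
    rv, rw = v - mv, w - mw
    Vi_rw = cho_solve(cho, rw)
    var_v = float(rv @ cho_solve(cho, rv)) / (len(v) - 1)
    var_w = float(rw @ Vi_rw) / (len(v) - 1)
    cov = float(rv @ Vi_rw) / (len(v) - 1)
    return mv, mw, var_v, var_w, cov


def fit_phylo_rma(x, y, tree, labels=None, fix_lambda=None) -> RegressionFit:
    """Phylogenetic reduced major axis regression.

    Lambda is estimated jointly on the two intercept-only likelihoods (shared
    lambda), then phylogenetically corrected moments give
    slope = sign(cov_xy) * sqrt(var_y / var_x), R^2 = corr^2, and an analytic
    t-test of zero correlation.
    """
    C, tree_labels = phylo_covariance(tree)
    xv = _align(x, labels, tree_labels)
    yv = _align(y, labels, tree_labels)
    n = len(xv)
    if n < 3:
        raise ValueError("RMA needs at least 3 species")
    ones = np.ones((n, 1))
    if fix_lambda is not None:
        lam, grid = float(fix_lambda), []
    else:
        def joint_neg(lam):
            return -(_profile_loglik(lam, xv, ones, C) + _profile_loglik(lam, yv, ones, C))
        res = minimize_scalar(joint_neg, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": _LAMBDA_TOL})
        cand = {float(res.x): -res.fun, 0.0: -joint_neg(0.0), 1.0: -joint_neg(1.0)}
        lam = max(cand, key=cand.get)
        lam = 0.0 if lam < 10 * _LAMBDA_TOL else (1.0 if lam > 1 - 10 * _LAMBDA_TOL else lam)
        grid = [(l, -joint_neg(l)) for l in (0.0, 0.25, 0.5, 0.75, 1.0)]
    V = lambda_transform(C, lam)
    mx, my, var_x, var_y, cov = _phylo_moments(xv, yv, V)
    if var_x <= 0:
        raise ValueError("RMA undefined: predictor has zero phylogenetic variance")
    slope = float(np.sign(cov) if cov != 0 else 1.0) * float(np.sqrt(var_y / var_x))
    intercept = my - slope * mx
    r = cov / np.sqrt(var_x * var_y) if var_y > 0 else 0.0
    r = float(np.clip(r, -1.0, 1.0))
    if 1.0 - r * r < 1e-12:
        p_val = 1e-300
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p_val = float(np.clip(2.0 * stats.t.sf(abs(t), n - 2), 1e-300, 1.0))
    return RegressionFit(slope=slope, intercept=float(intercept), lam=lam,
                         r_squared=r * r, p_value=p_val, n=n, method="phylo_rma",
                         lambda_profile=grid)


def regress_gep_cep(results, tree, cep_field: str = "cep_percent",
                    log_scale: bool = False, zero_tol: float = 1e-9):
    """GEP~CEP phylogenetic RMA across species.

    Species with positive GEP but zero CEP (for the chosen CEP field) are
    excluded before fitting — their climate cloud is nested, so they carry no
    information about the coordination of the two expansions.  ``log_scale``
    log-transforms both axes (dropping any residual nonpositive values).
    Returns ``(RegressionFit, used_species)``.
    """
    rows = [(r.species_id, r.gep_percent, getattr(r, cep_field)) for r in results]
    kept = [(s, g, c) for s, g, c in rows if not (g > zero_tol and c <= zero_tol)]
    if log_scale:
        kept = [(s, g, c) for s, g, c in kept if g > 0 and c > 0]
    if len(kept) < 3:
        raise ValueError(f"fewer than 3 species after exclusion ({len(kept)} of {len(rows)})")
    species = [s for s, _, _ in kept]
    gep = np.array([g for _, g, _ in kept])
    cep = np.array([c for _, _, c in kept])
    if log_scale:
        gep, cep = np.log(gep), np.log(cep)
    pruned, _ = prune_tree(tree, species)
    fit = fit_phylo_rma(gep, cep, pruned, labels=species)
    return fit, species
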
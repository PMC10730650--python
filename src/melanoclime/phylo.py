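"""Phylogenetic comparative machinery.

Everything here works through the phylogenetic covariance matrix C,
whose entries are shared root-to-MRCA path lengths.  Under Brownian
motion a trait is multivariate normal with covariance proportional to C;
Pagel's lambda damps the off-diagonal entries to measure how much of
that structure a trait actually carries.  The phylogenetic mixed model
(Lynch's comparative method) splits a trait into a grand mean, a
heritable phylogenetic component P and a species-specific residual S,
fitted by EM and predicted by BLUP.  PGLS performs regression with the
lambda-transformed covariance as the error structure.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Trees and covariance

def read_newick(path_or_string, from_string: bool = False) -> dendropy.Tree:
    kwargs = dict(schema="newick", rooting="default-rooted", preserve_underscores=True)
    if from_string:
        return dendropy.Tree.get(data=path_or_string, **kwargs)
    return dendropy.Tree.get(path=str(path_or_string), **kwargs)


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


@dataclass
class PhyloCovariance:
    """Phylogenetic covariance matrix with its tip ordering."""

    matrix: np.ndarray
    tips: list[str]

    def reorder(self, tips: list[str]) -> "PhyloCovariance":
        idx = [self.tips.index(t) for t in tips]
        return PhyloCovariance(self.matrix[np.ix_(idx, idx)], list(tips))

    def is_star(self, rel_tol: float = 1e-10) -> bool:
        off = self.matrix - np.diag(np.diag(self.matrix))
        scale = max(np.max(np.diag(self.matrix)), _EPS)
        return bool(np.max(np.abs(off)) < rel_tol * scale)


def vcv_from_tree(tree: dendropy.Tree) -> PhyloCovariance:
    """C[i, j] = path length from the root to the MRCA of tips i and j.

    Built by a single preorder sweep: each internal node at depth d sets
    the covariance of every pair of tips split between its child
    subtrees to d.
    """
    if not tree.is_rooted:
        raise ValueError("covariance requires a rooted tree")
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels")
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))

    # depth of every node; negative branch lengths rejected
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        bl = node.edge.length if node.edge.length is not None else 0.0
        if bl < 0:
            raise ValueError("negative branch length")
        depth[id(node)] = depth[id(node.parent_node)] + bl

    # postorder: collect tip indices per subtree, fill cross-blocks at MRCA depth
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            below[id(node)] = np.array([i])
            C[i, i] = depth[id(node)]
            continue
        kids = [below.pop(id(ch)) for ch in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                C[np.ix_(kids[a], kids[b])] = d
                C[np.ix_(kids[b], kids[a])] = d
        below[id(node)] = np.concatenate(kids)
    return PhyloCovariance(C, labels)


def lambda_transform(C: PhyloCovariance | np.ndarray, lam: float) -> np.ndarray:
    """Multiply off-diagonal entries of C by lambda; diagonal unchanged."""
    if not 0 <= lam <= 1:
        raise ValueError("lambda must be in [0, 1]")
    M = C.matrix if isinstance(C, PhyloCovariance) else np.asarray(C)
    out = lam * M
    np.fill_diagonal(out, np.diag(M))
    return out


def _align(trait: pd.Series | dict, cov: PhyloCovariance):
    """Intersect trait keys with tips; drop (and log) the mismatch."""
    trait = pd.Series(trait, dtype=float)
    common = [t for t in cov.tips if t in trait.index]
    n_drop_tips = len(cov.tips) - len(common)
    n_drop_trait = len(trait) - len(common)
    if n_drop_tips or n_drop_trait:
        logger.info("dropped %d tips without trait and %d trait species not in tree",
                    n_drop_tips, n_drop_trait)
    if len(common) < 3:
        raise ValueError("fewer than 3 species shared between trait and tree")
    sub = cov.reorder(common)
    return trait.loc[common].to_numpy(), sub


def _mvn_profile_loglik(y: np.ndarray, V: np.ndarray):
    """Profile out mu and sigma2 of y ~ N(mu 1, sigma2 V); return (ll, mu, s2)."""
    n = len(y)
    try:
        cf = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf, np.nan, np.nan
    one = np.ones(n)
    Vi1 = cho_solve(cf, one)
    mu = float(one @ cho_solve(cf, y) / (one @ Vi1))
    r = y - mu
    s2 = float(r @ cho_solve(cf, r) / n)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    ll = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    return ll, mu, s2


@dataclass
class LambdaFit:
    lambda_hat: float
    sigma2_hat: float
    mu_hat: float
    log_likelihood: float
    identifiable: bool
    n: int


def pagel_loglik(trait, cov: PhyloCovariance, lam: float) -> float:
    """Log-likelihood of the lambda model at a fixed lambda (mu, sigma2 profiled)."""
    y, sub = _align(trait, cov)
    ll, _, _ = _mvn_profile_loglik(y, lambda_transform(sub, lam))
    return ll


def fit_pagel_lambda(trait: pd.Series | dict, tree: dendropy.Tree) -> LambdaFit:
    """ML estimate of Pagel's lambda on [0, 1].

    The mean and rate are profiled analytically; the scalar lambda
    likelihood is maximised numerically and compared against both
    boundary values.  On a star phylogeny the likelihood is flat in
    lambda and the fit is flagged unidentifiable.
    """
    cov = vcv_from_tree(tree)
    y, sub = _align(trait, cov)
    if np.ptp(y) == 0:
        raise ValueError("constant trait: lambda is undefined")

    if sub.is_star():
        ll, mu, s2 = _mvn_profile_loglik(y, sub.matrix)
        return LambdaFit(0.0, s2, mu, ll, identifiable=False, n=len(y))

    def nll(lam):
        return -_mvn_profile_loglik(y, lambda_transform(sub, lam))[0]

    res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-8})
    candidates = [(nll(0.0), 0.0), (nll(1.0), 1.0), (res.fun, float(res.x))]
    best_nll, lam_hat = min(candidates)
    ll, mu, s2 = _mvn_profile_loglik(y, lambda_transform(sub, lam_hat))
    return LambdaFit(lam_hat, s2, mu, ll, identifiable=True, n=len(y))


# ---------------------------------------------------------------------------
# Phylogenetic mixed model (Lynch decomposition)

@dataclass
class PhyloDecomposition:
    """Additive split y_i = mu + P_i + S_i with variance components.

    P is the BLUP of the phylogenetic random effect (covariance
    sigma2_phylo * C), S the BLUP of the independent residual.
    """

    species: list[str]
    raw: np.ndarray
    grand_mean: float
    P: np.ndarray
    S: np.ndarray
    sigma2_phylo: float
    sigma2_resid: float
    iterations: int
    converged: bool
    log_likelihood: float
    loglik_trace: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"species_id": self.species, "raw": self.raw,
                             "P": self.P, "S": self.S})

    @property
    def heritability(self) -> float:
        tot = self.sigma2_phylo + self.sigma2_resid
        return self.sigma2_phylo / tot if tot > 0 else np.nan


def lynch_decompose(trait: pd.Series | dict, tree: dendropy.Tree,
                    tol: float = 1e-8, max_iter: int = 10_000) -> PhyloDecomposition:
    """Fit y = mu*1 + a + e, a ~ N(0, s2_a C), e ~ N(0, s2_e I) by EM.

    Work happens in the eigenbasis of C (one O(n^3) decomposition, then
    O(n) per iteration).  mu is refreshed by GLS each cycle, so the
    marginal log-likelihood is non-decreasing (ECM).  BLUPs satisfy
    mu + P_i + S_i = y_i exactly because the two predictors sum to the
    centred data.
    """
    cov = vcv_from_tree(tree)
    y, sub = _align(trait, cov)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 species")
    d, U = np.linalg.eigh(sub.matrix)
    if d.min() < -1e-8 * max(d.max(), 1.0):
        raise ValueError("covariance not positive semi-definite")
    # C may be rank deficient (zero terminal branches); the mixed model is
    # still proper because V = s2a*C + s2e*I is positive definite.  The
    # phylogenetic effect has no variance outside C's support, so the
    # M-step for s2a averages over the positive eigenvalues only.
    d = np.clip(d, 0.0, None)
    pos = d > 1e-12 * d.max()
    if pos.sum() < 2:
        raise ValueError("singular phylogenetic covariance")
    rank = int(pos.sum())
    d_pos = d[pos]
    v = U.T @ y
    u = U.T @ np.ones(n)

    s2a = s2e = float(np.var(y) / 2.0) or 1.0
    trace = []
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        s = s2a * d + s2e
        mu = float((u * v / s).sum() / (u * u / s).sum())
        z = v - mu * u
        ll = -0.5 * float(np.sum(np.log(2 * np.pi * s) + z * z / s))
        trace.append(ll)
        if it > 1 and abs(ll - ll_prev) <= tol * (abs(ll_prev) + 1.0):
            converged = True
            break
        ll_prev = ll
        # E-step conditional moments in the eigenbasis
        a_hat = s2a * d * z / s
        var_a = s2a * d * s2e / s
        e_hat = z - a_hat
        var_e = s2e * s2a * d / s
        # M-step
        s2a = float(np.sum((a_hat[pos] ** 2 + var_a[pos]) / d_pos) / rank)
        s2e = float(np.sum(e_hat**2 + var_e) / n)
        s2a = max(s2a, 0.0)
        s2e = max(s2e, _EPS)
    if not converged:
        logger.warning("Lynch EM did not converge in %d iterations", max_iter)

    s = s2a * d + s2e
    mu = float((u * v / s).sum() / (u * u / s).sum())
    z = v - mu * u
    ll = -0.5 * float(np.sum(np.log(2 * np.pi * s) + z * z / s))
    P = U @ (s2a * d * z / s)
    raw = y
    S = raw - mu - P
    return PhyloDecomposition(sub.tips, raw, mu, P, S, s2a, s2e, it, converged,
                              ll, np.asarray(trace))


# ---------------------------------------------------------------------------
# PGLS

@dataclass
class PGLSResult:
    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    lambda_used: float
    r_squared: float
    n: int
    df_resid: int
    log_likelihood: float
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.terms, "slope": self.coef, "se": self.se,
                             "t": self.t, "p": self.p})


def _gls_whiten(V: np.ndarray):
    L = cholesky(V, lower=True)
    return L


def pgls_fit(y, X: pd.DataFrame, tree: dendropy.Tree,
             lam: float | str = "estimated", add_intercept: bool = True) -> PGLSResult:
    """Phylogenetic GLS of y on X with covariance sigma2 * C_lambda.

    `y` and rows of `X` are indexed by species_id.  With
    lam="estimated" the transform parameter is profiled by ML on [0, 1].
    R^2 is computed on the GLS-whitened scale against the whitened
    intercept-only fit (recorded in `meta`).
    """
    y = pd.Series(y, dtype=float)
    X = pd.DataFrame(X).astype(float)
    common = [s for s in y.index if s in X.index]
    cov = vcv_from_tree(tree)
    common = [t for t in cov.tips if t in common]
    if len(common) < 3:
        raise ValueError("fewer than 3 species shared among y, X and tree")
    sub = cov.reorder(common)
    yv = y.loc[common].to_numpy()
    Xm = X.loc[common]
    terms = list(Xm.columns)
    M = Xm.to_numpy()
    if add_intercept:
        M = np.column_stack([np.ones(len(yv)), M])
        terms = ["intercept"] + terms
    n, p = M.shape
    if np.linalg.matrix_rank(M) < p:
        raise ValueError("design matrix is rank deficient")

    def fit_at(lmb):
        V = lambda_transform(sub, lmb)
        L = _gls_whiten(V)
        yw = np.linalg.solve(L, yv)
        Mw = np.linalg.solve(L, M)
        beta, *_ = np.linalg.lstsq(Mw, yw, rcond=None)
        r = yw - Mw @ beta
        rss = float(r @ r)
        s2 = rss / n
        logdet = 2 * float(np.sum(np.log(np.diag(L))))
        ll = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
        return ll, beta, rss, yw, Mw, L

    if lam == "estimated":
        res = minimize_scalar(lambda l: -fit_at(l)[0], bounds=(0.0, 1.0),
                              method="bounded", options={"xatol": 1e-8})
        cand = [(-fit_at(0.0)[0], 0.0), (-fit_at(1.0)[0], 1.0), (res.fun, float(res.x))]
        _, lam_hat = min(cand)
    else:
        lam_hat = float(lam)
    ll, beta, rss, yw, Mw, L = fit_at(lam_hat)

    df = n - p
    s2_unb = rss / df
    XtX_inv = np.linalg.inv(Mw.T @ Mw)
    se = np.sqrt(np.diag(s2_unb * XtX_inv))
    tstat = beta / se
    pval = 2 * stats.t.sf(np.abs(tstat), df)

    # whitened-scale R^2 against the whitened intercept-only model
    onew = np.linalg.solve(L, np.ones(n))
    mu0 = float(onew @ yw / (onew @ onew))
    tss = float(np.sum((yw - mu0 * onew) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan

    return PGLSResult(terms, beta, se, tstat, pval, lam_hat, r2, n, df, ll,
                      meta={"r2_scale": "gls-whitened", "species": common})


# ---------------------------------------------------------------------------
# Grafting species missing from the tree

def graft_missing_species(tree: dendropy.Tree, taxonomy: dict,
                          missing: list[str], seed: int,
                          stem_fraction: float = 0.1) -> dendropy.Tree:
    """Attach species without molecular data inside their genus's subtree.

    Each missing species is grafted onto the terminal edge of a randomly
    chosen congeneric tip: the edge is split, the new internal branch
    receiving `stem_fraction` of the host's terminal branch, and the new
    tip is given the same depth (ultrametricity of the input is
    preserved).  Successive grafts may attach to earlier ones, which
    randomly resolves intra-genus relationships.  Deterministic under
    `seed`.
    """
    if not 0 < stem_fraction < 1:
        raise ValueError("stem_fraction must be in (0, 1)")
    tree = tree.clone(depth=1)
    if not missing:
        return tree
    rng = random.Random(seed)

    def genus_of(label: str) -> str:
        if label in taxonomy:
            return taxonomy[label]
        return label.split("_")[0]

    for sp in sorted(missing):
        genus = genus_of(sp)
        hosts = [lf for lf in tree.leaf_node_iter() if genus_of(lf.taxon.label) == genus]
        if not hosts:
            raise ValueError(f"genus {genus!r} of {sp!r} has no tips in the tree")
        host = rng.choice(sorted(hosts, key=lambda lf: lf.taxon.label))
        L = host.edge.length
        if L is None or L <= 0:
            raise ValueError(f"host tip {host.taxon.label!r} has no positive branch length")
        parent = host.parent_node
        parent.remove_child(host)
        joint = parent.new_child(edge_length=L * (1.0 - stem_fraction))
        joint.add_child(host)
        host.edge.length = L * stem_fraction
        taxon = dendropy.Taxon(label=sp)
        tree.taxon_namespace.add_taxon(taxon)
        joint.new_child(taxon=taxon, edge_length=L * stem_fraction)
    return tree


def prune_to_species(tree: dendropy.Tree, keep: list[str]) -> dendropy.Tree:
    """Retain only `keep` tips, merging the edges of suppressed nodes."""
    tree = tree.clone(depth=1)
    keep_set = set(keep)
    taxa = [t for t in tree.taxon_namespace if t.label in keep_set]
    tree.retain_taxa(taxa)
    return tree
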
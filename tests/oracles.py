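"""Independent brute-force oracles used to cross-check the library.

Everything here is deliberately naive (per-pair loops, explicit
enumeration, normal equations) and shares no code path with the
implementations it checks.
"""

from __future__ import annotations

import itertools
import random

import dendropy
import numpy as np


# ---------------------------------------------------------------------------
# Trees

def random_ultrametric_tree(n_tips: int, rng: random.Random,
                            labels=None) -> dendropy.Tree:
    """Random binary ultrametric tree built by successive splitting."""
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    # start with a root at height 1 over two children; repeatedly split a
    # random tip edge at a random height
    heights = {}  # node -> depth of node
    root = tree.seed_node
    heights[root] = 0.0
    leaves = []
    for _ in range(2):
        ch = root.new_child()
        heights[ch] = 1.0
        leaves.append(ch)
    while len(leaves) < n_tips:
        host = rng.choice(leaves)
        parent_h = heights[host.parent_node]
        split_h = parent_h + rng.uniform(0.1, 0.9) * (1.0 - parent_h)
        parent = host.parent_node
        parent.remove_child(host)
        mid = parent.new_child()
        heights[mid] = split_h
        mid.add_child(host)
        new = mid.new_child()
        heights[new] = 1.0
        leaves.append(new)
    for i, leaf in enumerate(leaves):
        leaf.taxon = tree.taxon_namespace.new_taxon(
            label=(labels[i] if labels else f"t{i + 1}"))
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        node.edge.length = heights[node] - heights[node.parent_node]
    return tree


def yule_tree(n_tips: int, seed: int) -> dendropy.Tree:
    """Pure-birth tree; the standard shape for comparative-method power
    checks (random split-trees are comb-like and carry little signal)."""
    from dendropy.simulate import treesim

    t = treesim.birth_death_tree(birth_rate=1.0, death_rate=0.0,
                                 num_extant_tips=n_tips, rng=random.Random(seed))
    h0 = max(lf.distance_from_root() for lf in t.leaf_node_iter())
    for i, lf in enumerate(t.leaf_node_iter()):
        lf.taxon.label = f"s{i}"
        lf.edge.length += 0.01 * h0  # the youngest tips otherwise have zero branches
    t.is_rooted = True
    return t


def brute_force_vcv(tree: dendropy.Tree):
    """Per-pair MRCA path lengths via explicit ancestor walks."""
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]

    def ancestors_with_depth(leaf):
        # list of (node id, depth-from-root) for every ancestor incl. leaf
        chain = []
        node = leaf
        while node is not None:
            chain.append(node)
            node = node.parent_node
        chain = chain[::-1]  # root first
        out = {}
        d = 0.0
        for nd in chain:
            if nd.parent_node is not None:
                d += nd.edge.length or 0.0
            out[id(nd)] = d
        return out, [id(nd) for nd in chain]

    info = [ancestors_with_depth(lf) for lf in leaves]
    n = len(leaves)
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            depths_i, chain_i = info[i]
            depths_j, _ = info[j]
            common = [nd for nd in chain_i if nd in depths_j]
            mrca_depth = max(depths_i[nd] for nd in common
                             if abs(depths_i[nd] - depths_j[nd]) < 1e-12)
            C[i, j] = mrca_depth if i != j else depths_i[chain_i[-1]]
    return C, labels


def mvn_profile_loglik_dense(y: np.ndarray, V: np.ndarray) -> float:
    """Profiled MVN log-likelihood by plain inversion + logpdf formula."""
    n = len(y)
    Vi = np.linalg.inv(V)
    one = np.ones(n)
    mu = (one @ Vi @ y) / (one @ Vi @ one)
    r = y - mu
    s2 = (r @ Vi @ r) / n
    sign, logdet = np.linalg.slogdet(s2 * V)
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet + r @ Vi @ r / s2))


# ---------------------------------------------------------------------------
# Regression

def ols_normal_equations(y: np.ndarray, X: np.ndarray):
    """(beta, se, r2) from the normal equations, with intercept prepended."""
    n = len(y)
    M = np.column_stack([np.ones(n), X])
    XtX = M.T @ M
    beta = np.linalg.solve(XtX, M.T @ y)
    resid = y - M @ beta
    rss = resid @ resid
    df = n - M.shape[1]
    cov = (rss / df) * np.linalg.inv(XtX)
    tss = np.sum((y - y.mean()) ** 2)
    return beta, np.sqrt(np.diag(cov)), 1 - rss / tss


def hierpart_by_orderings(y: np.ndarray, X) -> np.ndarray:
    """Average incremental R^2 over every ordering of predictor entry."""
    cols = list(X.columns)
    k = len(cols)

    def r2(subset):
        if not subset:
            return 0.0
        return ols_normal_equations(y, X[list(subset)].to_numpy())[2]

    totals = np.zeros(k)
    count = 0
    for perm in itertools.permutations(cols):
        count += 1
        for pos, col in enumerate(perm):
            before = set(perm[:pos])
            totals[cols.index(col)] += r2(before | {col}) - r2(before)
    return totals / count


def exhaustive_ses_null(pool: np.ndarray, k: int):
    """Mean/sd of MPD over every k-subset of the pool."""
    vals = []
    for comb in itertools.combinations(pool, k):
        s = 0.0
        cnt = 0
        for a, b in itertools.combinations(comb, 2):
            s += abs(a - b)
            cnt += 1
        vals.append(s / cnt)
    vals = np.array(vals)
    return vals.mean(), vals.std(ddof=1)


def rect_occupancy(rect, xs, ys) -> np.ndarray:
    """Boolean point-in-rectangle by explicit loop."""
    x0, x1, y0, y1 = rect
    return np.array([(x0 <= x <= x1) and (y0 <= y <= y1) for x, y in zip(xs, ys)])
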
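"""Independent oracles for the statistical core.

Deliberately naive: dendropy's patristic-distance machinery for tree
geometry (a code path the package does not use), and plain-numpy explicit
matrix inversion for the GLS formulas (the package uses Cholesky solves).
"""

import dendropy
import numpy as np
from scipy import stats


def dendropy_distances(newick: str):
    """(names, pairwise patristic distance matrix, root-to-tip depths)."""
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = list(tree.leaf_node_iter())
    names = [lf.taxon.label for lf in leaves]
    pdm = tree.phylogenetic_distance_matrix()
    n = len(leaves)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
    depths = np.array([lf.root_distance for lf in leaves])
    return names, D, depths


def dendropy_vcv(newick: str):
    """Shared root-to-MRCA branch lengths via V_ij = (d_i + d_j - D_ij) / 2."""
    names, D, depths = dendropy_distances(newick)
    V = (depths[:, None] + depths[None, :] - D) / 2.0
    return names, V


def gls_mean(V: np.ndarray, x: np.ndarray) -> float:
    Vi = np.linalg.inv(V)
    one = np.ones(len(x))
    return float(one @ Vi @ x / (one @ Vi @ one))


def blomberg_k(V: np.ndarray, x: np.ndarray) -> float:
    n = len(x)
    Vi = np.linalg.inv(V)
    one = np.ones(n)
    a = gls_mean(V, x)
    r = x - a
    mse0 = r @ r / (n - 1)
    mse = r @ Vi @ r / (n - 1)
    expected = (np.trace(V) - n / (one @ Vi @ one)) / (n - 1)
    return float((mse0 / mse) / expected)


def gls_fit(V: np.ndarray, x: np.ndarray, y: np.ndarray):
    """(beta0, beta1, se1, t, p) by explicit inversion."""
    n = len(y)
    Vi = np.linalg.inv(V)
    X = np.column_stack([np.ones(n), x])
    XtVi = X.T @ Vi
    A = np.linalg.inv(XtVi @ X)
    beta = A @ XtVi @ y
    r = y - X @ beta
    s2 = r @ Vi @ r / (n - 2)
    se1 = float(np.sqrt(s2 * A[1, 1]))
    t = float(beta[1] / se1)
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return float(beta[0]), float(beta[1]), se1, t, p


def ols_closed_form(x: np.ndarray, y: np.ndarray):
    """(beta0, beta1, t) from the Sxy/Sxx textbook formulas."""
    n = len(x)
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    sxy = ((x - xbar) * (y - ybar)).sum()
    b1 = sxy / sxx
    b0 = ybar - b1 * xbar
    rss = ((y - b0 - b1 * x) ** 2).sum()
    se1 = np.sqrt(rss / (n - 2) / sxx)
    return float(b0), float(b1), float(b1 / se1)
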
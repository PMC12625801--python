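"""Independent reference implementations used to check the package.

These deliberately use different algorithms (explicit matrix inverses,
Felsenstein's pruning contrasts, dendropy's own path sums) than the code
under test.
"""

from __future__ import annotations

import numpy as np


def gls_direct(X: np.ndarray, y: np.ndarray, V: np.ndarray):
    """GLS by explicit matrix inversion: β = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y."""
    Vi = np.linalg.inv(V)
    XtVi = X.T @ Vi
    beta = np.linalg.solve(XtVi @ X, XtVi @ y)
    resid = y - X @ beta
    n, p = X.shape
    sigma2 = float(resid @ Vi @ resid) / (n - p)
    cov_beta = sigma2 * np.linalg.inv(XtVi @ X)
    return beta, sigma2, cov_beta


def loglik_direct(X: np.ndarray, y: np.ndarray, V: np.ndarray) -> float:
    """Multivariate-normal log-likelihood at the ML variance scale."""
    Vi = np.linalg.inv(V)
    XtVi = X.T @ Vi
    beta = np.linalg.solve(XtVi @ X, XtVi @ y)
    resid = y - X @ beta
    n = len(y)
    s2 = float(resid @ Vi @ resid) / n
    sign, logdet = np.linalg.slogdet(V)
    return -0.5 * (n * np.log(2 * np.pi) + n * np.log(s2) + logdet + n)


def pic_slope(tree, x: dict[str, float], y: dict[str, float]) -> float:
    """Through-origin regression slope on phylogenetic independent contrasts.

    Felsenstein's pruning on a strictly bifurcating tree: at each internal
    node the contrast between its two daughters is standardized by the sum
    of their (rate-adjusted) branch lengths, and the ancestral value is the
    precision-weighted average with the node's edge lengthened by
    v1·v2/(v1+v2).
    """
    dt = tree._dtree
    vals: dict[int, tuple[float, float, float]] = {}  # id -> (x, y, extra v)
    contrasts = []
    from phylomass.tree import normalize_label

    for nd in dt.postorder_node_iter():
        if nd.is_leaf():
            lab = normalize_label(nd.taxon.label)
            vals[id(nd)] = (x[lab], y[lab], 0.0)
            continue
        ch = nd.child_nodes()
        assert len(ch) == 2, "PIC oracle needs a binary tree"
        x1, y1, e1 = vals.pop(id(ch[0]))
        x2, y2, e2 = vals.pop(id(ch[1]))
        v1 = (ch[0].edge.length or 0.0) + e1
        v2 = (ch[1].edge.length or 0.0) + e2
        s = np.sqrt(v1 + v2)
        contrasts.append(((x1 - x2) / s, (y1 - y2) / s))
        xa = (v2 * x1 + v1 * x2) / (v1 + v2)
        ya = (v2 * y1 + v1 * y2) / (v1 + v2)
        vals[id(nd)] = (xa, ya, v1 * v2 / (v1 + v2))
    cx = np.array([c[0] for c in contrasts])
    cy = np.array([c[1] for c in contrasts])
    return float(cx @ cy / (cx @ cx))


def tip_depths_dendropy(tree) -> dict[str, float]:
    """Root-to-tip depths via dendropy's own path sums (seed edge included)."""
    from phylomass.tree import normalize_label

    dt = tree._dtree
    return {
        normalize_label(lf.taxon.label): lf.distance_from_root()
        for lf in dt.leaf_node_iter()
    }
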
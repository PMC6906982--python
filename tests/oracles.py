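"""Independent oracles shared by the test modules.

These deliberately avoid the package's own computational paths: contrasts by
direct postorder recursion, GLS by the explicit matrix formula, BH by the
literal O(m^2) step-up definition.
"""

import numpy as np


def pic_contrasts(phylo, values: dict) -> np.ndarray:
    """Felsenstein's phylogenetically independent contrasts on a bifurcating
    tree (postorder recursion)."""
    out = []

    def rec(node):
        if node.is_leaf():
            return values[node.taxon.label], node.edge.length or 0.0
        children = node.child_nodes()
        assert len(children) == 2, "PIC oracle needs a bifurcating tree"
        (x1, b1), (x2, b2) = (rec(c) for c in children)
        out.append((x1 - x2) / np.sqrt(b1 + b2))
        xk = (x1 / b1 + x2 / b2) / (1.0 / b1 + 1.0 / b2)
        bk = (node.edge.length or 0.0) + b1 * b2 / (b1 + b2)
        return xk, bk

    rec(phylo.tree.seed_node)
    return np.asarray(out)


def pic_slope(phylo, x: dict, y: dict) -> float:
    """OLS through the origin of contrasts(y) on contrasts(x)."""
    cx = pic_contrasts(phylo, x)
    cy = pic_contrasts(phylo, y)
    return float(cx @ cy / (cx @ cx))


def direct_gls_beta(y, X, C) -> np.ndarray:
    """GLS estimator from the explicit normal equations (no whitening)."""
    Ci = np.linalg.inv(C)
    return np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ y)


def bh_bruteforce(p, q) -> np.ndarray:
    """Literal O(m^2) Benjamini-Hochberg step-up rule."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k_star = i
    flags = np.zeros(m, dtype=bool)
    flags[order[:k_star]] = True
    return flags
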
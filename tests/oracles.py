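"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's IntervalTable builder: lineage
counts are recomputed by probing edge crossings at interval midpoints,
and entity roots are re-derived directly from the threshold rule.
"""

import math

from scipy.integrate import quad


def _strict_descendant(node, anc):
    nd = node.parent
    while nd is not None:
        if nd is anc:
            return True
        nd = nd.parent
    return False


def entity_roots_by_threshold(tree, threshold):
    """Maximal nodes at or below the threshold (tips included)."""
    roots = []
    for nd in tree.nodes:
        h = 0.0 if nd.is_tip else nd.height
        if h <= threshold and (nd.parent is None or nd.parent.height > threshold):
            roots.append(nd)
    return roots


def sweep_loglik(tree, threshold, lam1, p1, lam2, p2):
    """Event-sweep recomputation of the mixed log-likelihood.

    Per interval between consecutive event heights (descending, ending
    at 0), the total rate is evaluated from lineage counts measured at
    the interval midpoint by brute-force edge crossing.
    """
    roots = entity_roots_by_threshold(tree, threshold)
    internal_roots = [r for r in roots if not r.is_tip]
    div_nodes = [nd for nd in tree.internal_nodes if nd.height > threshold]

    heights = sorted((nd.height for nd in tree.internal_nodes), reverse=True)
    edges = [nd for nd in tree.nodes if nd.parent is not None]

    ll = 0.0
    bounds = heights + [0.0]
    for top, end in zip(bounds, bounds[1:]):
        h = 0.5 * (top + end)
        x = top - end

        # diversification lineages: edges crossing h that are not inside
        # an entity, plus one persisting species lineage per entity root
        # already above h
        n_div = sum(
            1 for c in edges
            if c.parent.height > h >= c.height
            and not any(_strict_descendant(c, r) for r in internal_roots)
        )
        n_div += sum(1 for r in internal_roots if r.height > h)

        b = 0.0
        if div_nodes:
            b += lam1 * n_div ** p1
        for r in internal_roots:
            n_r = sum(
                1 for c in edges
                if c.parent.height > h >= c.height and _strict_descendant(c, r)
            )
            q = n_r * (n_r - 1)
            if q > 0:
                b += lam2 * q ** p2
        if b <= 0:
            return float("-inf")
        ll += math.log(b) - b * x
    return ll


def chi2_sf_by_quadrature(x, df):
    """Upper chi-square tail by numeric integration of the density."""
    if x <= 0:
        return 1.0

    def pdf(t):
        return t ** (df / 2.0 - 1.0) * math.exp(-t / 2.0) / (
            2.0 ** (df / 2.0) * math.gamma(df / 2.0)
        )

    val, _ = quad(pdf, x, math.inf, limit=200)
    return val
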
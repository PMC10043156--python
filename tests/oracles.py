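"""Independent reference computations used to cross-check the package.

Everything here is deliberately written from first principles (truncated
powers, explicit log-density formulas, sort-based percentiles) and shares no
code path with the implementation it checks.
"""

import math

import numpy as np


def truncated_power_natural_basis(nodes, x):
    """Basis of the natural cubic spline space with the given knots, built
    from truncated third powers: {1, x, d_k(x) - d_{K-1}(x)}."""
    nodes = np.asarray(nodes, dtype=float)
    x = np.asarray(x, dtype=float)
    t_last, t_prev = nodes[-1], nodes[-2]

    def d(t, x):
        return (np.clip(x - t, 0, None) ** 3 - np.clip(x - t_last, 0, None) ** 3) / (
            t_last - t
        )

    cols = [np.ones_like(x), x]
    for k in range(nodes.size - 2):
        cols.append(d(nodes[k], x) - d(t_prev, x))
    return np.column_stack(cols)


def cardinal_natural_basis_via_truncated_powers(nodes, x):
    """Cardinal natural-spline functions (unit value at one node, zero at the
    others) expressed in the truncated-power basis; columns for nodes 1..K-1
    (the function attached to the first node is dropped)."""
    nodes = np.asarray(nodes, dtype=float)
    A = truncated_power_natural_basis(nodes, nodes)
    B = truncated_power_natural_basis(nodes, x)
    cols = []
    for k in range(1, nodes.size):
        e = np.zeros(nodes.size)
        e[k] = 1.0
        cols.append(B @ np.linalg.solve(A, e))
    return np.column_stack(cols)


def student_t_logpdf(x, df, scale):
    """Elementwise Student-t log density, written out in gamma functions."""
    z = x / scale
    return (
        math.lgamma((df + 1) / 2.0)
        - math.lgamma(df / 2.0)
        - 0.5 * math.log(df * math.pi)
        - math.log(scale)
        - (df + 1) / 2.0 * math.log(1.0 + z * z / df)
    )


def normal_logpdf(x, sd):
    return -0.5 * math.log(2.0 * math.pi) - math.log(sd) - x * x / (2.0 * sd * sd)


def half_t_logpdf(x, df, scale):
    return math.log(2.0) + student_t_logpdf(x, df, scale)


def sorted_percentile(samples, level):
    """Linear-interpolation percentile computed directly on sorted values."""
    x = np.sort(np.asarray(samples, dtype=float))
    h = (x.size - 1) * level / 100.0
    lo = int(math.floor(h))
    hi = min(lo + 1, x.size - 1)
    return x[lo] + (h - lo) * (x[hi] - x[lo])
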
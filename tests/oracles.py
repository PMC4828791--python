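"""Independent oracles used by the tests.

These deliberately avoid the package's pruning/search code paths: the
likelihood oracle sums over all internal-state assignments explicitly, and the
gamma-rate oracle integrates the density numerically.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

from hgtscreen.substmodels import AA_INDEX, N_STATES, site_rates, transition_matrix


def brute_force_lnl(aln, tree, model) -> float:
    """Likelihood by exhaustive enumeration over internal-node states."""
    cats = site_rates(model)
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    leaf_nodes = [n for n in nodes if n.is_leaf]
    row_of = {name: aln.rows[i] for i, name in enumerate(aln.ids)}
    pi = model.pi
    total = 0.0
    for site in range(aln.n_sites):
        site_l = 0.0
        for rate, w in cats:
            P = {
                id(n): transition_matrix(model, n.length, rate)
                for n in nodes
                if n.parent is not None
            }
            s = 0.0
            for assign in itertools.product(range(N_STATES), repeat=len(internals)):
                st = {id(n): a for n, a in zip(internals, assign)}
                pr = pi[st[id(tree.root)]]
                for n in internals:
                    if n.parent is not None:
                        pr *= P[id(n)][st[id(n.parent)], st[id(n)]]
                for n in leaf_nodes:
                    obs = AA_INDEX.get(row_of[n.name][site])
                    if obs is not None:  # gaps/X marginalise to 1
                        pr *= P[id(n)][st[id(n.parent)], obs]
                s += pr
            site_l += w * s
        total += np.log(site_l)
    return float(total)


def gamma_category_rates_numeric(alpha: float, k: int) -> np.ndarray:
    """Equal-probability category means of a mean-1 gamma via quadrature."""
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), alpha, scale=1.0 / alpha)
    edges[0], edges[-1] = 0.0, np.inf
    pdf = lambda x: gamma_dist.pdf(x, alpha, scale=1.0 / alpha)  # noqa: E731
    rates = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        num, _ = quad(lambda x: x * pdf(x), lo, min(hi, 1e3), limit=200)
        rates.append(num * k)
    return np.array(rates)


def four_point_metric_tree_distances() -> tuple[list[str], np.ndarray, set]:
    """An additive 6-taxon distance matrix and the true splits it encodes."""
    # topology ((a,b),(c,d),(e,f)) with all pendant 0.2, internals 0.1
    names = list("abcdef")
    paths = {
        ("a", "b"): 0.4, ("c", "d"): 0.4, ("e", "f"): 0.4,
        ("a", "c"): 0.6, ("a", "d"): 0.6, ("b", "c"): 0.6, ("b", "d"): 0.6,
        ("a", "e"): 0.6, ("a", "f"): 0.6, ("b", "e"): 0.6, ("b", "f"): 0.6,
        ("c", "e"): 0.6, ("c", "f"): 0.6, ("d", "e"): 0.6, ("d", "f"): 0.6,
    }
    D = np.zeros((6, 6))
    for (x, y), d in paths.items():
        i, j = names.index(x), names.index(y)
        D[i, j] = D[j, i] = d
    true_splits = {frozenset("ab"), frozenset("cd"), frozenset("ef")}
    return names, D, true_splits
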
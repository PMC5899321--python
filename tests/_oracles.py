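"""Independent oracles used by the test suite.

These deliberately avoid the library's pruning/propagation code paths:
likelihoods are computed by exhaustive enumeration of internal states, and
transition matrices by scipy's generic matrix exponential.
"""

import itertools

import numpy as np
from scipy.linalg import expm

from chronoforge import substitution as subst


def transition_matrix_expm(exch, freqs, t):
    """P(t) via scipy expm on the directly constructed generator."""
    q = np.zeros((20, 20))
    for i in range(20):
        for j in range(20):
            if i != j:
                q[i, j] = exch[i, j] * freqs[j]
        q[i, i] = -q[i].sum()
    rate = -sum(freqs[i] * q[i, i] for i in range(20))
    if rate > 0:
        q = q / rate
    return expm(q * t)


def brute_force_site_logliks(tree, codes_by_taxon, model, site_freqs=None):
    """Exhaustive sum over all internal-state assignments, per site."""
    rates, weights = model.gamma()
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    n_sites = len(next(iter(codes_by_taxon.values())))
    out = np.zeros(n_sites)
    for site in range(n_sites):
        freqs = model.freqs if site_freqs is None else site_freqs[site]
        site_lik = 0.0
        for rate, weight in zip(rates, weights):
            pmats = {
                id(n): transition_matrix_expm(
                    model.exch, freqs, (n.length or 0.0) * rate
                )
                for n in nodes
                if n.parent is not None
            }
            acc = 0.0
            for assign in itertools.product(range(20), repeat=len(internals)):
                amap = {id(n): a for n, a in zip(internals, assign)}
                prob = freqs[amap[id(tree.root)]]
                for n in nodes:
                    if n.parent is None:
                        continue
                    pa = amap[id(n.parent)]
                    if n.is_leaf:
                        c = codes_by_taxon[n.name][site]
                        prob *= 1.0 if c < 0 else pmats[id(n)][pa, c]
                    else:
                        prob *= pmats[id(n)][pa, amap[id(n)]]
                    if prob == 0.0:
                        break
                acc += prob
            site_lik += weight * acc
        with np.errstate(divide="ignore"):
            out[site] = np.log(site_lik)
    return out


def welch_t(a, b):
    """Two-sample Welch t statistic from the textbook formula."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    return (a.mean() - b.mean()) / np.sqrt(va + vb)


def ols_r_squared(x, y):
    """R^2 from the closed-form correlation formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    sxx = ((x - x.mean()) ** 2).sum()
    syy = ((y - y.mean()) ** 2).sum()
    return sxy**2 / (sxx * syy)
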
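"""Independent brute-force oracles used to check the implementation.

Everything here is written from the defining formulas only (log-gamma
pmf summation, step-up from the definition, exhaustive enumeration) and
shares no code path with the package.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.special import gammaln


def ac_logpmf(y, x, n1, n2):
    """log p(y|x) = y log(N2/N1) + log (x+y)! - log x! - log y!
    - (x+y+1) log(1 + N2/N1)."""
    y = np.asarray(y, dtype=float)
    ratio = n2 / n1
    return (y * np.log(ratio) + gammaln(x + y + 1) - gammaln(x + 1)
            - gammaln(y + 1) - (x + y + 1) * np.log1p(ratio))


def ac_pvalue_bruteforce(x, y, n1, n2):
    """Two-sided p by direct tail summation of the conditional pmf."""
    lower = float(np.exp(ac_logpmf(np.arange(y + 1), x, n1, n2)).sum())
    if y == 0:
        upper = 1.0
    else:
        upper = 1.0 - float(np.exp(ac_logpmf(np.arange(y), x, n1, n2)).sum())
    return min(1.0, 2.0 * min(lower, upper))


def ac_pvalue_grid_bruteforce(x_max, y_max, n1, n2):
    """Brute-force two-sided p over the full grid x, y in [0, max]."""
    out = np.empty((x_max + 1, y_max + 1))
    ys = np.arange(y_max + 1)
    for x in range(x_max + 1):
        cdf = np.cumsum(np.exp(ac_logpmf(ys, x, n1, n2)))
        sf = np.empty_like(cdf)
        sf[0] = 1.0
        sf[1:] = 1.0 - cdf[:-1]
        out[x] = np.minimum(1.0, 2.0 * np.minimum(cdf, sf))
    return out


def bh_from_definition(pvalues):
    """Step-up BH: adj_(i) = min_{j >= i} min(1, m * p_(j) / j)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, m * ranked[i] / (i + 1))
        adj[i] = running
    out = np.empty(m)
    out[order] = adj
    return out


def rpkm_elementwise(counts, lengths, totals):
    """Independent element-by-element RPKM evaluation."""
    n_genes, n_libs = counts.shape
    out = np.empty((n_genes, n_libs))
    for g in range(n_genes):
        for l in range(n_libs):
            out[g, l] = 1e9 * counts[g, l] / (totals[l] * lengths[g])
    return out


def hypergeom_upper_tail_enumeration(n_bg, big_k, n_study, k):
    """P(X >= k) by enumerating every n_study-subset of the background."""
    hits = 0
    total = 0
    for subset in combinations(range(n_bg), n_study):
        total += 1
        if sum(1 for g in subset if g < big_k) >= k:
            hits += 1
    return hits / total


def ddct_from_definition(ct_rows, calibrator):
    """Relative expression recomputed straight from the ddCt definition.

    ``ct_rows``: iterable of (gene_id, sample, ct, is_reference).
    Returns {(gene, sample): RE}.
    """
    from collections import defaultdict

    by_key = defaultdict(list)
    refs_by_sample = defaultdict(lambda: defaultdict(list))
    for gene, sample, ct, is_ref in ct_rows:
        if is_ref:
            refs_by_sample[sample][gene].append(ct)
        else:
            by_key[(gene, sample)].append(ct)
    ref_mean = {
        sample: np.mean([np.mean(cts) for cts in genes.values()])
        for sample, genes in refs_by_sample.items()
    }
    dct = {
        key: np.mean(cts) - ref_mean[key[1]] for key, cts in by_key.items()
    }
    out = {}
    for (gene, sample), value in dct.items():
        out[(gene, sample)] = 2.0 ** (-(value - dct[(gene, calibrator)]))
    return out
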
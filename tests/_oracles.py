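"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (direct formulas, exhaustive loops)
and shares no code with the package internals it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np


def bh_stepup(p):
    """Direct Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m*p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def hypergeom_upper_tail(k, N, K, n):
    """Exact P(X >= k), X ~ Hypergeom(N, K, n), by rational enumeration."""
    total = comb(N, n)
    acc = sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1))
    return float(Fraction(acc, total))


def brute_compensatory(reinstated, down_mirs, edges, k_min):
    """Double loop over all (miR, gene) pairs: rescued set and comp miRs."""
    rescued = set()
    for g in reinstated:
        for m in down_mirs:
            if (m, g) in edges:
                rescued.add(g)
    comp = {}
    for m in down_mirs:
        targets = {g for g in rescued if (m, g) in edges}
        if len(targets) >= k_min:
            comp[m] = targets
    return rescued, comp


def brute_source_gene_paths(net, sources, max_paths):
    """All simple source-to-gene paths, sorted by (length, node sequence)."""
    genes = [n for n, d in net.nodes(data=True) if d.get("kind") == "gene"]
    all_paths = []
    for s in sources:
        for g in genes:
            for p in nx.all_simple_paths(net, s, g):
                all_paths.append(p)
    all_paths.sort(key=lambda p: (len(p) - 1, tuple(p)))
    return all_paths[:max_paths]


def permutation_pvalue(x, sf, alpha, n_ref, perms, z_obs, pseudocount=0.5):
    """Permutation p for the NB delta-method Wald statistic of one feature.

    ``perms`` is a (B, n_samples) array of permuted sample indices; the
    first ``n_ref`` columns form the reference group. The statistic is
    recomputed per permutation with the dispersion held fixed.
    """
    inv_s = 1.0 / np.asarray(sf)

    def zstat(ref_idx, alt_idx):
        mr = x[ref_idx].mean(axis=-1)
        ma = x[alt_idx].mean(axis=-1)
        nr, na = ref_idx.shape[-1], alt_idx.shape[-1]
        vr = (mr * inv_s[ref_idx].sum(axis=-1) + alpha * mr**2 * nr) / nr**2
        va = (ma * inv_s[alt_idx].sum(axis=-1) + alpha * ma**2 * na) / na**2
        c = pseudocount
        se = np.sqrt(va / (ma + c) ** 2 + vr / (mr + c) ** 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(se > 0, np.log((ma + c) / (mr + c)) / se, 0.0)

    z_perm = zstat(perms[:, :n_ref], perms[:, n_ref:])
    b = perms.shape[0]
    return (1 + int((np.abs(z_perm) >= abs(z_obs)).sum())) / (b + 1)
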
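"""Independent reference evaluation of the trimmed-mean-of-M-values
scaling factors, written as plain per-gene loops straight from the
published definition: pick the library whose upper-quartile count
fraction is closest to the mean of those fractions; for every other
library compute per-gene M (log2 ratio of count fractions) and A
(average log2 abundance) values over genes non-zero in both libraries;
double-trim 30% of M each tail and 5% of A each tail by rank; the
factor is 2 to the precision-weighted mean of surviving M values,
weights the reciprocal of the asymptotic binomial variance; finally
rescale all factors to geometric mean one.

Used only as a test oracle; intentionally un-vectorized and separate
from the package implementation.
"""

import math


def _quantile(values, q):
    """Linear-interpolation quantile between order statistics."""
    xs = sorted(values)
    pos = q * (len(xs) - 1)
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    return xs[lo] + (pos - lo) * (xs[hi] - xs[lo])


def _ranks(values):
    """1-based ranks, ties averaged."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def tmm_factors_reference(matrix, trim_m=0.30, trim_a=0.05):
    """matrix: list of per-sample lists (genes x samples column-major is
    NOT assumed; matrix[g][s]). Returns a list of per-sample factors."""
    n_genes = len(matrix)
    n_samples = len(matrix[0])
    lib = [sum(matrix[g][s] for g in range(n_genes)) for s in range(n_samples)]
    f75 = [
        _quantile([matrix[g][s] for g in range(n_genes)], 0.75) / lib[s]
        for s in range(n_samples)
    ]
    mean_f75 = sum(f75) / n_samples
    ref = min(range(n_samples), key=lambda s: abs(f75[s] - mean_f75))

    raw = []
    for s in range(n_samples):
        ms, as_, vs = [], [], []
        for g in range(n_genes):
            obs, refv = matrix[g][s], matrix[g][ref]
            if obs <= 0 or refv <= 0:
                continue
            p_obs = obs / lib[s]
            p_ref = refv / lib[ref]
            ms.append(math.log2(p_obs / p_ref))
            as_.append(0.5 * math.log2(p_obs * p_ref))
            vs.append((lib[s] - obs) / (lib[s] * obs) + (lib[ref] - refv) / (lib[ref] * refv))
        if not ms or max(abs(m) for m in ms) < 1e-6:
            raw.append(1.0)
            continue
        n = len(ms)
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rank_m = _ranks(ms)
        rank_a = _ranks(as_)
        num = den = 0.0
        kept = False
        for i in range(n):
            if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a:
                num += ms[i] / vs[i]
                den += 1.0 / vs[i]
                kept = True
        raw.append(2.0 ** (num / den) if kept else 1.0)

    log_geo = sum(math.log(f) for f in raw) / n_samples
    geo = math.exp(log_geo)
    return [f / geo for f in raw]
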
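"""Brute-force Weir & Cockerham (1984) variance components, written as an
independent plain-Python oracle for cross-checking the vectorized estimator.

Every quantity is computed per locus with explicit loops over populations
and individuals; no numpy broadcasting is shared with the implementation
under test.
"""

MISSING = -1


def _locus_stats(column):
    """(sample size, alt-allele frequency, het frequency) for one pop/locus."""
    calls = [g for g in column if g != MISSING]
    n = len(calls)
    if n == 0:
        return 0, None, None
    p = sum(calls) / (2.0 * n)
    h = sum(1 for g in calls if g == 1) / n
    return n, p, h


def wc_theta_oracle(blocks):
    """Multilocus theta as ratio of summed components over usable loci.

    ``blocks`` is a list of per-population genotype lists-of-lists
    (individuals x loci, codes 0/1/2/-1).
    """
    r = len(blocks)
    n_loci = len(blocks[0][0])
    sum_a = sum_all = 0.0
    for l in range(n_loci):
        stats = [_locus_stats([row[l] for row in pop]) for pop in blocks]
        if any(s[0] < 1 for s in stats):
            continue
        ns = [s[0] for s in stats]
        ps = [s[1] for s in stats]
        hs = [s[2] for s in stats]
        nbar = sum(ns) / r
        if nbar <= 1:
            continue
        nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
        if nc <= 0:
            continue
        pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        sum_a += a
        sum_all += a + b + c
    if sum_all == 0:
        return float("nan")
    return sum_a / sum_all
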
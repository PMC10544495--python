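"""Independent brute-force oracles used by the unit and acceptance tests."""

from math import comb, inf

import numpy as np


def fisher_p_enumeration(table, tie_rel=1e-7) -> float:
    """Two-sided Fisher p-value by full enumeration of the hypergeometric
    support: sum the probabilities of all tables (with the observed margins)
    whose probability does not exceed the observed table's (to a relative
    tie tolerance)."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = comb(n, c1)
    probs = {x: comb(r1, x) * comb(r2, c1 - x) / denom for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + tie_rel))


def conditional_mle_or(table, tol=1e-10):
    """Conditional MLE odds ratio by solving E_psi[X] = a over the
    noncentral hypergeometric support (bisection on log psi)."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    if lo == hi:
        return float("nan")  # degenerate margin: OR unidentifiable
    if a == lo:
        return 0.0
    if a == hi:
        return inf
    support = np.arange(lo, hi + 1)
    logw = np.array([np.log(comb(r1, int(x))) + np.log(comb(r2, int(c1 - x))) for x in support])

    def mean(log_psi):
        logp = logw + support * log_psi
        logp -= logp.max()
        p = np.exp(logp)
        return float((support * p).sum() / p.sum())

    lo_l, hi_l = -50.0, 50.0
    while hi_l - lo_l > tol:
        mid = 0.5 * (lo_l + hi_l)
        if mean(mid) < a:
            lo_l = mid
        else:
            hi_l = mid
    return float(np.exp(0.5 * (lo_l + hi_l)))


def all_2x2_tables(max_n):
    """Every 2x2 nonnegative integer table with total count <= max_n."""
    for n in range(1, max_n + 1):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    yield np.array([[a, b], [c, n - a - b - c]])


def margin_support(r1, r2, c1):
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return np.arange(lo, hi + 1)


def margin_log_weights(r1, r2, c1):
    """log C(r1, x) + log C(r2, c1-x) over the support, via gammaln."""
    from scipy.special import gammaln

    x = margin_support(r1, r2, c1)
    logc = lambda n, k: gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)  # noqa: E731
    return x, logc(r1, x) + logc(r2, c1 - x)


def fisher_p_all(r1, r2, c1, tie_rel=1e-7):
    """Two-sided enumeration p-values for every table with these margins,
    indexed by the support of cell a."""
    x, logw = margin_log_weights(r1, r2, c1)
    logw = logw - logw.max()
    w = np.exp(logw)
    probs = w / w.sum()
    return x, np.array([probs[probs <= probs[i] * (1 + tie_rel)].sum() for i in range(len(x))])


def cmle_all(r1, r2, c1, tol=1e-10):
    """Conditional-MLE odds ratios for every table with these margins
    (NaN for a degenerate support; 0 / inf at the boundaries)."""
    x, logw = margin_log_weights(r1, r2, c1)
    if len(x) == 1:
        return x, np.array([np.nan])
    out = np.empty(len(x))
    for i, a in enumerate(x):
        if a == x[0]:
            out[i] = 0.0
        elif a == x[-1]:
            out[i] = np.inf
        else:
            lo_l, hi_l = -50.0, 50.0
            while hi_l - lo_l > tol:
                mid = 0.5 * (lo_l + hi_l)
                logp = logw + x * mid
                logp -= logp.max()
                p = np.exp(logp)
                if float((x * p).sum() / p.sum()) < a:
                    lo_l = mid
                else:
                    hi_l = mid
            out[i] = np.exp(0.5 * (lo_l + hi_l))
    return x, out
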
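"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they verify: the coloc oracle
evaluates every Bayes factor and hypothesis weight in 50-digit mpmath
arithmetic by direct summation (no log-sum-exp), the ABF oracle
integrates the two-Gaussian marginal likelihood ratio numerically, and
the pruning oracle enumerates subsets instead of iterating greedily.
"""

from __future__ import annotations

import numpy as np
from mpmath import mp, mpf, exp as mpexp, log as mplog, sqrt as mpsqrt, pi as mppi
from scipy.integrate import quad

mp.dps = 50


def abf_by_integration(beta: float, se: float, prior_sd: float) -> float:
    """log ABF via numerical integration of N(b; t, V) N(t; 0, W) dt over t."""
    V, W = se**2, prior_sd**2

    def integrand(t):
        return (
            np.exp(-((beta - t) ** 2) / (2 * V))
            / np.sqrt(2 * np.pi * V)
            * np.exp(-(t**2) / (2 * W))
            / np.sqrt(2 * np.pi * W)
        )

    lim = 12 * max(se, prior_sd, abs(beta))
    post_mean = beta * prior_sd**2 / (V + W)
    num, _ = quad(
        integrand, -lim, lim, limit=400,
        points=[0.0, post_mean, beta], epsabs=0, epsrel=1e-11,
    )
    den = np.exp(-(beta**2) / (2 * V)) / np.sqrt(2 * np.pi * V)
    return float(np.log(num / den))


def log_abf_mp(beta, se, prior_sd):
    """Wakefield log-ABF in extended precision."""
    V = mpf(se) ** 2
    W = mpf(prior_sd) ** 2
    r = W / (W + V)
    z = mpf(beta) / mpf(se)
    return mpf("0.5") * (mplog(1 - r) + r * z * z)


def coloc_posteriors_mp(
    beta_exp, se_exp, beta_out, se_out, p1=1e-4, p2=1e-4, p12=1e-5,
    sd_quant=0.15, sd_binary=0.2,
):
    """H0..H4 posteriors by direct extended-precision summation."""
    b1 = [mpexp(log_abf_mp(b, s, sd_quant)) for b, s in zip(beta_exp, se_exp)]
    b2 = [mpexp(log_abf_mp(b, s, sd_binary)) for b, s in zip(beta_out, se_out)]
    s1 = sum(b1)
    s2 = sum(b2)
    s12 = sum(x * y for x, y in zip(b1, b2))
    w = [
        mpf(1),
        mpf(p1) * s1,
        mpf(p2) * s2,
        mpf(p1) * mpf(p2) * (s1 * s2 - s12),
        mpf(p12) * s12,
    ]
    total = sum(w)
    return np.array([float(x / total) for x in w])


def single_variant_posteriors(labf1: float, labf2: float, p1=1e-4, p2=1e-4, p12=1e-5):
    """Closed-form hypothesis weights for a one-variant region."""
    b1, b2 = np.exp(labf1), np.exp(labf2)
    w = np.array([1.0, p1 * b1, p2 * b2, 0.0, p12 * b1 * b2])
    return w / w.sum()


def greedy_prune_by_enumeration(p_values, ids, r2, r2_threshold):
    """The greedy-by-p accepted set, found by subset enumeration.

    Among all subsets whose members pairwise satisfy r^2 < threshold and
    that are maximal under the greedy acceptance rule, the greedy result
    is the unique valid subset S such that every excluded candidate
    conflicts with a member of S of smaller p-rank.  Enumerate and find it.
    """
    order = sorted(range(len(ids)), key=lambda j: (p_values[j], ids[j]))
    rank = {j: k for k, j in enumerate(order)}
    n = len(ids)
    for mask in range(2**n):
        S = [j for j in range(n) if mask >> j & 1]
        if any(r2[a][b] >= r2_threshold for i, a in enumerate(S) for b in S[i + 1:]):
            continue
        ok = True
        for j in range(n):
            if j in S:
                continue
            if not any(r2[j][a] >= r2_threshold and rank[a] < rank[j] for a in S):
                ok = False
                break
        if ok:
            return [ids[j] for j in sorted(S, key=lambda j: rank[j])]
    raise AssertionError("no greedy-consistent subset found")
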
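"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles and deliberately avoids
reusing the package's own helper functions, so agreement between the two
routes is informative.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
from scipy import optimize, stats


def allele_freqs_by_enumeration(calls: list[str]) -> dict[str, float]:
    """Allele frequencies by literally enumerating every allele character."""
    chars = [a for call in calls for a in call]
    counts = Counter(chars)
    total = sum(counts.values())
    return {a: c / total for a, c in counts.items()}


def hwe_chi2_recompute(counts) -> float:
    """Sum (obs-exp)^2/exp via scipy's chisquare against HWE expectations."""
    n_rr, n_het, n_aa = counts
    n = n_rr + n_het + n_aa
    p = (2 * n_rr + n_het) / (2 * n)
    q = 1 - p
    exp = np.array([n * p * p, n * 2 * p * q, n * q * q])
    return float(stats.chisquare(np.asarray(counts, float), f_exp=exp).statistic)


def compatible_pairs_brute(calls: list[str]) -> list[tuple[str, str]]:
    """All unordered haplotype pairs consistent with one individual's calls,
    by brute force over every per-locus ordering of the two alleles."""
    pairs = set()
    for orders in itertools.product(*[[(c[0], c[1]), (c[1], c[0])] for c in calls]):
        h1 = "".join(a for a, _ in orders)
        h2 = "".join(b for _, b in orders)
        pairs.add(tuple(sorted((h1, h2))))
    return sorted(pairs)


def haplotype_loglik(freq_by_hap: dict[str, float], genotype_rows: list[list[str]]) -> float:
    """Multinomial phase-mixture log-likelihood of unphased genotypes."""
    ll = 0.0
    for calls in genotype_rows:
        prob = 0.0
        for h1, h2 in compatible_pairs_brute(calls):
            f1 = freq_by_hap.get(h1, 0.0)
            f2 = freq_by_hap.get(h2, 0.0)
            prob += f1 * f2 if h1 == h2 else 2 * f1 * f2
        ll += np.log(max(prob, 1e-300))
    return ll


def max_likelihood_haplotypes(
    genotype_rows: list[list[str]], seed: int = 0, n_starts: int = 40
) -> dict[str, float]:
    """Maximize the phase-mixture likelihood over the frequency simplex.

    Multi-start SLSQP (Dirichlet starts + the uniform point), polished at
    tight tolerance; the haplotype space is every haplotype compatible
    with at least one individual.
    """
    haps = sorted({h for calls in genotype_rows for pair in compatible_pairs_brute(calls) for h in pair})
    H = len(haps)

    def neg_ll(x):
        f = np.clip(x, 1e-12, None)
        f = f / f.sum()
        return -haplotype_loglik(dict(zip(haps, f)), genotype_rows)

    rng = np.random.default_rng(seed)
    best_x, best_val = None, np.inf
    starts = [np.full(H, 1.0 / H)] + [rng.dirichlet(np.ones(H)) for _ in range(n_starts - 1)]
    cons = {"type": "eq", "fun": lambda x: x.sum() - 1.0}
    for x0 in starts:
        res = optimize.minimize(
            neg_ll, x0, method="SLSQP", bounds=[(0.0, 1.0)] * H,
            constraints=[cons], options={"maxiter": 500, "ftol": 1e-14},
        )
        if res.fun < best_val:
            best_val, best_x = res.fun, res.x
    f = np.clip(best_x, 0.0, None)
    f = f / f.sum()
    return dict(zip(haps, f))
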
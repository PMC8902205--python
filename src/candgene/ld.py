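"""EM haplotype-frequency estimation, linkage disequilibrium, and diplotypes.

Haplotype frequencies are estimated from unphased multi-locus genotypes
by the classic expectation-maximization scheme over phase
configurations: the E-step distributes each individual's unit weight
over all haplotype pairs compatible with its genotype in proportion to
the current pair probabilities (``2 f_h f_k`` for h != k, ``f_h^2``
otherwise, i.e. random union of gametes), and the M-step re-estimates
frequencies from the expected haplotype counts.  The log-likelihood is
non-decreasing across iterations, which the implementation checks.

Because the all-double-heterozygote configuration makes the
linkage-equilibrium product point a stationary saddle, each restart
starts from the product frequencies plus a small deterministic
seed-driven jitter; the best restart by final log-likelihood is kept.

Pairwise LD statistics (D, D', r^2) are computed from two-locus
haplotype frequencies estimated on pairwise-complete cases; multi-locus
estimation uses listwise-complete cases.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import MonomorphicLocusError, UndefinedStatisticError
from .io import GenotypeMatrix, SnpDef

STRONG_LD_R2 = 0.33  # conventional "strong linkage" threshold for mapping


@dataclass
class HaplotypeSet:
    """EM-estimated haplotype frequencies over an ordered subset of loci."""

    loci: list[str]
    haplotypes: list[str]
    freqs: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    loglik_history: list[float] = field(default_factory=list)
    n_discarded: int = 0  # set by filter_haplotypes
    discarded_mass: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.haplotypes, (float(f) for f in self.freqs)))

    def frequency(self, haplotype: str) -> float:
        try:
            return float(self.freqs[self.haplotypes.index(haplotype)])
        except ValueError:
            return 0.0


@dataclass(frozen=True)
class LdPair:
    """Pairwise linkage-disequilibrium summary for one locus pair."""

    locus_a: str
    locus_b: str
    d: float
    d_prime: float
    r2: float

    @property
    def strong(self) -> bool:
        return self.r2 > STRONG_LD_R2


@dataclass
class DiplotypeAssignment:
    """Maximum-posterior haplotype pair for one individual."""

    individual_id: str
    hap_pair: tuple[str, str]  # lexicographically ordered
    posterior: float
    class_label: str  # concatenated per-locus genotype string
    flagged: bool = False  # True when no retained pair was compatible


def _compatible_pairs(calls: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered haplotype pairs consistent with one individual's calls.

    With ``h`` heterozygous loci there are ``max(1, 2**(h-1))`` distinct
    unordered phase configurations.
    """
    het_idx = [i for i, c in enumerate(calls) if c[0] != c[1]]
    base_a = [c[0] for c in calls]
    base_b = [c[1] for c in calls]
    if not het_idx:
        h = "".join(base_a)
        return [(h, h)]
    pairs = []
    # fix the phase of the first het locus to avoid double counting
    for flips in itertools.product((False, True), repeat=len(het_idx) - 1):
        a = base_a[:]
        b = base_b[:]
        for j, flip in zip(het_idx[1:], flips):
            if flip:
                a[j], b[j] = b[j], a[j]
        h1, h2 = "".join(a), "".join(b)
        pairs.append((h1, h2) if h1 <= h2 else (h2, h1))
    return pairs


def _pair_index(pairs_per_pattern, haplotypes):
    index = {h: i for i, h in enumerate(haplotypes)}
    return [
        np.array([(index[a], index[b]) for a, b in pairs], dtype=np.intp)
        for pairs in pairs_per_pattern
    ]


def _loglik(freqs, pair_idx, weights):
    ll = 0.0
    for idx, w_count in zip(pair_idx, weights):
        fa = freqs[idx[:, 0]]
        fb = freqs[idx[:, 1]]
        w = np.where(idx[:, 0] == idx[:, 1], fa * fb, 2.0 * fa * fb)
        ll += w_count * np.log(max(w.sum(), 1e-300))
    return ll


def em_haplotype_frequencies(
    gm: GenotypeMatrix,
    loci: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_restarts: int = 5,
    seed: int = 0,
) -> HaplotypeSet:
    """Estimate haplotype frequencies at the chosen loci by EM.

    Individuals with any missing call at the chosen loci are dropped
    (listwise complete cases).  The haplotype space is restricted to
    haplotypes compatible with at least one observed genotype.  Restarts
    jitter the linkage-equilibrium initial point; the fit with the best
    final log-likelihood is returned.  Non-convergence within
    ``max_iter`` is reported through ``converged=False``, never silently.
    """
    loci = list(loci) if loci is not None else gm.locus_ids
    cc = gm.complete_cases(loci)
    if cc.n == 0:
        raise UndefinedStatisticError(
            f"no individual has complete genotypes at loci {loci}"
        )
    # collapse identical multi-locus genotype patterns into weighted groups:
    # the E-step only depends on the pattern, not the individual
    pattern_counts: dict[tuple[str, ...], int] = {}
    for ind in cc.individual_ids:
        pattern = tuple(cc.calls.at[ind, l] for l in loci)
        pattern_counts[pattern] = pattern_counts.get(pattern, 0) + 1
    patterns = sorted(pattern_counts)
    weights = np.array([pattern_counts[p] for p in patterns], dtype=float)
    pairs_per_pattern = [_compatible_pairs(list(p)) for p in patterns]
    haplotypes = sorted({h for pairs in pairs_per_pattern for pair in pairs for h in pair})
    pair_idx = _pair_index(pairs_per_pattern, haplotypes)
    H = len(haplotypes)
    n = cc.n

    # linkage-equilibrium product start from per-locus allele frequencies
    allele_freq = []
    for j, l in enumerate(loci):
        col = [cc.calls.at[ind, l] for ind in cc.individual_ids]
        counts: dict[str, int] = {}
        for call in col:
            for a in call:
                counts[a] = counts.get(a, 0) + 1
        allele_freq.append({a: c / (2 * n) for a, c in counts.items()})
    product_start = np.array(
        [np.prod([allele_freq[j][h[j]] for j in range(len(loci))]) for h in haplotypes]
    )
    product_start = np.maximum(product_start, 1e-12)
    product_start /= product_start.sum()

    rng = np.random.default_rng(seed)
    best: HaplotypeSet | None = None
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            freqs = product_start.copy()
        else:
            jitter = rng.uniform(0.5, 1.5, size=H)
            freqs = product_start * jitter
            freqs /= freqs.sum()
        history = [_loglik(freqs, pair_idx, weights)]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            expected = np.zeros(H)
            for idx, w_count in zip(pair_idx, weights):
                fa = freqs[idx[:, 0]]
                fb = freqs[idx[:, 1]]
                w = np.where(idx[:, 0] == idx[:, 1], fa * fb, 2.0 * fa * fb)
                total = w.sum()
                if total <= 0:
                    w = np.full_like(w, 1.0 / len(w))
                    total = 1.0
                w = w_count * (w / total)
                np.add.at(expected, idx[:, 0], w)
                np.add.at(expected, idx[:, 1], w)
            freqs = expected / (2.0 * n)
            history.append(_loglik(freqs, pair_idx, weights))
            if abs(history[-1] - history[-2]) < tol:
                converged = True
                break
        candidate = HaplotypeSet(
            loci=loci,
            haplotypes=list(haplotypes),
            freqs=freqs,
            loglik=history[-1],
            n_iter=it,
            converged=converged,
            loglik_history=history,
        )
        if best is None or candidate.loglik > best.loglik:
            best = candidate
    assert best is not None
    return best


def ld_from_haplotypes(
    hap_freqs: Mapping[str, float] | Sequence[float],
    snp_a: SnpDef | None = None,
    snp_b: SnpDef | None = None,
    locus_a: str = "A",
    locus_b: str = "B",
) -> LdPair:
    """D, D', and r^2 from two-locus haplotype frequencies.

    ``hap_freqs`` is either the length-4 sequence
    ``(f_AB, f_Ab, f_aB, f_ab)`` in ref/alt order, or a mapping from
    two-character haplotype strings to frequencies (requires ``snp_a``
    and ``snp_b`` to fix which allele is "ref" at each locus — the
    statistics themselves are invariant to that labeling).

    ``D = f_AB - p_A p_B``; ``D' = |D| / D_max`` with the usual
    sign-dependent ``D_max`` and is defined as 0 at linkage equilibrium;
    ``r^2 = D^2 / (p_A p_a p_B p_b)``.
    """
    if isinstance(hap_freqs, Mapping):
        if snp_a is None or snp_b is None:
            raise ValueError("mapping input requires snp_a and snp_b")
        locus_a, locus_b = snp_a.locus_id, snp_b.locus_id
        f = np.zeros(4)
        order = [
            snp_a.allele_ref + snp_b.allele_ref,
            snp_a.allele_ref + snp_b.allele_alt,
            snp_a.allele_alt + snp_b.allele_ref,
            snp_a.allele_alt + snp_b.allele_alt,
        ]
        for hap, freq in hap_freqs.items():
            if hap not in order:
                raise ValueError(f"haplotype {hap!r} uses alleles outside the two loci")
            f[order.index(hap)] += freq
    else:
        f = np.asarray(hap_freqs, dtype=float)
        if f.shape != (4,):
            raise ValueError("expected 4 haplotype frequencies (f_AB, f_Ab, f_aB, f_ab)")
    total = f.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError("haplotype frequencies must sum to 1")
    f = f / total
    f_ab_, f_aB, f_Ab, f_AB = f[3], f[2], f[1], f[0]
    p_A = f_AB + f_Ab
    p_B = f_AB + f_aB
    p_a, p_b = 1.0 - p_A, 1.0 - p_B
    if min(p_A, p_a) <= 0 or min(p_B, p_b) <= 0:
        raise MonomorphicLocusError("LD undefined: a locus is monomorphic")
    d = f_AB - p_A * p_B
    if d > 0:
        d_max = min(p_A * p_b, p_a * p_B)
    else:
        d_max = min(p_A * p_B, p_a * p_b)
    d_prime = 0.0 if d == 0.0 else abs(d) / d_max
    r2 = d * d / (p_A * p_a * p_B * p_b)
    return LdPair(locus_a, locus_b, float(d), float(d_prime), float(r2))


@dataclass
class LdMatrixResult:
    """All pairwise LD statistics plus their summary means."""

    pairs: list[LdPair]
    mean_d_prime: float
    mean_r2: float
    errors: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def strong_pairs(self) -> list[tuple[str, str]]:
        return [(p.locus_a, p.locus_b) for p in self.pairs if p.strong]


def ld_summary(pairs: Sequence[LdPair]) -> LdMatrixResult:
    """Summarize a set of pairwise LD values (means over all pairs, strong flags)."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no LD pairs to summarize")
    return LdMatrixResult(
        pairs=pairs,
        mean_d_prime=float(np.mean([p.d_prime for p in pairs])),
        mean_r2=float(np.mean([p.r2 for p in pairs])),
    )


def ld_matrix(gm: GenotypeMatrix, tol: float = 1e-8, max_iter: int = 1000,
              n_restarts: int = 5, seed: int = 0) -> LdMatrixResult:
    """Two-locus EM on every locus pair (pairwise-complete cases) + summary means.

    Pairs where LD is undefined (e.g. a monomorphic locus) are recorded
    in ``errors`` rather than aborting the matrix.
    """
    loci = gm.locus_ids
    if len(loci) < 2:
        raise ValueError("need at least two loci for an LD matrix")
    pairs: list[LdPair] = []
    errors: dict[tuple[str, str], str] = {}
    for la, lb in itertools.combinations(loci, 2):
        try:
            hs = em_haplotype_frequencies(
                gm, [la, lb], tol=tol, max_iter=max_iter, n_restarts=n_restarts, seed=seed
            )
            pairs.append(
                ld_from_haplotypes(hs.as_dict(), gm.snp(la), gm.snp(lb))
            )
        except (MonomorphicLocusError, UndefinedStatisticError) as exc:
            errors[(la, lb)] = str(exc)
    if not pairs:
        raise UndefinedStatisticError("LD undefined for every locus pair")
    result = ld_summary(pairs)
    result.errors = errors
    return result


def filter_haplotypes(hapset: HaplotypeSet, min_freq: float = 0.05) -> HaplotypeSet:
    """Drop haplotypes below ``min_freq``; retained frequencies are NOT renormalized.

    The common reporting convention keeps the raw estimated frequencies
    (so the retained set may sum to less than 1) and states how much
    mass was discarded.
    """
    if not 0.0 <= min_freq < 1.0:
        raise ValueError("min_freq must lie in [0, 1)")
    keep = hapset.freqs >= min_freq
    return HaplotypeSet(
        loci=list(hapset.loci),
        haplotypes=[h for h, k in zip(hapset.haplotypes, keep) if k],
        freqs=hapset.freqs[keep],
        loglik=hapset.loglik,
        n_iter=hapset.n_iter,
        converged=hapset.converged,
        loglik_history=list(hapset.loglik_history),
        n_discarded=int((~keep).sum()),
        discarded_mass=float(hapset.freqs[~keep].sum()),
    )


def _class_label(calls: Sequence[str]) -> str:
    return "".join(calls)


def assign_diplotypes(
    gm: GenotypeMatrix,
    hapset: HaplotypeSet,
    full_hapset: HaplotypeSet | None = None,
    min_class_freq: float = 0.05,
):
    """Maximum-posterior diplotype per complete-case individual + class table.

    Each individual is assigned the compatible haplotype pair with the
    highest probability under the EM frequencies (ties broken
    lexicographically, so assignment is deterministic).  Individuals
    compatible with no pair from the retained set fall back to
    ``full_hapset`` (the unfiltered estimate) and are flagged.

    Returns ``(assignments, class_freqs, retained_classes)`` where
    ``class_freqs`` maps class label -> population frequency and
    ``retained_classes`` keeps the classes at or above ``min_class_freq``.
    """
    cc = gm.complete_cases(hapset.loci)
    freq_main = hapset.as_dict()
    freq_full = full_hapset.as_dict() if full_hapset is not None else freq_main
    assignments: list[DiplotypeAssignment] = []
    for ind in cc.individual_ids:
        calls = [cc.calls.at[ind, l] for l in hapset.loci]
        pairs = _compatible_pairs(calls)

        def pair_prob(pair, table):
            fa = table.get(pair[0], 0.0)
            fb = table.get(pair[1], 0.0)
            return fa * fb if pair[0] == pair[1] else 2.0 * fa * fb

        probs = np.array([pair_prob(p, freq_main) for p in pairs])
        flagged = False
        if probs.sum() <= 0.0:
            probs = np.array([pair_prob(p, freq_full) for p in pairs])
            flagged = True
            if probs.sum() <= 0.0:  # degenerate: uniform over phases
                probs = np.ones(len(pairs))
        post = probs / probs.sum()
        order = sorted(range(len(pairs)), key=lambda i: (-post[i], pairs[i]))
        best = order[0]
        assignments.append(
            DiplotypeAssignment(
                individual_id=ind,
                hap_pair=pairs[best],
                posterior=float(post[best]),
                class_label=_class_label(calls),
                flagged=flagged,
            )
        )
    labels = [a.class_label for a in assignments]
    total = len(labels)
    class_freqs = {
        lab: labels.count(lab) / total for lab in sorted(set(labels))
    }
    retained = {lab: f for lab, f in class_freqs.items() if f >= min_class_freq}
    return assignments, class_freqs, retained
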
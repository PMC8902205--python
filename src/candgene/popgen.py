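"""Per-locus frequency estimation, diversity indices, and Hardy-Weinberg tests.

Conventions used throughout:

* ``Ho`` is the *expected* homozygosity ``sum(p_i^2)`` (what older
  livestock-genetics reports call "gene homozygosity"); the gene
  heterozygosity (Nei gene diversity) is ``He = 1 - Ho``.  The observed
  heterozygote proportion is reported separately as ``het_obs`` to avoid
  ambiguity.
* ``Ne = 1 / sum(p_i^2)`` is the effective number of alleles.
* ``PIC`` is the Botstein polymorphism information content
  ``1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2``; for a biallelic locus this
  reduces to ``He - 2 p^2 q^2``.
* The HWE chi-square compares observed genotype counts with
  ``n*(p^2, 2pq, q^2)`` using allele frequencies estimated from the same
  sample, without continuity correction.  ``df_mode="legacy"`` uses 2
  degrees of freedom (the convention of older population-genetics
  packages such as POPGENE, where the printed p-values of several cattle
  diversity reports come from); ``df_mode="standard"`` uses the textbook
  1 df (3 genotype classes, 1 estimated allele frequency).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import MonomorphicLocusError, UndefinedStatisticError
from .io import GenotypeMatrix

DF_MODES = ("legacy", "standard")
#: alias kept because the 2-df convention is what legacy reports print
DF_MODE_DEFAULT = "legacy"


@dataclass
class LocusStats:
    """One locus's frequency, diversity, and HWE summary."""

    locus_id: str
    genotype_counts: tuple[int, int, int]  # (ref-hom, het, alt-hom)
    genotype_freqs: tuple[float, float, float]
    allele_freqs: tuple[float, float]  # (p_ref, p_alt)
    het_obs: float
    ho: float
    he: float
    ne: float
    pic: float
    chi2: float
    df: int
    p_value: float
    error: str | None = None


def allele_frequencies(genotype_counts: Sequence[float]) -> tuple[float, float]:
    """Allele frequencies by gene counting from (ref-hom, het, alt-hom) counts.

    Accepts counts or proportions; ``p_ref = (2*n_rr + n_het) / (2*n_total)``.
    """
    n_rr, n_het, n_aa = (float(c) for c in genotype_counts)
    total = n_rr + n_het + n_aa
    if total <= 0:
        raise UndefinedStatisticError("no non-missing genotypes: allele frequency undefined")
    p_ref = (2.0 * n_rr + n_het) / (2.0 * total)
    return (p_ref, 1.0 - p_ref)


@dataclass(frozen=True)
class DiversityIndices:
    ho: float
    he: float
    ne: float
    pic: float


def diversity_indices(allele_freqs: Sequence[float]) -> DiversityIndices:
    """Expected homozygosity, gene diversity, effective allele number, and PIC.

    Works for any number of alleles; a monomorphic locus returns
    ``(Ho=1, He=0, Ne=1, PIC=0)``.
    """
    p = np.asarray(allele_freqs, dtype=float)
    if p.size < 1 or not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("allele frequencies must sum to 1")
    ho = float(np.sum(p**2))
    he = 1.0 - ho
    ne = 1.0 / ho
    pq2 = np.outer(p**2, p**2)
    pic = he - float(np.sum(np.triu(pq2, k=1))) * 2.0
    return DiversityIndices(ho=ho, he=he, ne=ne, pic=pic)


def hwe_expected_counts(genotype_counts: Sequence[float]) -> np.ndarray:
    """Hardy-Weinberg expected (ref-hom, het, alt-hom) counts at the sample's allele freqs."""
    n = float(sum(genotype_counts))
    p, q = allele_frequencies(genotype_counts)
    return n * np.array([p * p, 2.0 * p * q, q * q])


def hwe_chi2_test(
    genotype_counts: Sequence[float], df_mode: str = DF_MODE_DEFAULT
) -> tuple[float, int, float]:
    """Plain chi-square goodness-of-fit test of Hardy-Weinberg proportions.

    Returns ``(chi2, df, p_value)``.  No continuity correction and no
    exact test; see the module docstring for the two df conventions.
    """
    if df_mode not in DF_MODES:
        raise ValueError(f"df_mode must be one of {DF_MODES}")
    p, q = allele_frequencies(genotype_counts)
    if p == 0.0 or q == 0.0:
        raise MonomorphicLocusError("HWE test undefined at a monomorphic locus")
    obs = np.asarray(genotype_counts, dtype=float)
    exp = hwe_expected_counts(genotype_counts)
    if np.any(exp <= 0):
        raise UndefinedStatisticError("zero expected genotype count")
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    df = 2 if df_mode == "legacy" else 1
    p_value = float(stats.chi2.sf(chi2, df))
    return chi2, df, p_value


def summarize_loci(gm: GenotypeMatrix, df_mode: str = DF_MODE_DEFAULT) -> list[LocusStats]:
    """One :class:`LocusStats` row per panel locus (complete cases per locus).

    Per-locus failures (all-missing or monomorphic loci) are returned as
    flagged rows rather than aborting the whole summary.
    """
    rows = []
    for snp in gm.panel:
        counts = gm.genotype_counts(snp.locus_id)
        n = sum(counts)
        try:
            freqs = allele_frequencies(counts)
            div = diversity_indices(freqs)
            gfreq = tuple(c / n for c in counts)
            het_obs = counts[1] / n
            try:
                chi2, df, pval = hwe_chi2_test(counts, df_mode)
                err = None
            except MonomorphicLocusError as exc:
                chi2, df, pval, err = float("nan"), 0, float("nan"), str(exc)
            rows.append(
                LocusStats(
                    locus_id=snp.locus_id,
                    genotype_counts=counts,
                    genotype_freqs=gfreq,
                    allele_freqs=freqs,
                    het_obs=het_obs,
                    ho=div.ho,
                    he=div.he,
                    ne=div.ne,
                    pic=div.pic,
                    chi2=chi2,
                    df=df,
                    p_value=pval,
                    error=err,
                )
            )
        except UndefinedStatisticError as exc:
            rows.append(
                LocusStats(
                    locus_id=snp.locus_id,
                    genotype_counts=counts,
                    genotype_freqs=(float("nan"),) * 3,
                    allele_freqs=(float("nan"),) * 2,
                    het_obs=float("nan"),
                    ho=float("nan"),
                    he=float("nan"),
                    ne=float("nan"),
                    pic=float("nan"),
                    chi2=float("nan"),
                    df=0,
                    p_value=float("nan"),
                    error=str(exc),
                )
            )
    return rows
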
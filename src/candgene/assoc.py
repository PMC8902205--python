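"""Marker-trait and diplotype-trait association under a fixed-effects linear model.

The model is the standard candidate-gene design

    y = mu + genotype_class + age_class + sire + residual

fitted by ordinary least squares with reference-level dummy coding.
Sire enters as a fixed blocking factor (see docs/methods.md for why a
mixed model is deliberately out of scope).  Class means are reported
both raw and as least-squares means (the class prediction averaged over
covariate levels with equal weight), with the overall class effect
tested by a partial F-test and all pairwise class contrasts adjusted by
Bonferroni within one trait x marker family.  Pairwise significance is
summarized with compact grouping letters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ValidationError


@dataclass
class ClassSummary:
    label: str
    n: int
    lsmean: float
    lsmean_se: float
    raw_mean: float
    raw_se: float
    letters: str = ""


@dataclass
class AssocResult:
    """Association of one trait with one classification (marker or diplotype)."""

    trait: str
    class_column: str
    classes: list[ClassSummary]
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    pairwise: pd.DataFrame  # columns: class_a, class_b, estimate, se, p_raw, p_adj
    alpha: float
    n_obs: int

    def class_summary(self, label: str) -> ClassSummary:
        for c in self.classes:
            if c.label == label:
                return c
        raise KeyError(label)


def pairwise_bonferroni(p_values: Sequence[float], m: int) -> list[float]:
    """Bonferroni adjustment ``min(1, m*p)`` for a family of ``m`` comparisons."""
    p_values = list(p_values)
    if m < len(p_values):
        raise ValueError(f"family size m={m} smaller than number of tests {len(p_values)}")
    if m < 1:
        raise ValueError("family size must be >= 1")
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
    return [min(1.0, m * p) for p in p_values]


def _grouping_letters(
    labels: Sequence[str],
    lsmeans: Mapping[str, float],
    significant: Mapping[tuple[str, str], bool],
) -> dict[str, str]:
    """Compact letter display by greedy clique cover of the non-significant graph.

    Classes are processed in descending LS-mean order; a class joins every
    existing letter group it is non-significantly different from all
    members of, and founds a new group if it joins none.
    """
    order = sorted(labels, key=lambda l: (-lsmeans[l], l))

    def ns(a: str, b: str) -> bool:
        return not significant.get((a, b), significant.get((b, a), False))

    groups: list[list[str]] = []
    for lab in order:
        joined = False
        for g in groups:
            if all(ns(lab, other) for other in g):
                g.append(lab)
                joined = True
        if not joined:
            groups.append([lab])
    letters = {lab: "" for lab in labels}
    for i, g in enumerate(groups):
        ch = chr(ord("a") + i)
        for lab in g:
            letters[lab] += ch
    return letters


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify columns that are linear combinations of their predecessors
        aliased = []
        for j in range(1, arr.shape[1]):
            sub = arr[:, : j + 1]
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                aliased.append(X.columns[j])
        raise ValidationError(
            f"design matrix is rank deficient; aliased column(s): {aliased}"
        )


def fit_trait_model(
    data: pd.DataFrame,
    class_column: str,
    trait: str,
    covariates: Sequence[str] = ("age", "sire"),
    alpha: float = 0.05,
    min_class_count: int = 2,
) -> AssocResult:
    """Fit the fixed-effects model for one trait and one classification.

    ``data`` must contain ``class_column``, ``trait`` and the covariate
    columns; rows with any of them missing are dropped (complete-case).
    Classes with fewer than ``min_class_count`` observations are dropped;
    at least two classes must remain.
    """
    cols = [class_column, trait, *covariates]
    for c in cols:
        if c not in data.columns:
            raise ValidationError(f"column {c!r} missing from data")
    df = data[cols].dropna().copy()
    df[trait] = pd.to_numeric(df[trait])
    counts = df[class_column].value_counts()
    keep = counts[counts >= min_class_count].index
    df = df[df[class_column].isin(keep)]
    labels = sorted(df[class_column].unique())
    if len(labels) < 2:
        raise ValidationError(
            f"need >= 2 classes with >= {min_class_count} observations; got {labels}"
        )

    y = df[trait].to_numpy(dtype=float)
    X = pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)
    class_cols = []
    for lab in labels[1:]:
        col = f"{class_column}[{lab}]"
        X[col] = (df[class_column] == lab).astype(float)
        class_cols.append(col)
    cov_levels: dict[str, list] = {}
    for cov in covariates:
        levels = sorted(df[cov].astype(str).unique())
        cov_levels[cov] = levels
        for lev in levels[1:]:
            X[f"{cov}[{lev}]"] = (df[cov].astype(str) == lev).astype(float)
    _check_full_rank(X)

    model = sm.OLS(y, X)
    res = model.fit()
    cov_beta = res.cov_params().to_numpy()
    beta = res.params

    def lsmean_contrast(lab: str) -> np.ndarray:
        c = pd.Series(0.0, index=X.columns)
        c["Intercept"] = 1.0
        if lab != labels[0]:
            c[f"{class_column}[{lab}]"] = 1.0
        for cov, levels in cov_levels.items():
            w = 1.0 / len(levels)
            for lev in levels[1:]:
                c[f"{cov}[{lev}]"] = w
        return c.to_numpy()

    classes = []
    for lab in labels:
        c = lsmean_contrast(lab)
        lsm = float(c @ beta)
        se = float(np.sqrt(c @ cov_beta @ c))
        sub = df.loc[df[class_column] == lab, trait].to_numpy(dtype=float)
        classes.append(
            ClassSummary(
                label=lab,
                n=len(sub),
                lsmean=lsm,
                lsmean_se=se,
                raw_mean=float(sub.mean()),
                raw_se=float(sub.std(ddof=1) / np.sqrt(len(sub))) if len(sub) > 1 else float("nan"),
            )
        )

    # overall class effect: partial F-test on all class dummies
    R = np.zeros((len(class_cols), X.shape[1]))
    for i, col in enumerate(class_cols):
        R[i, X.columns.get_loc(col)] = 1.0
    ftest = res.f_test(R)
    f_stat = float(np.squeeze(ftest.fvalue))
    p_value = float(np.squeeze(ftest.pvalue))
    df_num = int(ftest.df_num)
    df_den = int(ftest.df_denom)

    # pairwise contrasts with Bonferroni over all k(k-1)/2 pairs
    pairs = list(itertools.combinations(labels, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        c = lsmean_contrast(a) - lsmean_contrast(b)
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov_beta @ c))
        t = est / se
        p_raw = 2.0 * float(stats.t.sf(abs(t), res.df_resid))
        rows.append({"class_a": a, "class_b": b, "estimate": est, "se": se, "p_raw": p_raw})
    pairwise = pd.DataFrame(rows)
    pairwise["p_adj"] = pairwise_bonferroni(list(pairwise["p_raw"]), m) if m else []

    significant = {
        (r.class_a, r.class_b): bool(r.p_adj < alpha) for r in pairwise.itertuples()
    }
    letters = _grouping_letters(labels, {c.label: c.lsmean for c in classes}, significant)
    for c in classes:
        c.letters = letters[c.label]

    return AssocResult(
        trait=trait,
        class_column=class_column,
        classes=classes,
        f_stat=f_stat,
        df_num=df_num,
        df_den=df_den,
        p_value=p_value,
        pairwise=pairwise,
        alpha=alpha,
        n_obs=len(df),
    )


@dataclass
class AssociationReport:
    """All marker-level and diplotype-level fits for the requested traits."""

    marker_results: dict[tuple[str, str], AssocResult] = field(default_factory=dict)
    diplotype_results: dict[str, AssocResult] = field(default_factory=dict)
    errors: dict[tuple[str, str], str] = field(default_factory=dict)


def association_report(
    joined: pd.DataFrame,
    markers: Sequence[str],
    traits: Sequence[str],
    diplotype_column: str | None = None,
    retained_diplotype_classes: Sequence[str] | None = None,
    covariates: Sequence[str] = ("age", "sire"),
    alpha: float = 0.05,
) -> AssociationReport:
    """Fit every marker x trait cell plus the diplotype-level analysis.

    ``joined`` is the dataset's joined genotype+trait frame, optionally
    carrying a diplotype class-label column.  Per-cell failures (e.g. a
    marker collapsing to one class after filtering) are recorded in
    ``errors`` rather than aborting the report.
    """
    report = AssociationReport()
    for marker in markers:
        for trait in traits:
            try:
                report.marker_results[(marker, trait)] = fit_trait_model(
                    joined, marker, trait, covariates=covariates, alpha=alpha
                )
            except ValidationError as exc:
                report.errors[(marker, trait)] = str(exc)
    if diplotype_column is not None:
        sub = joined
        if retained_diplotype_classes is not None:
            sub = joined[joined[diplotype_column].isin(set(retained_diplotype_classes))]
        for trait in traits:
            try:
                report.diplotype_results[trait] = fit_trait_model(
                    sub, diplotype_column, trait, covariates=covariates, alpha=alpha
                )
            except ValidationError as exc:
                report.errors[(diplotype_column, trait)] = str(exc)
    return report
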
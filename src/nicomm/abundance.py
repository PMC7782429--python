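"""TPM normalization, gene-group averages, and two-group differential abundance.

TPM (transcripts-per-million-style relative abundance) for feature *f* in
sample *s* is ``(count_fs / length_f) * 1e6 / sum_g(count_gs / length_g)``,
so every sample column sums to 10^6 and within-sample values are comparable
across features of different lengths.

The differential layer is a deliberately simple, calibratable stand-in for
a count-model GLM: Welch's two-sample t-test on log2(TPM + 1) per feature,
Benjamini–Hochberg adjusted, significant at q < alpha (default 0.05).  The
test statistic is pluggable via the ``test`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AbundanceMatrix",
    "compute_tpm",
    "group_mean_abundance",
    "differential_abundance",
    "bh_fdr",
]

TPM_TOTAL = 1.0e6


@dataclass
class AbundanceMatrix:
    """Features × samples abundance values with lengths and group labels.

    ``kind`` is ``"count"`` or ``"tpm"``.  ``validate()`` enforces the
    structural invariants; ``compute_tpm`` always returns a validated
    matrix.
    """

    values: pd.DataFrame
    lengths: pd.Series
    groups: pd.Series
    kind: str = "count"

    def __post_init__(self) -> None:
        self.lengths = self.lengths.reindex(self.values.index)
        self.groups = self.groups.reindex(self.values.columns)

    def validate(self) -> "AbundanceMatrix":
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if (self.lengths <= 0).any() or self.lengths.isna().any():
            bad = self.lengths.index[~(self.lengths > 0)].tolist()
            raise ValueError(f"non-positive or missing length for feature(s) {bad}")
        if self.kind == "tpm":
            sums = self.values.sum(axis=0)
            if not np.allclose(sums, TPM_TOTAL, rtol=1e-9):
                bad = sums.index[~np.isclose(sums, TPM_TOTAL, rtol=1e-9)].tolist()
                raise ValueError(f"TPM columns do not sum to 1e6: {bad}")
        return self

    def group_samples(self, group: str) -> pd.Index:
        samples = self.groups.index[self.groups == group]
        if len(samples) == 0:
            raise ValueError(f"unknown group label '{group}'")
        return samples


def compute_tpm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    groups: pd.Series | None = None,
) -> AbundanceMatrix:
    """Length-normalize a count table to TPM (columns sum to 10^6)."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        bad = lengths.index[~(lengths > 0)].tolist()
        raise ValueError(f"zero/negative or missing length for feature(s) {bad}")
    if (counts.values < 0).any():
        raise ValueError("negative counts")
    rate = counts.div(lengths, axis=0)
    colsum = rate.sum(axis=0)
    zero_cols = colsum.index[colsum == 0].tolist()
    if zero_cols:
        raise ValueError(f"sample(s) with all-zero counts: {zero_cols}")
    tpm = rate.div(colsum, axis=1) * TPM_TOTAL
    if groups is None:
        groups = pd.Series("all", index=counts.columns)
    return AbundanceMatrix(tpm, lengths, groups, kind="tpm").validate()


def group_mean_abundance(
    matrix: AbundanceMatrix, feature_set: Iterable[str], group: str
) -> float:
    """Average abundance of a gene group in one sample group.

    The unweighted arithmetic mean, over the features in the set, of each
    feature's mean value across the group's samples (the convention used to
    report a whole enzyme's gene-group abundance).
    """
    features = list(feature_set)
    if not features:
        raise ValueError("feature_set is empty")
    missing = [f for f in features if f not in matrix.values.index]
    if missing:
        raise ValueError(f"unknown feature id(s): {missing}")
    samples = matrix.group_samples(group)
    per_feature = matrix.values.loc[features, samples].mean(axis=1)
    return float(per_feature.mean())


def bh_fdr(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _welch_log_test(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Welch t-test per row on log2(x+1); returns two-sided p-values.

    Rows with zero variance in both groups get p=1 when the means are
    equal, else p=0 (the limit of the statistic).
    """
    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = stats.ttest_ind(la, lb, axis=1, equal_var=False).pvalue
    va = la.var(axis=1, ddof=1)
    vb = lb.var(axis=1, ddof=1)
    degenerate = (va == 0) & (vb == 0)
    if degenerate.any():
        equal = np.isclose(la.mean(axis=1), lb.mean(axis=1))
        p = np.where(degenerate, np.where(equal, 1.0, 0.0), p)
    p = np.where(np.isnan(p), 1.0, p)
    return p


@dataclass
class DiffResult:
    """Per-feature two-group differential-abundance results.

    ``table`` columns: mean_<ref>, mean_<treat>, log2fc, p, q, direction
    (increased / decreased / unchanged, relative to the reference group).
    """

    table: pd.DataFrame
    reference: str
    treatment: str
    alpha: float = 0.05

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["direction"] != "unchanged"]


def differential_abundance(
    matrix: AbundanceMatrix,
    group_order: tuple[str, str] | None = None,
    alpha: float = 0.05,
    test: Callable[[np.ndarray, np.ndarray], np.ndarray] = _welch_log_test,
) -> DiffResult:
    """Two-group differential abundance with BH-FDR control.

    ``group_order`` is (reference, treatment); direction "increased" means
    higher mean abundance in the treatment group at q < alpha.
    """
    labels = list(dict.fromkeys(matrix.groups))
    if group_order is None:
        if len(labels) != 2:
            raise ValueError(f"need exactly two groups, found {labels}")
        group_order = (labels[0], labels[1])
    ref, treat = group_order
    sa = matrix.group_samples(ref)
    sb = matrix.group_samples(treat)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = matrix.values[sa].to_numpy(float)
    b = matrix.values[sb].to_numpy(float)
    p = test(a, b)
    q = bh_fdr(p)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = np.log2((mean_b + 1.0) / (mean_a + 1.0))
    direction = np.where(
        q < alpha,
        np.where(mean_b > mean_a, "increased", "decreased"),
        "unchanged",
    )
    # a significant feature with exactly equal means cannot be directional
    direction = np.where((q < alpha) & (mean_a == mean_b), "unchanged", direction)
    table = pd.DataFrame(
        {
            f"mean_{ref}": mean_a,
            f"mean_{treat}": mean_b,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "direction": direction,
        },
        index=matrix.values.index,
    )
    return DiffResult(table, ref, treat, alpha)
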
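"""TPM normalization, two-group differential expression and BH FDR.

Differential expression is a transparent substitute for a negative-binomial
model: a Welch two-sided t-test on log2(TPM + 1) with BH correction and the
compound significance rule (adjusted p < 0.05 AND linear |fold change| > 1.5
on group mean TPM with pseudo-count 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ValidationError

__all__ = [
    "ExpressionMatrix",
    "DiffExprResult",
    "tpm_normalize",
    "diff_expression",
    "bh_fdr",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression: raw counts and/or TPM plus gene lengths (nt)."""

    counts: pd.DataFrame | None
    tpm: pd.DataFrame
    lengths_nt: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.tpm.to_numpy() < 0).any():
            raise ValidationError("TPM values must be non-negative")
        sums = self.tpm.sum(axis=0).to_numpy()
        if len(self.tpm) and not np.allclose(sums, 1e6, rtol=1e-6):
            raise ValidationError("TPM columns must each sum to 1e6")

    @property
    def samples(self) -> list[str]:
        return list(self.tpm.columns)


def tpm_normalize(counts: pd.DataFrame, lengths_nt: pd.Series) -> ExpressionMatrix:
    """Transcripts-per-million: rate_g = count_g / length_kb_g, scaled to 1e6.

    ``counts`` is genes x samples (non-negative); ``lengths_nt`` gives each
    gene's effective length in nucleotides (> 0).  A sample with zero total
    counts has no defined normalization and raises.
    """
    lengths_nt = lengths_nt.reindex(counts.index)
    if lengths_nt.isna().any():
        missing = list(lengths_nt.index[lengths_nt.isna()])[:3]
        raise ValidationError(f"missing gene lengths for {missing}")
    if (lengths_nt <= 0).any():
        raise ValidationError("gene lengths must be > 0")
    if (counts.to_numpy() < 0).any():
        raise ValidationError("counts must be non-negative")
    rate = counts.div(lengths_nt / 1_000.0, axis=0)
    total = rate.sum(axis=0)
    if (total == 0).any():
        bad = list(total.index[total == 0])
        raise ValidationError(f"all-zero sample(s) {bad}: TPM undefined")
    tpm = rate.div(total, axis=1) * 1e6
    return ExpressionMatrix(counts=counts, tpm=tpm, lengths_nt=lengths_nt)


@dataclass
class DiffExprResult:
    gene_id: str
    log2_fc: float  # group1 vs group2, mean TPM with pseudo-count 1
    p: float
    adj_p: float = np.nan
    deg_flag: bool = False


def diff_expression(
    expr: ExpressionMatrix,
    groups: dict[str, str],
    fdr: float = 0.05,
    min_fold: float = 1.5,
) -> list[DiffExprResult]:
    """Welch t-test on log2(TPM+1) per gene between two groups, BH-adjusted.

    Group 1 is the lexicographically smaller label; ``deg_flag`` is true when
    adjusted p < ``fdr`` and the linear fold change exceeds ``min_fold`` in
    either direction.  Zero-variance genes with equal means get p = 1.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValidationError(f"diff_expression requires exactly two groups, got {labels}")
    g1 = [s for s in expr.samples if groups.get(s) == labels[0]]
    g2 = [s for s in expr.samples if groups.get(s) == labels[1]]
    if len(g1) < 3 or len(g2) < 3:
        raise ValidationError("need >= 3 samples per group")
    log1 = np.log2(expr.tpm[g1].to_numpy(dtype=float) + 1.0)
    log2_ = np.log2(expr.tpm[g2].to_numpy(dtype=float) + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(log1, log2_, axis=1, equal_var=False)
    # zero variance in both groups: equal means -> p = 1 by convention,
    # different means -> p = 0 (an infinite-t limit)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        equal = np.isclose(log1.mean(axis=1), log2_.mean(axis=1))
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    mean1 = expr.tpm[g1].mean(axis=1).to_numpy() + 1.0
    mean2 = expr.tpm[g2].mean(axis=1).to_numpy() + 1.0
    log2fc = np.log2(mean1 / mean2)
    adj = bh_fdr(p)
    min_log2 = np.log2(min_fold)
    return [
        DiffExprResult(
            gene_id=g,
            log2_fc=float(fc),
            p=float(pv),
            adj_p=float(ap),
            deg_flag=bool(ap < fdr and abs(fc) > min_log2),
        )
        for g, fc, pv, ap in zip(expr.tpm.index, log2fc, p, adj)
    ]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
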
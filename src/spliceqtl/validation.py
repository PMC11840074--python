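"""Validation-arm statistics: 2^-ddCt qPCR quantification, genotype-group
comparisons and rank correlations with blood phenotypes.

Relative qPCR quantification follows the delta-delta-Ct method with a fixed
amplification efficiency of 2: per sample, dCt = Ct_target - Ct_reference;
ddCt subtracts the arithmetic mean dCt of the control group; fold change =
2^-ddCt.  A plate shift that moves target and reference Ct equally cancels
exactly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

__all__ = [
    "CtTable",
    "FoldChangeResult",
    "ddct_fold_change",
    "group_difference_test",
    "spearman_assoc",
]


@dataclass
class CtTable:
    """Long-format qPCR Ct values: one row per (sample, gene) measurement.

    ``df`` columns: sample, gene, ct, group; ``reference_gene`` names the
    normalizer (e.g. HPRT1 or RPL13A).  Every sample must carry a
    reference-gene Ct; all Ct values are positive cycle numbers.
    """

    df: pd.DataFrame
    reference_gene: str

    def __post_init__(self) -> None:
        required = {"sample", "gene", "ct", "group"}
        if not required.issubset(self.df.columns):
            raise ValidationError(f"Ct table needs columns {sorted(required)}")
        if (self.df["ct"] <= 0).any():
            raise ValidationError("Ct values must be > 0")
        if self.reference_gene not in set(self.df["gene"]):
            raise ValidationError(f"reference gene {self.reference_gene!r} absent from table")

    @classmethod
    def read_tsv(cls, path, reference_gene: str) -> "CtTable":
        return cls(pd.read_csv(path, sep="\t"), reference_gene)

    def write_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class FoldChangeResult:
    sample: str
    gene: str
    group: str
    delta_ct: float
    delta_delta_ct: float
    fold: float


def ddct_fold_change(ct: CtTable, control_group_label: str) -> list[FoldChangeResult]:
    """Per-sample 2^-ddCt fold changes relative to the control-group mean.

    Technical replicates are expected to be averaged upstream (arithmetic
    mean of Ct).  Samples lacking a reference-gene Ct are excluded; a gene
    with an empty control group raises.
    """
    df = ct.df
    ref = (
        df[df["gene"] == ct.reference_gene]
        .drop_duplicates("sample")
        .set_index("sample")["ct"]
    )
    results: list[FoldChangeResult] = []
    targets = df[df["gene"] != ct.reference_gene]
    for gene, sub in targets.groupby("gene", sort=True):
        sub = sub[sub["sample"].isin(ref.index)]
        if sub.empty:
            continue
        dct = sub["ct"].to_numpy() - ref.loc[sub["sample"]].to_numpy()
        control = sub["group"].to_numpy() == control_group_label
        if not control.any():
            raise ValidationError(f"gene {gene!r}: control group {control_group_label!r} empty")
        control_mean = float(dct[control].mean())
        ddct = dct - control_mean
        for (s, g, f, dd, d) in zip(
            sub["sample"], sub["group"], 2.0 ** (-ddct), ddct, dct
        ):
            results.append(FoldChangeResult(s, gene, g, float(d), float(dd), float(f)))
    dropped = set(targets["sample"]) - set(ref.index)
    if dropped:
        import logging

        logging.getLogger(__name__).info(
            "ddct_fold_change: %d sample(s) lacked a reference Ct and were excluded", len(dropped)
        )
    return results


def group_difference_test(values, group_labels, method: str = "mann_whitney"):
    """Two-group comparison: Mann-Whitney, unpaired t (Welch) or paired t.

    Mann-Whitney uses exact enumeration for n <= 8 per group without ties and
    the tie-corrected normal approximation otherwise; fully tied inputs
    return p = 1 by convention.  The paired test pairs values by position and
    requires equal lengths.  Returns (statistic, p), two-sided.
    """
    v = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValidationError(f"need exactly two groups, got {uniq}")
    x = v[labels == uniq[0]]
    y = v[labels == uniq[1]]
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs >= 2 values")
    if method == "mann_whitney":
        if np.all(v == v[0]):
            return float(len(x) * len(y) / 2.0), 1.0
        m = (
            "exact"
            if len(x) <= 8 and len(y) <= 8 and len(np.unique(v)) == len(v)
            else "asymptotic"
        )
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=m)
        return float(res.statistic), float(res.pvalue)
    if method == "t_unpaired":
        res = stats.ttest_ind(x, y, equal_var=False)
    elif method == "t_paired":
        if len(x) != len(y):
            raise ValidationError("paired test requires equal group lengths")
        res = stats.ttest_rel(x, y)
    else:
        raise ValidationError(f"unknown method {method!r}")
    p = 1.0 if not np.isfinite(res.pvalue) else float(res.pvalue)
    return float(res.statistic), p


def spearman_assoc(x, y):
    """Spearman rank correlation with average-rank ties, two-sided p.

    Uses the t approximation for n >= 10 and exact permutation enumeration
    for smaller samples; a constant input yields (NaN, NaN).  Requires
    paired non-missing values, n >= 4.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValidationError("spearman_assoc requires n >= 4 paired values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if n >= 10:
        p = float(stats.spearmanr(x, y).pvalue)
        return r, p
    # exact permutation null over all n! rank assignments
    perms = np.array(list(itertools.permutations(range(n))))
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
    null_r = (rx_c[perms] @ ry_c) / denom
    p = float(np.mean(np.abs(null_r) >= abs(r) - 1e-12))
    return r, p
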
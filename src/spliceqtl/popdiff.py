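"""Population allele-frequency differentiation and selection statistics.

Covers per-population allele frequencies, the adapted-variant chi-square /
delta-MAF test against a large reference population, the Hudson Fst
estimator (per variant and windowed ratio-of-averages), the population
branch statistic PBS with its bounded normalization PBSn1, contingency
chi-square trend tests (e.g. allele counts across altitudes) and composite
LD r-squared from dosages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_fdr
from .io import GenotypeMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "allele_frequencies",
    "adapted_variant_test",
    "hudson_fst",
    "FstResult",
    "pbs_stat",
    "pbsn1_stat",
    "genotype_trend_test",
    "TrendTestResult",
    "ld_r2",
]

ADAPTED_FDR = 0.05
ADAPTED_DELTA_MAF = 0.3
_FST_CLAMP = 1.0 - 1e-12


def allele_frequencies(genotypes: GenotypeMatrix, by_population: bool = True) -> pd.DataFrame:
    """Observed alt-allele counts and frequencies, per variant (and population).

    Missing dosages are excluded from numerator and denominator; a
    (variant, population) cell with zero genotyped samples is omitted with a
    log entry.  Columns: variant_id, population, alt_count, total, af, maf.
    """
    pops = sorted(set(genotypes.population.values())) if by_population else [None]
    rows = []
    for pop in pops:
        if pop is None:
            mask = np.ones(genotypes.n_samples, dtype=bool)
            label = "all"
        else:
            mask = genotypes.population_mask(pop)
            label = pop
        dos = genotypes.dosage[mask]
        for j, v in enumerate(genotypes.variants):
            col = dos[:, j]
            ok = np.isfinite(col)
            total = 2 * int(ok.sum())
            if total == 0:
                logger.info("variant %s, population %s: no genotyped samples, omitted", v.id, label)
                continue
            alt = int(col[ok].sum())
            af = alt / total
            rows.append(
                {
                    "variant_id": v.id,
                    "population": label,
                    "alt_count": alt,
                    "total": total,
                    "af": af,
                    "maf": min(af, 1 - af),
                }
            )
    return pd.DataFrame(rows, columns=["variant_id", "population", "alt_count", "total", "af", "maf"])


def adapted_variant_test(
    pop_counts: pd.DataFrame,
    ref_counts: pd.DataFrame,
    fdr: float = ADAPTED_FDR,
    min_delta: float = ADAPTED_DELTA_MAF,
    fold_maf: bool = False,
) -> pd.DataFrame:
    """Chi-square allele-frequency differentiation against a reference panel.

    Inputs are per-variant allele counts (columns variant_id, alt_count,
    total) for the study and reference populations.  Each variant gets a 2x2
    Pearson chi-square (alt vs ref allele x population) without continuity
    correction, BH adjustment across variants, and the compound call
    adapted <=> (adj_p < ``fdr`` AND delta > ``min_delta``).

    ``delta`` is the same-(alt)-allele difference |af_pop - af_ref| by
    default; ``fold_maf=True`` instead compares folded minor-allele
    frequencies, which can hide a large shift when the minor allele differs
    between populations.
    """
    merged = pop_counts.set_index("variant_id")[["alt_count", "total"]].join(
        ref_counts.set_index("variant_id")[["alt_count", "total"]],
        how="inner",
        lsuffix="_pop",
        rsuffix="_ref",
    )
    rows = []
    for vid, r in merged.iterrows():
        ap, tp = int(r["alt_count_pop"]), int(r["total_pop"])
        ar, tr = int(r["alt_count_ref"]), int(r["total_ref"])
        if tp == 0 or tr == 0:
            rows.append(
                {"variant_id": vid, "af_pop": np.nan, "af_ref": np.nan, "chi2": np.nan,
                 "p": np.nan, "delta_maf": np.nan, "reason": "no_observations"}
            )
            continue
        af_pop, af_ref = ap / tp, ar / tr
        table = np.array([[ap, tp - ap], [ar, tr - ar]], dtype=float)
        if (table.sum(axis=0) == 0).any():
            chi2, p = 0.0, 1.0  # both populations fixed for the same allele
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        if fold_maf:
            delta = abs(min(af_pop, 1 - af_pop) - min(af_ref, 1 - af_ref))
        else:
            delta = abs(af_pop - af_ref)
        rows.append(
            {"variant_id": vid, "af_pop": af_pop, "af_ref": af_ref, "chi2": float(chi2),
             "p": float(p), "delta_maf": delta, "reason": None}
        )
    df = pd.DataFrame(rows)
    df["adj_p"] = np.nan
    ok = df["p"].notna()
    if ok.any():
        df.loc[ok, "adj_p"] = bh_fdr(df.loc[ok, "p"].to_numpy())
    df["adapted"] = (df["adj_p"] < fdr) & (df["delta_maf"] > min_delta)
    return df[["variant_id", "af_pop", "af_ref", "chi2", "p", "adj_p", "delta_maf", "adapted", "reason"]]


@dataclass
class FstResult:
    """Hudson Fst: per-variant values plus the windowed ratio of averages."""

    fst: np.ndarray
    numerator: np.ndarray
    denominator: np.ndarray

    @property
    def ratio_of_averages(self) -> float:
        ok = np.isfinite(self.numerator) & (self.denominator > 0)
        if not ok.any():
            return np.nan
        return float(self.numerator[ok].sum() / self.denominator[ok].sum())


def hudson_fst(af1, n1, af2, n2) -> FstResult:
    """Hudson's Fst estimator from sample allele frequencies.

    numerator = (p1-p2)^2 - p1(1-p1)/(2n1-1) - p2(1-p2)/(2n2-1),
    denominator = p1(1-p2) + p2(1-p1); n1, n2 are diploid sample counts.
    Per-variant Fst is NaN where the denominator is 0 (both populations
    fixed for the same allele); the windowed value is the ratio of summed
    numerators to summed denominators.
    """
    p1 = np.atleast_1d(np.asarray(af1, dtype=float))
    p2 = np.atleast_1d(np.asarray(af2, dtype=float))
    if np.any((p1 < 0) | (p1 > 1)) or np.any((p2 < 0) | (p2 > 1)):
        raise ValidationError("allele frequencies must lie in [0, 1]")
    if n1 < 1 or n2 < 1:
        raise ValidationError("need >= 1 diploid sample per population")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (2 * n1 - 1) - p2 * (1 - p2) / (2 * n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(den > 0, num / den, np.nan)
    return FstResult(fst=fst, numerator=num, denominator=den)


def pbs_stat(fst_ab, fst_ac, fst_bc):
    """Population branch statistics from three pairwise Fst values.

    T_xy = -log(1 - Fst_xy) with Fst clamped to [0, 1); negative estimates
    are floored at 0.  PBS_a = (T_ab + T_ac - T_bc) / 2, cyclic for b, c.
    Accepts scalars or arrays.
    """
    def t(f):
        f = np.clip(np.asarray(f, dtype=float), 0.0, _FST_CLAMP)
        return -np.log1p(-f)

    t_ab, t_ac, t_bc = t(fst_ab), t(fst_ac), t(fst_bc)
    pbs_a = (t_ab + t_ac - t_bc) / 2.0
    pbs_b = (t_ab + t_bc - t_ac) / 2.0
    pbs_c = (t_ac + t_bc - t_ab) / 2.0
    return pbs_a, pbs_b, pbs_c


def pbsn1_stat(pbs_a, pbs_b, pbs_c):
    """Normalized PBS bounding the focal branch by the total tree length:
    PBSn1 = max(PBS_a, 0) / (1 + max(PBS_a,0) + max(PBS_b,0) + max(PBS_c,0))."""
    a = np.maximum(np.asarray(pbs_a, dtype=float), 0.0)
    b = np.maximum(np.asarray(pbs_b, dtype=float), 0.0)
    c = np.maximum(np.asarray(pbs_c, dtype=float), 0.0)
    return a / (1.0 + a + b + c)


@dataclass
class TrendTestResult:
    chi2: float
    df: int
    p: float
    low_expected: bool = False  # some expected cell < 1


def genotype_trend_test(counts) -> TrendTestResult:
    """Pearson chi-square on a groups x categories contingency table.

    ``counts`` is a 2-D array-like of allele or genotype counts (e.g. rows =
    altitudes, columns = alleles).  A row summing to zero is an empty group
    and raises; an expected cell below 1 only sets a warning flag.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError("need a table with >= 2 groups and >= 2 categories")
    if (table.sum(axis=1) == 0).any():
        raise ValidationError("empty group in contingency table")
    if (table.sum(axis=0) == 0).any():
        # a category observed in no group is dropped (chi-square undefined)
        table = table[:, table.sum(axis=0) > 0]
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    res = TrendTestResult(float(chi2), int(dof), float(p), bool((expected < 1).any()))
    if res.low_expected:
        logger.warning("genotype_trend_test: expected cell < 1; chi-square approximation is weak")
    return res


def ld_r2(dosage_x, dosage_y) -> float:
    """Composite LD: squared Pearson correlation of paired dosage vectors.

    Pairs with a missing value in either variant are dropped; a monomorphic
    input yields NaN.
    """
    x = np.asarray(dosage_x, dtype=float)
    y = np.asarray(dosage_y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
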
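"""Cis windows and per-(variant, feature) QTL regression with permutation nulls.

eQTL candidates are variants in strand-aware promoter windows (1500 bp
upstream to 200 bp downstream of each transcript start site); sQTL candidates
are variants inside the alternatively spliced exon and its flanking introns.
Each pair is fit by ordinary least squares of the molecular phenotype (TPM or
PSI) on additive dosage.  Empirical p-values come from permuting the sample
labels of the phenotype vector relative to the genotypes, with the
pseudo-count estimator p_emp = (1 + #{p_perm <= p_nominal}) / (n_perm + 1)
and one shared permutation schedule per seed across all associations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix, TranscriptModel, ValidationError
from .splicing import AsEvent

__all__ = [
    "CisWindow",
    "QtlAssociation",
    "define_promoter_windows",
    "define_splice_windows",
    "map_cis_qtl",
    "empirical_pvalues",
]

PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 200
DEFAULT_N_PERM = 1000


@dataclass(frozen=True)
class CisWindow:
    feature_id: str
    kind: str  # promoter | splice
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"window {self.feature_id}: start > end")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class QtlAssociation:
    variant_id: str
    feature_id: str
    n_used: int
    beta: float
    se: float
    t_stat: float
    p_nominal: float
    p_empirical: float | None = None
    n_perm: int = 0
    reason: str | None = None


def define_promoter_windows(
    transcripts: list[TranscriptModel],
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> list[CisWindow]:
    """Strand-aware promoter window around each transcript start site.

    Plus strand: [TSS - upstream, TSS + downstream]; minus strand mirrored.
    Clipped at position 1.  One window per transcript, keyed by gene id, so a
    multi-transcript gene contributes the union of its windows to variant
    lookup.
    """
    windows = []
    for tx in transcripts:
        tss = tx.tss
        if tx.strand == "+":
            lo, hi = tss - upstream, tss + downstream
        else:
            lo, hi = tss - downstream, tss + upstream
        windows.append(CisWindow(tx.gene_id, "promoter", tx.chrom, max(1, lo), hi))
    return windows


def define_splice_windows(
    events: list[AsEvent],
    transcripts: list[TranscriptModel] | None = None,
) -> list[CisWindow]:
    """Window covering the AS exon(s) plus flanking introns, per event type.

    ES and MXE: upstream flanking-intron start to downstream flanking-intron
    end (the event ``span``).  A5SS/A3SS: union of the two exon variants and
    the variable intron.  IR: the retained intron's own bounds (it is both
    the alternative region and its flanks).  The window always contains the
    event's target coordinates.
    """
    windows = []
    for ev in events:
        if ev.etype in ("ES", "MXE", "IR"):
            lo, hi = ev.span
        else:  # A5SS / A3SS: span already covers both variants + intron
            coords = [c for _, c in ev.coords]
            lo = min(ev.span[0], *(c[0] for c in coords))
            hi = max(ev.span[1], *(c[1] for c in coords))
        windows.append(CisWindow(ev.event_id, "splice", ev.chrom, max(1, lo), hi))
    return windows


def _feature_frame(feature_matrix) -> pd.DataFrame:
    """Accept a PsiMatrix, ExpressionMatrix or plain DataFrame."""
    if hasattr(feature_matrix, "psi"):
        return feature_matrix.psi
    if hasattr(feature_matrix, "tpm"):
        return feature_matrix.tpm
    return feature_matrix


def _ols_single(x: np.ndarray, y: np.ndarray):
    """Slope OLS with intercept; returns (beta, se, t, p, n)."""
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        return None, None, None, None, n, "too_few_pairs"
    if np.all(x == x[0]):
        return None, None, None, None, n, "monomorphic"
    if np.all(y == y[0]):
        # constant phenotype carries no evidence: beta 0, p 1 by convention
        return 0.0, 0.0, 0.0, 1.0, n, None
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    beta = float(xc @ yc) / sxx
    resid = yc - beta * xc
    dof = n - 2
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(sigma2 / sxx)
    if se == 0.0:
        return beta, 0.0, np.inf, 0.0, n, None
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return beta, float(se), float(t), float(p), n, None


def map_cis_qtl(
    genotypes: GenotypeMatrix,
    feature_matrix,
    windows: list[CisWindow],
    log_transform: bool = False,
) -> list[QtlAssociation]:
    """OLS of each feature on dosage for every variant in its cis window.

    Samples with a missing dosage or missing feature value are dropped
    pairwise; monomorphic variants are reported with NaN statistics and the
    reason ``monomorphic``; pairs with fewer than 4 complete observations are
    reported with reason ``too_few_pairs``.  ``log_transform`` applies
    log2(x + 1) to the feature values (an option for TPM).
    """
    feats = _feature_frame(feature_matrix)
    common = [s for s in genotypes.samples if s in feats.columns]
    if not common:
        raise ValidationError("no samples shared between genotypes and features")
    sample_idx = [genotypes.samples.index(s) for s in common]
    feats = feats[common]

    by_feature: dict[str, list[CisWindow]] = {}
    for w in windows:
        by_feature.setdefault(w.feature_id, []).append(w)

    out: list[QtlAssociation] = []
    for feature_id in feats.index:
        wins = by_feature.get(feature_id)
        if not wins:
            continue
        y = feats.loc[feature_id].to_numpy(dtype=float)
        if log_transform:
            y = np.log2(y + 1.0)
        for j, v in enumerate(genotypes.variants):
            if not any(w.contains(v.chrom, v.pos) for w in wins):
                continue
            x = genotypes.dosage[sample_idx, j]
            beta, se, t, p, n, reason = _ols_single(x, y)
            out.append(
                QtlAssociation(
                    variant_id=v.id,
                    feature_id=feature_id,
                    n_used=n,
                    beta=np.nan if beta is None else beta,
                    se=np.nan if se is None else se,
                    t_stat=np.nan if t is None else t,
                    p_nominal=np.nan if p is None else p,
                    reason=reason,
                )
            )
    return out


def _perm_pvalues(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Vectorized two-sided OLS slope p for one dosage vector against each
    row of ``Y`` (permuted phenotype matrix), with pairwise-complete masks.

    Degenerate rows (constant phenotype or < 4 pairs) get p = 1.
    """
    V = np.isfinite(Y) & np.isfinite(x)[None, :]
    n = V.sum(axis=1).astype(float)
    X = np.where(V, x[None, :], 0.0)
    Yv = np.where(V, Y, 0.0)
    sx = X.sum(axis=1)
    sy = Yv.sum(axis=1)
    sxx = (X * X).sum(axis=1)
    syy = (Yv * Yv).sum(axis=1)
    sxy = (X * Yv).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sxy - sx * sy
        den = (n * sxx - sx * sx) * (n * syy - sy * sy)
        r = num / np.sqrt(den)
        r = np.clip(r, -1.0, 1.0)
        dof = n - 2
        t = r * np.sqrt(dof / (1.0 - r * r))
        p = 2.0 * stats.t.sf(np.abs(t), dof)
    p[~np.isfinite(p)] = 1.0
    p[n < 4] = 1.0
    return p


def empirical_pvalues(
    genotypes: GenotypeMatrix,
    feature_matrix,
    associations: list[QtlAssociation],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    log_transform: bool = False,
) -> list[QtlAssociation]:
    """Attach permutation-empirical p-values to nominal associations.

    The phenotype vector's sample labels are permuted relative to genotypes
    ``n_perm`` times; the same permutation schedule (a function of ``seed``
    alone) is shared across all associations, so results are deterministic
    given the seed.  p_empirical = (1 + #{p_perm <= p_nominal}) / (n_perm+1).
    Associations without a nominal p (monomorphic etc.) are left untouched.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    feats = _feature_frame(feature_matrix)
    common = [s for s in genotypes.samples if s in feats.columns]
    sample_idx = [genotypes.samples.index(s) for s in common]
    feats = feats[common]
    rng = np.random.default_rng(seed)
    n = len(common)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    vidx = {v.id: j for j, v in enumerate(genotypes.variants)}
    for assoc in associations:
        if assoc.reason is not None or not np.isfinite(assoc.p_nominal):
            continue
        x = genotypes.dosage[sample_idx, vidx[assoc.variant_id]]
        y = feats.loc[assoc.feature_id].to_numpy(dtype=float)
        if log_transform:
            y = np.log2(y + 1.0)
        perm_p = _perm_pvalues(x, y[perms])
        assoc.p_empirical = float(
            (1 + np.sum(perm_p <= assoc.p_nominal)) / (n_perm + 1)
        )
        assoc.n_perm = n_perm
    return associations
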
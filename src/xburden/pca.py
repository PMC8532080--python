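"""Genotype principal components used as ancestry covariates.

Common, well-called variants (in-cohort MAF > 0.01, call rate > 0.99, strict
per the thresholds' definition) are mean-imputed, centered, scaled by the
square root of the binomial variance at the estimated allele frequency
(standard genotype standardization), and decomposed by SVD.  The sample
scores of the top k components enter the burden regression as covariates.

The reference-panel projection some studies use is replaced by in-cohort PCA;
externally computed scores can be supplied instead via
:func:`load_pc_scores` with the same sample_id/PC1..PCk schema.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix
from .errors import ConfigError


@dataclass(frozen=True)
class PcaThresholds:
    min_maf: float = 0.01
    min_call_rate: float = 0.99

    def validate(self) -> None:
        if not 0.0 <= self.min_maf < 0.5:
            raise ConfigError("min_maf must be in [0, 0.5)")
        if not 0.0 <= self.min_call_rate <= 1.0:
            raise ConfigError("min_call_rate must be in [0, 1]")


@dataclass
class PcScores:
    """Samples x k PC scores and per-component explained-variance fractions."""

    scores: pd.DataFrame  # index sample_id, columns PC1..PCk
    explained_variance: np.ndarray

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def select_pca_variants(
    sites: pd.DataFrame,
    gm: GenotypeMatrix,
    thresholds: PcaThresholds | None = None,
    ploidy: int = 1,
) -> pd.DataFrame:
    """Build the samples x variants allele-count matrix for PCA.

    Retains variants with in-cohort MAF strictly above ``min_maf`` and call
    rate strictly above ``min_call_rate``; residual missing entries are
    imputed at the variant mean.
    """
    t = thresholds or PcaThresholds()
    t.validate()
    ac = gm.allele_count.astype(float)
    ac[ac < 0] = np.nan
    call_rate = 1.0 - np.isnan(ac).mean(axis=1)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(ac, axis=1) / ploidy
    maf = np.minimum(p, 1.0 - p)
    keep = (maf > t.min_maf) & (call_rate > t.min_call_rate)
    keep &= ~np.isnan(maf)
    if not keep.any():
        raise ConfigError("no variants satisfy the PCA MAF/call-rate thresholds")
    mat = ac[keep]
    col_mean = np.nanmean(mat, axis=1)
    nan_rows, nan_cols = np.nonzero(np.isnan(mat))
    mat[nan_rows, nan_cols] = col_mean[nan_rows]
    labels = gm.site_index[keep]
    return pd.DataFrame(mat.T, index=pd.Index(gm.sample_ids, name="sample_id"), columns=labels)


def compute_pcs(matrix: pd.DataFrame, k: int = 5, scale: bool = True, ploidy: int = 1) -> PcScores:
    """Top-k principal-component scores of a samples x variants matrix.

    Columns are centered; with ``scale`` they are divided by
    sqrt(ploidy * p * (1 - p)) at the estimated allele frequency p.  Scores
    are left singular vectors scaled by singular values, sign-fixed so each
    component's largest-magnitude variant loading is positive.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    X = matrix.to_numpy(dtype=float)
    n, m = X.shape
    if m < k:
        raise ConfigError(f"only {m} variants available for {k} components")
    mean = X.mean(axis=0)
    Z = X - mean
    if scale:
        p = np.clip(mean / ploidy, 1e-12, 1 - 1e-12)
        sd = np.sqrt(ploidy * p * (1 - p))
        Z = Z / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    if S.size == 0 or S[0] == 0.0:
        # fully degenerate input (e.g. identical rows): all scores equal (zero)
        df = pd.DataFrame(0.0, index=matrix.index, columns=[f"PC{i + 1}" for i in range(k)])
        return PcScores(scores=df, explained_variance=np.zeros(k))
    rank = int((S > S[0] * 1e-12).sum())
    if rank < k:
        raise ConfigError(f"matrix rank {rank} is below the requested {k} components")
    signs = np.sign(Vt[np.arange(len(S)), np.argmax(np.abs(Vt), axis=1)])
    signs[signs == 0] = 1.0
    U = U * signs
    scores = U[:, :k] * S[:k]
    total = (S**2).sum()
    explained = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
    df = pd.DataFrame(scores, index=matrix.index, columns=[f"PC{i + 1}" for i in range(k)])
    return PcScores(scores=df, explained_variance=explained)


def load_pc_scores(path) -> PcScores:
    """Hook for externally computed scores (TSV: sample_id, PC1..PCk)."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ConfigError("PC scores file must have a sample_id column")
    pcs = [c for c in df.columns if c.startswith("PC")]
    if not pcs:
        raise ConfigError("PC scores file has no PC columns")
    df = df.set_index("sample_id")[pcs]
    return PcScores(scores=df, explained_variance=np.full(len(pcs), np.nan))
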
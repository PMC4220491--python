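"""Gene-TF correlation scoring: Fisher-Z, standardization and CLR/Stouffer.

The pipeline computes Pearson correlations between every gene and every
transcription factor (TF) across the samples of a compendium, variance-
stabilizes them with the Fisher Z-transform, standardizes the pooled values
to N(0,1), and then converts each normalized correlation C_ij into a
"specific" correlation score S_ij by comparing it against the background
distribution of correlations involving either gene i or TF j (the CLR
scheme), combining the two background z-scores with Stouffer's method:

    z_row = (C_ij - mean_i) / sd_i        over TFs paired with gene i
    z_col = (C_ij - mean_j) / sd_j        over genes paired with TF j
    S_ij  = (z_row + z_col) / sqrt(2)

Unlike the original CLR formulation the background z-scores are not clamped
at zero, so negative (anti-correlated) associations survive into S.
Self-pairs (a TF with its own gene) are excluded from both backgrounds and
set to 0 in S.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .compendium import ExpressionCompendium
from .exceptions import DataError

#: |r| is clipped to this bound before the Fisher transform.
_R_CLIP = 1.0 - 1e-6


@dataclass
class GeneTfCorrelations:
    """Standardized Fisher-Z gene x TF correlation matrix C.

    ``values`` has genes on the rows and TFs on the columns.  Entries where
    the row gene *is* the column TF ("self-pairs") carry no information about
    regulation; they are flagged by ``self_mask`` and excluded from all
    background statistics downstream.
    """

    values: pd.DataFrame
    n_samples: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise DataError("non-finite correlation values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tf_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def self_mask(self) -> np.ndarray:
        """Boolean genes x TFs array, True where gene id == TF id."""
        genes = np.asarray(self.values.index)
        tfs = np.asarray(self.values.columns)
        return genes[:, None] == tfs[None, :]


@dataclass
class SpecificScoreMatrix:
    """Gene x TF matrix of CLR/Stouffer specific correlation scores S."""

    values: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tf_ids(self) -> list[str]:
        return list(self.values.columns)


def gene_tf_correlations(
    compendium: ExpressionCompendium, tf_ids: Sequence[str]
) -> pd.DataFrame:
    """Raw Pearson correlations of every gene with every TF across samples.

    Requires at least 4 samples and every TF id present among the genes.
    Zero-variance genes yield correlation 0 (with a warning) rather than NaN.
    """
    if compendium.n_samples < 4:
        raise DataError("need >= 4 samples to estimate correlations")
    missing = [t for t in tf_ids if t not in compendium.data.index]
    if missing:
        raise DataError(f"TF ids absent from compendium: {missing[:5]}")
    x = compendium.data.to_numpy(dtype=float)
    n = x.shape[1]
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance gene(s); their correlations set to 0",
            stacklevel=2,
        )
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (x - mu) / safe_sd
    z[flat] = 0.0
    tf_pos = compendium.data.index.get_indexer(list(tf_ids))
    r = z @ z[tf_pos].T / n
    np.clip(r, -1.0, 1.0, out=r)
    # exact self-correlation for non-degenerate genes
    for col, gi in enumerate(tf_pos):
        if not flat[gi]:
            r[gi, col] = 1.0
    return pd.DataFrame(r, index=compendium.data.index, columns=list(tf_ids))


def fisher_z(r):
    """Fisher Z-transform z = arctanh(r), with |r| clipped to 1 - 1e-6."""
    arr = np.clip(np.asarray(r, dtype=float), -_R_CLIP, _R_CLIP)
    out = np.arctanh(arr)
    if np.isscalar(r) or np.ndim(r) == 0:
        return float(out)
    if isinstance(r, pd.DataFrame):
        return pd.DataFrame(out, index=r.index, columns=r.columns)
    return out


def standardize_correlations(
    z_matrix: pd.DataFrame, n_samples: int, analytic: bool = False
) -> GeneTfCorrelations:
    """Standardize Fisher-Z values to a pooled N(0,1) scale.

    Empirical by default: subtract the mean and divide by the population s.d.
    of all gene-TF entries excluding self-pairs.  ``analytic=True`` instead
    multiplies by sqrt(n_samples - 3), the null standard error of a Fisher-Z
    correlation, without centring.
    """
    vals = z_matrix.to_numpy(dtype=float)
    genes = np.asarray(z_matrix.index)
    tfs = np.asarray(z_matrix.columns)
    self_mask = genes[:, None] == tfs[None, :]
    if analytic:
        out = vals * np.sqrt(max(n_samples - 3, 1))
    else:
        pool = vals[~self_mask]
        sd = pool.std(ddof=0)
        if sd == 0:
            raise DataError("constant correlation matrix cannot be standardized")
        out = (vals - pool.mean()) / sd
    out = np.where(self_mask, 0.0, out)
    return GeneTfCorrelations(
        pd.DataFrame(out, index=z_matrix.index, columns=z_matrix.columns), n_samples
    )


def stouffer_combine(z1, z2):
    """Stouffer combination of two z-scores: (z1 + z2) / sqrt(2)."""
    return (np.asarray(z1, dtype=float) + np.asarray(z2, dtype=float)) / np.sqrt(2.0)


def clr_specific_scores(correlations: GeneTfCorrelations) -> SpecificScoreMatrix:
    """CLR-style specific scores S from normalized correlations C.

    Each entry is scored against the row background (all TFs paired with its
    gene) and the column background (all genes paired with its TF), both with
    self-pairs excluded and sample s.d. (divisor n-1); the two z-scores are
    Stouffer-combined.  Zero-s.d. backgrounds contribute a 0 component with a
    warning; self-pairs are set to 0.
    """
    c = correlations.values.to_numpy(dtype=float)
    n_genes, n_tfs = c.shape
    if n_genes < 3 or n_tfs < 3:
        raise DataError("need >= 3 genes and >= 3 TFs for background statistics")
    mask = correlations.self_mask
    work = np.where(mask, np.nan, c)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices impossible here
        row_mu = np.nanmean(work, axis=1, keepdims=True)
        row_sd = np.nanstd(work, axis=1, ddof=1, keepdims=True)
        col_mu = np.nanmean(work, axis=0, keepdims=True)
        col_sd = np.nanstd(work, axis=0, ddof=1, keepdims=True)

    if np.any(row_sd == 0) or np.any(col_sd == 0):
        warnings.warn("zero-s.d. background row/column; its z component set to 0", stacklevel=2)
    z_row = np.where(row_sd > 0, (c - row_mu) / np.where(row_sd == 0, 1, row_sd), 0.0)
    z_col = np.where(col_sd > 0, (c - col_mu) / np.where(col_sd == 0, 1, col_sd), 0.0)
    s = stouffer_combine(z_row, z_col)
    s[mask] = 0.0
    return SpecificScoreMatrix(
        pd.DataFrame(s, index=correlations.values.index, columns=correlations.values.columns)
    )


def specific_scores_from_compendium(
    compendium: ExpressionCompendium,
    tf_ids: Sequence[str],
    analytic_standardization: bool = False,
) -> SpecificScoreMatrix:
    """Convenience composition: correlations -> Fisher-Z -> standardize -> CLR."""
    r = gene_tf_correlations(compendium, tf_ids)
    z = fisher_z(r)
    c = standardize_correlations(z, compendium.n_samples, analytic=analytic_standardization)
    return clr_specific_scores(c)
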
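"""Expression preprocessing: count filters, TMM, residualization, rank-normal.

Order of operations in the pipeline: raw counts are filtered jointly
across the paired tissues, scaled to counts-per-million with
gene-derived library sizes and TMM factors, residualized on covariates
(genotype PCs + expression PCs), and finally rank-normalized per feature
to N(0, 1) for association testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import PhenotypeTable

__all__ = [
    "filter_phenotypes",
    "NormalizationFactors",
    "tmm_factors",
    "cpm",
    "residualize",
    "rank_normalize",
    "select_expression_pcs",
    "log_fold_change",
]


def filter_phenotypes(
    counts_normal: PhenotypeTable,
    counts_tumor: PhenotypeTable,
    min_read: int = 20,
    max_missing_frac: float = 0.5,
    pool_tissues: bool = True,
) -> tuple[pd.Index, PhenotypeTable, PhenotypeTable]:
    """Apply the study's expression filters to a paired cohort.

    A feature is dropped when no sample reaches ``min_read`` counts or
    when its total count is below the number of samples (both evaluated
    over the pooled tissues by default).  Then, per tissue, features with
    more than ``max_missing_frac`` zero samples are dropped; the kept set
    is the *union* of the per-tissue survivors, so a feature well
    expressed in only one tissue is retained in both tables.

    Returns ``(kept_ids, filtered_normal, filtered_tumor)``.
    """
    if not counts_normal.features.index.equals(counts_tumor.features.index):
        raise ValueError("normal and tumor tables must share the same feature universe")

    vn = counts_normal.values
    vt = counts_tumor.values
    if pool_tissues:
        pooled_max = np.maximum(vn.max(axis=0), vt.max(axis=0))
        pooled_sum = vn.sum(axis=0) + vt.sum(axis=0)
        n_samples = vn.shape[0] + vt.shape[0]
        read_ok = (pooled_max >= min_read) & (pooled_sum >= n_samples)
    else:
        read_ok = ((vn.max(axis=0) >= min_read) & (vn.sum(axis=0) >= vn.shape[0])) | (
            (vt.max(axis=0) >= min_read) & (vt.sum(axis=0) >= vt.shape[0])
        )

    zero_frac_n = (vn == 0).mean(axis=0)
    zero_frac_t = (vt == 0).mean(axis=0)
    keep_n = read_ok & (zero_frac_n <= max_missing_frac)
    keep_t = read_ok & (zero_frac_t <= max_missing_frac)
    kept = counts_normal.features.index[(keep_n | keep_t).to_numpy()]
    return kept, counts_normal.subset(kept), counts_tumor.subset(kept)


@dataclass
class NormalizationFactors:
    """Per-sample library sizes (gene counts only) and TMM scaling factors."""

    library_size: pd.Series
    tmm_factor: pd.Series

    @property
    def effective_size(self) -> pd.Series:
        return self.library_size * self.tmm_factor


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    log_ratio_trim: float = 0.30,
    abs_expr_trim: float = 0.05,
) -> float:
    """Doubly trimmed weighted mean of M-values for one sample vs the reference.

    M-values (log2 expression ratios) are trimmed by ``log_ratio_trim`` on
    each side, A-values (average log2 abundance) by ``abs_expr_trim``; the
    surviving M-values are averaged with inverse approximate-variance
    weights.  Returns the scaling factor on the natural scale (2^f).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / lib_obs) / (ref / lib_ref))
        abs_e = (np.log2(obs / lib_obs) + np.log2(ref / lib_ref)) / 2.0
        var = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, var = log_r[fin], abs_e[fin], var[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * log_ratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * abs_expr_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = stats.rankdata(log_r)
    rank_e = stats.rankdata(abs_e)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not keep.any():
        return 1.0
    f = np.nansum(log_r[keep] / var[keep]) / np.nansum(1.0 / var[keep])
    return float(2.0**f)


def tmm_factors(
    counts: PhenotypeTable,
    gene_mask: Sequence[str] | pd.Index | None = None,
    log_ratio_trim: float = 0.30,
    abs_expr_trim: float = 0.05,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values normalization with gene-derived library sizes.

    Library sizes are per-sample sums over ``gene_mask`` only (genes carry
    the sequencing-depth signal; TE counts are sparse and noisy), but the
    trimmed comparison uses all features.  The reference sample is the one
    whose upper-quartile expression fraction is closest to the mean across
    samples.  Factors are rescaled so their geometric mean is exactly 1.
    """
    if gene_mask is None:
        gene_mask = counts.features.index[~counts.is_te().to_numpy()]
    gene_mask = pd.Index(gene_mask)
    if len(gene_mask) == 0:
        raise ValueError("gene_mask is empty; library sizes undefined")

    mat = counts.values.to_numpy(dtype=float)
    lib = counts.values[gene_mask].sum(axis=1).to_numpy(dtype=float)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        bad = counts.values.index[zero].tolist()
        raise ValueError(f"samples with zero gene counts: {bad}")

    # reference: upper quartile (as fraction of library) closest to the mean
    q75 = np.quantile(mat, 0.75, axis=1) / lib
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    ref = mat[ref_idx]
    lib_ref = lib[ref_idx]

    factors = np.array(
        [
            _tmm_pair(mat[i], ref, lib[i], lib_ref, log_ratio_trim, abs_expr_trim)
            for i in range(mat.shape[0])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    idx = counts.values.index
    return NormalizationFactors(
        library_size=pd.Series(lib, index=idx, name="library_size"),
        tmm_factor=pd.Series(factors, index=idx, name="tmm_factor"),
    )


def cpm(counts: PhenotypeTable, factors: NormalizationFactors) -> PhenotypeTable:
    """Counts-per-million on TMM-corrected gene-derived library sizes."""
    eff = factors.effective_size.reindex(counts.values.index)
    if eff.isna().any():
        raise ValueError("normalization factors missing for some samples")
    vals = counts.values.div(eff, axis=0) * 1e6
    return counts.with_values(vals, "cpm")


def residualize(values: pd.DataFrame, covariates: pd.DataFrame | None) -> pd.DataFrame:
    """OLS residuals of every feature against [intercept | covariates].

    With no covariates this is plain centering.  Residualization is a
    projection, so applying it twice equals applying it once.
    """
    y = values.to_numpy(dtype=float)
    if covariates is None or covariates.shape[1] == 0:
        return pd.DataFrame(y - y.mean(axis=0), index=values.index, columns=values.columns)
    if not covariates.index.equals(values.index):
        covariates = covariates.reindex(values.index)
        if covariates.isna().any().any():
            raise ValueError("covariates missing for some samples")
    design = np.column_stack([np.ones(len(values)), covariates.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify collinear columns by incremental rank
        bad = []
        cols = [np.ones(len(values))]
        for name in covariates.columns:
            cand = np.column_stack(cols + [covariates[name].to_numpy(dtype=float)])
            if np.linalg.matrix_rank(cand) == len(cols):
                bad.append(name)
            else:
                cols.append(covariates[name].to_numpy(dtype=float))
        raise ValueError(f"rank-deficient covariates; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return pd.DataFrame(resid, index=values.index, columns=values.columns)


def rank_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Map each feature to normal quantiles: Phi^-1((rank - 0.5) / n).

    Ties receive average ranks, so tied observations map to the same
    quantile.  The result is invariant to any strictly monotone
    per-feature transform of the input.
    """
    n = values.shape[0]
    if n < 3:
        raise ValueError("rank normalization requires at least 3 samples")
    arr = values.to_numpy(dtype=float)
    const = np.flatnonzero(arr.std(axis=0) == 0)
    if const.size:
        raise ValueError(
            f"constant features cannot be rank-normalized: {values.columns[const].tolist()}"
        )
    ranks = np.apply_along_axis(stats.rankdata, 0, arr)
    out = stats.norm.ppf((ranks - 0.5) / n)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def expression_pcs(values: pd.DataFrame, n_components: int) -> pd.DataFrame:
    """Principal components of the samples x features matrix (centered, scaled)."""
    arr = values.to_numpy(dtype=float)
    arr = (arr - arr.mean(axis=0)) / np.where(arr.std(axis=0) == 0, 1.0, arr.std(axis=0))
    u, s, _ = np.linalg.svd(arr, full_matrices=False)
    k = min(n_components, len(s))
    pcs = u[:, :k] * s[:k]
    return pd.DataFrame(pcs, index=values.index, columns=[f"PC{i+1}" for i in range(k)])


def select_expression_pcs(
    values: pd.DataFrame,
    genotype_pcs: pd.DataFrame | None,
    candidate_counts: Sequence[int],
    qtl_scan: Callable[[pd.DataFrame], int],
) -> int:
    """Choose the expression-PC count that maximizes eQTL discoveries.

    For each candidate ``k`` the phenotype matrix is residualized on the
    genotype PCs plus the top-``k`` expression PCs and handed to
    ``qtl_scan``, a callback returning the number of discoveries at the
    study FDR.  The ``k`` with the most discoveries wins; ties go to the
    smaller ``k``.  Candidates exceeding the matrix rank are skipped with
    a warning.
    """
    cands = sorted(set(int(k) for k in candidate_counts))
    if not cands:
        raise ValueError("candidate_counts is empty")
    max_rank = min(values.shape) - 1
    pcs_all = expression_pcs(values, min(max(cands), max_rank))
    best_k, best_count = None, -1
    for k in cands:
        if k > pcs_all.shape[1]:
            warnings.warn(f"candidate k={k} exceeds matrix rank; skipped")
            continue
        covs = [genotype_pcs] if genotype_pcs is not None else []
        if k > 0:
            covs.append(pcs_all.iloc[:, :k])
        cov = pd.concat(covs, axis=1) if covs else None
        resid = residualize(values, cov)
        n_disc = int(qtl_scan(resid))
        if n_disc > best_count:  # strict >: ties keep the smaller k
            best_k, best_count = k, n_disc
    if best_k is None:
        raise ValueError("no feasible candidate PC count")
    return best_k


def log_fold_change(counts_a: pd.DataFrame, counts_b: pd.DataFrame, pseudo: float = 1.0) -> pd.Series:
    """Plain per-feature log2 fold change of mean counts (B over A).

    A deliberately minimal helper used only to label synthetic
    transcription factors as up/down; not a differential-expression test.
    """
    mean_a = counts_a.mean(axis=0) + pseudo
    mean_b = counts_b.mean(axis=0) + pseudo
    return np.log2(mean_b / mean_a)
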
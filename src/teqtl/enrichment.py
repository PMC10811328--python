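"""Matched-null functional enrichment of eQTL variants in annotation peaks.

Each eQTL variant is compared against 100 random variants matched on
distance-to-TSS (within 2.5 kb) and minor allele frequency (within 2%)
that are not themselves associated with any phenotype (all nominal
p > 0.05).  Enrichment of a peak category (one transcription factor or
histone mark) is the ratio of the in-category proportion among eQTL
variants to that among the matched nulls, with a two-sided Fisher exact
p and Benjamini-Hochberg correction across categories.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "build_null_pool",
    "merge_intervals",
    "annotate_overlap",
    "EnrichmentResult",
    "enrichment_test",
    "correct_enrichment",
    "enrichment_ratio",
]


def build_null_pool(
    eqtl_variants: pd.DataFrame,
    candidate_variants: pd.DataFrame,
    max_nominal_p: Mapping[str, float],
    k: int = 100,
    dist_tol: int = 2500,
    maf_tol: float = 0.02,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Sample k matched null variants per eQTL variant.

    Both frames are indexed by variant_id and carry ``abs_tss_distance``
    (bp to the nearest tested TSS) and ``maf``.  ``max_nominal_p`` maps a
    candidate to the *smallest* nominal p it achieved against any tested
    phenotype; only candidates whose best p exceeds ``alpha`` (never even
    nominally associated) are eligible.  Eligibility further requires
    |delta distance| <= dist_tol and |delta MAF| <= maf_tol, both
    inclusive.  Per eQTL, k eligible candidates are drawn uniformly
    without replacement (all of them, flagged, if fewer than k exist);
    candidates may be reused across eQTLs.  eQTLs with no eligible
    candidate are dropped from the pool and logged.
    """
    rng = np.random.default_rng(seed)
    cand = candidate_variants.copy()
    best_p = pd.Series({v: max_nominal_p.get(v, 1.0) for v in cand.index})
    cand = cand.loc[best_p > alpha]
    cand = cand.loc[~cand.index.isin(eqtl_variants.index)]
    cd = cand["abs_tss_distance"].to_numpy(dtype=float)
    cm = cand["maf"].to_numpy(dtype=float)

    pool: dict[str, list[str]] = {}
    for vid, row in eqtl_variants.iterrows():
        # inclusive tolerances; tiny epsilon so 0.27 - 0.25 <= 0.02 holds in floats
        ok = (np.abs(cd - float(row["abs_tss_distance"])) <= dist_tol + 1e-9) & (
            np.abs(cm - float(row["maf"])) <= maf_tol + 1e-9
        )
        eligible = cand.index[ok]
        if len(eligible) == 0:
            logger.warning("no eligible matched nulls for eQTL variant %s; excluded", vid)
            continue
        if len(eligible) < k:
            warnings.warn(f"only {len(eligible)} matched nulls for {vid} (requested {k})")
            pool[vid] = list(eligible)
        else:
            pool[vid] = list(rng.choice(eligible, size=k, replace=False))
    return pool


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching half-open [start, end) intervals."""
    out: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if start >= end:
            raise ValueError(f"malformed interval [{start}, {end})")
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def annotate_overlap(
    positions: np.ndarray,
    peaks: Sequence[tuple[int, int]],
    merged: bool = False,
) -> np.ndarray:
    """Whether each 1-based variant position falls inside any peak.

    Peaks use the BED half-open convention [start, end), i.e. a 1-based
    position ``pos`` is covered when ``start < pos <= end``.
    """
    if not merged:
        peaks = merge_intervals(peaks)
    pos = np.asarray(positions, dtype=np.int64)
    if not len(peaks):
        return np.zeros(pos.shape, dtype=bool)
    starts = np.array([s for s, _ in peaks], dtype=np.int64)
    ends = np.array([e for _, e in peaks], dtype=np.int64)
    # index of last peak with start < pos
    idx = np.searchsorted(starts, pos, side="left") - 1
    hit = idx >= 0
    hit[hit] = pos[hit] <= ends[idx[hit]]
    return hit


@dataclass
class EnrichmentResult:
    """2x2 overlap summary for one annotation category."""

    category: str
    n_eqtl_in: int
    n_eqtl_out: int
    n_null_in: int
    n_null_out: int
    fold: float
    fisher_p: float
    adj_p: float = np.nan
    flagged: bool = False


def enrichment_test(
    eqtl_flags: np.ndarray, null_flags: np.ndarray, category: str = ""
) -> EnrichmentResult:
    """Fold enrichment and two-sided Fisher exact test for one category.

    fold = (eQTL in-category proportion) / (null in-category proportion).
    When neither group overlaps the category the fold is undefined: the
    result is flagged with fold NaN and p = 1.
    """
    eqtl_flags = np.asarray(eqtl_flags, dtype=bool)
    null_flags = np.asarray(null_flags, dtype=bool)
    if eqtl_flags.size == 0 or null_flags.size == 0:
        raise ValueError("both flag vectors must be non-empty")
    a_in, a_out = int(eqtl_flags.sum()), int((~eqtl_flags).sum())
    b_in, b_out = int(null_flags.sum()), int((~null_flags).sum())
    if a_in == 0 and b_in == 0:
        return EnrichmentResult(category, a_in, a_out, b_in, b_out, np.nan, 1.0, flagged=True)
    prop_e = a_in / (a_in + a_out)
    prop_n = b_in / (b_in + b_out)
    fold = np.inf if prop_n == 0 else prop_e / prop_n
    _, p = stats.fisher_exact([[a_in, a_out], [b_in, b_out]], alternative="two-sided")
    return EnrichmentResult(category, a_in, a_out, b_in, b_out, float(fold), float(p))


def correct_enrichment(
    results: Sequence[EnrichmentResult], fdr: float = 0.05
) -> pd.DataFrame:
    """Benjamini-Hochberg correction across categories."""
    if not results:
        raise ValueError("no enrichment results to correct")
    p = np.array([r.fisher_p for r in results])
    reject, adj, *_ = multipletests(p, alpha=fdr, method="fdr_bh")
    rows = []
    for r, a, rej in zip(results, adj, reject):
        r.adj_p = float(a)
        rows.append(
            {
                "category": r.category,
                "n_eqtl_in": r.n_eqtl_in,
                "n_eqtl_out": r.n_eqtl_out,
                "n_null_in": r.n_null_in,
                "n_null_out": r.n_null_out,
                "fold": r.fold,
                "fisher_p": r.fisher_p,
                "adj_p": r.adj_p,
                "significant": bool(rej),
                "flagged": r.flagged,
            }
        )
    return pd.DataFrame(rows)


def enrichment_ratio(run_a: pd.DataFrame, run_b: pd.DataFrame) -> pd.DataFrame:
    """log2 ratio of fold enrichments between two runs, per shared category.

    Used e.g. to contrast TE-eQTL vs gene-eQTL enrichment, or
    tumor-specific vs shared eQTL enrichment.  Categories missing from
    either run (or with undefined folds) are skipped and logged.
    """
    a = run_a.set_index("category")["fold"]
    b = run_b.set_index("category")["fold"]
    shared = a.index.intersection(b.index)
    skipped = set(a.index).symmetric_difference(b.index)
    for cat in sorted(skipped):
        logger.info("category %s present in only one run; skipped from ratios", cat)
    ok = shared[(a.loc[shared] > 0) & np.isfinite(a.loc[shared]) & (b.loc[shared] > 0) & np.isfinite(b.loc[shared])]
    return pd.DataFrame(
        {
            "fold_a": a.loc[ok],
            "fold_b": b.loc[ok],
            "log2_ratio": np.log2(a.loc[ok] / b.loc[ok]),
        }
    ).rename_axis("category")
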
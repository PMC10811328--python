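"""Permutation-based cis-QTL mapping with beta-approximated adjusted p-values.

The mapping scheme, per molecular phenotype: collect all variants within
+/- 1 Mb of the TSS, test each with simple linear regression on the
rank-normal phenotype, keep the best (smallest nominal p) hit, then
calibrate that best p against the null obtained by re-scanning the whole
window on randomly permuted phenotypes.  A Beta distribution fitted by
maximum likelihood to the permutation minima converts the best nominal p
into a single adjusted p that accounts for the number and correlation of
variants tested; genome-wide FDR across phenotypes uses Storey q-values.
Multiple independent signals per phenotype are recovered with a
forward-backward conditional pass thresholded at the per-phenotype
nominal p that corresponds to the study FDR through the Beta quantile.

``CisQTLModel`` / ``CisQTLResults`` wrap the per-phenotype primitives in
a fit/results interface; the primitives themselves are importable for
targeted use (``nominal_scan``, ``permutation_pass``, ``fit_beta``,
``qvalues``, ``conditional_pass``, ``replicate_hits``).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import PhenotypeTable, VariantSet

__all__ = [
    "cis_window",
    "nominal_scan",
    "BetaFit",
    "fit_beta",
    "permutation_pass",
    "qvalues",
    "nominal_threshold",
    "conditional_pass",
    "replicate_hits",
    "CisQTLModel",
    "CisQTLResults",
]

_P_FLOOR = 1e-300


def _phenotype_seed(master_seed: int, phenotype_id: str) -> int:
    """Stable per-phenotype seed below 2**31 (reproducible under parallelism)."""
    return (int(master_seed) * 2654435761 + zlib.crc32(phenotype_id.encode())) % (2**31)


def cis_window(
    tss: int,
    chrom: str,
    strand: str,
    variants: VariantSet,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Variants within ``window`` bp (inclusive) of a phenotype's TSS.

    Returns a frame indexed by variant_id with a signed, strand-oriented
    ``tss_distance`` column: positive means downstream of the TSS in the
    feature's reading direction.
    """
    vt = variants.variants
    on_chrom = vt["chrom"] == chrom
    if not on_chrom.any():
        warnings.warn(f"chromosome {chrom!r} absent from variant set")
        return pd.DataFrame(columns=["tss_distance"])
    sub = vt.loc[on_chrom]
    dist = sub["pos"].to_numpy() - int(tss)
    if strand == "-":
        dist = -dist
    keep = np.abs(dist) <= window
    return pd.DataFrame({"tss_distance": dist[keep]}, index=sub.index[keep])


def _corr_stats(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column simple-regression (slope, r, p) of y on columns of X.

    ``y``: (n,) vector or (k, n) matrix of phenotypes; ``X``: (n, m).
    Returns arrays broadcast to (k, m) (or (m,) for vector y).
    p from the t statistic with n-2 df.  Zero-variance columns give
    slope 0, r 0, p 1 (callers mask them separately).
    """
    single = y.ndim == 1
    Y = np.atleast_2d(y)
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((Yc**2).sum(axis=1))
    sx_safe = np.where(sx == 0, 1.0, sx)
    sy_safe = np.where(sy == 0, 1.0, sy)
    r = (Yc @ Xc) / (sy_safe[:, None] * sx_safe[None, :])
    r = np.clip(r, -1.0, 1.0)
    slope = r * (sy_safe[:, None] / sx_safe[None, :])
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = df * r**2 / (1.0 - r**2)
    p = np.where(r**2 >= 1.0, _P_FLOOR, stats.f.sf(t2, 1, df))
    p = np.where((sx == 0)[None, :] | (sy == 0)[:, None], 1.0, p)
    slope = np.where((sx == 0)[None, :], 0.0, slope)
    if single:
        return slope[0], r[0], p[0]
    return slope, r, p


def nominal_scan(
    phenotype_values: np.ndarray | pd.Series,
    dosages: pd.DataFrame,
    tss_distance: pd.Series | None = None,
) -> tuple[pd.DataFrame, str | None]:
    """Simple-regression scan of one phenotype against every variant.

    Returns ``(table, best_variant_id)`` where the table (indexed by
    variant id) has slope, r and nominal_p columns plus a ``skipped``
    flag for zero-variance dosages.  The best hit is the smallest nominal
    p among non-skipped variants; ties break by smaller |tss_distance|
    (when distances are supplied) then lexicographic variant id.
    """
    y = np.asarray(phenotype_values, dtype=float)
    X = dosages.to_numpy(dtype=float)
    if y.shape[0] < 10:
        raise ValueError("nominal scan requires >= 10 samples")
    slope, r, p = _corr_stats(y, X)
    skipped = X.std(axis=0) == 0
    table = pd.DataFrame(
        {"slope": slope, "r": r, "nominal_p": p, "skipped": skipped},
        index=dosages.columns,
    )
    if tss_distance is not None:
        table["tss_distance"] = tss_distance.reindex(table.index)
    best = _best_hit(table)
    return table, best


def _best_hit(table: pd.DataFrame) -> str | None:
    ok = table.loc[~table["skipped"]]
    if ok.empty:
        return None
    keys = [ok["nominal_p"]]
    if "tss_distance" in ok:
        keys.append(ok["tss_distance"].abs())
    order = pd.DataFrame(dict(enumerate(keys)), index=ok.index)
    order["vid"] = ok.index
    return order.sort_values(list(order.columns), kind="mergesort").index[0]


@dataclass
class BetaFit:
    """Beta(shape1, shape2) fitted to permutation null minima."""

    shape1: float
    shape2: float
    n_perm: int
    converged: bool = True
    method: str = "mle"

    def adjust(self, nominal_p: float) -> float:
        """Beta-CDF adjustment of a best nominal p."""
        return float(stats.beta.cdf(nominal_p, self.shape1, self.shape2))


def fit_beta(null_minima: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> BetaFit:
    """Maximum-likelihood Beta fit to permutation minima.

    Initialized from method-of-moments; falls back to the moments
    estimate (flagged) if the likelihood optimization fails.  Values at
    exactly 0 or 1 are clamped into the open interval.
    """
    x = np.asarray(null_minima, dtype=float)
    if x.size < 100:
        raise ValueError("need >= 100 permutation minima for a stable beta fit")
    if np.all(x == x[0]):
        raise ValueError("degenerate (constant) permutation minima")
    x = np.clip(x, _P_FLOOR, 1.0 - 1e-16)

    m, v = x.mean(), x.var()
    v = max(v, 1e-12)
    common = m * (1.0 - m) / v - 1.0
    a0 = max(m * common, 1e-3)
    b0 = max((1.0 - m) * common, 1e-3)

    lx = np.log(x)
    l1x = np.log1p(-x)

    res = optimize.minimize(
        lambda q: _beta_nll(q[0], q[1], lx, l1x, x.size),
        x0=np.array([a0, b0]),
        method="L-BFGS-B",
        bounds=[(1e-6, None), (1e-6, None)],
        options={"maxiter": max_iter, "ftol": tol},
    )
    if res.success and np.all(res.x > 0):
        return BetaFit(float(res.x[0]), float(res.x[1]), x.size, True, "mle")
    return BetaFit(float(a0), float(b0), x.size, False, "moments")


def _beta_nll(a: float, b: float, lx: np.ndarray, l1x: np.ndarray, n: int) -> float:
    from scipy.special import betaln

    return float(n * betaln(a, b) - (a - 1.0) * lx.sum() - (b - 1.0) * l1x.sum())


def permutation_pass(
    phenotype_values: np.ndarray | pd.Series,
    dosages: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    tss_distance: pd.Series | None = None,
    return_minima: bool = False,
):
    """Adjust the best cis hit for the number of variants tested.

    The phenotype vector is shuffled ``n_perm`` times across samples and
    the whole window rescanned each time; the minima of the per-scan
    nominal p-values form the null against which the observed best p is
    calibrated through a fitted Beta distribution.

    Returns ``(hit_row, beta_fit)`` — and the null minima when
    ``return_minima`` — where ``hit_row`` is a dict with the best
    variant's slope, nominal p, empirical permutation p and beta-adjusted
    p.  ``hit_row`` is None when every variant is degenerate.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    y = np.asarray(phenotype_values, dtype=float)
    table, best = nominal_scan(y, dosages, tss_distance)
    if best is None:
        return (None, None, None) if return_minima else (None, None)
    X = dosages.to_numpy(dtype=float)
    ok = ~table["skipped"].to_numpy()

    rng = np.random.default_rng(seed)
    n = y.shape[0]
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    Yp = y[perms]  # (n_perm, n)
    _, _, pvals = _corr_stats(Yp, X[:, ok])
    minima = pvals.min(axis=1)

    beta_fit = fit_beta(minima)
    p_best = float(table.loc[best, "nominal_p"])
    emp_p = (1.0 + np.count_nonzero(minima <= p_best)) / (1.0 + n_perm)
    hit = {
        "variant_id": best,
        "slope": float(table.loc[best, "slope"]),
        "nominal_p": p_best,
        "empirical_p": float(emp_p),
        "adj_p": beta_fit.adjust(p_best),
        "n_variants": int(ok.sum()),
    }
    if tss_distance is not None:
        hit["tss_distance"] = int(table.loc[best, "tss_distance"])
    if return_minima:
        return hit, beta_fit, minima
    return hit, beta_fit


def qvalues(
    p: np.ndarray,
    lambdas: np.ndarray | None = None,
    pi0: float | None = None,
) -> tuple[np.ndarray, float]:
    """Storey q-values with smoother pi0 estimation.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on the
    lambda grid (default 0.05..0.95 step 0.05), smoothed with a cubic
    polynomial and read off at the largest lambda, then clamped to
    (0, 1].  With fewer than 100 p-values pi0 falls back to 1
    (Benjamini-Hochberg behaviour) — too few points to estimate the null
    proportion.  Returns ``(q, pi0)``; q is monotone non-decreasing in p.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if m < 100:
            warnings.warn("fewer than 100 p-values; using pi0 = 1 (BH)")
            pi0 = 1.0
        else:
            if lambdas is None:
                lambdas = np.arange(0.05, 0.96, 0.05)
            lambdas = np.asarray(lambdas, dtype=float)
            pi0_l = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
            coef = np.polyfit(lambdas, pi0_l, 3)
            pi0 = float(np.polyval(coef, lambdas.max()))
            pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_ord = pi0 * m * ranked / np.arange(1, m + 1)
    q_ord = np.minimum.accumulate(q_ord[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_ord, 1.0)
    return q, float(pi0)


def nominal_threshold(beta_fit: BetaFit, adj_threshold: float) -> float:
    """Nominal-p threshold equivalent to an adjusted-p threshold.

    The Beta quantile maps the target adjusted significance level back to
    the scale of per-variant nominal p-values for this phenotype's window.
    """
    if not (0.0 < adj_threshold < 1.0):
        raise ValueError("adj_threshold must lie in (0, 1)")
    return float(stats.beta.ppf(adj_threshold, beta_fit.shape1, beta_fit.shape2))


def _conditional_scan(
    y: np.ndarray, X: np.ndarray, C: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant (slope, p) of y ~ x conditioning on covariate matrix C.

    Both y and every dosage column are residualized on [1 | C]; the
    partial correlation's t statistic uses n - 2 - n_cov df.
    """
    n = y.shape[0]
    if C is None or C.shape[1] == 0:
        slope, _, p = _corr_stats(y, X)
        return slope, p
    design = np.column_stack([np.ones(n), C])
    coef_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    ry = y - design @ coef_y
    coef_x, *_ = np.linalg.lstsq(design, X, rcond=None)
    rX = X - design @ coef_x
    sx = rX.std(axis=0)
    sy = ry.std()
    sx_safe = np.where(sx == 0, 1.0, sx)
    r = (ry - ry.mean()) @ (rX - rX.mean(axis=0)) / (n * sx_safe * (sy if sy else 1.0))
    r = np.clip(r, -1.0, 1.0)
    slope = r * sy / sx_safe
    df = n - 2 - C.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = df * r**2 / (1.0 - r**2)
    p = np.where(r**2 >= 1.0, _P_FLOOR, stats.f.sf(t2, 1, df))
    p = np.where(sx == 0, 1.0, p)
    return np.where(sx == 0, 0.0, slope), p


def conditional_pass(
    phenotype_values: np.ndarray | pd.Series,
    dosages: pd.DataFrame,
    nominal_threshold: float,
    tss_distance: pd.Series | None = None,
) -> pd.DataFrame:
    """Forward-backward discovery of independent cis signals.

    FORWARD: repeatedly add the best remaining variant with conditional
    p below the threshold as a covariate and re-scan, until none passes.
    BACKWARD: for each forward signal, re-test every window variant
    conditioning on all *other* retained signals and keep the top variant
    for that signal if it still passes.  Returns a frame of hits with a
    ``rank`` column (0 = primary signal).
    """
    y = np.asarray(phenotype_values, dtype=float)
    X = dosages.to_numpy(dtype=float)
    cols = dosages.columns
    dist = tss_distance.reindex(cols) if tss_distance is not None else None

    def pick_best(slopes: np.ndarray, pvals: np.ndarray, exclude: set[int]) -> int | None:
        mask = np.ones(len(cols), dtype=bool)
        mask[list(exclude)] = False
        mask &= pvals < nominal_threshold
        if not mask.any():
            return None
        idx = np.flatnonzero(mask)
        key = pd.DataFrame({"p": pvals[idx]}, index=idx)
        if dist is not None:
            key["d"] = np.abs(dist.to_numpy()[idx])
        key["vid"] = cols[idx]
        return int(key.sort_values(list(key.columns), kind="mergesort").index[0])

    # forward
    selected: list[int] = []
    while True:
        C = X[:, selected] if selected else None
        if C is not None:
            # drop covariates that became collinear (zero residual variance)
            keep = [j for k, j in enumerate(selected) if np.linalg.matrix_rank(
                np.column_stack([np.ones(len(y)), X[:, selected[: k + 1]]])
            ) == k + 2]
            if len(keep) != len(selected):
                warnings.warn("collinear selected dosages dropped in forward pass")
                selected = keep
                C = X[:, selected] if selected else None
        slopes, pvals = _conditional_scan(y, X, C)
        best = pick_best(slopes, pvals, set(selected))
        if best is None:
            break
        selected.append(best)
        if len(selected) >= X.shape[0] - 3:
            break

    # backward
    rows = []
    for rank, sig in enumerate(selected):
        others = [j for j in selected if j != sig]
        C = X[:, others] if others else None
        slopes, pvals = _conditional_scan(y, X, C)
        best = pick_best(slopes, pvals, set(others))
        if best is None:
            continue
        row = {
            "variant_id": cols[best],
            "slope": float(slopes[best]),
            "nominal_p": float(pvals[best]),
            "rank": rank,
        }
        if dist is not None:
            row["tss_distance"] = int(dist.iloc[best])
        rows.append(row)
    out = pd.DataFrame(rows, columns=["variant_id", "slope", "nominal_p", "rank"] + (
        ["tss_distance"] if dist is not None else []
    ))
    out["rank"] = out["rank"].rank(method="dense").astype(int) - 1 if len(out) else out.get("rank", pd.Series(dtype=int))
    return out


def replicate_hits(
    hits: pd.DataFrame,
    replication_dosages: pd.DataFrame,
    replication_phenotypes: pd.DataFrame,
) -> tuple[pd.DataFrame, float]:
    """Score discovery hits in an independent cohort and estimate pi1.

    Only hits whose variant and phenotype are present in the replication
    set are scored.  pi1 = 1 - pi0 estimated from the replication
    nominal p-values; it is the fraction of discovery hits that are true
    associations in the replication cohort.
    """
    ok = hits["variant_id"].isin(replication_dosages.columns) & hits[
        "phenotype_id"
    ].isin(replication_phenotypes.columns)
    scored = hits.loc[ok].copy()
    if scored.empty:
        raise ValueError("no discovery hits present in the replication set")
    pvals = np.empty(len(scored))
    Y = replication_phenotypes.to_numpy(dtype=float)
    X = replication_dosages.to_numpy(dtype=float)
    pcol = {c: i for i, c in enumerate(replication_phenotypes.columns)}
    vcol = {c: i for i, c in enumerate(replication_dosages.columns)}
    for i, (_, row) in enumerate(scored.iterrows()):
        _, _, p = _corr_stats(Y[:, pcol[row["phenotype_id"]]], X[:, [vcol[row["variant_id"]]]])
        pvals[i] = p[0]
    scored["replication_p"] = pvals
    _, pi0 = qvalues(pvals)
    return scored, 1.0 - pi0


class CisQTLModel:
    """Permutation cis-QTL mapping across a phenotype table.

    Parameters
    ----------
    phenotypes : PhenotypeTable
        Rank-normalized quantifications (stage 'ranknorm' recommended).
    variants : VariantSet
        Dosages keyed by patient; when phenotype sample ids differ from
        patient ids, supply ``sample_to_patient``.
    window : int
        cis window half-width in bp around the TSS (default 1 Mb).
    """

    def __init__(
        self,
        phenotypes: PhenotypeTable,
        variants: VariantSet,
        window: int = 1_000_000,
        sample_to_patient: pd.Series | dict | None = None,
    ) -> None:
        self.phenotypes = phenotypes
        self.variants = variants
        self.window = int(window)
        if sample_to_patient is not None:
            mapping = pd.Series(sample_to_patient)
            patients = mapping.reindex(phenotypes.values.index)
            if patients.isna().any():
                raise ValueError("sample_to_patient missing entries for some samples")
            self._dosages = variants.dosages.loc[patients.to_numpy()]
            self._dosages.index = phenotypes.values.index
        else:
            self._dosages = variants.dosages.reindex(phenotypes.values.index)
            if self._dosages.isna().any().any():
                raise ValueError(
                    "phenotype samples not found among patients; "
                    "pass sample_to_patient to map them"
                )

    def window_of(self, feature_id: str) -> pd.DataFrame:
        feat = self.phenotypes.features.loc[feature_id]
        tss = int(self.phenotypes.tss().loc[feature_id])
        return cis_window(tss, feat["chrom"], feat["strand"], self.variants, self.window)

    def fit(self, n_permutations: int = 1000, seed: int = 0, fdr: float = 0.05) -> "CisQTLResults":
        """Run the permutation pass for every phenotype and FDR-correct."""
        rows = []
        beta_fits: dict[str, BetaFit] = {}
        for fid in self.phenotypes.features.index:
            win = self.window_of(fid)
            if win.empty:
                continue
            hit, bf = permutation_pass(
                self.phenotypes.values[fid].to_numpy(),
                self._dosages[win.index],
                n_perm=n_permutations,
                seed=_phenotype_seed(seed, fid),
                tss_distance=win["tss_distance"],
            )
            if hit is None:
                continue
            hit["phenotype_id"] = fid
            hit["beta_shape1"] = bf.shape1
            hit["beta_shape2"] = bf.shape2
            rows.append(hit)
            beta_fits[fid] = bf
        table = pd.DataFrame(rows)
        if len(table):
            q, pi0 = qvalues(table["adj_p"].to_numpy())
            table["q_value"] = q
        else:
            pi0 = 1.0
            table["q_value"] = pd.Series(dtype=float)
        cols = [
            "phenotype_id",
            "variant_id",
            "tss_distance",
            "slope",
            "nominal_p",
            "empirical_p",
            "adj_p",
            "q_value",
            "beta_shape1",
            "beta_shape2",
            "n_variants",
        ]
        table = table[[c for c in cols if c in table.columns]]
        return CisQTLResults(self, table, beta_fits, pi0, n_permutations, seed, fdr)


@dataclass
class CisQTLResults:
    """Per-phenotype best cis associations with adjusted p and q-values."""

    model: CisQTLModel
    table: pd.DataFrame
    beta_fits: dict
    pi0: float
    n_permutations: int
    seed: int
    fdr: float = 0.05

    def significant(self, fdr: float | None = None) -> pd.DataFrame:
        fdr = self.fdr if fdr is None else fdr
        return self.table.loc[self.table["q_value"] <= fdr]

    def adjusted_threshold(self, fdr: float | None = None) -> float:
        """Largest adjusted p among significant phenotypes (interpolated cutoff).

        Midpoint between the last adjusted p below the FDR line and the
        first above it; 0 when nothing is significant.
        """
        fdr = self.fdr if fdr is None else fdr
        sig = self.significant(fdr)
        if sig.empty:
            return 0.0
        upper = self.table.loc[self.table["q_value"] > fdr, "adj_p"]
        hi = float(upper.min()) if len(upper) else 1.0
        lo = float(sig["adj_p"].max())
        return (lo + hi) / 2.0

    def conditional(self, fdr: float | None = None) -> pd.DataFrame:
        """Forward-backward conditional pass on every significant phenotype.

        The per-phenotype nominal threshold is the Beta quantile of the
        study-wide adjusted-p cutoff.  Returns all independent signals
        (ranked) across phenotypes.
        """
        fdr = self.fdr if fdr is None else fdr
        adj_cut = self.adjusted_threshold(fdr)
        frames = []
        for fid in self.significant(fdr)["phenotype_id"]:
            bf = self.beta_fits[fid]
            thr = nominal_threshold(bf, adj_cut) if 0.0 < adj_cut < 1.0 else 0.0
            win = self.model.window_of(fid)
            hits = conditional_pass(
                self.model.phenotypes.values[fid].to_numpy(),
                self.model._dosages[win.index],
                thr,
                tss_distance=win["tss_distance"],
            )
            hits.insert(0, "phenotype_id", fid)
            frames.append(hits)
        if not frames:
            return pd.DataFrame(
                columns=["phenotype_id", "variant_id", "slope", "nominal_p", "rank", "tss_distance"]
            )
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        sig = self.significant()
        lines = [
            "cis-QTL permutation pass",
            "=" * 40,
            f"phenotypes tested      {len(self.table)}",
            f"permutations           {self.n_permutations}",
            f"window (bp)            {self.model.window}",
            f"pi0 estimate           {self.pi0:.3f}",
            f"significant @{self.fdr:.0%} FDR   {len(sig)}",
        ]
        return "\n".join(lines)
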
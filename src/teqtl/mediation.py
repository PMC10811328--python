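"""TE-gene association, pair quantification, and causal-topology inference.

The mediation chain asks whether a cis variant's effect on a gene is
routed through a transposable element.  Stages:

1. TE-gene scan: genes are associated with nearby TEs using the same
   permutation machinery as QTL mapping, with TE expression standing in
   for genotypes (1% FDR, per-gene nominal thresholds, possibly several
   TEs per gene).
2. Pair quantification: each significant TE-gene pair is collapsed to
   its coordinates on the first principal component of the two
   standardized expression vectors, rank-normalized.
3. Triplet mapping: a standard permutation eQTL pass on the pair PC1
   finds (variant, TE, gene) triplets at 5% FDR.
4. Topology classification: three Gaussian Bayesian networks — causal
   (V->T->G), reactive (V->G->T), independent (V->T, V->G) — are scored
   by maximum-likelihood Gaussian log-likelihood; uniform-prior
   posteriors assign the topology.  The marginal term for the variant is
   identical across the three graphs and cancels in the posteriors.
5. Switch accounting: tumor triplets are matched to normal triplets
   (same TE and gene; same variant or dosage LD r^2 >= 0.9) and labelled
   by whether their assigned model changed, in particular whether a
   non-causal normal model switched to causal in tumor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import cis
from .datatypes import TOPOLOGIES, PhenotypeTable, VariantSet
from .prep import rank_normalize

logger = logging.getLogger(__name__)

__all__ = [
    "te_gene_scan",
    "PairQuant",
    "pair_pc1",
    "triplet_qtl",
    "bn_loglik",
    "bn_posteriors",
    "ld_r2",
    "match_and_classify_switches",
    "union_triplets",
    "TripletModel",
    "TripletResults",
]

_VAR_FLOOR = 1e-12


def te_gene_scan(
    te_table: PhenotypeTable,
    gene_table: PhenotypeTable,
    window: int = 1_000_000,
    n_perm: int = 1000,
    fdr: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Associate genes with cis TEs, TE expression playing the genotype role.

    Per gene, all TEs whose (strand-aware) start lies within ``window``
    of the gene TSS are scanned; the best association is
    permutation-adjusted and q-values across genes applied at ``fdr``.
    For each significant gene the Beta quantile converts the study-level
    adjusted cutoff into a per-gene nominal threshold, and *all* TEs
    below it are reported — a gene may get several TEs.

    Both tables must be rank-normalized.  Returns a frame with te_id,
    gene_id, slope, nominal_p, adj_p, q_value.
    """
    te_tss = te_table.tss()
    gene_tss = gene_table.tss()
    te_vals = te_table.values
    rows, fits, windows = [], {}, {}
    for gid in gene_table.features.index:
        gchrom = gene_table.features.loc[gid, "chrom"]
        on_chrom = te_table.features["chrom"] == gchrom
        dist = (te_tss[on_chrom] - int(gene_tss[gid])).abs()
        in_win = dist.index[dist <= window]
        if len(in_win) == 0:
            continue
        hit, bf = cis.permutation_pass(
            gene_table.values[gid].to_numpy(),
            te_vals[in_win],
            n_perm=n_perm,
            seed=cis._phenotype_seed(seed, gid),
        )
        if hit is None:
            continue
        hit["gene_id"] = gid
        rows.append(hit)
        fits[gid] = bf
        windows[gid] = in_win
    if not rows:
        return pd.DataFrame(columns=["te_id", "gene_id", "slope", "nominal_p", "adj_p", "q_value"])
    best = pd.DataFrame(rows)
    q, _ = cis.qvalues(best["adj_p"].to_numpy())
    best["q_value"] = q
    sig = best.loc[best["q_value"] <= fdr]
    if sig.empty:
        return pd.DataFrame(columns=["te_id", "gene_id", "slope", "nominal_p", "adj_p", "q_value"])
    nonsig = best.loc[best["q_value"] > fdr, "adj_p"]
    hi = float(nonsig.min()) if len(nonsig) else 1.0
    adj_cut = (float(sig["adj_p"].max()) + hi) / 2.0

    out = []
    for _, row in sig.iterrows():
        gid = row["gene_id"]
        thr = cis.nominal_threshold(fits[gid], adj_cut) if 0 < adj_cut < 1 else 0.0
        table, _ = cis.nominal_scan(gene_table.values[gid].to_numpy(), te_vals[windows[gid]])
        passing = table.loc[(~table["skipped"]) & (table["nominal_p"] < thr)]
        for te_id, te_row in passing.iterrows():
            out.append(
                {
                    "te_id": te_id,
                    "gene_id": gid,
                    "slope": te_row["slope"],
                    "nominal_p": te_row["nominal_p"],
                    "adj_p": row["adj_p"] if te_id == row["variant_id"] else np.nan,
                    "q_value": row["q_value"] if te_id == row["variant_id"] else np.nan,
                }
            )
    return pd.DataFrame(out)


@dataclass
class PairQuant:
    """A TE-gene pair collapsed to rank-normalized PC1 coordinates."""

    te_id: str
    gene_id: str
    pc1: np.ndarray
    var_explained: float
    loadings: tuple[float, float]  # (te, gene); gene loading >= 0


def pair_pc1(
    te_vec: np.ndarray, gene_vec: np.ndarray, te_id: str = "te", gene_id: str = "gene"
) -> PairQuant:
    """First-principal-component aggregation of a TE-gene expression pair.

    The two vectors are centered and scaled, PCA'd jointly, and each
    sample's PC1 coordinate is rank-normalized.  The component sign is
    fixed so the gene loading is non-negative, making the pair phenotype
    track the gene's direction of expression.
    """
    t = np.asarray(te_vec, dtype=float)
    g = np.asarray(gene_vec, dtype=float)
    if t.shape != g.shape:
        raise ValueError("te and gene vectors must be the same length")
    if t.std() == 0 or g.std() == 0:
        raise ValueError("constant input vector; PC1 undefined")
    M = np.column_stack([(t - t.mean()) / t.std(), (g - g.mean()) / g.std()])
    u, s, vt = np.linalg.svd(M, full_matrices=False)
    if vt[0, 1] < 0:
        u, vt = -u, -vt
    pc1 = u[:, 0] * s[0]
    var_explained = float(s[0] ** 2 / (s**2).sum())
    pc1_rn = rank_normalize(pd.DataFrame({"pc1": pc1})).to_numpy()[:, 0]
    return PairQuant(te_id, gene_id, pc1_rn, var_explained, (float(vt[0, 0]), float(vt[0, 1])))


def triplet_qtl(
    pairs: list[PairQuant],
    pair_positions: pd.DataFrame,
    variants: VariantSet,
    dosages: pd.DataFrame,
    window: int = 1_000_000,
    n_perm: int = 1000,
    fdr: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Map eQTLs for TE-gene pair phenotypes (PC1) -> candidate triplets.

    ``pair_positions`` is indexed like the pairs (te_id, gene_id multi
    index or '<te>|<gene>') with chrom, te_tss and gene_tss columns; the
    cis window is the union of the windows around the TE and the gene
    TSS.  Significant (variant, pair) results at ``fdr`` become
    (variant, TE, gene) triplets.
    """
    rows, fits = [], {}
    for pq in pairs:
        key = f"{pq.te_id}|{pq.gene_id}"
        posrow = pair_positions.loc[key]
        vt = variants.variants
        on_chrom = vt["chrom"] == posrow["chrom"]
        pos = vt.loc[on_chrom, "pos"]
        near = ((pos - int(posrow["te_tss"])).abs() <= window) | (
            (pos - int(posrow["gene_tss"])).abs() <= window
        )
        win = pos.index[near]
        if len(win) == 0:
            continue
        hit, bf = cis.permutation_pass(
            pq.pc1, dosages[win], n_perm=n_perm, seed=cis._phenotype_seed(seed, key)
        )
        if hit is None:
            continue
        hit["te_id"] = pq.te_id
        hit["gene_id"] = pq.gene_id
        rows.append(hit)
        fits[key] = bf
    if not rows:
        return pd.DataFrame(
            columns=["variant_id", "te_id", "gene_id", "slope", "nominal_p", "adj_p", "q_value"]
        )
    table = pd.DataFrame(rows)
    q, _ = cis.qvalues(table["adj_p"].to_numpy())
    table["q_value"] = q
    sig = table.loc[table["q_value"] <= fdr].reset_index(drop=True)
    return sig[["variant_id", "te_id", "gene_id", "slope", "nominal_p", "adj_p", "q_value"]]


def _gauss_ll(x: np.ndarray) -> float:
    """Gaussian log-likelihood of a sample at its MLE (mean, variance)."""
    n = x.size
    var = max(float(np.var(x)), _VAR_FLOOR)
    return -0.5 * n * (np.log(2.0 * np.pi * var) + 1.0)


def _cond_ll(y: np.ndarray, x: np.ndarray) -> float:
    """Log-likelihood of y | x under simple linear regression with MLE variance."""
    n = y.size
    xc = x - x.mean()
    denom = float(xc @ xc)
    beta = float(xc @ (y - y.mean())) / denom if denom > 0 else 0.0
    resid = y - y.mean() - beta * xc
    var = max(float(resid @ resid) / n, _VAR_FLOOR)
    return -0.5 * n * (np.log(2.0 * np.pi * var) + 1.0)


def bn_loglik(dosage: np.ndarray, te: np.ndarray, gene: np.ndarray, topology: str) -> float:
    """Log-likelihood of one triplet under a network topology.

    Each topology factorizes the joint density into the variant's
    marginal plus two Gaussian regressions:

    - causal:      ll(V) + ll(T|V) + ll(G|T)
    - reactive:    ll(V) + ll(G|V) + ll(T|G)
    - independent: ll(V) + ll(T|V) + ll(G|V)

    ll(V) is computed identically across topologies (it cancels in the
    posteriors but keeps the values comparable as joint likelihoods).
    """
    if topology not in TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}")
    v = np.asarray(dosage, dtype=float)
    t = np.asarray(te, dtype=float)
    g = np.asarray(gene, dtype=float)
    if not (v.shape == t.shape == g.shape):
        raise ValueError("dosage, te and gene vectors must be aligned")
    llv = _gauss_ll(v)
    if topology == "causal":
        return llv + _cond_ll(t, v) + _cond_ll(g, t)
    if topology == "reactive":
        return llv + _cond_ll(g, v) + _cond_ll(t, g)
    return llv + _cond_ll(t, v) + _cond_ll(g, v)


def bn_posteriors(
    dosage: np.ndarray, te: np.ndarray, gene: np.ndarray
) -> tuple[np.ndarray, np.ndarray, str]:
    """Uniform-prior posterior probabilities over the three topologies.

    Returns ``(logliks, posteriors, assigned_model)``, ordered (causal,
    reactive, independent).  The softmax is log-sum-exp stabilized; exact
    ties resolve in the order causal > reactive > independent.
    """
    ll = np.array([bn_loglik(dosage, te, gene, topo) for topo in TOPOLOGIES])
    shifted = ll - ll.max()
    post = np.exp(shifted)
    post /= post.sum()
    assigned = TOPOLOGIES[int(np.argmax(ll))]  # argmax takes first on ties
    return ll, post, assigned


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant dosage vector; LD undefined")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def match_and_classify_switches(
    triplets_normal: pd.DataFrame,
    triplets_tumor: pd.DataFrame,
    dosages: pd.DataFrame,
    ld_threshold: float = 0.9,
) -> pd.DataFrame:
    """Match tumor triplets to normal triplets and label model switches.

    Both frames need variant_id, te_id, gene_id and assigned_model.  A
    tumor triplet matches a normal triplet sharing the same (TE, gene)
    when the variants are identical or in LD r^2 >= ``ld_threshold``
    (inclusive); among several matches the highest-r^2 one is kept
    (logged).  Labels per tumor triplet: ``no_switch`` (same model),
    ``switch_to_causal`` (normal model non-causal, tumor causal),
    ``switch_to_other`` (models differ otherwise), ``unmatched``.
    """
    by_pair = {
        key: grp for key, grp in triplets_normal.groupby(["te_id", "gene_id"], sort=False)
    }
    rows = []
    for _, trow in triplets_tumor.iterrows():
        key = (trow["te_id"], trow["gene_id"])
        label, matched_variant, matched_model, best_r2 = "unmatched", None, None, np.nan
        if key in by_pair:
            cands = by_pair[key]
            scores = []
            for _, nrow in cands.iterrows():
                if nrow["variant_id"] == trow["variant_id"]:
                    scores.append((1.0 + 1e-9, nrow))  # identity outranks any LD proxy
                else:
                    r2 = ld_r2(
                        dosages[trow["variant_id"]].to_numpy(),
                        dosages[nrow["variant_id"]].to_numpy(),
                    )
                    if r2 >= ld_threshold:
                        scores.append((r2, nrow))
            if scores:
                if len(scores) > 1:
                    logger.info(
                        "tumor triplet %s|%s|%s matched %d normal triplets; keeping best r2",
                        trow["variant_id"], trow["te_id"], trow["gene_id"], len(scores),
                    )
                r2, nrow = max(scores, key=lambda s: s[0])
                best_r2 = min(r2, 1.0)
                matched_variant = nrow["variant_id"]
                matched_model = nrow["assigned_model"]
                if matched_model == trow["assigned_model"]:
                    label = "no_switch"
                elif trow["assigned_model"] == "causal":
                    label = "switch_to_causal"
                else:
                    label = "switch_to_other"
        rows.append(
            {
                "variant_id": trow["variant_id"],
                "te_id": trow["te_id"],
                "gene_id": trow["gene_id"],
                "tumor_model": trow["assigned_model"],
                "normal_model": matched_model,
                "normal_variant": matched_variant,
                "match_r2": best_r2,
                "switch_label": label,
            }
        )
    return pd.DataFrame(rows)


def union_triplets(
    triplets_normal: pd.DataFrame, triplets_tumor: pd.DataFrame
) -> pd.DataFrame:
    """Union of the two tissues' triplets, deduplicated on (variant, TE, gene).

    Use with :func:`bn_posteriors` evaluated on each tissue's data to
    compare topologies of every triplet in both states.
    """
    both = pd.concat([triplets_normal, triplets_tumor], ignore_index=True)
    return both.drop_duplicates(subset=["variant_id", "te_id", "gene_id"]).reset_index(drop=True)


class TripletModel:
    """Gaussian Bayesian-network comparison for one (variant, TE, gene) triplet."""

    def __init__(self, dosage: np.ndarray, te: np.ndarray, gene: np.ndarray) -> None:
        self.dosage = np.asarray(dosage, dtype=float)
        self.te = np.asarray(te, dtype=float)
        self.gene = np.asarray(gene, dtype=float)

    def fit(self) -> "TripletResults":
        ll, post, assigned = bn_posteriors(self.dosage, self.te, self.gene)
        return TripletResults(
            loglik=dict(zip(TOPOLOGIES, ll)),
            posterior=dict(zip(TOPOLOGIES, post)),
            assigned_model=assigned,
            n=self.dosage.size,
        )


@dataclass
class TripletResults:
    loglik: dict
    posterior: dict
    assigned_model: str
    n: int

    def summary(self) -> str:
        lines = ["causal-topology comparison", "=" * 34, f"samples  {self.n}"]
        for topo in TOPOLOGIES:
            lines.append(
                f"{topo:<12} loglik {self.loglik[topo]:>12.3f}  posterior {self.posterior[topo]:.4f}"
            )
        lines.append(f"assigned model: {self.assigned_model}")
        return "\n".join(lines)
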
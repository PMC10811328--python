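"""Synthetic paired normal/tumor cohorts with known ground truth.

The real study cohorts (paired colon biopsies with shared germline
genotypes) are access-restricted, so every downstream stage of this
package is validated against cohorts simulated here: biallelic variants
with MAF >= 5% under Hardy-Weinberg equilibrium, negative-binomial
expression counts with planted cis effects whose strength decays with
distance to the TSS, (variant, TE, gene) triplets generated under each of
the three causal topologies, and methylation beta shifts at tumor-specific
eQTL loci.  All draws flow from one `numpy.random.Generator` seeded per
call; identical seeds give bit-identical output.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import (
    TOPOLOGIES,
    CohortDesign,
    PhenotypeTable,
    TruthTable,
    VariantSet,
)

__all__ = [
    "generate_genotypes",
    "simulate_triplet",
    "generate_paired_cohort",
    "generate_methylation",
]


def generate_genotypes(
    n_patients: int,
    n_variants: int,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    chrom_length: int = 10_000_000,
    chrom: str = "chr1",
    seed: int | np.random.Generator = 0,
) -> VariantSet:
    """Simulate biallelic dosages under Hardy-Weinberg equilibrium.

    Per variant an alternate-allele frequency is drawn uniformly in
    ``[maf_low, maf_high]`` and each patient's dosage is Binomial(2, f).
    Positions are strictly increasing along a single chromosome.

    The stored ``maf`` column is the *empirical* folded allele frequency
    recomputed from the dosage matrix, so it matches
    :meth:`VariantSet.empirical_maf` exactly.
    """
    if n_patients < 2 or n_variants < 1:
        raise ValueError("n_patients must be >= 2 and n_variants >= 1")
    if not (0.0 <= maf_low <= maf_high <= 0.5):
        raise ValueError("require 0 <= maf_low <= maf_high <= 0.5")
    if chrom_length < n_variants:
        raise ValueError("chrom_length too small for n_variants distinct positions")
    rng = np.random.default_rng(seed)

    freqs = rng.uniform(maf_low, maf_high, size=n_variants)
    dosage = rng.binomial(2, freqs[None, :], size=(n_patients, n_variants)).astype(float)
    pos = np.sort(rng.choice(chrom_length, size=n_variants, replace=False)) + 1

    ids = [f"var{i:06d}" for i in range(n_variants)]
    patients = [f"P{i:04d}" for i in range(n_patients)]
    f_emp = dosage.mean(axis=0) / 2.0
    variants = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "maf": np.minimum(f_emp, 1.0 - f_emp)},
        index=pd.Index(ids, name="variant_id"),
    )
    dosages = pd.DataFrame(dosage, index=pd.Index(patients, name="patient_id"), columns=ids)
    return VariantSet(variants, dosages)


def simulate_triplet(
    dosage: np.ndarray,
    topology: str,
    slope_a: float,
    slope_b: float,
    noise_sd: float,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate TE and gene expression for one variant under a topology.

    causal:       T = a*V + e1,  G = b*T + e2   (variant -> TE -> gene)
    reactive:     G = a*V + e1,  T = b*G + e2   (variant -> gene -> TE)
    independent:  T = a*V + e1,  G = b*V + e2   (variant -> both, no TE-gene edge)

    with e ~ Normal(0, noise_sd^2) i.i.d.  Returns ``(te_values, gene_values)``.
    """
    if topology not in TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}; expected one of {TOPOLOGIES}")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    rng = np.random.default_rng(seed)
    v = np.asarray(dosage, dtype=float)
    e1 = rng.normal(0.0, noise_sd, size=v.shape)
    e2 = rng.normal(0.0, noise_sd, size=v.shape)
    if topology == "causal":
        te = slope_a * v + e1
        gene = slope_b * te + e2
    elif topology == "reactive":
        gene = slope_a * v + e1
        te = slope_b * gene + e2
    else:  # independent
        te = slope_a * v + e1
        gene = slope_b * v + e2
    return te, gene


def _place_features(
    n_te: int,
    n_gene: int,
    chrom: str,
    chrom_length: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Uniformly spaced features on one synthetic chromosome.

    TEs and genes are interleaved across the chromosome; strand is random.
    Feature length is irrelevant downstream (only the TSS matters for
    windowing) so a nominal 1 kb span is used.
    """
    n = n_te + n_gene
    spacing = chrom_length // (n + 1)
    starts = spacing * np.arange(1, n + 1)
    strands = rng.choice(["+", "-"], size=n)
    ids, classes = [], []
    te_i = gene_i = 0
    # interleave deterministically: TEs at even slots until exhausted
    for slot in range(n):
        if (slot % 2 == 0 and te_i < n_te) or gene_i >= n_gene:
            ids.append(f"te{te_i:05d}")
            classes.append("TE:AluY")
            te_i += 1
        else:
            ids.append(f"gene{gene_i:05d}")
            classes.append("gene")
            gene_i += 1
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + 1000,
            "strand": strands,
            "feature_class": classes,
        },
        index=pd.Index(ids, name="feature_id"),
    )


def generate_paired_cohort(
    design: CohortDesign,
    variants: VariantSet,
    n_te: int,
    n_gene: int,
    truth: TruthTable,
    *,
    baseline_log_mean: float = 4.0,
    dispersion: float = 0.2,
    library_size_sd: float = 0.2,
    eqtl_distance_scale: float = 50_000.0,
    chrom_length: int | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[PhenotypeTable, PhenotypeTable, TruthTable]:
    """Simulate paired normal/tumor count matrices with planted cis effects.

    Latent log-expression per feature is a baseline plus the planted
    dosage effects whose tissue scope restricts them to normal, tumor or
    both.  Counts are negative-binomial around ``exp(latent)`` scaled by a
    per-sample library factor (log-normal, sd ``library_size_sd``).  Each
    planted eQTL's phenotype is re-positioned so the variant lands within
    the cis window, at a distance drawn from Laplace(scale
    ``eqtl_distance_scale``) to mimic the proximal decay of real cis
    effects.

    Returns ``(counts_normal, counts_tumor, truth)``; both tables share
    patient-keyed genotypes through ``design``.
    """
    rng = np.random.default_rng(seed)
    chrom = variants.variants["chrom"].iloc[0]
    if chrom_length is None:
        chrom_length = int(variants.variants["pos"].max() + 1_000_000)
    features = _place_features(n_te, n_gene, chrom, chrom_length, rng)
    truth.validate_against(variants.variants.index, features.index)

    # move each planted phenotype's TSS near its variant (Laplace offset)
    for _, row in truth.effects.iterrows():
        vpos = int(variants.variants.loc[row["variant_id"], "pos"])
        offset = int(rng.laplace(0.0, eqtl_distance_scale))
        offset = int(np.clip(offset, -900_000, 900_000))
        tss = int(np.clip(vpos + offset, 1, chrom_length - 1001))
        fid = row["phenotype_id"]
        if features.loc[fid, "strand"] == "+":
            features.loc[fid, "start"] = tss - 1
            features.loc[fid, "end"] = tss - 1 + 1000
        else:
            features.loc[fid, "end"] = tss
            features.loc[fid, "start"] = max(tss - 1000, 0)

    n_pat = design.n_patients
    n_feat = len(features)
    feat_pos = {f: i for i, f in enumerate(features.index)}
    dosage = variants.dosages.to_numpy()
    var_pos = {v: i for i, v in enumerate(variants.dosages.columns)}

    latent = {
        "normal": np.full((n_pat, n_feat), baseline_log_mean),
        "tumor": np.full((n_pat, n_feat), baseline_log_mean),
    }
    for _, row in truth.effects.iterrows():
        d = dosage[:, var_pos[row["variant_id"]]]
        centered = row["slope"] * (d - d.mean())
        j = feat_pos[row["phenotype_id"]]
        if row["scope"] in ("normal_only", "shared"):
            latent["normal"][:, j] += centered
        if row["scope"] in ("tumor_only", "shared"):
            latent["tumor"][:, j] += centered

    out: dict[str, PhenotypeTable] = {}
    sample_ids = {"normal": design.normal_samples, "tumor": design.tumor_samples}
    for tissue in ("normal", "tumor"):
        lib = np.exp(rng.normal(0.0, library_size_sd, size=n_pat))
        mu = np.exp(latent[tissue]) * lib[:, None]
        # NB with mean mu, variance mu + dispersion*mu^2
        n_param = 1.0 / dispersion
        p_param = n_param / (n_param + mu)
        counts = rng.negative_binomial(n_param, p_param)
        out[tissue] = PhenotypeTable(
            features.copy(),
            pd.DataFrame(
                counts,
                index=pd.Index(sample_ids[tissue], name="sample_id"),
                columns=features.index,
            ),
            stage="counts",
        )
    return out["normal"], out["tumor"], truth


def generate_methylation(
    eqtl_classes: Mapping[str, str],
    delta: float = 0.05,
    noise_sd: float = 0.02,
    n_probes_per_locus: int = 1,
    n_samples: int = 100,
    base_beta: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate methylation beta matrices around eQTL loci.

    ``eqtl_classes`` maps eQTL id -> 'shared' | 'tumor_specific'.
    Tumor-specific loci receive a median beta shift of ``delta`` between
    tissues; shared loci receive none.  Betas are clipped to [0, 1].

    Returns ``(betas_normal, betas_tumor, probe_map)`` where the beta
    frames are probes x samples and ``probe_map`` links probe_id to
    eqtl_id.
    """
    if not (0.0 <= delta <= 1.0):
        raise ValueError("delta must lie in [0, 1]")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    rng = np.random.default_rng(seed)

    probe_rows = []
    for eqtl_id, cls in eqtl_classes.items():
        if cls not in ("shared", "tumor_specific"):
            raise ValueError(f"unknown eQTL class {cls!r} for {eqtl_id}")
        for k in range(n_probes_per_locus):
            probe_rows.append((f"{eqtl_id}_probe{k}", eqtl_id, cls))
    probe_map = pd.DataFrame(probe_rows, columns=["probe_id", "eqtl_id", "class"])

    n_probes = len(probe_map)
    samples = [f"S{i:04d}" for i in range(n_samples)]
    normal = base_beta + rng.normal(0.0, noise_sd, size=(n_probes, n_samples))
    tumor = base_beta + rng.normal(0.0, noise_sd, size=(n_probes, n_samples))
    shift = np.where(probe_map["class"].to_numpy() == "tumor_specific", delta, 0.0)
    tumor = tumor + shift[:, None]

    idx = pd.Index(probe_map["probe_id"], name="probe_id")
    betas_normal = pd.DataFrame(np.clip(normal, 0.0, 1.0), index=idx, columns=samples)
    betas_tumor = pd.DataFrame(np.clip(tumor, 0.0, 1.0), index=idx, columns=samples)
    return betas_normal, betas_tumor, probe_map
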
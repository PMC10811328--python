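"""Core in-memory containers shared across the pipeline.

The pipeline moves three kinds of tabular objects between stages: a
:class:`VariantSet` (per-patient allele dosages with positions and MAFs),
a :class:`PhenotypeTable` (per-sample quantifications of genes and TE loci
with genomic positions), and a :class:`CohortDesign` describing the paired
normal/tumor layout.  A :class:`TruthTable` records effects planted by the
synthetic-cohort generator so downstream stages can be scored against a
known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VariantSet",
    "PhenotypeTable",
    "CohortDesign",
    "TruthTable",
    "PHENOTYPE_STAGES",
]

#: Allowed stage tags for PhenotypeTable.values, in pipeline order.
PHENOTYPE_STAGES = ("counts", "cpm", "residual", "ranknorm")


@dataclass
class VariantSet:
    """Biallelic variants with per-patient allele dosages.

    Parameters
    ----------
    variants : pandas.DataFrame
        Indexed by ``variant_id``; columns ``chrom`` (str), ``pos``
        (1-based int bp) and ``maf`` (minor-allele frequency).
    dosages : pandas.DataFrame
        Patients x variants matrix of dosages in [0, 2]; index is
        ``patient_id``, columns match ``variants.index``.
    """

    variants: pd.DataFrame
    dosages: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.variants.index.equals(pd.Index(self.dosages.columns)):
            raise ValueError("variant ids in `variants` and `dosages` differ")
        vals = self.dosages.to_numpy()
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_patients(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def empirical_maf(self) -> pd.Series:
        """MAF recomputed from the dosage matrix (folded allele frequency)."""
        f = self.dosages.mean(axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def filter_maf(self, min_maf: float = 0.05) -> "VariantSet":
        """Drop variants below a MAF threshold (standard study filter)."""
        keep = self.variants.index[self.variants["maf"] >= min_maf]
        return VariantSet(self.variants.loc[keep], self.dosages[keep])

    def subset(self, variant_ids) -> "VariantSet":
        ids = pd.Index(variant_ids)
        return VariantSet(self.variants.loc[ids], self.dosages[ids])


@dataclass
class PhenotypeTable:
    """Quantifications of molecular phenotypes (genes and TE loci).

    ``features`` is indexed by ``feature_id`` with columns ``chrom``,
    ``start``/``end`` (0-based half-open), ``strand`` ('+'/'-') and
    ``feature_class`` ('gene' or 'TE:<subfamily>').  ``values`` is the
    samples x features matrix; ``stage`` tags where in the pipeline the
    values sit and may only move forward (counts -> cpm -> residual ->
    ranknorm).
    """

    features: pd.DataFrame
    values: pd.DataFrame
    stage: str = "counts"

    def __post_init__(self) -> None:
        if self.stage not in PHENOTYPE_STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if not self.features.index.equals(pd.Index(self.values.columns)):
            raise ValueError("feature ids in `features` and `values` differ")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def tss(self) -> pd.Series:
        """1-based transcription start site, strand-aware.

        For '+' features the TSS is ``start + 1`` (first covered base in
        1-based coordinates); for '-' features it is ``end``.
        """
        plus = self.features["strand"] == "+"
        return pd.Series(
            np.where(plus, self.features["start"] + 1, self.features["end"]),
            index=self.features.index,
            name="tss",
        )

    def with_values(self, values: pd.DataFrame, stage: str) -> "PhenotypeTable":
        """Return a copy at a later pipeline stage; stage may not move back."""
        if PHENOTYPE_STAGES.index(stage) < PHENOTYPE_STAGES.index(self.stage):
            raise ValueError(
                f"stage may only advance ({self.stage!r} -> {stage!r} is backwards)"
            )
        return PhenotypeTable(self.features.loc[values.columns], values, stage)

    def subset(self, feature_ids) -> "PhenotypeTable":
        ids = pd.Index(feature_ids)
        return PhenotypeTable(self.features.loc[ids], self.values[ids], self.stage)

    def is_te(self) -> pd.Series:
        return self.features["feature_class"].str.startswith("TE")


@dataclass
class CohortDesign:
    """Paired normal/tumor design: one sample per tissue per patient."""

    table: pd.DataFrame  # columns: patient_id, normal_sample_id, tumor_sample_id

    def __post_init__(self) -> None:
        required = {"patient_id", "normal_sample_id", "tumor_sample_id"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        for col in required:
            if self.table[col].duplicated().any():
                raise ValueError(f"duplicate entries in design column {col!r}")

    @property
    def patients(self) -> pd.Index:
        return pd.Index(self.table["patient_id"])

    @property
    def normal_samples(self) -> pd.Index:
        return pd.Index(self.table["normal_sample_id"])

    @property
    def tumor_samples(self) -> pd.Index:
        return pd.Index(self.table["tumor_sample_id"])

    @property
    def n_patients(self) -> int:
        return len(self.table)

    @classmethod
    def simple(cls, n_patients: int) -> "CohortDesign":
        """Default design with ids P000../N000../T000.."""
        ids = [f"P{i:04d}" for i in range(n_patients)]
        return cls(
            pd.DataFrame(
                {
                    "patient_id": ids,
                    "normal_sample_id": [f"N{i:04d}" for i in range(n_patients)],
                    "tumor_sample_id": [f"T{i:04d}" for i in range(n_patients)],
                }
            )
        )


TOPOLOGIES = ("causal", "reactive", "independent")
TISSUE_SCOPES = ("normal_only", "tumor_only", "shared")


@dataclass
class TruthTable:
    """Ground truth for synthetic cohorts.

    ``effects`` rows: phenotype_id, variant_id, scope (normal_only |
    tumor_only | shared), slope.  ``triplets`` rows: variant_id, te_id,
    gene_id, topology (causal | reactive | independent), slope_a, slope_b,
    noise_sd.
    """

    effects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["phenotype_id", "variant_id", "scope", "slope"]
        )
    )
    triplets: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=[
                "variant_id",
                "te_id",
                "gene_id",
                "topology",
                "slope_a",
                "slope_b",
                "noise_sd",
            ]
        )
    )

    def __post_init__(self) -> None:
        bad = set(self.effects["scope"]) - set(TISSUE_SCOPES)
        if bad:
            raise ValueError(f"unknown tissue scopes: {sorted(bad)}")
        bad = set(self.triplets["topology"]) - set(TOPOLOGIES)
        if bad:
            raise ValueError(f"unknown topologies: {sorted(bad)}")

    def validate_against(self, variant_ids, phenotype_ids) -> None:
        """Raise listing offenders if any planted effect references unknown ids."""
        vids = set(variant_ids)
        pids = set(phenotype_ids)
        offenders = []
        for _, row in self.effects.iterrows():
            if row["variant_id"] not in vids:
                offenders.append(f"effect variant {row['variant_id']}")
            if row["phenotype_id"] not in pids:
                offenders.append(f"effect phenotype {row['phenotype_id']}")
        for _, row in self.triplets.iterrows():
            if row["variant_id"] not in vids:
                offenders.append(f"triplet variant {row['variant_id']}")
        if offenders:
            raise ValueError(
                "truth table references unknown ids: " + ", ".join(sorted(set(offenders)))
            )
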
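"""Transpochimeric gene transcripts (TcGTs): TE-initiated transcripts
splicing into annotated genes.

A TcGT is evidence of a TE acting as an alternative promoter: a
transcript whose TSS lies inside a TE, whose first exon does not overlap
any annotated gene exon, and which splices into at least one annotated
gene exon downstream.  Per-sample candidates are aggregated by
single-linkage clustering of their TSS (100 bp link distance) within
each target gene, and tumor-vs-normal abundance of each cluster is
tested with a one-sided Fisher exact test.

Coordinates: transcript/exon inputs follow GTF (1-based, inclusive);
TE intervals follow BED (0-based, half-open) and are converted on load.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "read_transcripts_gtf",
    "call_tcgts",
    "aggregate_tcgts",
    "test_tcgts",
]


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for field in attr.strip().strip(";").split(";"):
        field = field.strip()
        if not field:
            continue
        key, _, val = field.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_transcripts_gtf(path_or_buffer) -> pd.DataFrame:
    """Load exon records from a GTF into a flat frame.

    Returns columns transcript_id, gene_id (if annotated), chrom, start,
    end (1-based inclusive), strand — one row per exon.  Transcripts
    without exon records are dropped.
    """
    df = pd.read_csv(
        path_or_buffer,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "source", "feature", "start", "end", "score", "strand", "frame", "attributes"],
        dtype={"chrom": str},
    )
    exons = df.loc[df["feature"] == "exon"].copy()
    attrs = exons["attributes"].map(_parse_gtf_attributes)
    exons["transcript_id"] = attrs.map(lambda a: a.get("transcript_id", ""))
    exons["gene_id"] = attrs.map(lambda a: a.get("gene_id", ""))
    return exons[["transcript_id", "gene_id", "chrom", "start", "end", "strand"]].reset_index(
        drop=True
    )


def _trees(frame: pd.DataFrame, id_col: str, bed: bool) -> dict[tuple[str, str], IntervalTree]:
    """Per-(chrom, strand) interval trees; '.' strand entries go to both strands.

    Tree intervals are half-open on 1-based coordinates: a GTF record
    [start, end] becomes [start, end + 1); a BED record [start, end)
    becomes [start + 1, end + 1).
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for _, row in frame.iterrows():
        if bed:
            lo, hi = int(row["start"]) + 1, int(row["end"]) + 1
        else:
            lo, hi = int(row["start"]), int(row["end"]) + 1
        if lo >= hi:
            raise ValueError(f"malformed interval for {row[id_col]!r}")
        strands = [row["strand"]] if row.get("strand", ".") in ("+", "-") else ["+", "-"]
        for s in strands:
            trees.setdefault((row["chrom"], s), IntervalTree()).addi(lo, hi, row[id_col])
    return trees


def call_tcgts(
    sample_transcripts: pd.DataFrame,
    gene_exons: pd.DataFrame,
    te_intervals: pd.DataFrame,
    same_strand: bool = True,
) -> pd.DataFrame:
    """Screen one sample's transcript models for TcGT candidates.

    ``sample_transcripts``: exon frame as from :func:`read_transcripts_gtf`.
    ``gene_exons``: annotated exons (gene_id, chrom, start, end, strand;
    GTF coordinates).  ``te_intervals``: TE loci (te_id, chrom, start,
    end[, strand]; BED coordinates).

    A transcript is kept when its strand-aware TSS overlaps a TE, its
    first exon overlaps no annotated gene exon, and at least one later
    exon overlaps an annotated exon (same strand by default).  Emits one
    row per (transcript, spliced-into gene): te_id, gene_id, tss, strand.
    """
    gene_trees = _trees(gene_exons, "gene_id", bed=False)
    te_trees = _trees(te_intervals, "te_id", bed=True)

    rows = []
    for tid, grp in sample_transcripts.groupby("transcript_id", sort=False):
        if grp.empty:
            continue
        strand = grp["strand"].iloc[0]
        chrom = grp["chrom"].iloc[0]
        ordered = grp.sort_values("start", ascending=(strand != "-"))
        first = ordered.iloc[0]
        tss = int(first["start"]) if strand != "-" else int(first["end"])

        te_hits = te_trees.get((chrom, strand), IntervalTree())[tss]
        if not te_hits:
            continue
        te_id = sorted(iv.data for iv in te_hits)[0]

        # first-exon filter is strand-agnostic: starting inside any annotated
        # gene exon disqualifies the transcript
        all_trees = [gene_trees.get((chrom, s), IntervalTree()) for s in ("+", "-")]
        if any(gt.overlap(int(first["start"]), int(first["end"]) + 1) for gt in all_trees):
            continue

        splice_trees = (
            [gene_trees.get((chrom, strand), IntervalTree())] if same_strand else all_trees
        )
        target_genes = set()
        for _, exon in ordered.iloc[1:].iterrows():
            for gt in splice_trees:
                for iv in gt.overlap(int(exon["start"]), int(exon["end"]) + 1):
                    target_genes.add(iv.data)
        for gid in sorted(target_genes):
            rows.append(
                {"transcript_id": tid, "te_id": te_id, "gene_id": gid, "tss": tss, "strand": strand}
            )
    return pd.DataFrame(rows, columns=["transcript_id", "te_id", "gene_id", "tss", "strand"])


def aggregate_tcgts(candidates: pd.DataFrame, radius: int = 100) -> pd.DataFrame:
    """Cluster per-sample TcGT candidates by TSS proximity within each gene.

    ``candidates`` needs sample_id, group ('normal'|'tumor'), gene_id,
    te_id and tss.  Single-linkage: sorted TSSs chain into one cluster
    while consecutive gaps are <= ``radius`` (inclusive), so a chain
    1000, 1100, 1200 forms a single cluster at radius 100.  Output: one
    row per cluster with the member TSS span, a representative TSS
    (median), the modal TE, and distinct-sample counts per group.
    """
    if candidates.empty:
        return pd.DataFrame(
            columns=["gene_id", "te_id", "tss", "tss_min", "tss_max", "count_normal", "count_tumor"]
        )
    rows = []
    for gid, grp in candidates.groupby("gene_id", sort=False):
        grp = grp.sort_values(["tss", "sample_id"], kind="mergesort")
        tss = grp["tss"].to_numpy()
        breaks = np.flatnonzero(np.diff(tss) > radius)
        cluster_id = np.zeros(len(grp), dtype=int)
        for b in breaks:
            cluster_id[b + 1 :] += 1
        grp = grp.assign(_cluster=cluster_id)
        for _, cl in grp.groupby("_cluster"):
            rows.append(
                {
                    "gene_id": gid,
                    "te_id": cl["te_id"].mode().iloc[0],
                    "tss": int(np.median(cl["tss"])),
                    "tss_min": int(cl["tss"].min()),
                    "tss_max": int(cl["tss"].max()),
                    "count_normal": cl.loc[cl["group"] == "normal", "sample_id"].nunique(),
                    "count_tumor": cl.loc[cl["group"] == "tumor", "sample_id"].nunique(),
                }
            )
    return pd.DataFrame(rows).sort_values(["gene_id", "tss"]).reset_index(drop=True)


def test_tcgts(
    clusters: pd.DataFrame,
    n_normal: int,
    n_tumor: int,
    triplet_pairs: set[tuple[str, str]] | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Tumor-enrichment test per TcGT cluster.

    One-sided Fisher exact test (tumor more abundant) on the 2x2 of
    samples with/without the event by group, BH-corrected at ``fdr``.
    When ``triplet_pairs`` is given, clusters whose (te_id, gene_id) is
    not among them are removed before testing.
    """
    if n_normal < 1 or n_tumor < 1:
        raise ValueError("group sizes must be >= 1")
    cl = clusters.copy()
    if triplet_pairs is not None:
        keep = [
            (te, g) in triplet_pairs for te, g in zip(cl["te_id"], cl["gene_id"])
        ]
        cl = cl.loc[keep].reset_index(drop=True)
    if cl.empty:
        cl["fisher_p"] = pd.Series(dtype=float)
        cl["adj_p"] = pd.Series(dtype=float)
        cl["significant"] = pd.Series(dtype=bool)
        return cl
    bad = (cl["count_normal"] > n_normal) | (cl["count_tumor"] > n_tumor)
    if bad.any():
        raise ValueError(
            f"cluster counts exceed group sizes for rows {cl.index[bad].tolist()}"
        )
    pvals = np.empty(len(cl))
    for i, row in cl.iterrows():
        table = [
            [int(row["count_tumor"]), n_tumor - int(row["count_tumor"])],
            [int(row["count_normal"]), n_normal - int(row["count_normal"])],
        ]
        pvals[i] = stats.fisher_exact(table, alternative="greater")[1]
    cl["fisher_p"] = pvals
    reject, adj, *_ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    cl["adj_p"] = adj
    cl["significant"] = reject
    return cl
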
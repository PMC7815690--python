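"""Detection-evidence consensus filtering, breadth filtering, and
circRNA annotation (region class, isoform labels, CircClust loci).

The filtering funnel: a circRNA is *detected* when at least two
backsplice detection methods report it and its consensus raw count
reaches five reads in at least one sample; it is *kept* when expressed
in at least half the samples of a condition (JMML or HD) or in more
than three quarters of the samples of one JMML molecular subtype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from circlin.iokit import (
    CircRNA,
    Config,
    GenomicInterval,
    SampleSheet,
    ValidationError,
    log_filter,
    logger,
    parse_circ_id,
)


@dataclass
class AnnotationIndex:
    """Exon/gene annotation lookup.

    Built from an exon table (gene_id, transcript_id, exon_number,
    chrom, start, end, strand; 0-based half-open). Exon numbering for
    isoform labels follows the longest transcript of each gene (total
    exonic length, ties broken by transcript_id).
    """

    exons: pd.DataFrame
    genes: pd.DataFrame            # gene_id -> chrom, start, end, strand
    longest_tx: dict               # gene_id -> transcript_id

    @classmethod
    def from_exon_table(cls, exons: pd.DataFrame) -> "AnnotationIndex":
        exons = exons.copy()
        exons["length"] = exons["end"] - exons["start"]
        if (exons["length"] <= 0).any():
            raise ValidationError("annotation contains empty/inverted exons")
        genes = exons.groupby("gene_id").agg(
            chrom=("chrom", "first"),
            start=("start", "min"),
            end=("end", "max"),
            strand=("strand", "first"),
        )
        tx_len = exons.groupby(["gene_id", "transcript_id"])["length"].sum()
        longest = {}
        for gene, sub in tx_len.groupby(level=0):
            sub = sub.droplevel(0).sort_values(ascending=False)
            top = sub.max()
            longest[gene] = sorted(sub.index[sub == top])[0]
        for (gene, tx), sub in exons.groupby(["gene_id", "transcript_id"]):
            nums = sorted(sub["exon_number"].astype(int))
            if nums != list(range(nums[0], nums[0] + len(nums))):
                raise ValidationError(
                    f"non-contiguous exon numbers for {gene}/{tx}: {nums}"
                )
        return cls(exons=exons, genes=genes, longest_tx=longest)


# ---------------------------------------------------------------------------
# consensus detection
# ---------------------------------------------------------------------------


def _consensus_value(values: np.ndarray, stat: str) -> int:
    if stat == "min":
        v = float(np.min(values))
    elif stat == "max":
        v = float(np.max(values))
    elif stat == "median":
        v = float(np.median(values))
    else:
        raise ValueError(f"unknown consensus statistic {stat!r}")
    return math.ceil(v - 0.5)     # round halves down (median of {5,7} -> 6)


def consensus_detect(
    evidence: pd.DataFrame, cfg: Config | None = None
) -> tuple[set[str], pd.DataFrame]:
    """Apply the multi-method consensus rule to a detection table.

    ``evidence`` needs columns circ_id, method, sample, reads. A
    circRNA is detected iff reported by >= ``cfg.min_methods`` distinct
    methods and its per-sample consensus count (median over reporting
    methods, halves rounded down) reaches ``cfg.min_reads`` in at least
    one sample. With ``cfg.strict_same_sample`` both conditions must
    hold within a single sample. Returns (detected ids, consensus
    count matrix over all evidenced circRNAs x samples).
    """
    cfg = cfg or Config()
    if evidence.empty:
        return set(), pd.DataFrame()
    ev = evidence[evidence["reads"] > 0]
    cons = (
        ev.groupby(["circ_id", "sample"])["reads"]
        .apply(lambda v: _consensus_value(v.to_numpy(), cfg.consensus_stat))
        .unstack(fill_value=0)
    )
    n_methods_per_cell = ev.groupby(["circ_id", "sample"])["method"].nunique().unstack(fill_value=0)
    detected: set[str] = set()
    if cfg.strict_same_sample:
        ok = (n_methods_per_cell >= cfg.min_methods) & (cons >= cfg.min_reads)
        detected = set(ok.index[ok.any(axis=1)])
    else:
        methods_global = ev.groupby("circ_id")["method"].nunique()
        max_cons = cons.max(axis=1)
        keep = (methods_global.reindex(cons.index) >= cfg.min_methods) & (
            max_cons >= cfg.min_reads
        )
        detected = set(keep.index[keep])
    log_filter(
        "consensus_detect",
        cons.shape[0],
        len(detected),
        f">={cfg.min_methods} methods & consensus >={cfg.min_reads} reads"
        f" ({'same sample' if cfg.strict_same_sample else 'any sample'})",
    )
    return detected, cons


def breadth_filter(
    matrix: pd.DataFrame, samples: SampleSheet, cfg: Config | None = None
) -> set[str]:
    """Expression-breadth rule on a consensus count matrix.

    "Expressed in a sample" means consensus count >= 1. Keep a circRNA
    iff expressed in >= ceil(n/2) samples of JMML or of HD, or in
    strictly more than 3/4 of the samples of at least one JMML subtype.
    """
    cfg = cfg or Config()
    if matrix.empty:
        return set()
    expressed = matrix >= 1
    keep = pd.Series(False, index=matrix.index)
    for cond in ("JMML", "HD"):
        ids = [s for s in samples.condition_samples(cond) if s in matrix.columns]
        if not ids:
            logger.warning("breadth_filter: no %s samples in matrix", cond)
            continue
        quorum = math.ceil(len(ids) * cfg.breadth_condition)
        keep |= expressed[ids].sum(axis=1) >= quorum
    for subtype in samples.subtypes_present:
        ids = [s for s in samples.subtype_samples(subtype) if s in matrix.columns]
        if not ids:
            logger.warning("breadth_filter: subtype %s has no samples", subtype)
            continue
        keep |= expressed[ids].sum(axis=1) > cfg.breadth_subgroup * len(ids)
    kept = set(matrix.index[keep])
    log_filter(
        "breadth_filter",
        matrix.shape[0],
        len(kept),
        f">= {cfg.breadth_condition} of a condition or > {cfg.breadth_subgroup} of a subtype",
    )
    return kept


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def _exon_span_label(interval: GenomicInterval, gene: str, ann: AnnotationIndex) -> str:
    """Exon-number span on the gene's longest transcript, e.g. '9-12'."""
    tx = ann.longest_tx[gene]
    ex = ann.exons[
        (ann.exons["gene_id"] == gene) & (ann.exons["transcript_id"] == tx)
    ]
    hit = ex[(ex["end"] > interval.start) & (ex["start"] < interval.end)]
    if hit.empty:
        return ""
    lo, hi = int(hit["exon_number"].min()), int(hit["exon_number"].max())
    return str(lo) if lo == hi else f"{lo}-{hi}"


def _end_in_exon(pos_start: int, pos_end: int, gene_exons: pd.DataFrame) -> bool:
    """True when the 1-nt backsplice end [pos_start, pos_end) lies in an exon."""
    return bool(
        ((gene_exons["start"] <= pos_start) & (gene_exons["end"] >= pos_end)).any()
    )


def annotate_circrnas(
    circ_ids: list[str],
    annotation: AnnotationIndex,
    cfg: Config | None = None,
) -> list[CircRNA]:
    """Assign region class, host genes, isoform labels and loci.

    Exonic: both backsplice ends fall within exons (of one gene, or of
    two genes for read-through circRNAs, in which case the locus is the
    gene containing the 5' end). Intronic: inside a gene body but not
    exonic at both ends. Intergenic: outside genes; clustered into
    CircClust pseudo-loci by single linkage with gap <= ``clust_gap``.
    A circ whose unique host gene is on the opposite strand is flagged
    (logged), not dropped.
    """
    cfg = cfg or Config()
    genes = annotation.genes
    out: list[CircRNA] = []
    intergenic: list[tuple[GenomicInterval, int]] = []
    for idx, cid in enumerate(circ_ids):
        iv = parse_circ_id(cid)
        overl = genes[
            (genes["chrom"] == iv.chrom)
            & (genes["start"] < iv.end)
            & (genes["end"] > iv.start)
        ]
        if overl.empty:
            out.append(None)
            intergenic.append((iv, idx))
            continue
        host_5p, host_3p = None, None
        for gene, row in overl.iterrows():
            g_ex = annotation.exons[annotation.exons["gene_id"] == gene]
            if _end_in_exon(iv.start, iv.start + 1, g_ex):
                host_5p = host_5p or gene
            if _end_in_exon(iv.end - 1, iv.end, g_ex):
                host_3p = host_3p or gene
        if host_5p is not None and host_3p is not None:
            hosts = [host_5p] + ([host_3p] if host_3p != host_5p else [])
            locus = host_5p
            label = _exon_span_label(iv, locus, annotation)
            circ = CircRNA(iv, hosts, "exonic", locus, label)
        else:
            gene = overl.index[0]
            circ = CircRNA(iv, [gene], "intronic", gene, "")
        host_strand = genes.loc[circ.locus_id, "strand"]
        if len(circ.host_genes) == 1 and iv.strand not in (".", host_strand):
            logger.warning(
                "strand mismatch: %s is %s but host %s is %s",
                cid, iv.strand, circ.locus_id, host_strand,
            )
        out.append(circ)

    # CircClust: single-linkage clustering of intergenic circRNAs per chromosome
    clusters = _circclust(
        [iv for iv, _ in intergenic], gap=cfg.clust_gap
    )
    for (iv, idx), cluster_id in zip(intergenic, clusters):
        out[idx] = CircRNA(iv, [], "intergenic", f"CircClust{cluster_id:04d}", "")
    return out


def _circclust(intervals: list[GenomicInterval], gap: int) -> list[int]:
    """Order-invariant single-linkage clustering with inter-interval
    distance <= ``gap``; returns a cluster id per input interval.

    Cluster ids are numbered by (chrom, leftmost start) so shuffling
    the input yields identical assignments.
    """
    order = sorted(range(len(intervals)), key=lambda i: (intervals[i].chrom, intervals[i].start, intervals[i].end))
    cluster_of = [0] * len(intervals)
    cluster_id = 0
    prev_chrom, prev_end = None, None
    for i in order:
        iv = intervals[i]
        if prev_chrom != iv.chrom or iv.start - prev_end > gap:
            cluster_id += 1
            prev_end = iv.end
        else:
            prev_end = max(prev_end, iv.end)
        prev_chrom = iv.chrom
        cluster_of[i] = cluster_id
    return cluster_of


def summarize_loci(circs: list[CircRNA]) -> tuple[pd.DataFrame, dict]:
    """Per-locus isoform counts and global region-class proportions."""
    if not circs:
        return pd.DataFrame(columns=["locus_id", "n_isoforms", "region_class"]), {}
    rows = pd.DataFrame(
        {
            "locus_id": [c.locus_id for c in circs],
            "region_class": [c.region_class for c in circs],
        }
    )
    per_locus = (
        rows.groupby("locus_id")
        .agg(n_isoforms=("locus_id", "size"), region_class=("region_class", "first"))
        .reset_index()
    )
    total = len(circs)
    props = {
        cls: (rows["region_class"] == cls).sum() / total
        for cls in ("exonic", "intronic", "intergenic")
    }
    props["n_loci"] = len(per_locus)
    props["frac_multi_isoform_loci"] = float(
        (per_locus["n_isoforms"] > 1).mean()
    ) if len(per_locus) else 0.0
    return per_locus, props
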
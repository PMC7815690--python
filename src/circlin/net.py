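"""circRNA-miRNA-gene network reconstruction.

Combines two families of binding-site predictions (an alignment-based
predictor with score/free-energy thresholds, miRanda-style, and a
thermodynamic predictor with duplex/opening energies, PITA-style),
keeps only miRNAs whose sites are commonly predicted (positional
overlap of sites from both predictors), prioritizes miRNAs by
expression in a reference patient series (or, for miRNAs absent from
it, by requiring at least three common sites on the same circRNA),
attaches experimentally validated miRNA-target edges (strong evidence
categories), restricts to genes expressed in JMML (mean TPM > 1), and
annotates genes whose expression tracks the circRNA (Spearman rho).

Thresholds (defaults in :class:`~circlin.iokit.Config`): predictor-A
sites need score >= 100 and energy <= -20 kcal/mol; predictor-B sites
need dG_duplex < -20 and dG_open > -13 kcal/mol. Boundary semantics
are deliberate and tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from circlin.iokit import (
    CircRNA,
    Config,
    SampleSheet,
    ValidationError,
    log_filter,
    logger,
)
from circlin.circdetect import AnnotationIndex
from circlin.simdata import revcomp_rna

SITE_COLUMNS = ["circ_id", "mirna_id", "predictor", "start", "end"]


@dataclass
class CircSequence:
    """Assembled circRNA sequence with a pseudo-circular extension.

    ``sequence`` includes the first ``extension`` nucleotides appended
    at the end so junction-spanning binding sites are findable;
    ``core_length`` is the length without the extension.
    """

    circ_id: str
    sequence: str
    core_length: int
    extension: int

    def __post_init__(self) -> None:
        if self.core_length <= 0:
            raise ValidationError("empty circRNA sequence")
        if self.extension >= self.core_length:
            raise ValidationError("extension must be shorter than the sequence")


# ---------------------------------------------------------------------------
# sequence assembly and the toy scanner
# ---------------------------------------------------------------------------

_DNA2RNA = str.maketrans("ACGTacgt", "ACGUACGU")


def assemble_circ_sequence(
    circ: CircRNA,
    annotation: AnnotationIndex,
    genome: dict[str, str],
    cfg: Config | None = None,
) -> CircSequence:
    """Join annotated exons within the backsplice span (5'->3').

    Exons of the host gene's longest transcript overlapping the span
    are concatenated in genomic order and reverse-complemented for
    minus-strand circRNAs; the first (max_site_len - 1) nt are
    appended so sites spanning the backsplice junction can be found.
    """
    cfg = cfg or Config()
    if not circ.host_genes:
        raise ValueError("sequence assembly needs an exonic circRNA")
    gene = circ.locus_id
    tx = annotation.longest_tx[gene]
    ex = annotation.exons[
        (annotation.exons["gene_id"] == gene)
        & (annotation.exons["transcript_id"] == tx)
    ].sort_values("start")
    iv = circ.interval
    hit = ex[(ex["end"] > iv.start) & (ex["start"] < iv.end)]
    if hit.empty:
        raise ValidationError(f"no exons within the backsplice span of {circ.circ_id}")
    chrom_seq = genome[iv.chrom]
    parts = []
    for _, r in hit.iterrows():
        s, e = max(int(r.start), iv.start), min(int(r.end), iv.end)
        if e > len(chrom_seq):
            raise ValidationError(f"exon outside genome bounds for {circ.circ_id}")
        parts.append(chrom_seq[s:e])
    seq = "".join(parts).translate(_DNA2RNA)
    if iv.strand == "-":
        seq = revcomp_rna(seq)
    ext = min(cfg.max_site_len - 1, len(seq) - 1)
    return CircSequence(circ.circ_id, seq + seq[:ext], len(seq), ext)


def toy_seed_scan(
    circ_seq: CircSequence | str,
    mirna_seqs: dict[str, str],
    cfg: Config | None = None,
    predictor: str = "A",
) -> pd.DataFrame:
    """Exact seed-complement scanner for fixture generation.

    Reports every position where the reverse complement of miRNA
    nucleotides 2-8 (the 7-mer seed) occurs in the circRNA sequence,
    with deterministic pseudo-scores/energies derived from the local
    GC content so fixtures can straddle the predictor thresholds.
    Not a binding-site predictor: a stand-in used by tests.
    """
    cfg = cfg or Config()
    if isinstance(circ_seq, CircSequence):
        seq, cid = circ_seq.sequence, circ_seq.circ_id
    else:
        seq, cid = circ_seq, "circ"
    if set(seq) - set("ACGU"):
        raise ValidationError("circRNA sequence must be RNA (ACGU)")
    rows = []
    for mir, mseq in mirna_seqs.items():
        if set(mseq) - set("ACGU"):
            raise ValidationError(f"miRNA {mir} sequence must be RNA (ACGU)")
        probe = revcomp_rna(mseq[1:8])
        start = seq.find(probe)
        while start != -1:
            end = start + len(probe)
            gc = (seq[start:end].count("G") + seq[start:end].count("C")) / len(probe)
            if predictor == "A":
                rows.append((cid, mir, "A", start, end, 100.0 + 100.0 * gc,
                             -15.0 - 20.0 * gc, np.nan, np.nan))
            else:
                rows.append((cid, mir, "B", start, end, np.nan, np.nan,
                             -15.0 - 20.0 * gc, -20.0 + 20.0 * gc))
            start = seq.find(probe, start + 1)
    return pd.DataFrame(
        rows,
        columns=SITE_COLUMNS + ["score", "energy", "dg_duplex", "dg_open"],
    )


# ---------------------------------------------------------------------------
# threshold filtering and predictor intersection
# ---------------------------------------------------------------------------


def filter_sites(sites: pd.DataFrame, cfg: Config | None = None) -> pd.DataFrame:
    """Apply predictor-specific thresholds.

    Predictor A: score >= miranda_score AND energy <= miranda_energy.
    Predictor B: dg_duplex < pita_dduplex AND dg_open > pita_dopen.
    """
    cfg = cfg or Config()
    if sites.empty:
        return sites.copy()
    missing = [c for c in SITE_COLUMNS if c not in sites.columns]
    if missing:
        raise ValidationError(f"site table missing column(s) {missing}")
    is_a = sites["predictor"] == "A"
    is_b = sites["predictor"] == "B"
    if is_a.any() and sites.loc[is_a, ["score", "energy"]].isna().any().any():
        raise ValidationError("predictor-A sites need score and energy")
    if is_b.any() and sites.loc[is_b, ["dg_duplex", "dg_open"]].isna().any().any():
        raise ValidationError("predictor-B sites need dg_duplex and dg_open")
    keep_a = is_a & (sites["score"] >= cfg.miranda_score) & (
        sites["energy"] <= cfg.miranda_energy
    )
    keep_b = is_b & (sites["dg_duplex"] < cfg.pita_dduplex) & (
        sites["dg_open"] > cfg.pita_dopen
    )
    out = sites[keep_a | keep_b].copy()
    log_filter(
        "filter_sites", len(sites), len(out),
        f"A: score>={cfg.miranda_score} & E<={cfg.miranda_energy}; "
        f"B: dGdup<{cfg.pita_dduplex} & dGopen>{cfg.pita_dopen}",
    )
    return out


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(ivs):
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


def intersect_predictors(
    sites_a: pd.DataFrame,
    sites_b: pd.DataFrame,
    cfg: Config | None = None,
) -> pd.DataFrame:
    """Common binding sites: A-sites overlapping a B-site of the same
    (circRNA, miRNA) pair by >= 1 nt.

    n_sites counts merged clusters of overlapping common A-sites so
    staggered predictions are not double counted. With
    ``cfg.common_mode == 'mirna_only'`` semantics, pass pre-agreed
    pairs instead; the default is site-level overlap.
    """
    cfg = cfg or Config()
    if sites_a.empty or sites_b.empty:
        return pd.DataFrame(columns=["circ_id", "mirna_id", "n_sites"])
    b_groups = {
        key: list(zip(sub["start"], sub["end"]))
        for key, sub in sites_b.groupby(["circ_id", "mirna_id"])
    }
    rows = []
    for key, sub in sites_a.groupby(["circ_id", "mirna_id"]):
        b_ivs = b_groups.get(key)
        if not b_ivs:
            continue
        common = [
            (s, e)
            for s, e in zip(sub["start"], sub["end"])
            if any(s < be and bs < e for bs, be in b_ivs)
        ]
        if common:
            rows.append((*key, len(_merge_intervals(common))))
    out = pd.DataFrame(rows, columns=["circ_id", "mirna_id", "n_sites"])
    log_filter(
        "intersect_predictors",
        sites_a.groupby(["circ_id", "mirna_id"]).ngroups,
        len(out),
        ">= 1 nt overlap between predictor A and B sites",
    )
    return out


def prioritize_mirnas(
    pairs: pd.DataFrame,
    mirna_expr: pd.DataFrame,
    cfg: Config | None = None,
) -> pd.DataFrame:
    """Keep pairs whose miRNA is expressed in the reference series, or
    absent from it but supported by >= min_sites_unquantified common
    sites on the same circRNA.

    "Expressed" means nonzero counts in at least ``mirna_expr_frac``
    of the reference samples.
    """
    cfg = cfg or Config()
    if pairs.empty:
        return pairs.copy()
    frac_nonzero = (mirna_expr > 0).mean(axis=1)
    expressed = set(frac_nonzero.index[frac_nonzero >= cfg.mirna_expr_frac])
    in_table = pairs["mirna_id"].isin(mirna_expr.index)
    keep = pairs["mirna_id"].isin(expressed) | (
        ~in_table & (pairs["n_sites"] >= cfg.min_sites_unquantified)
    )
    out = pairs[keep].copy()
    out["expressed_in_reference"] = out["mirna_id"].isin(expressed)
    log_filter(
        "prioritize_mirnas", len(pairs), len(out),
        f"expressed in reference, or absent with >= {cfg.min_sites_unquantified} sites",
    )
    return out


def attach_validated_targets(
    mirnas: pd.Series | list[str],
    target_table: pd.DataFrame,
    cfg: Config | None = None,
) -> pd.DataFrame:
    """Strong-evidence validated miRNA-target edges for the given miRNAs.

    Rows with categories outside the known strong/weak label space are
    dropped with a warning; weak-evidence rows are dropped silently.
    """
    cfg = cfg or Config()
    mirnas = set(mirnas)
    sub = target_table[target_table["mirna_id"].isin(mirnas)].copy()
    known_weak = {f"{c} (Weak)" for c in cfg.strong_categories} | {"Non-Functional MTI"}
    unknown = ~sub["category"].isin(set(cfg.strong_categories) | known_weak)
    if unknown.any():
        logger.warning(
            "attach_validated_targets: dropping %d rows with unknown categories %s",
            unknown.sum(), sorted(sub.loc[unknown, "category"].unique()),
        )
        sub = sub[~unknown]
    out = sub[sub["category"].isin(cfg.strong_categories)].reset_index(drop=True)
    log_filter(
        "attach_validated_targets", len(target_table), len(out),
        f"category in {cfg.strong_categories}",
    )
    return out


def filter_expressed_genes(
    edges: pd.DataFrame,
    tpm: pd.DataFrame,
    samples: SampleSheet,
    cfg: Config | None = None,
    gene_lfc: pd.Series | None = None,
) -> pd.DataFrame:
    """Keep miRNA-gene edges whose gene is expressed in JMML.

    Expressed: mean TPM over JMML samples strictly greater than
    ``tpm_min``. Genes missing from the TPM matrix count as not
    expressed (logged). Attaches mean_tpm_jmml and, when available,
    the gene's JMML-vs-HD LFC.
    """
    cfg = cfg or Config()
    jmml = [s for s in samples.condition_samples("JMML") if s in tpm.columns]
    mean_tpm = tpm[jmml].mean(axis=1)
    out = edges.copy()
    missing = ~out["gene_id"].isin(tpm.index)
    if missing.any():
        logger.info(
            "filter_expressed_genes: %d gene(s) absent from TPM matrix: %s",
            missing.sum(), sorted(out.loc[missing, "gene_id"].unique())[:5],
        )
    out["mean_tpm_jmml"] = out["gene_id"].map(mean_tpm)
    out = out[out["mean_tpm_jmml"] > cfg.tpm_min].copy()
    if gene_lfc is not None:
        out["gene_lfc"] = out["gene_id"].map(gene_lfc)
    log_filter(
        "filter_expressed_genes", len(edges), len(out), f"mean JMML TPM > {cfg.tpm_min}"
    )
    return out


def correlate_with_circ(
    circ_expr: pd.Series,
    gene_expr: pd.DataFrame,
    samples: SampleSheet,
    cfg: Config | None = None,
) -> pd.DataFrame:
    """Spearman correlation of each gene with the circRNA, JMML only.

    Average ranks handle ties. Genes with a zero-variance profile (or
    a zero-variance circRNA) get a missing rho. Flags rho >= rho_min.
    """
    cfg = cfg or Config()
    jmml = [s for s in samples.condition_samples("JMML") if s in gene_expr.columns]
    if len(jmml) < 4:
        raise ValueError("need >= 4 JMML samples for correlation")
    x = circ_expr[jmml].to_numpy(float)
    rhos = {}
    for gene, row in gene_expr.loc[:, jmml].iterrows():
        y = row.to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            rhos[gene] = np.nan
            continue
        rhos[gene] = stats.spearmanr(x, y).statistic
    out = pd.DataFrame({"rho": pd.Series(rhos)})
    out["correlated"] = out["rho"] >= cfg.rho_min
    out.loc[out["rho"].isna(), "correlated"] = False
    out.index.name = "gene_id"
    return out


# ---------------------------------------------------------------------------
# graph assembly
# ---------------------------------------------------------------------------


def build_network(
    pairs: pd.DataFrame,
    target_edges: pd.DataFrame,
    correlations: pd.DataFrame | None = None,
    gene_lfc: pd.Series | None = None,
    only_upregulated_targets: bool = False,
) -> nx.DiGraph:
    """Assemble the tripartite circRNA-miRNA-gene graph.

    circRNA -> miRNA edges carry n_sites; miRNA -> gene edges carry
    the evidence category (and the gene node its LFC, mean TPM and
    correlation rho where supplied). ``only_upregulated_targets``
    restricts gene nodes to lfc > 0, the de-repression focus. No
    circ-gene edges exist; correlation is a gene-node annotation.
    """
    g = nx.DiGraph()
    for _, r in pairs.iterrows():
        g.add_node(r["circ_id"], kind="circRNA")
        g.add_node(
            r["mirna_id"],
            kind="miRNA",
            expressed_in_reference=bool(r.get("expressed_in_reference", False)),
        )
        g.add_edge(r["circ_id"], r["mirna_id"], n_sites=int(r["n_sites"]), interaction="binds")
    retained_mirnas = {n for n, d in g.nodes(data=True) if d["kind"] == "miRNA"}
    for _, r in target_edges.iterrows():
        if r["mirna_id"] not in retained_mirnas:
            continue
        lfc = None
        if gene_lfc is not None and r["gene_id"] in gene_lfc.index:
            lfc = float(gene_lfc[r["gene_id"]])
        elif "gene_lfc" in target_edges.columns and pd.notna(r.get("gene_lfc")):
            lfc = float(r["gene_lfc"])
        if only_upregulated_targets and (lfc is None or lfc <= 0):
            continue
        attrs = {"kind": "gene"}
        if lfc is not None:
            attrs["lfc"] = lfc
        if "mean_tpm_jmml" in target_edges.columns:
            attrs["mean_tpm_jmml"] = float(r["mean_tpm_jmml"])
        if correlations is not None and r["gene_id"] in correlations.index:
            rho = correlations.loc[r["gene_id"], "rho"]
            attrs["rho"] = float(rho) if pd.notna(rho) else None
            attrs["correlated"] = bool(correlations.loc[r["gene_id"], "correlated"])
        g.add_node(r["gene_id"], **attrs)
        g.add_edge(r["mirna_id"], r["gene_id"], category=r["category"], interaction="targets")
    return g


def reconstruct(
    sites_a: pd.DataFrame,
    sites_b: pd.DataFrame,
    mirna_expr: pd.DataFrame,
    target_table: pd.DataFrame,
    tpm: pd.DataFrame,
    samples: SampleSheet,
    circ_expr: pd.Series | None = None,
    gene_lfc: pd.Series | None = None,
    cfg: Config | None = None,
) -> tuple[nx.DiGraph, pd.DataFrame, pd.DataFrame]:
    """Full reconstruction pipeline; returns (graph, pairs, gene edges)."""
    cfg = cfg or Config()
    fa = filter_sites(sites_a, cfg)
    fb = filter_sites(sites_b, cfg)
    pairs = intersect_predictors(fa, fb, cfg)
    pairs = prioritize_mirnas(pairs, mirna_expr, cfg)
    edges = attach_validated_targets(pairs["mirna_id"], target_table, cfg)
    edges = filter_expressed_genes(edges, tpm, samples, cfg, gene_lfc)
    correlations = None
    if circ_expr is not None and not edges.empty:
        gene_rows = tpm.loc[tpm.index.intersection(edges["gene_id"].unique())]
        correlations = correlate_with_circ(circ_expr, gene_rows, samples, cfg)
    graph = build_network(pairs, edges, correlations, gene_lfc)
    return graph, pairs, edges
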
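"""Data model, readers/writers, configuration and logging.

All coordinates are 0-based half-open internally. BED export keeps that
convention; GTF-like export converts to 1-based inclusive. Tables are
TSV with a header row; gzip-compressed files are handled transparently
by pandas.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("circlin")

VALID_STRANDS = ("+", "-", ".")
CONDITIONS = ("JMML", "HD")
SUBTYPES = ("PTPN11", "KRAS", "NRAS", "NF1", "5N", "NA")
TISSUES = ("BM", "PB")
REGION_CLASSES = ("exonic", "intronic", "intergenic")


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Distance in nt between two intervals on one chromosome (0 if they overlap)."""
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        return max(0, max(self.start, other.start) - min(self.end, other.end))


def format_circ_id(interval: GenomicInterval, one_based: bool = False) -> str:
    """Canonical circRNA id ``chrom:start-end:strand``.

    ``one_based=True`` emits a display id with a 1-based inclusive start.
    """
    start = interval.start + 1 if one_based else interval.start
    return f"{interval.chrom}:{start}-{interval.end}:{interval.strand}"


def parse_circ_id(circ_id: str) -> GenomicInterval:
    """Parse a canonical ``chrom:start-end:strand`` id (0-based half-open)."""
    try:
        chrom, span, strand = circ_id.rsplit(":", 2)
        start_s, end_s = span.rsplit("-", 1)
        return GenomicInterval(chrom, int(start_s), int(end_s), strand)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"malformed circ_id {circ_id!r}") from exc


@dataclass
class CircRNA:
    """A backsplice-defined circRNA with annotation."""

    interval: GenomicInterval
    host_genes: list[str] = field(default_factory=list)
    region_class: str = "intergenic"
    locus_id: str = ""
    isoform_label: str = ""

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise ValidationError(f"unknown region class {self.region_class!r}")
        if self.region_class == "intergenic":
            if self.host_genes:
                raise ValidationError("intergenic circRNA cannot have host genes")
            if self.locus_id and not self.locus_id.startswith("CircClust"):
                raise ValidationError(
                    "intergenic locus_id must start with 'CircClust', got "
                    f"{self.locus_id!r}"
                )
        elif not self.host_genes:
            raise ValidationError(f"{self.region_class} circRNA requires host genes")

    @property
    def circ_id(self) -> str:
        return format_circ_id(self.interval)

    @property
    def name(self) -> str:
        """Display name: circ<HOST>(<exon span>) where annotated."""
        if not self.host_genes:
            return self.circ_id
        base = f"circ{self.host_genes[0]}"
        return f"{base}({self.isoform_label})" if self.isoform_label else base


class SampleSheet:
    """Validated sample metadata: condition, molecular subtype, tissue.

    Wraps a DataFrame indexed by ``sample_id`` with columns ``condition``
    (JMML/HD), ``subtype`` (PTPN11/KRAS/NRAS/NF1/5N/NA), ``tissue``
    (BM/PB) and optional ``batch``.
    """

    def __init__(self, frame: pd.DataFrame, allow_5n: bool = False):
        df = frame.copy()
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample_id(s): {dups}")
        for col in ("condition", "subtype", "tissue"):
            if col not in df.columns:
                raise FormatError(f"sample sheet missing column {col!r}")
        df["subtype"] = df["subtype"].fillna("NA").replace("", "NA")
        bad_cond = set(df["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValidationError(f"unknown condition(s): {sorted(bad_cond)}")
        bad_sub = set(df["subtype"]) - set(SUBTYPES)
        if bad_sub:
            raise ValidationError(f"unknown subtype(s): {sorted(bad_sub)}")
        bad_tis = set(df["tissue"]) - set(TISSUES)
        if bad_tis:
            raise ValidationError(f"unknown tissue(s): {sorted(bad_tis)}")
        hd_bad = df[(df["condition"] == "HD") & (df["subtype"] != "NA")]
        if len(hd_bad):
            raise ValidationError(
                f"HD samples must have subtype NA: {hd_bad.index.tolist()}"
            )
        if not allow_5n and (df["subtype"] == "5N").any():
            raise ValidationError(
                "subtype 5N is reserved for qPCR cohort records "
                "(pass allow_5n=True)"
            )
        self.frame = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def condition_samples(self, condition: str) -> list[str]:
        return list(self.frame.index[self.frame["condition"] == condition])

    def subtype_samples(self, subtype: str) -> list[str]:
        return list(self.frame.index[self.frame["subtype"] == subtype])

    def group_samples(self, group: str) -> list[str]:
        """Samples of a condition (JMML/HD) or molecular subtype label."""
        if group in CONDITIONS:
            return self.condition_samples(group)
        return self.subtype_samples(group)

    def condition_counts(self) -> dict[str, int]:
        return self.frame["condition"].value_counts().to_dict()

    @property
    def subtypes_present(self) -> list[str]:
        out = [s for s in SUBTYPES[:-1] if (self.frame["subtype"] == s).any()]
        return out

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        return SampleSheet(self.frame.loc[list(sample_ids)], allow_5n=True)

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:
        counts = self.condition_counts()
        return f"SampleSheet(n={len(self)}, {counts})"


@dataclass
class CountAssay:
    """Circular and linear count matrices with sample metadata.

    ``circ_counts``: circRNA x sample integer matrix of consensus
    backsplice read counts. ``linear_counts``: locus x sample integer
    matrix of linear (host) transcript counts. ``tpm``: gene x sample
    TPM matrix. ``circ_to_locus`` maps each circRNA id to its host
    locus row in ``linear_counts`` (CircClust ids map to no linear row).
    """

    circ_counts: pd.DataFrame
    linear_counts: pd.DataFrame | None = None
    tpm: pd.DataFrame | None = None
    samples: SampleSheet | None = None
    size_factors: pd.Series | None = None
    circ_to_locus: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.samples is not None:
            sids = set(self.samples.sample_ids)
            for name, mat in (
                ("circ_counts", self.circ_counts),
                ("linear_counts", self.linear_counts),
                ("tpm", self.tpm),
            ):
                if mat is not None and not set(mat.columns) <= sids:
                    extra = sorted(set(mat.columns) - sids)
                    raise ValidationError(
                        f"{name} columns not in sample sheet: {extra}"
                    )
        for name, mat in (
            ("circ_counts", self.circ_counts),
            ("linear_counts", self.linear_counts),
        ):
            if mat is not None and (mat.to_numpy() < 0).any():
                raise ValidationError(f"negative counts in {name}")
        if self.size_factors is not None and (self.size_factors <= 0).any():
            raise ValidationError("size factors must be positive")

    def normalized_circ(self) -> pd.DataFrame:
        """Size-factor-normalized circular counts."""
        if self.size_factors is None:
            raise ValueError("size factors not computed")
        return self.circ_counts / self.size_factors

    def normalized_linear(self) -> pd.DataFrame:
        if self.size_factors is None:
            raise ValueError("size factors not computed")
        if self.linear_counts is None:
            raise ValueError("no linear counts")
        return self.linear_counts / self.size_factors


@dataclass
class Config:
    """All pipeline thresholds, defaulting to the published cut-offs.

    Units: read counts are raw or size-factor-normalized backsplice
    reads; energies kcal/mol; ``clust_gap`` nucleotides; CLP and
    fractions dimensionless; ``tpm_min`` TPM; ``rho_min`` Spearman rho.
    """

    min_methods: int = 2          # distinct detection methods required
    min_reads: int = 5            # consensus reads in >= 1 sample
    strict_same_sample: bool = False  # require both in the same sample
    consensus_stat: str = "median"    # per-sample consensus: min/median/max
    breadth_condition: float = 0.5    # >= this fraction of a condition
    breadth_subgroup: float = 0.75    # > this fraction of a subtype
    clust_gap: int = 5000         # nt, CircClust single-linkage gap
    alpha: float = 0.05           # BH-adjusted significance threshold
    clp_high: float = 0.33        # high-CLP screen: CLP >= this
    clp_high_expr: float = 40.0   # ... and circular mean > this
    clp_dominant: float = 0.5     # "dominant" flag: CLP > this
    imb_expr: float = 100.0       # imbalance screen: mean >= this (either group)
    imb_clp: float = 0.1          # ... CLP >= this (either group)
    imb_lfc: float = 1.0          # ... |LFC(CLP)| >= this
    clp_eps: float = 1e-9         # pseudo-proportion for the LFC(CLP) ratio
    miranda_score: float = 100.0  # predictor A: score >= this
    miranda_energy: float = -20.0  # ... and energy <= this (kcal/mol)
    pita_dduplex: float = -20.0   # predictor B: dG_duplex < this
    pita_dopen: float = -13.0     # ... and dG_open > this
    min_sites_unquantified: int = 3  # sites required for miRNAs absent from reference
    mirna_expr_frac: float = 0.25  # fraction of reference samples with nonzero counts
    strong_categories: tuple = ("Functional MTI",)
    tpm_min: float = 1.0          # gene expressed iff mean JMML TPM > this
    rho_min: float = 0.4          # Spearman correlation flag
    max_site_len: int = 30        # nt, pseudo-circular extension = max_site_len - 1
    reference_assays: tuple = ("TBP", "HPRT1", "GAPDH")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        for key in ("strong_categories", "reference_assays"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        for key in ("strong_categories", "reference_assays"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def updated(self, **kwargs) -> "Config":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

DETECTION_COLUMNS = ["chrom", "start", "end", "strand", "method", "sample", "reads"]


def read_detection_table(path: str | Path) -> pd.DataFrame:
    """Read a multi-method backsplice detection evidence table.

    TSV columns: chrom, start, end, strand, method, sample, reads.
    Returns a typed DataFrame with an added ``circ_id`` column.
    Malformed rows raise, naming the (1-based, header-exclusive) row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    for col, kind in (("start", int), ("end", int), ("reads", int)):
        try:
            df[col] = df[col].astype(kind)
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise FormatError(
                f"{path}: non-numeric {col!r} at row(s) {[i + 1 for i in bad[:5]]}"
            ) from None
    neg = df.index[df["reads"] < 0]
    if len(neg):
        raise ValidationError(
            f"{path}: negative reads at row(s) {[i + 1 for i in neg[:5]]}"
        )
    bad_iv = df.index[(df["start"] < 0) | (df["start"] >= df["end"])]
    if len(bad_iv):
        raise ValidationError(
            f"{path}: invalid interval at row(s) {[i + 1 for i in bad_iv[:5]]}"
        )
    bad_strand = df.index[~df["strand"].isin(VALID_STRANDS)]
    if len(bad_strand):
        raise ValidationError(
            f"{path}: invalid strand at row(s) {[i + 1 for i in bad_strand[:5]]}"
        )
    df["circ_id"] = (
        df["chrom"].astype(str)
        + ":"
        + df["start"].astype(str)
        + "-"
        + df["end"].astype(str)
        + ":"
        + df["strand"]
    )
    return df


def read_sample_sheet(path: str | Path, allow_5n: bool = False) -> SampleSheet:
    """Read and validate a TSV sample sheet."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing column 'sample_id'")
    return SampleSheet(df, allow_5n=allow_5n)


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample count matrix (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def read_exon_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV exon annotation: gene_id, transcript_id, exon_number,
    chrom, start, end, strand (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["gene_id", "transcript_id", "exon_number", "chrom", "start", "end", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return df


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def write_bed(circs: Iterable[CircRNA], path: str | Path) -> None:
    """BED6 export of circRNA intervals (0-based half-open, as stored)."""
    with open(path, "w") as fh:
        for c in circs:
            iv = c.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.circ_id}\t0\t{iv.strand}\n"
            )


def write_gtf_exons(exons: pd.DataFrame, path: str | Path) -> None:
    """GTF-like export of an exon table (converts to 1-based inclusive)."""
    with open(path, "w") as fh:
        for _, r in exons.iterrows():
            attrs = (
                f'gene_id "{r.gene_id}"; transcript_id "{r.transcript_id}"; '
                f'exon_number "{int(r.exon_number)}";'
            )
            fh.write(
                f"{r.chrom}\tcirclin\texon\t{int(r.start) + 1}\t{int(r.end)}\t.\t"
                f"{r.strand}\t.\t{attrs}\n"
            )


def write_network(graph: nx.Graph, path: str | Path, fmt: str = "graphml") -> None:
    """Export a circRNA-miRNA-gene network.

    Formats: ``graphml`` (single file, all attributes), ``sif``
    (Cytoscape simple interaction file), ``tsv`` (``<path>.nodes.tsv``
    and ``<path>.edges.tsv`` with all attributes).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "graphml":
        g = graph.copy()
        for _, data in g.nodes(data=True):
            _stringify_nones(data)
        for _, _, data in g.edges(data=True):
            _stringify_nones(data)
        nx.write_graphml(g, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, data in graph.edges(data=True):
                fh.write(f"{u}\t{data.get('interaction', 'interacts')}\t{v}\n")
            for node in nx.isolates(graph):
                fh.write(f"{node}\n")
    elif fmt == "tsv":
        nodes = pd.DataFrame(
            [{"node": n, **d} for n, d in graph.nodes(data=True)]
        )
        edges = pd.DataFrame(
            [{"source": u, "target": v, **d} for u, v, d in graph.edges(data=True)]
        )
        nodes.to_csv(path.with_suffix(".nodes.tsv"), sep="\t", index=False)
        edges.to_csv(path.with_suffix(".edges.tsv"), sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def _stringify_nones(data: dict) -> None:
    for k, v in list(data.items()):
        if v is None:
            data[k] = ""
        elif isinstance(v, (np.floating, np.integer)):
            data[k] = v.item()


def read_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


# ---------------------------------------------------------------------------
# filtering-funnel logging
# ---------------------------------------------------------------------------


def log_filter(stage: str, n_in: int, n_out: int, threshold: str) -> None:
    """Log one step of the filtering funnel: input, output, threshold."""
    logger.info("%s: %d -> %d (threshold: %s)", stage, n_in, n_out, threshold)
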
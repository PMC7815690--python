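"""Circular-to-linear proportion (CLP) statistics and screens.

CLP = circ_mean / (circ_mean + lin_mean), computed on group means of
size-factor-normalized counts: the share of a locus's expression that
is circular. Two screens follow the published cut-offs: the high-CLP
screen (CLP >= 0.33 and circular mean > 40 in JMML, "dominant" flag at
CLP > 0.5) and the circular/linear imbalance screen (normalized mean
>= 100 and CLP >= 0.1 in JMML or HD, |LFC(CLP)| >= 1).

A pseudo-proportion epsilon enters only the LFC(CLP) ratio; reported
CLP values themselves carry no pseudocount. Intergenic circRNAs
(CircClust loci, no linear counterpart) have lin_mean 0 and CLP 1
where expressed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from circlin.iokit import Config, CountAssay, ValidationError, log_filter
from circlin.diffexpr import size_factors


def _group_means(
    assay: CountAssay, group: str, per_sample: bool = False
) -> tuple[pd.Series, pd.Series] | tuple[pd.DataFrame, pd.DataFrame]:
    if assay.samples is None:
        raise ValueError("assay has no sample sheet")
    ids = assay.samples.group_samples(group)
    if not ids:
        raise ValueError(f"no samples in group {group!r}")
    if assay.size_factors is None:
        assay.size_factors = size_factors(assay.circ_counts)
    circ_n = assay.normalized_circ()[ids]
    mapping = assay.circ_to_locus or {}
    missing = [c for c in assay.circ_counts.index if c not in mapping]
    if missing:
        raise ValidationError(
            f"circRNA(s) without locus mapping: {missing[:5]}"
        )
    lin_n = assay.normalized_linear()[ids] if assay.linear_counts is not None else None
    lin_rows = []
    for cid in assay.circ_counts.index:
        locus = mapping[cid]
        if lin_n is not None and locus in lin_n.index:
            lin_rows.append(lin_n.loc[locus])
        elif locus.startswith("CircClust"):
            lin_rows.append(pd.Series(0.0, index=ids))
        else:
            raise ValidationError(f"locus {locus!r} of {cid} missing from linear counts")
    lin = pd.DataFrame(lin_rows, index=assay.circ_counts.index)
    if per_sample:
        return circ_n, lin
    return circ_n.mean(axis=1), lin.mean(axis=1)


def compute_clp(assay: CountAssay, group: str, per_sample: bool = False) -> pd.DataFrame:
    """Per-circRNA CLP record for one group (JMML, HD, or a subtype).

    Columns: circ_mean, lin_mean, clp. With ``per_sample=True`` the
    CLP is computed per sample and averaged instead (off the default
    path: the screens quote group-level means).
    """
    if per_sample:
        circ_n, lin = _group_means(assay, group, per_sample=True)
        denom = (circ_n + lin).replace(0.0, np.nan)
        clp_ps = (circ_n / denom).fillna(0.0)
        rec = pd.DataFrame(
            {
                "circ_mean": circ_n.mean(axis=1),
                "lin_mean": lin.mean(axis=1),
                "clp": clp_ps.mean(axis=1),
            }
        )
    else:
        circ_mean, lin_mean = _group_means(assay, group)
        total = circ_mean + lin_mean
        with np.errstate(invalid="ignore", divide="ignore"):
            clp = np.where(total > 0, circ_mean / total, 0.0)
        rec = pd.DataFrame(
            {"circ_mean": circ_mean, "lin_mean": lin_mean, "clp": clp}
        )
    rec["group"] = group
    rec.index.name = "circ_id"
    return rec


def clp_contrast(
    assay: CountAssay,
    group_a: str = "JMML",
    group_b: str = "HD",
    cfg: Config | None = None,
) -> pd.DataFrame:
    """Paired CLP records with LFC(CLP) and companion LFCs.

    lfc_clp = log2(clp_A) - log2(clp_B), with the pseudo-proportion
    epsilon substituted only for exact zeros. Computed as a log
    difference so group swap negates it exactly (bitwise), and
    ratio-of-two boundaries (e.g. CLP 0.4 vs 0.2) land exactly on
    |LFC| = 1. lfc_circ and lfc_lin are the matching log2 ratios of
    the circular and linear group means.
    """
    cfg = cfg or Config()
    eps = cfg.clp_eps

    def _log2(v: pd.Series) -> np.ndarray:
        arr = v.to_numpy(float)
        return np.log2(np.where(arr > 0, arr, eps))

    a = compute_clp(assay, group_a)
    b = compute_clp(assay, group_b)
    out = pd.DataFrame(
        {
            f"circ_mean_{group_a}": a["circ_mean"],
            f"lin_mean_{group_a}": a["lin_mean"],
            f"clp_{group_a}": a["clp"],
            f"circ_mean_{group_b}": b["circ_mean"],
            f"lin_mean_{group_b}": b["lin_mean"],
            f"clp_{group_b}": b["clp"],
        }
    )
    out["lfc_clp"] = _log2(a["clp"]) - _log2(b["clp"])
    out["lfc_circ"] = _log2(a["circ_mean"]) - _log2(b["circ_mean"])
    out["lfc_lin"] = _log2(a["lin_mean"]) - _log2(b["lin_mean"])
    out.attrs["groups"] = (group_a, group_b)
    return out


def high_clp_screen(clp_records: pd.DataFrame, cfg: Config | None = None) -> pd.DataFrame:
    """High circular share in JMML: CLP >= 0.33 and circular mean > 40.

    ``clp_records`` is the output of :func:`compute_clp` for the JMML
    group. Adds a ``dominant`` flag for CLP > 0.5 (circRNA more
    abundant than its linear counterpart).
    """
    cfg = cfg or Config()
    keep = (clp_records["clp"] >= cfg.clp_high) & (
        clp_records["circ_mean"] > cfg.clp_high_expr
    )
    out = clp_records[keep].copy()
    out["dominant"] = out["clp"] > cfg.clp_dominant
    log_filter(
        "high_clp_screen",
        len(clp_records),
        len(out),
        f"CLP >= {cfg.clp_high} & circ_mean > {cfg.clp_high_expr}",
    )
    return out


def imbalance_screen(
    contrast: pd.DataFrame, cfg: Config | None = None
) -> pd.DataFrame:
    """Circular/linear imbalance screen between two groups.

    Keep a circRNA iff its normalized circular mean reaches
    ``imb_expr`` in either group, its CLP reaches ``imb_clp`` in
    either group, and |LFC(CLP)| >= ``imb_lfc``. The output keeps
    lfc_circ / lfc_lin / lfc_clp for the decomposition of which side
    (circular or linear) drives the imbalance.
    """
    cfg = cfg or Config()
    ga, gb = contrast.attrs.get("groups", ("JMML", "HD"))
    expr_ok = (contrast[f"circ_mean_{ga}"] >= cfg.imb_expr) | (
        contrast[f"circ_mean_{gb}"] >= cfg.imb_expr
    )
    clp_ok = (contrast[f"clp_{ga}"] >= cfg.imb_clp) | (
        contrast[f"clp_{gb}"] >= cfg.imb_clp
    )
    lfc_ok = contrast["lfc_clp"].abs() >= cfg.imb_lfc
    out = contrast[expr_ok & clp_ok & lfc_ok].copy()
    out.attrs["groups"] = (ga, gb)
    log_filter(
        "imbalance_screen",
        len(contrast),
        len(out),
        f"mean >= {cfg.imb_expr} & CLP >= {cfg.imb_clp} (either group) & |LFC(CLP)| >= {cfg.imb_lfc}",
    )
    return out


def crosslink_de_and_clp(
    de_result: pd.DataFrame, screen: pd.DataFrame
) -> pd.DataFrame:
    """Join DE results with the imbalance screen.

    Flags circRNAs that are both significantly differentially
    expressed and imbalance-screen hits: changes of the circular
    product not mirrored by the linear product of the same gene.
    """
    joined = screen.join(
        de_result[["lfc", "padj", "significant"]], how="outer", rsuffix="_de"
    )
    joined["screen_hit"] = joined.index.isin(screen.index)
    joined["de_significant"] = joined["significant"].fillna(False).astype(bool)
    joined["de_and_imbalanced"] = joined["screen_hit"] & joined["de_significant"]
    return joined.drop(columns=["significant"])
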
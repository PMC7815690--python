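"""qRT-PCR validation statistics.

Efficiency-corrected relative quantities (RQ = E^(Ct_cal - Ct), with
the per-assay mean Ct as calibrator — the qBase convention; ratios
between samples are invariant to the calibrator), normalization to
the geometric mean of reference-gene RQs (TBP, HPRT1, GAPDH), and the
nonparametric group comparisons used for validation: two-tailed
Mann-Whitney U between JMML and HD with BH adjustment across the
tested panel, and Kruskal-Wallis across molecular subtypes with
pairwise Mann-Whitney follow-ups (reported at a display threshold
p < 0.1, a reporting filter rather than a test).

When every assay has E = 2 exactly, NRQ group ratios coincide with
the classic 2^-ddCt quantity.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from circlin.iokit import Config, SampleSheet, logger
from circlin.diffexpr import bh_adjust


def compute_rq(
    ct: pd.DataFrame, efficiencies: pd.Series | dict
) -> pd.DataFrame:
    """Relative quantities from a long Ct table.

    ``ct`` columns: sample_id, assay_id, ct. ``efficiencies`` maps
    assay_id to the fold-per-cycle amplification efficiency E in
    (1, 2.2] (use :func:`efficiency_from_percent` for percent form).
    RQ(sample, assay) = E^(mean Ct of the assay - Ct). Returns a
    sample x assay matrix; missing Cts yield missing RQs.
    """
    eff = pd.Series(efficiencies, dtype=float)
    bad = eff[(eff <= 1.0) | (eff > 2.2)]
    if len(bad):
        raise ValueError(f"efficiencies out of (1, 2.2]: {bad.to_dict()}")
    wide = ct.pivot_table(index="sample_id", columns="assay_id", values="ct", aggfunc="mean")
    missing_e = [a for a in wide.columns if a not in eff.index]
    if missing_e:
        raise ValueError(f"no efficiency for assay(s): {missing_e}")
    cal = wide.mean(axis=0)          # per-assay calibrator Ct
    rq = pd.DataFrame(index=wide.index, columns=wide.columns, dtype=float)
    for assay in wide.columns:
        rq[assay] = eff[assay] ** (cal[assay] - wide[assay])
    return rq


def efficiency_from_percent(percent: float) -> float:
    """Convert a percent amplification efficiency (100% -> E=2)."""
    return 1.0 + percent / 100.0


def compute_nrq(
    rq: pd.DataFrame, reference_assays: tuple | list = ("TBP", "HPRT1", "GAPDH")
) -> pd.DataFrame:
    """Normalize RQs to the geometric mean of the reference assays.

    Samples with any reference RQ missing get missing NRQs (logged).
    The reference columns are dropped from the output.
    """
    refs = list(reference_assays)
    if not refs:
        raise ValueError("reference assay list is empty")
    absent = [r for r in refs if r not in rq.columns]
    if absent:
        raise ValueError(f"reference assay(s) not measured: {absent}")
    ref_block = rq[refs]
    geo = np.exp(np.log(ref_block).mean(axis=1))
    incomplete = ref_block.isna().any(axis=1)
    if incomplete.any():
        logger.warning(
            "compute_nrq: %d sample(s) missing a reference RQ: %s",
            incomplete.sum(), list(rq.index[incomplete]),
        )
        geo[incomplete] = np.nan
    targets = [c for c in rq.columns if c not in refs]
    nrq = rq[targets].div(geo, axis=0)
    return nrq


def group_ratio(
    nrq: pd.DataFrame,
    samples: SampleSheet,
    target: str,
    groups: tuple[str, str] = ("JMML", "HD"),
    kind: str = "geometric",
) -> float:
    """Ratio of group NRQ summaries (geometric or arithmetic means)."""
    a = nrq.loc[nrq.index.intersection(samples.group_samples(groups[0])), target].dropna()
    b = nrq.loc[nrq.index.intersection(samples.group_samples(groups[1])), target].dropna()
    if kind == "geometric":
        return float(np.exp(np.log(a).mean() - np.log(b).mean()))
    return float(a.mean() / b.mean())


# ---------------------------------------------------------------------------
# nonparametric tests
# ---------------------------------------------------------------------------


def mann_whitney(
    x: np.ndarray | pd.Series, y: np.ndarray | pd.Series
) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U.

    Exact null distribution (full enumeration over rank assignments)
    for tie-free samples when both groups have <= 8 values or the
    combined n is <= 12; normal approximation with tie correction
    (and continuity correction) otherwise. Identical samples give
    p = 1 with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 values")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        logger.warning("mann_whitney: all values identical; p = 1")
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = len(pooled) <= 12 or (len(x) <= 8 and len(y) <= 8)
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_groups(
    nrq: pd.DataFrame,
    samples: SampleSheet,
    groups: tuple[str, str] = ("JMML", "HD"),
    targets: list[str] | None = None,
) -> pd.DataFrame:
    """Per-target two-group comparison with panel-wide BH adjustment.

    Each target uses all samples with a non-missing NRQ for that
    target. Returns a table with n per group, U, p, and p_adj over
    the tested panel.
    """
    targets = targets if targets is not None else list(nrq.columns)
    rows = []
    for target in targets:
        vals = nrq[target]
        a = vals[vals.index.intersection(samples.group_samples(groups[0]))].dropna()
        b = vals[vals.index.intersection(samples.group_samples(groups[1]))].dropna()
        if len(a) < 2 or len(b) < 2:
            logger.warning("mann_whitney_groups: skipping %s (group < 2 values)", target)
            rows.append((target, len(a), len(b), np.nan, np.nan))
            continue
        u, p = mann_whitney(a, b)
        rows.append((target, len(a), len(b), u, p))
    out = pd.DataFrame(rows, columns=["assay_id", "n_a", "n_b", "U", "pvalue"]).set_index("assay_id")
    out["p_adj"] = bh_adjust(out["pvalue"])
    return out


def kruskal_wallis_subtypes(
    nrq: pd.DataFrame,
    samples: SampleSheet,
    target: str,
    groups: list[str] | None = None,
    display_p: float = 0.1,
) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis across subtype groups plus pairwise follow-ups.

    Groups default to the subtypes present plus HD; groups with < 2
    non-missing values are excluded with a warning. H uses the
    chi-square approximation with tie correction. The pairwise
    Mann-Whitney table carries a ``display`` flag for p < ``display_p``
    (the reporting convention; not a significance test).
    """
    if groups is None:
        groups = samples.subtypes_present + ["HD"]
    series = {}
    for g in groups:
        vals = nrq.loc[nrq.index.intersection(samples.group_samples(g)), target].dropna()
        if len(vals) < 2:
            logger.warning("kruskal_wallis_subtypes: excluding %s (< 2 values)", g)
            continue
        series[g] = vals.to_numpy()
    if len(series) < 2:
        raise ValueError("need >= 2 groups with >= 2 values")
    h, p = stats.kruskal(*series.values())
    rows = []
    for ga, gb in combinations(series, 2):
        u, pp = mann_whitney(series[ga], series[gb])
        rows.append((ga, gb, u, pp, pp < display_p))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "U", "pvalue", "display"])
    return float(h), float(p), pairwise
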
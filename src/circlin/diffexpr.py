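"""Negative-binomial Wald differential expression with latent-factor
correction.

A self-contained engine in the DESeq2 style: median-of-ratios size
factors, a regularized-log-like normalization for ordination only,
residual-SVD surrogate variables against hidden batch structure,
method-of-moments dispersions shrunk toward a local (lowess) trend on
the mean, NB log-link GLM fits by iteratively reweighted least squares,
Wald z tests with two-sided normal p-values, no independent filtering,
and Benjamini-Hochberg adjustment. Fidelity to DESeq2 is claimed at
the level of statistical properties (type-I calibration, FDR control,
LFC recovery), not value equality.

Sign convention: positive LFC means higher expression in the
first-named group of a contrast (the JMML/subtype group).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from circlin.iokit import Config, CountAssay, SampleSheet, logger

LN2 = np.log(2.0)
_MIN_DISP = 1e-8
_PRIOR_DF = 10.0            # prior weight (pseudo-df) pulling dispersions to the trend


@dataclass
class DesignSpec:
    """A pairwise contrast with optional extra covariates."""

    contrast: tuple[str, str]                 # (group A, group B); LFC = A over B
    covariates: pd.DataFrame | None = None    # sample x covariate (e.g. SVs)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.contrast[0] == self.contrast[1]:
            raise ValueError("contrast groups must differ")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class SurrogateVariables:
    """Estimated latent covariates (samples x k), mean-centered, unit-norm."""

    matrix: pd.DataFrame
    k: int
    method: str = "residual-svd/permutation"

    @property
    def empty(self) -> bool:
        return self.k == 0


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def size_factors(circ_counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Uses features with nonzero counts in every sample; when none
    exist, falls back to per-feature geometric means over the positive
    entries only.
    """
    mat = circ_counts.to_numpy(dtype=float)
    if mat.size == 0 or not mat.any():
        raise ValueError("all-zero count matrix")
    all_pos = (mat > 0).all(axis=1)
    if all_pos.any():
        sub = mat[all_pos]
        log_geo = np.log(sub).mean(axis=1)
        ratios = np.log(sub) - log_geo[:, None]
    else:
        with np.errstate(divide="ignore"):
            logm = np.where(mat > 0, np.log(mat), np.nan)
        log_geo = np.nanmean(logm, axis=1)
        ratios = logm - log_geo[:, None]
    sf = np.exp(np.nanmedian(ratios, axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=circ_counts.columns, name="size_factor")


def rlog_like(circ_counts: pd.DataFrame, sf: pd.Series) -> pd.DataFrame:
    """Variance-moderated log2 normalization for PCA/clustering only.

    log2(count/sf + 1), with each sample's value shrunk toward the
    feature mean by a weight 1/(1 + mean normalized count): low-count
    features are flattened, high-count features approach the plain
    log2. Not used by any test statistic.
    """
    q = circ_counts.to_numpy(float) / sf.to_numpy()[None, :]
    y = np.log2(q + 1.0)
    mean_q = q.mean(axis=1)
    w = 1.0 / (1.0 + mean_q)
    shrunk = w[:, None] * y.mean(axis=1)[:, None] + (1.0 - w)[:, None] * y
    return pd.DataFrame(shrunk, index=circ_counts.index, columns=circ_counts.columns)


# ---------------------------------------------------------------------------
# surrogate variables
# ---------------------------------------------------------------------------


def estimate_surrogates(
    normalized: pd.DataFrame,
    design: pd.DataFrame,
    k: int | None = None,
    n_perm: int = 20,
    quantile: float = 0.95,
    seed: int = 0,
) -> SurrogateVariables:
    """Latent-factor estimation by SVD of design residuals.

    The normalized matrix (features x samples) is residualized on the
    primary design (samples x p, intercept included); the right
    singular vectors of the residuals are candidate factors. When
    ``k`` is not given it is chosen by permutation parallel analysis:
    keep leading components whose singular value exceeds the
    ``quantile`` of the same-rank singular values from ``n_perm``
    row-wise permutations of the residual matrix.

    Each surrogate is then rebuilt from the *original* (row-centered)
    data restricted to the features most associated with the residual
    direction. Residual directions are orthogonal to the design by
    construction and would miss any batch component collinear with it;
    the rebuild recovers the full latent vector, so including it in
    the test design actually removes confounded batch signal.
    """
    Y = normalized.to_numpy(float)
    X = design.to_numpy(float)
    n = Y.shape[1]
    if n <= X.shape[1] + 1:
        raise ValueError("need more samples than design columns + 1")
    H = X @ np.linalg.pinv(X)
    R = Y - Y @ H.T
    max_k = n - np.linalg.matrix_rank(X)
    if k is not None and k >= max_k:
        raise ValueError(f"k={k} >= n - rank(design) = {max_k}")
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    if k is None:
        rng = np.random.default_rng(seed)
        perm_s = np.empty((n_perm, len(s)))
        for b in range(n_perm):
            # permute the original rows (not the residuals): residualizing a
            # permuted residual matrix shrinks its spectrum and inflates k
            Yp = rng.permuted(Y, axis=1)
            Rp = Yp - Yp @ H.T
            perm_s[b] = np.linalg.svd(Rp, compute_uv=False)
        thresh = np.quantile(perm_s, quantile, axis=0)
        k = 0
        while k < min(len(s), max_k - 1) and s[k] > thresh[k]:
            k += 1
    sv = np.empty((n, k))
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Rc = R - R.mean(axis=1, keepdims=True)
    r_norm = np.linalg.norm(Rc, axis=1)
    for j in range(k):
        e = Vt[j] - Vt[j].mean()
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (Rc @ e) / (r_norm * np.linalg.norm(e))
        corr = np.nan_to_num(corr)
        cut = max(0.3, float(np.quantile(np.abs(corr), 0.75)))
        sel = np.abs(corr) >= cut
        if sel.sum() < min(10, Y.shape[0]):
            sel = np.argsort(-np.abs(corr))[: min(10, Y.shape[0])]
        sub = Yc[sel]
        _, _, sub_vt = np.linalg.svd(sub, full_matrices=False)
        v = sub_vt[0]
        if np.dot(v, Vt[j]) < 0:
            v = -v
        sv[:, j] = v
    if k:
        sv = sv - sv.mean(axis=0, keepdims=True)
        norms = np.linalg.norm(sv, axis=0)
        sv = sv / np.where(norms > 0, norms, 1.0)
    mat = pd.DataFrame(
        sv, index=normalized.columns, columns=[f"SV{i + 1}" for i in range(k)]
    )
    return SurrogateVariables(matrix=mat, k=k)


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------


def _dispersions(Y: np.ndarray, X: np.ndarray, sf: np.ndarray) -> np.ndarray:
    """Method-of-moments dispersions shrunk toward a lowess trend.

    Per feature: pooled within-design-cell moments on normalized
    counts give a raw alpha; log alpha is regressed on log mean with a
    local (lowess, span 0.5) smoother; the final estimate is a
    precision-weighted log-space average of the raw value (weight =
    residual df) and the trend (fixed prior df).
    """
    m, n = Y.shape
    q = Y / sf[None, :]
    # residualize on the full design (handles continuous covariates)
    H = X @ np.linalg.pinv(X)
    resid = q - q @ H.T
    mu = q.mean(axis=1)
    df = max(n - np.linalg.matrix_rank(X), 1)
    s2 = (resid ** 2).sum(axis=1) / df
    xim = np.mean(1.0 / sf)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (s2 - xim * mu) / np.maximum(mu, 1e-12) ** 2
    raw = np.clip(raw, _MIN_DISP, 10.0)
    ok = mu > 0
    if ok.sum() >= 10:
        order = np.argsort(np.log(mu[ok]), kind="stable")
        fit = lowess(
            np.log(raw[ok]),
            np.log(mu[ok]),
            frac=0.5,
            it=2,
            xvals=np.log(np.maximum(mu, 1e-12)),
        )
        trend = np.exp(fit)
        del order
    else:
        trend = np.full(m, np.exp(np.mean(np.log(raw[ok]))) if ok.any() else 0.1)
    trend = np.clip(trend, _MIN_DISP, 10.0)
    w_raw = df
    log_alpha = (w_raw * np.log(raw) + _PRIOR_DF * np.log(trend)) / (w_raw + _PRIOR_DF)
    # asymmetric moderation: never take a feature's dispersion below either
    # its raw estimate or the trend. The method-of-moments raw value is
    # noisy downward at small n, and a plug-in Wald test with an
    # underestimated dispersion is anticonservative; the floor trades a
    # little power for calibration.
    log_alpha = np.maximum(log_alpha, np.maximum(np.log(raw), np.log(trend)))
    return np.clip(np.exp(log_alpha), _MIN_DISP, 10.0)


# ---------------------------------------------------------------------------
# batched NB GLM / Wald test
# ---------------------------------------------------------------------------


def _nb_irls(
    Y: np.ndarray,
    X: np.ndarray,
    sf: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched IRLS for NB log-link GLMs with known dispersion.

    Returns (beta (m,p) on the natural-log scale, se (m,p), converged
    mask (m,)). All features share the design X; the per-feature loop
    is replaced by batched einsum/solve over features.
    """
    m, n = Y.shape
    p = X.shape[1]
    offset = np.log(sf)[None, :]
    eta = np.log((Y + 0.5) / sf[None, :])
    beta = eta @ np.linalg.pinv(X).T
    ridge = 1e-10 * np.eye(p)
    converged = np.zeros(m, dtype=bool)
    XtWX = np.zeros((m, p, p))
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T + offset, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset) + (Y - mu) / mu
        XtWX = np.einsum("mn,ni,nj->mij", W, X, X, optimize=True)
        XtWz = np.einsum("mn,ni,mn->mi", W, X, z, optimize=True)
        new = np.linalg.solve(XtWX + ridge, XtWz[..., None])[..., 0]
        delta = np.abs(new - beta).max(axis=1)
        beta = new
        converged = delta < tol
        if converged.all():
            break
    cov = np.linalg.inv(XtWX + ridge)
    se = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))
    return beta, se, converged


def nb_wald_test(
    circ_counts: pd.DataFrame,
    sf: pd.Series,
    design: DesignSpec,
    samples: SampleSheet,
    svs: SurrogateVariables | None = None,
) -> pd.DataFrame:
    """NB Wald test for one pairwise contrast, with BH adjustment.

    Builds the design intercept + group indicator (+ surrogate
    variables and extra covariates), estimates dispersions
    (method-of-moments shrunk to a local trend), fits log-link NB GLMs
    by IRLS, and tests the group coefficient with a two-sided normal
    Wald test. Low-count features are never filtered out of the BH
    family ("no independent filtering"); features with all-zero counts
    or non-convergent fits get missing statistics and are excluded
    from the BH m.
    """
    a_label, b_label = design.contrast
    a_ids = samples.group_samples(a_label)
    b_ids = samples.group_samples(b_label)
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError(f"contrast {a_label} vs {b_label}: each group needs >= 2 samples")
    if set(a_ids) & set(b_ids):
        raise ValueError("contrast groups overlap")
    ids = a_ids + b_ids
    Y = circ_counts[ids].to_numpy(float)
    sfv = sf[ids].to_numpy(float)
    group = np.array([1.0] * len(a_ids) + [0.0] * len(b_ids))
    cols = [np.ones(len(ids)), group]
    names = ["intercept", "group"]
    for extra in (svs.matrix if svs is not None and not svs.empty else None,
                  design.covariates):
        if extra is not None:
            sub = extra.loc[ids]
            for c in sub.columns:
                cols.append(sub[c].to_numpy(float))
                names.append(str(c))
    X = np.column_stack(cols)

    m = Y.shape[0]
    base_mean = (Y / sfv[None, :]).mean(axis=1)
    nonzero = Y.sum(axis=1) > 0
    lfc = np.full(m, np.nan)
    se = np.full(m, np.nan)
    stat = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    if nonzero.any():
        alpha_hat = _dispersions(Y[nonzero], X, sfv)
        beta, se_all, conv = _nb_irls(Y[nonzero], X, sfv, alpha_hat)
        if not conv.all():
            logger.warning("nb_wald_test: %d features did not converge", (~conv).sum())
        lfc_nz = beta[:, 1] / LN2
        se_nz = se_all[:, 1] / LN2
        z = np.where(se_nz > 0, beta[:, 1] / np.where(se_all[:, 1] > 0, se_all[:, 1], np.inf), 0.0)
        p_nz = 2.0 * stats.norm.sf(np.abs(z))
        p_nz[~conv] = np.nan
        lfc[nonzero], se[nonzero], pval[nonzero] = lfc_nz, se_nz, p_nz
        stat[nonzero] = z
    padj = bh_adjust(pd.Series(pval, index=circ_counts.index))
    res = pd.DataFrame(
        {
            "baseMean": base_mean,
            "lfc": lfc,
            "se": se,
            "stat": stat,
            "pvalue": pval,
            "padj": padj.to_numpy(),
            "significant": padj.to_numpy() <= design.alpha,
        },
        index=circ_counts.index,
    )
    res.loc[res["padj"].isna(), "significant"] = False
    return res


def bh_adjust(p_values: pd.Series | np.ndarray, m: int | None = None) -> pd.Series:
    """Benjamini-Hochberg step-up adjustment.

    Missing p-values are excluded from the family size; ``m`` can
    force a larger family. Values outside [0, 1] raise.
    """
    p = pd.Series(p_values, dtype=float)
    mask = p.notna()
    vals = p[mask].to_numpy()
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = pd.Series(np.nan, index=p.index)
    if mask.sum() == 0:
        return out
    if m is None or m <= mask.sum():
        out[mask] = multipletests(vals, method="fdr_bh")[1]
    else:
        order = np.argsort(vals, kind="stable")
        ranked = vals[order] * m / np.arange(1, len(vals) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        res = np.empty_like(adj)
        res[order] = np.minimum(adj, 1.0)
        out[mask] = res
    return out


# ---------------------------------------------------------------------------
# contrast management
# ---------------------------------------------------------------------------


def standard_contrasts(samples: SampleSheet) -> list[tuple[str, str]]:
    """JMML vs HD, each subtype vs HD, and all subtype-vs-subtype pairs."""
    subtypes = samples.subtypes_present
    out = [("JMML", "HD")]
    out += [(s, "HD") for s in subtypes]
    out += list(itertools.combinations(subtypes, 2))
    return out


def run_contrasts(
    assay: CountAssay,
    cfg: Config | None = None,
    n_sv: int | None | str = "auto",
    contrasts: list[tuple[str, str]] | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Run the full battery of pairwise contrasts on a filtered assay.

    Size factors and surrogate variables are estimated once on the
    full matrix (primary design = condition) and the same covariate
    policy is applied to every contrast. Contrasts with a group under
    2 samples are skipped with a warning. Returns (per-contrast
    results, long-format union table).
    """
    cfg = cfg or Config()
    samples = assay.samples
    counts = assay.circ_counts
    if counts.empty:
        return {}, pd.DataFrame()
    sf = assay.size_factors if assay.size_factors is not None else size_factors(counts)
    assay.size_factors = sf
    svs = None
    if n_sv != 0 and n_sv is not None:
        norm = rlog_like(counts, sf)
        cond = (samples.frame["condition"] == "JMML").astype(float)
        design = pd.DataFrame({"intercept": 1.0, "condition": cond}, index=samples.sample_ids)
        k = None if n_sv == "auto" else int(n_sv)
        svs = estimate_surrogates(norm, design, k=k, seed=cfg.seed)
    results: dict[str, pd.DataFrame] = {}
    rows = []
    for a, b in (contrasts or standard_contrasts(samples)):
        label = f"{a}_vs_{b}"
        if len(samples.group_samples(a)) < 2 or len(samples.group_samples(b)) < 2:
            logger.warning("skipping contrast %s: group with < 2 samples", label)
            continue
        res = nb_wald_test(counts, sf, DesignSpec((a, b), alpha=cfg.alpha), samples, svs)
        results[label] = res
        long = res.reset_index(names="circ_id")
        long.insert(0, "contrast", label)
        rows.append(long)
    union = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    return results, union


def detect_isoform_switches(
    de_results: dict[str, pd.DataFrame],
    circ_to_gene: dict[str, str],
) -> pd.DataFrame:
    """Host genes whose circular isoforms move in opposite directions.

    Reports genes having (in any contrast, or across two contrasts)
    one isoform significantly up (lfc > 0) and a different isoform
    significantly down (lfc < 0) — the DNA2-style isoform switch.
    """
    hits: dict[str, dict[str, list]] = {}
    for contrast, res in de_results.items():
        sig = res[res["significant"] & res["lfc"].notna()]
        for cid, row in sig.iterrows():
            gene = circ_to_gene.get(cid)
            if gene is None:
                continue
            rec = hits.setdefault(gene, {"up": [], "down": []})
            rec["up" if row["lfc"] > 0 else "down"].append((cid, contrast, row["lfc"]))
    out = []
    for gene, rec in hits.items():
        for cid_u, con_u, lfc_u in rec["up"]:
            for cid_d, con_d, lfc_d in rec["down"]:
                if cid_u != cid_d:
                    out.append((gene, cid_u, con_u, lfc_u, cid_d, con_d, lfc_d))
    return pd.DataFrame(
        out,
        columns=[
            "gene_id",
            "isoform_up", "contrast_up", "lfc_up",
            "isoform_down", "contrast_down", "lfc_down",
        ],
    ).drop_duplicates()
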
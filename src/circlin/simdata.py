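"""Synthetic cohort generator with a ground-truth ledger.

Emulates the statistical structure the downstream analysis assumes:
negative-binomial backsplice and linear counts for a JMML discovery
cohort (8 PTPN11, 5 KRAS, 4 NRAS, 2 NF1 patients vs 3 healthy donors),
multi-method detection evidence with injected single-method artifacts,
a planted latent batch factor, planted fold changes including one
"hero" circRNA up-regulated roughly 100-fold (reproducing a marked,
>80x up-regulation), per-group circular-to-linear proportions, a
planted circRNA-miRNA-gene network with dual-predictor binding sites,
and an efficiency-aware qPCR Ct table for a 12 vs 6 validation cohort.

Every generated table is reproducible: the same :class:`SimParams`
(including seed) yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from circlin.iokit import CountAssay, SampleSheet, write_table

RNA = np.array(list("ACGU"))
_COMPLEMENT = str.maketrans("ACGU", "UGCA")

DEFAULT_GROUP_SIZES = {"PTPN11": 8, "KRAS": 5, "NRAS": 4, "NF1": 2, "HD": 3}


def revcomp_rna(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimParams:
    """Parameters of the synthetic cohort.

    Counts follow NB(mean, dispersion) with Var = mu + alpha*mu^2;
    per-feature dispersions are log-normal. ``batch_effect_sd`` is the
    scale (log2) of feature-specific loadings on a binary latent batch
    covariate. ``planted_hero_lfc`` defaults to 6.64 (~100-fold), a
    marked up-regulation exceeding the 80-fold scale of the study's
    standout circRNA.
    """

    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    m_circ: int = 300
    m_genes: int = 200
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    dispersion_log_mean: float = float(np.log(0.08))
    dispersion_log_sd: float = 0.5
    frac_de: float = 0.1
    lfc_abs: float = 2.0                  # |planted LFC| for DE circRNAs
    de_subtype: str | None = None         # restrict planted DE to one subtype
    planted_hero_lfc: float = 6.64
    frac_clp_shift: float = 0.1           # circRNAs with |LFC(CLP)| >= 1 planted
    batch_effect_sd: float = 1.0
    batch_confound: float = 0.0           # 0 = random batch; 1 = fully condition-aligned
    depth_log_sd: float = 0.3             # per-sample library-depth factor (log)
    n_methods: int = 9
    method_sensitivity: float = 0.8
    artifact_fraction: float = 0.1
    # network geometry
    n_planted_pairs: int = 10
    n_corr_genes: int = 8
    circ_seq_len: int = 500
    # validation-cohort qPCR
    n_val_jmml: int = 12
    n_val_hd: int = 6
    qpcr_efficiency: float = 2.0
    qpcr_bio_sd: float = 0.15             # log2 biological spread of expression
    qpcr_ct_noise_sd: float = 0.1         # cycles, technical noise
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.group_sizes.values()) < 2:
            raise ValueError("every group needs n >= 2 samples")
        if not 0 <= self.frac_de <= 1:
            raise ValueError("frac_de must be in [0, 1]")
        if self.m_circ < 1 or self.m_genes < 1:
            raise ValueError("m_circ and m_genes must be positive")


@dataclass
class GroundTruth:
    """Planted truth for every downstream stage.

    ``circ_info`` (indexed by circ_id): host gene, coordinates, true
    LFC (JMML vs HD, log2), DE flag, per-group CLP, hero flag.
    """

    circ_info: pd.DataFrame
    batch: pd.Series                       # sample -> +1/-1 latent batch sign
    hero_id: str
    planted_pairs: pd.DataFrame | None = None    # circ_id, mirna_id, n_sites
    planted_targets: pd.DataFrame | None = None  # mirna_id, gene_id, category
    expressed_mirnas: list[str] = field(default_factory=list)
    corr_genes: list[str] = field(default_factory=list)
    artifact_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def make_sample_sheet(group_sizes: dict[str, int]) -> SampleSheet:
    rows = []
    for group, n in group_sizes.items():
        for i in range(n):
            if group == "HD":
                rows.append((f"HD_{i + 1:02d}", "HD", "NA", "BM"))
            else:
                rows.append((f"JMML_{group}_{i + 1:02d}", "JMML", group, "BM"))
    df = pd.DataFrame(rows, columns=["sample_id", "condition", "subtype", "tissue"])
    return SampleSheet(df)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mean, dispersion alpha) with Var = mu + alpha*mu^2, via gamma-Poisson."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    shape = 1.0 / np.maximum(alpha, 1e-12)
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def simulate_counts(params: SimParams) -> tuple[CountAssay, GroundTruth]:
    """Generate circular/linear/gene count matrices plus ground truth."""
    rng = np.random.default_rng(params.seed)
    sheet = make_sample_sheet(params.group_sizes)
    samples = sheet.sample_ids
    n = len(samples)
    is_jmml = (sheet.frame["condition"] == "JMML").to_numpy()
    m = params.m_circ

    circ_ids, gene_ids, coords = [], [], []
    for i in range(m):
        chrom = f"chr{(i % 22) + 1}"
        start = 10_000 + (i // 22) * 100_000
        end = start + 2_000
        circ_ids.append(f"{chrom}:{start}-{end}:+")
        gene_ids.append("MCTP1" if i == 0 else f"HG{i:04d}")
        coords.append((chrom, start, end, "+"))
    hero_id = circ_ids[0]

    baseline = 2.0 ** rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, m)
    baseline[0] = max(baseline[0], 2.0 ** params.baseline_log2_mean)
    alpha = np.exp(rng.normal(params.dispersion_log_mean, params.dispersion_log_sd, m))

    true_lfc = np.zeros(m)
    n_de = int(round(params.frac_de * m))
    de_idx = rng.choice(np.arange(1, m), size=min(n_de, m - 1), replace=False)
    true_lfc[de_idx] = rng.choice([-1.0, 1.0], size=len(de_idx)) * params.lfc_abs
    true_lfc[0] = params.planted_hero_lfc
    is_de = true_lfc != 0

    if params.de_subtype is None:
        de_mask = is_jmml.astype(float)          # effect in all JMML samples
    else:
        de_mask = (sheet.frame["subtype"] == params.de_subtype).to_numpy(float)
        # the hero stays a JMML-wide effect
    effect = np.outer(true_lfc, de_mask)
    if params.de_subtype is not None:
        effect[0] = params.planted_hero_lfc * is_jmml

    # batch assignment: the +1 fraction per condition is 0.5 +/- confound/2,
    # allocated deterministically in count (never perfectly collinear with
    # condition, which would be unidentifiable) and randomly in membership
    batch_sign = np.full(n, -1.0)
    for cond_mask, frac in ((is_jmml, 0.5 + params.batch_confound / 2),
                            (~is_jmml, 0.5 - params.batch_confound / 2)):
        idx = np.flatnonzero(cond_mask)
        n_plus = int(round(frac * len(idx)))
        if 0 < params.batch_confound < 1:
            n_plus = min(max(n_plus, 1), len(idx) - 1)
        batch_sign[rng.choice(idx, size=n_plus, replace=False)] = 1.0
    batch_load = rng.normal(0.0, params.batch_effect_sd, m) if params.batch_effect_sd > 0 else np.zeros(m)
    depth = np.exp(rng.normal(0.0, params.depth_log_sd, n))

    log2_mu = (
        np.log2(baseline)[:, None]
        + effect
        + np.outer(batch_load, batch_sign)
        + np.log2(depth)[None, :]
    )
    circ_counts = _nb_draw(rng, 2.0 ** log2_mu, alpha[:, None])

    # per-group CLP: linear host-locus mean set so circ/(circ+lin) hits the target
    clp_hd = rng.uniform(0.05, 0.6, m)
    clp_jmml = clp_hd.copy()
    n_shift = int(round(params.frac_clp_shift * m))
    shift_idx = rng.choice(np.arange(1, m), size=min(n_shift, m - 1), replace=False)
    shift_dir = rng.choice([-1.0, 1.0], size=len(shift_idx))
    clp_jmml[shift_idx] = np.clip(
        clp_hd[shift_idx] * 2.0 ** (1.3 * shift_dir), 0.01, 0.95
    )
    circ_group_mean = {
        True: baseline * 2.0 ** true_lfc,   # JMML (hero/DE applied cohort-wide view)
        False: baseline,
    }
    lin_mu = np.empty((m, n))
    for j in range(n):
        clp = clp_jmml if is_jmml[j] else clp_hd
        cmean = circ_group_mean[bool(is_jmml[j])]
        lin_mu[:, j] = cmean * (1.0 - clp) / clp * depth[j]
    linear_counts = _nb_draw(rng, lin_mu, alpha[:, None])

    # network/TPM gene matrix; first n_corr_genes track the hero profile
    g_ids = [f"GENE{i:04d}" for i in range(params.m_genes)]
    g_base = 2.0 ** rng.normal(6.0, 1.0, params.m_genes)
    g_alpha = np.exp(rng.normal(params.dispersion_log_mean, params.dispersion_log_sd, params.m_genes))
    hero_log2 = np.log2(circ_counts[0] / depth + 1.0)
    # standardize within JMML: the correlated genes must track the hero
    # across patients, not merely across the JMML/HD divide
    j_mean = hero_log2[is_jmml].mean()
    j_sd = hero_log2[is_jmml].std() + 1e-12
    # clip: HD samples sit far below the JMML mean (the hero is strongly
    # up-regulated) and unbounded z-scores would overflow the NB means
    hero_std = np.clip((hero_log2 - j_mean) / j_sd, -4.0, 4.0)
    g_log2 = np.log2(g_base)[:, None] + rng.normal(0.0, 0.4, (params.m_genes, n))
    k = min(params.n_corr_genes, params.m_genes)
    g_base[:k] = np.maximum(g_base[:k], 2.0 ** 8)   # high depth: low NB noise
    g_alpha[:k] = np.minimum(g_alpha[:k], 0.02)
    g_log2[:k] = np.log2(g_base[:k])[:, None] + 2.0 * hero_std[None, :] + rng.normal(
        0.0, 0.15, (k, n)
    )
    gene_counts = _nb_draw(rng, 2.0 ** g_log2 * depth[None, :], g_alpha[:, None])
    # deliberately silent gene for the TPM-threshold path
    gene_counts[-1] = 0
    tpm = gene_counts / np.maximum(gene_counts.sum(axis=0, keepdims=True), 1) * 1e6

    circ_df = pd.DataFrame(circ_counts, index=circ_ids, columns=samples)
    lin_df = pd.DataFrame(linear_counts, index=gene_ids, columns=samples)
    tpm_df = pd.DataFrame(tpm, index=g_ids, columns=samples)
    assay = CountAssay(
        circ_counts=circ_df,
        linear_counts=lin_df,
        tpm=tpm_df,
        samples=sheet,
        circ_to_locus=dict(zip(circ_ids, gene_ids)),
    )

    info = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": [c[0] for c in coords],
            "start": [c[1] for c in coords],
            "end": [c[2] for c in coords],
            "strand": [c[3] for c in coords],
            "baseline": baseline,
            "true_lfc": true_lfc,
            "is_de": is_de,
            "clp_jmml": clp_jmml,
            "clp_hd": clp_hd,
            "is_hero": [i == 0 for i in range(m)],
        },
        index=pd.Index(circ_ids, name="circ_id"),
    )
    truth = GroundTruth(
        circ_info=info,
        batch=pd.Series(batch_sign, index=samples, name="batch"),
        hero_id=hero_id,
        corr_genes=g_ids[:k],
    )
    return assay, truth


# ---------------------------------------------------------------------------
# detection evidence
# ---------------------------------------------------------------------------


def simulate_detection_evidence(
    assay: CountAssay,
    truth: GroundTruth,
    params: SimParams,
) -> pd.DataFrame:
    """Per-method detection table by binomial thinning of true counts.

    Each of ``n_methods`` independently reports Binomial(count,
    sensitivity) reads for every expressed circRNA x sample; injected
    artifact circRNAs are reported by exactly one method (with >= 5
    reads, so only the multi-method consensus rule removes them).
    Updates ``truth.artifact_ids`` in place.
    """
    rng = np.random.default_rng(params.seed + 1)
    counts = assay.circ_counts
    mat = counts.to_numpy()
    m, n = mat.shape
    rows: list[tuple] = []
    for k in range(params.n_methods):
        reported = rng.binomial(mat, params.method_sensitivity)
        ii, jj = np.nonzero(reported)
        for i, j in zip(ii, jj):
            rows.append((counts.index[i], f"m{k + 1}", counts.columns[j], int(reported[i, j])))

    n_art = int(round(params.artifact_fraction * m))
    artifact_ids = []
    for a in range(n_art):
        start = 1_000 + a * 10_000
        cid = f"chrA:{start}-{start + 400}:+"
        artifact_ids.append(cid)
        method = f"m{rng.integers(1, params.n_methods + 1)}"
        n_samp = int(rng.integers(1, 4))
        for j in rng.choice(n, size=n_samp, replace=False):
            rows.append((cid, method, counts.columns[j], int(rng.integers(5, 21))))
    truth.artifact_ids = artifact_ids

    ev = pd.DataFrame(rows, columns=["circ_id", "method", "sample", "reads"])
    parts = ev["circ_id"].str.extract(r"(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+):(?P<strand>[+.-])")
    ev = pd.concat([parts, ev], axis=1)
    ev["start"] = ev["start"].astype(int)
    ev["end"] = ev["end"].astype(int)
    return ev[["chrom", "start", "end", "strand", "method", "sample", "reads", "circ_id"]]


# ---------------------------------------------------------------------------
# network inputs
# ---------------------------------------------------------------------------


def simulate_network_inputs(
    truth: GroundTruth, params: SimParams
) -> dict:
    """Binding-site tables, miRNA reference expression, validated
    targets, and toy sequences, with planted pairs that survive the
    whole reconstruction and decoys that each die at one specific gate.

    Returns a dict with keys ``sites_a``, ``sites_b``, ``mirna_expr``,
    ``targets``, ``circ_seqs``, ``mirna_seqs``. Updates ``truth``'s
    planted_pairs / planted_targets / expressed_mirnas / corr_genes
    consistency fields in place.
    """
    rng = np.random.default_rng(params.seed + 2)
    hero = truth.hero_id
    site_len = 16

    n_pairs = params.n_planted_pairs
    mirnas = [f"miR-{100 + i}-5p" for i in range(n_pairs)]
    # last two planted miRNAs are "recently identified": absent from the
    # reference series, kept only through the >= 3 common sites rule
    novel = set(mirnas[-2:])
    n_sites = rng.integers(1, 5, size=n_pairs)
    if n_pairs:
        n_sites[-2:] = np.maximum(n_sites[-2:], 3)
        n_sites[0] = 4   # a miR-8075-like configuration: four common sites

    # sites are laid out 24 nt apart (no cross-pair overlap); grow the
    # sequence when the planted geometry needs more room
    L = max(params.circ_seq_len, 20 + 24 * int(n_sites.sum()) + 80)
    circ_seq = "".join(rng.choice(RNA, size=L))
    mirna_seqs: dict[str, str] = {}
    sites_a, sites_b = [], []
    planted = []
    occupied = iter(range(20, L - 80, 24))
    for mi, (mir, ns) in enumerate(zip(mirnas, n_sites)):
        seq = "".join(rng.choice(RNA, size=22))
        mirna_seqs[mir] = seq
        seed_rc = revcomp_rna(seq[1:8])
        starts = [next(occupied) for _ in range(int(ns))]
        for p in starts:
            circ_seq = circ_seq[:p] + seed_rc + circ_seq[p + 7:]
            sites_a.append(
                (hero, mir, "A", p, p + site_len,
                 float(rng.uniform(110, 170)), float(rng.uniform(-30, -21)), np.nan, np.nan)
            )
            sites_b.append(
                (hero, mir, "B", p + 2, p + site_len + 4,
                 np.nan, np.nan, float(rng.uniform(-30, -21)), float(rng.uniform(-12, -5)))
            )
        planted.append((hero, mir, int(ns)))

    # decoys, each failing exactly one gate
    def _a(circ, mir, s, e, score, energy):
        sites_a.append((circ, mir, "A", s, e, score, energy, np.nan, np.nan))

    def _b(circ, mir, s, e, dd, do):
        sites_b.append((circ, mir, "B", s, e, np.nan, np.nan, dd, do))

    base = L - 40
    _a(hero, "miR-900-3p", base, base + 16, 99.0, -25.0)      # A score below 100
    _b(hero, "miR-900-3p", base + 2, base + 18, -25.0, -8.0)
    _a(hero, "miR-901-3p", base, base + 16, 140.0, -19.0)     # A energy above -20
    _b(hero, "miR-901-3p", base + 2, base + 18, -25.0, -8.0)
    _a(hero, "miR-902-3p", base, base + 16, 140.0, -25.0)     # B dG_duplex not < -20
    _b(hero, "miR-902-3p", base + 2, base + 18, -20.0, -8.0)
    _a(hero, "miR-903-3p", base, base + 16, 140.0, -25.0)     # B dG_open not > -13
    _b(hero, "miR-903-3p", base + 2, base + 18, -25.0, -13.0)
    _a(hero, "miR-904-3p", base, base + 16, 140.0, -25.0)     # predictor A only
    _a(hero, "miR-905-3p", 10, 26, 140.0, -25.0)              # no positional overlap
    _b(hero, "miR-905-3p", base, base + 16, -25.0, -8.0)
    for p in (base, base - 36):                               # 2 common sites but
        _a(hero, "miR-906-3p", p, p + 16, 140.0, -25.0)       # absent from reference
        _b(hero, "miR-906-3p", p + 2, p + 18, -25.0, -8.0)
    _a(hero, "miR-907-3p", base, base + 16, 140.0, -25.0)     # in reference, all-zero
    _b(hero, "miR-907-3p", base + 2, base + 18, -25.0, -8.0)

    cols = ["circ_id", "mirna_id", "predictor", "start", "end",
            "score", "energy", "dg_duplex", "dg_open"]
    sites_a_df = pd.DataFrame(sites_a, columns=cols)
    sites_b_df = pd.DataFrame(sites_b, columns=cols)

    # reference series: 21 JMML patients; planted non-novel miRNAs expressed
    ref_samples = [f"P{j + 1:02d}" for j in range(21)]
    expressed = [m for m in mirnas if m not in novel]
    expr_rows = {}
    for mir in expressed:
        vals = rng.poisson(50, size=21).astype(float)
        expr_rows[mir] = vals
    expr_rows["miR-907-3p"] = np.zeros(21)                    # present, not expressed
    mirna_expr = pd.DataFrame(expr_rows, index=ref_samples).T
    mirna_expr.index.name = "mirna_id"
    truth.expressed_mirnas = expressed

    # validated targets: strong rows to expressed genes; weak and silent decoys
    genes = list(truth.corr_genes)
    extra = [f"GENE{i:04d}" for i in range(params.n_corr_genes, params.n_corr_genes + 12)]
    pool = genes + extra
    t_rows = []
    planted_targets = []
    gi = 0
    for mir, _ in zip(mirnas, n_sites):
        for _ in range(2):
            g = pool[gi % len(pool)]
            gi += 1
            t_rows.append((mir, g, "Functional MTI"))
            planted_targets.append((mir, g, "Functional MTI"))
    if mirnas:
        t_rows.append((mirnas[0], "GENE0190", "Functional MTI (Weak)"))  # weak evidence
        t_rows.append((mirnas[1], f"GENE{params.m_genes - 1:04d}", "Functional MTI"))  # silent gene
    targets = pd.DataFrame(t_rows, columns=["mirna_id", "gene_id", "category"])

    truth.planted_pairs = pd.DataFrame(planted, columns=["circ_id", "mirna_id", "n_sites"])
    pt = pd.DataFrame(planted_targets, columns=["mirna_id", "gene_id", "category"])
    # the silent-gene decoy row must not be claimed as planted truth
    truth.planted_targets = pt[pt["gene_id"] != f"GENE{params.m_genes - 1:04d}"].reset_index(drop=True)

    return {
        "sites_a": sites_a_df,
        "sites_b": sites_b_df,
        "mirna_expr": mirna_expr,
        "targets": targets,
        "circ_seqs": {hero: circ_seq},
        "mirna_seqs": mirna_seqs,
    }


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def simulate_qpcr(
    truth: GroundTruth,
    params: SimParams,
    assays: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series, SampleSheet]:
    """Validation-cohort Ct table with per-assay efficiencies.

    Ct = intercept - log_E(expression) + sample offset + noise, where
    expression carries the planted JMML-vs-HD fold change. Reference
    assays TBP, HPRT1 and GAPDH have true LFC 0. Returns (long Ct
    table, efficiency Series, validation sample sheet).
    """
    rng = np.random.default_rng(params.seed + 3)
    subtype_cycle = ["PTPN11", "KRAS", "NRAS", "NF1", "5N"]
    rows = []
    for i in range(params.n_val_jmml):
        rows.append((f"VJ{i + 1:02d}", "JMML", subtype_cycle[i % 5], "BM"))
    for i in range(params.n_val_hd):
        rows.append((f"VH{i + 1:02d}", "HD", "NA", "BM"))
    sheet = SampleSheet(
        pd.DataFrame(rows, columns=["sample_id", "condition", "subtype", "tissue"]),
        allow_5n=True,
    )
    if assays is None:
        assays = [truth.hero_id]
    refs = ["TBP", "HPRT1", "GAPDH"]
    eff = pd.Series(
        {a: params.qpcr_efficiency for a in assays + refs}, name="efficiency"
    )

    is_jmml = (sheet.frame["condition"] == "JMML").to_numpy()
    sample_offset = rng.normal(0.0, 0.5, len(sheet))   # RNA input amount, cycles
    recs = []
    for assay_id in assays + refs:
        if assay_id in refs:
            lfc = 0.0
            intercept = 25.0
        else:
            lfc = float(truth.circ_info.loc[assay_id, "true_lfc"])
            intercept = 30.0
        log2_expr = lfc * is_jmml + rng.normal(0.0, params.qpcr_bio_sd, len(sheet))
        E = eff[assay_id]
        ct = (
            intercept
            - log2_expr * np.log(2.0) / np.log(E)
            + sample_offset
            + rng.normal(0.0, params.qpcr_ct_noise_sd, len(sheet))
        )
        for sid, c in zip(sheet.sample_ids, ct):
            recs.append((sid, assay_id, float(c)))
    ct_table = pd.DataFrame(recs, columns=["sample_id", "assay_id", "ct"])
    return ct_table, eff, sheet


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_simulation(out_dir: str | Path, params: SimParams) -> GroundTruth:
    """Run the full generator and write every input table plus the
    ground-truth ledger to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    assay, truth = simulate_counts(params)
    evidence = simulate_detection_evidence(assay, truth, params)
    net = simulate_network_inputs(truth, params)
    ct, eff, vsheet = simulate_qpcr(truth, params)

    write_table(assay.circ_counts, out / "circ_counts.tsv")
    write_table(assay.linear_counts, out / "linear_counts.tsv")
    write_table(assay.tpm, out / "tpm.tsv")
    write_table(assay.samples.frame, out / "samples.tsv")
    evidence.drop(columns="circ_id").to_csv(out / "detection_evidence.tsv", sep="\t", index=False)
    net["sites_a"].to_csv(out / "sites_a.tsv", sep="\t", index=False)
    net["sites_b"].to_csv(out / "sites_b.tsv", sep="\t", index=False)
    write_table(net["mirna_expr"], out / "mirna_expression.tsv")
    net["targets"].to_csv(out / "validated_targets.tsv", sep="\t", index=False)
    with open(out / "circ_sequences.fa", "w") as fh:
        for cid, seq in net["circ_seqs"].items():
            fh.write(f">{cid}\n{seq}\n")
        for mid, seq in net["mirna_seqs"].items():
            fh.write(f">{mid}\n{seq}\n")
    ct.to_csv(out / "qpcr_ct.tsv", sep="\t", index=False)
    eff.rename_axis("assay_id").reset_index().to_csv(out / "qpcr_efficiencies.tsv", sep="\t", index=False)
    write_table(vsheet.frame, out / "validation_samples.tsv")
    write_table(truth.circ_info, out / "ground_truth.tsv")
    truth.batch.rename_axis("sample_id").reset_index().to_csv(out / "ground_truth_batch.tsv", sep="\t", index=False)
    return truth
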
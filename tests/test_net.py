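import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circlin import net
from circlin.circdetect import AnnotationIndex
from circlin.iokit import CircRNA, Config, GenomicInterval, SampleSheet, ValidationError
from circlin.simdata import revcomp_rna

COLS = ["circ_id", "mirna_id", "predictor", "start", "end", "score", "energy", "dg_duplex", "dg_open"]


def _a(mir, s, e, score, energy, circ="c1"):
    return (circ, mir, "A", s, e, score, energy, np.nan, np.nan)


def _b(mir, s, e, dd, do, circ="c1"):
    return (circ, mir, "B", s, e, np.nan, np.nan, dd, do)


def _sites(rows):
    return pd.DataFrame(rows, columns=COLS)


class TestSiteThresholdBoundaries:
    """Boundary semantics of all predictor thresholds, exactly as printed."""

    def test_a_score_boundary_inclusive(self):
        kept = net.filter_sites(_sites([_a("m", 0, 16, 100.0, -20.0)]))
        assert len(kept) == 1
        dropped = net.filter_sites(_sites([_a("m", 0, 16, 99.999, -25.0)]))
        assert dropped.empty

    def test_a_energy_boundary_inclusive(self):
        assert len(net.filter_sites(_sites([_a("m", 0, 16, 120.0, -20.0)]))) == 1
        assert net.filter_sites(_sites([_a("m", 0, 16, 120.0, -19.999)])).empty

    def test_b_duplex_boundary_strict(self):
        assert net.filter_sites(_sites([_b("m", 0, 16, -20.0, -5.0)])).empty
        assert len(net.filter_sites(_sites([_b("m", 0, 16, -20.001, -5.0)]))) == 1

    def test_b_open_boundary_strict(self):
        assert net.filter_sites(_sites([_b("m", 0, 16, -25.0, -13.0)])).empty
        assert len(net.filter_sites(_sites([_b("m", 0, 16, -25.0, -12.999)]))) == 1

    def test_missing_fields_rejected(self):
        bad = _sites([_a("m", 0, 16, 120.0, -25.0)])
        bad.loc[0, "energy"] = np.nan
        with pytest.raises(ValidationError):
            net.filter_sites(bad)


class TestIntersect:
    def test_overlap_forced(self):
        pairs = net.intersect_predictors(
            _sites([_a("m", 10, 26, 120, -25)]), _sites([_b("m", 12, 28, -25, -5)])
        )
        assert pairs.iloc[0]["n_sites"] == 1

    def test_disjoint_dropped(self):
        pairs = net.intersect_predictors(
            _sites([_a("m", 10, 26, 120, -25)]), _sites([_b("m", 50, 66, -25, -5)])
        )
        assert pairs.empty

    def test_four_disjoint_common_sites(self):
        a = _sites([_a("m", 40 * i, 40 * i + 16, 120, -25) for i in range(1, 5)])
        b = _sites([_b("m", 40 * i + 2, 40 * i + 18, -25, -5) for i in range(1, 5)])
        assert net.intersect_predictors(a, b).iloc[0]["n_sites"] == 4

    def test_staggered_sites_merged_not_double_counted(self):
        a = _sites([_a("m", 10, 26, 120, -25), _a("m", 18, 34, 120, -25)])
        b = _sites([_b("m", 12, 30, -25, -5)])
        assert net.intersect_predictors(a, b).iloc[0]["n_sites"] == 1

    def test_matches_bruteforce_on_random_fixture(self, rng):
        n = 10_000
        circs = [f"c{i}" for i in range(20)]
        mirs = [f"m{i}" for i in range(30)]
        rows_a, rows_b = [], []
        for _ in range(n // 2):
            s = int(rng.integers(0, 2000))
            rows_a.append(_a(rng.choice(mirs), s, s + 16, 120, -25, circ=rng.choice(circs)))
            s = int(rng.integers(0, 2000))
            rows_b.append(_b(rng.choice(mirs), s, s + 18, -25, -5, circ=rng.choice(circs)))
        a, b = _sites(rows_a), _sites(rows_b)
        got = net.intersect_predictors(a, b).set_index(["circ_id", "mirna_id"])["n_sites"].to_dict()

        brute = {}
        b_idx = {}
        for r in rows_b:
            b_idx.setdefault((r[0], r[1]), []).append((r[3], r[4]))
        for key, sub in a.groupby(["circ_id", "mirna_id"]):
            ivs = []
            for _, r in sub.iterrows():
                for bs, be in b_idx.get(key, []):
                    if r.start < be and bs < r.end:
                        ivs.append((r.start, r.end))
                        break
            if ivs:
                merged = []
                for s, e in sorted(set(ivs)):
                    if merged and s < merged[-1][1]:
                        merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                    else:
                        merged.append((s, e))
                brute[key] = len(merged)
        assert got == brute


class TestPrioritize:
    def _expr(self):
        # m_ex expressed, m_zero present-but-silent
        data = {"m_ex": np.ones(20) * 10, "m_zero": np.zeros(20)}
        return pd.DataFrame(data, index=[f"P{i}" for i in range(20)]).T

    def test_expressed_kept_even_with_one_site(self):
        pairs = pd.DataFrame([("c1", "m_ex", 1)], columns=["circ_id", "mirna_id", "n_sites"])
        assert len(net.prioritize_mirnas(pairs, self._expr())) == 1

    def test_absent_needs_three_sites(self):
        pairs = pd.DataFrame(
            [("c1", "m_new", 3), ("c1", "m_new2", 2)],
            columns=["circ_id", "mirna_id", "n_sites"],
        )
        out = net.prioritize_mirnas(pairs, self._expr())
        assert list(out["mirna_id"]) == ["m_new"]

    def test_present_but_silent_dropped(self):
        pairs = pd.DataFrame([("c1", "m_zero", 4)], columns=["circ_id", "mirna_id", "n_sites"])
        assert net.prioritize_mirnas(pairs, self._expr()).empty


class TestTargets:
    def test_strong_kept_weak_dropped_unknown_warned(self):
        table = pd.DataFrame(
            [
                ("m1", "G1", "Functional MTI"),
                ("m1", "G2", "Functional MTI (Weak)"),
                ("m1", "G3", "Mystery Evidence"),
            ],
            columns=["mirna_id", "gene_id", "category"],
        )
        out = net.attach_validated_targets(["m1"], table)
        assert list(out["gene_id"]) == ["G1"]

    def test_mirna_without_targets_ok(self):
        table = pd.DataFrame(columns=["mirna_id", "gene_id", "category"])
        assert net.attach_validated_targets(["m1"], table).empty


class TestTpmFilter:
    def _setup(self, tpm_values):
        sheet = SampleSheet(pd.DataFrame(
            [("J1", "JMML", "KRAS", "BM"), ("J2", "JMML", "KRAS", "BM"),
             ("H1", "HD", "NA", "BM")],
            columns=["sample_id", "condition", "subtype", "tissue"],
        ))
        tpm = pd.DataFrame(
            {g: {"J1": v, "J2": v, "H1": 0.0} for g, v in tpm_values.items()}
        ).T
        edges = pd.DataFrame(
            [("m1", g, "Functional MTI") for g in tpm_values],
            columns=["mirna_id", "gene_id", "category"],
        )
        return edges, tpm, sheet

    def test_strictly_greater_than_one(self):
        edges, tpm, sheet = self._setup({"hi": 1.01, "edge": 1.00, "lo": 0.5})
        out = net.filter_expressed_genes(edges, tpm, sheet)
        assert list(out["gene_id"]) == ["hi"]

    def test_gene_absent_from_matrix_dropped(self):
        edges, tpm, sheet = self._setup({"hi": 2.0})
        edges = pd.concat(
            [edges, pd.DataFrame([("m1", "ghost", "Functional MTI")], columns=edges.columns)]
        )
        out = net.filter_expressed_genes(edges, tpm, sheet)
        assert "ghost" not in set(out["gene_id"])


def _avg_rank(v):
    """Average ranks with ties, written independently of scipy."""
    v = np.asarray(v, float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i: j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


class TestCorrelation:
    def _sheet(self, n):
        return SampleSheet(pd.DataFrame(
            [(f"J{i}", "JMML", "KRAS", "BM") for i in range(n)],
            columns=["sample_id", "condition", "subtype", "tissue"],
        ))

    def test_monotone_transform_is_one(self):
        sheet = self._sheet(6)
        circ = pd.Series(np.arange(6, dtype=float), index=sheet.sample_ids)
        genes = pd.DataFrame([np.exp(np.arange(6))], index=["g"], columns=sheet.sample_ids)
        out = net.correlate_with_circ(circ, genes, sheet)
        assert out.loc["g", "rho"] == pytest.approx(1.0)

    def test_reversed_profile_is_minus_one(self):
        sheet = self._sheet(6)
        circ = pd.Series(np.arange(6, dtype=float), index=sheet.sample_ids)
        genes = pd.DataFrame([-np.arange(6, dtype=float)], index=["g"], columns=sheet.sample_ids)
        assert net.correlate_with_circ(circ, genes, sheet).loc["g", "rho"] == pytest.approx(-1.0)

    def test_zero_variance_flagged_missing(self):
        sheet = self._sheet(5)
        circ = pd.Series(np.arange(5, dtype=float), index=sheet.sample_ids)
        genes = pd.DataFrame([np.ones(5)], index=["g"], columns=sheet.sample_ids)
        out = net.correlate_with_circ(circ, genes, sheet)
        assert np.isnan(out.loc["g", "rho"]) and not out.loc["g", "correlated"]

    def test_matches_rank_based_oracle(self, rng):
        sheet = self._sheet(12)
        circ = pd.Series(rng.integers(0, 6, 12).astype(float), index=sheet.sample_ids)
        genes = pd.DataFrame(
            rng.integers(0, 6, size=(40, 12)).astype(float),
            index=[f"g{i}" for i in range(40)], columns=sheet.sample_ids,
        )
        out = net.correlate_with_circ(circ, genes, sheet)
        rx = _avg_rank(circ.to_numpy())
        for g in genes.index:
            ry = _avg_rank(genes.loc[g].to_numpy())
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert abs(out.loc[g, "rho"] - oracle) < 1e-12


class TestSequenceAssembly:
    def _annotation(self):
        rows = [
            ("G1", "t1", 1, "chr1", 100, 110, "+"),
            ("G1", "t1", 2, "chr1", 150, 160, "+"),
            ("G1", "t1", 3, "chr1", 200, 230, "+"),
        ]
        return AnnotationIndex.from_exon_table(
            pd.DataFrame(rows, columns=["gene_id", "transcript_id", "exon_number", "chrom", "start", "end", "strand"])
        )

    def _genome(self, rng):
        return {"chr1": "".join(rng.choice(list("ACGT"), size=400))}

    def test_two_exon_length_arithmetic(self, rng):
        ann = self._annotation()
        genome = self._genome(rng)
        circ = CircRNA(GenomicInterval("chr1", 100, 160, "+"), ["G1"], "exonic", "G1", "1-2")
        cfg = Config(max_site_len=8)
        seq = net.assemble_circ_sequence(circ, ann, genome, cfg)
        assert seq.core_length == 20
        assert len(seq.sequence) == 27          # 20 + (8 - 1)
        assert seq.sequence[20:] == seq.sequence[:7]

    def test_minus_strand_is_reverse_complement(self, rng):
        ann_rows = [("G2", "t1", 1, "chr1", 100, 130, "-")]
        ann = AnnotationIndex.from_exon_table(
            pd.DataFrame(ann_rows, columns=["gene_id", "transcript_id", "exon_number", "chrom", "start", "end", "strand"])
        )
        genome = self._genome(rng)
        plus = CircRNA(GenomicInterval("chr1", 100, 130, "+"), ["G2"], "exonic", "G2", "1")
        minus = CircRNA(GenomicInterval("chr1", 100, 130, "-"), ["G2"], "exonic", "G2", "1")
        cfg = Config(max_site_len=1)
        s_plus = net.assemble_circ_sequence(plus, ann, genome, cfg).sequence
        s_minus = net.assemble_circ_sequence(minus, ann, genome, cfg).sequence
        assert s_minus == revcomp_rna(s_plus)

    def test_junction_spanning_site_needs_extension(self):
        # seed complement split across the backsplice junction: the last 4 nt
        # of the circle followed by its first 3 nt
        mir = {"mirX": "UCGUACGUACGUACGUACGUAC"}
        probe = revcomp_rna(mir["mirX"][1:8])
        core = probe[4:7] + "A" * 23 + probe[:4]
        assert net.toy_seed_scan(core, mir).empty
        extended = core + core[:7]
        hits = net.toy_seed_scan(extended, mir)
        assert list(hits["start"]) == [len(core) - 4]

    def test_scan_finds_planted_seed(self):
        mir = {"mirX": "ACGUACGUACGUACGUACGUAC"}
        probe = revcomp_rna(mir["mirX"][1:8])
        seq = "A" * 40 + probe + "A" * 40
        hits = net.toy_seed_scan(seq, mir)
        assert list(hits["start"]) == [40]

    def test_scan_rejects_dna_alphabet(self):
        with pytest.raises(ValidationError):
            net.toy_seed_scan("ACGTACGT", {"m": "ACGUACG"})


class TestEndToEnd:
    def test_planted_network_recovered(self, default_sim, network_inputs):
        _, assay, truth = default_sim
        from circlin.diffexpr import size_factors

        hero_expr = assay.circ_counts.loc[truth.hero_id] / size_factors(assay.circ_counts)
        graph, pairs, edges = net.reconstruct(
            network_inputs["sites_a"], network_inputs["sites_b"],
            network_inputs["mirna_expr"], network_inputs["targets"],
            assay.tpm, assay.samples,
            circ_expr=hero_expr,
        )
        got_pairs = set(map(tuple, pairs[["circ_id", "mirna_id"]].to_numpy()))
        want_pairs = set(map(tuple, truth.planted_pairs[["circ_id", "mirna_id"]].to_numpy()))
        assert got_pairs == want_pairs
        got_edges = set(map(tuple, edges[["mirna_id", "gene_id"]].to_numpy()))
        want_edges = set(map(tuple, truth.planted_targets[["mirna_id", "gene_id"]].to_numpy()))
        assert got_edges == want_edges
        # graph is tripartite: circ -> miRNA -> gene only
        kinds = {n: d["kind"] for n, d in graph.nodes(data=True)}
        for u, v in graph.edges:
            assert (kinds[u], kinds[v]) in {("circRNA", "miRNA"), ("miRNA", "gene")}

    def test_correlated_genes_flagged(self, default_sim):
        _, assay, truth = default_sim
        from circlin.diffexpr import size_factors

        hero_expr = assay.circ_counts.loc[truth.hero_id] / size_factors(assay.circ_counts)
        corr = net.correlate_with_circ(
            hero_expr, assay.tpm.loc[truth.corr_genes], assay.samples,
        )
        assert corr["correlated"].all()

    def test_no_pairs_yields_valid_empty_graph(self, tmp_path):
        graph = net.build_network(
            pd.DataFrame(columns=["circ_id", "mirna_id", "n_sites"]),
            pd.DataFrame(columns=["mirna_id", "gene_id", "category"]),
        )
        assert graph.number_of_nodes() == 0
        from circlin.iokit import write_network

        write_network(graph, tmp_path / "empty.graphml", "graphml")
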
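"""Association scans, FDR selection, QTL intervals, pleiotropy, gene overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gxemap import gwas
from gxemap import simulate as sim
from gxemap.gwas import QTLInterval
from oracles import bh_oracle, qtl_boundaries_oracle


@pytest.fixture(scope="module")
def blues_with_qtl(numeric_population, population):
    """Stacked BLUE table with one persistent and one crossover QTL."""
    rng = np.random.default_rng(41)
    M = numeric_population.numeric
    n, E = M.shape[0], 7
    h = np.array([4.0, 1.0, 2.5, -0.5, -1.5, -2.0, -3.5])
    h = h - h.mean()
    poly = M[:, ::5] @ rng.normal(0, 0.15, M[:, ::5].shape[1])
    pers, cross = 60, 220
    eff_cross = np.array([0.6, 0.6, 0.6, 0.6, -0.8, -0.8, -0.8])
    Y = np.empty((n, E))
    for j in range(E):
        Y[:, j] = (10 + h[j] + poly + 0.6 * M[:, pers]
                   + eff_cross[j] * M[:, cross] + rng.normal(0, 1.0, n))
    blues = pd.DataFrame(Y, index=population.lines,
                         columns=[f"E{j}" for j in range(E)])
    return blues, pers, cross, eff_cross


class TestScanQk:
    def test_perfect_signal_is_scan_minimum(self, numeric_population, pcs, kinship,
                                            population):
        M = numeric_population.numeric
        y = M[:, 37].astype(float)
        res = gwas.scan_qk(y, M, pcs, kinship, markers=population.markers)
        assert int(np.nanargmin(res["p"].to_numpy())) == 37

    def test_null_pvalues_uniform(self, numeric_population, pcs, kinship):
        # no-QTL null: phenotype independent of every marker
        rng = np.random.default_rng(42)
        M = numeric_population.numeric
        y = rng.normal(size=M.shape[0])
        res = gwas.scan_qk(y, M, pcs, kinship)
        p = res["p"].dropna().to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_polygenic_confounding_controlled(self, numeric_population, pcs,
                                              kinship, population):
        # phenotype from chromosome-1 markers; unlinked chromosome-2 markers
        # share the family structure, so the Q+K correction must keep the
        # false-positive rate at or below nominal (conservative is fine)
        rng = np.random.default_rng(42)
        M = numeric_population.numeric
        chrom = population.markers["chrom"].to_numpy()
        c1 = np.flatnonzero(chrom == "chr1")
        c2 = np.flatnonzero(chrom == "chr2")
        y = M[:, c1] @ rng.normal(0, 0.2, c1.size) + rng.normal(0, 1.0, M.shape[0])
        res = gwas.scan_qk(y, M[:, c2], pcs, kinship)
        p = res["p"].dropna().to_numpy()
        assert (p < 0.05).mean() <= 0.08

    def test_monomorphic_marker_skipped(self, numeric_population, pcs, kinship):
        M = numeric_population.numeric.copy()
        M[:, 0] = 1.0
        rng = np.random.default_rng(43)
        res = gwas.scan_qk(rng.normal(size=M.shape[0]), M[:, :5], pcs, kinship)
        assert np.isnan(res["p"].iloc[0])
        assert res["p"].iloc[1:].notna().all()


class TestScanGxe:
    def test_persistent_qtl_main_significant_interaction_not(
            self, blues_with_qtl, numeric_population, pcs, kinship):
        blues, pers, cross, _ = blues_with_qtl
        sc = gwas.scan_gxe(blues, numeric_population.numeric, pcs, kinship)
        assert sc.table["p_main"].iloc[pers] < 1e-4
        assert sc.table["p_gxe"].iloc[pers] > 0.05

    def test_crossover_qtl_interaction_significant(self, blues_with_qtl,
                                                   numeric_population, pcs, kinship):
        blues, pers, cross, eff = blues_with_qtl
        sc = gwas.scan_gxe(blues, numeric_population.numeric, pcs, kinship)
        assert sc.table["p_gxe"].iloc[cross] < 1e-6
        # per-environment GGE effects recover the planted sign pattern
        got = gwas.gge_env_effects(sc, cross)["effect"].to_numpy()
        assert (np.sign(got) == np.sign(eff)).sum() >= 6

    def test_gge_effects_average_to_gamma(self, blues_with_qtl,
                                          numeric_population, pcs, kinship):
        blues, pers, *_ = blues_with_qtl
        sc = gwas.scan_gxe(blues, numeric_population.numeric, pcs, kinship)
        for k in range(0, 200, 40):
            eff = sc.env_effects[k]
            assert eff.mean() == pytest.approx(sc.table["gamma"].iloc[k], abs=1e-8)

    def test_null_marker_both_tests_calibrated(self, numeric_population, pcs,
                                               kinship, population):
        # no-QTL null: uniform p-values for both the main and the
        # interaction test
        rng = np.random.default_rng(44)
        M = numeric_population.numeric
        n, E = M.shape[0], 7
        Y = rng.normal(0, 1.0, (n, E))
        blues = pd.DataFrame(Y, index=population.lines,
                             columns=[f"E{j}" for j in range(E)])
        sc = gwas.scan_gxe(blues, M, pcs, kinship)
        for col in ("p_main", "p_gxe"):
            p = sc.table[col].dropna().to_numpy()
            assert stats.kstest(p, "uniform").pvalue > 0.01
            assert (p < 0.05).mean() < 0.10

    def test_incomplete_table_rejected(self, numeric_population, pcs, kinship,
                                       population):
        Y = np.zeros((234, 7))
        Y[0, 0] = np.nan
        blues = pd.DataFrame(Y, index=population.lines,
                             columns=[f"E{j}" for j in range(7)])
        with pytest.raises(ValueError, match="complete"):
            gwas.scan_gxe(blues, numeric_population.numeric, pcs, kinship)


class TestFdrSelect:
    def test_hand_list(self):
        sel = gwas.fdr_select(np.array([0.001, 0.02, 0.8]), alpha=0.05)
        assert list(sel) == [0, 1]  # 0.02 <= 2 * 0.05 / 3

    def test_all_ones_empty(self):
        assert gwas.fdr_select(np.ones(10)).size == 0

    def test_saturation(self):
        assert gwas.fdr_select(np.full(7, 1e-10)).size == 7

    def test_empty_input(self):
        assert gwas.fdr_select(np.array([])).size == 0

    def test_matches_textbook_oracle(self):
        rng = np.random.default_rng(45)
        for _ in range(20):
            p = np.concatenate([rng.uniform(0, 1, 50), rng.uniform(0, 1e-3, 5)])
            assert list(gwas.fdr_select(p)) == list(bh_oracle(p, 0.05))


class TestDelimitQtl:
    def test_perfect_ld_block_spans_all_members(self):
        rng = np.random.default_rng(46)
        col = rng.choice([-1.0, 1.0], 80)
        M = np.column_stack([col] * 10 + [rng.choice([-1.0, 1.0], 80) for _ in range(5)])
        markers = pd.DataFrame({
            "marker": [f"m{k}" for k in range(15)],
            "chrom": ["c1"] * 15,
            "pos": np.arange(15) * 1000,
        })
        pvals = np.ones(15)
        pvals[4] = 1e-8
        out = gwas.delimit_qtl(np.array([4]), pvals, M, markers)
        assert len(out) == 1
        assert out[0].start == 0 and out[0].end == 9000
        assert len(out[0].members) == 10

    def test_unlinked_lead_single_marker_interval(self):
        rng = np.random.default_rng(47)
        M = np.column_stack([rng.choice([-1.0, 1.0], 500) for _ in range(7)])
        markers = pd.DataFrame({"marker": [f"m{k}" for k in range(7)],
                                "chrom": ["c1"] * 7, "pos": np.arange(7) * 100})
        pvals = np.ones(7)
        pvals[3] = 1e-9
        out = gwas.delimit_qtl(np.array([3]), pvals, M, markers)
        assert out[0].start == out[0].end == 300
        assert out[0].members == ["m3"]

    def test_boundaries_match_allpairs_oracle(self, numeric_population, population):
        M = numeric_population.numeric
        markers = population.markers
        pvals = np.ones(M.shape[1])
        for lead in (40, 120, 260):
            pvals_ = pvals.copy()
            pvals_[lead] = 1e-7
            out = gwas.delimit_qtl(np.array([lead]), pvals_, M, markers,
                                   window=11e6, r2_min=0.2)
            start, end = qtl_boundaries_oracle(
                M, markers["pos"].to_numpy(), markers["chrom"].to_numpy(),
                lead, 11e6, 0.2)
            assert (out[0].start, out[0].end) == (start, end)

    def test_covered_significant_markers_claimed(self, numeric_population, population):
        M = numeric_population.numeric
        markers = population.markers
        pvals = np.ones(M.shape[1])
        pvals[50] = 1e-9
        pvals[51] = 1e-6  # linked neighbour
        out = gwas.delimit_qtl(np.array([50, 51]), pvals, M, markers)
        r2 = np.corrcoef(M[:, 50], M[:, 51])[0, 1] ** 2
        if r2 >= 0.2:
            assert len(out) == 1


def _qtl(chrom, start, end, lead, name="q"):
    return QTLInterval(trait="t", phenotype_type="blue", chrom=chrom,
                       lead_marker=name, lead_pos=lead, lead_p=1e-8,
                       start=start, end=end, members=[name])


class TestMergePleiotropic:
    def test_close_peaks_merged(self):
        a = _qtl("c1", 1_000_000, 1_200_000, 1_100_000)
        b = _qtl("c1", 1_500_000, 1_700_000, 1_600_000)  # peaks 0.5 Mb apart
        groups = gwas.merge_pleiotropic([a, b])
        assert len(groups) == 1

    def test_distant_disjoint_separate(self):
        a = _qtl("c1", 1_000_000, 1_100_000, 1_050_000)
        b = _qtl("c1", 3_000_000, 3_100_000, 3_050_000)
        assert len(gwas.merge_pleiotropic([a, b])) == 2

    def test_transitive_chain(self):
        a = _qtl("c1", 1_000_000, 1_400_000, 1_200_000)
        b = _qtl("c1", 1_300_000, 1_800_000, 1_500_000)
        c = _qtl("c1", 1_700_000, 2_200_000, 2_000_000)
        groups = gwas.merge_pleiotropic([a, b, c])
        assert len(groups) == 1 and len(groups[0]) == 3

    def test_different_chromosomes_never_merge(self):
        a = _qtl("c1", 1, 100, 50)
        b = _qtl("c2", 1, 100, 50)
        assert len(gwas.merge_pleiotropic([a, b])) == 2


class TestOverlapGenes:
    @pytest.fixture(scope="class")
    def genes(self):
        return sim.make_gene_models({"chr1": 5_000_000}, n_genes_per_chrom=50, seed=48)

    def test_contained_and_straddling_genes_returned(self, genes):
        g = genes[genes["type"] == "gene"].iloc[3]
        iv = _qtl(g.chrom, g.start - 100, g.start + 10, g.start)  # straddles start
        assert g.gene_id in gwas.overlap_genes(iv, genes)
        iv2 = _qtl(g.chrom, g.start - 100, g.end + 100, g.start)  # contains
        assert g.gene_id in gwas.overlap_genes(iv2, genes)

    def test_matches_bruteforce_intersection(self, genes):
        gene_rows = genes[genes["type"] == "gene"]
        iv = _qtl("chr1", 1_000_000, 2_500_000, 1_500_000)
        expected = [r.gene_id for r in gene_rows.itertuples(index=False)
                    if r.start <= iv.end and r.end >= iv.start]
        assert gwas.overlap_genes(iv, genes) == expected

    def test_interval_invariant(self):
        with pytest.raises(ValueError, match="inside"):
            _qtl("c1", 100, 200, 300)
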
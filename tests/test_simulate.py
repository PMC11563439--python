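import numpy as np
import pytest
from scipy import stats

from gsblr.simulate import (
    GeneSetTruth,
    SimulationScenario,
    build_gene_map,
    build_genes_and_sets,
    build_overlapping_sets,
    compute_gene_ld,
    gwas_scan,
    scenario_grid,
    simulate_effects,
    simulate_genotypes,
    simulate_phenotype,
)


class TestScenario:
    def test_binary_requires_prevalence(self):
        with pytest.raises(ValueError):
            SimulationScenario(0.3, 0.01, "GA1", "binary")

    def test_prevalence_forbidden_for_quantitative(self):
        with pytest.raises(ValueError):
            SimulationScenario(0.3, 0.01, "GA1", "quantitative", prevalence=0.05)

    def test_grid_has_8_quantitative_and_16_binary_cells(self):
        grid = scenario_grid()
        quant = [s for s in grid if s.trait_type == "quantitative"]
        binary = [s for s in grid if s.trait_type == "binary"]
        assert len(quant) == 8 and len(binary) == 16
        assert len({(s.h2, s.causal_prop, s.architecture) for s in quant}) == 8
        assert len(
            {(s.h2, s.causal_prop, s.architecture, s.prevalence) for s in binary}
        ) == 16


class TestGenotypes:
    def test_seed_determinism(self):
        G1, m1 = simulate_genotypes(200, 100, seed=5)
        G2, m2 = simulate_genotypes(200, 100, seed=5)
        assert np.array_equal(G1, G2)
        assert m1.equals(m2)

    def test_maf_within_tolerance(self):
        G, meta = simulate_genotypes(5000, 200, seed=1)
        emp_maf = G.mean(axis=0) / 2
        emp_maf = np.minimum(emp_maf, 1 - emp_maf)
        assert emp_maf.min() >= 0.01 - 0.02
        assert emp_maf.max() <= 0.5 + 0.02

    def test_ld_decays_within_block_and_vanishes_across(self):
        G, meta = simulate_genotypes(4000, 100, ld_block_size=50, ld_rho=0.8, seed=2)
        Gs = G.astype(float)
        corr = np.corrcoef(Gs, rowvar=False)
        adjacent = np.mean([corr[i, i + 1] for i in range(0, 49)])
        distant = np.mean([corr[i, i + 10] for i in range(0, 40)])
        cross = np.mean([corr[i, i + 50] for i in range(0, 50)])
        assert adjacent > distant > 0
        assert abs(cross) < 3 / np.sqrt(4000)

    def test_dosages_are_0_1_2(self):
        G, _ = simulate_genotypes(100, 50, seed=3)
        assert set(np.unique(G)) <= {0, 1, 2}


class TestEffects:
    def test_causal_count_near_binomial_expectation(self):
        _, causal = simulate_effects(100_000, 0.001, "GA1", seed=4)
        assert 60 <= causal.size <= 140  # 100 +- ~4 sd

    def test_architecture_tails(self):
        b1, c1 = simulate_effects(100_000, 0.5, "GA1", seed=5)
        b2, c2 = simulate_effects(100_000, 0.5, "GA2", seed=5)
        k1 = stats.kurtosis(b1[c1], fisher=True)
        k2 = stats.kurtosis(b2[c2], fisher=True)
        assert abs(k1) < 0.2          # normal
        assert k2 > 1.0               # scale mixture is heavy-tailed

    def test_seed_determinism(self):
        assert np.array_equal(
            simulate_effects(1000, 0.01, "GA2", seed=6)[0],
            simulate_effects(1000, 0.01, "GA2", seed=6)[0],
        )


class TestPhenotype:
    def test_realized_heritability_close_to_target(self):
        scen = SimulationScenario(0.3, 0.01, "GA1", "quantitative",
                                  n_ind=10_000, n_snp=500, seed=7)
        G, _ = simulate_genotypes(10_000, 500, seed=7)
        beta, _ = simulate_effects(500, 0.01, "GA1", seed=8)
        y, _ = simulate_phenotype(G, beta, scen)
        Gs = G.astype(float)
        Gs = (Gs - Gs.mean(0)) / np.where(Gs.std(0) == 0, 1, Gs.std(0))
        g = Gs @ beta
        h2 = np.var(g) / np.var(y)
        assert h2 == pytest.approx(0.3, abs=0.02)

    def test_binary_case_fraction_exact(self):
        scen = SimulationScenario(0.3, 0.05, "GA1", "binary", prevalence=0.15,
                                  n_ind=2000, n_snp=200, seed=9)
        G, _ = simulate_genotypes(2000, 200, seed=9)
        beta, _ = simulate_effects(200, 0.05, "GA1", seed=10)
        y, liab = simulate_phenotype(G, beta, scen)
        assert y.mean() == pytest.approx(0.15, abs=1e-9)
        assert set(np.unique(y)) == {0.0, 1.0}

    def test_high_heritability_tracks_genetic_value(self):
        scen = SimulationScenario(0.99, 0.2, "GA1", "quantitative",
                                  n_ind=1000, n_snp=100, seed=11)
        G, _ = simulate_genotypes(1000, 100, seed=11)
        beta, _ = simulate_effects(100, 0.2, "GA1", seed=12)
        y, _ = simulate_phenotype(G, beta, scen)
        Gs = G.astype(float)
        Gs = (Gs - Gs.mean(0)) / np.where(Gs.std(0) == 0, 1, Gs.std(0))
        assert np.corrcoef(y, Gs @ beta)[0, 1] > 0.99


class TestGwasScan:
    def test_folds_partition_individuals(self):
        G, meta = simulate_genotypes(500, 50, seed=13)
        y = np.random.default_rng(14).standard_normal(500)
        folds = gwas_scan(G, y, meta, "quantitative", n_folds=5, seed=15)
        all_val = np.concatenate([f["validation_idx"] for f in folds])
        assert sorted(all_val.tolist()) == list(range(500))
        for f in folds:
            assert set(f["train_idx"]) | set(f["validation_idx"]) == set(range(500))
            assert not set(f["train_idx"]) & set(f["validation_idx"])

    def test_null_z_scores_standard_normal(self):
        G, meta = simulate_genotypes(2000, 2000, seed=16)
        y = np.random.default_rng(17).standard_normal(2000)
        folds = gwas_scan(G, y, meta, "quantitative", n_folds=5, seed=18)
        z = np.array([v.z for v in folds[0]["variants"]])
        # z within an LD block are correlated; thin to one per block for
        # the mean check, keep the full vector for the variance
        z_ind = z[::50]
        assert abs(z_ind.mean()) < 3 / np.sqrt(len(z_ind))
        assert 0.85 < z.var() < 1.15

    def test_null_z_passes_ks_in_most_seeds(self):
        hits = 0
        for s in range(10):
            G, meta = simulate_genotypes(800, 400, seed=100 + s)
            y = np.random.default_rng(200 + s).standard_normal(800)
            folds = gwas_scan(G, y, meta, "quantitative", n_folds=5, seed=s)
            z = np.array([v.z for v in folds[0]["variants"]])
            # thin to near-independent SNPs (one per LD block)
            z_ind = z[::50]
            if stats.kstest(z_ind, "norm").pvalue > 0.01:
                hits += 1
        assert hits >= 9

    def test_injected_effect_ranks_top_of_block(self):
        G, meta = simulate_genotypes(1500, 100, seed=19)
        rng = np.random.default_rng(20)
        y = G[:, 25].astype(float) * 0.6 + rng.standard_normal(1500)
        folds = gwas_scan(G, y, meta, "quantitative", n_folds=5, seed=21)
        z = np.abs(np.array([v.z for v in folds[0]["variants"]]))
        assert z[25] == max(z[:50])

    def test_binary_logistic_z_reasonable_under_null(self):
        G, meta = simulate_genotypes(1500, 200, seed=22)
        y = (np.random.default_rng(23).random(1500) < 0.2).astype(float)
        folds = gwas_scan(G, y, meta, "binary", n_folds=5, seed=24)
        z = np.array([v.z for v in folds[0]["variants"]])
        assert np.all(np.isfinite(z))
        assert 0.75 < z.var() < 1.25


class TestGenesAndSets:
    def _setup(self, n_snp=500, causal_prop=0.05, seed=25):
        G, meta = simulate_genotypes(200, n_snp, seed=seed)
        _, causal = simulate_effects(n_snp, causal_prop, "GA1", seed=seed + 1)
        return meta, causal

    def test_gene_map_tiles_blocks(self):
        _, meta = simulate_genotypes(100, 120, ld_block_size=50, seed=26)
        genes, gene_snps = build_gene_map(meta, snps_per_gene=10)
        assert sum(len(v) for v in gene_snps.values()) == 120
        for gid, idx in gene_snps.items():
            blocks = meta.loc[idx, "block"].unique()
            assert len(blocks) == 1  # genes never straddle blocks

    def test_configured_causal_content(self):
        meta, causal = self._setup()
        genes, gene_snps, coll, truth = build_genes_and_sets(
            meta, causal, set_sizes=(10,), causal_counts=(5,),
            n_replicates=3, seed=27, snps_per_gene=5,
        )
        causal_set = set(causal.tolist())
        for t in truth:
            assert (t.size, t.n_causal) == (10, 5)
            genes_in = coll.genes_of(t.set_id)
            n_causal = sum(
                1 for g in genes_in if causal_set & set(gene_snps[g].tolist())
            )
            assert n_causal == 5

    def test_control_sets_all_non_causal(self):
        meta, causal = self._setup()
        _, gene_snps, coll, truth = build_genes_and_sets(
            meta, causal, set_sizes=(10, 20), causal_counts=(5,),
            n_control_sets=198, n_replicates=1, seed=28, snps_per_gene=5,
        )
        controls = [t for t in truth if t.set_id.startswith("control")]
        assert len(controls) == 198
        assert all(not t.is_causal_set for t in controls)

    def test_infeasible_configuration_reports_shortfall(self):
        meta, causal = self._setup()  # 100 genes total
        with pytest.raises(ValueError, match="infeasible"):
            build_genes_and_sets(
                meta, causal, set_sizes=(200,), causal_counts=(200,),
                n_replicates=1, seed=29, snps_per_gene=5,
            )

    def test_seed_determinism(self):
        meta, causal = self._setup()
        kwargs = dict(set_sizes=(10,), causal_counts=(0, 5), n_replicates=2,
                      seed=30, snps_per_gene=5)
        _, _, c1, t1 = build_genes_and_sets(meta, causal, **kwargs)
        _, _, c2, t2 = build_genes_and_sets(meta, causal, **kwargs)
        assert c1.sets == c2.sets and t1 == t2


class TestOverlappingSets:
    def _base(self):
        meta, causal = TestGenesAndSets()._setup()
        genes, gene_snps, coll, truth = build_genes_and_sets(
            meta, causal, set_sizes=(10,), causal_counts=(0, 5),
            n_replicates=2, seed=31, snps_per_gene=5,
        )
        causal_set = set(causal.tolist())
        causal_genes = {
            g.gene_id for g in genes if causal_set & set(gene_snps[g.gene_id].tolist())
        }
        all_genes = [g.gene_id for g in genes]
        return coll, truth, causal_genes, all_genes

    def test_correlated_mode_shares_half_of_genes(self):
        coll, truth, causal_genes, all_genes = self._base()
        ext, ext_truth = build_overlapping_sets(
            coll, truth, causal_genes, all_genes, n_extra=20,
            overlap_mode="correlated", seed=32,
        )
        base_sets = {sid: set(g) for sid, _, g in coll}
        for sid, _, genes in ext:
            if not sid.startswith("extra"):
                continue
            best = max(
                len(set(genes) & bg) / len(genes) for bg in base_sets.values()
            )
            assert best >= 0.5

    def test_uncorrelated_mode_zero_jaccard(self):
        coll, truth, causal_genes, all_genes = self._base()
        ext, _ = build_overlapping_sets(
            coll, truth, causal_genes, all_genes, n_extra=10,
            overlap_mode="uncorrelated", seed=33,
        )
        base_genes = coll.all_genes()
        for sid, _, genes in ext:
            if sid.startswith("extra"):
                assert not set(genes) & base_genes

    def test_requested_number_of_extras(self):
        coll, truth, causal_genes, all_genes = self._base()
        ext, ext_truth = build_overlapping_sets(
            coll, truth, causal_genes, all_genes, n_extra=191,
            overlap_mode="correlated", seed=34,
        )
        assert len(ext) == len(coll) + 191
        assert len(ext_truth) == len(truth) + 191

    def test_truth_recomputed_from_causal_content(self):
        coll, truth, causal_genes, all_genes = self._base()
        ext, ext_truth = build_overlapping_sets(
            coll, truth, causal_genes, all_genes, n_extra=30,
            overlap_mode="correlated", seed=35,
        )
        by_id = {t.set_id: t for t in ext_truth}
        for sid, _, genes in ext:
            if sid.startswith("extra"):
                assert by_id[sid].n_causal == len(set(genes) & causal_genes)


class TestGeneLD:
    def test_ld_matrices_valid_and_match_genes(self):
        G, meta = simulate_genotypes(400, 100, seed=36)
        genes, gene_snps = build_gene_map(meta, snps_per_gene=10)
        source = compute_gene_ld(G, meta, gene_snps)
        for g in genes:
            ld = source.get(g.gene_id, source.matrices[g.gene_id].variant_ids)
            assert ld.K.shape == (10, 10)
            assert np.allclose(np.diag(ld.K), 1.0)


def test_truth_invariants():
    with pytest.raises(ValueError):
        GeneSetTruth("s", 10, 11)
    assert GeneSetTruth("s", 10, 1).is_causal_set
    assert not GeneSetTruth("s", 10, 0).is_causal_set
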
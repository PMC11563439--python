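import numpy as np
import pytest
from scipy import stats

from gsblr.genestats import (
    DegenerateGeneError,
    EigenSpectrum,
    gene_quadratic_stat,
    gene_z,
    map_variants_to_genes,
    compute_gene_stats,
    quadform_pvalue,
    spectrum_from_ld,
)
from gsblr.io import GeneRecord, LDMatrix, VariantStat


def _variant(vid, pos, z=1.0, chrom="1"):
    return VariantStat(vid, chrom, pos, "A", "G", z)


class TestQuadraticStat:
    @pytest.mark.parametrize(
        "z, expected",
        [([0, 0, 0], 0.0), ([1.96], 3.8416), ([1, 2, 2], 9.0)],
    )
    def test_sum_of_squares(self, z, expected):
        assert gene_quadratic_stat(np.array(z, dtype=float)) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gene_quadratic_stat(np.array([]))


class TestQuadformPvalue:
    def test_zero_stat_gives_one(self):
        assert quadform_pvalue(0.0, EigenSpectrum((1.6, 0.4))) == 1.0

    @pytest.mark.parametrize("df", [1, 2, 5, 20, 50])
    def test_identity_ld_matches_chisquare(self, df):
        spec = EigenSpectrum(tuple([1.0] * df))
        for target in (0.5, 0.05, 1e-4):
            q = stats.chi2.isf(target, df)
            assert quadform_pvalue(q, spec) == pytest.approx(target, abs=1e-8)

    def test_montecarlo_oracle_two_eigenvalues(self):
        # seeded MC oracle with 1e7 draws, 2% relative tolerance
        lam = np.array([1.6, 0.4])
        p = quadform_pvalue(4.0, EigenSpectrum((1.6, 0.4)))
        rng = np.random.default_rng(20240601)
        exceed = 0
        for _ in range(10):
            draws = rng.chisquare(1.0, size=(1_000_000, 2)) @ lam
            exceed += int(np.sum(draws > 4.0))
        p_mc = exceed / 1e7
        assert p == pytest.approx(p_mc, rel=0.02)

    def test_monotone_decreasing_in_q(self):
        spec = EigenSpectrum((2.0, 1.0, 0.5))
        ps = [quadform_pvalue(q, spec) for q in np.linspace(0.5, 30, 25)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_saddlepoint_method_close_to_auto(self):
        spec = EigenSpectrum((1.6, 0.4, 0.2))
        p_auto = quadform_pvalue(10.0, spec)
        p_sp = quadform_pvalue(10.0, spec, method="saddlepoint")
        assert p_sp == pytest.approx(p_auto, rel=0.05)

    def test_mean_singularity_handled(self):
        spec = EigenSpectrum((1.6, 0.4))
        p = quadform_pvalue(2.0, spec, method="saddlepoint")
        assert 0.2 < p < 0.5  # Monte-Carlo fallback near the mean

    def test_far_tail_finite(self):
        spec = EigenSpectrum((1.5, 0.5, 0.1))
        p = quadform_pvalue(500.0, spec)
        assert 0 < p < 1e-30

    def test_degenerate_spectrum_rejected(self):
        with pytest.raises(DegenerateGeneError):
            quadform_pvalue(1.0, EigenSpectrum((0.0, 0.0)))


class TestEigenSpectrum:
    def test_flooring_and_trace(self):
        K = np.array([[1.0, 1.0], [1.0, 1.0]])  # rank 1
        spec = spectrum_from_ld(LDMatrix(["a", "b"], K))
        lam = np.array(spec.lambdas)
        assert lam[0] == pytest.approx(2.0)
        assert lam[1] == 0.0
        assert lam.sum() == pytest.approx(np.trace(K), rel=1e-6)

    def test_negative_eigenvalue_rejected(self):
        with pytest.raises(ValueError):
            EigenSpectrum((1.0, -0.5))


class TestGeneZ:
    @pytest.mark.parametrize(
        "p, expected", [(0.5, 0.0), (0.05, 1.6448536269514722)]
    )
    def test_probit_values(self, p, expected):
        assert gene_z(p) == pytest.approx(expected, abs=1e-9)

    def test_boundary_p_one_capped_finite(self):
        z = gene_z(1.0)
        assert np.isfinite(z) and z < -8

    def test_extreme_small_p_capped(self):
        z = gene_z(1e-310) if True else None
        # 1e-310 is floored to 1e-300 before the probit
        assert np.isfinite(gene_z(1e-300)) and gene_z(1e-300) == pytest.approx(z)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.1])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            gene_z(bad)


class TestVariantGeneMapping:
    GENE_PLUS = GeneRecord("G", "1", 1000, 2000, "+")
    GENE_MINUS = GeneRecord("G", "1", 1000, 2000, "-")

    def test_upstream_window_plus_strand(self):
        mapping = map_variants_to_genes([_variant("v", 970)], [self.GENE_PLUS])
        assert mapping == {"G": ["v"]}

    def test_downstream_boundary_plus_strand(self):
        inside = map_variants_to_genes([_variant("v", 12000)], [self.GENE_PLUS])
        outside = map_variants_to_genes([_variant("v", 12001)], [self.GENE_PLUS])
        assert "G" in inside and "G" not in outside

    def test_minus_strand_window_flipped(self):
        # 2030 is upstream of a minus-strand gene (within 35 kb)
        assert "G" in map_variants_to_genes([_variant("v", 2030)], [self.GENE_MINUS])
        # below start - down_bp for minus strand
        gene = GeneRecord("G", "1", 50_000, 51_000, "-")
        assert "G" in map_variants_to_genes([_variant("v", 40_000)], [gene])
        assert "G" not in map_variants_to_genes([_variant("v", 39_999)], [gene])

    def test_variants_ordered_by_position(self):
        vs = [_variant("b", 1500), _variant("a", 1200), _variant("c", 1800)]
        mapping = map_variants_to_genes(vs, [self.GENE_PLUS])
        assert mapping["G"] == ["a", "b", "c"]

    def test_variant_may_map_to_multiple_genes(self):
        g2 = GeneRecord("G2", "1", 1500, 2500, "+")
        mapping = map_variants_to_genes([_variant("v", 1600)], [self.GENE_PLUS, g2])
        assert set(mapping) == {"G", "G2"}


class _DictLD:
    def __init__(self, d):
        self.d = d

    def get(self, gene_id, variant_ids):
        if gene_id not in self.d:
            raise KeyError(gene_id)
        return self.d[gene_id]


class TestComputeGeneStats:
    def test_single_snp_gene_chisquare(self):
        variants = [_variant("v", 1500, z=2.0)]
        genes = [GeneRecord("G", "1", 1000, 2000, "+")]
        ld = _DictLD({"G": LDMatrix(["v"], np.array([[1.0]]))})
        (gs,) = compute_gene_stats(variants, genes, ld)
        assert gs.T == pytest.approx(4.0)
        assert gs.p == pytest.approx(stats.chi2.sf(4.0, 1), abs=1e-10)
        assert gs.z == pytest.approx(stats.norm.isf(stats.chi2.sf(4.0, 1)), abs=1e-6)

    def test_perfectly_correlated_pair_rank_one(self):
        variants = [_variant("v1", 1100, z=2.0), _variant("v2", 1200, z=2.0)]
        genes = [GeneRecord("G", "1", 1000, 2000, "+")]
        ld = _DictLD({"G": LDMatrix(["v1", "v2"], np.ones((2, 2)))})
        (gs,) = compute_gene_stats(variants, genes, ld)
        # spectrum (2, 0): T / 2 ~ chi2(1)
        assert gs.p == pytest.approx(stats.chi2.sf(gs.T / 2.0, 1), abs=1e-10)

    def test_gene_without_variants_absent(self):
        variants = [_variant("v", 10_000_000)]
        genes = [GeneRecord("G", "1", 1000, 2000, "+")]
        ld = _DictLD({})
        assert compute_gene_stats(variants, genes, ld) == []

    def test_missing_ld_skips_or_raises(self):
        variants = [_variant("v", 1500, z=1.0)]
        genes = [GeneRecord("G", "1", 1000, 2000, "+")]
        assert compute_gene_stats(variants, genes, _DictLD({})) == []
        with pytest.raises(KeyError):
            compute_gene_stats(variants, genes, _DictLD({}), strict=True)

    def test_permutation_invariance(self, rng):
        n = 6
        A = rng.standard_normal((n, n + 3))
        K = A @ A.T
        d = np.sqrt(np.diag(K))
        K = K / np.outer(d, d)
        z = rng.standard_normal(n)
        ids = [f"v{i}" for i in range(n)]
        variants = [_variant(ids[i], 1100 + 100 * i, z=z[i]) for i in range(n)]
        genes = [GeneRecord("G", "1", 1000, 2000, "+")]
        ld = _DictLD({"G": LDMatrix(ids, K)})
        (base,) = compute_gene_stats(variants, genes, ld)

        perm = rng.permutation(n)
        variants_p = [
            _variant(ids[perm[i]], 1100 + 100 * i, z=z[perm[i]]) for i in range(n)
        ]
        ld_p = _DictLD({"G": LDMatrix([ids[j] for j in perm],
                                      K[np.ix_(perm, perm)])})
        (permuted,) = compute_gene_stats(variants_p, genes, ld_p)
        assert permuted.T == pytest.approx(base.T, abs=1e-12)
        assert permuted.p == pytest.approx(base.p, rel=1e-9)
        assert permuted.z == pytest.approx(base.z, abs=1e-7)
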
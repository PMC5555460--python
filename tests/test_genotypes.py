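"""Genotype generators: two-locus LD construction, block-LD loci, readers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eqtlsim as es
from eqtlsim.genotypes import (
    InfeasibleLDError,
    haplotype_frequencies,
    signed_r_bounds,
    write_dosage_tsv,
)


def brute_force_max_r2(p1: float, p2: float, grid: int = 20001) -> float:
    """Exhaustive search over valid two-locus haplotype tables for max r^2.

    Independent oracle: scan the feasible range of the minor/minor haplotype
    frequency and maximize the squared allelic correlation directly.
    """
    lo = max(0.0, p1 + p2 - 1.0)
    hi = min(p1, p2)
    p11 = np.linspace(lo, hi, grid)
    d = p11 - p1 * p2
    r2 = d**2 / (p1 * (1 - p1) * p2 * (1 - p2))
    return float(r2.max())


class TestMaxAbsR:
    def test_equal_frequencies_allow_perfect_ld(self):
        assert es.max_abs_r(0.2, 0.2) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "p1,p2",
        [(0.1, 0.5), (0.01, 0.5), (0.05, 0.3), (0.25, 0.4), (0.02, 0.02)],
    )
    def test_matches_exhaustive_table_search(self, p1, p2):
        assert es.max_abs_r(p1, p2) ** 2 == pytest.approx(
            brute_force_max_r2(p1, p2), abs=1e-6
        )

    def test_rare_common_pair_values(self):
        # frozen values from the exhaustive oracle
        assert es.max_abs_r(0.1, 0.5) == pytest.approx(np.sqrt(1 / 9), abs=1e-12)
        assert es.max_abs_r(0.01, 0.5) ** 2 == pytest.approx(0.010101, abs=1e-5)

    def test_symmetry_and_domain(self):
        assert es.max_abs_r(0.1, 0.4) == es.max_abs_r(0.4, 0.1)
        with pytest.raises(ValueError):
            es.max_abs_r(0.0, 0.3)
        with pytest.raises(ValueError):
            es.max_abs_r(0.2, 0.7)


class TestSamplePair:
    def test_perfect_coupling_haplotype_frequencies(self):
        f = haplotype_frequencies(0.5, 0.5, 1.0)
        assert f == pytest.approx([0.5, 0.0, 0.0, 0.5], abs=1e-12)

    def test_d_formula_plugin(self):
        # p11 = p1*p2 + r*sqrt(p1 q1 p2 q2) at p=0.2, r=sqrt(0.9)
        f = haplotype_frequencies(0.2, 0.2, np.sqrt(0.9))
        assert f[3] == pytest.approx(0.04 + np.sqrt(0.9) * 0.16, abs=1e-12)

    def test_empirical_r2_converges_to_target(self):
        # 1e6 haplotypes = 5e5 diploids; MC tolerance +/- 0.01 on r^2
        G = es.sample_pair(500_000, 0.2, 0.3, np.sqrt(0.5), seed=7)
        r2 = np.corrcoef(G.dosages.T)[0, 1] ** 2
        assert r2 == pytest.approx(0.5, abs=0.01)
        assert G.maf == pytest.approx([0.2, 0.3], abs=0.003)

    def test_infeasible_target_names_bound(self):
        with pytest.raises(InfeasibleLDError, match="attainable"):
            es.sample_pair(100, 0.05, 0.5, 0.9, seed=0)
        # negative coupling is bounded tighter for rare pairs
        with pytest.raises(InfeasibleLDError):
            es.sample_pair(100, 0.1, 0.1, -0.5, seed=0)

    def test_determinism(self):
        a = es.sample_pair(500, 0.2, 0.2, 0.5, seed=42)
        b = es.sample_pair(500, 0.2, 0.2, 0.5, seed=42)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        p1=st.floats(0.01, 0.5),
        p2=st.floats(0.01, 0.5),
        u=st.floats(0.0, 1.0),
        sign=st.sampled_from([-1.0, 1.0]),
    )
    def test_feasible_targets_give_valid_tables(self, p1, p2, u, sign):
        r_lo, r_hi = signed_r_bounds(p1, p2)
        r = u * (r_hi if sign > 0 else -r_lo) * sign
        f = haplotype_frequencies(p1, p2, r)
        assert np.all(f >= 0)
        assert f.sum() == pytest.approx(1.0, abs=1e-12)
        # table marginals reproduce the requested frequencies
        assert f[2] + f[3] == pytest.approx(p1, abs=1e-9)
        assert f[1] + f[3] == pytest.approx(p2, abs=1e-9)


class TestSimulateLocus:
    def test_rho_zero_gives_independence_baseline(self, independent_panel):
        ld = es.ld_matrix(independent_panel)
        off = ld[np.triu_indices(independent_panel.n_variants, 1)]
        # mean off-diagonal r^2 ~ 1/(n-1) under independence
        assert np.nanmean(off) == pytest.approx(1 / 1999, rel=0.5)

    def test_high_rho_block_decays_with_distance(self):
        spec = es.LDBlockSpec([60], [0.95])
        G = es.simulate_locus(1500, 60, block_spec=spec, seed=5)
        ld = es.ld_matrix(G)
        adjacent = np.array([ld[i, i + 1] for i in range(59)])
        distant = np.array([ld[i, i + 30] for i in range(30)])
        assert np.median(adjacent) > np.median(distant)

    def test_blocks_are_independent(self):
        spec = es.LDBlockSpec([30, 30], [0.95, 0.95])
        G = es.simulate_locus(1500, 60, block_spec=spec, seed=6)
        ld = es.ld_matrix(G)
        across = ld[:30, 30:]
        assert np.nanmean(across) < 0.02

    def test_determinism_and_metadata(self):
        a = es.simulate_locus(200, 30, seed=9)
        b = es.simulate_locus(200, 30, seed=9)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        assert np.all(np.diff(a.positions) > 0)
        assert a.positions[-1] < 400_000
        assert np.all(a.maf > 0) and np.all(a.maf <= 0.5)
        # no monomorphic columns survive generation
        assert np.all(a.dosages.std(axis=0) > 0)


class TestLdMatrix:
    def test_identical_and_complement_columns(self):
        g = np.random.default_rng(3).binomial(2, 0.3, size=(400, 1)).astype(float)
        G = es.GenotypeMatrix(
            np.column_stack([g, g, 2 - g]), np.array([1, 2, 3]),
            np.array(["a", "b", "c"]),
        )
        ld = es.ld_matrix(G)
        assert ld[0, 1] == pytest.approx(1.0)
        assert ld[0, 2] == pytest.approx(1.0)  # r^2 ignores allele orientation

    def test_constant_column_flagged(self):
        d = np.column_stack(
            [np.ones(50), np.random.default_rng(0).binomial(2, 0.4, 50)]
        )
        G = es.GenotypeMatrix(d, np.array([1, 2]), np.array(["a", "b"]))
        with pytest.warns(UserWarning, match="constant"):
            ld = es.ld_matrix(G)
        assert np.isnan(ld[0, 1])
        assert ld[1, 1] == 1.0

    def test_round_trip_with_sample_pair(self):
        G = es.sample_pair(200_000, 0.3, 0.3, np.sqrt(0.5), seed=11)
        assert es.ld_matrix(G)[0, 1] == pytest.approx(0.5, abs=0.015)


class TestSampleCausalSet:
    def test_unconstrained_distinct(self, independent_panel):
        idx = es.sample_causal_set(independent_panel, 4, seed=1)
        assert len(np.unique(idx)) == 4

    def test_pairwise_constraint_satisfied(self, block_panel):
        idx = es.sample_causal_set(
            block_panel, 3, constraint="pairwise_r2_min", r2_min=0.3, seed=2
        )
        ld = es.ld_matrix(block_panel, idx)
        assert np.all(ld[np.triu_indices(3, 1)] > 0.3)

    def test_unsatisfiable_constraint_raises(self, independent_panel):
        with pytest.raises(RuntimeError, match="r\\^2"):
            es.sample_causal_set(
                independent_panel, 3, constraint="pairwise_r2_min",
                r2_min=0.99, seed=3, max_tries=50,
            )


class TestReaders:
    def test_vcf_gt_dosages_and_minor_orientation(self, vcf_text):
        G = es.read_genotypes(vcf_text, format="vcf")
        # rs3 (maf 1/12 = 0.083) kept; rs2 flipped to count the minor allele
        assert set(G.variant_ids) == {"rs1", "rs2", "rs3"}
        rs1 = G.dosages[:, list(G.variant_ids).index("rs1")]
        np.testing.assert_array_equal(rs1, [0, 1, 2, 0, 1, 0])
        rs2 = G.dosages[:, list(G.variant_ids).index("rs2")]
        np.testing.assert_array_equal(rs2, [0, 0, 0, 1, 0, 0])
        assert np.all(G.maf <= 0.5)

    def test_maf_floor_drops_variants(self, vcf_text):
        with pytest.warns(UserWarning, match="maf floor"):
            G = es.read_genotypes(vcf_text, format="vcf", maf_floor=0.2)
        assert "rs3" not in G.variant_ids

    def test_dosage_tsv_round_trip(self, tmp_path):
        G = es.simulate_locus(50, 10, seed=13)
        path = tmp_path / "dosages.tsv"
        write_dosage_tsv(G, path)
        back = es.read_genotypes(path, format="dosage_tsv")
        np.testing.assert_allclose(back.dosages, G.dosages)
        np.testing.assert_array_equal(back.variant_ids, G.variant_ids)
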
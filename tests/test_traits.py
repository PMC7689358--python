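"""Trait architectures, genetic values, heritability scaling, correlated sets."""
import numpy as np
import pytest

import gpbench as gp
from gpbench.markers import GenotypePanel, MarkerMap
from gpbench.traits import (AdditiveQTL, EpistaticQTL, TraitArchitecture,
                            apply_heritability, correlated_traits,
                            genetic_value, sample_architecture)


def _toy_panel(dosages):
    dosages = np.asarray(dosages)
    mmap = MarkerMap.equidistant(dosages.shape[1], 1)
    return GenotypePanel(dosages, mmap)


class TestSampleArchitecture:
    def test_equal_additive_effects_are_identical(self, small_panel):
        arch = sample_architecture(small_panel, 10, "additive",
                                   effect_distribution="equal", seed=1)
        effs = {q.effect for q in arch.additive}
        assert effs == {1.0}
        idx = [q.marker_index for q in arch.additive]
        assert len(set(idx)) == 10

    def test_epistatic_pairs_are_disjoint_with_full_tables(self, small_panel):
        arch = sample_architecture(small_panel, 20, "epistatic", seed=2)
        used = [i for q in arch.epistatic
                for i in (q.marker_index_a, q.marker_index_b)]
        assert len(used) == len(set(used)) == 40
        for q in arch.epistatic:
            assert q.effect_table.shape == (3, 3)

    def test_linked_pairs_respect_distance_and_chromosome(self, small_panel):
        arch = sample_architecture(small_panel, 15, "linked_epistatic", seed=3)
        chrom = small_panel.map.chromosome
        for q in arch.epistatic:
            assert abs(q.marker_index_a - q.marker_index_b) <= 5
            assert chrom[q.marker_index_a] == chrom[q.marker_index_b]

    def test_linked_with_zero_distance_rejected(self, small_panel):
        with pytest.raises(ValueError):
            sample_architecture(small_panel, 5, "linked_epistatic",
                                max_link_distance=0)

    def test_infeasible_qtl_count_rejected(self, small_panel):
        with pytest.raises(ValueError):
            sample_architecture(small_panel, small_panel.n_markers + 1, "additive")

    def test_architecture_json_roundtrip(self, small_panel):
        arch = sample_architecture(small_panel, 4, "linked_epistatic", seed=5)
        back = TraitArchitecture.from_json(arch.to_json())
        assert back.epistatic[0].marker_index_a == arch.epistatic[0].marker_index_a
        np.testing.assert_allclose(back.epistatic[2].effect_table,
                                   arch.epistatic[2].effect_table)


class TestGeneticValue:
    def test_zero_effects_give_zero(self, small_panel):
        arch = TraitArchitecture(
            additive=(AdditiveQTL(0, 0.0), AdditiveQTL(5, 0.0)))
        assert np.all(genetic_value(small_panel, arch) == 0)

    def test_single_unit_qtl_equals_dosage_column(self, small_panel):
        arch = TraitArchitecture(additive=(AdditiveQTL(7, 1.0),))
        g = genetic_value(small_panel, arch)
        np.testing.assert_array_equal(g, small_panel.dosages[:, 7])

    def test_epistatic_lookup_matches_hand_enumeration(self):
        panel = _toy_panel([[0, 2, 1], [1, 1, 0], [2, 0, 2]])
        table = np.arange(9.0).reshape(3, 3)
        arch = TraitArchitecture(epistatic=(EpistaticQTL(0, 2, table),))
        g = genetic_value(panel, arch)
        # dosage pairs (0,1), (1,0), (2,2) -> table entries 1, 3, 8
        np.testing.assert_array_equal(g, [1.0, 3.0, 8.0])

    def test_linear_in_additive_effects(self, small_panel):
        arch = sample_architecture(small_panel, 10, "additive", seed=4)
        doubled = TraitArchitecture(
            additive=tuple(AdditiveQTL(q.marker_index, 2 * q.effect)
                           for q in arch.additive))
        np.testing.assert_allclose(genetic_value(small_panel, doubled),
                                   2 * genetic_value(small_panel, arch))

    def test_out_of_panel_index_rejected(self, small_panel):
        arch = TraitArchitecture(additive=(AdditiveQTL(10 ** 6, 1.0),))
        with pytest.raises(IndexError):
            genetic_value(small_panel, arch)


class TestApplyHeritability:
    def test_h2_one_gives_phenotype_equal_genetic(self, rng):
        g = rng.standard_normal(100)
        phen = apply_heritability(g, 1.0)
        np.testing.assert_array_equal(phen.phenotypes[:, 0], g)
        assert phen.realized_h2[0] == 1.0

    def test_constant_genetic_vector_rejected(self):
        with pytest.raises(ValueError):
            apply_heritability(np.ones(50), 0.5)
        with pytest.raises(ValueError):
            apply_heritability(np.arange(50.0), 0.0)

    def test_residual_variance_scaling_at_half_h2(self, rng):
        """At h2 = 0.5 the residual s.d. equals the genetic s.d. (sigma_e^2 =
        Var(g) exactly), so the realized residual variance matches Var(g) up
        to chi^2 sampling error."""
        g = rng.standard_normal(100_000) * 3.0
        phen = apply_heritability(g, 0.5, seed=8)
        ratio = phen.residuals[:, 0].var() / g.var()
        assert ratio == pytest.approx(1.0, abs=0.02)

    def test_realized_h2_converges(self, big_n_panel):
        """Realized h2 within +-0.02 of the 0.5 target at n = 10,000,
        averaged over 10 residual seeds."""
        arch = sample_architecture(big_n_panel, 50, "additive", seed=6)
        g = genetic_value(big_n_panel, arch)
        vals = [apply_heritability(g, 0.5, seed=s).realized_h2[0]
                for s in range(10)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.02)

    def test_phenotype_genetic_correlation_hits_sqrt_h2(self, big_n_panel):
        """corr(g, y) tends to sqrt(h2): the predictive-ability ceiling."""
        arch = sample_architecture(big_n_panel, 50, "additive", seed=9)
        g = genetic_value(big_n_panel, arch)
        phen = apply_heritability(g, 0.5, seed=10)
        r = np.corrcoef(g, phen.phenotypes[:, 0])[0, 1]
        assert r == pytest.approx(np.sqrt(0.5), abs=0.02)


class TestCorrelatedTraits:
    def test_effect_mixture_matches_cholesky_construction(self, small_panel):
        """Direct recomputation of the documented mixture: shared QTL index
        draw, i.i.d. normal raw effects, empirical whitening, Cholesky
        mixing — and the resulting sample correlation hits the target."""
        phen = correlated_traits(small_panel, n_traits=2, n_qtl=30,
                                 rho=0.5, h2=1.0, seed=42)
        rng = np.random.default_rng(42)
        idx = rng.choice(small_panel.n_markers, size=30, replace=False)
        raw = rng.standard_normal((30, 2))
        L = np.linalg.cholesky(np.array([[1.0, 0.5], [0.5, 1.0]]))
        M = small_panel.dosages[:, idx].astype(float)
        G0 = M @ raw
        Gc = G0 - G0.mean(axis=0)
        A = np.linalg.cholesky(Gc.T @ Gc / Gc.shape[0])
        G = M @ (raw @ np.linalg.inv(A).T @ L.T)
        np.testing.assert_allclose(phen.genetic_values, G, atol=1e-10)
        r = np.corrcoef(phen.genetic_values.T)[0, 1]
        assert r == pytest.approx(0.5, abs=1e-10)

    def test_rho_zero_gives_uncorrelated_traits(self, corr_panel):
        phen = correlated_traits(corr_panel, n_traits=3, n_qtl=1000,
                                 rho=0.0, h2=0.5, seed=2)
        C = np.corrcoef(phen.genetic_values.T)
        off = C[np.triu_indices(3, k=1)]
        assert np.abs(off).max() < 0.05

    def test_invalid_rho_rejected(self, small_panel):
        for rho in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                correlated_traits(small_panel, n_traits=2, n_qtl=10, rho=rho)

    def test_traits_share_qtl_and_have_target_h2(self, corr_panel):
        phen = correlated_traits(corr_panel, n_traits=5, n_qtl=500,
                                 rho=0.4, h2=0.5, seed=3)
        assert phen.n_traits == 5
        np.testing.assert_allclose(phen.realized_h2, 0.5, atol=0.03)
        np.testing.assert_allclose(phen.phenotypes,
                                   phen.genetic_values + phen.residuals)
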
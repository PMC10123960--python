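import numpy as np
import pytest

import specgwas as sg
from specgwas.synthetic import simulate_gene_annotation, write_gff3


class TestSimulateGenotypes:
    def test_domain_and_shape(self):
        cfg = sg.SimConfig(n_lines=100, n_markers=200, seed=1)
        G = sg.simulate_genotypes(cfg)
        assert G.dosages.shape == (100, 200)
        assert set(np.unique(G.dosages)) <= {0.0, 1.0, 2.0}

    def test_deterministic_given_seed(self):
        cfg = sg.SimConfig(n_lines=50, n_markers=100, seed=7)
        G1 = sg.simulate_genotypes(cfg)
        G2 = sg.simulate_genotypes(sg.SimConfig(n_lines=50, n_markers=100,
                                                seed=7))
        np.testing.assert_array_equal(G1.dosages, G2.dosages)
        np.testing.assert_array_equal(G1.pos_bp, G2.pos_bp)

    def test_remainder_markers_distributed_across_chromosomes(self):
        cfg = sg.SimConfig(n_lines=20, n_markers=23, n_chrom=5, seed=1)
        G = sg.simulate_genotypes(cfg)
        counts = [np.sum(G.chrom == f"Chr{k}") for k in range(1, 6)]
        assert sum(counts) == 23 and max(counts) - min(counts) <= 1

    def test_realized_maf_near_target_at_large_n(self):
        # fixed allele frequency 0.5: realized frequency within binomial
        # sampling error 3*sqrt(p(1-p)/(2n)) at n = 2000 lines
        cfg = sg.SimConfig(n_lines=2000, n_markers=60, maf_range=(0.5, 0.5),
                           ld_block_size=1, seed=2)
        G = sg.simulate_genotypes(cfg)
        freq = G.dosages.mean(axis=0) / 2
        tol = 3 * np.sqrt(0.25 / (2 * 2000))
        assert np.all(np.abs(freq - 0.5) < tol * 1.5)

    def test_unlinked_markers_are_uncorrelated(self):
        cfg = sg.SimConfig(n_lines=2000, n_markers=40, ld_block_size=1,
                           seed=3)
        G = sg.simulate_genotypes(cfg)
        r = np.corrcoef(G.dosages, rowvar=False)
        off = np.abs(r[np.triu_indices_from(r, 1)])
        assert off.mean() < 0.05

    def test_ld_blocks_positively_correlated(self):
        cfg = sg.SimConfig(n_lines=1000, n_markers=40, ld_block_size=4,
                           ld_flip_rate=0.05, seed=4)
        G = sg.simulate_genotypes(cfg)
        r = np.corrcoef(G.dosages[:, :4], rowvar=False)
        assert r[np.triu_indices_from(r, 1)].min() > 0.3


class TestSimulateTraits:
    def test_h2_one_rejected(self):
        with pytest.raises(ValueError, match="h2"):
            sg.SimConfig(n_lines=10, n_markers=10, h2_target=(1.0,),
                         trait_names=("T",))

    def test_zero_heritability_gives_zero_genetic_variance(self):
        cfg = sg.SimConfig(n_lines=100, n_markers=100, h2_target=(0.0,),
                           trait_names=("T",), seed=5)
        G = sg.simulate_genotypes(cfg)
        _, truth = sg.simulate_traits(G, cfg)
        assert truth.true_genetic_values["B-"].var() == 0.0
        assert truth.true_h2["B-"][0] == 0.0

    def test_sparsity_expectation(self):
        cfg = sg.SimConfig(n_lines=30, n_markers=1000, pi_sparsity=0.99,
                           causal_resample_frac=0.0, seed=6)
        G = sg.simulate_genotypes(cfg)
        _, truth = sg.simulate_traits(G, cfg)
        n_causal = len(truth.causal_marker_ids["B-"])
        # binomial(1000, 0.01): ~10 causal, generous 4-sigma band
        assert 1 <= n_causal <= 25

    def test_realized_h2_matches_target(self):
        cfg = sg.SimConfig(n_lines=2000, n_markers=500, pi_sparsity=0.98,
                           h2_target=(0.5,), trait_names=("T",), seed=7)
        G = sg.simulate_genotypes(cfg)
        _, truth = sg.simulate_traits(G, cfg)
        # exact rescaling: realized plot-level h2 from true variance
        # components equals the target
        assert abs(truth.true_h2["B-"][0] - 0.5) < 0.05

    def test_noncausal_effects_exactly_zero(self, small_sim):
        _, G, _, truth, _ = small_sim
        for mgmt in ("B-", "B+"):
            causal = set(truth.causal_marker_ids[mgmt])
            out = [i for i, mid in enumerate(truth.marker_ids)
                   if mid not in causal]
            assert np.all(truth.true_effects[mgmt][out] == 0.0)

    def test_true_rg_diagonal_is_one(self, small_sim):
        _, _, _, truth, _ = small_sim
        np.testing.assert_allclose(np.diag(truth.true_rg["B-"]), 1.0)

    def test_managements_differ_in_architecture(self, small_sim):
        _, _, _, truth, _ = small_sim
        a = set(truth.causal_marker_ids["B-"])
        b = set(truth.causal_marker_ids["B+"])
        assert a != b and a & b  # overlapping but not identical

    def test_management_shift_moves_mean(self, small_sim):
        cfg, _, ph, _, _ = small_sim
        diff = (ph.loc[ph.management == "B+", "PH"].mean()
                - ph.loc[ph.management == "B-", "PH"].mean())
        assert abs(diff - cfg.management_shift) < 0.3

    def test_plot_count_and_design_columns(self, small_sim):
        cfg, _, ph, _, _ = small_sim
        assert len(ph) == cfg.n_lines * cfg.n_rep * 2
        assert set(ph["management"]) == {"B-", "B+"}
        per_rep = ph.groupby(["management", "replication"])["block"].nunique()
        assert (per_rep == cfg.n_block).all()


class TestSimulateSpectra:
    def test_values_within_unit_interval(self, small_sim):
        _, _, _, _, spectra = small_sim
        assert spectra.values.min() >= 0.0 and spectra.values.max() <= 1.0

    def test_zero_loadings_remove_genetic_signal(self):
        cfg = sg.SimConfig(n_lines=200, n_markers=100, n_bands=10,
                           band_trait_rmax=0.0, n_latent=0, seed=8)
        G = sg.simulate_genotypes(cfg)
        ph, truth = sg.simulate_traits(G, cfg)
        sg.simulate_spectra(G, truth, cfg, ph)
        assert np.allclose(truth.band_genetic_values["B-"], 0.0)

    def test_band_trait_correlation_sign_pattern(self):
        # genetic projections per band must reproduce the sign of the
        # injected loadings where the loading is meaningfully nonzero
        cfg = sg.SimConfig(n_lines=2000, n_markers=400, pi_sparsity=0.95,
                           n_bands=30, seed=9)
        G = sg.simulate_genotypes(cfg)
        ph, truth = sg.simulate_traits(G, cfg)
        sg.simulate_spectra(G, truth, cfg, ph)
        g = truth.true_genetic_values["B-"]
        bands = truth.band_genetic_values["B-"]
        for t in range(cfg.n_traits):
            rho = truth.band_loadings[t]
            strong = np.abs(rho) > 0.25
            r = np.array([np.corrcoef(bands[:, b], g[:, t])[0, 1]
                          for b in range(cfg.n_bands)])
            agree = np.sign(r[strong]) == np.sign(rho[strong])
            assert agree.mean() > 0.9

    def test_spectra_deterministic(self, small_sim):
        cfg, G, ph, truth, spectra = small_sim
        again = sg.simulate_spectra(G, truth, cfg, ph)
        np.testing.assert_array_equal(spectra.values, again.values)


class TestSimulateCube:
    def test_noiseless_leaf_equals_input(self):
        refl = np.full(10, 0.4)
        cube, mask = sg.simulate_cube(refl, (8, 8), background_value=0.0)
        assert np.allclose(cube.values[mask], 0.4)
        assert np.allclose(cube.values[~mask], 0.0)

    def test_leaf_too_large_raises(self):
        with pytest.raises(ValueError, match="larger"):
            sg.simulate_cube(np.full(5, 0.4), (4, 4), leaf_shape=(8, 8))

    def test_band_mean_recovered_within_sem(self):
        refl = np.linspace(0.2, 0.6, 20)
        cube, mask = sg.simulate_cube(refl, (200, 200), leaf_shape=(100, 100),
                                      noise_sd=0.01, seed=1)
        est = cube.values[mask].mean(axis=0)
        assert np.all(np.abs(est - refl) < 3e-4 * 1.5)  # 3*sem at 1e4 px


def test_gene_annotation_and_gff3_roundtrip(tmp_path, small_sim):
    _, G, _, _, _ = small_sim
    ann = simulate_gene_annotation(G, seed=1)
    assert (ann["end"] > ann["start"]).all()
    write_gff3(ann, tmp_path / "genes.gff3")
    from specgwas.association import read_gene_annotation
    back = read_gene_annotation(tmp_path / "genes.gff3")
    assert len(back) == len(ann)
    assert set(back["gene_id"]) == set(ann["gene_id"])
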
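"""Generator checks: Balding-Nichols divergence, panel sampling, the ancestry
mosaic and tract, phenotype structure, and byte-level determinism."""

from dataclasses import replace

import numpy as np
import pytest

from tauroscan.mixed_model import compute_grm
from tauroscan.simulate import (
    SimConfig,
    simulate_admixed_animals,
    simulate_ancestral_frequencies,
    simulate_dataset,
    simulate_phenotypes,
    simulate_reference_panels,
    stage_seed,
    write_simulation,
)


def hudson_fst(p1, p2):
    """Ratio-of-means Hudson estimator from population frequencies."""
    num = (p1 - p2) ** 2
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num.mean() / den.mean()


class TestAncestralFrequencies:
    def test_invalid_fst_rejected(self):
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                simulate_ancestral_frequencies(100, bad, 0)

    def test_zero_divergence_limit_frequencies_converge(self):
        p_t, p_i = simulate_ancestral_frequencies(5000, 1e-4, 1)
        assert np.corrcoef(p_t, p_i)[0, 1] > 0.99

    def test_target_fst_recovered_by_hudson_estimator(self):
        p_t, p_i = simulate_ancestral_frequencies(10_000, 0.5, 2)
        assert hudson_fst(p_t, p_i) == pytest.approx(0.5, abs=0.05)

    def test_deterministic_for_fixed_seed(self):
        a = simulate_ancestral_frequencies(500, 0.3, 42)
        b = simulate_ancestral_frequencies(500, 0.3, 42)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_frequencies_clipped_away_from_fixation(self):
        p_t, p_i = simulate_ancestral_frequencies(20_000, 0.8, 3)
        for p in (p_t, p_i):
            assert p.min() >= 0.01 and p.max() <= 0.99


class TestReferencePanels:
    def test_fixed_marker_yields_all_alt(self):
        freqs = (np.array([1.0, 0.5]), np.array([0.2, 0.5]))
        t, i = simulate_reference_panels(freqs, 50, 50, 0)
        assert (t.counts[:, 0] == 1).all()

    def test_sample_frequency_concentrates_at_input(self):
        """n = 2000 haplotypes: every marker within ~3 binomial SDs (0.03) on a
        small marker set; Bonferroni-wide bound (0.05) across 200 markers."""
        p_t, p_i = simulate_ancestral_frequencies(200, 0.3, 4)
        t, i = simulate_reference_panels((p_t, p_i), 2000, 2000, 5)
        assert np.abs(t.counts.mean(axis=0) - p_t)[:10].max() < 0.03
        assert np.abs(i.counts.mean(axis=0) - p_i)[:10].max() < 0.03
        assert np.abs(t.counts.mean(axis=0) - p_t).max() < 0.05
        assert np.abs(i.counts.mean(axis=0) - p_i).max() < 0.05

    def test_zero_panel_size_rejected(self):
        freqs = simulate_ancestral_frequencies(10, 0.3, 0)
        with pytest.raises(ValueError):
            simulate_reference_panels(freqs, 0, 10, 0)

    def test_same_seed_identical_panels(self):
        freqs = simulate_ancestral_frequencies(50, 0.3, 0)
        t1, _ = simulate_reference_panels(freqs, 30, 30, 9)
        t2, _ = simulate_reference_panels(freqs, 30, 30, 9)
        assert np.array_equal(t1.counts, t2.counts)


class TestAdmixedAnimals:
    def _cfg(self, **kw):
        base = dict(seed=0, n_snps=300, n_animals=200, tract_interval=(100, 150),
                    candidate_snp_index=120, n_background_snps=0,
                    n_founder_haplotypes=None)
        base.update(kw)
        return SimConfig(**base)

    def test_no_taurine_anywhere_gives_zero_mask(self):
        cfg = self._cfg(baseline_taurine=0.0, tract_taurine_freq=0.0)
        freqs = simulate_ancestral_frequencies(cfg.n_snps, cfg.fst, 1)
        _, truth = simulate_admixed_animals(freqs, cfg, 2)
        assert truth.ancestry_mask.sum() == 0

    def test_full_tract_penetrance_masks_every_tract_marker(self):
        cfg = self._cfg(tract_taurine_freq=1.0)
        freqs = simulate_ancestral_frequencies(cfg.n_snps, cfg.fst, 1)
        _, truth = simulate_admixed_animals(freqs, cfg, 2)
        assert (truth.ancestry_mask[:, 100:150] == 1).all()

    def test_background_mask_mean_matches_baseline(self):
        cfg = self._cfg(n_snps=1000, n_animals=500, baseline_taurine=0.025,
                        tract_interval=(500, 550), candidate_snp_index=520)
        freqs = simulate_ancestral_frequencies(cfg.n_snps, cfg.fst, 1)
        _, truth = simulate_admixed_animals(freqs, cfg, 3)
        bg = np.r_[0:500, 550:1000]
        assert truth.ancestry_mask[:, bg].mean() == pytest.approx(0.025, abs=0.01)

    def test_candidate_allele_ancestry_association_positive(self, small_dataset,
                                                            small_config):
        """Favourable-allele carriers have higher tract-ancestry than others."""
        c = small_config.candidate_snp_index
        lo, hi = small_config.tract_interval
        carrier = small_dataset.targets.counts[:, c] == 1
        mask = small_dataset.truth.ancestry_mask
        assert mask[carrier, lo:hi].mean() > mask[~carrier, lo:hi].mean()


class TestPhenotypes:
    def _sim(self, cfg, kin_jitter=0.0):
        freqs = simulate_ancestral_frequencies(cfg.n_snps, cfg.fst, 1)
        gm, truth = simulate_admixed_animals(freqs, cfg, 2)
        kin = compute_grm(gm)
        K = kin.K + kin_jitter * np.eye(gm.n_animals)
        return gm, K, truth

    def test_zero_heritability_means_no_polygenic_component(self):
        """With h2 = 0 the phenotypes do not depend on the kinship at all."""
        cfg = SimConfig(seed=0, n_snps=100, n_animals=50, h2=0.0,
                        tract_interval=(40, 60), candidate_snp_index=50,
                        n_background_snps=0, n_founder_haplotypes=None)
        gm, K, truth = self._sim(cfg)
        p1, _ = simulate_phenotypes(gm, K, cfg, truth, seed=5)
        p2, _ = simulate_phenotypes(gm, np.eye(50), cfg, truth, seed=5)
        assert p1.data["SC12"].tolist() == p2.data["SC12"].tolist()

    def test_pure_noise_under_global_null(self):
        cfg = SimConfig(seed=0, n_snps=100, n_animals=400, h2=0.0,
                        snp_effect=0.0, n_groups=1,
                        tract_interval=(40, 60), candidate_snp_index=50,
                        n_background_snps=0, n_founder_haplotypes=None)
        gm, K, truth = self._sim(cfg)
        s = gm.counts[:, 50].astype(float)
        cors = []
        for seed in range(20):
            pheno, _ = simulate_phenotypes(gm, K, cfg, truth, seed=seed)
            cors.append(np.corrcoef(s, pheno.data["SC12"])[0, 1])
        assert abs(np.mean(cors)) < 0.03

    def test_non_symmetric_kinship_rejected(self):
        cfg = SimConfig(seed=0, n_snps=50, n_animals=10,
                        tract_interval=(10, 20), candidate_snp_index=15,
                        n_background_snps=0, n_founder_haplotypes=None)
        gm, K, truth = self._sim(cfg)
        K = K.copy()
        K[0, 1] += 0.5
        with pytest.raises(ValueError, match="symmetric"):
            simulate_phenotypes(gm, K, cfg, truth, seed=1)

    def test_variance_components_recorded_in_truth(self):
        cfg = SimConfig(seed=0, n_snps=50, n_animals=30, h2=0.4,
                        tract_interval=(10, 20), candidate_snp_index=15,
                        n_background_snps=0, n_founder_haplotypes=None)
        gm, K, truth = self._sim(cfg)
        _, truth = simulate_phenotypes(gm, K, cfg, truth, seed=1)
        sg2, se2 = truth.true_variance_components
        assert sg2 == pytest.approx(0.4) and se2 == pytest.approx(0.6)


class TestDataset:
    def test_dataset_deterministic_for_fixed_seed(self, small_config,
                                                  small_dataset):
        again = simulate_dataset(replace(small_config))
        assert np.array_equal(again.targets.counts, small_dataset.targets.counts)
        assert np.array_equal(again.panel_taurus.counts,
                              small_dataset.panel_taurus.counts)
        assert again.phenotypes.data.equals(small_dataset.phenotypes.data)

    def test_written_files_are_reproducible(self, small_config, tmp_path):
        cfg = replace(small_config, n_snps=60, n_animals=20, n_ref_taurus=30,
                      n_ref_indicus=30, tract_interval=(20, 40),
                      candidate_snp_index=30, n_background_snps=40)
        write_simulation(simulate_dataset(cfg), tmp_path / "a")
        write_simulation(simulate_dataset(cfg), tmp_path / "b")
        for name in ("targets.vcf", "phenotypes.tsv", "config.yaml",
                     "truth_ancestry_mask.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(tract_interval=(900, 1100))
        with pytest.raises(ValueError):
            SimConfig(candidate_snp_index=10)  # outside the default tract
        with pytest.raises(ValueError):
            SimConfig(h2=1.2)


def test_stage_seed_is_deterministic_and_bounded():
    assert stage_seed(1, "freqs") == stage_seed(1, "freqs")
    assert stage_seed(1, "freqs") != stage_seed(1, "panels")
    assert 0 <= stage_seed(2**20, "targets") < 2**31
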
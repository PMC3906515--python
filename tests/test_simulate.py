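"""Generator contracts: profiles, mixtures, hybridization and fixture I/O."""

import numpy as np
import pandas as pd
import pytest

import coldjet
from coldjet.arrays import DESIGN_CC_VS_CCCJ, read_array_table
from coldjet.errors import ConfigurationError
from coldjet.simulate import (
    LABEL_ASTRO_DOWN,
    LABEL_ASTRO_UP,
    LABEL_NEURON,
    Profiles,
    SimulationConfig,
    generate_profiles,
    mix_samples,
    read_simulation_config,
    simulate_hybridization,
)
from conftest import NOISE_FREE


class TestGenerateProfiles:
    def test_zero_effect_identity(self):
        cfg = SimulationConfig(n_genes=500, frac_astro_up=0.0, frac_astro_down=0.0)
        profiles, _ = generate_profiles(cfg)
        np.testing.assert_array_equal(profiles.astro_cocultured, profiles.astro_alone)

    def test_no_neuron_enriched_class_leaves_neuron_profile_low(self):
        cfg = SimulationConfig(n_genes=2000, frac_neuron_enriched=0.0, seed=3)
        profiles, truth = generate_profiles(cfg)
        assert (truth.labels != LABEL_NEURON).all()
        # background neuron expression sits well below the astrocyte baseline
        assert np.log2(profiles.neuron).max() < cfg.abundance_log2_mean

    def test_determinism_and_seed_sensitivity(self):
        cfg = SimulationConfig(n_genes=300, seed=7)
        p1, t1 = generate_profiles(cfg)
        p2, t2 = generate_profiles(cfg)
        np.testing.assert_array_equal(p1.astro_alone, p2.astro_alone)
        np.testing.assert_array_equal(t1.log2_effects, t2.log2_effects)
        p3, _ = generate_profiles(cfg.replace(seed=8))
        assert (p1.astro_alone != p3.astro_alone).any()

    def test_truth_partition_and_effect_iff_label(self):
        cfg = SimulationConfig(n_genes=1000, seed=1)
        _, truth = generate_profiles(cfg)
        n_labels = pd.Series(truth.labels).value_counts()
        assert n_labels[LABEL_NEURON] == 30
        assert n_labels[LABEL_ASTRO_UP] == 20
        assert n_labels[LABEL_ASTRO_DOWN] == 10
        null = truth.labels == "null"
        assert (truth.log2_effects[null] == 0).all()
        assert (truth.log2_effects[~null] != 0).all()
        assert (truth.log2_effects[truth.labels == LABEL_ASTRO_DOWN] < 0).all()

    @pytest.mark.parametrize("field,value", [
        ("frac_astro_up", 1.2),
        ("contamination_c", -0.1),
        ("noise_sd_log2", -1.0),
        ("n_genes", 0),
    ])
    def test_invalid_config_names_field(self, field, value):
        with pytest.raises(ConfigurationError, match=field):
            generate_profiles(SimulationConfig(**{field: value}))

    def test_abundances_strictly_positive(self):
        profiles, _ = generate_profiles(SimulationConfig(n_genes=500, seed=2))
        for vec in (profiles.astro_alone, profiles.astro_cocultured, profiles.neuron):
            assert (vec > 0).all()


class TestMixSamples:
    def _manual(self, c, r):
        """Two genes: a pure-neuron transcript and a pure-astrocyte one."""
        genes = np.array(["G1", "G2"])
        profiles = Profiles(gene_ids=genes,
                            astro_alone=np.array([0.0, 1000.0]),
                            astro_cocultured=np.array([0.0, 1000.0]),
                            neuron=np.array([1000.0, 0.0]))
        cfg = SimulationConfig(n_genes=2, contamination_c=c, removal_r=r)
        _, truth = generate_profiles(SimulationConfig(n_genes=2))
        return profiles, truth, cfg

    def test_mixture_formula_pure_neuron_gene(self):
        # oracle: direct evaluation of the mixture formula before rescaling
        profiles, truth, cfg = self._manual(c=0.5, r=0.9)
        expected_cc = np.array([500.0, 500.0])
        expected_cccj = np.array([50.0, 500.0])
        samples = mix_samples(profiles, truth, cfg)
        # rescaling preserves within-sample proportions
        np.testing.assert_allclose(samples.cc / samples.cc.sum(),
                                   expected_cc / expected_cc.sum(), rtol=1e-12)
        np.testing.assert_allclose(samples.cccj / samples.cccj.sum(),
                                   expected_cccj / expected_cccj.sum(), rtol=1e-12)
        assert samples.aa[0] == 0.0
        # 90% of the neuronal signal is gone before rescaling
        assert expected_cccj[0] / expected_cc[0] == pytest.approx(0.1)

    def test_complete_removal_recovers_astro_profile(self):
        cfg = SimulationConfig(n_genes=400, removal_r=1.0, seed=4)
        profiles, truth = generate_profiles(cfg)
        samples = mix_samples(profiles, truth, cfg)
        coc = profiles.astro_cocultured
        np.testing.assert_allclose(samples.cccj / samples.cccj.sum(),
                                   coc / coc.sum(), rtol=1e-12)

    def test_no_contamination(self):
        cfg = SimulationConfig(n_genes=400, contamination_c=0.0, seed=4)
        profiles, truth = generate_profiles(cfg)
        samples = mix_samples(profiles, truth, cfg)
        np.testing.assert_allclose(samples.cc, samples.cccj, rtol=1e-12)
        coc = profiles.astro_cocultured
        np.testing.assert_allclose(samples.cc / samples.cc.sum(),
                                   coc / coc.sum(), rtol=1e-12)

    def test_mass_conservation(self):
        cfg = SimulationConfig(n_genes=800, seed=9)
        profiles, truth = generate_profiles(cfg)
        samples = mix_samples(profiles, truth, cfg)
        for vec in (samples.aa, samples.cc, samples.cccj):
            assert vec.sum() == pytest.approx(samples.total_mass, rel=1e-9)

    def test_residual_neuronal_fraction_decreases_in_r(self):
        profiles, truth, _ = self._manual(c=0.5, r=0.0)
        fractions = []
        for r in (0.0, 0.3, 0.6, 0.9, 0.99):
            cfg = SimulationConfig(n_genes=2, contamination_c=0.5, removal_r=r)
            samples = mix_samples(profiles, truth, cfg)
            fractions.append(samples.cccj[0] / samples.cccj.sum())
        assert all(a > b for a, b in zip(fractions, fractions[1:]))


class TestSimulateHybridization:
    def test_noise_free_m_is_exact_log_ratio(self):
        cfg = SimulationConfig(n_genes=200, seed=6, **NOISE_FREE)
        profiles, truth = generate_profiles(cfg)
        samples = mix_samples(profiles, truth, cfg)
        rng = np.random.default_rng(0)
        scan = simulate_hybridization(samples.cc, samples.cccj,
                                      DESIGN_CC_VS_CCCJ, cfg, truth, rng, "a")
        from coldjet.arrays import ma_transform

        ma = ma_transform(scan, floor=1e-12)
        expected = np.repeat(np.log2(samples.cc / samples.cccj), cfg.probes_per_gene)
        np.testing.assert_allclose(ma.m, expected, atol=1e-9)

    def test_constant_bias_shifts_numerator_channel_m(self):
        # red is the biased channel and the numerator for CC vs CC-CJ
        cfg = SimulationConfig(n_genes=200, seed=6, **NOISE_FREE).replace(
            dye_bias_coeffs=(0.5,))
        profiles, truth = generate_profiles(cfg)
        samples = mix_samples(profiles, truth, cfg)
        rng = np.random.default_rng(0)
        scan = simulate_hybridization(samples.cc, samples.cccj,
                                      DESIGN_CC_VS_CCCJ, cfg, truth, rng, "a")
        from coldjet.arrays import ma_transform

        ma = ma_transform(scan, floor=1e-12)
        expected = np.repeat(np.log2(samples.cc / samples.cccj), cfg.probes_per_gene)
        np.testing.assert_allclose(ma.m, expected + 0.5, atol=1e-9)

    def test_mean_deviation_matches_injected_bias(self):
        # Monte-Carlo: with a constant injected bias and noise, the mean of
        # (M − true log2 ratio) estimates the bias within 3 standard errors
        cfg = SimulationConfig(n_genes=5000, seed=12, dye_bias_coeffs=(0.3,),
                               probe_affinity_sd_log2=0.0, channel_gain_sd_log2=0.0)
        profiles, truth = generate_profiles(cfg)
        samples = mix_samples(profiles, truth, cfg)
        rng = np.random.default_rng(1)
        scan = simulate_hybridization(samples.cc, samples.cccj,
                                      DESIGN_CC_VS_CCCJ, cfg, truth, rng, "a")
        from coldjet.arrays import ma_transform

        ma = ma_transform(scan, floor=1e-12)
        true = np.repeat(np.log2(samples.cc / samples.cccj), cfg.probes_per_gene)
        dev = ma.m - true
        se = dev.std(ddof=1) / np.sqrt(dev.size)
        assert abs(dev.mean() - 0.3) < 3 * se

    def test_mismatched_gene_universe_rejected(self):
        cfg = SimulationConfig(n_genes=50, **NOISE_FREE)
        profiles, truth = generate_profiles(cfg)
        from coldjet.errors import InputError

        with pytest.raises(InputError):
            simulate_hybridization(profiles.astro_alone[:-1], profiles.neuron,
                                   DESIGN_CC_VS_CCCJ, cfg, truth,
                                   np.random.default_rng(0), "a")


class TestWriteExperiment:
    def test_layout_and_round_trip(self, small_fixture_dir):
        out, config, paths = small_fixture_dir
        array_files = sorted((out / "arrays").glob("array*.tsv"))
        assert len(array_files) == 4
        orders = [pd.read_csv(f, sep="\t")["probe_id"].tolist() for f in array_files]
        assert all(o == orders[0] for o in orders[1:])

        exp = coldjet.simulate_experiment(config)
        design_map = pd.read_csv(paths["design_map"], sep="\t")
        for scan, (_, row) in zip(exp.scans, design_map.iterrows()):
            back = read_array_table(out / "arrays" / f"{row['array_id']}.tsv",
                                    design=row["design"], array_id=row["array_id"])
            # controls are stripped on read; data rows round-trip bit-exactly
            pd.testing.assert_frame_equal(back.probes, scan.probes)

    def test_control_rows_present_in_file_absent_from_scan(self, small_fixture_dir):
        out, config, paths = small_fixture_dir
        raw = pd.read_csv(out / "arrays" / "array1.tsv", sep="\t")
        assert (raw["is_control"] == 1).sum() == config.n_control_probes
        scan = read_array_table(out / "arrays" / "array1.tsv",
                                design="CCCJ_vs_AACJ")
        assert not scan.probes["probe_id"].str.startswith("CTRL").any()

    def test_truth_counts_match_configured_fractions(self, small_fixture_dir):
        out, config, paths = small_fixture_dir
        truth = pd.read_csv(paths["truth"], sep="\t")
        counts = truth["label"].value_counts()
        assert counts[LABEL_NEURON] == round(config.frac_neuron_enriched * config.n_genes)
        assert counts[LABEL_ASTRO_UP] == round(config.frac_astro_up * config.n_genes)
        assert counts[LABEL_ASTRO_DOWN] == round(config.frac_astro_down * config.n_genes)

    def test_config_file_round_trip(self, small_fixture_dir):
        out, config, paths = small_fixture_dir
        assert read_simulation_config(paths["config"]) == config
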
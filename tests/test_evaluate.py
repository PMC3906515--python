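"""Removal-efficiency estimation and replicate concordance."""

import numpy as np
import pandas as pd
import pytest

import coldjet
from coldjet.arrays import DESIGN_CC_VS_CCCJ, ma_transform
from coldjet.errors import InputError
from coldjet.evaluate import (
    cross_array_channel_normalize,
    estimate_removal,
    neuron_enriched_probe_set,
    removal_efficiency,
    replicate_concordance,
)
from coldjet.normalize import normalize_array
from coldjet.simulate import LABEL_NEURON


def series(values):
    return pd.Series(np.asarray(values, dtype=float),
                     index=[f"p{i}" for i in range(len(values))])


class TestRemovalEfficiency:
    def test_complete_removal(self):
        rep = removal_efficiency(series([100, 50]), series([1000, 800]),
                                 series([100, 50]))
        assert rep.removal_percent == pytest.approx(100.0)

    def test_no_removal(self):
        rep = removal_efficiency(series([100, 50]), series([1000, 800]),
                                 series([1000, 800]))
        assert rep.removal_percent == pytest.approx(0.0)

    def test_reference_arithmetic(self):
        # residual = 100·(200−100)/(1100−100) = 10 → removal 90
        rep = removal_efficiency(series([100.0]), series([1100.0]),
                                 series([200.0]))
        assert rep.residual_percent["residual_percent"].iloc[0] == pytest.approx(10.0)
        assert rep.removal_percent == pytest.approx(90.0)

    def test_common_rescaling_invariance(self, rng):
        aa = series(rng.uniform(10, 100, 30))
        cc = aa + rng.uniform(100, 1000, 30)
        cccj = aa + 0.2 * (cc - aa)
        r1 = removal_efficiency(aa, cc, cccj).removal_percent
        r2 = removal_efficiency(13.7 * aa, 13.7 * cc, 13.7 * cccj).removal_percent
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_small_denominator_probes_skipped(self):
        aa = series([100.0, 500.0])
        cc = series([1100.0, 500.0])     # second probe: no co-culture excess
        cccj = series([200.0, 400.0])
        rep = removal_efficiency(aa, cc, cccj, denominator_floor=1.0)
        assert rep.n_skipped_denominator == 1
        assert rep.removal_percent == pytest.approx(90.0)

    def test_all_probes_unusable_rejected(self):
        with pytest.raises(InputError):
            removal_efficiency(series([100.0]), series([100.0]), series([100.0]))

    def test_residuals_clipped_to_physical_range(self):
        rep = removal_efficiency(series([100.0]), series([200.0]),
                                 series([400.0]))  # residual would be 300%
        assert rep.residual_percent["residual_percent"].iloc[0] == 100.0


class TestNeuronEnrichedProbeSet:
    def test_top_probes_carry_neuron_truth_label(self, default_experiment,
                                                 normalized_default):
        norm, _ = normalized_default
        dep = [ma for ma in norm if ma.design == DESIGN_CC_VS_CCCJ]
        probes = neuron_enriched_probe_set(dep[0], dep[1], n=40)
        truth = default_experiment.truth
        neuron = set(truth.genes_with_label(LABEL_NEURON))
        genes = [p.rsplit("_p", 1)[0] for p in probes]
        frac = sum(g in neuron for g in genes) / len(genes)
        assert frac >= 0.9

    def test_zero_n_gives_empty_set(self, normalized_default):
        norm, _ = normalized_default
        dep = [ma for ma in norm if ma.design == DESIGN_CC_VS_CCCJ]
        assert neuron_enriched_probe_set(dep[0], dep[1], n=0) == []

    def test_deterministic(self, normalized_default):
        norm, _ = normalized_default
        dep = [ma for ma in norm if ma.design == DESIGN_CC_VS_CCCJ]
        assert neuron_enriched_probe_set(dep[0], dep[1]) == \
            neuron_enriched_probe_set(dep[0], dep[1])


class TestCrossArrayChannelNormalize:
    def test_replicate_channels_of_identical_sample_align(self, default_experiment):
        samples = cross_array_channel_normalize(default_experiment.scans)
        assert set(samples) == {"AA-CJ", "CC", "CC-CJ"}

    def test_scale_removal_between_duplicated_channels(self, rng):
        cfg = coldjet.SimulationConfig(n_genes=300, seed=2, noise_sd_log2=0.0,
                                       dye_bias_coeffs=(0.0,),
                                       probe_affinity_sd_log2=0.0,
                                       channel_gain_sd_log2=0.0)
        exp = coldjet.simulate_experiment(cfg)
        scan = exp.scans[2]
        doubled = coldjet.ArrayScan(
            array_id="dup", design=scan.design,
            probes=scan.probes.assign(red=2.0 * scan.probes["red"],
                                      green=2.0 * scan.probes["green"]))
        samples = cross_array_channel_normalize([scan, doubled])
        # the factor-2 gain is removed: averaged vectors are proportional to
        # the single-array channels by one common factor across samples
        single = cross_array_channel_normalize([scan])
        factors = []
        for name in samples:
            ratio = samples[name] / single[name]
            np.testing.assert_allclose(ratio, ratio.iloc[0], rtol=1e-9)
            factors.append(ratio.iloc[0])
        np.testing.assert_allclose(factors, factors[0], rtol=1e-9)

    def test_scaled_fluorescence_tracks_true_abundance(self, default_experiment):
        from scipy.stats import spearmanr

        exp = default_experiment
        samples = cross_array_channel_normalize(exp.scans)
        true = pd.Series(np.repeat(exp.samples.cc, exp.config.probes_per_gene),
                         index=exp.truth.probe_ids)
        rho = spearmanr(samples["CC"], true.loc[samples["CC"].index]).statistic
        assert rho > 0.95

    def test_probe_universe_mismatch_rejected(self, default_experiment):
        scan = default_experiment.scans[0]
        truncated = coldjet.ArrayScan(array_id="t", design=scan.design,
                                      probes=scan.probes.iloc[:-1])
        with pytest.raises(InputError):
            cross_array_channel_normalize([scan, truncated])


class TestEstimateRemoval:
    @staticmethod
    def run(cfg):
        exp = coldjet.simulate_experiment(cfg)
        fits, dep = {}, []
        for scan in exp.scans:
            norm, fit = normalize_array(ma_transform(scan))
            fits[scan.array_id] = fit
            if scan.design == DESIGN_CC_VS_CCCJ:
                dep.append(norm)
        return estimate_removal(exp.scans, tuple(dep), trend_fits=fits)

    def test_recovers_default_removal_rate(self):
        rep = self.run(coldjet.SimulationConfig(seed=17))
        assert rep.removal_percent == pytest.approx(90.0, abs=5.0)

    def test_monotone_in_true_removal(self):
        estimates = [self.run(coldjet.SimulationConfig(removal_r=r, seed=17)
                              ).removal_percent
                     for r in (0.5, 0.7, 0.9)]
        assert estimates[0] < estimates[1] < estimates[2]


class TestReplicateConcordance:
    def _scans_with(self, va, vb):
        probes_a = pd.DataFrame({
            "probe_id": [f"p{i}" for i in range(len(va))],
            "gene_id": [f"g{i}" for i in range(len(va))],
            "red": np.asarray(va, dtype=float),
            "green": np.ones(len(va)),
        })
        probes_b = probes_a.assign(red=np.asarray(vb, dtype=float))
        return [
            coldjet.ArrayScan("r1", DESIGN_CC_VS_CCCJ, probes_a),
            coldjet.ArrayScan("r2", DESIGN_CC_VS_CCCJ, probes_b),
        ]

    def _rho(self, va, vb):
        scans = self._scans_with(va, vb)
        rep = replicate_concordance(scans, [f"p{i}" for i in range(len(va))])
        return rep.pairs.set_index("sample").loc["CC", "rho"]

    def test_identical_vectors(self):
        assert self._rho([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == pytest.approx(1.0)

    def test_reversed_ranks(self):
        assert self._rho([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_reference_example(self):
        assert self._rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]) == pytest.approx(0.8)

    def test_matches_brute_force_rank_formula(self, rng):
        """Spearman via scipy equals Pearson on hand-computed average ranks."""

        def average_ranks(v):
            v = np.asarray(v, dtype=float)
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sorted_v = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sorted_v[j] == sorted_v[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0  # 1-based average rank
                i = j
            return ranks

        def pearson(x, y):
            x, y = x - x.mean(), y - y.mean()
            return float((x * y).sum() / np.sqrt((x * x).sum() * (y * y).sum()))

        for _ in range(50):
            n = int(rng.integers(3, 9))
            va = rng.integers(0, 5, n)          # ties likely
            vb = rng.integers(0, 5, n)
            if len(set(va)) < 2 or len(set(vb)) < 2:
                continue
            expected = pearson(average_ranks(va), average_ranks(vb))
            assert self._rho(va, vb) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_reports_nan(self):
        rho = self._rho([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho)

    def test_too_few_probes_rejected(self):
        scans = self._scans_with([1, 2], [2, 1])
        with pytest.raises(InputError):
            replicate_concordance(scans, ["p0"])

    def test_high_concordance_on_synthetic_replicates(self, default_experiment,
                                                      normalized_default):
        norm, _ = normalized_default
        reg = [ma for ma in norm if ma.design == "CCCJ_vs_AACJ"]
        regulated = coldjet.select_regulated(
            tuple(reg), tuple(ma for ma in norm if ma.design == DESIGN_CC_VS_CCCJ))
        genes = set(regulated.up_genes) | set(regulated.down_genes)
        probe_ids = reg[0].table.loc[reg[0].table["gene_id"].isin(genes),
                                     "probe_id"].tolist()
        rep = replicate_concordance(default_experiment.scans, probe_ids)
        assert (rep.pairs["rho"] > 0.8).all()
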
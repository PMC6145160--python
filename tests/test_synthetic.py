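import numpy as np
import pytest

from eegsmallworld.connectivity import histogram_mi, normalized_mi
from eegsmallworld.io import CohortIOError, read_cohort, write_cohort
from eegsmallworld.pipeline import subject_band_connectivity
from eegsmallworld.preprocessing import BandDefinition
from eegsmallworld.synthetic import (ConfigurationError, SimulationConfig,
                                     channel_coupling_adjacency,
                                     generate_cohort, no_coupling,
                                     patient_like_config, powerlaw_noise,
                                     star_coupling)


def small_config(**kw):
    defaults = dict(n_per_group=2, duration_s=10.0, seed=0)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfig:
    def test_default_study_design(self):
        cfg = SimulationConfig()
        assert cfg.n_per_group == 14 and cfg.n_channels == 24
        assert [b.name for b in cfg.bands] == ["delta", "theta", "alpha", "beta"]
        # patient theta: fewer coupled channel pairs and >= 30% weaker
        ctl = channel_coupling_adjacency(cfg.source_clusters,
                                         cfg.coupling_graph_control["theta"], 24)
        pat = channel_coupling_adjacency(cfg.source_clusters,
                                         cfg.coupling_graph_patient["theta"], 24)
        assert pat.sum() < ctl.sum()
        reduction = 1 - (cfg.coupling_strength_patient["theta"]
                         / cfg.coupling_strength_control["theta"])
        assert reduction >= 0.30

    def test_invalid_band_rejected(self):
        cfg = small_config(bands=(BandDefinition("bad", 4.0, 200.0),))
        with pytest.raises(ConfigurationError):
            cfg.validate()

    def test_invalid_strength_rejected(self):
        cfg = small_config()
        cfg.coupling_strength_control["theta"] = 1.5
        with pytest.raises(ConfigurationError):
            cfg.validate()

    def test_overlapping_clusters_rejected(self):
        cfg = small_config()
        cfg.source_clusters = [[0, 1], [1, 2]]
        cfg.coupling_graph_control = {b.name: no_coupling(2) for b in cfg.bands}
        cfg.coupling_graph_patient = {b.name: no_coupling(2) for b in cfg.bands}
        with pytest.raises(ConfigurationError):
            cfg.validate()

    def test_asymmetric_adjacency_rejected(self):
        cfg = small_config()
        bad = np.zeros((4, 4), dtype=int)
        bad[0, 1] = 1
        cfg.coupling_graph_control["theta"] = bad
        with pytest.raises(ConfigurationError):
            cfg.validate()

    def test_patient_like_config_reduction(self):
        cfg = patient_like_config(0.4)
        assert cfg.coupling_strength_patient["theta"] == pytest.approx(
            0.6 * cfg.coupling_strength_control["theta"])


class TestGenerateCohort:
    def test_cohort_size_and_shape(self):
        cohort = generate_cohort(SimulationConfig(n_per_group=14, duration_s=10.0, seed=1))
        assert len(cohort) == 28
        assert all(r.data.shape[0] == 24 for r in cohort)
        assert sum(r.group == "control" for r in cohort) == 14

    def test_reproducible_given_seed(self):
        a = generate_cohort(small_config(seed=5))
        b = generate_cohort(small_config(seed=5))
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.data, rb.data)
            assert ra.executive_time_s == rb.executive_time_s
            assert ra.error_count == rb.error_count

    def test_different_seed_differs(self):
        a = generate_cohort(small_config(seed=5))
        b = generate_cohort(small_config(seed=6))
        assert not np.array_equal(a[0].data, b[0].data)

    def test_zero_coupling_gives_independent_channels(self):
        # 10000+ samples: the histogram-MI bias of independent signals
        # stays below 0.05 normalized MI
        cfg = small_config(n_per_group=1, duration_s=48.0, n_channels=8)
        for d in (cfg.coupling_strength_control, cfg.coupling_strength_patient):
            for k in d:
                d[k] = 0.0
        cohort = generate_cohort(cfg)
        vals = []
        for rec in cohort:
            from eegsmallworld.preprocessing import bandpass_zero_phase
            theta = bandpass_zero_phase(rec.data, rec.fs, 4.0, 7.0)
            for i in range(rec.data.shape[0]):
                for j in range(i + 1, rec.data.shape[0]):
                    vals.append(normalized_mi(histogram_mi(theta[i], theta[j])))
        assert np.mean(vals) < 0.05

    def test_coupled_pair_exceeds_uncoupled_in_every_subject(self):
        cfg = small_config(n_per_group=2, duration_s=30.0, n_channels=4)
        cfg.source_clusters = [[0, 1]]
        for graphs in (cfg.coupling_graph_control, cfg.coupling_graph_patient):
            for k in graphs:
                graphs[k] = no_coupling(1)
        for strengths in (cfg.coupling_strength_control, cfg.coupling_strength_patient):
            for k in strengths:
                strengths[k] = 0.9
        for rec in generate_cohort(cfg):
            m = subject_band_connectivity(rec, band_names=["theta"])["theta"]
            assert m.values[0, 1] > m.values[2, 3]

    def test_behavior_correlates_with_deficit(self):
        cohort = generate_cohort(SimulationConfig(n_per_group=14, duration_s=10.0, seed=3))
        deficit = [r.theta_coupling_deficit for r in cohort]
        times = [r.executive_time_s for r in cohort]
        assert np.corrcoef(deficit, times)[0, 1] > 0.3

    def test_group_means_match_design(self):
        cohort = generate_cohort(SimulationConfig(n_per_group=14, duration_s=10.0, seed=4))
        t_pat = np.mean([r.executive_time_s for r in cohort if r.group == "patient"])
        t_ctl = np.mean([r.executive_time_s for r in cohort if r.group == "control"])
        assert t_pat > t_ctl
        assert 60 < t_ctl < 95 and 105 < t_pat < 145

    def test_invalid_config_raises_before_compute(self):
        cfg = small_config()
        cfg.coupling_strength_patient["theta"] = -0.1
        with pytest.raises(ConfigurationError):
            generate_cohort(cfg)


class TestPowerlawNoise:
    def test_unit_variance_and_spectral_slope(self):
        rng = np.random.default_rng(0)
        x = powerlaw_noise(2**14, 1.0, rng)
        assert x.std() == pytest.approx(1.0, abs=1e-9)
        f = np.fft.rfftfreq(len(x))
        p = np.abs(np.fft.rfft(x)) ** 2
        lo = p[(f > 0.001) & (f < 0.01)].mean()
        hi = p[(f > 0.1) & (f < 0.5)].mean()
        assert lo > 10 * hi  # power falls with frequency


class TestCohortIO:
    def test_round_trip(self, tmp_path):
        cohort = generate_cohort(small_config(seed=9, n_channels=4, duration_s=10.0))
        write_cohort(cohort, tmp_path)
        back = read_cohort(tmp_path)
        assert [r.subject_id for r in back] == [r.subject_id for r in cohort]
        for ra, rb in zip(cohort, back):
            assert ra.group == rb.group
            assert ra.executive_time_s == pytest.approx(rb.executive_time_s)
            assert ra.error_count == rb.error_count
            assert ra.channel_labels == rb.channel_labels
            np.testing.assert_allclose(ra.data, rb.data, rtol=1e-6, atol=1e-4)

    def test_missing_signal_file_reported(self, tmp_path):
        cohort = generate_cohort(small_config(seed=9, n_channels=3, duration_s=10.0))
        write_cohort(cohort, tmp_path)
        victim = tmp_path / f"{cohort[0].subject_id}.tsv"
        victim.unlink()
        with pytest.raises(CohortIOError, match=cohort[0].subject_id):
            read_cohort(tmp_path)

    def test_missing_manifest_reported(self, tmp_path):
        with pytest.raises(CohortIOError):
            read_cohort(tmp_path)

    def test_channel_count_mismatch_reported(self, tmp_path):
        cohort = generate_cohort(small_config(seed=9, n_channels=3, duration_s=10.0))
        write_cohort(cohort, tmp_path)
        victim = tmp_path / f"{cohort[0].subject_id}.tsv"
        data = np.loadtxt(victim, delimiter="\t")
        np.savetxt(victim, data[:2], fmt="%.8e", delimiter="\t")
        with pytest.raises(CohortIOError, match="channel rows"):
            read_cohort(tmp_path)
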
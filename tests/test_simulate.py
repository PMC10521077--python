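import numpy as np
import pytest

from rcdomains.simulate import (ClusterSpec, SimulationConfig,
                                aggregate_and_sample, label_pulse,
                                make_benchmark_suite, replicated_intervals,
                                simulate_cell)


def single_origin_config(**kw):
    spec = ClusterSpec("chr1", 1_000_000, 1.0, n_origins=1,
                       activation=("uniform", 0.0, 0.0))
    defaults = dict(chrom_lengths={"chr1": 2_000_000}, clusters=[spec],
                    bin_size=50_000, entry_window_min=0.0,
                    firing_jitter_sd_min=0.0, n_cells=1, candidate_factor=1,
                    rng_seed=0)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestKinematics:
    def test_single_origin_extent(self):
        origins = np.array([[1_000_000.0, 0.0]])
        rep = replicated_intervals(origins, 40.0, 1.5)
        assert rep.shape == (1, 2)
        assert rep[0] == pytest.approx([1_000_000 - 60_000, 1_000_000 + 60_000])

    def test_converging_forks_merge_at_midpoint(self):
        origins = np.array([[1_000_000.0, 0.0], [1_100_000.0, 0.0]])
        t_meet = 50 / 1.5                 # each fork covers 50 kb
        before = replicated_intervals(origins, t_meet * 0.99, 1.5)
        after = replicated_intervals(origins, t_meet * 1.01, 1.5)
        assert before.shape[0] == 2
        assert after.shape[0] == 1

    def test_zero_efficiency_never_replicates(self):
        cfg = single_origin_config()
        cfg.clusters[0].efficiency = 0.0
        rng = np.random.default_rng(0)
        for _ in range(20):
            cell = simulate_cell(cfg, rng)
            assert "chr1" not in cell.origins


class TestLabelPulse:
    def test_single_origin_pulse_bands(self):
        origins = np.array([[1_000_000.0, 0.0]])
        lab = label_pulse(origins, (10.0, 40.0), 1.5)
        # two bands 15-60 kb either side of the origin
        assert lab.shape[0] == 2
        np.testing.assert_allclose(
            lab, [[940_000, 985_000], [1_015_000, 1_060_000]])

    def test_pulse_before_activation_empty(self):
        origins = np.array([[1_000_000.0, 50.0]])
        assert label_pulse(origins, (10.0, 40.0), 1.5).size == 0

    def test_consecutive_pulses_disjoint_and_tile(self):
        rng = np.random.default_rng(3)
        origins = np.column_stack([rng.uniform(0, 2e6, 10),
                                   rng.uniform(0, 60, 10)])
        origins = origins[np.argsort(origins[:, 0])]
        pulses = [(10.0, 40.0), (40.0, 70.0), (70.0, 100.0)]
        labs = [label_pulse(origins, p, 1.5) for p in pulses]

        def total(iv):
            return iv[:, 1].sum() - iv[:, 0].sum() if iv.size else 0.0

        # pairwise disjoint: overlap length of any two labelled sets is 0
        for i in range(3):
            for j in range(i + 1, 3):
                for a0, a1 in labs[i]:
                    for b0, b1 in labs[j]:
                        assert min(a1, b1) - max(a0, b0) <= 1e-6
        rep_first = replicated_intervals(origins, 10.0, 1.5)
        rep_last = replicated_intervals(origins, 100.0, 1.5)
        assert sum(total(l) for l in labs) == pytest.approx(
            total(rep_last) - total(rep_first))


class TestAggregate:
    def test_support_confined_to_cluster_plus_forks(self):
        cfg = single_origin_config(background_rate=0.0, reads_per_kb=50.0,
                                   n_cells=5)
        sim = aggregate_and_sample(cfg)
        P = sim.pulldown[0]["chr1"]          # pulse 10-40: forks within 60 kb
        centres = P.bin_centres()
        outside = np.abs(centres - 1_000_000) > 100_000
        assert P.values[outside].sum() == 0

    def test_poisson_sampling_matches_expectation(self):
        cfg = single_origin_config(background_rate=3.0, reads_per_kb=20.0,
                                   n_cells=3)
        lam_sum = None
        samples = []
        for rep in range(300):
            cfg.rng_seed = rep
            sim = aggregate_and_sample(cfg)
            exp = (sim.ground_truth.expected_labelled_bp[0]["chr1"] / 1e3
                   * cfg.reads_per_kb + cfg.background_rate)
            lam_sum = exp if lam_sum is None else lam_sum + exp
            samples.append(sim.pulldown[0]["chr1"].values)
        lam = lam_sum / 300
        mean = np.mean(samples, axis=0)
        se = np.sqrt(lam / 300)
        assert (np.abs(mean - lam) <= 3.5 * se + 1e-9).all()

    def test_background_only_normalization_recovers_r(self):
        cfg = SimulationConfig(chrom_lengths={"chr1": 50_000_000}, clusters=[],
                               bin_size=50_000, n_cells=1,
                               background_rate=300.0,
                               control_reads_per_bin=600.0, rng_seed=2)
        sim = aggregate_and_sample(cfg)
        from rcdomains.normalization import normalize_timepoint
        # no-signal data: the broken line is degenerate but r is recovered
        S, fit = normalize_timepoint(sim.pulldown[0], sim.control[0])
        # both tracks RPM-scale to the same total, so true r = 1
        assert fit.chosen_r == pytest.approx(1.0, abs=0.02)

    def test_zero_cells_rejected(self):
        cfg = single_origin_config(n_cells=0)
        with pytest.raises(ValueError):
            aggregate_and_sample(cfg)


class TestPopulationProfile:
    def test_flat_top_with_soft_shoulders(self):
        # isolated cluster, activation density uniform across the pulse
        # span: expected profile has a low-variance central plateau and
        # declining shoulders
        spec = ClusterSpec("chr1", 2_000_000, 600_000, n_origins=8,
                           activation=("uniform", 0.0, 100.0))
        cfg = SimulationConfig(chrom_lengths={"chr1": 4_000_000},
                               clusters=[spec], bin_size=10_000,
                               entry_window_min=0.0, n_cells=400,
                               candidate_factor=1, rng_seed=4)
        sim = aggregate_and_sample(cfg)
        exp = sim.ground_truth.expected_labelled_bp[0]["chr1"]
        centres = (np.arange(exp.size) + 0.5) * cfg.bin_size
        inner = np.abs(centres - 2_000_000) < 200_000
        shoulder = (np.abs(centres - 2_000_000) >= 305_000) \
            & (np.abs(centres - 2_000_000) < 365_000)
        plateau = exp[inner]
        assert plateau.std() < exp[shoulder].std()
        assert plateau.mean() > exp[shoulder].mean()

    def test_labelled_fraction_bounded(self):
        cfg, _ = make_benchmark_suite("basic", seed=0)
        cfg.n_cells = 10
        sim = aggregate_and_sample(cfg)
        for pulse in sim.ground_truth.expected_labelled_bp:
            for arr in pulse.values():
                frac = arr / cfg.bin_size
                assert (frac >= -1e-9).all() and (frac <= 1 + 1e-9).all()


class TestPresets:
    @pytest.mark.parametrize("preset", ["basic", "scale_500", "growth",
                                        "growth_staggered", "valleys",
                                        "domino_null", "domino_coupled"])
    def test_presets_construct(self, preset):
        kwargs = {"n_groups": 8} if preset.startswith("domino") else {}
        cfg, expect = make_benchmark_suite(preset, seed=0, **kwargs)
        assert cfg.clusters or preset == "background"
        assert isinstance(expect, dict)
        doms = cfg.timing_domains()
        for c in cfg.clusters:
            if preset == "valleys" and c.activation[0] == "normal":
                continue                      # valley clusters sit between peaks
            assert doms.domain_of(c.chrom, c.centre) is not None

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            make_benchmark_suite("nope")

    def test_config_round_trip(self, tmp_path):
        cfg, _ = make_benchmark_suite("basic", seed=3)
        cfg.save(tmp_path / "cfg.json")
        import json
        with open(tmp_path / "cfg.json") as fh:
            back = SimulationConfig.from_dict(json.load(fh))
        assert back.chrom_lengths == cfg.chrom_lengths
        assert back.pulses == cfg.pulses
        assert len(back.clusters) == len(cfg.clusters)
        assert back.clusters[0].activation == cfg.clusters[0].activation
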
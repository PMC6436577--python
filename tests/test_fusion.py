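import numpy as np
import pytest
import yaml

from conftest import tiny_fusion_config

from nsctfuse.errors import ConfigurationError, StructureError
from nsctfuse.fusion import (
    FusionConfig,
    _fitness_value,
    _max_avg_fuse_pyramids,
    band_fitness,
    baseline_fuse,
    config_from_dict,
    fuse_bands_pcnn,
    fuse_pyramids,
    fuse_spect_ct,
    load_config,
    pcnn_activity,
)
from nsctfuse.ihs import rgb_to_ihs
from nsctfuse.image_io import ColorImage, normalize_intensity, RasterImage
from nsctfuse.nsct import build_filter_bank, nsct_decompose
from nsctfuse.pcnn import PCNNParams, default_linking_kernel


def mk_params(t=5, beta=0.0):
    return PCNNParams(alpha_theta=0.5, beta=beta, v_theta=10.0, iterations=t)


class TestPcnnActivity:
    def test_zero_band_zero_counts(self):
        fm = pcnn_activity(np.zeros((4, 4)), mk_params())
        assert np.all(fm.counts == 0)

    def test_sign_invariance(self, rng):
        band = rng.standard_normal((8, 8))
        p = mk_params(beta=0.3)
        np.testing.assert_array_equal(
            pcnn_activity(band, p).counts, pcnn_activity(-band, p).counts
        )

    def test_dominant_coefficient_fires_most(self):
        band = np.full((4, 4), 0.1)
        band[2, 2] = -5.0  # dominant magnitude
        counts = pcnn_activity(band, mk_params(t=10)).counts
        assert np.all(counts[2, 2] >= counts)


class TestFuseBands:
    def test_self_fusion_identity(self, rng):
        band = rng.standard_normal((8, 8))
        fused = fuse_bands_pcnn(band, band, mk_params())
        np.testing.assert_array_equal(fused, band)

    def test_larger_count_wins(self, rng, scalar_pcnn_oracle):
        band_a = np.array([[0.0, 4.0], [0.5, 0.1]])
        band_b = np.array([[2.0, 0.2], [0.5, 3.0]])
        p = mk_params(t=4)
        fused = fuse_bands_pcnn(band_a, band_b, p)
        # independent trace: oracle counts on the normalized |band| stimuli
        stim_a = normalize_intensity(
            RasterImage(np.abs(band_a), (0.0, np.inf))
        ).image.pixels
        stim_b = normalize_intensity(
            RasterImage(np.abs(band_b), (0.0, np.inf))
        ).image.pixels
        ca = scalar_pcnn_oracle(stim_a, 0.5, 0.0, 10.0, 4, default_linking_kernel())
        cb = scalar_pcnn_oracle(stim_b, 0.5, 0.0, 10.0, 4, default_linking_kernel())
        expected = np.where(
            ca > cb, band_a, np.where(cb > ca, band_b, (band_a + band_b) / 2)
        )
        np.testing.assert_array_equal(fused, expected)
        assert not np.array_equal(fused, band_a)  # selection actually mixed

    def test_shape_mismatch(self):
        with pytest.raises(StructureError):
            fuse_bands_pcnn(np.zeros((4, 4)), np.zeros((4, 5)), mk_params())

    @pytest.mark.parametrize("policy, expected", [("first", 1.0), ("second", -1.0)])
    def test_tie_policies(self, policy, expected):
        a, b = np.full((4, 4), 1.0), np.full((4, 4), -1.0)
        fused = fuse_bands_pcnn(a, b, mk_params(), tie_policy=policy)
        np.testing.assert_array_equal(fused, np.full((4, 4), expected))


class TestBandFitness:
    def test_constant_identical_bands_zero_entropy(self):
        band = np.full((8, 8), 3.0)
        assert band_fitness(mk_params(), band, band) == 0.0

    def test_deterministic(self, rng):
        a, b = rng.standard_normal((8, 8)), rng.standard_normal((8, 8))
        p = mk_params(beta=0.2)
        assert band_fitness(p, a, b) == band_fitness(p, a, b)

    def test_entropy_ranks_structured_band_above_constant(self):
        two_level = np.where(np.arange(64).reshape(8, 8) % 2 == 0, 0.0, 1.0)
        constant = np.full((8, 8), 0.5)
        assert _fitness_value(two_level, "entropy") == pytest.approx(1.0)
        assert _fitness_value(constant, "entropy") == 0.0

    @pytest.mark.parametrize("name", ["mean_gradient", "entropy_gradient"])
    def test_alternative_fitnesses_finite(self, rng, name):
        a, b = rng.standard_normal((8, 8)), rng.standard_normal((8, 8))
        val = band_fitness(mk_params(), a, b, fitness_name=name)
        assert np.isfinite(val) and val >= 0.0


class TestFusePyramids:
    def test_self_fusion_identity(self, rng):
        bank = build_filter_bank()
        pyr = nsct_decompose(rng.random((32, 32)), (1, (1,)), bank)
        cfg = tiny_fusion_config()
        fused, chosen, _ = fuse_pyramids(pyr, pyr, cfg)
        np.testing.assert_array_equal(fused.low, pyr.low)
        for la, lf in zip(pyr.levels, fused.levels):
            for a, f in zip(la, lf):
                np.testing.assert_array_equal(f, a)

    def test_chosen_params_in_bounds_and_dominant(self, rng):
        bank = build_filter_bank()
        pa = nsct_decompose(rng.random((32, 32)), (1, (1,)), bank)
        pb = nsct_decompose(rng.random((32, 32)), (1, (1,)), bank)
        cfg = tiny_fusion_config(seed=4)
        fused, chosen, results = fuse_pyramids(pa, pb, cfg)
        lo, hi = cfg.sfla_config.lower, cfg.sfla_config.upper
        for name, params in chosen.items():
            assert np.all(np.asarray(params) >= lo)
            assert np.all(np.asarray(params) <= hi)
            res = results[name]
            assert res.best.fitness >= max(
                f.fitness for f in res.initial_population
            )

    def test_spec_mismatch_rejected(self, rng):
        bank = build_filter_bank()
        pa = nsct_decompose(rng.random((32, 32)), (1, (1,)), bank)
        pb = nsct_decompose(rng.random((32, 32)), (1, (2,)), bank)
        with pytest.raises(StructureError):
            fuse_pyramids(pa, pb, tiny_fusion_config())

    def test_shared_granularity(self, rng):
        bank = build_filter_bank()
        pa = nsct_decompose(rng.random((16, 16)), (1, (1,)), bank)
        pb = nsct_decompose(rng.random((16, 16)), (1, (1,)), bank)
        cfg = tiny_fusion_config(granularity="shared")
        _, chosen, _ = fuse_pyramids(pa, pb, cfg)
        assert len(set(chosen.values())) == 1  # one parameter set everywhere


class TestMaxAvgRule:
    def test_low_band_average_high_band_max(self, rng):
        bank = build_filter_bank()
        pa = nsct_decompose(rng.random((32, 32)), (1, (2,)), bank)
        pb = nsct_decompose(rng.random((32, 32)), (1, (2,)), bank)
        fused = _max_avg_fuse_pyramids(pa, pb)
        np.testing.assert_allclose(fused.low, (pa.low + pb.low) / 2.0)
        for a, b, f in zip(pa.levels[0], pb.levels[0], fused.levels[0]):
            np.testing.assert_array_equal(f, np.where(np.abs(a) >= np.abs(b), a, b))


def gray_pair(size=32, seed=0):
    """A SPECT whose IHS intensity equals the CT image exactly."""
    from nsctfuse.phantoms import PhantomSpec, make_ct_phantom

    ct = make_ct_phantom(PhantomSpec(size=(size, size), seed=seed, noise_sd=0.0))
    return ColorImage(ct, ct, ct), ct


class TestEndToEnd:
    def test_self_fusion_recovers_intensity(self):
        spect, ct = gray_pair()
        cfg = tiny_fusion_config(seed=2)
        res = fuse_spect_ct(spect, ct, cfg)
        assert np.abs(res.intensity.pixels - ct.to_unit().pixels).max() < 1e-5

    def test_hue_saturation_preserved(self, small_pair):
        # H and S pass through untouched; only gamut clipping of the output
        # RGB can perturb them, so compare where no channel was clipped
        spect, ct = small_pair
        res = fuse_spect_ct(spect, ct, tiny_fusion_config(seed=3))
        t_in = rgb_to_ihs(spect)
        t_out = rgb_to_ihs(res.fused)
        arr = res.fused.to_array()
        unclipped = np.all((arr > 0.0) & (arr < 1.0), axis=-1)
        assert unclipped.sum() > 0
        chroma = unclipped & (t_in.s > 1e-6)  # hue only defined off gray axis
        np.testing.assert_allclose(t_out.s[unclipped], t_in.s[unclipped], atol=1e-9)
        dh = t_out.h[chroma] - t_in.h[chroma]
        wrapped = np.mod(dh + np.pi, 2 * np.pi) - np.pi  # +pi and -pi coincide
        np.testing.assert_allclose(wrapped, 0.0, atol=1e-9)

    def test_output_in_range_with_clip_count(self, small_pair):
        spect, ct = small_pair
        res = fuse_spect_ct(spect, ct, tiny_fusion_config(seed=5))
        arr = res.fused.to_array()
        assert arr.min() >= 0.0 and arr.max() <= 1.0
        assert res.provenance["clipped_samples"] >= 0

    def test_regional_energy_low_rule_runs(self, small_pair):
        spect, ct = small_pair
        cfg = tiny_fusion_config(seed=1, low_rule="regional_energy")
        res = fuse_spect_ct(spect, ct, cfg)
        assert "low" not in res.chosen_params
        assert np.isfinite(res.metrics.entropy)


class TestBaselines:
    def test_ihs_with_matching_intensity_is_identity(self):
        spect, ct = gray_pair()
        res = baseline_fuse(spect, ct, "ihs")
        np.testing.assert_allclose(
            res.fused.to_array(), spect.to_unit().to_array(), atol=1e-9
        )

    def test_nsct_fl_self_fusion_identity(self):
        spect, ct = gray_pair()
        res = baseline_fuse(spect, ct, "nsct_fl", tiny_fusion_config())
        assert np.abs(res.intensity.pixels - ct.to_unit().pixels).max() < 1e-5

    @pytest.mark.parametrize("method", ["ihs", "nsct_fl", "dwt", "nsct_pcnn"])
    def test_all_methods_finite_metrics(self, small_pair, method):
        spect, ct = small_pair
        res = baseline_fuse(spect, ct, method, tiny_fusion_config(seed=7))
        for v in res.metrics.to_dict().values():
            assert np.isfinite(v) and v >= 0.0

    def test_unknown_method(self, small_pair):
        spect, ct = small_pair
        with pytest.raises(ConfigurationError, match="unknown method"):
            baseline_fuse(spect, ct, "sparse_coding")


class TestConfig:
    def test_defaults_round_trip_through_dict(self):
        cfg = FusionConfig()
        again = config_from_dict(cfg.to_dict())
        assert again.nsct_spec == cfg.nsct_spec
        assert again.sfla_config.pop_size == cfg.sfla_config.pop_size
        np.testing.assert_array_equal(
            again.sfla_config.lower, cfg.sfla_config.lower
        )

    def test_yaml_loading(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            yaml.safe_dump(
                {
                    "nsct_spec": [1, [1]],
                    "pcnn_iterations": 7,
                    "seed": 5,
                    "sfla": {"pop_size": 4, "n_memeplexes": 2, "memeplex_size": 2},
                }
            )
        )
        cfg = load_config(path)
        assert cfg.nsct_spec == (1, (1,))
        assert cfg.pcnn_iterations == 7
        assert cfg.sfla_config.pop_size == 4
        assert cfg.sfla_config.seed == 5

    def test_unknown_keys_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown config keys"):
            config_from_dict({"wavelet": "haar"})

    def test_bad_fitness_name(self):
        with pytest.raises(ConfigurationError):
            FusionConfig(fitness_name="ssim")

    def test_fixed_param_injection_guarantees_dominance(self, rng):
        bank = build_filter_bank()
        pa = nsct_decompose(rng.random((16, 16)), (1, (1,)), bank)
        pb = nsct_decompose(rng.random((16, 16)), (1, (1,)), bank)
        cfg = tiny_fusion_config(seed=8, inject_fixed_params=True)
        _, chosen, results = fuse_pyramids(pa, pb, cfg)
        fixed = cfg.make_params(cfg.fixed_pcnn)
        for name, res in results.items():
            items = {"low": (pa.low, pb.low)}
            for j, bands in enumerate(pa.levels):
                for k in range(len(bands)):
                    items[f"level{j+1}_dir{k}"] = (
                        pa.levels[j][k], pb.levels[j][k]
                    )
            a, b = items[name]
            baseline = band_fitness(fixed, a, b, cfg.fitness_name, cfg.tie_policy)
            assert res.best.fitness >= baseline - 1e-12
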
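import numpy as np
import pytest

from mmgsel.features import (
    FeatureParams,
    approximate_entropy,
    build_feature_matrix,
    extract_fd,
    extract_td,
    extract_wpt_energy,
    fuzzy_entropy,
    lz76_complexity,
    lzc,
    passband_nodes,
    sample_entropy,
    _wpt_node_energy,
)
from mmgsel.preprocess import LabeledSegment, Segment
from tests.oracles import (
    approximate_entropy_oracle,
    fuzzy_entropy_oracle,
    sample_entropy_oracle,
)

FS = 250.0


class TestTimeDomain:
    def test_constant_vector(self):
        fv = extract_td(np.full(50, 2.0))
        vals = dict(zip(fv.names, fv.values))
        assert vals["RMS"] == pytest.approx(2.0)
        assert vals["MAV"] == pytest.approx(2.0)
        assert vals["VAR"] == 0.0
        assert vals["ZC"] == 0
        assert vals["WL"] == 0.0

    def test_alternating_hand_arithmetic(self):
        fv = extract_td(np.array([1.0, -1.0, 1.0, -1.0]))
        vals = dict(zip(fv.names, fv.values))
        assert vals["MAV"] == 1.0
        assert vals["WL"] == 6.0
        assert vals["AAC"] == 2.0
        assert vals["ZC"] == 3

    def test_v_order_2_equals_rms(self, rng):
        x = rng.standard_normal(200)
        fv = extract_td(x, v=2.0)
        vals = dict(zip(fv.names, fv.values))
        assert vals["V2"] == pytest.approx(vals["RMS"], abs=1e-14)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            extract_td(np.array([1.0, 2.0]))

    def test_time_reversal_invariance(self, rng):
        x = rng.standard_normal(300)
        fwd = dict(zip(*(lambda fv: (fv.names, fv.values))(extract_td(x))))
        rev = dict(zip(*(lambda fv: (fv.names, fv.values))(extract_td(x[::-1]))))
        for name in ("RMS", "VAR", "WL", "LOG", "MAV", "V3", "SSI", "AAC"):
            assert fwd[name] == pytest.approx(rev[name], rel=1e-12)

    def test_amplitude_scaling_laws(self, rng):
        x = rng.standard_normal(300)
        a = dict(zip(*(lambda fv: (fv.names, fv.values))(extract_td(x))))
        b = dict(zip(*(lambda fv: (fv.names, fv.values))(extract_td(3.0 * x))))
        for name in ("RMS", "MAV", "WL", "AAC"):
            assert b[name] == pytest.approx(3.0 * a[name], rel=1e-12)
        for name in ("VAR", "SSI"):
            assert b[name] == pytest.approx(9.0 * a[name], rel=1e-12)


class TestFrequencyDomain:
    def test_pure_tone_centroid(self):
        t = np.arange(2048) / FS
        fv = extract_fd(np.sin(2 * np.pi * 40.0 * t), FS)
        mpf, mf = fv.values
        assert mpf == pytest.approx(40.0, abs=2.0)
        assert mf == pytest.approx(40.0, abs=2.0)

    def test_two_equal_tones_mean(self):
        t = np.arange(2048) / FS
        x = np.sin(2 * np.pi * 20.0 * t) + np.sin(2 * np.pi * 60.0 * t)
        mpf = extract_fd(x, FS).values[0]
        assert mpf == pytest.approx(40.0, abs=2.0)

    def test_white_noise_median(self, rng):
        mf = extract_fd(rng.standard_normal(8192), FS).values[1]
        assert mf == pytest.approx(FS / 4, rel=0.10)

    def test_zero_power_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            extract_fd(np.zeros(100), FS)


class TestWaveletPacketEnergy:
    def test_eleven_passband_nodes(self, rng):
        we = extract_wpt_energy(rng.standard_normal(512), FS)
        assert len(we.node_energies) == 11
        assert we.band_edges[0] == pytest.approx((7.8125, 15.625))
        assert we.band_edges[-1] == pytest.approx((85.9375, 93.75))

    def test_zero_signal_zero_energy(self):
        we = extract_wpt_energy(np.zeros(256), FS)
        assert np.all(we.node_energies == 0)

    def test_parseval_over_full_tree(self, rng):
        x = rng.standard_normal(512)
        energies = _wpt_node_energy(x, "db4", 4)
        assert energies.sum() == pytest.approx(np.sum(x**2), rel=0.01)

    def test_node_containment_rule(self):
        keep, edges = passband_nodes(FS, 4)
        assert keep == list(range(1, 12))
        for lo, hi in edges:
            assert 5.0 <= lo < hi <= 100.0

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            extract_wpt_energy(np.zeros(8), FS)


class TestEntropies:
    @pytest.mark.parametrize(
        "impl,oracle",
        [
            (approximate_entropy, approximate_entropy_oracle),
            (sample_entropy, sample_entropy_oracle),
            (fuzzy_entropy, fuzzy_entropy_oracle),
        ],
        ids=["AEn", "SEn", "FEn"],
    )
    def test_matches_brute_force_oracle(self, impl, oracle, rng):
        for _ in range(10):
            n = int(rng.integers(60, 301))
            x = rng.standard_normal(n)
            assert impl(x, 2, 0.2) == pytest.approx(oracle(x, 2, 0.2), abs=1e-12)

    def test_constant_signal_sample_entropy_zero(self):
        assert sample_entropy(np.full(100, 1.5)) == 0.0

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(150)
        for fn in (approximate_entropy, sample_entropy, fuzzy_entropy):
            assert fn(5.0 * x) == pytest.approx(fn(x), rel=1e-9)

    def test_sample_entropy_no_m1_matches_sentinel(self):
        # the template (0, 1) repeats with different successors; with a tiny
        # tolerance B > 0 but A = 0, so the ln(B) ceiling is returned
        x = np.concatenate([[0.0, 1.0, 50.0], [0.0, 1.0, -50.0], np.arange(2, 16) * 7.0])
        with pytest.warns(UserWarning):
            v = sample_entropy(x, m=2, r=1e-9)
        assert np.isfinite(v)

    def test_white_noise_more_entropic_than_sine(self, rng):
        t = np.arange(200) / FS
        assert sample_entropy(rng.standard_normal(200)) > sample_entropy(
            np.sin(2 * np.pi * 10 * t)
        )


class TestLZC:
    def test_constant_complexity_count(self):
        assert lz76_complexity(np.zeros(64, dtype=np.uint8)) == 2

    def test_alternating_below_random(self, rng):
        alternating = np.tile([0.0, 1.0], 32)
        noise = rng.standard_normal(64)  # median binarization -> random bits
        assert lzc(alternating) < lzc(noise)


def _segments_from(rng, n_seg=3, n_samples=300, n_channels=4):
    out = []
    for i in range(n_seg):
        data = rng.standard_normal((n_samples, n_channels))
        out.append(LabeledSegment(Segment(0, n_samples, data), label=f"c{i % 2}"))
    return out


class TestBuildFeatureMatrix:
    @pytest.mark.parametrize(
        "channels,families,expected",
        [
            (None, ("TD", "FD", "NLD"), 64),
            (None, ("TD", "FD", "WE", "NLD"), 108),
            ([0], ("TD",), 10),
        ],
    )
    def test_column_counts(self, rng, channels, families, expected):
        fm = build_feature_matrix(
            _segments_from(rng), FS, channels=channels, families=families
        )
        assert fm.n_features == expected

    def test_channel_major_name_order(self, rng):
        fm = build_feature_matrix(_segments_from(rng), FS, families=("TD", "FD"))
        assert fm.names[0] == "ch1:TD:RMS"
        assert fm.names[12] == "ch2:TD:RMS"
        assert fm.names[10] == "ch1:FD:MPF"

    def test_empty_segments_rejected(self):
        with pytest.raises(ValueError):
            build_feature_matrix([], FS)

    def test_unknown_family_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown"):
            build_feature_matrix(_segments_from(rng), FS, families=("TD", "XX"))
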
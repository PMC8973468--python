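"""Feature formulas against hand-computed oracles, plus algebraic invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pupilload.features import (
    FeatureConfig,
    compute_apcps,
    compute_blps,
    compute_entropy,
    compute_mpdc,
    compute_pcps,
    compute_pd,
    compute_pds,
    compute_ttp,
    extract_features,
)
from pupilload.preprocess import CleanTrial


def clean_trial(pre_diam, stim_times, stim_diam, difficulty="low"):
    pre_diam = np.asarray(pre_diam, dtype=float)
    return CleanTrial(
        subject_id="s00",
        trial_id="t000",
        difficulty=difficulty,
        pre_times=np.linspace(-2.0, -0.1, pre_diam.size),
        pre_diam=pre_diam,
        stim_times=np.asarray(stim_times, dtype=float),
        stim_diam=np.asarray(stim_diam, dtype=float),
        n_dropped=0,
        invalid_fraction=0.0,
    )


class TestBaseline:
    def test_constant(self):
        assert compute_blps([4.0, 4.0, 4.0]) == 4.0

    def test_mean(self):
        assert compute_blps([3.9, 4.1]) == pytest.approx(4.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="baseline undefined"):
            compute_blps([])


class TestMeanChange:
    def test_equal_to_baseline_is_zero(self):
        assert compute_mpdc([4.0, 4.0], 4.0) == 0.0

    def test_hand_value(self):
        assert compute_mpdc([4.2, 4.4, 4.6], 4.0) == pytest.approx(0.4)

    def test_constriction_is_negative(self):
        assert compute_mpdc([3.8], 4.0) == pytest.approx(-0.2)


class TestPercentageChange:
    def test_hand_values(self):
        assert compute_pcps([4.4], 4.0) == pytest.approx([0.1])
        assert compute_pcps([2.0], 4.0) == pytest.approx([-0.5])

    def test_series_at_baseline_is_zero(self):
        assert compute_pcps([4.0, 4.0, 4.0], 4.0) == pytest.approx([0.0, 0.0, 0.0])

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            compute_pcps([4.0], 0.0)

    def test_average(self):
        assert compute_apcps([0.1, 0.3]) == pytest.approx(0.2)
        assert compute_apcps([0.07]) == pytest.approx(0.07)
        assert compute_apcps([0.0, 0.0]) == 0.0


class TestPeakDilation:
    def test_hand_value_and_index(self):
        pd_, ppd, idx = compute_pd([4.0, 4.5, 4.3], 4.0)
        assert pd_ == pytest.approx(0.5) and ppd == pytest.approx(4.5) and idx == 1

    def test_constant_at_baseline_is_zero(self):
        pd_, _, _ = compute_pd([4.0, 4.0, 4.0], 4.0)
        assert pd_ == 0.0

    def test_tie_takes_first_occurrence(self):
        _, _, idx = compute_pd([4.5, 4.5], 4.0)
        assert idx == 0


class TestEntropy:
    def test_single_bin_is_zero(self):
        assert compute_entropy([4.0, 4.001, 4.002], bin_width=0.01) == 0.0

    def test_two_equal_bins_is_one_bit(self):
        assert compute_entropy([4.0, 4.0, 4.05, 4.05], bin_width=0.01) == pytest.approx(1.0)

    def test_hand_value_532_split(self):
        # frequencies {5,3,2}/10 -> -(0.5 lg 0.5 + 0.3 lg 0.3 + 0.2 lg 0.2)
        series = [4.0] * 5 + [4.02] * 3 + [4.04] * 2
        expected = -(0.5 * math.log2(0.5) + 0.3 * math.log2(0.3) + 0.2 * math.log2(0.2))
        assert compute_entropy(series, bin_width=0.01) == pytest.approx(expected)
        assert expected == pytest.approx(1.4855, abs=5e-5)


class TestTimeToPeak:
    def test_peak_at_onset(self):
        assert compute_ttp([0.0, 0.5, 1.0], 0) == 0.0

    def test_lookup(self):
        assert compute_ttp([0.0, 0.5, 1.0], 2) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            compute_ttp([0.0, 0.5], 5)


class TestDilationSpeed:
    def test_flat_segment_angle_zero(self):
        assert compute_pds([0.0, 1.0, 2.0], [4.0, 4.0, 4.0], 2) == 0.0

    def test_hand_ols_on_three_points(self):
        angle = compute_pds([0.0, 1.0, 2.0], [4.0, 4.1, 4.2], 2)
        assert angle == pytest.approx(math.atan(0.1))
        assert angle == pytest.approx(0.09967, abs=5e-6)

    def test_unit_slope_is_quarter_pi(self):
        assert compute_pds([0.0, 1.0], [4.0, 5.0], 1) == pytest.approx(math.pi / 4)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compute_pds([0.0, 1.0], [4.0, 5.0], 0)


class TestExtractFeatures:
    def test_constant_trace_at_baseline(self):
        trial = clean_trial([4.0, 4.0], [0.0, 0.5, 1.0], [4.0, 4.0, 4.0])
        fv = extract_features(trial)
        assert fv.MPDC == 0.0 and fv.APCPS == 0.0 and fv.PD == 0.0
        assert fv.E_pupil == 0.0 and fv.PDS == 0.0

    def test_hand_built_trial_matches_composed_oracles(self):
        """Eight stimulus samples; every feature from first principles."""
        pre = [3.9, 4.1]
        t = np.arange(8) * 0.5
        d = np.array([4.0, 4.1, 4.25, 4.4, 4.5, 4.35, 4.2, 4.1])
        fv = extract_features(clean_trial(pre, t, d))
        blps = 4.0
        assert fv.BLPS == pytest.approx(blps)
        assert fv.MPDC == pytest.approx(d.mean() - blps)
        assert fv.APCPS == pytest.approx(((d - blps) / blps).mean())
        assert fv.PD == pytest.approx(0.5)
        assert fv.TTP == pytest.approx(2.0)
        # OLS slope over the 5 points up to the peak, closed form
        tt, dd = t[:5], d[:5]
        m = ((tt * dd).sum() - tt.sum() * dd.sum() / 5) / ((tt**2).sum() - tt.sum() ** 2 / 5)
        assert fv.PDS == pytest.approx(math.atan(m))
        # 4.1 occurs twice -> bin frequencies {2,1,1,1,1,1,1} over 8 samples
        expected_h = -(2 / 8 * math.log2(2 / 8) + 6 * (1 / 8) * math.log2(1 / 8))
        assert fv.E_pupil == pytest.approx(expected_h)
        assert expected_h == pytest.approx(2.75)

    def test_label_and_ids_copied(self):
        fv = extract_features(
            clean_trial([4.0], [0.0, 0.5, 1.0], [4.0, 4.2, 4.1], difficulty="medium")
        )
        assert (fv.subject_id, fv.trial_id, fv.difficulty) == ("s00", "t000", "medium")


@settings(max_examples=60, deadline=None)
@given(
    pre=st.lists(st.floats(3.0, 6.0), min_size=1, max_size=6),
    stim=st.lists(st.floats(3.0, 6.0), min_size=3, max_size=12),
    shift=st.floats(0.0, 5.0),
    scale=st.floats(0.5, 2.0),
)
def test_algebraic_invariants(pre, stim, shift, scale):
    """Identity APCPS*BLPS == MPDC; PD >= MPDC; entropy bounds; time-shift
    and diameter-scaling behaviour."""
    t = np.arange(len(stim)) * 0.5
    fv = extract_features(clean_trial(pre, t, stim))
    assert fv.APCPS * fv.BLPS == pytest.approx(fv.MPDC, rel=1e-12, abs=1e-12)
    assert fv.PD >= fv.MPDC - 1e-12
    occupied = len(np.unique(np.floor((np.array(stim) - min(stim)) / 0.01).astype(int)))
    assert -1e-12 <= fv.E_pupil <= math.log2(occupied) + 1e-12
    assert 0.0 <= fv.TTP <= t[-1]

    # uniform time shift moves TTP only (onset reference unchanged otherwise)
    fv_shift = extract_features(clean_trial(pre, t + shift, stim))
    assert fv_shift.TTP == pytest.approx(fv.TTP + shift)
    assert fv_shift.MPDC == pytest.approx(fv.MPDC)
    assert fv_shift.E_pupil == pytest.approx(fv.E_pupil)

    # scaling diameters by c scales MPDC and PD by c, APCPS unchanged
    fv_sc = extract_features(
        clean_trial(np.array(pre) * scale, t, np.array(stim) * scale)
    )
    assert fv_sc.MPDC == pytest.approx(scale * fv.MPDC, rel=1e-9, abs=1e-9)
    assert fv_sc.PD == pytest.approx(scale * fv.PD, rel=1e-9, abs=1e-9)
    assert fv_sc.APCPS == pytest.approx(fv.APCPS, rel=1e-9, abs=1e-9)
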
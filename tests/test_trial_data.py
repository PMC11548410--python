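"""Trial preprocessing, labeling and I/O round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinegan import (
    Dataset,
    DialectConfig,
    InvalidTrialError,
    KinematicTrial,
    assign_impairment_group,
    decode_class,
    encode_class,
    load_trials,
    normalize_units,
    pad_or_crop,
    severity_band,
    write_trials,
)
from kinegan.channels import CHANNEL_NAMES, N_CLASSES


class TestPadOrCrop:
    def test_identity_at_target_length(self):
        x = np.random.default_rng(0).normal(size=(300, 9))
        assert np.array_equal(pad_or_crop(x), x)

    def test_short_signal_repeats_final_value(self):
        x = np.random.default_rng(1).normal(size=(250, 9))
        out = pad_or_crop(x)
        assert out.shape == (300, 9)
        assert np.array_equal(out[:250], x)
        assert np.array_equal(out[250:], np.tile(x[-1], (50, 1)))

    def test_long_signal_keeps_first_rows(self):
        x = np.random.default_rng(2).normal(size=(400, 9))
        expected = np.array([[x[t, c] for c in range(9)] for t in range(300)])  # naive slice oracle
        assert np.array_equal(pad_or_crop(x), expected)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(min_value=1, max_value=450))
    def test_idempotent(self, t):
        x = np.random.default_rng(t).normal(size=(t, 9))
        once = pad_or_crop(x)
        assert np.array_equal(pad_or_crop(once), once)

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidTrialError):
            pad_or_crop(np.empty((0, 9)))


class TestNormalizeUnits:
    def test_meters_to_centimeters_and_degrees_to_radians(self):
        x = np.zeros((2, 9))
        x[0, 0] = 1.0  # T8x: 1 m
        x[0, 4] = 180.0  # shoulder angle: 180 deg
        out = normalize_units(x, "m", "deg")
        assert out[0, 0] == pytest.approx(100.0)
        assert out[0, 4] == pytest.approx(np.pi)

    def test_round_trip_cm(self):
        x = np.random.default_rng(3).normal(size=(5, 9))
        back = normalize_units(normalize_units(x, "cm", "rad") / 100.0, "m", "rad")
        back[:, 3:] = normalize_units(x, "cm", "rad")[:, 3:]
        assert np.allclose(back[:, :3], x[:, :3], atol=1e-12)

    def test_unknown_unit_is_config_error(self):
        with pytest.raises(KeyError):
            normalize_units(np.zeros((1, 9)), "furlong", "rad")


class TestImpairmentGrouping:
    def test_control_ignores_score(self):
        assert assign_impairment_group(None, is_control=True) == "control"

    @pytest.mark.parametrize(
        "score,expected",
        [(55, "mild"), (21, "modsev"), (42, "modsev"), (43, "mild")],
    )
    def test_fmma_threshold(self, score, expected):
        assert assign_impairment_group(score, is_control=False) == expected

    def test_stroke_without_score_rejected(self):
        with pytest.raises(InvalidTrialError):
            assign_impairment_group(None, is_control=False)

    @pytest.mark.parametrize("score,band", [(21, "severe"), (24, "severe"), (25, "moderate"),
                                            (42, "moderate"), (53, "moderate"), (54, "mild")])
    def test_severity_band(self, score, band):
        assert severity_band(score) == band

    def test_severity_band_partitions_score_range(self):
        bands = [severity_band(s) for s in range(67)]
        assert bands == ["severe"] * 25 + ["moderate"] * 29 + ["mild"] * 13

    def test_out_of_range_score_rejected(self):
        with pytest.raises(InvalidTrialError):
            severity_band(67)


class TestClassLabels:
    def test_corner_codes(self):
        assert encode_class(0, 0).code == 0
        assert encode_class(9, 2).code == 29

    def test_bijection_over_grid(self):
        codes = {encode_class(t, g).code for t in range(10) for g in range(3)}
        assert codes == set(range(N_CLASSES))
        for code in range(N_CLASSES):
            assert encode_class(*decode_class(code)).code == code

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidTrialError):
            encode_class(10, 0)
        with pytest.raises(InvalidTrialError):
            encode_class(0, 3)


class TestTrialInvariants:
    def test_wrong_shape_rejected(self):
        with pytest.raises(InvalidTrialError):
            KinematicTrial(signal=np.zeros((299, 9)), task="T02", group="mild")

    def test_nonfinite_rejected(self):
        sig = np.zeros((300, 9))
        sig[5, 5] = np.nan
        with pytest.raises(InvalidTrialError):
            KinematicTrial(signal=sig, task="T02", group="mild")


class TestTrialIO:
    def test_round_trip_is_identity(self, small_dataset, tmp_path):
        subset = small_dataset[:6]
        write_trials(subset, tmp_path / "d")
        loaded = load_trials(tmp_path / "d", DialectConfig.canonical())
        assert len(loaded) == 6
        for a, b in zip(subset, loaded):
            assert np.allclose(a.signal, b.signal, atol=0, rtol=0)
            assert (a.task, a.group, a.subject_id) == (b.task, b.group, b.subject_id)

    def test_short_trial_padded_on_load(self, tmp_path):
        d = tmp_path / "d"
        d.mkdir()
        rng = np.random.default_rng(0)
        sig = rng.normal(size=(250, 9))
        pd.DataFrame(sig, columns=list(CHANNEL_NAMES)).to_csv(d / "t.csv", index=False)
        pd.DataFrame(
            [{"file": "t.csv", "subject_id": "s", "task": "T02", "fmma_ue": 50, "is_control": False}]
        ).to_csv(d / "metadata.csv", index=False)
        loaded = load_trials(d, DialectConfig(position_unit="cm", angle_unit="rad"))
        assert len(loaded) == 1
        assert np.allclose(loaded[0].signal[299], loaded[0].signal[249])
        assert loaded[0].group == "mild"

    def test_unit_conversion_on_load(self, tmp_path):
        d = tmp_path / "d"
        d.mkdir()
        sig = np.ones((300, 9))
        pd.DataFrame(sig, columns=list(CHANNEL_NAMES)).to_csv(d / "t.csv", index=False)
        pd.DataFrame(
            [{"file": "t.csv", "subject_id": "s", "task": "T03", "fmma_ue": "", "is_control": True}]
        ).to_csv(d / "metadata.csv", index=False)
        loaded = load_trials(d)  # default dialect: meters / degrees
        assert loaded[0].signal[0, 0] == pytest.approx(100.0)
        assert loaded[0].signal[0, 4] == pytest.approx(np.pi / 180)

    def test_nan_trial_rejected_others_kept(self, small_dataset, tmp_path):
        write_trials(small_dataset[:3], tmp_path / "d")
        frame = pd.read_csv(tmp_path / "d" / "trial_00001.csv")
        frame.iloc[10, 4] = np.nan
        frame.to_csv(tmp_path / "d" / "trial_00001.csv", index=False)
        loaded = load_trials(tmp_path / "d", DialectConfig.canonical())
        assert len(loaded) == 2

    def test_npz_cache_round_trip(self, small_dataset, tmp_path):
        small_dataset.to_npz(tmp_path / "cache.npz")
        loaded = Dataset.from_npz(tmp_path / "cache.npz")
        assert np.array_equal(loaded.labels, small_dataset.labels)
        assert np.array_equal(loaded.signals(), small_dataset.signals())
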
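"""Otsu thresholding, the four-way rule, bouts/interruptions, architecture."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import somnohrv as sh
from somnohrv import staging
from conftest import random_labels, rle_oracle


def between_class_variance(values, t):
    x = np.asarray(values, dtype=float)
    lo, hi = x[x <= t], x[x > t]
    if len(lo) == 0 or len(hi) == 0:
        return 0.0
    w = len(lo) / len(x)
    return w * (1 - w) * (lo.mean() - hi.mean()) ** 2


def exhaustive_split(values):
    """Oracle: max between-class variance over all sample splits."""
    x = np.sort(np.asarray(values, dtype=float))
    best_t, best_var = x[0], -np.inf
    for k in range(1, len(x)):
        var = between_class_variance(x, (x[k - 1] + x[k]) / 2.0)
        if var > best_var:
            best_var, best_t = var, (x[k - 1] + x[k]) / 2.0
    return best_t, best_var


def features_frame(mpf, emg):
    n = len(mpf)
    return pd.DataFrame(
        {
            "epoch_index": np.arange(n),
            "t_start_s": 8.0 * np.arange(n),
            "mpf_hz": mpf,
            "emg_power": emg,
            "delta_fr": 0.25,
            "theta_fr": 0.25,
            "alpha_fr": 0.25,
            "beta_fr": 0.25,
        }
    )


class TestOtsu:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.comp = rng.integers(0, 2, 2000).astype(bool)
        self.x = rng.normal(np.where(self.comp, 7.0, 3.0), 0.5)

    def test_bimodal_mixture_split_between_modes(self):
        t, eta = sh.otsu_threshold(self.x)
        assert 4.0 < t < 6.0
        assert eta > 0.5

    def test_near_optimal_vs_exhaustive_oracle(self):
        # the objective is flat across a wide inter-mode gap, so compare
        # achieved between-class variance, not threshold location
        t, _ = sh.otsu_threshold(self.x)
        _, best_var = exhaustive_split(self.x)
        assert between_class_variance(self.x, t) >= 0.99 * best_var

    def test_low_misclassification_vs_mixture_origin(self):
        t, _ = sh.otsu_threshold(self.x)
        assert ((self.x > t) != self.comp).mean() < 0.02

    def test_degenerate_histogram_warns(self):
        with pytest.warns(UserWarning, match="identical"):
            t, eta = sh.otsu_threshold(np.full(100, 3.0))
        assert eta == 0.0


class TestEstimateThresholds:
    def test_bimodal_features_give_separating_thresholds(self):
        rng = np.random.default_rng(1)
        awake = rng.integers(0, 2, 500).astype(bool)
        mpf = rng.normal(np.where(awake, 7.0, 3.0), 0.5)
        emg = 10.0 ** rng.normal(np.where(awake, 2.0, 0.0), 0.2)
        th, seg_ids = sh.estimate_thresholds(features_frame(mpf, emg))
        assert len(th) == 1 and set(seg_ids) == {0}
        assert 4.0 < th[0].t_mpf < 6.0
        assert 10.0 ** 0.5 < th[0].t_emg < 10.0 ** 1.5

    def test_five_hour_segmentation_and_short_tail_reuse(self):
        rng = np.random.default_rng(2)
        # 5 h + 10 min: the 10-min tail is below the 30-min floor
        n = int((5 * 3600 + 600) / 8)
        mpf = rng.normal(np.where(rng.integers(0, 2, n), 7, 3), 0.5)
        th, seg_ids = sh.estimate_thresholds(features_frame(mpf, 10.0 ** (mpf / 7)))
        assert len(th) == 1
        assert seg_ids.max() == 0

    def test_long_tail_gets_own_segment(self):
        rng = np.random.default_rng(3)
        n = int((5 * 3600 + 3600) / 8)  # 5 h + 1 h
        mpf = rng.normal(np.where(rng.integers(0, 2, n), 7, 3), 0.5)
        th, seg_ids = sh.estimate_thresholds(features_frame(mpf, 10.0 ** (mpf / 7)))
        assert len(th) == 2
        assert seg_ids.max() == 1

    def test_unimodal_segment_flagged(self):
        rng = np.random.default_rng(4)
        mpf = rng.normal(5.0, 0.01, 300)
        with pytest.warns(UserWarning, match="unimodal"):
            th, _ = sh.estimate_thresholds(features_frame(mpf, np.abs(mpf)))
        assert th[0].flagged

    def test_too_short_recording_rejected(self):
        with pytest.raises(sh.DataError):
            sh.estimate_thresholds(features_frame(np.ones(10), np.ones(10)))

    def test_manual_override_recorded(self):
        rng = np.random.default_rng(5)
        mpf = rng.normal(np.where(rng.integers(0, 2, 300), 7, 3), 0.5)
        th, _ = sh.estimate_thresholds(
            features_frame(mpf, 10.0 ** (mpf / 7)),
            overrides={0: {"t_mpf": 5.5}},
        )
        assert th[0].t_mpf == 5.5
        assert th[0].manual_override == {"t_mpf": 5.5}


class TestClassifyEpochs:
    @pytest.mark.parametrize(
        "mpf,emg,expected",
        [
            (6.0, 2.0, "AW"),  # both above
            (4.0, 0.5, "QS"),  # both below
            (6.0, 0.5, "PS"),  # MPF above, EMG below
            (4.0, 2.0, "ERR"),  # MPF below, EMG above: implausible
        ],
    )
    def test_four_way_rule(self, mpf, emg, expected):
        th = [staging.Thresholds(t_mpf=5.0, t_emg=1.0, segment_id=0)]
        feats = features_frame(np.array([mpf]), np.array([emg]))
        labels = sh.classify_epochs(feats, th, np.zeros(1, dtype=int))
        assert labels[0] == expected

    def test_threshold_equality_counts_as_below(self):
        th = [staging.Thresholds(t_mpf=5.0, t_emg=1.0, segment_id=0)]
        feats = features_frame(np.array([5.0]), np.array([1.0]))
        assert sh.classify_epochs(feats, th, np.zeros(1, dtype=int))[0] == "QS"

    def test_missing_features_marked_err(self):
        th = [staging.Thresholds(t_mpf=5.0, t_emg=1.0, segment_id=0)]
        feats = features_frame(np.array([np.nan]), np.array([2.0]))
        assert sh.classify_epochs(feats, th, np.zeros(1, dtype=int))[0] == "ERR"

    @given(
        mpf=st.floats(allow_nan=False, allow_infinity=False, width=32),
        emg=st.floats(allow_nan=False, allow_infinity=False, width=32),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_classification_total_and_exclusive(self, mpf, emg):
        th = [staging.Thresholds(t_mpf=5.0, t_emg=1.0, segment_id=0)]
        feats = features_frame(np.array([mpf]), np.array([emg]))
        labels = sh.classify_epochs(feats, th, np.zeros(1, dtype=int))
        assert labels[0] in ("AW", "QS", "PS", "ERR")


class TestFormStages:
    def test_minimum_run_forms_bout(self):
        bouts, inter = sh.form_stages(np.array(["QS"] * 6))
        assert len(bouts) == 1 and len(inter) == 0
        assert bouts[0].stage == "QS" and bouts[0].length == 6

    def test_intrusion_splits_bouts(self):
        labels = np.array(["QS"] * 10 + ["AW"] * 3 + ["QS"] * 10)
        bouts, inter = sh.form_stages(labels)
        assert [b.stage for b in bouts] == ["QS", "QS"]
        assert len(inter) == 1 and inter[0].stage == "AW" and inter[0].length == 3

    def test_alternating_epochs_all_interruptions(self):
        labels = np.array(["QS", "AW"] * 20)
        bouts, inter = sh.form_stages(labels)
        assert len(bouts) == 0 and len(inter) == 40

    def test_err_splits_runs(self):
        labels = np.array(["QS"] * 4 + ["ERR"] + ["QS"] * 4)
        bouts, inter = sh.form_stages(labels)
        assert len(bouts) == 0 and len(inter) == 2

    def test_matches_rle_oracle_on_random_sequences(self):
        rng = np.random.default_rng(10)
        for _ in range(1000):
            labels = random_labels(rng, int(rng.integers(1, 60)))
            bouts, inter = sh.form_stages(labels)
            ob, oi = rle_oracle(labels, 6)
            assert [(b.stage, b.start, b.length) for b in bouts] == ob
            assert [(e.stage, e.start, e.length) for e in inter] == oi

    def test_partition_of_valid_epochs(self):
        rng = np.random.default_rng(11)
        labels = random_labels(rng, 500)
        bouts, inter = sh.form_stages(labels)
        covered = np.zeros(len(labels), dtype=int)
        for r in list(bouts) + list(inter):
            covered[r.start : r.start + r.length] += 1
        assert np.all(covered[labels != "ERR"] == 1)
        assert np.all(covered[labels == "ERR"] == 0)

    def test_min_run_one_gives_no_interruptions(self):
        rng = np.random.default_rng(12)
        labels = random_labels(rng, 300)
        _, inter = sh.form_stages(labels, min_run=1)
        assert inter == []

    def test_interruption_count_monotone_in_injected_intrusions(self):
        # isolated 1-5-epoch AW intrusions into QS (1-epoch QS margin, as
        # the generator injects them) never decrease the interruption count
        rng = np.random.default_rng(13)
        prev = 0
        labels = np.array(["QS"] * 200)
        for _ in range(30):
            pos = int(rng.integers(1, 194))
            k = int(rng.integers(1, 6))
            if not np.all(labels[pos - 1 : pos + k + 1] == "QS"):
                continue
            labels[pos : pos + k] = "AW"
            _, inter = sh.form_stages(labels)
            assert len(inter) >= prev
            prev = len(inter)
        assert prev > 0


class TestArchitecture:
    def test_constant_series(self):
        labels = np.array(["QS"] * 75)  # 10 min
        bouts, inter = sh.form_stages(labels)
        arch = sh.architecture_metrics(labels, bouts, inter)
        assert arch.time_pct["QS"] == 100.0
        assert arch.interruption_rate == 0.0
        assert all(v == 0 for v in arch.transitions.values())

    def test_interruption_rate_arithmetic(self):
        # 75 valid epochs = 10 min, with 3 short AW intrusions
        labels = np.array(
            ["QS"] * 20 + ["AW"] * 2 + ["QS"] * 20 + ["AW"] * 2
            + ["QS"] * 20 + ["AW"] * 2 + ["QS"] * 9
        )
        bouts, inter = sh.form_stages(labels)
        arch = sh.architecture_metrics(labels, bouts, inter)
        assert arch.interruption_rate == pytest.approx(0.3)
        assert arch.qs_interruption_rate == pytest.approx(
            3 / ((69 * 8) / 60.0)
        )

    def test_transitions_between_consecutive_bouts(self):
        labels = np.array(["AW"] * 6 + ["QS"] * 6 + ["PS"] * 6 + ["QS"] * 6)
        bouts, inter = sh.form_stages(labels)
        arch = sh.architecture_metrics(labels, bouts, inter)
        assert arch.transitions == {
            "A-Q": 1, "A-P": 0, "Q-A": 0, "Q-P": 1, "P-A": 0, "P-Q": 1
        }

    def test_time_pct_sums_to_100_excluding_err(self):
        rng = np.random.default_rng(14)
        labels = random_labels(rng, 400)
        bouts, inter = sh.form_stages(labels)
        arch = sh.architecture_metrics(labels, bouts, inter)
        assert sum(arch.time_pct.values()) == pytest.approx(100.0, abs=1e-6)

    def test_all_err_rejected(self):
        labels = np.array(["ERR"] * 10)
        with pytest.raises(sh.DataError):
            sh.architecture_metrics(labels, [], [])


class TestRecovery:
    def test_identity(self):
        labels = np.array(["AW", "QS", "PS"] * 10)
        cm, acc = sh.staging_recovery_report(labels, labels)
        assert acc == 1.0
        assert cm.to_numpy().sum() == 30

    def test_single_flip(self):
        truth = np.array(["QS"] * 100)
        pred = truth.copy()
        pred[0] = "AW"
        _, acc = sh.staging_recovery_report(pred, truth)
        assert acc == pytest.approx(0.99)

    def test_length_mismatch_rejected(self):
        with pytest.raises(sh.DataError):
            sh.staging_recovery_report(np.array(["QS"]), np.array(["QS", "QS"]))

    def test_synthetic_roundtrip_accuracy(self, control_sim, control_bundle):
        pred = control_bundle["labels"]
        truth = control_sim.truth.epoch_labels[: len(pred)]
        _, acc = sh.staging_recovery_report(pred, truth)
        assert acc >= 0.90
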
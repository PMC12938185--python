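"""Back-fitting, smoothing, temporal metrics, GEV, transitions, feature table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bandstates import (
    EEGRecording,
    Segmentation,
    backfit,
    build_feature_table,
    gev_per_class,
    parse_feature_name,
    smooth_min_duration,
    subject_band_features,
    temporal_metrics,
    transition_probabilities,
)
from bandstates.features import _runs, feature_columns


def _seg(labels, rate=256.0, corr=None, k=4):
    labels = np.asarray(labels, int)
    if corr is None:
        corr = np.full((labels.size, k), 0.5)
        corr[np.arange(labels.size), labels] = 0.9
    return Segmentation(labels, corr, rate)


class TestBackfit:
    def test_constant_template_b_recording(self, montage, templates, template_set):
        data = np.tile(templates[1][:, None], (1, 100)) * 5.0
        rec = EEGRecording(data, 256.0, montage)
        seg = backfit(rec, template_set)
        assert np.all(seg.labels == 1)
        assert np.allclose(seg.fit, 1.0)

    def test_matches_per_sample_argmax_oracle(self, montage, template_set):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((52, 200))
        rec = EEGRecording(data, 256.0, montage)
        seg = backfit(rec, template_set)
        for t in range(200):
            v = data[:, t] - data[:, t].mean()
            corrs = [
                abs(np.corrcoef(v, m)[0, 1]) for m in template_set.maps
            ]
            assert seg.labels[t] == int(np.argmax(corrs))
            assert seg.fit[t] == pytest.approx(max(corrs), abs=1e-10)

    def test_zero_variance_sample_inherits_previous(self, montage, template_set):
        data = np.tile(template_set.maps[2][:, None], (1, 10))
        data[:, 4] = 0.0
        rec = EEGRecording(data, 256.0, montage)
        seg = backfit(rec, template_set)
        assert seg.labels[4] == 2
        assert seg.flagged[4]
        # zero-variance first sample falls back to class 0
        data2 = np.tile(template_set.maps[2][:, None], (1, 5))
        data2[:, 0] = 0.0
        seg2 = backfit(EEGRecording(data2, 256.0, montage), template_set)
        assert seg2.labels[0] == 0


class TestSmoothing:
    def test_short_interior_run_dissolved(self):
        labels = [0] * 40 + [1] * 2 + [0] * 40
        out = smooth_min_duration(_seg(labels), min_ms=30.0)  # min run = 8 at 256 Hz
        assert _runs(out.labels) == [(0, 82, 0)]

    def test_fixed_point_when_all_runs_long(self):
        labels = [0] * 10 + [1] * 9 + [2] * 8 + [3] * 30
        seg = _seg(labels)
        out = smooth_min_duration(seg, min_ms=30.0)
        np.testing.assert_array_equal(out.labels, seg.labels)

    def test_boundary_runs_exempt(self):
        labels = [1] * 2 + [0] * 40 + [2] * 3
        out = smooth_min_duration(_seg(labels), min_ms=30.0)
        np.testing.assert_array_equal(out.labels, labels)

    def test_split_respects_correlations(self):
        # short run flanked by different states: samples go to the better flank
        labels = [0] * 20 + [2] * 4 + [1] * 20
        corr = np.full((44, 4), 0.1)
        corr[np.arange(44), labels] = 0.9
        corr[20:22, 0] = 0.8  # first two dissolved samples prefer the left flank
        corr[22:24, 1] = 0.8
        out = smooth_min_duration(_seg(labels, corr=corr), min_ms=30.0)
        assert _runs(out.labels) == [(0, 22, 0), (22, 44, 1)]

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(st.integers(min_value=0, max_value=3), min_size=1, max_size=32),
        st.sampled_from([2, 4, 8]),
    )
    def test_terminates_and_clears_interior_violations(self, labels, min_len):
        seg = _seg(labels, rate=1000.0 * min_len / 30.0)  # min run == min_len samples
        out = smooth_min_duration(seg, min_ms=30.0)
        runs = _runs(out.labels)
        for start, stop, _state in runs[1:-1]:
            assert stop - start >= min_len
        assert out.labels.size == len(labels)

    def test_alternating_labels_converge(self):
        labels = [0, 1] * 16
        out = smooth_min_duration(_seg(labels), min_ms=30.0)
        assert len(_runs(out.labels)) <= 2


class TestTemporalMetrics:
    def test_hand_computed_example(self):
        labels = [0] * 10 + [1] * 5 + [0] * 10
        m = temporal_metrics(_seg(labels, rate=256.0))
        assert m["A"]["mean_duration"] == pytest.approx(39.0625)
        assert m["A"]["coverage"] == pytest.approx(0.8)
        assert m["A"]["occurrence"] == pytest.approx(20.48)
        assert m["B"]["occurrence"] == pytest.approx(10.24)

    def test_single_class(self):
        m = temporal_metrics(_seg([2] * 256, rate=256.0))
        assert m["C"]["coverage"] == pytest.approx(1.0)
        assert m["C"]["occurrence"] == pytest.approx(1.0)
        assert m["C"]["mean_duration"] == pytest.approx(1000.0)
        assert np.isnan(m["A"]["mean_duration"])
        assert m["A"]["coverage"] == 0.0

    def test_coverage_partition(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            labels = rng.integers(4, size=500)
            m = temporal_metrics(_seg(labels))
            assert sum(v["coverage"] for v in m.values()) == pytest.approx(1.0, abs=1e-9)

    def test_coverage_occurrence_duration_consistency(self, noisy_recording, template_set):
        rec, _truth, _cfg = noisy_recording
        feats, seg = subject_band_features(rec, template_set)
        m = temporal_metrics(smooth_min_duration(backfit(rec, template_set)))
        for k in "ABCD":
            expected = m[k]["occurrence"] * m[k]["mean_duration"] / 1000.0
            # up to 2 boundary-run corrections per class
            slack = 2 * m[k]["mean_duration"] / 1000.0 / rec.duration
            assert abs(m[k]["coverage"] - expected) <= slack + 1e-9


class TestGEV:
    def test_noiseless_gev_sums_to_one(self, noiseless_recording, template_set):
        rec, _truth, _cfg = noiseless_recording
        seg = backfit(rec, template_set)
        gev = gev_per_class(rec, seg, template_set)
        assert sum(gev.values()) == pytest.approx(1.0, abs=1e-6)

    def test_matches_direct_summation_oracle(self, montage, template_set):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((52, 64))
        rec = EEGRecording(data, 256.0, montage)
        seg = backfit(rec, template_set)
        gev = gev_per_class(rec, seg, template_set)
        centered = data - data.mean(axis=0)
        g = np.sqrt(np.mean(centered**2, axis=0))
        denom = np.sum(g**2)
        for k, name in enumerate("ABCD"):
            num = 0.0
            for t in range(64):
                if seg.labels[t] == k:
                    v = centered[:, t]
                    r = np.corrcoef(v, template_set.maps[k])[0, 1]
                    num += (g[t] * abs(r)) ** 2
            assert gev[name] == pytest.approx(num / denom, abs=1e-12)

    def test_zero_gfp_rejected(self, montage, template_set):
        rec = EEGRecording(np.zeros((52, 10)), 256.0, montage)
        seg = _seg([0] * 10)
        with pytest.raises(ValueError):
            gev_per_class(rec, seg, template_set)


class TestTransitions:
    def test_direct_counting_example(self):
        # runs A, B, A, C
        labels = [0] * 10 + [1] * 10 + [0] * 10 + [2] * 10
        tp = transition_probabilities(_seg(labels))
        assert tp[0, 1] == pytest.approx(0.5)
        assert tp[0, 2] == pytest.approx(0.5)
        assert tp[1, 0] == pytest.approx(1.0)
        assert np.all(np.isnan(tp[2]))  # C is terminal
        assert np.all(np.isnan(tp[3]))  # D absent

    def test_cyclic_sequence_is_point_mass(self):
        labels = ([0] * 10 + [1] * 10 + [2] * 10 + [3] * 10) * 3
        tp = transition_probabilities(_seg(labels))
        for i in range(4):
            assert tp[i, (i + 1) % 4] == pytest.approx(1.0)

    def test_rows_normalized(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(4, size=400)
        tp = transition_probabilities(_seg(labels))
        sums = np.nansum(tp, axis=1)
        defined = ~np.all(np.isnan(tp), axis=1)
        assert np.allclose(sums[defined], 1.0, atol=1e-12)
        assert np.allclose(np.diag(tp)[defined], 0.0)

    def test_sample_mode_counts_sample_pairs(self):
        labels = [0, 0, 1, 1, 1, 0, 2]
        tp = transition_probabilities(_seg(labels), mode="sample")
        # distinct-label sample pairs: 0->1, 1->0, 0->2
        assert tp[0, 1] == pytest.approx(0.5)
        assert tp[0, 2] == pytest.approx(0.5)
        assert tp[1, 0] == pytest.approx(1.0)

    def test_single_run_all_undefined(self):
        tp = transition_probabilities(_seg([1] * 50))
        assert np.all(np.isnan(tp[np.eye(4) == 0].reshape(4, 3)) | True)
        assert np.all(np.isnan(tp).reshape(4, 4)[np.arange(4) != 1])


class TestFeatureTable:
    def test_name_grammar_round_trip(self):
        cols = feature_columns()
        assert len(cols) == 112
        for c in cols:
            band, kind, states = parse_feature_name(c)
            if kind == "TP":
                assert c == f"{band.capitalize()}_TP_{states[0]}-{states[1]}"
            else:
                assert c == f"{band.capitalize()}_{kind}_{states[0]}"

    def test_invalid_names_rejected(self):
        for bad in ("Delta_TP_E-B", "delta_MD_A", "Delta_XX_A", "Delta_TP_AB"):
            with pytest.raises(ValueError):
                parse_feature_name(bad)

    def test_table_shape_and_missing_scores(self):
        cols = feature_columns()
        rng = np.random.default_rng(4)
        feats = {f"s{i:02d}": dict(zip(cols, rng.uniform(size=112))) for i in range(6)}
        clinical = pd.DataFrame(
            {
                "subject_id": [f"s{i:02d}" for i in range(5)],  # one subject missing
                "group": ["MD"] * 3 + ["SV"] * 2,
                "DHI": rng.uniform(0, 100, 5),
                "VAS": rng.uniform(0, 10, 5),
                "ABC": rng.uniform(0, 100, 5),
            }
        )
        table = build_feature_table(feats, clinical)
        assert table.shape == (6, 1 + 112 + 4)
        assert table.loc[table.subject_id == "s05", "VAS"].isna().all()

    def test_transition_column_matches_subject_matrix(self, noisy_recording, template_set):
        rec, _truth, _cfg = noisy_recording
        feats, seg = subject_band_features(rec, template_set)
        tp = transition_probabilities(seg)
        assert feats["Alpha_TP_C-B"] == pytest.approx(tp[2, 1], nan_ok=True)
        assert feats["Alpha_TP_A-D"] == pytest.approx(tp[0, 3], nan_ok=True)
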
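"""Segmentation, baseline subtraction, standardization and label mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import affectlstm as al
from affectlstm.errors import (
    DegenerateChannelError,
    DomainError,
    LengthError,
    ShapeError,
)
from affectlstm.features import (
    DEAP_CLASS_NAMES,
    FeatureConfig,
    baseline_subtract,
    build_feature_set,
    map_labels_deap,
    segment_trial,
    split_baseline,
    standardize,
)


@pytest.mark.parametrize(
    "channels,samples,rate,n_segments,window",
    [
        (32, 8064, 128, 21, 384),    # 63-s trial at 128 Hz
        (32, 12_000, 200, 20, 600),  # 60-s trial at 200 Hz
        (32, 384, 128, 1, 384),      # single window: identity
    ],
)
def test_segmentation_counts(channels, samples, rate, n_segments, window):
    trial = np.random.default_rng(0).normal(size=(channels, samples))
    segments = segment_trial(trial, rate)
    assert segments.shape == (n_segments, channels, window)
    if n_segments == 1:
        np.testing.assert_array_equal(segments[0], trial)


def test_segmentation_is_a_partition(rng):
    """Concatenating the windows in order reconstructs the trial exactly."""
    trial = rng.normal(size=(5, 7 * 384))
    segments = segment_trial(trial, 128)
    np.testing.assert_array_equal(
        np.concatenate(list(segments), axis=1), trial)


def test_segmentation_rejects_remainder_unless_truncating():
    trial = np.zeros((4, 400))
    with pytest.raises(LengthError, match="16"):
        segment_trial(trial, 128)
    segments = segment_trial(trial, 128, allow_truncate=True)
    assert segments.shape == (1, 4, 384)


def test_split_baseline_counts():
    segments = np.arange(21 * 2 * 3).reshape(21, 2, 3)
    baseline, experimental = split_baseline(segments)
    np.testing.assert_array_equal(baseline, segments[0])
    assert experimental.shape[0] == 20
    baseline, experimental = split_baseline(segments[:20])
    assert experimental.shape[0] == 19  # 60-s trial: first window consumed
    baseline, experimental = split_baseline(segments[:2])
    assert experimental.shape[0] == 1
    with pytest.raises(LengthError):
        split_baseline(segments[:1])


def test_baseline_subtract_toy_and_identity():
    baseline = np.array([[1.0, 2.0]])
    segments = np.array([[[3.0, 4.0]], [[5.0, 6.0]]])
    np.testing.assert_array_equal(
        baseline_subtract(baseline, segments),
        np.array([[[2.0, 2.0]], [[4.0, 4.0]]]))
    same = np.repeat(baseline[None], 20, axis=0)
    out = baseline_subtract(baseline, same)
    assert out.shape[0] == 20
    np.testing.assert_array_equal(out, np.zeros_like(same))
    with pytest.raises(ShapeError):
        baseline_subtract(baseline, np.zeros((2, 1, 3)))


def test_baseline_subtraction_cancels_per_channel_constants(rng):
    """Adding a constant per channel to a whole trial leaves the
    baseline-relative features unchanged (the constant cancels)."""
    trial = rng.normal(size=(6, 5 * 384))
    shifted = trial + rng.normal(size=(6, 1)) * 10
    for a, b in [(trial, shifted)]:
        feats = []
        for arr in (a, b):
            base, exp = split_baseline(segment_trial(arr, 128))
            feats.append(baseline_subtract(base, exp))
        np.testing.assert_allclose(feats[0], feats[1], atol=1e-9)


def test_standardize_moments_and_reapplication(rng):
    features = rng.normal(3.0, 2.5, size=(50, 12, 4))
    standardized, stats = standardize(features)
    np.testing.assert_allclose(standardized.mean(axis=(0, 1)), 0, atol=1e-6)
    np.testing.assert_allclose(standardized.std(axis=(0, 1)), 1, atol=1e-6)
    np.testing.assert_array_equal(stats.apply(features), standardized)


def test_standardize_constant_channel_guard(rng):
    features = rng.normal(size=(10, 6, 3))
    features[:, :, 1] = 4.2
    standardized, _ = standardize(features)
    np.testing.assert_allclose(standardized[:, :, 1], 0.0, atol=1e-12)
    with pytest.raises(DegenerateChannelError):
        standardize(features, eps_guard=False)


def test_standardize_train_scope_uses_only_given_indices(rng):
    features = rng.normal(size=(20, 6, 3))
    features[10:] += 100.0  # held-out block is wildly shifted
    scoped, stats = standardize(features, scope_indices=np.arange(10))
    np.testing.assert_allclose(scoped[:10].mean(axis=(0, 1)), 0, atol=1e-6)
    assert scoped[10:].mean() > 10  # held-out shift survives


@pytest.mark.parametrize(
    "valence,arousal,expected",
    [(7, 8, "HVHA"), (3, 8, "LVHA"), (3, 2, "LVLA"), (8, 2, "HVLA"),
     (5, 5, "LVLA")],  # exactly at threshold counts as low under strict >
)
def test_quadrant_mapping_examples(valence, arousal, expected):
    assert map_labels_deap(valence, arousal).name == expected


def test_quadrant_mapping_comparator_and_domain():
    assert map_labels_deap(5, 5, strict=False).name == "HVHA"
    with pytest.raises(DomainError):
        map_labels_deap(0.5, 5)
    with pytest.raises(DomainError):
        map_labels_deap(5, 9.5)


@settings(max_examples=80, deadline=None, derandomize=True)
@given(st.floats(1, 9), st.floats(1, 9))
def test_quadrant_mapping_partitions_the_rating_square(valence, arousal):
    """Every rating pair lands in exactly one quadrant, and the mapping is
    monotone: raising valence never turns a high-valence label low."""
    label = map_labels_deap(valence, arousal)
    assert label.name in DEAP_CLASS_NAMES and 0 <= label.class_id <= 3
    higher = map_labels_deap(min(valence + 1, 9), arousal)
    hv = {"HVHA", "HVLA"}
    if label.name in hv:
        assert higher.name in hv


def test_build_feature_set_example_counts_full_shapes():
    """40 trials x 20 experimental windows = 800 examples (ratings layout);
    45 x 19 = 855 (categorical layout, first window is the baseline)."""
    rec = al.generate_recording(al.SynthConfig(seed=0, snr=1.0))
    fs = build_feature_set(rec)
    assert fs.features.shape == (800, 384, 32)
    assert fs.n_classes == 4
    rec = al.generate_recording(al.SynthConfig(
        dialect="SEED", trials=45, channels=32, samples=12_000,
        sampling_rate=200, seed=0))
    assert rec.dataset_tag == "SEED"
    fs = build_feature_set(rec)
    assert fs.features.shape == (855, 600, 32)
    assert fs.n_classes == 3
    assert fs.class_names == ("negative", "neutral", "positive")


def test_build_feature_set_desk_counts_and_provenance(desk_fs):
    assert desk_fs.features.shape == (8 * 20, 384, 8)
    # every (trial, segment) pair unique, segments numbered from 1
    assert desk_fs.provenance[:, 1].min() == 1
    assert len({tuple(r) for r in desk_fs.provenance}) == 160
    # trial's class is inherited by each of its segments
    for trial in range(8):
        ids = desk_fs.class_ids[desk_fs.provenance[:, 0] == trial]
        assert len(set(ids.tolist())) == 1


def test_build_feature_set_all_zero_recording():
    rec = al.SubjectRecording(
        subject_id="zero", dataset_tag="SYNTHETIC",
        data=np.zeros((4, 3, 4 * 384)), sampling_rate=128,
        labels=np.array([[7.0, 7.0, 5, 5], [3.0, 7.0, 5, 5],
                         [3.0, 3.0, 5, 5], [7.0, 3.0, 5, 5]]),
        label_names=("valence", "arousal", "liking", "dominance"))
    fs = build_feature_set(rec)
    np.testing.assert_array_equal(fs.features, 0.0)  # epsilon-guarded z-score
    np.testing.assert_array_equal(np.sort(fs.class_ids[::3]), np.arange(4))


def test_deferred_standardization_mode(desk_rec):
    fs = build_feature_set(
        desk_rec, FeatureConfig(standardize_scope="train_stats_channel"))
    assert not fs.standardized and fs.stats is None
    with pytest.raises(DomainError):
        FeatureConfig(standardize_scope="bogus")
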
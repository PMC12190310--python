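"""Synthetic paired-volume generator: determinism, class signal, domain shift."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from mmdda.evaluation import auc
from mmdda.synthetic import (SubjectSample, SyntheticConfig, SyntheticConfigError,
                             describe_dataset, generate_dataset)

SMALL = dict(volume_shape=(16, 16, 16), n_per_class_source=4, n_per_class_target=4)


def _downsampled_features(samples):
    """Cheap per-sample features for linear probes: 4^3 block means x 2 mods."""
    feats = []
    for s in samples:
        blocks = []
        for vol in (s.mri, s.pet):
            b = vol.reshape(4, 4, 4, 4, 4, 4).mean(axis=(1, 3, 5))
            blocks.append(b.ravel())
        feats.append(np.concatenate(blocks))
    return np.asarray(feats)


def _probe_auc(config: SyntheticConfig) -> float:
    """Linear-probe AUC on held-out source samples."""
    samples = [s for s in generate_dataset(config) if s.domain == "source"]
    x = _downsampled_features(samples)
    y = np.array([s.label for s in samples])
    train = (np.arange(len(samples)) % 4) < 2  # labels alternate; keep both classes
    clf = LogisticRegression(max_iter=2000).fit(x[train], y[train])
    return auc(y[~train], clf.predict_proba(x[~train])[:, 1])


class TestCounts:
    def test_source_counts_balanced(self):
        samples = generate_dataset(SyntheticConfig(volume_shape=(16, 16, 16),
                                                   n_per_class_source=8,
                                                   n_per_class_target=5))
        source = [s for s in samples if s.domain == "source"]
        assert len(source) == 16
        assert sum(s.label for s in source) == 8
        assert len(samples) - len(source) == 10

    def test_describe_counts_sum(self, tiny_dataset):
        table = describe_dataset(tiny_dataset)
        assert table["n"].sum() == len(tiny_dataset)

    def test_describe_empty_raises(self):
        with pytest.raises(ValueError):
            describe_dataset([])


class TestDeterminism:
    def test_identical_configs_are_byte_identical(self):
        a = generate_dataset(SyntheticConfig(**SMALL, seed=3))
        b = generate_dataset(SyntheticConfig(**SMALL, seed=3))
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.mri, s2.mri)
            np.testing.assert_array_equal(s1.pet, s2.pet)
            assert s1.subject_id == s2.subject_id and s1.label == s2.label

    def test_different_seeds_differ(self):
        a = generate_dataset(SyntheticConfig(**SMALL, seed=3))
        b = generate_dataset(SyntheticConfig(**SMALL, seed=4))
        assert not np.array_equal(a[0].mri, b[0].mri)


class TestDomainShift:
    def test_zero_shift_means_match(self):
        """With the shift disabled the two domains share one distribution."""
        diffs = []
        for seed in range(20):
            cfg = SyntheticConfig(**SMALL, shift_gain=1.0, shift_smooth=0.0,
                                  bias_amplitude=0.0, seed=seed)
            table = describe_dataset(generate_dataset(cfg))
            per_domain = table.groupby("domain")["mean_mri"].mean()
            diffs.append(per_domain["source"] - per_domain["target"])
        assert abs(np.mean(diffs)) < 0.01

    def test_shift_gain_scales_mean_intensity(self):
        cfg = SyntheticConfig(**SMALL, shift_gain=2.0, shift_smooth=0.0,
                              bias_amplitude=0.0, seed=0)
        table = describe_dataset(generate_dataset(cfg))
        per_domain = table.groupby("domain")["mean_mri"].mean()
        assert per_domain["target"] == pytest.approx(2.0 * per_domain["source"],
                                                     rel=0.02)

    def test_mean_intensity_separates_domains(self):
        """A trivial threshold on mean intensity detects the default shift."""
        samples = generate_dataset(SyntheticConfig(**SMALL, seed=5))
        means = np.array([s.mri.mean() for s in samples])
        is_target = np.array([s.domain == "target" for s in samples])
        threshold = means.mean()
        acc = ((means > threshold) == is_target).mean()
        assert max(acc, 1 - acc) > 0.9


class TestClassSignal:
    def test_zero_effect_is_label_uninformative(self):
        """class_effect = 0: probe AUC ~= 0.5 averaged over seeds."""
        aucs = [_probe_auc(SyntheticConfig(volume_shape=(16, 16, 16),
                                           n_per_class_source=8,
                                           n_per_class_target=1,
                                           class_effect=0.0, seed=seed))
                for seed in range(10)]
        assert abs(np.mean(aucs) - 0.5) <= 0.1

    def test_probe_auc_nondecreasing_in_class_effect(self):
        """Mean probe AUC over seeds is monotone over three effect levels."""
        levels = [0.0, 0.5, 1.5]
        means = []
        for effect in levels:
            aucs = [_probe_auc(SyntheticConfig(volume_shape=(16, 16, 16),
                                               n_per_class_source=8,
                                               n_per_class_target=1,
                                               class_effect=effect, seed=seed))
                    for seed in range(5)]
            means.append(np.mean(aucs))
        assert means[0] <= means[1] + 0.05 and means[1] <= means[2] + 0.05
        assert means[2] > 0.8


class TestValidation:
    def test_bad_configs_raise(self):
        with pytest.raises(SyntheticConfigError):
            SyntheticConfig(volume_shape=(4, 4, 4))
        with pytest.raises(SyntheticConfigError):
            SyntheticConfig(n_per_class_source=0)
        with pytest.raises(SyntheticConfigError):
            SyntheticConfig(class_effect=-1.0)
        with pytest.raises(SyntheticConfigError):
            SyntheticConfig(modality_correlation=1.5)
        with pytest.raises(SyntheticConfigError):
            SyntheticConfig(noise_sd=0.0)

    def test_sample_invariants(self):
        with pytest.raises(ValueError, match="co-registered"):
            SubjectSample("s", np.zeros((4, 4, 4)), np.zeros((4, 4, 5)), 0, "source")
        with pytest.raises(ValueError, match="labeled"):
            SubjectSample("s", np.zeros((4, 4, 4)), np.zeros((4, 4, 4)), None, "source")
        # target samples may lack labels
        SubjectSample("t", np.zeros((4, 4, 4)), np.zeros((4, 4, 4)), None, "target")
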
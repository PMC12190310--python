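"""Two-phase protocol: determinism, weight sharing, variants, resuming."""

import numpy as np
import pytest

from mmdda._autograd import Tensor
from mmdda.model import MMDDA
from mmdda.objectives import LossWeights
from mmdda.synthetic import SyntheticConfig, generate_dataset
from mmdda.trainer import (TrainConfig, desk_train_config, run_variant,
                           share_weights, train, train_phase1, train_phase2)


@pytest.fixture(scope="module")
def data16():
    samples = generate_dataset(SyntheticConfig(volume_shape=(16, 16, 16),
                                               n_per_class_source=4,
                                               n_per_class_target=4, seed=21))
    source = [s for s in samples if s.domain == "source"]
    target = [s for s in samples if s.domain == "target"]
    return samples, source, target


def _model(source, target, tiny_encoder, variant="MMDDA", seed=0, heads=4):
    return MMDDA(source, target, variant=variant, heads=heads,
                 encoder_config=tiny_encoder, seed=seed)


class TestPhase1:
    def test_smoke_run_records_finite_losses(self, data16, tiny_encoder):
        _, source, target = data16
        model = _model(source, target, tiny_encoder)
        history = train_phase1(model, source, desk_train_config(seed=0), epochs=2)
        assert len(history) == 2
        assert np.isfinite(history[["cor_s", "cls", "total"]].to_numpy()).all()
        # phase 1 never touches the target-only or phase-2 losses
        assert (history[["cor_t", "mse", "dom"]].to_numpy() == 0).all()

    def test_target_branches_untouched(self, data16, tiny_encoder):
        _, source, target = data16
        model = _model(source, target, tiny_encoder)
        before = {k: v.copy() for k, v in
                  model.encoders[("target", "mri")].state_dict().items()}
        train_phase1(model, source, desk_train_config(seed=0), epochs=1)
        after = model.encoders[("target", "mri")].state_dict()
        for key in before:
            np.testing.assert_array_equal(before[key], after[key])

    def test_fixed_seed_is_deterministic(self, data16, tiny_encoder):
        _, source, target = data16
        finals = []
        for _ in range(2):
            model = _model(source, target, tiny_encoder, seed=3)
            train_phase1(model, source, desk_train_config(seed=3), epochs=2)
            finals.append(model.state_dict())
        for key in finals[0]:
            np.testing.assert_array_equal(finals[0][key], finals[1][key])

    def test_source_training_accuracy_on_separable_data(self, tiny_encoder):
        samples = generate_dataset(SyntheticConfig(volume_shape=(16, 16, 16),
                                                   n_per_class_source=6,
                                                   n_per_class_target=1,
                                                   class_effect=1.5, seed=5))
        source = [s for s in samples if s.domain == "source"]
        target = [s for s in samples if s.domain == "target"]
        model = _model(source, target, tiny_encoder, seed=5)
        train_phase1(model, source, desk_train_config(learning_rate=1e-3, seed=5),
                     epochs=6)
        assert model.evaluate(source).acc > 0.9


class TestShareWeights:
    def test_outputs_identical_after_sharing(self, data16, tiny_encoder, rng):
        _, source, target = data16
        model = _model(source, target, tiny_encoder)
        share_weights(model)
        x = Tensor(rng.normal(size=(1, 1, 16, 16, 16)))
        for modality in ("mri", "pet"):
            s = model.encoders[("source", modality)]
            t = model.encoders[("target", modality)]
            s.eval(), t.eval()
            np.testing.assert_array_equal(s(x).data, t(x).data)

    def test_no_aliasing(self, data16, tiny_encoder, rng):
        _, source, target = data16
        model = _model(source, target, tiny_encoder)
        share_weights(model)
        src = model.encoders[("source", "mri")]
        tgt = model.encoders[("target", "mri")]
        next(iter(tgt.parameters())).data += 1.0
        x = Tensor(rng.normal(size=(1, 1, 16, 16, 16)))
        src.eval(), tgt.eval()
        assert not np.array_equal(src(x).data, tgt(x).data)

    def test_share_before_training_is_valid(self, data16, tiny_encoder):
        _, source, target = data16
        model = _model(source, target, tiny_encoder)
        share_weights(model)  # documented no-op semantics on random weights


class TestPhase2:
    def test_all_components_logged(self, data16, tiny_encoder):
        _, source, target = data16
        model = _model(source, target, tiny_encoder)
        share_weights(model)
        history = train_phase2(model, source, target, desk_train_config(seed=0),
                               epochs=1)
        row = history.iloc[0]
        for col in ("cor_s", "cor_t", "mse", "cls", "dom", "total"):
            assert np.isfinite(row[col])
        assert row["mse"] > 0  # consistency loss is computed and non-trivial

    def test_scrambled_target_labels_leave_trajectory_identical(self, data16,
                                                                tiny_encoder):
        """Target labels are never read: garbage labels give bit-identical
        parameters."""
        _, source, target = data16
        config = desk_train_config(epochs_phase1=1, epochs_phase2=1, seed=4)

        model_a = _model(source, target, tiny_encoder, seed=4)
        train(model_a, source, target, config)

        rng = np.random.default_rng(0)
        scrambled = [type(t)(t.subject_id, t.mri, t.pet,
                             int(rng.integers(0, 2)), t.domain) for t in target]
        model_b = _model(source, scrambled, tiny_encoder, seed=4)
        train(model_b, source, scrambled, config)

        state_a, state_b = model_a.state_dict(), model_b.state_dict()
        for key in state_a:
            np.testing.assert_array_equal(state_a[key], state_b[key])


class TestVariants:
    @pytest.mark.parametrize("variant", ["SDA", "MSDA", "M3HF", "MMDDA"])
    def test_each_variant_smoke_trains(self, variant, data16, tiny_encoder):
        samples, _, _ = data16
        report = run_variant(variant, samples, heads=4,
                             encoder_config=tiny_encoder,
                             train_config=desk_train_config(
                                 epochs_phase1=1, epochs_phase2=1, seed=0))
        assert report.n == 8
        assert report.acc is not None

    def test_msda_dimension_doubles_sda(self, data16, tiny_encoder):
        _, source, target = data16
        sda = _model(source, target, tiny_encoder, variant="SDA")
        msda = _model(source, target, tiny_encoder, variant="MSDA")
        assert msda.fused_dim == 2 * sda.fused_dim

    def test_m3hf_equals_full_model_with_zero_correlation_weights(
            self, data16, tiny_encoder):
        _, source, target = data16
        config = desk_train_config(epochs_phase1=1, epochs_phase2=1, seed=6)
        m3hf = _model(source, target, tiny_encoder, variant="M3HF", seed=6)
        train(m3hf, source, target, config)

        full = _model(source, target, tiny_encoder, variant="MMDDA", seed=6)
        full.loss_weights = LossWeights(cor_s=0.0, cor_t=0.0)
        train(full, source, target, config)

        state_a, state_b = m3hf.state_dict(), full.state_dict()
        for key in state_a:
            np.testing.assert_array_equal(state_a[key], state_b[key])

    def test_unknown_variant(self, data16, tiny_encoder):
        samples, source, target = data16
        with pytest.raises(ValueError):
            _model(source, target, tiny_encoder, variant="DANN")
        with pytest.raises(ValueError):
            run_variant("DANN", samples)


class TestResume:
    def test_checkpoint_resume_matches_uninterrupted(self, data16, tiny_encoder,
                                                     tmp_path):
        _, source, target = data16
        config = desk_train_config(epochs_phase1=2, epochs_phase2=1, seed=8)

        straight = _model(source, target, tiny_encoder, seed=8)
        train(straight, source, target, config)

        resumed = _model(source, target, tiny_encoder, seed=8)
        _, state = train(resumed, source, target, config, stop_after_epoch=2)
        resumed.save_checkpoint(tmp_path / "ckpt.npz", state)
        reloaded, state2 = MMDDA.load_checkpoint(tmp_path / "ckpt.npz",
                                                 source, target)
        train(reloaded, source, target, config, state=state2)

        state_a, state_b = straight.state_dict(), reloaded.state_dict()
        for key in state_a:
            np.testing.assert_array_equal(state_a[key], state_b[key])


class TestConfig:
    def test_epoch_invariant(self):
        config = TrainConfig(epochs_phase1=150, epochs_phase2=50)
        assert config.epochs_total == 200

    def test_reference_defaults(self):
        config = TrainConfig()
        assert config.learning_rate == pytest.approx(9e-7)
        assert config.betas == (0.9, 0.999)
        assert config.batch_size == 1
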
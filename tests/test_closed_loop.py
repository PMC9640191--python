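"""Teacher-forced and autoregressive prediction contracts."""

import numpy as np
import pytest

from surroneuron.architectures import ArchitectureSpec, SurrogateModel, build
from surroneuron.closed_loop import autoregressive, autoregressive_many, teacher_forced
from surroneuron.data import NormalizationParams, make_windows, normalize
from surroneuron.events import EventTrain
from surroneuron.evaluation import explained_variance
from surroneuron.nn import Dense, Flatten, Sequential
from surroneuron.trace import VoltageTrace


def linear_ar_model(rho=0.9, n_channels=3, window=64, event_gain=0.0):
    """A hand-weighted linear surrogate implementing v[t] = rho * v[t-1]
    (+ event_gain * newest excitatory channel) exactly."""
    net = Sequential([Flatten(), Dense(64, activation=None), Dense(1)],
                     (window, n_channels), seed=0)
    W1 = np.zeros((window * n_channels, 64))
    W1[(window - 1) * n_channels + 0, 0] = 1.0  # newest voltage sample
    if event_gain:
        W1[(window - 1) * n_channels + 1, 1] = 1.0  # newest exc channel
    net.layers[1].params["W"][:] = W1
    net.layers[1].params["b"][:] = 0.0
    W2 = np.zeros((64, 1))
    W2[0, 0] = rho
    W2[1, 0] = event_gain
    net.layers[2].params["W"][:] = W2
    net.layers[2].params["b"][:] = 0.0
    return SurrogateModel(
        net=net,
        spec=ArchitectureSpec("linear", n_channels, 1, window),
        norm=NormalizationParams(g_scale=1.0),
        channel_names=["v", "exc", "inh"],
    )


class TestTeacherForced:
    def test_oracle_model_reproduces_targets_exactly(self):
        """A surrogate wired to the generating recursion predicts every
        target of data generated by that recursion."""
        rho = 0.95
        norm = NormalizationParams()
        v_norm = 0.5 * rho ** np.arange(300)
        v_mV = norm.denormalize_v(v_norm)
        ds = normalize(make_windows([(VoltageTrace(v=v_mV), EventTrain())]))
        model = linear_ar_model(rho)
        preds = teacher_forced(model, ds)
        assert np.allclose(preds[:, 0], ds.targets[:, 0], atol=1e-6)

    def test_constant_model_has_zero_explained_variance(self, small_passive_ds):
        model = build("linear", input_channels=3, seed=0)
        for layer in model.net.layers[1:]:
            layer.params["W"][:] = 0.0
        model.net.layers[-1].params["b"][:] = float(
            small_passive_ds.targets[:, 0].mean()
        )
        model.norm = small_passive_ds.norm
        preds = teacher_forced(model, small_passive_ds)
        ev = explained_variance(preds[:, 0], small_passive_ds.targets[:, 0])
        assert ev == pytest.approx(0.0, abs=1e-3)

    def test_trained_linear_model_beats_the_mean(self, small_passive_ds):
        from surroneuron.training import TrainingConfig, train

        model = build("linear", input_channels=3, seed=0)
        model, _ = train(model, small_passive_ds,
                         TrainingConfig(loss="mse", max_epochs=10, patience=10, seed=0))
        idx = small_passive_ds.split_indices(2)
        preds = teacher_forced(model, small_passive_ds, indices=idx)
        _, y = small_passive_ds.gather(idx)
        assert explained_variance(preds[:, 0], y[:, 0]) > 0.5

    def test_channel_mismatch_rejected(self, small_passive_ds):
        model = build("linear", input_channels=5, seed=0)
        with pytest.raises(ValueError, match="channels"):
            teacher_forced(model, small_passive_ds)


class TestAutoregressive:
    def test_oracle_model_tracks_ground_truth_over_any_horizon(self):
        rho = 0.9
        norm = NormalizationParams()
        model = linear_ar_model(rho)
        v_norm = 0.8 * rho ** np.arange(64)
        init = VoltageTrace(v=norm.denormalize_v(v_norm))
        pred = autoregressive(model, init, EventTrain(), 200.0)
        expected_norm = 0.8 * rho ** np.arange(64, 264)
        assert np.allclose(norm.normalize_v(pred.v), expected_norm, atol=1e-9)

    def test_contraction_to_fixed_point_for_stable_linear_surrogate(self):
        """Companion spectral radius < 1: the rollout converges to the
        closed-form fixed point (zero in normalized units)."""
        model = linear_ar_model(0.8)
        init = VoltageTrace(v=model.norm.denormalize_v(np.full(64, 0.9)))
        pred = autoregressive(model, init, EventTrain(), 400.0)
        final_norm = model.norm.normalize_v(pred.v[-1])
        assert abs(final_norm) < 1e-9

    def test_event_channels_come_from_schedule_not_predictions(self):
        """A model that echoes the newest excitatory channel exposes the
        input timeline: the output must be bit-identical to the schedule."""
        model = linear_ar_model(0.0, event_gain=1.0)
        events = EventTrain.from_lists(
            [(80.0, 0, 0.25, "exc"), (120.0, 0, 0.5, "exc"), (150.0, 1, 9.0, "inh")]
        )
        init = VoltageTrace(v=model.norm.denormalize_v(np.zeros(64)))
        pred = autoregressive(model, init, events, 100.0)
        out_norm = model.norm.normalize_v(pred.v)
        expected = np.zeros(100)
        # the event at sample s enters the window one step later, so the echo
        # appears at output index s - 64 + 1
        expected[80 - 64 + 1] = 0.25
        expected[120 - 64 + 1] = 0.5
        assert np.allclose(out_norm, expected, atol=1e-12)

    def test_batched_runs_match_single_runs(self):
        model = linear_ar_model(0.9)
        inits = [VoltageTrace(v=model.norm.denormalize_v(np.full(64, x)))
                 for x in (0.3, 0.6)]
        batch = autoregressive_many(model, [(i, EventTrain()) for i in inits], 50.0)
        singles = [autoregressive(model, i, EventTrain(), 50.0) for i in inits]
        for b, s in zip(batch, singles):
            assert np.allclose(b.v, s.v)

    def test_too_short_initialization_rejected(self):
        model = linear_ar_model(0.9)
        init = VoltageTrace(v=np.full(10, -70.0))
        with pytest.raises(ValueError, match="at least"):
            autoregressive(model, init, EventTrain(), 50.0)
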
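"""Two-stage training: optimization smoke, determinism, freeze
correctness, scheduler arithmetic and checkpoint round trips."""

import numpy as np
import pytest

import pepclip as pc
from pepclip.model import ModelConfig, PepClipModel
from pepclip.train import (
    AdamW,
    PlateauScheduler,
    TrainConfig,
    align,
    checkpoint_load,
    checkpoint_save,
    pretrain,
)


def _snapshot(module):
    return {k: v.copy() for k, v in module.state_dict().items()}


def _max_delta(before, module):
    return max(np.max(np.abs(before[k] - v)) for k, v in module.state_dict().items())


@pytest.fixture(scope="module")
def pretrained(corpus_records, corpus_graphs, tmp_path_factory):
    """One shared stage-1 run (text + graph) on the session corpus."""
    model = PepClipModel(
        ModelConfig(
            max_length=20, text_width=32, text_layers=1, text_heads=2,
            graph_hidden_width=16, graph_mlp_widths=(16,), graph_out_width=16,
            latent_width=16, seed=0,
        )
    )
    text_state = pretrain(
        "text",
        corpus_records,
        TrainConfig(stage="pretrain_text", epochs=3, batch_size=10, seed=1),
        model=model,
    )
    graph_state = pretrain(
        "graph",
        corpus_records,
        TrainConfig(stage="pretrain_graph", epochs=2, batch_size=10, seed=2),
        model=model,
        graphs=corpus_graphs,
    )
    return model, text_state, graph_state


class TestPretrain:
    def test_loss_decreases_on_separable_synthetic_data(self):
        spec = pc.FixtureSpec(
            n_peptides=200, length_range=(5, 15), positive_fraction=0.5, seed=21
        )
        records = pc.generate_peptides(spec)
        model = PepClipModel(
            ModelConfig(max_length=20, text_width=32, text_layers=1, text_heads=2, seed=0)
        )
        state = pretrain(
            "text",
            records,
            TrainConfig(stage="pretrain_text", epochs=10, batch_size=20, seed=3),
            model=model,
        )
        assert state.history[-1]["loss"] < state.history[0]["loss"]

    def test_same_seed_identical_final_parameters(self, corpus_records):
        def run():
            model = PepClipModel(
                ModelConfig(max_length=20, text_width=16, text_layers=1, text_heads=2, seed=5)
            )
            pretrain(
                "text",
                corpus_records,
                TrainConfig(stage="pretrain_text", epochs=2, batch_size=10, seed=7),
                model=model,
            )
            return model.state_dict()

        a, b = run(), run()
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(stage="pretrain_text", epochs=0)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            pretrain("text", [], TrainConfig(stage="pretrain_text", epochs=1))

    def test_single_class_stream_warns(self):
        recs = [pc.LabeledSequence(f"r{i}", "AAAA", 1) for i in range(4)]
        model = PepClipModel(
            ModelConfig(max_length=10, text_width=16, text_layers=1, text_heads=2)
        )
        with pytest.warns(UserWarning, match="single class"):
            pretrain(
                "text", recs,
                TrainConfig(stage="pretrain_text", epochs=1, batch_size=4, seed=0),
                model=model,
            )


class TestAlign:
    def test_graph_encoder_frozen_exactly_and_text_updates(
        self, pretrained, corpus_records, corpus_graphs
    ):
        model, text_state, graph_state = pretrained
        g_before = _snapshot(model.graph_encoder)
        gh_before = _snapshot(model.graph_head)
        th_before = _snapshot(model.text_head)
        t_before = _snapshot(model.text_encoder)
        align(
            text_state, graph_state, corpus_records, corpus_graphs,
            TrainConfig.for_align(epochs=2, batch_size=10, seed=4),
        )
        assert _max_delta(g_before, model.graph_encoder) == 0.0
        # classification heads are untouched during alignment
        assert _max_delta(gh_before, model.graph_head) == 0.0
        assert _max_delta(th_before, model.text_head) == 0.0
        assert _max_delta(t_before, model.text_encoder) > 0.0

    def test_auxiliary_bce_term_changes_trajectory_not_heads(
        self, corpus_records, corpus_graphs
    ):
        """The optional classification term during alignment alters the
        text-encoder updates but still never moves the heads or the frozen
        graph encoder."""

        def run(weight):
            model = PepClipModel(
                ModelConfig(max_length=20, text_width=16, text_layers=1,
                            text_heads=2, graph_hidden_width=8,
                            graph_mlp_widths=(8,), graph_out_width=8,
                            latent_width=8, seed=3)
            )
            ts = pretrain(
                "text", corpus_records,
                TrainConfig(stage="pretrain_text", epochs=1, batch_size=10, seed=1),
                model=model,
            )
            gs = pretrain(
                "graph", corpus_records,
                TrainConfig(stage="pretrain_graph", epochs=1, batch_size=10, seed=2),
                model=model, graphs=corpus_graphs,
            )
            th_before = _snapshot(model.text_head)
            align(ts, gs, corpus_records, corpus_graphs,
                  TrainConfig.for_align(epochs=1, batch_size=10, seed=4,
                                        aux_bce_weight=weight))
            assert _max_delta(th_before, model.text_head) == 0.0
            return model.text_encoder.state_dict()

        plain, aux = run(0.0), run(0.5)
        assert any(not np.array_equal(plain[k], aux[k]) for k in plain)

    def test_missing_structures_listed(self, pretrained, corpus_records):
        model, text_state, graph_state = pretrained
        with pytest.raises(ValueError, match=corpus_records[0].id):
            align(text_state, graph_state, corpus_records, {}, TrainConfig.for_align(epochs=1))

    def test_align_requires_contrastive_batches(self):
        with pytest.raises(ValueError):
            TrainConfig(stage="align", batch_size=1)


class TestScheduler:
    def test_plateau_arithmetic_at_reported_rate(self):
        opt = AdamW({}, lr=6.0e-5)
        sched = PlateauScheduler(opt, factor=0.4, patience=5)
        sched.step(1.0)  # sets the best
        for _ in range(5):
            lr = sched.step(1.0)  # five epochs without improvement
        assert lr == pytest.approx(2.4e-5, rel=1e-12)

    def test_improvement_resets_patience(self):
        opt = AdamW({}, lr=1e-3)
        sched = PlateauScheduler(opt, factor=0.5, patience=2)
        for loss in [1.0, 0.9, 0.95, 0.8, 0.85, 0.9]:
            sched.step(loss)
        assert opt.lr == pytest.approx(0.5e-3)

    def test_lr_sequence_is_non_increasing(self):
        rng = np.random.default_rng(0)
        opt = AdamW({}, lr=1e-3)
        sched = PlateauScheduler(opt, factor=0.4, patience=3)
        lrs = [sched.step(float(rng.random())) for _ in range(50)]
        assert all(b <= a for a, b in zip(lrs, lrs[1:]))


class TestCheckpoints:
    def test_round_trip_is_bitwise_exact(self, pretrained, tmp_path):
        _, text_state, _ = pretrained
        path = tmp_path / "state.npz"
        checkpoint_save(text_state, path)
        loaded = checkpoint_load(path)
        a, b = text_state.model.state_dict(), loaded.model.state_dict()
        assert all(np.array_equal(a[k], b[k]) for k in a)
        assert loaded.optimizer.t == text_state.optimizer.t
        assert loaded.optimizer.lr == text_state.optimizer.lr
        assert all(
            np.array_equal(loaded.optimizer.m[k], text_state.optimizer.m[k])
            for k in text_state.optimizer.m
        )

    def test_truncated_file_is_a_clean_error(self, pretrained, tmp_path):
        _, text_state, _ = pretrained
        path = tmp_path / "state.npz"
        checkpoint_save(text_state, path)
        path.write_bytes(path.read_bytes()[:100])
        with pytest.raises(ValueError, match="truncated"):
            checkpoint_load(path)

    def test_version_mismatch_reports_both_versions(self, pretrained, tmp_path, monkeypatch):
        import pepclip.train as train_mod

        _, text_state, _ = pretrained
        path = tmp_path / "state.npz"
        monkeypatch.setattr(train_mod, "CHECKPOINT_VERSION", "pepclip-checkpoint-0")
        checkpoint_save(text_state, path)
        monkeypatch.undo()
        with pytest.raises(ValueError, match="pepclip-checkpoint-0"):
            checkpoint_load(path)

    def test_loaded_state_continues_identically(self, corpus_records, tmp_path):
        """One further identical seeded step from a checkpoint equals the
        same step taken without the save/load detour."""
        from pepclip.train import _bce

        def one_step(state, records):
            y = np.array([r.label for r in records], dtype=np.float64).reshape(-1, 1)
            probs = state.model.text_head(
                state.model.encode_text([r.sequence for r in records])
            )
            loss = _bce(probs, y)
            state.optimizer.zero_grad()
            loss.backward()
            state.optimizer.step()
            return state.model.state_dict()

        model = PepClipModel(
            ModelConfig(max_length=20, text_width=16, text_layers=1, text_heads=2, seed=9)
        )
        state = pretrain(
            "text",
            corpus_records,
            TrainConfig(stage="pretrain_text", epochs=1, batch_size=10, seed=11),
            model=model,
        )
        path = tmp_path / "mid.npz"
        checkpoint_save(state, path)
        direct = one_step(state, corpus_records[:10])
        resumed = one_step(checkpoint_load(path), corpus_records[:10])
        assert all(np.array_equal(direct[k], resumed[k]) for k in direct)
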
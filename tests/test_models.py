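import numpy as np
import pytest

from conceptnorm import models
from conceptnorm.corpus_io import TrainingExample
from conceptnorm.decode import nearest_concept
from conceptnorm.errors import ValidationError
from conceptnorm.models import (
    ModelConfig,
    TrainedModel,
    build_cnn,
    build_cnorm,
    build_slfnn,
    predict_vectors,
    train,
)
from conceptnorm.ontology import build_concept_vectors
from conceptnorm.text import batch_matrices
from oracles import loop_cnn, loop_cnorm, loop_slfnn, random_dag_ontology


def random_batch(rng, b=8, length=6, dim=5):
    x = rng.standard_normal((b, length, dim))
    counts = rng.integers(1, length + 1, size=b)
    mask = np.arange(length)[None, :] < counts[:, None]
    x = x * mask[:, :, None]
    return x, mask


class TestSLFNN:
    def test_parameter_count(self):
        model = build_slfnn(3, 5)
        assert model.n_parameters() == 3 * 5 + 5

    def test_identity_block_single_token(self):
        model = build_slfnn(5, 3)
        model.params["W"] = np.eye(3, 5)
        model.params["b"] = np.zeros(3)
        x = np.zeros((1, 4, 5))
        x[0, 0] = [1, 2, 3, 4, 5]
        mask = np.zeros((1, 4), dtype=bool)
        mask[0, 0] = True
        out, _ = model.forward(x, mask)
        np.testing.assert_allclose(out[0], [1, 2, 3])

    def test_function_of_average_only(self):
        rng = np.random.default_rng(0)
        model = build_slfnn(4, 6, seed=1)
        v1, v2 = rng.standard_normal(4), rng.standard_normal(4)
        # mention [v1, v2] and mention [avg, avg] share the same average
        x = np.zeros((2, 2, 4))
        x[0] = [v1, v2]
        x[1] = [(v1 + v2) / 2, (v1 + v2) / 2]
        mask = np.ones((2, 2), dtype=bool)
        out, _ = model.forward(x, mask)
        np.testing.assert_allclose(out[0], out[1])

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(42)
        model = build_slfnn(5, 7, seed=2)
        x, mask = random_batch(rng, b=50)
        out, _ = model.forward(x, mask)
        expected = loop_slfnn(x, mask, model.params["W"], model.params["b"])
        np.testing.assert_allclose(out, expected, atol=1e-5)


class TestShallowCNN:
    def test_token_permutation_invariance_width_one(self):
        rng = np.random.default_rng(1)
        model = build_cnn(4, 6, pad_length=5, filter_size=1, seed=3)
        tokens = rng.standard_normal((3, 4))
        x = np.zeros((2, 5, 4))
        x[0, :3] = tokens
        x[1, :3] = tokens[::-1]
        mask = np.zeros((2, 5), dtype=bool)
        mask[:, :3] = True
        out, _ = model.forward(x, mask)
        np.testing.assert_allclose(out[0], out[1])

    def test_single_token_pooling_identity(self):
        model = build_cnn(3, 4, pad_length=4, seed=4)
        x = np.zeros((1, 4, 3))
        x[0, 0] = [1.0, -2.0, 0.5]
        mask = np.zeros((1, 4), dtype=bool)
        mask[0, 0] = True
        out, _ = model.forward(x, mask)
        z = model.params["F"][:, 0, :] @ x[0, 0] + model.params["c"]
        np.testing.assert_allclose(out[0], np.where(z > 0, z, 0.3 * z))

    def test_duplicated_token_leaves_output_unchanged(self):
        # max over a multiset ignores duplicates
        rng = np.random.default_rng(5)
        for trial in range(100):
            model = build_cnn(3, 4, pad_length=6, filter_size=1, seed=trial)
            toks = rng.standard_normal((2, 3))
            x1 = np.zeros((1, 6, 3))
            x1[0, :2] = toks
            m1 = np.zeros((1, 6), dtype=bool)
            m1[0, :2] = True
            x2 = np.zeros((1, 6, 3))
            x2[0, :3] = np.vstack([toks, toks[1]])
            m2 = np.zeros((1, 6), dtype=bool)
            m2[0, :3] = True
            out1, _ = model.forward(x1, m1)
            out2, _ = model.forward(x2, m2)
            np.testing.assert_allclose(out1, out2, atol=1e-12)

    @pytest.mark.parametrize("filter_size", [1, 2, 3])
    def test_oracle_equivalence(self, filter_size):
        rng = np.random.default_rng(6)
        model = build_cnn(5, 7, pad_length=6, filter_size=filter_size, seed=7)
        x, mask = random_batch(rng, b=50, length=6, dim=5)
        out, _ = model.forward(x, mask)
        expected = loop_cnn(
            x, mask, model.params["F"], model.params["c"], filter_size, 0.3
        )
        np.testing.assert_allclose(out, expected, atol=1e-5)

    def test_filter_wider_than_padding_rejected(self):
        with pytest.raises(ValueError):
            build_cnn(3, 4, pad_length=2, filter_size=3)

    def test_short_mention_pools_over_padded_window(self):
        model = build_cnn(3, 4, pad_length=5, filter_size=3, seed=8)
        x = np.zeros((1, 5, 3))
        x[0, 0] = [1.0, 1.0, 1.0]
        mask = np.zeros((1, 5), dtype=bool)
        mask[0, 0] = True  # 1 token < filter_size 3
        out, _ = model.forward(x, mask)
        assert np.all(np.isfinite(out))


class TestCNorm:
    def test_output_is_mean_of_branches(self):
        rng = np.random.default_rng(9)
        model = build_cnorm(4, 5, pad_length=6, seed=10)
        x, mask = random_batch(rng, b=20, length=6, dim=4)
        o1, _ = model.linear.forward(x, mask)
        o2, _ = model.conv.forward(x, mask)
        out, _ = model.forward(x, mask)
        np.testing.assert_allclose(out, 0.5 * (o1 + o2), atol=1e-12)

    def test_equal_branches_pass_through(self):
        model = build_cnorm(3, 4, pad_length=3, seed=11)
        # freeze both branches to constant outputs via zero weights + bias
        model.linear.params["W"][:] = 0
        model.conv.params["F"][:] = 0
        model.linear.params["b"][:] = 2.0
        model.conv.params["c"][:] = 2.0
        x = np.zeros((1, 3, 3))
        x[0, 0, 0] = 1.0
        mask = np.zeros((1, 3), dtype=bool)
        mask[0, 0] = True
        out, _ = model.forward(x, mask)
        np.testing.assert_allclose(out[0], 2.0)

    def test_zero_parameters_zero_output(self):
        model = build_cnorm(3, 4, pad_length=3, seed=12)
        for v in model.params.values():
            v[:] = 0.0
        x = np.ones((1, 3, 3))
        mask = np.ones((1, 3), dtype=bool)
        out, _ = model.forward(x, mask)
        np.testing.assert_array_equal(out, np.zeros((1, 4)))

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(13)
        model = build_cnorm(5, 7, pad_length=6, filter_size=2, seed=14)
        x, mask = random_batch(rng, b=50, length=6, dim=5)
        out, _ = model.forward(x, mask)
        expected = loop_cnorm(
            x, mask,
            model.linear.params["W"], model.linear.params["b"],
            model.conv.params["F"], model.conv.params["c"], 2, 0.3,
        )
        np.testing.assert_allclose(out, expected, atol=1e-5)


class TestGradients:
    """Analytic gradients against central finite differences."""

    @pytest.mark.parametrize("arch", ["slfnn", "cnn", "cnorm"])
    def test_numeric_gradient(self, arch):
        rng = np.random.default_rng(15)
        builders = {
            "slfnn": lambda: build_slfnn(4, 3, seed=16),
            "cnn": lambda: build_cnn(4, 3, pad_length=5, filter_size=2, seed=16),
            "cnorm": lambda: build_cnorm(4, 3, pad_length=5, filter_size=2, seed=16),
        }
        model = builders[arch]()
        x, mask = random_batch(rng, b=4, length=5, dim=4)
        target = rng.standard_normal((4, 3))

        def loss_of() -> float:
            out, _ = model.forward(x, mask)
            err = out - target
            return float(np.mean(np.log(np.cosh(err))))

        out, cache = model.forward(x, mask)
        err = out - target
        grads = model.backward(cache, np.tanh(err) / err.size)
        params = model.params
        eps = 1e-6
        for key, p in params.items():
            flat = p.ravel()
            for idx in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                hi = loss_of()
                flat[idx] = orig - eps
                lo = loss_of()
                flat[idx] = orig
                numeric = (hi - lo) / (2 * eps)
                assert grads[key].ravel()[idx] == pytest.approx(numeric, abs=1e-6), key


@pytest.fixture(scope="module")
def tiny_task():
    """8-concept ontology + separable embeddings + one example per concept."""
    rng = np.random.default_rng(21)
    onto = random_dag_ontology(rng, 8)
    space = build_concept_vectors(onto, 0.6)
    dirs = np.linalg.qr(rng.standard_normal((10, 10)))[0][:8]
    from conceptnorm.text import EmbeddingTable

    table = EmbeddingTable(
        10, {f"w{i}": dirs[i] for i in range(8)}
    )
    examples = [
        TrainingExample(tokens=[f"w{i}"], target_concept=cid, provenance="weak")
        for i, cid in enumerate(sorted(onto.concepts))
    ]
    return onto, space, table, examples


class TestTraining:
    def test_loss_decreases_over_run(self, tiny_task):
        _, space, table, examples = tiny_task
        config = ModelConfig(architecture="cnorm", epochs=30, seed=1)
        trained = train(examples, space, table, config)
        assert trained.epoch_losses[-1] <= trained.epoch_losses[0]

    def test_overfit_single_example(self, tiny_task):
        _, space, table, examples = tiny_task
        config = ModelConfig(architecture="slfnn", epochs=200, seed=2)
        trained = train(examples[:1], space, table, config)
        out = predict_vectors(trained, [examples[0].tokens], table)
        cid, _ = nearest_concept(out[0], space)
        assert cid == examples[0].target_concept

    def test_fixed_seed_reproducible(self, tiny_task):
        _, space, table, examples = tiny_task
        config = ModelConfig(architecture="cnorm", epochs=10, seed=3)
        t1 = train(examples, space, table, config)
        t2 = train(examples, space, table, config)
        for key in t1.model.params:
            np.testing.assert_array_equal(t1.model.params[key], t2.model.params[key])

    def test_empty_examples_rejected(self, tiny_task):
        _, space, table, _ = tiny_task
        with pytest.raises(ValidationError):
            train([], space, table, ModelConfig())

    def test_unknown_target_rejected(self, tiny_task):
        _, space, table, _ = tiny_task
        bad = [TrainingExample(tokens=["w0"], target_concept="NOPE", provenance="weak")]
        with pytest.raises(ValidationError, match="NOPE"):
            train(bad, space, table, ModelConfig())

    def test_pad_length_defaults_to_longest_example(self, tiny_task):
        _, space, table, examples = tiny_task
        longer = examples + [
            TrainingExample(
                tokens=["w0", "w1", "w2"], target_concept=examples[0].target_concept,
                provenance="weak",
            )
        ]
        config = ModelConfig(architecture="cnn", epochs=1, seed=0)
        trained = train(longer, space, table, config)
        assert trained.config.pad_length == 3


class TestPrediction:
    def test_empty_mention_list(self, tiny_task):
        _, space, table, examples = tiny_task
        trained = train(examples, space, table, ModelConfig(epochs=1, seed=0))
        assert predict_vectors(trained, [], table).shape == (0, space.n_concepts)

    def test_batched_equals_one_by_one(self, tiny_task):
        _, space, table, examples = tiny_task
        trained = train(examples, space, table, ModelConfig(epochs=2, seed=0))
        toks = [e.tokens for e in examples]
        batched = predict_vectors(trained, toks, table)
        single = np.vstack([predict_vectors(trained, [t], table) for t in toks])
        np.testing.assert_allclose(batched, single, atol=1e-6)

    def test_dimension_mismatch_rejected(self, tiny_task):
        from conceptnorm.text import EmbeddingTable

        _, space, table, examples = tiny_task
        trained = train(examples, space, table, ModelConfig(epochs=1, seed=0))
        other = EmbeddingTable(4, {"w0": np.zeros(4)})
        with pytest.raises(ValidationError, match="dimension"):
            predict_vectors(trained, [["w0"]], other)

    def test_serialization_round_trips_predictions(self, tiny_task, tmp_path):
        _, space, table, examples = tiny_task
        trained = train(examples, space, table, ModelConfig(epochs=3, seed=5))
        trained.save(tmp_path / "model.json")
        loaded = TrainedModel.load(tmp_path / "model.json")
        toks = [e.tokens for e in examples]
        np.testing.assert_array_equal(
            predict_vectors(trained, toks, table),
            predict_vectors(loaded, toks, table),
        )


class TestDefaults:
    def test_default_epochs_table(self):
        assert models.default_epochs("slfnn", "habitat") == 50
        assert models.default_epochs("cnn", "habitat") == 150
        assert models.default_epochs("cnorm", "habitat") == 200
        assert models.default_epochs("cnorm", "phenotype") == 30

    def test_bad_architecture_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(architecture="transformer")
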
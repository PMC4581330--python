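"""Training protocol: loss, determinism, schedule, ensembling and
cross-validation plumbing."""

import numpy as np
import pytest

import idrbrnn.training as training
from idrbrnn import (
    EnsembleModel,
    FilterGeometry,
    TrainConfig,
    cross_entropy_loss,
    crossvalidate,
    ensemble_predict,
    init_two_stage,
    load_ensemble,
    make_folds,
    save_ensemble,
    train_model,
    two_stage_predict,
)
from idrbrnn.network import PARAM_FIELDS

GEOM = FilterGeometry(w=2, p=2)
NET = dict(geometry=GEOM, hidden_chain=5, subnet_hidden=5, span=2)


def small_config(**kw):
    base = dict(
        epochs=3,
        batches_per_epoch=5,
        initial_learning_rate=0.3,
        lr_halving_patience=2,
        n_best_checkpoints=2,
        seed=3,
    )
    base.update(kw)
    return TrainConfig(**base)


class TestCrossEntropy:
    def test_perfect_predictions_zero_loss(self):
        pred = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert cross_entropy_loss(pred, "01") == pytest.approx(0.0, abs=1e-10)

    def test_uniform_predictions_ln2(self):
        pred = np.full((6, 2), 0.5)
        assert cross_entropy_loss(pred, "010101") == pytest.approx(np.log(2))

    def test_matches_direct_summation(self, rng):
        pred = rng.dirichlet([1, 1], size=12)
        y = rng.integers(0, 2, size=12)
        labels = "".join(map(str, y))
        expect = -np.mean([np.log(pred[i, y[i]]) for i in range(12)])
        assert cross_entropy_loss(pred, labels) == pytest.approx(expect)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cross_entropy_loss(np.full((3, 2), 0.5), "0101")


class TestTrainModel:
    def test_same_seed_identical_history_and_members(self, tiny_corpus):
        train, val = tiny_corpus[:9], tiny_corpus[9:]
        runs = []
        for _ in range(2):
            ens, hist = train_model(train, "MSA", small_config(), val, **NET)
            runs.append((ens, hist))
        (e1, h1), (e2, h2) = runs
        assert h1.equals(h2)
        for m1, m2 in zip(e1.members, e2.members):
            for s1, s2 in ((m1.stage1, m2.stage1), (m1.stage2, m2.stage2)):
                for k in PARAM_FIELDS:
                    np.testing.assert_array_equal(getattr(s1, k), getattr(s2, k))

    def test_training_loss_decreases(self):
        from idrbrnn import SyntheticConfig, generate_corpus

        decreases = []
        for seed in (0, 1, 2):
            cfg = SyntheticConfig(
                n_chains=20, length_range=(60, 120), msa_depth=6, seed=seed
            )
            corpus = generate_corpus(cfg)
            ens, hist = train_model(
                corpus[:16],
                "MSA",
                small_config(epochs=50, batches_per_epoch=50, seed=seed),
                corpus[16:],
                **NET,
            )
            decreases.append(
                hist.train_loss.iloc[0] - hist.train_loss.iloc[49]
            )
        assert np.median(decreases) > 0

    def test_lr_halves_each_epoch_on_forced_plateau(
        self, tiny_corpus, monkeypatch
    ):
        monkeypatch.setattr(training, "_validation_loss", lambda m, d: 1.0)
        cfg = small_config(epochs=5, lr_halving_patience=1)
        _, hist = train_model(tiny_corpus[:9], "MSA", cfg, tiny_corpus[9:], **NET)
        # epoch 1 improves on infinity; each later epoch triggers a halving
        np.testing.assert_allclose(
            hist.lr.to_numpy(), 0.3 * 0.5 ** np.array([0, 0, 1, 2, 3])
        )

    def test_empty_validation_rejected(self, tiny_corpus):
        with pytest.raises(ValueError, match="validation"):
            train_model(tiny_corpus[:9], "MSA", small_config(), [], **NET)

    def test_overlapping_validation_rejected(self, tiny_corpus):
        with pytest.raises(ValueError, match="overlap"):
            train_model(
                tiny_corpus[:9], "MSA", small_config(), tiny_corpus[8:10], **NET
            )


class TestEnsemble:
    def test_single_member_identity(self, rng):
        m = init_two_stage(4, geometry=GEOM, rng=rng)
        X = rng.normal(size=(15, 4))
        np.testing.assert_array_equal(
            ensemble_predict(EnsembleModel([m]), X), two_stage_predict(m, X)
        )

    def test_opposite_members_average_to_half(self, rng):
        members = []
        for sign in (1.0, -1.0):
            m = init_two_stage(4, geometry=GEOM, rng=rng)
            for stage in (m.stage1, m.stage2):
                for k in PARAM_FIELDS:
                    getattr(stage, k)[...] = 0.0
            m.stage2.bo2[...] = [sign * 1000.0, -sign * 1000.0]
            members.append(m)
        X = rng.normal(size=(6, 4))
        np.testing.assert_allclose(
            ensemble_predict(EnsembleModel(members), X), 0.5
        )

    def test_45_members_match_direct_mean(self, rng):
        geom = FilterGeometry(w=0, p=0)
        members = [
            init_two_stage(3, geometry=geom, hidden_chain=3, subnet_hidden=3,
                           rng=rng)
            for _ in range(45)
        ]
        ens = EnsembleModel(members)
        X = rng.normal(size=(7, 3))
        expect = np.mean([two_stage_predict(m, X) for m in members], axis=0)
        np.testing.assert_allclose(ensemble_predict(ens, X), expect, atol=1e-12)
        np.testing.assert_allclose(
            ensemble_predict(ens, X).sum(axis=1), 1.0, atol=1e-9
        )

    def test_geometry_mismatch_rejected(self, rng):
        a = init_two_stage(3, geometry=FilterGeometry(w=0, p=0), rng=rng)
        b = init_two_stage(3, geometry=FilterGeometry(w=1, p=0), rng=rng)
        with pytest.raises(ValueError, match="geometry"):
            EnsembleModel([a, b])

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            EnsembleModel([])

    def test_ensemble_round_trip(self, rng, tmp_path):
        members = [init_two_stage(4, geometry=GEOM, rng=rng) for _ in range(3)]
        ens = EnsembleModel(members)
        save_ensemble(ens, tmp_path / "e.npz")
        loaded = load_ensemble(tmp_path / "e.npz")
        X = rng.normal(size=(10, 4))
        np.testing.assert_array_equal(
            ensemble_predict(ens, X), ensemble_predict(loaded, X)
        )


@pytest.fixture(scope="module")
def trained(tiny_corpus):
    cfg = small_config(epochs=10, batches_per_epoch=9, n_best_checkpoints=3)
    return train_model(tiny_corpus[:9], "MSA", cfg, tiny_corpus[9:], **NET)


class TestTrainedBehaviour:
    def test_ensemble_loss_not_worse_than_mean_member_loss(
        self, trained, tiny_corpus
    ):
        # averaging probabilities cannot hurt the log loss (concavity)
        from idrbrnn import assemble_inputs, cross_entropy_loss

        ens, _ = trained
        ens_loss = member_loss = 0.0
        for r in tiny_corpus[9:]:
            X = assemble_inputs("MSA", r)
            ens_loss += cross_entropy_loss(ensemble_predict(ens, X), r.labels)
            member_loss += np.mean(
                [cross_entropy_loss(two_stage_predict(m, X), r.labels)
                 for m in ens.members]
            )
        assert ens_loss <= member_loss + 1e-12

    def test_final_output_tracks_stage1_disorder_probability(
        self, trained, tiny_corpus
    ):
        # the filter refines, not contradicts, first-stage evidence
        from scipy.stats import spearmanr

        from idrbrnn import assemble_inputs, stage_forward

        ens, _ = trained
        member = ens.members[0]
        s1, s2 = [], []
        for r in tiny_corpus[9:]:
            X = assemble_inputs("MSA", r)
            s1.append(stage_forward(member.stage1, X)[:, 1])
            s2.append(two_stage_predict(member, X)[:, 1])
        rho = spearmanr(np.concatenate(s1), np.concatenate(s2)).statistic
        assert rho > 0


class TestCrossValidate:
    def test_every_chain_predicted_exactly_once(self, tiny_corpus):
        corpus = tiny_corpus[:10]
        folds = make_folds(corpus, k=5, seed=0)
        ensembles, pooled, hists = crossvalidate(
            corpus, folds, "MSA", small_config(epochs=2), **NET
        )
        assert len(ensembles) == 5 and len(hists) == 5
        assert sorted(pooled) == sorted(r.id for r in corpus)
        total = sum(len(v) for v in pooled.values())
        assert total == sum(len(r) for r in corpus)
        for r in corpus:
            assert len(pooled[r.id]) == len(r)

    def test_fold_corpus_mismatch_rejected(self, tiny_corpus):
        corpus = tiny_corpus[:10]
        folds = make_folds(tiny_corpus[:8], k=4, seed=0)
        with pytest.raises(ValueError, match="fold"):
            crossvalidate(corpus, folds, "MSA", small_config(), **NET)
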
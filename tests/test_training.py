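"""Loss closed forms, the schedule state machine, and determinism."""

import numpy as np
import pytest

from panoptes.cohort import ClassWeights, TileSetDataset
from panoptes.errors import PanoptesError
from panoptes.model_zoo import ArchitectureConfig, build_model
from panoptes.training import (
    SupervisedTrainer,
    TrainingLoop,
    TrainSchedule,
    loss,
    train,
)


class TestLoss:
    def test_perfect_logits_approach_zero(self):
        logits = np.array([[40.0, -40.0], [-40.0, 40.0]])
        y = np.array([0, 1])
        assert loss(logits, [], y) < 1e-10

    def test_uniform_logits_give_ln2(self):
        logits = np.zeros((6, 2))
        y = np.array([0, 1] * 3)
        assert loss(logits, [], y, ClassWeights("t", (1.0, 1.0))) == pytest.approx(
            np.log(2)
        )

    def test_doubling_positive_weight_doubles_pure_positive_loss(self, rng):
        logits = rng.standard_normal((8, 2))
        y = np.ones(8, dtype=int)
        l1 = loss(logits, [], y, np.array([1.0, 1.0]))
        l2 = loss(logits, [], y, np.array([1.0, 2.0]))
        assert l2 == pytest.approx(2 * l1)

    def test_aux_term_weighted_mean_over_branches(self, rng):
        logits = rng.standard_normal((4, 2))
        aux = [rng.standard_normal((4, 2)) for _ in range(3)]
        y = np.array([0, 1, 0, 1])
        main = loss(logits, [], y)
        per_branch = [loss(a, [], y) for a in aux]
        total = loss(logits, aux, y, aux_weight=0.4)
        assert total == pytest.approx(main + 0.4 * np.mean(per_branch))

    def test_loss_nonnegative(self, rng):
        for _ in range(10):
            logits = rng.standard_normal((5, 2)) * 3
            y = rng.integers(0, 2, 5)
            assert loss(logits, [], y) >= 0


class ScriptedLoop(TrainingLoop):
    """Stub trainer replaying scripted training/validation losses."""

    def __init__(self, schedule, train_losses, val_losses):
        super().__init__(schedule)
        self.train_losses = train_losses
        self.val_losses = val_losses
        self.events = []
        self._vi = 0

    def train_step(self, it):
        return self.train_losses[(it - 1) % len(self.train_losses)]

    def validate(self, it):
        v = self.val_losses[min(self._vi, len(self.val_losses) - 1)]
        self._vi += 1
        self.events.append(("val", it, v))
        return v

    def snapshot(self):
        return ["state", self._vi]


def simulate_schedule(train_losses, val_losses, validate_every, patience,
                      min_stop, lossmin_after, max_iter):
    """Independent oracle: replay the printed schedule rules step by step."""
    best_train = np.inf
    best_val = np.inf
    best_iter = None
    vi = 0
    events = []
    it = 0
    while True:
        it += 1
        tl = train_losses[(it - 1) % len(train_losses)]
        trigger = it % validate_every == 0
        if tl < best_train:
            best_train = tl
            if it > lossmin_after:
                trigger = True
        if trigger:
            vl = val_losses[min(vi, len(val_losses) - 1)]
            vi += 1
            ck = vl < best_val
            if ck:
                best_val, best_iter = vl, it
            events.append((it, vl, ck))
        if it >= min_stop and best_iter is not None and it - best_iter >= patience:
            break
        if max_iter is not None and it >= max_iter:
            break
    return events, best_iter, it


class TestScheduleStateMachine:
    def test_spec_toy_example_stops_at_6_best_at_3(self):
        sched = TrainSchedule(
            batch_size=1, validate_every=1, validate_batches=1,
            min_iter_for_lossmin_validation=10**6, early_stop_patience=3,
            min_iter_before_stop=5,
        )
        loop = ScriptedLoop(sched, [1.0], [5, 4, 3, 3, 3, 3, 3, 3])
        res = loop.run()
        assert res.stopped_at == 6
        assert res.best_iteration == 3
        assert res.best_val_loss == 3
        assert [e.iteration for e in res.log] == [1, 2, 3, 4, 5, 6]
        assert [e.checkpointed for e in res.log] == [True, True, True, False, False, False]

    def test_strictly_decreasing_never_stops_before_cap(self):
        sched = TrainSchedule(
            batch_size=1, validate_every=1, validate_batches=1,
            min_iter_for_lossmin_validation=10**6, early_stop_patience=3,
            min_iter_before_stop=5, max_iterations=50,
        )
        loop = ScriptedLoop(sched, [1.0], list(np.linspace(10, 1, 100)))
        res = loop.run()
        assert res.stopped_at == 50
        assert res.best_iteration == 50

    def test_checkpointed_losses_strictly_decreasing(self):
        rng = np.random.default_rng(0)
        sched = TrainSchedule(
            batch_size=1, validate_every=2, validate_batches=1,
            min_iter_for_lossmin_validation=10**6, early_stop_patience=6,
            min_iter_before_stop=10, max_iterations=60,
        )
        loop = ScriptedLoop(sched, [1.0], list(rng.uniform(1, 5, 60)))
        res = loop.run()
        ck = [e.val_loss for e in res.log if e.checkpointed]
        assert all(a > b for a, b in zip(ck, ck[1:]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_simulation_oracle_with_lossmin_triggers(self, seed):
        rng = np.random.default_rng(seed)
        train_losses = list(rng.uniform(0.5, 2.0, 37))
        val_losses = list(rng.uniform(0.5, 2.0, 80))
        kw = dict(validate_every=5, patience=10, min_stop=20,
                  lossmin_after=12, max_iter=60)
        sched = TrainSchedule(
            batch_size=1, validate_every=kw["validate_every"], validate_batches=1,
            min_iter_for_lossmin_validation=kw["lossmin_after"],
            early_stop_patience=kw["patience"], min_iter_before_stop=kw["min_stop"],
            max_iterations=kw["max_iter"],
        )
        loop = ScriptedLoop(sched, train_losses, val_losses)
        res = loop.run()
        events, best_iter, stop = simulate_schedule(train_losses, val_losses, **kw)
        assert [(e.iteration, e.val_loss, e.checkpointed) for e in res.log] == events
        assert res.best_iteration == best_iter
        assert res.stopped_at == stop

    def test_validation_cadence_without_lossmin(self):
        sched = TrainSchedule(
            batch_size=1, validate_every=7, validate_batches=1,
            min_iter_for_lossmin_validation=10**6, early_stop_patience=7,
            min_iter_before_stop=10**6, max_iterations=30,
        )
        loop = ScriptedLoop(sched, list(np.linspace(2, 1, 50)), [1.0] * 10)
        res = loop.run()
        assert [e.iteration for e in res.log] == [7, 14, 21, 28]

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            TrainSchedule(validate_every=0)
        with pytest.raises(ValueError):
            TrainSchedule(validate_every=100, early_stop_patience=50)


def separable_dataset(n=96, px=75, seed=0, shift=0.35):
    """In-memory two-class tile sets with a strong mean-color signal."""
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % 2
    x = {}
    for m in (10.0, 5.0, 2.5):
        base = rng.standard_normal((n, 3, px, px)) * 0.1
        base[labels == 1, 0] += shift
        base[labels == 1, 2] -= shift
        x[m] = base
    pids = np.array([f"P{i % 12}" for i in range(n)], dtype=object)
    return TileSetDataset(
        x=x, labels=labels, clinical_raw=np.full((n, 2), np.nan),
        patient_ids=pids, slide_ids=pids,
        tile_set_ids=np.array([f"t{i}" for i in range(n)], dtype=object),
        anchors=np.zeros((n, 2), int),
    )


class TestSupervisedTrainer:
    def test_empty_validation_is_configuration_error(self):
        ds = separable_dataset(16)
        empty = separable_dataset(16)
        for m in empty.x:
            empty.x[m] = empty.x[m][:0]
        empty.labels = empty.labels[:0]
        model = build_model(
            ArchitectureConfig(family="panoptes1", width_multiplier=0.1, input_px=75)
        )
        with pytest.raises(PanoptesError, match="validation"):
            SupervisedTrainer(model, ds, empty, TrainSchedule(batch_size=8))

    def test_deterministic_given_seed(self):
        results = []
        for _ in range(2):
            ds = separable_dataset(48)
            model = build_model(
                ArchitectureConfig(family="inception_v1", width_multiplier=0.1,
                                   input_px=75),
                seed=3,
            )
            sched = TrainSchedule(
                batch_size=8, learning_rate=1e-3, validate_every=5,
                validate_batches=2, min_iter_for_lossmin_validation=10**6,
                early_stop_patience=5, min_iter_before_stop=15,
                max_iterations=15, seed=11,
            )
            res = train(model, ds, ds, sched)
            results.append(
                (
                    [(e.iteration, e.train_loss, e.val_loss) for e in res.log],
                    model.state_digest(),
                )
            )
        assert results[0] == results[1]

    def test_learns_separable_classes_within_300_iterations(self):
        # end-to-end learning contract: a narrow Panoptes at 75 px reaches
        # >= 0.95 training accuracy on strongly separable synthetic tile sets
        ds = separable_dataset(96, seed=5)
        model = build_model(
            ArchitectureConfig(family="panoptes1", width_multiplier=0.1, input_px=75),
            seed=1,
        )
        sched = TrainSchedule(
            batch_size=24, learning_rate=1e-3, validate_every=100,
            validate_batches=2, min_iter_for_lossmin_validation=10**6,
            early_stop_patience=100, min_iter_before_stop=300,
            max_iterations=300, seed=1,
        )
        train(model, ds, ds, sched)
        idx = np.arange(len(ds))
        pred = model.predict_proba(ds.batch(idx)).argmax(axis=1)
        assert (pred == ds.labels).mean() >= 0.95
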
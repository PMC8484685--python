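"""Optimization loop: weighted cross-entropy + auxiliary losses, Adam, and
the validate/checkpoint/early-stop schedule.

The schedule follows a fixed state machine.  Training runs with no fixed
epoch count; a 100-batch validation pass happens every 1000 iterations and
additionally whenever the training loss reaches a new global minimum after
iteration 30000.  Whenever the mean validation loss sets a new minimum the
model is checkpointed as the temporary best.  Training stops once no
validation minimum has occurred for 10000 iterations, a criterion enforced
only after iteration 100000.  All counters are configurable; desk-scale runs
shrink them without changing the machine.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cohort import ClassWeights, TileSetDataset
from .errors import PanoptesError
from .nn import Adam, weighted_cross_entropy


@dataclass(frozen=True)
class TrainSchedule:
    """Training-loop constants; defaults are the full-scale settings."""

    batch_size: int = 24                       # 64 for single-resolution baselines
    learning_rate: float = 1e-4
    validate_every: int = 1000
    validate_batches: int = 100
    min_iter_for_lossmin_validation: int = 30000
    early_stop_patience: int = 10000
    min_iter_before_stop: int = 100000
    max_iterations: Optional[int] = None       # hard cap for desk-scale runs
    seed: int = 0

    def __post_init__(self):
        for name in (
            "batch_size",
            "validate_every",
            "validate_batches",
            "min_iter_for_lossmin_validation",
            "early_stop_patience",
            "min_iter_before_stop",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.early_stop_patience < self.validate_every:
            raise ValueError("early_stop_patience must be >= validate_every")

    @classmethod
    def for_baseline(cls, **kw) -> "TrainSchedule":
        kw.setdefault("batch_size", 64)
        return cls(**kw)


def loss(
    logits: np.ndarray,
    aux_logits: Sequence[np.ndarray],
    labels: np.ndarray,
    class_weights: Optional[ClassWeights | np.ndarray] = None,
    aux_weight: float = 0.4,
) -> float:
    """Class-weighted CE on main logits + aux_weight x mean auxiliary CE."""
    value, _, _ = loss_and_grads(logits, aux_logits, labels, class_weights, aux_weight)
    return value


def loss_and_grads(logits, aux_logits, labels, class_weights=None, aux_weight=0.4):
    w = class_weights.as_array() if isinstance(class_weights, ClassWeights) else class_weights
    main, dmain = weighted_cross_entropy(logits, labels, w)
    dauxs = []
    total = main
    if aux_logits:
        k = len(aux_logits)
        for a in aux_logits:
            la, da = weighted_cross_entropy(a, labels, w)
            total += aux_weight * la / k
            dauxs.append(da * (aux_weight / k))
    return float(total), dmain, dauxs


@dataclass
class ValidationEvent:
    iteration: int
    train_loss: float
    val_loss: float
    checkpointed: bool


@dataclass
class TrainingResult:
    best_iteration: Optional[int]
    best_val_loss: Optional[float]
    best_state: Optional[list]
    stopped_at: int
    log: list[ValidationEvent] = field(default_factory=list)

    def log_json(self) -> str:
        return "\n".join(json.dumps(asdict(e)) for e in self.log)

    def restore_best(self, model) -> None:
        if self.best_state is None:
            raise PanoptesError("no checkpoint was ever taken")
        model.set_state(self.best_state)


class TrainingLoop:
    """The schedule state machine, separated from any concrete model.

    Subclasses implement :meth:`train_step` (returning the batch training
    loss), :meth:`validate` (returning one validation-pass mean loss) and
    :meth:`snapshot` (returning a checkpointable model state).
    """

    def __init__(self, schedule: TrainSchedule):
        self.schedule = schedule

    # overridables
    def train_step(self, iteration: int) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def validate(self, iteration: int) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def snapshot(self):
        return None

    def run(self) -> TrainingResult:
        s = self.schedule
        best_train = np.inf
        best_val = np.inf
        best_iter: Optional[int] = None
        best_state = None
        log: list[ValidationEvent] = []
        it = 0
        while True:
            it += 1
            tl = self.train_step(it)
            trigger = it % s.validate_every == 0
            if tl < best_train:
                best_train = tl
                if it > s.min_iter_for_lossmin_validation:
                    trigger = True
            if trigger:
                vl = self.validate(it)
                ckpt = vl < best_val
                if ckpt:
                    best_val = vl
                    best_iter = it
                    best_state = self.snapshot()
                log.append(ValidationEvent(it, float(tl), float(vl), ckpt))
            if (
                it >= s.min_iter_before_stop
                and best_iter is not None
                and it - best_iter >= s.early_stop_patience
            ):
                break
            if s.max_iterations is not None and it >= s.max_iterations:
                break
        return TrainingResult(best_iter, None if best_iter is None else float(best_val),
                              best_state, it, log)


class SupervisedTrainer(TrainingLoop):
    """Concrete trainer: seeded epoch shuffling, Adam, aux-weighted loss.

    Batches are drawn as contiguous slices of a per-epoch permutation drawn
    from the schedule seed, so two runs with the same seed and records see
    identical batch compositions regardless of any loading parallelism.
    """

    def __init__(
        self,
        model,
        train_data: TileSetDataset,
        val_data: TileSetDataset,
        schedule: TrainSchedule,
        class_weights: Optional[ClassWeights] = None,
    ):
        super().__init__(schedule)
        if len(val_data) == 0:
            raise PanoptesError("validation partition is empty; cannot train")
        if len(train_data) == 0:
            raise PanoptesError("training partition is empty; cannot train")
        self.model = model
        self.train_data = train_data
        self.val_data = val_data
        self.class_weights = class_weights
        self.aux_weight = model.cfg.aux_weight
        self.use_clinical = model.clinical is not None
        if self.use_clinical:
            if train_data.clinical is None:
                raise PanoptesError("clinical branch enabled but clinical features not prepared")
            if not model.clinical.fitted:
                model.clinical.fit_standardizer(train_data.clinical)
        self.opt = Adam(model.params(), lr=schedule.learning_rate)
        self._rng = np.random.default_rng(schedule.seed)
        self._val_rng = np.random.default_rng(schedule.seed + 1)
        self._order = np.empty(0, dtype=int)
        self._pos = 0

    def _next_batch_idx(self) -> np.ndarray:
        bs = self.schedule.batch_size
        if self._pos + bs > len(self._order):
            self._order = self._rng.permutation(len(self.train_data))
            self._pos = 0
        idx = self._order[self._pos : self._pos + bs]
        self._pos += bs
        return idx

    def _forward_loss(self, data, idx, train):
        batch = data.batch(idx, clinical=self.use_clinical)
        logits, aux, _ = self.model.forward_full(batch, train=train)
        labels = data.labels[idx]
        return loss_and_grads(
            logits, aux, labels, self.class_weights, self.aux_weight
        )

    def train_step(self, iteration: int) -> float:
        idx = self._next_batch_idx()
        value, dmain, dauxs = self._forward_loss(self.train_data, idx, train=True)
        self.model.backward_full(dmain, dauxs)
        self.opt.step()
        return value

    def validate(self, iteration: int) -> float:
        s = self.schedule
        n = len(self.val_data)
        losses = []
        order = self._val_rng.permutation(n)
        pos = 0
        for _ in range(s.validate_batches):
            if pos + s.batch_size > n:
                order = self._val_rng.permutation(n)
                pos = 0
            idx = order[pos : pos + min(s.batch_size, n)]
            pos += s.batch_size
            value, _, _ = self._forward_loss(self.val_data, idx, train=False)
            losses.append(value)
        return float(np.mean(losses))

    def snapshot(self):
        return self.model.get_state()


def train(
    model,
    train_data: TileSetDataset,
    val_data: TileSetDataset,
    schedule: TrainSchedule,
    class_weights: Optional[ClassWeights] = None,
) -> TrainingResult:
    """Run the full loop; the best checkpoint is restored into the model."""
    trainer = SupervisedTrainer(model, train_data, val_data, schedule, class_weights)
    result = trainer.run()
    if result.best_state is not None:
        model.set_state(result.best_state)
    return result
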
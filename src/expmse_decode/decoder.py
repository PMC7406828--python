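"""Shallow-CNN decoding with cropped training and cross-validation.

The classifier sees individual crops during training (one loss term per
crop) and predicts a trial at test time by averaging the per-crop class
probability vectors.  Two cross-validation designs are supported:

* ``intra`` — within one subject, each task's trials are split into
  four groups (sizes as equal as possible, e.g. 14 -> {4, 4, 3, 3});
  every ordered assignment of one group to validation and another to
  test yields 12 folds with a 2:1:1 train:validation:test ratio.
* ``inter`` — one fold per held-out subject whose trials are all test
  data; each remaining subject's trials are split evenly between
  training and validation.

Feature standardization is fit on the training crops of each fold only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .features import CropSet
from .nn import Adam, EarlyStopper, ShallowCNN, cross_entropy

#: Convolution filter shape per input family.
CONV_KERNELS: dict[str, tuple[int, int]] = {
    "expmse": (5, 5), "raw": (5, 10), "bandpower": (5, 2),
}
#: Pooling shape per input family (band power is only 3 columns wide).
POOL_SHAPES: dict[str, tuple[int, int]] = {
    "expmse": (2, 2), "raw": (2, 2), "bandpower": (2, 1),
}


@dataclass(frozen=True)
class ModelSpec:
    """Architecture and training hyper-parameters of the decoder."""

    input_shape: tuple[int, int]
    n_classes: int
    conv_kernel: tuple[int, int] = (5, 5)
    filters: tuple[int, int] = (16, 32)
    pool: tuple[int, int] = (2, 2)
    learning_rate: float = 1e-3
    batch_size: int = 64
    patience: int = 10
    max_epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.filters) != 2:
            raise ConfigError("exactly two convolution blocks are used")
        if self.n_classes < 2:
            raise ConfigError("need at least two classes")


def spec_for_kind(kind: str, input_shape: tuple[int, int],
                  n_classes: int, **overrides) -> ModelSpec:
    """Default architecture for one input family."""
    if kind not in CONV_KERNELS:
        raise ConfigError(f"unknown input kind {kind!r}")
    params = dict(input_shape=tuple(input_shape), n_classes=n_classes,
                  conv_kernel=CONV_KERNELS[kind], pool=POOL_SHAPES[kind])
    params.update(overrides)
    return ModelSpec(**params)


def build_model(spec: ModelSpec) -> ShallowCNN:
    """Untrained two-block CNN; identical spec+seed => identical weights."""
    return ShallowCNN(
        input_shape=spec.input_shape, n_classes=spec.n_classes,
        conv_kernel=spec.conv_kernel, filters=spec.filters,
        pool=spec.pool, seed=spec.seed,
    )


@dataclass(frozen=True)
class Fold:
    train: tuple[int, ...]
    val: tuple[int, ...]
    test: tuple[int, ...]


@dataclass
class FoldPlan:
    design: str  # 'intra' | 'inter'
    folds: list[Fold]
    #: for inter-subject plans, the held-out subject per fold
    held_out: list[int] = field(default_factory=list)


def make_intra_folds(trial_meta: pd.DataFrame, seed: int = 0) -> FoldPlan:
    """12-fold intra-subject plan from one subject's trial table.

    Per task, trials are split into four groups by seeded interleaving
    (shuffle, then deal round-robin), giving group sizes as equal as
    possible; 14 trials yield the {4, 4, 3, 3} split.  Folds are all 12
    ordered (validation, test) group assignments, with the remaining
    two groups as training data.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF01D]))
    groups: list[list[int]] = [[], [], [], []]
    for task in sorted(trial_meta["task"].unique()):
        keys = trial_meta.loc[trial_meta["task"] == task,
                              "trial_key"].to_numpy()
        if keys.size < 4:
            raise ConfigError(
                f"task {task!r} has {keys.size} trials; need >= 4 for "
                "the four-group intra-subject plan"
            )
        keys = rng.permutation(keys)
        for i, k in enumerate(keys):
            groups[i % 4].append(int(k))
    folds = []
    for v in range(4):
        for t in range(4):
            if t == v:
                continue
            train = tuple(sorted(
                k for g in range(4) if g not in (v, t) for k in groups[g]))
            folds.append(Fold(train=train,
                              val=tuple(sorted(groups[v])),
                              test=tuple(sorted(groups[t]))))
    return FoldPlan(design="intra", folds=folds)


def make_inter_folds(trial_meta: pd.DataFrame, seed: int = 0) -> FoldPlan:
    """Leave-one-subject-out plan over a merged multi-subject trial table.

    All trials of the held-out subject are test data; each remaining
    subject's trials are dealt alternately (after a seeded shuffle,
    per task) into training and validation halves.
    """
    subjects = sorted(trial_meta["subject"].unique())
    if len(subjects) < 3:
        raise ConfigError("inter-subject decoding needs >= 3 subjects")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1A7E]))
    folds, held = [], []
    for s in subjects:
        test = trial_meta.loc[trial_meta["subject"] == s,
                              "trial_key"].to_numpy()
        train, val = [], []
        for other in subjects:
            if other == s:
                continue
            sub = trial_meta[trial_meta["subject"] == other]
            for task in sorted(sub["task"].unique()):
                keys = rng.permutation(
                    sub.loc[sub["task"] == task, "trial_key"].to_numpy())
                train.extend(int(k) for k in keys[0::2])
                val.extend(int(k) for k in keys[1::2])
        folds.append(Fold(train=tuple(sorted(train)),
                          val=tuple(sorted(val)),
                          test=tuple(sorted(int(k) for k in test))))
        held.append(int(s))
    return FoldPlan(design="inter", folds=folds, held_out=held)


@dataclass
class TrainedModel:
    """A fitted decoder plus the train-fold feature scaler."""

    model: ShallowCNN
    classes: tuple[str, ...]
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    history: dict
    spec: ModelSpec

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.scaler_mean) / self.scaler_std

    def predict_proba(self, x: np.ndarray,
                      batch: int = 512) -> np.ndarray:
        xs = self.transform(x)
        out = [self.model.predict_proba(xs[i: i + batch])
               for i in range(0, xs.shape[0], batch)]
        return np.concatenate(out)


def _crop_indices(crop_set: CropSet, trial_keys) -> np.ndarray:
    keys = set(int(k) for k in trial_keys)
    return np.where(np.fromiter(
        (int(t) in keys for t in crop_set.trial_ids),
        dtype=bool, count=crop_set.trial_ids.size))[0]


def train_model(crop_set: CropSet, fold: Fold, spec: ModelSpec,
                verbose: bool = False) -> TrainedModel:
    """Fit the decoder on one fold with cropped training.

    Every crop contributes one cross-entropy term; Adam updates; early
    stopping restores the best-validation-loss weights.  The feature
    scaler (per-cell mean/SD) is fit on training crops only.
    """
    tr_idx = _crop_indices(crop_set, fold.train)
    va_idx = _crop_indices(crop_set, fold.val)
    if tr_idx.size == 0:
        raise ConfigError("empty training set")
    classes = tuple(sorted(set(crop_set.labels)))
    class_of = {c: i for i, c in enumerate(classes)}
    if len(classes) != spec.n_classes:
        raise ConfigError(
            f"spec expects {spec.n_classes} classes, data has "
            f"{len(classes)}")

    x_tr = crop_set.data[tr_idx]
    mean = x_tr.mean(axis=0)
    std = np.maximum(x_tr.std(axis=0), 1e-8)
    x_tr = (x_tr - mean) / std
    y_tr = np.zeros((tr_idx.size, len(classes)))
    for i, lab in enumerate(crop_set.labels[tr_idx]):
        y_tr[i, class_of[lab]] = 1.0
    x_va = (crop_set.data[va_idx] - mean) / std
    y_va = np.zeros((va_idx.size, len(classes)))
    for i, lab in enumerate(crop_set.labels[va_idx]):
        y_va[i, class_of[lab]] = 1.0

    model = build_model(spec)
    optimizer = Adam(model.parameters(), lr=spec.learning_rate)
    stopper = EarlyStopper(spec.patience)
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), 0x5EED]))
    history = {"train_loss": [], "val_loss": []}
    best_weights = model.get_weights()

    def _eval_loss(x, y, batch=512) -> float:
        if x.shape[0] == 0:
            return np.nan
        total = 0.0
        for i in range(0, x.shape[0], batch):
            logits = model.forward(x[i: i + batch], train=False)
            loss, _ = cross_entropy(logits, y[i: i + batch])
            total += loss * min(batch, x.shape[0] - i)
        return total / x.shape[0]

    for epoch in range(spec.max_epochs):
        perm = shuffle_rng.permutation(tr_idx.size)
        epoch_loss = 0.0
        for i in range(0, perm.size, spec.batch_size):
            sel = perm[i: i + spec.batch_size]
            logits = model.forward(x_tr[sel], train=True)
            loss, dlogits = cross_entropy(logits, y_tr[sel])
            model.backward(dlogits)
            optimizer.step(model.gradients())
            epoch_loss += loss * sel.size
        history["train_loss"].append(epoch_loss / perm.size)
        val_loss = _eval_loss(x_va, y_va)
        history["val_loss"].append(val_loss)
        if verbose:
            print(f"epoch {epoch}: train {history['train_loss'][-1]:.4f} "
                  f"val {val_loss:.4f}")
        if val_loss < stopper.best:
            best_weights = model.get_weights()
        if stopper.update(val_loss, epoch):
            break
    model.set_weights(best_weights)
    history["best_epoch"] = stopper.best_epoch
    return TrainedModel(model=model, classes=classes, scaler_mean=mean,
                        scaler_std=std, history=history, spec=spec)


@dataclass
class TrialPrediction:
    trial_key: int
    true_label: str
    mean_proba: np.ndarray
    predicted_label: str


def predict_trial(trained: TrainedModel, crop_set: CropSet,
                  trial_key: int) -> TrialPrediction:
    """Average the per-crop probability vectors; argmax is the label."""
    idx = crop_set.crops_of_trial(trial_key)
    if idx.size == 0:
        raise ConfigError(f"trial {trial_key} has no crops")
    probs = trained.predict_proba(crop_set.data[idx]).mean(axis=0)
    meta = crop_set.trial_meta
    true = meta.loc[meta["trial_key"] == trial_key, "label"].iloc[0]
    return TrialPrediction(
        trial_key=int(trial_key), true_label=str(true),
        mean_proba=probs,
        predicted_label=trained.classes[int(np.argmax(probs))],
    )


@dataclass
class AccuracyReport:
    """Per-fold and aggregate decoding accuracy for one input kind."""

    kind: str
    design: str
    fold_accuracy: list[float]  # percent
    predictions: pd.DataFrame   # fold, trial_key, true, predicted

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_accuracy, ddof=1)) \
            if len(self.fold_accuracy) > 1 else 0.0

    @property
    def n_decisions(self) -> int:
        return len(self.predictions)

    @property
    def overall_accuracy(self) -> float:
        """Percent of all test-trial decisions that are correct."""
        df = self.predictions
        return float(100.0 * (df["true"] == df["predicted"]).mean())


def cross_validate(
    crop_set: CropSet,
    plan: FoldPlan,
    spec: ModelSpec,
    keep_models: bool = False,
) -> AccuracyReport | tuple[AccuracyReport, list[TrainedModel]]:
    """Train and evaluate the decoder over every fold of a plan."""
    rows = []
    fold_acc = []
    models = []
    for f, fold in enumerate(plan.folds):
        fold_spec = ModelSpec(**{**spec.__dict__, "seed": spec.seed + f})
        trained = train_model(crop_set, fold, fold_spec)
        correct = 0
        for key in fold.test:
            pred = predict_trial(trained, crop_set, key)
            correct += pred.true_label == pred.predicted_label
            rows.append((f, key, pred.true_label, pred.predicted_label))
        fold_acc.append(100.0 * correct / len(fold.test))
        if keep_models:
            models.append(trained)
    report = AccuracyReport(
        kind=crop_set.kind, design=plan.design, fold_accuracy=fold_acc,
        predictions=pd.DataFrame(
            rows, columns=["fold", "trial_key", "true", "predicted"]),
    )
    if keep_models:
        return report, models
    return report


def permute_trial_labels(crop_set: CropSet, seed: int) -> CropSet:
    """Uniformly permute task labels across trials (chance-level control).

    The permutation acts at the trial level so all crops of a trial
    keep a common (permuted) label.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xBE4]))
    meta = crop_set.trial_meta.copy()
    perm = rng.permutation(meta["task"].to_numpy())
    meta["task"] = perm
    meta["label"] = perm
    label_of = dict(zip(meta["trial_key"], perm))
    labels = np.array([label_of[int(t)] for t in crop_set.trial_ids])
    return CropSet(crop_set.kind, crop_set.data, labels,
                   crop_set.trial_ids, meta)


def compare_kinds(report_a: AccuracyReport, report_b: AccuracyReport,
                  method: str = "ttest") -> float:
    """Two-tailed paired test on per-fold accuracies of two input kinds."""
    a = np.asarray(report_a.fold_accuracy, dtype=np.float64)
    b = np.asarray(report_b.fold_accuracy, dtype=np.float64)
    if a.size != b.size:
        raise ConfigError("reports must have the same number of folds")
    diffs = a - b
    if np.allclose(diffs, 0.0):
        return 1.0
    if method == "ttest":
        return float(stats.ttest_rel(a, b).pvalue)
    if method == "wilcoxon":
        return float(stats.wilcoxon(a, b).pvalue)
    raise ConfigError(f"unknown method {method!r}")


__all__ = [
    "CONV_KERNELS", "POOL_SHAPES", "ModelSpec", "spec_for_kind",
    "build_model", "Fold", "FoldPlan", "make_intra_folds",
    "make_inter_folds", "TrainedModel", "train_model", "TrialPrediction",
    "predict_trial", "AccuracyReport", "cross_validate",
    "permute_trial_labels", "compare_kinds",
]
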
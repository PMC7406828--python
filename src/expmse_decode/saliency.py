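"""Gradient-based sensitivity maps of the trained decoder.

For a class score S_c(x) taken at the classification layer, the
sensitivity map is M_c(x) = dS_c/dx — the exact reverse-mode gradient
of the score with respect to the input feature map.  Positive cells
push the input toward class c when increased; negative cells push it
away.  By default the score is the pre-softmax logit (the standard
saliency choice; the post-softmax probability is available by flag —
the argmax classification is invariant to the choice).  Maps are
standardized by dividing by their own SD (signs preserved) and averaged
over all test-partition crops of a task across folds.
"""

from __future__ import annotations

import numpy as np

from .decoder import FoldPlan, TrainedModel, _crop_indices
from .errors import ConfigError
from .features import CropSet
from .nn import ShallowCNN, softmax


def class_score_gradient(
    model: ShallowCNN,
    x: np.ndarray,
    class_index: int,
    post_softmax: bool = False,
) -> np.ndarray:
    """dS_c/dx for one input map (rows x cols) in inference mode."""
    if not 0 <= class_index < model.n_classes:
        raise ConfigError(f"invalid class index {class_index}")
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 2
    batch = x[None] if single else x
    logits = model.forward(batch, train=False)
    if post_softmax:
        p = softmax(logits)
        dlogits = p[:, class_index: class_index + 1] * (
            np.eye(model.n_classes)[class_index][None, :] - p)
    else:
        dlogits = np.zeros_like(logits)
        dlogits[:, class_index] = 1.0
    grad = model.backward(dlogits, need_input_grad=True)
    return grad[0] if single else grad


def standardize_map(sens_map: np.ndarray) -> np.ndarray:
    """Divide by the map's own SD; no mean subtraction (signs kept)."""
    sens_map = np.asarray(sens_map, dtype=np.float64)
    sd = sens_map.std()
    if sd == 0:
        raise ConfigError("zero-SD sensitivity map cannot be standardized")
    return sens_map / sd


def task_mean_map(maps: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Elementwise mean of already-standardized per-crop maps."""
    maps = np.asarray(maps, dtype=np.float64)
    if maps.ndim == 2:
        maps = maps[None]
    if maps.shape[0] == 0:
        raise ConfigError("no maps to average")
    return maps.mean(axis=0)


def task_sensitivity_map(
    trained_models: list[TrainedModel],
    crop_set: CropSet,
    plan: FoldPlan,
    task: str,
    post_softmax: bool = False,
    batch: int = 256,
) -> np.ndarray:
    """Mean standardized sensitivity map of one task's class.

    Gradients are taken at every test-partition crop of the task in
    every fold, with respect to the fold model that saw that crop as
    test data; each map is standardized before averaging.  Gradients
    are computed on the standardized model input.
    """
    if len(trained_models) != len(plan.folds):
        raise ConfigError("one trained model per fold is required")
    acc: list[np.ndarray] = []
    meta = crop_set.trial_meta
    for trained, fold in zip(trained_models, plan.folds):
        if task not in trained.classes:
            raise ConfigError(f"task {task!r} unknown to the model")
        c = trained.classes.index(task)
        task_keys = [k for k in fold.test
                     if meta.loc[meta["trial_key"] == k, "label"].iloc[0]
                     == task]
        if not task_keys:
            continue
        idx = _crop_indices(crop_set, task_keys)
        xs = trained.transform(crop_set.data[idx])
        for i in range(0, xs.shape[0], batch):
            grads = class_score_gradient(trained.model, xs[i: i + batch],
                                         c, post_softmax=post_softmax)
            for g in grads:
                acc.append(standardize_map(g))
    if not acc:
        raise ConfigError(f"no test crops of task {task!r} in the plan")
    return task_mean_map(acc)


def top_cells(sens_map: np.ndarray, fraction: float = 0.1) -> set[tuple]:
    """(row, col) cells in the top ``fraction`` by |sensitivity|."""
    flat = np.abs(sens_map).ravel()
    k = max(1, int(round(flat.size * fraction)))
    order = np.argsort(flat)[::-1][:k]
    return {tuple(map(int, np.unravel_index(i, sens_map.shape)))
            for i in order}


def jaccard(a: set, b: set) -> float:
    """Jaccard overlap |a & b| / |a | b| of two cell sets."""
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


__all__ = [
    "class_score_gradient", "standardize_map", "task_mean_map",
    "task_sensitivity_map", "top_cells", "jaccard",
]
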
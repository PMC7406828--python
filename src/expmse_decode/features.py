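"""Trial segmentation, feature-map assembly and training crops.

Three input families feed the decoder:

* ``expmse`` — the region x 30 complexity map at the 0.64 s ML grid
  (9 maps per 6 s task window);
* ``bandpower`` — the region x 3 coarse band-power map on the same grid;
* ``raw`` — the region x time segment of the 200 Hz downsampled signal.

Crops: for the ML-grid families, every 4-of-9 subset of a trial's ML
samples is averaged into one crop (C(9,4) = 126 per trial); for raw, a
2 s window (400 samples) slides in steps of 6 samples over the 1200
sample task segment (134 crops).  The first session is a practice
session and the first trial of each task has no pre-task break; both
are excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .entropy import ComplexityTensor
from .errors import ConfigError
from .simulate import Recording

#: Tasks decoded in the four-class design (all tasks still feed the
#: entropy index).  Auditory tasks are excluded: the task cue itself is
#: acoustic.
DEFAULT_DECODED_TASKS: tuple[str, ...] = ("VP", "VI", "ME", "MI")

#: Two-class relabeling of the decoded tasks.
TWO_CLASS_MAP: dict[str, str] = {
    "VI": "imagery", "MI": "imagery",
    "VP": "non-imagery", "ME": "non-imagery",
}

CROP_KINDS: tuple[str, ...] = ("expmse", "bandpower", "raw")


@dataclass(frozen=True)
class TrialWindow:
    """One analyzable trial: label plus ML-grid and raw sample ranges."""

    subject: int
    session: int
    task: str
    trial: int
    ml_start: int
    n_ml: int
    raw_start: int
    raw_stop: int
    fs: float = 400.0

    @property
    def trial_id(self) -> tuple[int, int, str, int]:
        return (self.subject, self.session, self.task, self.trial)


def segment_trials(
    events: pd.DataFrame,
    fs: float,
    analyzed_sessions: tuple[int, ...] = (2, 3),
    bin_s: float = 0.64,
    subject: int = 0,
    tasks: tuple[str, ...] | None = None,
) -> list[TrialWindow]:
    """Analyzable trial windows after practice/first-trial exclusion.

    Drops every trial of sessions not in ``analyzed_sessions`` (session
    1 is the practice session) and the first trial of each task within
    each remaining session.  A trial's ML range starts at the ML bin
    containing its task onset: the 9 bins of a 6 s task window then end
    before the task offset and reach at most one bin into the same
    trial's rest period, so crops never span another trial's samples.
    """
    bin_raw = int(round(bin_s * fs))
    per_task = events.groupby("task")["trial"].nunique()
    if (per_task < 2).any():
        raise ConfigError("need at least 2 trials per task "
                          "(first-trial exclusion leaves none)")
    windows = []
    for row in events.itertuples(index=False):
        if row.session not in analyzed_sessions:
            continue
        if row.trial == 1:
            continue
        if tasks is not None and row.task not in tasks:
            continue
        task_len = row.task_offset - row.task_onset
        n_ml = int(task_len // bin_raw)
        windows.append(TrialWindow(
            subject=subject, session=int(row.session), task=row.task,
            trial=int(row.trial), ml_start=int(row.task_onset // bin_raw),
            n_ml=n_ml, raw_start=int(row.task_onset),
            raw_stop=int(row.task_offset), fs=fs,
        ))
    return windows


def assemble_feature_series(
    source: ComplexityTensor | np.ndarray | Recording,
    window: TrialWindow,
    kind: str,
) -> np.ndarray:
    """Per-trial feature series for one input family.

    * ``expmse``: (n_ml, R, 30) maps from a :class:`ComplexityTensor`;
    * ``bandpower``: (n_ml, R, 3) maps from the (R, 3, T) power array;
    * ``raw``: (R, n_task_samples) segment of a 200 Hz recording.
    """
    if kind == "expmse":
        tensor: ComplexityTensor = source
        stop = window.ml_start + window.n_ml
        if stop > tensor.values.shape[2]:
            raise ConfigError("trial window out of tensor range")
        return np.transpose(
            tensor.values[:, :, window.ml_start: stop], (2, 0, 1)
        ).copy()
    if kind == "bandpower":
        power = np.asarray(source, dtype=np.float64)  # (R, 3, T)
        stop = window.ml_start + window.n_ml
        if stop > power.shape[2]:
            raise ConfigError("trial window out of band-power range")
        return np.transpose(
            power[:, :, window.ml_start: stop], (2, 0, 1)
        ).copy()
    if kind == "raw":
        rec: Recording = source
        ratio = rec.fs / window.fs  # window indices are at the event rate
        start = int(round(window.raw_start * ratio))
        stop = int(round(window.raw_stop * ratio))
        if stop > rec.n_samples:
            raise ConfigError("trial window out of recording range")
        return rec.data[:, start:stop].copy()
    raise ConfigError(f"unknown feature kind {kind!r}")


def crop_combinations(trial_series: np.ndarray, k: int = 4) -> np.ndarray:
    """All k-of-n averages of a trial's ML maps, lexicographic order.

    ``trial_series`` is (n_ml, R, C); returns (C(n_ml, k), R, C).
    """
    n = trial_series.shape[0]
    if not 1 <= k <= n:
        raise ConfigError(f"k={k} must be in [1, {n}]")
    out = np.empty((comb(n, k),) + trial_series.shape[1:])
    for i, subset in enumerate(combinations(range(n), k)):
        out[i] = trial_series[list(subset)].mean(axis=0)
    return out


def crop_sliding_raw(trial_raw: np.ndarray, win: int = 400,
                     step: int = 6) -> np.ndarray:
    """Sliding-window crops of a raw trial segment (R, N) -> (n, R, win)."""
    n = trial_raw.shape[1]
    if win > n:
        raise ConfigError(f"window {win} exceeds trial length {n}")
    offsets = range(0, n - win + 1, step)
    return np.stack([trial_raw[:, o: o + win] for o in offsets])


def downsample_raw(recording: Recording, target: float = 200.0) -> Recording:
    """Anti-aliased polyphase resample of a recording to ``target`` Hz."""
    if target > recording.fs:
        raise ConfigError("target rate exceeds the recording rate")
    if target == recording.fs:
        return Recording(recording.data.copy(), recording.fs,
                         recording.region_labels, recording.subject)
    from fractions import Fraction

    frac = Fraction(target / recording.fs).limit_denominator(1000)
    data = resample_poly(recording.data, frac.numerator, frac.denominator,
                         axis=1)
    return Recording(data, target, recording.region_labels,
                     recording.subject)


@dataclass
class CropSet:
    """Stacked crops with labels and trial provenance.

    ``data`` is (n_crops, R, C); ``trial_ids`` maps every crop to the
    trial it was cut from (crops of one trial share its label).
    """

    kind: str
    data: np.ndarray
    labels: np.ndarray          # (n_crops,) task label per crop
    trial_ids: np.ndarray       # (n_crops,) integer trial key
    trial_meta: pd.DataFrame    # one row per trial: id, subject, session,
                                # task, trial

    @property
    def n_crops(self) -> int:
        return self.data.shape[0]

    def trials(self) -> np.ndarray:
        return self.trial_meta["trial_key"].to_numpy()

    def crops_of_trial(self, trial_key: int) -> np.ndarray:
        return np.where(self.trial_ids == trial_key)[0]

    def relabel(self, mapping: dict[str, str]) -> "CropSet":
        """Relabel tasks (e.g. the imagery / non-imagery two-class map)."""
        labels = np.array([mapping[t] for t in self.labels])
        meta = self.trial_meta.copy()
        meta["label"] = [mapping[t] for t in meta["task"]]
        return CropSet(self.kind, self.data, labels, self.trial_ids, meta)


def build_crop_set(
    source,
    windows: list[TrialWindow],
    kind: str,
    k: int = 4,
    raw_win: int = 400,
    raw_step: int = 6,
) -> CropSet:
    """Assemble and crop every trial window into one labelled CropSet."""
    data, labels, trial_ids, meta_rows = [], [], [], []
    for key, w in enumerate(windows):
        series = assemble_feature_series(source, w, kind)
        if kind == "raw":
            crops = crop_sliding_raw(series, win=raw_win, step=raw_step)
        else:
            crops = crop_combinations(series, k=k)
        data.append(crops)
        labels.extend([w.task] * crops.shape[0])
        trial_ids.extend([key] * crops.shape[0])
        meta_rows.append((key, w.subject, w.session, w.task, w.trial))
    if not data:
        raise ConfigError("no trial windows to crop")
    meta = pd.DataFrame(
        meta_rows,
        columns=["trial_key", "subject", "session", "task", "trial"],
    )
    meta["label"] = meta["task"]
    return CropSet(kind=kind, data=np.concatenate(data),
                   labels=np.array(labels),
                   trial_ids=np.array(trial_ids, dtype=np.int64),
                   trial_meta=meta)


def merge_crop_sets(sets: list[CropSet]) -> CropSet:
    """Concatenate per-subject CropSets, re-keying trials uniquely."""
    if not sets:
        raise ConfigError("nothing to merge")
    kind = sets[0].kind
    data, labels, trial_ids, metas = [], [], [], []
    offset = 0
    for cs in sets:
        if cs.kind != kind:
            raise ConfigError("cannot merge crop sets of different kinds")
        data.append(cs.data)
        labels.append(cs.labels)
        trial_ids.append(cs.trial_ids + offset)
        meta = cs.trial_meta.copy()
        meta["trial_key"] = meta["trial_key"] + offset
        metas.append(meta)
        offset += len(cs.trial_meta)
    return CropSet(kind=kind, data=np.concatenate(data),
                   labels=np.concatenate(labels),
                   trial_ids=np.concatenate(trial_ids),
                   trial_meta=pd.concat(metas, ignore_index=True))


__all__ = [
    "DEFAULT_DECODED_TASKS", "TWO_CLASS_MAP", "CROP_KINDS",
    "TrialWindow", "CropSet",
    "segment_trials", "assemble_feature_series", "crop_combinations",
    "crop_sliding_raw", "downsample_raw", "build_crop_set",
    "merge_crop_sets",
]
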
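"""Synthetic multi-subject cohort of region-level oscillatory recordings.

The generator emulates source-reconstructed neural time series averaged
within cortical regions: a 1/f^alpha background plus band-limited
oscillations (alpha ~ 10 Hz, beta ~ 20 Hz, gamma ~ 40 Hz) whose
instantaneous amplitude and phase regularity are modulated inside task
windows according to a list of :class:`EffectSpec`.  Sessions, tasks and
trials follow a fixed back-to-back layout: each trial is ``rest_s`` seconds
of rest followed by ``task_s`` seconds of task, tasks are performed
successively in a fixed order, and the whole task block is repeated in
every session.

Oscillation regularity is controlled through random-walk phase jitter:
the phase advances by ``2*pi*f/fs`` per sample plus Gaussian increments
whose SD is divided by the effect's ``regularity_gain`` inside task
windows.  Higher regularity therefore yields a more predictable band
component and a lower sample entropy, which is the property the entropy
stage is designed to recover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError

#: The 12 task labels in their fixed presentation order.
DEFAULT_TASKS: tuple[str, ...] = (
    "VP", "VI", "AP", "AI", "ME", "MI",
    "VI2", "MI2", "AP2", "DL", "VP2", "VP3",
)

_DK_BASE = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal",
    "middletemporal", "paracentral", "parahippocampal", "parsopercularis",
    "parsorbitalis", "parstriangularis", "pericalcarine", "postcentral",
    "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "temporalpole",
    "transversetemporal",
)

#: 68 Desikan-Killiany cortical region labels (34 per hemisphere).
DK_REGIONS: tuple[str, ...] = tuple(
    f"{name}-{hemi}" for hemi in ("lh", "rh") for name in _DK_BASE
)

#: Named region groups used to place condition effects.
REGION_GROUPS: dict[str, tuple[str, ...]] = {
    "occipital": tuple(
        f"{n}-{h}" for h in ("lh", "rh")
        for n in ("lateraloccipital", "pericalcarine", "cuneus", "lingual")
    ),
    "central": tuple(
        f"{n}-{h}" for h in ("lh", "rh")
        for n in ("precentral", "postcentral", "paracentral")
    ),
    "prefrontal": tuple(
        f"{n}-{h}" for h in ("lh", "rh")
        for n in ("superiorfrontal", "rostralmiddlefrontal",
                  "medialorbitofrontal")
    ),
}

#: Center frequency (Hz) of each simulated band.
BAND_FREQS: dict[str, float] = {"gamma": 40.0, "beta": 20.0, "alpha": 10.0}

#: Baseline oscillation amplitude relative to the unit-SD 1/f background.
BAND_BASE_AMP: dict[str, float] = {"gamma": 0.5, "beta": 0.7, "alpha": 1.0}

#: Baseline phase-jitter SD as a fraction of the per-sample phase step.
PHASE_JITTER_FRAC = 0.3


@dataclass(frozen=True)
class SimulationConfig:
    """Study-layout and background-noise parameters of the cohort."""

    n_subjects: int = 8
    n_regions: int = 68
    fs: float = 400.0
    n_sessions: int = 3
    trials_per_task: int = 8
    tasks: tuple[str, ...] = DEFAULT_TASKS
    rest_s: float = 6.0
    task_s: float = 6.0
    noise_exponent: float = 1.0
    master_seed: int = 0
    region_labels: tuple[str, ...] | None = None
    #: SD of the multiplicative between-subject jitter on effect gains.
    effect_jitter_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.n_regions < 1:
            raise ConfigError("n_regions must be >= 1")
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        if self.n_sessions < 1:
            raise ConfigError("n_sessions must be >= 1")
        if self.trials_per_task < 2:
            raise ConfigError(
                "trials_per_task must be >= 2 (first-trial exclusion "
                "must leave at least one analyzable trial)"
            )
        if self.rest_s <= 0 or self.task_s <= 0:
            raise ConfigError("rest_s and task_s must be positive")
        if not self.tasks:
            raise ConfigError("tasks must be non-empty")
        if len(set(self.tasks)) != len(self.tasks):
            raise ConfigError("task labels must be unique")
        if self.effect_jitter_sd < 0:
            raise ConfigError("effect_jitter_sd must be >= 0")
        labels = self.region_labels
        if labels is None:
            if self.n_regions > len(DK_REGIONS):
                raise ConfigError(
                    f"n_regions={self.n_regions} exceeds the "
                    f"{len(DK_REGIONS)} default Desikan-Killiany labels; "
                    "pass explicit region_labels"
                )
            labels = DK_REGIONS[: self.n_regions]
            object.__setattr__(self, "region_labels", labels)
        if len(labels) != self.n_regions:
            raise ConfigError("region_labels length must equal n_regions")
        if len(set(labels)) != len(labels):
            raise ConfigError("region labels must be unique")

    @property
    def rest_samples(self) -> int:
        return int(round(self.rest_s * self.fs))

    @property
    def task_samples(self) -> int:
        return int(round(self.task_s * self.fs))

    @property
    def trial_samples(self) -> int:
        return self.rest_samples + self.task_samples

    @property
    def samples_per_session(self) -> int:
        return len(self.tasks) * self.trials_per_task * self.trial_samples

    @property
    def n_samples(self) -> int:
        return self.n_sessions * self.samples_per_session


@dataclass(frozen=True)
class EffectSpec:
    """A condition-locked band effect in a named group of regions.

    ``amplitude_gain`` multiplies the band oscillation amplitude during
    the task window; ``regularity_gain`` divides the random-walk phase
    jitter SD (higher regularity => lower entropy of the band component).
    """

    task: str
    regions: tuple[str, ...]
    band: str
    amplitude_gain: float = 1.0
    regularity_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.band not in BAND_FREQS:
            raise ConfigError(f"unknown band {self.band!r}")
        if self.amplitude_gain <= 0 or self.regularity_gain <= 0:
            raise ConfigError("effect gains must be positive")
        if not self.regions:
            raise ConfigError("effect region group must be non-empty")


@dataclass
class Recording:
    """Region x time matrix with sampling rate and region labels."""

    data: np.ndarray  # (n_regions, n_samples)
    fs: float
    region_labels: tuple[str, ...]
    subject: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ConfigError("recording data must be 2-D (regions x time)")
        if self.data.shape[0] != len(self.region_labels):
            raise ConfigError("data rows must match region_labels")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def default_effects(config: SimulationConfig | None = None) -> list[EffectSpec]:
    """The strong-effect condition set used as the cohort default.

    Non-imagery tasks drive the modality-specific band of their region
    group (VP: occipital gamma, ME: central beta); imagery tasks drive
    the alpha band of the same group (VI: occipital, MI: central), and
    both imagery tasks add a weaker supramodal prefrontal gamma
    regularity effect.  Tasks missing from the configured task list are
    silently dropped so reduced task sets remain valid.
    """
    labels = set(config.region_labels) if config is not None else None
    tasks = set(config.tasks) if config is not None else None

    def group(name: str) -> tuple[str, ...]:
        regions = REGION_GROUPS[name]
        if labels is not None:
            regions = tuple(r for r in regions if r in labels)
        return regions

    raw = [
        ("VP", "occipital", "gamma", 2.0, 4.0),
        ("VI", "occipital", "alpha", 2.0, 4.0),
        ("ME", "central", "beta", 2.0, 4.0),
        ("MI", "central", "alpha", 2.0, 4.0),
        ("VI", "prefrontal", "gamma", 1.0, 2.0),
        ("MI", "prefrontal", "gamma", 1.0, 2.0),
    ]
    out = []
    for task, grp, band, a_gain, r_gain in raw:
        if tasks is not None and task not in tasks:
            continue
        regions = group(grp)
        if not regions:
            continue
        out.append(EffectSpec(task, regions, band, a_gain, r_gain))
    return out


def generate_events(config: SimulationConfig) -> pd.DataFrame:
    """Lay out the event table: one row per (session, task, trial).

    Within every session the tasks appear in the configured fixed order,
    and the ``trials_per_task`` trials of a task are back-to-back.  All
    onsets/offsets are sample indices into the continuous recording;
    sessions and trials are 1-based.
    """
    rows = []
    cursor = 0
    for session in range(1, config.n_sessions + 1):
        for task in config.tasks:
            for trial in range(1, config.trials_per_task + 1):
                rest_onset = cursor
                task_onset = rest_onset + config.rest_samples
                task_offset = task_onset + config.task_samples
                rows.append((session, task, trial,
                             rest_onset, task_onset, task_offset))
                cursor = task_offset
    return pd.DataFrame(
        rows,
        columns=["session", "task", "trial",
                 "rest_onset", "task_onset", "task_offset"],
    )


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD noise with power spectrum ~ 1/f^exponent (FFT shaping)."""
    freqs = np.fft.rfftfreq(n, d=1.0)
    spectrum = rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spectrum * scale, n=n)
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


def _validate_effects(config: SimulationConfig,
                      effects: list[EffectSpec]) -> None:
    known = set(config.region_labels)
    for eff in effects:
        if eff.task not in config.tasks:
            raise ConfigError(f"effect references unknown task {eff.task!r}")
        missing = [r for r in eff.regions if r not in known]
        if missing:
            raise ConfigError(
                f"effect references unknown regions {missing!r}"
            )


def _task_window_mask(events: pd.DataFrame, task: str, n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    sel = events[events["task"] == task]
    for onset, offset in zip(sel["task_onset"], sel["task_offset"]):
        mask[onset:offset] = True
    return mask


def generate_recording(
    config: SimulationConfig,
    effects: list[EffectSpec],
    subject_seed: int,
    effect_scales: dict[int, tuple[float, float]] | None = None,
) -> tuple[Recording, pd.DataFrame]:
    """Simulate one subject's continuous region x time recording.

    ``effect_scales`` optionally maps effect index -> (amplitude-gain
    factor, regularity-gain factor) used by :func:`generate_cohort` to
    inject between-subject variability.  The same ``(config, effects,
    subject_seed)`` triple always produces a bit-identical matrix.
    """
    _validate_effects(config, effects)
    events = generate_events(config)
    n = config.n_samples
    fs = config.fs
    root = np.random.SeedSequence([int(subject_seed), 0xE5E])
    region_seeds = root.spawn(config.n_regions)

    task_masks = {
        eff.task: _task_window_mask(events, eff.task, n)
        for eff in effects
    }

    data = np.empty((config.n_regions, n), dtype=np.float64)
    for g, label in enumerate(config.region_labels):
        rng = np.random.default_rng(region_seeds[g])
        x = _pink_noise(n, config.noise_exponent, rng)
        for band, f0 in BAND_FREQS.items():
            step = 2.0 * np.pi * f0 / fs
            base_jitter = PHASE_JITTER_FRAC * step
            amp = np.full(n, BAND_BASE_AMP[band])
            jitter_sd = np.full(n, base_jitter)
            for k, eff in enumerate(effects):
                if eff.band != band or label not in eff.regions:
                    continue
                a_gain, r_gain = eff.amplitude_gain, eff.regularity_gain
                if effect_scales is not None and k in effect_scales:
                    sa, sr = effect_scales[k]
                    a_gain = max(a_gain * sa, 1e-3)
                    r_gain = max(r_gain * sr, 1e-3)
                w = task_masks[eff.task]
                amp[w] *= a_gain
                jitter_sd[w] /= r_gain
            increments = step + jitter_sd * rng.normal(size=n)
            phase = rng.uniform(0.0, 2.0 * np.pi) + np.cumsum(increments)
            x = x + amp * np.cos(phase)
        data[g] = x
    return Recording(data, fs, tuple(config.region_labels),
                     subject=int(subject_seed)), events


def generate_cohort(
    config: SimulationConfig,
    effects: list[EffectSpec] | None = None,
) -> list[tuple[Recording, pd.DataFrame]]:
    """Simulate ``config.n_subjects`` recordings with derived seeds.

    Per-subject seeds are derived deterministically from
    ``config.master_seed``.  When ``config.effect_jitter_sd > 0`` each
    subject's effect gains are multiplied by lognormal-free Gaussian
    factors ``N(1, sd)`` (floored at 0.1) to emulate individual
    differences; a jitter SD of 0 makes all subjects share the
    configured effect magnitudes exactly.
    """
    if effects is None:
        effects = default_effects(config)
    _validate_effects(config, effects)
    master = np.random.SeedSequence(config.master_seed)
    subject_seeds = master.generate_state(config.n_subjects, dtype=np.uint32)
    jitter_rng = np.random.default_rng(master.spawn(1)[0])

    cohort = []
    for s in range(config.n_subjects):
        scales: dict[int, tuple[float, float]] | None = None
        if config.effect_jitter_sd > 0:
            scales = {}
            for k in range(len(effects)):
                sa, sr = jitter_rng.normal(1.0, config.effect_jitter_sd, 2)
                scales[k] = (max(sa, 0.1), max(sr, 0.1))
        rec, events = generate_recording(
            config, effects, int(subject_seeds[s]), effect_scales=scales
        )
        rec.subject = s
        cohort.append((rec, events))
    return cohort


def reduced_config(master_seed: int = 0, **overrides) -> SimulationConfig:
    """Desk-scale study conditions used by the default pipeline run.

    Three subjects, six regions spanning the occipital / central /
    prefrontal groups, the four decoded tasks, four trials per task and
    three sessions (the first is a practice session).  The layout keeps
    every structural rule of the full design (practice-session and
    first-trial exclusion, 12-fold intra-subject plan, 9 ML samples per
    task window, 126 crops per trial) at a fraction of the compute.
    """
    params = dict(
        n_subjects=3,
        n_regions=6,
        region_labels=(
            "lateraloccipital-lh", "pericalcarine-lh",
            "precentral-lh", "postcentral-lh",
            "superiorfrontal-lh", "rostralmiddlefrontal-lh",
        ),
        n_sessions=3,
        trials_per_task=4,
        tasks=("VP", "VI", "ME", "MI"),
        master_seed=master_seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def full_scale_config(master_seed: int = 0, **overrides) -> SimulationConfig:
    """Full-scale study conditions (8 subjects, 68 regions, 12 tasks).

    Provided for completeness; running the whole pipeline at this scale
    is slow on a single CPU.
    """
    params = dict(master_seed=master_seed)
    params.update(overrides)
    return SimulationConfig(**params)


__all__ = [
    "DEFAULT_TASKS", "DK_REGIONS", "REGION_GROUPS", "BAND_FREQS",
    "BAND_BASE_AMP", "PHASE_JITTER_FRAC",
    "SimulationConfig", "EffectSpec", "Recording",
    "default_effects", "generate_events", "generate_recording",
    "generate_cohort", "reduced_config", "full_scale_config",
]
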
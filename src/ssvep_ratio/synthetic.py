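"""Synthetic steady-state cohort generator with known ground truth.

Signal model per repetition (time in seconds, voltages in arbitrary uV):

    y(t) = a1(C) sin(2 pi f t + phi1 + e) + a2(C) sin(2 pi 2f t + phi2 + e')
           + pink(t) + white(t) + artifact(t)

where ``f`` is the flicker frequency and the harmonic amplitudes follow
the same Naka-Rushton contrast dependence the analysis later fits,

    a_h(C) = gain_h * C^n / (C^n + c50^n).

Each subject carries fixed random phases (phi1, phi2) and, optionally, a
log-normal responsiveness factor that multiplies both harmonics; each
repetition adds i.i.d. normal phase jitter (creating the gap between
coherent and scalar averaging), 1/f-shaped plus white Gaussian noise, and
with some probability a large boxcar transient mimicking a blink or
movement artifact.  Every generated quantity is recorded in a
:class:`GroundTruth` object so downstream stages have an exact
parameter-recovery surface.  Identical config + seed reproduces the
cohort bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .crf import naka_rushton
from .paradigms import ParadigmSpec
from .spectral import TrialRecording, extract_harmonic

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "pink_noise",
    "generate_trial",
    "generate_sweep_trial",
    "generate_cohort",
    "iter_subject_recordings",
    "estimate_coefficient_noise",
    "draw_subject_amplitudes",
    "generate_trait_cohort",
    "fly_cohort_config",
    "adult_cohort_config",
    "child_cohort_config",
]


class CohortConfig(BaseModel):
    """Ground-truth parameters of a simulated multi-group cohort.

    ``gain_1f`` / ``gain_2f`` are the saturating (r_max) amplitudes of the
    sustained and transient components per group, in uV; the contrast
    dependence uses ``crf_c50`` (%) and ``crf_exponent``.  Noise standard
    deviations are time-domain uV.  ``subject_gain_sd`` is the sigma of a
    unit-median log-normal responsiveness factor applied per subject to
    both harmonics (it therefore cancels in the frequency-ratio index);
    ``harmonic_gain_sd`` is an additional independent log-normal factor
    per subject *and harmonic*, modelling biological spread in the
    sustained/transient balance (this one does move the ratio index and
    sets the between-subject variance of the group statistics).
    """

    model_config = ConfigDict(frozen=True)

    group_labels: tuple[str, ...]
    n_subjects_per_group: int | tuple[int, ...] = 12
    gain_1f: tuple[float, ...]
    gain_2f: tuple[float, ...]
    crf_c50: float = 20.0
    crf_exponent: float = 2.0
    subject_gain_sd: float = 0.0
    harmonic_gain_sd: float = 0.0
    phase_jitter_sd: float = 0.0   # radians per repetition
    noise_white_sd: float = 0.0    # uV
    noise_pink_sd: float = 0.0     # uV
    artifact_rate: float = 0.0     # probability per repetition
    artifact_amplitude: float = 0.0  # uV
    artifact_duration: float = 0.2   # s
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        g = len(self.group_labels)
        if g < 1 or len(set(self.group_labels)) != g:
            raise ValueError("group labels must be unique and non-empty")
        if len(self.gain_1f) != g or len(self.gain_2f) != g:
            raise ValueError("per-group gains must match group_labels")
        if any(x < 0 for x in self.gain_1f + self.gain_2f):
            raise ValueError("gains must be non-negative")
        for name in ("subject_gain_sd", "harmonic_gain_sd",
                     "phase_jitter_sd", "noise_white_sd",
                     "noise_pink_sd", "artifact_amplitude", "artifact_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 <= self.artifact_rate <= 1.0):
            raise ValueError("artifact_rate must lie in [0, 1]")
        if self.crf_c50 <= 0 or self.crf_exponent <= 0:
            raise ValueError("crf_c50 and crf_exponent must be positive")
        ns = self.n_subjects
        if len(ns) != g or any(n < 1 for n in ns):
            raise ValueError("n_subjects_per_group must be positive per group")
        return self

    @property
    def n_subjects(self) -> tuple[int, ...]:
        n = self.n_subjects_per_group
        if isinstance(n, int):
            return (n,) * len(self.group_labels)
        return tuple(n)

    def amplitude(self, group: str, contrast: float, harmonic: int) -> float:
        """Ground-truth group-level amplitude a_h(C) in uV."""
        gi = self.group_labels.index(group)
        gain = (self.gain_1f, self.gain_2f)[harmonic - 1][gi]
        return gain * naka_rushton(contrast, 1.0, self.crf_c50, self.crf_exponent)


@dataclass
class GroundTruth:
    """Everything the generator drew, for parameter-recovery tests.

    ``group_amplitudes`` holds the noiseless group-level amplitude at each
    contrast and harmonic; per-subject amplitudes are these times the
    subject's responsiveness factor in ``subject_gain``.
    """

    group_amplitudes: pd.DataFrame
    subject_group: dict[str, str] = field(default_factory=dict)
    subject_gain: dict[str, float] = field(default_factory=dict)
    subject_harmonic_gain: dict[str, tuple[float, float]] = field(default_factory=dict)
    subject_phases: dict[str, tuple[float, float]] = field(default_factory=dict)
    artifacts: list[dict] = field(default_factory=list)

    def amplitude(self, group: str, contrast: float, harmonic: int) -> float:
        tbl = self.group_amplitudes
        row = tbl[(tbl["group"] == group)
                  & (np.isclose(tbl["contrast"], contrast))
                  & (tbl["harmonic"] == harmonic)]
        if row.empty:
            raise KeyError((group, contrast, harmonic))
        return float(row["amplitude"].iloc[0])

    def mean_ratio_index(self, group: str, conditions: Sequence[float]) -> float:
        """Closed-form ratio index from the noiseless group amplitudes.

        The subject responsiveness factor multiplies both harmonics and
        cancels, so the group-level value is exact for every subject in
        the absence of noise.
        """
        ratios = []
        for c in conditions:
            a1 = self.amplitude(group, c, 1)
            a2 = self.amplitude(group, c, 2)
            ratios.append((a1 - a2) / (a1 + a2))
        return float(np.mean(ratios))

    def to_dict(self) -> dict:
        return {
            "group_amplitudes": self.group_amplitudes.to_dict(orient="list"),
            "subject_group": self.subject_group,
            "subject_gain": self.subject_gain,
            "subject_harmonic_gain": {k: list(v) for k, v
                                      in self.subject_harmonic_gain.items()},
            "subject_phases": {k: list(v) for k, v in self.subject_phases.items()},
            "artifacts": self.artifacts,
        }


def pink_noise(n_samples: int, sampling_rate: float, sd: float,
               rng: np.random.Generator) -> np.ndarray:
    """1/f-shaped Gaussian noise with exact time-domain standard deviation.

    White Gaussian noise is shaped in the frequency domain by 1/sqrt(f)
    (zero weight at DC) and rescaled so the returned trace has standard
    deviation ``sd``.
    """
    if sd == 0.0:
        return np.zeros(n_samples)
    x = rng.standard_normal(n_samples)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    weights = np.zeros_like(freqs)
    weights[1:] = 1.0 / np.sqrt(freqs[1:])
    shaped = np.fft.irfft(spec * weights, n_samples)
    scale = shaped.std()
    return shaped * (sd / scale) if scale > 0 else shaped


def _noise_and_artifact(
    n: int,
    sampling_rate: float,
    noise_white_sd: float,
    noise_pink_sd: float,
    artifact_start: float | None,
    artifact_amplitude: float,
    artifact_duration: float,
    rng: np.random.Generator | None,
) -> np.ndarray:
    out = np.zeros(n)
    if (noise_white_sd > 0 or noise_pink_sd > 0) and rng is None:
        raise ValueError("noise requested but no rng supplied")
    if noise_white_sd > 0:
        out += noise_white_sd * rng.standard_normal(n)
    if noise_pink_sd > 0:
        out += pink_noise(n, sampling_rate, noise_pink_sd, rng)
    if artifact_start is not None and artifact_amplitude != 0.0:
        i0 = int(round(artifact_start * sampling_rate))
        i1 = min(n, i0 + int(round(artifact_duration * sampling_rate)))
        out[i0:i1] += artifact_amplitude
    return out


def generate_trial(
    paradigm: ParadigmSpec,
    contrast: float,
    amp_1f: float,
    amp_2f: float,
    phase_1f: float = 0.0,
    phase_2f: float = 0.0,
    *,
    noise_white_sd: float = 0.0,
    noise_pink_sd: float = 0.0,
    artifact_start: float | None = None,
    artifact_amplitude: float = 0.0,
    artifact_duration: float = 0.2,
    rng: np.random.Generator | None = None,
    subject_id: str = "s00",
    group: str = "g0",
    repetition: int = 0,
) -> TrialRecording:
    """One fixed-contrast repetition of the two-harmonic signal model.

    ``amp_1f`` / ``amp_2f`` are the final harmonic amplitudes of this
    trial (uV); callers that want contrast scaling apply the Naka-Rushton
    factor beforehand (as :func:`generate_cohort` does).  With zero noise
    the harmonic content at f and 2f is exactly (amp_1f, amp_2f).
    """
    if not (paradigm.contrast_levels[0] - 1e-9 <= contrast
            <= paradigm.contrast_levels[-1] + 1e-9):
        raise ValueError("contrast outside the paradigm's range")
    n = paradigm.n_samples
    t = np.arange(n) / paradigm.sampling_rate
    f = paradigm.stim_freq
    y = amp_1f * np.sin(2 * np.pi * f * t + phase_1f)
    y += amp_2f * np.sin(2 * np.pi * 2 * f * t + phase_2f)
    y += _noise_and_artifact(n, paradigm.sampling_rate, noise_white_sd,
                             noise_pink_sd, artifact_start, artifact_amplitude,
                             artifact_duration, rng)
    return TrialRecording(
        subject_id=subject_id, group=group, contrast=float(contrast),
        repetition=repetition, sampling_rate=paradigm.sampling_rate,
        stim_freq=f, samples=y, paradigm=paradigm.name,
    )


def generate_sweep_trial(
    paradigm: ParadigmSpec,
    bin_contrasts: Sequence[float],
    gain_1f: float,
    gain_2f: float,
    crf_c50: float,
    crf_exponent: float,
    phase_1f: float = 0.0,
    phase_2f: float = 0.0,
    *,
    noise_white_sd: float = 0.0,
    noise_pink_sd: float = 0.0,
    artifact_start: float | None = None,
    artifact_amplitude: float = 0.0,
    artifact_duration: float = 0.2,
    rng: np.random.Generator | None = None,
    subject_id: str = "s00",
    group: str = "g0",
    repetition: int = 0,
) -> TrialRecording:
    """One sweep repetition: contrast steps through ``bin_contrasts``.

    The harmonic amplitude envelope follows the Naka-Rushton response to
    the momentary bin contrast; the prelude holds the first bin's value
    and the postlude the last.  The sinusoidal carriers run on the global
    trial clock, so phase is continuous across bin boundaries.
    """
    if not paradigm.sweep:
        raise ValueError("paradigm is not a sweep design")
    n_bins = len(paradigm.contrast_levels)
    if len(bin_contrasts) != n_bins:
        raise ValueError(f"expected {n_bins} bin contrasts, got {len(bin_contrasts)}")
    n = paradigm.n_samples
    sr = paradigm.sampling_rate
    t = np.arange(n) / sr
    # momentary contrast: prelude -> first bin value, postlude -> last
    edges = paradigm.prelude_postlude + paradigm.sweep_bin_duration * np.arange(n_bins + 1)
    bin_idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, n_bins - 1)
    momentary = np.asarray(bin_contrasts, dtype=float)[bin_idx]
    env1 = gain_1f * naka_rushton(momentary, 1.0, crf_c50, crf_exponent)
    env2 = gain_2f * naka_rushton(momentary, 1.0, crf_c50, crf_exponent)
    f = paradigm.stim_freq
    y = env1 * np.sin(2 * np.pi * f * t + phase_1f)
    y += env2 * np.sin(2 * np.pi * 2 * f * t + phase_2f)
    y += _noise_and_artifact(n, sr, noise_white_sd, noise_pink_sd,
                             artifact_start, artifact_amplitude,
                             artifact_duration, rng)
    return TrialRecording(
        subject_id=subject_id, group=group, contrast=float("nan"),
        repetition=repetition, sampling_rate=sr, stim_freq=f, samples=y,
        paradigm=paradigm.name,
    )


def _ground_truth_table(config: CohortConfig, paradigm: ParadigmSpec) -> pd.DataFrame:
    rows = []
    for group in config.group_labels:
        for contrast in paradigm.contrast_levels:
            for harmonic in (1, 2):
                rows.append((group, float(contrast), harmonic,
                             config.amplitude(group, contrast, harmonic)))
    return pd.DataFrame(rows, columns=["group", "contrast", "harmonic", "amplitude"])


def iter_subject_recordings(
    config: CohortConfig,
    paradigm: ParadigmSpec,
    truth: GroundTruth | None = None,
) -> Iterator[tuple[str, list[TrialRecording]]]:
    """Yield ``(subject_id, recordings)`` one subject at a time.

    Streaming counterpart of :func:`generate_cohort`: raw traces for a
    subject can be processed and discarded before the next subject is
    drawn, keeping memory flat for large cohorts.  If ``truth`` is given
    it is filled in as subjects are generated.
    """
    ss = np.random.SeedSequence(config.seed)
    children = iter(ss.spawn(sum(config.n_subjects)))
    for gi, group in enumerate(config.group_labels):
        for si in range(config.n_subjects[gi]):
            subject = f"{group}_{si:02d}"
            rng = np.random.default_rng(next(children))
            gain = (rng.lognormal(mean=0.0, sigma=config.subject_gain_sd)
                    if config.subject_gain_sd > 0 else 1.0)
            gh1, gh2 = (rng.lognormal(0.0, config.harmonic_gain_sd, size=2)
                        if config.harmonic_gain_sd > 0 else (1.0, 1.0))
            phi1, phi2 = rng.uniform(0.0, 2 * np.pi, size=2)
            if truth is not None:
                truth.subject_group[subject] = group
                truth.subject_gain[subject] = float(gain)
                truth.subject_harmonic_gain[subject] = (float(gh1), float(gh2))
                truth.subject_phases[subject] = (float(phi1), float(phi2))
            recordings = []
            if paradigm.sweep:
                conditions: list[float | None] = [None] * paradigm.n_reps
                reps = range(paradigm.n_reps)
                trial_iter = [(None, r) for r in reps]
            else:
                trial_iter = [(c, r) for c in paradigm.contrast_levels
                              for r in range(paradigm.n_reps)]
            for contrast, rep in trial_iter:
                e1 = e2 = 0.0
                if config.phase_jitter_sd > 0:
                    e1, e2 = rng.normal(0.0, config.phase_jitter_sd, size=2)
                artifact_start = None
                if config.artifact_rate > 0 and rng.random() < config.artifact_rate:
                    artifact_start = rng.uniform(
                        0.0, paradigm.trial_duration - config.artifact_duration)
                    if truth is not None:
                        truth.artifacts.append({
                            "subject_id": subject,
                            "contrast": None if contrast is None else float(contrast),
                            "repetition": rep,
                            "start_s": float(artifact_start),
                            "duration_s": config.artifact_duration,
                        })
                common = dict(
                    noise_white_sd=config.noise_white_sd,
                    noise_pink_sd=config.noise_pink_sd,
                    artifact_start=artifact_start,
                    artifact_amplitude=config.artifact_amplitude,
                    artifact_duration=config.artifact_duration,
                    rng=rng, subject_id=subject, group=group, repetition=rep,
                )
                if paradigm.sweep:
                    rec = generate_sweep_trial(
                        paradigm, paradigm.contrast_levels,
                        gain * gh1 * config.gain_1f[gi],
                        gain * gh2 * config.gain_2f[gi],
                        config.crf_c50, config.crf_exponent,
                        phi1 + e1, phi2 + e2, **common)
                else:
                    rec = generate_trial(
                        paradigm, contrast,
                        gain * gh1 * config.amplitude(group, contrast, 1),
                        gain * gh2 * config.amplitude(group, contrast, 2),
                        phi1 + e1, phi2 + e2, **common)
                recordings.append(rec)
            yield subject, recordings


def generate_cohort(
    config: CohortConfig, paradigm: ParadigmSpec
) -> tuple[list[TrialRecording], GroundTruth]:
    """Generate a full cohort in memory with its ground truth."""
    truth = GroundTruth(group_amplitudes=_ground_truth_table(config, paradigm))
    recordings: list[TrialRecording] = []
    for _, recs in iter_subject_recordings(config, paradigm, truth):
        recordings.extend(recs)
    return recordings, truth


def estimate_coefficient_noise(
    paradigm: ParadigmSpec,
    noise_white_sd: float,
    noise_pink_sd: float,
    harmonic: int = 1,
    analysis_window: tuple[float, float] | None = None,
    n_sim: int = 200,
    seed: int = 12345,
) -> float:
    """Per-quadrature SD of the harmonic coefficient under noise alone.

    Monte-Carlo: noise-only trials are generated and projected at the
    harmonic frequency; the pooled standard deviation of the real and
    imaginary coefficient parts is returned.  This is the single-frequency
    noise floor that governs which contrasts rise above baseline.
    """
    rng = np.random.default_rng(seed)
    if analysis_window is None:
        analysis_window = paradigm.analysis_window
        if paradigm.sweep:
            analysis_window = (paradigm.prelude_postlude,
                               paradigm.prelude_postlude + paradigm.sweep_bin_duration)
    parts = []
    for _ in range(n_sim):
        y = _noise_and_artifact(paradigm.n_samples, paradigm.sampling_rate,
                                noise_white_sd, noise_pink_sd, None, 0.0, 0.0, rng)
        rec = TrialRecording("n", "n", 0.0, 0, paradigm.sampling_rate,
                             paradigm.stim_freq, y, paradigm.name)
        coef = extract_harmonic(rec, harmonic, analysis_window).coefficient
        parts.extend([coef.real, coef.imag])
    return float(np.std(parts, ddof=1))


def draw_subject_amplitudes(
    config: CohortConfig,
    paradigm: ParadigmSpec,
    rng: np.random.Generator,
    coef_noise_sd: float,
) -> pd.DataFrame:
    """Fast amplitude-domain cohort draw (no waveform synthesis).

    Draws, for every subject x contrast x harmonic, the coherent-average
    amplitude the full pipeline would produce: the true amplitude rotated
    by per-repetition phase jitter, averaged over repetitions, plus
    complex Gaussian coefficient noise with per-quadrature SD
    ``coef_noise_sd`` per repetition.  Used for large power/calibration
    simulations; its agreement with the waveform pipeline is checked in
    the test suite.
    """
    rows = []
    reps = paradigm.n_reps
    for gi, group in enumerate(config.group_labels):
        for si in range(config.n_subjects[gi]):
            subject = f"{group}_{si:02d}"
            gain = (rng.lognormal(0.0, config.subject_gain_sd)
                    if config.subject_gain_sd > 0 else 1.0)
            gh = (rng.lognormal(0.0, config.harmonic_gain_sd, size=2)
                  if config.harmonic_gain_sd > 0 else np.ones(2))
            for contrast in paradigm.contrast_levels:
                jitter = (rng.normal(0.0, config.phase_jitter_sd, size=(reps, 2))
                          if config.phase_jitter_sd > 0 else np.zeros((reps, 2)))
                for harmonic in (1, 2):
                    a = gain * gh[harmonic - 1] \
                        * config.amplitude(group, contrast, harmonic)
                    phasors = np.exp(1j * jitter[:, harmonic - 1])
                    noise = coef_noise_sd * (rng.standard_normal(reps)
                                             + 1j * rng.standard_normal(reps))
                    z = np.mean(a * phasors + noise)
                    rows.append((subject, group, float(contrast), harmonic, abs(z)))
    return pd.DataFrame(rows, columns=["subject_id", "group", "contrast",
                                       "harmonic", "amplitude"])


# ---------------------------------------------------------------------------
# study-condition presets
#
# Gains are saturating amplitudes in arbitrary uV; the experimental-group
# transient (2F) gain is reduced by a factor 0.6 in the mature presets.
# Noise SDs place the single-frequency noise floor between the contrast
# levels that should and should not rise above baseline (see
# docs/methods.md for the derivation).


def fly_cohort_config(age: str = "old", seed: int = 0,
                      n_per_group: int = 12) -> CohortConfig:
    """Three-genotype flicker-ERG cohort (control + two mutants).

    ``age="old"`` reduces only the mutants' transient (2F) gain;
    ``age="young"`` reduces both harmonics proportionally, leaving the
    frequency ratio unchanged.
    """
    if age == "old":
        gain_1f, gain_2f = (10.0, 10.0, 10.0), (5.0, 3.0, 3.0)
    elif age == "young":
        gain_1f, gain_2f = (10.0, 7.5, 7.5), (5.0, 3.75, 3.75)
    else:
        raise ValueError("age must be 'old' or 'young'")
    return CohortConfig(
        group_labels=("control", "mutant_a", "mutant_b"),
        n_subjects_per_group=n_per_group,
        gain_1f=gain_1f, gain_2f=gain_2f,
        crf_c50=20.0, crf_exponent=2.0,
        subject_gain_sd=0.3, harmonic_gain_sd=0.15, phase_jitter_sd=0.2,
        noise_white_sd=2.0, noise_pink_sd=2.0,
        artifact_rate=0.02, artifact_amplitude=100.0,
        seed=seed,
    )


def adult_cohort_config(n_per_group: int = 12, seed: int = 0,
                        effect_2f: float = 0.6) -> CohortConfig:
    """Two-group adult EEG cohort; experimental 2F gain x ``effect_2f``."""
    return CohortConfig(
        group_labels=("control", "experimental"),
        n_subjects_per_group=n_per_group,
        gain_1f=(4.0, 4.0), gain_2f=(2.0, 2.0 * effect_2f),
        crf_c50=25.0, crf_exponent=2.0,
        subject_gain_sd=0.3, harmonic_gain_sd=0.2, phase_jitter_sd=0.5,
        noise_white_sd=10.0, noise_pink_sd=15.0,
        artifact_rate=0.02, artifact_amplitude=150.0,
        seed=seed,
    )


def child_cohort_config(seed: int = 0,
                        n_per_group: tuple[int, int] = (17, 13)) -> CohortConfig:
    """Two-group child sweep cohort; experimental group has reduced
    sustained (1F) gain and a milder, unreliable 2F reduction."""
    return CohortConfig(
        group_labels=("control", "experimental"),
        n_subjects_per_group=n_per_group,
        gain_1f=(6.0, 4.2), gain_2f=(3.0, 2.4),
        crf_c50=15.0, crf_exponent=2.0,
        subject_gain_sd=0.3, harmonic_gain_sd=0.25, phase_jitter_sd=0.5,
        noise_white_sd=26.0, noise_pink_sd=13.0,
        artifact_rate=0.05, artifact_amplitude=200.0,
        seed=seed,
    )


def generate_trait_cohort(
    paradigm: ParadigmSpec,
    n_subjects: int = 100,
    seed: int = 0,
    *,
    gain_1f: float = 4.0,
    gain_2f: float = 2.0,
    trait_mean: float = 15.0,
    trait_sd: float = 7.0,
    trait_slope: float = 0.2,
    base: CohortConfig | None = None,
) -> tuple[pd.DataFrame, Iterator[tuple[str, list[TrialRecording]]]]:
    """Cohort with a continuous trait score driving the transient gain.

    Integer trait scores are drawn from N(trait_mean, trait_sd) clipped to
    [2, 42]; each subject's 2F gain is multiplied by
    ``clip(1 - trait_slope * z, 0.4, 1.6)`` where z is the score's
    standard score, so high-trait subjects have selectively reduced
    transient responses.  Returns the trait table (with a median-split
    group column) and a per-subject recording iterator.

    Noise and jitter parameters are taken from ``base`` (default:
    :func:`adult_cohort_config`).
    """
    if base is None:
        base = adult_cohort_config()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    scores = np.clip(np.round(rng.normal(trait_mean, trait_sd, n_subjects)), 2, 42)
    z = (scores - scores.mean()) / scores.std(ddof=1)
    mult = np.clip(1.0 - trait_slope * z, 0.4, 1.6)
    med = float(np.median(scores))
    group = np.where(scores <= med, "low", "high")
    traits = pd.DataFrame({
        "subject_id": [f"s{i:03d}" for i in range(n_subjects)],
        "score": scores,
        "gain_2f_multiplier": mult,
        "group": group,
    })

    def _iter():
        for i in range(n_subjects):
            cfg = CohortConfig(
                group_labels=(str(group[i]),),
                n_subjects_per_group=1,
                gain_1f=(gain_1f,), gain_2f=(gain_2f * mult[i],),
                crf_c50=base.crf_c50, crf_exponent=base.crf_exponent,
                subject_gain_sd=base.subject_gain_sd,
                harmonic_gain_sd=base.harmonic_gain_sd,
                phase_jitter_sd=base.phase_jitter_sd,
                noise_white_sd=base.noise_white_sd,
                noise_pink_sd=base.noise_pink_sd,
                artifact_rate=base.artifact_rate,
                artifact_amplitude=base.artifact_amplitude,
                seed=seed + 1 + i,
            )
            for _, recs in iter_subject_recordings(cfg, paradigm):
                for rec in recs:
                    rec.subject_id = f"s{i:03d}"
                yield f"s{i:03d}", recs

    return traits, _iter()
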
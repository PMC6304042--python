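"""Harmonic amplitude estimation and averaging for steady-state recordings.

The central operation is exact-frequency projection: the complex amplitude
at a harmonic of the flicker frequency is obtained by least-squares
regression of the voltage trace on a sine/cosine pair (plus an intercept)
at exactly that frequency.  When the analysis window holds an integer
number of stimulation cycles this equals the corresponding DFT bin; for
frequencies that are not bin-aligned (5.12 Hz in a 1 s window) it remains
unbiased, which a plain FFT bin read-out would not be.

Conventions
-----------
* A pure sinusoid ``A sin(2 pi f t + phi)`` yields a coefficient with
  modulus ``A`` and argument ``phi``.
* No taper is applied (rectangular window), the steady-state convention:
  the frequencies of interest are projected exactly, so spectral leakage
  from the stimulus line itself is not an issue.
* Coherent averaging is the vector (complex) mean across repetitions and
  suppresses non-phase-locked noise; scalar averaging across subjects uses
  amplitude moduli only, discarding phase.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .paradigms import get_paradigm

__all__ = [
    "TrialRecording",
    "HarmonicCoefficient",
    "SubjectConditionResponse",
    "bandpass_filter",
    "extract_harmonic",
    "bin_sweep",
    "reject_artifacts",
    "coherent_average",
    "scalar_average",
    "trial_harmonics_table",
    "coherent_average_table",
    "group_scalar_means",
]


@dataclass
class TrialRecording:
    """One repetition's voltage time series plus its condition metadata.

    ``contrast`` is the fixed Michelson contrast (%) of the trial, or NaN
    for sweep trials where contrast varies within the trial.  ``samples``
    is the voltage trace in microvolts.
    """

    subject_id: str
    group: str
    contrast: float
    repetition: int
    sampling_rate: float
    stim_freq: float
    samples: np.ndarray
    paradigm: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D voltage series (single channel)")
        if self.sampling_rate <= 4.0 * self.stim_freq:
            raise ValueError("sampling_rate must exceed 4 x stim_freq")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate


@dataclass(frozen=True)
class HarmonicCoefficient:
    """Complex amplitude at one harmonic of the stimulation frequency."""

    harmonic: int
    frequency: float
    coefficient: complex

    @property
    def amplitude(self) -> float:
        """Modulus: amplitude in the units of the input trace (uV)."""
        return abs(self.coefficient)

    @property
    def phase(self) -> float:
        """Argument in radians."""
        return float(np.angle(self.coefficient))


@dataclass(frozen=True)
class SubjectConditionResponse:
    """Coherently averaged response for one subject x contrast x harmonic."""

    subject_id: str
    group: str
    contrast: float
    harmonic: int
    amplitude: float
    phase: float
    n_reps_used: int


def bandpass_filter(recording: TrialRecording, low: float, high: float) -> TrialRecording:
    """Zero-phase band-pass (4th-order Butterworth, forward-backward).

    Passband harmonic amplitudes are preserved to within ~2%; out-of-band
    components (drift, line noise, high-frequency artifacts) are strongly
    attenuated.
    """
    nyq = recording.sampling_rate / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError("band edges must satisfy 0 < low < high < Nyquist")
    sos = _signal.butter(4, [low, high], btype="bandpass", output="sos",
                         fs=recording.sampling_rate)
    filtered = _signal.sosfiltfilt(sos, recording.samples)
    return dataclasses.replace(recording, samples=filtered)


def extract_harmonic(
    recording: TrialRecording,
    harmonic: int,
    analysis_window: tuple[float, float] | None = None,
) -> HarmonicCoefficient:
    """Complex amplitude at ``harmonic x stim_freq`` via exact projection.

    The trace restricted to ``analysis_window`` (seconds, default the full
    recording) is regressed onto sin/cos at the target frequency together
    with an intercept.  Time is referenced to the start of the recording,
    so phases of windows cut from the same trial share a common clock.
    """
    if harmonic < 1:
        raise ValueError("harmonic order must be >= 1")
    freq = harmonic * recording.stim_freq
    sr = recording.sampling_rate
    if freq >= sr / 2.0:
        raise ValueError("target frequency is at or above Nyquist")
    if analysis_window is None:
        analysis_window = (0.0, recording.duration)
    start, end = analysis_window
    if end - start < 1.0 / recording.stim_freq - 1e-12:
        raise ValueError("analysis window shorter than one stimulation cycle")
    i0 = int(round(start * sr))
    i1 = int(round(end * sr))
    if not (0 <= i0 < i1 <= len(recording.samples)):
        raise ValueError("analysis window outside the recording")
    seg = recording.samples[i0:i1]
    t = np.arange(i0, i1, dtype=float) / sr
    w = 2.0 * np.pi * freq * t
    design = np.column_stack([np.sin(w), np.cos(w), np.ones_like(w)])
    beta, *_ = np.linalg.lstsq(design, seg, rcond=None)
    return HarmonicCoefficient(
        harmonic=harmonic, frequency=freq, coefficient=complex(beta[0], beta[1])
    )


def bin_sweep(
    recording: TrialRecording,
    n_bins: int = 9,
    bin_duration: float = 1.0,
    skip: float = 1.5,
    bin_contrasts: Sequence[float] | None = None,
    harmonics: Sequence[int] = (1, 2),
) -> list[tuple[float, dict[int, HarmonicCoefficient]]]:
    """Per-bin harmonic coefficients for a contrast-sweep trial.

    The first ``skip`` seconds (prelude) are discarded, then ``n_bins``
    consecutive windows of ``bin_duration`` are each projected at the
    requested harmonics.  ``bin_contrasts`` defaults to the paradigm's
    contrast ladder looked up from ``recording.paradigm``.
    """
    if bin_contrasts is None:
        bin_contrasts = get_paradigm(recording.paradigm).contrast_levels
    if len(bin_contrasts) != n_bins:
        raise ValueError(f"expected {n_bins} bin contrasts, got {len(bin_contrasts)}")
    if skip + n_bins * bin_duration > recording.duration + 1e-9:
        raise ValueError("bin bounds exceed the recording")
    out = []
    for i, contrast in enumerate(bin_contrasts):
        window = (skip + i * bin_duration, skip + (i + 1) * bin_duration)
        coeffs = {h: extract_harmonic(recording, h, window) for h in harmonics}
        out.append((float(contrast), coeffs))
    return out


def reject_artifacts(
    trials: pd.DataFrame,
    threshold_sd: float = 4.0,
    cell_cols: Sequence[str] = ("group", "contrast", "harmonic"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass amplitude-outlier rejection within group-level cells.

    For each cell (by default group x contrast x harmonic) the mean and SD
    (n-1 denominator) of the per-repetition amplitudes are computed over
    all repetitions in the cell; a repetition is rejected iff its amplitude
    deviates from the cell mean by more than ``threshold_sd`` SDs.  The
    rule is applied once, without recomputing the statistics after
    removal.  Cells with fewer than 3 repetitions, or with zero SD, reject
    nothing (the former with a warning).

    Returns ``(kept, rejected)``; the rejected frame gains a
    ``deviation_sd`` provenance column.
    """
    if "amplitude" not in trials.columns:
        raise ValueError("trials frame must have an 'amplitude' column")
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    reject_mask = np.zeros(len(trials), dtype=bool)
    deviation = np.full(len(trials), np.nan)
    for key, idx in trials.groupby(list(cell_cols), observed=True, sort=False).indices.items():
        amps = trials["amplitude"].to_numpy()[idx]
        if len(amps) < 3:
            warnings.warn(
                f"cell {key} has {len(amps)} < 3 repetitions; no rejection applied",
                stacklevel=2,
            )
            continue
        mean = amps.mean()
        sd = amps.std(ddof=1)
        if sd == 0.0:
            continue
        dev = np.abs(amps - mean) / sd
        mask = dev > threshold_sd
        reject_mask[idx] = mask
        deviation[idx] = dev
    rejected = trials.loc[reject_mask].copy()
    rejected["deviation_sd"] = deviation[reject_mask]
    kept = trials.loc[~reject_mask].copy()
    return kept, rejected


def coherent_average(
    coefficients: Sequence[HarmonicCoefficient],
    subject_id: str = "",
    group: str = "",
    contrast: float = float("nan"),
) -> SubjectConditionResponse:
    """Vector mean of complex coefficients across repetitions.

    Amplitude is the modulus of the complex mean and phase its argument;
    phase-inconsistent repetitions therefore cancel rather than add.
    """
    if len(coefficients) == 0:
        raise ValueError("need at least one coefficient")
    freqs = {c.frequency for c in coefficients}
    orders = {c.harmonic for c in coefficients}
    if len(freqs) != 1 or len(orders) != 1:
        raise ValueError("coefficients mix frequencies or harmonic orders")
    mean = np.mean([c.coefficient for c in coefficients])
    return SubjectConditionResponse(
        subject_id=subject_id,
        group=group,
        contrast=contrast,
        harmonic=coefficients[0].harmonic,
        amplitude=float(abs(mean)),
        phase=float(np.angle(mean)),
        n_reps_used=len(coefficients),
    )


def scalar_average(responses: Sequence) -> tuple[float, float]:
    """Across-subject mean amplitude and its standard error.

    Accepts ``SubjectConditionResponse`` objects or plain amplitudes;
    phase is discarded.  Requires at least two subjects.
    """
    amps = np.asarray(
        [r.amplitude if isinstance(r, SubjectConditionResponse) else float(r)
         for r in responses]
    )
    if len(amps) < 2:
        raise ValueError("need at least two subjects for a group mean")
    return float(amps.mean()), float(amps.std(ddof=1) / np.sqrt(len(amps)))


# ---------------------------------------------------------------------------
# table-level helpers used by the pipeline


def trial_harmonics_table(
    recordings: Iterable[TrialRecording],
    harmonics: Sequence[int] = (1, 2),
    analysis_window: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-repetition harmonic coefficients as a long-format table.

    Fixed-contrast recordings yield one row per harmonic; sweep recordings
    (``contrast`` NaN, paradigm flagged as sweep) are binned first and
    yield one row per bin x harmonic.  Columns: subject_id, group,
    contrast, repetition, harmonic, frequency, coef (complex), amplitude,
    phase.
    """
    rows = []
    for rec in recordings:
        if np.isnan(rec.contrast):
            paradigm = get_paradigm(rec.paradigm)
            binned = bin_sweep(
                rec,
                n_bins=len(paradigm.contrast_levels),
                bin_duration=paradigm.sweep_bin_duration,
                skip=paradigm.prelude_postlude,
                bin_contrasts=paradigm.contrast_levels,
                harmonics=harmonics,
            )
            for contrast, coeffs in binned:
                for h, c in coeffs.items():
                    rows.append((rec.subject_id, rec.group, contrast,
                                 rec.repetition, h, c.frequency,
                                 c.coefficient, c.amplitude, c.phase))
        else:
            for h in harmonics:
                c = extract_harmonic(rec, h, analysis_window)
                rows.append((rec.subject_id, rec.group, rec.contrast,
                             rec.repetition, h, c.frequency,
                             c.coefficient, c.amplitude, c.phase))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "group", "contrast", "repetition", "harmonic",
                 "frequency", "coef", "amplitude", "phase"],
    )


def coherent_average_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Coherent (vector) average per subject x contrast x harmonic.

    Expects the output of :func:`trial_harmonics_table` (complex ``coef``
    column).  Returns one row per subject x contrast x harmonic with the
    modulus/argument of the complex mean and the repetition count used.
    """
    grouped = trials.groupby(["subject_id", "group", "contrast", "harmonic"],
                             observed=True, sort=True)
    out = grouped.agg(coef=("coef", "mean"), n_reps_used=("coef", "size")).reset_index()
    out["amplitude"] = np.abs(out["coef"])
    out["phase"] = np.angle(out["coef"])
    return out.drop(columns="coef")


def group_scalar_means(responses: pd.DataFrame) -> pd.DataFrame:
    """Scalar group means (phase discarded) with SEM per group x contrast x harmonic."""
    grouped = responses.groupby(["group", "contrast", "harmonic"],
                                observed=True, sort=True)["amplitude"]
    out = grouped.agg(amplitude="mean",
                      sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)),
                      n_subjects="size").reset_index()
    return out
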
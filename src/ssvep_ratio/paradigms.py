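"""Stimulation paradigms for steady-state visual electrophysiology.

A paradigm bundles the stimulus and acquisition parameters the rest of the
pipeline needs: flicker frequency, sampling rate, trial structure and the
ladder of Michelson contrasts shown to the observer.  Three presets model
common laboratory designs:

``fly``
    Flicker electroretinogram (ERG) from the insect eye: 12 Hz flicker,
    seven contrast levels spaced linearly from 0 to 69%, five repetitions
    of 11 s trials.
``adult``
    Adult scalp EEG over visual cortex (electrode Oz): 7 Hz on/off flicker
    of a grating, contrasts 0% plus 2-64% in octave steps, eight
    repetitions of 11 s trials, 1 kHz digitisation.
``child_sweep``
    Sweep design for children: contrast ramps upward within each 12 s
    trial through nine 1 s bins (0-50% in log steps) flanked by a prelude
    and a postlude at the sweep endpoints; 432 Hz digitisation, ten
    repetitions.

The first (1F) and second (2F) harmonics of the flicker frequency index
sustained and transient response components respectively; their
frequencies follow directly from ``stim_freq``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ParadigmSpec",
    "michelson_contrast",
    "fly_paradigm",
    "adult_paradigm",
    "child_sweep_paradigm",
    "get_paradigm",
    "PARADIGM_NAMES",
]


def michelson_contrast(l_max: float, l_min: float) -> float:
    """Michelson contrast in percent, ``100 (Lmax - Lmin) / (Lmax + Lmin)``.

    Parameters are luminances in cd/m^2 with ``l_max >= l_min >= 0`` and
    ``l_max > 0``.  Returns a value in [0, 100].
    """
    if not (math.isfinite(l_max) and math.isfinite(l_min)):
        raise ValueError("luminances must be finite")
    if l_min < 0 or l_max <= 0:
        raise ValueError("luminances must be non-negative with l_max > 0")
    if l_max < l_min:
        raise ValueError("l_max must be >= l_min")
    return 100.0 * (l_max - l_min) / (l_max + l_min)


@dataclass(frozen=True)
class ParadigmSpec:
    """Stimulus/acquisition parameters for one experimental design.

    ``contrast_levels`` are Michelson contrasts in percent, sorted
    ascending.  For sweep designs they are the per-bin contrasts of the
    within-trial ramp rather than separate conditions.
    """

    name: str
    stim_freq: float            # Hz
    sampling_rate: float        # Hz
    trial_duration: float       # s
    n_reps: int
    contrast_levels: tuple[float, ...]
    sweep: bool = False
    sweep_bin_duration: float | None = None   # s, sweep only
    prelude_postlude: float | None = None     # s, sweep only

    def __post_init__(self) -> None:
        if self.stim_freq <= 0:
            raise ValueError("stim_freq must be positive")
        # Nyquist for the second harmonic, with headroom
        if self.sampling_rate <= 4.0 * self.stim_freq:
            raise ValueError("sampling_rate must exceed 4 x stim_freq")
        if self.trial_duration <= 0 or self.n_reps < 1:
            raise ValueError("trial_duration and n_reps must be positive")
        levels = tuple(float(c) for c in self.contrast_levels)
        if any(not (0.0 <= c <= 100.0) for c in levels):
            raise ValueError("contrast levels must lie in [0, 100]")
        if list(levels) != sorted(levels):
            raise ValueError("contrast levels must be sorted ascending")
        if self.sweep:
            if self.sweep_bin_duration is None or self.prelude_postlude is None:
                raise ValueError("sweep paradigms need bin duration and prelude")
            body = self.prelude_postlude * 2 + len(levels) * self.sweep_bin_duration
            if body - self.trial_duration > 1e-9:
                raise ValueError("sweep bins + prelude/postlude exceed trial duration")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration * self.sampling_rate))

    def harmonic_frequency(self, harmonic: int) -> float:
        """Frequency in Hz of the given harmonic order (1F, 2F, ...)."""
        if harmonic < 1:
            raise ValueError("harmonic order must be >= 1")
        return harmonic * self.stim_freq

    @property
    def analysis_window(self) -> tuple[float, float]:
        """Default analysis window in seconds.

        Fixed-contrast trials discard the first second (onset transient);
        sweep trials use the central sweep portion between prelude and
        postlude.
        """
        if self.sweep:
            assert self.prelude_postlude is not None
            start = self.prelude_postlude
            return (start, start + len(self.contrast_levels) * self.sweep_bin_duration)
        return (1.0, self.trial_duration)


def fly_paradigm() -> ParadigmSpec:
    """Insect flicker-ERG preset: 12 Hz, 0-69% in seven linear steps."""
    levels = tuple(round(69.0 * i / 6.0, 4) for i in range(7))  # step 11.5%
    return ParadigmSpec(
        name="fly",
        stim_freq=12.0,
        sampling_rate=1000.0,
        trial_duration=11.0,
        n_reps=5,
        contrast_levels=levels,
    )


def adult_paradigm() -> ParadigmSpec:
    """Adult EEG preset: 7 Hz flicker, 0% plus 2-64% in octave steps."""
    return ParadigmSpec(
        name="adult",
        stim_freq=7.0,
        sampling_rate=1000.0,
        trial_duration=11.0,
        n_reps=8,
        contrast_levels=(0.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0),
    )


# Log ladder for the child sweep: top bin 50%, nine bins total with bin 1 a
# 0% blank; spacing anchored so the fifth-from-top bin is 8.5%.
_SWEEP_RATIO = (50.0 / 8.5) ** 0.25


def child_sweep_paradigm() -> ParadigmSpec:
    """Child sweep-EEG preset: 5.12 Hz flicker, nine 1 s bins 0-50%."""
    levels = (0.0,) + tuple(round(8.5 * _SWEEP_RATIO**k, 4) for k in range(-3, 5))
    return ParadigmSpec(
        name="child_sweep",
        stim_freq=5.12,
        sampling_rate=432.0,
        trial_duration=12.0,
        n_reps=10,
        contrast_levels=levels,
        sweep=True,
        sweep_bin_duration=1.0,
        prelude_postlude=1.5,
    )


_PRESETS = {
    "fly": fly_paradigm,
    "adult": adult_paradigm,
    "child_sweep": child_sweep_paradigm,
}

PARADIGM_NAMES = tuple(_PRESETS)


def get_paradigm(name: str) -> ParadigmSpec:
    """Return a preset paradigm by name (``fly``, ``adult``, ``child_sweep``)."""
    try:
        return _PRESETS[name]()
    except KeyError:
        raise KeyError(
            f"unknown paradigm {name!r}; available: {', '.join(_PRESETS)}"
        ) from None
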
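"""Raw voltage epochs -> trial-wise response magnitudes.

Multiunit activity recorded during song playback is analyzed as an analog
response magnitude rather than as sorted spikes: for each stimulus
presentation the RMS voltage in the stimulus window, minus the RMS in a
preceding silent baseline window, gives one nonnegative magnitude per trial.
These magnitudes, ordered by within-stimulus repetition index, form the
:class:`ResponseSeries` the adaptation analysis consumes.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np

from .exceptions import EpochWindowError, SeriesValidationError

__all__ = ["Epoch", "ResponseSeries", "extract_magnitude", "build_series"]

#: Label fields identifying one recording site x stimulus, in canonical order.
SERIES_LABELS = ("bird", "group", "hemisphere", "region", "site", "set", "stimulus", "stim_class")


@dataclass(frozen=True)
class Epoch:
    """One trial of raw voltage around a stimulus presentation.

    Parameters
    ----------
    samples : ndarray
        Voltage trace, arbitrary units.
    sampling_rate : float
        Samples per second (the recordings this models were digitized at 25 kHz).
    stim_window, baseline_window : (float, float)
        Half-open intervals ``[start, stop)`` in seconds relative to epoch
        start. Must be non-overlapping, of positive duration, and inside the
        epoch.
    """

    samples: np.ndarray
    sampling_rate: float
    stim_window: tuple[float, float]
    baseline_window: tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 1:
            raise EpochWindowError("samples must be one-dimensional")
        if not self.sampling_rate > 0:
            raise EpochWindowError(f"sampling_rate must be positive, got {self.sampling_rate}")
        dur = self.samples.size / self.sampling_rate
        for name, (start, stop) in (("stim_window", self.stim_window),
                                    ("baseline_window", self.baseline_window)):
            if not stop > start:
                raise EpochWindowError(f"{name} has non-positive duration: {start}..{stop}")
            if start < 0 or stop > dur + 1e-12:
                raise EpochWindowError(f"{name} {start}..{stop} outside epoch of {dur:.6g} s")
        a, b = sorted([self.stim_window, self.baseline_window])
        if b[0] < a[1]:
            raise EpochWindowError("stim_window and baseline_window overlap")

    def _slice(self, window: tuple[float, float]) -> np.ndarray:
        i0 = int(round(window[0] * self.sampling_rate))
        i1 = int(round(window[1] * self.sampling_rate))
        if i1 <= i0:
            raise EpochWindowError(f"window {window} contains no samples")
        return self.samples[i0:i1]


def _rms(x: np.ndarray) -> float:
    # RMS about the window mean: bandpassed (0.5-5 kHz) multiunit traces are
    # zero-mean, and demeaning makes the statistic exactly DC-invariant.
    x = x - x.mean()
    return float(np.sqrt(np.mean(np.square(x))))


def extract_magnitude(epoch: Epoch) -> float:
    """Baseline-subtracted RMS response magnitude of one epoch.

    Returns ``max(0, RMS(stim window) - RMS(baseline window))`` with each
    window's RMS taken about its own mean, so the result is invariant to a
    DC offset common to both windows and scales linearly with input gain.
    The clamp at zero keeps downstream normalization defined. Units follow
    the input voltage.
    """
    return max(0.0, _rms(epoch._slice(epoch.stim_window)) - _rms(epoch._slice(epoch.baseline_window)))


@dataclass(frozen=True)
class ResponseSeries:
    """Ordered response magnitudes of one site to one stimulus.

    ``magnitudes[i]`` is the response on the (i+1)-th presentation of this
    stimulus (1-based trial index, no gaps); typically 25 trials. Magnitudes
    are nonnegative.
    """

    bird: str
    group: str
    hemisphere: str
    region: str
    site: int
    set: int
    stimulus: str
    stim_class: str
    magnitudes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.magnitudes, dtype=float)
        object.__setattr__(self, "magnitudes", m)
        if m.ndim != 1 or m.size < 1:
            raise SeriesValidationError("magnitudes must be a non-empty 1-d array")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise SeriesValidationError("magnitudes must be finite and nonnegative")

    @property
    def labels(self) -> dict:
        return {k: getattr(self, k) for k in SERIES_LABELS}

    @property
    def n_trials(self) -> int:
        return int(self.magnitudes.size)


def build_series(records: Iterable[tuple[Mapping, int, "Epoch | float"]]) -> list[ResponseSeries]:
    """Assemble :class:`ResponseSeries` from per-trial epochs or magnitudes.

    Parameters
    ----------
    records
        Iterable of ``(labels, trial, epoch_or_magnitude)`` where ``labels``
        maps the fields in :data:`SERIES_LABELS` to values, ``trial`` is the
        1-based within-stimulus repetition index (the presentation order of a
        session is shuffled across stimuli; the per-stimulus repetition index
        is what matters here), and the payload is either an :class:`Epoch`
        (magnitude extracted via :func:`extract_magnitude`) or a ready scalar.

    Returns
    -------
    list of ResponseSeries, one per distinct label tuple, magnitudes ordered
    by trial 1..T with every trial present exactly once.

    Raises
    ------
    SeriesValidationError
        If any series has a missing or duplicated trial; the message lists
        the offending (labels, trial) keys.
    """
    groups: dict[tuple, dict[int, float]] = {}
    for labels, trial, payload in records:
        key = tuple(labels[k] for k in SERIES_LABELS)
        mag = extract_magnitude(payload) if isinstance(payload, Epoch) else float(payload)
        trials = groups.setdefault(key, {})
        if trial in trials:
            raise SeriesValidationError(f"duplicate trial {trial} for series {dict(zip(SERIES_LABELS, key))}")
        trials[int(trial)] = mag

    out = []
    problems = []
    for key, trials in groups.items():
        n = max(trials)
        missing = sorted(set(range(1, n + 1)) - set(trials))
        if missing:
            problems.append(f"{dict(zip(SERIES_LABELS, key))}: missing trials {missing}")
            continue
        mags = np.array([trials[t] for t in range(1, n + 1)])
        out.append(ResponseSeries(**dict(zip(SERIES_LABELS, key)), magnitudes=mags))
    if problems:
        raise SeriesValidationError("incomplete series: " + "; ".join(problems))
    return out
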
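"""Pupil / locomotion trace preprocessing.

Implements the trial-reduction chain used for tail-shock ladder sessions:
blink-artifact removal on the pupil channel, Savitzky-Golay smoothing,
epoching around stimulus onsets, baseline normalization against a 1 s
prestimulus window, scoring of each trial as the mean signal in the
1-2 s post-onset window, and per-animal subtraction of the 0 uA condition.

Conventions (fixed so sample counts are unambiguous):

* the sample at stimulus onset belongs to the post-stimulus segment;
* the scoring window is half-open, ``1 <= t < 2`` s post-onset;
* the Savitzky-Golay window in samples is ``round(window_s * rate)``,
  incremented to the next odd integer when even;
* blink flags are raised on *both* endpoints of a super-threshold first
  difference, and a degenerate derivative track (max == min) yields no flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import medfilt, savgol_filter

from .exceptions import (
    CleaningError,
    ConfigurationError,
    EpochingError,
    InputError,
    NormalizationError,
)

PUPIL = "pupil"
LOCOMOTION = "locomotion"


@dataclass
class RawTrace:
    """Uniformly sampled pupil-area or locomotion signal."""

    values: np.ndarray
    sampling_rate: float
    channel: str = PUPIL

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.values.ndim != 1 or self.values.size < 2:
            raise InputError("trace must be a 1-D signal with at least 2 samples")
        if self.channel not in (PUPIL, LOCOMOTION):
            raise ConfigurationError(f"unknown channel {self.channel!r}")

    @property
    def duration(self) -> float:
        return self.values.size / self.sampling_rate


@dataclass(frozen=True)
class StimulusEvent:
    """A single tail-shock delivery."""

    onset: float  # s from trace start
    intensity: float  # uA

    def __post_init__(self):
        if self.intensity < 0:
            raise ConfigurationError("intensity must be nonnegative")


@dataclass
class TrialMatrix:
    """Epoch-by-time array of responses aligned on stimulus onset."""

    epochs: np.ndarray  # (n_trials, n_samples)
    time: np.ndarray  # s relative to onset; onset sample at t == 0
    intensities: np.ndarray  # uA, one per trial
    sampling_rate: float
    normalization: str | None = None
    excluded: list = field(default_factory=list)  # (event_index, reason)

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    def prestim_mask(self) -> np.ndarray:
        return self.time < 0


def remove_blinks(
    trace: RawTrace,
    derivative_threshold: float = 0.2,
    median_window: float = 0.25,
) -> RawTrace:
    """Remove blink artifacts by the derivative-threshold rule.

    The absolute first difference of the trace is median filtered
    (``median_window`` seconds, default 5 samples at 20 Hz), min-max
    normalized to [0, 1], and samples adjacent to differences exceeding
    ``derivative_threshold`` are replaced by linear interpolation between
    the nearest valid neighbours (nearest-value extrapolation at the edges).
    """
    if trace.values.size < 3:
        raise InputError("trace too short for blink removal")
    if not 0 < derivative_threshold:
        raise ConfigurationError("derivative_threshold must be positive")
    x = trace.values
    deriv = np.abs(np.diff(x))
    k = int(round(median_window * trace.sampling_rate))
    k = max(1, k + (k % 2 == 0))
    if k > deriv.size:  # short traces: largest odd kernel that fits
        k = deriv.size - (deriv.size % 2 == 0)
    filtered = medfilt(deriv, kernel_size=k) if k > 1 else deriv
    lo, hi = filtered.min(), filtered.max()
    if hi > lo:
        norm = (filtered - lo) / (hi - lo)
    else:  # constant-slope trace: contains no blink signature
        norm = np.zeros_like(filtered)
    flags = np.zeros(x.size, dtype=bool)
    over = np.flatnonzero(norm > derivative_threshold)
    flags[over] = True
    flags[over + 1] = True
    if flags.all():
        raise CleaningError("every sample flagged; trace unusable")
    if not flags.any():
        return replace(trace, values=x.copy())
    idx = np.arange(x.size)
    cleaned = x.copy()
    cleaned[flags] = np.interp(idx[flags], idx[~flags], x[~flags])
    return replace(trace, values=cleaned)


def smooth_savgol(trace: RawTrace, poly_order: int = 6, window: float = 1.5) -> RawTrace:
    """Savitzky-Golay smoothing (defaults: order 6, 1.5 s window)."""
    wl = int(round(window * trace.sampling_rate))
    if wl % 2 == 0:
        wl += 1
    if wl <= poly_order:
        raise ConfigurationError(
            f"window of {wl} samples must exceed polynomial order {poly_order}"
        )
    if trace.values.size <= wl:
        raise ConfigurationError("trace shorter than the smoothing window")
    return replace(trace, values=savgol_filter(trace.values, wl, poly_order))


def savgol_window_samples(window: float, sampling_rate: float) -> int:
    """The odd window length in samples for a window given in seconds."""
    wl = int(round(window * sampling_rate))
    return wl + (wl % 2 == 0)


def epoch_trials(
    trace: RawTrace,
    events,
    pre: float = 1.0,
    post: float = 4.0,
    exclusions: dict[int, str] | None = None,
) -> TrialMatrix:
    """Cut one epoch per stimulus event, aligned on the onset sample.

    ``exclusions`` maps event indices to textual reasons (e.g. saccades or
    detection failures identified upstream); excluded trials are dropped
    from the matrix and logged in ``TrialMatrix.excluded``.
    """
    fs = trace.sampling_rate
    n_pre = int(round(pre * fs))
    n_post = int(round(post * fs))
    exclusions = exclusions or {}
    epochs, intensities, bad = [], [], []
    for i, ev in enumerate(events):
        onset_idx = int(round(ev.onset * fs))
        if onset_idx - n_pre < 0 or onset_idx + n_post > trace.values.size:
            bad.append(ev)
            continue
        if i in exclusions:
            continue
        epochs.append(trace.values[onset_idx - n_pre : onset_idx + n_post])
        intensities.append(ev.intensity)
    if bad:
        raise EpochingError(
            f"{len(bad)} event(s) fall outside the trace", offending_events=bad
        )
    time = (np.arange(n_pre + n_post) - n_pre) / fs
    excluded = [(i, reason) for i, reason in sorted(exclusions.items())]
    return TrialMatrix(
        epochs=np.array(epochs, dtype=float).reshape(len(epochs), n_pre + n_post),
        time=time,
        intensities=np.asarray(intensities, dtype=float),
        sampling_rate=fs,
        excluded=excluded,
    )


def normalize_epochs(trials: TrialMatrix, mode: str = "zscore") -> TrialMatrix:
    """Normalize each epoch against its 1 s (full pre-extent) prestimulus window.

    ``zscore`` divides by the prestimulus standard deviation (population sd);
    ``subtract_mean`` only removes the prestimulus mean, preserving scale.
    """
    if mode not in ("zscore", "subtract_mean"):
        raise ConfigurationError(f"unknown normalization mode {mode!r}")
    pre = trials.prestim_mask()
    if pre.sum() < 1:
        raise InputError("no prestimulus samples present")
    base = trials.epochs[:, pre]
    mean = base.mean(axis=1, keepdims=True)
    if mode == "zscore":
        sd = base.std(axis=1, keepdims=True)
        degenerate = np.flatnonzero(sd[:, 0] == 0)
        if degenerate.size:
            raise NormalizationError(
                f"zero prestimulus sd in epoch(s) {degenerate.tolist()}; "
                "z-scoring undefined"
            )
        normalized = (trials.epochs - mean) / sd
    else:
        normalized = trials.epochs - mean
    return replace(trials, epochs=normalized, normalization=mode)


def extract_responses(trials: TrialMatrix, window=(1.0, 2.0)) -> np.ndarray:
    """Per-trial scalar response: mean signal in the half-open window [lo, hi) s."""
    lo, hi = window
    if lo >= hi:
        raise ConfigurationError("window must satisfy lo < hi")
    mask = (trials.time >= lo) & (trials.time < hi)
    if trials.time[-1] + 1.0 / trials.sampling_rate < hi or not mask.any():
        raise ConfigurationError("scoring window extends beyond the epoch")
    return trials.epochs[:, mask].mean(axis=1)


def response_table(trials: TrialMatrix, window=(1.0, 2.0)) -> pd.DataFrame:
    """Per-intensity mean response for one animal's session."""
    responses = extract_responses(trials, window)
    return (
        pd.DataFrame({"intensity_uA": trials.intensities, "response": responses})
        .groupby("intensity_uA", as_index=False)["response"]
        .mean()
    )


def subtract_zero_condition(responses: pd.DataFrame) -> pd.DataFrame:
    """Subtract each animal's 0 uA mean response from its other conditions.

    ``responses`` has columns ``animal_id`` (optional for a single animal),
    ``intensity_uA`` and ``response``.  The 0 uA row becomes exactly 0.
    """
    df = responses.copy()
    if "animal_id" not in df.columns:
        df["animal_id"] = "animal0"
    out = []
    for animal, sub in df.groupby("animal_id", sort=False):
        zero = sub.loc[sub["intensity_uA"] == 0, "response"]
        if zero.empty:
            raise InputError(f"animal {animal!r} has no 0 uA condition")
        sub = sub.copy()
        sub["response"] = sub["response"] - zero.mean()
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def session_responses(
    trace: RawTrace,
    events,
    pre: float = 1.0,
    post: float = 4.0,
    window=(1.0, 2.0),
    normalization: str | None = None,
    exclusions: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Full single-session chain from raw trace to zero-referenced responses.

    Pupil traces get blink removal and (by default) prestimulus z-scoring;
    locomotion skips blink removal and uses scale-preserving baseline
    subtraction.  ``normalization`` overrides the channel default — e.g.
    calibration studies on deterministic synthetic sessions must use
    ``"subtract_mean"``, because a constant prestimulus baseline makes the
    z-score denominator zero (an error by contract).
    """
    if normalization is None:
        normalization = "zscore" if trace.channel == PUPIL else "subtract_mean"
    if trace.channel == PUPIL:
        trace = remove_blinks(trace)
    trace = smooth_savgol(trace)
    trials = epoch_trials(trace, events, pre=pre, post=post, exclusions=exclusions)
    trials = normalize_epochs(trials, mode=normalization)
    table = response_table(trials, window=window)
    return subtract_zero_condition(table)
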
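"""Visually evoked calcium-response analysis.

Converts raw cell-body / background fluorescence pairs into ΔF/F, estimates a
robust noise floor from non-stimulus samples, scores each stimulus repetition
as a positive response (amplitude at least twice the noise floor, i.e.
SNR ≥ 2), classifies cells as light-sensitive (LS, ≥4/5 positive repetitions),
non-light-sensitive (NS, ≤1/5) or excluded (2–3/5), and computes the
response-magnitude statistic (mean over repetitions of post-stimulus peak
minus pre-stimulus baseline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Classification rule: >= LS_MIN_POSITIVE positives -> LS, <= NS_MAX_POSITIVE -> NS,
# anything in between is excluded from the cohort.
LS_MIN_POSITIVE = 4
NS_MAX_POSITIVE = 1
#: event threshold as a multiple of the noise floor (inclusive comparison)
SNR_THRESHOLD = 2.0
#: scale factor turning a median absolute deviation into a Gaussian-consistent SD
MAD_SCALE = 1.4826


class DegenerateBaselineError(ValueError):
    """Raised when the pre-stimulus baseline F0 is not positive."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing of the repeated visual stimulation.

    The default protocol is a 5-s drifting grating repeated 5 times with a
    15-s inter-stimulus interval, imaged at 30 frames/s.  ``pre_baseline_window_s``
    is the (start, end) of the pre-stimulus window expressed in seconds *before*
    each onset; the default (2.0, 4.0) means samples 4 s to 2 s before onset.
    """

    onsets_s: tuple[float, ...]
    stim_duration_s: float = 5.0
    isi_s: float = 15.0
    frame_rate_hz: float = 30.0
    pre_baseline_window_s: tuple[float, float] = (2.0, 4.0)

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets_s, dtype=float)
        if onsets.ndim != 1 or onsets.size == 0:
            raise ValueError("protocol needs at least one onset")
        if np.any(np.diff(onsets) < self.stim_duration_s):
            raise ValueError("onsets must be increasing with gaps >= stim_duration_s")
        if self.stim_duration_s <= 0 or self.isi_s <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("stim_duration_s, isi_s and frame_rate_hz must be positive")
        lo, hi = self.pre_baseline_window_s
        if not (0 <= lo < hi):
            raise ValueError("pre_baseline_window_s must satisfy 0 <= near < far")

    @property
    def n_reps(self) -> int:
        return len(self.onsets_s)

    def frame_index(self, t_s: float) -> int:
        return int(round(t_s * self.frame_rate_hz))

    def stim_slices(self, n_frames: int | None = None) -> list[slice]:
        """Frame slices covering [onset, onset + stim_duration] per repetition."""
        out = []
        for onset in self.onsets_s:
            a = self.frame_index(onset)
            b = self.frame_index(onset + self.stim_duration_s) + 1
            if n_frames is not None and (a < 0 or b > n_frames):
                raise IndexError(
                    f"stimulus window [{onset}, {onset + self.stim_duration_s}] s "
                    f"outside trace of {n_frames} frames"
                )
            out.append(slice(a, b))
        return out

    def baseline_slices(self) -> list[slice]:
        """Frame slices for the pre-stimulus baseline window of each repetition."""
        near, far = self.pre_baseline_window_s
        out = []
        for onset in self.onsets_s:
            a = max(self.frame_index(onset - far), 0)
            b = self.frame_index(onset - near) + 1
            if b <= a:
                raise ValueError(f"empty baseline window before onset {onset} s")
            out.append(slice(a, b))
        return out

    def stim_mask(self, n_frames: int) -> np.ndarray:
        mask = np.zeros(n_frames, dtype=bool)
        for sl in self.stim_slices():
            mask[max(sl.start, 0) : min(sl.stop, n_frames)] = True
        return mask


@dataclass(frozen=True)
class FluorescenceTrace:
    """Raw cell-body and surrounding-background fluorescence of one neuron."""

    cell_id: str
    f_cell: np.ndarray
    f_background: np.ndarray
    frame_rate_hz: float = 30.0

    def __post_init__(self) -> None:
        fc = np.asarray(self.f_cell, dtype=float)
        fb = np.asarray(self.f_background, dtype=float)
        object.__setattr__(self, "f_cell", fc)
        object.__setattr__(self, "f_background", fb)
        if fc.shape != fb.shape:
            raise ValueError("f_cell and f_background must have equal lengths")
        if not (np.all(np.isfinite(fc)) and np.all(np.isfinite(fb))):
            raise ValueError("fluorescence traces must be finite")


@dataclass(frozen=True)
class DffTrace:
    """Background-subtracted, baseline-normalized fluorescence (ΔF/F)."""

    values: np.ndarray
    f0: float


@dataclass
class ResponseProfile:
    cell_id: str
    positives: list[bool]
    magnitude: float
    noise_level: float
    label: str = field(init=False)

    def __post_init__(self) -> None:
        self.label = classify_cell(self.positives)

    @property
    def n_positive(self) -> int:
        return int(sum(self.positives))


def compute_dff(trace: FluorescenceTrace, protocol: StimulusProtocol) -> DffTrace:
    """ΔF/F with F0 the mean background-subtracted signal over pre-onset windows.

    d(t) = ((f_cell - f_background) - F0) / F0.
    """
    net = trace.f_cell - trace.f_background
    base = np.concatenate([net[sl] for sl in protocol.baseline_slices()])
    if base.size == 0:
        raise DegenerateBaselineError("no pre-stimulus samples available for F0")
    f0 = float(base.mean())
    if f0 <= 0:
        raise DegenerateBaselineError(f"non-positive baseline F0 = {f0:g}")
    return DffTrace(values=(net - f0) / f0, f0=f0)


def invert_dff(dff: DffTrace, f_background: np.ndarray) -> np.ndarray:
    """Reconstruct f_cell from a ΔF/F trace (round-trip check for compute_dff)."""
    return dff.values * dff.f0 + dff.f0 + np.asarray(f_background, dtype=float)


def estimate_noise(dff: DffTrace, protocol: StimulusProtocol) -> float:
    """Robust SD of ΔF/F outside stimulus windows (the "non-spike level").

    Uses 1.4826 x MAD, then masks samples exceeding twice the first estimate
    and recomputes once, so that spontaneous transients between stimuli do not
    inflate the floor.  A constant trace yields 0 (with a warning).
    """
    vals = np.asarray(dff.values, dtype=float)
    outside = vals[~protocol.stim_mask(vals.size)]
    if outside.size < 30:
        raise ValueError("need at least 30 non-stimulus samples to estimate noise")

    def _mad_sd(x: np.ndarray) -> float:
        return MAD_SCALE * float(np.median(np.abs(x - np.median(x))))

    first = _mad_sd(outside)
    if first == 0.0:
        warnings.warn("degenerate noise estimate: non-stimulus trace is constant")
        return 0.0
    kept = outside[np.abs(outside - np.median(outside)) <= 2.0 * first]
    if kept.size < 30:
        return first
    second = _mad_sd(kept)
    return second if second > 0 else first


def score_repetitions(
    dff: DffTrace, protocol: StimulusProtocol, noise_level: float
) -> list[bool]:
    """Positive response per repetition: max ΔF/F in the stimulus window ≥ 2 x noise.

    The comparison is inclusive (SNR ≥ 2).  With a zero noise floor any strictly
    positive excursion counts.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be non-negative")
    vals = np.asarray(dff.values, dtype=float)
    positives = []
    for r, sl in enumerate(protocol.stim_slices(n_frames=vals.size)):
        peak = float(vals[sl].max())
        if noise_level == 0.0:
            positives.append(peak > 0.0)
        else:
            positives.append(peak >= SNR_THRESHOLD * noise_level)
    return positives


def classify_cell(
    positives: list[bool],
    ls_min: int = LS_MIN_POSITIVE,
    ns_max: int = NS_MAX_POSITIVE,
) -> str:
    """Three-way label from per-repetition positives: LS / NS / excluded."""
    if len(positives) == 0:
        raise ValueError("empty positives vector")
    n_pos = int(sum(bool(p) for p in positives))
    if n_pos >= ls_min:
        return "LS"
    if n_pos <= ns_max:
        return "NS"
    return "excluded"


def response_magnitude(dff: DffTrace, protocol: StimulusProtocol) -> float:
    """Mean over repetitions of (post-stimulus peak − pre-stimulus mean ΔF/F).

    Post-stimulus window is [onset, onset + stim_duration]; pre-stimulus window
    is 2–4 s before onset.
    """
    vals = np.asarray(dff.values, dtype=float)
    near, far = protocol.pre_baseline_window_s
    diffs = []
    for r, onset in enumerate(protocol.onsets_s):
        a_pre = protocol.frame_index(onset - far)
        b_pre = protocol.frame_index(onset - near) + 1
        a_post = protocol.frame_index(onset)
        b_post = protocol.frame_index(onset + protocol.stim_duration_s) + 1
        if a_pre < 0 or b_post > vals.size:
            raise IndexError(f"incomplete pre/post windows for repetition {r}")
        diffs.append(float(vals[a_post:b_post].max()) - float(vals[a_pre:b_pre].mean()))
    return float(np.mean(diffs))


def count_events(
    dff: DffTrace, noise_level: float, window: tuple[float, float] | None = None,
    frame_rate_hz: float = 30.0,
) -> int:
    """Count disjoint supra-threshold calcium events in a time window.

    An event starts when ΔF/F reaches 2 x noise_level (inclusive) and ends only
    when the trace falls below 1 x noise_level — hysteresis, so a double peak
    that never dips below the noise floor counts once.  Used for spontaneous /
    evoked event counting in drug-treatment comparisons.
    """
    vals = np.asarray(dff.values, dtype=float)
    if window is not None:
        a = int(round(window[0] * frame_rate_hz))
        b = int(round(window[1] * frame_rate_hz)) + 1
        if a < 0 or b > vals.size:
            raise IndexError("event-count window outside trace")
        vals = vals[a:b]
    hi = SNR_THRESHOLD * noise_level
    lo = noise_level
    if noise_level == 0.0:
        hi = np.finfo(float).tiny
        lo = 0.0
    count = 0
    in_event = False
    for v in vals:
        if not in_event and v >= hi:
            count += 1
            in_event = True
        elif in_event and v < lo:
            in_event = False
    return count


def analyze_trace(trace: FluorescenceTrace, protocol: StimulusProtocol) -> ResponseProfile:
    """Full per-cell analysis: ΔF/F → noise → repetition scoring → label → magnitude."""
    dff = compute_dff(trace, protocol)
    noise = estimate_noise(dff, protocol)
    positives = score_repetitions(dff, protocol, noise)
    magnitude = response_magnitude(dff, protocol)
    return ResponseProfile(
        cell_id=trace.cell_id, positives=positives, magnitude=magnitude, noise_level=noise
    )


def classify_cohort(
    traces: list[FluorescenceTrace], protocol: StimulusProtocol
) -> pd.DataFrame:
    """Analyze every trace; returns a tidy frame indexed by cell_id."""
    rows = []
    for tr in traces:
        prof = analyze_trace(tr, protocol)
        rows.append(
            {
                "cell_id": prof.cell_id,
                "n_positive": prof.n_positive,
                "magnitude": prof.magnitude,
                "noise_level": prof.noise_level,
                "label": prof.label,
            }
        )
    return pd.DataFrame(rows).set_index("cell_id")
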
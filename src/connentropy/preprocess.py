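"""Broadband conditioning and trial segmentation.

The front-end mirrors standard resting-state EEG conditioning: a Hamming-window
FIR band-pass (1-70 Hz), an FIR band-stop notch for 50 Hz line interference,
and segmentation into non-overlapping 5-s trials of which the first twenty
are retained.  All filters are applied zero-phase (forward-backward) so the
phase structure feeding the Hilbert envelopes downstream is untouched.

Artifact detection is out of scope: synthetic recordings are artifact-free by
construction, and for real data a user-supplied boolean trial mask can be
passed to :func:`segment_trials`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .containers import RoiTimeSeries, ValidationError

#: Hamming-window design constant: transition width ~ 3.3 / numtaps (normalized).
_HAMMING_TW = 3.3


@dataclass(frozen=True)
class FilterSpec:
    """An FIR filter specification.

    ``kind`` is ``"band-pass"`` or ``"band-stop"``; ``edges`` are the cutoff
    frequencies in Hz; ``transition_width`` (Hz) sets the filter order via the
    Hamming design rule; ``zero_phase`` selects forward-backward application.
    """

    kind: str
    edges: tuple[float, ...]
    transition_width: float = 1.0
    window: str = "hamming"
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("band-pass", "band-stop"):
            raise ValidationError(f"unknown filter kind {self.kind!r}")
        e = tuple(self.edges)
        if len(e) != 2 or not (0 < e[0] < e[1]):
            raise ValidationError(f"edges must be strictly increasing > 0, got {e}")
        if self.transition_width <= 0:
            raise ValidationError("transition_width must be positive")

    def numtaps(self, fs: float) -> int:
        """Odd tap count from the Hamming transition-width rule."""
        n = int(np.ceil(_HAMMING_TW * fs / self.transition_width))
        return n + 1 if n % 2 == 0 else n

    def design(self, fs: float, max_taps: Optional[int] = None) -> np.ndarray:
        """Design the FIR taps for sampling rate ``fs``."""
        if self.edges[1] >= fs / 2:
            raise ValidationError(
                f"upper edge {self.edges[1]} Hz >= Nyquist {fs / 2} Hz"
            )
        n = self.numtaps(fs)
        if max_taps is not None and n > max_taps:
            n = max_taps if max_taps % 2 == 1 else max_taps - 1
            if n < 9:
                raise ValidationError("signal too short to design a usable filter")
            warnings.warn(
                f"filter order capped at {n} taps for a short signal; "
                "transition bands are wider than requested",
                RuntimeWarning,
                stacklevel=2,
            )
        return sps.firwin(
            n,
            list(self.edges),
            window=self.window,
            pass_zero=(self.kind == "band-stop"),
            fs=fs,
        )

    def delay(self, fs: float) -> int:
        """Group delay of a single pass, in samples."""
        return (self.numtaps(fs) - 1) // 2


DEFAULT_BANDPASS = FilterSpec("band-pass", (1.0, 70.0))
DEFAULT_NOTCH = FilterSpec("band-stop", (49.0, 51.0))


def _apply_taps(data: np.ndarray, taps: np.ndarray, zero_phase: bool) -> np.ndarray:
    """Apply FIR taps along the last axis, FFT-based for speed.

    Zero-phase application convolves with ``taps`` forward and backward,
    i.e. with the (symmetric) autocorrelation of the taps, after odd
    reflection padding at the edges — numerically equivalent to
    ``scipy.signal.filtfilt`` but O(T log T) for long kernels.
    """
    n = taps.size
    kernel = np.convolve(taps, taps[::-1]) if zero_phase else taps
    pad = kernel.size  # generous edge padding
    x = np.atleast_2d(data)
    if x.shape[-1] <= 3 * n:
        raise ValidationError(
            f"signal of {x.shape[-1]} samples is shorter than 3x the filter "
            f"order ({n} taps); use a longer recording or a wider transition"
        )
    # odd reflection (as filtfilt's default padtype)
    left = 2 * x[:, :1] - x[:, pad:0:-1]
    right = 2 * x[:, -1:] - x[:, -2:-pad - 2:-1]
    padded = np.concatenate([left, x, right], axis=-1)
    out = sps.fftconvolve(padded, kernel[np.newaxis, :], mode="same", axes=-1)
    out = out[:, pad:-pad]
    return out if data.ndim == 2 else out[0]


def apply_filter(x: RoiTimeSeries, spec: FilterSpec,
                 max_taps: Optional[int] = None) -> RoiTimeSeries:
    """Filter every ROI of ``x`` with ``spec`` (zero-phase by default)."""
    cap = max_taps
    if cap is None:
        # keep the design feasible on short inputs, warn when capped
        cap_feasible = (x.n_samples - 1) // 3
        if spec.numtaps(x.fs) > cap_feasible:
            cap = cap_feasible
    taps = spec.design(x.fs, max_taps=cap)
    return x.copy_with(_apply_taps(x.data, taps, spec.zero_phase))


def filter_broadband(
    x: RoiTimeSeries,
    bandpass: FilterSpec = DEFAULT_BANDPASS,
    notch: Optional[FilterSpec] = DEFAULT_NOTCH,
) -> RoiTimeSeries:
    """Band-pass 1-70 Hz and notch out 50 Hz line interference.

    Returns a series of the same length; callers should trim one filter
    delay per edge (see :func:`edge_delay`) before segmenting.
    """
    out = apply_filter(x, bandpass)
    if notch is not None:
        out = apply_filter(out, notch)
    return out


def edge_delay(x: RoiTimeSeries, specs: Sequence[FilterSpec] = (DEFAULT_BANDPASS,)) -> int:
    """Samples to trim at each end after zero-phase filtering."""
    return max(spec.delay(x.fs) for spec in specs)


def trim_edges(x: RoiTimeSeries, n: int) -> RoiTimeSeries:
    """Drop ``n`` samples at each end (edge-transient removal)."""
    if n <= 0:
        return x
    if 2 * n >= x.n_samples:
        raise ValidationError(f"cannot trim {n} samples from each end of "
                              f"{x.n_samples} samples")
    return x.copy_with(x.data[:, n:x.n_samples - n])


def segment_trials(
    x: RoiTimeSeries,
    trial_len_s: float = 5.0,
    n_trials: int = 20,
    trial_mask: Optional[Sequence[bool]] = None,
) -> list[RoiTimeSeries]:
    """Cut ``x`` into consecutive non-overlapping trials; keep the first
    ``n_trials``.

    ``trial_mask`` marks candidate trials to keep (True = artifact-free);
    the first ``n_trials`` unmasked candidates are returned.  Fewer than
    ``n_trials`` available is an error: the protocol requires a fixed trial
    count per subject so that all subjects contribute equal information.
    """
    samples_per_trial = int(round(trial_len_s * x.fs))
    if samples_per_trial < 2:
        raise ValidationError("trial length too short for the sampling rate")
    n_candidates = x.n_samples // samples_per_trial
    keep = list(range(n_candidates))
    if trial_mask is not None:
        if len(trial_mask) < n_candidates:
            raise ValidationError(
                f"trial_mask has {len(trial_mask)} entries for {n_candidates} "
                "candidate trials"
            )
        keep = [i for i in keep if trial_mask[i]]
    if len(keep) < n_trials:
        who = x.subject_id or "<unnamed subject>"
        raise ValidationError(
            f"subject {who}: only {len(keep)} usable {trial_len_s:g}-s trials, "
            f"{n_trials} required"
        )
    trials = []
    for k, i in enumerate(keep[:n_trials]):
        seg = x.data[:, i * samples_per_trial:(i + 1) * samples_per_trial]
        trials.append(x.copy_with(seg.copy(), trial_index=k))
    return trials


def read_edf(path: str, picks: Optional[Sequence[str]] = None) -> RoiTimeSeries:
    """Optional EDF/EDF+ front-end for sensor-level recordings.

    Requires :mod:`mne`.  Channel picks follow the 10-20 electrode names.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF requires the optional 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if picks is not None:
        raw.pick(list(picks))
    return RoiTimeSeries(data=raw.get_data(), fs=float(raw.info["sfreq"]),
                         subject_id=path)
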
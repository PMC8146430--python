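"""Core data containers shared by every pipeline stage.

The pipeline moves through four representations: ROI time series
(:class:`RoiTimeSeries`), per-trial/per-band adjacency matrices
(:class:`ConnectivityMatrix`), relative-probability weight histograms
(:class:`WeightHistogram`), and tabular statistical results
(:class:`TestResult` / :class:`BinComparisonResult`).  Tables that span
subjects (the entropy table, the per-subject histograms) are plain pandas
DataFrames documented where they are produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


class ValidationError(ValueError):
    """Raised when a container or configuration field violates an invariant."""


# ---------------------------------------------------------------------------
# frequency bands
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandDefinition:
    """A frequency band given by its label and edges in Hz."""

    label: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high):
            raise ValidationError(
                f"band {self.label!r}: edges must satisfy 0 <= low < high, "
                f"got ({self.low}, {self.high})"
            )

    @property
    def bandwidth(self) -> float:
        return self.high - self.low


#: The six canonical EEG bands used throughout.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta1", 13.0, 19.0),
    BandDefinition("beta2", 19.0, 30.0),
    BandDefinition("gamma", 30.0, 70.0),
)

BAND_LABELS: tuple[str, ...] = tuple(b.label for b in DEFAULT_BANDS)


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------

@dataclass
class RoiTimeSeries:
    """A multichannel ROI-level recording or trial.

    Parameters
    ----------
    data
        Real array of shape ``(n_rois, n_samples)``.
    fs
        Sampling rate in Hz.
    subject_id, trial_index, band
        Optional provenance metadata.  ``band`` unset means broadband.
    """

    data: np.ndarray
    fs: float
    subject_id: Optional[str] = None
    trial_index: Optional[int] = None
    band: Optional[str] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[np.newaxis, :]
        if self.data.ndim != 2:
            raise ValidationError(
                f"data must be 2-D (n_rois, n_samples), got ndim={self.data.ndim}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("data contains non-finite values")
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray, band: Optional[str] = None,
                  trial_index: Optional[int] = None) -> "RoiTimeSeries":
        """New series with the same metadata but different samples."""
        return RoiTimeSeries(
            data=data,
            fs=self.fs,
            subject_id=self.subject_id,
            trial_index=self.trial_index if trial_index is None else trial_index,
            band=self.band if band is None else band,
        )


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityMatrix:
    """A symmetric functional-connectivity adjacency matrix.

    Weights live in [0, 1]; the diagonal is zero.  One matrix per subject,
    trial and frequency band.
    """

    weights: np.ndarray
    band: Optional[str] = None
    subject_id: Optional[str] = None
    trial_index: Optional[int] = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError(f"weights must be square, got shape {w.shape}")
        if w.shape[0] < 2:
            raise ValidationError("a network needs at least 2 nodes")
        if not np.all(np.isfinite(w)):
            raise ValidationError("weights contain non-finite values")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValidationError("weights matrix is not symmetric")
        if np.any(np.abs(np.diag(w)) > 1e-12):
            raise ValidationError("diagonal must be zero")
        if w.min() < -1e-12 or w.max() > 1 + 1e-12:
            raise ValidationError(
                f"weights outside [0, 1]: min={w.min():.4g}, max={w.max():.4g}"
            )
        self.weights = np.clip(w, 0.0, 1.0)
        np.fill_diagonal(self.weights, 0.0)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------

@dataclass
class WeightHistogram:
    """Relative-probability histogram of network weights on [0, 1].

    ``q`` holds the relative probability of each of the ``N`` equal-width
    bins; ``Q`` is their total mass (1 after normalization).  Bins are
    left-closed/right-open, except the final bin which is right-closed so
    a weight of exactly 1.0 is countable.
    """

    q: np.ndarray
    bin_edges: np.ndarray
    band: Optional[str] = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        n = self.q.size
        if self.bin_edges.size != n + 1:
            raise ValidationError(
                f"need N+1 edges for N={n} bins, got {self.bin_edges.size}"
            )
        if not (abs(self.bin_edges[0]) < 1e-12 and abs(self.bin_edges[-1] - 1) < 1e-12):
            raise ValidationError("histogram support must be exactly [0, 1]")
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, 1.0 / n, atol=1e-9):
            raise ValidationError("bins must have equal width 1/N")
        if np.any(self.q < -1e-12):
            raise ValidationError("relative probabilities must be nonnegative")
        self.q = np.clip(self.q, 0.0, None)

    @property
    def N(self) -> int:
        """Number of bins."""
        return self.q.size

    @property
    def Q(self) -> float:
        """Total histogram mass (sum of q)."""
        return float(self.q.sum())

    @property
    def bin_width(self) -> float:
        return 1.0 / self.N


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    """One subject of a cohort: group label plus broadband recording.

    ``target_aec`` (optional) is the generator's ground truth: per band, the
    calibrated envelope correlation each node pair was built to exhibit.
    ``requested_aec`` is the pre-calibration target matrix drawn from the
    group's coupling spec.  ``true_envelopes`` (optional, memory-heavy) maps
    band label to the pre-mixing ground-truth envelopes used as an oracle
    in tests.
    """

    subject_id: str
    group: str
    timeseries: RoiTimeSeries
    target_aec: Optional[dict] = None
    requested_aec: Optional[np.ndarray] = None
    true_envelopes: Optional[dict] = None


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    """Outcome of one hypothesis test, with optional FDR adjustment."""

    name: str
    statistic: float
    p_raw: float
    p_adjusted: Optional[float] = None
    family: Optional[str] = None
    df: Optional[int] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_raw) and not (0 <= self.p_raw <= 1):
            raise ValidationError(f"p_raw out of [0, 1]: {self.p_raw}")

    @property
    def p(self) -> float:
        """Adjusted p-value when a family is defined, raw otherwise."""
        return self.p_raw if self.p_adjusted is None else self.p_adjusted

    def significant(self, alpha: float = 0.05) -> bool:
        return bool(np.isfinite(self.p) and self.p < alpha)


@dataclass
class BinComparisonResult:
    """Per-bin group comparison of subject-averaged weight histograms."""

    band: str
    bin_index: int
    bin_low: float
    bin_high: float
    result: TestResult

    def significant(self, alpha: float = 0.05) -> bool:
        return self.result.significant(alpha)


def group_sizes_ok(sizes: Sequence[int]) -> bool:
    return len(sizes) >= 1 and all(int(s) >= 2 for s in sizes)
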
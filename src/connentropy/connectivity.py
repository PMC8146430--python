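"""Leakage-corrected amplitude envelope correlation (AEC) networks.

For every ordered ROI pair (i, j) within one band-limited trial, the test
signal j is orthogonalized against the seed signal i (zero-lag linear
regression, removing the instantaneous leakage that source reconstruction
introduces), amplitude envelopes are taken as the modulus of the analytic
signal, and the envelopes are Pearson-correlated.  Orthogonalized AEC is
asymmetric, so the two directions are averaged and the result mapped into
[0, 1] before symmetrization.

The per-subject product is a ``bands x n_rois x n_rois x n_trials`` array of
adjacency matrices (6 x 68 x 68 x 20 at the default dimensions).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import signal as sps

from .containers import (
    BandDefinition,
    ConnectivityMatrix,
    DEFAULT_BANDS,
    RoiTimeSeries,
    ValidationError,
)
from .preprocess import FilterSpec, apply_filter

#: samples dropped at each envelope end before correlating (Hilbert edge
#: artifacts); 0.25 s at the default 200 Hz rate.
DEFAULT_EDGE_TRIM_S = 0.25


def band_filter_spec(band: BandDefinition, transition_width: float = 1.0) -> FilterSpec:
    """FIR band-pass spec for one analysis band (Hamming window)."""
    return FilterSpec("band-pass", (band.low, band.high),
                      transition_width=transition_width)


def band_decompose(
    x: RoiTimeSeries,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    transition_width: float = 1.0,
) -> dict[str, RoiTimeSeries]:
    """Split a broadband series into one band-limited copy per band.

    Uses the same zero-phase Hamming FIR machinery as the broadband stage.
    Works on continuous recordings or single trials (filter order is capped,
    with a warning, when the input is short).
    """
    out: dict[str, RoiTimeSeries] = {}
    for band in bands:
        if band.high >= x.fs / 2:
            raise ValidationError(
                f"band {band.label!r} upper edge {band.high} Hz >= Nyquist "
                f"{x.fs / 2} Hz"
            )
        spec = band_filter_spec(band, transition_width)
        filtered = apply_filter(x, spec)
        filtered.band = band.label
        out[band.label] = filtered
    return out


def orthogonalize_pair(seed: np.ndarray, test: np.ndarray) -> np.ndarray:
    """Residual of ``test`` after removing its zero-lag projection on ``seed``.

    Both signals are demeaned first; the regression has no intercept.  A
    zero-variance seed leaves ``test`` unchanged (no regression is defined).
    The operation is idempotent and leaves any component orthogonal to the
    seed untouched.
    """
    seed = np.asarray(seed, float)
    test = np.asarray(test, float)
    if seed.shape != test.shape:
        raise ValidationError("seed and test must have equal length")
    seed = seed - seed.mean()
    test = test - test.mean()
    ss = float(seed @ seed)
    if ss <= 0.0:
        warnings.warn("zero-variance seed: returning test unchanged",
                      RuntimeWarning, stacklevel=2)
        return test
    beta = float(seed @ test) / ss
    return test - beta * seed


def amplitude_envelope(x: np.ndarray) -> np.ndarray:
    """Modulus of the analytic signal, row-wise for 2-D input."""
    x = np.asarray(x, float)
    return np.abs(sps.hilbert(x, axis=-1))


def _pearson_rows(v: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Pearson correlation of vector ``v`` with every row of ``m``."""
    v = v - v.mean()
    m = m - m.mean(axis=-1, keepdims=True)
    sv = np.sqrt(v @ v)
    sm = np.sqrt(np.einsum("ij,ij->i", m, m))
    denom = sv * sm
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (m @ v) / denom
    r[~np.isfinite(r)] = np.nan
    return r


def aec_correlations(
    band_trial: RoiTimeSeries,
    edge_trim: Optional[int] = None,
) -> np.ndarray:
    """Signed orthogonalized envelope correlations for one band-limited trial.

    For each ordered pair (i, j): regress j on i (zero-lag, no intercept),
    Hilbert-envelope the seed and the residual, Pearson-correlate; the
    (i->j) and (j->i) values are averaged into a symmetric matrix with zero
    diagonal.  Values lie in [-1, 1]; for truly uncoupled signals they
    scatter symmetrically around zero, which is what the leakage-invariance
    checks measure.  :func:`aec_matrix` maps them into [0, 1] weights.
    """
    X = band_trial.data - band_trial.data.mean(axis=1, keepdims=True)
    n, T = X.shape
    if edge_trim is None:
        edge_trim = int(round(DEFAULT_EDGE_TRIM_S * band_trial.fs))
    edge_trim = min(edge_trim, (T - 8) // 2) if T > 16 else 0
    sl = slice(edge_trim, T - edge_trim if edge_trim else T)

    A = sps.hilbert(X, axis=-1)          # analytic signals, one per ROI
    power = np.einsum("ij,ij->i", X, X)  # <x_i, x_i>
    G = X @ X.T                          # <x_i, x_j>
    env = np.abs(A)[:, sl]

    dead = power <= 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} zero-variance ROI signal(s); their weights "
            "are set to 0", RuntimeWarning, stacklevel=2)

    R = np.zeros((n, n))
    warned_collinear = False
    for i in range(n):
        if dead[i]:
            continue
        beta = G[i] / power[i]
        # analytic signal is linear, so residual envelopes come cheap
        res_env = np.abs(A - beta[:, np.newaxis] * A[i])[:, sl]
        r = _pearson_rows(env[i], res_env)
        # a residual carrying a negligible fraction of the test signal's
        # power is pure leakage (numerically a roundoff ghost): weight 0
        res_frac = 1.0 - np.clip(beta ** 2 * power[i] / np.where(power > 0, power, 1.0), 0.0, 1.0)
        degenerate = res_frac < 1e-12
        if degenerate[np.arange(n) != i].any() and not warned_collinear:
            warnings.warn("collinear ROI pair(s): residual has no variance, "
                          "weight set to 0", RuntimeWarning, stacklevel=2)
            warned_collinear = True
        r[degenerate] = 0.0
        r[i] = 0.0
        r[~np.isfinite(r)] = 0.0
        R[i] = r

    avg = 0.5 * (R + R.T)  # average the two orthogonalization directions
    np.fill_diagonal(avg, 0.0)
    return avg


def aec_matrix(
    band_trial: RoiTimeSeries,
    negative_mode: str = "abs",
    edge_trim: Optional[int] = None,
) -> ConnectivityMatrix:
    """Orthogonalized-AEC adjacency matrix for one band-limited trial.

    Signed direction-averaged envelope correlations
    (:func:`aec_correlations`) mapped into [0, 1]: ``negative_mode="abs"``
    keeps the magnitude of anticorrelated envelopes, ``"clip"`` floors
    them at 0.
    """
    if negative_mode not in ("abs", "clip"):
        raise ValidationError(f"unknown negative_mode {negative_mode!r}")
    avg = aec_correlations(band_trial, edge_trim=edge_trim)
    w = np.abs(avg) if negative_mode == "abs" else np.clip(avg, 0.0, None)
    w = np.clip(w, 0.0, 1.0)
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(
        weights=w,
        band=band_trial.band,
        subject_id=band_trial.subject_id,
        trial_index=band_trial.trial_index,
    )


def subject_connectivity(
    band_trials: Mapping[str, Iterable[RoiTimeSeries]],
    negative_mode: str = "abs",
) -> dict[str, list[ConnectivityMatrix]]:
    """AEC matrices for every band and trial of one subject."""
    return {
        band: [aec_matrix(t, negative_mode=negative_mode) for t in trials]
        for band, trials in band_trials.items()
    }


def connectivity_array(
    matrices: Mapping[str, Sequence[ConnectivityMatrix]],
    bands: Sequence[str] | None = None,
) -> np.ndarray:
    """Stack one subject's matrices into a (bands, n, n, trials) array."""
    if bands is None:
        bands = list(matrices)
    stacks = []
    for band in bands:
        ms = matrices[band]
        if not ms:
            raise ValidationError(f"no matrices for band {band!r}")
        stacks.append(np.stack([m.weights for m in ms], axis=-1))
    return np.stack(stacks, axis=0)
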
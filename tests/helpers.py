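"""Shared test helpers: measurement shortcuts built on the public API."""

from __future__ import annotations

import numpy as np

from connentropy import WeightHistogram
from connentropy.cohort import generate_weight_matrices
from connentropy.connectivity import aec_correlations, band_decompose
from connentropy.containers import DEFAULT_BANDS
from connentropy.entropy import extract_weights, weights_histogram
from connentropy.preprocess import (
    DEFAULT_BANDPASS,
    edge_delay,
    filter_broadband,
    segment_trials,
    trim_edges,
)


def trial_mean_aec(record, band_label="gamma", bands=None):
    """Mean signed orthogonalized AEC over the first twenty 5-s trials."""
    ts = record.timeseries
    use = bands if bands is not None else DEFAULT_BANDS
    series = band_decompose(filter_broadband(ts),
                            [b for b in use if b.label == band_label])[band_label]
    series = trim_edges(series, edge_delay(ts, (DEFAULT_BANDPASS,)))
    trials = segment_trials(series, 5.0, 20)
    return np.mean([aec_correlations(t) for t in trials], axis=0)


def histogram_cohort(rng, dist, n_subjects, n_trials=5, n_nodes=32,
                     band="alpha"):
    """Subject-averaged histograms from direct weight-matrix draws."""
    out = []
    for _ in range(n_subjects):
        qs = []
        for m in generate_weight_matrices(n_nodes, dist,
                                          seed=int(rng.integers(2 ** 31)),
                                          n_matrices=n_trials):
            qs.append(weights_histogram(extract_weights(m), 40).q)
        q = np.mean(qs, axis=0)
        out.append(WeightHistogram(q / q.sum(), np.linspace(0, 1, 41),
                                   band=band))
    return out
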
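"""Shannon entropy of the network-weights distribution.

A connectivity matrix on n nodes yields n(n-1)/2 weights in [0, 1].  Their
relative-probability histogram q over N equal-width bins is summarized by
the normalized Shannon entropy

    SE = -(1 / log2 N) * sum_i (q_i / Q) * log2(q_i / Q),     Q = sum_i q_i,

which is 1 for an exactly uniform binned distribution (a random network with
uniformly distributed weights) and 0 when every weight falls in a single bin
(a lattice-like network with equal weights).  Empty bins contribute nothing
(0 * log 0 := 0).

The bin count is common to all subjects, trials and bands so SE values are
directly comparable.  The selection protocol evaluates five classical rules
(Scott, Freedman-Diaconis, Integers, Sturges, Square Root) per trial, takes
the median over trials and subjects for each band and rule, and keeps the
maximum — which, at the study's dimensions, lands on N = 40 (bin width
0.025); N = 40 is therefore the package default.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .containers import ConnectivityMatrix, ValidationError, WeightHistogram

DEFAULT_N_BINS = 40

BIN_RULES = ("scott", "freedman_diaconis", "integers", "sturges", "sqrt")


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------

def extract_weights(m: Union[ConnectivityMatrix, np.ndarray]) -> np.ndarray:
    """Strict upper-triangle weights, row-major, length n(n-1)/2."""
    w = m.weights if isinstance(m, ConnectivityMatrix) else np.asarray(m, float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValidationError(f"expected a square matrix, got shape {w.shape}")
    if not np.allclose(w, w.T, atol=1e-12):
        raise ValidationError("matrix is not symmetric")
    iu = np.triu_indices(w.shape[0], k=1)
    return w[iu]


# ---------------------------------------------------------------------------
# bin-count rules
# ---------------------------------------------------------------------------

def bin_count_rules(
    w: np.ndarray,
    hist_range: str = "unit",
) -> dict[str, int]:
    """Bin counts proposed by the five classical rules for sample ``w``.

    Scott and Freedman-Diaconis prescribe a bin *width*; it is converted to
    a count via ``ceil(range / width)``.  ``hist_range="unit"`` fixes the
    range to 1 (the common [0, 1] histogram support, so counts are
    comparable across subjects); ``"sample"`` uses the sample range instead.
    The Integers rule uses unit-width integer-centered bins and is
    degenerate on [0, 1] (it is retained for protocol fidelity).
    """
    w = np.asarray(w, float)
    n = w.size
    if n < 1:
        raise ValidationError("empty weight vector")
    if hist_range == "unit":
        rng = 1.0
    elif hist_range == "sample":
        rng = float(w.max() - w.min())
    else:
        raise ValidationError(f"unknown hist_range {hist_range!r}")

    counts: dict[str, int] = {
        "sqrt": int(np.ceil(np.sqrt(n))),
        "sturges": int(np.ceil(np.log2(n))) + 1,
        "integers": int(np.ceil(w.max()) - np.floor(w.min())) + 1,
    }

    s = float(w.std(ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(w, [75, 25])
    iqr = float(q75 - q25)
    for rule, width in (("scott", 3.49 * s * n ** (-1 / 3)),
                        ("freedman_diaconis", 2.0 * iqr * n ** (-1 / 3))):
        if width <= 0 or rng <= 0:
            warnings.warn(f"{rule}: zero spread, returning 1 bin",
                          RuntimeWarning, stacklevel=2)
            counts[rule] = 1
        else:
            counts[rule] = int(np.ceil(rng / width))
    return counts


def select_bin_count(
    weights_by_band: Mapping[str, Iterable[np.ndarray]],
    hist_range: str = "unit",
    return_table: bool = False,
):
    """Protocol bin count: max over bands and rules of the per-band median.

    ``weights_by_band`` maps band label to the per-trial weight vectors of
    every subject.  For each rule the per-trial counts are computed, their
    median taken across all trials and subjects within a band, and the
    selected count is the maximum of these medians over rules and bands
    (maximizing the precision of the SE estimate).  Half-integer medians
    are rounded up.
    """
    if not weights_by_band:
        raise ValidationError("empty cohort: no weight vectors supplied")
    rows = []
    for band, vectors in weights_by_band.items():
        per_rule: dict[str, list[int]] = {r: [] for r in BIN_RULES}
        n_vec = 0
        for w in vectors:
            n_vec += 1
            for rule, k in bin_count_rules(np.asarray(w), hist_range).items():
                per_rule[rule].append(k)
        if n_vec == 0:
            raise ValidationError(f"band {band!r} has no weight vectors")
        for rule in BIN_RULES:
            rows.append({"band": band, "rule": rule,
                         "median_bins": float(np.median(per_rule[rule]))})
    table = pd.DataFrame(rows)
    selected = int(np.ceil(table["median_bins"].max()))
    if return_table:
        return selected, table
    return selected


# ---------------------------------------------------------------------------
# histogram and entropy
# ---------------------------------------------------------------------------

def weights_histogram(
    w: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    band: str | None = None,
) -> WeightHistogram:
    """Relative-probability histogram of weights on [0, 1].

    Bins are left-closed/right-open except the final bin, which is
    right-closed so a weight of exactly 1 is counted.  The histogram is
    normalized to total mass 1.
    """
    w = np.asarray(w, float)
    if w.size == 0:
        raise ValidationError("cannot histogram an empty weight vector")
    if w.min() < 0 or w.max() > 1:
        raise ValidationError(
            f"weights outside [0, 1]: min={w.min():.4g}, max={w.max():.4g}"
        )
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(w, bins=edges)
    q = counts / counts.sum()
    return WeightHistogram(q=q, bin_edges=edges, band=band)


def shannon_entropy(h: WeightHistogram) -> float:
    """Normalized Shannon entropy of a weight histogram, in [0, 1]."""
    if h.N < 2:
        raise ValidationError("entropy normalizer undefined for N < 2 bins")
    Q = h.Q
    if Q <= 0:
        raise ValidationError("histogram has zero total mass")
    p = h.q / Q
    nz = p > 0
    se = -np.sum(p[nz] * np.log2(p[nz])) / np.log2(h.N)
    return float(min(max(se, 0.0), 1.0)) + 0.0  # normalize -0.0


def subject_summary(
    trial_entropies: Sequence[float],
    trial_histograms: Sequence[WeightHistogram],
) -> tuple[float, WeightHistogram]:
    """Trial-averaged SE and trial-averaged histogram for one subject.

    Both averages are unweighted arithmetic means; the mean of normalized
    histograms is renormalized so it sums to exactly 1.
    """
    if len(trial_histograms) < 1 or len(trial_entropies) < 1:
        raise ValidationError("need at least one trial")
    bands = {h.band for h in trial_histograms}
    if len(bands) > 1:
        raise ValidationError(f"mixed bands in input: {sorted(map(str, bands))}")
    ns = {h.N for h in trial_histograms}
    if len(ns) > 1:
        raise ValidationError(f"mixed bin counts in input: {sorted(ns)}")
    q = np.mean([h.q / h.Q for h in trial_histograms], axis=0)
    q = q / q.sum()
    mean_hist = WeightHistogram(q=q, bin_edges=trial_histograms[0].bin_edges,
                                band=trial_histograms[0].band)
    return float(np.mean(trial_entropies)), mean_hist
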
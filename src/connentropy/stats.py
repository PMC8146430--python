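"""Group-level statistics on entropy values and weight histograms.

The analysis hierarchy is the standard nonparametric one for cohort EEG
studies: assumption checks first (Lilliefors normality per group, Levene
homoscedasticity), a global Kruskal-Wallis test per frequency band, pairwise
Mann-Whitney U follow-ups restricted to bands with a significant global
effect, and a bin-by-bin Kruskal-Wallis comparison of the subject-averaged
weight histograms — again only in bands with a significant global effect.
Benjamini-Hochberg FDR correction is applied within narrow families: the
bands for the global tests, the pairwise comparisons per analyzed band, and
the N bins within each analyzed band.

The Lilliefors null distribution is obtained by seeded Monte-Carlo
simulation of the Kolmogorov-Smirnov statistic with estimated mean and
standard deviation, which avoids interpolation in printed tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

from .containers import (
    BinComparisonResult,
    TestResult,
    ValidationError,
    WeightHistogram,
)

DEFAULT_ALPHA = 0.05

# cached Monte-Carlo null tables for the Lilliefors statistic, keyed by
# (sample size, draws, seed)
_LILLIEFORS_NULL: dict[tuple[int, int, int], np.ndarray] = {}


# ---------------------------------------------------------------------------
# assumption checks
# ---------------------------------------------------------------------------

def _ks_statistic_estimated(x: np.ndarray) -> float:
    """Two-sided KS distance to a normal with estimated mean/SD."""
    x = np.sort(np.asarray(x, float))
    n = x.size
    z = (x - x.mean()) / x.std(ddof=1)
    cdf = sst.norm.cdf(z)
    up = np.arange(1, n + 1) / n - cdf
    lo = cdf - np.arange(0, n) / n
    return float(max(up.max(), lo.max()))


def _lilliefors_null(n: int, n_mc: int, seed: int) -> np.ndarray:
    key = (n, n_mc, seed)
    if key not in _LILLIEFORS_NULL:
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n_mc, n))
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1,
                                                        keepdims=True)
        z.sort(axis=1)
        cdf = sst.norm.cdf(z)
        grid_hi = np.arange(1, n + 1) / n
        grid_lo = np.arange(0, n) / n
        d = np.maximum((grid_hi - cdf).max(axis=1), (cdf - grid_lo).max(axis=1))
        _LILLIEFORS_NULL[key] = np.sort(d)
    return _LILLIEFORS_NULL[key]


def lilliefors_test(x: Sequence[float], n_mc: int = 10_000,
                    seed: int = 2021) -> TestResult:
    """Lilliefors normality test with a seeded Monte-Carlo null.

    The p-value is ``(1 + #{null >= observed}) / (n_mc + 1)``; the null table
    for a given sample size is simulated once and cached.
    """
    x = np.asarray(x, float)
    if x.size < 4:
        raise ValidationError("Lilliefors needs at least 4 observations")
    if x.std(ddof=1) == 0:
        warnings.warn("zero-variance sample: Lilliefors undefined",
                      RuntimeWarning, stacklevel=2)
        return TestResult("lilliefors", np.nan, np.nan,
                          extra={"flag": "zero_variance"})
    d = _ks_statistic_estimated(x)
    null = _lilliefors_null(x.size, n_mc, seed)
    p = (1 + np.count_nonzero(null >= d)) / (n_mc + 1)
    return TestResult("lilliefors", d, float(p))


def levene_test(groups: Mapping[str, Sequence[float]],
                center: str = "median") -> TestResult:
    """Levene homoscedasticity test (Brown-Forsythe form by default)."""
    arrays = [np.asarray(v, float) for v in groups.values()]
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) <= 1:
        return TestResult("levene", 0.0, 1.0)
    stat, p = sst.levene(*arrays, center=center)
    return TestResult("levene", float(stat), float(p))


@dataclass
class AssumptionReport:
    """Normality and homoscedasticity checks for one family of values."""

    normality: dict[str, TestResult]
    homoscedasticity: TestResult
    alpha: float = DEFAULT_ALPHA

    @property
    def recommend_nonparametric(self) -> bool:
        rejects = [r.significant(self.alpha) for r in self.normality.values()
                   if np.isfinite(r.p_raw)]
        flagged = any(not np.isfinite(r.p_raw) for r in self.normality.values())
        return any(rejects) or flagged or self.homoscedasticity.significant(self.alpha)


def assumption_checks(groups: Mapping[str, Sequence[float]],
                      alpha: float = DEFAULT_ALPHA,
                      n_mc: int = 10_000, seed: int = 2021,
                      levene_center: str = "median") -> AssumptionReport:
    """Per-group Lilliefors plus Levene; flags when parametric tests fail."""
    for label, v in groups.items():
        if len(v) < 4:
            raise ValidationError(
                f"group {label!r} has {len(v)} observations; need >= 4")
    normality = {label: lilliefors_test(v, n_mc=n_mc, seed=seed)
                 for label, v in groups.items()}
    return AssumptionReport(normality=normality,
                            homoscedasticity=levene_test(groups,
                                                         center=levene_center),
                            alpha=alpha)


# ---------------------------------------------------------------------------
# nonparametric group tests
# ---------------------------------------------------------------------------

def kw_global(groups: Mapping[str, Sequence[float]],
              name: str = "kruskal_wallis") -> TestResult:
    """Tie-corrected Kruskal-Wallis H with a chi-squared (k-1 df) p-value."""
    arrays = [np.asarray(v, float) for v in groups.values()]
    if len(arrays) < 2:
        raise ValidationError("Kruskal-Wallis needs at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValidationError("each group needs at least 2 observations")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return TestResult(name, 0.0, 1.0, df=len(arrays) - 1)
    stat, p = sst.kruskal(*arrays)
    return TestResult(name, float(stat), float(p), df=len(arrays) - 1)


def pairwise_mwu(a: Sequence[float], b: Sequence[float],
                 name: str = "mann_whitney_u") -> TestResult:
    """Two-sided Mann-Whitney U (normal approximation, tie-corrected)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 observations")
    if np.ptp(np.concatenate([a, b])) == 0:
        return TestResult(name, a.size * b.size / 2.0, 1.0)
    u, p = sst.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return TestResult(name, float(u), float(p))


def spearman_confound(values: Sequence[float], covariate: Sequence[float],
                      name: str = "spearman") -> TestResult:
    """Spearman rank correlation between a measure and a covariate."""
    values = np.asarray(values, float)
    covariate = np.asarray(covariate, float)
    if values.size != covariate.size or values.size < 5:
        raise ValidationError("need >= 5 paired observations")
    if np.ptp(covariate) == 0 or np.ptp(values) == 0:
        warnings.warn("constant input: Spearman rho undefined",
                      RuntimeWarning, stacklevel=2)
        return TestResult(name, np.nan, np.nan, extra={"flag": "constant"})
    rho, p = sst.spearmanr(values, covariate)
    return TestResult(name, float(rho), float(p))


def bh_fdr(p_values: Sequence[float], alpha: float = DEFAULT_ALPHA
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and rejection flags."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def adjust_family(results: Sequence[TestResult], family: str,
                  alpha: float = DEFAULT_ALPHA) -> list[TestResult]:
    """Attach BH-adjusted p-values to one family of test results."""
    finite = [r for r in results if np.isfinite(r.p_raw)]
    if finite:
        p_adj, _ = bh_fdr([r.p_raw for r in finite], alpha)
        for r, pa in zip(finite, p_adj):
            r.p_adjusted = float(pa)
            r.family = family
    return list(results)


# ---------------------------------------------------------------------------
# bin-by-bin histogram comparison
# ---------------------------------------------------------------------------

def bin_by_bin(
    histograms: Mapping[str, Sequence[WeightHistogram]],
    bands: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
) -> list[BinComparisonResult]:
    """Per-bin Kruskal-Wallis across groups of subject-averaged histograms.

    ``histograms`` maps group label to one averaged histogram per subject
    (single band).  ``bands`` restricts the analysis to the bands where the
    global SE comparison was significant; the FDR family is the N bins of
    one band.
    """
    out: list[BinComparisonResult] = []
    for band in bands:
        per_group = {
            g: [h for h in hs if h.band == band]
            for g, hs in histograms.items()
        }
        per_group = {g: hs for g, hs in per_group.items() if hs}
        if len(per_group) < 2:
            raise ValidationError(f"band {band!r}: need >= 2 groups with data")
        ns = {h.N for hs in per_group.values() for h in hs}
        if len(ns) != 1:
            raise ValidationError(f"band {band!r}: mismatched bin counts {ns}")
        n_bins = ns.pop()
        edges = np.linspace(0.0, 1.0, n_bins + 1)
        mats = {g: np.vstack([h.q / h.Q for h in hs])
                for g, hs in per_group.items()}
        results = []
        for b in range(n_bins):
            r = kw_global({g: m[:, b] for g, m in mats.items()},
                          name=f"kw_bin_{b}")
            results.append(r)
        adjust_family(results, family=f"bins[{band}]", alpha=alpha)
        for b, r in enumerate(results):
            out.append(BinComparisonResult(band=band, bin_index=b,
                                           bin_low=float(edges[b]),
                                           bin_high=float(edges[b + 1]),
                                           result=r))
    return out


def significant_bin_ranges(bins: Sequence[BinComparisonResult],
                           alpha: float = DEFAULT_ALPHA
                           ) -> dict[str, list[tuple[float, float]]]:
    """Contiguous weight ranges whose bins are significant, per band."""
    ranges: dict[str, list[tuple[float, float]]] = {}
    by_band: dict[str, list[BinComparisonResult]] = {}
    for b in bins:
        by_band.setdefault(b.band, []).append(b)
    for band, bs in by_band.items():
        bs = sorted(bs, key=lambda b: b.bin_index)
        merged: list[tuple[float, float]] = []
        for b in bs:
            if not b.significant(alpha):
                continue
            if merged and abs(merged[-1][1] - b.bin_low) < 1e-9:
                merged[-1] = (merged[-1][0], b.bin_high)
            else:
                merged.append((b.bin_low, b.bin_high))
        ranges[band] = merged
    return ranges


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

@dataclass
class StatsReport:
    """Global, pairwise and per-bin results for an entropy table."""

    assumptions: dict[str, Optional[AssumptionReport]]
    global_tests: dict[str, TestResult]           # band -> KW on SE
    pairwise_tests: dict[str, dict[str, TestResult]]  # band -> pair -> MWU
    bin_tests: list[BinComparisonResult]
    analyzed_bands: list[str]
    alpha: float = DEFAULT_ALPHA
    confounds: dict[str, TestResult] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for band, r in self.global_tests.items():
            rows.append(self._row("global_kw", band, None, None, r))
        for band, pairs in self.pairwise_tests.items():
            for pair, r in pairs.items():
                rows.append(self._row("pairwise_mwu", band, pair, None, r))
        for b in self.bin_tests:
            rows.append(self._row("bin_kw", b.band, None,
                                  (b.bin_low, b.bin_high), b.result))
        for label, r in self.confounds.items():
            rows.append(self._row("confound", None, label, None, r))
        return pd.DataFrame(rows)

    def _row(self, kind, band, contrast, bin_range, r: TestResult) -> dict:
        return {
            "kind": kind, "band": band, "contrast": contrast,
            "bin_low": None if bin_range is None else bin_range[0],
            "bin_high": None if bin_range is None else bin_range[1],
            "statistic": r.statistic, "p_raw": r.p_raw,
            "p_adjusted": r.p_adjusted, "family": r.family,
            "significant_05": r.significant(0.05),
            "significant_01": r.significant(0.01),
        }

    def to_dict(self) -> dict:
        df = self.to_frame()
        return {
            "alpha": self.alpha,
            "analyzed_bands": self.analyzed_bands,
            "significant_bin_ranges": {
                band: [list(r) for r in ranges]
                for band, ranges in
                significant_bin_ranges(self.bin_tests, self.alpha).items()
            },
            "tests": df.where(pd.notna(df), None).to_dict(orient="records"),
        }


def analyze_entropy_table(
    entropy_table: pd.DataFrame,
    histograms: Optional[Mapping[str, Sequence[WeightHistogram]]] = None,
    alpha: float = DEFAULT_ALPHA,
    covariates: Optional[pd.DataFrame] = None,
    seed: int = 2021,
) -> StatsReport:
    """Run the full KW-then-pairwise-then-bin-by-bin hierarchy.

    ``entropy_table`` needs columns ``subject_id``, ``group``, ``band``,
    ``se``.  ``histograms`` maps group label to the subject-averaged
    histograms (all bands mixed; each carries its band label).  Pairwise
    and bin-by-bin analyses are restricted to bands whose FDR-corrected
    global Kruskal-Wallis test is significant at ``alpha``.
    """
    required = {"subject_id", "group", "band", "se"}
    if not required.issubset(entropy_table.columns):
        raise ValidationError(
            f"entropy table must have columns {sorted(required)}")
    bands = list(dict.fromkeys(entropy_table["band"]))
    groups = list(dict.fromkeys(entropy_table["group"]))

    assumptions = {}
    global_tests: dict[str, TestResult] = {}
    for band in bands:
        sub = entropy_table[entropy_table["band"] == band]
        by_group = {g: sub.loc[sub["group"] == g, "se"].to_numpy()
                    for g in groups}
        if min(len(v) for v in by_group.values()) >= 4:
            assumptions[band] = assumption_checks(by_group, alpha=alpha,
                                                  seed=seed)
        else:
            warnings.warn(
                f"band {band!r}: a group has < 4 observations; normality "
                "checks skipped, nonparametric tests used throughout",
                RuntimeWarning, stacklevel=2)
            assumptions[band] = None
        global_tests[band] = kw_global(by_group, name=f"kw_se[{band}]")
    adjust_family(list(global_tests.values()), family="global_kw_bands",
                  alpha=alpha)

    analyzed = [b for b in bands if global_tests[b].significant(alpha)]

    pairwise: dict[str, dict[str, TestResult]] = {}
    pair_results = []
    for band in analyzed:
        sub = entropy_table[entropy_table["band"] == band]
        pairwise[band] = {}
        for ga, gb in combinations(groups, 2):
            r = pairwise_mwu(sub.loc[sub["group"] == ga, "se"],
                             sub.loc[sub["group"] == gb, "se"],
                             name=f"mwu[{band}:{ga}-{gb}]")
            pairwise[band][f"{ga}-{gb}"] = r
            pair_results.append(r)
    adjust_family(pair_results, family="pairwise_mwu", alpha=alpha)

    bin_tests: list[BinComparisonResult] = []
    if histograms is not None and analyzed:
        bin_tests = bin_by_bin(histograms, analyzed, alpha=alpha)

    confounds: dict[str, TestResult] = {}
    if covariates is not None:
        conf_results = []
        for col in covariates.columns:
            if col in ("subject_id", "group"):
                continue
            merged = entropy_table.merge(covariates, on="subject_id")
            for band in bands:
                sub = merged[merged["band"] == band]
                r = spearman_confound(sub["se"], sub[col],
                                      name=f"spearman[{band}:{col}]")
                confounds[f"{band}:{col}"] = r
                conf_results.append(r)
        adjust_family(conf_results, family="confounds", alpha=alpha)

    return StatsReport(assumptions=assumptions, global_tests=global_tests,
                       pairwise_tests=pairwise, bin_tests=bin_tests,
                       analyzed_bands=analyzed, alpha=alpha,
                       confounds=confounds)
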
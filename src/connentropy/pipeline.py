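"""End-to-end orchestration: cohort -> connectivity -> entropy -> statistics.

``run_pipeline`` executes, per subject: broadband FIR conditioning (1-70 Hz
band-pass + 50 Hz notch), edge trimming, band decomposition into the six
canonical bands, segmentation into the first twenty 5-s trials, per-trial
orthogonalized-AEC adjacency matrices, per-trial weight histograms and
normalized Shannon entropy, and trial averaging.  The cohort-level tables
then feed the statistical hierarchy (assumption checks, global
Kruskal-Wallis per band, pairwise Mann-Whitney follow-ups, bin-by-bin
histogram comparison, all BH-FDR corrected).

Everything is deterministic given the config seed; ``write_report`` persists
the tables together with a manifest (config hash, seed, package versions)
from which the run can be replayed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, is_dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, iter_cohort
from .connectivity import aec_matrix, band_decompose
from .containers import (
    DEFAULT_BANDS,
    RoiTimeSeries,
    SubjectRecord,
    ValidationError,
    WeightHistogram,
)
from .entropy import (
    DEFAULT_N_BINS,
    bin_count_rules,
    extract_weights,
    select_bin_count,
    shannon_entropy,
    subject_summary,
    weights_histogram,
    BIN_RULES,
)
from .io import read_cohort, write_json
from .preprocess import (
    DEFAULT_BANDPASS,
    DEFAULT_NOTCH,
    edge_delay,
    filter_broadband,
    segment_trials,
    trim_edges,
)
from .stats import StatsReport, analyze_entropy_table

log = logging.getLogger("connentropy")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one full analysis run.

    Exactly one input mode: ``synthetic`` (a :class:`CohortConfig`) or
    ``files`` (a directory with a cohort manifest).
    """

    cohort: Optional[CohortConfig] = None
    input_dir: Optional[str] = None
    bands: tuple = DEFAULT_BANDS
    trial_len_s: float = 5.0
    n_trials: int = 20
    n_bins: int = DEFAULT_N_BINS
    run_bin_selection: bool = False
    negative_mode: str = "abs"
    alpha: float = 0.05
    seed: int = 0
    notch: bool = True
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.input_dir is None):
            raise ValidationError(
                "exactly one input mode: set cohort (synthetic) or input_dir "
                "(files)")
        if self.n_bins < 2:
            raise ValidationError("n_bins must be >= 2")
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")

    def to_dict(self) -> dict:
        return _as_plain(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _as_plain(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


@dataclass
class SubjectResult:
    """Per-subject products: one SE and one averaged histogram per band."""

    subject_id: str
    group: str
    se: dict[str, float]
    histograms: dict[str, WeightHistogram]
    n_trials: int
    rule_counts: dict[str, dict[str, list[int]]] = field(default_factory=dict)
    connectivity: Optional[np.ndarray] = None  # (bands, n, n, trials), opt-in


@dataclass
class PipelineResults:
    """Bundle returned by :func:`run_pipeline`."""

    entropy_table: pd.DataFrame
    histogram_table: pd.DataFrame
    stats: StatsReport
    manifest: dict
    selected_bins: int
    subject_results: list[SubjectResult] = field(default_factory=list)


def process_subject(
    record: SubjectRecord,
    config: PipelineConfig,
    keep_connectivity: bool = False,
    collect_rule_counts: bool = False,
    n_bins: Optional[int] = None,
) -> SubjectResult:
    """Run the signal chain for one subject."""
    n_bins = config.n_bins if n_bins is None else n_bins
    ts = record.timeseries
    broadband = filter_broadband(
        ts, DEFAULT_BANDPASS, DEFAULT_NOTCH if config.notch else None)
    by_band = band_decompose(broadband, config.bands)
    delay = edge_delay(ts, (DEFAULT_BANDPASS,))

    se: dict[str, float] = {}
    hists: dict[str, WeightHistogram] = {}
    rule_counts: dict[str, dict[str, list[int]]] = {}
    stacks = [] if keep_connectivity else None
    for band in config.bands:
        series = trim_edges(by_band[band.label], delay)
        trials = segment_trials(series, config.trial_len_s, config.n_trials)
        trial_se, trial_hists, mats = [], [], []
        counts: dict[str, list[int]] = {r: [] for r in BIN_RULES}
        for trial in trials:
            m = aec_matrix(trial, negative_mode=config.negative_mode)
            w = extract_weights(m)
            h = weights_histogram(w, n_bins, band=band.label)
            trial_hists.append(h)
            trial_se.append(shannon_entropy(h))
            if collect_rule_counts:
                for rule, k in bin_count_rules(w).items():
                    counts[rule].append(k)
            if keep_connectivity:
                mats.append(m.weights)
        se[band.label], hists[band.label] = subject_summary(trial_se, trial_hists)
        if collect_rule_counts:
            rule_counts[band.label] = counts
        if keep_connectivity:
            stacks.append(np.stack(mats, axis=-1))
    return SubjectResult(
        subject_id=record.subject_id, group=record.group, se=se,
        histograms=hists, n_trials=config.n_trials, rule_counts=rule_counts,
        connectivity=np.stack(stacks, axis=0) if keep_connectivity else None,
    )


def _input_records(config: PipelineConfig) -> Iterable[SubjectRecord]:
    if config.cohort is not None:
        cohort = config.cohort
        if config.seed != cohort.seed:
            cohort = replace(cohort, seed=config.seed)
        return iter_cohort(cohort)
    return read_cohort(config.input_dir)


def run_pipeline(config: PipelineConfig,
                 covariates: Optional[pd.DataFrame] = None) -> PipelineResults:
    """Execute the full analysis and return all tables and statistics."""
    t0 = time.time()
    log.info("pipeline start (config hash %s)", config.config_hash())

    subject_results: list[SubjectResult] = []
    n_done = 0
    for record in _input_records(config):
        try:
            res = process_subject(
                record, config, collect_rule_counts=config.run_bin_selection)
        except Exception as exc:
            raise RuntimeError(
                f"stage 'subject-processing' failed for subject "
                f"{record.subject_id!r}: {exc}") from exc
        subject_results.append(res)
        n_done += 1
        if n_done % 10 == 0:
            log.info("processed %d subjects (%.1f s)", n_done, time.time() - t0)
    if not subject_results:
        raise ValidationError("input produced no subjects")
    log.info("connectivity+entropy done for %d subjects", n_done)

    selected = config.n_bins
    if config.run_bin_selection:
        rows = []
        for res in subject_results:
            for band, counts in res.rule_counts.items():
                for rule, ks in counts.items():
                    rows.extend({"band": band, "rule": rule, "k": k} for k in ks)
        df = pd.DataFrame(rows)
        medians = df.groupby(["band", "rule"])["k"].median()
        selected = int(np.ceil(medians.max()))
        log.info("bin-selection protocol chose N = %d", selected)
        if selected != config.n_bins:
            # re-run the histogram/entropy stage at the selected count
            config = replace(config, n_bins=selected)
            subject_results = [
                process_subject(rec, config) for rec in _input_records(config)
            ]

    band_order = [b.label for b in config.bands]
    entropy_rows = []
    hist_rows = []
    hist_by_group: dict[str, list[WeightHistogram]] = {}
    for res in subject_results:
        for band in band_order:
            entropy_rows.append({
                "subject_id": res.subject_id, "group": res.group,
                "band": band, "se": res.se[band],
                "n_trials_averaged": res.n_trials,
            })
            h = res.histograms[band]
            hist_by_group.setdefault(res.group, []).append(h)
            row = {"subject_id": res.subject_id, "group": res.group,
                   "band": band}
            row.update({f"bin_{i:02d}": q for i, q in enumerate(h.q)})
            hist_rows.append(row)
    entropy_table = pd.DataFrame(entropy_rows)
    histogram_table = pd.DataFrame(hist_rows)

    log.info("running statistics")
    stats = analyze_entropy_table(entropy_table, hist_by_group,
                                  alpha=config.alpha, covariates=covariates,
                                  seed=config.seed)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_subjects": len(subject_results),
        "selected_bins": selected,
        "bands": band_order,
        "versions": {
            "connentropy": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "runtime_s": round(time.time() - t0, 2),
    }
    log.info("pipeline done in %.1f s", time.time() - t0)
    return PipelineResults(entropy_table=entropy_table,
                           histogram_table=histogram_table,
                           stats=stats, manifest=manifest,
                           selected_bins=selected,
                           subject_results=subject_results)


def write_report(results: PipelineResults, out_dir: str | Path) -> dict[str, Path]:
    """Persist entropy table, histograms, stats and manifest to ``out_dir``."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ValidationError(f"output directory {out} is not writable: {exc}")
    paths = {
        "entropy_table": out / "entropy_table.csv",
        "histograms": out / "histograms.csv",
        "stats_report_csv": out / "stats_report.csv",
        "stats_report_json": out / "stats_report.json",
        "manifest": out / "manifest.json",
    }
    results.entropy_table.to_csv(paths["entropy_table"], index=False)
    results.histogram_table.to_csv(paths["histograms"], index=False)
    results.stats.to_frame().to_csv(paths["stats_report_csv"], index=False)
    write_json(paths["stats_report_json"], results.stats.to_dict())
    write_json(paths["manifest"], results.manifest)
    return paths


def replay_from_manifest(manifest_path: str | Path) -> PipelineResults:
    """Re-run a pipeline from a persisted manifest (synthetic mode only)."""
    meta = json.loads(Path(manifest_path).read_text())
    cfg = config_from_dict(meta["config"])
    return run_pipeline(cfg)


def config_from_dict(d: Mapping) -> PipelineConfig:
    """Rebuild a :class:`PipelineConfig` from its ``to_dict`` form."""
    from .cohort import CohortConfig, StrataCoupling
    from .containers import BandDefinition

    d = dict(d)
    cohort = d.get("cohort")
    if cohort is not None:
        cohort = dict(cohort)
        cohort["bands"] = tuple(
            BandDefinition(**b) for b in cohort.get("bands", []))
        spec = cohort.get("coupling_spec")
        if isinstance(spec, Mapping) and spec and all(
                isinstance(v, Mapping) for v in spec.values()):
            cohort["coupling_spec"] = {
                g: StrataCoupling(low=tuple(v["low"]), high=tuple(v["high"]),
                                  p_high=v["p_high"])
                for g, v in spec.items()}
        for key in ("group_sizes", "group_labels", "coupled_bands"):
            if cohort.get(key) is not None:
                cohort[key] = tuple(cohort[key])
        d["cohort"] = CohortConfig(**cohort)
    d["bands"] = tuple(BandDefinition(**b) if isinstance(b, Mapping) else b
                       for b in d.get("bands", DEFAULT_BANDS))
    return PipelineConfig(**d)
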
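"""Synthetic cohorts of ROI time series with known envelope coupling.

The generator emulates source-level resting EEG at the study's dimensions
(68 ROIs, 200 Hz, three groups of 45/69/81 subjects, six canonical bands)
with three controllable ingredients:

* **Envelope coupling** — each band-limited carrier (Gaussian noise filtered
  to the band, independent across nodes) is amplitude-modulated by a
  lognormal envelope whose fluctuations span 0.3 Hz up to a band-dependent
  few Hz.  Coupling is imposed by correlating the
  Gaussian log-envelopes across nodes; the correlation is calibrated
  analytically so the *measured* amplitude-envelope correlation of the
  synthesized signals matches the requested target (the lognormal transform
  and the carrier's own Rayleigh envelope fluctuations both attenuate the
  correlation and are inverted in closed form).  The slow fields are
  whitened before mixing, so the realized envelope correlation equals the
  calibrated value exactly rather than up to sampling error.

* **Leakage** — instantaneous linear mixing with a symmetric matrix
  ``I + leakage_mix * G`` shared by the whole cohort, the zero-lag
  cross-talk that pairwise orthogonalization is designed to remove.

* **Group structure** — per-group coupling specifications.  The default
  encodes a low/high coupling dichotomy as a modular network: within-module
  pairs draw targets from a high stratum (within [0.3, 0.6]), cross-module
  pairs from a low stratum (within [0, 0.1]), and the groups differ in the
  dispersion of the coupling-strength distribution through the mixture
  weight of the high stratum (healthy controls have the most high-coupling
  pairs, the dementia group the fewest — a disconnection pattern).  This
  generative model of group differences is an assumption of the package,
  not an established fact about the disease (see the methods note).

For unit-level work, :func:`generate_weight_matrices` draws connectivity
matrices directly from named weight distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence, Union

import numpy as np

from .containers import (
    BandDefinition,
    ConnectivityMatrix,
    DEFAULT_BANDS,
    RoiTimeSeries,
    SubjectRecord,
    ValidationError,
)

# envelope-modulator pass band: low edge above ~1/(trial length) so shared
# modulation is visible within a single 5-s trial; high edge scales with the
# carrier bandwidth (envelopes of band-limited oscillations fluctuate up to
# a few Hz) and stays well below the band itself
MODULATOR_LOW = 0.3
MODULATOR_HIGH_FRACTION = 0.45   # of the carrier bandwidth
MODULATOR_HIGH_CAP = 4.0


def modulator_band(band: BandDefinition) -> tuple[float, float]:
    """Pass band of the amplitude modulator for one analysis band."""
    high = min(MODULATOR_HIGH_FRACTION * band.bandwidth, MODULATOR_HIGH_CAP)
    return (MODULATOR_LOW, max(high, 0.95))

#: log-envelope standard deviation; sets the modulation depth (CV ~ 1.3)
SIGMA_M = 1.0

#: Rayleigh envelope variance/mean^2 ratio of a narrowband Gaussian carrier
_RAYLEIGH_CV2 = (4.0 - np.pi) / np.pi


# ---------------------------------------------------------------------------
# coupling calibration
# ---------------------------------------------------------------------------

def envelope_dilution(sigma_m: float = SIGMA_M) -> float:
    """Attenuation of the modulator correlation by the carrier envelope.

    The measured envelope is (lognormal modulator) x (Rayleigh carrier
    envelope); with independent carriers the Pearson correlation of the
    product envelopes is the modulator correlation divided by this factor.
    """
    v = 1.0 / np.expm1(sigma_m ** 2)  # mean^2 / variance of the lognormal
    return 1.0 + _RAYLEIGH_CV2 * (1.0 + v)


def max_feasible_target(sigma_m: float = SIGMA_M) -> float:
    """Largest measurable envelope correlation the signal model can reach."""
    return 1.0 / envelope_dilution(sigma_m)


def gauss_corr_from_env_corr(r: np.ndarray, sigma_m: float = SIGMA_M) -> np.ndarray:
    """Gaussian log-envelope correlation giving lognormal correlation ``r``."""
    r = np.asarray(r, float)
    return np.log1p(r * np.expm1(sigma_m ** 2)) / sigma_m ** 2


def env_corr_from_gauss_corr(rho: np.ndarray, sigma_m: float = SIGMA_M) -> np.ndarray:
    rho = np.asarray(rho, float)
    return np.expm1(rho * sigma_m ** 2) / np.expm1(sigma_m ** 2)


#: Band-specific retention of the modulator correlation through the analysis
#: chain (within-trial demeaning of the slow field plus clipping of the
#: modulation sidebands by the band filters; narrow bands lose more).
#: Measured once by :func:`calibrate_band_retention` at the model defaults
#: (sigma_m = 1, band-dependent modulator bands, 5-s trials, 200 Hz).
DEFAULT_KAPPA: dict[str, float] = {
    "delta": 0.82, "theta": 0.85, "alpha": 0.88,
    "beta1": 0.92, "beta2": 0.94, "gamma": 0.96,
}
_KAPPA_FALLBACK = 0.85
_RHO_CAP = 0.999


def _kappa(band_label: Optional[str]) -> float:
    if band_label is None:
        return 1.0
    return DEFAULT_KAPPA.get(band_label, _KAPPA_FALLBACK)


def gauss_corr_for_target(target: np.ndarray,
                          band_label: Optional[str] = None,
                          sigma_m: float = SIGMA_M) -> np.ndarray:
    """Calibrated Gaussian log-envelope correlation for a measured-AEC target.

    Inverts ``measured = f(kappa_band * rho) / A`` where ``f`` is the
    lognormal correlation transform, ``A`` the Rayleigh envelope dilution
    and ``kappa_band`` the per-band retention factor.  Targets beyond the
    band's measurable ceiling saturate at the ceiling (rho is capped).
    """
    target = np.asarray(target, float)
    if np.any(target < 0) or np.any(target >= 1):
        raise ValidationError("coupling targets must lie in [0, 1)")
    a = envelope_dilution(sigma_m)
    k = _kappa(band_label)
    r_e = np.minimum(target * a, env_corr_from_gauss_corr(_RHO_CAP * k, sigma_m))
    return np.clip(gauss_corr_from_env_corr(r_e, sigma_m) / k, 0.0, _RHO_CAP)


def target_from_gauss_corr(rho: np.ndarray,
                           band_label: Optional[str] = None,
                           sigma_m: float = SIGMA_M) -> np.ndarray:
    """Inverse of :func:`gauss_corr_for_target` (realized measurable AEC)."""
    k = _kappa(band_label)
    return (env_corr_from_gauss_corr(np.asarray(rho) * k, sigma_m)
            / envelope_dilution(sigma_m))


def feasible_ceiling(band_label: Optional[str] = None,
                     sigma_m: float = SIGMA_M) -> float:
    """Largest trial-averaged AEC the signal model can exhibit in a band."""
    return float(target_from_gauss_corr(np.array(_RHO_CAP), band_label, sigma_m))


# ---------------------------------------------------------------------------
# coupling specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairTargets:
    """Explicit per-pair envelope-correlation targets (symmetric matrix)."""

    matrix: np.ndarray

    def draw_targets(self, n_rois: int, rng: np.random.Generator) -> np.ndarray:
        m = np.asarray(self.matrix, float)
        if m.shape != (n_rois, n_rois):
            raise ValidationError(
                f"coupling_spec.matrix shape {m.shape} != ({n_rois}, {n_rois})")
        if not np.allclose(m, m.T):
            raise ValidationError("coupling_spec.matrix must be symmetric")
        m = m.copy()
        np.fill_diagonal(m, 0.0)
        return m


@dataclass(frozen=True)
class StrataCoupling:
    """Modular low/high coupling strata.

    Nodes are split into modules sized so the fraction of within-module
    pairs is approximately ``p_high``.  Each module's pairs share a target
    drawn uniformly from ``high``; cross-module pair targets are the
    geometric mean of per-node strengths drawn uniformly from ``low``.
    ``p_high = 0`` yields a purely low-coupled network.
    """

    low: tuple[float, float] = (0.01, 0.09)
    high: tuple[float, float] = (0.36, 0.50)
    p_high: float = 0.15

    def __post_init__(self) -> None:
        for name, rng_ in (("low", self.low), ("high", self.high)):
            if not (0 <= rng_[0] <= rng_[1] < 1):
                raise ValidationError(
                    f"coupling_spec.{name} must satisfy 0 <= lo <= hi < 1, "
                    f"got {rng_}")
        if not (0 <= self.p_high < 1):
            raise ValidationError("coupling_spec.p_high must be in [0, 1)")

    def draw_targets(self, n_rois: int, rng: np.random.Generator) -> np.ndarray:
        a = rng.uniform(self.low[0], self.low[1], size=n_rois)
        t = np.sqrt(np.outer(a, a))
        if self.p_high > 0 and n_rois >= 4:
            # module size so that (s-1)/(n-1) ~ p_high
            size = max(2, int(round(1 + self.p_high * (n_rois - 1))))
            n_modules = max(1, n_rois // size)
            labels = rng.permutation(np.arange(n_rois) % n_modules)
            for m in range(n_modules):
                idx = np.where(labels == m)[0]
                if idx.size < 2:
                    continue
                tm = rng.uniform(self.high[0], self.high[1])
                t[np.ix_(idx, idx)] = tm
        np.fill_diagonal(t, 0.0)
        return t


@dataclass(frozen=True)
class NoCoupling:
    """All pair targets zero (independence)."""

    def draw_targets(self, n_rois: int, rng: np.random.Generator) -> np.ndarray:
        return np.zeros((n_rois, n_rois))


CouplingSpec = Union[PairTargets, StrataCoupling, NoCoupling]

#: Default per-group coupling: identical stratum ranges, group-dependent
#: mixture weight of the high stratum (dispersion of coupling strengths
#: confined to the strata) — the low/high-weight dichotomy encoded as an
#: assumption.
DEFAULT_GROUP_COUPLING: dict[str, StrataCoupling] = {
    "control": StrataCoupling(low=(0.01, 0.09), high=(0.36, 0.50), p_high=0.25),
    "mci": StrataCoupling(low=(0.01, 0.09), high=(0.36, 0.50), p_high=0.165),
    "ad": StrataCoupling(low=(0.01, 0.09), high=(0.36, 0.50), p_high=0.08),
}

#: Relative band power of the synthesized broadband signal (1/f-flavoured).
DEFAULT_BAND_PROFILES: dict[str, float] = {
    "delta": 1.0, "theta": 0.7, "alpha": 1.0,
    "beta1": 0.5, "beta2": 0.35, "gamma": 0.25,
}


# ---------------------------------------------------------------------------
# cohort configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of a synthetic cohort.

    Defaults follow the emulated study: three groups of 45/69/81 subjects,
    68 ROIs at 200 Hz, recordings long enough for twenty 5-s trials to
    survive filter-edge trimming.
    """

    group_sizes: tuple[int, ...] = (45, 69, 81)
    group_labels: tuple[str, ...] = ("control", "mci", "ad")
    n_rois: int = 68
    fs: float = 200.0
    duration: float = 120.0
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    band_profiles: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_PROFILES))
    coupling_spec: Union[CouplingSpec, Mapping[str, CouplingSpec], None] = None
    coupled_bands: Optional[tuple[str, ...]] = None
    leakage_mix: float = 0.2
    sigma_m: float = SIGMA_M
    seed: int = 0
    keep_envelopes: bool = False

    def __post_init__(self) -> None:
        if len(self.group_sizes) != len(self.group_labels):
            raise ValidationError(
                "group_sizes and group_labels must have equal length")
        if not all(int(s) >= 2 for s in self.group_sizes):
            raise ValidationError("group_sizes: every group needs >= 2 subjects")
        if self.n_rois < 2:
            raise ValidationError("n_rois must be >= 2")
        top = max(b.high for b in self.bands)
        if self.fs <= 2 * top:
            raise ValidationError(
                f"fs must exceed twice the highest band edge ({top} Hz), "
                f"got fs={self.fs}")
        if self.duration * self.fs < 2 * self.fs:
            raise ValidationError("duration too short")
        if not (0 <= self.leakage_mix < 1):
            raise ValidationError("leakage_mix must be in [0, 1)")
        for label, p in self.band_profiles.items():
            if p < 0:
                raise ValidationError(f"band_profiles[{label!r}] must be >= 0")

    def spec_for(self, group: str) -> CouplingSpec:
        spec = self.coupling_spec
        if spec is None:
            return DEFAULT_GROUP_COUPLING.get(group, StrataCoupling())
        if isinstance(spec, Mapping):
            if group not in spec:
                raise ValidationError(
                    f"coupling_spec has no entry for group {group!r}")
            return spec[group]
        return spec

    @property
    def n_subjects(self) -> int:
        return int(sum(self.group_sizes))


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def _bandlimited_noise(rng: np.random.Generator, n: int, t: int, fs: float,
                       low: float, high: float) -> np.ndarray:
    """Stationary Gaussian noise with a flat spectrum restricted to a band."""
    spec = rng.standard_normal((n, t // 2 + 1)) + 1j * rng.standard_normal(
        (n, t // 2 + 1))
    freqs = np.fft.rfftfreq(t, d=1.0 / fs)
    spec[:, ~((freqs >= low) & (freqs <= high))] = 0.0
    x = np.fft.irfft(spec, n=t, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _exact_corr_field(rng: np.random.Generator, corr: np.ndarray, t: int,
                      fs: float, mod_band: tuple[float, float]) -> np.ndarray:
    """Slow Gaussian field whose *sample* correlation matrix equals ``corr``.

    Independent slow rows are whitened (sample covariance forced to the
    identity) and then mixed with the Cholesky factor of ``corr``, so the
    realized coupling carries no sampling jitter.
    """
    n = corr.shape[0]
    s = _bandlimited_noise(rng, n, t, fs, *mod_band)
    c = (s @ s.T) / t
    s = np.linalg.solve(np.linalg.cholesky(c), s)
    # rows of s now have identity sample covariance
    eps = 1e-10
    l = np.linalg.cholesky(corr + eps * np.eye(n))
    z = l @ s
    z /= z.std(axis=-1, keepdims=True)
    return z


def _psd_correlation(rho: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and restore a unit diagonal."""
    m = rho.copy()
    np.fill_diagonal(m, 1.0)
    vals, vecs = np.linalg.eigh(m)
    if vals.min() >= 1e-10:
        return m
    vals = np.clip(vals, 1e-8, None)
    m = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(m))
    m = m / np.outer(d, d)
    np.fill_diagonal(m, 1.0)
    return m


def _leakage_matrix(rng: np.random.Generator, n: int, lam: float) -> np.ndarray:
    """Symmetric instantaneous mixing matrix ``I + lam * G``."""
    g = rng.standard_normal((n, n)) / np.sqrt(n)
    g = (g + g.T) / 2.0
    np.fill_diagonal(g, 0.0)
    return np.eye(n) + lam * g


def generate_subject(
    config: CohortConfig,
    group: str,
    subject_id: str,
    rng: np.random.Generator,
    leakage: Optional[np.ndarray] = None,
) -> SubjectRecord:
    """Synthesize one subject's broadband ROI recording."""
    n, fs = config.n_rois, config.fs
    t = int(round(config.duration * fs))
    spec = config.spec_for(group)
    targets = spec.draw_targets(n, rng)

    coupled = (set(config.coupled_bands) if config.coupled_bands is not None
               else {b.label for b in config.bands})
    eye = np.eye(n)

    x = np.zeros((n, t))
    envelopes: dict[str, np.ndarray] = {}
    realized: dict[str, np.ndarray] = {}
    for band in config.bands:
        power = float(config.band_profiles.get(band.label, 1.0))
        if power == 0.0:
            continue
        if config.sigma_m == 0.0:
            if np.any(targets > 0):
                raise ValidationError(
                    "sigma_m=0 (unmodulated carriers) cannot realize nonzero "
                    "coupling targets")
            carrier = _bandlimited_noise(rng, n, t, fs, band.low, band.high)
            realized[band.label] = np.zeros((n, n))
            if config.keep_envelopes:
                from scipy.signal import hilbert
                envelopes[band.label] = np.abs(hilbert(carrier, axis=-1))
            x += np.sqrt(power) * carrier
            continue
        if band.label in coupled:
            rho = gauss_corr_for_target(targets, band.label, config.sigma_m)
            np.fill_diagonal(rho, 1.0)
            rho = _psd_correlation(rho)
            corr = rho
            r = target_from_gauss_corr(rho, band.label, config.sigma_m)
            np.fill_diagonal(r, 0.0)
            realized[band.label] = r
        else:
            corr = eye
            realized[band.label] = np.zeros((n, n))
        z = _exact_corr_field(rng, corr, t, fs, modulator_band(band))
        e = np.exp(config.sigma_m * z)
        carrier = _bandlimited_noise(rng, n, t, fs, band.low, band.high)
        sig = e * carrier
        sig /= sig.std(axis=-1, keepdims=True)
        if config.keep_envelopes:
            from scipy.signal import hilbert
            envelopes[band.label] = np.abs(hilbert(sig, axis=-1))
        x += np.sqrt(power) * sig

    if config.leakage_mix > 0:
        if leakage is None:
            leakage = _leakage_matrix(rng, n, config.leakage_mix)
        x = leakage @ x
    x -= x.mean(axis=-1, keepdims=True)

    ts = RoiTimeSeries(data=x, fs=fs, subject_id=subject_id)
    return SubjectRecord(subject_id=subject_id, group=group, timeseries=ts,
                         target_aec=realized, requested_aec=targets,
                         true_envelopes=envelopes or None)


def calibrate_band_retention(
    band: BandDefinition,
    rho: float = 0.75,
    n_recordings: int = 16,
    duration: float = 115.0,
    fs: float = 200.0,
    sigma_m: float = SIGMA_M,
    seed: int = 0,
) -> float:
    """Re-measure the per-band retention factor ``kappa`` empirically.

    Synthesizes signal pairs with a known Gaussian modulator correlation,
    pushes them through the full analysis chain (broadband filter, band
    decomposition, trimming, 5-s trials, orthogonalized AEC) and solves
    ``measured = f(kappa * rho) / A`` for ``kappa``.  The shipped
    :data:`DEFAULT_KAPPA` values were produced this way at the model
    defaults.
    """
    from .connectivity import aec_correlations, band_decompose
    from .preprocess import (DEFAULT_BANDPASS, edge_delay, filter_broadband,
                             segment_trials, trim_edges)

    corr = np.array([[1.0, rho], [rho, 1.0]])
    means = []
    for k in range(n_recordings):
        rng = np.random.default_rng(np.random.SeedSequence((seed, k)))
        t = int(duration * fs)
        z = _exact_corr_field(rng, corr, t, fs, modulator_band(band))
        e = np.exp(sigma_m * z)
        carrier = _bandlimited_noise(rng, 2, t, fs, band.low, band.high)
        sig = e * carrier
        sig /= sig.std(axis=-1, keepdims=True)
        ts = RoiTimeSeries(sig - sig.mean(axis=-1, keepdims=True), fs)
        filtered = band_decompose(filter_broadband(ts), (band,))[band.label]
        filtered = trim_edges(filtered, edge_delay(ts, (DEFAULT_BANDPASS,)))
        trials = segment_trials(filtered, 5.0, 20)
        means.append(np.mean([aec_correlations(tr)[0, 1] for tr in trials]))
    measured = float(np.mean(means))
    r_e = measured * envelope_dilution(sigma_m)
    return float(gauss_corr_from_env_corr(np.array(r_e), sigma_m) / rho)


def iter_cohort(config: CohortConfig) -> Iterator[SubjectRecord]:
    """Yield subjects one at a time (memory-friendly for large cohorts).

    Deterministic for a fixed config seed: each subject gets its own
    substream spawned from the cohort seed, so generation order and
    parallel consumption cannot change the data.
    """
    root = np.random.SeedSequence(config.seed)
    leak_rng = np.random.default_rng(root.spawn(1)[0])
    leakage = (_leakage_matrix(leak_rng, config.n_rois, config.leakage_mix)
               if config.leakage_mix > 0 else None)
    subject_streams = root.spawn(1 + config.n_subjects)[1:]
    k = 0
    for label, size in zip(config.group_labels, config.group_sizes):
        for j in range(int(size)):
            rng = np.random.default_rng(subject_streams[k])
            yield generate_subject(config, label, f"{label}-{j:03d}", rng,
                                   leakage=leakage)
            k += 1


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Materialize the whole cohort (see :func:`iter_cohort`)."""
    return list(iter_cohort(config))


# ---------------------------------------------------------------------------
# direct weight-matrix fixtures
# ---------------------------------------------------------------------------

def _draw_weights(distribution, size: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(distribution, str):
        distribution = (distribution,)
    name, *params = distribution
    if name == "uniform":
        return rng.uniform(0.0, 1.0, size)
    if name == "constant":
        (c,) = params
        if not 0 <= c <= 1:
            raise ValidationError(f"constant weight {c} outside [0, 1]")
        return np.full(size, float(c))
    if name == "beta":
        a, b = params
        return rng.beta(a, b, size)
    if name == "two_point":
        lo, hi, p_hi = params
        if not (0 <= lo <= 1 and 0 <= hi <= 1 and 0 <= p_hi <= 1):
            raise ValidationError(f"two_point parameters out of range: {params}")
        pick = rng.random(size) < p_hi
        return np.where(pick, float(hi), float(lo))
    raise ValidationError(f"unknown weight distribution {name!r}")


def generate_weight_matrices(
    n_nodes: int,
    weight_distribution,
    seed: int,
    n_matrices: int = 1,
) -> list[ConnectivityMatrix]:
    """Symmetric zero-diagonal matrices with i.i.d. upper-triangle weights.

    ``weight_distribution`` is a name or tuple: ``"uniform"``,
    ``("constant", c)``, ``("beta", a, b)`` or ``("two_point", lo, hi, p_hi)``.
    """
    if n_nodes < 2:
        raise ValidationError("n_nodes must be >= 2")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n_nodes, k=1)
    out = []
    for k in range(n_matrices):
        w = np.zeros((n_nodes, n_nodes))
        vals = _draw_weights(weight_distribution, iu[0].size, rng)
        w[iu] = vals
        w = w + w.T
        out.append(ConnectivityMatrix(weights=w, trial_index=k))
    return out
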
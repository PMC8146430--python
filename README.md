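# connentropy

Shannon entropy of functional brain-network weight distributions, computed
from leakage-corrected amplitude-envelope-correlation (AEC) networks.

## The scientific problem

Neurodegeneration progressively rewires functional brain networks.  One way
to quantify this is to look not at individual connections but at the
*distribution* of all connection strengths in a subject's functional
network: a network whose weights are spread evenly over many values carries
a different integration/segregation balance than one whose weights are all
alike.  This package implements, end to end, the pipeline needed to test
such hypotheses on source-level EEG:

1. **Preprocessing** — zero-phase Hamming-window FIR band-pass (1–70 Hz),
   50 Hz band-stop, and segmentation of each recording into its first
   twenty artifact-free 5-s trials.
2. **Connectivity** — per trial and per canonical band
   (δ 1–4, θ 4–8, α 8–13, β₁ 13–19, β₂ 19–30, γ 30–70 Hz), the
   orthogonalized AEC between every pair of the 68 cortical ROI time
   series: the test signal is regressed on the seed at zero lag (removing
   source-leakage cross-talk), amplitude envelopes are taken as the modulus
   of the analytic signal, and envelopes are Pearson-correlated; both
   directions are averaged and mapped into [0, 1].  Per subject this yields
   a 6 × 68 × 68 × 20 array of adjacency matrices.
3. **Weight-distribution entropy** — each matrix's n(n−1)/2 weights are
   histogrammed on [0, 1] into N equal bins (N = 40, bin width 0.025, the
   outcome of a median-over-trials/subjects, maximum-over-rules selection
   protocol across the Scott, Freedman–Diaconis, Integers, Sturges and
   Square-Root rules), and summarized by the normalized Shannon entropy

   SE = −(1 / log₂N) · Σᵢ (qᵢ/Q) · log₂(qᵢ/Q),  Q = Σᵢ qᵢ,

   which is 1 for a uniform weight distribution and 0 when all weights fall
   in a single bin.  Per-trial SE values and histograms are averaged into
   one value and one histogram per subject and band.
4. **Group statistics** — Lilliefors and Levene assumption checks, global
   Kruskal–Wallis tests on SE per band, pairwise Mann–Whitney follow-ups,
   and a bin-by-bin Kruskal–Wallis comparison of the subject-averaged
   histograms identifying *which weight ranges* differ between cohorts —
   all Benjamini–Hochberg FDR-corrected within narrow families.

Because clinical EEG of this kind is not openly deposited, the package
ships a first-class **synthetic-cohort generator**: band-limited Gaussian
carriers amplitude-modulated by correlated lognormal envelopes, with exact,
calibrated control of the per-pair envelope correlation, instantaneous
linear mixing ("leakage") and group-dependent coupling structure.  Its
defaults emulate the study conditions this package targets: three groups of
45/69/81 subjects (healthy elderly controls, mild cognitive impairment, and
dementia), 68 Desikan–Killiany ROIs at 200 Hz.

## Worked example

```python
from connentropy import run_pipeline
from connentropy.cohort import CohortConfig
from connentropy.pipeline import PipelineConfig

cohort = CohortConfig(group_sizes=(5, 5, 5), n_rois=16, duration=115.0,
                      coupled_bands=("delta", "alpha", "beta1"), seed=1)
results = run_pipeline(PipelineConfig(cohort=cohort, seed=1))

print(results.entropy_table.groupby(["band", "group"])["se"]
      .mean().unstack().round(3))
for band in ("delta", "alpha", "beta1"):
    r = results.stats.global_tests[band]
    print(f"{band}: H = {r.statistic:.2f}, FDR-adjusted p = {r.p_adjusted:.4f}")
```

prints

```
group     ad  control    mci
band
alpha  0.757    0.815  0.777
beta1  0.731    0.788  0.765
beta2  0.642    0.638  0.641
delta  0.810    0.846  0.823
gamma  0.567    0.568  0.570
theta  0.748    0.754  0.749

delta: H = 11.18, FDR-adjusted p = 0.0075
alpha: H = 12.50, FDR-adjusted p = 0.0058
beta1: H = 12.50, FDR-adjusted p = 0.0058
```

Group differences were injected (via the default coupling specification)
only in the delta, alpha and beta-1 bands: the dementia group has the
fewest strongly coupled node pairs, so its weight distribution is the least
spread and its SE the lowest; the three affected bands separate sharply
under the Kruskal–Wallis test while theta, beta-2 and gamma stay flat.
`results.stats.bin_tests` then localizes the differences to specific weight
ranges, and `write_report(results, out_dir)` persists the entropy table,
per-subject histograms (columns `bin_00` … `bin_39`, edges 0.000–1.000 in
steps of 0.025), the statistics and a re-runnable manifest.

A command-line interface mirrors the library:

```sh
connentropy simulate --out cohort/ --group-sizes 5,5,5 --n-rois 16 --duration 115
connentropy run-all --input cohort/ --out report/
```

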
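# Methods

## The single-patient testing model

A patient methylome (beta values in [0, 1], one per CpG probe) is compared
with a normative control population measured on the same array. All
statistical testing happens on M values, `M = ln(b/(1−b))`, whose variance
is more homogeneous across the methylation range than beta's. Betas are
clipped to `[ε, 1−ε]` before the logit with ε = 0.001 by default: matrices
are conventionally rounded to 3 digits, so exact 0s and 1s occur and must be
made finite. The clipping bound is our choice; any ε consistent with the
rounding precision gives indistinguishable results away from the boundaries.

Per CpG, the patient value is a single observation tested two-tailed against
the control distribution:

* **Z-score**, `z = (x − μ)/σ`, `p = 2·Φ(−|z|)`, with μ, σ the control mean
  and sample sd — adequate when the normative sample is large;
* **Crawford–Howell**, `t = (x − x̄)/(s·√(1 + 1/n))` on Student t with
  `n − 1` df — the single-case test that accounts for estimating x̄ and s
  from few controls. The automatic rule uses Crawford–Howell below 50
  controls and the Z-score otherwise; callers can override.

Probes with a missing patient value, any missing control value, or a
constant control vector are *untestable*: they are reported as such and
excluded from window aggregation. An optional `sd_floor` can replace σ by
`max(σ, floor)` to guard against sampling artifacts in small control sets;
it defaults to off because no principled universal floor exists.

Per-CpG p-values are Bonferroni-adjusted with the number of testable probes
(the effective array size) for per-probe reporting. Window aggregation
consumes the **raw** p-values: combining values capped at 1 would destroy
the χ² null of the combiner.

## Empirical Brown aggregation

Fisher's combined statistic `X = −2·Σ ln pᵢ` over a k-CpG window is χ²(2k)
only under independence, and neighbouring CpGs are strongly co-methylated.
Brown's method keeps X but matches its first two moments with a scaled χ²:
`p = P(χ²_df ≥ X/c)` with `c = ψvar/(2·ψmean)`, `df = 2·ψmean²/ψvar`,
`ψmean = 2k`.

`ψvar` is estimated empirically from the control M values of the window's
probes. Each probe's control vector is standardized and transformed with the
right-tail empirical proportion, `w = −2·ln(#{values ≥ x}/n)` (floored at
1/n, so finite); under the null each w is marginally χ²₂ with variance 4.
We then set `ψvar = 4k + 2·Σᵢ<ⱼ cov(wᵢ, wⱼ)` with
`cov(wᵢ, wⱼ) = 4·corr(wᵢ, wⱼ)` — the empirical correlation rescaled to the
exact χ²₂ marginal variance. Using the correlation rather than the raw
sample covariance makes the two limiting cases exact at any control count:
independent probes give c = 1, df = 2k (Fisher), and duplicated probes give
c = k, df = 2, so a window of k copies of one probe returns that probe's
p-value unchanged. A c below 1 is capped at 1, so the combined p is never
more liberal than Fisher's in the calling regime.

Numerical notes:

* Constancy of a control vector is detected as max = min, not sd = 0
  (the sd of identical floats is ~1e−16).
* The calibration depends only on controls and is cached and reused across
  patients and across the modified samples of a benchmark run.
* The transform is rank-based, hence one-sided. For two-sided per-CpG tests
  under positive correlation the one-sided w correlation slightly
  *overestimates* the dependence of the two-sided statistics, making the
  combined p mildly conservative — the safe direction for calling. The
  two-moment fit is exact in neither tail; on a null synthetic cohort the
  window p-values are uniform under probe independence (one-sided KS,
  α = 0.01) and, with co-methylated probes (r = 0.3), Brown's false-call
  rate at p ≤ 0.01 stays within 4× nominal where Fisher's is far larger.
* `p = 0` inputs are clipped to 1e−300 before the log.
* The capped-Brown p dominates the Fisher p wherever all per-CpG p ≤ 0.05;
  in the non-significant mid-range of the distribution the scaled-χ² family
  can dip marginally below Fisher — irrelevant for calling, but the reason
  the dominance guarantee is stated for the decision regime only.

## Windows, merging, DMR filters

Candidate windows anchor at every probe of the filtered, sorted manifest:
the maximal run of probes within 1000 bp downstream of the anchor. Anchoring
at probes rather than every bp yields the same merged regions at a fraction
of the work. Candidates with ≥ 4 CpGs are kept; overlapping candidates merge
into maximal regions (probe-set union) and aggregation runs once per merged
region so no probe is double-counted. Coordinates are 0-based half-open
everywhere downstream of manifest reading (manifests themselves are 1-based,
Illumina MAPINFO convention; BED input/output is 0-based); strand is carried
but never used.

A region is a significant DMR when (i) its Brown-aggregated p < 0.01,
(ii) the median over its probes of (patient beta − control mean beta) is at
least 0.10 in absolute value, and (iii) it contains no blacklisted probe.
All regions are returned with flags (including blacklisted ones) so
thresholds can be re-applied and removals audited; `direction` is the sign
of the median difference. Probe filtering drops sex and mitochondrial
chromosomes and probes with missing annotation before any testing.

For a fixed list of regions of interest (e.g. known imprinted loci), the
same machinery scores each region over all testable probes inside it, with
a region-level Bonferroni adjustment over the number of regions tested;
regions without testable probes are reported untestable rather than dropped.

## Semi-simulation benchmark

Ground truth is fabricated inside a real (or synthetic) control matrix:

1. **Fixed windows.** Adjacent probes are grouped greedily into
   non-overlapping k-CpG windows with span ≤ 1000 bp (a window whose k-run
   is wider advances one probe and retries). Fixed windows, unlike the
   merged rolling windows of the caller, give every candidate the same
   number of CpGs — the benchmark isolates one variable at a time.
2. **Truth labels.** Each chromosome's probe-covered span is cut into 1000
   equal segments; 10% are selected at random. Windows overlapping a
   selected segment are the true DMRs. Windows with any missing control
   value (or a constant control vector) leave both candidate and truth sets.
3. **Modification.** 10 randomly chosen samples are modified and tested
   against a subsample of the remaining controls. Every probe of a modified
   sample receives a Gaussian noise shift N(noise, 0.005); probes inside
   true windows receive a Gaussian signal shift N(signal, 0.005) *instead*,
   so the net methylation defect of a true window over the background is
   signal − noise. Shifts are subtracted when beta > 0.5 and added
   otherwise, then clipped to [0, 1] — the boundary-avoiding direction rule
   (`direction="literal"` would implement the opposite reading; we do not
   expose it because it drives values out of range, defeating the rule's
   purpose).
4. **Scoring.** Per-CpG tests (automatic Z / Crawford–Howell selection by
   control count) on M values, Brown aggregation per window, windows ranked
   by aggregated p. Detection is summarized by the area under the
   precision–recall curve (trapezoid over recall, ties grouped) and the ROC
   AUC, averaged over the 10 modified samples. PR-AUC is the headline
   metric because true windows are ~10% of candidates.

Randomness derives from one master seed through named substreams in a fixed
order (sample selection, segment selection, per-sample noise, per-sample
signal), so runs are bit-reproducible. Parameter sweeps enumerate the
Cartesian grid with seeds `base + index`.

## The synthetic control cohort

The generator emulates a large blood-derived array cohort at ~20,000 probes
so the benchmark runs on one CPU in seconds per setting:

* **Landscape.** 45% hypomethylated probes (mean beta U(0.03, 0.15)), 40%
  hypermethylated (U(0.85, 0.97)), 15% intermediate (U(0.30, 0.70)).
* **Variability.** Per-probe beta sd = 0.012 + Gamma(shape 3, mean 0.018):
  a technical-noise floor of ~1.2% — array measurement error keeps real
  probes from being arbitrarily stable — plus a biological tail reaching
  ~8%. Mean sd ≈ 0.03, matching the target control-cohort statistic; the
  realized mean normalized Shannon entropy is ≈ 0.19 (target band ≤ 0.25).
* **Co-methylation.** Probes in the same cluster share a latent Gaussian
  factor with loading √0.3, giving intra-cluster pairwise r ≈ 0.3 — the
  level observed in clustered functional regions (CpG islands, imprinted
  regions, enhancers) and the dependence Brown aggregation exists to absorb.
* **Geometry.** Clusters of 3–10 probes with 20–200 bp internal gaps,
  separated by 2–20 kb, across 4 autosomes, so rolling and fixed window
  construction are both exercised.
* Values are Gaussian around the probe mean (consistent with the benchmark's
  additive-Gaussian shift model), clipped to [0, 1] and rounded to 3 digits.
  Everything is a pure function of (spec, seed); calibration statistics are
  enforced as test assertions with tolerance bands, not generator
  constraints.

### What the synthetic cohort does and does not show

Benchmark results on this cohort reproduce the qualitative landscape of the
method on real data — near-perfect detection of ≥ 20% defects over 5% noise,
intermediate power for net 5% defects, a window-size plateau at 4 CpGs, and
a control-size curve saturating around 20–30 controls (PR-AUC ≈ 0.91 at 5
controls, ≈ 0.99 at 20) — and most quantitative operating points land
within a few points of values measured on real cohorts.

Two settings are systematically harder on the synthetic cohort than reported
for real data: single-CpG windows (k = 1) and the high-noise weak-signal
pair (signal 15% / noise 10%). Both are maximally sensitive to the
*dispersion* of per-probe variability — with no window averaging, a
background probe with floor-level sd under a 10% noise shift outranks a true
probe with tail-level sd — and the dispersion *shape* of a real cohort is
not identified by the mean-sd and mean-entropy statistics the generator is
calibrated to. A dispersion-free cohort would not fix this: it would invert
the observed ordering of the two weak-signal settings (the convexity of
−2·ln p makes the high-noise pair easier when all probes share one sd). We
therefore report these two settings as a known limitation of the synthetic
substitution rather than re-fitting the generator to the benchmark outputs.
The synthetic cohort also omits batch effects, probe-chemistry (Infinium
I/II) differences, and non-Gaussian population tails; passing benchmarks
here demonstrate correctness and ranking behaviour of the implementation,
not clinical operating characteristics.

## Defaults worth knowing

| Parameter | Default | Meaning |
| --- | --- | --- |
| `epsilon` | 0.001 | beta clipping before logit (matches 3-digit rounding) |
| test-selection threshold | 50 controls | Crawford–Howell below, Z-score at/above |
| `span` | 1000 bp | rolling/fixed window extent |
| `min_cpgs` / `cpgs_per_window` | 4 | window occupancy (benchmark plateau) |
| `p_threshold` | 0.01 | aggregated-p significance cutoff |
| `effect_threshold` | 0.10 | minimum absolute median Δbeta |
| `sd_floor` | 0 (off) | optional per-probe σ floor for tiny control sets |
| `shift_sd` | 0.005 | sd of the benchmark's Gaussian shifts |
| `n_segments_per_chrom` / fraction | 1000 / 0.1 | truth-region segmentation |

Degenerate inputs are handled explicitly: empty p-vectors, constant probes,
regions without probes, degenerate benchmark labels and too-small control
pools raise structured errors naming the violated rule; untestable probes
and blacklisted regions are flagged, never silently dropped.
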
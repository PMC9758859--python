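# solodmr

Single-patient detection of differentially methylated regions (DMRs) on
methylation arrays.

Canonical DMR pipelines compare groups of cases against groups of controls.
That breaks down for rare diseases — imprinting disorders, multi-locus
imprinting disturbances (MLID), heterogeneous neurodevelopmental syndromes —
where cohorts are tiny and each patient may carry a different set of
epivariants. `solodmr` scores **one patient against a normative control
population**, probe by probe and region by region:

1. **Per-CpG outlier test** on M values (logit of beta). With *n* controls,
   each patient value *x* is tested two-tailed against the control
   distribution, using the Z-score `z = (x − μ)/σ` when *n* ≥ 50 and the
   Crawford–Howell single-case t test
   `t = (x − x̄) / (s·√(1 + 1/n))`, df = *n* − 1, for smaller normative
   samples. Per-CpG p-values are Bonferroni-adjusted using the array size.
2. **Region aggregation with the Empirical Brown method.** Neighbouring CpGs
   are co-methylated, so Fisher's statistic `X = −2·Σ ln pᵢ` over a window of
   *k* CpGs does not follow χ²(2k). Brown's correction refers `X/c` to
   χ²(df), with `c = ψvar/(2·ψmean)` and `df = 2·ψmean²/ψvar` estimated
   empirically from the **controls only**: each probe's control vector is
   transformed by `w = −2·ln(P̂(X ≥ x))` and `ψvar = 4k + 2·Σᵢ<ⱼ cov(wᵢ, wⱼ)`.
   The calibration never sees the patient, so it is reusable across patients.
3. **Windows and filters.** Rolling 1000-bp windows with ≥ 4 CpGs are merged
   into maximal regions; a region is a significant DMR when its aggregated
   p < 0.01, the median patient-minus-control-mean beta difference is at
   least 10 percentage points, and it contains no blacklisted CpG (probes
   associated with BMI, age, smoking or ethnicity).

The package also ships the two companion analyses: a **semi-simulation
benchmark** (insert known Gaussian methylation shifts into a control matrix,
score detection by precision–recall AUC) and **control-cohort
characterization** (distance-binned co-methylation with Fisher-z mean
correlation, per-probe sd and normalized Shannon entropy), plus a synthetic
cohort generator so everything is testable without any data download.

## Worked example

Implant a 30% methylation shift into a 5-probe cluster of a synthetic
patient and recover it genome-wide:

```python
import numpy as np
from solodmr import fixtures, dmr_calling
from solodmr.methylome_io import RegionSet

spec = fixtures.FixtureSpec(n_probes=3000, n_samples=150, seed=33)
manifest = fixtures.make_manifest(spec)
controls = fixtures.make_controls(spec, manifest)

region = RegionSet("implant", [("chr1", 447002, 447424)])  # a 5-probe cluster
patient, modified = fixtures.make_patient(
    controls, manifest, region, shift=0.30, seed=7, spec=spec
)
dmrs = dmr_calling.call_dmrs(patient, controls, manifest)
for d in dmrs:
    if d.significant:
        print(f"significant DMR {d.window.chrom}:{d.window.start}-{d.window.end} "
              f"n_probes={d.n_probes} p={d.p_aggregated:.2e} "
              f"median_delta_beta={d.median_delta_beta:+.3f} direction={d.direction}")
```

prints exactly one hit — the implanted region:

```
significant DMR chr1:447002-447424 n_probes=5 p=7.57e-28 median_delta_beta=+0.300 direction=hyper
```

Of the 401 candidate regions scanned, only the implanted one passes the
aggregated-p (< 0.01) and effect-size (≥ 10%) thresholds: the Brown p-value
says the five probes are jointly far outside the control distribution, and
`median_delta_beta = +0.300` is the implanted effect on the beta scale
(direction `hyper` = patient more methylated than controls).

The same runs from the shell:

```sh
solo-dmr fixtures --probes 2000 --samples 120 --seed 3 --out-dir demo
solo-dmr call --beta demo/beta.tsv --manifest demo/manifest.csv \
    --patient S0000 --out demo/dmrs.tsv
solo-dmr simulate --beta demo/beta.tsv --manifest demo/manifest.csv \
    --signal 0.3 --noise 0.05 --k 4 --n-controls 100 --seed 3 --out demo/sweep.tsv
solo-dmr characterize --beta demo/beta.tsv --manifest demo/manifest.csv \
    --regions example=demo/regions.bed --out demo/profile.tsv
```

The `simulate` run above reports `mean_pr_auc = 0.992` over 385 fixed 4-CpG
windows (53 of them true), i.e. inserted 30%-shift DMRs are ranked almost
perfectly above the 5% background noise. Every command writes a
`<out>.run.json` sidecar recording the effective parameters and version.

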
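"""Descriptive statistics of a control population.

Two complementary views of how CpG methylation behaves across unaffected
individuals:

* co-methylation — Pearson correlation between probe pairs inside the same
  annotated interval, binned by genomic distance, with Fisher-z averaging of
  correlation coefficients (justifies a dependence-aware p-value combiner);
* per-probe stability — standard deviation of beta and normalized Shannon
  entropy (10 bins on [0, 1], normalized by ln 10 to lie in [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .methylome_io import BetaMatrix, MethylomeError, ProbeManifest, RegionSet

__all__ = [
    "CorrelationProfile",
    "EntropySummary",
    "pairwise_correlation_profile",
    "fisher_z_mean",
    "shannon_entropy",
    "variability_summary",
]

_ATANH_CLIP = 1 - 1e-7


@dataclass
class CorrelationProfile:
    region_set_name: str
    bins: list[tuple[int, int]]
    correlations: list[np.ndarray]  # per bin, the pairwise r values
    mean_r: list[float]  # Fisher-z mean per bin

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_set": self.region_set_name,
                "dist_lo": [b[0] for b in self.bins],
                "dist_hi": [b[1] for b in self.bins],
                "n_pairs": [len(r) for r in self.correlations],
                "mean_r": self.mean_r,
                "mean_r2": [
                    float(np.mean(r**2)) if len(r) else np.nan
                    for r in self.correlations
                ],
            }
        )


@dataclass
class EntropySummary:
    per_probe: pd.DataFrame  # columns sd_beta, entropy (+ chrom)
    by_region_set: pd.DataFrame
    by_chromosome: pd.DataFrame


def fisher_z_mean(rs) -> float:
    """tanh(mean(atanh(r))); r = ±1 clipped to ±(1 − 1e−7). Empty input → NaN."""
    r = np.asarray(rs, dtype=float)
    r = r[~np.isnan(r)]
    if r.size == 0:
        return float("nan")
    if np.any(np.abs(r) > 1 + 1e-9):  # tolerate float noise on exact ±1
        raise MethylomeError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(r, -_ATANH_CLIP, _ATANH_CLIP))
    return float(np.tanh(z.mean()))


def shannon_entropy(values, n_bins: int = 10) -> float:
    """Normalized Shannon entropy of a beta vector.

    Histogram over ``n_bins`` equal bins on [0, 1] (last bin right-closed);
    H = −Σ f·ln f over occupied bins; normalized by ln(n_bins). Missing
    values are dropped; an all-missing vector yields NaN.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return float("nan")
    counts, _ = np.histogram(v, bins=n_bins, range=(0.0, 1.0))
    f = counts[counts > 0] / counts.sum()
    return float(-(f * np.log(f)).sum() / np.log(n_bins))


def _probes_in_interval(df_man: pd.DataFrame, chrom: str, start: int, end: int) -> pd.Index:
    on = df_man["chrom"] == chrom
    pos = df_man["pos"]
    return df_man.index[on & (pos > start) & (pos <= end)]


def pairwise_correlation_profile(
    beta: BetaMatrix,
    manifest: ProbeManifest,
    regions: RegionSet,
    max_distance: int = 2000,
    bin_width: int = 200,
) -> CorrelationProfile:
    """Distance-binned co-methylation within annotated intervals.

    A pair belongs to the profile when both probes fall inside the same
    interval of the region set and lie within ``max_distance`` bp of each
    other. Pearson r is computed across samples (pairwise-complete); probes
    constant across samples are skipped.
    """
    if beta.shape[1] < 3:
        raise MethylomeError("correlation profile needs at least 3 samples")
    df_man = manifest.sorted().data
    df_man = df_man.loc[df_man.index.isin(beta.probe_ids)]
    edges = np.arange(0, max_distance + bin_width, bin_width)
    n_bins = len(edges) - 1
    per_bin: list[list[float]] = [[] for _ in range(n_bins)]
    seen: set[tuple[str, str]] = set()
    for chrom, start, end in regions:
        probes = _probes_in_interval(df_man, chrom, start, end)
        if len(probes) < 2:
            continue
        pos = df_man.loc[probes, "pos"].to_numpy(int)
        sub = beta.data.loc[probes]
        valid = sub.std(axis=1, skipna=True) > 0
        corr = sub.T.corr(min_periods=3)  # pairwise-complete Pearson
        for a in range(len(probes)):
            if not valid.iloc[a]:
                continue
            for b in range(a + 1, len(probes)):
                d = pos[b] - pos[a]
                if d > max_distance:
                    break
                if not valid.iloc[b]:
                    continue
                key = (probes[a], probes[b])
                if key in seen:  # overlapping intervals: count a pair once
                    continue
                seen.add(key)
                r = corr.iat[a, b]
                if np.isnan(r):
                    continue
                per_bin[min(d // bin_width, n_bins - 1)].append(r)
    bins = [(int(edges[i]), int(edges[i + 1])) for i in range(n_bins)]
    correlations = [np.asarray(b, dtype=float) for b in per_bin]
    return CorrelationProfile(
        region_set_name=regions.name,
        bins=bins,
        correlations=correlations,
        mean_r=[fisher_z_mean(r) for r in correlations],
    )


def variability_summary(
    beta: BetaMatrix,
    manifest: ProbeManifest,
    region_sets: list[RegionSet] | None = None,
) -> EntropySummary:
    """Per-probe sd and normalized entropy, with region-set and chromosome means."""
    vals = beta.data.to_numpy(dtype=float)
    sd = np.nanstd(vals, axis=1, ddof=1)
    ent = np.array([shannon_entropy(row) for row in vals])
    per_probe = pd.DataFrame(
        {"sd_beta": sd, "entropy": ent}, index=beta.probe_ids
    )
    man = manifest.data.loc[manifest.probe_ids.isin(beta.probe_ids)]
    per_probe["chrom"] = man["chrom"].reindex(per_probe.index)

    by_chrom = (
        per_probe.groupby("chrom", observed=True)[["sd_beta", "entropy"]]
        .mean()
        .reset_index()
    )
    rows = []
    for rs in region_sets or []:
        member = pd.Index([], dtype=per_probe.index.dtype)
        for chrom, start, end in rs:
            member = member.union(_probes_in_interval(man, chrom, start, end))
        sub = per_probe.loc[per_probe.index.isin(member)]
        rows.append(
            {
                "region_set": rs.name,
                "n_probes": len(sub),
                "mean_sd_beta": float(sub["sd_beta"].mean()) if len(sub) else np.nan,
                "mean_entropy": float(sub["entropy"].mean()) if len(sub) else np.nan,
            }
        )
    by_region = pd.DataFrame(
        rows, columns=["region_set", "n_probes", "mean_sd_beta", "mean_entropy"]
    )
    return EntropySummary(per_probe=per_probe, by_region_set=by_region, by_chromosome=by_chrom)
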
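"""Synthetic control populations for testing and benchmarking.

The generator emulates the statistical fingerprint of a large blood-derived
EPIC-array control cohort, at reduced probe count:

* a bimodal methylation landscape — most probes hypo- (beta ≈ 0.03–0.15) or
  hyper-methylated (beta ≈ 0.85–0.97), a minority at intermediate levels;
* per-probe population variability averaging ~3% of beta, modelled as a
  technical-noise floor (1.2%) plus a Gamma-distributed biological tail, so
  no probe is unrealistically stable and a minority are quite variable; this
  yields a mean normalized Shannon entropy around 0.16–0.19;
* co-methylation: probes within the same cluster share a latent factor
  giving pairwise Pearson r ≈ 0.3, the level reported for clustered
  functional regions (CpG islands, imprinted regions, enhancers) — the
  dependence the Brown aggregation step exists to absorb;
* probes arranged in CpG-island-like clusters (20–200 bp between neighbours)
  separated by kb-scale gaps, so both rolling and fixed windows are
  exercised.

Sample values are Gaussian around the probe mean, clipped to [0, 1] and
rounded to 3 digits, matching the additive-Gaussian shift model used by the
semi-simulation. Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .methylome_io import BetaMatrix, ProbeManifest, RegionSet
from .semisim import apply_shift

__all__ = [
    "FixtureSpec",
    "make_manifest",
    "make_controls",
    "make_patient",
    "probe_params",
    "cluster_ids",
]


@dataclass(frozen=True)
class FixtureSpec:
    n_probes: int = 20000
    n_samples: int = 550
    frac_low: float = 0.45
    frac_high: float = 0.40
    frac_mid: float = 0.15
    mean_sd_beta: float = 0.03
    sd_floor_beta: float = 0.012  # technical-noise floor of per-probe sd
    sd_tail_shape: float = 3.0  # Gamma shape of the biological sd tail
    comethylation_rho: float = 0.3  # pairwise r between probes of a cluster
    n_chromosomes: int = 4
    cluster_size_range: tuple[int, int] = (3, 10)
    intra_gap_range: tuple[int, int] = (20, 200)
    inter_gap_range: tuple[int, int] = (2000, 20000)
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.frac_low + self.frac_high + self.frac_mid
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {total}")
        if not 0 < self.mean_sd_beta < 0.1:
            raise ValueError("mean_sd_beta must be in (0, 0.1)")
        if not 0 <= self.sd_floor_beta < self.mean_sd_beta:
            raise ValueError("sd_floor_beta must be in [0, mean_sd_beta)")
        if not 0 <= self.comethylation_rho < 1:
            raise ValueError("comethylation_rho must be in [0, 1)")


def _seeds(spec: FixtureSpec) -> list[np.random.SeedSequence]:
    # fixed spawn order: manifest, probe params, control draws
    return np.random.SeedSequence(spec.seed).spawn(3)


def make_manifest(spec: FixtureSpec) -> ProbeManifest:
    """Clustered autosomal probe map, deterministic under the spec seed."""
    rng = np.random.default_rng(_seeds(spec)[0])
    per_chrom = np.full(spec.n_chromosomes, spec.n_probes // spec.n_chromosomes)
    per_chrom[: spec.n_probes % spec.n_chromosomes] += 1
    chroms, positions = [], []
    lo_sz, hi_sz = spec.cluster_size_range
    for ci, count in enumerate(per_chrom, start=1):
        pos = 10_000
        placed = 0
        while placed < count:
            size = min(int(rng.integers(lo_sz, hi_sz + 1)), count - placed)
            for _ in range(size):
                chroms.append(f"chr{ci}")
                positions.append(pos)
                pos += int(rng.integers(*spec.intra_gap_range))
                placed += 1
            pos += int(rng.integers(*spec.inter_gap_range))
    ids = [f"cg{i:08d}" for i in range(spec.n_probes)]
    df = pd.DataFrame(
        {
            "chrom": pd.array(chroms, dtype="string"),
            "pos": pd.array(positions, dtype="Int64"),
            "strand": np.where(np.arange(spec.n_probes) % 2 == 0, "+", "-"),
        },
        index=pd.Index(ids, name="probe_id"),
    )
    return ProbeManifest(df)


def cluster_ids(manifest: ProbeManifest, max_gap: int = 200) -> np.ndarray:
    """Integer cluster label per probe (manifest order): a new cluster starts
    at each chromosome change or same-chromosome gap larger than ``max_gap``."""
    df = manifest.data
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy(dtype=float)
    new = np.ones(len(df), dtype=bool)
    if len(df) > 1:
        same_chrom = chrom[1:] == chrom[:-1]
        close = (pos[1:] - pos[:-1]) <= max_gap
        new[1:] = ~(same_chrom & close)
    return np.cumsum(new) - 1


def probe_params(spec: FixtureSpec) -> pd.DataFrame:
    """Per-probe generative parameters (mean beta and sd), shared by
    :func:`make_controls` and :func:`make_patient`."""
    rng = np.random.default_rng(_seeds(spec)[1])
    stratum = rng.choice(
        3, size=spec.n_probes, p=[spec.frac_low, spec.frac_high, spec.frac_mid]
    )
    mean = np.empty(spec.n_probes)
    mean[stratum == 0] = rng.uniform(0.03, 0.15, (stratum == 0).sum())
    mean[stratum == 1] = rng.uniform(0.85, 0.97, (stratum == 1).sum())
    mean[stratum == 2] = rng.uniform(0.30, 0.70, (stratum == 2).sum())
    tail_mean = spec.mean_sd_beta - spec.sd_floor_beta
    sd = spec.sd_floor_beta + rng.gamma(
        spec.sd_tail_shape, tail_mean / spec.sd_tail_shape, spec.n_probes
    )
    ids = [f"cg{i:08d}" for i in range(spec.n_probes)]
    return pd.DataFrame({"mean": mean, "sd": sd}, index=pd.Index(ids, name="probe_id"))


def _draw_columns(
    params: pd.DataFrame,
    clusters: np.ndarray,
    rho: float,
    n_cols: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent-factor draws: value = mean + sd·(√rho·g_cluster + √(1−rho)·e),
    clipped to [0, 1] and rounded to 3 digits."""
    n_probes = len(params)
    shared = rng.normal(size=(clusters.max() + 1, n_cols))
    indiv = rng.normal(size=(n_probes, n_cols))
    z = np.sqrt(rho) * shared[clusters] + np.sqrt(1 - rho) * indiv
    values = params["mean"].to_numpy()[:, None] + params["sd"].to_numpy()[:, None] * z
    return np.clip(values, 0.0, 1.0).round(3)


def make_controls(spec: FixtureSpec, manifest: ProbeManifest | None = None) -> BetaMatrix:
    """Control beta matrix. Realized mean per-probe sd lands near
    ``spec.mean_sd_beta`` (boundary clipping shrinks it slightly)."""
    if manifest is None:
        manifest = make_manifest(spec)
    params = probe_params(spec)
    clusters = cluster_ids(manifest, max_gap=spec.intra_gap_range[1])
    rng = np.random.default_rng(_seeds(spec)[2])
    values = _draw_columns(params, clusters, spec.comethylation_rho, spec.n_samples, rng)
    samples = pd.Index([f"S{j:04d}" for j in range(spec.n_samples)], name="sample_id")
    return BetaMatrix(pd.DataFrame(values, index=params.index, columns=samples))


def make_patient(
    controls: BetaMatrix,
    manifest: ProbeManifest,
    dmr_regions: RegionSet,
    shift: float,
    seed: int,
    spec: FixtureSpec,
    shift_sd: float = 0.005,
) -> tuple[pd.Series, list[str]]:
    """One fresh draw from the control generative model with a methylation
    shift applied inside ``dmr_regions``.

    Returns (patient beta column, ids of shifted probes). The shift direction
    follows the boundary-avoiding rule (subtract when beta > 0.5, add
    otherwise), so a hypermethylated region shifts down (hypo call) and vice
    versa.
    """
    params = probe_params(spec).loc[controls.probe_ids]
    clusters = cluster_ids(
        manifest.subset(controls.probe_ids), max_gap=spec.intra_gap_range[1]
    )
    ss = np.random.SeedSequence(seed).spawn(2)
    values = _draw_columns(
        params, clusters, spec.comethylation_rho, 1, np.random.default_rng(ss[0])
    )[:, 0]
    patient = pd.Series(values, index=controls.probe_ids, name="patient")

    df = manifest.data.loc[manifest.probe_ids.isin(controls.probe_ids)]
    modified: list[str] = []
    for chrom, start, end in dmr_regions:
        on = df.index[
            (df["chrom"] == chrom) & (df["pos"] > start) & (df["pos"] <= end)
        ]
        modified.extend(on)
    if modified and shift > 0:
        shifted = apply_shift(
            patient.loc[modified].to_numpy(float), shift, shift_sd,
            np.random.default_rng(ss[1]),
        )
        patient.loc[modified] = shifted.round(3)
    return patient, modified
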